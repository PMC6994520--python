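"""Four-concentric-sphere volume conductor and analytic dipole lead fields.

The head is modelled as four concentric spherical shells (inner to outer:
white matter, gray matter, skull, scalp), each with a homogeneous isotropic
conductivity.  A current dipole inside the innermost sphere produces a scalp
potential that is computed by a Legendre-series expansion: the free-medium
dipole potential is expanded in spherical harmonics about the sphere center,
and for every harmonic degree ``n`` the radial boundary-value problem across
the shells is solved exactly (continuity of potential and of radial current
at each interface, zero radial current at the scalp surface).

Coordinates are RAS millimetres throughout with the sphere center at the
origin by default; dipole moments are in nA*m and potentials in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ShellHeadModel",
    "DipoleSource",
    "ElectrodeMontage",
    "LeadField",
    "build_head_model",
    "leadfield_potential",
    "compute_leadfield",
    "simulate_scalp_topography",
    "coregister_affine",
    "fibonacci_sphere",
]

# Conductivities reported for the adult head (S/m), inner -> outer:
# white matter, gray matter, skull, scalp.
DEFAULT_CONDUCTIVITIES = (0.14, 0.33, 0.01, 0.43)
# Shell radii are a standard adult head geometry choice (mm), inner -> outer.
DEFAULT_RADII = (78.0, 80.0, 86.0, 92.0)

# Unit bookkeeping: positions mm, moments nA*m, potentials uV.
# V[V] = m[A*m] * g / (sigma[S/m] * R[m]^2); with mm and nA*m the factor
# 1e-9 / 1e-6 = 1e-3 converts to volts, i.e. 1e3 to microvolts.
_UNIT_SCALE = 1e3


class HeadModelError(ValueError):
    """Invalid head-model geometry or source placement."""


@dataclass(frozen=True)
class ShellHeadModel:
    """Concentric-sphere volume conductor.

    Parameters
    ----------
    radii
        Four strictly increasing shell radii in mm, inner to outer.
    conductivities
        Four shell conductivities in S/m, inner to outer.
    center
        Sphere center in mm.
    """

    radii: tuple[float, float, float, float] = DEFAULT_RADII
    conductivities: tuple[float, float, float, float] = DEFAULT_CONDUCTIVITIES
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        cond = np.asarray(self.conductivities, dtype=float)
        if radii.shape != (4,):
            raise HeadModelError(f"expected 4 shell radii, got {radii.shape}")
        if cond.shape != (4,):
            raise HeadModelError(f"expected 4 conductivities, got {cond.shape}")
        if not np.all(np.diff(radii) > 0):
            raise HeadModelError(f"shell radii must be strictly increasing, got {tuple(radii)}")
        if not np.all(radii > 0):
            raise HeadModelError("shell radii must be positive")
        if not np.all(cond > 0):
            raise HeadModelError(f"conductivities must be positive, got {tuple(cond)}")
        object.__setattr__(self, "radii", tuple(radii))
        object.__setattr__(self, "conductivities", tuple(cond))
        object.__setattr__(self, "center", tuple(np.asarray(self.center, dtype=float)))

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    @property
    def brain_radius(self) -> float:
        """Radius of the innermost sphere, the admissible source region."""
        return self.radii[0]

    def contains_source(self, position: np.ndarray, tol: float = 1e-9) -> bool:
        r = np.linalg.norm(np.asarray(position, float) - self.center)
        return r < self.radii[0] - tol


def build_head_model(
    radii: Sequence[float] = DEFAULT_RADII,
    conductivities: Sequence[float] = DEFAULT_CONDUCTIVITIES,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> ShellHeadModel:
    """Validate and construct a :class:`ShellHeadModel`."""
    return ShellHeadModel(tuple(radii), tuple(conductivities), tuple(center))


@dataclass(frozen=True)
class DipoleSource:
    """Current dipole: position (mm), unit orientation, moment (nA*m)."""

    position: tuple[float, float, float]
    orientation: tuple[float, float, float]
    moment: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        ori = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(ori)
        if nrm == 0:
            raise HeadModelError("dipole orientation must be a nonzero vector")
        object.__setattr__(self, "position", tuple(pos))
        object.__setattr__(self, "orientation", tuple(ori / nrm))

    @classmethod
    def radial(cls, position: Sequence[float], moment: float = 1.0,
               center: Sequence[float] = (0.0, 0.0, 0.0)) -> "DipoleSource":
        """Dipole oriented radially outward from the sphere center."""
        pos = np.asarray(position, float)
        d = pos - np.asarray(center, float)
        return cls(tuple(pos), tuple(d / np.linalg.norm(d)), moment)

    @property
    def moment_vector(self) -> np.ndarray:
        return self.moment * np.asarray(self.orientation)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels, 3-D positions (mm) and fiducial landmarks."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) mm
    fiducials: dict = field(default_factory=dict)  # Nasion/LPA/RPA -> 3-vector
    reference_scheme: str = "mastoid-average"

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise HeadModelError(f"positions must be (n, 3), got {pos.shape}")
        if len(labels) != pos.shape[0]:
            raise HeadModelError("labels and positions length mismatch")
        if len(set(labels)) != len(labels):
            raise HeadModelError("electrode labels must be unique")
        if self.reference_scheme not in ("mastoid-average", "common-average"):
            raise HeadModelError(f"unknown reference scheme {self.reference_scheme!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not in montage") from exc

    def picks(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=int)

    def subset(self, labels: Sequence[str]) -> "ElectrodeMontage":
        """Montage restricted to the given channels, in the given order."""
        idx = self.picks(labels)
        return replace(self, labels=tuple(labels), positions=self.positions[idx])

    def projected_to_sphere(self, model: ShellHeadModel) -> "ElectrodeMontage":
        """Return a copy with positions projected radially onto the scalp sphere."""
        c = np.asarray(model.center)
        d = self.positions - c
        r = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(r == 0):
            raise HeadModelError("electrode at sphere center cannot be projected")
        return replace(self, positions=c + d / r * model.scalp_radius)


@dataclass(frozen=True)
class LeadField:
    """Gain matrix: electrodes x (n_sources * 3), microvolt per nA*m.

    Columns are ordered source-major: (src0_x, src0_y, src0_z, src1_x, ...).
    """

    gain: np.ndarray
    source_positions: np.ndarray  # (n_sources, 3) mm
    labels: tuple[str, ...]
    reference_scheme: str = "common-average"

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]

    def for_source(self, i: int) -> np.ndarray:
        """(n_electrodes, 3) gain block of source ``i``."""
        return self.gain[:, 3 * i:3 * i + 3]


# ---------------------------------------------------------------------------
# Series solution
# ---------------------------------------------------------------------------

def _scalp_transfer_coefficients(model: ShellHeadModel, n_max: int) -> np.ndarray:
    """Per-degree transfer factor of the shell stack.

    For harmonic degree ``n`` the dipole contributes a source potential
    ``rho^-(n+1)`` (radii normalized to the scalp radius) inside the
    innermost shell.  This solves the radial boundary-value problem and
    returns ``g[n-1]`` = potential at the scalp surface for a unit source
    coefficient, n = 1..n_max.

    In the equal-conductivity limit the stack reduces to a homogeneous
    sphere with insulating boundary, for which g_n = (2n + 1) / n.
    """
    radii = np.asarray(model.radii) / model.scalp_radius  # x1..x4, x4 = 1
    sigma = np.asarray(model.conductivities)
    x = np.concatenate([[0.0], radii])  # x[j] = outer radius of layer j (1-based)

    ns = np.arange(1, n_max + 1, dtype=float)
    n_count = len(ns)
    # Unknowns per degree: a1, (a2, b2), (a3, b3), (a4, b4) with the scaled
    # bases  a_j (r / x_j)^n  and  b_j (x_{j-1} / r)^(n+1), all O(1) on the
    # layer so the 7x7 systems stay well conditioned at large n.
    A = np.zeros((n_count, 7, 7))
    rhs = np.zeros((n_count, 7))

    def a_val(j, r):  # (r/x_j)^n at radius r for layer j (1-based)
        return (r / x[j]) ** ns

    def a_der(j, r):
        return (ns / r) * (r / x[j]) ** ns

    def b_val(j, r):
        return (x[j - 1] / r) ** (ns + 1)

    def b_der(j, r):
        return -((ns + 1) / r) * (x[j - 1] / r) ** (ns + 1)

    # Source radial profile S(r) = r^-(n+1) and derivative, unit coefficient.
    def s_val(r):
        return r ** -(ns + 1)

    def s_der(r):
        return -(ns + 1) * r ** -(ns + 2)

    # Column layout: [a1, a2, b2, a3, b3, a4, b4]
    col_a = {1: 0, 2: 1, 3: 3, 4: 5}
    col_b = {2: 2, 3: 4, 4: 6}

    row = 0
    for j in (1, 2, 3):  # interface between layer j and j+1 at radius x[j]
        r = x[j]
        # potential continuity
        A[:, row, col_a[j]] = a_val(j, r)
        if j >= 2:
            A[:, row, col_b[j]] = b_val(j, r)
        A[:, row, col_a[j + 1]] = -a_val(j + 1, r)
        A[:, row, col_b[j + 1]] = -b_val(j + 1, r)
        if j == 1:
            rhs[:, row] = -s_val(r)
        row += 1
        # radial current continuity
        A[:, row, col_a[j]] = sigma[j - 1] * a_der(j, r)
        if j >= 2:
            A[:, row, col_b[j]] = sigma[j - 1] * b_der(j, r)
        A[:, row, col_a[j + 1]] = -sigma[j] * a_der(j + 1, r)
        A[:, row, col_b[j + 1]] = -sigma[j] * b_der(j + 1, r)
        if j == 1:
            rhs[:, row] = -sigma[0] * s_der(r)
        row += 1
    # insulating outer boundary at x4 = 1
    A[:, row, col_a[4]] = a_der(4, 1.0)
    A[:, row, col_b[4]] = b_der(4, 1.0)

    sol = np.linalg.solve(A, rhs[..., None])[..., 0]
    # scalp potential = a4 * 1 + b4 * x3^(n+1)
    return sol[:, col_a[4]] + sol[:, col_b[4]] * x[3] ** (ns + 1)


def leadfield_potential(
    model: ShellHeadModel,
    dipole: DipoleSource,
    montage: ElectrodeMontage,
    n_terms: int = 200,
    rtol: float = 1e-8,
    reference: str | None = None,
) -> np.ndarray:
    """Scalp potentials (uV) of a dipole in the four-shell model.

    Electrode positions are projected radially onto the scalp sphere.  The
    series over Legendre degrees is truncated once the relative increment of
    every electrode potential falls below ``rtol`` (or at ``n_terms``).

    ``reference=None`` returns unreferenced (infinity-referenced) potentials;
    ``"common-average"`` subtracts the electrode mean.
    """
    c = np.asarray(model.center)
    pos_d = np.asarray(dipole.position, float) - c
    b = np.linalg.norm(pos_d)
    if b >= model.brain_radius:
        raise HeadModelError(
            f"dipole at radius {b:.1f} mm is outside the innermost shell "
            f"({model.brain_radius:.1f} mm)")

    elec = montage.projected_to_sphere(model).positions - c
    R = model.scalp_radius
    e_hat = elec / R

    m_vec = dipole.moment_vector  # nA*m
    if b == 0:
        # Central dipole: radial component undefined; treat as purely
        # "tangential" about an arbitrary axis -- handled by the m_r = 0,
        # full-vector tangential path below with d_hat = orientation.
        d_hat = np.asarray(dipole.orientation)
    else:
        d_hat = pos_d / b
    m_r = float(m_vec @ d_hat)
    m_t_vec = m_vec - m_r * d_hat

    u = e_hat @ d_hat  # cos(gamma) per electrode
    et = e_hat @ m_t_vec  # sin(gamma) cos(beta) * |m_t| per electrode

    g = _scalp_transfer_coefficients(model, n_terms)
    b_hat = b / R

    sigma1 = model.conductivities[0]
    # prefactor in uV with mm/nA*m inputs
    pref = _UNIT_SCALE / (4.0 * np.pi * sigma1 * R ** 2)

    V = np.zeros(len(u))
    # Legendre recurrences: P_n(u) and P_n'(u)
    p_nm1 = np.ones_like(u)   # P_0
    p_n = u.copy()            # P_1
    dp_nm1 = np.zeros_like(u)  # P_0'
    dp_n = np.ones_like(u)     # P_1'
    scale = np.maximum(np.max(np.abs(V)), 0.0)
    bpow = 1.0  # b_hat^(n-1)
    for n in range(1, n_terms + 1):
        if n > 1:
            p_np1 = ((2 * n - 1) * u * p_n - (n - 1) * p_nm1) / n
            dp_np1 = u * dp_n + n * p_n  # P_n' = x P_{n-1}' + n P_{n-1}
            p_nm1, p_n = p_n, p_np1
            dp_nm1, dp_n = dp_n, dp_np1
            bpow *= b_hat
        ang = n * m_r * p_n + dp_n * et
        term = pref * g[n - 1] * bpow * ang
        V += term
        scale = max(scale, float(np.max(np.abs(V))))
        if scale > 0 and float(np.max(np.abs(term))) < rtol * scale and n >= 10:
            break

    if reference == "common-average":
        V = V - V.mean()
    elif reference is not None:
        raise HeadModelError(f"unknown reference {reference!r}")
    return V


def compute_leadfield(
    model: ShellHeadModel,
    source_positions: np.ndarray,
    montage: ElectrodeMontage,
    reference: str = "common-average",
    n_terms: int = 200,
) -> LeadField:
    """Full 3-orientation gain matrix for a set of source positions.

    All sources are evaluated in one vectorized pass over the Legendre
    series (the angular recurrences run on (sources, electrodes) arrays).
    """
    src = np.atleast_2d(np.asarray(source_positions, dtype=float))
    c = np.asarray(model.center)
    rel = src - c
    b = np.linalg.norm(rel, axis=1)
    if np.any(b >= model.brain_radius):
        worst = float(b.max())
        raise HeadModelError(
            f"source at radius {worst:.1f} mm is outside the innermost shell "
            f"({model.brain_radius:.1f} mm)")
    R = model.scalp_radius
    e_hat = (montage.projected_to_sphere(model).positions - c) / R
    n_elec = e_hat.shape[0]
    n_src = src.shape[0]
    with np.errstate(invalid="ignore"):
        d_hat = np.where(b[:, None] > 0, rel / np.maximum(b, 1e-300)[:, None], 0.0)

    u = d_hat @ e_hat.T                     # (S, E) cos(gamma)
    g = _scalp_transfer_coefficients(model, n_terms)
    pref = _UNIT_SCALE / (4.0 * np.pi * model.conductivities[0] * R ** 2)
    b_hat = b / R

    # per axis k: m_r[s] = d_hat[s, k]; tangential part e.m_t = e_k - m_r*u
    V = np.zeros((3, n_src, n_elec))
    p_n = u.copy()
    p_nm1 = np.ones_like(u)
    dp_n = np.ones_like(u)
    bpow = np.ones(n_src)
    for n in range(1, n_terms + 1):
        if n > 1:
            p_np1 = ((2 * n - 1) * u * p_n - (n - 1) * p_nm1) / n
            dp_np1 = u * dp_n + n * p_n
            p_nm1, p_n = p_n, p_np1
            dp_n = dp_np1
            bpow = bpow * b_hat
        coef = pref * g[n - 1] * bpow[:, None]
        for k in range(3):
            m_r = d_hat[:, k][:, None]
            et = e_hat[:, k][None, :] - m_r * u
            V[k] += coef * (n * m_r * p_n + dp_n * et)
        if np.max(b_hat) ** n < 1e-10 and n >= 10:
            break
    gain = np.empty((n_elec, 3 * n_src))
    for i in range(n_src):
        gain[:, 3 * i:3 * i + 3] = V[:, i, :].T
    if reference == "common-average":
        gain = gain - gain.mean(axis=0, keepdims=True)
    elif reference != "none":
        raise HeadModelError(f"unknown lead-field reference {reference!r}")
    return LeadField(gain=gain, source_positions=src, labels=montage.labels,
                     reference_scheme=reference)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere sampling (golden-spiral lattice), (n, 3)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def simulate_scalp_topography(
    model: ShellHeadModel,
    dipoles: Sequence[DipoleSource],
    montage: ElectrodeMontage | None = None,
    n_points: int = 2562,
    z_min: float | None = -70.0,
) -> dict:
    """Scalp power map of a set of dipoles on a dense scalp sampling.

    Used to choose electrode placement: for bilateral radial dipoles in the
    olfactory bulbs the power concentrates at the inferior-frontal scalp
    around the nasal bridge.  Returns the sampling positions, the per-point
    power (sum of squared potentials over dipoles) and the argmax position.
    """
    if montage is None:
        pts = fibonacci_sphere(n_points) * model.scalp_radius + np.asarray(model.center)
        if z_min is not None:
            pts = pts[pts[:, 2] >= z_min]
        labels = tuple(f"S{i}" for i in range(len(pts)))
        montage = ElectrodeMontage(labels, pts, reference_scheme="common-average")
    if len(montage) == 0:
        raise HeadModelError("empty montage")
    if not dipoles:
        raise HeadModelError("at least one dipole required")
    power = np.zeros(len(montage))
    for dip in dipoles:
        v = leadfield_potential(model, dip, montage, reference="common-average")
        power += v ** 2
    imax = int(np.argmax(power))
    return {
        "positions": montage.projected_to_sphere(model).positions,
        "labels": montage.labels,
        "power": power,
        "argmax_index": imax,
        "argmax_position": montage.projected_to_sphere(model).positions[imax],
        "argmax_label": montage.labels[imax],
    }


def coregister_affine(
    measured_fiducials: np.ndarray,
    template_fiducials: np.ndarray,
    positions: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Six-parameter (rigid) affine co-registration of digitized points.

    Finds rotation R and translation t minimizing
    ``sum ||R p_i + t - q_i||^2`` over the fiducial pairs (Kabsch / SVD
    solution, reflection excluded), applies it to ``positions`` and reports
    the residual RMS over fiducials.
    """
    p = np.asarray(measured_fiducials, dtype=float)
    q = np.asarray(template_fiducials, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise HeadModelError("fiducial arrays must both be (n, 3)")
    if p.shape[0] < 3:
        raise HeadModelError("at least 3 fiducials are required")
    pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
    # collinearity check: rank of centered cloud
    if np.linalg.matrix_rank(pc, tol=1e-8 * max(1.0, np.abs(pc).max())) < 2:
        raise HeadModelError("fiducials are collinear; rigid fit is degenerate")
    H = pc.T @ qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = q.mean(axis=0) - R @ p.mean(axis=0)
    resid = (R @ p.T).T + t - q
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    out = (R @ np.asarray(positions, dtype=float).T).T + t
    transform = {"rotation": R, "translation": t, "residual_rms": rms}
    return out, transform
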