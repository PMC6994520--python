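"""Cross-spectral density, DICS beamformer and guided dipole comparison.

Source localization of the odor event-related synchronization follows the
frequency-domain beamformer route: the sensor cross-spectral density (CSD)
is estimated at 60 Hz +/- 5 Hz over the 100-250 ms post-stimulus window
with multitaper FFTs on common-average-referenced data; a spatial filter is
computed per grid voxel from the condition-pooled CSD (the balanced common
filter, so the Odor-vs-Air contrast is not biased by per-condition filter
differences) through the four-shell lead field with 10% diagonal (ridge)
regularization; per-condition voxel power is the dominant eigenvalue of the
real part of the filtered CSD, and the contrast is the relative power
change (Odor - Air) / Air.

The source space is a regular grid (>= 10 mm spacing) restricted to voxels
whose gray-matter probability exceeds 40%; a procedural spherical phantom
stands in for an MRI segmentation, and anchor points (the olfactory-bulb
seeds) are guaranteed to be grid nodes.  A guided symmetric-dipole-pair
comparison quantifies how much sensor-space (co)variance competing source
hypotheses explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .headmodel import (
    DipoleSource,
    ElectrodeMontage,
    LeadField,
    ShellHeadModel,
    build_head_model,
    compute_leadfield,
)
from .preproc import EpochSet
from .timefreq import dpss_tapers

__all__ = [
    "CrossSpectralDensity", "SourceGrid", "SourcePowerMap", "DipoleFitReport",
    "GrayMatterPhantom", "csd_multitaper", "evoked_csd", "build_source_grid",
    "dics_localize", "dipole_fit_compare", "CANDIDATE_SITES",
]

# Bilateral candidate source sites for the guided dipole comparison (RAS mm,
# right-hemisphere seed; the left seed is the x-mirror).  Coordinates for
# the alternatives are literature-standard defaults and fully configurable.
CANDIDATE_SITES = {
    "olfactory_bulb": (6.0, 30.0, -32.0),
    "anterior_piriform": (22.0, 2.0, -14.0),
    "medial_ofc": (6.0, 42.0, -16.0),
    "primary_auditory": (48.0, -22.0, 8.0),
}


class SourceLocError(ValueError):
    pass


@dataclass
class CrossSpectralDensity:
    """Hermitian channels x channels complex CSD at a center frequency."""

    matrix: np.ndarray
    ch_names: tuple[str, ...]
    center_freq: float = 60.0
    smoothing: float = 5.0
    window: tuple[float, float] = (0.100, 0.250)
    n_tapers: int = 1
    n_trials: int = 0
    per_trial: np.ndarray | None = None  # (n_trials, C, C)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        herm_err = np.max(np.abs(m - m.conj().T))
        if herm_err > 1e-10 * max(np.max(np.abs(m)), 1e-30):
            raise SourceLocError(f"CSD is not Hermitian (max dev {herm_err:.2e})")
        if np.any(np.diag(m).real < -1e-12) or np.max(np.abs(np.diag(m).imag)) > 1e-10 * max(np.max(np.abs(m)), 1e-30):
            raise SourceLocError("CSD diagonal must be real and nonnegative")
        self.matrix = m

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def coherence(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.matrix).real)
        denom = np.outer(d, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.abs(self.matrix) / denom


def csd_multitaper(
    epochs: EpochSet,
    foi: float = 60.0,
    smoothing: float = 5.0,
    window: tuple[float, float] = (0.100, 0.250),
    picks=None,
    keep_per_trial: bool = False,
) -> CrossSpectralDensity:
    """Multitaper cross-spectral density at ``foi`` +/- ``smoothing`` Hz.

    The number of tapers follows the time-half-bandwidth rule
    (K = max(1, floor(2 T W - 1))); spectra are computed by tapered DFT at
    the exact frequency of interest, and the CSD is the taper- and
    trial-averaged outer product of the spectra with their conjugates.
    Epochs are expected on a common-average reference.
    """
    fs = epochs.fs
    if window[0] < epochs.times[0] or window[1] > epochs.times[-1] + 1e-9:
        raise SourceLocError(f"CSD window {window} outside the epoch")
    mask = (epochs.times >= window[0]) & (epochs.times <= window[1])
    n_win = int(mask.sum())
    t_win = np.arange(n_win) / fs
    nw = smoothing * (n_win / fs)
    n_tapers = max(1, int(np.floor(2 * nw - 1)))
    tapers = dpss_tapers(n_win, n_tapers, nw=max(nw, 0.6))
    carrier = np.exp(-2j * np.pi * foi * t_win)

    if picks is None:
        data = epochs.data[:, :, mask]
        names = tuple(epochs.ch_names)
    else:
        idx = epochs.picks(picks)
        data = epochs.data[:, idx, :][:, :, mask]
        names = tuple(epochs.ch_names[i] for i in idx)

    # spectra: (trials, tapers, channels)
    spec = np.einsum("tcs,ks->tkc", data, tapers * carrier[None, :])
    per_trial = np.einsum("tkc,tkd->tcd", spec, spec.conj()) / n_tapers
    pooled = per_trial.mean(axis=0)
    pooled = 0.5 * (pooled + pooled.conj().T)  # enforce exact Hermitianity
    return CrossSpectralDensity(
        pooled, names, foi, smoothing, tuple(window), n_tapers,
        data.shape[0], per_trial if keep_per_trial else None)


def evoked_csd(
    epochs: EpochSet,
    condition: str | None = None,
    **kwargs,
) -> CrossSpectralDensity:
    """CSD of the trial-averaged (phase-locked, evoked) response.

    For brief, largely phase-locked bursts the trial-level CSD is dominated
    by background fluctuations at realistic trial counts; averaging trials
    first suppresses non-phase-locked background by the trial count while
    retaining the stimulus-locked component.
    """
    if condition is None:
        mask = np.ones(epochs.n_trials, dtype=bool)
    else:
        mask = epochs.labels == condition
    if not mask.any():
        raise SourceLocError(f"no trials for condition {condition!r}")
    avg = epochs.data[mask].mean(axis=0, keepdims=True)
    ep1 = EpochSet(avg, epochs.times, epochs.fs, tuple(epochs.ch_names),
                   np.array([condition or "evoked"], dtype=object),
                   np.array([0]))
    out = csd_multitaper(ep1, **kwargs)
    out.n_trials = int(mask.sum())
    return out


# ---------------------------------------------------------------------------
# Source space
# ---------------------------------------------------------------------------

@dataclass
class GrayMatterPhantom:
    """Procedural gray-matter probability volume: a smooth spherical brain.

    Probability is ``prob_inside`` out to ``radius`` mm from ``center`` and
    falls linearly to zero over ``edge`` mm.  Stands in for an MRI tissue
    segmentation; any object with a ``probability(points)`` method (or a
    NIfTI probability map wrapped accordingly) can replace it.
    """

    radius: float = 70.0
    prob_inside: float = 0.9
    edge: float = 5.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def probability(self, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.atleast_2d(points) - np.asarray(self.center), axis=1)
        p = np.clip((self.radius + self.edge - r) / self.edge, 0.0, 1.0)
        return self.prob_inside * p

    @classmethod
    def from_nifti(cls, path):
        """Wrap a NIfTI gray-matter probability map (nearest-voxel lookup)."""
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        inv = np.linalg.inv(img.affine)

        class _NiftiProb:
            def probability(self, points):
                pts = np.atleast_2d(points)
                ijk = (inv @ np.c_[pts, np.ones(len(pts))].T)[:3].round().astype(int)
                ok = np.all((ijk >= 0) & (ijk < np.array(vol.shape)[:, None]), axis=0)
                out = np.zeros(len(pts))
                out[ok] = vol[tuple(ijk[:, ok])]
                return out

        return _NiftiProb()


@dataclass
class SourceGrid:
    """Gray-matter-constrained source grid (inside voxels only)."""

    positions: np.ndarray          # (n_inside, 3) mm
    gm_probability: np.ndarray     # per inside-voxel
    spacing: float
    prob_thresh: float

    def __len__(self) -> int:
        return self.positions.shape[0]

    def nearest(self, point) -> int:
        return int(np.argmin(np.linalg.norm(
            self.positions - np.asarray(point), axis=1)))

    def index_of(self, point, tol: float = 1e-6) -> int:
        i = self.nearest(point)
        if np.linalg.norm(self.positions[i] - np.asarray(point)) > tol:
            raise SourceLocError(f"point {point} is not a grid node")
        return i


def build_source_grid(
    gm_volume,
    spacing: float = 10.0,
    prob_thresh: float = 0.40,
    anchor_points=None,
    bounds: float = 110.0,
) -> SourceGrid:
    """Regular grid over the gray-matter volume, thresholded at 40%.

    The lattice is shifted so the first anchor point is exactly a grid node;
    further anchors that do not fall on the lattice (e.g. the two OB seeds
    are 12 mm apart, not a multiple of the 10 mm spacing) are inserted as
    additional nodes so that they are always present in the source space.
    """
    if spacing < 10.0:
        raise SourceLocError("grid spacing below the 10 mm minimum")
    anchors = (np.atleast_2d(np.asarray(anchor_points, dtype=float))
               if anchor_points is not None else np.zeros((1, 3)))
    origin = anchors[0]
    ax = [origin[k] + spacing * np.arange(-np.ceil((bounds + origin[k]) / spacing),
                                          np.ceil((bounds - origin[k]) / spacing) + 1)
          for k in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    extra = [a for a in anchors[1:]
             if np.min(np.linalg.norm(pts - a, axis=1)) > 1e-9]
    if extra:
        pts = np.vstack([pts] + [np.asarray(extra)])
    prob = gm_volume.probability(pts)
    inside = prob > prob_thresh
    if not inside.any():
        raise SourceLocError("no voxels exceed the gray-matter threshold")
    return SourceGrid(pts[inside], prob[inside], spacing, prob_thresh)


# ---------------------------------------------------------------------------
# DICS
# ---------------------------------------------------------------------------

@dataclass
class SourcePowerMap:
    """Per-voxel power for both conditions and their relative contrast."""

    grid: SourceGrid
    power_odor: np.ndarray
    power_air: np.ndarray
    contrast: np.ndarray          # (P_odor - P_air) / P_air
    noise_gain: np.ndarray | None = None  # white-noise gain of each filter
    filter_provenance: str = "common"

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.contrast))

    @property
    def peak_position(self) -> np.ndarray:
        return self.grid.positions[self.peak_index]

    @property
    def difference(self) -> np.ndarray:
        """Noise-gain-normalized power difference (P_odor - P_air) / g.

        For evoked (trial-averaged) CSDs the Air power is a near-zero noise
        residual, so the relative contrast is ill-conditioned; the absolute
        difference instead carries the unit-gain beamformer's depth bias
        (filters for weak-leadfield voxels amplify).  Dividing by the
        white-noise gain g = lambda_max(W W^H) — the neural-activity-index
        construction — removes that bias.
        """
        d = self.power_odor - self.power_air
        if self.noise_gain is None:
            return d
        return d / self.noise_gain

    @property
    def difference_peak_position(self) -> np.ndarray:
        return self.grid.positions[int(np.argmax(self.difference))]


def dics_localize(
    csd_odor: CrossSpectralDensity,
    csd_air: CrossSpectralDensity,
    leadfield: LeadField,
    lambda_pct: float = 10.0,
    grid: SourceGrid | None = None,
) -> SourcePowerMap:
    """DICS beamformer with a balanced common filter.

    One unit-gain spatial filter per voxel is computed from the pooled
    (Odor + Air) CSD with ridge loading ``lambda_pct``% of the mean CSD
    diagonal; per-condition voxel power is the dominant eigenvalue of the
    real part of ``F C F^H`` over the free-orientation triplet, and the
    contrast is the relative power change, which is invariant to a common
    scaling of both CSDs and identically zero when the CSDs are equal.
    """
    if csd_odor.ch_names != csd_air.ch_names:
        raise SourceLocError("CSDs computed on different channel sets")
    if leadfield.gain.shape[0] != csd_odor.n_channels:
        raise SourceLocError("lead field channel count does not match CSDs")
    C_pool = 0.5 * (csd_odor.matrix + csd_air.matrix)
    loading = lambda_pct / 100.0 * np.mean(np.diag(C_pool).real)
    C_reg = C_pool + loading * np.eye(C_pool.shape[0])
    try:
        C_inv = np.linalg.inv(C_reg)
    except np.linalg.LinAlgError as exc:
        raise SourceLocError(
            "regularized CSD is singular; increase lambda_pct") from exc
    cond = np.linalg.cond(C_reg)
    if not np.isfinite(cond) or cond > 1e12:
        raise SourceLocError(
            f"regularized CSD is numerically singular (cond {cond:.1e}); "
            "increase lambda_pct")

    n_src = leadfield.n_sources
    p_odor = np.empty(n_src)
    p_air = np.empty(n_src)
    noise_gain = np.empty(n_src)
    for i in range(n_src):
        L = leadfield.for_source(i)                      # (C, 3)
        G = L.T @ C_inv @ L                              # (3, 3)
        W = np.linalg.solve(G, L.T @ C_inv)              # (3, C) unit-gain
        for mat, out in ((csd_odor.matrix, p_odor), (csd_air.matrix, p_air)):
            P = W @ mat @ W.conj().T
            P = 0.5 * (P + P.conj().T)
            out[i] = float(np.linalg.eigvalsh(P.real).max())
        WW = (W @ W.conj().T).real
        noise_gain[i] = float(np.linalg.eigvalsh(0.5 * (WW + WW.T)).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(p_air > 0, (p_odor - p_air) / p_air,
                            np.where(p_odor > 0, np.inf, 0.0))
    if grid is None:
        grid = SourceGrid(leadfield.source_positions,
                          np.ones(n_src), 10.0, 0.4)
    return SourcePowerMap(grid, p_odor, p_air, contrast, noise_gain, "common")


# ---------------------------------------------------------------------------
# Guided dipole comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DipoleFitReport:
    site: str
    seed_right: tuple[float, float, float]
    explained_variance: float
    residual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.explained_variance <= 1.0 + 1e-9:
            raise SourceLocError("explained variance must be in [0, 1]")


def dipole_fit_compare(
    csd: CrossSpectralDensity | np.ndarray,
    head_model: ShellHeadModel | None,
    montage: ElectrodeMontage,
    candidate_sites: dict | None = None,
    orientation: str = "radial",
    noise_csd: CrossSpectralDensity | np.ndarray | None = None,
    noise_loading: float = 0.05,
) -> list[DipoleFitReport]:
    """Explained sensor variance of symmetric bilateral dipole pairs.

    The dominant spatial pattern (leading eigenvector of the real part of
    the CSD — the measured topography of the band-limited response) is
    fitted by least squares against the forward model of each left/right
    mirror pair (radially oriented by default, free orientation optional);
    the report gives the captured fraction ||P_site v||^2 of that pattern.
    Data generated by a given pair is best explained by its own site; pure
    sensor noise has an arbitrary dominant pattern that no focal pair
    captures well.

    ``noise_csd`` (e.g. the Air-condition CSD) prewhitens the fit: the
    pattern and the forward models are transformed by the inverse matrix
    square root of the (diagonal-loaded) noise covariance, the standard
    dipole-fitting practice that stops spatially correlated background
    from inflating the fit of smooth but wrong source models.
    """
    if head_model is None:
        head_model = build_head_model()
    if candidate_sites is None:
        candidate_sites = CANDIDATE_SITES
    C = csd.matrix if isinstance(csd, CrossSpectralDensity) else np.asarray(csd)
    S = 0.5 * (C + C.conj().T).real
    if float(np.trace(S)) <= 0:
        raise SourceLocError("CSD has nonpositive total power")
    whiten = None
    if noise_csd is not None:
        from scipy.linalg import sqrtm

        Nmat = (noise_csd.matrix if isinstance(noise_csd, CrossSpectralDensity)
                else np.asarray(noise_csd))
        N = 0.5 * (Nmat + Nmat.conj().T).real
        N = N + noise_loading * np.trace(N) / N.shape[0] * np.eye(N.shape[0])
        whiten = np.linalg.inv(sqrtm(N)).real
        S = whiten @ S @ whiten.T
    evals, evecs = np.linalg.eigh(S)
    pattern = evecs[:, -1]  # dominant topography, unit norm

    reports = []
    for name, seed in candidate_sites.items():
        seed = np.asarray(seed, dtype=float)
        pair = np.array([seed * np.array([-1, 1, 1]), seed])
        for p in pair:
            if not head_model.contains_source(p):
                raise SourceLocError(
                    f"candidate {name} seed {tuple(p)} outside the innermost shell")
        lf = compute_leadfield(head_model, pair, montage,
                               reference="common-average")
        if orientation == "radial":
            cols = []
            for i, p in enumerate(pair):
                d = p - np.asarray(head_model.center)
                cols.append(lf.for_source(i) @ (d / np.linalg.norm(d)))
            G = np.column_stack(cols)
        elif orientation == "free":
            G = lf.gain
        else:
            raise SourceLocError(f"unknown orientation {orientation!r}")
        if whiten is not None:
            G = whiten @ G
        Q, _ = np.linalg.qr(G)
        captured = float(np.sum((Q.T @ pattern) ** 2))
        ev = min(max(captured, 0.0), 1.0)
        reports.append(DipoleFitReport(name, tuple(seed), ev, 1.0 - ev))
    return reports
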