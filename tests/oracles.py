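"""Independent reference implementations used as test oracles.

These deliberately share no code with the package internals: the
homogeneous-sphere potential is the classical closed form (generating-
function summation of the Legendre series), the infinite-medium dipole
potential is the textbook formula, and the ICC oracle recomputes the
two-way ANOVA mean squares from explicit loops.
"""

import numpy as np

UNIT = 1e3  # mm / nA*m inputs -> microvolts


def free_dipole_potential(sigma, dip_pos, m_vec, points):
    """Infinite homogeneous medium: V = m.(r-r0) / (4 pi sigma |r-r0|^3)."""
    d = np.atleast_2d(points) - np.asarray(dip_pos, float)
    r3 = np.linalg.norm(d, axis=1) ** 3
    return UNIT * (d @ np.asarray(m_vec)) / (4 * np.pi * sigma * r3)


def single_sphere_potential(radius, sigma, dip_pos, m_vec, electrodes):
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Obtained by summing the Legendre expansion with generating functions:
    sum (2n+1) t^(n-1) P_n = 2(u-t)/W^3 + (1/W - 1)/t and
    sum (2n+1)/n t^(n-1) P_n' = 2/W^3 + (1 + 1/W)/(1 - t u + W),
    with t = b/R, u = cos(gamma), W = sqrt(1 - 2 t u + t^2).
    """
    e = np.atleast_2d(electrodes)
    e_hat = e / np.linalg.norm(e, axis=1, keepdims=True)
    b = np.linalg.norm(dip_pos)
    d_hat = np.asarray(dip_pos, float) / b
    t = b / radius
    u = e_hat @ d_hat
    m_r = float(np.asarray(m_vec) @ d_hat)
    m_t = np.asarray(m_vec) - m_r * d_hat
    et = e_hat @ m_t
    W = np.sqrt(1 - 2 * t * u + t * t)
    radial = m_r * (2 * (u - t) / W ** 3 + (1 / W - 1) / t)
    tangential = et * (2 / W ** 3 + (1 + 1 / W) / (1 - t * u + W))
    return UNIT * (radial + tangential) / (4 * np.pi * sigma * radius ** 2)


def anova_icc2k(x):
    """ICC(2,k) and its F test from explicitly looped ANOVA mean squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_r = ss_c = ss_e = 0.0
    row_means = [x[i].sum() / k for i in range(n)]
    col_means = [x[:, j].sum() / n for j in range(k)]
    for i in range(n):
        ss_r += k * (row_means[i] - grand) ** 2
    for j in range(k):
        ss_c += n * (col_means[j] - grand) ** 2
    for i in range(n):
        for j in range(k):
            ss_e += (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = ss_e / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (msc - mse) / n)
    f = msr / mse
    return icc, f
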