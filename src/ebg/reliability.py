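"""Permutation contrasts, ICC(2,k) reliability, effect sizes and dispersion.

The sensor-level Odor-vs-Air contrast is tested with a Monte-Carlo
permutation test: per-subject condition labels are randomly exchanged in
each permutation and the paired two-tailed t statistic recomputed; the
p-value uses the add-one estimator p = (1 + #{|t_perm| >= |t_obs|}) /
(n_perm + 1), which is valid (never exactly zero) where the naive
exceedance fraction is not.  Test-retest reliability across sessions is
quantified by the two-way random-effects, absolute-agreement,
average-measures intraclass correlation ICC(2,k) from the ANOVA
decomposition, pairwise Pearson correlations, per-session and pooled
Cohen's d with noncentral-t confidence intervals, and the Cochran-style
dispersion statistic Q comparing per-session effect sizes to their
inverse-variance-pooled estimate (Q ~ chi-square with k-1 df under
homogeneity).

No multiple-testing correction is applied across time-frequency maps;
replication across independent experiments is the intended guard, and map
outputs carry raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "PermutationResult", "ReliabilityReport", "montecarlo_permutation",
    "icc2k", "test_retest", "effect_size_meta", "sem_across_sessions",
    "cohens_d_ci",
]


class StatsError(ValueError):
    pass


@dataclass
class PermutationResult:
    """Observed t map (scalar or freq x time), permutation p-values, mask."""

    t_obs: np.ndarray
    p: np.ndarray
    n_perm: int
    alpha: float
    mask: np.ndarray

    @property
    def significant(self) -> bool:
        return bool(np.any(self.mask))


def montecarlo_permutation(
    odor_maps: np.ndarray,
    air_maps: np.ndarray,
    n_perm: int = 1000,
    paired: bool = True,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Monte-Carlo permutation test of Odor vs Air.

    ``odor_maps``/``air_maps`` are (n_subjects, ...) arrays (scalars or
    maps).  Paired mode exchanges the two condition labels within subject
    (sign flips of the difference); unpaired mode shuffles condition labels
    across the pooled sample (e.g. trials of a single subject) and uses the
    two-sample t statistic.
    """
    odor = np.atleast_1d(np.asarray(odor_maps, dtype=float))
    air = np.atleast_1d(np.asarray(air_maps, dtype=float))
    if n_perm < 1:
        raise StatsError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    if paired:
        if odor.shape != air.shape:
            raise StatsError("paired test requires identical shapes")
        d = odor - air
        n = d.shape[0]
        if n < 2:
            raise StatsError("need at least 2 subjects")

        def tstat(x):
            m = x.mean(axis=0)
            s = x.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(s > 0, m / (s / np.sqrt(n)), 0.0)

        t_obs = tstat(d)
        flips = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
        if d.ndim == 1:  # scalar contrast: all permutations at once
            x = flips * d[None, :]
            m = x.mean(axis=1)
            s = x.std(axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_all = np.where(s > 0, m / (s / np.sqrt(n)), 0.0)
            exceed = np.sum(np.abs(t_all) >= np.abs(t_obs)).astype(float)
        else:
            exceed = np.zeros_like(t_obs, dtype=float)
            for i in range(n_perm):
                t_p = tstat(d * flips[i].reshape((n,) + (1,) * (d.ndim - 1)))
                exceed += np.abs(t_p) >= np.abs(t_obs)
    else:
        n1, n2 = odor.shape[0], air.shape[0]
        if odor.shape[1:] != air.shape[1:]:
            raise StatsError("map shapes differ between conditions")
        pooled = np.concatenate([odor, air], axis=0)

        def tstat2(x1, x2):
            v1 = x1.var(axis=0, ddof=1)
            v2 = x2.var(axis=0, ddof=1)
            se = np.sqrt(v1 / n1 + v2 / n2)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(se > 0, (x1.mean(0) - x2.mean(0)) / se, 0.0)

        t_obs = tstat2(odor, air)
        exceed = np.zeros_like(t_obs, dtype=float)
        for _ in range(n_perm):
            perm = rng.permutation(n1 + n2)
            t_p = tstat2(pooled[perm[:n1]], pooled[perm[n1:]])
            exceed += np.abs(t_p) >= np.abs(t_obs)

    p = (1.0 + exceed) / (n_perm + 1.0)
    t_obs = np.asarray(t_obs)
    return PermutationResult(t_obs, np.asarray(p), n_perm, alpha, p <= alpha)


def icc2k(values) -> tuple[float, float, float, float, float]:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``values`` is a subjects x sessions array with no missing cells.
    Returns (r_i, F, df1, df2, p) where the F test of between-subject
    agreement is F = MS_rows / MS_error with df (n-1, (n-1)(k-1)).
    """
    x = np.asarray(values, dtype=float)
    if isinstance(values, pd.DataFrame):
        x = values.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise StatsError("need a subjects x sessions table, >= 2 each")
    if np.isnan(x).any():
        raise StatsError("missing cells are not supported (no imputation)")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (ms_cols - ms_err) / n
    r_i = (ms_rows - ms_err) / denom if denom != 0 else 1.0
    if ms_err == 0:
        return float(r_i), np.inf, float(n - 1), float((n - 1) * (k - 1)), 0.0
    F = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(sstats.f.sf(F, df1, df2))
    return float(r_i), float(F), float(df1), float(df2), p


def test_retest(values) -> pd.DataFrame:
    """Pairwise Pearson correlations between sessions (unit diagonal)."""
    if isinstance(values, pd.DataFrame):
        df = values.astype(float)
    else:
        x = np.asarray(values, dtype=float)
        df = pd.DataFrame(x, columns=[f"ses-{j + 1}" for j in range(x.shape[1])])
    sds = df.std(ddof=1)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise StatsError(f"constant session column(s) {flat}: r undefined")
    return df.corr(method="pearson")


def cohens_d_ci(deltas, confidence: float = 0.95) -> tuple[float, float, float]:
    """One-sample Cohen's d with a noncentral-t confidence interval."""
    x = np.asarray(deltas, dtype=float)
    n = len(x)
    if n < 3:
        raise StatsError("need at least 3 values per session")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance: effect size undefined")
    d = x.mean() / sd
    t = d * np.sqrt(n)
    df = n - 1
    alpha = 1 - confidence

    def solve(target_p):
        # find ncp such that P(T_{df,ncp} > t) = target_p
        lo, hi = t - 10 - 5 * abs(t), t + 10 + 5 * abs(t)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if sstats.nct.sf(t, df, mid) < target_p:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # sf(t; ncp) increases with ncp: the lower bound leaves alpha/2 above t
    lo = solve(alpha / 2) / np.sqrt(n)
    hi = solve(1 - alpha / 2) / np.sqrt(n)
    return float(d), float(lo), float(hi)


def effect_size_meta(session_deltas, ci: bool = True) -> dict:
    """Per-session Cohen's d, fixed-effect pooled d, and dispersion Q.

    ``session_deltas`` is a list of per-subject Odor-Air difference vectors,
    one per session.  Pooling is inverse-variance (fixed effect) with
    var(d_i) = 1/n_i + d_i^2 / (2 n_i); Q = sum w_i (d_i - d_pooled)^2 is
    compared to chi-square with k-1 df.  ``ci=False`` skips the
    noncentral-t interval computation (useful in large calibration loops).
    """
    if len(session_deltas) < 1:
        raise StatsError("need at least one session")
    ds, los, his, ws, ns = [], [], [], [], []
    for dl in session_deltas:
        if ci:
            d, lo, hi = cohens_d_ci(dl)
        else:
            x = np.asarray(dl, dtype=float)
            if len(x) < 3:
                raise StatsError("need at least 3 values per session")
            sd = x.std(ddof=1)
            if sd == 0:
                raise StatsError("zero variance: effect size undefined")
            d, lo, hi = float(x.mean() / sd), np.nan, np.nan
        n = len(dl)
        var_d = 1.0 / n + d ** 2 / (2.0 * n)
        ds.append(d), los.append(lo), his.append(hi)
        ws.append(1.0 / var_d), ns.append(n)
    ds, ws = np.array(ds), np.array(ws)
    d_pooled = float(np.sum(ws * ds) / np.sum(ws))
    q = float(np.sum(ws * (ds - d_pooled) ** 2))
    return {
        "d_per_session": list(map(float, ds)),
        "ci_per_session": list(zip(map(float, los), map(float, his))),
        "d_pooled": d_pooled,
        "Q": q,
        "df": len(ds) - 1,
        "n_per_session": ns,
    }


def sem_across_sessions(values) -> float:
    """Standard error of the session-mean power across sessions.

    With a single session the s.e.m. is computed across subjects, with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if isinstance(values, pd.DataFrame):
        x = values.to_numpy(dtype=float)
    x = np.atleast_2d(x)
    n, k = x.shape
    if k >= 2:
        sess_means = x.mean(axis=0)
        return float(sess_means.std(ddof=1) / np.sqrt(k))
    if n < 2:
        raise StatsError("need at least 2 values")
    warnings.warn("single session: s.e.m. computed across subjects")
    return float(x[:, 0].std(ddof=1) / np.sqrt(n))


@dataclass
class ReliabilityReport:
    """Full retest summary for a subjects x sessions OERS table."""

    icc: float
    icc_F: float
    icc_df1: float
    icc_df2: float
    icc_p: float
    pairwise_r: pd.DataFrame
    effects: dict
    sem: float
    mean_power: float

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   session_deltas=None) -> "ReliabilityReport":
        r_i, F, df1, df2, p = icc2k(table)
        corr = test_retest(table)
        if session_deltas is None:
            # table values are per-subject per-session contrasts already
            session_deltas = [table.iloc[:, j].to_numpy()
                              for j in range(table.shape[1])]
        eff = effect_size_meta(session_deltas)
        return cls(r_i, F, df1, df2, p, corr, eff,
                   sem_across_sessions(table), float(np.mean(table.to_numpy())))

    def to_dict(self) -> dict:
        return {
            "icc2k": self.icc, "icc_F": self.icc_F,
            "icc_df": [self.icc_df1, self.icc_df2], "icc_p": self.icc_p,
            "pairwise_r": self.pairwise_r.to_dict(),
            "effect_sizes": self.effects, "sem": self.sem,
            "mean_power": self.mean_power,
        }
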