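"""Habituation analysis: OERS trend, early/late split, and N1-P2/3 ERPs.

The olfactory bulb, unlike piriform and downstream cortex, shows little
habituation to rapid repeated odor exposure.  The analysis therefore runs
two trend tests on an odor-repetition session: (1) a linear mixed model of
per-trial OERS gamma power (trial as fixed slope, subject as random
intercept) which should be flat if the signal is bulbar, and (2) the
peak-to-peak N1-P2/3 amplitude of the low-frequency olfactory ERP at Pz,
which tracks perceived intensity and should decline.  An early-vs-late
split-half permutation test complements the mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preproc import EpochSet, bandpass
from .reliability import PermutationResult, StatsError, montecarlo_permutation

__all__ = [
    "TrialSeries", "ErpPeaks", "TrendResult", "mixed_trend",
    "split_half_test", "n1_p23_delta",
    "N1_WINDOW", "P23_WINDOW", "ERP_BAND",
]

# Peak-search windows (s, post-onset) and ERP band (Hz) for the olfactory
# N1 / P2-3 components; conventional values, configurable per call.
N1_WINDOW = (0.250, 0.500)
P23_WINDOW = (0.450, 0.900)
ERP_BAND = (1.0, 7.0)


@dataclass
class TrialSeries:
    """Per-trial measurements for one or more subjects (long format)."""

    table: pd.DataFrame  # columns: subject, trial, value (+ optional rating)

    def __post_init__(self) -> None:
        need = {"subject", "trial", "value"}
        if not need.issubset(self.table.columns):
            raise StatsError(f"TrialSeries needs columns {sorted(need)}")

    @classmethod
    def from_arrays(cls, values, subjects=None) -> "TrialSeries":
        """Build from (n_trials,) or a dict subject -> per-trial values."""
        if isinstance(values, dict):
            rows = [(s, t, v) for s, vals in values.items()
                    for t, v in enumerate(vals)]
        else:
            rows = [("sub-01", t, v) for t, v in enumerate(np.asarray(values))]
        return cls(pd.DataFrame(rows, columns=["subject", "trial", "value"]))


@dataclass
class TrendResult:
    slope: float
    t: float
    df: float
    ci: tuple[float, float]
    p: float
    method: str


def mixed_trend(series: TrialSeries) -> TrendResult:
    """Linear mixed model: value ~ trial with subject random intercepts (ML).

    Falls back to ordinary least squares with a warning when only a single
    subject is present.  Returns the Wald t, df and 95% CI of the slope.
    """
    df = series.table
    subjects = df["subject"].unique()
    counts = df.groupby("subject")["trial"].count()
    if len(subjects) >= 2 and (counts < 3).any():
        raise StatsError("each subject needs at least 3 trials")
    if len(subjects) < 2:
        warnings.warn("single subject: falling back to ordinary regression")
        import statsmodels.api as sm

        X = sm.add_constant(df["trial"].to_numpy(dtype=float))
        fit = sm.OLS(df["value"].to_numpy(dtype=float), X).fit()
        ci = fit.conf_int()[1]
        return TrendResult(float(fit.params[1]), float(fit.tvalues[1]),
                           float(fit.df_resid), (float(ci[0]), float(ci[1])),
                           float(fit.pvalues[1]), "ols")
    import statsmodels.formula.api as smf

    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ trial", df, groups=df["subject"])
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=False, method=method)
                if np.isfinite(fit.bse["trial"]):
                    break
            except (np.linalg.LinAlgError, ValueError):
                fit = None
    if fit is None or not np.isfinite(fit.bse["trial"]):
        # random-intercept variance collapsed; subjects share one intercept
        warnings.warn("mixed model degenerate; using pooled OLS")
        import statsmodels.api as sm

        X = sm.add_constant(df["trial"].to_numpy(dtype=float))
        ols = sm.OLS(df["value"].to_numpy(dtype=float), X).fit()
        ci = ols.conf_int()[1]
        return TrendResult(float(ols.params[1]), float(ols.tvalues[1]),
                           float(ols.df_resid), (float(ci[0]), float(ci[1])),
                           float(ols.pvalues[1]), "ols-pooled")
    slope = float(fit.params["trial"])
    se = float(fit.bse["trial"])
    tval = slope / se if se > 0 else np.inf
    dof = float(len(df) - 2 - len(subjects))  # residual df after fixed+groups
    from scipy import stats as sstats

    ci = (slope - 1.96 * se, slope + 1.96 * se)
    p = float(2 * sstats.t.sf(abs(tval), dof))
    return TrendResult(slope, float(tval), dof, ci, p, "mixedlm")


def split_half_test(series: TrialSeries, n_perm: int = 1000,
                    seed: int = 0) -> PermutationResult:
    """Early-vs-late permutation contrast of per-subject half means.

    The session is split per subject into first and second halves (an odd
    trial count puts the extra trial in the early half); the per-subject
    early and late means are contrasted with the paired Monte-Carlo
    permutation test.
    """
    early, late = [], []
    for _, sub in series.table.groupby("subject"):
        v = sub.sort_values("trial")["value"].to_numpy(dtype=float)
        h = (len(v) + 1) // 2  # early half gets the extra trial
        early.append(v[:h].mean())
        late.append(v[h:].mean() if len(v) > h else v[:h].mean())
    early, late = np.array(early), np.array(late)
    if len(early) >= 2:
        return montecarlo_permutation(early, late, n_perm=n_perm, seed=seed)
    # single subject: permute trial labels within the session instead
    v = series.table.sort_values("trial")["value"].to_numpy(dtype=float)
    h = (len(v) + 1) // 2
    return montecarlo_permutation(v[:h], v[h:], n_perm=n_perm, paired=False,
                                  seed=seed)


@dataclass
class ErpPeaks:
    """Per-trial N1 / P2-3 peaks and their peak-to-peak delta."""

    table: pd.DataFrame  # trial, n1_amp, n1_lat, p23_amp, p23_lat, delta

    @property
    def delta(self) -> np.ndarray:
        return self.table["delta"].to_numpy()


def n1_p23_delta(
    epochs: EpochSet,
    channel: str = "Pz",
    n1_window: tuple[float, float] = N1_WINDOW,
    p23_window: tuple[float, float] = P23_WINDOW,
    erp_band: tuple[float, float] = ERP_BAND,
) -> ErpPeaks:
    """Per-trial N1 and P2/3 peaks of the band-passed ERP at one channel.

    N1 is the most negative sample within ``n1_window``, P2/3 the most
    positive within ``p23_window``; delta = P2/3 - N1 amplitudes.  A flat
    signal in a window yields a zero peak with a warning.
    """
    if n1_window[0] >= p23_window[0]:
        raise StatsError("N1 window must start before the P2/3 window")
    for w in (n1_window, p23_window):
        if w[0] < epochs.times[0] or w[1] > epochs.times[-1] + 1e-9:
            raise StatsError(f"window {w} outside the epoch")
    ep = bandpass(epochs.pick_channels([channel]), *erp_band)
    x = ep.data[:, 0, :]
    m1 = (ep.times >= n1_window[0]) & (ep.times <= n1_window[1])
    m2 = (ep.times >= p23_window[0]) & (ep.times <= p23_window[1])
    rows = []
    for i in range(x.shape[0]):
        seg1, seg2 = x[i, m1], x[i, m2]
        if np.ptp(seg1) == 0 or np.ptp(seg2) == 0:
            warnings.warn(f"flat signal in peak window on trial {i}")
        i1 = int(np.argmin(seg1))
        i2 = int(np.argmax(seg2))
        n1a, p2a = float(seg1[i1]), float(seg2[i2])
        rows.append((int(epochs.trial_ids[i]), n1a,
                     float(ep.times[m1][i1]), p2a, float(ep.times[m2][i2]),
                     p2a - n1a))
    return ErpPeaks(pd.DataFrame(
        rows, columns=["trial", "n1_amp", "n1_lat", "p23_amp", "p23_lat",
                       "delta"]))
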