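"""End-to-end study runners: detection, reliability, habituation.

Each runner executes the full chain on synthetic (or ingested) data —
simulate -> preprocess -> time-frequency -> OERS -> statistics (and source
localization for the detection study) — and writes its artifacts, resolved
configuration and log to an output directory so a run can be reproduced
exactly from what it leaves on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .habituation import TrialSeries, mixed_trend, n1_p23_delta, split_half_test
from .headmodel import ShellHeadModel, build_head_model, compute_leadfield
from .montage import EBG_LABELS, MASTOID_LABELS, default_ebg_montage
from .preproc import EpochSet, preprocess, rereference_average
from .reliability import (
    ReliabilityReport,
    montecarlo_permutation,
)
from .simulate import (
    OB_LEFT,
    OB_RIGHT,
    ScenarioConfig,
    generate_habituation_session,
    generate_recording,
    generate_reliability_sessions,
)
from .sourceloc import (
    CANDIDATE_SITES,
    GrayMatterPhantom,
    build_source_grid,
    csd_multitaper,
    dics_localize,
    dipole_fit_compare,
    evoked_csd,
)
from .timefreq import baseline_db, extract_oers, multitaper_tfr

__all__ = [
    "PipelineConfig", "run_study1", "run_reliability", "run_habituation",
    "subject_oers", "per_trial_oers",
]

log = logging.getLogger("ebg")


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run (serialized next to outputs)."""

    out_dir: str = "ebg_output"
    seed: int = 0
    n_subjects: int = 8
    n_trials: int = 20            # per condition per subject
    n_scalp: int = 64
    line_freq: float = 50.0
    alpha: float = 0.05
    n_perm: int = 1000
    anosmia: bool = False
    reject_artifacts: bool = True
    # OERS extraction
    oers_band: tuple[float, float] = (55.0, 65.0)
    oers_window: tuple[float, float] = (0.100, 0.125)
    # source stage
    grid_spacing: float = 10.0
    lambda_pct: float = 10.0
    csd_mode: str = "evoked"      # "evoked" | "trial"
    run_source: bool = True
    # reliability
    n_sessions: int = 3
    between_sd: float = 0.25
    within_sd: float = 0.433
    # habituation
    n_habit_trials: int = 24
    ob_slope: float = 0.0
    cortical_decay: float = 0.05
    scenario_overrides: dict = field(default_factory=dict)

    def scenario(self, seed: int, **kw) -> ScenarioConfig:
        base = dict(n_trials=self.n_trials, line_freq=self.line_freq,
                    anosmia=self.anosmia, seed=seed)
        base.update(self.scenario_overrides)
        base.update(kw)
        return ScenarioConfig(**base)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _prepare_out(config: PipelineConfig, name: str) -> Path:
    out = Path(config.out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return out


def subject_oers(epochs: EpochSet, band=(55.0, 65.0), window=(0.100, 0.125)):
    """Odor and Air OERS values (dB) for one subject's cleaned epochs."""
    kept = epochs.retained()
    tfr = multitaper_tfr(kept, fmin=max(30.0, band[0] - 10),
                         fmax=min(100.0, band[1] + 10),
                         picks=[l for l in EBG_LABELS if l in kept.ch_names])
    db = baseline_db(tfr)
    odor = extract_oers(db, band, window, condition="Odor")
    air = extract_oers(db, band, window, condition="Air")
    return odor, air


def per_trial_oers(epochs: EpochSet, band=(55.0, 65.0), window=(0.100, 0.125)):
    """Per-trial OERS dB values (retained trials, all conditions)."""
    kept = epochs.retained()
    tfr = multitaper_tfr(kept, fmin=max(30.0, band[0] - 10),
                         fmax=min(100.0, band[1] + 10),
                         picks=[l for l in EBG_LABELS if l in kept.ch_names])
    db = baseline_db(tfr)
    vals = extract_oers(db, band, window, per_trial=True)
    return kept.trial_ids, vals


def run_study1(config: PipelineConfig) -> dict:
    """Odor-vs-Air detection and localization study.

    Per subject: simulate -> preprocess -> OERS (Odor and Air).  Group
    level: paired permutation contrast; pooled evoked CSDs -> DICS source
    map on the gray-matter grid anchored at the OB seeds -> guided dipole
    comparison.
    """
    out = _prepare_out(config, "study1")
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    model = build_head_model()
    montage = default_ebg_montage(config.n_scalp, model)
    keep = [l for l in montage.labels if l not in MASTOID_LABELS]
    montage_sub = montage.subset(keep)

    rows = []
    csd_o = csd_a = csd_noise = None
    n_rej = 0
    n_tot = 0
    for s in range(config.n_subjects):
        cfg = config.scenario(int(rng.integers(2 ** 31)))
        rec, gt = generate_recording(cfg, montage=montage, head_model=model)
        ep = preprocess(rec, montage=montage, line_freq=config.line_freq,
                        reject=config.reject_artifacts)
        n_rej += int(ep.reject_mask.sum())
        n_tot += ep.n_trials
        odor, air = subject_oers(ep, config.oers_band, config.oers_window)
        rows.append((f"sub-{s + 1:02d}", odor.power_db, air.power_db,
                     odor.n_trials + air.n_trials))
        if config.run_source:
            avg = rereference_average(ep.retained()).pick_channels(keep)
            if config.csd_mode == "evoked":
                co = evoked_csd(avg, "Odor")
                ca = evoked_csd(avg, "Air")
            else:
                co = csd_multitaper(avg.select_condition("Odor"))
                ca = csd_multitaper(avg.select_condition("Air"))
            csd_o = co.matrix if csd_o is None else csd_o + co.matrix
            csd_a = ca.matrix if csd_a is None else csd_a + ca.matrix
            # trial-level Air CSD estimates the background covariance used
            # to prewhiten the guided dipole fit
            cn = csd_multitaper(avg.select_condition("Air")).matrix
            csd_noise = cn if csd_noise is None else csd_noise + cn
        log.info("subject %d/%d done", s + 1, config.n_subjects)

    table = pd.DataFrame(rows, columns=["subject", "oers_odor_db",
                                        "oers_air_db", "n_trials"])
    table.to_csv(out / "oers.tsv", sep="\t", index=False)
    log.info("trial rejection rate: %.1f%%", 100 * n_rej / max(n_tot, 1))

    perm = montecarlo_permutation(
        table["oers_odor_db"].to_numpy(), table["oers_air_db"].to_numpy(),
        n_perm=config.n_perm, alpha=config.alpha, seed=int(rng.integers(2 ** 31)))

    summary = {
        "n_subjects": config.n_subjects,
        "oers_odor_mean_db": float(table["oers_odor_db"].mean()),
        "oers_air_mean_db": float(table["oers_air_db"].mean()),
        "t_obs": float(np.asarray(perm.t_obs)),
        "p": float(np.asarray(perm.p)),
        "significant": bool(perm.significant),
        "rejection_rate": n_rej / max(n_tot, 1),
    }

    if config.run_source:
        from .sourceloc import CrossSpectralDensity

        co = CrossSpectralDensity(csd_o / config.n_subjects, tuple(keep))
        ca = CrossSpectralDensity(csd_a / config.n_subjects, tuple(keep))
        grid = build_source_grid(GrayMatterPhantom(),
                                 spacing=config.grid_spacing,
                                 anchor_points=[OB_LEFT, OB_RIGHT])
        lf = compute_leadfield(model, grid.positions, montage_sub)
        smap = dics_localize(co, ca, lf, lambda_pct=config.lambda_pct,
                             grid=grid)
        peak = (smap.difference_peak_position if config.csd_mode == "evoked"
                else smap.peak_position)
        d_ob = min(np.linalg.norm(peak - np.asarray(OB_LEFT)),
                   np.linalg.norm(peak - np.asarray(OB_RIGHT)))
        dC = 0.5 * ((co.matrix - ca.matrix) + (co.matrix - ca.matrix).conj().T)
        reports = dipole_fit_compare(dC.real, model, montage_sub,
                                     noise_csd=csd_noise / config.n_subjects)
        vox = pd.DataFrame(np.c_[grid.positions, smap.power_odor,
                                 smap.power_air, smap.contrast],
                           columns=["x", "y", "z", "p_odor", "p_air",
                                    "contrast"])
        vox.to_csv(out / "source_map.tsv", sep="\t", index=False)
        summary["source_peak"] = [float(v) for v in peak]
        summary["source_peak_dist_to_ob_mm"] = float(d_ob)
        summary["source_contrast_at_peak"] = float(
            smap.contrast[smap.peak_index])
        summary["dipole_fit"] = {r.site: r.explained_variance for r in reports}
        (out / "dipole_fit.json").write_text(
            json.dumps(summary["dipole_fit"], indent=2))

    summary["runtime_s"] = time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_reliability(config: PipelineConfig) -> dict:
    """Three-session retest study -> ICC(2,k), pairwise r, d, Q, s.e.m."""
    if config.n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    out = _prepare_out(config, "reliability")
    table, _ = generate_reliability_sessions(
        config.n_subjects, config.n_sessions, config.between_sd,
        config.within_sd, seed=config.seed)
    report = ReliabilityReport.from_table(table)
    table.to_csv(out / "oers_sessions.tsv", sep="\t")
    result = report.to_dict()
    (out / "reliability.json").write_text(json.dumps(result, indent=2))
    return result


def run_habituation(config: PipelineConfig) -> dict:
    """Odor-repetition study: OERS trend, split-half test, N1-P2/3 trend."""
    out = _prepare_out(config, "habituation")
    rng = np.random.default_rng(config.seed)
    model = build_head_model()
    montage = default_ebg_montage(32, model)

    oers_rows, delta_rows, rating_rows = [], [], []
    for s in range(config.n_subjects):
        sub = f"sub-{s + 1:02d}"
        rec, gt, ratings = generate_habituation_session(
            n_trials=config.n_habit_trials, ob_slope=config.ob_slope,
            cortical_decay=config.cortical_decay,
            seed=int(rng.integers(2 ** 31)), montage=montage,
            head_model=model)
        ep = preprocess(rec, line_freq=config.line_freq, reject=False)
        tids, vals = per_trial_oers(ep, config.oers_band, config.oers_window)
        oers_rows += [(sub, int(t), float(v)) for t, v in zip(tids, vals)]
        peaks = n1_p23_delta(ep)
        delta_rows += [(sub, int(t), float(d)) for t, d in
                       zip(peaks.table["trial"], peaks.table["delta"])]
        rating_rows += [(sub, int(t), float(r)) for t, r in
                        zip(ratings["trial_id"], ratings["intensity_rating"])]

    oers_series = TrialSeries(pd.DataFrame(
        oers_rows, columns=["subject", "trial", "value"]))
    delta_series = TrialSeries(pd.DataFrame(
        delta_rows, columns=["subject", "trial", "value"]))
    oers_series.table.to_csv(out / "oers_trials.tsv", sep="\t", index=False)
    delta_series.table.to_csv(out / "erp_deltas.tsv", sep="\t", index=False)
    pd.DataFrame(rating_rows, columns=["subject", "trial", "rating"]).to_csv(
        out / "ratings.tsv", sep="\t", index=False)

    oers_trend = mixed_trend(oers_series)
    erp_trend = mixed_trend(delta_series)
    split = split_half_test(oers_series, n_perm=config.n_perm,
                            seed=int(rng.integers(2 ** 31)))
    result = {
        "oers_trend": dataclasses.asdict(oers_trend),
        "erp_trend": dataclasses.asdict(erp_trend),
        "split_half_p": float(np.asarray(split.p)),
        "oers_trend_flat": bool(oers_trend.ci[0] <= 0 <= oers_trend.ci[1]),
        "erp_trend_negative": bool(erp_trend.ci[1] < 0),
    }
    (out / "habituation.json").write_text(json.dumps(result, indent=2))
    return result
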