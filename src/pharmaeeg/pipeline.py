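"""End-to-end study runs: baseline and treatment analyses, plus reporting.

`run_baseline` reproduces the 24-h baseline analysis: 1-h binned,
total-power-normalized band fractions with per-band genotype tests and
Bonferroni per-bin post-hocs. `run_treatment` reproduces the pharmaco-EEG
analysis: pretreatment-normalized time courses, per-band factorial rank
tests (treatment x genotype x time) over the acute (0-2 h) and subacute
(2-5 h) windows, and post-hoc comparisons. Both operate on in-memory
session records (from `pharmaeeg.synth.make_study` or loaded from disk)
and return tidy tables; `render_report` turns them into figures.

All bin widths and windows are configurable so that scaled-down simulated
studies use the same code path as full-scale sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BAND_ORDER
from .bandpower import (ACUTE_WINDOW_S, SUBACUTE_WINDOW_S, aggregate_bands,
                        bin_time, normalize_baseline, normalize_pretreatment,
                        to_long, window_mean)
from .longstats import (LongitudinalDataset, TestResult, anova_type_statistic,
                        bonferroni, fit_design, posthoc_timepoints,
                        results_table, significance_tier, wald_type_statistic)
from .spectral import FS_ANALYSIS, compute_epoch_power, detect_artifacts, downsample


@dataclass
class StudyConfig:
    """Knobs for an end-to-end run (durations in seconds)."""

    channel: str = "eeg_frontal"
    baseline_bin_s: float = 3600.0
    treatment_bin_s: float = 600.0
    pre_window_s: tuple[float, float] = (-3600.0, 0.0)
    windows: dict = field(default_factory=lambda: {
        "acute": ACUTE_WINDOW_S, "subacute": SUBACUTE_WINDOW_S})
    headline_statistic: str = "ats"   # "ats" (default) or "wts"
    use_detector: bool = False        # detect artifacts instead of provided masks
    single_precision: bool = False
    compute_posthocs: bool = True     # pairwise/per-bin post-hoc comparisons
    seed: int = 0

    def stat_fn(self):
        return anova_type_statistic if self.headline_statistic == "ats" \
            else wald_type_statistic

    def digest(self) -> str:
        """Stable short hash of the configuration (for table provenance)."""
        import hashlib
        import json
        from dataclasses import asdict

        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(table: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    from . import __version__

    table = table.copy()
    table["software_version"] = __version__
    table["config_hash"] = config.digest()
    return table


def session_band_table(record, config: StudyConfig, anchor_s: float,
                       bin_width_s: float) -> pd.DataFrame:
    """Raw binned band table for one session record."""
    rec = downsample(record.recording, FS_ANALYSIS)
    if config.use_detector:
        mask = detect_artifacts(rec.channels[config.channel], rec.channels["emg"],
                                FS_ANALYSIS)
    else:
        mask = record.mask
    epm = compute_epoch_power(rec, mask=mask, channel=config.channel,
                              single_precision=config.single_precision)
    bands = aggregate_bands(epm)
    return bin_time(bands, bin_width_s, anchor_s)


def _long_study_table(records, config: StudyConfig, anchor_fn, bin_width_s,
                      normalize_fn) -> pd.DataFrame:
    frames = []
    for record in records:
        binned = session_band_table(record, config, anchor_fn(record), bin_width_s)
        try:
            norm = normalize_fn(binned)
        except ValueError as err:
            warnings.warn(f"session {record.subject}/{record.session} excluded: {err}")
            continue
        frames.append(to_long(norm, subject=record.subject, session=record.session,
                              treatment=record.treatment, genotype=record.genotype))
    if not frames:
        raise ValueError("no usable sessions")
    return pd.concat(frames, ignore_index=True)


def run_baseline(records, config: StudyConfig | None = None) -> dict:
    """Baseline study: normalized band fractions + genotype tests per band.

    ``records`` are session records with session == "baseline" (others are
    ignored). Returns {"bands": long table, "tests": per-band genotype
    TestResults (Bonferroni m=7), "posthoc": per-bin genotype comparisons
    per band, "table": tidy results}.
    """
    config = config or StudyConfig()
    base = [r for r in records if r.session == "baseline"]
    if not base:
        raise ValueError("no baseline recordings in study")
    long = _long_study_table(base, config, lambda r: 0.0,
                             config.baseline_bin_s, normalize_baseline)

    tests: dict[str, TestResult] = {}
    posthoc: dict[str, list[TestResult]] = {}
    stat_fn = config.stat_fn()
    if long["genotype"].nunique() < 2:
        warnings.warn("single-genotype study: genotype tests skipped")
        return {"bands": long, "tests": tests, "posthoc": posthoc,
                "table": _stamp(results_table({}), config)}
    for band in BAND_ORDER:
        sub = long[(long["band"] == band) & long["value"].notna()]
        ld = LongitudinalDataset(
            sub.rename(columns={"time_bin_start_min": "time"}),
            unit="subject", factors=("genotype",), value="value")
        tests[band] = stat_fn(ld, "genotype")
        posthoc[band] = posthoc_timepoints(
            sub, unit="subject", group="genotype", time="time_bin_start_min",
            value="value", statistic=config.headline_statistic)
    pvals = [tests[b].p_raw for b in BAND_ORDER]
    for band, pc in zip(BAND_ORDER, bonferroni(pvals, len(BAND_ORDER))):
        tests[band].p_corrected = float(pc)
    return {"bands": long, "tests": tests, "posthoc": posthoc,
            "table": _stamp(results_table({"genotype": tests,
                                           "posthoc": posthoc}), config)}


def _session_unit(df: pd.DataFrame) -> pd.Series:
    return df["subject"].astype(str) + ":" + df["session"].astype(str)


def run_treatment(records, config: StudyConfig | None = None) -> dict:
    """Treatment study: normalized time courses + factorial tests + post-hocs.

    Sessions are pretreatment-normalized per band, binned at
    ``config.treatment_bin_s``. Per band and per analysis window an
    F2-LD-F1 layout (treatment x genotype x time bin) is fitted (WTS and
    ATS); post-hocs compare each treatment against SAL within genotype on
    window means and the genotypes within each treatment per time bin.
    (Subject, session) is the experimental unit.
    """
    config = config or StudyConfig()
    sessions = [r for r in records if r.session != "baseline"]
    if not sessions:
        raise ValueError("no treatment sessions in study")
    long = _long_study_table(
        sessions, config, lambda r: r.injection_time_s, config.treatment_bin_s,
        lambda binned: normalize_pretreatment(binned, config.pre_window_s))
    long = long.assign(unit=_session_unit(long))

    designs: dict[str, dict] = {}
    window_tests: dict[str, dict] = {}
    posthoc_vs_sal: dict[str, dict] = {}
    posthoc_genotype: dict[str, dict] = {}
    n_treat = long["treatment"].nunique()

    for wname, (w0, w1) in config.windows.items():
        w0m, w1m = w0 / 60.0, w1 / 60.0
        for band in BAND_ORDER:
            sub = long[(long["band"] == band) & long["value"].notna()
                       & (long["time_bin_start_min"] >= w0m)
                       & (long["time_bin_start_min"] < w1m)]
            if sub.empty:
                continue
            factors = ("genotype", "treatment") if n_treat > 1 else ("genotype",)
            ld = LongitudinalDataset(
                sub.rename(columns={"time_bin_start_min": "time"}),
                unit="unit", factors=factors, value="value")
            designs[f"{wname}/{band}"] = fit_design(ld)

            if not config.compute_posthocs:
                continue
            # window-mean per session for the pairwise matrices
            wm = (sub.groupby(["unit", "subject", "genotype", "treatment"],
                              as_index=False)
                  .apply(lambda d: pd.Series({
                      "value": np.average(d["value"], weights=d["n_epochs"])}),
                      include_groups=False))
            if n_treat > 1:
                comp = []
                for genotype in wm["genotype"].unique():
                    gsub = wm[wm["genotype"] == genotype]
                    for treat in sorted(gsub["treatment"].unique()):
                        if treat == "SAL" or "SAL" not in set(gsub["treatment"]):
                            continue
                        pair = gsub[gsub["treatment"].isin(["SAL", treat])]
                        ld2 = LongitudinalDataset(
                            pair.assign(_one=0), unit="unit",
                            factors=("treatment",), time="_one", value="value")
                        res = config.stat_fn()(ld2, "group")
                        res.factor = f"{genotype}: SAL vs {treat}"
                        comp.append(res)
                for res in comp:
                    res.p_corrected = bonferroni(res.p_raw, max(len(comp), 1))
                posthoc_vs_sal[f"{wname}/{band}"] = comp

        # per-time-bin genotype comparisons within each treatment (full course)
    for band in BAND_ORDER if config.compute_posthocs else ():
        for treat in long["treatment"].unique():
            sub = long[(long["band"] == band) & (long["treatment"] == treat)
                       & long["value"].notna()
                       & (long["time_bin_start_min"] >= 0)]
            if sub.empty:
                continue
            posthoc_genotype[f"{band}/{treat}"] = posthoc_timepoints(
                sub, unit="unit", group="genotype", time="time_bin_start_min",
                value="value", statistic=config.headline_statistic)

    return {"bands": long, "designs": designs,
            "posthoc_vs_sal": posthoc_vs_sal,
            "posthoc_genotype": posthoc_genotype,
            "table": _stamp(results_table({"design": designs,
                                           "vs_sal": posthoc_vs_sal,
                                           "genotype_bins": posthoc_genotype}),
                            config)}


def check_pretreatment_stability(records, config: StudyConfig | None = None,
                                 session_order: list[str] | None = None) -> dict:
    """Cross-session comparability of raw pretreatment band power.

    Per band, an F1-LD-F1 layout with session index as the repeated factor
    on the raw (un-normalized) pretreatment window mean. Subjects with a
    single session are excluded; with fewer than two sessions overall an
    empty result is returned with a warning.
    """
    config = config or StudyConfig()
    sessions = [r for r in records if r.session != "baseline"]
    rows = []
    for record in sessions:
        binned = session_band_table(record, config, record.injection_time_s,
                                    config.treatment_bin_s)
        pre = window_mean(binned, config.pre_window_s)
        for band in BAND_ORDER:
            rows.append({"subject": record.subject, "genotype": record.genotype,
                         "session": record.session, "band": band,
                         "value": pre[band]})
    df = pd.DataFrame(rows)
    counts = df.groupby("subject")["session"].nunique()
    keep = counts[counts >= 2].index
    df = df[df["subject"].isin(keep)]
    if df.empty or df["session"].nunique() < 2:
        warnings.warn("fewer than two sessions per subject: no stability test")
        return {"pre_power": df, "tests": {}}
    order = session_order or list(pd.unique(df["session"]))
    df["session_idx"] = df["session"].map({s: i for i, s in enumerate(order)})
    tests = {}
    for band in BAND_ORDER:
        sub = df[(df["band"] == band) & df["value"].notna()]
        ld = LongitudinalDataset(sub, unit="subject", factors=("genotype",),
                                 time="session_idx", value="value")
        tests[band] = config.stat_fn()(ld, "time")
    pvals = [tests[b].p_raw for b in BAND_ORDER]
    for band, pc in zip(BAND_ORDER, bonferroni(pvals, len(BAND_ORDER))):
        tests[band].p_corrected = float(pc)
    return {"pre_power": df, "tests": tests,
            "table": _stamp(results_table(tests), config)}


def sem(values) -> float:
    """Standard error of the mean (SD / sqrt(n), ddof=1)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


TIER_COLORS = {1: "0.6", 2: "tab:blue", 3: "tab:red"}
TIER_GLYPHS = {0: "", 1: "*", 2: "**", 3: "***"}


def render_report(band_long: pd.DataFrame, posthoc: dict | None = None,
                  out_dir=None, light_dark: tuple[float, float] | None = None,
                  fmt: str = "svg") -> dict:
    """Per-band time-course figures (mean +/- SEM) with significance underlays.

    ``posthoc`` maps band -> list of per-bin TestResults; corrected p-values
    are drawn as horizontal underlay segments in three severity tiers
    (p < 0.05 gray, < 0.001 blue, < 0.0001 red). ``light_dark`` shades the
    lights-off interval (start_min, end_min). Returns {band: figure};
    writes files when ``out_dir`` is given. Missing panels are skipped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    posthoc = posthoc or {}
    figures = {}
    for band in BAND_ORDER:
        sub = band_long[(band_long["band"] == band) & band_long["value"].notna()]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 3))
        for key, g in sub.groupby(sub.get("genotype", "all")):
            agg = g.groupby("time_bin_start_min")["value"]
            mean, err = agg.mean(), agg.apply(sem)
            ax.errorbar(mean.index, mean.to_numpy(), yerr=err.to_numpy(),
                        label=str(key), capsize=2)
        if light_dark is not None:
            ax.axvspan(light_dark[0], light_dark[1], color="0.9", zorder=0)
        y0 = ax.get_ylim()[0]
        for res in posthoc.get(band, []):
            tier = significance_tier(res.p_corrected if res.p_corrected is not None
                                     else res.p_raw)
            if tier:
                t = float(str(res.factor).rsplit("=", 1)[-1])
                ax.plot([t, t + 1e-9], [y0, y0], lw=4, solid_capstyle="butt",
                        marker="s", ms=4, color=TIER_COLORS[tier])
        ax.set_xlabel("time bin (min)")
        ax.set_ylabel(f"{band} power (normalized)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        figures[band] = fig
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            fig.savefig(out / f"timecourse_{band}.{fmt}")
            plt.close(fig)
    return figures


def comparison_matrix(posthoc_vs_sal: dict, window: str) -> pd.DataFrame:
    """Tier-glyph matrix (band x comparison) for a window, mirroring the
    pairwise treatment-vs-SAL summary figures."""
    rows = {}
    for key, tests in posthoc_vs_sal.items():
        wname, band = key.split("/")
        if wname != window:
            continue
        rows[band] = {t.factor: TIER_GLYPHS[significance_tier(
            t.p_corrected if t.p_corrected is not None else t.p_raw)]
            for t in tests}
    return pd.DataFrame(rows).T.fillna("")
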