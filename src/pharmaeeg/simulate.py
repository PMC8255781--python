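"""Monte-Carlo experiments on scaled-down simulated studies.

These helpers run the complete analysis chain (signal synthesis ->
filter-bank Hilbert power -> band aggregation and normalization -> rank
tests) over many replicate studies to measure type-I error calibration and
power for the qualitative drug-by-genotype findings. Sessions use the
reduced protocol (96-s baseline-style recordings / 48-s pre + 96-s post
treatment sessions at the 200-Hz analysis rate, 3 post-injection time
bins): long enough for stable 4-s-epoch medians, short enough that
hundreds of replicates run on one CPU. Between-subject variability and
effect sizes are the generator defaults, so calibration and power are
measured under the documented study conditions, not tuned per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .longstats import LongitudinalDataset, anova_type_statistic
from .pipeline import StudyConfig, run_treatment, _long_study_table
from .bandpower import normalize_baseline
from .synth import (DrugEffectProfile, default_design, make_study,
                    mmc_like_profile, reduced_protocol, saline_profile,
                    thip_like_profile)

REDUCED_BIN_S = 24.0          # 6 epochs per bin; 2 pre + 4 post bins
REDUCED_PRE_WINDOW_S = (-48.0, 0.0)
REDUCED_ACUTE_S = (0.0, 96.0)


def reduced_config(seed: int = 0) -> StudyConfig:
    return StudyConfig(treatment_bin_s=REDUCED_BIN_S,
                       baseline_bin_s=REDUCED_BIN_S,
                       pre_window_s=REDUCED_PRE_WINDOW_S,
                       windows={"acute": REDUCED_ACUTE_S},
                       single_precision=True, compute_posthocs=False, seed=seed)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def null_study_pvalue(seed: int, band: str = "delta") -> float:
    """One null replicate: no genotype scaling, no drug effect.

    Generates one short drug-free recording per subject (9 WT + 8 KO
    labels), runs the spectral chain, total-power-normalizes the band
    fractions in 3 time bins and returns the raw ATS p-value of the
    genotype main effect (F1-LD-F1).
    """
    from .synth import StudyProtocol

    design = default_design(treatments=("SAL",))
    null_profile = DrugEffectProfile(band_gains={}, stress_transient_gain={})
    protocol = StudyProtocol(baseline_s=96.0, pre_s=0.0, post_s=96.0, fs=200.0,
                             artifact_rate_per_h=0.0,
                             channels=("eeg_frontal", "emg"))
    records = make_study(design, seed=seed, protocol=protocol,
                         drug_profiles={"SAL": null_profile},
                         ko_band_scale={})
    config = reduced_config(seed)
    long = _long_study_table(records, config, lambda r: 0.0, REDUCED_BIN_S,
                             normalize_baseline)
    sub = long[(long["band"] == band) & long["value"].notna()
               & (long["bin_start_s"] >= 0)]
    ld = LongitudinalDataset(sub.rename(columns={"time_bin_start_min": "time"}),
                             unit="subject", factors=("genotype",), value="value")
    return anova_type_statistic(ld, "genotype").p_raw


def null_rejection_rate(n_reps: int = 200, seed: int = 0, alpha: float = 0.05,
                        band: str = "delta"):
    """Type-I error of the genotype ATS over replicate null studies."""
    pvals = np.array([null_study_pvalue(int(s), band) for s in _seeds(seed, n_reps)])
    return float(np.mean(pvals < alpha)), pvals


def null_dataset_pvalues(n_reps: int = 500, seed: int = 0, n_wt: int = 9,
                         n_ko: int = 8, n_times: int = 3) -> np.ndarray:
    """Raw ATS p-values under a null longitudinal-data generator.

    Observations are iid log-normal band-power values (no genotype or time
    structure); each replicate tests the genotype main effect. Used for the
    uniformity check, where hundreds of full signal-level replicates would
    be redundant: the rank tests see only the per-bin band values.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        rows = []
        for g, n in (("WT", n_wt), ("KO", n_ko)):
            for j in range(n):
                for t in range(n_times):
                    rows.append({"unit": f"{g}{j}", "genotype": g, "time": t,
                                 "value": rng.lognormal(0.0, 0.3)})
        ld = LongitudinalDataset(pd.DataFrame(rows), unit="unit",
                                 factors=("genotype",), value="value")
        out[i] = anova_type_statistic(ld, "genotype").p_raw
    return out


def thip_study_pvalues(seed: int) -> dict[str, float]:
    """One THIP-like replicate: delta/theta gain in WT only, vs saline.

    9 WT + 8 KO subjects x {SAL, THIP}; KO animals respond to THIP like
    saline (blunted superagonist response). Returns raw p-values of the
    genotype x treatment interaction (ATS and WTS) for the delta band over
    the acute window.
    """
    design = default_design(treatments=("SAL", "THIP"))
    records = make_study(
        design, seed=seed, protocol=reduced_protocol(),
        drug_profiles={"SAL": saline_profile(), "THIP": thip_like_profile()},
        ko_drug_profiles={"THIP": saline_profile()})
    result = run_treatment(records, reduced_config(seed))
    fits = result["designs"]["acute/delta"]
    return {"ats": fits["A:B"]["ats"].p_raw, "wts": fits["A:B"]["wts"].p_raw}


def mmc_study_pvalues(seed: int) -> dict[str, float]:
    """One 4-MMC-like replicate: broadband WT-only suppression sparing gamma1.

    Only the drug sessions are simulated (the genotype contrast within the
    treatment needs no saline arm). Returns raw ATS p-values of the
    genotype effect on the pretreatment-normalized acute window for beta
    (suppressed in WT) and gamma1 (spared -> null).
    """
    design = default_design(treatments=("4MMC",))
    records = make_study(
        design, seed=seed, protocol=reduced_protocol(),
        drug_profiles={"4MMC": mmc_like_profile()},
        ko_drug_profiles={"4MMC": saline_profile()})
    result = run_treatment(records, reduced_config(seed))
    out = {}
    for band in ("beta", "gamma1"):
        fits = result["designs"][f"acute/{band}"]
        out[band] = fits["group"]["ats"].p_raw   # group = genotype (F1 layout)
    return out


def power_fractions(fn, n_reps: int = 50, seed: int = 0, alpha: float = 0.05):
    """Fraction of replicates with p < alpha, per key returned by ``fn``."""
    seeds = _seeds(seed, n_reps)
    rows = [fn(int(s)) for s in seeds]
    df = pd.DataFrame(rows)
    return {k: float((df[k] < alpha).mean()) for k in df.columns}, df
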