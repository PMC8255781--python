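"""Rank-based nonparametric tests for longitudinal factorial designs.

Implements the estimands and test statistics of nonparametric analysis of
longitudinal data in factorial experiments ("F1-LD-F1" and "F2-LD-F1"
layouts: one or two whole-plot/between-subject factors crossed with a
repeated time factor).

All observations are converted to global midranks R_ik. The relative
treatment effect (RTE) of a cell is

    p_hat = (mean midrank - 1/2) / N,

a probability-scale effect size in (0, 1) whose observation-weighted mean
over all cells is exactly 1/2. Hypotheses about the vector p of cell RTEs
are tested with contrast matrices C built from centering matrices
(Kronecker products over the factors):

* Wald-type statistic (WTS):  Q = (C p_hat)' (C V C')^+ (C p_hat),
  referred to chi-square with df = rank(C). V is the estimated covariance
  of p_hat, block-diagonal over whole-plot groups, from the empirical
  covariance of subject-level rank vectors. The WTS is known to be liberal
  at small sample sizes.
* ANOVA-type statistic (ATS): F = p_hat' T p_hat / tr(T V) with
  T = C'(CC')^+ C, referred to the Box approximation chi-square(f)/f with
  f = tr(TV)^2 / tr(TVTV). Better calibrated for the group sizes typical
  of mouse studies (n ~ 8-9).

Ties are handled by midranks throughout; both statistics are invariant
under strictly monotone transforms of the data. Missing cells use
available-case covariance; entirely empty cells are dropped from the
contrast and named in the result rather than silently imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-values."""

    factor: str
    statistic: float
    df: float
    p_raw: float
    method: str  # "wts" or "ats"
    n_units: int
    p_corrected: float | None = None
    dropped_cells: tuple = ()

    def as_dict(self) -> dict:
        return {
            "factor": self.factor, "method": self.method,
            "statistic": self.statistic, "df": self.df,
            "p_raw": self.p_raw, "p_corrected": self.p_corrected,
            "n": self.n_units,
        }


@dataclass
class LongitudinalDataset:
    """Long-format observations: unit x whole-plot factor(s) x time.

    ``factors`` names one (F1-LD-F1) or two (F2-LD-F1) between-unit
    columns; each unit must have a single whole-plot assignment. Factor and
    time level orders are taken from first appearance unless given.
    """

    data: pd.DataFrame
    unit: str = "unit"
    factors: tuple[str, ...] = ("group",)
    time: str = "time"
    value: str = "value"
    time_levels: tuple | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        needed = {self.unit, self.time, self.value, *self.factors}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        df = df.dropna(subset=[self.value])
        if not np.isfinite(df[self.value].to_numpy(dtype=float)).all():
            raise ValueError("non-finite observation values")
        assign = df.groupby(self.unit)[list(self.factors)].nunique()
        if (assign > 1).any().any():
            raise ValueError("a unit appears under more than one whole-plot assignment")
        self.data = df
        if self.time_levels is None:
            self.time_levels = tuple(pd.unique(df[self.time]))

    @property
    def design_type(self) -> str:
        return {1: "F1_LD_F1", 2: "F2_LD_F1"}[len(self.factors)]

    def factor_levels(self) -> list[tuple]:
        return [tuple(pd.unique(self.data[f])) for f in self.factors]


def midranks(values) -> np.ndarray:
    """Midranks (ties get the mean of their covered rank positions)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values")
    return sstats.rankdata(values, method="average")


def _cell_layout(ld: LongitudinalDataset):
    """Cell bookkeeping: ordered whole-plot groups x time levels."""
    flevels = ld.factor_levels()
    if len(flevels) == 1:
        groups = [(a,) for a in flevels[0]]
    else:
        groups = [(a, b) for a in flevels[0] for b in flevels[1]]
    times = list(ld.time_levels)
    return flevels, groups, times


def _rank_matrices(ld: LongitudinalDataset):
    """Per-group unit x time matrices of global midranks / N (NaN = missing)."""
    df = ld.data
    N = len(df)
    r = midranks(df[ld.value].to_numpy()) / N
    flevels, groups, times = _cell_layout(ld)
    tpos = {t: j for j, t in enumerate(times)}
    t_idx = df[ld.time].map(tpos).to_numpy()
    if len(ld.factors) == 1:
        cell_codes, cell_levels = pd.factorize(df[ld.factors[0]])
        code_of = {(lev,): c for c, lev in enumerate(cell_levels)}
    else:
        mi = pd.MultiIndex.from_arrays([df[f] for f in ld.factors])
        cell_codes, cell_levels = pd.factorize(mi)
        code_of = {tuple(lev): c for c, lev in enumerate(cell_levels)}
    units = df[ld.unit].to_numpy()
    mats = {}
    for g in groups:
        code = code_of.get(g)
        sel = cell_codes == code if code is not None else np.zeros(len(df), bool)
        if not sel.any():
            mats[g] = np.empty((0, len(times)))
            continue
        u_codes, _ = pd.factorize(units[sel])
        M = np.full((u_codes.max() + 1, len(times)), np.nan)
        M[u_codes, t_idx[sel]] = r[sel]
        mats[g] = M
    return mats, groups, times, N


def relative_effects(ld: LongitudinalDataset) -> pd.DataFrame:
    """RTE p_hat = (mean midrank - 1/2)/N per (group, time) cell."""
    mats, groups, times, N = _rank_matrices(ld)
    rows = []
    for g in groups:
        M = mats[g]
        for j, t in enumerate(times):
            col = M[:, j] if M.size else np.array([])
            n_obs = int(np.sum(np.isfinite(col)))
            if n_obs == 0:
                warnings.warn(f"empty cell {g} x time={t}: relative effect missing")
                p_hat = np.nan
            else:
                p_hat = float(np.nanmean(col)) - 0.5 / N
            row = {f: lev for f, lev in zip(ld.factors, g)}
            row.update({ld.time: t, "p_hat": p_hat, "n_obs": n_obs})
            rows.append(row)
    return pd.DataFrame(rows)


def _phat_and_cov(ld: LongitudinalDataset):
    """Stacked cell RTE vector and its block-diagonal covariance estimate."""
    mats, groups, times, N = _rank_matrices(ld)
    T = len(times)
    d = len(groups) * T
    phat = np.full(d, np.nan)
    V = np.zeros((d, d))
    n_units_total = 0
    group_n = {}
    for gi, g in enumerate(groups):
        M = mats[g]
        n_units = M.shape[0]
        group_n[g] = n_units
        n_units_total += n_units
        if n_units < 2:
            raise ValueError(
                f"whole-plot cell {g} has {n_units} unit(s); >=2 required for "
                "covariance estimation")
        sl = slice(gi * T, (gi + 1) * T)
        counts = np.sum(np.isfinite(M), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(M, axis=0)
        phat[sl] = means - 0.5 / N
        # available-case covariance of unit rank vectors
        S = pd.DataFrame(M).cov(min_periods=2).to_numpy()
        S = np.nan_to_num(S, nan=0.0)
        denom = np.sqrt(np.outer(np.maximum(counts, 1), np.maximum(counts, 1)))
        V[sl, sl] = S / denom
    return phat, V, groups, times, n_units_total, group_n


def _centering(k: int) -> np.ndarray:
    return np.eye(k) - np.ones((k, k)) / k


def _avg(k: int) -> np.ndarray:
    return np.ones((1, k)) / k


def effect_contrasts(n_levels: list[int], time_levels: int) -> dict[str, np.ndarray]:
    """Contrast matrices for all main effects and interactions.

    Cell order is the lexicographic product (factor A outermost, time
    innermost) matching `_phat_and_cov`.
    """
    parts = {name: None for name in ()}
    out: dict[str, np.ndarray] = {}
    if len(n_levels) == 1:
        a, t = n_levels[0], time_levels
        out["group"] = np.kron(_centering(a), _avg(t))
        out["time"] = np.kron(_avg(a), _centering(t))
        out["group:time"] = np.kron(_centering(a), _centering(t))
    elif len(n_levels) == 2:
        a, b, t = n_levels[0], n_levels[1], time_levels
        out["A"] = np.kron(np.kron(_centering(a), _avg(b)), _avg(t))
        out["B"] = np.kron(np.kron(_avg(a), _centering(b)), _avg(t))
        out["A:B"] = np.kron(np.kron(_centering(a), _centering(b)), _avg(t))
        out["time"] = np.kron(np.kron(_avg(a), _avg(b)), _centering(t))
        out["A:time"] = np.kron(np.kron(_centering(a), _avg(b)), _centering(t))
        out["B:time"] = np.kron(np.kron(_avg(a), _centering(b)), _centering(t))
        out["A:B:time"] = np.kron(np.kron(_centering(a), _centering(b)), _centering(t))
    else:
        raise ValueError("only one or two whole-plot factors supported")
    return out


def _resolve_contrast(ld: LongitudinalDataset, effect: str) -> np.ndarray:
    flevels, groups, times = _cell_layout(ld)
    contrasts = effect_contrasts([len(l) for l in flevels], len(times))
    # factor column names act as aliases for the canonical effect labels
    if len(flevels) == 1:
        aliases = {ld.factors[0]: "group"}
    else:
        aliases = {ld.factors[0]: "A", ld.factors[1]: "B",
                   f"{ld.factors[0]}:{ld.factors[1]}": "A:B",
                   f"{ld.factors[0]}:time": "A:time",
                   f"{ld.factors[1]}:time": "B:time",
                   f"{ld.factors[0]}:{ld.factors[1]}:time": "A:B:time"}
    key = aliases.get(effect, effect)
    if key not in contrasts:
        raise ValueError(f"unknown effect {effect!r}; available: {sorted(contrasts)}")
    return contrasts[key]


def _drop_missing_cells(C, phat, V, groups, times):
    """Available-case handling: remove entirely empty cells from the test."""
    ok = np.isfinite(phat)
    dropped = []
    if not ok.all():
        T = len(times)
        labels = [f"{g}@t={t}" for g in groups for t in times]
        dropped = [labels[i] for i in np.flatnonzero(~ok)]
        C = C[:, ok]
        # keep only contrast rows not touching missing cells got truncated;
        # re-center rows so each still sums to zero where applicable
        phat = phat[ok]
        V = V[np.ix_(ok, ok)]
        keep_rows = np.abs(C).sum(axis=1) > 1e-12
        C = C[keep_rows]
    return C, phat, V, tuple(dropped)


def wald_type_statistic(ld: LongitudinalDataset, effect: str,
                        _prep=None) -> TestResult:
    """Wald-type statistic for a main effect or interaction.

    chi-square reference with df = rank(C); liberal at small n.
    """
    phat, V, groups, times, n_units, _group_n = _prep or _phat_and_cov(ld)
    C = _resolve_contrast(ld, effect)
    C, phat, V, dropped = _drop_missing_cells(C, phat, V, groups, times)
    M = C @ V @ C.T
    df = int(np.linalg.matrix_rank(C))
    if df == 0 or np.allclose(M, 0):
        raise ValueError(
            f"singular covariance for effect {effect!r}; deficient cells: "
            f"{dropped or 'rank-0 contrast'}")
    Cp = C @ phat
    Q = float(Cp @ np.linalg.pinv(M) @ Cp)
    p = float(sstats.chi2.sf(Q, df))
    return TestResult(effect, Q, df, p, "wts", n_units, dropped_cells=dropped)


def anova_type_statistic(ld: LongitudinalDataset, effect: str,
                         _prep=None) -> TestResult:
    """ANOVA-type statistic with Box-approximated degrees of freedom.

    Within-unit effects (those involving time) use the chi2(f)/f
    reference. Purely between-unit effects use the Box-modified F(f, f0)
    reference with a denominator df estimated from the per-group blocks:
    with groups of 8-9 units the plain chi2 reference is measurably
    liberal, and the F tail accounts for the finite covariance sample.
    With dropped (entirely empty) cells the chi2 reference is used, since
    the group blocks are no longer aligned.
    """
    phat, V, groups, times, n_units, group_n = _prep or _phat_and_cov(ld)
    C = _resolve_contrast(ld, effect)
    C, phat, V, dropped = _drop_missing_cells(C, phat, V, groups, times)
    Tm = C.T @ np.linalg.pinv(C @ C.T) @ C
    TV = Tm @ V
    tv = float(np.trace(TV))
    if tv <= 0:
        raise ValueError(
            f"singular covariance for effect {effect!r}; deficient cells: "
            f"{dropped or 'zero trace'}")
    F = float(phat @ Tm @ phat) / tv
    f_hat = tv**2 / float(np.trace(TV @ TV))
    f0 = None
    if "time" not in effect and not dropped:
        T_count = len(times)
        denom = 0.0
        for gi, g in enumerate(groups):
            block = TV[gi * T_count:(gi + 1) * T_count,
                       gi * T_count:(gi + 1) * T_count]
            denom += float(np.trace(block)) ** 2 / (group_n[g] - 1)
        if denom > 0:
            f0 = tv**2 / denom
    if f0 is not None:
        p = float(sstats.f.sf(F, f_hat, f0))
    else:
        p = float(sstats.chi2.sf(F * f_hat, f_hat))
    return TestResult(effect, F, f_hat, p, "ats", n_units, dropped_cells=dropped)


def fit_design(ld: LongitudinalDataset) -> dict[str, dict[str, TestResult]]:
    """All main effects and interactions of the design, as WTS and ATS.

    F1-LD-F1 yields {group, time, group:time}; F2-LD-F1 yields
    {A, B, A:B, time, A:time, B:time, A:B:time}. With a single time level
    the time-involving tests are omitted.
    """
    flevels, groups, times = _cell_layout(ld)
    contrasts = effect_contrasts([len(l) for l in flevels], len(times))
    effects = [e for e, C in contrasts.items() if np.abs(C).sum() > 1e-12]
    if len(times) == 1:
        effects = [e for e in effects if "time" not in e]
    prep = _phat_and_cov(ld)  # shared across effects: one ranking/covariance pass
    out = {}
    for e in effects:
        out[e] = {"wts": wald_type_statistic(ld, e, _prep=prep),
                  "ats": anova_type_statistic(ld, e, _prep=prep)}
    return out


def bonferroni(p_values, family_size: int | None = None):
    """Bonferroni correction p_c = min(1, m * p), order-preserving.

    ``family_size`` defaults to len(p_values); it may exceed it when the
    family includes tests reported elsewhere.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family size must be >= 1")
    out = np.minimum(1.0, m * p)
    return float(out[0]) if np.isscalar(p_values) or np.ndim(p_values) == 0 else out


#: severity tiers used in report rendering (p < threshold)
SIGNIFICANCE_TIERS = (0.05, 0.001, 0.0001)


def significance_tier(p_corrected: float) -> int:
    """0 = not significant; 1, 2, 3 = p < 0.05, 0.001, 0.0001."""
    tier = 0
    for i, thr in enumerate(SIGNIFICANCE_TIERS, start=1):
        if p_corrected < thr:
            tier = i
    return tier


def posthoc_timepoints(data: pd.DataFrame, unit: str = "unit", group: str = "group",
                       time: str = "time", value: str = "value",
                       family_size: int | None = None,
                       statistic: str = "ats") -> list[TestResult]:
    """Per-time-bin two-group rank comparison with Bonferroni correction.

    For each time level, the two groups are compared with a one-timepoint
    rank test (the WTS/ATS machinery at a single time level, i.e. a
    rank-based two-sample test of the relative effect). The Bonferroni
    family size defaults to the number of time levels tested. Bins with
    fewer than 2 units in either group are skipped with a warning.
    """
    df = pd.DataFrame(data)
    times = list(pd.unique(df[time]))
    results = []
    for t in times:
        sub = df[df[time] == t]
        counts = sub.groupby(group)[unit].nunique()
        if len(counts) < 2 or (counts < 2).any():
            warnings.warn(f"time bin {t}: fewer than 2 units per group; skipped")
            continue
        ld = LongitudinalDataset(sub.assign(_one=0), unit=unit, factors=(group,),
                                 time="_one", value=value)
        fn = anova_type_statistic if statistic == "ats" else wald_type_statistic
        res = fn(ld, "group")
        res.factor = f"{group}@{time}={t}"
        results.append(res)
    m = family_size if family_size is not None else max(len(results), 1)
    for res in results:
        res.p_corrected = bonferroni(res.p_raw, m)
    return results


def results_table(results) -> pd.DataFrame:
    """Flatten TestResults (list or nested dict) into a tidy DataFrame."""
    rows = []

    def _walk(obj, prefix=()):
        if isinstance(obj, TestResult):
            row = obj.as_dict()
            if prefix:
                row["context"] = "/".join(map(str, prefix))
            rows.append(row)
        elif isinstance(obj, dict):
            for k, v in obj.items():
                _walk(v, prefix + (k,))
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                _walk(v, prefix)

    _walk(results)
    return pd.DataFrame(rows)
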