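"""Band aggregation, time binning and the two normalization schemes.

The 70 filter-bank channels are averaged (unweighted) into the seven named
bands by channel center frequency, using half-open ranges [lo, hi). The
channel grid (centers 1.8 + 1.4k Hz) never lands exactly on a band edge,
and the overlapping sigma band shares channels with alpha and beta by
construction.

Two normalizations are supported:

* baseline ("fraction"): each band divided by the sum of all seven bands in
  the same time bin, so every bin's bands sum to 1 — note the overlapping
  bands mean shared channels count once per band in the total;
* pretreatment ("ratio"): each band's time course divided by that band's
  (epoch-weighted) mean power over the pre-injection window, so the
  pretreatment mean of the output is exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_ORDER, BAND_RANGES
from .spectral import EpochPowerMatrix, EPOCH_LEN_S

ACUTE_WINDOW_S = (0.0, 120 * 60.0)
SUBACUTE_WINDOW_S = (120 * 60.0, 300 * 60.0)


def band_members(centers: np.ndarray) -> dict[str, np.ndarray]:
    """Filter-bank channel indices belonging to each band (by center freq)."""
    centers = np.asarray(centers)
    members = {}
    for band, (lo, hi) in BAND_RANGES.items():
        idx = np.flatnonzero((centers >= lo) & (centers < hi))
        if idx.size == 0:
            raise ValueError(f"band {band} has no member channels")
        members[band] = idx
    return members


def aggregate_bands(epm: EpochPowerMatrix) -> pd.DataFrame:
    """Per-epoch 7-band power table (unweighted mean over member channels).

    Returns a DataFrame with columns epoch_index, t_start_s, kept and one
    column per band; all epochs are present, artifact epochs have kept=False.
    """
    members = band_members(epm.centers)
    kept = np.zeros(epm.n_epochs, dtype=bool)
    kept[epm.kept_epochs] = True
    out = {
        "epoch_index": np.arange(epm.n_epochs),
        "t_start_s": np.arange(epm.n_epochs) * epm.epoch_len_s,
        "kept": kept,
    }
    for band in BAND_ORDER:
        out[band] = epm.values[:, members[band]].mean(axis=1)
    return pd.DataFrame(out)


def bin_time(band_table: pd.DataFrame, bin_width_s: float,
             anchor_s: float = 0.0, epoch_len_s: float = EPOCH_LEN_S) -> pd.DataFrame:
    """Average kept epochs into fixed-width time bins.

    Bin k covers [anchor + k*w, anchor + (k+1)*w) seconds; k may be
    negative (pre-injection bins when anchored at the injection). Bins with
    zero kept epochs appear with NaN band values and n_epochs 0. Returns a
    DataFrame with bin_start_s (relative to anchor), n_epochs and band
    columns.
    """
    if abs(bin_width_s / epoch_len_s - round(bin_width_s / epoch_len_s)) > 1e-9:
        raise ValueError(f"bin width {bin_width_s} s not a multiple of {epoch_len_s}-s epochs")
    t_rel = band_table["t_start_s"].to_numpy() - anchor_s
    bin_idx = np.floor(t_rel / bin_width_s).astype(int)
    kept = band_table["kept"].to_numpy()

    rows = []
    for k in range(bin_idx.min(), bin_idx.max() + 1):
        sel = (bin_idx == k) & kept
        n = int(sel.sum())
        row = {"bin_start_s": k * bin_width_s, "n_epochs": n}
        for band in BAND_ORDER:
            row[band] = band_table.loc[sel, band].mean() if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_baseline(binned: pd.DataFrame) -> pd.DataFrame:
    """Divide each band by the 7-band total within the same time bin.

    Bins whose total is zero (or missing) come out as NaN with a warning.
    """
    out = binned.copy()
    totals = binned[list(BAND_ORDER)].sum(axis=1, skipna=False)
    bad = (totals == 0) | totals.isna()
    if (bad & (binned["n_epochs"] > 0)).any():
        import warnings

        warnings.warn("bins with zero total band power normalized to NaN")
    safe = totals.where(~bad)
    for band in BAND_ORDER:
        out[band] = binned[band] / safe
    return out


def normalize_pretreatment(binned: pd.DataFrame,
                           pre_window_s: tuple[float, float] = (-3600.0, 0.0)) -> pd.DataFrame:
    """Divide each band's time course by its pretreatment-window mean.

    The pretreatment mean is epoch-weighted over bins whose start lies in
    ``pre_window_s`` (seconds relative to injection). Raises when the
    window contains no kept epochs or a band's mean is zero.
    """
    sel = (binned["bin_start_s"] >= pre_window_s[0]) & \
          (binned["bin_start_s"] < pre_window_s[1]) & (binned["n_epochs"] > 0)
    if not sel.any():
        raise ValueError("no kept pretreatment bins in the normalization window")
    weights = binned.loc[sel, "n_epochs"].to_numpy(dtype=float)
    out = binned.copy()
    for band in BAND_ORDER:
        pre_mean = np.average(binned.loc[sel, band].to_numpy(dtype=float), weights=weights)
        if not np.isfinite(pre_mean) or pre_mean == 0:
            raise ValueError(f"zero or undefined pretreatment mean for band {band}")
        out[band] = binned[band] / pre_mean
    return out


def window_mean(binned: pd.DataFrame, window_s: tuple[float, float]) -> pd.Series:
    """Epoch-weighted mean band power over a time window (per band).

    ``window_s`` is (start, end) in seconds relative to the binning anchor;
    bins are included when their start lies inside. Returns a Series
    indexed by band; all-NaN (no bins / no epochs) when the window is empty.
    """
    sel = (binned["bin_start_s"] >= window_s[0]) & \
          (binned["bin_start_s"] < window_s[1]) & (binned["n_epochs"] > 0)
    if not sel.any():
        return pd.Series({band: np.nan for band in BAND_ORDER})
    w = binned.loc[sel, "n_epochs"].to_numpy(dtype=float)
    return pd.Series({
        band: float(np.average(binned.loc[sel, band].to_numpy(dtype=float), weights=w))
        for band in BAND_ORDER
    })


def to_long(binned: pd.DataFrame, **keys) -> pd.DataFrame:
    """Long-format view (one row per band x bin) with identifying columns.

    ``keys`` (e.g. subject, session, treatment, genotype) are attached as
    constant columns; bin start is reported in minutes for readability.
    """
    long = binned.melt(id_vars=["bin_start_s", "n_epochs"],
                       value_vars=list(BAND_ORDER),
                       var_name="band", value_name="value")
    long["time_bin_start_min"] = long["bin_start_s"] / 60.0
    for k, v in keys.items():
        long[k] = v
    return long
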