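"""Canonical EEG frequency-band definitions.

Seven named bands cover 1-100 Hz. Sigma (10-15 Hz) deliberately overlaps
alpha (8-12) and beta (12-30): sleep-spindle activity straddles the
alpha/beta boundary, and the bands are analyzed independently, so a
filter-bank channel may contribute to two bands.
"""

from __future__ import annotations

# Half-open ranges [lo, hi) in Hz, in canonical order.
BAND_RANGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (10.0, 15.0),
    "beta": (12.0, 30.0),
    "gamma1": (30.0, 50.0),
    "gamma2": (50.0, 100.0),
}

BAND_ORDER: tuple[str, ...] = tuple(BAND_RANGES)


def band_of(freq: float) -> list[str]:
    """Return every band whose half-open range contains ``freq``."""
    return [b for b, (lo, hi) in BAND_RANGES.items() if lo <= freq < hi]


def check_band(label: str) -> None:
    if label not in BAND_RANGES:
        raise ValueError(f"unknown band label {label!r}; expected one of {BAND_ORDER}")
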