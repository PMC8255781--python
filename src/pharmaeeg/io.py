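"""Reading and writing the pipeline's interchange formats.

Raw recordings travel as EDF (16-bit, physical units uV) with channel
labels EEG1 (frontal), EEG2 (parietal), and EMG; artifact masks, study
design tables and result tables are TSV with a header row; generator and
study configuration is YAML/JSON. Reading EDF goes through MNE; writing
uses a minimal EDF encoder in this module (1-s data records, per-channel
physical scaling), so a written file is always re-read by an independent
implementation.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import ArtifactMask
from .synth import RawRecording

#: EDF label <-> internal channel name
CHANNEL_ALIASES = {
    "EEG1": "eeg_frontal",
    "EEG2": "eeg_parietal",
    "EMG": "emg",
}
_REVERSE_ALIASES = {v: k for k, v in CHANNEL_ALIASES.items()}


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: RawRecording, start: _dt.datetime | None = None) -> Path:
    """Write a recording as EDF (16-bit integers, physical dimension uV).

    Uses 1-s data records; the recording is zero-padded to a whole number
    of seconds. Physical ranges are symmetric per channel and rounded to
    integers so the header scale is exactly representable in ASCII.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    start = start or _dt.datetime(2021, 1, 1, 9, 0, 0)

    labels = [_REVERSE_ALIASES.get(name, name[:16]) for name in recording.channels]
    data = [np.asarray(x, dtype=np.float64) for x in recording.channels.values()]
    n = max(len(x) for x in data)
    n_records = int(np.ceil(n / fs))
    padded = np.zeros((len(data), n_records * fs))
    for i, x in enumerate(data):
        padded[i, : len(x)] = x

    phys_max = [max(1, int(np.ceil(np.max(np.abs(x)) * 1.001))) for x in padded]
    dig_min, dig_max = -32768, 32767

    ns = len(data)
    header = b"".join([
        _ascii_field(0, 8),
        _ascii_field("X X X X", 80),
        _ascii_field("Startdate X X X X", 80),
        _ascii_field(start.strftime("%d.%m.%y"), 8),
        _ascii_field(start.strftime("%H.%M.%S"), 8),
        _ascii_field(256 * (ns + 1), 8),
        _ascii_field("EDF+C", 44),
        _ascii_field(n_records, 8),
        _ascii_field(1, 8),
        _ascii_field(ns, 4),
    ])
    sig_header = b"".join([
        b"".join(_ascii_field(lab, 16) for lab in labels),
        b"".join(_ascii_field("synthetic", 80) for _ in labels),
        b"".join(_ascii_field("uV", 8) for _ in labels),
        b"".join(_ascii_field(-pm, 8) for pm in phys_max),
        b"".join(_ascii_field(pm, 8) for pm in phys_max),
        b"".join(_ascii_field(dig_min, 8) for _ in labels),
        b"".join(_ascii_field(dig_max, 8) for _ in labels),
        b"".join(_ascii_field("", 80) for _ in labels),
        b"".join(_ascii_field(fs, 8) for _ in labels),
        b"".join(_ascii_field("", 32) for _ in labels),
    ])

    digital = np.empty((len(data), n_records * fs), dtype=np.int16)
    for i, x in enumerate(padded):
        scale = (dig_max - dig_min) / (2.0 * phys_max[i])
        d = np.rint((x + phys_max[i]) * scale + dig_min)
        digital[i] = np.clip(d, dig_min, dig_max).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: for each second, each channel's fs samples, int16 LE
        rec_view = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec_view, dtype="<i2").tobytes())
    return path


def read_recording(path, expected_channels=("eeg_frontal", "eeg_parietal", "emg"),
                   aliases: dict[str, str] | None = None) -> RawRecording:
    """Read an EDF/EDF+ file into a RawRecording (channel data in uV).

    ``aliases`` maps EDF labels to internal channel names (defaults to
    EEG1/EEG2/EMG). ``expected_channels=None`` accepts whatever channels
    the file has; otherwise a missing required channel raises.
    """
    import mne

    aliases = aliases or CHANNEL_ALIASES
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = {}
    for label in raw.ch_names:
        internal = aliases.get(label, label)
        available[internal] = label
    if expected_channels is None:
        expected_channels = tuple(available)
    missing = [c for c in expected_channels if c not in available]
    if missing:
        raise ValueError(f"missing channel(s) {missing} in {path}; found {raw.ch_names}")
    fs = float(raw.info["sfreq"])
    picks = [available[c] for c in expected_channels]
    data = raw.get_data(picks=picks, units="uV")
    channels = {c: data[i] for i, c in enumerate(expected_channels)}
    return RawRecording(channels=channels, fs=fs, meta={"path": str(path)})


def write_artifact_mask(path, mask: ArtifactMask, subject: str = "", session: str = "") -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "subject": subject,
        "session": session,
        "epoch_index": np.arange(mask.n_epochs),
        "is_artifact": mask.is_artifact.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)
    return path


def read_artifact_mask(path, n_epochs: int) -> ArtifactMask:
    """Read a TSV artifact mask; absent epoch indices default to clean.

    Raises on duplicate indices and on indices >= ``n_epochs``.
    """
    df = pd.read_csv(path, sep="\t")
    if "epoch_index" not in df.columns or "is_artifact" not in df.columns:
        raise ValueError(f"{path}: expected columns epoch_index, is_artifact")
    idx = df["epoch_index"].to_numpy(dtype=int)
    if len(idx) and (idx.min() < 0 or idx.max() >= n_epochs):
        raise ValueError(f"{path}: epoch_index out of range [0, {n_epochs})")
    if pd.Series(idx).duplicated().any():
        raise ValueError(f"{path}: duplicate epoch_index entries")
    flags = np.zeros(n_epochs, dtype=bool)
    flags[idx] = df["is_artifact"].astype(bool).to_numpy()
    return ArtifactMask(flags)


def write_design(path, design: pd.DataFrame) -> Path:
    path = Path(path)
    design.to_csv(path, sep="\t", index=False)
    return path


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "genotype", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    return df


def write_config(path, config: dict) -> Path:
    """Write a configuration mapping (e.g. a GeneratorSpec dict) as YAML."""
    import yaml

    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def read_config(path) -> dict:
    import yaml

    return yaml.safe_load(Path(path).read_text())


@dataclass(frozen=True)
class SessionLayout:
    """Expected pharmaco-EEG session geometry (seconds from recording start)."""

    pre_start_s: float = 0.0
    injection_time_s: float = 3600.0
    post_end_s: float = 3600.0 + 5 * 3600.0

    def __post_init__(self) -> None:
        if not (self.pre_start_s < self.injection_time_s < self.post_end_s):
            raise ValueError("require pre_start < injection_time < post_end")


def validate_session(recording: RawRecording, layout: SessionLayout) -> list[dict]:
    """Structural diagnostics for a session recording (never raises).

    Returns a list of {level, code, message} dicts; empty when conforming.
    """
    diags: list[dict] = []
    dur = recording.duration_s
    if dur + 1e-9 < layout.post_end_s - layout.pre_start_s:
        diags.append({
            "level": "warning", "code": "truncated",
            "message": f"recording {dur:.0f} s shorter than expected "
                       f"{layout.post_end_s - layout.pre_start_s:.0f} s session",
        })
    for name, x in recording.channels.items():
        bad = ~np.isfinite(np.asarray(x))
        if bad.any():
            diags.append({
                "level": "error", "code": "non_finite",
                "message": f"channel {name}: {int(bad.sum())} non-finite samples",
            })
    if recording.fs <= 0:
        diags.append({"level": "error", "code": "bad_rate",
                      "message": f"non-positive sampling rate {recording.fs}"})
    return diags
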