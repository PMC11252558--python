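"""EDF interchange: a minimal 16-bit EDF writer and an MNE-backed reader.

EDF (European Data Format) is the clinical standard for scalp EEG
exchange. Reading goes through :func:`mne.io.read_raw_edf`; writing is a
small self-contained implementation of the EDF header + 16-bit
little-endian data records (1-second records), sufficient for synthetic
cohorts and round-trip tests.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .recording import CHANNELS_1020, EegRecording

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32767, 32767


def _pad(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EegRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be a whole number of samples per second; a
    trailing partial second is truncated. Amplitudes are quantized onto the
    symmetric 16-bit grid spanning the recording's amplitude range.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * spr]
    ns = rec.n_channels

    phys_max = float(np.max(np.abs(data)))
    phys_max = phys_max if phys_max > 0 else 1.0
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + _DIG_MIN).astype("<i2")

    header = b"".join([
        _pad(0, 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(256 * (ns + 1), 8),
        _pad("", 44),
        _pad(n_records, 8),
        _pad(1, 8),
        _pad(ns, 4),
    ])
    fields = [
        (16, [f"EEG {ch}-REF" for ch in rec.channel_labels]),
        (80, [""] * ns),                       # transducer
        (8, ["uV"] * ns),
        (8, [f"{phys_min:.6g}" for _ in range(ns)]),
        (8, [f"{phys_max:.6g}" for _ in range(ns)]),
        (8, [str(_DIG_MIN)] * ns),
        (8, [str(_DIG_MAX)] * ns),
        (80, [""] * ns),                       # prefiltering
        (8, [str(spr)] * ns),
        (32, [""] * ns),
    ]
    signal_header = b"".join(
        b"".join(_pad(v, width) for v in values) for width, values in fields
    )
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


def normalize_channel_label(raw_label: str, channel_map: dict | None = None) -> str | None:
    """Map a vendor channel name onto the 19-name 10-20 vocabulary.

    Strips an ``EEG `` prefix and a ``-REF``/``-LE``-style reference suffix,
    then matches case-insensitively; an explicit ``channel_map`` entry wins.
    Returns None for channels outside the vocabulary.
    """
    if channel_map and raw_label in channel_map:
        return channel_map[raw_label]
    name = raw_label
    if name.upper().startswith("EEG "):
        name = name[4:]
    name = name.split("-")[0].strip()
    for ch in CHANNELS_1020:
        if name.lower() == ch.lower():
            return ch
    return None


def read_edf(
    path: str | Path,
    channel_map: dict | None = None,
    required_channels: tuple[str, ...] | None = None,
) -> EegRecording:
    """Read an EDF file into an :class:`EegRecording` (amplitudes in microvolts).

    Channel names are normalized onto the 10-20 vocabulary; channels outside
    it are dropped with a log line. ``required_channels`` raises a named
    error for any electrode the analysis needs that the file lacks.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels, keep_idx = [], []
    for i, raw_label in enumerate(raw.ch_names):
        label = normalize_channel_label(raw_label, channel_map)
        if label is None:
            logger.info("dropping non-10-20 channel %r from %s", raw_label, path)
            continue
        labels.append(label)
        keep_idx.append(i)
    if len(labels) < 2:
        raise ValueError(f"{path}: fewer than 2 recognized EEG channels")
    if required_channels:
        missing = [ch for ch in required_channels if ch not in labels]
        if missing:
            raise ValueError(f"{path}: required channel(s) missing: {missing}")
    data = raw.get_data(picks=keep_idx, units="uV")
    return EegRecording(
        data=np.asarray(data, dtype=float),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        meta={"source": str(path)},
    )
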