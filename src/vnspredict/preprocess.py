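"""Deterministic EEG conditioning: re-referencing, resampling, filtering, epoching.

All filters are zero-phase FIR (forward design with delay compensation, as
implemented by MNE) with 1 Hz transition bands; phase distortion would bias
the phase-lag-index estimates downstream, so IIR filtering is deliberately
avoided.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from mne.filter import filter_data, notch_filter
from scipy.signal import resample_poly

from .recording import BandDefinition, EegRecording, EpochedSignal

#: Transition bandwidth (Hz) for all FIR designs.
TRANSITION_BANDWIDTH = 1.0

DEFAULT_SAMPLING_RATE = 500.0
BROADBAND = (1.0, 30.0)
NOTCH_FREQ = 50.0
DEFAULT_EPOCH_LENGTH = 2.0


def rereference_average(rec: EegRecording) -> EegRecording:
    """Subtract the instantaneous mean across channels (average reference).

    After this operation the mean over channels is zero at every sample.
    Idempotent. Requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(data, reference="average")


def resample(rec: EegRecording, target_rate: float = DEFAULT_SAMPLING_RATE) -> EegRecording:
    """Resample to ``target_rate`` Hz with polyphase anti-aliasing filtering.

    Duration is preserved to within one output sample.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sampling_rate:
        return rec
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(10000)
    data = resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    out = rec.with_data(data, resampled_from=rec.sampling_rate)
    out.sampling_rate = float(target_rate)
    return out


def filter_broadband(
    rec: EegRecording,
    f_lo: float = BROADBAND[0],
    f_hi: float = BROADBAND[1],
    notch: float | None = NOTCH_FREQ,
) -> EegRecording:
    """Band-pass 1-30 Hz plus a 50 Hz power-line notch, zero phase.

    The sampling rate must exceed 100 Hz so the notch lies below Nyquist.
    """
    if rec.sampling_rate <= 100:
        raise ValueError("sampling_rate must exceed 100 Hz for the 50 Hz notch")
    data = filter_data(
        rec.data, rec.sampling_rate, f_lo, f_hi,
        l_trans_bandwidth=TRANSITION_BANDWIDTH,
        h_trans_bandwidth=TRANSITION_BANDWIDTH,
        verbose=False,
    )
    if notch is not None:
        data = notch_filter(
            data, rec.sampling_rate, notch,
            trans_bandwidth=TRANSITION_BANDWIDTH, verbose=False,
        )
    return rec.with_data(data, broadband=(f_lo, f_hi), notch=notch)


def filter_band(rec: EegRecording, band: BandDefinition) -> EegRecording:
    """Zero-phase band-pass to [f_lo, f_hi).

    Shared edges between adjacent bands are resolved at the design level:
    the passband edge sits at the nominal frequency with a 1 Hz transition
    band on each side, so a tone at a shared edge appears at roughly half
    amplitude in both neighbours.
    """
    nyquist = rec.sampling_rate / 2
    if band.f_hi >= nyquist:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_hi} Hz >= Nyquist {nyquist} Hz"
        )
    data = filter_data(
        rec.data, rec.sampling_rate, band.f_lo, band.f_hi,
        l_trans_bandwidth=TRANSITION_BANDWIDTH,
        h_trans_bandwidth=TRANSITION_BANDWIDTH,
        verbose=False,
    )
    return rec.with_data(data, band=band.name)


def segment_epochs(
    rec: EegRecording,
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    band: BandDefinition | None = None,
    edge_trim: float = 0.0,
) -> EpochedSignal:
    """Cut the recording into contiguous non-overlapping epochs.

    The trailing partial epoch is discarded. ``edge_trim`` seconds are
    removed from each end first (used downstream to exclude analytic-signal
    boundary distortion from phase epochs).
    """
    n_per = int(round(epoch_length * rec.sampling_rate))
    trim = int(round(edge_trim * rec.sampling_rate))
    data = rec.data[:, trim: rec.n_samples - trim if trim else rec.n_samples]
    if data.shape[1] < n_per:
        raise ValueError(
            f"duration after trimming ({data.shape[1] / rec.sampling_rate:.3f} s) "
            f"shorter than epoch length ({epoch_length} s)"
        )
    n_epochs = data.shape[1] // n_per
    epochs = data[:, : n_epochs * n_per].reshape(rec.n_channels, n_epochs, n_per)
    return EpochedSignal(
        epochs=np.ascontiguousarray(epochs.transpose(1, 0, 2)),
        epoch_length=epoch_length,
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
        band=band,
    )


def reject_high_amplitude(epoched: EpochedSignal, ptp_threshold: float) -> EpochedSignal:
    """Drop epochs whose peak-to-peak amplitude exceeds ``ptp_threshold`` on any channel.

    Automatic stand-in for manual artifact review; disabled by default in
    the pipeline (synthetic inputs are clean).
    """
    ptp = epoched.epochs.max(axis=2) - epoched.epochs.min(axis=2)
    keep = (ptp <= ptp_threshold).all(axis=1)
    return EpochedSignal(
        epochs=epoched.epochs[keep],
        epoch_length=epoched.epoch_length,
        sampling_rate=epoched.sampling_rate,
        channel_labels=epoched.channel_labels,
        band=epoched.band,
    )


def preprocess_recording(
    rec: EegRecording,
    target_rate: float = DEFAULT_SAMPLING_RATE,
    bands: dict[str, BandDefinition] | None = None,
) -> tuple[EegRecording, dict[str, EegRecording]]:
    """Full conditioning chain: re-reference -> resample -> broadband -> band split.

    Returns the broadband recording and one band-filtered recording per band.
    """
    from .recording import BANDS

    rec = rereference_average(rec)
    rec = resample(rec, target_rate)
    broad = filter_broadband(rec)
    out = {}
    for name, band in (bands or BANDS).items():
        out[name] = filter_band(broad, band)
    return broad, out
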