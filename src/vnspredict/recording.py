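"""Core data containers: EEG recordings, frequency bands, regions of interest.

The montage is the 19-electrode subset of the international 10-20 system
used by clinical scalp EEG. Band edges follow the standard clinical
convention with a half-open [f_lo, f_hi) reading at shared edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 named 10-20 electrodes the pipeline standardizes on.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "F7", "F8",
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < f_lo < f_hi, "
                f"got [{self.f_lo}, {self.f_hi})"
            )


#: Standard clinical bands.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "low_beta": BandDefinition("low_beta", 13.0, 20.0),
    "high_beta": BandDefinition("high_beta", 20.0, 29.0),
}


@dataclass(frozen=True)
class RoiDefinition:
    """A band-specific electrode region of interest."""

    band: BandDefinition
    channels: tuple[str, ...]

    def validate_against(self, channel_labels: list[str] | tuple[str, ...]) -> None:
        missing = [ch for ch in self.channels if ch not in channel_labels]
        if missing:
            raise ValueError(f"ROI channels missing from recording: {missing}")


#: Parieto-occipital ROI for alpha-band connectivity/efficiency analysis.
ALPHA_ROI = RoiDefinition(
    BANDS["alpha"], ("C3", "C4", "Cz", "T5", "T6", "P3", "P4", "Pz", "O1", "O2")
)
#: Central-frontal ROI for theta-band entropy analysis.
THETA_ROI = RoiDefinition(BANDS["theta"], ("Fz", "Cz", "C3", "C4"))


@dataclass
class EegRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    sampling_rate : float
        Samples per second, > 0.
    channel_labels : list of str
        Unique electrode names, ordered as the rows of ``data``.
    meta : dict
        Free-form provenance (subject id, group, generator spec, ...).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, **meta_updates) -> "EegRecording":
        """Copy of this recording with new samples and updated provenance."""
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            meta={**self.meta, **meta_updates},
        )

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]


@dataclass
class EpochedSignal:
    """Contiguous equal-length epochs of a (band-filtered) recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    epoch_length: float
    sampling_rate: float
    channel_labels: list[str]
    band: BandDefinition | None = None

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]
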