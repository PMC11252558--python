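"""Hilbert-Huang spectral entropy (HHSE).

Chain: empirical mode decomposition (EMD) of the broadband signal into
intrinsic mode functions (IMFs); analytic-signal amplitude a_i(t) and
instantaneous frequency w_i(t) per IMF; accumulation into a time-frequency
amplitude spectrum H(f, t); time integration into the marginal spectrum
h(f); band-local normalization over the band of interest F; and the Shannon
entropy of the normalized local marginal spectrum,

    HHSE_loc = - sum_{f in F} h_loc(f) ln h_loc(f),

with 0 ln 0 = 0 and natural logarithm. Low values indicate spectrally
concentrated ("regular") activity in the band; the maximum is ln K for K
frequency bins in F.

EMD is implemented here directly: sifting with cubic-spline envelopes of
the extrema, mirror extension at the boundaries, a Cauchy-type SD stopping
criterion, and termination when the residue is monotone or has fewer than
three extrema. The decomposition is complete by construction: the IMFs and
residue sum exactly to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .recording import BandDefinition, RoiDefinition

DEFAULT_BIN_WIDTH = 0.5
DEFAULT_FREQ_RANGE = (1.0, 30.0)
DEFAULT_SD_TOL = 0.2
DEFAULT_MAX_SIFTS = 10
#: Extrema mirrored at each boundary when building envelopes.
_N_MIRROR = 2
#: Tie-guard (Hz) so a frequency exactly on a bin edge lands in the upper bin.
_EDGE_EPS = 1e-9


@dataclass
class EmdDecomposition:
    imfs: list[np.ndarray]
    residue: np.ndarray
    config: dict = field(default_factory=dict)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class HilbertSpectrum:
    """Binned time-frequency amplitude H(f, t) plus per-IMF traces."""

    H: np.ndarray                 # (n_bins, n_times)
    bin_edges: np.ndarray         # (n_bins + 1,)
    amplitudes: list[np.ndarray]  # a_i(t) per IMF
    frequencies: list[np.ndarray] # w_i(t)/2pi per IMF, Hz
    n_dropped: int                # samples with non-positive or out-of-range freq


@dataclass
class MarginalSpectrum:
    h: np.ndarray            # amplitude per frequency bin
    bin_edges: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        total = self.h.sum()
        if total <= 0:
            raise ValueError("all-zero marginal spectrum: normalization undefined")
        return self.h / total

    def local(self, band: BandDefinition) -> np.ndarray:
        """Normalized local marginal spectrum over band [f_lo, f_hi)."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        mask = (centers >= band.f_lo) & (centers < band.f_hi)
        if mask.sum() < 2:
            raise ValueError(f"band {band.name!r} covered by fewer than 2 bins")
        local = self.h[mask]
        total = local.sum()
        if total <= 0:
            raise ValueError(
                f"no spectral mass in band {band.name!r}: normalization undefined"
            )
        return local / total


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the midpoint)."""
    dx = np.diff(x)
    # collapse flat segments so plateau extrema are detected once
    nonzero = np.flatnonzero(dx)
    if nonzero.size == 0:
        return np.array([], int), np.array([], int)
    sign = np.sign(dx)
    # forward-fill zero slopes with the previous nonzero slope
    filled = sign.copy()
    for i in range(1, len(filled)):
        if filled[i] == 0:
            filled[i] = filled[i - 1]
    turns = np.diff(filled)
    maxima = np.flatnonzero(turns < 0) + 1
    minima = np.flatnonzero(turns > 0) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended past both ends."""
    n = len(x)
    k = min(_N_MIRROR, len(idx))
    left_t = -idx[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([x[idx[:k][::-1]], x[idx], x[idx[-k:][::-1]]])
    # mirroring can duplicate t=0 / t=n-1 anchors; keep unique knots
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    if len(t) < 2:
        return np.full(n, v[0])
    if len(t) < 4:
        return np.interp(np.arange(n), t, v)
    return CubicSpline(t, v)(np.arange(n))


def _is_monotone(x: np.ndarray) -> bool:
    dx = np.diff(x)
    return bool((dx >= 0).all() or (dx <= 0).all())


def emd(
    x: np.ndarray,
    sd_tol: float = DEFAULT_SD_TOL,
    max_sifts: int = DEFAULT_MAX_SIFTS,
    max_imfs: int | None = None,
) -> EmdDecomposition:
    """Empirical mode decomposition by sifting.

    Each IMF is extracted by repeatedly subtracting the mean of the upper
    and lower cubic-spline envelopes until the normalized change between
    consecutive sifts falls below ``sd_tol`` or ``max_sifts`` is reached.
    Decomposition stops when the residue is monotone or has fewer than three
    extrema. A constant input yields zero IMFs and residue = input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a single-channel 1-D series")
    if x.size < 16:
        raise ValueError("series too short for decomposition (need >= 16 samples)")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in input")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    while max_imfs is None or len(imfs) < max_imfs:
        maxima, minima = _extrema(residue)
        if len(maxima) + len(minima) < 3 or _is_monotone(residue):
            break
        h = residue.copy()
        for _ in range(max_sifts):
            maxima, minima = _extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _envelope(h, maxima)
            lower = _envelope(h, minima)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h ** 2)) + 1e-300
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sd_tol:
                break
        imfs.append(h)
        residue = residue - h
    return EmdDecomposition(
        imfs=imfs,
        residue=residue,
        config={"sd_tol": sd_tol, "max_sifts": max_sifts, "max_imfs": max_imfs},
    )


def _instantaneous(imf: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic amplitude and instantaneous frequency (Hz), 5-point smoothed."""
    z = hilbert(imf)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * fs / (2 * np.pi)
    if len(freq) >= 5:
        kernel = np.ones(5) / 5
        freq = np.convolve(freq, kernel, mode="same")
    return amp, freq


def hilbert_spectrum(
    dec: EmdDecomposition,
    fs: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
) -> HilbertSpectrum:
    """Accumulate per-IMF analytic amplitude into (frequency-bin, time) cells.

    Samples with non-positive instantaneous frequency, or frequency outside
    ``freq_range`` or above Nyquist, are dropped and counted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    f_lo, f_hi = freq_range
    f_hi = min(f_hi, fs / 2)
    n_bins = int(round((f_hi - f_lo) / bin_width))
    edges = f_lo + bin_width * np.arange(n_bins + 1)
    n_times = dec.residue.size
    H = np.zeros((n_bins, n_times))
    amps, freqs = [], []
    dropped = 0
    for imf in dec.imfs:
        amp, freq = _instantaneous(imf, fs)
        amps.append(amp)
        freqs.append(freq)
        bins = np.floor((freq - f_lo) / bin_width + _EDGE_EPS).astype(int)
        valid = (freq > 0) & (bins >= 0) & (bins < n_bins)
        dropped += int((~valid).sum())
        t_idx = np.flatnonzero(valid)
        np.add.at(H, (bins[valid], t_idx), amp[valid])
    return HilbertSpectrum(
        H=H, bin_edges=edges, amplitudes=amps, frequencies=freqs, n_dropped=dropped
    )


def marginal_spectrum(spec: HilbertSpectrum) -> MarginalSpectrum:
    """Time integration of H(f, t) into the marginal amplitude spectrum h(f)."""
    h = spec.H.sum(axis=1)
    if h.sum() <= 0:
        raise ValueError("all-zero Hilbert spectrum: marginal normalization undefined")
    return MarginalSpectrum(h=h, bin_edges=spec.bin_edges)


def local_hhse(m: MarginalSpectrum, band: BandDefinition) -> float:
    """Shannon entropy of the normalized local marginal spectrum over ``band``."""
    p = m.local(band)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def channel_hhse(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    bin_width: float = DEFAULT_BIN_WIDTH,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    **emd_kwargs,
) -> float:
    """Band-local HHSE of one broadband channel (full EMD -> entropy chain)."""
    dec = emd(x, **emd_kwargs)
    spec = hilbert_spectrum(dec, fs, bin_width=bin_width, freq_range=freq_range)
    return local_hhse(marginal_spectrum(spec), band)


@dataclass
class HhseResult:
    """Per-channel band-local HHSE with ROI and global summaries."""

    values: dict[str, float]      # channel -> HHSE
    band: BandDefinition
    roi_mean: float
    global_mean: float
    roi: RoiDefinition | None = None


def summarize_hhse(
    values: dict[str, float], roi: RoiDefinition, band: BandDefinition | None = None
) -> HhseResult:
    """ROI mean and global mean of per-channel HHSE values."""
    missing = [ch for ch in roi.channels if ch not in values]
    if missing:
        raise ValueError(f"ROI channel(s) missing from HHSE values: {missing}")
    roi_mean = float(np.mean([values[ch] for ch in roi.channels]))
    global_mean = float(np.mean(list(values.values())))
    return HhseResult(
        values=dict(values),
        band=band or roi.band,
        roi_mean=roi_mean,
        global_mean=global_mean,
        roi=roi,
    )
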