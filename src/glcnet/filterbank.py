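"""Filter-bank decomposition of epochs into non-overlapping narrow bands.

Each epoch is passed through a bank of Chebyshev Type II band-pass filters
(default: nine 4 Hz bands covering 4-40 Hz), producing the multi-view
``trials x bands x channels x times`` tensor that the decoder consumes.
Filters are applied forward-backward by default so band signals stay
time-aligned across bands; a single-pass causal mode is available.

The implementation assumes broadband input containing energy up to at
least the highest band edge; any upstream broadband pre-filtering must
keep that content.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .core_data import ConfigurationError, EpochSet, ValidationError

__all__ = ["FilterBankSpec", "BandTensor", "make_default_bank", "apply_filterbank",
           "band_sos", "frequency_response"]

#: half of the default transition bandwidth, in Hz, added on each side of a
#: pass band to place the Chebyshev II stop-band edges
DEFAULT_TRANSITION_HZ = 2.0


@dataclasses.dataclass
class FilterBankSpec:
    """Bank of band-pass filters.

    Parameters
    ----------
    bands : list of (low_hz, high_hz)
        Pass-band edges; sorted, non-overlapping half-open intervals.
    design : str
        Only ``"cheby2"`` is supported.
    order : int
        Design order passed to the Chebyshev II design (the effective
        band-pass order is twice this).
    stopband_attenuation_db : float
        Minimum attenuation outside the pass band plus transition.
    zero_phase : bool
        Forward-backward application (no phase shift) when True.
    transition_hz : float
        Distance from each pass-band edge to the stop-band edge.
    """

    bands: list[tuple[float, float]]
    design: str = "cheby2"
    order: int = 4
    stopband_attenuation_db: float = 30.0
    zero_phase: bool = True
    transition_hz: float = DEFAULT_TRANSITION_HZ

    def __post_init__(self) -> None:
        if self.design != "cheby2":
            raise ConfigurationError(f"unsupported filter design {self.design!r}")
        self.bands = [(float(lo), float(hi)) for lo, hi in self.bands]
        prev_hi = 0.0
        for lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ConfigurationError(f"invalid band ({lo}, {hi})")
            if lo < prev_hi:
                raise ConfigurationError("bands must be sorted and non-overlapping")
            prev_hi = hi

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclasses.dataclass
class BandTensor:
    """Per-trial band decomposition: ``trials x bands x channels x times``."""

    data: np.ndarray
    band_edges: list[tuple[float, float]]
    sfreq: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"BandTensor data must be 4-D, got {self.data.shape}")
        if self.data.shape[1] != len(self.band_edges):
            raise ValidationError(
                f"{self.data.shape[1]} band slabs vs {len(self.band_edges)} band edges"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("non-finite values in band tensor")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]


def make_default_bank() -> FilterBankSpec:
    """Nine 4 Hz-wide bands: (4,8), (8,12), ..., (36,40) Hz."""
    bands = [(float(lo), float(lo + 4)) for lo in range(4, 40, 4)]
    return FilterBankSpec(bands=bands)


def band_sos(spec: FilterBankSpec, band: tuple[float, float], sfreq: float) -> np.ndarray:
    """Design the second-order-section filter for one band.

    Chebyshev II is specified by its stop-band edges; these sit
    ``transition_hz`` outside the pass band (the low stop edge is clipped
    away from 0, the high one away from Nyquist).
    """
    lo, hi = band
    nyq = sfreq / 2.0
    if hi >= nyq:
        raise ConfigurationError(
            f"band ({lo}, {hi}) exceeds Nyquist frequency {nyq} Hz"
        )
    stop_lo = max(lo - spec.transition_hz, 0.1 * lo)
    stop_hi = min(hi + spec.transition_hz, nyq * 0.99)
    return signal.cheby2(
        spec.order,
        spec.stopband_attenuation_db,
        [stop_lo / nyq, stop_hi / nyq],
        btype="bandpass",
        output="sos",
    )


def frequency_response(
    spec: FilterBankSpec, sfreq: float, n_freqs: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude response of every band on a frequency grid.

    Returns ``(freqs_hz, mags)`` where ``mags`` has shape
    ``(n_bands, n_freqs)``. With ``zero_phase`` the single-pass magnitude is
    squared, which is what forward-backward filtering realises.
    """
    freqs = np.linspace(0, sfreq / 2, n_freqs)
    mags = np.empty((spec.n_bands, n_freqs))
    for i, band in enumerate(spec.bands):
        sos = band_sos(spec, band, sfreq)
        _, h = signal.sosfreqz(sos, worN=freqs, fs=sfreq)
        mag = np.abs(h)
        mags[i] = mag**2 if spec.zero_phase else mag
    return freqs, mags


def apply_filterbank(epochs: EpochSet, spec: FilterBankSpec) -> BandTensor:
    """Decompose every epoch into the bank's frequency bands.

    The operation is linear and preserves the time length. Edge transients
    are suppressed by the reflect padding built into the forward-backward
    pass (or explicit reflect padding in causal mode).
    """
    sfreq = epochs.sfreq
    max_edge = max(hi for _, hi in spec.bands)
    if sfreq / 2 <= max_edge:
        raise ConfigurationError(
            f"sampling rate {sfreq} Hz cannot represent a band up to {max_edge} Hz"
        )
    n_times = epochs.n_times
    # sosfiltfilt needs > 3 * (number of second-order sections * 2) samples;
    # require a margin of 3x the effective order
    min_len = 6 * spec.order + 1
    if n_times < min_len:
        raise ValidationError(
            f"epochs of {n_times} samples are too short for order-{spec.order} "
            f"filtering (need >= {min_len})"
        )
    x = epochs.data  # (n, c, t)
    out = np.empty((x.shape[0], spec.n_bands, x.shape[1], x.shape[2]), dtype=np.float64)
    for i, band in enumerate(spec.bands):
        sos = band_sos(spec, band, sfreq)
        if spec.zero_phase:
            out[:, i] = signal.sosfiltfilt(sos, x, axis=-1, padtype="even")
        else:
            pad = min(3 * 2 * spec.order, n_times - 1)
            xp = np.concatenate([x[..., pad - 1 :: -1], x], axis=-1)
            y = signal.sosfilt(sos, xp, axis=-1)
            out[:, i] = y[..., pad:]
    return BandTensor(data=out, band_edges=list(spec.bands), sfreq=sfreq)


def filter_band(
    data: np.ndarray, band: tuple[float, float], sfreq: float,
    spec: FilterBankSpec | None = None,
) -> np.ndarray:
    """Band-pass an arbitrary array along its last axis (zero phase)."""
    spec = spec or make_default_bank()
    sos = band_sos(spec, band, sfreq)
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=np.float64), axis=-1,
                              padtype="even")
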