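"""Synthetic MEG-like epoch generator with controllable class structure.

Each trial is 1/f-shaped background noise on every channel plus white
sensor noise; trials of class k additionally carry a narrow-band
oscillation (band-limited noise by default, a pure tone on request) on
that class's channel subset, scaled by ``modulation_depth`` relative to
the unit-variance background.  This emulates the band-limited, spatially
specific power modulations (ERD/ERS-like signatures) that imagery
decoders exploit.  Within a class's channel subset, channels after the
first receive a phase-lagged copy of the first channel's oscillation
(constant lag ``coupling_lag_deg``), giving phase-lag-index estimation a
known ground truth.

What this generator does NOT emulate: realistic sensor geometry or
forward fields, inter-trial nonstationarity, artifacts, or correlated
background between channels.  Passing tests on this data demonstrates
that the pipeline recovers planted band-power/connectivity structure,
not performance on recorded MEG.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .core_data import ConfigurationError, EpochSet
from .filterbank import FilterBankSpec, apply_filterbank, filter_band, make_default_bank

__all__ = ["SynthConfig", "generate_epochs", "make_fixture_suite",
           "band_power_features"]


def _default_bands() -> list[tuple[float, float]]:
    return [(10.0, 12.0), (20.0, 22.0), (14.0, 16.0), (26.0, 28.0)]


@dataclasses.dataclass
class SynthConfig:
    """Generator settings.

    Defaults give the desk-scale geometry used throughout the tests:
    32 channels at 250 Hz, 2 s epochs (T = 500), 4 classes with disjoint
    8-channel subsets and well-separated rhythm bands, modulation depth 3
    (oscillation standard deviation = 3x the unit background), 1/f
    background and moderate white sensor noise.
    """

    n_trials_per_class: int = 100
    n_classes: int = 4
    n_channels: int = 32
    sfreq: float = 250.0
    duration_s: float = 2.0
    class_bands: list[tuple[float, float]] = dataclasses.field(default_factory=_default_bands)
    class_channels: list[list[int]] | None = None
    modulation_depth: float = 3.0
    background_exponent: float = 1.0
    noise_sigma: float = 0.5
    coupling_lag_deg: float = 90.0
    tone_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if len(self.class_bands) < self.n_classes:
            raise ConfigurationError(
                f"{self.n_classes} classes but only {len(self.class_bands)} class bands")
        nyq = self.sfreq / 2
        for lo, hi in self.class_bands[: self.n_classes]:
            if not 0 < lo < hi < nyq:
                raise ConfigurationError(
                    f"class band ({lo}, {hi}) outside (0, {nyq}) Hz")
        if self.class_channels is None:
            per = max(1, self.n_channels // (2 * self.n_classes))
            self.class_channels = [
                list(range(k * per, (k + 1) * per)) for k in range(self.n_classes)
            ]
        for k, chans in enumerate(self.class_channels[: self.n_classes]):
            if not chans:
                raise ConfigurationError(f"class {k} has an empty channel subset")
            if max(chans) >= self.n_channels:
                raise ConfigurationError(
                    f"class {k} channel index {max(chans)} out of range")

    @property
    def n_times(self) -> int:
        return int(round(self.duration_s * self.sfreq))


def _one_over_f(rng: np.random.Generator, n_ch: int, n_t: int,
                exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise per channel (spectral shaping)."""
    freqs = np.fft.rfftfreq(n_t, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * amp
    x = np.fft.irfft(spec, n=n_t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _phase_shift(x: np.ndarray, lag_deg: float) -> np.ndarray:
    """Delay a narrow-band signal's phase by ``lag_deg`` degrees."""
    analytic = hilbert(x)
    return np.real(analytic * np.exp(-1j * np.deg2rad(lag_deg)))


def _oscillation(rng: np.random.Generator, band: tuple[float, float],
                 sfreq: float, n_t: int, tone: bool) -> np.ndarray:
    if tone:
        f0 = (band[0] + band[1]) / 2.0
        t = np.arange(n_t) / sfreq
        x = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        return x
    # band-limited noise: white noise pushed through the band-pass design
    w = rng.standard_normal(n_t * 2)  # extra length, crop filter transients
    y = filter_band(w, band, sfreq)
    y = y[n_t // 2 : n_t // 2 + n_t]
    sd = y.std()
    return y / (sd if sd > 0 else 1.0)


def generate_epochs(config: SynthConfig) -> EpochSet:
    """Draw a balanced, label-shuffled epoch set; deterministic by seed."""
    rng = np.random.default_rng(config.seed)
    n_t = config.n_times
    n_total = config.n_trials_per_class * config.n_classes
    labels = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)
    labels = labels[rng.permutation(n_total)]
    data = np.empty((n_total, config.n_channels, n_t))
    for i, cls in enumerate(labels):
        x = _one_over_f(rng, config.n_channels, n_t, config.background_exponent)
        x = x + config.noise_sigma * rng.standard_normal((config.n_channels, n_t))
        if config.modulation_depth > 0:
            band = config.class_bands[cls]
            chans = config.class_channels[cls]
            osc = _oscillation(rng, band, config.sfreq, n_t, config.tone_mode)
            x[chans[0]] += config.modulation_depth * osc
            for ch in chans[1:]:
                x[ch] += config.modulation_depth * _phase_shift(
                    osc, config.coupling_lag_deg)
        data[i] = x
    return EpochSet(
        data=data,
        labels=labels,
        sfreq=config.sfreq,
        channel_names=[f"SYN{i:03d}" for i in range(config.n_channels)],
    )


def band_power_features(epochs: EpochSet,
                        bank: FilterBankSpec | None = None) -> np.ndarray:
    """Log band-power per (band, channel): the linear-baseline feature set."""
    bank = bank or make_default_bank()
    bt = apply_filterbank(epochs, bank)
    power = bt.data.var(axis=-1)  # (n, bands, channels)
    return np.log(power + 1e-20).reshape(epochs.n_trials, -1)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

FIXTURE_VERSION = "1"


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the versioned HDF5 fixtures used across the test suite.

    tiny              8 trials, 4 channels, quick I/O checks
    separable-2class  2 x 60 trials, high SNR
    separable-4class  4 x 100 trials, C=32, T=500 (the end-to-end fixture)
    null              depth 0, no class signal
    """
    from .core_data import save_epochs

    out_dir = Path(out_dir) / f"v{FIXTURE_VERSION}"
    out_dir.mkdir(parents=True, exist_ok=True)
    configs = {
        "tiny": SynthConfig(n_trials_per_class=4, n_classes=2, n_channels=4,
                            duration_s=0.6, class_channels=[[0, 1], [2, 3]],
                            seed=101),
        "separable-2class": SynthConfig(n_trials_per_class=60, n_classes=2,
                                        seed=202),
        "separable-4class": SynthConfig(seed=303),
        "null": SynthConfig(modulation_depth=0.0, n_trials_per_class=50,
                            seed=404),
    }
    paths: dict[str, Path] = {}
    manifest = {"version": FIXTURE_VERSION, "fixtures": {}}
    for name, cfg in configs.items():
        path = out_dir / f"{name}.h5"
        save_epochs(generate_epochs(cfg), path)
        paths[name] = path
        d = dataclasses.asdict(cfg)
        manifest["fixtures"][name] = d
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths
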