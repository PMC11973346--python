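"""Data model and file I/O for epoched multichannel neuromagnetic signals.

The universal container is :class:`EpochSet`: a ``trials x channels x times``
array with integer class labels, a sampling frequency and channel metadata.
Epochs are assumed pre-cut (no event timing is stored); the HDF5 layout
defined here is the canonical interchange format, FIF epoch files can be
read through :mod:`mne` and are converted immediately.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "EpochSet",
    "SplitSpec",
    "ConfusionMatrix",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "load_epochs",
    "save_epochs",
    "split_epochs",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """In-memory data violates an invariant of its type."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent or inapplicable."""


@dataclasses.dataclass
class EpochSet:
    """Epoched multichannel time series with per-trial class labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Signal amplitudes (Tesla/m for gradiometers, or arbitrary units).
    labels : ndarray of int, shape (n_trials,)
        Class labels, 0-based contiguous. External label sets are remapped
        on load; the original values are kept in ``label_mapping``.
    sfreq : float
        Sampling frequency in Hz.
    channel_names : list of str
    positions : ndarray, shape (n_channels, 3), optional
        Sensor coordinates in meters.
    label_mapping : dict, optional
        Maps internal 0-based label -> original external label.
    """

    data: np.ndarray
    labels: np.ndarray
    sfreq: float
    channel_names: list[str] = dataclasses.field(default_factory=list)
    positions: np.ndarray | None = None
    label_mapping: dict[int, object] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.channel_names:
            self.channel_names = [f"CH{i:03d}" for i in range(self.data.shape[1])]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (trials, channels, times); got shape {self.data.shape}"
            )
        n_trials, n_channels, n_times = self.data.shape
        if n_trials < 1 or n_channels < 2 or n_times < 2:
            raise ValidationError(
                f"need n_trials>=1, n_channels>=2, n_times>=2; got {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            t, c, s = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"non-finite sample at trial {t}, channel {c}, sample {s}"
            )
        if self.labels.shape != (n_trials,):
            raise ValidationError(
                f"labels length {self.labels.shape[0] if self.labels.ndim == 1 else self.labels.shape}"
                f" does not match n_trials {n_trials}"
            )
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative 0-based integers")
        if len(self.channel_names) != n_channels:
            raise ValidationError(
                f"channel_names length {len(self.channel_names)} != n_channels {n_channels}"
            )
        if not float(self.sfreq) > 0:
            raise ValidationError(f"sfreq must be positive, got {self.sfreq}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.float64)
            if self.positions.shape != (n_channels, 3):
                raise ValidationError(
                    f"positions shape {self.positions.shape} != ({n_channels}, 3)"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to the given trial indices."""
        idx = np.asarray(idx, dtype=np.int64)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
            positions=None if self.positions is None else self.positions.copy(),
            label_mapping=self.label_mapping,
        )

    @staticmethod
    def concatenate(parts: Sequence["EpochSet"]) -> "EpochSet":
        first = parts[0]
        return EpochSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts], axis=0),
            sfreq=first.sfreq,
            channel_names=list(first.channel_names),
            positions=None if first.positions is None else first.positions.copy(),
            label_mapping=first.label_mapping,
        )


@dataclasses.dataclass
class SplitSpec:
    """Train/validation/test partition specification."""

    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if not all(0 < f < 1 for f in fracs):
            raise ConfigurationError(f"all fractions must lie in (0, 1); got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1; got {sum(fracs)!r}")


@dataclasses.dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path, class_names: Sequence[str] | None = None) -> Path:
        import pandas as pd

        names = list(class_names) if class_names else [str(i) for i in range(self.n_classes)]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df.index.name = "true\\pred"
        path = Path(path)
        df.to_csv(path)
        return path


# ---------------------------------------------------------------------------
# HDF5 interchange
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to the canonical HDF5 layout.

    Layout: ``/data`` float32 ``[n_trials, n_channels, n_times]``,
    ``/labels`` int64, ``/sfreq`` scalar, ``/channel_names`` UTF-8 strings,
    ``/positions`` optional float32 ``[n_channels, 3]``.
    """
    epochs.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int64))
        f.create_dataset("sfreq", data=float(epochs.sfreq))
        dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("channel_names", data=np.array(epochs.channel_names, dtype=dt))
        if epochs.positions is not None:
            f.create_dataset("positions", data=epochs.positions.astype(np.float32))
        if epochs.label_mapping is not None:
            f.attrs["label_mapping"] = json.dumps(
                {str(k): v for k, v in epochs.label_mapping.items()}
            )
    return path


def _remap_labels(raw: np.ndarray) -> tuple[np.ndarray, dict[int, object] | None]:
    """Map arbitrary integer labels to 0-based contiguous ones."""
    uniq = np.unique(raw)
    if uniq.size and uniq[0] == 0 and uniq[-1] == uniq.size - 1:
        return raw.astype(np.int64), None
    lut = {orig: i for i, orig in enumerate(uniq.tolist())}
    mapped = np.array([lut[v] for v in raw.tolist()], dtype=np.int64)
    return mapped, {i: orig for orig, i in lut.items()}


def load_epochs(path: str | Path, format: str = "hdf5") -> EpochSet:
    """Read epochs from disk.

    Parameters
    ----------
    path : path to an HDF5 container (canonical layout) or a FIF epoch file.
    format : {"hdf5", "fif"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "fif":
        return _load_fif(path)
    raise ConfigurationError(f"unknown format {format!r}; expected 'hdf5' or 'fif'")


def _load_hdf5(path: Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "sfreq"):
            if key not in f:
                raise FormatError(f"missing dataset '/{key}' in {path}")
        data = np.asarray(f["data"], dtype=np.float64)
        raw_labels = np.asarray(f["labels"])
        sfreq = float(np.asarray(f["sfreq"]))
        if data.ndim != 3:
            raise FormatError(f"'/data' must be 3-D, got shape {data.shape}")
        if raw_labels.shape != (data.shape[0],):
            raise FormatError(
                f"'/labels' has length {raw_labels.shape}, expected ({data.shape[0]},)"
            )
        if "channel_names" in f:
            names = [
                n.decode("utf-8") if isinstance(n, bytes) else str(n)
                for n in f["channel_names"][()]
            ]
        else:
            names = []
        positions = np.asarray(f["positions"], dtype=np.float64) if "positions" in f else None
        mapping_attr = f.attrs.get("label_mapping")
    labels, mapping = _remap_labels(raw_labels)
    if mapping is None and mapping_attr is not None:
        mapping = {int(k): v for k, v in json.loads(mapping_attr).items()}
    return EpochSet(
        data=data,
        labels=labels,
        sfreq=sfreq,
        channel_names=names,
        positions=positions,
        label_mapping=mapping,
    )


def _load_fif(path: Path) -> EpochSet:
    import mne

    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    data = ep.get_data(copy=True)
    raw_labels = ep.events[:, 2]
    labels, mapping = _remap_labels(np.asarray(raw_labels))
    pos = None
    try:
        locs = np.array([ch["loc"][:3] for ch in ep.info["chs"]])
        if np.isfinite(locs).all() and not np.allclose(locs, 0):
            pos = locs
    except Exception:
        pos = None
    return EpochSet(
        data=data,
        labels=labels,
        sfreq=float(ep.info["sfreq"]),
        channel_names=list(ep.ch_names),
        positions=pos,
        label_mapping=mapping,
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_epochs(
    epochs: EpochSet, spec: SplitSpec
) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Partition trials into train/validation/test sets.

    The partition is disjoint and covers every trial. With
    ``spec.stratified`` the per-class proportions match the requested
    fractions within one trial. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = epochs.n_trials
    idx_sets: list[list[int]] = [[], [], []]
    if spec.stratified:
        for cls in np.unique(epochs.labels):
            cls_idx = np.flatnonzero(epochs.labels == cls)
            if cls_idx.size < 3:
                raise ConfigurationError(
                    f"class {cls} has only {cls_idx.size} trials; "
                    "stratified splitting needs at least 3 per class"
                )
            perm = rng.permutation(cls_idx)
            n_tr = int(round(spec.train_fraction * cls_idx.size))
            n_val = int(round(spec.val_fraction * cls_idx.size))
            n_tr = min(max(n_tr, 1), cls_idx.size - 2)
            n_val = min(max(n_val, 1), cls_idx.size - n_tr - 1)
            idx_sets[0].extend(perm[:n_tr].tolist())
            idx_sets[1].extend(perm[n_tr : n_tr + n_val].tolist())
            idx_sets[2].extend(perm[n_tr + n_val :].tolist())
    else:
        perm = rng.permutation(n)
        n_tr = int(round(spec.train_fraction * n))
        n_val = int(round(spec.val_fraction * n))
        idx_sets[0] = perm[:n_tr].tolist()
        idx_sets[1] = perm[n_tr : n_tr + n_val].tolist()
        idx_sets[2] = perm[n_tr + n_val :].tolist()
    parts = tuple(epochs.subset(sorted(s)) for s in idx_sets)
    return parts  # type: ignore[return-value]
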