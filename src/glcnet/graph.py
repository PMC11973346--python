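"""Sensor-graph construction and graph convolution.

The sensor array is modelled as a weighted graph: one node per channel,
edge weights either from functional connectivity (phase lag index, PLI)
or from sensor geometry (one minus the min-max normalized inter-sensor
distance).  The adjacency A is augmented with self loops and symmetrically
degree-normalized into the propagation operator

    S = D̃^{-1/2} (A + I) D̃^{-1/2},     D̃_ii = sum_j (A + I)_ij,

whose spectrum lies in [-1, 1]; a graph-convolution layer then computes
``activation(S · H · W + b)`` for node features H.

PLI between channels j and k is the absolute time-and-trial average of the
sign of their instantaneous phase difference, estimated from the analytic
signal of each band-limited channel.  It is insensitive to zero-lag
(volume-conduction) coupling: identical channels score 0, a constant
non-zero lag scores 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import hilbert

from .core_data import ConfigurationError, EpochSet, ValidationError
from .filterbank import FilterBankSpec, filter_band, make_default_bank

__all__ = [
    "AdjacencySpec",
    "PropagationMatrix",
    "GCNLayerParams",
    "compute_pli_adjacency",
    "compute_distance_adjacency",
    "normalize_adjacency",
    "gcn_layer_forward",
]

#: fraction of samples dropped at each end before averaging phase-difference
#: signs, to limit analytic-signal edge effects
PLI_EDGE_FRACTION = 0.05


@dataclasses.dataclass
class AdjacencySpec:
    """Symmetric non-negative sensor adjacency with zero diagonal."""

    mode: str  # {"pli", "distance", "custom"}
    matrix: np.ndarray
    self_loops_added: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        a = self.matrix
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got {a.shape}")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValidationError("adjacency must be symmetric")
        if (a < -1e-12).any():
            raise ValidationError("adjacency entries must be non-negative")
        if not self.self_loops_added and np.abs(np.diag(a)).max() > 1e-12:
            raise ValidationError("adjacency diagonal must be zero before augmentation")
        if self.mode in ("pli", "distance") and a.max(initial=0.0) > 1 + 1e-9:
            raise ValidationError(f"{self.mode} adjacency values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class PropagationMatrix:
    """Degree-normalized, self-loop-augmented propagation operator."""

    matrix: np.ndarray
    normalization: str = "sym"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValidationError("propagation matrix must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class GCNLayerParams:
    """Weights of one graph-convolution layer."""

    weight: np.ndarray
    bias: np.ndarray
    activation: str = "relu"  # {"relu", "elu", "identity"}

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weight.ndim != 2:
            raise ValidationError("weight must be 2-D (in_features x out_features)")
        if self.bias.shape != (self.weight.shape[1],):
            raise ValidationError("bias length must equal out_features")
        if not (np.isfinite(self.weight).all() and np.isfinite(self.bias).all()):
            raise ValidationError("non-finite layer parameters")


def _apply_activation(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "elu":
        return np.where(x > 0, x, np.expm1(x))
    if kind == "identity":
        return x
    raise ConfigurationError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# Adjacency estimation
# ---------------------------------------------------------------------------

def compute_pli_adjacency(
    epochs: EpochSet,
    band_hz: tuple[float, float] | None = None,
    bank: FilterBankSpec | None = None,
) -> AdjacencySpec:
    """Phase-lag-index adjacency from epoched data.

    With ``band_hz`` given, channels are band-passed to that band first;
    with ``band_hz=None`` the PLI is averaged over every band of ``bank``
    (default: the nine-band 4-40 Hz bank), giving one shared adjacency.

    PLI_jk = | mean over trials and retained samples of
              sign(phi_j(t) - phi_k(t)) |.
    """
    if epochs.n_channels < 2:
        raise ValidationError("PLI needs at least 2 channels")
    if epochs.n_times < 64:
        raise ValidationError(
            f"epochs of {epochs.n_times} samples are too short for analytic-signal "
            "phase estimation (need >= 64)"
        )
    var = epochs.data.var(axis=(0, 2))
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValidationError(
            f"channel {dead[0]} ({epochs.channel_names[dead[0]]}) has zero variance"
        )
    if band_hz is not None:
        bands = [tuple(band_hz)]
    else:
        bands = list((bank or make_default_bank()).bands)

    n_ch = epochs.n_channels
    acc = np.zeros((n_ch, n_ch))
    edge = max(1, int(PLI_EDGE_FRACTION * epochs.n_times))
    for band in bands:
        xb = filter_band(epochs.data, band, epochs.sfreq)
        phase = np.angle(hilbert(xb, axis=-1))[..., edge:-edge]
        # accumulate sign of the wrapped pairwise phase difference trial by
        # trial (the full n_trials x C x C x T tensor would not fit memory)
        sign_sum = np.zeros((n_ch, n_ch))
        n_samples = 0
        for ph in phase:  # (C, Tkept)
            diff = ph[:, None, :] - ph[None, :, :]
            sign_sum += np.sign(np.sin(diff)).sum(axis=-1)
            n_samples += ph.shape[-1]
        acc += np.abs(sign_sum / n_samples)
    pli = acc / len(bands)
    np.fill_diagonal(pli, 0.0)
    pli = np.clip((pli + pli.T) / 2.0, 0.0, 1.0)
    return AdjacencySpec(mode="pli", matrix=pli)


def compute_distance_adjacency(positions: np.ndarray) -> AdjacencySpec:
    """Adjacency ``A_jk = 1 - d_jk`` from min-max normalized distances.

    ``d`` is the straight-line (chordal) inter-sensor distance, min-max
    normalized over off-diagonal pairs; when all pairwise distances are
    equal the degenerate normalization defines d = 0 (A = 1) off-diagonal.
    """
    if positions is None:
        raise ConfigurationError("sensor positions are required for distance adjacency")
    pos = np.asarray(positions, dtype=np.float64)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ConfigurationError(f"positions must be (n_channels >= 2, dim), got {pos.shape}")
    n = pos.shape[0]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ConfigurationError("duplicate sensor coordinates")
    dmin, dmax = d[off].min(), d[off].max()
    if dmax - dmin < 1e-15:
        dn = np.zeros_like(d)
    else:
        dn = (d - dmin) / (dmax - dmin)
    a = 1.0 - dn
    np.fill_diagonal(a, 0.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return AdjacencySpec(mode="distance", matrix=a)


# ---------------------------------------------------------------------------
# Normalization and graph convolution
# ---------------------------------------------------------------------------

def normalize_adjacency(adj: AdjacencySpec) -> PropagationMatrix:
    """Symmetric degree normalization of the self-loop-augmented adjacency."""
    a_tilde = adj.matrix + np.eye(adj.n_channels)
    deg = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    s = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return PropagationMatrix(matrix=s, normalization="sym")


def gcn_layer_forward(
    node_features: np.ndarray,
    prop: PropagationMatrix,
    params: GCNLayerParams,
) -> np.ndarray:
    """One graph-convolution layer: ``activation(S H W + b)``.

    ``node_features`` may be ``[n_channels, in_features]`` or carry leading
    batch/band axes ``[..., n_channels, in_features]``; the propagation
    matrix and weights broadcast over them.
    """
    h = np.asarray(node_features, dtype=np.float64)
    n_ch = prop.n_channels
    if h.shape[-2] != n_ch:
        raise ValidationError(
            f"expected {n_ch} channels on axis -2, got shape {h.shape}"
        )
    if h.shape[-1] != params.weight.shape[0]:
        raise ValidationError(
            f"feature dim {h.shape[-1]} does not match weight in_features "
            f"{params.weight.shape[0]}"
        )
    z = prop.matrix @ h @ params.weight + params.bias
    return _apply_activation(z, params.activation)


# ---------------------------------------------------------------------------
# Import/export helpers
# ---------------------------------------------------------------------------

def adjacency_to_csv(adj: AdjacencySpec, path, channel_names=None) -> None:
    import pandas as pd

    names = channel_names or [f"CH{i:03d}" for i in range(adj.n_channels)]
    pd.DataFrame(adj.matrix, index=names, columns=names).to_csv(path)


def adjacency_from_csv(path, mode: str = "custom") -> AdjacencySpec:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return AdjacencySpec(mode=mode, matrix=df.to_numpy(dtype=np.float64))
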