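"""GLCNet: multi-branch decoder for band-decomposed multichannel epochs.

The network fuses three feature extractors applied to the filter-bank
tensor ``(N, bands, C, T)``:

* a graph branch (F1): temporal convolution front-end (conv, batch-norm,
  max-pool, dropout), two graph-convolution layers over the sensor graph,
  and a channel-aggregating (C, 1) convolution to ``spatial_filters`` maps;
* a spatial branch (F3): grouped (C, 1) spatial convolution (one filter
  group per band), batch-norm, and non-overlapping temporal averaging;
* a recurrent branch (F2): a single-layer LSTM over the averaged spatial
  sequence, with a per-step linear readout back to ``spatial_filters`` dims.

F1, F2 and F3 are fused by elementwise summation and classified by a
fully connected layer with log-softmax output.  Any single branch can be
ablated; removing the spatial branch drops F3 from the fusion but keeps
the spatial convolution that feeds the LSTM.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

from . import nnops
from .core_data import ConfigurationError, ValidationError
from .filterbank import BandTensor
from .graph import AdjacencySpec, normalize_adjacency

__all__ = [
    "ModelConfig", "Model", "LSTMParams",
    "build_glcnet", "count_parameters", "lstm_forward", "ablate",
    "save_checkpoint", "load_checkpoint",
]

ABLATABLE = ("module1_gcn", "module2_spatialconv", "module3_lstm")


@dataclasses.dataclass
class ModelConfig:
    """Architecture description; defaults mirror the published layout.

    The defaults target 204 gradiometer channels sampled at 500 Hz for
    5 s epochs (T = 2500).  Desk-scale variants only need C, T and
    avg_window changed consistently (T divisible by pool_factor and
    avg_window).
    """

    n_channels: int = 204
    n_times: int = 2500
    n_bands: int = 9
    n_classes: int = 4
    temporal_conv_kernel: int = 10
    temporal_conv_filters: int = 9
    pool_factor: int = 10
    gcn_dims: tuple[int, int] = (64, 5)
    spatial_filters: int = 288
    spatial_groups: int = 9
    avg_window: int = 500
    lstm_hidden: int = 32
    dropout_p: float = 0.25
    adjacency: AdjacencySpec | None = None
    removed: str | None = None

    def __post_init__(self) -> None:
        if self.n_times % self.pool_factor:
            raise ConfigurationError(
                f"n_times {self.n_times} not divisible by pool_factor {self.pool_factor}")
        if self.n_times % self.avg_window:
            raise ConfigurationError(
                f"n_times {self.n_times} not divisible by avg_window {self.avg_window}")
        if self.spatial_filters % self.spatial_groups:
            raise ConfigurationError(
                f"spatial_filters {self.spatial_filters} not divisible by "
                f"spatial_groups {self.spatial_groups}")
        if not 0 <= self.dropout_p < 1:
            raise ConfigurationError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.removed is not None and self.removed not in ABLATABLE:
            raise ConfigurationError(
                f"unknown ablation {self.removed!r}; valid: {ABLATABLE}")
        for name in ("n_channels", "n_times", "n_bands", "n_classes",
                     "temporal_conv_kernel", "temporal_conv_filters", "pool_factor",
                     "spatial_filters", "spatial_groups", "avg_window", "lstm_hidden"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @property
    def n_steps(self) -> int:
        """Length of the averaged temporal sequence, T / avg_window."""
        return self.n_times // self.avg_window

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        adj = d.pop("adjacency")
        d["gcn_dims"] = list(self.gcn_dims)
        if adj is not None:
            d["adjacency_mode"] = self.adjacency.mode
        return d


@dataclasses.dataclass
class LSTMParams:
    """Explicit LSTM gate weights for the functional forward pass."""

    w_i: np.ndarray
    w_f: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    u_i: np.ndarray
    u_f: np.ndarray
    u_o: np.ndarray
    u_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        h = self.u_i.shape[0]
        d = self.w_i.shape[0]
        for g in "ifoc":
            if getattr(self, f"w_{g}").shape != (d, h):
                raise ValidationError(f"w_{g} must have shape ({d}, {h})")
            if getattr(self, f"u_{g}").shape != (h, h):
                raise ValidationError(f"u_{g} must have shape ({h}, {h})")
            if getattr(self, f"b_{g}").shape != (h,):
                raise ValidationError(f"b_{g} must have shape ({h},)")

    @property
    def hidden_size(self) -> int:
        return self.u_i.shape[0]


def lstm_forward(params: LSTMParams, sequence: np.ndarray) -> np.ndarray:
    """Run the gate recursion over a ``(steps, features)`` sequence.

    Zero initial hidden and cell state; returns the stacked hidden states
    ``(steps, hidden)``.  Every hidden entry lies in (-1, 1).
    """
    seq = np.asarray(sequence, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[1] != params.w_i.shape[0]:
        raise ValidationError(
            f"sequence must be (steps, {params.w_i.shape[0]}), got {seq.shape}")

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    h = np.zeros(params.hidden_size)
    c = np.zeros(params.hidden_size)
    out = np.empty((seq.shape[0], params.hidden_size))
    for t, x in enumerate(seq):
        i = sig(x @ params.w_i + h @ params.u_i + params.b_i)
        f = sig(x @ params.w_f + h @ params.u_f + params.b_f)
        o = sig(x @ params.w_o + h @ params.u_o + params.b_o)
        c_tilde = np.tanh(x @ params.w_c + h @ params.u_c + params.b_c)
        c = f * c + i * c_tilde
        h = o * np.tanh(c)
        out[t] = h
    return out


# ---------------------------------------------------------------------------
# Branch wrappers
# ---------------------------------------------------------------------------

class _LSTMBranch(nnops.Layer):
    """(N, F, steps) -> LSTM over steps -> per-step linear -> (N, F, steps)."""

    def __init__(self, n_features: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.lstm = nnops.LSTM(n_features, hidden, rng)
        self.readout = nnops.Linear(hidden, n_features, rng)
        self.params = self.lstm.params + self.readout.params

    def forward(self, x, training=False):
        seq = np.transpose(x, (0, 2, 1))  # (N, steps, F)
        h = self.lstm.forward(seq, training)
        y = self.readout.forward(h, training)
        return np.transpose(y, (0, 2, 1))

    def backward(self, dy):
        dh = self.readout.backward(np.transpose(dy, (0, 2, 1)))
        dseq = self.lstm.backward(dh)
        return np.transpose(dseq, (0, 2, 1))


class _Classifier(nnops.Layer):
    """Flatten (N, F, steps) -> linear -> log-softmax."""

    def __init__(self, in_features: int, n_classes: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.linear = nnops.Linear(in_features, n_classes, rng)
        self.logsoftmax = nnops.LogSoftmax()
        self.params = self.linear.params

    def forward(self, x, training=False):
        self._shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        return self.logsoftmax.forward(self.linear.forward(flat, training), training)

    def backward(self, dy):
        dflat = self.linear.backward(self.logsoftmax.backward(dy))
        return dflat.reshape(self._shape)


class Model:
    """Instantiated GLCNet with named sub-modules and a parameter registry.

    Sub-modules: ``frontend``, ``gcn_branch``, ``spatial_branch``,
    ``lstm_branch``, ``classifier``; ablated branches are simply absent.
    ``forward`` consumes a band tensor and returns log-probability rows;
    ``backward`` expects the gradient of the loss w.r.t. those rows.
    """

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        if config.adjacency is None:
            raise ConfigurationError("ModelConfig.adjacency is required to build the model")
        if config.adjacency.n_channels != config.n_channels:
            raise ConfigurationError(
                f"adjacency is {config.adjacency.n_channels} channels, "
                f"config expects {config.n_channels}")
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        c = config
        prop = normalize_adjacency(c.adjacency).matrix
        steps = c.n_steps
        per_group = c.spatial_filters // c.spatial_groups
        self.submodules: dict[str, nnops.Layer] = {}

        use_f1 = c.removed != "module1_gcn"
        use_f3 = True  # spatial conv always built (feeds the LSTM)
        use_f2 = c.removed != "module3_lstm"
        self.fuse_f1 = use_f1
        self.fuse_f2 = use_f2
        self.fuse_f3 = c.removed != "module2_spatialconv"

        if use_f1:
            front_conv = nnops.TemporalConv(c.n_bands, c.temporal_conv_filters,
                                            c.temporal_conv_kernel, rng)
            front_conv.skip_input_grad = True  # sits on the network input
            self.submodules["frontend"] = nnops.Sequential(
                front_conv,
                nnops.ReLU(),
                nnops.BatchNorm(c.temporal_conv_filters),
                nnops.ELU(),
                nnops.MaxPoolTime(c.pool_factor),
                nnops.Dropout(c.dropout_p, self.dropout_rng),
            )
            self.submodules["gcn_branch"] = nnops.Sequential(
                nnops.GraphConv(prop, c.n_times // c.pool_factor, c.gcn_dims[0], rng),
                nnops.GraphConv(prop, c.gcn_dims[0], c.gcn_dims[1], rng),
                nnops.ChannelConv(c.temporal_conv_filters, c.n_channels,
                                  c.spatial_filters, rng),
                nnops.ReLU(),
                nnops.BatchNorm(c.spatial_filters),
                nnops.ELU(),
                nnops.Dropout(c.dropout_p, self.dropout_rng),
            )
        if use_f3:
            spat_conv = nnops.GroupedChannelConv(c.spatial_groups, c.n_channels,
                                                 per_group, rng)
            spat_conv.skip_input_grad = True  # sits on the network input
            self.submodules["spatial_branch"] = nnops.Sequential(
                spat_conv,
                nnops.ReLU(),
                nnops.BatchNorm(c.spatial_filters),
                nnops.Dropout(c.dropout_p, self.dropout_rng),
                nnops.AvgPoolTime(c.avg_window),
            )
        if use_f2:
            self.submodules["lstm_branch"] = _LSTMBranch(c.spatial_filters,
                                                         c.lstm_hidden, rng)
        self.submodules["classifier"] = _Classifier(
            c.spatial_filters * steps, c.n_classes, rng)

        # fixed linear interpolation matrix mapping the F1 feature axis
        # (gcn_dims[1]) onto the fused temporal axis (steps)
        self._interp = None
        if self.fuse_f1 and c.gcn_dims[1] != steps:
            self._interp = _interp_matrix(c.gcn_dims[1], steps)

    # -- registry --------------------------------------------------------
    def parameters(self, submodule: str = "all") -> list[nnops.Parameter]:
        if submodule == "all":
            return [p for m in self.submodules.values() for p in m.params]
        if submodule not in self.submodules:
            raise KeyError(
                f"unknown sub-module {submodule!r}; valid names: "
                f"{sorted(self.submodules)} or 'all'")
        return list(self.submodules[submodule].params)

    def parameter_registry(self) -> dict[str, int]:
        return {name: sum(p.size for p in m.params)
                for name, m in self.submodules.items()}

    # -- forward / backward ---------------------------------------------
    def forward(self, bands: BandTensor | np.ndarray, mode: str = "eval") -> np.ndarray:
        """Log-probability rows ``(n_trials, n_classes)``.

        ``mode="eval"`` is deterministic (dropout off, batch-norm running
        stats); ``mode="train"`` updates batch statistics and samples
        dropout from the model's seeded generator.
        """
        x = bands.data if isinstance(bands, BandTensor) else np.asarray(bands)
        c = self.config
        if x.ndim != 4 or x.shape[1:] != (c.n_bands, c.n_channels, c.n_times):
            raise ValidationError(
                f"expected band tensor (N, {c.n_bands}, {c.n_channels}, "
                f"{c.n_times}), got {x.shape}")
        training = mode == "train"
        n = x.shape[0]
        steps = c.n_steps
        fused = np.zeros((n, c.spatial_filters, steps))
        self._cache = {}
        if self.fuse_f1:
            front = self.submodules["frontend"].forward(x, training)
            f1 = self.submodules["gcn_branch"].forward(front, training)
            if self._interp is not None:
                f1 = f1 @ self._interp
            self._check_finite(f1, "gcn_branch")
            fused += f1
        f3 = None
        if "spatial_branch" in self.submodules:
            f3 = self.submodules["spatial_branch"].forward(x, training)
            self._check_finite(f3, "spatial_branch")
        if self.fuse_f3:
            fused += f3
        if self.fuse_f2:
            f2 = self.submodules["lstm_branch"].forward(f3, training)
            self._check_finite(f2, "lstm_branch")
            fused += f2
        logp = self.submodules["classifier"].forward(fused, training)
        self._check_finite(logp, "classifier")
        self._cache["f3_used"] = f3 is not None
        return logp

    def branch_features(self, bands: BandTensor | np.ndarray) -> dict[str, np.ndarray]:
        """Eval-mode activations of the fusion inputs and their sum.

        Returns arrays of shape ``(n_trials, spatial_filters, n_steps)``
        under keys ``f1``, ``f2``, ``f3`` (absent branches omitted) and
        ``fused``; this is the feature set an external embedding (e.g.
        t-SNE) would consume after flattening.
        """
        x = bands.data if isinstance(bands, BandTensor) else np.asarray(bands)
        c = self.config
        n = x.shape[0]
        feats: dict[str, np.ndarray] = {}
        fused = np.zeros((n, c.spatial_filters, c.n_steps))
        if self.fuse_f1:
            front = self.submodules["frontend"].forward(x, False)
            f1 = self.submodules["gcn_branch"].forward(front, False)
            if self._interp is not None:
                f1 = f1 @ self._interp
            feats["f1"] = f1
            fused += f1
        f3 = None
        if "spatial_branch" in self.submodules:
            f3 = self.submodules["spatial_branch"].forward(x, False)
        if self.fuse_f3:
            feats["f3"] = f3
            fused += f3
        if self.fuse_f2:
            f2 = self.submodules["lstm_branch"].forward(f3, False)
            feats["f2"] = f2
            fused += f2
        feats["fused"] = fused
        return feats

    def backward(self, dlogp: np.ndarray) -> None:
        """Accumulate parameter gradients for a preceding train-mode forward."""
        dfused = self.submodules["classifier"].backward(dlogp)
        df3 = np.zeros_like(dfused) if self._cache.get("f3_used") else None
        if self.fuse_f2:
            df3 += self.submodules["lstm_branch"].backward(dfused)
        if self.fuse_f3:
            df3 += dfused
        if df3 is not None and "spatial_branch" in self.submodules:
            self.submodules["spatial_branch"].backward(df3)
        if self.fuse_f1:
            df1 = dfused
            if self._interp is not None:
                df1 = df1 @ self._interp.T
            dfront = self.submodules["gcn_branch"].backward(df1)
            self.submodules["frontend"].backward(dfront)

    @staticmethod
    def _check_finite(x: np.ndarray, branch: str) -> None:
        if not np.isfinite(x).all():
            raise FloatingPointError(f"non-finite activations in {branch}")

    # -- state -----------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all weights and batch-norm stats."""
        out: dict[str, np.ndarray] = {}
        for mod_name, mod in self.submodules.items():
            for i, p in enumerate(mod.params):
                out[f"{mod_name}/p{i:03d}_{p.name}"] = p.data
            for i, bn in enumerate(_batchnorms(mod)):
                out[f"{mod_name}/bn{i}_running_mean"] = bn.running_mean
                out[f"{mod_name}/bn{i}_running_var"] = bn.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for mod_name, mod in self.submodules.items():
            for i, p in enumerate(mod.params):
                key = f"{mod_name}/p{i:03d}_{p.name}"
                if state[key].shape != p.data.shape:
                    raise ValidationError(
                        f"checkpoint array {key} has shape {state[key].shape}, "
                        f"expected {p.data.shape}")
                p.data = state[key].copy()
            for i, bn in enumerate(_batchnorms(mod)):
                bn.running_mean = state[f"{mod_name}/bn{i}_running_mean"].copy()
                bn.running_var = state[f"{mod_name}/bn{i}_running_var"].copy()


def _batchnorms(layer: nnops.Layer) -> Iterable[nnops.BatchNorm]:
    if isinstance(layer, nnops.BatchNorm):
        yield layer
    for child in getattr(layer, "layers", []):
        yield from _batchnorms(child)


def _interp_matrix(src: int, dst: int) -> np.ndarray:
    """(src, dst) linear-interpolation matrix mapping length src -> dst."""
    m = np.zeros((src, dst))
    if src == 1:
        m[0, :] = 1.0
        return m
    pos = np.linspace(0, src - 1, dst)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    w = pos - lo
    for j in range(dst):
        m[lo[j], j] += 1 - w[j]
        m[hi[j], j] += w[j]
    return m


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_glcnet(config: ModelConfig, seed: int = 0) -> Model:
    """Instantiate the decoder with seeded fan-in uniform initialization."""
    return Model(config, seed=seed)


def count_parameters(model: Model, submodule: str = "all") -> int:
    """Exact number of trainable scalars in a named sub-module (or all)."""
    return sum(p.size for p in model.parameters(submodule))


def ablate(config: ModelConfig, remove: str) -> ModelConfig:
    """Config whose built model omits one branch from the fusion.

    ``module1_gcn`` removes the front-end and graph branch entirely;
    ``module2_spatialconv`` drops F3 from the fusion (keeping the spatial
    convolution the LSTM needs); ``module3_lstm`` drops the recurrent
    branch.
    """
    if not isinstance(remove, str):
        raise ConfigurationError("remove exactly one module per call")
    if remove not in ABLATABLE:
        raise ConfigurationError(f"unknown module {remove!r}; valid: {ABLATABLE}")
    if config.removed is not None:
        raise ConfigurationError(
            f"config already ablates {config.removed!r}; only one module "
            "may be removed")
    return dataclasses.replace(config, removed=remove)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path: str | Path) -> Path:
    """Single-file HDF5 archive: weights, config, adjacency and seed."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in model.state_arrays().items():
            f.create_dataset(f"state/{name}", data=arr)
        f.create_dataset("adjacency", data=model.config.adjacency.matrix)
        f.attrs["adjacency_mode"] = model.config.adjacency.mode
        f.attrs["config"] = json.dumps(model.config.to_dict())
        f.attrs["seed"] = model.seed
    return path


def load_checkpoint(path: str | Path) -> Model:
    path = Path(path)
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        cfg.pop("adjacency_mode", None)
        cfg["gcn_dims"] = tuple(cfg["gcn_dims"])
        adjacency = AdjacencySpec(
            mode=str(f.attrs["adjacency_mode"]),
            matrix=np.asarray(f["adjacency"]),
        )
        seed = int(f.attrs["seed"])
        state = {k: np.asarray(v) for k, v in _walk(f["state"])}
    config = ModelConfig(adjacency=adjacency, **cfg)
    model = Model(config, seed=seed)
    model.load_state_arrays(state)
    return model


def _walk(group, prefix=""):
    for key, item in group.items():
        name = f"{prefix}{key}"
        if isinstance(item, h5py.Group):
            yield from _walk(item, prefix=f"{name}/")
        else:
            yield name, item
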