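"""Base retention-index regressors: training, transfer learning, prediction.

Two architectures serve each phase family: a residual MLP over the 327
descriptors plus the 38-slot phase encoding, and a 1-D CNN over the SMILES
one-hot grid merged with the phase encoding.  Non-polar models are trained
from random initialization; polar models are *transfer-trained*, initialized
from the non-polar weights after the full schedule (not the best-validation
checkpoint).  Training minimizes mean absolute error on RI/1000; a held-out
10% of training *compounds* drives best-checkpoint selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .chem import Molecule, SMILES_ALPHABET, cnn_encode
from .data import RetentionRecord
from .features import Featurizer, default_featurizer
from .phases import ENCODING_LENGTH, NON_POLAR, POLAR, PhaseRegistry, SPEncoding, sp_encode

RI_SCALE = 1000.0


class ConfigurationError(ValueError):
    """Raised for unusable training configuration (e.g. empty partitions)."""


class IncompatibleInitializationError(ValueError):
    """Raised when transfer weights do not match the target architecture."""


class IncompleteEnsembleError(KeyError):
    """Raised when the four-net ensemble is missing a member."""


class EncodingFamilyError(ValueError):
    """Raised when a phase encoding family does not match the net's family."""


@dataclass(frozen=True)
class NetSpec:
    """Architecture plan for a base regressor.

    Defaults follow the full-scale configuration (MLP: three residual blocks
    of width 512; CNN: 64->128 channels, kernel 5, dense head 256); the
    ``*_desk`` constructors give the reduced sizes used for simulator-scale
    studies on one CPU.
    """

    kind: str  # "mlp" | "cnn"
    hidden_width: int = 512
    n_blocks: int = 3
    conv_channels: tuple[int, int] = (64, 128)
    kernel_size: int = 5
    dense_width: int = 256
    l_max: int = 150
    desc_dim: int = 327
    sp_dim: int = ENCODING_LENGTH

    def __post_init__(self):
        if self.kind not in ("mlp", "cnn"):
            raise ValueError(f"unknown net kind {self.kind!r}")

    @classmethod
    def mlp_default(cls) -> "NetSpec":
        return cls(kind="mlp")

    @classmethod
    def cnn_default(cls) -> "NetSpec":
        return cls(kind="cnn")

    @classmethod
    def mlp_desk(cls) -> "NetSpec":
        return cls(kind="mlp", hidden_width=128, n_blocks=2)

    @classmethod
    def cnn_desk(cls) -> "NetSpec":
        return cls(kind="cnn", conv_channels=(8, 16), dense_width=64, l_max=60)


@dataclass(frozen=True)
class TrainProtocol:
    """Training schedule: batch size 256, 50k base / 10k transfer iterations,
    10% compound-held-out validation with best-checkpoint selection."""

    max_iterations: int = 50_000
    batch_size: int = 256
    validation_fraction: float = 0.10
    checkpoint_every: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    @classmethod
    def base(cls, **overrides) -> "TrainProtocol":
        return replace(cls(max_iterations=50_000), **overrides)

    @classmethod
    def transfer(cls, **overrides) -> "TrainProtocol":
        return replace(cls(max_iterations=10_000), **overrides)


@dataclass
class TrainedNet:
    """A trained base regressor.

    ``final_params`` are the weights after the last iteration (the transfer
    initialization source); ``best_params`` the weights at the checkpoint
    with the lowest validation MAE (used for prediction).  ``history`` holds
    (iteration, validation MAE on RI/1000) pairs.
    """

    spec: NetSpec
    family: str
    final_params: list[np.ndarray]
    best_params: list[np.ndarray]
    history: list[tuple[int, float]]
    validation_keys: frozenset[str] = field(default_factory=frozenset)

    @property
    def best_validation_mae(self) -> float:
        return min(v for _, v in self.history) if self.history else float("nan")


def build_net(spec: NetSpec, rng: np.random.Generator):
    if spec.kind == "mlp":
        return nn.MLPNet(rng, spec.desc_dim + spec.sp_dim, spec.hidden_width, spec.n_blocks)
    return nn.CNNNet(rng, len(SMILES_ALPHABET), spec.sp_dim,
                     spec.conv_channels[0], spec.conv_channels[1],
                     spec.kernel_size, spec.dense_width)


@dataclass
class _TrainData:
    """Featurized records: per-unique-molecule features plus per-record rows."""

    mol_feats: np.ndarray  # (n_mols, 327) for mlp; (n_mols, L, A) for cnn
    mol_index: np.ndarray  # (n_records,)
    sp: np.ndarray         # (n_records, 38)
    y: np.ndarray          # (n_records,) scaled RI
    keys: list[str]        # per record


def _prepare(records: list[RetentionRecord], spec: NetSpec, family: str,
             featurizer: Featurizer, registry: PhaseRegistry) -> _TrainData:
    mol_by_key: dict[str, Molecule] = {}
    for rec in records:
        if rec.family != family:
            raise ConfigurationError(
                f"record family {rec.family!r} does not match net family {family!r}")
        mol_by_key.setdefault(rec.compound_key, rec.molecule)
    order = {key: i for i, key in enumerate(mol_by_key)}
    mols = list(mol_by_key.values())
    if spec.kind == "mlp":
        feats = featurizer.matrix(mols)
    else:
        feats = np.stack([cnn_encode(m, spec.l_max).grid for m in mols])
    enc_cache: dict[str, np.ndarray] = {}
    sp_rows = np.empty((len(records), spec.sp_dim), dtype=np.float32)
    for i, rec in enumerate(records):
        enc = enc_cache.get(rec.phase)
        if enc is None:
            enc = sp_encode(rec.phase, registry, family).vector
            enc_cache[rec.phase] = enc
        sp_rows[i] = enc
    return _TrainData(
        mol_feats=feats,
        mol_index=np.array([order[r.compound_key] for r in records]),
        sp=sp_rows,
        y=np.array([r.ri for r in records], dtype=np.float32) / RI_SCALE,
        keys=[r.compound_key for r in records],
    )


def _forward(net, spec: NetSpec, data: _TrainData, idx: np.ndarray) -> np.ndarray:
    if spec.kind == "mlp":
        x = np.concatenate([data.mol_feats[data.mol_index[idx]], data.sp[idx]], axis=1)
        return net.forward(x)
    return net.forward(data.mol_feats[data.mol_index[idx]], data.sp[idx])


def _eval_mae(net, spec: NetSpec, data: _TrainData, idx: np.ndarray,
              batch: int = 1024) -> float:
    total = 0.0
    for start in range(0, len(idx), batch):
        sel = idx[start:start + batch]
        pred = _forward(net, spec, data, sel)
        total += float(np.abs(pred - data.y[sel]).sum())
    return total / len(idx)


def _split_validation(data: _TrainData, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, frozenset]:
    keys = sorted(set(data.keys))
    rng.shuffle(keys)
    n_val = max(1, int(round(fraction * len(keys))))
    val_keys = frozenset(keys[:n_val])
    is_val = np.array([k in val_keys for k in data.keys])
    train_idx = np.flatnonzero(~is_val)
    val_idx = np.flatnonzero(is_val)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ConfigurationError("training or validation partition is empty")
    return train_idx, val_idx, val_keys


def _run_training(net, spec: NetSpec, family: str, data: _TrainData,
                  protocol: TrainProtocol, rng: np.random.Generator) -> TrainedNet:
    train_idx, val_idx, val_keys = _split_validation(
        data, protocol.validation_fraction, rng)
    optimizer = nn.Adam(net.params, net.grads, lr=protocol.learning_rate)
    best_params = nn.get_params(net)
    best_score = _eval_mae(net, spec, data, val_idx) if protocol.max_iterations == 0 else np.inf
    history: list[tuple[int, float]] = []
    for it in range(1, protocol.max_iterations + 1):
        batch = train_idx[rng.integers(0, len(train_idx), protocol.batch_size)]
        pred = _forward(net, spec, data, batch)
        dy = np.sign(pred - data.y[batch]).astype(np.float32) / len(batch)
        net.backward(dy)
        optimizer.step()
        if it % protocol.checkpoint_every == 0 or it == protocol.max_iterations:
            score = _eval_mae(net, spec, data, val_idx)
            history.append((it, score))
            if score < best_score:
                best_score = score
                best_params = nn.get_params(net)
    return TrainedNet(spec=spec, family=family, final_params=nn.get_params(net),
                      best_params=best_params, history=history,
                      validation_keys=val_keys)


def train_from_scratch(spec: NetSpec, records: list[RetentionRecord], family: str,
                       protocol: TrainProtocol, registry: PhaseRegistry,
                       featurizer: Featurizer | None = None) -> TrainedNet:
    """Train a regressor for one phase family from random initialization."""
    featurizer = featurizer or default_featurizer()
    if not records:
        raise ConfigurationError("no training records")
    data = _prepare(records, spec, family, featurizer, registry)
    rng = np.random.default_rng(protocol.seed)
    net = build_net(spec, rng)
    return _run_training(net, spec, family, data, protocol, rng)


def train_base(spec: NetSpec, records: list[RetentionRecord],
               protocol: TrainProtocol, registry: PhaseRegistry,
               featurizer: Featurizer | None = None) -> TrainedNet:
    """Train a non-polar base regressor from random initialization.

    Targets are RI/1000; returns both the final weights (transfer source) and
    the best-validation weights (used for prediction).
    """
    return train_from_scratch(spec, records, NON_POLAR, protocol, registry, featurizer)


def transfer_train(init_params: list[np.ndarray], spec: NetSpec,
                   polar_records: list[RetentionRecord], protocol: TrainProtocol,
                   registry: PhaseRegistry,
                   featurizer: Featurizer | None = None) -> TrainedNet:
    """Train a polar regressor initialized from non-polar final weights."""
    featurizer = featurizer or default_featurizer()
    if not polar_records:
        raise ConfigurationError("no training records")
    data = _prepare(polar_records, spec, POLAR, featurizer, registry)
    rng = np.random.default_rng(protocol.seed)
    net = build_net(spec, rng)
    try:
        nn.set_params(net, init_params)
    except ValueError as exc:
        raise IncompatibleInitializationError(str(exc)) from None
    if protocol.max_iterations == 0:
        init_copy = [p.copy() for p in init_params]
        return TrainedNet(spec=spec, family=POLAR, final_params=init_copy,
                          best_params=[p.copy() for p in init_params], history=[])
    return _run_training(net, spec, POLAR, data, protocol, rng)


def _restore(trained: TrainedNet, which: str = "best"):
    net = build_net(trained.spec, np.random.default_rng(0))
    nn.set_params(net, trained.best_params if which == "best" else trained.final_params)
    return net


def predict_ri_batch(trained: TrainedNet, molecules: list[Molecule],
                     enc: SPEncoding, featurizer: Featurizer | None = None,
                     which: str = "best") -> np.ndarray:
    """Predicted RI (index units) for molecules on one encoded phase."""
    if enc.family != trained.family:
        raise EncodingFamilyError(
            f"encoding family {enc.family!r} does not match net family {trained.family!r}")
    featurizer = featurizer or default_featurizer()
    net = _restore(trained, which)
    spec = trained.spec
    sp = np.tile(enc.vector, (len(molecules), 1))
    if spec.kind == "mlp":
        x = np.concatenate([featurizer.matrix(molecules), sp], axis=1)
        preds = [net.forward(x[s:s + 1024]) for s in range(0, len(x), 1024)]
    else:
        grids = np.stack([cnn_encode(m, spec.l_max).grid for m in molecules])
        preds = [net.forward(grids[s:s + 1024], sp[s:s + 1024])
                 for s in range(0, len(grids), 1024)]
    return np.concatenate(preds) * RI_SCALE


def predict_ri(trained: TrainedNet, molecule: Molecule, enc: SPEncoding,
               featurizer: Featurizer | None = None) -> float:
    """Predicted RI (index units) for one molecule on one encoded phase."""
    return float(predict_ri_batch(trained, [molecule], enc, featurizer)[0])


def evaluate_scaled_mae(trained: TrainedNet, records: list[RetentionRecord],
                        registry: PhaseRegistry,
                        featurizer: Featurizer | None = None,
                        which: str = "best") -> float:
    """MAE on RI/1000 of a trained net over arbitrary records (for checks)."""
    featurizer = featurizer or default_featurizer()
    data = _prepare(records, trained.spec, trained.family, featurizer, registry)
    net = _restore(trained, which)
    return _eval_mae(net, trained.spec, data, np.arange(len(data.y)))


def ensemble_average(preds: list[float] | np.ndarray) -> float:
    """Arithmetic mean of per-model RI predictions for one (molecule, phase)."""
    preds = np.asarray(preds, dtype=np.float64)
    if preds.size == 0:
        raise ValueError("ensemble_average requires at least one prediction")
    return float(preds.mean())


ENSEMBLE_KEYS = ("cnn", "mlp", "cnn_polar", "mlp_polar")


def feature_block_names(registry: PhaseRegistry) -> list[str]:
    """Fixed ordering of the 114 predicted-RI features."""
    names = [f"CNN:{p}" for p in registry.nonpolar_types]
    names += [f"MLP:{p}" for p in registry.nonpolar_types]
    names += [f"CNNPolar:{p}" for p in registry.polar_types]
    names += [f"MLPPolar:{p}" for p in registry.polar_types]
    return names


def ri_feature_matrix(nets: dict[str, TrainedNet], molecules: list[Molecule],
                      registry: PhaseRegistry,
                      featurizer: Featurizer | None = None) -> np.ndarray:
    """The 114 predicted-RI features (RI/1000) for each molecule.

    Layout: 36 non-polar phases through the CNN, 36 through the MLP, then 21
    polar phases through CNNPolar and 21 through MLPPolar, in registry order.
    """
    missing = [k for k in ENSEMBLE_KEYS if k not in nets]
    if missing:
        raise IncompleteEnsembleError(f"missing nets: {missing}")
    featurizer = featurizer or default_featurizer()
    n = len(molecules)
    desc = None
    grids_by_lmax: dict[int, np.ndarray] = {}
    cols: list[np.ndarray] = []
    for key, family in (("cnn", NON_POLAR), ("mlp", NON_POLAR),
                        ("cnn_polar", POLAR), ("mlp_polar", POLAR)):
        trained = nets[key]
        if trained.family != family:
            raise EncodingFamilyError(f"net {key!r} must have family {family!r}")
        net = _restore(trained, "best")
        spec = trained.spec
        if spec.kind == "mlp":
            if desc is None:
                desc = featurizer.matrix(molecules)
            mol_feats = desc
        else:
            if spec.l_max not in grids_by_lmax:
                grids_by_lmax[spec.l_max] = np.stack(
                    [cnn_encode(m, spec.l_max).grid for m in molecules])
            mol_feats = grids_by_lmax[spec.l_max]
        for phase in registry.types(family):
            sp = np.tile(sp_encode(phase, registry, family).vector, (n, 1))
            preds = []
            for s in range(0, n, 1024):
                if spec.kind == "mlp":
                    x = np.concatenate([mol_feats[s:s + 1024], sp[s:s + 1024]], axis=1)
                    preds.append(net.forward(x))
                else:
                    preds.append(net.forward(mol_feats[s:s + 1024], sp[s:s + 1024]))
            cols.append(np.concatenate(preds))
    return np.stack(cols, axis=1).astype(np.float32)


def ri_feature_block(nets: dict[str, TrainedNet], molecule: Molecule,
                     registry: PhaseRegistry,
                     featurizer: Featurizer | None = None) -> np.ndarray:
    """Length-114 predicted-RI feature block for a single molecule."""
    return ri_feature_matrix(nets, [molecule], registry, featurizer)[0]


def save_trained(trained: TrainedNet, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON sidecar manifest."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(trained.final_params):
        arrays[f"final_{i}"] = p
    for i, p in enumerate(trained.best_params):
        arrays[f"best_{i}"] = p
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {
        "spec": {k: getattr(trained.spec, k) for k in
                 ("kind", "hidden_width", "n_blocks", "conv_channels", "kernel_size",
                  "dense_width", "l_max", "desc_dim", "sp_dim")},
        "family": trained.family,
        "history": trained.history,
        "validation_keys": sorted(trained.validation_keys),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_trained(path: str | Path) -> TrainedNet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    raw = dict(manifest["spec"])
    raw["conv_channels"] = tuple(raw["conv_channels"])
    spec = NetSpec(**raw)
    with np.load(path.with_suffix(".npz")) as arrays:
        n = len(arrays.files) // 2
        final = [arrays[f"final_{i}"] for i in range(n)]
        best = [arrays[f"best_{i}"] for i in range(n)]
    return TrainedNet(spec=spec, family=manifest["family"], final_params=final,
                      best_params=best,
                      history=[tuple(h) for h in manifest["history"]],
                      validation_keys=frozenset(manifest["validation_keys"]))
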