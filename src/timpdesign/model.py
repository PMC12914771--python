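"""Ensemble multilayer-perceptron regression of log2 enrichment ratios.

The affinity model is a small fully connected network on one-hot encoded
variant signatures (20 residues x 7 positions = 140 inputs): two hidden
layers with ReLU activations and dropout, and a single linear output unit.
Two named architectures are supported:

* ``Lib``: 32 units / 20% dropout, then 4 units / 10% dropout.
* ``Ala``: 8 units / 0% dropout, then 2 units / 30% dropout.

Robustness comes from a random-initialization ensemble: ten members are
trained with consecutive seeds (different weight initializations, minibatch
shuffles, and dropout masks) and the model's prediction is the arithmetic
mean of the member outputs.  Training minimizes (optionally read-depth
weighted) mean squared error with the Adam optimizer; everything stochastic
is derived from the member seed, so training is deterministic given
(data, hyper-parameters, seed).

The networks are implemented directly in NumPy: they are tiny (a few
thousand parameters), and a framework-free implementation keeps training
bit-reproducible and the saved models portable (plain JSON).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import TrainingExample
from .variant_space import ReferenceScheme, one_hot_batch


# ---------------------------------------------------------------------------
# Architectures and hyper-parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    fcl1_units: int
    dropout1: float
    fcl2_units: int
    dropout2: float

    def n_parameters(self, n_inputs: int) -> int:
        """Trainable scalars (weights + biases) for a given input width."""
        h1, h2 = self.fcl1_units, self.fcl2_units
        return (n_inputs * h1 + h1) + (h1 * h2 + h2) + (h2 * 1 + 1)


ARCHITECTURES: dict[str, ArchitectureSpec] = {
    "Lib": ArchitectureSpec("Lib", fcl1_units=32, dropout1=0.20, fcl2_units=4, dropout2=0.10),
    "Ala": ArchitectureSpec("Ala", fcl1_units=8, dropout1=0.00, fcl2_units=2, dropout2=0.30),
}

#: Hyper-parameter search grids.
DEFAULT_GRID: dict[str, tuple] = {
    "batch_size": (2, 4, 8, 16, 32, 64),
    "epochs": (10, 20, 30, 40, 50),
    "learning_rate": (1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 3e-2),
    "architecture": ("Ala", "Lib"),
    "sample_weighting": ("no-weight", "with-weight"),
}


@dataclass(frozen=True)
class HyperParams:
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 5e-3
    architecture: str = "Lib"
    sample_weighting: str = "no-weight"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.sample_weighting not in ("no-weight", "with-weight"):
            raise ValueError(f"unknown sample_weighting {self.sample_weighting!r}")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


# ---------------------------------------------------------------------------
# Dataset split and weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[TrainingExample, ...]
    val: tuple[TrainingExample, ...]
    test: tuple[TrainingExample, ...]


def split_by_depth(examples: Sequence[TrainingExample]) -> DatasetSplit:
    """Depth-based split: deepest 10% -> test, next 10% -> validation.

    Variants with the highest summed read counts have the least shot noise in
    their log2 ER labels, so they make the most reliable evaluation sets.
    Sorting is by raw weight descending with a lexicographic signature
    tie-break, making the split deterministic.
    """
    n = len(examples)
    if n < 10:
        raise ValueError(f"TOO_FEW_EXAMPLES: need >= 10, got {n}")
    ordered = sorted(examples, key=lambda e: (-e.weight_raw, e.signature))
    n_test = n // 10
    n_val = n // 10
    return DatasetSplit(
        test=tuple(ordered[:n_test]),
        val=tuple(ordered[n_test : n_test + n_val]),
        train=tuple(ordered[n_test + n_val :]),
    )


def sample_weight(example: TrainingExample) -> float:
    """log2 of the summed read count (prioritizes well-sampled variants)."""
    if example.weight_raw <= 0:
        raise ValueError("weight_raw must be positive")
    return math.log2(example.weight_raw)


def _design_matrices(
    examples: Sequence[TrainingExample], scheme: ReferenceScheme, hp: HyperParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = one_hot_batch([e.signature for e in examples], scheme)
    y = np.array([e.label for e in examples], dtype=np.float64)
    if hp.sample_weighting == "with-weight":
        w = np.array([sample_weight(e) for e in examples], dtype=np.float64)
    else:
        w = np.ones(len(examples), dtype=np.float64)
    return X, y, w


# ---------------------------------------------------------------------------
# The MLP itself
# ---------------------------------------------------------------------------

class MLP:
    """Two-hidden-layer perceptron with ReLU, dropout, and Adam training."""

    def __init__(self, n_inputs: int, arch: ArchitectureSpec, rng: np.random.Generator):
        self.arch = arch
        self.n_inputs = n_inputs
        dims = [n_inputs, arch.fcl1_units, arch.fcl2_units, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims, dims[1:]):
            # Glorot-uniform initialization, seeded per member.
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Forward pass; dropout (inverted) is applied only when ``rng`` is given."""
        dropouts = (self.arch.dropout1, self.arch.dropout2)
        cache = []
        h = X
        for layer in range(2):
            z = h @ self.weights[layer] + self.biases[layer]
            a = np.maximum(z, 0.0)
            mask = None
            rate = dropouts[layer]
            if rng is not None and rate > 0.0:
                mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
                a = a * mask
            cache.append((h, z, a, mask))
            h = a
        out = h @ self.weights[2] + self.biases[2]
        cache.append((h, out))
        return out[:, 0], cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X)
        return out

    def _backward(
        self, cache: list, dout: np.ndarray
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * 3  # type: ignore[list-item]
        h_last, _ = cache[2]
        d = dout[:, None]
        grads[2] = (h_last.T @ d, d.sum(axis=0))
        dh = d @ self.weights[2].T
        for layer in (1, 0):
            h_in, z, _a, mask = cache[layer]
            if mask is not None:
                dh = dh * mask
            dz = dh * (z > 0.0)
            grads[layer] = (h_in.T @ dz, dz.sum(axis=0))
            dh = dz @ self.weights[layer].T
        return grads

    def to_dict(self) -> dict:
        return {
            "architecture": self.arch.name,
            "n_inputs": self.n_inputs,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MLP":
        arch = ARCHITECTURES[data["architecture"]]
        obj = cls.__new__(cls)
        obj.arch = arch
        obj.n_inputs = data["n_inputs"]
        obj.weights = [np.asarray(w, dtype=np.float64) for w in data["weights"]]
        obj.biases = [np.asarray(b, dtype=np.float64) for b in data["biases"]]
        return obj


def train_member(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    hp: HyperParams,
    seed: int,
) -> tuple[MLP, list[float]]:
    """Train a single MLP member; returns the model and its per-epoch loss curve.

    Minimizes the weighted MSE  mean_i w_i (f(x_i) - y_i)^2  with Adam for
    exactly ``hp.epochs`` passes over the data in shuffled minibatches of
    ``hp.batch_size``.  Initialization, shuffling, and dropout masks all come
    from one generator seeded with ``seed``.
    """
    rng = np.random.default_rng(seed)
    arch = ARCHITECTURES[hp.architecture]
    net = MLP(X.shape[1], arch, rng)

    # Adam state.
    params = net.weights + net.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    n = X.shape[0]
    loss_curve: list[float] = []
    for _epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb, wb = X[idx], y[idx], w[idx]
            pred, cache = net.forward(xb, rng=rng)
            err = pred - yb
            loss = float(np.mean(wb * err**2))
            epoch_loss += loss * len(idx)
            # d(mean w e^2)/d pred = 2 w e / batch
            dout = 2.0 * wb * err / len(idx)
            grads = net._backward(cache, dout)
            flat_grads = [g for g, _ in grads] + [b for _, b in grads]
            t += 1
            lr_t = hp.learning_rate * math.sqrt(1 - beta2**t) / (1 - beta1**t)
            for p, g, mi, vi in zip(params, flat_grads, m, v):
                mi += (1 - beta1) * (g - mi)
                vi += (1 - beta2) * (g**2 - vi)
                p -= lr_t * mi / (np.sqrt(vi) + eps)
        epoch_loss /= n
        # Adam's normalized steps rarely yield literal NaN; runaway loss
        # magnitude is treated as divergence too.
        if not math.isfinite(epoch_loss) or epoch_loss > 1e100:
            raise DivergenceError(f"loss diverged with {hp}")
        loss_curve.append(epoch_loss)
    return net, loss_curve


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Mean of independently seeded MLP members trained on the same data."""

    members: list[MLP]
    hyperparams: HyperParams
    scheme: ReferenceScheme
    member_seeds: list[int]
    loss_curves: list[list[float]] = field(default_factory=list)

    def predict_signatures(self, signatures: Sequence[str], chunk: int = 65536) -> np.ndarray:
        if len(signatures) == 0:
            return np.empty(0)
        out = np.empty(len(signatures))
        for start in range(0, len(signatures), chunk):
            block = signatures[start : start + chunk]
            X = one_hot_batch(block, self.scheme)
            out[start : start + len(block)] = self.predict_matrix(X)
        return out

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([member.predict(X) for member in self.members])
        return preds.mean(axis=0)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "hyperparams": asdict(self.hyperparams),
            "member_seeds": self.member_seeds,
            "scheme": self.scheme.to_dict(),
            "loss_curves": self.loss_curves,
        }
        (directory / "model.json").write_text(
            json.dumps({"meta": meta, "members": [m.to_dict() for m in self.members]})
        )

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        data = json.loads((Path(directory) / "model.json").read_text())
        meta = data["meta"]
        scheme_cfg = meta["scheme"]
        scheme = ReferenceScheme(
            wt_sequence=scheme_cfg["wt_sequence"],
            targeted_positions=tuple(scheme_cfg["positions"]),
            alphabet=tuple(scheme_cfg["alphabet"]),
        )
        return cls(
            members=[MLP.from_dict(m) for m in data["members"]],
            hyperparams=HyperParams(**meta["hyperparams"]),
            scheme=scheme,
            member_seeds=list(meta["member_seeds"]),
            loss_curves=meta["loss_curves"],
        )


def train_ensemble(
    train: Sequence[TrainingExample],
    hp: HyperParams,
    scheme: ReferenceScheme,
    n_members: int = 10,
) -> EnsembleModel:
    """Train ``n_members`` MLPs with seeds base_seed .. base_seed+n_members-1."""
    if not train:
        raise ValueError("empty training set")
    X, y, w = _design_matrices(train, scheme, hp)
    members, curves, seeds = [], [], []
    for offset in range(n_members):
        seed = hp.base_seed + offset
        net, curve = train_member(X, y, w, hp, seed)
        members.append(net)
        curves.append(curve)
        seeds.append(seed)
    return EnsembleModel(
        members=members, hyperparams=hp, scheme=scheme, member_seeds=seeds, loss_curves=curves
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def pearson(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Pearson correlation sum((x-xbar)(y-ybar)) / sqrt(sum sq * sum sq)."""
    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise ZeroVarianceError("constant vector: correlation undefined")
    return float(dx @ dy) / denom


def evaluate(
    model: EnsembleModel, examples: Sequence[TrainingExample]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pearson between predicted and observed labels, plus the raw pairs."""
    predicted = model.predict_signatures([e.signature for e in examples])
    observed = np.array([e.label for e in examples])
    return pearson(predicted, observed), predicted, observed


def grid_combinations(grid: dict[str, tuple] | None = None) -> list[dict]:
    """Deterministic enumeration of a hyper-parameter grid (dicts of values)."""
    grid = dict(DEFAULT_GRID if grid is None else grid)
    keys = list(grid)
    return [dict(zip(keys, values)) for values in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    examples: Sequence[TrainingExample],
    scheme: ReferenceScheme,
    grid: dict[str, tuple] | None = None,
    base_seed: int = 0,
    n_members: int = 10,
) -> tuple[HyperParams, EnsembleModel, pd.DataFrame]:
    """Exhaustive grid search scored by validation-set Pearson correlation.

    The depth split is frozen once and reused for every combination.  The
    winning combination (argmax validation Pearson, first-in-grid tie-break)
    is rescored exactly once on the held-out test set; the returned
    leaderboard has one row per combination.
    """
    split = split_by_depth(examples)
    rows = []
    best: tuple[float, int, HyperParams, EnsembleModel] | None = None
    for i, combo in enumerate(grid_combinations(grid)):
        hp = HyperParams(base_seed=base_seed, **combo)
        try:
            model = train_ensemble(split.train, hp, scheme, n_members=n_members)
            val_r, _, _ = evaluate(model, split.val)
        except DivergenceError:
            rows.append({**combo, "val_pearson": float("nan"), "status": "diverged"})
            continue
        rows.append({**combo, "val_pearson": val_r, "status": "ok"})
        if best is None or val_r > best[0]:
            best = (val_r, i, hp, model)
    if best is None:
        raise RuntimeError("all hyper-parameter combinations failed")
    _, _, best_hp, best_model = best
    test_r, _, _ = evaluate(best_model, split.test)
    leaderboard = pd.DataFrame(rows)
    leaderboard["test_pearson"] = np.nan
    leaderboard.loc[leaderboard.index[best[1]], "test_pearson"] = test_r
    return best_hp, best_model, leaderboard
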