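"""Counter-propagation artificial neural network (CP ANN).

A CP ANN is a Kohonen self-organizing map extended with a supervised output
layer.  Both layers share one nx x ny grid of neurons: the Kohonen (input)
layer holds one weight vector per neuron in descriptor space (its p slices
are the "weight levels"), the output layer holds one response vector per
neuron.  Training is competitive: each object is assigned to the neuron
whose Kohonen weights are closest (Euclidean), and the weights of all
neurons within the current neighbourhood radius — in *both* layers — move
toward the object's inputs and targets respectively, scaled by a decaying
learning rate and a neighbourhood factor.  Prediction projects a new object
onto its winning neuron and reads the output weights stored there.

Exact update rule (one object presentation = one step ``t`` of
``total = epochs * n``):

    eta_t    = eta_max + (eta_min - eta_max) * t / (total - 1)
    radius_t = (max(nx, ny) / 2) * (1 - t / total)
    d(c)     = Chebyshev grid distance of neuron c from the winner
    h(c)     = max(0, 1 - d / (radius_t + 1))        (triangular)
               exp(-(d / (radius_t + 1))^2) for d <= radius_t (gaussian)
    w_c     += eta_t * h(c) * (x - w_c);   o_c += eta_t * h(c) * (y - o_c)

With inputs in [0, 1] and eta_max <= 1 every update is a convex step, so
Kohonen weights never leave [0, 1].  Objects are presented in dataset order
(optionally shuffled with the model seed), making runs bit-reproducible.

Two output encodings cover the two model variants: ``numeric_class`` (one
response level, classes coded 1 = non-carcinogen / 2 = carcinogen, decoded
at the 1.5 midpoint) and ``one_hot`` (one response level per class, decoded
by argmax) for the structural-alert-group model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .records import NormalizationParams

logger = logging.getLogger(__name__)

RANGE_TOL = 1e-9


class NeuronPosition(NamedTuple):
    """1-based grid coordinates, matching the map-reading convention."""

    ix: int
    iy: int


@dataclass(frozen=True)
class TrainingConfig:
    nx: int = 35
    ny: int = 35
    epochs: int = 200
    eta_max: float = 0.5
    eta_min: float = 0.01
    topology: str = "planar"  # or "toroidal"
    neighborhood: str = "triangular"  # or "gaussian"
    grid_metric: str = "chebyshev"  # or "cityblock"
    seed: int = 0
    output_encoding: str = "numeric_class"  # or "one_hot"
    shuffle: bool = False

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.eta_max >= self.eta_min > 0):
            raise ValueError("need eta_max >= eta_min > 0")
        if self.eta_max > 1:
            raise ValueError("eta_max > 1 breaks the weight-range invariant")
        for fld, allowed in (
            ("topology", {"planar", "toroidal"}),
            ("neighborhood", {"triangular", "gaussian"}),
            ("grid_metric", {"chebyshev", "cityblock"}),
            ("output_encoding", {"numeric_class", "one_hot"}),
        ):
            if getattr(self, fld) not in allowed:
                raise ValueError(f"{fld} must be one of {sorted(allowed)}")


@dataclass
class CPANNModel:
    """Kohonen weight tensor (nx, ny, p) + output weight tensor (nx, ny, r)."""

    kohonen_weights: np.ndarray
    output_weights: np.ndarray
    config: TrainingConfig
    norm: NormalizationParams | None = None
    column_names: list[str] | None = None
    classes: np.ndarray | None = None
    trained: bool = False

    @property
    def n_levels(self) -> int:
        return self.kohonen_weights.shape[2]

    @property
    def n_responses(self) -> int:
        return self.output_weights.shape[2]


def initialize(config: TrainingConfig, p: int, r: int) -> CPANNModel:
    """Fresh model with weights drawn uniform in [0, 1] from the seeded generator."""
    if p < 1 or r < 1:
        raise ValueError("need p >= 1 input levels and r >= 1 response levels")
    rng = np.random.default_rng(config.seed)
    return CPANNModel(
        kohonen_weights=rng.random((config.nx, config.ny, p)),
        output_weights=rng.random((config.nx, config.ny, r)),
        config=config,
    )


def _winner_flat(W: np.ndarray, x: np.ndarray) -> tuple[int, int]:
    """Row-major argmin of squared Euclidean distance; ties -> smallest (ix, iy)."""
    diff = W - x
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    flat = int(np.argmin(d2))
    return flat // W.shape[1], flat % W.shape[1]


def find_winner(model: CPANNModel, x: np.ndarray) -> NeuronPosition:
    """Neuron whose Kohonen weight vector is closest to x (1-based position)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_levels,):
        raise ValueError(f"input has length {x.shape}, model expects {model.n_levels}")
    i, j = _winner_flat(model.kohonen_weights, x)
    return NeuronPosition(i + 1, j + 1)


def _grid_distance_row(n: int, center: int, toroidal: bool) -> np.ndarray:
    d = np.abs(np.arange(n) - center)
    if toroidal:
        d = np.minimum(d, n - d)
    return d


def _neighborhood_factor(d: np.ndarray, radius: float, kind: str) -> np.ndarray:
    if kind == "triangular":
        h = 1.0 - d / (radius + 1.0)
    else:  # gaussian
        h = np.exp(-((d / (radius + 1.0)) ** 2))
    return np.where(d <= radius, h, 0.0)


def train(
    model: CPANNModel,
    X: np.ndarray,
    Y: np.ndarray,
    epoch_callback: Callable[[CPANNModel, int], None] | None = None,
    record_winners: list[tuple[int, int]] | None = None,
) -> CPANNModel:
    """Train in place and return the model.

    X must already be normalized to [0, 1] (checked); Y is an (n, r) target
    matrix row-aligned with X.  ``epoch_callback(model, epoch)`` runs after
    each epoch (used e.g. to assert invariants during training); a list
    passed as ``record_winners`` collects the 0-based winner sequence.
    """
    cfg = model.config
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if X.ndim != 2 or X.shape[1] != model.n_levels:
        raise ValueError("X does not match the model's input levels")
    if Y.shape != (n, model.n_responses):
        raise ValueError("Y does not align with X / the model's response levels")
    if X.min() < -RANGE_TOL or X.max() > 1 + RANGE_TOL:
        raise ValueError(
            "training inputs outside [0, 1]; normalize with MinMaxClipScaler first"
        )

    W, O = model.kohonen_weights, model.output_weights
    nx, ny = cfg.nx, cfg.ny
    toroidal = cfg.topology == "toroidal"
    r_max = max(nx, ny) / 2.0
    total = cfg.epochs * n
    shuffle_rng = np.random.default_rng(cfg.seed + 1) if cfg.shuffle else None
    order = np.arange(n)
    t = 0
    for epoch in range(cfg.epochs):
        if shuffle_rng is not None:
            shuffle_rng.shuffle(order)
        for i in order:
            x, y = X[i], Y[i]
            wi, wj = _winner_flat(W, x)
            if record_winners is not None:
                record_winners.append((wi, wj))
            eta = cfg.eta_max + (cfg.eta_min - cfg.eta_max) * (t / (total - 1)) if total > 1 else cfg.eta_max
            radius = r_max * (1.0 - t / total)
            dx = _grid_distance_row(nx, wi, toroidal)
            dy = _grid_distance_row(ny, wj, toroidal)
            if cfg.grid_metric == "chebyshev":
                d = np.maximum(dx[:, None], dy[None, :])
            else:
                d = dx[:, None] + dy[None, :]
            h = _neighborhood_factor(d, radius, cfg.neighborhood)
            f = (eta * h)[:, :, None]
            W += f * (x - W)
            O += f * (y - O)
            t += 1
        if epoch_callback is not None:
            epoch_callback(model, epoch)
    model.trained = True
    return model


def decode_output(out: np.ndarray, encoding: str, classes: np.ndarray | None = None):
    """Class decoding: 1.5-midpoint rule for numeric 1/2 coding, argmax for one-hot."""
    if encoding == "numeric_class":
        return 2 if float(out[0]) >= 1.5 else 1
    idx = int(np.argmax(out))
    return classes[idx] if classes is not None else idx


def predict(model: CPANNModel, x: np.ndarray) -> tuple[NeuronPosition, np.ndarray, object]:
    """Winner position, output weights there, decoded class label."""
    pos = find_winner(model, x)
    out = model.output_weights[pos.ix - 1, pos.iy - 1].copy()
    label = decode_output(out, model.config.output_encoding, model.classes)
    return pos, out, label


def save_model(model: CPANNModel, path: str | Path) -> None:
    """Serialize to an .npz container with the config embedded as JSON."""
    meta = {
        "config": asdict(model.config),
        "column_names": model.column_names,
        "trained": model.trained,
    }
    arrays = {
        "kohonen_weights": model.kohonen_weights,
        "output_weights": model.output_weights,
    }
    if model.classes is not None:
        arrays["classes"] = np.asarray(model.classes)
    if model.norm is not None:
        arrays["norm_mins"] = model.norm.mins
        arrays["norm_maxs"] = model.norm.maxs
        meta["norm_columns"] = model.norm.column_names
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> CPANNModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        norm = None
        if "norm_mins" in data:
            norm = NormalizationParams(
                mins=data["norm_mins"],
                maxs=data["norm_maxs"],
                column_names=meta.get("norm_columns") or [],
            )
        return CPANNModel(
            kohonen_weights=data["kohonen_weights"],
            output_weights=data["output_weights"],
            config=TrainingConfig(**meta["config"]),
            norm=norm,
            column_names=meta.get("column_names"),
            classes=data["classes"] if "classes" in data else None,
            trained=meta.get("trained", False),
        )


class CPANNClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style counter-propagation network classifier.

    Expects features already scaled to [0, 1] (compose with
    :class:`cpqsar.scaling.MinMaxClipScaler` in a Pipeline).  With
    ``output_encoding="numeric_class"`` the targets must be the 1/2
    carcinogenicity coding; ``"one_hot"`` accepts any integer labels (the
    structural-alert groups 1..10 in the SA model variant).
    """

    def __init__(
        self,
        nx: int = 35,
        ny: int = 35,
        epochs: int = 200,
        eta_max: float = 0.5,
        eta_min: float = 0.01,
        topology: str = "planar",
        neighborhood: str = "triangular",
        grid_metric: str = "chebyshev",
        output_encoding: str = "numeric_class",
        shuffle: bool = False,
        random_state: int = 0,
    ):
        self.nx = nx
        self.ny = ny
        self.epochs = epochs
        self.eta_max = eta_max
        self.eta_min = eta_min
        self.topology = topology
        self.neighborhood = neighborhood
        self.grid_metric = grid_metric
        self.output_encoding = output_encoding
        self.shuffle = shuffle
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            nx=self.nx,
            ny=self.ny,
            epochs=self.epochs,
            eta_max=self.eta_max,
            eta_min=self.eta_min,
            topology=self.topology,
            neighborhood=self.neighborhood,
            grid_metric=self.grid_metric,
            seed=self.random_state,
            output_encoding=self.output_encoding,
            shuffle=self.shuffle,
        )

    def fit(self, X, y, epoch_callback=None):
        X, y = validate_data(self, X, y, dtype=float, ensure_all_finite=True)
        self.classes_ = np.unique(y)
        cfg = self._config()
        if cfg.output_encoding == "numeric_class":
            if not set(self.classes_).issubset({1, 2}):
                raise ValueError(
                    "numeric_class encoding expects labels in {1, 2} "
                    "(1 = non-carcinogen, 2 = carcinogen)"
                )
            Y = np.asarray(y, dtype=float)[:, None]
        else:
            idx = np.searchsorted(self.classes_, y)
            Y = np.zeros((len(y), len(self.classes_)))
            Y[np.arange(len(y)), idx] = 1.0
        model = initialize(cfg, p=X.shape[1], r=Y.shape[1])
        model.classes = self.classes_
        train(model, X, Y, epoch_callback=epoch_callback)
        self.model_ = model
        self.kohonen_weights_ = model.kohonen_weights
        self.output_weights_ = model.output_weights
        return self

    def winners(self, X) -> np.ndarray:
        """(n, 2) array of 1-based winning-neuron coordinates."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return np.array([find_winner(self.model_, x) for x in X], dtype=int)

    def predict_output(self, X) -> np.ndarray:
        """Raw output-layer vectors at the winning neurons."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        pos = self.winners(X)
        return self.output_weights_[pos[:, 0] - 1, pos[:, 1] - 1]

    def predict(self, X):
        out = self.predict_output(X)
        enc = self.output_encoding
        return np.array([decode_output(o, enc, self.classes_) for o in out])

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.positive_only = True
        return tags
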