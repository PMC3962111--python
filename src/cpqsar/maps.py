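"""Kohonen-map analytics: the interpretability layer of a trained CP ANN.

A trained model is read through 2-D views of its weight tensors:

- the *top map* — which objects occupy which neurons;
- *weight-level maps* — one grid slice per descriptor, showing where that
  descriptor takes high or low values;
- the *class surface* — the decoded class at every neuron of the output
  layer;
- *influential zones* — the grid region where a weight level takes its
  largest values, operationalized as a quantile threshold;
- *SA-group maps* — output-weight levels of the structural-alert-group
  model variant;
- carcinogen / non-carcinogen separation within one alert family.

All map functions are pure views: they never mutate the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cpann import CPANNClassifier, CPANNModel, decode_output

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapLayer:
    """An nx x ny scalar field over the neuron grid."""

    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("a map layer is a 2-D field")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class InfluentialZone:
    """Set of 1-based neuron positions where a layer is largest."""

    positions: frozenset[tuple[int, int]]
    source_label: str
    threshold: float


@dataclass
class TopMap:
    counts: np.ndarray
    assignments: dict[tuple[int, int], list[str]] = field(default_factory=dict)


@dataclass
class SeparationReport:
    """P/NP occupancy inside one alert family (see
    :func:`class_separation_within_alert`)."""

    alert_id: str
    occupancy: dict[tuple[int, int], tuple[int, int]]  # position -> (P, NP)
    purity: float
    jaccard: float
    n_molecules: int


def _unwrap(model: CPANNModel | CPANNClassifier) -> CPANNModel:
    return model.model_ if isinstance(model, CPANNClassifier) else model


def top_map(model, X: np.ndarray, ids: list[str] | None = None) -> TopMap:
    """Occupancy counts plus the per-neuron listing of object ids."""
    m = _unwrap(model)
    X = np.asarray(X, dtype=float)
    ids = ids if ids is not None else [str(i) for i in range(len(X))]
    counts = np.zeros((m.config.nx, m.config.ny), dtype=int)
    assignments: dict[tuple[int, int], list[str]] = {}
    from .cpann import find_winner  # local import avoids cycle at module load

    for x, rid in zip(X, ids):
        pos = find_winner(m, x)
        counts[pos.ix - 1, pos.iy - 1] += 1
        assignments.setdefault((pos.ix, pos.iy), []).append(rid)
    return TopMap(counts=counts, assignments=assignments)


def weight_level_map(model, level: int | str) -> MapLayer:
    """The Kohonen weight slice for one descriptor (by name or 0-based index)."""
    m = _unwrap(model)
    if isinstance(level, str):
        if not m.column_names or level not in m.column_names:
            raise KeyError(f"unknown weight level {level!r}")
        idx = m.column_names.index(level)
        label = level
    else:
        idx = level
        if not 0 <= idx < m.n_levels:
            raise KeyError(f"weight level index {idx} out of range")
        label = m.column_names[idx] if m.column_names else f"level_{idx}"
    return MapLayer(values=m.kohonen_weights[:, :, idx].copy(), label=label)


def class_surface(model) -> MapLayer:
    """Decoded class at every neuron of the output layer."""
    m = _unwrap(model)
    nx, ny = m.config.nx, m.config.ny
    surface = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            surface[i, j] = decode_output(
                m.output_weights[i, j], m.config.output_encoding, m.classes
            )
    return MapLayer(values=surface, label="class")


def influential_zone(layer: MapLayer, quantile: float = 0.9) -> InfluentialZone:
    """Neurons whose value reaches the given quantile of the layer's values.

    A constant layer has no "largest values": the zone is empty (warned).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    v = layer.values
    if v.max() == v.min():
        logger.warning("constant layer %r: influential zone is empty", layer.label)
        return InfluentialZone(frozenset(), layer.label, float(v.max()))
    threshold = float(np.quantile(v, quantile))
    ii, jj = np.where(v >= threshold)
    positions = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))
    return InfluentialZone(positions, layer.label, threshold)


def zone_overlap(z1: InfluentialZone, z2: InfluentialZone) -> float:
    """Jaccard similarity of two zones: |intersection| / |union| in [0, 1]."""
    a, b = z1.positions, z2.positions
    union = a | b
    if not union:
        logger.warning("both zones empty; overlap defined as 0")
        return 0.0
    return len(a & b) / len(union)


def sa_group_map(model, group: int) -> MapLayer:
    """Output-weight level of one structural-alert group (one-hot SA model)."""
    m = _unwrap(model)
    if m.config.output_encoding != "one_hot":
        raise ValueError("SA-group maps require a one_hot output encoding")
    if m.classes is None:
        raise ValueError("model has no class labels recorded")
    classes = list(np.asarray(m.classes))
    if group not in classes:
        raise KeyError(f"unknown group {group}; model groups: {classes}")
    idx = classes.index(group)
    return MapLayer(values=m.output_weights[:, :, idx].copy(), label=f"group_{group}")


def class_separation_within_alert(
    model,
    X: np.ndarray,
    ids: list[str],
    annotations: dict[str, set[str]],
    labels: dict[str, int],
    alert_id: str,
) -> SeparationReport:
    """How carcinogens (P, class 2) and non-carcinogens (NP, class 1) separate
    on the map within the family of chemicals matching one alert.

    Reports per-neuron (P, NP) occupancy, the fraction of occupied neurons
    holding a single class (purity) and the Jaccard overlap of the
    P-occupied and NP-occupied neuron sets.
    """
    m = _unwrap(model)
    from .cpann import find_winner

    occupancy: dict[tuple[int, int], list[int]] = {}
    n_mol = 0
    for x, rid in zip(np.asarray(X, dtype=float), ids):
        if alert_id not in annotations.get(rid, set()):
            continue
        label = labels.get(rid)
        if label not in (1, 2):
            continue
        n_mol += 1
        pos = find_winner(m, x)
        cell = occupancy.setdefault((pos.ix, pos.iy), [0, 0])
        cell[0 if label == 2 else 1] += 1
    if not occupancy:
        return SeparationReport(alert_id, {}, purity=0.0, jaccard=0.0, n_molecules=0)
    pure = sum(1 for p, np_ in occupancy.values() if p == 0 or np_ == 0)
    p_zone = {pos for pos, (p, _) in occupancy.items() if p > 0}
    np_zone = {pos for pos, (_, np_) in occupancy.items() if np_ > 0}
    union = p_zone | np_zone
    jac = len(p_zone & np_zone) / len(union) if union else 0.0
    return SeparationReport(
        alert_id=alert_id,
        occupancy={k: (v[0], v[1]) for k, v in occupancy.items()},
        purity=pure / len(occupancy),
        jaccard=jac,
        n_molecules=n_mol,
    )


def count_contiguous_clusters(positions: set[tuple[int, int]]) -> int:
    """Number of 4-connected components of a neuron set (1-based positions)."""
    remaining = set(positions)
    clusters = 0
    while remaining:
        clusters += 1
        stack = [remaining.pop()]
        while stack:
            i, j = stack.pop()
            for ni, nj in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)):
                if (ni, nj) in remaining:
                    remaining.remove((ni, nj))
                    stack.append((ni, nj))
    return clusters


def layer_to_csv(layer: MapLayer, path: str | Path) -> None:
    np.savetxt(path, layer.values, delimiter=",", fmt="%.6g")


def layer_to_png(layer: MapLayer, path: str | Path) -> None:
    """Render with the conventional SOM colouring: red/yellow high, dark blue low."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(layer.values.T, origin="lower", cmap="jet", aspect="equal")
    ax.set_title(layer.label)
    ax.set_xlabel("n_x")
    ax.set_ylabel("n_y")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
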