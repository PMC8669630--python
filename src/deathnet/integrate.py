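"""Convex aggregation of relation layers into one weight matrix.

The sixteen relation layers are combined as M = sum_l w_l * A_l with
non-negative weights summing to one, so every off-diagonal entry is a
weighted mean of the per-layer adjacencies.  Diagonal entries mark node
presence only and are zeroed again before any spectral computation.

Degree summaries follow Tukey boxplot conventions (median, quartiles by
linear interpolation, whiskers at 1.5x the interquartile range) so the
numbers behind a per-layer degree boxplot can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ContractError
from .netio import MultilayerNetwork, canon

__all__ = [
    "LayerWeights",
    "WeightMatrix",
    "DegreeSummary",
    "uniform_weights",
    "density_weights",
    "aggregate_layers",
    "degree_summary",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class LayerWeights:
    """Convex weight per relation label: w_l >= 0, sum_l w_l = 1."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        for lab, v in self.w.items():
            if v < 0:
                raise ContractError(f"negative layer weight for {lab!r}: {v}")
        total = sum(self.w.values())
        if self.w and abs(total - 1.0) > _SUM_TOL:
            raise ContractError(f"layer weights sum to {total!r}, expected 1")

    def __getitem__(self, label: str) -> float:
        return self.w[label]


def uniform_weights(net: MultilayerNetwork) -> LayerWeights:
    """w_l = 1/L over the network's layers."""
    labels = net.layer_labels()
    if not labels:
        raise ContractError("network has no layers")
    return LayerWeights({lab: 1.0 / len(labels) for lab in labels})


def density_weights(net: MultilayerNetwork) -> LayerWeights:
    """w_l proportional to 1/|edges_l|, so sparse layers count more.

    A layer with zero edges gets weight 0 before renormalization.
    """
    labels = net.layer_labels()
    if not labels:
        raise ContractError("network has no layers")
    inv = {lab: (1.0 / net.n_edges(lab) if net.n_edges(lab) else 0.0) for lab in labels}
    total = sum(inv.values())
    if total == 0:
        raise ContractError("all layers are empty; density weights undefined")
    return LayerWeights({lab: v / total for lab, v in inv.items()})


@dataclass
class WeightMatrix:
    """Aggregated symmetric gene-gene weight matrix.

    ``genes`` is the canonical sorted symbol order indexing ``M``; the
    diagonal holds node-presence indicators (1 for every present gene) and
    is bookkeeping only.  ``isolated`` lists genes with zero degree in all
    layers.
    """

    genes: list[str]
    M: np.ndarray
    isolated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.M.shape != (n, n):
            raise ContractError(f"matrix shape {self.M.shape} != ({n}, {n})")

    def index(self, symbol: str) -> int:
        return self._idx[canon(symbol)]

    @property
    def _idx(self) -> dict[str, int]:
        return {canon(g): i for i, g in enumerate(self.genes)}

    def offdiag(self) -> np.ndarray:
        """Copy of M with the bookkeeping diagonal zeroed."""
        A = self.M.copy()
        np.fill_diagonal(A, 0.0)
        return A


def aggregate_layers(net: MultilayerNetwork, weights: LayerWeights) -> WeightMatrix:
    """M_ij = sum_l w_l * A_l,ij for i != j; diagonal = node presence.

    Every layer of the network must carry a weight; genes untouched by any
    edge are flagged isolated.
    """
    labels = net.layer_labels()
    missing = [lab for lab in labels if lab not in weights.w]
    if missing:
        raise ContractError(f"weights missing layers: {missing}")
    symbols = net.gene_symbols
    n = len(symbols)
    idx = {canon(s): i for i, s in enumerate(symbols)}
    M = np.zeros((n, n))
    for lab in labels:
        w = weights[lab]
        if w == 0:
            continue
        for e in net.edges(lab):
            i, j = idx[canon(e.a)], idx[canon(e.b)]
            M[i, j] += w * e.weight
            M[j, i] += w * e.weight
    isolated = [symbols[i] for i in range(n) if not M[i].any()]
    np.fill_diagonal(M, 1.0)
    return WeightMatrix(genes=symbols, M=M, isolated=isolated)


@dataclass
class DegreeSummary:
    """Tukey boxplot statistics of a degree distribution."""

    scope: str
    degrees: dict[str, int]
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[str]


def degree_summary(net: MultilayerNetwork, scope: Optional[str] = None) -> DegreeSummary:
    """Degree distribution of one layer, or of the aggregate when scope is None.

    Degree is the unweighted count of incident edges; in the aggregate it is
    the number of distinct neighbours across layers, so it is never below
    any single-layer degree.  Whisker bounds are q1 - 1.5*IQR and
    q3 + 1.5*IQR; outlier genes are exactly the degrees outside them.
    """
    degs: dict[str, int] = {}
    if scope is None:
        for g in net.gene_symbols:
            degs[g] = len(net.neighbors(g))
        label = "aggregate"
    else:
        if scope not in net.layer_labels():
            raise ContractError(f"no layer {scope!r} in network")
        counts: dict[str, int] = {}
        for e in net.edges(scope):
            for s in (e.a, e.b):
                counts[canon(s)] = counts.get(canon(s), 0) + 1
        degs = {g: counts.get(canon(g), 0) for g in net.gene_symbols if canon(g) in counts}
        label = scope
    if not degs:
        raise ContractError("no degrees to summarize")
    vals = np.array(sorted(degs.values()), dtype=float)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted(g for g, d in degs.items() if d < lo or d > hi)
    return DegreeSummary(
        scope=label,
        degrees=degs,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(lo),
        whisker_high=float(hi),
        outliers=outliers,
    )
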