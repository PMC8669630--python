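"""Crosstalk statistics between two cell-death-mode networks.

Two modes talk to each other where their subnetwork modules share genes,
where reference edges bridge a module of one mode to a module of the
other, or where the modules' pathway-annotation profiles coincide.  The
headline statistic is the hypergeometric overlap tail on shared genes —
the same functional form and score scale (-log10 p, threshold 4) as the
enrichment score — computed over the union of the two mode networks'
genes by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .enrich import AnnotationMatrix, DEFAULT_THRESHOLD, network_score, passes_threshold
from .errors import ContractError
from .modules import ModulePartition
from .netio import MultilayerNetwork, canon

__all__ = [
    "CrosstalkRecord",
    "crosstalk_score",
    "crosstalk_table",
    "crosstalk_genes",
    "crosstalk_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class CrosstalkRecord:
    """Overlap statistics for one (module of mode A, module of mode B) pair."""

    mode_a: str
    module_a: int
    mode_b: str
    module_b: int
    shared_genes: set[str]
    n_shared: int
    bridging_edges: int
    p_value: float
    score: float
    term_profile_similarity: Optional[float]
    passed: bool


def crosstalk_score(
    module_a: Iterable[str], module_b: Iterable[str], universe: int
) -> tuple[float, float]:
    """Hypergeometric P(overlap >= f) for two gene modules in a universe.

    Symmetric in its module arguments.  An empty module gives p = 1,
    score = 0 with a warning.
    """
    a = {canon(g) for g in module_a}
    b = {canon(g) for g in module_b}
    if not a or not b:
        warnings.warn("empty module in crosstalk_score; p = 1", stacklevel=2)
        return 1.0, 0.0
    if universe < len(a | b):
        raise ContractError(
            f"universe {universe} smaller than |a union b| = {len(a | b)}"
        )
    f = len(a & b)
    p, score = network_score(universe, len(a), len(b), f)
    return p, score


def _bridging(
    reference: MultilayerNetwork, a: set[str], b: set[str]
) -> int:
    """Reference edges with one endpoint in a and the other in b."""
    n = 0
    for x, y in reference.edge_pairs():
        if (x in a and y in b) or (x in b and y in a):
            n += 1
    return n


def crosstalk_table(
    partition_a: ModulePartition,
    partition_b: ModulePartition,
    reference: Optional[MultilayerNetwork] = None,
    annotation: Optional[AnnotationMatrix] = None,
    threshold: float = DEFAULT_THRESHOLD,
    universe: Optional[int] = None,
    mode_a: Optional[str] = None,
    mode_b: Optional[str] = None,
) -> list[CrosstalkRecord]:
    """Score every module pair of two mode partitions.

    One record per pair with shared genes or bridging reference edges,
    sorted by score descending (ties: smaller p, then module ids).  The
    gene universe defaults to the union of the two partitions' genes and
    can be widened to a knowledge-base-wide count.  Partitions over
    disjoint gene universes are rejected.
    """
    mode_a = mode_a or partition_a.mode or "mode_a"
    mode_b = mode_b or partition_b.mode or "mode_b"
    genes_a = {canon(g) for g in partition_a.universe()}
    genes_b = {canon(g) for g in partition_b.universe()}
    if not genes_a & genes_b:
        raise ContractError("partitions share no genes; crosstalk undefined")
    U = universe if universe is not None else len(genes_a | genes_b)
    mods_a = {m: {canon(g) for g in gs} for m, gs in partition_a.modules().items()}
    mods_b = {m: {canon(g) for g in gs} for m, gs in partition_b.modules().items()}
    records: list[CrosstalkRecord] = []
    for ma, ga in sorted(mods_a.items()):
        for mb, gb in sorted(mods_b.items()):
            shared = ga & gb
            bridges = _bridging(reference, ga, gb) if reference is not None else 0
            if not shared and bridges == 0:
                continue
            p, score = crosstalk_score(ga, gb, U) if ga and gb else (1.0, 0.0)
            sim = None
            if annotation is not None:
                pa = annotation.profile_of_genes(ga)
                pb = annotation.profile_of_genes(gb)
                union = int(((pa + pb) > 0).sum())
                inter = int(((pa * pb) > 0).sum())
                sim = inter / union if union else 0.0
            records.append(
                CrosstalkRecord(
                    mode_a=mode_a,
                    module_a=ma,
                    mode_b=mode_b,
                    module_b=mb,
                    shared_genes={g for g in shared},
                    n_shared=len(shared),
                    bridging_edges=bridges,
                    p_value=p,
                    score=score,
                    term_profile_similarity=sim,
                    passed=passes_threshold(p, threshold),
                )
            )
    records.sort(key=lambda r: (-r.score, r.p_value, r.module_a, r.module_b))
    return records


def crosstalk_genes(
    networks: list[tuple[str, MultilayerNetwork]],
) -> pd.DataFrame:
    """Genes present in two or more cell-death-mode networks.

    Rows sorted by the number of containing modes (descending), then by
    symbol; the hallmark flag is carried through (true if any mode's node
    marks it).
    """
    if len(networks) < 2:
        raise ContractError("need >= 2 mode networks")
    presence: dict[str, set[str]] = {}
    hallmark: dict[str, bool] = {}
    display: dict[str, str] = {}
    for mode, net in networks:
        for g in net.genes:
            k = canon(g.symbol)
            presence.setdefault(k, set()).add(mode)
            hallmark[k] = hallmark.get(k, False) or g.hallmark
            display.setdefault(k, g.symbol)
    rows = [
        {
            "gene": display[k],
            "modes": ";".join(sorted(ms)),
            "n_modes": len(ms),
            "hallmark": hallmark[k],
        }
        for k, ms in presence.items()
        if len(ms) >= 2
    ]
    rows.sort(key=lambda r: (-r["n_modes"], r["gene"]))
    return pd.DataFrame(rows, columns=["gene", "modes", "n_modes", "hallmark"])


def crosstalk_to_frame(records: Iterable[CrosstalkRecord]) -> pd.DataFrame:
    rows = [
        {
            "mode_a": r.mode_a,
            "module_a": r.module_a,
            "mode_b": r.mode_b,
            "module_b": r.module_b,
            "n_shared": r.n_shared,
            "bridging_edges": r.bridging_edges,
            "p_value": r.p_value,
            "score": r.score,
            "jaccard_terms": r.term_profile_similarity,
            "passed": r.passed,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mode_a",
            "module_a",
            "mode_b",
            "module_b",
            "n_shared",
            "bridging_edges",
            "p_value",
            "score",
            "jaccard_terms",
            "passed",
        ],
    )
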