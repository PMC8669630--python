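"""Seeded generators of synthetic multilayer networks and gene sets.

The generators emulate the shape of a curated cell-death knowledge base at
desk scale: a planted-partition (stochastic block model) gene network whose
base edges are copied into typed relation layers, pathway gene sets with
known enrichment planted on the true modules, and paired mode networks
sharing one module for crosstalk experiments.  The planted ground truth is
the oracle every detection module is tested against.

Defaults define the standard study conditions: 600 genes in 27 equal
modules with within-module edge probability 0.2 and between-module 0.005,
four relation layers led by a fully retained protein-binding layer, and
gene sets carrying 80% module genes plus 20% background.

All randomness flows from one seed, split into named substreams (edges,
layers, sets, shared) so adding a generator never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .errors import ContractError
from .modules import ModulePartition
from .netio import GeneSetCollection, MultilayerNetwork, TypedEdge, canon

__all__ = [
    "SynthConfig",
    "simulate_multilayer",
    "simulate_genesets",
    "simulate_crosstalk_pair",
    "adjusted_rand",
]

#: Relation layers of the default fixture: (label, edge retention probability).
#: Protein-protein binding dominates curated interactomes, so it retains
#: every base edge; causal layers are sparser copies.
DEFAULT_LAYER_SPECS: tuple[tuple[str, float], ...] = (
    ("PP", 1.0),
    ("A", 0.6),
    ("E", 0.5),
    ("P", 0.3),
)

_SUBSTREAMS = ("edges", "layers", "sets", "shared")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study conditions."""

    n_genes: int = 600
    k_true: int = 27
    p_in: float = 0.2
    p_out: float = 0.005
    layer_specs: tuple[tuple[str, float], ...] = DEFAULT_LAYER_SPECS
    shared_module_size: int = 20
    n_sets: int = 40
    n_enriched: Optional[int] = None  # default: one per module, capped by n_sets
    enriched_fraction: float = 0.8
    background_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ContractError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.k_true < 1:
            raise ContractError("k_true must be >= 1")
        if self.k_true > self.n_genes:
            raise ContractError(f"k_true={self.k_true} exceeds n_genes={self.n_genes}")
        for lab, r in self.layer_specs:
            if not (0 < r <= 1):
                raise ContractError(f"retention for layer {lab!r} must be in (0, 1], got {r}")
        for name in ("enriched_fraction", "background_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ContractError(f"{name} must be in [0, 1], got {v}")
        if self.background_fraction >= 1:
            raise ContractError("background_fraction must be < 1")

    def rng(self, substream: str) -> np.random.Generator:
        if substream not in _SUBSTREAMS:
            raise ContractError(f"unknown substream {substream!r}")
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_SUBSTREAMS))
        return np.random.default_rng(children[_SUBSTREAMS.index(substream)])


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _block_labels(n: int, k: int, sizes: Optional[Sequence[int]] = None) -> np.ndarray:
    """Equal module sizes; the remainder goes round-robin to the first modules."""
    if sizes is not None:
        if sum(sizes) != n or len(sizes) != k:
            raise ContractError("explicit size vector must sum to n with k entries")
        out = np.concatenate([np.full(sz, i + 1) for i, sz in enumerate(sizes)])
        return out
    base = n // k
    rem = n % k
    sizes_eq = [base + (1 if i < rem else 0) for i in range(k)]
    return np.concatenate([np.full(sz, i + 1) for i, sz in enumerate(sizes_eq)])


def _sample_base_edges(
    labels: np.ndarray, p_in: float, p_out: float, rng: np.random.Generator
) -> np.ndarray:
    """Upper-triangular pair indices of the planted-partition base graph."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    prob = np.where(labels[iu[0]] == labels[iu[1]], p_in, p_out)
    keep = rng.random(prob.shape) < prob
    return np.stack([iu[0][keep], iu[1][keep]], axis=1)


def simulate_multilayer(
    cfg: SynthConfig, mode: Optional[str] = None, gene_prefix: str = "G"
) -> tuple[MultilayerNetwork, ModulePartition]:
    """Planted-partition multilayer network plus its ground-truth partition.

    Each base edge is copied independently into every layer with that
    layer's retention probability (a base edge retained by no layer is
    absent from the network).  Same seed, same output, byte for byte.
    """
    names = _gene_names(cfg.n_genes, gene_prefix)
    labels = _block_labels(cfg.n_genes, cfg.k_true)
    base = _sample_base_edges(labels, cfg.p_in, cfg.p_out, cfg.rng("edges"))
    rng_layers = cfg.rng("layers")
    net = MultilayerNetwork(mode=mode)
    for g in names:
        net.add_gene(g)
    for lab, retention in cfg.layer_specs:
        keep = rng_layers.random(len(base)) < retention
        for i, j in base[keep]:
            net.add_edge(TypedEdge(a=names[i], b=names[j], relation=lab))
    truth = ModulePartition(
        assignment={names[i]: int(labels[i]) for i in range(cfg.n_genes)},
        k=cfg.k_true,
        mode=mode,
    )
    return net, truth


def simulate_genesets(
    truth: ModulePartition, cfg: SynthConfig
) -> tuple[GeneSetCollection, list[tuple[int, str]]]:
    """Gene sets with enrichment planted on true modules.

    Each planted set takes ``enriched_fraction`` of one module's genes and
    pads with background genes from outside the module so that the
    background makes up ``background_fraction`` of the set.  Remaining sets
    are uniform draws from the whole gene universe.  Returns the collection
    and the planted (module id, set name) pairs.
    """
    rng = cfg.rng("sets")
    universe = sorted(truth.universe())
    mods = truth.modules()
    n_enriched = cfg.n_enriched
    if n_enriched is None:
        n_enriched = min(truth.k, cfg.n_sets)
    if n_enriched > cfg.n_sets:
        raise ContractError(f"n_enriched={n_enriched} exceeds n_sets={cfg.n_sets}")
    coll = GeneSetCollection()
    planted: list[tuple[int, str]] = []
    module_ids = sorted(mods)
    typical = max(2, int(round(np.mean([len(mods[m]) for m in module_ids]))))
    for idx in range(n_enriched):
        m = module_ids[idx % len(module_ids)]
        members = sorted(mods[m])
        n_core = max(1, int(round(cfg.enriched_fraction * len(members))))
        core = list(rng.choice(members, size=n_core, replace=False))
        total = int(round(n_core / (1.0 - cfg.background_fraction)))
        n_bg = max(0, total - n_core)
        outside = sorted(set(universe) - set(members))
        bg = list(rng.choice(outside, size=min(n_bg, len(outside)), replace=False))
        name = f"SET_P{idx + 1:03d}"
        coll.add(name, f"planted on module {m}", core + bg)
        planted.append((m, name))
    for idx in range(cfg.n_sets - n_enriched):
        size = int(rng.integers(max(2, typical // 2), 2 * typical))
        genes = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        coll.add(f"SET_R{idx + 1:03d}", "random background set", genes)
    return coll, planted


def simulate_crosstalk_pair(
    cfg: SynthConfig,
    n_per_mode: int = 150,
    k_per_mode: int = 6,
    p_in: float = 0.3,
    p_out: float = 0.01,
) -> tuple[
    tuple[MultilayerNetwork, ModulePartition],
    tuple[MultilayerNetwork, ModulePartition],
]:
    """Two mode networks sharing one planted module of shared_module_size.

    Module 1 of each mode consists of the same shared genes; all other
    genes are private to their mode.  Both networks are planted-partition
    graphs over their own genes with the given densities and cfg's layer
    specs.
    """
    if cfg.shared_module_size > n_per_mode // 2:
        raise ContractError("shared module too large for the per-mode size")
    rng = cfg.rng("shared")
    shared = _gene_names(cfg.shared_module_size, prefix="X")
    nets = []
    for tag in ("A", "B"):
        n_priv = n_per_mode - cfg.shared_module_size
        priv = _gene_names(n_priv, prefix=tag)
        names = shared + priv
        sizes = [cfg.shared_module_size] + _equal_sizes(n_priv, k_per_mode - 1)
        labels = _block_labels(n_per_mode, k_per_mode, sizes=sizes)
        sub_rng = np.random.default_rng(rng.integers(2**31))
        base = _sample_base_edges(labels, p_in, p_out, sub_rng)
        net = MultilayerNetwork(mode=f"mode{tag}")
        for g in names:
            net.add_gene(g)
        for lab, retention in cfg.layer_specs:
            keep = sub_rng.random(len(base)) < retention
            for i, j in base[keep]:
                net.add_edge(TypedEdge(a=names[i], b=names[j], relation=lab))
        truth = ModulePartition(
            assignment={names[i]: int(labels[i]) for i in range(n_per_mode)},
            k=k_per_mode,
            mode=f"mode{tag}",
        )
        nets.append((net, truth))
    return nets[0], nets[1]


def _equal_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def adjusted_rand(a: ModulePartition, b: ModulePartition) -> float:
    """Adjusted Rand index between two partitions of the same gene universe."""
    ca = {canon(g): m for g, m in a.assignment.items()}
    cb = {canon(g): m for g, m in b.assignment.items()}
    if set(ca) != set(cb):
        raise ContractError(
            f"partition universes differ ({len(ca)} vs {len(cb)} genes)"
        )
    order = sorted(ca)
    return float(adjusted_rand_score([ca[g] for g in order], [cb[g] for g in order]))
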