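"""Synthetic-data generators for every pipeline stage.

Three forward models, all pure functions of (config, seed):

* replicate morphometric measurements of a known karyotype
  (Gaussian noise on relative length and centromeric index, mean +/- SD
  over a small number of metaphase plates);
* karyotype evolution along a tree (Poisson numbers of shape-flip
  inversions and pair-fusion translocations per edge) with the full
  ground-truth event record;
* Jukes-Cantor sequence evolution along a tree with branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import dendropy
import numpy as np

from .events import (
    INVERSION,
    TRANSLOCATION,
    Event,
    EventScenario,
    name_internal_nodes,
    node_name,
)
from .karyo_io import SHAPE_LABELS, ChromosomePair, Karyotype, parse_tree
from .seqdist import Alignment

__all__ = [
    "SimConfig",
    "REPRESENTATIVE_CI",
    "default_rl_profile",
    "all_metacentric_karyotype",
    "simulate_measurements",
    "simulate_karyotype_evolution",
    "simulate_alignment_jc",
]

#: Centromeric-index band midpoints used when a simulated pair needs a
#: concrete CI value for its shape class.
REPRESENTATIVE_CI = {"M": 43.75, "sM": 31.25, "sT": 18.75, "T": 6.25}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the generators; ``seed`` is mandatory."""

    seed: int
    n_pairs: int = 24
    rl_profile: tuple[float, ...] | None = None
    rl_sd: float = 0.5
    ci_sd: float = 2.0
    n_replicates: int = 5
    inversion_rate: float = 0.0
    translocation_rate: float = 0.0
    n_sites: int = 1000
    subst_rate: float | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.inversion_rate, self.translocation_rate) < 0:
            raise ValueError("event rates must be >= 0")
        if self.rl_sd < 0 or self.ci_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.rl_profile is not None:
            prof = tuple(float(x) for x in self.rl_profile)
            if len(prof) != self.n_pairs:
                raise ValueError("rl_profile length must equal n_pairs")
            if any(a < b for a, b in zip(prof, prof[1:])) or min(prof) <= 0:
                raise ValueError("rl_profile must be positive and non-increasing")
            if abs(sum(prof) - 100.0) > 1.0:
                raise ValueError("rl_profile must sum to 100 within +/- 1")
            object.__setattr__(self, "rl_profile", prof)

    def profile(self) -> tuple[float, ...]:
        if self.rl_profile is not None:
            return self.rl_profile
        return default_rl_profile(self.n_pairs)


def default_rl_profile(n_pairs: int) -> tuple[float, ...]:
    """Linearly decreasing relative lengths summing to 100."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    raw = np.linspace(2.0, 1.0, n_pairs)
    return tuple(100.0 * raw / raw.sum())


def all_metacentric_karyotype(
    taxon_id: str, n_pairs: int, rl_profile=None, ci: float = 43.75
) -> Karyotype:
    """An all-M karyotype (the presumed primitive configuration)."""
    profile = tuple(rl_profile) if rl_profile is not None else default_rl_profile(n_pairs)
    pairs = tuple(
        ChromosomePair(index=i + 1, rl_mean=rl, rl_sd=0.0, ci_mean=ci, ci_sd=0.0, shape="M")
        for i, rl in enumerate(profile)
    )
    return Karyotype(taxon_id=taxon_id, pairs=pairs)


def simulate_measurements(true_karyotype: Karyotype, config: SimConfig) -> Karyotype:
    """Replicate noisy measurements of a karyotype, reported as mean +/- SD.

    For each pair, ``config.n_replicates`` observations of (rl, ci) are
    drawn from Gaussians centred on the true values with scales
    ``config.rl_sd`` / ``config.ci_sd``; per-replicate relative lengths
    are renormalized to sum to 100 and centromeric indices clamped to
    [0, 50] before summarizing.
    """
    rng = np.random.default_rng(config.seed)
    n = true_karyotype.n_pairs
    true_rl = np.array([p.rl_mean for p in true_karyotype.pairs])
    true_ci = np.array([p.ci_mean for p in true_karyotype.pairs])

    rl_obs = rng.normal(true_rl, config.rl_sd, size=(config.n_replicates, n))
    rl_obs = np.clip(rl_obs, 1e-6, None)
    rl_obs = 100.0 * rl_obs / rl_obs.sum(axis=1, keepdims=True)
    ci_obs = np.clip(rng.normal(true_ci, config.ci_sd, size=(config.n_replicates, n)), 0.0, 50.0)

    rl_mean = rl_obs.mean(axis=0)
    rl_mean = 100.0 * rl_mean / rl_mean.sum()
    rl_sd = rl_obs.std(axis=0, ddof=1) if config.n_replicates > 1 else np.zeros(n)
    ci_mean = ci_obs.mean(axis=0)
    ci_sd = ci_obs.std(axis=0, ddof=1) if config.n_replicates > 1 else np.zeros(n)

    pairs = tuple(
        ChromosomePair(
            index=i + 1,
            rl_mean=float(rl_mean[i]),
            rl_sd=float(rl_sd[i]),
            ci_mean=float(ci_mean[i]),
            ci_sd=float(ci_sd[i]),
        )
        for i in range(n)
    )
    return Karyotype(
        taxon_id=f"{true_karyotype.taxon_id}_measured",
        pairs=pairs,
        keep_order=True,
    )


def _apply_fusion(rl: list[float], shapes: list[str], lost: int, survivor: int) -> None:
    """Fuse pair ``lost`` into ``survivor`` (indices into the lists)."""
    rl[survivor] += rl[lost]
    del rl[lost], shapes[lost]


def simulate_karyotype_evolution(
    tree: dendropy.Tree | str, config: SimConfig
) -> tuple[dict[str, Karyotype], EventScenario]:
    """Evolve karyotypes down a tree, recording every event.

    The root is all-metacentric.  On each edge the number of shape-flip
    inversions is Poisson(``inversion_rate``) (uniform position, uniform
    different target class) and the number of fusions is
    Poisson(``translocation_rate``) (a uniform pair is removed and its
    length appended to a uniform survivor).  Returns leaf karyotypes and
    the ground-truth scenario.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(tree, str):
        tree = parse_tree(tree)
    name_internal_nodes(tree)
    leaves = [node_name(n) for n in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")

    root_rl = list(config.profile())
    root_shapes = ["M"] * config.n_pairs

    node_states: dict[str, tuple[str, ...]] = {}
    node_rl: dict[str, list[float]] = {}
    events: list[Event] = []

    for node in tree.preorder_node_iter():
        name = node_name(node)
        if node.parent_node is None:
            rl, shapes = list(root_rl), list(root_shapes)
        else:
            parent = node_name(node.parent_node)
            rl = list(node_rl[parent])
            shapes = list(node_states[parent])
            edge = (parent, name)

            for _ in range(rng.poisson(config.translocation_rate)):
                if len(shapes) <= 2:
                    raise ValueError("fusion would leave fewer than 2 pairs")
                lost = int(rng.integers(len(shapes)))
                survivor = int(rng.integers(len(shapes) - 1))
                if survivor >= lost:
                    survivor += 1
                events.append(
                    Event(
                        TRANSLOCATION,
                        edge,
                        position=lost + 1,
                        from_state=len(shapes),
                        to_state=len(shapes) - 1,
                    )
                )
                _apply_fusion(rl, shapes, lost, survivor)

            for _ in range(rng.poisson(config.inversion_rate)):
                pos = int(rng.integers(len(shapes)))
                old = shapes[pos]
                choices = [s for s in SHAPE_LABELS if s != old]
                new = choices[int(rng.integers(len(choices)))]
                events.append(
                    Event(INVERSION, edge, position=pos + 1, from_state=old, to_state=new)
                )
                shapes[pos] = new

        node_states[name] = tuple(shapes)
        node_rl[name] = rl

    leaf_karyotypes = {}
    for name in leaves:
        rl = np.array(node_rl[name])
        rl = 100.0 * rl / rl.sum()
        pairs = tuple(
            ChromosomePair(
                index=i + 1,
                rl_mean=float(rl[i]),
                rl_sd=config.rl_sd,
                ci_mean=REPRESENTATIVE_CI[s],
                ci_sd=config.ci_sd,
                shape=s,
            )
            for i, s in enumerate(node_states[name])
        )
        leaf_karyotypes[name] = Karyotype(taxon_id=name, pairs=pairs, keep_order=True)

    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    scenario = EventScenario(
        tree_newick=newick,
        node_states=node_states,
        events=tuple(events),
        params={
            "seed": config.seed,
            "inversion_rate": config.inversion_rate,
            "translocation_rate": config.translocation_rate,
            "n_pairs": config.n_pairs,
        },
    )
    return leaf_karyotypes, scenario


def simulate_alignment_jc(tree: dendropy.Tree | str, config: SimConfig) -> Alignment:
    """Jukes-Cantor sequence evolution along a tree.

    Branch lengths are substitutions per site; edges without a length
    fall back to ``config.subst_rate`` (an error if both are missing).
    The root sequence is uniform over {A, C, G, T}.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(tree, str):
        tree = parse_tree(tree)
    name_internal_nodes(tree)

    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        name = node_name(node)
        if node.parent_node is None:
            seqs[name] = rng.integers(0, 4, size=config.n_sites).astype(np.uint8)
            continue
        t = node.edge.length if node.edge.length is not None else config.subst_rate
        if t is None:
            raise ValueError(
                f"edge to {name!r} has no branch length and no subst_rate fallback"
            )
        parent = seqs[node_name(node.parent_node)]
        # JC69: a site changes to each other base with prob (1 - e^{-4t/3})/4
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        child = parent.copy()
        hit = rng.random(config.n_sites) < p_change
        if hit.any():
            shifts = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
            child[hit] = (child[hit] + shifts) % 4
        seqs[name] = child

    ids = tuple(node_name(n) for n in tree.leaf_node_iter())
    sequences = tuple("".join("ACGT"[b] for b in seqs[name]) for name in ids)
    return Alignment(ids, sequences)
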