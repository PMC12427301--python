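"""Uncorrected p-distance, neighbour joining, and bootstrap support.

All three are implemented here rather than delegated to external
phylogenetics software.  p-distance uses pairwise deletion: only sites
where both sequences carry an unambiguous nucleotide (A/C/G/T) are
compared.  Neighbour joining follows the standard Saitou-Nei
agglomeration with explicit, documented tie-breaking (smallest index
pair in the current active-node order) and negative branch lengths
clamped to zero, so results are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "p_distance",
    "p_distance_matrix",
    "nj_tree",
    "tree_splits",
    "bootstrap_support",
]

_UNAMBIGUOUS = frozenset(b"ACGT")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of sequences over {A, C, G, T, -, N, ...}."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("one id per sequence required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(tuple(r.id for r in records), tuple(str(r.seq) for r in records))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.sequences):
                fh.write(f">{name}\n{seq}\n")

    def columns(self, indices: Sequence[int]) -> "Alignment":
        """New alignment from the given column indices (with repetition)."""
        seqs = tuple("".join(s[i] for i in indices) for s in self.sequences)
        return Alignment(self.ids, seqs)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = self.ids.index(key[0]), self.ids.index(key[1])
        return float(self.values[i, j])


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, pairwise-deleting gaps/ambiguities.

    Sites count only when both symbols are in {A, C, G, T}.  When no
    site is comparable the distance is 0 with a warning.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ ({len(a)} vs {len(b)})")
    xa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    ok = np.isin(xa, list(_UNAMBIGUOUS)) & np.isin(xb, list(_UNAMBIGUOUS))
    n = int(ok.sum())
    if n == 0:
        warnings.warn("no comparable sites; p-distance reported as 0", stacklevel=2)
        return 0.0
    return float((xa[ok] != xb[ok]).sum() / n)


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    n = aln.n_sequences
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = p_distance(aln.sequences[i], aln.sequences[j])
    return DistanceMatrix(aln.ids, v)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; returns an unrooted dendropy tree.

    Ties in the Q criterion are broken toward the smallest (i, j) index
    pair in the current active-node order (nodes ordered by creation).
    Negative branch lengths are clamped to 0 with a warning.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")

    tns = dendropy.TaxonNamespace(list(dm.ids))
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    D = dm.values.astype(float).copy()
    active = list(range(n))  # indices into D/nodes, in creation order

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative branch length {x:.6g} clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = smallest (i, j) on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = sub[ai, aj]
        limb_i = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        limb_j = dij - limb_i
        parent = dendropy.Node()
        ei = parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(limb_i)
        ej = parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(limb_j)
        del ei, ej

        new_index = D.shape[0]
        newD = np.zeros((new_index + 1, new_index + 1))
        newD[:new_index, :new_index] = D
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - dij)
            newD[new_index, k] = newD[k, new_index] = dk
        D = newD
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_index]

    # Final three-way join (three-point formulas).
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    center = dendropy.Node()
    for idx, limb in (
        (i, 0.5 * (dij + dik - djk)),
        (j, 0.5 * (dij + djk - dik)),
        (k, 0.5 * (dik + djk - dij)),
    ):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(limb)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, as label frozensets.

    Each split is normalized to the side not containing the
    lexicographically smallest leaf, so rooted and unrooted versions of
    the same topology compare equal.
    """
    leaves = sorted(
        (n.taxon.label if n.taxon else n.label) for n in tree.leaf_node_iter()
    )
    full = set(leaves)
    anchor = leaves[0]
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {
            (n.taxon.label if n.taxon else n.label)
            for n in node.leaf_iter()
        }
        side = full - below if anchor in below else below
        if 2 <= len(side) <= len(full) - 2:
            splits.add(frozenset(side))
    return splits


def bootstrap_support(
    aln: Alignment, replicates: int, seed: int
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree from the full alignment with bootstrap support values.

    Columns are resampled with replacement ``replicates`` times; support
    for each internal split of the full-data tree is the percentage of
    replicate trees containing it.  Supports are written onto the
    internal node labels of the returned tree and also returned as a
    mapping from split to percentage.  Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if aln.n_sites == 0:
        raise ValueError("alignment has no columns")
    rng = np.random.default_rng(seed)

    full_tree = nj_tree(p_distance_matrix(aln))
    target_splits = tree_splits(full_tree)
    counts = {s: 0 for s in target_splits}

    for _ in range(replicates):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = aln.columns(list(cols))
        rep_splits = tree_splits(nj_tree(p_distance_matrix(rep)))
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1

    supports = {s: 100.0 * c / replicates for s, c in counts.items()}

    leaves_all = sorted(aln.ids)
    anchor = leaves_all[0]
    full = set(leaves_all)
    for node in full_tree.preorder_node_iter():
        if node is full_tree.seed_node or node.is_leaf():
            continue
        below = {(n.taxon.label if n.taxon else n.label) for n in node.leaf_iter()}
        side = full - below if anchor in below else below
        key = frozenset(side)
        if key in supports:
            node.label = f"{supports[key]:g}"
    return full_tree, supports
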