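"""Ancestral karyotype reconstruction and rearrangement-event inference.

Two event classes are modeled.  An *inversion* (equivalently a
centromeric shift — both produce the same observable change) flips the
shape class of one pair without touching the diploid number.  A
*translocation* fuses two pairs into one, reducing the pair count by 1
and the diploid number by 2.

Per-position ancestral states come from small parsimony (Sankoff
dynamic programming with a unit cost matrix by default, so polytomies
are handled exactly); ties are broken toward the metacentric end of
the shape order M > sM > sT > T, metacentric being the presumed
primitive state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

from .karyo_io import SHAPE_LABELS, Karyotype, parse_tree

__all__ = [
    "SHAPE_PREFERENCE",
    "Event",
    "EventScenario",
    "fitch_changes",
    "reconstruct_root_majority",
    "infer_edge_events",
    "infer_scenario",
]

#: Tie-break preference order for ancestral states (most median first).
SHAPE_PREFERENCE = SHAPE_LABELS

INVERSION = "inversion"
TRANSLOCATION = "translocation"


@dataclass(frozen=True)
class Event:
    """One rearrangement event on a tree edge.

    ``position`` is the 1-based pair index on the parent side (``None``
    allowed for translocations).  For inversions ``from_state`` and
    ``to_state`` are shape labels; for translocations they are parent
    and child pair counts.
    """

    kind: str
    edge: tuple[str, str]
    position: int | None = None
    from_state: str | int | None = None
    to_state: str | int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (INVERSION, TRANSLOCATION):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == INVERSION:
            if self.position is None:
                raise ValueError("inversion events require a position")
            if self.from_state == self.to_state:
                raise ValueError("inversion must change the shape class")
        else:
            if (
                isinstance(self.from_state, int)
                and isinstance(self.to_state, int)
                and self.from_state - self.to_state != 1
            ):
                raise ValueError("one translocation removes exactly one pair")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "edge": list(self.edge),
            "position": self.position,
            "from_state": self.from_state,
            "to_state": self.to_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(
            kind=d["kind"],
            edge=tuple(d["edge"]),
            position=d["position"],
            from_state=d["from_state"],
            to_state=d["to_state"],
        )


@dataclass
class EventScenario:
    """Per-edge rearrangement events plus the node states they connect."""

    tree_newick: str
    node_states: dict[str, tuple[str, ...]]
    events: tuple[Event, ...] = ()
    params: dict = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        out = {INVERSION: 0, TRANSLOCATION: 0}
        for e in self.events:
            out[e.kind] += 1
        return out

    @property
    def node_pair_counts(self) -> dict[str, int]:
        return {name: len(states) for name, states in self.node_states.items()}

    def events_on_edge(self, parent: str, child: str) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.edge == (parent, child))

    def to_dict(self) -> dict:
        return {
            "tree": self.tree_newick,
            "node_states": {k: list(v) for k, v in self.node_states.items()},
            "node_pair_counts": self.node_pair_counts,
            "events": [e.to_dict() for e in self.events],
            "totals": self.totals,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventScenario":
        return cls(
            tree_newick=d["tree"],
            node_states={k: tuple(v) for k, v in d["node_states"].items()},
            events=tuple(Event.from_dict(e) for e in d["events"]),
            params=dict(d.get("params", {})),
        )


# ---------------------------------------------------------------------------
# Tree plumbing
# ---------------------------------------------------------------------------


def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def name_internal_nodes(tree: dendropy.Tree) -> None:
    """Give unnamed internal nodes deterministic preorder names N1, N2, ..."""
    counter = itertools.count(1)
    taken = {node_name(n) for n in tree if node_name(n)}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node_name(node):
            continue
        name = f"N{next(counter)}"
        while name in taken:
            name = f"N{next(counter)}"
        node.label = name
        taken.add(name)


# ---------------------------------------------------------------------------
# Small parsimony (Sankoff)
# ---------------------------------------------------------------------------


def _unit_cost(a: str, b: str) -> float:
    return 0.0 if a == b else 1.0


def fitch_changes(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, str],
    alphabet: Sequence[str] = SHAPE_PREFERENCE,
    cost=None,
):
    """Minimal change count and one optimal internal labeling.

    Sankoff dynamic programming over ``alphabet`` with a unit cost
    matrix by default (``cost(a, b)`` may override it), so non-binary
    trees are handled exactly.  Ties in the backtrace are broken by
    ``alphabet`` order, i.e. toward M for the default shape alphabet.
    Returns ``(count, labeling)`` where labeling maps node names (leaf
    labels and N1, N2, ... for internal nodes) to states.
    """
    if cost is None:
        cost = _unit_cost
    name_internal_nodes(tree)
    idx = {s: k for k, s in enumerate(alphabet)}
    INF = float("inf")

    table: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node_name(node)
            if name not in leaf_states:
                raise ValueError(f"leaf {name!r} has no state")
            state = leaf_states[name]
            if state not in idx:
                raise ValueError(f"leaf {name!r} has state {state!r} outside the alphabet")
            table[node] = [0.0 if s == state else INF for s in alphabet]
        else:
            vec = [0.0] * len(alphabet)
            for child in node.child_nodes():
                cvec = table[child]
                for k, s in enumerate(alphabet):
                    vec[k] += min(cost(s, t) + cvec[m] for m, t in enumerate(alphabet))
            table[node] = vec

    root = tree.seed_node
    best = min(table[root])
    labeling: dict[str, str] = {}
    assigned: dict[dendropy.Node, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            state = next(s for k, s in enumerate(alphabet) if table[root][k] == best)
        elif node.is_leaf():
            state = leaf_states[node_name(node)]
        else:
            parent_state = assigned[node.parent_node]
            vec = table[node]
            target = min(cost(parent_state, t) + vec[m] for m, t in enumerate(alphabet))
            state = next(
                t
                for m, t in enumerate(alphabet)
                if cost(parent_state, t) + vec[m] == target
            )
        assigned[node] = state
        labeling[node_name(node)] = state
    return int(best), labeling


def reconstruct_root_majority(
    leaf_karyotypes: Sequence[Sequence[str]],
    preference: Sequence[str] = SHAPE_PREFERENCE,
) -> tuple[str, ...]:
    """Per-position modal shape label across aligned karyotypes.

    Ties are broken by ``preference`` order (toward the metacentric,
    presumed primitive, state).
    """
    if not leaf_karyotypes:
        raise ValueError("at least one karyotype is required")
    lengths = {len(v) for v in leaf_karyotypes}
    if len(lengths) != 1:
        raise ValueError(f"karyotypes have unequal pair counts: {sorted(lengths)}")
    out = []
    for states in zip(*leaf_karyotypes):
        tally = {s: states.count(s) for s in set(states)}
        top = max(tally.values())
        out.append(next(s for s in preference if tally.get(s) == top))
    return tuple(out)


# ---------------------------------------------------------------------------
# Event inference
# ---------------------------------------------------------------------------


def infer_edge_events(
    parent_states: Sequence[str],
    child_states: Sequence[str],
    edge: tuple[str, str] = ("parent", "child"),
    mapping=None,
) -> list[Event]:
    """Events turning the parent state vector into the child's.

    Equal pair counts: one inversion per mapped position with differing
    labels.  Parent longer by d: exactly d translocations; the d parent
    positions lost to fusion are chosen (exhaustively, d <= 2) to
    minimize the inversions then needed on the surviving positions,
    ties resolved toward the lexicographically least position set.
    Fissions (child longer) are unsupported.
    """
    np_, nc = len(parent_states), len(child_states)
    if nc > np_:
        raise ValueError(
            f"child has more pairs than parent ({nc} > {np_}); fissions are not modeled"
        )
    d = np_ - nc
    if d == 0:
        if mapping is None:
            pairs = {i: i for i in range(1, np_ + 1)}
        elif hasattr(mapping, "a_to_b"):
            pairs = dict(mapping.a_to_b)
        else:
            pairs = dict(mapping)
        events = []
        for i in sorted(pairs):
            p, c = parent_states[i - 1], child_states[pairs[i] - 1]
            if p != c:
                events.append(Event(INVERSION, edge, position=i, from_state=p, to_state=c))
        return events

    if d > 2:
        raise NotImplementedError(
            f"fusion-position search is exhaustive only for d <= 2 (got d = {d})"
        )
    if mapping is not None:
        raise ValueError("explicit mappings are only supported for equal pair counts")

    best_lost: tuple[int, ...] | None = None
    best_mismatch: list[int] | None = None
    for lost in itertools.combinations(range(np_), d):
        kept = [k for k in range(np_) if k not in lost]
        mism = [k for k, c in zip(kept, range(nc)) if parent_states[k] != child_states[c]]
        if best_mismatch is None or len(mism) < len(best_mismatch):
            best_lost, best_mismatch = lost, mism
    assert best_lost is not None and best_mismatch is not None

    events = [
        Event(
            TRANSLOCATION,
            edge,
            position=pos + 1,
            from_state=np_ - k,
            to_state=np_ - k - 1,
        )
        for k, pos in enumerate(best_lost)
    ]
    kept = [k for k in range(np_) if k not in best_lost]
    for k, c in zip(kept, range(nc)):
        if parent_states[k] != child_states[c]:
            events.append(
                Event(
                    INVERSION,
                    edge,
                    position=k + 1,
                    from_state=parent_states[k],
                    to_state=child_states[c],
                )
            )
    return events


def _leaf_labels(karyotype_or_labels, thresholds) -> tuple[str, ...]:
    from .morphology import classify_karyotype

    if isinstance(karyotype_or_labels, Karyotype):
        k = karyotype_or_labels
        if all(p.shape is not None for p in k.pairs):
            return tuple(p.shape for p in k.pairs)
        return tuple(classify_karyotype(k, thresholds).karyotype.shape_labels)
    return tuple(karyotype_or_labels)


def infer_scenario(
    tree: dendropy.Tree | str,
    leaf_karyotypes: Mapping[str, object],
    thresholds=None,
) -> EventScenario:
    """Full parsimony scenario: ancestral states plus per-edge events.

    ``leaf_karyotypes`` maps each tree leaf label to a
    :class:`~karyoevol.karyo_io.Karyotype` (printed shapes used when
    complete, otherwise classified from the centromeric index) or a
    plain shape-label sequence.  All leaves must share one pair count;
    apply homology maps upstream to align them.
    """
    from .morphology import DEFAULT_THRESHOLDS

    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    if isinstance(tree, str):
        tree = parse_tree(tree)
    name_internal_nodes(tree)

    leaf_names = [node_name(leaf) for leaf in tree.leaf_node_iter()]
    missing = [n for n in leaf_names if n not in leaf_karyotypes]
    if missing:
        raise ValueError(f"no karyotype provided for leaf/leaves: {', '.join(missing)}")

    vectors = {n: _leaf_labels(leaf_karyotypes[n], thresholds) for n in leaf_names}
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"leaf karyotypes have unequal pair counts {sorted(lengths)}; "
            "align them with homology maps first"
        )
    n_pairs = lengths.pop()

    node_states: dict[str, list[str]] = {
        node_name(node): [] for node in tree.preorder_node_iter()
    }
    for pos in range(n_pairs):
        leaf_states = {name: vectors[name][pos] for name in leaf_names}
        _, labeling = fitch_changes(tree, leaf_states)
        for name, state in labeling.items():
            node_states[name].append(state)

    events: list[Event] = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edge = (node_name(node), node_name(child))
            events.extend(
                infer_edge_events(node_states[edge[0]], node_states[edge[1]], edge)
            )

    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return EventScenario(
        tree_newick=newick,
        node_states={k: tuple(v) for k, v in node_states.items()},
        events=tuple(events),
    )
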