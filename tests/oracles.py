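"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately written from first principles —
enumeration, closed forms, direct elementwise comparison — and shares
no code path with the implementations under test.
"""

from __future__ import annotations

import itertools
import math

TIE_TOL = 1e-9


# --- matching ---------------------------------------------------------------


def oracle_cost(p, q, sd_floor=0.1):
    """Squared z-distance, written independently of the package."""
    srl = math.sqrt(max(p.rl_sd, sd_floor) ** 2 + max(q.rl_sd, sd_floor) ** 2)
    sci = math.sqrt(max(p.ci_sd, sd_floor) ** 2 + max(q.ci_sd, sd_floor) ** 2)
    return ((p.rl_mean - q.rl_mean) / srl) ** 2 + ((p.ci_mean - q.ci_mean) / sci) ** 2


def _oracle_shape(p):
    """Default-threshold shape call, written out independently."""
    if p.shape is not None:
        return p.shape
    ci = p.ci_mean
    if ci >= 37.5:
        return "M"
    if ci >= 25.0:
        return "sM"
    if ci >= 12.5:
        return "sT"
    return "T"


def oracle_cost_matrix(a, b, window_k=2.0, shape_penalty=1.0, sd_floor=0.1):
    """Window-masked cost matrix; None marks infeasible cells."""
    n = len(a.pairs)
    C = [[None] * n for _ in range(n)]
    for i, p in enumerate(a.pairs):
        for j, q in enumerate(b.pairs):
            if abs(p.rl_mean - q.rl_mean) > window_k * (p.rl_sd + q.rl_sd):
                continue
            c = oracle_cost(p, q, sd_floor)
            if _oracle_shape(p) != _oracle_shape(q):
                c += shape_penalty
            C[i][j] = c
    return C


def brute_force_matching(a, b, window_k=2.0, shape_penalty=1.0, sd_floor=0.1):
    """Exhaustive optimum over all feasible permutations.

    Objective: (total cost, displaced positions, permutation) with the
    cost compared up to TIE_TOL.  Returns (permutation as a tuple of
    0-based column indices, total cost), or None when infeasible.
    """
    C = oracle_cost_matrix(a, b, window_k, shape_penalty, sd_floor)
    n = len(C)
    best = None
    for perm in itertools.permutations(range(n)):
        total = 0.0
        ok = True
        for i, j in enumerate(perm):
            if C[i][j] is None:
                ok = False
                break
            total += C[i][j]
        if not ok:
            continue
        displaced = sum(1 for i, j in enumerate(perm) if i != j)
        if best is None:
            best = (total, displaced, perm)
            continue
        if total < best[0] - TIE_TOL:
            best = (total, displaced, perm)
        elif total <= best[0] + TIE_TOL and (displaced, perm) < (best[1], best[2]):
            best = (min(total, best[0]), displaced, perm)
    if best is None:
        return None
    return best[2], best[0]


def lp_matching_optimum(a, b, window_k=2.0, shape_penalty=1.0, sd_floor=0.1):
    """Exact minimum matching cost via the assignment linear program.

    The LP relaxation of the assignment polytope has integral optima
    (Birkhoff-von Neumann), so solving it with an LP solver (HiGHS
    simplex/IPM) gives the exact optimum by a route entirely different
    from a combinatorial matching algorithm.  Returns the optimal total
    cost, or None when infeasible.
    """
    from scipy.optimize import linprog

    C = oracle_cost_matrix(a, b, window_k, shape_penalty, sd_floor)
    n = len(C)
    edges = [(i, j) for i in range(n) for j in range(n) if C[i][j] is not None]
    costs = [C[i][j] for i, j in edges]
    A_eq = []
    b_eq = []
    for i in range(n):  # each row assigned once
        A_eq.append([1.0 if e[0] == i else 0.0 for e in edges])
        b_eq.append(1.0)
    for j in range(n):  # each column assigned once
        A_eq.append([1.0 if e[1] == j else 0.0 for e in edges])
        b_eq.append(1.0)
    res = linprog(costs, A_eq=A_eq, b_eq=b_eq, bounds=(0, 1), method="highs")
    if not res.success:
        return None
    return float(res.fun)


# --- small parsimony --------------------------------------------------------


def enumerate_parsimony(edges, leaf_states, alphabet):
    """Minimum changes over all internal labelings, by full enumeration.

    ``edges`` is a list of (parent, child) node-name pairs; internal
    nodes are every name appearing as a parent.
    """
    internal = sorted({p for p, _ in edges})
    best = None
    for combo in itertools.product(alphabet, repeat=len(internal)):
        labels = dict(zip(internal, combo))
        labels.update(leaf_states)
        changes = sum(1 for p, c in edges if labels[p] != labels[c])
        if best is None or changes < best:
            best = changes
    return best


# --- trees and distances ----------------------------------------------------


def random_tree_edges(labels, rng, min_len=0.1, max_len=1.0):
    """Random binary topology over labels, built by repeated joins.

    Returns (edges, lengths, root) with edges as (parent, child) names;
    internal nodes are named I0, I1, ...
    """
    nodes = list(labels)
    rng.shuffle(nodes)
    edges = []
    lengths = {}
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        parent = f"I{counter}"
        counter += 1
        for child in (a, b):
            edges.append((parent, child))
            lengths[(parent, child)] = rng.uniform(min_len, max_len)
        nodes.append(parent)
    return edges, lengths, nodes[0]


def path_distance_matrix(labels, edges, lengths):
    """Leaf-to-leaf path-length matrix by shortest path on the tree graph."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for (p, c), w in lengths.items():
        adj.setdefault(p, []).append((c, w))
        adj.setdefault(c, []).append((p, w))

    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    mat = []
    for a in labels:
        d = dist_from(a)
        mat.append([d[b] for b in labels])
    return mat


def tree_split_set(labels, edges):
    """Non-trivial splits of a tree given as (parent, child) edges.

    Normalized to the side not containing the lexicographically
    smallest leaf, matching how splits are compared everywhere.
    """
    children: dict[str, list[str]] = {}
    for p, c in edges:
        children.setdefault(p, []).append(c)
    leafset = set(labels)
    anchor = min(leafset)

    def leaves_below(node):
        if node not in children:
            return {node}
        out = set()
        for c in children[node]:
            out |= leaves_below(c)
        return out

    splits = set()
    for p, c in edges:
        below = leaves_below(c)
        if not below <= leafset:
            continue
        side = leafset - below if anchor in below else below
        if 2 <= len(side) <= len(leafset) - 2:
            splits.add(frozenset(side))
    return splits


def jc_expected_p(d):
    """Closed-form expected p-distance between two JC-evolved sequences
    separated by total branch length d (substitutions/site)."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
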