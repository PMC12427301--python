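"""Homologous-pair correspondence between two karyotypes.

Pairs are matched by minimum-cost assignment on a squared z-distance
over (relative length, centromeric index), with SDs pooled in
quadrature.  An assignment is feasible only when the relative-length
difference stays within ``window_k`` summed SDs — the "shift to a
nearby position" rule — and differing shape classes incur a soft
``shape_penalty`` so the matcher prefers maps that imply fewer
rearrangements.  Among cost-optimal maps the one closest to the
identity (fewest displaced positions, then lexicographically least
permutation) is returned, which makes results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .karyo_io import ChromosomePair, Karyotype
from .morphology import DEFAULT_THRESHOLDS, ShapeThresholds, classify_shape

__all__ = [
    "SD_FLOOR",
    "HomologyMap",
    "InfeasibleMatchingError",
    "assignment_cost",
    "pair_karyotypes",
]

#: Floor (percentage points) applied to SDs so degenerate zero-SD
#: inputs do not produce infinite z-scores.
SD_FLOOR = 0.1

#: Cost differences at or below this are treated as exact ties.
TIE_TOL = 1e-9

# Perturbation that steers the assignment solver toward the identity
# among (near-)tied optima; must stay far below genuine cost gaps.
_IDENTITY_EPS = 1e-6


class InfeasibleMatchingError(ValueError):
    """No perfect matching exists within the relative-length windows."""

    def __init__(self, message: str, blocking_positions: Sequence[int] = ()):
        super().__init__(message)
        self.blocking_positions = tuple(blocking_positions)


@dataclass(frozen=True)
class HomologyMap:
    """A bijection between pair positions of two karyotypes.

    ``a_to_b[i]`` is the 1-based position in ``b`` matched to position
    ``i`` of ``a``; ``costs[i]`` is that assignment's cost.
    """

    a_to_b: tuple[tuple[int, int], ...]
    costs: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.a_to_b)
        src = sorted(i for i, _ in self.a_to_b)
        dst = sorted(j for _, j in self.a_to_b)
        if src != list(range(1, n + 1)) or dst != list(range(1, n + 1)):
            raise ValueError("a_to_b must be a bijection on positions 1..n")
        if len(self.costs) != n:
            raise ValueError("one cost per assignment required")
        if any(c < 0 for c in self.costs):
            raise ValueError("assignment costs must be non-negative")

    @classmethod
    def identity(cls, n: int, costs: Sequence[float] | None = None) -> "HomologyMap":
        return cls(
            tuple((i, i) for i in range(1, n + 1)),
            tuple(costs) if costs is not None else (0.0,) * n,
        )

    def __getitem__(self, position: int) -> int:
        for i, j in self.a_to_b:
            if i == position:
                return j
        raise KeyError(position)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs))

    @property
    def permutation(self) -> tuple[int, ...]:
        """b-positions in a-position order: permutation[i-1] = map(i)."""
        return tuple(j for _, j in sorted(self.a_to_b))

    @property
    def displaced(self) -> int:
        """Number of positions not mapped to themselves."""
        return sum(1 for i, j in self.a_to_b if i != j)

    def to_dict(self) -> dict:
        return {
            "a_to_b": {str(i): j for i, j in self.a_to_b},
            "costs": {str(i): c for (i, _), c in zip(sorted(self.a_to_b), sorted_costs(self))},
            "total_cost": self.total_cost,
        }


def sorted_costs(hmap: HomologyMap) -> tuple[float, ...]:
    order = sorted(range(len(hmap.a_to_b)), key=lambda k: hmap.a_to_b[k][0])
    return tuple(hmap.costs[k] for k in order)


def assignment_cost(p: ChromosomePair, q: ChromosomePair, sd_floor: float = SD_FLOOR) -> float:
    """Squared z-distance between two pairs on (rl, ci), SDs pooled.

    cost = z_rl^2 + z_ci^2 with z_x = (x_p - x_q) / sqrt(sd_p^2 + sd_q^2)
    (SDs floored at ``sd_floor``).  Symmetric; zero iff both means agree.
    """
    z_rl = (p.rl_mean - q.rl_mean) / np.hypot(
        max(p.rl_sd, sd_floor), max(q.rl_sd, sd_floor)
    )
    z_ci = (p.ci_mean - q.ci_mean) / np.hypot(
        max(p.ci_sd, sd_floor), max(q.ci_sd, sd_floor)
    )
    return float(z_rl**2 + z_ci**2)


def _shape_label(p: ChromosomePair, thresholds: ShapeThresholds) -> str:
    return p.shape if p.shape is not None else classify_shape(p.ci_mean, thresholds)


def cost_matrix(
    a: Karyotype,
    b: Karyotype,
    *,
    window_k: float = 2.0,
    shape_penalty: float = 1.0,
    sd_floor: float = SD_FLOOR,
    thresholds: ShapeThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Feasibility-masked cost matrix (infeasible assignments are +inf)."""
    n = a.n_pairs
    C = np.full((n, n), np.inf)
    for i, p in enumerate(a.pairs):
        for j, q in enumerate(b.pairs):
            if abs(p.rl_mean - q.rl_mean) > window_k * (p.rl_sd + q.rl_sd):
                continue
            c = assignment_cost(p, q, sd_floor)
            if _shape_label(p, thresholds) != _shape_label(q, thresholds):
                c += shape_penalty
            C[i, j] = c
    return C


def _solve(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Hungarian solve; raises if no finite-cost perfect matching exists."""
    try:
        rows, cols = linear_sum_assignment(C)
    except ValueError as exc:
        raise InfeasibleMatchingError(
            "no perfect matching within the relative-length windows", ()
        ) from exc
    total = C[rows, cols].sum()
    if not np.isfinite(total):
        raise InfeasibleMatchingError(
            "no perfect matching within the relative-length windows", ()
        )
    return cols, float(total)


def pair_karyotypes(
    a: Karyotype,
    b: Karyotype,
    *,
    window_k: float = 2.0,
    shape_penalty: float = 1.0,
    sd_floor: float = SD_FLOOR,
    thresholds: ShapeThresholds = DEFAULT_THRESHOLDS,
) -> HomologyMap:
    """Minimum-cost SD-constrained matching between two karyotypes.

    Raises :class:`InfeasibleMatchingError` (naming blocking positions)
    when some pair has no window-feasible partner or no perfect
    matching exists; raises ``ValueError`` on unequal pair counts.
    """
    if a.n_pairs != b.n_pairs:
        raise ValueError(
            f"pair counts differ ({a.n_pairs} vs {b.n_pairs}); "
            "fusion handling lives in the events module"
        )
    if window_k <= 0:
        raise ValueError("window_k must be positive")
    n = a.n_pairs
    C = cost_matrix(
        a, b, window_k=window_k, shape_penalty=shape_penalty,
        sd_floor=sd_floor, thresholds=thresholds,
    )

    blocked = [i + 1 for i in range(n) if not np.isfinite(C[i]).any()]
    blocked += [j + 1 for j in range(n) if not np.isfinite(C[:, j]).any()]
    if blocked:
        raise InfeasibleMatchingError(
            f"position(s) {sorted(set(blocked))} have no window-feasible partner",
            sorted(set(blocked)),
        )

    # Prefer the identity among (near-)tied optima, then pick the
    # lexicographically least permutation by greedy prefix fixing.
    C_pref = C + _IDENTITY_EPS * (1 - np.eye(n))
    _, best = _solve(C_pref)

    fixed_rows: list[int] = []
    fixed_cols: list[int] = []
    free_cols = list(range(n))
    for i in range(n):
        prefix = sum(C_pref[r, c] for r, c in zip(fixed_rows, fixed_cols))
        chosen = None
        for j in sorted(free_cols):
            if not np.isfinite(C[i, j]):
                continue
            rest_rows = [r for r in range(n) if r not in fixed_rows and r != i]
            rest_cols = [c for c in free_cols if c != j]
            if rest_rows:
                sub = C_pref[np.ix_(rest_rows, rest_cols)]
                try:
                    _, rest = _solve(sub)
                except InfeasibleMatchingError:
                    continue
            else:
                rest = 0.0
            if prefix + C_pref[i, j] + rest <= best + TIE_TOL:
                chosen = j
                break
        if chosen is None:  # cannot happen if the full solve succeeded
            raise InfeasibleMatchingError("matching became infeasible during tie-break", ())
        fixed_rows.append(i)
        fixed_cols.append(chosen)
        free_cols.remove(chosen)

    assignments = tuple((i + 1, j + 1) for i, j in zip(fixed_rows, fixed_cols))
    costs = tuple(float(C[i, j]) for i, j in zip(fixed_rows, fixed_cols))
    return HomologyMap(assignments, costs)
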