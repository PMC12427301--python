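"""Domain types and readers/writers for karyotype tables, trees, and reports.

Karyotype tables are tab-separated with a header naming at least
``taxon``, ``pair``, ``rl_mean``, ``rl_sd``, ``ci_mean``, ``ci_sd``;
a ``shape`` column is optional and preserved verbatim when present.
Trees are Newick (support values read as internal node labels, branch
lengths optional).  Rearrangement scenarios serialize to deterministic
JSON (sorted keys, no timestamps).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "SHAPE_LABELS",
    "ShapeClass",
    "ChromosomePair",
    "Karyotype",
    "KaryotypeFormula",
    "KaryotypeValidationError",
    "TreeValidationError",
    "read_karyotype_table",
    "parse_karyotype_table",
    "write_karyotype_table",
    "read_tree",
    "parse_tree",
    "write_scenario_report",
    "read_scenario_report",
]

#: Shape-class labels from most median to most terminal centromere.
SHAPE_LABELS = ("M", "sM", "sT", "T")

#: Default tolerance on the sum of relative lengths (printed tables
#: sum to 100 only up to rounding of individual entries).
RL_SUM_TOLERANCE = 1.0

#: Relative lengths whose SD exceeds this fraction of the mean are
#: suspicious (likely typographic) and trigger a validation warning.
RL_SD_WARN_FRACTION = 0.5

REQUIRED_COLUMNS = ("taxon", "pair", "rl_mean", "rl_sd", "ci_mean", "ci_sd")


class KaryotypeValidationError(ValueError):
    """A karyotype table or object violates a structural invariant."""


class TreeValidationError(ValueError):
    """A Newick tree violates a structural invariant."""


@dataclass(frozen=True)
class ShapeClass:
    """One chromosome shape class with its centromeric-index band.

    The band is half-open ``[ci_lo, ci_hi)`` except for the class
    containing a perfectly median centromere (M), which is closed at 50.
    """

    label: str
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if self.label not in SHAPE_LABELS:
            raise ValueError(f"unknown shape label {self.label!r}")
        if not 0 <= self.ci_lo < self.ci_hi <= 50:
            raise ValueError("shape class interval must satisfy 0 <= lo < hi <= 50")

    def __contains__(self, ci: float) -> bool:
        if self.ci_hi == 50:  # M is closed above: CI 50 is a median centromere
            return self.ci_lo <= ci <= 50
        return self.ci_lo <= ci < self.ci_hi


@dataclass(frozen=True)
class ChromosomePair:
    """Morphometrics of one homologous chromosome pair.

    ``rl_mean``/``rl_sd`` are relative length (% of total haploid
    complement length); ``ci_mean``/``ci_sd`` are centromeric index
    (short arm / chromosome length x 100).  ``shape`` is a given or
    computed shape-class label, or ``None`` when unknown.
    """

    index: int
    rl_mean: float
    rl_sd: float
    ci_mean: float
    ci_sd: float
    shape: str | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise KaryotypeValidationError(f"pair index must be >= 1, got {self.index}")
        if not 0 < self.rl_mean <= 100:
            raise KaryotypeValidationError(
                f"pair {self.index}: rl_mean must be in (0, 100], got {self.rl_mean}"
            )
        if not 0 <= self.ci_mean <= 50:
            raise KaryotypeValidationError(
                f"pair {self.index}: ci_mean must be in [0, 50], got {self.ci_mean}"
            )
        if self.rl_sd < 0 or self.ci_sd < 0:
            raise KaryotypeValidationError(f"pair {self.index}: SDs must be >= 0")
        if self.shape is not None and self.shape not in SHAPE_LABELS:
            raise KaryotypeValidationError(
                f"pair {self.index}: unknown shape label {self.shape!r}"
            )


@dataclass(frozen=True)
class Karyotype:
    """An ordered sequence of chromosome pairs for one taxon/population.

    Pairs must be sorted by non-increasing ``rl_mean`` (the rank order
    of a conventional karyotype table) unless ``keep_order`` is set,
    and their relative lengths must sum to 100 within
    ``rl_sum_tolerance``.  ``nor_pair`` is an annotation only (the
    1-based index of the NOR-bearing pair); nothing computes it.
    """

    taxon_id: str
    pairs: tuple[ChromosomePair, ...]
    nor_pair: int | None = None
    keep_order: bool = field(default=False, compare=False)
    rl_sum_tolerance: float = field(default=RL_SUM_TOLERANCE, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if not self.pairs:
            raise KaryotypeValidationError(f"{self.taxon_id}: karyotype has no pairs")
        if [p.index for p in self.pairs] != list(range(1, len(self.pairs) + 1)):
            raise KaryotypeValidationError(
                f"{self.taxon_id}: pair indices must be 1..{len(self.pairs)} in order"
            )
        if not self.keep_order:
            rls = [p.rl_mean for p in self.pairs]
            if any(a < b for a, b in zip(rls, rls[1:])):
                raise KaryotypeValidationError(
                    f"{self.taxon_id}: pairs are not sorted by non-increasing "
                    "relative length (pass keep_order=True to accept)"
                )
        total = sum(p.rl_mean for p in self.pairs)
        if abs(total - 100.0) > self.rl_sum_tolerance:
            raise KaryotypeValidationError(
                f"{self.taxon_id}: relative lengths sum to {total:.2f}, "
                f"outside 100 +/- {self.rl_sum_tolerance}"
            )
        if self.nor_pair is not None and not 1 <= self.nor_pair <= len(self.pairs):
            raise KaryotypeValidationError(
                f"{self.taxon_id}: nor_pair {self.nor_pair} out of range"
            )
        for p in self.pairs:
            if p.rl_sd > RL_SD_WARN_FRACTION * p.rl_mean:
                warnings.warn(
                    f"{self.taxon_id} pair {p.index}: rl_sd {p.rl_sd} exceeds "
                    f"{RL_SD_WARN_FRACTION:g} x rl_mean {p.rl_mean} (possible typo)",
                    stacklevel=2,
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def diploid_number(self) -> int:
        """2n: twice the number of homologous pairs."""
        return 2 * len(self.pairs)

    @property
    def shape_labels(self) -> tuple[str | None, ...]:
        return tuple(p.shape for p in self.pairs)

    def with_shapes(self, labels: Sequence[str]) -> "Karyotype":
        """Copy of this karyotype with shape labels replaced."""
        if len(labels) != len(self.pairs):
            raise KaryotypeValidationError("label count does not match pair count")
        new_pairs = tuple(replace(p, shape=s) for p, s in zip(self.pairs, labels))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # already flagged when first built
            return replace(self, pairs=new_pairs)


@dataclass(frozen=True)
class KaryotypeFormula:
    """Counts of chromosome pairs per shape class, e.g. ``19M, 4sM, 1sT``."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for label, count in self.counts:
            if label not in SHAPE_LABELS:
                raise ValueError(f"unknown shape label {label!r}")
            if label in seen:
                raise ValueError(f"repeated shape class {label!r}")
            if count < 0:
                raise ValueError(f"negative count for {label!r}")
            seen.add(label)

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "KaryotypeFormula":
        return cls(tuple((lab, counts[lab]) for lab in SHAPE_LABELS if counts.get(lab)))

    def as_dict(self) -> dict[str, int]:
        return {label: count for label, count in self.counts}

    @property
    def total(self) -> int:
        return sum(count for _, count in self.counts)

    def __str__(self) -> str:
        # Canonical rendering: class order M, sM, sT, T; zero classes omitted.
        parts = [
            f"{count}{label}"
            for label in SHAPE_LABELS
            for lab, count in self.counts
            if lab == label and count > 0
        ]
        return ", ".join(parts)


# ---------------------------------------------------------------------------
# Karyotype tables (TSV)
# ---------------------------------------------------------------------------


def parse_karyotype_table(
    frame: pd.DataFrame,
    *,
    keep_order: bool = False,
    rl_sum_tolerance: float = RL_SUM_TOLERANCE,
) -> list[Karyotype]:
    """Build one :class:`Karyotype` per distinct taxon from a table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise KaryotypeValidationError(f"missing required column(s): {', '.join(missing)}")
    if frame.empty:
        return []

    numeric = {}
    for col in ("pair", "rl_mean", "rl_sd", "ci_mean", "ci_sd"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad) or converted.isna().any():
            row = int((converted.isna()).idxmax())
            raise KaryotypeValidationError(
                f"non-numeric value in column {col!r} at table row {row}"
            )
        numeric[col] = converted

    dup = frame.assign(pair=numeric["pair"]).duplicated(subset=["taxon", "pair"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise KaryotypeValidationError(
            f"duplicate (taxon, pair) entry: ({row['taxon']!r}, {int(row['pair'])})"
        )

    karyotypes = []
    for taxon in frame["taxon"].drop_duplicates():
        mask = frame["taxon"] == taxon
        sub = frame[mask].copy()
        for col, series in numeric.items():
            sub[col] = series[mask]
        sub = sub.sort_values("pair")
        pairs = []
        for _, row in sub.iterrows():
            shape = None
            if "shape" in sub.columns and pd.notna(row.get("shape")):
                shape = str(row["shape"]).strip().strip("()") or None
            pairs.append(
                ChromosomePair(
                    index=int(row["pair"]),
                    rl_mean=float(row["rl_mean"]),
                    rl_sd=float(row["rl_sd"]),
                    ci_mean=float(row["ci_mean"]),
                    ci_sd=float(row["ci_sd"]),
                    shape=shape,
                )
            )
        karyotypes.append(
            Karyotype(
                taxon_id=str(taxon),
                pairs=tuple(pairs),
                keep_order=keep_order,
                rl_sum_tolerance=rl_sum_tolerance,
            )
        )
    return karyotypes


def read_karyotype_table(
    path: str | Path,
    *,
    keep_order: bool = False,
    rl_sum_tolerance: float = RL_SUM_TOLERANCE,
) -> list[Karyotype]:
    """Read a tab-separated karyotype table; one Karyotype per taxon.

    An empty file with only a header yields an empty list.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return parse_karyotype_table(
        frame, keep_order=keep_order, rl_sum_tolerance=rl_sum_tolerance
    )


def write_karyotype_table(karyotypes: Iterable[Karyotype], path: str | Path) -> None:
    """Write karyotypes back to the TSV dialect read_karyotype_table accepts."""
    rows = []
    for k in karyotypes:
        for p in k.pairs:
            rows.append(
                {
                    "taxon": k.taxon_id,
                    "pair": p.index,
                    "rl_mean": p.rl_mean,
                    "rl_sd": p.rl_sd,
                    "ci_mean": p.ci_mean,
                    "ci_sd": p.ci_sd,
                    "shape": p.shape if p.shape is not None else "",
                }
            )
    frame = pd.DataFrame(
        rows, columns=["taxon", "pair", "rl_mean", "rl_sd", "ci_mean", "ci_sd", "shape"]
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees (Newick)
# ---------------------------------------------------------------------------


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree and validate it.

    Internal node labels (commonly support values) are kept as plain
    node labels; branch lengths are optional.
    """
    text = newick.strip()
    if not text.endswith(";"):
        raise TreeValidationError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeValidationError(f"could not parse Newick tree: {exc}") from exc
    labels = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        if not label:
            raise TreeValidationError("tree contains a leaf with an empty label")
        labels.append(label)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeValidationError(f"duplicate leaf label(s): {', '.join(dupes)}")
    if len(labels) < 2:
        raise TreeValidationError("tree must have at least 2 leaves")
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a file."""
    return parse_tree(Path(path).read_text())


# ---------------------------------------------------------------------------
# Scenario reports (JSON)
# ---------------------------------------------------------------------------


def write_scenario_report(scenario, path: str | Path) -> None:
    """Write an event scenario as deterministic JSON (sorted keys)."""
    payload = scenario.to_dict()
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def read_scenario_report(path: str | Path):
    """Read a scenario report written by :func:`write_scenario_report`."""
    from .events import EventScenario  # local import avoids a cycle at import time

    payload = json.loads(Path(path).read_text())
    return EventScenario.from_dict(payload)
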