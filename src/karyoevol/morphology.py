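"""Shape classification from the centromeric index, and formula handling.

The four-class reduction of centromere-position nomenclature used here
cuts the centromeric-index axis (0-50, where 50 is a perfectly median
centromere) at 12.5 / 25 / 37.5:

    T  : ci <  12.5        (telocentric)
    sT : 12.5 <= ci < 25   (subtelocentric)
    sM : 25 <= ci < 37.5   (submetacentric)
    M  : ci >= 37.5        (metacentric; closed at both boundaries)
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .karyo_io import (
    SHAPE_LABELS,
    Karyotype,
    KaryotypeFormula,
    ShapeClass,
)

__all__ = [
    "ShapeThresholds",
    "DEFAULT_THRESHOLDS",
    "LabelConflict",
    "ClassificationResult",
    "classify_shape",
    "classify_karyotype",
    "summarize_formula",
    "parse_formula",
    "karyotype_diff",
]


@dataclass(frozen=True)
class ShapeThresholds:
    """Cut points on the centromeric-index axis separating T/sT/sM/M."""

    t_st: float = 12.5
    st_sm: float = 25.0
    sm_m: float = 37.5

    def __post_init__(self) -> None:
        cuts = (self.t_st, self.st_sm, self.sm_m)
        if not all(0 < c < 50 for c in cuts):
            raise ValueError("thresholds must lie strictly inside (0, 50)")
        if not cuts[0] < cuts[1] < cuts[2]:
            raise ValueError("thresholds must be strictly increasing")

    def classes(self) -> tuple[ShapeClass, ...]:
        """The four shape classes; their bands partition [0, 50]."""
        return (
            ShapeClass("T", 0.0, self.t_st),
            ShapeClass("sT", self.t_st, self.st_sm),
            ShapeClass("sM", self.st_sm, self.sm_m),
            ShapeClass("M", self.sm_m, 50.0),
        )


DEFAULT_THRESHOLDS = ShapeThresholds()


class LabelConflict(NamedTuple):
    """A printed shape label that disagrees with the computed class."""

    position: int
    printed: str
    computed: str


class ClassificationResult(NamedTuple):
    karyotype: Karyotype
    label_conflicts: list[LabelConflict]


def classify_shape(ci_mean: float, thresholds: ShapeThresholds = DEFAULT_THRESHOLDS) -> str:
    """Shape-class label for a mean centromeric index (total step function)."""
    if not 0 <= ci_mean <= 50:
        raise ValueError(f"centromeric index must be in [0, 50], got {ci_mean}")
    if ci_mean >= thresholds.sm_m:
        return "M"
    if ci_mean >= thresholds.st_sm:
        return "sM"
    if ci_mean >= thresholds.t_st:
        return "sT"
    return "T"


def classify_karyotype(
    k: Karyotype, thresholds: ShapeThresholds = DEFAULT_THRESHOLDS
) -> ClassificationResult:
    """Classify every pair from its mean centromeric index.

    Returns a copy of the karyotype with computed shapes, plus the list
    of positions where a given (printed) label disagrees with the
    computed class.  Printed labels are never silently overwritten:
    disagreements are surfaced, and the copy carries the computed class.
    """
    computed = [classify_shape(p.ci_mean, thresholds) for p in k.pairs]
    conflicts = [
        LabelConflict(p.index, p.shape, c)
        for p, c in zip(k.pairs, computed)
        if p.shape is not None and p.shape != c
    ]
    return ClassificationResult(k.with_shapes(computed), conflicts)


def summarize_formula(shapes: Sequence[str]) -> KaryotypeFormula:
    """Count pairs per shape class, e.g. ['M','M','sM',...] -> 2M, 1sM."""
    if not shapes:
        raise ValueError("cannot summarize an empty label list")
    counts = {label: 0 for label in SHAPE_LABELS}
    for s in shapes:
        if s not in counts:
            raise ValueError(f"unknown shape label {s!r}")
        counts[s] += 1
    return KaryotypeFormula.from_counts(counts)


_FORMULA_TOKEN = re.compile(r"^\s*(\d+)\s*(M|sM|sT|T)\s*$")


def parse_formula(text: str) -> KaryotypeFormula:
    """Parse a chromosomal formula string such as ``"16M, 7sM, 1T"``.

    Whitespace-tolerant (``"5 sM"`` equals ``"5sM"``); inverse of the
    canonical rendering produced by :func:`summarize_formula`.
    """
    counts: dict[str, int] = {}
    tokens = [t for t in text.split(",")]
    if not any(t.strip() for t in tokens):
        raise ValueError("empty formula string")
    for token in tokens:
        m = _FORMULA_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed formula token {token.strip()!r}")
        count, label = int(m.group(1)), m.group(2)
        if label in counts:
            raise ValueError(f"repeated shape class {label!r}")
        counts[label] = count
    return KaryotypeFormula.from_counts(counts)


def karyotype_diff(
    a: Sequence[str],
    b: Sequence[str],
    mapping=None,
) -> list[tuple[int, str, str]]:
    """Positions where mapped shape labels differ between two karyotypes.

    ``mapping`` maps 1-based positions of ``a`` onto positions of ``b``
    (a :class:`~karyoevol.homology.HomologyMap`, a dict, or ``None``
    for the identity, allowed only when lengths match).  Records are
    ordered by position in ``a``.
    """
    if mapping is None:
        if len(a) != len(b):
            raise ValueError(
                "identity mapping requires equal pair counts "
                f"({len(a)} vs {len(b)})"
            )
        pairs = {i: i for i in range(1, len(a) + 1)}
    elif hasattr(mapping, "a_to_b"):
        pairs = dict(mapping.a_to_b)
    else:
        pairs = dict(mapping)
    if sorted(pairs) != list(range(1, len(a) + 1)) or sorted(
        pairs.values()
    ) != list(range(1, len(b) + 1)):
        raise ValueError("mapping must be a bijection covering both karyotypes")
    out = []
    for i in sorted(pairs):
        ai, bj = a[i - 1], b[pairs[i] - 1]
        if ai != bj:
            out.append((i, ai, bj))
    return out
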