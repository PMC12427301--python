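"""Bundled karyotype data for the *Trochoidea* study system.

Morphometric measurements (relative length and centromeric index,
mean +/- SD over five metaphase plates, plus the published shape call)
for the two *Trochoidea caroni* populations — Capri/Terracina and
Palermo — together with the published chromosomal formulas of the
congeners and the reference topology.  All karyotypes have 2n = 48;
the NOR-bearing pair is the 16th.
"""

from __future__ import annotations

import io

from .karyo_io import ChromosomePair, Karyotype

__all__ = [
    "CAPRI_ROWS",
    "PALERMO_ROWS",
    "CONGENER_FORMULAS",
    "TROCHOIDEA_TREE",
    "NOR_PAIR",
    "capri_karyotype",
    "palermo_karyotype",
    "caroni_table_tsv",
    "geomitrid_ancestor_karyotype",
]

NOR_PAIR = 16

# (pair, rl_mean, rl_sd, ci_mean, ci_sd, shape)
CAPRI_ROWS = (
    (1, 7.5, 0.8, 39.0, 2.4, "M"),
    (2, 6.8, 0.4, 40.9, 1.7, "M"),
    (3, 6.8, 0.6, 32.3, 1.2, "sM"),
    (4, 5.3, 0.3, 43.3, 1.5, "M"),
    (5, 5.3, 0.7, 42.8, 1.0, "M"),
    (6, 4.9, 0.5, 46.9, 2.9, "M"),
    (7, 4.8, 0.3, 36.2, 2.0, "sM"),
    (8, 4.8, 0.8, 22.4, 2.5, "sT"),
    (9, 4.4, 0.2, 44.9, 2.7, "M"),
    (10, 4.2, 0.7, 41.2, 2.2, "M"),
    (11, 4.1, 0.8, 40.3, 1.8, "M"),
    (12, 4.0, 0.6, 34.3, 2.1, "sM"),
    (13, 3.8, 0.6, 39.5, 1.7, "M"),
    (14, 3.8, 0.4, 33.6, 1.6, "sM"),
    (15, 3.7, 0.5, 43.6, 2.3, "M"),
    (16, 3.5, 0.8, 38.9, 2.1, "M"),
    (17, 3.4, 0.4, 44.1, 2.0, "M"),
    (18, 3.3, 0.5, 48.3, 1.5, "M"),
    (19, 3.1, 0.6, 45.4, 2.6, "M"),
    (20, 2.9, 0.5, 40.2, 3.1, "M"),
    (21, 2.8, 0.5, 44.9, 2.9, "M"),
    (22, 2.7, 0.4, 43.5, 2.5, "M"),
    (23, 2.3, 0.3, 43.5, 2.1, "M"),
    (24, 1.9, 0.2, 39.3, 1.9, "M"),
)

PALERMO_ROWS = (
    (1, 7.7, 0.7, 39.8, 2.9, "M"),
    (2, 7.5, 0.6, 41.9, 2.6, "M"),
    (3, 6.3, 0.7, 35.1, 2.0, "sM"),
    (4, 5.3, 0.5, 42.5, 2.7, "M"),
    (5, 4.6, 0.4, 40.8, 2.3, "M"),
    (6, 4.4, 0.6, 46.3, 2.5, "M"),
    (7, 4.3, 0.8, 36.2, 2.6, "sM"),
    (8, 4.2, 0.5, 40.2, 2.0, "M"),
    (9, 4.1, 0.6, 43.8, 2.4, "M"),
    (10, 4.0, 0.8, 41.9, 2.2, "M"),
    (11, 3.8, 0.4, 41.8, 2.9, "M"),
    (12, 3.8, 0.4, 35.4, 1.7, "sM"),
    (13, 3.7, 0.5, 39.5, 2.0, "M"),
    (14, 3.6, 0.7, 33.9, 1.6, "sM"),
    (15, 3.6, 0.6, 45.4, 1.9, "M"),
    (16, 3.6, 0.5, 39.4, 2.4, "M"),
    (17, 3.5, 0.6, 35.1, 2.2, "sM"),
    (18, 3.5, 0.9, 49.1, 2.1, "M"),
    (19, 3.5, 0.7, 43.0, 2.7, "M"),
    (20, 3.3, 0.3, 39.7, 2.0, "M"),
    # SDs of the last four relative lengths are printed near the means
    # themselves (likely typographic); stored as published.
    (21, 3.1, 2.2, 35.8, 2.3, "M"),
    (22, 3.1, 2.0, 40.3, 2.7, "M"),
    (23, 3.0, 2.4, 46.6, 1.9, "M"),
    (24, 2.5, 2.7, 39.4, 2.0, "M"),
)

#: Published chromosomal formulas of the congeners (all 2n = 48).
CONGENER_FORMULAS = {
    "T_elegans": "16M, 6sM, 2T",
    "T_pyramidata": "20M, 4sM",
    "T_trochoides": "16M, 7sM, 1T",
}

#: Reference topology for the four karyotyped taxa.
TROCHOIDEA_TREE = "((elegans,caroni),(pyramidata,trochoides));"


def _build(taxon_id: str, rows) -> Karyotype:
    pairs = tuple(
        ChromosomePair(index=i, rl_mean=rl, rl_sd=rls, ci_mean=ci, ci_sd=cis, shape=sh)
        for i, rl, rls, ci, cis, sh in rows
    )
    return Karyotype(taxon_id=taxon_id, pairs=pairs, nor_pair=NOR_PAIR)


def capri_karyotype() -> Karyotype:
    """*T. caroni* from Capri/Terracina (pooled), 24 pairs."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _build("Capri", CAPRI_ROWS)


def palermo_karyotype() -> Karyotype:
    """*T. caroni* from Palermo, 24 pairs."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pairs 21-24 trigger the rl_sd sanity warning
        return _build("Palermo", PALERMO_ROWS)


def caroni_table_tsv() -> str:
    """Both population tables in the TSV dialect the readers accept."""
    buf = io.StringIO()
    buf.write("taxon\tpair\trl_mean\trl_sd\tci_mean\tci_sd\tshape\n")
    for taxon, rows in (("Capri", CAPRI_ROWS), ("Palermo", PALERMO_ROWS)):
        for i, rl, rls, ci, cis, sh in rows:
            buf.write(f"{taxon}\t{i}\t{rl}\t{rls}\t{ci}\t{cis}\t{sh}\n")
    return buf.getvalue()


def geomitrid_ancestor_karyotype() -> Karyotype:
    """The presumed primitive configuration: 26 pairs, all metacentric.

    2n = 52 with every chromosome metacentric; relative lengths are a
    nominal decreasing profile (only the pair count and shapes matter
    downstream).
    """
    from .synthetic import all_metacentric_karyotype

    return all_metacentric_karyotype("Geomitridae_ancestor", 26)
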