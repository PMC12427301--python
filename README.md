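# karyoevol

Karyotype morphometrics and chromosomal-rearrangement inference for the
land-snail genus *Trochoidea*, built as a reusable pipeline:

- **karyo_io** — domain types (`ChromosomePair`, `Karyotype`,
  `KaryotypeFormula`) and readers/writers for TSV karyotype tables,
  Newick trees, and deterministic JSON scenario reports.
- **morphology** — shape classification from the centromeric index
  (four Levan-style classes M/sM/sT/T with cut points 12.5/25/37.5),
  chromosomal-formula rendering/parsing, and karyotype diffs.
- **homology** — SD-constrained minimum-cost matching of homologous
  pairs between karyotypes (squared z-distance on relative length and
  centromeric index, relative-length feasibility windows, shape-change
  penalty, deterministic tie-breaking toward the identity).
- **events** — small-parsimony ancestral reconstruction (Sankoff, exact
  on polytomies, ties broken toward metacentric) and per-edge inference
  of inversion/translocation events, including fusion-position search
  for pair-count reductions.
- **seqdist** — uncorrected p-distance with pairwise deletion,
  neighbour joining, and bootstrap support, implemented from scratch.
- **synthetic** — seeded generators: replicate morphometric
  measurements, karyotype evolution along a tree with ground-truth
  event records, and Jukes–Cantor sequence evolution.
- **datasets** — the bundled *T. caroni* measurement tables
  (Capri/Terracina and Palermo populations, 24 pairs each, 2n = 48),
  congener formulas, and the reference topology.

## Command line

The `karyoevol` entry point exposes the pipeline stages; every
subcommand echoes its parameters to stderr so runs are reproducible
from their logs.

```sh
karyoevol classify table.tsv                 # formula per taxon + label conflicts
karyoevol diff table.tsv Capri Palermo       # positions whose shapes differ
karyoevol match table.tsv Capri Palermo      # SD-constrained homology map (JSON)
karyoevol events table.tsv --tree tree.nwk --out scenario.json
karyoevol pdist alignment.fasta              # p-distance matrix (TSV)
karyoevol njtree --fasta alignment.fasta     # or --matrix distances.tsv
karyoevol bootstrap alignment.fasta --replicates 1000 --seed 1
karyoevol simulate --tree tree.nwk --seed 1 --out-prefix run
```

Karyotype tables are tab-separated with header columns
`taxon  pair  rl_mean  rl_sd  ci_mean  ci_sd  shape` (shape optional);
`rl` is relative length in % of the haploid complement, `ci` the
centromeric index in % (0–50).

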