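# barcodeval

Distance-based evaluation of DNA barcodes for island radiations.

DNA barcoding assigns unknown samples to species from short standardized gene
regions (for plants typically *matK* + *rbcL*, often supplemented with
*trnH-psbA*, *rpoB*, *rpoC1* and the nuclear ITS). In recently radiated island
lineages, too little sequence variation may have accumulated for this to work:
conspecific and heterospecific samples can be identical or interleaved.
`barcodeval` is a toolkit for quantifying exactly that, aimed at systematists
and conservation biologists who need to know *which* barcode combination
discriminates *which* lineages — and how discrimination success depends on
lineage age.

## What it computes

Given one aligned FASTA per locus and a sample-metadata table (accession →
species → informal taxonomic group, threat flag), the pipeline runs, for every
requested locus combination and missing-data mode:

1. **Concatenation** — mode A keeps every accession and pads missing loci
   with `?`; mode B keeps only accessions sequenced for all included loci.
2. **K2P distances** with pairwise deletion. With transition proportion *P*
   (A↔G, C↔T) and transversion proportion *Q* over the sites comparable in a
   pair,

   d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

   Saturated pairs (log argument ≤ 0) are masked as undefined, never imputed.
3. **Neighbour-joining** (Saitou–Nei; UPGMA available as an alternative),
   with deterministic lexicographic tie-breaking and negative branch lengths
   clamped to zero, then zero-length internal edges collapsed to polytomies.
4. **Discrimination scoring** — a species with ≥2 accessions is discriminated
   iff its accessions form an exclusive clade (some edge-removal bipartition
   isolates exactly them); a single-accession species iff it has non-zero
   distance to every heterospecific accession. An informal group is
   discriminated iff some clade containing only that group's accessions
   covers ≥50 % of its sampled species.
5. **Age analysis** — per-group success percentages related to lineage MRCA
   ages via Spearman rank correlation and an age-threshold scan.

A seeded simulator (`barcodeval.simulate`) generates dated island radiations
(clades of configurable stem/crown ages, Yule topologies, HKY+Γ sequences for
six loci of differing rates, missing-data injection), so the whole pipeline is
testable without any sequence downloads.

## Worked example

```python
from barcodeval import (
    lotus_like_config, make_dataset, run_evaluation, format_report_table,
)

ds = make_dataset(lotus_like_config(seed=1))   # 9 groups, 38 species, 6 loci
res = run_evaluation(list(ds.loci), ds.table, schemes=("singles", "all"),
                     modes=("A",))
print(format_report_table(list(res.reports)))
```

prints

```
combination	mode	aligned_bp	n_species_total	n_species_discriminated	n_endangered_discriminated	n_groups_discriminated	pct_species
ITS	A	621	38	36	13	9	94.74
matK	A	867	38	26	9	8	68.42
rbcL	A	588	38	19	6	6	50.00
rpoB	A	354	37	6	1	1	16.22
rpoC1	A	511	37	20	5	5	54.05
trnH-psbA	A	342	38	21	6	7	55.26
ITS+trnH-psbA+matK+rpoC1+rbcL+rpoB	A	3283	38	32	11	9	84.21
```

Each row is one locus combination under missing-data mode A: the aligned
length, how many of the sampled species (and of the flagged endangered
species) form exclusive clusters on the NJ tree, how many informal groups meet
the 50 % rule, and the species percentage. On this synthetic radiation the
fast nuclear ITS discriminates most species, the slow plastid *rpoB* almost
none, and rows with `n_species_total` 37 show a species dropped entirely by
simulated amplification failure at that locus.

The same pipeline is available from the shell:

```bash
barcodeval simulate --seed 1 --out fixtures/
barcodeval evaluate --loci fixtures/ITS.fasta --loci fixtures/matK.fasta \
    --meta fixtures/samples.tsv --schemes singles,all --modes A,B --out results/
barcodeval agescan --report results/reports.json --meta fixtures/samples.tsv \
    --ages fixtures/ages.tsv --thresholds 2,3,3.5,4
```

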