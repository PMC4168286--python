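# Methods

## Problem setting

The package evaluates how well short barcode regions discriminate species and
morphology-based informal taxonomic groups in a clade-structured sample, with
particular attention to island radiations in which lineage ages span an order
of magnitude. The analysis pipeline is deliberately the standard barcoding
workflow — K2P distances, neighbour-joining, monophyly-based scoring — so that
its outputs are comparable with the barcoding literature; the package's value
is in making every stage explicit, deterministic and testable.

## Distances

Distances are computed under the Kimura two-parameter model,
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, with *P* and *Q* the transition and
transversion proportions over *comparable sites*: columns where both members
of a pair carry one of A, C, G, T (pairwise deletion). Design choices:

- `?` (missing datum, e.g. a failed amplification) and `-` (alignment gap)
  are distinct characters in files but both excluded from distances. Mode-A
  concatenation pads whole missing loci with `?`, so complete deletion would
  be degenerate there; pairwise deletion is the only workable convention.
- IUPAC ambiguity codes are excluded even when compatible with the other
  sequence (R vs A), for determinism.
- A pair is *undefined* when no comparable sites remain or a log argument is
  ≤ 0 (saturation). Undefined entries travel in a mask; tree building refuses
  matrices containing them rather than imputing, because silently imputed
  distances would corrupt discrimination scoring downstream. The evaluation
  runner records such combinations as failures and continues.

## Trees

Neighbour joining uses the Saitou–Nei Q-criterion
`Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)` with the standard limb
lengths. Numerical conventions:

- Ties in Q (and in UPGMA merge distances) are broken by the
  lexicographically smallest pair of cluster labels, a cluster being labelled
  by its smallest accession id. Identical inputs therefore give
  byte-identical Newick output on any platform.
- Negative limb-length estimates are clamped to zero; the clamped total is
  recorded on the tree (`negative_branch_clamp_total`) and logged, rather
  than redistributed to the sibling edge — the simplest auditable convention.
- Trees are left unrooted for scoring. UPGMA (rooted, ultrametric,
  average linkage) is provided as the alternative construction method.

Before scoring, internal edges with length ≤ 1e-9 are collapsed into
polytomies. This matters: two identical sequences from different species
otherwise receive an arbitrary resolution that could spuriously grant or deny
monophyly. Leaf edges are never collapsed.

## Discrimination scoring

Species with ≥2 accessions: discriminated iff the accession set is one side
of some edge-removal bipartition of the collapsed unrooted tree (an
*exclusive clade*). Species with one accession cannot be tested for
monophyly; the default rule discriminates them iff their minimum K2P distance
to every heterospecific accession is strictly positive (a saturated/undefined
pair counts as positive — saturation implies divergence). This rule is a
package convention, switchable via `singleton_policy`
(`nonzero_distance` | `always` | `never`), since no published standard
exists for single-accession species.

Groups: for each informal group, every clade containing only that group's
accessions is found, and the group is discriminated iff the best such clade
covers at least 50 % of the group's sampled species (distinct species, not
accessions; a species counts as covered when at least one of its accessions
is in the clade). Exclusivity is read strictly — one foreign accession
disqualifies a clade.

Edge cases: if a species (or group) comprises the entire tree, it is scored
as discriminated — there is nothing to confuse it with. Accessions present in
the tree but absent from the metadata table are an error, not a warning.

The missing-data modes follow the two conventions used for combination
analyses: mode A (all accessions, missing loci padded) and mode B (accessions
with any missing included locus excluded). Mode B was originally described
for two-locus combinations only; this package applies the same exclusion rule
to any combination size, with `pairs_only_mode_b=True` restoring the
pairs-only behaviour.

## Age analysis

Per-group success is the percentage of the group's sampled species
discriminated in a given report. With only five to eleven groups, only rank
order is defensible, so the age–success association is summarized by a
Spearman correlation (average ranks on ties, ≥3 groups required), plus a
threshold scan reporting mean success among groups older/younger than each
candidate age. Lineage ages are inputs (user-supplied MRCA ages, or simulator
truth); molecular dating itself is outside this package's scope — relaxed
clock dating is an established external workflow and its output is consumed
as a table.

## Simulator

`simulate.make_dataset` produces a dated accession-level tree, one aligned
FASTA per locus, a metadata table, a group-age table and a ground-truth JSON.
Structure and defaults:

- **Backbone and clades.** Clades attach to a ladder backbone at their stem
  ages (equal stems form a polytomy; the youngest clade shares the youngest
  backbone node). Within a clade of *n* species, topology follows the Yule
  process (each lineage equally likely to split) and the *n−2* non-crown
  split ages are i.i.d. uniform on `(0.1·crown, crown)` — the slow-speciation
  limit of the age-conditioned Yule process. The lower bound emulates
  extinction pruning: in mature radiations the surviving, recognized species
  are separated by at least a fraction of the clade's depth, while young
  radiations (small crown) keep their shallow splits. Crown age is
  `stem_age × crown_age_fraction` (default 0.7, reflecting a colonization
  lag before radiation).
- **Accessions.** 1–4 accessions per species (uniform); within a species
  they coalesce on a pectinate genealogy at uniform depths ≤ 0.05 Myr
  (`intraspecific_depth_mya`), a typical within-island, within-species
  divergence scale.
- **Sequences.** HKY+Γ: root sequence from stationary frequencies (equal by
  default), transition/transversion rate ratio κ = 2, Γ shape 0.8 discretized
  into 4 equal-probability categories using the mean rate per category.
  The rate matrix is normalized to one expected substitution per site per
  unit time, so a branch of length *t* Myr at locus rate *r* accumulates
  `r·t·(category multiplier)` expected substitutions per site. Transition
  matrices are exact (`expm`), so a zero-length tree yields identical
  sequences and the two-tip expectation `E[d] ≈ 2·r·T` is recovered to
  Monte-Carlo error.
- **Loci.** The six-locus default mirrors the aligned lengths of the
  standard plant-barcode panel (ITS 621, *trnH-psbA* 342, *matK* 867,
  *rpoC1* 511, *rbcL* 588, *rpoB* 354 bp) with literature-scale per-Myr
  rates ordered ITS > *trnH-psbA* > *matK* > *rpoC1* > *rbcL* > *rpoB*
  (5×10⁻³ down to 4×10⁻⁴ subs/site/Myr).
- **Missing data.** Each (accession, locus) is deleted independently with
  probability 0.05 — the typical per-region combined amplification +
  sequencing failure rate in plant-barcoding panels — with at least one locus
  retained per accession. Mode A vs B comparisons are meaningful only
  because of this step.
- **Presets.** `lotus_like_config()` instantiates nine informal groups with
  stem ages drawn from five dated divergence nodes (4.78, 4.55, 4.34, 3.71,
  2.53 Mya; groups sharing a node share its age) totalling 38 species;
  `include_young=True` appends two 0.5-Mya-stem radiations with
  `crown_age_fraction=0.25` (a very recent burst) for age-contrast
  experiments. `uniform_radiation_config(age)` gives all clades one stem age
  for gradient studies.
- **Seeding.** All randomness flows from one integer seed through named
  per-operation child streams (tree, per-locus sequences, missing pattern,
  threat flags), so each component is reproducible in isolation.

What the simulator does *not* model — and what passing tests therefore do not
show about real data: indel evolution (sequences are born aligned; the indel
counter is exercised on separate gap-injection fixtures), inversions,
coalescent gene-tree/species-tree discordance, introgression, rate variation
among lineages, and base-composition heterogeneity. Real barcoding data also
violate the clean species boundaries the truth tables assume.

## Alignment summaries

Variable sites are columns with ≥2 distinct unambiguous states;
parsimony-informative sites require ≥2 states each in ≥2 sequences; gaps,
`?` and ambiguity codes never count as states (conservative). An indel
*event* is an equivalence class of maximal `-` runs sharing identical start
and end columns — coordinate identity, not overlap, defines the class, as the
most reproducible convention when only event counts are published.
Inversions are not detected; they surface as runs of substitutions.

## Problem sizes and numerical tolerances

The self-checks run at sizes chosen to exercise every code path while staying
desk-scale: NJ consistency on 200 random additive matrices of ≤8 taxa
(path-length recovery to 1e-9), discrimination scoring against a brute-force
edge-removal oracle on 200 random trees of ≤12 leaves, K2P against the closed
form to 1e-12 on a (P, Q) grid, and the age-contrast experiment on 20 seeded
replicates of the extended preset (~47 species, ~120 accessions, 3283
aligned columns each). The two-tip sequence-simulation expectation is tested
at 200 replicates within three standard errors.

## Known limitations

- NJ on strongly non-additive matrices (saturation, heavy missingness) can
  misplace long branches; this is a property of the method being evaluated,
  not a defect of the implementation, and it is why mode-A results with
  rate-heterogeneous loci can fall below mode-B results.
- The group-level 50 % rule counts a species as "assigned" if any accession
  falls in the exclusive clade; with strongly non-monophyletic species this
  is generous.
- Exact tree-shape agreement with other NJ implementations is not guaranteed
  under ties; only the distance-consistency properties are.
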