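# Methods

## Model and procedure

A cohort is a binary incidence matrix over samples and genes: entry 1 iff
the sample carries at least one protein-altering somatic variant in the
gene. "Protein-altering" is a fixed, configurable vocabulary of MAF
`Variant_Classification` terms — missense, nonsense, nonstop,
frameshift/in-frame indels and translation-start changes count; silent,
intronic, UTR/flank, IGR, RNA and splice-site calls do not. Splice-site
events are excluded because the filter is deliberately exon/protein-centric;
callers wanting them can pass an extended vocabulary. Coordinates are
1-based (MAF convention), chromosome labels verbatim, and gene identity is
the raw symbol string with no alias resolution.

A sample is *covered* by an h-gene combination when it has a 1 in every one
of its genes. With tumors `T` (size `N_t`) and normals `N` (size `N_n`),
each candidate combination is scored by its confusion counts — covered
tumors TP, uncovered tumors FN, covered normals FP, uncovered normals TN —
and weighted by the inverse scaled accuracy

    w = (N_t + N_n) / (alpha * TP + TN)

with `alpha` in [0, 1]. `w` is +infinity when the denominator is zero (a
combination covering no tumor and every normal is useless). The discovery
problem is a weighted set cover: the training tumor set is the universe,
each combination's covered-tumor set is a weighted subset, and we want a
minimum-total-weight cover. The greedy approximation iterates: score all
candidates on the currently *active* samples, select the minimum-weight
candidate, retire the samples it covers, stop when no active tumor remains.
All totals in the weight (`N_t`, `N_n`, TP, TN) are recomputed over active
samples each iteration.

Design choices made where the procedure was genuinely open:

* **Normal retirement.** Covered normal samples are retired along with
  covered tumors (default). The alternative reading — normals stay active
  forever — is preserved behind `GreedyConfig.exclude_covered_normals=False`.
* **Tie-breaking.** Among minimum-weight candidates: larger TP first, then
  the lexicographically smallest gene tuple. This is deterministic and
  independent of input row/column order, which a test verifies by permuting
  both.
* **Candidate pruning.** Only tuples covering at least one active tumor are
  scored. This is exact, not an approximation: a TP=0 tuple can never
  shrink the uncovered set. Candidates are enumerated from the mutated gene
  sets of active tumors, so enumeration cost scales with observed mutation
  load rather than with `C(G, h)`.
* **Degenerate inputs.** A tumor with fewer than h mutated genes can never
  be covered; such samples are reported as uncoverable and the run returns
  a partial cover instead of looping. A cohort with no tumors yields an
  empty solution. If every remaining candidate has infinite weight
  (possible only at alpha = 0 with no active normals), the greedy still
  selects by the tie rule so the coverage guarantee holds; the brute-force
  oracle (`exhaustive_best_step`) instead raises, since as a test oracle it
  must flag the boundary.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `alpha` | weight-function trade-off between covering tumors (TP) and sparing normals (TN); dimensionless in [0, 1] | 0.1 | training sensitivity is already forced to 1.0 by the cover loop, so the weight mostly guards specificity; 0.1 keeps a mild pull toward high-TP candidates |
| `h` | genes per combination | 2 | candidate counts grow as `C(G, h)`; h >= 3 at genome scale is computationally out of reach, and 2-hit pairs already separate cohorts well |
| `train_fraction` | stratified training share | 0.75 | conventional 75/25 hold-out; tumors and normals split independently |
| `exclude_covered_normals` | retire covered normals between iterations | true | see above |
| correlation threshold | flag in-combination gene pairs as correlated | 0.25 | below this the pair is treated as independent evidence rather than a shared-cause artifact |

Evaluation: a sample is predicted tumor iff it is covered by at least one
selected combination. Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)
carry 95% Wilson score intervals (no continuity correction); display
rounding is half-up to integer percent, machine outputs keep raw
proportions. A cohort with no tumors reports sensitivity as missing, never
as 0. Aggregation across cohorts sums confusion counts first; note that a
Wilson interval of summed counts is not the same object as any average of
per-cohort intervals, and the package only ever reports the former.

## The synthetic-data generator

`PlantedModel` emulates the structure the discovery step assumes: `K`
disjoint h-gene combinations are planted; each tumor receives one (chosen by
the assignment weights, uniform by default) and a second with probability
`p_multi`; every sample, tumor and normal, additionally gets independent
background (passenger) mutations at per-gene rate `p_bg`. Defaults —
G = 60 genes, K = 5 pairs, 80 tumors, 60 normals, p_bg = 0.05,
p_multi = 0.2 — describe a desk-scale cohort in which every tumor is
coverable and passengers are sparse but present; p_multi = 0.2 is a mild
version of the multiple-combination regime seen in real tumors. Gene
columns mutated in no sample are dropped, and samples are emitted in sorted
order, so a simulated cohort round-trips exactly through MAF serialisation
and matrix rebuilding.

What the generator does **not** model: mutational signatures or any
gene–gene dependence in the background, hypermutator samples, copy-number
or structural events, germline variants, and per-position hotspot structure
(MAF serialisation assigns one synthetic locus per gene). Consequently,
passing tests show the algorithm recovers planted combinatorial signal
under independent noise; they do not show robustness to correlated
backgrounds or to variant-calling artifacts in real cohorts.

## Post-hoc analyses

* **Correlation.** Pearson r between the binary mutation vectors of the two
  genes of each combination, over normal samples by default (the cohort
  where a correlation would indicate a shared non-carcinogenic cause).
  Zero-variance vectors make r undefined; it is reported as missing, never
  coerced to 0.
* **Co-location.** A combination is flagged when all its genes share a
  chromosome label; genes missing from the location table mark the
  combination unknown and drop it from the summary count.
* **Occurrence and overlap.** Per-combination fraction of tumors covered
  (fractions may sum past 1), the combinations-per-tumor histogram, and the
  fraction of tumors carrying >= 2 combinations — the signature that 2-hit
  pairs may be faces of deeper combinations.
* **Locus contrast.** Within the samples covered by one combination,
  per-position variant counts for one gene are tabulated separately for
  tumors and normals; tumor-exclusive positions are candidate drivers,
  positions mutated in both cohorts candidate passengers. Positions are
  (chromosome, 1-based genomic position) pairs — a stated proxy for protein
  residue positions, since consequence re-annotation is out of scope.

## Problem sizes and numerical notes

The exact candidate count `sum_{c=2}^{h} C(G, c)` is exposed as
`search_space_size` (Python integers, no overflow): ~6x10^29 for
G = 20000, h = 8, and a greedy work bound `N*M` of ~4x10^10 for N = 200 at
h = 2 — the arithmetic behind restricting practical runs to h = 2. Tests
and the acceptance script run the full pipeline on cohorts of 140 samples
x 60 genes and brute-force oracle checks on <= 12-gene instances; these
sizes exercise every code path while keeping the whole suite around a few
seconds. Weight comparisons are exact float comparisons; ties are resolved
combinatorially (TP, then gene tuple), never by float tolerance.

## Known limitations

* Per-gene granularity: a gene with only passenger variants still counts as
  mutated; the locus-contrast report is a manual aid, not an automatic
  filter.
* The greedy cover is near-optimal, not optimal; different training splits
  can select different low-frequency combinations even when headline
  accuracy is stable.
* h >= 3 is supported by the API but not practical at genome scale in this
  single-threaded implementation.
* No gene pre-filter (e.g. minimum tumor frequency) is applied before
  enumeration by default.
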