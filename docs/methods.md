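# Methods

## Model and assumptions

`dartf` treats differential chromatin accessibility as a binary, region-level
signal. No read counts are modelled: a condition's accessible chromatin is
the set-theoretic intersection of its replicate peak calls, and a DAR is an
accessible region *exclusive* to one group (zero bp overlap against every
accessible region of the other group). This mirrors analyses that pipe
MACS2 peak BEDs through BEDtools rather than fitting a count model; the
trade-off is that regions accessible in both groups but with quantitatively
different openness are invisible to the method.

Coordinates are BED-native 0-based half-open everywhere; there is no
conversion layer. `[10, 20)` and `[20, 30)` do not overlap. Chromosome
names match as exact strings ("chr1" ≠ "1"); an optional normalization maps
bare names to the "chr" dialect. Overlapping peaks within one peak set are
*not* merged before counting: merging would change overlap counts relative
to raw peak-caller output. Replicate intersection is bp-level (maximal
sub-intervals covered in every replicate), not a per-peak vote, and is
applied to each group independently whatever the replicate-count imbalance.

## Enrichment statistics

"Number of intersects" is the count of *query regions* with ≥ 1 bp overlap
against ≥ 1 library peak — binary per query. This is forced by the 2×2
design: each DAR must be classified overlapping/non-overlapping exactly
once or the table margins (a+b = #opened, c+d = #closed) would not be fixed
across experiments.

The two-sided Fisher p-value sums hypergeometric point probabilities
≤ that of the observed table; the comparison carries a 10⁻⁷ relative
tolerance so floating-point noise cannot misclassify equal-probability
tables (scipy's convention, validated in the tests against exact integer
enumeration). A degenerate margin returns p = 1 with a warning. BH
adjustment spans all experiments of one `enrich` call — one condition
against one library, the family a single enrichment submission would form;
the family is not configurable because no other family is visible to the
tool.

Enrichment score = min(−log₁₀ Q, `score_cap`). The cap (default 500)
keeps ranking and "maximum score" statistics finite when Q underflows.
Fold enrichment is log₂[((a+0.5)/(a+b+0.5)) / ((c+0.5)/(c+d+0.5))]: the
+0.5 smoothing keeps it finite when either overlap count is zero, while
p-values always use raw counts. One caveat: with extremely unequal margins
and near-zero counts the smoothing can flip the sign relative to the raw
rate ratio (e.g. a=1/b=999 vs c=0/d=10); margins are equal-by-construction
within a run, where the sign tracks the raw rates whenever they differ.
Antigen collapse keeps the highest-scoring experiment per antigen, with
deterministic tie-breaks (larger |log₂FE|, then smallest experiment ID).

## Triads and evaluation

Antigen/gene symbols match exactly after uppercasing ("Pparg" ↔ "PPARG");
no ortholog mapping is attempted because none can be inferred from symbol
tables alone. Cells with no linking TF score 0 rather than being dropped,
so every condition contributes a complete score vector; the disease
columns are the associated diseases reachable from ≥ 1 condition plus any
disease named in the evaluation standard. TF ties at the maximal score
resolve to the lexicographically smallest symbol.

The per-condition negative set is "diseases scored but not curated for
this condition" over the shared matrix columns. AUROC uses tie-aware
Mann–Whitney (ties as a block); AUPR is the PR step-curve area via a
descending-threshold sweep, whose random baseline is the positive
prevalence. Conditions with zero positives or zero negatives are excluded
from per-condition means (and logged) but their cells remain in the merged
global vector as negatives. Method comparison uses the unpaired two-tailed
Wilcoxon rank-sum test — exact enumeration for tie-free groups of ≤ 20,
tie-corrected normal approximation otherwise — with Bonferroni
multiplication clamped at 1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `peak_score_threshold` | 100 | BED score filter; 100 ≡ MACS2 Q ≤ 10⁻¹⁰ under int(−10·log₁₀ Q) |
| `flank` | 5000 bp | TSS window half-width for gene-list (DEG) mode, symmetric about the TSS regardless of strand |
| `score_cap` | 500 | upper bound on −log₁₀ Q and on &#124;log₂FE&#124; |
| `cell_type_class_filter` | none | optional library restriction before enrichment |

## Synthetic data

The generator emulates, at desk scale, a perturbation study built from
peak BEDs: planted opened/closed DAR loci plus a shared accessible
background on a toy genome (default 2 × 5 Mb), 2 replicates per group with
±50 bp edge jitter, and a 10-TF × 2-experiment library in which planted
TFs cover opened loci with probability p_fg = 0.9 and everything else is
covered at p_bg = 0.1, plus 200 uniform decoy peaks per experiment and
scores drawn at/above the default filter threshold. Loci are placed with
> 2 × jitter separation so jitter can never merge loci across groups, and
`dar_width > 2 × jitter` guarantees replicate intersections stay nonempty
— hence zero-jitter runs recover the planted loci exactly and jittered
runs recover them up to edge shrinkage. Each generator stage draws from
its own stream seeded as (master seed, stage offset), so outputs are
byte-deterministic and changing e.g. `n_tfs` does not move the DAR
placement. Truth records are serialized next to the fixtures so tests
never re-derive ground truth from generator internals.

Association tables: every TF gets a base link to a dedicated disease;
planted TFs' diseases form the condition's standard positives and
non-planted TFs' diseases guarantee negative columns, so every condition
is evaluable. Noise links are drawn among non-planted TFs only — this
keeps the planted ground truth unambiguous (a noise link from a planted TF
would create a "false" positive that is actually correctly ranked),
at the cost of not modelling pleiotropy of true mediator TFs.

What the simulation does *not* emulate: read-level data, peak-width and
score distributions of real callers, chromosomal clustering of regulatory
elements, cell-type heterogeneity of the library, or disease-ontology
structure. Passing tests therefore demonstrate correctness of the interval
algebra, the statistics and the join/evaluation logic under planted
truth — not performance on real exposure data.

## Numerical and design choices

- p-values are validated in (0, 1]; q ≥ p and monotone along sorted p.
- All tabular outputs use fixed column orders and 6-significant-digit
  floats; outputs carry provenance sidecars (config hash + input SHA-256),
  making reruns byte-identical.
- Conditions with zero opened or zero closed DARs are carried to the
  enrichment stage, which refuses them with an explicit message rather
  than silently dropping them.
- Benchmark problem sizes (20 runs × 200 DARs/side × 20 experiments; one
  500-experiment null library) were chosen as the smallest configuration
  at which planted/non-planted score separation and null calibration are
  statistically unambiguous.

## Limitations

- The DAR definition is presence/absence only; dose–response and graded
  accessibility changes are out of scope.
- Symbol-level TF matching ignores orthology subtleties and TF complexes.
- The evaluation's negative set is the scored disease universe, which
  understates negatives relative to an all-diseases universe; AUPR values
  are therefore comparable within a run, not across universes.
- No liftover, no BAM/FASTQ handling, no peak calling, no motif analysis.
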