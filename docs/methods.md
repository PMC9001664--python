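# Methods

## Cell and clonotype model

A cell is identified by `(sample_id, barcode)`; barcodes are opaque
strings and are never suffix-stripped, because identical barcodes recur
across 10x libraries. Per cell, productive TRA/TRB contigs are kept and
sorted by UMI support (ties broken on `contig_id`) so that all downstream
keys are independent of file order. Cells with several productive chains
at a locus are counted and reported, but keyed on the highest-UMI chain
only — the Cell Ranger convention — so no cell ever contributes to two
clonotypes.

Clonotype key schemes: `nt_paired` (default; paired α+β CDR3 nucleotide
identity, the strictest reading of "identical α and β chains"),
`aa_paired`, `nt_paired_vj` (adds V/J gene names), `beta_nt_only`, and
`beta_aa_only` (used for CDR3β pooling). Under paired schemes, cells
missing either chain are unkeyed; clone frequencies are computed over
keyed cells only, so they always sum to 1 and are comparable across
schemes, while raw cell counts are reported alongside. An expanded clone
has ≥ 10 member cells; the threshold is a parameter everywhere.

Low-confidence contigs are excluded by default where the
`high_confidence` column exists (flag-controlled), since droplet V(D)J
pipelines flag them for a reason; inputs without the column are taken as
high confidence.

## Diversity statistics

- Gini: computed through the sorted identity
  G = (2 Σᵢ i·x₍ᵢ₎)/(n Σx) − (n+1)/n, equal to the pairwise-difference
  definition but O(n log n). No small-sample n/(n−1) correction by
  default (flag available).
- Shannon entropy defaults to log base 2 (configurable to natural log).
  Printed entropy magnitudes depend on the base, so cross-cohort
  comparisons here rely on orderings, not absolute values.
- Power-law fit: ordinary least squares through the log₁₀–log₁₀
  complementary CDF points, one point per distinct clone size — the
  fit that matches how such distributions are usually plotted. This
  estimator is known to be noisier than a maximum-likelihood fit; on
  truncated power-law repertoires of 5000 clones it recovers γ = 1.5
  with a mean error well inside ±0.15 (verified per run by the
  acceptance script). At least 3 distinct sizes are required; samples
  with fewer raise rather than returning a meaningless slope.
- Spectratype: CDR3 amino-acid length histogram of the representative
  chain, normalized within each subset label.

## Sharing and dynamics

Sharing counts distinct clonotype keys present in two samples, optionally
restricted to each sample's top-n clones (size-then-key tie-break, so the
cut is deterministic). The matrix diagonal holds each sample's own clone
count under the mode.

Dynamics classifies on *frequency*, not raw size, so unequal sequencing
depth between visits cannot masquerade as expansion; absolute cell-count
deltas are still reported per class. The ±20% band is closed
(|r| = 0.20 is "unchanged"). Emergent (absent pre) and lost (absent post)
clones never enter the three proportional classes — inventing a
proportional change from a zero baseline would be arbitrary — and are
tallied separately. The headline counts restrict to clones expanded at
either visit (flag lifts this).

## Convergence groups and motif enrichment

CDR3β sequences are trimmed (first 3 and last 2 residues removed) before
k-mer extraction, because the germline-encoded flanks are shared by
construction and carry no specificity signal. A k-mer (k = 2–4) is
enriched when (a) it occurs in at least 3 distinct sample CDR3s, (b) its
per-sequence frequency exceeds 10× the reference frequency, and (c) its
resampling tail probability — the add-one fraction of 1000 size-matched
draws (with replacement) from the reference whose motif count reaches the
observed count — is ≤ 0.001. The support floor (a) is essential with a
finite reference: without it any k-mer merely absent from the reference
would pass on a single occurrence, and the false-positive calibration
fails. Motifs absent from the reference get a continuity rate of
1/(2·n_ref) for the fold computation.

Groups are connected components of the graph whose edges join CDR3s
sharing an enriched motif or sitting at Hamming distance ≤ 1 at equal
length; components need strictly more than `min_members` (default 5)
distinct sequences, are named `CRG_` + most abundant member, and retain
per-edge evidence for audit. Per-group sample contributions report the
fraction of member cells from the five largest contributing samples,
restrictable (e.g. to pre-treatment samples).

The bundled reference repertoire is synthetic — drawn from the same CDR3
length/composition model with no planted motifs (fixed seed 12345) — and
is user-replaceable by a file of sequences. The CMVpp65 motif panel
(TGT, ATN, FQ, SSA, QTG) is scanned by substring on the *untrimmed* CDR3,
since the panel contains 2-mers that flank trimming could delete; the
Fisher exact test compares motif-bearing fractions between expanded
clones of CMV-seropositive subjects and all other clones.

## Embedding coupling

Distances are Euclidean in the embedding as provided (typically 2-D
t-SNE); the package never re-embeds. Group coherence uses the mean
pairwise distance among group cells against a null of equal-sized uniform
cell subsets (without replacement), with the add-one estimator
p = (1 + #{null ≤ obs})/(n_perm + 1); one-sided by default (coherence =
smaller distances), two-sided by flag. The add-one estimator is
conservative and never returns 0.

The Damerau-Levenshtein distance is the optimal-string-alignment variant
(substitution, insertion, deletion, adjacent transposition at unit cost;
a transposed pair is not re-edited). OSA can violate the triangle
inequality; it is used only as a dissimilarity, never as a metric.
Sequence–embedding correlation defaults to Spearman on a seeded random
sample of cell pairs.

Mixing entropy is the per-cell Shannon entropy of batch labels among the
k = 30 nearest neighbours (self excluded), normalized by log of the
number of batches; it is invariant to batch renaming and embedding
isometries by construction.

## Synthetic cohort generator

The generator emulates exactly the structure the analyses assume, and no
more:

- Clone sizes: truncated discrete power law, P(X ≥ x) ∝ x^(−γ),
  default γ = 1.5, truncation at `max_clone_size`.
- Chains: per cell, α detected with probability 0.61 and β with 0.95 —
  the median per-sample detection rates reported for droplet scTCR-seq —
  with extra productive chains at rates 0.10 (α) and 0.05 (β). Cells
  losing both chains stay in the truth's total-cell count but emit no
  contig rows, mirroring real `filtered_contig_annotations.csv` files.
- CDR3s: "C" + i.i.d. uniform interior + "F", lengths Normal(14, 1.5)
  clipped to [8, 22]; no V(D)J recombination model, since the analyses
  depend only on clone structure, motifs and lengths. Nucleotide CDR3s
  use deterministic first-codon back-translation, so nt- and aa-level
  identity coincide in synthetic data while the key schemes still
  exercise both code paths.
- Planted motifs are inserted at a random offset *within the trimmed
  interior* (planted CDR3s are drawn long enough to hold motif plus
  flanks). Planting into the trimmed-off flanks would create truth the
  motif stage cannot see by definition, voiding recovery tests.
- Timepoints: each clone draws a class from the configured mixture
  (defaults — increased: ×1.5–3, unchanged: ×0.95–1.05, decreased:
  ×0.2–0.7) and a fold change from that class's range. Because
  frequencies renormalise, the drawn size fold and the realized frequency
  change can disagree near the ±20% boundary, so the truth records both
  the drawn `intended_class` and the realized frequency-based
  `dynamics_class` computed from true sizes; recovery tests compare
  pipeline output to the latter, which is the quantity the pipeline
  defines. The unchanged default range is ×0.95–1.05 (not the wider
  ×0.9–1.1) so that integer rounding of small clones cannot push a
  drawn-unchanged clone past the boundary for reasons unrelated to the
  classifier.
- Embedding: clone centers ~ N(0, σ²_between·I), cells ~ N(center,
  σ²_within·I); σ_between = 0 is the null mode with no clone–embedding
  association. Batch = sample.
- Cross-subject sharing defaults to 0 (private clones, as observed in
  clonal lymphoproliferations) and is raised only in sharing tests.

One `numpy` generator seeded from `SimConfig.seed` drives the first
visit; the timepoint and embedding stages derive independent streams from
the same seed, so adding a visit or an embedding never perturbs
already-generated data, and identical configs are byte-identical on disk.

### What the generator does not emulate

Real V(D)J recombination biases, convergent recombination at the
nucleotide level, UMI/read noise, doublets, ambient contigs, or any
transcriptome content (the embedding is a geometric stand-in, not
expression data). Tests passing on synthetic cohorts therefore validate
the statistical machinery — estimator correctness, calibration,
recovery — not robustness to those artefacts in real data.

## Problem sizes in tests and the acceptance script

Recovery and calibration runs use cohorts of 80–8000 clones per subject
(≈ 20,000 cells for the dropout-recovery check, matching the scale at
which a ±0.02 binomial tolerance is meaningful), 10–20 seeds for
mean/rate estimates, 199–1000 permutations/resamples for the permutation
and resampling tests, and 500 trials for rejection-rate calibration.
These sizes keep every Monte-Carlo band several standard errors wide at
desk scale.

## Known limitations

- OLS-on-CCDF slope estimation is biased for heavy truncation and small
  repertoires; an MLE fit is deliberately out of scope.
- The two-sided Fisher exact test is conservative for small tables; its
  empirical size approaches the nominal level only with hundreds of
  clones per margin.
- CRG construction is quadratic in the number of pooled distinct CDR3s
  within a motif's carrier set; intended for top-500-per-sample pools,
  not whole repertoires.
- The clinical cohort statistics this package is designed around (e.g.
  patient-vs-control Gini/entropy orderings) are reproduced here
  directionally on synthetic cohorts; absolute published magnitudes
  depend on the underlying patient data and unreported parameters.
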