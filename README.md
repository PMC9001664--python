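# tcrclonics

Single-cell TCR repertoire analysis for paired-chain (scTCR-seq) data:
clonotype calling, clonality and diversity statistics, cross-sample
clonotype sharing, longitudinal clone dynamics, GLIPH-style CDR3
convergence groups with motif enrichment, and tests coupling TCR identity
to a transcriptome embedding. A fully seeded synthetic-cohort generator
with exported ground truth backs every analysis with recovery tests.

## Who this is for

Groups studying clonal T-cell expansions — for example T-cell large
granular lymphocyte leukemia (T-LGLL), where a handful of CD8+ cytotoxic
clones dominate the repertoire — who have per-sample 10x Cell Ranger
`filtered_contig_annotations.csv` (or AIRR Rearrangement TSV) output and
want reproducible repertoire statistics without touching raw reads.

## The statistics at the core

A **clonotype** is the set of cells sharing identical TCR sequence under a
key scheme; the default keys cells on the paired α+β nucleotide CDR3, and
an **expanded clone** has ≥ 10 member cells. From the clone-size vector
x₁…x_n the package computes:

- **Gini index** G = Σᵢⱼ|xᵢ − xⱼ| / (2n²x̄) ∈ [0, 1): 0 for a perfectly
  even repertoire, → 1 under single-clone dominance.
- **Shannon entropy** H = −Σ pᵢ log₂ pᵢ with pᵢ = xᵢ/Σx: higher = more
  diverse; H = log₂ n for n equal clones.
- **Top-3 fraction**: summed frequency of the three largest clones.
- **Power-law slope**: OLS fit to the log–log complementary CDF
  (log₁₀ P(X ≥ x) vs log₁₀ x); a repertoire with P(X ≥ x) ∝ x^(−γ) yields
  slope −γ, and more clonal repertoires have shallower (less negative) γ.
- **Clone dynamics** between paired visits: each clone's relative
  frequency change r = (f_post − f_pre)/f_pre is classified as increased
  (r > +0.20), unchanged (|r| ≤ 0.20) or decreased (r < −0.20); clones
  seen at only one visit are emergent or lost.
- **Convergence groups (CRGs)**: distinct CDR3β amino-acid sequences
  linked when they share a k-mer (k = 2–4) enriched ≥ 10-fold over a
  reference repertoire at a resampling tail probability ≤ 0.001, or are
  equal-length at Hamming distance ≤ 1; connected components with more
  than five member sequences are reported, GLIPH-style.
- **Embedding coupling**: a permutation test on mean pairwise embedding
  distance within a clone/CRG, Spearman correlation between
  Damerau-Levenshtein CDR3 distance and embedding distance, and a
  k-nearest-neighbour batch-mixing entropy.

## Worked example

Simulate a two-subject, two-visit cohort and run the pipeline end to end:

```python
from tcrclonics import (SimConfig, generate_repertoire, generate_timepoints,
                        records_from_frame, build_cell_chains, call_clonotypes,
                        call_expanded, diversity_metrics, match_clones,
                        dynamics_summary)

cfg = SimConfig(seed=7, n_subjects=2, clones_per_subject=300,
                ccdf_exponent=1.0, max_clone_size=500)
cohort = generate_timepoints(generate_repertoire(cfg))

tables = {}
for sample_id, frame in cohort.contig_tables.items():
    cells = build_cell_chains(records_from_frame(frame), sample_id=sample_id)
    tables[sample_id] = call_clonotypes(cells, "nt_paired", sample_id=sample_id)

for sample_id in sorted(tables):
    t = tables[sample_id]
    m = diversity_metrics(t)
    n_exp = len(call_expanded(t, 10))
    print(f"{sample_id}: {t.n_clones} clonotypes, {t.n_keyed_cells} paired cells, "
          f"{n_exp} expanded; G={m.gini:.3f} H={m.shannon:.2f} "
          f"top3={m.top3_fraction:.3f} slope={m.powerlaw_slope:.2f}")

records = match_clones(tables["S01_pre"], tables["S01_post"], subject_id="S01")
s = dynamics_summary(records)
print("S01 expanded-clone dynamics:",
      {k: s[k]["count"] for k in ("increased", "unchanged", "decreased")},
      "emergent:", s["emergent"], "lost:", s["lost"])
```

prints

```
S01_post: 237 clonotypes, 1030 paired cells, 20 expanded; G=0.645 H=6.42 top3=0.226 slope=-1.11
S01_pre: 230 clonotypes, 979 paired cells, 16 expanded; G=0.661 H=6.04 top3=0.348 slope=-1.06
S02_post: 229 clonotypes, 1845 paired cells, 25 expanded; G=0.789 H=5.14 top3=0.486 slope=-0.86
S02_pre: 228 clonotypes, 1395 paired cells, 20 expanded; G=0.746 H=5.42 top3=0.452 slope=-0.92
S01 expanded-clone dynamics: {'increased': 12, 'unchanged': 4, 'decreased': 8} emergent: 49 lost: 42
```

With γ = 1.0 the repertoires are strongly clonal: Gini ≈ 0.65–0.79,
entropy well below log₂(n_clones) ≈ 7.9, and 16–25 expanded clones per
sample. Only cells with both a detected α and β chain are keyed (the
generator drops chains at the realistic rates of 0.39 for α and 0.05 for
β, which is why ~1000 of ~1700 sequenced cells are paired). The dynamics
counts restrict to clones expanded at either visit; emergent/lost clones
are tallied separately.

The same stages are available from a shell via the `tcrclonics` CLI
(`simulate`, `clonotype`, `diversity`, `sharing`, `dynamics`, `crg`,
`motifscan`, `coupling`, `mixing`); run `tcrclonics --help`.

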