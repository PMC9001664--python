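import numpy as np
import pandas as pd
import pytest

from tcrclonics.clonotyping import (
    build_cell_chains,
    call_clonotypes,
    call_expanded,
    chain_detection_summary,
)
from tcrclonics.coupling import seq_embed_correlation
from tcrclonics.io import read_contig_table, translate
from tcrclonics.sharing import match_clones, sharing_matrix
from tcrclonics.simulate import (
    PlantedMotif,
    SimConfig,
    back_translate,
    generate_embedding,
    generate_repertoire,
    generate_timepoints,
    write_cohort,
)


def tables_from_cohort(cohort, tmp_path, scheme="nt_paired"):
    """Run the cohort's contig tables through the real parsing path."""
    write_cohort(cohort, tmp_path)
    tables = {}
    for sample_id in cohort.contig_tables:
        recs = read_contig_table(tmp_path / f"{sample_id}.csv", "tenx_csv")
        cells = build_cell_chains(recs, sample_id=sample_id)
        tables[sample_id] = call_clonotypes(cells, scheme, sample_id=sample_id)
    return tables


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=42, n_subjects=2, clones_per_subject=40,
                        max_clone_size=100)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            cohort = generate_repertoire(SimConfig(**vars(cfg)))
            generate_timepoints(cohort)
            generate_embedding(cohort)
            write_cohort(cohort, d)
        for f in sorted(p.name for p in d1.iterdir() if p.is_file()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f
        assert (d1 / "truth/clones.tsv").read_bytes() == \
            (d2 / "truth/clones.tsv").read_bytes()

    def test_different_seeds_differ(self):
        c1 = generate_repertoire(SimConfig(seed=1, n_subjects=1,
                                           clones_per_subject=30))
        c2 = generate_repertoire(SimConfig(seed=2, n_subjects=1,
                                           clones_per_subject=30))
        k1 = {c.cdr3_nt_beta for c in c1.truth.clones}
        k2 = {c.cdr3_nt_beta for c in c2.truth.clones}
        assert k1 != k2


class TestRepertoireStructure:
    def test_back_translation_round_trips(self):
        for aa in ("CASSPGTNYGYTF", "CF", "CWAMF"):
            assert translate(back_translate(aa)) == aa

    def test_nt_and_aa_consistent_in_output(self, dropout_free_cohort):
        table = next(iter(dropout_free_cohort.contig_tables.values()))
        for r in table.itertuples(index=False):
            assert translate(r.cdr3_nt) == r.cdr3

    def test_detection_fractions_near_config(self, tmp_path):
        cfg = SimConfig(seed=11, n_subjects=1, clones_per_subject=2500,
                        max_clone_size=500)
        cohort = generate_repertoire(cfg)
        (sample_id,) = cohort.contig_tables
        write_cohort(cohort, tmp_path)
        recs = read_contig_table(tmp_path / f"{sample_id}.csv")
        cells = build_cell_chains(recs, sample_id=sample_id)
        s = chain_detection_summary(cells, cohort.truth.n_total_cells[sample_id])
        assert s.f_ge1_alpha == pytest.approx(0.61, abs=0.03)
        assert s.f_ge1_beta == pytest.approx(0.95, abs=0.03)
        assert s.f_paired == pytest.approx(0.61 * 0.95, abs=0.03)

    def test_planted_motif_lands_in_beta_interior(self):
        cfg = SimConfig(seed=5, n_subjects=1, clones_per_subject=100,
                        planted_motifs=[PlantedMotif("PGTN", 8, stratum="any")])
        cohort = generate_repertoire(cfg)
        planted = [c for c in cohort.truth.clones if c.planted_motif == "PGTN"]
        assert len(planted) == 8
        assert all("PGTN" in c.cdr3_aa_beta for c in planted)

    def test_motif_longer_than_interior_rejected(self):
        cfg = SimConfig(seed=5, cdr3_length_max=22,
                        planted_motifs=[PlantedMotif("P" * 20, 2)])
        with pytest.raises(ValueError, match="motif"):
            cfg.validate()

    def test_planted_motif_survives_flank_trimming(self):
        from tcrclonics.motifs import trim_cdr3
        cfg = SimConfig(seed=5, n_subjects=1, clones_per_subject=100,
                        planted_motifs=[PlantedMotif("PGTN", 10, stratum="any")])
        cohort = generate_repertoire(cfg)
        planted = [c for c in cohort.truth.clones if c.planted_motif == "PGTN"]
        assert all("PGTN" in trim_cdr3(c.cdr3_aa_beta) for c in planted)

    def test_cross_subject_overlap_zero_keeps_clones_private(
            self, dropout_free_cohort, tmp_path):
        tables = tables_from_cohort(dropout_free_cohort, tmp_path)
        m = sharing_matrix(list(tables.values()), mode="all_clones")
        off_diag = m.matrix[~np.eye(len(tables), dtype=bool)]
        assert (off_diag == 0).all()

    def test_cross_subject_overlap_produces_sharing(self, tmp_path):
        cfg = SimConfig(seed=9, n_subjects=2, clones_per_subject=100,
                        cross_subject_overlap=0.3,
                        p_alpha_detect=1.0, p_beta_detect=1.0,
                        p_multi_alpha=0.0, p_multi_beta=0.0)
        cohort = generate_repertoire(cfg)
        tables = tables_from_cohort(cohort, tmp_path)
        m = sharing_matrix(list(tables.values()), mode="all_clones")
        assert m.matrix[0, 1] > 0


class TestTruthSufficiency:
    def test_expanded_set_matches_truth_without_dropout(
            self, dropout_free_cohort, tmp_path):
        tables = tables_from_cohort(dropout_free_cohort, tmp_path)
        for subj in dropout_free_cohort.truth.subjects:
            table = tables[f"{subj}_pre"]
            expected = dropout_free_cohort.truth.expanded_keys(subj, "pre")
            assert call_expanded(table, 10) == expected

    def test_dynamics_classes_match_realized_truth(self, tmp_path):
        cfg = SimConfig(seed=13, n_subjects=2, clones_per_subject=50,
                        max_clone_size=200,
                        p_alpha_detect=1.0, p_beta_detect=1.0,
                        p_multi_alpha=0.0, p_multi_beta=0.0)
        cohort = generate_timepoints(generate_repertoire(cfg))
        tables = tables_from_cohort(cohort, tmp_path)
        for subj in cohort.truth.subjects:
            records = match_clones(tables[f"{subj}_pre"], tables[f"{subj}_post"],
                                   subject_id=subj)
            expected = cohort.truth.realized_dynamics(subj)
            got = {r.key: r.dynamics_class for r in records}
            assert got == expected

    def test_all_unchanged_mixture_yields_no_expansion_calls(self, tmp_path):
        cfg = SimConfig(seed=17, n_subjects=1, clones_per_subject=40,
                        max_clone_size=200,
                        p_alpha_detect=1.0, p_beta_detect=1.0,
                        p_multi_alpha=0.0, p_multi_beta=0.0,
                        dynamics_mixture={"unchanged": (1.0, 1.0, 1.0)})
        cohort = generate_timepoints(generate_repertoire(cfg))
        tables = tables_from_cohort(cohort, tmp_path)
        records = match_clones(tables["S01_pre"], tables["S01_post"],
                               subject_id="S01")
        classes = {r.dynamics_class for r in records}
        assert classes == {"unchanged"}

    def test_no_emergent_without_emergent_rate(self, tmp_path):
        cfg = SimConfig(seed=19, n_subjects=1, clones_per_subject=40,
                        p_alpha_detect=1.0, p_beta_detect=1.0,
                        p_multi_alpha=0.0, p_multi_beta=0.0)
        cohort = generate_timepoints(generate_repertoire(cfg))
        tables = tables_from_cohort(cohort, tmp_path)
        records = match_clones(tables["S01_pre"], tables["S01_post"],
                               subject_id="S01")
        assert all(r.dynamics_class != "emergent" for r in records)


class TestEmbedding:
    def test_null_mode_has_no_seq_embed_association(self, tmp_path):
        cfg = SimConfig(seed=23, n_subjects=1, clones_per_subject=150,
                        max_clone_size=50, sigma_between=0.0, sigma_within=1.0,
                        p_alpha_detect=1.0, p_beta_detect=1.0,
                        p_multi_alpha=0.0, p_multi_beta=0.0)
        cohort = generate_repertoire(cfg)
        emb = generate_embedding(cohort)
        cells = []
        for sample_id, table in cohort.contig_tables.items():
            seen = {}
            for r in table.itertuples(index=False):
                if r.chain == "TRB":
                    seen[r.barcode] = r.cdr3
            cells.extend(((sample_id, bc), aa) for bc, aa in seen.items())
        r, _ = seq_embed_correlation(emb, cells, n_pairs=50_000, seed=0)
        assert abs(r) < 0.05

    def test_separated_clone_centers_give_positive_association(self):
        cfg = SimConfig(seed=29, n_subjects=1, clones_per_subject=60,
                        max_clone_size=80, sigma_between=10.0, sigma_within=0.5,
                        p_alpha_detect=1.0, p_beta_detect=1.0,
                        p_multi_alpha=0.0, p_multi_beta=0.0)
        cohort = generate_repertoire(cfg)
        emb = generate_embedding(cohort)
        cells = []
        for sample_id, table in cohort.contig_tables.items():
            seen = {}
            for r in table.itertuples(index=False):
                if r.chain == "TRB":
                    seen[r.barcode] = r.cdr3
            cells.extend(((sample_id, bc), aa) for bc, aa in seen.items())
        r, p = seq_embed_correlation(emb, cells, n_pairs=20_000, seed=0)
        assert r > 0.2 and p < 1e-6

    def test_embedding_covers_contig_bearing_cells(self, dropout_free_cohort):
        emb = generate_embedding(dropout_free_cohort)
        n_cells = sum(t["barcode"].nunique()
                      for t in dropout_free_cohort.contig_tables.values())
        assert len(emb) == n_cells
        assert {"barcode", "sample_id", "dim_1", "dim_2", "batch"} <= set(emb.columns)
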