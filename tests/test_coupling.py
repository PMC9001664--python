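import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrclonics.coupling import (
    damerau_levenshtein,
    group_coherence,
    mixing_entropy,
    seq_embed_correlation,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def osa_oracle(a, b):
    """Independent recursive optimal-string-alignment definition."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


class TestDamerauLevenshtein:
    def test_identity(self):
        assert damerau_levenshtein("CASSL", "CASSL") == 0

    def test_adjacent_transposition_costs_one(self):
        assert damerau_levenshtein("CA", "AC") == 1
        assert damerau_levenshtein("CASSL", "CASLS") == 1

    def test_empty_string_distance_is_other_length(self):
        assert damerau_levenshtein("", "CASS") == 4
        assert damerau_levenshtein("CASS", "") == 4

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            a = "".join(rng.choice(list(AA), size=rng.integers(0, 19)))
            b = "".join(rng.choice(list(AA), size=rng.integers(0, 19)))
            assert damerau_levenshtein(a, b) == osa_oracle(a, b), (a, b)

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=AA, min_size=0, max_size=15),
           st.text(alphabet=AA, min_size=0, max_size=15))
    def test_symmetry_and_identity_of_indiscernibles(self, a, b):
        assert damerau_levenshtein(a, b) == damerau_levenshtein(b, a)
        assert (damerau_levenshtein(a, b) == 0) == (a == b)

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=AA, min_size=2, max_size=15),
           st.randoms(use_true_random=False))
    def test_single_edit_changes_distance_by_at_most_one(self, s, rnd):
        pos = rnd.randrange(len(s))
        kind = rnd.choice(["sub", "ins", "del", "swap"])
        if kind == "sub":
            edited = s[:pos] + rnd.choice(AA) + s[pos + 1:]
        elif kind == "ins":
            edited = s[:pos] + rnd.choice(AA) + s[pos:]
        elif kind == "del":
            edited = s[:pos] + s[pos + 1:]
        else:
            pos = min(pos, len(s) - 2)
            edited = s[:pos] + s[pos + 1] + s[pos] + s[pos + 2:]
        assert damerau_levenshtein(s, edited) <= 1


def make_embedding(coords, batches=None, sample_id="s1"):
    n = len(coords)
    df = pd.DataFrame({
        "barcode": [f"bc{i}" for i in range(n)],
        "sample_id": [sample_id] * n,
    })
    for d in range(coords.shape[1]):
        df[f"dim_{d + 1}"] = coords[:, d]
    df["batch"] = batches if batches is not None else ["b1"] * n
    return df


class TestGroupCoherence:
    def test_planted_tight_cluster_gets_minimal_p(self, rng):
        cloud = rng.normal(0, 1, size=(300, 2))
        cluster = rng.normal([50, 50], 0.01, size=(10, 2))
        emb = make_embedding(np.vstack([cloud, cluster]))
        cells = [("s1", f"bc{i}") for i in range(300, 310)]
        res = group_coherence(emb, cells, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_identical_coordinates_give_zero_observed(self, rng):
        cloud = rng.normal(0, 1, size=(50, 2))
        cloud[:3] = [7.0, 7.0]
        emb = make_embedding(cloud)
        res = group_coherence(emb, [("s1", "bc0"), ("s1", "bc1"), ("s1", "bc2")],
                              n_perm=99, seed=1)
        assert res.observed_mean_distance == 0.0
        assert res.p_value == pytest.approx(1 / 100)

    def test_missing_cells_listed(self, rng):
        emb = make_embedding(rng.normal(size=(20, 2)))
        with pytest.raises(KeyError, match="ghost"):
            group_coherence(emb, [("s1", "bc0"), ("s1", "bc1"), ("s1", "ghost")])

    def test_too_small_group_rejected(self, rng):
        emb = make_embedding(rng.normal(size=(20, 2)))
        with pytest.raises(ValueError):
            group_coherence(emb, [("s1", "bc0"), ("s1", "bc1")])

    def test_null_p_values_approximately_uniform(self, rng):
        """Random groups from the cloud reject at ~alpha (validity)."""
        rejections = 0
        n_trials = 200
        cloud = rng.normal(0, 1, size=(250, 2))
        emb = make_embedding(cloud)
        for t in range(n_trials):
            members = rng.choice(250, size=8, replace=False)
            cells = [("s1", f"bc{i}") for i in members]
            res = group_coherence(emb, cells, n_perm=199, seed=int(t))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_trials <= 0.09


class TestSeqEmbedCorrelation:
    def test_two_clone_structure_gives_rank_correlation_one(self):
        coords = np.array([[0.0, 0.0]] * 5 + [[10.0, 0.0]] * 5)
        emb = make_embedding(coords)
        cells = ([(("s1", f"bc{i}"), "CASSAAAAF") for i in range(5)]
                 + [(("s1", f"bc{i}"), "CWWWWWWWWWWF") for i in range(5, 10)])
        r, _ = seq_embed_correlation(emb, cells, n_pairs=2000, seed=0)
        assert r == pytest.approx(1.0)

    def test_clone_centered_embedding_positively_correlated(self, rng):
        # 20 clones, distinct CDR3s, well-separated centers
        centers = rng.normal(0, 20, size=(20, 2))
        coords, cells = [], []
        for k in range(20):
            cdr3 = "CAS" + "".join(rng.choice(list(AA), size=9)) + "F"
            for i in range(10):
                coords.append(centers[k] + rng.normal(0, 0.3, 2))
                cells.append((("s1", f"bc{k}_{i}"), cdr3))
        emb = make_embedding(np.array(coords))
        emb["barcode"] = [c[0][1] for c in cells]
        r, p = seq_embed_correlation(emb, cells, n_pairs=5000, seed=1)
        assert r > 0 and p < 0.01

    def test_shuffled_embedding_destroys_association(self, rng):
        centers = rng.normal(0, 20, size=(10, 2))
        coords, cells = [], []
        for k in range(10):
            cdr3 = "CAS" + "".join(rng.choice(list(AA), size=9)) + "F"
            for i in range(20):
                coords.append(centers[k] + rng.normal(0, 0.3, 2))
                cells.append((("s1", f"bc{k}_{i}"), cdr3))
        coords = np.array(coords)
        rng.shuffle(coords)
        emb = make_embedding(coords)
        emb["barcode"] = [c[0][1] for c in cells]
        r, _ = seq_embed_correlation(emb, cells, n_pairs=50_000, seed=2)
        assert abs(r) < 0.05

    def test_identical_cdr3s_rejected(self, rng):
        emb = make_embedding(rng.normal(size=(4, 2)))
        cells = [(("s1", f"bc{i}"), "CASSF") for i in range(4)]
        with pytest.raises(ValueError):
            seq_embed_correlation(emb, cells, n_pairs=10, seed=0)


class TestMixingEntropy:
    def test_interleaved_batches_score_high(self):
        # checkerboard: alternating batch labels on a grid
        xs, ys = np.meshgrid(np.arange(20), np.arange(20))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        batches = [("A" if (i + j) % 2 == 0 else "B")
                   for i, j in zip(xs.ravel(), ys.ravel())]
        emb = make_embedding(coords, batches)
        _, mean = mixing_entropy(emb, k_neighbors=30)
        assert mean >= 0.95

    def test_disjoint_clusters_score_low(self, rng):
        coords = np.vstack([rng.normal(0, 1, (100, 2)),
                            rng.normal([1000, 1000], 1, (100, 2))])
        batches = ["A"] * 100 + ["B"] * 100
        _, mean = mixing_entropy(make_embedding(coords, batches), k_neighbors=30)
        assert mean <= 0.05

    def test_random_labels_match_binomial_expectation(self, rng):
        coords = rng.normal(0, 1, size=(1500, 2))
        batches = list(rng.choice(["A", "B"], size=1500))
        _, mean = mixing_entropy(make_embedding(coords, batches), k_neighbors=30)
        # closed-form E[H(Binomial(k, 1/2)/k)] / log 2 for k = 30
        k = 30
        expect = 0.0
        for m in range(k + 1):
            pm = math.comb(k, m) * 0.5**k
            if 0 < m < k:
                p = m / k
                expect += pm * (-(p * math.log2(p) + (1 - p) * math.log2(1 - p)))
        assert mean == pytest.approx(expect, abs=0.05)

    def test_invariant_to_label_renaming_and_isometry(self, rng):
        coords = rng.normal(0, 1, size=(200, 2))
        batches = list(rng.choice(["A", "B", "C"], size=200))
        emb = make_embedding(coords, batches)
        per1, m1 = mixing_entropy(emb, k_neighbors=15)
        renamed = make_embedding(coords + 100.0,
                                 [{"A": "Z", "B": "Q", "C": "A"}[b] for b in batches])
        per2, m2 = mixing_entropy(renamed, k_neighbors=15)
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert np.allclose(per1.to_numpy(), per2.to_numpy())

    def test_single_batch_rejected(self, rng):
        emb = make_embedding(rng.normal(size=(50, 2)), ["A"] * 50)
        with pytest.raises(ValueError):
            mixing_entropy(emb, k_neighbors=10)
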