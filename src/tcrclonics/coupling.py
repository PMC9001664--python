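"""Coupling between TCR identity and transcriptome embeddings.

Cells of one clonotype or convergence group should sit close together in a
transcriptome embedding if TCR identity shapes phenotype. This module tests
that with a permutation test on mean pairwise embedding distance, correlates
CDR3 sequence dissimilarity (Damerau-Levenshtein distance) with embedding
distance over random cell pairs, and scores batch mixing by the Shannon
entropy of batch labels in k-nearest-neighbour neighbourhoods.

The embedding (typically 2-D t-SNE) is consumed as given; distances are
Euclidean in its coordinates, with no re-embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr
from sklearn.neighbors import NearestNeighbors


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment Damerau-Levenshtein distance.

    Counts substitutions, insertions, deletions and adjacent
    transpositions, each at unit cost; a transposed pair is not edited
    again (the OSA restriction, which can violate the triangle
    inequality). Symmetric; 0 iff the strings are equal.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: Optional[list[int]] = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1,        # deletion
                         cur[j - 1] + 1,     # insertion
                         prev[j - 1] + cost)  # substitution
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + 1)  # transposition
        prev2, prev = prev, cur
    return prev[lb]


@dataclass(frozen=True)
class CoherenceResult:
    group_id: str
    n_cells: int
    observed_mean_distance: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float


def _embedding_matrix(embedding: pd.DataFrame) -> tuple[np.ndarray, dict]:
    dims = [c for c in embedding.columns if c.startswith("dim_")]
    coords = embedding[dims].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding coordinates must be finite")
    index = {
        (str(s), str(b)): i
        for i, (s, b) in enumerate(zip(embedding["sample_id"], embedding["barcode"]))
    }
    return coords, index


def group_coherence(
    embedding: pd.DataFrame,
    group_cells: Sequence[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    group_id: str = "",
    alternative: str = "less",
) -> CoherenceResult:
    """Permutation test for transcriptional coherence of a cell group.

    The observed statistic is the mean pairwise Euclidean distance among the
    group's cells; the null draws ``n_perm`` equal-sized cell subsets
    uniformly without replacement from the whole embedding. The one-sided
    p-value (coherence = smaller distances) uses the add-one estimator
    p = (1 + #{null <= observed}) / (n_perm + 1); ``alternative="two-sided"``
    doubles the smaller tail (capped at 1).
    """
    coords, index = _embedding_matrix(embedding)
    cells = sorted(set(tuple(map(str, c)) for c in group_cells))
    if len(cells) < 3:
        raise ValueError("group must contain >= 3 cells")
    missing = [c for c in cells if c not in index]
    if missing:
        raise KeyError(f"group cells missing from embedding: {missing[:10]}")
    rows = np.array([index[c] for c in cells])
    observed = float(pdist(coords[rows]).mean())

    rng = np.random.default_rng(seed)
    m = len(rows)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(coords.shape[0], size=m, replace=False)
        null[i] = pdist(coords[draw]).mean()
    n_le = int(np.sum(null <= observed))
    p_less = (1 + n_le) / (n_perm + 1)
    if alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p_greater = (1 + (n_perm - n_le)) / (n_perm + 1)
        p = min(1.0, 2 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return CoherenceResult(
        group_id=group_id, n_cells=m, observed_mean_distance=observed,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
        n_perm=n_perm, p_value=p,
    )


def seq_embed_correlation(
    embedding: pd.DataFrame,
    cells_with_cdr3: Sequence[tuple[tuple[str, str], str]],
    n_pairs: int = 50_000,
    method: str = "spearman",
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between CDR3 edit distance and embedding distance.

    *cells_with_cdr3* pairs each cell key with its (beta) CDR3 amino-acid
    string. On a seeded random sample of cell pairs, returns the Spearman
    (default) or Pearson correlation between Damerau-Levenshtein CDR3
    distance and Euclidean embedding distance, with its p-value.
    """
    coords, index = _embedding_matrix(embedding)
    usable = [(index[tuple(map(str, cell))], cdr3)
              for cell, cdr3 in cells_with_cdr3
              if tuple(map(str, cell)) in index]
    if len({cdr3 for _, cdr3 in usable}) < 2:
        raise ValueError("correlation undefined: fewer than 2 distinct CDR3s")
    rng = np.random.default_rng(seed)
    n = len(usable)
    ii = rng.integers(0, n, size=n_pairs)
    jj = rng.integers(0, n, size=n_pairs)
    keep = ii != jj
    ii, jj = ii[keep], jj[keep]

    @lru_cache(maxsize=None)
    def _dl(a: str, b: str) -> int:
        return damerau_levenshtein(a, b)

    seq_d = np.array([
        _dl(*sorted((usable[i][1], usable[j][1]))) for i, j in zip(ii, jj)
    ], dtype=float)
    rows_i = np.array([usable[i][0] for i in ii])
    rows_j = np.array([usable[j][0] for j in jj])
    emb_d = np.linalg.norm(coords[rows_i] - coords[rows_j], axis=1)
    if method == "spearman":
        r, p = spearmanr(seq_d, emb_d)
    elif method == "pearson":
        r, p = pearsonr(seq_d, emb_d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def mixing_entropy(
    embedding: pd.DataFrame, k_neighbors: int = 30
) -> tuple[pd.Series, float]:
    """Per-cell and mean normalized batch-label entropy of kNN neighbourhoods.

    For each cell, the Shannon entropy of the batch labels among its
    ``k_neighbors`` nearest Euclidean neighbours (self excluded), divided by
    log of the number of batches, so a perfectly mixed embedding scores near
    1 and fully separated batches score near 0.
    """
    coords, _ = _embedding_matrix(embedding)
    batches = embedding["batch"].astype(str).to_numpy()
    labels = np.unique(batches)
    if len(labels) < 2:
        raise ValueError("mixing entropy undefined with a single batch")
    if coords.shape[0] < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    idx = idx[:, 1:]  # drop self
    label_codes = np.searchsorted(labels, batches)
    neigh = label_codes[idx]
    ent = np.empty(coords.shape[0])
    log_k = math.log(len(labels))
    for i in range(coords.shape[0]):
        counts = np.bincount(neigh[i], minlength=len(labels))
        p = counts[counts > 0] / k_neighbors
        ent[i] = -np.sum(p * np.log(p)) / log_k
    series = pd.Series(ent, index=embedding.index, name="mixing_entropy")
    return series, float(ent.mean())
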