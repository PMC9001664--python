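"""Per-sample clonality and diversity statistics.

Gini index G of clone sizes (0 = perfectly even repertoire, towards 1 =
single-clone dominance), Shannon entropy H of the clone-frequency
distribution, the CDR3 amino-acid length spectratype, and an ordinary
least-squares fit of the log-log complementary CDF of clone sizes, whose
slope is the (negated) power-law exponent of the repertoire.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clonotyping import CellChains, ClonotypeTable, top_k_fraction

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversityMetrics:
    sample_id: str
    gini: float
    shannon: float
    n_clones: int
    n_cells: int
    top3_fraction: float
    powerlaw_slope: Optional[float] = None
    powerlaw_r2: Optional[float] = None


def _check_sizes(sizes) -> np.ndarray:
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("empty size vector")
    if np.any(x <= 0):
        raise ValueError("clone sizes must be positive")
    return x


def gini_index(sizes: Sequence[int], small_sample_correction: bool = False) -> float:
    """Gini index of a clone-size vector.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), evaluated through the sorted
    O(n log n) identity G = (2 sum_i i*x_(i))/(n sum x) - (n+1)/n with
    1-based ranks over the ascending sort. Scale-invariant; G in [0, 1).
    The optional n/(n-1) correction rescales to the sample-unbiased form.
    """
    x = np.sort(_check_sizes(sizes))
    n = x.size
    ranks = np.arange(1, n + 1)
    g = 2.0 * float(ranks @ x) / (n * float(x.sum())) - (n + 1.0) / n
    if small_sample_correction and n > 1:
        g *= n / (n - 1.0)
    return g


def shannon_entropy(sizes: Sequence[int], base: float = 2) -> float:
    """Shannon entropy H of clone frequencies, in log-*base* units.

    H = 0 for a single clone and log_base(n) for n equal clones.
    """
    x = _check_sizes(sizes)
    p = x / x.sum()
    h = -float(np.sum(p * np.log(p))) / math.log(base)
    return max(h, 0.0)  # clamp -0.0 from the single-clone case


@dataclass(frozen=True)
class Spectratype:
    sample_id: str
    subset: str
    histogram: dict[int, float]  # CDR3 aa length -> frequency


def spectratype(
    cells: Sequence[CellChains],
    locus: str = "TRB",
    subset_labels: Optional[Sequence[str]] = None,
    sample_id: str = "",
) -> list[Spectratype]:
    """CDR3 amino-acid length distribution of the representative chain.

    One histogram per subset label (a single "all" subset when labels are
    not given); each histogram sums to 1 over cells carrying the locus.
    """
    if locus not in ("TRA", "TRB"):
        raise ValueError(f"invalid locus {locus!r}")
    labels = subset_labels if subset_labels is not None else ["all"] * len(cells)
    counts: dict[str, dict[int, int]] = {}
    for cell, label in zip(cells, labels):
        chains = cell.tra if locus == "TRA" else cell.trb
        if not chains or chains[0].cdr3_aa is None:
            continue
        counts.setdefault(label, {})
        length = len(chains[0].cdr3_aa)
        counts[label][length] = counts[label].get(length, 0) + 1
    if not counts:
        log.warning("sample %s: no cells with a productive %s CDR3", sample_id, locus)
        return [Spectratype(sample_id=sample_id, subset="all", histogram={})]
    out = []
    for label in sorted(counts):
        total = sum(counts[label].values())
        hist = {l: c / total for l, c in sorted(counts[label].items())}
        out.append(Spectratype(sample_id=sample_id, subset=label, histogram=hist))
    return out


def clone_size_ccdf(sizes: Sequence[int]) -> list[tuple[float, float]]:
    """Log-log complementary CDF of clone sizes.

    One point (log10 x, log10 P(X >= x)) per distinct size x, where P is
    the fraction of clones with size >= x. The second coordinate is
    strictly decreasing in x.
    """
    x = _check_sizes(sizes)
    xs = np.unique(x)
    n = x.size
    return [
        (math.log10(v), math.log10(float(np.sum(x >= v)) / n)) for v in xs
    ]


def powerlaw_slope(
    sizes: Sequence[int], min_size: int = 1
) -> tuple[float, float]:
    """OLS fit to the log-log CCDF of clone sizes.

    Returns (slope, r2). The slope of a power-law repertoire with
    P(X >= x) ~ x^(-gamma) estimates -gamma. Requires at least 3 distinct
    sizes >= *min_size*.
    """
    pts = [(lx, ly) for lx, ly in clone_size_ccdf(sizes)
           if 10 ** lx >= min_size - 1e-9]
    if len(pts) < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct clone sizes >= {min_size} "
            f"(got {len(pts)}); lower min_size or skip this sample"
        )
    xy = np.asarray(pts)
    slope, intercept = np.polyfit(xy[:, 0], xy[:, 1], 1)
    resid = xy[:, 1] - (slope * xy[:, 0] + intercept)
    ss_tot = float(np.sum((xy[:, 1] - xy[:, 1].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def diversity_metrics(
    table: ClonotypeTable, base: float = 2, min_size: int = 1
) -> DiversityMetrics:
    """All per-sample diversity statistics from one clonotype table."""
    sizes = table.sizes()
    try:
        slope, r2 = powerlaw_slope(sizes, min_size=min_size)
    except ValueError:
        slope, r2 = None, None
    return DiversityMetrics(
        sample_id=table.sample_id,
        gini=gini_index(sizes),
        shannon=shannon_entropy(sizes, base=base),
        n_clones=table.n_clones,
        n_cells=table.n_keyed_cells,
        top3_fraction=top_k_fraction(table, 3),
        powerlaw_slope=slope,
        powerlaw_r2=r2,
    )
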