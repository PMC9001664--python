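"""CDR3 convergence groups (TCR specificity groups) and motif enrichment.

Distinct CDR3beta amino-acid sequences are linked into convergence groups
(CRGs) when they share a k-mer motif enriched against a reference repertoire
or are near-identical (equal length, Hamming distance <= 1) — the grouping
logic popularised by GLIPH. Motif enrichment combines a fold-change filter
with a resampling tail probability from size-matched draws out of the
reference. A small panel of CMVpp65-associated CDR3 motifs (TGT, ATN, FQ,
SSA, QTG) can be scanned against expanded clones of CMV-seropositive
subjects with a Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact

from .clonotyping import ClonotypeTable

log = logging.getLogger(__name__)

#: CMVpp65 CDR3 motif panel (HLA-A*02:01-restricted)
CMV_MOTIFS = ("TGT", "ATN", "FQ", "SSA", "QTG")

#: residues removed before k-mer extraction: first 3 and last 2, the
#: germline-conserved CDR3 flanks (C..F/W anchors and neighbours)
TRIM_HEAD, TRIM_TAIL = 3, 2


def trim_cdr3(seq: str) -> str:
    """Interior of a CDR3 after removing the conserved flanks."""
    return seq[TRIM_HEAD: len(seq) - TRIM_TAIL] if len(seq) > TRIM_HEAD + TRIM_TAIL else ""


@dataclass(frozen=True)
class MotifHit:
    motif: str
    observed_count: int
    reference_rate: float
    fold: float
    p_resample: float


@dataclass
class ConvergenceGroup:
    name: str
    members: frozenset  # distinct CDR3 aa strings
    member_cells: int
    edges: list[tuple[str, str, str]] = field(default_factory=list)  # (a, b, evidence)
    per_sample_cells: dict[str, int] = field(default_factory=dict)
    top5_contribution: float = 0.0

    @property
    def n_members(self) -> int:
        return len(self.members)


def pool_top_cdr3(tables: Sequence[ClonotypeTable], n: int = 500) -> list[tuple]:
    """Union of each sample's top-n beta CDR3s, with per-sample cell counts.

    Tables must use the ``beta_nt_only`` or ``aa_paired``/paired schemes with
    a beta CDR3 aa available; in practice call this on per-sample tables
    built from cells (see :func:`pool_top_cdr3_from_cells`) or on
    clonotype tables whose keys are beta CDR3 aa strings.

    Returns a list of (cdr3_aa, total_cells, per_sample_counts dict) sorted
    by total cells descending then sequence.
    """
    pooled: dict[str, dict[str, int]] = {}
    for t in tables:
        ranked = sorted(t.entries.items(), key=lambda kv: (-kv[1]["size"], kv[0]))
        for key, e in ranked[:n]:
            cdr3 = key[-1] if isinstance(key, tuple) else key
            pooled.setdefault(cdr3, {})
            pooled[cdr3][t.sample_id] = pooled[cdr3].get(t.sample_id, 0) + e["size"]
    out = [
        (cdr3, sum(per.values()), dict(sorted(per.items())))
        for cdr3, per in pooled.items()
    ]
    out.sort(key=lambda r: (-r[1], r[0]))
    return out


def _as_sequences(pooled) -> list[str]:
    return [p[0] if isinstance(p, tuple) else p for p in pooled]


def _kmer_presence(seqs: Sequence[str], motif: str) -> np.ndarray:
    return np.array([motif in trim_cdr3(s) for s in seqs], dtype=bool)


def enriched_kmers(
    cdr3s,
    reference: Sequence[str],
    k_set: Sequence[int] = (2, 3, 4),
    fold_min: float = 10.0,
    p_max: float = 0.001,
    n_resample: int = 1000,
    seed: int = 0,
    min_support: int = 3,
) -> list[MotifHit]:
    """Contiguous k-mers enriched in the sample CDR3s over a reference.

    Sequences are trimmed (first 3 / last 2 residues dropped) before k-mer
    extraction; sequences whose interior is shorter than k are skipped for
    that k. A motif is reported when it occurs in at least ``min_support``
    distinct sample CDR3s, its per-sequence frequency strictly exceeds
    ``fold_min`` times the reference frequency, AND its resampling tail
    probability — the add-one fraction of ``n_resample`` size-matched draws
    (with replacement) from the reference whose motif count reaches the
    observed count — is at most ``p_max``. The support floor keeps k-mers
    that are merely absent from a finite reference from passing on a single
    occurrence. Deterministic given *seed*.
    """
    if not reference:
        raise ValueError("reference repertoire is empty")
    seqs = _as_sequences(cdr3s)
    n_sample, n_ref = len(seqs), len(reference)
    if n_sample == 0:
        return []
    rng = np.random.default_rng(seed)

    # candidate motifs and observed presence counts
    obs_counts: dict[str, int] = {}
    n_skipped = 0
    for k in sorted(set(k_set)):
        seen_any = False
        for s in seqs:
            interior = trim_cdr3(s)
            if len(interior) < k:
                n_skipped += 1
                continue
            seen_any = True
            for kmer in {interior[i: i + k] for i in range(len(interior) - k + 1)}:
                obs_counts[kmer] = obs_counts.get(kmer, 0) + 1
        if not seen_any:
            log.info("no sample sequence long enough for k=%d", k)
    if n_skipped:
        log.debug("%d (sequence, k) combinations skipped: interior shorter than k",
                  n_skipped)

    # fold filter against reference presence frequencies; reference k-mer
    # presence is pre-counted once (per-sequence k-mer sets) for speed
    ref_trimmed = [trim_cdr3(s) for s in reference]
    ref_presence_count: dict[str, int] = {}
    ks = sorted(set(k_set))
    for s in ref_trimmed:
        kmers = set()
        for k in ks:
            kmers.update(s[i: i + k] for i in range(len(s) - k + 1))
        for kmer in kmers:
            ref_presence_count[kmer] = ref_presence_count.get(kmer, 0) + 1
    candidates = []
    for motif in sorted(obs_counts):
        if obs_counts[motif] < min_support:
            continue
        ref_count = ref_presence_count.get(motif, 0)
        # continuity value for motifs absent from the reference
        ref_rate = ref_count / n_ref if ref_count else 1.0 / (2 * n_ref)
        obs_freq = obs_counts[motif] / n_sample
        fold = obs_freq / ref_rate
        if fold > fold_min:
            candidates.append((motif, obs_counts[motif], ref_rate, fold))

    if not candidates:
        return []

    # resampling: shared index draws so the test is vectorised per motif
    draws = rng.integers(0, n_ref, size=(n_resample, n_sample))
    hits = []
    for motif, obs, ref_rate, fold in candidates:
        presence = np.array([motif in s for s in ref_trimmed], dtype=bool)
        null_counts = presence[draws].sum(axis=1)
        p = (1 + int(np.sum(null_counts >= obs))) / (n_resample + 1)
        if p <= p_max:
            hits.append(MotifHit(motif=motif, observed_count=obs,
                                 reference_rate=ref_rate, fold=fold, p_resample=p))
    hits.sort(key=lambda h: (h.p_resample, -h.fold, h.motif))
    return hits


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mismatches = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            mismatches += 1
            if mismatches > 1:
                return False
    return mismatches == 1


def build_crgs(
    pooled: Sequence[tuple],
    motifs: Sequence[MotifHit],
    min_members: int = 5,
    strict: bool = True,
) -> list[ConvergenceGroup]:
    """Connect CDR3s into convergence groups and keep the large components.

    Two distinct CDR3s are linked when they share an enriched motif (in
    their trimmed interiors) or are equal-length with Hamming distance <= 1.
    Components with more than ``min_members`` distinct sequences (strictly,
    by default) are returned, named ``CRG_`` + most abundant member and
    sorted by total member cells descending.
    """
    entries = {}
    for p in pooled:
        if isinstance(p, tuple):
            cdr3, cells, per_sample = p[0], p[1], (p[2] if len(p) > 2 else {})
        else:
            cdr3, cells, per_sample = p, 1, {}
        if cdr3 in entries:  # merge duplicate pooled rows
            prev = entries[cdr3]
            merged = dict(prev[1])
            for s, c in per_sample.items():
                merged[s] = merged.get(s, 0) + c
            entries[cdr3] = (prev[0] + cells, merged)
        else:
            entries[cdr3] = (cells, dict(per_sample))

    g = nx.Graph()
    g.add_nodes_from(entries)
    evidence: dict[tuple[str, str], str] = {}
    seqs = sorted(entries)

    # motif edges: all pairs of sequences containing a shared enriched motif
    for hit in motifs:
        carriers = [s for s in seqs if hit.motif in trim_cdr3(s)]
        for i, a in enumerate(carriers):
            for b in carriers[i + 1:]:
                g.add_edge(a, b)
                evidence.setdefault((a, b), f"motif:{hit.motif}")

    # near-identity edges, bucketed by length
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    for same_len in by_len.values():
        for i, a in enumerate(same_len):
            for b in same_len[i + 1:]:
                if _hamming1(a, b):
                    g.add_edge(a, b)
                    evidence.setdefault((a, b), "hamming1")

    groups = []
    for comp in nx.connected_components(g):
        n = len(comp)
        keep = n > min_members if strict else n >= min_members
        if not keep:
            continue
        members = frozenset(comp)
        # most abundant member names the group; ties broken lexicographically
        top = min(members, key=lambda s: (-entries[s][0], s))
        per_sample: dict[str, int] = {}
        for s in members:
            for sid, c in entries[s][1].items():
                per_sample[sid] = per_sample.get(sid, 0) + c
        total = sum(entries[s][0] for s in members)
        edges = sorted(
            (a, b, ev) for (a, b), ev in evidence.items()
            if a in members and b in members
        )
        grp = ConvergenceGroup(
            name=f"CRG_{top}", members=members, member_cells=total,
            edges=edges, per_sample_cells=dict(sorted(per_sample.items())),
        )
        grp.top5_contribution = crg_contribution(grp)[0]
        groups.append(grp)
    groups.sort(key=lambda g: (-g.member_cells, g.name))
    return groups


def crg_contribution(
    group: ConvergenceGroup,
    allowed_samples: Optional[set] = None,
) -> tuple[float, dict[str, int]]:
    """Fraction of a group's cells contributed by its 5 largest samples.

    ``allowed_samples`` restricts the accounting (e.g. to pre-treatment
    samples only); contributions outside it are dropped from both numerator
    and denominator.
    """
    per = {s: c for s, c in group.per_sample_cells.items()
           if allowed_samples is None or s in allowed_samples}
    total = sum(per.values())
    if total == 0:
        return 0.0, {}
    top5 = sorted(per.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    return sum(c for _, c in top5) / total, dict(top5)


def fisher_exact_p(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value of a 2x2 count table."""
    _, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def motif_scan_fisher(
    clones: Sequence[tuple],
    motifs: Sequence[str] = CMV_MOTIFS,
) -> tuple[list[list[int]], float]:
    """Fisher exact test: CMV motifs in expanded CMV+ clones vs the rest.

    *clones* is a sequence of (cdr3_aa, expanded: bool, cmv_status: str)
    triples, one per clone. A clone is motif-bearing when any panel motif
    occurs as a substring of its full (untrimmed) CDR3 — the panel includes
    2-mers that would vanish under flank trimming. Returns the 2x2 table
    [[motif+ expanded-CMV+, motif- expanded-CMV+], [motif+ other, motif-
    other]] and the two-sided Fisher exact p-value.
    """
    a = b = c = d = 0
    for cdr3, expanded, cmv in clones:
        bearing = any(m in cdr3 for m in motifs)
        in_group = bool(expanded) and str(cmv).lower() in ("positive", "pos", "+")
        if in_group:
            a, b = (a + 1, b) if bearing else (a, b + 1)
        else:
            c, d = (c + 1, d) if bearing else (c, d + 1)
    table = [[a, b], [c, d]]
    if a + b == 0 or c + d == 0:
        raise ValueError(f"degenerate margin: empty row in {table}")
    return table, fisher_exact_p(table)
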