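"""Clonotype calling from per-cell contigs.

A clonotype is the set of cells sharing identical TCR sequence under a key
scheme. The default scheme (``nt_paired``) keys cells on the paired
alpha+beta nucleotide CDR3, the strictest notion of "identical TCRalpha- and
beta-chains"; an expanded clone is a clonotype with at least 10 member cells.

Cells with multiple productive chains at one locus are keyed on the
highest-UMI chain (ties broken by contig_id) so no cell ever carries two
clonotypes; multi-chain cells are counted and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import ConfigError, ContigRecord

log = logging.getLogger(__name__)

KEY_SCHEMES = ("nt_paired", "aa_paired", "nt_paired_vj", "beta_nt_only",
               "beta_aa_only")

#: minimum cell count for an expanded clone
EXPANDED_MIN_CELLS = 10


@dataclass(frozen=True)
class CellChains:
    """Productive TRA/TRB contigs of one cell, sorted by UMI support."""

    cell: tuple[str, str]  # (sample_id, barcode)
    tra: tuple[ContigRecord, ...]
    trb: tuple[ContigRecord, ...]


@dataclass(frozen=True)
class ChainDetectionSummary:
    sample_id: str
    n_cells: int
    f_ge1_alpha: float
    f_ge1_beta: float
    f_exactly1_alpha: float
    f_exactly1_beta: float
    f_paired: float


@dataclass
class ClonotypeTable:
    """Per-sample clonotypes: key -> (member cells, size, frequency).

    Frequencies are over keyed cells only (cells that received a key under
    the scheme), so they always sum to 1.
    """

    sample_id: str
    key_scheme: str
    entries: dict[tuple, dict] = field(default_factory=dict)
    n_keyed_cells: int = 0
    n_unkeyed_cells: int = 0

    def sizes(self) -> list[int]:
        return [e["size"] for e in self.entries.values()]

    def frequencies(self) -> list[float]:
        return [e["frequency"] for e in self.entries.values()]

    @property
    def n_clones(self) -> int:
        return len(self.entries)


def build_cell_chains(
    contigs: Sequence[ContigRecord],
    sample_id: str = "",
    require_high_confidence: bool = False,
) -> list[CellChains]:
    """Group a sample's productive contigs by barcode.

    Returns one CellChains per barcode with >= 1 productive TRA or TRB
    contig. Per-locus lists are sorted by UMIs descending, tie-break on
    contig_id, so clonotype keys are independent of input order.
    """
    by_cell: dict[str, dict[str, list[ContigRecord]]] = {}
    for c in contigs:
        if not c.productive or c.umis < 1:
            continue
        if require_high_confidence and not c.high_confidence:
            continue
        if c.chain not in ("TRA", "TRB"):
            continue
        by_cell.setdefault(c.barcode, {"TRA": [], "TRB": []})[c.chain].append(c)

    out, n_multi_a, n_multi_b = [], 0, 0
    for barcode in sorted(by_cell):
        chains = by_cell[barcode]
        tra = tuple(sorted(chains["TRA"], key=lambda c: (-c.umis, c.contig_id)))
        trb = tuple(sorted(chains["TRB"], key=lambda c: (-c.umis, c.contig_id)))
        if len(tra) > 1:
            n_multi_a += 1
        if len(trb) > 1:
            n_multi_b += 1
        out.append(CellChains(cell=(sample_id, barcode), tra=tra, trb=trb))
    if n_multi_a or n_multi_b:
        log.info("sample %s: %d multi-alpha, %d multi-beta cells",
                 sample_id, n_multi_a, n_multi_b)
    return out


def chain_detection_summary(
    cells: Sequence[CellChains], n_total_cells: int, sample_id: str = ""
) -> ChainDetectionSummary:
    """Per-sample chain-detection fractions over all sequenced cells.

    The denominator is *n_total_cells* (all sequenced cells, not just
    chain-bearing ones), matching how detection rates are reported for
    droplet scTCR-seq.
    """
    if n_total_cells <= 0:
        raise ValueError("n_total_cells must be positive")
    if n_total_cells < len(cells):
        raise ValueError("n_total_cells smaller than number of chain-bearing cells")
    ge1a = sum(1 for c in cells if len(c.tra) >= 1)
    ge1b = sum(1 for c in cells if len(c.trb) >= 1)
    ex1a = sum(1 for c in cells if len(c.tra) == 1)
    ex1b = sum(1 for c in cells if len(c.trb) == 1)
    paired = sum(1 for c in cells if c.tra and c.trb)
    n = n_total_cells
    return ChainDetectionSummary(
        sample_id=sample_id, n_cells=n,
        f_ge1_alpha=ge1a / n, f_ge1_beta=ge1b / n,
        f_exactly1_alpha=ex1a / n, f_exactly1_beta=ex1b / n,
        f_paired=paired / n,
    )


def _representative(chains: tuple[ContigRecord, ...]) -> Optional[ContigRecord]:
    return chains[0] if chains else None


def clonotype_key(cell: CellChains, key_scheme: str) -> Optional[tuple]:
    """The cell's clonotype key under a scheme, or None if unkeyable.

    Paired schemes require both a productive alpha and beta chain with the
    relevant CDR3 present; ``beta_nt_only`` requires a beta chain.
    """
    if key_scheme not in KEY_SCHEMES:
        raise ConfigError(f"unknown key scheme {key_scheme!r}; valid: {KEY_SCHEMES}")
    a, b = _representative(cell.tra), _representative(cell.trb)
    if key_scheme == "beta_nt_only":
        if b is None or b.cdr3_nt is None:
            return None
        return (b.cdr3_nt,)
    if key_scheme == "beta_aa_only":
        if b is None or b.cdr3_aa is None:
            return None
        return (b.cdr3_aa,)
    if a is None or b is None:
        return None
    if key_scheme == "nt_paired":
        if a.cdr3_nt is None or b.cdr3_nt is None:
            return None
        return (a.cdr3_nt, b.cdr3_nt)
    if key_scheme == "aa_paired":
        if a.cdr3_aa is None or b.cdr3_aa is None:
            return None
        return (a.cdr3_aa, b.cdr3_aa)
    # nt_paired_vj
    if a.cdr3_nt is None or b.cdr3_nt is None:
        return None
    return (a.cdr3_nt, b.cdr3_nt, a.v_gene, a.j_gene, b.v_gene, b.j_gene)


def call_clonotypes(
    cells: Sequence[CellChains],
    key_scheme: str = "nt_paired",
    sample_id: Optional[str] = None,
) -> ClonotypeTable:
    """Assign each keyable cell to exactly one clonotype and tabulate sizes."""
    if key_scheme not in KEY_SCHEMES:
        raise ConfigError(f"unknown key scheme {key_scheme!r}; valid: {KEY_SCHEMES}")
    if sample_id is None:
        sample_id = cells[0].cell[0] if cells else ""
    members: dict[tuple, list[tuple[str, str]]] = {}
    n_unkeyed = 0
    for cell in cells:
        key = clonotype_key(cell, key_scheme)
        if key is None:
            n_unkeyed += 1
            continue
        members.setdefault(key, []).append(cell.cell)
    n_keyed = sum(len(v) for v in members.values())
    table = ClonotypeTable(sample_id=sample_id, key_scheme=key_scheme,
                           n_keyed_cells=n_keyed, n_unkeyed_cells=n_unkeyed)
    for key in sorted(members):
        cells_k = sorted(members[key])
        table.entries[key] = {
            "cells": cells_k,
            "size": len(cells_k),
            "frequency": len(cells_k) / n_keyed if n_keyed else 0.0,
        }
    return table


def call_expanded(table: ClonotypeTable, min_cells: int = EXPANDED_MIN_CELLS) -> set:
    """Keys of expanded clones: clonotypes with >= min_cells member cells."""
    if min_cells < 2:
        raise ValueError("min_cells must be >= 2")
    return {k for k, e in table.entries.items() if e["size"] >= min_cells}


def top_k_fraction(table: ClonotypeTable, k: int = 3) -> float:
    """Summed frequency of the k largest clones (key-lexicographic ties)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not table.entries:
        raise ValueError("empty clonotype table")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1]["size"], kv[0]))
    return sum(e["frequency"] for _, e in ranked[:k])
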