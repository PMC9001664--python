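"""Synthetic scTCR-seq cohort generator with full ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* clone sizes drawn from a truncated discrete power law,
  P(X >= x) proportional to x^(-gamma);
* subject-private clones with a configurable small cross-subject overlap;
* per-cell chain dropout at configurable detection probabilities
  (defaults: alpha 0.61, beta 0.95, the median per-sample detection rates
  of droplet scTCR-seq) and extra productive chains at multi-chain rates;
* CDR3beta = "C" + random interior + "F" with Normal(14, 1.5) amino-acid
  lengths clipped to [8, 22], planted k-mer motifs in designated clones,
  and deterministic first-codon back-translation to nucleotides;
* paired pre/post timepoints with per-clone fold changes drawn from an
  increased / unchanged / decreased mixture, plus emergent and lost clones;
* clone-correlated embedding coordinates (clone centers
  ~ N(0, sigma_between^2 I), cells ~ N(center, sigma_within^2 I)); the
  null mode sigma_between = 0 removes all clone-embedding association.

Every random draw flows through one seeded generator, so an identical
config reproduces identical outputs bit for bit, and the returned
SyntheticTruth is sufficient to recompute every expected pipeline result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CODON_TABLE
from .sharing import classify_change

# first codon per amino acid, in standard-table insertion order
AA_TO_CODON: dict[str, str] = {}
for _codon, _aa in CODON_TABLE.items():
    AA_TO_CODON.setdefault(_aa, _codon)

#: CDR3 interior alphabet (20 proteinogenic residues)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

TRBV = ["TRBV5-6", "TRBV19", "TRBV20-1", "TRBV27", "TRBV7-9", "TRBV28",
        "TRBV9", "TRBV6-5"]
TRBJ = ["TRBJ2-2", "TRBJ2-7", "TRBJ1-1", "TRBJ2-1", "TRBJ1-2"]
TRAV = ["TRAV12-1", "TRAV8-4", "TRAV29", "TRAV21", "TRAV1-2", "TRAV17"]
TRAJ = ["TRAJ33", "TRAJ42", "TRAJ49", "TRAJ20", "TRAJ30"]


@dataclass(frozen=True)
class PlantedMotif:
    motif: str
    n_distinct_cdr3s: int
    stratum: str = "expanded"  # "expanded" (size >= 10 clones) or "any"


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    seed: int
    n_subjects: int = 4
    groups: Optional[list[str]] = None          # per subject; default half/half
    cmv_status: Optional[list[str]] = None      # per subject; default alternating
    clones_per_subject: int = 200
    ccdf_exponent: float = 1.5
    max_clone_size: int = 2000
    cross_subject_overlap: float = 0.0
    p_alpha_detect: float = 0.61
    p_beta_detect: float = 0.95
    p_multi_alpha: float = 0.10
    p_multi_beta: float = 0.05
    cdr3_length_mean: float = 14.0
    cdr3_length_sd: float = 1.5
    cdr3_length_min: int = 8
    cdr3_length_max: int = 22
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    # timepoint-2 fold-change mixture: class -> (probability, fold_lo, fold_hi)
    dynamics_mixture: dict = field(default_factory=lambda: {
        "increased": (0.3, 1.5, 3.0),
        "unchanged": (0.4, 0.95, 1.05),
        "decreased": (0.3, 0.2, 0.7),
    })
    emergent_rate: float = 0.0
    lost_rate: float = 0.0
    sigma_between: float = 5.0
    sigma_within: float = 0.5
    n_dims: int = 2

    def validate(self) -> None:
        for name in ("cross_subject_overlap", "p_alpha_detect", "p_beta_detect",
                     "p_multi_alpha", "p_multi_beta", "emergent_rate", "lost_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.ccdf_exponent <= 0:
            raise ValueError("ccdf_exponent must be positive")
        for pm in self.planted_motifs:
            # planted sequences need room for the motif inside the trimmed
            # interior: C + 2 flank + motif + 1 flank + F
            if len(pm.motif) + 5 > self.cdr3_length_max:
                raise ValueError(
                    f"motif {pm.motif!r} cannot fit any CDR3 interior after "
                    f"flank trimming (max length {self.cdr3_length_max})"
                )


@dataclass
class CloneTruth:
    clone_id: str
    subject_id: str
    cdr3_aa_alpha: str
    cdr3_aa_beta: str
    cdr3_nt_alpha: str
    cdr3_nt_beta: str
    v_alpha: str
    j_alpha: str
    v_beta: str
    j_beta: str
    size_pre: int
    size_post: Optional[int] = None
    intended_class: Optional[str] = None   # drawn mixture class
    dynamics_class: Optional[str] = None   # realized frequency-based class
    planted_motif: Optional[str] = None
    embedding_center: Optional[np.ndarray] = None


@dataclass
class SyntheticTruth:
    config: SimConfig
    clones: list[CloneTruth]
    subjects: list[str]
    groups: dict[str, str]
    cmv: dict[str, str]
    n_total_cells: dict[str, int] = field(default_factory=dict)

    def clones_of(self, subject_id: str) -> list[CloneTruth]:
        return [c for c in self.clones if c.subject_id == subject_id]

    def expanded_keys(self, subject_id: str, timepoint: str = "pre",
                      min_cells: int = 10) -> set[tuple]:
        """Ground-truth expanded paired-nt clonotype keys at a timepoint."""
        keys = set()
        for c in self.clones_of(subject_id):
            size = c.size_pre if timepoint == "pre" else (c.size_post or 0)
            if size >= min_cells:
                keys.add((c.cdr3_nt_alpha, c.cdr3_nt_beta))
        return keys

    def realized_dynamics(self, subject_id: str,
                          threshold: float = 0.20) -> dict[tuple, str]:
        """Frequency-based dynamics class per clone key, from true sizes."""
        clones = [c for c in self.clones_of(subject_id)]
        tot_pre = sum(c.size_pre for c in clones)
        tot_post = sum(c.size_post or 0 for c in clones)
        out = {}
        for c in clones:
            key = (c.cdr3_nt_alpha, c.cdr3_nt_beta)
            post = c.size_post or 0
            if c.size_pre == 0:
                out[key] = "emergent"
            elif post == 0:
                out[key] = "lost"
            else:
                f_pre = c.size_pre / tot_pre
                f_post = post / tot_post
                out[key] = classify_change((f_post - f_pre) / f_pre, threshold)
        return out


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort: contig tables + sample sheet + truth."""

    contig_tables: dict[str, pd.DataFrame]  # sample_id -> 10x-dialect table
    sample_sheet: pd.DataFrame
    truth: SyntheticTruth
    embedding: Optional[pd.DataFrame] = None


def back_translate(aa: str) -> str:
    """Deterministic nucleotide sequence translating to *aa* (first codon)."""
    return "".join(AA_TO_CODON[c] for c in aa)


def _sample_powerlaw_sizes(n: int, gamma: float, max_size: int,
                           rng: np.random.Generator) -> np.ndarray:
    x = np.arange(1, max_size + 1, dtype=float)
    ccdf = x ** (-gamma)
    pmf = ccdf - np.append(ccdf[1:], 0.0)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, max_size + 1), size=n, p=pmf)


def _random_cdr3(rng: np.random.Generator, cfg: SimConfig,
                 motif: Optional[str] = None) -> str:
    lo = cfg.cdr3_length_min
    if motif is not None:
        # the motif must survive flank trimming (first 3 / last 2 residues of
        # the full CDR3, i.e. interior offsets < 2 and the last interior
        # position), otherwise the planted signal is invisible by design
        lo = max(lo, len(motif) + 5)
    length = int(np.clip(round(rng.normal(cfg.cdr3_length_mean, cfg.cdr3_length_sd)),
                         lo, max(cfg.cdr3_length_max, lo)))
    interior_len = length - 2
    interior = "".join(rng.choice(list(AA_ALPHABET), size=interior_len))
    if motif is not None:
        if len(motif) + 3 > interior_len:
            raise ValueError(f"motif {motif!r} longer than trimmed interior")
        offset = int(rng.integers(2, interior_len - len(motif)))
        interior = interior[:offset] + motif + interior[offset + len(motif):]
    return "C" + interior + "F"


def _make_clone(rng: np.random.Generator, cfg: SimConfig, clone_id: str,
                subject_id: str, size: int,
                motif: Optional[str] = None) -> CloneTruth:
    aa_a = _random_cdr3(rng, cfg)
    aa_b = _random_cdr3(rng, cfg, motif=motif)
    return CloneTruth(
        clone_id=clone_id, subject_id=subject_id,
        cdr3_aa_alpha=aa_a, cdr3_aa_beta=aa_b,
        cdr3_nt_alpha=back_translate(aa_a), cdr3_nt_beta=back_translate(aa_b),
        v_alpha=str(rng.choice(TRAV)), j_alpha=str(rng.choice(TRAJ)),
        v_beta=str(rng.choice(TRBV)), j_beta=str(rng.choice(TRBJ)),
        size_pre=int(size), planted_motif=motif,
    )


def _contig_rows_for_cell(rng: np.random.Generator, cfg: SimConfig,
                          barcode: str, clone: CloneTruth) -> list[dict]:
    """Contig rows for one cell after chain dropout / multi-chain noise."""
    rows = []
    has_alpha = rng.random() < cfg.p_alpha_detect
    has_beta = rng.random() < cfg.p_beta_detect
    n_contig = 0

    def _row(chain, v, j, aa, nt, umis):
        nonlocal n_contig
        n_contig += 1
        return {
            "barcode": barcode, "is_cell": "True",
            "contig_id": f"{barcode}_contig_{n_contig}",
            "high_confidence": "True", "length": len(nt) + 300,
            "chain": chain, "v_gene": v, "d_gene": "None", "j_gene": j,
            "c_gene": "TRAC" if chain == "TRA" else "TRBC2",
            "full_length": "True", "productive": "True",
            "cdr3": aa, "cdr3_nt": nt,
            "reads": int(umis) * 30, "umis": int(umis),
        }

    if has_alpha:
        rows.append(_row("TRA", clone.v_alpha, clone.j_alpha,
                         clone.cdr3_aa_alpha, clone.cdr3_nt_alpha,
                         rng.integers(3, 50)))
        if rng.random() < cfg.p_multi_alpha:
            aa2 = _random_cdr3(rng, cfg)
            rows.append(_row("TRA", str(rng.choice(TRAV)), str(rng.choice(TRAJ)),
                             aa2, back_translate(aa2), rng.integers(1, 3)))
    if has_beta:
        rows.append(_row("TRB", clone.v_beta, clone.j_beta,
                         clone.cdr3_aa_beta, clone.cdr3_nt_beta,
                         rng.integers(3, 50)))
        if rng.random() < cfg.p_multi_beta:
            aa2 = _random_cdr3(rng, cfg)
            rows.append(_row("TRB", str(rng.choice(TRBV)), str(rng.choice(TRBJ)),
                             aa2, back_translate(aa2), rng.integers(1, 3)))
    return rows


_TENX_COLUMNS = ["barcode", "is_cell", "contig_id", "high_confidence", "length",
                 "chain", "v_gene", "d_gene", "j_gene", "c_gene", "full_length",
                 "productive", "cdr3", "cdr3_nt", "reads", "umis"]


def _emit_sample(rng: np.random.Generator, cfg: SimConfig, sample_id: str,
                 clones: Sequence[CloneTruth], timepoint: str) -> tuple[pd.DataFrame, int, list]:
    """Contig table for one sample; returns (table, n_total_cells, cell map).

    The cell map lists (barcode, clone) for every sequenced cell, including
    cells that lost both chains to dropout (absent from the table but
    counted in n_total_cells).
    """
    rows, cell_map = [], []
    i = 0
    for clone in clones:
        size = clone.size_pre if timepoint == "pre" else (clone.size_post or 0)
        for _ in range(size):
            barcode = f"{sample_id}_bc{i:06d}"
            i += 1
            cell_map.append((barcode, clone))
            rows.extend(_contig_rows_for_cell(rng, cfg, barcode, clone))
    df = pd.DataFrame(rows, columns=_TENX_COLUMNS)
    return df, i, cell_map


def generate_repertoire(config: SimConfig) -> SimulatedCohort:
    """Generate the first-visit cohort: contig tables, sample sheet, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    groups = config.groups or [
        "patient" if i < (config.n_subjects + 1) // 2 else "healthy"
        for i in range(config.n_subjects)
    ]
    cmv = config.cmv_status or [
        "positive" if i % 2 == 0 else "negative" for i in range(config.n_subjects)
    ]
    if len(groups) != config.n_subjects or len(cmv) != config.n_subjects:
        raise ValueError("groups / cmv_status length must equal n_subjects")

    clones: list[CloneTruth] = []
    for s_ix, subj in enumerate(subjects):
        sizes = _sample_powerlaw_sizes(config.clones_per_subject,
                                       config.ccdf_exponent,
                                       config.max_clone_size, rng)
        for c_ix, size in enumerate(sizes):
            clone_id = f"{subj}_c{c_ix:04d}"
            if s_ix > 0 and rng.random() < config.cross_subject_overlap:
                donor = clones[int(rng.integers(0, len(clones)))]
                clone = replace(donor, clone_id=clone_id, subject_id=subj,
                                size_pre=int(size), planted_motif=None)
            else:
                clone = _make_clone(rng, config, clone_id, subj, int(size))
            clones.append(clone)

    # plant motifs into designated clones' beta chains
    for pm in config.planted_motifs:
        pool = [c for c in clones if c.planted_motif is None]
        if pm.stratum == "expanded":
            preferred = [c for c in pool if c.size_pre >= 10]
            pool = preferred + [c for c in pool if c.size_pre < 10]
        if len(pool) < pm.n_distinct_cdr3s:
            raise ValueError(f"not enough clones to plant motif {pm.motif!r}")
        for c in pool[: pm.n_distinct_cdr3s]:
            aa_b = _random_cdr3(rng, config, motif=pm.motif)
            c.cdr3_aa_beta = aa_b
            c.cdr3_nt_beta = back_translate(aa_b)
            c.planted_motif = pm.motif

    truth = SyntheticTruth(
        config=config, clones=clones, subjects=subjects,
        groups=dict(zip(subjects, groups)), cmv=dict(zip(subjects, cmv)),
    )

    contig_tables: dict[str, pd.DataFrame] = {}
    sheet_rows = []
    for subj in subjects:
        sample_id = f"{subj}_pre"
        table, n_cells, _ = _emit_sample(rng, config, sample_id,
                                         truth.clones_of(subj), "pre")
        contig_tables[sample_id] = table
        truth.n_total_cells[sample_id] = n_cells
        sheet_rows.append({
            "sample_id": sample_id, "subject_id": subj, "timepoint": "pre",
            "group": truth.groups[subj], "cmv_status": truth.cmv[subj],
            "responder": "na",
        })
    return SimulatedCohort(
        contig_tables=contig_tables,
        sample_sheet=pd.DataFrame(sheet_rows),
        truth=truth,
    )


def generate_timepoints(cohort: SimulatedCohort,
                        config: Optional[SimConfig] = None) -> SimulatedCohort:
    """Add a post-treatment visit with per-clone fold changes.

    Each first-visit clone draws a dynamics class from the configured
    mixture and a fold change from that class's range; ``lost_rate`` clones
    drop to zero and ``emergent_rate`` (relative to clones_per_subject) new
    clones appear. Both the drawn class and the realized frequency-based
    class (which renormalisation can shift across the ±20% boundary) are
    recorded in truth. Returns an extended cohort, leaving the input's
    pre-visit tables intact.
    """
    cfg = config or cohort.truth.config
    truth = cohort.truth
    # independent stream so the pre visit is unchanged by adding a post visit
    rng = np.random.default_rng((cfg.seed + 0x9E3779B1) % (2**31))
    class_names = list(cfg.dynamics_mixture)
    probs = np.array([cfg.dynamics_mixture[c][0] for c in class_names], dtype=float)
    probs /= probs.sum()

    for clone in truth.clones:
        if rng.random() < cfg.lost_rate:
            clone.size_post = 0
            clone.intended_class = "lost"
            continue
        cls = str(rng.choice(class_names, p=probs))
        _, lo, hi = cfg.dynamics_mixture[cls]
        fold = rng.uniform(lo, hi)
        clone.size_post = max(1, int(round(clone.size_pre * fold)))
        clone.intended_class = cls

    # emergent clones
    new_clones = []
    for subj in truth.subjects:
        n_new = int(round(cfg.emergent_rate * cfg.clones_per_subject))
        sizes = _sample_powerlaw_sizes(max(n_new, 1), cfg.ccdf_exponent,
                                       cfg.max_clone_size, rng)[:n_new]
        for j, size in enumerate(sizes):
            c = _make_clone(rng, cfg, f"{subj}_e{j:04d}", subj, 0)
            c.size_pre = 0
            c.size_post = int(size)
            c.intended_class = "emergent"
            new_clones.append(c)
    truth.clones.extend(new_clones)

    # realized frequency-based classes from true sizes
    for subj in truth.subjects:
        realized = truth.realized_dynamics(subj)
        for c in truth.clones_of(subj):
            c.dynamics_class = realized[(c.cdr3_nt_alpha, c.cdr3_nt_beta)]

    sheet_rows = cohort.sample_sheet.to_dict("records")
    for subj in truth.subjects:
        sample_id = f"{subj}_post"
        table, n_cells, _ = _emit_sample(rng, cfg, sample_id,
                                         truth.clones_of(subj), "post")
        cohort.contig_tables[sample_id] = table
        truth.n_total_cells[sample_id] = n_cells
        sheet_rows.append({
            "sample_id": sample_id, "subject_id": subj, "timepoint": "post",
            "group": truth.groups[subj], "cmv_status": truth.cmv[subj],
            "responder": "na",
        })
    cohort.sample_sheet = pd.DataFrame(sheet_rows)
    return cohort


def generate_embedding(cohort: SimulatedCohort,
                       config: Optional[SimConfig] = None) -> pd.DataFrame:
    """Clone-correlated embedding for every contig-bearing cell.

    Clone centers ~ N(0, sigma_between^2 I); cell coordinates ~ N(center,
    sigma_within^2 I); batch = sample_id. sigma_between = 0 is the null
    mode with no clone-embedding association.
    """
    cfg = config or cohort.truth.config
    truth = cohort.truth
    rng = np.random.default_rng((cfg.seed + 0x85EBCA77) % (2**31))
    centers: dict[str, np.ndarray] = {}
    for clone in truth.clones:
        key = clone.cdr3_nt_alpha + "|" + clone.cdr3_nt_beta
        if key not in centers:
            centers[key] = rng.normal(0.0, cfg.sigma_between, size=cfg.n_dims)
        clone.embedding_center = centers[key]

    # map barcodes back to clones through each table's contig rows
    rows = []
    for sample_id, table in cohort.contig_tables.items():
        clone_by_beta_nt = {c.cdr3_nt_beta: c for c in truth.clones}
        clone_by_alpha_nt = {c.cdr3_nt_alpha: c for c in truth.clones}
        seen = set()
        for r in table.itertuples(index=False):
            if r.barcode in seen:
                continue
            clone = (clone_by_beta_nt.get(r.cdr3_nt)
                     if r.chain == "TRB" else clone_by_alpha_nt.get(r.cdr3_nt))
            if clone is None:
                continue
            seen.add(r.barcode)
            coord = rng.normal(clone.embedding_center, cfg.sigma_within)
            row = {"barcode": r.barcode, "sample_id": sample_id}
            row.update({f"dim_{d + 1}": coord[d] for d in range(cfg.n_dims)})
            row["batch"] = sample_id
            rows.append(row)
    emb = pd.DataFrame(rows)
    cohort.embedding = emb
    return emb


def write_cohort(cohort: SimulatedCohort, out_dir) -> None:
    """Write the cohort as text files: per-sample 10x contig CSVs,
    sample_sheet.csv, embedding.tsv (if generated) and truth/*.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample_id, table in cohort.contig_tables.items():
        table.to_csv(out / f"{sample_id}.csv", index=False)
    cohort.sample_sheet.to_csv(out / "sample_sheet.csv", index=False)
    if cohort.embedding is not None:
        cohort.embedding.to_csv(out / "embedding.tsv", sep="\t", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    clone_rows = [
        {
            "clone_id": c.clone_id, "subject_id": c.subject_id,
            "cdr3_aa_alpha": c.cdr3_aa_alpha, "cdr3_aa_beta": c.cdr3_aa_beta,
            "cdr3_nt_alpha": c.cdr3_nt_alpha, "cdr3_nt_beta": c.cdr3_nt_beta,
            "v_alpha": c.v_alpha, "j_alpha": c.j_alpha,
            "v_beta": c.v_beta, "j_beta": c.j_beta,
            "size_pre": c.size_pre,
            "size_post": "" if c.size_post is None else c.size_post,
            "intended_class": c.intended_class or "",
            "dynamics_class": c.dynamics_class or "",
            "planted_motif": c.planted_motif or "",
        }
        for c in cohort.truth.clones
    ]
    pd.DataFrame(clone_rows).to_csv(truth_dir / "clones.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s, "n_total_cells": n}
         for s, n in sorted(cohort.truth.n_total_cells.items())]
    ).to_csv(truth_dir / "cells.tsv", sep="\t", index=False)


def reference_repertoire(n: int = 5000, seed: int = 12345,
                         config: Optional[SimConfig] = None) -> list[str]:
    """Synthetic naive reference repertoire for motif enrichment.

    CDR3beta strings drawn from the same length/composition model with no
    planted motifs; a stand-in for an external naive reference, replaceable
    by a user-supplied file of sequences.
    """
    cfg = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    return [_random_cdr3(rng, cfg) for _ in range(n)]
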