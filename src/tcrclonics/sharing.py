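"""Cross-sample clonotype sharing and longitudinal clone dynamics.

Sharing counts identical CDR3 keys between samples (optionally restricted
to each sample's top-n clones, as in top-200 sharing heatmaps). Dynamics
matches a subject's pre- and post-treatment clonotype tables and classifies
every clone by its proportional frequency change: increased (> +20%),
unchanged (within ±20%, boundary inclusive), decreased (< −20%); clones
observed at only one timepoint are emergent or lost and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clonotyping import ClonotypeTable, EXPANDED_MIN_CELLS
from .io import ConfigError

#: proportional-change threshold for the increased/unchanged/decreased calls
DYNAMICS_THRESHOLD = 0.20


def _identity_key(key: tuple, scheme: str, identity: str) -> tuple:
    """Project a clonotype key to the requested identity level.

    nt-level keys are the scheme's CDR3 nucleotide tuple; aa-level identity
    is only available for aa_paired tables (nt keys are not translated here,
    they come from the caller's chosen scheme).
    """
    if identity not in ("nt", "aa"):
        raise ConfigError(f"identity must be 'nt' or 'aa', got {identity!r}")
    if scheme == "nt_paired_vj":
        return key[:2]  # drop gene names for sequence-identity sharing
    return key


def shared_clonotypes(a: ClonotypeTable, b: ClonotypeTable,
                      identity: str = "nt") -> int:
    """Number of distinct clonotype keys present in both samples."""
    if a.key_scheme != b.key_scheme:
        raise ConfigError(
            f"incompatible key schemes: {a.key_scheme} vs {b.key_scheme}"
        )
    nt_schemes = ("nt_paired", "nt_paired_vj", "beta_nt_only")
    if identity == "nt" and a.key_scheme not in nt_schemes:
        raise ConfigError("nt identity requires a nucleotide key scheme")
    if identity == "aa" and a.key_scheme not in ("aa_paired", "beta_aa_only"):
        raise ConfigError("aa identity requires an amino-acid key scheme")
    ka = {_identity_key(k, a.key_scheme, identity) for k in a.entries}
    kb = {_identity_key(k, b.key_scheme, identity) for k in b.entries}
    return len(ka & kb)


def _top_n_keys(table: ClonotypeTable, n: int) -> set:
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1]["size"], kv[0]))
    return {k for k, _ in ranked[:n]}


@dataclass
class SharingMatrix:
    sample_ids: list[str]
    matrix: np.ndarray  # symmetric counts; diagonal = own clone count under mode
    mode: str
    n: Optional[int]
    identity: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids,
                            columns=self.sample_ids)


def sharing_matrix(tables: Sequence[ClonotypeTable], mode: str = "top_n",
                   n: int = 200, identity: str = "nt") -> SharingMatrix:
    """Pairwise shared-clonotype counts across samples.

    mode = "top_n" restricts each sample to its n largest clones (size-then-
    key tie-break) before intersecting; mode = "all_clones" uses every clone.
    The diagonal holds each sample's own clone count under the mode.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 samples")
    if mode not in ("all_clones", "top_n"):
        raise ConfigError(f"unknown sharing mode {mode!r}")
    scheme = tables[0].key_scheme
    keysets = []
    for t in tables:
        if t.key_scheme != scheme:
            raise ConfigError("all tables must share one key scheme")
        keys = _top_n_keys(t, n) if mode == "top_n" else set(t.entries)
        keysets.append({_identity_key(k, scheme, identity) for k in keys})
    m = len(tables)
    mat = np.zeros((m, m), dtype=int)
    for i in range(m):
        mat[i, i] = len(keysets[i])
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = len(keysets[i] & keysets[j])
    return SharingMatrix(
        sample_ids=[t.sample_id for t in tables], matrix=mat,
        mode=mode, n=n if mode == "top_n" else None, identity=identity,
    )


@dataclass(frozen=True)
class CloneDynamicsRecord:
    subject_id: str
    key: tuple
    size_pre: int
    size_post: int
    freq_pre: float
    freq_post: float
    rel_change: Optional[float]  # (freq_post - freq_pre)/freq_pre when defined
    dynamics_class: str  # increased | unchanged | decreased | emergent | lost


def classify_change(rel_change: float,
                    threshold: float = DYNAMICS_THRESHOLD) -> str:
    if rel_change > threshold:
        return "increased"
    if rel_change < -threshold:
        return "decreased"
    return "unchanged"


def match_clones(pre: ClonotypeTable, post: ClonotypeTable,
                 subject_id: Optional[str] = None,
                 threshold: float = DYNAMICS_THRESHOLD) -> list[CloneDynamicsRecord]:
    """Outer-join two timepoints of one subject and classify every clone.

    Frequencies come from each table's own keyed-cell denominator, so
    differing sequencing depths do not masquerade as expansion.
    """
    if pre.key_scheme != post.key_scheme:
        raise ConfigError("pre/post tables use different key schemes")
    if subject_id is None:
        subject_id = pre.sample_id
    records = []
    for key in sorted(set(pre.entries) | set(post.entries)):
        e_pre, e_post = pre.entries.get(key), post.entries.get(key)
        size_pre = e_pre["size"] if e_pre else 0
        size_post = e_post["size"] if e_post else 0
        freq_pre = e_pre["frequency"] if e_pre else 0.0
        freq_post = e_post["frequency"] if e_post else 0.0
        if size_pre == 0:
            rel, cls = None, "emergent"
        elif size_post == 0:
            rel, cls = None, "lost"
        else:
            rel = (freq_post - freq_pre) / freq_pre
            cls = classify_change(rel, threshold)
        records.append(CloneDynamicsRecord(
            subject_id=subject_id, key=key,
            size_pre=size_pre, size_post=size_post,
            freq_pre=freq_pre, freq_post=freq_post,
            rel_change=rel, dynamics_class=cls,
        ))
    return records


def dynamics_summary(records: Sequence[CloneDynamicsRecord],
                     restrict_to: str = "expanded_either",
                     min_cells: int = EXPANDED_MIN_CELLS) -> dict:
    """Counts per dynamics class with per-class absolute size-change ranges.

    By default only clones expanded (>= min_cells) at either timepoint enter
    the increased/unchanged/decreased counts; emergent and lost clones are
    tallied separately and never enter the three classes.
    """
    if restrict_to not in ("expanded_either", "all"):
        raise ConfigError(f"unknown restriction {restrict_to!r}")
    summary = {c: {"count": 0, "size_change_range": None}
               for c in ("increased", "unchanged", "decreased")}
    n_emergent = n_lost = 0
    deltas: dict[str, list[int]] = {c: [] for c in summary}
    for r in records:
        if r.dynamics_class == "emergent":
            n_emergent += 1
            continue
        if r.dynamics_class == "lost":
            n_lost += 1
            continue
        if restrict_to == "expanded_either" and max(r.size_pre, r.size_post) < min_cells:
            continue
        summary[r.dynamics_class]["count"] += 1
        deltas[r.dynamics_class].append(abs(r.size_post - r.size_pre))
    for cls, d in deltas.items():
        if d:
            summary[cls]["size_change_range"] = (min(d), max(d))
    summary["emergent"] = n_emergent
    summary["lost"] = n_lost
    return summary
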