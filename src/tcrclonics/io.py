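"""Reading and writing repertoire file formats.

Supports the 10x Cell Ranger ``filtered_contig_annotations.csv`` dialect and
the AIRR Rearrangement TSV, plus a cohort sample sheet and an optional
per-cell embedding table. All downstream cell identity is the pair
``(sample_id, barcode)``: barcodes are opaque strings and may collide across
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

VALID_LOCI = frozenset({"TRA", "TRB"})

#: standard-table codon -> amino acid (DNA alphabet), used for the
#: productive-contig translation invariant and by the simulator
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Standard-table translation of an in-frame nucleotide string."""
    if len(nt) % 3:
        raise ValueError(f"length {len(nt)} not a multiple of 3")
    return "".join(CODON_TABLE[nt[i : i + 3].upper()] for i in range(0, len(nt), 3))


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


class ConfigError(ValueError):
    """Inconsistent cohort configuration (sample sheet, paths, schemes)."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig for one cell barcode."""

    barcode: str
    contig_id: str
    chain: str
    v_gene: Optional[str] = None
    d_gene: Optional[str] = None
    j_gene: Optional[str] = None
    c_gene: Optional[str] = None
    cdr3_aa: Optional[str] = None
    cdr3_nt: Optional[str] = None
    productive: bool = False
    high_confidence: bool = True
    umis: int = 0
    reads: int = 0


@dataclass(frozen=True)
class SampleSheetRow:
    sample_id: str
    subject_id: str
    timepoint: str
    group: str
    cmv_status: str = "unknown"
    responder: str = "na"
    contig_file: Optional[str] = None


@dataclass
class Cohort:
    """A loaded cohort: sample metadata, per-sample contigs, optional embedding."""

    samples: list[SampleSheetRow]
    contigs: dict[str, list[ContigRecord]]
    embedding: Optional[pd.DataFrame] = None
    n_orphan_embedding_cells: int = 0

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleSheetRow:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


_TRUE_STRINGS = {"true", "t", "yes", "1", "productive"}
_FALSE_STRINGS = {"false", "f", "no", "0", "none", "non-productive", "not productive"}


def _parse_bool(value, default: bool = False) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    return default


def _clean_str(value) -> Optional[str]:
    """Missing sentinel handling: NaN / 'None' / '' -> None, never ''."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"none", "nan", "na"}:
        return None
    return s


# column aliases: Cell Ranger versions drift between cdr3/junction naming
_TENX_ALIASES = {
    "cdr3_aa": ("cdr3", "junction_aa"),
    "cdr3_nt": ("cdr3_nt", "junction"),
}
_TENX_REQUIRED = ("barcode", "chain", "v_gene", "j_gene", "productive", "umis")
_AIRR_REQUIRED = (
    "cell_id", "locus", "v_call", "j_call", "junction", "junction_aa",
    "productive", "duplicate_count",
)


def read_contig_table(path, dialect: str = "tenx_csv") -> list[ContigRecord]:
    """Read a per-sample contig annotation table.

    Parameters
    ----------
    path : path-like
        CSV (``tenx_csv``) or TSV (``airr_tsv``) file.
    dialect : {"tenx_csv", "airr_tsv"}

    Returns
    -------
    list of ContigRecord, in file order. Rows whose locus is not TRA/TRB are
    dropped (count logged). Missing CDR3 fields become ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tenx_csv":
        df = pd.read_csv(path, dtype=str)
        return _records_from_tenx(df, str(path))
    if dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return _records_from_airr(df, str(path))
    raise ConfigError(f"unknown dialect {dialect!r}")


def records_from_frame(df: pd.DataFrame, dialect: str = "tenx_csv",
                       source: str = "<frame>") -> list[ContigRecord]:
    """Parse an in-memory contig table (same contract as read_contig_table)."""
    df = df.astype(str)
    if dialect == "tenx_csv":
        return _records_from_tenx(df, source)
    if dialect == "airr_tsv":
        return _records_from_airr(df, source)
    raise ConfigError(f"unknown dialect {dialect!r}")


def _require_columns(df: pd.DataFrame, required: Iterable[str], source: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing mandatory column(s) {missing}")


def _resolve_alias(df: pd.DataFrame, names: Sequence[str]) -> Optional[str]:
    for n in names:
        if n in df.columns:
            return n
    return None


def _int_field(value, row_ix: int, source: str, colname: str) -> int:
    try:
        return int(float(value)) if _clean_str(value) is not None else 0
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{source} row {row_ix}: bad {colname} {value!r}") from exc


def _records_from_tenx(df: pd.DataFrame, source: str) -> list[ContigRecord]:
    _require_columns(df, _TENX_REQUIRED, source)
    aa_col = _resolve_alias(df, _TENX_ALIASES["cdr3_aa"])
    nt_col = _resolve_alias(df, _TENX_ALIASES["cdr3_nt"])
    if aa_col is None or nt_col is None:
        raise FormatError(
            f"{source}: missing mandatory column(s) "
            f"{[c for c, col in (('cdr3', aa_col), ('cdr3_nt', nt_col)) if col is None]}"
        )
    records, n_dropped = [], 0
    for ix, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        chain = _clean_str(r.get("chain"))
        if chain not in VALID_LOCI:
            n_dropped += 1
            continue
        records.append(
            ContigRecord(
                barcode=str(r["barcode"]),
                contig_id=str(r.get("contig_id", f"contig_{ix}")),
                chain=chain,
                v_gene=_clean_str(r.get("v_gene")),
                d_gene=_clean_str(r.get("d_gene")),
                j_gene=_clean_str(r.get("j_gene")),
                c_gene=_clean_str(r.get("c_gene")),
                cdr3_aa=_clean_str(r.get(aa_col)),
                cdr3_nt=_clean_str(r.get(nt_col)),
                productive=_parse_bool(r.get("productive")),
                high_confidence=_parse_bool(r.get("high_confidence"), default=True),
                umis=_int_field(r.get("umis"), ix, source, "umis"),
                reads=_int_field(r.get("reads", 0), ix, source, "reads"),
            )
        )
    if n_dropped:
        log.info("%s: dropped %d non-TRA/TRB contig rows", source, n_dropped)
    if not records:
        log.warning("%s: no usable contig records", source)
    return records


def _records_from_airr(df: pd.DataFrame, source: str) -> list[ContigRecord]:
    _require_columns(df, _AIRR_REQUIRED, source)
    records, n_dropped = [], 0
    for ix, row in enumerate(df.itertuples(index=False), start=2):
        r = dict(zip(df.columns, row))
        chain = _clean_str(r.get("locus"))
        if chain not in VALID_LOCI:
            n_dropped += 1
            continue
        records.append(
            ContigRecord(
                barcode=str(r["cell_id"]),
                contig_id=str(r.get("sequence_id", f"contig_{ix}")),
                chain=chain,
                v_gene=_clean_str(r.get("v_call")),
                d_gene=_clean_str(r.get("d_call")),
                j_gene=_clean_str(r.get("j_call")),
                c_gene=_clean_str(r.get("c_call")),
                cdr3_aa=_clean_str(r.get("junction_aa")),
                cdr3_nt=_clean_str(r.get("junction")),
                productive=_parse_bool(r.get("productive")),
                high_confidence=_parse_bool(r.get("high_confidence"), default=True),
                umis=_int_field(r.get("duplicate_count"), ix, source, "duplicate_count"),
                reads=_int_field(r.get("consensus_count", 0), ix, source, "consensus_count"),
            )
        )
    if n_dropped:
        log.info("%s: dropped %d non-TRA/TRB rows", source, n_dropped)
    if not records:
        log.warning("%s: no usable contig records", source)
    return records


_AIRR_EXPORT_COLUMNS = [
    "cell_id", "sequence_id", "locus", "v_call", "d_call", "j_call", "c_call",
    "junction", "junction_aa", "productive", "duplicate_count", "consensus_count",
]


def write_airr(records: Iterable[ContigRecord], path) -> None:
    """Export contigs as AIRR Rearrangement TSV (round-trips with read)."""
    rows = [
        {
            "cell_id": r.barcode,
            "sequence_id": r.contig_id,
            "locus": r.chain,
            "v_call": r.v_gene or "",
            "d_call": r.d_gene or "",
            "j_call": r.j_gene or "",
            "c_call": r.c_gene or "",
            "junction": r.cdr3_nt or "",
            "junction_aa": r.cdr3_aa or "",
            "productive": "T" if r.productive else "F",
            "duplicate_count": r.umis,
            "consensus_count": r.reads,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_AIRR_EXPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_table(rows, path) -> None:
    """Write any tabular result as TSV with 6-significant-digit floats.

    Accepts a DataFrame or an iterable of mapping rows. Row order is
    preserved as given (producers are responsible for a deterministic sort),
    so writing the same result twice yields byte-identical files.
    """
    if rows is None:
        raise ValueError("rows is None")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sample_sheet(path) -> list[SampleSheetRow]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("sample_id", "subject_id", "timepoint", "group"), str(path))
    rows = []
    for r in df.to_dict("records"):
        rows.append(
            SampleSheetRow(
                sample_id=str(r["sample_id"]),
                subject_id=str(r["subject_id"]),
                timepoint=str(r["timepoint"]),
                group=str(r["group"]),
                cmv_status=_clean_str(r.get("cmv_status")) or "unknown",
                responder=_clean_str(r.get("responder")) or "na",
                contig_file=_clean_str(r.get("contig_file")),
            )
        )
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate sample_id(s) in sample sheet: {dupes}")
    pairs = [(r.subject_id, r.timepoint) for r in rows]
    if len(set(pairs)) != len(pairs):
        raise ConfigError("duplicate (subject_id, timepoint) pairs in sample sheet")
    return rows


def read_embedding(path) -> pd.DataFrame:
    """Read a per-cell embedding TSV: barcode, sample_id, dim_1..dim_k, batch."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("barcode", "sample_id"), str(path))
    dims = [c for c in df.columns if c.startswith("dim_")]
    if len(dims) < 2:
        raise FormatError(f"{path}: embedding needs >= 2 dim_* columns")
    if "batch" not in df.columns:
        df["batch"] = df["sample_id"]
    if df.duplicated(subset=["sample_id", "barcode"]).any():
        raise FormatError(f"{path}: duplicate (sample_id, barcode) keys")
    return df


def load_cohort(sample_sheet, contig_dir, embedding_path=None,
                dialect: str = "tenx_csv") -> Cohort:
    """Assemble a Cohort from a sample sheet, a contig directory and an
    optional embedding table.

    Contig files are located by the sample sheet's ``contig_file`` column
    when present, else ``<sample_id>.csv`` (or ``.tsv`` for AIRR) in
    *contig_dir*. A sample whose table parses to zero contigs is retained
    with a warning; a missing file is an error naming the sample.
    """
    samples = read_sample_sheet(sample_sheet)
    contig_dir = Path(contig_dir)
    ext = ".csv" if dialect == "tenx_csv" else ".tsv"
    contigs: dict[str, list[ContigRecord]] = {}
    for s in samples:
        f = contig_dir / (s.contig_file or f"{s.sample_id}{ext}")
        if not f.exists():
            raise ConfigError(f"sample {s.sample_id!r}: contig file {f} not found")
        recs = read_contig_table(f, dialect=dialect)
        if not recs:
            log.warning("sample %s: zero contig records; sample retained", s.sample_id)
        contigs[s.sample_id] = recs
        log.info("sample %s: %d contigs, %d cells", s.sample_id, len(recs),
                 len({r.barcode for r in recs}))
    cohort = Cohort(samples=samples, contigs=contigs)
    if embedding_path is not None:
        emb = read_embedding(embedding_path)
        known = {
            (sid, r.barcode) for sid, recs in contigs.items() for r in recs
        }
        keys = list(zip(emb["sample_id"].astype(str), emb["barcode"].astype(str)))
        orphan = [k not in known for k in keys]
        cohort.n_orphan_embedding_cells = int(sum(orphan))
        if cohort.n_orphan_embedding_cells:
            log.warning("embedding: %d orphan cells with no contig-bearing match",
                        cohort.n_orphan_embedding_cells)
        cohort.embedding = emb
    return cohort
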