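import numpy as np
import pytest

from tcrclonics.io import ContigRecord
from tcrclonics.simulate import SimConfig, generate_repertoire


def contig(barcode, chain, cdr3_nt=None, cdr3_aa=None, umis=5, productive=True,
           contig_id=None, v_gene=None, j_gene=None):
    return ContigRecord(
        barcode=barcode,
        contig_id=contig_id or f"{barcode}_{chain}_{umis}",
        chain=chain, v_gene=v_gene, j_gene=j_gene,
        cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt,
        productive=productive, umis=umis,
    )


@pytest.fixture
def four_barcode_contigs():
    """(alpha+beta), (alpha only), (beta only), (2 alpha + beta) cells."""
    return [
        contig("bc1", "TRA", "TGTGCTGCT", "CAA"),
        contig("bc1", "TRB", "TGTGCTTCT", "CAS"),
        contig("bc2", "TRA", "TGTGCTGGT", "CAG"),
        contig("bc3", "TRB", "TGTGCTTTT", "CAF"),
        contig("bc4", "TRA", "TGTGCTATT", "CAI", umis=9),
        contig("bc4", "TRA", "TGTGCTCTT", "CAL", umis=4),
        contig("bc4", "TRB", "TGTGCTTGT", "CAC"),
    ]


@pytest.fixture
def dropout_free_cohort():
    """Small two-subject cohort with no chain dropout or multi-chain noise."""
    cfg = SimConfig(
        seed=7, n_subjects=2, clones_per_subject=60, max_clone_size=200,
        p_alpha_detect=1.0, p_beta_detect=1.0,
        p_multi_alpha=0.0, p_multi_beta=0.0,
    )
    return generate_repertoire(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)
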