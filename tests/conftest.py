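"""Shared fixtures: programmatically built sequence records and files.

All fixtures are synthetic, generated at test time; nothing binary is stored
in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from endloop.sequence_io import Clade, GeneClass, MRNARecord

BASES = np.array(list("ACGU"))


def make_eligible_record(
    rec_id: str,
    *,
    species: str = "XX",
    clade: Clade = Clade.OTHER,
    gene_class: GeneClass = GeneClass.UNKNOWN,
    length: int = 260,
    gc: float = 0.5,
    seed: int = 0,
    polya: int = 10,
) -> MRNARecord:
    """A synthetic record passing every eligibility criterion.

    Layout: 30 nt 5'UTR | CDS | 3'UTR ending in AAUAAA + spacer + poly(A).
    ``length`` counts everything including the poly(A) run.
    """
    rng = np.random.default_rng(seed)
    p_gc = gc / 2
    probs = [(1 - gc) / 2, p_gc, p_gc, (1 - gc) / 2]  # A C G U
    tail = "AAUAAA" + "CUCUGC"[: max(0, 6)] + "A" * polya
    body_len = length - len(tail)
    assert body_len > 60, "length too short for the fixture layout"
    body = "".join(rng.choice(BASES, size=body_len, p=probs))
    seq = body + tail
    utr3_start = length - len(tail) - 20
    return MRNARecord(
        id=rec_id,
        sequence=seq,
        species_code=species,
        clade=clade,
        gene_class=gene_class,
        utr5_span=(1, 30),
        cds_span=(31, utr3_start - 1),
        utr3_span=(utr3_start, length),
    )


@pytest.fixture
def eligible_record() -> MRNARecord:
    """A 391-nt record with both UTRs, a PAS and a terminal poly(A) run."""
    return make_eligible_record("syn_hamp_391", length=391, seed=7)


GENBANK_FIXTURE = """\
LOCUS       SYNREC01                 120 bp    mRNA    linear   SYN 01-JAN-2024
DEFINITION  synthetic test mRNA with annotated UTRs.
ACCESSION   SYNREC01
VERSION     SYNREC01.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     source          1..120
                     /organism="synthetic construct"
     5'UTR           1..20
     CDS             21..80
                     /codon_start=1
                     /translation="MAAAAAAAAAAAAAAAAAAA"
     3'UTR           81..120
ORIGIN
        1 acgtacgtac gtacgtacgt atggcagcag cagcagcagc agcagcagca gcagcagcag
       61 cagcagcagc agcagcatga aataaacgta cgtacgtacg aaaaaaaaaa aaaaaaaaaa
//
"""


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "synthetic.gb"
    path.write_text(GENBANK_FIXTURE)
    return path


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "records.fa"
    path.write_text(
        ">rec1 species=GB clade=viridiplantae gene_class=housekeeping utr5=1-4 cds=5-12 utr3=13-20\n"
        "ACGTACGTACGTACGTACGT\n"
        ">rec2\n"
        "GGGGAAAACCCC\n"
    )
    return path
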