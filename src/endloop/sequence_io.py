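"""Reading mRNA sequences and applying the survey's eligibility criteria.

Records come from FASTA or GenBank flat files (via Biopython).  Eligibility
follows the survey's selection rules for full-length native mRNAs: annotated
5' and 3' UTRs, a polyadenylation signal (PAS) plus the start of the poly(A)
tail in the 3' UTR, and a total length between 200 and 7000 nt.

Coordinates are 1-based closed intervals throughout, matching the GenBank
feature convention.  Sequences are sense-strand mRNA; DNA input (T) is
transparently normalized to RNA (U).

FASTA headers may carry annotations as ``key=value`` tokens after the id,
e.g.::

    >HAMP_PT species=PT clade=vertebrate gene_class=homologous utr5=1-50 cds=51-300 utr3=301-391

This is the package's own lightweight convention for moving annotated
records through plain-text fixtures and pipelines; GenBank files carry the
same information in their feature tables.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, TextIO

from Bio import SeqIO

from .errors import DomainError, ParseError
from .folding import RNA_ALPHABET

__all__ = [
    "Clade",
    "GeneClass",
    "MRNARecord",
    "FilterCriteria",
    "FilterResult",
    "read_sequences",
    "check_eligibility",
    "gc_content",
    "at_content",
    "utr3_length",
    "trim_polya_tail",
    "write_filter_report",
]


class Clade(str, enum.Enum):
    HALOBACTERIA = "halobacteria"
    VIRIDIPLANTAE = "viridiplantae"
    INVERTEBRATE = "invertebrate"
    VERTEBRATE = "vertebrate"
    OTHER = "other"


class GeneClass(str, enum.Enum):
    HOMOLOGOUS = "homologous"
    HOUSEKEEPING = "housekeeping"
    HIGHLY_EXPRESSED = "highly_expressed"
    HETEROLOGOUS = "heterologous"
    UNKNOWN = "unknown"


Span = tuple[int, int]  # 1-based closed interval


def _normalize(sequence: str, *, context: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ParseError(f"record {context}: non-RNA characters {sorted(bad)}")
    return seq


def _check_span(span: Span | None, n: int, name: str, context: str) -> None:
    if span is None:
        return
    s, e = span
    if not (1 <= s <= e <= n):
        raise ParseError(f"record {context}: {name} span {span} outside 1..{n}")


@dataclass(frozen=True)
class MRNARecord:
    """One annotated mRNA sequence."""

    id: str
    sequence: str
    species_code: str = ""
    clade: Clade = Clade.OTHER
    gene_class: GeneClass = GeneClass.UNKNOWN
    utr5_span: Span | None = None
    cds_span: Span | None = None
    utr3_span: Span | None = None
    source: str = ""

    def __post_init__(self) -> None:
        seq = _normalize(self.sequence, context=self.id or "<unnamed>")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise DomainError(f"record {self.id}: empty sequence")
        n = len(seq)
        for name, span in (
            ("utr5", self.utr5_span),
            ("cds", self.cds_span),
            ("utr3", self.utr3_span),
        ):
            _check_span(span, n, name, self.id)
        spans = [s for s in (self.utr5_span, self.cds_span, self.utr3_span) if s]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 >= s2:
                raise ParseError(
                    f"record {self.id}: spans overlap or out of order "
                    f"({(s1, e1)} vs {(s2, e2)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterCriteria:
    """Eligibility rules for full-length native mRNAs.

    An empty ``pas_motifs`` tuple disables the PAS check; ``min_polya_run=0``
    disables the poly(A)-start check.  The PAS is searched within the 3' UTR
    when annotated, else within the final ``pas_window`` nt.
    """

    min_len: int = 200
    max_len: int = 7000
    require_utrs: bool = True
    pas_motifs: tuple[str, ...] = ("AAUAAA", "AUUAAA")
    min_polya_run: int = 8
    pas_window: int = 200

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise DomainError(
                f"min_len {self.min_len} > max_len {self.max_len}"
            )
        for motif in self.pas_motifs:
            bad = set(motif.upper().replace("T", "U")) - RNA_ALPHABET
            if bad:
                raise DomainError(f"PAS motif {motif!r}: non-RNA characters")


class FailureCode(str, enum.Enum):
    TOO_SHORT = "TOO_SHORT"
    TOO_LONG = "TOO_LONG"
    NO_UTR5 = "NO_UTR5"
    NO_UTR3 = "NO_UTR3"
    NO_PAS = "NO_PAS"
    NO_POLYA_START = "NO_POLYA_START"


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    failures: tuple[FailureCode, ...]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failures) == 0)


def check_eligibility(
    record: MRNARecord, criteria: FilterCriteria = FilterCriteria()
) -> FilterResult:
    """Evaluate every criterion and accumulate all failures (no short-circuit)."""
    failures: list[FailureCode] = []
    n = len(record)
    if n < criteria.min_len:
        failures.append(FailureCode.TOO_SHORT)
    if n > criteria.max_len:
        failures.append(FailureCode.TOO_LONG)
    if criteria.require_utrs:
        if record.utr5_span is None:
            failures.append(FailureCode.NO_UTR5)
        if record.utr3_span is None:
            failures.append(FailureCode.NO_UTR3)
    if criteria.pas_motifs:
        if record.utr3_span is not None:
            s, e = record.utr3_span
            region = record.sequence[s - 1 : e]
        else:
            region = record.sequence[-criteria.pas_window :]
        motifs = [m.upper().replace("T", "U") for m in criteria.pas_motifs]
        if not any(m in region for m in motifs):
            failures.append(FailureCode.NO_PAS)
    if criteria.min_polya_run > 0:
        if _terminal_polya_run(record.sequence) < criteria.min_polya_run:
            failures.append(FailureCode.NO_POLYA_START)
    return FilterResult(passed=not failures, failures=tuple(failures))


def _terminal_polya_run(sequence: str) -> int:
    """Length of the run of consecutive A ending at the 3' terminus."""
    run = 0
    for ch in reversed(sequence):
        if ch != "A":
            break
        run += 1
    return run


def trim_polya_tail(sequence: str, min_run: int = 8) -> str:
    """Remove the terminal poly(A) homopolymer before folding.

    A long poly(A) run is entirely unpaired in predicted structures and would
    trivially inflate the exterior loop; moreover the tail is bound by
    poly(A)-binding protein in vivo.  Runs shorter than ``min_run`` are kept
    (they may be genuine 3'-UTR sequence).
    """
    run = _terminal_polya_run(sequence)
    if run >= min_run:
        return sequence[: len(sequence) - run]
    return sequence


def gc_content(sequence: str) -> float:
    """GC percentage of a sequence, in [0, 100]."""
    if not sequence:
        raise DomainError("gc_content of empty sequence")
    seq = sequence.upper().replace("T", "U")
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def at_content(sequence: str) -> float:
    """AU percentage; complements gc_content for gap-free RNA."""
    if not sequence:
        raise DomainError("at_content of empty sequence")
    seq = sequence.upper().replace("T", "U")
    return 100.0 * sum(1 for c in seq if c in "AU") / len(seq)


def utr3_length(record: MRNARecord) -> int | None:
    """3'-UTR length in nt, or None when unannotated (excluded downstream)."""
    if record.utr3_span is None:
        return None
    s, e = record.utr3_span
    return e - s + 1


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

_SPAN_RE = re.compile(r"^(\d+)-(\d+)$")
_HEADER_KEYS = {"species", "clade", "gene_class", "utr5", "cds", "utr3"}


def _parse_header_annotations(description: str) -> dict:
    out: dict = {}
    for token in description.split()[1:]:
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key not in _HEADER_KEYS:
            continue
        if key in ("utr5", "cds", "utr3"):
            m = _SPAN_RE.match(value)
            if not m:
                raise ParseError(f"bad span annotation {token!r}")
            out[f"{key}_span"] = (int(m.group(1)), int(m.group(2)))
        elif key == "species":
            out["species_code"] = value
        elif key == "clade":
            out["clade"] = Clade(value)
        elif key == "gene_class":
            out["gene_class"] = GeneClass(value)
    return out


_GENBANK_UTR5 = {"5'UTR", "5'utr", "five_prime_UTR"}
_GENBANK_UTR3 = {"3'UTR", "3'utr", "three_prime_UTR"}


def _genbank_spans(seqrecord) -> dict:
    spans: dict = {}
    for feat in seqrecord.features:
        key = None
        if feat.type in _GENBANK_UTR5:
            key = "utr5_span"
        elif feat.type in _GENBANK_UTR3:
            key = "utr3_span"
        elif feat.type == "CDS":
            key = "cds_span"
        if key is None or key in spans:
            continue
        spans[key] = (int(feat.location.start) + 1, int(feat.location.end))
    return spans


def read_sequences(
    path: str | Path | TextIO, format: str = "fasta"
) -> list[MRNARecord]:
    """Read MRNARecords from a FASTA or GenBank flat file.

    FASTA: header ``key=value`` tokens populate annotations (see module
    docstring).  GenBank: the feature table populates UTR/CDS spans and the
    organism annotation the source field.
    """
    if format not in ("fasta", "genbank"):
        raise DomainError(f"unsupported format {format!r}")
    records: list[MRNARecord] = []
    for seqrecord in SeqIO.parse(path, format):
        try:
            if format == "fasta":
                extra = _parse_header_annotations(seqrecord.description)
                source = str(path)
            else:
                extra = _genbank_spans(seqrecord)
                organism = seqrecord.annotations.get("organism", "")
                source = f"{path}|{organism}" if organism else str(path)
            records.append(
                MRNARecord(
                    id=seqrecord.id,
                    sequence=str(seqrecord.seq),
                    source=source,
                    **extra,
                )
            )
        except (DomainError, ParseError, ValueError) as exc:
            raise ParseError(f"malformed record {seqrecord.id!r}: {exc}") from exc
    return records


def write_filter_report(
    records: Sequence[MRNARecord],
    results: Sequence[FilterResult],
    path: str | Path,
) -> None:
    """TSV report: id, length, passed, semicolon-joined failure codes."""
    with open(path, "w") as fh:
        fh.write("id\tlength\tpassed\tfailures\n")
        for rec, res in zip(records, results, strict=True):
            codes = ";".join(c.value for c in res.failures)
            fh.write(f"{rec.id}\t{len(rec)}\t{str(res.passed).lower()}\t{codes}\n")
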