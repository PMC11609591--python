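"""Secondary structures: MFE/suboptimal prediction and structure-file parsing.

The package never implements a folding algorithm itself.  Minimum-free-energy
(MFE) and suboptimal structures come from the ViennaRNA library, which is
treated as a pluggable, version-pinned engine: every :class:`SecondaryStructure`
carries an ``engine`` provenance string (name, version, temperature and
option flags) so that downstream contour-length values are auditable.

Structures produced elsewhere can be read from Vienna dot-bracket text
(:func:`parse_dotbracket`) or mfold connectivity tables (:func:`parse_ct`).
Both parsers reject pseudoknots: the pairing model throughout is nested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Sequence

from .errors import DomainError, EngineError, ParseError

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "FoldConfig",
    "SecondaryStructure",
    "fold_mfe",
    "fold_suboptimal",
    "parse_dotbracket",
    "parse_ct",
    "render_dotbracket",
    "read_fold_file",
]


@dataclass(frozen=True)
class FoldConfig:
    """Engine settings for MFE prediction.

    temperature : folding temperature in degrees Celsius (engine default 37).
    no_lonely_pairs : forbid isolated (helix-of-one) base pairs, as the mfold
        and RNAfold web interfaces do by default.
    dangles : ViennaRNA dangling-end model (2 = engine default).
    """

    temperature: float = 37.0
    no_lonely_pairs: bool = False
    dangles: int = 2


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested RNA secondary structure.

    ``pairs[i]`` (0-based list index, 1-based values) is the 1-based partner of
    position ``i + 1``, or 0 if unpaired.  Pairing must be an involution with
    no self-pairs and no crossing (pseudoknotted) pairs.
    """

    sequence: str
    pairs: tuple[int, ...]
    free_energy: float | None = None
    engine: str = "unspecified"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise DomainError("empty structure")
        if len(self.pairs) != n:
            raise DomainError(
                f"pairs length {len(self.pairs)} != sequence length {n}"
            )
        for i, j in enumerate(self.pairs, start=1):
            if j == 0:
                continue
            if not 1 <= j <= n:
                raise DomainError(f"position {i}: partner {j} out of range 1..{n}")
            if j == i:
                raise DomainError(f"position {i} pairs with itself")
            if self.pairs[j - 1] != i:
                raise ParseError(
                    f"inconsistent pairing: {i}->{j} but {j}->{self.pairs[j - 1]}"
                )
        _check_nested(self.pairs)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dotbracket(self) -> str:
        return render_dotbracket(self)


def _check_nested(pairs: Sequence[int]) -> None:
    """Reject crossing pairs: (i,j) and (k,l) with i < k < j < l."""
    open_stack: list[int] = []
    for i, j in enumerate(pairs, start=1):
        if j > i:
            open_stack.append(j)
        elif 0 < j < i:
            if not open_stack or open_stack[-1] != i:
                raise ParseError(
                    f"pseudoknot: pair ({j},{i}) crosses an enclosing pair"
                )
            open_stack.pop()


def _normalize_rna(sequence: str, *, context: str = "sequence") -> str:
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ParseError(f"{context}: non-RNA characters {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# Engine wrappers
# ---------------------------------------------------------------------------

def _load_engine():
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise EngineError(
            "ViennaRNA python bindings not found; install the 'viennarna' "
            "package (conda-forge/bioconda) or `pip install ViennaRNA`"
        ) from exc
    return RNA


def _model_details(RNA, config: FoldConfig):
    md = RNA.md()
    md.temperature = config.temperature
    md.noLP = 1 if config.no_lonely_pairs else 0
    md.dangles = config.dangles
    return md


def _provenance(RNA, config: FoldConfig) -> str:
    return (
        f"ViennaRNA {RNA.__version__} T={config.temperature:g}C "
        f"noLP={int(config.no_lonely_pairs)} dangles={config.dangles}"
    )


def _pairs_from_dotbracket(structure: str) -> tuple[int, ...]:
    pairs = [0] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i - 1] = j
            pairs[j - 1] = i
        elif ch != ".":
            raise ParseError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(pairs)


def fold_mfe(sequence: str, config: FoldConfig = FoldConfig()) -> SecondaryStructure:
    """Predict the single minimum-free-energy structure of `sequence`.

    Deterministic for a fixed engine version and configuration.  The returned
    free energy is in kcal/mol.
    """
    seq = _normalize_rna(sequence)
    if not seq:
        raise DomainError("cannot fold an empty sequence")
    RNA = _load_engine()
    try:
        fc = RNA.fold_compound(seq, _model_details(RNA, config))
        structure, energy = fc.mfe()
    except Exception as exc:  # pragma: no cover - engine-internal failures
        raise EngineError(f"ViennaRNA fold failed: {exc}") from exc
    return SecondaryStructure(
        sequence=seq,
        pairs=_pairs_from_dotbracket(structure),
        free_energy=float(energy),
        engine=_provenance(RNA, config),
    )


def fold_suboptimal(
    sequence: str,
    k: int,
    config: FoldConfig = FoldConfig(),
    *,
    max_delta: float = 5.0,
) -> list[SecondaryStructure]:
    """Return the `k` lowest-energy structures, ascending by free energy.

    Uses ViennaRNA's complete suboptimal enumeration within an adaptive
    energy band above the MFE (widened until at least `k` structures are
    found, capped at `max_delta` kcal/mol).  The first element is always the
    MFE structure.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    seq = _normalize_rna(sequence)
    mfe = fold_mfe(seq, config)
    if k == 1:
        return [mfe]
    RNA = _load_engine()
    fc = RNA.fold_compound(seq, _model_details(RNA, config))
    delta = 10  # dekacal/mol = 0.1 kcal/mol
    solutions = []
    while True:
        solutions = [s for s in fc.subopt(delta) if s.structure]
        if len(solutions) >= k or delta >= int(max_delta * 100):
            break
        delta *= 2
    solutions.sort(key=lambda s: (s.energy, s.structure != mfe.dotbracket))
    out: list[SecondaryStructure] = []
    provenance = _provenance(RNA, config)
    for sol in solutions[:k]:
        out.append(
            SecondaryStructure(
                sequence=seq,
                pairs=_pairs_from_dotbracket(sol.structure),
                free_energy=float(sol.energy),
                engine=provenance,
            )
        )
    # The enumeration is exhaustive within the band, so the lowest-energy
    # solution is the MFE structure; keep its exact energy.
    if out and out[0].dotbracket != mfe.dotbracket:
        out[0] = mfe
    return out


# ---------------------------------------------------------------------------
# Structure-file parsers
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_dotbracket(text: str, *, engine: str = "dot-bracket input") -> SecondaryStructure:
    """Parse Vienna-style text: a sequence line then a structure line.

    A FASTA-style ``>name`` header line is tolerated; a trailing energy
    annotation ``(-12.30)`` on the structure line is captured.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ParseError("expected a sequence line and a structure line")
    seq = _normalize_rna(lines[0])
    struct_line = lines[1]
    energy: float | None = None
    m = _ENERGY_RE.search(struct_line)
    if m:
        energy = float(m.group(1))
        struct_line = struct_line[: m.start()].strip()
    if len(struct_line) != len(seq):
        raise ParseError(
            f"structure length {len(struct_line)} != sequence length {len(seq)}"
        )
    return SecondaryStructure(
        sequence=seq,
        pairs=_pairs_from_dotbracket(struct_line),
        free_energy=energy,
        engine=engine,
    )


def render_dotbracket(structure: SecondaryStructure) -> str:
    """Dot-bracket string for a nested structure (inverse of parse)."""
    out = []
    for i, j in enumerate(structure.pairs, start=1):
        out.append("." if j == 0 else ("(" if j > i else ")"))
    return "".join(out)


def parse_ct(text: str, *, engine: str = "CT input") -> SecondaryStructure:
    """Parse an mfold connectivity table (CT).

    Header line: length (first token) and optional free-energy annotation
    (``dG = -12.3`` or ``ENERGY = -12.3``).  Body: six whitespace-separated
    columns per position; column 5 is the 1-based partner (0 = unpaired).
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise ParseError(f"CT header does not start with a length: {lines[0]!r}")
    m = re.search(r"(?:dG|ENERGY)\s*=\s*(-?\d+(?:\.\d+)?)", lines[0], re.IGNORECASE)
    energy = float(m.group(1)) if m else None
    body = lines[1 : n + 1]
    if len(body) != n:
        raise ParseError(f"CT body has {len(body)} rows, header says {n}")
    seq_chars = []
    pairs = [0] * n
    for row in body:
        cols = row.split()
        if len(cols) < 6:
            raise ParseError(f"CT row has fewer than 6 columns: {row!r}")
        i = int(cols[0])
        if not 1 <= i <= n:
            raise ParseError(f"CT row index {i} out of range 1..{n}")
        seq_chars.append((i, cols[1]))
        pairs[i - 1] = int(cols[4])
    seq_chars.sort()
    if [i for i, _ in seq_chars] != list(range(1, n + 1)):
        raise ParseError("CT rows do not cover positions 1..n exactly once")
    seq = _normalize_rna("".join(c for _, c in seq_chars), context="CT sequence")
    # SecondaryStructure validation enforces involution and nestedness.
    return SecondaryStructure(
        sequence=seq, pairs=tuple(pairs), free_energy=energy, engine=engine
    )


def read_fold_file(text: str) -> Iterator[tuple[str, SecondaryStructure]]:
    """Iterate (name, structure) records from a multi-record Vienna ``.fold`` file.

    Each record is ``>name`` followed by a sequence line and a structure line.
    """
    name = None
    block: list[str] = []
    count = 0
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith(">"):
            if name is not None:
                yield name, parse_dotbracket("\n".join(block))
            name = ln[1:].strip() or f"record_{count}"
            count += 1
            block = []
        else:
            block.append(ln)
    if name is not None:
        yield name, parse_dotbracket("\n".join(block))
    elif block:  # headerless single record
        yield "record_0", parse_dotbracket("\n".join(block))
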