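"""Synthetic inputs with known ground truth.

Three generators:

* uniform-composition random nucleotide sequences — the survey's null model
  (the published control is 50 sequences of 1600 nt with equal probability
  for the four nucleotides);
* secondary structures with a prescribed exterior-loop composition (u
  unpaired exterior nucleotides, h depth-0 helices), whose link count
  u + 2h - 1 is known by construction and serves as the oracle for the
  exterior-loop statistic;
* Gaussian-distributed contour-length samples for parameter-recovery tests
  of the histogram-fit machinery.

All generators take an explicit seed and are byte-reproducible for a fixed
seed (numpy PCG64).  No attempt is made to emulate realistic mRNA base
composition or codon structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "RandomSeqSpec",
    "SyntheticStructureSpec",
    "SyntheticStructure",
    "generate_random_sequences",
    "generate_structure",
    "sample_gaussian",
    "write_fasta",
    "write_fold_file",
]

_BASES = np.array(list("ACGU"))
# Watson-Crick pairs used on helix strands (no wobble)
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class RandomSeqSpec:
    """Uniform(ish)-composition random sequence batch."""

    count: int
    length: int
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DomainError(f"count must be >= 0, got {self.count}")
        if self.length < 1:
            raise DomainError(f"length must be >= 1, got {self.length}")
        if len(self.base_probs) != 4 or any(p < 0 for p in self.base_probs):
            raise DomainError(f"base_probs must be 4 non-negative values")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise DomainError(
                f"base_probs sum to {sum(self.base_probs)}, expected 1"
            )


def generate_random_sequences(spec: RandomSeqSpec) -> list[str]:
    """Generate ``spec.count`` independent sequences of ``spec.length`` nt."""
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.base_probs, dtype=float)
    probs = probs / probs.sum()
    return [
        "".join(rng.choice(_BASES, size=spec.length, p=probs))
        for _ in range(spec.count)
    ]


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Structure with a prescribed exterior-loop composition.

    ``ext_unpaired`` exterior unpaired nucleotides are scattered uniformly at
    random among the h + 1 gaps around the ``top_helices`` depth-0 helices;
    each helix is a stack of ``helix_len`` Watson-Crick pairs closed by a
    ``hairpin_len``-nt terminal loop.
    """

    ext_unpaired: int
    top_helices: int
    helix_len: int = 2
    hairpin_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ext_unpaired < 0 or self.top_helices < 0:
            raise DomainError("counts must be non-negative")
        if self.ext_unpaired + self.top_helices < 1:
            raise DomainError("need at least one exterior node (u + h >= 1)")
        if self.helix_len < 1:
            raise DomainError("helix_len must be >= 1")
        if self.hairpin_len < 3:
            raise DomainError("hairpin loops need >= 3 nt")


@dataclass(frozen=True)
class SyntheticStructure:
    sequence: str
    structure: str  # dot-bracket
    ext_unpaired: int
    top_helices: int
    link_count: int  # ground truth: u + 2h - 1


def generate_structure(spec: SyntheticStructureSpec) -> SyntheticStructure:
    """Build a structure whose exterior-loop composition is known exactly."""
    rng = np.random.default_rng(spec.seed)
    u, h = spec.ext_unpaired, spec.top_helices
    # multinomial split of u unpaired nt over the h+1 exterior gaps
    if h == 0:
        gaps = [u]
    else:
        gaps = list(rng.multinomial(u, [1.0 / (h + 1)] * (h + 1)))
    seq_parts: list[str] = []
    db_parts: list[str] = []
    for gi in range(len(gaps)):
        g = gaps[gi]
        seq_parts.append("".join(rng.choice(_BASES, size=g)))
        db_parts.append("." * g)
        if gi < h:
            strand5 = "".join(rng.choice(_BASES, size=spec.helix_len))
            loop = "".join(rng.choice(_BASES, size=spec.hairpin_len))
            strand3 = "".join(_WC[c] for c in reversed(strand5))
            seq_parts.append(strand5 + loop + strand3)
            db_parts.append(
                "(" * spec.helix_len + "." * spec.hairpin_len + ")" * spec.helix_len
            )
    return SyntheticStructure(
        sequence="".join(seq_parts),
        structure="".join(db_parts),
        ext_unpaired=u,
        top_helices=h,
        link_count=max(u + 2 * h - 1, 0),
    )


def sample_gaussian(
    n: int, center: float, width_w: float, seed: int = 0
) -> np.ndarray:
    """Draw n contour-length values: Normal(center, sigma = width_w / sqrt(2)).

    ``width_w`` follows the 1/e half-width convention used by the histogram
    fits.  Draws below zero are rejected and redrawn (contour length is
    physically non-negative); for the parameter regimes of interest the
    truncated mass is negligible.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if width_w <= 0:
        raise DomainError(f"width_w must be positive, got {width_w}")
    rng = np.random.default_rng(seed)
    sigma = width_w / np.sqrt(2.0)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(center, sigma, size=max(n - out.size, 16))
        out = np.concatenate([out, draw[draw >= 0]])
    return out[:n]


# ---------------------------------------------------------------------------
# Plain-text output
# ---------------------------------------------------------------------------

def write_fasta(sequences: Sequence[str], path: str | Path, prefix: str = "rnd") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences, start=1):
            fh.write(f">{prefix}_{i:04d}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


def write_fold_file(
    structures: Sequence[SyntheticStructure], path: str | Path, prefix: str = "syn"
) -> None:
    """Vienna-style multi-record file: >name / sequence / dot-bracket."""
    with open(path, "w") as fh:
        for i, st in enumerate(structures, start=1):
            fh.write(f">{prefix}_{i:04d}\n{st.sequence}\n{st.structure}\n")
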