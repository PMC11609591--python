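"""The core statistic: exterior-loop link count and contour length.

The exterior loop of a nested secondary structure is the backbone path that
connects the 5' and 3' termini: all nucleotides enclosed by no base pair
(nesting depth 0), plus the closing base pair of each outermost (depth-0)
helix, which shortcuts the enclosed region.  Counting the links along that
path and multiplying by the typical internucleotide distance d = 0.59 nm
gives the contour length C_L, an upper bound on the end-to-end separation of
the molecule.

Under the default convention each depth-0 helix contributes its two closing
nucleotides joined by one base-pair link, so a structure with u exterior
unpaired nucleotides and h depth-0 helices has

    L = u + 2h - 1        (u + h >= 1)

links: u + 2h path nodes, L bonds between consecutive nodes.  This is the
convention under which the minimum possible C_L — a structure whose termini
are directly base-paired (u = 0, h = 1) — is exactly one link, 0.59 nm.
Alternative conventions are selectable for comparison but do not reproduce
that minimum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import DomainError
from .folding import SecondaryStructure

#: Typical distance between consecutive nucleotides in RNA, nm per link.
DEFAULT_LINK_NM = 0.59

__all__ = [
    "DEFAULT_LINK_NM",
    "LinkConvention",
    "ExteriorLoopSummary",
    "exterior_summary",
    "contour_length",
]


class LinkConvention(str, enum.Enum):
    """How depth-0 helices contribute to the exterior-loop link count."""

    #: each depth-0 helix = two closing nucleotides + one base-pair link
    CLOSING_PAIR = "closing_pair"  # L = u + 2h - 1
    #: each depth-0 helix collapses to a single zero-width node
    HELIX_SINGLE_NODE = "helix_single_node"  # L = u + h - 1
    #: only unpaired exterior nucleotides are counted as nodes
    UNPAIRED_ONLY = "unpaired_only"  # L = max(u - 1, 0)


@dataclass(frozen=True)
class ExteriorLoopSummary:
    """Composition of the exterior loop of one structure."""

    ext_unpaired: int  # u: depth-0 unpaired nucleotides
    top_helices: int  # h: depth-0 helices
    link_count: int  # L: links along the exterior path
    contour_length: float  # C_L = L * d, nm
    convention: LinkConvention = LinkConvention.CLOSING_PAIR
    d: float = DEFAULT_LINK_NM


def _link_count(u: int, h: int, convention: LinkConvention) -> int:
    if convention is LinkConvention.CLOSING_PAIR:
        return max(u + 2 * h - 1, 0)
    if convention is LinkConvention.HELIX_SINGLE_NODE:
        return max(u + h - 1, 0)
    return max(u - 1, 0)


def exterior_summary(
    structure: SecondaryStructure,
    *,
    convention: LinkConvention = LinkConvention.CLOSING_PAIR,
    d: float = DEFAULT_LINK_NM,
) -> ExteriorLoopSummary:
    """Walk the backbone at nesting depth 0 and summarise the exterior loop.

    Every unpaired depth-0 nucleotide is an exterior node; every depth-0
    helix is entered at its outermost 5' nucleotide and left at its outermost
    3' nucleotide (one base-pair link bridging the enclosed region).
    """
    if d <= 0:
        raise DomainError(f"d must be positive, got {d}")
    pairs = structure.pairs
    n = len(pairs)
    u = 0
    h = 0
    pos = 1
    while pos <= n:
        j = pairs[pos - 1]
        if j == 0:
            u += 1
            pos += 1
        else:
            # structure validity guarantees j > pos at depth 0
            h += 1
            pos = j + 1
    L = _link_count(u, h, convention)
    return ExteriorLoopSummary(
        ext_unpaired=u,
        top_helices=h,
        link_count=L,
        contour_length=contour_length(L, d),
        convention=convention,
        d=d,
    )


def contour_length(link_count: int, d: float = DEFAULT_LINK_NM) -> float:
    """Contour length in nm for a given number of links."""
    if link_count < 0:
        raise DomainError(f"link_count must be >= 0, got {link_count}")
    if d <= 0:
        raise DomainError(f"d must be positive, got {d}")
    return link_count * d
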