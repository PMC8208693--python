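"""Degenerate-motif scanning for the bacterial poly(A) polymerase signature.

Bacterial PAP I is distinguished from its tRNA-nucleotidyltransferase
paralogues by an 11-position degenerate signature in the catalytic-domain
β-turn, written PROSITE-style:

    [LIV][LIV]G[RK][RK]Fx-[LIV]h[HQL][LIV]

Bracketed groups are residue alternatives, bare letters are literal, ``x``
matches any residue, ``h`` matches a hydrophobic residue, and hyphens are
cosmetic separators. The scanner slides the pattern over a protein and
reports every window within a mismatch tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io_formats import AA_ALPHABET, SequenceRecord

#: the conventional aliphatic + aromatic hydrophobic set
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWC")

#: the published PAP I consensus signature
PAP_CONSENSUS = "[LIV][LIV]G[RK][RK]Fx-[LIV]h[HQL][LIV]"

WILDCARD = "wildcard"
HYDROPHOBIC = "hydrophobic"


class PatternError(ValueError):
    """Raised for a malformed degenerate-pattern string."""


@dataclass(frozen=True)
class ConsensusPattern:
    """Ordered positional residue classes parsed from a degenerate motif.

    Each position is a frozenset of residues, the string ``"wildcard"`` or
    the string ``"hydrophobic"``.
    """

    positions: tuple
    source_text: str

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, residue: str, index: int,
                   hydrophobic=DEFAULT_HYDROPHOBIC) -> bool:
        cls = self.positions[index]
        if cls == WILDCARD:
            return True
        if cls == HYDROPHOBIC:
            return residue in hydrophobic
        return residue in cls


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based window start
    window: str
    mismatches: int


def parse_pattern(text: str) -> ConsensusPattern:
    """Parse a PROSITE-like degenerate pattern into positional classes.

    Raises PatternError (with the character offset) on unbalanced brackets
    or characters outside A–Z, x, h, brackets and hyphen.
    """
    positions: list = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "-":
            i += 1
        elif ch == "x":
            positions.append(WILDCARD)
            i += 1
        elif ch == "h":
            positions.append(HYDROPHOBIC)
            i += 1
        elif ch == "[":
            j = text.find("]", i)
            if j == -1:
                raise PatternError(f"unbalanced '[' at offset {i}")
            group = text[i + 1:j]
            if not group or not set(group) <= AA_ALPHABET - {"X"}:
                raise PatternError(f"invalid residue set {group!r} at offset {i}")
            positions.append(frozenset(group))
            i = j + 1
        elif ch == "]":
            raise PatternError(f"unbalanced ']' at offset {i}")
        elif ch.isupper() and ch in AA_ALPHABET - {"X"}:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise PatternError(f"unexpected character {ch!r} at offset {i}")
    if not positions:
        raise PatternError("empty pattern")
    return ConsensusPattern(positions=tuple(positions), source_text=text)


def _window_mismatches(window: str, pattern: ConsensusPattern,
                       hydrophobic) -> int:
    return sum(
        0 if pattern.matches_at(res, k, hydrophobic) else 1
        for k, res in enumerate(window)
    )


def scan(record: SequenceRecord, pattern: ConsensusPattern,
         max_mismatches: int = 0,
         hydrophobic=DEFAULT_HYDROPHOBIC) -> list[MotifHit]:
    """Return every window whose class-violation count is within tolerance.

    Hits are reported at every overlapping offset, in ascending start order.
    A sequence shorter than the pattern yields no hits.
    """
    if record.alphabet != "aa":
        raise ValueError("motif scanning requires a protein (aa) record")
    seq = record.residues
    plen = len(pattern)
    hits = []
    for off in range(len(seq) - plen + 1):
        window = seq[off:off + plen]
        mm = _window_mismatches(window, pattern, hydrophobic)
        if mm <= max_mismatches:
            hits.append(MotifHit(record.id, off + 1, window, mm))
    return hits


def best_window(record: SequenceRecord, pattern: ConsensusPattern,
                hydrophobic=DEFAULT_HYDROPHOBIC) -> MotifHit:
    """The window with the fewest violations (ties: smallest start).

    Always returns a hit, whatever its mismatch count — useful for reporting
    near-matches that fail the strict consensus.
    """
    if record.alphabet != "aa":
        raise ValueError("motif scanning requires a protein (aa) record")
    seq = record.residues
    plen = len(pattern)
    if len(seq) < plen:
        raise ValueError(
            f"sequence {record.id!r} (length {len(seq)}) shorter than "
            f"pattern (length {plen})"
        )
    best: Optional[MotifHit] = None
    for off in range(len(seq) - plen + 1):
        window = seq[off:off + plen]
        mm = _window_mismatches(window, pattern, hydrophobic)
        if best is None or mm < best.mismatches:
            best = MotifHit(record.id, off + 1, window, mm)
            if mm == 0:
                break
    return best
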