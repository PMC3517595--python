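"""Consensus motif patterns, lexical sets, and sequence scanning.

A short linear motif (minimotif) is conventionally written as a degenerate
consensus string: literal residues, ``x`` for "any of the 20 amino acids",
bracketed residue classes such as ``[ST]``, and a trailing ``>`` marking a
motif that must sit on the C-terminus.  A consensus such as ``[ST]xx[DE]``
is ambiguous — it asserts nothing about which of the 4 x 400 concrete
sequences are functional.  The *lexical set* (lexicon) makes the definition
explicit: the set of all concrete sequences matching the consensus, whose
size is the product of the per-position class sizes.

This module parses consensus strings, computes and enumerates lexical sets,
and scans protein sequences for motif matches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import LexiconSizeError, MotifParseError

#: The 20 canonical amino acids, one-letter IUPAC codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_FULL_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class MotifPattern:
    """A parsed consensus: one residue set per position plus an anchor flag.

    Attributes
    ----------
    raw_text : str
        The consensus string as given; re-parsing it yields an identical
        pattern.
    positions : tuple of frozenset of str
        One nonempty subset of the 20 canonical amino acids per motif
        position, in sequence order.
    c_terminal_anchor : bool
        True when the motif must end exactly at the C-terminus (the
        trailing ``>`` of the consensus syntax).
    """

    raw_text: str
    positions: tuple[frozenset, ...]
    c_terminal_anchor: bool = False

    def __post_init__(self):
        if len(self.positions) < 1:
            raise MotifParseError("pattern must have at least one position")
        for i, pos in enumerate(self.positions):
            if not pos:
                raise MotifParseError(f"position {i} has an empty residue set")
            bad = set(pos) - _AA_SET
            if bad:
                raise MotifParseError(
                    f"position {i} contains non-amino-acid letters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def matches_window(self, window: str) -> bool:
        """True if *window* (same length as the pattern) satisfies every
        per-position residue set."""
        if len(window) != len(self.positions):
            return False
        return all(res in pos for res, pos in zip(window, self.positions))


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif in a sequence.

    Offsets are 0-based half-open internally; :attr:`start_1based` gives the
    1-based position used in user-facing reports (PDB convention).
    """

    sequence_id: str
    start: int
    matched_text: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_text)

    @property
    def start_1based(self) -> int:
        return self.start + 1


def parse_consensus(pattern_text: str) -> MotifPattern:
    """Parse a consensus string into a :class:`MotifPattern`.

    Grammar: ``x`` or ``X`` expands to the full 20-residue set; ``[...]`` to
    the listed set; a bare upper-case letter to a singleton; a trailing
    ``>`` sets the C-terminal anchor.  Phosphorylation and other
    modification marks are not part of the grammar — matching is by residue
    identity only.

    Raises
    ------
    MotifParseError
        On unbalanced or empty brackets, non-amino-acid letters, or a ``>``
        anywhere but the final position.
    """
    if not pattern_text:
        raise MotifParseError("empty pattern")
    text = pattern_text
    anchor = False
    if ">" in text:
        if text.index(">") != len(text) - 1:
            raise MotifParseError(
                "'>' is only valid in the final position", text.index(">")
            )
        anchor = True
        text = text[:-1]
        if not text:
            raise MotifParseError("pattern has no positions before '>'")

    positions: list[frozenset] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            close = text.find("]", i + 1)
            if close == -1:
                raise MotifParseError("unbalanced '['", i)
            members = text[i + 1 : close]
            if not members:
                raise MotifParseError("empty bracket class", i)
            bad = [c for c in members if c not in _AA_SET]
            if bad:
                raise MotifParseError(
                    f"non-amino-acid letter {bad[0]!r} in bracket class",
                    i + 1 + members.index(bad[0]),
                )
            positions.append(frozenset(members))
            i = close + 1
        elif ch == "]":
            raise MotifParseError("unbalanced ']'", i)
        elif ch in ("x", "X"):
            positions.append(_FULL_SET)
            i += 1
        elif ch in _AA_SET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise MotifParseError(f"unexpected character {ch!r}", i)

    return MotifPattern(raw_text=pattern_text, positions=tuple(positions),
                        c_terminal_anchor=anchor)


def lexicon_size(pattern: MotifPattern) -> int:
    """Size of the lexical set: the product of per-position set sizes.

    Exact integer arithmetic; patterns with sizes well beyond 10^9 are fine.
    """
    size = 1
    for pos in pattern.positions:
        size *= len(pos)
    return size


def enumerate_lexicon(pattern: MotifPattern, cap: int = 1_000_000) -> list[str]:
    """All distinct sequences matching *pattern*, lexicographically ordered.

    Refuses (raising :class:`LexiconSizeError` carrying the computed size)
    when the lexical set exceeds *cap*, so an accidental ``x``-heavy pattern
    cannot exhaust memory.
    """
    size = lexicon_size(pattern)
    if size > cap:
        raise LexiconSizeError(size, cap)
    choices = [sorted(pos) for pos in pattern.positions]
    return ["".join(t) for t in itertools.product(*choices)]


def scan_sequence(seq: str, pattern: MotifPattern,
                  sequence_id: str = "") -> list[MotifMatch]:
    """Find every motif occurrence in *seq*.

    Overlapping matches are all reported.  Unknown residues (``X`` or any
    non-canonical letter) match nothing.  For a C-terminally anchored
    pattern only the final window is eligible.
    """
    n, m = len(seq), len(pattern)
    if n < m:
        return []
    if pattern.c_terminal_anchor:
        starts: range | list = [n - m]
    else:
        starts = range(n - m + 1)
    out = []
    for s in starts:
        window = seq[s : s + m]
        if pattern.matches_window(window):
            out.append(MotifMatch(sequence_id=sequence_id, start=s,
                                  matched_text=window))
    return out
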