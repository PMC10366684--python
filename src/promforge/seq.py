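"""Low-level nucleotide string helpers shared across modules.

All sequence operations in this package are case-insensitive for matching and
case-preserving for output. Only the unambiguous DNA alphabet {A,C,G,T} is
accepted; anything else raises :class:`AlphabetError` at the boundary rather
than propagating silently.
"""

from __future__ import annotations

import re

_VALID = re.compile(r"[ACGTacgt]*\Z")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: deterministic substitution preference per reference base: the transition
#: partner first (purine<->purine, pyrimidine<->pyrimidine), then transversions.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
SUBSTITUTION_ORDER = {
    "A": ("G", "C", "T"),
    "G": ("A", "C", "T"),
    "C": ("T", "A", "G"),
    "T": ("C", "A", "G"),
}


class AlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T} (either case)."""


def check_alphabet(seq: str) -> str:
    """Validate *seq* against the strict DNA alphabet and return it unchanged."""
    if not _VALID.match(seq):
        bad = sorted({c for c in seq if c not in "ACGTacgt"})
        raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case."""
    return seq.translate(_COMPLEMENT)[::-1]


def match_case(base: str, template: str) -> str:
    """Return *base* in the same case as *template* (a single character)."""
    return base.lower() if template.islower() else base.upper()


def substitute(seq: str, position: int, base: str) -> str:
    """Return *seq* with a single-base substitution, preserving local case."""
    return seq[:position] + match_case(base, seq[position]) + seq[position + 1 :]


def longest_common_suffix(seqs: list[str]) -> str:
    """Longest exact common suffix of all strings (case-sensitive)."""
    if not seqs:
        return ""
    out = []
    for chars in zip(*(s[::-1] for s in seqs)):
        if len(set(chars)) != 1:
            break
        out.append(chars[0])
    return "".join(out)[::-1]
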