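"""Make promoter parts synthesis- and Golden-Gate-ready.

Two sequence classes of violations are scrubbed with single-base
substitutions: homopolymer runs at or above a length threshold (default
10 bp), and type-IIS recognition sites (default BsaI, ``GGTCTC``) on either
strand. Scrubbed parts are then extended with the fixed 15 bp cloning linker
(a partial attB1 site plus the ``aaaa`` consensus start pad) and flanked with
outward-reading donor sites so that digestion releases the part with
designed 4-nt overhangs.

Substitution policy (deterministic, no randomness involved):

* a run of length ``L`` receives ``floor(L / threshold)`` substitutions at
  1-based offsets ``threshold, 2*threshold, ...`` within the run, splitting
  it into sub-runs of at most ``threshold - 1``;
* a recognition site receives one substitution, preferring the third base of
  the hexamer (read on the strand carrying the site);
* the replacement base is the transition partner of the reference base when
  possible, falling back to transversions; any placement or base that would
  create a fresh violation is skipped in favour of the next candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seq import (
    SUBSTITUTION_ORDER,
    check_alphabet,
    revcomp,
    substitute,
)

BSAI_RECOGNITION = "GGTCTC"
PARTIAL_ATTB1 = "aaaagcaggct"
START_PAD = "aaaa"
CLONING_LINKER = PARTIAL_ATTB1 + START_PAD  # 15 bp, always appended lowercase

EDIT_REASONS = ("homopolymer", "type_iis")


class DomesticationError(RuntimeError):
    """Raised when a sequence cannot be scrubbed under the given config."""


class PartValidationError(ValueError):
    """Raised when a part offered for flanking fails the cleanliness checks."""


@dataclass(frozen=True)
class SequenceEdit:
    """A single-base substitution with its motivation."""

    position: int  # 0-based in the part
    ref_base: str
    alt_base: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EDIT_REASONS:
            raise ValueError(f"unknown edit reason {self.reason!r}")
        if self.ref_base.upper() == self.alt_base.upper():
            raise ValueError("edit must change the base")


@dataclass(frozen=True)
class DomesticatedPromoter:
    original: str
    edited: str
    edits: tuple[SequenceEdit, ...]

    def __post_init__(self) -> None:
        if len(self.original) != len(self.edited):
            raise ValueError("domestication must preserve length")
        replayed = self.original
        for e in self.edits:
            replayed = substitute(replayed, e.position, e.alt_base)
        if replayed.upper() != self.edited.upper():
            raise ValueError("edit list does not reproduce the edited sequence")


@dataclass(frozen=True)
class DomesticationConfig:
    run_threshold: int = 10
    enzymes: tuple[str, ...] = (BSAI_RECOGNITION,)
    linker: str = CLONING_LINKER
    overhang_len: int = 4

    def __post_init__(self) -> None:
        if self.run_threshold < 2:
            raise ValueError("run_threshold must be >= 2")
        for enz in self.enzymes:
            if len(enz) < 4:
                raise ValueError("recognition sequences must be >= 4 nt")
            check_alphabet(enz)


DEFAULT_CONFIG = DomesticationConfig()


def find_homopolymers(
    seq: str, min_len: int
) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= *min_len*, as (start, length, base).

    Runs are reported in upper case and sorted by start; a shorter run inside
    a longer one is never reported (maximality).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    check_alphabet(seq)
    out = []
    for m in re.finditer(r"(.)\1*", seq.upper()):
        if m.end() - m.start() >= min_len:
            out.append((m.start(), m.end() - m.start(), m.group(1)))
    return out


def find_type_iis_sites(
    seq: str, recognition: str = BSAI_RECOGNITION
) -> list[tuple[int, str]]:
    """All matches of *recognition* on either strand, in plus-strand coordinates.

    Minus-strand hits are matches of the reverse complement; for palindromic
    recognition sequences each position is reported once, on the plus strand.
    Overlapping matches are all reported.
    """
    if len(recognition) < 4:
        raise ValueError("recognition sequence must be >= 4 nt")
    check_alphabet(seq)
    check_alphabet(recognition)
    upper = seq.upper()
    fwd = recognition.upper()
    rev = revcomp(fwd)
    hits = [(m.start(), "+") for m in re.finditer(f"(?={fwd})", upper)]
    if rev != fwd:
        hits += [(m.start(), "-") for m in re.finditer(f"(?={rev})", upper)]
    return sorted(hits)


def scan_violations(
    seq: str, config: DomesticationConfig = DEFAULT_CONFIG
) -> tuple[list[tuple[int, int, str]], list[tuple[int, str, str]]]:
    """Return (homopolymer runs, enzyme sites) present in *seq*.

    Sites are (position, strand, recognition) tuples.
    """
    runs = find_homopolymers(seq, config.run_threshold)
    sites = [
        (pos, strand, enz)
        for enz in config.enzymes
        for pos, strand in find_type_iis_sites(seq, enz)
    ]
    return runs, sorted(sites)


def is_clean(seq: str, config: DomesticationConfig = DEFAULT_CONFIG) -> bool:
    runs, sites = scan_violations(seq, config)
    return not runs and not sites


def _window_sites(
    seq: str, lo: int, hi: int, config: DomesticationConfig
) -> set[tuple[int, str, str]]:
    """Enzyme sites whose recognition span intersects [lo, hi)."""
    out = set()
    for enz in config.enzymes:
        span = len(enz)
        a = max(0, lo - span + 1)
        sub = seq[a : hi + span - 1]
        for pos, strand in find_type_iis_sites(sub, enz):
            out.add((pos + a, strand, enz))
    return out


def _run_through(seq: str, pos: int) -> int:
    """Length of the maximal homopolymer run containing position *pos*."""
    base = seq[pos].upper()
    upper = seq.upper()
    i = pos
    while i > 0 and upper[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(upper) and upper[j + 1] == base:
        j += 1
    return j - i + 1


def _edit_is_safe(
    before: str, after: str, pos: int, config: DomesticationConfig
) -> bool:
    """A candidate substitution must not create a run or a site that was not
    already present around the edited position."""
    if _run_through(after, pos) >= config.run_threshold:
        return False
    margin = max(len(e) for e in config.enzymes)
    new = _window_sites(after, pos - margin, pos + margin + 1, config)
    old = _window_sites(before, pos - margin, pos + margin + 1, config)
    return new <= old


def _fix_run(
    seq: str, start: int, length: int, config: DomesticationConfig
) -> tuple[str, list[SequenceEdit]]:
    base = seq[start].upper()
    edits: list[SequenceEdit] = []
    anchor = start
    end = start + length
    thr = config.run_threshold
    while end - anchor >= thr:
        placed = False
        for pos in range(anchor + thr - 1, anchor - 1, -1):
            for alt in SUBSTITUTION_ORDER[base]:
                cand = substitute(seq, pos, alt)
                if _edit_is_safe(seq, cand, pos, config):
                    edits.append(SequenceEdit(pos, seq[pos], alt, "homopolymer"))
                    seq = cand
                    anchor = pos + 1
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise DomesticationError(
                f"cannot break {base}-run at {start} (length {length}) "
                f"without creating a new violation"
            )
    return seq, edits


def _fix_site(
    seq: str, pos: int, strand: str, recognition: str, config: DomesticationConfig
) -> tuple[str, SequenceEdit]:
    span = len(recognition)
    # third base of the recognition sequence first, read on the carrying strand
    offset_order = [k for k in (2, 3, 1, 4, 0, 5) if k < span]
    offset_order += [k for k in range(6, span)]
    if strand == "+":
        positions = [pos + k for k in offset_order]
    else:
        positions = [pos + span - 1 - k for k in offset_order]
    for p in positions:
        ref = seq[p]
        for alt in SUBSTITUTION_ORDER[ref.upper()]:
            cand = substitute(seq, p, alt)
            still_there = (pos, strand) in find_type_iis_sites(cand, recognition)
            if not still_there and _edit_is_safe(seq, cand, p, config):
                return cand, SequenceEdit(p, ref, alt, "type_iis")
    raise DomesticationError(
        f"cannot remove {recognition} site at {pos}{strand} without creating "
        f"a new violation"
    )


def domesticate(
    seq: str,
    config: DomesticationConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> DomesticatedPromoter:
    """Scrub *seq* of homopolymer runs and enzyme sites with minimal edits.

    The policy is fully deterministic; *seed* is accepted for interface
    stability with pluggable randomized policies and is unused by the default
    one. Raises :class:`DomesticationError` when no safe substitution exists
    (pathological configurations such as very low run thresholds on highly
    repetitive input).
    """
    check_alphabet(seq)
    if not seq:
        raise ValueError("cannot domesticate an empty sequence")
    original = seq
    edits: list[SequenceEdit] = []
    for _ in range(len(seq) + 10):  # each pass strictly reduces violations
        runs, sites = scan_violations(seq, config)
        if not runs and not sites:
            break
        for start, length, _base in runs:
            seq, run_edits = _fix_run(seq, start, length, config)
            edits.extend(run_edits)
        _, sites = scan_violations(seq, config)
        for pos, strand, enz in sites:
            if (pos, strand) not in find_type_iis_sites(seq, enz):
                continue  # removed as a side effect of an earlier fix
            seq, edit = _fix_site(seq, pos, strand, enz, config)
            edits.append(edit)
    else:
        raise DomesticationError("domestication did not converge")

    # collapse to one edit per position, referenced against the original
    final: dict[int, SequenceEdit] = {}
    for e in edits:
        final[e.position] = SequenceEdit(
            e.position, original[e.position], seq[e.position], e.reason
        )
    kept = tuple(
        sorted(
            (e for e in final.values() if e.ref_base.upper() != e.alt_base.upper()),
            key=lambda e: e.position,
        )
    )
    return DomesticatedPromoter(original=original, edited=seq, edits=kept)


def append_cloning_linker(
    seq: str, config: DomesticationConfig = DEFAULT_CONFIG
) -> str:
    """Append the fixed 15 bp linker (partial attB1 + ``aaaa`` start pad)."""
    check_alphabet(seq)
    return seq + config.linker


@dataclass(frozen=True)
class PartValidation:
    internal_runs: int
    internal_sites: int
    flank_sites: int
    orientation_ok: bool

    @property
    def ok(self) -> bool:
        return self.internal_runs == 0 and self.internal_sites == 0


def validate_part(
    fragment: str, config: DomesticationConfig = DEFAULT_CONFIG
) -> PartValidation:
    """Report cleanliness of a fragment: internal runs/sites and flank geometry.

    Flank sites are the two expected donor sites of :func:`add_flanks`: a
    plus-strand recognition at position 0 and a minus-strand recognition at
    the very end, both cutting inward. Everything else counts as internal.
    """
    runs, sites = scan_violations(fragment, config)
    flank = 0
    left = right = False
    for pos, strand, enz in sites:
        if strand == "+" and pos == 0:
            flank += 1
            left = True
        elif strand == "-" and pos == len(fragment) - len(enz):
            flank += 1
            right = True
        # sites anywhere else are internal
    return PartValidation(
        internal_runs=len(runs),
        internal_sites=len(sites) - flank,
        flank_sites=flank,
        orientation_ok=left and right,
    )


def add_flanks(
    part: str,
    overhang5: str,
    overhang3: str,
    config: DomesticationConfig = DEFAULT_CONFIG,
) -> str:
    """Flank a clean part with outward donor sites and designed 4-nt overhangs.

    Layout: ``recognition + N + overhang5 + part + overhang3 + N + rc(recognition)``
    with a 1-nt spacer on each side (standard BsaI N1/N5 cut geometry), so that
    digestion releases ``overhang5 + part + overhang3`` with the stated sticky
    ends. The spacer bases are chosen deterministically so the junctions do not
    themselves create new sites or runs.
    """
    check_alphabet(part)
    for oh in (overhang5, overhang3):
        check_alphabet(oh)
        if len(oh) != config.overhang_len:
            raise ValueError(f"overhangs must be {config.overhang_len} nt, got {oh!r}")
    if overhang5.upper() == overhang3.upper():
        raise ValueError("identical 5' and 3' overhangs make ligation ambiguous")
    runs, sites = scan_violations(part, config)
    if runs or sites:
        raise PartValidationError(
            f"part is not clean: {len(runs)} runs, {len(sites)} enzyme sites"
        )
    recog = config.enzymes[0]
    for s5 in "acgt":
        for s3 in "acgt":
            frag = recog + s5 + overhang5 + part + overhang3 + s3 + revcomp(recog)
            rep = validate_part(frag, config)
            if (
                rep.flank_sites == 2
                and rep.internal_sites == 0
                and rep.internal_runs == 0
                and rep.orientation_ok
            ):
                return frag
    raise PartValidationError(
        "no spacer choice yields a clean flanked fragment; check the part "
        "boundaries and overhangs"
    )


def edit_table(
    parts: Iterable[tuple[str, DomesticatedPromoter]]
) -> list[dict]:
    """Rows for the TSV edit report (1-based positions)."""
    rows = []
    for name, dom in parts:
        for e in dom.edits:
            rows.append(
                {
                    "seq_id": name,
                    "position": e.position + 1,
                    "ref": e.ref_base,
                    "alt": e.alt_base,
                    "reason": e.reason,
                }
            )
    return rows
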