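"""In silico Golden Gate: type-IIS digestion, overhang ligation, verification.

The enzyme model is the standard type-IIS geometry: the recognition sequence
is followed by a spacer, the top strand is cut after the spacer and the
bottom strand ``overhang_len`` further along, leaving 4-nt 5' extensions
(BsaI: GGTCTC(N1), 4-nt overhangs). Sticky ends are represented throughout
by the top-strand sequence of the overhang region; two ends ligate when
those 4-mers are identical (case-insensitive).

Fragment bookkeeping convention: a fragment's ``sequence`` is the top strand
from its 5' top-strand cut to its 3' bottom-strand cut, i.e. it *includes*
both overhang regions. Consequently the total length of a digest equals the
input length plus ``overhang_len`` per cut (each overhang appears in two
fragments), which :func:`digest` asserts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seq import check_alphabet, revcomp

__all__ = [
    "Enzyme",
    "BSAI",
    "DigestFragment",
    "Feature",
    "Construct",
    "AssemblyError",
    "AmbiguousAssemblyError",
    "digest",
    "assemble",
    "verify_construct",
    "injection_mix",
    "canonical_rotation",
]


class AssemblyError(RuntimeError):
    """No valid circular product could be formed."""


class AmbiguousAssemblyError(AssemblyError):
    """More than one distinct circular product is possible."""

    def __init__(self, products: list[str]):
        self.products = products
        super().__init__(
            f"{len(products)} distinct circular products possible; "
            "refusing to pick one arbitrarily"
        )


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    spacer_len: int = 1
    overhang_len: int = 4

    def __post_init__(self) -> None:
        check_alphabet(self.recognition)


BSAI = Enzyme(name="BsaI", recognition="GGTCTC", spacer_len=1, overhang_len=4)


@dataclass(frozen=True)
class DigestFragment:
    """A double-stranded fragment with 5' extensions at zero, one or two ends.

    ``sequence`` spans both overhang regions (see module docstring); ``core``
    is the fully double-stranded interior.
    """

    sequence: str
    five_prime_overhang: str | None
    three_prime_overhang: str | None
    source: tuple[int, int] | None = None

    @property
    def core(self) -> str:
        lo = len(self.five_prime_overhang) if self.five_prime_overhang else 0
        hi = len(self.three_prime_overhang) if self.three_prime_overhang else 0
        return self.sequence[lo : len(self.sequence) - hi]


@dataclass(frozen=True)
class Feature:
    name: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class Construct:
    sequence: str
    topology: str = "circular"  # or "linear"
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        check_alphabet(self.sequence)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        for f in self.features:
            if not (0 <= f.start < f.end <= len(self.sequence)):
                raise ValueError(f"feature {f.name} outside sequence")

    def equivalent(self, other: "Construct") -> bool:
        """Topology-aware equality: circular molecules compare under rotation
        and strand flip; linear ones under strand flip only."""
        if self.topology != other.topology:
            return False
        if self.topology == "circular":
            return canonical_rotation(self.sequence) == canonical_rotation(
                other.sequence
            )
        a, b = self.sequence.lower(), other.sequence.lower()
        return a == b or a == revcomp(b)


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation of the lowercase sequence or of its
    reverse complement — a rotation- and strand-invariant key for circles."""
    best = None
    for s in (seq.lower(), revcomp(seq.lower())):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i : i + len(s)]
            if best is None or rot < best:
                best = rot
    return best or ""


def _site_positions(seq: str, enzyme: Enzyme, circular: bool) -> list[tuple[int, str]]:
    fwd = enzyme.recognition.upper()
    rev = revcomp(fwd)
    search = seq.upper()
    if circular:
        # sites may straddle the origin; extend by one recognition span
        search = search + search[: len(fwd) - 1]
    hits = [(m.start(), "+") for m in re.finditer(f"(?={fwd})", search)]
    if rev != fwd:
        hits += [(m.start(), "-") for m in re.finditer(f"(?={rev})", search)]
    return sorted((p % len(seq), s) for p, s in hits)


def _cut_events(seq: str, enzyme: Enzyme, circular: bool) -> list[int]:
    """Top-strand cut coordinates (0-based, left edge of the overhang region)."""
    n = len(seq)
    cuts = []
    for pos, strand in _site_positions(seq, enzyme, circular):
        if strand == "+":
            c_top = pos + len(enzyme.recognition) + enzyme.spacer_len
        else:
            c_top = pos - enzyme.spacer_len - enzyme.overhang_len
        if circular:
            c_top %= n
        cuts.append(c_top)
    return sorted(set(cuts))


def digest(
    seq: str, enzyme: Enzyme = BSAI, topology: str = "linear"
) -> list[DigestFragment]:
    """Cut *seq* with a type-IIS enzyme; n sites yield n+1 fragments when
    linear and n fragments when circular.

    Raises ``ValueError`` on a linear molecule whose cut would run off an end
    (no room for the full overhang).
    """
    check_alphabet(seq)
    if topology not in ("linear", "circular"):
        raise ValueError(f"bad topology {topology!r}")
    circular = topology == "circular"
    n = len(seq)
    oh = enzyme.overhang_len
    cuts = _cut_events(seq, enzyme, circular)
    if not cuts:
        if circular:
            return [DigestFragment(seq, None, None, source=(0, n))]
        return [DigestFragment(seq, None, None, source=(0, n))]
    if circular:
        frags = []
        ext = seq + seq
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            end = nxt if nxt > c else nxt + n
            sub = ext[c : end + oh]
            frags.append(
                DigestFragment(
                    sequence=sub,
                    five_prime_overhang=sub[:oh],
                    three_prime_overhang=sub[-oh:],
                    source=(c, end % n),
                )
            )
        total = sum(len(f.sequence) for f in frags)
        assert total == n + oh * len(cuts)
        return frags
    for c in cuts:
        if c < 0 or c + oh > n:
            raise ValueError(
                f"cut at {c} truncated by the end of a linear molecule; "
                "no room for a full overhang"
            )
    frags = []
    bounds = [0] + cuts + [n]
    for i in range(len(bounds) - 1):
        start = bounds[i]
        end = bounds[i + 1] + oh if bounds[i + 1] != n else n
        sub = seq[start:end]
        frags.append(
            DigestFragment(
                sequence=sub,
                five_prime_overhang=sub[:oh] if start != 0 else None,
                three_prime_overhang=sub[-oh:] if bounds[i + 1] != n else None,
                source=(start, end),
            )
        )
    total = sum(len(f.sequence) for f in frags)
    assert total == n + oh * len(cuts)
    return frags


def _has_site(seq: str, enzyme: Enzyme, circular: bool = False) -> bool:
    return bool(_site_positions(seq, enzyme, circular))


def _join_cycle(cycle: list[DigestFragment], oh: int) -> str:
    # consecutive fragments share the 4-nt overhang; drop it once per junction
    return "".join(f.sequence[:-oh] for f in cycle)


def assemble(
    parts: list,
    destination: "Construct | str",
    enzyme: Enzyme = BSAI,
) -> Construct:
    """One-pot digestion/ligation returning the unique circular product that
    carries no residual recognition site.

    *parts* may be flanked linear sequences (strings), :class:`Construct`
    objects, or pre-digested :class:`DigestFragment` lists. Ambiguity (more
    than one distinct circular product) and failure (none) both raise.
    """
    pool: list[DigestFragment] = []
    inputs: list[tuple[str, str]] = []  # (sequence, topology) for feature mapping
    if isinstance(destination, str):
        destination = Construct(sequence=destination, topology="circular")
    everything = list(parts) + [destination]
    for item in everything:
        if isinstance(item, DigestFragment):
            pool.append(item)
            continue
        if isinstance(item, Construct):
            seq, topo = item.sequence, item.topology
        else:
            seq, topo = item, "linear"
        inputs.append((seq, topo))
        pool.extend(digest(seq, enzyme, topology=topo))

    oh = enzyme.overhang_len
    usable = [
        f
        for f in pool
        if f.five_prime_overhang
        and f.three_prime_overhang
        and not _has_site(f.sequence, enzyme)
    ]

    # enumerate simple cycles in the overhang-complementarity graph
    products: dict[str, str] = {}  # canonical -> representative sequence

    def extend(path: list[DigestFragment], used: set[int]) -> None:
        last = path[-1]
        for i, f in enumerate(usable):
            if i in used:
                continue
            if last.three_prime_overhang.upper() != f.five_prime_overhang.upper():
                continue
            if (
                f.three_prime_overhang.upper()
                == path[0].five_prime_overhang.upper()
            ):
                seq = _join_cycle(path + [f], oh)
                if not _has_site(seq, enzyme, circular=True):
                    products.setdefault(canonical_rotation(seq), seq)
            extend(path + [f], used | {i})

    for i, f in enumerate(usable):
        extend([f], {i})

    if not products:
        raise AssemblyError(
            "no circular product without residual recognition sites could be "
            "assembled from the given parts"
        )
    if len(products) > 1:
        raise AmbiguousAssemblyError(sorted(products.values()))
    (product_seq,) = products.values()

    # rotate the circle so the destination's first feature sits at the origin,
    # keeping downstream features from wrapping
    if destination.features:
        first = destination.features[0]
        sub = destination.sequence[first.start : first.end].upper()
        idx = (product_seq + product_seq).upper().find(sub)
        if 0 <= idx < len(product_seq):
            product_seq = product_seq[idx:] + product_seq[:idx]

    features = _map_features(product_seq, destination)
    return Construct(sequence=product_seq, topology="circular", features=features)


def _map_features(product: str, destination: Construct) -> tuple[Feature, ...]:
    """Carry destination features (and part bodies) onto the product by exact
    subsequence search on the rotated product; features lost to the dropout
    simply do not map."""
    doubled = (product + product).upper()
    feats = []
    for f in destination.features:
        sub = destination.sequence[f.start : f.end].upper()
        idx = doubled.find(sub)
        strand = f.strand
        if idx < 0:
            idx = doubled.find(revcomp(sub))
            strand = "-"
        if idx < 0 or idx >= len(product) or idx + len(sub) > len(product):
            continue  # lost to the dropout, or wraps the origin
        feats.append(Feature(f.name, idx, idx + len(sub), strand))
    return tuple(sorted(feats, key=lambda f: f.start))


@dataclass(frozen=True)
class VerificationReport:
    features_present: dict
    order_ok: bool
    orientation_ok: bool
    no_enzyme_sites: bool
    restriction_fragments: tuple[int, ...]

    @property
    def ok(self) -> bool:
        return (
            all(self.features_present.values())
            and self.order_ok
            and self.orientation_ok
            and self.no_enzyme_sites
        )


def verify_construct(
    construct: Construct,
    expected_order: list[str],
    enzyme: Enzyme = BSAI,
    summary_enzyme: Enzyme | None = None,
) -> VerificationReport:
    """Check feature presence/order/orientation, residual-site absence, and an
    in silico restriction pattern for a chosen summary enzyme."""
    names = [f.name for f in construct.features]
    present = {n: n in names for n in expected_order}
    found = [n for n in names if n in expected_order]
    # on a circle, order is defined up to rotation
    order_ok = False
    if all(present.values()):
        want = [n for n in expected_order]
        if construct.topology == "circular":
            for shift in range(len(found)):
                if found[shift:] + found[:shift] == want:
                    order_ok = True
                    break
        else:
            order_ok = found == want
    orientation_ok = all(
        f.strand == "+" for f in construct.features if f.name in expected_order
    )
    circular = construct.topology == "circular"
    no_sites = not _has_site(construct.sequence, enzyme, circular=circular)
    summary = summary_enzyme or enzyme
    frags = digest(construct.sequence, summary, topology=construct.topology)
    return VerificationReport(
        features_present=present,
        order_ok=order_ok,
        orientation_ok=orientation_ok,
        no_enzyme_sites=no_sites,
        restriction_fragments=tuple(sorted(len(f.core) if (f.five_prime_overhang or f.three_prime_overhang) else len(f.sequence) for f in frags)),
    )


@dataclass(frozen=True)
class InjectionMixComponent:
    name: str
    concentration: float  # ng/ul

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError(
                f"component {self.name!r} has non-positive concentration"
            )


def injection_mix(
    components: list[InjectionMixComponent],
) -> tuple[float, list[dict]]:
    """Total DNA concentration (ng/ul) and a recipe table echoing the inputs."""
    if not components:
        raise ValueError("injection mix needs at least one component")
    total = float(sum(c.concentration for c in components))
    recipe = [
        {"component": c.name, "concentration_ng_per_ul": c.concentration}
        for c in components
    ]
    return total, recipe
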