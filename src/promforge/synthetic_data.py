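"""Generators for every input the pipeline consumes, with known ground truth.

Each generator is a pure function of (parameters, seed): rerunning with the
same arguments reproduces the output byte for byte. The accompanying
:class:`SyntheticTruth` records exactly what was planted so recovery tests
never have to re-derive it from the generated files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import Construct, Feature
from .domestication import DEFAULT_CONFIG, DomesticationConfig, is_clean
from .selection import TISSUES, AnnotationSet, GeneAnnotation, TissueExpressionTable
from .seq import revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted parameters serialized alongside every generated dataset."""

    rng_seed: int
    params: dict = field(default_factory=dict)
    enriched_gene_ids: list[str] = field(default_factory=list)
    short_gap_genes: list[str] = field(default_factory=list)
    planted_violations: list[dict] = field(default_factory=list)
    planted_relative_levels: dict[str, float] = field(default_factory=dict)
    adult_fraction: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _clean_dna(
    rng: np.random.Generator,
    length: int,
    config: DomesticationConfig = DEFAULT_CONFIG,
    max_tries: int = 200,
) -> str:
    """Random sequence free of homopolymer runs and enzyme sites."""
    for _ in range(max_tries):
        seq = _random_dna(rng, length)
        if is_clean(seq, config):
            return seq
    raise RuntimeError(f"could not sample a clean sequence of length {length}")


# ---------------------------------------------------------------------------
# genome + annotation


def synth_genome_annotation(
    n_genes: int = 50,
    n_short_gaps: int = 10,
    short_gap_range: tuple[int, int] = (150, 1000),
    long_gap_range: tuple[int, int] = (1100, 3000),
    gene_length_range: tuple[int, int] = (300, 900),
    strand_flip_prob: float = 0.0,
    noncoding_prob: float = 0.0,
    chrom: str = "chrI",
    seed: int = 0,
) -> tuple[dict[str, str], AnnotationSet, SyntheticTruth]:
    """Lay out *n_genes* along one chromosome with controllable intergenic gaps.

    ``n_short_gaps`` of the inter-gene gaps are drawn from ``short_gap_range``
    (promoter-sized) and the rest from ``long_gap_range``. Gene strands flip
    with ``strand_flip_prob``, producing both tandem and head-to-head neighbour
    configurations; ``noncoding_prob`` converts genes to non-coding ones that
    neighbour searches must skip. The truth lists every protein-coding gene
    whose upstream intergenic interval (computed on the generated layout) is
    at most ``short_gap_range[1]`` bp.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if short_gap_range[0] < 0 or long_gap_range[0] < 0:
        raise ValueError("gaps must be non-negative")
    if n_short_gaps > n_genes - 1:
        raise ValueError("more short gaps than gaps")
    rng = np.random.default_rng(seed)

    n_gaps = n_genes - 1
    short_idx = set(rng.choice(n_gaps, size=n_short_gaps, replace=False).tolist())
    gaps = [
        int(rng.integers(*short_gap_range, endpoint=True))
        if i in short_idx
        else int(rng.integers(*long_gap_range, endpoint=True))
        for i in range(n_gaps)
    ]
    lengths = [
        3 * int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3))
        for _ in range(n_genes)
    ]
    strands = [
        "-" if rng.random() < strand_flip_prob else "+" for _ in range(n_genes)
    ]
    coding = [rng.random() >= noncoding_prob for _ in range(n_genes)]

    genes = []
    pos = int(rng.integers(long_gap_range[0], long_gap_range[1]))  # leading margin
    for i in range(n_genes):
        start = pos
        end = start + lengths[i]
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strands[i],
                is_protein_coding=bool(coding[i]),
                trans_spliced=bool(rng.random() < 0.5),
            )
        )
        if i < n_gaps:
            pos = end + gaps[i]
    total = genes[-1].end + int(rng.integers(*long_gap_range))
    sequence = _random_dna(rng, total)
    genome = {chrom: sequence}

    # layout-side arithmetic: upstream gap of each coding gene, skipping
    # non-coding neighbours (independent of the selection module's search)
    short_gap_genes = []
    max_short = short_gap_range[1]
    for i, g in enumerate(genes):
        if not g.is_protein_coding:
            continue
        if g.strand == "+":
            nbrs = [h for h in genes[:i] if h.is_protein_coding]
            if not nbrs:
                continue
            gap = g.start - nbrs[-1].end
        else:
            nbrs = [h for h in genes[i + 1 :] if h.is_protein_coding]
            if not nbrs:
                continue
            gap = nbrs[0].start - g.end
        if 0 < gap <= max_short:
            short_gap_genes.append(g.gene_id)

    truth = SyntheticTruth(
        rng_seed=seed,
        params={
            "n_genes": n_genes,
            "n_short_gaps": n_short_gaps,
            "short_gap_range": list(short_gap_range),
            "long_gap_range": list(long_gap_range),
            "strand_flip_prob": strand_flip_prob,
            "noncoding_prob": noncoding_prob,
            "chrom": chrom,
        },
        short_gap_genes=short_gap_genes,
    )
    return genome, AnnotationSet(genes), truth


# ---------------------------------------------------------------------------
# expression


def expected_fractions(
    n_genes: int, n_enriched: int, fold: float
) -> tuple[float, float]:
    """Closed-form germline fractions (enriched, background) in the noiseless
    limit, accounting for the per-tissue rescaling to one million."""
    # pre-scaling column sums with unit baseline
    germline_sum = (n_genes - n_enriched) + n_enriched * fold
    other_sum = float(n_genes)
    c_g = 1e6 / germline_sum
    c_o = 1e6 / other_sum
    enriched = fold * c_g / (fold * c_g + 4 * c_o)
    background = c_g / (c_g + 4 * c_o)
    return enriched, background


def synth_expression(
    genes: list[str],
    n_enriched: int,
    enrichment_fold: float = 10.0,
    noise_cv: float = 0.1,
    baseline_tpm: float = 200.0,
    seed: int = 0,
) -> tuple[TissueExpressionTable, SyntheticTruth]:
    """TPM table with ``n_enriched`` genes planted at ``enrichment_fold`` x
    germline enrichment, multiplicative lognormal noise of the given CV, and
    every tissue column rescaled to one million."""
    if n_enriched > len(genes):
        raise ValueError("cannot enrich more genes than exist")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    enriched = sorted(
        rng.choice(np.array(genes), size=n_enriched, replace=False).tolist()
    )
    enriched_set = set(enriched)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(
            mean=-(sigma**2) / 2, sigma=sigma, size=(len(genes), len(TISSUES))
        )
    else:
        noise = np.ones((len(genes), len(TISSUES)))
    values = np.full((len(genes), len(TISSUES)), baseline_tpm, dtype=float)
    gi = {t: j for j, t in enumerate(TISSUES)}
    for i, g in enumerate(genes):
        if g in enriched_set:
            values[i, gi["germline"]] *= enrichment_fold
    values *= noise
    values *= 1e6 / values.sum(axis=0, keepdims=True)  # TPM semantics per tissue

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=TISSUES)
    exp_enriched, exp_background = expected_fractions(
        len(genes), n_enriched, enrichment_fold
    )
    truth = SyntheticTruth(
        rng_seed=seed,
        params={
            "n_genes": len(genes),
            "n_enriched": n_enriched,
            "enrichment_fold": enrichment_fold,
            "noise_cv": noise_cv,
            "baseline_tpm": baseline_tpm,
            "expected_enriched_fraction": exp_enriched,
            "expected_background_fraction": exp_background,
        },
        enriched_gene_ids=enriched,
    )
    return TissueExpressionTable(frame), truth


# ---------------------------------------------------------------------------
# sequences with planted violations


def plant_violations(
    seq_len: int,
    run_lengths: tuple[int, ...] = (),
    n_sites: int = 0,
    site_strands: tuple[str, ...] | None = None,
    config: DomesticationConfig = DEFAULT_CONFIG,
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[str, SyntheticTruth]:
    """Sequence of *seq_len* with exactly the requested homopolymer runs and
    enzyme sites planted at recorded positions, on an otherwise clean,
    rejection-sampled background."""
    from .domestication import scan_violations  # local to avoid cycle at import

    if site_strands is None:
        site_strands = tuple("+" if i % 2 == 0 else "-" for i in range(n_sites))
    if len(site_strands) != n_sites:
        raise ValueError("site_strands length must equal n_sites")
    recog = config.enzymes[0]
    elements: list[tuple[str, int | str]] = [("run", L) for L in run_lengths]
    elements += [("site", s) for s in site_strands]
    need = sum(L for L in run_lengths) + n_sites * len(recog) + 2 * len(elements)
    if need > seq_len:
        raise ValueError(
            f"cannot fit planted elements ({need} bp with margins) in {seq_len} bp"
        )
    rng = np.random.default_rng(seed)
    n_el = len(elements)
    for _ in range(max_tries):
        seq = list(_random_dna(rng, seq_len))
        placements = []
        if n_el:
            # one element per equal-width segment, at a random interior offset
            seg = seq_len // n_el
            order = rng.permutation(n_el)
            ok = True
            for slot, ei in enumerate(order):
                kind, spec = elements[ei]
                width = spec if kind == "run" else len(recog)
                lo = slot * seg + 1
                hi = (slot + 1) * seg - width - 1
                if hi < lo:
                    ok = False
                    break
                start = int(rng.integers(lo, hi + 1))
                placements.append((kind, spec, start, width))
            if not ok:
                continue
        for kind, spec, start, width in placements:
            if kind == "run":
                base = str(rng.choice(_BASES))
                seq[start : start + width] = base * width
                # cap the run so background cannot extend it
                others = [b for b in "ACGT" if b != base]
                if start > 0:
                    seq[start - 1] = str(rng.choice(others))
                if start + width < seq_len:
                    seq[start + width] = str(rng.choice(others))
            else:
                motif = recog.upper() if spec == "+" else revcomp(recog.upper())
                seq[start : start + width] = motif
        candidate = "".join(seq)
        runs_found, sites_found = scan_violations(candidate, config)
        want_runs = sorted(
            (start, width)
            for kind, spec, start, width in placements
            if kind == "run"
        )
        want_sites = sorted(
            (start, spec)
            for kind, spec, start, width in placements
            if kind == "site"
        )
        if sorted((r[0], r[1]) for r in runs_found) != want_runs:
            continue
        if sorted((p, s) for p, s, _ in sites_found) != want_sites:
            continue
        truth = SyntheticTruth(
            rng_seed=seed,
            params={
                "seq_len": seq_len,
                "run_lengths": list(run_lengths),
                "n_sites": n_sites,
                "recognition": recog,
            },
            planted_violations=[
                {
                    "kind": kind,
                    "position": start,
                    "length": width,
                    "strand": spec if kind == "site" else None,
                    "base": candidate[start].upper() if kind == "run" else None,
                }
                for kind, spec, start, width in sorted(
                    placements, key=lambda p: p[2]
                )
            ],
        )
        return candidate, truth
    raise RuntimeError("could not plant violations without accidental extras")


# ---------------------------------------------------------------------------
# cytometry events


def synth_copas(
    strains: dict[str, float],
    n_events: int | dict[str, int] = 1000,
    control_strain: str = "N2",
    adult_fraction: float = 0.3,
    adult_tof: tuple[float, float] = (1650.0, 50.0),
    larval_tof: tuple[float, float] = (600.0, 150.0),
    adult_extinction: tuple[float, float] = (20000.0, 4000.0),
    debris_rate: float = 0.0,
    green_mu: float = np.log(100.0),
    green_sigma: float = 0.4,
    larval_green: tuple[float, float] = (5.0, 2.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Mixed-stage event table with planted per-strain fold-changes.

    ``strains`` maps strain name to fold-change of adult green fluorescence
    over the control (the control should be present with fold 1). TOF is an
    adult/larval normal mixture; extinction gains a heavy tail beyond 35,000
    at ``debris_rate``; adult green is lognormal scaled by the planted fold
    while larvae emit background only.
    """
    if isinstance(n_events, int):
        n_events = {s: n_events for s in strains}
    missing = [s for s in strains if s not in n_events]
    if missing:
        raise ValueError(f"missing event counts for strains: {missing}")
    if not 0 <= adult_fraction <= 1:
        raise ValueError("adult_fraction must be in [0, 1]")
    if not 0 <= debris_rate <= 1:
        raise ValueError("debris_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for strain, fold in strains.items():
        if fold <= 0:
            raise ValueError(f"fold for {strain!r} must be positive")
        n = int(n_events[strain])
        if n < 1:
            raise ValueError("n_events must be >= 1")
        is_adult = rng.random(n) < adult_fraction
        tof = np.where(
            is_adult,
            rng.normal(*adult_tof, size=n),
            rng.normal(*larval_tof, size=n),
        )
        tof = np.clip(tof, 0, None)
        ext = np.clip(rng.normal(*adult_extinction, size=n), 0, None)
        is_debris = rng.random(n) < debris_rate
        ext = np.where(ext >= 35000, 34999.0, ext)  # keep the tail planted only
        ext = np.where(is_debris, 35000.0 + rng.exponential(10000.0, size=n), ext)
        green = np.where(
            is_adult,
            fold * rng.lognormal(green_mu, green_sigma, size=n),
            rng.normal(*larval_green, size=n),
        )
        frames.append(
            pd.DataFrame(
                {
                    "strain": strain,
                    "tof": tof,
                    "extinction": ext,
                    "green": green,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(
        rng_seed=seed,
        params={
            "control_strain": control_strain,
            "n_events": dict(n_events),
            "adult_tof": list(adult_tof),
            "larval_tof": list(larval_tof),
            "adult_extinction": list(adult_extinction),
            "debris_rate": debris_rate,
            "green_mu": green_mu,
            "green_sigma": green_sigma,
            "larval_green": list(larval_green),
        },
        planted_relative_levels=dict(strains),
        adult_fraction={s: adult_fraction for s in strains},
    )
    return events, truth


# ---------------------------------------------------------------------------
# toy destination vector


def synth_destination(
    promoter_overhang: str = "GGAG",
    start_pad: str = "aaaa",
    gfp_len: int = 120,
    utr_len: int = 60,
    backbone_len: int = 240,
    stuffer_len: int = 50,
    config: DomesticationConfig = DEFAULT_CONFIG,
    seed: int = 7,
) -> Construct:
    """Circular stand-in destination vector with documented feature order.

    Two inward-cutting acceptor sites flank a stuffer dropout; digestion
    releases the backbone with a 5' ``start_pad`` overhang (leading straight
    into the reporter ATG) and a 3' ``promoter_overhang``, ready to accept a
    flanked promoter part. Feature layout downstream of the start pad:
    gfp (with both NLS), 3' UTR, selection fragment, homology arms.
    """
    from .domestication import scan_violations

    rng = np.random.default_rng(seed)
    recog = config.enzymes[0].upper()
    if len(start_pad) != 4 or len(promoter_overhang) != 4:
        raise ValueError("overhangs must be 4 nt")
    for _ in range(100):
        gfp_body = _clean_dna(rng, gfp_len - 3, config)
        gfp = "ATG" + gfp_body
        utr = _clean_dna(rng, utr_len, config)
        unc_frag = _clean_dna(rng, backbone_len // 2, config)
        arms = _clean_dna(rng, backbone_len - len(unc_frag), config)
        stuffer = _clean_dna(rng, stuffer_len, config)

        # overhang5 + spacer + reverse-site ... stuffer ... site + spacer + pad
        dropout = promoter_overhang + "t" + revcomp(recog) + stuffer + recog + "a"
        seq = dropout + start_pad + gfp + utr + unc_frag + arms
        runs, sites = scan_violations(seq, config)
        if not runs and len(sites) == 2:  # only the two acceptor sites
            break
    else:
        raise RuntimeError("could not sample a clean destination backbone")

    off = len(dropout) + len(start_pad)
    features = [
        Feature("gfp", off, off + len(gfp)),
        Feature("nls_sv40", off + 3, off + 24),
        Feature("nls_egl13", off + len(gfp) - 21, off + len(gfp)),
        Feature("tbb2_utr", off + len(gfp), off + len(gfp) + len(utr)),
        Feature(
            "unc119_fragment",
            off + len(gfp) + len(utr),
            off + len(gfp) + len(utr) + len(unc_frag),
        ),
        Feature(
            "homology_arms",
            off + len(gfp) + len(utr) + len(unc_frag),
            off + len(gfp) + len(utr) + len(unc_frag) + len(arms),
        ),
        Feature("dropout", 0, len(dropout)),
    ]
    construct = Construct(sequence=seq, topology="circular", features=tuple(features))
    return construct
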