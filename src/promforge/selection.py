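"""Rank genes by germline specificity and extract candidate promoter regions.

A candidate's promoter is the intergenic interval from the proximal coding
boundary of the nearest *upstream protein-coding* gene (its stop codon when
tandem, its start codon when head-to-head) up to — and excluding — the
candidate's own start codon. Non-coding genes are skipped during the
neighbour search. All intervals are 0-based half-open; GFF3 input is
converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

TISSUES = ("germline", "neurons", "intestine", "hypodermis", "muscle")


class ExpressionTableError(ValueError):
    """Malformed expression input: missing tissues, genes, or negative TPM."""


class UndefinedFractionError(ValueError):
    """All five tissue TPM values are zero; the fraction is undefined."""


class NoNeighborError(LookupError):
    """No upstream protein-coding gene exists on the chromosome."""


class OverlapError(ValueError):
    """Candidate and neighbour coding spans overlap; no promoter interval."""


class TissueExpressionTable:
    """Gene x tissue TPM matrix over the fixed five-tissue panel.

    Wraps a :class:`pandas.DataFrame` indexed by gene id with exactly the
    columns of :data:`TISSUES`. Validation is strict at load time: a missing
    tissue column, a missing (NaN) value, or a negative TPM raises
    :class:`ExpressionTableError` rather than being silently coerced.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [t for t in TISSUES if t not in frame.columns]
        if missing:
            raise ExpressionTableError(f"missing tissue columns: {missing}")
        frame = frame[list(TISSUES)].copy()
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ExpressionTableError(f"duplicate gene ids: {dups}")
        if frame.isna().any().any():
            bad = frame.index[frame.isna().any(axis=1)].tolist()
            raise ExpressionTableError(f"missing TPM values for genes: {bad}")
        try:
            frame = frame.astype(float)
        except (TypeError, ValueError) as exc:
            raise ExpressionTableError(f"non-numeric TPM values: {exc}") from exc
        if (frame < 0).any().any():
            bad = frame.index[(frame < 0).any(axis=1)].tolist()
            raise ExpressionTableError(f"negative TPM values for genes: {bad}")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def genes(self) -> list[str]:
        return list(self._frame.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self._frame.index

    def tpm(self, gene: str, tissue: str) -> float:
        if tissue not in TISSUES:
            raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        if gene not in self._frame.index:
            raise KeyError(f"unknown gene {gene!r}")
        return float(self._frame.at[gene, tissue])


def relative_tissue_fraction(
    table: TissueExpressionTable, gene: str, tissue: str
) -> float:
    """TPM in *tissue* as a fraction of the gene's summed TPM over the fixed
    five-tissue panel. All-zero genes raise :class:`UndefinedFractionError`."""
    total = sum(table.tpm(gene, t) for t in TISSUES)
    if total == 0:
        raise UndefinedFractionError(
            f"gene {gene!r} has zero TPM in every tissue; fraction undefined"
        )
    return table.tpm(gene, tissue) / total


@dataclass(frozen=True)
class GeneAnnotation:
    """Coding span (start codon through stop codon) of one gene."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open coding span
    end: int
    strand: str
    is_protein_coding: bool = True
    trans_spliced: bool | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty or inverted interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


class AnnotationSet:
    """Indexed collection of :class:`GeneAnnotation` for neighbour queries."""

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self._by_id: dict[str, GeneAnnotation] = {}
        self._by_chrom: dict[str, list[GeneAnnotation]] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def gene(self, gene_id: str) -> GeneAnnotation:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def on_chrom(self, chrom: str) -> list[GeneAnnotation]:
        return list(self._by_chrom.get(chrom, []))


@dataclass(frozen=True)
class PromoterCandidate:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open promoter interval on the plus strand
    end: int
    strand: str
    length_bp: int
    adjacent_gene_id: str
    adjacent_boundary: str  # start_codon | stop_codon
    germline_tpm: float | None = None
    relative_germline_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.length_bp != self.end - self.start:
            raise ValueError("length_bp inconsistent with interval")
        if self.adjacent_boundary not in ("start_codon", "stop_codon"):
            raise ValueError(f"bad boundary {self.adjacent_boundary!r}")
        if self.relative_germline_fraction is not None and not (
            0.0 <= self.relative_germline_fraction <= 1.0
        ):
            raise ValueError("relative_germline_fraction outside [0, 1]")


def extract_promoter_region(ann: AnnotationSet, gene_id: str) -> PromoterCandidate:
    """Intergenic promoter interval upstream of *gene_id*.

    Upstream means 5' of the start codon on the candidate's strand; the
    nearest protein-coding gene bounds the region at its proximal coding
    edge. The candidate's own ATG is excluded (the region ends immediately
    before it).
    """
    cand = ann.gene(gene_id)
    chrom_genes = ann.on_chrom(cand.chrom)
    if cand.strand == "+":
        neighbors = [
            g
            for g in chrom_genes
            if g.is_protein_coding and g.gene_id != gene_id and g.end <= cand.start
        ]
        overlapping = [
            g
            for g in chrom_genes
            if g.is_protein_coding
            and g.gene_id != gene_id
            and g.start < cand.start
            and g.end > cand.start
        ]
        if overlapping:
            raise OverlapError(
                f"{gene_id}: coding span of {overlapping[0].gene_id} overlaps "
                "the candidate start codon"
            )
        if not neighbors:
            raise NoNeighborError(
                f"{gene_id}: no upstream protein-coding gene on {cand.chrom}"
            )
        nb = max(neighbors, key=lambda g: (g.end, g.gene_id))
        region = (nb.end, cand.start)
        # tandem neighbour ends in its stop codon; head-to-head in its start
        boundary = "stop_codon" if nb.strand == "+" else "start_codon"
    else:
        neighbors = [
            g
            for g in chrom_genes
            if g.is_protein_coding and g.gene_id != gene_id and g.start >= cand.end
        ]
        overlapping = [
            g
            for g in chrom_genes
            if g.is_protein_coding
            and g.gene_id != gene_id
            and g.start < cand.end
            and g.end > cand.end
        ]
        if overlapping:
            raise OverlapError(
                f"{gene_id}: coding span of {overlapping[0].gene_id} overlaps "
                "the candidate start codon"
            )
        if not neighbors:
            raise NoNeighborError(
                f"{gene_id}: no upstream protein-coding gene on {cand.chrom}"
            )
        nb = min(neighbors, key=lambda g: (g.start, g.gene_id))
        region = (cand.end, nb.start)
        boundary = "stop_codon" if nb.strand == "-" else "start_codon"
    start, end = region
    if start >= end:
        raise OverlapError(
            f"{gene_id}: empty promoter interval against {nb.gene_id}"
        )
    return PromoterCandidate(
        gene_id=gene_id,
        chrom=cand.chrom,
        start=start,
        end=end,
        strand=cand.strand,
        length_bp=end - start,
        adjacent_gene_id=nb.gene_id,
        adjacent_boundary=boundary,
    )


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for candidate selection.

    Absolute/relative expression cut-offs are deliberately required
    configuration with documented defaults — they are design choices, not
    published constants. ``max_length_bp`` is inclusive ("1 kb or less").
    """

    min_germline_tpm: float = 100.0
    min_fraction: float = 0.4
    max_length_bp: int = 1000
    n_top: int | None = None


def select_candidates(
    table: TissueExpressionTable,
    ann: AnnotationSet,
    config: SelectionConfig = SelectionConfig(),
) -> list[PromoterCandidate]:
    """Ranked promoter candidates passing all thresholds.

    Genes lacking an upstream protein-coding neighbour, with overlapping
    neighbours, or with all-zero expression are excluded (they cannot satisfy
    the thresholds). Sort key: relative germline fraction desc, then germline
    TPM desc, then gene id (deterministic tie-break). Result is independent of
    input row order.
    """
    annotated_genes = [g.gene_id for g in ann if g.is_protein_coding]
    unknown = [g for g in annotated_genes if g not in table]
    if unknown:
        raise ExpressionTableError(
            f"annotation genes missing from expression table: {sorted(unknown)[:5]}..."
            if len(unknown) > 5
            else f"annotation genes missing from expression table: {sorted(unknown)}"
        )
    out = []
    for gene_id in sorted(annotated_genes):
        try:
            frac = relative_tissue_fraction(table, gene_id, "germline")
        except UndefinedFractionError:
            continue
        tpm = table.tpm(gene_id, "germline")
        if tpm < config.min_germline_tpm or frac < config.min_fraction:
            continue
        try:
            region = extract_promoter_region(ann, gene_id)
        except (NoNeighborError, OverlapError):
            continue
        if region.length_bp > config.max_length_bp:
            continue
        out.append(
            PromoterCandidate(
                gene_id=region.gene_id,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                strand=region.strand,
                length_bp=region.length_bp,
                adjacent_gene_id=region.adjacent_gene_id,
                adjacent_boundary=region.adjacent_boundary,
                germline_tpm=tpm,
                relative_germline_fraction=frac,
            )
        )
    out.sort(
        key=lambda c: (
            -c.relative_germline_fraction,
            -c.germline_tpm,
            c.gene_id,
        )
    )
    if config.n_top is not None:
        out = out[: config.n_top]
    return out


def candidates_frame(candidates: list[PromoterCandidate]) -> pd.DataFrame:
    """Tabular view of selection output for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "length_bp": c.length_bp,
                "germline_tpm": c.germline_tpm,
                "relative_germline_fraction": c.relative_germline_fraction,
                "adjacent_gene_id": c.adjacent_gene_id,
                "adjacent_boundary": c.adjacent_boundary,
            }
            for c in candidates
        ]
    )
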