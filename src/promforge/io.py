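"""File-format boundaries: FASTA, GFF3, expression and event tables, GenBank.

Interval convention: everything in memory is 0-based half-open; GFF3's
1-based closed coordinates are converted here and nowhere else.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .assembly import Construct
from .selection import TISSUES, AnnotationSet, GeneAnnotation, TissueExpressionTable


# --- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping of record id to sequence string."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


# --- expression table ------------------------------------------------------


def read_expression_table(path: str | Path) -> TissueExpressionTable:
    """TSV with header ``gene_id<TAB>germline<TAB>neurons<TAB>intestine<TAB>
    hypodermis<TAB>muscle``; strict validation happens in the table type."""
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    return TissueExpressionTable(frame)


def write_expression_table(table: TissueExpressionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="gene_id")


# --- GFF3 ------------------------------------------------------------------


def read_gff3(
    path: str | Path,
    biotype_attribute: str = "biotype",
    coding_value: str = "protein_coding",
) -> AnnotationSet:
    """Load gene coding spans from GFF3 via an in-memory gffutils database.

    The coding span of each gene is the min/max extent of its CDS children
    when present, otherwise the gene's own extent. The biotype attribute key
    is configurable; genes without it are treated as protein-coding.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if cds:
            start = min(c.start for c in cds) - 1  # GFF3 is 1-based closed
            end = max(c.end for c in cds)
        else:
            start, end = gene.start - 1, gene.end
        biotype = gene.attributes.get(biotype_attribute, [coding_value])[0]
        trans = gene.attributes.get("trans_spliced", [None])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=start,
                end=end,
                strand=gene.strand,
                is_protein_coding=biotype == coding_value,
                trans_spliced=None if trans is None else trans == "true",
            )
        )
    return AnnotationSet(genes)


def write_gff3(
    ann: AnnotationSet,
    path: str | Path,
    biotype_attribute: str = "biotype",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann, key=lambda g: (g.chrom, g.start, g.gene_id)):
            biotype = "protein_coding" if g.is_protein_coding else "ncRNA"
            attrs = f"ID={g.gene_id};{biotype_attribute}={biotype}"
            if g.trans_spliced is not None:
                attrs += f";trans_spliced={'true' if g.trans_spliced else 'false'}"
            fh.write(
                f"{g.chrom}\tpromforge\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tpromforge\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n"
            )


# --- COPAS events ----------------------------------------------------------


def read_copas_events(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Event table with columns ``strain, tof, extinction, green`` (plus any
    extras). *column_map* renames vendor-export columns to the canonical
    schema, e.g. ``{"Sample": "strain", "TOF": "tof"}``."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("strain", "tof", "extinction", "green") if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}; use column_map")
    return df


def write_copas_events(events: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    events.to_csv(path, sep=sep, index=False)


# --- reports ---------------------------------------------------------------


def write_edits_tsv(rows: list[dict], path: str | Path) -> None:
    """Edit report: ``seq_id, position (1-based), ref, alt, reason``."""
    pd.DataFrame(rows, columns=["seq_id", "position", "ref", "alt", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def write_summaries_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_construct_genbank(construct: Construct, path: str | Path, name: str = "construct") -> None:
    """Annotated GenBank flat file (features + topology) for a construct."""
    rec = SeqRecord(Seq(construct.sequence), id=name, name=name[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = construct.topology
    for f in construct.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="misc_feature",
                qualifiers={"label": [f.name]},
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def read_construct_genbank(path: str | Path) -> Construct:
    from .assembly import Feature

    rec = next(SeqIO.parse(str(path), "genbank"))
    feats = tuple(
        Feature(
            name=f.qualifiers.get("label", ["feature"])[0],
            start=int(f.location.start),
            end=int(f.location.end),
            strand="+" if (f.location.strand or 1) >= 0 else "-",
        )
        for f in rec.features
        if f.type == "misc_feature"
    )
    topology = rec.annotations.get("topology", "linear")
    return Construct(sequence=str(rec.seq), topology=topology, features=feats)
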