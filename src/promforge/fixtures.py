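"""Packaged reference data: the 20-entry promoter set and its annotations.

The bundled FASTA holds each promoter exactly as synthesized — endogenous
sequence followed by the 15 bp cloning linker — with the reporter start codon
kept in the metadata table rather than the sequence. SHA-256 checksums guard
the transcription; :func:`verify_checksums` recomputes them.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .domestication import CLONING_LINKER
from .quantification import ExpressionPatternRecord

_DATA = resources.files("promforge") / "data"


def _read_text(name: str) -> str:
    return (_DATA / name).read_text()


def load_reference_promoters() -> pd.DataFrame:
    """The packaged promoter set, one row per entry.

    Columns: ``gene, role (control|candidate), sequence (endogenous + linker,
    no start codon), endogenous_sequence, endogenous_length_bp, linker,
    start_codon``.
    """
    meta = pd.read_csv(_DATA / "reference_promoters.tsv", sep="\t")
    seqs: dict[str, str] = {}
    name = None
    for line in _read_text("reference_promoters.fasta").splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line.strip()
    meta["sequence"] = meta["gene"].map(seqs)
    if meta["sequence"].isna().any():
        raise RuntimeError("promoter FASTA and metadata disagree")
    for _, row in meta.iterrows():
        if not row["sequence"].endswith(row["linker"]):
            raise RuntimeError(f"{row['gene']}: linker suffix missing")
    meta["endogenous_sequence"] = meta.apply(
        lambda r: r["sequence"][: -len(r["linker"])], axis=1
    )
    assert (meta["endogenous_sequence"].str.len() == meta["endogenous_length_bp"]).all()
    return meta


def load_expression_patterns() -> list[ExpressionPatternRecord]:
    """Observed reporter expression pattern per candidate promoter."""
    df = pd.read_csv(_DATA / "expression_patterns.tsv", sep="\t")
    return [
        ExpressionPatternRecord(promoter=row.gene, pattern=row.pattern)
        for row in df.itertuples()
    ]


def load_copas_event_counts() -> dict[str, int]:
    """Per-strain event counts of the published cytometry runs."""
    df = pd.read_csv(_DATA / "copas_event_counts.tsv", sep="\t")
    return dict(zip(df["strain"], df["n_events"].astype(int)))


def verify_checksums() -> bool:
    expected = json.loads(_read_text("checksums.json"))["sha256"]
    for fname, digest in expected.items():
        actual = hashlib.sha256((_DATA / fname).read_bytes()).hexdigest()
        if actual != digest:
            raise RuntimeError(f"fixture {fname} fails its checksum")
    return True


LINKER = CLONING_LINKER
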