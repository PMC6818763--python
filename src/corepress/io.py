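"""Plain-text readers and writers: TSV tables, ID lists, FASTA and BED6."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifHit


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression table: transcript IDs in column 1, one column per sample."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table < 0).any().any():
        raise ValueError(f"negative expression values in {path}")
    return table


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


def read_gene_set(path: str | Path) -> set[str]:
    """One transcript ID per line; blank lines and '#' comments ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def write_gene_set(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(ids)))


def read_promoters(path: str | Path) -> dict[str, str]:
    """Upstream regions as FASTA; record ID is the gene ID."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters(
    promoters: Mapping[str, str], path: str | Path, description: str = ""
) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description=description)
        for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path: str | Path) -> pd.Series:
    """2-3 column TSV (transcript, category[, OG id]) -> transcript->category."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("annotation needs at least transcript and category columns")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values)


def write_annotation(annotation: pd.Series | Mapping[str, str], path: str | Path) -> None:
    annot = pd.Series(dict(annotation)) if not isinstance(annotation, pd.Series) else annotation
    frame = pd.DataFrame({"transcript_id": annot.index, "category": annot.values})
    frame.to_csv(path, sep="\t", index=False)


def write_bed6(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Motif hits as BED6: chrom=gene, 0-based half-open, name=probe, score=0."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.start}\t{h.end}\t{h.probe_id}\t0\t{h.strand}\n")


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
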