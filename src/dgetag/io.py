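"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tag libraries, count matrices and gene
sets use TSV (GMT-style for gene sets: term id, description, then member
gene ids, tab separated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import GeneCountMatrix, VirtualTagDB
from .simulate import ReferenceGene
from .tags import TagLibrary


def write_fasta(genes: Iterable[ReferenceGene], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> list[ReferenceGene]:
    return [
        ReferenceGene(gene_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(reads: Iterable[str], path: str | Path, quality_char: str = "I") -> Path:
    """Fixed-quality FASTQ; the pipeline carries no per-base qualities."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i + 1}\n{read}\n+\n{quality_char * len(read)}\n")
    return path


def read_fastq(path: str | Path) -> Iterator[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq).upper()


def write_tag_counts(lib: TagLibrary, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"tag": list(lib.counts), "count": list(lib.counts.values())}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tag_counts(path: str | Path, label: str = "") -> TagLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return TagLibrary.from_counts(label or Path(path).stem,
                                  dict(zip(df["tag"], df["count"])))


def write_count_matrix(matrix: GeneCountMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.counts.to_csv(path, sep="\t")
    return path


def read_count_matrix(path: str | Path) -> GeneCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneCountMatrix.from_counts(df)


def write_virtual_tag_db(db: VirtualTagDB, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for tag, genes in db.entries.items():
        for gid, rank in genes.items():
            rows.append({"tag": tag, "gene_id": gid, "rank_3p": rank})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            desc = (descriptions or {}).get(term, "")
            members = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")
    return path


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    gene_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, *members = parts
            gene_sets[term] = {m for m in members if m}
            descriptions[term] = desc
    return gene_sets, descriptions
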