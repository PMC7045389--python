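"""FASTA/FASTQ and table input/output (Biopython-backed)."""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from viromeshare.model import Contig, Read, Virome

_READS_RE = re.compile(r"reads=(\d+)")
_TEMPLATE_RE = re.compile(r"template=(\S+)")


def read_fastq(path) -> list[Read]:
    """Sanger/Phred+33 FASTQ -> reads with integer Phred qualities."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def read_fasta_reads(path) -> list[Read]:
    """FASTA -> reads without qualities (quality trimming is skipped)."""
    return [Read(id=rec.id, sequence=str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta_reads(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [30] * len(r)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{''.join(chr(q + 33) for q in quals)}\n")


def read_contigs(path) -> list[Contig]:
    """Contig FASTA; ``reads=N`` and ``template=X`` header tags are honored."""
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        m = _READS_RE.search(desc)
        t = _TEMPLATE_RE.search(desc)
        contigs.append(
            Contig(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                read_count=int(m.group(1)) if m else 1,
                template_id=t.group(1) if t else None,
            )
        )
    return contigs


def write_contigs(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            tag = f" template={c.template_id}" if c.template_id else ""
            fh.write(f">{c.id}{tag} reads={c.read_count}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata table: sample, group, week, diet."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "diet": str})
    required = {"sample", "group", "week", "diet"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


def load_study(directory) -> dict[str, Virome]:
    """Load per-sample contig FASTAs plus metadata.tsv from a directory."""
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    viromes = {}
    for _, row in meta.iterrows():
        contigs = read_contigs(directory / f"{row['sample']}.contigs.fasta")
        viromes[row["sample"]] = Virome(
            sample=row["sample"],
            contigs=contigs,
            group=row["group"],
            week=int(row["week"]),
            diet=row["diet"],
        )
    return viromes


def read_hit_table(path) -> pd.DataFrame:
    """12- or 13-column tabular alignment file (13th column: description)."""
    from viromeshare.synthetic_data import HIT_COLUMNS

    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 12:
        raise ValueError(f"hit table has {df.shape[1]} columns; expected >= 12")
    if df.shape[1] == 12:
        df[12] = ""
    df = df.iloc[:, :13]
    df.columns = HIT_COLUMNS
    return df
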