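"""Shared in-memory containers for reads, contigs and pooled samples."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Read:
    """A single sequencing read.

    ``qualities`` are Phred scores (Sanger scale); ``None`` for FASTA input.
    """

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def error_probabilities(self) -> list[float] | None:
        if self.qualities is None:
            return None
        return [10.0 ** (-q / 10.0) for q in self.qualities]


@dataclass
class ReadPlacement:
    """Where a member read sits on its contig's consensus."""

    read_id: str
    offset: int
    strand: int  # +1 or -1
    sequence: str  # oriented as placed


@dataclass
class Contig:
    """Assembled consensus sequence with its read-coverage weight.

    ``read_count`` is the number of reads assembled into the contig and is
    the abundance weight used throughout (read-weighted profiles, the
    homologous-virus diversity index). Synthetic contigs additionally carry
    the identity of the virus template they were fragmented from.
    """

    id: str
    sequence: str
    read_count: int = 1
    member_reads: list[ReadPlacement] = field(default_factory=list)
    template_id: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Virome:
    """One pooled sample's contig set plus its metadata."""

    sample: str
    contigs: list[Contig]
    group: str = ""
    week: int = 0
    diet: str = ""

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def contig_ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.contigs)
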