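"""Greedy overlap-consensus assembly of quality-filtered reads.

Reads are merged best-overlap-first: at every step the admissible pairwise
overlap with the greatest length (ties broken by identity, then by a fixed
lexicographic rule) is merged, where an overlap is admissible when its
identity is at least ``min_identity`` (default 98%) over at least
``max(min_overlap_frac * shorter_sequence_length, min_overlap_abs)``
aligned columns (defaults 50% and 25 nt) — with the fractional term
capped at the longest input read length, because the 50% requirement is a
*read* overlap: once a consensus outgrows a read, joining it still only
requires half a read of overlap. Overlaps are ungapped (layouts
are pure offsets); reverse-complement overlaps are considered, and the
final consensus is reported in canonical (lexicographically smaller)
orientation. Consensus bases follow per-column majority with ties broken
in the fixed base order A < C < G < T.

Candidate overlaps are seeded by shared k-mers, so only offsets supported
by an exact word are scored — the same shortcut overlap assemblers use.
After merging terminates, contigs shorter than 200 nt or containing
ambiguity are dropped (their reads count as unplaced); singleton reads
that merged with nothing are retained as contigs by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from viromeshare.model import Contig, Read, ReadPlacement

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASE_ORDER = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def majority_consensus(column_bases) -> str:
    """Most frequent base of one column; ties break A < C < G < T."""
    bases = list(column_bases)
    if not bases:
        raise ValueError("empty column")
    counts = {b: 0 for b in _BASE_ORDER}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    return max(_BASE_ORDER, key=lambda b: (counts.get(b, 0), -_BASE_ORDER.index(b)))


@dataclass
class AssemblyReport:
    n_input_reads: int
    n_contigs: int
    n_placed_reads: int
    contig_lengths: list[int]
    keep_singletons: bool = True

    @property
    def fraction_placed(self) -> float:
        return self.n_placed_reads / self.n_input_reads if self.n_input_reads else 0.0

    def summary(self) -> dict:
        lengths = sorted(self.contig_lengths)
        return {
            "n_input_reads": self.n_input_reads,
            "n_contigs": self.n_contigs,
            "fraction_placed": round(self.fraction_placed, 4),
            "min_length": lengths[0] if lengths else 0,
            "max_length": lengths[-1] if lengths else 0,
            "mean_length": float(np.mean(lengths)) if lengths else 0.0,
            "keep_singletons": self.keep_singletons,
        }


class _Unit:
    """An assembly unit: a consensus plus the layout of its member reads."""

    __slots__ = ("placements", "consensus", "arr")

    def __init__(self, placements: list[ReadPlacement], consensus: str):
        self.placements = placements
        self.consensus = consensus
        self.arr = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)

    @classmethod
    def from_read(cls, read: Read) -> "_Unit":
        return cls([ReadPlacement(read.id, 0, 1, read.sequence)], read.sequence)

    def flipped(self) -> "_Unit":
        length = len(self.consensus)
        placements = [
            ReadPlacement(
                p.read_id,
                length - (p.offset + len(p.sequence)),
                -p.strand,
                reverse_complement(p.sequence),
            )
            for p in self.placements
        ]
        return _Unit(placements, reverse_complement(self.consensus))

    def shifted(self, delta: int) -> list[ReadPlacement]:
        return [
            ReadPlacement(p.read_id, p.offset + delta, p.strand, p.sequence)
            for p in self.placements
        ]


def _consensus_from_layout(placements: list[ReadPlacement]) -> str:
    """Per-column majority over an ungapped layout (ties A < C < G < T)."""
    length = max(p.offset + len(p.sequence) for p in placements)
    counts = np.zeros((4, length), dtype=np.int32)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASE_ORDER):
        lut[ord(b)] = i
    for p in placements:
        arr = lut[np.frombuffer(p.sequence.encode("ascii"), dtype=np.uint8)]
        valid = arr >= 0
        np.add.at(counts, (arr[valid], p.offset + np.flatnonzero(valid)), 1)
    # argmax over rows in A,C,G,T order returns the first max: the tie rule
    best = np.argmax(counts, axis=0)
    covered = counts.sum(axis=0) > 0
    out = np.frombuffer(_BASE_ORDER.encode(), dtype=np.uint8)[best]
    out = np.where(covered, out, ord("N")).astype(np.uint8)
    return out.tobytes().decode("ascii")


def _candidate_shifts(a: np.ndarray, b: np.ndarray, k: int) -> set[int]:
    """Offsets of b relative to a supported by a shared k-mer."""
    if len(a) < k or len(b) < k:
        return set()
    index: dict[bytes, list[int]] = {}
    ab = a.tobytes()
    for i in range(len(a) - k + 1):
        index.setdefault(ab[i : i + k], []).append(i)
    shifts: set[int] = set()
    bb = b.tobytes()
    for j in range(len(b) - k + 1):
        for i in index.get(bb[j : j + k], ()):
            shifts.add(i - j)
    return shifts


def _best_overlap(
    a: "_Unit", b: "_Unit", min_identity: float, min_overlap_frac: float,
    min_overlap_abs: int, k: int, read_cap: int,
) -> tuple[int, float, int, int] | None:
    """Best admissible ungapped overlap of b (either strand) onto a.

    Returns ``(overlap_length, identity, shift, strand)`` or None. The
    fractional requirement is "50% read overlap": it applies to the
    shorter of the two sequences but is capped at the longest input read
    length (``read_cap``), so a growing contig never demands more overlap
    than half a read — otherwise low-coverage tilings could never close.
    """
    basis = min(len(a.arr), len(b.arr), read_cap)
    need = max(int(np.ceil(min_overlap_frac * basis)), min_overlap_abs)
    best: tuple[int, float, int, int] | None = None
    for strand, bu in ((1, b), (-1, b.flipped())):
        for shift in _candidate_shifts(a.arr, bu.arr, k):
            lo = max(0, shift)
            hi = min(len(a.arr), shift + len(bu.arr))
            ov = hi - lo
            if ov < need:
                continue
            eq = a.arr[lo:hi] == bu.arr[lo - shift : hi - shift]
            ident = float(eq.mean())
            if ident < min_identity:
                continue
            cand = (ov, ident, shift, strand)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    return best


def assemble(
    reads: list[Read],
    min_identity: float = 0.98,
    min_overlap_frac: float = 0.5,
    min_overlap_abs: int = 25,
    min_contig_length: int = 200,
    keep_singletons: bool = True,
    seed_k: int = 15,
) -> tuple[list[Contig], AssemblyReport]:
    """Greedy best-overlap-first assembly.

    Deterministic: candidate merges are ordered by (overlap length,
    identity) with ties broken by unit index. Contigs shorter than
    ``min_contig_length`` or containing ambiguous characters are dropped
    and their reads counted unplaced; singleton reads that never merged
    are kept as contigs when ``keep_singletons`` (and long enough).
    """
    if not reads:
        return [], AssemblyReport(0, 0, 0, [], keep_singletons)
    units: dict[int, _Unit] = {i: _Unit.from_read(r) for i, r in enumerate(reads)}
    merged_something = {i: False for i in units}
    read_cap = max(len(r) for r in reads)

    def score_pair(i: int, j: int):
        return _best_overlap(
            units[i], units[j], min_identity, min_overlap_frac, min_overlap_abs,
            seed_k, read_cap,
        )

    pair_cache: dict[tuple[int, int], tuple | None] = {}
    for i in units:
        for j in units:
            if i < j:
                pair_cache[(i, j)] = score_pair(i, j)

    next_id = len(reads)
    while True:
        best_key = None
        best_val = None
        for key, val in pair_cache.items():
            if val is None:
                continue
            rank = (val[0], val[1], -key[0], -key[1])
            if best_val is None or rank > best_val:
                best_val = rank
                best_key = key
        if best_key is None:
            break
        i, j = best_key
        ov, ident, shift, strand = pair_cache[best_key][:4]
        a, b = units[i], units[j]
        bu = b if strand == 1 else b.flipped()
        delta = -min(0, shift)
        placements = a.shifted(delta) + [
            ReadPlacement(p.read_id, p.offset + shift + delta, p.strand, p.sequence)
            for p in bu.placements
        ]
        consensus = _consensus_from_layout(placements)
        new = _Unit(placements, consensus)
        del units[i], units[j]
        pair_cache = {k: v for k, v in pair_cache.items() if i not in k and j not in k}
        units[next_id] = new
        merged_something[next_id] = True
        for other in units:
            if other != next_id:
                key = (min(other, next_id), max(other, next_id))
                pair_cache[key] = score_pair(key[0], key[1])
        next_id += 1

    contigs: list[Contig] = []
    n_placed = 0
    for uid, unit in sorted(units.items()):
        is_singleton = len(unit.placements) == 1 and not merged_something[uid]
        if is_singleton and not keep_singletons:
            continue
        seq = unit.consensus
        if len(seq) < min_contig_length or any(c not in "ACGT" for c in seq):
            continue
        canonical = min(seq, reverse_complement(seq))
        placements = unit.placements if canonical == seq else unit.flipped().placements
        n_placed += len(placements)
        contigs.append(
            Contig(
                id=f"contig_{len(contigs) + 1}",
                sequence=canonical,
                read_count=len(placements),
                member_reads=placements,
            )
        )
    report = AssemblyReport(
        n_input_reads=len(reads),
        n_contigs=len(contigs),
        n_placed_reads=n_placed,
        contig_lengths=[len(c) for c in contigs],
        keep_singletons=keep_singletons,
    )
    return contigs, report


def validate_layout(contig: Contig, min_identity: float = 0.98) -> bool:
    """Post-hoc check: every member read aligns to the consensus at
    ``min_identity`` over its placed span."""
    cons = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
    for p in contig.member_reads:
        span = cons[p.offset : p.offset + len(p.sequence)]
        read = np.frombuffer(p.sequence.encode("ascii"), dtype=np.uint8)
        if len(span) != len(read):
            return False
        if float((span == read).mean()) < min_identity:
            return False
    return True
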