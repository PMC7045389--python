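"""Nucleotide local-alignment homology search between viromes.

A light seed-and-extend aligner in the BLASTN mould: exact k-mer seeds on
both strands, optimal ungapped extension along each seed diagonal, and a
greedy chaining step that joins nearby collinear segments across short
gaps. Scores use the classic +1/-2 match/mismatch DNA scheme with
Karlin-Altschul significance: ``bitscore = (lambda*S - ln K) / ln 2`` and
``evalue = m * n * 2**(-bitscore)`` where m is the query length and n the
total subject length of the index. The defaults (lambda = 1.33, K = 0.621)
are the classic ungapped +1/-2 DNA calibration; only the E-value
thresholds, not the scoring, are fixed by the comparative protocol this
module serves (1e-10 for cross-virome comparisons, 1e-5 for host
screening).

Externally computed hits in the standard 12-column tabular dialect can be
imported in place of the built-in engine at any step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from viromeshare.model import Contig, Virome

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/gap scores and Karlin-Altschul calibration."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.33
    k: float = 0.621

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw_score))


@dataclass
class HomologyHit:
    """One local-alignment match (1-based inclusive coordinates).

    ``sstart > send`` marks a minus-strand hit, as in tabular BLAST output.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: float = 1.0
    bitscore: float = 0.0

    @property
    def strand(self) -> int:
        return -1 if self.sstart > self.send else 1


@dataclass
class SharedSet:
    """Directed sharing: which of A's contigs have a homologue in B."""

    query_virome: str
    subject_virome: str
    shared_ids: frozenset[str]
    n_queries: int

    @property
    def shared_fraction(self) -> float:
        return len(self.shared_ids) / self.n_queries if self.n_queries else 0.0


class HomologyIndex:
    """k-mer seed index over a set of subject contigs (both strands)."""

    def __init__(self, contigs: list[Contig], k: int = 11, scoring: ScoringScheme | None = None):
        if not contigs:
            raise ValueError("cannot build an index over an empty contig set")
        if not 8 <= k <= 15:
            raise ValueError(f"seed length k must be in [8, 15], got {k}")
        ids = [c.id for c in contigs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids in subject set: {dupes[:5]}")
        self.k = k
        self.scoring = scoring or ScoringScheme()
        self.subjects: dict[str, str] = {c.id: c.sequence for c in contigs}
        self._ids = ids
        # oriented subject strings: (id, strand) -> uint8 array
        self._arr: dict[tuple[str, int], np.ndarray] = {}
        self.total_length = sum(len(c.sequence) for c in contigs)
        self.seeds: dict[str, list[tuple[str, int, int]]] = {}
        for c in contigs:
            for strand, seq in ((1, c.sequence), (-1, reverse_complement(c.sequence))):
                self._arr[(c.id, strand)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                for i in range(len(seq) - k + 1):
                    self.seeds.setdefault(seq[i : i + k], []).append((c.id, i, strand))

    @property
    def n_seed_positions(self) -> int:
        return sum(len(v) for v in self.seeds.values())

    def oriented(self, subject_id: str, strand: int) -> np.ndarray:
        return self._arr[(subject_id, strand)]


def build_index(contigs: list[Contig], k: int = 11, scoring: ScoringScheme | None = None) -> HomologyIndex:
    """Index every k-mer of every subject contig on both strands."""
    return HomologyIndex(contigs, k=k, scoring=scoring)


def _extend_diagonal(
    q: np.ndarray, s: np.ndarray, diag: int, seed_q: int, k: int, scoring: ScoringScheme
) -> tuple[int, int, int, int] | None:
    """Optimal ungapped segment through a seed on one diagonal.

    Returns ``(qstart, qend_exclusive, score, matches)`` in query
    coordinates, or None for a non-positive segment. The extension scans
    the full diagonal from the seed outward, keeping the maximal-scoring
    prefix in each direction (exact for ungapped alignment through the
    seed).
    """
    lo = max(0, -diag)  # smallest query pos on this diagonal
    hi = min(len(q), len(s) - diag)  # one past largest
    if hi - lo < k:
        return None
    eq = q[lo:hi] == s[lo + diag : hi + diag]
    contrib = np.where(eq, scoring.match, scoring.mismatch).astype(np.int64)
    i0 = seed_q - lo
    # right extension: maximal prefix sum of contrib[i0:]
    right = np.cumsum(contrib[i0:])
    r_best = int(np.argmax(right))
    r_score = int(right[r_best])
    # left extension: maximal suffix sum of contrib[:i0]
    if i0 > 0:
        left = np.cumsum(contrib[:i0][::-1])
        l_best = int(np.argmax(left))
        l_score = int(left[l_best])
        if l_score <= 0:
            l_score, l_best = 0, -1
    else:
        l_score, l_best = 0, -1
    score = r_score + l_score
    if score <= 0:
        return None
    qstart = lo + i0 - 1 - l_best if l_best >= 0 else lo + i0
    qend = lo + i0 + r_best + 1
    matches = int(eq[qstart - lo : qend - lo].sum())
    return qstart, qend, score, matches


def search(
    query: Contig | str,
    index: HomologyIndex,
    evalue_max: float = 1e-10,
    query_id: str = "query",
    exclude_subjects: frozenset[str] | set[str] | None = None,
) -> list[HomologyHit]:
    """Seed-and-extend search of one query against the index.

    Both strands are searched (the index holds both subject orientations).
    Collinear ungapped segments on nearby diagonals are chained across
    short gaps with affine gap costs. Hits with ``evalue < evalue_max``
    are returned sorted by ascending E-value then descending bitscore.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    if isinstance(query, Contig):
        qseq, query_id = query.sequence, query.id
    else:
        qseq = query
    k, scoring = index.k, index.scoring
    if len(qseq) < k:
        return []
    q = np.frombuffer(qseq.encode("ascii"), dtype=np.uint8)
    # collect one representative seed per (subject, strand, diagonal)
    diag_seed: dict[tuple[str, int, int], int] = {}
    for i in range(len(qseq) - k + 1):
        for sid, pos, strand in index.seeds.get(qseq[i : i + k], ()):
            if exclude_subjects and sid in exclude_subjects:
                continue
            key = (sid, strand, pos - i)  # diag: subject pos = query pos + diag
            if key not in diag_seed:
                diag_seed[key] = i
    # ungapped extension per diagonal
    segs: dict[tuple[str, int], list[tuple[int, int, int, int, int]]] = {}
    for (sid, strand, diag), seed_q in diag_seed.items():
        ext = _extend_diagonal(q, index.oriented(sid, strand), diag, seed_q, k, scoring)
        if ext is None:
            continue
        qstart, qend, score, matches = ext
        segs.setdefault((sid, strand), []).append((qstart, qend, diag, score, matches))
    hits: list[HomologyHit] = []
    m = len(qseq)
    n = index.total_length
    for (sid, strand), seglist in segs.items():
        for qstart, qend, diag, score, matches in _chain_segments(seglist, scoring):
            evalue = scoring.evalue(score, m, n)
            if evalue >= evalue_max:
                continue
            length = qend - qstart
            slen = len(index.subjects[sid])
            s0, s1 = qstart + diag, qend + diag  # coords on oriented subject
            if strand == 1:
                sstart, send = s0 + 1, s1
            else:
                sstart, send = slen - s0, slen - s1 + 1
            hits.append(
                HomologyHit(
                    query_id=query_id,
                    subject_id=sid,
                    percent_identity=round(100.0 * matches / length, 2),
                    alignment_length=length,
                    mismatches=length - matches,
                    qstart=qstart + 1,
                    qend=qend,
                    sstart=sstart,
                    send=send,
                    evalue=evalue,
                    bitscore=round(scoring.bitscore(score), 1),
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.bitscore))
    return hits


def _chain_segments(
    segs: list[tuple[int, int, int, int, int]],
    scoring: ScoringScheme,
    max_diag_shift: int = 20,
    max_gap: int = 50,
) -> list[tuple[int, int, int, int, int]]:
    """Greedy chaining of collinear ungapped segments across short gaps.

    Two segments chain when the later one starts after the earlier ends
    (small overlaps trimmed), the diagonal shift is at most
    ``max_diag_shift`` (affine gap cost charged per shifted base) and the
    in-between stretch is at most ``max_gap``. Returns merged
    ``(qstart, qend, score, matches)`` tuples.
    """
    segs = sorted(segs, key=lambda s: s[0])
    merged: list[list[int]] = []
    for qstart, qend, diag, score, matches in segs:
        if merged:
            last = merged[-1]
            shift = abs(diag - last[2])
            gap = qstart - last[1]
            if shift <= max_diag_shift and -10 <= gap <= max_gap:
                gap_cost = (scoring.gap_open + scoring.gap_extend * max(shift - 1, 0)) if shift else 0
                bridge = max(gap, 0) * scoring.mismatch if shift == 0 else 0
                new_score = last[3] + score + gap_cost + bridge
                if new_score > max(last[3], score):
                    last[1] = max(last[1], qend)
                    last[2] = diag
                    last[3] = new_score
                    last[4] += matches
                    continue
            if score <= last[3] and qstart < last[1]:
                continue  # dominated overlap on a shifted diagonal
        merged.append([qstart, qend, diag, score, matches])
    return [(s[0], s[1], s[2], s[3], min(s[4], s[1] - s[0])) for s in merged]


def import_hits(stream, max_errors: int | None = None) -> tuple[list[HomologyHit], list[str]]:
    """Parse 12-column tabular alignment rows (query, subject, pident,
    length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore; extra columns ignored).

    Malformed rows are reported with their line numbers and skipped;
    parsing continues. Accepts a file path, file object, or iterable of
    lines.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return import_hits(fh)
    hits: list[HomologyHit] = []
    errors: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            errors.append(f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}")
            continue
        try:
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
        if max_errors is not None and len(errors) > max_errors:
            raise ValueError(f"too many malformed rows (> {max_errors}); last: {errors[-1]}")
    return hits, errors


def shared_fraction(
    queries: Virome, index: HomologyIndex, evalue_max: float = 1e-10,
    subject_virome: str = "", exclude_subjects: frozenset[str] | None = None,
) -> SharedSet:
    """Fraction of A's contigs with >=1 admissible hit in B's index.

    Directed: sharing(A->B) need not equal sharing(B->A); callers needing
    a symmetric quantity combine both directions (see the Jaccard
    construction in :mod:`viromeshare.community_metrics`).
    """
    if not queries.contigs:
        raise ValueError(f"query virome {queries.sample!r} is empty")
    shared = frozenset(
        c.id
        for c in queries.contigs
        if search(c, index, evalue_max=evalue_max, exclude_subjects=exclude_subjects)
    )
    return SharedSet(
        query_virome=queries.sample,
        subject_virome=subject_virome,
        shared_ids=shared,
        n_queries=len(queries.contigs),
    )


def cross_compare(
    viromes: dict[str, Virome], k: int = 11, evalue_max: float = 1e-10,
    scoring: ScoringScheme | None = None,
) -> dict[tuple[str, str], SharedSet]:
    """All-ordered-pairs sharing via one combined index.

    Every contig of every virome is searched once against an index over
    the union of all contigs; a query counts as shared with virome B when
    it hits any contig of B (own-sample subjects are ignored). Equivalent
    to building one index per virome and searching each against each, but
    with a single index build and one search per contig.
    """
    owner = {c.id: s for s, v in viromes.items() for c in v.contigs}
    all_contigs = [c for v in viromes.values() for c in v.contigs]
    index = build_index(all_contigs, k=k, scoring=scoring)
    partners: dict[str, set[str]] = {}
    for sample, v in viromes.items():
        for c in v.contigs:
            hit_samples = {owner[h.subject_id] for h in search(c, index, evalue_max=evalue_max)}
            hit_samples.discard(sample)
            partners[c.id] = hit_samples
    out: dict[tuple[str, str], SharedSet] = {}
    for a, va in viromes.items():
        for b in viromes:
            if a == b:
                continue
            shared = frozenset(c.id for c in va.contigs if b in partners[c.id])
            out[(a, b)] = SharedSet(a, b, shared, len(va.contigs))
    return out


def write_hits(hits: list[HomologyHit], path) -> None:
    """Write hits as 12-column tab-separated rows."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity}\t{h.alignment_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue:.3g}\t{h.bitscore}\n"
            )
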