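"""Read-level quality, complexity, length, ambiguity and host filters.

Quality trimming follows the running-sum (Mott) rule used by common
trimmers: every base contributes ``limit - p_error`` and the retained
segment is the contiguous stretch with the maximal cumulative score. With
the default ``limit=0.5`` a base only scores negative when its error
probability exceeds 0.5, which is the permissive "modified Phred score"
convention of workbench-style trimmers; the limit is configurable because
vendors differ.

The remaining filters are pure per-read predicates: length inside
[150, 300] nt, no homopolymer run of 8 or more identical bases, and no
non-ACGT character. Host screening removes reads with at least one
alignment hit (E < 1e-5 by default) against a host index built by the
homology module, or against an externally computed hit table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from viromeshare.model import Read

logger = logging.getLogger(__name__)

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass
class QCReport:
    """Per-filter removal tallies; conserves ``input = output + removed``."""

    input_count: int = 0
    removed_quality: int = 0
    removed_length: int = 0
    removed_homopolymer: int = 0
    removed_ambiguous: int = 0
    removed_host: int = 0
    output_count: int = 0
    mean_length: float = 0.0
    mean_gc: float = 0.0

    @property
    def removed_total(self) -> int:
        return (
            self.removed_quality
            + self.removed_length
            + self.removed_homopolymer
            + self.removed_ambiguous
            + self.removed_host
        )

    def check(self) -> None:
        if self.input_count != self.output_count + self.removed_total:
            raise AssertionError("QCReport conservation identity violated")

    def to_dict(self) -> dict:
        return {
            "input": self.input_count,
            "removed_quality": self.removed_quality,
            "removed_length": self.removed_length,
            "removed_homopolymer": self.removed_homopolymer,
            "removed_ambiguous": self.removed_ambiguous,
            "removed_host": self.removed_host,
            "output": self.output_count,
            "mean_length": round(self.mean_length, 2),
            "mean_gc": round(self.mean_gc, 4),
        }


def quality_trim(read: Read, limit: float = 0.5) -> Read | None:
    """Clip a read to its maximal-scoring segment under the Mott rule.

    Each base scores ``limit - p_error``; the retained segment maximizes
    the cumulative score (ties broken toward the leftmost, then shortest
    such segment). Returns ``None`` when no positive-scoring segment
    exists. Reads without qualities pass through unchanged with a warning.
    """
    if not 0.0 < limit < 1.0:
        raise ValueError(f"limit must be in (0, 1), got {limit}")
    probs = read.error_probabilities
    if probs is None:
        logger.warning("read %s has no qualities; quality trimming skipped", read.id)
        return read
    best = 0.0
    best_range: tuple[int, int] | None = None
    running = 0.0
    start = 0
    for i, p in enumerate(probs):
        running += limit - p
        if running <= 0.0:
            running = 0.0
            start = i + 1
        elif running > best + 1e-12:
            best = running
            best_range = (start, i + 1)
    if best_range is None:
        return None
    s, e = best_range
    return Read(
        id=read.id,
        sequence=read.sequence[s:e],
        qualities=read.qualities[s:e] if read.qualities is not None else None,
    )


def max_homopolymer_run(sequence: str) -> int:
    best = run = 1 if sequence else 0
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def filter_reads(
    reads: list[Read],
    min_len: int = 150,
    max_len: int = 300,
    max_homopolymer: int = 7,
    allow_ambiguous: bool = False,
) -> tuple[list[Read], QCReport]:
    """Apply the length, low-complexity and ambiguity filters.

    A read passes iff its length lies in ``[min_len, max_len]``, it has no
    homopolymer run longer than ``max_homopolymer`` and (unless
    ``allow_ambiguous``) contains only A/C/G/T. Each removed read is
    tallied under the first predicate it fails (length, then homopolymer,
    then ambiguity); survivors are order-independent because each filter is
    a pure per-read predicate.
    """
    report = QCReport(input_count=len(reads))
    passed: list[Read] = []
    for read in reads:
        if not min_len <= len(read) <= max_len:
            report.removed_length += 1
        elif max_homopolymer_run(read.sequence) > max_homopolymer:
            report.removed_homopolymer += 1
        elif not allow_ambiguous and _NON_ACGT.search(read.sequence):
            report.removed_ambiguous += 1
        else:
            passed.append(read)
    report.output_count = len(passed)
    if passed:
        total = sum(len(r) for r in passed)
        gc = sum(r.sequence.count("G") + r.sequence.count("C") for r in passed)
        report.mean_length = total / len(passed)
        report.mean_gc = gc / total
    report.check()
    return passed, report


def screen_host(
    reads: list[Read],
    host_index=None,
    host_hits: set[str] | None = None,
    evalue_max: float = 1e-5,
) -> tuple[list[Read], int]:
    """Remove reads with significant similarity to a host reference.

    Either ``host_index`` (a :class:`~viromeshare.homology.HomologyIndex`
    over host sequences) or ``host_hits`` (query ids from an externally
    computed hit table, already thresholded) must be supplied. Returns the
    surviving reads and the number removed.
    """
    if host_index is None and host_hits is None:
        logger.warning("no host index or hit table supplied; all reads pass")
        return list(reads), 0
    if host_hits is None:
        from viromeshare.homology import search

        if not host_index.subjects:
            logger.warning("empty host index; all reads pass")
            return list(reads), 0
        host_hits = set()
        for read in reads:
            if search(read.sequence, host_index, evalue_max=evalue_max, query_id=read.id):
                host_hits.add(read.id)
    passed = [r for r in reads if r.id not in host_hits]
    return passed, len(reads) - len(passed)


def run_qc(
    reads: list[Read],
    limit: float = 0.5,
    min_len: int = 150,
    max_len: int = 300,
    max_homopolymer: int = 7,
    host_index=None,
    host_hits: set[str] | None = None,
    host_evalue: float = 1e-5,
) -> tuple[list[Read], QCReport]:
    """Full QC pass: quality trim, then length/complexity/ambiguity filters,
    then host screening (when a host reference is supplied)."""
    trimmed: list[Read] = []
    n_quality_removed = 0
    for read in reads:
        t = quality_trim(read, limit=limit)
        if t is None:
            n_quality_removed += 1
        else:
            trimmed.append(t)
    passed, report = filter_reads(
        trimmed, min_len=min_len, max_len=max_len, max_homopolymer=max_homopolymer
    )
    report.input_count = len(reads)
    report.removed_quality = n_quality_removed
    if host_index is not None or host_hits is not None:
        passed, n_host = screen_host(
            passed, host_index=host_index, host_hits=host_hits, evalue_max=host_evalue
        )
        report.removed_host = n_host
        report.output_count = len(passed)
        if passed:
            total = sum(len(r) for r in passed)
            gc = sum(r.sequence.count("G") + r.sequence.count("C") for r in passed)
            report.mean_length = total / len(passed)
            report.mean_gc = gc / total
    report.check()
    return passed, report
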