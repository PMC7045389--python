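"""Functional, family and superkingdom profiling from ranked hit tables.

Consumes 12-column tabular alignment rows extended with a 13th subject
description column (the output shape of a translated protein search) and
turns them into per-contig annotation records and per-sample profiles:

* functional category (capsid/head, portal, tail, ..., integrase, lysin)
  from a keyword taxonomy at E <= 1e-5, walking hits in rank order and
  skipping past no-function best hits as long as a lower-ranked functional
  hit still meets the cutoff;
* virus family from the best-ranked hit carrying a bracketed organism at
  E < 1e-20;
* superkingdom of the best passing hit (virus / bacterium / none);
* family profiles weighted by reads, by contigs, or by read counts
  rescaled to the smallest per-sample total (depth-normalized);
* lifestyle statistics: percent integrase-positive and lysin-positive
  contigs and the integrase:lysin ratio.

The shipped keyword lists are a documented, versioned reconstruction of
gene-category parsing conventions for phage annotation; edit
``data/keywords.tsv`` to retune them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from viromeshare.model import Virome

FUNCTIONAL_EVALUE_MAX = 1e-5
FAMILY_EVALUE_MAX = 1e-20

_BRACKET = re.compile(r"\[([^\[\]]+)\]\s*$")

KNOWN_VIRUS_FAMILIES = frozenset(
    {
        "Siphoviridae",
        "Myoviridae",
        "Podoviridae",
        "Microviridae",
        "Phycodnaviridae",
        "Mimiviridae",
        "Iridoviridae",
        "Inoviridae",
        "Herelleviridae",
        "Ackermannviridae",
        "Autographiviridae",
        "Drexlerviridae",
        "Circoviridae",
        "Anelloviridae",
    }
)


@dataclass
class KeywordTaxonomy:
    """Ordered category -> keyword lists; matching is case-insensitive
    substring search, first category in file order wins."""

    categories: dict[str, list[str]]

    @classmethod
    def default(cls) -> "KeywordTaxonomy":
        path = resources.files("viromeshare") / "data" / "keywords.tsv"
        return cls.from_tsv(path)

    @classmethod
    def from_tsv(cls, path) -> "KeywordTaxonomy":
        categories: dict[str, list[str]] = {}
        with open(str(path)) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cat, _, kw = line.partition("\t")
                words = [w.strip().lower() for w in kw.split(",") if w.strip()]
                if not words and cat != "hypothetical":
                    raise ValueError(f"category {cat!r} has an empty keyword list")
                categories[cat] = words
        return cls(categories=categories)

    @property
    def functional_categories(self) -> list[str]:
        return [c for c in self.categories if c != "hypothetical"]

    def match(self, description: str) -> str | None:
        """Category of a description, or None when nothing matches.
        Functional categories take precedence over 'hypothetical'."""
        desc = description.lower()
        hypothetical = None
        for cat, words in self.categories.items():
            if any(w in desc for w in words):
                if cat == "hypothetical":
                    hypothetical = cat
                else:
                    return cat
        return hypothetical


@dataclass
class AnnotationRecord:
    contig_id: str
    functional_category: str  # a taxonomy category, "hypothetical" or "none"
    family: str  # family name or "unassigned"
    superkingdom: str  # virus | bacterium | none
    supporting_hit: str = ""
    read_count: int = 1
    categories_present: frozenset[str] = field(default_factory=frozenset)

    @property
    def annotated(self) -> bool:
        return self.functional_category != "none"


def _organism(description: str) -> str | None:
    m = _BRACKET.search(description.strip())
    return m.group(1) if m else None


def _superkingdom(description: str) -> str:
    org = _organism(description)
    if org is None:
        return "none"
    if org in KNOWN_VIRUS_FAMILIES or org.endswith("viridae") or org.endswith("virus"):
        return "virus"
    return "bacterium"


def categorize_contig(
    hits: pd.DataFrame,
    taxonomy: KeywordTaxonomy,
    evalue_max: float = FUNCTIONAL_EVALUE_MAX,
) -> str:
    """Functional category of one contig from its ranked hits.

    Hits are walked best-first; the first description matching a
    functional keyword and passing ``evalue_max`` decides. When only
    no-function descriptions pass, the contig is "hypothetical"; when
    nothing passes, "none".
    """
    hits = _ensure_sorted(hits)
    saw_hypothetical = False
    for _, row in hits.iterrows():
        if row["evalue"] > evalue_max:
            continue
        cat = taxonomy.match(str(row["stitle"]))
        if cat is None or cat == "hypothetical":
            saw_hypothetical = saw_hypothetical or cat == "hypothetical"
            continue
        return cat
    return "hypothetical" if saw_hypothetical else "none"


def _ensure_sorted(hits: pd.DataFrame) -> pd.DataFrame:
    ev = hits["evalue"].to_numpy()
    if len(ev) > 1 and np.any(np.diff(ev) < 0):
        return hits.sort_values("evalue", kind="mergesort")
    return hits


def annotate_contig(contig_id: str, hits: pd.DataFrame, taxonomy: KeywordTaxonomy,
                    read_count: int = 1) -> AnnotationRecord:
    """Full annotation record for one contig (category, family,
    superkingdom, every functional category present among passing hits)."""
    hits = _ensure_sorted(hits)
    category = categorize_contig(hits, taxonomy)
    passing = hits[hits["evalue"] <= FUNCTIONAL_EVALUE_MAX]
    present = set()
    for _, row in passing.iterrows():
        cat = taxonomy.match(str(row["stitle"]))
        if cat and cat != "hypothetical":
            present.add(cat)
    family = "unassigned"
    support = ""
    for _, row in hits.iterrows():
        if row["evalue"] < FAMILY_EVALUE_MAX:
            org = _organism(str(row["stitle"]))
            if org and _superkingdom(str(row["stitle"])) == "virus":
                family = org
                support = str(row["sseqid"])
                break
    superkingdom = "none"
    if len(passing):
        superkingdom = _superkingdom(str(passing.iloc[0]["stitle"]))
    return AnnotationRecord(
        contig_id=contig_id,
        functional_category=category,
        family=family,
        superkingdom=superkingdom,
        supporting_hit=support,
        read_count=read_count,
        categories_present=frozenset(present),
    )


def annotate_virome(
    virome: Virome, hits: pd.DataFrame, taxonomy: KeywordTaxonomy | None = None
) -> list[AnnotationRecord]:
    """Annotate every contig of a virome from a pooled hit table.

    Contigs without any hit rows get category/family/superkingdom
    "none"/"unassigned"/"none" but keep their read weight.
    """
    taxonomy = taxonomy or KeywordTaxonomy.default()
    by_query = dict(tuple(hits.groupby("qseqid", sort=False)))
    records = []
    for contig in virome.contigs:
        sub = by_query.get(contig.id)
        if sub is None or sub.empty:
            records.append(
                AnnotationRecord(
                    contig_id=contig.id,
                    functional_category="none",
                    family="unassigned",
                    superkingdom="none",
                    read_count=contig.read_count,
                )
            )
        else:
            rec = annotate_contig(contig.id, sub, taxonomy, read_count=contig.read_count)
            records.append(rec)
    return records


@dataclass
class FamilyProfile:
    sample: str
    mode: str  # reads | contigs | depth-normalized
    percentages: dict[str, float]  # families + "unassigned", sums to 100

    def check(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-6:
            raise AssertionError(f"profile percentages sum to {total}, not 100")


def family_profile(
    annotations: list[AnnotationRecord],
    mode: str = "reads",
    sample: str = "",
    depth_floor: int | None = None,
) -> FamilyProfile:
    """Family composition of one sample.

    ``mode='reads'`` weights each contig by its read count,
    ``mode='contigs'`` by 1, and ``mode='depth-normalized'`` by read
    counts rescaled (and floored to integers) so the sample total equals
    ``depth_floor`` — the study-wide smallest sampling depth, which the
    caller supplies (see :func:`family_profiles`). Percentages cover
    assigned families plus "unassigned" and sum to 100.
    """
    if mode not in {"reads", "contigs", "depth-normalized"}:
        raise ValueError(f"unknown mode {mode!r}")
    if not annotations:
        raise ValueError("no annotations")
    weights: dict[str, float] = {}
    if mode == "depth-normalized":
        if depth_floor is None:
            raise ValueError("depth-normalized mode requires depth_floor")
        total = sum(a.read_count for a in annotations)
        scale = depth_floor / total if total else 0.0
        w = [float(int(a.read_count * scale)) for a in annotations]
    elif mode == "reads":
        w = [float(a.read_count) for a in annotations]
    else:
        w = [1.0 for _ in annotations]
    for a, wi in zip(annotations, w):
        weights[a.family] = weights.get(a.family, 0.0) + wi
    total_w = sum(weights.values())
    if total_w == 0:
        raise ValueError("zero total weight (all contigs floored away?)")
    pct = {fam: 100.0 * v / total_w for fam, v in weights.items()}
    pct.setdefault("unassigned", 0.0)
    prof = FamilyProfile(sample=sample, mode=mode, percentages=pct)
    prof.check()
    return prof


def family_profiles(
    per_sample: dict[str, list[AnnotationRecord]], mode: str = "reads"
) -> dict[str, FamilyProfile]:
    """Profiles for every sample; in depth-normalized mode the floor is
    the smallest per-sample read total across the study."""
    floor = None
    if mode == "depth-normalized":
        floor = min(sum(a.read_count for a in annots) for annots in per_sample.values())
    return {
        s: family_profile(annots, mode=mode, sample=s, depth_floor=floor)
        for s, annots in per_sample.items()
    }


@dataclass
class LifestyleStats:
    pct_integrase: float
    pct_lysin: float
    ratio: float | None  # None when undefined (lysin count 0, integrase > 0)
    n_annotated: int

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def lifestyle_stats(annotations: list[AnnotationRecord]) -> LifestyleStats:
    """Integrase/lysin content of one sample.

    A contig counts toward a marker when any of its passing hits falls in
    that category (a contig can in principle carry both). Percentages are
    over annotated contigs; the ratio is integrase count / lysin count,
    undefined (None) when there are integrases but no lysins.
    """
    annotated = [a for a in annotations if a.annotated]
    if not annotated:
        raise ValueError("no annotated contigs")
    n_int = sum("integrase" in a.categories_present for a in annotated)
    n_lys = sum("lysin" in a.categories_present for a in annotated)
    if n_lys > 0:
        ratio: float | None = n_int / n_lys
    elif n_int == 0:
        ratio = 0.0
    else:
        ratio = None
    return LifestyleStats(
        pct_integrase=100.0 * n_int / len(annotated),
        pct_lysin=100.0 * n_lys / len(annotated),
        ratio=ratio,
        n_annotated=len(annotated),
    )


def superkingdom_fractions(annotations: list[AnnotationRecord]) -> dict[str, float]:
    """Read-weighted percentages of contigs by best-hit superkingdom."""
    totals = {"virus": 0.0, "bacterium": 0.0, "none": 0.0}
    for a in annotations:
        totals[a.superkingdom] += a.read_count
    grand = sum(totals.values())
    if grand == 0:
        return {k: 0.0 for k in totals}
    return {k: 100.0 * v / grand for k, v in totals.items()}
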