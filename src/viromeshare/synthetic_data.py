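"""Synthetic virome-study generator with known ground truth.

Builds complete virome studies — a pool of virus genome templates, one
pooled sample per group x timepoint, contigs (and optionally reads) derived
from the templates, and ranked annotation hits — so that every downstream
statistic (shared-homologue fractions, family profiles, integrase/lysin
content, G+C, beta diversity) can be checked against a recorded truth.

The default study emulates a murine diet-switch design: four treatment
groups (CTL, STAT, CTL-COHO, STAT-COHO) sampled at weeks 4, 5, 15, 16 and
28, with a switch from normal chow to a high-fat diet (HFD) between weeks
15 and 16. The diet switch replaces most of the circulating virus pool and
shifts family composition (caudoviruses down, Microviridae and eukaryotic
viruses up), the temperate fraction (integrase content down), and genome
G+C upward.

Sharing model
-------------
Within a diet regime the community is layered: a regime-wide common pool
(drawn by every sample of that regime), one pool per group (drawn only by
that group's samples), and sample-private templates. Each sample includes
each pool template independently with a per-sample inclusion probability,
so realized pairwise sharing fluctuates around the targets the way real
pooled viromes do. Expected pairwise shared-template fraction equals
``sharing_within`` for same-group same-diet pairs, ``sharing_between`` for
different-group same-diet pairs, and 0 across the diet switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from viromeshare.model import Contig, Read, Virome

VIRUS_FAMILIES = (
    "Siphoviridae",
    "Myoviridae",
    "Podoviridae",
    "Microviridae",
    "Phycodnaviridae",
    "Mimiviridae",
)

PHAGE_FAMILIES = frozenset({"Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae"})

# Gene categories placed on phage templates besides the lifestyle markers.
_STRUCTURAL = ("capsid/head", "portal", "tail", "baseplate", "sheath", "collar")
_OTHER_CATEGORIES = ("replication", "transposition", "restriction/modification")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# --------------------------------------------------------------------------
# domain types


@dataclass
class VirusTemplate:
    """A virus genome template from which sample contigs are fragmented.

    Temperate templates carry >=1 "integrase" gene interval; lytic phage
    templates carry >=1 "lysin" interval and no integrase; non-phage
    (eukaryotic) templates carry neither. ``window`` is the sub-genomic
    interval realized as a contig in every sample that draws the template,
    so that two samples sharing a template emit homologous contigs.
    """

    id: str
    family: str
    lifestyle: str  # temperate | lytic | non-phage
    genome: str
    gc_target: float
    gene_layout: list[tuple[str, int, int]]
    window: tuple[int, int] = (0, 0)

    @property
    def window_categories(self) -> list[str]:
        """Gene categories overlapped by the realized contig window."""
        ws, we = self.window
        out = []
        for label, start, end in self.gene_layout:
            ov = min(we, end) - max(ws, start)
            if ov >= min(50, (end - start) // 2):
                out.append(label)
        return out


@dataclass
class DietEffect:
    """Per-diet shift parameters applied at the chow -> HFD transition."""

    family_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "normal": {
                "Siphoviridae": 0.35,
                "Myoviridae": 0.20,
                "Podoviridae": 0.15,
                "Microviridae": 0.20,
                "Phycodnaviridae": 0.05,
                "Mimiviridae": 0.05,
            },
            "HFD": {
                "Siphoviridae": 0.12,
                "Myoviridae": 0.10,
                "Podoviridae": 0.08,
                "Microviridae": 0.45,
                "Phycodnaviridae": 0.13,
                "Mimiviridae": 0.12,
            },
        }
    )
    temperate_fraction: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.8, "HFD": 0.2}
    )
    gc: dict[str, float] = field(default_factory=lambda: {"normal": 0.41, "HFD": 0.445})


@dataclass
class StudyDesign:
    """Layout and effect sizes of a synthetic virome study.

    One pooled sample is generated per group x week. ``sharing_within`` /
    ``sharing_between`` are the expected pairwise shared-template fractions
    for same-group and different-group pairs under the same diet.
    ``pool_inclusion`` is the mean per-sample probability of including each
    pool template; ``propensity_sd`` (default 0: identical propensities)
    optionally spreads that probability across samples to emulate the
    large pair-to-pair dispersion seen in real shared-homologue tables.
    """

    groups: tuple[str, ...] = ("CTL", "STAT", "CTL-COHO", "STAT-COHO")
    weeks: tuple[int, ...] = (4, 5, 15, 16, 28)
    diet_by_week: dict[int, str] = field(
        default_factory=lambda: {4: "normal", 5: "normal", 15: "normal", 16: "HFD", 28: "HFD"}
    )
    sharing_within: float = 0.7
    sharing_between: float = 0.4
    diet_effect: DietEffect = field(default_factory=DietEffect)
    n_viruses_per_sample: int = 250
    reads_per_sample: int = 20_000
    seed: int = 0
    mutation_rate: float = 0.005
    pool_inclusion: float = 0.80
    propensity_sd: float = 0.0
    genome_length: tuple[int, int] = (1500, 2600)
    window_length: int = 800
    abundance_shape: float = 0.93  # log-series parameter for read counts

    def __post_init__(self) -> None:
        missing = [w for w in self.weeks if w not in self.diet_by_week]
        if missing:
            raise ValueError(f"diet_by_week does not cover weeks {missing}")
        if self.sharing_between > self.sharing_within:
            raise ValueError(
                "sharing_within must be >= sharing_between "
                f"({self.sharing_within} < {self.sharing_between})"
            )

    @property
    def diets(self) -> tuple[str, ...]:
        seen: list[str] = []
        for w in self.weeks:
            d = self.diet_by_week[w]
            if d not in seen:
                seen.append(d)
        return tuple(seen)

    @property
    def samples(self) -> list[tuple[str, str, int, str]]:
        """(sample id, group, week, diet) for every pooled sample."""
        return [
            (f"{g}_w{w}", g, w, self.diet_by_week[w])
            for g in self.groups
            for w in self.weeks
        ]


@dataclass
class GroundTruth:
    """Realized per-sample truth recorded while generating a study."""

    template_ids: dict[str, frozenset[str]]
    family_reads: pd.DataFrame  # sample x family, read-weighted proportions
    family_contigs: pd.DataFrame  # sample x family, contig-count proportions
    lifestyle: pd.DataFrame  # sample x (n_contigs, n_integrase, n_lysin)
    gc: pd.Series  # per-sample realized G+C fraction
    shared: pd.DataFrame  # sample x sample true shared-template fraction

    def shared_templates(self, a: str, b: str) -> frozenset[str]:
        return self.template_ids[a] & self.template_ids[b]


# --------------------------------------------------------------------------
# template pool


def _random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    """Genome with an exact G+C count (round(gc * length) strong bases)."""
    n_gc = int(round(gc * length))
    arr = np.empty(length, dtype=np.uint8)
    strong = rng.integers(0, 2, size=n_gc)  # G or C
    weak = rng.integers(0, 2, size=length - n_gc)  # A or T
    pos = rng.permutation(length)
    arr[pos[:n_gc]] = np.where(strong == 0, ord("G"), ord("C"))
    arr[pos[n_gc:]] = np.where(weak == 0, ord("A"), ord("T"))
    return arr.tobytes().decode("ascii")


def _gene_layout(
    length: int, lifestyle: str, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Tile non-overlapping gene intervals over the genome.

    Exactly one lifestyle marker (integrase or lysin) is placed for phage
    templates; remaining slots are structural / replication-type genes.
    """
    layout: list[tuple[str, int, int]] = []
    pos = int(rng.integers(0, 40))
    genes: list[str] = []
    while pos + 200 < length:
        glen = int(rng.integers(250, 500))
        end = min(pos + glen, length)
        if end - pos >= 150:
            genes.append((pos, end))  # type: ignore[arg-type]
        pos = end + int(rng.integers(10, 40))
    labels = [
        (_STRUCTURAL + _OTHER_CATEGORIES)[int(rng.integers(0, len(_STRUCTURAL) + 3))]
        for _ in genes
    ]
    if lifestyle == "temperate":
        labels[int(rng.integers(0, len(labels)))] = "integrase"
    elif lifestyle == "lytic":
        labels[int(rng.integers(0, len(labels)))] = "lysin"
    for (start, end), label in zip(genes, labels):
        layout.append((label, start, end))
    return layout


def generate_virus_pool(
    n: int,
    family_mix: dict[str, float],
    temperate_fraction: float = 0.8,
    gc_target: float = 0.41,
    seed: int = 0,
    genome_length: tuple[int, int] = (1500, 2600),
    window_length: int = 800,
    id_prefix: str = "T",
    genomes: bool = True,
) -> list[VirusTemplate]:
    """Draw ``n`` virus templates from a family mixture.

    Families are assigned by a seeded multinomial draw from ``family_mix``;
    among phage templates, lifestyle is temperate with probability
    ``temperate_fraction`` and lytic otherwise (non-phage families are
    always ``non-phage``). Identical arguments reproduce the pool exactly.
    With ``genomes=False`` templates carry empty genome strings (lengths,
    gene layouts and windows are still realized) — for statistical studies
    that never touch bases.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    total = sum(family_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"family_mix fractions must sum to 1, got {total!r}")
    rng = np.random.default_rng(seed)
    families = list(family_mix)
    fam_draw = rng.choice(len(families), size=n, p=[family_mix[f] for f in families])
    pool: list[VirusTemplate] = []
    for i in range(n):
        family = families[int(fam_draw[i])]
        if family in PHAGE_FAMILIES:
            lifestyle = "temperate" if rng.random() < temperate_fraction else "lytic"
        else:
            lifestyle = "non-phage"
        length = int(rng.integers(genome_length[0], genome_length[1]))
        genome = _random_genome(length, gc_target, rng) if genomes else ""
        layout = _gene_layout(length, lifestyle, rng)
        wlen = min(window_length, length)
        ws = int(rng.integers(0, length - wlen + 1))
        pool.append(
            VirusTemplate(
                id=f"{id_prefix}{i:05d}",
                family=family,
                lifestyle=lifestyle,
                genome=genome,
                gc_target=gc_target,
                gene_layout=layout,
                window=(ws, ws + wlen),
            )
        )
    return pool


def build_study_pool(
    design: StudyDesign, margin: float = 1.4, genomes: bool = True
) -> dict[str, list[VirusTemplate]]:
    """Generate one template pool per diet regime, sized for the design."""
    pools: dict[str, list[VirusTemplate]] = {}
    for ri, regime in enumerate(design.diets):
        n_samples = sum(1 for _, _, _, d in design.samples if d == regime)
        # common + per-group pools + private fill, with headroom
        need = int(
            margin * design.n_viruses_per_sample * (1 + len(design.groups))
            + n_samples * design.n_viruses_per_sample * 0.5
        ) + 50
        pools[regime] = generate_virus_pool(
            need,
            design.diet_effect.family_mix[regime],
            temperate_fraction=design.diet_effect.temperate_fraction[regime],
            gc_target=design.diet_effect.gc[regime],
            seed=design.seed * 1000003 % (2**31) + 7919 * ri + 1,
            genome_length=design.genome_length,
            window_length=design.window_length,
            id_prefix=f"{regime[:1].upper()}{ri}_",
            genomes=genomes,
        )
    return pools


# --------------------------------------------------------------------------
# study generation


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases independently at ``rate`` (no indels)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    k = rng.binomial(len(arr), rate)
    if k:
        pos = rng.choice(len(arr), size=k, replace=False)
        # shift each chosen base by 1..3 within ACGT (never identity)
        idx = np.searchsorted(_BASES, arr[pos])
        arr[pos] = _BASES[(idx + rng.integers(1, 4, size=k)) % 4]
    return arr.tobytes().decode("ascii")


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / max(len(seq), 1)


def generate_study(
    design: StudyDesign,
    pool: dict[str, list[VirusTemplate]] | list[VirusTemplate] | None = None,
    sequences: bool = True,
) -> tuple[dict[str, Virome], GroundTruth, dict[str, list[VirusTemplate]]]:
    """Realize a full synthetic study from a template pool.

    Returns the viromes keyed by sample id, the recorded :class:`GroundTruth`
    and the per-regime pool actually used. With ``sequences=False`` contigs
    carry empty sequences (template identities, read counts and all ground
    truth are still realized) — sufficient for purely statistical studies
    and much faster.
    """
    if pool is None:
        pool = build_study_pool(design, genomes=sequences)
    if isinstance(pool, list):
        if len(design.diets) != 1:
            raise ValueError("flat template list requires a single-diet design")
        pool = {design.diets[0]: pool}

    rng = np.random.default_rng(design.seed)
    n = design.n_viruses_per_sample
    s_w, s_b = design.sharing_within, design.sharing_between
    rho = max(design.pool_inclusion, s_w)
    if s_w >= 0.999:
        rho = 1.0

    m_common = int(round(s_b * n / rho**2))
    m_group = int(round((s_w - s_b) * n / rho**2))

    # partition each regime pool into common / per-group / private supplies
    alloc: dict[str, dict[str, list[VirusTemplate]]] = {}
    private_iter: dict[str, iter] = {}
    for regime, templates in pool.items():
        need = m_common + m_group * len(design.groups)
        if need > len(templates):
            raise ValueError(
                f"pool exhaustion for regime {regime!r}: need >= {need} "
                f"templates for shared pools, have {len(templates)}"
            )
        a: dict[str, list[VirusTemplate]] = {"__common__": templates[:m_common]}
        off = m_common
        for g in design.groups:
            a[g] = templates[off : off + m_group]
            off += m_group
        alloc[regime] = a
        private_iter[regime] = iter(templates[off:])

    sd = min(design.propensity_sd, 0.9 * math.sqrt(rho * (1 - rho))) if rho < 1 else 0.0

    viromes: dict[str, Virome] = {}
    draws: dict[str, list[VirusTemplate]] = {}
    for sample, group, week, diet in design.samples:
        if sd > 0:
            kappa = rho * (1 - rho) / sd**2 - 1
            rho_i = float(rng.beta(rho * kappa, (1 - rho) * kappa))
        else:
            rho_i = rho
        chosen: list[VirusTemplate] = []
        for t in alloc[diet]["__common__"] + alloc[diet][group]:
            if rho_i >= 1.0 or rng.random() < rho_i:
                chosen.append(t)
        if len(chosen) > n:
            keep = rng.choice(len(chosen), size=n, replace=False)
            chosen = [chosen[int(i)] for i in sorted(keep)]
        supply = private_iter[diet]
        while len(chosen) < n:
            try:
                chosen.append(next(supply))
            except StopIteration:
                raise ValueError(
                    f"pool exhaustion for regime {diet!r}: sample {sample} needs "
                    f"{n} templates, private supply ran out"
                ) from None
        draws[sample] = chosen

    truth_rows: dict[str, dict] = {}
    fam_reads: dict[str, dict[str, float]] = {}
    fam_contigs: dict[str, dict[str, float]] = {}
    gc_truth: dict[str, float] = {}
    for sample, group, week, diet in design.samples:
        chosen = draws[sample]
        weights = stats.logser.rvs(design.abundance_shape, size=n, random_state=rng)
        counts = rng.multinomial(design.reads_per_sample, weights / weights.sum())
        counts = np.maximum(counts, 1)  # every assembled contig has >=1 read
        contigs: list[Contig] = []
        n_int = n_lys = 0
        gc_num = gc_den = 0
        fr: dict[str, float] = {f: 0.0 for f in VIRUS_FAMILIES}
        fc: dict[str, float] = {f: 0.0 for f in VIRUS_FAMILIES}
        for k, t in enumerate(chosen):
            ws, we = t.window
            if sequences:
                if not t.genome:
                    raise ValueError(
                        f"template {t.id} has no genome; rebuild the pool with genomes=True"
                    )
                seq = _mutate(t.genome[ws:we], design.mutation_rate, rng)
                gc_num += seq.count("G") + seq.count("C")
                gc_den += len(seq)
            else:
                seq = ""
            cats = t.window_categories
            n_int += "integrase" in cats
            n_lys += "lysin" in cats
            fr[t.family] = fr.get(t.family, 0.0) + counts[k]
            fc[t.family] = fc.get(t.family, 0.0) + 1
            contigs.append(
                Contig(
                    id=f"{sample}.c{k:04d}",
                    sequence=seq,
                    read_count=int(counts[k]),
                    template_id=t.id,
                )
            )
        total_reads = float(sum(c.read_count for c in contigs))
        fam_reads[sample] = {f: v / total_reads for f, v in fr.items()}
        fam_contigs[sample] = {f: v / len(contigs) for f, v in fc.items()}
        gc_truth[sample] = gc_num / gc_den if gc_den else design.diet_effect.gc[diet]
        truth_rows[sample] = {
            "n_contigs": len(contigs),
            "n_integrase": n_int,
            "n_lysin": n_lys,
        }
        viromes[sample] = Virome(sample=sample, contigs=contigs, group=group, week=week, diet=diet)

    ids = [s for s, *_ in design.samples]
    tsets = {s: frozenset(t.id for t in draws[s]) for s in ids}
    shared = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        for b in ids:
            if a != b:
                shared.loc[a, b] = len(tsets[a] & tsets[b]) / len(tsets[a])

    truth = GroundTruth(
        template_ids=tsets,
        family_reads=pd.DataFrame(fam_reads).T.loc[ids].fillna(0.0),
        family_contigs=pd.DataFrame(fam_contigs).T.loc[ids].fillna(0.0),
        lifestyle=pd.DataFrame(truth_rows).T.loc[ids],
        gc=pd.Series(gc_truth).loc[ids],
        shared=shared,
    )
    return viromes, truth, pool


def shared_template_predicate(truth: GroundTruth):
    """Ground-truth shared-contig predicate for the overlap test.

    Returns ``f(virome_a, virome_b) -> bool array`` over a's contigs, true
    where the contig's template is also present in b — exactly what a
    cross-virome homology search recovers at low mutation rates.
    """

    def incidence(a: Virome, b: Virome) -> np.ndarray:
        tb = truth.template_ids[b.sample]
        return np.fromiter(
            (c.template_id in tb for c in a.contigs), dtype=bool, count=len(a.contigs)
        )

    return incidence


# --------------------------------------------------------------------------
# reads and annotation fixtures


def emit_reads(
    virome: Virome,
    seed: int = 0,
    mean_length: int = 216,
    sd_length: int = 30,
    min_length: int = 150,
    max_length: int = 300,
    quality: int = 30,
) -> list[Read]:
    """Fragment each contig into its ``read_count`` reads.

    Read lengths follow a clipped normal (defaults give a mean close to the
    post-QC read length of Ion Torrent viromes); starts are uniform over
    the contig. Qualities are flat Phred ``quality`` scores.
    """
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for contig in virome.contigs:
        if not contig.sequence:
            raise ValueError(f"contig {contig.id} has no sequence; emit with sequences=True")
        clen = len(contig.sequence)
        for j in range(contig.read_count):
            rl = int(np.clip(rng.normal(mean_length, sd_length), min_length, min(max_length, clen)))
            start = int(rng.integers(0, clen - rl + 1))
            seq = contig.sequence[start : start + rl]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(Read(id=f"{contig.id}.r{j}", sequence=seq, qualities=[quality] * rl))
    return reads


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# canonical subject descriptions per gene category (keyword taxonomy bait)
_CATEGORY_DESCRIPTIONS = {
    "capsid/head": "major capsid protein",
    "portal": "portal protein",
    "tail": "tail fiber protein",
    "baseplate": "baseplate assembly protein",
    "sheath": "tail sheath protein",
    "collar": "upper collar protein",
    "integrase": "phage integrase",
    "lysin": "endolysin",
    "replication": "DNA replication protein",
    "transposition": "transposase",
    "restriction/modification": "type II restriction endonuclease",
}

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "stitle",
]


def emit_annotation_fixture(
    viromes: dict[str, Virome],
    pool: dict[str, list[VirusTemplate]] | list[VirusTemplate],
    noise: float = 0.0,
    seed: int = 0,
    bacterial_fraction: float = 0.0,
    unannotated_fraction: float = 0.0,
) -> pd.DataFrame:
    """Ranked protein-style hits per contig, standing in for a translated
    search against an external protein database.

    For every gene interval a contig covers, a hit is emitted whose subject
    description carries the true gene-category keyword and the true family
    label (bracketed organism) with probability ``1 - noise``; corrupted
    hits become "hypothetical protein" decoys. True functional hits draw
    E-values well past the family (1e-20) and functional (1e-5) cutoffs.
    A fraction of contigs can be made bacterial-looking or hit-less to
    exercise superkingdom profiling.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError(f"noise must be in [0, 1), got {noise}")
    if isinstance(pool, dict):
        templates = {t.id: t for ts in pool.values() for t in ts}
    else:
        templates = {t.id: t for t in pool}
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for sample in sorted(viromes):
        for contig in viromes[sample].contigs:
            if contig.template_id is None or contig.template_id not in templates:
                continue
            r = rng.random()
            if r < unannotated_fraction:
                continue
            t = templates[contig.template_id]
            clen = len(contig.sequence) or (t.window[1] - t.window[0])
            if r < unannotated_fraction + bacterial_fraction:
                e = 10.0 ** -rng.uniform(21, 40)
                rows.append(
                    _hit_row(contig.id, "decoy_bact", clen, e, "hypothetical protein [Bacteria]", rng)
                )
                continue
            ws, we = t.window
            for label, gs, ge in t.gene_layout:
                ov = min(we, ge) - max(ws, gs)
                if ov < min(50, (ge - gs) // 2):
                    continue
                if rng.random() < noise:
                    desc = "hypothetical protein"
                    e = 10.0 ** -rng.uniform(6, 24)
                else:
                    desc = f"{_CATEGORY_DESCRIPTIONS[label]} [{t.family}]"
                    e = 10.0 ** -rng.uniform(25, 60)
                rows.append(_hit_row(contig.id, f"{t.id}_{label}", ov, e, desc, rng))
            # decoy below the true hits
            e = 10.0 ** -rng.uniform(6, 20)
            rows.append(_hit_row(contig.id, "decoy_hyp", clen // 3, e, "hypothetical protein", rng))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(["qseqid", "evalue"], kind="mergesort").reset_index(drop=True)


def _hit_row(qid: str, sid: str, span: int, evalue: float, desc: str, rng: np.random.Generator):
    aln = max(span // 3, 20)
    pident = float(np.round(rng.uniform(35, 95), 1))
    mism = int(aln * (1 - pident / 100))
    bits = float(np.round(-math.log10(evalue) * 2.2 + 28, 1))
    return (qid, sid, pident, aln, mism, 0, 1, span, 1, aln, evalue, bits, desc)


# --------------------------------------------------------------------------
# on-disk study


def write_study(
    outdir: str | Path,
    viromes: dict[str, Virome],
    truth: GroundTruth,
    hits: pd.DataFrame | None = None,
) -> None:
    """Write a study as plain-text files.

    Per-sample contig FASTA (headers encode sample, template id and read
    count), a tab-separated metadata table, ground-truth tables, and
    optionally the annotation hit table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for sample in sorted(viromes):
        v = viromes[sample]
        meta.append({"sample": v.sample, "group": v.group, "week": v.week, "diet": v.diet})
        with open(outdir / f"{sample}.contigs.fasta", "w") as fh:
            for c in v.contigs:
                fh.write(
                    f">{c.id} sample={sample} template={c.template_id} reads={c.read_count}\n"
                )
                for i in range(0, len(c.sequence), 80):
                    fh.write(c.sequence[i : i + 80] + "\n")
    pd.DataFrame(meta).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth.shared.to_csv(outdir / "truth_shared.tsv", sep="\t")
    truth.family_reads.to_csv(outdir / "truth_family_reads.tsv", sep="\t")
    truth.lifestyle.to_csv(outdir / "truth_lifestyle.tsv", sep="\t")
    truth.gc.rename("gc").to_csv(outdir / "truth_gc.tsv", sep="\t")
    if hits is not None:
        hits.to_csv(outdir / "annotation_hits.tsv", sep="\t", index=False, header=False)
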