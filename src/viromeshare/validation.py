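"""Synthetic-recovery benchmark suites.

Each function generates synthetic studies with known ground truth, runs
the relevant part of the pipeline on them, and returns the measured
operating characteristics: type-I error and power of the overlap
permutation test, shared-fraction recovery through the homology engine,
diet-signal recovery through Jaccard/PCoA/PERMANOVA, integrase/lysin
lifestyle-shift recovery, and G+C recovery. Problem sizes default to
desk scale (minutes on one core); every function takes a seed and is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from viromeshare import synthetic_data as syn
from viromeshare.annotation_profiles import (
    KeywordTaxonomy,
    annotate_virome,
    family_profile,
    lifestyle_stats,
)
from viromeshare.community_metrics import gc_content, jaccard_matrix
from viromeshare.homology import build_index, cross_compare, shared_fraction
from viromeshare.ordination_stats import PermanovaResult, pcoa, permanova, ttest2
from viromeshare.overlap_permutation import (
    GroupingScheme,
    incidence_from_predicate,
    overlap_test,
)


def _overlap_pvalues(
    sharing_within: float,
    sharing_between: float,
    groups: tuple[str, ...],
    weeks: tuple[int, ...],
    n_studies: int,
    seed: int,
    n_iter: int = 1000,
    n_contigs: int = 100,
) -> np.ndarray:
    """P-values of the overlap test over independent synthetic studies
    (one pooled row list per study, all group rows collected)."""
    ps: list[float] = []
    for s in range(n_studies):
        design = syn.StudyDesign(
            groups=groups,
            weeks=weeks,
            diet_by_week={w: "normal" for w in weeks},
            sharing_within=sharing_within,
            sharing_between=sharing_between,
            seed=seed + s,
        )
        viromes, truth, _ = syn.generate_study(design, sequences=False)
        incidence = incidence_from_predicate(viromes, syn.shared_template_predicate(truth))
        scheme = GroupingScheme("group", {v.sample: v.group for v in viromes.values()})
        results = overlap_test(
            viromes, incidence, scheme, n_iter=n_iter, n_contigs=n_contigs, seed=seed + s
        )
        ps.extend(r.p_value for r in results)
    return np.asarray(ps)


def overlap_type_i_error(n_studies: int = 200, seed: int = 1) -> dict:
    """Null calibration: equal within/between sharing (0.5), 2 groups of 4
    pooled samples, 1,000 iterations over 100 sampled contigs."""
    ps = _overlap_pvalues(0.5, 0.5, ("G1", "G2"), (1, 2, 3, 4), n_studies, seed)
    return {
        "fraction_significant": float((ps < 0.05).mean()),
        "n_tests": len(ps),
        "p_values": ps,
    }


def overlap_power(n_studies: int = 100, seed: int = 1) -> dict:
    """Power at the normal-chow regime: within 0.7 vs between 0.4 sharing,
    2 groups of 5 pooled samples."""
    ps = _overlap_pvalues(0.7, 0.4, ("G1", "G2"), (1, 2, 3, 4, 5), n_studies, seed)
    return {
        "fraction_significant": float((ps < 0.05).mean()),
        "n_tests": len(ps),
        "p_values": ps,
    }


def shared_fraction_recovery(
    n_replicates: int = 50, target: float = 0.30, seed: int = 1
) -> dict:
    """Homology-engine recovery of a known 30% template overlap between
    virome pairs diverged at the default per-base substitution rate."""
    estimates, truths = [], []
    for rep in range(n_replicates):
        design = syn.StudyDesign(
            groups=("G",),
            weeks=(1, 2),
            diet_by_week={1: "normal", 2: "normal"},
            sharing_within=target,
            sharing_between=target,
            n_viruses_per_sample=100,
            seed=seed + rep,
        )
        viromes, truth, _ = syn.generate_study(design)
        a, b = viromes["G_w1"], viromes["G_w2"]
        index = build_index(b.contigs)
        ss = shared_fraction(a, index, subject_virome=b.sample)
        estimates.append(ss.shared_fraction)
        truths.append(float(truth.shared.loc["G_w1", "G_w2"]))
    return {
        "mean_estimate": float(np.mean(estimates)),
        "mean_truth": float(np.mean(truths)),
        "target": target,
        "n_replicates": n_replicates,
    }


@dataclass
class DietSignalResult:
    permanova: PermanovaResult
    r2_diet: float
    r2_time: float
    p_diet: float
    n_samples: int
    pcoa_variance_axis1: float = 0.0


def diet_signal_recovery(n_viruses: int = 40, seed: int = 1) -> DietSignalResult:
    """Full default study (4 groups x 5 weeks, diet switch after week 15):
    contig sequences, all-pairs homology, Jaccard distances, PCoA, and a
    sequential two-factor PERMANOVA (~ diet * time)."""
    design = syn.StudyDesign(n_viruses_per_sample=n_viruses, seed=seed)
    viromes, _, _ = syn.generate_study(design)
    shared = cross_compare(viromes)
    d = jaccard_matrix(viromes, shared)
    ordn = pcoa(d)
    diet = [viromes[s].diet for s in d.ids]
    time = [str(viromes[s].week) for s in d.ids]
    res = permanova(d, {"diet": diet, "time": time}, n_perm=999, seed=seed)
    return DietSignalResult(
        permanova=res,
        r2_diet=res.r_squared["diet"],
        r2_time=res.r_squared["time"],
        p_diet=res.p_values["diet"],
        n_samples=len(d.ids),
        pcoa_variance_axis1=float(ordn.proportion_explained[0]) if len(ordn.proportion_explained) else 0.0,
    )


@dataclass
class LifestyleShiftResult:
    mean_pct_integrase_normal: float
    mean_pct_integrase_hfd: float
    t_integrase: float
    p_integrase: float
    mean_ratio_normal: float
    mean_ratio_hfd: float
    t_ratio: float
    p_ratio: float
    per_sample: dict = field(default_factory=dict)


def lifestyle_shift_recovery(n_viruses: int = 120, seed: int = 1) -> LifestyleShiftResult:
    """Integrase decline across the diet switch (temperate fraction 0.8 ->
    0.2 by default), recovered through annotation fixtures and the
    lifestyle statistics, tested with the module's own Welch t test."""
    design = syn.StudyDesign(n_viruses_per_sample=n_viruses, seed=seed)
    viromes, _, pool = syn.generate_study(design, sequences=False)
    hits = syn.emit_annotation_fixture(viromes, pool, noise=0.0, seed=seed)
    taxonomy = KeywordTaxonomy.default()
    pct_int: dict[str, list[float]] = {"normal": [], "HFD": []}
    ratios: dict[str, list[float]] = {"normal": [], "HFD": []}
    per_sample = {}
    for s, v in viromes.items():
        annots = annotate_virome(v, hits[hits.qseqid.str.startswith(s)], taxonomy)
        st = lifestyle_stats(annots)
        pct_int[v.diet].append(st.pct_integrase)
        if st.ratio is not None:
            ratios[v.diet].append(st.ratio)
        per_sample[s] = {"diet": v.diet, "pct_integrase": st.pct_integrase, "ratio": st.ratio}
    t_i, p_i = ttest2(pct_int["normal"], pct_int["HFD"])
    t_r, p_r = ttest2(ratios["normal"], ratios["HFD"])
    return LifestyleShiftResult(
        mean_pct_integrase_normal=float(np.mean(pct_int["normal"])),
        mean_pct_integrase_hfd=float(np.mean(pct_int["HFD"])),
        t_integrase=t_i,
        p_integrase=p_i,
        mean_ratio_normal=float(np.mean(ratios["normal"])),
        mean_ratio_hfd=float(np.mean(ratios["HFD"])),
        t_ratio=t_r,
        p_ratio=p_r,
        per_sample=per_sample,
    )


def gc_shift_recovery(n_viruses: int = 30, seed: int = 1) -> dict:
    """G+C recovery across the diet switch: normal-chow pool at 41% G+C,
    high-fat pool at 44.5%; per-sample contig G+C and a two-tailed t test."""
    design = syn.StudyDesign(
        weeks=(4, 5, 15, 16, 28),
        n_viruses_per_sample=n_viruses,
        seed=seed,
    )
    viromes, _, _ = syn.generate_study(design)
    gc_by_diet: dict[str, list[float]] = {"normal": [], "HFD": []}
    for v in viromes.values():
        gc_by_diet[v.diet].append(gc_content([c.sequence for c in v.contigs]))
    t, p = ttest2(gc_by_diet["normal"], gc_by_diet["HFD"])
    return {
        "mean_gc_normal": float(np.mean(gc_by_diet["normal"])),
        "mean_gc_hfd": float(np.mean(gc_by_diet["HFD"])),
        "target_normal": 100 * 0.41,
        "target_hfd": 100 * 0.445,
        "t": t,
        "p": p,
    }


def family_shift_summary(n_viruses: int = 120, seed: int = 1) -> dict:
    """Read-weighted family profiles pooled by diet: caudovirus share falls
    and Microviridae rises across the switch (companion to the family
    ground-truth checks)."""
    design = syn.StudyDesign(n_viruses_per_sample=n_viruses, seed=seed)
    viromes, _, pool = syn.generate_study(design, sequences=False)
    hits = syn.emit_annotation_fixture(viromes, pool, noise=0.0, seed=seed)
    taxonomy = KeywordTaxonomy.default()
    out: dict[str, dict[str, list[float]]] = {"normal": {}, "HFD": {}}
    for s, v in viromes.items():
        annots = annotate_virome(v, hits[hits.qseqid.str.startswith(s)], taxonomy)
        prof = family_profile(annots, mode="reads", sample=s)
        for fam, pct in prof.percentages.items():
            out[v.diet].setdefault(fam, []).append(pct)
    return {
        diet: {fam: float(np.mean(v)) for fam, v in fams.items()}
        for diet, fams in out.items()
    }
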