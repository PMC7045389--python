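"""Keyword categorization, family/superkingdom profiles, lifestyle stats."""

import numpy as np
import pandas as pd
import pytest

from viromeshare import synthetic_data as syn
from viromeshare.annotation_profiles import (
    AnnotationRecord,
    KeywordTaxonomy,
    annotate_virome,
    categorize_contig,
    family_profile,
    family_profiles,
    lifestyle_stats,
    superkingdom_fractions,
)
from viromeshare.model import Contig, Virome
from viromeshare.synthetic_data import HIT_COLUMNS


def _hits(rows):
    """rows: list of (evalue, description)."""
    return pd.DataFrame(
        [
            ("q", f"s{i}", 90.0, 100, 5, 0, 1, 100, 1, 100, e, 200.0, d)
            for i, (e, d) in enumerate(rows)
        ],
        columns=HIT_COLUMNS,
    )


@pytest.fixture(scope="module")
def taxonomy():
    return KeywordTaxonomy.default()


class TestCategorize:
    def test_best_hit_integrase(self, taxonomy):
        assert categorize_contig(_hits([(1e-30, "phage integrase [Siphoviridae]")]), taxonomy) == "integrase"

    def test_fallback_past_hypothetical_best_hit(self, taxonomy):
        hits = _hits(
            [(1e-40, "hypothetical protein"), (1e-8, "tail fiber protein [Myoviridae]")]
        )
        assert categorize_contig(hits, taxonomy) == "tail"

    def test_threshold_edge_none(self, taxonomy):
        assert categorize_contig(_hits([(1e-4, "tail protein")]), taxonomy) == "none"

    def test_only_hypothetical_passing(self, taxonomy):
        assert categorize_contig(_hits([(1e-12, "hypothetical protein")]), taxonomy) == "hypothetical"

    def test_holin_not_a_lysin(self, taxonomy):
        assert categorize_contig(_hits([(1e-30, "phage holin [Siphoviridae]")]), taxonomy) == "holin"

    def test_unsorted_input_sorted_internally(self, taxonomy):
        hits = _hits(
            [(1e-8, "tail fiber protein"), (1e-30, "portal protein [Siphoviridae]")]
        )
        shuffled = hits.iloc[[0, 1]]
        assert categorize_contig(shuffled, taxonomy) == "portal"

    def test_row_order_invariance(self, taxonomy, rng):
        rows = [
            (1e-25, "phage integrase [Siphoviridae]"),
            (1e-15, "major capsid protein [Myoviridae]"),
            (1e-9, "hypothetical protein"),
            (1e-6, "endolysin [Podoviridae]"),
        ]
        base = categorize_contig(_hits(rows), taxonomy)
        for _ in range(5):
            perm = list(rng.permutation(len(rows)))
            assert categorize_contig(_hits([rows[i] for i in perm]), taxonomy) == base


class TestFamilyAssignment:
    def test_family_needs_1e20(self, taxonomy):
        v = Virome(sample="s", contigs=[Contig(id="q", sequence="", read_count=3)])
        weak = _hits([(1e-12, "major capsid protein [Siphoviridae]")])
        rec = annotate_virome(v, weak, taxonomy)[0]
        assert rec.functional_category == "capsid/head"
        assert rec.family == "unassigned"
        strong = _hits([(1e-25, "major capsid protein [Siphoviridae]")])
        rec = annotate_virome(v, strong, taxonomy)[0]
        assert rec.family == "Siphoviridae"

    def test_contig_without_hits_is_none(self, taxonomy):
        v = Virome(sample="s", contigs=[Contig(id="q", sequence="", read_count=3)])
        rec = annotate_virome(v, _hits([]).iloc[0:0], taxonomy)[0]
        assert rec.functional_category == "none"
        assert rec.superkingdom == "none"


class TestProfiles:
    def _two_contig_annots(self):
        return [
            AnnotationRecord("c1", "capsid/head", "Siphoviridae", "virus", read_count=90),
            AnnotationRecord("c2", "replication", "Microviridae", "virus", read_count=10),
        ]

    def test_read_weighted(self):
        prof = family_profile(self._two_contig_annots(), mode="reads")
        assert prof.percentages["Siphoviridae"] == pytest.approx(90.0)
        assert prof.percentages["Microviridae"] == pytest.approx(10.0)

    def test_contig_weighted(self):
        prof = family_profile(self._two_contig_annots(), mode="contigs")
        assert prof.percentages["Siphoviridae"] == pytest.approx(50.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            family_profile(self._two_contig_annots(), mode="bogus")

    def test_modes_coincide_for_equal_read_counts(self):
        annots = [
            AnnotationRecord(f"c{i}", "tail", fam, "virus", read_count=7)
            for i, fam in enumerate(["Siphoviridae", "Myoviridae", "Siphoviridae"])
        ]
        by_reads = family_profile(annots, mode="reads").percentages
        by_contigs = family_profile(annots, mode="contigs").percentages
        assert by_reads == pytest.approx(by_contigs)

    def test_depth_normalized_uses_study_floor(self):
        per_sample = {
            "deep": [
                AnnotationRecord("d1", "tail", "Siphoviridae", "virus", read_count=900),
                AnnotationRecord("d2", "tail", "Microviridae", "virus", read_count=100),
            ],
            "shallow": [
                AnnotationRecord("s1", "tail", "Siphoviridae", "virus", read_count=50),
                AnnotationRecord("s2", "tail", "Microviridae", "virus", read_count=50),
            ],
        }
        profs = family_profiles(per_sample, mode="depth-normalized")
        # floor is 100; deep sample's contigs rescale to 90/10
        assert profs["deep"].percentages["Siphoviridae"] == pytest.approx(90.0)
        assert profs["shallow"].percentages["Siphoviridae"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        prof = family_profile(self._two_contig_annots(), mode="reads")
        assert sum(prof.percentages.values()) == pytest.approx(100.0, abs=1e-9)


class TestLifestyle:
    def _annots(self, n_int, n_lys, n_other):
        recs = []
        for i in range(n_int):
            recs.append(
                AnnotationRecord(f"i{i}", "integrase", "Siphoviridae", "virus",
                                 categories_present=frozenset({"integrase"}))
            )
        for i in range(n_lys):
            recs.append(
                AnnotationRecord(f"l{i}", "lysin", "Myoviridae", "virus",
                                 categories_present=frozenset({"lysin"}))
            )
        for i in range(n_other):
            recs.append(
                AnnotationRecord(f"o{i}", "tail", "Podoviridae", "virus",
                                 categories_present=frozenset({"tail"}))
            )
        return recs

    def test_counts_and_ratio(self):
        st = lifestyle_stats(self._annots(10, 5, 85))
        assert (st.pct_integrase, st.pct_lysin, st.ratio) == (10.0, 5.0, 2.0)

    def test_zero_integrase(self):
        st = lifestyle_stats(self._annots(0, 5, 95))
        assert (st.pct_integrase, st.pct_lysin, st.ratio) == (0.0, 5.0, 0.0)

    def test_zero_lysin_ratio_undefined(self):
        st = lifestyle_stats(self._annots(3, 0, 97))
        assert st.ratio is None and not st.ratio_defined

    def test_no_annotated_rejected(self):
        with pytest.raises(ValueError):
            lifestyle_stats([AnnotationRecord("x", "none", "unassigned", "none")])


class TestSuperkingdom:
    def test_all_virus(self):
        annots = [AnnotationRecord("a", "tail", "Siphoviridae", "virus", read_count=5)]
        assert superkingdom_fractions(annots)["virus"] == 100.0

    def test_read_weighted_split(self):
        annots = [
            AnnotationRecord("a", "tail", "Siphoviridae", "virus", read_count=80),
            AnnotationRecord("b", "hypothetical", "unassigned", "bacterium", read_count=15),
            AnnotationRecord("c", "none", "unassigned", "none", read_count=5),
        ]
        frac = superkingdom_fractions(annots)
        assert frac == {"virus": 80.0, "bacterium": 15.0, "none": 5.0}


class TestSyntheticRecovery:
    def test_noise_free_profiles_match_ground_truth(self, small_study, taxonomy):
        viromes, truth, pool = small_study
        hits = syn.emit_annotation_fixture(viromes, pool, noise=0.0, seed=4)
        sample = next(iter(viromes))
        annots = annotate_virome(viromes[sample], hits[hits.qseqid.str.startswith(sample)], taxonomy)
        prof = family_profile(annots, mode="reads", sample=sample)
        for fam, expected in truth.family_reads.loc[sample].items():
            if expected > 0:
                assert prof.percentages.get(fam, 0.0) == pytest.approx(100 * expected, abs=0.5)

    def test_lifestyle_matches_ground_truth_counts(self, small_study, taxonomy):
        viromes, truth, pool = small_study
        hits = syn.emit_annotation_fixture(viromes, pool, noise=0.0, seed=4)
        for sample in viromes:
            annots = annotate_virome(
                viromes[sample], hits[hits.qseqid.str.startswith(sample)], taxonomy
            )
            n_int = sum("integrase" in a.categories_present for a in annots)
            n_lys = sum("lysin" in a.categories_present for a in annots)
            assert n_int == truth.lifestyle.loc[sample, "n_integrase"]
            assert n_lys == truth.lifestyle.loc[sample, "n_lysin"]

    def test_planted_bacterial_fraction_recovered(self, small_study, taxonomy):
        viromes, _, pool = small_study
        hits = syn.emit_annotation_fixture(
            viromes, pool, noise=0.0, seed=9, bacterial_fraction=0.15
        )
        per_sample = {
            s: annotate_virome(v, hits[hits.qseqid.str.startswith(s)], taxonomy)
            for s, v in viromes.items()
        }
        all_annots = [a for annots in per_sample.values() for a in annots]
        frac = superkingdom_fractions(all_annots)
        # contigs are marked bacterial independently of read count, so the
        # read-weighted share fluctuates around 15%
        assert frac["bacterium"] == pytest.approx(15.0, abs=6.0)
        assert frac["virus"] > 70.0

    def test_integrase_correlates_with_siphoviridae(self, taxonomy):
        """Samples built with more Siphoviridae (temperate-rich) carry more
        integrase homologues: positive correlation, as in phage communities
        dominated by lysogeny-capable tailed phages."""
        rng = np.random.default_rng(12)
        pct_sipho, pct_int = [], []
        for i in range(12):
            sipho = 0.2 + 0.6 * i / 11
            design = syn.StudyDesign(
                groups=("G",),
                weeks=(1, 2),
                diet_by_week={1: "normal", 2: "normal"},
                n_viruses_per_sample=80,
                seed=300 + i,
            )
            design.diet_effect.family_mix["normal"] = {
                "Siphoviridae": sipho,
                "Microviridae": 1 - sipho,
            }
            # temperate fraction rises with the Siphoviridae share
            design.diet_effect.temperate_fraction["normal"] = sipho
            viromes, truth, pool = syn.generate_study(design, sequences=False)
            hits = syn.emit_annotation_fixture(viromes, pool, noise=0.0, seed=300 + i)
            for s, v in viromes.items():
                annots = annotate_virome(v, hits[hits.qseqid.str.startswith(s)], taxonomy)
                st = lifestyle_stats(annots)
                prof = family_profile(annots, mode="reads", sample=s)
                pct_sipho.append(prof.percentages.get("Siphoviridae", 0.0))
                pct_int.append(st.pct_integrase)
        from viromeshare.ordination_stats import pearson

        r, p = pearson(pct_sipho, pct_int)
        assert r > 0.5 and p < 0.01
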