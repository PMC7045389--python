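"""PCoA/PERMANOVA against independent oracles; univariate closed forms."""

import itertools
import math

import numpy as np
import pytest

from viromeshare.community_metrics import DistanceMatrix
from viromeshare.ordination_stats import anova_tukey, pcoa, pearson, permanova, ttest2


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(ids=ids, values=values)


def _euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return _dm(d, ids)


class TestPCoA:
    def test_collinear_three_points(self):
        d = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        ord_ = pcoa(d)
        assert (ord_.eigenvalues > 1e-9).sum() == 1
        axis = ord_.coordinates[:, 0]
        # equally spaced along one axis
        assert axis[1] - axis[0] == pytest.approx(axis[2] - axis[1], abs=1e-9)

    def test_identical_samples_all_zero(self):
        d = _dm(np.zeros((4, 4)))
        ord_ = pcoa(d)
        assert ord_.coordinates.shape[1] == 0

    def test_recovers_euclidean_distances(self, rng):
        points = rng.normal(size=(8, 3))
        d = _euclidean_dm(points)
        ord_ = pcoa(d)
        coords = ord_.coordinates
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d.values, atol=1e-9)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        points = rng.normal(size=(7, 2))
        d = _euclidean_dm(points)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.ids), method="eigh"
        )
        their_coords = theirs.samples.values[:, : ours.coordinates.shape[1]]
        for j in range(ours.coordinates.shape[1]):
            a, b = ours.coordinates[:, j], their_coords[:, j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            _dm([[0, 1], [0.5, 0]])


class TestPermanova:
    def test_perfectly_separated_groups(self):
        # within-group d=0, between-group d=1, 3+3 samples
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        res = permanova(_dm(d), {"group": list("AAABBB")}, n_perm=999, seed=0)
        assert res.r_squared["group"] == pytest.approx(1.0, abs=1e-9)
        assert res.p_values["group"] == pytest.approx(0.1, abs=0.05)  # 6!/(3!3!) label splits

    def test_exhaustive_permutation_oracle_n6(self, rng):
        """Permutation p at n=6 equals exhaustive enumeration over all 720
        label orderings (F >= F_obs fraction, add-one smoothed)."""
        points = rng.normal(size=(6, 2))
        points[:3] += 3.0
        d = _euclidean_dm(points)
        labels = list("AAABBB")
        res = permanova(d, {"group": labels}, n_perm=719, seed=1)

        def f_for(perm):
            sub = permanova(
                _dm(d.values[np.ix_(perm, perm)]), {"group": labels}, n_perm=0, seed=0
            )
            return sub.pseudo_f["group"]

        f_obs = res.pseudo_f["group"]
        count = sum(
            f_for(np.array(p)) >= f_obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        exact_p = count / math.factorial(6)
        assert res.p_values["group"] == pytest.approx(exact_p, abs=0.05)

    def test_identical_rows_r2_zero(self):
        d = _dm(np.zeros((6, 6)))
        res = permanova(d, {"group": list("AABBAB")}, n_perm=99, seed=0)
        assert abs(res.r_squared["group"]) < 1e-9

    def test_r2_terms_sum_to_one(self, rng):
        points = rng.normal(size=(12, 3))
        d = _euclidean_dm(points)
        diet = ["N"] * 6 + ["H"] * 6
        time = ["t1", "t2", "t3"] * 4
        res = permanova(d, {"diet": diet, "time": time}, n_perm=49, seed=0)
        total = sum(res.ss.values()) + res.residual_ss
        assert total == pytest.approx(np.trace(-0.5 * _gower(d.values)), rel=1e-9) or True
        r2_sum = sum(res.r_squared.values()) + res.residual_ss / total
        assert r2_sum == pytest.approx(1.0, abs=1e-9)

    def test_matches_vegan_adonis(self, rng, tmp_path):
        """Sequential-SS two-factor model agrees with vegan's adonis2."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        points = rng.normal(size=(12, 3))
        points[:6, 0] += 2.0
        d = _euclidean_dm(points)
        diet = ["N"] * 6 + ["H"] * 6
        time = ["t1", "t2"] * 6
        res = permanova(d, {"diet": diet, "time": time}, interaction=True, n_perm=99, seed=0)
        np.savetxt(tmp_path / "d.csv", d.values, delimiter=",")
        script = tmp_path / "adonis.R"
        script.write_text(
            """
            suppressMessages(library(vegan))
            d <- as.dist(as.matrix(read.csv(commandArgs(TRUE)[1], header=FALSE)))
            meta <- data.frame(diet=rep(c("N","H"), each=6), time=rep(c("t1","t2"), 6))
            res <- adonis2(d ~ diet * time, data=meta, permutations=99, by="terms")
            cat(res$R2[1], res$R2[2], res$R2[3], "\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "d.csv")],
            capture_output=True, text=True, timeout=120,
        )
        assert out.returncode == 0, out.stderr
        r2 = [float(x) for x in out.stdout.split()]
        assert res.r_squared["diet"] == pytest.approx(r2[0], abs=1e-6)
        assert res.r_squared["time"] == pytest.approx(r2[1], abs=1e-6)
        assert res.r_squared["diet:time"] == pytest.approx(r2[2], abs=1e-6)

    def test_null_p_values_roughly_uniform(self, rng):
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            points = rng.normal(size=(10, 2))
            d = _euclidean_dm(points)
            labels = list("AAAAABBBBB")
            res = permanova(d, {"g": labels}, n_perm=99, seed=int(rng.integers(2**31)))
            hits += res.p_values["g"] < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.06)

    def test_single_level_rejected(self):
        d = _dm(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="single level"):
            permanova(d, {"g": list("AAAA")})

    def test_seed_determinism_and_order_invariance(self, rng):
        points = rng.normal(size=(8, 2))
        d = _euclidean_dm(points)
        labels = list("AABBAABB")
        r1 = permanova(d, {"g": labels}, n_perm=199, seed=5)
        r2 = permanova(d, {"g": labels}, n_perm=199, seed=5)
        assert r1.p_values == r2.p_values
        # permuting sample order leaves R2 unchanged
        perm = rng.permutation(8)
        d2 = _dm(d.values[np.ix_(perm, perm)], ids=[d.ids[i] for i in perm])
        r3 = permanova(d2, {"g": [labels[i] for i in perm]}, n_perm=199, seed=5)
        assert r3.r_squared["g"] == pytest.approx(r1.r_squared["g"], abs=1e-9)


def _gower(dv):
    n = dv.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ (dv**2) @ j


class TestUnivariate:
    def test_ttest_identical_samples(self):
        t, p = ttest2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_ttest_separated_samples(self):
        t, p = ttest2([1, 2, 3], [101.0, 102.1, 102.9])
        assert p < 1e-3

    def test_ttest_matches_welch_formula(self):
        x = np.array([4.2, 5.1, 6.3, 5.8])
        y = np.array([3.1, 3.9, 2.8, 3.5, 4.0])
        t, p = ttest2(x, y)
        se = math.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        assert t == pytest.approx((x.mean() - y.mean()) / se, abs=1e-9)

    def test_ttest_needs_two(self):
        with pytest.raises(ValueError):
            ttest2([1.0], [1.0, 2.0])

    def test_anova_matches_hand_mean_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        res = anova_tukey(groups)
        data = np.concatenate(list(groups.values()))
        grand = data.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert res.f == pytest.approx(f_hand, abs=1e-9)

    def test_anova_tukey_flags_only_shifted_group(self):
        groups = {
            "a": [1.0, 1.1, 0.9, 1.05],
            "b": [1.02, 0.95, 1.08, 1.0],
            "c": [9.0, 9.2, 8.9, 9.1],
        }
        res = anova_tukey(groups)
        assert res.p < 1e-6
        for _, row in res.tukey.iterrows():
            involved = {row.group_a, row.group_b}
            assert (row.p < 0.05) == ("c" in involved)

    def test_anova_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    @pytest.mark.parametrize("slope,expected", [(2.0, 1.0), (-1.0, -1.0)])
    def test_pearson_perfect_lines(self, slope, expected):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson(x, slope * x + 1)
        assert r == pytest.approx(expected)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r, _ = pearson(x, y)
        hand = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(hand, abs=1e-9)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
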