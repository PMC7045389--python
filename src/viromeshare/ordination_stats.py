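"""Ordination and univariate statistics over virome-derived quantities.

PCoA is the eigendecomposition of the Gower-centered squared distance
matrix; PERMANOVA partitions the same centered matrix by sequential
(Type-I) sums of squares — the default of vegan's ``adonis`` — with a
pseudo-F per term and a label-permutation p-value. One- and two-factor
models (with interaction, ``~ A * B``) are supported; term order follows
the caller's factor order. Rank-deficient terms (e.g. an interaction
aliased with its margins) contribute zero degrees of freedom and are
reported with R^2 = 0.

The univariate wrappers (Welch t test, one-way ANOVA with Tukey HSD,
Pearson correlation) are thin layers over scipy with the degenerate-input
guards this pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from viromeshare.community_metrics import DistanceMatrix


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    n_negative: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix, eps: float = 1e-9) -> Ordination:
    """Principal-coordinates analysis of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; axes are ordered by descending eigenvalue, each axis's
    sign fixed so its largest-magnitude loading is positive.
    Negative-eigenvalue axes (non-Euclidean distances) are counted but
    excluded from coordinates and variance proportions.
    """
    b = _gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > eps * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for j in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return Ordination(
        ids=list(d.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
        n_negative=int((eigvals < -eps * max(abs(eigvals[0]), 1.0)).sum()),
    )


@dataclass
class PermanovaResult:
    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    r_squared: dict[str, float]
    pseudo_f: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int
    residual_df: int = 0
    residual_ss: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "df": self.df[t],
                "SS": self.ss[t],
                "R2": self.r_squared[t],
                "F": self.pseudo_f[t],
                "p": self.p_values[t],
            }
            for t in self.terms
        ]
        ss_total = sum(self.ss.values()) + self.residual_ss
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "SS": self.residual_ss,
                "R2": self.residual_ss / ss_total if ss_total > 0 else 0.0,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _dummy(labels: list) -> np.ndarray:
    levels = sorted(set(map(str, labels)))
    arr = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(map(str, labels)):
        arr[i, levels.index(lab)] = 1.0
    return arr


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    d: DistanceMatrix,
    factors: dict[str, list],
    interaction: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential sums of squares.

    ``factors`` maps factor name -> per-sample labels in ``d.ids`` order
    (one or two factors; with two and ``interaction=True`` the model is
    ``~ A * B`` in the given order). p-values come from ``n_perm`` seeded
    permutations of sample labels: p = (1 + #{F* >= F}) / (n_perm + 1).
    """
    n = len(d.ids)
    names = list(factors)
    if not 1 <= len(names) <= 2:
        raise ValueError("permanova supports one or two factors")
    for name, labs in factors.items():
        if len(labs) != n:
            raise ValueError(f"factor {name!r} has {len(labs)} labels for {n} samples")
        if len(set(map(str, labs))) < 2:
            raise ValueError(f"factor {name!r} has a single level")
    g = _gower_center(d.values)
    ss_total = float(np.trace(g))

    terms = list(names)
    mats = {name: _dummy(factors[name]) for name in names}
    if len(names) == 2 and interaction:
        a, b = names
        inter = np.einsum("ij,ik->ijk", mats[a], mats[b]).reshape(n, -1)
        terms.append(f"{a}:{b}")
        mats[terms[-1]] = inter

    ones = np.ones((n, 1))
    designs = []
    x = ones
    ranks = [1]
    hats = [_hat(x)]
    for t in terms:
        x = np.hstack([x, mats[t]])
        designs.append(x)
        ranks.append(int(np.linalg.matrix_rank(x)))
        hats.append(_hat(x))
    df_terms = {t: ranks[i + 1] - ranks[i] for i, t in enumerate(terms)}
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[dict[str, float], float]:
        traces = [float(np.sum(h * gmat.T)) for h in hats]
        ss = {t: traces[i + 1] - traces[i] for i, t in enumerate(terms)}
        ss_res = float(np.trace(gmat)) - traces[-1]
        return ss, ss_res

    def pseudo_f(ss_t: float, df_t: int, ss_r: float) -> float:
        if df_t <= 0:
            return np.nan
        ms_res = ss_r / df_res
        if ms_res <= 1e-12:
            # saturated fit: F is +inf when the term explains anything at all
            return np.inf if ss_t / df_t > 1e-12 else 0.0
        return (ss_t / df_t) / ms_res

    ss_obs, ss_res = term_stats(g)
    f_obs = {t: pseudo_f(ss_obs[t], df_terms[t], ss_res) for t in terms}

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_stats(gp)
        for t in terms:
            if df_terms[t] > 0:
                fp = pseudo_f(ss_p[t], df_terms[t], ss_res_p)
                if fp >= f_obs[t] - 1e-12:
                    exceed[t] += 1
    p = {
        t: (1 + exceed[t]) / (n_perm + 1) if df_terms[t] > 0 else np.nan for t in terms
    }
    r2 = {t: ss_obs[t] / ss_total if ss_total > 0 else 0.0 for t in terms}
    return PermanovaResult(
        terms=terms,
        df=df_terms,
        ss=ss_obs,
        r_squared=r2,
        pseudo_f=f_obs,
        p_values=p,
        n_permutations=n_perm,
        seed=seed,
        residual_df=df_res,
        residual_ss=ss_res,
    )


def ttest2(x, y, pooled: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t test (Welch by default)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    f: float
    p: float
    tukey: pd.DataFrame = field(default_factory=pd.DataFrame)


def anova_tukey(groups: dict[str, list]) -> AnovaResult:
    """One-way ANOVA with post hoc Tukey HSD over all group pairs."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled.var(), 0.0):
        raise ValueError("all observations identical: zero variance")
    f, p = stats.f_oneway(*arrays.values())
    hsd = stats.tukey_hsd(*arrays.values())
    names = list(arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                    "p": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaResult(f=float(f), p=float(p), tukey=pd.DataFrame(rows))


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-transform p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(x.var(), 0.0) or np.allclose(y.var(), 0.0):
        raise ValueError("zero variance in an input vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
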