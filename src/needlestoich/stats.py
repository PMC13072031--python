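"""Inferential chain: variance gate, ANOVA variants, letters, correlations, PCA.

Group comparisons follow a gated design common in ecophysiology: Levene's
test (mean-centred) decides at alpha whether variances are homogeneous; if
so, classical one-way ANOVA with Tukey's HSD post hoc; if not, Welch's
ANOVA with Games-Howell pairwise comparisons. Pairwise significance is
summarized as a compact letter display (groups sharing a letter do not
differ at alpha). All tests are two-sided at alpha = 0.05 by default.

Standard tests are delegated: Levene / one-way ANOVA / Tukey / Welch t /
Pearson to scipy, Welch ANOVA and Games-Howell to pingouin, PCA to
scikit-learn, Benjamini-Hochberg to statsmodels. The gate and the
insert-and-absorb letter algorithm are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .core_data import GROUP_CODES, SOIL_LAYERS, StudyDataset
from .indices import RATIO_NAMES, compute_ratios


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: tuple[str, ...] = ()
    note: str = ""


@dataclass(frozen=True)
class PairwiseResults:
    """All-pairs comparison table plus the symmetric p-value matrix."""

    method: str
    table: pd.DataFrame  # columns: group1, group2, statistic, p_value
    p_matrix: pd.DataFrame  # labels x labels, symmetric, unit diagonal


@dataclass(frozen=True)
class GatedComparison:
    levene: TestResult
    route: str  # "anova_tukey" | "welch_games_howell"
    omnibus: TestResult
    pairwise: PairwiseResults | None
    letters: dict[str, str] | None


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    column_means: np.ndarray = field(repr=False, default=None)
    column_sds: np.ndarray = field(repr=False, default=None)

    def reconstruct(self) -> pd.DataFrame:
        """Invert the transform back to the original (unstandardized) table."""
        z = self.scores.to_numpy() @ self.loadings.to_numpy().T
        x = z * self.column_sds + self.column_means
        return pd.DataFrame(x, index=self.scores.index, columns=self.loadings.index)


def _as_groups(groups: Sequence[Sequence[float]] | Mapping[str, Sequence[float]]):
    if isinstance(groups, Mapping):
        labels = tuple(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = tuple(f"g{i + 1}" for i in range(len(arrays)))
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for lab, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2, got {a.size}")
    return labels, arrays


def levene_test(groups) -> TestResult:
    """Levene's homogeneity-of-variance test with mean centring."""
    labels, arrays = _as_groups(groups)
    absdev = np.concatenate([np.abs(a - a.mean()) for a in arrays])
    scale = max(float(np.max(np.abs(np.concatenate(arrays)))), 1.0)
    if np.ptp(absdev) <= 1e-10 * scale:
        # all absolute deviations identical (to rounding): no spread signal at all
        return TestResult("levene", 0.0, (float(len(arrays) - 1), float(absdev.size - len(arrays))),
                          1.0, labels, note="degenerate: identical absolute deviations")
    w, p = sps.levene(*arrays, center="mean")
    df = (float(len(arrays) - 1), float(sum(a.size for a in arrays) - len(arrays)))
    return TestResult("levene", float(w), df, float(p), labels)


def oneway_anova(groups) -> TestResult:
    """Classical one-way ANOVA F test, df = (k-1, N-k)."""
    labels, arrays = _as_groups(groups)
    if all(np.ptp(a) == 0.0 for a in arrays):
        raise ValueError("F undefined: zero within-group variance in every group")
    f, p = sps.f_oneway(*arrays)
    df = (float(len(arrays) - 1), float(sum(a.size for a in arrays) - len(arrays)))
    return TestResult("oneway_anova", float(f), df, float(p), labels)


def welch_anova(groups) -> TestResult:
    """Welch's heteroscedasticity-robust ANOVA (Satterthwaite-type df)."""
    import pingouin as pg

    labels, arrays = _as_groups(groups)
    long = pd.DataFrame(
        {
            "y": np.concatenate(arrays),
            "g": np.repeat(labels, [a.size for a in arrays]),
        }
    )
    res = pg.welch_anova(data=long, dv="y", between="g").iloc[0]
    p_col = "p_unc" if "p_unc" in res.index else "p-unc"
    return TestResult(
        "welch_anova", float(res["F"]), (float(res["ddof1"]), float(res["ddof2"])),
        float(res[p_col]), labels,
    )


def tukey_hsd(groups) -> PairwiseResults:
    """Tukey's HSD all-pairs comparisons (studentized-range p-values)."""
    labels, arrays = _as_groups(groups)
    res = sps.tukey_hsd(*arrays)
    k = len(labels)
    pmat = pd.DataFrame(np.asarray(res.pvalue, dtype=float), index=labels, columns=labels)
    np.fill_diagonal(pmat.values, 1.0)
    rows = [
        {"group1": labels[i], "group2": labels[j],
         "statistic": float(res.statistic[i, j]), "p_value": float(pmat.iloc[i, j])}
        for i, j in combinations(range(k), 2)
    ]
    return PairwiseResults("tukey_hsd", pd.DataFrame(rows), pmat)


def games_howell(groups) -> PairwiseResults:
    """Games-Howell pairwise Welch comparisons for the heteroscedastic route."""
    import pingouin as pg

    labels, arrays = _as_groups(groups)
    long = pd.DataFrame(
        {
            "y": np.concatenate(arrays),
            "g": np.repeat(labels, [a.size for a in arrays]),
        }
    )
    res = pg.pairwise_gameshowell(data=long, dv="y", between="g")
    pmat = pd.DataFrame(1.0, index=labels, columns=labels)
    rows = []
    for _, r in res.iterrows():
        a, b = str(r["A"]), str(r["B"])
        p = float(r["pval"])
        pmat.loc[a, b] = pmat.loc[b, a] = p
        rows.append({"group1": a, "group2": b, "statistic": float(r["T"]), "p_value": p})
    # preserve the caller's pair order (combinations order over labels)
    order = {frozenset(pair): i for i, pair in enumerate(combinations(labels, 2))}
    rows.sort(key=lambda r: order[frozenset((r["group1"], r["group2"]))])
    return PairwiseResults("games_howell", pd.DataFrame(rows), pmat)


def welch_t_test(x, y, labels: tuple[str, str] = ("x", "y")) -> TestResult:
    """Welch two-sample t test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch t-test needs n >= 2 per group")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        if x[0] == y[0]:
            return TestResult("welch_t", float("nan"), (float("nan"),), float("nan"),
                              labels, note="undefined: zero variance and equal means")
        return TestResult("welch_t", float("inf") if x[0] > y[0] else float("-inf"),
                          (float(x.size + y.size - 2),), 0.0, labels,
                          note="zero variance, unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), (float(res.df),), float(res.pvalue), labels)


def compact_letter_display(
    pairwise_p: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a symmetric p matrix.

    Contract: two groups share at least one letter iff their pairwise
    comparison is non-significant at alpha. The diagonal is treated as
    non-significant. After the insert-and-absorb passes a redundancy sweep
    removes columns whose pairs and members are covered elsewhere, which
    keeps the letter count minimal on the small group counts (<= 6) this
    design produces.
    """
    if isinstance(pairwise_p, pd.DataFrame):
        if labels is None:
            labels = list(pairwise_p.index)
        P = pairwise_p.to_numpy(dtype=float)
    else:
        P = np.asarray(pairwise_p, dtype=float)
        if labels is None:
            labels = [f"g{i + 1}" for i in range(P.shape[0])]
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("pairwise p matrix must be square")
    if not np.allclose(P, P.T, equal_nan=True):
        raise ValueError("pairwise p matrix must be symmetric")
    k = P.shape[0]
    sig = [(i, j) for i, j in combinations(range(k), 2) if P[i, j] < alpha]

    columns: list[frozenset[int]] = [frozenset(range(k))]
    for i, j in sig:
        new: list[frozenset[int]] = []
        for col in columns:
            if i in col and j in col:
                new.append(col - {i})
                new.append(col - {j})
            else:
                new.append(col)
        columns = _absorb(new)
    columns = _sweep(columns, k, sig)
    columns.sort(key=lambda c: (min(c), -len(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for idx, col in enumerate(columns):
        letter = alphabet[idx] if idx < 26 else f"l{idx}"
        for g in sorted(col):
            letters[labels[g]].append(letter)
    return {lab: "".join(ls) for lab, ls in letters.items()}


def _absorb(columns: list[frozenset[int]]) -> list[frozenset[int]]:
    out: list[frozenset[int]] = []
    for col in columns:
        if any(col < other or (col == other) for other in out):
            continue
        out = [o for o in out if not o < col]
        out.append(col)
    return out


def _sweep(columns: list[frozenset[int]], k: int, sig: list[tuple[int, int]]) -> list[frozenset[int]]:
    """Drop columns whose non-significant pairs and members are covered elsewhere."""
    sig_set = set(sig)
    nonsig = [(i, j) for i, j in combinations(range(k), 2) if (i, j) not in sig_set]

    def valid(cols: list[frozenset[int]]) -> bool:
        if not all(any(g in c for c in cols) for g in range(k)):
            return False
        return all(any(i in c and j in c for c in cols) for i, j in nonsig)

    cols = list(columns)
    changed = True
    while changed:
        changed = False
        for idx in range(len(cols)):
            trial = cols[:idx] + cols[idx + 1:]
            if trial and valid(trial):
                cols = trial
                changed = True
                break
    return cols


def gated_group_comparison(
    groups, alpha: float = 0.05, posthoc: bool = True
) -> GatedComparison:
    """Levene gate -> (ANOVA + Tukey) or (Welch + Games-Howell) + letters."""
    labels, arrays = _as_groups(groups)
    named = dict(zip(labels, arrays))
    lev = levene_test(named)
    if lev.p_value >= alpha:
        route = "anova_tukey"
        omnibus = oneway_anova(named)
        pw = tukey_hsd(named) if posthoc else None
    else:
        route = "welch_games_howell"
        omnibus = welch_anova(named)
        pw = games_howell(named) if posthoc else None
    letters = compact_letter_display(pw.p_matrix, alpha=alpha) if pw is not None else None
    return GatedComparison(levene=lev, route=route, omnibus=omnibus, pairwise=pw, letters=letters)


@dataclass(frozen=True)
class CorrelationEntry:
    needle_group: str
    soil_layer: str
    ratio_name: str
    n: int
    r: float
    p_value: float
    flag: str  # "" | "low-power" | "insufficient" | "undefined"


def needle_soil_correlation(
    dataset: StudyDataset, needle_group: str, soil_layer: str, ratio_name: str
) -> CorrelationEntry:
    """Pearson r between a needle group's ratio and one soil layer's, across trees.

    Trees enter when they carry both the needle sample at the group's
    condition x position and the soil sample at the layer. n = 3 designs
    are computed but stamped "low-power".
    """
    if needle_group not in GROUP_CODES:
        raise ValueError(f"unknown needle group {needle_group!r}")
    if ratio_name not in RATIO_NAMES:
        raise ValueError(f"unknown ratio {ratio_name!r}")
    position = "apical" if needle_group[0] == "A" else "basal"
    condition = "healthy" if needle_group[1] == "H" else "chlorotic"
    needle_by_tree = {
        s.tree_id: compute_ratios(s)[ratio_name]
        for s in dataset.needles
        if s.condition == condition and s.position == position
    }
    soil_by_tree = {
        s.tree_id: compute_ratios(s)[ratio_name]
        for s in dataset.soils
        if s.condition == condition and s.soil_layer == soil_layer
    }
    trees = sorted(set(needle_by_tree) & set(soil_by_tree))
    x = np.array([needle_by_tree[t] for t in trees])
    y = np.array([soil_by_tree[t] for t in trees])
    if len(trees) < 3:
        return CorrelationEntry(needle_group, soil_layer, ratio_name, len(trees),
                                float("nan"), float("nan"), "insufficient")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CorrelationEntry(needle_group, soil_layer, ratio_name, len(trees),
                                float("nan"), float("nan"), "undefined")
    r, p = sps.pearsonr(x, y)
    flag = "low-power" if len(trees) == 3 else ""
    return CorrelationEntry(needle_group, soil_layer, ratio_name, len(trees),
                            float(r), float(p), flag)


def correlation_grid(dataset: StudyDataset) -> pd.DataFrame:
    """The full 4 needle groups x 5 layers x 3 ratios Pearson grid.

    Raw two-sided p-values are the primary output; a Benjamini-Hochberg
    adjusted column (``p_bh``, over the valid cells) is added as a clearly
    labelled extension — no correction is applied to the raw values.
    """
    rows = []
    for g in GROUP_CODES:
        for layer in SOIL_LAYERS:
            for ratio in RATIO_NAMES:
                e = needle_soil_correlation(dataset, g, layer, ratio)
                rows.append(vars(e).copy())
    df = pd.DataFrame(rows)
    valid = df["p_value"].notna()
    df["p_bh"] = np.nan
    if valid.any():
        df.loc[valid, "p_bh"] = multipletests(df.loc[valid, "p_value"], method="fdr_bh")[1]
    return df


def pca_ratios(ratio_table: pd.DataFrame) -> PCAResult:
    """PCA of the standardized needle ratio table (columns C:N, C:P, N:P).

    Columns are centred and scaled to unit sample variance (n-1), so the
    decomposition reflects the correlation structure; explained fractions
    over all three components sum to 1. Loading signs are fixed so each
    component's largest-magnitude entry is positive.
    """
    if ratio_table.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = ratio_table.to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    for name, sd in zip(ratio_table.columns, sds):
        if sd == 0.0:
            raise ValueError(f"ratio column {name!r} has zero variance")
    z = (x - means) / sds
    n_comp = min(x.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(z)
    components = pca.components_  # rows = components
    for i in range(n_comp):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ratio_table.index, columns=comp_names),
        loadings=pd.DataFrame(components.T, index=ratio_table.columns, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        column_means=means,
        column_sds=sds,
    )
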