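"""Differential-abundance testing between two dataset groups.

Two non-parametric tests operate on per-sample *relative* abundances (each
sample normalised by its own total weight, since sequencing depth differs
wildly between samples):

* Wilcoxon rank-sum: exact null enumeration for small tie-free samples,
  normal approximation with tie and continuity correction otherwise.
* Metastats-style permutation test: per feature, a two-sample
  unequal-variance (Welch) t statistic on the relative abundances, with a
  permutation p-value ``(1 + #{|t*| >= |t|}) / (B + 1)`` over random
  relabelings of the pooled samples.  Sparse features — total count across
  both groups at most ``sparse_threshold`` (default 8) — are instead tested
  with Fisher's exact test on the pooled 2x2 contingency table, since the
  t statistic is unstable at such depths.  A normal-theory 95% confidence
  interval on the mean difference accompanies each t-tested feature.

Family-wise error is controlled by Bonferroni: ``min(1, m * p)`` with ``m``
the number of features tested.  Reported summaries follow the usual result
panel: per-group medians of the relative abundance as percentages and their
ratio A/B (infinite when the group-B median is zero).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .annotation_store import Dataset
from .compare import build_matrix
from .hierarchies import OntologyDAG, PathwayMap, TaxonomyTree

DEFAULT_PERMUTATIONS = 10_000
DEFAULT_SPARSE_THRESHOLD = 8.0


def wilcoxon_rank_sum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``method='auto'`` uses exact null enumeration when the pooled sample size
    is at most 12 and the data are tie-free, otherwise the normal
    approximation with tie correction and continuity correction.  Two samples
    with all values identical give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    result = _sstats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(result.pvalue)


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, m * p)`` for m tests."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def group_medians(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature group medians of relative abundance (as %) and ratio A/B.

    Input matrices are samples x features of relative abundances.  Median of
    an even-sized group is the mean of the middle two order statistics.  The
    ratio is reported as ``inf`` when the group-B median is zero.
    """
    features = sorted(set(matrix_a.columns) | set(matrix_b.columns))
    a = matrix_a.reindex(columns=features, fill_value=0.0)
    b = matrix_b.reindex(columns=features, fill_value=0.0)
    median_a = a.median(axis=0).to_numpy() * 100.0
    median_b = b.median(axis=0).to_numpy() * 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(median_b > 0, median_a / np.where(median_b > 0, median_b, 1.0), np.inf)
    return pd.DataFrame(
        {"median_pct_a": median_a, "median_pct_b": median_b, "median_ratio": ratio},
        index=features,
    )


def _relative(matrix: pd.DataFrame) -> pd.DataFrame:
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample needs positive total abundance")
    return matrix.div(totals, axis=0)


def _welch_t(data: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorised Welch t statistic per column; 0/0 maps to 0, d/0 to +-inf."""
    a = data[mask_a]
    b = data[~mask_a]
    diff = a.mean(axis=0) - b.mean(axis=0)
    se2 = a.var(axis=0, ddof=1) / a.shape[0] + b.var(axis=0, ddof=1) / b.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(se2 > 0, t, np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return t


def metastats(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    sparse_threshold: float = DEFAULT_SPARSE_THRESHOLD,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Metastats-style differential abundance between two sample groups.

    ``matrix_a`` / ``matrix_b`` are samples x features matrices of *absolute*
    abundances (counts or weights); relative abundances are formed per sample
    internally.  Returns one row per feature with group summaries, the raw
    and Bonferroni-adjusted p-values, the test branch used, and a
    normal-theory CI on the difference of group means (t branch only).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if len(matrix_a) < 2 or len(matrix_b) < 2:
        raise ValueError("the t branch needs at least 2 samples per group")
    features = sorted(set(matrix_a.columns) | set(matrix_b.columns))
    raw_a = matrix_a.reindex(columns=features, fill_value=0.0)
    raw_b = matrix_b.reindex(columns=features, fill_value=0.0)
    rel_a = _relative(raw_a)
    rel_b = _relative(raw_b)

    n_a, n_b = len(rel_a), len(rel_b)
    n = n_a + n_b
    # canonical within-group row order, so permutation p-values do not depend
    # on how the caller happened to order the samples
    block_a = rel_a.to_numpy(dtype=float)
    block_b = rel_b.to_numpy(dtype=float)
    block_a = block_a[np.lexsort(block_a.T[::-1])]
    block_b = block_b[np.lexsort(block_b.T[::-1])]
    pooled = np.vstack([block_a, block_b])
    mask_a = np.zeros(n, dtype=bool)
    mask_a[:n_a] = True

    t_obs = _welch_t(pooled, mask_a)
    abs_t_obs = np.abs(t_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(features))
    for _ in range(permutations):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.permutation(n)[:n_a]] = True
        t_perm = _welch_t(pooled, perm_mask)
        exceed += np.abs(t_perm) >= abs_t_obs
    p_perm = (1.0 + exceed) / (permutations + 1.0)

    mean_a = pooled[mask_a].mean(axis=0)
    mean_b = pooled[~mask_a].mean(axis=0)
    var_a = pooled[mask_a].var(axis=0, ddof=1)
    var_b = pooled[~mask_a].var(axis=0, ddof=1)
    diff = mean_a - mean_b
    se = np.sqrt(var_a / n_a + var_b / n_b)
    z = float(_sstats.norm.ppf(0.5 + ci_level / 2.0))
    ci_lower = diff - z * se
    ci_upper = diff + z * se

    # zero variance in both groups and equal means: nothing to test
    degenerate = (se == 0) & (diff == 0)
    p_perm = np.where(degenerate, 1.0, p_perm)

    # sparse branch: pooled count at most the threshold -> Fisher's exact test
    # on the pooled 2x2 table of (feature count, remainder) per group
    sum_a = raw_a.sum(axis=0).to_numpy(dtype=float)
    sum_b = raw_b.sum(axis=0).to_numpy(dtype=float)
    total_a = float(raw_a.to_numpy().sum())
    total_b = float(raw_b.to_numpy().sum())
    sparse = (sum_a + sum_b) <= sparse_threshold
    p_value = p_perm.copy()
    test_name = np.where(sparse, "fisher", "t-permutation").astype(object)
    for index in np.nonzero(sparse)[0]:
        fa = int(round(sum_a[index]))
        fb = int(round(sum_b[index]))
        table = [
            [fa, max(0, int(round(total_a)) - fa)],
            [fb, max(0, int(round(total_b)) - fb)],
        ]
        p_value[index] = float(_sstats.fisher_exact(table, alternative="two-sided")[1])

    result = pd.DataFrame(
        {
            "n_a": n_a,
            "n_b": n_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "var_a": var_a,
            "var_b": var_b,
            "t_stat": np.where(sparse, np.nan, t_obs),
            "p_value": p_value,
            "adj_p_value": bonferroni(p_value),
            "ci_lower": np.where(sparse, np.nan, ci_lower),
            "ci_upper": np.where(sparse, np.nan, ci_upper),
            "test": test_name,
            "permutations": permutations,
            "seed": np.nan if seed is None else seed,
        },
        index=features,
    )
    medians = group_medians(rel_a, rel_b)
    return result.join(medians)


def wilcoxon_table(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum results on per-sample relative abundances."""
    features = sorted(set(matrix_a.columns) | set(matrix_b.columns))
    rel_a = _relative(matrix_a.reindex(columns=features, fill_value=0.0))
    rel_b = _relative(matrix_b.reindex(columns=features, fill_value=0.0))
    p_values = np.array(
        [
            wilcoxon_rank_sum(rel_a[f].to_numpy(), rel_b[f].to_numpy(), alternative)
            for f in features
        ]
    )
    result = pd.DataFrame(
        {
            "n_a": len(rel_a),
            "n_b": len(rel_b),
            "mean_a": rel_a.mean(axis=0),
            "mean_b": rel_b.mean(axis=0),
            "p_value": p_values,
            "adj_p_value": bonferroni(p_values),
            "test": "wilcoxon",
        },
        index=features,
    )
    return result.join(group_medians(rel_a, rel_b))


def differential_abundance(
    group_a: Sequence[Dataset],
    group_b: Sequence[Dataset],
    attribute: str,
    level: str | int | None = None,
    filter_query: str | None = None,
    test: str = "wilcoxon",
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    sparse_threshold: float = DEFAULT_SPARSE_THRESHOLD,
    *,
    tree: TaxonomyTree | None = None,
    ontology: OntologyDAG | None = None,
    pathway_map: PathwayMap | None = None,
) -> pd.DataFrame:
    """End-to-end two-group test on an annotation attribute.

    Builds per-sample absolute abundance matrices (after the optional filter),
    then runs the requested test over the union of features; multiplicity
    correction spans exactly the features present in either group.
    """
    if test not in ("wilcoxon", "metastats"):
        raise ValueError(f"unknown test {test!r}; expected 'wilcoxon' or 'metastats'")
    kwargs = dict(
        tree=tree,
        ontology=ontology,
        pathway_map=pathway_map,
        mode="absolute",
        include_unassigned=False,
    )
    matrix_a = build_matrix(group_a, attribute, level, filter_query, **kwargs)
    matrix_b = build_matrix(group_b, attribute, level, filter_query, **kwargs)
    if test == "wilcoxon":
        return wilcoxon_table(matrix_a, matrix_b)
    return metastats(
        matrix_a,
        matrix_b,
        permutations=permutations,
        seed=seed,
        sparse_threshold=sparse_threshold,
    )


def pairwise_distance_comparison(
    within_pairs: Sequence[float], all_pairs: Sequence[float]
) -> float:
    """One-sided Wilcoxon p for within-group distances being *smaller*.

    Used to ask whether repeat samples of the same subject/habitat are closer
    to each other than arbitrary sample pairs are.
    """
    return wilcoxon_rank_sum(within_pairs, all_pairs, alternative="less")
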