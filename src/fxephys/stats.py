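"""Group-comparison statistics for genotype x treatment designs.

* exact Wilcoxon rank-sum — two-sided p from the complete permutation
  distribution of the rank sum (midranks under ties), enumerated when
  C(n+m, n) is tractable and estimated by seeded Monte-Carlo permutation
  otherwise;
* Kruskal–Wallis with tie correction;
* two-way factorial ANOVA with interaction, Type III sums of squares
  (robust to unbalanced cells, exactly the textbook table when balanced);
* Benjamini–Hochberg FDR adjustment for families of pairwise comparisons.

Two-sidedness of the exact test uses the reflection definition: the null
probability that |W - E[W]| is at least the observed deviation, which is
well-defined under ties and asymmetry.  Results with 0.05 <= p < 0.1 are
annotated as trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

ENUMERATION_LIMIT = 2_000_000
MC_DRAWS = 100_000


@dataclass
class StatResult:
    """One test outcome; ``p_adj`` is set by FDR adjustment when part of a
    family of comparisons."""

    method: str
    statistic: float
    df: tuple[float, float] | None
    p_raw: float
    p_adj: float | None = None
    comparison: str = ""
    mode: str = ""
    n_draws: int | None = None

    @property
    def trend(self) -> bool:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return 0.05 <= p < 0.1


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


@lru_cache(maxsize=8)
def _combination_matrix(total: int, k: int) -> np.ndarray:
    """All C(total, k) index subsets as a (C, k) int array (cached)."""
    return np.array(list(combinations(range(total), k)), dtype=np.intp)


def exact_wilcoxon_ranksum(x: Sequence[float], y: Sequence[float],
                           mode: str = "auto", seed: int = 0,
                           n_draws: int = MC_DRAWS) -> StatResult:
    """Exact (or Monte-Carlo) two-sided Wilcoxon rank-sum test.

    W is the sum of the midranks of ``x`` in the pooled sample.  The
    two-sided p-value is the permutation-null probability that
    |W - E[W]| >= the observed deviation, by complete enumeration of all
    C(n+m, n) group assignments when that count is at most the enumeration
    limit, else by ``n_draws`` seeded random permutations (with the
    add-one convention so the observed assignment counts itself).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    total = n + m
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = float(ranks[:n].sum())
    e_w = n * (total + 1) / 2.0
    d_obs = abs(w_obs - e_w)

    n_comb = math.comb(total, n)
    if mode == "auto":
        mode = "exact" if n_comb <= ENUMERATION_LIMIT else "mc"
    if mode == "exact":
        if n_comb > ENUMERATION_LIMIT:
            raise ValueError(
                f"C({total},{n}) = {n_comb} exceeds the enumeration limit "
                f"{ENUMERATION_LIMIT}; use mode='mc'")
        idx = _combination_matrix(total, n)
        w_all = ranks[idx].sum(axis=1)
        p = float(np.mean(np.abs(w_all - e_w) >= d_obs - 1e-9))
        return StatResult(method="exact_wilcoxon_ranksum", statistic=w_obs,
                          df=None, p_raw=p, mode="exact")
    if mode == "mc":
        rng = np.random.default_rng(seed)
        hits = 0
        block = 20_000
        done = 0
        while done < n_draws:
            b = min(block, n_draws - done)
            perm = rng.permuted(np.broadcast_to(ranks, (b, total)).copy(),
                                axis=1)
            w = perm[:, :n].sum(axis=1)
            hits += int(np.sum(np.abs(w - e_w) >= d_obs - 1e-9))
            done += b
        p = (hits + 1) / (n_draws + 1)
        return StatResult(method="exact_wilcoxon_ranksum", statistic=w_obs,
                          df=None, p_raw=float(p), mode="mc",
                          n_draws=n_draws)
    raise ValueError(f"unknown mode {mode!r}")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return StatResult(method="kruskal_wallis", statistic=0.0,
                          df=(len(groups) - 1, float("nan")), p_raw=1.0)
    h, p = sps.kruskal(*arrays)
    return StatResult(method="kruskal_wallis", statistic=float(h),
                      df=(len(groups) - 1, float("nan")), p_raw=float(p))


def anova_two_way(data: pd.DataFrame, response: str = "value",
                  factor_a: str = "genotype",
                  factor_b: str = "treatment") -> list[StatResult]:
    """Two-way factorial ANOVA with interaction, Type III sums of squares.

    Fits the cell-means model by least squares with sum-to-zero contrasts
    (Type III is invariant to cell imbalance); with balanced cells the
    table equals the closed-form balanced ANOVA exactly.  An empty cell
    drops the design to one-way on the other factor, with a warning in the
    returned comparison labels.
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    levels_a = df[factor_a].nunique()
    levels_b = df[factor_b].nunique()
    if levels_a < 2 or levels_b < 2:
        raise ValueError("each factor needs at least 2 observed levels")
    cells = df.groupby([factor_a, factor_b], sort=True).size()
    if len(cells) < levels_a * levels_b:
        import warnings
        missing = levels_a * levels_b - len(cells)
        warnings.warn(f"{missing} empty cell(s); dropping to one-way ANOVA "
                      f"on {factor_a}", stacklevel=2)
        model = ols(f"Q('{response}') ~ C(Q('{factor_a}'), Sum)", data=df).fit()
        table = anova_lm(model, typ=3)
        row = table.loc[f"C(Q('{factor_a}'), Sum)"]
        resid = table.loc["Residual"]
        return [StatResult(method="anova_one_way", statistic=float(row["F"]),
                           df=(float(row["df"]), float(resid["df"])),
                           p_raw=float(row["PR(>F)"]), comparison=factor_a)]
    if not (cells >= 2).any():
        raise ValueError("need at least one cell with >= 2 observations")

    formula = (f"Q('{response}') ~ C(Q('{factor_a}'), Sum) * "
               f"C(Q('{factor_b}'), Sum)")
    model = ols(formula, data=df).fit()
    table = anova_lm(model, typ=3)
    resid_df = float(table.loc["Residual", "df"])
    if resid_df <= 0:
        raise ValueError("zero residual degrees of freedom")
    labels = {
        f"C(Q('{factor_a}'), Sum)": factor_a,
        f"C(Q('{factor_b}'), Sum)": factor_b,
        f"C(Q('{factor_a}'), Sum):C(Q('{factor_b}'), Sum)":
            f"{factor_a}:{factor_b}",
    }
    out = []
    for key, label in labels.items():
        row = table.loc[key]
        out.append(StatResult(method="anova_two_way",
                              statistic=float(row["F"]),
                              df=(float(row["df"]), resid_df),
                              p_raw=float(row["PR(>F)"]), comparison=label))
    return out


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def pairwise_group_comparisons(data: pd.DataFrame, measure: str,
                               test: str = "wilcoxon",
                               groups: Sequence[tuple[str, str]] | None = None,
                               value_col: str = "value",
                               seed: int = 0) -> pd.DataFrame:
    """All unordered pairwise group tests for one measure, FDR-corrected.

    Groups are (genotype, treatment) pairs; ``test`` is "wilcoxon" (exact
    rank-sum, Monte-Carlo above the enumeration limit) or "t" (Welch).
    Returns a table sorted by adjusted p, with method, statistic, raw and
    adjusted p, mode and trend annotation per row.
    """
    df = data[data["measure"] == measure] if "measure" in data.columns else data
    df = df.dropna(subset=[value_col])
    present = {(g, t): sub[value_col].to_numpy()
               for (g, t), sub in df.groupby(["genotype", "treatment"], sort=True)}
    if groups is None:
        groups = sorted(present)
    else:
        absent = [g for g in groups if g not in present]
        if absent:
            raise ValueError(f"groups absent from data: {absent}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    results = []
    for (ga, gb) in combinations(groups, 2):
        a, b = present[ga], present[gb]
        label = f"{'/'.join(ga)} vs {'/'.join(gb)}"
        if test == "wilcoxon":
            r = exact_wilcoxon_ranksum(a, b, seed=seed)
        elif test == "t":
            t, p = sps.ttest_ind(a, b, equal_var=False)
            r = StatResult(method="welch_t", statistic=float(t), df=None,
                           p_raw=float(p))
        else:
            raise ValueError(f"unknown test {test!r}")
        r.comparison = label
        results.append(r)

    adj = fdr_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = a
    rows = [{"comparison": r.comparison, "method": r.method,
             "statistic": r.statistic, "p_raw": r.p_raw, "p_adj": r.p_adj,
             "mode": r.mode, "trend": r.trend} for r in results]
    return (pd.DataFrame(rows)
            .sort_values(["p_adj", "comparison"], kind="mergesort")
            .reset_index(drop=True))
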