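"""Validation of centrality models against a-priori important gene sets.

Three complementary analyses quantify how well a centrality model places
known-important genes at topologically important positions:

1. **Quantile regression.**  Within each pathway, nodes are ranked by
   centrality and mapped to quantiles 1..100 (``Q = ceil(100 r / n)``, so
   the most central node always lands in quantile 100).  Counts are pooled
   across pathways — a gene occurring in k pathways contributes k
   observations — and the percentage of important genes per quantile,
   ``F_i = 100 * important_i / total_i``, is regressed on the quantile
   index ``i`` by ordinary least squares.  A positive slope means the model
   concentrates important genes at high centrality.

2. **CDF comparison.**  Scores are z-normalized within each pathway,
   pooled across pathways, placed into 100 quantiles by pooled rank, and
   the empirical CDFs of important versus other genes are compared with a
   one-sided two-sample Kolmogorov–Smirnov statistic
   ``D = sup_x (F_other(x) - F_important(x))`` (important genes stochastically
   larger when D is large).

3. **Per-pathway two-sample tests.**  Within each pathway, raw centrality
   of important versus other genes is compared by a one-sided Welch t-test
   and a one-sided Wilcoxon rank-sum test; p-values are corrected by
   Benjamini–Hochberg FDR separately per (model, variant, test) family.

A sensitivity scan repeats the regression for the four PageRank variants
over a grid of dampening factors and compares SSC against undirected
PageRank via Fisher's Z-transformation of the fit correlations.

The :class:`CentralityValidation` model class bundles the full pipeline
(filters -> profiles -> analyses) and returns a :class:`ValidationResults`
object with tidy tables and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .centrality import (
    DEFAULT_MODEL_SET,
    DEFAULT_PARAMS,
    CentralityParams,
    CentralityProfile,
    ConvergenceError,
    compute_centrality,
)
from .graph import PathwayGraph
from .pathway_io import FilterConfig, GeneSet, filter_pathways, filter_report_frame

__all__ = [
    "RegressionFit",
    "quantile_ranks",
    "pool_quantiles",
    "fit_quantile_regression",
    "znormalize",
    "pooled_quantile_scores",
    "ks_cdf_compare",
    "welch_test",
    "wilcoxon_test",
    "bh_fdr",
    "fisher_z",
    "sensitivity_scan",
    "CentralityValidation",
    "ValidationResults",
]

N_QUANTILES = 100

#: Sensitivity-scan default grid: 0.10 .. 0.90 in steps of 0.01 (81 values).
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(10, 91) / 100.0, 2))


# ---------------------------------------------------------------------------
# quantile machinery

def quantile_ranks(profile: CentralityProfile) -> np.ndarray:
    """Map per-node scores to quantiles 1..100 by ascending rank.

    Ties receive the average rank before the ceiling, so the mapping is
    deterministic and order-independent; the maximum-score node is always
    in quantile 100.  Constant profiles are a contract violation (the
    pathway filter removes them).
    """
    if profile.is_constant():
        raise ValueError(
            f"{profile.pathway_id}/{profile.model}-{profile.variant}: "
            "constant centrality profile has no quantile ranking"
        )
    n = len(profile.scores)
    ranks = scipy.stats.rankdata(profile.scores, method="average")
    return np.ceil(N_QUANTILES * ranks / n).astype(int)


def pool_quantiles(
    profiles: Sequence[CentralityProfile],
    important: GeneSet,
    quantiles: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Pool per-quantile important/total counts across pathways.

    Each occurrence of a gene counts separately (a gene in k pathways
    contributes k observations).  Returns a table with columns
    ``quantile, n_important, n_total, fraction`` (fraction in percent);
    empty bins are omitted.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    if quantiles is None:
        quantiles = [quantile_ranks(p) for p in profiles]
    total = np.zeros(N_QUANTILES + 1, dtype=int)
    imp = np.zeros(N_QUANTILES + 1, dtype=int)
    for profile, q in zip(profiles, quantiles):
        np.add.at(total, q, 1)
        is_imp = np.fromiter(
            (v in important for v in profile.nodes), dtype=bool, count=len(profile.nodes)
        )
        np.add.at(imp, q[is_imp], 1)
    bins = np.nonzero(total)[0]
    return pd.DataFrame(
        {
            "quantile": bins,
            "n_important": imp[bins],
            "n_total": total[bins],
            "fraction": 100.0 * imp[bins] / total[bins],
        }
    )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of the importance fraction on the quantile index."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_t: float
    intercept_t: float
    slope_p: float
    intercept_p: float
    adj_r_squared: float
    r: float  # signed Pearson correlation of the fit
    n: int


def fit_quantile_regression(table: pd.DataFrame) -> RegressionFit:
    """OLS of ``fraction`` on ``quantile`` with intercept."""
    if len(table) < 3:
        raise ValueError(
            f"need >= 3 populated quantile bins for a regression, got {len(table)}"
        )
    x = sm.add_constant(table["quantile"].to_numpy(dtype=float))
    y = table["fraction"].to_numpy(dtype=float)
    res = sm.OLS(y, x).fit()
    r = float(np.corrcoef(table["quantile"], y)[0, 1])
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        slope_t=float(res.tvalues[1]),
        intercept_t=float(res.tvalues[0]),
        slope_p=float(res.pvalues[1]),
        intercept_p=float(res.pvalues[0]),
        adj_r_squared=float(res.rsquared_adj),
        r=r,
        n=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# CDF comparison

def znormalize(profile: CentralityProfile, ddof: int = 1) -> np.ndarray:
    """Per-pathway z-scores ``(C - mean) / sd`` (sample sd by default)."""
    scores = profile.scores
    sd = float(np.std(scores, ddof=ddof))
    if not sd > 0:
        raise ValueError(
            f"{profile.pathway_id}/{profile.model}-{profile.variant}: "
            "zero variance, cannot z-normalize"
        )
    return (scores - float(np.mean(scores))) / sd


def pooled_quantile_scores(
    profiles: Sequence[CentralityProfile],
    important: GeneSet,
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-normalize per pathway, pool, and quantile the pooled ranks.

    This is the CDF-analysis discretization: the *pooled* collection of
    z-scores is placed into 100 quantiles (distinct from the within-pathway
    quantiles of the regression analysis).  Returns columns ``pathway_id,
    node_id, zscore, quantile, is_important``.
    """
    rows = []
    for p in profiles:
        z = znormalize(p, ddof=ddof)
        for node, zi in zip(p.nodes, z):
            rows.append((p.pathway_id, node, float(zi), node in important))
    df = pd.DataFrame(rows, columns=["pathway_id", "node_id", "zscore", "is_important"])
    ranks = scipy.stats.rankdata(df["zscore"].to_numpy(), method="average")
    df["quantile"] = np.ceil(N_QUANTILES * ranks / len(df)).astype(int)
    return df[["pathway_id", "node_id", "zscore", "quantile", "is_important"]]


def ks_cdf_compare(
    important_scores: np.ndarray, other_scores: np.ndarray
) -> tuple[float, float]:
    """One-sided two-sample KS: D = sup_x (F_other(x) - F_important(x)).

    Large D means important genes are stochastically larger (their CDF lies
    below).  The p-value is the one-sided Smirnov asymptotic with Hodges'
    second-order correction: with ``z = sqrt(nm/(n+m)) D`` and ``m >= n``,
    ``p = exp(-2 z^2 - 2 z (m + 2n) / (3 sqrt(nm(n+m))))``.
    """
    imp = np.sort(np.asarray(important_scores, dtype=float))
    oth = np.sort(np.asarray(other_scores, dtype=float))
    n_imp, n_oth = len(imp), len(oth)
    if n_imp == 0 or n_oth == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([imp, oth])
    f_imp = np.searchsorted(imp, grid, side="right") / n_imp
    f_oth = np.searchsorted(oth, grid, side="right") / n_oth
    d = float(max(np.max(f_oth - f_imp), 0.0))
    m, n = max(n_imp, n_oth), min(n_imp, n_oth)
    z = math.sqrt(m * n / (m + n)) * d
    expt = -2.0 * z * z - 2.0 * z * (m + 2 * n) / math.sqrt(m * n * (m + n)) / 3.0
    p = float(min(1.0, math.exp(expt)))
    return d, p


# ---------------------------------------------------------------------------
# two-sample tests and FDR

@dataclass(frozen=True)
class TwoSampleResult:
    statistic: float
    p_value: float
    n_important: int
    n_other: int
    testable: bool


def welch_test(important_scores, other_scores) -> TwoSampleResult:
    """One-sided Welch t-test of mean(important) > mean(other).

    ``t = (mean_c - mean_n) / sqrt(s_c^2/N_c + s_n^2/N_n)`` with
    Welch–Satterthwaite degrees of freedom.  Groups smaller than 2 make the
    variance undefined; the result is then marked untestable and excluded
    from its FDR family.
    """
    a = np.asarray(important_scores, dtype=float)
    b = np.asarray(other_scores, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return TwoSampleResult(float("nan"), float("nan"), len(a), len(b), False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / len(a), vb / len(b)
    denom = math.sqrt(sa + sb)
    if denom == 0.0:
        # identical constants in both groups: no evidence either way
        return TwoSampleResult(0.0, 0.5, len(a), len(b), True)
    t = (a.mean() - b.mean()) / denom
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = float(scipy.stats.t.sf(t, df))
    return TwoSampleResult(float(t), p, len(a), len(b), True)


# exact Wilcoxon null enumeration only below this combined sample size
_WILCOXON_EXACT_LIMIT = 50


def wilcoxon_test(important_scores, other_scores) -> TwoSampleResult:
    """One-sided Wilcoxon rank-sum (Mann–Whitney) test, important > other.

    Exact null distribution for combined n <= 50 without ties; otherwise
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(important_scores, dtype=float)
    b = np.asarray(other_scores, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return TwoSampleResult(float("nan"), float("nan"), len(a), len(b), False)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (len(pooled) <= _WILCOXON_EXACT_LIMIT and not has_ties)
        else "asymptotic"
    )
    res = scipy.stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return TwoSampleResult(
        float(res.statistic), float(res.pvalue), len(a), len(b), True
    )


def bh_fdr(p_values, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment and rejection flags.

    Returns ``(adjusted p-values, flags)`` with ``flags = p_adj < level``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj < level


def fisher_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher Z comparison of two correlation coefficients.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * float(scipy.stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


# ---------------------------------------------------------------------------
# sensitivity scan

def sensitivity_scan(
    graphs: Sequence[PathwayGraph],
    important: GeneSet,
    alphas: Iterable[float] = DEFAULT_ALPHA_GRID,
    beta: float = 0.15,
) -> pd.DataFrame:
    """Quantile regression of all four PageRank variants across alphas.

    For each alpha the four variants are recomputed and refitted; the SSC
    and undirected fits are compared by Fisher Z.  Returns one row per
    (alpha, variant) with slope, adjusted r², fit correlation and — on SSC
    rows — the Fisher-Z z and p against the undirected fit at the same
    alpha.
    """
    variants = ("source", "sink", "ssc", "undirected")
    rows = []
    for alpha in alphas:
        params = CentralityParams(alpha=float(alpha), beta=beta)
        fits: dict[str, RegressionFit] = {}
        for variant in variants:
            profiles = [
                compute_centrality(g, "pagerank", variant, params) for g in graphs
            ]
            table = pool_quantiles(profiles, important)
            fits[variant] = fit_quantile_regression(table)
        for variant in variants:
            fit = fits[variant]
            row = {
                "alpha": float(alpha),
                "variant": variant,
                "slope": fit.slope,
                "adj_r_squared": fit.adj_r_squared,
                "r": fit.r,
                "n_bins": fit.n,
                "fisher_z": np.nan,
                "fisher_p": np.nan,
            }
            if variant == "ssc":
                other = fits["undirected"]
                if fit.n > 3 and other.n > 3:
                    z, p = fisher_z(fit.r, fit.n, other.r, other.n)
                    row["fisher_z"], row["fisher_p"] = z, p
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the Model / Results pair

class CentralityValidation:
    """End-to-end validation of centrality models on a pathway cohort.

    Parameters
    ----------
    graphs : sequence of PathwayGraph
        The pathway cohort (pre-filtering).
    important : GeneSet
        A-priori important gene identifiers (exact string match against
        graph node ids).
    models : sequence of (model, variant)
        The centrality variants to analyse; defaults to the twelve-variant
        standard set.
    params : mapping model -> CentralityParams, optional
        Overrides of the default per-model parameters.
    filter_config : FilterConfig, optional
        Pathway quality-filter thresholds.
    fdr_level : float
        FDR level for the per-pathway test families (default 0.05).
    """

    def __init__(
        self,
        graphs: Sequence[PathwayGraph],
        important: GeneSet,
        models: Sequence[tuple[str, str]] = DEFAULT_MODEL_SET,
        params: dict[str, CentralityParams] | None = None,
        filter_config: FilterConfig | None = None,
        fdr_level: float = 0.05,
    ):
        self.graphs = list(graphs)
        self.important = important
        self.models = tuple(models)
        self.params = dict(DEFAULT_PARAMS)
        if params:
            self.params.update(params)
        self.filter_config = filter_config or FilterConfig(models=self.models)
        self.fdr_level = fdr_level

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "CentralityValidation":
        """Build the model from a :class:`~sscentrality.synthetic.SyntheticCohort`."""
        return cls(cohort.graphs, cohort.important, **kwargs)

    def _profiles(self, kept, model, variant):
        profiles = []
        for g in kept:
            try:
                profiles.append(
                    compute_centrality(g, model, variant, self.params[model])
                )
            except ConvergenceError:
                continue  # parameter inadmissible on this single graph
        return profiles

    def fit(self) -> "ValidationResults":
        kept, reports = filter_pathways(
            self.graphs, self.important, self.filter_config
        )
        if not kept:
            raise ValueError("no pathways pass the quality filters")
        regression_rows = []
        ks_rows = []
        test_rows = []
        for model, variant in self.models:
            label = f"{model}-{variant}"
            profiles = self._profiles(kept, model, variant)
            if not profiles:
                continue
            table = pool_quantiles(profiles, self.important)
            fit = fit_quantile_regression(table)
            for term, est, se, t, p in (
                ("intercept", fit.intercept, fit.intercept_se, fit.intercept_t,
                 fit.intercept_p),
                ("slope", fit.slope, fit.slope_se, fit.slope_t, fit.slope_p),
            ):
                regression_rows.append(
                    {
                        "centrality": label,
                        "term": term,
                        "estimate": est,
                        "std_error": se,
                        "statistic": t,
                        "p_value": p,
                        "adj_r_squared": fit.adj_r_squared,
                        "n_bins": fit.n,
                    }
                )
            pooled = pooled_quantile_scores(profiles, self.important)
            imp_q = pooled.loc[pooled["is_important"], "quantile"].to_numpy(float)
            oth_q = pooled.loc[~pooled["is_important"], "quantile"].to_numpy(float)
            if len(imp_q) and len(oth_q):
                d, p = ks_cdf_compare(imp_q, oth_q)
                ks_rows.append(
                    {
                        "centrality": label,
                        "ks_statistic": d,
                        "ks_p_value": p,
                        "n_important": len(imp_q),
                        "n_other": len(oth_q),
                    }
                )
            for profile in profiles:
                mask = np.fromiter(
                    (v in self.important for v in profile.nodes),
                    dtype=bool, count=len(profile.nodes),
                )
                imp_scores = profile.scores[mask]
                oth_scores = profile.scores[~mask]
                for test_name, func in (("welch", welch_test), ("wilcoxon", wilcoxon_test)):
                    res = func(imp_scores, oth_scores)
                    test_rows.append(
                        {
                            "centrality": label,
                            "pathway_id": profile.pathway_id,
                            "test": test_name,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "n_important": res.n_important,
                            "n_other": res.n_other,
                            "testable": res.testable,
                        }
                    )
        tests = pd.DataFrame(test_rows)
        if len(tests):
            tests["p_adjusted"] = np.nan
            tests["significant"] = False
            for _, idx in tests.groupby(["centrality", "test"]).groups.items():
                fam = tests.loc[idx]
                ok = fam.index[fam["testable"].to_numpy(bool)]
                if len(ok):
                    adj, flags = bh_fdr(
                        tests.loc[ok, "p_value"].to_numpy(), self.fdr_level
                    )
                    tests.loc[ok, "p_adjusted"] = adj
                    tests.loc[ok, "significant"] = flags
        return ValidationResults(
            model=self,
            filter_reports=filter_report_frame(reports),
            regression=pd.DataFrame(regression_rows),
            ks=pd.DataFrame(ks_rows),
            pathway_tests=tests,
            n_kept=len(kept),
        )

    def sensitivity(
        self,
        alphas: Iterable[float] = DEFAULT_ALPHA_GRID,
        beta: float | None = None,
    ) -> pd.DataFrame:
        """Run the PageRank alpha-sensitivity scan on the filtered cohort."""
        kept, _ = filter_pathways(self.graphs, self.important, self.filter_config)
        if beta is None:
            beta = self.params["pagerank"].beta
        return sensitivity_scan(kept, self.important, alphas=alphas, beta=beta)


class ValidationResults:
    """Tidy result tables of a fitted :class:`CentralityValidation`."""

    def __init__(self, model, filter_reports, regression, ks, pathway_tests, n_kept):
        self.model = model
        self.filter_reports = filter_reports
        self.regression = regression
        self.ks = ks
        self.pathway_tests = pathway_tests
        self.n_kept = n_kept

    def regression_fit(self, model: str, variant: str) -> dict:
        """Slope-row summary for one centrality variant."""
        label = f"{model}-{variant}"
        sel = self.regression[
            (self.regression["centrality"] == label)
            & (self.regression["term"] == "slope")
        ]
        if sel.empty:
            raise KeyError(f"no regression fit for {label}")
        return sel.iloc[0].to_dict()

    def n_significant(self, model: str, variant: str, test: str) -> int:
        label = f"{model}-{variant}"
        sel = self.pathway_tests
        if sel.empty:
            return 0
        sel = sel[(sel["centrality"] == label) & (sel["test"] == test)]
        return int(sel["significant"].sum())

    def summary(self) -> str:
        lines = [
            "Source/Sink centrality validation",
            "=" * 50,
            f"pathways analysed: {self.n_kept} kept / "
            f"{len(self.filter_reports)} input",
            f"important genes:   {len(self.model.important)}",
            f"FDR level:         {self.model.fdr_level}",
            "",
            "Quantile regression (importance fraction ~ quantile)",
            "-" * 50,
        ]
        slopes = self.regression[self.regression["term"] == "slope"]
        header = f"{'centrality':<22}{'slope':>10}{'p':>12}{'adj r2':>9}"
        lines.append(header)
        for _, row in slopes.iterrows():
            lines.append(
                f"{row['centrality']:<22}{row['estimate']:>10.4f}"
                f"{row['p_value']:>12.3e}{row['adj_r_squared']:>9.3f}"
            )
        if len(self.ks):
            lines += ["", "CDF comparison (one-sided KS)", "-" * 50]
            for _, row in self.ks.iterrows():
                lines.append(
                    f"{row['centrality']:<22}D={row['ks_statistic']:.4f}"
                    f"  p={row['ks_p_value']:.3e}"
                )
        if len(self.pathway_tests):
            lines += ["", f"Pathways significant at FDR<{self.model.fdr_level}",
                      "-" * 50]
            counts = (
                self.pathway_tests.groupby(["centrality", "test"])["significant"]
                .sum()
                .unstack(fill_value=0)
            )
            for label, row in counts.iterrows():
                lines.append(
                    f"{label:<22}welch={int(row.get('welch', 0)):>4}"
                    f"  wilcoxon={int(row.get('wilcoxon', 0)):>4}"
                )
        return "\n".join(lines)

    def to_files(self, directory) -> None:
        """Write the report tables as TSV files."""
        import os

        os.makedirs(directory, exist_ok=True)
        self.filter_reports.to_csv(
            os.path.join(directory, "filter_report.tsv"), sep="\t", index=False
        )
        self.regression.to_csv(
            os.path.join(directory, "regression.tsv"), sep="\t", index=False
        )
        self.ks.to_csv(os.path.join(directory, "ks.tsv"), sep="\t", index=False)
        self.pathway_tests.to_csv(
            os.path.join(directory, "pathway_tests.tsv"), sep="\t", index=False
        )
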