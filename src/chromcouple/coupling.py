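"""Coupling between promoter H3K27me3 loss and expression change.

Two views of the same question. The rank plot sorts all genes by promoter
H3K27me3 log2 fold change (+Dox/−Dox) and draws the mean expression log2
fold change in a sliding window of 1000 genes along that ranking; coupling
shows up as elevated window means at the demethylated (left) end.

PAGE (parametric analysis of gene set enrichment) tests whether a gene
set's mean value differs from the parent distribution:

    z = (Sm − μ) · √m / σ

with Sm the set mean over m members and μ, σ the parent mean and standard
deviation; p comes from the standard normal tail. By the central limit
theorem z is approximately standard normal under the null for moderate m
regardless of the parent's shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankPlotSeries",
    "rank_sliding_window",
    "PageResult",
    "page_statistic",
    "CouplingReport",
    "coupling_report",
]


@dataclass
class RankPlotSeries:
    """Sliding-window curve over the demethylation ranking.

    ``gene_order`` is every gene sorted ascending by ``k27_log2fc`` (stable,
    ties broken by input order); ``window_means[i]`` is the mean
    ``expr_log2fc`` over ranks [i·step, i·step + window_size).
    """

    gene_order: pd.Index
    k27_sorted: np.ndarray
    window_starts: np.ndarray
    window_means: np.ndarray
    window_size: int
    step: int

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per gene rank, window mean at window starts."""
        df = pd.DataFrame(
            {
                "rank": np.arange(self.gene_order.size),
                "gene_id": self.gene_order,
                "k27_log2fc": self.k27_sorted,
                "window_mean_expr_log2fc": np.nan,
            }
        )
        df.loc[self.window_starts, "window_mean_expr_log2fc"] = self.window_means
        return df


def rank_sliding_window(
    k27_log2fc: pd.Series,
    expr_log2fc: pd.Series,
    window_size: int = 1000,
    step: int = 1,
) -> RankPlotSeries:
    """Sort genes by H3K27me3 log2FC and average expression log2FC in windows."""
    if not k27_log2fc.index.equals(expr_log2fc.index):
        raise ValueError("k27 and expression series must share one gene universe")
    n = k27_log2fc.size
    if n < window_size:
        raise ValueError(
            f"{n} genes < window_size {window_size}; use a smaller window"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    order = np.argsort(k27_log2fc.to_numpy(), kind="stable")
    expr_sorted = expr_log2fc.to_numpy()[order]
    windows = np.lib.stride_tricks.sliding_window_view(expr_sorted, window_size)
    starts = np.arange(0, n - window_size + 1, step)
    means = windows[starts].mean(axis=1)
    return RankPlotSeries(
        gene_order=k27_log2fc.index[order],
        k27_sorted=k27_log2fc.to_numpy()[order],
        window_starts=starts,
        window_means=means,
        window_size=window_size,
        step=step,
    )


@dataclass
class PageResult:
    m: int
    set_mean: float
    parent_mean: float
    parent_sd: float
    z: float
    p: float
    alternative: str

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "m": self.m,
            "set_mean": self.set_mean,
            "parent_mean": self.parent_mean,
            "parent_sd": self.parent_sd,
            "z": self.z,
            "p": self.p,
            "alternative": self.alternative,
        }


def page_statistic(
    parent_values: pd.Series,
    set_members: set[str] | pd.Index | list[str],
    alternative: str = "two-sided",
) -> PageResult:
    """PAGE z and p for one gene set against its parent distribution."""
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    members = pd.Index(set_members)
    missing = members.difference(parent_values.index)
    if len(missing):
        raise ValueError(f"set members outside parent universe: {missing[:10].tolist()}")
    m = len(members)
    if m == 0:
        raise ValueError("empty gene set")
    values = parent_values.to_numpy(dtype=float)
    mu = float(values.mean())
    sigma = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sigma <= 0:
        raise ValueError("parent distribution has zero variance")
    sm = float(parent_values.loc[members].mean())
    z = (sm - mu) * np.sqrt(m) / sigma
    if alternative == "two-sided":
        p = min(2.0 * float(stats.norm.sf(abs(z))), 1.0)
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    else:
        p = float(stats.norm.cdf(z))
    return PageResult(
        m=m, set_mean=sm, parent_mean=mu, parent_sd=sigma,
        z=float(z), p=p, alternative=alternative,
    )


@dataclass
class CouplingReport:
    """PAGE in both framings plus the rank-plot series.

    ``page_demethylated_set``: set = strictly demethylated genes, values =
    expression log2FC (primary framing: are demethylated genes upregulated?).
    ``page_upregulated_set``: set = up-called genes, values = H3K27me3
    log2FC (reciprocal framing).
    """

    page_demethylated_set: PageResult
    page_upregulated_set: PageResult | None
    rank_series: RankPlotSeries
    params: dict = field(default_factory=dict)


def coupling_report(
    calls,
    de,
    window_size: int = 1000,
    step: int = 1,
    alternative: str = "two-sided",
    relaxed: bool = False,
) -> CouplingReport:
    """Full coupling analysis from state/demethylation calls and DE results.

    ``calls`` is a StateAndDemethylationCalls, ``de`` a DiffExprResult over
    the same gene universe.
    """
    k27 = calls.k27_log2fc
    expr = de.expr_log2fc
    if not k27.index.equals(expr.index):
        raise ValueError("calls and DE results must share one gene universe")
    dem = calls.demethylated_genes(relaxed=relaxed)
    page_dem = page_statistic(expr, dem, alternative=alternative)
    up = de.genes("up")
    page_up = (
        page_statistic(k27, up, alternative=alternative) if len(up) else None
    )
    series = rank_sliding_window(k27, expr, window_size=window_size, step=step)
    return CouplingReport(
        page_demethylated_set=page_dem,
        page_upregulated_set=page_up,
        rank_series=series,
        params={
            "window_size": window_size,
            "step": step,
            "alternative": alternative,
            "relaxed": relaxed,
        },
    )
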