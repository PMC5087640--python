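"""Expression-side filters: differential calls and z-augmented upregulation.

Two filters are implemented. ``differential_genes`` is the fold-change
rule used for the +Dox/−Dox comparison: a gene must clear FPKM > 4 in at
least one of the two conditions (otherwise it is ``filtered``) and is
``up``/``down`` when its pseudocounted fold change exceeds the threshold or
falls below its reciprocal. ``zscore_upregulated`` is the replicate-aware
rule used for cross-cell-type comparisons: fold change above a (large)
threshold plus a two-sample z on log2 FPKM above 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionTable

__all__ = [
    "DiffExprResult",
    "differential_genes",
    "zscore_upregulated",
    "intersect_gene_lists",
]


@dataclass
class DiffExprResult:
    """Per-gene expression log2 fold change and call.

    ``table`` columns: fpkm_ref, fpkm_alt, expr_fc, expr_log2fc,
    call ∈ {up, down, unchanged, filtered}; indexed by gene_id.
    """

    table: pd.DataFrame
    ref_condition: str
    alt_condition: str
    params: dict = field(default_factory=dict)

    @property
    def expr_log2fc(self) -> pd.Series:
        return self.table["expr_log2fc"]

    def genes(self, call: str) -> pd.Index:
        return self.table.index[self.table["call"] == call]

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    @property
    def n_differential(self) -> int:
        return self.n_up + self.n_down


def differential_genes(
    expr: ExpressionTable,
    ref_condition: str,
    alt_condition: str,
    fc_threshold: float = 2.0,
    min_fpkm: float = 4.0,
    pseudocount: float = 0.1,
) -> DiffExprResult:
    """Fold-change differential filter (FC > 2, FPKM > 4 by default).

    Replicates within a condition are averaged first. The expression floor
    applies to the larger of the two condition means, so a gene silent in
    the reference but induced in the alternative stays eligible. Down-calls
    use the reciprocal threshold (FC < 1/fc_threshold).
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    for cond in (ref_condition, alt_condition):
        if cond not in expr.conditions:
            raise ValueError(
                f"condition {cond!r} not in table (has {expr.conditions})"
            )
    ref = expr.condition_mean(ref_condition)
    alt = expr.condition_mean(alt_condition)
    fc = (alt + pseudocount) / (ref + pseudocount)
    expressed = np.maximum(ref, alt) > min_fpkm
    call = np.where(
        ~expressed, "filtered",
        np.where(fc > fc_threshold, "up",
                 np.where(fc < 1.0 / fc_threshold, "down", "unchanged")),
    )
    table = pd.DataFrame(
        {
            "fpkm_ref": ref,
            "fpkm_alt": alt,
            "expr_fc": fc,
            "expr_log2fc": np.log2(fc),
            "call": pd.Categorical(
                call, categories=["up", "down", "unchanged", "filtered"]
            ),
        },
        index=ref.index,
    )
    return DiffExprResult(
        table=table,
        ref_condition=ref_condition,
        alt_condition=alt_condition,
        params={
            "fc_threshold": fc_threshold,
            "min_fpkm": min_fpkm,
            "pseudocount": pseudocount,
        },
    )


def zscore_upregulated(
    expr: ExpressionTable,
    target_condition: str,
    ref_condition: str,
    fc_threshold: float = 4.0,
    z_threshold: float | None = 4.0,
    pseudocount: float = 0.1,
) -> pd.Index:
    """Genes with FC above ``fc_threshold`` and z above ``z_threshold``.

    z = (mean_t − mean_r) / sqrt(se_t² + se_r²) computed on log2(FPKM + ε)
    across replicates; the fold change is taken on the raw condition means.
    With identical means and zero spread z is defined as 0 (no evidence);
    with different means and zero spread it is ±inf. ``z_threshold=None``
    disables the z part (fold-change-only filter). Requires ≥2 replicates
    per condition when the z filter is active.
    """
    means = {}
    ses = {}
    for cond in (target_condition, ref_condition):
        reps = expr.replicate_values(cond)
        if z_threshold is not None and reps.shape[1] < 2:
            raise ValueError(
                f"condition {cond!r} has {reps.shape[1]} replicate(s); the z "
                "filter needs >= 2. Use z_threshold=None for the FC-only filter."
            )
        logged = np.log2(reps + pseudocount)
        means[cond] = logged.mean(axis=1)
        n = reps.shape[1]
        ses[cond] = logged.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else 0.0
    fc = (
        expr.condition_mean(target_condition) + pseudocount
    ) / (expr.condition_mean(ref_condition) + pseudocount)
    passes = fc > fc_threshold
    if z_threshold is not None:
        diff = means[target_condition] - means[ref_condition]
        denom = np.sqrt(ses[target_condition] ** 2 + ses[ref_condition] ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = diff / denom
        z = z.where(~((diff == 0) & (denom == 0)), 0.0)
        z = z.mask((diff != 0) & (denom == 0), np.sign(diff) * np.inf)
        passes &= z > z_threshold
    return expr.df.index[passes]


def intersect_gene_lists(
    a: pd.Index | list[str], b: pd.Index | list[str]
) -> dict[str, float | int]:
    """Overlap of two gene lists: count and fraction of the first list."""
    sa, sb = set(a), set(b)
    n = len(sa & sb)
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "n_overlap": n,
        "fraction_of_a": n / len(sa) if sa else float("nan"),
    }
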