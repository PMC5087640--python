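"""Promoter chromatin-state classification and H3K27me3 demethylation calls.

A promoter is Bivalent when both H3K4me3 and H3K27me3 occupancy exceed the
state threshold (strictly) in the uninduced condition, K4me3/K27me3 when
only one does, NoMark otherwise. Demethylation is called from the promoter
H3K27me3 fold change (+Dox/−Dox) with a symmetric pseudocount: strict below
0.5, relaxed below 0.66 (strict inequalities throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "classify_chromatin_state",
    "call_demethylation",
    "StateAndDemethylationCalls",
    "make_calls",
    "summarize_states",
    "StateSummary",
    "format_demethylation_summary",
    "overlap_with_reference_list",
]

STATES = ("K4me3", "K27me3", "Bivalent", "NoMark")


def _check_universe(a: pd.Series, b: pd.Series, what: str) -> None:
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index).tolist()
        only_b = b.index.difference(a.index).tolist()
        raise ValueError(
            f"gene universes differ for {what}: "
            f"only in first={only_a[:10]}, only in second={only_b[:10]}"
        )


def classify_chromatin_state(
    k4: pd.Series, k27: pd.Series, threshold: float = 20.0
) -> pd.Series:
    """Four-way state from uninduced H3K4me3/H3K27me3 promoter occupancy.

    The threshold is exclusive: occupancy exactly at the threshold does not
    count as marked.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    _check_universe(k4, k27, "state classification")
    k4_on = k4.to_numpy() > threshold
    k27_on = k27.to_numpy() > threshold
    state = np.where(
        k4_on & k27_on, "Bivalent",
        np.where(k4_on, "K4me3", np.where(k27_on, "K27me3", "NoMark")),
    )
    return pd.Series(
        pd.Categorical(state, categories=STATES), index=k4.index, name="state"
    )


def call_demethylation(
    k27_minus: pd.Series,
    k27_plus: pd.Series,
    pseudocount: float = 0.1,
    strict_fc: float = 0.5,
    relaxed_fc: float = 0.66,
) -> pd.DataFrame:
    """Promoter H3K27me3 fold change and demethylation flags per gene.

    FC = (occ_plus + ε) / (occ_minus + ε); the pseudocount keeps the fold
    change finite and maps equal occupancies to exactly 1. Returns columns
    ``k27_fc``, ``k27_log2fc``, ``demethylated_strict``,
    ``demethylated_relaxed``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not (0 < strict_fc < relaxed_fc < 1):
        raise ValueError("require 0 < strict_fc < relaxed_fc < 1")
    _check_universe(k27_minus, k27_plus, "demethylation call")
    if (k27_minus < 0).any() or (k27_plus < 0).any():
        raise ValueError("occupancies must be >= 0")
    fc = (k27_plus + pseudocount) / (k27_minus + pseudocount)
    return pd.DataFrame(
        {
            "k27_fc": fc,
            "k27_log2fc": np.log2(fc),
            "demethylated_strict": fc < strict_fc,
            "demethylated_relaxed": fc < relaxed_fc,
        },
        index=k27_minus.index,
    )


@dataclass
class StateAndDemethylationCalls:
    """Per-gene state + demethylation table and the thresholds that made it.

    ``table`` columns: state, k27_fc, k27_log2fc, demethylated_strict,
    demethylated_relaxed, indexed by gene_id.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def states(self) -> pd.Series:
        return self.table["state"]

    @property
    def k27_log2fc(self) -> pd.Series:
        return self.table["k27_log2fc"]

    def demethylated_genes(self, relaxed: bool = False) -> pd.Index:
        col = "demethylated_relaxed" if relaxed else "demethylated_strict"
        return self.table.index[self.table[col]]


def make_calls(
    k4_minus: pd.Series,
    k27_minus: pd.Series,
    k27_plus: pd.Series,
    state_threshold: float = 20.0,
    pseudocount: float = 0.1,
    strict_fc: float = 0.5,
    relaxed_fc: float = 0.66,
) -> StateAndDemethylationCalls:
    """Classify states (on −Dox occupancy) and call demethylation in one go."""
    state = classify_chromatin_state(k4_minus, k27_minus, threshold=state_threshold)
    dem = call_demethylation(
        k27_minus, k27_plus,
        pseudocount=pseudocount, strict_fc=strict_fc, relaxed_fc=relaxed_fc,
    )
    table = pd.concat([state, dem], axis=1)
    return StateAndDemethylationCalls(
        table=table,
        params={
            "state_threshold": state_threshold,
            "pseudocount": pseudocount,
            "strict_fc": strict_fc,
            "relaxed_fc": relaxed_fc,
        },
    )


@dataclass
class StateSummary:
    """Counts per state and demethylation rates within the bivalent class."""

    state_counts: dict[str, int]
    n_bivalent: int
    n_bivalent_demethylated_strict: int
    n_bivalent_demethylated_relaxed: int
    pct_bivalent_demethylated_strict: int | None
    pct_bivalent_demethylated_relaxed: int | None


def _pct(n: int, total: int) -> int | None:
    """Percentage rounded to the nearest integer; None when undefined."""
    if total == 0:
        return None
    return int(round(100.0 * n / total))


def summarize_states(calls: StateAndDemethylationCalls) -> StateSummary:
    """Contingency summary: per-state counts and bivalent demethylation rates."""
    t = calls.table
    counts = t["state"].value_counts().to_dict()
    state_counts = {s: int(counts.get(s, 0)) for s in STATES}
    biv = t[t["state"] == "Bivalent"]
    n_biv = len(biv)
    n_strict = int(biv["demethylated_strict"].sum())
    n_relaxed = int(biv["demethylated_relaxed"].sum())
    return StateSummary(
        state_counts=state_counts,
        n_bivalent=n_biv,
        n_bivalent_demethylated_strict=n_strict,
        n_bivalent_demethylated_relaxed=n_relaxed,
        pct_bivalent_demethylated_strict=_pct(n_strict, n_biv),
        pct_bivalent_demethylated_relaxed=_pct(n_relaxed, n_biv),
    )


def format_demethylation_summary(
    n_bivalent: int, n_strict: int, n_relaxed: int
) -> str:
    """Human-readable one-liner for the bivalent demethylation rates."""
    if n_bivalent == 0:
        return "No bivalent promoters; demethylation percentages undefined."
    return (
        f"Of the {n_bivalent} bivalent genes, {n_strict} "
        f"({_pct(n_strict, n_bivalent)}%) promoters were H3K27me3-demethylated "
        f"(fold change < 0.5); at the relaxed threshold (fold change < 0.66) "
        f"the number increased ({n_relaxed} genes, "
        f"{_pct(n_relaxed, n_bivalent)}%)."
    )


def overlap_with_reference_list(
    calls: StateAndDemethylationCalls, reference_bivalent: set[str]
) -> dict[str, float | int]:
    """Compare the called bivalent set with an externally supplied list.

    Returns the called-set size, overlap count, and the fraction of called
    bivalent genes present in the reference list.
    """
    called = set(calls.table.index[calls.states == "Bivalent"])
    inter = called & set(reference_bivalent)
    return {
        "n_called_bivalent": len(called),
        "n_reference": len(reference_bivalent),
        "n_overlap": len(inter),
        "fraction_of_called": len(inter) / len(called) if called else float("nan"),
    }
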