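"""Synthetic input bundles with planted chromatin states and coupling.

The generator emulates the structure the analysis assumes: a small genome
of non-overlapping genes; H3K4me3/H3K27me3 promoter plateaus for the
planted state of each gene; a −Dox/+Dox condition pair in which a planted
fraction of bivalent promoters lose most of their H3K27me3 signal; and
FPKM tables in which demethylated genes carry a planted positive log2
fold-change shift on top of log-normal noise.

Promoter signal is a flat-top plateau (TSS ± 2 kb) with linear shoulders;
bin counts are drawn negative-binomially around the mean profile
(dispersion ``inf`` recovers Poisson). Signal levels are parametrized on
the depth-normalized scale so the defaults land marked-promoter occupancy
well above the state threshold of 20 and background well below it.

Randomness derives from one seed with a fixed substream per component
(placement, states, expression, each coverage track), so adding a track
never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    GeneModelSet,
    write_coverage,
    write_expression_table,
    write_gene_models,
    write_genome,
)

__all__ = [
    "SimParams",
    "SimBundle",
    "simulate_dataset",
    "write_bundle",
    "read_bundle",
    "evaluate_recovery",
    "RecoveryMetrics",
    "MARK_K4",
    "MARK_K27",
    "COND_MINUS",
    "COND_PLUS",
]

MARK_K4 = "H3K4me3"
MARK_K27 = "H3K27me3"
COND_MINUS = "minus_dox"
COND_PLUS = "plus_dox"

# substream ids for the shared seed
_STREAM_PLACEMENT = 0
_STREAM_STATES = 1
_STREAM_EXPRESSION = 2
_STREAM_TRACKS = {
    (MARK_K27, COND_MINUS): 10,
    (MARK_K27, COND_PLUS): 11,
    (MARK_K4, COND_MINUS): 12,
    (MARK_K4, COND_PLUS): 13,
}


@dataclass
class SimParams:
    """Generator settings; defaults are the reference study conditions."""

    n_genes: int = 400
    n_chroms: int = 2
    bin_width: int = 50
    seed: int = 0
    # chromatin-state proportions (bivalent, K4-only, K27-only, no mark)
    p_bivalent: float = 0.3
    p_k4: float = 0.3
    p_k27: float = 0.2
    p_nomark: float = 0.2
    # demethylation plan
    p_demethylation: float = 0.4
    include_k27_only_demethylation: bool = False
    demethylation_effect: float = 0.2    # multiplier on the +Dox K27 plateau
    # expression coupling
    coupling_delta: float = 1.0          # log2 shift for demethylated genes
    # geometry (bp)
    promoter_halfwidth: int = 2000
    shoulder_width: int = 500
    gene_length_min: int = 2000
    gene_length_max: int = 8000
    gene_spacing: int = 12000
    edge_margin: int = 9000
    # signal levels: targets on the depth-normalized (per-million-bins) scale
    background_level: float = 2.5
    promoter_level: float = 45.0
    background_count: float = 5.0        # raw mean counts per background bin
    nb_dispersion: float = 20.0          # NB size; math.inf -> Poisson
    # expression model
    fpkm_log2_mean: float = 3.0
    fpkm_log2_sd: float = 1.5
    expr_noise_sd: float = 0.25          # log2, condition-level
    replicate_noise_sd: float = 0.15     # log2, per replicate
    n_replicates: int = 2
    genome_size: int | None = None       # optional total-bp budget

    def validate(self) -> None:
        props = (self.p_bivalent, self.p_k4, self.p_k27, self.p_nomark)
        if any(p < 0 or p > 1 for p in props) or abs(sum(props) - 1) > 1e-9:
            raise ValueError("state proportions must lie in [0,1] and sum to 1")
        if not 0 <= self.p_demethylation <= 1:
            raise ValueError("p_demethylation must lie in [0,1]")
        if self.gene_length_min < 1 or self.gene_length_max < self.gene_length_min:
            raise ValueError("bad gene length range")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")


@dataclass
class SimBundle:
    """One complete simulated input set plus its ground truth."""

    genes: GeneModelSet
    tracks: dict[tuple[str, str], CoverageTrack]
    expression: ExpressionTable
    truth: pd.DataFrame  # gene_id-indexed: state, demethylated, expr_shift
    params: SimParams


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _place_genes(params: SimParams) -> GeneModelSet:
    rng = _substream(params.seed, _STREAM_PLACEMENT)
    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    genome: dict[str, int] = {}
    gi = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = params.edge_margin
        for _ in range(n_here):
            length = int(rng.integers(params.gene_length_min,
                                      params.gene_length_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gi:04d}", chrom, pos, pos + length, strand))
            gi += 1
            pos += length + params.gene_spacing
        chrom_len = pos - params.gene_spacing + params.edge_margin
        # round up to a whole number of bins so files round-trip exactly
        chrom_len = math.ceil(chrom_len / params.bin_width) * params.bin_width
        genome[chrom] = chrom_len
    total = sum(genome.values())
    if params.genome_size is not None and params.genome_size < total:
        raise ValueError(
            f"genome_size {params.genome_size} too small for {params.n_genes} "
            f"genes at >= {params.gene_spacing} bp spacing; need >= {total} bp"
        )
    return GeneModelSet(genes, genome)


def _assign_truth(params: SimParams, genes: GeneModelSet) -> pd.DataFrame:
    rng = _substream(params.seed, _STREAM_STATES)
    props = [params.p_bivalent, params.p_k4, params.p_k27, params.p_nomark]
    labels = np.array(["Bivalent", "K4me3", "K27me3", "NoMark"])
    states = labels[rng.choice(4, size=len(genes), p=props)]
    eligible = (states == "Bivalent")
    if params.include_k27_only_demethylation:
        eligible |= states == "K27me3"
    flags = eligible & (rng.random(len(genes)) < params.p_demethylation)
    return pd.DataFrame(
        {
            "state": states,
            "demethylated": flags,
            "expr_shift": np.where(flags, params.coupling_delta, 0.0),
        },
        index=pd.Index(genes.gene_ids, name="gene_id"),
    )


def _mean_profile(
    params: SimParams,
    genes: GeneModelSet,
    marked: pd.Series,
    attenuation: pd.Series,
) -> dict[str, np.ndarray]:
    """Per-bin expected counts: background plus per-gene promoter bumps.

    ``attenuation`` multiplies the promoter enhancement (1 = full signal,
    e.g. 0.2 after demethylation).
    """
    peak = params.background_count * params.promoter_level / params.background_level
    enh_full = peak - params.background_count
    bw = params.bin_width
    means = {
        chrom: np.full(-(-length // bw), params.background_count, dtype=float)
        for chrom, length in genes.genome.items()
    }
    hw, sh = params.promoter_halfwidth, params.shoulder_width
    for g in genes:
        if not marked.loc[g.gene_id]:
            continue
        enh = enh_full * attenuation.loc[g.gene_id]
        arr = means[g.chrom]
        lo_bin = max((g.tss - hw - sh) // bw, 0)
        hi_bin = min((g.tss + hw + sh) // bw + 1, arr.size)
        centers = (np.arange(lo_bin, hi_bin) + 0.5) * bw
        d = np.abs(centers - g.tss)
        shape = np.clip((hw + sh - d) / sh, 0.0, 1.0)  # plateau w/ shoulders
        arr[lo_bin:hi_bin] += enh * shape
    return means


def _draw_counts(
    rng: np.random.Generator, means: dict[str, np.ndarray], dispersion: float
) -> dict[str, np.ndarray]:
    out = {}
    for chrom, mu in means.items():
        if math.isinf(dispersion):
            out[chrom] = rng.poisson(mu).astype(float)
        else:
            r = dispersion
            out[chrom] = rng.negative_binomial(r, r / (r + mu)).astype(float)
    return out


def _simulate_tracks(
    params: SimParams, genes: GeneModelSet, truth: pd.DataFrame
) -> dict[tuple[str, str], CoverageTrack]:
    ones = pd.Series(1.0, index=truth.index)
    atten_plus = pd.Series(
        np.where(truth["demethylated"], params.demethylation_effect, 1.0),
        index=truth.index,
    )
    marked_k27 = truth["state"].isin(["Bivalent", "K27me3"])
    marked_k4 = truth["state"].isin(["Bivalent", "K4me3"])
    plan = {
        (MARK_K27, COND_MINUS): (marked_k27, ones),
        (MARK_K27, COND_PLUS): (marked_k27, atten_plus),
        (MARK_K4, COND_MINUS): (marked_k4, ones),
        (MARK_K4, COND_PLUS): (marked_k4, ones),
    }
    tracks = {}
    for (mark, cond), (marked, atten) in plan.items():
        means = _mean_profile(params, genes, marked, atten)
        rng = _substream(params.seed, _STREAM_TRACKS[(mark, cond)])
        counts = _draw_counts(rng, means, params.nb_dispersion)
        tracks[(mark, cond)] = CoverageTrack(
            mark=mark, condition=cond, bin_width=params.bin_width,
            values=counts, genome=dict(genes.genome),
        )
    return tracks


def _simulate_expression(
    params: SimParams, truth: pd.DataFrame
) -> ExpressionTable:
    rng = _substream(params.seed, _STREAM_EXPRESSION)
    n = len(truth)
    base_log2 = rng.normal(params.fpkm_log2_mean, params.fpkm_log2_sd, size=n)
    shift = truth["expr_shift"].to_numpy() + rng.normal(
        0.0, params.expr_noise_sd, size=n
    )
    cond_log2 = {COND_MINUS: base_log2, COND_PLUS: base_log2 + shift}
    cols = {}
    for cond in (COND_MINUS, COND_PLUS):
        for rep in range(1, params.n_replicates + 1):
            noise = rng.normal(0.0, params.replicate_noise_sd, size=n)
            cols[f"{cond}:rep{rep}"] = 2.0 ** (cond_log2[cond] + noise)
    df = pd.DataFrame(cols, index=truth.index)
    return ExpressionTable(df)


def simulate_dataset(params: SimParams | None = None) -> SimBundle:
    """Generate one complete bundle; identical seeds give identical bundles."""
    params = params or SimParams()
    params.validate()
    genes = _place_genes(params)
    truth = _assign_truth(params, genes)
    tracks = _simulate_tracks(params, genes, truth)
    expression = _simulate_expression(params, truth)
    return SimBundle(
        genes=genes, tracks=tracks, expression=expression,
        truth=truth, params=params,
    )


# ---------------------------------------------------------------------------
# on-disk bundles

def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Write a ready-to-run directory (chrom sizes, BED, bedGraphs, TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(bundle.genes.genome, outdir / "genome.tsv")
    write_gene_models(bundle.genes, outdir / "genes.bed")
    for (mark, cond), track in bundle.tracks.items():
        write_coverage(track, outdir / f"{mark}_{cond}.bedGraph")
    write_expression_table(bundle.expression, outdir / "expression.tsv")
    truth = bundle.truth.copy()
    truth.insert(0, "gene_id", truth.index)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(bundle.params), fh, sort_keys=False)


def read_bundle(indir: str | Path) -> SimBundle:
    """Read a directory written by :func:`write_bundle`."""
    from .io import read_coverage, read_expression_table, read_gene_models, read_genome

    indir = Path(indir)
    with open(indir / "params.yaml") as fh:
        params = SimParams(**yaml.safe_load(fh))
    genome = read_genome(indir / "genome.tsv")
    genes = read_gene_models(indir / "genes.bed", genome)
    tracks = {}
    for (mark, cond) in _STREAM_TRACKS:
        tracks[(mark, cond)] = read_coverage(
            indir / f"{mark}_{cond}.bedGraph", genome,
            bin_width=params.bin_width, mark=mark, condition=cond,
        )
    expression = read_expression_table(indir / "expression.tsv")
    truth = pd.read_csv(indir / "truth.tsv", sep="\t", index_col="gene_id")
    return SimBundle(
        genes=genes, tracks=tracks, expression=expression,
        truth=truth, params=params,
    )


# ---------------------------------------------------------------------------
# recovery metrics

@dataclass
class RecoveryMetrics:
    """How well the pipeline recovered the planted structure."""

    state_accuracy: float
    state_confusion: pd.DataFrame
    demethylation_sensitivity: float
    demethylation_specificity: float
    recovered_delta: float
    n_genes: int
    n_planted_demethylated: int
    extras: dict = field(default_factory=dict)


def evaluate_recovery(calls, de, truth: pd.DataFrame) -> RecoveryMetrics:
    """Confusion and effect-recovery metrics against the planted truth.

    ``calls`` is a StateAndDemethylationCalls, ``de`` a DiffExprResult on
    the same gene universe as ``truth``. Sensitivity/specificity are for
    the strict demethylation call against the planted flag, over all genes.
    The recovered coupling effect is the difference in mean expression
    log2FC between planted-demethylated and untouched genes.
    """
    if not calls.table.index.equals(truth.index):
        raise ValueError("calls and truth must share one gene universe")
    called_state = calls.states.astype(str)
    true_state = truth["state"].astype(str)
    accuracy = float((called_state == true_state).mean())
    confusion = pd.crosstab(true_state, called_state)
    flag = truth["demethylated"].to_numpy(dtype=bool)
    called = calls.table["demethylated_strict"].to_numpy(dtype=bool)
    tp = int((called & flag).sum())
    tn = int((~called & ~flag).sum())
    sens = tp / flag.sum() if flag.any() else float("nan")
    spec = tn / (~flag).sum() if (~flag).any() else float("nan")
    expr_fc = de.expr_log2fc.to_numpy()
    delta_hat = (
        float(expr_fc[flag].mean() - expr_fc[~flag].mean())
        if flag.any() and (~flag).any() else float("nan")
    )
    return RecoveryMetrics(
        state_accuracy=accuracy,
        state_confusion=confusion,
        demethylation_sensitivity=float(sens),
        demethylation_specificity=float(spec),
        recovered_delta=delta_hat,
        n_genes=len(truth),
        n_planted_demethylated=int(flag.sum()),
    )
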