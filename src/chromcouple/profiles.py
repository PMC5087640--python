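"""Per-gene promoter occupancy and gene-body-scaled metagene profiles.

Coverage is first depth-normalized so libraries of different sizes are
comparable: bin values are scaled to sum to 10^6 across the genome
(counts-per-million-bins; ``library_total`` becomes 1e6 × bin_width).

Promoter occupancy is the per-base mean of normalized depth over
TSS ± flank. Metagene profiles average genes on an oriented grid of fixed
upstream-flank bins, a gene body rescaled to a fixed number of bins, and
fixed downstream-flank bins; the averaged profile is divided by its mean
density over the 6 kb downstream of the TES.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTrack, GeneModel, GeneModelSet

__all__ = [
    "normalize_library",
    "promoter_signal",
    "promoter_signal_table",
    "metagene_profile",
    "MetageneProfile",
]

logger = logging.getLogger(__name__)

NORMALIZED_BIN_SUM = 1.0e6
TES_NORM_SPAN = 6000  # bp downstream of the TES used for profile scaling


def normalize_library(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to depth-per-million (bin values summing to 10^6).

    Idempotent: renormalizing an already-normalized track is a no-op.
    Raises on an all-zero track.
    """
    total = track.library_total / track.bin_width  # = sum of bin values
    if total <= 0:
        raise ValueError(
            f"cannot normalize all-zero track ({track.mark}/{track.condition})"
        )
    return track.scaled(NORMALIZED_BIN_SUM / total)


def _window_mean(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Per-base mean depth over [start, end) clipped to the chromosome.

    Equivalent to averaging the per-base expansion of the bin values over
    the clipped window.
    """
    length = track.genome.get(
        chrom, track.values[chrom].size * track.bin_width
    )
    lo, hi = max(start, 0), min(end, length)
    if hi <= lo:
        return float("nan")
    arr = track.values[chrom]
    bw = track.bin_width
    b0, b1 = lo // bw, (hi - 1) // bw
    if b0 == b1:
        return float(arr[b0])
    mass = arr[b0] * ((b0 + 1) * bw - lo) + arr[b1] * (hi - b1 * bw)
    if b1 > b0 + 1:
        mass += arr[b0 + 1 : b1].sum() * bw
    return float(mass / (hi - lo))


def promoter_signal(
    track: CoverageTrack,
    genes: GeneModelSet,
    flank: int = 3000,
    stat: str = "mean",
) -> pd.Series:
    """Per-gene occupancy over TSS ± flank on a normalized track.

    The window [TSS − flank, TSS + flank) is clipped at chromosome edges;
    a gene whose window falls entirely off-contig gets occupancy 0 with a
    warning. ``stat`` is ``"mean"`` (per-base mean depth, default) or
    ``"sum"`` (total mass in the window).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if stat not in ("mean", "sum"):
        raise ValueError(f"stat must be 'mean' or 'sum', got {stat!r}")
    for g in genes:
        if g.chrom not in track.values:
            raise ValueError(
                f"gene {g.gene_id!r} on {g.chrom!r} absent from track"
            )
    out = np.empty(len(genes))
    for i, g in enumerate(genes):
        lo, hi = g.tss - flank, g.tss + flank
        m = _window_mean(track, g.chrom, lo, hi)
        if math.isnan(m):
            logger.warning(
                "gene %s: promoter window entirely off-contig; occupancy 0",
                g.gene_id,
            )
            m = 0.0
        if stat == "sum":
            length = track.genome.get(g.chrom, 0)
            clipped = min(hi, length) - max(lo, 0)
            m *= max(clipped, 0)
        out[i] = m
    return pd.Series(out, index=pd.Index(genes.gene_ids, name="gene_id"))


def promoter_signal_table(
    tracks: dict[tuple[str, str], CoverageTrack],
    genes: GeneModelSet,
    flank: int = 3000,
    stat: str = "mean",
) -> pd.DataFrame:
    """Occupancy for several (mark, condition) tracks as one table."""
    cols = {
        f"{mark}_{cond}": promoter_signal(track, genes, flank=flank, stat=stat)
        for (mark, cond), track in tracks.items()
    }
    df = pd.DataFrame(cols)
    df.attrs["flank"] = flank
    df.attrs["stat"] = stat
    return df


@dataclass
class MetageneProfile:
    """Averaged, oriented profile: upstream flank + scaled body + downstream flank.

    ``positions`` are grid labels (bp offsets for flanks, fractional body
    coordinates in (0, 1) for the body). ``tes_downstream`` is the averaged
    per-base density over [TES, TES + 6 kb) on the oriented axis, kept so
    the normalization constraint (its mean equals 1 after scaling) is
    checkable; ``normalization_factor`` is the divisor applied (1.0 when
    normalization is disabled).
    """

    positions: np.ndarray
    values: np.ndarray
    tes_downstream: np.ndarray
    normalization_factor: float
    n_genes_used: int
    flank: int
    body_bins: int
    flank_bins: int


def _oriented_per_base(
    track: CoverageTrack, gene: GeneModel, upstream: int, downstream: int
) -> np.ndarray:
    """Per-base depth from ``upstream`` bp before the gene to ``downstream``
    bp after it, on the oriented (TSS-left) axis; off-contig bases are 0."""
    arr = track.values[gene.chrom]
    bw = track.bin_width
    length = track.genome.get(gene.chrom, arr.size * bw)
    per_base = np.repeat(arr, bw)[:length]
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.end + downstream
    else:
        lo, hi = gene.start - downstream, gene.end + upstream
    out = np.zeros(hi - lo)
    src_lo, src_hi = max(lo, 0), min(hi, length)
    if src_hi > src_lo:
        out[src_lo - lo : src_hi - lo] = per_base[src_lo:src_hi]
    return out if gene.strand == "+" else out[::-1]


def _rebin(per_base: np.ndarray, nbins: int) -> np.ndarray:
    """Length-weighted mean resampling of a per-base vector into nbins."""
    idx = (np.arange(per_base.size) * nbins) // per_base.size
    sums = np.bincount(idx, weights=per_base, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    return sums / counts


def metagene_profile(
    track: CoverageTrack,
    genes: GeneModelSet,
    flank: int = 3000,
    body_bins: int = 100,
    flank_bins: int = 60,
    normalize: bool = True,
) -> MetageneProfile:
    """Average oriented gene profiles with the body rescaled to a fixed grid.

    Each gene contributes ``flank_bins`` upstream bins, ``body_bins`` body
    bins (length-weighted resampling of its per-base depth) and
    ``flank_bins`` downstream bins; minus-strand genes are orientation-
    flipped. Genes shorter than ``body_bins`` bp are dropped with a
    warning. When ``normalize`` is set, the averaged profile is divided by
    the mean of the averaged per-base density over [TES, TES + 6 kb).
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if flank % flank_bins != 0:
        raise ValueError("flank must be a multiple of flank_bins")
    downstream = max(flank, TES_NORM_SPAN)
    grid = np.zeros(2 * flank_bins + body_bins)
    tes_region = np.zeros(TES_NORM_SPAN)
    used = 0
    for g in genes:
        if g.length < body_bins:
            logger.warning(
                "gene %s: length %d < body_bins %d; dropped from metagene",
                g.gene_id, g.length, body_bins,
            )
            continue
        pb = _oriented_per_base(track, g, upstream=flank, downstream=downstream)
        up = _rebin(pb[:flank], flank_bins)
        body = _rebin(pb[flank : flank + g.length], body_bins)
        down = _rebin(pb[flank + g.length : flank + g.length + flank], flank_bins)
        grid += np.concatenate([up, body, down])
        tes_region += pb[flank + g.length : flank + g.length + TES_NORM_SPAN]
        used += 1
    if used == 0:
        raise ValueError("no gene long enough for metagene averaging")
    grid /= used
    tes_region /= used
    factor = 1.0
    if normalize:
        factor = float(tes_region.mean())
        if factor <= 0:
            raise ValueError(
                "mean density over [TES, TES+6kb) is zero; rerun with "
                "normalize=False (CLI: --no-normalize)"
            )
        grid = grid / factor
        tes_region = tes_region / factor
    flank_bw = flank // flank_bins
    positions = np.concatenate([
        np.arange(-flank, 0, flank_bw),                      # upstream of TSS
        (np.arange(body_bins) + 0.5) / body_bins,            # body fraction
        np.arange(0, flank, flank_bw) + 1,                   # downstream of TES
    ])
    return MetageneProfile(
        positions=positions,
        values=grid,
        tes_downstream=tes_region,
        normalization_factor=factor,
        n_genes_used=used,
        flank=flank,
        body_bins=body_bins,
        flank_bins=flank_bins,
    )
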