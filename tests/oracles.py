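"""Independent brute-force reference implementations used only by tests.

Everything here works per-base with plain Python loops so it shares no
code path with the package's binned/vectorized implementations.
"""

import math
import statistics

import numpy as np


def per_base(track, chrom):
    """Expand a binned track to one value per base, clipped to chrom length."""
    length = track.genome[chrom]
    out = []
    for value in track.values[chrom]:
        out.extend([float(value)] * track.bin_width)
    return out[:length]


def promoter_mean(track, gene, flank):
    """Per-base mean depth over TSS ± flank, clipped at chromosome edges."""
    depth = per_base(track, gene.chrom)
    lo = max(gene.tss - flank, 0)
    hi = min(gene.tss + flank, len(depth))
    window = depth[lo:hi]
    return sum(window) / len(window)


def _chunk_means(values, nbins):
    n = len(values)
    means = []
    for b in range(nbins):
        chunk = [v for i, v in enumerate(values) if (i * nbins) // n == b]
        means.append(sum(chunk) / len(chunk))
    return means


def metagene(track, genes, flank, body_bins, flank_bins, normalize=True):
    """Loop-based oriented metagene average with TES+6kb normalization."""
    grids = []
    tes_regions = []
    for gene in genes:
        depth = per_base(track, gene.chrom)
        length = len(depth)
        down = max(flank, 6000)
        if gene.strand == "+":
            lo, hi = gene.start - flank, gene.end + down
        else:
            lo, hi = gene.start - down, gene.end + flank
        window = [
            depth[i] if 0 <= i < length else 0.0 for i in range(lo, hi)
        ]
        if gene.strand == "-":
            window = window[::-1]
        body_len = gene.end - gene.start
        grids.append(
            _chunk_means(window[:flank], flank_bins)
            + _chunk_means(window[flank : flank + body_len], body_bins)
            + _chunk_means(window[flank + body_len : flank + body_len + flank],
                           flank_bins)
        )
        tes_regions.append(window[flank + body_len : flank + body_len + 6000])
    grid = [sum(col) / len(grids) for col in zip(*grids)]
    tes = [sum(col) / len(tes_regions) for col in zip(*tes_regions)]
    if normalize:
        factor = sum(tes) / len(tes)
        grid = [v / factor for v in grid]
    return grid


def sliding_window_means(k27_values, expr_values, window, step=1):
    """Stable-sort by k27 then average expr in every window, by loops."""
    order = sorted(range(len(k27_values)), key=lambda i: (k27_values[i], i))
    expr_sorted = [expr_values[i] for i in order]
    means = []
    for start in range(0, len(expr_sorted) - window + 1, step):
        means.append(sum(expr_sorted[start : start + window]) / window)
    return means


def page_z_and_p(values, member_flags):
    """PAGE z and two-sided normal p via the statistics module and erfc."""
    mu = statistics.fmean(values)
    sigma = statistics.stdev(values)
    members = [v for v, f in zip(values, member_flags) if f]
    sm = statistics.fmean(members)
    z = (sm - mu) * math.sqrt(len(members)) / sigma
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return z, min(p, 1.0)


def rasterize(intervals, chrom_length, bin_width):
    """Per-base rasterization then bin-mean, for comparing read_coverage."""
    depth = [0.0] * chrom_length
    for start, end, value in intervals:
        for i in range(start, end):
            depth[i] = value
    nbins = math.ceil(chrom_length / bin_width)
    out = []
    for b in range(nbins):
        chunk = depth[b * bin_width : (b + 1) * bin_width]
        out.append(sum(chunk) / bin_width)
    return out
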