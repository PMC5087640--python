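"""Library normalization, promoter occupancy, and metagene profiles."""

import numpy as np
import pytest

import oracles
from chromcouple import (
    CoverageTrack,
    GeneModel,
    GeneModelSet,
    metagene_profile,
    normalize_library,
    promoter_signal,
)

GENOME = {"chr1": 40_000, "chr2": 30_000}


def _track(values, bin_width=50, genome=GENOME):
    return CoverageTrack(
        mark="H3K27me3", condition="minus_dox", bin_width=bin_width,
        values=values, genome=genome,
    )


def _uniform_track(depth, bin_width=50, genome=GENOME):
    return _track(
        {c: np.full(-(-l // bin_width), float(depth)) for c, l in genome.items()},
        bin_width=bin_width, genome=genome,
    )


@pytest.fixture
def toy_genes():
    return GeneModelSet(
        [
            GeneModel("gA", "chr1", 10_000, 16_000, "+"),
            GeneModel("gB", "chr1", 25_000, 29_500, "-"),
            GeneModel("gC", "chr2", 12_000, 17_000, "+"),
        ],
        GENOME,
    )


@pytest.fixture
def toy_track():
    """Hand-placed steps and spikes around the toy genes' promoters."""
    rng = np.random.default_rng(7)
    values = {
        c: np.round(rng.gamma(1.5, 2.0, size=-(-l // 50)), 3)
        for c, l in GENOME.items()
    }
    values["chr1"][190:250] += 30.0   # plateau spanning gA's TSS at 10 kb
    values["chr1"][560:600] += 18.0   # asymmetric bump left of gB's TSS
    values["chr2"][235:260] += 25.0
    return _track(values)


class TestNormalizeLibrary:
    def test_uniform_scaling(self):
        track = _uniform_track(4.0)
        n_bins = sum(-(-l // 50) for l in GENOME.values())
        normalized = normalize_library(track)
        expected = 4.0 * 1e6 / (4.0 * n_bins)
        assert np.allclose(normalized.values["chr1"], expected)

    def test_idempotent(self):
        once = normalize_library(_uniform_track(7.0))
        twice = normalize_library(once)
        for chrom in GENOME:
            assert np.allclose(once.values[chrom], twice.values[chrom])

    def test_equal_shape_tracks_align_after_scaling(self):
        a = normalize_library(_uniform_track(2.0))
        b = normalize_library(_uniform_track(1.0))
        for chrom in GENOME:
            assert np.allclose(a.values[chrom], b.values[chrom])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_library(_uniform_track(0.0))


class TestPromoterSignal:
    def test_uniform_coverage_gives_constant_occupancy(self, toy_genes):
        occ = promoter_signal(_uniform_track(3.5), toy_genes)
        assert np.allclose(occ.to_numpy(), 3.5)

    def test_zero_coverage_gives_zero(self, toy_genes):
        occ = promoter_signal(_uniform_track(0.0), toy_genes)
        assert (occ == 0).all()

    def test_matches_per_base_oracle(self, toy_genes, toy_track):
        occ = promoter_signal(toy_track, toy_genes, flank=3000)
        for gene in toy_genes:
            expected = oracles.promoter_mean(toy_track, gene, 3000)
            assert occ[gene.gene_id] == pytest.approx(expected, rel=1e-9)

    def test_linear_in_coverage(self, toy_genes, toy_track):
        base = promoter_signal(toy_track, toy_genes)
        scaled = promoter_signal(toy_track.scaled(3.0), toy_genes)
        assert np.allclose(scaled.to_numpy(), 3.0 * base.to_numpy())

    def test_window_clipped_at_chromosome_start(self, toy_track):
        genes = GeneModelSet([GeneModel("edge", "chr1", 1000, 5000, "+")], GENOME)
        occ = promoter_signal(toy_track, genes, flank=3000)
        assert occ["edge"] == pytest.approx(
            oracles.promoter_mean(toy_track, genes["edge"], 3000), rel=1e-9
        )

    def test_unknown_chromosome_rejected(self, toy_track):
        genes = GeneModelSet(
            [GeneModel("g", "chrX", 0, 100, "+")], {**GENOME, "chrX": 1000}
        )
        with pytest.raises(ValueError, match="absent"):
            promoter_signal(toy_track, genes)


class TestMetageneProfile:
    def test_uniform_coverage_normalizes_to_one(self, toy_genes):
        prof = metagene_profile(_uniform_track(6.0), toy_genes)
        assert np.allclose(prof.values, 1.0)
        assert prof.normalization_factor == pytest.approx(6.0)

    def test_single_gene_matches_per_base_oracle(self, toy_track):
        genes = GeneModelSet([GeneModel("gA", "chr1", 10_000, 16_000, "+")], GENOME)
        prof = metagene_profile(toy_track, genes, body_bins=40, flank_bins=30)
        expected = oracles.metagene(
            toy_track, genes, flank=3000, body_bins=40, flank_bins=30
        )
        assert np.allclose(prof.values, expected, rtol=1e-9)

    def test_minus_strand_gene_matches_oracle(self, toy_track):
        genes = GeneModelSet([GeneModel("gB", "chr1", 25_000, 29_500, "-")], GENOME)
        prof = metagene_profile(toy_track, genes, body_bins=25, flank_bins=20)
        expected = oracles.metagene(
            toy_track, genes, flank=3000, body_bins=25, flank_bins=20
        )
        assert np.allclose(prof.values, expected, rtol=1e-9)

    def test_multi_gene_average_matches_oracle(self, toy_genes, toy_track):
        prof = metagene_profile(toy_track, toy_genes, body_bins=50, flank_bins=15)
        expected = oracles.metagene(
            toy_track, toy_genes, flank=3000, body_bins=50, flank_bins=15
        )
        assert np.allclose(prof.values, expected, rtol=1e-9)

    def test_tes_downstream_mean_is_one_after_normalization(
        self, toy_genes, toy_track
    ):
        prof = metagene_profile(toy_track, toy_genes)
        assert prof.tes_downstream.mean() == pytest.approx(1.0)

    def test_duplicated_gene_changes_nothing(self, toy_track):
        one = GeneModelSet([GeneModel("g", "chr1", 10_000, 16_000, "+")], GENOME)
        three = GeneModelSet(
            [
                GeneModel(f"g{i}", "chr1", 10_000, 16_000, "+")
                for i in range(3)
            ],
            GENOME,
        )
        p1 = metagene_profile(toy_track, one)
        p3 = metagene_profile(toy_track, three)
        assert np.allclose(p1.values, p3.values)

    def test_strand_flip_of_whole_dataset_is_invariant(self):
        """Mirroring coverage and genes leaves the profile unchanged."""
        genome = {"chr1": 30_000}
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 3.0, size=30_000)  # bin_width 1: exact mirror
        track = _track({"chr1": values}, bin_width=1, genome=genome)
        genes = GeneModelSet(
            [
                GeneModel("a", "chr1", 9_000, 13_000, "+"),
                GeneModel("b", "chr1", 20_000, 22_500, "-"),
            ],
            genome,
        )
        mirrored_track = _track({"chr1": values[::-1]}, bin_width=1, genome=genome)
        mirrored_genes = GeneModelSet(
            [
                GeneModel(
                    g.gene_id, "chr1", 30_000 - g.end, 30_000 - g.start,
                    "-" if g.strand == "+" else "+",
                )
                for g in genes
            ],
            genome,
        )
        forward = metagene_profile(track, genes)
        mirrored = metagene_profile(mirrored_track, mirrored_genes)
        assert np.allclose(forward.values, mirrored.values)

    def test_short_genes_dropped(self, toy_track):
        genes = GeneModelSet(
            [
                GeneModel("tiny", "chr1", 10_000, 10_050, "+"),
                GeneModel("ok", "chr1", 20_000, 24_000, "+"),
            ],
            GENOME,
        )
        prof = metagene_profile(toy_track, genes, body_bins=100)
        assert prof.n_genes_used == 1

    def test_zero_normalization_region_instructs_disabling(self):
        values = {c: np.zeros(-(-l // 50)) for c, l in GENOME.items()}
        values["chr1"][200:250] = 5.0  # signal only inside the gene body
        track = _track(values)
        genes = GeneModelSet([GeneModel("g", "chr1", 10_000, 12_600, "+")], GENOME)
        with pytest.raises(ValueError, match="normalize=False"):
            metagene_profile(track, genes)
        prof = metagene_profile(track, genes, normalize=False)
        assert prof.normalization_factor == 1.0
        assert prof.values.max() > 0
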