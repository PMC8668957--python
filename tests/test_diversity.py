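"""Frequencies, marker indices, pi, windows, genome summaries, PCA."""

import numpy as np
import pandas as pd
import pytest

from wheatdiv.diversity import (
    allele_frequencies,
    classify_maf,
    marker_stats,
    nucleotide_diversity,
    pca,
    per_genome_summary,
    polymorphic_mask,
    polymorphic_summary,
    subsample_even,
    windowed_diversity,
    write_track_bed,
)
from wheatdiv.simulate import RegionSpec, SimulationConfig, simulate_panel

from conftest import build_gm, random_gm, tiny_chrom_table


class TestAlleleFrequencies:
    def test_hand_count(self):
        gm = build_gm([["AA"], ["AA"], ["BB"], ["AB"]])
        freqs = allele_frequencies(gm)
        assert freqs.p[0] == pytest.approx(5 / 8)
        assert freqs.n_alleles_called[0] == 8

    def test_fixed_marker(self):
        gm = build_gm([["AA"], ["AA"]])
        freqs = allele_frequencies(gm)
        assert freqs.p[0] == 1.0 and freqs.maf[0] == 0.0

    def test_all_missing_undefined(self):
        gm = build_gm([["NN"], ["NN"]])
        freqs = allele_frequencies(gm)
        assert not freqs.defined[0]
        assert np.isnan(freqs.p[0])


class TestMarkerStats:
    def test_biallelic_maxima(self):
        gm = build_gm([["AA"], ["AA"], ["BB"], ["BB"]])  # p = 0.5
        stats = marker_stats(gm)
        assert stats.table["H"].iloc[0] == pytest.approx(0.5)
        assert stats.table["PIC"].iloc[0] == pytest.approx(0.375)

    def test_fixed_marker_zero(self):
        gm = build_gm([["AA"], ["AA"], ["AA"]])
        stats = marker_stats(gm)
        assert stats.table["H"].iloc[0] == 0.0
        assert stats.table["PIC"].iloc[0] == 0.0

    def test_discriminating_power_two_patterns(self):
        # N = 4 accessions split 2/2 over two genotype patterns -> D = 2/3
        gm = build_gm([["AA"], ["AA"], ["BB"], ["BB"]])
        stats = marker_stats(gm)
        assert stats.table["D"].iloc[0] == pytest.approx(2 / 3)

    def test_h_bounds_pic(self):
        rng = np.random.default_rng(40)
        gm = random_gm(rng, n_acc=30, n_markers=60)
        stats = marker_stats(gm)
        freqs = allele_frequencies(gm)
        ok = freqs.defined
        assert (stats.table["H"].values[ok] >= stats.table["PIC"].values[ok] - 1e-12).all()
        # H = 0 exactly where maf = 0
        assert np.array_equal(stats.table["H"].values[ok] < 1e-12, freqs.maf[ok] < 1e-12)

    def test_requires_two_accessions(self):
        gm = build_gm([["AA"]])
        with pytest.raises(ValueError):
            marker_stats(gm)


class TestClassifyMAF:
    def test_binning(self):
        gm = build_gm(
            [["AA"] * 3] * 99 + [["BB", "AA", "AA"]] * 1 + [["AA", "BB", "AA"]] * 10
            + [["AA", "AA", "BB"]] * 40
        )
        # maf: m0 = 1/150? build explicit instead via frequencies
        freqs = allele_frequencies(gm)
        cls = classify_maf(freqs, rare_thr=0.05, common_thr=0.15)
        maf = freqs.maf
        assert cls.n_rare == int((maf < 0.05).sum())
        assert cls.n_classified == 3

    def test_example_counts(self):
        class FakeFreqs:
            maf = np.array([0.01, 0.10, 0.30])
            defined = np.array([True, True, True])

        cls = classify_maf(FakeFreqs())
        assert (cls.n_rare, cls.n_intermediate, cls.n_common) == (1, 1, 1)

    def test_boundary_in_middle_bin(self):
        class FakeFreqs:
            maf = np.array([0.05, 0.15])
            defined = np.array([True, True])

        cls = classify_maf(FakeFreqs())
        assert cls.n_intermediate == 2

    def test_empty(self):
        class FakeFreqs:
            maf = np.array([])
            defined = np.array([], dtype=bool)

        cls = classify_maf(FakeFreqs())
        assert cls.n_classified == 0


class TestPolymorphism:
    def test_single_het_suffices(self):
        gm = build_gm([["AB"]])
        assert polymorphic_mask(gm, ["acc0"]).tolist() == [True]

    def test_brute_force_scan(self):
        rng = np.random.default_rng(41)
        gm = random_gm(rng, n_acc=4, n_markers=5)
        mask = polymorphic_mask(gm)
        for j in range(5):
            alleles = set()
            for c in gm.calls[:, j]:
                alleles |= {0: {"a"}, 1: {"a", "b"}, 2: {"b"}, -1: set()}[int(c)]
            assert mask[j] == (len(alleles) >= 2)

    def test_summary_percentage(self):
        gm = build_gm([["AA", "AA"], ["BB", "AA"]])
        (s,) = polymorphic_summary(gm, {"all": gm.accession_ids})
        assert s.n_polymorphic == 1 and s.percentage == 50.0


class TestNucleotideDiversity:
    def test_four_line_example(self):
        gm = build_gm([["AA"], ["AA"], ["BB"], ["BB"]])
        pi = nucleotide_diversity(gm, chrom_table=tiny_chrom_table(1000))
        assert pi.per_chromosome.loc["1A", "pi"] == pytest.approx(4 / 3 * 0.5 / 1000)

    def test_monomorphic_zero(self):
        gm = build_gm([["AA"], ["AA"], ["AA"]])
        pi = nucleotide_diversity(gm, chrom_table=tiny_chrom_table(1000))
        assert pi.per_chromosome["pi"].sum() == 0.0

    def test_length_scaling(self):
        gm = build_gm([["AA"], ["BB"]])
        pi1 = nucleotide_diversity(gm, chrom_table=tiny_chrom_table(1000))
        pi2 = nucleotide_diversity(gm, chrom_table=tiny_chrom_table(2000))
        assert pi1.per_chromosome.loc["1A", "pi"] == pytest.approx(
            2 * pi2.per_chromosome.loc["1A", "pi"]
        )

    def test_invariances(self):
        rng = np.random.default_rng(42)
        gm = random_gm(rng, n_acc=12, n_markers=20)
        ct = tiny_chrom_table(10**6)
        base = nucleotide_diversity(gm, chrom_table=ct).genome_wide
        # accession reordering
        perm = list(np.array(gm.accession_ids)[rng.permutation(12)])
        assert nucleotide_diversity(gm.take_accessions(perm), chrom_table=ct).genome_wide == pytest.approx(base)
        # allele label swap: exchange HOM_A <-> HOM_B
        swapped = gm.copy()
        calls = swapped.calls
        a, b = calls == 0, calls == 2
        calls[a], calls[b] = 2, 0
        assert nucleotide_diversity(swapped, chrom_table=ct).genome_wide == pytest.approx(base)


class TestWindowedDiversity:
    def test_half_open_assignment(self):
        gm = build_gm([["AA"], ["BB"]], positions=[4_000_001])
        ct = tiny_chrom_table(9_000_000)
        track = windowed_diversity(gm, chrom_table=ct, window_bp=3_000_000)
        on_1a = track[track["chrom"] == "1A"].reset_index()
        assert on_1a.loc[1, "window_start"] == 3_000_001
        assert on_1a["n_snps"].tolist() == [0, 1, 0]

    def test_conservation_identity(self):
        rng = np.random.default_rng(43)
        positions = sorted(rng.choice(10**7, size=40, replace=False).tolist())
        gm = random_gm(rng, n_acc=15, n_markers=40)
        gm.markers["pos"] = positions
        ct = tiny_chrom_table(10**7)
        track = windowed_diversity(gm, chrom_table=ct, window_bp=3_000_000)
        pi = nucleotide_diversity(gm, chrom_table=ct)
        for chrom in ["1A"]:
            w = track[track["chrom"] == chrom]
            total = (w["pi"] * (w["window_end"] - w["window_start"])).sum()
            assert total == pytest.approx(pi.per_chromosome.loc[chrom, "pi"] * 10**7)

    def test_assignment_matches_brute_force(self):
        rng = np.random.default_rng(44)
        positions = sorted(rng.choice(10**7, size=25, replace=False).tolist())
        gm = random_gm(rng, n_acc=10, n_markers=25, missing_rate=0, het_rate=0)
        gm.markers["pos"] = positions
        ct = tiny_chrom_table(10**7)
        track = windowed_diversity(gm, chrom_table=ct, window_bp=2_000_000)
        w1a = track[track["chrom"] == "1A"]
        for _, row in w1a.iterrows():
            expected = sum(
                1 for p in positions if row["window_start"] <= p < row["window_end"]
            )
            # markers with < 2 haploid calls are excluded from n_snps
            assert row["n_snps"] <= expected
        assert w1a["n_snps"].sum() <= 25


class TestGenomeSummary:
    def test_single_chromosome(self):
        gm = build_gm([["AA", "AA"], ["BB", "BB"]], chroms=["1A", "1A"])
        summary = per_genome_summary(gm, {"all": gm.accession_ids})
        assert summary.by_genome.loc["A", "all"] == 2
        assert summary.by_chromosome["all"].sum() == 2

    def test_hand_tally_and_conservation(self):
        rng = np.random.default_rng(45)
        chroms = [["1A", "3B", "7D", "1A", "5D"][j % 5] for j in range(20)]
        gm = random_gm(rng, n_acc=10, n_markers=20, chroms=chroms)
        summary = per_genome_summary(gm, {"all": gm.accession_ids})
        mask = polymorphic_mask(gm)
        for chrom in ("1A", "3B", "7D", "5D"):
            expected = sum(
                int(m) for m, c in zip(mask, gm.markers["chrom"]) if c == chrom
            )
            assert summary.by_chromosome.loc[chrom, "all"] == expected
        assert summary.by_chromosome["all"].sum() == summary.by_genome["all"].sum()
        assert summary.by_group["all"].sum() == summary.by_chromosome["all"].sum()


class TestPCA:
    def test_duplicate_accessions_identical_scores(self):
        rng = np.random.default_rng(46)
        gm = random_gm(rng, n_acc=8, n_markers=30)
        gm.calls[1] = gm.calls[0]
        result = pca(gm, n_components=3)
        assert np.allclose(result.scores.iloc[0], result.scores.iloc[1])

    def test_explained_pct_shape(self):
        rng = np.random.default_rng(47)
        gm = random_gm(rng, n_acc=10, n_markers=40)
        result = pca(gm, n_components=5)
        pct = result.explained_pct
        assert (np.diff(pct) <= 1e-9).all()
        assert pct.sum() <= 100 + 1e-9

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(48)
        gm = random_gm(rng, n_acc=4, n_markers=30)
        with pytest.warns(RuntimeWarning, match="rank"):
            result = pca(gm, n_components=10)
        assert result.scores.shape[1] == 3

    def test_two_population_separation(self):
        regions = [
            RegionSpec("P1", 30, alpha=[20.0, 0.05]),
            RegionSpec("P2", 30, alpha=[0.05, 20.0]),
        ]
        config = SimulationConfig(K_true=2, F=0.3, n_markers=400, regions=regions, seed=49)
        gm, truth = simulate_panel(config)
        result = pca(gm, n_components=2)
        pc1 = result.scores["PC1"].values
        labels = gm.accessions["region"].values
        side1 = pc1[labels == "P1"].mean()
        side2 = pc1[labels == "P2"].mean()
        assert np.sign(side1) != np.sign(side2)
        # sign-of-PC1 classification separates the populations cleanly
        agreement = max(
            ((pc1 > 0) == (labels == "P1")).mean(), ((pc1 > 0) == (labels == "P2")).mean()
        )
        assert agreement > 0.95


class TestSubsample:
    def test_already_at_target(self):
        rng = np.random.default_rng(50)
        gm = random_gm(rng, n_acc=10, n_markers=30, country="HU")
        result = pca(gm, n_components=2)
        subset = subsample_even(gm, result, "country", {"HU": 10})
        assert subset == gm.accession_ids

    def test_duplicate_removed_first(self):
        rng = np.random.default_rng(51)
        gm = random_gm(rng, n_acc=8, n_markers=40, country="HU")
        gm.calls[3] = gm.calls[2]  # acc2/acc3 are identical -> zero PC distance
        result = pca(gm, n_components=2)
        subset = subsample_even(gm, result, "country", {"HU": 7})
        assert "acc3" not in subset  # larger id of the closest pair dropped
        assert "acc2" in subset

    def test_targets_hit_exactly(self):
        rng = np.random.default_rng(52)
        country = ["HU"] * 12 + ["RO"] * 8
        gm = random_gm(rng, n_acc=20, n_markers=50, country=country)
        result = pca(gm, n_components=2)
        subset = subsample_even(gm, result, "country", {"HU": 5, "RO": 8})
        kept = gm.accessions.loc[subset, "country"].value_counts()
        assert kept["HU"] == 5 and kept["RO"] == 8


def test_bed_export_coordinates(tmp_path):
    track = pd.DataFrame(
        [{"chrom": "1A", "window_start": 1, "window_end": 3_000_001, "pi": 0.5}]
    )
    write_track_bed(track, tmp_path / "t.bed")
    assert (tmp_path / "t.bed").read_text() == "1A\t0\t3000000\t0.5\n"
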