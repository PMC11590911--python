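"""Distance-binned, point-distance, per-chromosome and adjacent-SNP LD summaries."""

import numpy as np
import pandas as pd
import pytest

from snpld import (
    DistanceBins,
    SnpldError,
    adjacent_snp_summary,
    bin_by_distance,
    decay_curve,
    ld_pair,
    make_panel,
    pairwise_syntenic_ld,
    per_chromosome_summary,
    point_distance_summary,
)


def _poly_panel(rng, n_samples, positions, chrom="1"):
    """Panel of independent polymorphic loci at given positions."""
    n_loci = len(positions)
    d = rng.binomial(2, 0.4, size=(n_samples, n_loci)).astype(np.int8)
    d[0] = 0
    d[1] = 1  # guarantee both alleles present at every locus
    return make_panel(d, positions=positions, chrom=chrom)


def _fake_estimates(distances, r2s, chrom="1"):
    n = len(distances)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
            "vid_i": [f"a{i}" for i in range(n)],
            "vid_j": [f"b{i}" for i in range(n)],
            "distance_bp": distances,
            "n_alleles": [100] * n,
            "D": [0.0] * n,
            "Dmax": [0.1] * n,
            "Dprime": [0.0] * n,
            "r2": r2s,
            "r2_corrected": r2s,
            "converged": [True] * n,
        }
    )


class TestPairwiseSyntenicLd:
    def test_distance_gating(self, rng):
        panel = _poly_panel(rng, 30, [1_000, 40_000, 2_000_000])
        est, skipped = pairwise_syntenic_ld(panel, "pop1", max_distance_bp=1_000_000)
        assert len(est) == 1
        assert est["distance_bp"].iloc[0] == 39_000

    def test_all_pairs_when_close(self, rng):
        L = 12
        panel = _poly_panel(rng, 30, [1000 * (i + 1) for i in range(L)])
        est, skipped = pairwise_syntenic_ld(panel, "pop1")
        assert len(est) + skipped["monomorphic"] + skipped["insufficient_data"] == L * (L - 1) // 2
        assert skipped["n_pairs_enumerated"] == L * (L - 1) // 2

    def test_pair_count_matches_brute_force(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=60, replace=False))
        chroms = ["1"] * 30 + ["2"] * 30
        panel = _poly_panel(rng, 25, pos.tolist(), chrom=chroms)
        max_d = 500_000
        est, skipped = pairwise_syntenic_ld(panel, "pop1", max_distance_bp=max_d)
        brute = 0
        for c in ("1", "2"):
            p = [v.pos for v in panel.variants if v.chrom == c]
            p.sort()
            for i in range(len(p)):
                for j in range(i + 1, len(p)):
                    if 1 <= p[j] - p[i] <= max_d:
                        brute += 1
        assert skipped["n_pairs_enumerated"] == brute
        assert len(est) + skipped["monomorphic"] + skipped["insufficient_data"] == brute

    def test_unknown_population_rejected(self, rng):
        panel = _poly_panel(rng, 10, [1000, 2000])
        with pytest.raises(SnpldError):
            pairwise_syntenic_ld(panel, "nope")


class TestBinByDistance:
    def test_single_bin_mean(self):
        est = _fake_estimates([10_000, 20_000, 30_000], [0.2, 0.4, 0.6])
        out = bin_by_distance(est)
        assert out[0].mean == pytest.approx(0.4)
        assert out[0].sd == pytest.approx(np.std([0.2, 0.4, 0.6]))
        assert out[0].n_pairs == 3
        assert out[1].n_pairs == 0 and np.isnan(out[1].mean)

    def test_boundary_goes_to_lower_bin(self):
        est = _fake_estimates([50_000, 50_001], [0.5, 0.3])
        out = bin_by_distance(est)
        assert out[0].n_pairs == 1 and out[0].mean == pytest.approx(0.5)
        assert out[1].n_pairs == 1 and out[1].mean == pytest.approx(0.3)

    def test_one_bp_pair_is_counted(self):
        out = bin_by_distance(_fake_estimates([1], [0.9]))
        assert out[0].n_pairs == 1

    def test_matches_independent_tabulation(self, rng):
        d = rng.integers(1, 1_200_000, size=400)
        r = rng.random(400)
        out = bin_by_distance(_fake_estimates(d.tolist(), r.tolist()), statistic="r2")
        edges = [(1, 50_000), (50_000, 100_000), (100_000, 500_000), (500_000, 1_000_000)]
        for k, (lo, hi) in enumerate(edges):
            sel = (d >= lo) & (d <= hi) if k == 0 else (d > lo) & (d <= hi)
            if sel.any():
                assert out[k].mean == pytest.approx(r[sel].mean(), abs=1e-12)
                assert out[k].sd == pytest.approx(r[sel].std(), abs=1e-12)
            assert out[k].n_pairs == int(sel.sum())

    def test_invalid_statistic(self):
        with pytest.raises(SnpldError):
            bin_by_distance(_fake_estimates([10], [0.1]), statistic="banana")


class TestPointDistanceSummary:
    def test_empty_window(self):
        out = point_distance_summary(_fake_estimates([500_000], [0.5]))
        assert all(s.n_pairs == 0 for s in out)

    def test_single_pair_at_center(self):
        out = point_distance_summary(_fake_estimates([10_000], [0.42]))
        assert out[1].n_pairs == 1 and out[1].mean == pytest.approx(0.42)

    def test_window_membership_matches_brute_filter(self, rng):
        d = rng.integers(1, 150_000, size=500)
        r = rng.random(500)
        out = point_distance_summary(_fake_estimates(d.tolist(), r.tolist()))
        for s, c in zip(out, (1_000, 10_000, 100_000)):
            sel = (d >= max(1, 0.9 * c)) & (d <= 1.1 * c)
            assert s.n_pairs == int(sel.sum())
            if sel.any():
                assert s.mean == pytest.approx(r[sel].mean(), abs=1e-12)


class TestPerChromosome:
    def test_single_chromosome_equals_global(self):
        est = _fake_estimates([1000, 2000, 3000], [0.1, 0.2, 0.6])
        out = per_chromosome_summary(est)
        assert len(out) == 1
        assert out["mean"][0] == pytest.approx(0.3)

    def test_two_chromosomes_with_constant_values(self):
        est = _fake_estimates([1000] * 4, [0.3, 0.3, 0.7, 0.7], chrom=["1", "1", "2", "2"])
        out = per_chromosome_summary(est)
        assert dict(zip(out["chrom"], out["mean"])) == pytest.approx({"1": 0.3, "2": 0.7})

    def test_matches_pandas_groupby_oracle(self, rng):
        chroms = rng.choice(["1", "2", "3"], size=200).tolist()
        r = rng.random(200)
        est = _fake_estimates([1000] * 200, r.tolist(), chrom=chroms)
        out = per_chromosome_summary(est)
        oracle = est.groupby("chrom")["r2"].agg(["mean", "count"])
        for _, row in out.iterrows():
            assert row["mean"] == pytest.approx(oracle.loc[row["chrom"], "mean"], abs=1e-12)
            assert row["n_pairs"] == oracle.loc[row["chrom"], "count"]


class TestAdjacentSnpSummary:
    def test_two_loci_single_pair(self, rng):
        panel = _poly_panel(rng, 40, [1000, 5000])
        means, skipped = adjacent_snp_summary(panel, "pop1")
        assert means["1"] == pytest.approx(ld_pair(panel, 0, 1).r2)
        assert skipped == {}

    def test_monomorphic_chromosome_has_no_entry(self, rng):
        d = np.zeros((10, 2), dtype=np.int8)  # chrom 2 all-monomorphic
        poly = rng.binomial(2, 0.5, size=(10, 2)).astype(np.int8)
        poly[0], poly[1] = 0, 1
        panel = make_panel(
            np.hstack([poly, d]), chrom=["1", "1", "2", "2"],
            positions=[1000, 2000, 1000, 2000],
        )
        means, skipped = adjacent_snp_summary(panel)
        assert "2" not in means
        assert skipped["2"] == 1

    def test_equals_rank_adjacent_filter_of_full_scan(self, rng):
        pos = sorted(rng.choice(np.arange(1, 200_000), size=10, replace=False).tolist())
        panel = _poly_panel(rng, 30, pos)
        means, _ = adjacent_snp_summary(panel, "pop1")
        est, _ = pairwise_syntenic_ld(panel, "pop1", max_distance_bp=10**9)
        vids = [v.vid for v in panel.sorted_by_position().variants]
        adj = {(vids[k], vids[k + 1]) for k in range(len(vids) - 1)}
        sel = est[[tuple(x) in adj for x in zip(est["vid_i"], est["vid_j"])]]
        assert means["1"] == pytest.approx(sel["r2"].mean())


class TestDecayCurve:
    def test_single_bin_is_global_mean(self):
        est = _fake_estimates([1000, 5000, 20_000], [0.1, 0.5, 0.9])
        out = decay_curve(est, n_log_bins=1)
        assert len(out) == 1
        assert out["mean"][0] == pytest.approx(0.5)
        assert out["n_pairs"][0] == 3

    def test_empty_input(self):
        out = decay_curve(_fake_estimates([], []))
        assert len(out) == 0

    def test_matches_bin_by_distance_with_equivalent_edges(self, rng):
        d = rng.integers(2, 1_000_000, size=300)
        r = rng.random(300)
        est = _fake_estimates(d.tolist(), r.tolist())
        curve = decay_curve(est, n_log_bins=1, statistic="r2")
        ref = bin_by_distance(est, DistanceBins(((1, 1_000_000),)), statistic="r2")
        assert curve["mean"][0] == pytest.approx(ref[0].mean, abs=1e-12)
        assert curve["n_pairs"][0] == ref[0].n_pairs


def test_conservation_of_pair_counts(rng):
    """Bin counts + out-of-range + skipped = pairs enumerated."""
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=80, replace=False))
    d = rng.binomial(2, 0.3, size=(15, 80)).astype(np.int8)
    d[:, :10] = 0  # ten monomorphic loci to force skips
    panel = make_panel(d, positions=pos.tolist())
    est, skipped = pairwise_syntenic_ld(panel, "pop1", max_distance_bp=1_500_000)
    bins = bin_by_distance(est)
    in_bins = sum(s.n_pairs for s in bins)
    out_of_range = int((est["distance_bp"] > 1_000_000).sum())
    total = in_bins + out_of_range + skipped["monomorphic"] + skipped["insufficient_data"]
    assert total == skipped["n_pairs_enumerated"]
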