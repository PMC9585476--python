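"""PBS scan: filters, thresholds, hit annotation, local zoom, trio contrast."""

import numpy as np
import pandas as pd
import pytest

from baiyue_scan import io, sim, stats
from baiyue_scan.scan import (
    ScanThresholds,
    SiteFilterConfig,
    TrioSpec,
    compute_thresholds,
    extract_and_annotate_hits,
    filter_sites,
    local_zoom,
    pbs_table_from_counts,
    run_pbs_scan,
    trio_contrast,
)
from conftest import make_site


class TestTrioSpec:
    def test_distinct_labels_required(self):
        with pytest.raises(ValueError):
            TrioSpec("A", "A", "C")

    def test_swapped(self, trio):
        assert trio.swapped() == TrioSpec("B", "A", "C")


class TestFilterSites:
    def test_depth_rule(self, trio):
        kept, report = filter_sites([make_site(depth=9.5)], SiteFilterConfig(), trio)
        assert kept == [] and report.removed["depth"] == 1

    def test_depth_rule_boundary_non_strict(self, trio):
        kept, _ = filter_sites([make_site(depth=10.0)], SiteFilterConfig(), trio)
        assert len(kept) == 1

    def test_nan_depth_passes_only_when_disabled(self, trio):
        site = make_site(depth=float("nan"))
        kept, _ = filter_sites([site], SiteFilterConfig(), trio)
        assert kept == []
        kept, _ = filter_sites(
            [site], SiteFilterConfig(min_site_mean_depth=None), trio
        )
        assert len(kept) == 1

    def test_monomorphic_in_all_trio_pops_removed(self, trio):
        site = make_site(counts={"A": (0, 20), "B": (0, 20), "C": (0, 20)})
        kept, report = filter_sites([site], SiteFilterConfig(), trio)
        assert kept == [] and report.removed["monomorphic"] == 1

    def test_constructed_panel_counts(self, trio):
        """10 sites, exactly 4 failing one rule each -> 6 survive."""
        sites = [make_site(pos=i) for i in range(1, 7)]
        sites.append(make_site(pos=7, depth=5.0))
        sites.append(make_site(pos=8, missing=0.20))
        sites.append(make_site(pos=9, counts={"A": (1, 1), "B": (5, 20), "C": (5, 20)}))
        sites.append(make_site(pos=10, counts={"A": (20, 20), "B": (20, 20), "C": (20, 20)}))
        kept, report = filter_sites(sites, SiteFilterConfig(), trio)
        assert len(kept) == 6
        assert report.removed == {
            "depth": 1,
            "missingness": 1,
            "insufficient_calls": 1,
            "monomorphic": 1,
        }
        assert report.n_input == report.n_kept + sum(report.removed.values())

    def test_missingness_strict_boundary(self, trio):
        site = make_site(missing=0.05)
        kept, _ = filter_sites([site], SiteFilterConfig(), trio)
        assert kept == []  # rate must be < 5%


class TestThresholdsAndScan:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScanThresholds(p90=1.0, p99995=0.5, p99999=2.0)

    def test_null_fraction_above_p90(self, small_panel, trio):
        counts = sim.site_counts(small_panel)
        kept, _ = filter_sites(counts, SiteFilterConfig(min_site_mean_depth=None, max_missing_fraction=1.0), trio)
        table = pbs_table_from_counts(kept, trio)
        thr = compute_thresholds(table["pbs"].to_numpy())
        frac = np.mean(table["pbs"] > thr.p90)
        assert frac == pytest.approx(0.10, abs=2 / len(table))

    def test_swap_identity_sitewise(self, small_panel, trio):
        counts = sim.site_counts(small_panel)
        cfg = SiteFilterConfig(min_site_mean_depth=None, max_missing_fraction=1.0)
        kept, _ = filter_sites(counts, cfg, trio)
        t1 = pbs_table_from_counts(kept, trio)
        t2 = pbs_table_from_counts(kept, trio.swapped())
        np.testing.assert_allclose(
            t1["pbs"].to_numpy() + t2["pbs"].to_numpy(), t1["t_ab"].to_numpy(), atol=1e-12
        )

    def test_scan_invariant_to_record_order(self, tmp_path, small_panel, trio):
        perm = np.random.default_rng(0).permutation(len(small_panel.sites))
        shuffled_sites = small_panel.sites.iloc[perm].reset_index(drop=True)
        io.write_vcf(
            small_panel.sites, small_panel.alt_dosage, small_panel.depth,
            small_panel.samples, tmp_path / "sorted.vcf",
        )
        io.write_vcf(
            shuffled_sites, small_panel.alt_dosage[perm], small_panel.depth[perm],
            small_panel.samples, tmp_path / "shuffled.vcf",
        )
        io.write_popmap(small_panel.popmap, tmp_path / "popmap.tsv")
        cfg = SiteFilterConfig(min_site_mean_depth=None, max_missing_fraction=1.0)
        t1, thr1, _ = run_pbs_scan(tmp_path / "sorted.vcf", tmp_path / "popmap.tsv", trio, cfg)
        t2, thr2, _ = run_pbs_scan(tmp_path / "shuffled.vcf", tmp_path / "popmap.tsv", trio, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert thr1 == thr2

    def test_missing_trio_population_rejected_early(self, tmp_path, small_panel):
        io.write_popmap(small_panel.popmap, tmp_path / "popmap.tsv")
        with pytest.raises(ValueError, match="Z"):
            run_pbs_scan(
                tmp_path / "nonexistent.vcf",
                tmp_path / "popmap.tsv",
                TrioSpec("A", "B", "Z"),
            )

    def test_null_median_pbs_near_zero(self):
        """Equal drift on all three branches, no sweeps: the genome-wide
        median PBS sits within 0.005 of zero."""
        cfg = sim.SimConfig(
            n_sites=50_000,
            chrom_plan=[("chr1", 50_000_000)],
            drift={"A": 0.02, "B": 0.02, "C": 0.02},
            sample_sizes={"A": 50, "B": 50, "C": 50},
            seed=7,
        )
        freqs = sim.simulate_trio_frequencies(cfg)
        panel = sim.sample_genotypes(freqs, cfg)
        trio = TrioSpec("A", "B", "C")
        kept, _ = filter_sites(
            sim.site_counts(panel),
            SiteFilterConfig(min_site_mean_depth=None, max_missing_fraction=1.0),
            trio,
        )
        table = pbs_table_from_counts(kept, trio)
        assert abs(np.median(table["pbs"])) < 0.005

    def test_sweep_power_monotone_in_target_freq(self):
        """Recovery of sweep sites rises with the forced derived frequency."""
        chrom_plan = [("chr1", 30_000_000)]
        base = dict(
            n_sites=20_000,
            chrom_plan=chrom_plan,
            drift={"A": 0.02, "B": 0.02, "C": 0.02},
            sample_sizes={"A": 50, "B": 50, "C": 50},
            seed=13,
        )
        # 10 sweeps in 20,000 sites: the top-0.1% threshold leaves room
        # for every sweep site, so recovery is not capped by definition
        neutral = sim.simulate_trio_frequencies(sim.SimConfig(**base))
        low = np.flatnonzero(neutral["ancestral_freq"].to_numpy() <= 0.2)
        idx = np.random.default_rng(13).choice(low, size=10, replace=False)
        trio = TrioSpec("A", "B", "C")
        powers = []
        for target in (0.4, 0.6, 0.9):
            sweeps = [sim.SweepLocus(int(i), "A", target) for i in idx]
            cfg = sim.SimConfig(sweep_spec=sweeps, **base)
            panel = sim.sample_genotypes(sim.simulate_trio_frequencies(cfg), cfg)
            kept, _ = filter_sites(
                sim.site_counts(panel),
                SiteFilterConfig(min_site_mean_depth=None, max_missing_fraction=1.0),
                trio,
            )
            table = pbs_table_from_counts(kept, trio)
            thr = stats.percentile(table["pbs"].to_numpy(), 99.9)
            swept_pos = set(
                (neutral.loc[i, "chrom"], int(neutral.loc[i, "pos"])) for i in idx
            )
            hit = [
                (c, p) in swept_pos and v > thr
                for c, p, v in zip(table["chrom"], table["pos"], table["pbs"])
            ]
            powers.append(sum(hit) / len(idx))
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > 0.8


class TestHits:
    def _thr(self):
        return ScanThresholds(p90=0.5, p99995=1.0, p99999=2.0)

    def _table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "site_id", "pbs"])

    def test_tier_counts(self):
        rows = [("chr1", int(p), f"v{p}", v) for p, v in zip(
            range(100, 1100, 100),
            [2.5, 2.2, 2.1, 1.5, 1.4, 1.3, 1.2, 1.1, 1.05, 0.9],
        )]
        hits = extract_and_annotate_hits(self._table(rows), self._thr(), [])
        assert len(hits) == 9  # 0.9 is below p99995
        assert (hits["tier"] == 1).sum() == 3
        assert (hits["tier"] == 2).sum() == 6

    def test_flank_boundary_inclusive(self):
        gene = io.GeneInterval("G1", "chr1", 50_000, 60_000)
        pos = gene.start + 1 - 20_000  # first covered position
        hits = extract_and_annotate_hits(
            self._table([("chr1", pos, "v", 1.5)]), self._thr(), [gene]
        )
        assert hits.loc[0, "genes"] == "G1"

    def test_just_outside_flank_intergenic(self):
        gene = io.GeneInterval("G1", "chr1", 50_000, 60_000)
        pos = gene.start + 1 - 20_001
        hits = extract_and_annotate_hits(
            self._table([("chr1", pos, "v", 1.5)]), self._thr(), [gene]
        )
        assert hits.loc[0, "genes"] == "intergenic"

    def test_downstream_boundary(self):
        gene = io.GeneInterval("G1", "chr1", 50_000, 60_000)
        inside = extract_and_annotate_hits(
            self._table([("chr1", 80_000, "v", 1.5)]), self._thr(), [gene]
        )
        outside = extract_and_annotate_hits(
            self._table([("chr1", 80_001, "v", 1.5)]), self._thr(), [gene]
        )
        assert inside.loc[0, "genes"] == "G1"
        assert outside.loc[0, "genes"] == "intergenic"


class TestLocalZoom:
    def _setup(self):
        gene = io.GeneInterval("G1", "chr1", 1_000, 2_000)
        pos = [1_100, 1_200, 1_300, 1_400, 1_500]
        dosage = np.array(
            [
                [0, 1, 2, 1, 0, 2],
                [0, 1, 2, 1, 0, 2],   # identical to index -> r2 = 1
                [2, 1, 0, 1, 2, 0],   # perfectly anti-correlated -> r2 = 1
                [0, 1, 1, 2, 2, 0],
                [1, 1, 1, 1, 1, -1],  # constant among called -> undefined
            ],
            dtype=np.int8,
        )
        pbs_vals = [3.0, 1.0, 0.5, 0.2, 0.1]
        table = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "site_id": [f"v{p}" for p in pos], "pbs": pbs_vals}
        )
        geno_sites = table[["chrom", "pos", "site_id"]]
        return table, geno_sites, dosage, gene

    def test_index_r2_is_one_and_hand_oracle(self):
        table, geno_sites, dosage, gene = self._setup()
        zoom = local_zoom(table, geno_sites, dosage, gene, flank_bp=500)
        assert zoom.loc[zoom["is_index"], "pos"].tolist() == [1_100]
        r2 = dict(zip(zoom["pos"], zoom["r2"]))
        assert r2[1_100] == pytest.approx(1.0)
        assert r2[1_200] == pytest.approx(1.0)
        assert r2[1_300] == pytest.approx(1.0)
        # hand Pearson of [0,1,1,2,2,0] vs [0,1,2,1,0,2]:
        # centred dot = -1, variances 4 and 4, r = -1/4
        assert r2[1_400] == pytest.approx((1 / 4) ** 2, abs=1e-12)
        assert np.isnan(r2[1_500])

    def test_tie_broken_to_smallest_position(self):
        table, geno_sites, dosage, gene = self._setup()
        table.loc[1, "pbs"] = 3.0  # tie with site at 1100
        zoom = local_zoom(table, geno_sites, dosage, gene, flank_bp=500)
        assert zoom.loc[zoom["is_index"], "pos"].tolist() == [1_100]

    def test_empty_window_names_gene(self):
        table, geno_sites, dosage, _ = self._setup()
        far = io.GeneInterval("FAR", "chr9", 10, 20)
        with pytest.raises(ValueError, match="FAR"):
            local_zoom(table, geno_sites, dosage, far, flank_bp=10)


class TestTrioContrast:
    def _tables(self, shift=0.0, n=10_000, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.exponential(0.05, size=n) + shift
        b = rng.exponential(0.05, size=n)
        return (
            pd.DataFrame({"pbs": a}),
            pd.DataFrame({"pbs": b}),
        )

    def test_identical_inputs_no_shift(self):
        t, _ = self._tables()
        res = trio_contrast(t, t.copy())
        assert res.p_value == pytest.approx(0.5, abs=0.02)

    def test_downward_shift_detected(self):
        rng = np.random.default_rng(1)
        lo = pd.DataFrame({"pbs": rng.normal(0.0, 1.0, size=12_000)})
        hi = pd.DataFrame({"pbs": rng.normal(0.0, 1.0, size=12_000) + 0.2})
        res = trio_contrast(lo, hi)
        assert res.n1 >= 1_000 and res.n2 >= 1_000
        assert res.p_value < 0.05
        assert res.median1 < res.median2

    def test_window_bounds_definition(self):
        t1, t2 = self._tables(n=100_000)
        res = trio_contrast(t1, t2)
        # open interval (p90, p99.995): keeps just under 9.995% per side
        for n in (res.n1, res.n2):
            assert n == pytest.approx(0.09995 * 100_000, rel=0.01)

    def test_too_few_values_rejected(self):
        t1, t2 = self._tables(n=50)
        with pytest.raises(ValueError):
            trio_contrast(t1, t2)

    def test_pooled_mode_runs(self):
        t1, t2 = self._tables(n=5_000)
        res = trio_contrast(t1, t2, pooled_percentiles=True)
        assert 0.0 <= res.p_value <= 1.0
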