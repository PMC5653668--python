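"""Allelic-imbalance analysis: MAF, LOH calls, harmonization, pooling."""

import numpy as np
import pandas as pd
import pytest

from lesionevo import loh
from lesionevo.segmentation import best_single_changepoint
from lesionevo.synthetic import degrade_to_low_input, simulate_patient
from tests.conftest import small_patient_config


def snp_rows(sample, chrom, positions, refs, alts):
    return pd.DataFrame(
        {
            "chrom": chrom, "pos": positions, "sample": sample,
            "ref_count": refs, "alt_count": alts,
        }
    )


class TestComputeMaf:
    def test_balanced_and_skewed_arithmetic(self):
        df = pd.concat(
            [
                snp_rows("T", "chr1", [100], [50], [50]),
                snp_rows("T", "chr1", [200], [80], [20]),
            ]
        )
        out = loh.compute_maf(df, "T")
        assert list(out.maf) == [0.5, 0.2]

    def test_depth_threshold_excludes(self):
        df = pd.concat(
            [
                snp_rows("T", "chr1", [100], [5], [4]),   # depth 9
                snp_rows("T", "chr1", [200], [5], [5]),   # depth 10
            ]
        )
        out = loh.compute_maf(df, "T")
        assert list(out.pos) == [200]

    def test_empty_warns(self):
        df = snp_rows("T", "chr1", [100], [3], [3])
        with pytest.warns(UserWarning):
            out = loh.compute_maf(df, "T")
        assert out.empty

    def test_maf_bounded_by_half(self, small_patient):
        out = loh.compute_maf(small_patient.snp_counts, "S0")
        assert out.maf.between(0, 0.5).all()


class TestSegmentMaf:
    def test_balanced_genome_one_segment_per_chromosome(self):
        rng = np.random.default_rng(0)
        frames = []
        for chrom in ("chr1", "chr2"):
            ref = rng.binomial(100, 0.5, 200)
            frames.append(
                snp_rows("T", chrom, np.arange(1, 201) * 100_000, ref, 100 - ref)
            )
        maf = loh.compute_maf(pd.concat(frames, ignore_index=True), "T")
        segs = loh.segment_maf(maf, seed=0)
        assert len(segs) == 2
        assert sorted(segs.chrom) == ["chr1", "chr2"]

    def test_step_recovered_near_oracle(self):
        rng = np.random.default_rng(1)
        maf_vals = np.concatenate(
            [rng.normal(0.5, 0.05, 200).clip(0, 0.5),
             rng.normal(0.25, 0.05, 200).clip(0, 0.5)]
        )
        maf = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, 401) * 100_000, "maf": maf_vals}
        )
        segs = loh.segment_maf(maf, seed=0)
        oracle = best_single_changepoint(maf_vals)
        assert len(segs) == 2
        boundary_snp = np.searchsorted(maf.pos.to_numpy(), segs.iloc[0].end)
        assert abs(boundary_snp - oracle) <= 2

    def test_chromosome_order_irrelevant(self):
        rng = np.random.default_rng(2)
        ref = rng.binomial(100, 0.5, 100)
        a = snp_rows("T", "chrA", np.arange(1, 101) * 1000, ref, 100 - ref)
        b = snp_rows("T", "chrB", np.arange(1, 101) * 1000, 100 - ref, ref)
        maf_ab = loh.compute_maf(pd.concat([a, b]), "T")
        maf_ba = loh.compute_maf(pd.concat([b, a]), "T")
        segs_ab = loh.segment_maf(maf_ab, seed=0).sort_values("chrom")
        segs_ba = loh.segment_maf(maf_ba, seed=0).sort_values("chrom")
        pd.testing.assert_frame_equal(
            segs_ab.reset_index(drop=True), segs_ba.reset_index(drop=True)
        )


class TestCallLoh:
    def make_segments(self, mafs, length=20_000_000):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [i * length for i in range(len(mafs))],
                "end": [(i + 1) * length for i in range(len(mafs))],
                "n_snps": 50,
                "maf_tumor": mafs,
            }
        )

    def normal_maf(self, value=0.5):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, 200) * 500_000, "maf": value}
        )

    def test_threshold_is_strict_at_010(self):
        segs = self.make_segments([0.38, 0.45])
        out, _ = loh.call_loh(segs, self.normal_maf())
        assert list(out.loh) == [True, False]  # deltas 0.12 and 0.05

    def test_confidence_tiers_against_minimum(self):
        segs = self.make_segments([0.15, 0.22, 0.30, 0.38])
        out, proxy = loh.call_loh(segs, self.normal_maf())
        assert proxy == 0.15
        assert out.loh.all()
        assert list(out.confidence) == ["high", "high", "intermediate", "low"]

    def test_no_confidence_for_balanced_segments(self):
        segs = self.make_segments([0.48])
        out, _ = loh.call_loh(segs, self.normal_maf())
        assert out.confidence.iloc[0] is None

    def test_purity_proxy_requires_10mb(self):
        segs = self.make_segments([0.2], length=5_000_000)
        with pytest.warns(UserWarning):
            _, proxy = loh.call_loh(segs, self.normal_maf())
        assert np.isnan(proxy)

    def test_purity_proxy_tracks_simulated_purity(self):
        """Higher purity suppresses the minor allele further: the proxy
        decreases as true purity increases."""
        proxies = {}
        for purity in (0.5, 0.7, 0.9):
            cfg = small_patient_config(
                seed=21, n_samples=3, purity_range=(purity, purity)
            )
            p = simulate_patient(cfg)
            maf = loh.compute_maf(p.snp_counts, "S0")
            normal = loh.compute_maf(p.snp_counts, "normal")
            segs = loh.segment_maf(maf, n_perm=200, seed=0)
            _, proxies[purity] = loh.call_loh(segs, normal)
        assert proxies[0.9] < proxies[0.7] < proxies[0.5]


class TestHarmonize:
    def run_small(self, seed=11, **kwargs):
        p = simulate_patient(small_patient_config(seed=seed))
        samples = p.tumor_samples
        maf = {s: loh.compute_maf(p.snp_counts, s) for s in samples}
        nmaf = loh.compute_maf(p.snp_counts, "normal")
        segd, proxy = {}, {}
        for s in samples:
            segs = loh.segment_maf(maf[s], n_perm=300, seed=1)
            segd[s], proxy[s] = loh.call_loh(segs, nmaf)
        return p, loh.harmonize_patient_segments(
            segd, maf, nmaf, proxy, **kwargs
        )

    def test_recovers_truth_markers_with_correct_patterns(self):
        p, ps = self.run_small()
        samples = p.tumor_samples
        truth = {
            (t.chrom, frozenset(t.samples)) for t in p.truth_segments
        }
        found = {
            (seg.chrom, frozenset(s for s in samples if getattr(seg, f"loh_{s}")))
            for seg in ps.itertuples()
        }
        assert truth <= found

    def test_identical_segments_pass_through(self):
        _, ps = self.run_small()
        # chr1 whole-chromosome event: exactly one marker, not fragments
        assert (ps.chrom == "chr1").sum() == 1

    def test_minimum_size_enforced(self):
        _, ps = self.run_small(min_length_mb=1e9)
        assert ps.empty

    def test_min_snps_enforced(self):
        _, ps = self.run_small(min_snps=10_000)
        assert ps.empty

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            loh.harmonize_patient_segments({"S0": pd.DataFrame()}, {}, None, {})

    def test_adjacent_merge_rule(self):
        """Two abutting fragments with identical calls and small MAF deltas
        merge; a brute-force check over adjacent pairs agrees."""
        samples = ["S0"]
        atoms = [
            {"chrom": "chr1", "start": 0, "end": 30_000_000, "n_snps": 60,
             "maf_normal": 0.5, "maf_S0": 0.20, "loh_S0": True, "conf_S0": "high"},
            {"chrom": "chr1", "start": 34_000_000, "end": 60_000_000, "n_snps": 60,
             "maf_normal": 0.5, "maf_S0": 0.23, "loh_S0": True, "conf_S0": "high"},
            {"chrom": "chr1", "start": 61_000_000, "end": 90_000_000, "n_snps": 60,
             "maf_normal": 0.5, "maf_S0": 0.48, "loh_S0": False, "conf_S0": None},
        ]
        merged = loh._merge_atoms(atoms, samples, 5.0, 0.05)
        assert len(merged) == 2
        assert merged[0]["end"] == 60_000_000
        # brute force: every adjacent pair, merge iff all conditions hold
        for a, b in zip(atoms, atoms[1:]):
            expected = (
                b["start"] - a["end"] <= 5_000_000
                and a["loh_S0"] == b["loh_S0"]
                and abs(a["maf_S0"] - b["maf_S0"]) <= 0.05
            )
            assert loh._mergeable(a, b, samples, 5.0, 0.05) == expected


class TestPooledLowInput:
    def test_pooled_ratio_arithmetic(self):
        """30 SNPs x 4x coverage with 12 minor of 120 total reads -> MAF 0.10,
        called LOH against a balanced normal (oracle: direct summation)."""
        positions = np.arange(1, 31) * 1_000_000
        low = snp_rows("P", "chr1", positions,
                       refs=[1] * 12 + [0] * 18,        # 12 minor(ref) reads
                       alts=[3] * 12 + [4] * 18)
        votes = snp_rows("S1", "chr1", positions, [20] * 30, [80] * 30)
        normal = snp_rows("normal", "chr1", positions, [50] * 30, [50] * 30)
        counts = pd.concat([low, votes, normal], ignore_index=True)
        segs = pd.DataFrame(
            [{"marker_id": "L0", "chrom": "chr1", "start": 0, "end": 40_000_000}]
        )
        out = loh.pooled_loh_low_input(segs, counts, "P", ["S1"])
        row = out.iloc[0]
        assert row.pooled_maf == pytest.approx(12 / 120)
        assert row.pooled_maf_normal == pytest.approx(0.5)
        assert bool(row.loh)

    def test_below_margin_not_loh(self):
        positions = np.arange(1, 31) * 1_000_000
        low = snp_rows("P", "chr1", positions, [2] * 30, [2] * 30)
        votes = snp_rows("S1", "chr1", positions, [40] * 30, [60] * 30)
        normal = snp_rows("normal", "chr1", positions, [50] * 30, [50] * 30)
        counts = pd.concat([low, votes, normal], ignore_index=True)
        segs = pd.DataFrame(
            [{"marker_id": "L0", "chrom": "chr1", "start": 0, "end": 40_000_000}]
        )
        out = loh.pooled_loh_low_input(segs, counts, "P", ["S1"])
        assert not out.iloc[0].loh

    def test_majority_vote_two_against_one(self):
        positions = [1_000_000]
        s1 = snp_rows("S1", "chr1", positions, [20], [80])   # minor = ref
        s2 = snp_rows("S2", "chr1", positions, [25], [75])   # minor = ref
        s3 = snp_rows("S3", "chr1", positions, [80], [20])   # minor = alt
        by_sample = {
            s: df.set_index(["chrom", "pos"])
            for s, df in (("S1", s1), ("S2", s2), ("S3", s3))
        }
        minor = loh._vote_minor_allele(
            ("chr1", 1_000_000), by_sample, ["S1", "S2", "S3"], 10
        )
        assert minor == "ref"

    def test_zero_coverage_segment_flagged(self):
        positions = [1_000_000]
        low = snp_rows("P", "chr1", positions, [0], [0])
        votes = snp_rows("S1", "chr1", positions, [20], [80])
        normal = snp_rows("normal", "chr1", positions, [50], [50])
        counts = pd.concat([low, votes, normal], ignore_index=True)
        segs = pd.DataFrame(
            [{"marker_id": "L0", "chrom": "chr1", "start": 0, "end": 2_000_000}]
        )
        out = loh.pooled_loh_low_input(segs, counts, "P", ["S1"])
        assert not out.iloc[0].defined

    def test_thinned_sample_recovers_full_coverage_calls(self):
        """End to end: define patient segments without the degraded sample,
        then pooled calls on the 5%-coverage sample match the segments'
        truth presence for that sample."""
        p = simulate_patient(small_patient_config(seed=13, n_samples=4))
        thin = degrade_to_low_input(p, "S3", 0.05, seed=3)
        samples = [s for s in p.tumor_samples if s != "S3"]
        maf = {s: loh.compute_maf(thin.snp_counts, s) for s in samples}
        nmaf = loh.compute_maf(thin.snp_counts, "normal")
        segd, proxy = {}, {}
        for s in samples:
            segs = loh.segment_maf(maf[s], n_perm=300, seed=1)
            segd[s], proxy[s] = loh.call_loh(segs, nmaf)
        ps = loh.harmonize_patient_segments(segd, maf, nmaf, proxy)
        pooled = loh.pooled_loh_low_input(ps, thin.snp_counts, "S3", samples)
        truth_by_chrom = {
            t.chrom: "S3" in t.samples for t in p.truth_segments
        }
        checked = 0
        for row in pooled.itertuples():
            if row.chrom in truth_by_chrom and row.defined:
                assert row.loh == truth_by_chrom[row.chrom]
                checked += 1
        assert checked >= 2
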