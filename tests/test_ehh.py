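"""EHH/iHH/iHS core: oracles, symmetries, standardization contracts."""

import numpy as np
import pandas as pd
import pytest

from haploscan.ehh import (
    ANCESTRAL,
    DERIVED,
    EHHProfile,
    ehh_at,
    ehh_profile,
    ihh,
    scan_ihs,
    standardize,
    unstandardized_ihs,
)
from haploscan.formats import HaplotypeMatrix

from conftest import make_map, random_hap


def pairwise_ehh_oracle(values, core, allele, target):
    """O(n^2) reference: fraction of carrier pairs identical over the interval."""
    carriers = np.nonzero(values[:, core] == allele)[0]
    lo, hi = min(core, target), max(core, target)
    n = len(carriers)
    same = 0
    for a in range(n):
        for b in range(a + 1, n):
            if np.array_equal(values[carriers[a], lo:hi + 1], values[carriers[b], lo:hi + 1]):
                same += 1
    return same / (n * (n - 1) / 2)


class TestEHHAt:
    def test_target_equals_core_is_one(self, rng):
        hap = random_hap(rng, 12, 20)
        assert ehh_at(hap, 5, DERIVED, 5) == 1.0

    def test_hand_enumerated_groups(self):
        # 4 derived carriers split into extended-haplotype groups (2,1,1):
        # identical pairs = 1 of 6 -> EHH = 1/6
        values = np.array([
            [1, 1, 0],   # carriers: rows 0-3 (core = column 0)
            [1, 1, 0],
            [1, 0, 1],
            [1, 0, 0],
            [0, 0, 0],
            [0, 1, 1],
        ], dtype=np.int8)
        hap = HaplotypeMatrix(values)
        assert ehh_at(hap, 0, DERIVED, 2) == pytest.approx(1 / 6)

    def test_matches_pairwise_oracle_on_random_matrices(self, rng):
        hap = random_hap(rng, 30, 80)
        for _ in range(50):
            core = int(rng.integers(0, 80))
            target = int(rng.integers(0, 80))
            allele = int(rng.integers(0, 2))
            if (hap.values[:, core] == allele).sum() < 2:
                continue
            got = ehh_at(hap, core, allele, target)
            assert got == pytest.approx(
                pairwise_ehh_oracle(hap.values, core, allele, target), abs=1e-12)

    def test_single_carrier_rejected(self, rng):
        values = np.zeros((6, 4), dtype=np.int8)
        values[0, 1] = 1
        with pytest.raises(ValueError, match="carriers"):
            ehh_at(HaplotypeMatrix(values), 1, DERIVED, 3)


class TestEHHProfile:
    def test_profile_matches_ehh_at_everywhere(self, rng):
        hap = random_hap(rng, 24, 60)
        mmap = make_map(60)
        prof = ehh_profile(hap, mmap, 30, ANCESTRAL, trunc_ehh=0.0)
        for side, step in ((prof.left, -1), (prof.right, +1)):
            for k, (dist, val) in enumerate(side):
                target = 30 + step * (k + 1)  # consecutive extension steps
                assert abs(mmap.pos[target] - mmap.pos[30]) == dist
                assert val == pytest.approx(ehh_at(hap, 30, ANCESTRAL, target), abs=1e-12)

    def test_monotone_non_increasing(self, rng):
        hap = random_hap(rng, 24, 60)
        prof = ehh_profile(hap, make_map(60), 30, DERIVED, trunc_ehh=0.0)
        for side in (prof.left, prof.right):
            if len(side):
                assert np.all(np.diff(side[:, 1]) <= 1e-15)

    def test_identical_carriers_reach_chromosome_end(self):
        values = np.zeros((10, 30), dtype=np.int8)
        values[:4, :] = 1  # 4 derived carriers, all identical everywhere
        values[4, 0] = 1   # keep other columns polymorphic? not needed for profile
        hap = HaplotypeMatrix(values)
        prof = ehh_profile(hap, make_map(30), 15, DERIVED)
        assert prof.left_reason == "chromosome_end"
        assert prof.right_reason == "chromosome_end"
        assert np.all(prof.left[:, 1] == 1.0) and np.all(prof.right[:, 1] == 1.0)

    def test_zero_threshold_never_truncates_below(self, rng):
        hap = random_hap(rng, 20, 50)
        prof = ehh_profile(hap, make_map(50), 25, ANCESTRAL, trunc_ehh=0.0,
                           max_extension=10_000)
        assert prof.left_reason in ("chromosome_end", "max_extension")
        assert prof.right_reason in ("chromosome_end", "max_extension")

    def test_gap_truncation(self, rng):
        hap = random_hap(rng, 20, 50)
        mmap = make_map(50)
        mmap.df.loc[40:, "pos"] += 300_000  # open a 300-kb gap after SNP 39
        prof = ehh_profile(hap, mmap, 35, ANCESTRAL, trunc_ehh=0.0, max_gap=200_000)
        assert prof.right_reason == "max_gap"


class TestIHH:
    def test_hand_trapezoid(self):
        prof = EHHProfile(core=0, allele=1, n_carriers=4,
                          left=np.empty((0, 2)),
                          right=np.array([[1000.0, 0.5]]),
                          left_reason="below_threshold", right_reason="below_threshold")
        assert ihh(prof) == pytest.approx(750.0)  # (1.0 + 0.5)/2 * 1000

    def test_rectangle(self):
        pts = np.column_stack([np.linspace(100, 5000, 25), np.ones(25)])
        prof = EHHProfile(0, 1, 4, pts.copy(), pts.copy(), "below_threshold", "below_threshold")
        assert ihh(prof) == pytest.approx(2 * 5000.0)

    def test_midpoint_refinement_invariance(self, rng):
        dist = np.sort(rng.uniform(100, 10_000, size=8))
        vals = np.sort(rng.uniform(0.1, 1.0, size=8))[::-1]
        side = np.column_stack([dist, vals])
        # insert midpoints with linearly interpolated EHH
        full = np.vstack([[0.0, 1.0], side])
        mid_d = (full[:-1, 0] + full[1:, 0]) / 2
        mid_v = (full[:-1, 1] + full[1:, 1]) / 2
        refined = np.vstack([side, np.column_stack([mid_d, mid_v])])
        refined = refined[np.argsort(refined[:, 0])]
        a = EHHProfile(0, 1, 4, np.empty((0, 2)), side, "below_threshold", "below_threshold")
        b = EHHProfile(0, 1, 4, np.empty((0, 2)), refined, "below_threshold", "below_threshold")
        assert ihh(a) == pytest.approx(ihh(b), rel=1e-12)


class TestUnstandardizedIHS:
    def test_mirror_structure_gives_zero(self):
        rng = np.random.default_rng(3)
        pattern = rng.integers(0, 2, size=(5, 41), dtype=np.int8)
        values = np.vstack([pattern, pattern])  # two identical blocks
        values[:5, 20] = 0   # ancestral carriers
        values[5:, 20] = 1   # derived carriers, same flanking structure
        hap = HaplotypeMatrix(values)
        rec = unstandardized_ihs(hap, make_map(41), 20, censor_chromosome_ends=False,
                                 min_carriers=2)
        assert rec.valid
        assert rec.u == pytest.approx(0.0, abs=1e-15)

    def test_long_derived_haplotypes_give_negative_u(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 2, size=(20, 41), dtype=np.int8)
        values[:8, :] = values[0, :]  # derived carriers all identical
        values[:8, 20] = 1
        values[8:, 20] = 0
        hap = HaplotypeMatrix(values)
        rec = unstandardized_ihs(hap, make_map(41), 20, censor_chromosome_ends=False)
        assert rec.valid and rec.u < 0

    def test_label_swap_negates_u_exactly(self, rng):
        hap = random_hap(rng, 30, 61)
        mmap = make_map(61)
        snp = 30
        rec = unstandardized_ihs(hap, mmap, snp, censor_chromosome_ends=False)
        flipped = hap.values.copy()
        flipped[:, snp] = 1 - flipped[:, snp]
        rec2 = unstandardized_ihs(HaplotypeMatrix(flipped), mmap, snp,
                                  censor_chromosome_ends=False)
        assert rec.valid and rec2.valid
        assert rec2.u == pytest.approx(-rec.u, abs=1e-12)

    def test_u_matches_profile_composition(self, rng):
        hap = random_hap(rng, 30, 61)
        mmap = make_map(61)
        rec = unstandardized_ihs(hap, mmap, 30, censor_chromosome_ends=False)
        ihh_a = ihh(ehh_profile(hap, mmap, 30, ANCESTRAL))
        ihh_d = ihh(ehh_profile(hap, mmap, 30, DERIVED))
        assert rec.u == pytest.approx(np.log(ihh_a / ihh_d), abs=1e-12)

    def test_few_carriers_invalid_not_exception(self):
        values = np.zeros((12, 21), dtype=np.int8)
        values[:2, 10] = 1
        values[0, 5] = 1
        rec = unstandardized_ihs(HaplotypeMatrix(values), make_map(21), 10)
        assert not rec.valid and rec.reason == "few_carriers"


def make_u_table(u, freq):
    return pd.DataFrame({
        "derived_freq": freq, "u": u,
        "valid": np.ones(len(u), dtype=bool), "reason": "",
    })


class TestStandardize:
    def test_single_bin_two_values(self):
        table = make_u_table(np.array([-1.0, 1.0]), np.array([0.3, 0.6]))
        out, bins = standardize(table, n_bins=1, min_bin_n=2)
        np.testing.assert_allclose(out["ihs"], [-1.0, 1.0])

    def test_location_invariance(self, rng):
        u = rng.normal(size=100)
        freq = rng.uniform(0.05, 0.95, size=100)
        a, _ = standardize(make_u_table(u, freq), n_bins=5, min_bin_n=5)
        b, _ = standardize(make_u_table(u + 3.7, freq), n_bins=5, min_bin_n=5)
        np.testing.assert_allclose(a["ihs"], b["ihs"], atol=1e-12)

    def test_per_bin_moments(self, rng):
        u = rng.normal(size=2000)
        freq = rng.uniform(0, 1, size=2000)
        out, bins = standardize(make_u_table(u, freq), n_bins=20, min_bin_n=10)
        which = np.clip(np.digitize(freq, bins.edges[1:-1]), 0, 19)
        for b in np.nonzero(bins.usable)[0]:
            vals = out.loc[which == b, "ihs"]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_zero_spread_bin_unusable(self):
        table = make_u_table(np.full(20, 2.5), np.full(20, 0.5))
        out, bins = standardize(table, n_bins=1, min_bin_n=2)
        assert not bins.usable.any()
        assert not out["valid"].any()


class TestScan:
    def test_maf_filter_excludes_snp(self, rng):
        hap = random_hap(rng, 40, 30)
        hap.values[:, 12] = 0
        hap.values[0, 12] = 1  # MAF 1/40 = 0.025 < 0.05
        mmap = make_map(30)
        table, _ = scan_ihs(hap, mmap, maf_min=0.05, censor_chromosome_ends=False)
        assert 12 not in set(table["snp_index"])

    def test_unknown_ancestral_excluded(self, rng):
        hap = random_hap(rng, 40, 30)
        mmap = make_map(30)
        mmap.df.loc[7, "ancestral"] = "unknown"
        table, _ = scan_ihs(hap, mmap, maf_min=0.0, censor_chromosome_ends=False)
        assert 7 not in set(table["snp_index"])
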