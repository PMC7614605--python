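"""Ten-step subclonal deconvolution: denoising, purity, CCFs, presence,
detection limits and clonal sweeps."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize

from phylotrace import (SimulationConfig, calibrate_ccf_sd_threshold,
                        call_clone_presence, call_tumour_presence,
                        ccf_from_vaf, compute_ccfs, denoise_vafs,
                        estimate_tumour_purity, expected_vaf,
                        flag_poor_quality_clones, min_detectable_ccf,
                        min_detectable_purity, naive_vaf_ccf,
                        purity_from_vaf, representative_min_ccf,
                        run_eclipse_sample, simulate_patient)
from phylotrace import test_clonal_sweep as clonal_sweep_test

from conftest import make_counts, make_variant


def purity_bruteforce(vaf, m, cnt, cnn):
    """Numerical root-find of the forward equation at CCF = 1."""
    return optimize.brentq(lambda p: expected_vaf(p, m, 1.0, cnt, cnn) - vaf, 0, 1)


def ccf_bruteforce(vaf, purity, m, cnt, cnn):
    return optimize.brentq(lambda c: expected_vaf(purity, m, c, cnt, cnn) - vaf, 0, 10)


class TestForwardModelInversions:
    @pytest.mark.parametrize("vaf, m, cnt, cnn, expected", [
        (0.005, 1.0, 2.0, 2.0, 0.01),
        (0.01, 2.0, 4.0, 2.0, 0.02 / 1.98),
        (0.0, 1.0, 2.0, 2.0, 0.0),
    ])
    def test_purity_inversion_against_root_finder(self, vaf, m, cnt, cnn, expected):
        got = purity_from_vaf(vaf, m, cnt, cnn)
        assert got == pytest.approx(expected, abs=1e-12)
        if vaf > 0:
            assert got == pytest.approx(purity_bruteforce(vaf, m, cnt, cnn), abs=1e-10)

    def test_ccf_inversion_against_root_finder(self):
        got = ccf_from_vaf(0.0005, 0.01, 1.0, 2.0, 2.0)
        assert got == pytest.approx(0.1, abs=1e-12)
        assert got == pytest.approx(ccf_bruteforce(0.0005, 0.01, 1.0, 2.0, 2.0), abs=1e-10)

    @pytest.mark.parametrize("purity, m, ccf, cnt", [
        (0.002, 1.0, 1.0, 2.0), (0.05, 2.0, 0.4, 4.0), (0.5, 1.0, 0.1, 3.0),
    ])
    def test_noise_free_round_trip(self, purity, m, ccf, cnt):
        vaf = expected_vaf(purity, m, ccf, cnt)
        if ccf == 1.0:
            assert purity_from_vaf(vaf, m, cnt) == pytest.approx(purity, abs=1e-10)
        assert ccf_from_vaf(vaf, purity, m, cnt) == pytest.approx(ccf, abs=1e-10)


class TestDenoising:
    def _run(self, daos, ddps, ers):
        variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                    for i in range(len(daos))]
        counts = {f"v{i}": make_counts(f"v{i}", dao, ddp)
                  for i, (dao, ddp) in enumerate(zip(daos, ddps))}
        err = {f"v{i}": er for i, er in enumerate(ers)}
        return denoise_vafs(variants, counts, err)

    @pytest.mark.parametrize("total_err, expected_groups", [
        (1.4, 1), (3.5, 3), (9.0, 4),
    ])
    def test_group_count_follows_total_error(self, total_err, expected_groups):
        n = 10
        per = total_err / n
        # spread error slightly so groups are distinguishable
        ers = [per * (1 + 0.01 * i) / 10_000 * 10_000 for i in range(n)]
        scale = total_err / sum(e * 10_000 for e in [er / 10_000 for er in ers])
        ers = [er / 10_000 * scale for er in ers]
        out = self._run([0] * n, [10_000] * n, ers)
        assert len({d.error_group for d in out}) == expected_groups

    def test_denoised_vaf_subtracts_group_mean(self):
        out = self._run([3], [10_000], [1.0 / 10_000])
        assert out[0].denoised_vaf == pytest.approx((3 - 1.0) / 10_000)

    def test_hard_filtered_and_empty_clone(self):
        variants = [make_variant("v0", clone_id="a", hard_filtered=True)]
        assert denoise_vafs(variants, {"v0": make_counts("v0", 1, 100)}, {"v0": 0.0}) == []


class TestPurityAndCcf:
    def test_purity_is_mean_of_clonal_inversions(self):
        variants = {f"v{i}": make_variant(f"v{i}", pos=100 + i) for i in range(2)}
        den = []
        for i, vaf in enumerate([0.004, 0.006]):
            dao = int(vaf * 10_000)
            den.append(
                denoise_vafs([variants[f"v{i}"]],
                             {f"v{i}": make_counts(f"v{i}", dao, 10_000)},
                             {f"v{i}": 0.0})[0])
        assert estimate_tumour_purity(den, variants) == pytest.approx(0.01)

    def test_ccf_caps_at_one(self):
        v = make_variant("v0")
        den = denoise_vafs([v], {"v0": make_counts("v0", 80, 10_000)}, {"v0": 0.0})
        table = compute_ccfs(den, {"v0": v}, purity=0.01)
        assert table["ccf"].iloc[0] == 1.0
        assert table["raw_ccf"].iloc[0] > 1.0

    def test_zero_purity_gives_empty_table(self):
        v = make_variant("v0")
        den = denoise_vafs([v], {"v0": make_counts("v0", 10, 10_000)}, {"v0": 0.0})
        assert compute_ccfs(den, {"v0": v}, purity=0.0).empty


class TestPoorQualityFlagging:
    def _table(self, ccfs, clone="a"):
        import pandas as pd
        return pd.DataFrame({"variant_id": [f"v{i}" for i in range(len(ccfs))],
                             "clone_id": clone, "ccf": ccfs, "raw_ccf": ccfs})

    def test_cv_hand_arithmetic_keep(self):
        out = flag_poor_quality_clones(self._table([0.4, 0.5, 0.6]))
        assert out["normalised_sd"].iloc[0] == pytest.approx(0.2)
        assert not out["poor_quality"].iloc[0]

    def test_cv_hand_arithmetic_flag(self):
        out = flag_poor_quality_clones(self._table([0.05, 0.5, 0.9]))
        assert out["normalised_sd"].iloc[0] == pytest.approx(0.8797, abs=1e-3)
        assert out["poor_quality"].iloc[0]

    def test_identical_ccfs_keep(self):
        out = flag_poor_quality_clones(self._table([0.5, 0.5, 0.5]))
        assert out["normalised_sd"].iloc[0] == 0.0 and not out["poor_quality"].iloc[0]

    def test_single_mutation_clone_not_flaggable(self):
        out = flag_poor_quality_clones(self._table([0.5]))
        assert math.isnan(out["normalised_sd"].iloc[0])
        assert not out["poor_quality"].iloc[0]


class TestThresholdCalibration:
    def test_bound_covers_upper_tail_of_cv_distribution(self, rng):
        cvs = rng.gamma(4.0, 0.05, size=400)
        got = calibrate_ccf_sd_threshold(cvs)
        # bootstrap oracle for the 95th percentile
        boot = [np.quantile(rng.choice(cvs, len(cvs)), 0.95) for _ in range(300)]
        assert np.quantile(boot, 0.01) <= got <= np.quantile(boot, 0.99)

    def test_identical_cvs_give_that_cv(self):
        assert calibrate_ccf_sd_threshold([0.3] * 10) == pytest.approx(0.3)

    def test_too_few_samples_falls_back_to_default(self):
        with pytest.warns(UserWarning, match="default"):
            assert calibrate_ccf_sd_threshold([0.2, 0.3]) == 0.56


class TestPresenceCalls:
    def _clone(self, daos, er=2.5e-5, ddp=5000, mid=False):
        variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False,
                                 mid_filtered=mid, pos=100 + i)
                    for i in range(len(daos))]
        counts = {f"v{i}": make_counts(f"v{i}", d, ddp) for i, d in enumerate(daos)}
        err = {f"v{i}": er for i in range(len(daos))}
        return variants, counts, err

    def test_zero_signal_absent(self):
        p, present = call_clone_presence(*self._clone([0, 0, 0, 0]))
        assert p == 1.0 and not present

    def test_six_reads_at_half_lambda_present(self):
        variants, counts, err = self._clone([3, 1, 2, 0], ddp=5000)
        p, present = call_clone_presence(variants, counts, err)
        assert p == pytest.approx(1.4e-5, rel=0.05)
        assert present

    def test_two_reads_at_half_lambda_absent(self):
        variants, counts, err = self._clone([1, 1, 0, 0], ddp=5000)
        p, present = call_clone_presence(variants, counts, err)
        assert p == pytest.approx(0.0902, abs=1e-3)
        assert not present

    def test_mid_filtered_variants_excluded(self):
        variants, counts, err = self._clone([5, 5, 5, 5], mid=True)
        p, present = call_clone_presence(variants, counts, err)
        assert math.isnan(p) and not present

    def test_tumour_presence_matches_clone_presence_for_one_clone(self):
        variants, counts, err = self._clone([3, 1, 2, 0])
        assert call_tumour_presence(variants, counts, err) == \
            call_clone_presence(variants, counts, err)

    def test_presence_false_positive_rate_bounded(self, rng):
        # background-only subclones: empirical detection fraction <= alpha
        er, ddp = 1e-5, 2000
        lam = 4 * ddp * er
        hits = 0
        for _ in range(1000):
            dao = rng.poisson(lam)
            from phylotrace import poisson_upper_tail
            hits += poisson_upper_tail(int(dao), lam) < 0.01
        assert hits / 1000 <= 0.01


class TestDetectionLimits:
    def test_min_detectable_ccf_chained_example(self):
        # lambda 0.2 over 4 variants at mean ddp 2226, purity 0.002 -> 0.337
        ddp = 2226
        er = 0.2 / (4 * ddp)
        variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                    for i in range(4)]
        counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(4)}
        err = {f"v{i}": er for i in range(4)}
        got = min_detectable_ccf(variants, counts, err, purity=0.002)
        assert got == pytest.approx(3 / 8904 * 2 / 0.002, rel=1e-9)
        assert got == pytest.approx(0.337, abs=5e-3)

    def test_doubling_depth_halves_min_ccf_at_fixed_lambda(self):
        for ddp, expected_ratio in ((2000, 1.0), (4000, 0.5)):
            er = 0.2 / (4 * ddp)
            variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                        for i in range(4)]
            counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(4)}
            err = {f"v{i}": er for i in range(4)}
            got = min_detectable_ccf(variants, counts, err, purity=0.01)
            if ddp == 2000:
                base = got
        assert got == pytest.approx(base / 2)

    def test_monotone_in_purity_and_mutation_count(self):
        er, ddp = 1e-5, 2000
        prev = math.inf
        for n in (2, 4, 8, 16):
            variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                        for i in range(n)]
            counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(n)}
            err = {f"v{i}": er for i in range(n)}
            got = min_detectable_ccf(variants, counts, err, purity=0.002)
            assert got <= prev + 1e-12
            prev = got
        prev = math.inf
        variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                    for i in range(4)]
        counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(4)}
        err = {f"v{i}": er for i in range(4)}
        for purity in (0.001, 0.002, 0.01, 0.05):
            got = min_detectable_ccf(variants, counts, err, purity=purity)
            assert got <= prev + 1e-12
            prev = got

    def test_representative_min_ccf_near_paper_scale(self):
        # 0.1% clonal level, depth 2226, near-zero background -> ~0.225
        ddp = 2226
        variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                    for i in range(4)]
        counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(4)}
        err = {f"v{i}": 1e-5 for i in range(4)}
        purity = purity_from_vaf(0.001, 1.0, 2.0)  # 0.1% clonal level
        got = representative_min_ccf(variants, counts, err, purity, n_mut=4)
        assert got == pytest.approx(2 / (4 * ddp) * 2 / purity, rel=1e-9)
        assert 0.15 <= got <= 0.35

    def test_representative_min_ccf_monotone_in_n_mut(self):
        ddp = 2226
        variants = [make_variant(f"v{i}", clone_id="a", is_clonal=False, pos=100 + i)
                    for i in range(4)]
        counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(4)}
        err = {f"v{i}": 1e-5 for i in range(4)}
        a = representative_min_ccf(variants, counts, err, 0.002, n_mut=4)
        b = representative_min_ccf(variants, counts, err, 0.002, n_mut=8)
        assert b < a

    def test_min_detectable_purity_chained_example(self):
        # k*=5 at lambda 1, ddp 100_000, m=1 diploid -> purity 1e-4
        ddp = 50_000
        er = 1.0 / (2 * ddp)
        variants = [make_variant(f"v{i}", pos=100 + i) for i in range(2)]
        counts = {f"v{i}": make_counts(f"v{i}", 0, ddp) for i in range(2)}
        err = {f"v{i}": er for i in range(2)}
        got = min_detectable_purity(variants, counts, err)
        assert got == pytest.approx(1e-4, rel=1e-9)

    def test_empty_panel_missing(self):
        assert math.isnan(min_detectable_purity([], {}, {}))


class TestClonalSweep:
    def test_sweep_called_when_ccfs_match_clonal(self):
        p, sweep, ok = clonal_sweep_test([1.0, 0.98, 1.0, 0.99],
                                         [1.0, 1.0, 0.97, 0.99, 1.0])
        assert ok and p > 0.05 and sweep

    def test_low_ccf_never_sweeps(self):
        p, sweep, ok = clonal_sweep_test([0.30, 0.35, 0.28, 0.32],
                                         [1.0, 0.99, 1.0, 0.98])
        assert ok and not sweep

    def test_identical_distributions(self):
        p, sweep, ok = clonal_sweep_test([0.95, 0.95], [0.95, 0.95])
        assert p == 1.0 and sweep
        p, sweep, ok = clonal_sweep_test([0.5, 0.5], [0.5, 0.5])
        assert p == 1.0 and not sweep  # mean below 90%

    def test_too_few_mutations_unevaluable(self):
        p, sweep, ok = clonal_sweep_test([1.0], [1.0, 1.0])
        assert not ok and not sweep

    def test_sweep_power_on_simulated_sweeps(self, rng):
        """Sweeps (subclone at CCF 1) accepted and 50% subclones rejected,
        each at >= 95% over replicates, 8 mutations per side."""
        n_rep, n_mut = 200, 8
        noise = 0.04
        sweeps = rejects = 0
        for _ in range(n_rep):
            clonal = np.clip(rng.normal(1.0, noise, n_mut), 0, 1)
            swept = np.clip(rng.normal(1.0, noise, n_mut), 0, 1)
            half = np.clip(rng.normal(0.5, noise, n_mut), 0, 1)
            _, s1, _ = clonal_sweep_test(swept, clonal)
            _, s2, _ = clonal_sweep_test(half, clonal)
            sweeps += s1
            rejects += not s2
        assert sweeps / n_rep >= 0.95
        assert rejects / n_rep >= 0.95


class TestNaiveComparator:
    def test_ratio_of_means(self):
        assert naive_vaf_ccf([0.0005], [0.001]) == pytest.approx(0.5)
        assert naive_vaf_ccf([0.001, 0.001], [0.001, 0.001]) == pytest.approx(1.0)

    def test_underestimates_under_wgd_while_copy_aware_recovers(self):
        # clonal mutations at multiplicity 2 (whole-genome doubled), CNt 4;
        # subclone at multiplicity 1, diploid, true CCF 0.5
        purity, true_ccf = 0.02, 0.5
        clonal_vaf = expected_vaf(purity, 2.0, 1.0, 4.0)
        sub_vaf = expected_vaf(purity, 1.0, true_ccf, 2.0)
        naive = naive_vaf_ccf([sub_vaf], [clonal_vaf])
        assert naive < 0.8 * true_ccf
        est_purity = purity_from_vaf(clonal_vaf, 2.0, 4.0)
        assert ccf_from_vaf(sub_vaf, est_purity, 1.0, 2.0) == pytest.approx(true_ccf, abs=1e-10)


class TestEndToEnd:
    def test_noise_free_cohort_recovers_purity_and_ccfs(self):
        """Counts drawn at expectation (no sampling noise) invert exactly."""
        variants = []
        counts = []
        err = {}
        purity = 0.01
        clone_ccfs = {"clonal": 1.0, "a": 0.6, "b": 0.25}
        ddp = 10_000_000  # depth large enough that rounding DAO is negligible
        i = 0
        for clone, ccf in clone_ccfs.items():
            for _ in range(4):
                i += 1
                vid = f"v{i}"
                variants.append(make_variant(vid, clone_id=clone,
                                             is_clonal=clone == "clonal", pos=100 + i))
                vaf = expected_vaf(purity, 1.0, ccf, 2.0)
                counts.append(make_counts(vid, round(vaf * ddp), ddp))
                err[vid] = 0.0
        sample, clones, table = run_eclipse_sample(variants, counts, err)
        assert sample.ctdna_purity == pytest.approx(purity, abs=1e-8)
        for c in clones:
            assert c.ccf == pytest.approx(clone_ccfs[c.clone_id], abs=1e-6)

    def test_simulated_patient_recovers_structure(self, simulated_patient):
        variants, counts, background, profile, truth = simulated_patient
        err = {v.variant_id: profile[v.tnc_alt] for v in variants}
        sample, clones, _ = run_eclipse_sample(variants, counts, err, input_ng=23.0)
        assert sample.tumour_present
        assert sample.ctdna_purity == pytest.approx(truth.purity, rel=0.25)
        est = {c.clone_id: c.ccf for c in clones if c.present}
        for clone_id, ccf in est.items():
            if not math.isnan(ccf):
                assert abs(ccf - truth.clone_ccf[clone_id]) < 0.25
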