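"""Binning, GC correction, the copy-number HMM and tumor-fraction recovery."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from fragmentome import cna
from fragmentome.simulate import (CNAProfile, CNASegment, SimulationConfig,
                                  SizeModel, simulate_sample)


def exhaustive_hmm(x, means, sd, p_self, start):
    """Brute-force enumeration over all state paths: total log-likelihood
    and the maximum-probability path."""
    K, T = len(means), len(x)
    logT = np.log(np.full((K, K), (1 - p_self) / (K - 1)))
    np.fill_diagonal(logT, np.log(p_self))
    logE = norm.logpdf(x[:, None], means[None, :], sd)
    paths = np.array(list(itertools.product(range(K), repeat=T)))
    lp = (np.log(start)[paths[:, 0]]
          + logE[np.arange(T)[None, :], paths].sum(axis=1)
          + logT[paths[:, :-1], paths[:, 1:]].sum(axis=1))
    return float(logsumexp(lp)), paths[int(np.argmax(lp))]


def profile_from_log2(x, contig="chr1"):
    n = len(x)
    bins = pd.DataFrame({
        "contig": contig, "start": np.arange(n) * 1000,
        "end": (np.arange(n) + 1) * 1000, "count": 100, "gc": 0.45,
        "mappability": 1.0, "log2": np.asarray(x, float), "masked": False})
    return cna.BinProfile(bins=bins, bin_width=1000)


class TestExpectedLog2Ratio:
    def test_closed_forms(self):
        assert cna.expected_log2_ratio(1.0, 3, 2.0) == 0.0
        assert cna.expected_log2_ratio(0.0, 4, 2.0) == pytest.approx(1.0)
        assert cna.expected_log2_ratio(0.9, 3, 2.0) == pytest.approx(
            np.log2(2.1 / 2.0))
        assert cna.expected_log2_ratio(0.5, 2, 2.0) == 0.0

    def test_floor_at_zero_copy(self):
        assert cna.expected_log2_ratio(0.0, 0, 2.0, floor=-8.0) == -8.0

    def test_monotone_in_copy_and_shrinks_with_n(self):
        ns = np.linspace(0.0, 1.0, 21)
        for n in ns:
            vals = [cna.expected_log2_ratio(n, c, 2.0) for c in range(5)]
            assert np.all(np.diff(vals) >= 0)
            if n < 1.0:
                assert np.all(np.diff(vals) > 0)
        for c in (0, 1, 3, 4):
            mags = [abs(cna.expected_log2_ratio(n, c, 2.0)) for n in ns]
            assert np.all(np.diff(mags) <= 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cna.expected_log2_ratio(1.5, 2, 2.0)
        with pytest.raises(ValueError):
            cna.expected_log2_ratio(0.5, -1, 2.0)


class TestBinFragments:
    def test_all_in_one_bin(self, ref_small):
        frags = pd.DataFrame({
            "name": [f"r{i}" for i in range(10)], "contig": "chr1",
            "start": 30_500, "end": 30_600, "length": 100, "mapq": 60,
            "strand": "+", "unmapped": False, "secondary": False,
            "supplementary": False, "duplicate": False, "label": None})
        prof = cna.bin_fragments(frags, 10_000, ref_small)
        counts = prof.bins.set_index(["contig", "start"])["count"]
        assert counts.loc[("chr1", 30_000)] == 10
        assert counts.sum() == 10

    def test_midpoint_rule_straddling_fragment(self, ref_small):
        frags = pd.DataFrame({
            "name": ["a"], "contig": ["chr1"], "start": [9_900],
            "end": [10_080], "length": [180], "mapq": [60], "strand": ["+"],
            "unmapped": [False], "secondary": [False],
            "supplementary": [False], "duplicate": [False], "label": [None]})
        prof = cna.bin_fragments(frags, 10_000, ref_small)
        counts = prof.bins.set_index(["contig", "start"])["count"]
        # midpoint 9,990 lies in the left bin
        assert counts.loc[("chr1", 0)] == 1

    def test_count_conservation_with_off_reference(self, ref_small):
        frags = pd.DataFrame({
            "name": ["a", "b"], "contig": ["chr1", "chrUn"],
            "start": [100, 100], "end": [267, 267], "length": [167, 167],
            "mapq": [60, 60], "strand": ["+", "+"], "unmapped": [False, False],
            "secondary": [False, False], "supplementary": [False, False],
            "duplicate": [False, False], "label": [None, None]})
        prof = cna.bin_fragments(frags, 10_000, ref_small)
        assert prof.bins["count"].sum() + prof.n_off_reference == 2

    def test_uniform_counts_poisson_spread(self, ref_medium):
        cfg = SimulationConfig(reference=ref_medium,
                               size_model=SizeModel.plasma(),
                               n_fragments=100_000, seed=13)
        frags = simulate_sample(cfg).fragments
        prof = cna.bin_fragments(frags, 80_000, ref_medium)  # 50 bins
        counts = prof.bins["count"].to_numpy()
        assert len(counts) == 50
        assert np.all(np.abs(counts - 2_000) < 4 * np.sqrt(2_000))


class TestCorrectAndNormalize:
    def test_flat_sample_log2_near_zero(self, ref_medium):
        cfg = SimulationConfig(reference=ref_medium,
                               size_model=SizeModel.plasma(),
                               n_fragments=200_000, seed=14)
        frags = simulate_sample(cfg).fragments
        corr = cna.correct_and_normalize(cna.bin_fragments(frags, 10_000,
                                                           ref_medium))
        med = np.nanmedian(corr.bins["log2"])
        assert abs(med) < 0.05

    def test_planted_gc_bias_removed(self, ref_medium):
        rng = np.random.default_rng(0)
        prof = cna.bin_fragments(pd.DataFrame({
            "name": [], "contig": [], "start": [], "end": [], "length": [],
            "mapq": [], "strand": [], "unmapped": [], "secondary": [],
            "supplementary": [], "duplicate": [], "label": []}),
            10_000, ref_medium)
        gc = prof.bins["gc"].to_numpy()
        prof.bins["count"] = rng.poisson(2_000 * (1.0 + gc))
        r_pre = np.corrcoef(prof.bins["count"], gc)[0, 1]
        assert r_pre > 0.5
        corr = cna.correct_and_normalize(prof)
        ok = ~corr.bins["masked"]
        r_post = np.corrcoef(corr.bins.loc[ok, "log2"],
                             corr.bins.loc[ok, "gc"])[0, 1]
        assert abs(r_post) < 0.1

    def test_self_panel_of_normals_zeroes(self, ref_medium):
        cfg = SimulationConfig(reference=ref_medium,
                               size_model=SizeModel.plasma(),
                               n_fragments=100_000, seed=15)
        frags = simulate_sample(cfg).fragments
        prof = cna.bin_fragments(frags, 10_000, ref_medium)
        corrected = cna.correct_and_normalize(prof)
        pon = cna.PanelOfNormals.from_profiles([corrected])
        again = cna.correct_and_normalize(prof, pon=pon)
        vals = again.bins.loc[~again.bins["masked"], "log2"]
        assert np.allclose(vals, 0.0)

    def test_panel_tsv_roundtrip(self, ref_medium, tmp_path):
        cfg = SimulationConfig(reference=ref_medium,
                               size_model=SizeModel.plasma(),
                               n_fragments=50_000, seed=16)
        frags = simulate_sample(cfg).fragments
        corrected = cna.correct_and_normalize(
            cna.bin_fragments(frags, 10_000, ref_medium))
        pon = cna.PanelOfNormals.from_profiles([corrected])
        path = tmp_path / "pon.tsv"
        pon.to_tsv(path)
        back = cna.PanelOfNormals.from_tsv(path)
        assert back.bin_width == pon.bin_width
        np.testing.assert_allclose(back.table["median_log2"],
                                   pon.table["median_log2"])

    def test_zero_counts_rejected(self, ref_small):
        prof = cna.bin_fragments(pd.DataFrame(columns=[
            "name", "contig", "start", "end", "length", "mapq", "strand",
            "unmapped", "secondary", "supplementary", "duplicate", "label"]),
            10_000, ref_small)
        with pytest.raises(ValueError):
            cna.correct_and_normalize(prof)


class TestHMM:
    def test_single_bin_closed_form(self):
        cfg = cna.HMMConfig(states=(2,), restarts=(0.99,))
        x = np.array([0.21])
        ll = cna.hmm_loglik(x, 0.9, 2.0, cfg, sd=0.3)
        assert ll == pytest.approx(norm.logpdf(0.21, 0.0, 0.3))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        cfg = cna.HMMConfig()
        for _ in range(20):
            T = int(rng.integers(2, 9))
            n = float(rng.uniform(0.5, 0.99))
            sd = float(rng.uniform(0.05, 0.3))
            means = cna.expected_log2_ratio(n, np.array(cfg.states, float), 2.0)
            x = means[rng.integers(0, 4, T)] + rng.normal(0, sd, T)
            ll = cna.hmm_loglik(x, n, 2.0, cfg, sd=sd)
            ll_ref, path_ref = exhaustive_hmm(x, means, sd,
                                              cfg.self_transition,
                                              cna.start_probs(cfg))
            assert ll == pytest.approx(ll_ref, abs=1e-9)
            path = cna._viterbi(x, n, cfg, sd)
            assert np.array_equal(path, np.array(cfg.states)[path_ref])

    def test_matches_hmmlearn_forward(self):
        from hmmlearn.hmm import GaussianHMM
        rng = np.random.default_rng(11)
        cfg = cna.HMMConfig()
        n, sd = 0.8, 0.12
        means = cna.expected_log2_ratio(n, np.array(cfg.states, float), 2.0)
        x = means[rng.integers(0, 4, 200)] + rng.normal(0, sd, 200)
        model = GaussianHMM(n_components=4, covariance_type="diag",
                            init_params="", params="")
        model.startprob_ = cna.start_probs(cfg)
        p = cfg.self_transition
        model.transmat_ = np.full((4, 4), (1 - p) / 3)
        np.fill_diagonal(model.transmat_, p)
        model.means_ = means[:, None]
        model.covars_ = np.full((4, 1), sd**2)
        assert cna.hmm_loglik(x, n, 2.0, cfg, sd=sd) == pytest.approx(
            model.score(x[:, None]), abs=1e-6)

    def test_longer_series_lowers_loglik_for_wide_emissions(self):
        cfg = cna.HMMConfig()
        x = np.array([0.1, -0.2, 0.05])
        ll1 = cna.hmm_loglik(x, 0.9, 2.0, cfg, sd=1.0)
        ll2 = cna.hmm_loglik(np.concatenate([x, x]), 0.9, 2.0, cfg, sd=1.0)
        assert ll2 < ll1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cna.hmm_loglik(np.array([]), 0.9, 2.0, cna.HMMConfig())


class TestFitTumorFraction:
    def test_selection_rule(self):
        rng = np.random.default_rng(3)
        truth_n = 0.8
        means = cna.expected_log2_ratio(truth_n, np.array([0., 1, 2, 3]), 2.0)
        states = np.repeat([2, 3, 2, 1, 2], 60)
        x = means[states] + rng.normal(0, 0.05, len(states))
        est = cna.fit_tumor_fraction(profile_from_log2(x))
        table = est.restart_table
        best = table["loglik"].idxmax()
        assert est.selected_restart == best
        assert est.tumor_fraction == pytest.approx(
            1.0 - table.loc[best, "n_hat"])
        assert est.detected == (est.tumor_fraction > 0.03)

    def test_flat_profile_not_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.05, 500)
        est = cna.fit_tumor_fraction(profile_from_log2(x))
        assert est.tumor_fraction < 0.03
        assert not est.detected

    def test_recovery_on_synthetic_log2(self):
        rng = np.random.default_rng(5)
        for tf in (0.1, 0.2, 0.4):
            means = cna.expected_log2_ratio(1 - tf, np.array([0., 1, 2, 3]),
                                            2.0)
            states = np.concatenate([np.full(100, 3), np.full(250, 2),
                                     np.full(100, 1), np.full(150, 2)])
            x = means[states] + rng.normal(0, 0.08, len(states))
            est = cna.fit_tumor_fraction(profile_from_log2(x))
            assert abs(est.tumor_fraction - tf) <= 0.05


class TestViterbiSegments:
    def test_flat_profile_single_segment_per_contig(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.04, 300)
        prof = profile_from_log2(x)
        est = cna.fit_tumor_fraction(prof)
        segs = cna.viterbi_segments(prof, est)
        assert len(segs) == 1
        assert segs.loc[0, "copy"] == 2
        assert segs.loc[0, "n_bins"] == 300

    def test_gain_segment_recovered(self):
        rng = np.random.default_rng(8)
        tf = 0.4
        means = cna.expected_log2_ratio(1 - tf, np.array([0., 1, 2, 3]), 2.0)
        states = np.concatenate([np.full(40, 2), np.full(20, 3),
                                 np.full(40, 2)])
        x = means[states] + rng.normal(0, 0.06, len(states))
        prof = profile_from_log2(x)
        est = cna.fit_tumor_fraction(prof)
        segs = cna.viterbi_segments(prof, est)
        gains = segs[segs["copy"] == 3]
        assert len(gains) >= 1
        # overlap with the true gain interval (bins 40..59)
        true_lo, true_hi = 40_000, 60_000
        overlap = sum(max(0, min(s.end, true_hi) - max(s.start, true_lo))
                      for s in gains.itertuples())
        assert overlap >= 0.8 * (true_hi - true_lo)

    def test_segments_partition_unmasked_bins(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.3, 120)
        prof = profile_from_log2(x)
        est = cna.fit_tumor_fraction(prof)
        segs = cna.viterbi_segments(prof, est)
        assert segs["n_bins"].sum() == 120
        assert (segs["start"].iloc[1:].to_numpy()
                == segs["end"].iloc[:-1].to_numpy()).all()
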