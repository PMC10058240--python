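"""Footprint statistic, hexamer bias estimation, FLR mixture model."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from etiofoot import (detect_footprints, estimate_hexamer_bias,
                      expected_cut_rates, extend_footprints,
                      filter_footprints)
from etiofoot.core import CutProfile, DHSCollection, GenomeSequence
from etiofoot.footprints import (Footprint, HexamerBiasTable,
                                 _em_two_gaussians, depletion_statistic,
                                 flr_from_fit, hexamer_indices,
                                 hexamer_to_index)

from conftest import make_profile


def log10_tail_oracle(k, n, p):
    """Direct summation of the upper binomial tail in log space."""
    if k <= 0:
        return 0.0
    ks = np.arange(k, n + 1)
    return logsumexp(stats.binom.logpmf(ks, n, p)) / np.log(10)


class TestBinomialScore:
    @pytest.mark.parametrize("n", [1, 7, 50, 120, 200])
    def test_logsf_matches_direct_summation(self, n):
        for p in (0.5, 35 / 46, 35 / 60):
            ks = np.arange(0, n + 1)
            impl = stats.binom.logsf(ks - 1, n, p) / np.log(10)
            oracle = np.array([log10_tail_oracle(k, n, p) for k in ks])
            assert np.max(np.abs(impl - oracle)) < 1e-10

    def test_constructed_extreme_depletion(self):
        """50 forward cuts in the left shoulder, none in the window (and the
        reverse-strand mirror) with shoulder == width gives p = 0.5^50 per
        strand, score ~ 2 * 50 * log10(0.5)."""
        L = 200
        fwd = np.zeros(L, dtype=int)
        rev = np.zeros(L, dtype=int)
        s, w, sh = 100, 10, 10
        fwd[s - sh:s] = 5          # 50 forward cuts in left shoulder
        rev[s + w:s + w + sh] = 5  # 50 reverse cuts in right shoulder
        prof = make_profile(fwd, rev)
        dhs = DHSCollection.from_records("d", [("chr1", 60, 160)])
        fps = detect_footprints(prof, dhs, widths=[w], shoulder=sh,
                                score_threshold=-10)
        best = min(fps, key=lambda f: f.score)
        assert best.score == pytest.approx(2 * 50 * np.log10(0.5), abs=1e-6)
        assert best.start == s and best.end == s + w

    def test_uniform_profile_detects_nothing(self):
        rng = np.random.default_rng(0)
        prof = make_profile(rng.poisson(5, 2000), rng.poisson(5, 2000))
        dhs = DHSCollection.from_records("d", [("chr1", 100, 1900)])
        assert detect_footprints(prof, dhs) == []

    def test_all_reported_scores_below_threshold(self, small_dataset):
        from etiofoot import call_peaks
        prof = small_dataset["profiles"][0.0]
        peaks = call_peaks(prof, fold_threshold=3.0)
        fps = detect_footprints(prof, peaks, score_threshold=-10)
        assert fps and all(f.score < -10 for f in fps)
        # greedy selection leaves no overlapping pair
        fps_sorted = sorted(fps, key=lambda f: (f.chrom, f.start))
        for a, b in zip(fps_sorted, fps_sorted[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_mirror_symmetry(self):
        """Swapping strands together with mirroring coordinates preserves
        the score of the mirrored candidate."""
        L = 400
        rng = np.random.default_rng(3)
        fwd = rng.poisson(4, L)
        rev = rng.poisson(4, L)
        fwd[180:200] = 0
        rev[180:200] = 0
        prof = make_profile(fwd, rev)
        mirror = make_profile(rev[::-1].copy(), fwd[::-1].copy())
        dhs = DHSCollection.from_records("d", [("chr1", 50, 350)])
        fps = detect_footprints(prof, dhs, score_threshold=-3)
        fps_m = detect_footprints(mirror, dhs, score_threshold=-3)
        scores = sorted(round(f.score, 9) for f in fps)
        scores_m = sorted(round(f.score, 9) for f in fps_m)
        assert scores == scores_m

    def test_narrow_dhs_skipped(self):
        prof = make_profile(np.ones(200, dtype=int), np.ones(200, dtype=int))
        dhs = DHSCollection.from_records("d", [("chr1", 10, 60)])
        assert detect_footprints(prof, dhs) == []

    def test_parameter_validation(self):
        prof = make_profile(np.ones(10, dtype=int), np.ones(10, dtype=int))
        dhs = DHSCollection("d", {})
        with pytest.raises(ValueError):
            detect_footprints(prof, dhs, widths=[4])
        with pytest.raises(ValueError):
            detect_footprints(prof, dhs, shoulder=2)
        with pytest.raises(ValueError):
            detect_footprints(prof, dhs, score_threshold=1.0)


def string_hexamer_oracle(seq, i, strand):
    """Context by direct string slicing (independent of the vector code)."""
    from etiofoot.core import revcomp
    if strand == "+":
        sub = seq[i - 3:i + 3] if i >= 3 else ""
    else:
        sub = revcomp(seq[i - 2:i + 4]) if i >= 2 else ""
    if len(sub) != 6 or "N" in sub:
        return -1
    return hexamer_to_index(sub)


class TestHexamerBias:
    def test_indices_match_string_oracle(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=300))
        genome = GenomeSequence({"chr1": seq})
        codes = genome.encode("chr1")
        for strand in "+-":
            idx, valid = hexamer_indices(codes, strand)
            for i in range(len(seq)):
                expect = string_hexamer_oracle(seq, i, strand)
                got = idx[i] if valid[i] else -1
                assert got == expect, (strand, i)

    def test_uniform_control_rates_near_one(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=200_000))
        genome = GenomeSequence({"chr1": seq})
        counts = {"chr1": {"+": rng.poisson(3, 200_000),
                           "-": rng.poisson(3, 200_000)}}
        control = CutProfile("c", counts, treatment="deproteinated")
        table = estimate_hexamer_bias(control, genome)
        assert abs(np.median(table.rates) - 1.0) < 0.1
        assert table.rates.std() < 0.2

    def test_planted_bias_recovered(self):
        rng = np.random.default_rng(3)
        n = 1_000_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        genome = GenomeSequence({"chr1": seq})
        codes = genome.encode("chr1")
        target = hexamer_to_index("AAAAAA")
        rate = np.ones(n)
        for strand in "+-":
            idx, valid = hexamer_indices(codes, strand)
            rate[valid & (idx == target)] = 4.0
        counts = {"chr1": {"+": rng.poisson(rate), "-": rng.poisson(rate)}}
        control = CutProfile("c", counts, treatment="deproteinated")
        table = estimate_hexamer_bias(control, genome)
        ratio = table.rate_of("AAAAAA") / np.median(table.rates)
        assert abs(ratio - 4.0) / 4.0 < 0.10

    def test_absent_hexamer_flagged_rate_one(self):
        genome = GenomeSequence({"chr1": "ACGT" * 100})
        counts = {"chr1": {"+": np.ones(400, dtype=int),
                           "-": np.ones(400, dtype=int)}}
        control = CutProfile("c", counts, treatment="deproteinated")
        table = estimate_hexamer_bias(control, genome)
        assert "AAAAAA" in table.absent
        assert table.rate_of("AAAAAA") == pytest.approx(1.0)

    def test_requires_deproteinated_control(self):
        genome = GenomeSequence({"chr1": "ACGT" * 10})
        prof = make_profile(np.ones(40, dtype=int), np.ones(40, dtype=int))
        with pytest.raises(ValueError, match="deproteinated"):
            estimate_hexamer_bias(prof, genome)


class TestExpectedRates:
    def test_uniform_bias_uniform_proportions(self):
        genome = GenomeSequence({"chr1": "ACGT" * 100})
        table = HexamerBiasTable(np.ones(4096), 1.0, 0)
        props = expected_cut_rates(table, genome, "chr1", 100, 200)
        assert np.allclose(props, 0.01)
        assert props.sum() == pytest.approx(1.0)

    def test_weights_match_string_oracle(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=400))
        genome = GenomeSequence({"chr1": seq})
        rates = rng.lognormal(0, 0.5, 4096)
        rates /= rates.mean()
        table = HexamerBiasTable(rates, 1.0, 0)
        props = expected_cut_rates(table, genome, "chr1", 50, 350)
        weights = []
        for i in range(50, 350):
            per = []
            for strand in "+-":
                h = string_hexamer_oracle(seq, i, strand)
                per.append(rates[h] if h >= 0 else 1.0)
            weights.append(np.mean(per))
        weights = np.array(weights)
        assert np.allclose(props, weights / weights.sum())


class TestMixtureAndFlr:
    def test_em_recovers_planted_mixture(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-1.5, 0.3, 600),
                            rng.normal(0.0, 0.3, 1400)])
        fit = _em_two_gaussians(x)
        assert abs(fit.means[0] - (-1.5)) < 0.1
        assert abs(fit.means[1] - 0.0) < 0.1
        assert abs(fit.weights[0] - 0.3) < 0.05
        assert fit.weights[0] + fit.weights[1] == pytest.approx(1.0)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-1, 0.4, 300), rng.normal(1, 0.4, 300)])
        fit = _em_two_gaussians(x)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7)

    def test_flr_sign_separates_components(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-1.5, 0.2, 500),
                            rng.normal(0.0, 0.2, 500)])
        fit = _em_two_gaussians(x)
        flr = flr_from_fit(fit, np.array([-1.5, 0.0]))
        assert flr[0] > 0 > flr[1]

    def test_degenerate_single_component_flagged(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 1e-4, 200)
        fit = _em_two_gaussians(x)
        flr = flr_from_fit(fit, x)
        if fit.degenerate:
            assert np.all(flr <= 0)


class TestFilterAndExtend:
    def _fp(self, start, end, flr, tp=0.0):
        return Footprint("chr1", start, end, time_point=tp, flr=flr)

    def test_empty_input(self):
        retained, report = filter_footprints([])
        assert retained == [] and report == {}

    def test_reduction_fraction(self):
        fps = [self._fp(i * 50, i * 50 + 20, -1.0 if i < 3 else 2.0)
               for i in range(10)]
        retained, report = filter_footprints(fps)
        assert len(retained) == 7
        assert report[0.0] == pytest.approx(0.30)

    def test_all_pass_identity(self):
        fps = [self._fp(0, 20, 1.0), self._fp(100, 130, 0.0)]
        retained, report = filter_footprints(fps)
        assert retained == fps and report[0.0] == 0.0

    def test_extension_and_clipping(self):
        fps = [Footprint("chr1", 100, 120), Footprint("chr1", 2, 10)]
        out = extend_footprints(fps, pad=4, chrom_lengths={"chr1": 1000})
        assert out == [("chr1", 96, 124), ("chr1", 0, 14)]

    def test_overlapping_extensions_not_merged(self):
        fps = [Footprint("chr1", 100, 110), Footprint("chr1", 112, 120)]
        out = extend_footprints(fps, pad=4)
        assert len(out) == 2
        assert out[0][2] > out[1][1]  # they overlap but stay separate

    def test_negative_pad_rejected(self):
        with pytest.raises(ValueError):
            extend_footprints([], pad=-1)
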