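"""Copy-number profiling: logR, GC correction, PCF, ploidy, MAPD."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dtctrace import (
    BinnedCounts,
    LogRProfile,
    SegmentProfile,
    SimConfig,
    compute_logr,
    compute_mapd,
    estimate_cn,
    estimate_ploidy,
    gc_correct,
    pcf_segment_series,
    segment_pcf,
    simulate_cohort,
)
from dtctrace.cnv import profile_cell


def _counts(values, chrom="chr1", gc=0.5):
    n = len(values)
    bins = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
            "start": np.arange(n) * 100 + 1,
            "end": (np.arange(n) + 1) * 100,
            "gc": gc if isinstance(gc, (list, np.ndarray)) else [gc] * n,
            "count": values,
        }
    )
    return BinnedCounts(cell_id="cell", bins=bins)


def _logr_profile(values, chrom="chr1", gc=0.5):
    n = len(values)
    bins = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
            "start": np.arange(n) * 100 + 1,
            "end": (np.arange(n) + 1) * 100,
            "gc": gc if isinstance(gc, (list, np.ndarray)) else [gc] * n,
            "logr": np.asarray(values, dtype=float),
        }
    )
    return LogRProfile(cell_id="cell", bins=bins)


class TestComputeLogr:
    def test_flat_profile_gives_zero(self):
        prof = compute_logr(_counts([100] * 50))
        assert np.allclose(prof.logr, 0.0)

    def test_doubled_bin_gives_logr_one(self):
        values = [100] * 1000 + [200]
        prof = compute_logr(_counts(values))
        # mean is barely above 100 with many flat bins
        assert prof.logr[-1] == pytest.approx(1.0, abs=0.01)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="empty library"):
            compute_logr(_counts([0] * 10))

    def test_zero_bins_floored_not_infinite(self):
        prof = compute_logr(_counts([0, 100, 100, 100]))
        assert np.all(np.isfinite(prof.logr))

    def test_clonal_gain_hits_expected_logr(self):
        """A single-copy gain on a diploid background sits at log2(3/2)."""
        rng = np.random.default_rng(5)
        n = 4000
        cn = np.full(n, 2)
        cn[:1000] = 3
        mu = 200 * cn / 2
        counts = rng.poisson(mu)
        prof = compute_logr(_counts(counts))
        gained = prof.logr[:1000]
        se = gained.std(ddof=1) / np.sqrt(len(gained))
        # the global mean count sits between the two states; correct for it
        expected = np.log2(3 / 2) - np.log2(np.mean(mu) / 200)
        assert abs(gained.mean() - expected) < 3 * se


class TestGcCorrect:
    def test_flat_gc_profile_is_noop_up_to_centering(self, rng):
        y = rng.normal(0, 0.1, 500)
        gc = rng.uniform(0.35, 0.6, 500)
        prof = _logr_profile(y, gc=gc)
        out = gc_correct(prof)
        # no GC structure to remove: correlation with input preserved
        assert np.corrcoef(out.logr, y)[0, 1] > 0.99
        assert out.gc_corrected

    def test_removes_injected_quadratic_trend(self, rng):
        n = 2000
        gc = rng.uniform(0.3, 0.65, n)
        noise = rng.normal(0, 0.05, n)
        y = noise + 1.2 * gc - 2.0 * gc**2
        out = gc_correct(_logr_profile(y, gc=gc))
        # corrected track is flat: refit coefficients indistinguishable from 0
        coef, cov = np.polyfit(gc, out.logr, 2, cov=True)
        assert np.all(np.abs(coef[:2]) < 3 * np.sqrt(np.diag(cov))[:2])
        assert out.logr.std() < 1.2 * noise.std()

    def test_preserves_real_cna_shift(self, rng):
        n = 3000
        gc = rng.uniform(0.3, 0.65, n)
        y = rng.normal(0, 0.05, n) + 0.8 * gc - 1.5 * gc**2
        y[:300] += 0.585  # true gain at GC-typical bins
        out = gc_correct(_logr_profile(y, gc=gc))
        shift = out.logr[:300].mean() - out.logr[300:].mean()
        assert shift == pytest.approx(0.585, abs=0.05)

    def test_constant_gc_warns(self):
        prof = _logr_profile([0.1, -0.1, 0.2, 0.0], gc=0.5)
        with pytest.warns(UserWarning, match="constant GC"):
            gc_correct(prof)


def _exhaustive_pcf(y, gamma):
    """Oracle: best cost over all 2^(n-1) segmentations."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    best_cost, best_segs = np.inf, None
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        cost = gamma * (len(bounds) - 2)
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg = y[s:e]
            cost += float(np.sum((seg - seg.mean()) ** 2))
        if cost < best_cost - 1e-12:
            best_cost, best_segs = cost, len(bounds) - 1
        elif abs(cost - best_cost) <= 1e-12 and len(bounds) - 1 < best_segs:
            best_segs = len(bounds) - 1
    return best_cost, best_segs


class TestPcf:
    def test_constant_series_single_segment(self):
        assert pcf_segment_series(np.full(30, 1.7), gamma=0.1) == [(0, 30)]

    def test_step_series_tie_prefers_fewer_segments(self):
        # RSS without break = 25.0 equals break cost at gamma 25: tie -> 1 segment
        y = np.array([0.0] * 50 + [1.0] * 50)
        assert len(pcf_segment_series(y, gamma=25.0)) == 1
        segs = pcf_segment_series(y, gamma=10.0)
        assert segs == [(0, 50), (50, 100)]

    def test_huge_gamma_one_segment_per_chromosome(self, rng):
        prof = _logr_profile(rng.normal(0, 1, 60), chrom=["chr1"] * 30 + ["chr2"] * 30)
        seg = segment_pcf(prof, gamma=1e9, normalize=False)
        assert list(seg.segments["chrom"]) == ["chr1", "chr2"]

    def test_dp_matches_exhaustive_enumeration(self, rng):
        """Exact-DP optimum equals brute force over all segmentations."""
        for _ in range(40):
            n = int(rng.integers(2, 13))
            y = rng.normal(0, 1, n)
            gamma = float(rng.uniform(0.1, 5.0))
            segs = pcf_segment_series(y, gamma)
            cost = gamma * (len(segs) - 1) + sum(
                float(np.sum((y[s:e] - y[s:e].mean()) ** 2)) for s, e in segs
            )
            best_cost, best_nseg = _exhaustive_pcf(y, gamma)
            assert cost == pytest.approx(best_cost, abs=1e-9)
            assert len(segs) == best_nseg

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            pcf_segment_series(np.zeros(5), gamma=0)


class TestEstimateCn:
    @pytest.mark.parametrize(
        "logr,psi,cn,state",
        [
            (0.0, 2.0, 2.0, 2),
            (0.585, 2.0, 3.0, 3),
            (-1.0, 4.0, 2.0, 2),
            (-5.0, 2.0, 0.0625, 0),
        ],
    )
    def test_scaling(self, logr, psi, cn, state):
        c, s = estimate_cn(logr, psi)
        assert c == pytest.approx(cn, abs=1e-3)
        assert s == state

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            estimate_cn(0.0, 0.0)


class TestEstimatePloidy:
    def _seg(self, logrs, weights=None):
        w = weights or [10] * len(logrs)
        seg = pd.DataFrame({"chrom": "chr1", "start": 1, "end": 2, "start_bin": 0,
                            "end_bin": 1, "n_bins": w, "mean_logr": logrs})
        return SegmentProfile(cell_id="c", segments=seg)

    def test_noise_free_diploid(self):
        assert estimate_ploidy(self._seg([0.0])) == 2.0

    def test_flat_tetraploid_resolves_to_smallest(self):
        # logR carries no absolute scale: a flat 4n cell looks diploid
        assert estimate_ploidy(self._seg([0.0])) == 2.0

    def test_informative_segments_pin_diploid(self):
        psi = estimate_ploidy(self._seg([0.0, 0.585, -1.0]))
        # brute-force oracle over the same grid
        logr = np.array([0.0, 0.585, -1.0])
        objs = {
            p: np.sum(10 * np.abs(2.0**logr * p - np.round(2.0**logr * p)))
            for p in np.round(np.arange(1.5, 5.01, 0.05), 2)
        }
        assert psi == min(objs, key=lambda p: (objs[p], p))
        assert psi == 2.0


class TestMapd:
    def test_constant_profile_zero(self):
        qc = compute_mapd(_logr_profile([0.3] * 20))
        assert qc.mapd == 0.0 and qc.passed

    def test_alternating_profile(self):
        d = 0.2
        y = [d if i % 2 else -d for i in range(40)]
        assert compute_mapd(_logr_profile(y)).mapd == pytest.approx(2 * d)

    def test_gaussian_noise_scaling(self, rng):
        """MAPD of i.i.d. N(0, sigma^2) logR is sigma*sqrt(2)*Phi^-1(0.75)."""
        sigma = 0.3
        y = rng.normal(0, sigma, 10_000)
        expected = sigma * np.sqrt(2) * 0.674489750196
        assert compute_mapd(_logr_profile(y)).mapd == pytest.approx(expected, rel=0.02)

    def test_invariant_under_constant_shift(self, rng):
        y = rng.normal(0, 0.2, 500)
        m1 = compute_mapd(_logr_profile(y)).mapd
        m2 = compute_mapd(_logr_profile(y + 3.7)).mapd
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            compute_mapd(_logr_profile([0.0]))

    def test_diffs_never_span_chromosomes(self):
        # two flat chromosomes at different levels: MAPD stays 0
        y = [0.0] * 10 + [5.0] * 10
        prof = _logr_profile(y, chrom=["chr1"] * 10 + ["chr2"] * 10)
        assert compute_mapd(prof).mapd == 0.0


class TestPipelineRoundTrip:
    def test_noise_free_cell_reproduces_cn_track(self):
        """compute_logr + estimate_cn with true ploidy inverts the generator."""
        cfg = SimConfig(seed=2, noise_free=True, gc_bias_coefficients=(1.0, 0.0, 0.0))
        cohort = simulate_cohort(cfg)
        cell = next(c for c in cohort.cells if c.true_class == "DTC")
        prof = compute_logr(cell.counts)
        true_mean_cn = cell.true_cn.mean()
        cn = 2.0**prof.logr * true_mean_cn
        assert np.allclose(np.round(cn), cell.true_cn)

    def test_default_noise_recovers_bin_states(self, default_cohort):
        """>=95% of bins get their true integer copy-number state."""
        for cell in default_cohort.cells:
            if cell.true_class == "doublet":
                continue
            seg, qc, _ = profile_cell(cell.counts)
            states = np.empty(cell.counts.n_bins, dtype=int)
            for r in seg.segments.itertuples():
                states[r.start_bin : r.end_bin + 1] = r.cn_state
            assert (states == cell.true_cn).mean() >= 0.95
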