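import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oisiwc import bandstats, preproc, wavelet
from oisiwc.bandstats import (
    BANDS,
    INTERVALS,
    DomainGrid,
    StatMatrix,
    assumption_checks,
    band_and_overall_comparison,
    band_interval_average,
    domain_mean_comparison,
    p_color_class,
    pairwise_domain_stats,
)
from oisiwc.schedule import make_trial_schedule
from oisiwc.synthdata import SynthConfig, generate_block_dataset
from oisiwc.wavelet import CoherenceMap, build_scale_grid


def _constant_cmap(value, n=3030, fs=10.0):
    grid = build_scale_grid(fs)
    coi = np.minimum(np.arange(n), np.arange(n)[::-1]) / fs / np.sqrt(2)
    return CoherenceMap(
        r2=np.full((grid.n_scales, n), value),
        phase=np.zeros((grid.n_scales, n)),
        grid=grid, sampling_rate=fs, coi_scale=coi,
    )


def _synthetic_pairwise_grids(rng, n_rep, level=0.5, jitter=0.02, nb=12):
    """Stacked pairwise domain grids with exchangeable replicate noise."""
    out = np.full((n_rep, nb, nb, 4, 4), np.nan)
    for r in range(n_rep):
        base = level + jitter * rng.standard_normal((nb, nb, 4, 4))
        base = np.clip((base + base.transpose(1, 0, 2, 3)) / 2, 0, 1)
        for i in range(nb):
            base[i, i] = np.nan
        out[r] = base
    return out


class TestBandIntervalAverage:
    sched = make_trial_schedule(9, 10.0)

    def test_constant_coherence_gives_constant_domains(self):
        dg = band_interval_average(_constant_cmap(0.37), self.sched)
        np.testing.assert_allclose(dg.values[np.isfinite(dg.values)], 0.37)
        assert dg.values.shape == (4, 4)

    def test_sixteen_domains(self):
        dg = band_interval_average(_constant_cmap(0.5), self.sched)
        assert dg.values.size == 16
        assert dg.bands == ("I", "II", "III", "IV")
        assert dg.intervals == ("dt1", "dt2", "dt3", "dt4")

    def test_band_partition_covers_range_without_overlap(self):
        grid = build_scale_grid(10.0)
        f = grid.fourier_freqs
        membership = np.zeros(len(f), dtype=int)
        for name, (lo, hi) in BANDS.items():
            closed = np.isclose(hi, 4.5)
            membership += ((f >= lo) & ((f <= hi) if closed else (f < hi)))
        assert np.all(membership[(f >= 0.05) & (f <= 4.5)] == 1)

    def test_interval_partition_tiles_the_epoch(self):
        edges = sorted(INTERVALS.values())
        assert edges[0][0] == -1.0 and edges[-1][1] == 14.0
        for (a, b), (c, d) in zip(edges, edges[1:]):
            assert b == c

    def test_coupling_in_one_band_localizes_there(self):
        """Coupling injected only at the 1.67 Hz component (band II) must
        raise band-II means above band-III means."""
        grid = build_scale_grid(10.0)
        wins = 0
        for seed in range(6):
            cfg = SynthConfig(
                rng_seed=seed,
                coupling={"healthy": (0.0, 0.0, 0.9, 0.0),
                          "stroke": (0.0, 0.0, 0.9, 0.0)},
                noise_coupling={"healthy": 0.0, "stroke": 0.0},
                active_blocks={"healthy": (), "stroke": ()})
            h, _, sched, _ = generate_block_dataset(cfg)
            b10 = preproc.temporal_average(h, 10)
            cm = wavelet.wavelet_coherence(b10.values[0], b10.values[1], grid)
            dg = band_interval_average(cm, sched)
            if np.nanmean(dg.values[1]) > np.nanmean(dg.values[2]):
                wins += 1
        assert wins >= 5

    def test_interval_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            band_interval_average(_constant_cmap(0.5), self.sched,
                                  intervals={"bad": (10.0, 20.0)})

    def test_coi_filter_excludes_edge_cells(self):
        # 15 s single-epoch series: every band-IV scale (>= 6.5 s) lies
        # outside the cone of influence everywhere
        cm = _constant_cmap(0.5, n=155)
        sched = make_trial_schedule(1, 10.0)
        dg = band_interval_average(cm, sched, coi_filter=True)
        assert np.isnan(dg.values[3]).all()
        dg2 = band_interval_average(cm, sched, coi_filter=False)
        assert np.isfinite(dg2.values).all()


class TestPairwiseDomainStats:
    def test_matrix_shape_symmetry_and_zero_diagonal(self, rng):
        h = _synthetic_pairwise_grids(rng, 4)
        s = _synthetic_pairwise_grids(rng, 4)
        mats = pairwise_domain_stats(h, s)
        assert len(mats) == 16
        for m in mats:
            assert m.p.shape == (12, 12)
            np.testing.assert_allclose(np.diag(m.p), 0.0)
            np.testing.assert_allclose(m.p, m.p.T)
            assert all(m.classes[i, i] == "white" for i in range(12))

    def test_group_p_matches_statsmodels_anova(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        y = rng.normal(size=(2, 6))
        p_mine = bandstats._twoway_anova_group_p(y[..., None])[0]
        df = pd.DataFrame({
            "y": y.ravel(),
            "group": np.repeat(["a", "b"], 6),
            "rep": list(range(6)) * 2,
        })
        tab = sm.stats.anova_lm(ols("y ~ C(group) + C(rep)", df).fit(), typ=2)
        assert p_mine == pytest.approx(tab.loc["C(group)", "PR(>F)"], rel=1e-10)

    def test_injected_band_ii_difference_detected(self):
        """Coupling 0.8 vs 0.2 in every band, 4 replicates per group: the
        band-II cells must be predominantly significant."""
        grid = build_scale_grid(10.0)
        groups = {"healthy": [], "stroke": []}
        for rep in range(4):
            cfg = SynthConfig(rng_seed=500 + rep, n_stim_epochs=3,
                              coupling={"healthy": (0.8,) * 4, "stroke": (0.2,) * 4},
                              noise_coupling={"healthy": 0.8, "stroke": 0.2})
            h, s, sched, _ = generate_block_dataset(cfg)
            for key, bs in (("healthy", h), ("stroke", s)):
                b10 = preproc.temporal_average(bs, 10)
                groups[key].append(bandstats.compute_pairwise_domains(
                    b10, sched, grid, coi_filter=False))
        mats = pairwise_domain_stats(np.stack(groups["healthy"]),
                                     np.stack(groups["stroke"]))
        iu = np.triu_indices(12, k=1)
        band_ii = [m for m in mats if m.band == "II"]
        frac = np.mean([(m.p[iu] < 0.05).mean() for m in band_ii])
        assert frac > 0.5

    def test_fewer_than_two_replicates_rejected(self, rng):
        h = _synthetic_pairwise_grids(rng, 1)
        with pytest.raises(ValueError):
            pairwise_domain_stats(h, h)


class TestDomainMeanComparison:
    def test_reported_means_are_arithmetic_means(self, rng):
        h = _synthetic_pairwise_grids(rng, 5, level=0.6)
        s = _synthetic_pairwise_grids(rng, 5, level=0.4)
        table = domain_mean_comparison(h, s)
        assert len(table) == 16
        iu = np.triu_indices(12, k=1)
        expected = h[:, iu[0], iu[1], 0, 0].mean()
        assert table.iloc[0]["mean_healthy"] == pytest.approx(expected)

    def test_halved_coherence_significant_everywhere(self, rng):
        h = _synthetic_pairwise_grids(rng, 6, level=0.6, jitter=0.02)
        s = 0.5 * h
        table = domain_mean_comparison(h, s)
        assert (table["p"] < 0.05).all()

    def test_identical_groups_mostly_nonsignificant(self, rng):
        rejections = []
        for _ in range(10):
            h = _synthetic_pairwise_grids(rng, 5)
            s = _synthetic_pairwise_grids(rng, 5)
            rejections.append((domain_mean_comparison(h, s)["p"] < 0.05).mean())
        assert np.mean(rejections) < 0.15


class TestBandAndOverallComparison:
    def test_equal_groups_give_t_near_zero(self, rng):
        h = _synthetic_pairwise_grids(rng, 6)
        res = band_and_overall_comparison(h, h)
        assert res["overall"]["t"] == pytest.approx(0.0, abs=1e-10)
        assert res["overall"]["test"] == "student-t"

    def test_band_means_average_their_intervals(self, rng):
        h = _synthetic_pairwise_grids(rng, 4, level=0.5)
        s = _synthetic_pairwise_grids(rng, 4, level=0.3)
        res = band_and_overall_comparison(h, s)
        iu = np.triu_indices(12, k=1)
        per_rep = h[:, iu[0], iu[1], 0, :].mean(axis=1)   # (reps, 4 intervals)
        assert res["bands"].iloc[0]["mean_healthy"] == pytest.approx(
            per_rep.mean(axis=1).mean())

    def test_grand_mean_difference_sign_recovered(self, rng):
        signs = []
        for _ in range(20):
            h = _synthetic_pairwise_grids(rng, 5, level=0.7)
            s = _synthetic_pairwise_grids(rng, 5, level=0.3)
            res = band_and_overall_comparison(h, s)
            signs.append(res["overall"]["mean_healthy"] > res["overall"]["mean_stroke"])
        assert all(signs)


class TestAssumptionChecks:
    def test_ks_calibration_on_normal_samples(self):
        rejected = 0
        n_trials = 200
        for seed in range(n_trials):
            r = np.random.default_rng(seed)
            rep = assumption_checks({"a": r.normal(size=100),
                                     "b": r.normal(size=100)})
            rejected += rep["ks_normality"]["a"]["p"] < 0.05
        # the tabulated corrected-KS p-values are slightly conservative
        assert 0.005 <= rejected / n_trials <= 0.09

    def test_levene_calibration_under_equal_variance(self):
        rejected = 0
        n_trials = 200
        for seed in range(n_trials):
            r = np.random.default_rng(10_000 + seed)
            rep = assumption_checks({"a": r.normal(size=50),
                                     "b": r.normal(size=50)})
            rejected += rep["levene"]["p"] < 0.05
        assert 0.02 <= rejected / n_trials <= 0.09

    def test_bonferroni_single_comparison_unadjusted(self, rng):
        rep = assumption_checks({"a": rng.normal(size=30),
                                 "b": rng.normal(size=30) + 1})
        ph = rep["posthoc_bonferroni"][0]
        assert ph["p_bonferroni"] == pytest.approx(ph["p"])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            assumption_checks({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestColorClasses:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, "red"), (0.005, "orange"), (0.02, "yellow"),
        (0.05, "blue"), (0.9, "blue"),
    ])
    def test_mapping(self, p, expected):
        assert p_color_class(p) == expected

    def test_diagonal_white(self):
        assert p_color_class(0.0, diagonal=True) == "white"

    def test_classes_consistent_with_p(self, rng):
        p = rng.uniform(size=(12, 12))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0.0)
        sm = StatMatrix(p=p, band="I", interval="dt1")
        for i in range(12):
            for j in range(12):
                expected = p_color_class(p[i, j], diagonal=i == j)
                assert sm.classes[i, j] == expected
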