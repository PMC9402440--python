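"""Filtering cascade: genotype rule, germline tests, overdispersion, valley."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.stats import betabinom as sp_betabinom

from lymphforge import synthetic_data as sd
from lymphforge import variant_filtering as vf


class TestCallGenotype:
    @pytest.mark.parametrize(
        "alt,depth,expected",
        [
            (2, 10, True),  # exact boundary: VAF 0.20 and 2 alt reads
            (1, 2, False),  # VAF 0.5 but below the alt-read minimum
            (3, 20, False),  # VAF 0.15
            (0, 0, False),  # no coverage
            (4, 20, True),
        ],
    )
    def test_rule(self, alt, depth, expected):
        assert vf.call_genotype(alt, depth) == expected

    def test_alt_exceeding_depth(self):
        with pytest.raises(ValueError):
            vf.call_genotype(5, 3)


class TestMeanVafScreen:
    def test_germline_dropped(self):
        assert vf.mean_vaf_screen([5, 5, 5], [10, 10, 10]) == "drop"

    def test_low_mean_kept(self):
        assert vf.mean_vaf_screen([5, 0, 0, 0, 0], [10, 10, 10, 10, 10]) == "keep"

    def test_boundary_not_strictly_greater(self):
        # mean VAF exactly 0.40 is retained
        assert vf.mean_vaf_screen([4, 4], [10, 10]) == "keep"

    def test_uncovered_indeterminate(self):
        assert vf.mean_vaf_screen([0, 0], [0, 0]) == "indeterminate"


class TestAggregateBinomial:
    def test_extreme_deficit(self):
        # P(X <= 0 | Bin(100, 0.5)) = 2^-100
        assert vf.aggregate_binomial_test(0, 100, 0.5) == pytest.approx(2.0**-100)

    def test_half(self):
        expected = stats.binom.cdf(50, 100, 0.5)  # 0.5398...
        assert vf.aggregate_binomial_test(50, 100, 0.5) == pytest.approx(expected)
        assert expected == pytest.approx(0.5398, abs=1e-4)

    def test_saturated(self):
        assert vf.aggregate_binomial_test(100, 100, 0.5) == 1.0

    def test_zero_depth_error(self):
        with pytest.raises(ValueError):
            vf.aggregate_binomial_test(0, 0)


class TestClassifyGermline:
    def test_single_nonsignificant_is_germline(self):
        out = vf.classify_germline([0.5])
        assert bool(out["germline"][0])

    def test_single_tiny_p_is_somatic(self):
        out = vf.classify_germline([1e-300])
        assert not bool(out["germline"][0])

    def test_bh_by_hand(self):
        """10 tiny + 10 large p-values: BH q reproduced by direct computation."""
        p = np.array([1e-300] * 10 + [0.5] * 10)
        out = vf.classify_germline(p)
        # hand BH: sorted p, q_i = min_{j>=i} p_j * n / j
        order = np.argsort(p)
        n = len(p)
        q_sorted = p[order] * n / (np.arange(n) + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q_hand = np.empty(n)
        q_hand[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(out["q"], q_hand)
        assert (~out["germline"][:10]).all() and out["germline"][10:].all()

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        out = vf.classify_germline(p)
        order = np.argsort(out["p"].to_numpy())
        assert (np.diff(out["q"].to_numpy()[order]) >= -1e-12).all()

    def test_empty(self):
        assert len(vf.classify_germline([])) == 0


def _oracle_rho(alt, depth, grid=vf.DEFAULT_RHO_GRID):
    """Brute-force grid ML: per-rho scalar optimisation of the shared mean."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)

    def nll(mu, rho):
        s = (1 - rho) / rho
        return -sp_betabinom.logpmf(alt, depth, mu * s, (1 - mu) * s).sum()

    mu0 = alt.sum() / depth.sum()
    best_ll = stats.binom.logpmf(alt, depth, max(mu0, 1e-12)).sum()
    best_rho = 0.0
    for rho in grid:
        res = optimize.minimize_scalar(
            nll, args=(rho,), bounds=(1e-6, 1 - 1e-6), method="bounded"
        )
        if -res.fun > best_ll + 1e-9:
            best_ll, best_rho = -res.fun, rho
    return best_rho


class TestOverdispersion:
    def test_binomial_consistent_data(self):
        rho, _ = vf.betabinom_overdispersion([5, 5, 5, 5], [10, 10, 10, 10])
        assert rho <= 0.01

    def test_strongly_overdispersed(self):
        rho, lrt = vf.betabinom_overdispersion([10, 0, 10, 0], [10, 10, 10, 10])
        assert rho >= 0.5
        assert lrt > 10

    def test_all_zero_alt_convention(self):
        rho, _ = vf.betabinom_overdispersion([0, 0, 0, 0], [20, 20, 20, 20])
        assert rho == 0.0

    def test_matches_grid_ml_oracle(self, rng):
        """Profile-likelihood estimator agrees with the brute-force oracle."""
        grid = vf.DEFAULT_RHO_GRID
        steps = 0
        for _ in range(100):
            n_col = rng.integers(4, 10)
            depth = rng.integers(8, 30, size=n_col)
            kind = rng.integers(0, 3)
            if kind == 0:  # binomial noise
                alt = rng.binomial(depth, 0.05)
            elif kind == 1:  # clonal bimodal
                carriers = rng.random(n_col) < 0.4
                alt = np.where(carriers, rng.binomial(depth, 0.5), 0)
            else:  # germline-like
                alt = rng.binomial(depth, 0.5)
            if alt.sum() == 0:
                continue
            mine, _ = vf.betabinom_overdispersion(alt, depth, grid)
            oracle = _oracle_rho(alt, depth, grid)
            i = np.searchsorted(grid, mine) if mine > 0 else -1
            j = np.searchsorted(grid, oracle) if oracle > 0 else -1
            assert abs(i - j) <= 1, (alt, depth, mine, oracle)
            steps += 1
        assert steps > 50

    def test_too_few_colonies(self):
        with pytest.raises(ValueError):
            vf.betabinom_overdispersion([1, 2], [10, 10])


class TestValleyThreshold:
    def test_bimodal_mixture_cutoff_in_gap(self, rng):
        scores = np.concatenate(
            [rng.normal(1, 0.1, 250), rng.normal(5, 0.3, 250)]
        )
        cutoff, fallback = vf.valley_threshold(scores)
        assert not fallback
        assert 2 < cutoff < 4
        # independent check: the KDE minimum between modes on the same sample
        kde = stats.gaussian_kde(scores, bw_method="silverman")
        grid = np.linspace(1, 5, 400)
        assert abs(cutoff - grid[np.argmin(kde(grid))]) < 0.5

    def test_two_spikes(self):
        scores = np.array([1.0] * 100 + [9.0] * 100)
        cutoff, fallback = vf.valley_threshold(scores)
        assert 1 < cutoff < 9

    def test_unimodal_fallback(self, rng):
        scores = rng.normal(3, 1, 500)
        cutoff, fallback = vf.valley_threshold(scores, fallback=10.0)
        assert fallback and cutoff == 10.0

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            vf.valley_threshold(np.arange(10))


class TestSensitivity:
    def test_all_detected(self):
        g = np.ones((10, 3), dtype=bool)
        assert (vf.germline_recall_sensitivity(g, np.ones(10, bool)) == 1.0).all()

    def test_half_detected(self):
        g = np.zeros((80, 1), dtype=bool)
        g[:40] = True
        assert vf.germline_recall_sensitivity(g, np.ones(80, bool))[0] == 0.5

    def test_analytic_binomial_model(self):
        """At 20x, the genotype rule needs >= 4 alt reads: P(X>=4) ~ 0.9987."""
        sens = vf.analytic_genotype_sensitivity(20)
        assert sens == pytest.approx(1 - stats.binom.cdf(3, 20, 0.5))
        assert sens == pytest.approx(0.9987, abs=5e-4)
        assert sens > 0.98

    def test_sensitivity_nondecreasing_in_depth(self):
        sens = [vf.analytic_genotype_sensitivity(d) for d in range(10, 61, 5)]
        assert (np.diff(sens) >= -1e-12).all()


class TestFilterDonor:
    def test_small_donor_confusion(self):
        cfg = sd.SimConfig(
            seed=21, n_colonies=12, n_germline_sites=400,
            n_somatic_sites=200, n_artifact_sites=100,
        )
        rc, _, truth = sd.simulate_colony_readcounts(cfg)
        res = vf.filter_donor(rc)
        labels = res.labels
        t = truth.site_labels
        germ_recall = (labels[t == "germline"] == "germline").mean()
        art_reject = (labels[t == "artifact"] == "artifact").mean()
        som_retain = (labels[t == "somatic"] == "somatic").mean()
        assert germ_recall >= 0.99
        assert art_reject >= 0.95
        assert som_retain >= 0.90

    def test_blacklist_hook(self):
        cfg = sd.SimConfig(
            seed=22, n_colonies=8, n_germline_sites=60,
            n_somatic_sites=60, n_artifact_sites=30,
        )
        rc, _, _ = sd.simulate_colony_readcounts(cfg)
        import pandas as pd

        black = pd.Series(True, index=rc.alt.index)
        res = vf.filter_donor(rc, blacklist=black)
        assert (res.labels != "somatic").all()


def test_filtered_vcf_output(tmp_path):
    cfg = sd.SimConfig(
        seed=23, n_colonies=6, n_germline_sites=30,
        n_somatic_sites=30, n_artifact_sites=10,
    )
    rc, _, _ = sd.simulate_colony_readcounts(cfg)
    res = vf.filter_donor(rc)
    path = tmp_path / "out.vcf"
    vf.write_filtered_vcf(rc, res, path)
    lines = path.read_text().splitlines()
    body = [l for l in lines if not l.startswith("#")]
    assert len(body) == 70
    tags = {l.split("\t")[6] for l in body}
    assert tags <= {"GERMLINE", "ARTEFACT_BB", "PASS"}
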