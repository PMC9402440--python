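"""Generator determinism, truth conservation and distributional checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lymphforge import synthetic_data as sd


def small_config(**kw):
    defaults = dict(
        seed=7,
        n_colonies=8,
        n_germline_sites=100,
        n_somatic_sites=60,
        n_artifact_sites=40,
    )
    defaults.update(kw)
    return sd.SimConfig(**defaults)


class TestColonyReadcounts:
    def test_same_seed_identical(self):
        a, _, _ = sd.simulate_colony_readcounts(small_config())
        b, _, _ = sd.simulate_colony_readcounts(small_config())
        pd.testing.assert_frame_equal(a.alt, b.alt)
        pd.testing.assert_frame_equal(a.total, b.total)

    def test_truth_partitions_sites(self):
        rc, meta, truth = sd.simulate_colony_readcounts(small_config())
        counts = truth.site_labels.value_counts()
        assert counts["germline"] == 100
        assert counts["somatic"] == 60
        assert counts["artifact"] == 40
        assert counts.sum() == len(rc.alt)

    def test_germline_vaf_near_half(self):
        cfg = small_config(n_germline_sites=100, n_somatic_sites=0, n_artifact_sites=0)
        rc, _, truth = sd.simulate_colony_readcounts(cfg)
        assert len(rc.alt) == 100
        vaf = rc.vaf.to_numpy()
        # mean over 100 sites x 8 colonies at depth ~20: se ~ 0.5/sqrt(n*20)
        se = 0.5 / np.sqrt(vaf.size * 20)
        assert abs(np.nanmean(vaf) - 0.5) < 3 * se

    def test_carrier_alt_counts_match_binomial(self):
        """Alt reads in carrier colonies at fixed depth follow Binomial(d, 1/2)."""
        cfg = sd.SimConfig(
            seed=11, n_colonies=30, n_germline_sites=0,
            n_somatic_sites=2000, n_artifact_sites=0,
        )
        rc, _, truth = sd.simulate_colony_readcounts(cfg)
        alt = rc.alt.to_numpy()
        depth = rc.total.to_numpy()
        draws = []
        col_pos = {c: i for i, c in enumerate(rc.alt.columns)}
        for s, (sid, carriers) in enumerate(truth.somatic_carriers.items()):
            i = rc.alt.index.get_loc(sid)
            for c in carriers:
                if depth[i, c] == 20:
                    draws.append(alt[i, c])
        draws = np.array(draws)
        assert len(draws) > 300
        observed = np.bincount(draws, minlength=21)
        expected = stats.binom.pmf(np.arange(21), 20, 0.5) * len(draws)
        keep = expected > 5  # merge sparse tails for the chi-square
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_artifact_sites_not_overdispersed(self):
        cfg = small_config(n_germline_sites=0, n_somatic_sites=0, n_artifact_sites=200)
        rc, _, _ = sd.simulate_colony_readcounts(cfg)
        vaf = np.nanmean(rc.vaf.to_numpy(), axis=1)
        assert (vaf < 0.15).all()  # error probabilities are at most 5%

    def test_zero_sites_error(self):
        with pytest.raises(sd.ConfigurationError):
            cfg = small_config(
                n_germline_sites=0, n_somatic_sites=0, n_artifact_sites=0
            )
            sd.simulate_colony_readcounts(cfg)


class TestBurdenTable:
    def test_noiseless_burden_exact(self):
        cfg = sd.SimConfig(
            seed=1, n_donors=2, ages=(5.0, 5.0),
            cell_types=("HSPC",),
            slope_per_type={"HSPC": 10.0},
            offset_per_type={"HSPC": 0.0},
            resid_sd_per_type={"HSPC": 0.0},
            donor_sd=0.0,
            n_colonies_per_group=4,
        )
        with pytest.warns(UserWarning):  # single age: slope unidentifiable
            tab = sd.simulate_burden_table(cfg)
        assert (tab["burden"] == 50.0).all()

    def test_residual_sd_recovered(self):
        """Monte-Carlo residual s.d. matches the configured value within 3%."""
        cfg = sd.SimConfig(
            seed=3, n_donors=2, ages=(20.0, 60.0),
            cell_types=("HSPC",),
            slope_per_type={"HSPC": 0.0},
            offset_per_type={"HSPC": 10000.0},  # keep away from the clamp
            resid_sd_per_type={"HSPC": 70.0},
            donor_sd=0.0,
            n_colonies_per_group=5000,
        )
        tab = sd.simulate_burden_table(cfg)
        assert len(tab) == 10000
        sds = tab.groupby("donor")["burden"].std(ddof=1)
        assert np.allclose(sds, 70.0, rtol=0.03)

    def test_same_seed_identical(self):
        t1 = sd.simulate_burden_table(sd.SimConfig(seed=5))
        t2 = sd.simulate_burden_table(sd.SimConfig(seed=5))
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_donor_error(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_burden_table(sd.SimConfig(seed=1, n_donors=1, ages=(30.0,)))


class TestCatalog:
    def test_uniform_signature_totals(self):
        sigs = pd.DataFrame(np.full((1, 96), 1 / 96.0))
        counts = sd.simulate_catalog([1.0], sigs, 96, seed=0)
        assert counts.sum() == 96

    def test_mixture_frequencies(self, catalog):
        w = np.zeros(len(catalog))
        w[[0, 5]] = [0.7, 0.3]
        n = 100_000
        counts = sd.simulate_catalog(w, catalog, n, seed=1)
        probs = w @ catalog.to_numpy()
        se = np.sqrt(probs * (1 - probs) / n)
        # with 96 simultaneous channels a few 3-s.e. excursions are expected
        violations = (np.abs(counts / n - probs) > 3 * se + 1e-12).sum()
        assert violations <= 3
        assert (np.abs(counts / n - probs) <= 5 * se + 1e-12).all()

    def test_zero_total(self, catalog):
        w = np.zeros(len(catalog))
        w[0] = 1.0
        assert sd.simulate_catalog(w, catalog, 0, seed=0).sum() == 0

    def test_negative_exposure_rejected(self, catalog):
        w = np.zeros(len(catalog))
        w[0], w[1] = 1.5, -0.5
        with pytest.raises(ValueError):
            sd.simulate_catalog(w, catalog, 10, seed=0)


class TestFeatureBins:
    def test_null_mean_rate(self):
        tab = sd.simulate_feature_bins(
            10_000, {"f": lambda x: np.zeros_like(x)}, seed=2, beta0=np.log(5)
        )
        se = np.sqrt(5.0 / len(tab))
        assert abs(tab["count"].mean() - 5.0) < 3 * se

    def test_monotone_feature_drives_counts(self):
        tab = sd.simulate_feature_bins(
            5000, {"f": lambda x: 0.8 * x}, seed=3
        )
        rho = stats.spearmanr(tab["f"], tab["count"]).statistic
        assert rho > 0.5

    def test_same_seed_identical(self):
        link = {"f": lambda x: x}
        a = sd.simulate_feature_bins(100, link, seed=9)
        b = sd.simulate_feature_bins(100, link, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestReferenceAndSVs:
    def test_rag_one_plants_heptamer_interior(self):
        ref, svs, truth = sd.simulate_reference_and_svs(500_000, 40, 1.0, 0.0, seed=4)
        assert (truth.sv_mechanism == "RAG").all()
        for _, r in svs.iterrows():
            window = ref[r.pos1 - 1 : r.pos1 - 1 + 50]
            assert sd.RSS_HEPTAMER in window

    def test_same_seed_identical_fasta(self):
        r1, _, _ = sd.simulate_reference_and_svs(100_000, 5, 0.5, 0.0, seed=6)
        r2, _, _ = sd.simulate_reference_and_svs(100_000, 5, 0.5, 0.0, seed=6)
        assert r1 == r2

    def test_genome_too_short(self):
        with pytest.raises(ValueError):
            sd.simulate_reference_and_svs(10_000, 50, 0.5, 0.0, seed=0)

    def test_region_labels_from_coordinates(self):
        _, svs, _ = sd.simulate_reference_and_svs(500_000, 40, 0.0, 0.0, seed=8)
        ig_end = 50_000
        expect = np.where(
            (svs["pos1"] <= ig_end) | (svs["pos2"] <= ig_end), "IgTCR", "other"
        )
        assert (svs["region"] == expect).all()


class TestEpigenomeTracks:
    def test_zero_mutations(self):
        _, counts, _ = sd.simulate_epigenome_tracks(3, 50, 0, 0, seed=1)
        assert (counts == 0).all()

    def test_placement_track_correlates_best(self):
        wins = 0
        for seed in range(10):
            tracks, counts, _ = sd.simulate_epigenome_tracks(
                4, 500, placement_track=2, n_mutations=5000, seed=seed
            )
            cors = [stats.spearmanr(tracks[:, j], counts).statistic for j in range(4)]
            wins += int(np.argmax(cors) == 2)
        assert wins >= 9

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            sd.simulate_epigenome_tracks(2, 5, 0, 100, seed=0)

    def test_same_seed_identical(self):
        t1, c1, _ = sd.simulate_epigenome_tracks(2, 100, 0, 500, seed=3)
        t2, c2, _ = sd.simulate_epigenome_tracks(2, 100, 0, 500, seed=3)
        assert np.array_equal(t1, t2) and np.array_equal(c1, c2)


def test_readcounts_tsv_roundtrip(tmp_path):
    rc, _, _ = sd.simulate_colony_readcounts(small_config())
    path = tmp_path / "rc.tsv"
    sd.write_readcounts_tsv(rc, path)
    back = sd.read_readcounts_tsv(path)
    assert np.array_equal(back.alt.to_numpy(), rc.alt.to_numpy())
    assert np.array_equal(back.total.to_numpy(), rc.total.to_numpy())


def test_bedpe_roundtrip(tmp_path):
    _, svs, _ = sd.simulate_reference_and_svs(100_000, 8, 0.5, 0.25, seed=2)
    path = tmp_path / "svs.bedpe"
    sd.write_bedpe(svs, path)
    back = sd.read_bedpe(path)
    assert list(back["pos1"]) == list(svs["pos1"])
    assert list(back["insseq"]) == list(svs["insseq"])
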