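"""Suitability models, split evaluation, TSS, and consensus projection."""

import numpy as np
import pytest

from islereserve.raster import Grid
from islereserve.sdm import (
    ClimateStack,
    EmptyEnsembleError,
    OccurrenceSet,
    TooFewOccurrencesError,
    compute_tss,
    consensus_votes,
    ensemble_consensus,
    fit_ensemble,
    fit_suitability_model,
    generate_splits,
    sample_background,
)
from islereserve.synth import generate_study, sample_occurrences


def toy_climate(nrows=6, ncols=6, seed=0) -> ClimateStack:
    rng = np.random.default_rng(seed)
    mask = np.zeros((nrows, ncols), bool)

    def g(lo, hi):
        return Grid(values=rng.uniform(lo, hi, (nrows, ncols)), nodata_mask=mask.copy())

    return ClimateStack(tmax=g(10, 25), ppmin=g(20, 80), prange=g(400, 900))


class TestSplits:
    def occ(self, n_pres=20, n_bg=20):
        return OccurrenceSet("sp", np.arange(n_pres), np.arange(100, 100 + n_bg))

    def test_eighty_twenty_partition(self):
        splits = generate_splits(self.occ(), n_splits=3, seed=1)
        for (cp, cb), (vp, vb) in splits:
            assert cp.size == 16 and vp.size == 4
            assert cb.size == 16 and vb.size == 4
            assert set(cp) | set(vp) == set(range(20))
            assert not set(cp) & set(vp)

    def test_ten_splits_by_default(self):
        assert len(generate_splits(self.occ(), seed=0)) == 10

    def test_occurrence_floor_refusal_names_species(self):
        occ = OccurrenceSet("rare_sp", np.arange(14), np.arange(50, 70))
        with pytest.raises(TooFewOccurrencesError, match="rare_sp.*15"):
            generate_splits(occ)

    def test_seed_reproducibility(self):
        a = generate_splits(self.occ(), seed=42)
        b = generate_splits(self.occ(), seed=42)
        for (ca, va), (cb, vb) in zip(a, b):
            assert np.array_equal(ca[0], cb[0]) and np.array_equal(va[1], vb[1])

    def test_configurable_floor(self):
        occ = OccurrenceSet("sp", np.arange(8), np.arange(50, 58))
        assert len(generate_splits(occ, n_splits=2, min_occurrences=5, seed=0)) == 2


class TestModels:
    def test_envelope_excludes_out_of_bounds(self):
        clim = toy_climate()
        cells = np.argsort(clim.tmax.values.ravel())[:5]  # coolest cells
        model = fit_suitability_model("envelope", cells, clim)
        hottest = int(np.argmax(clim.tmax.values.ravel()))
        assert not model.predict_cells(clim.at([hottest]))[0]

    @pytest.mark.parametrize("kind", ["envelope", "centroid"])
    def test_training_presences_predicted_present(self, kind):
        clim = toy_climate(seed=3)
        cells = np.array([0, 7, 14, 21, 28])
        model = fit_suitability_model(kind, cells, clim)
        assert model.predict_cells(clim.at(cells)).all()

    def test_single_presence_point_envelope(self):
        clim = toy_climate(seed=5)
        model = fit_suitability_model("envelope", np.array([11]), clim)
        pred = model.predict(clim)
        expected = np.all(clim.matrix() == clim.at([11]), axis=1).reshape(clim.shape)
        assert np.array_equal(pred.presence, expected)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_suitability_model("envelope", np.array([], dtype=int), toy_climate())

    def test_centroid_needs_two_presences(self):
        with pytest.raises(ValueError, match="2 presences"):
            fit_suitability_model("centroid", np.array([3]), toy_climate())


class TestTSS:
    def test_perfect_agreement_is_one(self):
        obs = np.array([1, 1, 0, 0], bool)
        assert compute_tss(obs, obs).tss == pytest.approx(1.0)

    def test_constant_predictor_is_zero(self):
        obs = np.array([1, 0, 1, 0], bool)
        r = compute_tss(np.ones(4, bool), obs)
        assert (r.sensitivity, r.specificity) == (1.0, 0.0)
        assert r.tss == pytest.approx(0.0)

    def test_confusion_counts_arithmetic(self):
        # TP=40, FN=10, TN=45, FP=5 -> sens 0.8, spec 0.9, tss 0.7
        obs = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        pred = np.concatenate([np.ones(40, bool), np.zeros(10, bool),
                               np.ones(5, bool), np.zeros(45, bool)])
        r = compute_tss(pred, obs)
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.9)
        assert r.tss == pytest.approx(0.7)

    def test_single_class_observed_is_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            compute_tss(np.ones(4, bool), np.ones(4, bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_label_swap_exchanges_sensitivity_and_specificity(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.random(60) < 0.5
        obs[:2] = [True, False]
        pred = rng.random(60) < 0.5
        r, rs = compute_tss(pred, obs), compute_tss(~pred, ~obs)
        assert rs.sensitivity == pytest.approx(r.specificity)
        assert rs.specificity == pytest.approx(r.sensitivity)
        assert rs.tss == pytest.approx(r.tss)


class TestConsensus:
    def test_half_of_members_suffices(self):
        votes = np.array([[1], [1], [0], [0]], bool)
        assert consensus_votes(votes)[0]  # 2 of 4 >= half

    def test_negative_tss_member_discarded(self):
        clim = toy_climate()
        strong = fit_suitability_model("envelope", np.arange(clim.tmax.values.size), clim)
        weak = fit_suitability_model("envelope", np.array([0]), clim)
        out = ensemble_consensus([(strong, 0.5), (weak, -0.2)], clim)
        assert np.array_equal(out.presence, strong.predict(clim).presence)

    def test_all_discarded_is_an_error(self):
        clim = toy_climate()
        m = fit_suitability_model("envelope", np.array([0]), clim)
        with pytest.raises(EmptyEnsembleError):
            ensemble_consensus([(m, -0.1)], clim)

    def test_unanimous_members_give_their_prediction(self):
        clim = toy_climate()
        m = fit_suitability_model("envelope", np.arange(clim.tmax.values.size), clim)
        out = ensemble_consensus([(m, 0.1), (m, 0.2), (m, 0.3)], clim)
        assert out.presence.all()

    def test_single_member_consensus_is_that_member(self):
        clim = toy_climate(seed=9)
        m = fit_suitability_model("envelope", np.array([4, 9, 16]), clim)
        out = ensemble_consensus([(m, 0.4)], clim)
        assert np.array_equal(out.presence, m.predict(clim).presence)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_always_present_member(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 5))
        votes = rng.random((k, 30)) < 0.5
        everywhere = np.ones((1, 30), bool)
        base = consensus_votes(votes)
        grown = consensus_votes(np.vstack([votes, everywhere]))
        assert not np.any(base & ~grown)


class TestEnsembleFit:
    def test_projection_reuses_identical_parameters(self):
        bundle = generate_study(seed=11)
        sid = bundle.species_ids[0]
        cells = sample_occurrences(bundle, sid, seed=1)
        bg = sample_background(cells, bundle.area, seed=2)
        occ = OccurrenceSet(sid, cells, bg)
        res = fit_ensemble(occ, bundle.climate["1961-1990"], seed=3)
        params_before = [
            (m.lower.copy(), m.upper.copy()) if m.kind == "envelope"
            else (m.center.copy(), m.threshold)
            for m in res.retained
        ]
        res.project(bundle.climate["2080-2099"])
        for m, before in zip(res.retained, params_before):
            if m.kind == "envelope":
                assert np.array_equal(m.lower, before[0]) and np.array_equal(m.upper, before[1])
            else:
                assert np.array_equal(m.center, before[0]) and m.threshold == before[1]
        assert set(res.consensus) == {"1961-1990", "2080-2099"}
        assert all(res.mean_tss[k] >= 0.0 for k in res.retained_kinds)

    def test_background_avoids_presences_and_is_seeded(self):
        bundle = generate_study(seed=11)
        sid = bundle.species_ids[0]
        cells = sample_occurrences(bundle, sid, seed=1)
        bg1 = sample_background(cells, bundle.area, seed=5)
        bg2 = sample_background(cells, bundle.area, seed=5)
        assert np.array_equal(bg1, bg2)
        assert not set(bg1) & set(cells)
        island = set(np.flatnonzero(bundle.area.cells.ravel()))
        assert set(bg1) <= island
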