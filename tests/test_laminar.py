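import numpy as np
import pandas as pd
import pytest

from crossconn import Area, ConnectomeError, SyntheticSpec, generate_cortex
from crossconn.laminar import (
    build_laminar_table,
    classify_ff_fb,
    compare_predictor_sets,
    compute_nsg,
    evaluate_out_of_sample,
    extrapolate_to_target,
    fit_laminar_model,
    map_human_regions,
    permutation_null,
    rostrocaudal_offset,
)
from crossconn.stats import partial_spearman


class TestComputeNSG:
    def test_worked_example(self):
        assert compute_nsg(20, 80) == 20.0

    def test_symmetry(self):
        assert compute_nsg(50, 50) == 50.0

    def test_boundary(self):
        assert compute_nsg(7, 0) == 100.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            compute_nsg(0, 0)


class TestRostrocaudalOffset:
    def _area(self, rc, i=0):
        return Area(id=f"r{i}", cyto=1.0, rostrocaudal=rc)

    def test_sign_convention(self):
        assert rostrocaudal_offset(self._area(1.0, 0), self._area(0.0, 1)) == 1.0

    def test_identity(self):
        assert rostrocaudal_offset(self._area(0.4, 0), self._area(0.4, 1)) == 0.0

    def test_antisymmetry(self):
        a, b = self._area(0.8, 0), self._area(0.3, 1)
        assert rostrocaudal_offset(a, b) == -rostrocaudal_offset(b, a)

    def test_missing_coordinate_errors(self):
        a = Area(id="x", cyto=1.0)
        with pytest.raises(ConnectomeError):
            rostrocaudal_offset(a, self._area(0.5, 1))


class TestBuildTable:
    def test_counts_to_nsg(self):
        areas = [
            Area(id="a", cyto=1.0, rostrocaudal=0.0),
            Area(id="b", cyto=3.0, rostrocaudal=1.0),
        ]
        proj = pd.DataFrame(
            {"origin": ["a"], "termination": ["b"], "n_supra": [20], "n_infra": [80]}
        )
        t = build_laminar_table(areas, proj)
        assert t["nsg"].iloc[0] == 20.0
        assert t["cyto_diff"].iloc[0] == -2.0
        assert t["rc_diff"].iloc[0] == -1.0

    def test_antisymmetric_predictors(self, std_cortex):
        t = std_cortex.laminar
        lookup = {(o, d): (c, r) for o, d, c, r in zip(
            t["origin"], t["termination"], t["cyto_diff"], t["rc_diff"]
        )}
        checked = 0
        for (o, d), (c, r) in lookup.items():
            if (d, o) in lookup:
                c2, r2 = lookup[(d, o)]
                assert c == -c2 and r == pytest.approx(-r2)
                checked += 1
        assert checked > 10

    def test_unknown_area_errors(self):
        areas = [Area(id="a", cyto=1.0, rostrocaudal=0.5)]
        proj = pd.DataFrame({"origin": ["a"], "termination": ["zzz"], "nsg": [50.0]})
        with pytest.raises(ConnectomeError, match="zzz"):
            build_laminar_table(areas, proj)


class TestEvaluate:
    def test_strong_signal_recovery(self, std_cortex):
        ev = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=100, seed=0)
        assert ev.median_rho >= 0.8

    def test_shuffled_null_centered(self, std_cortex):
        rng = np.random.default_rng(1)
        shuffled = std_cortex.laminar.copy()
        shuffled["nsg"] = rng.permutation(shuffled["nsg"].to_numpy())
        ev = evaluate_out_of_sample(shuffled, ("cyto_diff",), n_rep=100, seed=0)
        assert abs(np.median(ev.rho_per_rep)) < 0.15

    def test_deterministic(self, std_cortex):
        a = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=20, seed=7)
        b = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=20, seed=7)
        assert np.array_equal(a.rho_per_rep, b.rho_per_rep)

    def test_too_few_records_errors(self):
        t = pd.DataFrame({"cyto_diff": [0.1] * 5, "nsg": [50.0] * 5})
        with pytest.raises(ConnectomeError):
            evaluate_out_of_sample(t, ("cyto_diff",), n_rep=5, seed=0)


class TestPermutationNull:
    def test_centered_and_dominated(self, std_cortex):
        null = permutation_null(
            std_cortex.laminar, ("cyto_diff",), n_shuffles=30, inner_rep=10, seed=2
        )
        assert abs(null.mean()) < 0.1
        ev = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=50, seed=3)
        assert ev.median_rho > null.max()

    def test_null_slope_inside_permutation_null(self):
        from crossconn import SyntheticSpec, generate_cortex

        spec = SyntheticSpec(n_areas=50, beta0=0.5, nsg_slope=0.0, nsg_noise_sd=5.0,
                             seed=21)
        lam = generate_cortex(spec).laminar
        ev = evaluate_out_of_sample(lam, ("cyto_diff",), n_rep=50, seed=0)
        null = permutation_null(lam, ("cyto_diff",), n_shuffles=40, inner_rep=20, seed=1)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= np.mean(ev.rho_per_rep) <= hi

    def test_deterministic(self, std_cortex):
        a = permutation_null(std_cortex.laminar, ("cyto_diff",), n_shuffles=5,
                             inner_rep=5, seed=4)
        b = permutation_null(std_cortex.laminar, ("cyto_diff",), n_shuffles=5,
                             inner_rep=5, seed=4)
        assert np.array_equal(a, b)


class TestComparePredictorSets:
    def test_identical_not_significant(self, std_cortex):
        ev = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=50, seed=5)
        res = compare_predictor_sets(ev, ev, n_perm=200, seed=0)
        assert res.p_value >= 0.5

    def test_constructed_contrast(self, std_cortex):
        ev_c = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=100, seed=6)
        ev_r = evaluate_out_of_sample(std_cortex.laminar, ("rc_diff",), n_rep=100, seed=6)
        res = compare_predictor_sets(ev_c, ev_r, n_perm=500, seed=1)
        assert res.p_value < 0.01

    def test_null_symmetric(self, std_cortex):
        ev = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=50, seed=7)
        ev2 = evaluate_out_of_sample(std_cortex.laminar, ("rc_diff",), n_rep=50, seed=7)
        res = compare_predictor_sets(ev, ev2, n_perm=400, seed=2)
        assert abs(np.mean(res.null_values)) < 3 * np.std(res.null_values) / np.sqrt(400) * 3 + 1e-2

    def test_mismatched_reps_error(self, std_cortex):
        a = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=10, seed=8)
        b = evaluate_out_of_sample(std_cortex.laminar, ("cyto_diff",), n_rep=20, seed=8)
        with pytest.raises(ValueError):
            compare_predictor_sets(a, b)

    def test_combined_no_better_than_cyto_when_rc_noise(self, std_cortex):
        rng = np.random.default_rng(9)
        t = std_cortex.laminar.copy()
        t["rc_diff"] = rng.normal(size=len(t))  # pure noise predictor
        ev_c = evaluate_out_of_sample(t, ("cyto_diff",), n_rep=100, seed=10)
        ev_b = evaluate_out_of_sample(t, ("cyto_diff", "rc_diff"), n_rep=100, seed=10)
        assert ev_b.median_rho - ev_c.median_rho <= 0.05


class TestClassifyFFFB:
    @pytest.fixture(scope="class")
    def labeled(self, std_cortex):
        t = std_cortex.laminar.copy()
        t["label"] = np.where(t["cyto_diff"] > t["cyto_diff"].median(),
                              "feedforward", "feedback")
        return t

    def test_separable_labels_high_auc(self, labeled):
        ev = classify_ff_fb(labeled, ("cyto_diff",), n_rep=50, seed=0)
        assert np.median(ev.rho_per_rep) >= 0.95

    def test_shuffled_labels_half(self, labeled):
        rng = np.random.default_rng(1)
        t = labeled.copy()
        t["label"] = rng.permutation(t["label"].to_numpy())
        ev = classify_ff_fb(t, ("cyto_diff",), n_rep=50, seed=0)
        assert abs(np.median(ev.rho_per_rep) - 0.5) < 0.1

    def test_deterministic(self, labeled):
        a = classify_ff_fb(labeled, ("cyto_diff",), n_rep=10, seed=3)
        b = classify_ff_fb(labeled, ("cyto_diff",), n_rep=10, seed=3)
        assert np.array_equal(a.rho_per_rep, b.rho_per_rep)

    def test_single_class_errors(self, labeled):
        t = labeled.copy()
        t["label"] = "feedforward"
        with pytest.raises(ConnectomeError):
            classify_ff_fb(t, ("cyto_diff",), n_rep=5, seed=0)


class TestExtrapolation:
    @pytest.fixture(scope="class")
    def model(self, std_cortex):
        return fit_laminar_model(std_cortex.laminar, ("cyto_diff",))

    def test_equal_density_symmetric(self, model):
        targets = [
            Area(id="r1", cyto=40.0, cyto_kind="density"),
            Area(id="r2", cyto=40.0, cyto_kind="density"),
            Area(id="r3", cyto=70.0, cyto_kind="density"),
        ]
        pred = extrapolate_to_target(model, targets)
        assert pred.loc["r1", "r2"] == pred.loc["r2", "r1"]

    def test_pairwise_midpoint_antisymmetry(self, model):
        # linear kernel: pred(a,b) + pred(b,a) is constant over pairs
        targets = [
            Area(id=f"t{i}", cyto=10.0 + 10 * i, cyto_kind="density") for i in range(5)
        ]
        pred = extrapolate_to_target(model, targets).to_numpy()
        off = ~np.eye(5, dtype=bool)
        sums = (pred + pred.T)[off]
        if (pred[off] > 0).all() and (pred[off] < 100).all():  # unclipped regime
            assert np.ptp(sums) < 1e-6

    def test_in_sample_consistency(self, std_cortex, model):
        t = std_cortex.laminar
        direct = model.predict(t)
        via_diff = model.predict_from_diff(t["cyto_diff"].to_numpy())
        assert np.allclose(direct, via_diff)

    def test_range_clipped(self, model):
        targets = [
            Area(id=f"u{i}", cyto=float(v), cyto_kind="density")
            for i, v in enumerate([1, 1000, 2000])
        ]
        pred = extrapolate_to_target(model, targets)
        assert ((pred >= 0) & (pred <= 100)).all().all()

    def test_wrong_predictor_set_errors(self, std_cortex):
        m = fit_laminar_model(std_cortex.laminar, ("cyto_diff", "rc_diff"))
        with pytest.raises(ValueError):
            extrapolate_to_target(m, [Area(id="x", cyto=1.0, cyto_kind="density")])


class TestMapHumanRegions:
    def test_mean_density(self):
        t = pd.DataFrame(
            {"region": ["R1", "R1", "R2"], "area": ["a", "b", "c"],
             "density": [40.0, 60.0, 35.0]}
        )
        out = map_human_regions(t)
        by_id = {a.id: a.cyto for a in out}
        assert by_id == {"R1": 50.0, "R2": 35.0}

    def test_totality(self):
        t = pd.DataFrame(
            {"region": [f"R{i}" for i in range(7)], "area": list("abcdefg"),
             "density": np.arange(1.0, 8.0)}
        )
        assert len(map_human_regions(t)) == 7

    def test_missing_density_errors(self):
        t = pd.DataFrame(
            {"region": ["R1", "R2"], "area": ["a", "b"], "density": [40.0, np.nan]}
        )
        with pytest.raises(ConnectomeError, match="R2"):
            map_human_regions(t)


def test_partial_spearman_recovery_with_correlated_rc():
    # rc_diff correlated with cyto_diff by construction; partialling rc out
    # still recovers the cyto association
    rng = np.random.default_rng(20)
    n = 500
    cyto_diff = rng.normal(size=n)
    rc_diff = 0.6 * cyto_diff + 0.8 * rng.normal(size=n)
    nsg = 50 + 20 * cyto_diff + rng.normal(0, 8, size=n)
    r_direct = partial_spearman(nsg, cyto_diff, rc_diff)
    from crossconn.stats import spearman_rho

    r_marginal = spearman_rho(nsg, cyto_diff)
    assert r_direct > 0.5
    assert abs(r_direct - r_marginal) < 0.25
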