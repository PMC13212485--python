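import numpy as np
import pytest

from ghef.dataio import split_train_test
from ghef.eefo import EEFOConfig
from ghef.ensemble_fusion import (
    Frame,
    MassFunction,
    Reliability,
    TotalConflictError,
    WeightVector,
    bel_pl,
    build_mass_function,
    dempster_combine,
    dst_predict,
    fit_weights,
    pignistic_predict,
    reliability_from_rmse,
    vacuous_mass,
    weighted_predict,
)
from ghef.learners import DEFAULT_CONFIGS, LearnerKind, predict_learner, train_learner


def _small_eefo(m: int, seed: int = 0) -> EEFOConfig:
    return EEFOConfig(bounds=((0.0, 1.0),) * m, population_size=10, max_iterations=30, seed=seed)


# ---------------------------------------------------------------------------
# brute-force Dempster oracle over explicit focal sets


def _to_focal_sets(mass: MassFunction) -> dict[frozenset, float]:
    k = mass.frame.n_bins
    focal = {frozenset([i]): m for i, m in enumerate(mass.singleton_masses) if m > 0}
    if mass.ignorance_mass > 0:
        focal[frozenset(range(k))] = mass.ignorance_mass
    return focal


def _dempster_enumeration(m1: MassFunction, m2: MassFunction):
    """Textbook Dempster rule: enumerate every focal-set pair."""
    f1, f2 = _to_focal_sets(m1), _to_focal_sets(m2)
    conflict = 0.0
    combined: dict[frozenset, float] = {}
    for a, ma in f1.items():
        for b, mb in f2.items():
            inter = a & b
            if inter:
                combined[inter] = combined.get(inter, 0.0) + ma * mb
            else:
                conflict += ma * mb
    return {s: v / (1 - conflict) for s, v in combined.items()}, conflict


def _random_mass(frame: Frame, rng: np.random.Generator) -> MassFunction:
    raw = rng.dirichlet(np.ones(frame.n_bins + 1))
    return MassFunction(frame, tuple(raw[:-1]), float(raw[-1]))


class TestWeightedEnsemble:
    def test_exact_member_gets_all_the_weight(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 3, 50)
        P = np.column_stack([y, y + 1.0])
        w = fit_weights(P, y, _small_eefo(2))
        assert w.weights[0] == pytest.approx(1.0, abs=0.02)
        assert w.weights[1] == pytest.approx(0.0, abs=0.02)

    def test_identical_members_fuse_to_their_common_rmse(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 3, 40)
        yhat = y + rng.normal(0, 0.1, 40)
        P = np.column_stack([yhat, yhat])
        w = fit_weights(P, y, _small_eefo(2))
        fused = weighted_predict(w, P)
        member_rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
        assert float(np.sqrt(np.mean((fused - y) ** 2))) == pytest.approx(member_rmse, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_fitted_rmse_never_worse_than_best_member(self, seed):
        # unit vectors are seeded into the optimizer's population, so this
        # holds as a theorem, not a tendency
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 3, 30)
        P = np.column_stack([y + rng.normal(0, s, 30) for s in (0.05, 0.2, 0.5)])
        w = fit_weights(P, y, _small_eefo(3, seed))
        fused_rmse = float(np.sqrt(np.mean((weighted_predict(w, P) - y) ** 2)))
        best_member = min(float(np.sqrt(np.mean((P[:, m] - y) ** 2))) for m in range(3))
        assert fused_rmse <= best_member + 1e-9

    def test_weighted_predict_examples(self):
        w = WeightVector((1.0, 0.0))
        np.testing.assert_allclose(weighted_predict(w, [[0.3, 9.9]]), [0.3])
        w = WeightVector((0.25, 0.75))
        assert weighted_predict(w, [[0.2, 0.6]])[0] == pytest.approx(0.5)

    def test_fused_value_is_convex_combination(self):
        rng = np.random.default_rng(2)
        P = rng.uniform(0, 3, (20, 3))
        raw = rng.dirichlet(np.ones(3))
        fused = weighted_predict(WeightVector(tuple(raw)), P)
        assert np.all(fused >= P.min(axis=1) - 1e-12) and np.all(fused <= P.max(axis=1) + 1e-12)

    def test_degenerate_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_weights(np.empty((0, 2)), np.empty(0))
        with pytest.raises(ValueError):
            weighted_predict(WeightVector((0.5, 0.5)), [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            WeightVector((0.7, 0.7))
        with pytest.raises(ValueError):
            WeightVector((-0.1, 1.1))


class TestReliability:
    def test_perfect_learner_is_capped(self):
        assert reliability_from_rmse([0.0], 1.0).values[0] == pytest.approx(0.999)

    def test_rmse_equal_to_scale_gives_half(self):
        assert reliability_from_rmse([2.0], 2.0).values[0] == pytest.approx(0.5)

    def test_monotone_in_accuracy(self):
        r = reliability_from_rmse([0.1, 0.5], 1.0)
        assert r.values[0] > r.values[1]

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            reliability_from_rmse([0.1], 0.0)


class TestMassFunctions:
    frame = Frame(tuple(np.linspace(0.0, 3.0, 21)))

    def test_zero_reliability_is_vacuous(self):
        mass = build_mass_function(1.5, 0.2, 0.0, self.frame)
        assert mass.ignorance_mass == pytest.approx(1.0)
        assert all(m == 0 for m in mass.singleton_masses)

    def test_vanishing_bandwidth_concentrates_on_one_bin(self):
        mass = build_mass_function(1.51, 1e-9, 0.8, self.frame)
        masses = np.asarray(mass.singleton_masses)
        assert masses.max() == pytest.approx(0.8, abs=1e-9)
        assert self.frame.edges[int(masses.argmax())] <= 1.51 <= self.frame.edges[int(masses.argmax()) + 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_masses_sum_to_one_and_match_bin_integration(self, seed):
        rng = np.random.default_rng(seed)
        pred, bw, r = rng.uniform(0, 3), rng.uniform(0.05, 1.0), rng.uniform(0, 0.999)
        mass = build_mass_function(pred, bw, r, self.frame)
        total = sum(mass.singleton_masses) + mass.ignorance_mass
        assert total == pytest.approx(1.0, abs=1e-12)
        # brute-force numeric bin integration oracle
        from scipy.integrate import quad
        from scipy.stats import norm

        probs = []
        for lo, hi in zip(self.frame.edges[:-1], self.frame.edges[1:]):
            probs.append(quad(lambda x: norm.pdf(x, pred, bw), lo, hi)[0])
        probs = np.array(probs) / np.sum(probs)
        np.testing.assert_allclose(mass.singleton_masses, r * probs, atol=1e-7)

    def test_truncation_is_flagged_not_fatal(self):
        mass = build_mass_function(2.95, 0.5, 0.9, self.frame)
        assert mass.truncated
        assert sum(mass.singleton_masses) + mass.ignorance_mass == pytest.approx(1.0, abs=1e-12)

    def test_invalid_mass_vectors_rejected(self):
        with pytest.raises(ValueError):
            MassFunction(self.frame, (0.5,) * 20, 0.5)  # sums to 10.5


class TestDempsterCombination:
    def test_two_source_agreement_worked_example(self):
        frame = Frame((0.0, 1.0, 2.0))
        m1 = MassFunction(frame, (0.6, 0.0), 0.4)
        m2 = MassFunction(frame, (0.5, 0.0), 0.5)
        combined = dempster_combine(m1, m2)
        assert combined.singleton_masses[0] == pytest.approx(0.8)
        assert combined.ignorance_mass == pytest.approx(0.2)
        assert combined.conflict == pytest.approx(0.0)

    def test_two_bin_conflict_worked_example(self):
        frame = Frame((0.0, 1.0, 2.0))
        m1 = MassFunction(frame, (0.6, 0.4), 0.0)
        m2 = MassFunction(frame, (0.5, 0.5), 0.0)
        combined = dempster_combine(m1, m2)
        assert combined.conflict == pytest.approx(0.5)
        assert combined.singleton_masses[0] == pytest.approx(0.6)
        assert combined.singleton_masses[1] == pytest.approx(0.4)

    def test_vacuous_mass_is_the_identity(self):
        frame = Frame(tuple(np.linspace(0, 3, 7)))
        mass = _random_mass(frame, np.random.default_rng(0))
        for combined in (dempster_combine(mass, vacuous_mass(frame)), dempster_combine(vacuous_mass(frame), mass)):
            np.testing.assert_allclose(combined.singleton_masses, mass.singleton_masses, atol=1e-12)
            assert combined.ignorance_mass == pytest.approx(mass.ignorance_mass, abs=1e-12)

    @pytest.mark.parametrize("n_bins", [2, 3, 4, 5, 6])
    def test_matches_brute_force_enumeration(self, n_bins):
        frame = Frame(tuple(np.linspace(0, 1, n_bins + 1)))
        rng = np.random.default_rng(n_bins)
        for _ in range(20):
            m1, m2 = _random_mass(frame, rng), _random_mass(frame, rng)
            combined = dempster_combine(m1, m2)
            oracle, conflict = _dempster_enumeration(m1, m2)
            assert combined.conflict == pytest.approx(conflict, abs=1e-12)
            theta = frozenset(range(n_bins))
            for i, m in enumerate(combined.singleton_masses):
                assert m == pytest.approx(oracle.get(frozenset([i]), 0.0), abs=1e-10)
            assert combined.ignorance_mass == pytest.approx(oracle.get(theta, 0.0), abs=1e-10)

    def test_commutative_and_associative(self):
        frame = Frame(tuple(np.linspace(0, 1, 6)))
        rng = np.random.default_rng(5)
        a, b, c = (_random_mass(frame, rng) for _ in range(3))
        ab = dempster_combine(a, b)
        ba = dempster_combine(b, a)
        np.testing.assert_allclose(ab.singleton_masses, ba.singleton_masses, atol=1e-12)
        abc = dempster_combine(dempster_combine(a, b), c)
        acb = dempster_combine(a, dempster_combine(b, c))
        np.testing.assert_allclose(abc.singleton_masses, acb.singleton_masses, atol=1e-10)
        assert abc.ignorance_mass == pytest.approx(acb.ignorance_mass, abs=1e-10)

    def test_total_conflict_raises(self):
        frame = Frame((0.0, 1.0, 2.0))
        m1 = MassFunction(frame, (1.0, 0.0), 0.0)
        m2 = MassFunction(frame, (0.0, 1.0), 0.0)
        with pytest.raises(TotalConflictError):
            dempster_combine(m1, m2)

    def test_mismatched_frames_rejected(self):
        m1 = MassFunction(Frame((0.0, 1.0, 2.0)), (0.5, 0.5), 0.0)
        m2 = MassFunction(Frame((0.0, 1.5, 3.0)), (0.5, 0.5), 0.0)
        with pytest.raises(ValueError):
            dempster_combine(m1, m2)


class TestBeliefPlausibility:
    frame = Frame(tuple(np.linspace(0.0, 2.0, 5)))  # 4 bins of width 0.5

    def test_whole_frame_is_certain(self):
        mass = _random_mass(self.frame, np.random.default_rng(1))
        bel, pl = bel_pl(mass, (0.0, 2.0))
        assert bel == pytest.approx(1.0) and pl == pytest.approx(1.0)

    def test_vacuous_mass_is_total_ignorance(self):
        bel, pl = bel_pl(vacuous_mass(self.frame), (0.5, 1.0))
        assert (bel, pl) == (0.0, 1.0)

    def test_single_bin_query_worked_example(self):
        mass = MassFunction(self.frame, (0.0, 0.0, 0.7, 0.0), 0.3)
        bel, pl = bel_pl(mass, (1.0, 1.5))  # exactly bin 3
        assert bel == pytest.approx(0.7) and pl == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_belief_never_exceeds_plausibility(self, seed):
        rng = np.random.default_rng(seed)
        mass = _random_mass(self.frame, rng)
        for _ in range(200):
            a, b = np.sort(rng.uniform(-0.5, 2.5, 2))
            bel, pl = bel_pl(mass, (a, b))
            assert bel <= pl + 1e-12


class TestPignistic:
    frame = Frame(tuple(np.linspace(0.0, 2.0, 5)))

    def test_point_mass_gives_bin_center(self):
        mass = MassFunction(self.frame, (0.0, 1.0, 0.0, 0.0), 0.0)
        assert pignistic_predict(mass) == pytest.approx(0.75)

    def test_vacuous_gives_mean_of_centers(self):
        assert pignistic_predict(vacuous_mass(self.frame)) == pytest.approx(1.0)

    def test_estimate_stays_inside_the_frame(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            est = pignistic_predict(_random_mass(self.frame, rng))
            assert 0.0 <= est <= 2.0

    def test_agreeing_sharp_sources_converge_with_bin_refinement(self):
        target = 1.234
        errors = []
        for n_bins in (10, 40, 160):
            frame = Frame(tuple(np.linspace(0, 3, n_bins + 1)))
            m1 = build_mass_function(target, 0.05, 0.95, frame)
            m2 = build_mass_function(target, 0.05, 0.95, frame)
            errors.append(abs(pignistic_predict(dempster_combine(m1, m2)) - target))
        assert errors[-1] < errors[0]
        assert errors[-1] <= 3.0 / 160  # within one refined bin width


class TestDstPredict:
    def test_agreement_case_recovers_the_shared_prediction(self):
        frame = Frame(tuple(np.linspace(0, 3, 21)))
        center = frame.centers[7]
        fused = dst_predict([[center, center]], Reliability((0.9, 0.9)), (0.1, 0.1), frame)
        assert abs(fused[0].estimate - center) <= (3.0 / 20) / 2

    def test_vacuous_member_is_neutral(self):
        frame = Frame(tuple(np.linspace(0, 3, 21)))
        fused = dst_predict([[1.0, 9.9]], Reliability((0.999, 0.0)), (0.1, 0.1), frame)
        solo = build_mass_function(1.0, 0.1, 0.999, frame)
        assert fused[0].estimate == pytest.approx(pignistic_predict(solo), abs=1e-9)

    def test_fused_error_tracks_the_best_member_on_the_fixture(self, noiseless_dataset):
        split = split_train_test(noiseless_dataset, 0.2, seed=4)
        y_train, y_test = split.train.targets(), split.test.targets()
        members = [train_learner(DEFAULT_CONFIGS[k], split.train) for k in LearnerKind]
        P_test = np.column_stack([predict_learner(m, split.test) for m in members])
        base_rmse = [float(np.sqrt(np.mean((P_test[:, j] - y_test) ** 2))) for j in range(2)]
        frame = Frame.from_targets(y_train)
        rel = reliability_from_rmse(base_rmse, float(y_train.std(ddof=0)))
        fused = dst_predict(P_test, rel, [max(r, 0.01) for r in base_rmse], frame)
        fused_rmse = float(np.sqrt(np.mean((np.array([f.estimate for f in fused]) - y_test) ** 2)))
        bin_width = frame.edges[1] - frame.edges[0]
        assert fused_rmse <= 1.2 * min(base_rmse) + bin_width
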