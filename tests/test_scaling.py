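"""Choice matrices, the adapted MLDS fit, match interpolation, and the CCI."""

import numpy as np
import pytest

from constancy import scaling as sca
from constancy import scenes as sc

POSITIONS = {n: sc.COMPETITOR_POSITIONS[n] for n in sca.AXIS_ORDER}


class TestChoiceMatrix:
    def test_deterministic_r_chooser(self):
        trials = [sca.TrialRecord(presented=sca.AXIS_ORDER, chosen="R")
                  for _ in range(10)]
        cm = sca.build_choice_matrix(trials)
        i = cm.names.index("R")
        p = cm.proportions
        off = np.arange(len(cm.names)) != i
        assert np.all(p[i, off] == 1.0)
        assert np.all(p[off, i] == 0.0)

    def test_single_trial_counting(self):
        cm = sca.build_choice_matrix(
            [sca.TrialRecord(presented=sca.AXIS_ORDER, chosen="S1")])
        i = cm.names.index("S1")
        assert cm.wins[i].sum() == 4
        others = [k for k in range(5) if k != i]
        assert cm.counts[np.ix_(others, others)].sum() == 0

    def test_complement_property(self):
        for seed in range(5):
            trials = sca.simulate_observer(POSITIONS, 0.6, n_trials=80, seed=seed)
            cm = sca.build_choice_matrix(trials)
            p, c = cm.proportions, cm.counts
            for i in range(5):
                for j in range(i + 1, 5):
                    if c[i, j] > 0:
                        assert p[i, j] + p[j, i] == pytest.approx(1.0)

    def test_chosen_must_be_presented(self):
        with pytest.raises(ValueError):
            sca.TrialRecord(presented=("R", "T"), chosen="S1")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sca.build_choice_matrix([])


class TestSimulateObserver:
    def test_noiseless_limit(self):
        trials = sca.simulate_observer(POSITIONS, 0.70, noise_sd=1e-12,
                                       n_trials=50, seed=1)
        # 0.70 is nearest to S2 at 2/3.
        assert all(t.chosen == "S2" for t in trials)

    def test_seed_determinism(self):
        a = sca.simulate_observer(POSITIONS, 0.5, n_trials=40, seed=7)
        b = sca.simulate_observer(POSITIONS, 0.5, n_trials=40, seed=7)
        assert [t.chosen for t in a] == [t.chosen for t in b]

    def test_symmetric_flankers_chosen_equally(self):
        # Match exactly midway between S1 and S2, far from everything else:
        # the two flankers split the choices within binomial error.
        pos = {"T": -10.0, "S1": 1.0 / 3, "S2": 2.0 / 3, "R": 10.0, "O": 11.0}
        trials = sca.simulate_observer(pos, 0.5, n_trials=4000, seed=3)
        n_s1 = sum(t.chosen == "S1" for t in trials)
        n_s2 = sum(t.chosen == "S2" for t in trials)
        assert n_s1 + n_s2 == 4000
        assert abs(n_s1 - 2000) < 3 * np.sqrt(4000 * 0.25)


class TestFitMLDS:
    def test_recovery_large_n(self, competitors_blue):
        # Five selection frequencies carry four degrees of freedom, so the
        # five scale parameters are identified only up to a likelihood
        # ridge; what the procedure pins down — and what the index uses —
        # is the match relative to its flanking competitors. At n = 2000
        # the CCI recovered through the Lab interpolation is tight.
        trials = sca.simulate_observer(POSITIONS, 0.55, n_trials=2000, seed=11)
        cm = sca.build_choice_matrix(trials)
        scale = sca.fit_mlds(cm, seed=0)
        match_lab = sca.map_match_to_lab(scale, competitors_blue)
        cci = sca.compute_cci(match_lab, competitors_blue)
        assert cci == pytest.approx(55.0, abs=3.0)
        # The match must sit between the same flankers as the truth.
        assert scale.position_of("S1") < scale.match < scale.position_of("S2")

    def test_ml_dominance(self):
        trials = sca.simulate_observer(POSITIONS, 0.8, n_trials=300, seed=5)
        cm = sca.build_choice_matrix(trials)
        scale = sca.fit_mlds(cm, seed=0)
        nodes, weights = np.polynomial.hermite.hermgauss(48)
        n_chosen = cm.wins[np.ix_([cm.names.index(n) for n in sca.AXIS_ORDER],
                                  [cm.names.index(n) for n in sca.AXIS_ORDER])
                           ].sum(axis=1) / 4
        truth_nll = sca._neg_log_likelihood(
            np.array([1 / 3, 1 / 3, 1 / 3, 1 / 3, 0.8]),
            n_chosen, sca.NOISE_SD, nodes, weights)
        assert scale.log_likelihood >= -truth_nll - 1e-6

    def test_always_r_chooser_pushes_match_to_r(self):
        trials = [sca.TrialRecord(presented=sca.AXIS_ORDER, chosen="R")
                  for _ in range(100)]
        scale = sca.fit_mlds(sca.build_choice_matrix(trials), seed=0)
        assert scale.match >= scale.position_of("R") - 1e-6

    def test_constraints_respected(self):
        trials = sca.simulate_observer(POSITIONS, 0.4, n_trials=100, seed=9)
        scale = sca.fit_mlds(sca.build_choice_matrix(trials), seed=0)
        assert scale.position_of("T") == 0.0
        assert np.all(np.diff(scale.positions) >= sca.MIN_GAP - 1e-12)

    def test_uninformative_matrix_flagged(self):
        rng = np.random.default_rng(0)
        trials = [sca.TrialRecord(presented=sca.AXIS_ORDER,
                                  chosen=sca.AXIS_ORDER[rng.integers(5)])
                  for _ in range(500)]
        scale = sca.fit_mlds(sca.build_choice_matrix(trials), seed=0)
        assert scale.low_confidence


class TestMapMatchToLab:
    def _scale(self, match):
        return sca.PerceptualScale(
            names=sca.AXIS_ORDER,
            positions=np.array([0.0, 1 / 3, 2 / 3, 1.0, 4 / 3]),
            match=match, log_likelihood=0.0)

    def test_match_on_competitor(self, competitors_blue):
        lab = sca.map_match_to_lab(self._scale(1 / 3), competitors_blue)
        assert np.allclose(lab, competitors_blue.labs["S1"])

    def test_match_midway(self, competitors_blue):
        lab = sca.map_match_to_lab(self._scale(0.5), competitors_blue)
        mid = (competitors_blue.labs["S1"] + competitors_blue.labs["S2"]) / 2
        assert np.allclose(lab, mid)

    def test_arbitrary_ratio_on_first_segment(self, competitors_blue):
        r = 0.37
        lab = sca.map_match_to_lab(self._scale(r * (1 / 3)), competitors_blue)
        T, S1 = competitors_blue.labs["T"], competitors_blue.labs["S1"]
        assert np.allclose(lab, T + r * (S1 - T))


class TestCCI:
    @pytest.mark.parametrize("name,expected", [
        ("R", 100.0), ("T", 0.0), ("O", 400.0 / 3.0),
    ])
    def test_anchor_values(self, name, expected, competitors_blue):
        got = sca.compute_cci(competitors_blue.labs[name], competitors_blue)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_midpoint(self, competitors_blue):
        mid = (competitors_blue.labs["R"] + competitors_blue.labs["T"]) / 2
        assert sca.compute_cci(mid, competitors_blue) == pytest.approx(50.0)

    def test_degenerate_flagged(self, illuminants, neutral):
        comp = sc.make_competitor_set(0.35, neutral, neutral)
        with pytest.raises(ValueError):
            sca.compute_cci(comp.labs["R"], comp)

    def test_similarity_invariance(self, competitors_blue, rng):
        # Rotation + uniform scale + translation applied jointly to Match,
        # T and R leaves the index unchanged.
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        s, t = 2.7, rng.normal(size=3) * 10
        match = competitors_blue.labs["S2"]
        import copy

        comp2 = copy.deepcopy(competitors_blue)
        for k in comp2.labs:
            comp2.labs[k] = s * (q @ comp2.labs[k]) + t
        a = sca.compute_cci(match, competitors_blue)
        b = sca.compute_cci(s * (q @ match) + t, comp2)
        assert a == pytest.approx(b, rel=1e-9)


class TestVariability:
    def test_identical_participants(self):
        v = np.array([50.0, 60.0, 80.0, 40.0])
        inter, intra = sca.variability_stats({"a": v, "b": v, "c": v})
        assert all(x == pytest.approx(1.0) for x in inter.values())

    def test_constant_participant_cv_zero(self):
        inter, intra = sca.variability_stats(
            {"a": np.array([50.0, 50.0, 50.0]), "b": np.array([40.0, 60.0, 55.0])})
        assert intra["a"] == pytest.approx(0.0)

    def test_anticorrelated_pair_negative(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        inter, _ = sca.variability_stats({"a": x, "b": -x + 100, "c": x + 5})
        assert inter["b"] < 0
        expected = np.corrcoef(-x + 100, (x + (x + 5)) / 2)[0, 1]
        assert inter["b"] == pytest.approx(expected)
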