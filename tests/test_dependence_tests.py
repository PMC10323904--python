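import itertools

import numpy as np
import pytest

from p53lnc.dependence_tests import (
    POCKET_GENOTYPES,
    TpmExperiment,
    classify_p21_dependence,
    classify_pocket_dependence,
    p21_dependence_table,
    ttest_two_sided,
)
from p53lnc.synthetic_data import simulate_tpm_experiment


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        res = ttest_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_hand_computed_pooled_statistic(self):
        # closed form: sp2 = 1, se = sqrt(2/3), t = -3/se
        res = ttest_two_sided([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0213, abs=1e-4)

    def test_translation_invariance(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=4)
        r1 = ttest_two_sided(a, b)
        r2 = ttest_two_sided(a + 7.3, b + 7.3)
        assert r1.t == pytest.approx(r2.t)

    def test_degenerate_zero_variance_cases(self):
        res = ttest_two_sided([2.0, 2.0], [5.0, 5.0])
        assert res.p == 0.0 and res.degenerate
        with pytest.raises(ValueError):
            ttest_two_sided([1.0], [1.0, 2.0])

    def test_sign_decision_matches_permutation_test_under_null(self, rng):
        # calibration: the t decision at alpha=0.05 agrees with a
        # permutation test on >= 95% of null draws
        agree = 0
        n_trials = 200
        for _ in range(n_trials):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            t_sig = ttest_two_sided(a, b).p < 0.05
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = total = 0
            for idx in itertools.combinations(range(8), 4):
                sel = np.zeros(8, dtype=bool)
                sel[list(idx)] = True
                d = abs(pooled[sel].mean() - pooled[~sel].mean())
                total += 1
                count += d >= obs - 1e-12
            perm_sig = count / total < 0.05
            agree += t_sig == perm_sig
        assert agree / n_trials >= 0.95


def _exp(gene, control, treated):
    return TpmExperiment(gene, np.asarray(control, float), np.asarray(treated, float))


def _arm(mean_log2, n=3):
    # zero-variance-free deterministic arms around a log2 level
    return [2 ** (mean_log2 + d) - 1 for d in (-0.05, 0.0, 0.05)][:n]


class TestP21Dependence:
    def test_repression_failing_in_knockout_is_dependent(self):
        parental = _exp("G", _arm(6.0), _arm(4.0))   # -2 log2, significant
        knockout = _exp("G", _arm(6.0), _arm(6.02))  # ns
        assert classify_p21_dependence(parental, knockout).call == "p21_dependent"

    def test_no_parental_repression_is_not_dependent(self):
        parental = _exp("G", _arm(6.0), _arm(6.01))
        knockout = _exp("G", _arm(6.0), _arm(4.0))
        call = classify_p21_dependence(parental, knockout)
        assert call.call == "not_p21_dependent"
        assert "parental" in call.reason

    def test_retained_knockout_repression_is_not_dependent(self):
        parental = _exp("G", _arm(6.0), _arm(4.0))
        knockout = _exp("G", _arm(6.0), _arm(4.1))  # -1.9 log2, significant
        assert classify_p21_dependence(parental, knockout).call == "not_p21_dependent"

    def test_halved_magnitude_counts_as_failure_even_if_significant(self):
        parental = _exp("G", _arm(6.0), _arm(4.0))    # -2
        knockout = _exp("G", _arm(6.0), _arm(5.2))    # -0.8 < half of 2
        assert classify_p21_dependence(parental, knockout).call == "p21_dependent"

    def test_missing_arm_is_untestable(self):
        parental = _exp("G", _arm(6.0), _arm(4.0))
        assert classify_p21_dependence(parental, None).call == "untestable"

    def test_rule_table_enumeration(self):
        # call is a pure function of (parental repressed, ko repressed,
        # ko magnitude >= half parental)
        for par_rep, ko_rep, ko_big in itertools.product([0, 1], repeat=3):
            parental = _exp("G", _arm(6.0), _arm(4.0) if par_rep else _arm(6.01))
            ko_level = (4.2 if ko_big else 5.4) if ko_rep else 6.01
            knockout = _exp("G", _arm(6.0), _arm(ko_level))
            expected = (
                "p21_dependent"
                if par_rep and not (ko_rep and ko_big)
                else "not_p21_dependent"
            )
            assert classify_p21_dependence(parental, knockout).call == expected

    def test_planted_sensitivity_and_null_fpr(self):
        classes = {f"P{i}": "p21_dependent" for i in range(40)}
        classes.update({f"N{i}": "null" for i in range(40)})
        tpm, sheet = simulate_tpm_experiment(classes, "p21", effect_log2=2.0,
                                             noise_sd=0.2, seed=5)
        table = p21_dependence_table(tpm, sheet, list(classes))
        planted = table.loc[[g for g in classes if g.startswith("P")], "call"]
        nulls = table.loc[[g for g in classes if g.startswith("N")], "call"]
        assert (planted == "p21_dependent").mean() >= 0.9
        assert (nulls == "p21_dependent").mean() <= 0.10  # ~alpha + MC error


def _pocket(par=True, rb=True, dream=True, triple=True):
    """Experiments with repression present/absent per genotype."""
    exps = {}
    for genotype, rep in zip(POCKET_GENOTYPES, (par, rb, dream, triple)):
        exps[genotype] = _exp("G", _arm(6.0), _arm(4.0) if rep else _arm(6.01))
    return exps


class TestPocketDependence:
    def test_rb_predominant_pattern(self):
        call = classify_pocket_dependence(_pocket(rb=False, triple=False))
        assert call.call == "RB_predominant"

    def test_dream_predominant_pattern(self):
        call = classify_pocket_dependence(_pocket(dream=False, triple=False))
        assert call.call == "DREAM_predominant"

    def test_cooperative_pattern(self):
        assert classify_pocket_dependence(_pocket(triple=False)).call == "cooperative"

    def test_all_repressed_is_unresolved(self):
        assert classify_pocket_dependence(_pocket()).call == "unresolved"

    def test_no_parental_repression_is_not_detected(self):
        assert classify_pocket_dependence(_pocket(par=False)).call == "not_detected"

    def test_below_detection_floor_is_not_detected(self):
        exps = _pocket(rb=False, triple=False)
        low = {g: TpmExperiment("G", e.control * 1e-3, e.treated * 1e-3)
               for g, e in exps.items()}
        assert classify_pocket_dependence(low).call == "not_detected"

    def test_missing_genotype_is_unresolved_with_reason(self):
        exps = _pocket(rb=False, triple=False)
        exps["rb_depleted"] = None
        call = classify_pocket_dependence(exps)
        assert call.call == "unresolved"
        assert "rb_depleted" in call.reason

    def test_exhaustive_truth_table(self):
        # every 2^4 repression pattern maps to the independently coded rule
        for par, rb, dream, triple in itertools.product([0, 1], repeat=4):
            call = classify_pocket_dependence(
                _pocket(bool(par), bool(rb), bool(dream), bool(triple))
            ).call
            if not par:
                expected = "not_detected"
            elif triple:
                expected = "unresolved"
            elif not rb and dream:
                expected = "RB_predominant"
            elif rb and not dream:
                expected = "DREAM_predominant"
            elif rb and dream:
                expected = "cooperative"
            else:
                expected = "unresolved"
            assert call == expected, (par, rb, dream, triple)
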