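"""Design rows, log-odds, and the complete-data log-likelihood vs naive oracles."""

import math

import numpy as np
import pytest

from lbltvc import (Diplotype, FrequencyModel, ParameterState, SplineBasis,
                    build_design_row, complete_data_loglik, log_odds)
from lbltvc.haplotypes import diplotype_probability
from lbltvc.likelihood import ModelData, hap_copy_vector

BASIS = SplineBasis()


def make_params(rng, m, n_basis=6, beta0=None):
    f = rng.dirichlet(np.ones(m))
    return ParameterState(
        beta0=float(rng.normal()) if beta0 is None else beta0,
        spline_coeffs=rng.normal(size=(m - 1, n_basis)),
        beta_smoke=float(rng.normal()),
        beta_interaction=rng.normal(size=m - 1),
        beta_sex=float(rng.normal()),
        freq_model=FrequencyModel([f"H{i}" for i in range(m)], f, d=0.0))


def make_data(rng, n_indiv, max_exams=3):
    exams = rng.integers(1, max_exams + 1, size=n_indiv)
    indiv = np.repeat(np.arange(n_indiv), exams)
    N = indiv.size
    return ModelData(y=rng.integers(0, 2, N).astype(float),
                     smoke=rng.integers(0, 2, N).astype(float),
                     sex=rng.integers(0, 2, N).astype(float),
                     age=rng.uniform(25, 95, N), indiv=indiv,
                     n_indiv=n_indiv, basis=BASIS)


class TestDesignRow:
    def test_reference_homozygote_is_all_zero(self):
        x = hap_copy_vector(Diplotype(1, 1), m=4, reference=1)
        np.testing.assert_array_equal(x, [0, 0, 0])

    def test_single_copy_and_interaction(self, rng):
        fm = FrequencyModel(["H0", "H1", "H2", "H3"],
                            [0.4, 0.3, 0.2, 0.1], d=0.0)
        row = build_design_row(Diplotype(0, 3), {"smoke": 1, "sex": 0,
                                                 "age": 50.0}, fm, reference=0)
        np.testing.assert_array_equal(row.hap_copies, [0, 0, 1])
        np.testing.assert_array_equal(row.interaction, [0, 0, 1])

    def test_homozygote_two_copies_no_smoking(self):
        fm = FrequencyModel(["H0", "H1", "H2"], [0.5, 0.3, 0.2], d=0.0)
        row = build_design_row(Diplotype(2, 2), {"smoke": 0, "sex": 1,
                                                 "age": 60.0}, fm, reference=0)
        np.testing.assert_array_equal(row.hap_copies, [0, 2])
        np.testing.assert_array_equal(row.interaction, [0, 0])

    def test_total_copies_always_two(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 6))
            k, kp = sorted(rng.integers(0, m, 2))
            ref = int(rng.integers(0, m))
            x = hap_copy_vector(Diplotype(int(k), int(kp)), m, ref)
            ref_copies = 2 - x.sum()
            assert x.sum() + ref_copies == 2 and np.all(x >= 0)


class TestLogOdds:
    def test_all_zero_parameters(self, rng):
        p = make_params(rng, 3)
        p.beta0, p.beta_smoke, p.beta_sex = 0.0, 0.0, 0.0
        p.spline_coeffs[:] = 0
        p.beta_interaction[:] = 0
        row = build_design_row(Diplotype(0, 1), {"smoke": 1, "sex": 1,
                                                 "age": 44.0},
                               p.freq_model, reference=0)
        assert log_odds(p, row, BASIS) == 0.0

    def test_intercept_only(self, rng):
        p = make_params(rng, 3, beta0=-1.0)
        p.beta_smoke, p.beta_sex = 0.0, 0.0
        p.spline_coeffs[:] = 0
        p.beta_interaction[:] = 0
        row = build_design_row(Diplotype(1, 2), {"smoke": 1, "sex": 1,
                                                 "age": 70.0},
                               p.freq_model, reference=0)
        assert log_odds(p, row, BASIS) == pytest.approx(-1.0)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 6))
            p = make_params(rng, m)
            k, kp = sorted(rng.integers(0, m, 2))
            exam = {"smoke": int(rng.integers(0, 2)),
                    "sex": int(rng.integers(0, 2)),
                    "age": float(rng.uniform(20, 100))}
            ref = int(rng.integers(0, m))
            row = build_design_row(Diplotype(int(k), int(kp)), exam,
                                   p.freq_model, ref)
            b = BASIS.evaluate(exam["age"])
            expected = p.beta0 + p.beta_smoke * exam["smoke"] \
                + p.beta_sex * exam["sex"]
            for h in range(m - 1):
                expected += row.hap_copies[h] * float(b @ p.spline_coeffs[h])
                expected += p.beta_interaction[h] * row.hap_copies[h] \
                    * exam["smoke"]
            assert log_odds(p, row, BASIS) == pytest.approx(expected,
                                                            abs=1e-12)


def naive_loglik(params, data, assignment, reference):
    """Per-record Bernoulli + diplotype-probability oracle."""
    total = 0.0
    for r in range(data.y.size):
        dip = assignment[data.indiv[r]]
        row = build_design_row(dip, {"smoke": data.smoke[r],
                                     "sex": data.sex[r],
                                     "age": data.age[r]},
                               params.freq_model, reference)
        eta = log_odds(params, row, data.basis)
        pr = 1.0 / (1.0 + math.exp(-eta))
        total += math.log(pr if data.y[r] == 1 else 1 - pr)
    for dip in assignment:
        total += math.log(diplotype_probability(params.freq_model, dip))
    return total


class TestCompleteDataLoglik:
    def test_single_record_closed_form(self):
        """m=1 (reference only), all betas 0: log(1/2) + log P(Z) = log(1/2)."""
        fm = FrequencyModel(["H0"], [1.0], d=0.0)
        p = ParameterState(beta0=0.0, spline_coeffs=np.zeros((0, 6)),
                           beta_smoke=0.0, beta_interaction=np.zeros(0),
                           beta_sex=0.0, freq_model=fm)
        data = ModelData(y=np.array([1.0]), smoke=np.array([0.0]),
                         sex=np.array([0.0]), age=np.array([50.0]),
                         indiv=np.array([0]), n_indiv=1, basis=BASIS)
        got = complete_data_loglik(p, data, [Diplotype(0, 0)], reference=0)
        assert got == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_naive_oracle_on_random_fixtures(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 5))
            params = make_params(rng, m)
            data = make_data(rng, int(rng.integers(1, 6)))
            assignment = [Diplotype(*sorted(map(int, rng.integers(0, m, 2))))
                          for _ in range(data.n_indiv)]
            got = complete_data_loglik(params, data, assignment, reference=0)
            want = naive_loglik(params, data, assignment, reference=0)
            assert got == pytest.approx(want, abs=1e-10)

    def test_duplicated_cohort_doubles_phenotype_term(self, rng):
        m = 3
        params = make_params(rng, m)
        data = make_data(rng, 4)
        assignment = [Diplotype(0, 1)] * 4
        ll1 = complete_data_loglik(params, data, assignment, reference=0)
        data2 = ModelData(y=np.tile(data.y, 2), smoke=np.tile(data.smoke, 2),
                          sex=np.tile(data.sex, 2), age=np.tile(data.age, 2),
                          indiv=np.concatenate([data.indiv, data.indiv + 4]),
                          n_indiv=8, basis=BASIS)
        ll2 = complete_data_loglik(params, data2, assignment * 2, reference=0)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-9)

    def test_invariant_to_individual_ordering(self, rng):
        m = 3
        params = make_params(rng, m)
        data = make_data(rng, 5, max_exams=1)
        assignment = [Diplotype(*sorted(map(int, rng.integers(0, m, 2))))
                      for _ in range(5)]
        perm = rng.permutation(5)
        data_p = ModelData(y=data.y[perm], smoke=data.smoke[perm],
                           sex=data.sex[perm], age=data.age[perm],
                           indiv=np.arange(5), n_indiv=5, basis=BASIS)
        ll = complete_data_loglik(params, data, assignment, reference=0)
        ll_p = complete_data_loglik(params, data_p,
                                    [assignment[i] for i in perm], reference=0)
        assert ll_p == pytest.approx(ll, abs=1e-10)

    def test_assignment_outside_support_rejected(self, rng):
        params = make_params(rng, 3)
        data = make_data(rng, 1, max_exams=1)
        with pytest.raises(ValueError, match="support"):
            complete_data_loglik(params, data, [Diplotype(0, 2)], reference=0,
                                 supports=[[Diplotype(0, 1)]])

    def test_monotone_in_intercept_for_all_affected(self, rng):
        params = make_params(rng, 2)
        data = make_data(rng, 6)
        data.y[:] = 1.0
        assignment = [Diplotype(0, 1)] * 6
        lls = []
        for b0 in (-1.0, 0.0, 1.0, 2.0):
            params.beta0 = b0
            lls.append(complete_data_loglik(params, data, assignment,
                                            reference=0))
        assert np.all(np.diff(lls) > 0)
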