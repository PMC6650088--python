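import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import comb

from tci.engine import (
    EdgeCounts,
    a0_loglik,
    compute_scores,
    edge_counts,
    edge_loglik,
    infer_cohort,
    infer_tumor_model,
)
from tci.priors import cohort_priors
from tci.types import A0, BinaryEventMatrix, Cohort

from conftest import make_cohort


class TestEdgeCounts:
    def test_enumerated_cross_tab(self):
        c = edge_counts(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (c.n11, c.n10, c.n01, c.n00) == (1, 1, 1, 1)

    def test_all_zero_vectors(self):
        c = edge_counts(np.zeros(4), np.zeros(4))
        assert (c.n11, c.n10, c.n01, c.n00) == (0, 0, 0, 4)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            s = rng.integers(0, 2, 30)
            e = rng.integers(0, 2, 30)
            c = edge_counts(s, e)
            brute = {(1, 1): 0, (1, 0): 0, (0, 1): 0, (0, 0): 0}
            for a, b in zip(s, e):
                brute[(a, b)] += 1
            assert (c.n11, c.n10, c.n01, c.n00) == (
                brute[(1, 1)], brute[(1, 0)], brute[(0, 1)], brute[(0, 0)]
            )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            edge_counts(np.zeros(3), np.zeros(4))


def quadrature_stratum(k, n):
    """∫ θ^k (1−θ)^(n−k) dθ by numerical quadrature (Beta(1,1) prior)."""
    val, _ = integrate.quad(lambda t: t**k * (1 - t) ** (n - k), 0, 1, epsabs=1e-13)
    return val


class TestEdgeLoglik:
    def test_closed_form_example(self):
        # present stratum 3/4 positive, absent stratum 1/4: each term 0.05
        c = EdgeCounts(3, 1, 1, 3)
        assert edge_loglik(c) == pytest.approx(math.log(0.05 * 0.05), abs=1e-12)

    def test_empty_data_scores_zero(self):
        assert edge_loglik(EdgeCounts(0, 0, 0, 0)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EdgeCounts(-1, 0, 0, 0)

    def test_quadrature_agreement_sample(self):
        # full n<=12 enumeration lives in the acceptance suite; spot-check here
        for n11, n10, n01, n00 in [(3, 1, 1, 3), (0, 5, 2, 2), (4, 0, 0, 4), (2, 2, 2, 2)]:
            expected = math.log(
                quadrature_stratum(n11, n11 + n10) * quadrature_stratum(n01, n01 + n00)
            )
            assert edge_loglik(EdgeCounts(n11, n10, n01, n00)) == pytest.approx(
                expected, abs=1e-8
            )

    def test_a0_closed_form(self):
        col = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert a0_loglik(col) == pytest.approx(math.log(4 * 3 * 2 / (9 * 8 * 7 * 6 * 5)), abs=1e-12)

    def test_a0_empty_cohort_scores_zero(self):
        assert a0_loglik(np.array([])) == 0.0

    def test_split_model_beats_a0_for_associated_column(self):
        # spec's paired example: edge score 0.0025 > A0 score 0.0015873
        sga = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        deg = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        assert edge_loglik(edge_counts(sga, deg)) > a0_loglik(deg)

    def test_monotone_in_association_on_positive_tables(self):
        # shifting mass n10/n01 → n11/n00 (margins fixed) never lowers the
        # edge score once the table is non-negatively associated; enumerate
        # all tables with n <= 12
        for n in range(1, 13):
            for n11, n10, n01 in itertools.combinations_with_replacement(range(n + 1), 3):
                n00 = n - n11 - n10 - n01
                if n00 < 0 or n10 < 1 or n01 < 1:
                    continue
                if (n11 + 1) * (n00 + 1) < n10 * n01:
                    continue  # negatively associated: both directions explain variance
                before = edge_loglik(EdgeCounts(n11, n10, n01, n00))
                after = edge_loglik(EdgeCounts(n11 + 1, n10 - 1, n01 - 1, n00 + 1))
                assert after >= before - 1e-12


def naive_posteriors(sga, deg, theta0=0.1):
    """Reference implementation: no cache, no log-space, uniform prior.

    Direct products of Beta-function ratios per tumor and DEG; quadratic and
    numerically naive on purpose.
    """

    def beta_term(k, n):
        num = math.factorial(k) * math.factorial(n - k)
        return num / math.factorial(n + 1)

    n_t, n_s = sga.shape
    out = {}
    for t in range(n_t):
        hosted = [j for j in range(n_s) if sga[t, j]]
        m = len(hosted)
        for i in range(deg.shape[1]):
            if not deg[t, i]:
                continue
            col = deg[:, i]
            liks = []
            for j in hosted:
                mask = sga[:, j].astype(bool)
                liks.append(
                    beta_term(int(col[mask].sum()), int(mask.sum()))
                    * beta_term(int(col[~mask].sum()), int((~mask).sum()))
                )
            lik0 = beta_term(int(col.sum()), len(col))
            weights = [(1 - theta0) / m * l for l in liks] + [theta0 * lik0]
            z = sum(weights)
            out[(t, i)] = [w / z for w in weights]
    return out


class TestInference:
    def test_posterior_equals_prior_when_likelihoods_cancel(self):
        # one candidate SGA altered in every tumor: its stratum covers the
        # whole cohort but A0 integrates one Bernoulli while the edge pays no
        # split, so with a single tumor the scores coincide
        cohort = make_cohort([[1]], [[1]])
        priors = cohort_priors(cohort, "uniform")
        model = infer_cohort(cohort, priors)[0]
        assert model.assignments[0].cause == "A1"
        assert model.assignments[0].posterior == pytest.approx(0.9)

    def test_hand_evaluated_posterior(self):
        # θ=(0.1, 0.9), lik(A1)=0.0025, lik(A0)=0.0015873...
        lik1, lik0 = 0.05 * 0.05, 4 * 3 * 2 / (9 * 8 * 7 * 6 * 5)
        expected = 0.9 * lik1 / (0.9 * lik1 + 0.1 * lik0)
        sga = np.zeros((8, 1), dtype=int)
        sga[:4, 0] = 1
        deg = np.array([1, 1, 1, 0, 1, 0, 0, 0])[:, None]
        cohort = make_cohort(sga, deg)
        priors = cohort_priors(cohort, "uniform")
        model = infer_cohort(cohort, priors)[0]
        assert model.assignments[0].cause == "A1"
        assert model.assignments[0].posterior == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9341, abs=5e-5)

    def test_agrees_with_naive_brute_force(self, rng):
        # 3 SGAs, 4 DEGs, 10 tumors: log-space cached path vs direct products
        sga = (rng.random((10, 3)) < 0.5).astype(int)
        deg = (rng.random((10, 4)) < 0.5).astype(int)
        cohort = make_cohort(sga, deg)
        priors = cohort_priors(cohort, "uniform")
        models = infer_cohort(cohort, priors, keep_posteriors=True)
        naive = naive_posteriors(sga, deg)
        checked = 0
        for t, model in enumerate(models):
            hosted = [f"A{j + 1}" for j in range(3) if sga[t, j]]
            for a in model.assignments:
                i = int(a.deg[1:]) - 1
                ref = naive[(t, i)]
                ref_by_cause = dict(zip(hosted + [A0], ref))
                for cause, post in a.posterior_vector.items():
                    assert post == pytest.approx(ref_by_cause[cause], abs=1e-12)
                checked += 1
        assert checked > 0

    def test_posterior_vector_normalized(self, rng):
        sga = (rng.random((15, 4)) < 0.4).astype(int)
        deg = (rng.random((15, 5)) < 0.4).astype(int)
        cohort = make_cohort(sga, deg)
        models = infer_cohort(cohort, cohort_priors(cohort, "uniform"), keep_posteriors=True)
        for model in models:
            for a in model.assignments:
                assert sum(a.posterior_vector.values()) == pytest.approx(1.0, abs=1e-9)
                assert a.posterior_vector[a.cause] == pytest.approx(a.posterior)

    def test_cache_equivalence_and_determinism(self, rng):
        sga = (rng.random((12, 3)) < 0.5).astype(int)
        deg = (rng.random((12, 4)) < 0.5).astype(int)
        cohort = make_cohort(sga, deg)
        priors = cohort_priors(cohort, "uniform")
        scores = compute_scores(cohort.sga, cohort.deg)
        with_cache = infer_cohort(cohort, priors, scores=scores)
        without = infer_cohort(cohort, priors)
        for a, b in zip(with_cache, without):
            for x, y in zip(a.assignments, b.assignments):
                assert (x.cause, x.posterior) == (y.cause, y.posterior)

    def test_one_model_per_tumor(self, rng):
        cohort = make_cohort(
            (rng.random((9, 3)) < 0.5).astype(int), (rng.random((9, 3)) < 0.5).astype(int)
        )
        models = infer_cohort(cohort, cohort_priors(cohort, "uniform"))
        assert [m.tumor_id for m in models] == cohort.tumor_ids

    def test_zero_sga_tumor_assigns_everything_to_a0(self):
        cohort = make_cohort([[0, 0]], [[1, 1, 1]])
        model = infer_cohort(cohort, cohort_priors(cohort, "uniform"))[0]
        assert {a.cause for a in model.assignments} == {A0}
        assert all(a.posterior == 1.0 for a in model.assignments)

    def test_empty_deg_set_gives_empty_model(self):
        cohort = make_cohort([[1]], [[0]])
        model = infer_cohort(cohort, cohort_priors(cohort, "uniform"))[0]
        assert model.assignments == []

    def test_mutual_exclusivity_attribution(self):
        # two never-co-occurring SGAs drive the same DEG: each tumor's DEG is
        # attributed to whichever of the two that tumor hosts
        rng = np.random.default_rng(7)
        n = 60
        sga = np.zeros((n, 2), dtype=int)
        sga[:20, 0] = 1
        sga[20:40, 1] = 1
        deg = np.zeros((n, 1), dtype=int)
        deg[:40, 0] = rng.random(40) < 0.9
        deg[40:, 0] = rng.random(20) < 0.05
        cohort = make_cohort(sga, deg)
        models = infer_cohort(cohort, cohort_priors(cohort, "uniform"))
        for t, model in enumerate(models):
            for a in model.assignments:
                if t < 20:
                    assert a.cause == "A1"
                elif t < 40:
                    assert a.cause == "A2"
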