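"""Objective function and stochastic search machinery."""

import numpy as np
import pytest

from calbeta import (
    DoseParams,
    InjectionProtocol,
    ParamSpace,
    ScalingParams,
    fit_subset,
    generate_dose_response,
    make_objective,
    objective_err,
    random_search,
    random_walk_refine,
)


@pytest.fixture(scope="module")
def clean_dataset():
    """Noiseless single-dose synthetic recording from the large-dose truth."""
    truth = DoseParams.large_doses()
    ds = generate_dose_response(truth, InjectionProtocol(), (10.0,),
                                ScalingParams(), noise_sd=0.0, seed=5,
                                t_end=120.0)
    return truth, ds


class TestObjective:
    def test_zero_on_self_generated_data(self, clean_dataset):
        truth, ds = clean_dataset
        err = objective_err(ds.traces, truth, InjectionProtocol(),
                            ScalingParams(), rtol=1e-8, atol=1e-10)
        assert err < 1e-12

    def test_noise_sets_the_error_floor(self, clean_dataset, rng):
        # E[Err] = n sigma^2 for i.i.d. noise added to a perfect fit
        truth, ds = clean_dataset
        t, sed = ds.traces[10.0]
        sigma = 0.05
        errs = [objective_err((t, sed + sigma * rng.standard_normal(sed.size)),
                              truth, InjectionProtocol(a=10.0), ScalingParams(),
                              rtol=1e-8, atol=1e-10)
                for _ in range(20)]
        expected = t.size * sigma**2
        assert np.mean(errs) == pytest.approx(expected, rel=0.15)

    def test_invariant_to_data_reordering(self, clean_dataset, rng):
        truth, ds = clean_dataset
        t, sed = ds.traces[10.0]
        sed = sed + 0.01 * rng.standard_normal(sed.size)
        perm = rng.permutation(t.size)
        e1 = objective_err((t, sed), truth, InjectionProtocol(a=10.0),
                           ScalingParams())
        e2 = objective_err((t[perm], sed[perm]), truth,
                           InjectionProtocol(a=10.0), ScalingParams())
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_data_beyond_simulated_span_rejected(self, clean_dataset):
        truth, _ = clean_dataset
        with pytest.raises(ValueError, match="span"):
            objective_err((np.array([-5.0, 10.0]), np.zeros(2)), truth,
                          InjectionProtocol(a=10.0), ScalingParams())


def _quadratic_bowl(center):
    """Cheap analytic objective over (V_Q, k_a): minimum at the center."""
    def obj(params):
        return (np.log(params.V_Q / center["V_Q"]) ** 2
                + np.log(params.k_a / center["k_a"]) ** 2)
    return obj


class TestRandomSearch:
    def test_finds_quadratic_minimum(self, large):
        space = ParamSpace.default(large, ("V_Q", "k_a"))
        obj = _quadratic_bowl({"V_Q": large.V_Q, "k_a": large.k_a})
        coarse = random_search(space, obj, n_samples=20, threshold=-1.0, seed=3)
        fine = random_search(space, obj, n_samples=400, threshold=-1.0, seed=3)
        assert fine.best_err <= coarse.best_err
        assert fine.best_err < 0.05

    def test_deterministic_given_seed(self, large):
        space = ParamSpace.default(large, ("V_Q", "k_a"))
        obj = _quadratic_bowl({"V_Q": large.V_Q, "k_a": large.k_a})
        a = random_search(space, obj, n_samples=30, threshold=0.5, seed=11,
                          refine_steps=20)
        b = random_search(space, obj, n_samples=30, threshold=0.5, seed=11,
                          refine_steps=20)
        assert a.best_err == b.best_err
        assert a.best_params == b.best_params
        assert a.n_evaluated == b.n_evaluated

    def test_infinite_threshold_refines_every_sample(self, large):
        space = ParamSpace.default(large, ("V_Q",))
        obj = _quadratic_bowl({"V_Q": large.V_Q, "k_a": large.k_a})
        fit = random_search(space, obj, n_samples=3, threshold=np.inf,
                            seed=0, refine_steps=10)
        # every draw triggers a walk: 3 draws + 3 * 10 walk evaluations
        assert fit.n_evaluated == 3 + 3 * 10

    def test_sampling_respects_bounds(self, large, rng):
        space = ParamSpace.default(large, ("V_Q", "gamma"))
        for _ in range(200):
            s = space.sample(rng)
            assert large.V_Q / 5 <= s.V_Q <= large.V_Q * 5
            assert 0.5 * large.gamma <= s.gamma <= 1.5 * large.gamma


class TestRandomWalk:
    def test_error_sequence_non_increasing(self, large):
        obj = _quadratic_bowl({"V_Q": large.V_Q, "k_a": large.k_a})
        start = large.with_updates(V_Q=large.V_Q * 2.0, k_a=large.k_a * 0.5)
        fit = random_walk_refine(start, obj, ("V_Q", "k_a"), step_frac=0.1,
                                 n_steps=100, seed=2)
        errs = [e for e, _ in fit.history]
        assert all(b <= a for a, b in zip(errs, errs[1:]))
        assert fit.best_err < obj(start)

    def test_zero_step_returns_start(self, large):
        obj = _quadratic_bowl({"V_Q": large.V_Q, "k_a": large.k_a})
        start = large.with_updates(V_Q=large.V_Q * 2.0)
        fit = random_walk_refine(start, obj, ("V_Q",), step_frac=0.0,
                                 n_steps=50, seed=2)
        assert fit.best_params == start


class TestSubsetFits:
    def test_unknown_group_rejected(self, large):
        with pytest.raises(KeyError, match="unknown group"):
            fit_subset(("NotAGroup",), {}, large, InjectionProtocol(),
                       ScalingParams())

    def test_all_groups_equals_unrestricted_search(self, clean_dataset):
        truth, ds = clean_dataset
        groups = ("Cellular", "SERCA", "IP3Receptor", "IP3Model", "PLC",
                  "GProtein")
        sub = fit_subset(groups, ds.traces, truth, InjectionProtocol(),
                         ScalingParams(), n_samples=4, threshold=-1.0, seed=9)
        names = []
        from calbeta import PARAM_GROUPS
        for g in groups:
            names.extend(PARAM_GROUPS[g])
        space = ParamSpace(baseline=truth,
                           rules=ParamSpace.default(truth, tuple(names)).rules)
        direct = random_search(space, make_objective(ds.traces,
                                                     InjectionProtocol(),
                                                     ScalingParams()),
                               n_samples=4, threshold=-1.0, seed=9)
        assert sub.best_err == direct.best_err
        assert sub.best_params == direct.best_params

    def test_frozen_groups_stay_at_baseline(self, clean_dataset):
        truth, ds = clean_dataset
        fit = fit_subset(("PLC",), ds.traces, truth, InjectionProtocol(),
                         ScalingParams(), n_samples=3, threshold=-1.0, seed=1)
        for nm in ("k_f", "V_s", "K1", "V_Q", "k_c"):  # outside the PLC group
            assert getattr(fit.best_params, nm) == getattr(truth, nm)
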