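import numpy as np
import pytest

from enumeration_oracle import enumerate_first_release
from stpsim import (ParameterError, SpikeTrain, analytic_first_release,
                    analytic_per_spike_release, constant_release,
                    empirical_first_release, error_report,
                    facilitation_release, first_release_error_surface,
                    make_exponential, make_rayleigh, mean_trajectory,
                    periodic_train, release_prob_sequence, release_stats,
                    sample_first_release_indices, simulate_am1,
                    simulate_trials_loop, steady_state_availability)

VARIANTS = ["am1_correct", "am2_correct", "am1_i11", "am1_i2", "am2_i1"]


def _scenarios():
    rng = np.random.default_rng(987654)
    trains = [periodic_train(10.0, 5),
              periodic_train(40.0, 6),
              SpikeTrain(np.sort(rng.uniform(0.02, 1.5, size=6)))]
    dists = [make_exponential(0.5), make_rayleigh(0.5)]
    models = [constant_release(0.6), facilitation_release(0.4, 0.2, 0.1)]
    for tr in trains:
        for d in dists:
            for rm in models:
                yield tr, d, rm


@pytest.mark.parametrize("variant", VARIANTS)
def test_enumeration_oracle_anchors_analytic_law(variant):
    """For K <= 6 spikes, exhaustive branch enumeration of each algorithm's
    coin tree reproduces the analytic first-release law to 1e-12."""
    for train, dist, rm in _scenarios():
        p_seq = release_prob_sequence(rm, train)
        probs, resid = enumerate_first_release(variant, train.times,
                                               dist.cdf, p_seq)
        exact = analytic_first_release(variant, train, dist, rm)
        assert np.abs(exact.probs - probs).max() < 1e-12
        assert abs(exact.residual - resid) < 1e-12


@pytest.mark.parametrize("variant", VARIANTS + ["am1_i12"])
def test_first_release_mass_is_conserved(variant):
    for train, dist, rm in _scenarios():
        fr = analytic_first_release(variant, train, dist, rm)
        assert np.all(fr.probs >= -1e-15)
        assert abs(fr.probs.sum() + fr.residual - 1.0) < 1e-12


def test_am1_equals_am2_for_exponential_law(p06):
    d = make_exponential(0.5)
    for f in (5.0, 20.0, 150.0):
        train = periodic_train(f, 20)
        a = analytic_first_release("am1_correct", train, d, p06)
        b = analytic_first_release("am2_correct", train, d, p06)
        assert np.abs(a.probs - b.probs).max() < 1e-12


def test_am1_differs_from_am2_for_rayleigh(ray05, p06, train_10hz_20):
    a = analytic_first_release("am1_correct", train_10hz_20, ray05, p06)
    b = analytic_first_release("am2_correct", train_10hz_20, ray05, p06)
    assert np.abs(a.probs - b.probs).max() > 0.01


def test_i12_alias_matches_i11(exp05, p06, train_10hz_20):
    a = analytic_first_release("am1_i11", train_10hz_20, exp05, p06)
    b = analytic_first_release("am1_i12", train_10hz_20, exp05, p06)
    assert np.array_equal(a.probs, b.probs)


def test_deterministic_first_spike_release(p06):
    """cdf ~ 1 over any positive time and P_r|a = 1: the first spike
    releases with certainty."""
    from stpsim import make_custom
    d = make_custom(1e-9, lambda y: (np.asarray(y) > 0).astype(float),
                    inverse_cdf=lambda u: 0.0)
    fr = analytic_first_release("am1_correct", periodic_train(10, 4), d,
                                constant_release(1.0))
    assert fr.probs[0] == pytest.approx(1.0)
    assert fr.residual == pytest.approx(0.0, abs=1e-15)


def test_first_release_eq6_at_spike_one(exp05, p06, train_10hz_20):
    fr = analytic_first_release("am1_correct", train_10hz_20, exp05, p06)
    assert fr.probs[0] == pytest.approx(0.6 * float(exp05.cdf(0.1)),
                                        abs=1e-15)


# ---------------------------------------------------------------------------
# marginal (no-stopping) per-spike release law
# ---------------------------------------------------------------------------

def test_per_spike_release_equals_mean_model(exp05, p06):
    train = periodic_train(10.0, 40)
    r = analytic_per_spike_release("am1_correct", train, 0.5, p06)
    mt = mean_trajectory(train, 0.5, 0.6, initial_availability=0.0)
    assert np.abs(r - 0.6 * mt.na_pre).max() < 1e-14
    # long-run limit: steady-state availability times P_r|a
    nss = steady_state_availability(10.0, 0.5, 0.6)
    assert r[-1] == pytest.approx(0.6 * nss, abs=1e-6)


def test_per_spike_release_zero_when_p_zero(train_10hz_20):
    r = analytic_per_spike_release("am1_correct", train_10hz_20, 0.5,
                                   constant_release(0.0))
    assert np.all(r == 0.0)


@pytest.mark.parametrize("variant,model", [
    ("am1_i11", "am1_i11"), ("am1_i2", "am1_i2"), ("am2_i1", "am2_i1"),
    ("am1_correct", "am1"),
])
def test_renewal_law_matches_simulation(variant, model, exp05, p06,
                                        train_10hz_20):
    """The renewal decomposition over last-release epochs reproduces each
    algorithm's simulated marginal release probabilities."""
    r = analytic_per_spike_release(variant, train_10hz_20, 0.5, p06)
    n = 8000
    counts = simulate_trials_loop(train_10hz_20, exp05, p06, n, 112,
                                  model=model, warn_incorrect=False)
    se = np.sqrt(np.clip(r * (1 - r), 1e-9, 1) / n)
    z = np.abs(counts.fraction_released - r) / se
    assert z.max() < 4.5


def test_per_spike_release_rejects_unknown_variant(train_10hz_20, p06):
    with pytest.raises(ParameterError):
        analytic_per_spike_release("bogus", train_10hz_20, 0.5, p06)


# ---------------------------------------------------------------------------
# error reports and release statistics
# ---------------------------------------------------------------------------

def test_error_report_identity_is_zero():
    x = np.random.default_rng(0).uniform(0.01, 0.9, size=(3, 4))
    rep = error_report(x, x)
    assert rep.max_abs_error() == 0.0
    assert rep.max_rel_error() == 0.0


def test_error_report_worked_example():
    """82% (flawed) vs 70% (correct) availability is a 0.12 absolute
    error."""
    rep = error_report(np.array([0.70]), np.array([0.82]))
    assert rep.max_abs_error() == pytest.approx(0.12)
    assert rep.max_rel_error() == pytest.approx(0.12 / 0.70)


def test_error_report_zero_reference_flagged():
    rep = error_report(np.array([0.0, 0.5]), np.array([0.1, 0.6]))
    t = rep.table
    assert not t.loc[t["correct_prob"] == 0.0, "rel_defined"].any()
    assert np.isnan(t.loc[~t["rel_defined"], "rel_error"]).all()
    assert rep.max_rel_error() == pytest.approx(0.2)


def test_error_report_shape_mismatch():
    with pytest.raises(ParameterError):
        error_report(np.zeros(3), np.zeros(4))


def test_error_surface_grid_layout(exp05):
    rep = first_release_error_surface("am1_i11", n_spikes=5,
                                      frequencies=[10.0, 20.0])
    t = rep.table
    assert len(t) == 10
    assert set(t["frequency"]) == {10.0, 20.0}
    # the flawed law is exact at the first spike: zero error for i = 1
    assert t.loc[t["spike_index"] == 1, "abs_error"].max() < 1e-15


def test_release_stats_from_trajectories(exp05, train_10hz_20):
    none = constant_release(0.0)
    trajs = [simulate_am1(train_10hz_20, exp05, none, s) for s in range(3)]
    st = release_stats(trajs)
    assert (st.mean, st.min, st.max) == (0.0, 0, 0)


def test_release_stats_truncates_at_h(exp05, p06, train_10hz_20):
    trajs = [simulate_am1(train_10hz_20, exp05, p06, s) for s in range(20)]
    st_all = release_stats(trajs)
    st_5 = release_stats(trajs, h_spikes=5)
    assert st_5.mean <= st_all.mean
    assert st_5.h_spikes == 5


def test_release_stats_from_loop_counts(exp05, p06, train_10hz_20):
    counts = simulate_trials_loop(train_10hz_20, exp05, p06, 300, 9,
                                  model="am1")
    st = release_stats(counts)
    assert st.mean == pytest.approx(counts.per_trial_totals.mean())
    with pytest.raises(ParameterError):
        release_stats(counts, h_spikes=5)
    with pytest.raises(ParameterError):
        release_stats([])


def test_empirical_first_release_counts():
    idx = np.array([1, 1, 2, 0, 3, 2])
    emp = empirical_first_release(idx, 3)
    assert emp.probs == pytest.approx(np.array([2, 2, 1]) / 6)
    assert emp.residual == pytest.approx(1 / 6)
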