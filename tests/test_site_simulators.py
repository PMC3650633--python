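import math

import numpy as np
import pytest

from stpsim import (ParameterError, SpikeTrain, TrajectoryInvariantError,
                    analytic_first_release, constant_release,
                    empirical_first_release, is_valid_trajectory,
                    make_custom, make_exponential, make_rayleigh,
                    periodic_train, sample_first_release_indices,
                    simulate_am1, simulate_am2, simulate_incorrect,
                    simulate_time_stepped, validate_trajectory)

CORRECT_RUNNERS = [
    ("am1:resample", lambda tr, d, rm, s: simulate_am1(
        tr, d, rm, s, variant="resample_at_release")),
    ("am1:conditional", lambda tr, d, rm, s: simulate_am1(
        tr, d, rm, s, variant="per_spike_conditional")),
    ("am1:poisson", lambda tr, d, rm, s: simulate_am1(
        tr, d, rm, s, variant="pregenerated_poisson")),
    ("am2", lambda tr, d, rm, s: simulate_am2(tr, d, rm, s)),
]


def _instant_dist():
    """Availability time identically ~0: cdf jumps to 1 at any t > 0."""
    return make_custom(1e-9, lambda y: (np.asarray(y) > 0).astype(float),
                       inverse_cdf=lambda u: 0.0)


@pytest.mark.parametrize("name,run", CORRECT_RUNNERS)
def test_no_release_possible_when_p_zero(name, run, exp05, train_10hz_20):
    traj = run(train_10hz_20, exp05, constant_release(0.0), 123)
    assert traj.n_releases == 0
    # availability switches on once and stays on
    a = traj.available_before_decision
    first_on = np.argmax(a) if a.any() else a.size
    assert np.all(a[first_on:])
    validate_trajectory(traj)


@pytest.mark.parametrize("name,run", CORRECT_RUNNERS[:2] +
                         CORRECT_RUNNERS[3:])
def test_deterministic_limit_releases_every_spike(name, run, train_10hz_20):
    traj = run(train_10hz_20, _instant_dist(), constant_release(1.0), 5)
    assert traj.n_releases == train_10hz_20.count
    assert np.all(traj.released)


def test_spike_exactly_at_availability_time_finds_vesicle():
    """A spike landing exactly on the scheduled availability instant sees
    the vesicle as available (>= comparison)."""
    # deterministic availability time of exactly 0.1 s
    d = make_custom(0.1, lambda y: (np.asarray(y) >= 0.1).astype(float),
                    inverse_cdf=lambda u: 0.1)
    traj = simulate_am1(periodic_train(10.0, 1), d, constant_release(1.0), 0)
    assert traj.released[0]


@pytest.mark.parametrize("name,run", CORRECT_RUNNERS)
def test_fixed_seed_bit_identical(name, run, exp05, p06, train_10hz_20):
    a = run(train_10hz_20, exp05, p06, 99)
    b = run(train_10hz_20, exp05, p06, 99)
    assert np.array_equal(a.released, b.released)
    assert np.array_equal(a.available_before_decision,
                          b.available_before_decision)
    assert a.draws_used == b.draws_used


@pytest.mark.parametrize("variant", ["am1_i11", "am1_i12", "am1_i2",
                                     "am2_i1"])
def test_incorrect_variants_deterministic_and_warn(variant, exp05, p06,
                                                   train_10hz_20):
    with pytest.warns(UserWarning, match="known-flawed"):
        a = simulate_incorrect(train_10hz_20, exp05, p06, 4, variant)
    b = simulate_incorrect(train_10hz_20, exp05, p06, 4, variant, warn=False)
    assert np.array_equal(a.released, b.released)


def test_unknown_variants_rejected(exp05, p06, train_10hz_20):
    with pytest.raises(ParameterError):
        simulate_am1(train_10hz_20, exp05, p06, 0, variant="nope")
    with pytest.raises(ParameterError):
        simulate_incorrect(train_10hz_20, exp05, p06, 0, "am3_i9",
                           warn=False)


def test_pregenerated_poisson_requires_exponential(ray05, p06,
                                                   train_10hz_20):
    with pytest.raises(ParameterError):
        simulate_am1(train_10hz_20, ray05, p06, 0,
                     variant="pregenerated_poisson")


@pytest.mark.parametrize("name,run", CORRECT_RUNNERS)
def test_correct_trajectories_satisfy_state_machine(name, run, exp05, p06,
                                                    train_10hz_20):
    for seed in range(40):
        validate_trajectory(run(train_10hz_20, exp05, p06, seed))


@pytest.mark.parametrize("variant", ["am1_i11", "am1_i12"])
def test_flawed_variants_fail_state_machine_validation(variant, exp05, p06,
                                                       train_10hz_20):
    """The implied availability of i11/i12 flips off without a release —
    exactly the conceptual error the validator is built to catch."""
    invalid = 0
    for seed in range(200):
        traj = simulate_incorrect(train_10hz_20, exp05, p06, seed, variant,
                                  warn=False)
        if not is_valid_trajectory(traj):
            invalid += 1
    assert invalid > 0


@pytest.mark.parametrize("variant", ["am1_i11", "am1_i12", "am1_i2",
                                     "am2_i1"])
def test_no_release_without_implied_availability(variant, exp05, p06,
                                                 train_10hz_20):
    for seed in range(50):
        traj = simulate_incorrect(train_10hz_20, exp05, p06, seed, variant,
                                  warn=False)
        assert not np.any(traj.released & ~traj.available_before_decision)


@pytest.mark.parametrize("model,oracle_variant,dist_name", [
    ("am1", "am1_correct", "exp"),
    ("am2", "am2_correct", "exp"),
    ("am1", "am1_correct", "ray"),
    ("am2", "am2_correct", "ray"),
    ("am1_i11", "am1_i11", "exp"),
    ("am1_i12", "am1_i11", "exp"),
    ("am1_i2", "am1_i2", "exp"),
    ("am2_i1", "am2_i1", "exp"),
])
def test_simulators_match_analytic_first_release(model, oracle_variant,
                                                 dist_name, exp05, ray05,
                                                 p06, train_10hz_20):
    """Every simulator's empirical first-release distribution sits inside
    simultaneous binomial bands around its exact analytic law."""
    d = exp05 if dist_name == "exp" else ray05
    n = 8000
    idx = sample_first_release_indices(train_10hz_20, d, p06, n, 314,
                                       model=model)
    emp = empirical_first_release(idx, train_10hz_20.count)
    exact = analytic_first_release(oracle_variant, train_10hz_20, d, p06)
    se = np.sqrt(exact.probs * (1 - exact.probs) / n)
    z = np.abs(emp.probs - exact.probs) / np.maximum(se, 1e-9)
    assert z.max() < 4.5


def test_worked_example_two_spike_availability(p06):
    """With refill CDF 0.4 then 0.7 anchored at the release, the flawed
    persistent-flag algorithm makes 42% of trials first-available at the
    second spike (the correct figure is 30%)."""
    tau = 1.0
    t1, t2 = -math.log(0.6), -math.log(0.3)  # F(t1)=0.4, F(t2)=0.7
    train = SpikeTrain(np.array([t1, t2]))
    d = make_exponential(tau)
    none = constant_release(0.0)
    n = 40_000
    first_avail = np.zeros(3)
    for seed in range(n):
        traj = simulate_incorrect(train, d, none, seed, "am1_i2", warn=False)
        a = traj.available_before_decision
        first_avail[np.argmax(a) + 1 if a.any() else 0] += 1
    frac1, frac2 = first_avail[1] / n, first_avail[2] / n
    se = 3 * math.sqrt(0.42 * 0.58 / n)
    assert abs(frac1 - 0.40) < se
    assert abs(frac2 - 0.42) < se           # flawed: should be 30%
    assert abs(frac1 + frac2 - 0.82) < se   # flawed: should be 70%


# ---------------------------------------------------------------------------
# time-stepped comparator
# ---------------------------------------------------------------------------

def test_time_stepped_parameter_guards(p06, train_10hz_20):
    with pytest.raises(ParameterError):
        simulate_time_stepped(train_10hz_20, 0.5, p06, dt=0.5, seed=0)
    with pytest.warns(UserWarning, match="coarse"):
        simulate_time_stepped(train_10hz_20, 0.5, p06, dt=0.02, seed=0)


def test_time_stepped_no_release_when_p_zero(train_10hz_20):
    traj = simulate_time_stepped(train_10hz_20, 0.5, constant_release(0.0),
                                 dt=0.001, seed=0)
    assert traj.n_releases == 0


def test_time_stepped_burns_many_more_draws(exp05, p06, train_10hz_20):
    """The per-step coin flip consumes orders of magnitude more uniforms
    than the single-draw-per-release event-driven algorithm."""
    ts = simulate_time_stepped(train_10hz_20, 0.5, p06, dt=0.0005, seed=8)
    ev = simulate_am1(train_10hz_20, exp05, p06, 8)
    assert ts.draws_used > 50 * ev.draws_used


def test_time_stepped_matches_analytic_law(p06, exp05, train_10hz_20):
    n = 6000
    idx = sample_first_release_indices(train_10hz_20, None, p06, n, 2718,
                                       model="time_stepped", tau_a=0.5,
                                       dt=0.0005)
    emp = empirical_first_release(idx, train_10hz_20.count)
    exact = analytic_first_release("am1_correct", train_10hz_20, exp05, p06)
    se = np.sqrt(exact.probs * (1 - exact.probs) / n)
    assert (np.abs(emp.probs - exact.probs) / np.maximum(se, 1e-9)).max() \
        < 4.5
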