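"""Boost machinery and Langevin propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gamdpipe as gp
from gamdpipe.config import KBT_310, ProtocolConfig
from gamdpipe.gamd import GaMDParams, PotentialStats, RunningStats


class Harmonic1D(gp.PotentialModel):
    n_dof = 1

    def __init__(self, k=3.0, center=0.0):
        self.k, self.center = k, center

    def components(self, x):
        d = float(x[0]) - self.center
        return 0.5 * self.k * d * d, 0.0, np.array([self.k * d]), np.zeros(1)

    def collective_variables(self, x):
        return np.asarray(x, float)[:1]

    def initial_configuration(self):
        return np.array([self.center])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_collect_statistics_population_sd():
    """Mean, extrema and the population SD of a hand-computable series."""
    s = gp.collect_statistics([10.0, 20.0, 30.0])
    assert (s.v_max, s.v_min, s.v_avg) == (30.0, 10.0, 20.0)
    assert s.sigma_v == pytest.approx(math.sqrt(200.0 / 3.0), abs=1e-12)


def test_collect_statistics_degenerate_and_empty():
    s = gp.collect_statistics([5.0, 5.0, 5.0])
    assert s.v_max == s.v_min == s.v_avg == 5.0 and s.sigma_v == 0.0
    with pytest.raises(ValueError):
        gp.collect_statistics([])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=30),
       st.lists(st.floats(-100, 100), min_size=1, max_size=30))
def test_running_extrema_never_decrease(first, second):
    """Appending more samples can only widen the running extrema."""
    rs = RunningStats()
    rs.update(np.array(first))
    vmax1, vmin1 = rs.v_max, rs.v_min
    rs.update(np.array(second))
    assert rs.v_max >= vmax1 and rs.v_min <= vmin1


# ---------------------------------------------------------------------------
# boost parameter determination
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("stats, sigma0, mode, k0, e, k", [
    # lower bound, k0 capped at 1: min(1, (6/5) * 100/20) = 1
    (dict(v_max=100, v_min=0, v_avg=80, sigma_v=5), 6.0, "lower", 1.0, 100.0, 0.01),
    # lower bound, k0 = (6/24) * (100/50) = 0.5
    (dict(v_max=100, v_min=0, v_avg=50, sigma_v=24), 6.0, "lower", 0.5, 100.0, 0.005),
    # upper bound, k0'' = (1 - 6/12) * (100/50) = 1, E = v_min + 1/k
    (dict(v_max=100, v_min=0, v_avg=50, sigma_v=12), 6.0, "upper", 1.0, 100.0, 0.01),
])
def test_boost_params_hand_examples(stats, sigma0, mode, k0, e, k):
    """Hand-evaluated parameter determinations for both threshold bounds."""
    p = gp.compute_boost_params(PotentialStats(n_samples=10, **stats),
                                sigma0, mode)
    assert p.k0 == pytest.approx(k0, abs=1e-12)
    assert p.threshold_e == pytest.approx(e, abs=1e-12)
    assert p.force_constant_k == pytest.approx(k, abs=1e-12)


def test_boost_params_upper_falls_back_to_lower():
    """When k0'' leaves (0, 1], the lower-bound formula is used instead."""
    stats = PotentialStats(v_max=100, v_min=0, v_avg=50, sigma_v=24, n_samples=9)
    p = gp.compute_boost_params(stats, 6.0, "upper")  # k0'' = 1.5 > 1
    assert p.bound_mode == "lower" and p.threshold_e == 100.0


def test_boost_params_degenerate_statistics():
    with pytest.raises(ValueError):
        gp.compute_boost_params(
            PotentialStats(v_max=5, v_min=5, v_avg=5, sigma_v=0, n_samples=3), 6.0)
    # zero sigma_v with a finite range caps k0 at 1 in lower mode
    p = gp.compute_boost_params(
        PotentialStats(v_max=10, v_min=0, v_avg=5, sigma_v=0, n_samples=3), 6.0)
    assert p.k0 == 1.0


@settings(deadline=None, max_examples=100)
@given(st.floats(0.1, 50), st.floats(-20, 20), st.floats(0.01, 1.0),
       st.floats(0.5, 10))
def test_threshold_bound_always_satisfied(span, vmin, frac, sigma_v):
    """Every emitted parameter set satisfies v_max <= E <= v_min + 1/k."""
    vmax = vmin + span
    vavg = vmin + frac * span * 0.999 + 1e-9
    stats = PotentialStats(v_max=vmax, v_min=vmin, v_avg=vavg,
                           sigma_v=sigma_v, n_samples=5)
    for mode in ("lower", "upper"):
        p = gp.compute_boost_params(stats, 6.0, mode)
        assert vmax <= p.threshold_e + 1e-9
        assert p.threshold_e <= vmin + 1.0 / p.force_constant_k + 1e-9


# ---------------------------------------------------------------------------
# boost energy and force scale
# ---------------------------------------------------------------------------

def _params(e=100.0, k=0.01):
    return GaMDParams(threshold_e=e, k0=min(1.0, k * 100.0),
                      force_constant_k=k, sigma0=6.0)


def test_boost_energy_branches():
    """dV vanishes at/above the threshold and is 1/2 k (E-V)^2 below it."""
    p = _params()
    assert gp.boost_energy(110.0, p) == 0.0
    assert gp.boost_energy(100.0, p) == 0.0
    assert gp.boost_energy(90.0, p) == pytest.approx(0.5, abs=1e-12)


def test_boost_force_scale_values():
    p = _params()
    assert gp.boost_force_scale(110.0, p) == 1.0
    assert gp.boost_force_scale(90.0, p) == pytest.approx(0.9, abs=1e-12)
    # force vanishes exactly at the flattening limit V = E - 1/k
    assert gp.boost_force_scale(100.0 - 1.0 / 0.01, p) == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, max_examples=100)
@given(st.floats(-99, 99.9), st.floats(-99, 99.9))
def test_order_preservation_and_gap_contraction(v1, v2):
    """The boosted surface preserves energy ordering and contracts gaps
    for any pair of potential values below the threshold."""
    if abs(v1 - v2) < 1e-9:  # sub-epsilon gaps underflow in the boost terms
        return
    lo, hi = min(v1, v2), max(v1, v2)
    p = _params(e=100.0, k=1.0 / 200.0)  # E - 1/k = -100 < lo, so scale > 0
    lo_star = lo + gp.boost_energy(lo, p)
    hi_star = hi + gp.boost_energy(hi, p)
    assert lo_star < hi_star
    assert (hi_star - lo_star) < (hi - lo)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def test_dissipative_limit_relaxes_to_minimum():
    """At zero temperature and high friction the dynamics settle in the
    nearest local minimum."""
    model = Harmonic1D(k=3.0, center=2.0)
    traj = gp.propagate(model, [3.5], None, steps=4000, dt=0.02,
                        temperature=0.0, friction=20.0, stride=10, seed=1)
    assert traj.configurations[-1, 0] == pytest.approx(2.0, abs=1e-4)


def test_equipartition_in_harmonic_well():
    """Long unboosted sampling of a harmonic well reproduces the
    equipartition variance kBT/kappa within 5%."""
    kappa = 3.0
    traj = gp.propagate(Harmonic1D(k=kappa), [0.0], None, steps=200_000,
                        dt=0.02, temperature=310.0, friction=1.0, stride=10,
                        seed=4)
    var = traj.configurations[:, 0].var()
    assert var == pytest.approx(KBT_310 / kappa, rel=0.05)


def test_propagation_is_deterministic_and_seed_sensitive():
    a = gp.propagate(Harmonic1D(), [0.5], None, 3000, 0.02, 310.0, 1.0, 10, seed=9)
    b = gp.propagate(Harmonic1D(), [0.5], None, 3000, 0.02, 310.0, 1.0, 10, seed=9)
    c = gp.propagate(Harmonic1D(), [0.5], None, 3000, 0.02, 310.0, 1.0, 10, seed=10)
    assert np.array_equal(a.configurations, b.configurations)
    assert not np.array_equal(a.configurations, c.configurations)


def test_boosted_frames_internally_consistent(default_run):
    """Recorded boosts are non-negative and equal boost_energy of the
    recorded component energies."""
    for _, _, result in default_run.values():
        boost = result.boost
        for traj in result.production:
            assert np.all(traj.total_boost >= 0)
            expect = np.array([gp.boost_energy(v, boost.total_params)
                               for v in traj.v_total])
            np.testing.assert_allclose(traj.dv_total, expect, atol=1e-10)


def test_protocol_stage_validation():
    model = Harmonic1D()
    with pytest.raises(ValueError, match="update"):
        gp.run_gamd_protocol(model, ProtocolConfig(cmd_steps=100,
                                                   update_interval=5000),
                             master_seed=1)


def test_protocol_adapts_then_freezes_and_randomizes_replicas(default_run):
    """Equilibration re-derives E and k0 at every update point; production
    replicas share frozen parameters but have distinct seeds; sigma0 defaults
    to 6.0 kcal/mol."""
    _, _, result = default_run["partial_agonist"]
    assert len(result.params_history) == (
        ProtocolConfig().equil_steps // ProtocolConfig().update_interval)
    thresholds = {h["total_params"]["threshold_e"] for h in result.params_history}
    assert len(thresholds) > 1  # parameters actually refreshed
    assert len(result.production) == 3
    assert len({t.seed for t in result.production}) == 3
    assert result.boost.total_params.sigma0 == 6.0


def test_dual_boost_on_toy_chain():
    """A bonded chain exercises the dual-boost path: both components get
    independently determined parameters from their own statistics."""
    chain = gp.build_toy_chain(6, seed=11)
    cfg = ProtocolConfig(cmd_steps=4000, equil_steps=8000,
                         production_steps=8000, update_interval=2000,
                         n_replicas=2, dt=0.002, stride=5)
    result = gp.run_gamd_protocol(chain, cfg, master_seed=5, label="chain")
    assert result.boost.mode == "dual"
    tp, dp = result.boost.total_params, result.boost.dihedral_params
    assert tp.threshold_e != dp.threshold_e
    assert tp.sigma0 == dp.sigma0 == 6.0
    for traj in result.production:
        assert np.all(traj.total_boost >= 0)
        assert np.all(np.isfinite(traj.v_total))
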