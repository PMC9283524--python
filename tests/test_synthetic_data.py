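"""Synthetic generators: landscapes, toy chain, assay data, PDB fixtures."""

import math

import numpy as np
import pytest

import gamdpipe as gp
from gamdpipe.config import KBT_310
from gamdpipe.synthetic_data import LandscapeSpec, default_concentrations


# ---------------------------------------------------------------------------
# activation landscapes
# ---------------------------------------------------------------------------

def test_landscape_calibration_hits_stated_geometry(default_profiles):
    """Minima sit exactly at the basin centers, the active-minus-inactive
    difference equals the ligand's bias, and the saddle lies barrier_height
    above the lower well."""
    from scipy.optimize import minimize_scalar
    for profile in default_profiles:
        m = gp.build_activation_landscape(profile)
        assert m.derivative(m.inactive_center) == pytest.approx(0.0, abs=1e-8)
        assert m.derivative(m.active_center) == pytest.approx(0.0, abs=1e-8)
        diff = m.value(m.active_center) - m.value(m.inactive_center)
        assert diff == pytest.approx(profile.landscape_bias, abs=1e-8)
        res = minimize_scalar(lambda d: -m.value(d),
                              bounds=(m.inactive_center, m.active_center),
                              method="bounded")
        lower = min(m.value(m.inactive_center), m.value(m.active_center))
        assert -res.fun - lower == pytest.approx(profile.barrier_height, abs=1e-6)


def test_very_weak_profile_global_minimum_is_inactive(default_profiles):
    """With the inactive basin favored, the global minimum sits at 8.3 Å."""
    vw = [p for p in default_profiles if p.name == "very_weak_partial"][0]
    m = gp.build_activation_landscape(vw)
    grid = np.arange(4.0, 18.0, 0.001)
    assert grid[np.argmin(m.values(grid))] == pytest.approx(8.3, abs=0.01)


def test_zero_bias_symmetric_wells():
    p = gp.LigandProfile("sym", landscape_bias=0.0, barrier_height=4.0,
                         assay_relative_max=0.5, assay_ec50=1e-8,
                         association_rate_k=1e-3)
    m = gp.build_activation_landscape(p)
    assert m.value(8.3) == pytest.approx(m.value(13.0), abs=1e-8)


def test_landscape_gradient_matches_finite_differences(default_profiles):
    """Analytic gradient vs central differences at 100 random points."""
    m = gp.build_activation_landscape(default_profiles[1])
    rng = np.random.default_rng(0)
    for d in rng.uniform(4.0, 17.0, 100):
        fd = (m.value(d + 1e-5) - m.value(d - 1e-5)) / 2e-5
        assert abs(fd - m.derivative(d)) < 1e-4


def test_overlapping_wells_rejected():
    with pytest.raises(ValueError, match="[Oo]verlapping"):
        LandscapeSpec(inactive_center=8.3, active_center=9.0,
                      inactive_width=1.0, active_width=1.0)


def test_boltzmann_populations_ordered_and_grid_converged(default_profiles):
    """Equilibrium active-state populations are strictly ordered
    full > partial > very weak, and the quadrature is grid-converged."""
    fracs = []
    for profile in default_profiles:
        m = gp.build_activation_landscape(profile)
        coarse = gp.boltzmann_active_fraction(m, grid=0.001)
        fine = gp.boltzmann_active_fraction(m, grid=0.0005)
        assert abs(coarse - fine) / fine < 1e-6
        fracs.append(coarse)
    assert fracs[0] > fracs[1] > fracs[2]


def test_2d_landscape_is_separable_sum():
    spec = LandscapeSpec(second_coordinate={"inactive_center": 1.0,
                                            "active_center": 3.5,
                                            "bias": 1.0, "barrier": 2.0})
    m = gp.build_activation_landscape(gp.default_profiles()[0], spec)
    x = np.array([9.1, 2.2])
    v, vd, g, gd = m.components(x)
    assert v == pytest.approx(m.primary.value(9.1) + m.secondary.value(2.2))
    assert vd == 0.0 and np.all(gd == 0.0)


# ---------------------------------------------------------------------------
# toy chain
# ---------------------------------------------------------------------------

def test_chain_equilibrium_geometry_is_at_component_minima():
    chain = gp.build_toy_chain(6, seed=3)
    v, vd, g, _ = chain.components(chain.initial_configuration())
    assert v == pytest.approx(0.0, abs=1e-9)
    assert vd == pytest.approx(0.0, abs=1e-9)
    assert np.abs(g).max() < 1e-6


def test_chain_component_decomposition_identity():
    """Dihedral component + bonded remainder equals the total potential at
    random configurations."""
    chain = gp.build_toy_chain(5, seed=8)
    x0 = chain.initial_configuration()
    rng = np.random.default_rng(2)
    for _ in range(50):
        x = x0 + 0.2 * rng.standard_normal(x0.size)
        v, vd, _, _ = chain.components(x)
        # bonded remainder recomputed by zeroing the dihedral force constant
        bare = gp.build_toy_chain(5, seed=8, k_dihedral=0.0)
        v_bonded = bare.components(x)[0]
        assert v == pytest.approx(v_bonded + vd, rel=1e-10)


def test_chain_gradients_match_finite_differences():
    chain = gp.build_toy_chain(6, seed=3)
    rng = np.random.default_rng(0)
    x = chain.initial_configuration() + 0.1 * rng.standard_normal(chain.n_dof)
    v, vd, g, gd = chain.components(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = 1e-6
        assert (chain.components(x + e)[0] - chain.components(x - e)[0]) / 2e-6 \
            == pytest.approx(g[i], abs=1e-5)
        assert (chain.components(x + e)[1] - chain.components(x - e)[1]) / 2e-6 \
            == pytest.approx(gd[i], abs=1e-5)


def test_chain_seed_determinism_and_minimum_size():
    a, b = gp.build_toy_chain(6, seed=4), gp.build_toy_chain(6, seed=4)
    assert np.array_equal(a.r0, b.r0) and np.array_equal(a.phi0, b.phi0)
    c = gp.build_toy_chain(6, seed=5)
    assert not np.array_equal(a.phi0, c.phi0)
    with pytest.raises(ValueError):
        gp.build_toy_chain(3, seed=1)


# ---------------------------------------------------------------------------
# assay generators
# ---------------------------------------------------------------------------

def test_association_trace_model_values(default_profiles):
    """Noiseless trace starts at f0 and passes the closed-form half-rise at
    t = ln2/k."""
    p = gp.LigandProfile("k01", landscape_bias=-1, barrier_height=4,
                         assay_relative_max=0.5, assay_ec50=1e-8,
                         association_rate_k=0.1)
    tr = gp.simulate_association_trace(p, f0=10.0, fmax=50.0, duration=60.0,
                                       interval=math.log(2) / 0.1, noise_sd=0.0)
    assert tr.rfu[0] == 10.0
    assert tr.rfu[1] == pytest.approx((10.0 + 50.0) / 2.0, abs=1e-12)


def test_association_trace_default_sampling(default_profiles):
    """Default settings: 301 samples over 60 min at 12 s spacing."""
    tr = gp.simulate_association_trace(default_profiles[0], noise_sd=0.0)
    assert tr.time.size == 301
    assert tr.time[-1] == 3600.0
    assert np.all(np.diff(tr.time) == 12.0)


def test_association_trace_seeding_and_validation(default_profiles):
    p = default_profiles[0]
    a = gp.simulate_association_trace(p, seed=1)
    b = gp.simulate_association_trace(p, seed=1)
    c = gp.simulate_association_trace(p, seed=2)
    assert np.array_equal(a.rfu, b.rfu) and not np.array_equal(a.rfu, c.rfu)
    with pytest.raises(ValueError):
        gp.simulate_association_trace(p, f0=100.0, fmax=50.0)
    with pytest.raises(ValueError):
        gp.simulate_association_trace(p, noise_sd=-1.0)


def test_dose_response_midpoint_and_asymptote(default_profiles):
    """Noiseless response equals the bottom/top midpoint at EC50 and is
    within 0.1% of the ligand plateau at saturating concentration."""
    p = default_profiles[0]  # ec50 = 1 nM
    curve = gp.simulate_dose_response(p, [p.assay_ec50, 1.0], replicates=1,
                                      noise_sd=0.0)
    top = 100.0 * p.assay_relative_max
    assert curve.response[0] == pytest.approx(top / 2.0, abs=1e-9)
    assert curve.response[1] == pytest.approx(top, rel=1e-3)


def test_dose_response_plateau_ratio_reads_back_generator(default_profiles):
    full, _, vw = default_profiles
    cf = gp.simulate_dose_response(full, default_concentrations(full),
                                   noise_sd=0.0)
    cv = gp.simulate_dose_response(vw, default_concentrations(vw),
                                   noise_sd=0.0)
    assert cv.response.max() / cf.response.max() == pytest.approx(
        vw.assay_relative_max, rel=1e-3)


def test_dose_response_validation(default_profiles):
    p = default_profiles[0]
    with pytest.raises(ValueError):
        gp.simulate_dose_response(p, [])
    with pytest.raises(ValueError):
        gp.simulate_dose_response(p, [1e-9, 1e-10])  # unsorted


# ---------------------------------------------------------------------------
# PDB fixtures
# ---------------------------------------------------------------------------

def _two_residue_fixture():
    return [
        dict(chain="A", res_id=1, res_name="GLY", atom_name="CA",
             element="C", xyz=(0.0, 0.0, 0.0)),
        dict(chain="A", res_id=2, res_name="GLY", atom_name="CA",
             element="C", xyz=(10.0, 0.0, 0.0)),
    ]


def test_fixture_pdb_round_trip(tmp_path):
    """Write/read round trip preserves the atom inventory and coordinates to
    PDB precision (1e-3 Å)."""
    path = tmp_path / "two.pdb"
    atoms = _two_residue_fixture()
    atoms[0]["xyz"] = (1.234, -5.678, 9.012)
    gp.write_fixture_pdb(atoms, path)
    model = gp.read_structure(path)
    assert model.n_atoms == 2
    assert set(model.atoms.atom_name) == {"CA"}
    np.testing.assert_allclose(model.atom_coord("A", 1, "CA"),
                               [1.234, -5.678, 9.012], atol=1e-3)
    d = gp.labeled_distance(model, ("A", 1, "CA"), ("A", 2, "CA"))
    assert d == pytest.approx(
        float(np.linalg.norm(np.array([1.234, -5.678, 9.012]) - [10, 0, 0])),
        abs=2e-3)


def test_fixture_pdb_rejects_out_of_range_coordinates(tmp_path):
    atoms = _two_residue_fixture()
    atoms[0]["xyz"] = (123456.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="range"):
        gp.write_fixture_pdb(atoms, tmp_path / "bad.pdb")
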