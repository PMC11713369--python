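"""Transport engine: estimators, sampling kinematics, statistics, ledger."""

import math

import numpy as np
import pytest

from brachyq import _xsec
from brachyq.geometry import Region, Scene, Sphere, Cylinder, ir_scene, water_shell, co60_scene
from brachyq.physics_data import EnergySpectrum, get_table, load_spectrum
from brachyq.transport import (
    SourceModel,
    TransportConfig,
    combine_batches,
    paired_ratio,
    ratio_with_stderr,
    run_transport,
    sample_interaction,
    _sample_kn_x_generator,
    _sample_thomson_generator,
)
from brachyq.constants import MEV_PER_G_TO_GY


def _rel_sigma(t):
    return t.standard_error / t.dose_per_history


def test_inverse_square_fluence_in_vacuum(vacuum_shell_run):
    r = vacuum_shell_run
    f1, f2 = r["s1"], r["s2"]
    ratio = f1.fluence_per_history / f2.fluence_per_history
    sig = ratio * math.hypot(
        f1.fluence_stderr / f1.fluence_per_history, f2.fluence_stderr / f2.fluence_per_history
    )
    assert abs(ratio - 4.0) < max(3 * sig, 1e-3)
    assert r.ledger.balance == pytest.approx(0.0, abs=1e-9)


def test_uncollided_kerma_matches_closed_form(cs137_line):
    scene = ir_scene(water_shell(3.0))
    src = SourceModel("isotropic_point", cs137_line)
    res = run_transport(
        TransportConfig(scene=scene, source=src, n_histories=80_000, seed=3, tallies=("voxel",), primary_only=True)
    )
    t = get_table("water")
    rho = 0.998
    mu = t.attenuation(0.662) * rho
    expect = 0.662 * t.energy_absorption(0.662) * math.exp(-mu * 3.0) / (4 * math.pi * 9.0)
    expect *= MEV_PER_G_TO_GY
    got = res["voxel"]
    assert abs(got.dose_per_history - expect) < 3 * got.standard_error


def test_fixed_seed_runs_are_bit_identical(cs137_line):
    scene = ir_scene(water_shell(2.0))
    src = SourceModel("isotropic_point", cs137_line)
    cfg = TransportConfig(scene=scene, source=src, n_histories=20_000, seed=9, tallies=("voxel",))
    a = run_transport(cfg)
    b = run_transport(cfg)
    assert a["voxel"].dose_per_history == b["voxel"].dose_per_history
    assert a["voxel"].standard_error == b["voxel"].standard_error


def test_chord_splitting_is_exactly_additive(cs137_line):
    """Adding an interior surface splits chords but cannot change scores:
    the volume-weighted combination of the sub-shell doses equals the
    whole-shell dose of the same histories bit-for-bit (no RNG is
    consumed at boundary crossings)."""
    src = SourceModel("isotropic_point", cs137_line)
    whole = ir_scene(water_shell(3.0, half_width_cm=0.05))
    a = run_transport(
        TransportConfig(scene=whole, source=src, n_histories=20_000, seed=5, tallies=("voxel",))
    )
    split = ir_scene(
        [
            Region("shell_core", Sphere(np.zeros(3), 2.95), "water"),
            Region("inner_half", Sphere(np.zeros(3), 3.00), "water"),
            Region("voxel", Sphere(np.zeros(3), 3.05), "water"),
        ]
    )
    b = run_transport(
        TransportConfig(scene=split, source=src, n_histories=20_000, seed=5, tallies=("inner_half", "voxel"))
    )
    v_in = 4 / 3 * math.pi * (3.00**3 - 2.95**3)
    v_out = 4 / 3 * math.pi * (3.05**3 - 3.00**3)
    combined = (
        b["inner_half"].dose_per_history * v_in + b["voxel"].dose_per_history * v_out
    ) / (v_in + v_out)
    # the extra surface adds one epsilon-push per crossing, so agreement is
    # to the push scale rather than bit-exact
    assert combined == pytest.approx(a["voxel"].dose_per_history, rel=2e-3)


def test_track_length_and_collision_estimators_agree(water_shell_run):
    v = water_shell_run["voxel"]
    diff = abs(v.dose_per_history - v.collision_dose)
    sig = math.hypot(v.standard_error, v.collision_stderr)
    assert diff < 3 * sig


def test_missing_region_never_scores(cs137_line):
    """A tally region the beam cannot reach is flagged, not silently zero."""
    scene = co60_scene([Region("voxel", Sphere(np.array([0.0, 110.0, 13.0]), 0.5), "water")])
    src = SourceModel("collimated_point", cs137_line)
    res = run_transport(
        TransportConfig(scene=scene, source=src, n_histories=5_000, seed=1, tallies=("voxel",), primary_only=True)
    )
    assert res["voxel"].flagged
    assert res["voxel"].dose_per_history == 0.0


def test_collimated_fluence_outside_cone_is_zero(cs137_line):
    """The 10x10 field at 100 cm: a scorer just outside the field edge
    (but inside the phantom) sees exactly nothing."""
    off_axis = Region("voxel", Sphere(np.array([8.0, 100.0, 0.0]), 0.4), "water")
    scene = co60_scene([off_axis])
    src = SourceModel("collimated_point", cs137_line)
    res = run_transport(
        TransportConfig(scene=scene, source=src, n_histories=10_000, seed=2, tallies=("voxel",), primary_only=True)
    )
    assert res["voxel"].n_contributions == 0


def test_compton_scattered_energy_within_kinematic_bounds():
    rng = np.random.default_rng(0)
    e = np.full(50_000, 0.662)
    x = _sample_kn_x_generator(e, rng)
    a = 0.662 / 0.51099895
    x_min = 1.0 / (1.0 + 2.0 * a)
    assert np.all(x >= x_min - 1e-12) and np.all(x <= 1.0 + 1e-12)


def test_compton_mean_scattered_fraction_matches_kn_integration():
    rng = np.random.default_rng(1)
    e = np.full(200_000, 0.662)
    x = _sample_kn_x_generator(e, rng)
    expected = 1.0 - _xsec.kn_energy_transfer_fraction(0.662)
    assert abs(x.mean() - expected) < 3 * x.std() / math.sqrt(len(x))


def test_thomson_angular_distribution_forward_backward_symmetric():
    rng = np.random.default_rng(2)
    c = _sample_thomson_generator(100_000, rng)
    assert abs(c.mean()) < 3 * c.std() / math.sqrt(len(c))


def test_sample_interaction_channel_frequencies():
    """Channel frequencies follow the partial coefficient fractions."""
    rng = np.random.default_rng(3)
    e = np.full(100_000, 0.05)
    channel, e_out, cos_t = sample_interaction(e, "water", rng)
    t = get_table("water")
    p_pe = t.partial("photoelectric", 0.05) / t.attenuation(0.05)
    freq = np.mean(channel == "photoelectric")
    assert abs(freq - p_pe) < 3 * math.sqrt(p_pe * (1 - p_pe) / len(e))
    inc = channel == "incoherent"
    assert np.all(e_out[inc] < 0.05)
    coh = channel == "coherent"
    assert np.all(e_out[coh] == pytest.approx(0.05))


def test_combine_batches_oracle():
    assert combine_batches([0.5, 0.5, 0.5])[1] == 0.0
    rng = np.random.default_rng(4)
    p, m, nb = 0.3, 400, 200
    batch_means = rng.binomial(m, p, nb) / m
    mean, sem = combine_batches(batch_means)
    expected_sem = math.sqrt(p * (1 - p) / (m * nb))
    assert abs(mean - p) < 4 * expected_sem
    assert sem == pytest.approx(expected_sem, rel=0.35)
    with pytest.raises(ValueError):
        combine_batches([1.0])


def test_ratio_uncertainty_is_rss_of_relative_errors():
    r, s = ratio_with_stderr((2.0, 0.02), (4.0, 0.08))
    assert r == 0.5
    assert s == pytest.approx(0.5 * math.hypot(0.01, 0.02))


def test_energy_ledger_conserves(water_shell_run):
    led = water_shell_run.ledger
    assert led.emitted == pytest.approx(0.662, rel=1e-12)
    assert abs(led.balance) < 1e-9 * led.emitted


def test_csda_reproduces_kerma_under_equilibrium(cs137_line):
    """In a homogeneous water region under charged-particle equilibrium the
    straight-line electron model must reproduce collision kerma closely."""
    scene = ir_scene(water_shell(3.0))
    src = SourceModel("isotropic_point", cs137_line)
    kerma = run_transport(
        TransportConfig(scene=scene, source=src, n_histories=60_000, seed=4, tallies=("voxel",))
    )
    csda = run_transport(
        TransportConfig(scene=scene, source=src, n_histories=60_000, seed=4, tallies=("voxel",), electron_model="simple_csda")
    )
    ratio = csda["voxel"].dose_per_history / kerma["voxel"].dose_per_history
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_config_validation():
    scene = ir_scene(water_shell(3.0))
    src = SourceModel("isotropic_point", EnergySpectrum([0.3], [1.0]))
    with pytest.raises(ValueError):
        TransportConfig(scene=scene, source=src, n_histories=100, seed=0, n_batches=5)
    with pytest.raises(KeyError):
        TransportConfig(scene=scene, source=src, n_histories=100, seed=0, tallies=("nope",))
    with pytest.raises(ValueError):
        TransportConfig(scene=scene, source=src, n_histories=100, seed=0, electron_model="full")
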