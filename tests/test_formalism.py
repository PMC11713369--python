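"""kQ,Qo pipeline: ratios, perturbation ladder, deterministic oracles."""

import math

import numpy as np
import pytest

from brachyq.formalism import (
    EngineOptions,
    compute_kq,
    compute_perturbations,
    detector_dose,
    dose_ratio,
    format_parenthesized,
    geometric_volume_average,
    kq_table,
    primary_kerma_ratio_oracle,
    water_dose,
)
from brachyq.geometry import load_detector
from brachyq.synthetic_data import toy_detector

SMALL = EngineOptions(n_histories=60_000)


@pytest.fixture(scope="module")
def shared_cache():
    return {}


def test_cached_run_is_reused_and_self_ratio_is_unity(shared_cache):
    m = toy_detector("water_mimic")
    a = detector_dose(m, "ir192", 2.0, seed=3, opts=SMALL, cache=shared_cache)
    b = detector_dose(m, "ir192", 2.0, seed=3, opts=SMALL, cache=shared_cache)
    assert a is b  # identical geometry+seed resolves to one run
    assert a["cavity"].dose_per_history / b["cavity"].dose_per_history == 1.0


def test_water_mimic_dose_ratio_is_unity(shared_cache):
    """A detector made entirely of water measures Dw: ratio 1 within 3
    standard errors at any distance."""
    m = toy_detector("water_mimic")
    opts = EngineOptions(n_histories=200_000)
    r, s = dose_ratio(m, "ir192", 2.0, seed=3, opts=opts, cache=shared_cache)
    assert abs(r - 1.0) < max(3 * s, 0.02)


def test_out_of_range_distance_rejected():
    with pytest.raises(ValueError):
        dose_ratio(toy_detector("water_mimic"), "ir192", 0.5, seed=1, opts=SMALL)


def test_perturbation_telescoping_identity(shared_cache):
    """p_stem * p_cel * p_wall * p_repl == Dw/Ddet exactly, same tallies."""
    p = compute_perturbations("31016", 1.5, seed=2, opts=SMALL, cache=shared_cache)
    assert p.product == pytest.approx(p.full_ratio[0], rel=1e-12)


def test_microdiamond_p_cel_is_identity(shared_cache):
    p = compute_perturbations("60019", 2.0, seed=2, opts=SMALL, cache=shared_cache)
    assert p.p_cel == (1.0, 0.0)
    assert p.product == pytest.approx(p.full_ratio[0], rel=1e-12)


def test_big_cylinder_primary_ratio_matches_quadrature_oracle():
    """Uncollided-beam volume averaging against the deterministic
    closed-form quadrature (engine-independent)."""
    m = toy_detector("big_cylinder")
    opts = EngineOptions(n_histories=150_000)
    r, s = dose_ratio(m, "ir192", 1.0, seed=8, opts=opts, primary_only=True)
    expected = primary_kerma_ratio_oracle(m, 1.0)
    assert abs(r - expected) < max(3 * s, 0.01 * expected)


def test_geometric_average_matches_line_closed_form():
    """For a pencil-thin cavity the quadrature reduces to the analytic
    line average (2y/L) atan(L/2y) of the inverse-square field."""
    from brachyq.geometry import DetectorModel

    m = DetectorModel(
        name="pencil",
        kind="cylinder",
        cavity_diameter=0.05,
        cavity_length=23.0,
        gas="air",
        wall=(("pmma", 0.1),),
        electrode=None,
        nominal_volume_mm3=1.0,
    )
    y, L = 1.0, 2.30
    line_avg = (2 * y / L) * math.atan(L / (2 * y))
    assert geometric_volume_average(m, y, n=80) == pytest.approx(1.0 / line_avg, rel=5e-3)


def test_farmer_geometric_bounds_ordering():
    """The A12 cavity is longer and wider than the 30013's, so its
    volume-averaging bound is strictly larger."""
    b30013 = geometric_volume_average(load_detector("30013"), 1.0)
    ba12 = geometric_volume_average(load_detector("A12"), 1.0)
    assert 1.2 < b30013 < ba12 < 1.6


def test_kq_identical_quality_is_exactly_one(shared_cache):
    """If the 'user' and 'reference' qualities are the same cached setup,
    the quality-correction ratio collapses to exactly 1 (not just
    statistically)."""
    m = toy_detector("water_mimic")
    rq = dose_ratio(m, "ir192", 2.0, seed=3, opts=SMALL, cache=shared_cache)
    rqo = dose_ratio(m, "ir192", 2.0, seed=3, opts=SMALL, cache=shared_cache)
    assert rq[0] / rqo[0] == 1.0


def test_kq_table_header_only_for_empty_detector_list():
    df = kq_table([], (1.0,), seed=1, opts=SMALL)
    assert len(df) == 0
    assert list(df.columns) == ["distance_cm"]


def test_kq_table_single_entry_matches_compute_kq(shared_cache):
    m = toy_detector("water_mimic")
    df = kq_table([m], (2.0,), seed=3, opts=SMALL, cache=shared_cache)
    res = compute_kq(m, 2.0, seed=3, opts=SMALL, cache=shared_cache)
    assert df.loc[0, "water_mimic_kq"] == pytest.approx(res.kq, rel=1e-12)
    assert df.loc[0, "water_mimic"] == format_parenthesized(res.kq, res.kq_stderr)


def test_kq_table_rejects_off_grid_distance():
    with pytest.raises(ValueError):
        kq_table(["30013"], (1.25,), seed=1, opts=SMALL)


def test_format_parenthesized():
    assert format_parenthesized(1.177, 0.003) == "1.177 (3)"
    assert format_parenthesized(0.9802, 0.0054) == "0.980 (5)"


def test_intrinsic_response_ratio_scales_kq(shared_cache):
    m = toy_detector("water_mimic")
    a = compute_kq(m, 2.0, seed=3, opts=SMALL, cache=shared_cache)
    b = compute_kq(m, 2.0, seed=3, opts=SMALL, cache=shared_cache, intrinsic_response_ratio=1.02)
    assert b.kq == pytest.approx(1.02 * a.kq, rel=1e-12)
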