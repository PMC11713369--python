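"""Solids, ray tracing, detector models and the component-removal ladder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brachyq.geometry import (
    Box,
    Cylinder,
    DetectorVariant,
    LADDER,
    OUTSIDE,
    Region,
    Scene,
    Sphere,
    VOXEL_SIDE_CM,
    build_variant,
    cavity_volume,
    ir_scene,
    list_detectors,
    load_detector,
    water_voxel,
)
from brachyq.synthetic_data import toy_detector


def test_all_bundled_detectors_load():
    names = list_detectors()
    assert {"30013", "A12", "A16", "CC003", "60019"} <= set(names)
    for n in names:
        m = load_detector(n)
        assert m.cavity_diameter > 0


@pytest.mark.parametrize("name", ["30013", "A12", "CC003", "60019", "31016"])
def test_cavity_center_locates_to_cavity(name):
    m = load_detector(name)
    scene = ir_scene(build_variant(m, "det", center=(0.0, 2.0, 0.0)))
    idx = scene.locate(np.array([[0.0, 2.0, 0.0]]))[0]
    # innermost region at the center is the electrode when one is present
    assert scene.names[idx] in ("cavity", "electrode")
    edge = np.array([[0.0, 2.0 + m.cavity_diameter / 2 * 0.1 * 0.95, 0.0]])
    if m.kind == "sphere":
        assert scene.names[scene.locate(edge)[0]] == "cavity"


def test_phantom_and_outside_regions():
    scene = ir_scene([water_voxel((0.0, 1.0, 0.0))])
    assert scene.names[scene.locate(np.array([[0.0, 10.0, 0.0]]))[0]] == "phantom"
    assert scene.locate(np.array([[0.0, 15.5, 0.0]]))[0] == OUTSIDE


def test_electrode_removed_space_becomes_cavity():
    m = load_detector("30013")
    scene = ir_scene(build_variant(m, "wall", center=(0.0, 2.0, 0.0)))
    assert scene.names[scene.locate(np.array([[0.0, 2.0, 0.0]]))[0]] == "cavity"


def test_distance_to_boundary_sphere_center():
    s = Scene([], Region("ph", Sphere(np.zeros(3), 7.0), "water"))
    d = s.distance_to_boundary(np.zeros((1, 3)), np.array([[0.0, 1.0, 0.0]]))
    assert d[0] == pytest.approx(7.0, rel=1e-9)


def test_ray_parallel_outside_cylinder_misses():
    cyl = Cylinder(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0, 2.0)
    t = cyl.next_crossing(np.array([[3.0, 0.0, -5.0]]), np.array([[0.0, 0.0, 1.0]]))
    assert np.isinf(t[0])


def test_oblique_cylinder_intersection_matches_quadratic():
    """Independent closed-form check of the lateral-surface crossing."""
    cyl = Cylinder(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.5, 4.0)
    p = np.array([-5.0, 0.3, -1.0])
    d = np.array([0.9, 0.1, 0.2])
    d = d / np.linalg.norm(d)
    # radial quadratic in the xy-plane
    a = d[0] ** 2 + d[1] ** 2
    b = p[0] * d[0] + p[1] * d[1]
    c = p[0] ** 2 + p[1] ** 2 - 1.5**2
    t_expected = (-b - math.sqrt(b * b - a * c)) / a
    assert abs(p[2] + t_expected * d[2]) < 4.0  # crossing on the finite part
    t = cyl.next_crossing(p[None, :], d[None, :])
    assert t[0] == pytest.approx(t_expected, rel=1e-10)


def test_non_unit_direction_rejected():
    s = Scene([], Region("ph", Sphere(np.zeros(3), 7.0), "water"))
    with pytest.raises(ValueError):
        s.distance_to_boundary(np.zeros((1, 3)), np.array([[0.0, 2.0, 0.0]]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    px=st.floats(-3, 3),
    py=st.floats(-3, 3),
    pz=st.floats(-3, 3),
    u=st.floats(0, 2 * math.pi),
    v=st.floats(-1, 1),
)
def test_ray_marching_consistency(px, py, pz, u, v):
    """Stopping just short of the reported boundary never changes region."""
    m = load_detector("31016")
    scene = ir_scene(build_variant(m, "det", center=(0.0, 1.5, 0.0)))
    p = np.array([[px, py + 1.5, pz]])
    s = math.sqrt(max(0.0, 1 - v * v))
    d = np.array([[s * math.cos(u), s * math.sin(u), v]])
    if scene.locate(p)[0] == OUTSIDE:
        return
    t = scene.distance_to_boundary(p, d)[0]
    if not np.isfinite(t) or t < 1e-6:
        return
    before = p + (t - 1e-7) * d
    assert scene.locate(before)[0] == scene.locate(p)[0]


def test_variant_ladder_monotone_component_count():
    m = load_detector("30013")
    sizes = [len(build_variant(m, lvl)) for lvl in LADDER]
    assert sizes == sorted(sizes, reverse=True)
    air = build_variant(m, "air")
    assert [r.name for r in air] == ["cavity"]


def test_microdiamond_ladder_and_orientation():
    m = load_detector("60019")
    with pytest.raises(ValueError):
        DetectorVariant(m, "wall")  # no electrode rung for the diamond
    det = build_variant(m, "det", center=(0.0, 1.0, 0.0), axis=(0.0, 1.0, 0.0))
    names = [r.name for r in det]
    assert "stem" in names and "electrode" not in names
    stem = next(r for r in det if r.name == "stem")
    assert stem.material == "diamond"
    # base (stem) sits behind the sensitive volume, away from the source
    assert stem.solid.center[1] > 1.0
    # front window layers face the source
    w0 = next(r for r in det if r.name == "wall0")
    assert w0.solid.center[1] < 1.0


def test_voxel_scorer_dimensions():
    v = water_voxel((0.0, 1.0, 0.0))
    assert isinstance(v.solid, Box)
    np.testing.assert_allclose(v.solid.half_size, VOXEL_SIDE_CM / 2)
    assert VOXEL_SIDE_CM == pytest.approx(0.05)


def test_cavity_volume_against_nominals():
    cc003 = load_detector("CC003")
    assert cavity_volume(cc003) == pytest.approx(3.0, rel=0.30)
    a12 = load_detector("A12")
    assert cavity_volume(a12) == pytest.approx(640.0, rel=0.25)


def test_cavity_volume_degenerate_electrode():
    m = toy_detector("big_cylinder")
    assert m.electrode is None
    expected = math.pi * (6.1 / 2) ** 2 * 25.8
    assert cavity_volume(m) == pytest.approx(expected, rel=1e-12)


def test_boundary_point_belongs_to_inner_region():
    m = load_detector("A12")
    scene = ir_scene(build_variant(m, "det", center=(0.0, 2.0, 0.0)))
    r_cav = m.cavity_diameter / 2 * 0.1
    on_surface = np.array([[r_cav, 2.0, 0.0]])
    assert scene.names[scene.locate(on_surface)[0]] == "cavity"
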