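"""Analog Monte Carlo photon transport with track-length kerma scoring.

The engine transports photons through a :class:`~brachyq.geometry.Scene`
by optical-depth ray marching: one exponential deviate fixes the optical
depth to the next interaction, and the ray is advanced region by region,
accumulating ``mu * length`` until the depth is exhausted or the photon
escapes.  Because a single uniform decides each flight, two runs that
share a seed follow identical trajectories wherever their geometries
coincide — the correlated-sampling scheme used for all dose ratios.

Doses are estimated with the track-length collision-kerma estimator
(every chord through a scoring region contributes
``w * E * mu_en/rho(E) * chord / V``), which is efficient for the small
cavities involved.  An analog collision-site estimator is accumulated
alongside as an internal cross-check.  Uncertainties come from batch
statistics (default 20 batches).

Physics levels: ``kerma`` (default) assumes local energy deposition by
secondary electrons; ``simple_csda`` instead deposits the *expected*
secondary-electron current of every photon chord near the scoring
regions as straight lines with uniform energy loss over the CSDA range
(forward direction, mean transfer energy).  Taking the photon-to-
electron conversion in expectation rather than by analog sampling keeps
the cavity-dose variance at the photon-statistics level while preserving
what the option exists for: media that convert more photon energy per
unit mass (high-Z electrodes) inject proportionally more electron energy
into an adjacent cavity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _xsec
from .constants import MEV_PER_G_TO_GY, PAIR_THRESHOLD_MEV, ELECTRON_REST_MEV
from .geometry import OUTSIDE, Box, Cylinder, Region, Scene, Sphere
from .physics_data import EnergySpectrum, MATERIALS, get_table
from .rng import CounterRng

_PUSH = 1e-7  # cm, nudge across surfaces after a boundary crossing
_U64 = np.uint64


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceModel:
    """Point photon source.

    ``isotropic_point`` emits into 4 pi; ``collimated_point`` emits into a
    square cone along +y whose cross-section at ``field_distance_cm``
    equals ``field_size_cm`` x ``field_size_cm`` (the 10 x 10 reference
    field), with zero fluence outside the cone.
    """

    kind: str
    spectrum: EnergySpectrum
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_size_cm: float = 10.0
    field_distance_cm: float = 100.0

    def __post_init__(self):
        if self.kind not in ("isotropic_point", "collimated_point"):
            raise ValueError(f"unknown source kind {self.kind!r}")


@dataclass(frozen=True)
class DirectionalBias:
    """Mixture importance sampling of the emission direction: with
    probability ``q`` the direction is drawn uniformly inside the cone
    that subtends a sphere of ``radius_cm`` about ``target`` (plus margin),
    otherwise isotropically; weights restore the isotropic expectation."""

    target: tuple[float, float, float]
    radius_cm: float
    q: float = 0.75

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("bias probability must be in (0, 1)")


@dataclass(frozen=True)
class TransportConfig:
    scene: Scene
    source: SourceModel
    n_histories: int
    seed: int
    n_batches: int = 20
    tallies: tuple[str, ...] = ("cavity",)
    photon_cutoff_mev: float = 1e-3
    electron_model: str = "kerma"
    bias: DirectionalBias | None = None
    primary_only: bool = False
    max_segments: int = 3000
    chunk_size: int = 1 << 18

    def __post_init__(self):
        if self.n_batches < 10:
            raise ValueError("need at least 10 batches for stable errors")
        if self.n_histories < self.n_batches:
            raise ValueError("fewer histories than batches")
        if self.electron_model not in ("kerma", "simple_csda"):
            raise ValueError(f"unknown electron model {self.electron_model!r}")
        for t in self.tallies:
            if t not in self.scene.names:
                raise KeyError(f"tally region {t!r} not in scene")


@dataclass
class TallyEstimate:
    """Per-history dose for one region with batch-based standard error."""

    region: str
    dose_per_history: float  # Gy per emitted photon
    standard_error: float
    n_batches: int
    fluence_per_history: float = 0.0  # 1/cm^2, track-length fluence
    fluence_stderr: float = 0.0
    collision_dose: float = 0.0  # analog collision-site estimator, Gy
    collision_stderr: float = 0.0
    n_contributions: int = 0
    flagged: bool = False  # True when the region never scored
    batch_doses: np.ndarray | None = None  # per-batch dose means [Gy]

    @property
    def relative_error(self) -> float:
        return self.standard_error / self.dose_per_history if self.dose_per_history else math.inf


@dataclass
class EnergyLedger:
    """Analog energy bookkeeping per emitted photon [MeV]."""

    emitted: float = 0.0
    transferred: float = 0.0  # to electrons at interaction sites
    escaped: float = 0.0
    discarded: float = 0.0  # below-cutoff terminations + annihilation quanta

    @property
    def balance(self) -> float:
        return self.emitted - self.transferred - self.escaped - self.discarded


@dataclass
class TransportResult:
    tallies: dict[str, TallyEstimate]
    ledger: EnergyLedger
    n_histories: int
    seed: int

    def __getitem__(self, region: str) -> TallyEstimate:
        return self.tallies[region]


# ---------------------------------------------------------------------------
# Batch statistics
# ---------------------------------------------------------------------------


def combine_batches(batch_means: np.ndarray) -> tuple[float, float]:
    """Mean and standard error of the mean from per-batch means."""
    m = np.asarray(batch_means, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 batches")
    mean = float(m.mean())
    sem = float(m.std(ddof=1) / math.sqrt(m.size))
    return mean, sem


def ratio_with_stderr(num: tuple[float, float], den: tuple[float, float]) -> tuple[float, float]:
    """Quadrature propagation of relative errors for a ratio a/b."""
    (a, sa), (b, sb) = num, den
    if b == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    r = a / b
    rel = math.hypot(sa / a if a else 0.0, sb / b)
    return r, abs(r) * rel


def paired_ratio(num: "TallyEstimate", den: "TallyEstimate") -> tuple[float, float]:
    """Ratio of two tallies from shared-seed (correlated) runs.

    When both tallies carry matching per-batch means, the ratio is formed
    batch by batch so that noise common to both runs cancels — this is
    what makes the component-removal ladder resolvable at desk scale.
    Falls back to uncorrelated quadrature propagation otherwise.
    """
    a, b = num.batch_doses, den.batch_doses
    if (
        a is not None
        and b is not None
        and len(a) == len(b)
        and np.all(np.asarray(b) > 0)
        and np.all(np.asarray(a) > 0)
    ):
        # value from the ratio of overall means (so sequential factors
        # telescope exactly); error from the spread of per-batch ratios
        _, sem = combine_batches(np.asarray(a) / np.asarray(b))
        return num.dose_per_history / den.dose_per_history, sem
    return ratio_with_stderr(
        (num.dose_per_history, num.standard_error), (den.dose_per_history, den.standard_error)
    )


# ---------------------------------------------------------------------------
# Material lookup tables prepared per scene
# ---------------------------------------------------------------------------


class _MaterialLut:
    """Per-region linear-attenuation and channel tables on a log-E grid."""

    def __init__(self, scene: Scene):
        self.density = np.zeros(len(scene.regions))
        mats: list[str | None] = []
        for i, region in enumerate(scene.regions):
            if region.material == "vacuum":
                mats.append(None)
                continue
            mats.append(region.material)
            self.density[i] = MATERIALS[region.material].density
        grids = {}
        for m in set(m for m in mats if m):
            t = get_table(m)
            grids[m] = t
        # an all-vacuum scene still needs an energy grid for bookkeeping
        ref = next(iter(grids.values())) if grids else get_table("water")
        self.f_tr_grid = _xsec.kn_energy_transfer_fraction(ref.energies)
        self.energies = ref.energies
        self.log_e = np.log(ref.energies)
        self.e_min = ref.energies[0]
        self.e_max = ref.energies[-1]
        n_reg, n_e = len(scene.regions), len(ref.energies)
        self.mu_lin = np.zeros((n_reg, n_e))  # cm^-1
        self.mu_en = np.zeros((n_reg, n_e))  # cm^2/g
        self.partial_cum = np.zeros((n_reg, 4, n_e))  # cumulative channel fractions
        for i, m in enumerate(mats):
            if m is None:
                continue
            t = grids[m]
            if not np.array_equal(t.energies, ref.energies):
                raise ValueError("coefficient tables must share one energy grid")
            self.mu_lin[i] = t.mu_over_rho * self.density[i]
            self.mu_en[i] = t.mu_en_over_rho
            stack = np.vstack(
                [
                    t.partials["photoelectric"],
                    t.partials["incoherent"],
                    t.partials["coherent"],
                    t.partials["pair"],
                ]
            )
            cum = np.cumsum(stack, axis=0)
            self.partial_cum[i] = cum / cum[-1]

    def _index_weight(self, energy):
        x = np.log(np.clip(energy, self.e_min, self.e_max))
        idx = np.clip(np.searchsorted(self.log_e, x) - 1, 0, len(self.log_e) - 2)
        w = (x - self.log_e[idx]) / (self.log_e[idx + 1] - self.log_e[idx])
        return idx, w

    def mu_linear(self, region_idx, energy):
        idx, w = self._index_weight(energy)
        a = self.mu_lin[region_idx, idx]
        b = self.mu_lin[region_idx, idx + 1]
        with np.errstate(divide="ignore"):
            out = np.exp(
                (1 - w) * np.log(np.maximum(a, 1e-300)) + w * np.log(np.maximum(b, 1e-300))
            )
        return np.where(a <= 1e-290, 0.0, out)

    def mu_en_mass(self, region_idx, energy):
        idx, w = self._index_weight(energy)
        a = self.mu_en[region_idx, idx]
        b = self.mu_en[region_idx, idx + 1]
        with np.errstate(divide="ignore"):
            out = np.exp(
                (1 - w) * np.log(np.maximum(a, 1e-300)) + w * np.log(np.maximum(b, 1e-300))
            )
        return np.where(a <= 1e-290, 0.0, out)

    def channel_cdf(self, region_idx, energy):
        idx, w = self._index_weight(energy)
        a = self.partial_cum[region_idx, :, idx]
        b = self.partial_cum[region_idx, :, idx + 1]
        return a.T * (1 - w)[:, None] + b.T * w[:, None] if a.ndim == 2 else a

    def compton_transfer_fraction(self, energy):
        return np.interp(np.asarray(energy, dtype=float), self.energies, self.f_tr_grid)

    def channel_cdf_rows(self, region_idx, energy):
        idx, w = self._index_weight(energy)
        a = self.partial_cum[region_idx, :, idx]  # (n, 4) via fancy indexing
        b = self.partial_cum[region_idx, :, idx + 1]
        return a * (1 - w[:, None]) + b * w[:, None]


def _solid_volume(solid) -> float:
    if isinstance(solid, Sphere):
        return 4.0 / 3.0 * math.pi * solid.radius**3
    if isinstance(solid, Cylinder):
        return 2.0 * math.pi * solid.radius**2 * solid.half_length
    if isinstance(solid, Box):
        return float(8.0 * np.prod(solid.half_size))
    raise TypeError(f"no volume formula for {type(solid).__name__}")


def _bounding_radius(solid) -> float:
    if isinstance(solid, Sphere):
        return solid.radius
    if isinstance(solid, Cylinder):
        return math.hypot(solid.radius, solid.half_length)
    if isinstance(solid, Box):
        return float(np.linalg.norm(solid.half_size))
    raise TypeError(type(solid).__name__)


def region_volume(scene: Scene, name: str) -> float:
    """Net geometric volume [cm^3] of a region: its solid minus the
    *maximal* earlier (inner) solids nested inside it.

    Nesting is decided by center containment plus bounding-radius order,
    which is exact for the concentric/nested constructions this package
    builds (electrode-in-cavity, shell scorers, layered walls)."""
    k = scene.index_of(name)
    solid = scene.regions[k].solid

    def center_of(s):
        return np.atleast_2d(s.center)

    inner = [
        j
        for j in range(k)
        if solid.contains(center_of(scene.regions[j].solid))[0]
        and _bounding_radius(scene.regions[j].solid) <= _bounding_radius(solid)
    ]
    maximal = []
    for j in inner:
        sj = scene.regions[j].solid
        nested = any(
            m != j
            and scene.regions[m].solid.contains(center_of(sj))[0]
            and _bounding_radius(sj) <= _bounding_radius(scene.regions[m].solid)
            for m in inner
        )
        if not nested:
            maximal.append(j)
    vol = _solid_volume(solid) - sum(_solid_volume(scene.regions[j].solid) for j in maximal)
    if vol <= 0:
        raise ValueError(f"region {name!r} has non-positive net volume")
    return vol


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def kn_x_bounds(energy_mev):
    a = np.asarray(energy_mev) / ELECTRON_REST_MEV
    return 1.0 / (1.0 + 2.0 * a), 1.0


def _kn_density(a, x):
    """Unnormalized Klein-Nishina density in x = E'/E."""
    cos_t = 1.0 - (1.0 / x - 1.0) / a
    return x + 1.0 / x - (1.0 - cos_t**2)


def _rotate(dirs: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle (cos_t) about themselves with
    azimuth phi (vectorized local-frame construction)."""
    d = dirs
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    # build an orthonormal frame (u, v, d)
    small = np.abs(d[:, 2]) < 0.9
    helper = np.where(small[:, None], [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return (
        sin_t[:, None] * np.cos(phi)[:, None] * u
        + sin_t[:, None] * np.sin(phi)[:, None] * v
        + cos_t[:, None] * d
    )


def sample_interaction(energy, material: str, rng: np.random.Generator):
    """Sample the interaction channel and outgoing state at one energy.

    Returns ``(channel, scattered_energy, cos_theta)`` arrays; scattered
    energy is NaN for absorbing channels and unchanged for coherent.
    Compton kinematics use Klein-Nishina rejection sampling, coherent
    scattering the Thomson angular law.
    """
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    table = get_table(material)
    chans = ("photoelectric", "incoherent", "coherent", "pair")
    parts = np.vstack([table.partial(c, e) for c in chans])
    cdf = np.cumsum(parts, axis=0)
    cdf /= cdf[-1]
    u = rng.random(e.shape)
    channel_idx = (u[None, :] > cdf).sum(axis=0)
    channel = np.array(chans)[channel_idx]

    e_out = np.full_like(e, np.nan)
    cos_t = np.full_like(e, np.nan)

    inc = channel_idx == 1
    if inc.any():
        x = _sample_kn_x_generator(e[inc], rng)
        a = e[inc] / ELECTRON_REST_MEV
        cos_t[inc] = 1.0 - (1.0 / x - 1.0) / a
        e_out[inc] = x * e[inc]
    coh = channel_idx == 2
    if coh.any():
        cos_t[coh] = _sample_thomson_generator(int(coh.sum()), rng)
        e_out[coh] = e[coh]
    if np.ndim(energy) == 0:
        return channel[0], float(e_out[0]), float(cos_t[0])
    return channel, e_out, cos_t


def _sample_kn_x_generator(e: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = e / ELECTRON_REST_MEV
    x_min = 1.0 / (1.0 + 2.0 * a)
    f_max = x_min + 1.0 / x_min
    out = np.empty_like(e)
    pending = np.arange(len(e))
    while len(pending):
        x = x_min[pending] + (1.0 - x_min[pending]) * rng.random(len(pending))
        accept = rng.random(len(pending)) * f_max[pending] <= _kn_density(a[pending], x)
        out[pending[accept]] = x[accept]
        pending = pending[~accept]
    return out


def _sample_thomson_generator(n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n)
    pending = np.arange(n)
    while len(pending):
        c = 2.0 * rng.random(len(pending)) - 1.0
        accept = 2.0 * rng.random(len(pending)) <= 1.0 + c**2
        out[pending[accept]] = c[accept]
        pending = pending[~accept]
    return out


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------


class _Accumulator:
    """Per-batch score sums for every tally region."""

    def __init__(self, tally_idx: list[int]):
        self.dose = {i: 0.0 for i in tally_idx}
        self.fluence = {i: 0.0 for i in tally_idx}
        self.collision = {i: 0.0 for i in tally_idx}
        self.count = {i: 0 for i in tally_idx}


def run_transport(config: TransportConfig) -> TransportResult:
    """Run the full simulation and return per-region tally estimates.

    Deterministic for a fixed config and seed (bit-for-bit); per-history
    random streams make paired runs with shared seeds correlated.
    """
    scene = config.scene
    lut = _MaterialLut(scene)
    rng = CounterRng(config.seed)
    tally_idx = [scene.index_of(t) for t in config.tallies]
    volumes = {i: region_volume(scene, scene.names[i]) for i in tally_idx}

    batch_edges = np.linspace(0, config.n_histories, config.n_batches + 1).astype(np.int64)
    batch_dose = {i: [] for i in tally_idx}
    batch_flu = {i: [] for i in tally_idx}
    batch_col = {i: [] for i in tally_idx}
    counts = {i: 0 for i in tally_idx}
    ledger = EnergyLedger()

    for b in range(config.n_batches):
        lo, hi = batch_edges[b], batch_edges[b + 1]
        acc = _Accumulator(tally_idx)
        for start in range(lo, hi, config.chunk_size):
            stop = min(start + config.chunk_size, hi)
            _run_chunk(config, scene, lut, rng, np.arange(start, stop, dtype=np.uint64), acc, ledger, volumes)
        n_b = hi - lo
        for i in tally_idx:
            batch_dose[i].append(acc.dose[i] / n_b)
            batch_flu[i].append(acc.fluence[i] / n_b)
            batch_col[i].append(acc.collision[i] / n_b)
            counts[i] += acc.count[i]

    n = config.n_histories
    for f in ("emitted", "transferred", "escaped", "discarded"):
        setattr(ledger, f, getattr(ledger, f) / n)

    tallies = {}
    for i in tally_idx:
        name = scene.names[i]
        dose, dose_se = combine_batches(batch_dose[i])
        flu, flu_se = combine_batches(batch_flu[i])
        col, col_se = combine_batches(batch_col[i])
        tallies[name] = TallyEstimate(
            region=name,
            dose_per_history=dose * MEV_PER_G_TO_GY,
            standard_error=dose_se * MEV_PER_G_TO_GY,
            n_batches=config.n_batches,
            fluence_per_history=flu,
            fluence_stderr=flu_se,
            collision_dose=col * MEV_PER_G_TO_GY,
            collision_stderr=col_se * MEV_PER_G_TO_GY,
            n_contributions=counts[i],
            flagged=counts[i] == 0,
            batch_doses=np.asarray(batch_dose[i]) * MEV_PER_G_TO_GY,
        )
    return TransportResult(tallies=tallies, ledger=ledger, n_histories=n, seed=config.seed)


def _emit(config: TransportConfig, rng: CounterRng, hist: np.ndarray):
    """Sample emission energy, direction and weight; consumes counters 0-4."""
    src = config.source
    n = len(hist)
    c0 = np.zeros(n, dtype=np.uint64)
    u_e = rng.uniform(hist, c0)
    energy = src.spectrum.sample_from_uniform(u_e)
    u1 = rng.uniform(hist, c0 + _U64(1))
    u2 = rng.uniform(hist, c0 + _U64(2))

    if src.kind == "collimated_point":
        half = src.field_size_cm / 2.0 / src.field_distance_cm
        a = (2.0 * u1 - 1.0) * half
        b = (2.0 * u2 - 1.0) * half
        weight = np.ones(n)
        if config.bias is not None:
            # mixture importance sampling in the tangent plane: a small
            # square around the target's projection vs the full field
            bias = config.bias
            t = np.asarray(bias.target, dtype=float) - np.asarray(src.position, dtype=float)
            ca, cb = t[0] / t[1], t[2] / t[1]
            s = min(half, 1.5 * bias.radius_cm / t[1])
            lo_a, hi_a = max(-half, ca - s), min(half, ca + s)
            lo_b, hi_b = max(-half, cb - s), min(half, cb + s)
            if hi_a > lo_a and hi_b > lo_b:
                u3 = rng.uniform(hist, c0 + _U64(3))
                u4 = rng.uniform(hist, c0 + _U64(4))
                take = u3 < bias.q
                a_c = lo_a + u4 * (hi_a - lo_a)
                b_c = lo_b + u1 * (hi_b - lo_b)  # independent stream slot reuse
                a = np.where(take, a_c, a)
                b = np.where(take, b_c, b)
                area_full = (2 * half) ** 2
                area_small = (hi_a - lo_a) * (hi_b - lo_b)
                in_small = (a >= lo_a) & (a <= hi_a) & (b >= lo_b) & (b <= hi_b)
                pdf = (1.0 - bias.q) / area_full + np.where(in_small, bias.q / area_small, 0.0)
                weight = (1.0 / area_full) / pdf
        dirs = np.column_stack([a, np.ones(n), b])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return energy, dirs, weight

    cos_t = 2.0 * u1 - 1.0
    phi = 2.0 * np.pi * u2
    sin_t = np.sqrt(1.0 - cos_t**2)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    weight = np.ones(n)

    if config.bias is not None:
        bias = config.bias
        target = np.asarray(bias.target, dtype=float) - np.asarray(src.position, dtype=float)
        dist = np.linalg.norm(target)
        axis = target / dist
        # cone that subtends the aim sphere with a 50% angular margin
        sin_half = min(1.0, bias.radius_cm / dist)
        theta0 = min(math.pi / 2, 1.5 * math.asin(sin_half))
        cos_theta0 = math.cos(theta0)
        omega_cone = 2.0 * math.pi * (1.0 - cos_theta0)
        u3 = rng.uniform(hist, c0 + _U64(3))
        u4 = rng.uniform(hist, c0 + _U64(4))
        take_cone = u3 < bias.q
        cos_c = 1.0 - u4 * (1.0 - cos_theta0)
        phi_c = 2.0 * np.pi * u1  # reuse an independent uniform stream slot
        cone_dirs = _rotate(np.broadcast_to(axis, (n, 3)).copy(), cos_c, phi_c)
        dirs = np.where(take_cone[:, None], cone_dirs, dirs)
        mu_axis = dirs @ axis
        in_cone = mu_axis >= cos_theta0 - 1e-12
        pdf = (1.0 - bias.q) / (4.0 * math.pi) + np.where(in_cone, bias.q / omega_cone, 0.0)
        weight = (1.0 / (4.0 * math.pi)) / pdf
    return energy, dirs, weight


def _run_chunk(config, scene, lut, rng, hist, acc, ledger, volumes):
    src_pos = np.asarray(config.source.position, dtype=float)
    energy, dirs, weight = _emit(config, rng, hist)
    n = len(hist)
    pos = np.broadcast_to(src_pos, (n, 3)).copy()
    ctr = np.full(n, 5, dtype=np.uint64)
    alive = np.ones(n, dtype=bool)
    n_coll = np.zeros(n, dtype=np.int32)
    tau = np.zeros(n)
    need_tau = np.ones(n, dtype=bool)
    csda = config.electron_model == "simple_csda"
    electrons: list[tuple[np.ndarray, ...]] = []
    tally_set = set(volumes)
    if csda:
        # electron-source neighborhood: within reach of any tally region
        centers = np.array([np.asarray(scene.regions[i].solid.center, dtype=float) for i in tally_set])
        reach = np.array([_bounding_radius(scene.regions[i].solid) for i in tally_set]) + 1.2

    ledger.emitted += float((weight * energy).sum())

    for _ in range(config.max_segments):
        if not alive.any():
            break
        idx = np.nonzero(alive)[0]
        # draw a fresh optical depth where the previous flight ended
        fresh = idx[need_tau[idx]]
        if len(fresh):
            u = rng.uniform(hist[fresh], ctr[fresh])
            ctr[fresh] += _U64(1)
            tau[fresh] = -np.log(u)
            need_tau[fresh] = False

        reg = scene.locate(pos[idx])
        out = reg == OUTSIDE
        if out.any():
            kill = idx[out]
            ledger.escaped += float((weight[kill] * energy[kill]).sum())
            alive[kill] = False
            idx = idx[~out]
            reg = reg[~out]
            if len(idx) == 0:
                continue

        mu = lut.mu_linear(reg, energy[idx])
        t_bound = scene.distance_to_boundary(pos[idx], dirs[idx])
        with np.errstate(divide="ignore"):
            s_int = np.where(mu > 0, tau[idx] / np.where(mu > 0, mu, 1.0), np.inf)
        interacting = s_int <= t_bound
        step = np.where(interacting, s_int, t_bound)

        # escape guard: photons in an unbounded void marching to infinity
        runaway = ~np.isfinite(step)
        if runaway.any():
            kill = idx[runaway]
            ledger.escaped += float((weight[kill] * energy[kill]).sum())
            alive[kill] = False
            keep = ~runaway
            idx, reg, mu, step, interacting = (
                idx[keep],
                reg[keep],
                mu[keep],
                step[keep],
                interacting[keep],
            )
            if len(idx) == 0:
                continue

        # track-length scoring
        scoreable = np.ones(len(idx), dtype=bool)
        if config.primary_only:
            scoreable = n_coll[idx] == 0
        for t_i in tally_set:
            m = (reg == t_i) & scoreable
            if m.any():
                sel = idx[m]
                mu_en = lut.mu_en_mass(reg[m], energy[sel])
                chord = step[m]
                acc.fluence[t_i] += float((weight[sel] * chord).sum()) / volumes[t_i]
                if not csda:
                    acc.dose[t_i] += (
                        float((weight[sel] * energy[sel] * mu_en * chord).sum()) / volumes[t_i]
                    )
                acc.count[t_i] += int(m.sum())

        if csda:
            # expected electron emission from every chord near the tallies:
            # w * mu_tot * l electrons of mean energy E * mu_tr / mu_tot,
            # launched forward from the chord midpoint
            mid = pos[idx] + 0.5 * step[:, None] * dirs[idx]
            near = np.zeros(len(idx), dtype=bool)
            for c, rr in zip(centers, reach):
                d2 = np.einsum("ij,ij->i", mid - c, mid - c)
                # a segment qualifies when its midpoint lies within reach,
                # padded by half its length so long chords are not missed
                pad = rr + 0.5 * np.where(np.isfinite(step), step, 0.0)
                near |= d2 <= pad * pad
            emit = near & (mu > 0) & np.isfinite(step)
            if emit.any():
                sel = idx[emit]
                # launch point sampled uniformly along the chord keeps the
                # spatial emission density unbiased for chords longer than
                # the electron range
                u_pos = rng.uniform(hist[sel], ctr[sel])
                ctr[sel] += _U64(1)
                birth = pos[sel] + (u_pos * step[emit])[:, None] * dirs[sel]
                # two electron components per chord: photoelectrons carry
                # the full photon energy (their long range in high-Z media
                # drives electrode overresponse), Compton recoils the mean
                # Klein-Nishina transfer
                ch = lut.channel_cdf_rows(reg[emit], energy[sel])
                frac_pe = ch[:, 0]
                frac_inc = ch[:, 1] - ch[:, 0]
                mu_seg = mu[emit] * step[emit]
                n_pe = weight[sel] * mu_seg * frac_pe
                n_inc = weight[sel] * mu_seg * frac_inc
                e_rec = energy[sel] * lut.compton_transfer_fraction(energy[sel])
                for e_pack, n_pack in ((energy[sel], n_pe), (e_rec, n_inc)):
                    ok = (e_pack > 1e-4) & (n_pack > 0)
                    if ok.any():
                        electrons.append(
                            (birth[ok], dirs[sel][ok].copy(), e_pack[ok].copy(), n_pack[ok])
                        )

        pos[idx] += (step + _PUSH)[:, None] * dirs[idx]
        tau[idx] -= mu * np.minimum(step, t_bound)

        # interactions
        hit = idx[interacting]
        if len(hit) == 0:
            continue
        need_tau[hit] = True
        reg_hit = reg[interacting]
        cdf = lut.partial_cum[reg_hit]  # (k, 4, nE) -> interpolate
        e_hit = energy[hit]
        ch_cdf = lut.channel_cdf_rows(reg_hit, e_hit)
        u_ch = rng.uniform(hist[hit], ctr[hit])
        ctr[hit] += _U64(1)
        channel = (u_ch[:, None] > ch_cdf).sum(axis=1)

        # collision-site kerma estimator (cross-check of the track-length one)
        if not config.primary_only:
            for t_i in tally_set:
                m = reg_hit == t_i
                if m.any():
                    sel = hit[m]
                    mu_en = lut.mu_en_mass(reg_hit[m], energy[sel])
                    mu_l = lut.mu_linear(reg_hit[m], energy[sel])
                    acc.collision[t_i] += (
                        float((weight[sel] * energy[sel] * mu_en / mu_l).sum()) / volumes[t_i]
                    )
        n_coll[hit] += 1

        # photoelectric: local absorption
        pe = hit[channel == 0]
        if len(pe):
            ledger.transferred += float((weight[pe] * energy[pe]).sum())
            alive[pe] = False

        # incoherent (Compton)
        inc = hit[channel == 1]
        if len(inc):
            x = _sample_kn_x_counter(energy[inc], rng, hist[inc], ctr, inc)
            a = energy[inc] / ELECTRON_REST_MEV
            cos_t = 1.0 - (1.0 / x - 1.0) / a
            u_phi = rng.uniform(hist[inc], ctr[inc])
            ctr[inc] += _U64(1)
            phi = 2.0 * np.pi * u_phi
            e_new = x * energy[inc]
            e_electron = energy[inc] - e_new
            ledger.transferred += float((weight[inc] * e_electron).sum())
            dirs[inc] = _rotate(dirs[inc], cos_t, phi)
            energy[inc] = e_new
            low = inc[e_new < config.photon_cutoff_mev]
            if len(low):
                ledger.discarded += float((weight[low] * energy[low]).sum())
                alive[low] = False
            if config.primary_only:
                alive[inc] = False

        # coherent: direction change only (Thomson angular law)
        coh = hit[channel == 2]
        if len(coh):
            cos_t = _sample_thomson_counter(rng, hist[coh], ctr, coh)
            u_phi = rng.uniform(hist[coh], ctr[coh])
            ctr[coh] += _U64(1)
            dirs[coh] = _rotate(dirs[coh], cos_t, 2.0 * np.pi * u_phi)
            if config.primary_only:
                alive[coh] = False

        # pair production: electron energy local, annihilation discarded
        pp = hit[channel == 3]
        if len(pp):
            e_el = energy[pp] - PAIR_THRESHOLD_MEV
            ledger.transferred += float((weight[pp] * e_el).sum())
            ledger.discarded += float((weight[pp] * PAIR_THRESHOLD_MEV).sum())
            alive[pp] = False
    else:
        # segment cap reached: retire stragglers as escaped
        rest = np.nonzero(alive)[0]
        ledger.escaped += float((weight[rest] * energy[rest]).sum())
        alive[rest] = False

    if csda and electrons:
        e_pos = np.concatenate([e[0] for e in electrons])
        e_dir = np.concatenate([e[1] for e in electrons])
        e_en = np.concatenate([e[2] for e in electrons])
        e_w = np.concatenate([e[3] for e in electrons])
        _deposit_electrons(scene, lut, e_pos, e_dir, e_en, e_w, acc, volumes)


def _sample_kn_x_counter(e, rng, hist, ctr, idx):
    a = e / ELECTRON_REST_MEV
    x_min = 1.0 / (1.0 + 2.0 * a)
    f_max = x_min + 1.0 / x_min
    out = np.empty_like(e)
    pending = np.arange(len(e))
    while len(pending):
        h = hist[pending]
        c = ctr[idx[pending]]
        u1 = rng.uniform(h, c)
        u2 = rng.uniform(h, c + _U64(1))
        ctr[idx[pending]] += _U64(2)
        x = x_min[pending] + (1.0 - x_min[pending]) * u1
        accept = u2 * f_max[pending] <= _kn_density(a[pending], x)
        out[pending[accept]] = x[accept]
        pending = pending[~accept]
    return out


def _sample_thomson_counter(rng, hist, ctr, idx):
    out = np.empty(len(hist))
    pending = np.arange(len(hist))
    while len(pending):
        h = hist[pending]
        c = ctr[idx[pending]]
        u1 = rng.uniform(h, c)
        u2 = rng.uniform(h, c + _U64(1))
        ctr[idx[pending]] += _U64(2)
        cos_t = 2.0 * u1 - 1.0
        accept = 2.0 * u2 <= 1.0 + cos_t**2
        out[pending[accept]] = cos_t[accept]
        pending = pending[~accept]
    return out


def _deposit_electrons(scene, lut, pos, dirs, energy, weight, acc, volumes):
    """Straight-line continuous slowing-down deposition.

    Electrons deposit ``E0 * (rho * ds) / R_csda(E0)`` per path element,
    with the range taken from the water CSDA table and scaled only by
    local density (water-equivalent media assumption)."""
    alive = energy > 1e-4
    pos = pos[alive].copy()
    dirs = dirs[alive]
    e0 = energy[alive]
    w = weight[alive]
    if len(e0) == 0:
        return
    r_total = np.maximum(_xsec.electron_csda_range_water(e0), 1e-8)  # g/cm^2
    remaining = r_total.copy()
    active = np.ones(len(e0), dtype=bool)
    for _ in range(300):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        reg = scene.locate(pos[idx])
        out = reg == OUTSIDE
        if out.any():
            active[idx[out]] = False
            idx = idx[~out]
            reg = reg[~out]
            if len(idx) == 0:
                continue
        rho = lut.density[reg]
        t_bound = scene.distance_to_boundary(pos[idx], dirs[idx])
        with np.errstate(divide="ignore"):
            t_range = np.where(rho > 0, remaining[idx] / np.where(rho > 0, rho, 1.0), np.inf)
        step = np.minimum(t_bound, t_range)
        step = np.where(np.isfinite(step), step, t_bound)
        for t_i in volumes:
            m = reg == t_i
            if m.any():
                sel = idx[m]
                path_g = step[m] * rho[m]
                dep = w[sel] * e0[sel] * path_g / r_total[sel]
                acc.dose[t_i] += float(dep.sum()) / (volumes[t_i] * lut.density[t_i])
                acc.count[t_i] += int(m.sum())
        remaining[idx] -= step * rho
        pos[idx] += (step + _PUSH)[:, None] * dirs[idx]
        done = remaining[idx] <= 1e-10
        active[idx[done]] = False
    # stragglers beyond the iteration cap deposit nothing further
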