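"""Monte-Carlo random-walk simulation of water diffusion and PGSE signal synthesis.

Walkers take fixed-length steps l = sqrt(6 D dt) in uniformly random 3D
directions inside a substrate geometry; boundaries are impermeable and
resolved by specular reflection.  A pulsed-gradient spin-echo (PGSE) sequence
with ideal rectangular bipolar lobes accrues per-walker phase
phi_j = gamma * sum_t G(t) (r_j(t) . n) dt, and the normalized signal is the
ensemble mean of Re(exp(i phi_j)).

Units: lengths in um, time in ms, diffusivities in um^2/ms (numerically equal
to 1e-3 mm^2/s), b-values in s/mm^2.

Three substrate families model the cervical microstructure:

* ``Sphere`` — water inside a reflecting sphere (cells, radii 5-12 um),
* ``CrossingRods`` — water *between* tightly packed solid rods stacked in
  slabs whose axes cross at small angles (collagen fiber bundles),
* ``ParallelTubes`` — water *inside* a parallel hollow cylinder
  (muscle fibers).

The free parameters the substrates need but the tissue literature does not pin
down (rod radius and spacing, tube calibre, intrinsic diffusivity inside
fibers, PGSE timing) were calibrated once against the simulated
axial/radial-diffusivity working points of the model design and frozen in
``FROZEN_TIMING`` / ``frozen_collagen_config`` / ``frozen_muscle_config``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "SimConfig",
    "PGSETiming",
    "PulseSequence",
    "WalkerEnsemble",
    "Unbounded",
    "Sphere",
    "ParallelTubes",
    "CrossingRods",
    "FROZEN_TIMING",
    "FREE_WATER_D",
    "step_length",
    "propagate",
    "accrue_phase",
    "synthesize_signal",
    "simulate_scheme",
    "fit_single_tensor",
    "sphere_adc_sweep",
    "frozen_collagen_config",
    "frozen_muscle_config",
]

#: free water diffusivity at 37 degC, 1e-3 mm^2/s (um^2/ms)
FREE_WATER_D = 3.0

#: seed density used when sizing walker ensembles from substrate volume
DEFAULT_SEED_DENSITY = 10.0  # walkers per um^3

#: minimum ensemble size for signal synthesis regardless of substrate volume
MIN_WALKERS = 10_000

_MAX_BOUNCES = 32
_EPS = 1e-9


def step_length(d_intrinsic: float, dt: float) -> float:
    """Fixed random-walk step l = sqrt(6 D dt) (um for D in um^2/ms, dt in ms)."""
    if d_intrinsic < 0:
        raise ValueError("diffusivity must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return math.sqrt(6.0 * d_intrinsic * dt)


@dataclass(frozen=True)
class SimConfig:
    """Random-walk parameters: time step (ms), intrinsic D (um^2/ms), size, seed."""

    duration: float  # total simulated time, ms
    dt: float = 1.0
    d_intrinsic: float = FREE_WATER_D
    n_walkers: int = MIN_WALKERS
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.d_intrinsic < 0:
            raise ValueError("d_intrinsic must be >= 0")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


# ---------------------------------------------------------------------------
# substrate geometries
# ---------------------------------------------------------------------------

class Unbounded:
    """Free diffusion: no boundaries."""

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.zeros((n, 3))

    def move(self, pos: np.ndarray, disp: np.ndarray) -> np.ndarray:
        return pos + disp

    def contains(self, pos: np.ndarray) -> np.ndarray:
        return np.ones(len(pos), dtype=bool)

    def free_volume(self) -> float | None:
        return None


class Sphere:
    """Impermeable reflecting sphere; walkers live inside (cell model)."""

    def __init__(self, radius: float):
        if radius <= 0:
            raise ValueError("radius must be > 0")
        self.radius = float(radius)

    def free_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    def sample_positions(self, n, rng):
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = self.radius * rng.random(n) ** (1.0 / 3.0)
        return u * r[:, None]

    def contains(self, pos):
        return np.einsum("ij,ij->i", pos, pos) <= self.radius**2 * (1 + 1e-9)

    def move(self, pos, disp):
        p = pos.copy()
        d = disp.copy()
        r2 = self.radius**2
        for _ in range(_MAX_BOUNCES):
            tgt = p + d
            out = np.einsum("ij,ij->i", tgt, tgt) > r2
            if not out.any():
                return tgt
            p[~out] = tgt[~out]
            d[~out] = 0.0
            po, do = p[out], d[out]
            a = np.einsum("ij,ij->i", do, do)
            b = 2.0 * np.einsum("ij,ij->i", po, do)
            c = np.einsum("ij,ij->i", po, po) - r2
            disc = np.maximum(b * b - 4 * a * c, 0.0)
            t = (-b + np.sqrt(disc)) / (2 * a)
            t = np.clip(t, 0.0, 1.0)
            hit = po + t[:, None] * do
            nrm = hit / np.linalg.norm(hit, axis=1, keepdims=True)
            rem = (1.0 - t)[:, None] * do
            rem -= 2.0 * np.einsum("ij,ij->i", rem, nrm)[:, None] * nrm
            # nudge inward so the next quadratic starts strictly inside
            p[out] = hit * (1.0 - _EPS)
            d[out] = rem
        # residual sub-steps after the bounce cap are dropped (walker stays put)
        return p


class ParallelTubes:
    """Water inside an impermeable hollow cylinder along z (muscle-fiber model).

    Tubes in the bundle are parallel and do not exchange water, so a single
    tube represents the bundle.  ``lattice_spacing`` records the packing used
    to convert seed density to walker counts; it does not affect trajectories.
    """

    def __init__(self, inner_radius: float, lattice_spacing: float | None = None):
        if inner_radius <= 0:
            raise ValueError("inner_radius must be > 0")
        if lattice_spacing is not None and lattice_spacing < 2 * inner_radius:
            raise ValueError("lattice_spacing must be >= tube diameter")
        self.inner_radius = float(inner_radius)
        self.lattice_spacing = lattice_spacing

    def free_volume(self) -> None:
        return None  # infinite cylinder; use the MIN_WALKERS floor

    def sample_positions(self, n, rng):
        theta = rng.random(n) * 2 * math.pi
        r = self.inner_radius * np.sqrt(rng.random(n))
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)])

    def contains(self, pos):
        r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
        return r2 <= self.inner_radius**2 * (1 + 1e-9)

    def move(self, pos, disp):
        out3 = pos + disp
        p = pos[:, :2].copy()
        d = disp[:, :2].copy()
        r2 = self.inner_radius**2
        for _ in range(_MAX_BOUNCES):
            tgt = p + d
            out = np.einsum("ij,ij->i", tgt, tgt) > r2
            if not out.any():
                p = tgt
                break
            p[~out] = tgt[~out]
            d[~out] = 0.0
            po, do = p[out], d[out]
            a = np.einsum("ij,ij->i", do, do)
            b = 2.0 * np.einsum("ij,ij->i", po, do)
            c = np.einsum("ij,ij->i", po, po) - r2
            disc = np.maximum(b * b - 4 * a * c, 0.0)
            t = np.clip((-b + np.sqrt(disc)) / (2 * a), 0.0, 1.0)
            hit = po + t[:, None] * do
            nrm = hit / np.linalg.norm(hit, axis=1, keepdims=True)
            rem = (1.0 - t)[:, None] * do
            rem -= 2.0 * np.einsum("ij,ij->i", rem, nrm)[:, None] * nrm
            p[out] = hit * (1.0 - _EPS)
            d[out] = rem
        out3[:, :2] = p  # axial (z) motion is unrestricted
        return out3


class CrossingRods:
    """Water between solid impermeable rods whose axes cross at small angles.

    Rods are packed in slabs stacked along y (slab k occupies
    ``y in [k h, (k+1) h)``); within a slab the rods are parallel, lying in the
    slab mid-plane with axes tilted in the x-z plane by ``angles_deg[k % len]``
    from z and spaced ``spacing`` apart transversely.  Consecutive slabs
    therefore cross at angles spanning 0 up to
    ``max(angles) - min(angles)`` degrees.  Walkers move in the pore space
    outside the rods; segment-cylinder intersection (continuous collision
    detection) prevents tunneling through rods thinner than a step.
    """

    def __init__(
        self,
        rod_radius: float = 1.0,
        spacing: float = 2.4,
        slab_height: float | None = None,
        angles_deg: tuple[float, ...] = (-10.0, 0.0, 10.0),
    ):
        if rod_radius <= 0 or spacing <= 0:
            raise ValueError("rod_radius and spacing must be > 0")
        if spacing <= 2 * rod_radius:
            raise ValueError("spacing must exceed the rod diameter")
        self.rod_radius = float(rod_radius)
        self.spacing = float(spacing)
        self.slab_height = float(slab_height) if slab_height else 2.0 * rod_radius
        if self.slab_height < 2 * rod_radius:
            raise ValueError("slab_height must be >= rod diameter")
        self.angles_deg = tuple(float(a) for a in angles_deg)
        th = np.radians(self.angles_deg)
        # rod axis u and in-slab transverse direction w, both in the x-z plane
        self._u = np.column_stack([np.sin(th), np.zeros(len(th)), np.cos(th)])
        self._w = np.column_stack([np.cos(th), np.zeros(len(th)), -np.sin(th)])

    @property
    def crossing_angle_deg(self) -> float:
        return max(self.angles_deg) - min(self.angles_deg)

    def free_fraction(self) -> float:
        """Water volume fraction of the lattice."""
        return 1.0 - math.pi * self.rod_radius**2 / (self.spacing * self.slab_height)

    def free_volume(self) -> None:
        return None  # infinite lattice; use the MIN_WALKERS floor

    # -- geometry helpers ----------------------------------------------------
    def _slab_frames(self, k: np.ndarray):
        idx = np.mod(k, len(self.angles_deg)).astype(int)
        return self._u[idx], self._w[idx]

    def _min_rod_dist2(self, pos: np.ndarray) -> np.ndarray:
        """Squared distance from each point to the nearest rod surface axis."""
        y = pos[:, 1]
        k0 = np.floor(y / self.slab_height).astype(int)
        best = np.full(len(pos), np.inf)
        for dk in (-1, 0, 1):
            k = k0 + dk
            u, w = self._slab_frames(k)
            yk = (k + 0.5) * self.slab_height
            v = np.einsum("ij,ij->i", pos, w)
            dv = v - self.spacing * np.round(v / self.spacing)
            dy = y - yk
            best = np.minimum(best, dv * dv + dy * dy)
        return best

    def contains(self, pos):
        return self._min_rod_dist2(pos) >= self.rod_radius**2 * (1 - 1e-9)

    def sample_positions(self, n, rng):
        span_xz = 20.0 * self.spacing
        span_y = 4.0 * len(self.angles_deg) * self.slab_height
        out = np.empty((n, 3))
        have = 0
        while have < n:
            cand = rng.random((2 * (n - have) + 16, 3))
            cand[:, 0] *= span_xz
            cand[:, 2] *= span_xz
            cand[:, 1] *= span_y
            ok = cand[self.contains(cand)]
            take = min(len(ok), n - have)
            out[have : have + take] = ok[:take]
            have += take
        return out

    def _first_hit(self, p: np.ndarray, d: np.ndarray):
        """Earliest segment-rod intersection.

        Returns (t, normal) with t = inf where the full step is collision-free.
        """
        n = len(p)
        r2 = self.rod_radius**2
        y0, y1 = p[:, 1], p[:, 1] + d[:, 1]
        ylo = np.minimum(y0, y1) - self.rod_radius
        step_ext = np.linalg.norm(d, axis=1).max() if n else 0.0
        n_k = int(math.ceil((step_ext + 2 * self.rod_radius) / self.slab_height)) + 2
        k_base = np.floor(ylo / self.slab_height - 0.5).astype(int)

        t_best = np.full(n, np.inf)
        nrm_best = np.zeros((n, 3))
        for ok in range(n_k):
            k = k_base + ok
            u, w = self._slab_frames(k)
            yk = (k + 0.5) * self.slab_height
            v0 = np.einsum("ij,ij->i", p, w)
            dv = np.einsum("ij,ij->i", d, w)
            ay0 = p[:, 1] - yk
            ady = d[:, 1]
            vlo = np.minimum(v0, v0 + dv) - self.rod_radius
            m_base = np.floor(vlo / self.spacing - 0.5).astype(int) + 1
            n_m = int(math.ceil((step_ext + 2 * self.rod_radius) / self.spacing)) + 2
            for om in range(n_m):
                m = m_base + om
                rel_v = v0 - m * self.spacing
                A = dv * dv + ady * ady
                B = 2.0 * (rel_v * dv + ay0 * ady)
                C = rel_v * rel_v + ay0 * ay0 - r2
                disc = B * B - 4 * A * C
                valid = (disc > 0) & (A > 0)
                sq = np.sqrt(np.where(valid, disc, 0.0))
                t = np.where(valid, (-B - sq) / (2 * A), np.inf)
                # starting on/inside the surface moving inward: immediate hit
                t = np.where(valid & (C <= 0) & (B < 0), 0.0, t)
                t = np.where((t >= 0.0) & (t <= 1.0), t, np.inf)
                better = t < t_best
                if better.any():
                    tb = t[better]
                    hit = p[better] + tb[:, None] * d[better]
                    ub, wb = u[better], w[better]
                    rv = np.einsum("ij,ij->i", hit, wb) - m[better] * self.spacing
                    ry = hit[:, 1] - yk[better]
                    radial = rv[:, None] * wb
                    radial[:, 1] += ry
                    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
                    t_best[better] = tb
                    nrm_best[better] = radial
        return t_best, nrm_best

    def move(self, pos, disp):
        p = pos.copy()
        d = disp.copy()
        active = np.ones(len(p), dtype=bool)
        for _ in range(_MAX_BOUNCES):
            ia = np.flatnonzero(active)
            if ia.size == 0:
                break
            t, nrm = self._first_hit(p[ia], d[ia])
            hit = np.isfinite(t)
            done = ia[~hit]
            p[done] += d[done]
            active[done] = False
            ih = ia[hit]
            if ih.size == 0:
                break
            th = t[hit]
            nh = nrm[hit]
            hp = p[ih] + th[:, None] * d[ih]
            rem = (1.0 - th)[:, None] * d[ih]
            rem -= 2.0 * np.einsum("ij,ij->i", rem, nh)[:, None] * nh
            # nudge off the surface along the outward normal
            p[ih] = hp + 10 * _EPS * self.rod_radius * nh
            d[ih] = rem
        # walkers still bouncing after the cap drop their residual sub-step
        return p


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

@dataclass
class WalkerEnsemble:
    """Recorded trajectories (n_walkers, n_steps + 1, 3) plus accrued phases."""

    trajectories: np.ndarray
    dt: float
    d_intrinsic: float
    phases: np.ndarray | None = None

    @property
    def n_walkers(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_steps(self) -> int:
        return self.trajectories.shape[1] - 1


def propagate(config: SimConfig, geometry) -> WalkerEnsemble:
    """Random-walk all walkers through the geometry, recording every position.

    Steps have fixed length sqrt(6 D dt) in uniformly random directions;
    boundary interactions are specular reflections (multiple bounces per step
    allowed).  Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_walkers, config.n_steps
    l = step_length(config.d_intrinsic, config.dt)
    pos = geometry.sample_positions(n, rng)
    if not geometry.contains(pos).all():
        raise RuntimeError("walker initialization produced out-of-domain seeds")
    traj = np.empty((n, T + 1, 3))
    traj[:, 0] = pos
    for k in range(T):
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = geometry.move(pos, l * u)
        traj[:, k + 1] = pos
    return WalkerEnsemble(traj, config.dt, config.d_intrinsic)


# ---------------------------------------------------------------------------
# PGSE encoding
# ---------------------------------------------------------------------------

GAMMA_PROTON = 2.6752218744e8  # rad / (s T)

# Calibrated default timing: near-narrow-pulse lobes on the 1 ms step grid with
# an effective diffusion time Delta - delta/3 ~ 52.7 ms that places the
# reflecting-sphere ADC sweep (radii 5-12 um) onto the working endpoints of the
# cell model (0.089 and 0.612 um^2/ms).
FROZEN_DELTA_SMALL = 1.0  # gradient lobe duration delta, ms
FROZEN_DELTA_BIG = 53.0  # lobe separation Delta, ms


@dataclass(frozen=True)
class PGSETiming:
    delta_small: float = FROZEN_DELTA_SMALL  # ms
    delta_big: float = FROZEN_DELTA_BIG  # ms

    def __post_init__(self):
        if self.delta_small <= 0 or self.delta_big <= 0:
            raise ValueError("timings must be > 0")
        if self.delta_small > self.delta_big:
            raise ValueError("require delta <= Delta")

    @property
    def effective_diffusion_time(self) -> float:
        return self.delta_big - self.delta_small / 3.0

    @property
    def duration(self) -> float:
        return self.delta_big + self.delta_small


FROZEN_TIMING = PGSETiming()


@dataclass(frozen=True)
class PulseSequence:
    """One bipolar PGSE encoding: timing, target b-value, direction."""

    bvalue: float  # s/mm^2
    direction: np.ndarray  # unit 3-vector
    timing: PGSETiming = FROZEN_TIMING
    gamma: float = GAMMA_PROTON

    def __post_init__(self):
        if self.bvalue < 0:
            raise ValueError("bvalue must be >= 0")
        d = np.asarray(self.direction, dtype=float).ravel()
        if self.bvalue > 0:
            nrm = np.linalg.norm(d)
            if not math.isclose(nrm, 1.0, rel_tol=0, abs_tol=1e-6):
                raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "direction", d)

    def waveform(self, dt: float) -> np.ndarray:
        """Sampled bipolar lobe signs (+1 / -1 / 0) on the step grid."""
        n_small = int(round(self.timing.delta_small / dt))
        n_big = int(round(self.timing.delta_big / dt))
        if n_small < 1:
            raise ValueError("delta smaller than one time step")
        w = np.zeros(n_big + n_small)
        w[:n_small] = 1.0
        w[n_big : n_big + n_small] = -1.0
        return w


def _discrete_b_matrix(w: np.ndarray) -> float:
    """sum_{m,m'} w_m w_m' min(m, m') over step indices (1-based).

    For the fixed-step random walk, the per-axis position covariance between
    step m and m' is 2 D dt min(m, m'), so a unit-amplitude waveform attenuates
    free diffusion by exp(-a^2 dt M D): the discrete analogue of the PGSE
    b-factor.  The gradient amplitude is scaled so a^2 dt M equals the
    requested b exactly, making exp(-b D) hold for free diffusion up to
    Monte-Carlo error.
    """
    m = np.arange(1, len(w) + 1, dtype=float)
    return float(w @ np.minimum.outer(m, m) @ w)


def accrue_phase(ensemble: WalkerEnsemble, seq: PulseSequence) -> WalkerEnsemble:
    """Accumulate per-walker PGSE phase along the recorded trajectories."""
    w = seq.waveform(ensemble.dt)
    if len(w) > ensemble.n_steps:
        raise ValueError(
            f"sequence needs {len(w)} steps but trajectory has {ensemble.n_steps}"
        )
    if seq.bvalue == 0:
        phases = np.zeros(ensemble.n_walkers)
    else:
        b_int = seq.bvalue / 1000.0  # s/mm^2 -> ms/um^2
        M = _discrete_b_matrix(w)
        amp = math.sqrt(b_int / (ensemble.dt * M))  # = gamma G dt, rad/um
        proj = ensemble.trajectories[:, 1 : len(w) + 1] @ np.asarray(seq.direction)
        phases = amp * (proj @ w)
    return WalkerEnsemble(ensemble.trajectories, ensemble.dt,
                          ensemble.d_intrinsic, phases)


def synthesize_signal(ensemble: WalkerEnsemble) -> float:
    """Normalized signal S = (1/N) sum_j Re(exp(i phi_j))."""
    if ensemble.n_walkers == 0:
        raise ValueError("empty ensemble")
    if ensemble.phases is None:
        raise ValueError("phases not accrued; call accrue_phase first")
    return float(np.mean(np.cos(ensemble.phases)))


def simulate_scheme(
    config: SimConfig,
    geometry,
    scheme: AcquisitionScheme,
    timing: PGSETiming = FROZEN_TIMING,
) -> np.ndarray:
    """One normalized signal per scheme row; b=0 rows are exactly 1.

    A single walker ensemble is propagated for the sequence duration and
    re-encoded for every (b, direction) row.
    """
    if not np.any(scheme.bvalues == 0):
        raise ValueError("scheme must contain a b=0 measurement")
    duration = timing.duration
    if config.duration < duration:
        config = replace(config, duration=duration)
    ens = propagate(config, geometry)
    signals = np.empty(scheme.n_measurements)
    for k in range(scheme.n_measurements):
        b = scheme.bvalues[k]
        if b == 0:
            signals[k] = 1.0
            continue
        seq = PulseSequence(b, scheme.bvectors[k], timing=timing)
        signals[k] = synthesize_signal(accrue_phase(ens, seq))
    return signals


def ensemble_size(geometry, density: float = DEFAULT_SEED_DENSITY,
                  floor: int = MIN_WALKERS) -> int:
    """Walker count from seed density x free volume, with an absolute floor."""
    vol = geometry.free_volume()
    if vol is None:
        return floor
    return max(int(round(density * vol)), floor)


# ---------------------------------------------------------------------------
# single-tensor analysis of simulated signals
# ---------------------------------------------------------------------------

def fit_single_tensor(signals: np.ndarray, scheme: AcquisitionScheme):
    """Log-linear least-squares diffusion-tensor fit.

    Returns ``(ad, rd, principal_direction, eigenvalues)`` with eigenvalues
    sorted descending; AD is the largest, RD the mean of the two minor ones.
    Diffusivities in 1e-3 mm^2/s.
    """
    s = np.asarray(signals, dtype=float)
    b = scheme.bvalues / 1000.0  # exponent scale for D in 1e-3 mm^2/s
    g = scheme.bvectors
    usable = s > 0
    if np.sum(usable & (scheme.bvalues > 0)) < 6:
        raise ValueError("need >= 6 positive diffusion-weighted signals")
    X = np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )[usable]
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design: directions are collinear")
    beta, *_ = np.linalg.lstsq(X, np.log(s[usable]), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    ad = float(evals[0])
    rd = float((evals[1] + evals[2]) / 2.0)
    return ad, rd, evecs[:, order[0]], evals


def sphere_adc_sweep(
    radii,
    scheme: AcquisitionScheme,
    timing: PGSETiming = FROZEN_TIMING,
    d_intrinsic: float = FREE_WATER_D,
    dt: float = 1.0,
    seed: int = 0,
    density: float = DEFAULT_SEED_DENSITY,
) -> np.ndarray:
    """Apparent diffusion coefficient of reflecting spheres over a radius sweep.

    Each radius gets its own ensemble (seed density x sphere volume, floored at
    10^4 walkers); the ADC is the mean tensor eigenvalue of the single-tensor
    fit.  ADC grows monotonically with radius at fixed timing.
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if radii.size == 0:
        raise ValueError("radii must be non-empty")
    adcs = np.empty(radii.size)
    for i, r in enumerate(radii):
        geom = Sphere(r)
        cfg = SimConfig(
            duration=timing.duration,
            dt=dt,
            d_intrinsic=d_intrinsic,
            n_walkers=ensemble_size(geom, density=density),
            seed=seed + i,
        )
        signals = simulate_scheme(cfg, geom, scheme, timing)
        _, _, _, evals = fit_single_tensor(signals, scheme)
        adcs[i] = float(np.mean(evals))
    return adcs


# ---------------------------------------------------------------------------
# frozen substrate configurations (calibrated once, see docs/methods.md)
# ---------------------------------------------------------------------------

def frozen_collagen_config(seed: int = 0) -> tuple[SimConfig, CrossingRods]:
    """Crossing solid-rod collagen substrate with calibrated free parameters."""
    geom = CrossingRods(
        rod_radius=1.0,
        spacing=2.3,
        slab_height=2.0,
        angles_deg=(-10.0, 0.0, 10.0),
    )
    cfg = SimConfig(
        duration=FROZEN_TIMING.duration,
        dt=1.0,
        d_intrinsic=1.45,
        n_walkers=MIN_WALKERS,
        seed=seed,
    )
    return cfg, geom


def frozen_muscle_config(seed: int = 0) -> tuple[SimConfig, ParallelTubes]:
    """Parallel hollow-tube muscle substrate with calibrated free parameters."""
    geom = ParallelTubes(inner_radius=10.8)
    cfg = SimConfig(
        duration=FROZEN_TIMING.duration,
        dt=1.0,
        d_intrinsic=1.69,
        n_walkers=MIN_WALKERS,
        seed=seed,
    )
    return cfg, geom
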