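"""Synthetic cervix DWI phantoms generated from the multi-tensor forward model.

A phantom is a small 3D grid of voxels with known per-compartment fractions
arranged in concentric cervix-like zones around a central canal: a
*subglandular* zone (high cellularity and collagen, adjacent to the canal) and
an *outer stroma* zone (lower density).  Each voxel's diffusion-weighted
signal is synthesized as the fraction-weighted sum of dictionary-atom
attenuations (fiber atoms oriented along a circumferential direction field),
scaled by s0, and optionally corrupted with Rician noise.  Ground-truth
fraction maps ride along, enabling download-free round-trip testing of the
spectrum inversion.

Two presets mirror the in vivo contrast between groups:

* ``"term"`` — low cell fraction (< 5%), collagen 10-15%, moderate free water;
* ``"preterm"`` — elevated cell fraction with a few 10% hot spots, collagen
  below 5%, higher muscle and free-water fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dictionary import TensorDictionary, build_default_dictionary
from .fitting import (
    COMPARTMENTS,
    FractionMaps,
    REPRESENTATIVE_FIBER,
    REPRESENTATIVE_ISO_D,
)
from .scheme import AcquisitionScheme, default_scheme

__all__ = [
    "PhantomSpec",
    "ZONE_FRACTIONS",
    "forward_voxel",
    "add_rician_noise",
    "make_cervix_phantom",
]

#: ground-truth compartment fractions per preset and zone
#: (cell, hindered, free, ivim, collagen, muscle) — each row sums to 1
ZONE_FRACTIONS: dict[str, dict[str, dict[str, float]]] = {
    "term": {
        "subglandular": {"cell": 0.045, "hindered": 0.415, "free": 0.25,
                         "ivim": 0.02, "collagen": 0.15, "muscle": 0.12},
        "outer_stroma": {"cell": 0.03, "hindered": 0.47, "free": 0.28,
                         "ivim": 0.02, "collagen": 0.11, "muscle": 0.09},
    },
    "preterm": {
        "subglandular": {"cell": 0.06, "hindered": 0.285, "free": 0.40,
                         "ivim": 0.02, "collagen": 0.045, "muscle": 0.19},
        "outer_stroma": {"cell": 0.05, "hindered": 0.365, "free": 0.38,
                         "ivim": 0.02, "collagen": 0.035, "muscle": 0.15},
    },
}

#: cell fraction of the sparse "hot spot" voxels in the preterm preset
HOT_SPOT_CELL_FRACTION = 0.10
N_HOT_SPOTS = 6


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, zonation, noise, and seed of a synthetic phantom."""

    preset: str = "term"
    shape: tuple[int, int, int] = (24, 24, 8)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    canal_radius_mm: float = 4.5
    subglandular_radius_mm: float = 15.0
    outer_radius_mm: float = 27.0
    snr: float | None = 50.0
    s0: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.preset not in ZONE_FRACTIONS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if not (0 < self.canal_radius_mm < self.subglandular_radius_mm
                < self.outer_radius_mm):
            raise ValueError("zone radii must be increasing and positive")
        half_extent = self.shape[0] * self.voxel_size_mm[0] / 2.0
        if self.outer_radius_mm > half_extent * np.sqrt(2):
            raise ValueError("zone radii exceed the grid")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0 (or None for noiseless)")

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in (
                "preset", "shape", "voxel_size_mm", "canal_radius_mm",
                "subglandular_radius_mm", "outer_radius_mm", "snr", "s0",
                "seed")},
            indent=1,
        )


def _nearest_iso_atom(dictionary: TensorDictionary, compartment: str,
                      target: float) -> float:
    """Diffusivity of the in-band atom closest to the target value."""
    band = {"cell": "restricted", "hindered": "hindered",
            "free": "free", "ivim": "ivim"}[compartment]
    ds = dictionary.iso_diffusivities()
    comps = dictionary.iso_compartments()
    in_band = ds[comps == band]
    if in_band.size == 0:
        raise ValueError(f"dictionary has no {band} atoms")
    return float(in_band[np.argmin(np.abs(in_band - target))])


def _nearest_fiber_model(dictionary: TensorDictionary, compartment: str,
                         target: tuple[float, float]) -> tuple[float, float]:
    models = [m for m in dictionary.anisotropic_models
              if m.compartment == compartment]
    if not models:
        raise ValueError(f"dictionary has no {compartment} models")
    d2 = [(m.ad - target[0]) ** 2 + (m.rd - target[1]) ** 2 for m in models]
    m = models[int(np.argmin(d2))]
    return m.ad, m.rd


def forward_voxel(
    fractions: dict[str, float],
    direction: np.ndarray,
    dictionary: TensorDictionary,
    scheme: AcquisitionScheme,
    s0: float = 1.0,
    iso_targets: dict[str, float] | None = None,
    fiber_targets: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Noise-free signal of one voxel under the multi-tensor forward model.

    Each compartment is represented by the dictionary atom nearest its target
    diffusivity within the compartment's band (isotropic) or the nearest
    (ad, rd) model (fibers); fiber atoms are oriented along the voxel's
    ``direction``.  Targets default to the canonical representatives shared
    with the fitting stage; override them (e.g. off-grid values) to probe
    model mismatch.
    """
    total = sum(fractions.get(c, 0.0) for c in COMPARTMENTS)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {total}")
    if any(fractions.get(c, 0.0) < 0 for c in COMPARTMENTS):
        raise ValueError("fractions must be >= 0")
    iso_targets = dict(REPRESENTATIVE_ISO_D, **(iso_targets or {}))
    fiber_targets = dict(REPRESENTATIVE_FIBER, **(fiber_targets or {}))
    b = scheme.bvalues / 1000.0
    sig = np.zeros(scheme.n_measurements)
    for comp in ("cell", "hindered", "free", "ivim"):
        f = fractions.get(comp, 0.0)
        if f <= 0:
            continue
        D = _nearest_iso_atom(dictionary, comp, iso_targets[comp])
        sig += f * np.exp(-b * D)
    aniso = any(fractions.get(c, 0.0) > 0 for c in ("collagen", "muscle"))
    if aniso:
        u = np.asarray(direction, dtype=float).ravel()
        nrm = np.linalg.norm(u)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError("direction must be unit norm where fibers present")
        cos_psi = scheme.bvectors @ u
        for comp in ("collagen", "muscle"):
            f = fractions.get(comp, 0.0)
            if f <= 0:
                continue
            ad, rd = _nearest_fiber_model(dictionary, comp, fiber_targets[comp])
            sig += f * np.exp(-b * rd) * np.exp(-b * (ad - rd) * cos_psi**2)
    return s0 * sig


def add_rician_noise(signal: np.ndarray, snr: float, seed, s0: float = 1.0
                     ) -> np.ndarray:
    """Magnitude-MRI (Rician) noise: sqrt((S + n1)^2 + n2^2), n ~ N(0, s0/snr).

    ``seed`` may be an int or a numpy Generator.  Deterministic given an int
    seed.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    s = np.asarray(signal, dtype=float)
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, s.shape)
    n2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)


def _zone_labels(spec: PhantomSpec) -> np.ndarray:
    """0 = canal/background (out of mask), 1 = subglandular, 2 = outer stroma."""
    nx, ny, _ = spec.shape
    dx, dy, _ = spec.voxel_size_mm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rho = np.hypot((i - cx) * dx, (j - cy) * dy)
    zone2d = np.zeros((nx, ny), dtype=int)
    zone2d[(rho >= spec.canal_radius_mm) & (rho < spec.subglandular_radius_mm)] = 1
    zone2d[(rho >= spec.subglandular_radius_mm) & (rho < spec.outer_radius_mm)] = 2
    return np.repeat(zone2d[:, :, None], spec.shape[2], axis=2)


def _circumferential_directions(spec: PhantomSpec) -> np.ndarray:
    """In-plane tangential unit vectors around the canal (muscle-like field)."""
    nx, ny, nz = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    phi = np.arctan2(j - cy, i - cx)
    u = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)
    return np.repeat(u[:, :, None, :], nz, axis=2)


def make_cervix_phantom(
    spec: PhantomSpec,
    dictionary: TensorDictionary | None = None,
    scheme: AcquisitionScheme | None = None,
):
    """Synthesize a zoned cervix phantom.

    Returns ``(dwi, truth, mask, scheme)``: the (X, Y, Z, K) signal volume
    (Rician noise at ``spec.snr`` unless None), ground-truth
    :class:`FractionMaps`, the in-tissue mask, and the scheme used.
    """
    if dictionary is None:
        dictionary = build_default_dictionary()
    if scheme is None:
        scheme = default_scheme()
    zones = _zone_labels(spec)
    dirs = _circumferential_directions(spec)
    mask = zones > 0
    rng = np.random.default_rng(spec.seed)

    fractions = {z: ZONE_FRACTIONS[spec.preset][name]
                 for z, name in ((1, "subglandular"), (2, "outer_stroma"))}
    truth_maps = {c: np.zeros(spec.shape, dtype=np.float32) for c in COMPARTMENTS}
    dwi = np.zeros(spec.shape + (scheme.n_measurements,), dtype=np.float32)

    # sparse cellularity hot spots in the preterm subglandular zone
    hot = np.zeros(spec.shape, dtype=bool)
    if spec.preset == "preterm":
        sg = np.argwhere(zones == 1)
        pick = rng.choice(len(sg), size=min(N_HOT_SPOTS, len(sg)), replace=False)
        hot[tuple(sg[pick].T)] = True

    # precompute the two zone signals (direction varies per voxel, so the
    # isotropic part is shared and the fiber part evaluated per voxel)
    for idx in np.argwhere(mask):
        i, j, k = idx
        frac = dict(fractions[zones[i, j, k]])
        if hot[i, j, k]:
            bump = HOT_SPOT_CELL_FRACTION - frac["cell"]
            frac["cell"] = HOT_SPOT_CELL_FRACTION
            frac["hindered"] -= bump
        sig = forward_voxel(frac, dirs[i, j, k], dictionary, scheme, spec.s0)
        if spec.snr is not None:
            sig = add_rician_noise(sig, spec.snr, rng, s0=spec.s0)
        dwi[i, j, k] = sig
        for c in COMPARTMENTS:
            truth_maps[c][i, j, k] = frac[c]

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    truth = FractionMaps(truth_maps, mask.copy(), affine)
    return dwi, truth, mask, scheme
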