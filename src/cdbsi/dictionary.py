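"""Tensor basis ("dictionary") for cervix-optimized diffusion basis spectrum imaging.

The per-voxel diffusion-weighted signal is modeled as a nonnegative linear
combination of fixed tensor basis functions:

* an **isotropic spectrum** — a dense grid of isotropic diffusivities split into
  four physiological bands (restricted / intracellular, hindered, free,
  IVIM pseudo-diffusion), and
* a set of **anisotropic tensor models** — axially symmetric tensors defined by
  an axial/radial diffusivity pair ``(ad, rd)``, each replicated over a set of
  principal directions distributed uniformly on the hemisphere.

The default build carries 150 isotropic atoms (grid 0.0-14.9 in steps of 0.1,
units 1e-3 mm^2/s) and 9 anisotropic models x 25 directions = 225 anisotropic
atoms.  Models #2-#3 represent muscle fibers, #5-#7 collagen fibers, and the
rest other connective-tissue structure.  All diffusivities are referenced to
37 degC; a multiplicative temperature factor (derived from published water
self-diffusion data) rescales the whole dictionary for ex vivo work at room
temperature.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "IsotropicAtom",
    "AnisotropicModel",
    "DirectionSet",
    "TensorDictionary",
    "ISO_BANDS",
    "MUSCLE_MODEL_IDS",
    "COLLAGEN_MODEL_IDS",
    "DEFAULT_ANISOTROPIC_PAIRS",
    "WATER_SELF_DIFFUSION_TABLE",
    "REFERENCE_TEMPERATURE_C",
    "classify_isotropic",
    "repulsion_energy",
    "make_direction_set",
    "build_isotropic_spectrum",
    "build_anisotropic_models",
    "assemble_dictionary",
    "build_default_dictionary",
    "scale_temperature",
    "derive_temperature_factor",
]

REFERENCE_TEMPERATURE_C = 37.0

#: Isotropic diffusivity bands at the 37 degC reference, units 1e-3 mm^2/s.
#: Half-open on the low side: [lo, hi).
ISO_BANDS: dict[str, tuple[float, float]] = {
    "restricted": (0.0, 0.6),
    "hindered": (0.6, 3.0),
    "free": (3.0, 10.0),
    "ivim": (10.0, math.inf),
}

MUSCLE_MODEL_IDS = frozenset({2, 3})
COLLAGEN_MODEL_IDS = frozenset({5, 6, 7})

#: Default (ad, rd) pairs for the nine anisotropic models, 1e-3 mm^2/s at 37 degC.
#: Muscle models (#2, #3) tile AD 1.8-2.0 / RD 0.3-0.4; collagen models
#: (#5, #6, #7) tile AD 1.6-2.1 / RD 0.5-0.7; the remaining models cover other
#: connective-tissue structure.  All overridable via config.
DEFAULT_ANISOTROPIC_PAIRS: dict[int, tuple[float, float]] = {
    1: (1.2, 0.2),
    2: (1.8, 0.3),
    3: (2.0, 0.4),
    4: (1.4, 0.4),
    5: (1.6, 0.5),
    6: (1.8, 0.6),
    7: (2.1, 0.7),
    8: (2.4, 0.8),
    9: (1.0, 0.1),
}

#: Self-diffusion coefficient of pure water versus temperature, 1e-9 m^2/s
#: (numerically equal to 1e-3 mm^2/s).  Values follow the PGSE-NMR
#: measurements of Holz et al. (2000) and Easteal et al.; the 25 degC entry is
#: the benchmark 2.299e-9 m^2/s.
WATER_SELF_DIFFUSION_TABLE: tuple[tuple[float, float], ...] = (
    (5.0, 1.302),
    (10.0, 1.524),
    (15.0, 1.764),
    (20.0, 2.023),
    (25.0, 2.299),
    (30.0, 2.594),
    (35.0, 2.907),
    (40.0, 3.238),
)


def classify_isotropic(diffusivity: float) -> str:
    """Band label for an isotropic diffusivity (1e-3 mm^2/s at 37 degC)."""
    if diffusivity < 0:
        raise ValueError(f"negative diffusivity: {diffusivity}")
    for name, (lo, hi) in ISO_BANDS.items():
        if lo <= diffusivity < hi:
            return name
    raise AssertionError("bands must cover [0, inf)")


def _classify_model(model_id: int) -> str:
    if model_id in MUSCLE_MODEL_IDS:
        return "muscle"
    if model_id in COLLAGEN_MODEL_IDS:
        return "collagen"
    return "other"


@dataclass(frozen=True)
class IsotropicAtom:
    """One isotropic basis tensor: a single diffusivity with a band label."""

    diffusivity: float  # 1e-3 mm^2/s
    compartment: str

    def __post_init__(self):
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.compartment not in ISO_BANDS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class AnisotropicModel:
    """Axially symmetric tensor model: (axial, radial) diffusivity pair."""

    model_id: int
    ad: float  # axial diffusivity, 1e-3 mm^2/s
    rd: float  # radial diffusivity, 1e-3 mm^2/s
    compartment: str = ""

    def __post_init__(self):
        if not (1 <= self.model_id <= 9):
            raise ValueError("model_id must be in 1..9")
        if not (self.ad > self.rd > 0):
            raise ValueError(
                f"require ad > rd > 0, got ad={self.ad}, rd={self.rd}"
            )
        if not self.compartment:
            object.__setattr__(self, "compartment", _classify_model(self.model_id))


@dataclass(frozen=True)
class DirectionSet:
    """Antipodally non-redundant unit vectors, approximately uniform on the hemisphere."""

    vectors: np.ndarray  # (n, 3), unit rows

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vectors must be (n, 3)")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("direction vectors must be unit norm")
        if len(v) > 1:
            dots = np.abs(v @ v.T)
            np.fill_diagonal(dots, 0.0)
            if np.any(dots > 1.0 - 1e-12):
                raise ValueError("directions contain (anti)parallel duplicates")
        object.__setattr__(self, "vectors", v)

    @property
    def count(self) -> int:
        return len(self.vectors)

    def min_angle_deg(self) -> float:
        """Smallest pairwise angle, folding antipodes together."""
        if self.count < 2:
            return 180.0
        dots = np.clip(np.abs(self.vectors @ self.vectors.T), 0, 1)
        np.fill_diagonal(dots, 0.0)
        return float(np.degrees(np.arccos(dots.max())))


# ---------------------------------------------------------------------------
# direction-set optimization: electrostatic repulsion with antipodal symmetry
# ---------------------------------------------------------------------------

def repulsion_energy(vectors: np.ndarray) -> float:
    """Coulomb energy sum_{i<j} 1/|vi-vj| + 1/|vi+vj| of antipodal charge pairs."""
    v = np.asarray(vectors, dtype=float)
    n = len(v)
    if n < 2:
        return 0.0
    diff = v[:, None, :] - v[None, :, :]
    summ = v[:, None, :] + v[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    e = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(n, k=1)
    return float(np.sum(1.0 / d[iu]) + np.sum(1.0 / e[iu]))


def _energy_and_grad(x: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    v = x.reshape(n, 3)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    y = v / norms
    diff = y[:, None, :] - y[None, :, :]
    summ = y[:, None, :] + y[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    e = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(d, np.inf)
    np.fill_diagonal(e, np.inf)
    energy = 0.5 * np.sum(1.0 / d) + 0.5 * np.sum(1.0 / e)
    # dE/dy_i = sum_j -(y_i - y_j)/d^3 - (y_i + y_j)/e^3
    gd = -(diff / (d**3)[..., None]).sum(axis=1)
    ge = -(summ / (e**3)[..., None]).sum(axis=1)
    gy = gd + ge
    # project through the normalization y = v/|v|
    gv = (gy - (gy * y).sum(axis=1, keepdims=True) * y) / norms
    return float(energy), gv.ravel()


def make_direction_set(n: int, seed: int = 0, n_restarts: int = 8) -> DirectionSet:
    """Distribute ``n`` unit vectors uniformly on the hemisphere.

    Minimizes the Coulomb repulsion energy of ``n`` antipodal charge pairs
    (diffusion encoding is sign-invariant, so +/-v are the same direction)
    from several seeded random starts, keeping the lowest-energy layout.
    Deterministic for a given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return DirectionSet(np.array([[0.0, 0.0, 1.0]]))
    rng = np.random.default_rng(seed)
    best, best_e = None, np.inf
    for _ in range(n_restarts):
        x0 = rng.normal(size=(n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = minimize(
            _energy_and_grad,
            x0.ravel(),
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res.fun < best_e:
            best_e, best = res.fun, res.x.reshape(n, 3)
    v = best / np.linalg.norm(best, axis=1, keepdims=True)
    # canonical hemisphere: flip to z >= 0 (break ties on y, then x)
    flip = (v[:, 2] < 0) | ((v[:, 2] == 0) & (v[:, 1] < 0)) | (
        (v[:, 2] == 0) & (v[:, 1] == 0) & (v[:, 0] < 0)
    )
    v[flip] *= -1.0
    order = np.lexsort((v[:, 0], v[:, 1], -v[:, 2]))
    return DirectionSet(v[order])


# ---------------------------------------------------------------------------
# spectrum / model construction
# ---------------------------------------------------------------------------

def build_isotropic_spectrum(
    start: float = 0.0, step: float = 0.1, count: int = 150
) -> list[IsotropicAtom]:
    """Discretize the isotropic diffusivity spectrum into ``count`` atoms.

    The default uniform grid 0.0-14.9 (step 0.1, 1e-3 mm^2/s) covers all four
    bands: restricted [0, 0.6), hindered [0.6, 3), free [3, 10), IVIM >= 10.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if count < 1:
        raise ValueError("count must be >= 1")
    if start < 0:
        raise ValueError("start must be >= 0")
    ds = start + step * np.arange(count)
    return [IsotropicAtom(float(d), classify_isotropic(float(d))) for d in ds]


def build_anisotropic_models(
    pairs: dict[int, tuple[float, float]] | None = None,
) -> list[AnisotropicModel]:
    """Build the nine anisotropic (ad, rd) tensor models.

    ``pairs`` maps model_id -> (ad, rd); defaults to
    :data:`DEFAULT_ANISOTROPIC_PAIRS`.  Muscle models are #2-#3, collagen
    #5-#7, the rest labeled "other".
    """
    if pairs is None:
        pairs = DEFAULT_ANISOTROPIC_PAIRS
    return [
        AnisotropicModel(mid, float(ad), float(rd))
        for mid, (ad, rd) in sorted(pairs.items())
    ]


@dataclass(frozen=True)
class TensorDictionary:
    """The full fitting basis: isotropic spectrum + anisotropic models x directions."""

    isotropic_atoms: tuple[IsotropicAtom, ...]
    anisotropic_models: tuple[AnisotropicModel, ...]
    directions: DirectionSet
    temperature_celsius: float = REFERENCE_TEMPERATURE_C

    def __post_init__(self):
        if not self.isotropic_atoms and not self.anisotropic_models:
            raise ValueError("dictionary must contain at least one atom")

    # --- atom views -------------------------------------------------------
    @property
    def n_isotropic(self) -> int:
        return len(self.isotropic_atoms)

    @property
    def n_anisotropic(self) -> int:
        return len(self.anisotropic_models) * self.directions.count

    @property
    def n_atoms(self) -> int:
        return self.n_isotropic + self.n_anisotropic

    def iso_diffusivities(self) -> np.ndarray:
        return np.array([a.diffusivity for a in self.isotropic_atoms])

    def iso_compartments(self) -> np.ndarray:
        return np.array([a.compartment for a in self.isotropic_atoms])

    def aniso_atoms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Expanded anisotropic atoms as (ad, rd, direction, compartment) arrays.

        Atom ordering is model-major: all directions of model 1, then model 2, ...
        """
        nm = len(self.anisotropic_models)
        nd = self.directions.count
        ad = np.repeat([m.ad for m in self.anisotropic_models], nd)
        rd = np.repeat([m.rd for m in self.anisotropic_models], nd)
        comp = np.repeat([m.compartment for m in self.anisotropic_models], nd)
        dirs = np.tile(self.directions.vectors, (nm, 1))
        return ad, rd, dirs, comp

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "temperature_celsius": self.temperature_celsius,
            "isotropic_atoms": [
                {"diffusivity": a.diffusivity, "compartment": a.compartment}
                for a in self.isotropic_atoms
            ],
            "anisotropic_models": [
                {"model_id": m.model_id, "ad": m.ad, "rd": m.rd,
                 "compartment": m.compartment}
                for m in self.anisotropic_models
            ],
            "directions": self.directions.vectors.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "TensorDictionary":
        return cls(
            isotropic_atoms=tuple(
                IsotropicAtom(a["diffusivity"], a["compartment"])
                for a in d["isotropic_atoms"]
            ),
            anisotropic_models=tuple(
                AnisotropicModel(m["model_id"], m["ad"], m["rd"], m["compartment"])
                for m in d["anisotropic_models"]
            ),
            directions=DirectionSet(np.asarray(d["directions"], dtype=float)),
            temperature_celsius=d["temperature_celsius"],
        )

    @classmethod
    def from_json(cls, text_or_path) -> "TensorDictionary":
        if isinstance(text_or_path, str) and text_or_path.lstrip().startswith("{"):
            d = json.loads(text_or_path)
        else:
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def assemble_dictionary(
    isotropic: Sequence[IsotropicAtom],
    models: Sequence[AnisotropicModel],
    directions: DirectionSet,
    temperature_celsius: float = REFERENCE_TEMPERATURE_C,
) -> TensorDictionary:
    """Combine spectrum, models, and directions into a dictionary.

    Anisotropic atom count is ``len(models) * directions.count`` (default
    9 x 25 = 225).
    """
    if len(models) == 0:
        raise ValueError("need at least one anisotropic model")
    if directions.count == 0:
        raise ValueError("need at least one direction")
    return TensorDictionary(
        tuple(isotropic), tuple(models), directions, temperature_celsius
    )


def build_default_dictionary(seed: int = 0) -> TensorDictionary:
    """The default 150 + 225 = 375-atom basis at 37 degC."""
    return assemble_dictionary(
        build_isotropic_spectrum(),
        build_anisotropic_models(),
        make_direction_set(25, seed=seed),
    )


# ---------------------------------------------------------------------------
# temperature scaling
# ---------------------------------------------------------------------------

def scale_temperature(
    dictionary: TensorDictionary,
    factor: float,
    temperature_celsius: float | None = None,
) -> TensorDictionary:
    """Multiply every diffusivity in the dictionary by ``factor``.

    Compartment labels are defined at the 37 degC reference and travel with the
    atoms: the whole basis (band edges included) scales multiplicatively, so no
    atom changes compartment.  ``temperature_celsius`` optionally records the
    temperature the scaled diffusivities now refer to.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    t = (
        dictionary.temperature_celsius
        if temperature_celsius is None
        else temperature_celsius
    )
    return TensorDictionary(
        tuple(
            IsotropicAtom(a.diffusivity * factor, a.compartment)
            for a in dictionary.isotropic_atoms
        ),
        tuple(
            AnisotropicModel(m.model_id, m.ad * factor, m.rd * factor, m.compartment)
            for m in dictionary.anisotropic_models
        ),
        dictionary.directions,
        t,
    )


def derive_temperature_factor(
    reference_table: Sequence[tuple[float, float]] = WATER_SELF_DIFFUSION_TABLE,
    t_from: float = REFERENCE_TEMPERATURE_C,
    t_to: float = 20.0,
) -> float:
    """Diffusivity ratio D(t_to)/D(t_from) from a quadratic fit of water data.

    Fits D(T) = a T^2 + b T + c by least squares to the (temperature degC,
    diffusivity) table and evaluates the ratio.  With the packaged water
    self-diffusion table, 37 -> 20 degC gives ~0.667.
    """
    table = np.asarray(reference_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 3 or table.shape[1] != 2:
        raise ValueError("reference_table needs >= 3 (temperature, D) rows")
    coeffs = np.polyfit(table[:, 0], table[:, 1], deg=2)
    d_from = float(np.polyval(coeffs, t_from))
    d_to = float(np.polyval(coeffs, t_to))
    if d_from <= 0:
        raise ValueError("quadratic fit gives non-positive D at t_from")
    return d_to / d_from
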