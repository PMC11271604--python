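"""Diffusion acquisition schemes: b-values and encoding directions.

Schemes are read and written in the FSL convention: a ``.bval`` file with one
whitespace-separated row of b-values (s/mm^2) and a ``.bvec`` file with three
rows holding the x, y, z components of the unit encoding directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import make_direction_set

__all__ = ["AcquisitionScheme", "default_scheme"]

#: default multi-shell protocol: 2 x b=0 plus 6 shells x 12 directions = 74 rows
DEFAULT_SHELLS = (250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class AcquisitionScheme:
    bvalues: np.ndarray  # (K,), s/mm^2
    bvectors: np.ndarray  # (K, 3), unit rows for b > 0

    def __post_init__(self):
        b = np.asarray(self.bvalues, dtype=float).ravel()
        v = np.asarray(self.bvectors, dtype=float)
        if v.shape != (b.size, 3):
            raise ValueError("bvectors must be (K, 3) matching bvalues")
        if b.size < 1:
            raise ValueError("scheme must contain at least one measurement")
        if np.any(b < 0):
            raise ValueError("b-values must be >= 0")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b=0 measurement")
        norms = np.linalg.norm(v, axis=1)
        weighted = b > 0
        if not np.allclose(norms[weighted], 1.0, atol=1e-6):
            raise ValueError("bvectors must be unit norm where b > 0")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "bvectors", v)

    @property
    def n_measurements(self) -> int:
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    # --- FSL text IO -------------------------------------------------------
    @classmethod
    def from_fsl(cls, bval_path, bvec_path) -> "AcquisitionScheme":
        b = np.loadtxt(bval_path).ravel()
        v = np.loadtxt(bvec_path)
        if v.shape[0] == 3:
            v = v.T
        return cls(b, v)

    def to_fsl(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.bvalues[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvectors.T, fmt="%.8f")


def default_scheme(
    shells: tuple[float, ...] = DEFAULT_SHELLS,
    n_per_shell: int = 12,
    n_b0: int = 2,
    seed: int = 7,
) -> AcquisitionScheme:
    """Multi-shell scheme with repulsion-uniform directions per shell.

    The default layout (2 b=0 + 6 shells x 12 directions, b up to
    2000 s/mm^2) matches a 74-measurement in vivo protocol.  Each shell gets
    its own uniformly distributed direction set so the union samples
    orientation space densely.
    """
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for i, b in enumerate(shells):
        ds = make_direction_set(n_per_shell, seed=seed + i)
        bvals.extend([b] * n_per_shell)
        bvecs.extend(list(ds.vectors))
    return AcquisitionScheme(np.array(bvals), np.vstack(bvecs))
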