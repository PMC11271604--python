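"""Group-level statistics for per-patient median tissue-fraction summaries.

Each subject contributes the median of the nonzero voxel values of each
fraction map over the whole cervical volume.  The module reproduces the
study-level analyses: two-sample t-tests between term and preterm groups
(one- or two-sided), Pearson correlations of fractions with days-to-delivery
and cervical length, and 3D Gaussian ellipsoids (2 standard deviations) in
cell x collagen x muscle space with a numerical disjointness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "SubjectRecord",
    "EllipsoidSummary",
    "compare_groups",
    "correlate",
    "fit_ellipsoid",
    "ellipsoids_disjoint",
    "synthesize_cohort",
    "cohort_summary",
]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "term" or "preterm"
    cell: float
    collagen: float
    muscle: float
    free: float
    days_to_delivery: float
    cervical_length_mm: float | None = None

    def __post_init__(self):
        if self.group not in ("term", "preterm"):
            raise ValueError("group must be 'term' or 'preterm'")
        for name in ("cell", "collagen", "muscle", "free"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} fraction must lie in [0, 1]")
        if self.days_to_delivery < 0:
            raise ValueError("days_to_delivery must be >= 0")


def compare_groups(a, b, sided: str = "one", welch: bool = False,
                   direction: str = "greater"):
    """Two-sample t-test between groups ``a`` and ``b``.

    Pooled-variance by default (``welch=True`` switches to unequal-variance).
    ``sided="one"`` tests H1: mean(a) > mean(b) (or "<" with
    ``direction="less"``); ``sided="two"`` is two-sided.  Returns ``(t, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    alternative = "two-sided" if sided == "two" else direction
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def correlate(x, y):
    """Two-sided Pearson correlation ``(r, p)`` via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class EllipsoidSummary:
    """Gaussian ellipsoid: mean, covariance, and Mahalanobis scale (2 SD)."""

    mean: np.ndarray  # (3,)
    covariance: np.ndarray  # (3, 3), symmetric PSD
    scale: float = 2.0
    degenerate: bool = False

    def semi_axes(self) -> np.ndarray:
        """Ellipsoid semi-axis lengths: scale * sqrt(eigenvalues)."""
        evals = np.linalg.eigvalsh(self.covariance)
        return self.scale * np.sqrt(np.maximum(evals, 0.0))[::-1]

    def _sqrt_cov(self) -> np.ndarray:
        evals, evecs = np.linalg.eigh(self.covariance)
        return evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0))) @ evecs.T

    def surface_point(self, u: np.ndarray) -> np.ndarray:
        """Map a unit vector to the ellipsoid surface."""
        return self.mean + self.scale * (self._sqrt_cov() @ u)

    def mahalanobis(self, x: np.ndarray) -> float:
        d = np.asarray(x, dtype=float) - self.mean
        try:
            sol = np.linalg.solve(self.covariance, d)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(self.covariance) @ d
        return float(np.sqrt(max(d @ sol, 0.0)))


def fit_ellipsoid(points, scale: float = 2.0) -> EllipsoidSummary:
    """Sample mean + covariance of 3D points; surface at Mahalanobis ``scale``.

    A sample covariance that is numerically singular is flagged
    ``degenerate`` and handled with the pseudo-inverse in distance queries.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need >= 4 three-dimensional points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    degenerate = np.linalg.matrix_rank(cov, tol=1e-12) < 3
    return EllipsoidSummary(mean, cov, scale, degenerate)


def _min_mahalanobis_on_surface(e_from: EllipsoidSummary,
                                e_to: EllipsoidSummary,
                                n_starts: int = 26, tol: float = 1e-6) -> float:
    """Minimize e_to's Mahalanobis distance over e_from's surface."""
    def objective(ang):
        th, ph = ang
        u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                      np.cos(th)])
        return e_to.mahalanobis(e_from.surface_point(u))

    best = np.inf
    rng = np.random.default_rng(0)
    starts = [np.array([th, ph]) for th in (0.5, 1.5, 2.5)
              for ph in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    while len(starts) < n_starts:
        starts.append(rng.uniform([0, 0], [np.pi, 2 * np.pi]))
    for s in starts[:n_starts]:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": tol, "fatol": tol})
        best = min(best, res.fun)
    return float(best)


def ellipsoids_disjoint(e1: EllipsoidSummary, e2: EllipsoidSummary,
                        tol: float = 1e-6):
    """Do the two 2-SD surfaces enclose disjoint volumes?

    Numerically minimizes each ellipsoid's Mahalanobis distance over the other
    ellipsoid's surface (multi-start Nelder-Mead, tolerance ``tol``).  The
    pair is disjoint iff the smaller minimum still exceeds the scale AND
    neither center lies inside the other ellipsoid (which excludes the
    containment case).  Returns ``(disjoint, gap)`` where ``gap`` is the
    signed Mahalanobis clearance (negative when overlapping).
    """
    m12 = _min_mahalanobis_on_surface(e1, e2, tol=tol)
    m21 = _min_mahalanobis_on_surface(e2, e1, tol=tol)
    gap = min(m12 - e2.scale, m21 - e1.scale)
    centers_outside = (e2.mahalanobis(e1.mean) > e2.scale
                       and e1.mahalanobis(e2.mean) > e1.scale)
    return bool(gap > 0 and centers_outside), float(gap)


# group-median working points used by the synthetic cohort: the preterm/term
# ratios are cell ~1.94, muscle ~1.46, free ~1.36, and term/preterm collagen
# ~1.65
TERM_MEDIANS = {"cell": 0.030, "collagen": 0.120, "muscle": 0.100,
                "free": 0.280}
PRETERM_MEDIANS = {"cell": 0.0582, "collagen": 0.0727, "muscle": 0.146,
                   "free": 0.381}


def synthesize_cohort(seed: int = 0, n_term: int = 10, n_preterm: int = 7,
                      rel_spread: float = 0.10) -> pd.DataFrame:
    """Draw a synthetic two-group cohort around the group-median working points.

    Within-group values are independent Gaussians with ``rel_spread`` relative
    standard deviation (clipped to [0, 1]); days-to-delivery spans ~7 weeks
    for the term group and ~2.5 weeks for the preterm group, with fractions
    co-varying through group membership only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, med, days_rng in (
        ("term", n_term, TERM_MEDIANS, (35, 55)),
        ("preterm", n_preterm, PRETERM_MEDIANS, (5, 22)),
    ):
        for i in range(n):
            vals = {
                k: float(np.clip(rng.normal(v, rel_spread * v), 0, 1))
                for k, v in med.items()
            }
            rows.append(
                {
                    "subject_id": f"{group[0].upper()}{i + 1}",
                    "group": group,
                    **vals,
                    "days_to_delivery": float(rng.uniform(*days_rng)),
                    "cervical_length_mm": float(
                        rng.normal(33 if group == "term" else 22, 3)
                    ),
                }
            )
    return pd.DataFrame(rows)


def cohort_summary(subjects: pd.DataFrame) -> dict:
    """Full group-level analysis of a subject table.

    Expects columns group, cell, collagen, muscle, free, days_to_delivery
    (cervical_length_mm optional).  Returns group comparisons (one-sided
    pooled t-tests in the direction of the higher-median group), correlations
    with days to delivery, and the 2-SD ellipsoid pair with its disjointness.
    """
    term = subjects[subjects["group"] == "term"]
    pre = subjects[subjects["group"] == "preterm"]
    out: dict = {"tests": {}, "correlations": {}}
    for c in ("cell", "collagen", "muscle", "free"):
        direction = "greater" if pre[c].median() > term[c].median() else "less"
        t, p = compare_groups(pre[c], term[c], sided="one", direction=direction)
        out["tests"][c] = {"t": t, "p": p, "direction": f"preterm {direction}"}
        r, p = correlate(subjects[c], subjects["days_to_delivery"])
        out["correlations"][f"{c}_vs_days_to_delivery"] = {"r": r, "p": p}
    e_term = fit_ellipsoid(term[["cell", "collagen", "muscle"]].to_numpy())
    e_pre = fit_ellipsoid(pre[["cell", "collagen", "muscle"]].to_numpy())
    disjoint, gap = ellipsoids_disjoint(e_term, e_pre)
    out["ellipsoids"] = {
        "term_mean": e_term.mean.tolist(),
        "preterm_mean": e_pre.mean.tolist(),
        "disjoint": disjoint,
        "gap": gap,
    }
    return out
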