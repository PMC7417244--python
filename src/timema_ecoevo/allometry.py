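"""Per-morphospecies length-to-mass allometry.

Field protocol: every individual has a photographed body length; wet mass
was weighed only for a subset (all individuals for rare morphospecies,
fifteen spanning the observed length range for common ones).  A quadratic
curve mass = c0 + c1*L + c2*L^2 is fitted to the weighed subset of each
morphospecies by ordinary least squares and used to predict wet mass for
everyone not weighed.

With fewer than three distinct lengths the quadratic is unidentifiable;
the fit degrades gracefully to a line (two distinct lengths) or the mean
mass (one), with ``degree`` recording what was actually fitted.  Negative
predictions — possible when extrapolating a convex fit below the weighed
range — are clamped to the smallest weighed mass and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ArthropodIndividual

__all__ = [
    "AllometryFit",
    "select_weighing_subset",
    "fit_length_mass",
    "predict_mass",
    "MassPrediction",
]

WEIGHING_SUBSET_SIZE = 15


@dataclass(frozen=True)
class AllometryFit:
    morphospecies_id: str
    coef0: float  # mg
    coef1: float  # mg / mm
    coef2: float  # mg / mm^2
    n_weighed: int
    length_range: tuple[float, float]  # mm, weighed lengths
    min_weighed_mass: float  # mg
    residual_sd: float
    degree: int  # 2 quadratic, 1 linear fallback, 0 mean fallback
    coef_cov: np.ndarray | None = None  # HC3 covariance of the fitted coefficients

    def covers(self, length_mm: float) -> bool:
        lo, hi = self.length_range
        return lo <= length_mm <= hi

    def conf_int(self, level: float = 0.95) -> np.ndarray | None:
        """t-based confidence intervals for the fitted coefficients.

        Built on the HC3 covariance because weighing error and biological
        scatter both grow with body mass — pooled-variance intervals
        undercover the curvature coefficient badly when one large
        individual anchors the fit.  Shape (degree + 1, 2); None when
        there are no residual degrees of freedom.
        """
        from scipy import stats

        if self.coef_cov is None:
            return None
        dof = self.n_weighed - (self.degree + 1)
        if dof <= 0:
            return None
        est = np.array([self.coef0, self.coef1, self.coef2])[: self.degree + 1]
        half = stats.t.ppf(0.5 + level / 2, dof) * np.sqrt(np.diag(self.coef_cov))
        return np.column_stack([est - half, est + half])


@dataclass(frozen=True)
class MassPrediction:
    mass_mg: float
    extrapolated: bool
    clamped: bool


def select_weighing_indices(
    lengths: Sequence[float], n: int = WEIGHING_SUBSET_SIZE, seed: int = 0
) -> list[int]:
    """Indices of the individuals to weigh, given one morphospecies' lengths.

    With at most ``n`` individuals everyone is weighed.  Otherwise the
    ``n`` picks are the individuals nearest to ``n`` equally spaced
    quantiles of the observed lengths, which spans the range (the 0% and
    100% quantiles guarantee the minimum and maximum).  Ties in
    distance-to-quantile are broken by a seeded permutation, so the
    choice is deterministic given the seed and invariant to row order up
    to exact length ties.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("cannot select a weighing subset from no individuals")
    if lengths.size <= n:
        return list(range(lengths.size))
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(lengths.size)
    targets = np.quantile(lengths, np.linspace(0.0, 1.0, n))
    # endpoints claimed first so the min and max individuals are always weighed
    targets = np.concatenate([targets[[0, -1]], targets[1:-1]])
    chosen: list[int] = []
    taken = np.zeros(lengths.size, dtype=bool)
    for t in targets:
        dist = np.abs(lengths - t)
        dist[taken] = np.inf
        # among minimal-distance candidates pick by the seeded permutation
        cand = np.flatnonzero(dist == dist.min())
        pick = int(cand[np.argmin(tiebreak[cand])])
        taken[pick] = True
        chosen.append(pick)
    return sorted(chosen)


def select_weighing_subset(
    individuals: Sequence[ArthropodIndividual],
    n: int = WEIGHING_SUBSET_SIZE,
    seed: int = 0,
) -> list[ArthropodIndividual]:
    """The individuals of one morphospecies chosen for weighing (see above)."""
    idx = select_weighing_indices([i.length_mm for i in individuals], n=n, seed=seed)
    return [individuals[i] for i in idx]


def fit_length_mass(
    weighed: Sequence[tuple[float, float]], morphospecies_id: str = ""
) -> AllometryFit:
    """OLS fit of mass (mg) on length (mm) and length squared.

    ``weighed`` holds (length_mm, mass_mg) pairs.  The polynomial degree
    drops automatically when there are too few distinct lengths for the
    quadratic (see module docstring).
    """
    if not weighed:
        raise ValueError("no weighed individuals to fit")
    L = np.array([w[0] for w in weighed], dtype=float)
    m = np.array([w[1] for w in weighed], dtype=float)
    n_distinct = len(np.unique(L))
    degree = min(2, n_distinct - 1)
    cols = [np.ones_like(L), L, L**2][: degree + 1]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ beta
    dof = len(L) - (degree + 1)
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    coef_cov = None
    if dof > 0:
        xtx_inv = np.linalg.inv(X.T @ X)
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)  # leverages
        # a leverage-one point (exactly determined) has zero residual; clip
        # so the HC3 weight stays finite
        h = np.minimum(h, 1.0 - 1e-8)
        meat = X.T @ (X * ((resid / (1.0 - h)) ** 2)[:, None])
        coef_cov = xtx_inv @ meat @ xtx_inv
    coefs = np.zeros(3)
    coefs[: degree + 1] = beta
    return AllometryFit(
        morphospecies_id=morphospecies_id,
        coef0=float(coefs[0]),
        coef1=float(coefs[1]),
        coef2=float(coefs[2]),
        n_weighed=len(L),
        length_range=(float(L.min()), float(L.max())),
        min_weighed_mass=float(m.min()),
        residual_sd=residual_sd,
        degree=degree,
        coef_cov=coef_cov,
    )


def predict_mass(fit: AllometryFit, length_mm: float) -> MassPrediction:
    """Predict wet mass from body length with the fitted curve.

    Predictions outside the weighed length range are flagged as
    extrapolation; non-positive predictions are clamped to the smallest
    weighed mass (biomass cannot be negative) and flagged.
    """
    raw = fit.coef0 + fit.coef1 * length_mm + fit.coef2 * length_mm**2
    clamped = raw <= 0
    mass = fit.min_weighed_mass if clamped else raw
    return MassPrediction(
        mass_mg=float(mass),
        extrapolated=not fit.covers(length_mm),
        clamped=bool(clamped),
    )
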