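"""Per-plant derived predictors.

Camouflage maladaptation, optional predation-intensity transforms of it,
dispersal-kernel connectivity, rectangular-solid plant volume (with the
2013-from-2014 imputation model), foliar C:N ratio, and the >=5 mm
community metrics.

Maladaptation is the frequency of the poorly camouflaged morph among
striped + unstriped *Timema* on a plant: unstriped individuals are
conspicuous on *Adenostoma fasciculatum* (host ``A``), striped ones on
*Ceanothus spinosus* (host ``C``).  Melanic individuals show no
differential crypsis across hosts and are excluded from both numerator
and denominator of the ratio, though they still count toward *Timema*
abundance.

Connectivity of patch *i* follows the incidence-function form with an
exponential dispersal kernel,

    C_i = sum_{j != i} N_j * (alpha^2 / 2 pi) * exp(-alpha * d_ij),

where ``N_j`` is the source-patch abundance, ``d_ij`` the Euclidean
distance in metres, and ``1/alpha`` the mean movement distance (2 m by
default, from mark-recapture estimates).  The ``alpha^2 / 2 pi`` factor
normalises the 2-D kernel to unit integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import ArthropodIndividual, MorphCounts, PlantPatch

__all__ = [
    "ConnectivityParams",
    "PredationTransform",
    "VolumeImputationParams",
    "maladaptation",
    "predation_intensity",
    "pairwise_distances",
    "connectivity",
    "plant_volume",
    "fit_volume_imputation",
    "impute_volume_2013",
    "community_metrics",
    "cn_ratio",
]

DEFAULT_ALPHA = 0.5  # per metre; mean movement distance 1/alpha = 2 m
DEFAULT_THRESHOLD_MM = 5.0


@dataclass(frozen=True)
class ConnectivityParams:
    """Exponential-kernel parameters; ``kernel_scale`` is alpha^2/(2 pi)."""

    alpha: float = DEFAULT_ALPHA
    weight_source: str = "timema"  # "timema" | "arthropod"

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")

    @property
    def kernel_scale(self) -> float:
        return self.alpha**2 / (2.0 * math.pi)


@dataclass(frozen=True)
class PredationTransform:
    """Saturating-exponential map from morph frequency to predation intensity.

    ``shape_k = 0`` is the identity (linear) case; larger ``shape_k`` gives
    increasingly asymptotic (concave) curves, P(m) = (1-e^{-k m})/(1-e^{-k}),
    which fixes P(0)=0 and P(1)=1 for every k.
    """

    shape_k: float = 0.0

    def __post_init__(self):
        if self.shape_k < 0:
            raise ValueError("shape_k must be >= 0")


def maladaptation(counts: MorphCounts, host: str) -> float | None:
    """Frequency of the poorly camouflaged morph on ``host``.

    Host ``A``: unstriped / (striped + unstriped); host ``C``: the
    complement.  Melanics are excluded throughout.  Returns ``None`` when
    no striped or unstriped individuals were recorded (maladaptation is
    then undefined, not zero).
    """
    if host not in ("A", "C"):
        raise ValueError(f"host must be 'A' or 'C', got {host!r}")
    denom = counts.n_striped + counts.n_unstriped
    if denom == 0:
        return None
    bad = counts.n_unstriped if host == "A" else counts.n_striped
    return bad / denom


def predation_intensity(m: float, transform: PredationTransform) -> float:
    """Map morph frequency ``m`` in [0, 1] to relative predation intensity."""
    if not 0 <= m <= 1:
        raise ValueError(f"morph frequency must lie in [0, 1], got {m}")
    k = transform.shape_k
    if k == 0:
        return m
    # expm1 keeps the ratio stable as k -> 0 (limit is the identity)
    return math.expm1(-k * m) / math.expm1(-k)


def pairwise_distances(plants: Sequence[PlantPatch]) -> np.ndarray:
    """Symmetric Euclidean distance matrix (metres) over patch coordinates."""
    for p in plants:
        if p.x is None or p.y is None:
            raise ValueError(f"plant {p.plant_id}: missing coordinate")
    xy = np.array([[p.x, p.y] for p in plants], dtype=float)
    return cdist(xy, xy)


def connectivity(
    abundance_by_plant: Sequence[float] | np.ndarray,
    distances: np.ndarray,
    params: ConnectivityParams = ConnectivityParams(),
) -> np.ndarray:
    """Kernel-weighted immigrant supply C_i for every patch.

    The self term is excluded; the result is linear in the abundance
    vector, so e.g. doubling all source abundances doubles every C_i.
    """
    n = np.asarray(abundance_by_plant, dtype=float)
    d = np.asarray(distances, dtype=float)
    if d.shape != (n.size, n.size):
        raise ValueError(
            f"distance matrix shape {d.shape} does not match {n.size} abundances"
        )
    kernel = params.kernel_scale * np.exp(-params.alpha * d)
    np.fill_diagonal(kernel, 0.0)
    return kernel @ n


def plant_volume(p: PlantPatch) -> tuple[float | None, float | None]:
    """Rectangular-solid volume (m^3) and its natural log; None if geometry missing."""
    if not p.has_geometry:
        return None, None
    v = p.length_m * p.width_m * p.height_m
    return v, math.log(v)


@dataclass(frozen=True)
class VolumeImputationParams:
    """Linear model predicting 2013 volume from 2014 volume and host species.

    ``species_offset`` applies to host C (host A is the reference level).
    No volume-by-species interaction: refits of the survey's calibration
    plants show none, i.e. the two hosts grew proportionally.
    """

    intercept: float  # m^3
    slope_v2014: float  # dimensionless
    species_offset: float = 0.0  # m^3, added for host C

    def __post_init__(self):
        if not self.slope_v2014 > 0:
            raise ValueError("slope_v2014 must be > 0")


def fit_volume_imputation(
    v2013: Sequence[float], v2014: Sequence[float], host: Sequence[str]
) -> VolumeImputationParams:
    """Least-squares fit of v2013 ~ v2014 + host on plants measured in both years."""
    v13 = np.asarray(v2013, dtype=float)
    v14 = np.asarray(v2014, dtype=float)
    is_c = np.asarray([h == "C" for h in host], dtype=float)
    X = np.column_stack([np.ones_like(v14), v14, is_c])
    beta, *_ = np.linalg.lstsq(X, v13, rcond=None)
    return VolumeImputationParams(
        intercept=float(beta[0]), slope_v2014=float(beta[1]), species_offset=float(beta[2])
    )


def impute_volume_2013(
    v2014: float,
    host: str,
    params: VolumeImputationParams,
    min_observed_2013: float | None = None,
) -> float:
    """Predict a plant's 2013 volume from its 2014 volume and host species.

    Negative predictions (possible for tiny plants with a negative fitted
    intercept) are clamped to the smallest observed 2013 volume when one
    is supplied.
    """
    pred = params.intercept + params.slope_v2014 * v2014
    if host == "C":
        pred += params.species_offset
    if pred <= 0 and min_observed_2013 is not None:
        return min_observed_2013
    return pred


def community_metrics(
    individuals: Sequence[ArthropodIndividual],
    timema: MorphCounts | None,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    melanic_in_abundance: bool = True,
) -> dict[str, int]:
    """Per-plant counts used as model responses.

    Arthropod abundance counts non-*Timema* individuals with body length at
    or above ``threshold_mm`` (inclusive, reflecting size-selective bird
    predation); richness counts morphospecies with at least one such
    individual.  *Timema* abundance sums all three morphs by default
    (melanics lack differential crypsis but are still stick insects).
    """
    big = [i for i in individuals if i.length_mm >= threshold_mm]
    t = 0
    if timema is not None:
        t = timema.n_striped + timema.n_unstriped
        if melanic_in_abundance:
            t += timema.n_melanic
    return {
        "timema_abundance": t,
        "arthropod_abundance_ge5": len(big),
        "richness_ge5": len({i.morphospecies_id for i in big}),
    }


def cn_ratio(pct_carbon: float, pct_nitrogen: float) -> float:
    """Foliar carbon-to-nitrogen mass ratio; lower means more nitrogenous."""
    if pct_nitrogen <= 0:
        raise ValueError("pct_nitrogen must be > 0")
    if pct_carbon <= 0:
        raise ValueError("pct_carbon must be > 0")
    return pct_carbon / pct_nitrogen
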