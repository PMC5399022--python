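"""Dual p-values and layered classification of statistical parametric maps.

Alternative-based thresholding (ABT) complements the classical null
hypothesis test in every voxel with a symmetric test against a prespecified
alternative.  For a voxel with test statistic ``t = delta_hat / se`` the two
p-values are

* ``p0 = P(T >= t | H0)`` — evidence against the null of no activation,
  computed from a Student-t null with the residual degrees of freedom;
* ``p1 = P(T <= t | H1)`` — evidence against the alternative that the true
  effect is drawn from ``N(mu_delta1, tau^2)`` (in % BOLD signal change),
  under which the statistic is Gaussian:
  ``T ~ N(mu_delta1 / se, (se^2 + tau^2) / se^2)``.

Thresholding ``p0`` at ``alpha`` and ``p1`` at ``beta`` partitions the brain
into four layers: active (p0 < alpha, p1 > beta), inactive (p0 > alpha,
p1 < beta), uncertain (neither rejected) and practically insignificant
(both rejected).  Boundary ties resolve toward non-rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LAYER_OUTSIDE",
    "LAYER_ACTIVE",
    "LAYER_INACTIVE",
    "LAYER_UNCERTAIN",
    "LAYER_PRACTICALLY_INSIGNIFICANT",
    "LAYER_NAMES",
    "AlternativeSpec",
    "DecisionThresholds",
    "VoxelStat",
    "LayerMap",
    "null_p_value",
    "alt_p_value",
    "dual_p_values",
    "fdr_threshold",
    "classify_layers",
    "critical_values",
]

# Integer codes of the layered statistical parametric map (LSPM).
LAYER_OUTSIDE = 0
LAYER_ACTIVE = 1
LAYER_INACTIVE = 2
LAYER_UNCERTAIN = 3
LAYER_PRACTICALLY_INSIGNIFICANT = 4

LAYER_NAMES = {
    LAYER_OUTSIDE: "outside",
    LAYER_ACTIVE: "active",
    LAYER_INACTIVE: "inactive",
    LAYER_UNCERTAIN: "uncertain",
    LAYER_PRACTICALLY_INSIGNIFICANT: "practically_insignificant",
}


def _check_sign(sign: str) -> int:
    if sign in ("pos", "positive", "+"):
        return 1
    if sign in ("neg", "negative", "-"):
        return -1
    raise ValueError(f"sign must be 'pos' or 'neg', got {sign!r}")


@dataclass(frozen=True)
class AlternativeSpec:
    """Prespecified distribution of scientifically relevant effect sizes.

    Parameters
    ----------
    mu_delta1 : float
        Mean of the alternative effect-size distribution, in % BOLD signal
        change.  Positive for activation; a negative value flips the method
        to detect deactivation.  Must be nonzero.
    tau : float
        Standard deviation of the true effect sizes across voxels
        (% BOLD signal change), >= 0.
    """

    mu_delta1: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_delta1 == 0:
            raise ValueError("mu_delta1 must be nonzero")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    @property
    def sign(self) -> str:
        return "pos" if self.mu_delta1 > 0 else "neg"


@dataclass(frozen=True)
class DecisionThresholds:
    """Decision levels for the two hypothesis tests.

    ``null_mode`` selects how the null p-values are thresholded:
    ``"uncorrected"`` uses the fixed level ``alpha`` per voxel, ``"fdr"``
    derives a map-wide effective alpha from the Benjamini-Hochberg step-up
    rule at level ``q``.  ``beta`` is the false-negative level applied to
    the alternative p-values.
    """

    beta: float
    null_mode: str = "uncorrected"
    alpha: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.null_mode not in ("uncorrected", "fdr"):
            raise ValueError("null_mode must be 'uncorrected' or 'fdr'")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.null_mode == "uncorrected":
            if self.alpha is None or not 0 < self.alpha < 1:
                raise ValueError("uncorrected mode requires alpha in (0, 1)")
        else:
            if self.q is None or not 0 < self.q < 1:
                raise ValueError("fdr mode requires q in (0, 1)")


@dataclass(frozen=True)
class VoxelStat:
    """Per-voxel GLM summary: effect estimate, its SE, t and df."""

    delta_hat: float
    se: float
    df: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def t(self) -> float:
        return self.delta_hat / self.se


@dataclass
class LayerMap:
    """Integer-labeled volume encoding the four ABT layers.

    ``labels`` holds code 0 outside the analysis mask and codes 1-4
    (active, inactive, uncertain, practically insignificant) inside it.
    """

    labels: np.ndarray
    mask: np.ndarray
    thresholds: DecisionThresholds | None = None
    effective_alpha: float | None = field(default=None)

    def layer_mask(self, code: int) -> np.ndarray:
        """Boolean volume of the voxels carrying layer ``code``."""
        return self.labels == code

    def counts(self) -> dict[str, int]:
        """Number of in-mask voxels per layer, keyed by layer name."""
        return {
            LAYER_NAMES[c]: int(np.count_nonzero(self.labels == c))
            for c in (LAYER_ACTIVE, LAYER_INACTIVE, LAYER_UNCERTAIN,
                      LAYER_PRACTICALLY_INSIGNIFICANT)
        }


def null_p_value(t, df, *, sign: str = "pos"):
    """Classical one-sided p-value ``P(T >= t | H0)`` under a Student-t null.

    Parameters
    ----------
    t : array_like
        Observed test statistics.
    df : int or array_like
        Residual degrees of freedom (>= 1).
    sign : {"pos", "neg"}
        Direction of the alternative of interest.  In deactivation mode the
        p-value is the lower tail ``P(T <= t | H0)``.
    """
    t = np.asarray(t, dtype=float)
    df = np.asarray(df)
    if np.any(df < 1):
        raise ValueError("df must be >= 1")
    if _check_sign(sign) > 0:
        return stats.t.sf(t, df)
    return stats.t.cdf(t, df)


def alt_p_value(t, se, alt: AlternativeSpec, *, sign: str | None = None):
    """Alternative p-value ``P(T <= t | H1)`` under the Gaussian alternative.

    Under H1 the statistic of voxel *i* is
    ``T_i ~ N(mu_delta1 / se_i, (se_i^2 + tau^2) / se_i^2)``, hence

    ``p1 = Phi((t * se - mu_delta1) / sqrt(se^2 + tau^2))``.

    Small ``p1`` is evidence against true activation of the prespecified
    magnitude.  For the deactivation variant (negative ``mu_delta1``) the
    tail is mirrored: ``p1 = P(T >= t | H1)``.
    """
    t = np.asarray(t, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if sign is None:
        sign = alt.sign
    s = np.sqrt(se**2 + alt.tau**2)
    z = (t * se - alt.mu_delta1) / s
    if _check_sign(sign) > 0:
        return stats.norm.cdf(z)
    return stats.norm.sf(z)


def dual_p_values(t, se, df, mask, alt: AlternativeSpec,
                  *, sign: str | None = None):
    """Null and alternative p-value maps restricted to an analysis mask.

    Out-of-mask voxels receive the neutral value 1.0 for both p-values (no
    evidence against either hypothesis); they are excluded from every
    downstream decision by the mask anyway.
    """
    t = np.asarray(t, dtype=float)
    se = np.asarray(se, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if sign is None:
        sign = alt.sign
    p0 = np.ones(t.shape)
    p1 = np.ones(t.shape)
    p0[mask] = null_p_value(t[mask], df, sign=sign)
    p1[mask] = alt_p_value(t[mask], se[mask], alt, sign=sign)
    return p0, p1


def fdr_threshold(p0, q: float) -> float:
    """Benjamini-Hochberg step-up cut-off at FDR level ``q``.

    Returns the largest p-value ``p_(k)`` among the sorted input with
    ``p_(k) <= k * q / m``; thresholding the map at this value (inclusive)
    reproduces the BH rejection set.  Returns 0.0 when nothing is rejected.
    """
    p = np.asarray(p0, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cannot compute an FDR threshold on an empty mask")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p_sorted = np.sort(p)
    m = p.size
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= crit)[0]
    if passing.size == 0:
        return 0.0
    return float(p_sorted[passing[-1]])


def classify_layers(p0, p1, thresholds: DecisionThresholds, mask) -> LayerMap:
    """Label every in-mask voxel by its (p0 vs alpha, p1 vs beta) quadrant.

    Boundary ties resolve toward non-rejection: ``p0 == alpha`` counts as
    not significant and ``p1 == beta`` as H1 not rejected.  In FDR mode the
    effective alpha is the BH cut-off of the in-mask ``p0`` values, and the
    comparison is inclusive so that the rejection set is exactly the BH set.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (p0.shape == p1.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: p0 {p0.shape}, p1 {p1.shape}, mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("analysis mask is empty")

    if thresholds.null_mode == "fdr":
        alpha_eff = fdr_threshold(p0[mask], thresholds.q)
        sig0 = p0 <= alpha_eff
    else:
        alpha_eff = thresholds.alpha
        sig0 = p0 < alpha_eff
    rej1 = p1 < thresholds.beta

    labels = np.zeros(p0.shape, dtype=np.int16)
    labels[mask & sig0 & ~rej1] = LAYER_ACTIVE
    labels[mask & ~sig0 & rej1] = LAYER_INACTIVE
    labels[mask & ~sig0 & ~rej1] = LAYER_UNCERTAIN
    labels[mask & sig0 & rej1] = LAYER_PRACTICALLY_INSIGNIFICANT
    return LayerMap(labels=labels, mask=mask, thresholds=thresholds,
                    effective_alpha=float(alpha_eff))


def critical_values(
    se,
    df,
    alt: AlternativeSpec,
    thresholds: DecisionThresholds,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut-offs ``(t_alpha, t_beta)`` on the t scale, and the feasible layer.

    ``t_alpha`` is the alpha-level quantile of the Student-t null and
    ``t_beta = mu_delta1/se + Phi^{-1}(beta) * sqrt(se^2 + tau^2)/se`` the
    beta-quantile of the Gaussian alternative (mirrored for deactivation).
    The third return value reports which of the two mutually exclusive
    middle layers is possible for each voxel: ``LAYER_UNCERTAIN`` when the
    two no-rejection regions overlap, ``LAYER_PRACTICALLY_INSIGNIFICANT``
    when the rejection regions do.

    Requires ``null_mode="uncorrected"`` (an FDR-mode effective alpha is a
    property of a whole map, not of a single voxel).
    """
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if thresholds.null_mode != "uncorrected":
        raise ValueError("critical_values requires an uncorrected alpha")
    alpha, beta = thresholds.alpha, thresholds.beta
    s_rel = np.sqrt(se**2 + alt.tau**2) / se
    if alt.mu_delta1 > 0:
        t_alpha = np.broadcast_to(stats.t.ppf(1 - alpha, df), se.shape).copy()
        t_beta = alt.mu_delta1 / se + stats.norm.ppf(beta) * s_rel
        uncertain_possible = t_alpha > t_beta
    else:
        t_alpha = np.broadcast_to(stats.t.ppf(alpha, df), se.shape).copy()
        t_beta = alt.mu_delta1 / se - stats.norm.ppf(beta) * s_rel
        uncertain_possible = t_alpha < t_beta
    feasible = np.where(
        uncertain_possible, LAYER_UNCERTAIN, LAYER_PRACTICALLY_INSIGNIFICANT
    ).astype(np.int16)
    return t_alpha, t_beta, feasible
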