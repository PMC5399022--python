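"""Blocked-design regressor construction and vectorized per-voxel OLS.

The experimental paradigm is a boxcar alternating OFF/ON blocks of fixed
duration, convolved with a canonical double-gamma hemodynamic response
function and peak-normalized to 1 so that the fitted slope is directly in
% BOLD signal change at the response peak.  The per-voxel model is ordinary
least squares on ``[intercept, convolved regressor]`` with residual degrees
of freedom ``n_scans - 2``; no autocorrelation or nuisance regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DesignSpec",
    "Regressor",
    "GLMMaps",
    "double_gamma_hrf",
    "build_design",
    "fit_glm",
]

#: Microtime resolution (s) at which the boxcar is convolved with the HRF
#: before sampling at scan onsets.
MICROTIME_DT = 0.1

#: Canonical double-gamma parameters: response peak delay, undershoot delay
#: (gamma shapes with unit dispersion), undershoot ratio and kernel support.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_DURATION = 32.0


class DegenerateDesignError(ValueError):
    """Raised when the convolved regressor carries no signal."""


@dataclass(frozen=True)
class DesignSpec:
    """Blocked experimental design.

    The block duration need not be an integer number of TRs (the canonical
    25 s block with TR 2 s is 12.5 scans), but the run must span an integer
    number of blocks.

    Parameters
    ----------
    n_scans : int
        Number of acquired volumes.
    tr : float
        Repetition time in seconds.
    block_s : float
        Duration of one block (one ON or one OFF period) in seconds.
    start_state : {"off", "on"}
        Condition of the first block; rest-first by default.
    """

    n_scans: int
    tr: float = 2.0
    block_s: float = 25.0
    start_state: str = "off"

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if self.tr <= 0 or self.block_s <= 0:
            raise ValueError("tr and block_s must be positive")
        if self.start_state not in ("off", "on"):
            raise ValueError("start_state must be 'off' or 'on'")
        if abs(self.n_blocks - round(self.n_blocks)) > 1e-9:
            raise ValueError(
                f"run duration {self.n_scans * self.tr} s is not an integer "
                f"number of {self.block_s} s blocks"
            )

    @property
    def n_blocks(self) -> float:
        return self.n_scans * self.tr / self.block_s


@dataclass(frozen=True)
class Regressor:
    """Task regressor sampled at the scan grid.

    ``boxcar`` stores, per scan, the fraction of that TR interval spent in
    the ON state (0/1 except at block boundaries falling inside a TR, where
    it is fractional), so that ``boxcar.sum() * tr`` equals the total ON
    time.  ``convolved`` is the boxcar convolved with the double-gamma HRF
    on a microtime grid, sampled at scan onsets and divided by its maximum.
    """

    boxcar: np.ndarray
    convolved: np.ndarray
    spec: DesignSpec

    def __post_init__(self) -> None:
        if len(self.boxcar) != self.spec.n_scans:
            raise ValueError("boxcar length must equal n_scans")
        if len(self.convolved) != self.spec.n_scans:
            raise ValueError("convolved length must equal n_scans")


def double_gamma_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    ``h(t) = g(t; 6) - g(t; 16)/6`` with ``g`` the unit-scale gamma density,
    evaluated on ``[0, duration)``.  The positive lobe peaks near 5 s and
    the undershoot near 15 s.  Amplitude scaling is irrelevant downstream
    because the convolved regressor is peak-normalized.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    h = (
        stats.gamma.pdf(t, HRF_PEAK_DELAY)
        - HRF_UNDERSHOOT_RATIO * stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY)
    )
    return h


def build_design(spec: DesignSpec, dt: float = MICROTIME_DT) -> Regressor:
    """Construct the convolved, peak-normalized task regressor.

    The boxcar is defined in continuous time (block index = ``floor(t /
    block_s)``, parity set by ``start_state``), convolved with the HRF at
    microtime resolution ``dt`` and sampled at scan onsets ``i * tr``.
    """
    n, tr = spec.n_scans, spec.tr
    steps_per_tr = int(round(tr / dt))
    tt = np.arange(n * steps_per_tr) * dt
    on_parity = 0 if spec.start_state == "on" else 1
    box_micro = (np.floor(tt / spec.block_s).astype(int) % 2 == on_parity)
    box_micro = box_micro.astype(float)

    h = double_gamma_hrf(dt)
    conv = np.convolve(box_micro, h)[: len(tt)] * dt
    scan_idx = np.round(np.arange(n) * tr / dt).astype(int)
    conv = conv[scan_idx]
    peak = conv.max() if conv.size else 0.0
    if peak <= 0:
        raise DegenerateDesignError("convolved regressor has no positive peak")
    conv = conv / peak

    # per-scan ON fraction of each TR interval
    boxcar = box_micro.reshape(n, steps_per_tr).mean(axis=1)
    return Regressor(boxcar=boxcar, convolved=conv, spec=spec)


@dataclass
class GLMMaps:
    """Per-voxel OLS results on the spatial grid.

    ``beta`` (slope on the convolved regressor, % BOLD), ``se`` (its OLS
    standard error), ``t = beta/se`` and the common residual ``df``.
    ``degenerate`` flags voxels whose residual variance was exactly zero
    (their ``se`` is floored at the smallest positive normal float);
    ``mask`` is the effective analysis mask after dropping all-NaN voxels.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    mask: np.ndarray
    degenerate: np.ndarray


def fit_glm(bold: np.ndarray, reg: Regressor, mask: np.ndarray) -> GLMMaps:
    """Fit ``y = b0 + b1 * convolved`` by OLS in every in-mask voxel.

    Parameters
    ----------
    bold : ndarray, shape (X, Y, Z, T)
        4D time series; the time axis must match the regressor length.
    reg : Regressor
        Design built by :func:`build_design`.
    mask : ndarray of bool, shape (X, Y, Z)
        Voxels to analyze.  Voxels whose series is entirely NaN are dropped
        from the returned mask.

    Notes
    -----
    The two-column design admits the closed form ``b1 = S_xy / S_xx`` with
    ``se(b1) = sqrt(RSS / (n - 2) / S_xx)``; everything is computed
    vectorized in float64.
    """
    bold = np.asarray(bold)
    mask = np.asarray(mask, dtype=bool)
    if bold.ndim != 4:
        raise ValueError("bold must be a 4D (X, Y, Z, T) array")
    if bold.shape[:3] != mask.shape:
        raise ValueError("spatial shape of bold and mask differ")
    n = reg.spec.n_scans
    if bold.shape[3] != n:
        raise ValueError(
            f"bold has {bold.shape[3]} time points, design expects {n}"
        )
    if not mask.any():
        raise ValueError("analysis mask is empty")

    y = bold[mask].astype(np.float64)  # (V, T)
    nan_rows = np.isnan(y).all(axis=1)
    if nan_rows.any():
        keep = np.zeros(mask.shape, dtype=bool)
        idx = np.flatnonzero(mask.reshape(-1))
        keep.reshape(-1)[idx[~nan_rows]] = True
        mask = keep
        y = y[~nan_rows]
        if y.size == 0:
            raise ValueError("all in-mask voxels are NaN")

    x = reg.convolved.astype(np.float64)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise DegenerateDesignError("regressor has zero variance")

    ybar = y.mean(axis=1)
    yc = y - ybar[:, None]
    b1 = (yc @ xc) / sxx
    resid = yc - b1[:, None] * xc[None, :]
    df = n - 2
    rss = np.einsum("ij,ij->i", resid, resid)
    syy = np.einsum("ij,ij->i", yc, yc)
    # an exactly constant series has zero residual variance by construction
    degenerate_v = (syy == 0) | (rss == 0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    se[degenerate_v] = np.finfo(np.float64).tiny
    se = np.maximum(se, np.finfo(np.float64).tiny)

    shape = mask.shape
    beta_map = np.zeros(shape)
    se_map = np.zeros(shape)
    t_map = np.zeros(shape)
    degen_map = np.zeros(shape, dtype=bool)
    beta_map[mask] = b1
    se_map[mask] = se
    t_map[mask] = b1 / se
    degen_map[mask] = degenerate_v
    return GLMMaps(beta=beta_map, se=se_map, t=t_map, df=df, mask=mask,
                   degenerate=degen_map)
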