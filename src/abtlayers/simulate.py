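"""Synthetic blocked-design BOLD data with known ground truth.

A run is a 4D volume ``baseline + ES * regressor + noise``: two spherical
"hippocampal" regions carry task signal with effect sizes of 1% and 2%
BOLD signal change, every other voxel of a brain-like ellipsoidal analysis
mask is pure noise.  The noise is Gaussian, independent across time points,
spatially correlated through a 3D Gaussian smoothing kernel and rescaled so
that the per-voxel marginal standard deviation equals ``sigma_noise``
exactly — the contrast-to-noise ratio is therefore ``ES / sigma_noise`` by
construction.  An alternative ``literal_smoothing`` mode instead smooths
the complete signal+noise scans without rescaling, which shrinks the noise
far below nominal and erodes the spheres; it exists for comparison only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .evaluate import count_layers_by_truth
from .glm import DesignSpec, Regressor, build_design, fit_glm
from .model import (
    LAYER_NAMES,
    AlternativeSpec,
    DecisionThresholds,
    classify_layers,
    dual_p_values,
)

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_MASK_SIZE",
    "DEFAULT_SPHERE_CENTERS",
    "SimCondition",
    "GroundTruth",
    "sphere_mask",
    "analysis_mask",
    "noise_field",
    "simulate_run",
    "run_grid",
]

DEFAULT_GRID = (64, 64, 40)
#: Analyzed voxels implied by the per-layer population: 44,957 noise voxels
#: plus two 515-voxel spheres.
DEFAULT_MASK_SIZE = 45_987
_MASK_FRACTION = DEFAULT_MASK_SIZE / (64 * 64 * 40)
#: Bilateral sphere centers (voxel indices) on the default grid.
DEFAULT_SPHERE_CENTERS = ((22, 27, 16), (41, 27, 16))
#: Ellipsoid semi-axes (voxels) shaping the analysis mask.
_MASK_SEMI_AXES = (26.0, 31.0, 17.0)

TRUTH_NOISE = 0
TRUTH_SMALL = 1
TRUTH_LARGE = 2


@dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation design.

    Defaults are the canonical study conditions: a 64x64x40 grid, TR 2 s,
    25 s blocks, spheres of radius 5 (515 lattice voxels each) carrying 1%
    and 2% BOLD effects, noise smoothing kernel sigma 3.40 voxels, baseline
    intensity 100 so that slopes read directly in % BOLD signal change.
    """

    n_scans: int = 150
    sigma_noise: float = 3.0
    es_small: float = 1.0
    es_large: float = 2.0
    grid: tuple[int, int, int] = DEFAULT_GRID
    smooth_sigma: float = 3.40
    tr: float = 2.0
    block_s: float = 25.0
    baseline: float = 100.0
    sphere_radius: float = 5.0
    sphere_centers: tuple[tuple[int, int, int], ...] | None = None
    mask_size: int | None = None
    literal_smoothing: bool = False

    def __post_init__(self) -> None:
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.sphere_centers is not None and len(self.sphere_centers) != 2:
            raise ValueError("exactly two sphere centers are required")

    def resolved_centers(self) -> tuple[tuple[int, int, int], ...]:
        """Sphere centers; the canonical ones scale with a non-default grid."""
        if self.sphere_centers is not None:
            return self.sphere_centers
        scale = np.asarray(self.grid) / np.asarray(DEFAULT_GRID)
        return tuple(
            tuple(int(round(c * s)) for c, s in zip(center, scale))
            for center in DEFAULT_SPHERE_CENTERS
        )

    @property
    def design(self) -> DesignSpec:
        return DesignSpec(n_scans=self.n_scans, tr=self.tr,
                          block_s=self.block_s)

    @property
    def cnr(self) -> tuple[float, float]:
        """Contrast-to-noise ratios (small sphere, large sphere)."""
        return (
            round(self.es_small / self.sigma_noise, 2),
            round(self.es_large / self.sigma_noise, 2),
        )

    def resolved_mask_size(self) -> int:
        if self.mask_size is not None:
            return self.mask_size
        if self.grid == DEFAULT_GRID:
            return DEFAULT_MASK_SIZE
        return int(round(_MASK_FRACTION * int(np.prod(self.grid))))


@dataclass
class GroundTruth:
    """True per-voxel state: labels (0 noise, 1 small ES, 2 large ES),
    the effect-size volume in % BOLD, and the analysis mask."""

    labels: np.ndarray
    es: np.ndarray
    mask: np.ndarray

    def truth_mask(self, code: int) -> np.ndarray:
        return self.mask & (self.labels == code)


def sphere_mask(
    shape: tuple[int, int, int],
    center: tuple[int, int, int],
    radius: float,
) -> np.ndarray:
    """Lattice voxels within Euclidean distance ``radius`` of ``center``.

    The canonical radius 5 encloses exactly 515 voxels.  Raises if the
    sphere would be clipped by the grid boundary.
    """
    center = np.asarray(center, dtype=float)
    if np.any(center - radius < 0) or np.any(center + radius > np.asarray(shape) - 1):
        raise ValueError(
            f"sphere at {tuple(center)} with radius {radius} is clipped by "
            f"the {shape} grid"
        )
    coords = np.indices(shape, dtype=float)
    d2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2 + 1e-12


def analysis_mask(
    grid: tuple[int, int, int] = DEFAULT_GRID,
    n_voxels: int | None = None,
) -> np.ndarray:
    """Fixed, seed-independent ellipsoidal "brain" mask with an exact count.

    Voxels are ranked by normalized ellipsoidal distance from the grid
    center (semi-axes 26/31/17 voxels, scaled to non-default grids) and the
    ``n_voxels`` closest are kept, with a deterministic lexicographic
    tie-break.  On the default 64x64x40 grid the mask holds exactly 45,987
    voxels: the 44,957 noise voxels of the study tables plus the two
    515-voxel spheres.
    """
    grid = tuple(int(g) for g in grid)
    total = int(np.prod(grid))
    if n_voxels is None:
        n_voxels = (DEFAULT_MASK_SIZE if grid == DEFAULT_GRID
                    else int(round(_MASK_FRACTION * total)))
    if not 0 < n_voxels <= total:
        raise ValueError(
            f"requested mask size {n_voxels} unattainable on a {grid} grid"
        )
    center = (np.asarray(grid, dtype=float) - 1) / 2
    axes = np.asarray(_MASK_SEMI_AXES) * np.asarray(grid) / np.asarray(DEFAULT_GRID)
    coords = np.indices(grid, dtype=float)
    r2 = sum(((coords[i] - center[i]) / axes[i]) ** 2 for i in range(3))
    order = np.argsort(r2.ravel(), kind="stable")  # stable = lexicographic ties
    mask = np.zeros(total, dtype=bool)
    mask[order[:n_voxels]] = True
    return mask.reshape(grid)


@lru_cache(maxsize=16)
def _smoothing_l2_norm(shape: tuple[int, int, int], sigma: float) -> float:
    """L2 norm of the (circularly wrapped) 3D Gaussian smoothing kernel.

    Smoothing unit-variance white noise with this kernel yields a field
    whose exact per-voxel standard deviation equals this norm.
    """
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    w = gaussian_filter(impulse, sigma=sigma, mode="wrap")
    return float(np.sqrt((w**2).sum()))


def noise_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n_scans: int,
    sigma_noise: float,
    smooth_sigma: float = 3.40,
) -> np.ndarray:
    """Spatially correlated, temporally independent Gaussian noise.

    Each time point is an independent white Gaussian volume convolved with
    a 3D Gaussian kernel (circular boundary, so the field is stationary)
    and rescaled so the per-voxel marginal SD equals ``sigma_noise``
    exactly.  Returns a float32 array of shape ``shape + (n_scans,)``.
    """
    white = rng.standard_normal(size=shape + (n_scans,), dtype=np.float32)
    if smooth_sigma > 0:
        smooth = gaussian_filter(
            white, sigma=(smooth_sigma,) * 3 + (0.0,), mode="wrap"
        )
        scale = sigma_noise / _smoothing_l2_norm(tuple(shape), smooth_sigma)
    else:
        smooth = white
        scale = sigma_noise
    return smooth * np.float32(scale)


def _ground_truth(cond: SimCondition) -> GroundTruth:
    mask = analysis_mask(cond.grid, cond.mask_size)
    centers = cond.resolved_centers()
    small = sphere_mask(cond.grid, centers[0], cond.sphere_radius)
    large = sphere_mask(cond.grid, centers[1], cond.sphere_radius)
    if (small & large).any():
        raise ValueError("sphere masks overlap")
    if not (small | large)[mask].sum() == small.sum() + large.sum():
        raise ValueError("spheres are not contained in the analysis mask")
    labels = np.zeros(cond.grid, dtype=np.int16)
    labels[small] = TRUTH_SMALL
    labels[large] = TRUTH_LARGE
    es = np.zeros(cond.grid, dtype=np.float64)
    es[small] = cond.es_small
    es[large] = cond.es_large
    return GroundTruth(labels=labels, es=es, mask=mask)


def simulate_run(
    cond: SimCondition,
    reg: Regressor | None = None,
    *,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate one 4D run and its ground truth.

    The image is ``baseline + es * convolved_regressor`` in sphere voxels
    plus the rescaled smoothed noise everywhere (default mode).  In
    ``literal_smoothing`` mode, white noise is added first and the whole
    signal+noise scan is then smoothed without rescaling.
    """
    if reg is None:
        reg = build_design(cond.design)
    if reg.spec.n_scans != cond.n_scans:
        raise ValueError(
            f"regressor has {reg.spec.n_scans} scans, condition expects "
            f"{cond.n_scans}"
        )
    rng = np.random.default_rng(rng)
    truth = _ground_truth(cond)
    conv = reg.convolved.astype(np.float32)
    signal = truth.es.astype(np.float32)[..., None] * conv[None, None, None, :]

    if cond.literal_smoothing:
        white = rng.standard_normal(
            size=cond.grid + (cond.n_scans,), dtype=np.float32
        ) * np.float32(cond.sigma_noise)
        img = signal + white
        img = gaussian_filter(
            img, sigma=(cond.smooth_sigma,) * 3 + (0.0,), mode="wrap"
        )
        img += np.float32(cond.baseline)
    else:
        img = signal
        img += noise_field(rng, cond.grid, cond.n_scans, cond.sigma_noise,
                           cond.smooth_sigma)
        img += np.float32(cond.baseline)
    return img, truth


def _count_row(layers, truth) -> dict[str, float]:
    table = count_layers_by_truth(layers, truth)
    out: dict[str, float] = {}
    for layer_name in table.index:
        for es_code, es_name in ((TRUTH_SMALL, "es1"), (TRUTH_LARGE, "es2"),
                                 (TRUTH_NOISE, "es0")):
            out[f"{layer_name}:{es_name}"] = table.loc[layer_name, es_code]
    return out


def run_grid(
    conditions: list[SimCondition],
    n_reps: int,
    alt: AlternativeSpec,
    threshold_grid: list[DecisionThresholds],
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate, fit and classify over a condition x threshold grid.

    For every condition, ``n_reps`` independent runs are generated; each is
    fitted once and classified under every threshold setting.  Returns a
    tidy table with one row per condition x thresholds x layer carrying
    the mean and SD (across replicates) of the voxel counts per truth
    class, mirroring the study's per-layer summary tables.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for cond in conditions:
        reg = build_design(cond.design)
        child_seeds = ss.spawn(n_reps)
        per_thr: dict[int, list[dict[str, float]]] = {
            i: [] for i in range(len(threshold_grid))
        }
        for rep in range(n_reps):
            rng = np.random.default_rng(child_seeds[rep])
            img, truth = simulate_run(cond, reg, rng=rng)
            maps = fit_glm(img, reg, truth.mask)
            p0, p1 = dual_p_values(maps.t, maps.se, maps.df, maps.mask, alt)
            for i, thr in enumerate(threshold_grid):
                layers = classify_layers(p0, p1, thr, maps.mask)
                per_thr[i].append(_count_row(layers, truth))
        for i, thr in enumerate(threshold_grid):
            df = pd.DataFrame(per_thr[i])
            means, sds = df.mean(axis=0), df.std(axis=0, ddof=1)
            for layer_name in sorted({k.split(":")[0] for k in df.columns}):
                rows.append({
                    "n_scans": cond.n_scans,
                    "sigma_noise": cond.sigma_noise,
                    "null_mode": thr.null_mode,
                    "alpha": thr.alpha if thr.null_mode == "uncorrected" else thr.q,
                    "beta": thr.beta,
                    "layer": layer_name,
                    "n_reps": n_reps,
                    **{
                        f"{es}_{stat}": (means if stat == "mean" else sds)[
                            f"{layer_name}:{es}"
                        ]
                        for es, stat in itertools.product(
                            ("es1", "es2", "es0"), ("mean", "sd")
                        )
                    },
                })
    return pd.DataFrame(rows)
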