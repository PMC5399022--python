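"""Scoring of layered maps against ground truth or a data-derived reference.

Two complementary rates summarize how a layer relates to a set of
"scientifically relevant" voxels (reference effect size >= mu_delta1):

* RDR (reference detection rate) — fraction of the relevant voxels that a
  layer captures; sensitivity-like.
* LDR (layer detection rate) — fraction of a layer's voxels that are
  relevant; precision-like.

For the inactive (and NHST non-significant) layer the roles flip and the
rates are computed against the irrelevant voxels (effect size < mu_delta1).
The leave-one-out pipeline holds out one run, classifies it, and scores it
against the unthresholded fixed-effects mean of the remaining runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import Regressor, fit_glm
from .model import (
    LAYER_ACTIVE,
    LAYER_INACTIVE,
    LAYER_NAMES,
    LAYER_PRACTICALLY_INSIGNIFICANT,
    LAYER_UNCERTAIN,
    AlternativeSpec,
    DecisionThresholds,
    LayerMap,
    classify_layers,
    dual_p_values,
)

__all__ = [
    "ReferenceMap",
    "count_layers_by_truth",
    "rdr",
    "ldr",
    "inactive_orientation_metrics",
    "build_reference",
    "loocv_evaluate",
    "summarize_layer_es",
]

_LAYER_CODES = (
    LAYER_ACTIVE,
    LAYER_INACTIVE,
    LAYER_UNCERTAIN,
    LAYER_PRACTICALLY_INSIGNIFICANT,
)


@dataclass
class ReferenceMap:
    """Fixed-effects reference: voxelwise mean effect size of the held-in
    runs and the derived relevance indicator ``es >= mu_delta1``."""

    es: np.ndarray
    mu_delta1: float

    @property
    def relevance(self) -> np.ndarray:
        return self.es >= self.mu_delta1

    @property
    def irrelevance(self) -> np.ndarray:
        return self.es < self.mu_delta1


def count_layers_by_truth(layers: LayerMap, truth) -> pd.DataFrame:
    """4 x 3 contingency table: layer (rows) by truth class (columns).

    ``truth`` provides integer ``labels`` (0 noise, 1 small ES, 2 large ES)
    and the analysis ``mask``; counting is restricted to in-mask voxels, so
    each truth class's column sums to its in-mask population.
    """
    labels = np.asarray(truth.labels)
    mask = np.asarray(truth.mask, dtype=bool)
    if labels.shape != layers.labels.shape or mask.shape != layers.labels.shape:
        raise ValueError("layer map and ground truth are on different grids")
    table = {
        tc: [
            int(np.count_nonzero(mask & (labels == tc) & (layers.labels == lc)))
            for lc in _LAYER_CODES
        ]
        for tc in (0, 1, 2)
    }
    return pd.DataFrame(
        table, index=[LAYER_NAMES[lc] for lc in _LAYER_CODES]
    )


def rdr(layer_mask: np.ndarray, relevance_mask: np.ndarray) -> float:
    """|layer ∩ relevant| / |relevant| — coverage of the relevant set."""
    layer_mask = np.asarray(layer_mask, dtype=bool)
    relevance_mask = np.asarray(relevance_mask, dtype=bool)
    n_rel = int(relevance_mask.sum())
    if n_rel == 0:
        raise ValueError("relevance set is empty; RDR is undefined")
    return float(np.count_nonzero(layer_mask & relevance_mask) / n_rel)


def ldr(layer_mask: np.ndarray, relevance_mask: np.ndarray) -> float:
    """|layer ∩ relevant| / |layer|; NaN for an empty layer (the step is
    then excluded from cross-validation averages)."""
    layer_mask = np.asarray(layer_mask, dtype=bool)
    relevance_mask = np.asarray(relevance_mask, dtype=bool)
    n_layer = int(layer_mask.sum())
    if n_layer == 0:
        return float("nan")
    return float(np.count_nonzero(layer_mask & relevance_mask) / n_layer)


def inactive_orientation_metrics(
    layer_mask: np.ndarray,
    es_map: np.ndarray,
    mu_delta1: float,
) -> tuple[float, float]:
    """RDR and LDR of an exclusion-oriented layer, computed against the
    scientifically irrelevant voxels (``es < mu_delta1``)."""
    irrelevant = np.asarray(es_map) < mu_delta1
    return rdr(layer_mask, irrelevant), ldr(layer_mask, irrelevant)


def build_reference(
    runs: list[np.ndarray],
    held_out: int,
    mu_delta1: float,
) -> ReferenceMap:
    """Unweighted voxelwise mean of all effect maps except ``held_out``.

    The contributing maps are not thresholded.  Requires >= 2 runs.
    """
    if len(runs) < 2:
        raise ValueError("at least 2 runs are needed to build a reference")
    if not 0 <= held_out < len(runs):
        raise IndexError(f"held_out index {held_out} out of range")
    stack = np.stack(
        [np.asarray(r, dtype=np.float64) for i, r in enumerate(runs)
         if i != held_out]
    )
    return ReferenceMap(es=stack.mean(axis=0), mu_delta1=mu_delta1)


def _step_metrics(
    layers: LayerMap,
    reference: ReferenceMap,
    mask: np.ndarray,
) -> list[dict]:
    """RDR/LDR for the four ABT layers plus the NHST dichotomy, one step."""
    relevant = reference.relevance & mask
    irrelevant = reference.irrelevance & mask
    rows = []
    nhst_significant = (
        layers.layer_mask(LAYER_ACTIVE)
        | layers.layer_mask(LAYER_PRACTICALLY_INSIGNIFICANT)
    )
    sets = [
        ("active", layers.layer_mask(LAYER_ACTIVE), relevant),
        ("inactive", layers.layer_mask(LAYER_INACTIVE), irrelevant),
        ("uncertain", layers.layer_mask(LAYER_UNCERTAIN), relevant),
        ("practically_insignificant",
         layers.layer_mask(LAYER_PRACTICALLY_INSIGNIFICANT), relevant),
        ("significant", nhst_significant, relevant),
        ("non_significant", mask & ~nhst_significant, irrelevant),
    ]
    for name, lmask, ref_set in sets:
        n_ref = int(ref_set.sum())
        rows.append({
            "layer": name,
            "rdr": (float(np.count_nonzero(lmask & ref_set) / n_ref)
                    if n_ref else float("nan")),
            "ldr": ldr(lmask, ref_set),
            "layer_size": int(lmask.sum()),
        })
    return rows


def loocv_evaluate(
    runs: list[np.ndarray],
    reg: Regressor,
    alt: AlternativeSpec,
    thresholds: list[DecisionThresholds] | DecisionThresholds,
    mask: np.ndarray,
) -> pd.DataFrame:
    """Leave-one-out evaluation of single-run layer maps.

    Each step fits the GLM on the held-out 4D run, classifies it under each
    threshold setting, and scores every layer (plus the NHST significant /
    non-significant dichotomy) against the fixed-effects mean effect map of
    the remaining runs.  Returns per-threshold, per-layer means and SDs of
    RDR and LDR across steps; steps where a layer is empty contribute NaN
    to that layer's LDR and are dropped from its average.
    """
    if len(runs) < 3:
        raise ValueError("leave-one-out evaluation needs at least 3 runs")
    if isinstance(thresholds, DecisionThresholds):
        thresholds = [thresholds]
    mask = np.asarray(mask, dtype=bool)

    fits = [fit_glm(run, reg, mask) for run in runs]
    records: list[dict] = []
    for step in range(len(runs)):
        reference = build_reference([f.beta for f in fits], step,
                                    alt.mu_delta1)
        held = fits[step]
        p0, p1 = dual_p_values(held.t, held.se, held.df, held.mask, alt)
        for i, thr in enumerate(thresholds):
            layers = classify_layers(p0, p1, thr, held.mask)
            for row in _step_metrics(layers, reference, held.mask):
                records.append({"step": step, "threshold_index": i, **row})

    long = pd.DataFrame(records)
    grouped = long.groupby(["threshold_index", "layer"], sort=False)
    out = grouped.agg(
        rdr_mean=("rdr", "mean"),
        rdr_sd=("rdr", "std"),
        ldr_mean=("ldr", "mean"),
        ldr_sd=("ldr", "std"),
        mean_layer_size=("layer_size", "mean"),
        n_steps=("step", "count"),
    ).reset_index()
    meta = pd.DataFrame([
        {
            "threshold_index": i,
            "null_mode": t.null_mode,
            "alpha": t.alpha,
            "q": t.q,
            "beta": t.beta,
        }
        for i, t in enumerate(thresholds)
    ])
    return out.merge(meta, on="threshold_index")


def summarize_layer_es(layers: LayerMap, es_map: np.ndarray) -> pd.DataFrame:
    """Mean, median and SD of the reference effect size within each layer.

    Empty layers report NaN for all three statistics.
    """
    es_map = np.asarray(es_map, dtype=float)
    if es_map.shape != layers.labels.shape:
        raise ValueError("effect-size map and layer map are on different grids")
    rows = []
    for code in _LAYER_CODES:
        values = es_map[layers.layer_mask(code)]
        if values.size:
            rows.append({
                "layer": LAYER_NAMES[code],
                "n_voxels": int(values.size),
                "mean": float(values.mean()),
                "median": float(np.median(values)),
                "sd": float(values.std(ddof=0)),
            })
        else:
            rows.append({
                "layer": LAYER_NAMES[code], "n_voxels": 0,
                "mean": float("nan"), "median": float("nan"),
                "sd": float("nan"),
            })
    return pd.DataFrame(rows).set_index("layer")
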