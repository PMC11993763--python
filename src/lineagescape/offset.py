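"""Adaptively enriched RDA, adaptive index, and genetic-offset maps.

The adaptive index projects each grid cell's climate (standardized by the
calibration demes' mean/s.d.) onto the constrained axes of an RDA fitted
on candidate SNPs; the genetic offset between two scenarios is the
Euclidean distance between a cell's index vectors, a proxy for the allele-
frequency shift climate change would demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gea import RdaModel, rda_fit
from .io import ClimateGrid

logger = logging.getLogger("lineagescape")


@dataclass
class AdaptiveIndexMap:
    """Per-cell adaptive-index values for one climate scenario.

    ``index`` has shape (n_rows, n_cols, n_axes); NaN outside the range
    mask or where a predictor is missing.  Index values are on the RDA
    linear-combination site-score scale, so each axis already carries its
    eigenvalue weight.
    """

    scenario: str
    index: np.ndarray
    axes_used: int
    predictor_names: list[str]


@dataclass
class OffsetMap:
    """Non-negative per-cell genetic offset between two scenarios."""

    offset: np.ndarray
    scenario_pair: tuple[str, str]
    group_summaries: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Predictor ranking
# ---------------------------------------------------------------------------

def predictor_importance(freq: pd.DataFrame, climate: pd.DataFrame
                         ) -> pd.Series:
    """Marginal importance of each variable: the constrained-variance share
    of a single-predictor RDA of the candidate frequencies on it."""
    scores = {}
    for var in climate.columns:
        model = rda_fit(freq, climate[[var]])
        scores[var] = model.constrained_fraction
    return pd.Series(scores).sort_values(ascending=False)


def rank_offset_predictors(importance: pd.Series, climate: pd.DataFrame,
                           corr_threshold: float = 0.7,
                           n_select: int = 5) -> list[str]:
    """Greedy top-importance selection skipping collinear variables.

    Walks the importance ranking from the top and keeps a variable only if
    its |Pearson r| across demes with every already-kept variable is below
    ``corr_threshold``, until ``n_select`` variables are kept.
    """
    selected: list[str] = []
    for var in importance.sort_values(ascending=False).index:
        if len(selected) >= n_select:
            break
        x = climate[var].to_numpy(float)
        ok = True
        for prev in selected:
            r = np.corrcoef(x, climate[prev].to_numpy(float))[0, 1]
            if abs(r) >= corr_threshold:
                logger.info("rank_offset_predictors: %s skipped (|r|=%.2f "
                            "with %s)", var, abs(r), prev)
                ok = False
                break
        if ok:
            selected.append(var)
    return selected


def enriched_rda(freq: pd.DataFrame, candidate_ids: list[str],
                 climate: pd.DataFrame, predictors: list[str]) -> RdaModel:
    """RDA restricted to the candidate SNPs and the selected predictors."""
    if len(candidate_ids) < 2:
        raise ValueError("need at least 2 candidate SNPs")
    return rda_fit(freq[list(candidate_ids)], climate[list(predictors)])


# ---------------------------------------------------------------------------
# Index and offset
# ---------------------------------------------------------------------------

def adaptive_index(model: RdaModel, grid: ClimateGrid, axes: int = 1,
                   range_mask: np.ndarray | None = None) -> AdaptiveIndexMap:
    """Project every grid cell's climate onto the first ``axes`` RDA axes.

    Cell predictor values are standardized with the calibration demes'
    mean/s.d., so a cell whose climate equals a calibration deme's climate
    gets exactly that deme's site score.
    """
    axes = min(axes, model.n_axes)
    nr, nc = grid.shape
    stack = np.stack([grid.layers[v] for v in model.predictor_names], axis=-1)
    flat = stack.reshape(-1, len(model.predictor_names))
    finite = np.isfinite(flat).all(axis=1)
    idx = np.full((nr * nc, axes), np.nan)
    idx[finite] = model.project(flat[finite], axes=axes)
    idx = idx.reshape(nr, nc, axes)
    if range_mask is not None:
        idx[~range_mask] = np.nan
    return AdaptiveIndexMap(scenario=grid.scenario, index=idx,
                            axes_used=axes,
                            predictor_names=list(model.predictor_names))


def genetic_offset(current: AdaptiveIndexMap, future: AdaptiveIndexMap,
                   group_masks: dict[str, np.ndarray] | None = None
                   ) -> OffsetMap:
    """Per-cell Euclidean distance between current and future index vectors.

    With one axis this is the absolute index difference.  Optional group
    masks (e.g. per lineage / ESU) yield median and quartile summaries.
    """
    if current.index.shape != future.index.shape:
        raise ValueError("index maps are on different grids")
    if current.predictor_names != future.predictor_names:
        raise ValueError("index maps come from different models")
    off = np.sqrt(((future.index - current.index) ** 2).sum(axis=-1))
    rows = []
    if group_masks:
        for group, mask in group_masks.items():
            vals = off[mask & np.isfinite(off)]
            if vals.size:
                rows.append({
                    "group": group,
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                    "n_cells": int(vals.size),
                })
    summaries = pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame()
    return OffsetMap(offset=off,
                     scenario_pair=(current.scenario, future.scenario),
                     group_summaries=summaries)
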