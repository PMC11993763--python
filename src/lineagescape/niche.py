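"""Climatic-niche quantification and habitat-selection tests.

Environmental-space niche overlap follows the occupancy-density framework:
a PCA of the background climate defines a 2-D environmental space, kernel
densities of occurrences are corrected by background availability and
normalized, Schoener's D = 1 - 0.5 * sum |z1 - z2| measures overlap, and a
permutation equivalency test (pool, re-split, recompute D; lower tail)
tests niche divergence.  Habitat use versus availability is compared with
a bootstrap sign test per land-cover category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import BIOCLIM_VARS, ClimateGrid, OccurrenceSet

logger = logging.getLogger("lineagescape")


@dataclass
class DensitySurface:
    """Normalized occupancy density on an R x R environmental grid."""

    grid: np.ndarray
    extent: tuple[tuple[float, float], tuple[float, float]]  # (x0,x1),(y0,y1)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if (g < 0).any():
            raise ValueError("density surface has negative cells")
        total = g.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"density surface sums to {total}, not 1")
        self.grid = g


# ---------------------------------------------------------------------------
# Environmental space
# ---------------------------------------------------------------------------

def environmental_pca(background: pd.DataFrame,
                      occurrences: list[pd.DataFrame],
                      variables: tuple[str, ...] = BIOCLIM_VARS
                      ) -> tuple[np.ndarray, list[np.ndarray]]:
    """PCA of the pooled background climate; occurrences projected into it.

    Returns the background's 2-D scores and a list of 2-D score arrays,
    one per occurrence table, in the same space.
    """
    xb = background[list(variables)].to_numpy(float)
    mean = xb.mean(axis=0)
    sd = xb.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    zb = (xb - mean) / sd
    _, _, vt = np.linalg.svd(zb - zb.mean(axis=0), full_matrices=False)
    rot = vt[:2].T
    for a in range(2):
        j = np.argmax(np.abs(rot[:, a]))
        if rot[j, a] < 0:
            rot[:, a] *= -1
    bg_scores = zb @ rot
    occ_scores = [((o[list(variables)].to_numpy(float) - mean) / sd) @ rot
                  for o in occurrences]
    return bg_scores, occ_scores


def _grid_axes(extent, R):
    (x0, x1), (y0, y1) = extent
    xe = np.linspace(x0, x1, R + 1)
    ye = np.linspace(y0, y1, R + 1)
    return xe, ye


def _kde_on_grid(points: np.ndarray, extent, R: int,
                 bandwidth: tuple[float, float] | None = None) -> np.ndarray:
    """Binned Gaussian kernel density on an R x R grid (unnormalized ok)."""
    xe, ye = _grid_axes(extent, R)
    h, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=(xe, ye))
    n = len(points)
    if bandwidth is None:
        # per-axis normal-reference rule
        bandwidth = tuple(1.06 * points[:, a].std(ddof=1) * n ** (-1 / 5)
                          if n > 1 else 0.0 for a in (0, 1))
    cell = ((extent[0][1] - extent[0][0]) / R, (extent[1][1] - extent[1][0]) / R)
    sigma = tuple(max(b / c, 1e-9) for b, c in zip(bandwidth, cell))
    return gaussian_filter(h, sigma=sigma, mode="constant")


def occurrence_density(scores: np.ndarray, background_scores: np.ndarray,
                       R: int = 100, correct_availability: bool = True,
                       bandwidth: tuple[float, float] | None = None
                       ) -> DensitySurface:
    """Availability-corrected occurrence density in environmental space.

    Gaussian kernel densities of occurrences (and of the background) are
    evaluated on an R x R grid spanning the pooled background extent;
    occupancy = occurrence density / background density where background
    density is positive, else 0; renormalized to sum 1.
    """
    scores = np.asarray(scores, float)
    if len(scores) < 5:
        raise ValueError("need at least 5 occurrences for a stable density")
    bg = np.asarray(background_scores, float)
    pad = [(bg[:, a].max() - bg[:, a].min()) * 0.05 or 1.0 for a in (0, 1)]
    extent = ((bg[:, 0].min() - pad[0], bg[:, 0].max() + pad[0]),
              (bg[:, 1].min() - pad[1], bg[:, 1].max() + pad[1]))
    if bandwidth is None:
        # shared normal-reference bandwidth from the background: the same
        # kernel must smooth both surfaces or their ratio is biased
        bandwidth = tuple(
            1.06 * bg[:, a].std(ddof=1) * len(bg) ** (-1 / 5) for a in (0, 1))
    occ_d = _kde_on_grid(scores, extent, R, bandwidth)
    if correct_availability:
        bg_d = _kde_on_grid(bg, extent, R, bandwidth)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(bg_d > 0, occ_d / bg_d, 0.0)
    else:
        z = occ_d
    total = z.sum()
    if total <= 0:
        raise ValueError("density surface is identically zero")
    return DensitySurface(grid=z / total, extent=extent)


def schoener_d(z1: DensitySurface, z2: DensitySurface) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2| in [0, 1].

    For surfaces that each sum to 1 this equals sum min(z1, z2), which is
    the form computed here: it is exact (no floating-point residue) at the
    no-overlap and full-overlap boundaries.
    """
    if z1.grid.shape != z2.grid.shape:
        raise ValueError("density surfaces are on different grids")
    return float(np.clip(np.minimum(z1.grid, z2.grid).sum(), 0.0, 1.0))


def equivalency_test(occ1_scores: np.ndarray, occ2_scores: np.ndarray,
                     background_scores: np.ndarray, n_perm: int = 1000,
                     tail: str = "lower", R: int = 100,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[float, float]:
    """Niche equivalency test: pool occurrences, re-split, recompute D.

    The null distribution of Schoener's D is built by randomly re-splitting
    the pooled occurrence scores at the original sample sizes.  With the
    "lower" tail, p = (#{D_null <= D_obs} + 1) / (n_perm + 1): small p
    means the observed overlap is lower than expected for equivalent
    niches.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    occ1 = np.asarray(occ1_scores, float)
    occ2 = np.asarray(occ2_scores, float)
    bg = np.asarray(background_scores, float)

    def _d(a: np.ndarray, b: np.ndarray) -> float:
        return schoener_d(occurrence_density(a, bg, R=R),
                          occurrence_density(b, bg, R=R))

    d_obs = _d(occ1, occ2)
    pooled = np.concatenate([occ1, occ2])
    n1 = len(occ1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        d_null = _d(pooled[perm[:n1]], pooled[perm[n1:]])
        if tail == "lower":
            count += d_null <= d_obs
        else:
            count += d_null >= d_obs
    return d_obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Habitat use and selection
# ---------------------------------------------------------------------------

def habitat_proportions(occ: OccurrenceSet, grid: ClimateGrid,
                        availability_mask: np.ndarray,
                        layer: str = "landcover",
                        categories: tuple[str, ...] | None = None,
                        pooling: dict | None = None
                        ) -> pd.DataFrame:
    """Used vs available land-cover proportions.

    ``used`` is computed over the grid cells holding occurrence records,
    ``available`` over the cells of the availability mask.  ``pooling``
    optionally maps raw layer codes to pooled category labels (the 22 -> 7
    pooling); otherwise codes index ``categories`` directly.
    """
    lc = grid.layers[layer]
    r, c = grid.cell_index(occ.records["lon"].to_numpy(float),
                           occ.records["lat"].to_numpy(float))
    inside = (r >= 0) & (r < grid.shape[0]) & (c >= 0) & (c < grid.shape[1])
    cells = set(zip(r[inside], c[inside]))
    used_vals = np.array([lc[rr, cc] for rr, cc in sorted(cells)])
    avail_vals = lc[availability_mask]
    avail_vals = avail_vals[np.isfinite(avail_vals)]

    def _label(vals: np.ndarray) -> pd.Series:
        if pooling is not None:
            return pd.Series([pooling[int(v)] for v in vals])
        if categories is not None:
            return pd.Series([categories[int(v)] for v in vals])
        return pd.Series(vals.astype(int).astype(str))

    used = _label(used_vals).value_counts(normalize=True)
    avail = _label(avail_vals).value_counts(normalize=True)
    cats = categories or tuple(sorted(set(used.index) | set(avail.index)))
    out = pd.DataFrame({
        "used_prop": used.reindex(cats).fillna(0.0),
        "available_prop": avail.reindex(cats).fillna(0.0),
    })
    out.index.name = "category"
    return out


def habitat_sign_test(used_categories: np.ndarray,
                      available_categories: np.ndarray, category,
                      B: int = 1000,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[float, str]:
    """Bootstrap sign test of habitat selection for one category.

    The used-cell set is resampled with replacement B times (same size);
    f is the fraction of resamples in which the used proportion of the
    category strictly exceeds its available proportion.  Verdict:
    preferred if f >= 0.975, avoided if f <= 0.025, else proportional.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    used = np.asarray(used_categories)
    avail_prop = float(np.mean(np.asarray(available_categories) == category))
    is_cat = (used == category).astype(float)
    n = len(is_cat)
    if n == 0:
        raise ValueError("no used cells")
    idx = rng.integers(0, n, size=(B, n))
    props = is_cat[idx].mean(axis=1)
    f = float(np.mean(props > avail_prop))
    if f >= 0.975:
        verdict = "preferred"
    elif f <= 0.025:
        verdict = "avoided"
    else:
        verdict = "proportional"
    return f, verdict


def habitat_table(used_categories: np.ndarray,
                  available_categories: np.ndarray,
                  categories: tuple[str, ...], B: int = 1000,
                  rng: np.random.Generator | int | None = None
                  ) -> pd.DataFrame:
    """Full habitat-selection table: proportions, f, and verdict per category."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    used = np.asarray(used_categories)
    avail = np.asarray(available_categories)
    for cat in categories:
        f, verdict = habitat_sign_test(used, avail, cat, B=B, rng=rng)
        rows.append({
            "category": cat,
            "used_prop": float(np.mean(used == cat)),
            "available_prop": float(np.mean(avail == cat)),
            "f": f,
            "verdict": verdict,
        })
    return pd.DataFrame(rows).set_index("category")
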