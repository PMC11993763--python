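"""Synthetic landscape generator.

Emits genotypes, climate grids, occurrences, land cover and future-climate
scenarios with the statistical structure the downstream analyses assume:

* two hierarchical lineages (a west/east split) with weak internal
  structure, built from a two-level Balding–Nichols model;
* adaptive loci whose deme allele frequencies follow a logistic cline along
  a standardized climate gradient;
* bioclimatic layers made of planar gradients plus smooth Gaussian-field
  noise, with a configurable correlation between the temperature and
  precipitation blocks;
* occurrences drawn with probability proportional to a Gaussian climatic
  suitability around lineage-specific niche optima;
* categorical land cover with lineage-specific category weights;
* future scenarios as additive (optionally latitude-dependent) shifts.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .io import (ARCMIN_2_5, BIOCLIM_VARS, MISSING, ClimateGrid,
                 GeneIntervalTable, GenotypeMatrix, OccurrenceSet)

#: Plausible (mean, s.d.) per bioclim variable; temperature block in deg C
#: (or unitless seasonality), precipitation block in mm.
_BIO_SCALES: dict[str, tuple[float, float]] = {
    **{f"BIO{i}": (16.0 - i, 5.0) for i in range(1, 12)},
    **{f"BIO{i}": (600.0 - 30 * (i - 12), 200.0) for i in range(12, 20)},
}
_TEMP_BLOCK = tuple(f"BIO{i}" for i in range(1, 12))


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic landscape; the seed fixes every output."""

    seed: int = 0
    n_demes: int = 12
    n_ind_per_deme: int = 20
    n_neutral: int = 2000
    n_adaptive: int = 20
    f_lineage: float = 0.04      # lineage-vs-ancestral differentiation
    f_deme: float = 0.02         # deme-vs-lineage differentiation
    cline_slope: float = 3.0     # logistic slope per climate s.d.
    cline_var: str = "BIO1"      # variable driving the adaptive cline
    missing_rate: float = 0.0
    grid_shape: tuple[int, int] = (50, 50)
    origin: tuple[float, float] = (0.0, 30.0)
    resolution: float = 0.5      # degrees per cell
    noise_amp: float = 1.0       # Gaussian-field noise relative to gradient
    block_corr: float = 0.3      # corr between temperature & precip latents
    precip_axis: str = "lat"     # orientation of the precipitation gradient
    var_purity: float = 0.9      # loading of non-anchor variables on latent
    lineage_split: str = "ew"    # "ew" (west/east halves) or "none"
    min_deme_spacing: int = 5    # cells, Chebyshev
    # per-lineage (mean, s.d.) niche for (BIO1, BIO12)
    niche_optima: dict = field(default_factory=lambda: {
        "W": {"BIO1": (18.0, 3.0), "BIO12": (500.0, 150.0)},
        "E": {"BIO1": (10.0, 3.0), "BIO12": (700.0, 150.0)},
    })
    # per-lineage land-cover category weights (7 categories)
    landcover_weights: dict = field(default_factory=lambda: {
        "W": (0.05, 0.05, 0.30, 0.05, 0.40, 0.10, 0.05),
        "E": (0.10, 0.10, 0.45, 0.15, 0.10, 0.02, 0.08),
    })
    future_shift: dict = field(default_factory=lambda: {
        **{f"BIO{i}": 3.0 for i in range(1, 12)},     # block-wide warming
        **{f"BIO{i}": -100.0 for i in range(12, 20)}, # block-wide drying
    })
    future_lat_factor: float = 0.0  # delta scales by 1 + f*(2*rowfrac - 1)
    gene_span: int = 50          # bp covered either side of a tagged SNP
    gene_neutral_frac: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.f_deme <= self.f_lineage < 1.0):
            raise ValueError("need 0 < f_deme <= f_lineage < 1")
        if self.n_adaptive > self.n_neutral:
            raise ValueError("n_adaptive must not exceed n_neutral")


LANDCOVER_CATEGORIES = ("forest", "shrubs", "herbaceous", "bare",
                        "cropland", "urbanised", "other")


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests."""

    snp_ids: list[str]
    adaptive_snp_ids: list[str]
    deme_freq: np.ndarray          # n_demes x n_snps true allele frequencies
    deme_names: list[str]
    lineage_of_deme: list[str]
    deme_rc: np.ndarray            # n_demes x 2 (row, col) on the grid
    suitability: dict = field(default_factory=dict)  # group -> 2-D array

    @property
    def adaptive_index(self) -> np.ndarray:
        ids = set(self.adaptive_snp_ids)
        return np.array([s in ids for s in self.snp_ids])


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma_frac: float = 0.1) -> np.ndarray:
    """Standardized smooth Gaussian random field."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=max(1.0, sigma_frac * min(shape)))
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else a - a.mean()


def simulate_climate_grid(cfg: SyntheticConfig,
                          rng: np.random.Generator | None = None) -> ClimateGrid:
    """Current-scenario bioclim stack: gradients + smooth noise.

    BIO1 anchors a south–north temperature latent; BIO12 anchors a
    precipitation latent (gradient along ``cfg.precip_axis``) whose sample
    correlation with the temperature latent is exactly ``cfg.block_corr``
    (the raw precipitation field is orthogonalized against the temperature
    latent before mixing).  The other variables load on their block latent
    at ``cfg.var_purity`` plus independent smooth noise.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    nr, nc = cfg.grid_shape
    rows = np.arange(nr)[:, None] * np.ones((1, nc))
    cols = np.ones((nr, 1)) * np.arange(nc)[None, :]
    ygrad = _standardize(-rows)          # colder northwards
    wgrad = _standardize(cols) if cfg.precip_axis == "lon" else ygrad

    amp = cfg.noise_amp
    l_temp = _standardize(ygrad + amp * _smooth_field(cfg.grid_shape, rng))
    l_wet = _standardize(wgrad + amp * _smooth_field(cfg.grid_shape, rng))
    # orthogonalize so corr(l_temp, l_prec) is exactly block_corr
    resid = l_wet - (l_wet * l_temp).mean() / (l_temp ** 2).mean() * l_temp
    resid = _standardize(resid) if resid.std() > 0 else resid
    rho = cfg.block_corr
    l_prec = _standardize(rho * l_temp + np.sqrt(1 - rho ** 2) * resid)

    grid = ClimateGrid(origin=cfg.origin, resolution=cfg.resolution,
                       shape=cfg.grid_shape, scenario="current")
    for var in BIOCLIM_VARS:
        mean, sd = _BIO_SCALES[var]
        latent = l_temp if var in _TEMP_BLOCK else l_prec
        if var in ("BIO1", "BIO12"):
            z = latent
        else:
            w = cfg.var_purity
            noise = _smooth_field(cfg.grid_shape, rng) if amp > 0 else 0.0
            z = w * latent + np.sqrt(1 - w ** 2) * noise
        grid.add_layer(var, mean + sd * z)
    return grid


def project_future_climate(grid: ClimateGrid, cfg: SyntheticConfig,
                           scenario: str = "2071-2100") -> ClimateGrid:
    """Future scenario: current + per-variable additive delta.

    With ``future_lat_factor`` f != 0 the delta for a cell in row r scales
    by ``1 + f * (2 r/(nrows-1) - 1)``, i.e. larger shifts northwards for
    f > 0 (row 0 is the southernmost row).
    """
    fut = grid.copy(scenario=scenario)
    nr = grid.shape[0]
    rowfrac = (np.arange(nr) / max(nr - 1, 1))[:, None]
    scale = 1.0 + cfg.future_lat_factor * (2.0 * rowfrac - 1.0)
    for var, delta in cfg.future_shift.items():
        fut.layers[var] = grid.layers[var] + delta * scale
    return fut


# ---------------------------------------------------------------------------
# Demes and allele frequencies
# ---------------------------------------------------------------------------

def place_demes(cfg: SyntheticConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, list[str], list[str]]:
    """Seeded deme placement with minimum Chebyshev spacing.

    Returns (n_demes x 2 row/col array, deme names, lineage labels).  With
    ``lineage_split == "ew"`` demes in the western half of the grid belong
    to lineage W, the rest to E, with equal counts enforced.
    """
    nr, nc = cfg.grid_shape
    chosen: list[tuple[int, int]] = []
    spacing = cfg.min_deme_spacing
    if cfg.lineage_split == "ew":
        n_w = cfg.n_demes // 2
        halves = [(0, nc // 2, n_w), (nc // 2, nc, cfg.n_demes - n_w)]
    else:
        halves = [(0, nc, cfg.n_demes)]
    for c0, c1, k in halves:
        placed = 0
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 20000:
                raise RuntimeError("cannot place demes with requested spacing")
            r = int(rng.integers(0, nr))
            c = int(rng.integers(c0, c1))
            if all(max(abs(r - rr), abs(c - cc)) >= spacing for rr, cc in chosen):
                chosen.append((r, c))
                placed += 1
    rc = np.array(chosen)
    names = [f"deme{i:02d}" for i in range(cfg.n_demes)]
    if cfg.lineage_split == "ew":
        lineages = ["W" if c < nc // 2 else "E" for _, c in chosen]
    else:
        lineages = ["W"] * cfg.n_demes
    return rc, names, lineages


def _balding_nichols(p: np.ndarray, f: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def simulate_deme_frequencies(cfg: SyntheticConfig, grid: ClimateGrid,
                              rng: np.random.Generator | None = None
                              ) -> TruthTable:
    """True per-deme allele frequencies under the two-level island model.

    Neutral loci: ancestral p ~ U(0.05, 0.95); lineage frequency drawn by
    Balding–Nichols at ``f_lineage``; deme frequency drawn around the
    lineage frequency at ``f_deme``.  Adaptive loci: deme frequency is
    ``logistic(alpha + s * z)`` with z the deme's standardized cline-variable
    value, slope ``s = +-cline_slope`` (sign alternating over loci) and
    alpha solved so the mean frequency over demes is 0.5.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rc, names, lineages = place_demes(cfg, rng)
    n_loci = cfg.n_neutral + cfg.n_adaptive
    lineage_ids = sorted(set(lineages))
    lin_index = np.array([lineage_ids.index(l) for l in lineages])

    # neutral loci
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_neutral)
    lin_freq = np.stack([
        _balding_nichols(p_anc, cfg.f_lineage, rng) for _ in lineage_ids
    ])  # n_lineages x n_neutral
    neut = np.empty((cfg.n_demes, cfg.n_neutral))
    for d in range(cfg.n_demes):
        neut[d] = _balding_nichols(lin_freq[lin_index[d]], cfg.f_deme, rng)

    # adaptive loci: logistic cline in the standardized cline variable
    clim = grid.layers[cfg.cline_var][rc[:, 0], rc[:, 1]]
    z = (clim - clim.mean()) / clim.std() if clim.std() > 0 else clim * 0.0
    adapt = np.empty((cfg.n_demes, cfg.n_adaptive))
    for j in range(cfg.n_adaptive):
        s = cfg.cline_slope * (1 if j % 2 == 0 else -1)
        if cfg.cline_slope == 0:
            adapt[:, j] = 0.5
            continue
        alpha = brentq(lambda a: expit(a + s * z).mean() - 0.5, -50, 50)
        adapt[:, j] = expit(alpha + s * z)

    freq = np.concatenate([neut, adapt], axis=1)
    # interleave ids deterministically: adaptive loci get shuffled positions
    order = rng.permutation(n_loci)
    freq = freq[:, order]
    snp_ids = [f"snp{i + 1:06d}" for i in range(n_loci)]
    is_adaptive = order >= cfg.n_neutral
    adaptive_ids = [snp_ids[i] for i in np.flatnonzero(is_adaptive)]
    return TruthTable(snp_ids=snp_ids, adaptive_snp_ids=adaptive_ids,
                      deme_freq=freq, deme_names=names,
                      lineage_of_deme=lineages, deme_rc=rc)


def sample_genotypes(truth: TruthTable, cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Binomial(2, deme frequency) genotypes plus a sample table.

    Missing calls are injected uniformly at random at ``cfg.missing_rate``.
    Returns the matrix and a (sample, deme, lineage) table.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_demes, n_loci = truth.deme_freq.shape
    n = cfg.n_ind_per_deme
    calls = np.empty((n_demes * n, n_loci), dtype=np.int16)
    samples, demes, lineages = [], [], []
    for d in range(n_demes):
        calls[d * n:(d + 1) * n] = rng.binomial(
            2, truth.deme_freq[d], size=(n, n_loci))
        for i in range(n):
            samples.append(f"{truth.deme_names[d]}_ind{i:02d}")
            demes.append(truth.deme_names[d])
            lineages.append(truth.lineage_of_deme[d])
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    snps = [("1", 100 * (i + 1), sid) for i, sid in enumerate(truth.snp_ids)]
    g = GenotypeMatrix(samples=samples, snps=snps, calls=calls)
    table = pd.DataFrame({"sample": samples, "deme": demes,
                          "lineage": lineages})
    return g, table


def make_locality_table(truth: TruthTable, grid: ClimateGrid) -> pd.DataFrame:
    """Deme table with coordinates, lineage and the 19 bioclim values."""
    lon, lat = grid.cell_centers()
    r, c = truth.deme_rc[:, 0], truth.deme_rc[:, 1]
    data = {
        "deme": truth.deme_names,
        "lon": lon[r, c],
        "lat": lat[r, c],
        "lineage": truth.lineage_of_deme,
    }
    for var in BIOCLIM_VARS:
        data[var] = grid.layers[var][r, c]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Occurrences, suitability, land cover
# ---------------------------------------------------------------------------

def suitability_surface(grid: ClimateGrid, cfg: SyntheticConfig,
                        group: str) -> np.ndarray:
    """Gaussian climatic suitability exp(-Mahalanobis^2 / 2) for a lineage."""
    niche = cfg.niche_optima[group]
    maha2 = np.zeros(grid.shape)
    for var, (opt, tol) in niche.items():
        if np.isinf(tol):
            continue
        maha2 = maha2 + ((grid.layers[var] - opt) / tol) ** 2
    suit = np.exp(-0.5 * maha2)
    suit[~grid.finite_mask()] = np.nan
    return suit


def sample_occurrences(grid: ClimateGrid, cfg: SyntheticConfig, group: str,
                       season: str, n: int,
                       rng: np.random.Generator | None = None
                       ) -> OccurrenceSet:
    """Draw n presence records with cell probability proportional to
    suitability; the suitability surface is also stored as a grid layer."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    suit = suitability_surface(grid, cfg, group)
    grid.add_layer(f"suitability_{group}_{season}", suit)
    if n == 0:
        return OccurrenceSet(records=pd.DataFrame(
            columns=["lon", "lat", "season", "group"]))
    flat = np.nan_to_num(suit, nan=0.0).ravel()
    if flat.sum() <= 0:
        raise ValueError("suitability is zero everywhere")
    idx = rng.choice(flat.size, size=n, p=flat / flat.sum())
    r, c = np.unravel_index(idx, grid.shape)
    jitter = rng.uniform(-0.5, 0.5, size=(2, n))
    lon = grid.origin[0] + (c + 0.5 + jitter[0]) * grid.resolution
    lat = grid.origin[1] + (r + 0.5 + jitter[1]) * grid.resolution
    return OccurrenceSet(records=pd.DataFrame({
        "lon": lon, "lat": lat, "season": season, "group": group}))


def simulate_landcover(grid: ClimateGrid, cfg: SyntheticConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Categorical land-cover layer (codes 0..6).

    Cells in the western half draw from the W lineage's category weights,
    eastern cells from E's — the lineage-weighted composition the habitat
    tests measure.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    nr, nc = grid.shape
    lc = np.empty((nr, nc))
    k = len(LANDCOVER_CATEGORIES)
    w_west = np.asarray(cfg.landcover_weights["W"], dtype=float)
    w_east = np.asarray(cfg.landcover_weights.get("E", cfg.landcover_weights["W"]),
                        dtype=float)
    lc[:, :nc // 2] = rng.choice(k, size=(nr, nc // 2), p=w_west / w_west.sum())
    lc[:, nc // 2:] = rng.choice(k, size=(nr, nc - nc // 2),
                                 p=w_east / w_east.sum())
    grid.add_layer("landcover", lc)
    return lc


def make_gene_intervals(truth: TruthTable, g: GenotypeMatrix,
                        cfg: SyntheticConfig,
                        rng: np.random.Generator | None = None
                        ) -> GeneIntervalTable:
    """Synthetic genes tiling all adaptive SNPs plus a random fraction of
    neutral SNPs (``gene_neutral_frac``)."""
    rng = np.random.default_rng(cfg.seed + 4) if rng is None else rng
    adaptive = set(truth.adaptive_snp_ids)
    pos_of = {sid: (chrom, pos) for chrom, pos, sid in g.snps}
    covered = [sid for sid in truth.snp_ids if sid in adaptive]
    neutral = [sid for sid in truth.snp_ids if sid not in adaptive]
    n_extra = int(round(cfg.gene_neutral_frac * len(neutral)))
    covered += [neutral[i] for i in
                sorted(rng.choice(len(neutral), size=n_extra, replace=False))]
    intervals = []
    for i, sid in enumerate(sorted(covered, key=lambda s: pos_of[s][1])):
        chrom, pos = pos_of[sid]
        start = max(0, pos - 1 - cfg.gene_span)
        end = pos - 1 + cfg.gene_span + 1
        intervals.append((chrom, start, end, f"gene{i + 1:05d}"))
    return GeneIntervalTable(intervals=intervals)


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SyntheticConfig
    grid: ClimateGrid
    future_grid: ClimateGrid
    truth: TruthTable
    genotypes: GenotypeMatrix
    sample_table: pd.DataFrame
    localities: pd.DataFrame
    occurrences: dict  # (group, season) -> OccurrenceSet
    genes: GeneIntervalTable


def generate_dataset(cfg: SyntheticConfig,
                     n_occ_per_group: int = 400) -> SyntheticDataset:
    """Generate the full synthetic study: deterministic in ``cfg.seed``."""
    root = np.random.default_rng(cfg.seed)
    r_clim, r_freq, r_geno, r_occ, r_lc, r_gene = root.spawn(6)
    grid = simulate_climate_grid(cfg, r_clim)
    truth = simulate_deme_frequencies(cfg, grid, r_freq)
    g, samples = sample_genotypes(truth, cfg, r_geno)
    localities = make_locality_table(truth, grid)
    occurrences = {}
    for group in sorted(cfg.niche_optima):
        for season in ("breeding", "nonbreeding"):
            occ = sample_occurrences(grid, cfg, group, season,
                                     n_occ_per_group, r_occ)
            occurrences[(group, season)] = occ
        truth.suitability[group] = grid.layers[
            f"suitability_{group}_breeding"]
    simulate_landcover(grid, cfg, r_lc)
    genes = make_gene_intervals(truth, g, cfg, r_gene)
    future = project_future_climate(grid, cfg)
    return SyntheticDataset(cfg=cfg, grid=grid, future_grid=future,
                            truth=truth, genotypes=g, sample_table=samples,
                            localities=localities, occurrences=occurrences,
                            genes=genes)
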