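"""Population-genetic summaries and distance-matrix inference.

Allele frequencies, per-individual heterozygosity, pairwise multilocus
PhiST (Weir–Cockerham-type variance components, ratio of sums over loci),
genotype PCA, great-circle and climatic distances, and the Mantel /
multiple-regression-on-distance-matrices permutation tests used for
isolation-by-distance and isolation-by-climate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BIOCLIM_VARS, MISSING, GenotypeMatrix

logger = logging.getLogger("lineagescape")

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal labelled distance matrix."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"  # genetic_linearized | geographic_km | climatic

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal is not zero")
        if np.nanmin(v) < -1e-12:
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]


@dataclass
class MantelResult:
    r_m: float
    p: float
    n_perm: int
    tail: str


# ---------------------------------------------------------------------------
# Allele frequencies and heterozygosity
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix, deme_of_sample: pd.Series | dict
                       ) -> pd.DataFrame:
    """Per-deme alternate-allele frequencies (demes x SNPs).

    Frequency = alt-allele count / (2 x non-missing individuals); NaN where
    a deme has no calls at a locus.
    """
    if isinstance(deme_of_sample, dict):
        deme_of_sample = pd.Series(deme_of_sample)
    demes = deme_of_sample.reindex(g.samples)
    if demes.isna().any():
        raise ValueError("some samples have no deme assignment")
    calls = g.calls
    obs = calls != MISSING
    out = {}
    for deme in pd.unique(demes):
        rows = (demes == deme).to_numpy()
        n_obs = obs[rows].sum(axis=0)
        alt = np.where(obs[rows], calls[rows], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        if (n_obs == 0).any():
            logger.warning("deme %s has loci with no calls", deme)
        out[deme] = freq
    return pd.DataFrame(out, index=g.snp_ids).T


def individual_heterozygosity(g: GenotypeMatrix,
                              complete_cases_only: bool = True) -> pd.Series:
    """Proportion of heterozygous sites per individual.

    By default computed on the subset of sites with no missing call in any
    individual (the complete-cases dataset); set
    ``complete_cases_only=False`` to use each individual's own called sites.
    """
    calls = g.calls
    if complete_cases_only:
        keep = (calls != MISSING).all(axis=0)
        n_sites = int(keep.sum())
        if n_sites == 0:
            raise ValueError("no site is complete across all individuals")
        logger.info("heterozygosity computed on %d complete sites", n_sites)
        het = (calls[:, keep] == 1).mean(axis=1)
    else:
        obs = calls != MISSING
        het = (calls == 1).sum(axis=1) / obs.sum(axis=1)
    return pd.Series(het, index=g.samples, name="heterozygosity")


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components(freq: np.ndarray, n: np.ndarray, het: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) a, b, c components.

    freq, het: r x L per-population alt-allele frequency and observed
    heterozygote proportion; n: r x L non-missing diploid counts.
    Loci with fewer than two populations observed yield NaN components.
    """
    n = n.astype(float)
    valid = n > 0
    r_eff = valid.sum(axis=0)
    n_tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_tot / r_eff
        p_bar = np.nansum(np.where(valid, n * freq, 0.0), axis=0) / n_tot
        h_bar = np.nansum(np.where(valid, n * het, 0.0), axis=0) / n_tot
        s2 = np.nansum(np.where(valid, n * (freq - p_bar) ** 2, 0.0), axis=0) \
            / ((r_eff - 1) * n_bar)
        n_c = (n_tot - (n ** 2).sum(axis=0) / n_tot) / (r_eff - 1)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r_eff - 1) / r_eff * s2 - h_bar / 4)
            / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r_eff - 1) / r_eff * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
    bad = (r_eff < 2) | (n_bar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def per_locus_fst(g: GenotypeMatrix, deme_of_sample: pd.Series | dict
                  ) -> pd.Series:
    """Per-SNP multi-population Weir–Cockerham theta."""
    freq, n, het = _deme_summaries(g, deme_of_sample)
    a, b, c = _wc_components(freq, n, het)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return pd.Series(theta, index=g.snp_ids, name="fst")


def _deme_summaries(g: GenotypeMatrix, deme_of_sample: pd.Series | dict
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(deme_of_sample, dict):
        deme_of_sample = pd.Series(deme_of_sample)
    demes = deme_of_sample.reindex(g.samples)
    names = list(pd.unique(demes))
    calls = g.calls
    obs = calls != MISSING
    freq = np.empty((len(names), g.n_snps))
    nmat = np.empty_like(freq)
    het = np.empty_like(freq)
    for k, deme in enumerate(names):
        rows = (demes == deme).to_numpy()
        n_obs = obs[rows].sum(axis=0)
        alt = np.where(obs[rows], calls[rows], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
            het[k] = np.where(n_obs > 0,
                              (calls[rows] == 1).sum(axis=0) / n_obs, np.nan)
        nmat[k] = n_obs
    return freq, nmat, het


def multilocus_fst(g: GenotypeMatrix, deme_of_sample: pd.Series | dict
                   ) -> float:
    """Multilocus Weir–Cockerham theta as a ratio of sums over loci."""
    freq, n, het = _deme_summaries(g, deme_of_sample)
    a, b, c = _wc_components(freq, n, het)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den)


def pairwise_phist(g: GenotypeMatrix, deme_of_sample: pd.Series | dict,
                   min_deme_size: int = 3
                   ) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise multilocus PhiST and its linearization PhiST/(1-PhiST).

    Demes with fewer than ``min_deme_size`` individuals are excluded.
    Negative pairwise estimates are clipped at 0 before linearization.
    """
    if isinstance(deme_of_sample, dict):
        deme_of_sample = pd.Series(deme_of_sample)
    demes = deme_of_sample.reindex(g.samples)
    counts = demes.value_counts()
    keep = sorted(counts[counts >= min_deme_size].index)
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("pairwise_phist: dropping demes %s (< %d individuals)",
                    dropped, min_deme_size)
    if len(keep) < 2:
        raise ValueError("fewer than two demes meet the size threshold")
    freq, n, het = _deme_summaries(g, deme_of_sample)
    all_names = list(pd.unique(demes))
    idx = {d: all_names.index(d) for d in keep}
    m = len(keep)
    phi = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sel = [idx[keep[i]], idx[keep[j]]]
            a, b, c = _wc_components(freq[sel], n[sel], het[sel])
            den = np.nansum(a + b + c)
            val = np.nansum(a) / den if den > 0 else np.nan
            phi[i, j] = phi[j, i] = max(val, 0.0)
    with np.errstate(divide="ignore"):
        lin = phi / (1.0 - phi)
    return (DistanceMatrix(labels=keep, values=phi, kind="phist"),
            DistanceMatrix(labels=keep, values=lin, kind="genetic_linearized"))


# ---------------------------------------------------------------------------
# PCA and LD pruning
# ---------------------------------------------------------------------------

def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_threshold: float = 0.2) -> GenotypeMatrix:
    """Window-based r^2 pruning of correlated SNP pairs.

    Within each sliding window the later SNP of any pair with squared
    genotype correlation above the threshold is dropped.
    """
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    col_means = np.nanmean(calls, axis=0)
    filled = np.where(np.isnan(calls), col_means, calls)
    keep = np.ones(g.n_snps, dtype=bool)
    for start in range(0, g.n_snps, step):
        idx = [i for i in range(start, min(start + window, g.n_snps)) if keep[i]]
        if len(idx) < 2:
            continue
        block = filled[:, idx]
        sd = block.std(axis=0)
        ok = sd > 0
        corr = np.zeros((len(idx), len(idx)))
        if ok.sum() >= 2:
            sub = (block[:, ok] - block[:, ok].mean(axis=0)) / sd[ok]
            corr_ok = (sub.T @ sub) / len(sub)
            corr[np.ix_(ok, ok)] = corr_ok
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and corr[a, b] ** 2 > r2_threshold:
                    keep[idx[b]] = False
    return g.take_snps(keep)


def genotype_pca(g: GenotypeMatrix, n_components: int = 10,
                 scale: bool = True, ld_prune_first: bool = False
                 ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of the genotype matrix.

    Missing calls are mean-imputed per site; columns are centred and, when
    ``scale`` is on, divided by sqrt(p(1-p)) with p the alt-allele
    frequency.  Monomorphic sites are dropped.  The sign of each axis is
    fixed so the largest-|value| SNP loading is positive.

    Returns (scores DataFrame indexed by sample, explained-variance ratios,
    SNP loadings).
    """
    if ld_prune_first:
        g = ld_prune(g)
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    filled = np.where(np.isnan(calls), 2.0 * p, calls)
    poly = (p > 0) & (p < 1)
    x = filled[:, poly] - 2.0 * p[poly]
    if scale:
        x = x / np.sqrt(p[poly] * (1 - p[poly]))
    n_components = min(n_components, min(x.shape) - 1) or 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: largest-|loading| element positive per axis
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    ev = s ** 2
    evr = ev / (x ** 2).sum()
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (pd.DataFrame(scores, index=g.samples, columns=cols), evr, vt.T)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def geographic_distances(localities: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between demes."""
    lon = localities["lon"].to_numpy(float)
    lat = localities["lat"].to_numpy(float)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=localities["deme"].tolist(), values=d,
                          kind="geographic_km")


def climatic_distances(localities: pd.DataFrame,
                       variables: tuple[str, ...] = BIOCLIM_VARS,
                       check: bool = True) -> DistanceMatrix:
    """Euclidean distance across all PCs of the scaled bioclim table.

    Because a full PCA is a rotation, this equals the Euclidean distance on
    the z-scored variables; with ``check`` both routes are computed and
    asserted equal.  Constant columns carry no information and contribute 0.
    """
    x = localities[list(variables)].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    direct = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    if check:
        zc = z - z.mean(axis=0)
        _, _, vt = np.linalg.svd(zc, full_matrices=False)
        scores = zc @ vt.T  # all PCs
        via_pcs = np.sqrt(((scores[:, None, :] - scores[None, :, :]) ** 2)
                          .sum(axis=2))
        if not np.allclose(direct, via_pcs, atol=1e-8):
            raise AssertionError("PC-space and direct climatic distances differ")
    np.fill_diagonal(direct, 0.0)
    direct = (direct + direct.T) / 2
    return DistanceMatrix(labels=localities["deme"].tolist(), values=direct,
                          kind="climatic")


# ---------------------------------------------------------------------------
# Mantel and MRM permutation tests
# ---------------------------------------------------------------------------

def _check_labels(a: DistanceMatrix, b: DistanceMatrix) -> None:
    if a.labels != b.labels:
        raise ValueError("distance matrices have mismatched labels")


def mantel_test(a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 9999,
                tail: str = "greater",
                rng: np.random.Generator | int | None = None) -> MantelResult:
    """Mantel correlation with a simultaneous row/column permutation test.

    r_m is the Pearson correlation of the lower-triangle entries; the null
    is built by relabelling b's rows and columns together.  One-sided
    p-value with the (count + 1)/(n_perm + 1) convention.
    """
    _check_labels(a, b)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(a.labels)
    il, jl = np.tril_indices(n, k=-1)
    x = a.values[il, jl]
    y = b.values[il, jl]
    r_obs = _pearson(x, y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = b.values[np.ix_(perm, perm)][il, jl]
        r = _pearson(x, y_perm)
        if tail == "greater":
            count += r >= r_obs
        elif tail == "less":
            count += r <= r_obs
        else:
            count += abs(r) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_m=float(r_obs), p=float(p), n_perm=n_perm, tail=tail)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float(xc @ yc / den) if den > 0 else 0.0


def mrm(y: DistanceMatrix, xs: list[DistanceMatrix], n_perm: int = 9999,
        rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Multiple regression on distance matrices.

    OLS of y's unfolded lower triangle on the predictors' triangles (with
    intercept); per-coefficient two-sided permutation p-values obtained by
    simultaneously permuting y's rows and columns and re-estimating.
    """
    for x in xs:
        _check_labels(y, x)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(y.labels)
    il, jl = np.tril_indices(n, k=-1)
    design = np.column_stack([np.ones(il.size)] + [x.values[il, jl] for x in xs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictor distance matrices (rank deficient)")
    yv = y.values[il, jl]
    pinv = np.linalg.pinv(design)
    beta = pinv @ yv
    ss_res = ((yv - design @ beta) ** 2).sum()
    ss_tot = ((yv - yv.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    count = np.zeros(len(beta))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = y.values[np.ix_(perm, perm)][il, jl]
        b = pinv @ y_perm
        count += np.abs(b) >= np.abs(beta)
    pvals = (count + 1) / (n_perm + 1)
    names = ["intercept"] + [x.kind for x in xs]
    return pd.DataFrame({"coef": beta, "p": pvals, "n_perm": n_perm,
                         "r_squared": r2}, index=names)
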