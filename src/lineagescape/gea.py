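"""RDA-based genotype-environment association and candidate-SNP selection.

The candidate cascade: a redundancy analysis (RDA) of deme allele
frequencies on retained climate PCs; SNPs loading beyond +-k s.d. on the
significant axes become RDA candidates; a confounder filter drops
candidates whose frequencies track population structure or longitude more
strongly than climate; two differentiation scans (an FST scan against a
trimmed scaled chi-square null and a PC-regression Mahalanobis scan) are
intersected; the union of filtered RDA candidates and scan-intersection
outliers is restricted to SNPs inside genes.  A PCA of the final candidate
set delineates adaptive units (AUs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.covariance import MinCovDet

from .io import BIOCLIM_VARS, GenotypeMatrix
from .popgen import genotype_pca, per_locus_fst

logger = logging.getLogger("lineagescape")


@dataclass
class RdaModel:
    """A fitted constrained ordination (RDA).

    ``site_scores`` are linear-combination scores (linear in the
    standardized predictors), so any point in predictor space can be
    projected onto the axes with ``axis_weights`` — the basis of the
    adaptive index.
    """

    predictor_names: list[str]
    eigenvalues: np.ndarray
    snp_loadings: pd.DataFrame        # loci x axes, unit-norm columns
    site_scores: pd.DataFrame         # demes x axes
    coefficients: pd.DataFrame        # predictors x loci (standardized X)
    axis_weights: np.ndarray          # predictors x axes
    constrained_fraction: float
    predictor_means: np.ndarray
    predictor_sds: np.ndarray
    n_sites: int

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.predictor_means) / self.predictor_sds

    def project(self, x: np.ndarray, axes: int | None = None) -> np.ndarray:
        """Axis scores for raw predictor vectors (rows)."""
        w = self.axis_weights if axes is None else self.axis_weights[:, :axes]
        return self.standardize(x) @ w


# ---------------------------------------------------------------------------
# Climate PCA (predictor reduction)
# ---------------------------------------------------------------------------

def climate_pca(localities: pd.DataFrame, k: int = 3,
                variables: tuple[str, ...] = BIOCLIM_VARS
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """First ``k`` PCs of the scaled bioclim table, one row per deme.

    Returns (scores, explained-variance ratios of all PCs).  Warns when the
    scree is flat (no dominant gradient) and retention is arbitrary.
    """
    if len(localities) < 4:
        raise ValueError("need at least 4 demes for a climate PCA")
    x = localities[list(variables)].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    evr = s ** 2 / (s ** 2).sum()
    if evr.size > 1 and np.isclose(evr[0], evr[1], rtol=1e-6):
        logger.warning("climate_pca: flat scree; PC retention is arbitrary")
    for a in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    scores = u[:, :k] * s[:k]
    cols = [f"climPC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=localities["deme"].tolist(),
                         columns=cols), evr)


# ---------------------------------------------------------------------------
# RDA fit and significance
# ---------------------------------------------------------------------------

def rda_fit(freq: pd.DataFrame, predictors: pd.DataFrame) -> RdaModel:
    """Redundancy analysis of deme x SNP frequencies on deme predictors.

    The response columns are centred and the predictors standardized (a
    full-rank linear transform, so the constrained space is unchanged).
    Constrained axes come from the SVD of the fitted values
    ``Yhat = X (X'X)^-1 X' Y``.
    """
    if list(freq.index) != list(predictors.index):
        raise ValueError("freq and predictors must share deme index")
    n, q = predictors.shape
    if n < q + 2:
        raise ValueError(f"need at least {q + 2} demes for {q} predictors")
    xraw = predictors.to_numpy(float)
    means = xraw.mean(axis=0)
    sds = xraw.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [predictors.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant predictors: {bad}")
    x = (xraw - means) / sds
    rank = np.linalg.matrix_rank(x)
    if rank < q:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [(predictors.columns[i], predictors.columns[j])
                 for i in range(q) for j in range(i + 1, q)
                 if abs(corr[i, j]) > 0.999]
        raise ValueError(f"rank-deficient predictors; collinear pairs: {pairs}")
    y = freq.to_numpy(float)
    y = y - y.mean(axis=0)
    pinv_x = np.linalg.pinv(x)
    coef = pinv_x @ y
    yhat = x @ coef
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    n_axes = min(rank, n - 1, y.shape[1])
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    for a in range(n_axes):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    site = u * s
    tot = (y ** 2).sum()
    frac = float((s ** 2).sum() / tot) if tot > 0 else 0.0
    axes = [f"RDA{a + 1}" for a in range(n_axes)]
    axis_weights = pinv_x @ site  # predictors x axes; exact for lc scores
    return RdaModel(
        predictor_names=list(predictors.columns),
        eigenvalues=s ** 2 / max(n - 1, 1),
        snp_loadings=pd.DataFrame(vt.T, index=freq.columns, columns=axes),
        site_scores=pd.DataFrame(site, index=freq.index, columns=axes),
        coefficients=pd.DataFrame(coef, index=predictors.columns,
                                  columns=freq.columns),
        axis_weights=axis_weights,
        constrained_fraction=frac,
        predictor_means=means,
        predictor_sds=sds,
        n_sites=n,
    )


def rda_significance(freq: pd.DataFrame, predictors: pd.DataFrame,
                     n_perm: int = 999,
                     rng: np.random.Generator | int | None = None
                     ) -> pd.DataFrame:
    """Permutation ANOVA for the global RDA model and each axis.

    Global test: pseudo-F = (constrained SS / q) / (residual SS / (n-q-1)),
    null built by permuting predictor rows.  Axis k is tested sequentially:
    response and predictors are residualized on the previous axes' site
    scores and the first eigenvalue of the partial fit is compared with its
    permutation distribution (rows of the residualized response permuted).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    model = rda_fit(freq, predictors)
    n, q = predictors.shape
    x = (predictors.to_numpy(float) - model.predictor_means) / model.predictor_sds
    y = freq.to_numpy(float)
    y = y - y.mean(axis=0)
    df_resid = n - q - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    hat = x @ np.linalg.pinv(x)
    ss_con = float(((hat @ y) ** 2).sum())
    ss_tot = float((y ** 2).sum())
    f_obs = (ss_con / q) / ((ss_tot - ss_con) / df_resid)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssc = float(((hat @ y[perm]) ** 2).sum())
        f = (ssc / q) / ((ss_tot - ssc) / df_resid)
        count += f >= f_obs
    rows = [("global", f_obs, (count + 1) / (n_perm + 1))]

    # sequential axis tests
    site = model.site_scores.to_numpy()
    for k in range(model.n_axes):
        if k == 0:
            yk, xk = y, x
        else:
            w = site[:, :k]
            proj = w @ np.linalg.pinv(w)
            yk = y - proj @ y
            xk = x - proj @ x
        hatk = xk @ np.linalg.pinv(xk)
        sv = np.linalg.svd(hatk @ yk, compute_uv=False)
        lam = sv[0] ** 2
        ss_res_k = float((yk ** 2).sum()) - float(((hatk @ yk) ** 2).sum())
        denom = ss_res_k / df_resid if ss_res_k > 0 else np.finfo(float).tiny
        with np.errstate(over="ignore"):
            f_axis = lam / denom
        cnt = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ykp = yk[perm]
            sv_p = np.linalg.svd(hatk @ ykp, compute_uv=False)
            lam_p = sv_p[0] ** 2
            ss_res_p = float((ykp ** 2).sum()) - float(((hatk @ ykp) ** 2).sum())
            den_p = ss_res_p / df_resid if ss_res_p > 0 else np.finfo(float).tiny
            cnt += lam_p / den_p >= f_axis
        rows.append((f"RDA{k + 1}", f_axis, (cnt + 1) / (n_perm + 1)))
    return pd.DataFrame(rows, columns=["term", "pseudo_F", "p"]).set_index("term")


# ---------------------------------------------------------------------------
# Candidate selection cascade
# ---------------------------------------------------------------------------

def select_rda_candidates(model: RdaModel, axes: list[str] | None = None,
                          sd_mult: float = 3.0) -> pd.Series:
    """Flag SNPs with |loading - mean| > sd_mult * s.d. on any chosen axis.

    ``axes`` should be the statistically significant axes (default: RDA1).
    The implied two-tailed normal tail mass (0.0027 at 3 s.d.) is logged.
    """
    axes = axes or ["RDA1"]
    flags = pd.Series(False, index=model.snp_loadings.index)
    for ax in axes:
        lo = model.snp_loadings[ax]
        z = (lo - lo.mean()) / lo.std(ddof=1)
        flags |= z.abs() > sd_mult
    tail = 2 * stats.norm.sf(sd_mult)
    logger.info("select_rda_candidates: %d flagged on %s (normal tail mass "
                "%.4f)", int(flags.sum()), axes, tail)
    return flags


def filter_confounded(candidates: pd.Series, freq: pd.DataFrame,
                      climate_scores: pd.Series, structure_scores: pd.Series,
                      longitude: pd.Series) -> pd.DataFrame:
    """Drop candidates more associated with structure or geography.

    For each candidate SNP, |Spearman rho| of its deme frequencies against
    (i) the climate RDA1 site score, (ii) the neutral-genotype PC1 score
    and (iii) longitude is computed; the SNP survives only when (i) is the
    strict maximum.  Ties (including degenerate constant frequencies) are
    filtered conservatively.
    """
    out = pd.DataFrame(index=candidates.index, data={
        "rda_candidate": candidates,
        "rho_climate": np.nan, "rho_structure": np.nan, "rho_longitude": np.nan,
        "confound_filtered": False,
    })
    demes = freq.index
    refs = [climate_scores.reindex(demes).to_numpy(float),
            structure_scores.reindex(demes).to_numpy(float),
            longitude.reindex(demes).to_numpy(float)]
    for snp in candidates.index[candidates]:
        f = freq[snp].to_numpy(float)
        rhos = []
        for ref in refs:
            if np.std(f) == 0 or np.std(ref) == 0:
                rhos.append(np.nan)
            else:
                rhos.append(abs(stats.spearmanr(f, ref).statistic))
        out.loc[snp, ["rho_climate", "rho_structure", "rho_longitude"]] = rhos
        r_clim = rhos[0]
        others = [r for r in rhos[1:] if np.isfinite(r)]
        r_other = max(others) if others else np.nan
        keep = np.isfinite(r_clim) and (not np.isfinite(r_other)
                                        or r_clim > r_other)
        out.loc[snp, "confound_filtered"] = not keep
        if np.isfinite(r_clim) and np.isclose(r_clim, r_other):
            logger.info("filter_confounded: tie at %s, filtered", snp)
    n_kept = int((candidates & ~out["confound_filtered"]).sum())
    logger.info("filter_confounded: %d of %d candidates retained",
                n_kept, int(candidates.sum()))
    return out


def outlier_scan(g: GenotypeMatrix, deme_of_sample: pd.Series | dict,
                 method: str, fdr: float = 0.05, trim: float = 0.05,
                 n_pcs: int | None = None,
                 random_state: int = 0) -> pd.DataFrame:
    """Differentiation outlier scan (simplified FST or PC-based).

    ``fst``: per-SNP multi-deme Weir–Cockerham theta; the neutral null is a
    scaled chi-square with df = n_demes - 1 whose scale matches the trimmed
    mean of theta (``trim`` fraction cut from each tail).  ``pca``: each
    standardized SNP is regressed on the first K genotype PCs, the
    coefficient z-scores are combined into a robust Mahalanobis distance
    and referred to chi-square(K).  Both scans convert p-values to
    Benjamini-Hochberg q-values and flag q < ``fdr``.
    """
    if isinstance(deme_of_sample, dict):
        deme_of_sample = pd.Series(deme_of_sample)
    demes = deme_of_sample.reindex(g.samples)
    n_demes = demes.nunique()
    if n_demes < 2:
        raise ValueError("differentiation is undefined for a single deme")
    if method == "fst":
        theta = per_locus_fst(g, deme_of_sample).to_numpy()
        finite = np.isfinite(theta)
        tvals = np.sort(theta[finite])
        k = int(len(tvals) * trim)
        trimmed = tvals[k:len(tvals) - k] if len(tvals) > 2 * k else tvals
        df = n_demes - 1
        scale = max(trimmed.mean(), np.finfo(float).tiny) / df
        stat = np.where(finite, theta / scale, np.nan)
        pvals = np.where(finite, stats.chi2.sf(np.clip(stat, 0, None), df), np.nan)
        out = pd.DataFrame({"stat": theta, "p": pvals}, index=g.snp_ids)
    elif method == "pca":
        scores, evr, _ = genotype_pca(g, n_components=min(10, g.n_samples - 1))
        if n_pcs is None:
            n_pcs = max(1, int((evr > evr.mean()).sum()))
            n_pcs = min(n_pcs, scores.shape[1])
        pcs = scores.to_numpy()[:, :n_pcs]
        from .io import MISSING
        calls = g.calls.astype(float)
        calls[g.calls == MISSING] = np.nan
        mu = np.nanmean(calls, axis=0)
        filled = np.where(np.isnan(calls), mu, calls)
        sd = filled.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        ystd = (filled - mu) / sd
        xc = pcs - pcs.mean(axis=0)
        xtx_inv = np.linalg.inv(xc.T @ xc)
        beta = xtx_inv @ xc.T @ ystd            # K x loci
        resid = ystd - xc @ beta
        dfree = max(g.n_samples - n_pcs - 1, 1)
        sigma2 = (resid ** 2).sum(axis=0) / dfree
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (beta / se).T                    # loci x K
        z = np.where(np.isfinite(z), z, 0.0)
        mcd = MinCovDet(random_state=random_state).fit(z)
        d2 = mcd.mahalanobis(z)
        pvals = stats.chi2.sf(d2, n_pcs)
        out = pd.DataFrame({"stat": d2, "p": pvals}, index=g.snp_ids)
    else:
        raise ValueError(f"unknown scan method {method!r}")
    finite = np.isfinite(out["p"].to_numpy())
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite] = stats.false_discovery_control(out["p"].to_numpy()[finite])
    out["q"] = q
    out["outlier"] = out["q"] < fdr
    logger.info("outlier_scan[%s]: %d of %d flagged at q<%.3g",
                method, int(out["outlier"].sum()), len(out), fdr)
    return out


def combine_and_annotate(rda_flags: pd.DataFrame, fst_scan: pd.DataFrame,
                         pca_scan: pd.DataFrame, gene_hits: pd.DataFrame
                         ) -> tuple[pd.DataFrame, dict]:
    """Merge the cascade into a final candidate set.

    final = (RDA candidates surviving the confounder filter UNION the
    intersection of both differentiation scans) INTERSECT SNPs inside genes.
    Returns the per-SNP flag table and the stage counts.
    """
    idx = rda_flags.index
    hits = gene_hits.set_index("snp_id").reindex(idx)
    table = pd.DataFrame(index=idx, data={
        "rda_candidate": rda_flags["rda_candidate"],
        "confound_filtered": rda_flags["confound_filtered"],
        "fst_outlier": fst_scan["outlier"].reindex(idx).fillna(False),
        "pca_outlier": pca_scan["outlier"].reindex(idx).fillna(False),
        "in_gene": hits["gene_id"].notna(),
        "gene_id": hits["gene_id"],
    })
    rda_kept = table["rda_candidate"] & ~table["confound_filtered"]
    both = table["fst_outlier"] & table["pca_outlier"]
    merged = rda_kept | both
    table["final_candidate"] = merged & table["in_gene"]
    counts = {
        "rda_candidates": int(table["rda_candidate"].sum()),
        "rda_after_confound_filter": int(rda_kept.sum()),
        "scan_intersection_outliers": int(both.sum()),
        "merged_before_gene_filter": int(merged.sum()),
        "final_candidates": int(table["final_candidate"].sum()),
        "final_genes": int(table.loc[table["final_candidate"], "gene_id"]
                           .str.split(";").explode().nunique()),
    }
    logger.info("candidate cascade counts: %s", counts)
    return table, counts


# ---------------------------------------------------------------------------
# Correlation heatmap and adaptive units
# ---------------------------------------------------------------------------

def snp_climate_correlations(freq: pd.DataFrame, localities: pd.DataFrame,
                             snp_ids: list[str],
                             variables: tuple[str, ...] = BIOCLIM_VARS
                             ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """|Spearman rho| between candidate allele frequencies and bioclim values.

    Undefined correlations (constant columns) are reported as 0.  Row and
    column orders come from average-linkage clustering of the correlation
    patterns (distance = 1 - Pearson correlation of |rho| profiles), with
    deterministic tie-breaking by label.
    """
    f = freq[snp_ids].to_numpy(float)
    b = localities.set_index("deme").reindex(freq.index)[list(variables)] \
        .to_numpy(float)
    n_snp, n_var = f.shape[1], b.shape[1]
    rho = np.zeros((n_snp, n_var))
    for i in range(n_snp):
        if np.std(f[:, i]) == 0:
            logger.info("snp_climate_correlations: constant frequency at %s",
                        snp_ids[i])
            continue
        for j in range(n_var):
            if np.std(b[:, j]) == 0:
                continue
            rho[i, j] = abs(stats.spearmanr(f[:, i], b[:, j]).statistic)
    mat = pd.DataFrame(rho, index=snp_ids, columns=list(variables))

    def _order(m: np.ndarray, labels: list[str]) -> list[str]:
        if len(labels) < 3 or m.shape[1] < 2:
            return sorted(labels)
        from scipy.spatial.distance import pdist
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(m, metric="correlation")
        if not np.isfinite(d).all():  # zero-variance profiles
            return sorted(labels)
        leaves = hierarchy.leaves_list(hierarchy.linkage(d, method="average"))
        return [labels[i] for i in leaves]

    row_order = _order(np.nan_to_num(rho), list(snp_ids))
    col_order = _order(np.nan_to_num(rho.T), list(variables))
    return mat, row_order, col_order


def adaptive_units(g: GenotypeMatrix, deme_of_sample: pd.Series | dict,
                   candidate_ids: list[str], gap_threshold: float = 0.5
                   ) -> tuple[pd.Series, float]:
    """Delineate adaptive units from a PCA of candidate SNPs only.

    Deme-mean PC1 scores are split by sign; the discontinuity score is the
    largest gap between consecutive ordered deme scores as a fraction of
    the score range.  Below ``gap_threshold`` a single AU is reported.
    """
    if len(candidate_ids) < 2:
        raise ValueError("need at least 2 candidate SNPs to delineate AUs")
    keep = np.isin(g.snp_ids, candidate_ids)
    sub = g.take_snps(keep)
    scores, _, _ = genotype_pca(sub, n_components=2)
    if isinstance(deme_of_sample, dict):
        deme_of_sample = pd.Series(deme_of_sample)
    pc1 = scores["PC1"].groupby(deme_of_sample.reindex(scores.index)).mean()
    ordered = pc1.sort_values()
    gaps = np.diff(ordered.to_numpy())
    rng_ = ordered.iloc[-1] - ordered.iloc[0]
    gap_score = float(gaps.max() / rng_) if rng_ > 0 and len(gaps) else 0.0
    if gap_score < gap_threshold:
        labels = pd.Series("AU1", index=pc1.index)
    else:
        cut = ordered.index[int(np.argmax(gaps)) + 1]
        split_at = ordered[cut]
        labels = pd.Series(np.where(pc1 >= split_at, "AU2", "AU1"),
                           index=pc1.index)
    return labels, gap_score
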