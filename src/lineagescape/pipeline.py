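"""End-to-end pipeline driver.

Executes the stages in dependency order — structure -> ibd_ibc -> gea ->
niche -> offset -> range — on either the synthetic landscape (``input =
synthetic``) or user-supplied files, writing per-stage CSV tables, ASCII
grids and a JSON run manifest.  The run is a pure function of (inputs,
config, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gea import (adaptive_units, climate_pca, combine_and_annotate,
                  filter_confounded, outlier_scan, rda_fit, rda_significance,
                  select_rda_candidates, snp_climate_correlations)
from .io import (BIOCLIM_VARS, DEFAULT_CONFIG, ClimateGrid, annotate_snps,
                 pool_to_grid, read_bed, read_config, read_grid_stack,
                 read_localities, read_occurrences, read_vcf, write_ascii_grid,
                 write_manifest)
from .niche import environmental_pca, equivalency_test, habitat_table
from .offset import (adaptive_index, enriched_rda, genetic_offset,
                     predictor_importance, rank_offset_predictors)
from .popgen import (allele_frequencies, climatic_distances,
                     geographic_distances, genotype_pca,
                     individual_heterozygosity, mantel_test, mrm,
                     pairwise_phist)
from .ranges import binary_range, buffer_mask, migration_distance, \
    range_centroid, range_extent
from .synthetic import (LANDCOVER_CATEGORIES, SyntheticConfig,
                        generate_dataset)

logger = logging.getLogger("lineagescape")

STAGES = ("structure", "ibd_ibc", "gea", "niche", "offset", "range")


class DependencyError(RuntimeError):
    """A stage was requested without its required upstream input/stage."""


def _require(ctx: dict, key: str, stage: str, hint: str) -> object:
    if key not in ctx or ctx[key] is None:
        raise DependencyError(f"stage '{stage}' requires {hint}")
    return ctx[key]


def _load_inputs(cfg: dict, rng: np.random.Generator) -> dict:
    ctx: dict = {"cfg": cfg}
    if cfg.get("input", "synthetic") == "synthetic":
        scfg = SyntheticConfig(seed=int(cfg.get("seed", 0)))
        ds = generate_dataset(scfg)
        ctx.update(
            genotypes=ds.genotypes,
            deme_of_sample=ds.sample_table.set_index("sample")["deme"],
            localities=ds.localities,
            grid=ds.grid,
            future_grid=ds.future_grid,
            occurrences={k: pool_to_grid(v, cfg["grid_resolution_arcmin"])
                         for k, v in ds.occurrences.items()},
            genes=ds.genes,
            lineage_of_deme=dict(zip(ds.truth.deme_names,
                                     ds.truth.lineage_of_deme)),
            synthetic=ds,
        )
        return ctx
    if "vcf" in cfg:
        ctx["genotypes"] = read_vcf(cfg["vcf"], cfg["min_maf"],
                                    cfg["max_missing"])
    if "localities" in cfg:
        loc = read_localities(cfg["localities"])
        ctx["localities"] = loc
        if "sample_table" in cfg:
            st = pd.read_csv(cfg["sample_table"])
            ctx["deme_of_sample"] = st.set_index("sample")["deme"]
        ctx["lineage_of_deme"] = dict(zip(loc["deme"], loc["lineage"]))
    if "occurrences" in cfg:
        ctx["occurrences"] = {("all", "breeding"): pool_to_grid(
            read_occurrences(cfg["occurrences"]),
            cfg["grid_resolution_arcmin"])}
    if "grid_dir" in cfg:
        ctx["grid"] = read_grid_stack(cfg["grid_dir"], list(BIOCLIM_VARS))
    if "future_grid_dir" in cfg:
        ctx["future_grid"] = read_grid_stack(cfg["future_grid_dir"],
                                             list(BIOCLIM_VARS), "future")
    if "genes" in cfg:
        ctx["genes"] = read_bed(cfg["genes"])
    return ctx


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None
                 ) -> dict:
    """Run the configured stages and write the result bundle to disk."""
    cfg = dict(DEFAULT_CONFIG)
    if isinstance(config, (str, Path)):
        cfg.update(read_config(config))
    else:
        cfg.update(config)
    out = Path(out_dir or cfg.get("out_dir", "lineagescape_results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(seed)
    stage_rngs = dict(zip(STAGES, rng.spawn(len(STAGES))))
    stages = cfg.get("stages", "all")
    wanted = list(STAGES) if stages in ("all", None) else \
        [s.strip() for s in str(stages).split(",")]
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")

    ctx = _load_inputs(cfg, rng)
    completed: list[str] = []
    for stage in STAGES:
        if stage not in wanted:
            continue
        logger.info("stage %s: starting", stage)
        _STAGE_FUNCS[stage](ctx, cfg, out, stage_rngs[stage])
        completed.append(stage)
        logger.info("stage %s: done", stage)
    manifest = {
        "version": __version__,
        "seed": seed,
        "stages_completed": completed,
        "config": {k: v for k, v in sorted(cfg.items())
                   if isinstance(v, (int, float, str, bool))},
    }
    write_manifest(out / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_structure(ctx, cfg, out, rng):
    g = _require(ctx, "genotypes", "structure", "a genotype matrix (vcf=...)")
    demes = _require(ctx, "deme_of_sample", "structure",
                     "a sample->deme table")
    het = individual_heterozygosity(g)
    het.to_csv(out / "heterozygosity.csv")
    phist, lin = pairwise_phist(g, demes, cfg["min_deme_size"])
    phist.to_frame().to_csv(out / "phist.csv")
    lin.to_frame().to_csv(out / "phist_linearized.csv")
    scores, evr, _ = genotype_pca(g, scale=cfg["pca_scale"])
    scores.to_csv(out / "pca_scores.csv")
    freq = allele_frequencies(g, demes)
    freq.to_csv(out / "allele_frequencies.csv")
    ctx.update(freq=freq, phist_lin=lin, pca_scores=scores)


def _stage_ibd_ibc(ctx, cfg, out, rng):
    loc = _require(ctx, "localities", "ibd_ibc", "a locality table")
    lin = _require(ctx, "phist_lin", "ibd_ibc",
                   "the structure stage (linearized PhiST)")
    loc_kept = loc[loc["deme"].isin(lin.labels)].reset_index(drop=True)
    geo = geographic_distances(loc_kept)
    clim = climatic_distances(loc_kept)
    geo.to_frame().to_csv(out / "dist_geographic_km.csv")
    clim.to_frame().to_csv(out / "dist_climatic.csv")
    n_perm = int(cfg["n_perm"])
    rows = []
    for name, other in (("ibd_geographic", geo), ("ibc_climatic", clim)):
        res = mantel_test(lin, other, n_perm=n_perm, rng=rng)
        rows.append({"test": name, "statistic": res.r_m, "p": res.p,
                     "n_perm": res.n_perm})
    res = mantel_test(geo, clim, n_perm=n_perm, rng=rng)
    rows.append({"test": "geo_vs_climate", "statistic": res.r_m, "p": res.p,
                 "n_perm": n_perm})
    mrm_res = mrm(lin, [geo, clim], n_perm=n_perm, rng=rng)
    for term, row in mrm_res.iterrows():
        rows.append({"test": f"mrm_{term}", "statistic": row["coef"],
                     "p": row["p"], "n_perm": n_perm})
    pd.DataFrame(rows).to_csv(out / "ibd_ibc.csv", index=False)
    ctx.update(geo=geo, clim=clim)


def _stage_gea(ctx, cfg, out, rng):
    g = _require(ctx, "genotypes", "gea", "a genotype matrix")
    demes = _require(ctx, "deme_of_sample", "gea", "a sample->deme table")
    loc = _require(ctx, "localities", "gea", "a locality table")
    genes = _require(ctx, "genes", "gea", "a gene interval BED")
    freq = ctx.get("freq")
    if freq is None:
        freq = allele_frequencies(g, demes)
    # restrict to demes in the locality table and MAF-filter on the pooled data
    loc = loc[loc["deme"].isin(freq.index)].reset_index(drop=True)
    freq = freq.reindex(loc["deme"])
    clim_scores, _ = climate_pca(loc, k=int(cfg["n_climate_pcs"]))
    sig = rda_significance(freq, clim_scores, n_perm=min(999, int(cfg["n_perm"])),
                           rng=rng)
    sig.to_csv(out / "rda_anova.csv")
    model = rda_fit(freq, clim_scores)
    sig_axes = [t for t in sig.index if t.startswith("RDA")
                and sig.loc[t, "p"] < 0.05] or ["RDA1"]
    flags = select_rda_candidates(model, sig_axes, float(cfg["rda_sd_mult"]))
    # neutral-structure reference: PC1 of the non-candidate SNPs only
    neutral_g = g.take_snps(~np.isin(g.snp_ids, flags.index[flags]))
    pca_scores, _, _ = genotype_pca(neutral_g, scale=cfg["pca_scale"])
    pc1_deme = pca_scores["PC1"].groupby(
        demes.reindex(pca_scores.index)).mean().reindex(freq.index)
    conf = filter_confounded(
        flags, freq, model.site_scores["RDA1"],
        pc1_deme, loc.set_index("deme")["lon"])
    if not cfg.get("confound_filter", True):
        conf["confound_filtered"] = False
    fst_scan = outlier_scan(g, demes, "fst", float(cfg["outlier_fdr"]),
                            float(cfg["outlier_trim"]))
    pca_scan = outlier_scan(g, demes, "pca", float(cfg["outlier_fdr"]))
    hits = annotate_snps(g.snps, genes)
    table, counts = combine_and_annotate(conf, fst_scan, pca_scan, hits)
    table.to_csv(out / "candidates.csv")
    final_ids = table.index[table["final_candidate"]].tolist()
    if final_ids:
        mat, row_order, col_order = snp_climate_correlations(
            freq, loc, final_ids)
        mat.loc[row_order, col_order].to_csv(out / "snp_climate_correlations.csv")
    if len(final_ids) >= 2:
        au, gap = adaptive_units(g, demes, final_ids)
        au.rename("AU").to_frame().assign(gap_score=gap).to_csv(
            out / "adaptive_units.csv")
    write_manifest(out / "gea_counts.json", counts)
    ctx.update(candidates=table, cascade_counts=counts, freq=freq,
               gea_localities=loc, rda_model=model)


def _stage_niche(ctx, cfg, out, rng):
    occ = _require(ctx, "occurrences", "niche", "occurrence records")
    grid = _require(ctx, "grid", "niche", "a climate grid stack")
    groups = sorted({k[0] for k in occ})
    seasons = sorted({k[1] for k in occ})
    rows = []
    for season in seasons:
        present = [grp for grp in groups if (grp, season) in occ
                   and len(occ[(grp, season)]) >= 5]
        if len(present) < 2:
            continue
        g1, g2 = present[:2]
        o1, o2 = occ[(g1, season)], occ[(g2, season)]
        bg_mask = np.zeros(grid.shape, bool)
        for o in (o1, o2):
            bg_mask |= buffer_mask(o, grid, float(cfg["buffer_km"]))
        bg_mask &= grid.finite_mask()
        bg = pd.DataFrame({v: grid.layers[v][bg_mask] for v in BIOCLIM_VARS})
        clim_at = []
        for o in (o1, o2):
            r, c = grid.cell_index(o.records["lon"].to_numpy(),
                                   o.records["lat"].to_numpy())
            r = np.clip(r, 0, grid.shape[0] - 1)
            c = np.clip(c, 0, grid.shape[1] - 1)
            clim_at.append(pd.DataFrame(
                {v: grid.layers[v][r, c] for v in BIOCLIM_VARS}))
        bg_scores, (s1, s2) = environmental_pca(bg, clim_at)
        R = int(cfg["density_grid_R"])
        d_obs, p = equivalency_test(
            s1, s2, bg_scores, n_perm=int(cfg["equivalency_n_perm"]),
            R=R, rng=rng)
        rows.append({"season": season, "group1": g1, "group2": g2,
                     "schoener_d": d_obs, "p_equivalency": p,
                     "n_perm": int(cfg["equivalency_n_perm"])})
        # habitat tables per group (landcover layer required)
        if "landcover" in grid.layers:
            for grp, o in ((g1, o1), (g2, o2)):
                mask = buffer_mask(o, grid, float(cfg["buffer_km"]))
                mask &= grid.finite_mask()
                r, c = grid.cell_index(o.records["lon"].to_numpy(),
                                       o.records["lat"].to_numpy())
                r = np.clip(r, 0, grid.shape[0] - 1)
                c = np.clip(c, 0, grid.shape[1] - 1)
                used = np.array([LANDCOVER_CATEGORIES[int(v)]
                                 for v in grid.layers["landcover"][r, c]])
                avail = np.array([LANDCOVER_CATEGORIES[int(v)]
                                  for v in grid.layers["landcover"][mask]])
                tab = habitat_table(used, avail, LANDCOVER_CATEGORIES,
                                    B=int(cfg["sign_test_B"]), rng=rng)
                tab.to_csv(out / f"habitat_{grp}_{season}.csv")
    if not rows:
        raise DependencyError(
            "stage 'niche' requires occurrence sets for two groups "
            "(>= 5 records each) in at least one season")
    pd.DataFrame(rows).to_csv(out / "niche_overlap.csv", index=False)


def _stage_offset(ctx, cfg, out, rng):
    table = _require(ctx, "candidates", "offset", "the gea stage (candidates)")
    freq = _require(ctx, "freq", "offset", "the gea stage (frequencies)")
    grid = _require(ctx, "grid", "offset", "a climate grid stack")
    future = _require(ctx, "future_grid", "offset", "a future climate grid")
    loc = _require(ctx, "gea_localities", "offset", "the gea stage")
    final_ids = table.index[table["final_candidate"]].tolist()
    if len(final_ids) < 2:
        raise DependencyError("stage 'offset' requires >= 2 final candidates")
    clim = loc.set_index("deme")[list(BIOCLIM_VARS)]
    clim.index = freq.index
    imp = predictor_importance(freq[final_ids], clim)
    preds = rank_offset_predictors(imp, clim,
                                   float(cfg["offset_corr_threshold"]),
                                   int(cfg["n_offset_predictors"]))
    model = enriched_rda(freq, final_ids, clim, preds)
    cur_idx = adaptive_index(model, grid, axes=1)
    fut_idx = adaptive_index(model, future, axes=1)
    masks = {}
    for name in grid.layers:
        if name.startswith("suitability_") and name.endswith("_breeding"):
            grp = name.split("_")[1]
            masks[grp] = binary_range(grid, name,
                                      float(cfg["range_threshold"])).presence
    off = genetic_offset(cur_idx, fut_idx, masks or None)
    og = grid.copy()
    og.add_layer("adaptive_index_current", cur_idx.index[..., 0])
    og.add_layer("adaptive_index_future", fut_idx.index[..., 0])
    og.add_layer("genetic_offset", off.offset)
    for layer in ("adaptive_index_current", "adaptive_index_future",
                  "genetic_offset"):
        write_ascii_grid(og, layer, out / f"{layer}.asc")
    if not off.group_summaries.empty:
        off.group_summaries.to_csv(out / "offset_summaries.csv")
    pd.Series(preds, name="predictor").to_csv(out / "offset_predictors.csv",
                                              index=False)
    ctx["offset_map"] = off


def _stage_range(ctx, cfg, out, rng):
    grid = _require(ctx, "grid", "range", "a climate grid stack")
    rows = []
    thr = float(cfg["range_threshold"])
    ranges = {}
    for name in sorted(grid.layers):
        if not name.startswith("suitability_"):
            continue
        _, grp, season = name.split("_", 2)
        rm = binary_range(grid, name, thr, season=season, group=grp)
        ranges[(grp, season)] = rm
        if rm.presence.any():
            lonc, latc = range_centroid(rm)
            rows.append({"group": grp, "season": season,
                         "extent_km2": range_extent(rm),
                         "centroid_lon": lonc, "centroid_lat": latc})
    for grp in sorted({g for g, _ in ranges}):
        b = ranges.get((grp, "breeding"))
        nb = ranges.get((grp, "nonbreeding"))
        if b is not None and nb is not None and b.presence.any() \
                and nb.presence.any():
            rows.append({"group": grp, "season": "migration",
                         "extent_km2": np.nan,
                         "centroid_lon": np.nan,
                         "centroid_lat": np.nan,
                         "migration_km": migration_distance(b, nb)})
    if not rows:
        raise DependencyError("stage 'range' requires suitability layers")
    pd.DataFrame(rows).to_csv(out / "range_metrics.csv", index=False)


_STAGE_FUNCS = {
    "structure": _stage_structure,
    "ibd_ibc": _stage_ibd_ibc,
    "gea": _stage_gea,
    "niche": _stage_niche,
    "offset": _stage_offset,
    "range": _stage_range,
}
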