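"""RDA genotype-environment association and the candidate cascade."""

import numpy as np
import pandas as pd
import pytest

from lineagescape import (GenotypeMatrix, SyntheticConfig, allele_frequencies,
                          combine_and_annotate, filter_confounded,
                          outlier_scan, rda_fit, rda_significance,
                          select_rda_candidates, snp_climate_correlations)
from lineagescape.gea import RdaModel, adaptive_units, climate_pca
from lineagescape.io import BIOCLIM_VARS, annotate_snps, GeneIntervalTable


def _freq_frame(y, demes=None):
    demes = demes or [f"d{i}" for i in range(y.shape[0])]
    return pd.DataFrame(y, index=demes,
                        columns=[f"snp{j}" for j in range(y.shape[1])])


def _pred_frame(x, demes=None):
    demes = demes or [f"d{i}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=demes,
                        columns=[f"p{j}" for j in range(x.shape[1])])


class TestClimatePca:
    def _localities(self, x):
        df = pd.DataFrame(x, columns=list(BIOCLIM_VARS))
        df.insert(0, "deme", [f"d{i}" for i in range(len(df))])
        return df

    def test_dominant_gradient_captured(self, rng):
        grad = np.linspace(-2, 2, 15)
        x = np.outer(grad, rng.normal(size=19)) + 0.05 * rng.normal(
            size=(15, 19))
        scores, evr = climate_pca(self._localities(x))
        assert evr[0] > 0.9

    def test_full_rank_preserves_distances(self, rng):
        x = rng.normal(size=(12, 19))
        loc = self._localities(x)
        scores, _ = climate_pca(loc, k=12)
        sd = x.std(axis=0, ddof=1)
        z = (x - x.mean(axis=0)) / sd
        direct = np.sqrt(((z[:, None] - z[None, :]) ** 2).sum(-1))
        s = scores.to_numpy()
        via = np.sqrt(((s[:, None] - s[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(direct, via, atol=1e-8)

    def test_too_few_demes_rejected(self, rng):
        with pytest.raises(ValueError):
            climate_pca(self._localities(rng.normal(size=(3, 19))))


class TestRdaFit:
    def test_noiseless_linear_response_fully_constrained(self, rng):
        x = rng.normal(size=(10, 2))
        b = rng.normal(size=(2, 30))
        model = rda_fit(_freq_frame(x @ b), _pred_frame(x))
        assert model.constrained_fraction == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_response_unconstrained(self, rng):
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=(12, 20))
        xc = x - x.mean(axis=0)
        y = y - xc @ np.linalg.pinv(xc) @ y  # residualize: zero covariance
        model = rda_fit(_freq_frame(y), _pred_frame(x))
        assert model.constrained_fraction < 1e-10

    def test_single_predictor_loadings_match_ols_slopes(self, rng):
        x = rng.normal(size=(15, 1))
        y = rng.normal(size=(15, 40)) + x @ rng.normal(size=(1, 40))
        model = rda_fit(_freq_frame(y), _pred_frame(x))
        # per-locus OLS oracle
        xc = (x[:, 0] - x[:, 0].mean())
        yc = y - y.mean(axis=0)
        slopes = xc @ yc / (xc @ xc)
        load = model.snp_loadings["RDA1"].to_numpy()
        ratio = load / slopes
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=(10, 1))
        x2 = np.hstack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear|rank"):
            rda_fit(_freq_frame(rng.normal(size=(10, 5))), _pred_frame(x2))


class TestRdaSignificance:
    def test_strong_signal_minimal_p(self, rng):
        x = rng.normal(size=(12, 2))
        y = x @ rng.normal(size=(2, 30))
        res = rda_significance(_freq_frame(y), _pred_frame(x), n_perm=199,
                               rng=rng)
        assert res.loc["global", "p"] == pytest.approx(1 / 200)

    def test_second_axis_not_significant_for_rank_one_truth(self):
        rng = np.random.default_rng(21)
        n_reject = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(size=(12, 2))
            y = (np.outer(x[:, 0], rng.normal(size=25))
                 + 0.3 * rng.normal(size=(12, 25)))
            res = rda_significance(_freq_frame(y), _pred_frame(x),
                                   n_perm=99, rng=rng)
            n_reject += res.loc["RDA2", "p"] <= 0.05
        assert n_reject / reps <= 0.10


class TestSelectCandidates:
    @staticmethod
    def _model_with_loadings(lo):
        lo = np.asarray(lo, float)[:, None]
        idx = [f"snp{i}" for i in range(len(lo))]
        return RdaModel(
            predictor_names=["p0"], eigenvalues=np.array([1.0]),
            snp_loadings=pd.DataFrame(lo, index=idx, columns=["RDA1"]),
            site_scores=pd.DataFrame(np.zeros((4, 1)), columns=["RDA1"]),
            coefficients=pd.DataFrame(np.zeros((1, len(lo))),
                                      columns=idx, index=["p0"]),
            axis_weights=np.ones((1, 1)), constrained_fraction=1.0,
            predictor_means=np.zeros(1), predictor_sds=np.ones(1), n_sites=4)

    def test_normal_tail_rate(self):
        rng = np.random.default_rng(3)
        model = self._model_with_loadings(rng.normal(size=100_000))
        flags = select_rda_candidates(model, ["RDA1"], sd_mult=3.0)
        assert flags.mean() == pytest.approx(0.0027, abs=0.0006)

    def test_infinite_cutoff_empty(self):
        rng = np.random.default_rng(3)
        model = self._model_with_loadings(rng.normal(size=1000))
        assert select_rda_candidates(model, ["RDA1"], np.inf).sum() == 0

    def test_recall_on_default_scenario(self, default_dataset,
                                        deme_frequencies):
        ds = default_dataset
        clim, _ = climate_pca(ds.localities)
        model = rda_fit(deme_frequencies, clim)
        flags = select_rda_candidates(model, ["RDA1"])
        truth = pd.Index(ds.truth.adaptive_snp_ids)
        recall = flags.loc[truth].mean()
        assert recall >= 0.8


class TestConfoundFilter:
    def test_clinal_snp_retained_structure_snp_filtered(self):
        demes = [f"d{i}" for i in range(10)]
        climate = pd.Series(np.linspace(-1, 1, 10), index=demes)
        structure = pd.Series([0.0] * 5 + [1.0] * 5, index=demes)
        lon = pd.Series(np.r_[np.linspace(0, 1, 5), np.linspace(0, 1, 5)],
                        index=demes)
        freq = pd.DataFrame({
            "clinal": 0.5 + 0.4 * climate.to_numpy(),
            "structural": 0.2 + 0.6 * structure.to_numpy(),
            "flat": np.full(10, 0.5),
        }, index=demes)
        cand = pd.Series(True, index=freq.columns)
        out = filter_confounded(cand, freq, climate, structure, lon)
        assert not out.loc["clinal", "confound_filtered"]
        assert out.loc["structural", "confound_filtered"]
        assert out.loc["flat", "confound_filtered"]  # degenerate tie


class TestOutlierScans:
    def _neutral(self, seed, n_extra_fixed=0):
        cfg = SyntheticConfig(seed=seed, n_demes=4, n_ind_per_deme=25,
                              n_neutral=1000, n_adaptive=0, f_lineage=0.02,
                              f_deme=0.02, lineage_split="none")
        from lineagescape import (sample_genotypes, simulate_climate_grid,
                                  simulate_deme_frequencies)
        truth = simulate_deme_frequencies(cfg, simulate_climate_grid(cfg))
        if n_extra_fixed:
            # plant fixed differences between deme halves
            truth.deme_freq[:, :n_extra_fixed] = 0.0
            truth.deme_freq[:2, :n_extra_fixed] = 1.0
        g, table = sample_genotypes(truth, cfg)
        return g, table.set_index("sample")["deme"], truth

    def test_neutral_intersection_false_positive_rate(self):
        g, demes, _ = self._neutral(2)
        fst = outlier_scan(g, demes, "fst", fdr=0.05)
        pca = outlier_scan(g, demes, "pca", fdr=0.05)
        both = (fst["outlier"] & pca["outlier"]).mean()
        assert both <= 0.05 + 0.03

    def test_planted_outliers_recovered(self):
        g, demes, truth = self._neutral(3, n_extra_fixed=20)
        fst = outlier_scan(g, demes, "fst", fdr=0.05)
        pca = outlier_scan(g, demes, "pca", fdr=0.05)
        planted = truth.snp_ids[:20]
        both = fst.loc[planted, "outlier"] & pca.loc[planted, "outlier"]
        assert both.mean() >= 0.9

    def test_single_deme_rejected(self, rng):
        calls = rng.binomial(2, 0.5, size=(10, 50))
        samples = [f"s{i}" for i in range(10)]
        g = GenotypeMatrix(samples,
                           [("1", 10 * (j + 1), f"m{j}") for j in range(50)],
                           calls)
        with pytest.raises(ValueError, match="single deme"):
            outlier_scan(g, {s: "only" for s in samples}, "fst")


class TestCombine:
    def _flags(self, idx, rda, conf, fst, pca):
        rda_flags = pd.DataFrame({"rda_candidate": rda,
                                  "confound_filtered": conf}, index=idx)
        fst_scan = pd.DataFrame({"outlier": fst}, index=idx)
        pca_scan = pd.DataFrame({"outlier": pca}, index=idx)
        return rda_flags, fst_scan, pca_scan

    def test_no_gene_overlap_empty_final(self):
        idx = ["a", "b"]
        hits = pd.DataFrame({"snp_id": idx, "chrom": "1", "pos": [1, 2],
                             "gene_id": [None, None], "ambiguous": False})
        table, counts = combine_and_annotate(
            *self._flags(idx, [True, True], [False, False],
                         [True, False], [True, False]), hits)
        assert counts["final_candidates"] == 0
        assert counts["merged_before_gene_filter"] == 2

    def test_disjoint_sets_union(self):
        idx = list("abcd")
        hits = pd.DataFrame({"snp_id": idx, "chrom": "1",
                             "pos": range(1, 5),
                             "gene_id": ["g1", "g2", "g3", None],
                             "ambiguous": False})
        table, counts = combine_and_annotate(
            *self._flags(idx, [True, False, False, False],
                         [False] * 4,
                         [False, True, True, False],
                         [False, True, True, False]), hits)
        assert counts["merged_before_gene_filter"] == 3  # {a} U {b, c}
        assert counts["final_candidates"] == 3

    def test_cascade_counts_monotone(self, default_dataset):
        # full-cascade monotonicity is asserted on the pipeline outputs
        from lineagescape import run_pipeline
        import tempfile
        with tempfile.TemporaryDirectory() as td:
            run_pipeline({"input": "synthetic", "seed": 11,
                          "stages": "structure,gea", "n_perm": 199}, td)
            import json
            counts = json.load(open(f"{td}/gea_counts.json"))
        assert (counts["rda_candidates"]
                >= counts["rda_after_confound_filter"])
        assert (counts["merged_before_gene_filter"]
                >= counts["final_candidates"])


class TestCorrelationsAndUnits:
    def test_perfect_rank_correlation(self, rng):
        demes = [f"d{i}" for i in range(12)]
        loc = pd.DataFrame(rng.normal(size=(12, 19)),
                           columns=list(BIOCLIM_VARS))
        loc.insert(0, "deme", demes)
        freq = pd.DataFrame({"s1": loc["BIO1"].rank().to_numpy() / 13.0},
                            index=demes)
        mat, _, _ = snp_climate_correlations(freq, loc, ["s1"])
        assert mat.loc["s1", "BIO1"] == pytest.approx(1.0)

    def test_constant_frequency_reported_zero(self, rng):
        demes = [f"d{i}" for i in range(8)]
        loc = pd.DataFrame(rng.normal(size=(8, 19)), columns=list(BIOCLIM_VARS))
        loc.insert(0, "deme", demes)
        freq = pd.DataFrame({"s1": np.full(8, 0.5)}, index=demes)
        mat, _, _ = snp_climate_correlations(freq, loc, ["s1"])
        assert (mat.loc["s1"] == 0).all()

    def test_rank_invariance_under_monotone_transform(self, rng):
        demes = [f"d{i}" for i in range(12)]
        loc = pd.DataFrame(rng.normal(size=(12, 19)), columns=list(BIOCLIM_VARS))
        loc.insert(0, "deme", demes)
        freq = pd.DataFrame({"s1": rng.uniform(size=12)}, index=demes)
        m1, _, _ = snp_climate_correlations(freq, loc, ["s1"])
        loc2 = loc.copy()
        loc2["BIO1"] = np.exp(loc2["BIO1"])  # monotone transform
        m2, _, _ = snp_climate_correlations(freq, loc2, ["s1"])
        assert m1.loc["s1", "BIO1"] == pytest.approx(m2.loc["s1", "BIO1"])

    def test_adaptive_units_split_along_climate_cline(self, default_dataset,
                                                      deme_of_sample):
        """AUs from climate-associated SNPs partition the demes along the
        climate gradient that drives the adaptive clines: ordered by the
        cline variable, the AU labels form two contiguous blocks."""
        ds = default_dataset
        labels, gap = adaptive_units(ds.genotypes, deme_of_sample,
                                     ds.truth.adaptive_snp_ids)
        z = ds.localities.set_index("deme")["BIO1"]
        ordered = labels.reindex(z.sort_values().index)
        n_switches = (ordered.to_numpy()[1:] != ordered.to_numpy()[:-1]).sum()
        assert labels.nunique() == 2
        assert n_switches == 1

    def test_panmictic_single_unit(self, rng):
        calls = rng.binomial(2, 0.5, size=(40, 60))
        samples = [f"s{i}" for i in range(40)]
        g = GenotypeMatrix(samples,
                           [("1", 10 * (j + 1), f"m{j}") for j in range(60)],
                           calls)
        demes = {s: f"d{i % 4}" for i, s in enumerate(samples)}
        labels, gap = adaptive_units(g, demes, [f"m{j}" for j in range(60)])
        assert labels.nunique() == 1

    def test_too_few_candidates_rejected(self, default_dataset,
                                         deme_of_sample):
        with pytest.raises(ValueError):
            adaptive_units(default_dataset.genotypes, deme_of_sample,
                           ["snp000001"])
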