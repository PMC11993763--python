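"""Adaptive index and genetic offset under future climates."""

import numpy as np
import pandas as pd
import pytest

from lineagescape import (SyntheticConfig, adaptive_index, enriched_rda,
                          generate_dataset, genetic_offset,
                          predictor_importance, project_future_climate,
                          rank_offset_predictors, rda_fit)
from lineagescape.io import BIOCLIM_VARS
from lineagescape.ranges import binary_range


def _clim_frame(x, demes=None):
    demes = demes or [f"d{i}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=demes,
                        columns=[f"v{j}" for j in range(x.shape[1])])


class TestPredictorRanking:
    def test_all_collinear_selects_one(self, rng):
        base = rng.normal(size=10)
        clim = _clim_frame(np.column_stack(
            [base * (i + 1) + 1e-6 * rng.normal(size=10) for i in range(6)]))
        imp = pd.Series(np.linspace(1, 0.5, 6), index=clim.columns)
        assert len(rank_offset_predictors(imp, clim, 0.7, 5)) == 1

    def test_orthogonal_selects_top_five_in_order(self, rng):
        clim = _clim_frame(np.linalg.qr(rng.normal(size=(10, 8)))[0])
        imp = pd.Series(np.arange(8, 0, -1, dtype=float), index=clim.columns)
        sel = rank_offset_predictors(imp, clim, 0.7, 5)
        assert sel == list(clim.columns[:5])

    def test_duplicated_variable_skipped(self, rng):
        x = rng.normal(size=(10, 3))
        clim = _clim_frame(np.column_stack([x[:, 0], x[:, 0], x[:, 1]]))
        imp = pd.Series([3.0, 2.0, 1.0], index=clim.columns)
        sel = rank_offset_predictors(imp, clim, 0.7, 3)
        assert sel == ["v0", "v2"]

    def test_importance_ranks_true_driver_first(self, default_dataset,
                                                deme_frequencies):
        ds = default_dataset
        clim = ds.localities.set_index("deme")[list(BIOCLIM_VARS)]
        clim.index = deme_frequencies.index
        imp = predictor_importance(
            deme_frequencies[ds.truth.adaptive_snp_ids], clim)
        # the cline variable is in the temperature block driving the cline
        assert imp.index[0] in [f"BIO{i}" for i in range(1, 12)]


class TestEnrichedRda:
    def test_all_snps_equals_global_fit(self, rng):
        y = rng.normal(size=(10, 12))
        x = rng.normal(size=(10, 2))
        clim = _clim_frame(x)
        freq = pd.DataFrame(y, columns=[f"s{j}" for j in range(12)],
                            index=clim.index)
        full = rda_fit(freq, clim)
        sub = enriched_rda(freq, list(freq.columns), clim, list(clim.columns))
        np.testing.assert_allclose(full.eigenvalues, sub.eigenvalues)

    def test_two_demes_rejected(self, rng):
        freq = pd.DataFrame(rng.normal(size=(2, 5)))
        clim = _clim_frame(rng.normal(size=(2, 1)))
        with pytest.raises(ValueError):
            enriched_rda(freq, list(freq.columns), clim, list(clim.columns))

    def test_clinal_candidates_dominated_by_first_axis(self, default_dataset,
                                                       deme_frequencies):
        ds = default_dataset
        clim = ds.localities.set_index("deme")[list(BIOCLIM_VARS)]
        clim.index = deme_frequencies.index
        imp = predictor_importance(
            deme_frequencies[ds.truth.adaptive_snp_ids], clim)
        preds = rank_offset_predictors(imp, clim)
        model = enriched_rda(deme_frequencies, ds.truth.adaptive_snp_ids,
                             clim, preds)
        assert model.eigenvalues[0] / model.eigenvalues.sum() >= 0.8


def _fit_on_seed17(predictors):
    ds = generate_dataset(SyntheticConfig(seed=17), n_occ_per_group=50)
    from lineagescape import allele_frequencies
    freq = allele_frequencies(
        ds.genotypes, ds.sample_table.set_index("sample")["deme"])
    freq = freq.reindex(ds.localities["deme"])
    clim = ds.localities.set_index("deme")[list(BIOCLIM_VARS)]
    clim.index = freq.index
    model = enriched_rda(freq, ds.truth.adaptive_snp_ids, clim, predictors)
    return ds, model


@pytest.fixture(scope="module")
def fitted():
    return _fit_on_seed17(["BIO1", "BIO12", "BIO15"])


@pytest.fixture(scope="module")
def setup():
    return _fit_on_seed17(["BIO1"])


class TestAdaptiveIndex:
    def test_mean_climate_maps_to_zero(self, fitted):
        ds, model = fitted
        z = model.project(model.predictor_means[None, :])
        np.testing.assert_allclose(z, 0.0, atol=1e-10)

    def test_deme_climate_maps_to_site_score(self, fitted):
        ds, model = fitted
        clim = ds.localities.set_index("deme")[model.predictor_names]
        proj = model.project(clim.to_numpy())
        np.testing.assert_allclose(proj, model.site_scores.to_numpy(),
                                   atol=1e-8)

    def test_linear_ramp_gives_linear_index(self, fitted):
        ds, model = fitted
        idx = adaptive_index(model, ds.grid, axes=1)
        cfg2 = SyntheticConfig(seed=17, noise_amp=0.0)
        grid2 = __import__("lineagescape").simulate_climate_grid(cfg2)
        idx2 = adaptive_index(model, grid2, axes=1)
        col = idx2.index[:, 0, 0]
        steps = np.diff(col)
        np.testing.assert_allclose(steps, steps[0], atol=1e-8)


class TestGeneticOffset:
    def test_unchanged_climate_zero_offset(self, setup):
        ds, model = setup
        cur = adaptive_index(model, ds.grid, axes=1)
        off = genetic_offset(cur, cur)
        finite = np.isfinite(off.offset)
        assert (off.offset[finite] == 0).all()

    def test_uniform_shift_closed_form(self, setup):
        """A uniform +delta shift in the single predictor moves the index by
        exactly c * delta / s.d. everywhere."""
        ds, model = setup
        delta = 2.5
        cfg = SyntheticConfig(seed=17, future_shift={"BIO1": delta},
                              future_lat_factor=0.0)
        fut = project_future_climate(ds.grid, cfg)
        cur = adaptive_index(model, ds.grid, axes=1)
        fut_idx = adaptive_index(model, fut, axes=1)
        off = genetic_offset(cur, fut_idx)
        expected = abs(model.axis_weights[0, 0] * delta
                       / model.predictor_sds[0])
        finite = np.isfinite(off.offset)
        np.testing.assert_allclose(off.offset[finite], expected, rtol=1e-8)

    def test_monotone_in_shift_magnitude(self, setup):
        ds, model = setup
        cur = adaptive_index(model, ds.grid, axes=1)
        offs = []
        for delta in (1.0, 2.0, 4.0):
            cfg = SyntheticConfig(seed=17, future_shift={"BIO1": delta})
            fut = adaptive_index(model, project_future_climate(ds.grid, cfg),
                                 axes=1)
            offs.append(genetic_offset(cur, fut).offset)
        finite = np.isfinite(offs[0])
        assert (offs[0][finite] < offs[1][finite]).all()
        assert (offs[1][finite] < offs[2][finite]).all()

    def test_metric_properties_across_scenarios(self, setup):
        ds, model = setup
        cur = adaptive_index(model, ds.grid, axes=1)
        cfg_a = SyntheticConfig(seed=17, future_shift={"BIO1": 2.0})
        cfg_b = SyntheticConfig(seed=17, future_shift={"BIO1": -1.5})
        a = adaptive_index(model, project_future_climate(ds.grid, cfg_a),
                           axes=1)
        b = adaptive_index(model, project_future_climate(ds.grid, cfg_b),
                           axes=1)
        d_ca = genetic_offset(cur, a).offset
        d_cb = genetic_offset(cur, b).offset
        d_ab = genetic_offset(a, b).offset
        finite = np.isfinite(d_ca)
        assert (d_ca[finite] >= 0).all()
        np.testing.assert_allclose(d_ab[finite],
                                   genetic_offset(b, a).offset[finite])
        assert (d_ab[finite] <= d_ca[finite] + d_cb[finite] + 1e-9).all()

    def test_sign_convention_invariance(self, setup):
        ds, model = setup
        import copy
        flipped = copy.deepcopy(model)
        flipped.axis_weights = -flipped.axis_weights
        cfg = SyntheticConfig(seed=17, future_shift={"BIO1": 2.0})
        fut_grid = project_future_climate(ds.grid, cfg)
        o1 = genetic_offset(adaptive_index(model, ds.grid),
                            adaptive_index(model, fut_grid)).offset
        o2 = genetic_offset(adaptive_index(flipped, ds.grid),
                            adaptive_index(flipped, fut_grid)).offset
        finite = np.isfinite(o1)
        np.testing.assert_allclose(o1[finite], o2[finite])


def test_asymmetric_warming_hits_colder_lineage_harder():
    """With deltas growing northwards, the colder (northern) lineage's
    median offset exceeds the warmer lineage's."""
    cfg = SyntheticConfig(seed=19, future_lat_factor=0.8)
    ds = generate_dataset(cfg, n_occ_per_group=50)
    from lineagescape import allele_frequencies
    freq = allele_frequencies(ds.genotypes,
                              ds.sample_table.set_index("sample")["deme"])
    freq = freq.reindex(ds.localities["deme"])
    clim = ds.localities.set_index("deme")[list(BIOCLIM_VARS)]
    clim.index = freq.index
    model = enriched_rda(freq, ds.truth.adaptive_snp_ids, clim, ["BIO1"])
    cur = adaptive_index(model, ds.grid)
    fut = adaptive_index(model, ds.future_grid)
    masks = {g: binary_range(ds.grid, f"suitability_{g}_breeding", 0.5)
             .presence for g in ("W", "E")}
    off = genetic_offset(cur, fut, masks)
    # E's niche optimum (BIO1 = 10) is colder, so its range sits north
    assert (off.group_summaries.loc["E", "median"]
            > off.group_summaries.loc["W", "median"])
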