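"""Gene-species concordance, classification probabilities, grid, ensemble."""

import numpy as np
import pandas as pd
import pytest

from cladesparse import (
    GridConfig,
    build_report,
    ensemble_GSC,
    ensemble_SCP_CP,
    gsc_score,
    normalize_scp,
    run_grid,
    scp_raw,
)
from cladesparse.metrics import (
    DegenerateModelError,
    ModelEnsemble,
    gsc_table,
)
from cladesparse.solver import ESLModel, SparsityPair
from tests.oracles import random_tiny_dataset


def make_model(data, beta, beta0=0.0):
    meta = data.column_meta
    nz = np.flatnonzero(beta)
    return ESLModel(
        beta=np.asarray(beta, dtype=float),
        beta0=beta0,
        sparsity=SparsityPair(0.5, 0.5),
        selected_sites={(meta.iat[j, 0], int(meta.iat[j, 1])) for j in nz},
        selected_genes={meta.iat[j, 0] for j in nz},
        n_iter=1,
        objective=0.0,
    )


class TestGscScore:
    def test_zero_when_gene_unselected(self):
        data = random_tiny_dataset(np.random.default_rng(0))
        m = make_model(data, np.zeros(data.n_columns))
        member = data.member_taxa()[0]
        assert gsc_score(m, data, "g0", member) == 0.0

    def test_single_selected_column(self):
        data = random_tiny_dataset(np.random.default_rng(0))
        member = data.member_taxa()[0]
        s = data.taxon_index(member)
        beta = np.zeros(data.n_columns)
        beta[0] = 0.5
        data.X[s, 0] = 1.0
        m = make_model(data, beta)
        assert gsc_score(m, data, "g0", member) == pytest.approx(0.5)

    def test_matches_brute_force_loop(self, rng):
        data = random_tiny_dataset(rng, n=12, n_groups=3, cols_per_group=4)
        beta = rng.standard_normal(data.n_columns) * (rng.random(data.n_columns) < 0.6)
        m = make_model(data, beta)
        for member in data.member_taxa():
            s = data.taxon_index(member)
            for gene, (a, b) in data.group_map.items():
                expected = sum(
                    data.y[s] * beta[k] * data.X[s, k] for k in range(a, b)
                )
                assert gsc_score(m, data, gene, member) == pytest.approx(expected)

    def test_table_matches_scalar_scores(self, rng):
        data = random_tiny_dataset(rng, n=10, n_groups=3, cols_per_group=3)
        beta = rng.standard_normal(data.n_columns)
        m = make_model(data, beta)
        table = gsc_table(m, data)
        for member in data.member_taxa():
            for gene in data.gene_ids:
                assert table.loc[gene, member] == pytest.approx(
                    gsc_score(m, data, gene, member)
                )

    def test_non_member_rejected(self):
        data = random_tiny_dataset(np.random.default_rng(0))
        m = make_model(data, np.zeros(data.n_columns))
        non_member = [t for t, yv in zip(data.taxon_order, data.y) if yv < 0][0]
        with pytest.raises(ValueError, match="member"):
            gsc_score(m, data, "g0", non_member)


class TestScp:
    def test_logistic_of_zero_is_half(self):
        data = random_tiny_dataset(np.random.default_rng(0))
        data.X[:] = 0.0
        m = make_model(data, np.zeros(data.n_columns), beta0=0.0)
        assert scp_raw(m, data, data.member_taxa()[0]) == pytest.approx(0.5)

    def test_closed_form_log3(self):
        # beta0 = 0 and sum of gsc = ln 3 -> probability 0.75
        data = random_tiny_dataset(np.random.default_rng(0))
        member = data.member_taxa()[0]
        s = data.taxon_index(member)
        data.X[s] = 0.0
        data.X[s, 0] = 1.0
        beta = np.zeros(data.n_columns)
        beta[0] = np.log(3.0)
        m = make_model(data, beta)
        assert scp_raw(m, data, member) == pytest.approx(0.75)

    def test_equals_model_linear_predictor(self, rng):
        """The gsc decomposition must reproduce the model's own
        classification probability exactly."""
        data = random_tiny_dataset(rng, n=12, n_groups=3, cols_per_group=4)
        beta = rng.standard_normal(data.n_columns)
        m = make_model(data, beta, beta0=0.3)
        for member in data.member_taxa():
            s = data.taxon_index(member)
            direct = 1.0 / (1.0 + np.exp(-(m.beta0 + data.X[s] @ beta * data.y[s])))
            assert scp_raw(m, data, member) == pytest.approx(direct, abs=1e-15)


class TestNormalizeScp:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((0.9, 0.9), (1.0, 1.0)),
            ((0.9, 0.4), (1.0, 0.0)),
            ((0.9, 0.7), (1.0, 0.5)),
        ],
    )
    def test_examples(self, raw, expected):
        out = normalize_scp(np.array(raw))
        np.testing.assert_allclose(out, expected)

    def test_degenerate_model_flagged(self):
        with pytest.raises(DegenerateModelError):
            normalize_scp(np.array([0.5, 0.4]))

    def test_output_in_unit_interval(self, rng):
        raw = rng.uniform(0.01, 0.99, 30)
        raw[0] = 0.95
        out = normalize_scp(raw)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


def random_ensemble(rng, n_models=5, n_genes=4, n_species=3):
    genes = [f"g{i}" for i in range(n_genes)]
    species = [f"s{i}" for i in range(n_species)]
    gsc_tabs = [
        pd.DataFrame(rng.standard_normal((n_genes, n_species)),
                     index=genes, columns=species)
        for _ in range(n_models)
    ]
    scp_tabs = [
        pd.Series(rng.uniform(0, 1, n_species), index=species)
        for _ in range(n_models)
    ]
    return ModelEnsemble(
        models=[None] * n_models,
        grid_config=GridConfig(),
        gsc_tables=gsc_tabs,
        scp_tables=scp_tabs,
        raw_scp_tables=scp_tabs,
    )


class TestEnsemble:
    def test_median_of_singleton_is_identity(self, rng):
        e = random_ensemble(rng, n_models=1)
        pd.testing.assert_frame_equal(ensemble_GSC(e), e.gsc_tables[0])

    def test_odd_count_median(self, rng):
        e = random_ensemble(rng, n_models=3, n_genes=1, n_species=1)
        for t, v in zip(e.gsc_tables, [-0.1, 0.0, 0.3]):
            t.iloc[0, 0] = v
        assert ensemble_GSC(e).iloc[0, 0] == pytest.approx(0.0)

    def test_matches_brute_force_sort_and_mean(self, rng):
        """GSC median / SCP mean / CP min recomputed cell by cell."""
        for _ in range(30):
            e = random_ensemble(
                rng,
                n_models=int(rng.integers(1, 7)),
                n_genes=int(rng.integers(1, 5)),
                n_species=int(rng.integers(1, 5)),
            )
            gsc = ensemble_GSC(e)
            scp, cp = ensemble_SCP_CP(e)
            for g in gsc.index:
                for s in gsc.columns:
                    vals = sorted(t.loc[g, s] for t in e.gsc_tables)
                    k = len(vals)
                    med = vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
                    assert gsc.loc[g, s] == pytest.approx(med)
            for s in scp.index:
                assert scp[s] == pytest.approx(
                    sum(t[s] for t in e.scp_tables) / len(e.scp_tables)
                )
            assert cp == pytest.approx(min(scp))
            assert all(cp <= scp[s] + 1e-15 for s in scp.index)


class TestRunGrid:
    def test_full_grid_fits_81_models(self, small_dataset, small_ensemble):
        assert small_ensemble.n_fitted == 81

    def test_retained_models_are_multigene(self, small_ensemble):
        assert all(len(m.selected_genes) >= 2 for m in small_ensemble.models)

    def test_quick_is_full_restricted_to_visited_subgrid(self, small_dataset):
        _, _, data = small_dataset
        full = run_grid(data, GridConfig())
        quick = run_grid(data, GridConfig(quick=True))
        assert quick.n_fitted <= full.n_fitted
        full_by_pair = {
            (m.sparsity.lambda_site, m.sparsity.lambda_group): m
            for m in full.models
        }
        for m in quick.models:
            key = (m.sparsity.lambda_site, m.sparsity.lambda_group)
            assert key in full_by_pair
            assert m.selected_genes == full_by_pair[key].selected_genes

    def test_quick_records_lambda_group_cap(self, small_dataset):
        _, _, data = small_dataset
        quick = run_grid(data, GridConfig(quick=True))
        assert quick.lambda_group_max is not None
        assert all(
            m.sparsity.lambda_group <= quick.lambda_group_max + 1e-12
            for m in quick.models
        )

    def test_report_masks_missing_pairs(self, small_dataset, small_ensemble):
        _, _, data = small_dataset
        report = build_report(small_ensemble, data)
        members = data.member_taxa()
        for gi, gene in enumerate(data.gene_ids):
            for s in members:
                if data.missing_mask[data.taxon_index(s), gi]:
                    assert np.isnan(report.GSC.loc[gene, s])
        assert 0.0 <= report.CP <= 1.0
        assert report.CP == pytest.approx(report.SCP.min())

    def test_empty_grid_point_not_retained(self, small_dataset):
        _, _, data = small_dataset
        with pytest.raises(ValueError, match="no multigene model"):
            run_grid(
                data,
                GridConfig(lambda_site_range=(1.0, 1.0),
                           lambda_group_range=(1.0, 1.0)),
            )
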