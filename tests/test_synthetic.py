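import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmaster.de import nb_differential_expression
from mirmaster.synthetic import (CohortConfig, GroundTruth, generate_cohort,
                                 generate_driver_annotation,
                                 generate_target_databases)


def small_config(**kw):
    base = dict(n_tumor=20, n_normal=10, n_mirna=5, n_mrna=10, seed=3)
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("field", ["n_tumor", "n_normal", "n_mirna", "n_mrna"])
    def test_nonpositive_dimensions(self, field):
        with pytest.raises(ValueError):
            generate_cohort(small_config(**{field: 0}))

    def test_bad_stage_probs(self):
        with pytest.raises(ValueError):
            generate_cohort(small_config(stage_probs=(0.5, 0.5, 0.5, 0.5)))

    def test_unknown_edge_feature(self):
        with pytest.raises(ValueError, match="undeclared"):
            generate_cohort(
                small_config(planted_edges=((("mir-001"), "gene-9999", -1, 1.0),))
            )

    def test_bad_edge_sign(self):
        with pytest.raises(ValueError, match="sign"):
            generate_cohort(
                small_config(planted_edges=(("mir-001", "gene-0001", 2, 1.0),))
            )


class TestGenerateCohort:
    def test_seed_reproducibility(self):
        cfg = small_config()
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])
        assert a[3].true_log2fc == b[3].true_log2fc

    def test_different_seeds_differ(self):
        a = generate_cohort(small_config(seed=1))
        b = generate_cohort(small_config(seed=2))
        assert not a[0].equals(b[0])

    def test_shapes_and_metadata(self):
        mirna, mrna, meta, truth = generate_cohort(small_config())
        assert mirna.shape == (5, 30)
        assert mrna.shape == (10, 30)
        assert (meta["condition"] == "tumor").sum() == 20
        assert set(meta.loc[meta.condition == "tumor", "stage"]) <= {"I", "II", "III", "IV"}
        assert (meta.loc[meta.condition == "normal", "stage"] == "NA").all()
        assert truth.driver_roles == {g: "none" for g in truth.gene_ids}

    def test_null_cohort_type_one_error(self):
        # no planted signal: raw p < 0.05 should fire at ~5% of features
        cfg = CohortConfig(n_tumor=200, n_normal=200, n_mirna=5, n_mrna=1000, seed=11)
        _, mrna, meta, _ = generate_cohort(cfg)
        g = (meta.set_index("sample_id").loc[mrna.columns, "condition"] == "tumor")
        res = nb_differential_expression(mrna, g.to_numpy().astype(int))
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07
        # BH at 0.05 under the global null should call (almost) nothing
        assert (res["padj"] <= 0.05).sum() <= 5

    def test_planted_stage_trend_is_detectable(self):
        cfg = CohortConfig(n_tumor=400, n_normal=50, n_mirna=4, n_mrna=5,
                           planted_mmr_ids=("mir-001",), stage_trend=0.5, seed=5)
        mirna, _, meta, _ = generate_cohort(cfg)
        tum = meta[meta.condition == "tumor"]
        stages = tum["stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4})
        expr = np.log2(1 + mirna.loc["mir-001", tum.sample_id].to_numpy())
        rho, p = stats.spearmanr(expr, stages)
        assert rho > 0 and p <= 0.05

    def test_marginal_calibration(self):
        # unplanted features: sample mean within 3 MC standard errors of
        # base mean x mean library factor
        cfg = CohortConfig(n_tumor=150, n_normal=150, n_mirna=20, n_mrna=50,
                           libsize_lognormal_sd=0.0, seed=21)
        mirna, mrna, _, _ = generate_cohort(cfg)
        ok = 0
        for _, row in mrna.iterrows():
            x = row.to_numpy(float)
            se = x.std(ddof=1) / np.sqrt(x.size)
            ok += abs(x.mean() - cfg.mrna_base_mean) <= 3 * se
        assert ok >= 0.9 * mrna.shape[0]

    def test_planted_edge_shifts_target(self):
        cfg = CohortConfig(
            n_tumor=300, n_normal=100, n_mirna=3, n_mrna=20,
            planted_mmr_ids=("mir-001",),
            planted_edges=(("mir-001", "gene-0001", -1, 1.5),),
            stage_trend=0.25, tumor_lfc=2.0, seed=9,
        )
        _, mrna, meta, truth = generate_cohort(cfg)
        g = (meta.set_index("sample_id").loc[mrna.columns, "condition"] == "tumor")
        res = nb_differential_expression(mrna, g.to_numpy().astype(int))
        row = res.set_index("feature").loc["gene-0001"]
        assert row["log2FoldChange"] < 0 and row["padj"] <= 0.05
        assert truth.true_log2fc["gene-0001"] < 0

    def test_survival_columns(self):
        _, _, meta, _ = generate_cohort(small_config(survival_beta=0.5))
        tum = meta[meta.condition == "tumor"]
        assert (tum["time"] >= 0).all()
        assert set(tum["event"].astype(int)) <= {0, 1}
        assert meta.loc[meta.condition == "normal", "time"].isna().all()


def _toy_truth(n_mir=50, n_gene=40, edges_per_mir=20):
    mirnas = [f"mir-{i:03d}" for i in range(1, n_mir + 1)]
    genes = [f"gene-{j:04d}" for j in range(1, n_gene + 1)]
    edges = [(m, genes[j % n_gene], -1, 1.0)
             for i, m in enumerate(mirnas)
             for j in range(i * edges_per_mir, (i + 1) * edges_per_mir)]
    return GroundTruth(
        planted_mmr_ids=mirnas, planted_edges=edges,
        driver_roles={g: "none" for g in genes},
        true_log2fc={}, mirna_ids=mirnas, gene_ids=genes,
    )


class TestTargetDatabases:
    def test_identity_case(self):
        truth = _toy_truth(n_mir=5, n_gene=40, edges_per_mir=8)
        (db,) = generate_target_databases(truth, n_dbs=1, recall=1.0,
                                          precision=1.0, seed=0)
        assert db.pairs == frozenset((m, g) for m, g, _, _ in truth.planted_edges)

    def test_recall_binomial(self):
        truth = _toy_truth(n_mir=50, n_gene=40, edges_per_mir=20)  # 1000 true edges
        assert len(truth.planted_edges) == 1000
        (db,) = generate_target_databases(truth, n_dbs=1, recall=0.5,
                                          precision=1.0, seed=7)
        n_true = len(db.pairs)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= n_true <= hi

    def test_precision_in_expectation(self):
        truth = _toy_truth(n_mir=10, n_gene=100, edges_per_mir=10)
        (db,) = generate_target_databases(truth, n_dbs=1, recall=1.0,
                                          precision=0.5, seed=3)
        true = frozenset((m, g) for m, g, _, _ in truth.planted_edges)
        n_true = len(db.pairs & true)
        n_decoy = len(db.pairs - true)
        assert n_decoy == n_true  # precision 0.5 -> equal decoys

    def test_union_recall_monotone(self):
        truth = _toy_truth(n_mir=10, n_gene=100, edges_per_mir=10)
        dbs = generate_target_databases(truth, n_dbs=3, recall=0.4,
                                        precision=0.8, seed=11)
        true = frozenset((m, g) for m, g, _, _ in truth.planted_edges)
        union = frozenset().union(*(d.pairs for d in dbs))
        assert len(union & true) >= max(len(d.pairs & true) for d in dbs)

    def test_empty_truth_with_decoys_errors(self):
        truth = _toy_truth(n_mir=2, n_gene=10, edges_per_mir=0)
        truth.planted_edges = []
        with pytest.raises(ValueError, match="no true edges"):
            generate_target_databases(truth, n_dbs=1, recall=1.0,
                                      precision=0.5, seed=0)


class TestDriverAnnotation:
    def test_all_oncogene(self):
        roles = generate_driver_annotation(["a", "b", "c"], 1.0, 0.0, 0.0, seed=0)
        assert set(roles.values()) == {"oncogene"}

    def test_deterministic_rounding(self):
        genes = [f"g{i}" for i in range(100)]
        roles = generate_driver_annotation(genes, 0.1, 0.1, 0.05, seed=1)
        counts = pd.Series(roles).value_counts()
        assert counts["oncogene"] == 10
        assert counts["tsg"] == 10
        assert counts["dual"] == 5
        assert counts["none"] == 75

    def test_all_none(self):
        roles = generate_driver_annotation(["a", "b"], 0.0, 0.0, 0.0, seed=0)
        assert set(roles.values()) == {"none"}

    def test_fraction_sum_error(self):
        with pytest.raises(ValueError):
            generate_driver_annotation(["a"], 0.6, 0.6, 0.0, seed=0)

    def test_seed_reproducibility(self):
        genes = [f"g{i}" for i in range(30)]
        assert (generate_driver_annotation(genes, 0.2, 0.2, 0.1, seed=5)
                == generate_driver_annotation(genes, 0.2, 0.2, 0.1, seed=5))
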