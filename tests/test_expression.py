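"""Gene panels, z-scoring, DN compositing, the variable-gene filter, PCA."""

import io

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from thymoflux import (
    ExpressionMatrix,
    GenePanel,
    MOUSE_THYMUS_SCHEME,
    PopulationScheme,
    composite_dn,
    filter_variable_genes,
    pathway_trajectory,
    pca_standardized,
    read_expression,
    write_expression,
    zscore_rows,
)

STAGES = MOUSE_THYMUS_SCHEME.stages


def matrix_from(values: dict[str, list[float]], scheme=MOUSE_THYMUS_SCHEME, columns=None) -> ExpressionMatrix:
    cols = columns or list(scheme.stages)
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(values, orient="index", columns=cols),
        scheme=scheme,
    )


class TestPopulationScheme:
    def test_duplicate_stage_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PopulationScheme(system="X", stages=("A", "A", "B"))

    def test_dn_members_must_be_prefix(self):
        with pytest.raises(ValueError, match="prefix"):
            PopulationScheme(system="X", stages=("A", "B", "C"), dn_members=("B",))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationScheme(
                system="X", stages=("A", "B", "C"), dn_members=("A", "B"),
                dn_weights={"A": 0.6, "B": 0.6},
            )


class TestReadExpression:
    def tsv(self, columns=STAGES, genes=10) -> str:
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.uniform(0, 12, (genes, len(columns))),
            index=[f"g{i}" for i in range(genes)],
            columns=list(columns),
        )
        df.index.name = "gene_id"
        return df.to_csv(sep="\t")

    def test_row_count(self):
        mat = read_expression(io.StringIO(self.tsv()), MOUSE_THYMUS_SCHEME)
        assert len(mat.genes) == 10 and mat.populations == list(STAGES)

    def test_unknown_column_named(self):
        with pytest.raises(ValueError, match="SP9"):
            read_expression(io.StringIO(self.tsv(columns=STAGES[:-1] + ("SP9",))), MOUSE_THYMUS_SCHEME)

    def test_duplicate_gene_rejected(self):
        text = self.tsv(genes=3)
        dup = text + text.splitlines()[1] + "\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_expression(io.StringIO(dup), MOUSE_THYMUS_SCHEME)

    def test_non_numeric_cell_located(self):
        lines = self.tsv(genes=2).splitlines()
        fields = lines[2].split("\t")
        fields[3] = "oops"
        lines[2] = "\t".join(fields)
        with pytest.raises(ValueError, match="oops.*g1.*DN3"):
            read_expression(io.StringIO("\n".join(lines)), MOUSE_THYMUS_SCHEME)

    def test_round_trip(self, tmp_path):
        mat = read_expression(io.StringIO(self.tsv()), MOUSE_THYMUS_SCHEME)
        path = tmp_path / "expr.tsv"
        write_expression(mat, path)
        back = read_expression(path, MOUSE_THYMUS_SCHEME)
        pd.testing.assert_frame_equal(mat.values, back.values)


class TestZScoreRows:
    def test_three_point_row(self):
        scheme = PopulationScheme(system="X", stages=("a", "b", "c"))
        z, constant = zscore_rows(matrix_from({"g": [1, 2, 3]}, scheme=scheme))
        np.testing.assert_allclose(z.values.loc["g"], [-1, 0, 1])
        assert constant == []

    def test_constant_row_flagged_and_zeroed(self):
        scheme = PopulationScheme(system="X", stages=("a", "b", "c"))
        z, constant = zscore_rows(matrix_from({"g": [5, 5, 5], "h": [1, 2, 3]}, scheme=scheme))
        assert constant == ["g"]
        assert (z.values.loc["g"] == 0).all()

    def test_rows_are_standardized(self):
        rng = np.random.default_rng(4)
        mat = matrix_from({f"g{i}": rng.uniform(0, 20, 8).tolist() for i in range(12)})
        z, _ = zscore_rows(mat)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotent_on_zscored_rows(self):
        rng = np.random.default_rng(5)
        mat = matrix_from({f"g{i}": rng.uniform(0, 20, 8).tolist() for i in range(5)})
        z1, _ = zscore_rows(mat)
        z2, _ = zscore_rows(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)


class TestCompositeDN:
    def test_degenerate_weights_reproduce_dn3(self):
        rng = np.random.default_rng(6)
        mat = matrix_from({f"g{i}": rng.uniform(0, 10, 8).tolist() for i in range(4)})
        out = composite_dn(mat, {"DN1": 0.0, "DN2": 0.0, "DN3": 1.0})
        np.testing.assert_allclose(out.values["DN"], mat.values["DN3"])

    def test_measured_mouse_weights(self):
        mat = matrix_from({"g1": [1, 2, 3, 0, 0, 0, 0, 0], "g2": [10, 20, 30, 0, 0, 0, 0, 0], "g3": [4, 4, 7, 0, 0, 0, 0, 0]})
        out = composite_dn(mat)  # scheme weights 0.04/0.03/0.93
        np.testing.assert_allclose(
            out.values["DN"],
            [0.04 * 1 + 0.03 * 2 + 0.93 * 3, 0.04 * 10 + 0.03 * 20 + 0.93 * 30, 0.04 * 4 + 0.03 * 4 + 0.93 * 7],
        )

    def test_forced_arithmetic(self):
        scheme = PopulationScheme(system="X", stages=("d1", "d2", "d3", "later"), dn_members=("d1", "d2", "d3"))
        mat = matrix_from({"g": [1, 2, 3, 9]}, scheme=scheme)
        out = composite_dn(mat, {"d1": 0.2, "d2": 0.3, "d3": 0.5})
        assert out.values.loc["g", "DN"] == pytest.approx(2.3)
        assert list(out.values.columns) == ["DN", "later"]

    def test_linearity(self):
        rng = np.random.default_rng(7)
        a = matrix_from({f"g{i}": rng.uniform(0, 10, 8).tolist() for i in range(5)})
        b = matrix_from({f"g{i}": rng.uniform(0, 10, 8).tolist() for i in range(5)})
        summed = matrix_from({g: (a.values.loc[g] + b.values.loc[g]).tolist() for g in a.values.index})
        left = composite_dn(summed).values
        right = composite_dn(a).values + composite_dn(b).values
        pd.testing.assert_frame_equal(left, right)

    @pytest.mark.parametrize(
        "weights, match",
        [
            ({"DN1": 0.5, "DN2": 0.5}, "missing"),
            ({"DN1": 0.5, "DN2": 0.3, "DN3": 0.3}, "sum to 1"),
        ],
    )
    def test_bad_weights(self, weights, match):
        mat = matrix_from({"g": [1] * 8})
        with pytest.raises(ValueError, match=match):
            composite_dn(mat, weights)


class TestPathwayTrajectory:
    def zmat(self, rows: dict[str, list[float]]):
        scheme = PopulationScheme(system="X", stages=("a", "b", "c", "d"))
        z, _ = zscore_rows(matrix_from(rows, scheme=scheme))
        return z

    def test_single_gene_pathway_is_that_row(self):
        z = self.zmat({"g1": [1, 2, 3, 4], "g2": [4, 1, 2, 2]})
        traj, matches = pathway_trajectory(z, GenePanel(pathways={"p": ("g1",)}))
        np.testing.assert_allclose(traj.loc["p"], z.values.loc["g1"])
        assert matches["p"].absent == ()

    def test_opposite_rows_cancel(self):
        z = self.zmat({"up": [1, 2, 3, 4], "down": [4, 3, 2, 1]})
        traj, _ = pathway_trajectory(z, GenePanel(pathways={"p": ("up", "down")}))
        np.testing.assert_allclose(traj.loc["p"], 0, atol=1e-12)

    def test_hand_column_means(self):
        rng = np.random.default_rng(9)
        rows = {f"g{i}": rng.uniform(0, 5, 4).tolist() for i in range(5)}
        z = self.zmat(rows)
        traj, _ = pathway_trajectory(z, GenePanel(pathways={"p": tuple(rows)}))
        np.testing.assert_allclose(traj.loc["p"], z.values.mean(axis=0))

    def test_unmatched_pathway_is_an_error(self):
        z = self.zmat({"g1": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="ghost"):
            pathway_trajectory(z, GenePanel(pathways={"ghost": ("nope",)}))

    def test_panel_order_irrelevant_and_case_insensitive(self):
        z = self.zmat({"Hk2": [1, 2, 3, 4], "Ldha": [2, 2, 3, 5], "Cs": [5, 1, 2, 2]})
        a, _ = pathway_trajectory(z, GenePanel(pathways={"p": ("HK2", "LDHA", "CS")}))
        b, _ = pathway_trajectory(z, GenePanel(pathways={"p": ("cs", "ldha", "hk2")}))
        np.testing.assert_allclose(a.loc["p"], b.loc["p"])


def de_row(gene, contrast="c1", fc=3.0, p=0.005, fpkm=10.0, cpm=2.0, mappable=100.0, outlier=False):
    return {
        "gene_id": gene, "contrast": contrast, "fold_change": fc, "adj_p": p,
        "max_fpkm": fpkm, "max_cpm": cpm, "mappable_bp": mappable, "outlier": outlier,
    }


class TestFilterVariableGenes:
    def test_empty_table(self):
        res = filter_variable_genes(pd.DataFrame(columns=list(pd.DataFrame([de_row("g")]).columns)))
        assert res.passed == frozenset()

    def test_fully_qualified_gene_passes(self):
        res = filter_variable_genes(pd.DataFrame([de_row("g1")]))
        assert res.passed == {"g1"}

    def test_six_gene_toy_table(self):
        rows = [
            de_row("pass_up", fc=3.0),
            de_row("pass_down", fc=0.25),              # 4-fold down
            de_row("weak_fc", fc=1.5),
            de_row("weak_p", p=0.2),
            de_row("low_fpkm", fpkm=2.0),
            de_row("is_outlier", outlier=True),
        ]
        res = filter_variable_genes(pd.DataFrame(rows))
        assert res.passed == {"pass_up", "pass_down"}
        assert not res.reasons.loc["weak_fc", "fc_and_p"]
        assert not res.reasons.loc["low_fpkm", "fpkm_ok"]
        assert not res.reasons.loc["is_outlier", "not_outlier"]

    def test_one_qualifying_contrast_suffices(self):
        rows = [de_row("g", "c1", fc=1.1, p=0.9), de_row("g", "c2", fc=4.0, p=0.001)]
        assert filter_variable_genes(pd.DataFrame(rows)).passed == {"g"}

    def test_monotone_under_threshold_relaxation(self):
        rng = np.random.default_rng(10)
        rows = [
            de_row(
                f"g{i}",
                fc=float(np.exp(rng.normal(0, 1.2))),
                p=float(rng.uniform(0, 0.3)),
                fpkm=float(rng.uniform(0, 30)),
                cpm=float(rng.uniform(0, 3)),
                mappable=float(rng.uniform(20, 200)),
                outlier=bool(rng.random() < 0.2),
            )
            for i in range(60)
        ]
        table = pd.DataFrame(rows)
        strict = filter_variable_genes(table).passed
        relaxed = filter_variable_genes(
            table, fc_min=1.5, adj_p_max=0.05, fpkm_min=1.0, cpm_floor=0.1, mappability_min_bp=20.0
        ).passed
        assert strict <= relaxed


class TestPCAStandardized:
    def test_collinear_samples_have_single_component(self):
        scheme = PopulationScheme(system="X", stages=("a", "b", "c", "d"))
        base = np.array([1.0, 2.0, 3.0, 4.0])
        mat = matrix_from({f"g{i}": ((i + 1) * base + i).tolist() for i in range(5)}, scheme=scheme)
        res = pca_standardized(mat)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_to_one_and_nonincreasing(self):
        rng = np.random.default_rng(12)
        mat = matrix_from({f"g{i}": rng.uniform(0, 10, 8).tolist() for i in range(20)})
        res = pca_standardized(mat)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_matches_sklearn_eigendecomposition(self):
        rng = np.random.default_rng(14)
        scheme = PopulationScheme(system="X", stages=("a", "b", "c"))
        mat = matrix_from({f"g{i}": rng.uniform(0, 10, 3).tolist() for i in range(4)}, scheme=scheme)
        res = pca_standardized(mat)
        X = mat.values.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = SkPCA(n_components=len(res.variance_fraction)).fit(Xs)
        np.testing.assert_allclose(res.variance_fraction, ref.explained_variance_ratio_, atol=1e-9)
        np.testing.assert_allclose(np.abs(res.scores.to_numpy()), np.abs(ref.transform(Xs)), atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(15)
        mat = matrix_from({f"g{i}": rng.uniform(0, 10, 8).tolist() for i in range(6)})
        res = pca_standardized(mat)
        for pc in res.loadings.columns:
            col = res.loadings[pc].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(16)
        rows = {f"g{i}": rng.uniform(0, 10, 8).tolist() for i in range(4)}
        rows["flat"] = [3.0] * 8
        with pytest.warns(UserWarning, match="flat"):
            res = pca_standardized(matrix_from(rows))
        assert res.dropped_features == ("flat",)
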