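import numpy as np
import pandas as pd
import pytest

from regmeth.aggregate import (
    call_dm_genes,
    call_dm_promoters,
    correlate_promoter_expression,
    dm_fraction_of_gene_set,
    fold_threshold_gene_set,
    overlap_promoter_sets,
    promoter_methylation_matrix,
    translate_gene_set,
)
from regmeth.containers import (
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    ValidationError,
)


def make_annotation(rows):
    """rows: list of (cpg_id, genes, feature_groups, cgi)."""
    frame = pd.DataFrame(
        {
            "chrom": ["chr1"] * len(rows),
            "pos": np.arange(1, len(rows) + 1) * 100,
            "genes": [tuple(r[1]) for r in rows],
            "feature_groups": [tuple(r[2]) for r in rows],
            "cgi_relation": [r[3] if len(r) > 3 else "OpenSea" for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="cpg_id"),
    )
    return CpGAnnotation(frame)


@pytest.fixture
def gene_rule_annotation():
    return make_annotation(
        [
            ("cg01", ["WNT5A"], ["TSS200"]),
            ("cg02", ["GATA4"], ["TSS200"]),
            ("cg03", ["GATA4"], ["Body"]),
            ("cg04", ["GATA4"], ["Body"]),
            ("cg05", ["PDX1"], ["Body"]),
            ("cg06", ["PDX1"], ["3'UTR"]),
            ("cg07", ["PDX1"], ["Body"]),
            ("cg08", [], []),
        ]
    )


class TestDmGeneRule:
    def test_two_cpg_rule(self, gene_rule_annotation):
        calls = pd.Series(
            ["ns", "hyper", "hyper", "ns", "hyper", "ns", "ns", "hyper"],
            index=[f"cg{i:02d}" for i in range(1, 9)],
        )
        table = call_dm_genes(calls, gene_rule_annotation)
        assert set(table["gene"]) == {"GATA4"}
        row = table.iloc[0]
        assert row["direction"] == "hyper"
        assert row["n_dm_cpgs"] == 2 and row["n_total_cpgs"] == 3
        assert row["pct_dm"] == pytest.approx(100 * 2 / 3)

    def test_exception_list_lowers_to_one_cpg(self, gene_rule_annotation):
        calls = pd.Series(
            ["hyper", "ns", "ns", "ns", "ns", "ns", "ns", "ns"],
            index=[f"cg{i:02d}" for i in range(1, 9)],
        )
        assert call_dm_genes(calls, gene_rule_annotation).empty
        table = call_dm_genes(
            calls, gene_rule_annotation, one_cpg_gene_list=["WNT5A"]
        )
        assert list(table["gene"]) == ["WNT5A"]

    def test_mixed_directions_reported_in_both_tables(self, gene_rule_annotation):
        calls = pd.Series(
            ["ns", "hyper", "hyper", "ns", "hypo", "hypo", "hyper", "ns"],
            index=[f"cg{i:02d}" for i in range(1, 9)],
        )
        table = call_dm_genes(calls, gene_rule_annotation)
        pdx = table[table["gene"] == "PDX1"]
        assert set(pdx["direction"]) == {"hypo"}  # one hyper CpG is not enough
        calls["cg07"] = "hypo"
        calls["cg05"] = "hyper"
        calls["cg06"] = "hyper"
        table = call_dm_genes(calls, gene_rule_annotation)
        assert (table["gene"] == "PDX1").sum() == 1

    def test_unknown_exception_gene_warns_not_errors(self, gene_rule_annotation, caplog):
        calls = pd.Series(["ns"] * 8, index=[f"cg{i:02d}" for i in range(1, 9)])
        with caplog.at_level("WARNING"):
            call_dm_genes(calls, gene_rule_annotation, one_cpg_gene_list=["NOSUCH"])
        assert "NOSUCH" in caplog.text

    def test_brute_force_recount_on_random_fixture(self):
        """Rule agrees with a naive recount on a 30-gene random fixture."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(300):
            gene = f"G{rng.integers(0, 30):02d}"
            feat = str(rng.choice(["TSS200", "TSS1500", "Body", "3'UTR"]))
            rows.append((f"cg{i:03d}", [gene], [feat]))
        annotation = make_annotation(rows)
        calls = pd.Series(
            rng.choice(["hyper", "hypo", "ns"], size=300, p=[0.15, 0.15, 0.7]),
            index=[r[0] for r in rows],
        )
        table = call_dm_genes(calls, annotation, min_cpgs=2)
        got = {(r["gene"], r["direction"]): r["n_dm_cpgs"] for _, r in table.iterrows()}

        expected = {}
        for direction in ("hyper", "hypo"):
            per_gene = {}
            for (cpg, genes, feats), call in zip(rows, calls):
                if call == direction:
                    per_gene[genes[0]] = per_gene.get(genes[0], 0) + 1
            for g, n in per_gene.items():
                if n >= 2:
                    expected[(g, direction)] = n
        assert got == expected


class TestDmPromoterRule:
    def test_single_promoter_cpg_calls_promoter(self, gene_rule_annotation):
        calls = pd.Series(
            ["ns", "hyper", "ns", "ns", "ns", "ns", "ns", "ns"],
            index=[f"cg{i:02d}" for i in range(1, 9)],
        )
        table = call_dm_promoters(calls, gene_rule_annotation)
        assert list(table["gene"]) == ["GATA4"]
        assert table.iloc[0]["n_total_promoter_cpgs"] == 1

    def test_body_only_dm_not_called(self, gene_rule_annotation):
        calls = pd.Series(
            ["ns", "ns", "hyper", "hyper", "ns", "ns", "ns", "ns"],
            index=[f"cg{i:02d}" for i in range(1, 9)],
        )
        assert call_dm_promoters(calls, gene_rule_annotation).empty

    def test_gene_without_promoter_cpgs_absent(self, gene_rule_annotation):
        calls = pd.Series(
            ["hyper"] * 8, index=[f"cg{i:02d}" for i in range(1, 9)]
        )
        table = call_dm_promoters(calls, gene_rule_annotation)
        assert "PDX1" not in set(table["gene"])  # PDX1 has Body/3'UTR CpGs only


class TestGeneSetFractions:
    @pytest.mark.parametrize(
        "dm,gene_set,expected",
        [
            ([f"g{i}" for i in range(3)], [f"g{i}" for i in range(30)], 10.0),
            ([], ["a", "b"], 0.0),
            (["a", "b"], ["a", "b"], 100.0),
        ],
    )
    def test_percentage(self, dm, gene_set, expected):
        assert dm_fraction_of_gene_set(dm, gene_set) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            dm_fraction_of_gene_set(["a"], [])


class TestPromoterMethylation:
    def test_mean_over_promoter_cpgs(self):
        annotation = make_annotation(
            [
                ("cg1", ["X"], ["TSS200"]),
                ("cg2", ["X"], ["TSS1500"]),
                ("cg3", ["X"], ["Body"]),
                ("cg4", ["Y"], ["5'UTR"]),
                ("cg5", ["Z"], ["Body"]),
            ]
        )
        beta = BetaMatrix(
            pd.DataFrame(
                {"s1": [0.2, 0.4, 0.9, 0.7, 0.1]},
                index=["cg1", "cg2", "cg3", "cg4", "cg5"],
            )
        )
        prom = promoter_methylation_matrix(beta, annotation)
        assert prom.loc["X", "s1"] == pytest.approx(0.3)  # Body CpG excluded
        assert prom.loc["Y", "s1"] == pytest.approx(0.7)
        assert "Z" not in prom.index


class TestPromoterExpressionCorrelation:
    def _pair(self, meth_rows, expr_rows, samples):
        prom = pd.DataFrame(meth_rows, columns=samples)
        expr = ExpressionMatrix(pd.DataFrame(expr_rows, columns=samples,
                                             index=prom.index))
        return prom, expr

    def test_exact_negative_relation(self):
        samples = [f"s{i}" for i in range(5)]
        meth = np.linspace(0.1, 0.9, 5)
        prom = pd.DataFrame([meth], index=["X"], columns=samples)
        expr = ExpressionMatrix(
            pd.DataFrame([10 - 4 * meth], index=["X"], columns=samples)
        )
        out = correlate_promoter_expression(prom, expr)
        assert out.loc["X", "r"] == pytest.approx(-1.0)
        assert out.loc["X", "sign"] == "negative"

    def test_independent_noise_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(50)]
            prom = pd.DataFrame([rng.uniform(0, 1, 50)], index=["X"], columns=samples)
            expr = ExpressionMatrix(
                pd.DataFrame([rng.normal(5, 1, 50)], index=["X"], columns=samples)
            )
            out = correlate_promoter_expression(prom, expr)
            if out.loc["X", "sign"] != "none":
                hits += 1
        assert hits <= 2  # >=90% of seeds non-significant

    def test_constant_vector_flagged_undefined(self):
        samples = [f"s{i}" for i in range(5)]
        prom = pd.DataFrame([[0.5] * 5], index=["X"], columns=samples)
        expr = ExpressionMatrix(
            pd.DataFrame([np.arange(5.0)], index=["X"], columns=samples)
        )
        out = correlate_promoter_expression(prom, expr)
        assert out.loc["X", "sign"] == "undefined"

    def test_too_few_shared_samples_rejected(self):
        prom = pd.DataFrame([[0.5, 0.6]], index=["X"], columns=["s1", "s2"])
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["X"], columns=["s1", "s2"])
        )
        with pytest.raises(ValidationError):
            correlate_promoter_expression(prom, expr)


class TestSetOverlaps:
    def test_three_set_example(self):
        out = overlap_promoter_sets(
            {"A": ["g1", "g2", "g3"], "B": ["g2", "g3"], "C": ["g3"]},
            reference="A",
        )
        assert out["common"] == {"g3"}
        assert out["reference_shared_fraction"] == pytest.approx(100 / 3)

    def test_disjoint_sets(self):
        out = overlap_promoter_sets({"A": ["g1"], "B": ["g2"]})
        assert out["common"] == set()
        assert out["reference_shared_fraction"] == 0.0

    def test_reference_half_shared(self):
        out = overlap_promoter_sets(
            {"ref": ["g1", "g2", "g3", "g4"], "B": ["g1", "g2"], "C": ["g1", "g2", "g9"]},
            reference="ref",
        )
        assert out["reference_shared_fraction"] == pytest.approx(50.0)

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            overlap_promoter_sets({"A": ["g1"]})


class TestFoldThresholdGeneSet:
    @pytest.fixture
    def tissue_expr(self):
        return pd.DataFrame(
            {
                "stomach": [10.0, 4.0, 0.5],
                "liver": [1.0, 1.0, 0.0],
                "colon": [2.0, 1.0, 0.0],
            },
            index=["GKN1", "MUC5AC", "RARE1"],
        )

    def test_fivefold_rule(self, tissue_expr):
        result = fold_threshold_gene_set(tissue_expr, "stomach", fold=5.0)
        # GKN1: 10 / (1.5 + 0.01) = 6.62 -> in; MUC5AC: 4 -> out
        assert "GKN1" in result and "MUC5AC" not in result

    def test_zero_background_stays_finite(self, tissue_expr):
        result = fold_threshold_gene_set(tissue_expr, "stomach", fold=5.0)
        assert "RARE1" in result  # 0.5 / 0.01 = 50

    def test_logfc_mode(self, tissue_expr):
        result = fold_threshold_gene_set(tissue_expr, "stomach", fold=1.0, mode="logfc")
        assert "GKN1" in result and "MUC5AC" in result  # log2(4/1.01) > 1

    def test_single_tissue_rejected(self):
        with pytest.raises(ValidationError):
            fold_threshold_gene_set(
                pd.DataFrame({"stomach": [1.0]}, index=["g"]), "stomach"
            )


def test_translate_gene_set_through_orthology_map():
    mapping = pd.DataFrame({"mouse": ["Gkn1", "Cdx2"], "human": ["GKN1", "CDX2"]})
    assert translate_gene_set(["Gkn1", "Cdx2", "Xyz"], mapping) == {"GKN1", "CDX2"}


def test_aggregation_invariant_to_cpg_order(small_dataset):
    from regmeth.diffmeth import differential_methylation

    beta, annotation, sheet = (
        small_dataset["beta"], small_dataset["annotation"], small_dataset["sheet"],
    )
    dm = differential_methylation(beta, sheet, ("A", "B"))
    t1 = call_dm_genes(dm["call"], annotation)
    shuffled = dm["call"].sample(frac=1.0, random_state=1)
    perm = CpGAnnotation(annotation.frame.loc[shuffled.index])
    t2 = call_dm_genes(shuffled, perm)
    pd.testing.assert_frame_equal(t1, t2)
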