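import numpy as np
import pandas as pd
import pytest

from oxbskit import integrate
from oxbskit.synthgen import EffectSpec, ExpressionTable, simulate_expression


def expr_table(counts: pd.DataFrame, n_pairs=4) -> ExpressionTable:
    # counts are treated as already normalized for these fixtures
    tumor = [f"T{i}" for i in range(1, n_pairs + 1)]
    normal = [f"N{i}" for i in range(1, n_pairs + 1)]
    return ExpressionTable(
        counts=counts, cpm=counts.copy(), tpm=counts.copy(),
        groups={"tumor": tumor, "normal": normal},
    )


def classes_frame(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "dm", "dhm", "delta_m", "delta_h"]
    )
    pdmr = df[df["dm"] != "none"].rename(columns={"dm": "direction", "delta_m": "delta_beta"})
    pdhmr = df[df["dhm"] != "none"].rename(columns={"dhm": "direction", "delta_h": "delta_beta"})
    return integrate.classify_promoters(
        pdmr[["gene_id", "direction", "delta_beta"]],
        pdhmr[["gene_id", "direction", "delta_beta"]],
    )


class TestFilterExpressed:
    def make(self, nonzero_in):
        counts = pd.DataFrame(
            {f"S{i}": [1.0 if i < nonzero_in else 0.0] for i in range(8)},
            index=pd.Index(["G1"], name="gene_id"),
        )
        tumor = [f"S{i}" for i in range(4)]
        normal = [f"S{i}" for i in range(4, 8)]
        return ExpressionTable(counts, counts.copy(), counts.copy(),
                               {"tumor": tumor, "normal": normal})

    def test_quarter_of_samples_kept(self):
        assert integrate.filter_expressed(self.make(2)) == ["G1"]

    def test_below_quarter_dropped(self):
        assert integrate.filter_expressed(self.make(1)) == []

    def test_all_zero_matrix(self):
        assert integrate.filter_expressed(self.make(0)) == []


class TestClassifyPromoters:
    def test_four_way_patterns(self):
        cls = classes_frame(
            [
                ("G1", "up", "up", 0.3, 0.15),
                ("G2", "down", "up", -0.3, 0.15),
                ("G3", "up", "none", 0.3, np.nan),
            ]
        ).set_index("gene_id")
        assert cls.at["G1", "pattern"] == "up/up"
        assert cls.at["G1", "directionality"] == "unidirectional"
        assert cls.at["G2", "pattern"] == "down/up"
        assert cls.at["G2", "directionality"] == "bidirectional"
        assert cls.at["G3", "pattern"] == "partial"
        assert cls.at["G3", "directionality"] == "n/a"

    def test_conflicting_directions_error(self):
        pdmr = pd.DataFrame(
            {
                "gene_id": ["G1", "G1"],
                "direction": ["up", "down"],
                "delta_beta": [0.3, -0.3],
            }
        )
        with pytest.raises(ValueError, match="conflicting"):
            integrate.classify_promoters(pdmr, pdmr.iloc[:0])

    def test_patterns_partition_both_marks_genes(self, rng):
        rows = []
        for i in range(60):
            dm = rng.choice(["up", "down", "none"])
            dhm = rng.choice(["up", "down", "none"])
            rows.append((f"G{i:03d}", dm, dhm, 0.3, 0.12))
        cls = classes_frame(rows)
        cls = cls[cls["pattern"] != "none"]
        both = cls[cls["pattern"].isin(["up/up", "up/down", "down/up", "down/down"])]
        n_both = ((cls["dm"] != "none") & (cls["dhm"] != "none")).sum()
        assert len(both) == n_both
        assert both["pattern"].value_counts().sum() == n_both


def paper_fixture():
    """Classification fixture realizing the published 2x2 counts:
    162 up-5mC genes (105 with up-5hmC), 196 down-5mC genes (176 with
    down-5hmC); 77/105 up/up genes downregulated, 101/176 down/down genes
    upregulated."""
    rows, fc = [], {}
    k = 0
    for i in range(162):
        dhm = "up" if i < 105 else "down"
        g = f"U{k:04d}"; k += 1
        rows.append((g, "up", dhm, 0.3, 0.15 if dhm == "up" else -0.15))
        if dhm == "up":
            fc[g] = -1.0 if i < 77 else 1.0
        else:
            fc[g] = -0.5
    for i in range(196):
        dhm = "down" if i < 176 else "up"
        g = f"D{k:04d}"; k += 1
        rows.append((g, "down", dhm, -0.3, -0.15 if dhm == "down" else 0.15))
        if dhm == "down":
            fc[g] = 1.0 if i < 101 else -1.0
        else:
            fc[g] = 0.5
    return classes_frame(rows), pd.Series(fc)


class TestPatternSummary:
    def test_published_quadruple(self):
        classes, fc = paper_fixture()
        out = integrate.pattern_summary(classes, fc)
        assert out["n_both_marks"] == 358
        assert out["n_dm_up"] == 162
        assert out["n_dm_up_matching"] == 105
        assert out["pct_dm_up_matching"] == 64.81
        assert out["n_dm_down"] == 196
        assert out["n_dm_down_matching"] == 176
        assert out["pct_dm_down_matching"] == 89.80
        assert out["pct_up/up_expr_down"] == 73.33
        assert out["pct_down/down_expr_up"] == 57.39

    def test_percentages_recompute_from_counts(self):
        classes, fc = paper_fixture()
        out = integrate.pattern_summary(classes, fc)
        assert out["pct_dm_up_matching"] == pytest.approx(
            round(100 * out["n_dm_up_matching"] / out["n_dm_up"], 2)
        )
        assert out["pct_up/up_expr_down"] == pytest.approx(
            round(100 * out["n_up/up_expr_down"] / out["n_up/up"], 2)
        )

    def test_empty_class_set(self):
        empty = classes_frame([])
        out = integrate.pattern_summary(empty, pd.Series(dtype=float))
        assert out["n_both_marks"] == 0
        assert out["pct_dm_up_matching"] == 0.0


class TestComparePatternExpression:
    def test_exact_p_small_vectors(self):
        classes = classes_frame(
            [(f"A{i}", "up", "up", 0.3, 0.15) for i in range(3)]
            + [(f"B{i}", "up", "down", 0.3, -0.15) for i in range(3)]
        )
        fc = pd.Series(
            {"A0": 1.0, "A1": 2.0, "A2": 3.0, "B0": 4.0, "B1": 5.0, "B2": 6.0}
        )
        out = integrate.compare_pattern_expression(classes, fc)
        assert out.iloc[0]["p_value"] == pytest.approx(0.1)

    def test_identical_vectors_p_one(self):
        classes = classes_frame(
            [("A0", "up", "up", 0.3, 0.15), ("B0", "up", "down", 0.3, -0.15)]
        )
        fc = pd.Series({"A0": 1.0, "B0": 1.0})
        out = integrate.compare_pattern_expression(classes, fc)
        assert out.iloc[0]["p_value"] == 1.0

    def test_empty_pattern_skipped_with_notice(self):
        classes = classes_frame([("A0", "up", "up", 0.3, 0.15)])
        fc = pd.Series({"A0": 1.0})
        with pytest.warns(UserWarning, match="skipped"):
            out = integrate.compare_pattern_expression(classes, fc)
        assert out.empty

    def test_unidirectional_effect_dominates_in_simulation(self):
        wins = 0
        genes = [f"G{i}" for i in range(120)]
        patterns = {}
        for i, g in enumerate(genes):
            patterns[g] = ["up/up", "up/down", "down/down", "down/up"][i % 4]
        rows = []
        for g, p in patterns.items():
            dm, dhm = p.split("/")
            rows.append((g, dm, dhm, 0.3 if dm == "up" else -0.3,
                         0.15 if dhm == "up" else -0.15))
        classes = classes_frame(rows)
        for rep in range(50):
            expr = simulate_expression(genes, patterns, EffectSpec(), seed=1000 + rep)
            fc = integrate.gene_log2fc(expr)
            out = integrate.compare_pattern_expression(classes, fc)
            ok = all(
                abs(r["median_log2fc_unidirectional"]) > abs(r["median_log2fc_bidirectional"])
                for _, r in out.iterrows()
            )
            wins += ok
        assert wins >= 45  # >= 90% of 50 replicates


class TestStratify:
    @staticmethod
    def make_classes(deltas_h):
        rows = [
            (f"G{i}", "up", "up", 0.3, dh) for i, dh in enumerate(deltas_h)
        ]
        return classes_frame(rows)

    def test_boundary_assignment(self):
        classes = self.make_classes([0.15, 0.13, 0.11, 0.14, 0.10, 0.09])
        genes = list(classes["gene_id"])
        counts = pd.DataFrame(
            {c: 100.0 for c in ["T1", "T2", "T3", "T4", "N1", "N2", "N3", "N4"]},
            index=pd.Index(genes, name="gene_id"),
        )
        out = integrate.stratify_by_5hmc(classes, expr_table(counts)).set_index("stratum")
        assert out.at["high", "n_genes"] == 1      # 0.15
        assert out.at["medium", "n_genes"] == 2    # 0.13 and 0.14 (boundary)
        assert out.at["low", "n_genes"] == 1       # 0.11; 0.10 and 0.09 excluded

    def test_grouped_log2fc_formula(self):
        assert integrate.grouped_log2fc(8.0, 2.0, pseudocount=0) == pytest.approx(2.0)
        assert integrate.grouped_log2fc(8.0, 2.0) == pytest.approx(np.log2(9 / 3))

    def test_monotone_with_coupled_effects(self):
        # effect size proportional to |delta_h| -> |median log2FC| monotone
        rng = np.random.default_rng(5)
        deltas = [0.2] * 30 + [0.13] * 30 + [0.11] * 30
        classes = self.make_classes(deltas)
        genes = list(classes["gene_id"])
        base = 200.0
        cols = {}
        for c in ["N1", "N2", "N3", "N4"]:
            cols[c] = [base * rng.lognormal(0, 0.05) for _ in genes]
        for c in ["T1", "T2", "T3", "T4"]:
            cols[c] = [
                base * 2.0 ** (-10 * dh) * rng.lognormal(0, 0.05) for dh in deltas
            ]
        counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        out = integrate.stratify_by_5hmc(classes, expr_table(counts)).set_index("stratum")
        assert (
            abs(out.at["high", "median_log2fc"])
            > abs(out.at["medium", "median_log2fc"])
            > abs(out.at["low", "median_log2fc"])
        )


class TestSelectTopGenes:
    @staticmethod
    def eligible_classes(n, pattern="down/down", dh=0.15):
        dm, dhm = pattern.split("/")
        sign = 1 if dhm == "up" else -1
        return classes_frame(
            [(f"G{i:03d}", dm, dhm, 0.3 if dm == "up" else -0.3, sign * dh) for i in range(n)]
        )

    def test_low_delta_ineligible(self):
        classes = self.eligible_classes(1, dh=0.11)
        fc = pd.Series({"G000": 9.9})
        assert integrate.select_top_genes(classes, fc, "up", k=20) == []

    def test_returns_all_with_warning_when_scarce(self):
        classes = self.eligible_classes(5)
        fc = pd.Series({f"G{i:03d}": 1.0 + i for i in range(5)})
        with pytest.warns(UserWarning, match="only 5"):
            out = integrate.select_top_genes(classes, fc, "up", k=20)
        assert len(out) == 5

    def test_top_20_of_30_by_abs_fc(self):
        classes = self.eligible_classes(30)
        fc = pd.Series({f"G{i:03d}": 0.5 + 0.1 * i for i in range(30)})
        out = integrate.select_top_genes(classes, fc, "up", k=20)
        assert len(out) == 20
        assert out[0] == "G029"
        assert set(out) == {f"G{i:03d}" for i in range(10, 30)}

    def test_direction_sign_respected(self):
        classes = self.eligible_classes(2, pattern="up/up")
        fc = pd.Series({"G000": -3.0, "G001": 2.0})
        out = integrate.select_top_genes(classes, fc, "down", k=1)
        assert out == ["G000"]


class TestSignatureScore:
    def test_mean_log2_tpm(self):
        tpm = pd.DataFrame({"S1": [3.0, 7.0]}, index=["G1", "G2"])
        out = integrate.signature_score(tpm, ["G1", "G2"])
        assert out["score"].iloc[0] == pytest.approx(2.5)

    def test_constant_scores_no_high_low(self):
        tpm = pd.DataFrame({f"S{i}": [3.0] for i in range(10)}, index=["G1"])
        out = integrate.signature_score(tpm, ["G1"])
        assert (out["label"] == "mid").all()

    def test_100_distinct_scores_25_high_24_low(self):
        tpm = pd.DataFrame(
            {f"S{i:03d}": [float(2**i - 1)] for i in range(1, 101)}, index=["G1"]
        )
        out = integrate.signature_score(tpm, ["G1"])
        assert (out["label"] == "high").sum() == 25
        assert (out["label"] == "low").sum() == 24

    def test_empty_gene_set_errors(self):
        tpm = pd.DataFrame({"S1": [3.0]}, index=["G1"])
        with pytest.raises(ValueError, match="empty gene set"):
            integrate.signature_score(tpm, ["NOPE"])


class TestGeneBodyAnalysis:
    @staticmethod
    def levels(rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "promoter_m", "promoter_h", "genebody_h"]
        )

    def expr_for(self, genes, values=None):
        vals = values if values is not None else {g: 100.0 for g in genes}
        counts = pd.DataFrame(
            {c: [vals[g] for g in genes] for c in ["T1", "T2", "N1", "N2"]},
            index=pd.Index(genes, name="gene_id"),
        )
        return ExpressionTable(
            counts, counts.copy(), counts.copy(),
            {"tumor": ["T1", "T2"], "normal": ["N1", "N2"]},
        )

    def test_high_promoter_5mc_excluded(self):
        lv = self.levels(
            [("G1", 0.15, 0.1, 0.1), ("G2", 0.05, 0.1, 0.1), ("G3", 0.01, 0.2, 0.2)]
        )
        out = integrate.genebody_5hmc_analysis(lv, self.expr_for(["G1", "G2", "G3"]))
        assert "G1" not in out.eligible_genes
        assert set(out.eligible_genes) == {"G2", "G3"}

    def test_too_few_eligible_errors(self):
        lv = self.levels([("G1", 0.05, 0.1, 0.1)])
        with pytest.raises(ValueError, match="fewer than 2"):
            integrate.genebody_5hmc_analysis(lv, self.expr_for(["G1"]))

    def test_positive_genebody_coupling_direction(self):
        genes = [f"G{i}" for i in range(20)]
        gb = np.linspace(0.01, 0.3, 20)
        lv = self.levels([(g, 0.05, 0.1, gbh) for g, gbh in zip(genes, gb)])
        values = {g: 50.0 + 500.0 * gbh for g, gbh in zip(genes, gb)}
        out = integrate.genebody_5hmc_analysis(lv, self.expr_for(genes, values))
        tab = out.groups.set_index("group")
        assert (
            tab.at["genebody_high_5hmc", "grouped_expression"]
            > tab.at["genebody_low_5hmc", "grouped_expression"]
        )

    def test_all_identical_5hmc_stable_split(self):
        genes = [f"G{i}" for i in range(7)]
        lv = self.levels([(g, 0.05, 0.1, 0.1) for g in genes])
        out = integrate.genebody_5hmc_analysis(lv, self.expr_for(genes))
        tab = out.groups.set_index("group")
        n_hi = tab.at["genebody_high_5hmc", "n_genes"]
        n_lo = tab.at["genebody_low_5hmc", "n_genes"]
        assert abs(n_hi - n_lo) <= 1
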