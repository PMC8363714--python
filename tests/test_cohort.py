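"""Cohort layer: variant-table IO, rescaling, age-bin summaries,
dominant clones, and pathogenicity summaries."""

import numpy as np
import pandas as pd
import pytest

from clonesel.classifier import ClassPrediction
from clonesel.cohort import (
    CohortRecord,
    age_bin_summary,
    dominant_clone,
    function_altering_gene_sets,
    pathogenicity_summary,
    read_panel,
    read_variant_table,
    rescale_mutation_rate,
)
from clonesel.params import CLASS_LABELS


@pytest.fixture()
def panel(tmp_path):
    df = pd.DataFrame(
        {
            "gene": ["DNMT3A", "TET2", "GENE001", "GENE002"],
            "length_bp": [2700, 6000, 1500, 900],
            "driver": [True, True, False, False],
        }
    )
    path = tmp_path / "panel.tsv"
    df.to_csv(path, sep="\t", index=False)
    return read_panel(path)


def _write_tsv(tmp_path, rows, name="subject.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


class TestReadVariantTable:
    def test_empty_file_gives_empty_table(self, tmp_path, panel):
        path = tmp_path / "empty.tsv"
        path.write_text("gene\tconsequence\tvaf\n")
        vt = read_variant_table(path, panel)
        assert len(vt) == 0

    def test_read_support_rule_drops_strand_imbalanced_rows(self, tmp_path, panel):
        rows = [
            {"gene": "TET2", "consequence": "missense", "vaf": 0.01,
             "reads_fwd": 1, "reads_rev": 4},      # fails 2-per-strand
            {"gene": "TET2", "consequence": "missense", "vaf": 0.01,
             "reads_fwd": 2, "reads_rev": 2},      # fails min 5 total
            {"gene": "TET2", "consequence": "missense", "vaf": 0.01,
             "reads_fwd": 3, "reads_rev": 2},      # passes
        ]
        vt = read_variant_table(_write_tsv(tmp_path, rows), panel)
        assert len(vt) == 1
        assert vt["reads_fwd"].iloc[0] == 3

    def test_driver_flag_from_panel_and_unknown_gene_warning(self, tmp_path, panel):
        rows = [
            {"gene": "DNMT3A", "consequence": "missense", "vaf": 0.2},
            {"gene": "NOTINPANEL", "consequence": "silent", "vaf": 0.1},
        ]
        with pytest.warns(UserWarning, match="NOTINPANEL"):
            vt = read_variant_table(_write_tsv(tmp_path, rows), panel)
        assert vt["driver"].tolist() == [True, False]

    def test_nonsense_pooled_with_missense(self, tmp_path, panel):
        rows = [
            {"gene": "TET2", "consequence": "nonsense", "vaf": 0.2},
            {"gene": "TET2", "consequence": "synonymous", "vaf": 0.2},
        ]
        vt = read_variant_table(_write_tsv(tmp_path, rows), panel)
        assert vt["consequence"].tolist() == ["missense", "silent"]

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path, panel):
        rows = [
            {"gene": "TET2", "consequence": "missense", "vaf": 0.2},
            {"gene": "TET2", "consequence": "missense", "vaf": 1.7},
        ]
        with pytest.raises(ValueError, match="line 3"):
            read_variant_table(_write_tsv(tmp_path, rows), panel)
        rows = [{"gene": "TET2", "consequence": "frameshiftish", "vaf": 0.2}]
        with pytest.raises(ValueError, match="line 2"):
            read_variant_table(_write_tsv(tmp_path, rows), panel)

    def test_cadd_scores_merged(self, tmp_path, panel):
        rows = [
            {"variant_id": "v1", "gene": "TET2", "consequence": "missense",
             "vaf": 0.2},
        ]
        cadd = tmp_path / "cadd.tsv"
        pd.DataFrame({"variant_id": ["v1"], "cadd": [22.5]}).to_csv(
            cadd, sep="\t", index=False
        )
        vt = read_variant_table(_write_tsv(tmp_path, rows), panel,
                                cadd_path=cadd)
        assert vt["cadd"].iloc[0] == 22.5

    def test_vcf_dialect(self, tmp_path, panel):
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="c">\n'
            '##INFO=<ID=VAF,Number=1,Type=Float,Description="v">\n'
            '##INFO=<ID=FR,Number=1,Type=Integer,Description="f">\n'
            '##INFO=<ID=RR,Number=1,Type=Integer,Description="r">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\tv1\tA\tT\t.\t.\tGENE=DNMT3A;CSQCLASS=missense;"
            "VAF=0.15;FR=40;RR=35\n"
            "1\t200\tv2\tG\tC\t.\t.\tGENE=TET2;CSQCLASS=synonymous;"
            "VAF=0.02;FR=1;RR=9\n"
        )
        vt = read_variant_table(vcf, panel)
        assert len(vt) == 1   # the strand-imbalanced row is dropped
        assert vt["gene"].iloc[0] == "DNMT3A"
        assert vt["driver"].iloc[0]


class TestRescaleMutationRate:
    def test_identity_when_pool_size_unchanged(self):
        assert rescale_mutation_rate(1e-7, 1e4, 1e4) == 1e-7

    def test_theta_invariant_arithmetic(self):
        assert rescale_mutation_rate(1e-7, 1e4, 2e5) == pytest.approx(5e-9)

    def test_monotone_decreasing_over_hsc_pool_range(self):
        sizes = np.linspace(4e4, 2e5, 30)
        rates = [rescale_mutation_rate(1e-7, 1e4, n) for n in sizes]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_roundtrip_is_identity(self):
        mu = 3.7e-8
        back = rescale_mutation_rate(
            rescale_mutation_rate(mu, 1e4, 123_456.0), 123_456.0, 1e4
        )
        assert abs(back - mu) / mu < 1e-12

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            rescale_mutation_rate(0.0, 1e4, 1e5)
        with pytest.raises(ValueError):
            rescale_mutation_rate(1e-7, 1e4, 0.0)


def _predictions_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "status", "age",
                                       "predicted_class"])


class TestAgeBinSummary:
    def test_binomial_standard_error_formula(self):
        rows = (
            [(f"s{i}", "control", 45, "neutral") for i in range(50)]
            + [(f"t{i}", "control", 45, "combination") for i in range(50)]
        )
        summary, _ = age_bin_summary(_predictions_frame(rows))
        row = summary[(summary["class"] == "neutral")].iloc[0]
        assert row["p"] == 0.5
        assert row["se"] == pytest.approx(np.sqrt(0.25 / 100))
        zero = summary[(summary["class"] == "positive")].iloc[0]
        assert zero["p"] == 0.0 and zero["se"] == 0.0

    def test_proportions_sum_to_one_per_bin_and_status(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"s{i}", rng.choice(["case", "control"]),
             float(rng.uniform(31, 79)), rng.choice(CLASS_LABELS))
            for i in range(300)
        ]
        summary, _ = age_bin_summary(_predictions_frame(rows))
        sums = summary.groupby(["age_bin", "status"])["p"].sum()
        assert np.allclose(sums, 1.0)

    def test_single_class_cohort_has_unit_proportions(self):
        rows = [(f"s{i}", "case", 35 + i % 40, "combination")
                for i in range(60)]
        summary, _ = age_bin_summary(_predictions_frame(rows))
        comb = summary[summary["class"] == "combination"]
        assert (comb["p"] == 1.0).all()

    def test_out_of_range_ages_flagged(self):
        rows = [("s0", "case", 25, "neutral"), ("s1", "case", 85, "neutral"),
                ("s2", "case", 45, "neutral")]
        summary, _ = age_bin_summary(_predictions_frame(rows))
        assert set(summary[summary["flagged"]]["age_bin"]) == {"<30", ">=80"}

    def test_case_control_chi_squared_reported(self):
        rows = (
            [(f"c{i}", "case", 55, "combination") for i in range(40)]
            + [(f"c{i}", "case", 55, "neutral") for i in range(10)]
            + [(f"k{i}", "control", 55, "combination") for i in range(10)]
            + [(f"k{i}", "control", 55, "neutral") for i in range(40)]
        )
        _, tests = age_bin_summary(_predictions_frame(rows))
        comb = tests[(tests["class"] == "combination")].iloc[0]
        assert comb["p_value"] < 0.001


class TestDominantClone:
    def _vt(self, vafs, cadd=None):
        df = pd.DataFrame({
            "variant_id": np.arange(len(vafs)),
            "vaf": vafs,
            "consequence": ["missense"] * len(vafs),
            "gene": ["G"] * len(vafs),
            "driver": [False] * len(vafs),
        })
        if cadd is not None:
            df["cadd"] = cadd
        return df

    def test_single_variant_is_dominant(self):
        row = dominant_clone(self._vt([0.3]))
        assert row["vaf"] == 0.3 and not row["tie"]

    def test_maximum_vaf_selected(self):
        row = dominant_clone(self._vt([0.01, 0.4, 0.2]))
        assert row["vaf"] == 0.4

    def test_tie_broken_by_cadd_and_flagged(self):
        row = dominant_clone(self._vt([0.4, 0.4, 0.1], cadd=[5.0, 15.0, 30.0]))
        assert row["tie"]
        assert row["cadd"] == 15.0
        assert row["cadd_bin"] == 10.0

    def test_permutation_invariant_up_to_tie_flag(self):
        vt = self._vt([0.05, 0.5, 0.2], cadd=[1.0, 9.0, 3.0])
        a = dominant_clone(vt)
        b = dominant_clone(vt.iloc[::-1].reset_index(drop=True))
        assert a["vaf"] == b["vaf"] and a["cadd"] == b["cadd"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            dominant_clone(self._vt([]))

    def test_cadd_bin_is_width_ten_floor(self):
        row = dominant_clone(self._vt([0.2], cadd=[27.3]))
        assert row["cadd_bin"] == 20.0


def _record(subject, cls, variants):
    probs = np.full(4, 0.05)
    probs[CLASS_LABELS.index(cls)] = 0.85
    pred = ClassPrediction(
        probs_mean=probs, probs_se=np.zeros(4),
        params_mean=np.zeros(4), params_se=np.zeros(4),
        predicted_class=cls,
    )
    rec = CohortRecord(subject_id=subject, status="control", age=50.0,
                       variants=variants)
    rec.prediction = pred
    return rec


def _variants(gene_cadd_driver):
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(gene_cadd_driver))],
            "vaf": [0.1] * len(gene_cadd_driver),
            "consequence": ["missense"] * len(gene_cadd_driver),
            "gene": [g for g, _, _ in gene_cadd_driver],
            "cadd": [c for _, c, _ in gene_cadd_driver],
            "driver": [d for _, _, d in gene_cadd_driver],
        }
    )


class TestPathogenicitySummary:
    def test_low_cadd_everywhere_gives_empty_gene_sets(self):
        cohort = [
            _record("s0", "neutral", _variants([("A", 3.0, False),
                                                ("B", 9.9, True)])),
        ]
        sets = function_altering_gene_sets(cohort)
        assert all(len(v) == 0 for v in sets["per_class"].values())
        assert sets["intersections"] == {}

    def test_gene_lands_in_exact_class_intersection(self):
        cohort = [
            _record("s0", "positive", _variants([("TP53", 25.0, True)])),
            _record("s1", "combination", _variants([("TP53", 30.0, True)])),
            _record("s2", "neutral", _variants([("OTHER", 2.0, False)])),
        ]
        sets = function_altering_gene_sets(cohort)
        assert sets["intersections"] == {"positive+combination": ["TP53"]}

    def test_driver_cadd_exceeds_passenger_under_selection(self):
        # constructed so selected (driver) mutations carry higher scores
        rng = np.random.default_rng(0)
        cohort = []
        for i, cls in enumerate(["positive", "combination"] * 10):
            rows = [("DNMT3A", float(rng.normal(22, 2)), True),
                    ("GENE%d" % i, float(rng.normal(6, 2)), False)]
            cohort.append(_record(f"s{i}", cls, _variants(rows)))
        summary = pathogenicity_summary(cohort)
        for cls in ("positive", "combination"):
            entry = summary["classes"][cls]
            assert entry["driver"]["mean"] > entry["passenger"]["mean"]
            assert entry["ranksum"]["p_value"] < 0.01

    def test_classes_without_scored_mutations_omitted(self):
        cohort = [_record("s0", "neutral",
                          _variants([("A", 5.0, False)]))]
        summary = pathogenicity_summary(cohort)
        assert "positive" not in summary["classes"]
        assert "neutral" in summary["classes"]
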