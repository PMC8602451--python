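import numpy as np
import pandas as pd
import pytest

from simenrich import LFQTable, filter_proteins, load_protein_groups
from simenrich import test_and_classify as classify
from simenrich import transform_normalize_impute
from simenrich.lfq import LFQ_PREFIX
from simenrich.simulate import LFQModel, generate_lfq

GROUPS = {"WT": ["WT_1", "WT_2", "WT_3"],
          "control": ["control_1", "control_2", "control_3"]}
SAMPLES = GROUPS["WT"] + GROUPS["control"]


def make_table(rows, groups=GROUPS, **kwargs):
    df = pd.DataFrame(rows)
    for col in ("Protein IDs", "Peptides"):
        assert col in df.columns
    if "flagged" not in df.columns:
        df["flagged"] = False
    return LFQTable(data=df, groups={g: list(s) for g, s in groups.items()},
                    **kwargs)


def row(pid, values, peptides=5, flagged=False):
    d = {"Protein IDs": pid, "Peptides": peptides, "flagged": flagged}
    d.update({LFQ_PREFIX + s: v for s, v in zip(SAMPLES, values)})
    return d


class TestLoad:
    def fixture_file(self, tmp_path, extra_row=""):
        header = ("Protein IDs\tGene names\tPeptides\tReverse\t"
                  "Potential contaminant\tOnly identified by site\t"
                  + "\t".join(LFQ_PREFIX + s for s in SAMPLES))
        body = ("P1\tG1\t5\t\t\t\t1e7\t2e7\t1.5e7\t1e6\t2e6\t0\n"
                "P2\tG2\t3\t+\t\t\t1e7\t1e7\t1e7\t1e7\t1e7\t1e7\n")
        f = tmp_path / "proteinGroups.txt"
        f.write_text(header + "\n" + body + extra_row)
        return f

    def test_load_and_flag(self, tmp_path):
        table = load_protein_groups(self.fixture_file(tmp_path), GROUPS)
        assert len(table) == 2
        assert list(table.data["flagged"]) == [False, True]
        assert set(table.groups) == {"WT", "control"}

    def test_reverse_row_removed_by_filter(self, tmp_path):
        table = load_protein_groups(self.fixture_file(tmp_path), GROUPS)
        kept = filter_proteins(table)
        assert list(kept.data["Protein IDs"]) == ["P1"]

    def test_missing_lfq_columns_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("Protein IDs\tPeptides\nP1\t3\n")
        with pytest.raises(ValueError, match="LFQ intensity"):
            load_protein_groups(f, GROUPS)

    def test_non_numeric_intensity_named(self, tmp_path):
        f = self.fixture_file(tmp_path,
                              "P3\tG3\t4\t\t\t\toops\t1e6\t1e6\t1e6\t1e6\t1e6\n")
        with pytest.raises(ValueError, match="LFQ intensity WT_1"):
            load_protein_groups(f, GROUPS)

    def test_sample_in_two_groups_rejected(self, tmp_path):
        bad = {"WT": ["WT_1", "WT_2"], "control": ["WT_1", "control_1"]}
        with pytest.raises(ValueError, match="more than one group"):
            load_protein_groups(self.fixture_file(tmp_path), bad)


class TestFilter:
    def test_two_of_three_in_one_group_kept(self):
        table = make_table([row("P1", [1e7, 2e7, 0, 0, 0, 0])])
        assert len(filter_proteins(table)) == 1

    def test_one_peptide_removed(self):
        table = make_table([row("P1", [1e7] * 6, peptides=1)])
        assert len(filter_proteins(table)) == 0

    def test_one_valid_per_group_removed(self):
        table = make_table([row("P1", [1e7, 0, 0, 2e7, 0, 0])])
        assert len(filter_proteins(table)) == 0


class TestTransformImpute:
    def test_median_normalization_equalizes_medians(self, rng):
        vals = 2.0 ** rng.normal(25, 2, size=(100, 6))
        vals[:, 0] *= 4  # shift one sample
        rows = [row(f"P{i}", vals[i]) for i in range(100)]
        out = transform_normalize_impute(make_table(rows), median_normalize=True)
        mat = out.intensities().to_numpy()
        medians = np.median(mat, axis=0)
        assert np.allclose(medians, medians[0])

    def test_imputed_values_are_downshifted(self, rng):
        vals = 2.0 ** rng.normal(25, 2, size=(500, 6))
        missing = rng.random(vals.shape) < 0.2
        vals[missing] = 0.0
        rows = [row(f"P{i}", vals[i]) for i in range(500)]
        out = transform_normalize_impute(make_table(rows), seed=1)
        mat = out.intensities().to_numpy()
        below = 0
        for j in range(6):
            col = mat[:, j]
            imputed = col[missing[:, j]]
            below += (imputed < np.percentile(col, 50)).sum()
        assert below / missing.sum() >= 0.95

    def test_same_seed_identical(self, rng):
        vals = 2.0 ** rng.normal(25, 2, size=(50, 6))
        vals[rng.random(vals.shape) < 0.3] = 0.0
        rows = [row(f"P{i}", vals[i]) for i in range(50)]
        a = transform_normalize_impute(make_table(rows), seed=7)
        b = transform_normalize_impute(make_table(rows), seed=7)
        c = transform_normalize_impute(make_table(rows), seed=8)
        assert a.intensities().equals(b.intensities())
        assert not a.intensities().equals(c.intensities())

    def test_sample_with_too_few_valid_rejected(self):
        rows = [row("P1", [1e7, 0, 1e7, 1e7, 1e7, 1e7]),
                row("P2", [1e7, 0, 1e7, 1e7, 1e7, 1e7])]
        with pytest.raises(ValueError, match="WT_2"):
            transform_normalize_impute(make_table(rows))

    def test_double_transform_rejected(self, rng):
        rows = [row(f"P{i}", 2.0 ** rng.normal(25, 2, size=6)) for i in range(5)]
        out = transform_normalize_impute(make_table(rows))
        with pytest.raises(ValueError):
            transform_normalize_impute(out)


class TestTestAndClassify:
    def log_table(self, rows):
        return make_table(rows, log_scale=True)

    def test_identical_groups_not_significant(self):
        table = self.log_table([row("P1", [20.0] * 6)])
        res = classify(table)
        assert res.loc[0, "log2_difference"] == 0
        assert res.loc[0, "p_value"] == 1.0
        assert not res.loc[0, "high_confidence"]

    def test_or_rule_large_difference_wins_regardless_of_p(self):
        table = self.log_table([row("P1", [10.0, 10.0, 10.0, 12.0, 12.0, 12.000001])])
        res = classify(table)
        assert abs(res.loc[0, "log2_difference"]) > 1
        assert res.loc[0, "high_confidence"]
        assert res.loc[0, "direction"] == "control"

    def test_and_rule_requires_both(self):
        table = self.log_table(
            [row("P1", [10.0, 10.1, 9.9, 11.5, 11.6, 11.4])])
        res_or = classify(table, rule="or")
        res_and = classify(table, rule="and")
        assert res_or.loc[0, "high_confidence"]
        assert res_and.loc[0, "high_confidence"] == \
            ((abs(res_and.loc[0, "log2_difference"]) > 1)
             and (res_and.loc[0, "p_value"] < 0.05))

    def test_group_swap_negates_differences(self, rng):
        vals = rng.normal(25, 2, size=(40, 6))
        rows = [row(f"P{i}", vals[i]) for i in range(40)]
        fwd = classify(self.log_table(rows))
        swapped_groups = {"control": GROUPS["control"], "WT": GROUPS["WT"]}
        rev = classify(make_table(rows, groups=swapped_groups,
                                           log_scale=True))
        assert np.allclose(fwd["log2_difference"], -rev["log2_difference"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_requires_log_scale(self):
        table = make_table([row("P1", [1e7] * 6)])
        with pytest.raises(ValueError, match="log2"):
            classify(table)

    def test_welch_differs_under_unequal_variance(self):
        table = self.log_table(
            [row("P1", [20.0, 20.1, 19.9, 25.0, 22.0, 28.0])])
        student = classify(table, equal_var=True)
        welch = classify(table, equal_var=False)
        assert student.loc[0, "p_value"] != welch.loc[0, "p_value"]


class TestPipelineProperties:
    def test_no_missingness_output_seed_independent(self):
        table, _ = generate_lfq(LFQModel(n_proteins=80, n_hits=10, seed=3,
                                         dropout_max=0.0))
        a = transform_normalize_impute(table, seed=1)
        b = transform_normalize_impute(table, seed=99)
        assert a.intensities().equals(b.intensities())
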