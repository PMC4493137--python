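"""Dataset loading, terminology unification and cleaning."""

import numpy as np
import pandas as pd
import pytest

from phenokit.phenlist import (
    AmbiguityError,
    ConfigurationError,
    FormatError,
    TerminologyMap,
    build_phenlist,
    dataset_summary,
    load_table,
    unify_terminology,
)
from phenokit.synthetic import SyntheticSpec, synthetic_phenlist

from conftest import make_raw, make_phenlist

ROWS = [
    {"Genotype": "control", "Sex": "female", "Batch": "d1", "Weight": 20.1, "mass": 5.0},
    {"Genotype": "control", "Sex": "male", "Batch": "d1", "Weight": 25.0, "mass": 6.5},
    {"Genotype": "mutant", "Sex": "male", "Batch": "d2", "Weight": 24.0, "mass": 4.2},
    {"Genotype": "mutant", "Sex": "female", "Batch": "d2", "Weight": 19.0, "mass": 3.9},
]


class TestLoadTable:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(ROWS).to_csv(path, index=False)
        raw = load_table(path)
        assert len(raw) == 4
        assert raw.columns == list(ROWS[0])
        assert raw.frame.loc[2, "mass"] == "4.2"  # values read verbatim as text

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("Genotype,Sex,mass\n")
        assert len(load_table(path)) == 0

    def test_missing_cells_are_missing_not_empty(self, tmp_path):
        path = tmp_path / "na.csv"
        path.write_text("Genotype,Sex,mass\ncontrol,male,\ncontrol,female,NA\nmutant,male,NaN\n")
        raw = load_table(path)
        assert raw.frame["mass"].isna().all()

    def test_tab_dialect(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame(ROWS).to_csv(path, sep="\t", index=False)
        assert len(load_table(path, dialect="tab")) == 4

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            load_table(tmp_path / "absent.csv")

    def test_no_header(self, tmp_path):
        path = tmp_path / "blank.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            load_table(path)


class TestUnifyTerminology:
    def test_gender_becomes_sex_with_normalised_values(self):
        raw = make_raw([{"Genotype": "a", "Gender": "M"}, {"Genotype": "a", "Gender": "F"}])
        out = unify_terminology(raw)
        assert "Sex" in out.columns and "Gender" not in out.columns
        assert list(out.frame["Sex"]) == ["male", "female"]
        assert any("renamed" in e for e in out.pending_log)

    def test_canonical_table_unchanged_with_empty_log(self):
        raw = make_raw([{"Genotype": "a", "Sex": "male", "Batch": "b1"}])
        out = unify_terminology(raw)
        assert out.columns == raw.columns
        assert out.pending_log == []

    def test_sex_and_gender_together_is_ambiguous(self):
        raw = make_raw([{"Genotype": "a", "Sex": "male", "Gender": "M"}])
        with pytest.raises(AmbiguityError):
            unify_terminology(raw)

    def test_values_never_altered_only_names(self):
        raw = make_raw([{"Genotype": "a", "Gender": "M", "Body.Weight": 21.5, "mass": 3.3}])
        out = unify_terminology(raw)
        assert out.frame.loc[0, "Weight"] == 21.5
        assert out.frame.loc[0, "mass"] == 3.3

    def test_unknown_sex_label_marked_missing(self):
        raw = make_raw([{"Genotype": "a", "Sex": "hermaphrodite"}])
        out = unify_terminology(raw)
        assert out.frame["Sex"].isna().all()


class TestBuildPhenlist:
    def test_clean_dataset_logs_no_removals(self):
        pl = make_phenlist(ROWS)
        assert len(pl) == 4
        assert not any("dropped" in e for e in pl.cleaning_log)

    def test_extra_genotypes_dropped_and_counted(self):
        rows = ROWS + [
            {"Genotype": g, "Sex": "male", "Batch": "d3", "Weight": 1.0, "mass": 1.0}
            for g in ("wildtype", "het", "other", "x", "y")
        ]
        pl = make_phenlist(rows)
        assert len(pl) == 4
        assert any("dropped 5 rows" in e for e in pl.cleaning_log)

    def test_row_conservation(self):
        rows = ROWS + [
            {"Genotype": "mutant", "Sex": None, "Batch": "d9", "Weight": 1.0, "mass": 1.0},
            {"Genotype": "stray", "Sex": "male", "Batch": "d9", "Weight": 1.0, "mass": 1.0},
        ]
        pl = make_phenlist(rows)
        dropped = sum(
            int(e.split()[1]) for e in pl.cleaning_log if e.startswith("dropped")
        )
        assert len(rows) == len(pl) + dropped

    def test_idempotent_rebuild(self, tmp_path):
        pl = make_phenlist(ROWS)
        path = tmp_path / "clean.csv"
        pl.frame.to_csv(path, index=False)
        rebuilt = build_phenlist(load_table(path), "mutant", "control")
        assert len(rebuilt) == len(pl)
        assert not any("dropped" in e for e in rebuilt.cleaning_log)
        pd.testing.assert_frame_equal(
            rebuilt.frame.astype(str), pl.frame.astype(str), check_dtype=False
        )

    def test_absent_test_genotype_rejected(self):
        with pytest.raises(ConfigurationError):
            make_phenlist(ROWS, test="nonexistent")

    def test_missing_weight_does_not_drop_rows(self):
        rows = [dict(r) for r in ROWS]
        rows[0]["Weight"] = None
        pl = make_phenlist(rows)
        assert len(pl) == 4

    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 3, 4], "continuous"), (["a", "b", "a", "c"], "categorical")],
    )
    def test_variable_kind_inference(self, values, expected):
        rows = [
            {"Genotype": g, "Sex": s, "v": v}
            for (g, s), v in zip(
                [("control", "male"), ("control", "female"), ("mutant", "male"), ("mutant", "female")],
                values,
            )
        ]
        pl = make_phenlist(rows)
        assert pl.variables["v"] == expected

    def test_explicit_kind_override_wins(self):
        pl = make_phenlist(ROWS, variable_kinds={"mass": "categorical"})
        assert pl.variables["mass"] == "categorical"


class TestDatasetSummary:
    def test_single_row_dataset(self):
        rows = [
            {"Genotype": "control", "Sex": "male", "Batch": "b", "mass": 1.0},
            {"Genotype": "mutant", "Sex": "male", "Batch": "b", "mass": 2.0},
        ]
        s = dataset_summary(make_phenlist(rows), "mass")
        assert s.loc[("control", "male"), "n_animals"] == 1
        assert s.loc[("control", "male"), "n_batches"] == 1

    def test_balanced_design_batch_counts(self):
        spec = SyntheticSpec(
            n_control={"male": 8, "female": 8}, n_test={"male": 8, "female": 8},
            n_batches=4, n_test_batches=4, n_control_only_batches=0,
            design="concurrent_tf", seed=2,
        )
        pl, _ = synthetic_phenlist(spec)
        s = dataset_summary(pl, "response")
        assert (s["n_batches"] == 4).all()

    def test_mimics_printed_screen_characteristics(self):
        # multi-batch screen shaped like the rat cardiac study's count table
        spec = SyntheticSpec(
            n_control={"male": 235, "female": 58}, n_test={"male": 19, "female": 20},
            cell_batches={("control", "male"): 86, ("control", "female"): 9,
                          ("mutant", "male"): 2, ("mutant", "female"): 2},
            seed=3,
        )
        pl, _ = synthetic_phenlist(spec)
        s = dataset_summary(pl, "response")
        assert s.loc[("control", "male")].tolist() == [235, 86, 0]
        assert s.loc[("control", "female")].tolist() == [58, 9, 0]
        assert s.loc[("mutant", "male")].tolist() == [19, 2, 0]
        assert s.loc[("mutant", "female")].tolist() == [20, 2, 0]

    def test_counts_conserve_total(self, mm_phenlist):
        pl, _ = mm_phenlist
        s = dataset_summary(pl, "response")
        assert s["n_animals"].sum() == len(pl)

    def test_unknown_variable(self, mm_phenlist):
        pl, _ = mm_phenlist
        with pytest.raises(KeyError):
            dataset_summary(pl, "nope")
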