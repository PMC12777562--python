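import numpy as np
import pandas as pd
import pytest

from doorstat import (
    DoorCategoryScheme,
    DoorTable,
    GradingKey,
    expand,
    load_fixture,
    read_count_table,
    read_patient_table,
    tabulate,
)
from doorstat.datamodel import PatientDataset, SchemaError, ValidationError


SCHEME5 = DoorCategoryScheme(
    ("Alive with no events", "Alive with 1 event", "Alive with 2 events",
     "Alive with 3 events", "Death")
)


def write_csv(path, rows, header="id,arm,door_category"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadPatientTable:
    def test_minimal_two_per_arm(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,1", "b,experimental,2", "c,control,1", "d,control,2"])
        data = read_patient_table(f, DoorCategoryScheme.generic(2))
        assert (data.n1, data.n2) == (2, 2)

    def test_out_of_range_category_names_row(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,1", "b,control,6"])
        with pytest.raises(SchemaError, match="row 1"):
            read_patient_table(f, DoorCategoryScheme.generic(5))

    def test_unknown_label_rejected(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,Death", "b,control,Resurrected"])
        with pytest.raises(SchemaError, match="Resurrected"):
            read_patient_table(f, SCHEME5)

    def test_labels_coerced_to_indices(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,Death", "b,control,Alive with no events"])
        data = read_patient_table(f, SCHEME5)
        assert list(data.df["category"]) == [5.0, 1.0]

    def test_duplicate_id_rejected(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,1", "a,control,2"])
        with pytest.raises(ValidationError, match="duplicate"):
            read_patient_table(f, DoorCategoryScheme.generic(2))

    def test_empty_arm_rejected(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,1", "b,experimental,2"])
        with pytest.raises(ValidationError, match="empty"):
            read_patient_table(f, DoorCategoryScheme.generic(2))

    def test_missing_category_kept_but_warned(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(f, ["a,experimental,1", "b,control,2", "c,control,"])
        with pytest.warns(UserWarning, match="missing DOOR category"):
            data = read_patient_table(f, DoorCategoryScheme.generic(2))
        assert len(data.df) == 3 and data.n2 == 1

    def test_component_flags_preserved_with_missing(self, tmp_path):
        f = tmp_path / "p.csv"
        write_csv(
            f,
            ["a,experimental,1,0", "b,control,2,", "c,control,1,1"],
            header="id,arm,door_category,death",
        )
        data = read_patient_table(f, DoorCategoryScheme.generic(2), components=("death",))
        assert data.df["death"].isna().sum() == 1
        assert data.components == ("death",)


class TestTabulateExpand:
    def test_dori05_counts(self, dori05):
        pats = load_fixture("dori05_patients")
        assert (pats.n1, pats.n2) == (374, 374)
        assert np.array_equal(tabulate(pats).counts, dori05.counts)

    def test_single_patient_arms_one_hot(self):
        df = pd.DataFrame(
            {"id": ["a", "b"], "arm": ["experimental", "control"], "category": [2.0, 3.0]}
        )
        table = tabulate(PatientDataset(df, DoorCategoryScheme.generic(3)))
        assert np.array_equal(table.counts, [[0, 1, 0], [0, 0, 1]])

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_table

        table = random_table(rng)
        assert np.array_equal(tabulate(expand(table)).counts, table.counts)


class TestFixtures:
    def test_door_table_matches_published_distribution(self, dori05):
        assert np.array_equal(dori05.counts, [[263, 93, 16, 1, 1], [253, 111, 9, 1, 0]])
        assert dori05.n1 == dori05.n2 == 374

    def test_component_tables(self, dori05_components):
        c = dori05_components
        assert np.array_equal(c["Absence of clinical success"].counts, [[293, 81], [261, 113]])
        assert np.array_equal(c["Infectious complications"].counts, [[351, 23], [369, 5]])
        assert np.array_equal(c["Non-fatal SAEs"].counts, [[349, 25], [360, 14]])
        assert np.array_equal(c["Death"].counts, [[373, 1], [374, 0]])

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            load_fixture("nope")


class TestCountTableIO:
    def test_roundtrip(self, tmp_path, dori05):
        f = tmp_path / "t.csv"
        dori05.to_csv(f)
        back = read_count_table(f)
        assert np.array_equal(back.counts, dori05.counts)
        assert back.arms == dori05.arms
        assert back.scheme.labels == dori05.scheme.labels

    def test_arm_selection_reorders(self, tmp_path, dori05):
        f = tmp_path / "t.csv"
        dori05.to_csv(f)
        back = read_count_table(f, arms=("levofloxacin", "doripenem"))
        assert np.array_equal(back.counts, dori05.counts[::-1])


class TestTypes:
    def test_scheme_needs_two_unique_labels(self):
        with pytest.raises(ValidationError):
            DoorCategoryScheme(("only",))
        with pytest.raises(ValidationError):
            DoorCategoryScheme(("a", "a"))

    def test_table_rejects_empty_arm(self):
        with pytest.raises(ValidationError):
            DoorTable(np.array([[0, 0], [1, 2]]))

    def test_grading_key_pins_endpoints(self):
        with pytest.raises(ValidationError):
            GradingKey((90, 50, 0))
        with pytest.raises(ValidationError):
            GradingKey((100, 50, 10))
        with pytest.raises(ValidationError):
            GradingKey((100, 150, 0))

    def test_non_monotone_key_flagged_not_rejected(self):
        with pytest.warns(UserWarning, match="not monotone"):
            key = GradingKey((100, 30, 60, 0))
        assert not key.is_monotone

    def test_negative_weight_rejected(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "arm": ["experimental", "control"],
                "category": [1.0, 2.0],
                "weight": [1.0, -0.5],
            }
        )
        with pytest.raises(ValidationError, match="weights"):
            PatientDataset(df, DoorCategoryScheme.generic(2))

    def test_effect_estimate_bracket_check(self):
        from doorstat import EffectEstimate

        with pytest.raises(ValueError):
            EffectEstimate(0.5, 0.6, 0.7)
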