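"""Cell/clinical table parsing, validation and round-tripping."""

import numpy as np
import pandas as pd
import pytest

import ctcstrat as cs
from ctcstrat.errors import SchemaError, TableParseError, ValidationError
from ctcstrat.vocab import FEATURE_NAMES, CellClass


def _toy_features(scale=1.0):
    f = {}
    for name in FEATURE_NAMES:
        if name.startswith(("circularity_", "circularityOV_")):
            f[name] = 0.8
        elif name.startswith("mean_intensity_bgsub"):
            f[name] = 50.0 * scale
        elif name.startswith(("mean_intensity", "max_intensity")):
            f[name] = 100.0 * scale
        else:
            f[name] = 10.0 * scale
    return f


def _toy_cells_df(rows):
    out = []
    for pid, cid, cls, feats in rows:
        row = {"patient_id": pid, "cell_id": cid, "cell_class": cls}
        row.update(feats)
        out.append(row)
    return pd.DataFrame(out)


class TestReadCellTable:
    def test_identity_parse_of_three_classes(self, tmp_path):
        df = _toy_cells_df([
            ("P1", "c1", "eCTC", _toy_features()),
            ("P1", "c2", "CD45pos", _toy_features()),
            ("P2", "c1", "other", _toy_features()),
        ])
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        cells = cs.read_cell_table(path)
        assert [c.cell_class for c in cells] == [
            CellClass.ECTC, CellClass.CD45POS, CellClass.OTHER
        ]
        assert cells[0].features["circularity_brightfield"] == 0.8

    def test_missing_column_names_the_column(self, tmp_path):
        df = _toy_cells_df([("P1", "c1", "eCTC", _toy_features())])
        df = df.drop(columns=["diameter_apc"])
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="diameter_apc"):
            cs.read_cell_table(path)

    def test_non_numeric_feature_reports_row(self, tmp_path):
        df = _toy_cells_df([
            ("P1", "c1", "eCTC", _toy_features()),
            ("P1", "c2", "eCTC", {**_toy_features(), "perimeter_pe": "oops"}),
        ])
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TableParseError, match="row 3"):
            cs.read_cell_table(path)

    def test_unknown_class_label_rejected(self, tmp_path):
        df = _toy_cells_df([("P1", "c1", "mystery", _toy_features())])
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="mystery"):
            cs.read_cell_table(path)

    def test_circularity_above_one_lists_offending_cell(self, tmp_path):
        bad = {**_toy_features(), "circularity_fitc": 1.3}
        df = _toy_cells_df([("P1", "c1", "eCTC", _toy_features()),
                            ("P1", "c9", "eCTC", bad)])
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="P1/c9"):
            cs.read_cell_table(path)

    def test_bgsub_above_mean_intensity_rejected(self, tmp_path):
        bad = {**_toy_features(), "mean_intensity_bgsub_pe": 150.0}
        df = _toy_cells_df([("P1", "c1", "eCTC", bad)])
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="mean_intensity_bgsub_pe"):
            cs.read_cell_table(path)

    def test_extra_columns_preserved(self, tmp_path):
        df = _toy_cells_df([("P1", "c1", "eCTC", _toy_features())])
        df["note"] = "keep-me"
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        cells = cs.read_cell_table(path)
        assert cells[0].extra["note"] == "keep-me"


class TestClinicalTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "clinical.csv"
        pd.DataFrame(rows, columns=["patient_id", "os_months", "os_event", "bone_met"]
                     ).to_csv(path, index=False)
        return path

    @pytest.mark.parametrize(
        "os_months,event,expected",
        [
            (43.0, True, True),     # survived past the horizon
            (15.0, True, False),    # died before it
            (20.0, False, None),    # censored before it: indeterminate
            (35.0, False, True),    # censored after it: still known > 30
        ],
    )
    def test_os_class_dichotomization(self, tmp_path, os_months, event, expected):
        path = self._write(tmp_path, [("P1", os_months, event, True)])
        (rec,) = cs.read_clinical_table(path)
        assert rec.os_class is expected
        assert rec.os_indeterminate is (expected is None)

    def test_negative_os_months_rejected(self, tmp_path):
        path = self._write(tmp_path, [("P1", -1.0, True, False)])
        with pytest.raises(ValidationError, match="negative os_months"):
            cs.read_clinical_table(path)

    def test_duplicate_patient_rejected(self, tmp_path):
        path = self._write(tmp_path, [("P1", 10, True, False), ("P1", 12, True, False)])
        with pytest.raises(ValidationError, match="duplicate"):
            cs.read_clinical_table(path)


class TestAssembleAndRoundTrip:
    def test_orphan_cells_rejected(self):
        cells = [cs.CellRecord("X99", "c1", CellClass.ECTC, _toy_features())]
        clinical = [cs.ClinicalRecord("P1", 10.0, True, False)]
        with pytest.raises(ValidationError, match="X99"):
            cs.assemble_cohort(cells, clinical)

    def test_duplicate_cell_id_rejected(self):
        cells = [cs.CellRecord("P1", "c1", CellClass.ECTC, _toy_features())] * 2
        clinical = [cs.ClinicalRecord("P1", 10.0, True, False)]
        with pytest.raises(ValidationError, match="duplicate cell"):
            cs.assemble_cohort(cells, clinical)

    def test_zero_cell_patient_retained(self):
        cells = [cs.CellRecord("P1", "c1", CellClass.ECTC, _toy_features())]
        clinical = [cs.ClinicalRecord("P1", 10.0, True, False),
                    cs.ClinicalRecord("P2", 40.0, False, True)]
        cohort = cs.assemble_cohort(cells, clinical)
        counts = cohort.cell_counts()
        assert counts.loc["P2", "total_cells"] == 0

    def test_write_then_read_is_identity(self, tmp_path, small_cohort):
        cs.write_cohort(small_cohort, tmp_path)
        back = cs.read_cohort(tmp_path)
        assert len(back.cells) == len(small_cohort.cells)
        for a, b in zip(small_cohort.cells, back.cells):
            assert (a.patient_id, a.cell_id, a.cell_class) == (
                b.patient_id, b.cell_id, b.cell_class)
            for k in FEATURE_NAMES:
                assert a.features[k] == pytest.approx(b.features[k], rel=0, abs=0)
        for a, b in zip(small_cohort.clinical, back.clinical):
            assert (a.patient_id, a.os_months, a.os_event, a.bone_met) == (
                b.patient_id, b.os_months, b.os_event, b.bone_met)
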