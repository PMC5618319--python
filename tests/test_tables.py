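"""Bucket-table I/O, label cleaning and report writing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcaplanes import (
    FeatureKey,
    StrainReport,
    TableFormatError,
    UniqueFeatureRecord,
    clean_labels,
    read_bucket_table,
    read_report_csv,
    write_bucket_table,
    write_report,
)
from pcaplanes.tables import parse_bucket_header

from conftest import make_table


class TestReadBucketTable:
    def test_vendor_txt_headers(self, tmp_path):
        """Vendor-style 'Bucket_<rt>min_<mz>mz' headers parse into (rt, mz) keys."""
        p = tmp_path / "buckets.txt"
        p.write_text(
            "name\tBucket_2.50min_301.1000mz\tBucket_9.65min_1185.7445mz\n"
            "A\t1.0\t2.0\nB\t0.0\t3.0\nC\t4.0\t\n"
        )
        t = read_bucket_table(p, dialect="vendor_txt")
        assert t.features == [
            FeatureKey(rt=2.50, mz=301.1000),
            FeatureKey(rt=9.65, mz=1185.7445),
        ]
        assert t.strain_ids == ["A", "B", "C"]
        # missing cell becomes 0 (dense absence encoding)
        assert t.values[2, 1] == 0.0

    @pytest.mark.parametrize(
        "header,rt,mz",
        [
            ("Bucket_2.50min_301.1000mz", 2.50, 301.1000),
            ("9.65min : 1185.7445 m/z", 9.65, 1185.7445),
            ("2.5_301.1", 2.5, 301.1),  # untagged fallback: first two floats
        ],
    )
    def test_header_grammar_is_permissive(self, header, rt, mz):
        assert parse_bucket_header(header) == FeatureKey(rt=rt, mz=mz)

    def test_unparseable_header_names_column(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("name\tnonsense\nA\t1.0\n")
        with pytest.raises(TableFormatError, match="nonsense"):
            read_bucket_table(p, dialect="vendor_txt")

    def test_duplicate_strain_label_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("name\tBucket_2.50min_301.1000mz\nA\t1.0\nA\t2.0\n")
        with pytest.raises(TableFormatError, match="duplicate"):
            read_bucket_table(p, dialect="vendor_txt")

    def test_empty_rows_valid_header(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("name\tBucket_2.50min_301.1000mz\n")
        t = read_bucket_table(p, dialect="vendor_txt")
        assert t.n_strains == 0 and t.n_features == 1
        assert t.meta.get("empty") is True

    @pytest.mark.parametrize("dialect", ["vendor_txt", "wide_csv", "long_csv"])
    def test_round_trip_reproduces_matrix_exactly(self, dialect, tmp_path, rng):
        t = make_table(rng.lognormal(10, 2, (4, 6)))
        path = tmp_path / "t.csv"
        write_bucket_table(t, path, dialect=dialect)
        back = read_bucket_table(path, dialect=dialect)
        assert back.strain_ids == t.strain_ids
        assert back.features == t.features
        np.testing.assert_array_equal(back.values, t.values)


class TestBucketTableInvariants:
    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_table([[1.0, -0.5]])

    def test_shape_mismatch_rejected(self):
        from pcaplanes import BucketTable

        with pytest.raises(ValueError, match="shape"):
            BucketTable(
                strain_ids=["A"],
                features=[FeatureKey(rt=1, mz=100)],
                values=np.ones((2, 1)),
            )

    def test_feature_key_requires_positive_coordinates(self):
        with pytest.raises(ValueError):
            FeatureKey(rt=-1.0, mz=100.0)


class TestCleanLabels:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (["/data/ACT-0499_01.d"], ["ACT_0499_01"]),
            (["a", "a"], ["a", "a_2"]),
            (["  x.mzML "], ["x"]),
            (["C:\\runs\\s1.d", "s1"], ["s1", "s1_2"]),
        ],
    )
    def test_examples(self, raw, expected):
        assert clean_labels(raw) == expected

    @given(st.lists(st.text(max_size=30), min_size=1, max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent_and_unique(self, raw):
        once = clean_labels(raw)
        assert clean_labels(once) == once
        assert len(set(once)) == len(once)


def _records(n, strain="A", plane=(13, 15)):
    d = np.linspace(1.0, 0.1, n)
    return [
        UniqueFeatureRecord(
            feature=FeatureKey(rt=9.65, mz=1185.7445 + k),
            strain_id=strain,
            plane=plane,
            distance=float(d[k]),
            intensity=1000.0 + k,
            rank=k + 1,
        )
        for k in range(n)
    ]


class TestWriteReport:
    def test_xlsx_one_sheet_per_strain(self, tmp_path):
        """Top-60 style report: one sheet, 60 ranked data rows."""
        openpyxl = pytest.importorskip("openpyxl")
        rep = StrainReport(strain_id="ACT_0499", plane=(13, 15), records=_records(60))
        path = write_report([rep], tmp_path / "r.xlsx", format="xlsx")
        wb = openpyxl.load_workbook(path)
        assert wb.sheetnames == ["ACT_0499"]
        assert wb["ACT_0499"].max_row == 61  # header + 60

    def test_xlsx_empty_report_has_header_only(self, tmp_path):
        openpyxl = pytest.importorskip("openpyxl")
        reps = [
            StrainReport(strain_id="A", plane=(1, 2), records=[]),
            StrainReport(strain_id="B", plane=(1, 2), records=_records(3, strain="B")),
        ]
        wb = openpyxl.load_workbook(write_report(reps, tmp_path / "r.xlsx"))
        assert wb["A"].max_row == 1

    def test_sheet_names_truncated_and_deduplicated(self, tmp_path):
        openpyxl = pytest.importorskip("openpyxl")
        long_a = "Streptomyces_sp_very_long_identifier_one"
        long_b = "Streptomyces_sp_very_long_identifier_two"
        reps = [StrainReport(strain_id=s, plane=(1, 2), records=[]) for s in (long_a, long_b)]
        with pytest.warns(UserWarning, match="collision"):
            wb = openpyxl.load_workbook(write_report(reps, tmp_path / "r.xlsx"))
        assert len(set(wb.sheetnames)) == 2
        assert all(len(s) <= 31 for s in wb.sheetnames)

    def test_csv_round_trip_to_six_decimals(self, tmp_path):
        reps = [StrainReport(strain_id="A", plane=(13, 15), records=_records(5))]
        path = write_report(reps, tmp_path / "r.csv", format="csv")
        back = read_report_csv(path)
        assert len(back) == 1 and len(back[0].records) == 5
        for orig, rec in zip(reps[0].records, back[0].records):
            assert rec.rank == orig.rank and rec.plane == orig.plane
            assert rec.feature.mz == pytest.approx(orig.feature.mz, abs=1e-6)
            assert rec.distance == pytest.approx(orig.distance, abs=1e-6)
            assert rec.intensity == pytest.approx(orig.intensity, abs=1e-6)

    def test_records_must_be_distance_sorted(self):
        recs = _records(3)
        recs.reverse()
        with pytest.raises(ValueError, match="non-increasing"):
            StrainReport(strain_id="A", plane=(1, 2), records=recs)

    def test_empty_report_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_report([], tmp_path / "r.csv", format="csv")
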