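import numpy as np
import pandas as pd
import pytest

from graminet.core import (
    AlignmentError,
    CountTable,
    DistanceMatrix,
    SampleTable,
    SchemaError,
    ValidationError,
    align_bundle,
    align_pair,
    read_count_table,
    read_sample_frame,
)
from graminet.simulate import GeneratorConfig, generate_landscape


class TestCountTableIO:
    def test_identity_round_trip(self, tmp_path, toy_table):
        path = tmp_path / "t.tsv"
        toy_table.write(path)
        back = read_count_table(path, "bacteria")
        assert back.samples == toy_table.samples
        assert back.taxa == toy_table.taxa
        np.testing.assert_array_equal(back.counts, toy_table.counts)

    def test_taxa_rows_round_trip_bit_identical(self, tmp_path, toy_table):
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        toy_table.write(p1, orientation="taxa_rows")
        back = read_count_table(p1, "bacteria", orientation="taxa_rows")
        back.write(p2, orientation="taxa_rows")
        assert p1.read_bytes() == p2.read_bytes()

    def test_3x2_tsv(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\ta\tb\ns1\t1\t2\ns2\t3\t4\ns3\t5\t6\n")
        t = read_count_table(path, "archaea")
        assert t.n_samples == 3 and t.n_taxa == 2

    def test_duplicate_sample_id_errors(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\ta\tb\ns1\t1\t2\ns1\t3\t4\n")
        with pytest.raises(ValidationError):
            read_count_table(path, "archaea")

    def test_negative_cell_errors(self):
        with pytest.raises(ValidationError):
            CountTable(["s1"], ["a"], np.array([[-1]]), "fungi")

    def test_non_numeric_cell_errors(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\ta\tb\ns1\t1\tx\ns2\t3\t4\n")
        with pytest.raises((SchemaError, ValidationError)):
            read_count_table(path, "archaea")

    def test_zero_sum_sample_errors(self):
        with pytest.raises(ValidationError):
            CountTable(["s1", "s2"], ["a"], np.array([[0], [1]]), "fungi")

    def test_unknown_domain_errors(self):
        with pytest.raises(ValidationError):
            CountTable(["s1"], ["a"], np.array([[1]]), "viruses")


class TestSampleFrame:
    def test_cd_out_of_range(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tlatitude\tlongitude\tCD\ns1\t33\t98\t105\n")
        with pytest.raises(ValidationError):
            read_sample_frame(path)

    def test_empty_file_schema_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_sample_frame(path)

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tpH\ns1\t7.0\n")
        with pytest.raises(SchemaError):
            read_sample_frame(path)

    def test_case_insensitive_columns(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("SAMPLE_ID\tLatitude\tLONGITUDE\tph\ns1\t33\t98\t7.0\n")
        frame = read_sample_frame(path)
        assert "pH" in frame.data.columns

    def test_absent_columns_recorded_not_zeroed(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tlatitude\tlongitude\ns1\t33\t98\n")
        frame = read_sample_frame(path)
        assert "CD" in frame.absent
        assert "CD" not in frame.data.columns

    def test_generator_frame_round_trip(self, tmp_path):
        frame = generate_landscape(GeneratorConfig(seed=2))
        path = tmp_path / "frame.tsv"
        frame.write(path)
        back = read_sample_frame(path)
        assert len(back) == 48
        assert set(back.data["grassland_type"]) == {"ASM", "AM", "AS", "TS"}


class TestDistanceMatrix:
    def test_symmetry_enforced(self):
        vals = np.array([[0.0, 1.0], [1.0, 0.0]])
        dm = DistanceMatrix(["a", "b"], vals, "test")
        assert dm.values[0, 1] == dm.values[1, 0]

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]), "test")

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "test")

    def test_round_trip(self, tmp_path):
        from graminet.core import read_distance_matrix

        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float), "test")
        path = tmp_path / "dm.tsv"
        dm.write(path)
        back = read_distance_matrix(path, "test")
        np.testing.assert_allclose(back.values, dm.values)

    def test_condensed_order_matches_squareform(self):
        from scipy.spatial.distance import squareform

        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dm = DistanceMatrix(["a", "b", "c"], vals, "test")
        np.testing.assert_array_equal(dm.condensed(), squareform(vals))


class TestAlignBundle:
    def _table(self, samples, domain="archaea"):
        rng = np.random.default_rng(0)
        return CountTable(samples, ["a", "b"],
                          rng.integers(1, 9, (len(samples), 2)), domain)

    def _frame(self, samples):
        data = pd.DataFrame(
            {"latitude": 33.0, "longitude": 98.0},
            index=pd.Index(samples, name="sample_id"),
        )
        return SampleTable(data)

    def test_intersection(self):
        b = align_bundle(
            [self._table(["A", "B", "C"]), self._table(["B", "C", "D"], "fungi")],
            self._frame(["A", "B", "C", "D"]),
        )
        assert b.samples == ["B", "C"]
        assert b.dropped["archaea"] == ["A"]

    def test_lexicographic_order(self):
        b = align_bundle([self._table(["C", "A", "B"])], self._frame(["B", "C", "A"]))
        assert b.samples == ["A", "B", "C"]

    def test_idempotent(self):
        b = align_bundle(
            [self._table(["A", "B", "C"]), self._table(["B", "C", "D"], "fungi")],
            self._frame(["A", "B", "C", "D"]),
        )
        b2 = align_bundle(list(b.tables.values()), b.frame)
        assert b2.samples == b.samples
        for dom in b.tables:
            np.testing.assert_array_equal(b2.tables[dom].counts, b.tables[dom].counts)

    def test_disjoint_errors(self):
        with pytest.raises(AlignmentError):
            align_bundle([self._table(["A", "B"])], self._frame(["C", "D"]))

    def test_per_domain_sample_loss(self):
        # prokaryote table covers all 48 samples, the fungal table only 41:
        # per-domain alignment keeps each analysis on its largest sample set
        samples48 = [f"s{i:02d}" for i in range(48)]
        samples41 = samples48[:41]
        frame = self._frame(samples48)
        t16s = self._table(samples48, "bacteria")
        tits = self._table(samples41, "fungi")
        b16, f16 = align_pair(t16s, frame)
        bits, fits = align_pair(tits, frame)
        assert b16.n_samples == 48
        assert bits.n_samples == 41
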