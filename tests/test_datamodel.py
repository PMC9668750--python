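"""Tests for data types, readers/writers, QC filters and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbmap.datamodel import (
    CountMatrix,
    FeatureMatrix,
    FormatError,
    ObservationMeta,
    SpatialCoordinates,
    mirror_x,
    normalize_log1p_cpm,
    qc_filter_cells,
    qc_filter_genes,
    qc_filter_spatial_barcodes,
    read_dense_counts,
    read_mtx_triplet,
    read_scores_table,
    read_spatial_positions,
    write_mtx_triplet,
    write_scores_table,
)
from perturbmap.spatial import BarcodeScore


def write_triplet(tmp_path, header_shape, entries, genes, barcodes):
    mtx = tmp_path / "matrix.mtx"
    lines = ["%%MatrixMarket matrix coordinate integer general"]
    lines.append(f"{header_shape[0]} {header_shape[1]} {len(entries)}")
    lines += [f"{i} {j} {v}" for i, j, v in entries]
    mtx.write_text("\n".join(lines) + "\n")
    (tmp_path / "features.tsv").write_text("".join(f"{g}\n" for g in genes))
    (tmp_path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))
    return mtx, tmp_path / "features.tsv", tmp_path / "barcodes.tsv"


class TestReadMtxTriplet:
    def test_toy_triplet_roundtrips_entries(self, tmp_path):
        paths = write_triplet(
            tmp_path, (3, 2), [(1, 1, 5), (3, 2, 1)], ["g1", "g2", "g3"], ["b1", "b2"]
        )
        cm = read_mtx_triplet(*paths)
        expected = np.zeros((3, 2), int)
        expected[0, 0] = 5
        expected[2, 1] = 1
        assert np.array_equal(cm.values, expected)
        assert cm.gene_ids == ["g1", "g2", "g3"]
        assert cm.barcodes == ["b1", "b2"]

    def test_empty_matrix_keeps_declared_shape(self, tmp_path):
        paths = write_triplet(tmp_path, (3, 2), [], ["g1", "g2", "g3"], ["b1", "b2"])
        cm = read_mtx_triplet(*paths)
        assert cm.values.shape == (3, 2)
        assert cm.values.sum() == 0

    def test_barcode_count_mismatch_names_file(self, tmp_path):
        paths = write_triplet(tmp_path, (3, 3), [(1, 1, 2)], ["g1", "g2", "g3"], ["b1", "b2"])
        with pytest.raises(FormatError, match="barcodes"):
            read_mtx_triplet(*paths)

    def test_feature_count_mismatch_names_file(self, tmp_path):
        paths = write_triplet(tmp_path, (4, 2), [(1, 1, 2)], ["g1", "g2"], ["b1", "b2"])
        with pytest.raises(FormatError, match="features"):
            read_mtx_triplet(*paths)

    def test_non_integer_entries_rejected(self, tmp_path):
        mtx = tmp_path / "m.mtx"
        mtx.write_text(
            "%%MatrixMarket matrix coordinate real general\n2 2 1\n1 1 2.5\n"
        )
        (tmp_path / "f.tsv").write_text("g1\ng2\n")
        (tmp_path / "b.tsv").write_text("b1\nb2\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_mtx_triplet(mtx, tmp_path / "f.tsv", tmp_path / "b.tsv")

    def test_write_read_roundtrip(self, tmp_path, toy_counts):
        write_mtx_triplet(toy_counts, tmp_path)
        back = read_mtx_triplet(
            tmp_path / "matrix.mtx", tmp_path / "features.tsv", tmp_path / "barcodes.tsv"
        )
        assert np.array_equal(back.values, toy_counts.values)
        assert back.gene_ids == toy_counts.gene_ids
        assert back.barcodes == toy_counts.barcodes


class TestReadDense:
    def test_roundtrip(self, tmp_path, toy_counts):
        frame = pd.DataFrame(
            toy_counts.values, index=toy_counts.gene_ids, columns=toy_counts.barcodes
        )
        path = tmp_path / "counts.tsv"
        frame.to_csv(path, sep="\t")
        cm = read_dense_counts(path)
        assert np.array_equal(cm.values, toy_counts.values)


class TestCountMatrixInvariants:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(np.array([[-1]]), ["g"], ["b"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(np.ones((2, 2), int), ["g1"], ["b1", "b2"])

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(np.ones((1, 2), int), ["g"], ["b", "b"])

    def test_duplicate_genes_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate gene"):
            cm = CountMatrix(np.ones((2, 1), int), ["g", "g"], ["b"])
        assert cm.gene_ids == ["g", "g-1"]


class TestReadSpatialPositions:
    def write(self, tmp_path, rows):
        path = tmp_path / "positions.tsv"
        lines = ["barcode\tx\ty\tsection\tcondition"] + rows
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_four_rows_four_records(self, tmp_path):
        path = self.write(
            tmp_path,
            [f"b{i}\t{i}.0\t{i}.5\ts1\tA" for i in range(4)],
        )
        coords, cond = read_spatial_positions(path)
        assert len(coords.barcodes) == 4
        assert list(cond) == ["A"] * 4

    def test_unknown_barcode_dropped_with_warning(self, tmp_path, toy_counts, caplog):
        path = self.write(
            tmp_path,
            ["b1\t0\t0\ts\tA", "b2\t1\t0\ts\tA", "b3\t0\t1\ts\tB", "zz\t9\t9\ts\tB"],
        )
        with caplog.at_level("WARNING"):
            coords, _ = read_spatial_positions(path, toy_counts)
        assert coords.barcodes == ["b1", "b2", "b3"]
        assert any("absent" in r.message for r in caplog.records)

    def test_duplicate_barcode_raises(self, tmp_path):
        path = self.write(tmp_path, ["b1\t0\t0\ts\tA", "b1\t1\t1\ts\tB"])
        with pytest.raises(FormatError, match="duplicated"):
            read_spatial_positions(path)

    def test_missing_coordinate_raises(self, tmp_path):
        path = self.write(tmp_path, ["b1\t\t0\ts\tA"])
        with pytest.raises(FormatError, match="coordinate"):
            read_spatial_positions(path)


def meta_for(counts, n_genes=None, mito=None, condition="A"):
    n = counts.n_obs
    return ObservationMeta(
        pd.DataFrame(
            {
                "condition": [condition] * n,
                "n_genes_detected": n_genes if n_genes is not None else [999] * n,
                "mito_fraction": mito if mito is not None else [0.0] * n,
            },
            index=counts.barcodes,
        )
    )


class TestQcFilterCells:
    def test_low_gene_cell_removed(self, toy_counts):
        meta = meta_for(toy_counts, n_genes=[150, 300, 300, 300])
        out, _ = qc_filter_cells(toy_counts, meta)
        assert out.barcodes == ["b2", "b3", "b4"]

    def test_boundary_values_retained(self, toy_counts):
        meta = meta_for(toy_counts, n_genes=[200] * 4, mito=[0.05] * 4)
        out, _ = qc_filter_cells(toy_counts, meta)
        assert out.barcodes == toy_counts.barcodes

    def test_high_mito_removed(self, toy_counts):
        meta = meta_for(toy_counts, mito=[0.051, 0.0, 0.0, 0.0])
        out, _ = qc_filter_cells(toy_counts, meta)
        assert out.barcodes == ["b2", "b3", "b4"]

    def test_compliant_input_is_identity(self, toy_counts):
        meta = meta_for(toy_counts)
        out, out_meta = qc_filter_cells(toy_counts, meta)
        assert out.barcodes == toy_counts.barcodes
        assert np.array_equal(out.values, toy_counts.values)

    def test_covariates_computed_from_counts_when_absent(self):
        values = np.array([[10, 0], [5, 100], [0, 3]])
        cm = CountMatrix(values, ["mt-co1", "g1", "g2"], ["b1", "b2"])
        meta = ObservationMeta(pd.DataFrame({"condition": ["A", "A"]}, index=["b1", "b2"]))
        out, _ = qc_filter_cells(cm, meta, min_genes=2, max_mito=0.5)
        # b1: 2 genes detected, mito 10/15 -> removed; b2: mito 0/103 -> kept
        assert out.barcodes == ["b2"]

    def test_idempotent(self, toy_counts):
        meta = meta_for(toy_counts, n_genes=[150, 300, 300, 300])
        once, meta1 = qc_filter_cells(toy_counts, meta)
        twice, _ = qc_filter_cells(once, meta1)
        assert twice.barcodes == once.barcodes


class TestQcFilterGenes:
    def test_boundary(self):
        values = np.array([[1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]])
        cm = CountMatrix(values, ["g2cells", "g3cells", "g4cells"], list("abcd"))
        out = qc_filter_genes(cm)
        assert out.gene_ids == ["g3cells", "g4cells"]

    def test_zero_threshold_is_identity(self, toy_counts):
        out = qc_filter_genes(toy_counts, min_observations=0)
        assert out.gene_ids == toy_counts.gene_ids

    def test_idempotent(self, toy_counts):
        once = qc_filter_genes(toy_counts, 2)
        assert qc_filter_genes(once, 2).gene_ids == once.gene_ids


class TestQcFilterSpatial:
    def test_boundary_5000(self):
        values = np.array([[4999, 5000, 6000]])
        cm = CountMatrix(values, ["g"], ["low", "edge", "high"])
        out = qc_filter_spatial_barcodes(cm)
        assert out.barcodes == ["edge", "high"]

    def test_zero_threshold_identity(self, toy_counts):
        assert qc_filter_spatial_barcodes(toy_counts, 0).barcodes == toy_counts.barcodes


class TestFilterOrderIndependence:
    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_cells_then_genes_equals_genes_then_cells(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 4, size=(12, 15))
        cm = CountMatrix(values, [f"g{i}" for i in range(12)], [f"b{i}" for i in range(15)])
        meta = ObservationMeta(
            pd.DataFrame(
                {
                    "condition": "A",
                    "n_genes_detected": rng.integers(0, 12, 15),
                    "mito_fraction": rng.random(15) * 0.1,
                },
                index=cm.barcodes,
            )
        )
        a, _ = qc_filter_cells(cm, meta, min_genes=5, max_mito=0.05)
        a = qc_filter_genes(a, 2)
        b = qc_filter_genes(cm, 2)
        b, _ = qc_filter_cells(b, meta, min_genes=5, max_mito=0.05)
        assert a.barcodes == b.barcodes


class TestNormalize:
    def test_zero_count_maps_to_zero(self, toy_counts):
        fm = normalize_log1p_cpm(toy_counts)
        assert fm.values[toy_counts.values.T == 0].sum() == 0

    def test_single_gene_column_invariant_to_depth(self):
        cm = CountMatrix(np.array([[3, 17]]), ["g"], ["b1", "b2"])
        fm = normalize_log1p_cpm(cm)
        assert np.allclose(fm.values.ravel(), np.log(1 + 1e4))

    def test_hand_computed_two_gene_column(self):
        cm = CountMatrix(np.array([[3], [1]]), ["g1", "g2"], ["b"])
        fm = normalize_log1p_cpm(cm)
        assert fm.values[0, 0] == pytest.approx(np.log(1 + 7500))
        assert fm.values[0, 1] == pytest.approx(np.log(1 + 2500))

    def test_zero_sum_column_names_barcode(self):
        cm = CountMatrix(np.array([[1, 0]]), ["g"], ["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            normalize_log1p_cpm(cm)

    @given(st.integers(1, 50))
    @settings(max_examples=15, deadline=None)
    def test_invariant_to_integer_column_scaling(self, factor):
        rng = np.random.default_rng(factor)
        values = rng.integers(0, 9, (6, 4))
        values[0, :] += 1  # non-zero columns
        cm = CountMatrix(values, [f"g{i}" for i in range(6)], list("abcd"))
        scaled = CountMatrix(values * factor, cm.gene_ids, cm.barcodes)
        assert np.allclose(
            normalize_log1p_cpm(cm).values, normalize_log1p_cpm(scaled).values
        )

    def test_kind_flag(self, toy_counts):
        assert normalize_log1p_cpm(toy_counts).kind == "log_normalized_counts"


class TestMirrorX:
    def test_negative_x_folded(self):
        coords = SpatialCoordinates(
            pd.DataFrame({"x": [-1.2, 0.0, 2.0], "y": [3.0, 0.0, 1.0]}, index=list("abc"))
        )
        out = mirror_x(coords)
        assert list(out.table["x"]) == [1.2, 0.0, 2.0]
        assert list(out.table["y"]) == [3.0, 0.0, 1.0]

    def test_all_positive_identity(self):
        coords = SpatialCoordinates(
            pd.DataFrame({"x": [0.5, 1.0], "y": [0.1, 0.2]}, index=list("ab"))
        )
        assert mirror_x(coords).table[["x", "y"]].equals(coords.table[["x", "y"]])


class TestScoresTable:
    def scores(self):
        return [
            BarcodeScore("b1", 0.75, np.array([0.7, 0.8]), []),
            BarcodeScore("b2", 0.5, np.array([0.4, 0.6]), []),
        ]

    def test_two_unit_table(self, tmp_path):
        path = tmp_path / "scores.tsv"
        write_scores_table(self.scores(), path)
        frame = read_scores_table(path)
        assert len(frame) == 2
        assert list(frame.columns) == ["unit_id", "mean_auc", "n_repeats", "sd_auc"]

    def test_empty_scores_header_only(self, tmp_path):
        path = tmp_path / "scores.tsv"
        write_scores_table([], path)
        frame = read_scores_table(path)
        assert len(frame) == 0

    def test_roundtrip_to_1e6(self, tmp_path):
        path = tmp_path / "scores.tsv"
        scores = self.scores()
        write_scores_table(scores, path)
        frame = read_scores_table(path).set_index("unit_id")
        for s in scores:
            assert frame.at[s.barcode, "mean_auc"] == pytest.approx(s.mean_auc, abs=1e-6)
            assert frame.at[s.barcode, "sd_auc"] == pytest.approx(
                np.std(s.auc_samples), abs=1e-6
            )


class TestFeatureMatrix:
    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureMatrix(np.array([[np.nan]]), ["f"], ["b"])

    def test_bad_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            FeatureMatrix(np.zeros((1, 1)), ["f"], ["b"], kind="bogus")
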