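"""Chaos-game geometry, trajectories, and segment histograms."""

import math

import numpy as np
import pytest

from rpiforest.cgr import (
    POLYGON_VERTICES,
    cgr_histogram_protein,
    cgr_histogram_rna,
    cgr_trajectory_protein,
    cgr_trajectory_rna,
    encode_cgr_protein,
    encode_cgr_rna,
    polygon_vertex,
    segment_index_16,
    segment_index_24,
)
from rpiforest.seqio import MolType, SequenceError, SequenceRecord, TWELVE_GROUP_MAP

from conftest import random_protein, random_rna

# amino acids whose CGR class is vertex 1 under the default partition
_V1_RESIDUE = next(a for a, g in TWELVE_GROUP_MAP.items() if g == 1)


class TestPolygonGeometry:
    def test_vertex_formula_and_unit_circle(self):
        for k in range(1, 13):
            x, y = polygon_vertex(k)
            theta = (k - 1) * math.pi / 6
            assert x == pytest.approx(math.cos(theta), abs=1e-15)
            assert y == pytest.approx(math.sin(theta), abs=1e-15)
            assert math.hypot(x, y) == pytest.approx(1.0, abs=1e-15)

    def test_named_vertices(self):
        assert polygon_vertex(1) == pytest.approx((1, 0))
        assert polygon_vertex(4) == pytest.approx((0, 1), abs=1e-15)
        assert polygon_vertex(7) == pytest.approx((-1, 0), abs=1e-15)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            polygon_vertex(0)
        with pytest.raises(ValueError):
            polygon_vertex(13)


class TestTrajectories:
    def test_protein_single_midpoint(self):
        rec = SequenceRecord("p", _V1_RESIDUE, MolType.protein)
        pts = cgr_trajectory_protein(rec)
        assert pts.tolist() == [[0.5, 0.0]]

    def test_protein_repeated_vertex(self):
        rec = SequenceRecord("p", _V1_RESIDUE * 2, MolType.protein)
        pts = cgr_trajectory_protein(rec)
        assert pts.tolist() == [[0.5, 0.0], [0.75, 0.0]]

    def test_rna_single_midpoint(self):
        pts = cgr_trajectory_rna(SequenceRecord("r", "A", MolType.rna))
        assert pts.tolist() == [[0.25, 0.25]]

    def test_point_count_matches_length(self):
        rng = np.random.default_rng(7)
        rec = random_rna(rng, 57)
        assert len(cgr_trajectory_rna(rec)) == 57

    def test_contraction_bounds(self):
        rng = np.random.default_rng(8)
        prot = random_protein(rng, 300)
        pts = cgr_trajectory_protein(prot)
        assert (np.linalg.norm(pts, axis=1) <= 1 + 1e-12).all()
        rna = random_rna(rng, 300)
        pts = cgr_trajectory_rna(rna)
        assert ((pts >= 0) & (pts <= 1)).all()

    def test_determinism(self):
        rng = np.random.default_rng(9)
        rec = random_protein(rng, 80)
        a = cgr_trajectory_protein(rec)
        b = cgr_trajectory_protein(rec)
        assert np.array_equal(a, b)


class TestSegmentRules:
    @pytest.mark.parametrize("point,expected", [
        ((0.25, 0), 1),    # sector 1, inner
        ((0.5, 0), 2),     # r == 0.5 belongs to the outer band
        ((0, 0.6), 8),     # 90 degrees -> sector 4, outer
    ])
    def test_polygon_segments(self, point, expected):
        assert segment_index_24(point) == expected

    @pytest.mark.parametrize("point,expected", [
        ((0.25, 0.25), 6),
        ((0, 0), 1),
        ((1, 1), 16),      # top/right boundary clamped inward
    ])
    def test_square_segments(self, point, expected):
        assert segment_index_16(point) == expected

    def test_segments_total_on_domain(self):
        rng = np.random.default_rng(10)
        for _ in range(500):
            p = rng.uniform(-1, 1, 2)
            assert 1 <= segment_index_24(p) <= 24
            q = rng.uniform(0, 1, 2)
            assert 1 <= segment_index_16(q) <= 16


def classify_point_24(x: float, y: float) -> int:
    """Independent reference: degrees-based sector, explicit band.

    Angles within 1e-9 degrees of a sector edge are snapped to it, since a
    point mathematically on an edge can fall either side of it after
    atan2 rounding.
    """
    ang = math.degrees(math.atan2(y, x)) % 360.0
    nearest = round(ang / 30.0) * 30.0
    if abs(ang - nearest) < 1e-9:
        ang = nearest % 360.0
    sector = int(ang // 30.0) % 12
    band = 0 if math.sqrt(x * x + y * y) < 0.5 else 1
    return 2 * sector + band + 1


def classify_point_16(x: float, y: float) -> int:
    for r in range(4):
        for c in range(4):
            x_hi = (c + 1) / 4
            y_hi = (r + 1) / 4
            in_x = c / 4 <= x < x_hi or (c == 3 and x == 1.0)
            in_y = r / 4 <= y < y_hi or (r == 3 and y == 1.0)
            if in_x and in_y:
                return 4 * r + c + 1
    raise AssertionError("point outside unit square")


class TestHistograms:
    def test_rna_single_base(self):
        v = encode_cgr_rna(SequenceRecord("r", "A", MolType.rna))
        assert v[5] == 1.0 and v.sum() == 1.0  # segment 6

    def test_protein_single_v1_residue(self):
        # trajectory point (0.5, 0): r = 0.5 -> outer band -> segment 2
        v = encode_cgr_protein(SequenceRecord("p", _V1_RESIDUE, MolType.protein))
        assert v[1] == 1.0

    def test_counts_and_frequency_normalization(self):
        rng = np.random.default_rng(11)
        rec = random_rna(rng, 90)
        h = cgr_histogram_rna(rec)
        assert h.counts.sum() == 90
        assert h.values.sum() == pytest.approx(1.0)

    def test_oracle_per_point_classification(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            prot = random_protein(rng, int(rng.integers(1, 120)))
            h = cgr_histogram_protein(prot)
            expected = np.zeros(24, dtype=int)
            for x, y in cgr_trajectory_protein(prot):
                expected[classify_point_24(x, y) - 1] += 1
            assert np.array_equal(h.counts, expected)

            rna = random_rna(rng, int(rng.integers(1, 120)))
            h = cgr_histogram_rna(rna)
            expected = np.zeros(16, dtype=int)
            for x, y in cgr_trajectory_rna(rna):
                expected[classify_point_16(x, y) - 1] += 1
            assert np.array_equal(h.counts, expected)

    def test_distinct_sequences_distinct_histograms(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(20):
            a = random_rna(rng, 60, "a")
            b = random_rna(rng, 60, "b")
            if a.seq != b.seq and not np.array_equal(
                    encode_cgr_rna(a), encode_cgr_rna(b)):
                hits += 1
        assert hits >= 18  # distinct random sequences almost always differ

    def test_wrong_moltype_rejected(self):
        with pytest.raises(SequenceError):
            cgr_trajectory_rna(SequenceRecord("r", "A", MolType.protein))
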