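from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grdf.fegs import (
    ConeEmbedding,
    PropertyTable,
    PropertyTableError,
    aac,
    build_curve,
    cone_pair,
    cone_vertex,
    curve_descriptor,
    curve_matrix,
    dpc,
    fegs_vector,
    graphical_descriptors,
    order_amino_acids,
)
from grdf.seqio import AA_ALPHABET, AA_INDEX
from grdf.synthetic import gen_property_table

seq_strategy = st.text(alphabet=AA_ALPHABET, min_size=2, max_size=12)


def oracle_curve(seq: str, emb: ConeEmbedding) -> np.ndarray:
    """Literal step-by-step curve construction: vertex point of each residue
    plus prefix pair frequencies times pair points."""
    pts = [np.zeros(3)]
    for i in range(1, len(seq) + 1):
        phi = emb.vertex_points[emb.ranks[AA_INDEX[seq[i - 1]]] - 1]
        pair_sum = np.zeros(3)
        if i > 1:
            prefix = seq[:i]
            for (a, b), cnt in Counter(zip(prefix, prefix[1:])).items():
                psi = emb.pair_points[
                    emb.ranks[AA_INDEX[a]] - 1, emb.ranks[AA_INDEX[b]] - 1
                ]
                pair_sum += (cnt / (i - 1)) * psi
        pts.append(pts[-1] + phi + pair_sum)
    return np.array(pts)


def oracle_matrix(pts: np.ndarray) -> np.ndarray:
    """Brute-force double loop: Euclidean distance over along-curve path length."""
    n = len(pts)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                lo, hi = min(i, j), max(i, j)
                path = sum(
                    np.linalg.norm(pts[k + 1] - pts[k]) for k in range(lo, hi)
                )
                m[i, j] = np.linalg.norm(pts[i] - pts[j]) / path
    return m


class TestPropertyTable:
    def test_shape_and_names_validated(self):
        with pytest.raises(PropertyTableError):
            PropertyTable(names=("a",), values=np.ones((1, 19)))
        with pytest.raises(PropertyTableError):
            PropertyTable(names=("a", "b"), values=np.ones((1, 20)))

    def test_nonfinite_rows_rejected(self):
        vals = np.ones((2, 20))
        vals[1, 3] = np.nan
        with pytest.raises(PropertyTableError, match="non-finite"):
            PropertyTable(names=("a", "b"), values=vals)

    def test_tsv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        small_table.to_tsv(path)
        back = PropertyTable.from_tsv(path)
        assert back.names == small_table.names
        np.testing.assert_allclose(back.values, small_table.values)

    def test_tsv_missing_value_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "\t".join(AA_ALPHABET)
        row = "\t".join(["1.0"] * 19)  # one value short -> NA
        path.write_text(f"idx\t{header}\nr1\t{row}\t\n")
        with pytest.raises(PropertyTableError, match="missing"):
            PropertyTable.from_tsv(path)


class TestConeGeometry:
    def test_ordering_ascending_and_reversed(self):
        vals = np.arange(20, dtype=float)
        assert order_amino_acids(vals) == AA_ALPHABET
        assert order_amino_acids(vals[::-1]) == AA_ALPHABET[::-1]

    def test_ordering_tie_breaks_alphabetically(self):
        vals = np.zeros(20)
        assert order_amino_acids(vals) == AA_ALPHABET
        vals[AA_INDEX["W"]] = -1.0
        vals[AA_INDEX["C"]] = -1.0
        assert order_amino_acids(vals).startswith("CW")

    def test_ordering_rejects_nonfinite(self):
        vals = np.zeros(20)
        vals[0] = np.inf
        with pytest.raises(ValueError):
            order_amino_acids(vals)

    @pytest.mark.parametrize(
        "rank,expected",
        [(20, (1, 0, 1)), (5, (0, 1, 1)), (10, (-1, 0, 1))],
    )
    def test_vertex_worked_values(self, rank, expected):
        np.testing.assert_allclose(cone_vertex(rank), expected, atol=1e-14)

    def test_vertex_rank_bounds(self):
        for bad in (0, 21):
            with pytest.raises(ValueError):
                cone_vertex(bad)

    def test_pair_worked_value_and_identity(self):
        np.testing.assert_allclose(cone_pair(20, 10), (0.5, 0, 1), atol=1e-14)
        for i in (1, 7, 20):
            np.testing.assert_allclose(cone_pair(i, i), cone_vertex(i), atol=1e-14)

    def test_vertex_on_unit_circle_pairs_inside(self):
        for i in range(1, 21):
            v = cone_vertex(i)
            assert v[2] == 1.0
            assert np.isclose(v[0] ** 2 + v[1] ** 2, 1.0)
            for j in range(1, 21):
                p = cone_pair(i, j)
                assert p[2] == 1.0
                if i != j:
                    assert p[0] ** 2 + p[1] ** 2 < 1.0


class TestCurve:
    def test_length_one_sequence_is_vertex_step(self, small_table):
        emb = ConeEmbedding.from_property_row(small_table.values[0])
        curve = build_curve("A", emb)
        np.testing.assert_allclose(curve[0], np.zeros(3))
        np.testing.assert_allclose(
            curve[1], emb.vertex_points[emb.ranks[AA_INDEX["A"]] - 1]
        )

    def test_length_two_hand_evaluation(self, small_table):
        emb = ConeEmbedding.from_property_row(small_table.values[0])
        curve = build_curve("AC", emb)
        phi_a = emb.vertex_points[emb.ranks[AA_INDEX["A"]] - 1]
        phi_c = emb.vertex_points[emb.ranks[AA_INDEX["C"]] - 1]
        psi_ac = emb.pair_points[
            emb.ranks[AA_INDEX["A"]] - 1, emb.ranks[AA_INDEX["C"]] - 1
        ]
        np.testing.assert_allclose(curve[2], phi_a + phi_c + psi_ac, atol=1e-14)

    def test_empty_sequence_rejected(self, small_table):
        emb = ConeEmbedding.from_property_row(small_table.values[0])
        with pytest.raises(ValueError):
            build_curve("", emb)

    @given(seq=seq_strategy, row_seed=st.integers(0, 100))
    def test_curve_matches_stepwise_oracle(self, seq, row_seed):
        row = np.random.default_rng(row_seed).standard_normal(20)
        emb = ConeEmbedding.from_property_row(row)
        np.testing.assert_allclose(
            build_curve(seq, emb), oracle_curve(seq, emb), atol=1e-12
        )


class TestCurveMatrix:
    @given(seq=st.text(alphabet=AA_ALPHABET, min_size=2, max_size=9))
    def test_matches_brute_force_oracle(self, seq):
        emb = ConeEmbedding.from_property_row(
            np.random.default_rng(0).standard_normal(20)
        )
        curve = build_curve(seq, emb)
        m = curve_matrix(curve)
        np.testing.assert_allclose(m, oracle_matrix(curve[1:]), atol=1e-12)
        # bounds and adjacency entries
        assert np.all(m >= 0) and np.all(m <= 1 + 1e-12)
        np.testing.assert_allclose(np.diag(m, 1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0)

    def test_collinear_curve_all_ones_off_diagonal(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.5, 0, 0], [5, 0, 0]], float)
        m = curve_matrix(pts)
        off = m[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-14)

    def test_translation_invariance(self, small_table):
        emb = ConeEmbedding.from_property_row(small_table.values[1])
        curve = build_curve("ACDKLM", emb)
        shifted = curve + np.array([3.0, -2.0, 7.0])
        np.testing.assert_allclose(curve_matrix(curve), curve_matrix(shifted), atol=1e-12)

    def test_degenerate_curve_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [1, 1, 1], [2, 2, 2]], float)
        with pytest.raises(ValueError, match="degenerate"):
            curve_matrix(pts)


class TestCurveDescriptor:
    def test_two_by_two_closed_form(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert curve_descriptor(m, 2) == pytest.approx(0.5)

    def test_zero_matrix(self):
        assert curve_descriptor(np.zeros((4, 4))) == 0.0

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((8, 8))
        m = np.abs(a + a.T)
        np.fill_diagonal(m, 0.0)
        expected = max(np.real(np.roots(np.poly(m))))  # characteristic polynomial
        assert curve_descriptor(m, 8) == pytest.approx(expected / 8, abs=1e-9)

    def test_nonsymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            curve_descriptor(m)


class TestCompositions:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"A": 1.0}),
            (AA_ALPHABET, {a: 0.05 for a in AA_ALPHABET}),
            ("ACCA", {"A": 0.5, "C": 0.5}),
        ],
    )
    def test_aac_worked_examples(self, seq, expected):
        v = aac(seq)
        for a in AA_ALPHABET:
            assert v[AA_INDEX[a]] == pytest.approx(expected.get(a, 0.0))

    def test_dpc_worked_examples(self):
        v = dpc("AA")
        assert v[20 * AA_INDEX["A"] + AA_INDEX["A"]] == 1.0
        assert v.sum() == pytest.approx(1.0)
        v = dpc("ACAC")
        assert v[20 * AA_INDEX["A"] + AA_INDEX["C"]] == pytest.approx(2 / 3)
        assert v[20 * AA_INDEX["C"] + AA_INDEX["A"]] == pytest.approx(1 / 3)

    def test_dpc_needs_length_two(self):
        with pytest.raises(ValueError):
            dpc("A")

    @given(seq=seq_strategy)
    def test_compositions_are_distributions(self, seq):
        assert aac(seq).sum() == pytest.approx(1.0)
        assert np.all(aac(seq) >= 0)
        assert dpc(seq).sum() == pytest.approx(1.0)
        assert np.all(dpc(seq) >= 0)


class TestFegsVector:
    def test_bundled_table_gives_578_dims(self, default_table):
        v = fegs_vector("FLPIIAKLLSGLL", default_table)
        assert v.full.shape == (578,)
        assert v.graphical.shape == (158,)

    def test_k_plus_420_dims(self, small_table):
        assert fegs_vector("FLPIIAKLLSGLL", small_table).full.shape == (423,)
        one = gen_property_table(1, seed=0)
        assert fegs_vector("FLPIIAKLLSGLL", one).full.shape == (421,)

    def test_deterministic(self, small_table):
        a = fegs_vector("KLWKKILKVLK", small_table).full
        b = fegs_vector("KLWKKILKVLK", small_table).full
        np.testing.assert_array_equal(a, b)

    def test_batched_matches_per_property_route(self, small_table):
        seq = "FLPIIAKLLSG"
        g = graphical_descriptors(seq, small_table)
        for k in range(small_table.n_properties):
            emb = ConeEmbedding.from_property_row(small_table.values[k])
            d = curve_descriptor(curve_matrix(build_curve(seq, emb)), len(seq))
            assert g[k] == pytest.approx(d, abs=1e-12)

    def test_order_preserving_row_shift_leaves_descriptor_unchanged(self, small_table):
        """Adding a constant to a property row preserves the ascending order,
        hence the embedding, curve, and descriptor."""
        seq = "ACDKLMNPQR"
        row = small_table.values[0]
        g1 = curve_descriptor(
            curve_matrix(build_curve(seq, ConeEmbedding.from_property_row(row)))
        )
        g2 = curve_descriptor(
            curve_matrix(build_curve(seq, ConeEmbedding.from_property_row(row + 42.0)))
        )
        assert g1 == pytest.approx(g2, abs=1e-12)
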