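"""CGR trajectory, FCGR rasterization and the k-mer equivalence oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcgrcaps.fcgr import (FCGREncoder, InvalidAlphabetError, SequenceRecord,
                           cgr_encode, encode_sequence, fcgr_rasterize,
                           gc_content, kmer_counts, kmer_suffix_cell,
                           normalize_residues, nucleotide_corner)

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestCorners:
    def test_fixed_assignment(self):
        # T upper-right is stated; the rest follow from the clockwise
        # TT, GT, CT, AT sub-square reading within the T quadrant
        assert nucleotide_corner("T") == (1.0, 1.0)
        assert nucleotide_corner("A") == (-1.0, 1.0)
        assert nucleotide_corner("C") == (-1.0, -1.0)
        assert nucleotide_corner("G") == (1.0, -1.0)

    def test_gt_subsquare_is_nearest_the_g_corner(self):
        # the GT cell at N=4 must be the T-quadrant cell closest to G's corner
        row, col = kmer_suffix_cell("GT", 4)
        centers = {(r, c): (-1 + (c + 0.5) / 2, 1 - (r + 0.5) / 2)
                   for r in range(2) for c in range(2, 4)}  # T quadrant cells
        gx, gy = nucleotide_corner("G")
        nearest = min(centers, key=lambda rc: (centers[rc][0] - gx) ** 2
                      + (centers[rc][1] - gy) ** 2)
        assert (row, col) == nearest

    def test_non_canonical_symbol_is_an_error(self):
        with pytest.raises(InvalidAlphabetError, match="N"):
            nucleotide_corner("N")


class TestTrajectory:
    def test_single_t_lands_at_midpoint_of_origin_and_t_corner(self):
        assert np.allclose(cgr_encode("T"), [[0.5, 0.5]])

    def test_catg_worked_example(self):
        # midpoint iteration by hand from (0,0)
        expected = [(-0.5, -0.5), (-0.75, 0.25), (0.125, 0.625), (0.5625, -0.1875)]
        assert np.allclose(cgr_encode("CATG"), expected)

    def test_empty_sequence_gives_empty_trajectory(self):
        assert cgr_encode("").shape == (0, 2)

    @given(dna.filter(lambda s: len(s) > 0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_points_strictly_inside_open_square(self, seq):
        traj = cgr_encode(seq)
        assert np.all(np.abs(traj) < 1.0)
        assert traj.shape == (len(seq), 2)

    def test_determinism(self):
        seq = "ACGTTGCAACGT" * 10
        assert np.array_equal(cgr_encode(seq), cgr_encode(seq))


class TestNormalization:
    def test_case_fold_and_u_mapping(self):
        assert normalize_residues("acgu") == "ACGT"

    def test_strict_policy_names_offender_and_position(self):
        with pytest.raises(InvalidAlphabetError, match=r"'N' at position 2"):
            normalize_residues("ACNGT", "strict")

    def test_skip_policy_drops_bad_characters(self):
        assert normalize_residues("ACNGT", "skip") == "ACGT"

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            normalize_residues("ACGT", "lenient")


class TestRasterize:
    def test_t_quadrant_is_upper_right_at_n2(self):
        img = encode_sequence("T", 2)
        expected = np.zeros((2, 2), dtype=int)
        expected[0, 1] = 1
        assert np.array_equal(img.counts, expected)

    @given(dna, st.integers(min_value=1, max_value=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_count_conservation(self, seq, resolution):
        img = encode_sequence(seq, resolution)
        assert img.counts.sum() == len(seq) == img.total_points
        assert np.all(img.counts >= 0)

    def test_resolution_below_one_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            fcgr_rasterize(np.zeros((0, 2)), 0)

    def test_normalization_modes(self):
        img_raw = encode_sequence("ACGTACGT", 4, "raw")
        per_total = encode_sequence("ACGTACGT", 4, "per_total").as_array()
        per_max = encode_sequence("ACGTACGT", 4, "per_max").as_array()
        assert np.isclose(per_total.sum(), 1.0)
        assert np.isclose(per_max.max(), 1.0)
        assert np.array_equal(img_raw.counts, encode_sequence("ACGTACGT", 4).counts)


class TestKmerCounts:
    @pytest.mark.parametrize("seq,k,expected", [
        ("ACGTACGT", 2, {"AC": 2, "CG": 2, "GT": 2, "TA": 1}),
        ("AAAA", 1, {"A": 4}),
        ("AC", 3, {}),
    ])
    def test_window_counts(self, seq, k, expected):
        assert kmer_counts(seq, k) == expected

    @given(dna.filter(lambda s: len(s) >= 3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_counts_sum_to_window_count(self, seq):
        for k in (1, 2, 3):
            assert sum(kmer_counts(seq, k).values()) == len(seq) - k + 1


class TestSuffixCell:
    def test_worked_cells(self):
        assert kmer_suffix_cell("T", 2) == (0, 1)
        assert kmer_suffix_cell("GT", 4) == (1, 3)

    def test_gt_cell_matches_hand_traced_trajectory(self):
        # "GT" -> point (0.75, 0.25); at N=4: col=floor(1.75/2*4)=3, row=floor(0.75/2*4)=1
        traj = cgr_encode("GT")
        assert np.allclose(traj[-1], [0.75, 0.25])
        img = fcgr_rasterize(traj[-1:], 4)
        assert img.counts[1, 3] == 1

    def test_mismatched_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            kmer_suffix_cell("GT", 8)


class TestKmerEquivalence:
    """The core encoding oracle: at N = 2^k the FCGR is the k-mer count table."""

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_fcgr_equals_kmer_counts_cell_by_cell(self, k, rng):
        N = 2 ** k
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            traj = cgr_encode(seq)
            tail = fcgr_rasterize(traj[k - 1:], N).counts  # points with index >= k (1-based)
            grid = np.zeros((N, N), dtype=int)
            for kmer, count in kmer_counts(seq, k).items():
                grid[kmer_suffix_cell(kmer, N)] = count
            assert np.array_equal(tail, grid)
            full = fcgr_rasterize(traj, N).counts
            assert np.abs(full - grid).sum() <= k - 1  # only the first k-1 points differ

    def test_suffix_locality_under_prefix_perturbation(self, rng):
        # the cell of point i at N=2^k depends only on the last k residues
        k, N = 3, 8
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            other = "".join(rng.choice(list("ACGT"), size=50))
            hybrid = other[: 50 - k] + seq[-k:]
            cell_a = np.argwhere(fcgr_rasterize(cgr_encode(seq)[-1:], N).counts)[0]
            cell_b = np.argwhere(fcgr_rasterize(cgr_encode(hybrid)[-1:], N).counts)[0]
            assert np.array_equal(cell_a, cell_b)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_sequence_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            gc_content("")


class TestEncoderTransformer:
    def test_stacks_records_and_strings(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "GGCC")]
        X = FCGREncoder(resolution=8).transform(recs)
        assert X.shape == (2, 8, 8)
        assert np.array_equal(X, FCGREncoder(resolution=8).transform(["ACGT", "GGCC"]))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        enc = FCGREncoder(resolution=16, policy="skip")
        assert clone(enc).get_params() == enc.get_params()

    def test_invalid_resolution_raises_on_fit(self):
        with pytest.raises(ValueError):
            FCGREncoder(resolution=0).fit()
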