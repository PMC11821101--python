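"""Core algorithm: matrix construction, windowed extrema, suppression."""

import math

import numpy as np
import pytest

from cdkd import (
    BackendSpec,
    DetectorParams,
    FrameSequence,
    MetricSpec,
    PairwiseMatrix,
    ValidationError,
    build_matrix,
    detect,
    export_matrix,
    find_local_extrema,
    import_matrix,
    suppress,
)
from cdkd.frame_metrics import SsimConstants, l1_distance, psnr, ssim_global
from cdkd.keyframe_detection import CandidatePair


# ---------------------------------------------------------------- oracles


def brute_force_extrema(values, orientation, window_radius, min_separation,
                        require_full_window=False):
    """Exhaustive window check, written independently of the implementation."""
    n = values.shape[0]
    out = []
    for i in range(n):
        for j in range(n):
            if j - i < min_separation:
                continue
            if require_full_window and not (
                window_radius <= i < n - window_radius
                and window_radius <= j < n - window_radius
            ):
                continue
            ok = True
            for a in range(max(0, i - window_radius), min(n, i + window_radius + 1)):
                for b in range(max(0, j - window_radius), min(n, j + window_radius + 1)):
                    if (a, b) == (i, j):
                        continue
                    if orientation == "similarity":
                        if values[a, b] <= values[i, j]:
                            ok = False
                    else:
                        if values[a, b] >= values[i, j]:
                            ok = False
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                out.append((i, j, values[i, j]))
    return set((i, j) for i, j, _ in out)


def step_through_suppression(pairs, orientation, min_separation):
    """Literal transcription of the greedy suppression loop."""
    sign = 1 if orientation == "similarity" else -1
    ordered = sorted(pairs, key=lambda p: (sign * p[2], p[0], p[1]))
    accepted = []
    for i, j, _ in ordered:
        for frame in (i, j):
            if all(abs(frame - a) >= min_separation for a in accepted):
                accepted.append(frame)
    return sorted(accepted)


def random_symmetric_matrix(rng, n):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, m.max() + 1.0)  # similarity-style diagonal
    return m


# ---------------------------------------------------------------- build_matrix


class TestBuildMatrix:
    def test_identical_frames_cosine_all_ones(self):
        f = np.full((8, 8), 42.0)
        seq = FrameSequence(np.stack([f, f, f]), max_value=255.0)
        M = build_matrix(seq, DetectorParams(metric=MetricSpec("cosine"), backend=BackendSpec("flatten")))
        np.testing.assert_allclose(M.values, 1.0, atol=1e-12)
        assert M.orientation == "similarity"

    def test_identical_frames_l1_all_zeros(self):
        f = np.full((8, 8), 42.0)
        seq = FrameSequence(np.stack([f, f, f]), max_value=255.0)
        M = build_matrix(seq, DetectorParams(metric=MetricSpec("l1")))
        np.testing.assert_array_equal(M.values, 0.0)
        assert M.orientation == "difference"

    @pytest.mark.parametrize("metric", ["cosine", "l1", "psnr", "ssim"])
    def test_matches_brute_force_double_loop(self, metric, random_sequence):
        params = DetectorParams(metric=MetricSpec(metric), backend=BackendSpec("flatten"))
        M = build_matrix(random_sequence, params)
        n = len(random_sequence)
        frames = random_sequence.frames
        consts = SsimConstants(L=255.0)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if metric == "cosine":
                    u, v = frames[i].ravel(), frames[j].ravel()
                    exp = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
                elif metric == "l1":
                    exp = l1_distance(frames[i], frames[j])
                elif metric == "psnr":
                    exp = psnr(frames[i], frames[j], 255.0)
                else:
                    exp = ssim_global(frames[i], frames[j], consts)
                assert M.values[i, j] == pytest.approx(exp, abs=1e-12)

    def test_psnr_infinities_are_capped_finite(self):
        f = np.full((4, 4), 9.0)
        g = np.full((4, 4), 11.0)
        seq = FrameSequence(np.stack([f, f, g]), max_value=255.0)
        M = build_matrix(seq, DetectorParams(metric=MetricSpec("psnr")))
        assert np.isfinite(M.values).all()
        finite_max = psnr(f, g, 255.0)
        # identical pair (0,1) capped above every true finite value
        assert M.values[0, 1] > finite_max

    def test_symmetry_enforced(self):
        with pytest.raises(ValidationError):
            PairwiseMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), orientation="similarity")


# ---------------------------------------------------------------- extrema


class TestFindLocalExtrema:
    def test_constant_matrix_has_no_strict_extrema(self):
        M = PairwiseMatrix(np.ones((6, 6)), orientation="similarity")
        assert find_local_extrema(M) == []

    def test_single_deep_minimum(self):
        v = np.full((5, 5), 0.9)
        np.fill_diagonal(v, 1.0)
        v[1, 4] = v[4, 1] = 0.2
        M = PairwiseMatrix(v, orientation="similarity")
        cands = find_local_extrema(M, window_radius=2, min_separation=2)
        assert cands == [CandidatePair(1, 4, 0.2)]

    def test_negation_duality(self):
        v = np.full((5, 5), 0.9)
        np.fill_diagonal(v, 1.0)
        v[1, 4] = v[4, 1] = 0.2
        sim = find_local_extrema(PairwiseMatrix(v, orientation="similarity"))
        diff = find_local_extrema(PairwiseMatrix(-v, orientation="difference"))
        assert [(c.i, c.j) for c in sim] == [(c.i, c.j) for c in diff]

    @pytest.mark.parametrize("require_full_window", [False, True])
    def test_matches_brute_force_on_random_matrices(self, rng, require_full_window):
        """Oracle equivalence over 100 random symmetric matrices."""
        for _ in range(100):
            n = int(rng.integers(6, 26))
            v = random_symmetric_matrix(rng, n)
            M = PairwiseMatrix(v, orientation="similarity")
            got = {
                (c.i, c.j)
                for c in find_local_extrema(M, 2, 2, require_full_window=require_full_window)
            }
            exp = brute_force_extrema(v, "similarity", 2, 2, require_full_window)
            assert got == exp

    def test_difference_orientation_against_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            v = random_symmetric_matrix(rng, n)
            v = -v  # keyframes become maxima
            M = PairwiseMatrix(v, orientation="difference")
            got = {(c.i, c.j) for c in find_local_extrema(M, 2, 2)}
            assert got == brute_force_extrema(v, "difference", 2, 2)

    def test_sorted_most_extreme_first(self, rng):
        v = random_symmetric_matrix(rng, 15)
        M = PairwiseMatrix(v, orientation="similarity")
        cands = find_local_extrema(M)
        values = [c.value for c in cands]
        assert values == sorted(values)

    def test_wider_windows_never_add_candidates(self, rng):
        for _ in range(10):
            v = random_symmetric_matrix(rng, 18)
            M = PairwiseMatrix(v, orientation="similarity")
            counts = [len(find_local_extrema(M, r, 2)) for r in (1, 2, 3, 4)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------- suppression


class TestSuppress:
    def test_distance_one_suppressed(self):
        # second pair re-offers frame 1, one frame away from accepted 0
        pairs = [CandidatePair(0, 5, 0.1), CandidatePair(1, 8, 0.2)]
        res = suppress(pairs, "similarity", min_separation=2)
        assert res.keyframes == [0, 5, 8]

    def test_distance_two_retained(self):
        # threshold is strict: skip iff distance < min_separation
        pairs = [CandidatePair(0, 5, 0.1), CandidatePair(2, 8, 0.2)]
        res = suppress(pairs, "similarity", min_separation=2)
        assert 2 in res.keyframes

    def test_distance_three_retained(self):
        pairs = [CandidatePair(0, 5, 0.1), CandidatePair(3, 8, 0.2)]
        res = suppress(pairs, "similarity", min_separation=2)
        assert res.keyframes == [0, 3, 5, 8]

    def test_worked_sequence(self):
        pairs = [
            CandidatePair(2, 9, 0.1),
            CandidatePair(3, 9, 0.15),
            CandidatePair(6, 12, 0.2),
        ]
        res = suppress(pairs, "similarity", min_separation=2)
        # frame 3 suppressed by accepted 2; duplicate 9 dropped
        assert res.keyframes == [2, 6, 9, 12]

    def test_difference_orientation_processes_descending(self):
        pairs = [CandidatePair(0, 5, 1.0), CandidatePair(4, 9, 10.0)]
        res = suppress(pairs, "difference", min_separation=2)
        # the strongest (largest) pair is accepted first; frame 5 then
        # falls within distance 1 of accepted frame 4
        assert res.keyframes == [0, 4, 9]

    def test_empty_input(self):
        res = suppress([], "similarity", 2)
        assert res.keyframes == [] and res.provenance == []

    def test_matches_step_through_oracle_on_random_lists(self, rng):
        for _ in range(50):
            n_pairs = int(rng.integers(1, 12))
            pairs = []
            for _ in range(n_pairs):
                i = int(rng.integers(0, 30))
                j = int(rng.integers(i + 2, i + 20))
                pairs.append(CandidatePair(i, j, float(rng.normal())))
            sep = int(rng.integers(1, 4))
            res = suppress(pairs, "similarity", sep)
            assert res.keyframes == step_through_suppression(
                [(p.i, p.j, p.value) for p in pairs], "similarity", sep
            )
            ks = res.keyframes
            assert all(
                abs(a - b) >= sep for x, a in enumerate(ks) for b in ks[x + 1 :]
            )

    def test_provenance_covers_all_keyframes(self, rng):
        pairs = [CandidatePair(2, 9, 0.1), CandidatePair(3, 9, 0.15), CandidatePair(6, 12, 0.2)]
        res = suppress(pairs, "similarity", 2)
        endpoints = {p.i for p in res.provenance} | {p.j for p in res.provenance}
        assert set(res.keyframes) <= endpoints


# ---------------------------------------------------------------- detect


class TestDetect:
    def test_noise_free_phantom_recovery(self, clean_phantom):
        params = DetectorParams(metric=MetricSpec("cosine"), backend=BackendSpec("flatten"))
        res = detect(clean_phantom.sequence, params)
        truth = clean_phantom.labels.keyframe_indices
        matched = [k for k in res.keyframes if min(abs(k - t) for t in truth) <= 1]
        assert len(matched) == len(res.keyframes), "no spurious detections"
        recovered = [t for t in truth if any(abs(k - t) <= 1 for k in res.keyframes)]
        assert len(recovered) >= 5

    def test_constant_sequence_yields_nothing(self):
        seq = FrameSequence(np.full((10, 8, 8), 3.0), max_value=255.0)
        res = detect(seq, DetectorParams(metric=MetricSpec("l1")))
        assert res.keyframes == []

    def test_deterministic(self, clean_phantom):
        params = DetectorParams(metric=MetricSpec("cosine"), backend=BackendSpec("downsample"))
        a = detect(clean_phantom.sequence, params)
        b = detect(clean_phantom.sequence, params)
        assert a == b

    def test_duality_on_negated_matrix(self, rng):
        v = random_symmetric_matrix(rng, 20)
        sim_M = PairwiseMatrix(v, orientation="similarity")
        diff_M = PairwiseMatrix(-v, orientation="difference")
        a = suppress(find_local_extrema(sim_M, 2, 2, require_full_window=True), "similarity", 2)
        b = suppress(find_local_extrema(diff_M, 2, 2, require_full_window=True), "difference", 2)
        assert a.keyframes == b.keyframes

    def test_parameters_recorded(self, clean_phantom):
        res = detect(clean_phantom.sequence, DetectorParams(metric=MetricSpec("ssim")))
        assert res.parameters["metric"] == "ssim"
        assert res.parameters["min_separation"] == 2


# ---------------------------------------------------------------- export


class TestMatrixExport:
    def test_roundtrip(self, tmp_path, rng):
        v = random_symmetric_matrix(rng, 6)
        M = PairwiseMatrix(v, orientation="similarity", metric_name="cosine")
        export_matrix(M, tmp_path / "m.csv")
        got = import_matrix(tmp_path / "m.csv", orientation="similarity")
        np.testing.assert_allclose(got.values, v, atol=1e-9)

    def test_header_grid_shape(self, tmp_path):
        M = PairwiseMatrix(np.ones((3, 3)), orientation="similarity")
        export_matrix(M, tmp_path / "m.csv")
        lines = (tmp_path / "m.csv").read_text().strip().splitlines()
        assert len(lines) == 4  # header row + 3 data rows
        assert all(len(line.split(",")) == 4 for line in lines)

    def test_asymmetric_refused_on_import(self, tmp_path):
        (tmp_path / "bad.csv").write_text(",0,1,2\n0,0,1,2\n1,9,0,1\n2,2,1,0\n")
        with pytest.raises(ValidationError):
            import_matrix(tmp_path / "bad.csv")
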