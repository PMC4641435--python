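import numpy as np
import pytest
from hypothesis import given, strategies as st

import tractometry as tm
from tractometry.cleaning import (
    CoreTract,
    ResampledBundle,
    clean_bundle,
    core_tract,
    fascicle_distance,
    node_mahalanobis,
    orient_bundle,
    resample_streamline,
    retention_fraction,
    streamline_length,
)
from tractometry.config import RunConfig
from tractometry.errors import GeometryError, InsufficientBundleError

from conftest import START, make_bundle_spec


class TestResample:
    def test_straight_segment_gives_uniform_nodes(self):
        line = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        nodes = resample_streamline(line, 11)
        np.testing.assert_allclose(nodes[:, 0], np.arange(11.0), atol=1e-12)
        np.testing.assert_allclose(nodes[:, 1:], 0.0)

    def test_quarter_circle_spacing_matches_dense_oracle(self):
        """Node spacing on a radius-10 quarter circle must be constant to
        1e-3 against a densely resampled arc-length oracle."""
        theta = np.linspace(0, np.pi / 2, 2000)
        arc = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), 0 * theta])
        nodes = resample_streamline(arc, 101)
        spacing = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        # dense oracle: true arc length split into 100 equal chords
        oracle = 2 * 10 * np.sin((np.pi / 2) / 100 / 2)
        np.testing.assert_allclose(spacing, oracle, atol=1e-3)

    def test_endpoints_preserved_exactly(self, rng):
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0)
        nodes = resample_streamline(pts, 100)
        np.testing.assert_array_equal(nodes[0], pts[0])
        np.testing.assert_array_equal(nodes[-1], pts[-1])

    def test_degenerate_streamline_rejected(self):
        with pytest.raises(GeometryError):
            resample_streamline(np.zeros((3, 3)), 10)
        with pytest.raises(GeometryError):
            resample_streamline(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 1)

    @given(st.integers(2, 60), st.integers(0, 2 ** 31 - 1))
    def test_nodes_sit_at_uniform_arc_positions_of_dense_oracle(self, n_pts_extra, seed):
        """Resampled nodes must coincide with a brute-force oracle that
        walks the cumulative arc length of the polyline directly."""
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(2 + n_pts_extra, 3)), axis=0)
        nodes = resample_streamline(pts, 50)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.r_[0.0, np.cumsum(seg)]
        oracle = []
        for target in np.linspace(0.0, s[-1], 50):
            j = np.searchsorted(s, target, side="right") - 1
            j = min(j, len(seg) - 1)
            frac = 0.0 if seg[j] == 0 else (target - s[j]) / seg[j]
            oracle.append(pts[j] + frac * (pts[j + 1] - pts[j]))
        np.testing.assert_allclose(nodes, np.asarray(oracle), atol=1e-9)


class TestOrient:
    def test_reversed_streamlines_are_flipped_to_cluster(self, clean_bundle_file):
        sls = [s if i % 2 else s[::-1] for i, s in enumerate(clean_bundle_file.streamlines)]
        bundle = orient_bundle(sls, START, 100)
        starts = bundle.nodes[:, 0, :]
        assert np.linalg.norm(starts - starts.mean(axis=0), axis=1).max() < 10.0
        assert bundle.orientation_flipped.sum() == 50

    def test_already_oriented_bundle_untouched(self, clean_bundle_file):
        bundle = orient_bundle(clean_bundle_file.streamlines, START, 100)
        assert not bundle.orientation_flipped.any()

    def test_equidistant_tie_keeps_stored_order(self):
        s = np.array([[-1.0, 0, 0], [0.0, 1.0, 0], [1.0, 0, 0]])
        bundle = orient_bundle([s], np.array([0.0, 0, 0]), 10)
        assert not bundle.orientation_flipped[0]
        np.testing.assert_allclose(bundle.nodes[0, 0], s[0])


class TestCoreTract:
    def test_identical_streamlines_give_zero_covariance(self):
        s = np.column_stack([np.linspace(0, 30, 50), np.zeros(50), np.zeros(50)])
        bundle = orient_bundle([s, s.copy(), s.copy()], START, 20)
        core = core_tract(bundle)
        np.testing.assert_allclose(core.mean_position, bundle.nodes[0], atol=1e-12)
        assert np.abs(core.node_covariance).max() < 1e-3  # regularization floor only

    def test_mirrored_pair_mean_lies_on_plane(self):
        t = np.linspace(0, 1, 50)
        a = np.column_stack([t * 20, np.sin(np.pi * t) * 5, np.zeros(50)])
        b = a * np.array([1.0, -1.0, 1.0])
        core = core_tract(orient_bundle([a, b], np.zeros(3), 30))
        np.testing.assert_allclose(core.mean_position[:, 1], 0.0, atol=1e-9)

    def test_requires_two_streamlines(self):
        s = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(InsufficientBundleError):
            core_tract(orient_bundle([s], np.zeros(3), 10))


def _manual_bundle(nodes, lengths=None):
    nodes = np.asarray(nodes, dtype=float)
    if lengths is None:
        lengths = [streamline_length(s) for s in nodes]
    return ResampledBundle(
        nodes=nodes,
        lengths=np.asarray(lengths, dtype=float),
        orientation_flipped=np.zeros(len(nodes), dtype=bool),
    )


def _identity_core(mean_path, n_nodes):
    return CoreTract(
        mean_position=mean_path,
        node_covariance=np.broadcast_to(np.eye(3), (n_nodes, 3, 3)).copy(),
        mean_length=float(streamline_length(mean_path)),
        length_sd=1.0,
    )


class TestFascicleDistance:
    def test_streamline_on_core_scores_zero(self):
        path = np.column_stack([np.linspace(0, 99, 100), np.zeros(100), np.zeros(100)])
        core = _identity_core(path, 100)
        bundle = _manual_bundle([path])
        assert fascicle_distance(bundle, core)[0] == pytest.approx(0.0)

    def test_single_node_three_sd_displacement_mean_rule(self):
        """One node displaced 3 SD along a covariance eigenvector, 99 on
        the mean: mean-over-nodes score is 3/100 = 0.03."""
        path = np.column_stack([np.linspace(0, 99, 100), np.zeros(100), np.zeros(100)])
        core = _identity_core(path, 100)
        displaced = path.copy()
        displaced[40, 1] += 3.0
        score = fascicle_distance(_manual_bundle([displaced]), core)[0]
        assert score == pytest.approx(0.03, rel=1e-6)
        score_max = fascicle_distance(_manual_bundle([displaced]), core, stat="max")[0]
        assert score_max == pytest.approx(3.0, rel=1e-6)

    def test_uniform_offset_under_identity_covariance(self):
        path = np.column_stack([np.linspace(0, 99, 100), np.zeros(100), np.zeros(100)])
        core = _identity_core(path, 100)
        offset = path + np.array([0.0, 2.6, 0.0])
        assert fascicle_distance(_manual_bundle([offset]), core)[0] == pytest.approx(2.6)


class TestCleanBundle:
    def test_tight_bundle_converges_first_pass(self, clean_bundle_file):
        bundle = orient_bundle(clean_bundle_file.streamlines, START, 100)
        result = clean_bundle(bundle)
        assert result.iterations == 1
        assert result.kept == list(range(100))
        assert not result.failed

    @pytest.mark.parametrize("seed", [1, 3, 4])
    def test_planted_outliers_recovered_exactly(self, seed):
        sf = tm.gen_bundle(make_bundle_spec(outlier_fraction=0.10, rng_seed=seed))
        bundle = orient_bundle(sf.streamlines, START, 100)
        result = clean_bundle(bundle)
        assert result.removed_distance == sf.outlier_indices
        assert result.removed_length == []

    def test_length_outliers_removed_by_length_not_distance(self):
        sf = tm.gen_bundle(make_bundle_spec(length_outlier_fraction=0.10, rng_seed=3))
        bundle = orient_bundle(sf.streamlines, START, 100)
        result = clean_bundle(bundle)
        assert result.removed_length == sf.outlier_indices
        assert result.removed_distance == []

    def test_sparse_survival_flags_failure(self, rng):
        """12 fascicles of which only 5 are coherent: under the <10
        surviving-fascicle rule the bundle is a tracking failure."""
        t = np.linspace(0, 1, 50)
        base = np.column_stack([t * 60, np.zeros(50), np.zeros(50)])
        tight = [base + rng.normal(0, 0.5, (50, 3)) for _ in range(5)]
        plateau = np.sin(np.pi * t)[:, None]
        wild = []
        for amplitude in (10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            wild.append(base + amplitude * plateau * u)
        result = clean_bundle(orient_bundle(tight + wild, np.zeros(3), 50))
        assert result.failed
        assert len(result.kept) < 10
        assert set(range(5)) <= set(result.kept)  # coherent fascicles survive

    def test_failure_is_reported_not_raised_and_partitions_input(self, rng):
        sls = [np.cumsum(rng.normal(size=(20, 3)), axis=0) for _ in range(8)]
        result = clean_bundle(orient_bundle(sls, np.zeros(3), 30))
        all_idx = sorted(result.kept + result.removed_distance + result.removed_length)
        assert all_idx == list(range(8))

    def test_cleaning_is_idempotent(self, outlier_bundle_file):
        bundle = orient_bundle(outlier_bundle_file.streamlines, START, 100)
        first = clean_bundle(bundle)
        again = clean_bundle(bundle.subset(first.kept))
        assert again.kept == list(range(len(first.kept)))
        assert not again.removed_distance and not again.removed_length

    def test_raising_dist_sd_never_removes_more(self, outlier_bundle_file):
        bundle = orient_bundle(outlier_bundle_file.streamlines, START, 100)
        strict = set(clean_bundle(bundle, RunConfig(dist_sd=2.6)).kept)
        loose = set(clean_bundle(bundle, RunConfig(dist_sd=3.5)).kept)
        assert strict <= loose

    def test_kept_set_invariant_under_permutation(self, outlier_bundle_file):
        bundle = orient_bundle(outlier_bundle_file.streamlines, START, 100)
        perm = np.random.default_rng(9).permutation(100)
        permuted = orient_bundle(
            [outlier_bundle_file.streamlines[i] for i in perm], START, 100
        )
        ref = clean_bundle(bundle)
        shuffled = clean_bundle(permuted)
        assert sorted(perm[shuffled.kept].tolist()) == ref.kept

    def test_matches_brute_force_reference(self, rng):
        """On tiny bundles the iterative cleaner must agree with an
        exhaustive reference that recomputes every statistic each pass."""
        for trial in range(5):
            sls = []
            base = np.column_stack([np.linspace(0, 40, 5), np.zeros(5), np.zeros(5)])
            for i in range(20):
                sls.append(base + rng.normal(0, 1.0, (5, 3)))
            if trial % 2:
                sls[3] = sls[3] + np.array([0.0, 25.0, 0.0])
            bundle = _manual_bundle(np.stack(sls))
            config = RunConfig(n_nodes=5, clip_range=(0, 4), distal_range=(2, 4))
            result = clean_bundle(bundle, config)
            assert sorted(result.kept) == _brute_force_clean(bundle.nodes, config)


def _brute_force_clean(nodes, config):
    """Reference implementation: plain loops, recomputed exhaustively."""
    kept = list(range(len(nodes)))
    for _ in range(config.max_clean_iterations):
        if len(kept) < 2:
            break
        pts = nodes[kept]
        lengths = np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in pts]
        )
        drop = set()
        scores = []
        for si in range(len(kept)):
            ds = []
            for n in range(pts.shape[1]):
                x = pts[:, n, :]
                mu = x.mean(axis=0)
                cov = np.cov(x.T, ddof=1) + 1e-6 * np.eye(3)
                d = pts[si, n] - mu
                ds.append(np.sqrt(d @ np.linalg.inv(cov) @ d))
            scores.append(np.mean(ds))
        limit = lengths.mean() + config.len_sd * lengths.std(ddof=1)
        for si in range(len(kept)):
            if scores[si] > config.dist_sd or lengths[si] > limit:
                drop.add(kept[si])
        if not drop:
            break
        kept = [i for i in kept if i not in drop]
    return sorted(kept)


class TestRetention:
    @pytest.mark.parametrize(
        "kept,total,expected", [(25, 100, 0.25), (100, 100, 1.0), (5, 12, 5 / 12)]
    )
    def test_fraction(self, kept, total, expected):
        result = tm.CleaningResult(
            kept=list(range(kept)), removed_distance=[], removed_length=[],
            iterations=1, failed=kept < 10, original_count=total,
        )
        assert retention_fraction(result) == pytest.approx(expected)
        assert retention_fraction(result, total) == pytest.approx(expected)

    def test_failed_bundle_still_reports_fraction(self):
        result = tm.CleaningResult(
            kept=[0, 1], removed_distance=list(range(2, 12)), removed_length=[],
            iterations=3, failed=True, original_count=12,
        )
        assert retention_fraction(result) == pytest.approx(2 / 12)

    def test_json_round_trip(self, tmp_path):
        result = tm.CleaningResult(
            kept=[0, 2], removed_distance=[1], removed_length=[3],
            iterations=2, failed=False, original_count=4,
        )
        import json

        payload = json.loads(result.to_json(tmp_path / "clean.json"))
        assert payload["kept"] == [0, 2]
        assert payload["iterations"] == 2
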