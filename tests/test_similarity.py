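"""The similarity score, benchmark protocols and bias metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazebench import (
    GazeTrack,
    PresentationCondition,
    build_benchmark,
    central_bias,
    chance_baseline,
    clip_similarity,
    cross_sequence_similarity,
    euclidean_distance,
    frame_similarity,
    interobserver_similarity,
)
from gazebench.errors import InputError
from gazebench.sequencing import SequenceMap

COND = PresentationCondition.NORMAL_VIDEO


def track(xy, source="o", clip="c", cond=COND, w=720, h=404):
    return GazeTrack(source, clip, cond, np.asarray(xy, dtype=float), w, h)


def random_tracks(rng, n_obs=6, n_frames=20, w=720, h=404, p_missing=0.0):
    tracks = []
    for i in range(n_obs):
        xy = rng.uniform((0, 0), (w, h), size=(n_frames, 2))
        if p_missing:
            xy[rng.random(n_frames) < p_missing] = np.nan
        tracks.append(track(xy, source=f"o{i}", w=w, h=h))
    return tracks


def brute_force_clip_score(bench_tracks_xy, pred_xy):
    """Independent oracle: per-frame loop computing the benchmark, D̄ and S
    from raw observer coordinates."""
    svals = []
    for k in range(pred_xy.shape[0]):
        pts = [xy[k] for xy in bench_tracks_xy if not np.isnan(xy[k]).any()]
        if not pts or np.isnan(pred_xy[k]).any():
            continue
        bx = sum(p[0] for p in pts) / len(pts)
        by = sum(p[1] for p in pts) / len(pts)
        dbar = sum(((p[0] - bx) ** 2 + (p[1] - by) ** 2) ** 0.5 for p in pts) / len(pts)
        d_f = ((pred_xy[k][0] - bx) ** 2 + (pred_xy[k][1] - by) ** 2) ** 0.5
        if dbar == 0:
            svals.append(1.0 if d_f == 0 else 0.0)
        else:
            svals.append(dbar / (dbar + d_f))
    return float(np.mean(svals)) if svals else None


class TestFrameScore:
    @pytest.mark.parametrize(
        "p, q, expected",
        [((0, 0), (3, 4), 5.0), ((7.5, -2), (7.5, -2), 0.0), ((360, 202), (0, 0), 412.8002)],
    )
    def test_euclidean_distance(self, p, q, expected):
        assert euclidean_distance(p, q) == pytest.approx(expected, abs=1e-3)
        assert euclidean_distance(q, p) == euclidean_distance(p, q)

    @pytest.mark.parametrize(
        "dbar, d_f, expected",
        [
            (10, 0, 1.0),  # perfect prediction
            (20, 20, 0.5),  # error equals human dispersion
            (10, 30, 0.25),
            (0, 0, 1.0),  # perfectly concordant cohort, perfect prediction
            (0, 5, 0.0),  # the formula's own limit
        ],
    )
    def test_similarity_values(self, dbar, d_f, expected):
        assert frame_similarity(dbar, d_f) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            frame_similarity(-1, 5)
        with pytest.raises(InputError):
            frame_similarity(5, -1)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounded_in_unit_interval(self, dbar, d_f):
        assert 0.0 <= frame_similarity(dbar, d_f) <= 1.0

    @given(st.floats(1e-3, 1e5))
    def test_balance_point(self, d):
        assert frame_similarity(d, d) == pytest.approx(0.5)

    @given(st.floats(1e-3, 1e4), st.floats(0, 1e4), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, dbar, d_f, c):
        assert frame_similarity(c * dbar, c * d_f) == pytest.approx(
            frame_similarity(dbar, d_f)
        )

    def test_monotonicity(self):
        s = [frame_similarity(10, d) for d in (0, 5, 10, 50, 500)]
        assert s == sorted(s, reverse=True)
        s2 = [frame_similarity(d, 10) for d in (1, 5, 10, 50)]
        assert s2 == sorted(s2)


class TestBenchmark:
    def test_single_observer_is_own_benchmark(self, rng):
        (tr,) = random_tracks(rng, n_obs=1)
        bench = build_benchmark([tr])
        np.testing.assert_allclose(bench.xy, tr.xy)
        np.testing.assert_allclose(bench.dbar, 0.0)

    def test_two_observer_midpoint(self):
        t1 = track([[0, 0]])
        t2 = track([[10, 0]], source="o2")
        bench = build_benchmark([t1, t2])
        np.testing.assert_allclose(bench.xy, [[5, 0]])
        np.testing.assert_allclose(bench.dists, [[5, 5]])
        np.testing.assert_allclose(bench.dbar, [5])
        assert bench.n_observers.tolist() == [2]

    def test_missing_observer_excluded_vs_bruteforce(self, rng):
        tracks = random_tracks(rng, n_obs=10, n_frames=6)
        tracks[4].xy[2] = np.nan  # one observer missing at frame 3
        bench = build_benchmark(tracks)
        assert bench.n_observers[2] == 9
        # oracle: explicit loop over contributing observers
        pts = [tr.xy[2] for i, tr in enumerate(tracks) if i != 4]
        np.testing.assert_allclose(bench.xy[2], np.mean(pts, axis=0))
        dists = [np.hypot(*(p - bench.xy[2])) for p in pts]
        assert bench.dbar[2] == pytest.approx(np.mean(dists))

    def test_dbar_is_mean_of_stored_distances(self, rng):
        bench = build_benchmark(random_tracks(rng, p_missing=0.2))
        with np.errstate(invalid="ignore"):
            expect = np.nanmean(bench.dists, axis=1)
        ok = ~np.isnan(expect)
        np.testing.assert_allclose(bench.dbar[ok], expect[ok])

    def test_empty_and_mismatched_inputs_rejected(self, rng):
        with pytest.raises(InputError):
            build_benchmark([])
        t1, t2 = random_tracks(rng, n_obs=2, n_frames=5)
        t3 = random_tracks(rng, n_obs=1, n_frames=6)[0]
        with pytest.raises(InputError):
            build_benchmark([t1, t3])


class TestClipSimilarity:
    def test_identical_prediction_scores_one(self, rng):
        tracks = random_tracks(rng, n_obs=5)
        bench = build_benchmark(tracks)
        pred = track(bench.xy.copy(), source="perfect")
        assert clip_similarity(bench, pred).mean_s == pytest.approx(1.0)

    def test_two_frame_toy(self):
        # frame 1: D̄=10, D_f=10 -> 0.5; frame 2: D̄=10, D_f=30 -> 0.25
        obs = [track([[100, 100], [100, 100]]), track([[120, 100], [120, 100]], source="o2")]
        bench = build_benchmark(obs)
        pred = track([[110 + 10, 100], [110 + 30, 100]], source="m")
        cs = clip_similarity(bench, pred)
        assert [f.s for f in cs.frames] == pytest.approx([0.5, 0.25])
        assert cs.mean_s == pytest.approx(0.375)

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(10):
            tracks = random_tracks(rng, n_obs=8, n_frames=90, p_missing=0.1)
            bench = build_benchmark(tracks)
            pred_xy = rng.uniform((0, 0), (720, 404), size=(90, 2))
            pred_xy[rng.random(90) < 0.05] = np.nan
            cs = clip_similarity(bench, track(pred_xy, source="m"))
            oracle = brute_force_clip_score([t.xy for t in tracks], pred_xy)
            assert cs.mean_s == pytest.approx(oracle, abs=1e-9)

    def test_skip_accounting(self, rng):
        tracks = random_tracks(rng, n_frames=10)
        bench = build_benchmark(tracks)
        pred_xy = rng.uniform((0, 0), (720, 404), size=(10, 2))
        pred_xy[:4] = np.nan
        cs = clip_similarity(bench, track(pred_xy, source="m"))
        assert (cs.n_scored, cs.n_skipped) == (6, 4)
        assert cs.n_scored + cs.n_skipped == bench.n_frames

    def test_all_missing_prediction_is_unscorable_not_a_number(self, rng):
        bench = build_benchmark(random_tracks(rng, n_frames=4))
        cs = clip_similarity(bench, track(np.full((4, 2), np.nan), source="m"))
        assert not cs.scorable
        assert cs.mean_s is None

    def test_translation_and_scale_invariance(self, rng):
        """Shifting every point by a constant vector, or scaling all
        coordinates by c > 0, leaves every frame's S unchanged."""
        tracks = random_tracks(rng, n_obs=6, n_frames=30, w=2000, h=2000)
        pred_xy = rng.uniform((500, 500), (900, 900), size=(30, 2))
        base = clip_similarity(build_benchmark(tracks), track(pred_xy, source="m", w=2000, h=2000))

        def remap(f, w, h):
            moved = [
                track(f(tr.xy), source=tr.source_id, w=w, h=h) for tr in tracks
            ]
            return clip_similarity(
                build_benchmark(moved), track(f(pred_xy), source="m", w=w, h=h)
            )

        shifted = remap(lambda xy: xy + np.array([37.0, 11.0]), 3000, 3000)
        scaled = remap(lambda xy: xy * 0.25, 2000, 2000)
        for other in (shifted, scaled):
            np.testing.assert_allclose(
                [f.s for f in other.frames], [f.s for f in base.frames], atol=1e-9
            )


class TestInterObserver:
    def test_identical_observers_score_one(self):
        xy = np.tile([200.0, 150.0], (5, 1))
        tracks = [track(xy.copy(), source=f"o{i}") for i in range(4)]
        for cs in interobserver_similarity(tracks):
            assert cs.mean_s == pytest.approx(1.0)  # 0/0 rule

    def test_three_observer_single_frame(self):
        tracks = [
            track([[0, 0]]),
            track([[6, 0]], source="o2"),
            track([[12, 0]], source="o3"),
        ]
        scores = interobserver_similarity(tracks)
        # held-out (0,0): others' benchmark (9,0), D̄=3, D_f=9 -> 0.25
        assert scores[0].mean_s == pytest.approx(0.25)

    def test_needs_two_observers(self, rng):
        with pytest.raises(InputError):
            interobserver_similarity(random_tracks(rng, n_obs=1))

    def test_held_out_observer_does_not_normalise_own_score(self, rng):
        """D̄ comes from the n-1 predicting observers only."""
        tracks = random_tracks(rng, n_obs=4, n_frames=8)
        scores = interobserver_similarity(tracks)
        others = [t.xy for t in tracks[1:]]
        assert scores[0].mean_s == pytest.approx(
            brute_force_clip_score(others, tracks[0].xy), abs=1e-9
        )

    def test_agreement_is_scale_free_in_cohort_noise(self):
        """Because S is a ratio of distances, the leave-one-out score of an
        i.i.d. isotropic-noise cohort around a shared trajectory does not
        depend on the noise scale: it is exactly 1 for a perfectly concordant
        cohort (0/0 rule) and sits near the Gaussian-cohort level (~0.51)
        for any positive noise."""
        base = np.random.default_rng(0).uniform((150, 120), (560, 280), size=(60, 2))
        means = []
        for sd in (0.0, 1e-6, 5.0, 40.0):
            rng = np.random.default_rng(42)
            tracks = [
                track(
                    np.clip(base + rng.normal(0, sd, base.shape), 0, [719.9, 403.9]),
                    source=f"o{i}", w=720, h=404,
                )
                for i in range(8)
            ]
            scores = [cs.mean_s for cs in interobserver_similarity(tracks)]
            means.append(float(np.mean(scores)))
        assert means[0] == pytest.approx(1.0)
        positive = means[1:]
        assert max(positive) - min(positive) < 0.05
        assert all(0.4 < m < 0.65 for m in positive)


class TestChanceBaseline:
    def test_degenerate_single_pixel_frame_scores_one(self):
        tracks = [track([[0, 0]], w=1, h=1), track([[0, 0]], source="o2", w=1, h=1)]
        cb = chance_baseline(build_benchmark(tracks), n_reps=10, rng_seed=0)
        assert cb.mean_s == pytest.approx(1.0)  # forced coincidence

    def test_matches_independent_sampler(self, rng):
        """Fixed benchmark at the frame centre with D̄ = 60: the Monte-Carlo
        mean matches a brute-force resampling within 2 standard errors."""
        n_frames = 90
        xy = np.tile([360.0, 202.0], (n_frames, 1))
        offsets = np.array([[60.0, 0], [-60.0, 0], [0, 60.0], [0, -60.0]])
        tracks = [
            track(xy + off, source=f"o{i}") for i, off in enumerate(offsets)
        ]
        bench = build_benchmark(tracks)
        np.testing.assert_allclose(bench.dbar, 60.0)
        cb = chance_baseline(bench, n_reps=100, rng_seed=1)

        # independent oracle: same protocol, separate implementation
        oracle_rng = np.random.default_rng(12345)
        reps = []
        for _ in range(400):
            svals = []
            for k in range(n_frames):
                px = oracle_rng.integers(0, 720)
                py = oracle_rng.integers(0, 404)
                d = np.hypot(px - 360.0, py - 202.0)
                svals.append(60.0 / (60.0 + d))
            reps.append(np.mean(svals))
        se = np.std(reps, ddof=1) / np.sqrt(len(reps)) + cb.sd_s / np.sqrt(cb.n_reps)
        assert cb.mean_s == pytest.approx(np.mean(reps), abs=2 * se)

    def test_seed_reproducibility(self, rng):
        bench = build_benchmark(random_tracks(rng))
        a = chance_baseline(bench, n_reps=20, rng_seed=9)
        b = chance_baseline(bench, n_reps=20, rng_seed=9)
        np.testing.assert_array_equal(a.per_rep, b.per_rep)

    def test_condition_label_invariance(self, small_cohort):
        """Chance level depends only on cohort dispersion and the frame, not
        on the condition label; across conditions it stays in a narrow band."""
        from gazebench import CONDITIONS

        means = []
        for cond in CONDITIONS:
            vals = [
                chance_baseline(
                    build_benchmark(small_cohort.tracks_for(clip_id, cond)),
                    n_reps=40,
                    rng_seed=3,
                ).mean_s
                for clip_id in small_cohort.clip_ids
            ]
            means.append(np.mean(vals))
        assert max(means) - min(means) < 0.1


class TestCrossSequence:
    def test_identity_map_self_comparison_scores_one(self, rng):
        tracks = random_tracks(rng, n_obs=4, n_frames=12)
        bench = build_benchmark(tracks)
        smap = SequenceMap.identity(12)
        cs = cross_sequence_similarity(tracks[0], tracks[0], smap, bench)
        assert cs.mean_s == pytest.approx(1.0)

    def test_content_locked_source_scores_one_under_reversal(self, rng):
        """A source whose gaze depends only on frame content lands at the
        same point at content-aligned frames, so the score is exactly 1."""
        tracks = random_tracks(rng, n_obs=5, n_frames=20)
        bench = build_benchmark(tracks)
        normal = tracks[0]
        smap = SequenceMap.reverse(20)
        reversed_xy = normal.xy[smap.mapping - 1]
        test = track(reversed_xy, source="o0", cond=PresentationCondition.REVERSED_VIDEO)
        cs = cross_sequence_similarity(normal, test, smap, bench)
        assert cs.mean_s == 1.0

    def test_requires_same_source(self, rng):
        t1, t2 = random_tracks(rng, n_obs=2, n_frames=5)
        with pytest.raises(InputError):
            cross_sequence_similarity(t1, t2, SequenceMap.identity(5), build_benchmark([t1, t2]))

    def test_missing_map_rejected(self, rng):
        (t1,) = random_tracks(rng, n_obs=1, n_frames=5)
        with pytest.raises(InputError):
            cross_sequence_similarity(t1, t1, None, None)

    def test_uses_reference_dispersion_at_source_frames(self):
        """D̄ enters from the normal-condition benchmark at the content-matched
        source frame, not the presented index."""
        n = 4
        obs_a = track(np.column_stack([np.arange(n) * 10.0 + 100, np.full(n, 100.0)]))
        obs_b = track(
            np.column_stack([np.arange(n) * 10.0 + 100, np.full(n, 100.0) + (np.arange(n) + 1) * 8]),
            source="o2",
        )
        bench = build_benchmark([obs_a, obs_b])  # D̄ varies per source frame
        smap = SequenceMap.reverse(n)
        test_xy = obs_a.xy[smap.mapping - 1] + np.array([5.0, 0.0])
        test = track(test_xy, source="o", cond=PresentationCondition.REVERSED_VIDEO)
        cs = cross_sequence_similarity(obs_a, test, smap, bench)
        for j, f in enumerate(cs.frames):
            src = smap.source_frame(j + 1)
            expected = bench.dbar[src - 1] / (bench.dbar[src - 1] + 5.0)
            assert f.s == pytest.approx(expected)


class TestCentralBias:
    def test_pinned_to_centre_is_zero(self):
        xy = np.tile([360.0, 202.0], (10, 1))
        assert central_bias(track(xy)).mean_dist == 0.0

    def test_corner_distance(self):
        cb = central_bias(track([[0.0, 0.0]]))
        assert cb.mean_dist == pytest.approx(412.8002, abs=1e-3)

    def test_all_missing_is_unscorable(self):
        cb = central_bias(track(np.full((5, 2), np.nan)))
        assert not cb.scorable

    def test_central_cohort_beats_uniform_predictor(self, rng):
        """Gaze scattered around the centre with sd 40 px sits closer to the
        centre on average than uniform random gaze."""
        cohort = np.clip(
            rng.normal([360, 202], 40, size=(500, 2)), 0, [719.9, 403.9]
        )
        uniform = rng.uniform((0, 0), (720, 404), size=(500, 2))
        d_cohort = central_bias(track(cohort)).mean_dist
        d_uniform = central_bias(track(uniform)).mean_dist
        assert d_cohort < d_uniform
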