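import numpy as np
import pytest

from conftest import frame_records, truth_trajectory
from iristrack.detection import IrisTemplate, disc_mask, extract_template
from iristrack.metrics import evaluate
from iristrack.tracking import (
    MatchCandidate,
    MatchConfig,
    TrackerConfig,
    TrackingError,
    flag_invalid_frames,
    match_similarity_map,
    match_template,
    select_darkest,
    track_video_cht_acm,
    track_video_cht_tm,
)
from iristrack.synthetic import TaskSpec, render_sequence


def make_template(frame, cx, cy, r):
    return extract_template(frame, (cx, cy), r)


def brute_force_ncc(frame, tmpl, use_mask=True):
    """Double-loop masked NCC at every placement (oracle)."""
    f = frame.astype(float)
    t = tmpl.patch.astype(float)
    m = tmpl.mask.astype(float) if use_mask else np.ones_like(t)
    th, tw = t.shape
    out = np.zeros((f.shape[0] - th + 1, f.shape[1] - tw + 1))
    n = m.sum()
    tb = (t * m).sum() / n
    for y in range(out.shape[0]):
        for x in range(out.shape[1]):
            w = f[y : y + th, x : x + tw]
            wb = (w * m).sum() / n
            num = (m * (w - wb) * (t - tb)).sum()
            den = np.sqrt((m * (w - wb) ** 2).sum() * (m * (t - tb) ** 2).sum())
            out[y, x] = num / den if den > 1e-9 else 0.0
    return out


class TestMatchTemplate:
    def test_self_match_is_unique_argmax_at_cut_location(self):
        rng = np.random.default_rng(21)
        frame = rng.integers(0, 256, (60, 80), dtype=np.uint8)
        tmpl = make_template(frame, 40, 30, 10)
        sim = match_similarity_map(frame, tmpl)
        y, x = np.unravel_index(sim.argmax(), sim.shape)
        assert (x, y) == (30, 20)  # cut corner = centre - (r + margin)
        assert sim[y, x] == pytest.approx(1.0, abs=1e-9)
        # unique global maximum
        sim[y, x] = -2
        assert sim.max() < 1.0 - 1e-6

    def test_matches_brute_force_oracle_small_instance(self):
        rng = np.random.default_rng(22)
        frame = rng.integers(0, 256, (24, 24), dtype=np.uint8)
        tmpl = make_template(frame, 12, 12, 4)  # 8x8 patch
        for use_mask in (True, False):
            ours = match_similarity_map(frame, tmpl, use_mask=use_mask)
            oracle = brute_force_ncc(frame, tmpl, use_mask=use_mask)
            assert np.abs(ours - oracle).max() <= 1e-9

    def test_fft_and_direct_paths_agree(self):
        from iristrack import tracking

        rng = np.random.default_rng(23)
        frame = rng.integers(0, 256, (100, 120), dtype=np.uint8)
        tmpl = make_template(frame, 60, 50, 15)
        fft = match_similarity_map(frame, tmpl)
        old = tracking._DIRECT_OP_LIMIT
        tracking._DIRECT_OP_LIMIT = 10**12
        try:
            direct = match_similarity_map(frame, tmpl)
        finally:
            tracking._DIRECT_OP_LIMIT = old
        assert np.abs(fft - direct).max() <= 1e-6

    def test_constant_frame_and_template_degenerate_without_nan(self):
        frame = np.full((30, 30), 128, dtype=np.uint8)
        tmpl = make_template(frame, 15, 15, 5)
        sim = match_similarity_map(frame, tmpl)
        assert np.isfinite(sim).all()
        assert match_template(frame, tmpl) == []

    def test_template_larger_than_frame_rejected(self):
        rng = np.random.default_rng(24)
        big = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        tmpl = make_template(big, 30, 30, 20)
        with pytest.raises(ValueError):
            match_template(rng.integers(0, 256, (20, 20), dtype=np.uint8), tmpl)

    def test_translation_equivariance(self, open_eye_frame):
        frame, (cx, cy) = open_eye_frame
        tmpl = make_template(frame, int(cx), int(cy), 30)
        shifted = np.roll(frame, (3, 5), axis=(0, 1))
        a = match_template(frame, tmpl)[0]
        b = match_template(shifted, tmpl)[0]
        assert (b.x - a.x, b.y - a.y) == (5, 3)


class TestSelectDarkest:
    def _tmpl(self, r=5):
        side = 2 * r
        patch = np.zeros((side, side), dtype=np.uint8)
        return IrisTemplate(
            patch=patch, mask=disc_mask((side, side), r, r, r),
            iris_radius=r, centre_offset=(float(r), float(r)),
        )

    def test_darker_region_wins(self):
        frame = np.full((40, 40), 120, dtype=np.uint8)
        frame[:, :20] = 40
        tmpl = self._tmpl()
        cands = [
            MatchCandidate(x=5, y=15, similarity=0.9),
            MatchCandidate(x=25, y=15, similarity=0.99),
        ]
        assert select_darkest(frame, cands, tmpl) == (10.0, 20.0)

    def test_single_candidate_returned_unconditionally(self):
        frame = np.full((40, 40), 200, dtype=np.uint8)
        tmpl = self._tmpl()
        assert select_darkest(frame, [MatchCandidate(x=7, y=9, similarity=0.5)], tmpl) == (12.0, 14.0)

    def test_matches_exhaustive_region_mean_oracle(self):
        rng = np.random.default_rng(25)
        frame = (np.linspace(0, 255, 50)[None, :] * np.ones((50, 1))).astype(np.uint8)
        tmpl = self._tmpl()
        cands = [
            MatchCandidate(x=int(x), y=int(y), similarity=float(s))
            for x, y, s in zip(
                rng.integers(0, 40, 5), rng.integers(0, 40, 5), rng.random(5)
            )
        ]
        chosen = select_darkest(frame, cands, tmpl)
        r = tmpl.iris_radius
        means = []
        for c in cands:
            m = disc_mask(frame.shape, c.x + r, c.y + r, r)
            means.append(frame[m].mean())
        best = cands[int(np.argmin(means))]
        assert chosen == (best.x + float(r), best.y + float(r))

    def test_empty_candidates_signal_failure(self):
        with pytest.raises(ValueError):
            select_darkest(np.zeros((10, 10), dtype=np.uint8), [], self._tmpl(3))


class TestTrackVideo:
    def test_tm_recovers_horizontal_trajectory(self, horizontal_video):
        frames, truth = horizontal_video
        traj = track_video_cht_tm(frame_records(frames))
        rep = evaluate(traj, truth_trajectory(truth))
        assert rep.x.mae <= 2.0 and rep.y.mae <= 2.0

    def test_acm_recovers_horizontal_trajectory(self, horizontal_video):
        frames, truth = horizontal_video
        traj = track_video_cht_acm(frame_records(frames, interval=30))
        rep = evaluate(traj, truth_trajectory(truth))
        assert rep.x.mae <= 2.0 and rep.y.mae <= 2.0

    def test_single_frame_uses_acm_path(self, horizontal_video):
        frames, _ = horizontal_video
        traj = track_video_cht_tm(frame_records(frames)[:1])
        assert len(traj) == 1
        assert traj.points[0].method == "CHT_ACM"
        assert traj.points[0].valid

    def test_blink_frames_flagged_invalid(self, default_scene):
        frames, truth = render_sequence(
            default_scene, TaskSpec(task="horizontal", duration_s=5.0),
            blink_frames=[40, 90, 130],
        )
        traj = track_video_cht_tm(frame_records(frames))
        invalid = {p.frame_index for p in traj if not p.valid}
        assert invalid == {40, 90, 130}

    def test_first_frame_blink_aborts_with_diagnostic(self, default_scene):
        frames, _ = render_sequence(
            default_scene, TaskSpec(task="horizontal", duration_s=1.0),
            blink_frames=[0],
        )
        with pytest.raises(TrackingError):
            track_video_cht_tm(frame_records(frames))

    def test_template_is_never_updated(self, horizontal_video, monkeypatch):
        from iristrack import tracking

        frames, _ = horizontal_video
        seen = []
        orig = tracking.match_template

        def spy(frame, tmpl, **kw):
            seen.append((tmpl.patch.copy(), tmpl.mask.copy()))
            return orig(frame, tmpl, **kw)

        monkeypatch.setattr(tracking, "match_template", spy)
        track_video_cht_tm(frame_records(frames))
        first_patch, first_mask = seen[0]
        for patch, mask in seen[1:]:
            assert np.array_equal(patch, first_patch)
            assert np.array_equal(mask, first_mask)

    def test_repeated_identical_frame_gives_identical_centres(self, open_eye_frame):
        from iristrack.video_io import FrameRecord

        frame, _ = open_eye_frame
        recs = [FrameRecord(i, i / 30, frame) for i in range(5)]
        traj = track_video_cht_acm(recs)
        centres = {(p.x, p.y) for p in traj}
        assert len(centres) == 1

    def test_masked_y_error_not_worse_under_occlusion(self, default_scene):
        import dataclasses

        scene = dataclasses.replace(default_scene, coverage_top=0.25)
        frames, truth = render_sequence(scene, TaskSpec(task="vertical", duration_s=5.0))
        recs = frame_records(frames)
        gt = truth_trajectory(truth)
        masked = evaluate(
            track_video_cht_tm(recs, TrackerConfig(match=MatchConfig(use_mask=True))), gt
        )
        unmasked = evaluate(
            track_video_cht_tm(recs, TrackerConfig(match=MatchConfig(use_mask=False))), gt
        )
        assert masked.y.mae <= unmasked.y.mae


class TestFlagInvalidFrames:
    def test_low_similarity_points_invalidated(self, horizontal_video):
        import dataclasses

        from iristrack.video_io import TrajectoryPoint

        frames, _ = horizontal_video
        traj = track_video_cht_tm(frame_records(frames))
        # forge one low-similarity point and re-apply the policy
        pts = list(traj.points)
        pts[3] = dataclasses.replace(pts[3], similarity=0.1)
        forged = dataclasses.replace(traj, points=pts)
        flagged = flag_invalid_frames(forged)
        assert not flagged.points[3].valid
        # previously valid points keep their centres
        for old, new in zip(traj.points, flagged.points):
            if new.valid:
                assert (new.x, new.y) == (old.x, old.y)

    def test_all_invalid_video_refused_by_metrics(self, default_scene):
        from iristrack.video_io import Trajectory, TrajectoryPoint

        gt = Trajectory([TrajectoryPoint(0, 0.0, 1.0, 1.0, True)])
        empty = Trajectory([TrajectoryPoint(0, 0.0, None, None, False)])
        with pytest.raises(ValueError):
            evaluate(empty, gt)
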