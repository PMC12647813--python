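import numpy as np
import pandas as pd
import pytest

from narrecall.agreement import match_boundaries
from narrecall.consistency import within_participant
from narrecall.data_model import (
    build_analysis_table,
    read_annotations,
    read_recalls,
    write_annotations,
    write_recalls,
)
from narrecall.synthetic import (
    SyntheticConfig,
    generate_rater,
    generate_study,
    generate_videos,
    simulate_table,
    video_boundaries,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="rho"):
            SyntheticConfig(seed=1, rho=1.2)
        with pytest.raises(ValueError, match="sigma"):
            SyntheticConfig(seed=1, sigma_video=-0.1)
        with pytest.raises(ValueError, match="vocab"):
            SyntheticConfig(seed=1, shared_pool_size=0)


class TestGenerateVideos:
    def test_same_seed_byte_identical(self, tmp_path, tiny_cfg):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_annotations(generate_videos(tiny_cfg), p1)
        write_annotations(generate_videos(tiny_cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_events_tile_duration(self, tiny_cfg):
        for v in generate_videos(tiny_cfg):
            assert v.events[0].onset_s == 0.0
            assert v.events[-1].offset_s == pytest.approx(v.duration_s)
            for a, b in zip(v.events, v.events[1:]):
                assert b.onset_s == pytest.approx(a.offset_s)

    def test_event_count_range(self, tiny_cfg):
        for v in generate_videos(tiny_cfg):
            assert tiny_cfg.events_min <= v.n_events <= tiny_cfg.events_max

    def test_disjoint_pools_degenerate_centrality_handled(self, caplog):
        from narrecall.synthetic import centrality_z_for

        cfg = SyntheticConfig(seed=2, topic_overlap=0.0, n_videos=2,
                              events_min=4, events_max=5)
        videos = generate_videos(cfg)
        with caplog.at_level("WARNING"):
            zmap = centrality_z_for(videos)
        for v in videos:
            z = zmap[v.video_id]
            assert np.all(np.isfinite(z))  # degenerate networks fall back to 0

    def test_hub_event_attains_max_z(self):
        from narrecall.synthetic import centrality_z_for

        hits = total = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                seed=seed, n_videos=2, events_min=6, events_max=8,
                topic_overlap=0.15, hub_event_index=3, hub_overlap=1.0,
            )
            zmap = centrality_z_for(generate_videos(cfg))
            for z in zmap.values():
                total += 1
                hits += int(np.argmax(z) == 2)
        assert hits / total >= 0.95


class TestGenerateStudy:
    def test_design_structure(self, tiny_cfg, tiny_study):
        participants, videos, transcripts, ratings, truth = tiny_study
        assert len(participants) == 2 * tiny_cfg.n_per_group
        by_ps = {}
        for t in transcripts:
            by_ps.setdefault((t.participant_id, t.session), []).append(t)
        for pid in [p.participant_id for p in participants]:
            n_multi = tiny_cfg.n_videos // 2
            assert len(by_ps[(pid, "day1")]) == n_multi
            assert len(by_ps[(pid, "day2")]) == n_multi
            day8 = by_ps[(pid, "day8")]
            assert len(day8) == tiny_cfg.n_videos
            assert sum(t.recall_type == "one" for t in day8) == tiny_cfg.n_videos - n_multi

    def test_rehearsal_only_day2_day8(self, tiny_study):
        transcripts = tiny_study[2]
        for t in transcripts:
            if t.session == "day1":
                assert t.rehearsal is None
            else:
                assert 1 <= t.rehearsal <= 5

    def test_table_matches_ground_truth_mask(self, tiny_study):
        _, videos, transcripts, _, truth = tiny_study
        zmap = {k: list(v) for k, v in truth.centrality_z.items()}
        rows = build_analysis_table(transcripts, videos, zmap)
        built = pd.DataFrame(
            [(r.participant_id, r.video_id, r.event_index, r.session,
              r.recalled, r.n_central, r.n_peripheral) for r in rows],
            columns=["participant_id", "video_id", "event_index", "session",
                     "recalled", "n_central", "n_peripheral"],
        ).sort_values(["participant_id", "session", "video_id", "event_index"])
        want = truth.rows[built.columns].sort_values(
            ["participant_id", "session", "video_id", "event_index"]
        )
        pd.testing.assert_frame_equal(
            built.reset_index(drop=True), want.reset_index(drop=True)
        )

    def test_simulate_table_agrees_with_generate_study(self, tiny_cfg, tiny_study):
        table = simulate_table(tiny_cfg)
        truth_rows = tiny_study[4].rows.drop(columns=["true_prob"])
        pd.testing.assert_frame_equal(table, truth_rows)

    def test_round_trip_through_files(self, tmp_path, tiny_study):
        _, videos, transcripts, _, _ = tiny_study
        write_annotations(videos, tmp_path / "ann.json")
        write_recalls(transcripts, tmp_path / "rec.csv")
        assert len(read_annotations(tmp_path / "ann.json")) == len(videos)
        loaded = read_recalls(tmp_path / "rec.csv")
        assert len(loaded) == len(transcripts)  # every cued video survives
        for a, b in zip(loaded, transcripts):
            assert a.segments == b.segments

    def test_verbatim_recall_gives_jaccard_one(self):
        cfg = SyntheticConfig(
            seed=77, n_per_group=3, n_videos=4, events_min=4, events_max=6,
            rho=1.0, noise_words_rate=0.0,
        )
        _, _, transcripts, _, _ = generate_study(cfg)
        rows = within_participant(transcripts)
        assert rows
        assert all(r.jaccard == 1.0 for r in rows)

    def test_recall_rate_monotone_in_centrality_terciles(self):
        cfg = SyntheticConfig(seed=8, beta_centrality=0.6, events_min=12, events_max=18)
        df = simulate_table(cfg)
        terciles = pd.qcut(df["centrality_z"], 3, labels=[0, 1, 2])
        rates = df.groupby(terciles, observed=True)["recalled"].mean()
        assert rates[0] < rates[1] < rates[2]

    def test_true_probabilities_stored(self, tiny_study):
        truth = tiny_study[4]
        assert "true_prob" in truth.rows.columns
        assert ((truth.rows["true_prob"] > 0) & (truth.rows["true_prob"] < 1)).all()

    def test_ground_truth_json(self, tmp_path, tiny_study):
        import json

        truth = tiny_study[4]
        p = tmp_path / "gt.json"
        truth.to_json(p)
        data = json.loads(p.read_text())
        assert set(data) == {"config", "u_participant", "w_video", "centrality_z", "rows"}
        assert len(data["rows"]) == len(truth.rows)


class TestGenerateRater:
    def _truth(self, cfg):
        return video_boundaries(generate_videos(cfg)[0])

    def test_noise_free_rater_perfect_f1(self):
        cfg = SyntheticConfig(
            seed=4, boundary_jitter_sd_s=0.0, boundary_miss_rate=0.0, boundary_fa_rate=0.0
        )
        truth = self._truth(cfg)
        obs = generate_rater(truth, cfg)
        assert match_boundaries(truth, obs).f1 == 1.0

    def test_miss_rate_drives_recall(self, rng):
        cfg = SyntheticConfig(
            seed=4, boundary_miss_rate=0.3, boundary_jitter_sd_s=0.05,
            boundary_fa_rate=0.0, events_min=20, events_max=25,
        )
        truth = self._truth(cfg)
        recalls = [
            match_boundaries(truth, generate_rater(truth, cfg, rng=rng)).recall
            for _ in range(50)
        ]
        assert np.mean(recalls) == pytest.approx(0.7, abs=0.06)

    def test_large_jitter_degrades_f1(self, rng):
        cfg0 = SyntheticConfig(seed=4, boundary_jitter_sd_s=0.0,
                               boundary_miss_rate=0.0, boundary_fa_rate=0.0)
        cfg2 = SyntheticConfig(seed=4, boundary_jitter_sd_s=2.0,
                               boundary_miss_rate=0.0, boundary_fa_rate=0.0)
        truth = self._truth(cfg0)
        f1_clean = match_boundaries(truth, generate_rater(truth, cfg0, rng=rng)).f1
        f1_noisy = np.mean([
            match_boundaries(truth, generate_rater(truth, cfg2, rng=rng), tol_s=1.0).f1
            for _ in range(20)
        ])
        assert f1_noisy < f1_clean

    def test_output_strictly_increasing(self, rng):
        cfg = SyntheticConfig(seed=4, boundary_jitter_sd_s=1.5, boundary_fa_rate=3.0)
        truth = self._truth(cfg)
        for _ in range(20):
            obs = generate_rater(truth, cfg, rng=rng)
            t = obs.times_s
            assert all(b > a for a, b in zip(t, t[1:]))
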