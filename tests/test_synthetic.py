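"""The synthetic cohort / behavior / EP generators."""

import numpy as np
import pandas as pd
import pytest

from timemap import microstates as ms
from timemap import synthetic as syn
from timemap.behavior import CONDITIONS
from timemap.montage import read_montage, spherical_montage, write_montage


class TestMontage:
    def test_positions_on_unit_sphere_with_unique_labels(self, montage32):
        norms = np.linalg.norm(montage32.positions, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert len(set(montage32.labels)) == 32

    def test_text_roundtrip(self, tmp_path, montage32):
        path = tmp_path / "montage.sfp"
        write_montage(montage32, path)
        back = read_montage(path)
        assert back.labels == montage32.labels
        np.testing.assert_allclose(back.positions, montage32.positions, atol=1e-7)


class TestCohort:
    def test_degenerate_spec_pins_all_tpas_items_to_baseline(self):
        spec = syn.CohortSpec(
            n_subjects=5, tpas_baseline=1.0, tpas_loading=0.0,
            tpas_method_sd=0.0, tpas_item_sd=0.0, seed=0,
        )
        cohort = syn.generate_cohort(spec)
        assert all(s.tpas_score == 1.0 for s in cohort)

    def test_large_negative_intercept_silences_pas(self):
        spec = syn.CohortSpec(
            n_subjects=5, pas_intercept=-40.0, pas_loading=0.0,
            pas_method_sd=0.0, seed=0,
        )
        assert all(s.pas_score == 0 for s in syn.generate_cohort(spec))

    def test_seeded_reproducibility(self):
        a = syn.generate_cohort(syn.CohortSpec(n_subjects=20, seed=9))
        b = syn.generate_cohort(syn.CohortSpec(n_subjects=20, seed=9))
        assert a == b

    def test_score_trait_coupling_monotone_in_loading(self):
        rs = []
        for loading in (0.2, 1.0, 3.0):
            cohort = syn.generate_cohort(
                syn.CohortSpec(n_subjects=800, tpas_loading=loading, seed=3)
            )
            z = [s.trait for s in cohort]
            score = [s.tpas_score for s in cohort]
            rs.append(np.corrcoef(z, score)[0, 1])
        assert rs[0] < rs[1] < rs[2]

    def test_sex_split_follows_ratio(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=170, seed=0))
        assert sum(s.sex == "F" for s in cohort) == 85

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            syn.CohortSpec(n_subjects=10, sex_ratio=1.5)
        with pytest.raises(ValueError):
            syn.CohortSpec(n_subjects=10, tpas_loading=np.inf)


class TestBehaviorGenerator:
    def test_noise_free_trials_equal_condition_means(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=3, seed=1))
        spec = syn.BehaviorSpec(
            rt_sd_between=0.0, rt_lognormal_sigma=0.0, trait_rt_slope=0.0,
            n_trials_per_condition=8, seed=2,
        )
        trials = syn.generate_behavior(cohort, spec)
        for cond, g in trials.groupby("condition"):
            assert np.allclose(g["rt"], spec.condition_rt_means[cond])

    def test_zero_error_rates_give_all_correct(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=3, seed=1))
        spec = syn.BehaviorSpec(
            error_rates={c: 0.0 for c in CONDITIONS},
            n_trials_per_condition=8, seed=2,
        )
        assert syn.generate_behavior(cohort, spec)["correct"].all()

    def test_trials_positive_and_balanced(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=2, seed=4))
        trials = syn.generate_behavior(
            cohort, syn.BehaviorSpec(n_trials_per_condition=8, seed=5)
        )
        assert (trials["rt"] > 0).all()
        counts = trials.groupby(["subject", "condition"]).size()
        assert (counts == 8).all()
        groups = trials.groupby(["event_category", "direction"]).size()
        assert len(groups) == 4

    def test_seeded_reproducibility(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=4, seed=6))
        spec = syn.BehaviorSpec(n_trials_per_condition=6, seed=7)
        pd.testing.assert_frame_equal(
            syn.generate_behavior(cohort, spec), syn.generate_behavior(cohort, spec)
        )


class TestTemplateMaps:
    def test_single_map_zero_mean_unit_gfp(self, montage32):
        maps = syn.generate_template_maps(montage32, 1, seed=0)
        assert maps.shape == (1, 32)
        assert abs(maps[0].mean()) < 1e-12
        assert ms.gfp(maps[0][:, None]) == pytest.approx(1.0)

    def test_pairwise_orthogonality(self, montage32):
        maps = syn.generate_template_maps(montage32, 6, seed=1)
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(ms.spatial_corr(maps[i], maps[j])) < 1e-10

    def test_seeded_byte_identical(self, montage32):
        a = syn.generate_template_maps(montage32, 4, seed=5)
        b = syn.generate_template_maps(montage32, 4, seed=5)
        assert a.tobytes() == b.tobytes()

    def test_too_many_maps_rejected(self, montage32):
        with pytest.raises(ValueError):
            syn.generate_template_maps(montage32, 33, seed=0)


def _small_spec(**kw):
    defaults = dict(n_channels=24, sampling_rate=512.0, seed=0)
    defaults.update(kw)
    return syn.EPGeneratorSpec(**defaults)


class TestEvokedGenerator:
    def test_noiseless_samples_match_active_template(self, montage32):
        spec = _small_spec(n_channels=32, noise_sd=0.0)
        subject = syn.generate_cohort(syn.CohortSpec(n_subjects=2, seed=0))[0]
        templates = syn.generate_template_maps(montage32, spec.n_templates, seed=1)
        ev, truth = syn.generate_evoked(subject, "Now", spec, templates)
        for _, seg in truth.iterrows():
            a = int(seg.onset_ms * spec.sampling_rate / 1000)
            b = int(seg.offset_ms * spec.sampling_rate / 1000)
            for t in range(a, b, max((b - a) // 3, 1)):
                r = ms.spatial_corr(ev.data[:, t], templates[int(seg.template)])
                assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_zero_envelope_gives_silent_evoked(self, montage32):
        spec = _small_spec(n_channels=32, noise_sd=0.0, envelope_floor=0.0, envelope_peak=0.0)
        subject = syn.generate_cohort(syn.CohortSpec(n_subjects=2, seed=0))[0]
        templates = syn.generate_template_maps(montage32, spec.n_templates, seed=1)
        ev, _ = syn.generate_evoked(subject, "Past", spec, templates)
        assert np.abs(ev.data).max() == 0.0

    def test_average_reference_holds_at_every_sample(self, montage32):
        spec = _small_spec(n_channels=32)
        subject = syn.generate_cohort(syn.CohortSpec(n_subjects=2, seed=0))[1]
        templates = syn.generate_template_maps(montage32, spec.n_templates, seed=1)
        ev, _ = syn.generate_evoked(subject, "Future", spec, templates)
        assert np.abs(ev.data.mean(axis=0)).max() < 1e-9

    def test_ground_truth_segments_tile_the_epoch(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=3, seed=2))
        spec = _small_spec()
        _, truth, _ = syn.generate_eeg_cohort(cohort, spec)
        for (_, _), g in truth.groupby(["subject", "condition"]):
            g = g.sort_values("onset_ms")
            assert g.iloc[0].onset_ms == 0.0
            assert g.iloc[-1].offset_ms <= spec.epoch_ms[1]
            # contiguous, non-overlapping
            np.testing.assert_allclose(
                g.iloc[1:].onset_ms.to_numpy(), g.iloc[:-1].offset_ms.to_numpy()
            )

    def test_planted_duration_mean_tracks_spec(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=120, seed=3))
        spec = _small_spec(seed=4)
        _, truth, _ = syn.generate_eeg_cohort(cohort, spec)
        tm = truth[truth.is_timemap]
        for cond in CONDITIONS:
            mean = tm[tm.condition == cond]["duration_ms"].mean()
            planted = spec.timemap_duration_means[cond]
            sd = np.sqrt(
                spec.timemap_duration_resid_sd[cond] ** 2
                + spec.trait_duration_slope ** 2
            )
            assert mean == pytest.approx(planted, abs=3 * sd / np.sqrt(120) + 1.0)

    def test_seeded_reproducibility(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=2, seed=5))
        spec = _small_spec(seed=6)
        a, _, _ = syn.generate_eeg_cohort(cohort, spec)
        b, _, _ = syn.generate_eeg_cohort(cohort, spec)
        for x, y in zip(a, b):
            assert x.data.tobytes() == y.data.tobytes()

    def test_subsample_duration_clips_to_one_sample_with_warning(self, montage32):
        spec = _small_spec(
            n_channels=32,
            timemap_duration_means={"Past": 0.1, "Now": 0.1, "Future": 0.1},
            timemap_duration_resid_sd={"Past": 0.0, "Now": 0.0, "Future": 0.0},
            trait_duration_slope=0.0,
        )
        subject = syn.generate_cohort(syn.CohortSpec(n_subjects=2, seed=0))[0]
        templates = syn.generate_template_maps(montage32, spec.n_templates, seed=1)
        with pytest.warns(UserWarning, match="clipped"):
            _, truth = syn.generate_evoked(subject, "Now", spec, templates)
        tm = truth[truth.is_timemap].iloc[0]
        assert tm.duration_ms == pytest.approx(1000.0 / spec.sampling_rate)
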