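"""Topographic segmentation, model-order selection, back-fitting, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from timemap import microstates as ms
from timemap import synthetic as syn
from timemap.behavior import CONDITIONS
from timemap.montage import spherical_montage
from timemap.preprocess import Evoked


class TestGFP:
    @pytest.mark.parametrize(
        "column, expected",
        [([3.0, 3.0, 3.0], 0.0), ([1.0, -1.0], 1.0), ([2.0, 0.0], 1.0)],
    )
    def test_known_maps(self, column, expected):
        val = ms.gfp(np.array(column)[:, None])
        assert val == pytest.approx(expected)

    def test_invariant_under_average_reference_and_linear_in_scale(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((16, 40))
        g = ms.gfp(data)
        np.testing.assert_allclose(ms.gfp(data - data.mean(axis=0)), g, atol=1e-12)
        np.testing.assert_allclose(ms.gfp(3.5 * data), 3.5 * g, atol=1e-12)


class TestSpatialCorr:
    def test_scaling_and_polarity(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(12)
        assert ms.spatial_corr(v, 3 * v) == pytest.approx(1.0)
        assert ms.spatial_corr(v, -v) == pytest.approx(-1.0)
        assert ms.spatial_corr(v, -v, polarity_sensitive=False) == pytest.approx(1.0)

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            ms.spatial_corr(np.ones(5), np.arange(5.0))


def _two_template_data(n_ch=16, n_samples=40, seed=0, noise=0.0):
    mont = spherical_montage(n_ch)
    maps = syn.generate_template_maps(mont, 2, seed=seed)
    labels = (np.arange(n_samples) // 5) % 2  # alternating blocks of 5
    amps = 2.0 + np.cos(np.arange(n_samples))
    data = (maps[labels] * amps[:, None]).T
    if noise:
        data = data + noise * np.random.default_rng(seed).standard_normal(data.shape)
    return data, maps, labels


class TestSegmentation:
    def test_recovers_planted_two_template_alternation(self):
        data, maps, labels = _two_template_data()
        model = ms.MicrostateModel(data, sfreq=256.0)
        res = model.fit(n_maps=2, n_restarts=8, seed=0)
        # align fitted to planted templates
        perm = int(abs(ms.spatial_corr(res.templates[0], maps[1])) > 0.9)
        for k in range(2):
            r = ms.spatial_corr(res.templates[k], maps[(k + perm) % 2])
            assert abs(r) > 0.999
        mapped = (res.labels + perm) % 2
        np.testing.assert_array_equal(mapped, labels)
        assert res.gev > 0.999

    def test_single_template_matches_dominant_eigenvector(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((10, 30))
        data -= data.mean(axis=0)
        model = ms.MicrostateModel(data, sfreq=256.0, polarity_sensitive=False)
        res = model.fit(n_maps=1, n_restarts=1, seed=0)
        # oracle: dominant eigenvector of the sample scatter matrix
        evals, evecs = np.linalg.eigh(data @ data.T)
        v = evecs[:, -1]
        v = (v - v.mean()) / (v - v.mean()).std()
        assert abs(ms.spatial_corr(res.templates[0], v)) > 1 - 1e-9
        # explained variance vs direct eigendecomposition (GFP^2-weighted)
        top = evals[-1] / evals.sum()
        corr = ms._corr_matrix(res.templates, data)[0]
        g2 = np.sum(data**2, axis=0)
        assert res.gev == pytest.approx(np.sum(g2 * corr**2) / g2.sum(), abs=1e-9)
        assert res.gev == pytest.approx(top, abs=0.05)

    def test_tiny_instance_matches_exhaustive_labeling(self):
        # 8 samples, 4 channels, q = 2: enumerate all 2^8 labelings and score
        # each with the same objective (sum of squared correlations weighted
        # by squared map norm, optimal eigenvector template per cluster)
        rng = np.random.default_rng(7)
        data = rng.standard_normal((4, 8))
        data -= data.mean(axis=0)

        def objective(lbl):
            tot = 0.0
            for k in (0, 1):
                cols = data[:, np.array(lbl) == k]
                if cols.size == 0:
                    continue
                scatter = cols @ cols.T
                tot += np.linalg.eigvalsh(scatter)[-1]
            return tot

        best = max(
            (objective(lbl), lbl) for lbl in itertools.product((0, 1), repeat=8)
            if len(set(lbl)) == 2
        )
        model = ms.MicrostateModel(data, sfreq=256.0, polarity_sensitive=False)
        res = model.fit(n_maps=2, n_restarts=64, seed=1)
        assert objective(tuple(res.labels)) == pytest.approx(best[0], rel=1e-9)

    def test_seeded_determinism(self):
        data, _, _ = _two_template_data(noise=0.3)
        model = ms.MicrostateModel(data, sfreq=256.0)
        a = model.fit(n_maps=2, n_restarts=4, seed=11)
        b = model.fit(n_maps=2, n_restarts=4, seed=11)
        assert a.templates.tobytes() == b.templates.tobytes()

    def test_gev_nondecreasing_in_q(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((12, 30))
        model = ms.MicrostateModel(data, sfreq=256.0)
        gevs = [model.fit(n_maps=q, n_restarts=30, seed=2).gev for q in (1, 2, 3, 4)]
        assert all(b >= a - 1e-9 for a, b in zip(gevs, gevs[1:]))

    def test_templates_normalized(self):
        data, _, _ = _two_template_data(noise=0.5)
        res = ms.MicrostateModel(data, sfreq=256.0).fit(n_maps=3, n_restarts=4, seed=0)
        np.testing.assert_allclose(res.templates.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(res.templates.std(axis=1), 1.0, atol=1e-10)


class TestCrossValidation:
    def test_planted_model_order_recovered(self):
        # small noise so residual variance is positive and the penalty can
        # discriminate among orders that all fit perfectly
        data, _, _ = _two_template_data(n_ch=16, n_samples=60, noise=0.02)
        model = ms.MicrostateModel(data, sfreq=256.0)
        res = model.fit(q_range=(1, 6), n_restarts=8, seed=0)
        assert res.n_maps == 2
        sigma2_q2 = res.cv_curve.set_index("q").loc[2, "sigma2"]
        assert sigma2_q2 < 1e-3

    def test_matches_longhand_formula(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((8, 12))
        data -= data.mean(axis=0)
        templates = np.array(
            [ms.normalize_map(rng.standard_normal(8)) for _ in range(2)]
        )
        score = ms.cross_validation(templates, data)
        # long-hand: assign each sample, accumulate unexplained power
        n_ch = 8
        resid = 0.0
        for t in range(12):
            x = data[:, t]
            rs = [ms.spatial_corr(x, tpl) for tpl in templates]
            a = templates[int(np.argmax(rs))]
            a = a / np.linalg.norm(a)
            resid += x @ x - (a @ x) ** 2
        sigma2 = resid / (12 * (n_ch - 1))
        cv = sigma2 * ((n_ch - 1) / (n_ch - 1 - 2)) ** 2
        assert score.sigma2 == pytest.approx(sigma2, rel=1e-10)
        assert score.cv == pytest.approx(cv, rel=1e-10)

    def test_penalty_strictly_increasing_in_q(self):
        n_ch = 32
        factors = [((n_ch - 1) / (n_ch - 1 - q)) ** 2 for q in range(1, 10)]
        assert all(b > a for a, b in zip(factors, factors[1:]))

    def test_q_too_large_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((6, 20))
        templates = np.array(
            [ms.normalize_map(rng.standard_normal(6)) for _ in range(5)]
        )
        with pytest.raises(ValueError, match="n_channels"):
            ms.cross_validation(templates, data)


class TestBackfit:
    def _evoked_from_template(self, template, n=50, sfreq=256.0):
        amps = 1.0 + 0.5 * np.sin(np.arange(n) / 5.0)
        return Evoked(data=template[:, None] * amps[None, :], sfreq=sfreq)

    def test_pure_template_takes_whole_window(self, montage32):
        maps = syn.generate_template_maps(montage32, 3, seed=0)
        ev = self._evoked_from_template(maps[1])
        res = ms.backfit(maps, ev)
        table = res.table.set_index("template")
        assert table.loc[1, "duration_ms"] == pytest.approx(50 * 1000.0 / 256.0)
        assert table.loc[0, "duration_ms"] == 0.0
        assert np.isnan(table.loc[0, "mean_gfp"])

    def test_durations_partition_the_window(self, montage32):
        rng = np.random.default_rng(2)
        maps = syn.generate_template_maps(montage32, 4, seed=1)
        ev = Evoked(data=rng.standard_normal((32, 80)), sfreq=256.0)
        res = ms.backfit(maps, ev)
        total = res.table["duration_ms"].sum()
        assert total == pytest.approx(80 * 1000.0 / 256.0)

    def test_window_restriction(self, montage32):
        maps = syn.generate_template_maps(montage32, 2, seed=1)
        ev = self._evoked_from_template(maps[0], n=100)
        res = ms.backfit(maps, ev, window_ms=(100.0, 200.0))
        in_window = res.labels != ms.UNASSIGNED
        # half-open window: first sample at/after 100 ms, last before 200 ms
        lo = int(np.ceil(100.0 * 256.0 / 1000.0))
        hi = int(np.floor(200.0 * 256.0 / 1000.0))
        assert in_window[lo:hi].all()
        assert not in_window[:lo].any() and not in_window[hi:].any()
        with pytest.raises(ValueError, match="empty"):
            ms.backfit(maps, ev, window_ms=(100.0, 100.0))

    def test_min_duration_absorbs_short_runs(self, montage32):
        maps = syn.generate_template_maps(montage32, 2, seed=3)
        # template 0 everywhere except one isolated sample of template 1
        data = np.tile(maps[0][:, None], (1, 21)) * 2.0
        data[:, 10] = maps[1]
        ev = Evoked(data=data, sfreq=256.0)
        raw = ms.backfit(maps, ev, min_duration_samples=1)
        assert raw.labels[10] == 1
        smoothed = ms.backfit(maps, ev, min_duration_samples=3)
        assert (smoothed.labels == 0).all()

    def test_planted_cohort_durations_recovered(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=5, seed=20))
        spec = syn.EPGeneratorSpec(n_channels=32, sampling_rate=512.0, seed=21)
        evokeds, truth, templates = syn.generate_eeg_cohort(cohort, spec)
        fit = []
        for ev in evokeds:
            res = ms.backfit(templates, ev)
            t = res.table
            t.insert(0, "condition", ev.condition)
            t.insert(0, "subject", ev.subject)
            fit.append(t)
        fit = pd.concat(fit)
        tm = spec.timemap_template
        rec = fit[fit.template == tm].groupby("condition")["duration_ms"].mean()
        planted = truth[truth.is_timemap].groupby("condition")["duration_ms"].mean()
        dt = 1000.0 / spec.sampling_rate
        for cond in CONDITIONS:
            assert abs(rec[cond] - planted[cond]) <= 2 * dt


class TestDurationStatistics:
    def _fit_table(self, durations):
        rows = []
        for i, per_subject in enumerate(durations):
            for cond, d in zip(CONDITIONS, per_subject):
                rows.append(
                    {"subject": f"s{i}", "condition": cond, "template": 0,
                     "duration_ms": d, "mean_gfp": 1.0}
                )
        return pd.DataFrame(rows)

    def test_equal_durations_give_zero_f(self):
        table = self._fit_table([[50.0, 50, 50], [60, 60, 60], [70, 70, 70]])
        res = ms.duration_statistics(table)
        assert res.loc[0, "F"] == 0.0

    def test_df_for_14_subject_cohort(self):
        rng = np.random.default_rng(0)
        table = self._fit_table(rng.normal(80, 10, (14, 3)))
        res = ms.duration_statistics(table)
        assert (res.loc[0, "df1"], res.loc[0, "df2"]) == (2, 26)

    def test_type_one_error_rate_under_null_generator(self):
        # zero condition effect: equal planted means, per-cohort ANOVA on
        # back-fitted durations should reject at ~alpha
        alpha, n_rep = 0.05, 200
        null_means = {c: 80.0 for c in CONDITIONS}
        null_sd = {c: 10.0 for c in CONDITIONS}
        rejections = 0
        for rep in range(n_rep):
            cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=8, seed=1000 + rep))
            spec = syn.EPGeneratorSpec(
                n_channels=16, sampling_rate=256.0,
                timemap_duration_means=null_means,
                timemap_duration_resid_sd=null_sd,
                seed=2000 + rep,
            )
            evokeds, _, templates = syn.generate_eeg_cohort(cohort, spec)
            rows = []
            for ev in evokeds:
                t = ms.backfit(templates, ev).table
                t.insert(0, "condition", ev.condition)
                t.insert(0, "subject", ev.subject)
                rows.append(t)
            fit = pd.concat(rows)
            stats = ms.duration_statistics(fit).set_index("template")
            if stats.loc[spec.timemap_template, "p"] < alpha:
                rejections += 1
        rate = rejections / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 3 * se + 1e-12


class TestScoreCorrelations:
    def test_duration_equal_to_score_gives_r_one(self):
        rows = []
        scores = []
        for i in range(6):
            val = float(10 + i)
            scores.append({"subject": f"s{i}", "tpas_score": val, "pas_score": val})
            for cond in CONDITIONS:
                rows.append(
                    {"subject": f"s{i}", "condition": cond, "template": 0,
                     "duration_ms": val, "mean_gfp": 1.0}
                )
        out = ms.correlate_map_stats(pd.DataFrame(rows), pd.DataFrame(scores))
        r = out[(out.measure == "duration_ms") & (out.scale == "tpas_score")].iloc[0].r
        assert r == pytest.approx(1.0)

    def test_uncoupled_cohort_has_small_r(self):
        n = 200
        rng = np.random.default_rng(4)
        rows, scores = [], []
        for i in range(n):
            scores.append(
                {"subject": f"s{i}", "tpas_score": rng.normal(), "pas_score": rng.normal()}
            )
            for cond in CONDITIONS:
                rows.append(
                    {"subject": f"s{i}", "condition": cond, "template": 0,
                     "duration_ms": rng.normal(80, 10),
                     "mean_gfp": rng.normal(3, 0.5)}
                )
        out = ms.correlate_map_stats(pd.DataFrame(rows), pd.DataFrame(scores))
        assert (out["r"].abs() < 3 / np.sqrt(n)).all()


class TestParameterRecovery:
    def test_duration_mae_below_two_sampling_intervals(self):
        # full segmentation + back-fitting recovery over seeded cohorts at
        # default noise, reduced spatial/temporal resolution for speed
        errors = []
        for rep in range(20):
            cohort = syn.generate_cohort(syn.CohortSpec(n_subjects=5, seed=300 + rep))
            spec = syn.EPGeneratorSpec(
                n_channels=32, sampling_rate=512.0, seed=400 + rep
            )
            evokeds, truth, templates = syn.generate_eeg_cohort(cohort, spec)
            group = [
                Evoked(
                    np.mean([e.data for e in evokeds if e.condition == c], axis=0),
                    spec.sampling_rate, condition=c,
                )
                for c in CONDITIONS
            ]
            res = ms.MicrostateModel.from_evokeds(group).fit(
                q_range=(2, 8), n_restarts=4, seed=rep
            )
            fitted = res.backfit_cohort(evokeds)
            tm_fit = int(
                np.argmax(
                    [abs(ms.spatial_corr(t, templates[spec.timemap_template]))
                     for t in res.templates]
                )
            )
            rec = fitted[fitted.template == tm_fit].groupby("condition")["duration_ms"].mean()
            planted = truth[truth.is_timemap].groupby("condition")["duration_ms"].mean()
            errors.extend(abs(rec[c] - planted[c]) for c in CONDITIONS)
        mae = float(np.mean(errors))
        assert mae < 2 * 1000.0 / 512.0
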