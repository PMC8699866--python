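"""Summary t-test, dataset bookkeeping, TSTR harness and report writing."""

import numpy as np
import pytest

from conftest import make_band_images
from pcglvdd.classify import CNNConfig
from pcglvdd.evaluate import (
    SummaryStats,
    dataset_sizes,
    similarity_tstr,
    summary_ttest,
    write_report,
)
from pcglvdd.types import SpectrogramImage


class TestSummaryTTest:
    def test_e_wave_row_reproduced(self):
        t, df, p = summary_ttest(SummaryStats(73.81, 26.60, 30),
                                 SummaryStats(63.25, 14.07, 41))
        assert df == 69
        assert round(p, 3) == 0.034

    def test_lvef_row_highly_significant(self):
        _, _, p = summary_ttest(SummaryStats(0.45, 0.16, 30),
                                SummaryStats(0.64, 0.03, 41))
        assert p < 0.0005  # prints as 0.000

    def test_identical_groups(self):
        t, _, p = summary_ttest(SummaryStats(5.0, 1.0, 10), SummaryStats(5.0, 1.0, 10))
        assert t == 0.0 and p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(1.0, 1.0, 1)

    def test_agrees_with_raw_sample_ttest(self):
        """Pooled summary t equals scipy on raw data with those exact moments."""
        from scipy import stats

        def synth(mean, sd, n, seed):
            x = np.random.default_rng(seed).standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = synth(3.2, 1.1, 14, 0)
        b = synth(2.4, 0.9, 19, 1)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t_sum, _, p_sum = summary_ttest(SummaryStats(3.2, 1.1, 14), SummaryStats(2.4, 0.9, 19))
        assert abs(t_sum - t_raw) < 1e-9
        assert abs(p_sum - p_raw) < 1e-9

    def test_welch_flag_changes_df(self):
        _, df_w, _ = summary_ttest(SummaryStats(1.0, 2.0, 10),
                                   SummaryStats(1.5, 0.5, 40), welch=True)
        assert df_w != 48


class TestDatasetSizes:
    def test_reference_counts(self):
        sizes = dataset_sizes({"lvdd": 3677, "control": 4803})
        assert sizes["lvdd"]["ng"] == 18385
        assert sizes["control"]["ng"] == 24015
        assert sizes["lvdd"]["dcgan"] == 29416
        assert sizes["control"]["dcgan"] == 38424
        assert sizes["lvdd"]["rs_plus_dcgan"] == 33093
        assert sizes["control"]["rs_plus_dcgan"] == 43227
        assert sizes["lvdd"]["rs_plus_ng"] == 22062
        assert sizes["control"]["rs_plus_ng"] == 28818


class TestTSTR:
    def test_single_class_generated_rejected(self):
        imgs = [im for im in make_band_images(8, size=32) if im.class_label == "lvdd"]
        with pytest.raises(ValueError):
            similarity_tstr(imgs, imgs, CNNConfig(image_size=32, epochs=1))

    def test_identical_sets_upper_bound(self):
        real = make_band_images(30, size=32, seed=3)
        gen = [SpectrogramImage(im.pixels.copy(), class_label=im.class_label,
                                origin="gan_generated") for im in real]
        cfg = CNNConfig(image_size=32, epochs=10, batch_size=32, seed=0)
        acc = similarity_tstr(gen, real, cfg)
        assert acc >= 0.95  # relabelled copy of the real set is a ceiling case

    def test_noise_generator_scores_at_chance(self):
        """A classifier trained on label-free noise is at chance on real data.

        Any single noise-trained network maps the two real clusters to one
        side each, so per-seed accuracy is bimodal; the chance level emerges
        as the average over many independent training seeds.
        """
        rng = np.random.default_rng(0)
        real = make_band_images(40, size=32, seed=4)
        accs = []
        for seed in range(20):
            noise = [SpectrogramImage(rng.random((32, 32, 3)).astype(np.float32),
                                      class_label="lvdd" if i % 2 else "control",
                                      origin="gan_generated") for i in range(80)]
            cfg = CNNConfig(image_size=32, epochs=3, batch_size=32, seed=seed)
            accs.append(similarity_tstr(noise, real, cfg))
        assert abs(np.mean(accs) - 0.5) <= 0.1


@pytest.fixture(scope="module")
def sweep_setup():
    from pcglvdd.classify import make_cv_plan
    from pcglvdd.gan import GANConfig, train_dcgan

    images = make_band_images(24, size=32, seed=11, n_subjects=8)
    generators = {}
    for label in ("lvdd", "control"):
        real = [im for im in images if im.class_label == label]
        cfg = GANConfig(image_size=32, base_channels=8, batch_size=16,
                        epochs=40, seed=1 if label == "lvdd" else 2)
        generators[label], _, _ = train_dcgan(real, cfg)
    plan = make_cv_plan(images, k=4, seed=0)
    return images, generators, plan


class TestExpansionSweep:
    def test_zero_coefficient_matches_plain_cv(self, sweep_setup, monkeypatch):
        import pcglvdd.classify as C
        from pcglvdd.evaluate import expansion_sweep
        from test_classify import _oracle_predict, _oracle_trainer

        images, generators, plan = sweep_setup
        monkeypatch.setattr(C, "predict", _oracle_predict)
        cfg = CNNConfig(image_size=32)
        res = expansion_sweep(images, generators, [0], cfg, plan,
                              repetitions=2, trainer=_oracle_trainer)
        plain = C.run_cross_validation(images, [], cfg, plan,
                                       repetitions=2, trainer=_oracle_trainer)
        assert res[0].metrics == plain["summary"]
        assert res[0].n_generated == {"lvdd": 0, "control": 0}

    def test_generated_counts_per_coefficient(self, sweep_setup, monkeypatch):
        import pcglvdd.classify as C
        from pcglvdd.evaluate import expansion_sweep
        from test_classify import _oracle_predict, _oracle_trainer

        images, generators, plan = sweep_setup
        monkeypatch.setattr(C, "predict", _oracle_predict)
        n_per_class = {lab: sum(im.class_label == lab for im in images)
                       for lab in ("lvdd", "control")}
        res = expansion_sweep(images, generators, [1, 3], CNNConfig(image_size=32),
                              plan, repetitions=1, trainer=_oracle_trainer)
        for r in res:
            for lab in n_per_class:
                assert r.n_generated[lab] == r.coefficient * n_per_class[lab]

    def test_unsorted_or_empty_coefficients_rejected(self, sweep_setup):
        from pcglvdd.evaluate import expansion_sweep

        images, generators, plan = sweep_setup
        with pytest.raises(ValueError):
            expansion_sweep(images, generators, [], CNNConfig(image_size=32), plan)
        with pytest.raises(ValueError):
            expansion_sweep(images, generators, [4, 2], CNNConfig(image_size=32), plan)

    def test_gan_augmentation_not_harmful_on_separable_task(self, sweep_setup):
        from pcglvdd.evaluate import expansion_sweep

        images, generators, plan = sweep_setup
        cfg = CNNConfig(image_size=32, epochs=5, batch_size=16, seed=3)
        res = expansion_sweep(images, generators, [0, 2], cfg, plan, repetitions=2)
        acc0 = res[0].metrics["accuracy"]["mean"]
        acc2 = res[1].metrics["accuracy"]["mean"]
        assert acc2 >= acc0 - 0.05


class TestReport:
    def test_report_deterministic_and_complete(self, tmp_path):
        results = {
            "sweep": [{"coefficient": k, "accuracy": 0.8 + 0.01 * k} for k in (0, 2, 4)],
            "sizes": dataset_sizes({"lvdd": 3677, "control": 4803}),
        }
        j1, c1 = write_report(results, tmp_path, name="r1")
        j2, _ = write_report(results, tmp_path, name="r2")
        assert j1.read_text().replace("r1", "") == j2.read_text().replace("r2", "")
        text = j1.read_text()
        for k in (0, 2, 4):
            assert f'"coefficient": {k}' in text
        assert "33093" in text
        assert c1.exists()
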