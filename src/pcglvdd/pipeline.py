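"""End-to-end orchestration: simulate -> preprocess -> segment -> image ->
augment -> cross-validate -> TSTR -> report.

The pipeline is the integration surface for the whole package; the smoke
profile runs every stage at desk scale (small cohort, short recordings,
32x32 images, few epochs) in a few minutes on one CPU. A single global seed
fans out to per-stage seeds through a fixed offset table so stages stay
independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import augment as aug
from .classify import CNNConfig, make_cv_plan, run_cross_validation
from .evaluate import dataset_sizes, similarity_tstr, write_report
from .gan import GANConfig, generate_samples, train_dcgan
from .preprocess import DenoiseConfig, preprocess
from .segment import extract_frames, segment_states, train_segmenter
from .spectro import SpectrogramConfig, frame_to_image
from .synth import default_config, simulate_cohort
from .types import SpectrogramImage

log = logging.getLogger("pcglvdd")

# fixed per-stage seed offsets so the global seed fans out deterministically
_STAGE_SEED = {"synth": 1, "segment": 2, "gan": 3, "cnn": 4, "cv": 5, "tstr": 6}


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults are the smoke (desk-scale) profile."""

    n_lvdd: int = 4
    n_control: int = 4
    recording_seconds: float = 30.0
    sim_sampling_rate: float = 8000.0
    noise_snr: float = 30.0
    image_size: int = 32
    gan_epochs: int = 60
    gan_batch_size: int = 32
    gan_base_channels: int = 16
    cnn_epochs: int = 60
    cnn_batch_size: int = 32
    expansion_coefficient: int = 2
    k_folds: int = 4
    seed: int = 0
    out_dir: str = "runs/smoke"

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _STAGE_SEED[stage]) % (2**31 - 1)


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute every stage and write a JSON report; returns the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"config": asdict(cfg)}

    log.info("stage 1/7: simulating cohort (%d + %d subjects)", cfg.n_lvdd, cfg.n_control)
    base = default_config("control", duration=cfg.recording_seconds,
                          sampling_rate=cfg.sim_sampling_rate, noise_snr=cfg.noise_snr)
    cohort = simulate_cohort(cfg.n_lvdd, cfg.n_control, base, seed=cfg.stage_seed("synth"))

    log.info("stage 2/7: preprocessing to 1000 Hz")
    processed = [preprocess(rec) for rec in cohort]

    log.info("stage 3/7: training segmenter and framing")
    model = train_segmenter(cohort)
    spect_cfg = SpectrogramConfig(output_size=(cfg.image_size, cfg.image_size))
    images: List[SpectrogramImage] = []
    frames_all = []
    for rec in processed:
        states = segment_states(rec, model)
        frames = extract_frames(rec, states)
        frames_all.extend(frames)
        for fr in frames:
            images.append(frame_to_image(fr, spect_cfg))
    report["n_frames"] = len(frames_all)
    report["n_real_images"] = len(images)
    by_class: Dict[str, List[SpectrogramImage]] = {}
    for im in images:
        by_class.setdefault(im.class_label, []).append(im)
    n_real = {label: len(v) for label, v in by_class.items()}
    report["dataset_sizes"] = dataset_sizes(n_real, expansion_coefficient=cfg.expansion_coefficient)

    log.info("stage 4/7: non-generative augmentation")
    sample_frames = frames_all[:: max(1, len(frames_all) // 8)]  # keep the smoke profile quick
    ng_images = aug.augment_nongenerative_dataset(sample_frames, spectro_cfg=spect_cfg)
    report["n_nongenerative_images"] = len(ng_images)

    log.info("stage 5/7: per-class DCGAN training")
    generators = {}
    extra: List[SpectrogramImage] = []
    for label, imgs in sorted(by_class.items()):
        gan_cfg = GANConfig(image_size=cfg.image_size, epochs=cfg.gan_epochs,
                            batch_size=min(cfg.gan_batch_size, len(imgs)),
                            base_channels=cfg.gan_base_channels,
                            seed=cfg.stage_seed("gan"))
        gen, trace, _ = train_dcgan(imgs, gan_cfg)
        generators[label] = gen
        extra.extend(generate_samples(gen, cfg.expansion_coefficient * len(imgs),
                                      seed=cfg.stage_seed("gan") + 7, class_label=label))
    report["n_gan_images"] = len(extra)

    log.info("stage 6/7: subject-wise cross-validation")
    cnn_cfg = CNNConfig(image_size=cfg.image_size, epochs=cfg.cnn_epochs,
                        batch_size=cfg.cnn_batch_size, seed=cfg.stage_seed("cnn"))
    plan = make_cv_plan(images, k=cfg.k_folds, seed=cfg.stage_seed("cv"))
    cv = run_cross_validation(images, extra, cnn_cfg, plan, repetitions=cfg.k_folds)
    report["cross_validation"] = cv["summary"]

    log.info("stage 7/7: TSTR similarity")
    report["tstr_accuracy"] = similarity_tstr(extra, images, cnn_cfg)

    json_path, csv_path = write_report(report, out, name="pipeline_report")
    log.info("report written to %s", json_path)
    return json.loads(json_path.read_text())
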