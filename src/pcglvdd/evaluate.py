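"""Evaluation protocols: TSTR similarity, expansion-coefficient sweep,
summary-statistics t-test and report writing.

TSTR (train-synthetic, test-real) measures how faithful GAN samples are: a
classifier trained only on generated images is tested on real images, and
its test accuracy reflects the similarity of the two distributions. The
expansion sweep retrains the classifier with k generated images per real
image for a range of k. The t-test utility reproduces group-comparison
p-values from printed summary statistics (mean, SD, n) alone.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .classify import (
    CNNConfig,
    CVPlan,
    Metrics,
    confusion_from_predictions,
    confusion_metrics,
    predict,
    run_cross_validation,
    train_cnn,
)
from .gan import Generator, expand_dataset
from .types import SpectrogramImage, labels_of

__all__ = [
    "SummaryStats", "SweepResult", "similarity_tstr", "expansion_sweep",
    "summary_ttest", "write_report", "dataset_sizes",
]


@dataclass
class SummaryStats:
    """Printed group summary: mean, standard deviation and group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


def summary_ttest(a: SummaryStats, b: SummaryStats,
                  welch: bool = False) -> Tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Default is the pooled-variance (Student) form with df = n_a + n_b - 2;
    ``welch=True`` uses the Welch-Satterthwaite form. Returns
    (t, df, two-sided p).
    """
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch)
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return float(t), float(df), float(p)


def similarity_tstr(
    generated: Sequence[SpectrogramImage],
    real: Sequence[SpectrogramImage],
    cfg: CNNConfig,
    repeats: int = 1,
) -> float:
    """Mean test accuracy of a classifier trained on generated, tested on real."""
    if np.unique(labels_of(generated)).size < 2:
        raise ValueError("generated set must contain both classes")
    accs = []
    for r in range(repeats):
        run_cfg = CNNConfig(**{**cfg.__dict__, "seed": cfg.seed + r})
        params, _ = train_cnn(generated, [], run_cfg)
        _, pred = predict(params, real)
        accs.append(float(np.mean(pred == labels_of(real))))
    return float(np.mean(accs))


@dataclass
class SweepResult:
    coefficient: int
    metrics: Dict[str, Dict[str, float]]  # summary of run_cross_validation
    n_generated: Dict[str, int]


def expansion_sweep(
    real: Sequence[SpectrogramImage],
    generators: Dict[str, Generator],
    coefficients: Sequence[int],
    cfg: CNNConfig,
    plan: CVPlan,
    seed: int = 0,
    repetitions: Optional[int] = None,
    trainer=None,
) -> List[SweepResult]:
    """Cross-validation at each expansion coefficient k (k generated per real)."""
    if not coefficients:
        raise ValueError("empty coefficient list")
    if list(coefficients) != sorted(coefficients):
        raise ValueError("coefficients must be sorted ascending")
    by_class: Dict[str, List[SpectrogramImage]] = {}
    for im in real:
        by_class.setdefault(im.class_label, []).append(im)
    results: List[SweepResult] = []
    for k in coefficients:
        extra: List[SpectrogramImage] = []
        n_gen: Dict[str, int] = {}
        for label, imgs in sorted(by_class.items()):
            gen_imgs = expand_dataset(imgs, generators[label], k, seed=seed + k)
            n_gen[label] = len(gen_imgs)
            extra.extend(gen_imgs)
        res = run_cross_validation(real, extra, cfg, plan,
                                   trainer=trainer, repetitions=repetitions)
        results.append(SweepResult(int(k), res["summary"], n_gen))
    return results


def dataset_sizes(n_real: Dict[str, int], ng_per_frame: int = 5,
                  expansion_coefficient: int = 8) -> Dict[str, Dict[str, int]]:
    """Bookkeeping of dataset sizes per class for the three training corpora.

    Returns per-class counts of the real-sample (RS), non-generative (NG)
    and GAN-expanded datasets plus the combined RS+NG and RS+GAN totals.
    """
    out: Dict[str, Dict[str, int]] = {}
    for label, n in n_real.items():
        ng = ng_per_frame * n
        gan = expansion_coefficient * n
        out[label] = {
            "rs": n,
            "ng": ng,
            "dcgan": gan,
            "rs_plus_ng": n + ng,
            "rs_plus_dcgan": n + gan,
        }
    return out


def write_report(results: Dict[str, object], out_dir: str | Path,
                 name: str = "report") -> Tuple[Path, Path]:
    """Machine-readable JSON + human-readable CSV.

    JSON is written with sorted keys and fixed float formatting, so a rerun
    with identical inputs reproduces the bytes exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, Metrics):
            return o.__dict__
        if isinstance(o, SweepResult):
            return o.__dict__
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    canonical = json.loads(json.dumps(results, default=_default))

    def _round(obj):
        if isinstance(obj, float):
            return round(obj, 9)
        if isinstance(obj, dict):
            return {k: _round(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [_round(v) for v in obj]
        return obj

    canonical = _round(canonical)
    json_path = out / f"{name}.json"
    json_path.write_text(json.dumps(canonical, indent=2, sort_keys=True) + "\n")

    csv_path = out / f"{name}.csv"
    rows: List[Tuple[str, str]] = []

    def _flatten(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k in sorted(obj):
                _flatten(f"{prefix}.{k}" if prefix else str(k), obj[k])
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                _flatten(f"{prefix}[{i}]", v)
        else:
            rows.append((prefix, repr(obj)))

    _flatten("", canonical)
    with open(csv_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["key", "value"])
        w.writerows(rows)
    return json_path, csv_path
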