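"""Image quality control and split-shift testing.

Eight per-image metrics (mean grey, std grey, p95-p05 dynamic range,
Laplacian-variance sharpness, Shannon entropy, near-black fraction,
saturated fraction, file size) summarise brightness, contrast, sharpness,
information content, clipping and export quality. Mann-Whitney U and
two-sample Kolmogorov-Smirnov tests between the training and test splits
flag any metric whose distribution shifts across splits; a clean battery
supports attributing performance differences to the method rather than to
image-quality drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["QCRecord", "ShiftTestResult", "qc_metrics", "shift_tests", "records_to_frame", "QC_METRIC_NAMES"]

QC_METRIC_NAMES = (
    "mean_grey",
    "std_grey",
    "dyn_range_p95_p05",
    "sharpness_lapvar",
    "entropy",
    "pct_black_le5",
    "pct_white_ge250",
    "file_size_kb",
)


@dataclass(frozen=True)
class QCRecord:
    mean_grey: float
    std_grey: float
    dyn_range_p95_p05: float
    sharpness_lapvar: float
    entropy: float  # bits, in [0, 8] for 8-bit images
    pct_black_le5: float
    pct_white_ge250: float
    file_size_kb: float
    split: str = ""  # train | val | test

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_black_le5 <= 1.0 and 0.0 <= self.pct_white_ge250 <= 1.0):
            raise ValueError("pixel fractions must lie in [0, 1]")
        if self.dyn_range_p95_p05 < 0:
            raise ValueError("dynamic range must be non-negative")


@dataclass(frozen=True)
class ShiftTestResult:
    metric_name: str
    p_mwu: float
    p_ks: float
    median_iqr_by_split: Mapping[str, tuple[float, float, float]]  # (median, q1, q3)
    flagged: bool = False


def qc_metrics(image: np.ndarray, file_size_bytes: int, split: str = "") -> QCRecord:
    """Compute the eight QC metrics for one 8-bit single-channel image.

    Sharpness is the variance of the 3x3 Laplacian response
    ([[0,1,0],[1,-4,1],[0,1,0]], reflect-padded); entropy is the base-2
    Shannon entropy of the normalised 256-bin histogram; percentiles use
    the linear-interpolation definition.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel image")
    x = arr.astype(float)
    hist = np.bincount(arr.astype(np.uint8).ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    lap = ndimage.laplace(x, mode="reflect")
    return QCRecord(
        mean_grey=float(x.mean()),
        std_grey=float(x.std()),
        dyn_range_p95_p05=float(np.percentile(x, 95) - np.percentile(x, 5)),
        sharpness_lapvar=float(lap.var()),
        entropy=float(-(nz * np.log2(nz)).sum()),
        pct_black_le5=float(np.mean(x <= 5)),
        pct_white_ge250=float(np.mean(x >= 250)),
        file_size_kb=file_size_bytes / 1024.0,
        split=split,
    )


def records_to_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def shift_tests(
    train: Sequence[QCRecord],
    test: Sequence[QCRecord],
    val: Sequence[QCRecord] | None = None,
    alpha: float = 0.05,
    metrics: Sequence[str] = QC_METRIC_NAMES,
) -> list[ShiftTestResult]:
    """Train-vs-test distribution-shift tests for every QC metric.

    Two-sided Mann-Whitney U (exact for tie-free samples of size <= 8,
    normal approximation with tie correction otherwise) and two-sample KS.
    A metric is flagged when either p-value falls below ``alpha``. When the
    two groups carry identical constant values the tests are degenerate and
    p is reported as 1 with a warning.
    """
    if len(train) < 3 or len(test) < 3:
        raise ValueError("need at least 3 records per split")
    frames = {"train": records_to_frame(list(train)), "test": records_to_frame(list(test))}
    if val:
        frames["val"] = records_to_frame(list(val))
    results = []
    for metric in metrics:
        a = frames["train"][metric].to_numpy(dtype=float)
        b = frames["test"][metric].to_numpy(dtype=float)
        summaries = {name: _median_iqr(f[metric].to_numpy(dtype=float)) for name, f in frames.items()}
        if np.all(a == a[0]) and np.all(b == a[0]):
            warnings.warn(f"QC metric {metric!r}: all values tied; shift tests degenerate")
            p_mwu = p_ks = 1.0
        else:
            tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
            method = "exact" if (max(len(a), len(b)) <= 8 and tie_free) else "asymptotic"
            p_mwu = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
            ks_method = "exact" if max(len(a), len(b)) <= 8 else "asymp"
            p_ks = float(stats.ks_2samp(a, b, alternative="two-sided", method=ks_method).pvalue)
        results.append(
            ShiftTestResult(
                metric_name=metric,
                p_mwu=p_mwu,
                p_ks=p_ks,
                median_iqr_by_split=summaries,
                flagged=(p_mwu < alpha) or (p_ks < alpha),
            )
        )
    return results


def shift_tests_frame(results: Sequence[ShiftTestResult]) -> pd.DataFrame:
    """Long-format export: one row per metric with per-split median/IQR."""
    rows = []
    for r in results:
        row: dict[str, float | str | bool] = {"metric": r.metric_name}
        for split, (med, q1, q3) in r.median_iqr_by_split.items():
            row[f"{split}_median"] = med
            row[f"{split}_q1"] = q1
            row[f"{split}_q3"] = q3
        row["p_mwu"] = r.p_mwu
        row["p_ks"] = r.p_ks
        row["flagged"] = r.flagged
        rows.append(row)
    return pd.DataFrame(rows)
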