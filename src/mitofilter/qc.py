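"""Sample quality control.

Poor samples are identified before analysis from three views of the primary
quality track: the quality-score histogram, the Pearson correlation of
quality vectors between samples, and the residual sum of squares (RSS) of
each sample against the per-position mean quality baseline. Rosner's
generalized extreme studentized deviate (ESD) many-outlier procedure is run
on the RSS vector (high side) and on the mean pairwise correlation vector
(low side); a sample fails if flagged by either.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .model import Batch, PipelineConfig, SampleDataset


def quality_histogram(
    sample: SampleDataset, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of primary quality scores; returns ``(counts, bin_edges)``.

    Counts always sum to the number of primary records.
    """
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    q = sample.primary.quality
    if len(q) == 0:
        raise ValidationError("empty sample")
    hi = max(float(q.max()), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if edges[-1] <= q.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(q, bins=edges)
    return counts, edges


def quality_correlation_matrix(batch: Batch) -> np.ndarray:
    """Pearson correlation of per-position primary quality vectors.

    Symmetric with unit diagonal. A sample with zero quality variance has
    undefined correlations; they are reported as 0 with a warning.
    """
    if len(batch.samples) < 2:
        raise ValidationError("need at least 2 samples")
    Q = batch.quality_matrix()
    sd = Q.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        ids = [batch.samples[i].sample_id for i in flat]
        warnings.warn(
            f"zero quality variance in {ids}; correlations reported as 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(Q)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def rss_vs_baseline(batch: Batch) -> np.ndarray:
    """Per-sample sum of squared deviations from the per-position mean
    quality across samples."""
    if len(batch.samples) < 2:
        raise ValidationError("need at least 2 samples")
    Q = batch.quality_matrix()
    baseline = Q.mean(axis=0)
    return ((Q - baseline) ** 2).sum(axis=1)


def gsd_outliers(
    values: Sequence[float], max_k: int | None = None, alpha: float = 0.05
) -> set[int]:
    """Rosner's generalized ESD many-outlier procedure.

    Iteratively removes the point with the largest studentized deviation
    ``R_i = max|x - mean| / sd`` and compares each ``R_i`` against its
    critical value from the t-distribution at level ``alpha``; the outliers
    are the first ``i*`` removals where ``i*`` is the largest step with
    ``R_i > lambda_i``. Returns the set of flagged indices (possibly empty).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n <= 2:
        raise ValidationError("generalized ESD needs n >= 3")
    if max_k is None:
        max_k = math.ceil(0.2 * n)
    if max_k <= 0:
        raise ValidationError("max_k must be positive")
    if max_k >= n:
        raise ValidationError("max_k must be smaller than n")
    max_k = min(max_k, n - 2)  # t critical value needs n - i - 1 >= 1
    if np.ptp(x) == 0:
        return set()
    remaining = list(range(n))
    removed: list[int] = []
    R: list[float] = []
    lam: list[float] = []
    for i in range(1, max_k + 1):
        sub = x[remaining]
        mu = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - mu)
        j = int(np.argmax(dev))
        R.append(float(dev[j] / sd))
        ni = n - i + 1  # sample size at this step
        p = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(p, ni - 2)
        lam.append((ni - 1) * t / math.sqrt((ni - 2 + t**2) * ni))
        removed.append(remaining.pop(j))
    n_out = 0
    for i, (r, l) in enumerate(zip(R, lam), start=1):
        if r > l:
            n_out = i
    return set(removed[:n_out])


@dataclass
class QCReport:
    sample_ids: list[str]
    initial_call_rate: np.ndarray
    mean_pairwise_correlation: np.ndarray
    rss: np.ndarray
    rss_outlier: np.ndarray
    correlation_outlier: np.ndarray
    verdict: np.ndarray  # True = pass
    correlation_matrix: np.ndarray

    @property
    def passing_ids(self) -> list[str]:
        return [s for s, v in zip(self.sample_ids, self.verdict) if v]

    @property
    def failing_ids(self) -> list[str]:
        return [s for s, v in zip(self.sample_ids, self.verdict) if not v]

    def to_dict(self) -> dict:
        return {
            "samples": [
                {
                    "sample_id": s,
                    "initial_call_rate": float(self.initial_call_rate[i]),
                    "mean_pairwise_correlation": float(
                        self.mean_pairwise_correlation[i]
                    ),
                    "rss": float(self.rss[i]),
                    "rss_outlier": bool(self.rss_outlier[i]),
                    "correlation_outlier": bool(self.correlation_outlier[i]),
                    "verdict": "pass" if self.verdict[i] else "fail",
                }
                for i, s in enumerate(self.sample_ids)
            ],
            "correlation_matrix": self.correlation_matrix.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def qc_gate(batch: Batch, cfg: PipelineConfig | None = None) -> QCReport:
    """Flag poor samples via the ESD procedure on RSS (high side) and on the
    mean pairwise quality correlation (low side)."""
    cfg = cfg or PipelineConfig()
    n = len(batch.samples)
    if n < 3:
        raise ValidationError("qc_gate needs at least 3 samples")
    Q = batch.quality_matrix()
    icr = (Q >= cfg.q_call_floor).mean(axis=1)
    corr = quality_correlation_matrix(batch)
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    mean_corr = np.nanmean(off, axis=1)
    rss = rss_vs_baseline(batch)
    max_k = max(1, math.ceil(cfg.gsd_max_fraction * n))

    rss_flags = gsd_outliers(rss, max_k=max_k, alpha=cfg.gsd_alpha)
    rss_out = np.zeros(n, dtype=bool)
    for i in rss_flags:
        if rss[i] > rss.mean():  # only high-RSS removals count
            rss_out[i] = True

    corr_flags = gsd_outliers(mean_corr, max_k=max_k, alpha=cfg.gsd_alpha)
    corr_out = np.zeros(n, dtype=bool)
    for i in corr_flags:
        if mean_corr[i] < mean_corr.mean():  # only low-correlation removals
            corr_out[i] = True

    verdict = ~(rss_out | corr_out)
    return QCReport(
        sample_ids=batch.sample_ids,
        initial_call_rate=icr,
        mean_pairwise_correlation=mean_corr,
        rss=rss,
        rss_outlier=rss_out,
        correlation_outlier=corr_out,
        verdict=verdict,
        correlation_matrix=corr,
    )


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_quality_histogram(sample: SampleDataset, bin_width: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges = quality_histogram(sample, bin_width)
    fig, ax = plt.subplots()
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
    ax.set_xlabel("quality score")
    ax.set_ylabel("bases")
    ax.set_title(sample.sample_id)
    fig.savefig(path)
    plt.close(fig)


def plot_correlation_heatmap(report: QCReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    im = ax.imshow(report.correlation_matrix, vmin=-1, vmax=1, cmap="viridis")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xticks(range(len(report.sample_ids)))
    ax.set_yticks(range(len(report.sample_ids)))
    ax.set_xticklabels(report.sample_ids, rotation=90, fontsize=6)
    ax.set_yticklabels(report.sample_ids, fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_rss(report: QCReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    colors = ["tab:red" if f else "tab:blue" for f in report.rss_outlier]
    ax.bar(report.sample_ids, report.rss, color=colors)
    ax.set_ylabel("RSS vs baseline")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
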