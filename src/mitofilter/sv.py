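"""Large-deletion detection by moving-window statistics.

Deleted mtDNA segments leave no template for the tiled probes, so both the
base-call quality scores and the highest probe intensities collapse across
the deleted span. A centred moving average of the per-position primary
quality (25 bp window by default) is compared against a cutoff pooled from
deletion-free samples (mean − 3 SD); maximal runs of window means strictly
below the cutoff are reported as deletions. A 50 bp scan of the highest
probe intensity provides corroborating evidence; the quality channel is
authoritative.

Spans are half-open ``(start, end]``: ``start`` is the last retained
position, ``end`` the last deleted one, so ``length == end - start``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .model import SampleDataset


@dataclass(frozen=True)
class DeletionCall:
    """A genomic span flagged as deleted, half-open ``(start, end]``."""

    start: int
    end: int
    min_window_mean: float
    cutoff_used: float
    channel: str = "quality"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("deletion span must satisfy end > start")
        if not self.min_window_mean < self.cutoff_used:
            raise ValidationError("min window mean must lie below the cutoff")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """Overlap with another half-open span ``(start, end]``."""
        return self.start < end and start < self.end


@dataclass
class SensitivityCurve:
    """Detection sensitivity of the deletion scan per deletion size."""

    sizes: list[int]
    detected: list[int]
    replicates: int

    @property
    def sensitivity(self) -> list[float]:
        return [d / self.replicates for d in self.detected]

    def to_rows(self) -> list[dict]:
        return [
            {"size": s, "replicates": self.replicates, "detected": d,
             "sensitivity": d / self.replicates}
            for s, d in zip(self.sizes, self.detected)
        ]


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Centred moving mean with truncated windows at the edges.

    Output has the same length as the input; near the edges the mean is taken
    over however much of the window lies inside the series. Windows never
    wrap the origin (the scan is linear).
    """
    x = np.asarray(series, dtype=float)
    if window <= 0:
        raise ValidationError("window must be positive")
    if window > len(x):
        raise ValidationError("window larger than the series")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def deletion_cutoff(
    clean_samples: Sequence[SampleDataset], multiplier: float = 3.0
) -> float:
    """Pooled primary-quality mean − ``multiplier`` × SD over deletion-free
    samples."""
    if not clean_samples:
        raise ValidationError("deletion_cutoff needs at least one sample")
    pooled = np.concatenate([s.primary.quality for s in clean_samples])
    return float(pooled.mean() - multiplier * pooled.std(ddof=1))


def _series(sample: SampleDataset, channel: str) -> np.ndarray:
    block = sample.primary
    if channel == "quality":
        return block.quality
    if channel == "intensity":
        return np.maximum(block.sense.max(axis=1), block.antisense.max(axis=1))
    raise ValidationError(f"unknown channel {channel!r}")


def detect_deletions(
    sample: SampleDataset,
    cutoff: float,
    window: int = 25,
    channel: str = "quality",
) -> list[DeletionCall]:
    """Scan one sample for deletions.

    Positions whose centred window mean falls strictly below ``cutoff`` are
    "low"; maximal runs of consecutive low positions become calls with
    ``start = first low position − 1`` and ``end = last low position``
    (half-open convention). Runs are broken at gaps in the interrogable
    positions. Calls are returned sorted and disjoint.
    """
    block = sample.primary
    series = _series(sample, channel)
    ma = moving_average(series, window)
    low = np.flatnonzero(ma < cutoff)
    calls: list[DeletionCall] = []
    if len(low) == 0:
        return calls
    pos = block.positions
    # break runs at index gaps or genomic gaps
    breaks = np.flatnonzero((np.diff(low) > 1) | (np.diff(pos[low]) > 1))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(low) - 1]])
    for a, b in zip(starts, ends):
        run = low[a : b + 1]
        calls.append(
            DeletionCall(
                start=int(pos[run[0]]) - 1,
                end=int(pos[run[-1]]),
                min_window_mean=float(ma[run].min()),
                cutoff_used=float(cutoff),
                channel=channel,
            )
        )
    return calls


def deletion_sensitivity(
    cfg,
    sizes: Sequence[int],
    reps: int = 200,
    window: int = 25,
    n_cutoff_samples: int = 8,
    multiplier: float = 3.0,
) -> SensitivityCurve:
    """Estimate detection sensitivity by simulation.

    The cutoff is precomputed once from ``n_cutoff_samples`` clean synthetic
    samples. For each size and replicate, a fresh clean sample is generated,
    a deletion of that size is injected at a uniformly random interrogable
    location, the scan is run, and the replicate scores as detected iff some
    call overlaps the injected span. Fully reproducible from ``cfg.seed``.

    Parameters
    ----------
    cfg:
        A :class:`~mitofilter.simulate.GeneratorConfig`; its intensity and
        quality parameters define the simulation conditions.
    """
    from .simulate import GeneratorConfig, SampleSpec, _generate_sample, _delete_span

    if not isinstance(cfg, GeneratorConfig):
        raise ValidationError("cfg must be a GeneratorConfig")
    layout = cfg.resolved_layout()
    genome = layout.genome_length
    for size in sizes:
        if size < 1 or size > genome:
            raise ValidationError(f"deletion size {size} outside [1, {genome}]")
    rng = np.random.default_rng(cfg.seed)
    reference = cfg.resolved_reference(rng)
    clean = SampleSpec("clean")

    pool = [
        _generate_sample(layout, reference, clean, cfg, rng)
        for _ in range(n_cutoff_samples)
    ]
    cutoff = deletion_cutoff(pool, multiplier)

    # valid deletion starts: every deleted position start+1 .. start+size
    # must be interrogable
    runs_ok: dict[int, np.ndarray] = {}

    def valid_starts(size: int) -> np.ndarray:
        if size not in runs_ok:
            # a start value of s deletes positions s+1..s+size, i.e. mask
            # indices s..s+size-1
            csum = np.concatenate([[0], np.cumsum(layout.interrogable_mask)])
            counts = csum[size:] - csum[:-size]
            runs_ok[size] = np.flatnonzero(counts == size)
        return runs_ok[size]

    detected = []
    for size in sizes:
        starts = valid_starts(size)
        if len(starts) == 0:
            raise ValidationError(f"no interrogable run of length {size}")
        hits = 0
        for _ in range(reps):
            sample = _generate_sample(layout, reference, clean, cfg, rng)
            start = int(rng.choice(starts))
            span = (start, start + size)
            _delete_span(sample, span, cfg, rng)
            calls = detect_deletions(sample, cutoff, window)
            if any(c.overlaps(*span) for c in calls):
                hits += 1
        detected.append(hits)
    return SensitivityCurve(sizes=list(sizes), detected=detected, replicates=reps)
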