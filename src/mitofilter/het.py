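"""Heteroplasmy detection and load quantitation.

At a heteroplasmic position two probes carry true signal, so the highest and
second-highest intensities are close to each other while the second-highest
is far from the lowest. The per-position statistic

    log[(I_highest / I_second) / (I_second / I_lowest)]

(natural log, strand-summed intensities) is therefore strongly negative at
heteroplasmic sites and positive at clean homoplasmic ones. Candidates are
positions extreme in the left tail both within their sample and across
samples at the same position (mean − 3 SD in both views), then pass a
four-step filter: (1) the double 3σ cutoff, (2) strand agreement of the
highest-intensity base, (3) disagreement between the haploid- and
diploid-model calls, (4) no immediately adjacent variant call.

The allele load of a surviving site is quantified from the major/minor
intensity ratio per strand, combined as the geometric mean r̄ and converted
to the major allele's abundance 100·r̄/(1+r̄).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .model import BASES, Batch, PipelineConfig, PositionRecord
from .calling import BaseCallTrack


@dataclass(frozen=True)
class HetCandidate:
    """A (sample, position) pair passing the double 3σ screen."""

    sample_id: str
    position: int
    statistic: float
    z_within: float
    z_across: float


@dataclass(frozen=True)
class HeteroplasmyCall:
    sample_id: str
    position: int
    major_allele: str
    minor_allele: str
    rbar: float
    major_fraction_pct: float
    filter_trail: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.major_fraction_pct < 100:
            raise ValidationError("major fraction must lie in (0, 100)")


def _statistic_from_sums(sums: np.ndarray) -> np.ndarray:
    """Vectorised statistic for (n, 4) strand-summed intensities."""
    srt = np.sort(sums, axis=1)
    return np.log((srt[:, 3] / srt[:, 2]) / (srt[:, 2] / srt[:, 0]))


def het_statistic(record: PositionRecord) -> float:
    """Left-tail heteroplasmy statistic of one record (strand-summed)."""
    sums = (record.sense.as_array() + record.antisense.as_array())[None, :]
    return float(_statistic_from_sums(sums)[0])


def sample_statistics(batch: Batch) -> np.ndarray:
    """(n_samples, n_positions) statistic matrix over primary records."""
    rows = []
    for s in batch.samples:
        block = s.primary
        rows.append(_statistic_from_sums(block.sense + block.antisense))
    return np.stack(rows)


def het_candidates(
    batch: Batch,
    cfg: PipelineConfig | None = None,
    within_sample_only: bool = False,
) -> list[HetCandidate]:
    """Screen every interrogable position of every sample.

    A candidate must lie at or below mean − ``het_sd_multiplier``·SD of its
    sample's statistic distribution and of the cross-sample distribution at
    its position (computed leave-one-out, the tested sample excluded).
    Positions are additionally required to lie strictly below the mean, so a
    zero-variance (noise-free homoplasmic) batch yields no candidates.

    With fewer than 3 samples cross-sample moments are unsupported; pass
    ``within_sample_only=True`` to screen on the within-sample tail alone.
    """
    cfg = cfg or PipelineConfig()
    n = len(batch.samples)
    if n < 3 and not within_sample_only:
        raise ValidationError(
            "cross-sample moments need at least 3 samples; rerun with "
            "within_sample_only=True to screen within samples only"
        )
    k = cfg.het_sd_multiplier
    stats_mat = sample_statistics(batch)
    positions = batch.samples[0].primary.positions

    mu_s = stats_mat.mean(axis=1, keepdims=True)
    sd_s = stats_mat.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_within = (stats_mat - mu_s) / sd_s
    within = (stats_mat <= mu_s - k * sd_s) & (stats_mat < mu_s)

    if within_sample_only or n < 3:
        keep = within
        z_across = np.full_like(stats_mat, np.nan)
    else:
        # leave-one-out positional moments
        tot = stats_mat.sum(axis=0)
        tot2 = (stats_mat**2).sum(axis=0)
        loo_mean = (tot - stats_mat) / (n - 1)
        loo_var = (tot2 - stats_mat**2 - (n - 1) * loo_mean**2) / (n - 2)
        loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z_across = (stats_mat - loo_mean) / loo_sd
        across = (stats_mat <= loo_mean - k * loo_sd) & (stats_mat < loo_mean)
        keep = within & across

    out: list[HetCandidate] = []
    for i, j in zip(*np.nonzero(keep)):
        out.append(
            HetCandidate(
                sample_id=batch.samples[i].sample_id,
                position=int(positions[j]),
                statistic=float(stats_mat[i, j]),
                z_within=float(z_within[i, j]),
                z_across=float(z_across[i, j]),
            )
        )
    return out


def het_level(
    record: PositionRecord, major: str, minor: str, method: str = "geometric"
) -> float:
    """Major-allele abundance (percent) from per-strand intensity ratios.

    The two strand ratios I_major/I_minor are combined as their geometric
    mean r̄ (``method="product"`` keeps the raw product instead); the
    abundance is 100·r̄/(1+r̄).
    """
    if major == minor:
        raise ValidationError("major and minor alleles must differ")
    rbar = _rbar(record, major, minor, method)
    return 100.0 * rbar / (1.0 + rbar)


def _rbar(record: PositionRecord, major: str, minor: str, method: str) -> float:
    i, j = BASE_IDX[major], BASE_IDX[minor]
    s = record.sense.as_array()
    a = record.antisense.as_array()
    product = (s[i] / s[j]) * (a[i] / a[j])
    if method == "geometric":
        return float(math.sqrt(product))
    if method == "product":
        return float(product)
    raise ValidationError(f"unknown method {method!r}")


BASE_IDX = {b: i for i, b in enumerate(BASES)}


def filter_het(
    candidates: Sequence[HetCandidate],
    tracks: Mapping[str, BaseCallTrack],
    batch: Batch,
    cfg: PipelineConfig | None = None,
    level_method: str = "geometric",
) -> list[HeteroplasmyCall]:
    """Apply filter steps 2-4 to screened candidates and quantify survivors.

    Step 2 removes candidates whose two strands disagree on the
    highest-intensity base; step 3 requires the haploid- and diploid-model
    calls to differ (skipped with a warning flag when the diploid call is
    missing); step 4 removes candidates immediately adjacent (distance 1) to
    a variant call in the sample's refined track.
    """
    cfg = cfg or PipelineConfig()
    reference = batch.reference
    out: list[HeteroplasmyCall] = []
    for c in candidates:
        sample = batch.sample(c.sample_id)
        rec = sample.record(c.position)
        trail: dict[str, object] = {"extreme_3sd": True}

        s = rec.sense.as_array()
        a = rec.antisense.as_array()
        strand_ok = int(np.argmax(s)) == int(np.argmax(a))
        trail["strand_concordant"] = strand_ok
        if not strand_ok:
            continue

        if rec.diploid_call in ("", "?", None):
            trail["model_discordant"] = None
            warnings.warn(
                f"{c.sample_id} position {c.position}: diploid call missing, "
                "model-discordance step skipped"
            )
        else:
            discordant = rec.haploid_call != rec.diploid_call
            trail["model_discordant"] = discordant
            if not discordant:
                continue

        track = tracks.get(c.sample_id)
        adjacent = False
        if track is not None:
            for p in (c.position - 1, c.position + 1):
                if 1 <= p <= len(reference) and track.has_position(p):
                    call = track.call_at(p)
                    if call != "N" and call != reference[p - 1]:
                        adjacent = True
        trail["not_adjacent_snp"] = not adjacent
        if adjacent:
            continue

        sums = s + a
        order = np.argsort(sums)
        major = BASES[int(order[-1])]
        minor = BASES[int(order[-2])]
        rbar = _rbar(rec, major, minor, level_method)
        out.append(
            HeteroplasmyCall(
                sample_id=c.sample_id,
                position=c.position,
                major_allele=major,
                minor_allele=minor,
                rbar=rbar,
                major_fraction_pct=100.0 * rbar / (1.0 + rbar),
                filter_trail=trail,
            )
        )
    return out
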