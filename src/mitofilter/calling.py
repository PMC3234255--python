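"""Base-call refinement.

Two stages operate on the array software's haploid calls:

1. *Signal-to-noise refinement* — per position, the ratio of the highest to
   second-highest probe intensity (taken conservatively as the minimum over
   the two strands, requiring both strands to agree on the top base) rescues
   non-calls when it exceeds a noise-derived threshold, and demotes variant
   calls that are low quality (< 12) or low SNR (< threshold) back to "N".
2. *Redundant-probe consolidation* — in regions tiled by several probe sets,
   a majority vote over all calls with quality above the call floor decides
   the base; two-way vote ties are broken by a rank-sum test on the two
   groups' quality scores, and unresolvable ties are flagged as potential
   heteroplasmy.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .model import (
    BASES,
    ArrayLayout,
    PipelineConfig,
    PositionRecord,
    ProbeBlock,
    SampleDataset,
)

#: Provenance labels carried by :class:`BaseCallTrack`.
PROVENANCE = (
    "primary",
    "rescued",
    "demoted_quality",
    "demoted_snr",
    "consolidated",
    "het_flagged",
)


@dataclass
class BaseCallTrack:
    """Final per-position calls of one sample, with provenance."""

    sample_id: str
    positions: np.ndarray  # 1-based, sorted, interrogable positions
    final_call: np.ndarray  # '<U1', one of A/C/G/T/N
    provenance: np.ndarray  # '<U16', see PROVENANCE
    snr: np.ndarray  # combined signal-to-noise ratio per position
    quality: np.ndarray  # primary probe-set quality per position
    _index: dict | None = field(default=None, repr=False, compare=False)

    def index_of(self, position: int) -> int:
        if self._index is None:
            self._index = {int(p): i for i, p in enumerate(self.positions)}
        try:
            return self._index[int(position)]
        except KeyError:
            raise ValidationError(f"position {position} not in track") from None

    def call_at(self, position: int) -> str:
        return str(self.final_call[self.index_of(position)])

    def has_position(self, position: int) -> bool:
        if self._index is None:
            self.index_of(int(self.positions[0]))
        return int(position) in self._index


@dataclass(frozen=True)
class ConsensusSequence:
    """Full-genome consensus with N at non-called/non-interrogable positions."""

    sample_id: str
    sequence: str


@dataclass(frozen=True)
class VariantCall:
    position: int
    ref: str
    alt: str
    quality: float
    snr: float

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValidationError(f"variant ALT equals REF at position {self.position}")


# ---------------------------------------------------------------------------
# signal-to-noise ratio
# ---------------------------------------------------------------------------

def _strand_top(intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row top-base index and highest/second-highest ratio for (n,4) data."""
    order = np.argsort(intensities, axis=1)
    n = len(intensities)
    rows = np.arange(n)
    top = order[:, -1]
    second = order[:, -2]
    ratio = intensities[rows, top] / intensities[rows, second]
    return ratio, top


def block_snr(block: ProbeBlock) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised combined SNR over a probe block.

    Returns ``(ratio, top_base)`` arrays; ``top_base`` is ``""`` where the
    two strands disagree on the highest-intensity base.
    """
    rs, ts = _strand_top(block.sense)
    ra, ta = _strand_top(block.antisense)
    ratio = np.minimum(rs, ra)
    bases = np.array(BASES)
    top = np.where(ts == ta, bases[ts], "")
    return ratio, top


def combined_snr(record: PositionRecord) -> tuple[float, str | None]:
    """Highest/second-highest intensity ratio combined across strands.

    Per strand the ratio is highest/second-highest; the combined ratio is the
    minimum of the two strand ratios. The top base is defined only when both
    strands agree on the highest-intensity base; otherwise ``None``.
    """
    sense = record.sense.as_array()[None, :]
    anti = record.antisense.as_array()[None, :]
    rs, ts = _strand_top(sense)
    ra, ta = _strand_top(anti)
    ratio = float(min(rs[0], ra[0]))
    if ts[0] != ta[0]:
        return ratio, None
    return ratio, BASES[int(ts[0])]


def snr_threshold_from_noise(
    noise_ratios: Sequence[float], multiplier: float = 4.0
) -> float:
    """Noise-derived SNR threshold: median + multiplier × SD of the
    inter-quartile values (the ratios lying within [Q1, Q3])."""
    x = np.asarray(noise_ratios, dtype=float)
    if len(x) < 4:
        raise ValidationError("need at least 4 noise ratios")
    q1, q3 = np.percentile(x, [25, 75])
    inner = x[(x >= q1) & (x <= q3)]
    sd = float(np.std(inner, ddof=1)) if len(inner) > 1 else 0.0
    return float(np.median(x) + multiplier * sd)


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def refine_calls(
    sample: SampleDataset,
    reference: str,
    cfg: PipelineConfig | None = None,
    prior: BaseCallTrack | None = None,
) -> BaseCallTrack:
    """Refine a sample's primary calls.

    Steps, in order: (1) the initial call is the haploid call where quality
    ≥ ``q_call_floor``, else N; (2) N calls whose combined SNR exceeds
    ``snr_threshold`` with strand-consistent top base are *rescued* to that
    base; (3) non-rescued calls differing from the reference with quality
    below ``q_variant_floor`` are demoted to N; (4) remaining non-rescued
    calls differing from the reference with combined SNR below
    ``snr_threshold`` are demoted to N.

    ``prior`` enables provenance-aware reprocessing: positions previously
    demoted stay N (they are not re-rescued) and previously rescued positions
    keep their rescue, which makes refinement idempotent.
    """
    cfg = cfg or PipelineConfig()
    block = sample.primary
    n = len(block)
    if len(reference) < int(block.positions.max(initial=0)):
        raise ValidationError("reference shorter than the sample's positions")
    ref = np.frombuffer(reference.upper().encode(), dtype="S1").astype("<U1")[
        block.positions - 1
    ]
    snr, top = block_snr(block)
    quality = block.quality

    call = np.where(quality >= cfg.q_call_floor, block.haploid_call, "N").astype("<U1")
    prov = np.full(n, "primary", dtype="<U16")

    rescued = (call == "N") & (snr > cfg.snr_threshold) & (top != "")
    call[rescued] = top[rescued].astype("<U1")
    prov[rescued] = "rescued"

    is_variant = (call != "N") & (call != ref)
    demote_q = ~rescued & is_variant & (quality < cfg.q_variant_floor)
    call[demote_q] = "N"
    prov[demote_q] = "demoted_quality"

    is_variant = (call != "N") & (call != ref)
    demote_s = ~rescued & is_variant & (snr < cfg.snr_threshold)
    call[demote_s] = "N"
    prov[demote_s] = "demoted_snr"

    if prior is not None:
        if not np.array_equal(prior.positions, block.positions):
            raise ValidationError("prior track does not cover the same positions")
        keep_demoted = np.isin(prior.provenance, ("demoted_quality", "demoted_snr"))
        call[keep_demoted] = "N"
        prov[keep_demoted] = prior.provenance[keep_demoted]
        keep_rescued = prior.provenance == "rescued"
        call[keep_rescued] = prior.final_call[keep_rescued]
        prov[keep_rescued] = "rescued"

    return BaseCallTrack(
        sample_id=sample.sample_id,
        positions=block.positions.copy(),
        final_call=call,
        provenance=prov,
        snr=snr,
        quality=quality.copy(),
    )


def call_rate(track: BaseCallTrack, layout: ArrayLayout) -> float:
    """Fraction of interrogable positions with a final call other than N."""
    if len(track.positions) != layout.n_interrogable:
        raise ValidationError(
            f"track covers {len(track.positions)} positions; layout has "
            f"{layout.n_interrogable} interrogable positions"
        )
    return float(np.count_nonzero(track.final_call != "N") / layout.n_interrogable)


# ---------------------------------------------------------------------------
# rank-sum test and redundant-probe consolidation
# ---------------------------------------------------------------------------

def rank_sum_p(
    xs: Sequence[float], ys: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration of all rank assignments (midranks for ties) when the
    pooled size is ≤ 10 or ``method="exact"``; otherwise the tie-corrected
    normal approximation (Mann-Whitney U).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) == 0 or len(ys) == 0:
        raise ValidationError("rank_sum_p requires two nonempty groups")
    n, m = len(xs), len(ys)
    total = n + m
    if method == "auto":
        method = "exact" if total <= 10 else "normal"
    if method == "exact":
        ranks = stats.rankdata(np.concatenate([xs, ys]))
        w_obs = ranks[:n].sum()
        mu = n * (total + 1) / 2.0
        dev = abs(w_obs - mu)
        count = 0
        n_comb = 0
        for idx in itertools.combinations(range(total), n):
            w = ranks[list(idx)].sum()
            n_comb += 1
            if abs(w - mu) >= dev - 1e-9:
                count += 1
        return count / n_comb
    if method != "normal":
        raise ValidationError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
    return float(min(1.0, res.pvalue))


def consolidate_redundant(
    records: Sequence[PositionRecord], cfg: PipelineConfig | None = None
) -> tuple[str, bool]:
    """Majority vote over redundant probe sets at one position.

    Votes are the haploid calls of all records with quality strictly above
    ``q_call_floor`` (N never votes). A unique plurality wins. A two-way tie
    is broken by the rank-sum test on the two groups' quality scores: if
    p < ``rank_alpha`` the group with the higher mean quality wins, otherwise
    the position is called N and flagged as potentially heteroplasmic. Ties
    among three or more bases are flagged directly.
    """
    cfg = cfg or PipelineConfig()
    if not records:
        raise ValidationError("consolidate_redundant needs at least one record")
    positions = {r.position for r in records}
    if len(positions) != 1:
        raise ValidationError(f"records span multiple positions: {sorted(positions)}")
    votes: dict[str, list[float]] = {}
    for r in records:
        if r.quality > cfg.q_call_floor and r.haploid_call in BASES:
            votes.setdefault(r.haploid_call, []).append(r.quality)
    if not votes:
        return "N", False
    top_count = max(len(v) for v in votes.values())
    leaders = sorted(b for b, v in votes.items() if len(v) == top_count)
    if len(leaders) == 1:
        return leaders[0], False
    if len(leaders) == 2:
        a, b = leaders
        p = rank_sum_p(votes[a], votes[b])
        if p < cfg.rank_alpha:
            return (a if np.mean(votes[a]) >= np.mean(votes[b]) else b), False
        return "N", True
    return "N", True


# ---------------------------------------------------------------------------
# consensus and variants
# ---------------------------------------------------------------------------

def consensus_and_variants(
    track: BaseCallTrack, reference: str
) -> tuple[ConsensusSequence, list[VariantCall]]:
    """Project a track onto the genome and list calls that differ from the
    reference."""
    L = len(reference)
    if int(track.positions.max(initial=0)) > L:
        raise ValidationError("track positions exceed reference length")
    seq = np.full(L, "N", dtype="<U1")
    seq[track.positions - 1] = track.final_call
    ref = np.frombuffer(reference.upper().encode(), dtype="S1").astype("<U1")[
        track.positions - 1
    ]
    differs = (track.final_call != "N") & (track.final_call != ref)
    variants = [
        VariantCall(
            position=int(track.positions[i]),
            ref=str(ref[i]),
            alt=str(track.final_call[i]),
            quality=float(track.quality[i]),
            snr=float(track.snr[i]),
        )
        for i in np.flatnonzero(differs)
    ]
    return ConsensusSequence(track.sample_id, "".join(seq)), variants
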