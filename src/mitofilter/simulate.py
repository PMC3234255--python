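"""Synthetic array-data generator with known ground truth.

The generator emulates the probe-level export of a tiling resequencing
array. Per position, per strand, the four base probes fluoresce at

    E = S * f_b + B,        I = E * exp(sigma_I * Z)

where ``S`` is the full-signal level, ``B`` the background, ``f_b`` the
fraction of allele ``b`` in the sample's true genotype (1 for the
homoplasmic base; ``f`` and ``1-f`` for a heteroplasmic pair; 0 otherwise;
0 for every base across a deleted span), and the noise is log-normal and
independent per probe.

Quality scores are generated directly, not derived from the intensities, so
QC and deletion-scan behaviour is controlled by explicit parameters:
clean positions ~ Normal(30, 5) clipped to [0, 45], deleted positions
~ Normal(1.5, 1) clipped at 0, and degraded (QC-outlier) samples
~ Normal(18, 8) genome-wide with a low-quality peak. The clean/degraded SD
is split into a per-position probe effect shared by all samples (SD 3) plus
an independent component, so that sample-sample quality correlations carry
signal while the marginal distribution keeps the stated mean and SD. An
optional mode derives quality from intensities instead.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .model import (
    BASES,
    IUPAC2,
    ArrayLayout,
    Batch,
    ProbeBlock,
    SampleDataset,
)


@dataclass
class SampleSpec:
    """Ground-truth description of one simulated sample.

    ``variants`` are homoplasmic substitutions ``(position, alt_base)``;
    ``heteroplasmies`` are ``(position, minor_allele, minor_fraction)`` with
    the major allele taken from the (possibly variant-substituted) genotype;
    ``deletion`` is a half-open span ``(start, end]`` or None.
    """

    sample_id: str
    variants: list[tuple[int, str]] = field(default_factory=list)
    heteroplasmies: list[tuple[int, str, float]] = field(default_factory=list)
    deletion: tuple[int, int] | None = None
    degraded: bool = False


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic model. Defaults define the reference
    simulation conditions used throughout the test suite."""

    seed: int = 0
    n_samples: int = 1
    samples: list[SampleSpec] | None = None
    layout: ArrayLayout | None = None
    reference: str | None = None
    signal: float = 1000.0
    background: float = 50.0
    intensity_noise_sd: float = 0.2
    q_clean_mean: float = 30.0
    q_clean_sd: float = 5.0
    q_del_mean: float = 1.5
    q_del_sd: float = 1.0
    q_degraded_mean: float = 18.0
    q_degraded_sd: float = 8.0
    q_probe_effect_sd: float = 3.0
    degraded_low_peak_fraction: float = 0.1
    redundant_sets_k: int = 4
    q_call_floor: float = 3.0
    quality_from_intensity: bool = False

    def __post_init__(self) -> None:
        if not self.signal > self.background > 0:
            raise ValidationError("need signal > background > 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")

    def resolved_layout(self) -> ArrayLayout:
        return self.layout or ArrayLayout.default(self.redundant_sets_k)

    def resolved_reference(self, rng: np.random.Generator) -> str:
        if self.reference is not None:
            return self.reference.upper()
        return "".join(
            np.array(BASES)[rng.integers(0, 4, self.resolved_layout().genome_length)]
        )

    def resolved_specs(self) -> list[SampleSpec]:
        if self.samples is not None:
            return self.samples
        return [SampleSpec(f"S{i + 1:02d}") for i in range(self.n_samples)]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic batch."""

    reference: str
    variants: dict[str, list[tuple[int, str]]]
    heteroplasmies: dict[str, list[tuple[int, str, float]]]
    deletions: dict[str, tuple[int, int] | None]
    degraded: dict[str, bool]

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def _effect_split(total_sd: float, effect_sd: float) -> tuple[float, float]:
    """Split a total SD into (shared probe effect, independent) components."""
    eff = min(effect_sd, total_sd)
    indep = math.sqrt(max(total_sd**2 - eff**2, 0.0))
    return eff, indep


def _true_fractions(
    layout: ArrayLayout, reference: str, spec: SampleSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per interrogable position: (n,4) allele fractions, major-base index,
    boolean deleted mask."""
    pos = layout.interrogable_positions
    pos_index = {int(p): i for i, p in enumerate(pos)}
    ref_idx = np.array([BASES.index(reference[p - 1]) for p in pos])
    frac = np.zeros((len(pos), 4))
    frac[np.arange(len(pos)), ref_idx] = 1.0

    for p, alt in spec.variants:
        if p not in pos_index:
            raise ValidationError(f"variant position {p} is not interrogable")
        i = pos_index[p]
        frac[i] = 0.0
        frac[i, BASES.index(alt)] = 1.0

    for p, minor, f in spec.heteroplasmies:
        if not 0 < f < 1:
            raise ValidationError(f"heteroplasmy fraction {f} outside (0,1)")
        if p not in pos_index:
            raise ValidationError(f"heteroplasmy position {p} is not interrogable")
        i = pos_index[p]
        major_idx = int(np.argmax(frac[i]))
        if BASES[major_idx] == minor:
            raise ValidationError(f"minor allele equals major at position {p}")
        frac[i] = 0.0
        frac[i, major_idx] = 1.0 - f
        frac[i, BASES.index(minor)] = f

    # break f=0.5 ties toward the pre-heteroplasmy major allele
    major = np.argmax(frac + 1e-12 * np.eye(4)[ref_idx], axis=1)
    for p, alt in spec.variants:
        major[pos_index[p]] = BASES.index(alt)

    deleted = np.zeros(len(pos), dtype=bool)
    if spec.deletion is not None:
        start, end = spec.deletion
        if not (0 <= start < end <= layout.genome_length):
            raise ValidationError(f"deletion span ({start},{end}] outside layout")
        deleted = (pos > start) & (pos <= end)
        frac[deleted] = 0.0
    return frac, major, deleted


def _draw_intensities(
    frac: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    expected = cfg.signal * frac + cfg.background
    if cfg.intensity_noise_sd > 0:
        expected = expected * np.exp(
            cfg.intensity_noise_sd * rng.standard_normal(expected.shape)
        )
    return expected


def _draw_quality(
    n: int,
    deleted: np.ndarray,
    spec: SampleSpec,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    probe_effect: np.ndarray,
) -> np.ndarray:
    if spec.degraded:
        eff, indep = _effect_split(cfg.q_degraded_sd, cfg.q_probe_effect_sd)
        q = (
            cfg.q_degraded_mean
            + eff * probe_effect
            + indep * rng.standard_normal(n)
        )
        peak = rng.random(n) < cfg.degraded_low_peak_fraction
        q[peak] = cfg.q_del_mean + cfg.q_del_sd * rng.standard_normal(int(peak.sum()))
    else:
        eff, indep = _effect_split(cfg.q_clean_sd, cfg.q_probe_effect_sd)
        q = (
            cfg.q_clean_mean
            + eff * probe_effect
            + indep * rng.standard_normal(n)
        )
    q = np.clip(q, 0.0, 45.0)
    ndel = int(deleted.sum())
    if ndel:
        qd = cfg.q_del_mean + cfg.q_del_sd * rng.standard_normal(ndel)
        q[deleted] = np.clip(qd, 0.0, 45.0)
    return q


def _calls(
    frac: np.ndarray,
    major: np.ndarray,
    deleted: np.ndarray,
    quality: np.ndarray,
    sense: np.ndarray,
    antisense: np.ndarray,
    cfg: GeneratorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(BASES)
    hap = bases[major].astype("<U1")
    # deleted positions carry no true base: the call is whatever probe is
    # brightest, and usually N because the quality is below the floor
    if deleted.any():
        argmax = np.argmax(sense + antisense, axis=1)
        hap[deleted] = bases[argmax[deleted]]
    hap[quality < cfg.q_call_floor] = "N"
    dip = hap.copy()
    minor_frac = frac.copy()
    minor_frac[np.arange(len(major)), major] = 0.0
    f_minor = minor_frac.max(axis=1)
    het_idx = np.flatnonzero((f_minor >= 0.2) & (f_minor <= 0.8) & ~deleted)
    for i in het_idx:
        if hap[i] == "N":
            continue
        pair = frozenset({BASES[int(major[i])], BASES[int(np.argmax(minor_frac[i]))]})
        dip[i] = IUPAC2[pair]
    return hap, dip


def _generate_sample(
    layout: ArrayLayout,
    reference: str,
    spec: SampleSpec,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    probe_effect: np.ndarray | None = None,
) -> SampleDataset:
    pos = layout.interrogable_positions
    n = len(pos)
    if probe_effect is None:
        # standard-normal per-position probe effect, scaled at use
        probe_effect = rng.standard_normal(n)
    frac, major, deleted = _true_fractions(layout, reference, spec)
    set_counts = layout.redundant_set_count[pos - 1]
    max_sets = int(set_counts.max())
    blocks: dict[int, ProbeBlock] = {}
    for sid in range(max_sets):
        member = set_counts > sid
        f = frac[member]
        sense = _draw_intensities(f, cfg, rng)
        antisense = _draw_intensities(f, cfg, rng)
        quality = _draw_quality(
            int(member.sum()), deleted[member], spec, cfg, rng, probe_effect[member]
        )
        if cfg.quality_from_intensity:
            sums = np.sort(sense + antisense, axis=1)
            quality = np.clip(np.round(10.0 * np.log(sums[:, 3] / sums[:, 2])), 0, 45)
        hap, dip = _calls(
            f, major[member], deleted[member], quality, sense, antisense, cfg
        )
        blocks[sid] = ProbeBlock(
            sid, pos[member], sense, antisense, quality, hap, dip
        )
    return SampleDataset(spec.sample_id, blocks)


def generate_batch(cfg: GeneratorConfig) -> tuple[Batch, SimTruth]:
    """Generate a batch and its ground truth. Deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.resolved_layout()
    reference = cfg.resolved_reference(rng)
    if len(reference) != layout.genome_length:
        raise ValidationError("reference length does not match layout")
    specs = cfg.resolved_specs()
    probe_effect = rng.standard_normal(layout.n_interrogable)
    samples = [
        _generate_sample(layout, reference, spec, cfg, rng, probe_effect)
        for spec in specs
    ]
    batch = Batch(layout, reference, samples)
    truth = SimTruth(
        reference=reference,
        variants={s.sample_id: list(s.variants) for s in specs},
        heteroplasmies={s.sample_id: list(s.heteroplasmies) for s in specs},
        deletions={s.sample_id: s.deletion for s in specs},
        degraded={s.sample_id: s.degraded for s in specs},
    )
    return batch, truth


def _delete_span(
    sample: SampleDataset,
    span: tuple[int, int],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    """In-place: redraw quality and intensities inside ``(start, end]`` from
    the deleted-position model."""
    start, end = span
    if end <= start:
        raise ValidationError("empty deletion span")
    for block in sample.blocks.values():
        mask = (block.positions > start) & (block.positions <= end)
        ndel = int(mask.sum())
        if ndel == 0:
            continue
        zero = np.zeros((ndel, 4))
        block.sense[mask] = _draw_intensities(zero, cfg, rng)
        block.antisense[mask] = _draw_intensities(zero, cfg, rng)
        q = cfg.q_del_mean + cfg.q_del_sd * rng.standard_normal(ndel)
        block.quality[mask] = np.clip(q, 0.0, 45.0)
        argmax = np.argmax(block.sense[mask] + block.antisense[mask], axis=1)
        hap = np.array(BASES)[argmax].astype("<U1")
        hap[block.quality[mask] < cfg.q_call_floor] = "N"
        block.haploid_call[mask] = hap
        block.diploid_call[mask] = hap


def inject_deletion(
    sample: SampleDataset,
    span: tuple[int, int],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> SampleDataset:
    """Return a copy of ``sample`` with quality and intensities inside the
    half-open span ``(start, end]`` redrawn from the deleted-position model;
    everything outside the span is unchanged."""
    start, end = span
    if end <= start:
        raise ValidationError("empty deletion span")
    max_pos = int(sample.primary.positions.max())
    if not (0 <= start and end <= max_pos):
        raise ValidationError(f"deletion span ({start},{end}] outside layout")
    out = sample.copy()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _delete_span(out, span, cfg, rng)
    return out


def audit_truth(batch: Batch, truth: SimTruth) -> None:
    """Cross-check a batch against its ground truth; raises on inconsistency."""
    batch.validate()
    ids = set(batch.sample_ids)
    for key in (truth.variants, truth.heteroplasmies, truth.deletions, truth.degraded):
        if set(key) != ids:
            raise ValidationError("truth and batch sample ids differ")
    for s in batch.samples:
        block = s.primary
        span = truth.deletions[s.sample_id]
        if span is not None:
            start, end = span
            mask = (block.positions > start) & (block.positions <= end)
            if mask.any() and block.quality[mask].mean() > 10.0:
                raise ValidationError(
                    f"{s.sample_id}: deleted span does not show degraded quality"
                )
        for p, alt in truth.variants[s.sample_id]:
            rec = s.record(p)
            sums = rec.sense.as_array() + rec.antisense.as_array()
            if BASES[int(np.argmax(sums))] != alt:
                raise ValidationError(
                    f"{s.sample_id}: variant at {p} not dominant in intensities"
                )
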