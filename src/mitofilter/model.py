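"""Core data model for mtDNA resequencing-array data.

Coordinates are 1-based inclusive genome positions ("np" in the rCRS
coordinate system). Deletion spans are half-open ``(start, end]`` so that
``length == end - start``.

A sample's data are stored column-wise (NumPy arrays) per probe set for
speed; :class:`PositionRecord` is the single-position view used by the
scalar APIs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Canonical base order used for all per-base intensity arrays.
BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Two-allele IUPAC ambiguity codes (unordered pairs).
IUPAC2 = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

#: rCRS genome length.
DEFAULT_GENOME_LENGTH = 16569

#: Control region spans (1-based inclusive); the region wraps the origin so it
#: is represented as two linear spans.
DEFAULT_CONTROL_REGION_SPANS = ((16024, 16569), (1, 576))

#: Positions the array cannot interrogate. The real array misses 25 of the
#: 16,569 positions but their identities are not public; by convention we
#: exclude the first 12 and last 13 positions (configurable), which preserves
#: the interrogable count of 16,544.
DEFAULT_NONINTERROGABLE = tuple(range(1, 13)) + tuple(range(16557, 16570))


class ArrayLayout:
    """Static description of the tiling array.

    Parameters
    ----------
    genome_length:
        Number of genome positions (default 16,569, the rCRS length).
    interrogable_mask:
        Boolean array of length ``genome_length``; ``mask[p-1]`` is True when
        position ``p`` is interrogable. Defaults to all-True minus
        :data:`DEFAULT_NONINTERROGABLE` (16,544 interrogable positions).
    control_region_spans:
        1-based inclusive ``(start, end)`` intervals covered by redundant
        probe tilings.
    redundant_set_count:
        Integer array of length ``genome_length``: number of probe sets
        (primary included) tiled over each position. Defaults to
        ``redundant_sets_k`` inside the control region spans and 1 elsewhere.
    """

    def __init__(
        self,
        genome_length: int = DEFAULT_GENOME_LENGTH,
        interrogable_mask: np.ndarray | None = None,
        control_region_spans: Sequence[tuple[int, int]] | None = None,
        redundant_set_count: np.ndarray | None = None,
        redundant_sets_k: int = 4,
    ) -> None:
        if genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        self.genome_length = int(genome_length)
        if interrogable_mask is None:
            interrogable_mask = np.ones(self.genome_length, dtype=bool)
            if self.genome_length == DEFAULT_GENOME_LENGTH:
                interrogable_mask[[p - 1 for p in DEFAULT_NONINTERROGABLE]] = False
        self.interrogable_mask = np.asarray(interrogable_mask, dtype=bool)
        if self.interrogable_mask.shape != (self.genome_length,):
            raise ValidationError("interrogable_mask length must equal genome_length")
        if control_region_spans is None:
            control_region_spans = (
                DEFAULT_CONTROL_REGION_SPANS
                if self.genome_length == DEFAULT_GENOME_LENGTH
                else ()
            )
        self.control_region_spans = tuple(
            (int(a), int(b)) for a, b in control_region_spans
        )
        for a, b in self.control_region_spans:
            if not (1 <= a <= b <= self.genome_length):
                raise ValidationError(
                    f"control region span ({a},{b}) outside [1,{self.genome_length}]"
                )
        if redundant_set_count is None:
            redundant_set_count = np.ones(self.genome_length, dtype=np.int64)
            for a, b in self.control_region_spans:
                redundant_set_count[a - 1 : b] = max(1, int(redundant_sets_k))
        self.redundant_set_count = np.asarray(redundant_set_count, dtype=np.int64)
        if self.redundant_set_count.shape != (self.genome_length,):
            raise ValidationError("redundant_set_count length must equal genome_length")
        if (self.redundant_set_count < 1).any():
            raise ValidationError("redundant_set_count must be >= 1 everywhere")
        self._interrogable_positions = (
            np.flatnonzero(self.interrogable_mask).astype(np.int64) + 1
        )

    # -- convenience -------------------------------------------------------
    @classmethod
    def default(cls, redundant_sets_k: int = 4) -> "ArrayLayout":
        return cls(redundant_sets_k=redundant_sets_k)

    @property
    def interrogable_positions(self) -> np.ndarray:
        """Sorted 1-based positions the array interrogates."""
        return self._interrogable_positions

    @property
    def n_interrogable(self) -> int:
        return int(self.interrogable_mask.sum())

    def is_interrogable(self, position: int) -> bool:
        return bool(self.interrogable_mask[position - 1])

    def in_control_region(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.control_region_spans)

    def __eq__(self, other: object) -> bool:  # used by round-trip tests
        return (
            isinstance(other, ArrayLayout)
            and self.genome_length == other.genome_length
            and np.array_equal(self.interrogable_mask, other.interrogable_mask)
            and self.control_region_spans == other.control_region_spans
            and np.array_equal(self.redundant_set_count, other.redundant_set_count)
        )


@dataclass(frozen=True)
class StrandSignal:
    """Fluorescence intensities of one probe quartet (one strand)."""

    intensity_A: float
    intensity_C: float
    intensity_G: float
    intensity_T: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intensity_A, self.intensity_C, self.intensity_G, self.intensity_T],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "StrandSignal":
        a, c, g, t = (float(v) for v in arr)
        return cls(a, c, g, t)

    def __post_init__(self) -> None:
        if min(self.intensity_A, self.intensity_C, self.intensity_G, self.intensity_T) <= 0:
            raise ValidationError("strand intensities must be positive")


@dataclass(frozen=True)
class PositionRecord:
    """One interrogated position in one probe set of one sample."""

    position: int
    probe_set_id: int
    sense: StrandSignal
    antisense: StrandSignal
    quality: float
    haploid_call: str
    diploid_call: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("position must be >= 1")
        if self.probe_set_id < 0:
            raise ValidationError("probe_set_id must be >= 0")
        if self.quality < 0:
            raise ValidationError("quality must be >= 0")


class ProbeBlock:
    """Column-wise storage of every record of one probe set of one sample."""

    def __init__(
        self,
        probe_set_id: int,
        positions: np.ndarray,
        sense: np.ndarray,
        antisense: np.ndarray,
        quality: np.ndarray,
        haploid_call: np.ndarray,
        diploid_call: np.ndarray,
    ) -> None:
        order = np.argsort(positions, kind="stable")
        self.probe_set_id = int(probe_set_id)
        self.positions = np.asarray(positions, dtype=np.int64)[order]
        self.sense = np.asarray(sense, dtype=float)[order]
        self.antisense = np.asarray(antisense, dtype=float)[order]
        self.quality = np.asarray(quality, dtype=float)[order]
        self.haploid_call = np.asarray(haploid_call, dtype="<U1")[order]
        self.diploid_call = np.asarray(diploid_call, dtype="<U1")[order]
        n = len(self.positions)
        if self.sense.shape != (n, 4) or self.antisense.shape != (n, 4):
            raise ValidationError("intensity arrays must have shape (n, 4)")
        if len({len(self.quality), len(self.haploid_call), len(self.diploid_call)}) != 1:
            raise ValidationError("ragged probe block arrays")
        if (self.quality < 0).any():
            raise ValidationError("quality must be >= 0")
        if (self.sense <= 0).any() or (self.antisense <= 0).any():
            raise ValidationError("intensities must be positive (clamp on read)")
        self._index: dict[int, int] | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def index_of(self, position: int) -> int:
        if self._index is None:
            self._index = {int(p): i for i, p in enumerate(self.positions)}
        try:
            return self._index[int(position)]
        except KeyError:
            raise ValidationError(
                f"no record at position {position} in probe set {self.probe_set_id}"
            ) from None

    def record(self, i: int) -> PositionRecord:
        return PositionRecord(
            position=int(self.positions[i]),
            probe_set_id=self.probe_set_id,
            sense=StrandSignal.from_array(self.sense[i]),
            antisense=StrandSignal.from_array(self.antisense[i]),
            quality=float(self.quality[i]),
            haploid_call=str(self.haploid_call[i]),
            diploid_call=str(self.diploid_call[i]),
        )

    def copy(self) -> "ProbeBlock":
        return ProbeBlock(
            self.probe_set_id,
            self.positions.copy(),
            self.sense.copy(),
            self.antisense.copy(),
            self.quality.copy(),
            self.haploid_call.copy(),
            self.diploid_call.copy(),
        )


class SampleDataset:
    """All probe-level records of one sample (primary plus redundant sets)."""

    def __init__(self, sample_id: str, blocks: Mapping[int, ProbeBlock]) -> None:
        self.sample_id = str(sample_id)
        self.blocks = dict(sorted(blocks.items()))
        if 0 not in self.blocks:
            raise ValidationError(f"sample {sample_id}: missing primary probe set (id 0)")

    @property
    def primary(self) -> ProbeBlock:
        return self.blocks[0]

    def record(self, position: int, probe_set_id: int = 0) -> PositionRecord:
        block = self.blocks[probe_set_id]
        return block.record(block.index_of(position))

    def records_at(self, position: int) -> list[PositionRecord]:
        out = []
        for block in self.blocks.values():
            if self._block_has(block, position):
                out.append(block.record(block.index_of(position)))
        return out

    @staticmethod
    def _block_has(block: ProbeBlock, position: int) -> bool:
        try:
            block.index_of(position)
            return True
        except ValidationError:
            return False

    def validate(self, layout: ArrayLayout) -> None:
        prim = self.primary.positions
        expected = layout.interrogable_positions
        if len(prim) != len(np.unique(prim)):
            dup = int(prim[np.flatnonzero(np.diff(prim) == 0)[0]])
            raise ValidationError(
                f"sample {self.sample_id}: duplicate primary record at position {dup}"
            )
        if not np.array_equal(prim, expected):
            missing = np.setdiff1d(expected, prim)
            extra = np.setdiff1d(prim, expected)
            if len(missing):
                raise ValidationError(
                    f"sample {self.sample_id}: missing primary record at position "
                    f"{int(missing[0])}"
                )
            raise ValidationError(
                f"sample {self.sample_id}: record at non-interrogable position "
                f"{int(extra[0])}"
            )
        for sid, block in self.blocks.items():
            if sid == 0:
                continue
            counts = layout.redundant_set_count[block.positions - 1]
            if (counts <= sid).any():
                bad = int(block.positions[np.argmax(counts <= sid)])
                raise ValidationError(
                    f"sample {self.sample_id}: probe set {sid} not defined at "
                    f"position {bad}"
                )

    def copy(self) -> "SampleDataset":
        return SampleDataset(
            self.sample_id, {sid: b.copy() for sid, b in self.blocks.items()}
        )


class Batch:
    """A set of samples sharing one :class:`ArrayLayout` and reference."""

    def __init__(
        self, layout: ArrayLayout, reference: str, samples: Sequence[SampleDataset]
    ) -> None:
        self.layout = layout
        self.reference = str(reference).upper()
        self.samples = list(samples)
        if len(self.reference) != layout.genome_length:
            raise ValidationError(
                f"reference length {len(self.reference)} != genome length "
                f"{layout.genome_length}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleDataset:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise ValidationError(f"no such sample: {sample_id}")

    def validate(self) -> None:
        seen = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample id {s.sample_id}")
            seen.add(s.sample_id)
            s.validate(self.layout)

    def quality_matrix(self) -> np.ndarray:
        """(n_samples, n_interrogable) primary quality scores."""
        return np.stack([s.primary.quality for s in self.samples])


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the published defaults.

    ``q_call_floor`` is the array software's minimum quality for a base call;
    ``q_variant_floor`` demotes low-quality variant calls; ``snr_threshold``
    is the highest/second-highest intensity ratio below which calls are
    treated as noise (the value derived from the deleted-region ratio
    distribution); the deletion scan uses a ``del_window``-bp moving window
    and a pooled mean − ``del_sd_multiplier``·SD cutoff.
    """

    q_call_floor: float = 3.0
    q_variant_floor: float = 12.0
    snr_threshold: float = 1.26
    snr_sd_multiplier: float = 4.0
    del_window: int = 25
    intensity_window: int = 50
    del_sd_multiplier: float = 3.0
    het_sd_multiplier: float = 3.0
    rank_alpha: float = 0.05
    sim_reps: int = 200
    gsd_alpha: float = 0.05
    gsd_max_fraction: float = 0.2
    intensity_floor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "q_variant_floor",
            "snr_threshold",
            "snr_sd_multiplier",
            "del_window",
            "intensity_window",
            "del_sd_multiplier",
            "het_sd_multiplier",
            "rank_alpha",
            "sim_reps",
            "gsd_alpha",
            "gsd_max_fraction",
            "intensity_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.q_call_floor < 0:
            raise ValidationError("q_call_floor must be >= 0")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**dict(d))
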