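"""File formats: the TSV interchange dialect, consensus FASTA and VCF output.

The interchange TSV is a tab-separated table with header
``sample_id  position  probe_set_id  strand  int_A  int_C  int_G  int_T
quality  haploid_call  diploid_call`` and two rows (one per strand, ``+`` then
``-``) per (sample, position, probe set). Intensities below the configured
floor are clamped on read so that every downstream ratio is defined.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .model import ArrayLayout, Batch, PipelineConfig, ProbeBlock, SampleDataset
from .calling import ConsensusSequence, VariantCall
from .sv import DeletionCall
from .het import HeteroplasmyCall

TSV_COLUMNS = [
    "sample_id",
    "position",
    "probe_set_id",
    "strand",
    "int_A",
    "int_C",
    "int_G",
    "int_T",
    "quality",
    "haploid_call",
    "diploid_call",
]

_INTENSITY_COLS = ["int_A", "int_C", "int_G", "int_T"]


def write_batch_tsv(batch: Batch, path) -> None:
    """Write a batch in the interchange dialect (6 significant digits)."""
    frames = []
    for sample in batch.samples:
        for sid, block in sample.blocks.items():
            n = len(block)
            for strand, inten in (("+", block.sense), ("-", block.antisense)):
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample.sample_id,
                            "position": block.positions,
                            "probe_set_id": sid,
                            "strand": strand,
                            "int_A": inten[:, 0],
                            "int_C": inten[:, 1],
                            "int_G": inten[:, 2],
                            "int_T": inten[:, 3],
                            "quality": block.quality,
                            "haploid_call": block.haploid_call,
                            "diploid_call": block.diploid_call,
                        }
                    )
                )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(
            ["sample_id", "probe_set_id", "position", "strand"], kind="stable"
        )
    else:
        df = pd.DataFrame(columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", columns=TSV_COLUMNS)


def read_batch_tsv(
    path,
    layout: ArrayLayout,
    reference: str | None = None,
    cfg: PipelineConfig | None = None,
) -> Batch:
    """Read an interchange TSV into a :class:`Batch`.

    Intensities below ``cfg.intensity_floor`` (default 1.0) are clamped.
    Missing or duplicate primary records and records at non-interrogable
    positions raise :class:`ValidationError` naming the sample and position;
    non-numeric intensities raise :class:`ParseError` with the line number.
    """
    cfg = cfg or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in _INTENSITY_COLS + ["quality"]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad) or values.isna().any():
            line = int((bad if len(bad) else df.index[values.isna()])[0]) + 2
            raise ParseError(f"{path}: non-numeric {col} at line {line}")
        df[col] = values.astype(float)
    df["position"] = pd.to_numeric(df["position"], errors="coerce")
    df["probe_set_id"] = pd.to_numeric(df["probe_set_id"], errors="coerce")
    if df["position"].isna().any() or df["probe_set_id"].isna().any():
        line = int(df.index[df["position"].isna() | df["probe_set_id"].isna()][0]) + 2
        raise ParseError(f"{path}: non-numeric position/probe_set_id at line {line}")
    df[_INTENSITY_COLS] = df[_INTENSITY_COLS].clip(lower=cfg.intensity_floor)

    samples = []
    for sample_id, sdf in df.groupby("sample_id", sort=True):
        blocks = {}
        for sid, bdf in sdf.groupby("probe_set_id", sort=True):
            plus = bdf[bdf["strand"] == "+"].sort_values("position")
            minus = bdf[bdf["strand"] == "-"].sort_values("position")
            if len(plus) != len(minus) or not np.array_equal(
                plus["position"].to_numpy(), minus["position"].to_numpy()
            ):
                raise ValidationError(
                    f"sample {sample_id}, probe set {int(sid)}: strand rows do "
                    "not pair up"
                )
            pos = plus["position"].to_numpy(dtype=np.int64)
            dup = pos[:-1][np.diff(pos) == 0]
            if len(dup):
                raise ValidationError(
                    f"sample {sample_id}: duplicate record at position {int(dup[0])}"
                )
            blocks[int(sid)] = ProbeBlock(
                int(sid),
                pos,
                plus[_INTENSITY_COLS].to_numpy(dtype=float),
                minus[_INTENSITY_COLS].to_numpy(dtype=float),
                plus["quality"].to_numpy(dtype=float),
                plus["haploid_call"].to_numpy(dtype="<U1"),
                plus["diploid_call"].to_numpy(dtype="<U1"),
            )
        sample = SampleDataset(str(sample_id), blocks)
        sample.validate(layout)
        samples.append(sample)
    ref = reference.upper() if reference else "N" * layout.genome_length
    return Batch(layout, ref, samples)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_reference_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def write_consensus_fasta(
    consensus: ConsensusSequence, path, layout: ArrayLayout | None = None
) -> None:
    if layout is not None and len(consensus.sequence) != layout.genome_length:
        raise ValidationError(
            f"consensus length {len(consensus.sequence)} != genome length "
            f"{layout.genome_length}"
        )
    record = SeqRecord(
        Seq(consensus.sequence), id=consensus.sample_id, description="consensus"
    )
    SeqIO.write([record], str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrM,length={length}>
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the structural variant">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the structural variant">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction of the ALT allele">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample the call belongs to">
##ALT=<ID=DEL,Description="Deletion">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(
    variants: Mapping[str, Sequence[VariantCall]],
    deletions: Mapping[str, Sequence[DeletionCall]],
    heteroplasmies: Mapping[str, Sequence[HeteroplasmyCall]],
    reference: str,
    path,
) -> None:
    """Write SNVs, symbolic <DEL> records and AF-annotated heteroplasmy calls
    as VCF 4.2. Positions are 1-based; a deletion span ``(start, end]`` is
    anchored at POS=start (the last retained base) with INFO END=end.
    """
    rows: list[tuple[int, str]] = []
    for sample_id, calls in (variants or {}).items():
        for v in calls:
            if v.alt == v.ref:
                raise ValidationError(f"ALT equals REF at {v.position}")
            if reference[v.position - 1] != v.ref:
                raise ValidationError(
                    f"REF mismatch at {v.position}: {v.ref} vs reference "
                    f"{reference[v.position - 1]}"
                )
            rows.append(
                (
                    v.position,
                    f"chrM\t{v.position}\t.\t{v.ref}\t{v.alt}\t"
                    f"{v.quality:.6g}\tPASS\tSAMPLE={sample_id}",
                )
            )
    for sample_id, calls in (deletions or {}).items():
        for d in calls:
            pos = max(1, d.start)
            ref_base = reference[pos - 1]
            rows.append(
                (
                    pos,
                    f"chrM\t{pos}\t.\t{ref_base}\t<DEL>\t.\tPASS\t"
                    f"SVTYPE=DEL;END={d.end};SVLEN=-{d.length};SAMPLE={sample_id}",
                )
            )
    for sample_id, calls in (heteroplasmies or {}).items():
        for h in calls:
            ref_base = reference[h.position - 1]
            alts = [b for b in (h.major_allele, h.minor_allele) if b != ref_base]
            if not alts:
                continue
            major_f = h.major_fraction_pct / 100.0
            afs = [
                f"{(major_f if b == h.major_allele else 1.0 - major_f):.6g}"
                for b in alts
            ]
            rows.append(
                (
                    h.position,
                    f"chrM\t{h.position}\t.\t{ref_base}\t{','.join(alts)}\t.\t"
                    f"PASS\tAF={','.join(afs)};SAMPLE={sample_id}",
                )
            )
    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(length=len(reference)))
        for _, line in rows:
            fh.write(line + "\n")
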