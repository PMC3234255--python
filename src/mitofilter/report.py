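"""Pipeline orchestration, run reports and optional haplogroup assignment.

The full pipeline: QC gate → deletion scan (all samples) → base-call
refinement and redundant-probe consolidation (QC-passing samples) →
consensus/variants → heteroplasmy screen and four-step filter on passing
samples → writers. Samples failing QC still receive QC statistics and a
deletion scan but carry no downstream base or heteroplasmy calls, and are
excluded from every cross-sample statistic.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import __version__
from .errors import ValidationError
from .model import ArrayLayout, Batch, PipelineConfig
from .qc import qc_gate
from .sv import DeletionCall, deletion_cutoff, detect_deletions
from .calling import (
    BaseCallTrack,
    VariantCall,
    call_rate,
    consensus_and_variants,
    consolidate_redundant,
    refine_calls,
)
from .het import HetCandidate, HeteroplasmyCall, het_candidates, het_statistic, filter_het


@dataclass(frozen=True)
class PanelEntry:
    """One diagnostic SNP of a haplogroup panel."""

    position: int
    base: str
    haplogroup: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("panel position must be >= 1")
        if not self.haplogroup:
            raise ValidationError("haplogroup label must be nonempty")


def read_panel_tsv(path) -> list[PanelEntry]:
    """Read a panel TSV with columns position, base, haplogroup."""
    entries = []
    bad = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                pos, base, label = parts
                entries.append(PanelEntry(int(pos), base.upper(), label))
            except (ValueError, ValidationError):
                bad.append(lineno)
    if bad:
        raise ValidationError(f"{path}: malformed panel rows at lines {bad}")
    return entries


def assign_haplogroup(track: BaseCallTrack, panel: Sequence[PanelEntry]) -> str:
    """Best-match counting over the panel's diagnostic positions.

    Returns the label matching the most panel positions, requiring at least
    one match and a unique maximum; otherwise "unassigned". N calls never
    match. This is a deliberately simple tally, not phylogenetic placement.
    """
    scores: dict[str, int] = {}
    for e in panel:
        scores.setdefault(e.haplogroup, 0)
        if track.has_position(e.position):
            call = track.call_at(e.position)
            if call != "N" and call == e.base:
                scores[e.haplogroup] += 1
    if not scores:
        return "unassigned"
    best = max(scores.values())
    leaders = [h for h, s in scores.items() if s == best]
    if best >= 1 and len(leaders) == 1:
        return leaders[0]
    return "unassigned"


@dataclass
class RunReport:
    seed: int | None
    config: dict
    versions: dict
    qc: dict
    samples: list[dict]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "versions": self.versions,
            "qc": self.qc,
            "samples": self.samples,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


_REPORT_REQUIRED_SAMPLE_KEYS = {
    "sample_id": str,
    "qc_verdict": str,
    "initial_call_rate": float,
    "deletions": list,
}


def validate_report(report: dict) -> None:
    """Structural validation of a run-report dictionary; raises on defects."""
    for key in ("seed", "config", "versions", "qc", "samples"):
        if key not in report:
            raise ValidationError(f"report missing key {key!r}")
    if not isinstance(report["samples"], list):
        raise ValidationError("report['samples'] must be a list")
    for entry in report["samples"]:
        for key, typ in _REPORT_REQUIRED_SAMPLE_KEYS.items():
            if key not in entry:
                raise ValidationError(f"sample entry missing key {key!r}")
            if not isinstance(entry[key], typ):
                raise ValidationError(f"sample entry key {key!r} has wrong type")
        if entry["qc_verdict"] == "fail" and (
            entry.get("variants") or entry.get("heteroplasmies")
        ):
            raise ValidationError("excluded sample carries downstream results")


def _apply_consolidation(
    track: BaseCallTrack, sample, layout: ArrayLayout, cfg: PipelineConfig
) -> None:
    """Overwrite track calls at redundantly tiled positions with the
    majority-vote consolidation over all probe sets."""
    red = layout.redundant_set_count[track.positions - 1] >= 2
    for i in np.flatnonzero(red):
        pos = int(track.positions[i])
        records = sample.records_at(pos)
        if len(records) < 2:
            continue
        call, het_flag = consolidate_redundant(records, cfg)
        if het_flag:
            track.final_call[i] = "N"
            track.provenance[i] = "het_flagged"
        else:
            track.final_call[i] = call
            track.provenance[i] = "consolidated"


def run_pipeline(
    batch: Batch,
    cfg: PipelineConfig | None = None,
    reference: str | None = None,
    panel: Sequence[PanelEntry] | None = None,
    seed: int | None = None,
    out_dir=None,
) -> RunReport:
    """Run the full filtering pipeline on a batch and build a report.

    Deterministic given the batch and configuration; ``seed`` is recorded in
    the report for provenance of upstream data generation.
    """
    cfg = cfg or PipelineConfig()
    reference = (reference or batch.reference).upper()
    batch.validate()
    qc = qc_gate(batch, cfg)
    passing = [s for s, ok in zip(batch.samples, qc.verdict) if ok]

    # deletion scan: cutoff pooled from QC-passing samples (the best
    # available proxy for "samples without known deletions")
    pool = passing if passing else batch.samples
    cutoff = deletion_cutoff(pool, cfg.del_sd_multiplier)
    deletions: dict[str, list[DeletionCall]] = {
        s.sample_id: detect_deletions(s, cutoff, cfg.del_window)
        for s in batch.samples
    }

    tracks: dict[str, BaseCallTrack] = {}
    variants: dict[str, list[VariantCall]] = {}
    consensi = {}
    rates: dict[str, float] = {}
    for s in passing:
        track = refine_calls(s, reference, cfg)
        _apply_consolidation(track, s, batch.layout, cfg)
        tracks[s.sample_id] = track
        consensus, var = consensus_and_variants(track, reference)
        consensi[s.sample_id] = consensus
        variants[s.sample_id] = var
        rates[s.sample_id] = call_rate(track, batch.layout)

    het_calls: dict[str, list[HeteroplasmyCall]] = {s.sample_id: [] for s in passing}
    het_note = None
    if len(passing) >= 3:
        sub = Batch(batch.layout, reference, passing)
        candidates = het_candidates(sub, cfg)
        # merge unresolved consolidation ties into the candidate list
        seen = {(c.sample_id, c.position) for c in candidates}
        for s in passing:
            track = tracks[s.sample_id]
            for i in np.flatnonzero(track.provenance == "het_flagged"):
                pos = int(track.positions[i])
                if (s.sample_id, pos) not in seen:
                    candidates.append(
                        HetCandidate(
                            sample_id=s.sample_id,
                            position=pos,
                            statistic=het_statistic(s.record(pos)),
                            z_within=float("nan"),
                            z_across=float("nan"),
                        )
                    )
        for call in filter_het(candidates, tracks, sub, cfg):
            het_calls[call.sample_id].append(call)
    else:
        het_note = "fewer than 3 QC-passing samples; heteroplasmy screen skipped"

    haplogroups = {}
    if panel:
        for s in passing:
            haplogroups[s.sample_id] = assign_haplogroup(tracks[s.sample_id], panel)

    sample_entries = []
    for i, s in enumerate(batch.samples):
        sid = s.sample_id
        ok = bool(qc.verdict[i])
        entry = {
            "sample_id": sid,
            "qc_verdict": "pass" if ok else "fail",
            "initial_call_rate": float(qc.initial_call_rate[i]),
            "deletions": [
                {
                    "start": d.start,
                    "end": d.end,
                    "length": d.length,
                    "min_window_mean": d.min_window_mean,
                    "cutoff": d.cutoff_used,
                }
                for d in deletions[sid]
            ],
        }
        if ok:
            entry["call_rate"] = rates[sid]
            entry["variants"] = [
                {"position": v.position, "ref": v.ref, "alt": v.alt,
                 "quality": v.quality, "snr": v.snr}
                for v in variants[sid]
            ]
            entry["heteroplasmies"] = [
                {
                    "position": h.position,
                    "major_allele": h.major_allele,
                    "minor_allele": h.minor_allele,
                    "major_fraction_pct": h.major_fraction_pct,
                }
                for h in het_calls[sid]
            ]
            if panel:
                entry["haplogroup"] = haplogroups[sid]
        sample_entries.append(entry)

    import numpy, scipy, pandas

    report = RunReport(
        seed=seed,
        config=cfg.to_dict(),
        versions={
            "mitofilter": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        qc={**qc.to_dict(), **({"note": het_note} if het_note else {})},
        samples=sample_entries,
    )

    if out_dir is not None:
        from pathlib import Path
        from .io import write_consensus_fasta, write_variants_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, consensus in consensi.items():
            write_consensus_fasta(consensus, out / f"{sid}.consensus.fasta")
        write_variants_vcf(
            variants,
            {sid: deletions[sid] for sid in deletions},
            het_calls,
            reference,
            out / "variants.vcf",
        )
        qc.to_json(out / "qc.json")
        report.to_json(out / "report.json")
    return report
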