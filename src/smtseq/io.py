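"""Readers and writers for the package's external formats.

FASTA/FASTQ through Biopython, image stacks as per-channel multi-page
TIFF with TSV sidecars, spot/track tables as TSV through pandas, and a
minimal SAM dialect for alignments (POS 1-based, CIGAR over =/X/I/D).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignqc import AccuracyCurve, Alignment, ConsensusResult, ErrorProfile
from .basecall import Track
from .imageproc import Spot
from .imagesim import ImageStack
from .photobleach import CompositionSummary, StepResult
from .simcore import ReadSet, ReferenceSet, TemplateRecord, VariantSpec


# ---------------------------------------------------------------------------
# Reference sets
# ---------------------------------------------------------------------------


def write_reference_fasta(refs: ReferenceSet, fasta_path, variants_tsv_path=None) -> None:
    """One record per wild-type/mutant template plus probe_* records.

    Variant specs go to a TSV sidecar (name, kind, position, alt,
    del_length) so the set round-trips exactly.
    """
    records = []
    for t in refs.templates:
        records.append(SeqRecord(Seq(t.wild), id=t.name, description="wild"))
        records.append(SeqRecord(Seq(t.mutant), id=f"{t.name}__mut", description="mutant"))
    for name, seq in refs.probes:
        records.append(SeqRecord(Seq(seq), id=name, description="probe"))
    SeqIO.write(records, str(fasta_path), "fasta")
    if variants_tsv_path is not None:
        rows = [
            {
                "name": t.variant.name,
                "kind": t.variant.kind,
                "position": t.variant.position,
                "alt": t.variant.alt_base or "",
                "del_length": t.variant.del_length or 0,
            }
            for t in refs.templates
        ]
        pd.DataFrame(rows).to_csv(variants_tsv_path, sep="\t", index=False)


def read_reference_fasta(fasta_path, variants_tsv_path, seed: int = 0) -> ReferenceSet:
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(variants_tsv_path, sep="\t", keep_default_na=False)
    templates = []
    probes = [(k, v) for k, v in seqs.items() if k.startswith("probe_")]
    for _, row in table.iterrows():
        name = row["name"]
        spec = VariantSpec(
            name=name,
            kind=row["kind"],
            position=int(row["position"]),
            alt_base=row["alt"] or None,
            del_length=int(row["del_length"]) or None,
        )
        templates.append(
            TemplateRecord(name, seqs[name], seqs[f"{name}__mut"], spec)
        )
    return ReferenceSet(templates=templates, probes=probes, seed=seed)


# ---------------------------------------------------------------------------
# Read sets
# ---------------------------------------------------------------------------

PLACEHOLDER_QUALITY = "I"  # the platform emits no base qualities


def write_reads(reads: ReadSet, path, fmt: str = "fastq") -> None:
    records = []
    for rid, seq in zip(reads.ids, reads.seqs):
        rec = SeqRecord(Seq(seq), id=rid, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_reads(path, fmt: str = "fastq") -> ReadSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), fmt):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    n = len(ids)
    return ReadSet(
        ids=ids,
        seqs=seqs,
        template_index=np.full(n, -1, dtype=np.int32),
        origin=np.zeros(n, dtype=np.int8),
        batch=np.zeros(n, dtype=np.int32),
        provenance="loaded",
    )


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, directory, prefix: str = "field") -> None:
    """Per-channel multi-page TIFF (page = cycle) plus a drift TSV sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / f"{prefix}_template.tif", stack.template.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(d / f"{prefix}_incorporation.tif", stack.incorporation.astype(np.float32),
                     photometric="minisblack")
    pd.DataFrame(
        {
            "cycle": np.arange(1, stack.n_cycles + 1),
            "dx": stack.true_drift[:, 0],
            "dy": stack.true_drift[:, 1],
        }
    ).to_csv(d / f"{prefix}_drift.tsv", sep="\t", index=False)


def read_stack(directory, prefix: str = "field") -> ImageStack:
    d = Path(directory)
    template = tifffile.imread(d / f"{prefix}_template.tif").astype(float)
    incorporation = tifffile.imread(d / f"{prefix}_incorporation.tif").astype(float)
    drift = pd.read_csv(d / f"{prefix}_drift.tsv", sep="\t")
    return ImageStack(
        template=template,
        incorporation=incorporation,
        true_drift=drift[["dx", "dy"]].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def spots_to_frame(spots: Sequence[Spot], cycle: int = 0, channel: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cycle": cycle,
            "channel": channel,
            "x": [s.x for s in spots],
            "y": [s.y for s in spots],
            "amplitude": [s.amplitude for s in spots],
            "sigma": [s.sigma for s in spots],
            "area": [s.area for s in spots],
            "flag": [s.flag for s in spots],
        }
    )


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "anchor_id": [t.anchor_id for t in tracks],
            "x": [t.anchor_x for t in tracks],
            "y": [t.anchor_y for t in tracks],
            "ambiguous": [t.ambiguous for t in tracks],
            "event_cycles": [",".join(map(str, t.event_cycles)) for t in tracks],
        }
    )


def step_results_to_frame(results: Sequence[StepResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot": np.arange(len(results)),
            "n_steps": [r.n_steps for r in results],
            "label": [r.label for r in results],
            "quality": [r.quality for r in results],
        }
    )


def composition_to_json(summary: CompositionSummary, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"counts": summary.counts, "fractions": summary.fractions, "n": summary.n_total},
            indent=2,
        )
    )


def consensus_to_frame(result: ConsensusResult, reference: str) -> pd.DataFrame:
    t = result.tallies
    return pd.DataFrame(
        {
            "position": np.arange(len(reference)),
            "reference": list(reference),
            "consensus": list(result.consensus),
            "A": t[0],
            "C": t[1],
            "G": t[2],
            "T": t[3],
            "del": t[4],
            "coverage": result.coverage,
        }
    )


def accuracy_curve_to_frame(curve: AccuracyCurve) -> pd.DataFrame:
    return pd.DataFrame({"depth": curve.depths, "mean_identity": curve.mean_identity})


# ---------------------------------------------------------------------------
# Minimal SAM export
# ---------------------------------------------------------------------------


def _cigar(aln: Alignment) -> str:
    if not aln.ops:
        return "*"
    parts = []
    prev = aln.ops[0]
    run = 1
    for op in aln.ops[1:]:
        if op == prev:
            run += 1
        else:
            parts.append(f"{run}{prev}")
            prev = op
            run = 1
    parts.append(f"{run}{prev}")
    lead = aln.read_start
    tail = len(aln.read) - aln.read_end
    return (f"{lead}S" if lead else "") + "".join(parts) + (f"{tail}S" if tail else "")


def write_sam(
    alignments: Sequence[Alignment],
    reference_lengths: Dict[str, int],
    path,
    read_ids: Optional[Sequence[str]] = None,
) -> None:
    """Minimal SAM: @HD/@SQ header, 1-based POS, CIGAR over S/=/X/I/D."""
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in reference_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for i, aln in enumerate(alignments):
        rid = read_ids[i] if read_ids is not None else f"read{i}"
        lines.append(
            "\t".join(
                [
                    rid,
                    "0",
                    aln.reference_id,
                    str(aln.ref_start + 1),
                    "255",
                    _cigar(aln),
                    "*",
                    "0",
                    "0",
                    aln.read,
                    "*",
                    f"AS:i:{aln.score}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
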