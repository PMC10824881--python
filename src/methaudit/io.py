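"""Plain-text readers and writers: FASTA, BED-like manifests, TSV tables."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .guidescan import GuideRNA, OffTargetHit, ProximityRecord
from .methylome import ProbeAnnotation

FLOAT_FMT = "%.10g"


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
                str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_probe_manifest(path, probes: list[ProbeAnnotation]) -> None:
    """BED-like manifest: chrom, start, end (0-based half-open), probe id,
    gene, CpG-island flag (0/1)."""
    df = pd.DataFrame([{
        "chrom": p.chromosome, "start": p.position, "end": p.position + 1,
        "probe_id": p.probe_id, "gene": p.gene, "cpg_island": int(p.cpg_island),
    } for p in probes])
    df.to_csv(path, sep="\t", index=False)


def read_probe_manifest(path) -> list[ProbeAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [ProbeAnnotation(probe_id=str(r.probe_id), chromosome=str(r.chrom),
                            position=int(r.start), gene=str(r.gene),
                            cpg_island=bool(int(r.cpg_island)))
            for r in df.itertuples()]


def write_guides(path, guides: list[GuideRNA]) -> None:
    pd.DataFrame([asdict(g) for g in guides]).to_csv(path, sep="\t", index=False)


def read_guides(path) -> list[GuideRNA]:
    df = pd.read_csv(path, sep="\t")
    return [GuideRNA(guide_id=str(r.guide_id), spacer=str(r.spacer),
                     pam_pattern=str(getattr(r, "pam_pattern", "NGG")))
            for r in df.itertuples()]


def write_hits(path, hits: list[OffTargetHit]) -> None:
    df = pd.DataFrame([{
        "chrom": h.chromosome, "start": h.start, "end": h.end,
        "guide_id": h.guide_id, "mismatches": h.mismatches, "strand": h.strand,
        "mismatch_positions": ";".join(map(str, h.mismatch_positions)),
        "pam_observed": h.pam_observed,
    } for h in hits])
    df.to_csv(path, sep="\t", index=False)


def write_proximity(path, records: list[ProximityRecord]) -> None:
    df = pd.DataFrame([{
        "guide_id": r.guide_id, "probe_id": r.probe_id, "distance": r.distance,
        "hit_start": r.hit.start, "hit_end": r.hit.end, "hit_strand": r.hit.strand,
        "hit_mismatches": r.hit.mismatches,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)
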