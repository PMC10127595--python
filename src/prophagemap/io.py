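"""Sequence and ground-truth serialization.

FASTA/FASTQ output goes through Biopython; ground truth from the simulator
is written as BED6 (feature class in the name column) plus a JSON manifest
so external mappers can be benchmarked against the planted features.
"""

from __future__ import annotations

import json
from dataclasses import asdict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["write_fasta", "write_fastq", "write_truth_bed", "write_truth_manifest"]


def write_fasta(genome, path) -> None:
    """Write a GenomeModel's replicons (or an iterable of them) to FASTA."""
    replicons = getattr(genome, "replicons", genome)
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"circular={str(r.circular).lower()} length={len(r.sequence)}",
        )
        for r in replicons
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(readset, path, quality: int = 35) -> None:
    """Write a ReadSet to FASTQ with a constant phred quality (paired mates
    interleaved as ``<id>/1`` and ``<id>/2``)."""
    records = []
    for r in readset.reads:
        if r.mate is None:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
            records.append(rec)
        else:
            for suffix, seq in (("/1", r.sequence), ("/2", r.mate)):
                rec = SeqRecord(Seq(seq), id=r.id + suffix, description="")
                rec.letter_annotations["phred_quality"] = [quality] * len(seq)
                records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_truth_bed(genome, path) -> None:
    """BED6 of planted features; name column is ``<class>:<detail>``."""
    with open(path, "w") as fh:
        for p in genome.prophages:
            fh.write(f"{p.replicon_id}\t{p.start}\t{p.end}\tcore:prophage\t0\t.\n")
            fi = p.flank_interval()
            if fi is not None:
                fh.write(
                    f"{p.replicon_id}\t{fi[0]}\t{fi[1]}\tflank:{p.flank_side}\t0\t.\n"
                )
        for c in genome.is_copies:
            loc = "inside_prophage" if c.inside_prophage else "chromosomal"
            fh.write(f"{c.replicon_id}\t{c.start}\t{c.end}\tis:{c.family}:{loc}\t0\t.\n")


def write_truth_manifest(genome, path, params=None) -> None:
    """JSON manifest of the full simulation ground truth."""
    doc = {
        "seed": genome.seed,
        "replicons": [
            {"id": r.id, "length": len(r.sequence), "circular": r.circular}
            for r in genome.replicons
        ],
        "prophages": [asdict(p) for p in genome.prophages],
        "is_copies": [asdict(c) for c in genome.is_copies],
        "coordinate_convention": "0-based half-open",
    }
    if params is not None:
        doc["read_sim_params"] = asdict(params)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
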