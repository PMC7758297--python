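"""Plain-text readers/writers for the pipeline's interchange formats.

Everything the pipeline writes is diffable text: FASTA for sequences (via
Bio.SeqIO), BED6 for intervals, TSV with headers for tables, a small
header-block TSV layout for PSSM profiles, and a 5-column BED-like TSV for
methylation tracks.  Coordinates in files are the formats' conventions
(BED: 0-based half-open; tabular search output: 1-based inclusive); in
memory everything is 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domains import AA20, DomainProfile
from .loci import ExtendedLocus
from .methyl import Feature, MethylationSite
from .search import SearchHit


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(features: Sequence[Feature], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for f in features:
            w.writerow([f.contig, f.start, f.end, f"{f.category}|{f.feature_id}", 0, "+"])


def read_bed_features(path) -> list[Feature]:
    out: list[Feature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            name = parts[3]
            category, _, fid = name.partition("|")
            out.append(Feature(fid or name, parts[0], int(parts[1]), int(parts[2]), category))
    return out


def write_loci_bed(loci: Sequence[ExtendedLocus], scores: Mapping[str, float], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for l in loci:
            w.writerow([l.contig_id, l.core_start, l.core_end, l.locus_id, int(scores.get(l.locus_id, 0)), l.strand])


HITS_COLUMNS = [
    "query", "subject", "pct_identity", "length", "q_start", "q_end",
    "s_start", "s_end", "evalue", "bitscore", "frame",
]


def write_hits_tsv(hits: Sequence[SearchHit], path) -> None:
    """Tabular search output; coordinates 1-based inclusive, as in -m 8 files."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HITS_COLUMNS)
        for h in hits:
            w.writerow([
                h.query_id, h.contig_id, f"{100 * h.pct_identity:.2f}", h.end - h.start,
                h.query_from + 1, h.query_to, h.start + 1, h.end,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.frame,
            ])


def write_methylation_tsv(sites: Sequence[MethylationSite], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in sites:
            w.writerow([s.contig, s.position, s.position + 1, s.context, f"{s.level:.4f}"])


def write_profile(profile: DomainProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"#profile_id\t{profile.profile_id}\n")
        fh.write(f"#category\t{profile.category}\n")
        fh.write(f"#length\t{profile.length}\n")
        fh.write("#background\t" + "\t".join(f"{b:.6f}" for b in profile.background) + "\n")
        fh.write("pos\t" + "\t".join(AA20) + "\n")
        for j in range(profile.length):
            fh.write(str(j) + "\t" + "\t".join(f"{x:.4f}" for x in profile.pssm[j]) + "\n")


def read_profile(path) -> DomainProfile:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    background = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif line and not line.startswith("pos\t"):
                rows.append([float(x) for x in line.split("\t")[1:]])
    return DomainProfile(meta["profile_id"], meta["category"], np.array(rows), background)


def read_wig_fixed_step(path, context: str = "CG") -> list[MethylationSite]:
    """Minimal fixedStep WIG reader (convenience; the contract format is the
    5-column TSV).  Positions in WIG are 1-based; converted to 0-based."""
    sites: list[MethylationSite] = []
    chrom, start, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
            elif line and chrom is not None:
                sites.append(MethylationSite(chrom, start, context, float(line)))
                start += step
    return sites
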