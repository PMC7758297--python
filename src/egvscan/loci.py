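"""From raw translated-search hits to classified EGV loci.

Hits on the same contig and strand are merged into candidate loci, each locus
is extended by up to 1 kb of flanking sequence to recover complete genes, the
encoded Rep-like protein is reconstructed (allowing a single canonical GT..AG
intron, since several geminivirus rep genes are interrupted by one), and each
predicted protein is classified by its best hit back against a mixed
reference library (geminivirus vs genomovirus vs phytoplasma plasmid).
Proteins whose best qualifying reference hit is not geminiviral, or that are
shorter than 90 aa, are excluded — with the exclusion reason retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .scoring import ScoringScheme, compute_evalue
from .search import SearchHit, protein_search, revcomp, six_frame_translate


@dataclass
class MergedInterval:
    contig_id: str
    strand: str
    start: int
    end: int
    source_hits: list[int] = field(default_factory=list)  # indices into the hit list


@dataclass
class ExtendedLocus:
    """A merged-hit core plus up-to-1-kb flanks, the unit 'EGV locus'."""

    locus_id: str
    contig_id: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    strand: str
    source_hits: list[int] = field(default_factory=list)


@dataclass
class IntronModel:
    donor: int  # locus-local nt position of the G of GT (strand-local sense)
    acceptor: int  # locus-local nt position just past the G of AG


@dataclass
class ClassifiedRep:
    source_id: str  # locus id or transcript id
    protein: str
    length_aa: int
    intron: IntronModel | None
    best_ref_id: str
    best_ref_label: str
    best_evalue: float


def merge_hits(hits: Sequence[SearchHit], max_gap: int = 0) -> list[MergedInterval]:
    """Union hits per (contig, strand).

    Two hits merge when their intervals share at least one base, or — with
    ``max_gap`` > 0 — when separated by at most ``max_gap`` nt.  Half-open
    adjacency ([100,200) next to [200,300)) does not merge at max_gap=0.
    Idempotent and independent of input order.
    """
    order = sorted(range(len(hits)), key=lambda i: (hits[i].contig_id, hits[i].strand, hits[i].start, hits[i].end))
    merged: list[MergedInterval] = []
    for i in order:
        h = hits[i]
        cur = merged[-1] if merged else None
        if (
            cur is not None
            and cur.contig_id == h.contig_id
            and cur.strand == h.strand
            and (h.start < cur.end or (max_gap > 0 and h.start - cur.end <= max_gap))
        ):
            cur.end = max(cur.end, h.end)
            cur.source_hits.append(i)
        else:
            merged.append(MergedInterval(h.contig_id, h.strand, h.start, h.end, [i]))
    return merged


def extend_locus(
    interval: MergedInterval,
    contig_length: int,
    flank: int = 1000,
    locus_id: str | None = None,
) -> ExtendedLocus:
    """Extend a merged interval by up to ``flank`` nt each side, clamped to the contig."""
    if not (0 <= interval.start < interval.end <= contig_length):
        raise ValueError("interval outside contig")
    return ExtendedLocus(
        locus_id=locus_id or f"{interval.contig_id}:{interval.start}-{interval.end}({interval.strand})",
        contig_id=interval.contig_id,
        core_start=interval.start,
        core_end=interval.end,
        ext_start=max(0, interval.start - flank),
        ext_end=min(contig_length, interval.end + flank),
        strand=interval.strand,
        source_hits=list(interval.source_hits),
    )


def _frame_alignments(query: str, seq: str, scheme: ScoringScheme, top_per_frame: int = 2):
    """Best (and masked second-best) local alignment of query vs each frame of seq.

    Returns tuples (strand, frame_offset, score, q_from, q_to, s_from, s_to)
    with s coordinates in aa on the strand-local translation.
    """
    aligner = scheme.make_aligner(mode="local")
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        frames = six_frame_translate(s)
        for off in (0, 1, 2):
            faa = frames[off + 1]
            if len(faa) < 1:
                continue
            work = faa
            for _ in range(top_per_frame):
                alignments = aligner.align(query, work)
                score = float(alignments.score)
                if score <= 0:
                    break
                aln = alignments[0]
                qb, sb = aln.aligned
                q_from, q_to = int(qb[0][0]), int(qb[-1][1])
                s_from, s_to = int(sb[0][0]), int(sb[-1][1])
                out.append((strand, off, score, q_from, q_to, s_from, s_to, faa[s_from:s_to]))
                # mask the aligned region so a second, collinear exon can surface
                work = work[:s_from] + "*" * (s_to - s_from) + work[s_to:]
    return out


def predict_rep_protein(
    locus_seq: str,
    query: str,
    scheme: ScoringScheme | None = None,
    min_intron: int = 40,
):
    """Reconstruct the Rep-like protein encoded by an extended locus.

    Evaluates (a) the best single-segment translated local alignment and
    (b) the best two-segment model whose segments lie on the same strand,
    are collinear on both query and genome, and are separated by a canonical
    GT..AG genomic gap of at least ``min_intron`` nt.  Returns
    ``(protein, intron_or_None, score, strand)`` for the winning model, or
    ``None`` when nothing scores above zero (locus dropped).
    """
    if scheme is None:
        scheme = ScoringScheme()
    cands = _frame_alignments(query, locus_seq, scheme)
    if not cands:
        return None
    best_single = max(cands, key=lambda c: c[2])
    best = (best_single[2], best_single[7].replace("-", ""), None, best_single[0])

    n = len(locus_seq)
    for a in cands:
        for b in cands:
            if a is b or a[0] != b[0]:
                continue
            # strand-local nt coordinates of the two aligned segments
            a_nt = (a[1] + 3 * a[5], a[1] + 3 * a[6])
            b_nt = (b[1] + 3 * b[5], b[1] + 3 * b[6])
            if not (a[4] <= b[3] and a_nt[1] < b_nt[0]):
                continue  # must be collinear on query and genome
            gap = b_nt[0] - a_nt[1]
            if gap < min_intron:
                continue
            s = locus_seq if a[0] == "+" else revcomp(locus_seq)
            intron_seq = s[a_nt[1] : b_nt[0]]
            if not (intron_seq.startswith("GT") and intron_seq.endswith("AG")):
                continue
            score = a[2] + b[2]
            if score > best[0]:
                spliced = six_frame_translate(s[a_nt[0] : a_nt[1]] + s[b_nt[0] : b_nt[1]])[1]
                best = (score, spliced, IntronModel(donor=a_nt[1], acceptor=b_nt[0]), a[0])
    score, protein, intron, strand = best
    if score <= 0 or not protein:
        return None
    return protein, intron, score, strand


def reciprocal_classify(
    proteins: Mapping[str, str],
    reference_library: Mapping[str, tuple[str, str]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
    min_len: int = 90,
) -> tuple[list[ClassifiedRep], dict[str, str]]:
    """Label each protein by its best reference hit; exclude weak/short ones.

    ``reference_library`` maps reference id -> (label, sequence) with labels
    drawn from {geminivirus, genomovirus, phytoplasma_plasmid}.  The best hit
    is the highest bitscore, ties broken by lower E-value then lexicographic
    reference id.  Proteins shorter than ``min_len`` aa or with no hit at
    E <= ``e_max`` are excluded; reasons are returned alongside.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not reference_library:
        raise ValueError("reference library is empty")
    labels = {label for label, _ in reference_library.values()}
    required = {"geminivirus", "genomovirus", "phytoplasma_plasmid"}
    if not required <= labels:
        raise ValueError(f"reference library must cover labels {sorted(required)}")

    refs = {rid: seq for rid, (label, seq) in reference_library.items()}
    classified: list[ClassifiedRep] = []
    excluded: dict[str, str] = {}
    long_enough = {}
    for pid, prot in proteins.items():
        if len(prot) < min_len:
            excluded[pid] = f"length {len(prot)} aa < {min_len}"
        else:
            long_enough[pid] = prot
    hits = protein_search(long_enough, refs, scheme, e_max=e_max)
    best: dict[str, object] = {}
    for h in hits:  # already sorted by (query, -bitscore, evalue, subject)
        best.setdefault(h.query_id, h)
    for pid, prot in long_enough.items():
        h = best.get(pid)
        if h is None:
            excluded[pid] = f"no reference hit at E <= {e_max:g}"
            continue
        label = reference_library[h.subject_id][0]
        classified.append(
            ClassifiedRep(
                source_id=pid,
                protein=prot,
                length_aa=len(prot),
                intron=None,
                best_ref_id=h.subject_id,
                best_ref_label=label,
                best_evalue=h.evalue,
            )
        )
    return classified, excluded
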