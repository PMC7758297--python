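"""Reconstruction of ancestral circular viral genomes ("EGV integrons").

Many EGV loci in a single genome descend from one integrating virus.  When
the flank-extended loci are cut into k-mers, k-mers belonging to the
ancestral viral circle recur across loci (high multiplicity) while host
flank k-mers are unique, so a multiplicity-filtered De Bruijn graph distils
the circle back out.  Candidates in the geminivirus size range (2.5-5 kb)
are rotated so the conserved virion-strand replication-origin nonanucleotide
TAATATTAC sits at position 0, and ORFs longer than 75 aa are called on both
strands (junction-aware on circular sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .scoring import ScoringScheme
from .search import protein_search, revcomp, six_frame_translate

NONANUCLEOTIDE = "TAATATTAC"
DEFAULT_K = (21, 33, 55, 77, 99, 127)


@dataclass
class ORF:
    start: int  # nt on contig; for circular contigs end may exceed the length (wrap)
    end: int
    strand: str
    protein: str
    annotation: str | None = None

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class IntegronContig:
    sequence: str
    k: int
    mean_coverage: float
    circular: bool
    origin_flag: str = "unrotated"  # 'origin' | 'no-origin' | 'multi-origin' | 'unrotated'
    origin_pos: int | None = None
    orfs: list[ORF] = field(default_factory=list)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(sequences: Sequence[str], k: int) -> dict[str, int]:
    """Multiplicities of canonical k-mers (odd k, so no palindromes)."""
    counts: dict[str, int] = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            km = canonical(seq[i : i + k])
            counts[km] = counts.get(km, 0) + 1
    return counts


def _compact(kmers: Mapping[str, int], k: int) -> list[IntegronContig]:
    """Compact the De Bruijn graph of the given k-mers into unitigs.

    Both orientations of every canonical k-mer enter a directed graph over
    (k-1)-mer nodes; maximal non-branching paths become linear unitigs and
    isolated simple cycles become circular unitigs.  Reverse-complement
    twins are deduplicated to one representative.
    """
    out_edges: dict[str, list[tuple[str, str, int]]] = {}
    in_deg: dict[str, int] = {}

    def add_edge(km: str, count: int) -> None:
        u, v = km[:-1], km[1:]
        out_edges.setdefault(u, []).append((v, km, count))
        in_deg[v] = in_deg.get(v, 0) + 1
        in_deg.setdefault(u, in_deg.get(u, 0))

    for km in sorted(kmers):
        c = kmers[km]
        add_edge(km, c)
        add_edge(revcomp(km), c)
    for u in out_edges.values():
        u.sort()

    def is_branch(node: str) -> bool:
        return len(out_edges.get(node, ())) != 1 or in_deg.get(node, 0) != 1

    visited: set[str] = set()  # oriented k-mers consumed
    unitigs: list[tuple[str, float, bool]] = []

    def walk(km0: str) -> tuple[str, float, bool]:
        path = [km0]
        visited.add(km0)
        node = km0[1:]
        while not is_branch(node):
            (nxt, km, _c) = out_edges[node][0]
            if km in visited:
                break
            path.append(km)
            visited.add(km)
            node = km[1:]
        seq = path[0] + "".join(km[-1] for km in path[1:])
        cov = sum(kmers[canonical(km)] for km in path) / len(path)
        circular = len(seq) >= 2 * (k - 1) and seq[: k - 1] == seq[-(k - 1) :] and not is_branch(km0[:-1])
        if circular:
            seq = seq[: -(k - 1)]
        return seq, cov, circular

    # linear unitigs start on edges out of branch nodes
    for node in sorted(out_edges):
        if is_branch(node):
            for _v, km, _c in out_edges[node]:
                if km not in visited:
                    unitigs.append(walk(km))
    # remaining edges lie on isolated simple cycles
    for node in sorted(out_edges):
        for _v, km, _c in out_edges[node]:
            if km not in visited:
                unitigs.append(walk(km))

    seen: set[str] = set()
    contigs: list[IntegronContig] = []
    for seq, cov, circular in unitigs:
        if circular:
            rots = [seq[i:] + seq[:i] for i in range(len(seq))]
            rc = revcomp(seq)
            rots += [rc[i:] + rc[:i] for i in range(len(rc))]
            key = "C:" + min(rots)
        else:
            key = "L:" + min(seq, revcomp(seq))
        if key in seen:
            continue
        seen.add(key)
        contigs.append(IntegronContig(seq, k, cov, circular))
    contigs.sort(key=lambda c: (-c.circular, -c.mean_coverage, -len(c.sequence), c.sequence))
    return contigs


def assemble_loci(
    sequences: Sequence[str],
    k_values: Sequence[int] = DEFAULT_K,
    min_cov: float = 5.0,
    size_range: tuple[int, int] = (2500, 5000),
) -> tuple[list[IntegronContig], dict[int, list[IntegronContig]]]:
    """Multi-k De Bruijn assembly of extended-locus sequences.

    Per k, k-mers with multiplicity below ``min_cov`` are dropped (host
    flanks are unique, the shared viral circle recurs), the remaining graph
    is compacted, and unitigs within ``size_range`` become candidates.  The
    best candidate set (circularity, then coverage, then length) is
    returned first; the per-k results are returned alongside.
    """
    usable = [k for k in k_values if k % 2 == 1 and any(len(s) >= k for s in sequences)]
    if not usable:
        raise ValueError("all sequences shorter than the smallest odd k")
    lo, hi = size_range
    per_k: dict[int, list[IntegronContig]] = {}
    for k in usable:
        counts = {km: c for km, c in count_kmers(sequences, k).items() if c >= min_cov}
        contigs = _compact(counts, k) if counts else []
        per_k[k] = [c for c in contigs if lo <= len(c.sequence) <= hi]

    def rank(cands: list[IntegronContig]):
        if not cands:
            return (0, 0.0, 0)
        best = cands[0]
        return (int(best.circular), best.mean_coverage, len(best.sequence))

    best_k = max(per_k, key=lambda k: rank(per_k[k]))
    return per_k[best_k], per_k


def circularize_at_origin(contig: IntegronContig, nonanucleotide: str = NONANUCLEOTIDE) -> IntegronContig:
    """Rotate a circular contig so the origin nonanucleotide starts at 0.

    Both strands are searched (junction-aware); if the motif lies on the
    reverse strand the contig is reverse-complemented first.  With no motif
    the sequence is kept and flagged 'no-origin'; with several occurrences
    the lowest position wins and the contig is flagged 'multi-origin'.
    """
    if not contig.circular:
        raise ValueError("contig is not circular")
    L = len(contig.sequence)

    def occurrences(seq: str) -> list[int]:
        doubled = seq + seq[: len(nonanucleotide) - 1]
        out = []
        p = doubled.find(nonanucleotide)
        while p != -1:
            out.append(p)
            p = doubled.find(nonanucleotide, p + 1)
        return out

    seq = contig.sequence
    occ = occurrences(seq)
    if not occ:
        seq_rc = revcomp(seq)
        occ = occurrences(seq_rc)
        if occ:
            seq = seq_rc
    if not occ:
        contig.origin_flag = "no-origin"
        contig.origin_pos = None
        return contig
    pos = occ[0]
    contig.sequence = seq[pos:] + seq[:pos]
    contig.origin_pos = 0
    contig.origin_flag = "origin" if len(occ) == 1 else "multi-origin"
    return contig


def find_orfs(
    sequence: str,
    circular: bool = False,
    min_aa: int = 75,
    reference_proteins: Mapping[str, str] | None = None,
    scheme: ScoringScheme | None = None,
) -> list[ORF]:
    """ATG-to-stop ORFs on both strands, strictly longer than ``min_aa`` aa.

    On circular sequences the sequence is doubled internally so ORFs may
    cross the junction; duplicates are removed.  Each ORF may optionally be
    annotated with its best-matching viral reference protein.
    """
    L = len(sequence)
    orfs: list[ORF] = []
    seen: set[tuple[str, int, int]] = set()
    for strand, s in (("+", sequence), ("-", revcomp(sequence))):
        work = s + s if circular else s
        frames = six_frame_translate(work)
        for off in (0, 1, 2):
            aa = frames[off + 1]
            seg_start = 0  # aa index where current inter-stop segment starts
            i = 0
            while i <= len(aa):
                if i == len(aa) or aa[i] == "*":
                    m = aa.find("M", seg_start, i)
                    if m != -1 and i < len(aa):  # require a real stop codon
                        prot = aa[m:i]
                        nt_start = off + 3 * m
                        nt_end = off + 3 * (i + 1)
                        if len(prot) > min_aa and (not circular or (nt_start < L and nt_end - nt_start <= L)):
                            if strand == "+":
                                f_start = nt_start % L if circular else nt_start
                            else:
                                f_start = (L - (nt_end % L)) % L if circular else L - nt_end
                            f_end = f_start + (nt_end - nt_start)
                            key = (strand, f_start, f_end)
                            if key not in seen:
                                seen.add(key)
                                orfs.append(ORF(f_start, f_end, strand, prot))
                    seg_start = i + 1
                i += 1
    if reference_proteins:
        queries = {f"orf{j}": o.protein for j, o in enumerate(orfs)}
        hits = protein_search(queries, dict(reference_proteins), scheme)
        best: dict[str, str] = {}
        for h in hits:
            best.setdefault(h.query_id, h.subject_id)
        for j, o in enumerate(orfs):
            o.annotation = best.get(f"orf{j}")
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs
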