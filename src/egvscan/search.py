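"""Translated homology search of protein queries against nucleotide assemblies.

This is the discovery stage of the pipeline: each protein query (a viral Rep
library) is compared against all six reading frames of every contig, the way
a translated nucleotide search (tBLASTn) would.  The implementation is a
classic seed-and-extend design:

1. six-frame conceptual translation of the subject;
2. exact word seeding (default 3-mers) with a two-hit-on-a-diagonal trigger;
3. gapped local alignment of the query against a window around each seed
   cluster (full dynamic programming for short frames, so that small-subject
   searches are exactly the Smith-Waterman optimum);
4. Karlin-Altschul E-value calibration against the raw m*n search space.

Coordinates are 0-based half-open nucleotide positions on the forward strand
of the subject contig, regardless of the frame the hit was found in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scoring import ScoringScheme, compute_evalue

FRAMES = (1, 2, 3, -1, -2, -3)

# -- nucleotide encoding ----------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _BASE_CODE[ord(_c)] = _i
    _BASE_CODE[ord(_c.lower())] = _i

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_CODON_BASES = "TCAG"
_CODON_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)


def _build_codon_lut() -> np.ndarray:
    lut = np.full(125, ord("X"), dtype=np.uint8)
    order = {b: "TCAG".index(b) for b in "TCAG"}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for b0 in "ACGT":
        for b1 in "ACGT":
            for b2 in "ACGT":
                aa = _CODON_AAS[16 * order[b0] + 4 * order[b1] + order[b2]]
                lut[25 * code[b0] + 5 * code[b1] + code[b2]] = ord(aa)
    return lut


_CODON_LUT = _build_codon_lut()


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string (ACGTN, case-insensitive) as uint8 codes."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = chr(np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[codes == 255][0])
        raise ValueError(f"illegal nucleotide character {bad!r}")
    return codes


def revcomp(seq: str) -> str:
    codes = encode_nt(seq)
    return _COMP[codes][::-1].tobytes().decode("ascii").translate(_DECODE)


_DECODE = str.maketrans("\x00\x01\x02\x03\x04", "ACGTN")


def _translate_codes(codes: np.ndarray, offset: int) -> str:
    n = (codes.size - offset) // 3
    if n <= 0:
        return ""
    cod = codes[offset : offset + 3 * n].reshape(n, 3).astype(np.int32)
    idx = 25 * cod[:, 0] + 5 * cod[:, 1] + cod[:, 2]
    return _CODON_LUT[idx].tobytes().decode("ascii")


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate ``seq`` in all six frames.

    Frames +1..+3 read the forward strand at offsets 0..2; frames -1..-3
    read the reverse complement at offsets 0..2.  Stop codons are rendered
    '*'; any codon containing N becomes 'X'; trailing partial codons are
    dropped.  Raises ValueError on characters outside ACGTN.
    """
    codes = encode_nt(seq)
    rc = _COMP[codes][::-1]
    return {
        1: _translate_codes(codes, 0),
        2: _translate_codes(codes, 1),
        3: _translate_codes(codes, 2),
        -1: _translate_codes(rc, 0),
        -2: _translate_codes(rc, 1),
        -3: _translate_codes(rc, 2),
    }


# -- amino-acid word encoding for seeding -----------------------------------

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"
_AA_CODE = np.full(256, len(_AA_ALPHABET), dtype=np.int32)
for _i, _c in enumerate(_AA_ALPHABET):
    _AA_CODE[ord(_c)] = _i
_AA_RADIX = len(_AA_ALPHABET) + 1


def _word_ids(aa: str, w: int) -> np.ndarray:
    codes = _AA_CODE[np.frombuffer(aa.encode("ascii"), dtype=np.uint8)]
    if codes.size < w:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(codes.size - w + 1, dtype=np.int64)
    for j in range(w):
        ids = ids * _AA_RADIX + codes[j : codes.size - w + 1 + j]
    return ids


# -- hits -------------------------------------------------------------------


@dataclass
class SearchHit:
    """A local alignment between a protein query and one subject frame."""

    query_id: str
    contig_id: str
    start: int  # 0-based half-open nt, forward strand
    end: int
    strand: str  # '+' or '-'
    frame: int  # +1..+3 / -1..-3
    raw_score: float
    bitscore: float
    evalue: float
    pct_identity: float  # fraction in [0,1]
    query_from: int  # 0-based half-open aa on the query
    query_to: int
    subject_aa_from: int = 0  # aa coordinates on the frame translation
    subject_aa_to: int = 0

    def interval(self) -> tuple[str, str, int, int]:
        return (self.contig_id, self.strand, self.start, self.end)


def _frame_to_nt(frame: int, contig_len: int, aa_from: int, aa_to: int) -> tuple[int, int]:
    """Map an aa span on a frame translation to forward-strand nt coordinates."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_from, off + 3 * aa_to
    return contig_len - (off + 3 * aa_to), contig_len - (off + 3 * aa_from)


def _alignment_stats(alignment) -> tuple[int, int, int, int, float]:
    """(q_from, q_to, s_from, s_to, identity) from a Bio.Align alignment.

    Identity = identical columns / aligned columns (internal gap columns
    included in the denominator).
    """
    qblocks, sblocks = alignment.aligned
    if len(qblocks) == 0:  # e.g. free-end-gap alignment with no aligned columns
        return 0, 0, 0, 0, 0.0
    q_from, q_to = int(qblocks[0][0]), int(qblocks[-1][1])
    s_from, s_to = int(sblocks[0][0]), int(sblocks[-1][1])
    query = alignment.sequences[0]
    subject = alignment.sequences[1]
    ident = 0
    cols = 0
    prev_q = prev_s = None
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        if prev_q is not None:
            cols += (qa - prev_q) + (sa - prev_s)
        for k in range(qb - qa):
            cols += 1
            if query[qa + k] == subject[sa + k]:
                ident += 1
        prev_q, prev_s = qb, sb
    identity = ident / cols if cols else 0.0
    return q_from, q_to, s_from, s_to, identity


def _seed_windows(
    query: str,
    frame_aa: str,
    word_size: int,
    two_hit_span: int = 40,
) -> list[tuple[int, int]]:
    """Candidate alignment windows on ``frame_aa`` from two-hit diagonal seeding."""
    qw = _word_ids(query, word_size)
    sw = _word_ids(frame_aa, word_size)
    if qw.size == 0 or sw.size == 0:
        return []
    order = np.argsort(sw, kind="stable")
    sw_sorted = sw[order]
    left = np.searchsorted(sw_sorted, qw, side="left")
    right = np.searchsorted(sw_sorted, qw, side="right")
    counts = right - left
    if not counts.any():
        return []
    qpos = np.repeat(np.arange(qw.size), counts)
    spos = np.concatenate([order[l:r] for l, r in zip(left, right) if r > l])
    diag = spos - qpos
    idx = np.lexsort((spos, diag))
    diag_s, spos_s = diag[idx], spos[idx]
    # two non-overlapping word hits on one diagonal within the span; seeds on
    # a diagonal are strictly increasing, so lags 1..word_size suffice
    trigger = np.zeros(diag_s.size, dtype=bool)
    for lag in range(1, word_size + 1):
        if diag_s.size <= lag:
            break
        same = diag_s[lag:] == diag_s[:-lag]
        gap = spos_s[lag:] - spos_s[:-lag]
        trigger[lag:] |= same & (gap >= word_size) & (gap <= two_hit_span)
    if not trigger.any():
        return []
    anchors = np.unique(spos_s[trigger])
    margin = len(query) + 20
    windows: list[list[int]] = []
    for a in anchors:
        lo = max(0, int(a) - margin)
        hi = min(len(frame_aa), int(a) + margin + word_size)
        if windows and lo <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    return [(a, b) for a, b in windows]


def translated_search(
    queries: Mapping[str, str],
    subject: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
    exhaustive_limit: int = 2000,
) -> list[SearchHit]:
    """Search protein ``queries`` against all six frames of ``subject`` contigs.

    For frames up to ``exhaustive_limit`` aa the query is aligned against the
    whole frame (exact local-alignment optimum); longer frames are seeded with
    two word hits on a diagonal and aligned only within windows around the
    seed clusters.  Hits with E-value <= ``e_max`` are returned sorted by
    (contig, start).

    The search-space size n used for E-values is the total number of amino
    acids over all frames of all contigs.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if not queries:
        raise ValueError("query set is empty")

    frames_by_contig = {cid: six_frame_translate(seq) for cid, seq in subject.items()}
    n_letters = sum(len(f) for fr in frames_by_contig.values() for f in fr.values())
    if n_letters == 0:
        return []

    aligner = scheme.make_aligner(mode="local")
    hits: list[SearchHit] = []
    for qid, qseq in queries.items():
        if len(qseq) < scheme.word_size:
            warnings.warn(f"query {qid!r} shorter than word size; skipped")
            continue
        for cid, frames in frames_by_contig.items():
            contig_len = len(subject[cid])
            for frame, faa in frames.items():
                if len(faa) < scheme.word_size:
                    continue
                if len(faa) <= exhaustive_limit:
                    windows = [(0, len(faa))]
                else:
                    windows = _seed_windows(qseq, faa, scheme.word_size)
                for wa, wb in windows:
                    wseq = faa[wa:wb]
                    alignments = aligner.align(qseq, wseq)
                    score = float(alignments.score)
                    if score <= 0:
                        continue
                    aln = alignments[0]
                    q_from, q_to, s_from, s_to, identity = _alignment_stats(aln)
                    s_from += wa
                    s_to += wa
                    bit, ev = compute_evalue(score, len(qseq), n_letters, scheme)
                    if ev > e_max:
                        continue
                    nt_start, nt_end = _frame_to_nt(frame, contig_len, s_from, s_to)
                    hits.append(
                        SearchHit(
                            query_id=qid,
                            contig_id=cid,
                            start=nt_start,
                            end=nt_end,
                            strand="+" if frame > 0 else "-",
                            frame=frame,
                            raw_score=score,
                            bitscore=bit,
                            evalue=ev,
                            pct_identity=identity,
                            query_from=q_from,
                            query_to=q_to,
                            subject_aa_from=s_from,
                            subject_aa_to=s_to,
                        )
                    )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.query_id, h.frame))
    return hits


# -- protein-protein search (reused by classification and grouping) ---------


@dataclass
class ProteinHit:
    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    pct_identity: float


def protein_search(
    queries: Mapping[str, str],
    library: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_max: float = float("inf"),
) -> list[ProteinHit]:
    """All-vs-all gapped local alignment of ``queries`` against ``library``.

    E-values use n = total library letters, so results are comparable to a
    protein database search against the whole library.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not library:
        raise ValueError("reference library is empty")
    n_letters = sum(len(s) for s in library.values())
    aligner = scheme.make_aligner(mode="local")
    out: list[ProteinHit] = []
    for qid, q in queries.items():
        for sid, s in library.items():
            if not q or not s:
                continue
            alignments = aligner.align(q, s)
            score = float(alignments.score)
            if score <= 0:
                continue
            bit, ev = compute_evalue(score, len(q), n_letters, scheme)
            if ev > e_max:
                continue
            _, _, _, _, identity = _alignment_stats(alignments[0])
            out.append(ProteinHit(qid, sid, score, bit, ev, identity))
    out.sort(key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id))
    return out
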