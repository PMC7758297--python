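"""Profile (PSSM) domain scanning of locus flanks and transcripts.

The genomic neighbourhood of an EGV locus tells its story: host-gene domains
in the ±5-kb flanks are evidence of genuine endogenization, additional viral
domains (coat-protein- or movement-protein-like) suggest a larger integrated
viral fragment, and a transcript carrying both a Rep domain and a host
domain is a co-transcript — a viral gene expressed from a host mRNA.

Profiles are ungapped position-specific scoring matrices (log-odds in bits
against a background amino-acid distribution) built from small seed
alignments.  Scanning slides the profile along the target (overhangs
allowed), takes the maximal-scoring contiguous segment per offset, and
calibrates significance with a per-profile Karlin lambda computed from the
profile's own score distribution under the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .search import six_frame_translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = np.full(256, 20, dtype=np.int64)  # index 20 = unknown ('X', '*', ...)
for _i, _c in enumerate(AA20):
    _AA_INDEX[ord(_c)] = _i

UNKNOWN_SCORE = -1.0  # score for non-standard residues at any profile column


@dataclass
class DomainProfile:
    profile_id: str
    category: str  # 'geminiviral' | 'host'
    pssm: np.ndarray  # L x 20 log-odds (bits)
    background: np.ndarray  # length-20 background frequencies
    lam: float = field(default=0.0)  # Karlin lambda for this profile's scores
    K: float = 0.1

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
            raise ValueError("pssm must be L x 20")
        if self.pssm.shape[0] < 10:
            raise ValueError("profile length must be >= 10")
        if not np.isfinite(self.pssm).all():
            raise ValueError("pssm scores must be finite")
        if self.lam <= 0:
            self.lam = karlin_lambda(self.pssm, self.background)


@dataclass
class DomainHit:
    profile_id: str
    target_id: str
    target_from: int  # aa, 0-based half-open
    target_to: int
    score: float  # bits
    evalue: float
    frame: int = 0  # 0 for protein targets; +-1..3 for translated nt targets


def karlin_lambda(pssm: np.ndarray, background: np.ndarray) -> float:
    """Solve sum_j sum_a (p_a / L) * exp(lambda * s_ja) = 1 for lambda > 0.

    This is the ungapped Karlin-Altschul scale parameter for the pooled
    per-column score distribution; it requires a negative expected score and
    at least one positive score, which any log-odds PSSM satisfies.
    """
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    L = pssm.shape[0]

    def f(lam: float) -> float:
        return float(np.sum(bg[None, :] / L * np.exp(lam * pssm)) - 1.0)

    hi = 1.0
    while f(hi) < 0 and hi < 1024:
        hi *= 2
    return float(optimize.brentq(f, 1e-9, hi))


def build_profile(
    profile_id: str,
    category: str,
    seed_sequences: Sequence[str],
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> DomainProfile:
    """Build a log-odds PSSM from an ungapped seed alignment.

    All seed sequences must have equal length L >= 10.  Scores are
    log2((counts + pseudocount * bg) / (n + pseudocount) / bg).
    """
    if not seed_sequences:
        raise ValueError("empty seed alignment")
    L = len(seed_sequences[0])
    if any(len(s) != L for s in seed_sequences):
        raise ValueError("seed sequences must be aligned to equal length")
    bg = np.full(20, 0.05) if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    counts = np.zeros((L, 20), dtype=float)
    for s in seed_sequences:
        idx = _AA_INDEX[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        ok = idx < 20
        counts[np.nonzero(ok)[0], idx[ok]] += 1.0
    n = len(seed_sequences)
    freqs = (counts + pseudocount * bg[None, :]) / (n + pseudocount)
    pssm = np.log2(freqs / bg[None, :])
    return DomainProfile(profile_id, category, pssm, bg)


def _scan_one(profile: DomainProfile, idx: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal-scoring segments of the profile against an encoded target.

    Returns (target_from, target_to, score) candidates, one per window
    offset, via Kadane's maximal-subarray over the per-column scores; the
    profile may overhang the target (overhanging columns contribute 0).
    """
    L = profile.length
    n = idx.size
    if n < L:
        return []
    scores = np.concatenate([profile.pssm, np.full((L, 1), UNKNOWN_SCORE)], axis=1)
    pad = np.full(L - 1, 21, dtype=np.int64)  # sentinel column index
    scores = np.concatenate([scores, np.zeros((L, 1))], axis=1)  # col 21: overhang, 0
    padded = np.concatenate([pad, idx, pad])
    win = np.lib.stride_tricks.sliding_window_view(padded, L)  # (n+L-1, L)
    D = scores[np.arange(L)[None, :], win]  # (n_offsets, L)
    n_off = D.shape[0]
    best = np.zeros(n_off)
    best_end = np.zeros(n_off, dtype=np.int64)
    be = np.zeros(n_off)
    be_start = np.zeros(n_off, dtype=np.int64)
    best_start = np.zeros(n_off, dtype=np.int64)
    for j in range(L):
        restart = be < 0
        be[restart] = 0.0
        be_start[restart] = j
        be = be + D[:, j]
        better = be > best
        best[better] = be[better]
        best_start[better] = be_start[better]
        best_end[better] = j + 1
    out = []
    for o in range(n_off):
        if best[o] <= 0:
            continue
        # offset o places profile column 0 at target position o - (L-1)
        t0 = o - (L - 1) + int(best_start[o])
        t1 = o - (L - 1) + int(best_end[o])
        t0c, t1c = max(0, t0), min(n, t1)
        if t1c <= t0c:
            continue
        out.append((t0c, t1c, float(best[o])))
    return out


def scan_domains(
    targets: Mapping[str, str],
    profiles: Sequence[DomainProfile],
    e_max: float = 0.001,
    is_nucleotide: bool = False,
    max_hits_per_pair: int = 10,
) -> list[DomainHit]:
    """Scan targets with every profile; keep hits with E <= ``e_max``.

    Nucleotide targets are six-frame translated first.  Per (profile,
    target-frame) pair the best non-overlapping segments are reported
    greedily.  E = K * L * n * exp(-lambda * S).  Targets shorter than the
    shortest profile are skipped with a warning.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    min_L = min(p.length for p in profiles)
    hits: list[DomainHit] = []
    for tid, seq in targets.items():
        if is_nucleotide:
            frames = six_frame_translate(seq)
        else:
            frames = {0: seq}
        if max(len(f) for f in frames.values()) < min_L:
            warnings.warn(f"target {tid!r} shorter than shortest profile; skipped")
            continue
        for frame, aa in frames.items():
            idx = _AA_INDEX[np.frombuffer(aa.encode("ascii"), dtype=np.uint8)]
            for prof in profiles:
                cands = _scan_one(prof, idx)
                cands.sort(key=lambda c: -c[2])
                taken: list[tuple[int, int]] = []
                for t0, t1, s in cands:
                    if len(taken) >= max_hits_per_pair:
                        break
                    if any(t0 < b and a < t1 for a, b in taken):
                        continue
                    ev = prof.K * prof.length * len(aa) * float(np.exp(-prof.lam * s))
                    if ev > e_max:
                        break
                    taken.append((t0, t1))
                    hits.append(DomainHit(prof.profile_id, tid, t0, t1, s, ev, frame))
    hits.sort(key=lambda h: (h.target_id, h.evalue, h.profile_id, h.target_from))
    return hits


def classify_locus_context(
    flank_hits: Sequence[DomainHit],
    profiles: Sequence[DomainProfile],
    rep_profile_ids: Iterable[str] = ("Rep_AL1",),
) -> str:
    """Classify a locus by the domain content of its flanks.

    host_flanked when any host-category domain is present (evidence the
    insertion sits in genuine host sequence); else multi_viral when any
    non-Rep geminiviral domain is present; else rep_only.
    """
    categories = {p.profile_id: p.category for p in profiles}
    rep_ids = set(rep_profile_ids)
    has_host = any(categories.get(h.profile_id) == "host" for h in flank_hits)
    if has_host:
        return "host_flanked"
    has_other_viral = any(
        categories.get(h.profile_id) == "geminiviral" and h.profile_id not in rep_ids for h in flank_hits
    )
    return "multi_viral" if has_other_viral else "rep_only"


def flag_cotranscripts(
    transcript_hits: Mapping[str, Sequence[DomainHit]],
    profiles: Sequence[DomainProfile],
    rep_profile_ids: Iterable[str] = ("Rep_AL1",),
) -> list[str]:
    """Transcripts carrying both a Rep-domain hit and a host-domain hit."""
    categories = {p.profile_id: p.category for p in profiles}
    rep_ids = set(rep_profile_ids)
    out = []
    for tid, hits in transcript_hits.items():
        has_rep = any(h.profile_id in rep_ids for h in hits)
        has_host = any(categories.get(h.profile_id) == "host" for h in hits)
        if has_rep and has_host:
            out.append(tid)
    return sorted(out)


def filter_al1_fraction(
    nt_sequences: Mapping[str, str],
    al1_profile: DomainProfile,
    min_nt: int = 150,
    e_max: float = 0.001,
) -> list[str]:
    """Retain sequences whose best AL1-domain hit covers >= ``min_nt`` nt.

    The covered span is the aa extent of the best AL1 hit times three;
    the boundary is inclusive (exactly ``min_nt`` nt is retained).
    """
    hits = scan_domains(nt_sequences, [al1_profile], e_max=e_max, is_nucleotide=True)
    best: dict[str, int] = {}
    for h in hits:
        span_nt = 3 * (h.target_to - h.target_from)
        best[h.target_id] = max(best.get(h.target_id, 0), span_nt)
    return sorted(sid for sid, span in best.items() if span >= min_nt)
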