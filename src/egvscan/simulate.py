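"""Synthetic data generation with recorded ground truth.

Every input the pipeline consumes can be generated here: host genomes with
neutral background and planted repeat families, circular geminivirus-like
genomes with the TAATATTAC virion-strand origin and Rep/CP/MP ORFs,
variably degraded implanted fragments (substitutions, 1-nt indels, premature
stops, end truncation, tandem hotspot placement), a mixed Rep reference
library (geminivirus plus genomovirus and phytoplasma-plasmid outgroups),
Rep-HSP70 co-transcripts evolved under a chosen dN/dS, per-context cytosine
methylation tracks, and PSSM domain profiles.  All generators are
deterministic under a fixed seed.

The protein families are anchored on a fixed set of ancestral sequences
(drawn once from an internal family seed), so that independently generated
viral genomes, reference libraries and domain profiles are mutually
consistent: an implant degraded from a default viral genome really is closer
to the geminivirus references than to the outgroups.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .domains import DomainProfile, build_profile
from .methyl import CONTEXTS, Feature, MethylationSite
from .search import revcomp
from .selection import translate_cds

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NONANUCLEOTIDE = "TAATATTAC"
_FAMILY_SEED = 20200715  # anchors the ancestral protein families

import itertools as _it

_SYN_CODONS: dict[str, list[str]] = {}
for _codon in ("".join(t) for t in _it.product("ACGT", repeat=3)):
    _aa = translate_cds(_codon)
    _SYN_CODONS.setdefault(_aa, []).append(_codon)


# -- degradation & truth records -------------------------------------------


@dataclass
class DegradationModel:
    """Post-integration decay applied to each implanted fragment."""

    sub_rate: float = 0.0  # per-nt substitution probability
    indel_mean: float = 0.0  # Poisson mean number of 1-nt indels
    n_stops: int = 0  # forced in-frame stop codons
    truncation_max: float = 0.0  # max fraction of length removed from the ends

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.truncation_max):
            if not 0 <= r <= 1:
                raise ValueError("degradation rates must lie in [0, 1]")
        if self.indel_mean < 0 or self.n_stops < 0:
            raise ValueError("indel_mean and n_stops must be non-negative")


@dataclass
class DegradationRecord:
    sub_rate: float
    n_indels: int
    n_stops: int
    truncation_fraction: float
    left_trim: int = 0  # nt removed from the arc's 5' end by truncation


@dataclass
class ImplantTruth:
    contig: str
    start: int  # 0-based half-open, coordinates in the final mutated genome
    end: int
    strand: str
    source_id: str
    source_span: tuple[int, int]  # arc on the circular source (may wrap)
    fragment: str  # the degraded fragment, in source (arc) orientation
    degradation: DegradationRecord
    in_hotspot: bool


@dataclass
class ViralGenomeTruth:
    proteins: dict[str, str]  # gene -> protein (rep, cp, mp)
    cds: dict[str, tuple[int, int]]  # gene -> [start, end) incl. stop codon
    al1_span: tuple[int, int]  # nt span of the AL1-like region within rep


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    truth: list[ImplantTruth]
    viral_genome: str
    viral_truth: ViralGenomeTruth
    viral_refs: dict[str, tuple[str, str]]  # id -> (label, aa sequence)
    transcripts: dict[str, str]
    transcript_cds: dict[str, dict[str, tuple[int, int]]]
    methylation: list[MethylationSite]
    features: list[Feature]
    profiles: list[DomainProfile]
    seed: int


# -- ancestral protein families ---------------------------------------------


def _random_protein(rng: np.random.Generator, length: int, start_met: bool = True) -> str:
    aas = rng.choice(list(AA20), size=length)
    s = "".join(aas)
    return ("M" + s[1:]) if start_met else s


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


@functools.lru_cache(maxsize=1)
def ancestral_proteins() -> dict[str, str]:
    """The fixed ancestral protein set every generator derives from."""
    rng = np.random.default_rng(_FAMILY_SEED)
    anc = {
        "rep": _random_protein(rng, 350),
        "cp": _random_protein(rng, 220),
        "mp": _random_protein(rng, 110),
        "hsp70": _random_protein(rng, 300),
        "nadgh": _random_protein(rng, 200),
        "host1": _random_protein(rng, 150),
        "host2": _random_protein(rng, 150),
        "host3": _random_protein(rng, 150),
        # outgroup Rep ancestors: far from the geminivirus Rep but related
        "rep_genomovirus": None,
        "rep_phytoplasma": None,
    }
    anc["rep_genomovirus"] = mutate_protein(anc["rep"], 0.45, rng)
    anc["rep_phytoplasma"] = mutate_protein(anc["rep"], 0.55, rng)
    return anc


def make_reference_library(seed: int = 0, n_per_label: int = 3) -> dict[str, tuple[str, str]]:
    """A labeled Rep reference library: geminivirus plus two outgroups."""
    anc = ancestral_proteins()
    rng = np.random.default_rng([seed, 11])
    lib: dict[str, tuple[str, str]] = {}
    for label, ancestor in (
        ("geminivirus", anc["rep"]),
        ("genomovirus", anc["rep_genomovirus"]),
        ("phytoplasma_plasmid", anc["rep_phytoplasma"]),
    ):
        for i in range(n_per_label):
            lib[f"{label}_{i}"] = (label, mutate_protein(ancestor, 0.12, rng))
    return lib


# -- host genome -------------------------------------------------------------


def generate_host_genome(
    n_contigs: int,
    lengths: Sequence[int],
    gc: float,
    repeat_density: float = 0.0,
    seed: int = 0,
    n_repeat_families: int = 3,
) -> tuple[dict[str, str], list[Feature]]:
    """I.i.d. background at the stated GC plus planted repeat-family copies.

    Repeat copies are drawn from ``n_repeat_families`` consensus sequences,
    mutated to 80-95% within-family identity, and written over the
    background at non-overlapping positions until ``repeat_density`` of the
    total length is covered.  Returns (contigs, repeat features).
    """
    if n_contigs != len(lengths):
        raise ValueError("n_contigs must match len(lengths)")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    if not 0 <= repeat_density < 1:
        raise ValueError("repeat_density must lie in [0, 1)")
    rng = np.random.default_rng([seed, 1])
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for i, L in enumerate(lengths):
        arrays[f"contig{i + 1}"] = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L, p=p)
    repeat_bed: list[Feature] = []
    if repeat_density > 0:
        fams = []
        for f in range(n_repeat_families):
            fam_len = int(rng.integers(400, 801))
            fams.append("".join(rng.choice(list("ACGT"), size=fam_len, p=p)))
        total = sum(lengths)
        target = repeat_density * total
        covered = 0.0
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in arrays}
        cid_list = sorted(arrays)
        j = 0
        attempts = 0
        while covered < target and attempts < 10000:
            attempts += 1
            fam_idx = j % n_repeat_families
            cons = fams[fam_idx]
            cid = cid_list[int(rng.integers(len(cid_list)))]
            L = len(arrays[cid])
            if L <= len(cons):
                continue
            start = int(rng.integers(0, L - len(cons)))
            end = start + len(cons)
            if any(start < b and a < end for a, b in occupied[cid]):
                continue
            copy = mutate_nt(cons, float(rng.uniform(0.05, 0.20)), rng)
            arrays[cid][start:end] = np.frombuffer(copy.encode(), dtype="S1")
            occupied[cid].append((start, end))
            repeat_bed.append(Feature(f"repeat_fam{fam_idx + 1}_{len(repeat_bed)}", cid, start, end, "repeat"))
            covered += len(cons)
            j += 1
    for cid, arr in arrays.items():
        contigs[cid] = arr.tobytes().decode("ascii")
    repeat_bed.sort(key=lambda f: (f.contig, f.start))
    return contigs, repeat_bed


def mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = "ACGT".replace(out[i], "")
            out[i] = choices[rng.integers(3)]
    return "".join(out)


# -- viral genome ------------------------------------------------------------


def encode_protein(protein: str, rng: np.random.Generator, add_stop: bool = True) -> str:
    codons = [ _SYN_CODONS[a][rng.integers(len(_SYN_CODONS[a]))] for a in protein ]
    if add_stop:
        codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def _motif_count_circular(seq: str, motif: str = NONANUCLEOTIDE) -> int:
    doubled = seq + seq[: len(motif) - 1]
    n = 0
    p = doubled.find(motif)
    while p != -1:
        n += 1
        p = doubled.find(motif, p + 1)
    return n


def generate_viral_genome(
    length: int = 3500,
    seed: int = 0,
    rep_protein: str | None = None,
    cp_protein: str | None = None,
    mp_protein: str | None = None,
) -> tuple[str, ViralGenomeTruth]:
    """A circular geminivirus-like genome with the origin at position 0.

    Layout: TAATATTAC origin, then CP-, MP- and Rep-encoding ORFs separated
    by stop-terminated spacers (an in-frame TAA immediately precedes each
    ATG so ORF calling recovers the designed starts).  The genome contains
    exactly one forward-strand copy of the nonanucleotide, at position 0.
    Proteins default to mild variants of the ancestral families, so the
    encoded Rep is recognizably geminiviral.
    """
    anc = ancestral_proteins()
    base_rng = np.random.default_rng([seed, 2])
    rep = rep_protein or mutate_protein(anc["rep"], 0.08, base_rng)
    cp = cp_protein or mutate_protein(anc["cp"], 0.08, base_rng)
    mp = mp_protein or mutate_protein(anc["mp"], 0.08, base_rng)
    if len(rep) < 264:
        raise ValueError("Rep protein must be at least 264 aa")
    cds_budget = 3 * (len(rep) + len(cp) + len(mp) + 3)  # incl. stop codons
    min_needed = 9 + cds_budget + 4 * (6 + 3)
    if length < max(2500, min_needed):
        raise ValueError(f"length {length} below minimum ORF budget {max(2500, min_needed)}")

    for attempt in range(100):
        rng = np.random.default_rng([seed, 2, attempt])
        spare = length - 9 - cds_budget - 3 * 3  # three 'TAA' markers before the ORFs
        cuts = np.sort(rng.integers(0, spare + 1, size=3))
        spacer_lens = [int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1]), int(spare - cuts[2])]

        def spacer(n: int) -> str:
            return "".join(rng.choice(list("ACGT"), size=n))

        parts: list[str] = [NONANUCLEOTIDE]
        cds_spans: dict[str, tuple[int, int]] = {}
        proteins = {"cp": cp, "mp": mp, "rep": rep}
        for gene, slen in zip(("cp", "mp", "rep"), spacer_lens[:3]):
            parts.append(spacer(slen))
            parts.append("TAA")
            start = sum(len(x) for x in parts)
            cds = encode_protein(proteins[gene], rng)
            parts.append(cds)
            cds_spans[gene] = (start, start + len(cds))
        parts.append(spacer(spacer_lens[3]))
        seq = "".join(parts)
        assert len(seq) == length
        if _motif_count_circular(seq) == 1 and _motif_count_circular(revcomp(seq)) == 0:
            rep_start = cds_spans["rep"][0]
            truth = ViralGenomeTruth(
                proteins={"rep": rep, "cp": cp, "mp": mp},
                cds=cds_spans,
                al1_span=(rep_start, rep_start + 3 * 120),
            )
            return seq, truth
    raise RuntimeError("could not place a unique origin nonanucleotide")


# -- implantation ------------------------------------------------------------


def degrade_fragment(fragment: str, model: DegradationModel, rng: np.random.Generator) -> tuple[str, DegradationRecord]:
    frag = fragment
    trunc = float(rng.uniform(0, model.truncation_max)) if model.truncation_max > 0 else 0.0
    left = 0
    if trunc > 0:
        cut = int(trunc * len(frag))
        left = int(rng.integers(0, cut + 1))
        frag = frag[left : len(frag) - (cut - left)]
    if model.sub_rate > 0:
        frag = mutate_nt(frag, model.sub_rate, rng)
    n_indels = int(rng.poisson(model.indel_mean)) if model.indel_mean > 0 else 0
    for _ in range(n_indels):
        if len(frag) < 2:
            break
        pos = int(rng.integers(len(frag)))
        if rng.random() < 0.5:
            frag = frag[:pos] + frag[pos + 1 :]
        else:
            frag = frag[:pos] + "ACGT"[rng.integers(4)] + frag[pos:]
    for _ in range(model.n_stops):
        if len(frag) < 6:
            break
        codon_pos = 3 * int(rng.integers(len(frag) // 3 - 1))
        frag = frag[:codon_pos] + "TAA" + frag[codon_pos + 3 :]
    return frag, DegradationRecord(model.sub_rate, n_indels, model.n_stops, trunc, left)


def implant_fragments(
    genome: Mapping[str, str],
    viral: str,
    n: int,
    degradation: DegradationModel | None = None,
    hotspot_fraction: float = 0.0,
    seed: int = 0,
    frag_len_range: tuple[int, int] | None = None,
    arcs: Sequence[tuple[int, int]] | None = None,
    source_id: str = "virus1",
    hotspot_window: int = 100_000,
) -> tuple[dict[str, str], list[ImplantTruth]]:
    """Insert ``n`` degraded arcs of a circular viral genome into a host.

    Arcs default to random (start, length) slices of the circle — pass
    ``arcs`` to control them — on a random strand each.  A fraction of the
    fragments is co-located within a single ``hotspot_window`` of one
    contig.  Insertions are applied left-to-right with cumulative offset
    bookkeeping, so the returned truth coordinates are exact in the final
    mutated genome.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0 <= hotspot_fraction <= 1:
        raise ValueError("hotspot_fraction must lie in [0, 1]")
    if degradation is None:
        degradation = DegradationModel()
    rng = np.random.default_rng([seed, 3])
    contigs = dict(genome)
    if n == 0:
        return contigs, []
    L = len(viral)
    lo, hi = frag_len_range or (min(500, L), L)
    hi = min(hi, L)

    fragments: list[tuple[str, tuple[int, int], str, DegradationRecord]] = []
    for i in range(n):
        if arcs is not None:
            a_start, a_len = arcs[i]
        else:
            a_len = int(rng.integers(lo, hi + 1))
            a_start = int(rng.integers(0, L))
        arc = (viral + viral)[a_start : a_start + a_len]
        frag, record = degrade_fragment(arc, degradation, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        # span end may exceed the circle length: the arc wraps the origin
        fragments.append((frag, (a_start, a_start + a_len), strand, record))

    cids = sorted(contigs)
    weights = np.array([len(contigs[c]) for c in cids], dtype=float)
    if max(len(f[0]) for f in fragments) > int(weights.max()):
        raise ValueError("fragment longer than the largest target contig")
    weights /= weights.sum()

    n_hot = int(round(hotspot_fraction * n))
    hot_idx = set(rng.choice(n, size=n_hot, replace=False).tolist()) if n_hot else set()
    hot_cid = None
    hot_lo = 0
    if n_hot:
        eligible = [c for c in cids if len(contigs[c]) >= hotspot_window] or [max(cids, key=lambda c: len(contigs[c]))]
        hot_cid = eligible[int(rng.integers(len(eligible)))]
        span = max(1, len(contigs[hot_cid]) - hotspot_window)
        hot_lo = int(rng.integers(0, span))

    placements: list[tuple[str, int, int]] = []  # (contig, insertion point, fragment index)
    used: dict[str, set[int]] = {c: set() for c in cids}
    for i in range(n):
        frag_len = len(fragments[i][0])
        for _ in range(1000):
            if i in hot_idx:
                cid = hot_cid
                width = min(hotspot_window, len(contigs[cid]))
                point = hot_lo + int(rng.integers(0, max(1, width - frag_len)))
            else:
                cid = cids[int(rng.choice(len(cids), p=weights))]
                if len(contigs[cid]) <= frag_len:
                    continue
                point = int(rng.integers(0, len(contigs[cid])))
            if point not in used[cid]:
                used[cid].add(point)
                placements.append((cid, point, i))
                break
        else:
            raise RuntimeError("could not place fragment without collision")

    placements.sort(key=lambda t: (t[0], t[1]))
    truth: list[ImplantTruth] = []
    offset: dict[str, int] = {c: 0 for c in cids}
    for cid, point, i in placements:
        frag, span, strand, record = fragments[i]
        ins = frag if strand == "+" else revcomp(frag)
        pos = point + offset[cid]
        contigs[cid] = contigs[cid][:pos] + ins + contigs[cid][pos:]
        truth.append(
            ImplantTruth(
                contig=cid,
                start=pos,
                end=pos + len(ins),
                strand=strand,
                source_id=source_id,
                source_span=span,
                fragment=frag,
                degradation=record,
                in_hotspot=i in hot_idx,
            )
        )
        offset[cid] += len(ins)
    truth.sort(key=lambda t: (t.contig, t.start))
    return contigs, truth


# -- co-transcripts ----------------------------------------------------------


def _evolve_cds(cds: str, omega: float, depth: float, rng: np.random.Generator) -> str:
    """Codon evolution by attempt/accept: synonymous changes always accepted,
    nonsynonymous accepted with probability omega, stops rejected."""
    seq = list(cds)
    n_attempts = int(rng.poisson(depth * len(cds)))
    for _ in range(n_attempts):
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        alt = "ACGT".replace(old, "")[rng.integers(3)]
        ci = 3 * (pos // 3)
        codon = "".join(seq[ci : ci + 3])
        new_codon = codon[: pos - ci] + alt + codon[pos - ci + 1 :]
        if translate_cds(codon) == "*" or translate_cds(new_codon) == "*":
            continue
        if translate_cds(new_codon) != translate_cds(codon) and rng.random() >= omega:
            continue
        seq[pos] = alt
    return "".join(seq)


def generate_cotranscripts(
    n_species: int,
    rep_protein: str | None = None,
    hsp70_protein: str | None = None,
    omega: float = 0.2,
    tree_depth: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, dict[str, tuple[int, int]]], dict[str, dict[str, str]]]:
    """Rep-HSP70 co-transcripts for ``n_species`` related species.

    Each transcript carries an HSP70-like CDS followed by a Rep CDS on the
    same strand (UTRs and the spacer are identical across species); the
    coding regions evolve independently from the ancestor along a star tree
    with ``tree_depth`` expected mutation attempts per site and the stated
    dN/dS.  A single species is returned as the undiverged ancestor.
    Returns (transcripts, CDS coordinates per transcript, CDS sequences per
    gene per species).
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if n_species < 1:
        raise ValueError("need at least one species")
    anc = ancestral_proteins()
    rng = np.random.default_rng([seed, 4])
    rep = rep_protein or anc["rep"]
    hsp = hsp70_protein or anc["hsp70"]
    hsp_cds = encode_protein(hsp, rng, add_stop=True)
    rep_cds = encode_protein(rep, rng, add_stop=True)
    utr5 = "".join(rng.choice(list("ACGT"), size=60))
    spacer = "".join(rng.choice(list("ACGT"), size=30))
    utr3 = "".join(rng.choice(list("ACGT"), size=60))

    transcripts: dict[str, str] = {}
    coords: dict[str, dict[str, tuple[int, int]]] = {}
    cds_by_gene: dict[str, dict[str, str]] = {"hsp70": {}, "rep": {}}
    for s in range(n_species):
        name = f"species{s + 1}"
        if n_species == 1:
            h, r = hsp_cds, rep_cds
        else:
            h = _evolve_cds(hsp_cds, omega, tree_depth, rng)
            r = _evolve_cds(rep_cds, omega, tree_depth, rng)
        tr = utr5 + h + spacer + r + utr3
        transcripts[name] = tr
        coords[name] = {
            "hsp70": (len(utr5), len(utr5) + len(h)),
            "rep": (len(utr5) + len(h) + len(spacer), len(utr5) + len(h) + len(spacer) + len(r)),
        }
        cds_by_gene["hsp70"][name] = h
        cds_by_gene["rep"][name] = r
    return transcripts, coords, cds_by_gene


# -- methylation -------------------------------------------------------------

DEFAULT_METH_MEANS: dict[str, dict[str, float]] = {
    "EGV": {"CG": 0.8, "CHG": 0.7, "CHH": 0.5},
    "repeat": {"CG": 0.75, "CHG": 0.65, "CHH": 0.45},
    "gene": {"CG": 0.2, "CHG": 0.1, "CHH": 0.05},
}


def generate_methylation_track(
    genome: Mapping[str, str],
    features: Sequence[Feature],
    mean_levels: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[MethylationSite]:
    """Per-context methylation levels at every forward-strand cytosine inside
    a feature, drawn around the feature-category x context mean and clipped
    to [0, 1]."""
    if mean_levels is None:
        mean_levels = DEFAULT_METH_MEANS
    rng = np.random.default_rng([seed, 5])
    sites: list[MethylationSite] = []
    for f in sorted(features, key=lambda x: (x.contig, x.start, x.feature_id)):
        if f.category not in mean_levels:
            raise ValueError(f"unknown feature category {f.category!r}")
        seq = genome[f.contig]
        for i in range(f.start, min(f.end, len(seq) - 2)):
            if seq[i] != "C":
                continue
            if seq[i + 1] == "G":
                ctx = "CG"
            elif seq[i + 2] == "G":
                ctx = "CHG"
            else:
                ctx = "CHH"
            mean = mean_levels[f.category][ctx]
            level = mean if noise_sd == 0 else float(np.clip(rng.normal(mean, noise_sd), 0.0, 1.0))
            sites.append(MethylationSite(f.contig, i, ctx, level))
    return sites


# -- domain profiles ---------------------------------------------------------


def build_domain_profiles(seed: int = 0, n_seed_seqs: int = 8, divergence: float = 0.10) -> list[DomainProfile]:
    """PSSM profiles for the viral and host domain families.

    Each profile is built from a small synthetic seed alignment: the
    ancestral region plus ``n_seed_seqs - 1`` copies mutated to
    ``divergence``.  Categories mark Rep/CP/MP as geminiviral and
    HSP70/NAD-GH plus three controls as host.
    """
    anc = ancestral_proteins()
    rng = np.random.default_rng([seed, 6])
    spec = [
        ("Rep_AL1", "geminiviral", anc["rep"][:120]),
        ("CP_like", "geminiviral", anc["cp"][:100]),
        ("MP_like", "geminiviral", anc["mp"][:80]),
        ("HSP70_like", "host", anc["hsp70"][:120]),
        ("NADGH_like", "host", anc["nadgh"][:100]),
        ("HostDom1", "host", anc["host1"][:100]),
        ("HostDom2", "host", anc["host2"][:100]),
        ("HostDom3", "host", anc["host3"][:100]),
    ]
    profiles = []
    for pid, cat, region in spec:
        seeds = [region] + [mutate_protein(region, divergence, rng) for _ in range(n_seed_seqs - 1)]
        profiles.append(build_profile(pid, cat, seeds))
    return profiles


# -- bundle ------------------------------------------------------------------


def make_bundle(
    seed: int = 0,
    n_contigs: int = 2,
    contig_length: int = 500_000,
    gc: float = 0.38,
    repeat_density: float = 0.05,
    n_implants: int = 30,
    degradation: DegradationModel | None = None,
    hotspot_fraction: float = 0.4,
    viral_length: int = 3500,
    n_species: int = 6,
    omega: float = 0.2,
    tree_depth: float = 0.1,
    n_genes: int = 40,
    meth_noise_sd: float = 0.1,
    arc_mode: str = "random",
) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic study input.

    ``arc_mode`` controls which slice of the viral circle each implant
    carries: "random" draws arbitrary arcs (the realistic decay spectrum),
    "rep" draws arcs spanning the whole Rep gene with jittered ends (the
    condition for recall measurement, where every implant is discoverable).
    """
    if degradation is None:
        degradation = DegradationModel(sub_rate=0.05, indel_mean=1.0, n_stops=0, truncation_max=0.3)
    genome, repeat_bed = generate_host_genome(
        n_contigs, [contig_length] * n_contigs, gc, repeat_density, seed=seed
    )
    viral, viral_truth = generate_viral_genome(viral_length, seed=seed)
    arcs = None
    if arc_mode == "rep":
        arc_rng = np.random.default_rng([seed, 8])
        rs, re = viral_truth.cds["rep"]
        arcs = [
            (
                (rs - int(arc_rng.integers(0, 150))) % len(viral),
                (re - rs) + int(arc_rng.integers(50, 300)),
            )
            for _ in range(n_implants)
        ]
    elif arc_mode != "random":
        raise ValueError(f"unknown arc_mode {arc_mode!r}")
    genome, truth = implant_fragments(
        genome, viral, n_implants, degradation, hotspot_fraction, seed=seed, arcs=arcs
    )
    refs = make_reference_library(seed=seed)
    transcripts, transcript_cds, _ = generate_cotranscripts(
        n_species, omega=omega, tree_depth=tree_depth, seed=seed
    )

    # features: EGV intervals from truth, repeats shifted to post-insertion
    # coordinates, plus invented gene intervals in implant-free background
    rng = np.random.default_rng([seed, 7])
    features: list[Feature] = []
    for i, t in enumerate(truth):
        features.append(Feature(f"EGV_{i}", t.contig, t.start, t.end, "EGV"))
    shifts: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        shifts.setdefault(t.contig, []).append((t.start - _pre_insertion_offset(truth, t), t.end - t.start))
    for f in repeat_bed:
        d_start = sum(l for s, l in shifts.get(f.contig, []) if s <= f.start)
        d_end = sum(l for s, l in shifts.get(f.contig, []) if s < f.end)
        features.append(Feature(f.feature_id, f.contig, f.start + d_start, f.end + d_end, "repeat"))
    occupied = {c: [(t.start, t.end) for t in truth if t.contig == c] for c in genome}
    placed = 0
    attempts = 0
    while placed < n_genes and attempts < 10000:
        attempts += 1
        cid = sorted(genome)[int(rng.integers(len(genome)))]
        L = len(genome[cid])
        glen = int(rng.integers(1000, 3001))
        if L <= glen:
            continue
        start = int(rng.integers(0, L - glen))
        if any(start < b and a < start + glen for a, b in occupied[cid]):
            continue
        occupied[cid].append((start, start + glen))
        features.append(Feature(f"gene_{placed}", cid, start, start + glen, "gene"))
        placed += 1
    features.sort(key=lambda f: (f.contig, f.start, f.feature_id))

    methylation = generate_methylation_track(genome, features, noise_sd=meth_noise_sd, seed=seed)
    profiles = build_domain_profiles(seed=seed)
    return SyntheticBundle(
        genome=genome,
        truth=truth,
        viral_genome=viral,
        viral_truth=viral_truth,
        viral_refs=refs,
        transcripts=transcripts,
        transcript_cds=transcript_cds,
        methylation=methylation,
        features=features,
        profiles=profiles,
        seed=seed,
    )


def _pre_insertion_offset(truth: Sequence[ImplantTruth], t: ImplantTruth) -> int:
    """Total inserted length on t's contig strictly before t's own insertion."""
    return sum(x.end - x.start for x in truth if x.contig == t.contig and x.start < t.start)


def detectable_rep_interval(
    t: ImplantTruth,
    viral_truth: ViralGenomeTruth,
    circle_length: int,
) -> tuple[int, int] | None:
    """Genome interval of the Rep-gene portion carried by an implant.

    An implant is only discoverable by a Rep protein search where its arc
    overlaps the Rep CDS, so recall bookkeeping scores recovery against this
    sub-interval rather than the whole insert.  End truncation is accounted
    for exactly; the few nt of drift that 1-nt indels introduce are ignored.
    Returns None when the implant retains no Rep sequence.
    """
    a0, a1 = t.source_span
    rs, re = viral_truth.cds["rep"]
    best = None
    for shift in (0, circle_length):
        lo = max(a0, rs + shift)
        hi = min(a1, re + shift)
        if hi - lo > (best[1] - best[0] if best else 0):
            best = (lo - a0, hi - a0)  # arc-relative
    if best is None:
        return None
    frag_len = len(t.fragment)
    lo = min(max(0, best[0] - t.degradation.left_trim), frag_len)
    hi = min(max(0, best[1] - t.degradation.left_trim), frag_len)
    if hi <= lo:
        return None
    if t.strand == "+":
        return (t.start + lo, t.start + hi)
    return (t.end - hi, t.end - lo)
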