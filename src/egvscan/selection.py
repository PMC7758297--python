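"""Codon alignments and per-site selection tests on co-transcript genes.

A Rep gene captured inside a host transcript and maintained across related
species leaves a molecular-evolution signature: purifying selection shows up
as a deficit of nonsynonymous change.  This module converts a protein
alignment plus the underlying CDS into a codon alignment, then applies a
deterministic counting test (SLAC-style): per site, synonymous and
nonsynonymous differences and opportunities are tallied over all sequence
pairs (or over tree edges with parsimony ancestral states when a tree is
supplied), and the observed nonsynonymous proportion is compared with the
neutral expectation by a two-sided binomial test.  This is a counting
substitute for Bayesian site-model machinery: it asks the same question
(is site dN/dS below or above 1?) without MCMC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from scipy import stats

GAP_CODON = "---"
STOPS = {"TAA", "TAG", "TGA"}

_CODON_AA: dict[str, str] = {}
_T = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M", "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*", "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_CODON_AA.update(_T)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (length divisible by 3, ACGT only)."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon not in _CODON_AA:
            raise ValueError(f"unrecognized codon {codon!r} at position {i}")
        aas.append(_CODON_AA[codon])
    return "".join(aas)


@dataclass
class CodonAlignment:
    rows: dict[str, str]  # id -> gapped codon string, gap = '---'
    n_sites: int

    def site(self, i: int) -> dict[str, str]:
        return {rid: row[3 * i : 3 * i + 3] for rid, row in self.rows.items()}


@dataclass
class SiteSelection:
    site: int
    dN: float
    dS: float
    statistic: float  # observed nonsynonymous differences
    p_value: float
    classification: str  # 'purifying' | 'neutral' | 'positive'


def build_codon_alignment(protein_alignment: Mapping[str, str], cds: Mapping[str, str]) -> CodonAlignment:
    """Thread each CDS onto its gapped protein row (PAL2NAL-style).

    For every id the translated CDS must equal the ungapped protein row
    (one trailing stop codon is tolerated and trimmed); a mismatch is
    rejected with the offending id and amino-acid position.
    """
    lengths = {len(r) for r in protein_alignment.values()}
    if len(lengths) > 1:
        raise ValueError("protein alignment rows have unequal length")
    rows: dict[str, str] = {}
    for rid, prow in protein_alignment.items():
        if rid not in cds:
            raise ValueError(f"no CDS for {rid!r}")
        nt = cds[rid].upper()
        if len(nt) % 3:
            raise ValueError(f"CDS length of {rid!r} not divisible by 3")
        aa = translate_cds(nt)
        if aa.endswith("*"):
            aa = aa[:-1]
            nt = nt[:-3]
        ungapped = prow.replace("-", "")
        if aa != ungapped:
            pos = next((i for i, (a, b) in enumerate(zip(aa, ungapped)) if a != b), min(len(aa), len(ungapped)))
            raise ValueError(f"translation mismatch for {rid!r} at protein position {pos}")
        codons = [nt[3 * i : 3 * i + 3] for i in range(len(aa))]
        out = []
        j = 0
        for ch in prow:
            if ch == "-":
                out.append(GAP_CODON)
            else:
                out.append(codons[j])
                j += 1
        rows[rid] = "".join(out)
    n_sites = next(iter(lengths)) if lengths else 0
    return CodonAlignment(rows=rows, n_sites=n_sites)


@lru_cache(maxsize=None)
def codon_opportunities(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a codon.

    Per position, each of the three alternative bases is classified as
    synonymous or nonsynonymous; changes creating a stop are excluded from
    both counts (they are not an available path under selection).
    """
    aa = _CODON_AA[codon]
    syn = nonsyn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _CODON_AA[alt] == "*":
                continue
            if _CODON_AA[alt] == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all shortest mutational paths, equally weighted; paths
    passing through a stop codon are discarded (all-stop path sets fall
    back to counting through stops).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _CODON_AA[nxt] == "*":
                through_stop = True
            if _CODON_AA[nxt] == _CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    valid = [(s, n) for t, s, n in paths if not t] or [(s, n) for _t, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _is_codon(c: str) -> bool:
    return c in _CODON_AA and _CODON_AA[c] != "*"


def _fitch_states(tree, site_codons: Mapping[str, str]):
    """One deterministic minimal Fitch assignment of codon states; edge pairs."""
    import dendropy

    down: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = site_codons.get(node.taxon.label)
            down[node] = frozenset([c]) if c else None
        else:
            sets = [down[ch] for ch in node.child_nodes() if down[ch] is not None]
            if not sets:
                down[node] = None
            else:
                inter = frozenset.intersection(*sets)
                down[node] = inter if inter else frozenset.union(*sets)
    state: dict = {}
    pairs: list[tuple[str, str]] = []
    for node in tree.preorder_node_iter():
        if down[node] is None:
            continue
        parent = node.parent_node
        if parent is None or parent not in state:
            state[node] = min(down[node])
        else:
            p = state[parent]
            state[node] = p if p in down[node] else min(down[node])
            pairs.append((p, state[node]))
    return pairs


def site_dnds_test(
    alignment: CodonAlignment,
    tree_newick: str | None = None,
    p_threshold: float = 0.1,
) -> tuple[list[SiteSelection], float, list[int]]:
    """Per-site selection classification and global omega.

    Returns (per-site results, global dN/dS, skipped site indices).  Sites
    where fewer than two rows carry an unambiguous, ungapped codon are
    skipped.  Classification: purifying/positive when the two-sided binomial
    p-value is <= ``p_threshold`` and dN/dS is below/above 1.
    """
    if len(alignment.rows) < 3:
        raise ValueError("need at least three sequences")
    lengths = {len(r) for r in alignment.rows.values()}
    if len(lengths) != 1 or next(iter(lengths)) % 3:
        raise ValueError("alignment rows must share a length divisible by 3")
    n_sites = next(iter(lengths)) // 3

    tree = None
    if tree_newick is not None:
        import dendropy

        tree = dendropy.Tree.get(data=tree_newick, schema="newick")

    results: list[SiteSelection] = []
    skipped: list[int] = []
    tot_sd = tot_nd = tot_sopp = tot_nopp = 0.0
    for i in range(n_sites):
        site = {rid: row[3 * i : 3 * i + 3] for rid, row in alignment.rows.items()}
        valid = {rid: c for rid, c in site.items() if _is_codon(c)}
        if len(valid) < 2:
            skipped.append(i)
            continue
        if tree is not None:
            pairs = _fitch_states(tree, valid)
        else:
            ids = sorted(valid)
            pairs = [(valid[a], valid[b]) for a, b in itertools.combinations(ids, 2)]
        sd = nd = sopp = nopp = 0.0
        for c1, c2 in pairs:
            ds, dn = codon_differences(c1, c2)
            sd += ds
            nd += dn
            s1, n1 = codon_opportunities(c1)
            s2, n2 = codon_opportunities(c2)
            sopp += (s1 + s2) / 2
            nopp += (n1 + n2) / 2
        dN = nd / nopp if nopp else 0.0
        dS = sd / sopp if sopp else 0.0
        # all-pairs counting pseudo-replicates each variant roughly n/2
        # times; scale the test counts down to (n-1) effective comparisons
        # so the binomial p-value is not wildly anticonservative
        eff = (len(valid) - 1) / len(pairs) if (tree is None and pairs) else 1.0
        n_diff = (sd + nd) * eff
        if n_diff >= 1 and (sopp + nopp) > 0:
            p_neutral = nopp / (sopp + nopp)
            p = float(stats.binomtest(round(nd * eff), round(n_diff), p_neutral).pvalue)
        else:
            p = 1.0
        n_diff = sd + nd
        if p <= p_threshold and n_diff >= 1 and dN < dS:
            cls = "purifying"
        elif p <= p_threshold and n_diff >= 1 and dN > dS:
            cls = "positive"
        else:
            cls = "neutral"
        results.append(SiteSelection(i, dN, dS, nd, p, cls))
        tot_sd += sd
        tot_nd += nd
        tot_sopp += sopp
        tot_nopp += nopp
    if tot_sd > 0 and tot_nopp > 0:
        omega = (tot_nd / tot_nopp) / (tot_sd / tot_sopp)
    elif tot_nd > 0:
        omega = float("inf")
    else:
        omega = 0.0
    return results, omega, skipped
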