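"""Cytosine methylation of EGVs versus genes and repeats.

Plant genomes methylate cytosines in three sequence contexts (CG, CHG, CHH;
H = A, C or T), and silenced, repeat-like sequence tends to carry higher
levels in all three.  This module computes a length-normalized methylation
value per annotated feature (sum of per-site levels divided by feature
length) and compares the feature categories (EGV, gene, repeat) per context
with two-sided Wilcoxon rank-sum tests — exact enumeration for small
untied groups, tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

CONTEXTS = ("CG", "CHG", "CHH")
CATEGORIES = ("EGV", "gene", "repeat")


@dataclass(frozen=True)
class MethylationSite:
    contig: str
    position: int  # 0-based nt
    context: str  # CG | CHG | CHH
    level: float  # fraction in [0, 1]


@dataclass
class Feature:
    feature_id: str
    contig: str
    start: int
    end: int
    category: str  # EGV | gene | repeat


@dataclass
class FeatureMethylation:
    feature_id: str
    category: str
    context: str
    value: float


@dataclass
class PairTest:
    context: str
    category_a: str
    category_b: str
    statistic: float
    p_value: float
    method: str  # 'exact' | 'asymptotic'


def feature_methylation(
    features: Sequence[Feature],
    sites: Iterable[MethylationSite],
    per_covered_cytosine: bool = False,
) -> list[FeatureMethylation]:
    """Length-normalized methylation per feature and context.

    The default value is sum(site levels in [start,end)) / (end - start);
    with ``per_covered_cytosine`` the denominator is instead the number of
    sites that fell inside the feature (mean level over covered cytosines).
    Features with no sites get 0 in every context.
    """
    by_contig: dict[str, dict[str, list[tuple[int, float]]]] = {}
    for s in sites:
        if s.context not in CONTEXTS:
            raise ValueError(f"unknown context {s.context!r}")
        by_contig.setdefault(s.contig, {c: [] for c in CONTEXTS})[s.context].append((s.position, s.level))
    arrays: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for contig, ctxmap in by_contig.items():
        arrays[contig] = {}
        for ctx, pairs in ctxmap.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            lev = np.array([l for _, l in pairs], dtype=float)
            arrays[contig][ctx] = (pos, np.concatenate([[0.0], np.cumsum(lev)]))

    out: list[FeatureMethylation] = []
    for f in features:
        if f.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {f.category!r}")
        if f.end <= f.start:
            raise ValueError(f"feature {f.feature_id!r} has non-positive length")
        for ctx in CONTEXTS:
            if f.contig in arrays and ctx in arrays[f.contig]:
                pos, csum = arrays[f.contig][ctx]
                lo = int(np.searchsorted(pos, f.start, side="left"))
                hi = int(np.searchsorted(pos, f.end, side="left"))
                total = float(csum[hi] - csum[lo])
                n_sites = hi - lo
            else:
                total, n_sites = 0.0, 0
            denom = n_sites if per_covered_cytosine else (f.end - f.start)
            value = total / denom if denom else 0.0
            out.append(FeatureMethylation(f.feature_id, f.category, ctx, value))
    return out


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 25) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and the data carry no ties; tie-corrected normal approximation otherwise.
    Returns (U statistic, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def compare_methylation(values: Sequence[FeatureMethylation]) -> tuple[list[PairTest], list[str]]:
    """Pairwise category comparisons per methylation context.

    Tests every pair of categories present within each context; pairs where
    a category has fewer than two features are skipped and recorded.
    """
    table: list[PairTest] = []
    skipped: list[str] = []
    for ctx in CONTEXTS:
        groups: dict[str, list[float]] = {}
        for v in values:
            if v.context == ctx:
                groups.setdefault(v.category, []).append(v.value)
        present = sorted(groups)
        if len(present) < 2:
            continue
        for a, b in itertools.combinations(present, 2):
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                skipped.append(f"{ctx}:{a}-vs-{b} (group too small)")
                continue
            stat, p, method = rank_sum_test(groups[a], groups[b])
            table.append(PairTest(ctx, a, b, stat, p, method))
    return table, skipped


def read_sites_tsv(path) -> list[MethylationSite]:
    """Read a 5-column BED-like track: contig, start, end, context, level."""
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"malformed methylation line {ln}: {line!r}")
            contig, start, _end, context, level = parts[:5]
            sites.append(MethylationSite(contig, int(start), context, float(level)))
    return sites
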