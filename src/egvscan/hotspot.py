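"""Genomic hotspot statistics for EGV loci.

Endogenized geminivirus fragments are not uniformly scattered: they pile up
in hotspots, presumably through tandem duplication after integration.  To
quantify this, all contigs are concatenated (in lexicographic id order) into
a single artificial scaffold, locus counts are taken in fixed-size windows
(default 100 kb), and the occupancy of the fullest window is tested against
the uniform-placement null with an exact binomial upper tail, Bonferroni
adjusted across windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class HotspotResult:
    bin_size: int
    n_bins: int
    counts: list[int]
    n_loci: int
    max_count: int
    max_bin: int
    p_raw: float
    p_adj: float


def bin_counts(
    loci: Sequence[tuple[str, int]],
    genome_lengths: Mapping[str, int],
    bin_size: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Count loci per window of the concatenated scaffold.

    ``loci`` are (contig_id, core_start) pairs; a locus belongs to the bin
    containing its start.  Contigs are concatenated in sorted-id order; the
    final partial bin is retained with its true width.  Returns
    (counts, bin_widths, contig_offset_map).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    offsets: dict[str, int] = {}
    total = 0
    for cid in sorted(genome_lengths):
        offsets[cid] = total
        total += genome_lengths[cid]
    if total == 0:
        raise ValueError("zero-length genome")
    n_bins = max(1, -(-total // bin_size))
    widths = np.full(n_bins, bin_size, dtype=np.int64)
    widths[-1] = total - bin_size * (n_bins - 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for cid, start in loci:
        if cid not in offsets:
            raise ValueError(f"locus on unknown contig {cid!r}")
        if not (0 <= start < genome_lengths[cid]):
            raise ValueError(f"locus start {start} outside contig {cid!r}")
        counts[(offsets[cid] + start) // bin_size] += 1
    return counts, widths, offsets


def hotspot_pvalue(counts: Sequence[int], bin_widths: Sequence[int]) -> HotspotResult:
    """Exact binomial upper-tail probability of the fullest bin.

    With n total loci and the fullest bin covering a fraction p of the
    scaffold, p_raw = P(X >= max_count) for X ~ Binomial(n, p), computed as
    an exact tail sum; p_adj = min(1, n_bins * p_raw) (Bonferroni over bins).
    """
    counts = np.asarray(counts, dtype=np.int64)
    widths = np.asarray(bin_widths, dtype=np.int64)
    if counts.shape != widths.shape:
        raise ValueError("counts and bin_widths differ in length")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(widths.sum())
    if total <= 0:
        raise ValueError("zero-length genome")
    n = int(counts.sum())
    max_bin = int(np.argmax(counts))
    max_count = int(counts[max_bin])
    p = widths[max_bin] / total
    p_raw = 1.0 if max_count == 0 else float(stats.binom.sf(max_count - 1, n, p))
    n_bins = len(counts)
    return HotspotResult(
        bin_size=int(widths[0]),
        n_bins=n_bins,
        counts=[int(c) for c in counts],
        n_loci=n,
        max_count=max_count,
        max_bin=max_bin,
        p_raw=p_raw,
        p_adj=min(1.0, n_bins * p_raw),
    )
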