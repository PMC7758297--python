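"""Substitution scoring and Karlin-Altschul E-value calibration.

The translated search, reciprocal classification and clustering stages all
score alignments in the same matrix units, so the scheme (matrix, affine gap
penalties and the Karlin parameters lambda/K used to convert raw scores into
bit scores and expectation values) lives here and is passed around explicitly.

Default parameters are the standard published constants for gapped BLOSUM62
with gap open 11 / extend 1 (lambda = 0.267 nats, K = 0.041).  Stop codons
('*') score -4 against every residue and +1 against themselves, which lets
alignments run through the premature stops that accumulate in degraded
endogenous viral elements, as a translated nucleotide search does.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

LN2 = math.log(2.0)


@functools.lru_cache(maxsize=8)
def load_matrix(name: str):
    """Load a substitution matrix by name (cached; includes '*' and 'X')."""
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Protein substitution scoring scheme with E-value calibration constants.

    Attributes
    ----------
    matrix_name : substitution matrix (NCBI flavour, with '*' row/column).
    gap_open : penalty charged once per gap (positive number).
    gap_extend : penalty per gap position, including the first (positive).
        A gap of length k costs ``gap_open + k * gap_extend``, the BLAST
        convention.
    lam : Karlin-Altschul lambda in nats per matrix unit.
    K : Karlin-Altschul prefactor.
    word_size : seed word length (amino acids) for the translated search.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041
    word_size: int = 3

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin parameters lambda and K must be positive")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")

    @property
    def matrix(self):
        return load_matrix(self.matrix_name)

    def make_aligner(self, mode: str = "local", free_end_gaps: bool = False) -> Align.PairwiseAligner:
        """Configure a PairwiseAligner under this scheme.

        ``free_end_gaps`` only makes sense for global mode and gives the
        end-gap-free ("glocal") alignment used for percent identity.
        """
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = mode
        if free_end_gaps:
            aligner.end_gap_score = 0.0
        return aligner


def compute_evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> tuple[float, float]:
    """Convert a raw alignment score into (bitscore, E-value).

    bitscore = (lambda * S - ln K) / ln 2 and E = m * n * 2**(-bitscore),
    where m is the query length (aa) and n the number of searched letters.
    The search space is the raw product m*n; no edge-effect length
    correction is applied, so thresholds are directly interpretable.
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions m and n must be positive")
    bitscore = (scheme.lam * raw_score - math.log(scheme.K)) / LN2
    evalue = m * n * math.pow(2.0, -bitscore)
    return bitscore, evalue
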