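"""Sequence-logo conservation profiling and length-vs-property correlation.

Conservation of aligned α-linker regions is summarized per column as residue
frequencies over the 20 standard amino acids (gaps excluded from the
denominator) and as information content in bits,

    IC = log₂ 20 − H(column),

the stack height a sequence-logo renderer such as WebLogo would draw.
Linker-length relationships (interface area, catalytic efficiency) are
quantified by ordinary least squares with Pearson and Spearman coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .linker import scan_motifs

__all__ = [
    "Alignment",
    "ConservationProfile",
    "CorrelationResult",
    "conservation_profile",
    "motif_prevalence",
    "correlate",
    "AMINO_ACIDS",
    "MAX_BITS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
MAX_BITS = float(np.log2(20.0))  # 4.3219...


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]  # equal-length aligned sequences, '-' for gaps

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs ≥2 rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("aligned rows must all have the same length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def degapped(self) -> list[str]:
        return [r.replace("-", "") for r in self.rows]


@dataclass(frozen=True)
class ConservationProfile:
    freqs: np.ndarray         # (n_columns, 20)
    info_content: np.ndarray  # bits per column
    all_gap: np.ndarray       # bool per column


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    n: int


def conservation_profile(aln: Alignment) -> ConservationProfile:
    """Per-column residue frequencies and information content (bits).

    Gaps are excluded from the frequency denominator; an all-gap column is
    flagged and given zero information content.
    """
    width, nseq = aln.width, aln.n_seqs
    counts = np.zeros((width, 20))
    for row in aln.rows:
        for j, ch in enumerate(row):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1
    totals = counts.sum(axis=1)
    all_gap = totals == 0
    freqs = np.zeros_like(counts)
    nz = ~all_gap
    freqs[nz] = counts[nz] / totals[nz, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.where(all_gap, 0.0, MAX_BITS - entropy)
    return ConservationProfile(freqs=freqs, info_content=info, all_gap=all_gap)


def motif_prevalence(aln: Alignment, pattern_id: str) -> tuple[float, list[list[int]]]:
    """Fraction of sequences (de-gapped) containing ≥1 hit of the pattern,
    with the 1-based hit positions per sequence."""
    if aln.n_seqs == 0:
        raise ValueError("empty alignment")
    positions: list[list[int]] = []
    n_with = 0
    for seq in aln.degapped():
        hits = [h.position for h in scan_motifs(seq) if h.pattern_id == pattern_id]
        positions.append(hits)
        if hits:
            n_with += 1
    return n_with / aln.n_seqs, positions


def correlate(x, y) -> CorrelationResult:
    """OLS slope/intercept plus Pearson r and Spearman rho for paired data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need n ≥ 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0:
        raise ValueError("zero variance in y")
    ols = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return CorrelationResult(
        slope=float(ols.slope), intercept=float(ols.intercept),
        pearson_r=float(ols.rvalue), pearson_p=float(ols.pvalue),
        spearman_rho=float(rho), n=len(x),
    )
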