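"""Two-locus LD with D' confidence intervals and haplotype-block detection.

Inbred mode throughout: each SSD-homogenized line contributes one haplotype,
read off its homozygous calls; lines heterozygous or missing at either
marker of a pair are excluded for that pair, so no phasing/EM is needed.

Block detection follows the confidence-interval rule of Gabriel-style
algorithms: a marker pair is "strong LD" when the 90% bounds of its D'
likelihood are high (lower bound >= 0.70, upper >= 0.98) and shows
"recombination" when the upper bound is < 0.90; an interval of markers is a
block when its endpoint pair is strong and at least 95% of its informative
pairs (strong + recombination) are strong. Candidate intervals are accepted
greedily by decreasing marker span, leftmost first, skipping overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import HOM_A, HOM_B, ChromosomeTable, GenotypeMatrix


class PairClass(Enum):
    STRONG_LD = "strong_LD"
    RECOMBINATION = "recombination"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class TwoLocusCounts:
    """Haplotype counts from doubly-homozygous lines. 'A'/'a' denote
    allele_a/allele_b at the first marker, 'B'/'b' at the second."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    @property
    def n_total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_AB, self.n_Ab, self.n_aB, self.n_ab], dtype=float)


@dataclass
class LDPairStats:
    D_LD: float
    Dmax: float
    Dprime: float
    ci_low: float
    ci_high: float
    pair_class: PairClass


def two_locus_counts(gm: GenotypeMatrix, subset, m1: str, m2: str) -> TwoLocusCounts:
    """Haplotype counts for a marker pair on the same chromosome."""
    if m1 == m2:
        raise ValueError("m1 and m2 must differ")
    j1, j2 = gm.markers.index.get_loc(m1), gm.markers.index.get_loc(m2)
    if gm.markers.iloc[j1]["chrom"] != gm.markers.iloc[j2]["chrom"]:
        raise ValueError(f"{m1} and {m2} are on different chromosomes")
    idx = gm.accession_indices(subset)
    c1, c2 = gm.calls[idx, j1], gm.calls[idx, j2]
    return _counts_from_calls(c1, c2)


def _counts_from_calls(c1: np.ndarray, c2: np.ndarray) -> TwoLocusCounts:
    hom = lambda c: (c == HOM_A) | (c == HOM_B)
    use = hom(c1) & hom(c2)
    a1, a2 = c1[use] == HOM_A, c2[use] == HOM_A
    return TwoLocusCounts(
        n_AB=int((a1 & a2).sum()),
        n_Ab=int((a1 & ~a2).sum()),
        n_aB=int((~a1 & a2).sum()),
        n_ab=int((~a1 & ~a2).sum()),
    )


def ld_point(counts: TwoLocusCounts) -> Optional[tuple[float, float, float]]:
    """(D, Dmax, D') from haplotype counts; None for a monomorphic margin."""
    n = counts.n_total
    if n < 1:
        return None
    p = (counts.n_AB + counts.n_Ab) / n  # freq of allele_a at m1
    r = (counts.n_AB + counts.n_aB) / n  # freq of allele_a at m2
    if p in (0.0, 1.0) or r in (0.0, 1.0):
        return None
    D = counts.n_AB / n - p * r
    if D > 0:
        Dmax = min(p * (1 - r), (1 - p) * r)
    else:
        Dmax = min(p * r, (1 - p) * (1 - r))
    Dprime = abs(D) / Dmax if Dmax > 0 else 0.0
    return D, Dmax, Dprime


def dprime_ci(counts: TwoLocusCounts, grid_step: float = 0.001) -> Optional[tuple[float, float]]:
    """Likelihood-based confidence bounds for |D'| on a grid.

    The multinomial likelihood of the four haplotype counts is evaluated on
    the D' grid {0, grid_step, ..., 1} with allele margins fixed at their
    observed values and the haplotype probabilities reconstructed from
    (D', margins, sign of the point estimate D). After normalizing the
    likelihood to unit mass, ci_low is the smallest grid value whose
    cumulative mass reaches 5% and ci_high the smallest reaching 95%.
    Returns None for an uninformative (monomorphic-margin) pair.
    """
    point = ld_point(counts)
    if point is None:
        return None
    D, Dmax, _ = point
    n = counts.n_total
    p = (counts.n_AB + counts.n_Ab) / n
    r = (counts.n_AB + counts.n_aB) / n
    sign = 1.0 if D >= 0 else -1.0

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d = sign * grid * Dmax
    probs = np.stack(
        [p * r + d, p * (1 - r) - d, (1 - p) * r - d, (1 - p) * (1 - r) + d]
    )  # 4 x grid
    probs = np.clip(probs, 1e-12, None)
    loglik = counts.counts @ np.log(probs)
    loglik -= loglik.max()
    mass = np.exp(loglik)
    cum = np.cumsum(mass) / mass.sum()
    ci_low = float(grid[np.searchsorted(cum, 0.05)])
    ci_high = float(grid[np.searchsorted(cum, 0.95)])
    return ci_low, ci_high


def classify_pair(ci: Optional[tuple[float, float]], strong_low: float = 0.70,
                  strong_high: float = 0.98, recomb_high: float = 0.90) -> PairClass:
    """Gabriel CI rule: strong LD needs a high lower and upper bound;
    recombination a low upper bound; anything else is uninformative."""
    if ci is None:
        return PairClass.UNINFORMATIVE
    ci_low, ci_high = ci
    if ci_low >= strong_low and ci_high >= strong_high:
        return PairClass.STRONG_LD
    if ci_high < recomb_high:
        return PairClass.RECOMBINATION
    return PairClass.UNINFORMATIVE


def pair_stats(counts: TwoLocusCounts, grid_step: float = 0.001, **thresholds) -> LDPairStats:
    """Point estimate, CI and class for one pair (NaNs when uninformative)."""
    point = ld_point(counts)
    if point is None:
        return LDPairStats(np.nan, np.nan, np.nan, np.nan, np.nan, PairClass.UNINFORMATIVE)
    D, Dmax, Dprime = point
    ci = dprime_ci(counts, grid_step)
    return LDPairStats(D, Dmax, Dprime, ci[0], ci[1], classify_pair(ci, **thresholds))


# ---------------------------------------------------------------------------
# blocks


@dataclass
class HaploBlock:
    chromosome: str
    marker_ids: list[str]
    first_index: int  # positional index on the chromosome's eligible markers
    last_index: int
    start_bp: int
    end_bp: int
    haplotype_freqs: Optional[np.ndarray] = None
    hd: Optional[float] = None
    n_complete: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class BlockSummary:
    per_chromosome: pd.Series
    total: int
    mean_per_chromosome: float
    mean_hd: float

    @classmethod
    def from_blocks(cls, blocks: list[HaploBlock], n_chromosomes: int = 21) -> "BlockSummary":
        per_chrom = pd.Series(dtype=int)
        if blocks:
            per_chrom = pd.Series([b.chromosome for b in blocks]).value_counts().sort_index()
        total = len(blocks)
        hds = [b.hd for b in blocks if b.hd is not None]
        return cls(
            per_chromosome=per_chrom,
            total=total,
            mean_per_chromosome=total / n_chromosomes,
            mean_hd=float(np.mean(hds)) if hds else float("nan"),
        )


def _pairwise_classes(calls: np.ndarray, grid_step: float, thresholds: dict) -> np.ndarray:
    """Upper-triangular matrix of PairClass over the given marker columns."""
    m = calls.shape[1]
    classes = np.empty((m, m), dtype=object)
    for i in range(m):
        for j in range(i + 1, m):
            counts = _counts_from_calls(calls[:, i], calls[:, j])
            classes[i, j] = classify_pair(dprime_ci(counts, grid_step), **thresholds)
    return classes


def _qualifies(classes: np.ndarray, i: int, j: int, min_informative_frac: float) -> bool:
    if classes[i, j] is not PairClass.STRONG_LD:
        return False
    if j == i + 1:
        return True
    sub = [classes[a, b] for a in range(i, j + 1) for b in range(a + 1, j + 1)]
    n_strong = sum(c is PairClass.STRONG_LD for c in sub)
    n_inform = n_strong + sum(c is PairClass.RECOMBINATION for c in sub)
    if n_inform == 0:
        return False
    return n_strong / n_inform >= min_informative_frac


def find_blocks(gm: GenotypeMatrix, subset=None, chromosome: Optional[str] = None,
                min_maf: float = 0.05, max_span_bp: Optional[int] = None,
                min_informative_frac: float = 0.95, grid_step: float = 0.001,
                strong_low: float = 0.70, strong_high: float = 0.98,
                recomb_high: float = 0.90) -> list[HaploBlock]:
    """Partition one chromosome (or each in turn when ``chromosome`` is None)
    into haplotype blocks under the CI rule.

    Markers with subset MAF < ``min_maf`` are excluded from the search.
    Candidate intervals wider than ``max_span_bp`` (when set) are skipped.
    """
    from .diversity import allele_frequencies

    if chromosome is None:
        out: list[HaploBlock] = []
        for chrom in dict.fromkeys(gm.markers["chrom"]):
            out.extend(
                find_blocks(gm, subset, chrom, min_maf, max_span_bp,
                            min_informative_frac, grid_step,
                            strong_low, strong_high, recomb_high)
            )
        return out

    thresholds = dict(strong_low=strong_low, strong_high=strong_high, recomb_high=recomb_high)
    freqs = allele_frequencies(gm, subset)
    eligible = (
        (gm.markers["chrom"].values == chromosome)
        & freqs.defined
        & (np.nan_to_num(freqs.maf) >= min_maf)
    )
    sub_gm = gm.take_markers(eligible).sort_markers()
    m = sub_gm.n_markers
    if m < 2:
        return []
    idx = gm.accession_indices(subset)
    calls = sub_gm.calls[idx]
    pos = sub_gm.markers["pos"].values.astype(np.int64)
    classes = _pairwise_classes(calls, grid_step, thresholds)

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if max_span_bp is not None and pos[j] - pos[i] > max_span_bp:
                continue
            if _qualifies(classes, i, j, min_informative_frac):
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))

    taken = np.zeros(m, dtype=bool)
    blocks = []
    for i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        block = HaploBlock(
            chromosome=chromosome,
            marker_ids=list(sub_gm.markers.index[i : j + 1]),
            first_index=i,
            last_index=j,
            start_bp=int(pos[i]),
            end_bp=int(pos[j]),
        )
        freqs_h, hd, n_complete = block_haplotypes(gm, subset, block.marker_ids)
        block.haplotype_freqs, block.hd, block.n_complete = freqs_h, hd, n_complete
        blocks.append(block)
    blocks.sort(key=lambda b: b.start_bp)
    return blocks


def block_haplotypes(gm: GenotypeMatrix, subset, marker_ids) -> tuple[np.ndarray, Optional[float], int]:
    """Haplotype frequencies and Nei diversity for a block.

    Lines homozygous and non-missing across all block markers contribute one
    multilocus haplotype; ``Hd = n/(n-1) * (1 - sum h_i^2)``. Hd is None
    (undefined) with fewer than two complete lines.
    """
    j = gm.markers.index.get_indexer(list(marker_ids))
    if (j < 0).any():
        raise KeyError("unknown marker id in block")
    idx = gm.accession_indices(subset)
    calls = gm.calls[np.ix_(idx, j)]
    complete = ((calls == HOM_A) | (calls == HOM_B)).all(axis=1)
    haps = calls[complete]
    n = haps.shape[0]
    if n < 2:
        return np.array([]), None, n
    _, counts = np.unique(haps, axis=0, return_counts=True)
    h = counts / n
    hd = n / (n - 1) * (1.0 - float((h**2).sum()))
    return h, hd, n


def summarize_blocks(blocks: list[HaploBlock], n_chromosomes: int = 21) -> BlockSummary:
    return BlockSummary.from_blocks(blocks, n_chromosomes)


def write_blocks_bed(blocks: list[HaploBlock], path) -> None:
    """Blocks as BED (0-based half-open on the marker span)."""
    from .io import atomic_write_text

    lines = [
        f"{b.chromosome}\t{b.start_bp - 1}\t{b.end_bp}\tblock_{k}\t{b.n_markers}"
        for k, b in enumerate(blocks, start=1)
    ]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def write_blocks_detail(blocks: list[HaploBlock], path) -> None:
    from .io import atomic_write_text

    rows = []
    for k, b in enumerate(blocks, start=1):
        rows.append(
            {
                "block": f"block_{k}",
                "chrom": b.chromosome,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "n_markers": b.n_markers,
                "n_haplotypes": len(b.haplotype_freqs) if b.haplotype_freqs is not None else 0,
                "n_complete": b.n_complete,
                "hd": "" if b.hd is None else b.hd,
                "markers": ",".join(b.marker_ids),
            }
        )
    atomic_write_text(path, pd.DataFrame(rows).to_csv(sep="\t", index=False))
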