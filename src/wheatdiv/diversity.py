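"""Diversity statistics for inbred-line SNP panels.

Covers allele frequencies, marker informativeness indices (expected
heterozygosity H, polymorphic information content PIC, discriminating
power D), MAF classes, polymorphism counts, nucleotide diversity (pi) per
chromosome and in physical windows, per-genome polymorphism summaries,
PCA, and even-group subsampling.

Nucleotide diversity convention
-------------------------------
Lines homogenized by single-seed descent are treated as haploid sequences:
at each marker the sample consists of the homozygous, non-missing lines
(one allele copy each); residual heterozygous calls are ambiguous for a
single-sequence reading and are excluded at that site. With n such lines
and allele frequency p among them, the per-marker contribution is the
unbiased pairwise-difference average ``n/(n-1) * 2 p (1-p)``, and pi is
the sum of contributions divided by physical length (chromosome size or
window size), i.e. an average number of differences *per site*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import HET, HOM_A, HOM_B, MISSING, UNPLACED, ChromosomeTable, GenotypeMatrix

logger = logging.getLogger(__name__)

MB = 1_000_000


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class AlleleFrequencies:
    """Per-marker frequency of allele_a (p), its complement (q), minor
    allele frequency, number of allele copies called, and a defined-flag
    (False where every call is missing)."""

    marker_ids: pd.Index
    p: np.ndarray
    n_alleles_called: np.ndarray
    defined: np.ndarray

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p, "q": self.q, "maf": self.maf,
             "n_alleles_called": self.n_alleles_called, "defined": self.defined},
            index=self.marker_ids,
        )


def allele_frequencies(gm: GenotypeMatrix, subset=None) -> AlleleFrequencies:
    """Diploid-count allele frequencies over an accession subset.

    HOM_A contributes two copies of allele_a, HOM_B two of allele_b, HET one
    of each, MISSING none. Markers with no called alleles are flagged
    undefined (p reported as NaN) and excluded from downstream statistics.
    """
    idx = gm.accession_indices(subset)
    if len(idx) == 0:
        raise ValueError("accession subset is empty")
    calls = gm.calls[idx]
    n_a = 2 * (calls == HOM_A).sum(axis=0) + (calls == HET).sum(axis=0)
    n_b = 2 * (calls == HOM_B).sum(axis=0) + (calls == HET).sum(axis=0)
    total = (n_a + n_b).astype(np.int64)
    defined = total > 0
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("allele_frequencies: %d markers have no called alleles", n_undef)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(defined, n_a / np.maximum(total, 1), np.nan)
    return AlleleFrequencies(gm.markers.index, p, total, defined)


# ---------------------------------------------------------------------------
# marker informativeness (H / PIC / D)


@dataclass
class MarkerStats:
    """Per-marker H, PIC and discriminating power D with collection means.

    For a biallelic marker with allele frequencies (p, q):
    ``H = 1 - p^2 - q^2`` (expected heterozygosity, max 0.5) and
    ``PIC = 1 - (p^2 + q^2) - 2 p^2 q^2`` (Botstein), so PIC <= H.
    D follows Tessier: ``D = 1 - sum_i g_i (N g_i - 1) / (N - 1)`` over the
    observed genotype-pattern frequencies g_i among the N called accessions —
    the probability that two randomly drawn accessions differ at the marker.
    """

    table: pd.DataFrame  # columns: H, PIC, D
    mean_h: float
    mean_pic: float
    mean_d: float


def marker_stats(gm: GenotypeMatrix, subset=None) -> MarkerStats:
    idx = gm.accession_indices(subset)
    if len(idx) < 2:
        raise ValueError("marker_stats requires at least 2 accessions (D is undefined)")
    freqs = allele_frequencies(gm, subset)
    p, q = freqs.p, freqs.q
    H = 1.0 - p**2 - q**2
    PIC = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2

    calls = gm.calls[idx]
    counts = np.stack(
        [(calls == code).sum(axis=0) for code in (HOM_A, HET, HOM_B)]
    ).astype(float)  # 3 x markers, missing excluded
    N = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts / np.maximum(N, 1)
        D = 1.0 - (g * (N * g - 1.0) / np.maximum(N - 1.0, 1e-300)).sum(axis=0)
    D = np.where(N >= 2, D, np.nan)

    table = pd.DataFrame({"H": H, "PIC": PIC, "D": D}, index=gm.markers.index)
    ok = freqs.defined & np.isfinite(D)
    return MarkerStats(
        table,
        mean_h=float(np.nanmean(H[freqs.defined])),
        mean_pic=float(np.nanmean(PIC[freqs.defined])),
        mean_d=float(np.nanmean(D[ok])) if ok.any() else float("nan"),
    )


# ---------------------------------------------------------------------------
# MAF classification


@dataclass
class MAFClassification:
    """Counts of defined-frequency markers per MAF bin.

    Bins: rare ``[0, rare_thr)``, intermediate ``[rare_thr, common_thr]``
    (closed on both sides), common ``(common_thr, 0.5]``.
    """

    rare_thr: float
    common_thr: float
    n_rare: int
    n_intermediate: int
    n_common: int

    @property
    def n_classified(self) -> int:
        return self.n_rare + self.n_intermediate + self.n_common

    @property
    def proportions(self) -> dict:
        n = max(self.n_classified, 1)
        return {
            "rare": self.n_rare / n,
            "intermediate": self.n_intermediate / n,
            "common": self.n_common / n,
        }


def classify_maf(
    freqs: AlleleFrequencies, rare_thr: float = 0.05, common_thr: float = 0.15
) -> MAFClassification:
    if not 0.0 <= rare_thr <= common_thr <= 0.5:
        raise ValueError("need 0 <= rare_thr <= common_thr <= 0.5")
    maf = freqs.maf[freqs.defined]
    return MAFClassification(
        rare_thr,
        common_thr,
        n_rare=int((maf < rare_thr).sum()),
        n_intermediate=int(((maf >= rare_thr) & (maf <= common_thr)).sum()),
        n_common=int((maf > common_thr).sum()),
    )


# ---------------------------------------------------------------------------
# polymorphism counts


@dataclass
class PolymorphismSummary:
    label: str
    n_polymorphic: int
    n_total: int

    @property
    def percentage(self) -> float:
        return round(100.0 * self.n_polymorphic / self.n_total, 2)


def _observed_alleles(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(has_a, has_b) per marker among non-missing calls (HET carries both)."""
    has_a = ((calls == HOM_A) | (calls == HET)).any(axis=0)
    has_b = ((calls == HOM_B) | (calls == HET)).any(axis=0)
    return has_a, has_b


def polymorphic_mask(gm: GenotypeMatrix, subset=None) -> np.ndarray:
    """True where >= 2 distinct alleles are observed in the subset (a single
    heterozygous call suffices)."""
    idx = gm.accession_indices(subset)
    if len(idx) == 0:
        raise ValueError("accession subset is empty")
    has_a, has_b = _observed_alleles(gm.calls[idx])
    return has_a & has_b


def polymorphic_summary(gm: GenotypeMatrix, subsets: dict) -> list[PolymorphismSummary]:
    """Polymorphic-marker counts for each named accession subset."""
    return [
        PolymorphismSummary(label, int(polymorphic_mask(gm, ids).sum()), gm.n_markers)
        for label, ids in subsets.items()
    ]


# ---------------------------------------------------------------------------
# nucleotide diversity


def _pi_summands(gm: GenotypeMatrix, subset) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker pairwise-difference contribution and inclusion mask.

    Haploid line counting (see module docstring): n = homozygous non-missing
    lines; markers with n < 2 are excluded.
    """
    idx = gm.accession_indices(subset)
    calls = gm.calls[idx]
    n_a = (calls == HOM_A).sum(axis=0).astype(float)
    n_b = (calls == HOM_B).sum(axis=0).astype(float)
    n = n_a + n_b
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = n_a / np.maximum(n, 1)
        summand = np.where(ok, n / np.maximum(n - 1.0, 1) * 2.0 * p * (1.0 - p), 0.0)
    return summand, ok


@dataclass
class PiResult:
    per_chromosome: pd.DataFrame  # index chrom; columns pi, n_snps, n_excluded
    genome_wide: float
    n_unplaced: int


def nucleotide_diversity(gm: GenotypeMatrix, subset=None,
                         chrom_table: Optional[ChromosomeTable] = None) -> PiResult:
    """Per-chromosome and genome-wide pi, scaled by physical chromosome size.

    ``pi_c = sum_j contribution_j / L_c`` over markers j on chromosome c;
    genome-wide pi pools numerators and lengths over the 21 chromosomes.
    """
    if chrom_table is None:
        chrom_table = ChromosomeTable.wheat_default()
    summand, ok = _pi_summands(gm, subset)
    chroms = gm.markers["chrom"].values
    n_unplaced = int((chroms == UNPLACED).sum())

    rows = {}
    total_num = total_len = 0.0
    for chrom in chrom_table.names:
        on_c = chroms == chrom
        L = chrom_table.length_of(chrom)
        num = float(summand[on_c].sum())
        rows[chrom] = {
            "pi": num / L,
            "n_snps": int((on_c & ok).sum()),
            "n_excluded": int((on_c & ~ok).sum()),
        }
        total_num += num
        total_len += L
    return PiResult(
        per_chromosome=pd.DataFrame.from_dict(rows, orient="index"),
        genome_wide=total_num / total_len,
        n_unplaced=n_unplaced,
    )


def windowed_diversity(gm: GenotypeMatrix, subset=None,
                       chrom_table: Optional[ChromosomeTable] = None,
                       window_bp: int = 3 * MB) -> pd.DataFrame:
    """Pi and marker density in half-open physical windows tiling each
    chromosome.

    Windows are 1-based ``[start, start + window_bp)``; the last window is
    truncated at the chromosome end and its actual length is used as the
    pi denominator, so windowed values aggregate exactly to per-chromosome
    pi. Returns a DiversityTrack frame with columns chrom, window_start,
    window_end (exclusive), pi, n_snps, density_per_mb.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if chrom_table is None:
        chrom_table = ChromosomeTable.wheat_default()
    summand, ok = _pi_summands(gm, subset)
    chroms = gm.markers["chrom"].values
    pos = gm.markers["pos"].values.astype(np.int64)

    records = []
    for chrom in chrom_table.names:
        L = chrom_table.length_of(chrom)
        on_c = chroms == chrom
        pos_c = pos[on_c]
        sum_c = summand[on_c]
        ok_c = ok[on_c]
        widx = (pos_c - 1) // window_bp
        for w, start in enumerate(range(1, L + 1, window_bp)):
            end = min(start + window_bp, L + 1)  # exclusive
            length = end - start
            in_w = widx == w
            num = float(sum_c[in_w].sum())
            n_snps = int((in_w & ok_c).sum())
            records.append(
                {
                    "chrom": chrom,
                    "window_start": start,
                    "window_end": end,
                    "pi": num / length,
                    "n_snps": n_snps,
                    "density_per_mb": n_snps / (length / MB),
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# per-genome summaries


@dataclass
class GenomeSummary:
    by_chromosome: pd.DataFrame  # index chrom, one column per subset label
    by_genome: pd.DataFrame
    by_group: pd.DataFrame
    unplaced: pd.Series


def per_genome_summary(gm: GenotypeMatrix, subsets: dict,
                       chrom_table: Optional[ChromosomeTable] = None) -> GenomeSummary:
    """Polymorphic-marker counts by chromosome, subgenome (A/B/D) and
    homoeologous group for each named subset. UNPLACED markers are tallied
    separately and excluded from the placed aggregations."""
    if chrom_table is None:
        chrom_table = ChromosomeTable.wheat_default()
    chroms = gm.markers["chrom"].values
    per_chrom = {}
    unplaced = {}
    for label, ids in subsets.items():
        poly = polymorphic_mask(gm, ids)
        per_chrom[label] = {c: int((poly & (chroms == c)).sum()) for c in chrom_table.names}
        unplaced[label] = int((poly & (chroms == UNPLACED)).sum())
    by_chrom = pd.DataFrame(per_chrom).loc[chrom_table.names]
    meta = chrom_table.table
    by_genome = by_chrom.groupby(meta["genome"]).sum()
    by_group = by_chrom.groupby(meta["homoeo_group"]).sum()
    return GenomeSummary(by_chrom, by_genome, by_group, pd.Series(unplaced))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # accessions x PC1..PCk
    explained_pct: np.ndarray


def pca(gm: GenotypeMatrix, subset=None, n_components: int = 10) -> PCAResult:
    """PCA of accessions on 0/1/2 dosage with per-marker mean imputation.

    Markers whose frequency is undefined in the subset are excluded; columns
    are centered; ``explained_pct`` is 100 x eigenvalue / trace of the
    accession covariance.
    """
    from sklearn.decomposition import PCA as _SKPCA

    idx = gm.accession_indices(subset)
    if len(idx) < 2:
        raise ValueError("pca requires at least 2 accessions")
    calls = gm.calls[idx].astype(float)
    calls[gm.calls[idx] == MISSING] = np.nan
    defined = ~np.all(np.isnan(calls), axis=0)
    calls = calls[:, defined]
    col_mean = np.nanmean(calls, axis=0)
    nan_mask = np.isnan(calls)
    calls[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    rank = min(calls.shape[0] - 1, calls.shape[1])
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncated to {k}",
            RuntimeWarning, stacklevel=2,
        )
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(calls)
    acc_index = gm.accessions.index[idx]
    return PCAResult(
        scores=pd.DataFrame(scores, index=acc_index,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_pct=100.0 * model.explained_variance_ratio_,
    )


def subsample_even(gm: GenotypeMatrix, pca_result: PCAResult, groups,
                   target_per_group: dict, seed: int = 0) -> list[str]:
    """Reduce over-represented groups to target sizes by pruning the closest
    pairs in top-2 PC space.

    ``groups`` is either a metadata column name (e.g. ``"country"``) or a
    mapping accession_id -> group label. Within each oversized group the
    closest pair of accessions is found on (PC1, PC2) and one member removed
    (deterministically: the lexicographically larger id; distance ties break
    on the sorted id pair), until the group hits its target. Returns the
    retained accession ids in original panel order.
    """
    if isinstance(groups, str):
        labels = gm.accessions[groups].to_dict()
    else:
        labels = dict(groups)
    scores = pca_result.scores.iloc[:, :2]
    unknown = set(target_per_group) - set(labels.values())
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")

    keep = set(scores.index)
    for group, target in sorted(target_per_group.items()):
        members = sorted(a for a in keep if labels.get(a) == group)
        if target > len(members):
            raise ValueError(f"group {group!r}: target {target} exceeds size {len(members)}")
        while len(members) > target:
            pts = scores.loc[members].values
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            iu = np.triu_indices(len(members), k=1)
            flat = d2[iu]
            best = np.lexsort(
                (np.array(members)[iu[1]], np.array(members)[iu[0]], flat)
            )[0]
            a, b = members[iu[0][best]], members[iu[1][best]]
            drop = max(a, b)
            members.remove(drop)
            keep.discard(drop)
    return [a for a in gm.accession_ids if a in keep]


# ---------------------------------------------------------------------------
# track export


def write_track_tsv(track: pd.DataFrame, path) -> None:
    """DiversityTrack as tab-delimited (1-based inclusive start, exclusive end)."""
    from .io import atomic_write_text

    atomic_write_text(path, track.to_csv(sep="\t", index=False))


def write_track_bed(track: pd.DataFrame, path, value_col: str = "pi") -> None:
    """DiversityTrack as BED: 0-based half-open, one value column."""
    from .io import atomic_write_text

    lines = [
        f"{r.chrom}\t{int(r.window_start) - 1}\t{int(r.window_end) - 1}\t{getattr(r, value_col)}"
        for r in track.itertuples()
    ]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_track_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
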