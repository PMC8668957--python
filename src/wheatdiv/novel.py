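"""Novel-polymorphism accumulation against a modern-variety baseline.

The question: how many array markers does a landrace carry an allele at
that the modern baseline does not? Landraces are added to the baseline one
at a time; each step counts the markers at which the incoming accession
carries at least one allele absent from the running allele profile, then
folds its alleles in. Counting is at the *marker* level: a marker is novel
once per step even if an accession introduces both alleles at a marker
whose profile was empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import HET, HOM_A, HOM_B, GenotypeMatrix


@dataclass
class AlleleProfile:
    """Per-marker set of observed alleles as two boolean arrays."""

    marker_ids: pd.Index
    has_a: np.ndarray
    has_b: np.ndarray

    def copy(self) -> "AlleleProfile":
        return AlleleProfile(self.marker_ids, self.has_a.copy(), self.has_b.copy())

    def equals(self, other: "AlleleProfile") -> bool:
        return bool(
            np.array_equal(self.has_a, other.has_a)
            and np.array_equal(self.has_b, other.has_b)
        )

    @property
    def n_empty(self) -> int:
        return int((~self.has_a & ~self.has_b).sum())


@dataclass
class AccumulationResult:
    baseline_label: str
    order: list[str]
    per_step: np.ndarray  # novel-marker count contributed by each accession
    final_profile: AlleleProfile

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.per_step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession_id": self.order, "novel": self.per_step, "cumulative": self.cumulative}
        )


def _carried(calls_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(carries_a, carries_b) for one accession's call vector."""
    a = (calls_row == HOM_A) | (calls_row == HET)
    b = (calls_row == HOM_B) | (calls_row == HET)
    return a, b


def build_profile(gm: GenotypeMatrix, baseline) -> AlleleProfile:
    """Union of alleles carried at each marker by the baseline accessions."""
    idx = gm.accession_indices(baseline)
    if len(idx) == 0:
        raise ValueError("baseline is empty")
    calls = gm.calls[idx]
    has_a = ((calls == HOM_A) | (calls == HET)).any(axis=0)
    has_b = ((calls == HOM_B) | (calls == HET)).any(axis=0)
    return AlleleProfile(gm.markers.index, has_a, has_b)


def novel_count_single(gm: GenotypeMatrix, accession: str, profile: AlleleProfile,
                       count_empty_profile: bool = True) -> int:
    """Markers at which ``accession`` carries >= 1 allele absent from the
    profile. MISSING is never novel. At markers whose profile is empty the
    first observed allele counts as novel unless ``count_empty_profile`` is
    False (then such markers are ignored)."""
    (i,) = gm.accession_indices([accession])
    a, b = _carried(gm.calls[i])
    novel = (a & ~profile.has_a) | (b & ~profile.has_b)
    if not count_empty_profile:
        novel &= profile.has_a | profile.has_b
    return int(novel.sum())


def _fold_in(profile: AlleleProfile, gm: GenotypeMatrix, i: int) -> None:
    a, b = _carried(gm.calls[i])
    profile.has_a |= a
    profile.has_b |= b


def sequential_accumulation(gm: GenotypeMatrix, baseline, order,
                            baseline_label: str = "baseline",
                            count_empty_profile: bool = True) -> AccumulationResult:
    """Add accessions to the baseline in the given order, counting each
    step's novel markers before folding the accession's alleles in.

    The final profile equals ``build_profile(baseline + order)`` for any
    permutation of ``order``; the per-step counts depend on the order.
    """
    order = list(order)
    if len(set(order)) != len(order):
        dup = pd.Index(order)[pd.Index(order).duplicated()][0]
        raise ValueError(f"duplicate accession in order: {dup!r}")
    base_ids = set(gm.accessions.index[gm.accession_indices(baseline)])
    overlap = base_ids & set(order)
    if overlap:
        raise ValueError(f"order overlaps baseline: {sorted(overlap)[:5]}")

    profile = build_profile(gm, baseline)
    per_step = np.zeros(len(order), dtype=np.int64)
    for step, acc in enumerate(order):
        per_step[step] = novel_count_single(gm, acc, profile, count_empty_profile)
        (i,) = gm.accession_indices([acc])
        _fold_in(profile, gm, i)
    return AccumulationResult(baseline_label, order, per_step, profile)


def single_addition_counts(gm: GenotypeMatrix, baseline, candidates,
                           count_empty_profile: bool = True) -> pd.Series:
    """Each candidate's novelty against the bare baseline (no accumulation)."""
    profile = build_profile(gm, baseline)
    return pd.Series(
        {acc: novel_count_single(gm, acc, profile, count_empty_profile) for acc in candidates},
        name="novel",
    )


def random_order_accumulation(gm: GenotypeMatrix, baseline, candidates,
                              n_permutations: int = 20, seed: int = 0) -> pd.DataFrame:
    """Mean and sd of per-step novel counts over seeded random orders."""
    rng = np.random.default_rng(seed)
    candidates = list(candidates)
    steps = np.empty((n_permutations, len(candidates)), dtype=np.int64)
    for r in range(n_permutations):
        order = [candidates[i] for i in rng.permutation(len(candidates))]
        steps[r] = sequential_accumulation(gm, baseline, order).per_step
    return pd.DataFrame(
        {"step": np.arange(1, len(candidates) + 1),
         "mean_novel": steps.mean(axis=0), "sd_novel": steps.std(axis=0, ddof=1)}
    )


def country_summary(single_counts: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary plus mean of per-accession novelty by country.

    Quartiles use linear interpolation between order statistics.
    """
    missing = set(single_counts.index) - set(metadata.index)
    if missing:
        raise ValueError(f"accessions without metadata: {sorted(missing)[:5]}")
    df = pd.DataFrame(
        {"novel": single_counts, "country": metadata.loc[single_counts.index, "country"]}
    )
    rows = {}
    for country, grp in df.groupby("country", sort=True):
        v = grp["novel"].values.astype(float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
        rows[country] = {
            "n": len(v), "min": v.min(), "q1": q1, "median": med,
            "mean": v.mean(), "q3": q3, "max": v.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
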