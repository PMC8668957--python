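"""Marker quality control: missingness/heterozygosity and MAF filters.

Array-genotyped inbred lines should be nearly homozygous; markers with an
excess of missing or heterozygous calls are treated as assay failures and
removed. Filters act on markers only — the accession set never changes.
Filter order is fixed: missingness/heterozygosity first, then MAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import HET, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Bookkeeping for a marker-filtering pass.

    ``markers_out`` always equals ``markers_in`` minus the number of
    *distinct* removed markers (a marker failing both criteria is counted
    once in each removal tally but removed once).
    """

    markers_in: int
    removed_missing: int = 0
    removed_het: int = 0
    removed_maf: int = 0
    markers_out: int = 0
    missing_fraction: Optional[pd.Series] = field(default=None, repr=False)
    het_fraction: Optional[pd.Series] = field(default=None, repr=False)

    @classmethod
    def from_totals(cls, markers_in: int, removed: int) -> "QCReport":
        """Report built from aggregate totals only (no per-marker detail)."""
        return cls(markers_in=markers_in, removed_missing=removed,
                   markers_out=markers_in - removed)

    def to_dict(self) -> dict:
        return {
            "markers_in": self.markers_in,
            "removed_missing": self.removed_missing,
            "removed_het": self.removed_het,
            "removed_maf": self.removed_maf,
            "markers_out": self.markers_out,
        }


def marker_call_fractions(gm: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-marker missing fraction (over all accessions) and HET fraction
    (over called accessions; 0 where nothing is called)."""
    n = gm.n_accessions
    n_missing = (gm.calls == MISSING).sum(axis=0)
    n_het = (gm.calls == HET).sum(axis=0)
    n_called = n - n_missing
    missing_frac = pd.Series(n_missing / n, index=gm.markers.index, name="missing_fraction")
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    het_frac = pd.Series(het, index=gm.markers.index, name="het_fraction")
    return missing_frac, het_frac


def qc_filter(
    gm: GenotypeMatrix, max_missing: float = 0.10, max_het: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers whose missing fraction exceeds ``max_missing`` OR whose
    heterozygosity exceeds ``max_het`` (strict inequalities: a marker exactly
    at a threshold survives)."""
    for name, thr in (("max_missing", max_missing), ("max_het", max_het)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    missing_frac, het_frac = marker_call_fractions(gm)
    fail_missing = missing_frac.values > max_missing
    fail_het = het_frac.values > max_het
    keep = ~(fail_missing | fail_het)
    report = QCReport(
        markers_in=gm.n_markers,
        removed_missing=int(fail_missing.sum()),
        removed_het=int(fail_het.sum()),
        markers_out=int(keep.sum()),
        missing_fraction=missing_frac,
        het_fraction=het_frac,
    )
    if report.markers_out == 0:
        logger.warning("qc_filter: no markers survive (in=%d)", gm.n_markers)
    return gm.take_markers(keep), report


def maf_filter(
    gm: GenotypeMatrix, subset=None, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with minor allele frequency strictly below ``min_maf``
    in the given accession subset. All-missing markers have undefined
    frequency, are treated as MAF 0 and removed (logged)."""
    from .diversity import allele_frequencies

    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    freqs = allele_frequencies(gm, subset)
    maf = np.where(freqs.defined, freqs.maf, 0.0)
    n_undef = int((~freqs.defined).sum())
    if n_undef:
        logger.info("maf_filter: %d all-missing markers treated as MAF 0 and removed", n_undef)
    keep = maf >= min_maf
    report = QCReport(
        markers_in=gm.n_markers,
        removed_maf=int((~keep).sum()),
        markers_out=int(keep.sum()),
    )
    return gm.take_markers(keep), report
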