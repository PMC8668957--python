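"""Core data model for SNP panels of inbred wheat lines.

Genotype calls are stored as a dense ``int8`` matrix (accessions x markers)
using a 4-state code. Hexaploid bread wheat carries 21 chromosomes named by
homoeologous group (1-7) and subgenome (A/B/D); markers that cannot be placed
on the physical map carry the ``UNPLACED`` label and are excluded from
position-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# 4-state genotype code. HOM_A/HOM_B are homozygous for allele_a/allele_b,
# HET carries both alleles, MISSING carries none.
HOM_A = np.int8(0)
HET = np.int8(1)
HOM_B = np.int8(2)
MISSING = np.int8(-1)

GENOMES = ("A", "B", "D")
#: The 21 wheat chromosomes in canonical order: 1A, 1B, 1D, 2A, ..., 7D.
CHROMOSOMES = tuple(f"{g}{s}" for g in range(1, 8) for s in GENOMES)
UNPLACED = "UNPLACED"
#: Sort order used panel-wide: the 21 chromosomes, then UNPLACED.
CHROM_ORDER = {name: i for i, name in enumerate(CHROMOSOMES + (UNPLACED,))}

#: Approximate physical chromosome lengths (bp) of the hexaploid wheat
#: genome assembly (IWGSC RefSeq v1.0), used as the default size table
#: for per-chromosome diversity scaling.
WHEAT_CHROM_LENGTHS_BP = {
    "1A": 594_102_056, "1B": 689_851_870, "1D": 495_453_186,
    "2A": 780_798_557, "2B": 801_256_715, "2D": 651_852_609,
    "3A": 750_843_639, "3B": 830_829_764, "3D": 615_552_423,
    "4A": 744_588_157, "4B": 673_617_499, "4D": 509_857_067,
    "5A": 709_773_743, "5B": 713_149_757, "5D": 566_080_677,
    "6A": 618_079_260, "6B": 720_988_478, "6D": 473_592_718,
    "7A": 736_706_236, "7B": 750_620_385, "7D": 638_686_055,
}

MARKER_COLUMNS = ["chrom", "pos", "allele_a", "allele_b"]
ACCESSION_COLUMNS = ["country", "region", "chrono_class", "western_flag", "year"]


class PanelFormatError(ValueError):
    """Raised when an input file or table violates the panel data model."""


@dataclass(frozen=True)
class ChromosomeTable:
    """Per-chromosome name, subgenome, homoeologous group and length.

    ``table`` is indexed by chromosome name with columns
    ``genome``, ``homoeo_group`` and ``length_bp``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"genome", "homoeo_group", "length_bp"} - set(t.columns)
        if missing:
            raise PanelFormatError(f"chromosome table missing columns: {sorted(missing)}")
        if len(t) != 21:
            raise PanelFormatError(f"chromosome table must have 21 rows, got {len(t)}")
        for name, row in t.iterrows():
            expected = f"{int(row.homoeo_group)}{row.genome}"
            if name != expected:
                raise PanelFormatError(
                    f"chromosome name {name!r} does not match group+genome {expected!r}"
                )
            if int(row.length_bp) < 1:
                raise PanelFormatError(f"chromosome {name}: length_bp must be >= 1")

    @classmethod
    def wheat_default(cls) -> "ChromosomeTable":
        """The built-in hexaploid wheat size table (RefSeq v1.0 estimates)."""
        rows = {
            name: {"genome": name[1], "homoeo_group": int(name[0]), "length_bp": bp}
            for name, bp in WHEAT_CHROM_LENGTHS_BP.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index").loc[list(CHROMOSOMES)]
        df.index.name = "name"
        return cls(df)

    def length_of(self, chrom: str) -> int:
        return int(self.table.loc[chrom, "length_bp"])

    @property
    def names(self) -> list[str]:
        return list(self.table.index)


def _check_unique(values, axis_name: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise PanelFormatError(f"duplicate {axis_name} id: {dup[0]!r}")


@dataclass
class GenotypeMatrix:
    """An accessions x markers panel of 4-state genotype calls.

    Attributes
    ----------
    accessions : pd.DataFrame
        Indexed by accession_id; columns ``country``, ``region``,
        ``chrono_class`` (landrace/modern), ``western_flag``, ``year``.
    markers : pd.DataFrame
        Indexed by marker_id; columns ``chrom``, ``pos`` (1-based bp),
        ``allele_a``, ``allele_b``.
    calls : np.ndarray
        ``int8`` array of shape (n_accessions, n_markers) in the
        HOM_A/HET/HOM_B/MISSING code.
    """

    accessions: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accessions), len(self.markers)):
            raise PanelFormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        _check_unique(self.accessions.index, "accession")
        _check_unique(self.markers.index, "marker")
        bad = set(np.unique(self.calls)) - {-1, 0, 1, 2}
        if bad:
            raise PanelFormatError(f"invalid call codes present: {sorted(bad)}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.accessions.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def accession_indices(self, subset) -> np.ndarray:
        """Row indices for a list of accession ids (order preserved)."""
        if subset is None:
            return np.arange(self.n_accessions)
        idx = self.accessions.index.get_indexer(list(subset))
        if (idx < 0).any():
            missing = [s for s, i in zip(subset, idx) if i < 0]
            raise KeyError(f"unknown accession id(s): {missing[:5]}")
        return idx

    def ids_by_class(self, chrono_class: str) -> list[str]:
        return list(self.accessions.index[self.accessions["chrono_class"] == chrono_class])

    @property
    def landrace_ids(self) -> list[str]:
        return self.ids_by_class("landrace")

    @property
    def modern_ids(self) -> list[str]:
        return self.ids_by_class("modern")

    @property
    def western_modern_ids(self) -> list[str]:
        acc = self.accessions
        mask = (acc["chrono_class"] == "modern") & acc["western_flag"].astype(bool)
        return list(acc.index[mask])

    # -- transformations -----------------------------------------------------

    def sort_markers(self) -> "GenotypeMatrix":
        """Markers sorted by (chromosome in 1A..7D order, position, marker_id)."""
        m = self.markers
        order = np.lexsort(
            (m.index.values, m["pos"].values, m["chrom"].map(CHROM_ORDER).values)
        )
        return GenotypeMatrix(self.accessions, m.iloc[order], self.calls[:, order])

    def take_markers(self, selector) -> "GenotypeMatrix":
        """Subset markers by boolean mask or positional indices."""
        selector = np.asarray(selector)
        if selector.dtype == bool:
            selector = np.flatnonzero(selector)
        return GenotypeMatrix(
            self.accessions, self.markers.iloc[selector], self.calls[:, selector]
        )

    def take_accessions(self, subset) -> "GenotypeMatrix":
        idx = self.accession_indices(subset)
        return GenotypeMatrix(self.accessions.iloc[idx], self.markers, self.calls[idx])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.accessions.copy(), self.markers.copy(), self.calls.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Structural equality on ids, marker map, metadata and calls."""
        if not isinstance(other, GenotypeMatrix):
            return False
        if list(self.accessions.index) != list(other.accessions.index):
            return False
        if list(self.markers.index) != list(other.markers.index):
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        m1 = self.markers[MARKER_COLUMNS]
        m2 = other.markers[MARKER_COLUMNS]
        return bool((m1.values == m2.values).all())


def make_accession_frame(ids, country=None, region=None, chrono_class="landrace",
                         western_flag=False, year=None) -> pd.DataFrame:
    """Convenience constructor for the accession metadata frame."""
    n = len(ids)

    def expand(v, default):
        if v is None:
            v = default
        if np.isscalar(v) or v is None:
            return [v] * n
        return list(v)

    df = pd.DataFrame(
        {
            "country": expand(country, "unknown"),
            "region": expand(region, "unknown"),
            "chrono_class": expand(chrono_class, "landrace"),
            "western_flag": expand(western_flag, False),
            "year": expand(year, None),
        },
        index=pd.Index(ids, name="accession_id"),
    )
    bad = df["western_flag"].astype(bool) & (df["chrono_class"] != "modern")
    if bad.any():
        raise PanelFormatError(
            f"western_flag set on non-modern accession(s): {list(df.index[bad])[:5]}"
        )
    return df
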