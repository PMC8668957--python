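"""Ground-truthed synthetic SNP panels, clustering replicates and skyline
fixtures.

The panel generator emulates the statistical structure of a historical
wheat collection: inbred (effectively haploid) lines sampled from K_true
ancestral populations under the Balding-Nichols drift model, with
per-accession admixture proportions drawn from region-specific Dirichlet
priors. The default recipe mirrors the study panel this package targets:
199 landraces from 6 Central European countries admixed over four ancestral
groups, plus 67 modern cultivars dominated by the remaining two groups, on
~15.8K markers spread over the 21 wheat chromosomes.

Model
-----
* ancestral frequency  ``p_m ~ Uniform(0.05, 0.95)`` per marker;
* population frequency ``p_km ~ Beta(p_m (1-F_k)/F_k, (1-p_m)(1-F_k)/F_k)``
  so that ``E[p_km] = p_m`` and ``Var[p_km] = F_k p_m (1-p_m)``;
* admixture ``q_i ~ Dirichlet(alpha_region)``;
* each line draws allele a at marker m with probability ``sum_k q_ik p_km``
  and is recorded homozygous for the drawn allele; residual heterozygous
  calls and missing data are then injected independently at fixed rates.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix import CHROMOSOMES, HET, HOM_A, HOM_B, MISSING, ChromosomeTable, GenotypeMatrix, make_accession_frame
from .structure import QMatrix, RunLogProb

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class RegionSpec:
    """One sampling region: n accessions with a Dirichlet admixture prior."""

    name: str
    n_accessions: int
    alpha: Sequence[float]
    chrono_class: str = "landrace"
    country: Optional[str] = None
    western_flag: bool = False
    year_range: tuple[int, int] = (1950, 1960)

    def __post_init__(self) -> None:
        if self.country is None:
            self.country = self.name


@dataclass
class BlockSpec:
    """Planted-LD layout: per-block marker counts and haplotype-pool size."""

    n_blocks: int = 20
    min_markers: int = 4
    max_markers: int = 8
    pool_size: int = 4
    within_gap_bp: tuple[int, int] = (50_000, 500_000)
    between_gap_bp: tuple[int, int] = (5_000_000, 10_000_000)


@dataclass
class LnPCurveParams:
    """Synthetic log-probability curves for K selection: steep mean increase
    up to K_true, small increments after, Gaussian replicate noise. No
    likelihood is computed — the contract is the peak location and noise
    scale only."""

    base: float = -50_000.0
    pre_slope: float = 800.0
    post_slope: float = 30.0
    noise_sd: float = 15.0


@dataclass
class SimulationConfig:
    K_true: int
    F: float | Sequence[float]
    n_markers: int
    regions: list[RegionSpec]
    missing_rate: float = 0.0
    het_rate: float = 0.0
    block_spec: Optional[BlockSpec] = None
    seed: int = 0
    chrom_table: ChromosomeTable = field(default_factory=ChromosomeTable.wheat_default)

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        f = np.atleast_1d(np.asarray(self.F, dtype=float))
        if len(f) not in (1, self.K_true) or ((f <= 0) | (f >= 1)).any():
            raise ValueError("F must be in (0,1), scalar or one value per population")
        for r in self.regions:
            if len(r.alpha) != self.K_true:
                raise ValueError(f"region {r.name}: alpha length != K_true")
            if r.n_accessions < 1:
                raise ValueError(f"region {r.name}: n_accessions must be >= 1")
        for name, rate in (("missing_rate", self.missing_rate), ("het_rate", self.het_rate)):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    @property
    def n_accessions(self) -> int:
        return sum(r.n_accessions for r in self.regions)

    @property
    def f_per_pop(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.F, dtype=float))
        return np.full(self.K_true, f[0]) if len(f) == 1 else f

    # -- YAML round trip -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        regions = [
            RegionSpec(**{**r, "year_range": tuple(r.get("year_range", (1950, 1960)))})
            for r in raw["regions"]
        ]
        block = raw.get("block_spec")
        block_spec = None
        if block is not None:
            block = dict(block)
            for key in ("within_gap_bp", "between_gap_bp"):
                if key in block:
                    block[key] = tuple(block[key])
            block_spec = BlockSpec(**block)
        return cls(
            K_true=int(raw["K_true"]),
            F=raw["F"],
            n_markers=int(raw["n_markers"]),
            regions=regions,
            missing_rate=float(raw.get("missing_rate", 0.0)),
            het_rate=float(raw.get("het_rate", 0.0)),
            block_spec=block_spec,
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        from .io import atomic_write_text

        raw = {
            "K_true": self.K_true,
            "F": self.F if np.isscalar(self.F) else list(self.F),
            "n_markers": self.n_markers,
            "missing_rate": self.missing_rate,
            "het_rate": self.het_rate,
            "seed": self.seed,
            "regions": [
                {**asdict(r), "alpha": list(r.alpha), "year_range": list(r.year_range)}
                for r in self.regions
            ],
        }
        if self.block_spec is not None:
            b = asdict(self.block_spec)
            b["within_gap_bp"] = list(b["within_gap_bp"])
            b["between_gap_bp"] = list(b["between_gap_bp"])
            raw["block_spec"] = b
        atomic_write_text(path, yaml.safe_dump(raw, sort_keys=False))


@dataclass
class SimulationTruth:
    """Ground truth for a simulated panel."""

    ancestral_p: np.ndarray          # (m,)
    pop_p: np.ndarray                # (K_true, m)
    admixture: np.ndarray            # (n, K_true), rows sum to 1
    accession_ids: list[str]
    marker_ids: list[str]
    block_boundaries: list[tuple[str, int, int]] = field(default_factory=list)
    # (chrom, first marker index, last marker index) in panel marker order


def default_panel_config(seed: int = 0) -> SimulationConfig:
    """The study-panel emulation recipe shipped with the package."""
    path = importlib.resources.files("wheatdiv").joinpath("data/default_panel.yaml")
    with importlib.resources.as_file(path) as p:
        config = SimulationConfig.from_yaml(p)
    config.seed = seed
    return config


# ---------------------------------------------------------------------------
# panel simulation


def _place_markers(n_markers: int, chrom_table: ChromosomeTable, rng) -> pd.DataFrame:
    """Markers spread over chromosomes proportional to physical length."""
    lengths = np.array([chrom_table.length_of(c) for c in chrom_table.names], dtype=float)
    share = lengths / lengths.sum()
    counts = np.floor(share * n_markers).astype(int)
    # distribute the remainder to the largest fractional shares
    rem = n_markers - counts.sum()
    frac_order = np.argsort(-(share * n_markers - counts))
    counts[frac_order[:rem]] += 1

    frames = []
    k = 0
    for chrom, L, c in zip(chrom_table.names, lengths, counts):
        if c == 0:
            continue
        pos = np.unique(rng.integers(1, int(L) + 1, size=c))
        while len(pos) < c:  # top up the rare collisions
            pos = np.unique(np.concatenate([pos, rng.integers(1, int(L) + 1, size=c - len(pos))]))
        a1 = rng.integers(0, 4, size=c)
        a2 = (a1 + rng.integers(1, 4, size=c)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"M{k + i:06d}" for i in range(c)],
                    "chrom": chrom,
                    "pos": pos,
                    "allele_a": NUCLEOTIDES[a1],
                    "allele_b": NUCLEOTIDES[a2],
                }
            )
        )
        k += c
    return pd.concat(frames, ignore_index=True).set_index("marker_id")


def _accession_frame(config: SimulationConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """Metadata frame plus per-accession admixture proportions."""
    ids, country, region, chrono, western, year = [], [], [], [], [], []
    q_rows = []
    i = 0
    for spec in config.regions:
        alpha = np.asarray(spec.alpha, dtype=float)
        q = rng.dirichlet(alpha, size=spec.n_accessions) if config.K_true > 1 \
            else np.ones((spec.n_accessions, 1))
        q_rows.append(q)
        lo, hi = spec.year_range
        for _ in range(spec.n_accessions):
            ids.append(f"ACC{i:04d}")
            country.append(spec.country)
            region.append(spec.name)
            chrono.append(spec.chrono_class)
            western.append(spec.western_flag)
            year.append(int(rng.integers(lo, hi + 1)))
            i += 1
    acc = make_accession_frame(ids, country, region, chrono, western, year)
    return acc, np.vstack(q_rows)


def _inject_noise(calls: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    if config.het_rate > 0:
        calls[rng.random(calls.shape) < config.het_rate] = HET
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    return calls


def simulate_panel(config: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Balding-Nichols admixture panel of inbred lines (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    markers = _place_markers(config.n_markers, config.chrom_table, rng)
    m = len(markers)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.f_per_pop
    pop_p = np.empty((config.K_true, m))
    for k in range(config.K_true):
        scale = (1.0 - f[k]) / f[k]
        pop_p[k] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    accessions, q = _accession_frame(config, rng)
    prob_a = q @ pop_p  # n x m
    draws_a = rng.random(prob_a.shape) < prob_a
    calls = np.where(draws_a, HOM_A, HOM_B).astype(np.int8)
    calls = _inject_noise(calls, config, rng)

    gm = GenotypeMatrix(accessions, markers, calls)
    truth = SimulationTruth(p_anc, pop_p, q, gm.accession_ids, gm.marker_ids)
    return gm, truth


def simulate_blocked_panel(config: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Panel with planted haplotype blocks and independence between blocks.

    Within each block every line draws one of ``pool_size`` pool haplotypes
    (uniformly). Pool haplotypes are built by the nested-split construction:
    markers assign allele b to a random prefix of the ordered pool, so any
    two in-block markers are compatible with at most three of the four
    gametes and within-block |D'| is exactly 1 while marker frequencies
    still vary. Between blocks, draws are independent.
    """
    if config.block_spec is None:
        raise ValueError("config.block_spec is required for simulate_blocked_panel")
    spec = config.block_spec
    if spec.pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(config.seed)
    accessions, q = _accession_frame(config, rng)
    n = len(accessions)
    chrom_names = config.chrom_table.names

    marker_rows = []
    call_cols = []
    boundaries = []
    mk = 0
    chrom_cursor = {c: 0 for c in chrom_names}
    for b in range(spec.n_blocks):
        chrom = chrom_names[b % len(chrom_names)]
        n_mark = int(rng.integers(spec.min_markers, spec.max_markers + 1))
        start_idx = mk
        pos = chrom_cursor[chrom] + int(rng.integers(*spec.between_gap_bp))
        h = spec.pool_size
        # nested-split pool: allele b on a random prefix of the pool order
        thresholds = rng.integers(1, h, size=n_mark) if h > 1 else np.zeros(n_mark, int)
        line_hap = rng.integers(0, h, size=n)  # pool index drawn per line
        for t in thresholds:
            alleles = rng.choice(4, size=2, replace=False)
            marker_rows.append((f"M{mk:06d}", chrom, pos,
                                NUCLEOTIDES[alleles[0]], NUCLEOTIDES[alleles[1]]))
            col = np.where(line_hap < t, HOM_B, HOM_A).astype(np.int8)
            call_cols.append(col)
            pos += int(rng.integers(*spec.within_gap_bp))
            mk += 1
        chrom_cursor[chrom] = pos
        boundaries.append((chrom, start_idx, mk - 1))

    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "chrom", "pos", "allele_a", "allele_b"]
    ).set_index("marker_id")
    calls = np.column_stack(call_cols)
    calls = _inject_noise(calls, config, rng)
    gm = GenotypeMatrix(accessions, markers, calls)
    truth = SimulationTruth(
        ancestral_p=np.array([]), pop_p=np.empty((config.K_true, 0)), admixture=q,
        accession_ids=gm.accession_ids, marker_ids=gm.marker_ids,
        block_boundaries=boundaries,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# clustering replicates


def _target_q(q_true: np.ndarray, K: int, eps: float = 0.02) -> np.ndarray:
    """Expected memberships at an assumed K: merged columns below K_true,
    near-zero padding columns above."""
    n, k_true = q_true.shape
    if K == k_true:
        return q_true
    if K < k_true:
        parts = np.array_split(np.arange(k_true), K)
        return np.column_stack([q_true[:, p].sum(axis=1) for p in parts])
    extra = K - k_true
    pad = np.full((n, extra), eps)
    return np.column_stack([q_true * (1.0 - extra * eps), pad])


def simulate_structure_runs(
    truth: SimulationTruth,
    K_range: Sequence[int],
    replicates: int = 10,
    kappa: float = 50.0,
    lnp_params: Optional[LnPCurveParams] = None,
    seed: int = 0,
) -> tuple[list[QMatrix], list[RunLogProb]]:
    """Synthetic clustering replicates around the true admixture.

    At each assumed K every replicate's rows are drawn
    ``Dirichlet(kappa * target)`` around the merged/padded truth, and the
    replicate's columns are randomly permuted (exercising label alignment).
    lnP values follow a piecewise-linear mean curve peaked in slope at
    K_true with Gaussian replicate noise.
    """
    ks = sorted(set(int(k) for k in K_range))
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K_range must be contiguous, got {ks}")
    params = lnp_params or LnPCurveParams()
    rng = np.random.default_rng(seed)
    q_true = truth.admixture
    k_true = q_true.shape[1]
    n = q_true.shape[0]

    qs: list[QMatrix] = []
    lnps: list[RunLogProb] = []
    for K in ks:
        target = _target_q(q_true, K)
        mean_lnp = (
            params.base
            + params.pre_slope * min(K, k_true)
            + params.post_slope * max(0, K - k_true)
        )
        for r in range(replicates):
            run_id = f"K{K}_rep{r}"
            if K == 1:
                q = np.ones((n, 1))
            else:
                gamma = rng.gamma(np.maximum(kappa * target, 1e-3))
                q = gamma / gamma.sum(axis=1, keepdims=True)
                q = q[:, rng.permutation(K)]
            qs.append(QMatrix(run_id, K, list(truth.accession_ids), q))
            lnps.append(
                RunLogProb(run_id, K, mean_lnp + rng.normal(0.0, params.noise_sd))
            )
    return qs, lnps


# ---------------------------------------------------------------------------
# skyline fixtures


def simulate_skyline(
    epochs: Sequence[tuple[float, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    step_years: float = 5.0,
    band_factor: float = 2.0,
):
    """Piecewise-constant Ne trajectory with multiplicative log-normal noise.

    ``epochs`` is an ordered list of (start_year, end_year, ne). HPD bounds
    are the noisy median divided/multiplied by ``band_factor``, so the band
    always contains the median.
    """
    from .demography import SkylineTrajectory

    rng = np.random.default_rng(seed)
    times, ne = [], []
    for start, end, level in epochs:
        if end < start or level <= 0:
            raise ValueError(f"bad epoch ({start}, {end}, {level})")
        t = start
        while t <= end:
            if not times or t > times[-1]:
                times.append(float(t))
                ne.append(level)
            t += step_years
        if times[-1] < end:
            times.append(float(end))
            ne.append(level)
    ne = np.asarray(ne, dtype=float)
    if noise_sd > 0:
        ne = ne * np.exp(rng.normal(0.0, noise_sd, size=len(ne)))
    table = pd.DataFrame(
        {
            "time": times,
            "ne_median": ne,
            "hpd_low": ne / band_factor,
            "hpd_high": ne * band_factor,
        }
    )
    return SkylineTrajectory(table)
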