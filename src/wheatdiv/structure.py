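"""Post-processing of Bayesian-clustering replicates.

Consumes Q-matrices (per-individual membership proportions across K
clusters) and per-run log-probabilities from STRUCTURE-style programs, and
provides: parsing (native and CSV dialects), replicate label alignment
(CLUMPP-style, via optimal assignment), the Evanno delta-K statistic,
the Puechmaille group-based K estimators, hard membership assignment and
regional ancestry summaries. The MCMC itself is upstream and out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-3
UNASSIGNED = -1


@dataclass
class QMatrix:
    """One clustering replicate: individuals x K membership proportions."""

    run_id: str
    K: int
    individual_ids: list[str]
    q: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.individual_ids), self.K):
            raise ValueError(
                f"run {self.run_id}: Q shape {self.q.shape} != "
                f"({len(self.individual_ids)}, {self.K})"
            )
        if (self.q < -1e-12).any() or (self.q > 1 + 1e-9).any():
            raise ValueError(f"run {self.run_id}: memberships outside [0, 1]")
        sums = self.q.sum(axis=1)
        off = np.abs(sums - 1.0) > ROW_SUM_TOL
        if off.any():
            logger.warning(
                "run %s: %d membership rows off unit sum by > %g; renormalized",
                self.run_id, int(off.sum()), ROW_SUM_TOL,
            )
        self.q = self.q / sums[:, None]

    def permuted(self, perm) -> "QMatrix":
        return QMatrix(self.run_id, self.K, self.individual_ids, self.q[:, list(perm)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.q, index=self.individual_ids,
            columns=[f"q_{k + 1}" for k in range(self.K)],
        )


@dataclass(frozen=True)
class RunLogProb:
    run_id: str
    K: int
    lnP: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lnP):
            raise ValueError(f"run {self.run_id}: lnP must be finite")


# ---------------------------------------------------------------------------
# parsing

_LNP_NATIVE = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?[\d.eE+]+)")
_LNP_CSV = re.compile(r"#\s*lnP\s*=\s*(-?[\d.eE+]+)")


def parse_structure_run(path, run_id: Optional[str] = None) -> tuple[QMatrix, RunLogProb]:
    """Parse one clustering run from either the native output dialect
    (inferred-ancestry block + estimated-log-probability line) or the plain
    CSV dialect (``# lnP=`` header, then ``individual_id,group,q_1..q_K``).
    """
    run_id = run_id or str(path)
    with open(path) as fh:
        text = fh.read()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.lstrip().startswith("#") and "lnP" in first:
        return _parse_csv_dialect(text, path, run_id)
    return _parse_native_dialect(text, path, run_id)


def _parse_csv_dialect(text: str, path, run_id: str) -> tuple[QMatrix, RunLogProb]:
    m = _LNP_CSV.search(text)
    if m is None:
        raise ValueError(f"{path}: missing '# lnP=' header")
    lnp = float(m.group(1))
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    header = [c.strip() for c in lines[0].split(",")]
    qcols = [c for c in header if c.startswith("q_")]
    if not qcols or header[0] != "individual_id":
        raise ValueError(f"{path}: bad CSV dialect header {header}")
    ids, rows = [], []
    for ln in lines[1:]:
        parts = [c.strip() for c in ln.split(",")]
        ids.append(parts[0])
        rows.append([float(x) for x in parts[len(header) - len(qcols):]])
    K = len(qcols)
    if any(len(r) != K for r in rows):
        raise ValueError(f"{path}: inconsistent K across rows")
    return QMatrix(run_id, K, ids, np.array(rows)), RunLogProb(run_id, K, lnp)


def _parse_native_dialect(text: str, path, run_id: str) -> tuple[QMatrix, RunLogProb]:
    m = _LNP_NATIVE.search(text)
    if m is None:
        raise ValueError(f"{path}: missing 'Estimated Ln Prob of Data' line")
    lnp = float(m.group(1))
    lines = text.splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if "Inferred ancestry of individuals" in ln
        )
    except StopIteration:
        raise ValueError(f"{path}: missing inferred-ancestry block") from None
    ids, rows = [], []
    for ln in lines[start + 1:]:
        stripped = ln.strip()
        if not stripped:
            if rows:
                break
            continue
        if stripped.lower().startswith("label"):
            continue
        if ":" not in stripped:
            break
        left, right = stripped.split(":", 1)
        fields = left.split()
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed ancestry row {stripped!r}")
        ids.append(fields[1])
        rows.append([float(x) for x in right.split()])
    if not rows:
        raise ValueError(f"{path}: empty inferred-ancestry block")
    K = len(rows[0])
    if any(len(r) != K for r in rows):
        raise ValueError(f"{path}: inconsistent K across ancestry rows")
    return QMatrix(run_id, K, ids, np.array(rows)), RunLogProb(run_id, K, lnp)


def write_q_csv(q: QMatrix, lnp: RunLogProb, path, groups: Optional[dict] = None) -> None:
    """Write the plain CSV dialect (consumable by parse_structure_run)."""
    from .io import atomic_write_text

    lines = [f"# lnP={lnp.lnP}"]
    lines.append("individual_id,group," + ",".join(f"q_{k + 1}" for k in range(q.K)))
    for i, ind in enumerate(q.individual_ids):
        grp = "" if groups is None else str(groups.get(ind, ""))
        lines.append(f"{ind},{grp}," + ",".join(f"{v:.6f}" for v in q.q[i]))
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno(runs: list[RunLogProb], per_replicate: bool = True) -> pd.DataFrame:
    """K-selection table: mean/sd of lnP per K, first and second differences,
    and deltaK = mean |L''(K)| / sd(L(K)).

    With ``per_replicate`` (default, as in the common harvester
    implementations) the differences are taken per replicate index, which
    requires equal replicate counts at every K in a contiguous range; the
    alternative computes differences on the mean curve. deltaK is NaN at the
    endpoints of the K range and wherever sd = 0.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.lnP)
    ks = sorted(by_k)
    if len(ks) < 3:
        raise ValueError("evanno needs at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K range is not contiguous: {ks}")
    counts = {len(v) for v in by_k.values()}
    if per_replicate and len(counts) != 1:
        raise ValueError(f"unequal replicate counts per K: { {k: len(v) for k, v in by_k.items()} }")
    R = len(by_k[ks[0]])
    if R < 2:
        raise ValueError("evanno needs >= 2 replicates per K")
    L = np.array([sorted(by_k[k]) for k in ks])  # K x R, replicate-index pairing

    mean = L.mean(axis=1)
    sd = L.std(axis=1, ddof=1)
    n_k = len(ks)
    L1 = np.full(n_k, np.nan)
    L2 = np.full(n_k, np.nan)
    deltaK = np.full(n_k, np.nan)
    for i in range(n_k):
        if per_replicate:
            if i >= 1:
                L1[i] = float(np.mean(L[i] - L[i - 1]))
            if 1 <= i <= n_k - 2:
                l2_r = L[i + 1] - 2 * L[i] + L[i - 1]
                L2[i] = float(np.mean(l2_r))
                if sd[i] > 0:
                    deltaK[i] = float(np.mean(np.abs(l2_r)) / sd[i])
        else:
            if i >= 1:
                L1[i] = mean[i] - mean[i - 1]
            if 1 <= i <= n_k - 2:
                L2[i] = mean[i + 1] - 2 * mean[i] + mean[i - 1]
                if sd[i] > 0:
                    deltaK[i] = abs(L2[i]) / sd[i]
    return pd.DataFrame(
        {"mean_lnP": mean, "sd_lnP": sd, "L1": L1, "L2": L2, "deltaK": deltaK},
        index=pd.Index(ks, name="K"),
    )


def best_k_evanno(table: pd.DataFrame) -> int:
    """argmax of deltaK over the Ks where it is defined."""
    d = table["deltaK"].dropna()
    if d.empty:
        raise ValueError("deltaK undefined everywhere")
    return int(d.idxmax())


# ---------------------------------------------------------------------------
# replicate alignment


def align_runs(qs: list[QMatrix], reference: Optional[str] = None
               ) -> tuple[list[QMatrix], dict[str, tuple[int, ...]]]:
    """Align cluster labels across replicates to a reference run.

    For each run the column permutation minimizing the summed squared
    difference to the reference Q is found by optimal assignment on the
    K x K column-cost matrix. Returns the aligned runs (reference included,
    identity-permuted) and the permutation applied to each.
    """
    if not qs:
        return [], {}
    ks = {q.K for q in qs}
    if len(ks) != 1:
        raise ValueError(f"align_runs requires equal K, got {sorted(ks)}")
    ids0 = qs[0].individual_ids
    if any(q.individual_ids != ids0 for q in qs):
        raise ValueError("align_runs requires identical individual ordering")
    ref = qs[0] if reference is None else next(q for q in qs if q.run_id == reference)

    aligned, perms = [], {}
    for q in qs:
        # cost[c_ref, c_run] = sum_i (qref[i, c_ref] - q[i, c_run])^2
        cost = ((ref.q[:, :, None] - q.q[:, None, :]) ** 2).sum(axis=0)
        _, cols = linear_sum_assignment(cost)
        perm = tuple(int(c) for c in cols)
        aligned.append(q.permuted(perm))
        perms[q.run_id] = perm
    return aligned, perms


def mean_q(aligned: list[QMatrix], run_id: str = "mean") -> QMatrix:
    """Element-wise mean of aligned replicates."""
    stack = np.stack([q.q for q in aligned])
    return QMatrix(run_id, aligned[0].K, aligned[0].individual_ids, stack.mean(axis=0))


# ---------------------------------------------------------------------------
# Puechmaille estimators


@dataclass
class PuechmailleResult:
    """Group-based K estimators robust to uneven sampling.

    Per run, a cluster is *genuine* under the mean (median) criterion when
    at least one predefined sampling group has mean (median) membership
    >= threshold in it. ``per_k`` tabulates the per-run genuine-cluster
    counts aggregated per K; the four scalar estimators are read at K_max.
    """

    threshold: float
    per_k: pd.DataFrame  # index K; MedMeaK, MaxMeaK, MedMedK, MaxMedK
    med_mea_k: int
    max_mea_k: int
    med_med_k: int
    max_med_k: int


def _genuine_counts(q: QMatrix, group_of: dict, threshold: float) -> tuple[int, int]:
    """(mean-criterion, median-criterion) genuine-cluster counts for a run."""
    labels = []
    for ind in q.individual_ids:
        if ind not in group_of:
            raise ValueError(f"individual {ind!r} has no group label")
        labels.append(group_of[ind])
    labels = np.asarray(labels)
    n_mean = n_median = 0
    group_names = np.unique(labels)
    members = {g: labels == g for g in group_names}
    for k in range(q.K):
        col = q.q[:, k]
        means = [col[members[g]].mean() for g in group_names]
        medians = [np.median(col[members[g]]) for g in group_names]
        if max(means) >= threshold:
            n_mean += 1
        if max(medians) >= threshold:
            n_median += 1
    return n_mean, n_median


def puechmaille(qs: list[QMatrix], group_labels: dict, threshold: float = 0.5
                ) -> PuechmailleResult:
    """MedMeaK / MaxMeaK / MedMedK / MaxMedK from replicate Q-matrices.

    ``group_labels`` maps individual id -> sampling group (e.g. country or
    region). Estimators are label-permutation invariant by construction.
    Medians over runs are floored to stay integer cluster counts.
    """
    if not qs:
        raise ValueError("no runs given")
    rows = {}
    for q in qs:
        n_mean, n_median = _genuine_counts(q, group_labels, threshold)
        rows.setdefault(q.K, {"mean": [], "median": []})
        rows[q.K]["mean"].append(n_mean)
        rows[q.K]["median"].append(n_median)
    per_k = pd.DataFrame(
        {
            "MedMeaK": {k: int(np.floor(np.median(v["mean"]))) for k, v in rows.items()},
            "MaxMeaK": {k: int(max(v["mean"])) for k, v in rows.items()},
            "MedMedK": {k: int(np.floor(np.median(v["median"]))) for k, v in rows.items()},
            "MaxMedK": {k: int(max(v["median"])) for k, v in rows.items()},
        }
    ).sort_index()
    per_k.index.name = "K"
    at_max = per_k.loc[per_k.index.max()]
    return PuechmailleResult(
        threshold=threshold,
        per_k=per_k,
        med_mea_k=int(at_max["MedMeaK"]),
        max_mea_k=int(at_max["MaxMeaK"]),
        med_med_k=int(at_max["MedMedK"]),
        max_med_k=int(at_max["MaxMedK"]),
    )


# ---------------------------------------------------------------------------
# membership and regional summaries


def assign_membership(q: QMatrix, threshold: float = 0.5) -> pd.Series:
    """Hard assignment: the unique cluster with membership strictly above
    ``threshold`` (0-based index), else UNASSIGNED (-1). A threshold >= 0.5
    guarantees uniqueness."""
    best = q.q.argmax(axis=1)
    assigned = np.where(q.q[np.arange(len(best)), best] > threshold, best, UNASSIGNED)
    return pd.Series(assigned, index=q.individual_ids, name="cluster")


def regional_summary(q: QMatrix, metadata: pd.DataFrame,
                     chrono_class: Optional[str] = None) -> pd.DataFrame:
    """Region x cluster mean membership proportions.

    Optionally restricted to one chrono class (landrace / modern). Regions
    emptied by the filter are omitted with a warning.
    """
    meta = metadata.loc[[i for i in q.individual_ids if i in metadata.index]]
    missing = set(q.individual_ids) - set(meta.index)
    if missing:
        raise ValueError(f"individuals without metadata: {sorted(missing)[:5]}")
    frame = q.to_frame()
    frame["region"] = metadata.loc[q.individual_ids, "region"].values
    if chrono_class is not None:
        keep = metadata.loc[q.individual_ids, "chrono_class"].values == chrono_class
        dropped = set(frame["region"]) - set(frame["region"][keep])
        if dropped:
            logger.warning("regional_summary: regions emptied by filter: %s", sorted(dropped))
        frame = frame[keep]
    return frame.groupby("region").mean()
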