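"""Population-level analysis: size-binned estimates and group comparison.

Per animal, the nucleator-measured cells are distributed over half-open
cell-body size bins (default 50 µm³ wide, origin 0) and the total estimate
N̂ is apportioned proportionally, so the per-bin numbers sum to N̂ exactly.
Groups are compared — for the totals and for every bin — with the pooled
-variance two-sample Student's t-test; percent decline is reported relative
to the reference (first) group.  An optional Benjamini–Hochberg correction
across bins is available but off by default, matching the convention of
reporting raw per-bin significance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "BinSpec",
    "PopulationEstimate",
    "GroupComparison",
    "bin_population",
    "compare_groups",
    "percent_decline",
    "pooled_t",
]


@dataclass(frozen=True)
class BinSpec:
    """Half-open cell-body size bins ``[origin + k·w, origin + (k+1)·w)``."""

    bin_width: float = 50.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        if self.origin < 0:
            raise ConfigurationError("bin origin must be >= 0")

    def index(self, volumes: np.ndarray) -> np.ndarray:
        v = np.asarray(volumes, dtype=float)
        if np.any(v < self.origin):
            raise AnalysisError("volume below the bin origin")
        return np.floor((v - self.origin) / self.bin_width).astype(int)

    def left(self, k: int | np.ndarray) -> float | np.ndarray:
        return self.origin + np.asarray(k) * self.bin_width


@dataclass
class PopulationEstimate:
    """Per-animal total and per-size-bin estimated neuron numbers.

    ``per_bin`` is a Series indexed by the bin's left edge (µm³); bins with
    zero measured cells inside the observed range carry 0, not NaN.
    """

    animal_id: str
    N_hat: float
    per_bin: pd.Series
    n_measured: int


def bin_population(
    volumes: Sequence[float] | np.ndarray,
    N_hat: float,
    spec: BinSpec = BinSpec(),
    animal_id: str = "",
) -> PopulationEstimate:
    """Apportion N̂ over size bins in proportion to the measured cells."""
    v = np.asarray(volumes, dtype=float)
    m = v.size
    if m == 0:
        if N_hat > 0:
            raise AnalysisError("cannot bin a positive estimate with no measured cells")
        return PopulationEstimate(animal_id, 0.0, pd.Series(dtype=float), 0)
    idx = spec.index(v)
    counts = np.bincount(idx)
    lefts = spec.left(np.arange(counts.size))
    per_bin = pd.Series(N_hat * counts / m, index=np.asarray(lefts, dtype=float))
    return PopulationEstimate(animal_id, float(N_hat), per_bin, int(m))


def percent_decline(mean_ref: float, mean_other: float) -> float:
    """Decline of ``mean_other`` relative to ``mean_ref``, in percent."""
    if mean_ref == 0:
        raise AnalysisError("reference mean is zero")
    return 100.0 * (mean_ref - mean_other) / mean_ref


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test (two-sided).

    Degenerate zero-variance inputs are resolved explicitly: equal means give
    (t=0, p=1); unequal means with zero pooled variance give (±inf, p=0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs at least 2 animals")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        diff = float(np.mean(a) - np.mean(b))
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    with warnings.catch_warnings():
        # near-constant bins trigger a harmless precision warning in scipy
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


@dataclass
class GroupComparison:
    """Totals and per-bin group statistics for reference vs comparison group."""

    n_ref: int
    n_cmp: int
    mean_ref: float
    mean_cmp: float
    sem_ref: float
    sem_cmp: float
    percent_decline: float
    t_statistic: float
    p_value: float
    per_bin: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per bin plus a totals row (bin label 'total')."""
        totals = pd.DataFrame(
            [
                {
                    "bin": "total",
                    "bin_left_um3": np.nan,
                    "mean_ref": self.mean_ref,
                    "sem_ref": self.sem_ref,
                    "mean_cmp": self.mean_cmp,
                    "sem_cmp": self.sem_cmp,
                    "percent_decline": self.percent_decline,
                    "t": self.t_statistic,
                    "p": self.p_value,
                }
            ]
        )
        if self.per_bin.empty:
            return totals
        bins = self.per_bin.copy()
        bins.insert(0, "bin", bins["bin_left_um3"].map(lambda x: f"[{x:g},)"))
        return pd.concat([bins, totals], ignore_index=True)


def _bin_matrix(group: Sequence[PopulationEstimate], index: pd.Index) -> np.ndarray:
    rows = [pe.per_bin.reindex(index, fill_value=0.0).to_numpy() for pe in group]
    return np.vstack(rows)


def compare_groups(
    group_ref: Sequence[PopulationEstimate],
    group_cmp: Sequence[PopulationEstimate],
    bh_correction: bool = False,
) -> GroupComparison:
    """Compare two groups of per-animal estimates (totals and every bin).

    ``group_ref`` is the reference (e.g. wild-type); decline is reported as
    ``100·(mean_ref − mean_cmp)/mean_ref``.
    """
    if len(group_ref) < 2 or len(group_cmp) < 2:
        raise AnalysisError("each group needs at least 2 animals")
    tot_ref = np.array([pe.N_hat for pe in group_ref])
    tot_cmp = np.array([pe.N_hat for pe in group_cmp])
    t, p = pooled_t(tot_ref, tot_cmp)

    all_bins = pd.Index(
        sorted(set().union(*[pe.per_bin.index for pe in (*group_ref, *group_cmp)]))
    )
    per_bin = pd.DataFrame()
    if len(all_bins):
        mat_ref = _bin_matrix(group_ref, all_bins)
        mat_cmp = _bin_matrix(group_cmp, all_bins)
        rows = []
        for j, left in enumerate(all_bins):
            tb, pb = pooled_t(mat_ref[:, j], mat_cmp[:, j])
            mr, mc = float(mat_ref[:, j].mean()), float(mat_cmp[:, j].mean())
            rows.append(
                {
                    "bin_left_um3": float(left),
                    "mean_ref": mr,
                    "sem_ref": _sem(mat_ref[:, j]),
                    "mean_cmp": mc,
                    "sem_cmp": _sem(mat_cmp[:, j]),
                    "percent_decline": percent_decline(mr, mc) if mr != 0 else np.nan,
                    "t": tb,
                    "p": pb,
                }
            )
        per_bin = pd.DataFrame(rows)
        if bh_correction:
            valid = per_bin["p"].notna() & np.isfinite(per_bin["p"])
            q = np.full(len(per_bin), np.nan)
            if valid.any():
                q[valid.to_numpy()] = multipletests(
                    per_bin.loc[valid, "p"], method="fdr_bh"
                )[1]
            per_bin["q"] = q

    return GroupComparison(
        n_ref=len(group_ref),
        n_cmp=len(group_cmp),
        mean_ref=float(tot_ref.mean()),
        mean_cmp=float(tot_cmp.mean()),
        sem_ref=_sem(tot_ref),
        sem_cmp=_sem(tot_cmp),
        percent_decline=percent_decline(float(tot_ref.mean()), float(tot_cmp.mean())),
        t_statistic=t,
        p_value=p,
        per_bin=per_bin,
    )
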