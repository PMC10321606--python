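"""Cluster-based permutation testing of two time-locked condition traces.

Per timepoint, a paired t-test compares the two conditions across
participants; suprathreshold timepoints are grouped into contiguous
same-sign clusters whose mass is the sum of member t values.  A null
distribution of the maximum absolute cluster mass is built by sign-flipping
each participant's condition-difference trace (equivalent to swapping the
condition labels within participant), either over random Monte-Carlo draws
or exhaustively over all 2^P patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TSeries",
    "Cluster",
    "PermutationSpec",
    "ClusterResult",
    "paired_t_series",
    "form_clusters",
    "permutation_null",
    "cluster_test",
]

_TIE_EPS = 1e-12  # ties between null max and observed mass count as >=


class ExhaustiveTooLargeError(ValueError):
    """Raised when 2^P exceeds the configured exhaustive-enumeration cap."""


@dataclass
class TSeries:
    """Per-timepoint paired t statistics with df = participants - 1.

    ``degenerate`` flags zero-variance timepoints: t is +/-inf when the mean
    difference is nonzero and 0 (by convention, logged) when it is 0/0.
    """

    grid_times: np.ndarray
    t_values: np.ndarray
    df: int
    degenerate: np.ndarray = None

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.t_values), dtype=bool)


@dataclass
class Cluster:
    start_time: float
    end_time: float
    sign: int  # +1 or -1
    mass: float  # sum of member t values; sign(mass) == sign
    start_index: int
    end_index: int  # inclusive
    p_value: float | None = None
    significant: bool | None = None

    @property
    def n_timepoints(self) -> int:
        return self.end_index - self.start_index + 1

    def to_dict(self) -> dict:
        return {
            "start_s": float(self.start_time),
            "end_s": float(self.end_time),
            "sign": "+" if self.sign > 0 else "-",
            "mass": float(self.mass),
            "n_timepoints": self.n_timepoints,
            "p": None if self.p_value is None else float(self.p_value),
            "significant": self.significant,
        }


@dataclass
class PermutationSpec:
    n_permutations: int = 1000
    mode: Literal["monte_carlo", "exhaustive"] = "monte_carlo"
    alpha_cluster: float = 0.05
    alpha_final: float = 0.017  # .05 / 3 lockings
    seed: int = 0
    exhaustive_cap: int = 1 << 16

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for name, a in [("alpha_cluster", self.alpha_cluster),
                        ("alpha_final", self.alpha_final)]:
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _t_from_differences(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise one-sample t on a P x T difference matrix."""
    p = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(p))
    t = np.where(degenerate & (mean > 0), np.inf, t)
    t = np.where(degenerate & (mean < 0), -np.inf, t)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    return t, degenerate


def paired_t_series(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    grid_times: np.ndarray | None = None,
) -> TSeries:
    """Paired t statistic (a minus b) per timepoint across participants."""
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"matrix shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need P x T matrices with P >= 2")
    t, degenerate = _t_from_differences(a - b)
    if degenerate.any():
        logger.info("%d zero-variance timepoints in paired t series",
                    int(degenerate.sum()))
    if grid_times is None:
        grid_times = np.arange(a.shape[1], dtype=float)
    return TSeries(grid_times=np.asarray(grid_times, dtype=float),
                   t_values=t, df=a.shape[0] - 1, degenerate=degenerate)


def _scan_clusters(
    t: np.ndarray, crit: float, grid_times: np.ndarray
) -> list[Cluster]:
    """Maximal runs of contiguous suprathreshold same-sign timepoints."""
    above = np.abs(t) > crit
    # label: 0 below threshold, +/-1 above, runs split on sign change
    lab = np.where(above, np.sign(t).astype(np.int8), np.int8(0))
    boundaries = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(t)]))
    clusters = []
    for sta, sto in zip(starts, stops):
        sign = lab[sta]
        if sign == 0:
            continue
        mass = float(np.sum(t[sta:sto]))
        clusters.append(
            Cluster(
                start_time=float(grid_times[sta]),
                end_time=float(grid_times[sto - 1]),
                sign=int(sign),
                mass=mass,
                start_index=int(sta),
                end_index=int(sto - 1),
            )
        )
    return clusters


def critical_t(alpha_cluster: float, df: int) -> float:
    """Two-sided per-timepoint threshold on |t|."""
    return float(stats.t.ppf(1.0 - alpha_cluster / 2.0, df))


def form_clusters(tseries: TSeries, alpha_cluster: float = 0.05) -> list[Cluster]:
    """Threshold a t series two-sidedly and group runs into clusters."""
    crit = critical_t(alpha_cluster, tseries.df)
    return _scan_clusters(tseries.t_values, crit, tseries.grid_times)


def _max_cluster_masses(t_rows: np.ndarray, crit: float) -> np.ndarray:
    """max over clusters of |mass| per row; 0 when a row has no cluster."""
    out = np.empty(len(t_rows))
    dummy_times = np.arange(t_rows.shape[1], dtype=float)
    for i, t in enumerate(t_rows):
        clusters = _scan_clusters(t, crit, dummy_times)
        out[i] = max((abs(c.mass) for c in clusters), default=0.0)
    return out


def _sign_matrix_exhaustive(p: int) -> np.ndarray:
    codes = np.arange(1 << p, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(p)) & 1
    return bits.astype(np.int8) * 2 - 1


def permutation_null(
    differences: np.ndarray, spec: PermutationSpec
) -> np.ndarray:
    """Null distribution of the maximum |cluster mass| under sign flips.

    Each flip pattern negates a subset of participants' difference traces,
    the t series and clusters are recomputed, and the largest |mass| (0 if
    no cluster forms) enters the distribution.  The column-wise second
    moment is flip-invariant, so only the flipped means need recomputing.
    """
    diff = np.asarray(differences, dtype=float)
    if diff.ndim != 2 or diff.shape[0] < 2:
        raise ValueError("need a P x T difference matrix with P >= 2")
    p, n_t = diff.shape
    if spec.mode == "exhaustive":
        if (1 << p) > spec.exhaustive_cap:
            raise ExhaustiveTooLargeError(
                f"2^{p} exceeds cap {spec.exhaustive_cap}; use monte_carlo"
            )
        signs = _sign_matrix_exhaustive(p)
    else:
        rng = np.random.default_rng(spec.seed)
        signs = rng.integers(0, 2, size=(spec.n_permutations, p),
                             dtype=np.int8) * 2 - 1

    crit = critical_t(spec.alpha_cluster, p - 1)
    sumsq = np.einsum("pt,pt->t", diff, diff)
    null = np.empty(len(signs))
    chunk = 2048
    for i0 in range(0, len(signs), chunk):
        s = signs[i0 : i0 + chunk].astype(float)
        mean = s @ diff / p
        var = (sumsq[None, :] - p * mean**2) / (p - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / p)
        t = np.where(var == 0.0,
                     np.where(mean > 0, np.inf,
                              np.where(mean < 0, -np.inf, 0.0)),
                     t)
        null[i0 : i0 + len(s)] = _max_cluster_masses(t, crit)
    return null


@dataclass
class ClusterResult:
    """Observed clusters, their permutation p values, and the null summary."""

    grid_times: np.ndarray
    tseries: TSeries
    clusters: list
    null_max_mass: np.ndarray
    spec: PermutationSpec
    lock: str | None = None

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]

    def to_dict(self) -> dict:
        null = self.null_max_mass
        return {
            "lock": self.lock,
            "n_permutations": len(null),
            "mode": self.spec.mode,
            "seed": self.spec.seed,
            "alpha_cluster": self.spec.alpha_cluster,
            "alpha_final": self.spec.alpha_final,
            "df": self.tseries.df,
            "clusters": [c.to_dict() for c in self.clusters],
            "null_max_mass": {
                "mean": float(np.mean(null)),
                "q50": float(np.quantile(null, 0.5)),
                "q95": float(np.quantile(null, 0.95)),
                "q99": float(np.quantile(null, 0.99)),
                "max": float(np.max(null)),
            },
        }


def cluster_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    grid_times: np.ndarray | None = None,
    spec: PermutationSpec | None = None,
    lock: str | None = None,
) -> ClusterResult:
    """Full cluster-based permutation test of condition a vs condition b.

    Cluster p values use the add-one estimator
    ``(1 + #{null >= |mass|}) / (1 + n)`` in Monte-Carlo mode (never exactly
    zero); exhaustive mode uses the exact proportion over all 2^P patterns,
    which includes the identity flip and is therefore also positive.
    Significance is judged against ``spec.alpha_final``.
    """
    spec = spec or PermutationSpec()
    tseries = paired_t_series(matrix_a, matrix_b, grid_times)
    clusters = form_clusters(tseries, spec.alpha_cluster)
    null = permutation_null(np.asarray(matrix_a, float) - np.asarray(matrix_b, float),
                            spec)
    for c in clusters:
        exceed = int(np.sum(null >= abs(c.mass) - _TIE_EPS))
        if spec.mode == "exhaustive":
            c.p_value = exceed / len(null)
        else:
            c.p_value = (1 + exceed) / (1 + len(null))
        c.significant = bool(c.p_value < spec.alpha_final)
    return ClusterResult(
        grid_times=tseries.grid_times,
        tseries=tseries,
        clusters=clusters,
        null_max_mass=null,
        spec=spec,
        lock=lock,
    )
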