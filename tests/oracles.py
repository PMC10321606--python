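"""Independent reference implementations used to validate the package.

Everything here is deliberately written the slow, obvious way (explicit
loops, itertools enumeration) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def loop_frame_delta(frame_a, frame_b) -> float:
    """Double-loop Euclidean pixel distance."""
    total = 0.0
    h = len(frame_a)
    w = len(frame_a[0])
    for r in range(h):
        for c in range(w):
            d = float(frame_a[r][c]) - float(frame_b[r][c])
            total += d * d
    return math.sqrt(total)


def loop_delta_trace(frames) -> list[float]:
    """Frame-pair loop over a stack."""
    return [loop_frame_delta(frames[k], frames[k + 1]) for k in range(len(frames) - 1)]


def scan_runs(t_values, crit) -> list[dict]:
    """Exhaustive scan for suprathreshold same-sign runs.

    Walks every index, opening a run when |t| crosses the threshold and
    closing it on sub-threshold values or sign changes.
    """
    clusters = []
    current = None
    for i, t in enumerate(t_values):
        sign = 1 if t > 0 else (-1 if t < 0 else 0)
        above = abs(t) > crit
        if above and current is not None and sign == current["sign"]:
            current["end"] = i
            current["mass"] += t
        else:
            if current is not None:
                clusters.append(current)
                current = None
            if above:
                current = {"start": i, "end": i, "sign": sign, "mass": t}
    if current is not None:
        clusters.append(current)
    return clusters


def paired_t_columns(mat_a, mat_b) -> np.ndarray:
    """Column-wise paired t via scipy, with the 0/0 -> 0 convention."""
    out = []
    for col in range(mat_a.shape[1]):
        a, b = mat_a[:, col], mat_b[:, col]
        d = a - b
        if np.std(d, ddof=1) == 0:
            m = d.mean()
            out.append(0.0 if m == 0 else math.copysign(math.inf, m))
        else:
            out.append(stats.ttest_rel(a, b).statistic)
    return np.asarray(out)


def brute_force_cluster_test(mat_a, mat_b, alpha_cluster=0.05, alpha_final=0.017):
    """Monolithic re-implementation of the whole cluster permutation test.

    Exhaustively enumerates all 2^P sign-flip patterns with itertools; only
    feasible for small P.  Returns clusters as dicts with start/end indices,
    sign, mass, and p.
    """
    p_n = mat_a.shape[0]
    crit = stats.t.ppf(1 - alpha_cluster / 2, p_n - 1)
    diff = np.asarray(mat_a, float) - np.asarray(mat_b, float)

    observed = scan_runs(paired_t_columns(mat_a, mat_b), crit)

    null = []
    for signs in itertools.product((1.0, -1.0), repeat=p_n):
        flipped = np.asarray(signs)[:, None] * diff
        zeros = np.zeros_like(flipped)
        t_vals = paired_t_columns(flipped, zeros)
        runs = scan_runs(t_vals, crit)
        null.append(max((abs(r["mass"]) for r in runs), default=0.0))
    null = np.asarray(null)

    for c in observed:
        c["p"] = float(np.mean(null >= abs(c["mass"]) - 1e-12))
        c["significant"] = c["p"] < alpha_final
    return observed, null
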