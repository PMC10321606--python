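"""Behavioral response-time analysis: condition summaries and a linear
mixed-effects model with crossed random intercepts for participant and item.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .synthetic_data import CONDITIONS, EARLY, LATE

__all__ = ["RTModelResult", "summarize_rt", "fit_rt_model", "response_times_ms"]

#: histogram bin width (ms) used to estimate the RT mode
MODE_BIN_MS = 50.0


class ModelFitError(RuntimeError):
    """Raised when the mixed model cannot be fitted."""


def response_times_ms(events: pd.DataFrame) -> pd.Series:
    """RT in milliseconds: response onset minus question offset."""
    return 1000.0 * (events["response_onset"] - events["question_offset"])


def summarize_rt(events: pd.DataFrame) -> dict:
    """Per-condition RT mean/median/sd and the midpoint of the densest
    50-ms histogram bin (a crude mode estimate)."""
    rt = response_times_ms(events)
    out = {}
    for cond in CONDITIONS:
        vals = rt[events["condition"] == cond].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no trials in condition {cond!r}")
        lo = np.floor(vals.min() / MODE_BIN_MS) * MODE_BIN_MS
        hi = np.ceil(max(vals.max(), lo + MODE_BIN_MS) / MODE_BIN_MS) * MODE_BIN_MS
        edges = np.arange(lo, hi + MODE_BIN_MS, MODE_BIN_MS)
        counts, _ = np.histogram(vals, bins=edges)
        dens = int(np.argmax(counts))
        out[cond] = {
            "n": int(len(vals)),
            "mean_ms": float(np.mean(vals)),
            "median_ms": float(np.median(vals)),
            "sd_ms": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "mode_bin_ms": float(edges[dens] + MODE_BIN_MS / 2.0),
        }
    return out


@dataclass
class RTModelResult:
    """Cell-means view of the condition effect on RT (all in ms / ms^2)."""

    beta_ep: float
    beta_lp: float
    condition_effect: float  # beta_lp - beta_ep
    effect_se: float
    t_statistic: float
    variance_participant: float
    variance_item: float
    variance_residual: float
    significant: bool  # |t| > 2
    converged: bool
    singular: bool

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()}


def _degenerate_fit(df: pd.DataFrame) -> RTModelResult:
    means = df.groupby("condition")["rt_ms"].mean()
    effect = float(means[LATE] - means[EARLY])
    return RTModelResult(
        beta_ep=float(means[EARLY]),
        beta_lp=float(means[LATE]),
        condition_effect=effect,
        effect_se=0.0,
        t_statistic=np.inf if effect > 0 else (-np.inf if effect < 0 else 0.0),
        variance_participant=0.0,
        variance_item=0.0,
        variance_residual=0.0,
        significant=effect != 0.0,
        converged=True,
        singular=True,
    )


def fit_rt_model(events: pd.DataFrame) -> RTModelResult:
    """REML fit of RT ~ condition + (1 | participant) + (1 | item).

    The two random intercepts are crossed (every participant sees many
    items), so they are expressed as variance components within a single
    trivial group.  Returns cell means per condition, the condition effect
    with its t statistic (|t| > 2 flagged as significant), and the three
    variance components.
    """
    required = {"participant_id", "item_id", "condition",
                "response_onset", "question_offset"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table lacks columns {sorted(missing)}")
    df = events.copy()
    df["rt_ms"] = response_times_ms(df)
    if df["participant_id"].nunique() < 2 or df["item_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 items")
    if set(df["condition"].unique()) != set(CONDITIONS):
        raise ValueError("both conditions must be present")

    # zero within-condition variance: cell means are exact, t diverges
    resid_var = df.groupby("condition")["rt_ms"].var(ddof=0).max()
    if not np.isfinite(resid_var) or resid_var < 1e-10:
        warnings.warn("degenerate RT table (no residual variance); "
                      "returning exact cell means with infinite t", stacklevel=2)
        return _degenerate_fit(df)

    model = smf.mixedlm(
        "rt_ms ~ C(condition, Treatment('early_planning'))",
        df,
        groups=np.ones(len(df)),
        vc_formula={"participant": "0 + C(participant_id)",
                    "item": "0 + C(item_id)"},
    )
    fit = None
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                candidate = model.fit(reml=True, method=method)
            except Exception as exc:  # pragma: no cover - backend specific
                errors.append(f"{method}: {exc}")
                continue
            if candidate.converged:
                fit = candidate
                break
            errors.append(f"{method}: did not converge "
                          f"(params={np.asarray(candidate.params).round(3).tolist()})")
    if fit is None:
        raise ModelFitError("mixed-model fit failed: " + "; ".join(errors))

    params = fit.params
    intercept = float(params["Intercept"])
    effect_name = [n for n in params.index if "condition" in n][0]
    effect = float(params[effect_name])
    se = float(fit.bse[effect_name])
    tval = effect / se if se > 0 else np.inf * np.sign(effect)

    vc = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
    var_participant = vc.get("participant", 0.0)
    var_item = vc.get("item", 0.0)
    singular = min(var_participant, var_item) <= 1e-8
    if singular:
        warnings.warn("singular fit: a random-intercept variance is ~0",
                      stacklevel=2)
    return RTModelResult(
        beta_ep=intercept,
        beta_lp=intercept + effect,
        condition_effect=effect,
        effect_se=se,
        t_statistic=float(tval),
        variance_participant=float(var_participant),
        variance_item=float(var_item),
        variance_residual=float(fit.scale),
        significant=bool(abs(tval) > 2.0),
        converged=bool(fit.converged),
        singular=bool(singular),
    )
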