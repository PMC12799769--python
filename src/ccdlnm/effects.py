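"""Effect estimation: lag-specific and cumulative odds ratios, surfaces,
subgroup comparisons, and the sensitivity grid.

All effects are contrasts of the fitted exposure-lag-response surface
against a reference exposure value (by default the 99th percentile of the
trimmed exposure distribution; the 1st percentile is the "extreme low"
contrast).  For a contrast vector ``c`` in coefficient space the point
estimate is ``c . beta`` and the delta-method standard error is
``sqrt(c' Sigma c)``; 95% confidence intervals use the 1.96 normal quantile
on the log scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .basis import CrossBasisMatrix
from .clogit import FitResult

__all__ = [
    "EffectEstimate", "lag_specific_or", "cumulative_or", "effect_surface",
    "subgroup_ztest", "SensitivityVariant", "run_sensitivity_suite",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class EffectEstimate:
    log_or: float
    se: float
    label: str
    exposure_name: str = ""
    contrast: str = ""
    extrapolated: bool = False

    @property
    def or_(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_or - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_or + Z95 * self.se))

    @property
    def p(self) -> float:
        """Two-sided Wald p-value against OR = 1."""
        if self.se == 0.0:
            return 1.0 if self.log_or == 0.0 else 0.0
        z = self.log_or / self.se
        return float(2 * stats.norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_name, "contrast": self.contrast,
            "label": self.label, "log_or": self.log_or, "se": self.se,
            "or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "extrapolated": self.extrapolated,
        }


def _contrast_estimate(fit: FitResult, cb: CrossBasisMatrix, cols: slice,
                       x: float, x_ref: float, lags: np.ndarray,
                       label: str) -> EffectEstimate:
    if not fit.converged:
        raise ValueError("effects require a converged fit")
    c = cb.contrast_vector(x, x_ref, lags)
    beta = fit.beta[cols]
    log_or = float(c @ beta)
    if x == x_ref:
        se = 0.0
        log_or = 0.0
    else:
        sub = fit.cov[cols, cols]
        se = float(np.sqrt(max(c @ sub @ c, 0.0)))
    b0, b1 = cb.exposure_spec.boundary if cb.exposure_spec.boundary else (-np.inf, np.inf)
    extrap = not (b0 <= x <= b1) or not (b0 <= x_ref <= b1)
    return EffectEstimate(log_or, se, label, cb.exposure_name,
                          f"{x:g} vs {x_ref:g}", extrap)


def lag_specific_or(fit: FitResult, cb: CrossBasisMatrix, cols: slice,
                    x: float, x_ref: float, lag: int) -> EffectEstimate:
    """Odds ratio of exposure ``x`` against ``x_ref`` at a single lag.

    ``cols`` selects the cross-basis block within the fitted design.  Values
    outside the boundary knots use the natural-spline linear extrapolation
    and are flagged.
    """
    if not 0 <= lag <= cb.max_lag:
        raise ValueError(f"lag {lag} outside [0, {cb.max_lag}]")
    return _contrast_estimate(fit, cb, cols, x, x_ref, np.array([lag]),
                              label=f"lag {lag}")


def cumulative_or(fit: FitResult, cb: CrossBasisMatrix, cols: slice,
                  x: float, x_ref: float,
                  window: tuple[int, int]) -> EffectEstimate:
    """Cumulative odds ratio over the inclusive lag window ``(l0, l1)``:
    the sum of lag-specific log odds ratios, with a delta-method SE on the
    summed contrast vector."""
    l0, l1 = window
    if not (0 <= l0 <= l1 <= cb.max_lag):
        raise ValueError(f"invalid lag window {window} for max lag {cb.max_lag}")
    return _contrast_estimate(fit, cb, cols, x, x_ref,
                              np.arange(l0, l1 + 1), label=f"lag {l0}-{l1}")


def effect_surface(fit: FitResult, cb: CrossBasisMatrix, cols: slice,
                   x_grid: np.ndarray, lag_grid: np.ndarray,
                   x_ref: float) -> list[EffectEstimate]:
    """OR(x, l) over a grid, in row-major order (x outer, lag inner).

    Suitable for export as long-format CSV and 3-D plotting.
    """
    out = []
    for x in np.asarray(x_grid, dtype=float):
        for lag in np.asarray(lag_grid):
            est = lag_specific_or(fit, cb, cols, float(x), x_ref, int(lag))
            est = replace(est, label=f"x={x:g},lag={int(lag)}")
            out.append(est)
    return out


def subgroup_ztest(est1: EffectEstimate, est2: EffectEstimate):
    """Two-sample z-test comparing two independent log odds ratios.

    ``z = (log_or1 - log_or2) / sqrt(se1^2 + se2^2)``, two-sided normal p.
    """
    if est1.se <= 0 or est2.se <= 0:
        raise ValueError("both estimates need positive standard errors")
    z = (est1.log_or - est2.log_or) / np.hypot(est1.se, est2.se)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class SensitivityVariant:
    name: str
    deltas: dict
    estimates: dict = field(default_factory=dict)  # exposure -> EffectEstimate
    converged: bool = True
    message: str = ""


def sensitivity_variants(contrast_percentiles=(2.5, 5.0, 10.0, 15.0)) -> list[tuple[str, dict]]:
    """The nine-variant sensitivity grid: one configuration delta each."""
    grid = [
        ("remove_pollutants", {"adjust_pollutants": False}),
        ("spline_df_4", {"exposure_df": 4}),
        ("max_lag_36", {"max_lag": 36}),
        ("max_lag_48", {"max_lag": 48}),
        ("retain_extremes", {"retain_extremes": True}),
    ]
    for pct in contrast_percentiles:
        grid.append((f"percentile_{pct:g}", {"contrast_percentile": pct}))
    return grid


def run_sensitivity_suite(config, records, stations) -> list[SensitivityVariant]:
    """Refit the full pipeline under each of the nine sensitivity variants.

    Each variant perturbs exactly one family of settings relative to the main
    analysis: dropping pollutant adjustment, exposure-spline df 4, maximum
    lag 36 h or 48 h, retaining extreme values, or moving the low-exposure
    contrast percentile to 2.5/5/10/15 (reference fixed at the 99th).  A
    variant that fails to converge is reported with a message, not raised.
    """
    from .pipeline import run_pipeline  # local import: pipeline uses effects

    out = []
    for name, deltas in sensitivity_variants():
        cfg = config.with_updates(**deltas)
        variant = SensitivityVariant(name=name, deltas=deltas)
        try:
            result = run_pipeline(cfg, records, stations)
            for exposure in cfg.exposures:
                variant.estimates[exposure] = result.cumulative_estimate(exposure)
            variant.converged = result.fit.converged
        except Exception as err:  # refit failures are data outcomes here
            variant.converged = False
            variant.message = str(err)
        out.append(variant)
    return out
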