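"""End-to-end analysis pipeline: records + station series -> fitted model
and odds-ratio estimates.

Stages, in order: nearest-station assignment with distance exclusion;
time-stratified referent selection; backward lag matrices for each exposure;
two-stage percentile trimming on the pooled case-window values; event-hour
and stratum survival rules; cross-basis construction; optional pollutant
covariates and temperature x humidity interaction; conditional-logit fit;
contrast estimation against the 99th-percentile reference.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import exposure as expo
from .basis import (BasisSpec, CrossBasisMatrix, DesignMatrix, assemble_design,
                    cross_basis, lag_basis_spec)
from .clogit import FitResult, fit_clogit, likelihood_ratio_test
from .design import Stratum, build_strata
from .effects import EffectEstimate, cumulative_or, effect_surface, lag_specific_or

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "interaction_test"]

DEFAULT_WINDOWS = {
    # two window conventions are reported side by side for each exposure
    "temperature": [(0, 12), (0, 16)],
    "relative_humidity": [(0, 6), (0, 3)],
}


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration of one analysis run."""

    max_lag: int = 24                   # hours
    exposure_df: int = 3                # natural cubic spline df per exposure
    lag_knots: int = 2                  # log-spaced internal knots on the lag axis
    trim_lower_pct: float = 1.0
    trim_upper_pct: float = 99.0
    contrast_percentile: float = 1.0    # "extreme low" exposure
    reference_percentile: float = 99.0  # comparison baseline
    max_station_km: float = 50.0
    adjust_pollutants: bool = True
    interaction: bool = False
    retain_extremes: bool = False
    exposures: tuple = ("temperature", "relative_humidity")
    cumulative_windows: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_WINDOWS.items()})
    max_masked_frac: float = 0.25
    seed: int = 0
    output_dir: str = "results"
    patient_csv: str = ""
    station_csv: str = ""

    def __post_init__(self):
        if not self.contrast_percentile < self.reference_percentile:
            raise ValueError("contrast percentile must be below the reference")
        if self.max_lag not in (24, 36, 48):
            warnings.warn(f"max_lag={self.max_lag} h is outside the usual "
                          "{24, 36, 48} grid", stacklevel=2)

    def with_updates(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exposures"] = list(self.exposures)
        d["cumulative_windows"] = {
            k: [list(w) for w in v] for k, v in self.cumulative_windows.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def primary_window(self, exposure: str) -> tuple[int, int]:
        w = self.cumulative_windows.get(exposure)
        if not w:
            return (0, self.max_lag)
        l0, l1 = w[0]
        return (int(l0), int(min(l1, self.max_lag)))


@dataclass
class PipelineResult:
    config: RunConfig
    fit: FitResult
    design: DesignMatrix
    cross_bases: dict            # exposure -> CrossBasisMatrix
    trims: dict                  # exposure -> TrimResult
    pools: dict                  # exposure -> post-trim pooled case-window values
    strata: list
    exclusions: pd.DataFrame
    counts: dict
    rh_mean_centered: "np.ndarray | None" = None

    def contrast_values(self, exposure: str) -> tuple[float, float]:
        """(x_low, x_ref) for the configured contrast/reference percentiles."""
        trim = self.trims[exposure]
        pool = self.pools[exposure]
        cfg = self.config
        if cfg.contrast_percentile == cfg.trim_lower_pct:
            x = trim.x_ext
        else:
            x = float(np.quantile(pool, cfg.contrast_percentile / 100.0))
        if cfg.reference_percentile == cfg.trim_upper_pct:
            x_ref = trim.x_ref
        else:
            x_ref = float(np.quantile(pool, cfg.reference_percentile / 100.0))
        return x, x_ref

    def cumulative_estimate(self, exposure: str,
                            window: "tuple[int, int] | None" = None) -> EffectEstimate:
        cb = self.cross_bases[exposure]
        x, x_ref = self.contrast_values(exposure)
        if window is None:
            window = self.config.primary_window(exposure)
        return cumulative_or(self.fit, cb, self.design.block(exposure),
                             x, x_ref, window)

    def lag_curve(self, exposure: str) -> list[EffectEstimate]:
        cb = self.cross_bases[exposure]
        x, x_ref = self.contrast_values(exposure)
        return [lag_specific_or(self.fit, cb, self.design.block(exposure),
                                x, x_ref, lag)
                for lag in range(cb.max_lag + 1)]

    def surface(self, exposure: str, n_x: int = 30) -> list[EffectEstimate]:
        cb = self.cross_bases[exposure]
        _, x_ref = self.contrast_values(exposure)
        b0, b1 = cb.exposure_spec.boundary
        grid = np.linspace(b0, b1, n_x)
        return effect_surface(self.fit, cb, self.design.block(exposure),
                              grid, np.arange(cb.max_lag + 1), x_ref)


def _event_table(records: pd.DataFrame, stations, max_km: float):
    """Station assignment and the long event-hour table (cases + referents)."""
    from .design import select_referents

    assigned = []
    excluded = []
    station_list = list(stations)
    for row in records.itertuples(index=False):
        st, dist = expo.match_station(row, station_list, max_km=max_km)
        if st is None:
            excluded.append({"patient_id": str(row.patient_id),
                             "reason": f"nearest_station_{dist:.1f}_km"})
            continue
        assigned.append((row, st))
    rows = []
    for row, st in assigned:
        case_hour = pd.Timestamp(row.onset_time)
        for hour, is_case in [(case_hour, True)] + [
                (h, False) for h in select_referents(case_hour)]:
            rows.append((str(row.patient_id), hour, st, is_case))
    return assigned, rows, pd.DataFrame(excluded, columns=["patient_id", "reason"])


def run_pipeline(config: RunConfig, records: pd.DataFrame,
                 stations) -> PipelineResult:
    """Run the full analysis on a patient table and station series."""
    L = config.max_lag
    assigned, event_rows, excl_distance = _event_table(
        records, stations, config.max_station_km)
    if not event_rows:
        raise ValueError("no records within range of any station")

    hours = pd.DatetimeIndex([r[1] for r in event_rows])
    is_case = np.array([r[3] for r in event_rows])
    pids = [r[0] for r in event_rows]
    index_of = {(pid, hour): i for i, (pid, hour) in enumerate(zip(pids, hours))}

    # group rows by station so each lag matrix is built once per station
    by_station: dict = {}
    for i, (_, _, st, _) in enumerate(event_rows):
        by_station.setdefault(id(st), (st, []))[1].append(i)

    matrices: dict = {}
    trims: dict = {}
    pools: dict = {}
    for name in config.exposures:
        Q = np.full((len(event_rows), L + 1), np.nan)
        for st, idxs in by_station.values():
            sub = expo.build_lag_matrix(st, hours[idxs], name, L)
            Q[idxs] = sub.Q
        mat = expo.ExposureMatrix(hours, name, Q)
        trim, _ = expo.trim_extremes(
            mat.Q[is_case].ravel(), retain_extremes=config.retain_extremes,
            lower_pct=config.trim_lower_pct, upper_pct=config.trim_upper_pct)
        trim.exposure_name = name
        trim.require_contrast()
        mat = expo.apply_trim(mat, trim)
        case_vals = mat.Q[is_case].ravel()
        pools[name] = case_vals[np.isfinite(case_vals)]
        matrices[name] = mat
        trims[name] = trim

    # the cross-basis contract requires complete lag histories, so any
    # event-hour with a trimmed or missing cell anywhere in its window is
    # excluded (selection on a member's own exposure vector leaves the
    # conditional likelihood of the survivors intact)
    usable_rows = np.ones(len(event_rows), dtype=bool)
    for name in config.exposures:
        usable_rows &= ~matrices[name].mask.any(axis=1)

    pollutant_cols = None
    if config.adjust_pollutants:
        pol = np.full((len(event_rows), len(expo.POLLUTANTS)), np.nan)
        for st, idxs in by_station.values():
            means, _ = expo.pollutant_means(st, hours[idxs], L)
            pol[idxs] = means
        usable_rows &= np.all(np.isfinite(pol), axis=1)
        pollutant_cols = pol

    usable = {(pid, hour): bool(u)
              for pid, hour, u in zip(pids, hours, usable_rows)}
    matched = pd.DataFrame([r._asdict() if hasattr(r, "_asdict") else r
                            for r, _ in assigned])
    strata, excl_strata = build_strata(matched, usable)
    if not strata:
        raise ValueError("no stratum survived the exposure survival rules")
    exclusions = pd.concat([excl_distance, excl_strata], ignore_index=True)

    # final row order: stratum by stratum, case first
    sel = []
    y = []
    sidx = []
    for s in strata:
        for hour, case in [(s.case_hour, 1)] + [(h, 0) for h in s.control_hours]:
            sel.append(index_of[(s.patient_id, hour)])
            y.append(case)
            sidx.append(s.stratum_id)
    sel = np.asarray(sel)
    y = np.asarray(y, dtype=bool)
    sidx = np.asarray(sidx)

    cross_bases = {}
    cb_list = []
    for name in config.exposures:
        mat = matrices[name]
        spec = BasisSpec.from_quantiles(pools[name], df=config.exposure_df,
                                        intercept=False)
        lag_spec = lag_basis_spec(L, config.lag_knots)
        cb = cross_basis(mat.Q[sel], spec, lag_spec, exposure_name=name)
        cross_bases[name] = cb
        cb_list.append(cb)

    rh_centered = None
    if config.interaction:
        if "relative_humidity" not in matrices:
            raise ValueError("interaction requires a relative_humidity exposure")
        rh_mat = matrices["relative_humidity"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rh_mean = np.nanmean(np.where(rh_mat.mask, np.nan, rh_mat.Q), axis=1)[sel]
        rh_centered = rh_mean - np.nanmean(rh_mean)

    poll_block = pollutant_cols[sel] if pollutant_cols is not None else None
    if poll_block is not None:
        poll_block = poll_block - poll_block.mean(axis=0)  # conditioning only
    design = assemble_design(cb_list, poll_block,
                             pollutant_names=list(expo.POLLUTANTS),
                             interaction_with=rh_centered)
    fit = fit_clogit(design.X, y, sidx, column_names=design.column_names)

    counts = {
        "n_records": int(len(records)),
        "n_excluded_distance": int(len(excl_distance)),
        "n_excluded_strata": int(len(excl_strata)),
        "n_strata": len(strata),
        "n_rows": int(sel.size),
        "n_event_hours_excluded": int(np.sum(~usable_rows)),
        "n_trimmed": {k: trims[k].n_masked for k in trims},
    }
    return PipelineResult(config, fit, design, cross_bases, trims, pools,
                          strata, exclusions, counts, rh_centered)


def interaction_test(config: RunConfig, records: pd.DataFrame, stations):
    """LRT of the temperature x humidity interaction block.

    Fits the model with and without the interaction columns and returns
    ``(statistic, df, p, full_result, reduced_result)``.
    """
    full = run_pipeline(config.with_updates(interaction=True), records, stations)
    reduced = run_pipeline(config.with_updates(interaction=False), records, stations)
    stat, df, p = likelihood_ratio_test(full.fit, reduced.fit)
    return stat, df, p, full, reduced
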