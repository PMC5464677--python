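"""Single-cell titration analysis: induced fractions, F50 decision thresholds,
quality-control filters and panel summary statistics.

All F50 arithmetic is done in log2(% glucose).  The decision threshold of a
strain is the glucose concentration, at fixed galactose, at which half the
cells express the reporter above a basal cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DecisionThreshold",
    "basal_threshold",
    "induced_fraction",
    "build_titration_curve",
    "fit_decision_threshold",
    "reference_qc",
    "replicate_outlier_qc",
    "count_distinct_phenotypes",
    "fold_range",
    "phenotype_cells",
]

MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


@dataclass
class DecisionThreshold:
    """Fitted decision threshold for one titration."""

    strain_id: Optional[str] = None
    replicate: Optional[int] = None
    f50: Optional[float] = None  # % w/v glucose; None when censored/failed
    log2_f50: Optional[float] = None
    hill_h: Optional[float] = None
    censored: Optional[str] = None  # None | "low" | "high"
    qc_status: str = "pass"  # pass | reference_fail | poor_quality | replicate_outlier
    method: Optional[str] = None  # "hill" | "interpolation"


def basal_threshold(reporter: np.ndarray, quantile: float = 0.99) -> float:
    """Fluorescence cutoff: quantile of the repressed control's log reporter.

    The cutoff is computed on log10 reporter values and returned on the
    linear scale (quantiles commute with the monotone transform).  A control
    with fewer than 100 cells triggers a warning; an empty one is an error.
    """
    reporter = np.asarray(reporter, dtype=float)
    if reporter.size == 0:
        raise ValueError("empty uninduced control: cannot set basal cutoff")
    if reporter.size < 100:
        warnings.warn(
            f"basal control has only {reporter.size} cells (<100); "
            "cutoff may be unstable",
            stacklevel=2,
        )
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(10.0 ** np.quantile(np.log10(reporter), quantile))


def induced_fraction(reporter: np.ndarray, cutoff: float) -> float:
    """Fraction of cells with reporter strictly above the cutoff.

    Returns NaN (flagged missing) when the well has no cells.
    """
    reporter = np.asarray(reporter, dtype=float)
    if reporter.size == 0:
        return float("nan")
    return float(np.mean(reporter > cutoff))


def build_titration_curve(
    wells: Sequence[tuple[float, np.ndarray]], cutoff: float
) -> pd.DataFrame:
    """Induced fraction per glucose concentration, sorted high-to-low."""
    rows = [
        {"glucose_pct": g, "induced_fraction": induced_fraction(v, cutoff)}
        for g, v in wells
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("glucose_pct", ascending=False)
        .reset_index(drop=True)
    )


def _interp_crossing(log2_g: np.ndarray, frac: np.ndarray) -> Optional[float]:
    """Highest-glucose 0.5 crossing by linear interpolation in log2 g.

    ``log2_g`` must be sorted descending.  Returns None when no adjacent pair
    straddles 0.5.
    """
    d = frac - 0.5
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            return float(log2_g[i])
        if d[i] * d[i + 1] < 0:
            w = d[i] / (d[i] - d[i + 1])
            return float(log2_g[i] + w * (log2_g[i + 1] - log2_g[i]))
    if d[-1] == 0.0:
        return float(log2_g[-1])
    return None


def fit_decision_threshold(
    glucose_pct: np.ndarray,
    induced: np.ndarray,
    strain_id: Optional[str] = None,
    replicate: Optional[int] = None,
) -> DecisionThreshold:
    """Fit f(g) = 1 / (1 + (g/F50)^h) in log2 glucose.

    Falls back to linear interpolation of the 0.5 crossing when the fit fails
    or lands outside [min_grid/2, max_grid*2]; returns a censored threshold
    (low/high) when the fractions never reach 0.5 from both sides; fewer than
    4 usable points gives qc_status="poor_quality".
    """
    g = np.asarray(glucose_pct, dtype=float)
    y = np.asarray(induced, dtype=float)
    ok = np.isfinite(y) & (g > 0)
    g, y = g[ok], y[ok]
    order = np.argsort(-g)
    g, y = g[order], y[order]
    out = DecisionThreshold(strain_id=strain_id, replicate=replicate)
    if g.size < 4:
        out.qc_status = "poor_quality"
        return out
    if y.max() < 0.5:
        out.censored = "low"
        return out
    if y.min() > 0.5:
        out.censored = "high"
        return out

    lg = np.log2(g)
    lo, hi = lg.min() - 1.0, lg.max() + 1.0
    x0 = _interp_crossing(lg, y)
    init = x0 if x0 is not None else float(np.median(lg))

    def resid(params: np.ndarray) -> np.ndarray:
        lf, h = params
        return 1.0 / (1.0 + 2.0 ** (h * (lg - lf))) - y

    fit_lf: Optional[float] = None
    fit_h: Optional[float] = None
    try:
        res = least_squares(
            resid,
            x0=[np.clip(init, lo, hi), 2.0],
            bounds=([lo, 0.2], [hi, 20.0]),
        )
        if res.success and lo <= res.x[0] <= hi:
            fit_lf, fit_h = float(res.x[0]), float(res.x[1])
    except Exception:
        pass

    if fit_lf is not None:
        out.log2_f50, out.hill_h, out.method = fit_lf, fit_h, "hill"
    elif x0 is not None:
        out.log2_f50, out.method = float(x0), "interpolation"
    else:
        out.qc_status = "poor_quality"
        return out
    out.f50 = float(2.0**out.log2_f50)
    return out


def _truncated_stats(values: np.ndarray, trunc: float) -> tuple[float, float]:
    v = np.sort(np.asarray(values, dtype=float))
    n_cut = int(np.floor(v.size * trunc))
    core = v[n_cut : v.size - n_cut] if n_cut > 0 else v
    return float(core.mean()), float(core.std(ddof=1)) if core.size > 1 else 0.0


def reference_qc(
    reference_log2_f50: np.ndarray, trunc: float = 0.05, k: float = 2.0
) -> tuple[np.ndarray, float, float]:
    """Per-well pass/fail against the truncated reference distribution.

    Removes the top and bottom ``trunc`` fraction of reference values, takes
    mean and SD of the rest, and fails wells where |value - mean| > k * SD
    (strict).  Returns (pass mask, truncated mean, truncated SD).  The
    co-cultured query of a failed well is to be discarded by the caller.
    """
    values = np.asarray(reference_log2_f50, dtype=float)
    if values.size < 10:
        raise ValueError(f"need >= 10 reference wells, got {values.size}")
    mean, sd = _truncated_stats(values, trunc)
    passed = np.abs(values - mean) <= k * sd
    return passed, mean, sd


def replicate_outlier_qc(
    values_by_strain: dict[str, np.ndarray], cutoff_sd: float = 1.5
) -> tuple[dict[str, np.ndarray], pd.DataFrame, float]:
    """Discard replicate values far from the mean of their siblings.

    For every value, d = |x - mean(other replicates of the strain)|.  The d
    values are pooled over strains and a robust SD is estimated as
    MAD(d) * 1.4826; values with d > cutoff_sd * robust SD (strict) are
    discarded.  Strains with a single replicate are kept, flagged
    unvalidated.  Returns (kept values per strain, discard log, robust SD).
    """
    d_records: list[tuple[str, int, float, float]] = []
    singles: list[str] = []
    for strain, vals in values_by_strain.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            singles.append(strain)
            continue
        for i, x in enumerate(vals):
            others = np.delete(vals, i)
            d_records.append((strain, i, float(x), float(abs(x - others.mean()))))

    if d_records:
        # the d's are already absolute deviations from a (near-)zero-centered
        # difference distribution, so MAD = median(d)
        d = np.array([r[3] for r in d_records])
        robust_sd = float(np.median(d) * MAD_TO_SD)
    else:
        robust_sd = 0.0

    kept: dict[str, np.ndarray] = {}
    log_rows = []
    cutoff = cutoff_sd * robust_sd
    for strain, vals in values_by_strain.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            kept[strain] = vals
            log_rows.append(
                {"strain_id": strain, "replicate": 0, "value": float(vals[0]) if vals.size else np.nan,
                 "d": np.nan, "action": "unvalidated"}
            )
            continue
        mask = np.ones(vals.size, dtype=bool)
        for strain_r, i, x, di in d_records:
            if strain_r != strain:
                continue
            if robust_sd > 0 and di > cutoff:
                mask[i] = False
                log_rows.append(
                    {"strain_id": strain, "replicate": i, "value": x, "d": di,
                     "action": "discarded"}
                )
        kept[strain] = vals[mask]
    log = pd.DataFrame(
        log_rows, columns=["strain_id", "replicate", "value", "d", "action"]
    )
    return kept, log, robust_sd


def count_distinct_phenotypes(
    mean_log2_f50: np.ndarray, epsilon: float
) -> dict[str, Optional[int]]:
    """Lower bound on the number of distinguishable phenotypes.

    Method A divides the phenotype range by twice the measurement noise;
    method B walks strains in ascending order and opens a new group whenever
    a mean exceeds the current group seed by more than 1.96*sqrt(2)*epsilon
    (a pairwise two-sample z criterion).  The reported bound is method B.
    """
    means = np.sort(np.asarray(mean_log2_f50, dtype=float))
    if means.size < 2:
        raise ValueError("need at least 2 strains")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rng_log2 = float(means[-1] - means[0])

    method_a: Optional[int] = None
    if epsilon > 0:
        method_a = int(1 + np.floor(rng_log2 / (2.0 * epsilon)))
    elif rng_log2 == 0.0:
        method_a = 1

    gap = 1.96 * np.sqrt(2.0) * epsilon
    groups = 1
    seed = means[0]
    for m in means[1:]:
        if m - seed > gap:
            groups += 1
            seed = m
    return {"method_a": method_a, "method_b": groups, "reported": groups}


def fold_range(f50_pct: np.ndarray) -> float:
    """max(F50) / min(F50) over non-censored thresholds."""
    v = np.asarray(f50_pct, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no non-censored thresholds")
    return float(v.max() / v.min())


# ---------------------------------------------------------------------------
# end-to-end pipeline over a cells table
# ---------------------------------------------------------------------------


def _experiment_f50(
    cells: pd.DataFrame,
    role: str,
    galactose_pct: float,
    control_glucose_pct: float,
    basal_quantile: float,
) -> DecisionThreshold:
    sub = cells[cells["role"] == role]
    control = sub[
        (sub["glucose_pct"] == control_glucose_pct) & (sub["galactose_pct"] == 0.0)
    ]
    if control.empty:
        return DecisionThreshold(qc_status="poor_quality")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cutoff = basal_threshold(control["yfp"].to_numpy(), basal_quantile)
    titr = sub[sub["galactose_pct"] == galactose_pct]
    grouped = titr.groupby("glucose_pct")["yfp"]
    gs = np.array(sorted(grouped.groups, reverse=True))
    fracs = np.array([induced_fraction(grouped.get_group(g).to_numpy(), cutoff) for g in gs])
    return fit_decision_threshold(gs, fracs)


def phenotype_cells(
    cells: pd.DataFrame,
    galactose_pct: float = 0.25,
    control_glucose_pct: float = 2.0,
    basal_quantile: float = 0.99,
    reference_trunc: float = 0.05,
    reference_k: float = 2.0,
    replicate_cutoff_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full titration pipeline: fits, then QC in the documented discard order
    (reference QC, poor-quality, replicate outliers).

    Returns (per-strain summary, per-experiment detail).  The summary has one
    row per query strain with mean log2 F50 over surviving replicates, SEM,
    replicate count and qc_status.
    """
    detail_rows = []
    experiments = []
    for (strain, rep), sub in cells.groupby(["strain_id", "replicate"]):
        if (sub["role"] == "query").any() and strain in set(
            cells.loc[cells["role"] == "query", "strain_id"]
        ):
            experiments.append((strain, int(rep), sub))

    fits: list[DecisionThreshold] = []
    ref_fits: list[DecisionThreshold] = []
    for strain, rep, sub in experiments:
        well_ids = sub["well_id"].unique()
        exp_cells = cells[cells["well_id"].isin(well_ids)]
        q = _experiment_f50(
            exp_cells[exp_cells["role"] == "query"],
            "query",
            galactose_pct,
            control_glucose_pct,
            basal_quantile,
        )
        r = _experiment_f50(
            exp_cells,
            "reference",
            galactose_pct,
            control_glucose_pct,
            basal_quantile,
        )
        q.strain_id, q.replicate = strain, rep
        fits.append(q)
        ref_fits.append(r)

    # 1) reference QC
    ref_vals = np.array(
        [r.log2_f50 if r.log2_f50 is not None else np.nan for r in ref_fits]
    )
    usable = np.isfinite(ref_vals)
    if usable.sum() >= 10:
        passed, _, _ = reference_qc(ref_vals[usable], reference_trunc, reference_k)
        it = iter(passed)
        for q, ok in zip(fits, (next(it) if u else False for u in usable)):
            if not ok:
                q.qc_status = "reference_fail"

    # 2) poor quality (failed or censored fits)
    for q in fits:
        if q.qc_status == "pass" and q.log2_f50 is None:
            q.qc_status = "poor_quality"

    # 3) replicate outliers among surviving fits
    by_strain: dict[str, list[DecisionThreshold]] = {}
    for q in fits:
        if q.qc_status == "pass":
            by_strain.setdefault(q.strain_id, []).append(q)
    values = {s: np.array([q.log2_f50 for q in qs]) for s, qs in by_strain.items()}
    kept, qc_log, _ = replicate_outlier_qc(values, replicate_cutoff_sd)
    for _, row in qc_log.iterrows():
        if row["action"] == "discarded":
            by_strain[row["strain_id"]][int(row["replicate"])].qc_status = (
                "replicate_outlier"
            )

    for q in fits:
        detail_rows.append(
            {
                "strain_id": q.strain_id,
                "replicate": q.replicate,
                "f50_pct": q.f50,
                "log2_f50": q.log2_f50,
                "hill_h": q.hill_h,
                "censored": q.censored,
                "method": q.method,
                "qc_status": q.qc_status,
            }
        )
    detail = pd.DataFrame(detail_rows)

    summary_rows = []
    for strain in detail["strain_id"].unique():
        sub = detail[detail["strain_id"] == strain]
        good = sub[sub["qc_status"] == "pass"]["log2_f50"].dropna()
        if len(good) > 0:
            mean = float(good.mean())
            sem = float(good.std(ddof=1) / np.sqrt(len(good))) if len(good) > 1 else np.nan
            summary_rows.append(
                {
                    "strain_id": strain,
                    "f50_pct": 2.0**mean,
                    "log2_f50": mean,
                    "sem": sem,
                    "n_reps": len(good),
                    "qc_status": "pass",
                }
            )
        else:
            status = sub["qc_status"].iloc[0]
            summary_rows.append(
                {
                    "strain_id": strain,
                    "f50_pct": np.nan,
                    "log2_f50": np.nan,
                    "sem": np.nan,
                    "n_reps": 0,
                    "qc_status": status,
                }
            )
    return pd.DataFrame(summary_rows), detail
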