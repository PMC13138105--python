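"""Outcome measures and model-agreement statistics.

Turns kinetic fits into long-format tables of the study outcomes —
relative delivery R1, binding potential BP_ND (white-matter reference)
and distribution volume ratio DVR = BP_ND + 1 (cerebellum
pseudo-reference) — applies the rSE reliability filter, and quantifies
agreement between reference-tissue models and the plasma-input 1TC
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aif import FengInput
from .models import KineticFitResult, fit_1tc, fit_srtm, fit_srtm2, fit_srtmc
from .tacio import Cohort, Scan, truncate_curves, truncate_scan

__all__ = [
    "dvr_from_bpnd",
    "filter_reliable",
    "percent_difference",
    "agreement_stats",
    "bias_vs_k2prime_bias",
    "AgreementResult",
    "fit_scan",
    "cohort_outcomes",
    "onetissue_outcomes",
]

RSE_THRESHOLD = 25.0  # %; reliability cutoff on the outcome's relative SE


def dvr_from_bpnd(bpnd):
    """DVR = BP_ND + 1 (distribution volume ratio vs the same reference)."""
    bpnd = np.asarray(bpnd, dtype=float)
    if np.any(bpnd <= -1.0):
        raise ValueError("BP_ND must exceed -1 (DVR must be positive)")
    out = bpnd + 1.0
    return float(out) if out.ndim == 0 else out


def percent_difference(x, x_ref):
    """Signed percentage difference 100*(x - x_ref)/x_ref."""
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if np.any(x_ref == 0):
        raise ValueError("reference value must be nonzero")
    out = 100.0 * (x - x_ref) / x_ref
    return float(out) if out.ndim == 0 else out


def filter_reliable(
    records: pd.DataFrame, threshold: float = RSE_THRESHOLD, rse_col: str = "rse"
) -> pd.DataFrame:
    """Flag records whose outcome rSE exceeds ``threshold`` percent.

    Returns a copy with an ``excluded`` boolean column; rows are flagged,
    never dropped (strict inequality: rSE == threshold is kept).
    """
    if rse_col not in records.columns:
        raise ValueError(f"records lack an {rse_col!r} column")
    if records[rse_col].isna().any():
        raise ValueError(f"missing {rse_col!r} values; cannot apply reliability filter")
    out = records.copy()
    out["excluded"] = records[rse_col].to_numpy(dtype=float) > threshold
    return out


@dataclass(frozen=True)
class AgreementResult:
    """OLS agreement between two outcome vectors."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def __iter__(self):  # allow tuple unpacking (slope, intercept, r2)
        return iter((self.slope, self.intercept, self.r2))


def agreement_stats(x, y) -> AgreementResult:
    """Regress reference-model outcomes ``y`` on baseline outcomes ``x`` (OLS)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired, equal-length observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("agreement inputs must be finite")
    if np.var(x) == 0:
        raise ValueError("zero variance in baseline values; regression undefined")
    res = stats.linregress(x, y)
    return AgreementResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p=float(res.pvalue), n=int(x.size),
    )


def bias_vs_k2prime_bias(records: pd.DataFrame,
                         bias_col: str = "outcome_bias",
                         k2p_col: str = "k2prime_bias") -> AgreementResult:
    """Regress per-scan outcome bias (%) on reference-clearance bias (%)."""
    for c in (bias_col, k2p_col):
        if c not in records.columns:
            raise ValueError(f"records lack column {c!r}")
    if len(records) < 3:
        raise ValueError("need at least 3 scans")
    return agreement_stats(records[k2p_col], records[bias_col])


# ---------------------------------------------------------------------------
# cohort-level outcome tables


def fit_scan(
    scan: Scan,
    model: str,
    reference: str,
    k2prime: float | None = None,
    t_end: float | None = None,
    weights: str = "duration",
    targets: list[str] | None = None,
) -> tuple[list[KineticFitResult], float | None]:
    """Fit one reference-tissue model to every target region of a scan.

    Returns the per-region results plus, for SRTMC, the jointly
    estimated k2' (otherwise the fixed/derived value or None).
    """
    region_names = targets or [r for r in scan.curves if r != reference]
    curves = [scan.curve(r) for r in region_names]
    ref = scan.curve(reference)
    schedule = scan.schedule
    if t_end is not None and t_end < schedule.t_end - 1e-9:
        curves, _ = truncate_curves(curves, schedule, t_end)
        ref, schedule = truncate_scan(ref, schedule, t_end)
    if model == "srtm":
        return [fit_srtm(c, ref, schedule, weights) for c in curves], None
    if model == "srtm2":
        if k2prime is None:
            raise ValueError("SRTM2 requires a k2prime value")
        return [fit_srtm2(c, ref, k2prime, schedule, weights) for c in curves], k2prime
    if model == "srtmc":
        joint = fit_srtmc(curves, ref, schedule, weights)
        return joint.results, joint.k2prime
    raise ValueError(f"unknown reference-tissue model {model!r}")


def _result_record(fit: KineticFitResult, subject, session, reference, k2prime):
    bp = fit.params["BP_ND"]
    return {
        "subject": subject, "session": session, "region": fit.region_id,
        "model": fit.model, "reference": reference, "t_end": fit.t_end,
        "R1": fit.params["R1"], "BP_ND": bp,
        "DVR": bp + 1.0 if bp > -1.0 else np.nan,
        "k2prime": k2prime,
        "rse": fit.rse["BP_ND"], "rse_r1": fit.rse["R1"],
        "converged": fit.converged,
    }


def cohort_outcomes(
    cohort: Cohort,
    model: str,
    reference: str,
    k2prime: float | None = None,
    t_end: float | None = None,
    weights: str = "duration",
    scans: list[Scan] | None = None,
) -> pd.DataFrame:
    """Outcome table for every scan of a cohort under one model/reference."""
    rows = []
    for scan in scans if scans is not None else cohort.scans:
        fits, k2p = fit_scan(scan, model, reference, k2prime, t_end, weights,
                             targets=[r for r in cohort.regions if r != reference])
        rows += [_result_record(f, scan.subject, scan.session, reference, k2p)
                 for f in fits]
    return filter_reliable(pd.DataFrame(rows))


def onetissue_outcomes(
    cohort: Cohort,
    input_function: FengInput | None = None,
    reference: str | None = None,
    t_end: float | None = None,
    weights: str = "duration",
    scans: list[Scan] | None = None,
) -> pd.DataFrame:
    """1TC baseline outcomes: fit every region against the plasma input.

    BP_ND of a target is derived from distribution volumes,
    DV_target/DV_ref - 1, with DV = K1/k2 from the 1TC fits.
    """
    if input_function is None:
        if cohort.input_function is None:
            raise ValueError("cohort carries no input function; pass one explicitly")
        input_function = FengInput.from_dict(cohort.input_function)
    reference = reference or cohort.reference_regions["bpnd"]
    rows = []
    for scan in scans if scans is not None else cohort.scans:
        names = [reference] + [r for r in cohort.regions if r != reference]
        curves = [scan.curve(r) for r in names]
        schedule = scan.schedule
        if t_end is not None and t_end < schedule.t_end - 1e-9:
            curves, schedule = truncate_curves(curves, schedule, t_end)
        fits = {c.region_id: fit_1tc(c, input_function, schedule, weights) for c in curves}
        ref_fit = fits[reference]
        dv_ref = ref_fit.params["DV"]
        for region, f in fits.items():
            if region == reference:
                continue
            bp = f.params["DV"] / dv_ref - 1.0
            rows.append({
                "subject": scan.subject, "session": scan.session, "region": region,
                "model": "1TC", "reference": reference, "t_end": f.t_end,
                "K1": f.params["K1"], "k2": f.params["k2"], "DV": f.params["DV"],
                "BP_ND": bp, "DVR": bp + 1.0,
                "ref_k2": ref_fit.params["k2"],
                "rse": f.rse["DV"], "converged": f.converged,
            })
    return pd.DataFrame(rows)
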