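"""Time-stability (minimum scan time) analysis.

Every baseline scan is refitted at truncated durations (10..80 min in
10-min steps by default); the percentage difference of each outcome
against the same scan's 90-min estimate is aggregated across
participants, and the minimum scan time is the shortest duration from
which the mean stays within 5% and the inter-subject SD within 10%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .outcomes import RSE_THRESHOLD, cohort_outcomes, percent_difference
from .tacio import Cohort

__all__ = [
    "DEFAULT_TRUNCATIONS",
    "run_time_stability",
    "minimum_scan_time",
]

DEFAULT_TRUNCATIONS: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80)


def run_time_stability(
    cohort: Cohort,
    model: str,
    reference: str,
    outcome: str = "BP_ND",
    k2prime: float | None = None,
    truncations: tuple[float, ...] = DEFAULT_TRUNCATIONS,
    weights: str = "duration",
    rse_threshold: float = RSE_THRESHOLD,
    scans=None,
) -> pd.DataFrame:
    """Truncate, refit and aggregate percentage differences vs 90 min.

    Returns the stability table: one row per (region, t_end) with the
    mean and inter-subject SD of the percentage difference across
    baseline scans and the number of scans contributing. Fits whose
    outcome rSE exceeds ``rse_threshold`` at a given duration — or whose
    full-length fit is itself unreliable — are excluded from aggregation
    at that duration. The full scan duration appears as a 0%-difference
    reference row.
    """
    scans = scans if scans is not None else cohort.baseline_scans
    if not scans:
        raise ValueError("cohort has no baseline scans")
    full_t = scans[0].schedule.t_end

    def outcomes_at(t_end):
        return cohort_outcomes(
            cohort, model, reference, k2prime=k2prime, t_end=t_end,
            weights=weights, scans=scans,
        )

    full = outcomes_at(None).set_index(["subject", "region"])
    rows = []
    for t_end in (*truncations, full_t):
        tab = outcomes_at(None if t_end == full_t else t_end)
        tab = tab.set_index(["subject", "region"])
        for region in sorted({r for _, r in tab.index}):
            diffs = []
            for subject in {s for s, _ in tab.index}:
                try:
                    rec = tab.loc[(subject, region)]
                    ref90 = full.loc[(subject, region)]
                except KeyError:
                    continue
                if rec["excluded"] or ref90["excluded"]:
                    continue
                if not np.isfinite(rec[outcome]) or ref90[outcome] == 0:
                    continue
                diffs.append(percent_difference(rec[outcome], ref90[outcome]))
            diffs = np.asarray(diffs)
            rows.append({
                "region": region, "t_end": float(t_end),
                "mean": float(np.mean(diffs)) if diffs.size else np.nan,
                "sd": float(np.std(diffs, ddof=1)) if diffs.size > 1 else
                      (0.0 if diffs.size == 1 else np.nan),
                "n": int(diffs.size),
            })
    return pd.DataFrame(rows).sort_values(["region", "t_end"]).reset_index(drop=True)


def minimum_scan_time(
    table: pd.DataFrame,
    mean_thresh: float = 5.0,
    sd_thresh: float = 10.0,
    sustained: bool = True,
) -> pd.Series:
    """Per-region minimum scan duration from a stability table.

    A duration qualifies when |mean %diff| < ``mean_thresh`` and the
    inter-subject SD < ``sd_thresh``. With ``sustained=True`` (default)
    the criteria must also hold at every longer truncation; with
    ``sustained=False`` the first qualifying duration is returned.
    Returns the full duration when no earlier truncation qualifies.
    Cells with no contributing scans fail the criteria.
    """
    if table.empty:
        raise ValueError("empty stability table")
    out = {}
    full_t = table["t_end"].max()
    for region, sub in table.groupby("region"):
        sub = sub[sub["t_end"] < full_t].sort_values("t_end")
        ok = (
            (np.abs(sub["mean"].to_numpy()) < mean_thresh)
            & (sub["sd"].to_numpy() < sd_thresh)
            & (sub["n"].to_numpy() > 0)
        )
        t = sub["t_end"].to_numpy()
        ans = full_t
        if ok.size:
            if sustained:
                # smallest t from which every later truncation also passes
                holds_onward = np.flip(np.logical_and.accumulate(np.flip(ok)))
                idx = np.nonzero(holds_onward)[0]
            else:
                idx = np.nonzero(ok)[0]
            if idx.size:
                ans = float(t[idx[0]])
        out[region] = ans
    return pd.Series(out, name="minimum_scan_time").sort_index()
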