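"""Test-retest reproducibility: TRV and absolute TRV.

For a paired outcome (test, retest) the test-retest variability is the
signed difference over the pair mean,

    TRV = 100 * (retest - test) / ((test + retest)/2)  [%],

and aTRV = |TRV| per pair. Tables aggregate mean +/- SD of both across
pairs, per region and outcome, with a pooled "All regions" row
(pair-level pooling, not mean-of-means). Excluded (unreliable) records
drop the affected pair for that cell only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["trv", "cohort_trt"]

ALL_REGIONS = "All regions"


def trv(test_value, retest_value):
    """Signed test-retest variability, percent of the pair mean."""
    test_value = np.asarray(test_value, dtype=float)
    retest_value = np.asarray(retest_value, dtype=float)
    mean = (test_value + retest_value) / 2.0
    if np.any(mean == 0):
        raise ValueError("pair mean is zero; TRV undefined")
    out = 100.0 * (retest_value - test_value) / mean
    return float(out) if out.ndim == 0 else out


def cohort_trt(
    records: pd.DataFrame,
    outcomes: tuple[str, ...] = ("R1", "BP_ND", "DVR"),
    test_label: str = "test",
    retest_label: str = "retest",
) -> pd.DataFrame:
    """TRV/aTRV table from a long outcome table with test and retest rows.

    ``records`` needs columns subject, session, region, model, the
    outcome columns, and (optionally) ``excluded``. Pairs are formed per
    (model, region, subject); a pair contributes to a cell only when
    both sessions are present and neither is excluded.
    """
    req = {"subject", "session", "region", "model"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if "excluded" not in records.columns:
        records = records.assign(excluded=False)
    test = records[records["session"] == test_label]
    retest = records[records["session"] == retest_label]
    merged = test.merge(
        retest, on=["subject", "region", "model"], suffixes=("_test", "_retest")
    )
    if merged.empty:
        raise ValueError("no complete test-retest pairs")
    rows = []
    for model, by_model in merged.groupby("model"):
        for outcome in outcomes:
            a = f"{outcome}_test"
            b = f"{outcome}_retest"
            if a not in by_model.columns:
                continue
            ok = (~by_model["excluded_test"]) & (~by_model["excluded_retest"])
            ok &= np.isfinite(by_model[a]) & np.isfinite(by_model[b])
            usable = by_model[ok]
            groups = list(usable.groupby("region")) + [(ALL_REGIONS, usable)]
            for region, sub in groups:
                if sub.empty:
                    rows.append({
                        "model": model, "region": region, "outcome": outcome,
                        "trv_mean": np.nan, "trv_sd": np.nan,
                        "atrv_mean": np.nan, "atrv_sd": np.nan, "n_pairs": 0,
                    })
                    continue
                v = trv(sub[a].to_numpy(), sub[b].to_numpy())
                v = np.atleast_1d(v)
                rows.append({
                    "model": model, "region": region, "outcome": outcome,
                    "trv_mean": float(np.mean(v)),
                    "trv_sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    "atrv_mean": float(np.mean(np.abs(v))),
                    "atrv_sd": float(np.std(np.abs(v), ddof=1)) if v.size > 1 else 0.0,
                    "n_pairs": int(v.size),
                })
    out = pd.DataFrame(rows)
    if out.empty or (out["n_pairs"] == 0).all():
        raise ValueError("no complete test-retest pairs after exclusion")
    return out
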