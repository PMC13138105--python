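"""Reading, writing and truncating TAC tables; cohort manifests.

There is no standard interchange format for regional TACs, so a plain
delimited-text dialect is used: columns ``frame_start``, ``frame_end``
(minutes) followed by one column per region (kBq/mL), tab- or
comma-delimited (auto-detected on read). A cohort is a YAML manifest
listing scans plus one TAC table per scan.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frames import FrameSchedule, TimeActivityCurve

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "truncate_scan",
    "truncate_curves",
    "Scan",
    "Cohort",
    "load_cohort",
]

_TRUNC_TOL = 1e-9  # minutes; tolerance on frame_end <= t_end


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_tac_table(path: str | os.PathLike) -> tuple[list[TimeActivityCurve], FrameSchedule]:
    """Read a TAC table; returns one curve per region column plus the schedule.

    Raises ``ValueError`` naming the offending row or column on malformed
    input (bad header, non-monotone frames, non-numeric cells).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = list(df.columns)
    if cols[:2] != ["frame_start", "frame_end"]:
        raise ValueError(
            f"{path.name}: first two columns must be frame_start, frame_end (got {cols[:2]})"
        )
    if len(cols) < 3:
        raise ValueError(f"{path.name}: no region columns found")
    for c in cols:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(f"{path.name}: non-numeric value in column {c!r}, row {row}")
        if df[c].isna().any():
            row = int(df[df[c].isna()].index[0])
            raise ValueError(f"{path.name}: missing value in column {c!r}, row {row}")
    schedule = FrameSchedule(df["frame_start"].to_numpy(), df["frame_end"].to_numpy())
    curves = [
        TimeActivityCurve(c, df[c].to_numpy(), schedule) for c in cols[2:]
    ]
    return curves, schedule


def write_tac_table(
    curves: list[TimeActivityCurve],
    schedule: FrameSchedule,
    path: str | os.PathLike,
    sep: str = "\t",
) -> None:
    """Write curves sharing ``schedule`` to a delimited table at full precision."""
    if not curves:
        raise ValueError("no curves to write")
    for c in curves:
        if c.schedule.n_frames != schedule.n_frames or not np.array_equal(
            c.schedule.start, schedule.start
        ):
            raise ValueError(f"curve {c.region_id!r} does not share the given schedule")
    data = {"frame_start": schedule.start, "frame_end": schedule.end}
    for c in curves:
        if c.region_id in data:
            raise ValueError(f"duplicate region column {c.region_id!r}")
        data[c.region_id] = c.values
    df = pd.DataFrame(data)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def truncate_scan(
    curve: TimeActivityCurve, schedule: FrameSchedule, t_end: float
) -> tuple[TimeActivityCurve, FrameSchedule]:
    """Drop all frames ending after ``t_end`` minutes (whole frames only)."""
    keep = schedule.end <= t_end + _TRUNC_TOL
    if not keep[0]:
        raise ValueError(
            f"t_end={t_end} min precedes the end of the first frame ({schedule.end[0]} min)"
        )
    sched = FrameSchedule(schedule.start[keep], schedule.end[keep])
    return TimeActivityCurve(curve.region_id, curve.values[keep], sched), sched


def truncate_curves(
    curves: list[TimeActivityCurve], schedule: FrameSchedule, t_end: float
) -> tuple[list[TimeActivityCurve], FrameSchedule]:
    """Vector version of :func:`truncate_scan` for curves sharing a schedule."""
    out = []
    sched = None
    for c in curves:
        tc, sched = truncate_scan(c, schedule, t_end)
        out.append(tc)
    return out, sched


@dataclass
class Scan:
    """One dynamic scan: all regional TACs on a shared schedule."""

    subject: str
    session: str  # "test" | "retest" | "baseline"
    schedule: FrameSchedule
    curves: dict[str, TimeActivityCurve] = field(repr=False)

    def curve(self, region: str) -> TimeActivityCurve:
        try:
            return self.curves[region]
        except KeyError:
            raise KeyError(f"scan {self.subject}/{self.session} has no region {region!r}")


@dataclass
class Cohort:
    """A set of scans plus region bookkeeping and (optionally) ground truth.

    ``reference_regions`` maps outcome to reference label, e.g.
    ``{"bpnd": "centrum_semiovale", "dvr": "cerebellum"}``.
    """

    scans: list[Scan]
    regions: list[str]
    reference_regions: dict[str, str]
    input_function: dict | None = None
    truth: pd.DataFrame | None = None

    def scan(self, subject: str, session: str) -> Scan:
        for s in self.scans:
            if s.subject == subject and s.session == session:
                return s
        raise KeyError(f"no scan {subject}/{session}")

    @property
    def baseline_scans(self) -> list[Scan]:
        """First (test) session of every subject."""
        return [s for s in self.scans if s.session in ("test", "baseline")]

    @property
    def trt_pairs(self) -> list[tuple[Scan, Scan]]:
        pairs = []
        retests = {s.subject: s for s in self.scans if s.session == "retest"}
        for s in self.scans:
            if s.session in ("test", "baseline") and s.subject in retests:
                pairs.append((s, retests[s.subject]))
        return pairs


def load_cohort(manifest_path: str | os.PathLike) -> Cohort:
    """Load a cohort written by :func:`refkin.simulate.generate_cohort`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    root = manifest_path.parent
    scans = []
    for entry in man["scans"]:
        curves, schedule = read_tac_table(root / entry["path"])
        missing = [r for r in man["reference_regions"].values()
                   if r not in {c.region_id for c in curves}]
        if missing:
            raise ValueError(
                f"scan {entry['subject']}/{entry['session']}: missing reference region(s) {missing}"
            )
        scans.append(
            Scan(
                subject=entry["subject"],
                session=entry["session"],
                schedule=schedule,
                curves={c.region_id: c for c in curves},
            )
        )
    seen = set()
    for s in scans:
        key = (s.subject, s.session)
        if key in seen:
            raise ValueError(f"duplicate scan {key} in manifest")
        seen.add(key)
    truth = None
    truth_path = root / man.get("truth", "truth.tsv")
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
    return Cohort(
        scans=scans,
        regions=list(man["regions"]),
        reference_regions=dict(man["reference_regions"]),
        input_function=man.get("input_function"),
        truth=truth,
    )
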