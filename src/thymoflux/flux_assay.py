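"""Extracellular-flux (mito stress test) kinetic traces and derived metrics.

A mito stress test measures oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) per well over four
injection phases: baseline, oligomycin (ATP-synthase inhibitor), FCCP
(uncoupler; the assay uses two FCCP injections treated as one phase), and
rotenone/antimycin A (ETC inhibitors leaving only non-mitochondrial OCR).

Derived per-well metrics:

* basal ECAR      = baseline ECAR
* basal OCR       = baseline OCR - Rot/AA OCR
* maximal OCR     = maximum single post-FCCP OCR - Rot/AA OCR
* SRC             = maximal OCR - basal OCR (spare respiratory capacity)
* OCR/ECAR ratio  = basal OCR / basal ECAR

Rates are normalized to cell number per well (per 1000 cells by default)
before metric extraction. Negative derived metrics are reported with a
quality flag rather than clipped, so group means stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, two_sample_t

__all__ = [
    "PHASES",
    "InjectionEvent",
    "InjectionSchedule",
    "FluxTraceSet",
    "FluxMetrics",
    "read_flux_table",
    "read_cell_counts",
    "normalize_per_well",
    "assign_phases",
    "compute_well_metrics",
    "compute_plate_metrics",
    "summarize_groups",
    "compare_groups",
]

PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")

#: column names of the long-format trace table (input dialect)
TRACE_COLUMNS = ("well", "group", "experiment", "measurement", "time_min", "OCR", "ECAR")

METRIC_NAMES = ("basal_ecar", "basal_ocr", "maximal_ocr", "src", "ocr_ecar_ratio")


class FluxFormatError(ValueError):
    """Raised when an input table does not follow the expected dialect."""


@dataclass(frozen=True)
class InjectionEvent:
    """One phase of the injection schedule.

    ``first_measurement`` is the 1-based measurement index at which the
    phase begins; ``concentration`` is a free-form compound annotation
    such as "2 uM" (metadata only).
    """

    label: str
    first_measurement: int
    concentration: str | None = None


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injection events partitioning the measurement axis into phases."""

    events: tuple[InjectionEvent, ...]

    def __post_init__(self) -> None:
        labels = tuple(e.label for e in self.events)
        if labels != PHASES:
            raise ValueError(
                f"schedule must contain exactly the phases {PHASES} in order, got {labels}"
            )
        if self.events[0].first_measurement != 1:
            raise ValueError("baseline phase must start at measurement 1")
        starts = [e.first_measurement for e in self.events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError(f"first_measurement must be strictly increasing, got {starts}")

    @classmethod
    def default(cls, measurements_per_phase: int = 3) -> "InjectionSchedule":
        """Equal-length schedule: m baseline, m oligomycin, m FCCP, m Rot/AA."""
        m = measurements_per_phase
        if m < 1:
            raise ValueError("measurements_per_phase must be >= 1")
        return cls(
            events=(
                InjectionEvent("baseline", 1),
                InjectionEvent("oligomycin", m + 1, "2 uM"),
                InjectionEvent("fccp", 2 * m + 1, "0.75 uM x2"),
                InjectionEvent("rot_aa", 3 * m + 1, "2 uM"),
            )
        )

    @classmethod
    def from_dict(cls, spec: Iterable[Mapping]) -> "InjectionSchedule":
        events = tuple(
            InjectionEvent(
                label=str(e["label"]),
                first_measurement=int(e["first_measurement"]),
                concentration=e.get("concentration"),
            )
            for e in spec
        )
        return cls(events=events)

    def phase_labels(self, n_measurements: int) -> list[str]:
        """Phase label for measurements 1..n; every index maps to one phase."""
        last_start = self.events[-1].first_measurement
        if last_start > n_measurements:
            raise ValueError(
                f"schedule phase {self.events[-1].label!r} starts at measurement "
                f"{last_start} but the trace has only {n_measurements}"
            )
        starts = [e.first_measurement for e in self.events]
        labels = []
        for i in range(1, n_measurements + 1):
            k = int(np.searchsorted(starts, i, side="right")) - 1
            labels.append(self.events[k].label)
        return labels


@dataclass(frozen=True)
class FluxTraceSet:
    """Validated per-well OCR/ECAR kinetic traces for one plate.

    ``data`` holds columns well, group, experiment, measurement, time_min,
    ocr, ecar (plus phase once assigned), canonically sorted by
    (well, measurement). All wells on a plate share one injection schedule.
    """

    data: pd.DataFrame
    cell_counts: Mapping[str, int] | None = None
    normalized: bool = False
    schedule: InjectionSchedule | None = None

    def __post_init__(self) -> None:
        df = self.data
        required = {"well", "group", "experiment", "measurement", "time_min", "ocr", "ecar"}
        missing = required - set(df.columns)
        if missing:
            raise FluxFormatError(f"trace table lacks columns: {sorted(missing)}")
        df = df.sort_values(["well", "measurement"], kind="stable").reset_index(drop=True)
        for well, sub in df.groupby("well", sort=False):
            idx = sub["measurement"].to_numpy()
            if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
                raise ValueError(
                    f"well {well!r}: measurement indices must be contiguous from 1, got {idx.tolist()}"
                )
            t = sub["time_min"].to_numpy(dtype=float)
            if (t < 0).any() or (np.diff(t) <= 0).any():
                raise ValueError(f"well {well!r}: time_min must be nonnegative and strictly increasing")
        object.__setattr__(self, "data", df)

    @property
    def wells(self) -> list[str]:
        return list(dict.fromkeys(self.data["well"]))

    @property
    def n_measurements(self) -> int:
        return int(self.data["measurement"].max())

    def to_csv(self, path_or_buf=None):
        """Write the long-format trace dialect (well,group,...,OCR,ECAR)."""
        out = self.data.rename(columns={"ocr": "OCR", "ecar": "ECAR"})
        cols = [c for c in TRACE_COLUMNS]
        return out[cols].to_csv(path_or_buf, index=False)


@dataclass(frozen=True)
class FluxMetrics:
    """Derived bioenergetic metrics for one well.

    Units follow the trace: pmol O2/min for OCR-derived metrics and
    mpH/min for basal ECAR (each per 1000 cells when normalized);
    ``ocr_ecar_ratio`` is dimensionless and NaN when basal ECAR is 0.
    ``src == maximal_ocr - basal_ocr`` holds by construction.
    """

    well: str
    group: str
    basal_ecar: float
    basal_ocr: float
    maximal_ocr: float
    src: float
    ocr_ecar_ratio: float
    flags: frozenset[str] = field(default_factory=frozenset)


def read_flux_table(path, schedule: InjectionSchedule | None = None) -> FluxTraceSet:
    """Read a long-format trace CSV into a validated :class:`FluxTraceSet`.

    Row order in the file is irrelevant: rows are canonically sorted by
    (well, measurement). Missing columns raise :class:`FluxFormatError`
    naming them; non-contiguous measurement indices raise naming the well.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FluxFormatError(f"trace table lacks columns: {missing}")
    df = df.rename(columns={"OCR": "ocr", "ECAR": "ecar"})
    df["measurement"] = df["measurement"].astype(int)
    for col in ("time_min", "ocr", "ecar"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    ts = FluxTraceSet(data=df, schedule=schedule)
    if schedule is not None:
        ts = assign_phases(ts, schedule)
    return ts


def read_cell_counts(path) -> dict[str, int]:
    """Read a (well, cells) CSV into a mapping."""
    df = pd.read_csv(path)
    for col in ("well", "cells"):
        if col not in df.columns:
            raise FluxFormatError(f"cell-count table lacks column: {col!r}")
    if df["well"].duplicated().any():
        dup = df.loc[df["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate wells in cell-count table: {dup}")
    return {str(w): int(c) for w, c in zip(df["well"], df["cells"])}


def normalize_per_well(
    traces: FluxTraceSet,
    cell_counts: Mapping[str, int] | None = None,
    unit_cells: int = 1000,
) -> FluxTraceSet:
    """Divide each well's OCR and ECAR by its cell count / ``unit_cells``.

    Rates become "per unit_cells cells" (default per 1000). A second
    normalization of the same trace set is refused.
    """
    if traces.normalized:
        raise ValueError("trace set is already normalized; refusing to normalize twice")
    counts = cell_counts if cell_counts is not None else traces.cell_counts
    if counts is None:
        raise ValueError("no cell counts supplied")
    missing = [w for w in traces.wells if w not in counts]
    if missing:
        raise ValueError(f"missing cell count for wells: {missing}")
    bad = [w for w in traces.wells if counts[w] <= 0]
    if bad:
        raise ValueError(f"non-positive cell count for wells: {bad}")
    df = traces.data.copy()
    scale = df["well"].map(lambda w: counts[w] / unit_cells).astype(float)
    df["ocr"] = df["ocr"] / scale
    df["ecar"] = df["ecar"] / scale
    return replace(traces, data=df, cell_counts=dict(counts), normalized=True)


def assign_phases(traces: FluxTraceSet, schedule: InjectionSchedule) -> FluxTraceSet:
    """Label every record with its injection phase.

    Both FCCP injections fall in the single ``fccp`` phase. A schedule
    index beyond the last measurement is an error.
    """
    labels = schedule.phase_labels(traces.n_measurements)
    df = traces.data.copy()
    df["phase"] = [labels[i - 1] for i in df["measurement"]]
    return replace(traces, data=df, schedule=schedule)


def _phase_values(
    sub: pd.DataFrame, phase: str, column: str, exclude_first: bool, well: str
) -> np.ndarray:
    rows = sub[sub["phase"] == phase]
    if exclude_first and phase != "baseline" and len(rows) > 1:
        rows = rows.iloc[1:]
    vals = rows[column].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"well {well!r}: phase {phase!r} has no usable measurements")
    return vals


def compute_well_metrics(
    trace: pd.DataFrame,
    baseline_mode: Literal["mean", "last"] = "mean",
    exclude_first_post_injection: bool = False,
) -> FluxMetrics:
    """Derive the bioenergetic metrics for a single well.

    Parameters
    ----------
    trace
        Phase-annotated rows of one well (columns well, group, measurement,
        phase, ocr, ecar).
    baseline_mode
        "mean" averages all baseline measurements; "last" uses the final
        pre-injection measurement only.
    exclude_first_post_injection
        Drop the first measurement of each post-injection phase to discard
        mixing transients (off by default).

    Notes
    -----
    The Rot/AA floor is the mean of the rot_aa phase; maximum OCR is the
    single largest post-FCCP measurement. Negative basal or maximal OCR is
    returned unchanged and flagged (``negative_basal_ocr`` /
    ``negative_maximal_ocr``), never clipped.
    """
    if "phase" not in trace.columns:
        raise ValueError("trace has no phase labels; call assign_phases first")
    wells = trace["well"].unique()
    if len(wells) != 1:
        raise ValueError(f"compute_well_metrics expects one well, got {wells.tolist()}")
    well = str(wells[0])
    if baseline_mode not in ("mean", "last"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    sub = trace.sort_values("measurement", kind="stable")
    for phase in PHASES:
        if not (sub["phase"] == phase).any():
            raise ValueError(f"well {well!r}: phase {phase!r} has no measurements")

    base_ocr = _phase_values(sub, "baseline", "ocr", False, well)
    base_ecar = _phase_values(sub, "baseline", "ecar", False, well)
    rotaa_ocr = _phase_values(sub, "rot_aa", "ocr", exclude_first_post_injection, well)
    fccp_ocr = _phase_values(sub, "fccp", "ocr", exclude_first_post_injection, well)

    if baseline_mode == "mean":
        baseline_ocr = float(base_ocr.mean())
        basal_ecar = float(base_ecar.mean())
    else:
        baseline_ocr = float(base_ocr[-1])
        basal_ecar = float(base_ecar[-1])
    rotaa = float(rotaa_ocr.mean())
    max_ocr = float(fccp_ocr.max())

    basal_ocr = baseline_ocr - rotaa
    maximal_ocr = max_ocr - rotaa
    src = maximal_ocr - basal_ocr

    flags = set()
    if basal_ocr < 0:
        flags.add("negative_basal_ocr")
    if maximal_ocr < 0:
        flags.add("negative_maximal_ocr")
    if basal_ecar != 0.0:
        ratio = basal_ocr / basal_ecar
    else:
        ratio = float("nan")
        flags.add("zero_basal_ecar")

    return FluxMetrics(
        well=well,
        group=str(sub["group"].iloc[0]),
        basal_ecar=basal_ecar,
        basal_ocr=basal_ocr,
        maximal_ocr=maximal_ocr,
        src=src,
        ocr_ecar_ratio=ratio,
        flags=frozenset(flags),
    )


def compute_plate_metrics(
    traces: FluxTraceSet,
    schedule: InjectionSchedule | None = None,
    baseline_mode: Literal["mean", "last"] = "mean",
    exclude_first_post_injection: bool = False,
) -> pd.DataFrame:
    """Per-well metrics for a whole plate, one row per well.

    Returns a frame with columns well, group, the five metrics, and a
    comma-joined ``flags`` column.
    """
    ts = traces
    if "phase" not in ts.data.columns:
        sched = schedule or ts.schedule
        if sched is None:
            raise ValueError("no injection schedule available to assign phases")
        ts = assign_phases(ts, sched)
    rows = []
    for well, sub in ts.data.groupby("well", sort=False):
        m = compute_well_metrics(
            sub,
            baseline_mode=baseline_mode,
            exclude_first_post_injection=exclude_first_post_injection,
        )
        rows.append(
            {
                "well": m.well,
                "group": m.group,
                "basal_ecar": m.basal_ecar,
                "basal_ocr": m.basal_ocr,
                "maximal_ocr": m.maximal_ocr,
                "src": m.src,
                "ocr_ecar_ratio": m.ocr_ecar_ratio,
                "flags": ",".join(sorted(m.flags)),
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample sd per (group, metric) over technical-replicate wells.

    Single-well groups report sd as NaN (undefined), not zero.
    Returns a tidy frame (group, metric, mean, sd, n).
    """
    rows = []
    for group, sub in metrics.groupby("group", sort=False):
        for metric in METRIC_NAMES:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            n = vals.size
            mean = float(vals.mean()) if n else float("nan")
            sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
            rows.append({"group": group, "metric": metric, "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows)


def compare_groups(
    metrics: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    metric_names: Sequence[str] = METRIC_NAMES,
    variant: Literal["welch", "student"] = "welch",
) -> pd.DataFrame:
    """Two-tailed unpaired t tests between group pairs, BH-adjusted.

    The BH family is exactly the set of (pair, metric) comparisons made in
    this call; the caller controls family scope. Each group in a pair needs
    at least two wells.
    """
    rows = []
    for ga, gb in pairs:
        for metric in metric_names:
            a = metrics.loc[metrics["group"] == ga, metric].dropna().to_numpy(dtype=float)
            b = metrics.loc[metrics["group"] == gb, metric].dropna().to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                raise ValueError(
                    f"comparison {ga!r} vs {gb!r} on {metric!r}: each group needs >= 2 wells "
                    f"(got {a.size} and {b.size})"
                )
            res = two_sample_t(a, b, variant=variant)
            rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_a": float(a.mean()),
                    "sd_a": float(a.std(ddof=1)),
                    "n_a": int(a.size),
                    "mean_b": float(b.mean()),
                    "sd_b": float(b.std(ddof=1)),
                    "n_b": int(b.size),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
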