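"""Canonical session data model and on-disk round-trip.

A recording session is represented by four artifacts:

``SpikeRaster``
    Per-unit spike counts on a uniform 1 ms grid (units x bins), with one
    :class:`UnitMeta` record per row.  All downstream analyses (rate
    summaries, decoding features, modulation depth) consume this raster.
``TrialLog``
    The ordered list of finger-brushing trials (start, duration, finger,
    movement flag, session label).  Stored as a pandas DataFrame.
``SessionTimeline``
    Drug-onset time and the named analysis windows (pre-drug baseline,
    drug period, and the labelled brushing sessions).
``BroadbandSignal``
    A raw field-potential channel for the spectral stage.

Conventions: the session clock is in seconds with t = 0 at recording start;
windows are half-open ``[start, end)``; 1 ms bin ``k`` covers ``[k, k+1)`` ms,
so an event at time ``t`` seconds lands in bin ``floor(1000 * t)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

BIN_MS = 1
SESSION_LABELS = ("pre", "early", "late")

TRIAL_COLUMNS = ["start_s", "duration_s", "finger", "movement_flag", "session_label"]


# ---------------------------------------------------------------------------
# unit metadata


@dataclass(frozen=True)
class UnitMeta:
    """Identity and sort quality of one recorded unit.

    ``sort_score`` follows the 1-4 convention of manual sorting: 1 is noise
    (excluded), 2 a sorted multiunit, 3-4 an isolated single unit.  Units
    never passed through sorting carry ``unsorted=True`` and are the
    "unsorted multiunit" population used for decoding and modulation depth.
    """

    unit_id: int
    channel: int = -1
    sort_score: int = 2
    unsorted: bool = False

    def __post_init__(self) -> None:
        if not 1 <= int(self.sort_score) <= 4:
            raise ValidationError(f"sort_score must be 1-4, got {self.sort_score}")

    @property
    def category(self) -> str:
        if self.unsorted:
            return "unsorted-multiunit"
        return {1: "excluded", 2: "sorted-multiunit", 3: "single-unit", 4: "single-unit"}[
            int(self.sort_score)
        ]


# ---------------------------------------------------------------------------
# raster


@dataclass
class SpikeRaster:
    """Units x 1 ms bins spike-count matrix with per-unit metadata."""

    counts: np.ndarray
    units: list[UnitMeta]
    t0: float = 0.0
    bin_ms: int = BIN_MS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (units x bins)")
        if np.any(self.counts < 0):
            raise ValidationError("spike counts must be non-negative")
        if len(self.units) != self.counts.shape[0]:
            raise ValidationError(
                f"{len(self.units)} unit records for {self.counts.shape[0]} rows"
            )
        if self.bin_ms != BIN_MS:
            raise ValidationError("the raster grid is fixed at 1 ms bins")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_ms / 1000.0

    def bin_of(self, time_s: float) -> int:
        return int(np.floor(time_s * 1000.0 / self.bin_ms))

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (
            self.units == other.units
            and self.t0 == other.t0
            and self.counts.shape == other.counts.shape
            and bool(np.array_equal(self.counts, other.counts))
        )


def bin_events(
    events: Iterable[tuple[int, float]],
    duration_s: float,
    units: Sequence[UnitMeta] | None = None,
) -> SpikeRaster:
    """Bin ``(unit_id, time_s)`` events onto the 1 ms grid.

    Times must lie in ``[0, duration_s)``.  ``units`` defaults to one record
    per distinct unit_id in ascending order; unit_ids absent from ``events``
    but present in ``units`` yield all-zero rows.
    """
    ev = list(events)
    n_bins = int(round(duration_s * 1000.0))
    if units is None:
        ids = sorted({int(u) for u, _ in ev})
        units = [UnitMeta(unit_id=i) for i in ids]
    row = {u.unit_id: k for k, u in enumerate(units)}
    counts = np.zeros((len(units), n_bins), dtype=np.int32)
    for unit_id, t in ev:
        if not 0.0 <= t < duration_s:
            raise ValidationError(f"event time {t} outside [0, {duration_s})")
        if int(unit_id) not in row:
            raise ValidationError(f"event for unknown unit_id {unit_id}")
        counts[row[int(unit_id)], int(np.floor(t * 1000.0))] += 1
    return SpikeRaster(counts=counts, units=list(units))


def slice_window(raster: SpikeRaster, window: tuple[float, float]) -> SpikeRaster:
    """Return the half-open ``[start_s, end_s)`` slice of a raster.

    Adjacent slices concatenate back to the original counts exactly.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValidationError(f"inverted window {window}")
    b0, b1 = raster.bin_of(start_s), raster.bin_of(end_s)
    if b0 < 0 or b1 > raster.n_bins:
        raise ValidationError(f"window {window} outside raster span [0, {raster.duration_s})")
    return SpikeRaster(
        counts=raster.counts[:, b0:b1].copy(),
        units=list(raster.units),
        t0=raster.t0 + start_s,
    )


# ---------------------------------------------------------------------------
# trials


def make_trial_log(records: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a trial log DataFrame.

    Columns: start_s, duration_s, finger (1-based int), movement_flag (bool),
    session_label in {pre, early, late}.  Trials must be time-ordered and
    non-overlapping.
    """
    df = pd.DataFrame(records).reset_index(drop=True)
    if df.empty:
        df = pd.DataFrame(columns=TRIAL_COLUMNS)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial log missing columns {missing}")
    df = df[TRIAL_COLUMNS].astype(
        {"start_s": float, "duration_s": float, "finger": int, "movement_flag": bool}
    )
    bad = set(df["session_label"]) - set(SESSION_LABELS)
    if bad:
        raise ValidationError(f"unknown session labels {sorted(bad)}")
    if (df["finger"] < 1).any():
        raise ValidationError("finger labels are 1-based positive integers")
    starts = df["start_s"].to_numpy()
    ends = starts + df["duration_s"].to_numpy()
    if np.any(np.diff(starts) <= 0):
        raise ValidationError("trial starts must be strictly increasing")
    if np.any(ends[:-1] > starts[1:]):
        raise ValidationError("trials overlap")
    return df


# ---------------------------------------------------------------------------
# timeline


@dataclass
class SessionTimeline:
    """Drug onset and named analysis windows, all in session seconds."""

    t_drug_on: float
    pre_window: tuple[float, float]
    drug_window: tuple[float, float]
    brushing_sessions: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pre_window[1] > self.t_drug_on:
            raise ValidationError("pre_window must end at or before drug onset")
        if self.drug_window[0] < self.t_drug_on:
            raise ValidationError("drug_window must start at drug onset")
        for w in (self.pre_window, self.drug_window):
            if w[1] <= w[0]:
                raise ValidationError(f"inverted window {w}")
        by_label: dict[str, list[tuple[float, float]]] = {}
        for label, s, e in self.brushing_sessions:
            if label not in SESSION_LABELS:
                raise ValidationError(f"unknown brushing-session label {label!r}")
            if e <= s:
                raise ValidationError(f"inverted brushing window ({s}, {e})")
            by_label.setdefault(label, []).append((s, e))
        for label, wins in by_label.items():
            wins = sorted(wins)
            for (s0, e0), (s1, e1) in zip(wins, wins[1:]):
                if e0 > s1:
                    raise ValidationError(f"overlapping {label!r} brushing windows")

    @property
    def duration_s(self) -> float:
        ends = [self.drug_window[1]] + [e for _, _, e in self.brushing_sessions]
        return float(max(ends))

    def brushing_window(self, label: str) -> tuple[float, float]:
        wins = [(s, e) for lab, s, e in self.brushing_sessions if lab == label]
        if not wins:
            raise ValidationError(f"no brushing session labelled {label!r}")
        return wins[0]


# ---------------------------------------------------------------------------
# broadband


@dataclass
class BroadbandSignal:
    """A continuously sampled field-potential channel."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim not in (1, 2):
            raise ValidationError("samples must be 1-D or (channels x samples)")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("broadband samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# on-disk layout
#
#   spikes.csv        unit_id,time_ms  (one row per spike; time_ms = bin index)
#   units.csv         unit_id,channel,sort_score,unsorted
#   trials.csv        start_s,duration_s,finger,movement_flag,session_label
#   timeline.json     t_drug_on, pre_window, drug_window, brushing_sessions
#   raster.json       n_bins, t0  (so empty tails round-trip)
#   broadband.h5      dataset "samples", attrs fs, t0
#   ground_truth.json optional generator ground truth


def write_session(
    path: str | Path,
    raster: SpikeRaster | None = None,
    trials: pd.DataFrame | None = None,
    timeline: SessionTimeline | None = None,
    broadband: BroadbandSignal | None = None,
    ground_truth: dict | None = None,
) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if raster is not None:
        unit_rows, time_rows = np.nonzero(raster.counts)
        reps = raster.counts[unit_rows, time_rows]
        pd.DataFrame(
            {
                "unit_id": np.repeat([raster.units[i].unit_id for i in unit_rows], reps),
                "time_ms": np.repeat(time_rows, reps),
            }
        ).to_csv(path / "spikes.csv", index=False)
        pd.DataFrame(
            [
                {
                    "unit_id": u.unit_id,
                    "channel": u.channel,
                    "sort_score": u.sort_score,
                    "unsorted": u.unsorted,
                }
                for u in raster.units
            ]
        ).to_csv(path / "units.csv", index=False)
        (path / "raster.json").write_text(
            json.dumps({"n_bins": raster.n_bins, "t0": raster.t0})
        )
    if trials is not None:
        make_trial_log(trials).to_csv(path / "trials.csv", index=False)
    if timeline is not None:
        (path / "timeline.json").write_text(json.dumps(asdict(timeline)))
    if broadband is not None:
        with h5py.File(path / "broadband.h5", "w") as f:
            d = f.create_dataset("samples", data=broadband.samples)
            d.attrs["fs"] = broadband.fs
            d.attrs["t0"] = broadband.t0
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(json.dumps(ground_truth))
    return path


def read_session(path: str | Path) -> dict:
    """Read back whatever artifacts are present under ``path``.

    Returns a dict with any of the keys raster, trials, timeline, broadband,
    ground_truth.  ``read_session(write_session(x)) == x`` field by field.
    """
    path = Path(path)
    out: dict = {}
    if (path / "spikes.csv").exists():
        meta = pd.read_csv(path / "units.csv")
        units = [
            UnitMeta(
                unit_id=int(r.unit_id),
                channel=int(r.channel),
                sort_score=int(r.sort_score),
                unsorted=bool(r.unsorted),
            )
            for r in meta.itertuples()
        ]
        hdr = json.loads((path / "raster.json").read_text())
        spikes = pd.read_csv(path / "spikes.csv")
        counts = np.zeros((len(units), int(hdr["n_bins"])), dtype=np.int32)
        row = {u.unit_id: k for k, u in enumerate(units)}
        for rec in spikes.itertuples():
            if int(rec.unit_id) not in row:
                raise ParseError(f"spikes.csv row {rec.Index}: unknown unit_id {rec.unit_id}")
            if not 0 <= int(rec.time_ms) < counts.shape[1]:
                raise ParseError(f"spikes.csv row {rec.Index}: time_ms {rec.time_ms} out of range")
            counts[row[int(rec.unit_id)], int(rec.time_ms)] += 1
        out["raster"] = SpikeRaster(counts=counts, units=units, t0=float(hdr["t0"]))
    if (path / "trials.csv").exists():
        df = pd.read_csv(path / "trials.csv")
        try:
            out["trials"] = make_trial_log(df)
        except ValidationError as exc:
            raise ParseError(f"trials.csv: {exc}") from exc
    if (path / "timeline.json").exists():
        d = json.loads((path / "timeline.json").read_text())
        out["timeline"] = SessionTimeline(
            t_drug_on=d["t_drug_on"],
            pre_window=tuple(d["pre_window"]),
            drug_window=tuple(d["drug_window"]),
            brushing_sessions=[tuple(w) for w in d["brushing_sessions"]],
        )
    if (path / "broadband.h5").exists():
        with h5py.File(path / "broadband.h5", "r") as f:
            d = f["samples"]
            out["broadband"] = BroadbandSignal(
                samples=d[...], fs=float(d.attrs["fs"]), t0=float(d.attrs["t0"])
            )
    if (path / "ground_truth.json").exists():
        out["ground_truth"] = json.loads((path / "ground_truth.json").read_text())
    return out
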