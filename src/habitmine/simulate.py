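"""Synthetic single-resident smart home emitting CASAS-format event logs.

The simulator stands in for real testbed data: a resident follows a daily
schedule of labelled activities (jittered clock times, log-normal
durations), each activity fires ON/OFF pairs from its own sensor set,
planted habits trigger a consequent activity a short sampled gap after
their antecedent ends, decoy pairs co-occur daily but hours apart, a
temperature sensor logs periodically, and spurious noise events
interleave. The emitted log parses with :mod:`habitmine.casas` and carries
begin/end annotations, so both halves of the pipeline — classification and
habit mining — can be tested against a known ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np

from .casas import (BEGIN, END, ActivityAnnotation, Record, SensorEvent,
                    label_events, write_events)
from .mining import PlantedHabit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityDef:
    """How one activity behaves when it runs."""

    label: str
    room: str
    sensors: tuple[str, ...]        # sensors it fires (motion M###, door D###)
    mean_duration_s: float
    duration_sd_s: float            # sd of the log-normal duration, in seconds
    events_per_minute: float        # ON/OFF pair firing rate


@dataclass(frozen=True)
class ScheduledActivity:
    """A daily schedule entry: activity at a jittered clock time."""

    label: str
    clock_s: float       # mean start, seconds after midnight
    jitter_sd_s: float


@dataclass(frozen=True)
class HabitSpec:
    """A planted habit: consequent follows antecedent after a short gap."""

    antecedent: str
    consequent: str
    gap_mean_s: float
    gap_sd_s: float
    adherence: float     # probability the consequent is triggered


@dataclass(frozen=True)
class DecoySpec:
    """A frequently co-occurring pair separated by a long gap (not a habit)."""

    first: str
    second: str


@dataclass
class HomeSpec:
    """Full description of the simulated home and resident."""

    activities: dict[str, ActivityDef]
    schedule: list[ScheduledActivity]
    habits: list[HabitSpec]
    decoys: list[DecoySpec]
    temperature_sensor: Optional[str] = "T001"
    temperature_period_s: float = 1800.0
    temperature_mean: float = 21.0
    temperature_sd: float = 1.5
    noise_rate: float = 0.02          # spurious events as a fraction of real ones
    n_days: int = 60
    seed: int = 7
    start_date: date = date(2024, 1, 1)

    def __post_init__(self) -> None:
        for s in self.schedule:
            if s.label not in self.activities:
                raise ValueError(f"scheduled activity {s.label!r} is not defined")
        for h in self.habits:
            if h.antecedent not in self.activities or h.consequent not in self.activities:
                raise ValueError(f"habit references undefined activity: {h}")
            if not (0.0 <= h.adherence <= 1.0):
                raise ValueError("habit adherence must be in [0, 1]")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        all_sensors = self.all_sensors()
        if len(all_sensors) != len(set(all_sensors)):
            raise ValueError("sensor ids must be unique")

    def all_sensors(self) -> list[str]:
        seen: list[str] = []
        for a in self.activities.values():
            for s in a.sensors:
                if s not in seen:
                    seen.append(s)
        if self.temperature_sensor and self.temperature_sensor not in seen:
            seen.append(self.temperature_sensor)
        return seen


@dataclass
class GroundTruth:
    """What was planted: per-event labels, habits and decoys."""

    event_labels: list[str]
    planted_habits: list[PlantedHabit]
    decoy_pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    n_days: int
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "n_days": self.n_days,
            "seed": self.seed,
            "planted_habits": [
                {
                    "antecedent": sorted([list(i) for i in h.antecedent]),
                    "consequent": sorted([list(i) for i in h.consequent]),
                    "gap_tolerance_s": h.gap_tolerance_s,
                }
                for h in self.planted_habits
            ],
            "decoy_pairs": [[list(a), list(b)] for a, b in self.decoy_pairs],
            "event_labels": self.event_labels,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        habits = [
            PlantedHabit(
                frozenset(tuple(i) for i in h["antecedent"]),
                frozenset(tuple(i) for i in h["consequent"]),
                h["gap_tolerance_s"],
            )
            for h in d["planted_habits"]
        ]
        decoys = [(tuple(a), tuple(b)) for a, b in d["decoy_pairs"]]
        return cls(d["event_labels"], habits, decoys, d["n_days"], d["seed"])


@dataclass
class _Instance:
    label: str
    start: datetime
    end: datetime


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal sample parameterised by its own mean and sd."""
    var = sd * sd
    mu = np.log(mean * mean / np.sqrt(var + mean * mean))
    sigma = np.sqrt(np.log(1.0 + var / (mean * mean)))
    return float(rng.lognormal(mu, sigma))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor: float = 1.0) -> float:
    return max(floor, float(rng.normal(mean, sd)))


def generate(spec: HomeSpec) -> tuple[list[Record], GroundTruth]:
    """Simulate ``spec.n_days`` days of sensor events.

    Returns the annotated event records (time-ordered, begin/end matched)
    and the ground truth. Deterministic for a fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    habit_by_antecedent: dict[str, list[HabitSpec]] = {}
    for h in spec.habits:
        habit_by_antecedent.setdefault(h.antecedent, []).append(h)

    records: list[Record] = []
    for day_i in range(spec.n_days):
        day0 = datetime.combine(spec.start_date + timedelta(days=day_i), datetime.min.time())

        # --- schedule activity instances, then habit-triggered consequents
        instances: list[_Instance] = []
        pending = [
            (_positive_normal(rng, s.clock_s, s.jitter_sd_s, floor=0.0), s.label)
            for s in spec.schedule
        ]
        pending.sort()
        queue = [(day0 + timedelta(seconds=t), label) for t, label in pending]
        while queue:
            start, label = queue.pop(0)
            adef = spec.activities[label]
            dur = _lognormal(rng, adef.mean_duration_s, adef.duration_sd_s)
            if instances and start < instances[-1].end:
                # overlapping schedule: queue behind the running activity
                logger.debug("queueing %s behind %s on day %d", label,
                             instances[-1].label, day_i)
                start = instances[-1].end + timedelta(seconds=30)
            end = start + timedelta(seconds=dur)
            instances.append(_Instance(label, start, end))
            for habit in habit_by_antecedent.get(label, []):
                if rng.random() < habit.adherence:
                    gap = _positive_normal(rng, habit.gap_mean_s, habit.gap_sd_s, floor=30.0)
                    trigger = end + timedelta(seconds=gap)
                    # insert keeping the queue time-ordered
                    queue.append((trigger, habit.consequent))
                    queue.sort(key=lambda q: q[0])

        # --- emit sensor events per instance
        day_records: list[Record] = []
        for inst in instances:
            adef = spec.activities[inst.label]
            dur_s = (inst.end - inst.start).total_seconds()
            n_pairs = max(1, int(rng.poisson(adef.events_per_minute * dur_s / 60.0 / 2.0)))
            pair_starts = np.sort(rng.uniform(0.0, max(dur_s - 20.0, 1.0), size=n_pairs))
            pair_starts[0] = 0.0
            evs: list[Record] = []
            for k, t0 in enumerate(pair_starts):
                sensor = adef.sensors[rng.integers(len(adef.sensors))]
                on, off = ("OPEN", "CLOSE") if sensor.startswith("D") else ("ON", "OFF")
                t_on = inst.start + timedelta(seconds=float(t0))
                hold = float(rng.uniform(2.0, 15.0))
                t_off = min(t_on + timedelta(seconds=hold), inst.end)
                if k == n_pairs - 1:
                    t_off = inst.end
                evs.append((SensorEvent(t_on, sensor, on), None))
                evs.append((SensorEvent(t_off, sensor, off), None))
            evs.sort(key=lambda r: r[0].timestamp)
            evs[0] = (evs[0][0], ActivityAnnotation(inst.label, BEGIN))
            evs[-1] = (evs[-1][0], ActivityAnnotation(inst.label, END))
            day_records.extend(evs)

        # --- periodic temperature readings
        if spec.temperature_sensor:
            t = day0 + timedelta(seconds=float(rng.uniform(0, spec.temperature_period_s)))
            day_end = day0 + timedelta(days=1)
            while t < day_end:
                value = f"{rng.normal(spec.temperature_mean, spec.temperature_sd):.1f}"
                day_records.append((SensorEvent(t, spec.temperature_sensor, value), None))
                t += timedelta(seconds=spec.temperature_period_s)

        # --- spurious noise events
        sensors = [s for s in spec.all_sensors() if s != spec.temperature_sensor]
        n_noise = rng.poisson(spec.noise_rate * len(day_records))
        for _ in range(n_noise):
            t = day0 + timedelta(seconds=float(rng.uniform(0, 86400)))
            sensor = sensors[rng.integers(len(sensors))]
            on, off = ("OPEN", "CLOSE") if sensor.startswith("D") else ("ON", "OFF")
            value = on if rng.random() < 0.5 else off
            day_records.append((SensorEvent(t, sensor, value), None))

        day_records.sort(key=lambda r: r[0].timestamp)
        records.extend(day_records)

    records.sort(key=lambda r: r[0].timestamp)
    labels = [label for _, label in label_events(records)]
    truth = GroundTruth(
        event_labels=labels,
        planted_habits=_planted_habits(spec),
        decoy_pairs=_decoy_items(spec),
        n_days=spec.n_days,
        seed=spec.seed,
    )
    return records, truth


def _expected_start_s(spec: HomeSpec, label: str) -> float:
    """Mean clock time at which ``label`` starts, following habit chains."""
    for s in spec.schedule:
        if s.label == label:
            return s.clock_s
    for h in spec.habits:
        if h.consequent == label:
            ant = spec.activities[h.antecedent]
            return _expected_start_s(spec, h.antecedent) + ant.mean_duration_s + h.gap_mean_s
    raise ValueError(f"activity {label!r} is neither scheduled nor habit-triggered")


def _expected_bin(spec: HomeSpec, label: str, via: Optional[HabitSpec] = None) -> int:
    start = _expected_start_s(spec, label) if via is None else (
        _expected_start_s(spec, via.antecedent)
        + spec.activities[via.antecedent].mean_duration_s + via.gap_mean_s)
    return int(start // 3600) % 24


def _planted_habits(spec: HomeSpec) -> list[PlantedHabit]:
    out = []
    for h in spec.habits:
        ant_item = (h.antecedent, _expected_bin(spec, h.antecedent))
        cons_item = (h.consequent, _expected_bin(spec, h.consequent, via=h))
        out.append(PlantedHabit(frozenset([ant_item]), frozenset([cons_item]),
                                gap_tolerance_s=1800.0))
    return out


def _decoy_items(spec: HomeSpec) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    return [
        ((d.first, _expected_bin(spec, d.first)), (d.second, _expected_bin(spec, d.second)))
        for d in spec.decoys
    ]


def write_scenario(spec: HomeSpec, log_path: str | Path,
                   truth_path: str | Path | None = None) -> GroundTruth:
    """Generate and write the log (+ ground-truth JSON alongside)."""
    records, truth = generate(spec)
    write_events(records, log_path, header=f"synthetic home log, seed={spec.seed}")
    if truth_path is not None:
        truth.to_json(truth_path)
    return truth


def default_scenario(seed: int = 7, n_days: int = 60) -> HomeSpec:
    """The standard test-bed scenario.

    Five activities of daily living over 8 sensors and 60 days; three
    planted short-gap habits (post-sleep toileting, cooking then eating,
    evening toileting after relaxing), two long-gap decoy pairs that
    co-occur almost daily, periodic temperature readings and 2% spurious
    noise. Sized so the full pipeline runs in minutes on one CPU.
    """
    activities = {
        "Sleeping": ActivityDef("Sleeping", "bedroom", ("M001",),
                                mean_duration_s=6.7 * 3600, duration_sd_s=8 * 60,
                                events_per_minute=0.14),
        "Toileting": ActivityDef("Toileting", "bathroom", ("M002", "D001"),
                                 mean_duration_s=10 * 60, duration_sd_s=2 * 60,
                                 events_per_minute=1.6),
        "MealPrep": ActivityDef("MealPrep", "kitchen", ("M003", "D002"),
                                mean_duration_s=18 * 60, duration_sd_s=3 * 60,
                                events_per_minute=1.6),
        "Eating": ActivityDef("Eating", "dining", ("M004",),
                              mean_duration_s=20 * 60, duration_sd_s=3 * 60,
                              events_per_minute=1.3),
        "Relaxing": ActivityDef("Relaxing", "living", ("M005",),
                                mean_duration_s=60 * 60, duration_sd_s=7 * 60,
                                events_per_minute=0.75),
    }
    schedule = [
        ScheduledActivity("Sleeping", clock_s=40 * 60, jitter_sd_s=8 * 60),        # ~00:40
        ScheduledActivity("MealPrep", clock_s=11 * 3600 + 20 * 60, jitter_sd_s=7 * 60),  # ~11:20
        ScheduledActivity("Relaxing", clock_s=20 * 3600 + 25 * 60, jitter_sd_s=7 * 60),  # ~20:25
    ]
    habits = [
        HabitSpec("Sleeping", "Toileting", gap_mean_s=6 * 60, gap_sd_s=90, adherence=0.95),
        HabitSpec("MealPrep", "Eating", gap_mean_s=5 * 60, gap_sd_s=90, adherence=0.95),
        HabitSpec("Relaxing", "Toileting", gap_mean_s=6 * 60, gap_sd_s=90, adherence=0.95),
    ]
    decoys = [
        DecoySpec("Sleeping", "Relaxing"),   # ~19 h apart, co-occur daily
        DecoySpec("Eating", "Relaxing"),     # ~8 h apart, co-occur on most days
    ]
    return HomeSpec(
        activities=activities,
        schedule=schedule,
        habits=habits,
        decoys=decoys,
        noise_rate=0.02,
        n_days=n_days,
        seed=seed,
    )
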