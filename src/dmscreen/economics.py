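"""Health-economic evaluation of a screening strategy.

Three per-participant quantities are computed from a cascade's record
table:

* the proportion of participants requiring the confirmatory test;
* the average detection cost — the sum over participants of the medical
  plus non-medical cost of every test in their trail, divided by the
  number of participants;
* the potential complication cost attributed to false negatives: each
  missed diabetic accrues an annual complication cost within a printed
  (low, high) range that depends on the projection horizon, and the
  total is again divided by the number of participants.

The default cost schedule carries the published Chinese prices (CNY):
medical 9.89 / 23.56 / 33.45 / 84.16 and non-medical 8.3 / 27.5 / 27.5 /
8.3 for FPG / 2hPG / OGTT / HbA1c, and per-diabetic annual complication
ranges of 341–567, 1302–2555, 2802–5611, 4428–8212 and 5258–9132 CNY
over 5, 10, 15, 20 and 25 years. No discounting is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "CostSchedule",
    "EconomicSummary",
    "EconomicsError",
    "proportion_confirmatory",
    "detection_cost",
    "complication_cost",
    "summarize",
]


class EconomicsError(ValueError):
    pass


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs per test and per-diabetic annual complication ranges."""

    medical: dict[str, float]
    nonmedical: dict[str, float]
    #: horizon (years) -> (low, high) CNY per diabetic per year
    complication_per_dm_year: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, m in (("medical", self.medical), ("nonmedical", self.nonmedical)):
            if any(v < 0 for v in m.values()):
                raise EconomicsError(f"{name} costs must be non-negative")
        prev_lo = prev_hi = 0.0
        for h in sorted(self.complication_per_dm_year):
            lo, hi = self.complication_per_dm_year[h]
            if lo < 0 or lo > hi:
                raise EconomicsError(f"complication bounds at horizon {h} must satisfy "
                                     "0 <= low <= high")
            if lo < prev_lo or hi < prev_hi:
                raise EconomicsError("complication bounds must be non-decreasing in horizon")
            prev_lo, prev_hi = lo, hi

    def unit_cost(self, test: str) -> float:
        """Medical plus non-medical cost of one test."""
        if test not in self.medical or test not in self.nonmedical:
            raise EconomicsError(f"test {test!r} is not priced in the cost schedule")
        return self.medical[test] + self.nonmedical[test]

    @classmethod
    def default(cls) -> "CostSchedule":
        """The published default prices, loaded from the shipped YAML."""
        text = resources.files("dmscreen.data").joinpath("costs_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, d: dict) -> "CostSchedule":
        return cls(
            medical={str(k): float(v) for k, v in d["medical"].items()},
            nonmedical={str(k): float(v) for k, v in d["nonmedical"].items()},
            complication_per_dm_year={
                int(k): (float(v[0]), float(v[1]))
                for k, v in d["complication_per_dm_year"].items()},
        )

    def to_dict(self) -> dict:
        return {
            "medical": dict(self.medical),
            "nonmedical": dict(self.nonmedical),
            "complication_per_dm_year": {
                int(k): [float(v[0]), float(v[1])]
                for k, v in self.complication_per_dm_year.items()},
        }


@dataclass
class EconomicSummary:
    """Per-participant economics of one strategy at one operating point."""

    n: int
    prop_confirmatory: float
    avg_detection_cost: float
    #: horizon -> (low, high) CNY per participant per year
    complication_cost_range: dict[int, tuple[float, float]]
    fn_count: int

    def to_json(self) -> str:
        d = asdict(self)
        d["complication_cost_range"] = {
            int(k): [v[0], v[1]] for k, v in self.complication_cost_range.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EconomicSummary":
        d = json.loads(text)
        d["complication_cost_range"] = {
            int(k): (v[0], v[1]) for k, v in d["complication_cost_range"].items()}
        return cls(**d)


def _check_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise EconomicsError("empty record set: economics are per participant")


def _test_counts(records: pd.DataFrame) -> dict[str, int]:
    """Total number of times each test name appears across all trails.

    Trails are highly repetitive (a handful of distinct strings per
    cascade), so counting distinct trails first keeps this O(unique).
    """
    counts: dict[str, int] = {}
    for trail, k in records["tests"].value_counts().items():
        if trail:
            for test in str(trail).split(";"):
                counts[test] = counts.get(test, 0) + int(k)
    return counts


def proportion_confirmatory(records: pd.DataFrame) -> float:
    """Fraction of participants whose trail includes a confirmatory test."""
    _check_records(records)
    return float(records["confirmatory"].mean())


def detection_cost(records: pd.DataFrame, schedule: CostSchedule) -> float:
    """Average detection cost per participant (CNY), medical + non-medical."""
    _check_records(records)
    counts = _test_counts(records)
    total = sum(schedule.unit_cost(test) * k for test, k in counts.items())
    return total / len(records)


def complication_cost(records: pd.DataFrame, schedule: CostSchedule,
                      horizon: int) -> tuple[float, float]:
    """(low, high) potential complication cost per participant per year."""
    _check_records(records)
    if horizon not in schedule.complication_per_dm_year:
        raise EconomicsError(
            f"unknown horizon {horizon}; available: "
            f"{sorted(schedule.complication_per_dm_year)}")
    fn = int((records["outcome"] == "FN").sum())
    lo, hi = schedule.complication_per_dm_year[horizon]
    n = len(records)
    return (fn * lo / n, fn * hi / n)


def summarize(records: pd.DataFrame, schedule: CostSchedule,
              horizons: tuple[int, ...] = (5, 10, 15, 20, 25)) -> EconomicSummary:
    """Bundle the three quantities over a shared participant count."""
    _check_records(records)
    return EconomicSummary(
        n=len(records),
        prop_confirmatory=proportion_confirmatory(records),
        avg_detection_cost=detection_cost(records, schedule),
        complication_cost_range={h: complication_cost(records, schedule, h)
                                 for h in horizons},
        fn_count=int((records["outcome"] == "FN").sum()),
    )
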