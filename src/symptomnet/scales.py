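"""Screening instruments and item-response tables.

The study design pairs the 5-item Primary Care PTSD Screen for DSM-5
(PC-PTSD-5; dichotomous 0/1 items, positive screen at total >= 2) with the
20-item Zung Self-Rating Depression Scale (SDS; four-point items 1-4,
potential depression at raw total >= 40).  This module defines those
instruments, validates respondent-by-item CSV tables against them, and
computes descriptive statistics and screening prevalences.

Conventions: sample standard deviation (n-1 denominator); missing data are
rejected, never imputed (the source survey forced complete responses); SDS
uses raw totals, not the 1.25-scaled index; reverse-keyed SDS items are
assumed to arrive already keyed for analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemDefinition",
    "ScaleBattery",
    "ResponseMatrix",
    "DescriptiveTable",
    "ValidationError",
    "default_battery",
    "load_responses",
    "item_descriptives",
    "screen_positive_rates",
]


class ValidationError(ValueError):
    """Raised when a response table violates its battery definition."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item: code, label, admissible levels, instrument tag."""

    item_id: str
    label: str
    levels: tuple[int, ...]
    instrument: str  # "PTSD" or "DEP"

    def __post_init__(self) -> None:
        lv = tuple(int(v) for v in self.levels)
        if len(lv) < 2 or any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(
                f"item {self.item_id!r}: levels must be strictly increasing, length >= 2"
            )
        object.__setattr__(self, "levels", lv)
        if self.instrument not in ("PTSD", "DEP"):
            raise ValueError(f"item {self.item_id!r}: instrument must be PTSD or DEP")


@dataclass(frozen=True)
class ScaleBattery:
    """Ordered collection of items with instrument-level screening cutoffs."""

    items: tuple[ItemDefinition, ...]
    ptsd_cutoff: int = 2
    dep_cutoff: int = 40

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in battery")
        lo_p, hi_p = self._range("PTSD")
        lo_d, hi_d = self._range("DEP")
        if self.ptsd_items and not (lo_p <= self.ptsd_cutoff <= hi_p):
            raise ValueError(f"ptsd_cutoff {self.ptsd_cutoff} outside [{lo_p}, {hi_p}]")
        if self.dep_items and not (lo_d <= self.dep_cutoff <= hi_d):
            raise ValueError(f"dep_cutoff {self.dep_cutoff} outside [{lo_d}, {hi_d}]")

    def _range(self, instrument: str) -> tuple[int, int]:
        its = [it for it in self.items if it.instrument == instrument]
        return (
            sum(it.levels[0] for it in its),
            sum(it.levels[-1] for it in its),
        )

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def ptsd_items(self) -> list[str]:
        return [it.item_id for it in self.items if it.instrument == "PTSD"]

    @property
    def dep_items(self) -> list[str]:
        return [it.item_id for it in self.items if it.instrument == "DEP"]

    @property
    def p(self) -> int:
        return len(self.items)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ptsd_cutoff": self.ptsd_cutoff,
            "dep_cutoff": self.dep_cutoff,
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "levels": list(it.levels),
                    "instrument": it.instrument,
                }
                for it in self.items
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleBattery":
        payload = json.loads(Path(path).read_text())
        items = tuple(
            ItemDefinition(
                item_id=d["item_id"],
                label=d["label"],
                levels=tuple(d["levels"]),
                instrument=d["instrument"],
            )
            for d in payload["items"]
        )
        return cls(
            items=items,
            ptsd_cutoff=int(payload.get("ptsd_cutoff", 2)),
            dep_cutoff=int(payload.get("dep_cutoff", 40)),
        )


# Item codes and symptom labels of the 25-node battery.
_PCPTSD_LABELS = [
    ("PCPTSD1", "Flashback"),
    ("PCPTSD2", "Avoidance"),
    ("PCPTSD3", "High alertness"),
    ("PCPTSD4", "Numb feeling"),
    ("PCPTSD5", "Compunction and blame"),
]
_SDS_LABELS = [
    ("SDS1", "Sad mood"),
    ("SDS2", "Mood circadian rhythm"),
    ("SDS3", "Crying"),
    ("SDS4", "Sleep"),
    ("SDS5", "Appetite"),
    ("SDS6", "Sexuality"),
    ("SDS7", "Weight loss"),
    ("SDS8", "Constipation"),
    ("SDS9", "Tachycardia"),
    ("SDS10", "Fatigue"),
    ("SDS11", "Confusion"),
    ("SDS12", "Ability decline"),
    ("SDS13", "Feeling of upset"),
    ("SDS14", "Hopelessness"),
    ("SDS15", "Irritability"),
    ("SDS16", "Irresolution"),
    ("SDS17", "Unworthiness"),
    ("SDS18", "Life emptiness"),
    ("SDS19", "Guilty"),
    ("SDS20", "Interest loss"),
]


def default_battery() -> ScaleBattery:
    """The PC-PTSD-5 + SDS battery (25 items) with standard cutoffs 2 and 40."""
    items = [
        ItemDefinition(code, label, (0, 1), "PTSD") for code, label in _PCPTSD_LABELS
    ] + [
        ItemDefinition(code, label, (1, 2, 3, 4), "DEP") for code, label in _SDS_LABELS
    ]
    return ScaleBattery(items=tuple(items))


@dataclass
class ResponseMatrix:
    """Validated n x p integer item responses, optionally grouped.

    ``values`` is an (n, p) integer array whose columns follow
    ``battery.items`` order; ``group`` is an optional length-n label vector
    (e.g. only-child status) used by the network comparison test.
    """

    values: np.ndarray
    battery: ScaleBattery
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D")
        n, p = self.values.shape
        if n < 1 or p != self.battery.p:
            raise ValidationError(
                f"shape {self.values.shape} incompatible with battery of {self.battery.p} items"
            )
        for j, it in enumerate(self.battery.items):
            bad = ~np.isin(self.values[:, j], it.levels)
            if bad.any():
                row = int(np.nonzero(bad)[0][0])
                raise ValidationError(
                    f"value {self.values[row, j]} at row {row}, item {it.item_id!r} "
                    f"outside level set {it.levels}"
                )
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != (n,):
                raise ValidationError("group labels must align with rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.battery.item_ids)
        if self.group is not None:
            df["group"] = self.group
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def totals(self, instrument: str) -> np.ndarray:
        cols = [
            j
            for j, it in enumerate(self.battery.items)
            if it.instrument == instrument
        ]
        return self.values[:, cols].sum(axis=1)

    def group_sizes(self) -> dict:
        if self.group is None:
            return {}
        labels, counts = np.unique(self.group, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, rows: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            values=self.values[rows],
            battery=self.battery,
            group=None if self.group is None else self.group[rows],
        )

    def split_by_group(self) -> dict:
        if self.group is None:
            raise ValidationError("no group labels attached")
        return {
            lab: self.subset(np.nonzero(self.group == lab)[0])
            for lab in np.unique(self.group)
        }


def load_responses(
    path: str | Path,
    battery: ScaleBattery | str | Path | None = None,
    group_col: str | None = None,
) -> ResponseMatrix:
    """Read and validate a respondent-by-item CSV against a battery.

    ``battery`` may be a :class:`ScaleBattery`, a path to a battery JSON, or
    None for the default 25-item battery.  Unknown item columns, values
    outside an item's level set, and missing cells raise
    :class:`ValidationError` naming the offending row/column.
    """
    if battery is None:
        battery = default_battery()
    elif not isinstance(battery, ScaleBattery):
        battery = ScaleBattery.from_json(battery)
    df = pd.read_csv(path)
    missing = [c for c in battery.item_ids if c not in df.columns]
    if missing:
        raise ValidationError(f"CSV missing item columns: {missing}")
    sub = df[battery.item_ids]
    if sub.isna().any().any():
        col = sub.columns[sub.isna().any()][0]
        row = int(sub[sub[col].isna()].index[0])
        raise ValidationError(f"missing value at row {row}, column {col!r}")
    group = None
    if group_col is not None:
        if group_col not in df.columns:
            raise ValidationError(f"group column {group_col!r} not in CSV")
        group = df[group_col].to_numpy()
    return ResponseMatrix(values=sub.to_numpy(), battery=battery, group=group)


@dataclass
class DescriptiveTable:
    """Per-item and per-instrument descriptives plus screening prevalences."""

    items: pd.DataFrame  # index item_id; columns label, instrument, mean, sd
    instrument_totals: pd.DataFrame  # index instrument; columns mean, sd
    ptsd_positive_rate: float
    dep_positive_rate: float

    def to_frame(self) -> pd.DataFrame:
        return self.items


def item_descriptives(rm: ResponseMatrix) -> DescriptiveTable:
    """Item means/SDs, instrument total-score means/SDs, screening rates.

    SDs use the sample convention (ddof=1) and are reported as NaN when n < 2.
    """
    sd_ok = rm.n >= 2
    means = rm.values.mean(axis=0)
    sds = rm.values.std(axis=0, ddof=1) if sd_ok else np.full(rm.p, np.nan)
    items = pd.DataFrame(
        {
            "label": [it.label for it in rm.battery.items],
            "instrument": [it.instrument for it in rm.battery.items],
            "mean": means,
            "sd": sds,
        },
        index=pd.Index(rm.battery.item_ids, name="item_id"),
    )
    rows = []
    for instrument in ("PTSD", "DEP"):
        tot = rm.totals(instrument)
        rows.append(
            {
                "instrument": instrument,
                "mean": tot.mean(),
                "sd": tot.std(ddof=1) if sd_ok else np.nan,
            }
        )
    totals = pd.DataFrame(rows).set_index("instrument")
    ptsd_rate, dep_rate = screen_positive_rates(rm)
    return DescriptiveTable(
        items=items,
        instrument_totals=totals,
        ptsd_positive_rate=ptsd_rate,
        dep_positive_rate=dep_rate,
    )


def screen_positive_rates(rm: ResponseMatrix) -> tuple[float, float]:
    """Fractions of respondents at/above the PTSD and depression cutoffs."""
    ptsd = float(np.mean(rm.totals("PTSD") >= rm.battery.ptsd_cutoff))
    dep = float(np.mean(rm.totals("DEP") >= rm.battery.dep_cutoff))
    return ptsd, dep
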