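"""Rule-based dendritic-spine classification and segment summaries.

Spines measured on dendrite segments (head diameter and maximal length,
in µm) are classified with a two-branch rule: *thin* if the head is below
0.6 µm in diameter and the length is at least twice the head diameter;
*mushroom* if the head diameter exceeds 0.6 µm.  The two branches are not
exhaustive — a small-headed, short spine matches neither, and a head of
exactly 0.6 µm is left unassigned by the strict inequalities — so a third
class *other* is reported rather than forcing those cases into a bin.
Densities are spine counts per µm of dendrite, conventionally measured
along ~20 µm segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HEAD_THRESHOLD_UM",
    "SpineRecord",
    "SegmentSummary",
    "classify_spine",
    "summarize_segment",
    "summarize_table",
    "percent_of_control",
    "read_spine_table",
]

HEAD_THRESHOLD_UM = 0.6
CLASSES = ("thin", "mushroom", "other")


@dataclass(frozen=True)
class SpineRecord:
    id: str
    head_diameter: float  # µm
    length: float  # µm
    segment_id: str = ""

    def __post_init__(self) -> None:
        if self.head_diameter <= 0 or self.length <= 0:
            raise ValueError(f"spine {self.id!r}: measurements must be positive")


@dataclass
class SegmentSummary:
    segment_id: str
    dendrite_length: float  # µm
    spine_count: int
    density: float  # spines per µm
    class_counts: dict[str, int]
    class_percentages: dict[str, float]  # over all counted spines, sums to 100

    def percentages_of_classified(self) -> dict[str, float]:
        """Thin/mushroom percentages excluding the 'other' class."""
        classified = self.class_counts.get("thin", 0) + self.class_counts.get("mushroom", 0)
        if classified == 0:
            return {}
        return {
            cls: 100.0 * self.class_counts.get(cls, 0) / classified
            for cls in ("thin", "mushroom")
        }


def classify_spine(head_diameter: float, length: float) -> str:
    """Classify one spine from its head diameter and maximal length (µm).

    thin      — head < 0.6 µm and length ≥ 2 × head diameter
    mushroom  — head > 0.6 µm (length plays no role)
    other     — neither branch (incl. head exactly 0.6 µm, and
                small-headed spines shorter than twice their head)
    """
    if head_diameter <= 0 or length <= 0:
        raise ValueError("head diameter and length must be positive")
    if head_diameter > HEAD_THRESHOLD_UM:
        return "mushroom"
    if head_diameter < HEAD_THRESHOLD_UM and length >= 2.0 * head_diameter:
        return "thin"
    return "other"


def summarize_segment(records: Sequence[SpineRecord], dendrite_length: float,
                      segment_id: str = "") -> SegmentSummary:
    """Density and class distribution for one dendrite segment."""
    if dendrite_length <= 0:
        raise ValueError("dendrite_length must be positive")
    counts = {cls: 0 for cls in CLASSES}
    for rec in records:
        counts[classify_spine(rec.head_diameter, rec.length)] += 1
    n = len(records)
    percentages = {cls: 100.0 * c / n for cls, c in counts.items()} if n else {}
    return SegmentSummary(
        segment_id=segment_id or (records[0].segment_id if records else ""),
        dendrite_length=dendrite_length,
        spine_count=n,
        density=n / dendrite_length,
        class_counts=counts,
        class_percentages=percentages,
    )


def read_spine_table(path) -> pd.DataFrame:
    """Read a per-spine CSV: id, segment_id, head_diameter_um, length_um,
    optional neck_diameter_um (accepted, unused by the rule) and condition."""
    df = pd.read_csv(path)
    required = {"id", "segment_id", "head_diameter_um", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spine table missing columns: {sorted(missing)}")
    return df


def summarize_table(df: pd.DataFrame, dendrite_length: float = 20.0) -> pd.DataFrame:
    """Per-segment summaries from a spine table (one row per segment)."""
    rows = []
    group_cols = ["segment_id"] + (["condition"] if "condition" in df.columns else [])
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        records = [
            SpineRecord(id=str(r.id), head_diameter=float(r.head_diameter_um),
                        length=float(r.length_um), segment_id=str(r.segment_id))
            for r in sub.itertuples()
        ]
        summ = summarize_segment(records, dendrite_length, segment_id=str(key[0]))
        row = {
            "segment_id": key[0],
            "spine_count": summ.spine_count,
            "density_per_um": summ.density,
        }
        if len(key) > 1:
            row["condition"] = key[1]
        for cls in CLASSES:
            row[f"pct_{cls}"] = summ.class_percentages.get(cls, float("nan"))
        classified = summ.percentages_of_classified()
        row["pct_thin_of_classified"] = classified.get("thin", float("nan"))
        row["pct_mushroom_of_classified"] = classified.get("mushroom", float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def percent_of_control(treated_densities: Iterable[float],
                       control_densities: Iterable[float]) -> float:
    """Mean treated density as a percentage of mean control density."""
    control = list(control_densities)
    treated = list(treated_densities)
    if not control or not treated:
        raise ValueError("both groups must be nonempty")
    control_mean = sum(control) / len(control)
    if control_mean == 0:
        raise ValueError("control mean density is zero")
    return 100.0 * (sum(treated) / len(treated)) / control_mean
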