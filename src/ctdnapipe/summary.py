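"""Cohort aggregation: detection tables, detection rates, per-stage
breakdowns and cfDNA concentration ratios.

Detection at the sample level means at least one retained variant.  The
denominator of a detection rate is approach-specific: the tumour-informed
approaches (A/B) count participants with tissue driver variants and a
sequenced sample at the timepoint; the tumour-agnostic approaches (C/D) count
participants with a sequenced sample — an unfilterable NA row in D counts as
not detected, matching how the published rates were formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DETECTION_COLUMNS, DetectionTable, SampleRecord, ValidationError
from .plasma import PlasmaCallSet


def build_detection_table(
    callsets: Iterable[PlasmaCallSet],
    expected_variants: Mapping[str, Optional[bool]],
    plasma_metadata: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> DetectionTable:
    """Assemble per-participant counts from pipeline outputs.

    ``expected_variants`` maps participant id -> whether the tissue analysis
    found cancer-associated variants (None if tissue analysis failed).
    ``plasma_metadata`` optionally maps participant id -> the four
    volume/mass fields.
    """
    rows: dict[str, dict] = {}
    for cs in callsets:
        row = rows.setdefault(cs.participant_id, {"participant_id": cs.participant_id})
        tp = "diagnostic" if cs.timepoint == "diagnostic" else "post"
        col = f"{cs.approach.lower()}_{tp}"
        row[col] = pd.NA if cs.na else len(cs.retained)
    records = []
    for pid, row in rows.items():
        exp = expected_variants.get(pid)
        row["expected_variants"] = pd.NA if exp is None else ("Y" if exp else "N")
        for meta_col in (
            "plasma_diagnostic_ng",
            "plasma_diagnostic_ml",
            "plasma_post_ng",
            "plasma_post_ml",
        ):
            row.setdefault(meta_col, (plasma_metadata or {}).get(pid, {}).get(meta_col, np.nan))
        for col in DETECTION_COLUMNS[2:10]:
            row.setdefault(col, pd.NA)
        records.append(row)
    df = pd.DataFrame.from_records(records)[DETECTION_COLUMNS]
    return DetectionTable(df.sort_values("participant_id"))


@dataclass(frozen=True)
class DetectionRate:
    numerator: int
    denominator: int
    fraction: float

    def __iter__(self):
        return iter((self.numerator, self.denominator, self.fraction))


def tumour_informed_cohort(table: DetectionTable, timepoint: str = "diagnostic") -> pd.Series:
    """Mask of participants with tissue drivers and a sequenced sample at the
    timepoint (the tumour-informed denominator)."""
    df = table.df
    return df["expected_variants"].eq("Y") & df[f"a_{timepoint}"].notna()


def detection_rate(
    table: DetectionTable, approach: str, timepoint: str = "diagnostic"
) -> DetectionRate:
    """(numerator, denominator, fraction) for one approach at one timepoint."""
    approach = approach.upper()
    if approach not in ("A", "B", "C", "D"):
        raise ValidationError(f"unknown approach {approach!r}")
    df = table.df
    counts = df[f"{approach.lower()}_{timepoint}"]
    if approach in ("A", "B"):
        in_denominator = df["expected_variants"].eq("Y") & counts.notna()
    else:
        # sequenced diagnostic/post sample, judged from the tumour-agnostic column
        in_denominator = df[f"c_{timepoint}"].notna()
    denominator = int(in_denominator.sum())
    numerator = int((counts[in_denominator].fillna(0) >= 1).sum())
    if denominator == 0:
        return DetectionRate(0, 0, float("nan"))
    return DetectionRate(numerator, denominator, numerator / denominator)


def ch_filterable_count(table: DetectionTable, timepoint: str = "diagnostic") -> int:
    """Participants whose approach-D result is computable (WBC or paired
    plasma available) at the timepoint."""
    return int(table.df[f"d_{timepoint}"].notna().sum())


def variant_total(table: DetectionTable, approach: str, timepoint: str = "diagnostic") -> int:
    """Total retained variants across participants (NA rows skipped)."""
    return int(table.df[f"{approach.lower()}_{timepoint}"].dropna().sum())


def detected_any(
    table: DetectionTable, approaches: Sequence[str], timepoint: str = "diagnostic"
) -> int:
    """Participants detected by at least one of the given approaches."""
    df = table.df
    any_pos = pd.Series(False, index=df.index)
    for app in approaches:
        any_pos |= df[f"{app.lower()}_{timepoint}"].fillna(0) >= 1
    return int(any_pos.sum())


def detection_rate_by_stage(
    table: DetectionTable,
    stages: Mapping[str, str],
    approach: str,
    groups: Mapping[str, Sequence[str]],
    timepoint: str = "diagnostic",
) -> dict[str, DetectionRate]:
    """Detection rates within stage groups (e.g. I-II vs III-IV).

    ``stages`` maps participant id -> stage label; ``groups`` maps a group
    name -> the stage-label prefixes it covers.
    """
    out = {}
    df = table.df
    for name, prefixes in groups.items():
        ids = {
            pid
            for pid, stage in stages.items()
            if any(str(stage).startswith(p) for p in prefixes)
        }
        sub = DetectionTable(df[df["participant_id"].isin(ids)])
        out[name] = detection_rate(sub, approach, timepoint)
    return out


def concentration_ratio(diag: SampleRecord, post: SampleRecord) -> float:
    """Post/diagnostic total cfDNA concentration ratio (mass per mL plasma)."""
    for rec in (diag, post):
        if rec.cfdna_mass_ng is None or rec.plasma_volume_ml is None:
            raise ValidationError("both samples need cfdna_mass_ng and plasma_volume_ml")
    return (post.cfdna_mass_ng / post.plasma_volume_ml) / (
        diag.cfdna_mass_ng / diag.plasma_volume_ml
    )


def concentration_ratios_from_table(table: DetectionTable) -> pd.Series:
    """Per-participant ratios computed from the detection-table mass/volume
    columns.  Where masses are capped by the library-prep input limit the
    ratio is a lower bound, so cohort medians from capped tables understate
    the true post-surgical rise."""
    df = table.df
    diag = df["plasma_diagnostic_ng"] / df["plasma_diagnostic_ml"]
    post = df["plasma_post_ng"] / df["plasma_post_ml"]
    ratio = (post / diag).astype(float)
    return pd.Series(ratio.values, index=df["participant_id"], name="concentration_ratio").dropna()


def summarize(table: DetectionTable) -> dict:
    """All headline rates as a JSON-ready dict."""
    out: dict = {
        "n_participants": len(table),
        "tissue_positive_with_diagnostic_sample": int(tumour_informed_cohort(table).sum()),
    }
    for approach in ("A", "B", "C", "D"):
        for tp in ("diagnostic", "post"):
            num, den, frac = detection_rate(table, approach, tp)
            out[f"{approach}_{tp}"] = {
                "detected": num,
                "denominator": den,
                "rate_percent": None if den == 0 else round(100 * frac, 1),
                "variants_total": variant_total(table, approach, tp),
            }
    out["post_surgery_positive_a_or_b"] = detected_any(table, ["A", "B"], "post")
    return out
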