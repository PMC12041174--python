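"""Validation statistics and the embedded clinical validation tables.

Five validation patients (IDs 16-20) had proper-hepatic-artery (PHA) flow
measured intraoperatively after gastroduodenal (scenario clamp_GDA) and
common-hepatic (clamp_CHA) clamping, against model predictions with
acceptance intervals. The statistics:

* ``relative_error``      -- |predicted - real| / real x 100
* ``rel_error_of_min``    -- (real - interval_min) / real x 100, the safety
                             margin above the predicted minimum (negative
                             means the prediction failed on the safe side)
* ``range_accuracy``      -- percent of records whose real post-clamp flow
                             falls inside [interval_min, interval_max]

The tables are embedded verbatim as printed. A few printed error-column
entries do not reproduce under the stated formulas (the flows and intervals
themselves are internally consistent); those rows carry consistency flags
and are excluded from exact error reproduction while still counting toward
range-membership accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .solver import CLAMP_CHA, CLAMP_GDA

__all__ = [
    "ValidationRecord",
    "relative_error",
    "rel_error_of_min",
    "range_accuracy",
    "load_validation_tables",
    "round_percent",
]


@dataclass(frozen=True)
class ValidationRecord:
    """One validation patient-scenario row: measured baselines, prediction, real."""

    patient_id: str
    scenario: str
    cha0: float  # measured baseline common hepatic flow, ml/min
    gda0: float  # measured baseline gastroduodenal flow, ml/min
    pha0: float  # inferred baseline proper hepatic flow, ml/min
    real_post: float  # measured post-clamp PHA flow, ml/min
    predicted_post: float  # model-predicted post-clamp PHA flow, ml/min
    interval_min: float
    interval_max: float
    printed_error_pct: float | None = None
    printed_rel_error_min_pct: float | None = None
    error_consistent: bool = True  # printed error reproduces under the formula
    relmin_consistent: bool = True
    note: str = ""

    def in_range(self) -> bool:
        return self.interval_min <= self.real_post <= self.interval_max


def round_percent(value: float, ndigits: int = 0) -> float:
    """Half-up rounding for percent reporting (10.465 -> 10.5, 6.25 -> 6)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def relative_error(predicted: float, real: float) -> float:
    """Percent error of a prediction: |predicted - real| / real x 100."""
    if real == 0:
        raise ValueError("relative_error undefined for real == 0")
    return abs(predicted - real) / abs(real) * 100.0


def rel_error_of_min(real: float, interval_min: float) -> float:
    """Safety margin over the predicted minimum: (real - min) / real x 100.

    Negative when the real flow fell below the predicted minimum (a failed
    conservative prediction).
    """
    if real <= 0:
        raise ValueError("rel_error_of_min requires real > 0")
    return (real - interval_min) / real * 100.0


def range_accuracy(records: list[ValidationRecord]) -> float:
    """Percent of records whose real post-clamp flow lies inside its interval."""
    if not records:
        raise ValueError("range_accuracy requires a non-empty record set")
    hits = sum(1 for r in records if r.in_range())
    return 100.0 * hits / len(records)


# ---------------------------------------------------------------------------
# Embedded validation tables (clinical cohort, patients 16-20, both scenarios)
# ---------------------------------------------------------------------------
# Scenario clamp_GDA columns:
#   id, cha0, gda0, pha0, real, predicted, printed error %, interval, printed
#   rel-error-of-min %; consistency flags frozen after recomputing both error
#   columns with the stated formulas at the printed precision.
_TABLE_GDA = [
    # id, cha0, gda0, pha0, real, pred, err%, lo, hi, relmin%, err_ok, relmin_ok, note
    ("ID16", 331, 60, 271, 314, 289.2, 8, 247.1, 331.3, 21, True, True, ""),
    ("ID17", 144, 18, 126, 120, 129.6, 5, 112.5, 146.7, 6, False, True,
     "printed error 5% does not reproduce (formula gives 8%)"),
    ("ID18", 179, 52, 127, 136, 130.8, 4, 105.1, 156.6, 22, True, False,
     "printed rel-error-of-min 22% vs recomputed 23% (likely truncation)"),
    ("ID19", 215, 54, 161, 153, 171.6, 3, 142.3, 201.2, 7, False, True,
     "real post-clamp flow below baseline PHA0 and printed error 3% does not "
     "reproduce (formula gives 12%)"),
    ("ID20", 213, 67, 146, 176, 159.6, 9, 128.25, 190.95, 27, True, True, ""),
]

# Scenario clamp_CHA columns: id, cha0, pha0, gda0, real, pred, interval,
# printed error % (one decimal). No printed error reproduces under the
# stated formula at one-decimal precision; all rows carry
# error_consistent=False and participate only in range membership.
_TABLE_CHA = [
    ("ID16", 331, 271, 60, 91, 103.2, 89.72, 118.7, 13.1,
     "printed 13.1% vs recomputed 13.4%"),
    ("ID17", 144, 126, 18, 43, 47.5, 42.9, 51.06, 10.4,
     "printed 10.4% vs recomputed 10.5%"),
    ("ID18", 179, 127, 52, 203, 74.5, 68.9, 80.86, 3.3,
     "real 203 ml/min far outside the interval; printed 3.3% vs recomputed "
     "63.3% -- the single out-of-range case behind the 80% accuracy"),
    ("ID19", 215, 161, 54, 98, 102.3, 94.3, 109.9, 4.1,
     "printed 4.1% vs recomputed 4.4%"),
    ("ID20", 213, 146, 67, 99, 106.2, 98.2, 114.1, 8.1,
     "printed 8.1% vs recomputed 7.3%"),
]


def load_validation_tables() -> list[ValidationRecord]:
    """The ten embedded validation rows (5 patients x 2 clamp scenarios)."""
    records: list[ValidationRecord] = []
    for (pid, cha0, gda0, pha0, real, pred, err, lo, hi, relmin,
         err_ok, relmin_ok, note) in _TABLE_GDA:
        records.append(
            ValidationRecord(
                patient_id=pid, scenario=CLAMP_GDA,
                cha0=cha0, gda0=gda0, pha0=pha0,
                real_post=real, predicted_post=pred,
                interval_min=lo, interval_max=hi,
                printed_error_pct=err, printed_rel_error_min_pct=relmin,
                error_consistent=err_ok, relmin_consistent=relmin_ok, note=note,
            )
        )
    for (pid, cha0, pha0, gda0, real, pred, lo, hi, err, note) in _TABLE_CHA:
        records.append(
            ValidationRecord(
                patient_id=pid, scenario=CLAMP_CHA,
                cha0=cha0, gda0=gda0, pha0=pha0,
                real_post=real, predicted_post=pred,
                interval_min=lo, interval_max=hi,
                printed_error_pct=err, printed_rel_error_min_pct=None,
                error_consistent=False, relmin_consistent=True, note=note,
            )
        )
    return records


def validation_frame(records: list[ValidationRecord] | None = None) -> pd.DataFrame:
    """Reproduction report as a DataFrame: per-row membership and recomputed errors."""
    if records is None:
        records = load_validation_tables()
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "scenario": r.scenario,
                "cha0_ml_min": r.cha0,
                "gda0_ml_min": r.gda0,
                "pha0_ml_min": r.pha0,
                "real_post_ml_min": r.real_post,
                "predicted_post_ml_min": r.predicted_post,
                "interval_min_ml_min": r.interval_min,
                "interval_max_ml_min": r.interval_max,
                "in_range": r.in_range(),
                "error_pct": relative_error(r.predicted_post, r.real_post),
                "rel_error_of_min_pct": rel_error_of_min(r.real_post, r.interval_min),
                "printed_error_pct": r.printed_error_pct,
                "printed_rel_error_min_pct": r.printed_rel_error_min_pct,
            }
        )
    return pd.DataFrame(rows)
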