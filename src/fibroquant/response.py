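"""Paired pre-/post-treatment response classification.

Two readers of the same paired biopsies are compared:

histopathology
    the ordinal NASH CRN stage delta — a stage decrease is a responder,
    no change is not conclusive, an increase is a non-responder;

AI (ECA + EnC)
    a patient is a *responder* when both the Estimated Collagen Area and the
    Entropy of Collagen strictly decreased post-treatment, a *non-responder*
    when both strictly increased, and *not conclusive* when the two features
    moved in opposite directions (an exactly-zero delta in either feature
    also breaks congruity and yields not conclusive).

Cohort percentages are reported with half-up integer rounding.  The packaged
fixtures transcribe the study (9 pairs) and validation (8 pairs) cohorts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional, Sequence

import numpy as np

from fibroquant.stats import StageLabel

__all__ = [
    "PairedBiopsyRecord",
    "ResponseCall",
    "CohortReport",
    "classify_pair",
    "summarize_cohort",
    "weight_outcome",
    "render_response_heatmap",
    "load_fixture_pairs",
    "round_half_up_percent",
]

HistoCall = Literal["stage_decrease", "no_change", "stage_increase"]
AiCall = Literal["responder", "non_responder", "not_conclusive"]


@dataclass(frozen=True)
class PairedBiopsyRecord:
    patient_id: str
    cohort: str
    stage_pre: StageLabel
    stage_post: StageLabel
    eca_pre: float
    eca_post: float
    enc_pre: float
    enc_post: float
    weight_change_percent: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("eca_pre", "eca_post", "enc_pre", "enc_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ResponseCall:
    histo: HistoCall
    ai: AiCall
    congruous_with_histo: Optional[bool]  # None when histo did not change


def classify_pair(rec: PairedBiopsyRecord) -> ResponseCall:
    """Histology call from the ordinal stage delta; AI call from the joint
    direction of the ECA and EnC deltas, at the values as recorded."""
    if rec.stage_post < rec.stage_pre:
        histo: HistoCall = "stage_decrease"
    elif rec.stage_post > rec.stage_pre:
        histo = "stage_increase"
    else:
        histo = "no_change"

    d_eca = rec.eca_post - rec.eca_pre
    d_enc = rec.enc_post - rec.enc_pre
    if d_eca < 0 and d_enc < 0:
        ai: AiCall = "responder"
    elif d_eca > 0 and d_enc > 0:
        ai = "non_responder"
    else:
        ai = "not_conclusive"

    if histo == "no_change":
        congruous = None
    else:
        histo_sign = -1 if histo == "stage_decrease" else 1
        congruous = bool(np.sign(d_eca) == histo_sign and np.sign(d_enc) == histo_sign)
    return ResponseCall(histo=histo, ai=ai, congruous_with_histo=congruous)


def round_half_up_percent(count: int, total: int) -> int:
    """100*count/total rounded half-up to an integer percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


@dataclass
class CohortReport:
    n_pairs: int
    histo_decrease_percent: int
    histo_no_change_percent: int
    histo_increase_percent: int
    histo_any_change_percent: int
    ai_responder_percent: int
    ai_non_responder_percent: int
    ai_not_conclusive_percent: int
    ai_any_change_percent: int
    ai_congruous_change_percent: int
    #: among histo-unchanged pairs: share with congruous ECA+EnC decrease
    unchanged_congruous_decrease_percent: Optional[int]
    #: among histo-unchanged pairs: share with congruous ECA+EnC increase
    unchanged_congruous_increase_percent: Optional[int]
    #: among histo-changed pairs: share whose AI deltas matched the stage delta
    changed_congruous_percent: Optional[int]
    #: patient ids flagged by the >10% weight-loss outcome, with their calls
    weight_outcome_positive: list[dict]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_cohort(records: Sequence[PairedBiopsyRecord]) -> CohortReport:
    """Aggregate response calls into the cohort percentage report."""
    if not records:
        raise ValueError("summarize_cohort requires at least one record")
    calls = [classify_pair(r) for r in records]
    n = len(records)

    histo_dec = sum(c.histo == "stage_decrease" for c in calls)
    histo_inc = sum(c.histo == "stage_increase" for c in calls)
    histo_none = n - histo_dec - histo_inc

    ai_resp = sum(c.ai == "responder" for c in calls)
    ai_non = sum(c.ai == "non_responder" for c in calls)
    ai_nc = n - ai_resp - ai_non

    any_change = sum(
        (r.eca_post != r.eca_pre) and (r.enc_post != r.enc_pre) for r in records
    )

    unchanged = [(r, c) for r, c in zip(records, calls) if c.histo == "no_change"]
    changed = [(r, c) for r, c in zip(records, calls) if c.histo != "no_change"]
    if unchanged:
        u_dec = sum(c.ai == "responder" for _, c in unchanged)
        u_inc = sum(c.ai == "non_responder" for _, c in unchanged)
        u_dec_pct = round_half_up_percent(u_dec, len(unchanged))
        u_inc_pct = round_half_up_percent(u_inc, len(unchanged))
    else:
        u_dec_pct = u_inc_pct = None
    if changed:
        congr = sum(bool(c.congruous_with_histo) for _, c in changed)
        changed_pct = round_half_up_percent(congr, len(changed))
    else:
        changed_pct = None

    positives = []
    for r, c in zip(records, calls):
        if weight_outcome(r):
            positives.append(
                {
                    "patient_id": r.patient_id,
                    "cohort": r.cohort,
                    "ai": c.ai,
                    "histo": c.histo,
                }
            )

    return CohortReport(
        n_pairs=n,
        histo_decrease_percent=round_half_up_percent(histo_dec, n),
        histo_no_change_percent=round_half_up_percent(histo_none, n),
        histo_increase_percent=round_half_up_percent(histo_inc, n),
        histo_any_change_percent=round_half_up_percent(histo_dec + histo_inc, n),
        ai_responder_percent=round_half_up_percent(ai_resp, n),
        ai_non_responder_percent=round_half_up_percent(ai_non, n),
        ai_not_conclusive_percent=round_half_up_percent(ai_nc, n),
        ai_any_change_percent=round_half_up_percent(any_change, n),
        ai_congruous_change_percent=round_half_up_percent(ai_resp + ai_non, n),
        unchanged_congruous_decrease_percent=u_dec_pct,
        unchanged_congruous_increase_percent=u_inc_pct,
        changed_congruous_percent=changed_pct,
        weight_outcome_positive=positives,
    )


def weight_outcome(rec: PairedBiopsyRecord) -> Optional[bool]:
    """Clinical outcome: strictly more than 10% weight loss between the
    baseline and follow-up biopsies (i.e. weight_change_percent < -10).
    Missing weight data propagates as None."""
    if rec.weight_change_percent is None:
        return None
    return rec.weight_change_percent < -10.0


_GREEN = (46, 160, 67)
_YELLOW = (240, 200, 40)
_RED = (209, 59, 48)


def render_response_heatmap(
    records: Sequence[PairedBiopsyRecord],
    png_path=None,
    legend_csv_path=None,
    cell_px: int = 24,
) -> np.ndarray:
    """Categorical cases x {histo, ECA, EnC} grid.

    Histology column: green = stage decrease, yellow = no change,
    red = stage increase.  ECA/EnC columns: green = value decreased,
    red = increased, yellow = unchanged.  Returns the (n, 3, 3) RGB grid
    (one row per case); optionally writes an upscaled PNG and a CSV legend.
    """
    if not records:
        raise ValueError("at least one record is required")
    calls = [classify_pair(r) for r in records]
    grid = np.zeros((len(records), 3, 3), dtype=np.uint8)
    legend_rows = []
    for i, (r, c) in enumerate(zip(records, calls)):
        histo_color = {
            "stage_decrease": _GREEN,
            "no_change": _YELLOW,
            "stage_increase": _RED,
        }[c.histo]

        def delta_color(pre: float, post: float):
            if post < pre:
                return _GREEN
            if post > pre:
                return _RED
            return _YELLOW

        grid[i, 0] = histo_color
        grid[i, 1] = delta_color(r.eca_pre, r.eca_post)
        grid[i, 2] = delta_color(r.enc_pre, r.enc_post)
        legend_rows.append(
            {
                "patient_id": r.patient_id,
                "cohort": r.cohort,
                "histo": c.histo,
                "eca_direction": "decrease" if r.eca_post < r.eca_pre
                else ("increase" if r.eca_post > r.eca_pre else "unchanged"),
                "enc_direction": "decrease" if r.enc_post < r.enc_pre
                else ("increase" if r.enc_post > r.enc_pre else "unchanged"),
                "ai": c.ai,
            }
        )

    if png_path is not None:
        from PIL import Image

        big = np.repeat(np.repeat(grid, cell_px, axis=0), cell_px, axis=1)
        Image.fromarray(big).save(png_path)
    if legend_csv_path is not None:
        with open(legend_csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(legend_rows[0]))
            writer.writeheader()
            writer.writerows(legend_rows)
    return grid


def _parse_float(value: str) -> Optional[float]:
    value = value.strip()
    if value == "" or value.lower() in ("na", "nan", "none"):
        return None
    return float(value.rstrip("%"))


def load_fixture_pairs(
    which: Literal["study", "validation", "pooled"] = "pooled",
) -> list[PairedBiopsyRecord]:
    """Load the packaged paired-biopsy transcriptions.

    'study' gives the 9 study-cohort pairs, 'validation' the 8 validation
    pairs, 'pooled' all 17.  The weight_change_pct column holds synthetic
    stand-in magnitudes (see the fixture file headers).
    """
    names = {
        "study": ["table2_study.csv"],
        "validation": ["table3_validation.csv"],
        "pooled": ["table2_study.csv", "table3_validation.csv"],
    }[which]
    records: list[PairedBiopsyRecord] = []
    for name in names:
        with resources.files("fibroquant.data").joinpath(name).open() as fh:
            records.extend(read_pairs_csv(fh))
    return records


def read_pairs_csv(fh_or_path) -> list[PairedBiopsyRecord]:
    """Parse a paired-biopsy CSV (columns: patient_id, cohort, stage_pre,
    stage_post, eca_pre_pct, eca_post_pct, enc_pre, enc_post,
    weight_change_pct optional).  '#' lines are comments; errors name the
    offending row."""
    close = False
    if isinstance(fh_or_path, (str, bytes)) or hasattr(fh_or_path, "__fspath__"):
        fh = open(fh_or_path, newline="")
        close = True
    else:
        fh = fh_or_path
    try:
        rows = [line for line in fh if not line.lstrip().startswith("#")]
        reader = csv.DictReader(rows)
        required = {
            "patient_id",
            "cohort",
            "stage_pre",
            "stage_post",
            "eca_pre_pct",
            "eca_post_pct",
            "enc_pre",
            "enc_post",
        }
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"pairs CSV missing required columns: {missing}")
        records = []
        for k, row in enumerate(reader, start=1):
            try:
                weight = None
                if "weight_change_pct" in row and row["weight_change_pct"] is not None:
                    weight = _parse_float(row["weight_change_pct"])
                records.append(
                    PairedBiopsyRecord(
                        patient_id=row["patient_id"].strip(),
                        cohort=row["cohort"].strip(),
                        stage_pre=StageLabel.parse(row["stage_pre"]),
                        stage_post=StageLabel.parse(row["stage_post"]),
                        eca_pre=_parse_float(row["eca_pre_pct"]),
                        eca_post=_parse_float(row["eca_post_pct"]),
                        enc_pre=_parse_float(row["enc_pre"]),
                        enc_post=_parse_float(row["enc_post"]),
                        weight_change_percent=weight,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"invalid pairs CSV row {k}: {exc}") from exc
        return records
    finally:
        if close:
            fh.close()
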