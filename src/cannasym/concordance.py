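"""Prediction-vs-observation concordance for collection records.

For every mature flower with an observation, the predictor is run on the
topology and compared field by field: theca count (the petaloidy-degree
rule), appendage orientation (the orientation rule; only defined when a
half-fertile stamen is predicted), and symmetry class (the AF model).

Observed ``intermediate`` symmetry — one theca with appendages on both
sides, a transition stage — is a third outcome, reported separately and
never folded into match or mismatch.  Theca mismatches where the observed
count exceeds the prediction in a multi-flanked flower are flagged as
timing deviations: the developmental-delay reading, in which one proceeding
branch emerged late and exerted less influence.

The output is descriptive (counts); no hypothesis test is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .androecium import predict_flower_phenotype
from .fixtures import CollectionRecord
from .topology import MATURE, classify_partial_florescence, flanking_bracts


@dataclass(frozen=True)
class FlowerOutcome:
    flower_id: str
    predicted_theca: int
    observed_theca: Optional[int]
    theca_match: Optional[bool]
    orientation_match: Optional[bool]  # None = not applicable
    symmetry_outcome: Optional[str]  # match | mismatch | intermediate | None
    timing_deviation: bool
    rule_exception: bool


@dataclass
class ConcordanceReport:
    record_id: str
    pf_class: str
    per_flower: list[FlowerOutcome] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)  # flower id -> reason

    @property
    def aggregates(self) -> dict[str, int]:
        agg = {
            "flowers": len(self.per_flower),
            "theca_match": 0,
            "theca_mismatch": 0,
            "orientation_match": 0,
            "orientation_mismatch": 0,
            "orientation_na": 0,
            "symmetry_match": 0,
            "symmetry_mismatch": 0,
            "symmetry_intermediate": 0,
            "timing_deviations": 0,
            "rule_exceptions": 0,
            "skipped": len(self.skipped),
        }
        for o in self.per_flower:
            if o.theca_match is not None:
                agg["theca_match" if o.theca_match else "theca_mismatch"] += 1
            if o.orientation_match is None:
                agg["orientation_na"] += 1
            else:
                agg["orientation_match" if o.orientation_match else "orientation_mismatch"] += 1
            if o.symmetry_outcome == "match":
                agg["symmetry_match"] += 1
            elif o.symmetry_outcome == "mismatch":
                agg["symmetry_mismatch"] += 1
            elif o.symmetry_outcome == "intermediate":
                agg["symmetry_intermediate"] += 1
            if o.timing_deviation:
                agg["timing_deviations"] += 1
            if o.rule_exception:
                agg["rule_exceptions"] += 1
        return agg


def evaluate(record: CollectionRecord) -> ConcordanceReport:
    """Compare model predictions against a record's observations, per flower.

    Flowers lacking an observation, or whose observation lacks the compared
    fields, are listed under ``skipped`` with a reason — never silently
    dropped.
    """
    problems = record.validate()
    if problems:
        raise ValueError(f"invalid record {record.id}: " + "; ".join(problems))
    report = ConcordanceReport(
        record_id=record.id,
        pf_class=classify_partial_florescence(record.topology).label,
    )
    for flower in record.topology.flowers(status=MATURE):
        fid = flower.id
        obs = record.observed.get(fid)
        if obs is None:
            report.skipped[fid] = "no observation recorded"
            continue
        pred = predict_flower_phenotype(record.topology, fid)
        if obs.theca_count is None:
            report.skipped[fid] = "observation lacks a theca count"
            continue
        theca_match = obs.theca_count == pred.theca_count
        if pred.theca_count == 1:
            orientation: Optional[bool] = obs.appendage_side == pred.appendage_side
        else:
            orientation = None
        if obs.symmetry is None:
            symmetry_outcome: Optional[str] = None
        elif obs.symmetry == "intermediate":
            symmetry_outcome = "intermediate"
        elif obs.symmetry == pred.symmetry:
            symmetry_outcome = "match"
        else:
            symmetry_outcome = "mismatch"
        multi_flanked = len(flanking_bracts(record.topology, fid)) >= 2
        timing = bool(
            not theca_match and obs.theca_count > pred.theca_count and multi_flanked
        )
        report.per_flower.append(
            FlowerOutcome(
                flower_id=fid,
                predicted_theca=pred.theca_count,
                observed_theca=obs.theca_count,
                theca_match=theca_match,
                orientation_match=orientation,
                symmetry_outcome=symmetry_outcome,
                timing_deviation=timing,
                rule_exception=bool(record.rule_exceptions.get(fid, False)),
            )
        )
    return report


_AGG_COLUMNS = [
    "flowers", "theca_match", "theca_mismatch", "orientation_match",
    "orientation_mismatch", "orientation_na", "symmetry_match",
    "symmetry_mismatch", "symmetry_intermediate", "timing_deviations",
    "rule_exceptions", "skipped",
]


def aggregate(reports: list[ConcordanceReport]) -> pd.DataFrame:
    """Per-PF-class and overall concordance counts, deterministic row order.

    Counts are additive: evaluating the same report twice doubles every cell.
    Also reports ``records_with_deviation`` so agreement can be read at both
    the flower and the collection granularity.
    """
    rows = []
    classes = sorted({r.pf_class for r in reports})
    for pf_class in classes + ["all"]:
        pool = [r for r in reports if pf_class == "all" or r.pf_class == pf_class]
        row: dict[str, object] = {"pf_class": pf_class, "records": len(pool)}
        for col in _AGG_COLUMNS:
            row[col] = sum(r.aggregates[col] for r in pool)
        row["records_with_deviation"] = sum(
            1
            for r in pool
            if any(
                (o.theca_match is False) or (o.orientation_match is False) or o.rule_exception
                for o in r.per_flower
            )
        )
        rows.append(row)
    columns = ["pf_class", "records"] + _AGG_COLUMNS + ["records_with_deviation"]
    return pd.DataFrame(rows, columns=columns)
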