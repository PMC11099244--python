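"""Literature-survey fixture: train/test split practice in DNN-EEG studies.

Ships a machine-readable table of 63 published translational deep-learning
EEG studies, each labeled by the train/test split strategy it used, plus the
labeling rubric and tally operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "SurveyRecord",
    "SPLIT_VOCABULARY",
    "LABELING_RUBRIC",
    "load_survey_fixture",
    "tally_by_split",
]

SPLIT_VOCABULARY = ("Segments", "Subjects", "Both", "Unclear")

CONDITIONS = (
    "ADHD",
    "Alcoholism",
    "Alzheimer's",
    "Depression",
    "Parkinson's",
    "Schizophrenia",
    "Seizure",
    "Seizure and autism",
)

#: Rubric used to assign split labels, kept next to the fixture so future
#: rows can be labeled consistently (no automated text mining).
LABELING_RUBRIC = {
    "Segments": (
        "The study split recordings into segments but did not state that "
        "subjects organised the train/test split; or it explicitly placed "
        "segments from one subject on both sides (including per-subject "
        "models)."
    ),
    "Subjects": (
        "The study stated that all segments from a single subject were "
        "assigned to only the training or only the test set."
    ),
    "Both": "Different analyses used segment-based and subject-based splits.",
    "Unclear": (
        "It could not be determined whether models were trained on segments, "
        "and subject-wise holdout was not explicitly stated."
    ),
}


@dataclass(frozen=True)
class SurveyRecord:
    article: str
    condition: str
    split_label: str


class SurveyParseError(ValueError):
    pass


def load_survey_fixture() -> list[SurveyRecord]:
    """Load the packaged survey table; one record per surveyed study."""
    path = resources.files("eegleak") / "data" / "survey_table.tsv"
    records: list[SurveyRecord] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["article", "condition", "split_label"]:
            raise SurveyParseError(f"unexpected header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SurveyParseError(
                    f"line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            article, condition, split = parts
            if split not in SPLIT_VOCABULARY:
                raise SurveyParseError(
                    f"line {lineno}: split label {split!r} not in "
                    f"{SPLIT_VOCABULARY}"
                )
            if condition not in CONDITIONS:
                raise SurveyParseError(
                    f"line {lineno}: condition {condition!r} not in "
                    f"{CONDITIONS}"
                )
            if article in seen:
                raise SurveyParseError(f"line {lineno}: duplicate key {article!r}")
            seen.add(article)
            records.append(SurveyRecord(article, condition, split))
    return records


def tally_by_split(
    records: list[SurveyRecord], condition: str | None = None
) -> pd.DataFrame:
    """Counts and proportions per split label (optionally one condition).

    Proportions are percentages reported to one decimal; all four vocabulary
    labels appear even when their count is zero.
    """
    if not records:
        raise ValueError("no survey records to tally")
    if condition is not None:
        records = [r for r in records if r.condition == condition]
    counts = {label: 0 for label in SPLIT_VOCABULARY}
    for r in records:
        counts[r.split_label] += 1
    total = sum(counts.values())
    rows = [
        {
            "split_label": label,
            "count": cnt,
            "proportion_pct": round(100.0 * cnt / total, 1) if total else 0.0,
        }
        for label, cnt in counts.items()
    ]
    return pd.DataFrame(rows)
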