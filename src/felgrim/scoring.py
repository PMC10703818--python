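"""FGS total-score computation, pain binarisation and multi-rater aggregation.

Each of the five action units (AUs) is scored 0 (absent), 1 (moderately
present or uncertain) or 2 (obviously present).  The total FGS score is the
sum of the scored AUs divided by the maximum possible score given how many
AUs were actually scored, i.e. a ratio in [0, 1].  A cat scoring at or above
the analgesia cut-off (0.39 on the scale; 0.4 as used to label the prediction
models) is classified painful.

When several raters score the same image their scores are collapsed with an
aggregation rule: AND/OR on binarised pain labels, mean/maximum/minimum on
total-score ratios, and mode/maximum/minimum on per-AU ordinal scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import AUS

__all__ = [
    "RaterScoreSet",
    "FGSScore",
    "UnscorableError",
    "total_fgs",
    "binarize_fgs",
    "aggregate_binary",
    "aggregate_continuous",
    "aggregate_ordinal",
    "load_rater_table",
    "save_rater_table",
    "PAIN_THRESHOLD_SCALE",
    "PAIN_THRESHOLD_MODEL",
]

#: Cut-off defining "likely in pain requiring intervention" on the FGS scale.
PAIN_THRESHOLD_SCALE = 0.39
#: Cut-off used to build the binary labels for the prediction models.
PAIN_THRESHOLD_MODEL = 0.4

MAX_AU_SCORE = 2


class UnscorableError(ValueError):
    """No action unit carries a score."""


@dataclass(frozen=True)
class RaterScoreSet:
    """One rater's five AU scores for one image (``None`` = not scored)."""

    image_id: str
    rater_id: str
    au_scores: tuple  # length 5, entries in {0, 1, 2, None}, order = schema.AUS

    def __post_init__(self):
        if len(self.au_scores) != len(AUS):
            raise ValueError(f"expected {len(AUS)} AU scores")
        for s in self.au_scores:
            if s is not None and s not in (0, 1, 2):
                raise ValueError(f"AU score must be 0, 1, 2 or missing, got {s!r}")
        if all(s is None for s in self.au_scores):
            raise UnscorableError(
                f"image {self.image_id!r}, rater {self.rater_id!r}: no AU scored")


@dataclass(frozen=True)
class FGSScore:
    """Total FGS score as a ratio, plus how many AUs contributed."""

    ratio: float
    n_scored: int

    def __post_init__(self):
        if not 1 <= self.n_scored <= len(AUS):
            raise ValueError("n_scored must be between 1 and 5")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")


def total_fgs(s: RaterScoreSet) -> FGSScore:
    """Total score = sum of scored AUs / (2 x number of scored AUs)."""
    scored = [v for v in s.au_scores if v is not None]
    if not scored:
        raise UnscorableError("all AU scores missing")
    return FGSScore(ratio=sum(scored) / (MAX_AU_SCORE * len(scored)),
                    n_scored=len(scored))


def binarize_fgs(score: float, threshold: float = PAIN_THRESHOLD_SCALE) -> int:
    """1 (painful) iff ``score >= threshold`` (inclusive), else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    return int(score >= threshold)


def aggregate_binary(labels, rule: str) -> int:
    """AND: 1 iff every rater assigned 1.  OR: 1 iff any rater assigned 1."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to aggregate")
    if any(l not in (0, 1) for l in labels):
        raise ValueError("binary labels must be 0 or 1")
    rule = rule.upper()
    if rule == "AND":
        return int(all(labels))
    if rule == "OR":
        return int(any(labels))
    raise ValueError(f"unknown binary aggregation rule {rule!r}")


def aggregate_continuous(scores, rule: str) -> float:
    """mean / maximum / minimum of total-score ratios."""
    scores = [float(s) for s in scores]
    if not scores:
        raise ValueError("no scores to aggregate")
    rule = rule.lower()
    if rule == "mean":
        return float(np.mean(scores))
    if rule in ("max", "maximum"):
        return max(scores)
    if rule in ("min", "minimum"):
        return min(scores)
    raise ValueError(f"unknown continuous aggregation rule {rule!r}")


def aggregate_ordinal(scores, rule: str, tie: str = "lowest") -> int:
    """mode / maximum / minimum of ordinal 0/1/2 scores.

    Mode ties resolve deterministically to the lowest tied score by default
    (conservative: does not overcall pain); ``tie='highest'`` flips this.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to aggregate")
    if any(s not in (0, 1, 2) for s in scores):
        raise ValueError("ordinal scores must be 0, 1 or 2")
    rule = rule.lower()
    if rule in ("max", "maximum"):
        return max(scores)
    if rule in ("min", "minimum"):
        return min(scores)
    if rule == "mode":
        counts = Counter(scores)
        top = max(counts.values())
        tied = [s for s, c in counts.items() if c == top]
        if tie == "lowest":
            return min(tied)
        if tie == "highest":
            return max(tied)
        raise ValueError(f"unknown tie rule {tie!r}")
    raise ValueError(f"unknown ordinal aggregation rule {rule!r}")


# ---------------------------------------------------------------------------
# Rater table I/O: CSV with columns image_id, rater_id, ear, orbital, muzzle,
# whiskers, head; a blank cell is a missing score.
# ---------------------------------------------------------------------------

_AU_COLUMNS = ["ear", "orbital", "muzzle", "whiskers", "head"]


def load_rater_table(path_or_buf) -> list:
    """Read a rater-score CSV into a list of :class:`RaterScoreSet`."""
    df = pd.read_csv(path_or_buf, dtype={"image_id": str, "rater_id": str})
    missing = [c for c in ["image_id", "rater_id", *_AU_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"rater table missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        scores = tuple(None if pd.isna(row[c]) else int(row[c]) for c in _AU_COLUMNS)
        out.append(RaterScoreSet(row["image_id"], row["rater_id"], scores))
    return out


def save_rater_table(scores, path_or_buf) -> None:
    rows = []
    for s in scores:
        rec = {"image_id": s.image_id, "rater_id": s.rater_id}
        rec.update({c: ("" if v is None else v)
                    for c, v in zip(_AU_COLUMNS, s.au_scores)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def aggregate_labels(score_sets, task: str, rule: str,
                     threshold: float = PAIN_THRESHOLD_MODEL,
                     au: str | None = None) -> dict:
    """Collapse per-rater scores into one label per image.

    task='binary': binarise each rater's total score at *threshold*, then
    AND/OR.  task='regression': aggregate total ratios with mean/max/min.
    task='ordinal': aggregate the scores of action unit *au* with
    mode/max/min (raters who did not score that AU are ignored).
    """
    by_image: dict = {}
    for s in score_sets:
        by_image.setdefault(s.image_id, []).append(s)
    labels = {}
    for image_id, sets in by_image.items():
        if task == "binary":
            votes = [binarize_fgs(total_fgs(s).ratio, threshold) for s in sets]
            labels[image_id] = aggregate_binary(votes, rule)
        elif task == "regression":
            labels[image_id] = aggregate_continuous(
                [total_fgs(s).ratio for s in sets], rule)
        elif task == "ordinal":
            if au is None:
                raise ValueError("ordinal aggregation needs an action unit")
            idx = AUS.index(au)
            vals = [s.au_scores[idx] for s in sets if s.au_scores[idx] is not None]
            if vals:
                labels[image_id] = aggregate_ordinal(vals, rule)
        else:
            raise ValueError(f"unknown task {task!r}")
    return labels
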