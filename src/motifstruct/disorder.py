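"""Order/disorder categorization of motif instances.

Per-residue order labels come from an external disorder predictor (e.g.
PONDR VLXT or VSL2b output); this module consumes label tracks, it does
not predict.  A motif window is *structured* when every residue is
ordered, *unstructured* when every residue is disordered, and *hybrid*
otherwise; instances whose protein has no track (e.g. too short for the
predictor) are *unscored* and reported separately.  The four categories
partition every instance set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class OrderCategory(str, Enum):
    STRUCTURED = "structured"
    UNSTRUCTURED = "unstructured"
    HYBRID = "hybrid"
    UNSCORED = "unscored"


@dataclass
class DisorderTrack:
    """Per-residue binary disorder labels for one sequence.

    ``disordered[i]`` is True when residue i is predicted disordered.
    Build from real-valued predictor scores with :meth:`from_scores`
    (score >= threshold -> disordered; 0.5 is the conventional cutoff).
    """

    sequence_id: str
    disordered: np.ndarray

    def __post_init__(self):
        self.disordered = np.asarray(self.disordered, dtype=bool)

    def __len__(self) -> int:
        return len(self.disordered)

    @classmethod
    def from_scores(cls, sequence_id: str, scores, threshold: float = 0.5):
        scores = np.asarray(scores, dtype=float)
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        return cls(sequence_id=sequence_id, disordered=scores >= threshold)


def categorize_instance(track: DisorderTrack | None, start: int, end: int
                        ) -> OrderCategory:
    """Category of the window [start, end) (0-based half-open).

    A missing track yields UNSCORED.  A window outside the track raises.
    """
    if track is None:
        return OrderCategory.UNSCORED
    if not (0 <= start < end <= len(track)):
        raise IndexError(
            f"window [{start}, {end}) outside track of length {len(track)}")
    window = track.disordered[start:end]
    if not window.any():
        return OrderCategory.STRUCTURED
    if window.all():
        return OrderCategory.UNSTRUCTURED
    return OrderCategory.HYBRID


@dataclass
class CategorySummary:
    table: pd.DataFrame        # per activity class: counts + percentages
    suppressed: list           # classes below min_count
    unscored: dict             # per class unscored counts


def summarize(categories, activity_labels=None, min_count: int = 75
              ) -> CategorySummary:
    """Per-activity-class order/disorder percentages.

    Percentages are over *scored* instances only; unscored counts are
    reported separately.  Activity classes with fewer than *min_count*
    scored instances are suppressed (listed, not tabulated).
    """
    categories = [OrderCategory(c) for c in categories]
    if activity_labels is None:
        activity_labels = ["all"] * len(categories)
    if len(activity_labels) != len(categories):
        raise ValueError("one activity label per category required")
    df = pd.DataFrame({"activity": activity_labels,
                       "category": [c.value for c in categories]})
    rows, suppressed, unscored = [], [], {}
    for activity, grp in df.groupby("activity", sort=True):
        n_unscored = int((grp["category"] == "unscored").sum())
        scored = grp[grp["category"] != "unscored"]
        unscored[activity] = n_unscored
        n = len(scored)
        if n < min_count:
            suppressed.append(activity)
            continue
        row = {"activity": activity, "n_scored": n, "n_unscored": n_unscored}
        for cat in ("structured", "unstructured", "hybrid"):
            k = int((scored["category"] == cat).sum())
            row[f"n_{cat}"] = k
            row[f"pct_{cat}"] = 100.0 * k / n
        rows.append(row)
    table = pd.DataFrame(rows)
    return CategorySummary(table=table, suppressed=suppressed,
                           unscored=unscored)


def read_tracks(path, threshold: float = 0.5) -> dict:
    """Load tracks from TSV (sequence_id, position, score-or-label).

    Position is 1-based; values in {0,1} are labels (1 = disordered),
    anything else is a score cut at *threshold*.
    """
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for seq_id, grp in df.groupby(df.columns[0]):
        grp = grp.sort_values(grp.columns[1])
        vals = grp[grp.columns[2]].to_numpy(dtype=float)
        if np.isin(vals, (0.0, 1.0)).all():
            disordered = vals.astype(bool)
        else:
            disordered = vals >= threshold
        tracks[seq_id] = DisorderTrack(sequence_id=str(seq_id),
                                       disordered=disordered)
    return tracks


def write_tracks(tracks, path) -> None:
    rows = []
    for track in tracks:
        for i, lab in enumerate(track.disordered, start=1):
            rows.append({"sequence_id": track.sequence_id, "position": i,
                         "label": int(lab)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
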