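"""Evaluation metrics: Dice, multi-level region Dice, consensus, rater-based
accuracy, label MAE and group accuracy.

Plate-unit conventions: predictions and references are continuous plate
numbers (1 plate = 100 um along the AP axis), so the label MAE is reported
in micrometers via that conversion.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from sliceloc.atlas import LabeledSlice, StructureGraph, aggregate_labels
from sliceloc.frames import ARA_SPACING_UM, group_of_section
from sliceloc.synthetic import RaterLabels


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def multilevel_dice(
    labels_a: LabeledSlice,
    labels_b: LabeledSlice,
    graph: StructureGraph,
    level: int,
) -> pd.DataFrame:
    """Per-region Dice after aggregating both slices to a hierarchy level.

    Regions absent from both slices are omitted.  Returns a table with
    columns (id, acronym, dice, area_a, area_b).
    """
    if labels_a.labels.shape != labels_b.labels.shape:
        raise ValueError(
            f"shape mismatch: {labels_a.labels.shape} vs {labels_b.labels.shape}"
        )
    agg_a = aggregate_labels(labels_a, graph, level)
    agg_b = aggregate_labels(labels_b, graph, level)
    ids = sorted((agg_a.id_set() | agg_b.id_set()) - {0})
    rows = []
    for i in ids:
        ma = agg_a.labels == i
        mb = agg_b.labels == i
        rows.append({
            "id": i,
            "acronym": graph.acronym(i),
            "dice": dice(ma, mb),
            "area_a": int(ma.sum()),
            "area_b": int(mb.sum()),
        })
    return pd.DataFrame(rows, columns=["id", "acronym", "dice", "area_a", "area_b"])


def consensus_mask(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Strict-majority vote over >= 2 equal-shape binary masks (ties -> off)."""
    if len(masks) < 2:
        raise ValueError(f"need at least 2 masks, got {len(masks)}")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    return stack.sum(axis=0) > len(masks) / 2.0


def accuracy_2sd(ratings: RaterLabels | Sequence[float], prediction: float) -> bool:
    """True iff the prediction falls within mean +/- 2 * sample SD of the raters.

    Sample SD uses the n-1 denominator; when all raters agree (SD = 0) only
    an exact match counts as correct.
    """
    vals = np.asarray(
        ratings.ratings if isinstance(ratings, RaterLabels) else list(ratings),
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError(f"need at least 2 ratings, got {vals.size}")
    avg = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        return float(prediction) == avg
    return avg - 2 * sd <= float(prediction) <= avg + 2 * sd


def label_mae(predictions: Sequence[float], references: Sequence[float]) -> float:
    """Mean absolute plate-label error, converted to micrometers (x100)."""
    p = np.asarray(list(predictions), dtype=float)
    r = np.asarray(list(references), dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError(f"prediction/reference lengths differ or empty: {p.size} vs {r.size}")
    return float(np.abs(p - r).mean() * ARA_SPACING_UM)


def group_accuracy(predictions: Sequence[float], references: Sequence[float]) -> float:
    """Fraction of predictions attributed to the correct AP group."""
    p = list(predictions)
    r = list(references)
    if len(p) != len(r) or not p:
        raise ValueError(f"prediction/reference lengths differ or empty: {len(p)} vs {len(r)}")
    hits = sum(group_of_section(a) == group_of_section(b) for a, b in zip(p, r))
    return hits / len(p)
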