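"""Hemispheric asymmetry (laterality) scores.

For any network property X measured in both hemispheres,

    AS(X) = 100 * (X_R - X_L) / (X_R + X_L)

A positive score means rightward lateralization, a negative score
leftward.  The score is scale-invariant, antisymmetric under hemisphere
exchange, and bounded in (-100, 100) for strictly positive inputs.
Region pairs in which the property vanishes in both hemispheres (for
example a region isolated on both sides) have no defined score and are
reported as missing, to be dropped pairwise by downstream statistics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["asymmetry_score", "cohort_asymmetry"]

logger = logging.getLogger(__name__)


def asymmetry_score(x_right: float, x_left: float) -> float:
    """Laterality of a property measured in the right and left hemisphere."""
    if x_right < 0 or x_left < 0:
        raise ValueError(
            f"asymmetry score requires nonnegative inputs, got "
            f"R={x_right}, L={x_left}"
        )
    total = x_right + x_left
    if total == 0:
        warnings.warn("both hemisphere values are 0; asymmetry undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * (x_right - x_left) / total


def cohort_asymmetry(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-subject asymmetry scores from a long-format metrics table.

    ``metrics`` columns: subject_id, hemisphere, metric, node, value —
    one row per subject x hemisphere x measure, ``node`` holding the
    region abbreviation for nodal efficiency and empty/NaN for global
    measures.  Homotopic regions pair by abbreviation (identical label
    sequences in the two hemispheres).

    Returns one row per subject x measure with columns subject_id,
    metric, x_left, x_right, AS; nodal measures appear as
    ``Enodal:<abbrev>``.  Subjects missing either hemisphere are
    excluded with a logged reason.
    """
    df = metrics.copy()
    node = df["node"] if "node" in df else pd.Series("", index=df.index)
    node = node.fillna("").astype(str)
    df["measure"] = np.where(node != "", "Enodal:" + node, df["metric"])

    wide = df.pivot_table(
        index=["subject_id", "measure"],
        columns="hemisphere",
        values="value",
        aggfunc="first",
    ).reset_index()

    complete_subjects = []
    for sid, sub in wide.groupby("subject_id"):
        if "L" not in sub or "R" not in sub or sub[["L", "R"]].isna().all().any():
            logger.warning("subject %s missing a hemisphere; excluded", sid)
            continue
        complete_subjects.append(sid)
    wide = wide[wide["subject_id"].isin(complete_subjects)]

    x_l = wide["L"].to_numpy(dtype=float)
    x_r = wide["R"].to_numpy(dtype=float)
    if np.any((x_l < 0) | (x_r < 0)):
        raise ValueError("negative metric values; asymmetry score undefined")
    total = x_r + x_l
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(total > 0, 100.0 * (x_r - x_l) / np.where(total > 0, total, 1.0),
                         np.nan)
    n_undef = int(np.isnan(score).sum() - np.isnan(total).sum())
    if n_undef > 0:
        undef = wide.loc[(total == 0), "measure"].unique()
        logger.warning(
            "%d zero-denominator asymmetry scores set to missing (measures: %s)",
            n_undef, ", ".join(map(str, undef)),
        )
    out = pd.DataFrame(
        {
            "subject_id": wide["subject_id"],
            "metric": wide["measure"],
            "x_left": x_l,
            "x_right": x_r,
            "AS": score,
        }
    )
    return out.sort_values(["subject_id", "metric"]).reset_index(drop=True)
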