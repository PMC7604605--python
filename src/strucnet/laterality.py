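"""fMRI laterality index and lateralization classification.

LI = (L - R) / (L + R) over activated voxel counts in homologous left and
right frontal language ROIs; LI ranges over [-1, 1]. A subject is
typically left-lateralized when LI >= 0.2, atypically lateralized
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["laterality_index", "classify_lateralization", "LateralityRecord",
           "cohort_lateralization_summary", "TYPICAL_THRESHOLD"]

TYPICAL_THRESHOLD = 0.2


def laterality_index(L: float, R: float) -> float:
    """LI = (L - R)/(L + R); requires L, R >= 0 and L + R > 0."""
    if L < 0 or R < 0:
        raise ValueError("voxel counts must be nonnegative")
    if L + R == 0:
        raise ValueError("laterality index undefined: no activated voxels")
    return (L - R) / (L + R)


def classify_lateralization(li: float) -> str:
    """"typical" (left-lateralized) iff LI >= 0.2, else "atypical"."""
    if not -1.0 <= li <= 1.0:
        raise ValueError(f"LI must lie in [-1, 1], got {li}")
    return "typical" if li >= TYPICAL_THRESHOLD else "atypical"


@dataclass
class LateralityRecord:
    subject_id: str
    left_voxels: float
    right_voxels: float

    @property
    def li(self) -> float:
        return laterality_index(self.left_voxels, self.right_voxels)

    @property
    def classification(self) -> str:
        return classify_lateralization(self.li)


def cohort_lateralization_summary(records) -> pd.DataFrame:
    """Counts, percentages, and LI mean +/- SD per lateralization class.

    Accepts LateralityRecord instances or a DataFrame with columns
    subject_id, left_voxels, right_voxels. Percentages are rounded to one
    decimal; proportions sum to one.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            LateralityRecord(str(r["subject_id"]), float(r["left_voxels"]),
                             float(r["right_voxels"]))
            for _, r in records.iterrows()
        ]
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    lis = np.array([r.li for r in records])
    classes = np.array([r.classification for r in records])
    n = len(records)
    rows = []
    for cls in ("typical", "atypical"):
        sel = classes == cls
        count = int(sel.sum())
        sub = lis[sel]
        rows.append({
            "classification": cls,
            "count": count,
            "proportion": count / n,
            "percent": round(100.0 * count / n, 1),
            "mean_li": float(sub.mean()) if count else np.nan,
            "sd_li": float(sub.std(ddof=1)) if count > 1 else
                     (0.0 if count == 1 else np.nan),
        })
    return pd.DataFrame(rows)
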