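"""Dice similarity between PET segmentations and MRI lesion masks.

DICE = 2|A ∩ B| / (|A| + |B|), computed on voxel counts (both masks must
share one grid, so counts and ml volumes are proportional). A comparison is
evaluable only when both masks are non-empty — a PET-negative tumour or an
absent MRI lesion is excluded rather than scored 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .imaging_io import Mask, check_same_grid


@dataclass(frozen=True)
class DiceResult:
    dice: Optional[float]
    vol_a_ml: float
    vol_b_ml: float
    intersection_ml: float
    evaluable: bool
    reason_not_evaluable: str = ""

    def __post_init__(self) -> None:
        if self.evaluable:
            if self.dice is None or not (0.0 <= self.dice <= 1.0):
                raise ValueError(f"evaluable Dice must lie in [0, 1], got {self.dice}")

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "vol_a_ml": self.vol_a_ml,
            "vol_b_ml": self.vol_b_ml,
            "intersection_ml": self.intersection_ml,
            "evaluable": self.evaluable,
            "reason_not_evaluable": self.reason_not_evaluable,
        }


def dice_coefficient(a: Mask, b: Mask) -> DiceResult:
    """Voxel-count Dice between two masks on a common grid.

    Returns a non-evaluable result (dice=None) when either mask is empty,
    mirroring the clinical rule that overlap is only measured when a lesion
    is segmentable on both modalities.
    """
    check_same_grid(a, b)
    vv = a.voxel_volume_ml
    n_a, n_b = a.n_voxels, b.n_voxels
    inter = int(np.count_nonzero((a.values > 0) & (b.values > 0)))
    if n_a == 0 or n_b == 0:
        empties = [name for name, n in (("first", n_a), ("second", n_b)) if n == 0]
        return DiceResult(
            dice=None,
            vol_a_ml=n_a * vv,
            vol_b_ml=n_b * vv,
            intersection_ml=0.0,
            evaluable=False,
            reason_not_evaluable=f"{' and '.join(empties)} mask empty",
        )
    return DiceResult(
        dice=2.0 * inter / (n_a + n_b),
        vol_a_ml=n_a * vv,
        vol_b_ml=n_b * vv,
        intersection_ml=inter * vv,
        evaluable=True,
    )


def overlap_panel(
    pet_seg: Mask, flair: Mask, ce: Optional[Mask] = None
) -> dict[str, DiceResult]:
    """PET–FLAIR and PET–CE Dice results with evaluability.

    An absent CE mask (no contrast-enhancing lesion) yields a non-evaluable
    PET–CE entry rather than an error.
    """
    results = {"flair": dice_coefficient(pet_seg, flair)}
    if ce is None:
        results["ce"] = DiceResult(
            dice=None,
            vol_a_ml=pet_seg.volume_ml,
            vol_b_ml=0.0,
            intersection_ml=0.0,
            evaluable=False,
            reason_not_evaluable="no CE lesion",
        )
    else:
        results["ce"] = dice_coefficient(pet_seg, ce)
    return results
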