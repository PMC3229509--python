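"""Rule-based and SVM classification of nuclei left out of every cell graph.

Nuclei that neither touch nor intensity-match any neighbour never enter a
subgraph, so they get their own pass:

1. **inflammatory rule** — lymphocyte-like nuclei are small (< 500 px),
   round (isoperimetric roundness 4*pi*S/w^2 above a threshold) and very
   bright; hits are stroma.
2. **fibroblast rule** — strongly elongated nuclei
   (eccentricity sqrt(1 - (d_min/d_max)^2) above a threshold); hits are
   stroma.
3. the remainder go to a per-nucleus RBF-SVM over the 12 morphological and
   intensity features.

The intensity and roundness cut-offs are free parameters; by default the
intensity threshold is derived per core as the Otsu split of the nucleus
mean intensities plus 30 levels, which tracks staining variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import STROMA_LABEL, SvmModel
from .features import node_feature_matrix
from .preprocess import otsu_threshold
from .segment import NucleusRecord

__all__ = [
    "SingleCellRuleParams",
    "derive_intensity_threshold",
    "roundness",
    "is_inflammatory",
    "is_fibroblast",
    "classify_single_cells",
]


@dataclass
class SingleCellRuleParams:
    """Thresholds of the two stromal rules.

    ``intensity_threshold=None`` means "derive per core" via
    :func:`derive_intensity_threshold`.
    """

    intensity_threshold: Optional[float] = None
    roundness_threshold: float = 0.85
    max_inflammatory_area_px: int = 500
    eccentricity_threshold: float = 0.9

    def __post_init__(self):
        if self.roundness_threshold <= 0 or self.roundness_threshold > 1:
            raise ValueError("roundness_threshold must lie in (0,1]")
        if not 0 < self.eccentricity_threshold < 1:
            raise ValueError("eccentricity_threshold must lie in (0,1)")
        if self.max_inflammatory_area_px <= 0:
            raise ValueError("max_inflammatory_area_px must be positive")


def derive_intensity_threshold(records: Sequence[NucleusRecord],
                               offset: float = 30.0) -> float:
    """Otsu split of the core's nucleus mean intensities, plus ``offset``.

    Falls back to the overall mean + offset when the means cannot be split
    (fewer than two distinct levels).
    """
    means = np.array([r.mean_intensity for r in records], dtype=float)
    if means.size == 0:
        return offset
    try:
        t = float(otsu_threshold(np.clip(np.rint(means), 0, 255).astype(int)))
    except ValueError:
        t = float(means.mean())
    return t + offset


def roundness(nucleus: NucleusRecord) -> float:
    """Isoperimetric roundness 4*pi*S/w^2 (1 for a perfect disc)."""
    if nucleus.perimeter_px <= 0:
        raise ValueError("roundness undefined for zero perimeter")
    return 4.0 * np.pi * nucleus.area_px / nucleus.perimeter_px ** 2


def is_inflammatory(nucleus: NucleusRecord, params: SingleCellRuleParams,
                    intensity_threshold: Optional[float] = None) -> bool:
    """Small, round, very bright nucleus -> inflammatory (stromal) cell."""
    it = intensity_threshold if intensity_threshold is not None \
        else params.intensity_threshold
    if it is None:
        raise ValueError("intensity threshold neither set nor derived")
    return (nucleus.mean_intensity > it
            and roundness(nucleus) > params.roundness_threshold
            and nucleus.area_px < params.max_inflammatory_area_px)


def is_fibroblast(nucleus: NucleusRecord, params: SingleCellRuleParams) -> bool:
    """Strongly elongated nucleus -> fibroblast (stromal) cell."""
    if nucleus.major_axis_px <= 0:
        raise ValueError("eccentricity undefined for zero major axis")
    return nucleus.eccentricity > params.eccentricity_threshold


def classify_single_cells(isolated: Sequence[NucleusRecord],
                          params: SingleCellRuleParams,
                          node_model: Optional[SvmModel] = None) -> pd.DataFrame:
    """Label every isolated nucleus; rules first, then the per-nucleus SVM.

    Returns a DataFrame indexed by nucleus label with columns ``pred``
    (+-1) and ``rule_applied`` in {inflammatory, fibroblast, svm}.  Raises
    when non-rule nuclei remain but no model is supplied.
    """
    isolated = list(isolated)
    if not isolated:
        return pd.DataFrame(columns=["pred", "rule_applied"],
                            index=pd.Index([], name="label"))
    it = params.intensity_threshold
    if it is None:
        it = derive_intensity_threshold(isolated)
    preds: List[int] = [0] * len(isolated)
    rules: List[str] = [""] * len(isolated)
    remainder = []
    for i, rec in enumerate(isolated):
        if is_inflammatory(rec, params, intensity_threshold=it):
            preds[i], rules[i] = STROMA_LABEL, "inflammatory"
        elif is_fibroblast(rec, params):
            preds[i], rules[i] = STROMA_LABEL, "fibroblast"
        else:
            remainder.append(i)
    if remainder:
        if node_model is None:
            raise ValueError("a per-nucleus model is required for non-rule nuclei")
        feats = node_feature_matrix([isolated[i] for i in remainder])
        svm_pred = node_model.predict(feats)
        for i, p in zip(remainder, svm_pred):
            preds[i], rules[i] = int(p), "svm"
    return pd.DataFrame({"pred": preds, "rule_applied": rules},
                        index=pd.Index([r.label for r in isolated], name="label"))
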