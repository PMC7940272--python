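"""EM/EDX layer: telolysosome counts per beta cell and nitrogen-rim calls.

Telolysosomes (lipofuscin bodies) are identified morphologically upstream;
this module consumes annotated object masks with a ``kind`` label
(secondary lysosome vs telolysosome) and aligned elemental intensity maps
(N, P, Os).  The rim score of an object is the ratio of mean nitrogen in
its peripheral shell to mean nitrogen in its eroded core; objects whose
shell is N-enriched beyond a cutoff — and whose core is phosphorus-rich
relative to the image background, the phospholipid signature — are called
rim-positive.  Class occupancy is then reported over the four classes
Lys-/Lys+/Tel-/Tel+.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from punctaflux.stats_flux import sem, unpaired_t

KINDS = ("secondary", "telolysosome")
CLASS_ORDER = ("Lys-", "Lys+", "Tel-", "Tel+")


@dataclasses.dataclass(frozen=True)
class RimClassification:
    object_id: int
    kind: str  # secondary | telolysosome
    rim_score: float  # mean N in shell / mean N in core
    rim_positive: bool
    core_p_enriched: bool
    flag_unclassifiable: bool = False

    @property
    def class_label(self) -> str:
        base = "Tel" if self.kind == "telolysosome" else "Lys"
        return base + ("+" if self.rim_positive else "-")


def telolysosome_density(counts_by_group: dict[str, list[int]]) -> pd.DataFrame:
    """Per-cell telolysosome counts summarised per donor group.

    ``counts_by_group`` maps a group label to per-cell counts.  Returns
    mean +/- SEM and n per group; when exactly two groups are given, the
    unpaired t statistic and p-value against the other group are attached.
    """
    if not counts_by_group or any(len(v) == 0 for v in counts_by_group.values()):
        raise ValueError("every group needs a non-empty list of per-cell counts")
    rows = [
        {"group": g, "mean": float(np.mean(v)), "sem": sem(v), "n_cells": len(v)}
        for g, v in counts_by_group.items()
    ]
    out = pd.DataFrame(rows)
    if len(counts_by_group) == 2:
        (a, b) = counts_by_group.values()
        t_stat, p = unpaired_t(a, b)
        out["t"] = t_stat
        out["p"] = p
    return out


def rim_score(
    object_mask: np.ndarray, n_map: np.ndarray, shell_width: int = 3
) -> tuple[float, bool]:
    """Shell/core mean-nitrogen ratio for one object.

    The core is the object eroded by ``shell_width`` pixels; the shell is
    the remainder.  Returns ``(score, ok)``; ``ok`` is False when erosion
    empties the core (object too small to classify).  Being a ratio of
    means, the score is invariant to linear rescaling of the N map.
    """
    mask = np.asarray(object_mask, dtype=bool)
    if mask.shape != np.asarray(n_map).shape:
        raise ValueError("N map must be aligned with the object mask")
    core = ndimage.binary_erosion(mask, iterations=shell_width)
    shell = mask & ~core
    if not core.any() or not shell.any():
        return float("nan"), False
    core_mean = float(np.mean(n_map[core]))
    shell_mean = float(np.mean(n_map[shell]))
    if core_mean <= 0:
        return float("inf") if shell_mean > 0 else float("nan"), core_mean == 0 and shell_mean > 0
    return shell_mean / core_mean, True


def rim_classify(
    object_mask: np.ndarray,
    n_map: np.ndarray,
    p_map: np.ndarray,
    kind: str = "telolysosome",
    object_id: int = 0,
    shell_width: int = 3,
    ratio_cut: float = 1.5,
) -> RimClassification:
    """Classify one lysosomal object as rim-positive or rim-negative.

    rim-positive requires both (a) shell/core mean-N ratio >= ``ratio_cut``
    and (b) a phosphorus-enriched core (mean P over the core exceeds the
    mean P over the non-object background), consistent with nitrogen
    accumulating around a phospholipid-rich core.  Objects too small for a
    ``shell_width`` erosion are flagged unclassifiable.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    mask = np.asarray(object_mask, dtype=bool)
    score, ok = rim_score(mask, n_map, shell_width=shell_width)
    if not ok:
        return RimClassification(object_id, kind, float("nan"), False, False, flag_unclassifiable=True)
    core = ndimage.binary_erosion(mask, iterations=shell_width)
    background = ~mask
    core_p = float(np.mean(np.asarray(p_map)[core]))
    bg_p = float(np.mean(np.asarray(p_map)[background])) if background.any() else 0.0
    p_enriched = core_p > bg_p
    positive = bool(score >= ratio_cut and p_enriched)
    return RimClassification(object_id, kind, float(score), positive, p_enriched)


def classify_labelled_objects(
    labels: np.ndarray,
    kinds: dict[int, str],
    n_map: np.ndarray,
    p_map: np.ndarray,
    shell_width: int = 3,
    ratio_cut: float = 1.5,
) -> list[RimClassification]:
    """Run :func:`rim_classify` over every object of a label image."""
    out = []
    for obj_id in np.unique(labels):
        if obj_id == 0:
            continue
        out.append(
            rim_classify(
                labels == obj_id,
                n_map,
                p_map,
                kind=kinds.get(int(obj_id), "telolysosome"),
                object_id=int(obj_id),
                shell_width=shell_width,
                ratio_cut=ratio_cut,
            )
        )
    return out


def occupancy(objects: list[RimClassification]) -> pd.DataFrame:
    """Percent of objects in each of the Lys-/Lys+/Tel-/Tel+ classes.

    Unclassifiable objects are excluded from the denominator.  Percentages
    sum to 100 exactly (up to float round-off).
    """
    usable = [o for o in objects if not o.flag_unclassifiable]
    if not usable:
        raise ValueError("no classifiable objects")
    n = len(usable)
    counts = {c: 0 for c in CLASS_ORDER}
    for o in usable:
        counts[o.class_label] += 1
    return pd.DataFrame(
        {
            "class": list(CLASS_ORDER),
            "n": [counts[c] for c in CLASS_ORDER],
            "percent": [100.0 * counts[c] / n for c in CLASS_ORDER],
        }
    )
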