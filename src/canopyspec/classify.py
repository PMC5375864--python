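"""Canopy component separation.

Two spectral-matching baselines — the spectral angle mapper (SAM) and
spectral information divergence (SID) against per-class mean spectra —
and the index-based decision tree that actually separates the four
classes:

    PRI >= pri_split ?          (leaves have higher PRI than panicles)
      yes -> TCARI >= tcari_leaf_split    ? SL : SHL
      no  -> TCARI >= tcari_panicle_split ? SP : SHP

(sunlit components have higher TCARI, because TCARI scales with
reflectance amplitude).  Thresholds are midpoints of class mean index
values, each class mean taken by averaging its per-stage means over the
whole growing season.  Evaluation is stratified ten-fold cross-validation
with per-fold threshold re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DerivationError,
    StratificationError,
    UndefinedValueError,
)
from .indices import pri, tcari, vi_image
from .spectra import BLUE_WINDOW, RED_WINDOW, continuum_remove
from .types import (
    CLASS_CODES,
    COMPONENT_CLASSES,
    HyperCube,
    LabelMap,
    Spectrum,
    SpectralLibrary,
    Thresholds,
)

#: Lower value of a matching metric means more similar.
METRICS = ("sam", "sid")
SPACES = ("reflectance", "continuum_removed")

_SID_FLOOR = 1e-6


def sam(x: Spectrum, y: Spectrum) -> float:
    """Spectral angle (radians) between two spectra viewed as vectors.

    Amplitude-invariant: proportional spectra have angle 0.
    """
    a, b = np.asarray(x.values), np.asarray(y.values)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedValueError("SAM undefined for a zero spectrum")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def sid(x: Spectrum, y: Spectrum) -> float:
    """Spectral information divergence: symmetrized relative entropy of the
    two spectra normalized to probability vectors (natural log).

    Values <= 0 are floored to 1e-6 before normalization so the entropy
    stays defined on calibrated data containing zeros.
    """
    p = np.maximum(np.asarray(x.values, float), _SID_FLOOR)
    q = np.maximum(np.asarray(y.values, float), _SID_FLOOR)
    p, q = p / p.sum(), q / q.sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


_METRIC_FUNCS = {"sam": sam, "sid": sid}


def to_matching_space(s: Spectrum, space: str) -> Spectrum:
    """Spectrum in the requested matching space.  ``continuum_removed``
    concatenates the blue-window and red-window CR segments."""
    if space == "reflectance":
        return s
    if space == "continuum_removed":
        blue = continuum_remove(s, BLUE_WINDOW)
        red = continuum_remove(s, RED_WINDOW)
        wl = np.concatenate([blue.wavelengths, red.wavelengths + 1e-6])
        return Spectrum(wl, np.concatenate([blue.values, red.values]))
    raise ValueError(f"unknown matching space {space!r}")


def class_references(
    library: SpectralLibrary, space: str = "reflectance", stage: str | None = None
) -> dict:
    """Per-class mean spectra in the matching space (season-pooled by
    default)."""
    refs = {}
    for cls in COMPONENT_CLASSES:
        entries = library.select(cls, stage)
        transformed = [to_matching_space(s, space) for _, _, s in entries]
        stack = np.vstack([t.values for t in transformed])
        refs[cls] = Spectrum(transformed[0].wavelengths, stack.mean(axis=0))
    return refs


def match_classify(
    s: Spectrum,
    references: dict,
    metric: str = "sam",
    space: str = "reflectance",
) -> str:
    """Class whose reference spectrum minimizes the metric.  ``references``
    must already be in the matching ``space``; ties break in the fixed
    class order SL, SHL, SP, SHP."""
    f = _METRIC_FUNCS[metric]
    t = to_matching_space(s, space)
    best, best_d = None, np.inf
    for cls in COMPONENT_CLASSES:
        if cls not in references:
            continue
        d = f(t, references[cls])
        if d < best_d:
            best, best_d = cls, d
    return best


def class_distance_table(
    library: SpectralLibrary, metric: str = "sam", space: str = "reflectance"
) -> pd.DataFrame:
    """Mean metric value of every spectrum of class *i* (rows) against the
    mean spectrum of class *j* (columns).  Not symmetric in general."""
    f = _METRIC_FUNCS[metric]
    refs = class_references(library, space)
    table = pd.DataFrame(
        index=list(COMPONENT_CLASSES), columns=list(COMPONENT_CLASSES), dtype=float
    )
    for ci in COMPONENT_CLASSES:
        spectra = [to_matching_space(s, space) for _, _, s in library.select(ci)]
        for cj in COMPONENT_CLASSES:
            table.loc[ci, cj] = float(np.mean([f(s, refs[cj]) for s in spectra]))
    return table


def library_vi_samples(library: SpectralLibrary) -> pd.DataFrame:
    """PRI and TCARI of every library spectrum, with class and stage."""
    rows = [
        {
            "class": cls,
            "stage": stage,
            "pri": pri(s).value,
            "tcari": tcari(s).value,
        }
        for cls, stage, s in library.entries
    ]
    return pd.DataFrame(rows)


def _season_class_mean(samples: pd.DataFrame, cls: str, column: str, pooled: bool) -> float:
    sub = samples[samples["class"] == cls]
    if sub.empty:
        raise DerivationError(f"no samples for class {cls}")
    if pooled:
        return float(sub[column].mean())
    # average within each stage first, then average the stage means
    return float(sub.groupby("stage")[column].mean().mean())


def derive_thresholds(samples: pd.DataFrame, pooled: bool = False) -> Thresholds:
    """Decision-tree thresholds from labeled PRI/TCARI samples.

    Each class mean is the average of its per-stage means over the season
    (set ``pooled=True`` to average raw samples instead).  The PRI split is
    the midpoint of the leaf (SL+SHL) and panicle (SP+SHP) means; each
    TCARI split is the midpoint of the sunlit and shaded class means of
    that organ.
    """
    need = {"class", "stage", "pri", "tcari"} - set(samples.columns)
    if need:
        raise DerivationError(f"samples missing columns {sorted(need)}")
    m = {
        (cls, col): _season_class_mean(samples, cls, col, pooled)
        for cls in COMPONENT_CLASSES
        for col in ("pri", "tcari")
    }
    leaf_pri = (m[("SL", "pri")] + m[("SHL", "pri")]) / 2.0
    pan_pri = (m[("SP", "pri")] + m[("SHP", "pri")]) / 2.0
    return Thresholds(
        pri_split=(leaf_pri + pan_pri) / 2.0,
        tcari_leaf_split=(m[("SL", "tcari")] + m[("SHL", "tcari")]) / 2.0,
        tcari_panicle_split=(m[("SP", "tcari")] + m[("SHP", "tcari")]) / 2.0,
    )


def decision_tree_classify(pri_value: float, tcari_value: float, t: Thresholds) -> str:
    """One pixel through the PRI -> TCARI tree.  Boundary equality goes to
    the leaf / sunlit branch."""
    if pri_value >= t.pri_split:
        return "SL" if tcari_value >= t.tcari_leaf_split else "SHL"
    return "SP" if tcari_value >= t.tcari_panicle_split else "SHP"


def classify_image(
    cube: HyperCube, t: Thresholds, veg_mask: np.ndarray | None = None
) -> LabelMap:
    """Per-pixel decision-tree classification of a reflectance cube.

    Non-vegetation pixels (mask False) become NONVEG; pixels with an
    undefined index become UNLABELED; the map never aborts.
    """
    pri_map = vi_image(cube, "PRI", veg_mask)
    tcari_map = vi_image(cube, "TCARI", veg_mask)
    labels = np.full(pri_map.shape, CLASS_CODES["UNLABELED"], dtype=np.int32)
    valid = np.isfinite(pri_map) & np.isfinite(tcari_map)
    leaf = pri_map >= t.pri_split
    labels[valid & leaf & (tcari_map >= t.tcari_leaf_split)] = CLASS_CODES["SL"]
    labels[valid & leaf & (tcari_map < t.tcari_leaf_split)] = CLASS_CODES["SHL"]
    labels[valid & ~leaf & (tcari_map >= t.tcari_panicle_split)] = CLASS_CODES["SP"]
    labels[valid & ~leaf & (tcari_map < t.tcari_panicle_split)] = CLASS_CODES["SHP"]
    if veg_mask is not None:
        labels[~np.asarray(veg_mask, bool)] = CLASS_CODES["NONVEG"]
    return LabelMap(labels, {v: k for k, v in CLASS_CODES.items()})


@dataclass
class ConfusionMatrix:
    """Truth (rows) x predicted (cols) counts in fixed class order
    SL, SHL, SP, SHP."""

    counts: np.ndarray
    classes: tuple = COMPONENT_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )


def confusion_from_pairs(truth, predicted) -> ConfusionMatrix:
    """Build a confusion matrix from parallel truth/prediction label lists."""
    idx = {c: i for i, c in enumerate(COMPONENT_CLASSES)}
    counts = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts)


def cross_validate(
    samples: pd.DataFrame, folds: int = 10, seed: int = 0, pooled: bool = False
):
    """Stratified k-fold cross-validation of the decision tree.

    Folds are assigned per class with the seeded generator; thresholds are
    re-derived on each training split and applied to the held-out samples.
    Returns the pooled :class:`ConfusionMatrix` and its overall accuracy.
    """
    if folds < 2:
        raise StratificationError("need at least 2 folds")
    samples = samples.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(samples), dtype=int)
    for cls in COMPONENT_CLASSES:
        idx = np.flatnonzero(samples["class"].to_numpy() == cls)
        if len(idx) < folds:
            raise StratificationError(
                f"class {cls} has {len(idx)} samples < {folds} folds"
            )
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    truth_all, pred_all = [], []
    for f in range(folds):
        train = samples[fold_of != f]
        test = samples[fold_of == f]
        t = derive_thresholds(train, pooled=pooled)
        for _, row in test.iterrows():
            truth_all.append(row["class"])
            pred_all.append(decision_tree_classify(row["pri"], row["tcari"], t))
    cm = confusion_from_pairs(truth_all, pred_all)
    return cm, cm.overall_accuracy


def match_classify_accuracy(
    library: SpectralLibrary, metric: str = "sam", space: str = "reflectance"
) -> float:
    """Fraction of library spectra assigned to their own class when matched
    against the season-pooled class mean spectra."""
    refs = class_references(library, space)
    correct = sum(
        match_classify(s, refs, metric, space) == cls for cls, _, s in library.entries
    )
    return correct / len(library.entries)


def sunlit_shaded_ratio(labels: LabelMap) -> float:
    """count(SL) / count(SHL); NaN when there are no shaded-leaf pixels.
    Non-vegetation pixels do not enter the ratio."""
    n_shl = labels.count("SHL")
    if n_shl == 0:
        return float("nan")
    return labels.count("SL") / n_shl
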