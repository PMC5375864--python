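"""End-to-end composition: season generation -> ROI library -> thresholds
-> image classification -> group statistics.

These helpers glue the module-level operations into the workflow a field
campaign would follow: build a labeled spectral library from regions of
interest, derive decision-tree thresholds from its index values, classify
every scene, then relate per-scene group means of the indices to the
plot-level chlorophyll truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (
    classify_image,
    derive_thresholds,
    library_vi_samples,
    sunlit_shaded_ratio,
)
from .indices import vi_image
from .preprocess import evi_mask
from .types import CLASS_CODES, COMPONENT_CLASSES, Spectrum, SpectralLibrary, Thresholds

VI_NAMES = ("NDVI", "TCARI", "PRI", "CI_red_edge")


def roi_library(
    scenes, n_per_class: int = 20, seed: int = 0
) -> SpectralLibrary:
    """Sample ROI pixels per class from each scene's truth labels, as a
    labeled spectral library (the manual-ROI step of a field campaign)."""
    rng = np.random.default_rng(seed)
    entries = []
    for scene in scenes:
        for cls in COMPONENT_CLASSES:
            code = CLASS_CODES[cls]
            pix = np.argwhere(scene.labels.labels == code)
            if len(pix) == 0:
                continue
            take = pix[rng.choice(len(pix), min(n_per_class, len(pix)), replace=False)]
            for r, c in take:
                entries.append(
                    (cls, scene.stage, Spectrum(scene.cube.wavelengths,
                                                scene.cube.data[r, c]))
                )
    return SpectralLibrary(entries=entries)


def season_thresholds(library: SpectralLibrary, pooled: bool = False) -> Thresholds:
    """Decision-tree thresholds from a library's PRI/TCARI values."""
    return derive_thresholds(library_vi_samples(library), pooled=pooled)


def group_vi_table(scenes, thresholds: Thresholds, use_truth_labels: bool = False) -> pd.DataFrame:
    """Per-scene mean VI over SL and SHL pixels plus the plot truth.

    Pixels are separated with the EVI vegetation mask and the decision
    tree (or the generator's truth labels when ``use_truth_labels``).
    One row per scene x group, columns: plot_id, stage, group, lcc, ccc,
    and the four VIs.
    """
    rows = []
    for scene in scenes:
        if use_truth_labels:
            labels = scene.labels.labels
        else:
            mask = evi_mask(scene.cube)
            labels = classify_image(scene.cube, thresholds, mask).labels
        vi_maps = {vi: vi_image(scene.cube, vi) for vi in VI_NAMES}
        for group in ("SL", "SHL"):
            sel = labels == CLASS_CODES[group]
            if not sel.any():
                continue
            row = {
                "plot_id": scene.plot_id,
                "stage": scene.stage,
                "group": group,
                "lcc": scene.record.lcc if scene.record else np.nan,
                "ccc": scene.record.ccc if scene.record else np.nan,
                "n_pixels": int(sel.sum()),
            }
            for vi, vmap in vi_maps.items():
                row[vi] = float(np.nanmean(vmap[sel]))
            rows.append(row)
    return pd.DataFrame(rows)


def class_stage_vi_means(library: SpectralLibrary) -> pd.DataFrame:
    """Mean of each VI per class x stage over library spectra (the ROI
    seasonal-profile summary)."""
    from .indices import vi_spectrum

    rows = []
    for cls, stage, s in library.entries:
        row = {"class": cls, "stage": stage}
        for vi in VI_NAMES:
            row[vi] = vi_spectrum(s, vi).value
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby(["class", "stage"], as_index=False)[list(VI_NAMES)].mean()


def scene_class_vi_means(scenes) -> pd.DataFrame:
    """Mean of each VI per class x stage over *all* truth-labeled pixels of
    every scene (the seasonal class profile at full population size)."""
    rows = []
    for scene in scenes:
        vi_maps = {vi: vi_image(scene.cube, vi) for vi in VI_NAMES}
        for cls in COMPONENT_CLASSES:
            sel = scene.labels.labels == CLASS_CODES[cls]
            if not sel.any():
                continue
            row = {"class": cls, "stage": scene.stage, "n": int(sel.sum())}
            for vi, vmap in vi_maps.items():
                row[vi] = float(np.nanmean(vmap[sel]))
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby(["class", "stage"], as_index=False)[list(VI_NAMES)].mean()


def season_sunlit_shaded_ratios(scenes, thresholds: Thresholds) -> pd.DataFrame:
    """Per-stage mean sunlit/shaded leaf pixel ratio from classified maps."""
    rows = []
    for scene in scenes:
        mask = evi_mask(scene.cube)
        labels = classify_image(scene.cube, thresholds, mask)
        rows.append({"stage": scene.stage, "ratio": sunlit_shaded_ratio(labels)})
    return pd.DataFrame(rows).groupby("stage", as_index=False)["ratio"].mean()
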