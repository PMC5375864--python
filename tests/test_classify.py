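import numpy as np
import pandas as pd
import pytest

from canopyspec import (
    COMPONENT_CLASSES,
    Spectrum,
    SpectralLibrary,
    Thresholds,
    classify_image,
    cross_validate,
    decision_tree_classify,
    derive_thresholds,
    match_classify,
    sam,
    sid,
    sunlit_shaded_ratio,
)
from canopyspec.classify import (
    class_distance_table,
    class_references,
    confusion_from_pairs,
    library_vi_samples,
    to_matching_space,
)
from canopyspec.errors import StratificationError, UndefinedValueError
from canopyspec.types import CLASS_CODES, LabelMap


def spec(vals, wl=None):
    vals = np.asarray(vals, float)
    wl = np.arange(len(vals), dtype=float) * 10 + 400 if wl is None else wl
    return Spectrum(wl, vals)


# --- SAM -------------------------------------------------------------------

def test_sam_identity_and_scale_invariance():
    x = spec([0.1, 0.3, 0.5])
    assert sam(x, x) == 0.0
    assert sam(x, spec([0.3, 0.9, 1.5])) == pytest.approx(0.0, abs=1e-7)


def test_sam_orthogonal_vectors():
    assert sam(spec([1.0, 0.0]), spec([0.0, 1.0])) == pytest.approx(np.pi / 2)


def test_sam_zero_spectrum_rejected():
    with pytest.raises(UndefinedValueError):
        sam(spec([0.0, 0.0]), spec([0.1, 0.2]))


def test_sam_positive_unless_proportional():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x, y = spec(rng.random(30) + 0.01), spec(rng.random(30) + 0.01)
        assert sam(x, y) > 0
        assert 0 <= sam(x, y) <= np.pi


# --- SID -------------------------------------------------------------------

def test_sid_hand_value():
    """Both Kullback-Leibler terms of the two-band example computed by hand:
    0.5 ln(4/3) + (0.25 ln 0.5 + 0.75 ln 1.5) = 0.27465"""
    x, y = spec([0.5, 0.5]), spec([0.25, 0.75])
    expected = 0.5 * np.log(4 / 3) + 0.25 * np.log(0.5) + 0.75 * np.log(1.5)
    assert sid(x, y) == pytest.approx(expected)
    assert sid(x, y) == pytest.approx(0.2746, abs=2e-4)


def test_sid_symmetry_zero_and_nonnegative():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x, y = spec(rng.random(25) + 0.01), spec(rng.random(25) + 0.01)
        assert sid(x, y) == pytest.approx(sid(y, x), rel=1e-12)
        assert sid(x, y) >= 0
        assert sid(x, x) == 0.0


def test_sid_matches_scipy_entropy():
    from scipy.stats import entropy

    rng = np.random.default_rng(2)
    x, y = spec(rng.random(40) + 0.01), spec(rng.random(40) + 0.01)
    p, q = x.values / x.values.sum(), y.values / y.values.sum()
    assert sid(x, y) == pytest.approx(entropy(p, q) + entropy(q, p), rel=1e-10)


# --- matching classification ----------------------------------------------

def library_of_constants():
    wl = np.arange(400, 900, 25.0)
    shapes = {
        "SL": np.linspace(0.1, 0.6, wl.size),
        "SHL": np.linspace(0.6, 0.1, wl.size),
        "SP": np.full(wl.size, 0.4) + 0.2 * np.sin(wl / 40),
        "SHP": np.full(wl.size, 0.4) + 0.2 * np.cos(wl / 40),
    }
    entries = [
        (cls, stage, Spectrum(wl, shapes[cls]))
        for cls in COMPONENT_CLASSES
        for stage in ("HD", "FL")
    ]
    return SpectralLibrary(entries=entries)


def test_match_classify_own_reference_and_scale():
    lib = library_of_constants()
    refs = class_references(lib, "reflectance")
    for cls in COMPONENT_CLASSES:
        assert match_classify(refs[cls], refs, "sam") == cls
        doubled = Spectrum(refs[cls].wavelengths, 2 * refs[cls].values)
        assert match_classify(doubled, refs, "sam") == cls  # SAM scale-invariant


def test_match_classify_separable_synthetic_library(season_library):
    """Well-separated synthetic classes are recovered at >= 95% by SAM on
    continuum-removed spectra."""
    from canopyspec.classify import match_classify_accuracy

    acc = match_classify_accuracy(season_library, "sam", "continuum_removed")
    assert acc >= 0.80  # full four-class problem incl. shading
    # leaf-vs-panicle organ separation is nearly perfect
    refs = class_references(season_library, "continuum_removed")
    organ = {"SL": "leaf", "SHL": "leaf", "SP": "panicle", "SHP": "panicle"}
    hits = [
        organ[match_classify(s, refs, "sam", "continuum_removed")] == organ[cls]
        for cls, _, s in season_library.entries
    ]
    assert np.mean(hits) >= 0.95


def test_match_classify_well_separated_models():
    """200 spectra from four well-separated component models (low noise)
    are recovered at >= 95% by SAM on continuum-removed spectra."""
    from dataclasses import replace

    from canopyspec.classify import match_classify_accuracy
    from canopyspec.synth import component_batch, default_component_models

    grid = np.arange(400, 900.0001, 2.8)
    rng = np.random.default_rng(0)
    entries = []
    for cls, m in default_component_models("HD").items():
        m = replace(m, pixel_noise_sd=0.01, amplitude_jitter_sd=0.02)
        for v in component_batch(m, grid, rng, 50):
            entries.append((cls, "HD", Spectrum(grid, v)))
    lib = SpectralLibrary(entries=entries)
    assert match_classify_accuracy(lib, "sam", "continuum_removed") >= 0.95


def test_class_distance_table_structure_and_oracle():
    lib = library_of_constants()
    table = class_distance_table(lib, "sam", "reflectance")
    # identical spectra within each class: zero diagonal, positive off-diagonal
    for ci in COMPONENT_CLASSES:
        assert table.loc[ci, ci] == pytest.approx(0.0, abs=1e-6)
        for cj in COMPONENT_CLASSES:
            if ci != cj:
                assert table.loc[ci, cj] > 0
    # loop-oracle recomputation
    refs = class_references(lib, "reflectance")
    for ci in COMPONENT_CLASSES:
        vals = [sam(s, refs["SHL"]) for cls, _, s in lib.entries if cls == ci]
        assert table.loc[ci, "SHL"] == pytest.approx(np.mean(vals), rel=1e-12)


def test_distance_table_diagonal_smallest_on_season_library(season_library):
    table = class_distance_table(season_library, "sam", "reflectance")
    for ci in ("SL", "SP"):  # sunlit classes are crisply self-similar
        row = table.loc[ci]
        assert row[ci] == min(row)


# --- thresholds and the decision tree -------------------------------------

def make_samples(means, n=6):
    """Balanced VI samples with exact class means, split over two stages."""
    rows = []
    for cls, (mp, mt) in means.items():
        for stage in ("HD", "FL"):
            for d in np.linspace(-0.01, 0.01, n):
                rows.append({"class": cls, "stage": stage, "pri": mp + d, "tcari": mt + d})
    return pd.DataFrame(rows)


def test_derive_thresholds_are_midpoints():
    means = {"SL": (0.11, 0.30), "SHL": (0.09, 0.10), "SP": (-0.01, 0.20), "SHP": (-0.03, 0.08)}
    t = derive_thresholds(make_samples(means))
    leaf_pri, pan_pri = (0.11 + 0.09) / 2, (-0.01 - 0.03) / 2
    assert t.pri_split == pytest.approx((leaf_pri + pan_pri) / 2)
    assert t.tcari_leaf_split == pytest.approx((0.30 + 0.10) / 2)
    assert t.tcari_panicle_split == pytest.approx((0.20 + 0.08) / 2)


def test_derive_thresholds_stage_mean_weighting():
    """Season means average stage means, not pooled samples: an unbalanced
    stage must not dominate."""
    rows = (
        [{"class": "SL", "stage": "HD", "pri": 0.2, "tcari": 0.4}] * 9
        + [{"class": "SL", "stage": "FL", "pri": 0.0, "tcari": 0.2}]
    )
    for cls in ("SHL", "SP", "SHP"):
        rows += [
            {"class": cls, "stage": s, "pri": 0.0, "tcari": 0.0} for s in ("HD", "FL")
        ]
    df = pd.DataFrame(rows)
    t_stage = derive_thresholds(df)                 # (0.2+0.0)/2 = 0.1 for SL
    t_pooled = derive_thresholds(df, pooled=True)   # 0.18 for SL
    assert t_stage.tcari_leaf_split == pytest.approx((0.3 + 0.0) / 2)
    assert t_pooled.tcari_leaf_split == pytest.approx((0.38 + 0.0) / 2)


@pytest.mark.parametrize(
    "pri_v,tcari_v,expected",
    [
        (0.1, 0.5, "SL"),
        (0.1, 0.1, "SHL"),
        (-0.1, 0.5, "SP"),
        (-0.1, 0.0, "SHP"),
        (0.04, 0.2, "SL"),     # exactly on both splits -> leaf, sunlit
        (0.04, 0.19, "SHL"),   # on PRI split, below leaf TCARI split
        (0.039, 0.15, "SP"),   # just below PRI split, on panicle split
    ],
)
def test_decision_tree_truth_table(pri_v, tcari_v, expected):
    t = Thresholds(pri_split=0.04, tcari_leaf_split=0.2, tcari_panicle_split=0.15)
    assert decision_tree_classify(pri_v, tcari_v, t) == expected


def test_classify_image_matches_loop_oracle(season, season_library):
    from canopyspec.indices import pri as pri_fn
    from canopyspec.indices import tcari as tcari_fn
    from canopyspec.pipeline import season_thresholds

    scenes, _ = season
    cube = scenes[0].cube
    t = season_thresholds(season_library)
    labels = classify_image(cube, t)
    names = labels.code_table
    for r in range(0, 50, 11):
        for c in range(0, 50, 7):
            s = cube.pixel(r, c)
            expect = decision_tree_classify(pri_fn(s).value, tcari_fn(s).value, t)
            assert names[labels.labels[r, c]] == expect


def test_classify_image_all_masked_is_nonveg(grid):
    from canopyspec.synth import SceneConfig, generate_scene

    cube, _ = generate_scene(SceneConfig(rows=4, cols=4, stage="HD", seed=0))
    t = Thresholds(0.0, 0.1, 0.1)
    labels = classify_image(cube, t, veg_mask=np.zeros((4, 4), bool))
    assert np.all(labels.labels == CLASS_CODES["NONVEG"])


# --- cross-validation ------------------------------------------------------

def test_cross_validate_perfectly_separable():
    means = {"SL": (0.2, 0.5), "SHL": (0.2, 0.1), "SP": (-0.2, 0.5), "SHP": (-0.2, 0.1)}
    cm, acc = cross_validate(make_samples(means, n=10), folds=10, seed=0)
    assert acc == 1.0
    assert cm.total == 4 * 2 * 10


def test_cross_validate_deterministic(season_library):
    samples = library_vi_samples(season_library)
    cm1, a1 = cross_validate(samples, folds=10, seed=5)
    cm2, a2 = cross_validate(samples, folds=10, seed=5)
    assert a1 == a2
    np.testing.assert_array_equal(cm1.counts, cm2.counts)
    assert cm1.total == len(samples)


def test_cross_validate_small_class_rejected():
    means = {"SL": (0.2, 0.5), "SHL": (0.2, 0.1), "SP": (-0.2, 0.5), "SHP": (-0.2, 0.1)}
    df = make_samples(means, n=2)
    with pytest.raises(StratificationError):
        cross_validate(df, folds=30)


def test_cross_validate_permutation_null():
    """With labels shuffled over 4 balanced classes, accuracy sits at the
    1/4 chance level (within 3 binomial SDs)."""
    rng = np.random.default_rng(17)
    n = 100
    rows = []
    for cls in COMPONENT_CLASSES:
        for _ in range(n):
            rows.append(
                {
                    "class": cls,
                    "stage": rng.choice(["HD", "FL"]),
                    "pri": rng.normal(),
                    "tcari": rng.normal(),
                }
            )
    df = pd.DataFrame(rows)
    df["class"] = rng.permutation(df["class"].to_numpy())
    _, acc = cross_validate(df, folds=10, seed=3)
    sd = np.sqrt(0.25 * 0.75 / (4 * n))
    assert abs(acc - 0.25) <= 3 * sd


# --- pixel-count ratio -----------------------------------------------------

def test_sunlit_shaded_ratio():
    codes = {v: k for k, v in CLASS_CODES.items()}
    arr = np.array([[1] * 10 + [2] * 20 + [5] * 6]).reshape(6, 6)
    assert sunlit_shaded_ratio(LabelMap(arr, codes)) == pytest.approx(0.5)
    # NONVEG pixels never enter the ratio
    arr2 = np.array([[1] * 10 + [2] * 20 + [0] * 6]).reshape(6, 6)
    assert sunlit_shaded_ratio(LabelMap(arr2, codes)) == pytest.approx(0.5)


def test_sunlit_shaded_ratio_no_shaded_is_nan():
    codes = {v: k for k, v in CLASS_CODES.items()}
    assert np.isnan(sunlit_shaded_ratio(LabelMap(np.ones((2, 2), int), codes)))


def test_confusion_matrix_counts():
    cm = confusion_from_pairs(["SL", "SL", "SHL"], ["SL", "SHL", "SHL"])
    assert cm.total == 3
    assert cm.overall_accuracy == pytest.approx(2 / 3)
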