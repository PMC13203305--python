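"""Classical handcrafted-feature baselines: LBP / HOG / LBP+HOG with SVMs.

Images go through the same CLAHE preprocessing as the deep pipeline, are
resized to 224 px and converted to grayscale.  LBP uses the plain 256-code
8-neighbour formulation at radius 1 (neighbour >= centre sets the bit;
circular neighbour ordering as in scikit-image, diagonal samples bilinearly
interpolated), summarized as a normalized 256-bin histogram.  HOG uses a
single centred 128-px window with 16-px blocks, 8-px stride, 8-px cells and
9 orientation bins, giving a 8100-dimensional descriptor.  Each feature set
is classified with a standardize-then-SVM pipeline (C=1, gamma='scale',
balanced class weights, probability outputs) under the same stratified
cross-validation protocol as the deep models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import hog, local_binary_pattern
from skimage.transform import resize
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import CvSummary, run_cross_validation
from .preprocessing import PreprocessConfig, apply_clahe
from .synthetic import LabeledImageSet

__all__ = [
    "HandcraftedFeatureConfig",
    "lbp_features",
    "hog_features",
    "extract_feature_matrix",
    "make_svm_pipeline",
    "run_baseline",
    "run_svm_cv",
]

FEATURE_MODES = ("lbp", "hog", "lbp+hog")


@dataclass(frozen=True)
class HandcraftedFeatureConfig:
    lbp_radius: int = 1
    lbp_neighbors: int = 8
    lbp_bins: int = 256
    hog_window: int = 128
    hog_block: int = 16
    hog_stride: int = 8
    hog_cell: int = 8
    hog_orientations: int = 9
    svm_c: float = 1.0
    svm_kernel: str = "linear"
    class_weight_balanced: bool = True

    def __post_init__(self):
        if self.svm_kernel not in ("linear", "rbf"):
            raise ValueError("svm_kernel must be 'linear' or 'rbf'")
        if self.hog_block % self.hog_cell:
            raise ValueError("hog_block must be a multiple of hog_cell")


def _to_gray_uint8(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        image = rgb2gray(image) * 255.0
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def lbp_features(gray: np.ndarray, config: HandcraftedFeatureConfig = HandcraftedFeatureConfig()) -> np.ndarray:
    """Normalized 256-bin histogram of plain (non-rotation-invariant) LBP codes."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("lbp_features expects a single-channel image")
    if min(gray.shape) < 3:
        raise ValueError("image must be at least 3x3")
    codes = local_binary_pattern(
        np.ascontiguousarray(gray), P=config.lbp_neighbors, R=config.lbp_radius, method="default"
    )
    r = config.lbp_radius  # border pixels lack in-image neighbours; exclude them
    codes = codes[r:-r, r:-r]
    histogram = np.bincount(codes.astype(np.int64).ravel(), minlength=config.lbp_bins).astype(
        np.float64
    )
    return histogram / histogram.sum()


def hog_features(gray: np.ndarray, config: HandcraftedFeatureConfig = HandcraftedFeatureConfig()) -> np.ndarray:
    """HOG descriptor of a single centred square window (L2-Hys block norm)."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("hog_features expects a single-channel image")
    w = config.hog_window
    if min(gray.shape) < w:
        raise ValueError(f"image smaller than the {w}-px HOG window")
    oy = (gray.shape[0] - w) // 2
    ox = (gray.shape[1] - w) // 2
    crop = gray[oy : oy + w, ox : ox + w]
    cells_per_block = config.hog_block // config.hog_cell
    return hog(
        crop,
        orientations=config.hog_orientations,
        pixels_per_cell=(config.hog_cell, config.hog_cell),
        cells_per_block=(cells_per_block, cells_per_block),
        block_norm="L2-Hys",
        feature_vector=True,
    )


def extract_feature_matrix(
    dataset: LabeledImageSet,
    mode: str,
    config: HandcraftedFeatureConfig = HandcraftedFeatureConfig(),
    preprocess_config: PreprocessConfig | None = None,
) -> np.ndarray:
    """CLAHE -> resize 224 -> grayscale -> handcrafted features, row per image."""
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    pre = preprocess_config or PreprocessConfig()
    rows = []
    for img in dataset.images:
        enhanced = apply_clahe(img, pre)
        scaled = resize(
            enhanced.astype(np.float64) / 255.0,
            (pre.target_size, pre.target_size),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        gray = _to_gray_uint8(scaled * 255.0)
        parts = []
        if mode in ("lbp", "lbp+hog"):
            parts.append(lbp_features(gray, config))
        if mode in ("hog", "lbp+hog"):
            parts.append(hog_features(gray, config))
        rows.append(np.concatenate(parts))
    return np.asarray(rows)


def make_svm_pipeline(config: HandcraftedFeatureConfig, seed: int = 42) -> Pipeline:
    return Pipeline(
        [
            ("scaler", StandardScaler()),
            (
                "svm",
                SVC(
                    C=config.svm_c,
                    kernel=config.svm_kernel,
                    gamma="scale",
                    probability=True,
                    class_weight="balanced" if config.class_weight_balanced else None,
                    random_state=int(seed),
                ),
            ),
        ]
    )


def run_svm_cv(
    features: np.ndarray,
    dataset: LabeledImageSet,
    config: HandcraftedFeatureConfig,
    n_splits: int = 5,
    seed: int = 42,
) -> CvSummary:
    """Cross-validate an SVM on precomputed features; the scaler is fit on
    training folds only (no test leakage)."""
    index = {id(img): i for i, img in enumerate(dataset.images)}

    def fit_predict(train_split, test_split, fold_id):
        tr = np.array([index[id(img)] for img in train_split.images])
        te = np.array([index[id(img)] for img in test_split.images])
        pipe = make_svm_pipeline(config, seed)
        pipe.fit(features[tr], train_split.labels)
        prob = pipe.predict_proba(features[te])
        # SVC orders columns by sorted class label; re-expand to all classes
        full = np.zeros((len(te), dataset.n_classes))
        full[:, pipe.classes_.astype(int)] = prob
        return full

    return run_cross_validation(dataset, fit_predict, n_splits=n_splits, seed=seed)


def run_baseline(
    dataset: LabeledImageSet,
    mode: str,
    config: HandcraftedFeatureConfig = HandcraftedFeatureConfig(),
    preprocess_config: PreprocessConfig | None = None,
    n_splits: int = 5,
    seed: int = 42,
) -> CvSummary:
    """Full classical baseline: features + standardized SVM under stratified CV."""
    features = extract_feature_matrix(dataset, mode, config, preprocess_config)
    return run_svm_cv(features, dataset, config, n_splits=n_splits, seed=seed)
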