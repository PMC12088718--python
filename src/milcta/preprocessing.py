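"""Multi-attenuation-window edge-fusion preprocessing.

A single CT window cannot show soft plaque (≈ −30..60 HU), vessel wall and
calcification (≥ 600 HU) at once, so each slice is windowed into five HU
ranges, each window is clipped/normalized and Sobel-filtered, and the edge
maps are fused by pointwise maximum.  The fused map is thresholded, cleaned
(border text removal, small-object removal), and its connected components are
ranked by area, major axis length and perimeter; only the top-ranked regions
are kept in the output image fed to the classifier.

The stages are exposed both as plain functions and as the sklearn-style
:class:`EdgeFusionPreprocessor` transformer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, transform
from sklearn.base import BaseEstimator, TransformerMixin

from .core import HUSlice

#: the five clinical attenuation windows (HU): fat/loose tissue, soft
#: plaque/water, fibrous tissue, contrast lumen, calcification.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (-150.0, -50.0),
    (-50.0, 50.0),
    (50.0, 130.0),
    (130.0, 400.0),
    (400.0, 1000.0),
)

#: maximum Sobel gradient magnitude attainable on [0,1] inputs (|gx|,|gy| ≤ 4)
_SOBEL_MAX = 4.0 * math.sqrt(2.0)


@dataclass(frozen=True)
class WindowSpec:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"window requires low < high, got ({self.low}, {self.high})")


@dataclass
class PreprocessParams:
    """Tunable pipeline parameters with the published windows as default."""

    windows: tuple[WindowSpec, ...] = tuple(WindowSpec(*w) for w in DEFAULT_WINDOWS)
    edge_threshold: float = 0.25
    min_object_px: int = 20
    connectivity: int = 8
    border_margin_px: int = 8
    keep_top_k: int = 2
    output_size: tuple[int, int] = (224, 224)

    def __post_init__(self) -> None:
        self.windows = tuple(w if isinstance(w, WindowSpec) else WindowSpec(*w) for w in self.windows)
        if not 0.0 < self.edge_threshold < 1.0:
            raise ValueError("edge_threshold must lie strictly in (0, 1)")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be ≥ 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def clip_and_normalize(hu_slice: HUSlice | np.ndarray, window: WindowSpec) -> np.ndarray:
    """Clip a slice to a HU window and map it linearly onto [0, 1]."""
    pixels = hu_slice.pixels if isinstance(hu_slice, HUSlice) else np.asarray(hu_slice, dtype=np.float32)
    if not np.all(np.isfinite(pixels)):
        sid = hu_slice.slice_id if isinstance(hu_slice, HUSlice) else "<array>"
        raise ValueError(f"non-finite pixel values in slice {sid}")
    clipped = np.clip(pixels, window.low, window.high)
    return ((clipped - window.low) / (window.high - window.low)).astype(np.float32)


def sobel_edges(norm: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, reflect-padded, scaled by 4√2 into [0, 1].

    The analytic bound (rather than the per-image maximum) keeps magnitudes
    comparable across windows before max-fusion.
    """
    norm = np.asarray(norm, dtype=np.float64)
    gx = ndimage.sobel(norm, axis=1, mode="reflect")
    gy = ndimage.sobel(norm, axis=0, mode="reflect")
    mag = np.hypot(gx, gy) / _SOBEL_MAX
    return np.clip(mag, 0.0, 1.0).astype(np.float32)


def fuse_max(edge_maps: list[np.ndarray]) -> np.ndarray:
    """Merge edge maps by pointwise maximum response."""
    if len(edge_maps) == 0:
        raise ValueError("fuse_max requires at least one edge map")
    shape = edge_maps[0].shape
    for m in edge_maps[1:]:
        if m.shape != shape:
            raise ValueError(f"edge map shape mismatch: {m.shape} vs {shape}")
    out = edge_maps[0]
    for m in edge_maps[1:]:
        out = np.maximum(out, m)
    return np.array(out, dtype=np.float32)


def threshold_and_clean(fused: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Threshold the fused edge map and drop border pixels and small objects.

    The border frame (burned-in text sits at image borders) is zeroed before
    component analysis; components with area strictly below ``min_object_px``
    are removed.
    """
    mask = np.asarray(fused) >= params.edge_threshold
    m = params.border_margin_px
    if m > 0:
        mask = mask.copy()
        mask[:m, :] = False
        mask[-m:, :] = False
        mask[:, :m] = False
        mask[:, -m:] = False
    skimage_conn = 2 if params.connectivity == 8 else 1
    # removal is strict: a component of exactly min_object_px pixels survives
    return morphology.remove_small_objects(mask, connectivity=skimage_conn, max_size=params.min_object_px - 1)


def label_and_rank(mask: np.ndarray, params: PreprocessParams) -> pd.DataFrame:
    """Label connected components and rank them by a composite shape score.

    Area, major axis length and perimeter are each min–max normalized across
    components (all 1 when the metric is constant) and averaged into a
    composite score; rank 1 is the highest score, ties broken by larger area
    then smaller label id.  Returns an empty table for an empty mask.
    """
    skimage_conn = 2 if params.connectivity == 8 else 1
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=skimage_conn)
    props = measure.regionprops(labels)
    columns = ["label", "area", "major_axis_length", "perimeter", "composite_score", "rank"]
    if not props:
        return pd.DataFrame(columns=columns).astype({"label": int, "rank": int})
    df = pd.DataFrame(
        {
            "label": [p.label for p in props],
            "area": [float(p.area) for p in props],
            "major_axis_length": [float(p.axis_major_length) for p in props],
            "perimeter": [float(p.perimeter) for p in props],
        }
    )
    normed = np.empty((len(df), 3))
    for j, col in enumerate(("area", "major_axis_length", "perimeter")):
        v = df[col].to_numpy(dtype=float)
        span = v.max() - v.min()
        normed[:, j] = 1.0 if span == 0 else (v - v.min()) / span
    df["composite_score"] = normed.mean(axis=1)
    order = df.sort_values(
        by=["composite_score", "area", "label"], ascending=[False, False, True], kind="mergesort"
    ).index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    return df


def _resize_preserving_aspect(img: np.ndarray, output_size: tuple[int, int]) -> np.ndarray:
    """Aspect-preserving resize with zero padding to ``output_size``."""
    out_h, out_w = output_size
    h, w = img.shape
    scale = min(out_h / h, out_w / w)
    new_h, new_w = max(1, round(h * scale)), max(1, round(w * scale))
    resized = transform.resize(img.astype(np.float64), (new_h, new_w), order=1, anti_aliasing=scale < 1, preserve_range=True)
    out = np.zeros((out_h, out_w), dtype=np.float32)
    top, left = (out_h - new_h) // 2, (out_w - new_w) // 2
    out[top : top + new_h, left : left + new_w] = resized
    return np.clip(out, 0.0, 1.0)


def preprocess_slice(hu_slice: HUSlice | np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Run the full per-slice pipeline; returns a [0,1] grid of ``output_size``.

    window → clip/normalize → Sobel → max-fusion → threshold/clean →
    component ranking → keep top-k regions → masked fused edges → resize.
    """
    params = params or PreprocessParams()
    maps = [sobel_edges(clip_and_normalize(hu_slice, w)) for w in params.windows]
    fused = fuse_max(maps)
    mask = threshold_and_clean(fused, params)
    table = label_and_rank(mask, params)
    if len(table) > params.keep_top_k:
        keep = set(table.loc[table["rank"] <= params.keep_top_k, "label"])
        skimage_conn = 2 if params.connectivity == 8 else 1
        labels = measure.label(mask, connectivity=skimage_conn)
        mask = np.isin(labels, sorted(keep))
    out = fused * mask.astype(np.float32)
    return _resize_preserving_aspect(out, tuple(params.output_size))


class EdgeFusionPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying :func:`preprocess_slice` per slice.

    ``transform`` accepts an iterable of :class:`HUSlice` or raw 2-D HU
    arrays and returns a list of processed [0,1] grids.  Stateless: ``fit``
    only validates parameters.
    """

    def __init__(
        self,
        windows: tuple = DEFAULT_WINDOWS,
        edge_threshold: float = 0.25,
        min_object_px: int = 20,
        connectivity: int = 8,
        border_margin_px: int = 8,
        keep_top_k: int = 2,
        output_size: tuple[int, int] = (224, 224),
    ):
        self.windows = windows
        self.edge_threshold = edge_threshold
        self.min_object_px = min_object_px
        self.connectivity = connectivity
        self.border_margin_px = border_margin_px
        self.keep_top_k = keep_top_k
        self.output_size = output_size

    def _params(self) -> PreprocessParams:
        return PreprocessParams(
            windows=tuple(self.windows),
            edge_threshold=self.edge_threshold,
            min_object_px=self.min_object_px,
            connectivity=self.connectivity,
            border_margin_px=self.border_margin_px,
            keep_top_k=self.keep_top_k,
            output_size=tuple(self.output_size),
        )

    def fit(self, X=None, y=None):
        self.params_ = self._params()
        return self

    def transform(self, X) -> list[np.ndarray]:
        params = getattr(self, "params_", None) or self._params()
        return [preprocess_slice(x, params) for x in X]
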