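"""Synthetic CMR-like slice and cohort generation with known ground truth.

Clinical CMR data cannot be shared, so every downstream stage is exercised on
a synthetic cohort that emulates the relevant image statistics: soft-tissue
background around −30 HU, a curved contrast-filled vessel band in 300–500 HU,
localized calcified (≥600 HU) or soft (−30..60 HU) plaques on positive
patients, burned-in text near the border, additive HU noise, and a variable
slice count per patient.  Slice-level truth (which slices carry plaque, and
where) is recorded so attention localization can be scored exactly.

The multi-instance assumption is built in: a positive patient has a fixed
small number of plaque-bearing slices and a negative patient has none, so the
patient label is the OR over slice truths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import HU_MAX, HU_MIN, HUSlice
from .cohort import grade_from_percent

PLAQUE_KINDS = ("calcified", "soft", "none")


@dataclass
class SyntheticConfig:
    """Cohort generation parameters; equal configs give byte-identical cohorts."""

    image_height: int = 192
    image_width: int = 192
    n_patients: int = 120
    prevalence: float = 0.4
    slices_per_patient_range: tuple[int, int] = (6, 144)
    plaque_kind_mix: float = 0.5  # probability a plaque slice is calcified (else soft)
    plaque_slices_per_positive: int = 3
    text_annotation_prob: float = 0.2
    noise_sigma_hu: float = 15.0
    artery: str = "LAD"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.slices_per_patient_range
        if not (1 <= lo <= hi <= 10_000):
            raise ValueError("slices_per_patient_range must lie within [1, 10000]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image dimensions must be at least 32×32")
        if self.plaque_slices_per_positive < 1:
            raise ValueError("plaque_slices_per_positive must be ≥ 1")
        if lo < self.plaque_slices_per_positive:
            raise ValueError("slice range minimum must cover plaque_slices_per_positive")


@dataclass
class SliceTruth:
    """Ground truth for one synthetic slice."""

    patient_id: str
    slice_index: int
    has_plaque: bool
    plaque_kind: str = "none"
    plaque_center: tuple[int, int] | None = None  # (row, col)
    plaque_radius: float | None = None

    def __post_init__(self) -> None:
        if self.plaque_kind not in PLAQUE_KINDS:
            raise ValueError(f"plaque_kind must be one of {PLAQUE_KINDS}")
        if self.has_plaque != (self.plaque_kind != "none"):
            raise ValueError("has_plaque must agree with plaque_kind")

    @property
    def slice_id(self) -> str:
        return f"{self.patient_id}:{self.slice_index:04d}"


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _ellipse_mask(shape, center, radii, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def generate_slice(config: SyntheticConfig, truth: SliceTruth, rng_state) -> HUSlice:
    """Render one slice from its truth record.

    Background soft tissue in ≈[−120, 60] HU, a quadratic-Bézier vessel band
    of width 6–12 px at ≈400 HU, an optional plaque (calcified: ≥600 HU blob
    adjacent to the band; soft: −30..60 HU blob indenting the band), an
    optional high-HU text glyph near the border, plus Gaussian HU noise.
    """
    h, w = config.image_height, config.image_width
    if h < 32 or w < 32:
        raise ValueError("image dimensions must be at least 32×32")
    rng = np.random.default_rng(rng_state) if not isinstance(rng_state, np.random.Generator) else rng_state

    # smooth background texture around -30 HU
    coarse = rng.normal(0.0, 25.0, size=(8, 8))
    background = -30.0 + ndimage.zoom(coarse, (h / 8, w / 8), order=3)
    img = np.clip(background, -120.0, 60.0)

    # curved vessel: quadratic Bézier across the image, band half-width 3-6 px
    margin = 12
    p0 = np.array([rng.uniform(margin, h - margin), float(margin)])
    p2 = np.array([rng.uniform(margin, h - margin), float(w - margin)])
    p1 = np.array([rng.uniform(margin, h - margin), rng.uniform(0.3 * w, 0.7 * w)])
    pts = _bezier_points(p0, p1, p2, 4 * w)
    curve_raster = np.zeros((h, w), dtype=bool)
    ij = np.round(pts).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, h - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, w - 1)
    curve_raster[ij[:, 0], ij[:, 1]] = True
    dist = ndimage.distance_transform_edt(~curve_raster)
    halfwidth = rng.uniform(3.0, 6.0)
    band = dist <= halfwidth
    img[band] = rng.uniform(380.0, 460.0)

    if truth.has_plaque:
        # anchor the lesion to a mid-curve point
        t_idx = int(rng.uniform(0.30, 0.70) * len(pts))
        anchor = pts[t_idx]
        tangent = pts[min(t_idx + 8, len(pts) - 1)] - pts[max(t_idx - 8, 0)]
        normal = np.array([-tangent[1], tangent[0]])
        nrm = np.linalg.norm(normal)
        normal = normal / nrm if nrm > 0 else np.array([0.0, 1.0])
        radii = (rng.uniform(3.4, 4.2), rng.uniform(4.2, 5.2))
        angle = rng.uniform(0, np.pi)
        if truth.plaque_kind == "calcified":
            center = anchor + normal * (halfwidth + 0.6 * radii[0]) * rng.choice([-1.0, 1.0])
            value = rng.uniform(750.0, 900.0)
        else:  # soft plaque indents the vessel band (local lumen narrowing)
            center = anchor
            value = rng.uniform(0.0, 30.0)
        center = np.clip(center, margin, [h - margin, w - margin])
        blob = _ellipse_mask((h, w), center, radii, angle)
        img[blob] = value
        truth.plaque_center = (int(round(center[0])), int(round(center[1])))
        truth.plaque_radius = float(max(radii))

    stamp_text = rng.random() < config.text_annotation_prob
    if stamp_text:
        # thin separated character-like strokes (burned-in annotation text)
        r0 = 2 if rng.random() < 0.5 else h - 8
        c0 = int(rng.uniform(4, w - 18))
        for k in range(int(rng.integers(4, 7))):
            height = int(rng.integers(3, 7))
            img[r0 : r0 + height, c0 + 2 * k] = 1000.0

    img = img + rng.normal(0.0, config.noise_sigma_hu, size=(h, w))
    img = np.clip(img, HU_MIN, HU_MAX)
    return HUSlice(patient_id=truth.patient_id, slice_index=truth.slice_index, pixels=img)


def generate_patient(
    config: SyntheticConfig,
    patient_id: str,
    is_positive: bool,
    rng_state,
    materialize: bool = True,
) -> tuple[list[HUSlice], list[SliceTruth]]:
    """Generate one patient's slice stack and truth records.

    The slice count is uniform over ``slices_per_patient_range``; a positive
    patient has exactly ``plaque_slices_per_positive`` plaque-bearing slices,
    a negative patient has none.  With ``materialize=False`` only the truths
    are produced (pixel rendering skipped) without disturbing determinism.
    """
    rng = np.random.default_rng(rng_state) if not isinstance(rng_state, np.random.Generator) else rng_state
    lo, hi = config.slices_per_patient_range
    n_slices = int(rng.integers(lo, hi + 1))
    plaque_idx: set[int] = set()
    if is_positive:
        plaque_idx = set(rng.choice(n_slices, size=config.plaque_slices_per_positive, replace=False).tolist())
    truths: list[SliceTruth] = []
    slices: list[HUSlice] = []
    for i in range(n_slices):
        if i in plaque_idx:
            kind = "calcified" if rng.random() < config.plaque_kind_mix else "soft"
            truth = SliceTruth(patient_id=patient_id, slice_index=i, has_plaque=True, plaque_kind=kind)
        else:
            truth = SliceTruth(patient_id=patient_id, slice_index=i, has_plaque=False)
        slice_seed = int(rng.integers(0, 2**31 - 1))
        if materialize:
            slices.append(generate_slice(config, truth, slice_seed))
        truths.append(truth)
    return slices, truths


@dataclass
class CohortManifest:
    """A generated cohort: per-patient labels, truths and (optionally) pixels."""

    config: SyntheticConfig
    labels: dict[str, int]
    stenosis_percent: dict[str, float]
    truths: dict[str, list[SliceTruth]] = field(default_factory=dict)
    slices: dict[str, list[HUSlice]] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.labels)

    def slice_counts(self) -> dict[str, int]:
        return {pid: len(t) for pid, t in self.truths.items()}

    def plaque_slice_indices(self, patient_id: str) -> list[int]:
        return [t.slice_index for t in self.truths[patient_id] if t.has_plaque]

    def patients_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": pid,
                "artery": self.config.artery,
                "stenosis_percent": self.stenosis_percent[pid],
                "label": self.labels[pid],
            }
            for pid in self.patient_ids
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, write_pixels: bool = False) -> None:
        """Write the manifest CSV + slice-index JSONL (and optionally PNGs)."""
        from .core import write_png16

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.patients_frame().to_csv(out_dir / "manifest.csv", index=False)
        with open(out_dir / "slices.jsonl", "w") as fh:
            for pid, truths in self.truths.items():
                for t in truths:
                    fh.write(
                        json.dumps(
                            {
                                "slice_id": t.slice_id,
                                "patient_id": pid,
                                "slice_index": t.slice_index,
                                "has_plaque": t.has_plaque,
                                "plaque_kind": t.plaque_kind,
                            }
                        )
                        + "\n"
                    )
        if write_pixels:
            img_dir = out_dir / "slices"
            img_dir.mkdir(exist_ok=True)
            for pid, slices in self.slices.items():
                for s in slices:
                    write_png16(s, img_dir / f"{pid}_{s.slice_index:04d}.png")


def generate_cohort(config: SyntheticConfig, materialize: bool = True) -> CohortManifest:
    """Generate a full cohort; the positive fraction follows ``prevalence``.

    A configuration whose expected positive count is below one patient
    (0 < prevalence·n_patients < 1) is rejected rather than silently padded.
    """
    if config.n_patients < 2:
        raise ValueError("n_patients must be ≥ 2")
    expected_pos = config.prevalence * config.n_patients
    if 0.0 < expected_pos < 1.0:
        raise ValueError(
            f"prevalence {config.prevalence} with n_patients {config.n_patients} "
            "expects fewer than one positive patient; adjust the configuration"
        )
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(config.n_patients + 1)
    label_rng = np.random.default_rng(children[0])
    n_digits = max(4, len(str(config.n_patients)))
    labels: dict[str, int] = {}
    percents: dict[str, float] = {}
    manifest = CohortManifest(config=config, labels=labels, stenosis_percent=percents)
    for i, child in enumerate(children[1:]):
        pid = f"P{i:0{n_digits}d}"
        y = int(label_rng.random() < config.prevalence)
        prng = np.random.default_rng(child)
        # stenosis percent consistent with the binary label via the grade cut-offs
        percent = float(prng.uniform(50.0, 100.0)) if y else float(prng.uniform(0.0, 49.0))
        assert (grade_from_percent(percent) >= 3) == bool(y)
        slices, truths = generate_patient(config, pid, bool(y), prng, materialize=materialize)
        labels[pid] = y
        percents[pid] = round(percent, 1)
        manifest.truths[pid] = truths
        manifest.slices[pid] = slices
    return manifest
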