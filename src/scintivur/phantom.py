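"""Synthetic posterior DMSA-like renal scintigrams with known VUR grades.

The generator emulates the phenotype a DMSA-based VUR classifier must read:
two elliptical cortical-uptake regions on a low-uptake abdominal background,
count noise, and focal photopenic defects whose number, extent and depth
grow with the planted per-side VUR grade (0 = no reflux, 5 = severe).
It is an image-formation stand-in, not a SPECT simulation: no attenuation,
scatter, collimator blur or organ anatomy beyond the two kidneys.

Every scan is a single-channel 8-bit image plus per-side ground-truth
grades, so the whole downstream pipeline (preprocessing, side selection,
QC, training, evaluation) is testable without clinical data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomConfig",
    "ScintiScan",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "kidney_mask",
    "strong_effect_config",
    "STRONG_GRADE_P",
]

# grade -> (number of photopenic foci, fractional uptake reduction, focus
# radius as a fraction of the kidney's minor semi-axis). Depth and extent are
# non-decreasing in grade so expected cortical uptake falls monotonically.
_DEFAULT_DEFECT_COUNT = {0: 0, 1: 1, 2: 1, 3: 2, 4: 3, 5: 4}
_DEFAULT_DEFECT_DEPTH = {0: 0.0, 1: 0.35, 2: 0.50, 3: 0.65, 4: 0.80, 5: 0.92}
_DEFAULT_DEFECT_RADIUS = {0: 0.0, 1: 0.22, 2: 0.28, 3: 0.34, 4: 0.40, 5: 0.46}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, uptake levels and noise model of the synthetic scans.

    Intensities are on the 8-bit display scale [0, 255]. The default canvas
    is 256x512 so the bounding-rectangle crop downstream is non-trivial.
    """

    image_height: int = 256
    image_width: int = 512
    # (row, col) semi-axes per kidney, pixels
    kidney_axes: tuple[tuple[int, int], tuple[int, int]] = ((72, 44), (72, 44))
    # (row, col) centres: left kidney on the image left, right on the right
    kidney_centers: tuple[tuple[int, int], tuple[int, int]] = ((128, 150), (128, 362))
    cortical_uptake: float = 185.0
    background_uptake: float = 28.0
    defect_count_by_grade: Mapping[int, int] = field(
        default_factory=lambda: dict(_DEFAULT_DEFECT_COUNT)
    )
    defect_depth_by_grade: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEFECT_DEPTH)
    )
    defect_radius_by_grade: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEFECT_RADIUS)
    )
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    poisson_counts_per_level: float = 2.0  # counts per intensity unit
    gaussian_sigma: float = 6.0
    edge_softness: float = 0.18  # fractional width of the cortical rim falloff
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 128 or self.image_width < 128:
            raise ValueError("image dimensions must be at least 128x128")
        if not self.cortical_uptake > self.background_uptake:
            raise ValueError("cortical_uptake must exceed background_uptake")
        depths = [self.defect_depth_by_grade[g] for g in sorted(self.defect_depth_by_grade)]
        if any(b < a for a, b in zip(depths, depths[1:])):
            raise ValueError("defect depth must be non-decreasing in grade")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass(frozen=True)
class ScintiScan:
    """One patient's posterior scan plus VCUG-derived ground truth."""

    patient_id: str
    image: np.ndarray  # uint8, (H, W)
    vur_grade_left: int
    vur_grade_right: int
    file_size_bytes: int = 0

    @property
    def label(self) -> int:
        """Patient-level label: positive iff either side has grade >= 1."""
        return int(self.vur_grade_left >= 1 or self.vur_grade_right >= 1)

    def __post_init__(self) -> None:
        if self.image.dtype != np.uint8 or self.image.ndim != 2:
            raise ValueError("scan image must be a 2-D uint8 array")


def _elliptical_radius(h: int, w: int, center: tuple[int, int], axes: tuple[int, int]) -> np.ndarray:
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return np.sqrt(
        ((rows - center[0]) / axes[0]) ** 2 + ((cols - center[1]) / axes[1]) ** 2
    )


def _kidney_field(config: PhantomConfig, side_idx: int) -> np.ndarray:
    """Noise-free uptake of one healthy kidney: smooth rim falloff in [0, 1]."""
    r = _elliptical_radius(
        config.image_height,
        config.image_width,
        config.kidney_centers[side_idx],
        config.kidney_axes[side_idx],
    )
    soft = max(config.edge_softness, 1e-6)
    # 1 inside the cortex, cosine taper over the rim, 0 outside
    profile = np.clip((1.0 - r) / soft, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * profile)


def _plant_defects(
    field_map: np.ndarray,
    config: PhantomConfig,
    side_idx: int,
    grade: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiply focal Gaussian-profile photopenic holes into one kidney."""
    count = config.defect_count_by_grade[grade]
    if count == 0:
        return field_map
    depth = config.defect_depth_by_grade[grade]
    center = config.kidney_centers[side_idx]
    axes = config.kidney_axes[side_idx]
    radius = config.defect_radius_by_grade[grade] * min(axes)
    out = field_map.copy()
    h, w = out.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(count):
        # place foci on a mid-cortical ring so they stay inside the outline
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rho = rng.uniform(0.35, 0.7)
        cr = center[0] + rho * axes[0] * np.sin(theta)
        cc = center[1] + rho * axes[1] * np.cos(theta)
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        hole = 1.0 - depth * np.exp(-d2 / (2.0 * (radius / 1.5) ** 2))
        out *= hole
    return out


def generate_patient(
    config: PhantomConfig,
    grade_left: int,
    grade_right: int,
    patient_seed: int,
    patient_id: str | None = None,
) -> ScintiScan:
    """Render one bilateral scan with planted per-side VUR grades.

    Deterministic for a fixed ``(config, grades, patient_seed)``; the side
    with the higher grade has the lower expected cortical uptake because
    defect count, depth and extent are non-decreasing in grade.
    """
    for name, g in (("grade_left", grade_left), ("grade_right", grade_right)):
        if not (0 <= int(g) <= 5):
            raise ValueError(f"{name} must be an integer in 0..5, got {g}")
    rng = np.random.default_rng([config.seed, int(patient_seed)])
    image = np.full(
        (config.image_height, config.image_width), config.background_uptake, dtype=float
    )
    span = config.cortical_uptake - config.background_uptake
    for side_idx, grade in ((0, int(grade_left)), (1, int(grade_right))):
        healthy = _kidney_field(config, side_idx)
        image += span * _plant_defects(healthy, config, side_idx, grade, rng)
    if config.noise_model == "poisson":
        s = config.poisson_counts_per_level
        image = rng.poisson(np.clip(image, 0.0, None) * s) / s
    elif config.noise_model == "gaussian":
        image = image + rng.normal(0.0, config.gaussian_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    pid = patient_id if patient_id is not None else f"P{patient_seed:05d}"
    return ScintiScan(
        patient_id=pid,
        image=image,
        vur_grade_left=int(grade_left),
        vur_grade_right=int(grade_right),
        file_size_bytes=_png_size(image),
    )


def _png_size(image: np.ndarray) -> int:
    buf = io.BytesIO()
    Image.fromarray(image, mode="L").save(buf, format="PNG")
    return buf.getbuffer().nbytes


def kidney_mask(config: PhantomConfig, side: str, threshold: float = 0.5) -> np.ndarray:
    """Ground-truth boolean mask of one kidney (half-maximum outline)."""
    idx = {"left": 0, "right": 1}[side]
    r = _elliptical_radius(
        config.image_height, config.image_width, config.kidney_centers[idx], config.kidney_axes[idx]
    )
    soft = max(config.edge_softness, 1e-6)
    profile = np.clip((1.0 - r) / soft, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * profile)) >= threshold


# per-side grade distribution of positives: mass over grades 1..5 for the
# more affected ("primary") side; the other side is 0 more often than not,
# mirroring the predominance of unilateral reflux.
_PRIMARY_GRADE_P = np.array([0.14, 0.20, 0.26, 0.24, 0.16])
_P_BILATERAL = 0.35


def strong_effect_config(**overrides) -> PhantomConfig:
    """Phantom parameterisation with a strong planted defect effect.

    Deeper and larger photopenic foci than the default table, for
    scaled-down learning experiments where a small network must be able to
    separate the classes from few training scans.
    """
    params = dict(
        defect_count_by_grade={0: 0, 1: 2, 2: 2, 3: 3, 4: 4, 5: 5},
        defect_depth_by_grade={0: 0.0, 1: 0.60, 2: 0.75, 3: 0.85, 4: 0.92, 5: 0.97},
        defect_radius_by_grade={0: 0.0, 1: 0.32, 2: 0.38, 3: 0.44, 4: 0.50, 5: 0.56},
    )
    params.update(overrides)
    return PhantomConfig(**params)


#: primary-grade distribution concentrating positives at grade >= 3,
#: paired with `strong_effect_config` in scaled-down experiments.
STRONG_GRADE_P = np.array([0.0, 0.0, 0.30, 0.35, 0.35])


def _draw_positive_grades(
    rng: np.random.Generator, grade_p: np.ndarray | None = None
) -> tuple[int, int]:
    p = _PRIMARY_GRADE_P if grade_p is None else np.asarray(grade_p, dtype=float)
    primary = int(rng.choice(np.arange(1, 6), p=p / p.sum()))
    if rng.random() < _P_BILATERAL:
        other = int(rng.integers(1, primary + 1))
    else:
        other = 0
    if rng.random() < 0.5:
        return primary, other
    return other, primary


def generate_cohort(
    config: PhantomConfig,
    n_patients: int,
    prevalence: float,
    seed: int,
    grade_distribution: np.ndarray | None = None,
) -> tuple[list[ScintiScan], pd.DataFrame]:
    """Generate a cohort with a fixed VUR-positive fraction.

    Exactly ``round(n_patients * prevalence)`` patients are positive; grade
    pairs of positives are drawn per the module-level distribution, negatives
    are 0/0. Returns the scans and a manifest with one row per patient.
    """
    if n_patients < 10:
        raise ValueError("n_patients must be >= 10 for meaningful splitting")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    n_pos = int(round(n_patients * prevalence))
    rng = np.random.default_rng([seed, 0xC040, n_patients])
    positive = np.zeros(n_patients, dtype=bool)
    positive[rng.choice(n_patients, size=n_pos, replace=False)] = True
    scans: list[ScintiScan] = []
    rows = []
    for i in range(n_patients):
        if positive[i]:
            gl, gr = _draw_positive_grades(rng, grade_distribution)
        else:
            gl, gr = 0, 0
        scan = generate_patient(
            config, gl, gr, patient_seed=int(rng.integers(0, 2**31 - 1)), patient_id=f"P{i:05d}"
        )
        scans.append(scan)
        rows.append(
            {
                "patient_id": scan.patient_id,
                "image_path": f"{scan.patient_id}.png",
                "vur_grade_left": gl,
                "vur_grade_right": gr,
                "label": scan.label,
            }
        )
    return scans, pd.DataFrame(rows)


def write_cohort(
    scans: Sequence[ScintiScan], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write per-scan 8-bit grayscale PNGs plus the manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for scan, rel in zip(scans, manifest["image_path"]):
        Image.fromarray(scan.image, mode="L").save(out / rel)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
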