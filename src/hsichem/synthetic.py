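"""Synthetic NIR scene generator with ground truth.

The generator emulates line-scan near-infrared images of dried fruit kernels
on a dark tray: two object classes ("A" and "B", two varieties) whose clean
reflectance signatures carry Gaussian absorbance dips at the C–H overtone
bands near 1123, 1210 and 1308 nm and the water band near 1473 nm; three
size grades per class (Grade1 large, Grade2 medium, Grade3 small); and a
sensor model

    raw = dark + (white - dark) * (R * gain + offset + noise)

with one multiplicative gain and one additive offset per pixel shared across
bands (classic scatter, exactly the structure SNV removes) plus independent
per-pixel-per-band noise.  White/dark frames carry a small spatial ripple so
the reflectance correction is a non-trivial normalisation.

All randomness flows from explicit integer seeds; two calls with the same
configuration are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cubes import HyperspectralCube, ReferenceFrames, read_cube, write_cube

__all__ = [
    "SignatureSpec",
    "SceneConfig",
    "GroundTruth",
    "Scene",
    "GRADES",
    "GRADE_RADII",
    "wavelength_axis",
    "make_signature",
    "default_signatures",
    "mean_absolute_contrast",
    "generate_scene",
    "generate_study",
    "save_study",
    "load_study",
    "SceneGenerationError",
]

GRADES = ("Grade1", "Grade2", "Grade3")

#: semi-major axis range (pixels) per grade: large / medium / small kernels
GRADE_RADII = {"Grade1": (8.0, 10.0), "Grade2": (6.0, 7.5), "Grade3": (4.0, 5.5)}


class SceneGenerationError(RuntimeError):
    pass


@dataclass
class SignatureSpec:
    """Clean reflectance signature of one object class.

    ``peaks`` are Gaussian absorbance dips ``(center nm, depth, width nm)``
    subtracted from ``baseline``; ``class_offset`` is an optional per-band
    deterministic contrast vector added on top.  ``grade_drift_*`` optionally
    shifts the signature per grade by ``(grade_index - 2) * scale`` times a
    Gaussian bump, emulating composition that changes with kernel size
    (grade_index 1..3, so Grade2 is drift-free).
    """

    class_id: str
    baseline: float = 0.55
    peaks: Sequence[tuple[float, float, float]] = ()
    class_offset: np.ndarray | None = None
    grade_drift_scale: float = 0.0
    grade_drift_center: float = 1570.0
    grade_drift_width: float = 30.0


@dataclass
class SceneConfig:
    """Geometry, optics and noise of one synthetic scene."""

    bands: int = 200
    wavelength_range: tuple[float, float] = (975.0, 1646.0)
    image_shape: tuple[int, int] = (64, 64)
    n_objects: int = 4
    grade: str = "Grade1"
    background_level: float = 0.05
    scatter_gain_sd: float = 0.12
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bands < 8:
            raise ValueError("at least 8 bands are required")
        if self.grade not in GRADE_RADII:
            raise ValueError(f"unknown grade {self.grade!r}")


@dataclass
class GroundTruth:
    """Per-pixel object/class labels plus a per-object summary table."""

    label_map: np.ndarray  # 0 = background, k = object id
    class_map: np.ndarray  # 0 = background, code per class
    class_codes: dict[int, str]
    object_table: pd.DataFrame  # object_id, class, grade, centroid_*, n_pixels

    def __post_init__(self) -> None:
        if not np.array_equal(self.label_map > 0, self.class_map > 0):
            raise ValueError("label_map and class_map must agree on support")
        if int(self.object_table["n_pixels"].sum()) != int((self.label_map > 0).sum()):
            raise ValueError("object pixel counts must sum to the mask size")


@dataclass
class Scene:
    """One generated scene: raw cube, reference frames and ground truth."""

    scene_id: str
    class_id: str
    grade: str
    raw: HyperspectralCube
    refs: ReferenceFrames
    truth: GroundTruth


def wavelength_axis(config: SceneConfig) -> np.ndarray:
    lo, hi = config.wavelength_range
    return np.linspace(lo, hi, config.bands)


def _gaussian(axis: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / width) ** 2)


def make_signature(
    spec: SignatureSpec, axis: np.ndarray, grade: str | None = None
) -> np.ndarray:
    """Clean reflectance spectrum of a class on the given wavelength axis."""
    axis = np.asarray(axis, dtype=float)
    out = np.full(axis.shape, float(spec.baseline))
    for center, depth, width in spec.peaks:
        if not (axis[0] <= center <= axis[-1]):
            raise ValueError(
                f"absorbance peak at {center} nm outside axis "
                f"[{axis[0]}, {axis[-1]}] nm"
            )
        out -= depth * _gaussian(axis, center, width)
    if spec.class_offset is not None:
        offset = np.asarray(spec.class_offset, dtype=float)
        if offset.shape != axis.shape:
            raise ValueError("class_offset length must match the wavelength axis")
        out = out + offset
    if grade is not None and spec.grade_drift_scale:
        gidx = GRADES.index(grade) + 1
        out = out + (gidx - 2) * spec.grade_drift_scale * _gaussian(
            axis, spec.grade_drift_center, spec.grade_drift_width
        )
    if out.min() <= 0.0 or out.max() >= 1.0:
        raise ValueError("clean signature must lie strictly inside (0, 1)")
    return out


def default_signatures() -> dict[str, SignatureSpec]:
    """Two-variety defaults: shared band positions, distinct depths/baselines.

    Class A's water dip (1473 nm) is its deepest feature; class B differs in
    baseline and in the relative depths of the C–H bands, giving a shape
    contrast that survives SNV normalisation.
    """
    return {
        "A": SignatureSpec(
            class_id="A",
            baseline=0.55,
            peaks=[
                (1123.0, 0.060, 22.0),
                (1210.0, 0.050, 24.0),
                (1308.0, 0.045, 26.0),
                (1473.0, 0.120, 38.0),
            ],
        ),
        "B": SignatureSpec(
            class_id="B",
            baseline=0.50,
            peaks=[
                (1123.0, 0.042, 22.0),
                (1210.0, 0.068, 24.0),
                (1308.0, 0.060, 26.0),
                (1473.0, 0.100, 38.0),
            ],
        ),
    }


def mean_absolute_contrast(
    a: SignatureSpec, b: SignatureSpec, axis: np.ndarray
) -> float:
    return float(np.mean(np.abs(make_signature(a, axis) - make_signature(b, axis))))


# ---------------------------------------------------------------------------
# Scene synthesis


def _place_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_objects: int,
    radius_range: tuple[float, float],
    max_tries: int = 2000,
) -> list[tuple[float, float, float, float, float]]:
    """Non-overlapping random ellipses away from the border.

    Returns (row, col, semi-major, semi-minor, angle) tuples.  Overlap is
    rejected conservatively on semi-major axes, so accepted layouts never
    touch.  Raises :class:`SceneGenerationError` when the geometry cannot be
    satisfied within the retry budget.
    """
    rows, cols = shape
    restarts = 25
    for _ in range(restarts):
        placed: list[tuple[float, float, float, float, float]] = []
        tries = 0
        while len(placed) < n_objects and tries < max_tries:
            tries += 1
            a = rng.uniform(*radius_range)
            b = a * rng.uniform(0.6, 1.0)
            theta = rng.uniform(0.0, math.pi)
            margin = a + 1.5
            if 2 * margin >= min(rows, cols):
                raise SceneGenerationError(
                    f"object radius {a:.1f} px does not fit a {rows}x{cols} image"
                )
            r0 = rng.uniform(margin, rows - 1 - margin)
            c0 = rng.uniform(margin, cols - 1 - margin)
            ok = all(
                math.hypot(r0 - pr, c0 - pc) > a + pa + 1.0
                for pr, pc, pa, _, _ in placed
            )
            if ok:
                placed.append((r0, c0, a, b, theta))
        if len(placed) == n_objects:
            return placed
    raise SceneGenerationError(
        f"could not place {n_objects} objects (radius range {radius_range}) in a "
        f"{rows}x{cols} image without overlap or border contact after "
        f"{restarts} layout attempts"
    )


def _rasterize(
    shape: tuple[int, int],
    ellipses: Sequence[tuple[float, float, float, float, float]],
) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    label_map = np.zeros(shape, dtype=int)
    for k, (r0, c0, a, b, theta) in enumerate(ellipses, start=1):
        dr, dc = rr - r0, cc - c0
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        label_map[inside] = k
    return label_map


def _reference_frames(shape: tuple[int, int]) -> ReferenceFrames:
    # white ~0.9 and dark ~0.02 with a small deterministic spatial ripple
    rows, cols = shape
    r = np.arange(rows)[:, None] / max(rows - 1, 1)
    c = np.arange(cols)[None, :] / max(cols - 1, 1)
    white = 0.90 + 0.010 * np.sin(2 * np.pi * c) + 0.005 * np.cos(2 * np.pi * r)
    dark = np.broadcast_to(
        0.02 + 0.002 * np.sin(2 * np.pi * (c + 0.25)), white.shape
    ).copy()
    return ReferenceFrames(white=white, dark=dark)


def generate_scene(
    config: SceneConfig,
    signatures: Mapping[str, SignatureSpec],
    class_assignment: Sequence[str] | None = None,
) -> Scene:
    """Generate one raw scene with references and ground truth.

    By default every object carries the first class in ``signatures``; pass
    ``class_assignment`` (one class id per object) for mixed scenes.
    """
    rng = np.random.default_rng(config.seed)
    axis = wavelength_axis(config)
    class_ids = list(signatures)
    if class_assignment is None:
        class_assignment = [class_ids[0]] * config.n_objects
    if len(class_assignment) != config.n_objects:
        raise ValueError("class_assignment length must equal n_objects")

    ellipses = _place_ellipses(
        rng, config.image_shape, config.n_objects, GRADE_RADII[config.grade]
    )
    label_map = _rasterize(config.image_shape, ellipses)

    spectra = {
        cid: make_signature(spec, axis, grade=config.grade)
        for cid, spec in signatures.items()
    }
    codes = {i + 1: cid for i, cid in enumerate(class_ids)}
    code_of = {cid: i + 1 for i, cid in enumerate(class_ids)}

    rows, cols = config.image_shape
    reflectance = np.full((rows, cols, config.bands), config.background_level)
    class_map = np.zeros((rows, cols), dtype=int)
    records = []
    for k, (r0, c0, *_rest) in enumerate(ellipses, start=1):
        cid = class_assignment[k - 1]
        sel = label_map == k
        reflectance[sel] = spectra[cid]
        class_map[sel] = code_of[cid]
        records.append(
            {
                "object_id": k,
                "class": cid,
                "grade": config.grade,
                "centroid_row": float(np.nonzero(sel)[0].mean()),
                "centroid_col": float(np.nonzero(sel)[1].mean()),
                "n_pixels": int(sel.sum()),
            }
        )

    # scale=0 draws are exactly zero, so the zero-noise limit needs no branch
    gain = 1.0 + rng.normal(0.0, config.scatter_gain_sd, (rows, cols, 1))
    offset = rng.normal(0.0, config.scatter_offset_sd, (rows, cols, 1))
    noise = rng.normal(0.0, config.noise_sd, reflectance.shape)
    effective = reflectance * gain + offset + noise

    refs = _reference_frames(config.image_shape)
    white = refs.white[:, :, None]
    dark = refs.dark[:, :, None]
    raw = np.clip(dark + (white - dark) * effective, 0.0, 1.0)

    truth = GroundTruth(
        label_map=label_map,
        class_map=class_map,
        class_codes=codes,
        object_table=pd.DataFrame.from_records(records),
    )
    scene_class = class_assignment[0] if len(set(class_assignment)) == 1 else "mixed"
    scene = Scene(
        scene_id=f"{scene_class}-{config.grade}-s{config.seed}",
        class_id=scene_class,
        grade=config.grade,
        raw=HyperspectralCube(raw, axis, stage="raw"),
        refs=refs,
        truth=truth,
    )
    return scene


def generate_study(
    signatures: Mapping[str, SignatureSpec] | None = None,
    scenes_per_group: int = 30,
    grades: Sequence[str] = GRADES,
    base_config: SceneConfig | None = None,
    master_seed: int = 0,
) -> list[Scene]:
    """Full class x grade x replicate collection of single-class scenes.

    Defaults follow the study layout: 30 scenes per class-grade group
    (2 classes x 3 grades x 30 = 180 scenes).  Per-scene seeds are spawned
    deterministically from the master seed.
    """
    if signatures is None:
        signatures = default_signatures()
    if base_config is None:
        base_config = SceneConfig()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(signatures) * len(grades) * scenes_per_group)
    scenes: list[Scene] = []
    i = 0
    for cid, spec in signatures.items():
        for grade in grades:
            for rep in range(scenes_per_group):
                seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                cfg = replace(base_config, grade=grade, seed=seed)
                scene = generate_scene(cfg, {cid: spec})
                scene.scene_id = f"{cid}-{grade}-{rep:03d}"
                scenes.append(scene)
    return scenes


# ---------------------------------------------------------------------------
# On-disk study layout (ENVI cubes + reference/truth arrays + metadata)


def save_study(scenes: Sequence[Scene], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for scene in scenes:
        stem = out_dir / scene.scene_id
        write_cube(scene.raw, stem.with_suffix(".img"), dialect="envi")
        np.savez(
            stem.with_suffix(".aux.npz"),
            white=scene.refs.white,
            dark=scene.refs.dark,
            label_map=scene.truth.label_map,
            class_map=scene.truth.class_map,
        )
        scene.truth.object_table.to_csv(stem.with_suffix(".objects.csv"), index=False)
        index.append(
            {
                "scene_id": scene.scene_id,
                "class": scene.class_id,
                "grade": scene.grade,
                "class_codes": {int(k): v for k, v in scene.truth.class_codes.items()},
            }
        )
    (out_dir / "index.yaml").write_text(yaml.safe_dump(index, sort_keys=False))
    return out_dir


def load_study(in_dir: str | Path) -> list[Scene]:
    in_dir = Path(in_dir)
    index_path = in_dir / "index.yaml"
    if not index_path.exists():
        raise FileNotFoundError(f"missing study index {index_path}")
    index = yaml.safe_load(index_path.read_text())
    scenes = []
    for entry in index:
        stem = in_dir / entry["scene_id"]
        img = stem.with_suffix(".img")
        if not img.exists():
            raise FileNotFoundError(f"missing scene cube {img}")
        cube = read_cube(img, dialect="envi")
        with np.load(stem.with_suffix(".aux.npz")) as aux:
            refs = ReferenceFrames(white=aux["white"], dark=aux["dark"])
            label_map = aux["label_map"]
            class_map = aux["class_map"]
        truth = GroundTruth(
            label_map=label_map,
            class_map=class_map,
            class_codes={int(k): v for k, v in entry["class_codes"].items()},
            object_table=pd.read_csv(stem.with_suffix(".objects.csv")),
        )
        scenes.append(
            Scene(
                scene_id=entry["scene_id"],
                class_id=entry["class"],
                grade=entry["grade"],
                raw=cube,
                refs=refs,
                truth=truth,
            )
        )
    return scenes
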