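"""Seeded synthetic "slides": 4-class blob textures with white background.

The real study material — H&E-stained whole-slide kidney images labeled
ccRCC / ccpRCC / parenchyma / fat at the slide level — is private clinical
data. These fixtures stand in for it: each synthetic slide is a flat RGB
raster with near-white background regions and a tissue region filled with
class-colored elliptical blobs. They are explicitly synthetic textures, not
simulated histology; they exercise every pipeline contract (geometry,
background filtering, weak labels, multiscale fusion, metrics) without any
claim of morphological realism.

Class structure is designed so that different patch scales carry different
evidence, mirroring why a pathologist changes magnification: all classes
share one H&E-like palette (class identity must survive stain
normalization), blob size increases along ccRCC < ccpRCC < parenchyma <
fat, the ccpRCC class adds a fine dark speckle that only small fields of
view resolve, and fat's blobs are pale vacuole-like regions whose full
extent only large fields of view contain.

Everything is reproducible from the spec seed; per-slide streams are derived
with ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse

from .io import SlideRecord, write_image

__all__ = ["ClassSpec", "FixtureSpec", "default_spec", "hard_spec", "make_slide", "render_dataset", "make_dataset"]

DEFAULT_CLASSES = ("ccRCC", "ccpRCC", "parenchyma", "fat")


@dataclass(frozen=True)
class ClassSpec:
    """Texture definition for one class."""

    name: str
    base_color: tuple[int, int, int]  # tissue ground tone
    blob_color: tuple[int, int, int]
    blob_diameter_mean: float  # pixels
    blob_diameter_sd: float
    blob_density: float = 0.55  # expected blob area per unit tissue area
    speckle_color: tuple[int, int, int] | None = None
    speckle_fraction: float = 0.0  # fraction of tissue area covered by dots
    speckle_diameter: float = 10.0


@dataclass(frozen=True)
class FixtureSpec:
    """Dataset-level generation parameters (the study conditions)."""

    classes: tuple[ClassSpec, ...]
    n_slides_per_class: int = 3
    slide_size: tuple[int, int] = (800, 800)
    background_fraction: float = 0.30
    stain_shift: tuple[tuple[float, float], ...] = (
        (1.0, 0.0),
        (1.0, 0.0),
        (1.0, 0.0),
    )  # per-RGB-channel (multiplicative, additive); identity by default
    slides_per_subject: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        # pairwise blob-diameter separation: means differ by >= 2x either SD
        for i, a in enumerate(self.classes):
            for b in self.classes[i + 1 :]:
                gap = abs(a.blob_diameter_mean - b.blob_diameter_mean)
                if gap < 2.0 * max(a.blob_diameter_sd, b.blob_diameter_sd):
                    raise ValueError(
                        f"blob diameters of {a.name} and {b.name} are not separable"
                    )

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)


def default_spec(seed: int = 0) -> FixtureSpec:
    """The default, separable 4-class study conditions (3 slides per class).

    All four classes share one H&E-like palette and one blob-area budget —
    as real slides share the same two stains and comparable stain uptake —
    so class identity is carried by spatial structure, the part of the
    signal that survives per-slide histogram specification: blob size
    increases ccRCC < ccpRCC < parenchyma < fat; ccpRCC adds a fine dark
    speckle visible only at small fields of view; and fat's blobs are pale
    (adipocyte-vacuole-like) rather than dark, a contrast polarity that
    monotone per-channel normalization preserves. Matching the area budget
    across classes keeps every slide's color marginals (hence its
    normalization map) comparable, so structural contrast transfers across
    slides; the widest class's blobs exceed the smallest test patch, so
    different patch scales carry different evidence.
    """
    base = (202, 142, 192)  # eosin-like light purple-pink ground
    blob = (148, 94, 158)  # hematoxylin-like darker purple
    speckle = (78, 48, 90)
    classes = (
        ClassSpec(
            name="ccRCC",
            base_color=base,
            blob_color=blob,
            blob_diameter_mean=20.0,
            blob_diameter_sd=2.0,
        ),
        ClassSpec(
            name="ccpRCC",
            base_color=base,
            blob_color=blob,
            blob_diameter_mean=44.0,
            blob_diameter_sd=4.0,
            speckle_color=speckle,
            speckle_fraction=0.12,
            speckle_diameter=10.0,
        ),
        ClassSpec(
            name="parenchyma",
            base_color=base,
            blob_color=blob,
            blob_diameter_mean=100.0,
            blob_diameter_sd=10.0,
        ),
        ClassSpec(
            name="fat",
            base_color=base,
            blob_color=(240, 204, 230),  # pale vacuoles, as adipose tissue
            blob_diameter_mean=260.0,
            blob_diameter_sd=24.0,
        ),
    )
    return FixtureSpec(classes=classes, seed=seed)


def hard_spec(seed: int = 0) -> FixtureSpec:
    """Overlapping-structure conditions: noisier, weakly separable classes.

    Blob diameters barely clear the separability bound and the palettes are
    close, so per-scale classifiers disagree often — exercising the DISCARD
    and INDETERMINATE paths.
    """
    classes = (
        ClassSpec("ccRCC", (180, 126, 180), (162, 104, 164), 30.0, 5.0),
        ClassSpec("ccpRCC", (178, 124, 178), (160, 102, 162), 44.0, 7.0),
        ClassSpec("parenchyma", (196, 138, 158), (210, 152, 170), 62.0, 9.0),
        ClassSpec("fat", (198, 140, 160), (212, 154, 172), 92.0, 12.0),
    )
    return FixtureSpec(classes=classes, seed=seed)


def _tissue_mask(shape: tuple[int, int], bg_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field thresholded so background covers ~bg_fraction."""
    # low-frequency field -> few large background regions, so wide windows
    # mostly fall in contiguous tissue (as on real slides)
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=min(shape) / 3.0)
    thresh = np.quantile(smooth, bg_fraction)
    return smooth >= thresh  # True = tissue


def _class_spec(spec: FixtureSpec, class_label: str) -> ClassSpec:
    for c in spec.classes:
        if c.name == class_label:
            return c
    raise ValueError(f"unknown class {class_label!r}; expected one of {spec.class_names}")


def make_slide(spec: FixtureSpec, class_label: str, seed: int) -> np.ndarray:
    """Render one synthetic slide image for the given class, fully seeded."""
    cls = _class_spec(spec, class_label)
    rng = np.random.default_rng(seed)
    h, w = spec.slide_size
    # near-white background with mild sensor noise
    img = np.clip(rng.normal(250.0, 2.0, size=(h, w, 3)), 240, 255)
    tissue = _tissue_mask((h, w), spec.background_fraction, rng)
    base = np.asarray(cls.base_color, dtype=np.float64)
    img[tissue] = base + rng.normal(0.0, 4.0, size=(int(tissue.sum()), 3))

    # elliptical blobs of the class color, clipped to the tissue mask
    tissue_area = float(tissue.sum())
    blob_area = np.pi * (cls.blob_diameter_mean / 2.0) ** 2
    n_blobs = max(1, int(cls.blob_density * tissue_area / blob_area))
    blob_color = np.asarray(cls.blob_color, dtype=np.float64)
    for _ in range(n_blobs):
        d1 = max(4.0, rng.normal(cls.blob_diameter_mean, cls.blob_diameter_sd))
        d2 = max(4.0, rng.normal(cls.blob_diameter_mean, cls.blob_diameter_sd))
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, d1 / 2.0, d2 / 2.0, shape=(h, w), rotation=rot)
        keep = tissue[rr, cc]
        rr, cc = rr[keep], cc[keep]
        img[rr, cc] = blob_color + rng.normal(0.0, 3.0, size=(rr.size, 3))

    # fine dark speckle (high-frequency structure visible only at fine scales)
    if cls.speckle_color is not None and cls.speckle_fraction > 0:
        dot_area = np.pi * (cls.speckle_diameter / 2.0) ** 2
        n_dots = int(cls.speckle_fraction * tissue_area / dot_area)
        dot_color = np.asarray(cls.speckle_color, dtype=np.float64)
        r = cls.speckle_diameter / 2.0
        for _ in range(n_dots):
            r0, c0 = rng.integers(0, h), rng.integers(0, w)
            rr, cc = ellipse(r0, c0, r, r, shape=(h, w))
            keep = tissue[rr, cc]
            rr, cc = rr[keep], cc[keep]
            img[rr, cc] = dot_color + rng.normal(0.0, 3.0, size=(rr.size, 3))

    # optional global stain shift (multiplicative then additive per channel)
    for ch, (mul, add) in enumerate(spec.stain_shift):
        img[..., ch] = img[..., ch] * mul + add
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_dataset(spec: FixtureSpec) -> tuple[list[SlideRecord], dict[str, np.ndarray]]:
    """Render all slides in memory: (records, images keyed by slide id).

    Subjects get ``slides_per_subject`` consecutive same-class slides each
    (default 1, i.e. one subject per slide). Per-slide seeds are spawned
    from the spec seed, so the dataset is a pure function of the spec.
    """
    root = np.random.SeedSequence(spec.seed)
    slide_seeds = root.spawn(len(spec.classes) * spec.n_slides_per_class)
    records: list[SlideRecord] = []
    images: dict[str, np.ndarray] = {}
    i = 0
    for cls in spec.classes:
        for rep in range(spec.n_slides_per_class):
            slide_id = f"{cls.name}_{rep:02d}"
            subject_id = f"subj_{cls.name}_{rep // spec.slides_per_subject:02d}"
            seed = int(slide_seeds[i].generate_state(1)[0] % (2**31))
            i += 1
            images[slide_id] = make_slide(spec, cls.name, seed)
            records.append(
                SlideRecord(
                    slide_id=slide_id,
                    subject_id=subject_id,
                    path=f"{slide_id}.png",
                    label=cls.name,
                )
            )
    return records, images


def make_dataset(
    spec: FixtureSpec,
    out_dir: str | Path,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Render all slides and write PNGs plus a manifest CSV.

    Returns the manifest as a DataFrame (slide_id, subject_id, path, label).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    records, images = render_dataset(spec)
    rows = []
    for rec in records:
        path = out_dir / f"{rec.slide_id}.png"
        write_image(path, images[rec.slide_id])
        rows.append(
            {
                "slide_id": rec.slide_id,
                "subject_id": rec.subject_id,
                "path": str(path),
                "label": rec.label,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
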