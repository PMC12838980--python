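"""Procedural synthetic facial-pain benchmark.

Renders 64x64 schematic faces whose deformations follow the facial Action
Unit cues that accompany pain: brow lowering (AU4), eye tightening
(AU6/7), nasolabial deepening (AU9/10) and mouth opening (AU25/26). Each
deformation scales linearly with PSPI/10, so adjacent pain categories are
naturally confusable while the extremes are well separated. Per-subject
geometry (head shape, eye spacing, brow height, mouth width, skin tone)
emulates inter-subject appearance variation; nuisance variation adds an
illumination gradient, a small translation and Gaussian pixel noise.

Everything is a deterministic function of the master seed, so datasets
are reproducible byte-for-byte, and :func:`signal_mask` exposes the
ground-truth pain-informative regions used to score Grad-CAM localization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .labels import FaceRecord, consolidate_pspi, write_manifest

__all__ = [
    "SubjectProfile", "PainRendering", "NuisanceConfig",
    "render_face", "signal_mask", "generate_dataset", "save_dataset",
]

CANVAS = 64
# PSPI values available inside each consolidated label bin
_BIN_SCORES = {0: (0,), 1: (1,), 2: (2, 3), 3: (4, 5, 6), 4: (7, 8, 9, 10)}

# maximum deformation magnitudes (pixels, except aperture fraction)
BROW_DROP_MAX = 3.5
EYE_CLOSE_MAX = 0.65
MOUTH_OPEN_MAX = 5.0
NASOLABIAL_MAX = 0.6


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject base geometry; a deterministic function of (seed, index)."""

    subject_id: str
    head_rx: float        # head half-width, px
    head_ry: float        # head half-height, px
    eye_dx: float         # eye offset from face midline, px
    eye_y: float          # eye row, px
    eye_rx: float         # eye half-width, px
    eye_ry: float         # open-eye half-height, px
    brow_offset: float    # neutral brow height above the eyes, px
    mouth_y: float        # mouth row, px
    mouth_rx: float       # mouth half-width, px
    skin_tone: float      # base reflectance in [0.45, 0.85]
    subject_seed: int

    BOUNDS = {
        "head_rx": (17.0, 21.0), "head_ry": (23.0, 27.0),
        "eye_dx": (8.0, 11.0), "eye_y": (24.0, 27.0),
        "eye_rx": (3.2, 4.4), "eye_ry": (2.2, 3.2),
        "brow_offset": (5.0, 7.0), "mouth_y": (43.0, 46.0),
        "mouth_rx": (6.0, 9.0), "skin_tone": (0.45, 0.85),
    }

    def __post_init__(self):
        for name, (lo, hi) in self.BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")

    @classmethod
    def from_seed(cls, master_seed: int, index: int) -> "SubjectProfile":
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, index]))
        kwargs = {name: rng.uniform(lo, hi) for name, (lo, hi) in cls.BOUNDS.items()}
        return cls(subject_id=f"S{index:03d}",
                   subject_seed=int(rng.integers(0, 2 ** 31)), **kwargs)


@dataclass(frozen=True)
class PainRendering:
    """Deformation magnitudes for one PSPI level (all linear in PSPI/10)."""

    pspi_score: int
    brow_drop: float            # px the brows move down, >= 0
    eye_aperture: float         # fraction of open-eye height, in (0,1]
    mouth_open: float           # extra mouth half-height, px, >= 0
    nasolabial_intensity: float  # darkening of the nasolabial folds, >= 0

    @classmethod
    def from_pspi(cls, pspi_score: int) -> "PainRendering":
        consolidate_pspi(pspi_score)  # validates range/type
        x = pspi_score / 10.0
        return cls(
            pspi_score=pspi_score,
            brow_drop=BROW_DROP_MAX * x,
            eye_aperture=1.0 - EYE_CLOSE_MAX * x,
            mouth_open=MOUTH_OPEN_MAX * x,
            nasolabial_intensity=NASOLABIAL_MAX * x,
        )


@dataclass(frozen=True)
class NuisanceConfig:
    """Amplitudes of the nuisance variation; zeros disable it entirely."""

    illumination: float = 0.15   # max relative gradient across the canvas
    max_shift: int = 2           # max |translation| in px
    noise_sigma: float = 0.02    # additive Gaussian pixel noise

    @classmethod
    def none(cls) -> "NuisanceConfig":
        return cls(0.0, 0, 0.0)


_YY, _XX = np.mgrid[0:CANVAS, 0:CANVAS].astype(np.float64)


def _soft_ellipse(cy: float, cx: float, ry: float, rx: float,
                  edge: float = 0.7) -> np.ndarray:
    """Anti-aliased ellipse mask in [0,1] with ~``edge``-pixel soft border."""
    r = np.sqrt(((_YY - cy) / ry) ** 2 + ((_XX - cx) / rx) ** 2)
    return np.clip((1.0 - r) * min(ry, rx) / edge + 1.0, 0.0, 1.0) * (r <= 1.0 + edge)


def render_face(profile: SubjectProfile, pain: PainRendering,
                nuisance_seed: int = 0,
                nuisance: NuisanceConfig = NuisanceConfig()) -> np.ndarray:
    """Render one 64x64x3 face in [0,1]; deterministic for fixed inputs."""
    tone = profile.skin_tone
    img = np.full((CANVAS, CANVAS, 3), 0.08, dtype=np.float64)
    head = _soft_ellipse(33.0, 32.0, profile.head_ry, profile.head_rx, edge=1.2)
    skin = np.array([tone, tone * 0.84, tone * 0.72])
    img = img * (1 - head[..., None]) + head[..., None] * skin

    def darken(mask: np.ndarray, strength: float) -> None:
        nonlocal img
        img = img * (1.0 - np.clip(mask * strength, 0.0, 1.0)[..., None])

    # eyes — height shrinks with pain (lid tightening)
    eye_ry = max(profile.eye_ry * pain.eye_aperture, 0.35)
    for sx in (-1.0, 1.0):
        cx = 32.0 + sx * profile.eye_dx
        darken(_soft_ellipse(profile.eye_y, cx, eye_ry, profile.eye_rx), 0.85)
        # brows — drop toward the eyes and thicken slightly with pain
        brow_y = profile.eye_y - profile.brow_offset + pain.brow_drop
        brow_ry = 1.1 + 0.25 * pain.brow_drop
        darken(_soft_ellipse(brow_y, cx, brow_ry, profile.eye_rx + 1.2), 0.7)
    # nasolabial folds — short diagonal creases beside the nose
    for sx in (-1.0, 1.0):
        cx = 32.0 + sx * (profile.mouth_rx * 0.8 + 1.0)
        cy = profile.mouth_y - 4.0
        darken(_soft_ellipse(cy, cx, 2.6, 1.0), pain.nasolabial_intensity)
    # mouth — opens vertically with pain
    mouth_ry = 1.1 + pain.mouth_open
    darken(_soft_ellipse(profile.mouth_y, 32.0, mouth_ry, profile.mouth_rx), 0.8)

    if nuisance.illumination or nuisance.max_shift or nuisance.noise_sigma:
        rng = np.random.default_rng(
            np.random.SeedSequence([profile.subject_seed, int(nuisance_seed)]))
        if nuisance.illumination:
            theta = rng.uniform(0.0, 2 * np.pi)
            ramp = ((_XX - 32) * np.cos(theta) + (_YY - 32) * np.sin(theta)) / CANVAS
            img = img * (1.0 + nuisance.illumination * ramp)[..., None]
        if nuisance.max_shift:
            dy, dx = rng.integers(-nuisance.max_shift, nuisance.max_shift + 1, 2)
            img = np.roll(img, (int(dy), int(dx)), axis=(0, 1))
        if nuisance.noise_sigma:
            img = img + rng.normal(0.0, nuisance.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def signal_mask(profile: SubjectProfile) -> np.ndarray:
    """Boolean 64x64 mask over the pain-informative regions.

    Covers the brow+eye band and the mouth/nasolabial region across the
    full deformation range, i.e. every pixel whose value can change
    between the neutral and maximum-pain render (nuisance off).
    """
    mask = np.zeros((CANVAS, CANVAS), dtype=bool)
    pad = 2.5
    x_lo = int(np.floor(32 - profile.eye_dx - profile.eye_rx - 1.2 - pad))
    x_hi = int(np.ceil(32 + profile.eye_dx + profile.eye_rx + 1.2 + pad))
    y_lo = int(np.floor(profile.eye_y - profile.brow_offset - 2.0 - pad))
    y_hi = int(np.ceil(profile.eye_y + profile.eye_ry + pad))
    mask[max(y_lo, 0):y_hi + 1, max(x_lo, 0):x_hi + 1] = True
    mx_lo = int(np.floor(32 - profile.mouth_rx - 2.0 - pad))
    mx_hi = int(np.ceil(32 + profile.mouth_rx + 2.0 + pad))
    my_lo = int(np.floor(profile.mouth_y - 7.0 - pad))
    my_hi = int(np.ceil(profile.mouth_y + 1.1 + MOUTH_OPEN_MAX + pad))
    mask[max(my_lo, 0):my_hi + 1, max(mx_lo, 0):mx_hi + 1] = True
    return mask


def _subject_labels(images_per_subject: int, rng: np.random.Generator,
                    balance: bool) -> np.ndarray:
    if balance:
        reps = int(np.ceil(images_per_subject / 5))
        labels = np.tile(np.arange(5), reps)[:images_per_subject]
        rng.shuffle(labels)
        return labels
    return rng.integers(0, 5, images_per_subject)


def generate_dataset(n_subjects: int, images_per_subject: int, master_seed: int,
                     balance: bool = True,
                     nuisance: NuisanceConfig = NuisanceConfig(),
                     ) -> tuple[list[FaceRecord], list[SubjectProfile]]:
    """Generate the full in-memory benchmark.

    With ``balance`` on, each subject's label counts differ by at most one
    and every one of the five labels is populated overall. Images are kept
    as float arrays in each record's ``image_ref``.
    """
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    if images_per_subject < 5:
        raise ValueError("need at least 5 images per subject")
    if balance and images_per_subject < 5:
        raise ValueError("balanced generation needs >= 5 images per subject")
    records: list[FaceRecord] = []
    profiles: list[SubjectProfile] = []
    for si in range(n_subjects):
        profile = SubjectProfile.from_seed(master_seed, si)
        profiles.append(profile)
        rng = np.random.default_rng(
            np.random.SeedSequence([master_seed, si, 7]))
        labels = _subject_labels(images_per_subject, rng, balance)
        for ji, label in enumerate(labels):
            pspi = int(rng.choice(_BIN_SCORES[int(label)]))
            pain = PainRendering.from_pspi(pspi)
            img = render_face(profile, pain, nuisance_seed=ji, nuisance=nuisance)
            records.append(FaceRecord(
                image_ref=img, subject_id=profile.subject_id, pspi_score=pspi))
    return records, profiles


def save_dataset(records: list[FaceRecord], out_dir: str | Path,
                 profiles: list[SubjectProfile] | None = None) -> Path:
    """Write images/<subject>/<idx>.png plus manifest.csv; returns manifest path.

    Offline-augmented records are stored beside the originals with an
    ``_augN`` filename suffix. Float pixels are quantized as round(255*x),
    so a written-then-reloaded dataset reproduces the uint8 images exactly.
    When ``profiles`` is given they are serialized to ``profiles.json`` so
    ground-truth signal masks can be reconstructed later.
    """
    import dataclasses
    import json

    out_dir = Path(out_dir)
    per_subject: dict[str, int] = {}
    aug_counter: dict[str, int] = {}
    stored: list[FaceRecord] = []
    for rec in records:
        if rec.augmented:
            k = aug_counter.get(rec.subject_id, 0)
            aug_counter[rec.subject_id] = k + 1
            rel = Path("images") / rec.subject_id / f"{k:04d}_aug{k + 1}.png"
        else:
            idx = per_subject.get(rec.subject_id, 0)
            per_subject[rec.subject_id] = idx + 1
            rel = Path("images") / rec.subject_id / f"{idx:04d}.png"
        target = out_dir / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        arr = np.asarray(rec.image_ref)
        if arr.dtype != np.uint8:
            arr = np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(target)
        stored.append(replace(rec, image_ref=str(rel)))
    manifest = out_dir / "manifest.csv"
    write_manifest(stored, manifest)
    if profiles is not None:
        (out_dir / "profiles.json").write_text(json.dumps(
            {p.subject_id: dataclasses.asdict(p) for p in profiles},
            indent=2, sort_keys=True))
    return manifest


def load_profiles(path: str | Path) -> list[SubjectProfile]:
    """Read back the ``profiles.json`` written by :func:`save_dataset`."""
    import json

    payload = json.loads(Path(path).read_text())
    return [SubjectProfile(**fields) for fields in payload.values()]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG back into a float [0,1] RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
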