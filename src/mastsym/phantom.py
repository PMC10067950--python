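"""Synthetic bilateral mastoid-radiograph phantom.

Real mastoid AP views cannot be redistributed, so this module synthesizes
studies with the statistical structure the symmetry method assumes:

* **between-subject anatomic variation** — each subject draws its own
  air-cell texture (cell size, density, region geometry) plus subject-level
  opacity-baseline and cell-depth factors shared by both ears, emulating the
  large inter-individual variation of mastoid pneumatization;
* **within-subject bilateral symmetry** — the left ear is the mirror image
  of the right ear up to a small residual jitter, emulating the near-perfect
  bilateral symmetry of one person's air cells;
* **category-dependent opacification** — disease fills the air-cell texture
  toward an opaque ("hazy") appearance, with three increasing opacity means
  for normal / mild / severe and a bright sclerotic rim added for severe;
* **a configurable joint distribution** over the nine bilateral category
  pairs, from which the symmetry-grade distribution follows by the
  absolute-difference map.

The air-cell texture is thresholded smoothed noise ("blobby" cells), not an
anatomically faithful rendering: only the symmetry and opacity statistics
matter for exercising the method.

In the benchmark preset the subject-level opacity offset is comparable to
the normal-to-mild opacity step, so mild disease is ambiguous from a single
ear but plain from the contralateral comparison — the regime in which a
symmetry-aware model has headroom over a single-side model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .labels import BilateralLabel, EarCategory
from .preprocess import APView, Photometric, crop_ears, compose_pair
from .training import BilateralDataset

__all__ = [
    "PhantomParams",
    "PhantomStudy",
    "generate_subject",
    "generate_cohort",
    "generate_cohort_arrays",
    "default_benchmark_params",
    "cohort_dataset",
]


def _default_pair_distribution() -> np.ndarray:
    # rows: right category, cols: left category; concordant pairs dominate,
    # as bilateral disease status is positively correlated within a person
    return np.array(
        [
            [0.300, 0.100, 0.075],
            [0.100, 0.100, 0.075],
            [0.075, 0.075, 0.100],
        ]
    )


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration.

    ``haziness_levels`` are the mean air-cell opacities of the three
    categories (strictly increasing); ``baseline_opacity_sd`` is the
    subject-level opacity offset shared by both ears (the nuisance that
    makes unilateral reading hard); ``asymmetry_jitter_mm`` is the residual
    within-subject mirror error.
    """

    n_subjects: int = 600
    image_height_px: int = 1000
    image_width_px: int = 800
    pixel_spacing_mm: float = 0.5
    pair_distribution: np.ndarray = field(default_factory=_default_pair_distribution)
    anatomy_variation: float = 1.0
    asymmetry_jitter_mm: float = 0.4
    haziness_levels: tuple[float, float, float] = (0.10, 0.30, 0.80)
    baseline_opacity_sd: float = 0.12
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        pd_ = np.asarray(self.pair_distribution, dtype=float)
        object.__setattr__(self, "pair_distribution", pd_)
        if pd_.shape != (3, 3) or np.any(pd_ < 0) or abs(pd_.sum() - 1.0) > 1e-9:
            raise ValueError("pair_distribution must be a 3x3 probability table summing to 1")
        h = self.haziness_levels
        if not (h[0] < h[1] < h[2]):
            raise ValueError("haziness_levels must be strictly increasing")
        if min(self.anatomy_variation, self.asymmetry_jitter_mm,
               self.baseline_opacity_sd, self.noise_sd) < 0:
            raise ValueError("dispersions must be non-negative")
        if self.image_width_px % 2:
            raise ValueError("image width must be even (mirror construction)")
        box_h = 180.0 / self.pixel_spacing_mm
        box_w = 120.0 / self.pixel_spacing_mm
        if box_h > self.image_height_px or box_w > self.image_width_px / 2:
            raise ValueError(
                f"image {self.image_height_px}x{self.image_width_px} px at "
                f"{self.pixel_spacing_mm} mm cannot contain the 180x120 mm ear crops"
            )

    @property
    def params_hash(self) -> str:
        payload = asdict(self)
        payload["pair_distribution"] = self.pair_distribution.tolist()
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PhantomStudy:
    ap_view: APView
    truth: BilateralLabel
    seed: int
    params_hash: str


def default_benchmark_params() -> PhantomParams:
    """Benchmark preset: asymmetry is the informative signal for mild
    disease.

    The normal-to-mild opacity step (0.18) is of the same order as the
    subject-level opacity spread (0.15), so a single ear is ambiguous for
    mild disease, while severe (step 0.70) is clear either way.  Images are
    generated at 1.0 mm spacing (500x400 px) so the 180x120 mm crops are
    180x120 px, matching 4x-downscaled network inputs of 96x64.
    """
    return PhantomParams(
        n_subjects=600,
        image_height_px=500,
        image_width_px=400,
        pixel_spacing_mm=1.0,
        anatomy_variation=1.0,
        asymmetry_jitter_mm=0.4,
        haziness_levels=(0.10, 0.28, 0.80),
        baseline_opacity_sd=0.15,
        noise_sd=0.02,
        seed=20230401,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class _Anatomy:
    """Per-subject anatomy shared (mirrored) between the two ears."""

    bone_level: float
    background: np.ndarray     # smooth mirrored bone-density field, half frame
    cell_field: np.ndarray     # smoothed noise before thresholding, half frame
    cell_threshold: float
    ellipse: np.ndarray        # feathered air-cell region mask in [0, 1]
    rim: np.ndarray            # sclerotic rim band mask in [0, 1]
    ridge: np.ndarray          # dense petrous-ridge band mask in [0, 1]
    inferior_fade: np.ndarray  # dark soft-tissue fade below the mastoid in [0, 1]
    cell_depth: float          # subject-level lucency of fully aerated cells
    opacity_offset: float      # subject-level haziness baseline (both ears)


_CELL_DEPTH = 0.35
_RIM_AMPLITUDE = 0.15


def _draw_anatomy(params: PhantomParams, rng: np.random.Generator) -> _Anatomy:
    h = params.image_height_px
    w2 = params.image_width_px // 2
    sp = params.pixel_spacing_mm
    av = params.anatomy_variation

    bone = 0.55 + 0.05 * av * rng.standard_normal()
    bg = gaussian_filter(rng.standard_normal((h, w2)), sigma=30.0 / sp)
    bg *= 0.05 * av / max(bg.std(), 1e-9)

    cell_sigma = (3.5 + 1.5 * av * rng.random()) / sp
    field = gaussian_filter(rng.standard_normal((h, w2)), sigma=cell_sigma)
    field /= max(field.std(), 1e-9)
    threshold = 0.1 + 0.25 * av * rng.standard_normal()

    cy, cx = 0.5 * h, 0.5 * w2  # ear centre of the half frame = 0.25 W of the full frame
    ry = (50.0 + 8.0 * av * rng.standard_normal()) / sp
    rx = (35.0 + 6.0 * av * rng.standard_normal()) / sp
    ry, rx = max(ry, 20.0 / sp), max(rx, 15.0 / sp)
    rows = np.arange(h)[:, None]
    cols = np.arange(w2)[None, :]
    rho = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    ellipse = np.clip((1.0 - rho) / 0.15, 0.0, 1.0)          # feathered edge
    rim = np.clip(1.0 - np.abs(rho - 1.0) / 0.12, 0.0, 1.0)  # band at the boundary

    # dense bone and soft-tissue landmarks anchor the intensity range of
    # every crop, so per-crop windowing cannot cancel the opacity signal
    ridge_row = cy - (55.0 + 4.0 * av * rng.standard_normal()) / sp
    ridge = np.clip(1.0 - np.abs(rows - ridge_row) / (9.0 / sp), 0.0, 1.0) * np.ones_like(rho)
    fade_row = cy + (60.0 + 4.0 * av * rng.standard_normal()) / sp
    inferior_fade = np.clip((rows - fade_row) / (15.0 / sp), 0.0, 1.0) * np.ones_like(rho)

    return _Anatomy(
        bone_level=bone,
        background=bg,
        cell_field=field,
        cell_threshold=threshold,
        ellipse=ellipse,
        rim=rim,
        ridge=ridge,
        inferior_fade=inferior_fade,
        cell_depth=_CELL_DEPTH * float(np.exp(0.35 * av * rng.standard_normal())),
        opacity_offset=params.baseline_opacity_sd * rng.standard_normal(),
    )


def render_ear_half(
    params: PhantomParams,
    anatomy: _Anatomy,
    category: int,
    jitter_px: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Render one ear's half-frame (right-ear orientation, no noise).

    Air cells are dark pockets carved out of the bone level; disease fills
    them toward opacity.  Severe disease additionally brightens the
    sclerotic rim.  ``jitter_px`` shifts the cell texture to model residual
    within-subject asymmetry."""
    field = anatomy.cell_field
    if jitter_px != (0.0, 0.0):
        field = nd_shift(field, jitter_px, order=1, mode="nearest")
    cellness = 1.0 / (1.0 + np.exp(-(field - anatomy.cell_threshold) / 0.35))
    opacity = float(np.clip(
        params.haziness_levels[int(category)] + anatomy.opacity_offset, 0.0, 1.0
    ))
    img = anatomy.bone_level + anatomy.background
    img = img + 0.40 * anatomy.ridge
    img = img - (anatomy.bone_level - 0.15) * anatomy.inferior_fade
    img = img - anatomy.cell_depth * cellness * (1.0 - opacity) * anatomy.ellipse
    if int(category) == 2:
        img = img + _RIM_AMPLITUDE * anatomy.rim
    return img


def generate_subject(
    params: PhantomParams, rng: np.random.Generator, subject_id: str = "s00000"
) -> PhantomStudy:
    """Synthesize one bilateral study.

    Draws a category pair from ``pair_distribution``, renders the right
    half-frame, renders the left half from the same (mirrored) anatomy with
    the category and jitter of the left ear, and adds Gaussian noise.  With
    zero jitter and zero noise a concordant subject is exactly
    mirror-symmetric about the vertical midline.
    """
    flat = params.pair_distribution.ravel()
    pair_idx = int(rng.choice(9, p=flat))
    cat_r, cat_l = divmod(pair_idx, 3)

    anatomy = _draw_anatomy(params, rng)
    jitter_sd = params.asymmetry_jitter_mm / params.pixel_spacing_mm
    if jitter_sd > 0:
        jitter = tuple(jitter_sd * rng.standard_normal(2))
    else:
        jitter = (0.0, 0.0)

    right_half = render_ear_half(params, anatomy, cat_r)
    left_half = render_ear_half(params, anatomy, cat_l, jitter_px=jitter)
    full = np.concatenate([right_half, left_half[:, ::-1]], axis=1)
    if params.noise_sd > 0:
        full = full + params.noise_sd * rng.standard_normal(full.shape)

    view = APView(full, params.pixel_spacing_mm, params.pixel_spacing_mm,
                  Photometric.MONOCHROME2)
    truth = BilateralLabel(subject_id, EarCategory(cat_r), EarCategory(cat_l))
    return PhantomStudy(view, truth, params.seed, params.params_hash)


def generate_cohort_arrays(params: PhantomParams) -> list[PhantomStudy]:
    """Generate ``n_subjects`` studies in memory, reproducibly from
    ``params.seed`` (each subject gets an independent child stream)."""
    children = np.random.SeedSequence(params.seed).spawn(params.n_subjects)
    return [
        generate_subject(params, np.random.default_rng(child), f"s{i:05d}")
        for i, child in enumerate(children)
    ]


def cohort_dataset(studies, target_shape=(384, 256)) -> BilateralDataset:
    """Preprocess a cohort into a :class:`BilateralDataset` (crop both
    ears, flip/resize/normalize, keep the two halves)."""
    rights, lefts, yr, yl, ids = [], [], [], [], []
    for study in studies:
        r, l = crop_ears(study.ap_view)
        pair = compose_pair(r, l, target_shape=target_shape)
        rights.append(pair.right_image)
        lefts.append(pair.left_image)
        yr.append(int(study.truth.right))
        yl.append(int(study.truth.left))
        ids.append(study.truth.subject_id)
    return BilateralDataset(np.stack(rights), np.stack(lefts),
                            np.array(yr), np.array(yl), ids)


# ---------------------------------------------------------------------------
# DICOM output


def _write_dicom(path: Path, view: APView, subject_id: str, params_hash: str) -> None:
    # rescale slope/intercept map stored uint16 back to intensity; the
    # intercept keeps slightly negative soft-tissue pixels representable
    scale, intercept = 1.0e-4, -2.0
    stored = np.clip(np.round((view.pixels - intercept) / scale), 0, 65535).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[subject_id, params_hash])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CR"
    ds.PatientID = subject_id
    ds.SeriesDescription = "synthetic mastoid AP phantom"
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [view.row_spacing_mm, view.col_spacing_mm]
    ds.RescaleSlope = scale
    ds.RescaleIntercept = intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def generate_cohort(params: PhantomParams, outdir: str | Path) -> pd.DataFrame:
    """Write a cohort as DICOM files plus ``labels.csv``; returns the label
    table.  File ``<subject_id>.dcm`` round-trips through
    :func:`mastsym.preprocess.read_ap_view` with spacing preserved."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in generate_cohort_arrays(params):
        sid = study.truth.subject_id
        _write_dicom(outdir / f"{sid}.dcm", study.ap_view, sid, study.params_hash)
        rows.append(
            {
                "subject_id": sid,
                "right_category": int(study.truth.right),
                "left_category": int(study.truth.left),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "labels.csv", index=False)
    return table
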