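"""Synthetic phantom generators.

Every downstream stage of the pipeline is exercised on phantoms with known
ground truth generated here:

* ``make_phantom`` — a paired white-light / infrared (IR) image of one
  "specimen on a black table": an elliptical or blobby tumor embedded in
  tissue, with margin bands at two distances, a separate tumor-bed patch,
  a configurable true tumor-to-background contrast, optional
  inflammation-like false-positive foci and additive Gaussian noise.
* ``make_section_pair`` — the phantom's tissue pushed through a known
  similarity transform plus a smooth Gaussian-kernel displacement field,
  emulating the geometric artefacts a mounted histologic section acquires
  relative to the gross fixed-tissue section it was cut from.
* ``make_ihc_phantom`` — a chromogen-stained (DAB-brown on white) slide with
  exactly controlled stained-area fractions in tumor and peritumoral ROIs.
* ``make_cohort`` — a section cohort with exact, by-construction counts of
  true/false positive and negative sections for the detection-accuracy
  analysis.

All randomness flows from one explicit integer seed per call; identical
config + seed gives bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from fgsquant.exceptions import ConfigError, DegenerateDeformationError
from fgsquant.shapematch import OutlineTransform

MIN_IMAGE_SIDE = 32


@dataclass(frozen=True)
class PhantomConfig:
    """Generator truth for one phantom specimen.

    ``background_mfi`` and ``true_tbr`` set the expected IR intensity outside
    and inside the tumor (``background_mfi * true_tbr``) before noise and
    8-bit clipping. ``tumor_size`` are semi-axes in pixels (ellipse/blob);
    ``tumor_shape='none'`` generates a tumor-free (non-neoplastic) specimen
    whose tissue footprint uses the same size parameters. ``margin_widths``
    are the band widths (px) of the inner and outer margin-band analogs.
    """

    image_height: int = 192
    image_width: int = 192
    background_mfi: float = 40.0
    true_tbr: float = 3.0
    noise_sd: float = 2.0
    tumor_shape: str = "ellipse"  # ellipse | blob | none
    tumor_size: tuple[float, float] = (28.0, 18.0)
    margin_widths: tuple[float, float] = (10.0, 10.0)
    fp_foci: int = 0
    fp_intensity_multiplier: float = 2.5
    fp_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < MIN_IMAGE_SIDE or self.image_width < MIN_IMAGE_SIDE:
            raise ConfigError(f"image sides must be >= {MIN_IMAGE_SIDE} px")
        if self.true_tbr <= 0:
            raise ConfigError("true_tbr must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0 <= self.background_mfi <= 255):
            raise ConfigError("background_mfi must lie in [0, 255]")
        if self.tumor_shape not in ("ellipse", "blob", "none"):
            raise ConfigError("tumor_shape must be one of ellipse|blob|none")
        if self.fp_foci < 0:
            raise ConfigError("fp_foci must be >= 0")

    @property
    def clipping_expected(self) -> bool:
        return self.background_mfi * self.true_tbr > 255


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic specimen: paired images, ground-truth masks, truth config."""

    white_image: np.ndarray  # (h, w, 3) uint8
    ir_image: np.ndarray  # (h, w) uint8
    tumor_mask: np.ndarray
    margin1_mask: np.ndarray
    margin3_mask: np.ndarray
    tumorbed_mask: np.ndarray
    tissue_mask: np.ndarray
    clipped: bool
    truth: PhantomConfig


@dataclass(frozen=True)
class DeformConfig:
    """Known ground-truth deformation applied to derive the histology frame."""

    rotation: float = 0.0  # degrees
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    reflection: bool = False
    warp_amplitude: float = 0.0  # px
    warp_smoothness: float = 30.0  # px (Gaussian kernel bandwidth)
    n_warp_points: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigError("scale must be > 0")
        if self.warp_amplitude < 0:
            raise ConfigError("warp_amplitude must be >= 0")
        if self.warp_smoothness <= 0:
            raise ConfigError("warp_smoothness must be > 0")


#: Deformation magnitudes typical of mounting artefacts: moderate rotation,
#: slight shrink, a few-pixel shift and a gentle smooth warp.
MOUNTING_ARTEFACT_DEFORM = DeformConfig(
    rotation=25.0, scale=0.92, translation=(6.0, -4.0),
    warp_amplitude=4.0, warp_smoothness=30.0, seed=0,
)


@dataclass(frozen=True)
class SectionPair:
    """Paired fluorescence-frame section and its deformed histology frame."""

    fft_image: np.ndarray
    fft_tissue_mask: np.ndarray
    fft_tumor_mask: np.ndarray
    histo_tissue_mask: np.ndarray
    histo_tumor_mask: np.ndarray
    true_transform: OutlineTransform
    label: str  # neoplastic | non-neoplastic
    nirf_positive: bool = False  # generator-level signal presence


@dataclass(frozen=True)
class IHCPhantom:
    """Chromogen-stained slide with known stained fractions per ROI."""

    image: np.ndarray  # (h, w, 3) uint8
    tumor_roi: np.ndarray
    peritumoral_roi: np.ndarray
    true_stained_fraction_tumor: float
    true_stained_fraction_peri: float
    true_stain_od: float
    seed: int


def _ellipse_mask(shape, center, axes, rng=None, blob: bool = False) -> np.ndarray:
    h, w = shape
    cy, cx = center
    ay, ax = axes
    rows, cols = np.mgrid[0:h, 0:w]
    dy, dx = rows - cy, cols - cx
    if not blob:
        return (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0
    # blob: ellipse with a smooth random radial perturbation (Fourier modes)
    theta = np.arctan2(dy, dx)
    amp = rng.uniform(0.05, 0.15, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    pert = 1.0 + sum(a * np.cos((k + 2) * theta + p)
                     for k, (a, p) in enumerate(zip(amp, phase)))
    return (dy / ay) ** 2 + (dx / ax) ** 2 <= pert**2


def make_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one phantom specimen (deterministic for a fixed seed).

    Expected IR intensity is ``background_mfi * true_tbr`` inside the tumor
    and ``background_mfi`` elsewhere (before noise and 8-bit clipping);
    false-positive foci are bright disks in the outer margin band.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    center = (h / 2.0, w / 2.0)
    axes = (config.tumor_size[1], config.tumor_size[0])  # (ay, ax) from (x, y) sizes

    footprint = _ellipse_mask((h, w), center, axes,
                              rng=rng, blob=config.tumor_shape == "blob")
    tumor = footprint if config.tumor_shape != "none" else np.zeros((h, w), bool)
    if config.tumor_shape != "none" and not tumor.any():
        raise ConfigError("tumor_size too small: empty tumor mask")

    w1, w3 = config.margin_widths
    dist = ndimage.distance_transform_edt(~footprint)
    margin1 = (dist > 0) & (dist <= w1)
    margin3 = (dist > 2 * w1) & (dist <= 2 * w1 + w3)
    tissue = footprint | (dist <= 2 * w1 + w3)

    bed_center = (h - 0.12 * h, 0.12 * w)
    bed_r = max(6.0, 0.05 * min(h, w))
    tumorbed = _ellipse_mask((h, w), bed_center, (bed_r, bed_r))
    if (tumorbed & tissue).any():
        raise ConfigError("tumor-bed patch overlaps the tissue; enlarge the image")

    ir = np.full((h, w), float(config.background_mfi))
    ir[tumor] = config.background_mfi * config.true_tbr
    for _ in range(config.fp_foci):
        ys, xs = np.nonzero(margin3)
        if len(ys) == 0:
            break
        i = rng.integers(len(ys))
        focus = _ellipse_mask((h, w), (ys[i], xs[i]),
                              (config.fp_radius, config.fp_radius))
        ir[focus & ~tumor] = min(
            255.0, config.background_mfi * config.fp_intensity_multiplier
        )
    if config.noise_sd > 0:
        ir = ir + rng.normal(0.0, config.noise_sd, size=ir.shape)
    clipped = bool(config.clipping_expected)
    ir8 = np.floor(np.clip(ir, 0, 255) + 0.5).astype(np.uint8)

    white = np.empty((h, w, 3), np.uint8)
    white[...] = (15, 15, 18)  # black table
    white[tissue] = (205, 175, 160)
    white[tumor] = (185, 150, 140)
    wn = rng.normal(0, 2.0, size=white.shape)
    white = np.clip(white.astype(float) + wn, 0, 255).astype(np.uint8)

    return PhantomCase(
        white_image=white, ir_image=ir8, tumor_mask=tumor,
        margin1_mask=margin1, margin3_mask=margin3, tumorbed_mask=tumorbed,
        tissue_mask=tissue, clipped=clipped, truth=config,
    )


def _deform_transform(deform: DeformConfig, shape: tuple[int, int],
                      tissue_mask: np.ndarray) -> OutlineTransform:
    """Build the ground-truth fluorescence-frame -> histology-frame transform."""
    if deform.warp_amplitude > 0 and deform.warp_amplitude > deform.warp_smoothness:
        raise DegenerateDeformationError(
            "warp_amplitude exceeds warp_smoothness: displacement field may fold"
        )
    h, w = shape
    c = np.array([w / 2.0, h / 2.0])
    base = OutlineTransform(
        rotation_deg=deform.rotation, scale=deform.scale,
        translation=np.zeros(2), reflection=deform.reflection,
    )
    # rotate/scale about the image center, then shift
    t = c + np.asarray(deform.translation, float) - base.matrix @ c
    base = replace(base, translation=t)
    if deform.warp_amplitude == 0:
        return base
    rng = np.random.default_rng(deform.seed)
    ys, xs = np.nonzero(tissue_mask)
    idx = rng.choice(len(ys), size=min(deform.n_warp_points, len(ys)), replace=False)
    ctrl_src = np.column_stack([xs[idx], ys[idx]]).astype(float)
    ctrl = ctrl_src @ base.matrix.T + base.translation  # control pts in target frame
    ang = rng.uniform(0, 2 * np.pi, size=len(ctrl))
    mag = rng.uniform(0.5, 1.0, size=len(ctrl)) * deform.warp_amplitude
    disp = np.column_stack([mag * np.cos(ang), mag * np.sin(ang)])
    return replace(base, control_points=ctrl, displacements=disp,
                   smoothness=float(deform.warp_smoothness))


def make_section_pair(case: PhantomCase, deform: DeformConfig) -> SectionPair:
    """Push the phantom's tissue through a known deformation.

    The histology-frame masks are the fluorescence-frame masks warped by the
    stored ``true_transform`` (similarity about the image center plus a
    smooth Gaussian-kernel displacement field), so registration can be
    validated against exact ground truth.
    """
    from fgsquant.shapematch import transfer_mask

    if not case.tissue_mask.any():
        raise ConfigError("phantom case has an empty tissue region")
    shape = case.tissue_mask.shape
    transform = _deform_transform(deform, shape, case.tissue_mask)
    histo_tissue = transfer_mask(case.tissue_mask, transform, shape)
    histo_tumor = transfer_mask(case.tumor_mask, transform, shape)
    label = "neoplastic" if case.tumor_mask.any() else "non-neoplastic"
    return SectionPair(
        fft_image=case.ir_image, fft_tissue_mask=case.tissue_mask,
        fft_tumor_mask=case.tumor_mask,
        histo_tissue_mask=histo_tissue, histo_tumor_mask=histo_tumor & histo_tissue,
        true_transform=transform, label=label,
        nirf_positive=bool(case.tumor_mask.any() and case.truth.true_tbr >= 1.5),
    )


def make_ihc_phantom(frac_tumor: float, frac_peri: float, seed: int,
                     shape: tuple[int, int] = (160, 260),
                     stain_od: float = 0.6, noise_sd: float = 1.0) -> IHCPhantom:
    """A DAB-brown-on-white slide with exact stained fractions per ROI.

    Stained pixels are sampled uniformly within each ROI at exactly the
    requested count, colored through the inverse hematoxylin-eosin-DAB
    separation at optical density ``stain_od``, so realized fractions match
    the request up to finite-pixel rounding.
    """
    for name, frac in (("frac_tumor", frac_tumor), ("frac_peri", frac_peri)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    h, w = shape
    gap = max(8, w // 13)
    half = (w - 3 * gap) // 2
    tumor_roi = np.zeros((h, w), bool)
    peri_roi = np.zeros((h, w), bool)
    tumor_roi[gap:h - gap, gap:gap + half] = True
    peri_roi[gap:h - gap, 2 * gap + half:2 * gap + 2 * half] = True

    hed = np.zeros((h, w, 3), float)
    for roi, frac in ((tumor_roi, frac_tumor), (peri_roi, frac_peri)):
        ys, xs = np.nonzero(roi)
        k = int(round(frac * len(ys)))
        if k > 0:
            pick = rng.choice(len(ys), size=k, replace=False)
            hed[ys[pick], xs[pick], 2] = stain_od  # DAB channel
    rgb = np.clip(skcolor.hed2rgb(hed), 0, 1) * 255.0
    if noise_sd > 0:
        rgb = rgb + rng.normal(0, noise_sd, size=rgb.shape)
    image = np.clip(rgb, 0, 255).astype(np.uint8)
    return IHCPhantom(
        image=image, tumor_roi=tumor_roi, peritumoral_roi=peri_roi,
        true_stained_fraction_tumor=frac_tumor,
        true_stained_fraction_peri=frac_peri,
        true_stain_od=stain_od, seed=seed,
    )


def make_ihc_cohort(n_cases: int, seed: int,
                    frac_range: tuple[float, float] = (0.05, 0.90),
                    sbr_noise_sd: float = 0.8) -> list[tuple[float, IHCPhantom]]:
    """Coupled fluorescence / staining cohort for correlation experiments.

    Per case the tumor stained fraction is drawn uniformly from
    ``frac_range``; the stain optical density grows with the fraction
    (stronger expression stains both wider and darker) and the fluorescence
    signal-to-background ratio grows linearly with the fraction plus noise.
    Returns ``(sbr, phantom)`` pairs.
    """
    if n_cases < 3:
        raise ConfigError("need at least 3 cases for a correlation cohort")
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2**31)
    out = []
    for s in seeds:
        f = float(rng.uniform(*frac_range))
        od = 0.25 + 0.9 * f
        sbr = max(0.1, 1.0 + 8.0 * f + float(rng.normal(0, sbr_noise_sd)))
        phantom = make_ihc_phantom(
            frac_tumor=f, frac_peri=min(1.0, 0.2 * f), seed=int(s),
            shape=(120, 200), stain_od=od,
        )
        out.append((sbr, phantom))
    return out


@dataclass(frozen=True)
class CohortEffect:
    """Exact composition of a synthetic section cohort.

    Counts are by construction: ``n_neoplastic`` sections carry tumor;
    ``n_false_positive`` of the non-neoplastic sections carry an
    inflammation-like bright focus; ``n_false_negative`` of the neoplastic
    sections carry no fluorescence contrast.
    """

    n_neoplastic: int
    n_false_positive: int = 0
    n_false_negative: int = 0


#: Cohort composition matching the reported 148-section review:
#: 76 fluorescent tumor sections, 56 clean non-neoplastic sections,
#: 16 non-neoplastic sections with false-positive signal, no false negatives.
REFERENCE_COHORT_EFFECT = CohortEffect(n_neoplastic=76, n_false_positive=16,
                                       n_false_negative=0)


def make_cohort(n_sections: int, effect: CohortEffect, seed: int,
                image_side: int = 96) -> list[SectionPair]:
    """Generate a section cohort with exact ground-truth composition."""
    if n_sections < 1:
        raise ConfigError("n_sections must be >= 1")
    n_non = n_sections - effect.n_neoplastic
    if n_non < 0 or effect.n_false_positive > n_non:
        raise ConfigError("cohort composition exceeds n_sections")
    if effect.n_false_negative > effect.n_neoplastic:
        raise ConfigError("more false negatives than neoplastic sections")
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(n_sections) % (2**31)
    roles = (
        ["tp"] * (effect.n_neoplastic - effect.n_false_negative)
        + ["fn"] * effect.n_false_negative
        + ["fp"] * effect.n_false_positive
        + ["tn"] * (n_non - effect.n_false_positive)
    )
    rng.shuffle(roles)
    axes = (image_side / 6.0, image_side / 9.0)
    sections: list[SectionPair] = []
    for role, s in zip(roles, seeds):
        cfg = PhantomConfig(
            image_height=image_side, image_width=image_side,
            background_mfi=40.0, noise_sd=2.0, tumor_size=axes,
            margin_widths=(image_side / 16.0, image_side / 16.0),
            tumor_shape="ellipse" if role in ("tp", "fn") else "none",
            true_tbr=3.0 if role != "fn" else 1.0,
            fp_foci=1 if role == "fp" else 0,
            fp_intensity_multiplier=3.0, fp_radius=image_side / 14.0,
            seed=int(s),
        )
        pair = make_section_pair(make_phantom(cfg), DeformConfig(seed=int(s)))
        pair = replace(pair, nirf_positive=role in ("tp", "fp"))
        sections.append(pair)
    return sections
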