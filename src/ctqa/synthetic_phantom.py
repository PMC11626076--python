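"""Synthetic chest-CT slices and dose series with known ground truth.

The phantom is a 2D chest-like arrangement of HU compartments: air
background (-1000 HU), a soft-tissue body ellipse (+40 HU), two lung
ellipses (-800 HU), an air-filled trachea disk (-1000 HU) and a liver disk
(+60 HU).  Gaussian blur of the compartment image creates sigmoid-like
lung-to-pleura edges; seeded Gaussian noise emulates quantum noise with
SD scaling as 1/sqrt(mAs).

Dose-dependent sharpness: pure additive noise leaves the underlying edge
unchanged, so to reproduce the characteristic rise-then-plateau of edge
sharpness with dose, the effective edge blur widens with the noise level
(``recon_blur_scale``), emulating the stronger smoothing a noise-adaptive
reconstruction applies at low dose.

Ground-truth edge steepness is evaluated numerically from the blurred
noiseless image (maximum HU gradient along the interface normal), so it
stays exact for any compartment geometry.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .dosimetry import ScanRecord
from .image import CTImage
from .line_profiles import LEVELS, ProfileLine
from .roi_metrics import CircularROI
from .sharpness import logistic_model

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "DoseLevel",
    "generate_edge_image",
    "edge_measurement_grid",
    "generate_phantom_slice",
    "generate_phantom_stack",
    "generate_dose_series",
    "default_grid",
    "default_rois",
    "default_scan_settings",
    "write_nifti",
    "write_ground_truth",
]

# canonical geometry on a 512 px grid; scaled proportionally to spec.size
_BODY_CENTER = (256.0, 280.0)
_BODY_SEMI = (220.0, 170.0)
_LUNG_CENTERS = {"left": (160.0, 260.0), "right": (352.0, 260.0)}
_LUNG_SEMI = (80.0, 110.0)
_TRACHEA = ((256.0, 150.0), 55.0)
_LIVER = ((256.0, 382.0), 55.0)
# outward ellipse-parameter arcs that avoid the mediastinum (trachea/liver)
_ARCS_DEG = {"left": (95.0, 265.0), "right": (-85.0, 85.0)}

N_INTERFACES = 39
N_REPLICATES = 12
# tangential replicate offsets in px, symmetric around the interface point
REPLICATE_OFFSETS = (-6, -5, -4, -3, -2, -1, 1, 2, 3, 4, 5, 6)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom and its noise model."""

    size: int = 512  # square image, px
    spacing_mm: float = 0.6  # isotropic pixel spacing
    air_hu: float = -1000.0
    soft_tissue_hu: float = 40.0
    lung_hu: float = -800.0
    trachea_hu: float = -1000.0
    liver_hu: float = 60.0
    edge_blur_sigma: float = 1.2  # px, baseline reconstruction blur
    noise_sd_ref: float = 15.0  # HU at the reference mAs
    reference_mas: float = 14.0
    reference_kvp: float = 120.0
    kvp_exponent: float = 1.5  # noise multiplier (ref_kvp/kvp)^exponent
    recon_blur_scale: float = 1.0  # dose-dependent smoothing strength
    level_scales: tuple[float, float, float] = (0.8, 1.0, 0.9)  # apical/mid/basal
    line_half_length_px: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for hu in (self.air_hu, self.soft_tissue_hu, self.lung_hu,
                   self.trachea_hu, self.liver_hu):
            if not -1100.0 <= hu <= 3100.0:
                raise ValueError(f"compartment HU {hu} outside [-1100, 3100]")
        if self.edge_blur_sigma < 0 or self.noise_sd_ref < 0:
            raise ValueError("blur sigma and noise SD must be non-negative")
        if self.size < 64:
            raise ValueError("image size must be at least 64 px")

    @property
    def scale(self) -> float:
        return self.size / 512.0


@dataclass
class GroundTruth:
    """What the generator actually injected, for oracle-style comparisons."""

    edge_steepness: dict[str, float] = field(default_factory=dict)  # HU/mm
    compartment_hu: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    blur_sigma_px: float = 0.0
    seed_entropy: object = None


@dataclass
class DoseLevel:
    stack: list[CTImage]
    ground_truth: GroundTruth
    record: ScanRecord


# ---------------------------------------------------------------------------
# geometry helpers

def _interfaces(spec: PhantomSpec) -> list[dict]:
    """The 39 lung-to-pleura interface points across the 3-level stack.

    13 interfaces per level, alternating which side gets the extra line, at
    ellipse-parameter angles spread over the lateral/anterior/posterior arcs
    (never the mediastinal side).
    """
    out = []
    s = spec.scale
    for level_idx, level in enumerate(LEVELS):
        lscale = spec.level_scales[level_idx]
        a = _LUNG_SEMI[0] * s * lscale
        b = _LUNG_SEMI[1] * s * lscale
        n_left = 7 if level_idx % 2 == 0 else 6
        counts = {"left": n_left, "right": 13 - n_left}
        for side in ("left", "right"):
            cx, cy = (_LUNG_CENTERS[side][0] * s, _LUNG_CENTERS[side][1] * s)
            lo, hi = _ARCS_DEG[side]
            n = counts[side]
            for j in range(n):
                t = math.radians(lo + (hi - lo) * (j + 0.5) / n)
                px = cx + a * math.cos(t)
                py = cy + b * math.sin(t)
                normal = np.array([math.cos(t) / a, math.sin(t) / b])
                normal /= np.linalg.norm(normal)
                tangent = np.array([-normal[1], normal[0]])
                sin_t = math.sin(t)
                if sin_t < -0.5:
                    location = "anterior"
                elif sin_t > 0.5:
                    location = "posterior"
                else:
                    location = "lateral"
                out.append(
                    {
                        "interface_id": len(out),
                        "level": level,
                        "level_idx": level_idx,
                        "side": side,
                        "location": location,
                        "point": np.array([px, py]),
                        "normal": normal,
                        "tangent": tangent,
                    }
                )
    return out


def default_grid(spec: PhantomSpec | None = None) -> list[ProfileLine]:
    """The packaged default measurement grid: 39 interfaces x 12 replicates.

    Each interface gets 12 parallel line placements offset tangentially by
    a few pixels, for 468 measurement lines per scan.
    """
    spec = spec or PhantomSpec()
    h = spec.line_half_length_px
    lines = []
    for iface in _interfaces(spec):
        p, n_hat, t_hat = iface["point"], iface["normal"], iface["tangent"]
        for rep, offset in enumerate(REPLICATE_OFFSETS):
            shift = np.rint(offset * t_hat)
            start = np.rint(p - h * n_hat + shift).astype(int)
            end = np.rint(p + h * n_hat + shift).astype(int)
            lines.append(
                ProfileLine(
                    start=(int(start[0]), int(start[1])),
                    end=(int(end[0]), int(end[1])),
                    level=iface["level"],
                    side=iface["side"],
                    location=iface["location"],
                    replicate=rep,
                    interface_id=iface["interface_id"],
                )
            )
    return lines


def default_rois(spec: PhantomSpec | None = None) -> list[CircularROI]:
    """The packaged ROI protocol: trachea, liver, and 3 repeated air ROIs."""
    spec = spec or PhantomSpec()
    s = spec.scale
    return [
        CircularROI(center=(256 * s, 150 * s), radius=43 * s, tissue_label="trachea"),
        CircularROI(center=(256 * s, 382 * s), radius=43 * s, tissue_label="liver"),
        CircularROI(center=(176 * s, 50 * s), radius=45 * s, tissue_label="air"),
        CircularROI(center=(256 * s, 50 * s), radius=45 * s, tissue_label="air"),
        CircularROI(center=(336 * s, 50 * s), radius=45 * s, tissue_label="air"),
    ]


def _render_compartments(spec: PhantomSpec, level_scale: float = 1.0) -> np.ndarray:
    """Noiseless, unblurred compartment image (later shapes win overlaps)."""
    s = spec.scale
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size].astype(float)
    img = np.full((spec.size, spec.size), spec.air_hu)

    def ellipse(center, semi):
        return ((xx - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2 <= 1.0

    img[ellipse((_BODY_CENTER[0] * s, _BODY_CENTER[1] * s),
                (_BODY_SEMI[0] * s, _BODY_SEMI[1] * s))] = spec.soft_tissue_hu
    lung_semi = (_LUNG_SEMI[0] * s * level_scale, _LUNG_SEMI[1] * s * level_scale)
    for side in ("left", "right"):
        c = (_LUNG_CENTERS[side][0] * s, _LUNG_CENTERS[side][1] * s)
        img[ellipse(c, lung_semi)] = spec.lung_hu
    (tc, tr) = _TRACHEA
    img[ellipse((tc[0] * s, tc[1] * s), (tr * s, tr * s))] = spec.trachea_hu
    (lc, lr) = _LIVER
    img[ellipse((lc[0] * s, lc[1] * s), (lr * s, lr * s))] = spec.liver_hu
    return img


def _interface_steepness(
    blurred: np.ndarray, point: np.ndarray, normal: np.ndarray, spacing_mm: float,
    half_len_px: float,
) -> float:
    """Max |dHU/dl| along the interface normal, from dense resampling."""
    u = np.arange(-half_len_px, half_len_px, 0.02)
    xs = point[0] + u * normal[0]
    ys = point[1] + u * normal[1]
    values = map_coordinates(blurred, [ys, xs], order=3, mode="nearest")
    step_mm = 0.02 * spacing_mm
    return float(np.max(np.abs(np.diff(values))) / step_mm)


# ---------------------------------------------------------------------------
# generators

def generate_edge_image(
    spec: PhantomSpec,
    theta: tuple[float, float, float, float] = (0.0, 4.0, -800.0, 40.0),
    orientation_deg: float = 0.0,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CTImage, GroundTruth]:
    """A slice whose HU follows the logistic transition exactly.

    ``theta = (theta0, theta1, theta_begin, theta_end)``; the transition
    runs along the direction ``orientation_deg`` (0 = edge normal along +x)
    with theta0 measured in mm from the image centre.  Because the pixel
    values are the logistic model itself (plus optional noise), fitted
    steepness can be compared against the exact ``|theta1 (te - tb) / 4|``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    theta0, theta1, tb, te = theta
    phi = math.radians(orientation_deg)
    c = (spec.size - 1) / 2.0
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size].astype(float)
    # signed distance (mm) from the image-centre edge along the normal
    l = ((xx - c) * math.cos(phi) + (yy - c) * math.sin(phi)) * spec.spacing_mm
    img = logistic_model(l, theta0, theta1, tb, te)
    sd = spec.noise_sd_ref if noise_sd is None else noise_sd
    if sd > 0:
        img = img + rng.normal(0.0, sd, img.shape)
    truth = GroundTruth(
        edge_steepness={"edge": abs(theta1 * (te - tb) / 4.0)},
        compartment_hu={"begin": tb, "end": te},
        noise_sd=sd,
        blur_sigma_px=0.0,
        seed_entropy=spec.seed,
    )
    return CTImage(pixels=img, spacing_x=spec.spacing_mm, spacing_y=spec.spacing_mm), truth


def edge_measurement_grid(
    spec: PhantomSpec,
    orientation_deg: float = 0.0,
    n_interfaces: int = N_INTERFACES,
    n_replicates: int = N_REPLICATES,
) -> list[ProfileLine]:
    """Measurement lines crossing the synthetic edge of `generate_edge_image`.

    Lines run along the edge normal; interface positions are spread along
    the edge tangent so that (with a slightly tilted edge) the sampling
    phase relative to the pixel grid varies across lines.
    """
    phi = math.radians(orientation_deg)
    n_hat = np.array([math.cos(phi), math.sin(phi)])
    t_hat = np.array([-n_hat[1], n_hat[0]])
    c = (spec.size - 1) / 2.0
    center = np.array([c, c])
    h = spec.line_half_length_px
    span = spec.size / 3.0
    positions = np.linspace(-span, span, n_interfaces)
    offsets = np.arange(n_replicates) - (n_replicates - 1) / 2.0
    lines = []
    for i, pos in enumerate(positions):
        for rep, off in enumerate(offsets):
            p = center + (pos + off) * t_hat
            start = np.rint(p - h * n_hat).astype(int)
            end = np.rint(p + h * n_hat).astype(int)
            lines.append(
                ProfileLine(
                    start=(int(start[0]), int(start[1])),
                    end=(int(end[0]), int(end[1])),
                    level="mid",
                    side="left",
                    location="lateral",
                    replicate=rep,
                    interface_id=i,
                )
            )
    return lines


def generate_phantom_slice(
    spec: PhantomSpec,
    level: str = "mid",
    blur_sigma: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CTImage, GroundTruth]:
    """One phantom slice: compartments, Gaussian edge blur, seeded noise."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    rng = rng or np.random.default_rng(spec.seed)
    level_idx = LEVELS.index(level)
    sigma = spec.edge_blur_sigma if blur_sigma is None else blur_sigma
    sd = spec.noise_sd_ref if noise_sd is None else noise_sd

    clean = _render_compartments(spec, spec.level_scales[level_idx])
    blurred = gaussian_filter(clean, sigma) if sigma > 0 else clean

    truth = GroundTruth(
        compartment_hu={
            "air": spec.air_hu,
            "soft_tissue": spec.soft_tissue_hu,
            "lung": spec.lung_hu,
            "trachea": spec.trachea_hu,
            "liver": spec.liver_hu,
        },
        noise_sd=sd,
        blur_sigma_px=sigma,
        seed_entropy=spec.seed,
    )
    for iface in _interfaces(spec):
        if iface["level"] != level:
            continue
        truth.edge_steepness[str(iface["interface_id"])] = _interface_steepness(
            blurred, iface["point"], iface["normal"], spec.spacing_mm,
            spec.line_half_length_px,
        )
    pixels = blurred if sd == 0 else blurred + rng.normal(0.0, sd, blurred.shape)
    image = CTImage(
        pixels=pixels,
        spacing_x=spec.spacing_mm,
        spacing_y=spec.spacing_mm,
        metadata={"level": level, "noise_sd": sd, "blur_sigma_px": sigma},
    )
    return image, truth


def generate_phantom_stack(
    spec: PhantomSpec,
    blur_sigma: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CTImage], GroundTruth]:
    """The 3-level (apical/mid/basal) slice stack with merged ground truth."""
    rng = rng or np.random.default_rng(spec.seed)
    stack = []
    truth = GroundTruth(noise_sd=0.0, seed_entropy=spec.seed)
    for level in LEVELS:
        image, level_truth = generate_phantom_slice(
            spec, level=level, blur_sigma=blur_sigma, noise_sd=noise_sd, rng=rng
        )
        stack.append(image)
        truth.edge_steepness.update(level_truth.edge_steepness)
        truth.compartment_hu = level_truth.compartment_hu
        truth.noise_sd = level_truth.noise_sd
        truth.blur_sigma_px = level_truth.blur_sigma_px
    return stack, truth


def noise_ratio(spec: PhantomSpec, record: ScanRecord) -> float:
    """Noise SD multiplier relative to the reference level.

    1/sqrt(mAs) scaling combined with a configurable kVp penetration factor
    ``(reference_kvp / kvp) ** kvp_exponent``.
    """
    return (spec.reference_kvp / record.kvp) ** spec.kvp_exponent * math.sqrt(
        spec.reference_mas / record.mas
    )


def generate_dose_series(
    spec: PhantomSpec,
    settings: Sequence[ScanRecord],
    recon_blur_scale: float | None = None,
    shared_noise_field: bool = True,
) -> list[DoseLevel]:
    """One phantom stack per scan setting with dose-dependent noise and blur.

    Injected noise SD is ``noise_sd_ref * rho`` with
    ``rho = (ref_kvp/kvp)^e * sqrt(ref_mas/mas)``; the effective edge blur is
    ``edge_blur_sigma * sqrt(1 + recon_blur_scale * rho^2)`` so that edge
    sharpness rises with dose and plateaus, like a noise-adaptive
    reconstruction.  Seeding is deterministic from ``spec.seed``, so reruns
    are bit-identical.

    With ``shared_noise_field`` (default) all dose levels reuse the same
    unit-variance noise realization, scaled by each level's SD — common
    random numbers, so dose-to-quality curves vary only through the dose
    effect instead of resampling noise.  Set it False for independent noise
    per level.
    """
    if len(settings) < 2:
        raise ValueError("a dose series needs at least 2 scan settings")
    kappa = spec.recon_blur_scale if recon_blur_scale is None else recon_blur_scale
    root = np.random.SeedSequence(spec.seed)

    if shared_noise_field:
        rng = np.random.default_rng(root)
        clean = {
            level: _render_compartments(spec, spec.level_scales[i])
            for i, level in enumerate(LEVELS)
        }
        unit_noise = {
            level: rng.standard_normal((spec.size, spec.size)) for level in LEVELS
        }
        ifaces = _interfaces(spec)
        levels = []
        for record in settings:
            rho = noise_ratio(spec, record)
            sd = spec.noise_sd_ref * rho
            sigma = spec.edge_blur_sigma * math.sqrt(1.0 + kappa * rho**2)
            truth = GroundTruth(
                compartment_hu={
                    "air": spec.air_hu,
                    "soft_tissue": spec.soft_tissue_hu,
                    "lung": spec.lung_hu,
                    "trachea": spec.trachea_hu,
                    "liver": spec.liver_hu,
                },
                noise_sd=sd,
                blur_sigma_px=sigma,
                seed_entropy=spec.seed,
            )
            stack = []
            for level in LEVELS:
                blurred = gaussian_filter(clean[level], sigma) if sigma > 0 else clean[level]
                for iface in ifaces:
                    if iface["level"] != level:
                        continue
                    truth.edge_steepness[str(iface["interface_id"])] = (
                        _interface_steepness(
                            blurred, iface["point"], iface["normal"],
                            spec.spacing_mm, spec.line_half_length_px,
                        )
                    )
                stack.append(
                    CTImage(
                        pixels=blurred + sd * unit_noise[level],
                        spacing_x=spec.spacing_mm,
                        spacing_y=spec.spacing_mm,
                        metadata={"level": level, "noise_sd": sd, "blur_sigma_px": sigma},
                    )
                )
            levels.append(DoseLevel(stack=stack, ground_truth=truth, record=record))
        return levels

    seeds = root.spawn(len(settings))
    levels = []
    for child, record in zip(seeds, settings):
        rho = noise_ratio(spec, record)
        sd = spec.noise_sd_ref * rho
        sigma = spec.edge_blur_sigma * math.sqrt(1.0 + kappa * rho**2)
        rng = np.random.default_rng(child)
        stack, truth = generate_phantom_stack(
            spec, blur_sigma=sigma, noise_sd=sd, rng=rng
        )
        truth.seed_entropy = child.entropy
        levels.append(DoseLevel(stack=stack, ground_truth=truth, record=record))
    return levels


def default_scan_settings(phantom: str = "adult") -> list[ScanRecord]:
    """The packaged 13-level kVp/mA protocol for one phantom."""
    from .dosimetry import load_scan_records
    from importlib import resources

    with resources.as_file(
        resources.files("ctqa.data").joinpath("scan_settings.csv")
    ) as path:
        records = load_scan_records(path)
    selected = [r for r in records if r.phantom == phantom]
    if not selected:
        known = sorted({r.phantom for r in records})
        raise ValueError(f"unknown phantom {phantom!r}; known: {known}")
    return selected


# ---------------------------------------------------------------------------
# writers

def write_nifti(stack: Sequence[CTImage], path: str | os.PathLike) -> None:
    """Write a slice stack as a NIfTI volume (x, y, z order)."""
    import nibabel as nib

    data = np.stack([img.pixels.T for img in stack], axis=2)
    sx, sy = stack[0].spacing_x, stack[0].spacing_y
    affine = np.diag([sx, sy, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), os.fspath(path))


def write_ground_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=str)


def write_dicom(stack: Sequence[CTImage], directory: str | os.PathLike) -> None:
    """Write a slice stack as a minimal DICOM series (requires pydicom)."""
    try:
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM output requires the optional 'pydicom' package; "
            "use write_nifti instead"
        ) from exc

    os.makedirs(directory, exist_ok=True)
    study_uid, series_uid = generate_uid(), generate_uid()
    for k, img in enumerate(stack):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.PixelSpacing = [img.spacing_y, img.spacing_x]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows, ds.Columns = img.pixels.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        raw = np.clip(np.rint(img.pixels + 1024.0), 0, 65535).astype(np.uint16)
        ds.PixelData = raw.tobytes()
        ds.save_as(
            os.path.join(os.fspath(directory), f"slice_{k:03d}.dcm"),
            write_like_original=False,
        )
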