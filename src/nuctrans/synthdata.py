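"""Synthetic two-channel high-content-screening plates with ground truth.

Emulates the assay's imaging design — 384-well plates, several fields per
well, a nuclear-marker channel and a GFP reporter whose signal partitions
between nucleus and cytoplasm according to a true nuclear/cytoplasmic
mean-intensity ratio — so that every downstream stage (segmentation,
ring-region quantification, normalization, dose-response fitting) can be
tested against known truth without a microscope.

Geometry is deliberately simple: each cell is a nuclear disk inside a
concentric cell-body disk, which makes the cytoplasm-annulus intensity
analytically checkable. The per-cell ground truth *is* the pipeline's
read-out (the nuclear/ring mean-intensity ratio), so recovery tests are
direct.

The camera model is additive: constant background, per-pixel expected
photon counts, optional Gaussian point-spread blur, optional Poisson shot
noise and Gaussian read noise, then quantization to the sensor bit depth.
With all noise sources off the expected photon image is returned un-rounded,
so conservation and exact-ratio oracles hold to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .core import GFP_CHANNEL, NUCLEAR_CHANNEL, ImageField

GROUND_TRUTH_COLUMNS = [
    "plate",
    "well",
    "field",
    "cell",
    "row",
    "col",
    "nucleus_radius",
    "cell_radius",
    "true_ratio",
    "gfp_total",
    "touches_border",
]


@dataclass
class SceneSpec:
    """Cell geometry and placement for one field of view.

    Defaults mimic a 2x2-binned 2560x2160 sCMOS sensor (1080x1280 px at
    325 nm/px) seeded at screening density. ``n_cells_mean`` is the Poisson
    mean per field unless ``n_cells_poisson`` is off, in which case exactly
    that many placements are attempted. Placement is hard-core rejection
    sampling: no two accepted centers closer than ``min_center_distance``
    (default twice the median nucleus radius), and — unless ``clustered``
    is set — no two cell bodies may overlap at all, so the cytoplasm
    annulus of every cell is uncontaminated by its neighbors. ``clustered``
    drops the body-overlap constraint and is a deliberate segmentation
    stressor. If ``max_place_attempts`` tries fail for a cell it is skipped
    and the achieved count recorded — the generator never loops forever.
    """

    field_shape: tuple[int, int] = (1080, 1280)
    pixel_size_nm: float = 325.0
    n_cells_mean: float = 60.0
    n_cells_poisson: bool = True
    nucleus_radius_median: float = 12.0
    nucleus_radius_sigma_log: float = 0.15
    cell_radius_factor: float = 1.8
    min_center_distance: float | None = None
    clustered: bool = False
    allow_border_cells: bool = False
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        if self.nucleus_radius_median <= 0:
            raise ValueError("nucleus_radius_median must be > 0")
        if self.cell_radius_factor <= 1:
            raise ValueError("cell_radius_factor must be > 1")
        if self.n_cells_mean < 0:
            raise ValueError("n_cells_mean must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def spacing(self) -> float:
        if self.min_center_distance is not None:
            return float(self.min_center_distance)
        return 2.0 * self.nucleus_radius_median


@dataclass
class OpticsSpec:
    """Acquisition model: intensities, blur, noise and quantization."""

    background_level: float = 100.0
    nuclear_marker_intensity: float = 2000.0
    gfp_total_median: float = 5e5
    gfp_total_sigma_log: float = 0.3
    psf_sigma: float = 1.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be >= 0")
        if self.gfp_total_median <= 0 or self.nuclear_marker_intensity <= 0:
            raise ValueError("signal levels must be > 0")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def noiseless(self) -> bool:
        return (not self.shot_noise) and self.read_noise_sd == 0

    @classmethod
    def ideal(cls) -> "OpticsSpec":
        """Noise-free, blur-free, zero-background optics for exact oracles."""
        return cls(
            background_level=0.0,
            psf_sigma=0.0,
            read_noise_sd=0.0,
            shot_noise=False,
            gfp_total_sigma_log=0.0,
        )


@dataclass
class ResponseModel:
    """Ground-truth translocation response.

    ``kind="dose"``: true ratio r(c) = r0 * (1 + (f_max*partial_efficacy - 1)
    * c^h / (ec50^h + c^h)) — a Hill curve rising from the vehicle baseline
    ``r0`` toward ``r0 * f_max * partial_efficacy`` at saturation.
    ``partial_efficacy < 1`` emulates partial agonist-like ligands (RU-486
    style) that plateau below the full-agonist level.

    ``kind="time"``: r(t) = r0 * (1 + (f_max - 1) * (1 - exp(-t/tau))), a
    saturating time-course with rate constant ``tau`` minutes.

    ``cell_sigma_log`` is the log-normal dispersion of per-cell true ratios.
    ``well_sigma_log`` is the standard deviation of a bounded (log-uniform)
    replicate-well effect; it sets the assay window realized in plate QC —
    the defaults are chosen so Z' between vehicle and saturating-agonist
    wells sits in the 0.5–0.8 screening band (see docs/methods.md). Both
    are tunable, not measured quantities.
    """

    kind: str = "dose"
    r0: float = 0.5
    f_max: float = 4.0
    ec50: float = 3.0
    hill: float = 1.0
    tau: float = 45.0
    partial_efficacy: float = 1.0
    cell_sigma_log: float = 0.15
    well_sigma_log: float = 0.065

    def __post_init__(self) -> None:
        if self.kind not in ("dose", "time"):
            raise ValueError("kind must be 'dose' or 'time'")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if self.f_max < 1:
            raise ValueError("f_max must be >= 1")
        if self.ec50 <= 0 or self.tau <= 0 or self.hill <= 0:
            raise ValueError("ec50, tau and hill must be > 0")
        if not (0 < self.partial_efficacy <= 1):
            raise ValueError("partial_efficacy must be in (0, 1]")
        if self.f_max * self.partial_efficacy < 1:
            raise ValueError(
                "f_max * partial_efficacy must be >= 1: the plateau cannot "
                "fall below the vehicle baseline in this response model"
            )


def true_ratio_from_dose(model: ResponseModel, conc):
    """True nuclear/cytoplasmic ratio at concentration ``conc`` (nM)."""
    if model.kind != "dose":
        raise ValueError("model kind is not 'dose'")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    top_gain = model.f_max * model.partial_efficacy - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        occ = np.where(
            c > 0, c**model.hill / (model.ec50**model.hill + c**model.hill), 0.0
        )
    out = model.r0 * (1.0 + top_gain * occ)
    return float(out) if np.isscalar(conc) else out


def true_ratio_from_time(model: ResponseModel, t):
    """True nuclear/cytoplasmic ratio after ``t`` minutes of treatment."""
    if model.kind != "time":
        raise ValueError("model kind is not 'time'")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("time must be >= 0")
    out = model.r0 * (1.0 + (model.f_max - 1.0) * (1.0 - np.exp(-tt / model.tau)))
    return float(out) if np.isscalar(t) else out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _place_cells(scene: SceneSpec, rng: np.random.Generator):
    """Hard-core rejection sampling of cell centers; bounded attempts."""
    if scene.n_cells_poisson:
        n_req = int(rng.poisson(scene.n_cells_mean))
    else:
        n_req = int(round(scene.n_cells_mean))
    rows, cols = scene.field_shape
    placed: list[tuple[float, float, float, float, bool]] = []
    for _ in range(n_req):
        rn = scene.nucleus_radius_median * math.exp(
            rng.normal(0.0, scene.nucleus_radius_sigma_log)
        )
        rc = rn * scene.cell_radius_factor
        for _attempt in range(scene.max_place_attempts):
            if scene.allow_border_cells:
                r = rng.uniform(0, rows)
                c = rng.uniform(0, cols)
            else:
                margin = rc + 1.0
                if 2 * margin >= rows or 2 * margin >= cols:
                    break
                r = rng.uniform(margin, rows - margin)
                c = rng.uniform(margin, cols - margin)
            if all(
                (r - pr) ** 2 + (c - pc) ** 2
                >= max(
                    scene.spacing,
                    0.0 if scene.clustered else rc + prc + 1.0,
                )
                ** 2
                for pr, pc, prn, prc, _t in placed
            ):
                touches = (
                    r - rc < 0 or c - rc < 0 or r + rc > rows - 1 or c + rc > cols - 1
                )
                placed.append((r, c, rn, rc, touches))
                break
    return n_req, placed


def _cell_masks(shape, r, c, rn, rc):
    """Bounding-box slices and (nucleus, annulus) boolean masks for one cell."""
    rows, cols = shape
    r0 = max(int(math.floor(r - rc - 1)), 0)
    r1 = min(int(math.ceil(r + rc + 2)), rows)
    c0 = max(int(math.floor(c - rc - 1)), 0)
    c1 = min(int(math.ceil(c + rc + 2)), cols)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    nmask = d2 <= rn**2
    amask = (d2 <= rc**2) & ~nmask
    return (slice(r0, r1), slice(c0, c1)), nmask, amask


def generate_field(
    scene: SceneSpec,
    optics: OpticsSpec,
    true_ratio: float,
    rng_seed,
    *,
    ratio_sigma_log: float = 0.0,
    plate: str = "SIM",
    well: str = "A01",
    field_index: int = 0,
    timepoint: float | None = None,
) -> tuple[ImageField, pd.DataFrame]:
    """Render one field and return it with its ground-truth table.

    Each cell's GFP is distributed so that the expected nuclear mean over
    the expected cytoplasm-annulus mean equals the cell's true ratio while
    the expected GFP summed over the cell body equals its drawn total.
    With ``ratio_sigma_log > 0`` per-cell ratios are log-normal around
    ``true_ratio`` (median).
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    rng = _as_rng(rng_seed)
    rows, cols = scene.field_shape
    nuc_img = np.full((rows, cols), float(optics.background_level))
    gfp_img = np.full((rows, cols), float(optics.background_level))

    n_req, placed = _place_cells(scene, rng)
    records = []
    for i, (r, c, rn, rc, touches) in enumerate(placed):
        ratio = true_ratio
        if ratio_sigma_log > 0:
            ratio = true_ratio * math.exp(rng.normal(0.0, ratio_sigma_log))
        gfp_total = optics.gfp_total_median
        if optics.gfp_total_sigma_log > 0:
            gfp_total *= math.exp(rng.normal(0.0, optics.gfp_total_sigma_log))
        sl, nmask, amask = _cell_masks((rows, cols), r, c, rn, rc)
        n_nuc, n_ann = int(nmask.sum()), int(amask.sum())
        u_cyt = gfp_total / (ratio * n_nuc + n_ann) if (n_nuc + n_ann) else 0.0
        gfp_img[sl][nmask] += ratio * u_cyt
        gfp_img[sl][amask] += u_cyt
        nuc_img[sl][nmask] += optics.nuclear_marker_intensity
        records.append(
            {
                "plate": plate,
                "well": well,
                "field": field_index,
                "cell": i,
                "row": r,
                "col": c,
                "nucleus_radius": rn,
                "cell_radius": rc,
                "true_ratio": ratio,
                "gfp_total": gfp_total,
                "touches_border": touches,
            }
        )

    channels = {}
    saturation = {}
    for name, img in ((NUCLEAR_CHANNEL, nuc_img), (GFP_CHANNEL, gfp_img)):
        if optics.psf_sigma > 0:
            img = gaussian_filter(img, optics.psf_sigma)
        if optics.shot_noise:
            img = rng.poisson(np.maximum(img, 0)).astype(float)
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, img.shape)
        if not optics.noiseless:
            img = np.clip(np.rint(img), 0, optics.max_count)
        saturation[name] = float(np.mean(img >= optics.max_count))
        channels[name] = img

    gt = pd.DataFrame.from_records(records, columns=GROUND_TRUTH_COLUMNS)
    field_obj = ImageField(
        channels=channels,
        pixel_size_nm=scene.pixel_size_nm,
        plate=plate,
        well=well,
        field_index=field_index,
        timepoint=timepoint,
        metadata={
            "n_cells_requested": n_req,
            "n_cells_placed": len(placed),
            "saturation_fraction": saturation,
        },
    )
    return field_obj, gt


def _well_base_ratio(model: ResponseModel, well_spec) -> float:
    if model.kind == "dose":
        if well_spec.concentration is None:
            raise ValueError(
                f"well {well_spec.well}: layout gives no concentration but the "
                "response model is dose-kind"
            )
        return true_ratio_from_dose(model, well_spec.concentration)
    if well_spec.timepoint is None:
        raise ValueError(
            f"well {well_spec.well}: layout gives no timepoint but the "
            "response model is time-kind"
        )
    return true_ratio_from_time(model, well_spec.timepoint)


@dataclass
class SimulatedPlate:
    """In-memory simulated plate: rendered fields plus ground truth."""

    fields: list[ImageField]
    ground_truth: pd.DataFrame
    layout: object
    well_true_ratio: dict[str, float] = field(default_factory=dict)


def simulate_plate(
    layout,
    scene: SceneSpec | None = None,
    optics: OpticsSpec | None = None,
    model: ResponseModel | None = None,
    rng_seed: int = 0,
) -> SimulatedPlate:
    """Render every field of a plate layout in memory, deterministically.

    One root seed; hierarchical per-well and per-field substreams
    (``SeedSequence(root, spawn_key=...)``) so any single field is
    reproducible in isolation.
    """
    scene = scene or SceneSpec()
    optics = optics or OpticsSpec()
    model = model or ResponseModel()
    fields: list[ImageField] = []
    gts: list[pd.DataFrame] = []
    well_ratio: dict[str, float] = {}
    for wi, wspec in enumerate(layout.wells):
        base = _well_base_ratio(model, wspec)
        well_rng = np.random.default_rng(
            np.random.SeedSequence(rng_seed, spawn_key=(wi,))
        )
        ratio = base
        if model.well_sigma_log > 0:
            # bounded log-uniform well effect with sd = well_sigma_log
            half_width = model.well_sigma_log * math.sqrt(3.0)
            ratio = base * math.exp(well_rng.uniform(-half_width, half_width))
        well_ratio[wspec.well] = ratio
        for fi in range(layout.fields_per_well):
            fseed = np.random.SeedSequence(rng_seed, spawn_key=(wi, fi + 1))
            fld, gt = generate_field(
                scene,
                optics,
                ratio,
                np.random.default_rng(fseed),
                ratio_sigma_log=model.cell_sigma_log,
                plate=layout.plate,
                well=wspec.well,
                field_index=fi,
                timepoint=wspec.timepoint if model.kind == "time" else None,
            )
            fields.append(fld)
            gts.append(gt)
    gt_all = (
        pd.concat(gts, ignore_index=True)
        if gts
        else pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    )
    return SimulatedPlate(
        fields=fields, ground_truth=gt_all, layout=layout, well_true_ratio=well_ratio
    )


def to_uint16(img: np.ndarray, max_count: int = 65535) -> np.ndarray:
    return np.clip(np.rint(img), 0, max_count).astype(np.uint16)


def write_plate(sim: SimulatedPlate, out_dir) -> tuple[Path, Path]:
    """Write a simulated plate to disk: one 16-bit TIFF per channel per field,
    a manifest CSV and the ground-truth CSV. Returns (manifest, ground_truth)
    paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for fld in sim.fields:
        for ch, img in fld.channels.items():
            fname = f"{fld.plate}_{fld.well}_F{fld.field_index}_{ch}.tif"
            tifffile.imwrite(out / fname, to_uint16(img))
            rows.append(
                {
                    "plate": fld.plate,
                    "well": fld.well,
                    "field": fld.field_index,
                    "channel": ch,
                    "path": fname,
                }
            )
    manifest = pd.DataFrame(rows, columns=["plate", "well", "field", "channel", "path"])
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    gt_path = out / "ground_truth.csv"
    sim.ground_truth.to_csv(gt_path, index=False)
    return manifest_path, gt_path


def generate_plate(
    layout,
    scene: SceneSpec | None = None,
    optics: OpticsSpec | None = None,
    model: ResponseModel | None = None,
    rng_seed: int = 0,
    out_dir=None,
) -> SimulatedPlate:
    """Simulate a plate and, if ``out_dir`` is given, write images + tables."""
    sim = simulate_plate(layout, scene, optics, model, rng_seed)
    if out_dir is not None:
        write_plate(sim, out_dir)
    return sim
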