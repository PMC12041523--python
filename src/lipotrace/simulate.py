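"""Synthetic data with known ground truth for every downstream stage.

Four generators emulate the three input kinds of the study setting:

* :func:`gen_coloc_field` — two-channel lipid-aggregate images (Bodipy neutral
  lipid + PLIN2) with controllable per-cell coupling, for the co-localization
  classifier.
* :func:`gen_raft_field` — CT-B membrane puncta with controllable density and
  angular clustering, for the raft abundance/clustering metrics.
* :func:`gen_ctv_events` — dye-dilution (CellTrace Violet) event tables:
  log-normal generation mixtures with 2-fold dilution per division.
* :func:`gen_lipid_table` — lipid species intensity tables with class-matched
  internal standards and seeded group fold-changes.

Cells are non-overlapping disks placed by rejection sampling.  The camera
model is Poisson shot noise on (signal + background) followed by additive
Gaussian read noise, with 16-bit saturation clipping.  When all noise is
disabled the float-valued ideal image is returned unchanged so noise-free
identities hold exactly.  The point-spread function is an isotropic Gaussian.
Each generator consumes a single explicit seed; identical seeds and
parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rois import FieldImage


class DegenerateGeometryError(RuntimeError):
    """Non-overlapping cell placement failed after bounded retries."""


_MAX_PLACE_RETRIES = 1000


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class ColocSimParams:
    """Settings for two-channel (Bodipy / PLIN2) lipid-aggregate fields.

    ``coloc_fraction`` is the probability that a cell's aggregates carry
    PLIN2 signal coupled linearly (gain ``coupling_slope``) to Bodipy.
    """

    field_shape: tuple[int, int] = (512, 512)
    n_cells: int = 25
    cell_radius: float = 12.0
    aggregates_per_cell: tuple[int, int] = (2, 5)
    aggregate_radius: float = 2.0
    coloc_fraction: float = 1.0
    coupling_slope: float = 0.8
    psf_sigma: float = 1.0
    background: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0
    membrane_intensity: float = 400.0
    aggregate_intensity: tuple[float, float] = (500.0, 1000.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.cell_radius <= 0 or self.aggregate_radius <= 0:
            raise ValueError("radii must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        lo, hi = self.aggregates_per_cell
        if lo < 0 or hi < lo:
            raise ValueError("aggregates_per_cell must be a non-negative range")


@dataclass
class RaftSimParams:
    """Settings for CT-B membrane-puncta fields.

    ``clustering`` in [0, 1] concentrates puncta angularly: 0 places them
    uniformly around the membrane annulus, 1 confines them to one contiguous
    arc of half-width ``arc_halfwidth_rad``.
    """

    field_shape: tuple[int, int] = (512, 512)
    n_cells: int = 25
    cell_radius: float = 12.0
    puncta_per_cell: int = 8
    puncta_intensity: float = 800.0
    clustering: float = 0.0
    annulus_fraction: float = 0.85
    arc_halfwidth_rad: float = 0.15
    psf_sigma: float = 1.0
    background: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0
    membrane_intensity: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must lie in [0, 1]")
        if self.puncta_per_cell < 0:
            raise ValueError("puncta_per_cell must be non-negative")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")


@dataclass
class CtvSimParams:
    """Settings for dye-dilution (CTV) event tables.

    ``generation_fractions`` are cell-level fractions over generations
    0..G summing to 1; generation ``i`` events are drawn log-normal with
    log10 mean ``undivided_log10_mean - i * log10(dilution_per_division)``.
    """

    n_events: int = 20_000
    generation_fractions: tuple[float, ...] = (1.0,)
    undivided_log10_mean: float = 4.5
    log10_sd: float = 0.05
    dilution_per_division: float = 2.0
    autofluorescence_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.asarray(self.generation_fractions, dtype=float)
        if np.any(frac < 0):
            raise ValueError("generation fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("generation fractions must sum to 1 (±1e-9)")
        if self.dilution_per_division <= 1.0:
            raise ValueError("dilution_per_division must exceed 1")
        if self.log10_sd < 0:
            raise ValueError("log10_sd must be non-negative")


@dataclass
class LipidSimParams:
    """Settings for lipid intensity tables with class-matched standards.

    ``group_log2fc`` seeds per-species log2 fold-changes of the second group
    over the first; unlisted species have fold-change 0.  ``cv`` is the
    log-normal coefficient of variation of measured intensities.
    """

    classes: tuple[str, ...] = ("PC", "TAG", "SM", "CE", "PE")
    species_per_class: int = 6
    n_samples_per_group: int = 6
    group_names: tuple[str, str] = ("HD", "CLL")
    group_log2fc: dict[str, float] = field(default_factory=dict)
    cv: float = 0.1
    is_intensity: float = 5e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.species_per_class < 1 or self.n_samples_per_group < 1:
            raise ValueError("species_per_class and n_samples_per_group must be >= 1")


# --------------------------------------------------------------------------
# ground-truth containers
# --------------------------------------------------------------------------


@dataclass
class ColocGroundTruth:
    """Truth for one simulated co-localization field."""

    cell_centers: np.ndarray  # (n, 2) float (row, col)
    cell_radius: float
    coupled: np.ndarray  # (n,) bool
    aggregate_pixels: list[np.ndarray]  # per cell, (m, 2) int
    ideal: dict[str, np.ndarray]  # pre-blur, pre-noise channels

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)


@dataclass
class RaftGroundTruth:
    """Truth for one simulated raft field."""

    cell_centers: np.ndarray
    cell_radius: float
    puncta_coords: list[np.ndarray]  # per cell, (k, 2) float (row, col)
    ideal: dict[str, np.ndarray]

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)


@dataclass
class CtvGroundTruth:
    """Per-event true generation labels and the seeded fractions."""

    generations: np.ndarray  # (n,) int
    generation_fractions: np.ndarray


@dataclass
class LipidGroundTruth:
    """True amounts and seeded fold-changes behind a simulated lipid table."""

    true_nmol: pd.DataFrame  # samples x species
    log2fc: dict[str, float]
    species_class: dict[str, str]


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_cells: int,
    radius: float,
    margin: float,
) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers fully inside the field."""
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n_cells > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise DegenerateGeometryError("field too small for the requested cell radius")
    centers: list[np.ndarray] = []
    # 6-px buffer keeps blurred/smoothed masks of neighbours from merging
    min_sep2 = (2.0 * radius + 6.0) ** 2
    for _ in range(n_cells):
        for _attempt in range(_MAX_PLACE_RETRIES):
            cand = np.array(
                [rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)]
            )
            if all(np.sum((cand - c) ** 2) >= min_sep2 for c in centers):
                centers.append(cand)
                break
        else:
            raise DegenerateGeometryError(
                f"could not place cell {len(centers)} without overlap after "
                f"{_MAX_PLACE_RETRIES} retries"
            )
    return np.array(centers).reshape(n_cells, 2)


def _disk_pixels(
    center: np.ndarray, radius: float, shape: tuple[int, int]
) -> np.ndarray:
    """Integer (row, col) pixels within ``radius`` of ``center``."""
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.column_stack([rr[inside], cc[inside]])


def _apply_optics_and_noise(
    ideal: np.ndarray,
    psf_sigma: float,
    shot_noise: bool,
    read_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian PSF blur, then Poisson + Gaussian read noise with uint16 clip.

    Noise-free output stays float so exact identities survive; noisy output is
    quantized like a 16-bit camera export.
    """
    img = ndimage.gaussian_filter(ideal, psf_sigma) if psf_sigma > 0 else ideal.copy()
    if not shot_noise and read_noise_sd == 0:
        return img
    if shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def gen_coloc_field(params: ColocSimParams) -> tuple[FieldImage, ColocGroundTruth]:
    """Simulate one field with membrane, Bodipy, and PLIN2 channels.

    In coupled cells the pre-noise PLIN2 at aggregate pixels equals
    ``coupling_slope * bodipy + background``; in uncoupled cells it is
    background only.  PSF blur then per-channel noise are applied on top.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.field_shape)
    margin = params.cell_radius + 4.0 * params.psf_sigma + 2.0
    centers = _place_cells(rng, shape, params.n_cells, params.cell_radius, margin)
    coupled = rng.random(params.n_cells) < params.coloc_fraction

    membrane = np.full(shape, params.background, dtype=float)
    bodipy = np.full(shape, params.background, dtype=float)
    plin2 = np.full(shape, params.background, dtype=float)

    agg_pixels: list[np.ndarray] = []
    lo, hi = params.aggregates_per_cell
    for i in range(params.n_cells):
        cell_pix = _disk_pixels(centers[i], params.cell_radius, shape)
        membrane[cell_pix[:, 0], cell_pix[:, 1]] += params.membrane_intensity

        n_agg = int(rng.integers(lo, hi + 1))
        pix_sets = []
        for _ in range(n_agg):
            # aggregate center uniform in the cell interior
            while True:
                offset = rng.uniform(-1, 1, size=2) * (
                    params.cell_radius - params.aggregate_radius
                )
                if np.sum(offset**2) <= (
                    params.cell_radius - params.aggregate_radius
                ) ** 2:
                    break
            amp = rng.uniform(*params.aggregate_intensity)
            pix = _disk_pixels(centers[i] + offset, params.aggregate_radius, shape)
            bodipy[pix[:, 0], pix[:, 1]] += amp
            pix_sets.append(pix)
        pix_all = (
            np.unique(np.concatenate(pix_sets), axis=0)
            if pix_sets
            else np.empty((0, 2), dtype=int)
        )
        agg_pixels.append(pix_all)
        if coupled[i] and len(pix_all):
            rr, cc = pix_all[:, 0], pix_all[:, 1]
            plin2[rr, cc] = params.coupling_slope * bodipy[rr, cc] + params.background

    ideal = {"membrane": membrane, "bodipy": bodipy, "plin2": plin2}
    channels = {
        name: _apply_optics_and_noise(
            arr, params.psf_sigma, params.shot_noise, params.read_noise_sd, rng
        )
        for name, arr in ideal.items()
    }
    truth = ColocGroundTruth(
        cell_centers=centers,
        cell_radius=params.cell_radius,
        coupled=coupled,
        aggregate_pixels=agg_pixels,
        ideal=ideal,
    )
    return FieldImage(channels), truth


def gen_raft_field(params: RaftSimParams) -> tuple[FieldImage, RaftGroundTruth]:
    """Simulate one field with membrane and CT-B channels.

    Puncta sit on the membrane annulus at radial fraction
    ``annulus_fraction``; their angular spread narrows monotonically with
    ``clustering``, down to one arc of half-width ``arc_halfwidth_rad``.
    Total pre-noise puncta signal is independent of clustering.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.field_shape)
    margin = params.cell_radius + 4.0 * params.psf_sigma + 2.0
    centers = _place_cells(rng, shape, params.n_cells, params.cell_radius, margin)

    membrane = np.full(shape, params.background, dtype=float)
    ctb = np.full(shape, params.background, dtype=float)

    halfwidth = (
        1.0 - params.clustering
    ) * np.pi + params.clustering * params.arc_halfwidth_rad
    rad = params.annulus_fraction * params.cell_radius

    puncta_coords: list[np.ndarray] = []
    for i in range(params.n_cells):
        cell_pix = _disk_pixels(centers[i], params.cell_radius, shape)
        membrane[cell_pix[:, 0], cell_pix[:, 1]] += params.membrane_intensity

        theta0 = rng.uniform(0, 2 * np.pi)
        angles = theta0 + rng.uniform(
            -halfwidth, halfwidth, size=params.puncta_per_cell
        )
        coords = centers[i] + rad * np.column_stack(
            [np.sin(angles), np.cos(angles)]
        )
        puncta_coords.append(coords)
        for rc in coords:
            ctb[int(round(rc[0])), int(round(rc[1]))] += params.puncta_intensity

    ideal = {"membrane": membrane, "ctb": ctb}
    channels = {
        name: _apply_optics_and_noise(
            arr, params.psf_sigma, params.shot_noise, params.read_noise_sd, rng
        )
        for name, arr in ideal.items()
    }
    truth = RaftGroundTruth(
        cell_centers=centers,
        cell_radius=params.cell_radius,
        puncta_coords=puncta_coords,
        ideal=ideal,
    )
    return FieldImage(channels), truth


def gen_ctv_events(params: CtvSimParams) -> tuple[pd.DataFrame, CtvGroundTruth]:
    """Simulate a dye-dilution event table.

    Returns a one-column ``DataFrame`` (column ``"ctv"``) plus per-event true
    generations.  Intensity for generation ``i`` is 10**N(mu0 - i*log10(d),
    sigma) with the autofluorescence floor added linearly.
    """
    rng = np.random.default_rng(params.seed)
    frac = np.asarray(params.generation_fractions, dtype=float)
    frac = frac / frac.sum()  # exact renormalization within the 1e-9 tolerance
    gens = rng.choice(len(frac), size=params.n_events, p=frac)
    mu = params.undivided_log10_mean - gens * np.log10(params.dilution_per_division)
    log10_i = rng.normal(mu, params.log10_sd) if params.log10_sd > 0 else mu
    intensity = 10.0**log10_i + params.autofluorescence_floor
    events = pd.DataFrame({"ctv": intensity})
    return events, CtvGroundTruth(generations=gens, generation_fractions=frac)


def gen_lipid_table(params: LipidSimParams):
    """Simulate a samples x species intensity table with internal standards.

    Every class gets one internal-standard column at a known spiked amount
    (``data/internal_standards.csv`` amounts when the class is listed there,
    1 nmol otherwise) and intensity ``is_intensity`` scaled by the per-sample
    gain.  Species intensities are log-normal around class baselines scaled
    by the seeded group fold-changes; the per-sample gain cancels in the
    internal-standard ratio, emulating loading/instrument drift.

    Returns ``(LipidTable, LipidGroundTruth)``.
    """
    from .lipidomics import LipidTable, load_standards

    for sp in params.group_log2fc:
        cls = sp.split("_")[0]
        if cls not in params.classes:
            raise ValueError(
                f"fold-change species {sp!r} does not belong to a simulated class"
            )

    rng = np.random.default_rng(params.seed)
    standards = load_standards()
    sigma = np.sqrt(np.log(1.0 + params.cv**2))  # log-normal CV -> log sd

    g1, g2 = params.group_names
    samples = [f"{g1}_{i+1}" for i in range(params.n_samples_per_group)] + [
        f"{g2}_{i+1}" for i in range(params.n_samples_per_group)
    ]
    groups = pd.Series(
        [g1] * params.n_samples_per_group + [g2] * params.n_samples_per_group,
        index=samples,
        name="group",
    )
    n_total = len(samples)
    gain = np.exp(rng.normal(0.0, 0.2, size=n_total))  # per-sample global gain

    species_class: dict[str, str] = {}
    intensities: dict[str, np.ndarray] = {}
    true_nmol: dict[str, np.ndarray] = {}
    log2fc_full: dict[str, float] = {}

    for cls in params.classes:
        if cls in standards.classes:
            std_name, std_nmol = standards.standard_for(cls)
        else:
            std_name, std_nmol = f"{cls}(IS)", 1.0
        # response factor: measured intensity per nmol for this class
        response = params.is_intensity / std_nmol
        species_class[std_name] = cls
        intensities[std_name] = params.is_intensity * gain
        class_base = rng.uniform(0.05, 2.0)  # nmol scale of endogenous species
        for j in range(params.species_per_class):
            name = f"{cls}_sp{j+1}"
            base = class_base * rng.uniform(0.5, 2.0)
            lfc = float(params.group_log2fc.get(name, 0.0))
            log2fc_full[name] = lfc
            amt = np.where(groups.values == g2, base * 2.0**lfc, base)
            noise = (
                np.exp(rng.normal(0.0, sigma, size=n_total)) if params.cv > 0 else 1.0
            )
            species_class[name] = cls
            intensities[name] = amt * response * gain * noise
            true_nmol[name] = amt

    protein_ug = pd.Series(
        rng.uniform(40.0, 120.0, size=n_total), index=samples, name="protein_ug"
    )
    table = LipidTable(
        intensities=pd.DataFrame(intensities, index=samples),
        species_class=pd.Series(species_class, name="class"),
        groups=groups,
        protein_ug=protein_ug,
    )
    truth = LipidGroundTruth(
        true_nmol=pd.DataFrame(true_nmol, index=samples),
        log2fc=log2fc_full,
        species_class={k: v for k, v in species_class.items()},
    )
    return table, truth
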