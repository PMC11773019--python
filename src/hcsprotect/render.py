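"""Synthetic fluorescence microscopy of stained nuclei.

Nuclei are rendered as 2-D anisotropic Gaussian blobs on a dark
background.  Healthy nuclei are large and moderately bright; dying
(pyknotic) nuclei are rendered strictly brighter and smaller, with extra
intra-nuclear texture heterogeneity — the intensity/morphology contrast
an apoptosis classifier relies on.  Shot noise (approximated as Gaussian
with variance equal to the signal) and Gaussian read noise are added,
and images are quantised to 16-bit grayscale.

An optional second channel marks a configurable fraction of nuclei as
transfected with a red-labelled mimic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthdata import GroundTruth


@dataclass(frozen=True)
class ImagingParams:
    """Renderer configuration for one well image.

    Intensities are arbitrary 16-bit units.  ``healthy_sigma_px`` is the
    mean Gaussian radius of a healthy nucleus; the effective nucleus
    radius used for packing is ``2.5 * sigma``.  The dying template must
    be strictly brighter (``dying_intensity_mult > 1``) and smaller
    (``dying_sigma_mult < 1``) than the healthy one.
    """

    image_size: int = 300
    nuclei_per_well_mean: float = 80.0
    nuclei_count_fixed: int | None = None  # overrides the Poisson draw
    healthy_intensity: float = 1200.0
    healthy_sigma_px: float = 4.0
    dying_intensity_mult: float = 2.2
    dying_sigma_mult: float = 0.50
    dying_texture_cv: float = 0.30
    intensity_jitter_cv: float = 0.08
    sigma_jitter_cv: float = 0.05
    anisotropy_min: float = 0.80  # minor/major axis ratio lower bound
    background_level: float = 100.0
    read_noise_sd: float = 20.0
    overlap_fraction: float = 0.0
    transfected_fraction: float = 0.5
    red_intensity: float = 800.0
    red_background: float = 50.0
    red_noise_sd: float = 10.0

    def validate(self) -> None:
        if self.dying_intensity_mult <= 1.0:
            raise ValueError("dying nuclei must be strictly brighter than healthy")
        if not 0.0 < self.dying_sigma_mult < 1.0:
            raise ValueError("dying nuclei must be strictly smaller than healthy")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must lie in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image too small to host nuclei")


@dataclass
class PlantedNucleus:
    """Ground-truth record of one rendered nucleus."""

    center: tuple[float, float]  # (row, col)
    sigma: float
    dying: bool
    transfected: bool = False


@dataclass
class RenderedWell:
    image: np.ndarray                 # uint16, nuclear-stain channel
    red_image: np.ndarray | None      # uint16 transfection-marker channel
    nuclei: list[PlantedNucleus] = field(default_factory=list)

    @property
    def n_dying(self) -> int:
        return sum(n.dying for n in self.nuclei)

    @property
    def labels(self) -> list[bool]:
        return [n.dying for n in self.nuclei]


def _place_centers(n: int, size: int, radii: np.ndarray, overlap: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Random sequential placement with a minimum pairwise distance.

    Raises with a packing diagnostic when the requested count cannot be
    placed at the stated overlap fraction.
    """
    centers = np.empty((0, 2))
    placed_r: list[float] = []
    margin = radii.max() + 2.0
    low, high = margin, size - margin
    if high <= low:
        raise ValueError(f"image of size {size} cannot host nuclei of radius "
                         f"{radii.max():.1f} inside the border margin")
    max_attempts = 400 * max(n, 1)
    attempts = 0
    for i in range(n):
        r_i = radii[i]
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {n} nuclei in a {size}x{size} image at "
                    f"overlap fraction {overlap:.2f}: packed {i} after "
                    f"{max_attempts} attempts; reduce the count or allow overlap")
            cand = rng.uniform(low, high, size=2)
            if centers.shape[0]:
                min_d = (np.asarray(placed_r) + r_i) * (1.0 - overlap)
                d = np.hypot(*(centers - cand).T)
                if np.any(d < min_d):
                    continue
            centers = np.vstack([centers, cand])
            placed_r.append(r_i)
            break
    return centers


def _paint_gaussian(canvas: np.ndarray, center: np.ndarray, amplitude: float,
                    sigma_r: float, sigma_c: float, theta: float,
                    texture_cv: float, rng: np.random.Generator) -> None:
    """Add one rotated anisotropic Gaussian blob to the canvas in place."""
    size = canvas.shape[0]
    ext = int(np.ceil(4 * max(sigma_r, sigma_c)))
    r0, c0 = center
    rlo, rhi = max(0, int(r0) - ext), min(size, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(size, int(c0) + ext + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    blob = amplitude * np.exp(-0.5 * ((u / sigma_r) ** 2 + (v / sigma_c) ** 2))
    if texture_cv > 0:
        speckle = 1.0 + texture_cv * rng.standard_normal(blob.shape)
        blob *= np.clip(speckle, 0.0, None)
    canvas[rlo:rhi, clo:chi] += blob


def render_from_positions(
    centers: np.ndarray,
    dying: np.ndarray,
    params: ImagingParams,
    seed: int = 0,
    *,
    with_red: bool = False,
    transfected: np.ndarray | None = None,
) -> RenderedWell:
    """Render nuclei at explicit positions (row, col) with given labels."""
    params.validate()
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        centers = centers.reshape(0, 2)
    dying = np.asarray(dying, dtype=bool)
    n = centers.shape[0]
    if dying.shape[0] != n:
        raise ValueError("labels and centers disagree in length")
    if transfected is None:
        transfected = (rng.random(n) < params.transfected_fraction) if with_red \
            else np.zeros(n, dtype=bool)

    canvas = np.zeros((params.image_size, params.image_size))
    red = np.zeros_like(canvas) if with_red else None
    nuclei: list[PlantedNucleus] = []
    for i in range(n):
        base_sigma = params.healthy_sigma_px * max(
            0.2, 1.0 + params.sigma_jitter_cv * rng.standard_normal())
        amp = params.healthy_intensity * max(
            0.1, 1.0 + params.intensity_jitter_cv * rng.standard_normal())
        texture = 0.0
        if dying[i]:
            base_sigma *= params.dying_sigma_mult
            amp *= params.dying_intensity_mult
            texture = params.dying_texture_cv
        ratio = rng.uniform(params.anisotropy_min, 1.0)
        theta = rng.uniform(0, np.pi)
        _paint_gaussian(canvas, centers[i], amp, base_sigma, base_sigma * ratio,
                        theta, texture, rng)
        if with_red and transfected[i]:
            _paint_gaussian(red, centers[i], params.red_intensity,
                            base_sigma * 1.3, base_sigma * 1.3, 0.0, 0.0, rng)
        nuclei.append(PlantedNucleus(center=tuple(centers[i]), sigma=base_sigma,
                                     dying=bool(dying[i]),
                                     transfected=bool(transfected[i])))

    canvas += params.background_level
    canvas += rng.normal(0.0, np.sqrt(np.clip(canvas, 0, None)))  # shot noise
    canvas += rng.normal(0.0, params.read_noise_sd, canvas.shape)
    image = np.clip(canvas, 0, 65535).astype(np.uint16)

    red_image = None
    if with_red:
        red += params.red_background
        red += rng.normal(0.0, params.red_noise_sd, red.shape)
        red_image = np.clip(red, 0, 65535).astype(np.uint16)
    return RenderedWell(image=image, red_image=red_image, nuclei=nuclei)


def save_rendered_well(well: RenderedWell, outdir, plate_id: str,
                       well_name: str) -> list[str]:
    """Write a rendered well as 16-bit grayscale TIFF(s).

    Files are named ``<plate>_<well>_<channel>.tif`` with channels
    ``nuclei`` and (when present) ``red``.  Returns the paths written.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, image in (("nuclei", well.image), ("red", well.red_image)):
        if image is None:
            continue
        path = outdir / f"{plate_id}_{well_name}_{channel}.tif"
        tifffile.imwrite(path, image)
        paths.append(str(path))
    return paths


def render_well_image(
    mirna_id: str | None,
    lit: bool,
    truth: GroundTruth,
    params: ImagingParams,
    seed: int,
    *,
    with_red: bool = False,
    image_id: str | None = None,
) -> RenderedWell:
    """Render one well: draw a nuclei count, dying labels, and the image.

    The number of nuclei is Poisson (or fixed); each nucleus is dying with
    the well's planted probability (a binomial ground truth).  Labels are
    recorded in ``truth.per_nucleus_labels`` under ``image_id`` if given.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if params.nuclei_count_fixed is not None:
        n = int(params.nuclei_count_fixed)
    else:
        n = int(rng.poisson(params.nuclei_per_well_mean))
    p = truth.dying_probability(mirna_id, lit)
    dying = rng.random(n) < p

    # Packing radii: dying nuclei are smaller but use the healthy radius
    # bound for placement so labels do not leak into geometry.
    radius = 2.5 * params.healthy_sigma_px
    radii = np.full(n, radius)
    centers = (_place_centers(n, params.image_size, radii,
                              params.overlap_fraction, rng)
               if n else np.empty((0, 2)))
    well = render_from_positions(centers, dying, params,
                                 seed=int(rng.integers(0, 2**31 - 1)),
                                 with_red=with_red)
    if image_id is not None:
        truth.per_nucleus_labels[image_id] = well.labels
    return well
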