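"""Nuclei segmentation, healthy/dying classification, and well measurement.

This is the image-quantification stage of the screen: segment stained
nuclei from the nuclear channel, extract per-nucleus intensity and
morphology features, label each nucleus healthy or dying, and reduce a
well's nuclei to a percent-dying measurement.

Dying (pyknotic/apoptotic) nuclei condense: they appear brighter and
smaller than healthy nuclei.  The default classifier is therefore an
auditable two-threshold rule — a nucleus is dying iff its mean intensity
is high AND its area is low, with thresholds either fixed or fitted
robustly (median ± k * scaled MAD) from the nuclei of a plate's
dark-control wells, where almost all cells are healthy.  An optional
two-component clustering mode exists behind a flag.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border, watershed

MAD_SCALE = 1.4826  # makes the MAD consistent with the SD under normality

LABEL_HEALTHY = "healthy"
LABEL_DYING = "dying"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus with its features and classification label."""

    nucleus_id: int
    centroid: tuple[float, float]
    area: float
    mean_intensity: float
    integrated_intensity: float
    circularity: float
    intensity_dispersion: float
    label: str = LABEL_UNCLASSIFIED


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma: float = 1.0
    min_area: int = 30
    peak_min_distance: int = 7
    discard_edge: bool = True


@dataclass(frozen=True)
class ClassifierThresholds:
    """Fitted or fixed decision boundaries of the two-threshold rule."""

    intensity_high: float
    area_low: float
    intensity_center: float = np.nan
    intensity_scale: float = np.nan
    area_center: float = np.nan
    area_scale: float = np.nan


@dataclass(frozen=True)
class ClassifierParams:
    mode: str = "thresholds"        # or "cluster"
    k: float = 3.0                  # robust-z cut for fitted thresholds
    thresholds: ClassifierThresholds | None = None


@dataclass(frozen=True)
class WellMeasurement:
    """Per-well summary: the x of the plate Z-score formula."""

    plate_id: str
    well: str
    role: str
    mirna_id: str | None
    n_nuclei: int
    n_dying: int
    percent_dying: float
    valid: bool


def segment_nuclei(image: np.ndarray,
                   params: SegmentationParams = SegmentationParams()
                   ) -> list[NucleusRecord]:
    """Segment nuclei from a single-channel image.

    Global Otsu threshold on the smoothed image, distance-transform
    watershed to split touching nuclei, minimum-area filter, and
    (optionally) removal of edge-touching objects.  A constant or
    saturated image yields an empty list with a warning, not an error.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty single-channel 2-D image")
    img = image.astype(float)
    if np.ptp(img) == 0:
        warnings.warn("constant image: no nuclei segmented", stacklevel=2)
        return []

    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:
        warnings.warn("degenerate intensity histogram: no nuclei segmented",
                      stacklevel=2)
        return []
    # Contrast guard: on a background-only image Otsu just splits the
    # noise, so the threshold must clear the background by a robust margin.
    med = float(np.median(smoothed))
    mad = MAD_SCALE * float(np.median(np.abs(smoothed - med)))
    if thr <= med + 3.0 * mad:
        warnings.warn("no foreground contrast above background: "
                      "no nuclei segmented", stacklevel=2)
        return []
    mask = smoothed > thr
    if mask.all():
        warnings.warn("saturated image: no nuclei segmented", stacklevel=2)
        return []
    # max_size semantics: removes objects with area <= max_size.
    mask = remove_small_objects(mask, max_size=params.min_area - 1)
    if not mask.any():
        return []

    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(distance, min_distance=params.peak_min_distance,
                            labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    labels = watershed(-distance, markers, mask=mask)
    if params.discard_edge:
        labels = clear_border(labels)

    records: list[NucleusRecord] = []
    for prop in regionprops(labels, intensity_image=img):
        if prop.area < params.min_area:
            continue
        pix = prop.image_intensity[prop.image]
        mean_i = float(pix.mean())
        dispersion = float(pix.std() / mean_i) if mean_i > 0 else 0.0
        perim = max(prop.perimeter, 1e-9)
        circularity = min(1.0, 4.0 * np.pi * prop.area / perim ** 2)
        records.append(NucleusRecord(
            nucleus_id=int(prop.label),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            area=float(prop.area),
            mean_intensity=mean_i,
            integrated_intensity=float(pix.sum()),
            circularity=circularity,
            intensity_dispersion=dispersion,
        ))
    return records


def fit_thresholds(reference: list[NucleusRecord], k: float = 3.0
                   ) -> ClassifierThresholds:
    """Fit the dying-cell decision boundaries from control nuclei.

    Robust location/scale (median, scaled MAD) of the reference
    population — typically all nuclei from a plate's dark-control wells —
    give the cuts: dying iff intensity >= median + k*MAD_s and
    area <= median - k*MAD_s.
    """
    if not reference:
        raise ValueError("threshold fitting requires control-well nuclei")
    intens = np.array([r.mean_intensity for r in reference])
    areas = np.array([r.area for r in reference])
    i_med, a_med = float(np.median(intens)), float(np.median(areas))
    i_mad = MAD_SCALE * float(np.median(np.abs(intens - i_med)))
    a_mad = MAD_SCALE * float(np.median(np.abs(areas - a_med)))
    return ClassifierThresholds(
        intensity_high=i_med + k * i_mad,
        area_low=a_med - k * a_mad,
        intensity_center=i_med, intensity_scale=i_mad,
        area_center=a_med, area_scale=a_mad,
    )


def _classify_by_thresholds(records: list[NucleusRecord],
                            thr: ClassifierThresholds) -> list[NucleusRecord]:
    out = []
    for r in records:
        dying = (r.mean_intensity >= thr.intensity_high
                 and r.area <= thr.area_low)
        out.append(dataclasses.replace(
            r, label=LABEL_DYING if dying else LABEL_HEALTHY))
    return out


def _classify_by_clustering(records: list[NucleusRecord]) -> list[NucleusRecord]:
    """Optional mode: 2-component clustering on (log intensity, log area)."""
    from sklearn.cluster import KMeans

    if len(records) < 2:
        return [dataclasses.replace(r, label=LABEL_HEALTHY) for r in records]
    feats = np.log(np.array([[r.mean_intensity, r.area] for r in records]))
    feats = (feats - feats.mean(axis=0)) / (feats.std(axis=0) + 1e-12)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(feats)
    # The dying cluster is brighter and smaller.
    score = km.cluster_centers_[:, 0] - km.cluster_centers_[:, 1]
    dying_cluster = int(np.argmax(score))
    return [dataclasses.replace(
        r, label=LABEL_DYING if km.labels_[i] == dying_cluster else LABEL_HEALTHY)
        for i, r in enumerate(records)]


def classify_nuclei(records: list[NucleusRecord],
                    params: ClassifierParams = ClassifierParams(),
                    *,
                    reference: list[NucleusRecord] | None = None
                    ) -> list[NucleusRecord]:
    """Label every nucleus healthy or dying.

    With ``mode='thresholds'``, uses fixed ``params.thresholds`` when
    given, otherwise fits them from ``reference`` (control-well nuclei).
    """
    if params.mode == "cluster":
        return _classify_by_clustering(records)
    if params.mode != "thresholds":
        raise ValueError(f"unknown classifier mode {params.mode!r}")
    thr = params.thresholds
    if thr is None:
        if reference is None:
            raise ValueError("threshold classification needs fixed thresholds "
                             "or control-well reference nuclei")
        thr = fit_thresholds(reference, k=params.k)
    return _classify_by_thresholds(records, thr)


def measure_well(records: list[NucleusRecord], *, plate_id: str, well: str,
                 role: str, mirna_id: str | None = None,
                 min_nuclei: int = 50) -> WellMeasurement:
    """Reduce one well's labelled nuclei to a percent-dying measurement.

    Wells with fewer than ``min_nuclei`` nuclei are flagged invalid so
    unstable percentages never enter plate statistics.
    """
    unlabeled = [r for r in records if r.label == LABEL_UNCLASSIFIED]
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} unclassified nuclei in {plate_id}/{well}")
    n = len(records)
    n_dying = sum(r.label == LABEL_DYING for r in records)
    percent = 100.0 * n_dying / n if n > 0 else float("nan")
    return WellMeasurement(plate_id=plate_id, well=well, role=role,
                           mirna_id=mirna_id, n_nuclei=n, n_dying=n_dying,
                           percent_dying=percent, valid=n >= min_nuclei)


def measurements_to_frame(measurements: list[WellMeasurement]) -> pd.DataFrame:
    rows = [{
        "plate_id": m.plate_id, "well": m.well, "role": m.role,
        "mirna_id": m.mirna_id or "",
        "replicate": np.nan,
        "n_nuclei": m.n_nuclei, "n_dying": m.n_dying,
        "percent_dying": m.percent_dying, "valid": m.valid,
    } for m in measurements]
    return pd.DataFrame(rows)


def estimate_transfection_efficiency(
    nuclei_image: np.ndarray,
    red_image: np.ndarray,
    seg_params: SegmentationParams = SegmentationParams(),
    *,
    background_k: float = 5.0,
) -> float:
    """Fraction of nuclei whose red-channel signal exceeds background.

    Nuclei are segmented from the nuclear channel; the red background is
    estimated robustly from pixels outside all nuclear masks, and a
    nucleus counts as transfected when its mean red intensity exceeds
    background median + ``background_k`` scaled MADs.
    """
    if red_image is None:
        raise ValueError("transfection estimation requires the red channel")
    nuclei_image = np.asarray(nuclei_image)
    red = np.asarray(red_image, dtype=float)
    if red.shape != nuclei_image.shape:
        raise ValueError("channels must be registered and the same size")

    records = segment_nuclei(nuclei_image, seg_params)
    if not records:
        return 0.0

    # Rebuild an approximate foreground mask for background estimation.
    smoothed = gaussian(nuclei_image.astype(float), sigma=seg_params.smooth_sigma,
                        preserve_range=True)
    fg = smoothed > threshold_otsu(smoothed)
    bg_pix = red[~ndi.binary_dilation(fg, iterations=3)]
    if bg_pix.size == 0:
        bg_pix = red.ravel()
    med = float(np.median(bg_pix))
    mad = MAD_SCALE * float(np.median(np.abs(bg_pix - med)))
    cut = med + background_k * max(mad, 1e-9)

    positive = 0
    half = 4
    for r in records:
        rr, cc = int(round(r.centroid[0])), int(round(r.centroid[1]))
        patch = red[max(0, rr - half):rr + half + 1, max(0, cc - half):cc + half + 1]
        if patch.size and float(patch.mean()) > cut:
            positive += 1
    return positive / len(records)
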