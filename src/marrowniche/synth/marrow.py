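"""Synthetic H&E-style bone-marrow images with known adipocyte ground truth.

Emulates the appearance the segmentation protocol relies on: bright,
low-texture elliptical vacuoles (adipocyte ghosts) on eosin-pink, noisy
marrow tissue, inside a biopsy-shaped region of interest; optional dark
artifact bands (tears / bone) lie outside the ROI, as they would after
expert delineation. Every planted object is recorded in a label map with its
true area and centroid, so segmentation accuracy can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from ..histo import Image2D, ROIMask

__all__ = ["MarrowImageParams", "ImageGroundTruth", "gen_marrow_image", "PlacementError", "save_image_set"]

# appearance constants (8-bit RGB): vacuole interior, rim, eosin-pink marrow
_VACUOLE_RGB = np.array([246, 243, 247], dtype=float)
_RIM_RGB = np.array([168, 120, 150], dtype=float)
_TISSUE_RGB = np.array([205, 140, 165], dtype=float)
_ARTIFACT_RGB = np.array([60, 30, 45], dtype=float)


class PlacementError(RuntimeError):
    """Raised when the requested objects cannot be packed into the ROI."""

    def __init__(self, requested: int, placed: int):
        self.requested, self.placed = requested, placed
        super().__init__(
            f"could only place {placed} of {requested} adipocytes without "
            f"violating the packing constraints; enlarge the image or reduce "
            f"n_adipocytes / median_diameter_um"
        )


@dataclass
class MarrowImageParams:
    width_px: int = 768
    height_px: int = 768
    pixel_size_um: float = 1.0
    n_adipocytes: int = 50
    median_diameter_um: float = 40.0
    sigma_log: float = 0.25           # lognormal sigma of the diameter distribution
    cluster_fraction: float = 0.0     # fraction of objects planted as touching pairs
    background_noise_sd: float = 6.0  # 8-bit intensity units
    texture_amplitude: float = 14.0   # cellular marrow texture (smooth-field sd, 8-bit units)
    n_artifacts: int = 0
    rim_width_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.n_adipocytes < 0:
            raise ValueError("n_adipocytes must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")


@dataclass
class ImageGroundTruth:
    label_map: np.ndarray                 # 0 = background, 1..n = planted objects
    objects: pd.DataFrame                 # label, area_um2, centroid_row, centroid_col, pair_id
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def true_count(self) -> int:
        return int(len(self.objects))


def _sample_radii(rng: np.random.Generator, params: MarrowImageParams, n: int) -> np.ndarray:
    diam_um = rng.lognormal(mean=np.log(params.median_diameter_um), sigma=params.sigma_log, size=n)
    return diam_um / 2.0 / params.pixel_size_um  # radius in px


def _ellipse_axes(rng: np.random.Generator, r_px: float) -> tuple[float, float, float]:
    # axis ratio in [1, 1.6] keeps planted form factors above the default cut
    q = rng.uniform(1.0, 1.6)
    return r_px * np.sqrt(q), r_px / np.sqrt(q), rng.uniform(0, np.pi)


def gen_marrow_image(params: MarrowImageParams) -> tuple[Image2D, ROIMask, ImageGroundTruth]:
    """Generate one synthetic marrow image, its ROI mask, and its ground truth.

    Deterministic for a fixed ``params.seed``. Raises :class:`PlacementError`
    if the requested number of adipocytes cannot be placed without exceeding
    the packing limit (rejection sampling, never silent truncation).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px

    # ROI: biopsy-core ellipse with a safety margin off the image border
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h * 0.47, w * 0.47
    roi = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0

    # artifacts: dark bands excluded (with margin) from the ROI
    artifact_mask = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_artifacts):
        band_w = int(rng.integers(8, 25))
        if rng.random() < 0.5:
            c0 = int(rng.integers(0, max(1, w - band_w)))
            artifact_mask[:, c0 : c0 + band_w] = True
        else:
            r0 = int(rng.integers(0, max(1, h - band_w)))
            artifact_mask[r0 : r0 + band_w, :] = True
    if params.n_artifacts:
        roi &= ~ndi.binary_dilation(artifact_mask, iterations=4)

    # distance-to-ROI-edge lets us test quickly whether a vacuole fits fully inside
    roi_dist = ndi.distance_transform_edt(roi)

    label_map = np.zeros((h, w), dtype=np.int32)
    records: list[dict] = []
    pairs: list[tuple[int, int]] = []

    n = params.n_adipocytes
    n_pairs = int(round(params.cluster_fraction * n / 2.0))
    n_single = n - 2 * n_pairs
    radii = _sample_radii(rng, params, n)
    occupied = np.zeros((h, w), dtype=bool)  # planted footprints + clearance

    def try_place(r_px: float, centre: tuple[float, float] | None = None):
        """One rejection-sampling attempt; returns (mask, centre) or None."""
        if centre is None:
            row = rng.uniform(0, h)
            col = rng.uniform(0, w)
        else:
            row, col = centre
        ir, ic = int(round(row)), int(round(col))
        if not (0 <= ir < h and 0 <= ic < w):
            return None
        if roi_dist[ir, ic] < r_px + 3:
            return None
        a, b, theta = _ellipse_axes(rng, r_px)
        err, ecc = draw_ellipse(row, col, a, b, shape=(h, w), rotation=theta)
        mask = np.zeros((h, w), dtype=bool)
        mask[err, ecc] = True
        if mask.sum() < 4:
            return None
        grown = ndi.binary_dilation(mask, iterations=3)
        if (grown & occupied).any():
            return None
        return mask, (row, col)

    max_attempts = 400 * max(1, n)
    attempts = 0
    next_label = 1

    idx = 0
    for _ in range(n_single):
        r_px = radii[idx]
        idx += 1
        placed = None
        while placed is None:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(n, next_label - 1)
            placed = try_place(r_px)
        mask, (row, col) = placed
        label_map[mask] = next_label
        occupied |= ndi.binary_dilation(mask, iterations=3)
        records.append({"label": next_label, "pair_id": -1})
        next_label += 1

    for _ in range(n_pairs):
        r1, r2 = radii[idx], radii[idx + 1]
        idx += 2
        placed = None
        while placed is None:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(n, next_label - 1)
            first = try_place(r1)
            if first is None:
                continue
            mask1, (row1, col1) = first
            # second member overlaps the first by 10-30% of the smaller radius
            overlap = rng.uniform(0.1, 0.3) * min(r1, r2)
            d = r1 + r2 - overlap
            phi = rng.uniform(0, 2 * np.pi)
            row2, col2 = row1 + d * np.sin(phi), col1 + d * np.cos(phi)
            ir2, ic2 = int(round(row2)), int(round(col2))
            if not (0 <= ir2 < h and 0 <= ic2 < w) or roi_dist[ir2, ic2] < r2 + 3:
                continue
            a, b, theta = _ellipse_axes(rng, r2)
            err, ecc = draw_ellipse(row2, col2, a, b, shape=(h, w), rotation=theta)
            mask2 = np.zeros((h, w), dtype=bool)
            mask2[err, ecc] = True
            if mask2.sum() < 4:
                continue
            grown = ndi.binary_dilation(mask1 | mask2, iterations=3)
            if (grown & occupied).any():
                continue
            placed = (mask1, mask2)
        mask1, mask2 = placed
        l1, l2 = next_label, next_label + 1
        label_map[mask1] = l1
        label_map[mask2 & ~mask1] = l2  # shared pixels go to the first member
        occupied |= ndi.binary_dilation(mask1 | mask2, iterations=3)
        records.append({"label": l1, "pair_id": len(pairs)})
        records.append({"label": l2, "pair_id": len(pairs)})
        pairs.append((l1, l2))
        next_label += 2

    # render
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _TISSUE_RGB
    if params.n_artifacts:
        img[artifact_mask] = _ARTIFACT_RGB
    vac = label_map > 0
    rim = ndi.binary_dilation(vac, iterations=params.rim_width_px) & ~vac
    img[rim] = _RIM_RGB
    img[vac] = _VACUOLE_RGB
    if params.texture_amplitude > 0:
        # spatially correlated cellularity texture in the tissue, absent from
        # the empty vacuoles: this is what the texture channel discriminates on
        field = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 1.5)
        sd = field.std()
        if sd > 0:
            field *= params.texture_amplitude / sd
        tissue = ~(vac | rim)
        img[tissue] += field[tissue, None]
    if params.background_noise_sd > 0:
        img = img + rng.normal(0.0, params.background_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    px_area = params.pixel_size_um**2
    for rec in records:
        obj = label_map == rec["label"]
        area = int(obj.sum())
        rows, cols = np.nonzero(obj)
        rec["area_um2"] = area * px_area
        rec["centroid_row"] = float(rows.mean())
        rec["centroid_col"] = float(cols.mean())
    truth_df = pd.DataFrame(
        records, columns=["label", "pair_id", "area_um2", "centroid_row", "centroid_col"]
    )
    truth = ImageGroundTruth(label_map=label_map, objects=truth_df, pairs=pairs)
    image = Image2D(pixels=img, pixel_size_um=params.pixel_size_um)
    roi_mask = ROIMask(mask=roi, pixel_size_um=params.pixel_size_um)
    return image, roi_mask, truth


def save_image_set(
    out_dir: str | Path, image: Image2D, roi: ROIMask, truth: ImageGroundTruth, stem: str = "marrow"
) -> dict[str, Path]:
    """Write image (PNG, 8-bit RGB), ROI (0/255 PNG), truth table (TSV), label map (16-bit PNG)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}_image.png",
        "roi": out / f"{stem}_roi.png",
        "labels": out / f"{stem}_truth_labels.png",
        "truth": out / f"{stem}_truth.tsv",
    }
    iio.imwrite(paths["image"], image.pixels)
    iio.imwrite(paths["roi"], (roi.mask.astype(np.uint8) * 255))
    iio.imwrite(paths["labels"], truth.label_map.astype(np.uint16))
    truth.objects.to_csv(paths["truth"], sep="\t", index=False)
    return paths
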