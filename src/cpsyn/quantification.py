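"""Puncta segmentation, colocalization, synapse density, blot normalization.

Semi-thin (0.5 um) sections are immunolabelled for the presynaptic
active-zone marker Munc13-1 and a postsynaptic scaffold paralog (PSD-95 or
PSD-93). Puncta-like objects are segmented by intensity and size (>= 200
px^2 at 6 nm pixels, about 7,200 nm^2); a synapse is a Munc13-1 punctum
whose mask overlaps a paralog punctum by more than 5%. Density divides
the synapse count by the imaged volume (image area x section thickness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "PunctaSet",
    "segment_puncta",
    "colocalize",
    "synapse_density",
    "normalize_blot",
]

#: minimum object size in pixels (at 6 nm pixels: about 7,200 nm^2)
MIN_AREA_PX = 200
#: overlap fraction (of the smaller punctum) defining a synapse
MIN_OVERLAP = 0.05
DEFAULT_PIXEL_NM = 6.0
DEFAULT_THICKNESS_NM = 500.0


@dataclass
class PunctaSet:
    """Segmented puncta of one channel.

    ``table`` has one row per retained punctum: label, area_px,
    area_nm2, centroid_row, centroid_col. ``label_image`` assigns each
    pixel its punctum label (0 = background).
    """

    channel: str
    label_image: np.ndarray
    table: pd.DataFrame
    pixel_nm: float = DEFAULT_PIXEL_NM
    section_thickness_nm: float = DEFAULT_THICKNESS_NM

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0 or self.section_thickness_nm <= 0:
            raise ValueError("pixel_nm and section_thickness_nm must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def image_area_um2(self) -> float:
        h, w = self.label_image.shape
        return h * w * (self.pixel_nm * 1e-3) ** 2


def segment_puncta(
    image: np.ndarray,
    channel: str = "munc13",
    intensity_rule: str | float = "otsu",
    min_area_px: int = MIN_AREA_PX,
    split_touching: bool = False,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    section_thickness_nm: float = DEFAULT_THICKNESS_NM,
) -> PunctaSet:
    """Intensity-threshold segmentation of puncta-like objects.

    Thresholding defaults to Otsu (a surrogate for the interactive
    intensity thresholding of the original workflow; pass a float for an
    absolute threshold). Connected components smaller than
    ``min_area_px`` are discarded. ``split_touching`` applies a
    watershed split on the distance transform in place of the manual
    separation of fused puncta; results carry that provenance in logs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.size == 0:
        raise ValueError("empty image")
    if isinstance(intensity_rule, str):
        if intensity_rule != "otsu":
            raise ValueError("intensity_rule must be 'otsu' or a float threshold")
        if np.ptp(img) == 0:
            binary = np.zeros(img.shape, dtype=bool)
        else:
            binary = img > threshold_otsu(img)
    else:
        binary = img > float(intensity_rule)

    labels = measure.label(binary)
    if split_touching and labels.max() > 0:
        from scipy import ndimage as ndi

        logger.info("segment_puncta: watershed split of touching puncta enabled")
        dist = ndi.distance_transform_edt(binary)
        coords = peak_local_max(dist, labels=labels, min_distance=5)
        markers = np.zeros(img.shape, dtype=int)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = segmentation.watershed(-dist, markers, mask=binary)

    rows = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_label = 1
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        keep[region.label] = next_label
        rows.append(
            {
                "label": next_label,
                "area_px": int(region.area),
                "area_nm2": float(region.area * pixel_nm**2),
                "centroid_row": region.centroid[0],
                "centroid_col": region.centroid[1],
            }
        )
        next_label += 1
    relabeled = keep[labels]
    table = pd.DataFrame(
        rows, columns=["label", "area_px", "area_nm2", "centroid_row", "centroid_col"]
    )
    return PunctaSet(
        channel=channel,
        label_image=relabeled,
        table=table,
        pixel_nm=pixel_nm,
        section_thickness_nm=section_thickness_nm,
    )


def colocalize(
    a: PunctaSet,
    b: PunctaSet,
    min_overlap: float = MIN_OVERLAP,
    denominator: str = "min",
) -> pd.DataFrame:
    """Match puncta across two channels by mask overlap.

    A pair is a candidate when its intersection area exceeds
    ``min_overlap`` of the denominator area (default: the smaller
    punctum, which makes the rule symmetric; 'a', 'b' and 'union' are
    available alternatives). Each punctum is matched to at most one
    partner — candidates are ranked by overlap fraction (ties broken by
    label order) and matched greedily. Returns one row per matched pair
    with labels, areas, intersection area and overlap fraction.
    """
    if a.label_image.shape != b.label_image.shape:
        raise ValueError("puncta sets must share image geometry")
    la, lb = a.label_image, b.label_image
    both = (la > 0) & (lb > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        flat = np.stack([la[both], lb[both]])
        uniq, counts = np.unique(flat, axis=1, return_counts=True)
        for (ia, ib), n in zip(uniq.T, counts):
            pairs[(int(ia), int(ib))] = int(n)

    area_a = dict(zip(a.table["label"], a.table["area_px"]))
    area_b = dict(zip(b.table["label"], b.table["area_px"]))
    candidates = []
    for (ia, ib), inter in pairs.items():
        if denominator == "min":
            denom = min(area_a[ia], area_b[ib])
        elif denominator == "a":
            denom = area_a[ia]
        elif denominator == "b":
            denom = area_b[ib]
        elif denominator == "union":
            denom = area_a[ia] + area_b[ib] - inter
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        frac = inter / denom
        if frac > min_overlap:
            candidates.append((frac, ia, ib, inter))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for frac, ia, ib, inter in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append(
            {
                "label_a": ia,
                "label_b": ib,
                "area_a_px": area_a[ia],
                "area_b_px": area_b[ib],
                "overlap_px": inter,
                "overlap_frac": frac,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label_a",
            "label_b",
            "area_a_px",
            "area_b_px",
            "overlap_px",
            "overlap_frac",
        ],
    )


def synapse_density(
    n_synapses: int, image_area_um2: float, thickness_nm: float = DEFAULT_THICKNESS_NM
) -> float:
    """Synapses per um^3 of imaged tissue (area x section thickness)."""
    if image_area_um2 <= 0 or thickness_nm <= 0:
        raise ValueError("image area and thickness must be positive")
    if n_synapses < 0:
        raise ValueError("synapse count must be non-negative")
    return n_synapses / (image_area_um2 * thickness_nm * 1e-3)


def normalize_blot(
    table: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-blot, per-protein normalization of band intensities.

    Each band intensity is divided by the mean intensity of the
    control-group samples for the same protein on the same blot, so the
    control mean is 1 per (blot, protein) by construction and values are
    comparable across blots. Rows on blots lacking a control for their
    protein are flagged and returned separately, not silently dropped.
    """
    required = {"protein", "sample_id", "group", "band_intensity", "blot_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"blot table missing columns: {sorted(missing)}")
    ok_parts, bad_parts = [], []
    for (blot, protein), grp in table.groupby(["blot_id", "protein"], sort=False):
        ctrl = grp.loc[grp["group"] == control_group, "band_intensity"]
        if len(ctrl) == 0 or ctrl.mean() <= 0:
            bad = grp.copy()
            bad["reason"] = f"no usable {control_group} control on blot {blot}"
            bad_parts.append(bad)
            logger.warning(
                "normalize_blot: blot %s protein %s lacks a control; %d rows excluded",
                blot,
                protein,
                len(grp),
            )
            continue
        out = grp.copy()
        out["relative_amount"] = out["band_intensity"] / ctrl.mean()
        ok_parts.append(out)
    normalized = (
        pd.concat(ok_parts).sort_index() if ok_parts else table.iloc[0:0].copy()
    )
    excluded = (
        pd.concat(bad_parts).sort_index()
        if bad_parts
        else table.iloc[0:0].assign(reason=pd.Series(dtype=str))
    )
    return normalized, excluded
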