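"""X-ray bone-ingrowth quantification.

Implements the threshold-based analysis of 8-bit radiographs of the
implanted titanium scaffold: pixels brighter than 250 are scaffold
metal, pixels with intensity in [60, 180) are (regenerated) bone, the
rest is background/soft tissue.  The image is divided into equal grids
and each grid scored with the bone fraction of its non-scaffold area,

    P_b = S_bone / (S_all - S_s),

then grids are pooled into row/column profiles to expose vertical and
side-to-middle ingrowth trends.  Bone-scaffold contact is scored on
pixel connectivity: the share of scaffold interface pixels (scaffold
pixels with at least one non-scaffold neighbour) that touch at least
one bone pixel, under the 4-connected (edge) or 8-connected
(edge + diagonal) neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

SCAFFOLD_PX, BONE_PX, OTHER_PX = 2, 1, 0
CLASS_NAMES = {SCAFFOLD_PX: "scaffold", BONE_PX: "bone", OTHER_PX: "other"}


@dataclass(frozen=True)
class Thresholds:
    """Intensity cut-offs on the 0-255 grayscale."""

    scaffold_min: int = 250    # exclusive: scaffold iff I > scaffold_min
    bone_min: int = 60         # inclusive
    bone_max: int = 180        # exclusive

    def __post_init__(self):
        if not 0 <= self.bone_min < self.bone_max <= self.scaffold_min <= 255:
            raise ValueError("need 0 <= bone_min < bone_max <= scaffold_min "
                             "<= 255")


@dataclass
class LabelImage:
    """Per-pixel class labels plus the physical pixel size (mm)."""

    labels: np.ndarray
    pixel_size: float = 1.0

    @property
    def shape(self):
        return self.labels.shape

    def class_counts(self) -> dict:
        return {name: int(np.sum(self.labels == code))
                for code, name in CLASS_NAMES.items()}


def classify_pixels(image, thresholds: Thresholds = Thresholds(),
                    pixel_size: float = 1.0) -> LabelImage:
    """Threshold an 8-bit grayscale image into scaffold/bone/other."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 \
                and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("expected an 8-bit grayscale image")
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    labels = np.full(img.shape, OTHER_PX, np.uint8)
    labels[(img >= thresholds.bone_min) & (img < thresholds.bone_max)] = BONE_PX
    labels[img > thresholds.scaffold_min] = SCAFFOLD_PX
    return LabelImage(labels=labels, pixel_size=pixel_size)


def partition_grids(shape, n_rows: int, n_cols: int):
    """Half-open pixel ranges of an n_rows x n_cols equal grid.

    Strides are floor(size/n); remainder pixels are absorbed by the last
    row/column.  Returns a list of (row, col, rs, re, cs, ce).
    """
    h, w = shape
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid counts must be >= 1")
    if n_rows > h or n_cols > w:
        raise ValueError("grid finer than the image")
    rstride, cstride = h // n_rows, w // n_cols
    cells = []
    for r in range(n_rows):
        rs = r * rstride
        re = (r + 1) * rstride if r < n_rows - 1 else h
        for c in range(n_cols):
            cs = c * cstride
            ce = (c + 1) * cstride if c < n_cols - 1 else w
            cells.append((r, c, rs, re, cs, ce))
    return cells


def bone_fraction(label_image: LabelImage, grids=None, n_rows: int = 10,
                  n_cols: int = 10) -> pd.DataFrame:
    """Per-grid bone fraction P_b = S_bone / (S_all - S_s).

    Grids that are pure scaffold have no void area; their P_b is NaN and
    they are excluded from any aggregate.
    """
    lab = label_image.labels
    if grids is None:
        grids = partition_grids(lab.shape, n_rows, n_cols)
    rows = []
    for r, c, rs, re, cs, ce in grids:
        tile = lab[rs:re, cs:ce]
        s_all = tile.size
        s_s = int(np.sum(tile == SCAFFOLD_PX))
        s_bone = int(np.sum(tile == BONE_PX))
        denom = s_all - s_s
        pb = s_bone / denom if denom > 0 else np.nan
        rows.append(dict(row=r, col=c, S_all=s_all, S_s=s_s,
                         S_bone=s_bone, P_b=pb))
    return pd.DataFrame(rows)


def profiles(stats: pd.DataFrame, axis: str = "columns",
             n_groups: int | None = None) -> pd.DataFrame:
    """Mean P_b per row group or column group.

    ``axis='columns'`` pools grid columns (horizontal, side-to-side
    profile), ``axis='rows'`` pools grid rows (vertical profile).
    ``n_groups`` merges adjacent rows/columns into that many groups
    (e.g. 5 to mirror a five-band side-to-middle analysis).
    """
    key = {"columns": "col", "rows": "row"}.get(axis)
    if key is None:
        raise ValueError("axis must be 'rows' or 'columns'")
    df = stats.dropna(subset=["P_b"]).copy()
    n = int(stats[key].max()) + 1
    if n_groups is None:
        n_groups = n
    if n_groups < 1 or n_groups > n:
        raise ValueError("invalid group count")
    df["group"] = (df[key] * n_groups) // n
    out = df.groupby("group", as_index=False).agg(
        mean_P_b=("P_b", "mean"), n_grids=("P_b", "size"))
    if out.empty:
        raise ValueError("no grids with defined P_b to profile")
    return out


@dataclass
class ContactReport:
    """Connectivity-based bone-scaffold contact score."""

    connectivity: int
    interface_pixels: int
    contact_pixels: int

    @property
    def percentage(self) -> float:
        if self.interface_pixels == 0:
            return 0.0
        return 100.0 * self.contact_pixels / self.interface_pixels


def _neighbor_any(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """True where a pixel has >= 1 True neighbour (excluding itself)."""
    if connectivity == 4:
        footprint = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], bool)
    elif connectivity == 8:
        footprint = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], bool)
    else:
        raise ValueError("connectivity must be 4 or 8")
    return ndimage.correlate(mask.astype(np.uint8),
                             footprint.astype(np.uint8),
                             mode="constant", cval=0) > 0


def contact_percentage(label_image: LabelImage,
                       connectivity: int = 8) -> ContactReport:
    """Share of scaffold interface pixels with at least one bone neighbour.

    Interface pixels are scaffold pixels with >= 1 non-scaffold
    neighbour under the same connectivity; neighbours outside the image
    do not count.
    """
    lab = label_image.labels
    scaffold = lab == SCAFFOLD_PX
    if not scaffold.any():
        raise ValueError("image contains no scaffold pixels")
    bone = lab == BONE_PX
    non_scaffold = ~scaffold
    interface = scaffold & _neighbor_any(non_scaffold, connectivity)
    contact = interface & _neighbor_any(bone, connectivity)
    return ContactReport(connectivity=connectivity,
                         interface_pixels=int(interface.sum()),
                         contact_pixels=int(contact.sum()))


def quantify_image(image, thresholds: Thresholds = Thresholds(),
                   n_rows: int = 10, n_cols: int = 10) -> dict:
    """Full pipeline on one grayscale image: labels, grids, contact."""
    labels = classify_pixels(image, thresholds)
    stats = bone_fraction(labels, n_rows=n_rows, n_cols=n_cols)
    out = dict(labels=labels, grid_stats=stats,
               column_profile=profiles(stats, "columns"),
               row_profile=profiles(stats, "rows"))
    if (labels.labels == SCAFFOLD_PX).any():
        out["contact_4"] = contact_percentage(labels, 4)
        out["contact_8"] = contact_percentage(labels, 8)
    counts = labels.class_counts()
    void = counts["bone"] + counts["other"]
    out["global_bone_fraction"] = counts["bone"] / void if void else np.nan
    return out
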