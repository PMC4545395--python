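"""Cavity volumetry and the six cardiac function parameters.

Volumes use slice summation on contiguous short-axis slices:
``V = sum_slices (foreground pixels x pixel area mm^2) x thickness mm / 1000``
in ml.  From the end-diastolic (ED) and end-systolic (ES) endocardial
volumes and the ED epicardial volume the clinical indices follow:

* ``SV  = EDV - ESV``            (stroke volume, ml)
* ``LVEF = SV / EDV``            (ejection fraction; <= 0.45 is pathological)
* ``MM  = 1.05 x (EpV - EDV)``   (myocardial mass, g; 1.05 g/ml density)

Contour rasterization fixes a pixel-center, even-odd convention: a pixel
belongs to the mask iff its center (integer x=column, y=row coordinates)
lies inside the closed polygon under the half-open crossing-number rule.
That convention is part of the file-format contract, so it is implemented
here explicitly rather than delegated to a library with unspecified
boundary behavior.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import ClinicalIndices, MaskStack

__all__ = [
    "rasterize_contour",
    "cavity_volume",
    "clinical_indices",
    "indices_from_masks",
    "cohort_table",
    "subgroup_summary",
]

logger = logging.getLogger(__name__)


def rasterize_contour(
    polygon: np.ndarray, grid_shape: tuple[int, int], pixel_spacing_mm: float | None = None
) -> np.ndarray:
    """Fill a closed planar polygon on a pixel grid.

    ``polygon`` is an (n, 2) array of (x, y) vertices in 0-based pixel
    coordinates (x = column, y = row); closure is implied.  A pixel is set
    iff its center is inside by the even-odd rule with half-open edges
    (``y_min <= y_center < y_max``), which makes shared edges between
    adjacent polygons unambiguous.  ``pixel_spacing_mm`` is accepted for
    interface symmetry; the fill itself is purely in pixel coordinates.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an (n >= 3, 2) array of x y vertices")
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = y1 != y2  # horizontal edges never cross a horizontal ray
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    if x1.size == 0:
        return np.zeros(grid_shape, dtype=bool)

    ny, nx = grid_shape
    ys = np.arange(ny, dtype=float)
    # half-open in y: the edge covers min(y1,y2) <= y < max(y1,y2)
    lo = np.minimum(y1, y2)
    hi = np.maximum(y1, y2)
    mask = np.zeros((ny, nx), dtype=bool)
    xs = np.arange(nx, dtype=float)
    for iy, y in enumerate(ys):
        sel = (lo <= y) & (y < hi)
        if not sel.any():
            continue
        xi = x1[sel] + (y - y1[sel]) * (x2[sel] - x1[sel]) / (y2[sel] - y1[sel])
        crossings = (xi[None, :] > xs[:, None]).sum(axis=1)
        mask[iy] = (crossings % 2) == 1
    return mask


def cavity_volume(stack: MaskStack) -> float:
    """Slice-summation volume of a mask stack, in ml."""
    count = int(stack.slices.sum())
    if count == 0:
        logger.warning("empty mask stack for subject %r phase %r: volume 0 ml",
                       stack.subject, stack.phase)
        return 0.0
    return count * stack.pixel_area_mm2 * stack.slice_thickness_mm / 1000.0


def clinical_indices(edv_ml: float, esv_ml: float, epv_ml: float | None = None) -> ClinicalIndices:
    """Derive SV, LVEF and (if the epicardial volume is given) MM."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    if esv_ml < 0:
        raise ValueError("ESV must be non-negative")
    sv = edv_ml - esv_ml
    lvef = sv / edv_ml
    implausible = esv_ml > edv_ml
    if implausible:
        logger.warning("ESV (%.1f ml) exceeds EDV (%.1f ml): flagged implausible",
                       esv_ml, edv_ml)
    mm = None
    if epv_ml is not None:
        mm = 1.05 * (epv_ml - edv_ml)
        if epv_ml < edv_ml:
            logger.warning("EpV (%.1f ml) below EDV (%.1f ml)", epv_ml, edv_ml)
    return ClinicalIndices(
        edv_ml=float(edv_ml), esv_ml=float(esv_ml), sv_ml=float(sv),
        lvef=float(lvef), epv_ml=None if epv_ml is None else float(epv_ml),
        mm_g=None if mm is None else float(mm), implausible=implausible,
    )


def indices_from_masks(
    ed: MaskStack, es: MaskStack, epi: MaskStack | None = None
) -> ClinicalIndices:
    """Clinical indices from ED/ES endocardial (and optional ED epicardial) stacks."""
    edv = cavity_volume(ed)
    esv = cavity_volume(es)
    epv = None if epi is None else cavity_volume(epi)
    return clinical_indices(edv, esv, epv)


def cohort_table(
    indices_df: pd.DataFrame, index: str = "LVEF"
) -> pd.DataFrame:
    """Pivot a long per-subject indices table into a P x K estimate matrix.

    ``indices_df`` has one row per (subject, method) with at least columns
    ``subject``, ``method`` and the requested index column (``LVEF``,
    ``EDV_ml``, ...).  Missing subject/method cells stay missing (NaN) and
    are logged, never imputed.
    """
    required = {"subject", "method", index}
    missing_cols = required - set(indices_df.columns)
    if missing_cols:
        raise KeyError(f"indices table lacks columns {sorted(missing_cols)}")
    mat = indices_df.pivot_table(index="subject", columns="method", values=index,
                                 aggfunc="first", sort=False)
    n_missing = int(mat.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%d missing subject x method cell(s) in the %s matrix",
                       n_missing, index)
    if "subgroup" in indices_df.columns:
        sg = indices_df.drop_duplicates("subject").set_index("subject")["subgroup"]
        mat.attrs["subgroup"] = sg.reindex(mat.index)
    return mat


def subgroup_summary(
    matrix: pd.DataFrame,
    subgroups: pd.Series | None = None,
    percent: bool = False,
) -> pd.DataFrame:
    """Per-subgroup mean +- sample SD (n-1) of each method's estimates.

    Returns a table indexed by (subgroup, statistic in {mean, sd, n}) with
    one column per method; single-subject subgroups report SD as NaN.
    ``percent=True`` scales mean and SD by 100 (LVEF tables print percent).
    """
    if subgroups is None:
        subgroups = matrix.attrs.get("subgroup")
    if subgroups is None:
        raise ValueError("no subgroup labels available")
    subgroups = pd.Series(subgroups).reindex(matrix.index)
    if subgroups.isna().any():
        raise ValueError("every subject needs a subgroup label")
    scale = 100.0 if percent else 1.0
    rows = []
    for sg, idx in matrix.groupby(subgroups, sort=False).groups.items():
        block = matrix.loc[idx]
        if len(block) == 0:
            raise ValueError(f"empty subgroup {sg!r}")
        mean = block.mean(axis=0) * scale
        sd = block.std(axis=0, ddof=1) * scale  # NaN when n == 1
        rows.append(pd.DataFrame(
            {m: [mean[m], sd[m], float(len(block))] for m in matrix.columns},
            index=pd.MultiIndex.from_product([[sg], ["mean", "sd", "n"]],
                                             names=["subgroup", "stat"]),
        ))
    return pd.concat(rows)
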