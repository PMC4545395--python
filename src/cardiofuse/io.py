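"""Plain-text I/O: contour point lists, mask stacks, manifests, matrices.

Contour files follow the convention of the public cardiac segmentation
challenge datasets: one "x y" pair per line in 0-based pixel coordinates
(x = column, y = row), closed polygon implied.
Mask stacks are stored as a small text format (geometry header followed by
0/1 rows per slice) so cohorts stay plain text end to end.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import CohortSpec, MaskStack, RaterProfile

__all__ = [
    "read_contour",
    "write_contour",
    "mask_to_contours",
    "read_mask_stack",
    "write_mask_stack",
    "read_estimate_matrix",
    "write_estimate_matrix",
    "write_cohort",
]


def read_contour(path: str | Path) -> np.ndarray:
    """Read an "x y"-per-line contour file into an (n, 2) vertex array."""
    pts = np.loadtxt(path, dtype=float, ndmin=2)
    if pts.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (x y)")
    if pts.shape[0] < 3:
        raise ValueError(f"{path}: a closed contour needs at least 3 points")
    # drop an explicit closing vertex if present
    if np.allclose(pts[0], pts[-1]) and pts.shape[0] > 3:
        pts = pts[:-1]
    return pts


def write_contour(path: str | Path, polygon: np.ndarray) -> None:
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be (n >= 3, 2)")
    np.savetxt(path, poly, fmt="%.4f")


def mask_to_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Trace the boundary polygon(s) of a binary mask, as (x, y) vertices.

    Uses marching squares at level 0.5 (sub-pixel boundary half way between
    foreground and background pixel centers); only closed contours with at
    least 3 vertices are returned.
    """
    from skimage import measure  # local import: only contour export needs it

    out = []
    for c in measure.find_contours(np.asarray(mask, dtype=float), 0.5):
        if len(c) >= 4 and np.allclose(c[0], c[-1]):
            poly = np.column_stack([c[:-1, 1], c[:-1, 0]])  # (row, col) -> (x, y)
            if poly.shape[0] >= 3:
                out.append(poly)
    return out


def write_mask_stack(path: str | Path, stack: MaskStack) -> None:
    lines = [
        f"# nslices={stack.n_slices} ny={stack.grid_shape[0]} nx={stack.grid_shape[1]} "
        f"spacing={stack.pixel_spacing_mm[0]}x{stack.pixel_spacing_mm[1]} "
        f"thickness={stack.slice_thickness_mm} subject={stack.subject} phase={stack.phase}"
    ]
    for s in range(stack.n_slices):
        lines.append(f"# slice {s}")
        for row in stack.slices[s].astype(np.uint8):
            lines.append("".join(map(str, row)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_mask_stack(path: str | Path) -> MaskStack:
    text = Path(path).read_text().splitlines()
    header = text[0]
    if not header.startswith("# nslices="):
        raise ValueError(f"{path}: not a mask stack file")
    fields = dict(tok.split("=", 1) for tok in header[2:].split(" "))
    sy, sx = (float(v) for v in fields["spacing"].split("x"))
    rows = [ln for ln in text[1:] if ln and not ln.startswith("#")]
    ny, nx = int(fields["ny"]), int(fields["nx"])
    n_slices = int(fields["nslices"])
    data = np.array([[int(ch) for ch in ln] for ln in rows], dtype=bool)
    if data.shape != (n_slices * ny, nx):
        raise ValueError(f"{path}: mask data does not match header geometry")
    return MaskStack(
        slices=data.reshape(n_slices, ny, nx),
        pixel_spacing_mm=(sy, sx),
        slice_thickness_mm=float(fields["thickness"]),
        subject=fields.get("subject", ""),
        phase=fields.get("phase", "ED"),
    )


def write_estimate_matrix(path: str | Path, matrix: pd.DataFrame,
                          subgroups: pd.Series | None = None) -> None:
    """CSV with a subject index, optional subgroup column, method columns."""
    out = pd.DataFrame(matrix).copy()
    if subgroups is None:
        subgroups = out.attrs.get("subgroup")
    if subgroups is not None:
        out.insert(0, "subgroup", pd.Series(subgroups).reindex(out.index))
    out.to_csv(path, index_label="subject")


def read_estimate_matrix(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_estimate_matrix`; subgroup labels (if present)
    land in ``matrix.attrs['subgroup']``."""
    df = pd.read_csv(path, index_col="subject")
    if "subgroup" in df.columns:
        sg = df.pop("subgroup")
        df.attrs["subgroup"] = sg
    return df


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_cohort(
    outdir: str | Path,
    spec: CohortSpec,
    rater_profiles: Mapping[str, RaterProfile],
    phases: Sequence[str] = ("ED", "ES"),
    write_contours: bool = True,
) -> pd.DataFrame:
    """Materialize a synthetic cohort on disk.

    Writes, under ``outdir``: one mask-stack file (and optionally per-slice
    contour files) per subject/method/phase, a ``manifest.csv`` (subject,
    subgroup, method, phase, path) and a ``truth.csv`` with the latent true
    values.  Returns the manifest.
    """
    from . import synthetic  # deferred to avoid an import cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_table = synthetic.cohort_truth_table(spec)
    truth_table.to_csv(outdir / "truth.csv", index=False)
    records = []
    for si, (subject, sg) in enumerate(spec.subject_labels()):
        for phase in phases:
            truth = synthetic.simulate_lv_truth(spec, subject, phase)
            pap = synthetic.simulate_papillary(spec, subject, phase)
            sd = synthetic.signed_distance_stack(truth)
            for ri, (label, prof) in enumerate(rater_profiles.items()):
                mask = synthetic.simulate_rater(
                    truth, prof, seed=spec.seed + si, papillary=pap, rater_index=ri,
                    signed_distance=sd,
                )
                d = outdir / subject / label
                d.mkdir(parents=True, exist_ok=True)
                mpath = d / f"{phase}.mask.txt"
                write_mask_stack(mpath, mask)
                if write_contours:
                    for s in range(mask.n_slices):
                        for ci, poly in enumerate(mask_to_contours(mask.slices[s])):
                            write_contour(d / f"{phase}.slice{s:02d}.c{ci}.txt", poly)
                records.append({
                    "subject": subject, "subgroup": sg, "method": label,
                    "phase": phase, "path": str(mpath.relative_to(outdir)),
                })
    manifest = pd.DataFrame(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
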