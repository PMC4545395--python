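"""Synthetic cohorts with the statistical structure the ranking model assumes.

Two layers:

* **Estimate level** — latent truths drawn from a Beta distribution with
  finite support, observed through per-method linear models
  ``theta_pk = a_k * Theta_p + b_k + eps_pk`` with independent Gaussian
  errors.  This is exactly the generative model the ranking machinery fits,
  so it supports parameter-recovery studies.
* **Mask level** — left-ventricle cavity stacks rendered as stacked discs
  whose radii shrink from base to apex and from end-diastole (ED) to
  end-systole (ES) so that the implied ejection fraction hits a target, plus
  simulated raters that displace the true boundary radially (systematic
  bias, smooth angular jitter, optional papillary-muscle exclusion).

Random streams are split per subject and rater via ``np.random.SeedSequence``
spawn keys, so adding a rater never perturbs existing draws.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage import measure

from .types import (
    BetaShape,
    CohortSpec,
    GridGeometry,
    MaskStack,
    MethodProfile,
    RaterProfile,
)

__all__ = [
    "simulate_true_values",
    "simulate_estimates",
    "simulate_lv_truth",
    "simulate_papillary",
    "simulate_epicardial",
    "simulate_rater",
    "signed_distance_stack",
    "cohort_truth_table",
]

# stream tags keep subject/rater substreams disjoint
_STREAM_TRUTH = 0
_STREAM_RATER = 1
_STREAM_ESTIMATES = 2

# fraction of the long axis covered from base to apex (apex slice keeps a
# small non-zero radius, as the apical cap is rarely segmented to a point)
_APEX_FRACTION = 0.9
_PAPILLARY_RADIUS_MM = 3.5
_PAPILLARY_OFFSET_FRACTION = 0.45
_MIN_PAPILLARY_CAVITY_RADIUS_MM = 12.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_true_values(P: int, shape: BetaShape, seed: int) -> np.ndarray:
    """Draw ``P`` i.i.d. latent truths from ``Beta(mu, nu)`` on (0, 1).

    Values are clipped 1e-6 away from the support endpoints so downstream
    log-likelihoods never see an exact 0 or 1.
    """
    if P < 1:
        raise ValueError("P must be at least 1")
    draws = _rng(seed, _STREAM_TRUTH).beta(shape.mu, shape.nu, size=P)
    return np.clip(draws, 1e-6, 1.0 - 1e-6)


def simulate_estimates(
    truths: np.ndarray, profiles: Sequence[MethodProfile], seed: int
) -> pd.DataFrame:
    """Observe latent truths through per-method linear models.

    Returns a subjects x methods DataFrame where column ``k`` holds
    ``slope_k * Theta_p + intercept_k + Normal(0, noise_sd_k)``, with errors
    independent across subjects and methods.
    """
    truths = np.asarray(truths, dtype=float)
    if truths.ndim != 1 or truths.size < 1:
        raise ValueError("truths must be a non-empty 1D array")
    if len(profiles) < 2:
        raise ValueError("need at least 2 method profiles")
    P = truths.size
    cols = {}
    for k, prof in enumerate(profiles):
        eps = _rng(seed, _STREAM_ESTIMATES, k).normal(0.0, prof.noise_sd, size=P) \
            if prof.noise_sd > 0 else np.zeros(P)
        label = prof.label or f"M{k + 1}"
        cols[label] = prof.slope * truths + prof.intercept + eps
    if len(cols) != len(profiles):
        raise ValueError("method profile labels must be unique")
    return pd.DataFrame(cols, index=pd.RangeIndex(P, name="subject"))


def cohort_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject latent truth: subject id, subgroup, true LVEF, ED volume."""
    rows = []
    for idx, (subject, sg) in enumerate(spec.subject_labels()):
        regime = spec.subgroup_truth[sg]
        a = regime.lvef_mean * regime.lvef_concentration
        b = (1.0 - regime.lvef_mean) * regime.lvef_concentration
        lvef = float(np.clip(_rng(spec.seed, _STREAM_TRUTH, idx).beta(a, b), 1e-6, 1 - 1e-6))
        rows.append({"subject": subject, "subgroup": sg, "lvef_true": lvef,
                     "edv_ml": regime.edv_ml})
    return pd.DataFrame(rows)


def _radius_profile(geometry: GridGeometry, edv_ml: float) -> np.ndarray:
    """Per-slice disc radii (mm) whose summed-disc volume equals ``edv_ml``."""
    u = np.linspace(0.0, _APEX_FRACTION, geometry.n_slices)
    f = np.sqrt(1.0 - u**2)
    # sum_s pi (r_base f_s)^2 * thickness / 1000 = EDV
    r_base = math.sqrt(edv_ml * 1000.0 / (math.pi * geometry.slice_thickness_mm * float(np.sum(f**2))))
    radii = r_base * f
    half_extent = geometry.grid_size * geometry.pixel_spacing_mm / 2.0
    if r_base > 0.85 * half_extent:
        raise ValueError(
            f"EDV {edv_ml} ml needs a radius of {r_base:.1f} mm, too large for the "
            f"{geometry.grid_size}-pixel grid at {geometry.pixel_spacing_mm} mm spacing"
        )
    return radii


def _render_discs(geometry: GridGeometry, radii_mm: np.ndarray) -> np.ndarray:
    n = geometry.grid_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - c, xx - c) * geometry.pixel_spacing_mm
    return dist[None, :, :] <= np.asarray(radii_mm)[:, None, None]


def _truth_radii(spec: CohortSpec, subject: str, phase: str) -> tuple[np.ndarray, float]:
    labels = dict(spec.subject_labels())
    if subject not in labels:
        raise KeyError(f"unknown subject {subject!r}")
    if phase not in ("ED", "ES"):
        raise ValueError("phase must be 'ED' or 'ES'")
    truth = cohort_truth_table(spec)
    row = truth.loc[truth["subject"] == subject].iloc[0]
    lvef = float(row["lvef_true"])
    if not 0.0 < lvef < 1.0:
        raise ValueError("target LVEF must lie in (0, 1)")
    radii = _radius_profile(spec.geometry, float(row["edv_ml"]))
    if phase == "ES":
        # concentric contraction: scaling every radius by sqrt(1 - LVEF)
        # scales each disc area, hence the summed volume, by (1 - LVEF)
        radii = radii * math.sqrt(1.0 - lvef)
    return radii, lvef


def simulate_lv_truth(spec: CohortSpec, subject: str, phase: str) -> MaskStack:
    """Render the true LV cavity stack for one subject and phase.

    Each slice is a filled disc; radii shrink smoothly from base to apex and,
    at ES, are scaled concentrically so the implied ejection fraction matches
    the subject's latent truth up to rasterization error.  Papillary muscles
    are part of the cavity (blood-pool convention); raters that exclude them
    subtract :func:`simulate_papillary`.
    """
    radii, _ = _truth_radii(spec, subject, phase)
    g = spec.geometry
    return MaskStack(
        slices=_render_discs(g, radii),
        pixel_spacing_mm=(g.pixel_spacing_mm, g.pixel_spacing_mm),
        slice_thickness_mm=g.slice_thickness_mm,
        subject=subject,
        phase=phase,
    )


def simulate_papillary(spec: CohortSpec, subject: str, phase: str) -> MaskStack:
    """Papillary-muscle regions: two small discs inside the cavity on slices
    where the cavity is wide enough.  Deterministic companion of
    :func:`simulate_lv_truth`."""
    radii, _ = _truth_radii(spec, subject, phase)
    g = spec.geometry
    n = g.grid_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    out = np.zeros((g.n_slices, n, n), dtype=bool)
    for s, r in enumerate(radii):
        if r < _MIN_PAPILLARY_CAVITY_RADIUS_MM:
            continue
        off = _PAPILLARY_OFFSET_FRACTION * r / g.pixel_spacing_mm
        for dy, dx in ((-off, -off * 0.4), (off * 0.6, off * 0.5)):
            d = np.hypot(yy - (c + dy), xx - (c + dx)) * g.pixel_spacing_mm
            out[s] |= d <= _PAPILLARY_RADIUS_MM
    return MaskStack(
        slices=out,
        pixel_spacing_mm=(g.pixel_spacing_mm, g.pixel_spacing_mm),
        slice_thickness_mm=g.slice_thickness_mm,
        subject=subject,
        phase=phase,
    )


def simulate_epicardial(spec: CohortSpec, subject: str, phase: str = "ED",
                        wall_mm: float = 9.0) -> MaskStack:
    """Epicardial stack: cavity radii plus a uniform wall thickness (mm)."""
    if wall_mm <= 0:
        raise ValueError("wall_mm must be positive")
    radii, _ = _truth_radii(spec, subject, phase)
    g = spec.geometry
    return MaskStack(
        slices=_render_discs(g, radii + wall_mm),
        pixel_spacing_mm=(g.pixel_spacing_mm, g.pixel_spacing_mm),
        slice_thickness_mm=g.slice_thickness_mm,
        subject=subject,
        phase=phase,
    )


def _jitter_field(theta: np.ndarray, sd_mm: float, rng: np.random.Generator,
                  harmonics: int = 6) -> np.ndarray:
    """Smooth zero-mean angular perturbation with pointwise SD ``sd_mm``."""
    if sd_mm == 0.0:
        return np.zeros_like(theta)
    amp = sd_mm / math.sqrt(harmonics)
    field = np.zeros_like(theta)
    for h in range(1, harmonics + 1):
        a, b = rng.normal(0.0, amp, size=2)
        field += a * np.cos(h * theta) + b * np.sin(h * theta)
    return field


def _signed_distance_mm(mask: np.ndarray, spacing: tuple[float, float],
                        band_mm: float = 9.0) -> np.ndarray:
    """Signed distance (mm, negative inside) from pixel centers to the
    sub-pixel mask boundary.

    The boundary is the marching-squares 0.5-level contour, whose vertices
    sit between pixel centers with linear-interpolation precision, so
    boundary displacements well below one pixel pitch still flip the pixels
    they should (a lattice-quantized distance transform would make any
    offset smaller than the pixel spacing a no-op).  Pixels further than
    ``band_mm`` from the boundary keep the cheap lattice distance — only
    near-boundary pixels, where thresholding decisions happen, get the
    exact contour distance.
    """
    sy, sx = spacing
    inside = distance_transform_edt(mask, sampling=(sy, sx))
    outside = distance_transform_edt(~mask, sampling=(sy, sx))
    signed = outside - inside
    pts = []
    for c in measure.find_contours(mask.astype(float), 0.5):
        seg = np.column_stack([c[:, 0] * sy, c[:, 1] * sx])
        # densify segments so point-to-polyline distance ~ point-to-points
        d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        for (p0, p1), length in zip(zip(seg[:-1], seg[1:]), d):
            n = max(1, int(np.ceil(length / (0.25 * min(sy, sx)))))
            frac = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
            pts.append(p0 + frac * (p1 - p0))
    if not pts:
        return np.where(mask, -np.inf, np.inf)
    tree = cKDTree(np.concatenate(pts))
    band = np.abs(signed) <= band_mm
    yy, xx = np.nonzero(band)
    centers = np.column_stack([yy * sy, xx * sx])
    dist = tree.query(centers, workers=1)[0]
    signed[band] = np.where(mask[band], -dist, dist)
    return signed


def signed_distance_stack(truth: MaskStack) -> np.ndarray:
    """Per-slice signed distance fields (mm) to the truth boundary; shared
    by every simulated rater of the same subject/phase."""
    out = np.full(truth.slices.shape, np.inf)
    for s in range(truth.n_slices):
        if truth.slices[s].any():
            out[s] = _signed_distance_mm(truth.slices[s], truth.pixel_spacing_mm)
    return out


def simulate_rater(
    truth: MaskStack,
    profile: RaterProfile,
    seed: int,
    papillary: MaskStack | None = None,
    rater_index: int = 0,
    signed_distance: np.ndarray | None = None,
) -> MaskStack:
    """Apply a rater's spatial error profile to a true mask stack.

    The true boundary of each slice is displaced along its signed distance
    field: a pixel belongs to the rater's mask iff its signed distance
    (negative inside, sub-pixel resolution) does not exceed
    ``boundary_bias_mm + J(theta)``, where ``J`` is a smooth angular jitter
    field with SD ``jitter_sd_mm`` (independent per slice).  For star-shaped
    masks this is a radial displacement of the contour.
    """
    if papillary is not None and not truth.same_geometry(papillary):
        raise ValueError("papillary stack geometry does not match truth")
    out = truth.copy()
    if profile.boundary_bias_mm == 0.0 and profile.jitter_sd_mm == 0.0:
        pass  # identity profile: rater reproduces the truth exactly
    else:
        rng = _rng(seed, _STREAM_RATER, rater_index)
        sy, sx = truth.pixel_spacing_mm
        if signed_distance is None:
            signed_distance = signed_distance_stack(truth)
        elif signed_distance.shape != truth.slices.shape:
            raise ValueError("signed_distance shape does not match truth stack")
        new_slices = np.zeros_like(truth.slices)
        for s in range(truth.n_slices):
            m = truth.slices[s]
            if not m.any():
                continue
            signed = signed_distance[s]
            cy, cx = np.argwhere(m).mean(axis=0)
            yy, xx = np.mgrid[0:m.shape[0], 0:m.shape[1]]
            theta = np.arctan2((yy - cy) * sy, (xx - cx) * sx)
            offset = profile.boundary_bias_mm + _jitter_field(
                theta, profile.jitter_sd_mm, rng
            )
            new_slices[s] = signed <= offset
        out.slices = new_slices
    if not profile.include_papillary and papillary is not None:
        out.slices = out.slices & ~papillary.slices
    return out
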