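"""Binary STAPLE label fusion via expectation-maximization.

STAPLE (Simultaneous Truth and Performance Level Estimation) fuses several
binary segmentations of the same image into a probabilistic consensus while
estimating each rater's sensitivity ``p_j`` and specificity ``q_j``.

With decisions ``D_ij`` (rater ``j`` on pixel ``i``) and foreground prior
``gamma_i``, each EM iteration computes

* E-step: ``W_i = alpha_i / (alpha_i + beta_i)`` with
  ``alpha_i = gamma_i * prod_j p_j^{D_ij} (1 - p_j)^{1 - D_ij}`` and
  ``beta_i = (1 - gamma_i) * prod_j q_j^{1 - D_ij} (1 - q_j)^{D_ij}``;
* M-step: ``p_j = sum_{i: D_ij=1} W_i / sum_i W_i`` and
  ``q_j = sum_{i: D_ij=0} (1 - W_i) / sum_i (1 - W_i)``.

Fusion is strictly per-slice (short-axis stacks are too anisotropic for a
3D neighbourhood to help); slice results are stacked back into a 3D mask.
The EM runs inside the union bounding box of the rater masks, which makes
the result independent of how much background surrounds the structure.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import ConsensusResult, MaskStack, PerformanceLevel

__all__ = [
    "StapleFusion",
    "staple_slice",
    "fuse_stack",
    "crop_to_roi",
    "binarize",
]

logger = logging.getLogger(__name__)

# clip bounds keep logs finite at p,q -> {0,1} without perturbing any
# trajectory that stays away from exact 0/1
_PQ_FLOOR = 1e-300
_PQ_CEIL = 1.0 - 1e-16


def binarize(probability_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a posterior probability map; ties (W == threshold) go to
    background, which keeps the fused cavity conservative."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    w = np.asarray(probability_map, dtype=float)
    if w.size and (w.min() < -1e-12 or w.max() > 1 + 1e-12):
        raise ValueError("probability map values must lie in [0, 1]")
    return w > threshold


def crop_to_roi(
    rater_masks: Sequence[np.ndarray], margin: int = 2
) -> tuple[list[np.ndarray], tuple[slice, slice]]:
    """Crop all masks to the union bounding box of their foreground.

    Returns the cropped masks and the (row, col) slices into the original
    grid, so a fused result can be re-embedded.  Because the EM prior and
    statistics are computed inside this box, the fused result does not
    depend on the amount of surrounding background.
    """
    if not rater_masks:
        raise ValueError("no masks given")
    union = np.zeros_like(np.asarray(rater_masks[0], dtype=bool))
    for m in rater_masks:
        union |= np.asarray(m, dtype=bool)
    if not union.any():
        raise ValueError("all masks empty: no foreground to define an ROI")
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    r = slice(max(rows[0] - margin, 0), min(rows[-1] + margin + 1, union.shape[0]))
    c = slice(max(cols[0] - margin, 0), min(cols[-1] + margin + 1, union.shape[1]))
    return [np.asarray(m, dtype=bool)[r, c] for m in rater_masks], (r, c)


def _observed_loglik(log_a: np.ndarray, log_b: np.ndarray) -> float:
    """Observed-data log-likelihood sum_i log(alpha_i + beta_i); EM
    guarantees this never decreases across iterations."""
    m = np.maximum(log_a, log_b)
    return float(np.sum(m + np.log(np.exp(log_a - m) + np.exp(log_b - m))))


def staple_slice(
    rater_masks: Sequence[np.ndarray],
    init_p: float = 0.99,
    init_q: float = 0.99,
    prior: float | np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
    rater_labels: Sequence[str] | None = None,
) -> ConsensusResult:
    """Run binary STAPLE EM on one slice.

    ``prior`` is the foreground prior ``gamma_i`` (scalar or per-pixel map);
    if None it defaults to the mean foreground fraction of the rater masks.
    Raters that submit an empty mask on this slice are excluded from the EM
    for the slice (their performance is reported as NaN) rather than letting
    them drag ``q_j`` to a boundary.  An all-empty slice is returned as a
    degenerate empty consensus.
    """
    if len(rater_masks) < 2:
        raise ValueError("need at least 2 raters")
    if tol <= 0:
        raise ValueError("tol must be positive")
    shape = np.asarray(rater_masks[0]).shape
    masks = []
    for m in rater_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError("rater masks must share a common grid shape")
        masks.append(m)
    labels = list(rater_labels) if rater_labels is not None else [
        f"rater{j + 1}" for j in range(len(masks))
    ]
    if len(labels) != len(masks):
        raise ValueError("rater_labels length mismatch")

    active = [j for j, m in enumerate(masks) if m.any()]
    if not active:
        return ConsensusResult(
            probability_map=np.zeros(shape, dtype=float),
            performance=[PerformanceLevel(math.nan, math.nan, lab) for lab in labels],
            iterations=1,
            converged=True,
            degenerate=True,
        )
    if len(active) < len(masks):
        logger.warning(
            "excluding %d empty rater mask(s) from this slice's EM",
            len(masks) - len(active),
        )
    D = np.stack([masks[j].ravel() for j in active], axis=1).astype(float)  # (n, J)
    n_pix, J = D.shape

    if prior is None:
        gamma = np.full(n_pix, float(D.mean()))
    elif np.isscalar(prior):
        if not 0.0 < float(prior) < 1.0:
            raise ValueError("scalar prior must lie in (0, 1)")
        gamma = np.full(n_pix, float(prior))
    else:
        gamma = np.asarray(prior, dtype=float).ravel()
        if gamma.size != n_pix:
            raise ValueError("per-pixel prior shape mismatch")
        gamma = np.clip(gamma, _PQ_FLOOR, _PQ_CEIL)

    p = np.full(J, float(init_p))
    q = np.full(J, float(init_q))
    w = np.empty(n_pix)
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log space: stable for many raters or extreme p, q)
        pc = np.clip(p, _PQ_FLOOR, _PQ_CEIL)
        qc = np.clip(q, _PQ_FLOOR, _PQ_CEIL)
        log_a = np.log(gamma) + D @ np.log(pc) + (1 - D) @ np.log1p(-pc)
        log_b = np.log1p(-gamma) + (1 - D) @ np.log(qc) + D @ np.log1p(-qc)
        m = np.maximum(log_a, log_b)
        w = np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m))
        ll = _observed_loglik(log_a, log_b)
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            warnings.warn("EM log-likelihood decreased; numerical trouble")
        prev_ll = ll
        trace.append(ll)
        # M-step
        sw = w.sum()
        snw = n_pix - sw
        new_p = (D.T @ w) / sw if sw > 0 else p
        new_q = ((1 - D).T @ (1 - w)) / snw if snw > 0 else q
        delta = max(np.abs(new_p - p).max(), np.abs(new_q - q).max())
        p, q = new_p, new_q
        if delta < tol:
            converged = True
            break

    # final E-step so the returned posterior matches the returned (p, q)
    pc = np.clip(p, _PQ_FLOOR, _PQ_CEIL)
    qc = np.clip(q, _PQ_FLOOR, _PQ_CEIL)
    log_a = np.log(gamma) + D @ np.log(pc) + (1 - D) @ np.log1p(-pc)
    log_b = np.log1p(-gamma) + (1 - D) @ np.log(qc) + D @ np.log1p(-qc)
    m = np.maximum(log_a, log_b)
    w = np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m))
    trace.append(_observed_loglik(log_a, log_b))

    perf: list[PerformanceLevel] = []
    by_active = {j: (float(p[a]), float(q[a])) for a, j in enumerate(active)}
    for j, lab in enumerate(labels):
        if j in by_active:
            pj, qj = by_active[j]
            perf.append(PerformanceLevel(min(max(pj, 0.0), 1.0), min(max(qj, 0.0), 1.0), lab))
        else:
            perf.append(PerformanceLevel(math.nan, math.nan, lab))
    return ConsensusResult(
        probability_map=np.clip(w, 0.0, 1.0).reshape(shape),
        performance=perf,
        iterations=it,
        converged=converged,
        loglik_trace=trace,
    )


@dataclass
class StapleSettings:
    init_p: float = 0.99
    init_q: float = 0.99
    prior: float | None = None  # None -> mean foreground fraction in the ROI
    tol: float = 1e-7
    max_iter: int = 200
    threshold: float = 0.5
    roi_margin: int = 2


def fuse_stack(
    rater_stacks: Sequence[MaskStack],
    settings: StapleSettings | None = None,
) -> tuple[MaskStack, list[ConsensusResult]]:
    """Fuse congruent mask stacks slice by slice and restack the result.

    Each slice is cropped to the union ROI, fused with :func:`staple_slice`,
    binarized at ``settings.threshold`` and re-embedded into the full grid.
    Returns the fused stack and the per-slice consensus results (probability
    maps re-embedded; per-rater performance levels retained).
    """
    settings = settings or StapleSettings()
    if len(rater_stacks) < 2:
        raise ValueError("need at least 2 stacks")
    ref = rater_stacks[0]
    for st in rater_stacks[1:]:
        if not ref.same_geometry(st):
            raise ValueError("rater stacks must share geometry (shape, spacing, thickness)")
    labels = [f"rater{j + 1}" for j in range(len(rater_stacks))]

    fused = np.zeros_like(ref.slices)
    results: list[ConsensusResult] = []
    for s in range(ref.n_slices):
        slice_masks = [st.slices[s] for st in rater_stacks]
        if not any(m.any() for m in slice_masks):
            results.append(
                ConsensusResult(
                    probability_map=np.zeros(ref.grid_shape, dtype=float),
                    performance=[PerformanceLevel(math.nan, math.nan, lab) for lab in labels],
                    iterations=1,
                    converged=True,
                    degenerate=True,
                )
            )
            continue
        cropped, (r, c) = crop_to_roi(slice_masks, margin=settings.roi_margin)
        res = staple_slice(
            cropped,
            init_p=settings.init_p,
            init_q=settings.init_q,
            prior=settings.prior,
            tol=settings.tol,
            max_iter=settings.max_iter,
            rater_labels=labels,
        )
        full_w = np.zeros(ref.grid_shape, dtype=float)
        full_w[r, c] = res.probability_map
        res.probability_map = full_w
        fused[s] = binarize(full_w, settings.threshold)
        results.append(res)
    fused_stack = MaskStack(
        slices=fused,
        pixel_spacing_mm=ref.pixel_spacing_mm,
        slice_thickness_mm=ref.slice_thickness_mm,
        subject=ref.subject,
        phase=ref.phase,
    )
    return fused_stack, results


class StapleFusion:
    """Estimator-style wrapper around per-slice binary STAPLE fusion.

    Parameters mirror :class:`StapleSettings`.  After :meth:`fit` on a list
    of congruent :class:`MaskStack` the fused mask is in ``consensus_``, the
    per-slice posterior results in ``slice_results_`` and the per-rater
    performance averaged over non-degenerate slices in ``sensitivity_`` /
    ``specificity_``.
    """

    def __init__(self, init_p: float = 0.99, init_q: float = 0.99,
                 prior: float | None = None, tol: float = 1e-7,
                 max_iter: int = 200, threshold: float = 0.5,
                 roi_margin: int = 2):
        self.init_p = init_p
        self.init_q = init_q
        self.prior = prior
        self.tol = tol
        self.max_iter = max_iter
        self.threshold = threshold
        self.roi_margin = roi_margin

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("init_p", "init_q", "prior", "tol", "max_iter", "threshold", "roi_margin")}

    def set_params(self, **params) -> "StapleFusion":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, rater_stacks: Sequence[MaskStack]) -> "StapleFusion":
        settings = StapleSettings(
            init_p=self.init_p, init_q=self.init_q, prior=self.prior,
            tol=self.tol, max_iter=self.max_iter, threshold=self.threshold,
            roi_margin=self.roi_margin,
        )
        self.consensus_, self.slice_results_ = fuse_stack(rater_stacks, settings)
        J = len(rater_stacks)
        sens = np.full(J, np.nan)
        spec = np.full(J, np.nan)
        for j in range(J):
            ps = [r.performance[j].sensitivity for r in self.slice_results_
                  if not r.degenerate and not math.isnan(r.performance[j].sensitivity)]
            qs = [r.performance[j].specificity for r in self.slice_results_
                  if not r.degenerate and not math.isnan(r.performance[j].specificity)]
            if ps:
                sens[j] = float(np.mean(ps))
            if qs:
                spec[j] = float(np.mean(qs))
        self.sensitivity_ = sens
        self.specificity_ = spec
        self.n_raters_ = J
        return self

    def fit_transform(self, rater_stacks: Sequence[MaskStack]) -> MaskStack:
        return self.fit(rater_stacks).consensus_
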