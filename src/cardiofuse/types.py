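"""Shared domain types.

The package works with two in-memory containers throughout:

* :class:`MaskStack` — an ordered stack of 2D binary masks with physical
  voxel geometry (in-plane pixel spacing and slice thickness in mm), one
  stack per subject/phase/rater.  Short-axis cine MRI is strongly
  anisotropic (typically 1.25 mm in-plane vs 8 mm between slices), which is
  why all mask processing here is per-slice.
* estimate matrices — plain :class:`pandas.DataFrame` with one row per
  subject and one column per method, carrying the per-subject biomarker
  estimates (e.g. LVEF) that the ranking machinery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BetaShape",
    "MethodProfile",
    "RaterProfile",
    "GridGeometry",
    "CohortSpec",
    "MaskStack",
    "PerformanceLevel",
    "ConsensusResult",
    "ClinicalIndices",
]


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters (mu, nu) of the Beta distribution of the latent truth."""

    mu: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.nu > 0):
            raise ValueError(f"Beta shape parameters must be positive, got ({self.mu}, {self.nu})")

    @property
    def mean(self) -> float:
        return self.mu / (self.mu + self.nu)

    @property
    def variance(self) -> float:
        s = self.mu + self.nu
        return self.mu * self.nu / (s * s * (s + 1.0))


@dataclass(frozen=True)
class MethodProfile:
    """Linear observation model of one measurement method.

    An estimate of the latent truth ``t`` is generated as
    ``slope * t + intercept + Normal(0, noise_sd)``, independently per
    subject.  All three parameters live on the unit scale of the biomarker.
    """

    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class RaterProfile:
    """Spatial error profile of one simulated contouring rater.

    ``boundary_bias_mm`` displaces the true boundary radially outward
    (positive, over-delineation) or inward (negative, under-delineation).
    ``jitter_sd_mm`` adds smooth angular noise on top.  Raters with
    ``include_papillary=False`` carve the papillary-muscle regions out of
    the cavity, mimicking methods that exclude them from the blood pool.
    """

    boundary_bias_mm: float = 0.0
    jitter_sd_mm: float = 0.0
    include_papillary: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter_sd_mm must be non-negative")


@dataclass(frozen=True)
class GridGeometry:
    """Image grid: square matrix size, in-plane spacing, thickness, slice count."""

    grid_size: int = 96
    pixel_spacing_mm: float = 1.25
    slice_thickness_mm: float = 8.0
    n_slices: int = 9

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size too small")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")


@dataclass(frozen=True)
class SubgroupTruth:
    """Truth regime of one clinical subgroup.

    LVEF truths are drawn from Beta(mean*concentration, (1-mean)*concentration),
    i.e. a Beta reparametrised by mean and concentration; ``edv_ml`` sets the
    end-diastolic cavity size used when rendering mask stacks.
    """

    lvef_mean: float
    lvef_concentration: float
    edv_ml: float = 140.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lvef_mean < 1.0:
            raise ValueError("lvef_mean must be in (0, 1)")
        if self.lvef_concentration <= 0 or self.edv_ml <= 0:
            raise ValueError("concentration and edv_ml must be positive")


def default_subgroups() -> dict[str, SubgroupTruth]:
    # Centers follow the clinical regimes of the four-subgroup cohort:
    # heart-failure subgroups with reduced LVEF (pathological <= 0.45),
    # hypertrophic and control subgroups in the normal range.
    return {
        "HF-I": SubgroupTruth(lvef_mean=0.26, lvef_concentration=45.0, edv_ml=220.0),
        "HF-NI": SubgroupTruth(lvef_mean=0.32, lvef_concentration=40.0, edv_ml=210.0),
        "HYP": SubgroupTruth(lvef_mean=0.64, lvef_concentration=75.0, edv_ml=130.0),
        "CTRL": SubgroupTruth(lvef_mean=0.64, lvef_concentration=110.0, edv_ml=120.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    Defaults mirror the study cohort: 45 subjects split CTRL n=9, HYP n=12,
    HF-NI n=12, HF-I n=12, on an 8 mm / 1.25 mm short-axis grid.
    """

    n_per_subgroup: Mapping[str, int] = field(
        default_factory=lambda: {"HF-I": 12, "HF-NI": 12, "HYP": 12, "CTRL": 9}
    )
    subgroup_truth: Mapping[str, SubgroupTruth] = field(default_factory=default_subgroups)
    geometry: GridGeometry = field(default_factory=GridGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.n_per_subgroup.items():
            if n < 1:
                raise ValueError(f"subgroup {label!r} must have at least one subject")
            if label not in self.subgroup_truth:
                raise ValueError(f"no truth regime for subgroup {label!r}")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_subgroup.values())

    def subject_labels(self) -> list[tuple[str, str]]:
        """Ordered list of (subject_id, subgroup)."""
        out = []
        for sg in self.n_per_subgroup:
            for i in range(self.n_per_subgroup[sg]):
                out.append((f"{sg}-{i + 1:02d}", sg))
        return out


@dataclass
class MaskStack:
    """Ordered stack of 2D binary masks with physical geometry."""

    slices: np.ndarray  # (n_slices, ny, nx) boolean
    pixel_spacing_mm: tuple[float, float] = (1.25, 1.25)
    slice_thickness_mm: float = 8.0
    subject: str = ""
    phase: str = "ED"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n_slices, ny, nx) array")
        if self.slices.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if self.slices.dtype != bool:
            vals = np.unique(self.slices)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask labels must be binary")
            self.slices = self.slices.astype(bool)
        if min(self.pixel_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacing and thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]

    def copy(self) -> "MaskStack":
        return replace(self, slices=self.slices.copy())

    def same_geometry(self, other: "MaskStack") -> bool:
        return (
            self.slices.shape == other.slices.shape
            and self.pixel_spacing_mm == other.pixel_spacing_mm
            and self.slice_thickness_mm == other.slice_thickness_mm
        )


@dataclass(frozen=True)
class PerformanceLevel:
    """Sensitivity p_j and specificity q_j of one rater against the consensus."""

    sensitivity: float
    specificity: float
    rater: str = ""

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError("performance levels must lie in [0, 1]")


@dataclass
class ConsensusResult:
    """Posterior foreground probability map plus per-rater performance."""

    probability_map: np.ndarray
    performance: list[PerformanceLevel]
    iterations: int
    converged: bool
    degenerate: bool = False
    loglik_trace: list[float] | None = None


@dataclass(frozen=True)
class ClinicalIndices:
    """The six cardiac function parameters derived from cavity volumes.

    LVEF is stored as a fraction; tables report percent.  ``implausible``
    flags ESV > EDV (physically impossible; kept, not discarded).
    """

    edv_ml: float
    esv_ml: float
    sv_ml: float
    lvef: float
    epv_ml: float | None = None
    mm_g: float | None = None
    implausible: bool = False

    @property
    def lvef_percent(self) -> float:
        return 100.0 * self.lvef

    @property
    def pathological(self) -> bool:
        """Reduced LVEF (<= 0.45) marks the pathological regime."""
        return self.lvef <= 0.45
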