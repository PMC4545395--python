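"""End-to-end orchestration: simulate -> fuse -> indices -> evaluate.

A run reproduces the study design on a synthetic cohort: expert-like and
automated-like raters contour every subject at ED and ES; every subset of
at least three automated raters is fused with STAPLE into a candidate
method; cavity volumes give per-subject LVEF estimates; each candidate is
then ranked against the original raters by eRWT bootstrap ranking, and all
methods are compared to a reference rater by bias/limits of agreement.

Run directory layout: ``raw/ fused/ indices/ fits/ rankings/ reports/``
plus a ``run.yaml`` provenance file echoing the full configuration.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io, synthetic
from .erwt import ErwtModel
from .indices import cohort_table, indices_from_masks, subgroup_summary
from .ranking import bootstrap_foms, pairwise_ranking
from .staple import StapleFusion
from .supervised import bias_report, combination_bias_correlation
from .types import CohortSpec, GridGeometry, MaskStack, RaterProfile, SubgroupTruth

__all__ = ["CombinationPlan", "enumerate_combinations", "default_rater_profiles",
           "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombinationPlan:
    """Subsets of the automated methods selected for fusion."""

    base_methods: tuple[str, ...]
    subsets: tuple[tuple[str, ...], ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(len(s) < 2 for s in self.subsets):
            raise ValueError("every fusion subset needs at least 2 members")
        if len(set(self.names)) != len(self.names):
            raise ValueError("combination names must be unique")


def _suffix(label: str) -> str:
    m = re.search(r"(\d+)$", label)
    return m.group(1) if m else label


def enumerate_combinations(methods: Sequence[str], min_size: int = 3) -> CombinationPlan:
    """All subsets of size ``min_size`` .. len(methods), named "MS" plus the
    concatenated numeric suffixes of their sorted members (so fusing M4, M5,
    M6 is called MS456).  Five methods at min_size 3 give 10 + 5 + 1 = 16."""
    methods = [str(m) for m in methods]
    if len(methods) < min_size:
        raise ValueError(f"need at least {min_size} methods, got {len(methods)}")
    subsets = []
    for size in range(min_size, len(methods) + 1):
        subsets.extend(itertools.combinations(methods, size))
    names = tuple("MS" + "".join(_suffix(m) for m in sorted(s)) for s in subsets)
    return CombinationPlan(base_methods=tuple(methods), subsets=tuple(subsets), names=names)


def default_rater_profiles() -> dict[str, RaterProfile]:
    """Three expert-like raters (small jitter, negligible bias) and five
    automated-like raters with larger systematic bias and jitter.  The
    under-delineating rater A2 also excludes the papillary muscles from the
    cavity, like segmentation methods that carve them out of the blood pool."""
    return {
        "E1": RaterProfile(0.0, 0.6, True, "E1"),
        "E2": RaterProfile(0.0, 0.4, True, "E2"),
        "E3": RaterProfile(0.2, 0.5, True, "E3"),
        "A1": RaterProfile(0.5, 1.0, True, "A1"),
        "A2": RaterProfile(-1.5, 1.5, False, "A2"),
        "A3": RaterProfile(2.2, 1.5, True, "A3"),
        "A4": RaterProfile(-2.0, 1.8, True, "A4"),
        "A5": RaterProfile(1.8, 1.6, True, "A5"),
    }


_CONFIG_KEYS = {
    "seed", "n_per_subgroup", "grid_size", "pixel_spacing_mm", "slice_thickness_mm",
    "n_slices", "expert_methods", "automated_methods", "min_combination_size",
    "candidates", "mu", "nu", "n_boot", "alpha", "reference", "index",
    "multistart", "quadrature_nodes", "write_contours",
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-serializable)."""

    seed: int = 0
    n_per_subgroup: dict = field(
        default_factory=lambda: {"HF-I": 12, "HF-NI": 12, "HYP": 12, "CTRL": 9})
    grid_size: int = 96
    pixel_spacing_mm: float = 1.25
    slice_thickness_mm: float = 8.0
    n_slices: int = 9
    expert_methods: tuple[str, ...] = ("E1", "E2", "E3")
    automated_methods: tuple[str, ...] = ("A1", "A2", "A3", "A4", "A5")
    min_combination_size: int = 3
    candidates: tuple[str, ...] | None = None  # None -> every enumerated subset
    mu: float = 2.85
    nu: float = 3.40
    n_boot: int = 200
    alpha: float = 0.05
    reference: str = "E2"
    index: str = "LVEF"
    multistart: int = 1
    quadrature_nodes: int = 128
    write_contours: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        cfg = cls(**raw)
        for tup in ("expert_methods", "automated_methods", "candidates"):
            v = getattr(cfg, tup)
            if isinstance(v, list):
                setattr(cfg, tup, tuple(v))
        return cfg

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_per_subgroup=dict(self.n_per_subgroup),
            geometry=GridGeometry(
                grid_size=self.grid_size,
                pixel_spacing_mm=self.pixel_spacing_mm,
                slice_thickness_mm=self.slice_thickness_mm,
                n_slices=self.n_slices,
            ),
            seed=self.seed,
        )


def _simulate_masks(
    cfg: RunConfig, profiles: Mapping[str, RaterProfile]
) -> tuple[dict[tuple[str, str, str], MaskStack], pd.DataFrame]:
    """All rater masks keyed by (subject, method, phase), plus the truth table."""
    spec = cfg.cohort_spec()
    truth_table = synthetic.cohort_truth_table(spec)
    masks: dict[tuple[str, str, str], MaskStack] = {}
    for si, (subject, _sg) in enumerate(spec.subject_labels()):
        for phase in ("ED", "ES"):
            truth = synthetic.simulate_lv_truth(spec, subject, phase)
            pap = synthetic.simulate_papillary(spec, subject, phase)
            sd = synthetic.signed_distance_stack(truth)
            for ri, (label, prof) in enumerate(profiles.items()):
                masks[(subject, label, phase)] = synthetic.simulate_rater(
                    truth, prof, seed=spec.seed + si, papillary=pap, rater_index=ri,
                    signed_distance=sd,
                )
    return masks, truth_table


def _fuse_candidates(
    masks: dict[tuple[str, str, str], MaskStack],
    subjects: Sequence[str],
    plan: CombinationPlan,
    wanted: Sequence[str] | None,
) -> dict[tuple[str, str, str], MaskStack]:
    fused: dict[tuple[str, str, str], MaskStack] = {}
    for name, members in zip(plan.names, plan.subsets):
        if wanted is not None and name not in wanted:
            continue
        for subject in subjects:
            for phase in ("ED", "ES"):
                stacks = [masks[(subject, m, phase)] for m in members]
                fused[(subject, name, phase)] = StapleFusion().fit_transform(stacks)
    return fused


def _indices_table(
    masks: Mapping[tuple[str, str, str], MaskStack],
    subject_groups: Mapping[str, str],
) -> pd.DataFrame:
    methods = sorted({m for (_, m, _) in masks})
    subjects = sorted({s for (s, _, _) in masks})
    rows = []
    for subject in subjects:
        for method in methods:
            ed = masks.get((subject, method, "ED"))
            es = masks.get((subject, method, "ES"))
            if ed is None or es is None:
                logger.warning("missing ED/ES for subject %s method %s", subject, method)
                continue
            ci = indices_from_masks(ed, es)
            rows.append({
                "subject": subject, "subgroup": subject_groups[subject],
                "method": method, "EDV_ml": ci.edv_ml, "ESV_ml": ci.esv_ml,
                "SV_ml": ci.sv_ml, "LVEF": ci.lvef,
            })
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full study design; returns a summary dict (also written
    under ``reports/``)."""
    outdir = Path(outdir)
    for sub in ("raw", "fused", "indices", "fits", "rankings", "reports"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    (outdir / "run.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))

    profiles = {k: v for k, v in default_rater_profiles().items()
                if k in cfg.expert_methods + cfg.automated_methods}
    spec = cfg.cohort_spec()
    subjects = [s for s, _ in spec.subject_labels()]
    subject_groups = dict(spec.subject_labels())

    logger.info("stage 1/5: simulating %d subjects x %d raters", len(subjects), len(profiles))
    masks, truth_table = _simulate_masks(cfg, profiles)
    truth_table.to_csv(outdir / "raw" / "truth.csv", index=False)

    logger.info("stage 2/5: STAPLE fusion of automated-method combinations")
    plan = enumerate_combinations(list(cfg.automated_methods), cfg.min_combination_size)
    fused = _fuse_candidates(masks, subjects, plan, cfg.candidates)
    candidate_names = sorted({m for (_, m, _) in fused})

    logger.info("stage 3/5: cavity volumetry and clinical indices")
    table = _indices_table({**masks, **fused}, subject_groups)
    table.to_csv(outdir / "indices" / "indices.csv", index=False)
    matrix = cohort_table(table, index=cfg.index)
    io.write_estimate_matrix(outdir / "indices" / "estimates.csv", matrix)
    summary = subgroup_summary(matrix, percent=(cfg.index == "LVEF"))
    summary.to_csv(outdir / "indices" / "subgroup_summary.csv")

    logger.info("stage 4/5: supervised bias analysis vs %s", cfg.reference)
    report = bias_report(matrix, cfg.reference)
    report.to_csv(outdir / "reports" / "bias.csv")
    member_map = dict(zip(plan.names, plan.subsets))
    cand_bias, comp_sums = [], []
    for name in candidate_names:
        cand_bias.append(report.loc[name, "bias"])
        comp_sums.append(sum(report.loc[m, "bias"] for m in member_map[name]))
    r_bias = (combination_bias_correlation(np.array(cand_bias), np.array(comp_sums))
              if len(cand_bias) >= 3 else float("nan"))

    logger.info("stage 5/5: eRWT bootstrap ranking per candidate")
    base = list(cfg.expert_methods + cfg.automated_methods)
    model = ErwtModel(mu=cfg.mu, nu=cfg.nu, quadrature_nodes=cfg.quadrature_nodes,
                      multistart=cfg.multistart, seed=cfg.seed)
    rankings = {}
    for ci, name in enumerate(candidate_names):
        cols = base + [name]
        foms = bootstrap_foms(matrix[cols], model=model, n_draws=cfg.n_boot,
                              seed=cfg.seed * 100003 + ci)
        rt = pairwise_ranking(foms, alpha=cfg.alpha)
        rankings[name] = rt
        io.write_json(outdir / "rankings" / f"{name}.json", rt.to_dict())
        foms.fom.to_csv(outdir / "rankings" / f"{name}.foms.csv", index=False)

    # a candidate counts as expert-level when its tie group is within, or
    # adjacent to, the worst expert's tie group
    expert_level = {}
    for name, rt in rankings.items():
        worst_expert = max(rt.rank_of(m) for m in cfg.expert_methods)
        expert_level[name] = bool(rt.rank_of(name) <= worst_expert + 1)
    result = {
        "n_subjects": len(subjects),
        "methods": base,
        "candidates": candidate_names,
        "bias_correlation_r": r_bias,
        "reference": cfg.reference,
        "expert_level": expert_level,
        "n_expert_level": int(sum(expert_level.values())),
        "ranks": {name: {m: rt.rank_of(m) for m in rt.medians.index}
                  for name, rt in rankings.items()},
    }
    io.write_json(outdir / "reports" / "summary.json", result)
    return result
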