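"""Bootstrap ranking of methods by their eRWT figures of merit.

The point estimates F_k carry no uncertainty, so methods are ranked through
a subject-level bootstrap: N times, P subjects are resampled with
replacement (the same rows for every method, preserving inter-method
dependence), the latent-truth model is refit and the K figures of merit
recorded.  A Kruskal-Wallis omnibus test on the N x K values checks whether
any method differs; if so, every pair is compared with a rank-based test at
a Bonferroni-corrected level and methods whose adjacent pairs (in median
order) are not significantly different are merged into tie groups.

Caveat emitted with every result: bootstrap FoM columns are dependent
across methods (they share resamples), so the pairwise p-values are
heuristic ordering devices rather than calibrated error rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .erwt import ErwtModel

__all__ = ["BootstrapFoms", "RankingTable", "bootstrap_foms", "omnibus_test", "pairwise_ranking"]

logger = logging.getLogger(__name__)

CAUTION = (
    "bootstrap figure-of-merit columns share resamples and are therefore "
    "dependent across methods; pairwise p-values order methods heuristically"
)


@dataclass
class BootstrapFoms:
    """N bootstrap draws x K methods of figures of merit."""

    fom: pd.DataFrame  # (N, K)
    seed: int
    n_failures: int = 0

    def __post_init__(self) -> None:
        if self.fom.shape[0] < 2:
            raise ValueError("need at least 2 bootstrap draws")
        if (self.fom.to_numpy() < 0).any():
            raise ValueError("figures of merit must be non-negative")

    @property
    def n_draws(self) -> int:
        return self.fom.shape[0]

    @property
    def methods(self) -> list[str]:
        return [str(c) for c in self.fom.columns]


@dataclass
class RankingTable:
    """Ordered tie groups plus the tests that justify them."""

    groups: list[list[str]]  # ascending median FoM = best first
    medians: pd.Series
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: pd.DataFrame
    alpha: float
    correction: str = "bonferroni"
    caution: str = CAUTION

    def rank_of(self, method: str) -> int:
        """1-based rank (tie-group position) of a method; best group is 1."""
        for g, members in enumerate(self.groups, start=1):
            if method in members:
                return g
        raise KeyError(method)

    def to_dict(self) -> dict:
        return {
            "groups": [list(g) for g in self.groups],
            "medians": {str(k): float(v) for k, v in self.medians.items()},
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "correction": self.correction,
            "pairwise_p": {
                f"{a}|{b}": float(self.pairwise_p.loc[a, b])
                for a in self.pairwise_p.index for b in self.pairwise_p.columns
                if a < b
            },
            "caution": self.caution,
        }


def bootstrap_foms(
    matrix: pd.DataFrame,
    model: ErwtModel | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.05,
) -> BootstrapFoms:
    """Refit the eRWT model on ``n_draws`` subject resamples.

    The full-data fit provides a warm start for every bootstrap refit (one
    optimizer start each), which keeps N = 1000 tractable.  A failed refit
    is retried once with the model's full multistart; more than
    ``max_failure_fraction`` unrecoverable failures abort.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    model = model or ErwtModel()
    matrix = pd.DataFrame(matrix)
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix must be complete")
    # one fixed quadrature for the full fit and every draw: FoM spread must
    # reflect resampling, not quadrature changes
    full = ErwtModel(**{**model.get_params(), "adapt_quadrature": False}).fit(matrix)
    warm = np.concatenate([full.slope_, full.intercept_, np.log(full.noise_sd_)])

    # rescale once; per-draw refits run on the unit-scale array directly,
    # warm-started from the full-data solution with relaxed tolerances
    # (the bootstrap needs FoM spread, not 1e-11 optima)
    from .erwt import fit_erwt, rescale_to_unit

    unit = pd.DataFrame(
        rescale_to_unit(matrix.to_numpy(dtype=float), model.value_range),
        index=matrix.index, columns=matrix.columns,
    )
    shape = model.shape
    P = matrix.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    for n in range(n_draws):
        idx = rng.integers(0, P, size=P)
        sample = unit.iloc[idx]
        try:
            fit = fit_erwt(sample, shape=shape, quadrature_nodes=model.quadrature_nodes,
                           multistart=1, x0=warm, gtol=1e-5, ftol=1e-9,
                           adapt_nodes=False)
            rows.append(fit.fom)
        except RuntimeError:
            try:
                fit = fit_erwt(sample, shape=shape,
                               quadrature_nodes=model.quadrature_nodes,
                               multistart=model.multistart,
                               seed=model.seed + 1000 + n,
                               x0=warm, adapt_nodes=False)
                rows.append(fit.fom)
                logger.warning("bootstrap draw %d needed a restart", n)
            except RuntimeError:
                failures += 1
                logger.warning("bootstrap draw %d failed twice; skipped", n)
    if failures > max_failure_fraction * n_draws:
        raise RuntimeError(f"{failures}/{n_draws} bootstrap refits failed")
    fom = pd.DataFrame(rows, columns=matrix.columns).reset_index(drop=True)
    return BootstrapFoms(fom=fom, seed=seed, n_failures=failures)


def omnibus_test(foms: BootstrapFoms) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across the K columns of bootstrap FoMs."""
    cols = [foms.fom[c].to_numpy() for c in foms.fom.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 methods")
    if not all(np.isfinite(c).all() for c in cols):
        raise ValueError("non-finite figures of merit")
    stat, p = stats.kruskal(*cols)
    return float(stat), float(p)


def pairwise_ranking(foms: BootstrapFoms, alpha: float = 0.05) -> RankingTable:
    """Order methods by median bootstrap FoM and merge indistinct neighbours.

    All K(K-1)/2 pairs are compared with a two-sided Mann-Whitney U test at
    the Bonferroni level ``alpha / (K(K-1)/2)``.  Adjacent methods (in
    median order) whose test is non-significant share a tie group; a
    non-significant *non-adjacent* pair is logged but does not merge.  If
    the omnibus test does not reject at ``alpha``, all methods form one
    group.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    medians = foms.fom.median(axis=0).sort_values(kind="stable")
    order = [str(m) for m in medians.index]
    K = len(order)
    stat, p_omni = omnibus_test(foms)

    pairwise = pd.DataFrame(np.ones((K, K)), index=order, columns=order)
    n_pairs = K * (K - 1) // 2
    level = alpha / n_pairs
    for i in range(K):
        for j in range(i + 1, K):
            a, b = order[i], order[j]
            xa, xb = foms.fom[a], foms.fom[b]
            if np.array_equal(xa.to_numpy(), xb.to_numpy()):
                pv = 1.0
            else:
                pv = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            pairwise.loc[a, b] = pairwise.loc[b, a] = pv

    if p_omni >= alpha:
        groups = [list(order)]
    else:
        groups = [[order[0]]]
        for i in range(1, K):
            prev, cur = order[i - 1], order[i]
            if pairwise.loc[prev, cur] >= level:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        for i in range(K):
            for j in range(i + 2, K):
                if pairwise.loc[order[i], order[j]] >= level:
                    gi = next(g for g, ms in enumerate(groups) if order[i] in ms)
                    gj = next(g for g, ms in enumerate(groups) if order[j] in ms)
                    if gi != gj:
                        logger.info(
                            "non-adjacent pair (%s, %s) not significantly different; "
                            "groups kept separate", order[i], order[j],
                        )
    return RankingTable(
        groups=groups, medians=medians, omnibus_stat=stat, omnibus_p=p_omni,
        pairwise_p=pairwise, alpha=alpha,
    )
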