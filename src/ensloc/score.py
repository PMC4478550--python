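"""Protein-level scoring: localization profiles, abundance, and change calls.

For each protein (strain) and screen:

* the **LOC-score** profile is the 16-element vector of proportions of
  *classifiable* cells (cells assigned to at least one localization
  class) assigned to each class — elements may sum above 1 when cells
  multi-localize;
* abundance **I_g** is the arithmetic mean over cells of (integrated GFP
  intensity / segmented cell area), and **dPL** is the fold-change of
  I_g between a condition screen and its wild-type control;
* the **z-LOC** score quantifies a localization change between screens
  as a pooled two-proportion z statistic per class.

Significance cutoffs for z-LOC are not fixed constants: the observed
z-LOC distribution across a comparison is modeled as a Gaussian
"background" (measurement noise around no change) plus a uniform
"outlier" component (genuine relocalization), fitted by
expectation-maximization; the cutoffs are the z values where the
posterior probability of the outlier component crosses 0.5 on each side
of the background mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import AssignmentVector
from .phantom import CLASSES
from .segment import GFP, CellRegion


@dataclass
class LocalizationProfile:
    """16-element LOC-score vector for one protein in one screen."""

    protein_id: str
    screen_id: str
    loc_scores: np.ndarray
    n_cells_total: int
    n_classifiable: int
    class_counts: np.ndarray = field(default=None)
    classes: tuple[str, ...] = CLASSES
    low_confidence: bool = False

    @property
    def quantifiable(self) -> bool:
        return self.n_classifiable > 0


@dataclass
class AbundanceRecord:
    """Mean GFP intensity I_g of one protein in one screen."""

    protein_id: str
    screen_id: str
    ig: float | None
    n_cells: int
    per_cell_ratios: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def quantifiable(self) -> bool:
        return self.ig is not None


@dataclass
class ComparisonRecord:
    """Condition-vs-control deltas for one protein."""

    protein_id: str
    condition_screen: str
    control_screen: str
    dpl: float | None
    zloc: np.ndarray  # 16 z-scores
    significant: np.ndarray = field(default_factory=lambda: np.zeros(16, dtype=bool))
    direction: list[str] = field(default_factory=lambda: [""] * 16)
    classes: tuple[str, ...] = CLASSES


@dataclass
class MixtureFit:
    """Gaussian background + uniform outlier fit of a z-LOC distribution."""

    background: tuple[float, float]  # (mean, sd)
    outlier_weight: float
    uniform_bounds: tuple[float, float]
    cutoffs: tuple[float, float]
    converged: bool
    loglik: float
    n_iter: int = 0
    loglik_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# profiles and abundance

MIN_CLASSIFIABLE = 20  # fewer classifiable cells -> low-confidence flag


def loc_profile(
    assignments: list[AssignmentVector],
    protein_id: str = "",
    screen_id: str = "",
    min_classifiable: int = MIN_CLASSIFIABLE,
) -> LocalizationProfile:
    """LOC-score profile from per-cell assignments.

    Dead/ghost cells are excluded; the denominator is the number of
    classifiable cells (assigned to >= 1 class).  With zero classifiable
    cells the profile is unquantifiable (all-NaN scores).
    """
    if not assignments:
        raise ValueError("assignments must be nonempty")
    passing = [a for a in assignments if a.qc == "pass"]
    classifiable = [a for a in passing if a.classifiable]
    n_cls = len(classifiable)
    counts = np.zeros(16, dtype=int)
    for a in classifiable:
        counts += a.memberships.astype(int)
    scores = counts / n_cls if n_cls else np.full(16, np.nan)
    return LocalizationProfile(
        protein_id=protein_id,
        screen_id=screen_id,
        loc_scores=scores,
        n_cells_total=len(assignments),
        n_classifiable=n_cls,
        class_counts=counts,
        classes=assignments[0].classes,
        low_confidence=n_cls < min_classifiable,
    )


def abundance_ig(
    cells: list[CellRegion],
    protein_id: str = "",
    screen_id: str = "",
    assignments: list[AssignmentVector] | None = None,
) -> AbundanceRecord:
    """Mean GFP intensity: mean over cells of integrated GFP / area.

    When assignments are supplied, dead/ghost cells are excluded.  An
    empty cell list yields an unquantifiable record.
    """
    if assignments is not None:
        if len(assignments) != len(cells):
            raise ValueError("assignments must align with cells")
        cells = [c for c, a in zip(cells, assignments) if a.qc == "pass"]
    ratios = []
    for c in cells:
        if GFP not in c.integrated_intensity:
            raise ValueError(f"cell {c.object_id} lacks a GFP measurement")
        ratios.append(c.integrated_intensity[GFP] / c.area)
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.size == 0:
        return AbundanceRecord(protein_id, screen_id, None, 0)
    return AbundanceRecord(
        protein_id, screen_id, float(ratios.mean()), len(ratios), ratios
    )


def delta_pl(condition: AbundanceRecord, control: AbundanceRecord) -> float:
    """Abundance fold-change: I_g(condition) / I_g(control)."""
    if not condition.quantifiable or not control.quantifiable:
        raise ValueError("both records must be quantifiable")
    if control.ig == 0:
        raise ZeroDivisionError("control I_g is zero; fold-change undefined")
    return condition.ig / control.ig


# ---------------------------------------------------------------------------
# z-LOC


def zloc(k_cond: int, n_cond: int, k_ctrl: int, n_ctrl: int) -> float:
    """Pooled two-proportion z statistic for a localization change.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled estimate
    p = (k1+k2)/(n1+n2).  When the pooled proportion is 0 or 1 there is
    no evidence of a difference and z = 0.
    """
    for k, nn in ((k_cond, n_cond), (k_ctrl, n_ctrl)):
        if nn < 1:
            raise ValueError("sample sizes must be >= 1")
        if not (0 <= k <= nn):
            raise ValueError(f"count {k} outside [0, {nn}]")
    p1 = k_cond / n_cond
    p2 = k_ctrl / n_ctrl
    pooled = (k_cond + k_ctrl) / (n_cond + n_ctrl)
    if pooled in (0.0, 1.0):
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n_cond + 1.0 / n_ctrl))
    return (p1 - p2) / se


def compare_profiles(
    condition: LocalizationProfile,
    control: LocalizationProfile,
    condition_abundance: AbundanceRecord | None = None,
    control_abundance: AbundanceRecord | None = None,
) -> ComparisonRecord:
    """z-LOC vector (and optional dPL) between two profiles of one protein."""
    if not condition.quantifiable or not control.quantifiable:
        raise ValueError("both profiles must be quantifiable")
    z = np.array(
        [
            zloc(
                int(condition.class_counts[i]),
                condition.n_classifiable,
                int(control.class_counts[i]),
                control.n_classifiable,
            )
            for i in range(16)
        ]
    )
    dpl = None
    if condition_abundance is not None and control_abundance is not None:
        dpl = delta_pl(condition_abundance, control_abundance)
    return ComparisonRecord(
        protein_id=condition.protein_id,
        condition_screen=condition.screen_id,
        control_screen=control.screen_id,
        dpl=dpl,
        zloc=z,
        classes=condition.classes,
    )


# ---------------------------------------------------------------------------
# mixture model


def fit_mixture(
    zscores: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    init_weight: float = 0.05,
) -> MixtureFit:
    """EM fit of w*Uniform(lo,hi) + (1-w)*Normal(mu,sigma) to z-LOC scores.

    The uniform support is fixed at the data range.  Initialization is
    deterministic: mu and sigma from the interquartile-trimmed sample and
    w = ``init_weight``, so the fit is reproducible.  Cutoffs are the z
    values on each side of mu where the posterior probability of the
    outlier component crosses 0.5.  Non-convergence within ``max_iter``
    returns the last iterate with ``converged=False``.
    """
    z = np.asarray(zscores, dtype=np.float64).ravel()
    if z.size < 50:
        raise ValueError("need at least 50 z-scores to fit the mixture")
    lo, hi = float(z.min()), float(z.max())
    if hi <= lo:
        raise ValueError("degenerate z-score sample (all values identical)")
    u_dens = 1.0 / (hi - lo)

    q1, q3 = np.quantile(z, [0.25, 0.75])
    core = z[(z >= q1) & (z <= q3)]
    mu = float(core.mean())
    # sd of an IQR-trimmed normal underestimates sigma by a known factor
    sigma = max(float(core.std()) / 0.4857, 1e-3)
    w = float(init_weight)

    def normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
        return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))

    loglik_prev = -np.inf
    trajectory = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_out = w * u_dens
        f_bg = (1.0 - w) * normal_pdf(z, mu, sigma)
        total = f_out + f_bg
        total[total <= 0] = 1e-300
        loglik = float(np.log(total).sum())
        trajectory.append(loglik)
        resp = f_out / total  # posterior of outlier component
        w = float(resp.mean())
        wt = 1.0 - resp
        denom = wt.sum()
        if denom <= 0 or w >= 1.0:
            break
        mu = float((wt * z).sum() / denom)
        sigma = max(math.sqrt(float((wt * (z - mu) ** 2).sum() / denom)), 1e-6)
        if abs(loglik - loglik_prev) < tol * (1.0 + abs(loglik)):
            converged = True
            break
        loglik_prev = loglik

    cutoffs = _posterior_cutoffs(w, mu, sigma, u_dens)
    return MixtureFit(
        background=(mu, sigma),
        outlier_weight=w,
        uniform_bounds=(lo, hi),
        cutoffs=cutoffs,
        converged=converged,
        loglik=trajectory[-1] if trajectory else float("nan"),
        n_iter=it,
        loglik_trajectory=np.array(trajectory),
    )


def _posterior_cutoffs(
    w: float, mu: float, sigma: float, u_dens: float
) -> tuple[float, float]:
    """z values where outlier posterior = 0.5, i.e. (1-w) N(z) = w * u."""
    if w <= 0:
        return (-math.inf, math.inf)
    lhs = w * u_dens / (1.0 - w) if w < 1 else math.inf
    peak = 1.0 / (sigma * math.sqrt(2 * math.pi))
    if lhs >= peak:
        # outlier density dominates everywhere: every z is an outlier
        return (mu, mu)
    delta = sigma * math.sqrt(-2.0 * math.log(lhs * sigma * math.sqrt(2 * math.pi)))
    return (mu - delta, mu + delta)


def outlier_posterior(fit: MixtureFit, z: np.ndarray) -> np.ndarray:
    """Posterior probability that each z belongs to the outlier component."""
    z = np.asarray(z, dtype=np.float64)
    lo, hi = fit.uniform_bounds
    mu, sigma = fit.background
    u = np.where((z >= lo) & (z <= hi), 1.0 / (hi - lo), 0.0)
    f_out = fit.outlier_weight * u
    f_bg = (1.0 - fit.outlier_weight) * np.exp(-0.5 * ((z - mu) / sigma) ** 2) / (
        sigma * math.sqrt(2 * math.pi)
    )
    total = f_out + f_bg
    total[total <= 0] = 1e-300
    return f_out / total


def call_changes(comparison: ComparisonRecord, fit: MixtureFit) -> ComparisonRecord:
    """Flag significant localization changes using the mixture cutoffs.

    A class is significant when its z-LOC lies outside (lower, upper);
    the direction records whether cells moved toward (+z) or away from
    (-z) the compartment in the condition.
    """
    if not fit.converged:
        raise ValueError("mixture fit did not converge; cutoffs unreliable")
    lower, upper = fit.cutoffs
    sig = (comparison.zloc < lower) | (comparison.zloc > upper)
    direction = [
        ("toward" if zv > 0 else "away") if s else ""
        for zv, s in zip(comparison.zloc, sig)
    ]
    comparison.significant = sig
    comparison.direction = direction
    return comparison
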