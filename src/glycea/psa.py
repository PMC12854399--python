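"""Probabilistic sensitivity analysis on the cost-effectiveness plane.

All six input parameters (per-arm cost, TIR and GRI means) are redrawn
jointly and independently in each Monte Carlo simulation: costs from gamma
distributions moment-matched to the arm mean/SD (shape = (mean/SD)²,
scale = SD²/mean), glycemic outcomes from normal distributions truncated to
[0, 100] whose *parent* mean/SD are the arm statistics (the common
convention; no truncation-moment correction is applied here).  Each draw's
incremental triple (ΔC, ΔE, ΔS) is classified into a quadrant of the
cost–TIR plane and of the cost–GRI plane:

* SE — less costly and more effective (strong dominance),
* SW — less costly, less effective,
* NE — more costly, more effective,
* NW — more costly, less effective (dominated).

On the GRI plane "more effective" means a *lower* GRI.  The per-arm SDs are
used as the uncertainty scale by default; ``uncertainty_scale="se"``
rescales them to standard errors of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from glycea.cea import ArmSummary, incremental

__all__ = [
    "QUADRANTS", "PsaConfig", "PsaResult",
    "sample_parameters", "run_psa", "quadrant_of", "export_ce_plane",
]

QUADRANTS = ("SE", "SW", "NE", "NW")

_OUTCOME_BOUNDS = (0.0, 100.0)


@dataclass(frozen=True)
class PsaConfig:
    """Monte Carlo settings for the probabilistic sensitivity analysis."""

    n_sims: int = 10_000
    uncertainty_scale: str = "sd"  # "sd" | "se"
    seed: Optional[int] = None
    bounds: Tuple[float, float] = _OUTCOME_BOUNDS

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.uncertainty_scale not in ("sd", "se"):
            raise ValueError("uncertainty_scale must be 'sd' or 'se'")
        lo, hi = self.bounds
        if not (0 <= lo < hi <= 100):
            raise ValueError("bounds must satisfy 0 <= lower < upper <= 100")


def _gamma_draws(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean!r}")
    if sd == 0:
        warnings.warn("SD = 0: cost parameter drawn as a point mass")
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size=n)


def _truncnorm_draws(mean: float, sd: float, n: int, rng: np.random.Generator,
                     bounds: Tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    if sd == 0:
        warnings.warn("SD = 0: outcome parameter drawn as a point mass")
        return np.full(n, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _scaled_sd(sd: float, n: int, scale: str) -> float:
    return sd / np.sqrt(n) if scale == "se" else sd


def sample_parameters(
    intervention: ArmSummary,
    comparator: ArmSummary,
    config: PsaConfig,
    seed: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """Joint independent draws of all six model parameters.

    Returns arrays keyed ``cost_int, cost_comp, effect_int, effect_comp,
    safety_int, safety_comp``, each of length ``config.n_sims``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, sc = config.n_sims, config.uncertainty_scale
    draws = {}
    for tag, arm in (("int", intervention), ("comp", comparator)):
        draws[f"cost_{tag}"] = _gamma_draws(
            arm.cost_mean, _scaled_sd(arm.cost_sd, arm.n, sc), n, rng)
        draws[f"effect_{tag}"] = _truncnorm_draws(
            arm.effect_mean, _scaled_sd(arm.effect_sd, arm.n, sc), n, rng,
            config.bounds)
        draws[f"safety_{tag}"] = _truncnorm_draws(
            arm.safety_mean, _scaled_sd(arm.safety_sd, arm.n, sc), n, rng,
            config.bounds)
    return draws


def quadrant_of(dc: float, d_benefit: float,
                tie_signs: Tuple[int, int] = (-1, 1)) -> str:
    """Quadrant of one (ΔC, Δbenefit) point; Δbenefit > 0 = better outcome.

    Exact zeros (probability-zero under continuous sampling) are assigned
    the side given by ``tie_signs`` — by convention the sign of the
    base-case increment on each axis.
    """
    c = dc if dc != 0 else tie_signs[0]
    b = d_benefit if d_benefit != 0 else tie_signs[1]
    if c < 0:
        return "SE" if b > 0 else "SW"
    return "NE" if b > 0 else "NW"


def _quadrants_vec(dc: np.ndarray, d_benefit: np.ndarray,
                   tie_signs: Tuple[int, int]) -> np.ndarray:
    c = np.where(dc == 0, tie_signs[0], dc)
    b = np.where(d_benefit == 0, tie_signs[1], d_benefit)
    out = np.where(c < 0, np.where(b > 0, "SE", "SW"),
                   np.where(b > 0, "NE", "NW"))
    return out


@dataclass
class PsaResult:
    """Per-draw increments and quadrant occupancy on both outcome planes."""

    draws: pd.DataFrame  # columns dc, de, ds, quadrant_tir, quadrant_gri
    counts_tir: Dict[str, int]
    counts_gri: Dict[str, int]
    proportions_tir: Dict[str, float]
    proportions_gri: Dict[str, float]
    prop_less_costly: float
    n_sims: int
    base_case: Tuple[float, float, float]
    seed: Optional[int] = None

    def to_summary_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "seed": self.seed,
            "base_case": {"dc": self.base_case[0], "de": self.base_case[1],
                          "ds": self.base_case[2]},
            "counts_tir_plane": self.counts_tir,
            "counts_gri_plane": self.counts_gri,
            "proportions_tir_plane": self.proportions_tir,
            "proportions_gri_plane": self.proportions_gri,
            "prop_less_costly": self.prop_less_costly,
        }


def run_psa(
    intervention: ArmSummary,
    comparator: ArmSummary,
    config: PsaConfig = PsaConfig(),
) -> PsaResult:
    """Run the Monte Carlo PSA and tabulate quadrant occupancy.

    Deterministic for a given ``config.seed``.  The marginal
    ``prop_less_costly`` equals SE + SW on either plane.
    """
    draws = sample_parameters(intervention, comparator, config)
    dc = draws["cost_int"] - draws["cost_comp"]
    de = draws["effect_int"] - draws["effect_comp"]
    ds = draws["safety_int"] - draws["safety_comp"]

    base = incremental(intervention, comparator)
    tie_c = -1 if base.dc <= 0 else 1
    q_tir = _quadrants_vec(dc, de, (tie_c, 1 if base.de >= 0 else -1))
    # on the GRI plane benefit = -ds (a reduction in GRI is the good outcome)
    q_gri = _quadrants_vec(dc, -ds, (tie_c, 1 if base.ds <= 0 else -1))

    n = config.n_sims
    counts_tir = {q: int((q_tir == q).sum()) for q in QUADRANTS}
    counts_gri = {q: int((q_gri == q).sum()) for q in QUADRANTS}
    frame = pd.DataFrame({"dc": dc, "de": de, "ds": ds,
                          "quadrant_tir": q_tir, "quadrant_gri": q_gri})
    return PsaResult(
        draws=frame,
        counts_tir=counts_tir,
        counts_gri=counts_gri,
        proportions_tir={q: counts_tir[q] / n for q in QUADRANTS},
        proportions_gri={q: counts_gri[q] / n for q in QUADRANTS},
        prop_less_costly=float((dc < 0).mean()),
        n_sims=n,
        base_case=(base.dc, base.de, base.ds),
        seed=config.seed,
    )


def export_ce_plane(result: PsaResult) -> pd.DataFrame:
    """One row per draw (ΔC, ΔE, ΔS, quadrants), ready for scatter plotting."""
    if result.n_sims == 0 or result.draws.empty:
        raise ValueError("PSA result contains no draws")
    return result.draws.copy()


def plot_ce_plane(result: PsaResult, path=None):
    """Scatter the draws on both planes (TIR and GRI panels)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=True)
    for ax, (xcol, label, flip) in zip(axes, [
            ("ds", "Incremental GRI (points)", True),
            ("de", "Incremental TIR (points)", False)]):
        ax.scatter(result.draws[xcol], result.draws["dc"], s=3, alpha=0.3)
        ax.axhline(0, color="k", lw=0.6)
        ax.axvline(0, color="k", lw=0.6)
        ax.set_xlabel(label)
    axes[0].set_ylabel("Incremental cost (EUR)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
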