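"""Incremental cost-effectiveness and cost-safety analysis with dominance rules.

Two strategies are compared on two planes: cost vs effectiveness (time in
range, where more is better) and cost vs safety (Glycemia Risk Index, where
less is better).  The incremental cost-effectiveness ratio ICER = ΔC/ΔE is
the extra cost per percentage point of TIR gained; the incremental
cost-safety ratio ICSR is reported as a positive magnitude |ΔC|/|ΔS| per GRI
point reduced.  Following ISPOR practice, a negative ratio is never reported
bare: it always carries its quadrant/dominance label (an intervention that is
cheaper and more effective *dominates* its comparator; one that is more
costly and not more effective is *dominated*).

The statsmodels-style entry point is :class:`CostEffectivenessModel`,
constructed from two :class:`ArmSummary` objects (or a patient-level
DataFrame); ``fit()`` returns :class:`CEAResults` with a ``summary()`` table
and a ``run_psa()`` hook for the probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from glycea.psa import PsaConfig, PsaResult

__all__ = [
    "DOMINANT", "DOMINATED", "TRADEOFF_NE", "TRADEOFF_SW", "INDIFFERENT",
    "ArmSummary", "Increments", "RatioResult", "incremental", "icer", "icsr",
    "classify_dominance", "CostEffectivenessModel", "CEAResults",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADEOFF_NE = "tradeoff_NE"
TRADEOFF_SW = "tradeoff_SW"
INDIFFERENT = "indifferent"

#: Default equality tolerance on increments ("equally effective/costly").
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm summary statistics feeding the CEA.

    effect is TIR (%) and safety is GRI (points) at the analysis timepoint.
    """

    arm: str
    n: int
    cost_mean: float
    cost_sd: float
    effect_mean: float
    effect_sd: float
    safety_mean: float
    safety_sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if min(self.cost_sd, self.effect_sd, self.safety_sd) < 0:
            raise ValueError("SDs must be >= 0")
        for name in ("effect_mean", "safety_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v!r}")


class Increments(NamedTuple):
    """Incremental (intervention − comparator) cost, effect and safety."""

    dc: float  # EUR
    de: float  # TIR percentage points; >0 favours the intervention
    ds: float  # GRI points; <0 favours the intervention


@dataclass(frozen=True)
class RatioResult:
    """An ICER/ICSR value together with its dominance/quadrant label.

    ``value`` is None on the dominance-flag path (outcome increment within
    tolerance of zero, where a ratio is undefined or meaningless).
    """

    value: Optional[float]
    label: str

    @property
    def is_ratio(self) -> bool:
        return self.value is not None


def incremental(intervention: ArmSummary, comparator: ArmSummary) -> Increments:
    """Componentwise incremental cost, effectiveness and safety."""
    return Increments(
        intervention.cost_mean - comparator.cost_mean,
        intervention.effect_mean - comparator.effect_mean,
        intervention.safety_mean - comparator.safety_mean,
    )


def classify_dominance(dc: float, d_outcome: float, tol: float = DEFAULT_TOL) -> str:
    """Dominance label on a cost-benefit plane.

    ``d_outcome`` is oriented so positive = better (pass −ΔGRI for the
    safety plane).  Cheaper with no worse an outcome dominates; costlier
    with no better an outcome is dominated; same-sign combinations are
    trade-offs (NE: pay more for more benefit; SW: save money, lose
    benefit); both increments within tolerance is indifference.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    cheaper, costlier = dc < -tol, dc > tol
    better, worse = d_outcome > tol, d_outcome < -tol
    if cheaper:
        return DOMINANT if better else (TRADEOFF_SW if worse else DOMINANT)
    if costlier:
        return TRADEOFF_NE if better else DOMINATED
    # cost-indifferent edge
    if better:
        return DOMINANT
    if worse:
        return DOMINATED
    return INDIFFERENT


def icer(dc: float, de: float, tol: float = DEFAULT_TOL) -> RatioResult:
    """Incremental cost-effectiveness ratio (EUR per TIR point), or a flag.

    When |ΔE| ≤ tol no ratio is formed: cheaper-and-equally-effective is
    dominant, costlier-and-equally-effective is dominated, both-zero is
    indifferent.  Otherwise returns ΔC/ΔE with its quadrant label — a
    negative ratio is always accompanied by the label, never reported bare.
    """
    label = classify_dominance(dc, de, tol)
    if abs(de) <= tol:
        return RatioResult(None, label)
    return RatioResult(dc / de, label)


def icsr(dc: float, ds: float, tol: float = DEFAULT_TOL) -> RatioResult:
    """Incremental cost-safety ratio: |ΔC|/|ΔS| per GRI point, with label.

    Safety benefit is a *reduction* in GRI, so the plane is classified on
    (ΔC, −ΔS) and the ratio is reported as a positive magnitude (EUR moved
    per GRI point reduced) with the quadrant label carrying the signs.
    """
    label = classify_dominance(dc, -ds, tol)
    if abs(ds) <= tol:
        return RatioResult(None, label)
    return RatioResult(abs(dc) / abs(ds), label)


class CostEffectivenessModel:
    """Two-strategy cost-effectiveness model on the TIR and GRI planes.

    Parameters
    ----------
    intervention, comparator
        Per-arm summaries (cost, effect=TIR, safety=GRI mean/SD).
    tol
        Equality tolerance on increments.

    Examples
    --------
    >>> from glycea import defaults
    >>> model = CostEffectivenessModel(defaults.cirdia_summary(),
    ...                                defaults.hc_summary())
    >>> res = model.fit()
    >>> round(res.increments.dc, 2)
    -441.2
    """

    def __init__(self, intervention: ArmSummary, comparator: ArmSummary,
                 tol: float = DEFAULT_TOL):
        self.intervention = intervention
        self.comparator = comparator
        self.tol = tol

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        costs: pd.DataFrame,
        intervention: str,
        comparator: str,
        timepoint: str = "M12",
        tol: float = DEFAULT_TOL,
    ) -> "CostEffectivenessModel":
        """Build arm summaries from a long cohort frame and per-patient costs.

        ``cohort`` needs columns arm, patient_id, timepoint, tir, gri;
        ``costs`` needs columns arm, patient_id, total_eur.
        """
        summaries = {}
        at_tp = cohort[cohort["timepoint"] == timepoint]
        for arm in (intervention, comparator):
            g = at_tp[at_tp["arm"] == arm]
            c = costs[costs["arm"] == arm]["total_eur"]
            if g.empty or c.empty:
                raise ValueError(f"arm {arm!r} missing outcomes or costs")
            summaries[arm] = ArmSummary(
                arm, len(g),
                float(c.mean()), float(c.std(ddof=1)) if len(c) > 1 else 0.0,
                float(g["tir"].mean()), float(g["tir"].std(ddof=1)) if len(g) > 1 else 0.0,
                float(g["gri"].mean()), float(g["gri"].std(ddof=1)) if len(g) > 1 else 0.0,
            )
        return cls(summaries[intervention], summaries[comparator], tol)

    def fit(self) -> "CEAResults":
        inc = incremental(self.intervention, self.comparator)
        return CEAResults(
            model=self,
            increments=inc,
            icer=icer(inc.dc, inc.de, self.tol),
            icsr=icsr(inc.dc, inc.ds, self.tol),
            dominance_effect=classify_dominance(inc.dc, inc.de, self.tol),
            dominance_safety=classify_dominance(inc.dc, -inc.ds, self.tol),
        )


@dataclass
class CEAResults:
    """Base-case CEA results: increments, ratios and dominance labels."""

    model: CostEffectivenessModel
    increments: Increments
    icer: RatioResult
    icsr: RatioResult
    dominance_effect: str
    dominance_safety: str

    def run_psa(self, config: "PsaConfig" = None) -> "PsaResult":
        """Probabilistic sensitivity analysis around this comparison."""
        from glycea.psa import PsaConfig, run_psa
        return run_psa(self.model.intervention, self.model.comparator,
                       config or PsaConfig())

    def to_dict(self) -> dict:
        i, c = self.model.intervention, self.model.comparator
        return {
            "intervention": i.arm,
            "comparator": c.arm,
            "cost_per_patient_eur": {i.arm: i.cost_mean, c.arm: c.cost_mean},
            "mean_effect_tir": {i.arm: i.effect_mean, c.arm: c.effect_mean},
            "mean_safety_gri": {i.arm: i.safety_mean, c.arm: c.safety_mean},
            "incremental_cost_eur": self.increments.dc,
            "incremental_effect_tir": self.increments.de,
            "incremental_safety_gri": self.increments.ds,
            "icer_eur_per_tir_point": self.icer.value,
            "icer_label": self.icer.label,
            "icsr_eur_per_gri_point": self.icsr.value,
            "icsr_label": self.icsr.label,
            "dominance_effect_plane": self.dominance_effect,
            "dominance_safety_plane": self.dominance_safety,
        }

    def summary(self) -> str:
        i, c = self.model.intervention, self.model.comparator
        fmt = "{:<38}{:>14}{:>14}".format
        lines = [
            "Cost-effectiveness analysis (base case)",
            "=" * 66,
            fmt("Parameter", i.arm, c.arm),
            "-" * 66,
            fmt("Costs per patient (EUR)", f"{i.cost_mean:.2f}", f"{c.cost_mean:.2f}"),
            fmt("Incremental costs (EUR)", f"{self.increments.dc:.2f}", "-"),
            fmt("Mean efficacy (TIR, %)", f"{i.effect_mean:.2f}", f"{c.effect_mean:.2f}"),
            fmt("Incremental efficacy (TIR points)", f"{self.increments.de:.2f}", "-"),
            fmt("Mean safety (GRI)", f"{i.safety_mean:.2f}", f"{c.safety_mean:.2f}"),
            fmt("Incremental safety (GRI points)", f"{self.increments.ds:.2f}", "-"),
            fmt("ICER (EUR per TIR point)",
                "-" if self.icer.value is None else f"{self.icer.value:.2f}", "-"),
            fmt("ICSR (EUR per GRI point reduced)",
                "-" if self.icsr.value is None else f"{self.icsr.value:.2f}", "-"),
            "-" * 66,
            f"Effectiveness plane: intervention is {self.dominance_effect}",
            f"Safety plane:        intervention is {self.dominance_safety}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Table-layout export mirroring the base-case results block."""
        i, c = self.model.intervention, self.model.comparator
        rows = [
            ("Costs per patient (EUR)", i.cost_mean, c.cost_mean),
            ("Incremental costs (EUR)", self.increments.dc, np.nan),
            ("Mean efficacy (TIR)", i.effect_mean, c.effect_mean),
            ("Incremental efficacy (increase in TIR)", self.increments.de, np.nan),
            ("Mean safety (GRI)", i.safety_mean, c.safety_mean),
            ("Incremental safety", self.increments.ds, np.nan),
            ("ICER", self.icer.value, np.nan),
            ("ICSR", self.icsr.value, np.nan),
        ]
        return pd.DataFrame(rows, columns=["parameter", i.arm, c.arm])
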