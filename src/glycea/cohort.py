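"""Synthetic two-arm cohort generator with the study's statistical structure.

The generator emulates a retrospective cohort of people with type 1 diabetes
starting closed-loop insulin delivery in one of two care models (an
out-of-hospital initiation centre vs hospital-based care): per-patient
baseline (M0) and 12-month (M12) TIR and GRI values, demographics, and the
care-pathway cost events of the 1-year follow-up.

Glycemic values are drawn from normal distributions truncated to [0, 100]
whose parameters are solved so the *truncated* distribution has exactly the
requested mean/SD (a truncation-moment correction — without it the SD of a
mean-56/SD-21 score would be biased by more than a point).  The four values
per patient (TIR and GRI at M0 and M12) are coupled through a Gaussian
copula: a within-patient M0→M12 correlation (default 0.4) makes
longitudinal deltas realistic, and a strong negative TIR–GRI correlation
(default −0.85) reflects that both summarise the same glucose profile.
Neither correlation is an observed quantity; both are exposed parameters.

Cost events follow the care pathway: an initiation visit (day
hospitalization for the hospital arm; office visit, or day hospitalization
for a configurable fraction, in the out-of-hospital arm), three
teleconsultations, three consultations, an optional 3-month telemonitoring
period, and twelve months of device/consumable charges whose
gamma-distributed utilisation absorbs the calibration residual so per-arm
cost means and SDs match their targets in expectation.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from glycea import defaults
from glycea.costing import CostItem, TariffCatalog
from glycea.metrics import GlucoseTrace, GlycemicProfile

__all__ = [
    "CohortSpec", "PatientRecord", "generate_cohort", "generate_cgm_trace",
    "generate_cost_items", "cohort_to_frame", "truncnorm_parent_params",
]

AGE_CLASS_BOUNDS = ((16.0, 25.0), (25.0, 45.0), (45.0, 65.0), (65.0, 80.0))
AGE_CLASS_LABELS = ("<25", "25-45", "45-65", ">=65")

# catalog keys of the care-pathway events
KEY_CONSULT = ("NGAP", "CS")
KEY_TELECONSULT = ("NGAP", "TCG")
KEY_OFFICE_INIT = ("CCAM", "INIT-OV")
KEY_DH = ("GHS", "1794")
KEY_TELEMONITOR = ("LPP", "TLM-M")
KEY_DEVICE = ("LPP", "CL-RENT-M")


def _default(name):
    return field(default_factory=lambda: copy.deepcopy(getattr(defaults, name)))


@dataclass(frozen=True)
class CohortSpec:
    """Target statistical structure of the synthetic two-arm cohort.

    Defaults reproduce the study conditions: arm sizes 128/73, printed
    TIR/GRI means and SDs at M0 and M12, printed per-arm cost mean/SD,
    age-class and gender mix, and a 13% day-hospitalization fraction in
    the out-of-hospital arm.
    """

    n_intervention: int = defaults.N_CIRDIA
    n_comparator: int = defaults.N_HC
    intervention_label: str = defaults.INTERVENTION
    comparator_label: str = defaults.COMPARATOR
    tir: Dict[str, Dict[str, Tuple[float, float]]] = _default("TIR")
    gri: Dict[str, Dict[str, Tuple[float, float]]] = _default("GRI")
    cost: Dict[str, Tuple[float, float]] = _default("COST")
    longitudinal_corr: float = 0.4
    tir_gri_corr: float = -0.85
    age_class_props: Dict[str, Tuple[float, ...]] = _default("AGE_CLASS_PROPS")
    female_prop: float = defaults.FEMALE_PROP
    bmi: Dict[str, Tuple[float, float]] = _default("BMI")
    n_teleconsultations: int = 3
    n_consultations: int = 3
    telemonitoring_months: int = 3
    telemonitoring_fraction: float = 0.5
    dh_fraction: float = defaults.DH_FRACTION
    seed: int = 0

    @property
    def arms(self) -> Tuple[str, str]:
        return (self.intervention_label, self.comparator_label)

    def n_for(self, arm: str) -> int:
        if arm == self.intervention_label:
            return self.n_intervention
        if arm == self.comparator_label:
            return self.n_comparator
        raise ValueError(f"unknown arm {arm!r}")

    def __post_init__(self):
        if self.n_intervention < 1 or self.n_comparator < 1:
            raise ValueError("sample sizes (n_intervention/n_comparator) must be >= 1")
        for frac_name in ("female_prop", "dh_fraction", "telemonitoring_fraction"):
            v = getattr(self, frac_name)
            if not 0 <= v <= 1:
                raise ValueError(f"{frac_name} must lie in [0, 1], got {v!r}")
        for corr_name in ("longitudinal_corr", "tir_gri_corr"):
            v = getattr(self, corr_name)
            if not -1 <= v <= 1:
                raise ValueError(f"{corr_name} must lie in [-1, 1], got {v!r}")
        for arm in self.arms:
            props = self.age_class_props[arm]
            if len(props) != len(AGE_CLASS_LABELS) or min(props) < 0 or max(props) > 1:
                raise ValueError(f"age_class_props[{arm!r}] must be 4 fractions in [0,1]")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"age_class_props[{arm!r}] must sum to 1")
            for table_name, table in (("tir", self.tir), ("gri", self.gri)):
                for tp, (m, sd) in table[arm].items():
                    if not 0 <= m <= 100:
                        raise ValueError(
                            f"{table_name}[{arm!r}][{tp!r}] mean must lie in [0,100]")
                    if sd < 0:
                        raise ValueError(
                            f"{table_name}[{arm!r}][{tp!r}] SD must be >= 0")
            cm, csd = self.cost[arm]
            if cm <= 0 or csd < 0:
                raise ValueError(f"cost[{arm!r}] must have mean > 0 and SD >= 0")
            bm, bsd = self.bmi[arm]
            if bm <= 0 or bsd < 0:
                raise ValueError(f"bmi[{arm!r}] must have mean > 0 and SD >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        def tupled(x):
            if isinstance(x, dict):
                return {k: tupled(v) for k, v in x.items()}
            if isinstance(x, list):
                return tuple(tupled(v) for v in x)
            return x
        return cls(**{k: tupled(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path) -> "CohortSpec":
        p = str(path)
        with open(path) as fh:
            if p.endswith((".yaml", ".yml")):
                import yaml
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d or {})


@dataclass
class PatientRecord:
    """One synthetic patient: demographics plus per-timepoint TIR and GRI."""

    patient_id: str
    arm: str
    age: float
    age_class: str
    sex: str  # "F" | "M"
    bmi: float
    tir: Dict[str, float]
    gri: Dict[str, float]


@lru_cache(maxsize=512)
def truncnorm_parent_params(
    mean: float, sd: float, lo: float = 0.0, hi: float = 100.0
) -> Tuple[float, float]:
    """Parent (mu, sigma) of a [lo, hi]-truncated normal with given moments.

    Solves the two truncated-moment equations so that the truncated
    distribution itself has exactly ``(mean, sd)``.  When both bounds are
    more than six target-SDs from the mean the correction is below machine
    noise and the target parameters are returned unchanged.
    """
    if sd == 0:
        return mean, 0.0
    if not lo < mean < hi:
        raise ValueError(f"mean {mean!r} must lie strictly inside ({lo}, {hi})")
    if (mean - lo) / sd > 6 and (hi - mean) / sd > 6:
        return mean, sd

    def eqs(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(eqs, x0=[mean, math.log(sd)], tol=1e-12)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(
            f"truncated-normal moment matching failed for mean={mean}, sd={sd}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _copula_corr(rho_metric: float, rho_time: float) -> np.ndarray:
    """4x4 correlation for (TIR_M0, TIR_M12, GRI_M0, GRI_M12) as a Kronecker
    product of the metric-level and time-level 2x2 correlations."""
    k_metric = np.array([[1.0, rho_metric], [rho_metric, 1.0]])
    k_time = np.array([[1.0, rho_time], [rho_time, 1.0]])
    return np.kron(k_metric, k_time)


def _draw_glycemic(
    n: int, arm: str, spec: CohortSpec, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Coupled (TIR_M0, TIR_M12, GRI_M0, GRI_M12) draws for one arm."""
    targets = [
        spec.tir[arm]["M0"], spec.tir[arm]["M12"],
        spec.gri[arm]["M0"], spec.gri[arm]["M12"],
    ]
    corr = _copula_corr(spec.tir_gri_corr, spec.longitudinal_corr)
    # shrink marginally degenerate correlations off the boundary for Cholesky
    if np.linalg.matrix_rank(corr) < 4:
        corr = 0.999999 * corr + 0.000001 * np.eye(4)
    z = rng.standard_normal((n, 4)) @ np.linalg.cholesky(corr).T
    u = stats.norm.cdf(z)
    out = np.empty((n, 4))
    for j, (m, sd) in enumerate(targets):
        if sd == 0:
            out[:, j] = m
            continue
        mu, sigma = truncnorm_parent_params(m, sd)
        a, b = (0.0 - mu) / sigma, (100.0 - mu) / sigma
        out[:, j] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sigma)
    return {"tir_m0": out[:, 0], "tir_m12": out[:, 1],
            "gri_m0": out[:, 2], "gri_m12": out[:, 3]}


def _patient_ids(arm: str, n: int) -> List[str]:
    return [f"{arm}-{i + 1:04d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> List[PatientRecord]:
    """Generate the full two-arm cohort of :class:`PatientRecord` objects.

    Deterministic for a given ``spec.seed``; ages lie in [16, 80]; all
    TIR/GRI values lie in [0, 100]; with all SDs zero every patient in an
    arm carries exactly the arm means.
    """
    records: List[PatientRecord] = []
    for arm_idx, arm in enumerate(spec.arms):
        rng = np.random.default_rng([spec.seed, arm_idx])
        n = spec.n_for(arm)
        gly = _draw_glycemic(n, arm, spec, rng)
        classes = rng.choice(len(AGE_CLASS_LABELS), size=n,
                             p=np.asarray(spec.age_class_props[arm]))
        ages = np.array([rng.uniform(*AGE_CLASS_BOUNDS[c]) for c in classes])
        sexes = np.where(rng.random(n) < spec.female_prop, "F", "M")
        bm, bsd = spec.bmi[arm]
        bmis = np.clip(rng.normal(bm, bsd, size=n), 15.0, 60.0)
        for i, pid in enumerate(_patient_ids(arm, n)):
            records.append(PatientRecord(
                patient_id=pid,
                arm=arm,
                age=float(ages[i]),
                age_class=AGE_CLASS_LABELS[classes[i]],
                sex=str(sexes[i]),
                bmi=float(bmis[i]),
                tir={"M0": float(gly["tir_m0"][i]), "M12": float(gly["tir_m12"][i])},
                gri={"M0": float(gly["gri_m0"][i]), "M12": float(gly["gri_m12"][i])},
            ))
    return records


def cohort_to_frame(records: List[PatientRecord]) -> pd.DataFrame:
    """Long-format frame: one row per patient-timepoint."""
    rows = []
    for r in records:
        for tp in r.tir:
            rows.append({
                "patient_id": r.patient_id, "arm": r.arm, "age": r.age,
                "age_class": r.age_class, "sex": r.sex, "bmi": r.bmi,
                "timepoint": tp, "tir": r.tir[tp], "gri": r.gri[tp],
            })
    return pd.DataFrame(rows)


_TRACE_EPOCH = np.datetime64("2024-01-01T00:00:00")

_BAND_RANGES = ((40.0, 54.0), (54.0, 70.0), (70.0, 180.0),
                (180.0, 250.0), (250.0, 400.0))


def _largest_remainder(pct: np.ndarray, n: int) -> np.ndarray:
    """Integer sample counts per band summing to n, closest to pct/100*n."""
    exact = pct * n / 100.0
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_cgm_trace(
    target: GlycemicProfile,
    duration_days: int,
    sampling_minutes: int,
    seed: int,
) -> GlucoseTrace:
    """Build a CGM trace whose band occupancy matches ``target``.

    Sample counts per band are allocated by largest-remainder rounding, so
    the recomputed profile matches the target within the rounding
    granularity (100 / number of readings).  Glucose values are uniform
    within each band; ordering is a deterministic seeded shuffle (the trace
    has no physiological dynamics — only correct occupancy).
    """
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    if sampling_minutes < 1:
        raise ValueError("sampling_minutes must be >= 1")
    n = duration_days * 24 * 60 // sampling_minutes
    counts = _largest_remainder(target.as_array(), n)
    rng = np.random.default_rng(seed)
    chunks = [rng.uniform(lo, hi, size=c)
              for c, (lo, hi) in zip(counts, _BAND_RANGES)]
    glucose = rng.permutation(np.concatenate(chunks))
    ts = _TRACE_EPOCH + np.arange(n) * np.timedelta64(sampling_minutes, "m")
    return GlucoseTrace(ts, glucose)


def generate_cost_items(
    arm: str,
    catalog: TariffCatalog,
    spec: CohortSpec,
    seed: int,
) -> List[CostItem]:
    """Care-pathway cost items for every patient of one arm.

    Each patient gets an initiation event (always a day hospitalization in
    the comparator arm; in the intervention arm a seeded ``dh_fraction``
    subset gets one and the rest an office visit), the specified
    teleconsultations and consultations, telemonitoring for a
    ``telemonitoring_fraction`` subset, and a single 12-month
    device/consumable item whose gamma-distributed amount calibrates the
    per-patient total to the arm's cost target.
    """
    n = spec.n_for(arm)
    is_intervention = arm == spec.intervention_label
    # fail fast, naming any missing code
    for key in (KEY_CONSULT, KEY_TELECONSULT, KEY_OFFICE_INIT, KEY_DH,
                KEY_TELEMONITOR, KEY_DEVICE):
        catalog.lookup(*key)

    rng = np.random.default_rng([seed, 0 if is_intervention else 1])
    n_dh = round(n * spec.dh_fraction) if is_intervention else n
    dh_flags = np.zeros(n, dtype=bool)
    dh_flags[rng.permutation(n)[:n_dh]] = True
    n_tlm = round(n * spec.telemonitoring_fraction)
    tlm_flags = np.zeros(n, dtype=bool)
    tlm_flags[rng.permutation(n)[:n_tlm]] = True

    tariff = {k: catalog.lookup(*k).tariff_eur
              for k in (KEY_CONSULT, KEY_TELECONSULT, KEY_OFFICE_INIT,
                        KEY_DH, KEY_TELEMONITOR, KEY_DEVICE)}
    mean_target, sd_target = spec.cost[arm]

    items: List[CostItem] = []
    for i, pid in enumerate(_patient_ids(arm, n)):
        fixed = 0.0
        init_key = KEY_DH if dh_flags[i] else KEY_OFFICE_INIT
        items.append(CostItem(pid, *init_key, 1, "M0"))
        fixed += tariff[init_key]
        if spec.n_teleconsultations:
            items.append(CostItem(pid, *KEY_TELECONSULT,
                                  spec.n_teleconsultations, "M0-M12"))
            fixed += spec.n_teleconsultations * tariff[KEY_TELECONSULT]
        if spec.n_consultations:
            items.append(CostItem(pid, *KEY_CONSULT,
                                  spec.n_consultations, "M0-M12"))
            fixed += spec.n_consultations * tariff[KEY_CONSULT]
        if tlm_flags[i] and spec.telemonitoring_months:
            items.append(CostItem(pid, *KEY_TELEMONITOR,
                                  spec.telemonitoring_months, "M0-M3"))
            fixed += spec.telemonitoring_months * tariff[KEY_TELEMONITOR]
        # device/consumable charge absorbs the calibration residual:
        # gamma mean = target - fixed part, SD = full target SD, so the
        # per-patient total has exactly the target mean and SD.
        dev_mean = mean_target - fixed
        if dev_mean <= 0:
            raise ValueError(
                f"cost target {mean_target} for arm {arm!r} is below the "
                f"fixed pathway cost {fixed}")
        if sd_target == 0:
            amount = dev_mean
        else:
            shape = (dev_mean / sd_target) ** 2
            amount = rng.gamma(shape, sd_target ** 2 / dev_mean)
        items.append(CostItem(pid, *KEY_DEVICE,
                              amount / tariff[KEY_DEVICE], "M0-M12"))
    return items
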