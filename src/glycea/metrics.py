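"""CGM band occupancy, time in range (TIR) and the Glycemia Risk Index (GRI).

A continuous glucose trace is summarised into five occupancy bands:

======  =================  ==========================
band    glucose (mg/dL)    clinical reading
======  =================  ==========================
vlow    < 54               clinically significant hypoglycemia
low     54 – 69            hypoglycemia alert range
tir     70 – 180           time in range
high    181 – 250          hyperglycemia
vhigh   > 250              clinically significant hyperglycemia
======  =================  ==========================

The GRI combines the out-of-range bands into a single 0–100 risk score::

    hypo  = vlow + 0.8 * low
    hyper = vhigh + 0.5 * high
    GRI   = min(100, 3.0 * hypo + 1.6 * hyper)

with risk zones A–E as equal 20-point quintiles (A minimal, E maximal risk).
The weighting constants come from the metric's defining publication
(Klonoff et al.'s Glycemia Risk Index); the zone grid is the standard
clinical display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CGM_FLOOR", "CGM_CEILING", "BAND_NAMES",
    "GlucoseTrace", "GlycemicProfile", "GriResult",
    "profile_from_trace", "compute_tir", "compute_gri",
    "classify_gri_zone", "metric_delta", "zone_grid_counts",
]

#: CGM sensor reporting range — raw values are clamped into it.
CGM_FLOOR = 40.0
CGM_CEILING = 400.0
#: Raw values outside this physiological plausibility window are rejected.
RAW_MIN = 20.0
RAW_MAX = 600.0

BAND_NAMES = ("vlow", "low", "tir", "high", "vhigh")

# GRI component weights and clip, per the index's source publication.
_W_LOW = 0.8
_W_HIGH = 0.5
_W_HYPO = 3.0
_W_HYPER = 1.6
_GRI_MAX = 100.0

_ZONE_EDGES = (20.0, 40.0, 60.0, 80.0)
_ZONE_LABELS = ("A", "B", "C", "D", "E")


class GlucoseTrace:
    """An ordered CGM time series of (timestamp, glucose mg/dL) readings.

    Raw glucose values outside [20, 600] mg/dL are rejected as implausible;
    values outside the sensor reporting range [40, 400] are clamped to it.
    Timestamps must be strictly increasing.
    """

    def __init__(self, timestamps: Sequence, glucose: Sequence[float]):
        ts = pd.to_datetime(pd.Series(timestamps)).to_numpy()
        g = np.asarray(glucose, dtype=float)
        if ts.shape[0] != g.shape[0]:
            raise ValueError("timestamps and glucose must have equal length")
        if ts.shape[0] == 0:
            raise ValueError("trace must contain at least one reading")
        if ts.shape[0] > 1 and not (np.diff(ts).astype("timedelta64[ns]") > np.timedelta64(0)).all():
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(g)) or np.any(g < RAW_MIN) or np.any(g > RAW_MAX):
            raise ValueError(
                f"raw glucose values must lie within [{RAW_MIN:g}, {RAW_MAX:g}] mg/dL"
            )
        self.timestamps = ts
        self.glucose = np.clip(g, CGM_FLOOR, CGM_CEILING)

    def __len__(self) -> int:
        return len(self.glucose)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "glucose": self.glucose})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = pd.Series(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GlucoseTrace":
        df = pd.read_csv(path)
        return cls(df["timestamp"], df["glucose"])

    def reading_weights(self) -> np.ndarray:
        """Per-reading time weights.

        Uniform sampling gives equal weights.  Irregular sampling weights each
        reading by the interval to the next one (the last reading gets the
        median interval), capped at twice the median interval so isolated
        gaps cannot dominate the summary.
        """
        n = len(self)
        if n == 1:
            return np.ones(1)
        dt = np.diff(self.timestamps).astype("timedelta64[s]").astype(float)
        if np.allclose(dt, dt[0]):
            return np.ones(n)
        med = float(np.median(dt))
        w = np.append(dt, med)
        return np.minimum(w, 2.0 * med)


@dataclass(frozen=True)
class GlycemicProfile:
    """Percent of CGM time spent in each of the five glucose bands."""

    pct_vlow: float
    pct_low: float
    pct_tir: float
    pct_high: float
    pct_vhigh: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError(f"band percentages must lie in [0, 100], got {tuple(vals)}")
        if abs(vals.sum() - 100.0) > 1e-6:
            raise ValueError(f"band percentages must sum to 100, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pct_vlow, self.pct_low, self.pct_tir,
                         self.pct_high, self.pct_vhigh], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "GlycemicProfile":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class GriResult:
    """GRI decomposition: hypo/hyper components, composite score, risk zone."""

    hypo_component: float
    hyper_component: float
    gri: float
    zone: str


def _band_of(glucose: np.ndarray) -> np.ndarray:
    """Band index 0..4 for each glucose value.

    Edge convention: vlow g<54; low 54<=g<70; tir 70<=g<=180;
    high 180<g<=250; vhigh g>250 — matching the printed integer band labels
    with no gaps on the continuous axis.
    """
    idx = np.full(glucose.shape, 2, dtype=int)
    idx[glucose < 54] = 0
    idx[(glucose >= 54) & (glucose < 70)] = 1
    idx[(glucose > 180) & (glucose <= 250)] = 3
    idx[glucose > 250] = 4
    return idx


def profile_from_trace(trace: GlucoseTrace) -> GlycemicProfile:
    """Summarise a glucose trace into band-occupancy percentages.

    Readings are time-weighted via :meth:`GlucoseTrace.reading_weights`;
    for uniformly sampled traces this reduces to simple reading counts.
    """
    if len(trace) == 0:
        raise ValueError("cannot summarise an empty trace")
    bands = _band_of(trace.glucose)
    w = trace.reading_weights()
    occ = np.bincount(bands, weights=w, minlength=5)
    pct = 100.0 * occ / occ.sum()
    # guard against floating error pushing the sum off 100
    pct[int(np.argmax(pct))] += 100.0 - pct.sum()
    return GlycemicProfile.from_array(np.clip(pct, 0.0, 100.0))


def compute_tir(profile: GlycemicProfile) -> float:
    """Time in range 70–180 mg/dL, in percent."""
    return profile.pct_tir


def compute_gri(profile: GlycemicProfile) -> GriResult:
    """Glycemia Risk Index of a band-occupancy profile.

    hypo = vlow + 0.8*low; hyper = vhigh + 0.5*high;
    GRI = min(100, 3.0*hypo + 1.6*hyper); zone per 20-point quintiles.
    """
    hypo = profile.pct_vlow + _W_LOW * profile.pct_low
    hyper = profile.pct_vhigh + _W_HIGH * profile.pct_high
    gri = min(_GRI_MAX, _W_HYPO * hypo + _W_HYPER * hyper)
    return GriResult(hypo, hyper, gri, classify_gri_zone(gri))


def classify_gri_zone(gri: float) -> str:
    """Risk zone of a GRI score: A (0,20], B (20,40], C (40,60], D (60,80], E (80,100].

    Zone A is closed at 0; each zone is closed at its upper edge.
    """
    if not np.isfinite(gri) or gri < 0 or gri > 100:
        raise ValueError(f"GRI must lie in [0, 100], got {gri!r}")
    return _ZONE_LABELS[int(np.searchsorted(_ZONE_EDGES, gri, side="left"))]


def metric_delta(value_m0: float, value_m12: float) -> float:
    """Signed longitudinal change (follow-up minus baseline) of a 0–100 metric."""
    for v in (value_m0, value_m12):
        if not 0 <= v <= 100:
            raise ValueError(f"metric values must lie in [0, 100], got {v!r}")
    return value_m12 - value_m0


def zone_grid_counts(cohort: pd.DataFrame, timepoint: str) -> dict:
    """Per-zone patient counts at a timepoint, and the fraction in zones C–E.

    ``cohort`` is a long-format frame with columns ``patient_id``,
    ``timepoint`` and ``gri`` (see :func:`glycea.cohort.cohort_to_frame`).
    Returns ``{"n", "counts": {zone: count}, "cde_count", "cde_fraction"}``.
    """
    pat_ids = cohort["patient_id"].unique()
    at_tp = cohort[cohort["timepoint"] == timepoint]
    have = at_tp.dropna(subset=["gri"])["patient_id"].unique()
    missing = sorted(set(pat_ids) - set(have))
    if missing:
        raise ValueError(
            f"no GRI at timepoint {timepoint!r} for patients: {missing}"
        )
    zones = at_tp["gri"].map(classify_gri_zone)
    counts = {z: int((zones == z).sum()) for z in _ZONE_LABELS}
    n = int(len(at_tp))
    cde = counts["C"] + counts["D"] + counts["E"]
    return {"n": n, "counts": counts, "cde_count": cde, "cde_fraction": cde / n}


def profiles_to_csv(profiles: Mapping[tuple, GlycemicProfile], path) -> None:
    """Write profiles keyed by (patient_id, timepoint) as CSV rows."""
    rows = [
        {"patient_id": pid, "timepoint": tp,
         **dict(zip([f"pct_{b}" for b in BAND_NAMES], prof.as_array()))}
        for (pid, tp), prof in profiles.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
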