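"""Bottom-up micro-costing of care-pathway events against a tariff catalog.

Every resource-use item (consultation, teleconsultation, day hospitalization,
telemonitoring, device rental and consumables) is priced from the payer
perspective against a unit tariff keyed by French payer nomenclature
(NGAP professional acts, CCAM medical procedures, NABM laboratory acts,
LPP devices, GHS hospital-stay groups).  The one-year horizon means no
discounting, and full coverage of type 1 diabetes means no out-of-pocket
share: the price of an item is simply quantity × unit tariff.

Tariffs live in a versioned catalog file; the catalog shipped with the
package carries plausible placeholder values, not official tariffs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "NOMENCLATURE_SOURCES", "TariffEntry", "TariffCatalog", "CostItem",
    "PatientCostRecord", "UnknownTariffError", "price_item",
    "patient_total_cost", "arm_cost_summary", "default_catalog",
]

NOMENCLATURE_SOURCES = ("NGAP", "CCAM", "NABM", "LPP", "GHS")

#: Reporting metadata only (study-period exchange rate); never used in pricing.
EUR_TO_USD = 1.10


class UnknownTariffError(KeyError):
    """A cost item references a (source, code) absent from the catalog."""


@dataclass(frozen=True)
class TariffEntry:
    source: str
    code: str
    description: str
    tariff_eur: float
    year: int

    def __post_init__(self):
        if self.source not in NOMENCLATURE_SOURCES:
            raise ValueError(f"unknown nomenclature source {self.source!r}")
        if self.tariff_eur < 0:
            raise ValueError(f"tariff must be >= 0, got {self.tariff_eur!r}")


class TariffCatalog:
    """Unit tariffs keyed by (nomenclature source, code)."""

    def __init__(self, entries: Iterable[TariffEntry] = ()):
        self._entries: Dict[Tuple[str, str], TariffEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: TariffEntry) -> None:
        key = (entry.source, entry.code)
        if key in self._entries:
            raise ValueError(f"duplicate catalog key {key}")
        self._entries[key] = entry

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return tuple(key) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, source: str, code: str) -> TariffEntry:
        try:
            return self._entries[(source, code)]
        except KeyError:
            raise UnknownTariffError(
                f"no tariff for ({source!r}, {code!r}) in catalog"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self._entries.values()])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([vars(e) for e in self._entries.values()], fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "TariffCatalog":
        df = pd.read_csv(path)
        return cls(
            TariffEntry(r.source, str(r.code), r.description,
                        float(r.tariff_eur), int(r.year))
            for r in df.itertuples()
        )

    @classmethod
    def from_json(cls, path) -> "TariffCatalog":
        with open(path) as fh:
            rows = json.load(fh)
        return cls(
            TariffEntry(r["source"], str(r["code"]), r["description"],
                        float(r["tariff_eur"]), int(r["year"]))
            for r in rows
        )

    @classmethod
    def from_file(cls, path) -> "TariffCatalog":
        p = str(path)
        return cls.from_json(path) if p.endswith(".json") else cls.from_csv(path)


def default_catalog() -> TariffCatalog:
    """Catalog of the care-pathway events with placeholder 2024 tariffs.

    Values are plausible orders of magnitude for the French payer schedule,
    not official tariffs; analyses meant to reflect actual reimbursement
    must load a real catalog file.
    """
    return TariffCatalog([
        TariffEntry("NGAP", "CS", "Specialist follow-up consultation", 30.00, 2024),
        TariffEntry("NGAP", "TCG", "Teleconsultation", 30.00, 2024),
        TariffEntry("CCAM", "INIT-OV", "Closed-loop initiation, long office visit", 61.50, 2024),
        TariffEntry("GHS", "1794", "Day hospitalization, pump adjustment (Z451)", 795.00, 2024),
        TariffEntry("LPP", "TLM-M", "Telemonitoring package, per month", 50.00, 2024),
        TariffEntry("LPP", "CL-RENT-M", "Closed-loop system rental and consumables, per month", 610.00, 2024),
    ])


@dataclass(frozen=True)
class CostItem:
    """One resource-use event for one patient, to be priced from the catalog.

    ``quantity`` counts acts or months; fractional quantities express partial
    utilisation of a monthly charge (e.g. consumable over/under-use).
    """

    patient_id: str
    source: str
    code: str
    quantity: float
    timepoint: str = ""

    def __post_init__(self):
        if not self.quantity > 0:
            raise ValueError(f"quantity must be > 0, got {self.quantity!r}")


@dataclass
class PatientCostRecord:
    patient_id: str
    arm: str
    total_eur: float
    subtotals_eur: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.total_eur - sum(self.subtotals_eur.values())) > 1e-6:
            raise ValueError("total must equal the sum of subtotals")


def price_item(item: CostItem, catalog: TariffCatalog) -> float:
    """Price of one item: quantity × unit tariff (EUR, undiscounted)."""
    entry = catalog.lookup(item.source, item.code)
    return item.quantity * entry.tariff_eur


def patient_total_cost(
    items: Iterable[CostItem],
    catalog: TariffCatalog,
    arm: str = "",
    patient_id: Optional[str] = None,
) -> PatientCostRecord:
    """Total cost for one patient with subtotals by nomenclature source."""
    subtotals: Dict[str, float] = {}
    pid = patient_id or ""
    for item in items:
        pid = pid or item.patient_id
        if patient_id is not None and item.patient_id != patient_id:
            raise ValueError(
                f"item for patient {item.patient_id!r} in list for {patient_id!r}"
            )
        try:
            p = price_item(item, catalog)
        except UnknownTariffError as e:
            raise UnknownTariffError(f"patient {pid!r}: {e.args[0]}") from None
        subtotals[item.source] = subtotals.get(item.source, 0.0) + p
    return PatientCostRecord(pid, arm, sum(subtotals.values()), subtotals)


def arm_cost_summary(
    records: Iterable[PatientCostRecord], arm: str
) -> Tuple[int, float, float, float]:
    """(n, mean, sample SD, total) of per-patient costs in one arm.

    The SD uses the n−1 denominator; a singleton arm reports SD 0 with a
    warning.  mean × n equals total by construction.
    """
    costs = np.array([r.total_eur for r in records if r.arm == arm], dtype=float)
    n = len(costs)
    if n == 0:
        raise ValueError(f"no cost records for arm {arm!r}")
    if n == 1:
        warnings.warn(f"arm {arm!r} has a single patient; SD reported as 0")
        return 1, float(costs[0]), 0.0, float(costs[0])
    return n, float(costs.mean()), float(costs.std(ddof=1)), float(costs.sum())


def cost_records_to_frame(records: Iterable[PatientCostRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "arm": r.arm, "total_eur": r.total_eur}
        for src in NOMENCLATURE_SOURCES:
            row[f"eur_{src.lower()}"] = r.subtotals_eur.get(src, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def cost_items_to_frame(items: Iterable[CostItem]) -> pd.DataFrame:
    return pd.DataFrame([vars(i) for i in items])
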