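"""2x2 contingency tables for drug-event pairs.

The counting unit everywhere is the report x event pair: each Preferred Term
counts once per report, and denominators are pair totals, not report totals.
SOC-level tables roll each report-PT pair up to its SOC without re-deduplication
so pair totals are conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .faers_io import PtSocMap

logger = logging.getLogger(__name__)

#: PTs folded into a single device-use term (case-insensitive match)
DEVICE_PT_MERGE = frozenset(
    {"device use issue", "wrong technique in product usage process", "product use issue"}
)
DEVICE_PT_LABEL = "Device use issue"


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the 2x2 drug/event table.

    ``a`` target-drug pairs with the event, ``b`` target pairs without it,
    ``c`` non-target pairs with it, ``d`` non-target pairs without it.
    Cells may be floats for expected (analytic) tables.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError(f"negative cell in contingency table: {self}")
        if self.n <= 0:
            raise ValueError("contingency table is empty (N = 0)")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def merge_device_pts(reac: pd.DataFrame) -> pd.DataFrame:
    """Relabel the three device-handling PTs to a single term.

    After relabeling, (report, PT) pairs are re-deduplicated so a report that
    listed two of the merged terms contributes one pair.
    """
    out = reac.copy()
    if out.empty:
        return out
    key = out["pt"].str.strip().str.casefold()
    out["pt"] = np.where(key.isin(DEVICE_PT_MERGE), DEVICE_PT_LABEL, out["pt"].str.strip())
    dedup_key = out["pt"].str.casefold()
    keep = ~pd.DataFrame({"primaryid": out["primaryid"], "pt": dedup_key}).duplicated()
    return out.loc[keep].reset_index(drop=True)


def build_events(
    reac: pd.DataFrame, cases: pd.DataFrame, pt_soc_map: PtSocMap
) -> pd.DataFrame:
    """Join reactions to retained cases and attach SOCs.

    Returns one row per (caseid, pt) pair with columns ``caseid, pt, soc``.
    Reactions attached to dropped duplicate versions are excluded.
    """
    if reac.empty or cases.empty:
        return pd.DataFrame(columns=["caseid", "pt", "soc"])
    lookup = cases.set_index("primaryid")["caseid"]
    ev = pd.DataFrame(
        {"caseid": reac["primaryid"].map(lookup), "pt": reac["pt"].str.strip()}
    ).dropna(subset=["caseid"])
    ev = ev[ev["pt"] != ""]
    key = ev["pt"].str.casefold()
    ev = ev.loc[~pd.DataFrame({"c": ev["caseid"], "k": key}).duplicated().to_numpy()]
    ev = ev.reset_index(drop=True)
    ev["soc"] = pt_soc_map.map_series(ev["pt"])
    return ev


def _stratum_caseids(cases: pd.DataFrame, stratum: Mapping[str, object]) -> set:
    mask = pd.Series(True, index=cases.index)
    for col, value in stratum.items():
        if col not in cases.columns:
            raise KeyError(f"unknown stratum variable {col!r}")
        mask &= cases[col] == value
    return set(cases.loc[mask, "caseid"])


def tabulate(
    events: pd.DataFrame,
    target_caseids: Iterable,
    level: str = "PT",
    cases: pd.DataFrame | None = None,
    stratum: Mapping[str, object] | None = None,
) -> dict[str, ContingencyTable]:
    """Build one 2x2 table per event at PT or SOC level.

    ``stratum`` filters on case attributes (``sex``, ``age_bin``, ``country``,
    ``year``, ``quarter``) and requires ``cases``.  For each event in the
    stratum: ``a`` = target pairs with the event, ``a+b`` = all target pairs,
    ``a+c`` = all pairs with the event, ``N`` = all pairs.  Events with no
    pairs in the stratum are simply absent from the result.
    """
    if level not in {"PT", "SOC"}:
        raise ValueError("level must be 'PT' or 'SOC'")
    target_caseids = set(target_caseids)
    ev = events
    if stratum:
        if cases is None:
            raise ValueError("stratified tabulation requires the cases frame")
        keep = _stratum_caseids(cases, stratum)
        ev = ev[ev["caseid"].isin(keep)]
    if ev.empty:
        return {}

    label = ev["pt"] if level == "PT" else ev["soc"]
    is_target = ev["caseid"].isin(target_caseids).to_numpy()
    n_total = len(ev)
    n_target = int(is_target.sum())

    ac = label.value_counts()
    a = label[is_target].value_counts()

    out: dict[str, ContingencyTable] = {}
    for event, n_event in ac.items():
        a_cell = int(a.get(event, 0))
        out[event] = ContingencyTable(
            a=a_cell,
            b=n_target - a_cell,
            c=int(n_event) - a_cell,
            d=n_total - n_target - int(n_event) + a_cell,
        )
    return out


def yearly_series(
    events: pd.DataFrame,
    target_caseids: Iterable,
    pt: str,
    cases: pd.DataFrame,
    mode: str = "per_year",
    min_years: int = 2,
) -> list[tuple[int, ContingencyTable]]:
    """Time-scan tables for one PT by calendar year of the retained report.

    Qualifying years have at least one target pair for the PT; the series is
    emitted only when at least ``min_years`` years qualify.  ``per_year``
    tabulates each year alone; ``cumulative`` pools all years up to and
    including each qualifying year (so the last cumulative table equals the
    overall table).
    """
    if mode not in {"per_year", "cumulative"}:
        raise ValueError("mode must be 'per_year' or 'cumulative'")
    target_caseids = set(target_caseids)
    year_of = cases.set_index("caseid")["year"]
    ev = events.copy()
    ev["year"] = ev["caseid"].map(year_of)
    ev = ev.dropna(subset=["year"])
    ev["year"] = ev["year"].astype(int)

    key = pt.strip().casefold()
    is_pt = ev["pt"].str.casefold() == key
    is_target = ev["caseid"].isin(target_caseids)
    qualifying = sorted(ev.loc[is_pt & is_target, "year"].unique())
    if len(qualifying) < min_years:
        return []

    out: list[tuple[int, ContingencyTable]] = []
    for year in qualifying:
        sub = ev[ev["year"] == year] if mode == "per_year" else ev[ev["year"] <= year]
        tables = tabulate(sub, target_caseids, level="PT")
        match = next((t for name, t in tables.items() if name.casefold() == key), None)
        if match is not None:
            out.append((int(year), match))
    return out
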