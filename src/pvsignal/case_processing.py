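"""Case-level screening: deduplication, drug standardization, target selection.

The screening flow mirrors a typical spontaneous-report study: concatenate
quarterly DEMO tables, keep the latest version of each case, standardize free-
text drug names to canonical ingredients with a synonym dictionary, then select
the reports naming the target ingredient in a chosen role (primary suspect by
default).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .faers_io import SynonymDict

logger = logging.getLogger(__name__)

OTHER_INGREDIENT = "OTHER"

AGE_BIN_LABELS = ("<18", "18-39", "40-65", "66-79", ">=80", "unknown")
#: right-open bin edges in years; the "40-65" label covers [40, 66) so the
#: partition is exhaustive, and "66-79" covers [66, 80)
_AGE_EDGES = (0.0, 18.0, 40.0, 66.0, 80.0, np.inf)

DEFAULT_ROLES = frozenset({"PS"})

#: default dictionary for the two single-inhaler triple-therapy products;
#: brand and ingredient-combination spellings, first match wins
DEFAULT_SYNONYMS: list[tuple[str, str]] = [
    (r"breztri", "BUD/GLY/FOR"),
    (r"trixeo", "BUD/GLY/FOR"),
    (r"budesonide.{0,3}glycopyrr\w*.{0,3}formoterol", "BUD/GLY/FOR"),
    (r"trelegy", "FF/UMEC/VI"),
    (r"fluticasone( furoate)?.{0,3}umeclidinium.{0,3}vilanterol", "FF/UMEC/VI"),
]


def default_synonym_dict() -> SynonymDict:
    return SynonymDict(DEFAULT_SYNONYMS)


def assign_age_bin(age_years: float | None) -> str:
    """Map an age in years to its demographic bin label.

    Missing and negative ages map to ``"unknown"`` (negatives are logged).
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    if age_years < 0:
        logger.warning("negative age %.2f treated as unknown", age_years)
        return "unknown"
    idx = int(np.searchsorted(_AGE_EDGES, age_years, side="right")) - 1
    return AGE_BIN_LABELS[min(idx, len(AGE_BIN_LABELS) - 2)]


def assign_age_bins(age_years: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_age_bin`."""
    vals = pd.to_numeric(age_years, errors="coerce").to_numpy(dtype=float)
    neg = vals < 0
    if neg.any():
        logger.warning("%d negative age(s) treated as unknown", int(neg.sum()))
    out = pd.cut(
        np.where(neg, np.nan, vals),
        bins=list(_AGE_EDGES),
        right=False,
        labels=list(AGE_BIN_LABELS[:-1]),
    ).astype(object)
    return pd.Series(np.where(pd.isna(out), "unknown", out), index=age_years.index)


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse DEMO rows to one record per case.

    The retained version maximizes ``(fda_dt, caseversion, primaryid)``
    lexicographically; a missing or malformed receipt date sorts lowest.

    Returns ``(cases, n_dropped)`` where ``cases`` has one row per ``caseid``
    with derived ``year``, ``quarter`` and ``age_bin`` columns.
    """
    if demo.empty:
        cases = pd.DataFrame(
            columns=[
                "caseid", "primaryid", "fda_dt", "year", "quarter",
                "sex", "age_years", "age_bin", "reporter", "country",
            ]
        )
        return cases, 0

    df = demo.copy()
    valid = df["fda_dt_valid"] if "fda_dt_valid" in df else df["fda_dt"].str.fullmatch(r"\d{8}").fillna(False)
    df["_dt_key"] = np.where(valid, df["fda_dt"], "")
    df["_ver_key"] = pd.to_numeric(df["caseversion"], errors="coerce").fillna(-1.0)
    df = df.sort_values(
        ["caseid", "_dt_key", "_ver_key", "primaryid"], kind="mergesort"
    )
    kept = df.drop_duplicates(subset="caseid", keep="last").drop(columns=["_dt_key", "_ver_key"])
    n_dropped = len(df) - len(kept)

    dt_ok = kept["fda_dt_valid"] if "fda_dt_valid" in kept else kept["fda_dt"].str.fullmatch(r"\d{8}").fillna(False)
    years = pd.to_numeric(kept["fda_dt"].str[:4], errors="coerce").where(dt_ok)
    months = pd.to_numeric(kept["fda_dt"].str[4:6], errors="coerce").where(dt_ok)
    qnum = ((months - 1) // 3 + 1)
    quarter = np.where(
        dt_ok, years.astype("Int64").astype(str) + "Q" + qnum.astype("Int64").astype(str), "unknown"
    )

    cases = pd.DataFrame(
        {
            "caseid": kept["caseid"].to_numpy(),
            "primaryid": kept["primaryid"].to_numpy(),
            "fda_dt": kept["fda_dt"].to_numpy(),
            "year": years.astype("Int64").to_numpy(),
            "quarter": quarter,
            "sex": kept.get("sex", pd.Series("UNK", index=kept.index)).to_numpy(),
            "age_years": kept.get("age_years", pd.Series(np.nan, index=kept.index)).to_numpy(),
            "reporter": kept.get("reporter", pd.Series("UNK", index=kept.index)).to_numpy(),
            "country": kept.get("country", pd.Series("Unknown", index=kept.index)).to_numpy(),
        }
    )
    cases["age_bin"] = assign_age_bins(cases["age_years"]).to_numpy()
    cases = cases.reset_index(drop=True)
    logger.info("deduplicate: %d rows in, %d cases out, %d dropped", len(demo), len(cases), n_dropped)
    return cases, n_dropped


def standardize_drugs(drug: pd.DataFrame, dictionary: SynonymDict) -> pd.DataFrame:
    """Label each drug mention with its canonical ingredient.

    Matching is case-insensitive, ignores surrounding whitespace, and uses the
    dictionary's first-match-wins order; unmatched names get ``"OTHER"``.
    """
    if len(dictionary) == 0:
        raise ValueError("synonym dictionary is empty")
    out = drug.copy()
    if out.empty:
        out["canonical_ingredient"] = pd.Series(dtype=object)
        return out
    out["canonical_ingredient"] = dictionary.match_series(out["drugname"].astype(str))
    return out


def join_to_cases(table: pd.DataFrame, cases: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Attach ``caseid`` by primaryid, keeping only retained case versions.

    Rows whose primaryid does not belong to any retained case are dropped and
    counted (returned alongside the joined frame).
    """
    lookup = cases.set_index("primaryid")["caseid"]
    joined = table.copy()
    joined["caseid"] = joined["primaryid"].map(lookup)
    n_dropped = int(joined["caseid"].isna().sum())
    if n_dropped:
        logger.info("join_to_cases: dropped %d row(s) without a retained case version", n_dropped)
    return joined.dropna(subset=["caseid"]).reset_index(drop=True), n_dropped


def select_target_reports(
    assignments: pd.DataFrame,
    target: str,
    roles: Iterable[str] = DEFAULT_ROLES,
) -> set:
    """Case ids with at least one target-ingredient mention in the given roles."""
    roles = frozenset(roles)
    if not roles:
        raise ValueError("roles must be a non-empty set of role codes")
    bad = roles - {"PS", "SS", "C", "I"}
    if bad:
        raise ValueError(f"unknown role code(s): {sorted(bad)}")
    if assignments.empty:
        return set()
    mask = (assignments["canonical_ingredient"] == target) & assignments["role_cod"].isin(roles)
    return set(assignments.loc[mask, "caseid"])
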