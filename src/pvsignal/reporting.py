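"""Study orchestration and report surfaces.

``run_study`` executes the full workflow for each target drug over its own
quarter window — ingest, dedup, standardize, select, device-PT merge, event
building, tabulation (overall, SOC, subgroup, yearly), statistics, thresholds,
IC ranking — and writes deterministic CSV outputs:

    screening_flow.csv, quarterly_counts.csv, demographics.csv,
    soc_signals.csv, pt_signals.csv, subgroup_signals.csv, timescan.csv

All printed percentages use half-up rounding to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import case_processing as cp
from . import contingency as ct
from . import signal_stats as ss
from .faers_io import PtSocMap, SynonymDict, load_pt_soc_map, load_synonym_dict, read_table

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "screening_flow.csv",
    "quarterly_counts.csv",
    "demographics.csv",
    "soc_signals.csv",
    "pt_signals.csv",
    "subgroup_signals.csv",
    "timescan.csv",
)

_REPORTER_DISPLAY = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "UNK": "Unknown",
}
_SEX_DISPLAY = {"F": "Female", "M": "Male", "UNK": "Unknown"}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matches how the tables print percents)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def pt_percent(a: float, total_pairs: float) -> float:
    """Share of all drug-event pairs held by one event, as a printed percent."""
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    return round_half_up(100.0 * a / total_pairs)


def percent(count: float, total: float) -> float:
    if total <= 0:
        return 0.0
    return round_half_up(100.0 * count / total)


def quarterly_counts(cases: pd.DataFrame) -> pd.DataFrame:
    """Report counts per receipt quarter with printed percents."""
    total = len(cases)
    counts = cases["quarter"].value_counts().sort_index()
    return pd.DataFrame(
        {
            "quarter": counts.index.to_numpy(),
            "count": counts.to_numpy(),
            "percent": [percent(c, total) for c in counts.to_numpy()],
        }
    )


def demographics_table(cases: pd.DataFrame, top_countries: int = 5) -> pd.DataFrame:
    """Baseline characteristics blocks: sex, age bin, reporter, country, year.

    Countries below the top ``top_countries`` by report count are pooled as
    ``"Other"``; ties on count break lexicographically.
    """
    total = len(cases)
    blocks: list[tuple[str, str, int]] = []

    sex_counts = cases["sex"].value_counts()
    for code in ("F", "M", "UNK"):
        if code in sex_counts:
            blocks.append(("sex", _SEX_DISPLAY[code], int(sex_counts[code])))

    age_counts = cases["age_bin"].value_counts()
    for label in cp.AGE_BIN_LABELS:
        if label in age_counts:
            blocks.append(("age", label, int(age_counts[label])))

    rep_counts = cases["reporter"].value_counts()
    for code in ("CN", "MD", "PH", "OT", "UNK"):
        if code in rep_counts:
            blocks.append(("reporter", _REPORTER_DISPLAY[code], int(rep_counts[code])))

    country_counts = cases["country"].value_counts()
    ordered = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [name for name, _ in ordered[:top_countries]]
    pooled = int(sum(cnt for name, cnt in ordered[top_countries:]))
    for name in top:
        blocks.append(("country", name, int(country_counts[name])))
    if pooled:
        blocks.append(("country", "Other", pooled))

    year_counts = cases["year"].value_counts().sort_index()
    for year, cnt in year_counts.items():
        blocks.append(("year", str(int(year)), int(cnt)))

    return pd.DataFrame(
        [(b, cat, cnt, percent(cnt, total)) for b, cat, cnt in blocks],
        columns=["block", "category", "count", "percent"],
    )


# ---------------------------------------------------------------------------
# study configuration and orchestration


def quarter_range(start: str, end: str) -> tuple[str, ...]:
    """Inclusive quarter window, e.g. ('2020Q3', ..., '2024Q3')."""
    rng = pd.period_range(start=start, end=end, freq="Q")
    if len(rng) == 0:
        raise ValueError(f"empty quarter window {start}..{end}")
    return tuple(str(p) for p in rng)


@dataclass
class StudyConfig:
    input_dir: Path
    targets: dict[str, tuple[str, ...]]  # ingredient -> quarters in its window
    output_dir: Path
    pt_soc_map_path: Path | None = None
    synonym_dict_path: Path | None = None
    roles: frozenset = cp.DEFAULT_ROLES
    top_k: int = 10
    rank_exclusions: tuple[str, ...] = ss.DEFAULT_RANK_EXCLUSIONS
    yates: bool = True
    continuity: bool = False
    timescan_mode: str = "per_year"
    timescan_extra_pts: tuple[str, ...] = ("Pneumonia",)
    subgroups: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        targets = {}
        for name, window in doc["targets"].items():
            if isinstance(window, dict):
                targets[name] = quarter_range(window["start"], window["end"])
            else:
                targets[name] = tuple(window)
        kwargs = dict(
            input_dir=Path(doc["input_dir"]),
            targets=targets,
            output_dir=Path(doc["output_dir"]),
        )
        for key in ("pt_soc_map_path", "synonym_dict_path"):
            if doc.get(key):
                kwargs[key] = Path(doc[key])
        for key in (
            "top_k", "yates", "continuity", "timescan_mode", "subgroups", "seed",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        if "roles" in doc:
            kwargs["roles"] = frozenset(doc["roles"])
        if "rank_exclusions" in doc:
            kwargs["rank_exclusions"] = tuple(doc["rank_exclusions"])
        if "timescan_extra_pts" in doc:
            kwargs["timescan_extra_pts"] = tuple(doc["timescan_extra_pts"])
        return cls(**kwargs)


@dataclass
class StudyBundle:
    screening_flow: pd.DataFrame
    quarterly_counts: pd.DataFrame
    demographics: pd.DataFrame
    soc_signals: pd.DataFrame
    pt_signals: pd.DataFrame
    subgroup_signals: pd.DataFrame
    timescan: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)

    def write(self, output_dir: str | Path) -> None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        frames = {
            "screening_flow.csv": self.screening_flow,
            "quarterly_counts.csv": self.quarterly_counts,
            "demographics.csv": self.demographics,
            "soc_signals.csv": self.soc_signals,
            "pt_signals.csv": self.pt_signals,
            "subgroup_signals.csv": self.subgroup_signals,
            "timescan.csv": self.timescan,
        }
        for name, frame in frames.items():
            frame.to_csv(output_dir / name, index=False, float_format="%.6g")
        (output_dir / "run_log.txt").write_text("\n".join(self.log_lines) + "\n", encoding="utf-8")


def _read_window(input_dir: Path, quarters: tuple[str, ...], prefix: str, schema: str) -> tuple[pd.DataFrame, int]:
    frames = []
    total = 0
    for q in quarters:
        path = input_dir / f"{prefix}_{q}.txt"
        if not path.is_file():
            raise FileNotFoundError(f"missing {schema} table for quarter {q}: {path}")
        parsed = read_table(path, schema)
        total += parsed.n_rows
        frames.append(parsed.frame)
    joined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return joined, total


def _signal_frame_sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["drug", "level", "ic", "a", "event"],
        ascending=[True, True, False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)


def run_study(config: StudyConfig) -> StudyBundle:
    """Execute the full analysis for every configured target drug.

    Each drug is analyzed over its own quarter window; the background for its
    2x2 tables is every other report loaded in that window.  Results are
    written under ``config.output_dir`` and returned as frames.
    """
    stage = "setup"
    log: list[str] = []
    try:
        if config.pt_soc_map_path is not None:
            pt_soc = load_pt_soc_map(config.pt_soc_map_path)
        else:
            raise ValueError("pt_soc_map_path is required")
        synonyms = (
            load_synonym_dict(config.synonym_dict_path)
            if config.synonym_dict_path is not None
            else cp.default_synonym_dict()
        )

        flow_rows: list[tuple] = []
        quarterly_frames: list[pd.DataFrame] = []
        demo_frames: list[pd.DataFrame] = []
        pt_frames: list[pd.DataFrame] = []
        soc_frames: list[pd.DataFrame] = []
        sub_frames: list[pd.DataFrame] = []
        scan_frames: list[pd.DataFrame] = []
        overlap_cases: dict[str, set] = {}

        for drug_name in sorted(config.targets):
            quarters = config.targets[drug_name]
            stage = f"ingest[{drug_name}]"
            demo, n_demo_rows = _read_window(config.input_dir, quarters, "demo", "DEMO")
            drug_tab, _ = _read_window(config.input_dir, quarters, "drug", "DRUG")
            reac_tab, _ = _read_window(config.input_dir, quarters, "reac", "REAC")

            stage = f"dedup[{drug_name}]"
            cases, n_dropped = cp.deduplicate(demo)

            stage = f"standardize[{drug_name}]"
            assignments = cp.standardize_drugs(drug_tab, synonyms)
            assignments, n_orphan = cp.join_to_cases(assignments, cases)

            stage = f"select[{drug_name}]"
            target_ids = cp.select_target_reports(assignments, drug_name, config.roles)
            overlap_cases[drug_name] = target_ids

            stage = f"events[{drug_name}]"
            reac_merged = ct.merge_device_pts(reac_tab)
            events = ct.build_events(reac_merged, cases, pt_soc)
            target_events = events[events["caseid"].isin(target_ids)]

            flow_rows += [
                (drug_name, "reports", 1, "demo_rows_in_window", n_demo_rows),
                (drug_name, "reports", 2, "unique_cases_after_dedup", len(cases)),
                (drug_name, "reports", 3, "target_reports", len(target_ids)),
                (drug_name, "pairs", 1, "reaction_rows_in_window", len(reac_tab)),
                (drug_name, "pairs", 2, "event_pairs_after_merge", len(events)),
                (drug_name, "pairs", 3, "target_event_pairs", len(target_events)),
            ]
            log.append(
                f"{drug_name}: {n_demo_rows} demo rows, {len(cases)} cases "
                f"({n_dropped} duplicate versions dropped, {n_orphan} orphan drug rows), "
                f"{len(target_ids)} target reports, {len(target_events)} target pairs"
            )

            stage = f"descriptives[{drug_name}]"
            target_cases = cases[cases["caseid"].isin(target_ids)]
            qc = quarterly_counts(target_cases)
            qc.insert(0, "drug", drug_name)
            quarterly_frames.append(qc)
            dt = demographics_table(target_cases)
            dt.insert(0, "drug", drug_name)
            demo_frames.append(dt)

            stage = f"signals[{drug_name}]"
            for level, sink in (("PT", pt_frames), ("SOC", soc_frames)):
                tables = ct.tabulate(events, target_ids, level=level)
                sig = ss.compute_signals(
                    tables, level=level, yates=config.yates, continuity=config.continuity
                )
                sig.insert(0, "drug", drug_name)
                if level == "PT" and not sig.empty:
                    ranked = ss.rank_by_ic(sig, config.top_k, config.rank_exclusions)
                    rank_of = {e: i + 1 for i, e in enumerate(ranked["event"])}
                    sig["ic_rank"] = sig["event"].map(rank_of).astype("Int64")
                sink.append(sig)

            if config.subgroups:
                stage = f"subgroups[{drug_name}]"
                strata: list[tuple[str, object]] = [("sex", "F"), ("sex", "M")]
                strata += [("age_bin", b) for b in cp.AGE_BIN_LABELS]
                top5 = (
                    target_cases["country"].value_counts().sort_index()
                    .sort_values(ascending=False, kind="mergesort").head(5).index
                )
                strata += [("country", c) for c in top5]
                for var, value in strata:
                    for level in ("PT", "SOC"):
                        tables = ct.tabulate(
                            events, target_ids, level=level, cases=cases, stratum={var: value}
                        )
                        if not tables:
                            continue
                        sig = ss.compute_signals(
                            tables,
                            level=level,
                            stratum=f"{var}={value}",
                            yates=config.yates,
                            continuity=config.continuity,
                        )
                        sig.insert(0, "drug", drug_name)
                        sub_frames.append(sig)

            stage = f"timescan[{drug_name}]"
            scan_pts: list[str] = []
            if pt_frames and not pt_frames[-1].empty:
                ranked = ss.rank_by_ic(pt_frames[-1], config.top_k, config.rank_exclusions)
                scan_pts = list(ranked["event"])
            for extra in config.timescan_extra_pts:
                if extra not in scan_pts:
                    scan_pts.append(extra)
            for pt in scan_pts:
                series = ct.yearly_series(
                    events, target_ids, pt, cases, mode=config.timescan_mode
                )
                if not series:
                    continue
                rows = {str(year): table for year, table in series}
                frame = pd.DataFrame(
                    {
                        "event": list(rows.keys()),
                        "a": [t.a for t in rows.values()],
                        "b": [t.b for t in rows.values()],
                        "c": [t.c for t in rows.values()],
                        "d": [t.d for t in rows.values()],
                    }
                )
                sig = ss.compute_signals(
                    frame.rename(columns={"event": "event"}),
                    level="PT",
                    stratum=config.timescan_mode,
                    yates=config.yates,
                    continuity=config.continuity,
                )
                sig = sig.rename(columns={"event": "year"})
                sig.insert(0, "pt", pt)
                sig.insert(0, "drug", drug_name)
                scan_frames.append(sig)

        if len(overlap_cases) == 2:
            ids = list(overlap_cases.values())
            n_overlap = len(ids[0] & ids[1])
            log.append(f"reports naming both target drugs (counted for each): {n_overlap}")

        def _concat(frames: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
            usable = [f for f in frames if not f.empty]
            if not usable:
                return pd.DataFrame(columns=columns)
            return pd.concat(usable, ignore_index=True)

        sig_cols = ["drug"] + ss._SIGNAL_COLUMNS
        bundle = StudyBundle(
            screening_flow=pd.DataFrame(
                flow_rows, columns=["drug", "phase", "step", "stage", "count"]
            ),
            quarterly_counts=_concat(quarterly_frames, ["drug", "quarter", "count", "percent"]),
            demographics=_concat(demo_frames, ["drug", "block", "category", "count", "percent"]),
            soc_signals=_signal_frame_sorted(_concat(soc_frames, sig_cols)),
            pt_signals=_signal_frame_sorted(_concat(pt_frames, sig_cols + ["ic_rank"])),
            subgroup_signals=_signal_frame_sorted(_concat(sub_frames, sig_cols)),
            timescan=_concat(scan_frames, ["drug", "pt", "year"]),
            log_lines=log,
        )
        bundle.write(config.output_dir)
        for line in log:
            logger.info("%s", line)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"study aborted at stage {stage!r}: {exc}") from exc


def plot_timescan(timescan: pd.DataFrame, path: str | Path) -> None:
    """Simple IC-by-year line plot, one panel per drug (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    drugs = sorted(timescan["drug"].unique())
    fig, axes = plt.subplots(1, max(len(drugs), 1), figsize=(6 * max(len(drugs), 1), 4), squeeze=False)
    for ax, drug in zip(axes[0], drugs):
        sub = timescan[timescan["drug"] == drug]
        for pt, grp in sub.groupby("pt"):
            grp = grp.sort_values("year")
            ax.plot(grp["year"].astype(int), grp["ic"], marker="o", label=pt)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_title(drug)
        ax.set_xlabel("year")
        ax.set_ylabel("IC")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
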