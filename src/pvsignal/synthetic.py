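"""Synthetic FAERS-style quarterly dumps with known ground truth.

The generator emits DEMO/DRUG/REAC tables in the quarterly-dump dialect with
case versioning (duplicates), drug role codes, multiple PTs per report and
configurable injected drug-event associations of known relative risk, so the
whole pipeline is testable at desk scale with no download.

Generative model, per case:

1. a drug (or the OTHER pool) is assigned by share;
2. K ~ Poisson(lambda) truncated to [1, kmax] distinct PTs are drawn without
   replacement with probability proportional to ``background_rate`` times the
   relative risk of any injected (drug, PT) signal;
3. demographics, a role code and a receipt date uniform within a random
   quarter are attached;
4. a configured fraction of cases is additionally emitted as an earlier
   version (same caseid, decremented caseversion, earlier receipt date).

Identical seeds produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .contingency import DEVICE_PT_LABEL, DEVICE_PT_MERGE, ContingencyTable
from .faers_io import DELIMITER, write_table

logger = logging.getLogger(__name__)

FIRST_CASEID = 100_000_001

#: drug names used for non-target (background) cases
FILLER_DRUGS = (
    "ASPIRIN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
    "AMOXICILLIN", "IBUPROFEN", "LEVOTHYROXINE", "SERTRALINE", "AMLODIPINE",
)


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    rate: float  # unnormalized background weight, in (0, 1)


@dataclass(frozen=True)
class DrugSpec:
    ingredient: str
    names: tuple[str, ...]
    share: float  # fraction of cases exposed to this drug


@dataclass(frozen=True)
class InjectedSignal:
    ingredient: str
    pt: str
    rr: float  # multiplicative relative risk on the PT's background weight


@dataclass
class SyntheticConfig:
    n_cases: int
    quarters: tuple[str, ...]
    pt_vocabulary: tuple[PtSpec, ...]
    drugs: tuple[DrugSpec, ...]
    injected_signals: tuple[InjectedSignal, ...] = ()
    pts_per_report_mean: float = 2.0
    max_pts_per_report: int = 6
    duplicate_rate: float = 0.0
    role_probs: Mapping[str, float] = field(default_factory=lambda: {"PS": 0.9, "SS": 0.06, "C": 0.04})
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {"F": 0.46, "M": 0.36, "UNK": 0.18})
    reporter_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.75, "MD": 0.13, "PH": 0.09, "OT": 0.01, "UNK": 0.02}
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.88, "JP": 0.04, "CA": 0.03, "GB": 0.02, "CN": 0.02, "FR": 0.01}
    )
    age_mean: float = 66.0
    age_sd: float = 14.0
    age_missing_frac: float = 0.4
    concomitant_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not self.quarters:
            raise ValueError("at least one quarter is required")
        if not self.pt_vocabulary:
            raise ValueError("pt_vocabulary is empty")
        for p in self.pt_vocabulary:
            if not (0.0 < p.rate < 1.0):
                raise ValueError(f"background rate for {p.pt!r} must be in (0, 1)")
        share_sum = sum(d.share for d in self.drugs)
        if any(d.share < 0 for d in self.drugs) or share_sum > 1.0 + 1e-9:
            raise ValueError("drug shares must be non-negative and sum to <= 1")
        pts = {p.pt for p in self.pt_vocabulary}
        drugs = {d.ingredient for d in self.drugs}
        for s in self.injected_signals:
            if s.rr <= 0:
                raise ValueError(f"relative risk for {s.ingredient}/{s.pt} must be > 0")
            if s.pt not in pts:
                raise ValueError(f"injected signal PT {s.pt!r} not in vocabulary")
            if s.ingredient not in drugs:
                raise ValueError(f"injected signal drug {s.ingredient!r} not configured")
            base = next(p.rate for p in self.pt_vocabulary if p.pt == s.pt)
            if s.rr * base > 1.0:
                raise ValueError(
                    f"infeasible signal: rr*rate = {s.rr * base:.3f} > 1 for {s.ingredient}/{s.pt}"
                )
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.pts_per_report_mean <= 0:
            raise ValueError("pts_per_report_mean must be positive")
        if self.max_pts_per_report < 1 or self.max_pts_per_report > len(self.pt_vocabulary):
            raise ValueError("max_pts_per_report must be in [1, vocabulary size]")
        for name, probs in (
            ("role_probs", self.role_probs), ("sex_probs", self.sex_probs),
            ("reporter_probs", self.reporter_probs), ("country_probs", self.country_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    # -- (de)serialization ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["pt_vocabulary"] = [list(asdict(p).values()) for p in self.pt_vocabulary]
        doc["drugs"] = [[d.ingredient, list(d.names), d.share] for d in self.drugs]
        doc["injected_signals"] = [list(asdict(s).values()) for s in self.injected_signals]
        doc["quarters"] = list(self.quarters)
        for key in ("role_probs", "sex_probs", "reporter_probs", "country_probs"):
            doc[key] = dict(doc[key])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        doc["pt_vocabulary"] = tuple(PtSpec(pt, soc, float(rate)) for pt, soc, rate in doc["pt_vocabulary"])
        doc["drugs"] = tuple(DrugSpec(ing, tuple(names), float(share)) for ing, names, share in doc["drugs"])
        doc["injected_signals"] = tuple(
            InjectedSignal(ing, pt, float(rr)) for ing, pt, rr in doc.get("injected_signals", [])
        )
        doc["quarters"] = tuple(doc["quarters"])
        return cls(**doc)


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style assertions."""

    pair_counts: pd.DataFrame  # ingredient, pt, rr, pairs (per unique case)
    pair_counts_merged: pd.DataFrame  # same, after the device-PT merge rule
    case_drug: pd.DataFrame  # caseid, ingredient, role_cod
    duplicate_caseids: tuple  # caseids emitted as two versions
    n_cases: int

    def target_caseids(self, ingredient: str, roles: Sequence[str] = ("PS",)) -> set:
        df = self.case_drug
        mask = (df["ingredient"] == ingredient) & df["role_cod"].isin(set(roles))
        return set(df.loc[mask, "caseid"])

    def total_pairs(self, merged: bool = False) -> int:
        frame = self.pair_counts_merged if merged else self.pair_counts
        return int(frame["pairs"].sum())

    def pair_count(self, ingredient: str, pt: str, merged: bool = False) -> int:
        frame = self.pair_counts_merged if merged else self.pair_counts
        mask = (frame["ingredient"] == ingredient) & (frame["pt"] == pt)
        return int(frame.loc[mask, "pairs"].sum())


@dataclass
class SyntheticData:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> list[Path]:
        """Emit per-quarter ASCII files plus ground-truth and mapping tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        frames = {"demo": self.demo, "drug": self.drug, "reac": self.reac}
        for quarter in self.config.quarters:
            for name, frame in frames.items():
                part = frame[frame["_quarter"] == quarter]
                path = outdir / f"{name}_{quarter}.txt"
                write_table(part, path, name.upper())
                written.append(path)
        truth_pairs = outdir / "ground_truth_pairs.csv"
        self.truth.pair_counts.to_csv(truth_pairs, index=False)
        truth_merged = outdir / "ground_truth_pairs_merged.csv"
        self.truth.pair_counts_merged.to_csv(truth_merged, index=False)
        truth_cases = outdir / "ground_truth_cases.csv"
        self.truth.case_drug.to_csv(truth_cases, index=False)
        written += [truth_pairs, truth_merged, truth_cases]

        map_path = outdir / "pt_soc_map.txt"
        lines = ["pt" + DELIMITER + "soc"] + [
            f"{p.pt}{DELIMITER}{p.soc}" for p in self.config.pt_vocabulary
        ]
        map_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(map_path)

        syn_path = outdir / "synonyms.txt"
        lines = ["pattern" + DELIMITER + "canonical"]
        for d in self.config.drugs:
            for name in d.names:
                lines.append(f"{name}{DELIMITER}{d.ingredient}")
        syn_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(syn_path)
        return written


def _truncated_poisson_pmf(mean: float, kmax: int) -> np.ndarray:
    ks = np.arange(1, kmax + 1)
    pmf = stats.poisson.pmf(ks, mean)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("truncated Poisson has no mass on [1, kmax]")
    return pmf / total


def _choice(rng: np.random.Generator, options: Sequence[str], probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(options)
    p = np.array([probs[k] for k in keys], dtype=float)
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / p.sum())]


def generate(config: SyntheticConfig, outdir: str | Path | None = None) -> SyntheticData:
    """Run the generative model; optionally write the quarterly files.

    Returns the full DEMO/DRUG/REAC frames (raw schema columns as strings,
    plus a ``_quarter`` helper used for file splitting) and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    vocab = config.pt_vocabulary
    n_pt = len(vocab)
    rates = np.array([p.rate for p in vocab], dtype=float)
    pt_names = np.array([p.pt for p in vocab], dtype=object)

    labels = [d.ingredient for d in config.drugs] + ["OTHER"]
    shares = np.array([d.share for d in config.drugs] + [1.0 - sum(d.share for d in config.drugs)])
    shares = np.clip(shares, 0.0, None)
    drug_idx = rng.choice(len(labels), size=n, p=shares / shares.sum())

    # per-drug PT weights, with injected relative risks applied
    weights = np.tile(rates, (len(labels), 1))
    rr_table = np.ones_like(weights)
    pt_index = {p.pt: i for i, p in enumerate(vocab)}
    label_index = {lab: i for i, lab in enumerate(labels)}
    for sig in config.injected_signals:
        weights[label_index[sig.ingredient], pt_index[sig.pt]] *= sig.rr
        rr_table[label_index[sig.ingredient], pt_index[sig.pt]] = sig.rr

    # number of distinct PTs per report
    pmf = _truncated_poisson_pmf(config.pts_per_report_mean, config.max_pts_per_report)
    k_draws = rng.choice(np.arange(1, config.max_pts_per_report + 1), size=n, p=pmf)

    # weighted sampling without replacement via the exponential race:
    # the K smallest Exp(1)/w_j keys are a draw with prob proportional to w
    keys = rng.exponential(size=(n, n_pt)) / weights[drug_idx]
    order = np.argsort(keys, axis=1, kind="stable")
    mask = np.arange(n_pt)[None, :] < k_draws[:, None]
    case_pos = np.repeat(np.arange(n), k_draws)
    pt_ids = order[mask]

    # demographics and dates
    caseids = (FIRST_CASEID + np.arange(n)).astype(np.int64)
    sex = _choice(rng, list(config.sex_probs), config.sex_probs, n)
    reporter = _choice(rng, list(config.reporter_probs), config.reporter_probs, n)
    country = _choice(rng, list(config.country_probs), config.country_probs, n)
    role = _choice(rng, list(config.role_probs), config.role_probs, n)

    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 0.5, 99.0)
    age_missing = rng.random(n) < config.age_missing_frac
    age_cod = np.array(["YR"] * n, dtype=object)
    # a slice of reports uses non-year units to exercise unit conversion
    unit_pick = rng.random(n)
    age_cod[unit_pick < 0.05] = "DEC"
    age_cod[(unit_pick >= 0.05) & (unit_pick < 0.08)] = "MON"
    age_val = np.where(
        age_cod == "DEC", np.round(age_years / 10.0, 1),
        np.where(age_cod == "MON", np.round(age_years * 12.0), np.round(age_years)),
    )

    periods = pd.PeriodIndex(list(config.quarters), freq="Q")
    starts = periods.start_time
    span_days = (periods.end_time.normalize() - starts).days.to_numpy() + 1
    q_idx = rng.integers(len(periods), size=n)
    offsets = rng.integers(0, span_days[q_idx])
    dates = starts.to_numpy()[q_idx] + offsets.astype("timedelta64[D]")
    window_start = starts.min().to_datetime64()

    # duplicate versions: same caseid, earlier date, lower caseversion
    n_dup = int(round(config.duplicate_rate * n))
    dup_pos = np.sort(rng.choice(n, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)
    version = np.ones(n, dtype=np.int64)
    version[dup_pos] = 2
    primaryid = caseids * 10 + version
    dup_dates = np.maximum(
        dates[dup_pos] - rng.integers(1, 120, size=n_dup).astype("timedelta64[D]"),
        window_start,
    ) if n_dup else dates[:0]
    dup_primaryid = caseids[dup_pos] * 10 + 1

    def _fmt_dates(arr) -> np.ndarray:
        iso = np.datetime_as_string(np.asarray(arr, dtype="datetime64[D]"), unit="D")
        return np.char.replace(iso, "-", "").astype(object)

    def _fmt_quarters(arr) -> np.ndarray:
        idx = pd.DatetimeIndex(arr)
        return (
            idx.year.astype(str).astype(object) + "Q" + ((idx.month - 1) // 3 + 1).astype(str)
        ).to_numpy(dtype=object)

    primaryid_str = primaryid.astype(str).astype(object)
    caseid_str = caseids.astype(str).astype(object)

    demo_main = pd.DataFrame(
        {
            "primaryid": primaryid_str,
            "caseid": caseid_str,
            "caseversion": version.astype(str),
            "fda_dt": _fmt_dates(dates),
            "sex": sex,
            "age": np.where(age_missing, "", _trim_num(age_val)),
            "age_cod": np.where(age_missing, "", age_cod),
            "occp_cod": np.where(reporter == "UNK", "", reporter),
            "occr_country": country,
            "_quarter": _fmt_quarters(dates),
        }
    )
    if n_dup:
        demo_dup = demo_main.iloc[dup_pos].copy()
        demo_dup["primaryid"] = dup_primaryid.astype(str)
        demo_dup["caseversion"] = "1"
        demo_dup["fda_dt"] = _fmt_dates(dup_dates)
        demo_dup["_quarter"] = _fmt_quarters(dup_dates)
        demo = pd.concat([demo_main, demo_dup], ignore_index=True)
    else:
        demo = demo_main
    demo = demo.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    # DRUG rows: one row for the assigned drug (or a filler), optional filler concomitant
    name_choices = []
    for i, lab in enumerate(labels):
        if lab == "OTHER":
            name_choices.append(np.array(FILLER_DRUGS, dtype=object))
        else:
            name_choices.append(np.array(config.drugs[i].names, dtype=object))
    drugnames = np.empty(n, dtype=object)
    for i in range(len(labels)):
        sel = drug_idx == i
        pool = name_choices[i]
        drugnames[sel] = pool[rng.integers(len(pool), size=int(sel.sum()))]

    drug_rows = pd.DataFrame(
        {
            "primaryid": primaryid_str,
            "drugname": drugnames,
            "role_cod": role,
            "_quarter": demo_main["_quarter"].to_numpy(),
        }
    )
    conco = rng.random(n) < config.concomitant_prob
    if conco.any():
        extra = pd.DataFrame(
            {
                "primaryid": primaryid_str[conco],
                "drugname": np.array(FILLER_DRUGS, dtype=object)[
                    rng.integers(len(FILLER_DRUGS), size=int(conco.sum()))
                ],
                "role_cod": "C",
                "_quarter": demo_main["_quarter"].to_numpy()[conco],
            }
        )
        drug_rows = pd.concat([drug_rows, extra], ignore_index=True)

    reac_rows = pd.DataFrame(
        {
            "primaryid": primaryid_str[case_pos],
            "pt": pt_names[pt_ids],
            "_quarter": demo_main["_quarter"].to_numpy()[case_pos],
        }
    )

    if n_dup:
        # duplicate versions carry identical drug/reaction content
        retained_ids = primaryid_str[dup_pos]
        dup_map = pd.Series(dup_primaryid.astype(str), index=retained_ids)
        dup_quarters = pd.Series(_fmt_quarters(dup_dates), index=retained_ids)

        def _clone_for_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
            part = frame[frame["primaryid"].isin(dup_map.index)].copy()
            part["_quarter"] = part["primaryid"].map(dup_quarters)
            part["primaryid"] = part["primaryid"].map(dup_map)
            return pd.concat([frame, part], ignore_index=True)

        drug_rows = _clone_for_duplicates(drug_rows)
        reac_rows = _clone_for_duplicates(reac_rows)

    drug_rows = drug_rows.sort_values(["primaryid", "drugname"], kind="mergesort").reset_index(drop=True)
    reac_rows = reac_rows.sort_values(["primaryid", "pt"], kind="mergesort").reset_index(drop=True)

    # ground truth tallies (per unique case; duplicates share content)
    pair_frame = pd.DataFrame(
        {
            "case": case_pos,
            "ingredient": np.array(labels, dtype=object)[drug_idx[case_pos]],
            "pt": pt_names[pt_ids],
        }
    )

    def _tally(frame: pd.DataFrame) -> pd.DataFrame:
        counts = (
            frame[["ingredient", "pt"]].value_counts().rename("pairs").reset_index()
            .sort_values(["ingredient", "pt"], kind="mergesort").reset_index(drop=True)
        )
        counts["rr"] = [
            rr_table[label_index[row.ingredient], pt_index[row.pt]]
            if row.pt in pt_index else 1.0
            for row in counts.itertuples()
        ]
        return counts[["ingredient", "pt", "rr", "pairs"]]

    merged_frame = pair_frame.copy()
    device_names = {p.pt for p in vocab if p.pt.casefold() in DEVICE_PT_MERGE}
    is_device = merged_frame["pt"].isin(device_names)
    merged_frame.loc[is_device, "pt"] = DEVICE_PT_LABEL
    merged_frame = merged_frame.drop_duplicates(subset=["case", "pt"])

    truth = GroundTruth(
        pair_counts=_tally(pair_frame),
        pair_counts_merged=_tally(merged_frame),
        case_drug=pd.DataFrame(
            {
                "caseid": caseid_str,
                "ingredient": np.array(labels, dtype=object)[drug_idx],
                "role_cod": role,
            }
        ),
        duplicate_caseids=tuple(caseid_str[dup_pos]),
        n_cases=n,
    )

    data = SyntheticData(demo=demo, drug=drug_rows, reac=reac_rows, truth=truth, config=config)
    if outdir is not None:
        data.write(outdir)
    logger.info(
        "generated %d cases (%d duplicated), %d drug rows, %d reaction pairs",
        n, n_dup, len(drug_rows), len(reac_rows),
    )
    return data


def _trim_num(values: np.ndarray) -> np.ndarray:
    """Format numbers without trailing '.0' noise."""
    vals = np.asarray(values, dtype=float)
    is_int = np.mod(vals, 1.0) == 0.0
    return np.where(
        is_int,
        vals.astype(np.int64).astype(str).astype(object),
        vals.astype(str).astype(object),
    )


# ---------------------------------------------------------------------------
# analytic oracle


def inclusion_probability(config: SyntheticConfig, ingredient: str, pt: str) -> float:
    """P(the PT appears on a report exposed to the drug), rare-event form.

    Uses the with-replacement approximation ``E_K[1 - (1 - p)^K]`` for the
    without-replacement draw; accurate when the PT's normalized weight is
    small (see the exact-enumeration cross-check in the test-suite).
    """
    labels = [d.ingredient for d in config.drugs] + ["OTHER"]
    if ingredient not in labels:
        raise KeyError(f"unknown ingredient {ingredient!r}")
    idx = {p.pt: i for i, p in enumerate(config.pt_vocabulary)}
    if pt not in idx:
        raise KeyError(f"unknown PT {pt!r}")
    w = np.array([p.rate for p in config.pt_vocabulary], dtype=float)
    for sig in config.injected_signals:
        if sig.ingredient == ingredient:
            w[idx[sig.pt]] *= sig.rr
    p = w / w.sum()
    pmf = _truncated_poisson_pmf(config.pts_per_report_mean, config.max_pts_per_report)
    ks = np.arange(1, config.max_pts_per_report + 1)
    return float(np.sum(pmf * (1.0 - (1.0 - p[idx[pt]]) ** ks)))


def _expected_pair_matrix(config: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    """Expected pair counts per (drug label, PT), including the OTHER pool."""
    labels = [d.ingredient for d in config.drugs] + ["OTHER"]
    shares = [d.share for d in config.drugs] + [1.0 - sum(d.share for d in config.drugs)]
    out = np.zeros((len(labels), len(config.pt_vocabulary)))
    for i, (lab, share) in enumerate(zip(labels, shares)):
        for j, spec in enumerate(config.pt_vocabulary):
            out[i, j] = config.n_cases * share * inclusion_probability(config, lab, spec.pt)
    return labels, out


def expected_table(
    config: SyntheticConfig,
    ingredient: str,
    pt: str,
    roles: Sequence[str] = ("PS",),
) -> ContingencyTable:
    """Expected 2x2 cells for one (drug, PT) pair under the generative rates.

    Cells are real-valued expectations of the pipeline's pair counts after
    deduplication, with the target defined by the given role codes (cases of
    the target drug reported in other roles count as background).
    """
    labels, pairs = _expected_pair_matrix(config)
    if ingredient not in labels or ingredient == "OTHER":
        raise KeyError(f"unknown target ingredient {ingredient!r}")
    idx = {p.pt: j for j, p in enumerate(config.pt_vocabulary)}
    if pt not in idx:
        raise KeyError(f"unknown PT {pt!r}")
    role_frac = sum(config.role_probs.get(r, 0.0) for r in set(roles))
    i = labels.index(ingredient)
    j = idx[pt]

    a = pairs[i, j] * role_frac
    ab = pairs[i, :].sum() * role_frac
    total = pairs.sum()
    ac = pairs[:, j].sum() - a
    return ContingencyTable(a=a, b=ab - a, c=ac, d=total - ab - ac)


def expected_odds_ratio(
    config: SyntheticConfig, ingredient: str, pt: str, roles: Sequence[str] = ("PS",)
) -> float:
    t = expected_table(config, ingredient, pt, roles)
    return (t.a * t.d) / (t.b * t.c)


# ---------------------------------------------------------------------------
# default desk-scale fixture


_DEFAULT_VOCAB: tuple[tuple[str, str, float], ...] = (
    # Respiratory, thoracic and mediastinal disorders
    ("Dysphonia", "Respiratory, thoracic and mediastinal disorders", 0.012),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.040),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.050),
    ("Aphonia", "Respiratory, thoracic and mediastinal disorders", 0.004),
    ("Wheezing", "Respiratory, thoracic and mediastinal disorders", 0.015),
    ("Oropharyngeal pain", "Respiratory, thoracic and mediastinal disorders", 0.012),
    ("Nasal congestion", "Respiratory, thoracic and mediastinal disorders", 0.010),
    ("Throat irritation", "Respiratory, thoracic and mediastinal disorders", 0.008),
    ("Vocal cord disorder", "Respiratory, thoracic and mediastinal disorders", 0.002),
    # Infections and infestations
    ("Pneumonia", "Infections and infestations", 0.010),
    ("Candida infection", "Infections and infestations", 0.004),
    ("Oral candidiasis", "Infections and infestations", 0.005),
    ("Nasopharyngitis", "Infections and infestations", 0.020),
    ("Bronchitis", "Infections and infestations", 0.012),
    ("Urinary tract infection", "Infections and infestations", 0.015),
    ("Influenza", "Infections and infestations", 0.010),
    ("Sinusitis", "Infections and infestations", 0.008),
    # Gastrointestinal disorders
    ("Nausea", "Gastrointestinal disorders", 0.035),
    ("Diarrhoea", "Gastrointestinal disorders", 0.030),
    ("Dry mouth", "Gastrointestinal disorders", 0.012),
    ("Dysphagia", "Gastrointestinal disorders", 0.006),
    ("Vomiting", "Gastrointestinal disorders", 0.020),
    ("Abdominal pain", "Gastrointestinal disorders", 0.018),
    ("Constipation", "Gastrointestinal disorders", 0.012),
    ("Oral mucosal exfoliation", "Gastrointestinal disorders", 0.002),
    # Injury, poisoning and procedural complications
    ("Device use issue", "Injury, poisoning and procedural complications", 0.015),
    ("Wrong technique in product usage process", "Injury, poisoning and procedural complications", 0.010),
    ("Product use issue", "Injury, poisoning and procedural complications", 0.008),
    ("Fall", "Injury, poisoning and procedural complications", 0.015),
    ("Medication error", "Injury, poisoning and procedural complications", 0.008),
    ("Exposure via inhalation", "Injury, poisoning and procedural complications", 0.003),
    # Nervous system disorders
    ("Headache", "Nervous system disorders", 0.030),
    ("Dizziness", "Nervous system disorders", 0.022),
    ("Tremor", "Nervous system disorders", 0.008),
    ("Somnolence", "Nervous system disorders", 0.007),
    ("Dysgeusia", "Nervous system disorders", 0.006),
    # Cardiac disorders
    ("Palpitations", "Cardiac disorders", 0.012),
    ("Tachycardia", "Cardiac disorders", 0.008),
    ("Atrial fibrillation", "Cardiac disorders", 0.006),
    ("Myocardial infarction", "Cardiac disorders", 0.005),
    # General disorders and administration site conditions
    ("Fatigue", "General disorders and administration site conditions", 0.030),
    ("Chest discomfort", "General disorders and administration site conditions", 0.012),
    ("Malaise", "General disorders and administration site conditions", 0.015),
    ("Oedema peripheral", "General disorders and administration site conditions", 0.010),
    ("Chest pain", "General disorders and administration site conditions", 0.012),
    ("Drug ineffective", "General disorders and administration site conditions", 0.040),
    ("Condition aggravated", "General disorders and administration site conditions", 0.020),
    # Musculoskeletal and connective tissue disorders
    ("Muscle spasms", "Musculoskeletal and connective tissue disorders", 0.010),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.012),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.012),
    ("Pain in extremity", "Musculoskeletal and connective tissue disorders", 0.008),
    # Psychiatric disorders
    ("Anxiety", "Psychiatric disorders", 0.012),
    ("Insomnia", "Psychiatric disorders", 0.012),
    ("Depression", "Psychiatric disorders", 0.008),
    # Eye disorders
    ("Vision blurred", "Eye disorders", 0.008),
    ("Dry eye", "Eye disorders", 0.004),
    ("Cataract", "Eye disorders", 0.003),
    # Renal and urinary disorders
    ("Urinary retention", "Renal and urinary disorders", 0.004),
    ("Urine flow decreased", "Renal and urinary disorders", 0.002),
    ("Dysuria", "Renal and urinary disorders", 0.003),
    # Investigations
    ("Body height decreased", "Investigations", 0.002),
    ("Weight decreased", "Investigations", 0.010),
    ("Blood pressure increased", "Investigations", 0.010),
)


def default_config(n_cases: int = 5_000, seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale fixture: 2 target drugs + OTHER over a 63-PT vocabulary,
    4 years x 4 quarters, versioned duplicates and several injected signals."""
    quarters = tuple(f"{y}Q{q}" for y in range(2020, 2024) for q in range(1, 5))
    drugs = (
        DrugSpec(
            "BUD/GLY/FOR",
            ("BREZTRI AEROSPHERE", "BREZTRI", "Budesonide/Glycopyrrolate/Formoterol Fumarate"),
            0.18,
        ),
        DrugSpec(
            "FF/UMEC/VI",
            ("TRELEGY ELLIPTA", "Trelegy", "FLUTICASONE FUROATE/UMECLIDINIUM/VILANTEROL"),
            0.22,
        ),
    )
    signals = (
        InjectedSignal("BUD/GLY/FOR", "Device use issue", 6.0),
        InjectedSignal("BUD/GLY/FOR", "Wrong technique in product usage process", 6.0),
        InjectedSignal("BUD/GLY/FOR", "Dysphonia", 5.0),
        InjectedSignal("BUD/GLY/FOR", "Body height decreased", 8.0),
        InjectedSignal("FF/UMEC/VI", "Pneumonia", 3.0),
        InjectedSignal("FF/UMEC/VI", "Candida infection", 5.0),
        InjectedSignal("FF/UMEC/VI", "Dysphonia", 4.0),
        InjectedSignal("FF/UMEC/VI", "Device use issue", 3.0),
    )
    params = dict(
        n_cases=n_cases,
        quarters=quarters,
        pt_vocabulary=tuple(PtSpec(*row) for row in _DEFAULT_VOCAB),
        drugs=drugs,
        injected_signals=signals,
        pts_per_report_mean=2.0,
        max_pts_per_report=6,
        duplicate_rate=0.08,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)
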