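"""Generator tests: determinism, ground truth, null behaviour, analytic oracle."""

from __future__ import annotations

import filecmp
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvsignal import case_processing as cp
from pvsignal import contingency as ct
from pvsignal.faers_io import PtSocMap, SynonymDict, normalize_demo, read_table
from pvsignal.signal_stats import ror
from pvsignal.synthetic import (
    DrugSpec,
    InjectedSignal,
    PtSpec,
    SyntheticConfig,
    _truncated_poisson_pmf,
    default_config,
    expected_odds_ratio,
    expected_table,
    generate,
    inclusion_probability,
)

from conftest import run_pipeline


def small_config(**overrides):
    params = dict(
        n_cases=2_000,
        quarters=("2021Q1", "2021Q2", "2021Q3", "2021Q4"),
        pt_vocabulary=default_config().pt_vocabulary,
        drugs=(DrugSpec("DRUGA", ("DRUGA",), 0.3),),
        injected_signals=(),
        duplicate_rate=0.0,
        role_probs={"PS": 1.0},
        seed=0,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


class TestValidation:
    def test_infeasible_rate_rejected_before_writing(self, tmp_path):
        cfg = small_config(
            injected_signals=(InjectedSignal("DRUGA", "Dyspnoea", 25.0),)
        )  # 25 * 0.05 > 1
        with pytest.raises(ValueError, match="infeasible"):
            generate(cfg, outdir=tmp_path / "x")
        assert not (tmp_path / "x").exists()

    def test_unknown_signal_pt_rejected(self):
        with pytest.raises(ValueError, match="not in vocabulary"):
            small_config(injected_signals=(InjectedSignal("DRUGA", "Nope", 2.0),)).validate()

    def test_shares_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError, match="shares"):
            small_config(drugs=(DrugSpec("A", ("A",), 0.7), DrugSpec("B", ("B",), 0.7))).validate()


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = default_config(n_cases=1_000, seed=5)
        generate(cfg, outdir=tmp_path / "a")
        generate(default_config(n_cases=1_000, seed=5), outdir=tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in names:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_different_seed_differs(self):
        a = generate(default_config(n_cases=500, seed=1))
        b = generate(default_config(n_cases=500, seed=2))
        assert not a.reac["pt"].equals(b.reac["pt"])


class TestDuplicates:
    def test_exact_duplicate_count(self):
        data = generate(default_config(n_cases=1_000, seed=9, duplicate_rate=0.1))
        assert len(data.truth.duplicate_caseids) == round(0.1 * 1_000)
        versions = data.demo.groupby("caseid").size()
        assert (versions.loc[list(data.truth.duplicate_caseids)] == 2).all()

    def test_duplicate_versions_differ_only_in_version_fields(self):
        data = generate(default_config(n_cases=500, seed=9, duplicate_rate=0.2))
        dup = data.demo[data.demo["caseid"].isin(set(data.truth.duplicate_caseids))]
        for caseid, grp in itertools.islice(dup.groupby("caseid"), 20):
            v1 = grp[grp["caseversion"] == "1"].iloc[0]
            v2 = grp[grp["caseversion"] == "2"].iloc[0]
            assert v1["fda_dt"] <= v2["fda_dt"]
            for col in ("sex", "age", "age_cod", "occp_cod", "occr_country"):
                assert v1[col] == v2[col]

    def test_written_files_round_trip_through_reader(self, tmp_path):
        cfg = default_config(n_cases=800, seed=2)
        data = generate(cfg, outdir=tmp_path)
        demo = pd.concat(
            [read_table(tmp_path / f"demo_{q}.txt", "DEMO").frame for q in cfg.quarters],
            ignore_index=True,
        )
        assert len(demo) == len(data.demo)
        cases, dropped = cp.deduplicate(demo)
        assert len(cases) == cfg.n_cases
        assert dropped == len(data.truth.duplicate_caseids)


class TestNullCase:
    def test_rr_one_gives_homogeneous_frequencies(self):
        # no injected signals: target and background PT profiles differ only
        # by sampling noise (chi-square homogeneity test)
        cfg = small_config(n_cases=50_000, seed=13)
        data = generate(cfg)
        truth = data.truth
        target = truth.pair_counts[truth.pair_counts["ingredient"] == "DRUGA"]
        backgr = truth.pair_counts[truth.pair_counts["ingredient"] != "DRUGA"]
        merged = target.merge(backgr, on="pt", how="outer", suffixes=("_t", "_b")).fillna(0)
        table = merged[["pairs_t", "pairs_b"]].to_numpy().T
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001

    def test_rr_one_expected_ror_is_one(self):
        cfg = small_config()
        assert expected_odds_ratio(cfg, "DRUGA", "Pneumonia") == pytest.approx(1.0)


RARE_VOCAB = (
    PtSpec("Common1", "S", 0.10),
    PtSpec("Common2", "S", 0.10),
    PtSpec("Common3", "S", 0.10),
    PtSpec("Common4", "S", 0.10),
    PtSpec("Common5", "S", 0.10),
    PtSpec("RarePT", "S", 0.002),
)


def exact_inclusion(weights, j, pmf):
    """Enumeration oracle: P(item j among the first K of the weighted
    without-replacement draw), exact via successive-sampling products."""
    total = 0.0
    for k, pk in enumerate(pmf, start=1):
        hit = 0.0
        for seq in itertools.permutations(range(len(weights)), k):
            if j not in seq:
                continue
            prob, rem = 1.0, sum(weights)
            for i in seq:
                prob *= weights[i] / rem
                rem -= weights[i]
            hit += prob
        total += pk * hit
    return total


class TestExpectedTable:
    def rare_config(self, rr=5.0):
        return SyntheticConfig(
            n_cases=50_000,
            quarters=("2021Q1",),
            pt_vocabulary=RARE_VOCAB,
            drugs=(DrugSpec("DRUGA", ("DRUGA",), 0.3),),
            injected_signals=(InjectedSignal("DRUGA", "RarePT", rr),),
            pts_per_report_mean=1.2,
            max_pts_per_report=3,
            duplicate_rate=0.0,
            role_probs={"PS": 1.0},
            seed=21,
        )

    def test_rare_pt_expected_ror_near_rr(self):
        # rare-event closed form: OR within 2% of the injected RR=5
        assert expected_odds_ratio(self.rare_config(), "DRUGA", "RarePT") == pytest.approx(
            5.0, rel=0.02
        )

    def test_closed_form_or_matches_exact_enumeration(self):
        # the per-PT inclusion approximation biases both arms the same way;
        # the odds ratio agrees with the exact enumeration to < 2%
        cfg = self.rare_config()
        pmf = _truncated_poisson_pmf(cfg.pts_per_report_mean, cfg.max_pts_per_report)
        w_t = np.array([0.1] * 5 + [0.002 * 5.0])
        w_b = np.array([0.1] * 5 + [0.002])
        ek = float(np.sum(pmf * np.arange(1, len(pmf) + 1)))
        pi_t = exact_inclusion(w_t, 5, pmf)
        pi_b = exact_inclusion(w_b, 5, pmf)
        exact_or = (pi_t / (ek - pi_t)) / (pi_b / (ek - pi_b))
        got = expected_odds_ratio(cfg, "DRUGA", "RarePT")
        assert got == pytest.approx(exact_or, rel=0.02)

    def test_pipeline_ror_within_sampling_band(self):
        # injected RR=5 at n=50,000: the realized pipeline ROR stays within
        # the [4, 6.25] band implied by binomial sampling error
        cfg = self.rare_config()
        data = generate(cfg)
        demo, _ = normalize_demo(data.demo)
        cases, _ = cp.deduplicate(demo)
        assignments = cp.standardize_drugs(data.drug, SynonymDict([("DRUGA", "DRUGA")]))
        assignments, _ = cp.join_to_cases(assignments, cases)
        target = cp.select_target_reports(assignments, "DRUGA")
        soc_map = PtSocMap([(p.pt, p.soc) for p in cfg.pt_vocabulary])
        events = ct.build_events(ct.merge_device_pts(data.reac), cases, soc_map)
        table = ct.tabulate(events, target)["RarePT"]
        assert 4.0 <= ror(table).ror <= 6.25

    def test_zero_share_drug_has_zero_expected_a(self):
        cfg = small_config(
            drugs=(DrugSpec("DRUGA", ("DRUGA",), 0.3), DrugSpec("GHOST", ("GHOST",), 0.0))
        )
        assert expected_table(cfg, "GHOST", "Pneumonia").a == 0.0

    def test_unknown_pair_raises(self):
        cfg = small_config()
        with pytest.raises(KeyError):
            expected_table(cfg, "DRUGA", "Nope")
        with pytest.raises(KeyError):
            expected_table(cfg, "NOPE", "Pneumonia")

    def test_inclusion_probabilities_sum_below_expected_k(self):
        # sum over PTs of the approximate inclusion probability is at most
        # E[K] (the exact sum), reflecting the with-replacement lower bound
        cfg = small_config()
        pmf = _truncated_poisson_pmf(cfg.pts_per_report_mean, cfg.max_pts_per_report)
        ek = float(np.sum(pmf * np.arange(1, len(pmf) + 1)))
        total = sum(inclusion_probability(cfg, "DRUGA", p.pt) for p in cfg.pt_vocabulary)
        assert total <= ek + 1e-9


class TestConservation:
    def test_pipeline_totals_match_ground_truth(self, default_data, default_pt_soc):
        cases, target, events = run_pipeline(default_data, default_pt_soc, "BUD/GLY/FOR")
        truth = default_data.truth
        assert len(events) == truth.total_pairs(merged=True)
        # the selected target set is exactly the generator's PS-target cases,
        # so target pair counts agree pair-for-pair
        assert target == truth.target_caseids("BUD/GLY/FOR")
        ev_pt = events[events["pt"] == "Body height decreased"]
        assert int(ev_pt["caseid"].isin(target).sum()) == len(set(ev_pt["caseid"]) & target)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(n_cases=123, seed=8)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
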