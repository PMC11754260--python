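"""Shared fixtures: tiny hand-built tables and a reusable synthetic dataset."""

from __future__ import annotations

import pandas as pd
import pytest

from pvsignal import case_processing as cp
from pvsignal import contingency as ct
from pvsignal.faers_io import PtSocMap, normalize_demo
from pvsignal.synthetic import SyntheticData, default_config, generate


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def demo_file(tmp_path):
    """Three DEMO rows, one with a malformed receipt date."""
    return write_lines(
        tmp_path / "demo_2021Q1.txt",
        [
            "primaryid$caseid$caseversion$fda_dt$sex$age$age_cod$occp_cod$occr_country",
            "1000000011$100000001$1$20210105$F$64$YR$CN$US",
            "1000000021$100000002$1$2021013$M$720$MON$MD$JP",
            "1000000031$100000003$1$20210301$$$$$",
        ],
    )


@pytest.fixture
def pt_soc_file(tmp_path):
    return write_lines(
        tmp_path / "pt_soc.txt",
        [
            "pt$soc",
            "Dysphonia$Respiratory, thoracic and mediastinal disorders",
            "Pneumonia$Infections and infestations",
            "Device use issue$Injury, poisoning and procedural complications",
        ],
    )


@pytest.fixture(scope="session")
def default_data() -> SyntheticData:
    """One shared desk-scale synthetic dataset (in memory, no files)."""
    return generate(default_config(n_cases=4_000, seed=11))


@pytest.fixture(scope="session")
def default_pt_soc(default_data) -> PtSocMap:
    return PtSocMap([(p.pt, p.soc) for p in default_data.config.pt_vocabulary])


def run_pipeline(data: SyntheticData, pt_soc: PtSocMap, target: str, roles=("PS",)):
    """In-memory pipeline: dedup -> standardize -> select -> merge -> events.

    Returns (cases, target_caseids, events).
    """
    demo, _ = normalize_demo(data.demo)
    cases, _ = cp.deduplicate(demo)
    assignments = cp.standardize_drugs(data.drug, cp.default_synonym_dict())
    assignments, _ = cp.join_to_cases(assignments, cases)
    target_ids = cp.select_target_reports(assignments, target, roles)
    events = ct.build_events(ct.merge_device_pts(data.reac), cases, pt_soc)
    return cases, target_ids, events


@pytest.fixture(scope="session")
def default_pipeline(default_data, default_pt_soc):
    """Pipeline outputs for the shared dataset, target BUD/GLY/FOR."""
    return run_pipeline(default_data, default_pt_soc, "BUD/GLY/FOR")
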