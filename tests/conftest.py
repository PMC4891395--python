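"""Shared fixtures: the packaged study table and tolerance helpers."""

from __future__ import annotations

import pytest
from hypothesis import settings

from corrbf import StudySummary, load_table1_fixtures

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: printed reference values: label -> (BF01, BF0+, BF0r(.57), BF0r(.37))
PRINTED_BF = {
    "study1": (7.90, 22.59, 16825.57, 39.37),
    "study2": (17.36, 19.24, 17679.82, 47.45),
    "study3": (2.09, 1.08, 50.25, 1.15),
    "study4": (4.21, 28.58, 21904.40, 35.05),
    "study5": (1.67, 0.85, 134.72, 1.32),
    "study6": (3.13, 1.61, 398.01, 2.98),
    "study7": (13.21, 10.32, 4894.19, 23.76),
    "study8": (14.60, 11.84, 7002.82, 28.75),
    "study9": (2.17, 30.86, 21755.50, 28.25),
    "studies1-4": (16.17, 52.21, 49671.92, 70.00),
    "studies5-9": (29.53, 20.53, 31021.07, 70.36),
}


def ladder_rtol(bf: float) -> float:
    """Comparison tolerance for reference Bayes factors recomputed from
    2-decimal summaries: <100 -> 5%, 100..1e4 -> 15%, >1e4 -> 35%."""
    if bf < 100:
        return 0.05
    if bf <= 1e4:
        return 0.15
    return 0.35


@pytest.fixture(scope="session")
def table1() -> dict[str, StudySummary]:
    return {s.label: s for s in load_table1_fixtures()}


@pytest.fixture(scope="session")
def originals() -> dict[str, StudySummary]:
    from corrbf import ORIGINAL_STUDY_A, ORIGINAL_STUDY_B

    return {"a": ORIGINAL_STUDY_A, "b": ORIGINAL_STUDY_B}
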