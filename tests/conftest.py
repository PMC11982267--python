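import pandas as pd
import pytest

from mirtail.counting import CountTable, MiRNARecord, ReferenceSet
from mirtail.simulate import SampleSpec, SimulationConfig


@pytest.fixture
def tiny_refset() -> ReferenceSet:
    return ReferenceSet.from_records(
        [
            MiRNARecord("mir-a", "ACGTACGTACGTACGTACGT"),
            MiRNARecord("mir-b", "TTGCATTGCATTGCATTGCA"),
            MiRNARecord("mir-c", "GGGCCCGGGCCCGGGCCCGG"),
        ]
    )


@pytest.fixture
def basic_config() -> SimulationConfig:
    return SimulationConfig(
        n_mirnas=10,
        samples=[
            SampleSpec("s1", "control", 2000),
            SampleSpec("s2", "disease", 2000),
        ],
        adenylation_prob={"*": {"control": 0.05, "disease": 0.3}},
        seed=42,
    )


def make_count_table(canonical: dict, adenylated: dict, samples: list[str]) -> CountTable:
    """Build a CountTable from {mirna: [counts per sample]} dicts."""
    can = pd.DataFrame(canonical, index=samples).T
    ade = pd.DataFrame(adenylated, index=samples).T
    totals = pd.DataFrame(
        {
            "assigned": can.sum() + ade.sum(),
            "ambiguous": 0,
            "unassigned": 0,
        }
    )
    totals["total"] = totals["assigned"]
    return CountTable(can, ade, totals)
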