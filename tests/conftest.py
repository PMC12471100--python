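import numpy as np
import pytest

from retroburst import simulate as sim
from retroburst.seqio import Alignment, SequenceRecord

TRNA_3P = "TGGCGCCCGAAA"             # 12-nt tRNA 3'-end used by most fixtures
TRNA_3P_FULL = "GGTTCGAATCCCGTCCCA"  # 18-nt variant for exact PBS matches


@pytest.fixture(scope="session")
def small_template() -> sim.ElementTemplate:
    """Compact element (LTR 300, internal 2100, ORF 1800, RT 1311)."""
    return sim.make_template(300, 2100, 1800, TRNA_3P, seed=3, rt_len=1311)


@pytest.fixture(scope="session")
def burst_result(small_template) -> sim.SimulationResult:
    """A modestly diverged single-family burst shared across tests."""
    evo = sim.EvoParams(burst_schedule=[(0.0, 8)], mu_r=0.005, mu_h=0.01,
                        end_time=3.0, seed=2)
    return sim.simulate_expansion(small_template, 8, 42000, evo,
                                  min_spacing=16000)


@pytest.fixture(scope="session")
def two_family_sim(small_template) -> sim.FamilySimulation:
    evo = sim.EvoParams(burst_schedule=[(0.0, 6)], mu_r=0.005, mu_h=0.005,
                        end_time=2.0, seed=5, master_succession_p=0.2)
    fam = sim.simulate_families(small_template, 2, 6, 30000, evo, seed=11,
                                founder_identity=0.55, min_spacing=3000)
    fam.alignment.groups = fam.groups
    return fam


def make_alignment(rows: dict[str, str], groups: dict[str, str] | None = None,
                   region: str = "full") -> Alignment:
    return Alignment(records=[SequenceRecord(k, v) for k, v in rows.items()],
                     region_label=region, groups=groups or {})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
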