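import numpy as np
import pytest

from poescan import MISSING, Panel, PoeParams, SnpMeta
from poescan.simulate import SimConfig, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel():
    """3 families x 2 SNPs with one missing parent and one missing call."""
    snps = [
        SnpMeta("rs1", "1", 1000, "A", "G"),
        SnpMeta("rs2", "2", 2000, "C", "T"),
    ]
    m = np.array([[1, 0], [2, MISSING], [MISSING, MISSING]], dtype=np.int8)
    f = np.array([[0, 1], [1, 2], [0, 0]], dtype=np.int8)
    c = np.array([[1, 0], [2, 1], [0, 0]], dtype=np.int8)
    return Panel(
        snps=snps,
        family_ids=["famA", "famB", "famC"],
        m=m, f=f, c=c,
        mother_present=np.array([True, True, False]),
        father_present=np.array([True, True, True]),
    )


@pytest.fixture(scope="session")
def simulated_panel():
    """Moderate panel with a strong imprinting signal at SNP 0."""
    cfg = SimConfig(
        n_families=400,
        n_snps=6,
        maf_range=(0.2, 0.4),
        signal_snps={0: PoeParams(W=0.15)},
        seed=7,
    )
    return simulate_panel(cfg)


def random_params(rng, scale=0.4):
    """Random positive parameter point for property tests."""
    logs = rng.normal(scale=scale, size=11)
    return PoeParams(
        mu=tuple(np.exp(logs[:5])) + (1.0,),
        R1=float(np.exp(logs[5])),
        R2=float(np.exp(logs[6])),
        S1=float(np.exp(logs[7])),
        S2=float(np.exp(logs[8])),
        W=float(np.exp(logs[9])),
    )
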