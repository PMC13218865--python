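import math

import numpy as np
import pytest

from rvburden.simulate import GeneSpec, SimulationConfig, simulate_study


def exact_fisher_oracle(a: int, c: int, b: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive integer enumeration (exact arithmetic).

    Independent of the package: hypergeometric weights as Python integers,
    point-probability rule with the 1 + 1e-7 slack applied in integer
    arithmetic, final division exact-to-float.
    """
    A, B, M = a + c, b + d, a + b
    kmin, kmax = max(0, M - B), min(A, M)
    ws = [math.comb(A, k) * math.comb(B, M - k) for k in range(kmin, kmax + 1)]
    wa = ws[a - kmin]
    # w <= wa * (1 + 1e-7)  <=>  w * 10^7 <= wa * (10^7 + 1)
    threshold = (wa * (10**7 + 1)) // 10**7
    num = sum(w for w in ws if w <= threshold)
    return num / math.comb(A + B, M)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_cases=120,
        genes=[GeneSpec(f"G{i:02d}", cds_length=1200, n_variants=5) for i in range(10)],
        enrichment={"G03": 8.0},
        planted_pairs={"G02": 1},
        planted_syn_mis={"G04": 1},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
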