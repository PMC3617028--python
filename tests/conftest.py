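import math

import numpy as np
import pytest

import ppistab as ps


@pytest.fixture
def heterodimer():
    """A-B dimer, C = 100 nM each, K_d = 5 nM; closed form F = 20, D = 80."""
    return ps.fixture_heterodimer()


@pytest.fixture
def chain3():
    return ps.fixture_chain3()


@pytest.fixture
def star4():
    return ps.fixture_star(4)


@pytest.fixture
def heterodimer_F():
    """Exact free concentration of the symmetric heterodimer via the quadratic

    F^2 / K + F - C = 0  ->  F = (-K + sqrt(K^2 + 4 K C)) / 2.
    """
    C, K = 100.0, 5.0
    return (-K + math.sqrt(K * K + 4 * K * C)) / 2.0


def small_random_model(seed: int, n: int = 4, stability: str = "normal"):
    """Tiny random proteome from the generator, for oracle cross-checks."""
    spec = ps.GeneratorSpec(
        n_proteins=n,
        degree_params={"mean": 1.5},
        abundance_log_sd=1.0,
        stability=stability,
        kd_stability_coupling=0.0,
        seed=seed,
    )
    return ps.generate_proteome(spec)
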