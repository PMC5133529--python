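"""Shared fixtures: tiny handwritten PED/MAP files and simulated datasets.

The heavier simulation suites (parameter recovery, null calibration,
scheme-efficiency comparison) are session-scoped so several tests can share
one set of replicates.
"""

import warnings

import pytest

from longimap.estimator import GeneFit
from longimap.simulate import (SimConfig, longitudinal_config, null_config,
                               recovery_config, simulate_dataset)

TAU_TRUE = 1.0
C_TRUE = 0.6


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_ped_map(tmp_path):
    """Two markers, two founder couples + two trios, all genotypes called.

    Marker m1 alleles {A,G} with G rare among founders; m2 alleles {C,T}.
    """
    map_path = write_lines(tmp_path / "t.map", [
        "1\tm1\t13.64\t100",
        "1\tm2\t14.68\t200",
    ])
    ped_path = write_lines(tmp_path / "t.ped", [
        "F1 p1 0 0 1 0  A A  C T",
        "F1 p2 0 0 2 0  A G  C C",
        "F1 k1 p1 p2 0 0  A G  C C",
        "F2 q1 0 0 1 0  A A  T T",
        "F2 q2 0 0 2 0  A A  C T",
        "F2 k2 q1 q2 0 0  A A  C T",
    ])
    return ped_path, map_path


def fit_replicate(config: SimConfig, seed: int, scheme: str = "baseline") -> GeneFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(config, seed).analyze(scheme)


@pytest.fixture(scope="session")
def recovery_fits():
    """200 replicate fits of the parameter-recovery setting (20 markers over
    2 cM, disease locus mid-region, C = 0.6, N = 50, 600 affected + 600
    unaffected trios)."""
    return [fit_replicate(recovery_config(), seed) for seed in range(200)]


@pytest.fixture(scope="session")
def null_fits():
    """500 replicate fits with no genetic effect (flat penetrances)."""
    return [fit_replicate(null_config(), seed) for seed in range(500)]


@pytest.fixture(scope="session")
def efficiency_fits():
    """50 replicate genes with L = 4 visits, each analyzed under both the
    baseline-only and the longitudinal scheme."""
    out = []
    for seed in range(50):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = simulate_dataset(longitudinal_config(), seed)
            out.append((sim.analyze("baseline"), sim.analyze("longitudinal")))
    return out


@pytest.fixture(scope="session")
def demo_sim():
    """A small four-visit dataset exercising all phenotype schemes."""
    return simulate_dataset(longitudinal_config(n_families=250, dropout=0.05),
                            20240101)
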