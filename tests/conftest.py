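"""Shared fixtures: small simulated panels and file-backed inputs."""

from __future__ import annotations

import numpy as np
import pytest

from giacall import (GenotypeMatrix, ReferencePanel, SimulationConfig,
                     Variant, WorkflowConfig, simulate_panel)


@pytest.fixture(scope="session")
def cfg() -> WorkflowConfig:
    return WorkflowConfig()


@pytest.fixture(scope="session")
def small_panel() -> tuple[ReferencePanel, np.ndarray, SimulationConfig]:
    """3 populations, F_ST 0.1, 60 refs/pop, 1000 variants."""
    sim = SimulationConfig(n_pops=3, fst=0.1, n_ref_per_pop=60,
                           n_variants=1000, seed=42)
    panel, freqs = simulate_panel(sim)
    return panel, freqs, sim


@pytest.fixture(scope="session")
def study_panel() -> tuple[ReferencePanel, np.ndarray, SimulationConfig]:
    """The end-to-end study condition: 3 pops, F_ST 0.1, 100 refs/pop,
    2000 variants."""
    sim = SimulationConfig(n_pops=3, fst=0.1, n_ref_per_pop=100,
                           n_variants=2000, seed=2024)
    panel, freqs = simulate_panel(sim)
    return panel, freqs, sim


def make_matrix(dosages: np.ndarray, sample_prefix: str = "S",
                chrom: int = 1) -> GenotypeMatrix:
    """Wrap a raw dosage array in a GenotypeMatrix with synthetic variants."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n, m = dosages.shape
    alleles = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    variants = [Variant(chrom, 1000 + j * 10, *alleles[j % 4], f"v{j}")
                for j in range(m)]
    return GenotypeMatrix(variants=variants,
                          samples=[f"{sample_prefix}{i}" for i in range(n)],
                          dosages=dosages)
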