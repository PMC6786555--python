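import numpy as np
import pandas as pd
import pytest

from bloodconcord import (
    ExpressionMatrix,
    PlatformSpec,
    SimulationConfig,
    normalize_experiment,
    simulate_annotation,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully featured design: 4 donors, 2 platforms x 2 reps."""
    return SimulationConfig(
        n_donors=4,
        platform_specs=(
            PlatformSpec("alpha", 2, noise_sd=0.25, gc_noise_link=0.4,
                         donor_attenuation=1.0),
            PlatformSpec("beta", 2, noise_sd=0.35, donor_attenuation=0.7),
        ),
        n_probes=300,
        duplicate_fraction=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    annotation = simulate_annotation(small_config)
    arrays, sheet, truth = simulate_experiment(small_config, annotation)
    return annotation, arrays, sheet, truth


@pytest.fixture(scope="session")
def small_matrix(small_experiment) -> ExpressionMatrix:
    _, arrays, sheet, _ = small_experiment
    return normalize_experiment(arrays, sheet)


def make_matrix(M: np.ndarray, sheet: pd.DataFrame,
                probe_ids=None, gene_ids=None) -> ExpressionMatrix:
    """Hand-build an ExpressionMatrix from a dense M array."""
    M = np.asarray(M, dtype=float)
    probe_ids = (pd.Index(probe_ids, name="probe_id") if probe_ids is not None
                 else pd.Index([f"P{i:03d}" for i in range(M.shape[0])],
                               name="probe_id"))
    m = pd.DataFrame(M, index=probe_ids, columns=list(sheet["sample_id"]))
    gene_map = pd.Series(
        gene_ids if gene_ids is not None else list(probe_ids),
        index=probe_ids, name="gene_id",
    )
    return ExpressionMatrix(M=m, A=m * 0 + 10.0, samples=sheet, gene_map=gene_map)


def make_sheet(rows) -> pd.DataFrame:
    """rows: iterable of (sample_id, donor_id, platform, replicate_index)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "platform", "replicate_index"]
    )
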