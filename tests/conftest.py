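import numpy as np
import pandas as pd
import pytest

from tc2tf.preprocess import ExpressionDataset
from tc2tf.simulate import SimConfig, generate_expression_dataset


def make_dataset(values_by_sample: dict[str, list[float]],
                 design_rows: list[tuple[str, str, float, int]],
                 probes: list[str],
                 probe_map: pd.DataFrame | None = None) -> ExpressionDataset:
    """Assemble a small ExpressionDataset from explicit numbers."""
    values = pd.DataFrame(values_by_sample, index=probes)
    design = pd.DataFrame(design_rows,
                          columns=["sample_id", "genotype", "time_h",
                                   "replicate"])
    if probe_map is None:
        probe_map = pd.DataFrame({
            "probe_id": probes,
            "gene_id": [p.replace("p_", "") for p in probes],
            "ambiguous": False})
    return ExpressionDataset(values=values, design=design,
                             probe_map=probe_map)


@pytest.fixture(scope="session")
def small_noiseless():
    """Tiny noiseless simulated dataset: truth should be reproduced exactly."""
    cfg = SimConfig(n_genes=40, frac_responsive=0.5, noise_sd_log2=0.0,
                    frac_ambiguous_probes=0.0, frac_duplicate_probes=0.0,
                    seed=7)
    return generate_expression_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default-condition simulation shared across recovery tests."""
    cfg = SimConfig(seed=1)
    return cfg, generate_expression_dataset(cfg)
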