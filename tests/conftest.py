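import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crossomics import quant

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(intensities, peptide_counts, fraction="CE", n_rep=None):
    """FractionDataset from plain arrays (proteins x 2*reps, T24 block first)."""
    intensities = np.asarray(intensities, dtype=float)
    peptide_counts = np.asarray(peptide_counts, dtype=int)
    n_prot, n_samp = intensities.shape
    n_rep = n_rep or n_samp // 2
    samples = [f"T24_{r}" for r in range(1, n_rep + 1)] + [
        f"T24M_{r}" for r in range(1, n_samp - n_rep + 1)
    ]
    acc = pd.Index([f"P{i:04d}" for i in range(n_prot)], name="accession")
    return quant.FractionDataset(
        fraction_label=fraction,
        intensities=pd.DataFrame(intensities, index=acc, columns=samples),
        peptide_counts=pd.DataFrame(peptide_counts, index=acc, columns=samples),
        groups=pd.Series({s: s.rsplit("_", 1)[0] for s in samples}),
        replicate_index=pd.Series({s: int(s.rsplit("_", 1)[1]) for s in samples}),
    )


@pytest.fixture
def tiny_dataset():
    """3 proteins x 10 samples, all detected with >=2 peptides."""
    rng = np.random.default_rng(0)
    intens = rng.lognormal(10, 0.3, size=(3, 10))
    peps = np.full((3, 10), 3)
    return make_dataset(intens, peps)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed fixed)."""
    from crossomics.simulate import SimConfig, generate_proteome

    cfg = SimConfig(seed=20160511)
    datasets, truth = generate_proteome(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run on the default simulation workspace."""
    from crossomics import pipeline
    from crossomics.simulate import simulate_workspace

    cfg, _, truth = default_sim
    ws = simulate_workspace(cfg, tmp_path_factory.mktemp("ws") / "default")
    result = pipeline.run_pipeline(pipeline.workspace_config(ws))
    return ws, truth, result
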