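import numpy as np
import pytest

from pdbmend.fixtures import (
    AblationPlan,
    ablate,
    make_ideal_peptide,
    random_ablation_plan,
    random_sequence,
    roundtrip,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tri_ala():
    """Three-residue alanine peptide with hydrogens (via the PDB round trip)."""
    return roundtrip(make_ideal_peptide("AAA"))


@pytest.fixture
def helix60():
    """60-residue random helix, heavy atoms only, fixed seed."""
    seq = random_sequence(60, np.random.default_rng(7))
    return make_ideal_peptide(seq, "helix", with_hydrogens=False), seq


def damaged_helix(seed: int, n_res: int = 30, n_runs: int = 1, max_run: int = 5):
    """Seeded helix-ablation fixture: (damaged model, truth, full sequence)."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(n_res, rng)
    model = make_ideal_peptide(seq, "helix", with_hydrogens=False)
    plan = random_ablation_plan(n_res, rng, n_runs=n_runs, max_run=max_run)
    damaged, truth = ablate(model, plan)
    return roundtrip(damaged), truth, seq
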