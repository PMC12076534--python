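"""SEQRES/ATOM matching and internal-gap extraction."""

import numpy as np
import pytest

from pdbmend.errors import AlphaTraceError, SequenceMismatchError
from pdbmend.fixtures import (
    AblationPlan,
    ablate,
    make_ideal_peptide,
    random_ablation_plan,
    random_sequence,
    roundtrip,
)
from pdbmend.pdbio import parse_structure, write_structure
from pdbmend.sequence_gaps import (
    chain_gaps,
    gaps_to_table,
    internal_gaps,
    match_seqres,
    observed_sequence,
)


def _helix(seq, seed=0, **kw):
    return make_ideal_peptide(seq, "helix", with_hydrogens=False, **kw)


def test_observed_sequence_excludes_incomplete_backbone():
    model = _helix(random_sequence(20, np.random.default_rng(1)))
    chain = model.chains[0]
    # ablate backbone C of residue 7: that residue drops out of the sequence
    res = chain.residue(7)
    res.atoms = [a for a in res.atoms if a.name != "C"]
    obs = observed_sequence(chain)
    assert len(obs) == 19
    assert 7 not in [n for n, _, _ in obs]


def test_internal_deletion_observed_count():
    model = _helix(random_sequence(20, np.random.default_rng(2)))
    damaged, _ = ablate(model, AblationPlan(deleted_runs=[(9, 11)]))
    assert len(observed_sequence(damaged.chains[0])) == 17


def test_alpha_trace_chain_error():
    model = _helix(random_sequence(10, np.random.default_rng(3)))
    for res in model.chains[0].residues:
        res.atoms = [a for a in res.atoms if a.name == "CA"]
    with pytest.raises(AlphaTraceError, match="alpha-trace"):
        observed_sequence(model.chains[0])


def test_identical_sequences_zero_gaps():
    model = roundtrip(_helix(random_sequence(25, np.random.default_rng(4))))
    match = match_seqres(model.chains[0])
    assert match.identity == 1.0
    assert match.n_internal_gaps == 0
    assert internal_gaps(match, model.chains[0]) == []


def test_four_residue_deletion_recovered_in_order():
    seq = random_sequence(30, np.random.default_rng(5))
    damaged, _ = ablate(_helix(seq), AblationPlan(deleted_runs=[(12, 15)]))
    damaged = roundtrip(damaged)
    gaps = chain_gaps(damaged.chains[0])
    assert len(gaps) == 1
    assert gaps[0].missing_seq == seq[11:15]
    assert gaps[0].span == (12, 15)
    assert gaps[0].start_anchor == (11, seq[10])
    assert gaps[0].end_anchor == (16, seq[15])


def test_terminal_deletions_are_not_internal_gaps():
    seq = random_sequence(30, np.random.default_rng(6))
    model = roundtrip(_helix(seq))
    chain = model.chains[0]
    chain.residues = chain.residues[10:]  # first 10 residues unobserved
    match = match_seqres(chain)
    assert match.n_missing_nterm == 10
    assert match.n_internal_gaps == 0
    assert internal_gaps(match, chain) == []


def test_sum_rule_on_random_fixtures():
    """len(seqres) = observed + gaps + missing termini, whenever match succeeds."""
    for seed in range(6):
        rng = np.random.default_rng(seed)
        n = 40
        seq = random_sequence(n, rng)
        model = _helix(seq)
        plan = random_ablation_plan(n, rng, n_runs=2, max_run=4)
        damaged, _ = ablate(model, plan)
        chain = roundtrip(damaged).chains[0]
        chain.residues = chain.residues[3:]  # also chop the N-terminus
        match = match_seqres(chain)
        gaps = internal_gaps(match, chain)
        n_obs = sum(1 for p in match.pairs if p is not None)
        assert len(chain.seqres) == (
            n_obs + sum(len(g) for g in gaps)
            + match.n_missing_nterm + match.n_missing_cterm
        )


def test_gap_recovery_closure_property(rng):
    """Deletion plan -> detection recovers exactly the planned internal runs."""
    for _ in range(30):
        n = int(rng.integers(25, 60))
        seq = random_sequence(n, rng)
        plan = random_ablation_plan(n, rng, n_runs=int(rng.integers(1, 4)), max_run=5)
        damaged, truth = ablate(_helix(seq), plan)
        gaps = chain_gaps(roundtrip(damaged).chains[0])
        assert [(g.span[0], g.span[1]) for g in gaps] == truth.runs


def test_renumbered_chain_falls_back_to_alignment():
    seq = random_sequence(30, np.random.default_rng(8))
    damaged, _ = ablate(_helix(seq), AblationPlan(deleted_runs=[(10, 12)]))
    chain = roundtrip(damaged).chains[0]
    for res in chain.residues:  # renumber: numbering no longer embeds in SEQRES
        res.number += 500 if res.number > 15 else 0
    match = match_seqres(chain)
    gaps = internal_gaps(match, chain)
    assert [g.missing_seq for g in gaps][0] == seq[9:12]


def test_sequence_mismatch_error():
    seq = random_sequence(40, np.random.default_rng(9))
    model = roundtrip(_helix(seq))
    chain = model.chains[0]
    chain.seqres = random_sequence(40, np.random.default_rng(10))  # unrelated
    for r in chain.residues:  # force the alignment path
        r.number += 1000 if r.number > 20 else 0
    with pytest.raises(SequenceMismatchError):
        match_seqres(chain)


def test_no_seqres_numbering_fallback():
    seq = random_sequence(20, np.random.default_rng(11))
    damaged, _ = ablate(_helix(seq), AblationPlan(deleted_runs=[(8, 9)]))
    chain = roundtrip(damaged).chains[0]
    chain.seqres = []
    match = match_seqres(chain)
    assert match.numbering_only
    gaps = internal_gaps(match, chain)
    assert len(gaps) == 1 and gaps[0].span == (8, 9)
    assert not gaps[0].repairable  # contents unknown -> UNK -> unrepairable


def test_unknown_seqres_code_flags_unrepairable():
    seq = random_sequence(20, np.random.default_rng(12))
    damaged, _ = ablate(_helix(seq), AblationPlan(deleted_runs=[(8, 9)]))
    chain = roundtrip(damaged).chains[0]
    chain.seqres = chain.seqres[:7] + ["UNK", "UNK"] + chain.seqres[9:]
    gaps = chain_gaps(chain)
    assert len(gaps) == 1 and not gaps[0].repairable


def test_gap_table_export():
    seq = random_sequence(20, np.random.default_rng(13))
    damaged, _ = ablate(_helix(seq), AblationPlan(deleted_runs=[(5, 7)]))
    gaps = chain_gaps(roundtrip(damaged).chains[0])
    table = gaps_to_table(gaps)
    assert table.splitlines()[0].startswith("chain\t")
    assert "\t5\t7\t3\t" in table.splitlines()[1]
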