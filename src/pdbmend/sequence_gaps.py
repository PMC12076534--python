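"""SEQRES / ATOM sequence matching and internal-gap detection.

The deposited SEQRES records carry the full chain sequence; the ATOM records
carry only the resolved residues. Matching the two yields the *internal*
gaps — runs of unresolved residues strictly between the first and last
observed residue — which are the repairable defects. Missing N-/C-terminal
tails are reported but never modelled.

Matching strategy: most PDB entries number their ATOM records consistently
with SEQRES, so the primary path anchors on author residue numbers (a single
offset embedding the observed numbering into 1..len(SEQRES)). Chains that
were renumbered, or that carry insertion codes, fall back to a global
sequence alignment (match +1, mismatch -1, gap -2). An alignment identity
below 95% is reported as a sequence-mismatch failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio import Align

from .errors import AlphaTraceError, SequenceMismatchError
from .pdbio import Chain, Residue
from .templates import STANDARD_AA, THREE_TO_ONE

__all__ = [
    "GapRecord",
    "SequenceMatch",
    "observed_sequence",
    "match_seqres",
    "internal_gaps",
    "chain_gaps",
    "gaps_to_json",
    "gaps_to_table",
]


@dataclass
class GapRecord:
    chain_id: str
    start_anchor: tuple[int, str]  # (residue number, name) before the gap
    end_anchor: tuple[int, str]  # (residue number, name) after the gap
    missing_seq: list[str]  # 3-letter codes from SEQRES, in order
    span: tuple[int, int]  # inclusive residue-number range of the gap
    repairable: bool = True  # False when the gap contains untemplated codes

    def __len__(self) -> int:
        return len(self.missing_seq)


@dataclass
class SequenceMatch:
    chain_id: str
    # per SEQRES position (0-based): the observed Residue or None
    pairs: list[Residue | None]
    identity: float
    n_missing_nterm: int
    n_missing_cterm: int
    seqres_numbers: list[int]  # author number implied for each SEQRES position
    numbering_only: bool = False  # no SEQRES; gaps inferred from numbering jumps
    extras: list[Residue] = field(default_factory=list)  # observed, unalignable

    @property
    def n_internal_gaps(self) -> int:
        return len(self._internal_runs())

    def _internal_runs(self) -> list[tuple[int, int]]:
        """Runs of unobserved SEQRES indices strictly inside the observed span."""
        obs_idx = [i for i, r in enumerate(self.pairs) if r is not None]
        if not obs_idx:
            return []
        first, last = obs_idx[0], obs_idx[-1]
        runs = []
        i = first + 1
        while i < last:
            if self.pairs[i] is None:
                j = i
                while self.pairs[j + 1] is None:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        return runs


def observed_sequence(chain: Chain) -> list[tuple[int, str, str]]:
    """(number, icode, 3-letter code) for every residue with full N, CA, C.

    Raises :class:`AlphaTraceError` for chains that provide only alpha traces.
    """
    out = [(r.number, r.icode, r.name) for r in chain.residues if r.has_backbone]
    if not out:
        if any(r.atom("CA") is not None for r in chain.residues):
            raise AlphaTraceError(f"chain {chain.id}: alpha-trace chain")
        raise AlphaTraceError(f"chain {chain.id}: no protein backbone found")
    return out


def _one_letter(codes: list[str]) -> str:
    return "".join(THREE_TO_ONE.get(c, "X") for c in codes)


def _try_number_anchoring(chain: Chain, observed: list[Residue]) -> SequenceMatch | None:
    seqres = chain.seqres
    numbers = [r.number for r in observed]
    if any(r.icode for r in observed):
        return None
    if any(b <= a for a, b in zip(numbers, numbers[1:])):
        return None
    # candidate offsets: align the first observed residue onto each SEQRES
    # occurrence of its name
    first = observed[0]
    for j, code in enumerate(seqres):
        if code != first.name:
            continue
        offset = first.number - (j + 1)
        ok = True
        for r in observed:
            idx = r.number - offset - 1
            if idx < 0 or idx >= len(seqres) or seqres[idx] != r.name:
                ok = False
                break
        if ok:
            pairs: list[Residue | None] = [None] * len(seqres)
            for r in observed:
                pairs[r.number - offset - 1] = r
            obs_idx = [i for i, p in enumerate(pairs) if p is not None]
            return SequenceMatch(
                chain_id=chain.id,
                pairs=pairs,
                identity=1.0,
                n_missing_nterm=obs_idx[0],
                n_missing_cterm=len(seqres) - 1 - obs_idx[-1],
                seqres_numbers=[i + 1 + offset for i in range(len(seqres))],
            )
    return None


def _align_fallback(chain: Chain, observed: list[Residue]) -> SequenceMatch:
    seqres = chain.seqres
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    s1 = _one_letter(seqres)
    s2 = _one_letter([r.name for r in observed])
    aln = aligner.align(s1, s2)[0]
    pairs: list[Residue | None] = [None] * len(seqres)
    matched = mismatched = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            res = observed[b0 + k]
            if seqres[a0 + k] == res.name:
                matched += 1
            else:
                mismatched += 1
            pairs[a0 + k] = res
    aligned_cols = matched + mismatched
    identity = matched / aligned_cols if aligned_cols else 0.0
    if identity < 0.95:
        raise SequenceMismatchError(
            f"chain {chain.id}: sequence mismatch"
            f" (alignment identity {identity:.2f} < 0.95)"
        )
    aligned_set = {id(pairs[i]) for i in range(len(seqres)) if pairs[i] is not None}
    extras = [r for r in observed if id(r) not in aligned_set]
    obs_idx = [i for i, p in enumerate(pairs) if p is not None]
    # SEQRES-implied author numbers: anchor on observed residues, interpolate
    numbers = [0] * len(seqres)
    for i, p in enumerate(pairs):
        if p is not None:
            numbers[i] = p.number
    for i in range(len(seqres)):
        if pairs[i] is None:
            # nearest preceding observed position
            prev = next((k for k in range(i - 1, -1, -1) if pairs[k] is not None), None)
            if prev is not None:
                numbers[i] = numbers[prev] + (i - prev)
            else:
                nxt = next(k for k in range(i + 1, len(seqres)) if pairs[k] is not None)
                numbers[i] = numbers[nxt] - (nxt - i)
    return SequenceMatch(
        chain_id=chain.id,
        pairs=pairs,
        identity=identity,
        n_missing_nterm=obs_idx[0] if obs_idx else 0,
        n_missing_cterm=(len(seqres) - 1 - obs_idx[-1]) if obs_idx else 0,
        seqres_numbers=numbers,
        extras=extras,
    )


def _numbering_only(chain: Chain, observed: list[Residue]) -> SequenceMatch:
    """No SEQRES: infer gaps from residue-number jumps; contents unknown."""
    pairs: list[Residue | None] = []
    numbers: list[int] = []
    prev = None
    for r in observed:
        if prev is not None and r.number > prev + 1:
            for n in range(prev + 1, r.number):
                pairs.append(None)
                numbers.append(n)
        pairs.append(r)
        numbers.append(r.number)
        prev = r.number
    return SequenceMatch(
        chain_id=chain.id,
        pairs=pairs,
        identity=1.0,
        n_missing_nterm=0,
        n_missing_cterm=0,
        seqres_numbers=numbers,
        numbering_only=True,
    )


def match_seqres(chain: Chain) -> SequenceMatch:
    """Match SEQRES against the sequence perceived from the backbone atoms."""
    observed_keys = observed_sequence(chain)
    key_set = {(n, i) for n, i, _ in observed_keys}
    observed = [r for r in chain.residues if (r.number, r.icode) in key_set and r.has_backbone]
    if not chain.seqres:
        return _numbering_only(chain, observed)
    match = _try_number_anchoring(chain, observed)
    if match is None:
        match = _align_fallback(chain, observed)
    return match


def internal_gaps(match: SequenceMatch, chain: Chain) -> list[GapRecord]:
    """Internal gap records, sorted by position; terminal runs are excluded."""
    gaps = []
    seqres = chain.seqres if chain.seqres else [
        "UNK" if p is None else p.name for p in match.pairs
    ]
    for i, j in match._internal_runs():
        missing = list(seqres[i : j + 1])
        start = match.pairs[i - 1]
        end = match.pairs[j + 1]
        repairable = all(c in STANDARD_AA for c in missing)
        gaps.append(
            GapRecord(
                chain_id=match.chain_id,
                start_anchor=(start.number, start.name),
                end_anchor=(end.number, end.name),
                missing_seq=missing,
                span=(match.seqres_numbers[i], match.seqres_numbers[j]),
                repairable=repairable,
            )
        )
    return gaps


def chain_gaps(chain: Chain) -> list[GapRecord]:
    """Convenience: match then extract internal gaps for one chain."""
    return internal_gaps(match_seqres(chain), chain)


def gaps_to_json(gaps: list[GapRecord]) -> str:
    return json.dumps(
        [
            {
                "chain": g.chain_id,
                "start": g.start_anchor,
                "end": g.end_anchor,
                "span": g.span,
                "length": len(g),
                "sequence": g.missing_seq,
                "repairable": g.repairable,
            }
            for g in gaps
        ],
        indent=2,
    )


def gaps_to_table(gaps: list[GapRecord]) -> str:
    rows = ["chain\tstart\tend\tlength\tsequence"]
    for g in gaps:
        rows.append(
            f"{g.chain_id}\t{g.span[0]}\t{g.span[1]}\t{len(g)}\t"
            + "-".join(g.missing_seq)
        )
    return "\n".join(rows) + "\n"
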