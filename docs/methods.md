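# Methods

`pdbmend` turns a defective protein PDB file into a chemically complete,
geometry-sane model: it detects internal sequence gaps by matching SEQRES
against the residues perceived from the ATOM records, rebuilds the missing
stretches, completes side chains, assigns protonation states at pH 7, adds
hydrogens, minimizes the whole chain under a reduced force field, and can
wrap the result in a cubic water box. This note records the models,
parameter choices and their rationale, and what the synthetic test world
does and does not establish.

## Sequence matching and gap definition

The full deposited sequence lives in the SEQRES records; the observed
sequence is the ordered list of residues with at least N, CA and C atoms
(CA-only "alpha-trace" chains are a hard error — the backbone sequence
cannot be perceived from them). An *internal gap* is a run of SEQRES
residues with no coordinates lying strictly between the first and last
observed residue; missing terminal tails are counted but never modelled.

Matching is number-anchored first: if the author residue numbers embed
monotonically into 1..len(SEQRES) under a single offset with every residue
name agreeing, that embedding is the match. Chains that fail this (renumbered
chains, insertion codes) fall back to a global alignment of one-letter
sequences (match +1, mismatch −1, gap −2, via Biopython's `PairwiseAligner`).
An alignment identity below 95% over aligned columns is reported as a
sequence-mismatch failure rather than guessed through. Gaps whose SEQRES
content includes unknown or non-standard codes are reported but flagged
unrepairable.

## Residue templates

The 20 standard amino acids plus the protonation/tautomer/bridge variants
(HIE/HID/HIP, CYS/CYX/CYM, ASH/GLH/LYN) ship as a human-readable
internal-coordinate file (`data/residue_templates.dat`). Every atom is
placed by NeRF from three previously placed atoms (bond, angle, dihedral).
Two provenance classes:

* **Acyclic geometry** — standard single-conformer values (e.g. C–C
  1.526 Å, tetrahedral angles, amide N–H 1.01 Å). Rotatable dihedrals are
  fixed at staggered values chosen so the *extended* conformer is as
  clash-free as possible: this was selected by a one-off grid search over
  the ±120° chi rotations against extended homotetrapeptides. The winning
  choices put long side chains in g+ (χ1 = +60°), short polar ones in g−.
  β-branched residues (VAL/ILE) retain one ≈1.5 Å H contact in the fully
  extended backbone — intrinsic to that conformation and relaxed by any
  subsequent minimization.
* **Ring geometry** — internal coordinates measured from MMFF94-optimised
  side-chain analog molecules (toluene, p-cresol, 4-methylimidazole in both
  tautomers, 3-methylindole, L-proline), so rings close exactly on rebuild
  (closure bonds reproduce to <1e-3 Å).

Backbone construction uses Engh–Huber-like values (N–CA 1.458, CA–C 1.525,
C–N 1.329, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°). The
L-chirality improper dihedral (CB, CA, N, C) = −122.5° was verified against
an MMFF-optimised L-alanine. Proline is built with φ = −75° in otherwise
all-trans chains because its ring is geometrically incompatible with
φ = 180° (CD would fold onto the preceding carbonyl).

Chain termini: residues at true sequence termini are built charged
(NH3+/COO− with OXT); chains whose termini are unresolved keep neutral cut
ends (single amide H, plain C=O), since missing terminal residues are
excluded from modelling rather than capped. The atom census
(`expected_atom_count`) is computed purely from templates + assigned
variants + termini flags and therefore provides a geometry-independent
cross-check on every built model.

`declash_sidechains` is a deterministic post-build pass that re-rotates a
side chain by ±120° about CA–CB when the template rotamer collides with the
rest of the chain in a non-extended backbone (helices fold g+ side chains
onto i−3 neighbours). It considers heavy atoms only and runs before
hydrogen addition.

## Chemical state assignment (pH 7)

Defaults: histidine neutral in the ε tautomer, arginine/lysine protonated,
aspartate/glutamate deprotonated, cysteine protonated. Overrides:

* **Disulfides** — SG–SG pairs within 2.5 Å (typical bond 2.05 Å), greedy
  nearest-pair matching so each SG joins at most one bridge; both partners
  become CYX and an SSBOND record is written on output.
* **Metal coordination** — for each metal ion (single-atom HETATM whose
  element is in the configurable metal list) all protein N/O/S atoms within
  3.0 Å are collected. A CYS whose SG coordinates becomes the thiolate CYM
  (unless bridged: the bridge wins, with a warning). A HIS is flipped so the
  coordinating ring nitrogen is the bare one (NE2 coordinates → δ tautomer;
  ND1 → ε; both within the cutoff → warning, ε kept). Metals stay nonbonded
  particles throughout; no charge transfer, no bonded metal topology.

## Reduced force field and minimization

The published workflow minimizes under a full biomolecular force field;
re-implementing one is out of scope here, and a reduced transferable set is
used instead (shipped as `data/reduced_ff.dat`):

* harmonic bonds (k = 1000 kJ/mol/Å²) and angles (k = 400 kJ/mol/rad²) with
  equilibrium values measured from each variant's own template reference
  build — built structures start exactly at their bonded minimum;
* torsions: a 2-fold, 20 kJ/mol planarity term on every peptide ω, and a
  generic 3-fold 5 kJ/mol barrier on acyclic torsions whose two central
  atoms are both saturated (ring torsions and sp2 centers carry none);
* element-based Lennard-Jones (Lorentz–Berthelot), 10 Å cutoff with
  potential shift, Verlet neighbor list, 1-2/1-3 excluded, 1-4 scaled 0.5;
* no electrostatics by default (a hook accepts externally supplied charges
  and adds plain Coulomb); ligand het groups contribute no bonded terms and
  their internal pairs are excluded (rigid heavy-atom groups).

**Consequence (the largest declared deviation):** absolute energies are not
comparable to published force-field values, so the "≈ −100 kJ/mol per
residue" success heuristic is reported as a diagnostic only. Success is
judged instead on the gradient threshold — maximum per-atom gradient below
10 kJ/mol/Å — and on geometric quality (closure-bond tolerance, clash
relief).

The minimizer is Polak–Ribière(+) conjugate gradient with Armijo
backtracking, a 0.5 Å per-step displacement cap, and an exact fixed-atom
mask (constrained coordinates are bit-identical on return; pairs of fixed
atoms are skipped in the nonbonded sum since they only add a constant).
Accepted steps are non-increasing in energy by construction. The analytic
gradient is validated against central finite differences at 1e-6 relative
in the test suite.

## Gap repair

Each gap is processed independently, N→C along the chain, because
simultaneous multi-gap optimization invites inter-gap interference. Per gap:

1. Build the missing subsequence all-trans, its first N bonded to the
   upstream anchor's C (1.329 Å).
2. Generate six candidate orientations: the fragment is rigidly rotated
   about the attachment N so its axis — N(first)→CA(last), or N→C for
   1-residue fragments — points along ±3 orthonormal axes anchored on the
   upstream residue (e1 along the ideal next-peptide-bond direction, e2 in
   the anchor backbone plane).
3. Clash screen: orientations with more than 5 hard clashes (heavy-atom
   pairs closer than 0.6× the sum of vdW radii) against all atoms present
   at trial time are discarded. If *every* orientation clashes (typical for
   1-residue gaps inside a helix), the two least-clashing ones proceed
   anyway — relief of overlap is exactly what the closure minimization
   does, and giving up here would fail gaps the method can close.
4. Closure: minimize the fragment with both anchor residues (and nearby
   environment atoms within ≈12 Å) held fixed, under a harmonic restraint
   (k = 1000 kJ/mol/Å², r0 = 1.329 Å) between the fragment's C-terminal C
   and the downstream N, plus the nascent junction's angle and ω terms. The
   generic 3-fold torsions are dropped during closure only — the fragment
   must fold, and they oppose it. If the bond has not sealed to within
   ±0.1 Å, the restraint is stiffened (×4, ×16, ×64) and minimization
   continues — a deterministic continuation schedule.
5. Among successful closures, the lowest closure energy wins (ties → lowest
   direction index, for determinism); the closed coordinates are inserted
   with their SEQRES-implied author numbers.

After all gaps: side-chain completion, a *fresh* chemical-state assignment
(inserted residues can coordinate metals), hydrogen addition, and a final
unconstrained minimization of the whole chain with ligands held rigid and
metals as free nonbonded particles. Chains above 9,000 heavy atoms are
refused. The report carries per-trial clash/energy/bond data, the census
(N, Nh, NL), and the backbone RMSD of the originally observed atoms against
their deposited coordinates (no superposition — minimization does not move
the frame).

## Solvation

The solute is reoriented onto its principal axes (eigenvectors of the
coordinate covariance, decreasing eigenvalue order, right-handed, sign fixed
by the largest-|projection| atom). The cubic box side is the maximum
coordinate extent plus 2×15 Å, so no solute atom is nearer than 15 Å to a
wall. Water (rigid 3-site, O–H 0.9789 Å, H–O–H 109.47°) is placed on a
simple cubic lattice at the spacing implied by 0.997 g/cm³ —
(18.015 g·mol⁻¹ / N_A ρ)^(1/3) ≈ 3.107 Å — with a uniformly random rigid
orientation per site from the seeded generator; the rotation stream is
drawn per lattice site regardless of pruning, so the count and coordinates
are deterministic given the seed. Waters whose O lies within 2.6 Å of a
solute heavy atom are removed. No NPT equilibration is performed (second
declared deviation): the lattice construction already reproduces the bulk
density exactly over the filled region, and the box side is not
re-equilibrated. Boxes that would exceed 120,000 atoms are refused.

## Corpus survey

Over any local directory of PDB files: distribution of protein chains per
entry, chain length in ATOM-record heavy atoms, fraction of chains with ≥1
internal gap, and the mean internal-gap length with and without excluding
gaps longer than 100 residues (a few giant disordered regions dominate the
raw mean). Uncertainty is the standard error across equal random partitions
of the corpus (default 4 subsamples, seeded).

## The synthetic world — what a green test establishes

Fixtures are ideal peptides (extended, or α-helical at φ=−57°, ψ=−47°)
damaged by explicit plans (internal deletions, side-chain truncations,
hydrogen stripping) whose truth records make every downstream claim
checkable without reference data. They are always written to PDB text and
re-parsed, so format handling stays on the test path. Two stand-ins
reproduce the *published properties* of reference entries that cannot be
redistributed: a two-chain helicase-like model (exact gap spans totalling
20 + 7 missing residues, three zinc ions per chain, eight zinc-coordinating
cysteines, a 23-atom ligand) and a two-chain complex (chains of exactly
2310 and 899 heavy atoms, 338 SEQRES residues, two ligands, 415 waters).
In the helicase stand-in the zinc-site SG atoms are displaced onto ideal
coordination vertices; state assignment, gap detection and censuses are
exact there, but the local geometry around the zincs is not meaningful and
is never minimized in tests.

Green tests therefore establish: correctness of sequence/gap logic,
conservation between the template census and the geometric construction,
minimizer correctness (gradient, monotonicity, constraints), closure
quality on helix ablations, the protonation rule set, and deterministic
solvation. They do not establish biological realism of rebuilt loops
(fixtures test mechanics, not folds), force-field accuracy, or behaviour on
crystallographic pathologies (altloc ties and insertion codes are covered
only by constructed cases).

## Known limitations

* No electrostatics in the default energy: closure and clash relief are
  LJ/bonded-driven; metal sites keep their geometry only because metals and
  ligands are held rigid in the final minimization.
* Rebuilt loops are energy-plausible, not ensemble-representative; no
  rotamer library, no backbone sampling beyond the six-orientation search.
* Non-standard residues (modified amino acids, glycosylation) are carried
  as ligands or flagged unrepairable, mirroring the upstream tool's scope.
* mmCIF is not parsed; multi-model entries use the first model only; altloc
  collapse keeps the highest-occupancy conformer (ties → 'A').
* Large chains (> 9,000 heavy atoms) and boxes (> 120,000 atoms) are
  refused by design.
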