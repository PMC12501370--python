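# Methods

This note records how cofoldprobe defines its quantities, which defaults
it fixes and why, what the synthetic layer does and does not emulate, and
where genuinely open design choices were resolved.

## Binding-site definition

A residue belongs to the binding site when at least one of its side-chain
heavy atoms lies within a cutoff (default 3.5 Å, inclusive) of any ligand
heavy atom. Side chain means all heavy atoms outside the N/CA/C/O(/OXT)
backbone, so CB counts for alanine and glycine can never qualify — this is
a property of the definition, not a defect, and is left undocumented-around
rather than patched. Whether the boundary comparison is inclusive is
exposed (`inclusive=True` by default): "within" is read inclusively so that
a residue sitting exactly at the cutoff is stable under coordinate
rounding. Residues with partially missing side chains are evaluated on the
atoms present, with a warning. Alternate conformations are resolved before
detection (highest occupancy wins; ties keep file order), so detection
sees exactly one copy of every atom.

## Miyata distance and the inversion assignment

The dissimilarity between amino acids i and j is

    d_ij = sqrt((Δp_ij/σ_p)² + (Δv_ij/σ_v)²)

with polarity p and side-chain volume v on the Grantham scales. The
normalizations σ_p and σ_v are the *population* standard deviations of the
absolute property differences over the 190 unordered pairs of standard
amino acids; this choice reproduces the published distances of the
dissimilar-residue assignment to two decimals for all twenty residues,
which is the validation the default table must pass.
`MiyataPropertyTable.validated()` refuses any property set that fails this
check, so a silently re-scaled table cannot slip into the inversion
challenge. The inversion targets themselves are stored as an explicit
20-entry map ({Y,W,K,R}→G, {V,L,I,M,F}→D, rest→W) rather than recomputed
by arg-max over d_ij: the published assignment is the ground truth and is
not claimed to be an arg-max.

## Ligand editing

*Methylation* converts hydroxyl oxygens (O with exactly one heavy
neighbour, a carbon, and ≥1 H, formal charge 0) into methyl ethers, in
ascending carbon-locant order. Locants are assigned by walking a
single-oxygen ring from the anomeric carbon (the ring-oxygen neighbour
bearing an exocyclic OH); exocyclic carbons extend their parent's locant,
so β-D-glucopyranose enumerates C1, C2, C3, C4, C6 — five positions, the
anomeric one first. Molecules without a unique single-oxygen ring fall
back to canonical-rank ordering. Requests beyond the enumerable hydroxyl
count raise, citing the count.

*Triphosphate replacement* excises every phosphorus plus all oxygens bonded
only to phosphorus, keeping the carbon-bonded bridge oxygen (O5′ in ATP)
as the anchor. k ∈ {1,2,3} units are then chained from the anchor:
choline-like units (−CH₂CH₂N⁺(CH₃)₂−, terminal nitrogen trimethylated)
carry +1 each; tert-butyl-like units (quaternary carbon with methyls,
internal units chained through a CH₂) are neutral. The exact covalent
concatenation of multi-unit tails is a design choice — only the net formal
charge (+k or 0) and the preserved nucleoside core are guaranteed, and the
tests assert exactly that. The built-in ATP model keeps one proton on the
γ-phosphate so its net charge is −3; this deprotonation convention is a
documented constant (`ATP_SMILES`), not the physiological −4.

New atoms receive crude deterministic coordinates (1.45 Å outward from the
molecular centroid through their anchor). Modified ligands are never
conformer-embedded: predictors are expected to generate 3D structures, and
the evaluation maps only parent atoms whose coordinates are meaningful.

*Tanimoto similarity* uses a Morgan fingerprint, radius 2 over 2048 bits
(`FINGERPRINT_RADIUS`, `FINGERPRINT_BITS`). The fingerprint family is a
config choice; radius-2 circular fingerprints are the field's default for
small-molecule similarity.

## Pose scoring

The frame convention is docking-style: the predicted protein is superposed
onto the reference by least squares over shared Cα atoms (matched by
chain + author number + insertion code; ≥3 required), and the ligand RMSD
is computed in that frame. There is never a ligand-only refit — a
translated ligand in a perfectly predicted protein must score as moved.

Atom correspondence: identical ligands get a full graph bijection; modified
ligands get a maximum-common-substructure core (which covers every parent
atom in the methylation series, excluding the added methyls) extended along
unbranched chains so that replacement-group atoms map onto excised-group
positions where a topological correspondence exists. Mappings covering
less than half the reference heavy atoms (configurable floor) are refused
as incomparable.

Symmetry-aware RMSD minimizes over graph automorphisms of the reference
ligand (element, bond order and formal charge preserving), enumerated via
substructure self-matching with a cap of 10,000; beyond the cap the naive
mapping is used with a warning. Both symmetry-on and symmetry-off values
are available because published pose-conservation numbers do not always
state whether they are symmetry-corrected.

Conservation is strict: RMSD < 2.0 Å. A record at exactly 2.0 Å is not
conserved.

Clashes are non-bonded protein/ligand heavy-atom pairs with distance below
vdW_i + vdW_j − 0.4 Å, using Bondi radii (C 1.70, N 1.55, O 1.52, S/P
1.80 Å; 1.70 Å default for unlisted elements). The 0.4 Å tolerance is the
conventional severe-clash allowance in structure validation; the criterion
is a definition fixed in config, since "steric clash" admits no unique
formula.

Confidence stratification uses the mean per-atom confidence over mapped
ligand atoms as "the confidence score" (0–100 scale, consumed as given).
This is a config choice; nothing in the package produces or interprets
confidence values beyond averaging them.

## Occupancy analysis

Frames with ligand RMSD < 2 Å (strict) to the native pose are bound;
everything else is a single unbound class — no clustering of unbound
sub-states, because the downstream report has exactly two columns.
Occupancy is the bound-frame fraction per replicate; replicates aggregate
as mean ± sample (n−1) standard deviation, the triplicate convention. The
module consumes post-processed (unbiased or externally reweighted) series
only: free-energy machinery such as funnel restraints and bias reweighting
belongs to the simulation stack upstream and is deliberately out of scope.

## Synthetic data: what it does and does not show

`make_toy_complex` arranges residues geometrically around a 3D-embedded
ligand (seeded ETKDG): site residues point their side-chain tip at exactly
`pocket_radius` (default 3.2 Å) from their nearest ligand atom, scaffold
residues sit `scaffold_margin` (default 6 Å) further out. Residues have
correct heavy-atom names but linear, chemically idealized side-chain
geometry, and the chain has no fold. The mock predictors are caricatures:
`memorizer` always returns the wild-type pose (plus optional Gaussian
noise, default 0.05 Å in the benchmark); `physics` expels the ligand by
`displacement` (default 8 Å, required ≥ the 2 Å threshold) whenever the
pocket was perturbed, with the glycine-removal response configurable
(default: conserved, since backbone contacts survive removal). Mock
confidence values are uniform draws — high (85–98) for retained poses,
low (40–70) for expelled ones — and carry no calibration.

Passing the synthetic benchmark therefore shows that the *pipeline*
(detection → mutagenesis → job emission → scoring → statistics) is
correct and deterministic end to end; it says nothing about how any real
co-folding model behaves, and the generator does not imitate real error
distributions, partial displacements, or confidence calibration. The
`cdk2_pocket_mimic`/`mek1_pocket_mimic` builders are labelled synthetic
stand-ins: they reproduce published contact-residue identities and author
numbering around an embedded ligand so the mutagenesis bookkeeping can be
checked against published mutation strings, but their geometry is not the
crystal structures'.

`simulate_state_series` is a two-state Markov chain with leave
probabilities (1−p)/dwell and p/dwell, giving stationary bound fraction
exactly p and mean dwell `dwell` frames (default 20); bound frames draw
RMSD uniformly in [0.3, 1.9] Å, unbound in [2.5, 9.0] Å. With dwell = 1
the frames are independent Bernoulli draws, which is what the binomial
recovery checks use.

## Numerical choices and degenerate inputs

- Hydrogens are dropped on read; every criterion is stated on heavy atoms.
- Altloc policy: highest occupancy, tie → first encountered (deterministic
  parsing).
- Coordinates round-trip through PDB at 3 decimals (format precision).
- Empty binding site: challenge application raises; suite building returns
  wild-type only, with a warning.
- Single-replicate aggregation reports sd 0 and sets a flag rather than
  raising.
- All randomness flows from explicit per-call seeds; there is no global
  RNG state, and repeated calls are byte-identical (the PDB writer is
  deterministic).

## Problem sizes

The test suite and the benchmark run on toy complexes of ~28 residues and
ligands of ≤ 35 heavy atoms; the occupancy recovery checks use 100
triplicates of 3 × 600 frames and the exhaustive automorphism oracles stay
at ≤ 12-atom ligands, where brute-force enumeration is trivially complete.
These sizes exercise every code path; nothing in the implementation is
specific to them.

## Known limitations

- Ligand bond perception for arbitrary PDB components without a template
  SMILES is distance-based and order-less; supply `ligand_template` for
  chemistry-sensitive work.
- Side-chain rebuilding after mutation (and new-atom placement in ligand
  editing) is topological, not rotameric; planted clashes are therefore
  plausible but not physically minimized.
- The chain submitted to predictors defaults to all chains present after
  filtering; which chain(s) of a multi-chain entry to submit is exposed as
  `chain_filter` and left to the user.
- Only the three prescribed mutagenesis schemes are implemented; there is
  no optimization-based search for worst-case mutations.
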