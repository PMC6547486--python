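# Methods

## The potential

`andis` implements an atomic, orientation- and distance-dependent
knowledge-based potential for single-model protein quality assessment.
Energies are dimensionless log-odds scores (k_B·T ≡ 1): only rankings
within a decoy set are meaningful.

**Atom typing.** 167 residue-specific heavy-atom types cover the 20
standard amino acids (4 for Gly up to 14 for Trp).  Hydrogens, waters,
hetero-residues, terminal OXT and alternate locations other than
'A'/blank are discarded on input; modified residues (e.g.
selenomethionine) are treated as nonstandard and dropped rather than
remapped.  The canonical (residue, atom) → index table and the ordered
frame-neighbor candidates ship as `src/andis/data/atom_types.tsv`.

**Local frames and the five angles.** Every atom gets a right-handed
orthonormal frame from its first two available bonded-neighbor
candidates: u = n₁ − atom, v = n₂ − atom, Vx = û, Vz = unit(u × v),
Vy = Vz × Vx.  Atoms with a single bonded heavy neighbor use that
neighbor plus its own next bonded atom; backbone N and C at the chain
termini fall back to intra-residue anchors, with the full fallback order
fixed in the shipped table.  An ordered pair (a, b) is described by the
polar/azimuthal angles (θₐ, φₐ) of r_ab in frame a, (θ_b, φ_b) of r_ba in
frame b, and the dihedral χ between the planes (r_ab, Vz(a)) and
(Vz(b), r_ba) about the pair axis, mapped to [0, 360).  χ is invariant
under pair reversal with this convention.  Any fixed orthonormal
convention is self-consistent as long as derivation and scoring share it;
matrices produced by this package are therefore **not** interchangeable
with other implementations of orientation-dependent potentials.

**Binning.** Distances < 15 Å fall into 29 half-open bins: [0, 2.2),
twelve 0.4-Å bins to 7.0 Å, sixteen 0.5-Å bins to 15.0 Å.  Each angle is
split into 12 equal bins (15° polar, 30° azimuth/dihedral); the single
closed boundary θ = 180° maps to bin 11.  Angles are handled in degrees
throughout, matching the degree constants of the shielding formula.

**Pair selection.** Only pairs with residue separation ≥ 7 (positions in
the retained sequence, not author numbering) and r strictly < 15 Å are
observed or scored.  Pairs involving an atom whose frame is unavailable
(missing neighbors, collinear geometry) are skipped and surfaced as a
coverage fraction.

**Effective interactions (shielding).** For each pair, every heavy atom x
strictly within 7 Å of both endpoints is a shielding candidate.  If the
angle α = ∠(a–x–b) exceeds 60° *and* x is ≥ 2 residues from both
endpoints *and* ≥ 7 residues from at least one of them, it contributes a
factor (180 − α)/180; the pair weight is the product of such factors
(1.0 when none qualify, so a fully exposed pair is fully effective;
α = 60° exactly does not shield).  Weights are applied both when
accumulating training counts (weighted mode, the default, recorded in the
matrix header) and when scoring at short cutoffs.

**Angle potential.** For each angle kind, ordered type pair and distance
bin, counts start at a pseudocount of 0.1 per angle bin; both directions
of every unordered pair are accumulated (with θ/φ roles swapped), making
the tensor exactly mirror-symmetric.  With p_obs the smoothed bin
probabilities, the reference is the mean over the 12 bins (p_ref = 1/12),
giving E(s) = −ln(12·p_obs(s)).  Slices observed fewer than 20 times
(unweighted occurrences, even in weighted mode — the threshold is about
statistical sufficiency) are left at zero energy.  The five angles are
treated as conditionally independent given the distance bin, so a pair's
orientation energy is the sum of its five per-angle terms.

**Random-walk pair potential.** The distance-only term uses an ideal
freely-jointed chain as reference: for a protein of length L, the
reference density at distance r is proportional to
(r/r_cut)² · Σ_{n=1..L} exp(−3r²/2nl²)/n^{3/2}, with Kuhn length
l = 3.8 Å by default (the virtual Cα–Cα step; configurable and recorded
in the header) and r_cut fixed at 15 Å, the maximum considered distance.
The density is evaluated at each bin midpoint, multiplied by the bin
width and normalized over the 29 bins, so each protein's expected counts
within r_cut sum to its observed pair total; the expected count for a
type pair is this distribution weighted by the per-protein pair totals.
The normalization makes the reference a proper distribution — a corpus
actually sampled from it derives to E_RW ≈ 0, which the test suite
checks.  E_RW = −ln(N_obs/N_exp), capped at +10; cells with neither
observations nor expectation stay 0.  RW statistics are always
unweighted.

**Scoring.** The cutoff r_cut (7.0–15.0 Å on a 0.5-Å grid, default 15.0)
selects the pair set and the mode:

| r_cut | per-pair score |
|---|---|
| ≤ 9.0 Å | w·E_AG (shielding weights active) |
| 9.5 Å | E_AG (all weights 1) |
| ≥ 10.0 Å | 0.5·E_AG + E_RW |

Short cutoffs favor native recognition, long cutoffs favor decoy
discrimination; the sweep utility enumerates pairs once at 15 Å and
filters per cutoff (bitwise identical to independent scoring).  Totals
are not length-normalized — comparisons are within a decoy set of one
protein; a per-pair normalization flag exists for cross-protein use.
Decoys with missing atoms are scored over the atoms present.

**Metrics.** Native recognition requires the native to be *strictly*
lowest (ties fail).  Z = (⟨E_decoy⟩ − E_native)/σ with the population
standard deviation (n in the denominator; the convention is fixed for
reproducibility).  PCC is the Pearson correlation between decoy energies
and quality scores, native excluded; negative is better.  20% enrichment
uses k = max(1, ⌊0.2·N⌋) and equals |top-k by quality ∩ top-k by
energy|·N/k², so a random ranking gives 1 in expectation and perfect
agreement gives exactly 5 when N is divisible by 5; ranking ties are
broken by stable input order.  Sets with undefined metrics (zero spread)
are reported as undefined and excluded from averages.

## Synthetic data

The generator exists so that every mechanism is testable without
downloading structures.  Chains are built by natural-extension (NeRF)
placement with ideal bond lengths/angles: helix (φ/ψ = −57/−47°),
extended strand (−139/135°), or a helix-turn-helix *hairpin* whose
4-residue turn (φ/ψ = 60/120°, held rigid) packs the two helices against
each other.  The hairpin matters: an isolated ideal helix has no
separation-≥7 pairs below 7 Å, so only a folded topology exercises the
short-cutoff machinery.  Helix torsions carry ±4° uniform jitter by
default; side chains grow along the covalent bond tree with generic
dihedrals (rings are not closed exactly, rotamers are not physical).

Corpora default to a 4-residue alphabet (Ala/Gly/Leu/Ser): a desk-scale
corpus of tens of chains cannot populate statistics resolved over all
167 types the way thousands of experimental chains can, and the
restricted alphabet reaches the 20-observation threshold at a comparable
rate.  Decoys add i.i.d. Gaussian coordinate noise (default levels
0.5–2.5 Å, the range typical decoy ensembles span) and carry the
pseudo-quality score exp(−RMSD/3) in place of a TM-score — the
evaluation metrics only require a monotone quality signal.  RMSD is
computed without superposition since decoys are generated in the
native's frame.

Planted-bias corpora re-pose matching atom pairs onto exactly
constructed target geometries (position + frame realizing prescribed
values of all five angles), putting a chosen angle in a chosen hot bin
with probability 0.9; deriving from such a corpus must recover the hot
bin as the energy minimum.

What passing tests on these fixtures shows — and does not.  They verify
the machinery end to end: geometry against independent oracles,
derivation identities, and that natives drawn from the training
distribution are recognized against noise decoys (short cutoff) while
energies track the quality signal (long cutoff).  They do not show that
a potential derived from synthetic hairpins scores real proteins well:
real side-chain packing, hydrogen bonding, β-sheets and real decoy error
modes are absent.  For production use, derive from a culled experimental
set (the intended scale is thousands of chains, length 30–1000, complete
standard residues only).

## Numerical choices

- Half-open bins everywhere; the single closed boundary is θ = 180° → bin 11.
- Collinearity tolerance for frames: |u × v| < 1e-8·max(|u|, 1).
- Shielder candidates iterate in ascending atom index, so the weight
  product is deterministic; it equals a brute-force triple loop up to
  floating-point associativity.
- Derivation is deterministic and ordering-independent (pure summation);
  no randomness anywhere outside the synthetic generator.
- RW expected counts at bin midpoints; cap +10; Kuhn length recorded in
  the matrix header along with mode, r_cut_ref and tensor checksums
  (matrix format "andis-matrix/1", a NumPy `.npz` with a JSON header
  readable without loading the tensors).
- Pairs exactly at r = r_cut are excluded (strict `<`, consistent with
  the strict 15-Å observation window).

## Known limitations

- Matrices are convention-bound (frame construction, χ sign): never mix
  matrices and scorers from different implementations.
- Single chains only: no symmetry mates, ligands or inter-chain pairs;
  solvent atoms never shield.
- PDB input only (wwPDB v3.3 ATOM records); no mmCIF, no structure
  repair or hydrogen handling.
- The angle potential's conditional-independence assumption over the
  five angles is inherited from the model; no correction is applied.
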