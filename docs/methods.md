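# Methods

This note documents the models behind `rfscreen`, the defaults that matter,
the numerical choices, what the synthetic generators do and do not emulate,
and the known limitations.

## Flexibility statistics

Per-residue flexibility is the crystallographic/model B-factor (Å²).  The
per-residue reduction is the all-atom mean by default (`b_factor_policy =
"ca"` switches to the Cα value); the choice matters only when side-chain and
backbone mobility diverge.  Group means are arithmetic means over member
residues: by secondary-structure class, by surface/buried status, and over
the catalytic shell.  Shell membership is any-atom distance ≤ 5 Å to any
atom of a catalytic residue; the catalytic residues themselves are excluded
from their own shell, since the diagnostic question is whether the
*environment* of the active site is rigid.  Empty groups report NaN, never
zero.  B-factors are taken as given in the input file; for homology models
their provenance (template-copied vs server-assigned) is the user's
responsibility.  Negative B-factors are invalid but occur in the wild; they
are clamped to 0 with a warning so downstream statistics stay non-negative.

## Secondary structure and β-turns

Secondary structure is assigned from backbone torsions alone, which is
deterministic and needs no hydrogens: helix = run of ≥ 4 consecutive
residues with φ ∈ [−90, −30] and ψ ∈ [−77, −17]; sheet = run of ≥ 3 with
φ ∈ [−170, −70] and ψ ∈ [80, 180) ∪ (−180, −170]; everything else —
including residues whose φ or ψ is undefined at chain breaks/termini — is
loop.  This three-class partition is all the screen consumes; it is not a
DSSP replacement (no hydrogen-bond pattern, no 3₁₀/π subtypes).

A β-turn is a window i..i+3 with Cα(i)–Cα(i+3) ≤ 7 Å whose central residues
are not helical.  Typing compares (φ, ψ) of i+1 and i+2 against canonical
values — I: (−60,−30),(−90,0); II: (−60,120),(80,0); I′: (60,30),(90,0);
II′: (60,−120),(−80,0); VIII: (−60,−30),(−120,120) — with a ±30° tolerance,
one angle allowed ±45°; ties resolve in the listed order and non-matching
compact windows are the miscellaneous type IV.  Overlapping windows are all
reported (numbered N→C): merging discrete turns would need an arbitrary
rule and lose information.

Position-specific amino-acid preferences ship as an embedded propensity
table (dimensionless, ~1 = indifferent).  Its qualitative structure follows
classical β-turn statistics — proline dominant at i+1 (2.8, the table
maximum), glycine enriched at i+3, the polar turn-formers Asn/Asp/Ser at
i — and it is overridable from delimited text (`aa  i  i+1  i+2  i+3`) for
users with their own statistics.

## Solvent accessibility

Shrake–Rupley with a deterministic golden-section spiral of 960 points per
atom (no RNG, bit-reproducible), probe radius 1.4 Å, and a fixed internal
vdW table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; unknown
elements fall back to 1.70 Å with a warning).  Relative SASA divides the
residue sum by a fixed per-type maximum-accessibility reference; residues
at ≥ 25% relative SASA are "surface".  The 25% cut is the conventional
surface/buried boundary; it is configurable because no single threshold is
canonical.  Tests check the implementation against an independent
latitude–longitude quadrature oracle (different point set, sin θ area
weights); at the default resolutions the two agree within 2% on peptide
totals, with a few percent of discretization noise on individual small
residues.

## The filter chain

Filters are pure predicates evaluated per substitution and AND-ed, so the
chain is order-independent by construction.  Defaults and their reasoning:

- ΔΔG ≤ −0.5 kJ/mol, boundary inclusive.  ΔΔG predictions carry roughly
  0.5 kJ/mol of calculation error, so only substitutions predicted
  stabilizing beyond that margin are kept.  The table loader validates
  wild-type identities against the structure, rejects duplicate
  (position, substitution) rows, and converts kcal/mol on request
  (1 kcal = 4.184 kJ).  `aggregate_residue_ddg` offers residue-level
  summaries (min over substitutions by default — the most stabilizing
  achievable at the position — or mean), for excluding positions that are
  destabilizing however mutated.
- Minimum mean catalytic distance 13 Å.  Mutations near the active site
  trade activity for stability; rejected controls in practice sit around
  10–12 Å while accepted sites lie farther, so the default brackets that
  evidence and is configurable.  For turn members the distance is the
  turn's mean over its four Cα to all catalytic Cα; for non-turn positions,
  the residue's own mean.
- Conservation veto at 80%.  Conservation is identity-to-query: the
  fraction of non-gap homologs carrying the wild-type residue at the
  column.  Mutating a position conserved across already-thermostable
  homologs works against natural selection; positions below ~50% are safe,
  ≥ 92% clearly vetoed, and 0.80 splits those brackets.  Positions without
  alignment data cannot be vetoed.
- Ranking: weighted sum (equal weights by default) of z-scored B-factor,
  −ΔΔG, catalytic distance and turn propensity; ties break by lower ΔΔG,
  then higher B-factor, then N→C position.  Z-statistics default to the
  ranked set; `rank_candidates(..., norms=...)` freezes them, which makes
  the score exactly monotone in each feature — with re-estimated
  statistics an extreme value can shrink the spread faster than its own
  deviation, so monotonicity is only guaranteed under fixed normalization.

## Ensemble analytics

Superposition is least-squares (Kabsch; proper rotation enforced).  RMSF
and DCCM use deviations from a converged mean structure: frames are fitted
to the running mean until the mean shifts < 1e-6 Å, capped at 20 iterations
for determinism.  The fit selection can differ from the analysis selection;
fitting on a static subset gives the superposition-neutral behaviour that
the closed-form fixtures (single displaced atom → RMSD d/√n; ±a oscillation
→ RMSF a) require, because a fit that includes the moving atoms absorbs
part of their motion — a genuine property of RMSF on short mobile systems,
not an artifact.

Hydrogen bonds are geometric: donor–acceptor (N/O to N/O) distance ≤ 3.5 Å
and D–H⋯A angle ≥ 120°.  The backbone amide H is reconstructed from N, Cα
and the preceding C (1.01 Å, opposite the bisector) when absent; donors
with no usable hydrogen (chain-terminal N, hydroxyl side chains without
explicit H) fall back to the distance criterion alone and are flagged
`distance_only`.  Intra-residue pairs and the covalent N(i)→O(i−1) peptide
pair are excluded.  The 120° angle is the operative criterion for calling a
bond absent in bent geometries; 3.5 Å is the conventional heavy-atom cut.

Salt bridges pair side-chain carboxylate O (Asp/Glu) with side-chain N
(Arg/Lys/His); a frame counts when the minimum O⋯N distance ≤ 4.0 Å
(configurable — reported occupancies are sensitive to this convention), and
occupancy = frames present / total frames.  The per-frame minimum-distance
series is retained so contact tightening can be reported alongside
occupancy.

Constraint-network analysis is ingested, not computed: the pebble-game
rigidity decomposition belongs to the upstream CNA method, and this package
consumes its P∞(E_cut) output.  A series must be strictly decreasing in
E_cut; the transition is the point where the largest single-step P∞ drop
lands (ties favour the larger, less negative E_cut), and temperature is the
affine map T = −20·E_cut + 300 (E_cut in kcal/mol, T in K).

## Kinetics

Michaelis–Menten and single-exponential decay are fitted by bounded
nonlinear least squares (positive parameters; xtol 1e-8).  Initialization:
V_max⁰ = max(v), K_m⁰ = substrate at half-max (interpolated); decay starts
from the log-linear slope.  Flat velocity data drives K_m to its zero bound
and is flagged non-identifiable; flat decay data raises "no decay detected"
rather than reporting an infinite half-life; non-positive activities are
excluded with a warning (they carry no information for a log-scale decay
and usually mark assay floor effects).  The decay model is fixed
single-exponential: half-lives reported as t₁/₂ = ln2/k presuppose
first-order inactivation.  k_cat is treated as an input (or V_max
surrogate); converting specific activity to k_cat needs molar mass and
active-site normalization that assay tables do not carry.

A design caveat worth knowing: over the standard 1–10 mg/mL substrate
ladder with K_m ≈ 5.5 mg/mL, homoscedastic noise of 2% of V_max leaves
little information about K_m — the Cramér–Rao bound puts the best
achievable median relative error near 8.5%, and the fit tracks that floor.
Under constant-CV noise (2% of each observation, the usual behaviour of
activity assays and the generator's default) the bound drops to ~2.8% and
recovery within 5% is routine.  Tests assert both regimes.

## Synthetic data

Generators are deterministic under (spec, seed); all randomness flows
through one integer-seeded `numpy` Generator.

- Peptides are built by internal-coordinate (NeRF) placement with ideal
  bond lengths/angles (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; 111.2°,
  116.2°, 121.7°; ω = 180°), segment-wise (φ, ψ) (helix −57/−47, strand
  −120/130, canonical turn torsions; the type-IV plant uses a compact
  non-canonical pair), coordinates rounded to PDB precision so round-trips
  are exact.  A turn segment contributes the two central residues; the
  planted window spans the flanking residues, and the generator verifies
  the window geometrically.  The planted truth enumerates *every*
  qualifying window under the planted torsions (overlapping windows are
  reported by design), with the expected secondary-structure labels derived
  by applying the torsion-window run rules to the planted angles.
  Side chains are minimal: Cβ everywhere except Gly, full side chains only
  where analyses need them (Asp/Glu/Arg/Lys for salt bridges), idealized
  extended geometry.
- Ensembles displace each residue rigidly per frame by an isotropic
  Gaussian scaled so the planted RMSF equals the requested σ; correlated
  blocks share one latent vector with ±1 signs (in-/anti-phase).  Bond
  plants are enforced geometrically after displacement sampling — the
  relevant atoms are moved inside/outside the criterion in exactly the
  listed frames — so occupancy recovery is an exact count, not a
  probability.  In absent frames the acceptor keeps its natural position
  (pushed out only if a random displacement strays into range), because a
  fixed park position can collide with unrelated donors.
- MSAs set each homolog column to the query residue in exactly the
  requested count of homologs; ΔΔG tables draw planted-stable entries at
  ≤ −0.5 kJ/mol and the rest above; assay tables add seeded noise to the
  exact model.
- `build_screen_fixture` assembles a full screening problem and recounts
  the expected pass set with plain loops from the planted facts,
  independently of the filter-chain implementation.

What the generators do *not* emulate: real conformational ensembles
(no physical dynamics, no correlated backbone relaxation), rotamer
distributions, crystallographic artifacts (anisotropic B, occupancy
disorder beyond alt-locs), alignment gaps from true indel histories, or
epistasis in ΔΔG tables.  Passing plant-and-recover tests therefore
demonstrates that the analytics compute their definitions correctly, not
that the screen's thresholds are optimal for any particular real protein.

## Problem sizes in the shipped tests

The suite exercises 20 SASA fixtures against the quadrature oracle, 100
random turn fixtures, 50 screen fixtures, 500-frame ensembles for
RMSF/DCCM recovery, a 900-frame occupancy plant, and 200-seed kinetics
recovery — sizes chosen so plant-and-recover statistics are stable while
the full suite stays fast.

## Known limitations

- PDB only (fixed-column, plain or gzipped); no mmCIF.
- The conservation veto maps query positions by residue number; it assumes
  the MSA query matches the structure's author numbering from 1 without
  insertion codes.  For structures with offset numbering, supply the
  profile positions accordingly.
- Torsion-window secondary structure misclassifies irregular helices that
  DSSP would accept; only the 3-class partition is supported.
- Hydrogen-bond detection is O(donors × acceptors) per frame — fine for
  peptides and single proteins, not optimized for very large complexes.
- The CNA temperature map is linear by construction and only as good as
  the ingested P∞ series.
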