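# Methods

This note documents the models, conventions and numerical choices behind
`fameshell`, and what its synthetic fixtures do and do not establish about
real molecular-dynamics data.

## Quantities and conventions

**First hydration shell (N_w).**  A water molecule belongs to the chain's
first shell when its oxygen lies strictly within `water_cutoff` = 3.15 Å of
at least one peptide solute atom.  The solute side uses heavy atoms only
(`solute_atoms="heavy"`): the contact definition below is phrased in heavy
atoms, and including hydrogens would change absolute counts without
changing trends.  Both choices are switchable (`counting_atom=
"any_water_atom"`, `solute_atoms="all"`) for sensitivity checks.  Each
water counts at most once per chain; per-residue shells may overlap, so a
water equidistant from two residues counts once for each, and the
per-residue sum is an upper bound on the chain count.  The lipid is not
part of the "peptide chain" for N_w by default (`include_lipid=True`
includes it); lipid–peptide contacts are available separately through
`count_role_contacts`.

**Intrachain contacts (N_pp).**  Two peptide residues are in contact when
at least one heavy-atom pair is strictly within `contact_cutoff` = 6 Å and
their sequence separation is ≥ `min_sequence_separation` = 3 — bonded and
near-bonded neighbors are always within 6 Å and would only add a constant.
Counting is per residue pair by default; an atom-pair mode
(`contact_mode="atom_pairs"`) is exposed because either reading of
"contacts between residues" is defensible.

**Boundary convention.**  All cutoff predicates compare *squared* distances
with strict `<`.  This matters only on measure-zero inputs but makes the
behavior of exactly-on-boundary fixtures deterministic.

**Periodic boundaries.**  Orthorhombic boxes only; minimum-image distances
are valid only when the cutoff is below half the smallest box edge, and a
violation is a hard error rather than a silent wrong answer.  The
accelerated search is a `scipy.spatial.cKDTree` (periodic where boxed) with
a strict squared-distance confirmation pass; an O(N·M) brute-force path is
kept in the package as an oracle (`method="brute"`), and the test suite
additionally checks both against a from-definition recount written
independently in the tests.

**Units and indexing.**  Coordinates are Å internally (GRO nm are converted
on I/O); residue indices are 0-based internally and 1-based in every
emitted table.  Since PDB/GRO/XYZ cannot carry role labels or per-frame
temperature, `write_trajectory` emits a JSON sidecar
(`<file>.meta.json`) with residue roles and frame metadata that
`read_structure` restores; without it, roles default to `other` and
`assign_roles` applies name-based rules (common water names → water,
MYR → lipid, amino acids → peptide) with the lipidation-site/ELP boundary
set positionally (first 20 peptide residues by default), because residue
names cannot distinguish the two.

## The dewetting hydropathy scale

The protocol being analyzed: take a chain equilibrated at temperature
T_MD together with its first-shell waters, restrain the solute, and heat
the box from 250 K to 400 K at 1 K per 20 ps (3 ns); strongly
water-interacting residues keep their shell to higher dewetting
temperature T_dw.  `AnnealingSchedule` encodes and validates this
arithmetic ((t_final − t_initial)/rate = duration at 1e-9 relative
tolerance).

From per-T_dw trajectories, `occupancy_matrix` averages per-residue shell
counts over the trailing `window` fraction of frames (1.0 for the
stationary synthetic annealing fixtures; 0.25 is the convention used for
equilibrium trajectories, mirroring analysis of the final quarter of a
run) and normalizes each row by its count at the lowest grid temperature.
Per-residue normalization, rather than absolute counts, compensates for
shell-size differences between small and bulky residues; an absolute mode
remains available through the raw matrix.  Residues with fewer than
`min_baseline` = 1.0 waters at baseline are flagged: a residue that is
essentially dry at 250 K (buried, or the lipid itself) cannot meaningfully
"dewet", and flagged residues are excluded from all percentages.

A residue's dewetting temperature is the first grid temperature at which
normalized occupancy drops below θ, refined by linear interpolation
between the bracketing grid points (e.g. a row falling from 1.0 at 300 K
to 0.4 at 320 K crosses θ = 0.5 at 316.7 K).  θ = 0.5 — the midpoint of a
logistic decay — defines "dewetted" here; the threshold is configurable
since any fixed fraction gives the same ordering of residues.  Rows that
never cross θ return a sentinel that maps to hydropathy score 1.0 (rather
than NaN) so downstream tables stay dense.  The hydropathy score is the
linear rescaling (T_dw,res − 250)/(400 − 250), clipped to [0, 1]; higher
means more hydrophilic.  `percent_dehydrated_curve` reports, per T_dw, the
percentage of unflagged residues below θ, and `assemble_dewetting_map`
stacks per-T_MD curves into the (T_MD, T_dw) grid used for contour plots.

## Temperature trends

Chain-level N_w and N_pp grow with construct length, so
`normalize_series` divides per-temperature means by the number of peptide
residues (lipidation site + His tag + ELP; a pentad-only denominator can
be had by passing that count instead).  `fit_linear_trend` is ordinary
least squares with the slope CI from the t distribution with n − 2
degrees of freedom at 90 % two-sided coverage; supplying per-point
standard deviations and frame counts switches to WLS with weights
1/se².  Unweighted OLS is the default because the per-point error
structure of real trajectory averages (autocorrelation) is not modeled.
`confidence_band` emits the pointwise regression-line band from the
standard variance formula.

## Synthetic data: what it emulates, and what it does not

The generators produce coordinate data with the *statistical* structure
the analysis assumes — they are explicitly not a force field, and passing
tests on them validates the measurement pipeline, not any physical claim
about real FAMEs.

**Topology** (`build_fame_topology`): backbone N/CA/C/O per residue from
ideal internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å;
angles 111°/117°/121°; ω = 180°), one pseudo-CB per non-Gly residue, and
an optional 14-bead zigzag acyl chain at the N terminus.  The default
conformation is a jittered extended chain (Φ ≈ −140°, Ψ ≈ 140°,
σ = 10°), deterministic in the seed.

**Hydration frames** (`simulate_hydration_frames`): per-residue shell
counts are Poisson with mean `baseline·1/(1 + exp((T − T50)/w))` — counts
are non-negative integers and Poisson variance scales with the mean,
which is the natural noise model absent any stated one.  Each shell water
is placed uniformly in the spherical shell r ∈ [2.4, 3.15) Å around a
random heavy atom of its residue (the 2.4 Å inner radius keeps waters off
the solute; any value below the cutoff would do) and *rejected* if it
falls within the cutoff of any other peptide residue's heavy atoms, using
the same minimum-image geometry as the counters.  Bulk waters are placed
at least cutoff + 1 Å from all solute heavy atoms.  Placement therefore
guarantees that an independent recount reproduces the drawn ground truth
exactly, frame by frame — the generator/counter cross-oracle the tests
rely on.  Bounded retries (200 rounds) convert infeasible geometry into
an explicit generation error.  The solute is rigid across an annealing
series, mirroring the position restraints of the protocol.  Waters are
O-only by default (a documented dialect; 3-atom waters are available, with
ground-truth guarantees stated for oxygen counting).

**Temperature scans** (`simulate_temperature_scan`): per frame, target
counts are `round(intercept + slope·T + N(0, noise_sd))`, clipped at
zero.  Contacts are realized geometrically: residues sit on a dilated
lattice (14 Å spacing — no baseline contacts), and for each of k disjoint
residue pairs (sequence separation ≥ 3) one partner is translated to
4.5 Å from the other, with rejection against incidental contacts and a
brute-force verification that exactly k contacts exist.  Using disjoint
pairs caps realizable N_pp at ⌊n/2⌋ per frame; models exceeding that
capacity (including a 5σ noise margin) are rejected with an argument
error.  This realization is a statistical stand-in: real contact networks
are not disjoint pairings, but the recounted means follow the planted
linear model exactly in the noiseless case, which is the property the
trend-fitting stage needs.

**Dihedral ensembles** (`simulate_dihedral_ensemble`): (Φ, Ψ) are drawn
per residue per frame from von Mises distributions of concentration κ
centered at α_R (−75°, −50°), β (−120°, 130°) or α_L (60°, 40°), or
uniformly for coil; chains are rebuilt each frame by the internal-
coordinate builder, so measured dihedrals reproduce the drawn angles to
machine precision (the cross-oracle tolerance of 1e-3° is generous).

**Not emulated:** solvent structure beyond shell membership, water–water
interactions, hydrogen-bond geometry, excluded volume between waters,
equilibration transients within an annealing window (occupancy is sampled
stationary per T_dw), chain dynamics, and any force-field energetics.
Conclusions about real FAMEs require real trajectories; this package then
provides the measurement layer.

## Ramachandran conventions

Φ(i) = C(i−1)–N(i)–CA(i)–C(i), Ψ(i) = N(i)–CA(i)–C(i)–N(i+1), IUPAC
signs, range (−180°, 180°]; only interior residues (having both angles)
enter the series.  The α_R box is Φ ∈ [−100°, −50°], Ψ ∈ [−70°, −30°];
the β and α_L boxes follow common Ramachandran practice and all boxes are
closed at both ends, user-overridable, with interior disjointness
enforced at load.  Hard boxes operationalize what are physically soft
boundaries; occupancy fractions per residue always sum to 1 because
"other" is the complement.

## Composition

The hydrophilic fraction is operationalized as a **mass** fraction:
f = m_peptide/(m_peptide + m_lipid), with average-isotope masses by
default (monoisotopic available).  The default lipid contribution is the
myristoyl acyl group C14H26O (myristic acid minus the water lost on amide
formation, 210.36 Da average), and the peptide head includes the
lipidation site and His tag.  The construct's N-terminal Met is excluded
(removed upon myristoylation of the following Gly).  On this basis
myr-V20 gives f = 0.9805.  A residue-volume basis (e.g. Zamyatnin
volumes) would be a reasonable alternative; mass is used because it needs
no partial-volume table and the difference is far below the precision at
which f is quoted.

## Problem sizes and determinism

Every generator and the pipeline funnel all randomness through one
`numpy.random.SeedSequence`-derived stream per run, so a fixed
(config, seed) pair reproduces byte-identical numeric outputs; the
manifest records parameters and per-file SHA-256 checksums.  The test and
acceptance workloads use desk-scale sizes chosen to make the statistical
assertions sharp while staying quick: 25–50-residue chains, 10–25 K
dewetting grids with 100–200 frames per temperature, 6-temperature scans
with 100 frames each, 500-replicate CI-coverage simulations, and 100
random systems of up to 500 atoms for the neighbor-search equivalence
check.

## Known limitations

* Only orthorhombic boxes; triclinic input is rejected.
* Binary trajectory formats (DCD/XTC) are not read; PDB (multi-MODEL),
  GRO and an extended XYZ dialect (per-frame `T=<K> t=<ps>` comment) are.
* The XYZ reader recovers geometry and frame metadata but not residue
  topology (one residue per atom) unless a sidecar is present.
* N_pp ignores hydrogens by construction; there is no SASA or
  hydrogen-bond criterion.
* The dewetting analysis consumes (real or synthetic) annealing
  trajectories; it does not run restrained MD.
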