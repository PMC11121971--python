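# Methods

This note records the models, conventions and numerical choices behind
`oligodeg`, in the spirit of a statistics/chemistry package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structures

Oligomers are treated as strictly alternating chains of acyl (diacid)
and hydroxy/amino (diol, polyol, diamine) units. The builder performs a
formal polycondensation: fragments are concatenated so that each
junction is an ester `C(=O)O` (or amide `C(=O)N`) bond, eliminating one
water per bond; terminal acyl units keep a free carboxylic acid (methyl
esters on request, +14.027 g/mol per capped end) and terminal
diols a free primary hydroxyl.

Regiochemistry follows lipase (CaLB) selectivity for primary hydroxyls:
glycerol reacts through its 1,3-positions (secondary OH free) and
erythritol through its two terminal CH2OH groups. Stereocentres are left
unspecified — the recorded tetramer strings carry none. Structure
equality is always canonical-graph equality (RDKit canonical SMILES,
stereo stripped by default), never string comparison, because the same
chain can be written from either end. Eleven of the twelve recorded
tetramer SMILES are reproduced exactly; the oligoamide record ends in a
primary amide rather than the free acid/amine a condensation of the
stated units yields, so the builder intentionally disagrees with that
one string and the fixture keeps the printed form.

Mass balance is an invariant: `avg_mass = Σ unit masses − (n−1)·18.015`
(±0.01) for free-ended chains, amide or ester alike.

## MIF descriptor engine

A single low-energy conformer per molecule is generated by distance
geometry (ETKDGv3, seeded, hence deterministic) and relaxed with MMFF94
(UFF fallback). Partial charges are Gasteiger–Marsili (iterative
electronegativity equalisation). A conformer ensemble is deliberately
not used: the descriptors aim at rank-ordering molecular polarity
patterns, and a seeded single conformer keeps the whole pipeline
reproducible; the seed is exposed everywhere. The consequence — visible
in the acceptance output — is that multivariate statistics downstream
depend noticeably on the conformer seed for these highly flexible
chains; this is a property of single-conformer MIF descriptors, not a
bug.

**Canonical frame.** Before gridding, the conformer is moved to its
mass-weighted principal-axes frame (largest spread first, axis signs
fixed by the third-moment rule with a largest-coordinate fallback,
third axis right-handed so chirality is preserved). All grid and
surface descriptors are computed in this frame, which makes them
invariant under rigid motion of the input coordinates to machine
precision — the property tests assert a 2 % bound, and measure
~1e-14 — except for exactly degenerate inertia tensors, where the frame
is arbitrary but the molecule is correspondingly symmetric.

**Fields.** The grid covers the molecule's bounding box plus a 5 Å
margin at 0.5 Å spacing by default (1 Å in the large property-test
batches; spacings above 1 Å are refused). The probe–molecule energy at
a node is a sum over atoms of

* Lennard-Jones 12-6 with `ε_pair = √(ε_probe·ε_atom)` and
  `r_min = r_vdw,probe + r_vdw,atom`,
* Coulomb with distance-dependent dielectric (ε = 4r) for charged
  probes,
* a 12-10 hydrogen-bond term between complementary donor/acceptor
  partners (probe donors see N/O acceptors; probe acceptors see N/O
  atoms carrying H).

The DRY probe is the hydrophobic formulation: dispersion only, no
electrostatics, no hydrogen bonding. Energies are clamped to
[−30, +5] kcal/mol and distances floored at 0.5 Å so clash nodes stay
finite. Probe parameters (well depth, radius, charge, H-bond strength
and optimum distance) are GRID-like literature magnitudes shipped as an
editable table; no numerical equality with any commercial engine is
claimed or checked.

**Descriptors.** Hydrophilic volumes W1–W8 count water-probe nodes at
or below −0.2, −0.5, −1, −2, −3, −4, −5, −6 kcal/mol (the conventional
ladder for water-probe volume descriptors) times the voxel volume;
capacity factors are CWk = Wk/S; integy moments IW1–IW4 are the
distances from the centre of mass to the |E|-weighted barycentre of the
first four level sets (zero for empty sets). The total surface S is the
solvent-accessible surface from an in-package Shrake–Rupley dot method
(golden-spiral mesh, 960 dots per atom, probe radius 1.4 Å); PSA is the
summed contribution of N, O and their attached hydrogens, HSA = S − PSA,
so PSA + HSA = S exactly. An isolated atom reproduces the sphere closed
form 4π(r+1.4)² within 1 % at this dot density. logP is the Crippen
atomic-additive estimate; MpKaA comes from a four-rule table
(carboxylic acid 4.4, phenol 10.0, alcohol 15.5, amide N–H 16.5,
sentinel 20.0 when nothing matches). EMDIF is the signed difference
*polar minus apolar* between the deepest polar-probe (OH2/O/N1) and
deepest DRY node energies; EMDIS the distance between the atoms nearest
those two nodes; both are zero when either minimum is weaker than
−0.2 kcal/mol. The EMDIF sign convention is declared here because
published descriptions leave it open.

The 18 modelling descriptors are, in fixed column order: IW1–IW4,
CW1–CW8, logP, PSA, HSA, MpKaA, EMDIF, EMDIS. The wider VolSurf-style
set (hydrophobic volumes D1–D8, ADME predictors such as CACO2, MetStab,
PB, VD, LgBB, SKIN) is *not* implemented; the ADME names exist only in
the default pretreatment exclusion list.

## Chemometrics

Pretreatment drops columns with variance ≤ 1e-12 and columns named in
the exclusion list; it refuses to drop everything. Autoscaling (unit
variance) is the default for PCA and PLS — the source analysis does not
state its scaling, and autoscaling is the standard choice for
descriptors in mixed units; `center_only` is available.

PCA is computed by SVD of the scaled matrix; explained percentages come
from squared singular values; the largest-magnitude loading of each
component is forced positive so scores are reproducible under row
permutation. K-means is best-of-`n_init` Lloyd iterations
(scikit-learn), seeded.

PLS is a univariate NIPALS implementation with coefficients
back-transformed to the original descriptor scale; at full rank it
coincides with ordinary least squares (the tests check agreement with a
normal-equations oracle at 1e-8, and with scikit-learn's NIPALS as an
independent implementation). Leave-one-out Q² refits the entire model —
including the scaling — without each sample; Q² = 1 − PRESS/TSS with
TSS from the full response. Q² may be negative and is reported as
computed. Forward feature selection greedily adds the column that
maximises LOO Q² until the improvement is below a tolerance; the
packaged 18-name explicit list is the default reproduction path because
the original selection procedure is unspecified.

In the tetramer workflow the nitrogen-containing oligoamide is excluded
before PLS by explicit identifier — the published design treats it as
the PCA outlier — rather than by automated outlier detection. Among the
remaining eleven esters every molecule carries a free carboxylic acid,
so MpKaA is constant and pretreatment removes it: the regression runs
on 17 descriptors, and the run report says so. Whether the oligoamide
forms a singleton K-means cluster with the in-house descriptors is
recorded in the report as an observation, not asserted: with a
functional-analogue descriptor engine the cluster topology need not
match the published one.

## Respirometry and mass arithmetic

ThOD uses the ammonia rule (no nitrification):
`mol O₂ = c + h/4 − o/2 − 3n/4`, clamped at zero, over the average
molecular weight; only C/H/O/N formulas are accepted. Blank correction
subtracts the inoculum-only series pointwise, clamped at zero.
`Dt(t) = 100·BOD(t)/(ThOD·conc)`; the day-5/10/21 read-outs take the
nearest recorded time within half a day and report missing days rather
than interpolate. The test-substance concentration defaults to
100 mg/L: it is not printed in the source tables but is uniquely
implied by the Dt = BOD/ThOD consistency of the large majority of rows,
and it is exposed as a configuration value. The packaged printed ThOD
values are treated as authoritative inputs; the stoichiometric formula
path exists alongside and several printed monomer ThOD values disagree
with it — the tool never silently substitutes one for the other.

Mass summaries treat abundances as the Nᵢ of the defining sums and
`Mᵢ = m/z − adduct mass` (neutral oligomer mass). Average masses are
the default convention (unit-resolution ion trap); monoisotopic by
flag. The dispersity audit uses truncation (floor) to two decimals,
the convention under which the printed dispersity table is internally
consistent for nine of its eleven rows; the two inconsistent rows are
flagged, not corrected. Adduct ladders are predicted arithmetically for
binary (one acid, one diol) alternating series; for odd chain lengths
the acyl-rich split is used. Multi-species (terpolymer) ladders are a
known limitation. The recorded 475/685 Th co-oligoester peaks match a
single-methyl-ester-ended Na⁺ ladder within 1 Th; the recorded 899 Th
peak lies ~3 Th above the predicted octamer and is left unexplained.

## Synthetic data

The generators are pure functions of (config, seed). The planted
regression design builds its informative factors mutually orthogonal,
orthogonal to the intercept and to the correlated nuisance block, which
makes "noise-free data are fitted exactly with k latent variables" a
theorem of the construction (the Krylov space of the PLS algorithm has
dimension k) rather than a numerical accident. Default conditions —
n = 100 samples, 18 descriptor-like columns, 5 informative, 5 %
relative noise — mirror the dimensionality of the descriptor stage.
BOD curves are first-order uptake with a lag
(`BOD ∝ 1 − exp(−k·(t−lag))`) plus a blank offset and Gaussian noise —
the simplest family consistent with the reported respirometry profiles;
it is a stand-in, and real curves' microbial dynamics (adaptation,
diauxie, inoculum differences) are outside its scope, so passing tests
demonstrate estimator correctness, not biological realism. Flory peak
lists follow the most-probable chain-length distribution (weight
fraction `n·p^(n−1)·(1−p)²` by default, number fraction selectable)
truncated at `n_max`, with truth Mn/Mw computed by direct summation
over the truncated distribution in the generator, independent of the
spectrum summariser they test. The random small-molecule generator
produces seeded CHON chains with branches and carbonyls — enough
variety to exercise every descriptor code path, with no claim of
covering drug-like chemical space.

## Problem sizes and determinism

Default problem sizes: descriptor grids at 0.5 Å for the twelve
tetramers (the full workflow completes in well under a minute on one
CPU); the large property batches use 1 Å spacing and 1,000 random
molecules; permutation nulls use 100 permutations; Monte-Carlo checks
50 seeds. Every stochastic step takes an explicit seed, and repeated
runs with the same configuration produce byte-identical reports (the
run-report test asserts JSON equality).

## Known limitations

* Single-conformer descriptors make downstream statistics
  seed-sensitive for flexible chains (documented above, visible in the
  acceptance output).
* The MIF engine is a functional analogue of grid-based commercial
  engines, not a reimplementation; absolute descriptor values are not
  comparable across engines, only the workflow is.
* The twelve-molecule dataset is tiny by QSPR standards; LOO Q² on it
  has large variance, which is precisely why the acceptance checks rely
  on planted-truth calibration rather than on reproducing the published
  R²/Q².
* No cyclic oligomers, no polymerisation kinetics, no charge states
  beyond +1 in the MS arithmetic, no regulatory pass/fail
  classification.
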