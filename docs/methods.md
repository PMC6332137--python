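# Methods

## The survey model

The object of study is the MTPA-amide moiety
CF₃–C*(OMe)(Ph)–C(=O)–N(R^sp)(R^ap): a quaternary stereocenter C2 bearing a
trifluoromethyl carbon (C3), a methoxy oxygen (O2, methyl C4), a phenyl ipso
carbon (C5), and the amide carbonyl (C1, O1, N). Seven torsion angles
describe one moiety's conformation (see the README table). Each crystal
structure may contain several moieties — distinct conformers in one lattice,
or several MTPA arms on one molecule — and each is processed as an
independent record.

Because the survey aggregates both acid enantiomers, every S-acid record is
replaced by its mirror image before any statistic is computed: all torsions
change sign (with +180° its own fixed point under the (−180°, +180°]
convention), and the record is thereafter treated as R-acid. This
normalization is idempotent and commutes with every classification the
package performs; the end-to-end mirror theorem (structure vs. its point
inversion) is asserted over randomized generator output rather than assumed.

## Torsion conventions and selection rules

Torsions use the Klyne–Prelog sign convention: looking from the second axis
atom toward the third, clockwise rotation of the far bond is positive. The
implementation is the two-normal atan2 form; an independent
projection-onto-normal-plane formulation is kept in the test suite as an
oracle and the two agree to 1×10⁻⁹ degrees on random quadruples. A computed
value of exactly −180° is reported as +180°.

Two descriptors need an atom-selection convention:

- **F3** is the CF₃ fluorine antiperiplanar to the carbonyl carbon, found as
  the fluorine maximizing |C1–C2–C3–F|. For any near-tetrahedral CF₃ this
  guarantees |τ_F| ≥ 120°. A tie within 0.01° is broken by atom-label order
  and logged.
- **C10** is the phenyl ortho carbon minimizing |O2–C2–C5–C|, guaranteeing
  |θ²| ≤ 90°; a tie at exactly ±90° picks the positive torsion.

The two N-substituents other than the acyl carbon are lateralized by the
magnitude of their X–N–C1–O1 torsion: |τ| ≤ 90° is the *sp* side (its alpha
atom is C1′), the other is *ap* (alpha atom X1′′; an N–H hydrogen leaves
X1′′ null, so τ_ap is only defined for tertiary amides). Torsions in
[80°, 100°] are accepted with a logged warning; two substituents on the same
side (a strongly pyramidal nitrogen) raise an error listing both torsions
instead of guessing.

## Stereodescriptor at C2

The four substituents of C2 are fixed by the substructure itself, and their
CIP priorities are decided in the first sphere: O2 (oxygen) > C3 (C bonded
to F,F,F) > C1 (C bonded to O,O,N) > C5 (C bonded to C,C,C). The descriptor
is the sign of the scalar triple product of the bond vectors to the three
highest priorities (negative determinant = clockwise 1→2→3 sweep viewed with
C5 pointing away = R). The sign-to-descriptor mapping was frozen against a
hand-built reference tetrahedron, and is cross-checked in the tests against
RDKit's 3-D stereo perception on generator output. No general CIP engine is
implemented — the substructure makes one unnecessary.

## Substituent classes and Z/E forms

Alpha atoms of the N-substituents are classified by branching: H; then
methyl / primary / secondary / tertiary alkyl by the alpha carbon's count of
heavy non-N neighbors (0/1/2/3); carbons inside a six-membered carbocycle
are `aryl`; non-carbon alpha atoms map to element-keyed classes. The amide
is **Z** when the *sp*-side class outranks the *ap* side and **E** for the
reverse. Within the alkyl/H series rank is branching order; outside it, two
classes compare by the atomic number of their alpha atoms, and anything
unresolved (equal rank, or a special carbon class against an alkyl) is
reported `indeterminate` rather than guessed. This reproduces the survey's
tallies — 13 Z : 4 E (9 indeterminate) over the 26 tertiary amides, and all
14 secondary amides from primary amines Z — without a priority engine.

## Statistics

Central statistics are plain arithmetic means and medians (even n: midpoint
of the central pair), not von-Mises estimators: the survey's printed values
are consistent with branch-shifted ordinary statistics, which are simpler
and auditable. The two seam-straddling descriptors (τ_F, τ_ap concentrate
near ±180°) are shifted to the contiguous branch (−360°, 0°] before
averaging and the result re-wrapped for reporting. Windowed means use fixed
windows — θ¹ in (−30°, 0°], θ² in [0°, +50°], τ_OMe in [+30°, +80°] — chosen
once to reproduce the survey memberships 48/53/52; no tabulated value sits
on a boundary, so the open/closed choices are conventional. Excluded rows
are listed by row number, never silently dropped; nullable descriptors are
dropped from their own statistics with n recorded, never imputed.

Histograms use 10° bins, left-open/right-closed, aligned to 0° (a value of
exactly 0 falls in (−10°, 0°]), on the shifted branch for the seam
descriptors.

The "as-printed" panel rounds medians to one decimal where the survey prints
one (−14.5, +0.8) and otherwise to the nearest degree, ties away from zero;
full precision is retained alongside in the JSON report.

Two survey ambiguities are resolved as explicit defaults with toggles: the
sulfonamide row whose C1′ column stores an S–N–C1–O1 angle stays in the
amide-planarity statistics (dropping it moves the printed +0.8 median to
+0.5, covered by a test), and the *ap*-side median uses all 52 non-null
values.

## Bond perception

Atoms bond when their distance is at most r_cov(i) + r_cov(j) + 0.40 Å
(Cordero-style covalent radii), with bonds to hydrogen capped at 1.3 Å;
distances under 0.5 Å are an error. Only asymmetric-unit atoms are used —
no symmetry expansion — so moieties completed by symmetry operators are out
of scope and documented as such rather than silently wrong.

When a deposited structure omits riding hydrogens, a methine H on a
three-heavy-neighbor sp³ alpha carbon is inferred at 1.09 Å along the
negative vector sum of the heavy-neighbor unit vectors and the resulting
τ_H flagged `inferred`; planar (aryl) alpha carbons never receive an
inferred H.

## The synthetic generator

`mtpaconf.synth` places atoms sequentially from internal coordinates (bond
length, bond angle, torsion from three placed atoms — the NeRF scheme), so
every requested torsion target is met exactly by construction; standard
values are used elsewhere (C–C 1.53 Å, C=O 1.23 Å, C–N(amide) 1.34 Å,
C–F 1.34 Å, C–O 1.42 Å, aromatic C–C 1.39 Å, tetrahedral 109.47°, trigonal
120°). τ_F is imposed by rotating the whole CF₃ so the designated fluorine
hits the target with the other two trailing at ±120°. S enantiomers mirror
the finished R build, so their raw torsions are the negatives of the
targets. The molecule is centered in a 20 Å orthorhombic P1 box and written
as fractional coordinates.

Template notes: the cyclic-secondary-amine template is 2-methylpyrrolidine
(an unsubstituted pyrrolidine would have two primary-alkyl alpha carbons and
an indeterminate amide form); its ring is closed approximately — the last
ring bond is ~1.6 Å by construction, well inside the perception cutoff. The
four-arm template is tetrakis(4-MTPA-amidophenyl)methane: four aniline-type
arms on a tetraphenylmethane core, exercising the several-records-per-
structure bookkeeping without any metal or porphyrin machinery.

`perturb` adds isotropic Gaussian noise per atom; `noise_sigma` is the RMS
magnitude of the displacement vector (each Cartesian component has standard
deviation σ/√3), deterministic per seed. A Monte-Carlo calibration at
σ = 0.02 Å — a typical coordinate uncertainty for a well-refined
small-molecule structure — found ~95% of recovered torsions within 3° of
their targets (p95 ≈ 2.9°); that bound is frozen in the acceptance test.
`sample_survey` draws torsion targets from wrapped normal distributions
centered on the survey consensus (θ¹ −13°, τ_F −174°, τ_sp +2°, τ_ap −174°,
τ_H −11°, θ² +21°, τ_OMe +54°) with survey-like spreads (5–20°), Bernoulli
chirality, all seeded.

What the generator does **not** emulate: crystal packing and intermolecular
contacts (the very forces behind the survey's outliers), thermal motion and
disorder, libration, or the full chemical diversity of the deposited amine
moieties. Passing the round-trip tests therefore shows the *measurement
chain* is correct, not that real structures are free of the perception
pitfalls (disorder, symmetry-completed molecules) listed above.

## Problem sizes

The survey statistics are exact desk-scale computations over 58 rows. The
randomized checks use 1000 quadruples for the torsion oracle, 200 structures
for the mirror theorem, 200 noise trials per template, and 50-structure
synthetic surveys — sizes at which every property has been stable across
seeds while the whole suite stays in the seconds range.

## Known limitations

- Core CIF 1.1 only (no mmCIF/PDBx), no disorder assemblies, no
  symmetry-operator parsing or expansion.
- CIP handling is fixed-depth, valid only for this substructure.
- The Z/E priority comparison covers the classes occurring in the survey;
  exotic alpha substituents fall back to `indeterminate`.
- The generator's amine templates span the survey's substituent *classes*,
  not its full chemistry (no phosphonate, selone, thiocarbamide or
  sulfonamide templates); those classes are exercised through the packaged
  table instead.
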