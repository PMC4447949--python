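# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic generators emulate, and the known
limitations.

## Coordinate model and superposition

Structures are read through gemmi (PDB and mmCIF), keeping model 1 only and,
by default, the blank/'A' alternate location (deposited Ets structures show
dual side-chain conformations; `keep_altlocs=True` retains all). Author
residue numbering is preserved throughout, because the residues of interest
(e.g. the Etv1 domain spanning 326–429, the invariant Arg-391/Arg-394/
Tyr-395 triad) are conventionally cited in author numbering. Superposition
is closed-form Kabsch (SVD with determinant correction); the default
pairing is alpha-carbons matched by chain id and author number over the
shared residue range — the natural choice for comparing apo and DNA-bound
domain copies, where no reference alignment is published. Fewer than three
pairs, or collinear pairings, raise a geometry error rather than returning
an ill-conditioned rotation.

## Fiber-model B-DNA

The reference duplex is an idealized fiber: one rigid nucleotide template
per base, stacked with twist 36°/step and rise 3.38 Å/step, strand II
generated by the Watson–Crick dyad (180° about the pair x-axis). Base atoms
use idealized planar standard-reference-frame geometries; the
sugar–phosphate backbone template was derived once by least-squares fitting
ideal bond lengths (P–O 1.59/1.48 Å, C–C 1.52–1.53 Å, C–O 1.42–1.45 Å, a
C2'-endo-like ring) under the helix operation, with the phosphate placed so
the duplex reproduces near-canonical raw cross-strand P–P groove widths
(minor ≈ 12.0 Å, major ≈ 17.8 Å) and an intra-strand P–P spacing of
7.12 Å. 5'-terminal phosphates are omitted, as in deposited
oligonucleotide structures. The model is sequence-independent by
construction: it is a *reference state*, not a shape predictor.

## Contacts

Deposited structures at these resolutions carry no hydrogens, so hydrogen
bonds use the standard heavy-atom criterion: donor–acceptor ≤ 3.5 Å between
chemically eligible atoms (per-residue donor/acceptor dictionaries for
protein side chains, backbone, DNA bases/backbone and water), plus a ≥ 90°
antecedent–donor–acceptor angle where the donor has a covalent antecedent.
Salt bridges are Lys/Arg nitrogen to carboxylate/phosphate oxygen within
4.0 Å, reported once per residue pair at the minimum N–O distance; pairs
with salt-bridge chemistry are excluded from the hydrogen-bond list so the
classes partition the contacts. Histidine ring nitrogens are treated as
neutral and ambivalent. The footprint span uses an any-atom 3.9 Å cutoff
and is the inclusive index distance between the first and last contacted
base pair. The 3.5/4.0/3.9 Å values are standard practice and exposed as
configuration; they are not tuned per structure.

EBS registration scans the reference strand (then its partner) for the GGA
core; the first G is +1 and numbering runs −3…+6 with no zero.

## Solvent-accessible surface area and interfaces

Shrake–Rupley with a deterministic Fibonacci point lattice (default 960
points/atom, probe 1.4 Å) and the radius table C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å (unknown elements fall back to 1.70 Å with a warning).
Waters and ions are excluded by default. Exact duplicate atoms (a
degenerate tie for the point-rejection rule) contribute once. Buried
interface area is (SASA(A) + SASA(B) − SASA(A∪B))/2 — the one-face
convention used by interface servers — with the unhalved per-side loss kept
for percent-of-monomer statements; the `sum` convention is available where
a two-sided figure is wanted. An interface residue loses > 0.1 Å² on
complexation. Because the point lattice is orientation-dependent, sampled
areas are rigid-transform invariant only to sampling precision (≈1% at 960
points); refining 960 → 3840 points changes totals by < 2% on the bundled
fixtures.

## DNA geometry

Base pairs require complementary identities, purine N1 to pyrimidine N3
≤ 3.5 Å, base-plane normals within 65°, and C1'–C1' within 9.5–11 Å; a
greedy maximal non-conflicting assignment (by N1–N3 distance) makes pairing
deterministic and atom-order invariant. Pair frames are obtained by Kabsch
fitting the idealized base templates to the observed base atoms (partner
frame dyad-flipped, the two averaged and re-orthonormalized); this is a
simplified standard-frame construction — no full step-parameter
decomposition (twist/roll/tilt) is attempted. The bend angle is the angle
between local axes fitted to the first and last four pairs (principal axis
of the frame origins, oriented by the mean frame z; a 10-mer does not
support a meaningful global-curvature fit). Groove widths are raw
cross-strand P–P minima over offset windows characteristic of B-DNA
register (minor: partner level −5…−2; major: +3…+7) with no probe-radius
subtraction; terminal levels whose window is truncated are reported as
undefined rather than as inflated values. The B-form comparison superposes
a fiber duplex of identical sequence on the C1' atoms of the central four
pairs and reports per-level groove deltas, bend delta and per-pair origin
displacements.

## Water networks and hydrogen assignment

A bridging water has at least one protein and one DNA polar partner within
3.5 Å (waters with occupancy < 0.5 are ignored; the analysis is only
meaningful where resolution supports ordered-water placement, roughly
< 2 Å). Conservation across complexes maps every structure onto the first
(shared-CA superposition by default) and clusters bridging waters by greedy
mutual proximity; a cluster present in all inputs within 1.0 Å is
conserved.

The hydrogen-assignment problem fixes each polar site's chemistry at
physiological pH: Arg/Lys/amide nitrogens donate only; carbonyl,
carboxylate, phosphate and ester oxygens and ring N7/N3-type nitrogens
accept only; hydroxyls are ambivalent (one donation, two acceptances);
water donates ≤ 2 and accepts ≤ 2. Base exocyclic amino groups retain a
single free proton outside the Watson–Crick edge. Every edge must receive
exactly one direction (no bifurcation). Enumeration is exhaustive —
depth-first over edge directions with capacity pruning, equivalent to
filtering all 2^E assignments, verified against a naive product-enumeration
oracle — and refuses graphs above 25 edges rather than switching to
heuristics. When the solution is unique, the direction of the base-edge
water contact implies the allowed bases: an accepting water requires an
exocyclic donor (C via N4–H; A via N6–H only at an elongated ~4 Å reach), a
donating water requires an exocyclic acceptor (G O6, T O4).

## Modifications

Both builders are rigid (no relaxation), mirroring static modelling on
crystal coordinates; this deliberately *overestimates* clashes that real
side chains would relieve by repacking, which is the point of the analysis.
The 5-methyl carbon is placed in the base plane at 1.50 Å from C5 on the
exterior bisector of C4–C5–C6; phosphoserine adds a PO3 with P–OG 1.61 Å
and P=O 1.48 Å in tetrahedral geometry, with the CB–OG–P torsion exposed
for 360° rotamer scans reporting phosphate-to-DNA-backbone proximity.
Overlap = Σ vdW radii − distance; ≥ 0.4 Å is a clash, smaller positive
overlaps are close contacts (a common steric-analysis convention,
configurable).

## Profiles and identity

B-factor profiles are per-residue means (all atoms by default; backbone
scope available) minus the chain mean — mean-centring only, no variance
scaling — so apo and bound chains plot on a common axis and a rigidifying
recognition helix flips from positive to negative. Identity uses
Needleman–Wunsch (match +1, mismatch 0, gap −1, via biopython's
PairwiseAligner) with terminal gaps excluded from the denominator, the
natural policy for domain-range inputs.

## Binding model

f(c) = Bmax·c^h/(Kd^h + c^h), fitted in log10-concentration space by
bounded least squares with one start per decade of the grid (local minima
are real on noisy log-spaced data). Default titration: 12 log-spaced
points over 10⁻¹⁴–10⁻⁶ M, noise SD 0.02 — the regime of radiolabelled EMSA
fraction-bound data. No probe-depletion correction is applied by default
(the experimental remedy is lowering the probe concentration, not changing
the model); the two-species `redox_mixture_model` emulates
monomer/dimer redox titrations as an affinity-weighted sum. Parameter
standard errors come from the Jacobian covariance; curves flat below 0.05
fraction bound at the top concentrations are flagged non-binding instead of
fitted. Fold inhibition is Kd(variant)/Kd(reference).

## Synthetic generators: what they emulate, and what they do not

The planted-complex builders produce minimal systems whose ground truth is
exact by construction: probe side chains placed at requested distances from
DNA atoms, four-water networks whose realized distance graph equals the
intended donor/acceptor graph (verified at build time), footprints spanning
a chosen number of base pairs, compact CA-only pseudo-domains for
superposition at realistic size (~93 residues), and two-fold poly-Ala toy
dimers for interface properties. Passing on these systems demonstrates that
the measurement chains are correct and self-consistent; it does not
demonstrate agreement with any particular deposited crystal structure,
since the fixtures have idealized geometry, no crystal contacts, no
alternate conformations and no experimental noise beyond what is planted.
Analyses of real complexes run through exactly the same code path via the
PDB/mmCIF readers. The synthetic sequence family likewise plants the
published divergence pattern (>90% within the PEA3-like trio, ~65% to the
Fev-like member, conserved anchors at author-numbered positions, a
two-residue deletion near α4) and is labelled synthetic; it is not a
database sequence set.

Problem sizes throughout (10–20-mer duplexes, ~100-residue domains, 100
seeded replicates for recovery statistics, 3840-point SASA refinements)
were chosen as the smallest sizes at which the statistics of interest are
stable.

## Known limitations

* No energetics anywhere: contacts, clashes and assignments are geometric.
* The fiber model is sequence-independent; indirect-readout questions need
  a sequence-dependent shape model, which is out of scope.
* Groove widths and bend use raw-P–P and terminal-axis conventions; other
  software (probe-corrected widths, full step-parameter bends) will differ
  systematically, so cross-tool comparisons should state conventions.
* The hydrogen-assignment model is combinatorial, not energetic: it decides
  feasibility, not relative strength, and disallows bifurcated bonds.
* SASA determinism is per point-count; areas carry ~1% sampling noise
  relative to the analytic surface at the 960-point default.
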