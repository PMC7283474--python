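# Methods

`tcrpmhc` implements the computational analyses used to characterize how
alpha/beta T-cell receptors (TCRs) engage a peptide-MHC class I ligand:
docking-geometry descriptors, interface contact tables, buried peptide
surface, shape complementarity, rigid superposition metrics, and 1:1
surface-plasmon-resonance (SPR) binding analysis. The motivating system is a
set of three tumor-derived TCRs (12-6, 38-10, 1a2) recognizing the shared
p53 R175H neoepitope (HMTEVVRHC, mutation at P8) presented by HLA-A*02:01,
but every computation is generic over annotated TCR-pMHC complexes.

## The annotated complex

All structural analyses consume an `AnnotatedComplex`: atomic coordinates
plus a chain-role map (`mhc_heavy`, `b2m`, `peptide`, `tcr_alpha`,
`tcr_beta`), CDR loop ranges (CDR1/CDR2/HV4/CDR3 per TCR chain), MHC helix
ranges, and optional disulfide anchor positions. Author residue numbering is
the canonical key — nothing is renumbered — so loop and helix boundaries are
*data*, shipped as editable config (IMGT-like defaults: CDR1 27-38, CDR2
56-65, HV4 81-86, CDR3 105-117; helices alpha1 50-86, alpha2 138-176 on the
heavy chain). Published per-structure results are reproducible only given
the ranges actually used, which is why they are config rather than code.
Crystals with several complexes in the asymmetric unit are handled by the
same mechanism: the role map names one copy's chains, and a second config
selects the other copy.

Alternate locations keep the highest-occupancy conformer (ties by altloc
letter); hydrogens are parsed but excluded from contacts and surfaces;
waters are retained, flagged hetero, and excluded from the tables.

## Docking geometry

The pMHC reference frame is centered at the mean C-alpha of the two MHC
helices. The z-axis is the total-least-squares plane normal of those
C-alphas (smallest principal component), signed toward the TCR; the x-axis
is the first principal axis of the peptide C-alphas projected into that
plane, oriented so the peptide C-terminus has the greater x; y = z cross x.
Both fits are deterministic and rotation-equivariant.

V-domain centers are the mean of the two Sgamma atoms of the conserved
intrachain disulfide (detected as the unique Cys pair with Sgamma-Sgamma
<= 2.5 A; C-alpha substitutes, flagged, where a Cys is absent). When a
full-length chain carries both the V- and C-domain disulfides, the
lowest-numbered pair (the V domain) is used and a warning logged; a config
override is available. The TCR center is the midpoint of the Valpha and
Vbeta centers, and (x_pos, y_pos) are its in-plane frame coordinates —
larger x means a shift toward the peptide C-terminus.

* **Crossing angle**: angle in [0, 180] deg between the in-plane projection
  of the Valpha -> Vbeta vector and the +x (peptide) axis.
* **Incident angle**: elevation in [0, 90] deg of that vector out of the
  plane — the TCR's tilt over the pMHC surface.

Published surveys differ in the exact vectors used for these angles, so the
incident-angle definition is a pluggable strategy (`INCIDENT_STRATEGIES`),
with the elevation form as default, and the crossing angle can in principle
be anchored on full-domain centroids instead of disulfide centers; disulfide
anchors are the default because they are the only anchors the center
calculation itself defines. Angles are reported as magnitudes; canonical
docking polarity (Valpha over the alpha2 helix, Vbeta over alpha1) is a
separate boolean diagnostic.

Descriptors rank against a reference table of other class I complexes
(TSV: complex_id, crossing_angle, incident_angle, x_pos, y_pos). With rank
r among N complexes (table rows plus the query), the percentile is
round(100 * (1 - r/N)); this rounding reproduces e.g. rank 4 of 136 -> 97th
percentile and rank 14 of 136 -> 90th. Only a small synthetic demo table is
bundled; a real survey table is user-supplied data.

## Interface contacts

A contact is any pair of non-hydrogen atoms from opposite sides at <= 4.0 A
(inclusive bound; the cutoff is a parameter). The neighbor search uses a k-d
tree and is validated against brute-force pair enumeration in the tests.
Each TCR-side contact atom is assigned to exactly one loop by residue range;
atoms outside all loops land in a visible framework bucket, never dropped.
Tables count contacts per loop against two targets — the peptide and the MHC
heavy chain — with beta-2-microglobulin and water contacts tallied
separately (canonical docking puts neither in the interface). Percentages
are round-half-up integers of the per-target total, and chain shares sum a
chain's four loops plus its framework bucket.

Hydrogen bonds are flagged with a deliberately reproducible, distance-only
default: donor-typed N/O/S to acceptor-typed N/O heavy atoms at <= 3.5 A,
using a standard residue-specific donor/acceptor dictionary (element-level
fallback for non-standard residues). Without hydrogens and without angle
terms this over-calls weak bonds; treat H-bond counts as qualitative. An
angle filter can be added when hydrogens are present.

## Surfaces

**SASA** is Shrake-Rupley: each atom's sphere of radius (vdW + probe,
probe 1.4 A) is sampled with a fixed golden-spiral lattice (960 points by
default; >= 92 enforced) and the unoccluded fraction scales the sphere area.
The fixed lattice makes areas deterministic; rotation invariance holds to
~0.1% sampling noise. Radii sets are data: the default "chothia" set
(C 1.87, N 1.65, O 1.40, S 1.85) matches the united-atom lineage of the
classic SASA programs; a "bondi" element set is included and is used in the
tests to cross-check totals against an independent Shrake-Rupley
implementation (biotite) to <1%.

**Buried peptide surface** is the delta-SASA of the peptide: SASA within
the pMHC alone (heavy chain + beta-2-microglobulin as occluders) minus SASA
within the full complex, reported as area and as a fraction of the former.

**Shape complementarity (Sc)** follows the median-score statistic: for each
interface dot on one surface, the nearest partner dot contributes
s = -(n_a . n_b) exp(-w d^2); Sc is the mean of the two per-side medians.
Defaults w = 0.5 A^-2, border trim 1.5 A, interface distance 1.5 A — the
parameters of the original formulation, since no others are defensible.
Dots are spiral-lattice points on each atom's sphere with dots inside any
other atom's sphere removed (default density 4 dots/A^2). The surface used
is the **contact (vdW) surface**, not the solvent-accessible one: the
molecular surface that the statistic is defined on coincides with the
contact surface exactly in the touching patches Sc scores, whereas
probe-expanded accessible surfaces of two sides in contact interpenetrate,
scrambling nearest-dot pairing and normals (we observed perfectly
complementary slabs scoring negative Sc under the accessible variant, which
remains available as `surface="accessible"`). Rim trimming discards
interface dots within the border-trim distance of the nearest
non-interface dot of the same surface. Planar and hemispherical dot
fixtures with known closed-form Sc = exp(-w d^2) validate the statistic to
0.02. The sides default to TCR vs peptide+MHC heavy chain and are explicit
arguments.

## Superposition

Kabsch least-squares superposition via SVD, proper rotations only
(reflections rejected by sign correction); near-collinear inputs warn but
return the least-squares solution. `fit_measure_rmsd` computes the
transform on one selection and reports RMSD on another without refitting —
the pattern behind "superpose the MHC alpha1/alpha2 domains, measure the
peptide". Selections address atoms by role, residue ranges and atom subset
(`ca`, `main_chain` = N/CA/C/O, `all_non_h`, or custom names), with
per-residue side-chain exclusions for comparisons across point mutations.
Correspondence is by author numbering within matched roles (strict by
default; a lenient mode uses the matched intersection). For unbound-vs-bound
TCR comparisons the default fit set is all matched V-domain C-alphas outside
the CDR3 ranges. Displacement profiles report per-residue C-alpha distances
after superposition, ties at the maximum broken toward the lower residue
number.

## SPR binding kinetics

The 1:1 Langmuir model in closed form — association
R(t) = Req (1 - e^(-(kon C + koff) t)) with Req = Rmax C / (C + KD), then
exponential dissociation — with KD = koff/kon. No ODE integration is used:
the analytic phases are exact and fast. The simulator adds additive Gaussian
noise in response units (the standard first-order model of pre-subtracted
sensorgram noise) and samples at dt = 0.1 s, typical instrument acquisition.
Equilibrium analysis fits Req(C) by unweighted nonlinear least squares
(>= 3 distinct concentrations required; flagged poorly determined when the
ladder does not bracket the fitted KD). Kinetic analysis fits log10(kon),
log10(koff) and a shared Rmax globally across concentrations with a small
multistart over rate scales. A reliability flag clears when the fastest
kobs = kon*C + koff exceeds 1/(3 * median sampling interval) — rates too
fast for the time resolution, the regime reported for the two
lower-affinity TCRs. Reference-cell subtraction and mass-transport
limitation are out of scope; synthetic data are generated pre-subtracted.

## Synthetic structures

The generator (`make_toy_tcr_pmhc`) builds annotated complexes directly in
the canonical frame: two helix-like MHC C-alpha traces flattened into the
z = 0 plane (the radial wobble folded into y, mirrored so the combined
centroid is exactly on the frame origin), a 9-residue extended peptide along
+x ordered N -> C, a beta-2-microglobulin stub below the plane, and two
pseudo-V domains 28 A apart at height 25 A whose synthetic Cys Sgamma pairs
(2.0 A apart, mean = domain center) realize prescribed crossing/incident
angles and x/y positions to machine precision. Contact layouts are realized
by planting carbon atoms exactly 3.5 A from designated peptide C-alphas or
heavy-chain platform atoms — strictly inside the 4.0 A cutoff, with slot
geometry guaranteeing each planted atom contacts exactly one target — and
every generated layout is re-verified by brute force before the complex is
returned. Defaults are the study's printed conditions (crossing 51 deg,
incident 20 deg, 9-mer peptide); `tcrpmhc.study` carries the full printed
contact tables, docking angles, analyte ladders and rate constants as
generator inputs.

What the toys do and do not show: they exercise frames, descriptors,
contact counting, selection logic, delta-SASA bookkeeping and serialization
exactly, because those depend only on anchor atoms, ranges and distances.
They are geometric scaffolds, not packed protein interfaces — their
absolute Sc values and buried fractions are not comparable to
crystallographic ones (the closed-form dot fixtures carry that check), and
passing on toys does not validate the annotation ranges a user supplies for
real structures.

## Numerical choices and degenerate inputs

Plane/axis fits use SVD with no randomized initialization; frames raise on
collinear helices or coincident peptide atoms. The crossing angle is
undefined when the inter-domain vector is perpendicular to the MHC plane
(raised as a geometry error; the generator refuses incident = 90 deg for
the same reason). Contact cutoffs are inclusive with a relative epsilon
guarding float rounding at the boundary. Percentage cells use half-up
rounding; zero-total targets report empty cells rather than zeros. Sc is
undefined (raised) when no dot lies within the interface distance of the
partner surface. Equilibrium fits with all-zero responses or a single
concentration raise rather than returning spurious estimates.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic inputs:
toy complexes of a few hundred atoms, brute-force contact oracles on <= 200
atoms, 100-seed noise studies for the KD-recovery statistics, and 25-point
round-trip grids for the docking descriptors. These sizes were chosen so a
full run completes in well under a minute while every statistic retains a
meaningful sample; analyses of real deposited entries (user-supplied PDB
files, ~7000 atoms) take seconds per complex.

## Known limitations

* Loop/helix ranges for real structures must be supplied in the structure's
  own author numbering; no germline-alignment auto-numbering is attempted.
* The H-bond criterion is distance-only; published H-bond counts based on
  unstated geometric criteria will not be reproduced exactly.
* Sc uses a dot approximation to the molecular surface; agreement with the
  reference implementation is expected within ~0.05.
* The incident-angle convention of published surveys is not uniquely
  determined by their text; the elevation default is one reading, and
  alternative strategies plug in without code changes elsewhere.
* Kinetic fits assume pre-subtracted, drift-free sensorgrams and a single
  1:1 site; mass transport and bivalent models are out of scope.
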