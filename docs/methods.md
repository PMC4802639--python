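# Methods

## The scientific problem

SWS1 visual pigments (opsin + 11-*cis*-retinal) mediate either UV
(λ_max ≈ 360 nm) or violet (395–440 nm) vision. The phenotype is set
by the protonation state of the retinal Schiff-base (SB) nitrogen,
which is in turn controlled by the hydrogen-bond network (HBN) formed
by the residues at bovine-rhodopsin sites 86, 90, 113, 114, 118 and 295
and two waters. Mutational effects on λ_max are strongly epistatic:
the same substitution can shift λ_max by tens of nanometres in one
background and not at all in another, so "any mutations that reach the
target λ_max" is not evidence that those mutations drove evolution.
The package combines a structural signature (the A/B area ratio of the
HBN), a λ_max regression on that signature, explicit classification
criteria for mutants, an exact epistasis decomposition, and a
substitution-rate analysis over the known spectral-tuning codons.

## HBN geometry

Area A is spanned by the residues at sites 90, 113 and 118 (113 stands
in for the bonded 113/114 pair); area B by sites 86, 90, 118 and 295,
taken as a quadrilateral in that vertex order. When site 86 is absent —
the scabbardfish-style single-codon deletion — site 91, the nearest
remaining residue to the HBN, substitutes for it and the result carries
a `site86_substituted` flag.

Two conventions are implemented because the published areas do not
specify a construction:

* **distance-heron** — residue–residue separations are the shortest
  heavy-atom distances; triangle areas follow by Heron's formula and
  the quadrilateral is split along the 86–118 diagonal (configurable to
  90–295; for planar vertices both diagonals give the same sum).
* **coordinate-polygon** — each residue is collapsed to its side-chain
  heavy-atom centroid (Cα for glycine; configurable), and the polygon
  area is the shoelace formula after projecting the vertices onto their
  least-squares plane ("area" is only well defined for planar figures).

For planar, single-atom-per-residue inputs the two conventions agree to
1e−9 relative tolerance, which is the cross-check the test-suite
properties rely on; for real side chains they differ, and the
convention used is recorded in every result. Published A/B values are
therefore treated as tabulated inputs, not as regression targets for
either convention.

Sub-areas A1–A3 are the three triangles joining the SB nitrogen to the
edges of area A; they partition A exactly when the nitrogen is interior
and coplanar. For area B the figure labels three sub-areas but a fan
around an interior point of a quadrilateral yields four triangles, so
the convention here is B1 = (water, 86, 90), B2 = (water, 90, 118) and
B3 = the merged pair (water, 118, 295) + (water, 295, 86); with no
water supplied the sub-areas are reported absent rather than invented.
Numerical guards: Heron radicands above −1e−12 are clamped to zero
(collinear noise); larger violations of the triangle inequality raise a
degenerate-geometry error; area B of zero raises rather than returning
an infinite ratio.

All areas and distances are in Å/Å², read from PDB coordinates as-is —
no modelling, optimisation or hydrogen placement. A site map translates
file numbering to bovine-rhodopsin numbering (identity by default); the
SB nitrogen defaults to the NZ atom of residue 296.

## Spectral-tuning regression

λ_max is regressed on (A/B, B) by OLS with intercept, requiring at
least four records and a full-rank design. Diagnostics: R² = 1 −
SSE/SST; residual standard error S = √(SSE/(n−3)), the denominator
counting the three estimated coefficients; MAE = mean |residual|.
Predictions are also reported rounded half-away-from-zero to whole nm.
Two deliberate choices:

* The fit consumes the tabulated A/B column at its printed precision,
  not A/B recomputed from the A and B columns; the third decimal of
  the ratio moves the coefficients noticeably and the bundled table's
  published coefficients correspond to the printed column.
* Only the geometry-optimised (AMBER) records are fit by default: the
  inverse A/B–λ_max relationship does not hold across the raw
  homology-model (SWISS) rows, which are retained for the group-level
  A/B intervals instead.

## Mutant classification

d(λ_max) = mutant λ_max − target λ_max and d(A/B) = mutant A/B −
target A/B, where the target is the pigment whose phenotype the
mutations are supposed to reproduce. The |d(λ_max)| tolerance is
"3–5 nm depending on the total shift"; that verbal rule is realised as
a two-step function — 3 nm below a 40-nm total background→target
shift, 5 nm at or above it — with both cut-offs and the breakpoint
configurable. The breakpoint is validated only by consistency with the
bundled classification table (e.g. a 2-nm deviation passes for the
wallaby mutant while 7 nm fails for the bovine mutant across an
~80-nm shift); every tabulated row whose |d(λ_max)| falls in the
ambiguous (3, 5] band involves a total shift well above 40 nm, so the
default is not sharp. |d(A/B)| ≤ 0.002 defines a fully converted HBN
signature. Classification is exhaustive and mutually exclusive over
{I, II, III, ND}; an unmeasurable λ_max propagates as ND, and an
unknown d(A/B) can at best support class II (class I requires positive
evidence on both axes).

Two bundled rows print a class inconsistent with these criteria (one
shows d(A/B) = 0.01 against the 0.002 rule); they are flagged
`excluded` in the data and skipped by the reproduction tests. The
bundled table also carries curated background/target λ_max columns
(from the pigment-name suffixes and the pairings described with the
experiments) so the threshold tier can be chosen per row.

Phenotype groups: group 1 (UV) spans λ_max 354–371 nm or raw-model A/B
0.535–0.577; group 3 (violet) spans 395–440 nm or A/B 0.355–0.526;
group 2 (the 393-nm intermediates) is claimed by pigment identity or
the narrow A/B strip near 0.49, which lies inside the violet interval
and therefore never captures a pigment by interval alone. Values
outside every interval return an explicit `unclassified` flag.

## Epistasis decomposition

On a complete factorial (all 2^k combinations of k mutations, each
measured once) the model λ(S) = λ_bg + Σ_{∅≠T⊆S} θ(T) is triangular
and solved exactly by inclusion–exclusion in order of subset size.
Incomplete or duplicated designs are rejected with the offending
subsets named — the procedure is exact interpolation, not least
squares (a least-squares path exists only for replicated measurements,
where replicates are averaged first; it is off the default path).
Subset keys carry the mutation direction (F86S ≠ S86F), so a forward
model over an ancestor and a reverse model over its descendant are
independent objects that cannot be merged by accident — which is the
point: the forward F86S main effect (14 nm) is *not* the sign flip of
the reverse S86F effect (−52 nm).

Two derived views connect the directions. `complement_model`
re-indexes a reverse factorial around its full mutant (new background =
the fully reverted pigment) and decomposes that table, yielding the
forward-direction coefficients the reverse experiment implies.
`complement_equivalence` pairs each reverse subset with the forward
complement over the same sites and reports both λ_max values and their
difference; identical additive models pair with zero differences.

## Substitution rates

p is the proportion of differing nucleotides over positions where both
sequences have unambiguous bases (gaps and N excluded pairwise);
d = −(3/4)·ln[1 − (4/3)p] is the Jukes–Cantor distance, with p ≥ 3/4
raising a saturation error. For a (violet A, UV B, outgroup C) triple,
b_A = (d_AB + d_AC − d_BC)/2 and b_B = (d_AB − d_AC + d_BC)/2; the
identity b_A + b_B = d_AB holds to machine precision and negative
branch estimates are returned flagged, not clamped. Rates are branch
length divided by divergence time, reported in 10⁻⁹ substitutions per
site per year; the bundled divergence-time table lists the eight
violet/UV pairs (114, 298, 102, 98, 98, 98, 105 and 62 MY).

The critical-site mask expands the 17 spectral-tuning codons (46, 49,
52, 86, 90, 91, 93, 97, 109, 113, 114, 116, 118, 179, 207, 256, 277)
to their nucleotide triplets via an explicit codon-number map
(1-based; identity by default — no automatic alignment to rhodopsin is
attempted). A codon gapped or unmapped in any compared sequence is
dropped from the mask, so comparisons involving the site-86 deletion
automatically use 16 codons (48 nucleotide positions).

The SE formula [9p(1−p)/{(3−4p)²n}]^{1/2} is the delta-method standard
error of d from a single pairwise comparison. How it should propagate
through the three-taxon branch decomposition is not specified in the
source analysis, so the package deliberately does not invent a
propagation: the SE attached to a lineage rate is the pairwise A–B
distance SE scaled by the same 1/(divergence time) factor as the point
estimate, computed in one isolated function that a user can replace.
Published per-gene rates require the original GenBank alignments and
unstated alignment choices and are not reproduced here; the rate
machinery is validated by its closed-form examples and simulation
properties instead.

## Synthetic data

The generators define the test conditions and are all
seed-deterministic (NumPy `default_rng`), returning a ground-truth
manifest beside the data.

* **Structures**: planar single-atom residues placed in closed form so
  the computed areas equal the requested (A, B) exactly — sites 90/118
  on a 10-Å base, 113 below at depth 2A/width, 86/295 above at height
  B/width, SB nitrogen at the area-A centroid, waters inside area B —
  then moved through a seeded random rigid rotation + translation
  (areas are invariant, so the ground truth survives the pose).
  What this does *not* emulate: multi-atom side chains, non-planarity,
  or modelling error, so a passing geometry suite certifies the area
  machinery, not the fidelity of any homology model.
* **Alignments**: pairs differ at Bernoulli(p) positions with the
  realised count reported, so exact-p tests need no tolerance; triples
  derive two ingroup sequences and an outgroup from a common root with
  per-branch change probabilities. This is an independent-sites
  approximation (at most one change per site per branch), adequate for
  the moderate divergences tested; it is not a full continuous-time
  JC simulator and does not model codon structure or selection.
* **Factorials**: λ(S) = background + Σ chosen main effects and
  interactions + optional Gaussian noise; zero-noise integer inputs
  give integer tables on which decomposition recovers θ exactly.

Simulation sizes in the default suite — 1,000 geometry fixtures,
10,000 branch triples, 500 Jukes–Cantor replicates at 900 sites, 1,000
noisy factorial replicates — were chosen as the smallest round sizes at
which the checked statistical properties are stable.

The bundled reference tables were transcribed once from the published
tables and are SHA-256 checksummed; loaders verify the checksum, and
tests compare against the loaded copies rather than re-typed literals.
One transcription note: a garbled d(A/B) entry in the extracted source
text was recorded as 0.004 (its class is III regardless of the exact
value), and the row is annotated in the data file.

## Known limitations

- The A1–A3/B1–B3 sub-area constructions are explicit stand-ins; the
  published figure labels the sub-areas without defining them.
- The 40-nm threshold breakpoint is a calibrated realisation of a
  verbal "3–5 nm" rule, constrained but not pinned by the bundled
  classification rows.
- Geometry results depend on the convention (and, for polygons, the
  representative point); cross-convention agreement is guaranteed only
  for planar single-atom fixtures.
- Rate SEs ignore the covariance introduced by the shared outgroup in
  the relative-rate construction.
- The λ_max catalogue bundles the pigments recoverable from the source
  text; it is a reference list, not an exhaustive survey of SWS1
  measurements.
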