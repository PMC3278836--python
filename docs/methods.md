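# Methods

## The search problem

A base triple is three nucleobases mutually joined by hydrogen bonds. The
tool restricts itself to *multiply hydrogen-bonded* triples — every base
makes at least two base–base hydrogen bonds with the other two — because
these are the most stable and structurally consequential class. The
pipeline is a two-stage screen: a fast geometric pattern search over a
reduced representation, followed by explicit hydrogen-bond chemistry on
the candidates, then geometric classification of the survivors.

## Reduced pseudo-atom representation

Each admitted nucleotide (all ring heavy atoms present; modified residues
mapped to a parent base through an alias table, e.g. pseudouridine → U)
is represented by two directed vectors of two nodes each:

* **X vector** — `Sx` is the glycosidic nitrogen (N9 purines, N1
  pyrimidines); `Ex = 2·centroid − Sx`, where the centroid is the mean of
  the ring heavy atoms. X therefore encodes where the backbone attaches
  and how the base is oriented about it.
* **Y vector** — an in-plane anchor direction (N7−N3 purines, C4−C2
  pyrimidines) is projected onto the least-squares base plane and
  orthogonalized against X; `Sy`/`Ey` sit at ∓2.0 Å from the centroid
  along the result. Y encodes the in-plane spread perpendicular to X.

Both vector midpoints coincide at the centroid by construction, so the
1 Å intra-base midpoint constraint carried in every pattern is satisfied
with maximal margin, and intra-base node distances depend only on base
type, never on pose. The recipe is identified by a convention tag
(`glyN-centroid-L2.0-v1`) recorded in every pattern file; the matcher
refuses to mix conventions. The exact node placement is a design choice:
any recipe that makes the two midpoints nearly coincide and gives X and Y
discriminative directions would serve, which is why the recipe is a
single replaceable table rather than scattered constants.

## Pattern matrices

A pattern stores, for each of the 15 unordered pairs of the six units, a
block of four integers (SS, SE, ES, EE) — the node-pair distances in
tenths of an ångström, rounded half away from zero (10.0 Å → 100). The
intra-base X/Y block participates in matching like any other block and is
what ties a slot's two vectors to one physical base. Slots may carry the
wildcard `N`. Patterns are measured from occurrences in canonical slot
order (base type, then residue id), so the six input orders of a triple
give one canonical matrix; a chirality sign (see below) and the source
residues are recorded alongside.

The shipped starter library contains four patterns measured from the
synthetic fixtures (U·A·U Hoogsteen/Watson-Crick, G·C·G Watson-Crick +
sugar-edge, protonation-dependent A·C·C, and A·G·U wobble + amino-N3).
Large theoretically enumerated libraries are deliberately out of scope;
users grow libraries with `build-pattern` from occurrences they trust.

## Matching

Matching is Ullmann subgraph isomorphism at nucleotide granularity:
slot-to-nucleotide candidate lists are built from base-type and
intra-block compatibility, pruned with a KD-tree (two nucleotides can
only co-occur in a hit if their centroids lie within the largest pattern
distance plus the tolerance ceiling plus 4.5 Å of node-to-centroid
slack), refined by the Ullmann condition (a candidate survives only while
every other slot retains a compatible partner), and enumerated
depth-first. An edge is compatible when the structure distance deviates
from the decoded pattern distance by at most the tolerance — absolute in
Å, or percent *of the pattern distance* (the pattern is the reference
object). Hits on the same residue set arising from interchangeable slots
collapse to the assignment with the smallest worst-case deviation.

Distance matrices are mirror-invariant, so enantiomeric embeddings are
possible in principle. After matching, the sign of the scalar triple
product of the three base normals (ordered by slot) is compared with the
sign recorded in the pattern; a mismatch flags the hit as a mirror image
rather than silently keeping or dropping it. Near-coplanar triples make
this product nearly zero, where handedness is genuinely ill-defined;
magnitudes below 0.1 are treated as indeterminate and never flagged.

The brute-force reference matcher in the test suite enumerates all
ordered residue triples directly from coordinates and is the oracle for
the matcher's completeness and equivalence properties (fields up to ~50
nucleotides).

## Hydrogen-bond chemistry

Crystal structures mostly lack hydrogens, so polar hydrogens are placed
at idealized sp2 positions: 1.0 Å N–H; ring N–H along the external
bisector of the two ring neighbors; amino groups get two in-plane
hydrogens at ±120° from the N–C bond. A donor–acceptor pair is a bond
when d(D···A) ≤ 3.9 Å, some hydrogen has d(H···A) ≤ 2.5 Å and
∠D–H–A ≥ 90°, and every acceptor-antecedent angle is ≥ 90° — the default
thresholds of the classic HBPLUS geometry. All thresholds are
configurable (`HBondCriteria`); a heavy-atom fallback mode (distance plus
donor-angle only) exists for low-resolution work where idealized
hydrogens would mislead. C–H···O/N contacts are never counted toward the
per-base criterion, and neither are ribose or phosphate contacts — the
criterion is about base–base chemistry.

Protonation: adenine N1 and cytosine N3 can each carry an extra proton
and become donors. The triple filter optionally searches these variants
per base and accepts one only when it contributes a bond that neutral
chemistry cannot; such bonds are flagged. The search is off by default
because protonated triples are rare and a permissive default would
inflate counts.

## Classification

Edge membership tables (config data, not code constants) assign each base
atom to the Watson-Crick, Hoogsteen or Sugar edge; the pyrimidine C5/C6
face counts as Hoogsteen for uniformity. The edge a base presents to a
partner is the majority edge over its bonding atoms; atoms shared by two
edges side with the edge that also received an edge-exclusive vote, else
with the edge whose atoms point most directly at the partner; residual
ties break WC > H > S. Orientation is the C1′–N–N–C1′ glycosidic
dihedral, Cis iff |dihedral| ≤ 90° (the boundary is closed on Cis by
convention); when C1′ is absent the centroid→N direction substitutes.

Family strings render each bonded pair as `<Cis|Trans> <edge> / <edge>`
with edges alphabetical, sort pairs cis-before-trans then alphabetically,
and join with " – ". This is exactly the redundancy-ordering that makes
equivalent geometries collide on one name. Composition codes (`AGU1`)
append a registry suffix per distinct (family, donor/acceptor topology)
within a base composition; the registry is deterministic and stable
within a run, but the numeric suffixes are an artifact of first-seen
order and are not guaranteed to coincide with historical naming.

## Synthetic fixtures

The fixture generator is the package's no-download test surface. It
embeds idealized planar base geometries (standard reference-frame
coordinates, z = 0, base heavy atoms + C1′) and composes pairs/triples by
rigid in-plane placement: named donor–acceptor contacts are driven to a
target distance (default 2.9 Å, the ideal N/O hydrogen-bond separation;
directive range 2.4–3.9 Å), with soft terms for steric repulsion and
donor–H···acceptor linearity selecting the chemically sensible solution
among the discrete alternatives; both mirror states are tried and the
requested cis/trans orientation picks the final pose. The first two
contacts of a directive are enforced within 0.05 Å; additional contacts
are soft, reflecting the ~0.1 Å spread real multi-bond pairs show around
the ideal separation. Decoy fields scatter planted groups and isolated
single bases at seeded random poses with ≥ 8 Å separation, so planted-hit
counts are unambiguous by construction.

What the fixtures deliberately do **not** model: backbone and ribose
(beyond C1′), thermal displacement and alternate conformations, crystal
contacts, non-planar (propeller/buckled) pairs, water- or metal-mediated
bonds. Passing fixture tests therefore demonstrates the correctness of
the algorithms and the chemistry rules on clean geometry, not parser or
criteria robustness against the full messiness of experimental maps;
resolution filtering (≤ 3.0 Å by default, structures without a stated
resolution rejected unless overridden) is the first line of defense in
real surveys.

## Numerical choices and problem sizes

* Distance encoding loses at most 0.05 Å to rounding, so the tightest
  meaningful search tolerance against a measured pattern is 0.1 Å.
* Tolerance comparisons and the Cis boundary are closed (≤).
* Ties in altloc resolution go to the alphabetically first identifier at
  equal occupancy; nucleotide order is (chain, residue number, insertion
  code), making parsing and every downstream report deterministic.
* Test and demonstration problem sizes — fields of 30–50 nucleotides, 25
  replicate fields for matcher/oracle equivalence, 20 noise replicates at
  σ = 0.3 Å for fuzzy-recall statistics — were chosen so the exhaustive
  oracle stays exact and the whole suite completes in well under a
  minute; the matcher itself scales to ribosome-sized chains through the
  spatial index.

## Known limitations

* Only 3-base patterns; tetrads/pentads are out of scope (the data model
  does not preclude n-slot patterns later).
* First model of multi-model files only; no symmetry expansion, so
  triples formed across crystal contacts are invisible.
* mmCIF input is not parsed (PDB fixed-column only).
* The composition-code suffixes are registry-local, not a universal
  nomenclature.
* Idealized hydrogen placement can misjudge borderline bonds on distorted
  bases at ~3 Å resolution; the heavy-atom mode trades specificity for
  robustness there.
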