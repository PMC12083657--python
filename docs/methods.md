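# Methods

This note documents the models implemented in `cryptclones`, the choices made
where the underlying methodology leaves room, and what the synthetic-data
generators do and do not emulate.

## Lattice model of crypt dynamics

The colonic epithelium is modelled as an M×M lattice of crypts (one site =
one crypt), the flattened representation of a colon segment opened
longitudinally; both axes are periodic, reflecting the cylindrical tissue
topology. Site states are −1 (unlabelled), 0 (empty) and +1 (labelled).
Neighbourhoods are the six-site set
{(i,j±1), (i±1,j), (i+1,j+1), (i−1,j−1)} — the standard square-array
embedding of a hexagonal lattice. The printed neighbour set is implemented
exactly as stated (it omits the (i+1,j−1)/(i−1,j+1) diagonals, which is the
correct hexagonal embedding, not an error).

One *time step* selects one site uniformly at random:

1. an empty site with only empty neighbours does nothing;
2. an empty site with occupied neighbours draws one occupied neighbour
   uniformly and copies its state with that neighbour's fission probability
   ρ_s;
3. an occupied site draws any of its six neighbours uniformly. An empty
   neighbour is colonised with the focal site's ρ_s (fission). An occupied
   neighbour triggers fusion with probability (f_a+f_b)/2: one of the two
   sites (fair coin) becomes empty, and the survivor takes state a with
   probability P_a/(P_a+P_b) (monoclonal fixation; a fair coin when both
   fixation probabilities are zero). This normalised-fixation rule reduces
   to 50/50 under the neutral parameters (P=0.5 both states), the only
   regime the headline results depend on; it is a reconstruction, since only
   the neutral case is pinned down by the published description.

Defaults: ρ = f = P = 0.5 for both states (neutral homeostasis), labelling
efficiency 0.2 (each site initially labelled i.i.d. with probability 0.2, no
empty sites; an exact-count option exists). The fission-bias scenario sets
ρ₊₁ = 0.95 with everything else unchanged. Acute damage empties columns
M/2..M−1 at a configurable step; the damaged half regrows from both sides of
the seam because of the periodic topology.

**Lattice size.** M is not pinned down by the published repair times
(80,000 vs 115,315 steps, single realisations at unknown M); the package
default is M = 100, and all simulation-based tests and the acceptance script
run at M = 50 with 100 replicates, which keeps every scenario within seconds
on one CPU while leaving half-lattice statistics stable. Consequently the
repair-time comparison is matched *directionally* (biased repair strictly
faster; observed ratio ≈ 0.54 at M = 50), not numerically.

Under neutral dynamics the empty-site fraction relaxes to a plateau whose
mean-field value solves (1−e)² = e(2−e), i.e. e* = 1−√2/2 ≈ 0.293; the
simulated plateau (≈ 0.289 at M = 50) sits just below it because of spatial
correlations. Homeostasis is detected operationally: the plateau is declared
when consecutive windowed means of the empty-site count differ by less than
a relative tolerance (defaults: 2,000 recorded points and 1% at production
scale; 30 points at the reduced test scale). Repair time is the number of
steps from damage until the damaged half's occupancy first re-enters 5% of
its pre-damage plateau (the plateau estimated from the last quarter of
pre-damage records).

## Site aggregation

For every occupied site, each of its six neighbour relations to another
occupied site is one neighbour-pair link (NP); links whose states differ are
distinct-neighbour-pair links (DNP). With α total DNP links and β total NP
links, concentration C = α/β and site aggregation is 1−C. Empty sites are
excluded from both counts; aggregation is *undefined* (NaN, never 0) when
β = 0, e.g. a freshly damaged half. Counting is over the multiset of ordered
links — the printed set-of-state-pairs definition collapses to cardinality
≤ 2 and degenerates, so the stated intent ("number of distinct neighbour
pairs") is implemented as link counts; ordered counting doubles α and β and
leaves C unchanged. Half-lattice values attribute each link to the half of
its focal site, so cross-boundary links contribute to both halves once.

For an i.i.d. labelled/unlabelled lattice with labelled fraction p and no
empties, E[C] = 2p(1−p); at p = 0.2 aggregation ≈ 0.68, which the
implementation reproduces and the tests assert. Domain coarsening makes
aggregation drift slowly upward through "homeostasis" — the plateau is a
property of counts, not of spatial arrangement — and damage repair raises
the damaged half's aggregation above its pre-damage value persistently.

## Effective fission-rate inference

Clone sizes n (crypts per clone) observed t days after induction follow the
Yule–Furry pure-birth law f_n(ρ,t) = e^{−ρt}(1−e^{−ρt})^{n−1}: geometric
with success probability e^{−ρt} and mean e^{ρt}. Sizes are truncated at
n_max = 30 with the tail mass (1−e^{−ρt})^{n_max−1} folded into the last
category, so the category probabilities sum to one exactly and clones larger
than n_max remain informative through the fold. Counts per region are
multinomial in these probabilities.

Rates are *effective*: crypt fusion and tissue remodelling are not modelled
and are absorbed into ρ. The continuous-induction variant (integrating the
pure-birth solution over the animal's age) is deliberately not implemented;
this model conditions on a single induction time per region.

**Neighbour-merge correction.** Two unrelated adjacent clones can be
miscounted as one two-crypt clone. With merge probability λ (default 0.05),
f₂' ∝ f₂ + λf₁² and f₁' ∝ (1−2λf₁)f₁, renormalised; λ = 0 is the identity.
The exact algebraic form used in the original R implementation is not
published, so this parametric reconstruction is exposed in the configuration
and documented as such.

**Hierarchy and priors.** Region rates share a Student-T prior truncated at
zero, ρᵢ ~ StudentT(ν, μ, σ)·1[ρᵢ≥0], with μ ~ Normal(0, 0.1),
σ ~ HalfNormal(0.1) and ν ~ Gamma(shape 2, rate 0.1). The published prior
line reuses ρ for the location parameter and writes "10⁻²" without units;
this package reads it as the hierarchical location μ with *variance* 10⁻²
(sd 0.1), takes σ half-normal because a scale must be positive, and
truncates ρᵢ at zero because rates in 1/days cannot be negative. All of
these are configurable.

**Sampling.** The posterior over (μ, log σ, log ν, ρ₁..ρ_R) is drawn with an
affine-invariant ensemble sampler using differential-evolution moves (80%
DE, 20% DE-snooker), which mix far better than the stretch move on this
funnel-shaped hierarchy; σ and ν are sampled on the log scale with the
Jacobian included. Defaults: 32 walkers (serving as chains for split-R̂ and
ESS, computed with rank-normalised diagnostics), 1,500 warm-up and 4,000
retained moves, initialised in a small ball around the per-region closed-form
MLEs e^{−ρ̂t} = Σg_n / Σn·g_n. Convergence is reported, never enforced:
`FissionPosterior.converged` requires split-R̂ < 1.01 for every parameter.
At the calibration scale used in the tests (three regions at
ρ = 0.002/0.01/0.02 per day, t = 210 d, 200 clones each) posterior means
recover the truth within ≤ 6% at the default seed, in the correct rank
order. Note the closed-form MLE is biased low whenever ρt is large enough
for the n_max fold to bite (e.g. ≈ 25% at ρt = 4.2); the truncated
likelihood handles the fold correctly, which is why the MAP-vs-MLE agreement
check is run at moderate ρt where the closed form is valid.

## Spatial clone calling

Biopsies (2 mm discs) live on the opened colon: x longitudinal (mm), y
radial with period equal to the measured circumference. Replicate filtering
retains calls with strictly positive log probability ratios in *both*
replicate libraries and adjusted VAF ≥ 0.01% (the detection floor).

Adjacency is built per tissue section: a Voronoi tessellation of biopsy
centres with periodicity along y (realised by replicating centres at
y ± circumference and mapping ridges that touch the fundamental copy back to
the originals). Two biopsies are adjacent when their tiles share a boundary
segment of positive length — tiles touching at a point do not count — or
when their periodic centre distance is ≤ 2 mm (one biopsy diameter,
centre-to-centre). Tiles are clipped to the section's bounding box padded by
one biopsy diameter: ridge segments are reconstructed (half-infinite ridges
from the ridge normal) and clipped explicitly, so unbounded outer cells
cannot create adjacency through far-field contacts. Degenerate geometries
(e.g. collinear centres) fall back to the distance rule alone. Sections are
independent graphs; clones never span sections.

For each distinct mutation key (chrom, pos, ref, alt) the adjacency subgraph
induced on the biopsies carrying it is decomposed into connected components
(depth-first search); each component is one clone. Identity is DNA-level by
design — the same amino-acid change reached through different nucleotide
substitutions is two clones, because clonality is a DNA event. A clone's
summary VAF is the maximum adjusted VAF across its member biopsies.

## Neighbourhood integration

Spatial barcodes (one expression-cluster label each) are mapped to biopsies
geometrically: a barcode belongs to a biopsy when it lies within diameter/2
of the centre (periodic y), nearest centre winning where discs overlap. The
published workflow extracted these assignments manually in a browser; the
geometric rule is the reproducible equivalent.

- *Cluster coverage*: per-sample fraction of barcodes in each cluster
  (simplex-valued).
- *Coverage correlations*: Kendall tau-b between the tumour cluster's
  coverage and every other cluster's, across samples, with raw two-sided
  p-values (per-cluster reporting, no multiple-testing correction; a
  Benjamini–Hochberg column is available via `adjust="bh"`).
- *Tumour-associated mutation*: any non-synonymous SNV in a biopsy with at
  least 5 tumour-cluster barcodes. The tumour-cluster label (10 by
  convention here) and the threshold are configuration, since cluster
  numbering is dataset-specific. Classification is monotone in the
  threshold.
- *Malignancy score*: per gene, tumour-associated / total non-synonymous
  mutations; genes with only synonymous calls are undefined (NaN), not zero.
- *Barcode cluster probabilities*: among all barcodes in biopsies holding a
  mutation of a class (tumour-associated, or synonymous as control), the
  fraction per cluster — barcode-weighted, so large biopsies weigh more.
- *Association regressions*: OLS of per-biopsy responses (e.g. mean
  adjusted VAF below the 10% cap, or immunostain-derived clone counts) on
  per-biopsy cluster coverage, with the filter provenance recorded on the
  fit object.

## Synthetic data

The generator produces a coherent cohort at the study's scale: 16 tissue
samples, each a 6×3 grid of 2 mm biopsies (288 biopsies), 16 clusters with
tumour = 10 and epithelial-repair = 4, and a lineage-tracing arm of 9
regions (3 mice × 3) read at t = 210 days (≈ 7 months post induction) with
200 clones per region and planted rates spanning 0.002–0.02 /day.

Each sample carries a latent severity u ∈ [0,1]. Cluster labels come from a
nearest-seed partition of the cylinder (12 seed patches per sample), making
clusters contiguous; the repair-cluster seed weight grows linearly and the
tumour-cluster weight quadratically with u, and each tumour patch drags its
nearest neighbouring patch to the repair label — together these plant the
positive repair–tumour coverage correlation across samples. Planted clones
emit one identical SNV per footprint biopsy (footprints grown connected on
the true adjacency graph, sizes 1–4); tumour-class clones are seeded with
weight exp(enrichment × (tumour + repair coverage)) (default log-odds 2.5)
and their per-sample count scales with u, inflammation-class and synonymous
clones are uniform and severity-independent. Clone-level mean VAFs are
log-uniform on [0.001, 0.3] — spanning the observed range up to tumour-scale
VAFs — with per-biopsy Beta noise (concentration 30). False-positive calls
(rate 0.1 per biopsy) carry one negative replicate log-ratio so the
replicate filter removes exactly them. The gene panel (5 tumour-class, 7
inflammation-class genes) mirrors the IBD/CAC panel conceptually, not its
exact composition.

What the generator does *not* emulate: read-level sequencing error (calls
arrive as tables, as in the real workflow), expression counts (only cluster
labels), cross-section clones, germline contamination, or spatially varying
biopsy quality. Passing tests therefore demonstrate correctness of the
analysis pipeline on data satisfying its assumptions, not robustness to
upstream calling artefacts.

## Numerical and engineering choices

- The simulation loop and aggregation counts are compiled (numba); a
  readable pure-Python `step()` implements the identical rules and is what
  the unit tests exercise against the invariants. Replicate seeds derive
  from a `SeedSequence` spawn of the master seed; everything is
  bit-reproducible given the seed.
- Multinomial log-pmfs in the sampler's hot path use the gammaln/xlogy form;
  the library multinomial is kept as the oracle in tests.
- Table readers sniff the delimiter from the header, validate required
  columns by name, report malformed rows with line numbers, and parse floats
  in round-trip precision so write∘read is the identity.
- Undefined statistics (zero-denominator aggregation, constant-column
  correlations, zero-nonsynonymous malignancy scores) are NaN with explicit
  flags, never silent zeros.
- The pipeline manifest records the package version, seed, a parameter hash
  and the SHA-256 of every output; a rerun with identical configuration is
  a no-op unless forced.

## Known limitations

- The fixation-outcome rule after fusion and the f₁/f₂ correction are
  reconstructions of procedures whose exact published forms are unavailable;
  both reduce to the well-pinned neutral behaviour and are configurable.
- Printed repair times depend on an unstated lattice size and are matched
  directionally only.
- Ensemble MCMC diagnostics treat walkers as chains; walkers are not
  independent chains, so R̂ here is a necessary, not sufficient, convergence
  signal. The differential-evolution moves and the log-scale
  parameterisation were chosen precisely because the stretch move failed
  this diagnostic on the hierarchical funnel.
- Biopsy-level coverage regressions assume the barcode→biopsy map is exact;
  real capture areas lose barcodes at section edges (the generator places
  ~73% of barcodes inside some biopsy, similar in spirit to the 232/288
  biopsies captured in the motivating study design).
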