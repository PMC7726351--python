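# Methods

This note documents the statistical procedures implemented in `agstates`,
the choices made where the procedure definitions left room, and what the
synthetic validation does and does not demonstrate.

## Data model

Abundance tables are samples × taxa matrices of non-negative reals with a
unit flag (`counts`, `proportions`, or `hellinger` for square-root
transformed proportions). All proportion-like quantities live on the 0–1
scale internally; percent-valued parameters (the 1 % abundance cutoff,
the 0.5 % pseudo-count) are converted once, at the YAML config boundary,
to avoid double-scaling. Sample metadata carries reactor id, experiment
day, influent wastewater type (`simple`, `complex_monomeric`,
`complex_polymeric`, or `transition`) and sludge fraction (`mixed`,
`granules`, `flocs`). All-zero samples are retained with a warning but
excluded from distance computations, where Bray–Curtis is undefined
(zero denominator). Tables are tab-separated text; a BIOM reader is not
provided.

## Taxonomy post-processing

Upstream read processing, clustering and similarity search are outside
the package; it consumes a clusters × samples count table and a tabular
best-hit table (cluster id, percent identity, lineage).

*Cluster retention.* "At least 5 sequences per sample" admits two
readings. The default is the permissive one — a cluster is kept if it
reaches 5 sequences in **at least one** sample — because requiring 5 in
*every* sample of a multi-year, 100+-sample series would discard almost
everything. The strict all-samples reading is available via
`require_all_samples=True`.

*Rank truncation.* The lineage is cut to the deepest rank whose identity
threshold the best hit meets: 94.5 % genus, 86.5 % family, 82.0 % order,
78.5 % class, 75.0 % phylum. Comparison is inclusive (identity exactly
94.5 keeps the genus), the conventional reading of such thresholds.
Truncated ranks become `<parent>_unclassified_<rank>` placeholders
carrying the deepest retained name, so genus-level aggregation keeps
family-level identity (distinct families yield distinct genus-level
bins) and conserves per-sample totals exactly. Below 75 % identity
nothing is assigned. Relative abundances are computed **after** cluster
filtering; the alternative (normalize first) would shrink every
proportion by the filtered mass and is not offered.

## Distances and ordination

Bray–Curtis is computed with `scipy.spatial.distance.pdist`; on unit-sum
rows it equals half the L1 distance, a property the tests verify against
a direct absolute-difference evaluation. The Hellinger transform is the
entrywise square root of proportions, giving unit-Euclidean-norm rows.

PCoA is classical scaling: eigendecomposition of the double-centred
−½D². Bray–Curtis matrices are generally non-Euclidean, so negative
eigenvalues occur; the convention here is to report them but exclude
them from both the coordinates and the variance-explained denominator
(fraction of the sum of positive eigenvalues), matching common
ecology-package behaviour. The implementation is cross-checked against
scikit-bio's PCoA in the test suite. The taxonomic level of the input
table is always the caller's explicit choice: state detection operates
on the finest available (OTU-like) table, while ordinations and the
discriminant screen are typically genus-level.

## Stable-state detection

A stable state is a maximal temporally contiguous window of samples with
**all** pairwise distances strictly below the threshold (default 0.5).
The all-pairs condition is hereditary, so a two-pointer sweep finds for
each left endpoint the furthest right endpoint still valid; windows that
are not contained in another valid window are the maximal windows.

Maximal windows can overlap (e.g. [1..5] and [3..8]); reported states
must be disjoint. Overlaps are resolved greedily in temporal order:
accept the earliest-starting maximal window of at least `min_size`
samples (ties broken toward the longer window), remove its samples, and
recurse on the remaining segments. This is deterministic and yields
disjoint chronological states; it is the main interpretive choice in the
module and is validated exhaustively against a brute-force enumerator
that applies the same resolution rule to all-window enumeration.

Further choices:

- `min_size` defaults to 4 (≈ 3–4 weekly samples; long-term studies
  report states persisting six weeks or more). It is configurable; no
  minimum is inherent to the definition.
- The inequality is strict (`< threshold`), so pairs at exactly the
  threshold break a state.
- Succession is pooled across reactors by default: samples are ordered
  by (day, reactor id) in one sequence, so reactors running in parallel
  on the same influent can share a state. A `per-reactor` mode detects
  independently per reactor.
- Only `mixed`-fraction samples enter detection; granule and floc
  sub-samples supplement the mixed sample and receive the transition
  label.
- Threshold monotonicity holds at the maximal-window level (raising the
  threshold never shrinks the maximal valid window around a sample, by
  heredity) and is tested there. After greedy disjoint resolution the
  accepted state containing a given sample can in principle change
  non-monotonically, so no such guarantee is claimed for final labels.

## Discriminant-taxon screen

Stable-state samples are grouped by their state's modal wastewater type;
transition samples and states whose modal type is `transition` are
excluded. For each taxon, Hellinger-transformed abundances are compared
between the three type pairs with two-sided Welch (unequal-variance)
t-tests — the variant is not fixed by the procedure definition; Welch is
the safer default, and a pooled-variance option exists via the
underlying SciPy call. A taxon is divergent if **any** pairwise p-value
falls below the Bonferroni threshold α/n, with n defaulting to the
number of taxa tested (the correction the printed thresholds imply:
0.01/269 = 3.72 × 10⁻⁵). Degenerate pairs where both groups have zero
variance report p = 1 when means agree and are skipped (NaN) otherwise,
avoiding division-by-zero artifacts on sparse data.

Abundance is assessed on raw (untransformed) relative abundances: mean
> 1 % in at least one type. Discriminant = divergent AND abundant.

## Granule/floc comparison

Within a chosen state, each abundant taxon's proportions are compared
between granule and floc samples collected in the state's day span, with
two-sided t-tests (unpaired by default; although fractions derive from
the same mixed liquor, pairing is optional since it is not part of the
reference procedure) on abundances shifted by a 0.5 % pseudo-count. The
pseudo-count damps noise in very-low-abundance taxa; the reported
enrichment is log₂ of the ratio of pseudo-counted means, so it is
exactly antisymmetric under label swap and converges to the raw log
ratio as the pseudo-count vanishes. The Bonferroni denominator is the
number of taxa actually compared (reference analyses print both 29 and
34 for near-identical screens; parameterizing on the real count resolves
the ambiguity), and states with fewer than four samples in either
fraction are skipped with a message.

## Performance metrics

Removal efficiency is 100·(I − S)/I per analyte; total-N removal
compares the effluent inorganic pool (NH₄ + NO₃ + NO₂) with influent N,
using TKN when logged (reported separately, since amino-acid-bearing
feeds add organic N) and NH₄-N otherwise. SVI_t = (V/V_tot)/TS with TS
in g of dry solids per ml of mixed liquor, yielding ml g⁻¹ — the
standard-method definition and the only unit reading consistent with
typical reported magnitudes (tens to ~200 ml g⁻¹). Incident days can be
excluded via a per-reactor blacklist. Taxon–performance correlation uses
Pearson r with the t-distribution p (n − 2 df) over pairwise-complete
observations, after a nearest-day join within ±3 days per reactor
(biomass is typically weekly, chemistry bi-weekly); pairs with fewer
than 3 complete observations are reported missing.

## Synthetic scenarios

The generator emulates the regime structure of a multi-year two-reactor
study: weekly Dirichlet-multinomial samples (sequencing depth 20 000)
around per-regime mean compositions over 269 genus-level taxa. Regime
means are 40 % a shared power-law background (rank-offset 5, exponent
1.5) plus 60 % on a block of 8 regime-specific dominant taxa (geometric
shares, decay 0.75) drawn from the mid-tail of the background ranking.
With the default Dirichlet concentration of 200 this puts within-regime
Bray–Curtis around 0.25–0.35 and cross-regime distances above 0.6 —
i.e. clearly separated regimes on either side of the 0.5 threshold, the
situation the detector is designed for. The background head supplies
abundant-but-never-divergent taxa, so the planted truth exercises every
cell of the divergent × abundant contingency.

Paired granule/floc samples re-weight the drawn mixed composition by
√e and 1/√e for an enrichment multiplier e before renormalizing, so the
expected granule/floc ratio is ≈ e (renormalization and the analysis
pseudo-count shrink the measured log₂ ratio somewhat below log₂ e).
Performance series are baseline + Σ coeff·abundance + Gaussian noise on
a bi-weekly grid; for a taxon with abundance SD σₓ and noise SD σₙ the
planted correlation is analytically β·σₓ/√(β²σₓ² + σₙ²), which the tests
use to verify recovery of r ≈ 0.8. A phage-crash preset removes a
60 %-dominant taxon mid-regime and renormalizes, emulating a
predation-driven collapse of the dominant phosphate accumulator; the
jump in Bray–Curtis equals roughly the lost share, so the detector must
open a new state at the crash day.

What this validation shows: the detector, screen and enrichment analysis
recover planted structure under compositional count noise of realistic
depth and dimension, with family-wise error controlled under the null.
What it does not show: robustness to features of real AGS data the
generator omits — gradual regime transitions with 1–2-week community
lags, autocorrelated within-regime drift, sequencing-run batch effects,
variable library sizes, and taxa appearing de novo. Headline figures of
any specific real study (numbers of states or discriminant taxa, PCoA
axis percentages) depend on the real sequence data and upstream tool
settings and are not reproduced here.

## Problem sizes and determinism

Validation uses 50-seed replicates of the default 60-sample scenario,
200 random series for the detector/oracle comparison and 100 null
replicates for the false-positive check; each stage runs in seconds.
Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); the acceptance script derives independent
sub-seeds from its single `--seed` via `SeedSequence.spawn`, and the CLI
writes a manifest (config snapshot, input SHA-256, version, per-stage
counts) sufficient to reproduce a run bit-for-bit.

## Known limitations

- No rarefaction or library-size modelling: tables are analysed as
  relative abundances, as in the reference workflow.
- Bonferroni only; FDR and permutation alternatives are out of scope.
- The greedy overlap resolution is one defensible reading of "maximal
  cluster of successive samples"; other disjointifications (e.g.
  longest-first) can differ on pathological series.
- TSV only; no BIOM input.
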