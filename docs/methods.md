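# Methods

## Model and assumptions

`spongenet` detects miRNA-mediated (ceRNA / sponge) interactions from
co-expression alone. The underlying model is correlational, not
kinetic: an mRNA X and a lncRNA Y that compete for a shared miRNA Z are
both repressed by Z, so both correlate negatively with Z and — through
Z — positively with each other. If that shared repression is the
*only* source of their association, X and Y are conditionally
independent given Z, the first-order partial correlation

    ρ_XY|Z = (ρ_XY − ρ_XZ ρ_ZY) / sqrt((1 − ρ_XZ²)(1 − ρ_ZY²))

vanishes in population, and the sensitivity correlation
S = ρ_XY − ρ_XY|Z equals the full pairwise correlation. Conversely a
directly co-regulated pair (shared transcription factor, chromatin
domain, batch structure) keeps ρ_XY|Z ≈ ρ_XY and S ≈ 0. Conditioning
is on a single miRNA at a time; joint conditioning on miRNA sets is
deliberately out of scope.

Two boundary behaviors matter and are easy to get wrong:

* S = 0 holds **exactly** only when Z is uncorrelated with *both*
  partners. With one arm zero (say ρ_XZ = 0, ρ_ZY ≠ 0) the denominator
  still rescales: ρ_XY|Z = ρ_XY / sqrt(1 − ρ_ZY²) ≥ ρ_XY, giving a
  mildly *negative* S. The implementation follows the formula; it does
  not special-case one-armed zeros.
* The formula degenerates as |ρ_XZ| or |ρ_ZY| → 1. Cells within
  ε = 1e-12 of unit magnitude are flagged undefined (NaN) and
  propagate; they are never silently zeroed and never crash the scan.

Module classification follows the sign of the mRNA–miRNA correlation:
ρ_XZ < 0 is a *pure sponge* configuration (direct repression of both
competitors), ρ_XZ > 0 a *mixed TF-sponge* configuration (consistent
with an intervening miRNA-targeted transcriptional repressor; the TF
itself is a hypothesis, not something the method infers). ρ_XZ exactly
0 — measure-zero on real data — is reported as `ambiguous`.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `max_missing_frac` | 0.10 | genes with a missing fraction strictly above this are dropped; exactly 0.10 is kept |
| `min_utr_len` | 500 nt | mRNAs need an available 3'UTR at least this long |
| `min_pairs` | 30 | minimum pairwise-complete samples for a correlation to be defined |
| `pair_percentile` | 99 | nearest-rank percentile of the mRNA×lncRNA correlation distribution defining cognate pairs |
| `s_threshold` | 0.3 | fixed S cutoff, strict `>` |
| `s_percentile` | 99 | alternative percentile-mode S cutoff (`>=` the nearest-rank order statistic) |
| `enrichment_alpha` | 0.01 | raw hypergeometric threshold flagged in the enrichment summary |

Correlations are Pearson over pairwise-complete samples. The
`min_pairs` guard is applied as `min(min_pairs, n_samples)` (never
below 3): small complete designs stay fully defined, while residual
missingness in realistic cohorts must leave at least 30 complete pairs
per cell or the cell is flagged undefined rather than estimated from
a sliver of data. p-values (two-sided t test on r) are computed for
export but play no role in selection — selection is by correlation
magnitude and percentile only.

Percentiles use the nearest-rank definition (the ⌈p/100·n⌉-th order
statistic); realized cutoffs are always reported alongside the
requested percentile so runs on different cohorts remain comparable.
Ties at a pair cutoff are all included (`>=`); the fixed S cutoff is
strict (`>`). Cognate-pair selection takes the positive tail by
default; an anti-correlated mode (r ≤ −cutoff) is available behind the
`tail="negative"` flag.

The full (pairs × miRNAs) scan is computed as dense array algebra over
the three class-level correlation matrices — mathematically identical
to per-triplet computation (asserted by test) and the reason a
survey-scale scan of ~87,000 pairs × 311 miRNAs (~2.7×10⁷ triplets)
takes seconds on one CPU.

## Seed matching and enrichment

The seed is mature-miRNA positions 2–7 (1-based); a transcript carries
a site wherever it contains the seed's DNA reverse complement,
exact-match, U/T-insensitive, overlaps reported, `N` never matching.
mRNAs are scanned over the 3'UTR only (where site-mediated
destabilization is strongest); lncRNAs over the entire transcript.
Positions are 1-based inclusive start coordinates on the scanned
string. 6-mer exact match is the default stringency — the most
sensitive seed class — and is appropriate here because it acts as a
*refinement* of an already stringent correlation/sensitivity
selection, not as a genome-wide predictor; 7/8-mer variants can be
obtained by scanning longer sites but are not the default.

Per-miRNA enrichment uses the one-sided upper-tail hypergeometric
test with population N = all cognate pairs, K = those with dual seed
support for the miRNA, sample n = pairs selected by S for that miRNA,
k = selected pairs with dual support. The population choice is
configurable because the universe of "candidate pairs" is a modeling
decision; the cognate-pair set is the least arbitrary option and is
what the pipeline uses. Raw p-values drive the α = 0.01 flag;
Benjamini–Hochberg adjusted values are exported alongside.

## Network semantics

The MMI network is a bipartite lncRNA/mRNA multigraph: one edge per
(pair, miRNA) triplet passing both the S selection and dual seed
support. Edges are stored undirected but endpoint-typed ("outgoing
edges" of a node is a ranking device, not a causal claim). Hub degree
counts parallel edges; the distinct-partner count is always reported
next to it, since the two can differ by an order of magnitude for
promiscuous decoys. Pair weights count distinct mediating miRNAs and
sum to the edge count. Components are maximal connected subgraphs
under unweighted connectivity; each reports its modal edge label
(dominant miRNA), ties broken lexicographically and flagged. The
plain correlation network (one unlabeled edge per cognate pair) is the
permissive baseline: the MMI network is always a refinement of it on
the same pair set.

## The synthetic generator

The generator makes the model's assumptions literally true, which is
the point: it is a *calibration* instrument, not a tissue simulator.

* miRNA profiles Z ~ i.i.d. standard normal.
* Pure sponge triplet: X = −βZ + ε, Y = −βZ + ε′ with ε ~ N(0, σ²).
  Population values: ρ_XZ = −β/√(β²+σ²), ρ_XY = β²/(β²+σ²),
  ρ_XY|Z = 0, hence S = β²/(β²+σ²); at the default β = σ = 1, S = 0.5.
* Mixed TF-sponge triplet: T = −γZ + ε (latent repressor),
  X = −δT + ε, Y = −βZ + ε′. This gives the defining positive ρ_XZ,
  but note the consequence: corr(X, Y) < 0 in this configuration, so
  mixed pairs fall in the anti-correlated tail and are reachable only
  via the negative-tail pair selection. Under default (positive-tail)
  settings, planted mixed modules are intentionally invisible; the
  recovery guarantees below concern pure sponge pairs.
* Direct co-expression confounder: X = αW + ε, Y = αW + ε′ with a
  latent W independent of every miRNA — high ρ_XY (0.5 at defaults)
  but population S exactly 0. A latent factor is used instead of
  copying profiles so that S has realistic sampling noise.
* Everything else is independent noise.

Defaults describe a desk-scale cohort: 200 samples, 300 mRNAs, 60
lncRNAs, 30 miRNAs, 20 pure triplets cycling over 5 mediator miRNAs,
10 mixed triplets over 3 further mediators, 20 direct pairs. Sharing
mediators across triplets is deliberate: it reproduces the one-to-many
hub structure of real sponge programs and gives the enrichment test a
non-trivial K. Cross pairs (a pure mRNA with another pure lncRNA on
the same mediator) are genuinely sponge-coupled under the model and
legitimately enter the network; per-mediator components in the worked
example are exactly this structure.

Sequences: mature miRNAs are random 22-mers with pairwise-distinct
seeds; 3'UTRs (600 nt, comfortably past the 500 nt filter) and lncRNA
transcripts (1200 nt) are random DNA with the mediator's site written
at a recorded position in *both* partners of every planted triplet.
Every other occurrence of any planted site, anywhere, is removed by
iteratively resampling the offending window (planted windows are
protected), so the ground truth is exact: the scanner must achieve
perfect recall on planted positions and zero hits elsewhere. A
negative-binomial count emission with log2(x+1) readout is available
behind `count_emission` for count-scale realism; the Gaussian default
is the calibration condition. All randomness flows from `rng_seed`;
identical configs give bit-identical outputs, and the bundle manifest
records the config and its hash.

What passing on synthetic data does **not** show: robustness to
count-distribution artifacts, normalization and batch effects,
non-linear regulation, miRNA co-targeting of overlapping site sets, or
isoform-level site loss — real-data phenomena the generator does not
emulate.

## Numerical and design choices

* Self-correlation diagonals are set to exactly 1 via an identity fast
  path; floating-point algebra alone can land 1 ulp off.
* Expression TSVs are written with shortest round-trip float `repr`
  and parsed with correctly rounded conversion, so
  write∘read is bit-identical — determinism of the whole pipeline is
  asserted at the byte level.
* S is not clamped; negative values (suppression-like) are exported
  but never selected by default.
* Undefined correlations/scores are NaN everywhere and are excluded
  from percentile distributions and selections.
* The pipeline is run once per condition (e.g. normal vs tumor);
  condition labels live in sample metadata. No paired statistics are
  computed across conditions.
* Problem sizes in the test-suite experiments (200 samples, tens of
  planted modules, a 87k × 311 synthetic scan) were chosen as the
  smallest scales at which the closed-form predictions and separation
  guarantees are comfortably observable.

## Known limitations

* One-miRNA-at-a-time conditioning cannot attribute mediation shared
  across a seed family's members; family-level mediation statistics
  partially compensate.
* The hypergeometric universe is a modeling choice; different
  universes (all expressed pairs, all scanned pairs) shift p-values.
* The sensitivity statistic inherits Pearson's sensitivity to
  outliers and monotone-nonlinear distortions; inputs are assumed
  already normalized (an optional log2(x+1) transform is provided).
* Mixed TF-sponge modules are detected only through the
  anti-correlated selection mode, as dictated by the sign structure of
  the linear model (see above).
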