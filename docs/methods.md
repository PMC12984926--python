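# Methods

This note documents the models, rules and numerical choices behind
`phoscoreg`, the assumptions they encode, and what the synthetic corpora
used by the test suite do and do not establish about real data.

## Observation model and regulation calling

The package ingests two kinds of site-level observations. *Profiling*
records are bare detections of a phosphosite in a stand-alone dataset.
*Differential* records quantify a site in one treatment-vs-control
comparison ("condition"), belonging to a study identified by a PubMed
id, with a ratio-scale fold change and a study-level p-value.

Confidence filtering keeps **class-1** identifications: localization
probability ≥ 0.75 (inclusive — "75% or higher") **or** A-score > 13
(strict — "exceeding"). Records carrying neither field are dropped and
counted in the log. The filter is idempotent.

Regulation calling maps each differential record to one of three states:

* **U** — fold change strictly > 1.3 and p < 0.05,
* **D** — fold change strictly < 0.76 and p < 0.05,
* **N** — otherwise.

Both fold-change comparisons are strict, so a record at exactly 1.30 or
0.76 is N. Fold changes are ratio-scale; an input column
`log2_fold_change` is converted via 2^x before thresholding. A missing
p-value fails significance by default (it cannot demonstrate
study-specific significance); `allow_missing_p` inverts this for corpora
pre-filtered upstream. All cutoffs live in `DifferentialThresholds` and
are CLI flags.

Two deliberate collapses, both configurable nowhere because they define
the data model:

* **N conflates "quantified but unchanged" with "not detected".** The
  contingency cell *a* below is described as conditions where *neither
  site was detected*, which supports the collapse; corpora rarely
  distinguish the two states reliably across studies anyway.
* **Duplicate (site, condition) records** deduplicate when identical in
  called state and error when conflicting — a conflict indicates a
  curation problem that voting would silently hide.

The calls assemble into a **regulation matrix** (sites × conditions,
values U/D/N), with sites absent from a condition set to N. A condition
roster (condition → PMID) can be pre-registered so that conditions in
which *no* site was observed still contribute an all-N column; dropping
them would systematically deflate the *a* cell of every contingency
table and bias the exact test toward spurious association (this is
observable: with two sparse sites and no roster, ~38% of conditions
vanish and null pairs reject at far above nominal rates). The synthetic
generator always writes its full roster (`conditions.tsv`).

## Predominance

A site's *differential frequency* counts conditions with a U or D call
(not mere quantification); its *profiling frequency* counts distinct
profiling datasets containing it. Ranking is by differential frequency
descending, ties broken by profiling frequency descending, then position
ascending — a deterministic total order. The predominant site is the
rank-1 site of the protein of interest.

A configurable `min_fraction` inclusion rule (differential frequency ≥
fraction × condition count) exists but defaults to **0**, with a rank-1
override guaranteeing a non-empty result: a fixed 50% inclusion rule is
not generally satisfiable — in realistic corpora even a protein's most
recurrent site is typically called in well under half of all conditions
(detection is sparse), so predominance is defined by rank, not by an
absolute fraction.

## Co-regulation screening

For an anchor site and each candidate partner (by default, all sites on
*other* proteins; intra-protein pairs via a flag), per-condition joint
states are tallied: UU/DD → *d* (concordant), UD/DU → *c* (discordant),
NN → *a*, exactly one non-N → *b*. By construction a+b+c+d equals the
condition count for every pair.

**Fisher's exact test.** The 2×2 table [[a, b], [c, d]] is tested with a
from-scratch two-sided FET: the point probability of a table with the
observed margins is hypergeometric, and the p-value is the sum of point
probabilities over all admissible tables no more probable than the
observed one (the standard two-sided rule; sidedness is not otherwise
specified by the table construction). Numerics:

* factorials in log space (`gammaln`), summed in probability space over
  the ≤ n+1 admissible tables;
* the "no more probable" comparison uses relative tolerance 1e-12, so
  tables tied with the observed one up to floating-point error are
  included rather than dropped on the wrong side of an exact tie;
* if every admissible table qualifies, the p-value is returned as
  exactly 1.0 (the mass sums to one by definition);
* inputs are validated as non-negative integers; an all-zero table is an
  error.

The implementation agrees with an exhaustive exact-integer enumeration
oracle to < 1e-13 over all 135,750 tables with n ≤ 40 (the test suite
and acceptance script both recompute this), and with
`scipy.stats.fisher_exact` on spot checks; scipy is used only as a
cross-check, never as the implementation.

**Direction and filters.** A pair is positive when d > c (negative when
c > d; ties → none), with an optional `dominance_ratio` demanding
d/max(c,1) (resp. c/d) above a bar — the default 1.0 reduces to the
majority rule. High-confidence calls must satisfy *all* of: FET
p < alpha (0.05); supporting events (d if positive, c if negative) ≥
`freq_fraction` (0.10) × the anchor's differential frequency; supporting
PMIDs ≥ 3; supporting conditions ≥ 3. Supporting PMIDs/conditions are
those contributing the direction's own events — d-events for positive
pairs, c-events for negative — since those are the observations that
constitute "consistent evidence of co-regulation". Each criterion is
recorded separately in `filter_log` and the per-stage funnel is logged
at INFO.

Raw p-values are screened by default; Benjamini–Hochberg adjustment
(statsmodels) is available behind `bh_adjust` but off by default, since
the screening design is a raw-p candidate generator feeding downstream
annotation, not a confirmatory analysis. An odds-ratio column is emitted
for convenience but never filtered on.

## Conservation scoring

Site conservation within a kinase family is scored from a user-supplied
MSA (aligned FASTA or Clustal, auto-detected). The site position maps to
the alignment column whose ungapped reference index equals it; a residue
mismatch between the site and the reference sequence is an error, not a
warning.

The score is a convex combination with mixing weight w (default 0.5):

    score = w · acceptor_fraction + (1 − w) · window_identity

* `acceptor_fraction` — fraction of non-reference members whose residue
  in the site column is a compatible phospho-acceptor. S and T are
  interchangeable (an S site conserved as T in a paralog is functionally
  conserved — the canonical example being a turn-motif serine aligning
  with threonines in sister kinases); Y sites require Y.
* `window_identity` — mean per-column identity of non-reference members
  to the reference over the ±5-residue window (configurable radius)
  around the site. The window lives in *reference residue space*:
  reference-gap columns never enter it, and it truncates at sequence
  ends (no division by zero). A gap in a member counts as mismatch;
  columns where every non-reference member is gapped are skipped as
  uninformative.

A site classifies as conserved at score ≥ 0.75 (inclusive, so a score
printed as 0.75 is conserved; threshold configurable). A single-member
family scores 1.0 by convention. The score is permutation-invariant over
non-reference members, bounded in [0, 1], and never decreased by adding
a member identical to the reference.

This scoring function is this package's own fully specified surrogate
for family conservation. External resources compute family conservation
with their own unpublished formulas; no attempt is made to reproduce any
particular resource's numeric values, and validation here is
property-based, not value-matching.

## Annotation, enrichment and networks

Annotation edges (kinase_of, substrate_of, binary_interactor,
complex_interactor), disease-expression labels and GMT gene sets are
taken as user-supplied tables with provenance strings; no cross-database
confidence weighting is attempted, and any prediction-score cutoffs are
applied by the user when preparing the tables. Overlay matches edges in
either orientation between the partner and anchor proteins and never
drops calls.

Set enrichment is **hypergeometric over-representation** (upper tail
P(X ≥ k), scipy) rather than rank-based GSEA: the screened output is a
discrete protein set with no natural ranking metric to walk. Optional BH
adjustment.

Networks are built as directed multigraphs (networkx): nodes are the
anchor plus partners of passing calls (attributes: protein, residue,
position, expression direction, activity-associated flag), edges are
signed co-regulation links (`pos_coreg` / `neg_coreg`, carrying FET p
and supporting count) plus annotation edges between proteins present.
Exports: SIF, fully attributed edge TSV (round-trips byte-identically —
floats are written in shortest-repr form and re-read with Python's
correctly-rounded parser, since pandas' default CSV float parser is not)
and GraphML (validated against an independent parser, igraph, in tests).

## Synthetic corpus generator

The generator emulates a curated multi-study corpus at desk scale. Per
condition: the anchor is detected with probability θ_a and called U with
probability `up_prob`; a positive partner is detected with probability δ
given anchor detection (θ_0 otherwise) and copies the anchor's direction
with probability ρ when both are detected; a negative partner copies the
opposite direction; null sites are detected with probability θ_0 with
independent directions. Detected calls materialize as records with
direction-consistent fold changes (log-normal, rejection-truncated above
1.3 / below 0.76) and p ~ Uniform(0, 0.05); a `near_miss_fraction`
(default 10%) of records instead draws a sub-threshold fold change in
(0.77, 1.29) or a non-significant p, exercising the caller's N branch.
Near-misses are drawn independently per record, so the exact
state-copying limit (ρ = δ = θ_a = 1 ⇒ partner states identical to the
anchor's) holds at `near_miss_fraction = 0`.

Defaults — the package's study conditions, chosen once as a scaled-down
analogue of a realistic corpus (hundreds of conditions, few-condition
studies, sparse detection with the site of interest detected about
twice as often as background):

| parameter | default | meaning |
|---|---|---|
| `n_conditions` | 200 | differential comparisons |
| `conditions_per_study` | 3 | contiguous PMID grouping; makes the ≥3-PMID filter non-trivial |
| `anchor_detection_prob` θ_a | 0.5 | per-condition anchor detection |
| `null_detection_prob` θ_0 | 0.25 | background detection (half the anchor's) |
| `agreement_prob` ρ | 0.9 | direction copying fidelity of partners |
| `partner_detection_coupling` δ | 0.9 | partner detection given anchor detected |
| `up_prob` | 0.5 | direction coin |
| `fc_up` / `fc_down` log-mean | ln 1.8 / ln 0.55 | typical called effect sizes, σ = 0.25 |
| `near_miss_fraction` | 0.10 | sub-threshold records |
| `n_null_sites` | 20 | independent background sites |
| `n_profiling_datasets` | 40 | stand-alone inventories |

Studies partition conditions contiguously; one global seeded RNG stream
drives everything, so a fixed seed yields byte-identical fixture files
(a committed 30-condition golden corpus guards this across releases).

**What the generator does not model:** mass-spectrometry intensities,
missingness-not-at-random, batch effects beyond per-condition dropout,
correlated null sites, inter-study threshold heterogeneity, or multiple
sites per background protein. Passing the planted-structure tests
therefore shows the pipeline correctly recovers co-regulation of the
kind it assumes — conditionally independent detection with
direction-coupled calls — not that real corpora satisfy those
assumptions.

## Verified statistical properties

The suite and `scripts/acceptance.py` recompute, from seeded runs of the
package itself (problem sizes chosen to characterize the statistics at
desk scale):

* exactness of the FET against exhaustive enumeration, all tables
  n ≤ 40 (max |Δp| < 1e-13);
* empirical type-I error on 2,000 independent null pairs ≈ 0.03–0.07
  at nominal 0.05 (the discrete test is conservative; slight
  co-detection asymmetry of the [[a,b],[c,d]] construction keeps it
  near nominal rather than far below);
* power ≥ 0.9 (observed: 1.0) on 200 planted positive partners at
  ρ = δ = 0.9, θ_a = 0.5, 200 conditions, with zero planted negative
  partners misclassified as positive;
* predominant-site recovery ≥ 0.95 (observed ≈ 0.99) over 200 replicate
  corpora with a 2× detection-probability anchor and 100 conditions.

## Known limitations

* The FET treats conditions as exchangeable; correlated conditions
  within a study inflate effective evidence (mitigated, not solved, by
  the ≥3-PMID filter).
* The *a* cell depends on the condition roster; ingesting records
  without a roster silently restricts to conditions with ≥1 observation
  (correct for corpora where every condition assayed many sites, biased
  for very sparse corpora — supply `conditions.tsv` in that case).
* Alias normalization is table-driven; unknown symbols pass through
  upper-cased with a warning rather than failing.
* The conservation score is a surrogate; its absolute values are not
  comparable across scoring schemes, only its ordering and thresholded
  classification behavior are characterized here.
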