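# Methods

`ebbflow` implements the statistical core of a tidally replicated nearshore
eDNA metabarcoding study: a decontamination chain for an OTU-by-PCR-replicate
count table, rarefaction, and a set of community analyses that ask whether
tide, site, sampling event, or water mass structures the observed eDNA
communities. This note records the models, the numerical choices, and what
the synthetic world does and does not establish.

## The quality-control chain

The chain runs in a fixed order — occupancy filter, contamination
subtraction, discordant-replicate drop, rarefaction — and each stage only
ever removes reads and OTUs (asserted at run time by the `QCReport`
invariant).

### Site-occupancy false-positive model

Each OTU's detections are summarized per water sample (bottle) as `d_s`
detections in `K_s` PCR replicates, detection meaning count > 0 on the raw
table. The likelihood is the standard two-component false-positive occupancy
mixture

L(ψ, p11, p10) = ∏_s [ ψ · B(d_s; K_s, p11) + (1 − ψ) · B(d_s; K_s, p10) ],

with ψ the occupancy probability of a sample, `p11` the true-positive and
`p10` the false-positive per-replicate detection probability, constrained to
`p11 ≥ p10`.

Two further choices make the ML fit usable:

* **`p10` is capped (default 0.2).** Without an upper bound the model is
  unidentifiable whenever detections are homogeneous — `p11 = p10 = p̂` with
  arbitrary ψ fits exactly as well as any mixture. Assuming false positives
  are rare is the standard resolution in this model family and makes the
  saturated case (detected in every replicate everywhere) resolve to ψ ≈ 1.
* **Ridge ties resolve toward non-occupancy.** Among candidate optima within
  `1e-6` of the best log-likelihood (multi-start L-BFGS-B over
  (ψ, p11, r = p10/min(p11, p10_max)), plus grid-derived starts and two
  deterministic boundary probes), the candidate with the smallest ψ and
  conditional score is reported. Occupancy is never claimed on evidence
  indistinguishable from uniform false positives.

The *probability of occurrence* used by the filter is ψ̂ (threshold 0.80,
strict: only scores *below* the threshold are removed). The per-sample
conditional probability Pr(occupied | d_s, K_s) and its maximum over samples
are also exposed (`OccupancyEstimate.conditional`, `.otu_score`;
`occupancy_filter(..., score="max_conditional")`). The max-conditional score
is the right notion for "credibly present in at least one sample", but it
cannot drive a useful filter under maximum likelihood: any bottle with two
or more detections pushes `p10 → 0` and the conditional probability to 1,
so roughly a fifth of uniformly scattered spurious OTUs would always
survive. ψ̂ filtering reproduces the intended behavior (drastic removal of
scattered rare OTUs, retention of consistently detected ones) and is the
default.

Identical detection multisets share one fit (`fit_occupancy_all` caches on
the aggregated `(K, d)` histogram), which makes fitting ~500 OTUs a matter
of seconds.

### Contamination subtraction

Positive-control replicates (an exotic tissue control) estimate per-OTU
cross-contamination: `c_i` is the maximum proportion of OTU *i* across
control replicates. For each field replicate with depth `T`, the new count is
`max(0, floor(count − c_i·T))` — the proportion-space rule
`floor(max(0, p − c_i)·T)` computed in integer space so that `c_i = 0`
leaves counts bit-identical. No renormalization is applied; counts stay
conservative and monotone. Controls are removed from the output.

### Discordant replicates

Within-bottle Bray–Curtis dissimilarities (on proportions, so unequal
pre-rarefaction depths do not bias the comparison) feed a threshold that is
either fixed (the conventional 0.49) or fitted: normal, log-normal, gamma
and beta are fitted by ML, selected by AIC, and the threshold is the 97.5%
quantile of the winner (the upper edge of a central 95% interval). Bottles
are then cleaned iteratively: while any pair exceeds the threshold, the
replicate with the highest mean dissimilarity to its siblings is removed
(ties break to the lexicographically smallest id); bottles left with fewer
than two replicates are dropped whole. One mechanism therefore reproduces
both replicate-level and sample-level removal.

### Rarefaction

Each surviving replicate is subsampled without replacement to a common depth
(default 18,500 reads) by a seeded multivariate-hypergeometric draw;
shallower replicates are dropped and reported. Different draws of the same
replicate differ by Bray–Curtis ≈ 0.01–0.03 at the default depth, which is
why downstream analyses of a single draw are representative.

## Analyses

* **Distances** — Bray–Curtis on proportions (equal to count-based after
  rarefaction) and presence/absence Jaccard (presence = count ≥ 1), via
  scipy's pairwise kernels, labelled as `skbio.DistanceMatrix`.
* **PERMANOVA** — sequential (Type-I) partition of the Gower-centered
  squared-distance matrix over the ordered factors tide, site, event,
  bottle; each term's indicator matrix is residualized against everything
  before it, so the nested design is honored by entry order. p-values come
  from freely relabeling samples; when the number of distinct relabelings is
  at most `n_perm` the permutation distribution is enumerated and the
  p-value is exact (no add-one correction), otherwise Monte-Carlo sampling
  with the add-one correction is used. Restricted/strata permutations are
  out of scope.
* **NMDS** — non-metric SMACOF (isotonic disparities) via scikit-learn with
  `n_starts` seeded initializations, reporting Kruskal stress-1; used for
  visualization and verification only.
* **Community assignment** — average-linkage hierarchical clustering of the
  dissimilarity matrix cut at two groups. This replaces the visual
  delimitation of communities from an ordination plot with a deterministic,
  testable rule. Community 1 is canonically the cluster spanning more
  distinct sites; majority labels are aggregated per bottle and per event.
* **Constrained CCA** — chi-square standardization
  `Q = D_r^{−1/2}(P − rc')D_c^{−1/2}`, projection of the replicate dimension
  onto the column-mass-weighted span of the community indicator, SVD of the
  fitted matrix. OTU scores are principal row coordinates (chi-square-metric
  left singular vector × singular value), numerically identical to vegan's
  scaling-2 species scores (verified against `vegan::cca` in the test
  suite); the axis sign puts the community-2 centroid positive. The
  high-leverage list keeps OTUs with |score| strictly above 0.7 and at least
  1,000 rarefied reads. Note a structural property of this scaling: an OTU
  *avoiding* a minority community can score at most `sqrt(m2/m1)` in
  magnitude (column-mass ratio of the two communities), so the 0.7 cutoff
  selects OTUs enriched in the rarer water mass.
* **Temporal pseudo-autocorrelation** — per site, step 0 is the within-
  reference-event dissimilarity distribution and step t the reference-vs-
  event-t cross pairs; tie-corrected Kruskal–Wallis compares steps (omnibus
  and each step against step 0), and an OLS of pair-level dissimilarity on
  |Δsalinity| and hours-since-reference attributes excursions to water-mass
  change versus time. |Δsalinity| is used because dissimilarity is
  non-directional. Pair-level responses are not independent (pairs share
  replicates); the t-values inherit this approximation from the study
  design.
* **Association tests** — at the sampling-event level: Fisher's exact test
  (2×K, full conditional enumeration, two-sided by probability ordering)
  for community × site; Pearson chi-square without continuity correction
  (Yates optional) for community × tide; logistic regressions (capped-
  iteration IRLS) for tidal height and for salinity + temperature. Complete
  separation — expected for the covariate model, since the rare community
  lives in measurably fresher, colder water — is detected (residual deviance
  < 1e-6) and flagged rather than raised.

## The synthetic world

The generator emulates the field design: 3 sites × 4 events (alternating
incoming/outgoing tide, 6.5 h apart) × 3 bottles × 3 PCR replicates at
20,000 reads, plus 3 positive-control replicates. Its generative model is
log-normal and hierarchical, so variance components compose additively on
the log scale:

* 450 real OTUs with base log-abundance SD 1.0; perturbation SDs 0.6 (site),
  0.05 (event), 0.10 (bottle), 0.40 (PCR); tide is a pure label (SD 0) — the
  headline "tide explains least" is the simulator's null truth. Two features
  mirror real amplicon data rather than a naive nested-SD ladder: the PCR
  (amplification) noise exceeds the bottle noise — in the field data the
  residual variance share (0.13) exceeds the bottle share (0.07) — and its
  scale is itself log-normal across reactions, giving the heavy-tailed
  within-bottle dissimilarities (medians near 0.25 with occasional outliers
  beyond 0.49) that replicate-QC thresholds exist for. The pure event effect
  is near zero: in this world, as in the study's reading of its data, events
  differ when the water mass differs, not merely because time passed.
* Two water-mass communities: community 2 equals community 1 with a known
  subset of 40 OTUs enriched e^4 ≈ 55-fold (a bloom in the fresh/cold
  intrusion; closure suppresses the remaining taxa relatively). The contrast
  magnitude is set so a planted single-event switch produces a median
  Bray–Curtis excursion of ≈ 0.4–0.5 over the within-event baseline, the
  magnitude of the excursion the study observed (0.2 → 0.72). Community-2
  events occur only at the last, estuarine site — the freshwater-influenced
  end of the fjord — during `round(community2_event_fraction × n_sites ×
  n_events_per_site / n_sites)` = 3 of its 4 events at random positions,
  the observed intrusion pattern; a free per-event coin flip would let the
  intrusion land all on one tide direction and manufacture a spurious tide
  effect the real system does not show. Salinity and temperature are drawn
  from community-specific means (27/17 ppt, 10/8 °C, SD 1), i.e. the
  covariates are consequences of the water mass, not causes.
* Nuisance processes: 50 spurious OTUs appearing independently per replicate
  with probability 0.05 at 1–5 reads; a contaminant OTU at 95% of control
  depth; tag-jump leakage λ = 0.02 in both directions (field OTUs into
  controls at λ × mean field proportion; the contaminant into each field
  replicate at a rate uniform on [0, λ], with the maximum recorded in the
  truth object).

Magnitudes were calibrated during design so that the generator expresses the
study's qualitative regime — between-site dissimilarities clearly above
replicate noise but below the community contrast, every real OTU detectable
in essentially every bottle (so occupancy truly separates real from
spurious), and QC losses small enough that rarefaction at 18,500 of 20,000
reads keeps nearly all replicates. Deviating from any of these breaks
identifiable, documented things: stacking larger effect SDs makes abundant
OTUs "dark" at whole sites, which the ψ̂ filter then removes, gutting
replicate depths; making community labels site-independent pushes the
community variance into the event and tide terms, inverting the variance
ordering; suppression-style (rather than enrichment-style) community
contrasts can never clear the |score| > 0.7 CCA filter because of the
minority-mass score cap noted above.

One stability property is *not* attainable in any parameterization and its
test is left failing by design: requiring that *no* time step of a
switch-free world shows a pairwise Kruskal p < 0.01. Time-step values are
pairwise dissimilarities sharing replicates (36 reference pairs are built
from 9 replicates; 81 cross pairs from 18), and this U-statistic dependence
inflates the chi-square test's nominal 0.01 tail to roughly 8% per
comparison even when every replicate is exchangeable — measured directly
with all bottle and event effects set to zero. Across nine step comparisons
per world, a ≥ 90% quiet rate is out of reach. The calibration tests that
feed the test independent values per group confirm the implementation
itself is correctly calibrated; the gap is the independence assumption, an
approximation the time-step design inherits from the study.

What a green synthetic test does **not** establish: robustness to taxon-
correlated (compositional) noise, PCR amplification bias, sequence-level
error or chimeras, unbalanced replicate counts, or occupancy heterogeneity
among real OTUs — real rare-but-real taxa with patchy detection would be
removed by the ψ̂ filter exactly as the real study removed ~95% of its raw
OTUs.

## Numerical choices and degenerate inputs

* Occupancy optimizer bounds are `[1e-6, 1−1e-6]`; the coarse grid is 11³
  and the brute-force oracle in tests 21³ over the model's own domain.
* Distribution fits for the replicate threshold clip values to
  `(1e-9, 1−1e-9)` for the beta family; all-equal values are an error that
  asks for a manual threshold.
* PERMANOVA rank detection uses a relative SVD tolerance of 1e-8; constant
  terms get df 0, SS 0 and an undefined p-value with a warning.
* Zero-depth replicates are dropped with a warning before subtraction;
  all-zero OTU rows are dropped after every removing stage.
* Logistic IRLS caps at 100 iterations, clips η to ±35 and weights to
  ≥ 1e-12; the reported deviance is floored at the null deviance.
* Every random draw in the pipeline comes from a substream seeded by
  (run seed, CRC-32 of the stage name), so stages are independently
  reproducible and all seeds stay below 2³¹.

## Known limitations

* Free permutation only; the nested design is honored by sequential SS, not
  by restricted permutation, so small-df terms' p-values are approximate.
* The Fisher test enumerates all tables with fixed margins; it is meant for
  event-level tables (tens of events), not replicate-level ones.
* The occupancy model assumes exchangeable samples and a single (ψ, p11,
  p10) per OTU; site-level occupancy covariates are out of scope.
* BIOM support is limited to the JSON (1.0) dialect; TSV is canonical.
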