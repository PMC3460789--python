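# Methods

## Scope and model

`e3miner` treats "being an E3 ubiquitin ligase" as a domain property: a gene
is catalogued iff at least one of its protein products carries a RING
(`zf-C3HC4`), HECT or U-box profile-HMM hit with full-sequence E-value
≤ `e_max` (default 0.1, boundary inclusive — "no more than"). The
full-sequence E-value is used rather than the per-domain conditional
E-value because it is the headline per-target statistic of a HMMER search.
The catalogue is *exclusive*: a gene with hits from several families takes
the family of its lowest-E hit, with the fixed precedence
RING > HECT > U-box breaking exact ties. Isoforms collapse by an
any-isoform rule (the search runs on proteins, the catalogue counts genes).
F-box/SOCS-box adaptor families are deliberately excluded: they are complex
components rather than necessarily catalytic ligases, and restricting to
the three classical domains trades sensitivity for specificity.

## Homology summary and enrichment

Homology is group-based: one ortholog group hit by both species counts as
one homologue, which stays well-defined for many-to-many groups where
gene-pair counting does not. The summary fraction is taken over the union,
`n_shared / (n_a + n_b − n_shared)`. Enrichment of a set's homology over
the genome background is an exact one-sided upper binomial tail with
`n = union of the two sets`, `k = shared groups`, and `p0 = background
union-homology fraction` (default 15952/33868 ≈ 0.471); all four quantities
are overridable because other parameterizations of the same test are
defensible. The tail is evaluated through the regularized incomplete beta
function, which is monotone in `k` to machine precision and keeps extreme
tails (~1e-300) representable; a brute-force pmf summation serves as the
independent oracle in the tests (agreement to 1e-12 relative for n ≤ 200).
Under the default parameterization the reference enrichment for
(k=335, n=474, p0=15952/33868) evaluates to ≈ 2.4e-25; the package makes
no claim about other parameterizations of the same comparison.

## Tissue-specificity rating

Within one dataset, a gene's per-tissue z-scores are
`z_t = (x_t − μ)/s` with μ, s taken over **all** tissues of that gene
(including absent-called ones — the formula draws no exclusion) and `s` the
*sample* standard deviation (ddof = 1; population sd is available via
`sd_mode` for sensitivity analysis). Levels, most specific satisfied wins:

| level | condition |
|-------|-----------|
| A | P/A call is "A" (EST voter: count = 0) — overrides any z |
| SP | z_t ≥ 2.58 and z_i ≤ 1.96 for all other tissues |
| MS | z_t ≥ 1.96 |
| HP | z_t ≥ 1.0 |
| P | otherwise (call is "P") |

The thresholds are the two-sided normal quantiles at 68 / 95 / 99%
coverage; they are configurable but changing them changes the meaning of
the levels. A numerically constant expression vector (sd at rounding-error
scale relative to the mean) maps to all-zero z-scores, hence level P.

**Attainability.** z-scores of an n-vector are bounded: the one-hot-high
profile attains the maximum `(n−1)/√n` (sample sd). With the default
z₃ = 2.58 this means SP is structurally unreachable for n ≤ 8 tissues
(7/√8 ≈ 2.475) and reachable from n = 9 up; the rater emits an
`AttainabilityWarning` in the unreachable regime rather than silently
never assigning SP.

**EST voter.** EST (expressed-sequence-tag) count profiles have no MAS5
calls; presence is defined as count > 0 and z-scores are computed on
counts-per-million-normalized tissue columns so that library-depth
differences between tissues do not register as specificity.

**Ballot.** Each dataset votes one level per gene/tissue; genes missing
from a dataset abstain. The winning level needs the highest vote count
*and* at least `min_votes` (default 2) supporters; ties at the top resolve
to the least specific tied level (the natural generalization of the 2-way
tie rule to k-way ties, using the total order A < P < HP < MS < SP).
When no level reaches `min_votes` the gene/tissue is reported as
UNCLASSIFIED rather than falling back to any single vote — the only stated
support rule is the two-dataset minimum, and inventing a fallback would
fabricate confidence.

## Stage grouping

A gene qualifies as stage-differential when
`(max + floor)/(min + floor) ≥ fold_threshold` (default 3; the `floor`
pseudo-intensity, default 1, guards near-zero array values). Its onset is
the first stage at or above half-maximum,
`x_j ≥ min + 0.5·(max − min)`; the onset stage's phase tag gives the group
(mitotic → MI, meiotic → ME, post-meiotic → PM). The half-max rule is a
deterministic, scale-invariant replacement for manual inspection of
clustered heat maps; it implements the same verbal definition — the stage
where expression starts to increase — without an irreproducible clustering
step, which is why no clustering mode is offered. Fold filter and onset are
invariant under positive scaling of the profile when `floor` is scaled with
it. Days-postpartum series map to phases with breakpoints ≤ 8 dpp mitotic,
10–17 dpp meiotic, ≥ 20 dpp post-meiotic (the ages at which spermatogonia
and pachytene spermatocytes first dominate juvenile testis). The max/min
fold baseline is the default; a vs-first-time-point reading of
"differential" would need only a one-line change but is not exposed, to
keep one deterministic contract. Voting mirrors the tissue ballot with one
difference: NONE is an explicit vote, so a gene differential in only one
of three datasets cannot be grouped.

## Synthetic-data generator

The generators emulate the study conditions end to end: four array voters
with P/A calls plus one EST count voter over 10 tissues (testis the
target), and three stage-course voters over SG-A/pacSC/rST/eST.

* **Scale.** Values are drawn on log2 scale and exponentiated, matching
  MAS5-style intensity data; per-gene baselines are
  2^(6 ± 0.25) with measurement noise 2^N(0, 0.2) per cell and a 2%
  call-flip rate by default. The defaults are what we consider a realistic
  noise regime for between-platform microarray comparison; no estimate of
  any specific dataset's noise is implied.
* **Class mix.** Default planted proportions
  (A 15%, P 67%, HP 10%, MS 0.5%, SP 7.5%) roughly mirror the observed
  mouse-testis E3 catalogue mix.
* **Planted shapes.** Because z-scores depend only on profile shape, equal
  elevation of k tissues pins the target z at `sqrt((n−k)(n−1)/(nk))`
  regardless of fold — with 10 tissues: 2.846 (k=1), 1.897 (k=2), 1.449
  (k=3). One-hot elevation therefore plants SP exactly, but *no*
  equal-elevation pattern lands in the MS window [1.96, 2.58) at n = 10.
  HP and MS genes are instead planted with the target tissue at its
  configured fold plus secondary tissues whose height is solved by
  bisection so the target z sits at the mid-point of the level's window
  ((z₁+z₂)/2 for HP, (z₂+z₃)/2 for MS). At zero noise the rater then
  recovers every planted label exactly wherever the tissue count permits
  the label at all (`attainable_classes`).
* **Integer class sizes** come from largest-remainder apportionment so a
  given (n_genes, proportions) always yields the same planted counts.
* **Determinism.** All randomness flows from the config seed through one
  named `numpy` generator substream per dataset; identical configs give
  byte-identical outputs.

What the generator does **not** emulate: probe-level CEL data or the MAS5
algorithm itself, cross-platform probe-to-gene mapping artifacts,
correlated (batch) noise between tissues, and real tissue co-expression
structure. Passing recovery tests therefore demonstrates correctness of
the rating/balloting logic under the stated noise model, not performance
on any particular public dataset.

## Problem sizes and tolerances

Recovery checks run at 2000 genes × 10 tissues × 5 voters (panel) and
2000 genes × 4 stages × 3 voters (courses) with noise sd 0.2 log2 and 2%
call flips, thresholds ≥ 95% recovery; noiseless runs must recover 100%.
The ballot is verified against an independent restatement of the voting
rules over all 6⁵ five-voter vote combinations. Binomial tails are checked
against direct pmf summation at 1e-12 relative tolerance.

## Known limitations

* The pipeline expects one row per gene per dataset; multi-probe
  summarization is a preprocessing contract left to the caller.
* No between-dataset normalization is performed — each voter is z-scored
  internally, which is the implicit normalization of the rating scheme.
* Whether z-scores are taken on linear or log intensities is the caller's
  choice; the rater consumes whatever scale it is given (the two give
  different ratings; the generator defaults to intensity scale).
* Signal-peptide/TMD annotation is tallied from a user-supplied table
  only; no predictor is bundled.
* The enrichment test's parameterization for published headline values is
  ambiguous in general; the package documents and defaults to one reading
  (see above) and exposes every knob.
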