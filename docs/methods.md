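# Methods

This note records the statistical model, the numerical and design choices
made where the design was genuinely open, what the synthetic cohorts do and
do not emulate, and the known limitations.

## Scoring model

The package scores bipartite Bayesian-network models in which a single
binary variant node `V` may influence a binary trait node `T`. Only the
trait node's local BDeu score is computed and compared across candidate
parents: under a uniform structure prior, the parent's own marginal `P(V)`
is common to all single-edge models and cancels from every comparison, so it
is never evaluated. With equivalent sample size `ess` (default 1.0, the most
common BDeu default; the prior precision is configurable and every score
comparison in the package is ess-consistent), `q` parent configurations and
2 trait states, each cell of the conditional probability table receives the
Dirichlet pseudo-count `ess/(2q)`.

Restricted scores reuse the *same* per-configuration prior as the full
one-parent model (`q = 2`), so the carrier/non-carrier split obeys the exact
identity `M_s = M_s¹ + M_s⁰`. This identity is what makes the partitioned
score `M_s,r = M_s¹ + M_r⁰` comparable with `M_s`: the two differ only in
which estimator explains the non-carriers, and because the `V_r` search
includes `s` itself, `M_s,r ≥ M_s` holds exactly (asserted to 1e-10 in the
tests). An empty subpopulation scores exactly 0 (the marginal likelihood of
no data); a SNP with no carriers or all carriers therefore degrades
gracefully, with a warning rather than an error, and is effectively excluded
from meaningful `s` roles.

Numerics: everything stays in log space (`scipy.special.gammaln`,
`logsumexp`); raw exponentials of log marginals are never formed — at
cohort sizes in the thousands, `exp(M_s,r)` underflows double precision by
hundreds of orders of magnitude. Argmax ties in the `V_r` search and in all
rankings break to the smaller SNP index, making every output deterministic.
The pairwise counts `|{V_s = 0, V_r = 1, T = t}|` are computed as blocked
matrix products (default block: 1,024 SNPs), bounding memory at
O(block × panel) while keeping the search O(n·m²/flops-of-BLAS); a
5,000 × 20,000 panel is minutes of work on one CPU, and the 4,000 × 500
benchmark panels used throughout the tests score in well under a second.

## Individualized posteriors

Per patient, candidate SNPs are exactly the SNPs the patient carries, the
prior over candidates is uniform, and the posterior is the softmax of
`M_s,r` over the candidate set. Within one patient the posterior ranking
therefore equals the `M_s,r` ranking; across patients the same SNP can have
different posteriors because candidate sets differ. A patient carrying no
minor allele at all has no candidates and raises an error rather than
returning an arbitrary answer.

## GWAS baseline

Fisher's exact test, two-sided under the point-probability convention (the
p-value sums all hypergeometric tables whose probability does not exceed the
observed one) — conventions for two-sided exact tests differ, so this one is
pinned by an exhaustive enumeration oracle in the test suite. The reported
odds ratio is the unconditional sample OR `n11·n00/(n10·n01)` (+inf on a
zero denominator), not the conditional MLE, because it feeds the GRS
weighting where a plain odds ratio is the conventional weight. Bonferroni
correction is the only multiplicity control, matching the baseline being
reproduced.

## Preprocessing

* **Mode imputation** fills missing calls with the SNP's modal observed
  value; a 0/1 frequency tie resolves to 0.
* **Risk-allele filter** keeps SNPs with minor-allele risk ratio
  `P(T=1|V=1)/P(T=1|V=0) ≥ 1`. The boundary RR = 1 is kept. Zero
  non-carrier cases give RR = +inf → kept; a SNP with no carriers has an
  undefined ratio (0/0) and is removed — it carries no usable risk-allele
  signal and downstream scoring needs carriers. By default the filter runs
  on the full merged cohort (fidelity to the reproduced pipeline, whose SNP
  panel is post-filter); for new studies a train-only filter avoids
  test-set leakage and is available by filtering the training split.
* **D′** on dominant-coded columns treats the 0/1 column as a binary allele
  of a pseudo-haploid locus: `D = p11 − pA·pB`, `D′ = |D|/D_max` from the
  2×2 joint frequency table. No EM is needed because the package only ever
  holds 0/1 values — this deviates from diploid-genotype D′ estimation and
  is a deliberate simplification consistent with the package's data model.
* **LD pruning** scans each chromosome left-to-right by position; a pair
  closer than the window (default 500 kb, configurable — the region size is
  a free choice) with `|D′|` above the threshold (default 0.2) drops the
  lower-MAF member, ties dropping the larger position. The greedy scan is
  idempotent and leaves no retained within-window pair above the threshold.
  Which member of a high-LD pair to drop is a free design choice; dropping
  the lower-MAF SNP preserves power for downstream association tests.
  Constant columns carry no LD information and pass through.
* **HTN derivation**: +10/+5 mmHg added to SBP/DBP of medicated subjects,
  then HTN = 1 iff adjusted SBP ≥ 140, adjusted DBP ≥ 90, or medication.
  Monotone in both pressures. Missing blood pressure is an error unless the
  subject is medicated (status 1 regardless).
* **Stratified split**: cases and controls are split independently;
  `floor(fraction × n)` per stratum goes to training (so 0.8 of 930 cases
  is exactly 744). Deterministic under the seed.

## Synthetic cohorts

The generator emulates the statistical shape the individualized score is
designed for: independent dominant-coded SNPs with MAF uniform in
[0.01, 0.5] (carrier probability `1 − (1 − m)²`), and a trait drawn from a
first-match-wins penetrance model over an ordered list of causal
specifications, each optionally restricted to a carrier subgroup of a second
SNP. The benchmark scenario (`ab_scenario`) plants a rare variant
(carrier frequency ~0.03, penetrance 0.9) over a common one (carrier
frequency ~0.5, penetrance 0.4) with baseline prevalence 0.1 in a
5,000 × 500 cohort, which is stratified-split 80/20 into a 4,000-subject
discovery set and a 1,000-subject evaluation set. These sizes keep the full
ten-seed benchmark under a minute while giving the rare variant ~120
discovery-set carriers — enough for its carrier-restricted score to
dominate.

What the generator does **not** emulate: linkage disequilibrium beyond an
optional adjacent-copy-with-flips toggle (used only to exercise the pruning
path), population structure, relatedness, genotyping error and diploid
dosages. Passing the benchmark therefore demonstrates that the algorithm
recovers subgroup-specific causal structure from clean carrier data of
realistic size — not that it is robust to confounding or cryptic
relatedness, which real cohorts add.

## Evaluation

Genetic risk scores sum the weights of the top-k ranked SNPs *that the
subject carries* (k = 1 and 3 by convention) — weights are `M_s,r` for the
individualized ranking and the odds ratio for the GWAS ranking, summed
unnormalized, with min-max normalization applied to the resulting GRS
vector across the evaluated cohort (whether to normalize weights before
summation was an open choice; normalizing after matches the stated
procedure and is monotone for k = 1). AUROC uses the Mann-Whitney
formulation with ties at ½. The min-max utility maps `lo → 0, hi → 1` via
`(lo − x)/(lo − hi)`, supporting the order-reversing orientation used for
log marginals.

ROC curves are compared with a paired bootstrap by default (cases and
controls resampled separately, both score vectors indexed identically,
two-sided p with add-one smoothing, ≥ 2,000 resamples, seeded); it is
simpler to validate against first principles than an asymptotic variance.
The DeLong method is provided behind a flag for parity with standard ROC
tooling; with zero variance of the difference (identical scores) it reports
p = 1.

Information gain is plug-in Shannon entropy in bits. The paired gain
`IG(V_s, V_r; T)` defaults to the three-cell partition {V_s=1},
{V_s=0, V_r=1}, {V_s=0, V_r=0} that mirrors the model's generative story;
the textbook four-cell joint conditioning is available via `four_cell=True`.
Which definition the comparison "should" use is not settled, so both are
implemented; refinement guarantees four-cell ≥ three-cell ≥ single-variant
gain on every input, and the tests assert these exactly. No bias-corrected
entropy estimators are used — comparisons are always between sets evaluated
on the same cohort, where the plug-in bias largely cancels.

## Known limitations

* Single-parent models only: no joint (V_s, V_r) optimization per patient
  beyond the two-subpopulation scheme, no covariates, no mixed models for
  population structure.
* The BDeu prior precision is a modelling choice; rankings can shift for
  extreme `ess`.
* Dominant coding discards dosage information; D′ on carrier indicators
  understates haplotype-level LD.
* Plug-in information gain is biased upward in small cells; only
  comparisons between equally sized sets are meaningful.
* The bootstrap ROC p-value resolution is 2/(n_boot + 1).
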