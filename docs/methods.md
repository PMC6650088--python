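# Methods

## The model

`tci` treats each tumor *t* as its own causal discovery problem. The tumor
hosts a set of somatic genome alterations `SGA_SET_t` (binary gene-level
events combining non-synonymous mutations/indels with extreme GISTIC
copy-number calls) and a set of differentially expressed genes `DEG_SET_t`.
The model is a bipartite causal Bayesian network in which every DEG
*E_i* of the tumor has exactly one parent, drawn from
`{A0} ∪ SGA_SET_t`, where `A0` is a non-specific cause standing in for
unmeasured genomic events and the tumor micro-environment. The posterior of
a candidate edge is

    P(A_h → E_i | D) = (1/Z) · P(A_h → E_i) · P(D | A_h → E_i),

with Z summing the same product over all candidates of that tumor. A
candidate alteration therefore competes only with the other alterations
observed in the *same* tumor — which is what lets a rare alteration win a
DEG in a tumor where the usual suspects are absent.

### Marginal likelihood (edge score)

`P(D | A_h → E_i)` is a two-stratum Beta-Bernoulli (K2-style) marginal
likelihood evaluated on the whole cohort: tumors hosting *A_h* and tumors
not hosting *A_h* each contribute an integrated Bernoulli likelihood of the
*E_i* indicator with a Beta(α₁, α₀) parameter prior,

    P(D | A_h→E_i) = ∏_{v∈{0,1}} B(α₁ + n_{v1}, α₀ + n_{v0}) / B(α₁, α₀),

where `n_{v1}`/`n_{v0}` count DEG-positive/negative tumors in stratum
`A_h = v`. The score rewards an alteration that explains the variance of
*E_i* both in "tumors like me" and in tumors without the alteration. `A0`
has no on/off pattern, so it is scored as the single-stratum marginal over
all tumors; with one extra stratum the edge model pays an implicit
complexity penalty relative to `A0` and wins only when splitting on *A_h*
genuinely explains variance. Defaults are α₁ = α₀ = 1 (uniform parameter
prior); both are configurable, and the scoring function is a registry entry
(`tci.engine.SCORES`) so an alternative score can be dropped in.

Edge scores depend only on the (SGA gene, DEG gene) pair, so they are
computed once per cohort as a dense score matrix (vectorized `betaln`) and
shared by all tumors. Tumor specificity enters only through the candidate
set and the prior. All probability arithmetic is in log space with
log-sum-exp normalization; a cached and an uncached inference path agree to
machine precision (tested).

### Tumor-specific priors

The prior over a tumor's candidates gives `A0` a fixed mass θ₀ = 0.1 and
splits 1 − θ₀ across the tumor's *m* alterations by one of four schemes:

| scheme | θ_h ∝ | rationale |
|---|---|---|
| `mutsig` | μ_h = 1 − p_h (MutSigCV p-value) | positive selection evidence, corrected for gene length/location |
| `uniform` | 1/m | no prior information |
| `frequency` | f_h (cohort alteration count) | drivers are enriched in tumor populations |
| `weighted` | w_h = Σ_{t∈U_h} 1/m_t | frequency discounted by each hosting tumor's alteration burden |

Because *m* differs between tumors, the same gene's prior is
tumor-specific. Under `mutsig`, μ_h is floored at 1e-6 so a gene with
p = 1 keeps a vanishing but nonzero prior: the floor keeps the candidate
set identical to the SGA matrix, and a strong marginal likelihood can still
overcome the handicap (the behavior that demotes huge, frequently mutated
passenger genes by orders of magnitude without hard-excluding them). Genes
missing from the MutSig table get p = 1. θ₀ is configurable over
{0.001, …, 0.5}; `tci.analysis.a0_sensitivity` quantifies how many top-cause
assignments move as θ₀ varies — with strong signal the likelihood dominates
and the assignments barely move for θ₀ ∈ [0.05, 0.3].

Ties in the argmax cause are broken deterministically: highest posterior,
`A0` losing ties, then lexicographically smallest gene identifier.

## Calibration

Raw posteriors are not comparable across SGAs (a frequent alteration
reaches moderate posteriors by chance; a rare one cannot), so edge
posteriors are converted to empirical p-values against permutation nulls:
the DEG matrix is permuted column-wise *within each tissue of origin*
(preserving tissue structure and per-tissue DEG frequencies) while the SGA
matrix stays observed, inference is re-run, and for each SGA the posteriors
of the edges it wins (is the designated cause of) are pooled across
`n_perm = 20` permutations. The observed posterior's p-value is the
pseudo-counted upper-tail rank `(1 + #{null ≥ P_e}) / (1 + N)`, which is
never exactly zero and is monotone non-increasing in the posterior.

Two deliberate choices:

* **Winner pooling.** The null pools only designated-cause posteriors — the
  same statistic that is tested on real data. Pooling every candidate's
  posterior (available via `pool="all"`) yields a null stochastically below
  the winner distribution, hence anti-conservative p-values whose null
  rejection rate is roughly m × the nominal level. Winner pooling is what
  makes top-edge p-values uniform under the null (tested: fraction ≤ 0.05
  is 0.05 ± 0.02 on fully permuted data).
* **Per-SGA nulls with a global fallback.** Per-SGA nulls are trusted only
  above 1,000 values; smaller ones fall back to the global pool across all
  SGAs. At 20 permutations even rare alterations usually clear the bar
  because every win in every hosting tumor contributes.

The number of permutations is a cost/precision trade-off: pooling across a
gene's edges makes nulls large even at modest `n_perm`, and the p-value
resolution floor `1/(1+N)` sits far below the 0.05 decision threshold.

## Decision rules

* **SGA-FI (per tumor):** the SGA is the designated cause of ≥ 5 DEGs, each
  at empirical p < 0.05 (strict). `A0` is never callable.
* **Significant SGA-FI (cohort):** called in > 30 tumors (strict) with call
  rate ≥ 25% (inclusive), where call rate = calling tumors / altered tumors.
* **Target DEG:** designated, significant target in ≥ 50 tumors or ≥ 20% of
  the SGA's calling tumors; the fraction is the target's PPV.
* **Conserved edge:** (SGA, DEG) designated in ≥ 2 cancer types.

The 30-tumor threshold is absolute by design (an absolute evidence floor);
for desk-scale cohorts it can be lowered via configuration, and the test
suite does so explicitly where a cohort has only tens of tumors.

Downstream analyses reuse two primitives: the exact hypergeometric upper
tail (≡ one-sided Fisher) for target-set overlap between SGA pairs and for
process enrichment, with Benjamini–Hochberg control across tested
hypotheses; coverage of a gene set is simply |targets ∩ set| / |set|.
Per-tumor mechanism graphs link an SGA-FI to an enriched process when it
causes ≥ 10% (inclusive) of the tumor's DEGs inside that process.

## Preprocessing

* **Mutations:** gene-level; a tumor×gene cell is 1 iff the tumor has ≥ 1
  non-synonymous SNV or indel in the gene; synonymous/other classes never
  count.
* **Copy number:** GISTIC thresholded levels; only −2 (homozygous deletion)
  and +2 (high amplification) become events. Per cancer type, a gene whose
  −2 *and* +2 frequencies each exceed 25% (strict) of that type's tumors is
  zeroed there — both-direction calls within one type are untrustworthy.
* **SGA union:** elementwise OR of the two sources on the unioned gene axis.
* **DEG calling:** per (gene, tissue), tumor log2 expression is compared to
  the tissue-matched normal Gaussian; a gene is a DEG iff the smaller
  one-sided tail p is ≤ 0.005 (inclusive), with the direction recorded.
  Under the null the DEG rate is 2 × 0.005 = 1% (tested by simulation).
* **cis-SCNA filter:** a DEG is dropped in a tumor when the same gene
  carries a sign-concordant copy-number event there (+2 with
  over-expression, −2 with under-expression) — the expression change is
  then a dosage effect, not evidence of trans-regulation. Concordance is
  the conservative default (removes fewer DEGs); an any-event mode exists.
* **Tissue markers:** DEG columns that merely track tissue of origin are
  dropped — by default the presence rule (> 90% frequency in one type and
  < 1% in every other), with a Pearson-correlation rule (r > 0.9 against a
  one-vs-rest type indicator) available; both can be combined. Every
  removal across all rules is logged with gene, rule, statistic and type.

## Synthetic benchmark

`tci.simulate.generate_cohort` plants known causal structure: 500 tumors
over 2 tissues; 150 SGA genes of which 10 are drivers with frequencies
evenly spaced over 0.25–0.4; two 2-driver mutual-exclusivity modules whose
members never co-occur (a single uniform draw selects at most one member,
keeping marginal frequencies exact) and share one target set — the
pathway-level situation where cohort-wide association fails but per-tumor
attribution succeeds; 600 DEG genes with 20 targets per pathway (disjoint
across pathways), firing with fidelity 0.8 when a driver is hosted;
background DEG rate 0.05 and passenger SGA rate 0.03 carry no signal. An
optional Gaussian expression emitter produces a log2 matrix plus normal
reference that round-trips exactly through the DEG caller, exercising the
preprocessing path end to end.

What the generator does *not* emulate: correlated passenger structure,
copy-number segments (passengers are independent Bernoulli), expression
correlation between co-regulated genes, per-tumor mutation-burden
heterogeneity beyond what Bernoulli sampling induces, and cohort sizes or
alteration burdens at consortium scale (~268 alterations per tumor there
vs ~8 here). Passing the benchmark therefore demonstrates correctness of
the inferential machinery under the model's own assumptions, not
performance on real pan-cancer data. One consequence of the small per-tumor
candidate sets is that a single alteration can win dozens of edges in one
tumor, so isolated per-tumor chance calls do occur on permuted data even
with well-calibrated p-values; the cohort-level significance rule (> 30
tumors, ≥ 25% rate) is what drives chance designations to zero, and that is
the level at which the permutation experiments are evaluated.

Recovery is scored at two levels: significant-SGA-FI set vs planted
drivers, and qualifying (SGA, target DEG) pairs vs planted edges. An empty
call set scores precision 1 by convention (no false positives).

## Numerical and degenerate-input choices

* Scores and posteriors entirely in log space; `betaln`/`logsumexp` from
  scipy; posterior vectors renormalized to sum to 1 within 1e-9.
* A tumor with zero SGAs is retained; all its DEGs go to `A0` with
  posterior 1. A tumor with zero DEGs yields a valid empty model.
* Empirical p-values use a +1 pseudo-count in both numerator and
  denominator; p ∈ (0, 1].
* An SGA altered nowhere gets an empty per-SGA null and uses the global
  fallback.
* Single-cancer-type cohorts: the tissue-marker filter and the conservation
  rule are warned no-ops.
* The score matrix for a 500×150×600 benchmark takes ~0.1 s; the default
  20-permutation calibration ~3 s on one core. Benchmark sizes were chosen
  so the full acceptance run completes in seconds at desk scale.

## Known limitations

* One parent per DEG: synergistic multi-SGA causation is out of scope.
* Edge scores are cohort-level; only the candidate set and prior are
  tumor-specific. Per-tissue scoring is possible by running the pipeline on
  tissue subsets.
* The exact marginal-likelihood hyperparameters are a modeling choice;
  Beta(1,1) is the default, not a fitted quantity.
* Calibration assumes exchangeability of tumors within a tissue under the
  null; strong unmodeled subtype structure would make the null optimistic.
* No oncogene/tumor-suppressor directionality is inferred from the calls.
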