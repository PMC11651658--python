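# Methods

## The recurrence model

The unit of observation is the **site-allele**: a specific single-base
change (gene, CDS offset, alternative base on the coding strand). A
mutation "recurs" only when the identical nucleotide change is seen in
multiple *distinct patients*; per-patient consolidation upstream guarantees
that multiple samples of one patient count once.

Site totals use the **fractional convention**: each coding position
contributes k/3 to the missense site count *L_A* when k of its three
alternative bases are missense (likewise *L_S*, and a separately tracked
nonsense class excluded from both). Fractional counting makes
*L_A + L_S + L_nonsense* equal the number of coding positions exactly, and
it is the convention under which the unmutated classes close the books:
A₀ = L_A − Σ_{i≥1}A_i, S₀ = L_S − Σ_{i≥1}S_i. A per-allele convention is
available for sensitivity analysis.

Under neutrality we model per-site hits as Poisson with rate heterogeneous
across sites. With an exponential rate mixture of mean nE(u) (expected
neutral mutations per site in the whole cohort), the marginal recurrence
distribution is geometric,

    P(X = i) = q^i (1 − q),   q = nE(u)/(1 + nE(u)),

so the expected count of missense sites with recurrence exactly i is
A_i_e = L_A·q^i(1−q), the tail is E[A_{≥i}] = L_A·q^i, and the per-site CDF
is F(i) = 1 − q^{i+1}. This geometric form was adopted after verifying
independently that, with q calibrated as S₁/L_S, it reproduces the
published expectation tables for the breast, colon and lung cohorts to
within printed rounding (≤0.5% of every printed A_i_e); the alternative
reading of the printed cumulative-form exponent does not.

### Calibration

Two rate summaries are computed and kept distinct because both are used:

- **q = S₁/L_S** — the singleton density, which drives all geometric
  expectations. Synonymous singletons are the class least contaminated by
  selection; heavier synonymous classes may carry slight hitchhiking
  advantages and are not used for q.
- **nE(u)_total = Σ i·S_i / L_S** — the total expected neutral mutations
  per site, reported alongside q. The two differ at O(q²) plus any
  non-neutral weight in S_{≥2} (about 3% in the most mutable cohort);
  neither is silently preferred.

The per-site per-patient rate E(u) solves S₁ = L_S·n·E(u)·e^{−(n−1)E(u)}
by bracketed root-finding on [0, 1/(n−1)] (the smaller root, n·E(u) < 1,
relative tolerance 1e-12). A singleton density above the attainable maximum
n/(n−1)·e^{−1} is reported as an error ("singleton density too high"),
since no neutral rate can produce it.

### The threshold i*

i* = min{i ≥ 1 : L_A·q^i < 1}, with *strict* inequality — a tail
expectation of exactly 1 pushes the threshold up by one. For TCGA-scale
cohorts this yields i* = 3 (4 for the most mutable cohort, lung, whose
triple-hit expectation still exceeds 1). The package lets i* be computed
per cohort or fixed (the published analyses fix i* = 3 across cancer
types); excess tables report, per class, observed − expected and the
excess as a percentage of observed (the putative driver fraction).

## Downstream characterizations

**Amino-acid geometry.** Exactly 75 of the 190 unordered amino-acid pairs
are reachable by a single-nucleotide codon change under the standard code
("elementary pairs"). Each carries a physicochemical distance ΔU ∈ [0, 1];
the published scale anchors (Ser,Thr) = 0 and (Asp,Tyr) = 1 (resolved to
Tyr because Asp–Trp is not a 1-bp pair). The canonical per-pair values are
not reproduced here; a TSV loader accepts them, and a deterministic
placeholder grid (evenly spaced over the non-anchor pairs, flagged
`placeholder` in all outputs) supports fully self-contained runs.
Profiling groups CDNs by descending recurrence, accumulating whole
i-classes until a group holds ≥ 10 CDNs (a short trailing group merges
into the previous one — class-wise grouping keeps i-ranges well defined),
and reports per group the proportions with ΔU > 0.8 and ΔU < 0.4 (strict
bounds).

**Genes.** CDN-harboring genes are classified type I when an external
per-gene selection scan reports w > 1 with q-value < 0.1, type II
otherwise. The scan (e.g. dndscv) is consumed as an input table, not
re-implemented; a naive per-gene binomial A/S test is provided for offline
runs and labeled non-equivalent (no covariates, no context-dependent
mutation model).

**Pan-cancer sharing.** The site × cancer-type recurrence matrix derives
per site i_max (largest recurrence anywhere), NC (types with any
observation, i > 0), and a three-way class: multi-type CDN (threshold
reached in ≥ 2 types), single-type CDN, non-CDN. The published correlation
between i_max and sharing uses an unstated construction, so two labeled
variants are reported (per-site over multi-type rows; per-i_max medians
over all CDN rows) and neither is asserted against the published value.

**Patient burden.** CDN-level burden counts distinct CDN site-alleles per
patient; gene-level burden counts CDN genes with *any* nonsynonymous
mutation (missense or nonsense) in that patient. The two are deliberately
different resolutions: a patient with several CDNs in one gene has a
higher CDN-level than gene-level burden, while every CDN carrier has
gene-level burden ≥ 1. Expected burdens use the exact Poisson-binomial
convolution of per-CDN plug-in frequencies i/n, optionally conditioned on
carrying at least one (the published expectation construction is unstated;
both variants are emitted, labeled).

**Hallmarks.** The combination count is the exact integer product of
per-hallmark gene counts; a leave-k-out enumeration exists but is
exploratory and unvalidated.

## The synthetic-cohort generator

The generator emulates the neutral model it is meant to test: per
site-allele, patient hit counts are drawn from the geometric law with
q = (nEu/3)/(1 + nEu/3) (`exponential_mixed`, the exact marginal of
Poisson hits with exponentially mixed rates) or Binomial(n, nEu/(3n))
(`homogeneous`). The /3 spreads a site's rate evenly over its three
alternative alleles so that the singleton density S₁/L_S under the
fractional convention estimates q = nEu/(1+nEu) up to O(nEu²). Planted
driver site-alleles (missense only) receive additional independent
per-patient hits with probability f; counts add. Unmutated sites are never
materialized: a spectrum-level variant draws the number of mutated sites
as Binomial(L, P(X≥1)) and then conditional counts (memoryless for the
geometric; truncated-binomial inverse-CDF for the homogeneous model),
preserving exact marginals at genome scale in milliseconds. All outputs
are byte-identical for a fixed seed.

What the generator does **not** emulate: trinucleotide-context mutational
signatures, regional covariates of mutation rate (replication timing,
expression), clonal structure or allele frequencies, and correlated hits
within a patient. Passing tests therefore demonstrate the statistical
correctness of the machinery under the stated null, not robustness to the
rate heterogeneity structure of real tumors — on real data the exponential
mixture is an approximation whose adequacy is an empirical question.

## Numerical and design choices

- Exact integer/rational arithmetic where the quantity is exact: site
  tallies, fractional site counts (integer alt-class counts divided by 3
  at the end), hallmark products (Python big integers).
- Estimator expectation: q̂ = S₁/L_S has exact sampling expectation
  q(1−q) under the geometric law; calibration tests compare against that
  expectation, not against q, when the tolerance is tight enough for the
  O(q²) identity to matter.
- Tie-breaks: CDN output ordering is descending recurrence then
  lexicographic site key; overlapping genes resolve to the first listed.
- Degenerate inputs: S₁ = 0 calibrates to q = 0 (i* = 1); empty CDN lists
  yield empty profiles; a zero hallmark count absorbs the product; ratios
  with zero denominators are reported missing, never raised.
- QC order: germline-frequency and pipeline-concordance filters first,
  then hypermutator removal counted on the surviving coding point
  mutations (before consolidation), then donor age. The order is declared
  because the published description does not fix one; the chosen order is
  deterministic and idempotent.
- Problem sizes in tests: spectrum-level calibration runs 50 replicates at
  the 12-cohort average scale (L_A ≈ 2.16×10⁷ sites, n = 600,
  nE(u) = 2.6×10⁻³) via the sparse generator; cohort-level fixtures use
  10–20 gene models (10³–10⁴ coding positions), sizes chosen so the full
  suite completes in seconds while keeping every statistical check at ≥ 3
  standard errors of resolution.

## Known limitations

- One CDS per gene; no splice sites, UTRs, isoforms or noncoding sites.
- The ΔU placeholder grid supports structural testing only; scientific
  ΔU profiles require the canonical table as input.
- The naive gene-selection fallback is not a substitute for a proper
  dN/dS scan and is expected to be anticonservative on covariate-driven
  mutation-rate variation.
- Published summaries ship with binned high-recurrence classes
  (A_{6–9}, A_{[10,20)}, A_{≥20}); tail sums whose threshold falls inside
  a bin raise rather than guess, and the printed grand total of missense
  mutations is not exactly recoverable from the bins.
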