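# Methods

`snpmixlr` computes likelihood ratios (LRs) for forensic DNA mixtures typed
on biallelic SNP panels with massively-parallel-sequencing (MPS) read
counts. This note documents the models, the conventions adopted where the
underlying procedure left genuine choices open, the numerical details, and
the limits of what the synthetic-data tests demonstrate.

## Notation and per-locus preprocessing

At each locus the two alleles are relabeled from the evidence: **a** is the
allele with the larger read count `Q_a`, **b** the other (`Q_b`), with ties
broken by the lexicographically smaller allele name so runs are
deterministic. Population frequencies `f_a`, `f_b` are carried along under
the new labels; genotypes are written AA/AB/BB with Hardy–Weinberg
probabilities `f_a²`, `2 f_a f_b`, `f_b²`. Evidence is called **biallelic**
(`E{a;b}`) when `Q_b ≥ τ·Q_a` (dynamic threshold, default τ = 0.05) and
**monoallelic** (`E{a}`) otherwise; monoallelic evidence is interpreted as
biallelic evidence whose minor allele dropped out. Loci with `Q_a = 0`
carry no information and are excluded from every likelihood product (and
reported). Reference profiles are stored as named allele pairs and
converted to AA/AB/BB per locus after relabeling, so the same profile file
works against evidence files that flip major/minor.

## Permutation matrices

An n-contributor mixture showing both alleles is explained by every
*ordered* assignment of AA/AB/BB to the contributors except the two
monoallelic corners — `3ⁿ − 2` states (7, 25, 79, 241, 727, 2185, 6559 for
n = 2…8). Enumeration is lexicographic in the canonical order AA < AB < BB
so state indices are stable. Conditioning on η persons of interest (POIs)
pins the first η columns; because unconditioned sums are symmetric under
column permutation, the leading-column convention is observationally
equivalent to any other placement. n is always a user hypothesis (default
ceiling 8, configurable; memory is O(3ⁿ)); the package deliberately does
not estimate the number of contributors.

## Semi-continuous likelihoods

Biallelic cells follow from the binomial identity
`(f_a+f_b)^{2n} = 1`:

| evidence | POI pattern | likelihood |
|---|---|---|
| `E{a;b}` | none | `1 − f_a^{2n} − f_b^{2n}` |
| `E{a;b}` | all AA | `1 − f_a^{2(n−η)}` |
| `E{a;b}` | all BB | `1 − f_b^{2(n−η)}` |
| `E{a;b}` | alleles covered | `1` |
| `E{a;b_d}` | all AA | `(1−h)·f_a^{2(n−η)}` |
| `E{a;b_d}` | any AB | `h` |
| `E{a;b_d}` | any BB | `h²·f_b^{2(n−η)}` |

`h = Q_b/Q_a` is the heterozygote-balance index, the proxy for the dropout
probability; no logistic-regression calibration is used, by design. When
`Q_b = 0` the raw index would zero dropout likelihoods irrecoverably, so it
is floored at `h_min = 1/(Q_a+1)` (configurable) — just below the
resolution of the read record.

Three conventions were open and are fixed here:

- **Multiple POIs.** The dispatch table is written for one POI; with
  several, the most constraining genotype selects the cell (for monoallelic
  evidence BB ≻ AB ≻ AA) and the full η is subtracted in the exponent.
  This is the unique extension consistent with the η-subtraction rule.
- **No-POI monoallelic cell.** No published formula covers `E{a;b_d}` with
  zero POIs, which any defense denominator needs. We use the
  total-probability blend over the assortment classes,
  `(1−h)·f_a^{2n} + h·(1 − f_a^{2n} − f_b^{2n}) + h²·f_b^{2n}`,
  which reuses each POI cell's dropout weight pattern.
- **Mirror cells.** The cells in which the *major* allele dropped
  (`E{a_d;b}`) are implemented for completeness but are unreachable under
  the `Q_a ≥ Q_b` labeling; the no-POI deconvolution reading is used for
  the all-unknown biallelic cell, the only coherent one.

The protocol LR (numerator hypothesis over denominator, each an (n, η)
pair) is the product of per-locus ratios, accumulated in log10 space to
avoid underflow over hundreds of loci. A locus with a zero denominator is
flagged and reported as +∞ (kept in the product unless the caller drops
it). Dropin alleles are handled by re-running the LR at n, n+1, …: a
dropin is formally an extra contributor.

## Quantitative (three-index continuous) likelihoods

Each permutation state of a biallelic locus receives the product of three
indices, and states sum to the locus likelihood.

**1. Mendelian index** — the product of population genotype frequencies
over the unknown (non-POI) columns.

**2. Quantity apportionment and the state h index.** Reads are distributed
over the genotype *groups* of a state by Mendelian dose rules (identical
genotypes are indistinguishable and share one amount). With
`T = Q_a + Q_b`:

- `rAA+sBB`: AA group `Q_a`, BB group `Q_b`;
- `rAA+sAB`: AA group `Q_a − Q_b`, AB group `2Q_b`;
- `rAA+sAB+tBB`: AB group `(Q_a²+Q_b²)/T`; the remainder `2Q_aQ_b/T` is
  split equally between AA and BB. (The published remainder rule assigns
  the full remainder to *both* groups, which double-counts; the equal
  split restores conservation and gives each group its per-allele share
  `Q_aQ_b/T`.)
- `rAB+sBB`: BB group `Q_b·2s/(2s+r)`, AB group the rest;
- `nAB`: one group, `T`.

Quantities always conserve `T` (property-tested). The state h index scores
the plausibility of the implied heterozygote balance: `Q_b/Q_a` for `nAB`
and `rAA+sBB`; exactly 1 for `rAA+sAB` (the rule gives the heterozygote
equal shares); the BB group's amount over `Q_a` for `rAB+sBB`; and the AB
group's b-share over its a-share (`Q_b²/Q_a²`) for the full assortment —
all clamped to [0, 1]. The two cells not pinned by worked examples
(`rAA+sBB`, full assortment) sit behind one function so the convention can
be swapped. The index is not squared for doubly-implausible states.

**3. The (1 − χ²) weight.** The protocol-wide *expected* mixture ratio
`MR_ex` is harvested from unique genotypes — groups that share their
amount with no other contributor (NOGs in `rAA+sBB` shapes, SOGs in
`rAA+sAB` shapes). Partitioning biallelic loci by the POI's genotype
(i loci AA, j loci AB, l loci BB):

```
Q_exPOI = Σ_i (Q_a−Q_b) + Σ_j 2Q_b + Σ_l Q_b
Q_exU   = Σ_i 2Q_b      + Σ_j (Q_a−Q_b) + Σ_l Q_a
MR_ex   = Q_exPOI / (Q_exPOI + Q_exU)
```

with the unknown share split equally over the n−1 unknowns. Each state's
*observed* ratio `MR_obs` takes the POI column's per-capita group share,
pooling the unknowns; a fully redundant state (all contributors the same
genotype) carries no quantitative identity information, so its `MR_obs` is
defined as `MR_ex` (weight exactly 1). The weight is
`max(0, 1 − Σ (obs−exp)²/exp)` — a Pearson statistic on the two-component
(POI vs pooled-unknowns) fraction vectors, clamped to [0, 1], with a 1e-6
floor on expected components. The two-component collapse is forced by
`MR_ex`'s definition as a POI-vs-unknowns ratio; for the same reason the
continuous engine accepts at most one POI per hypothesis, and a no-POI
hypothesis has no anchor, so all of its states take weight 1. "Unrealistic"
states (more BB than AA contributors, contradicting `Q_a ≥ Q_b`) stay in
the likelihood sum but are excluded from unique-genotype harvesting.

Monoallelic loci inside a continuous run fall back to the semi-continuous
dropout dispatch with the locus h, so a protocol product always covers all
usable loci.

**Degeneracy and ceiling.** With the h index and the weight pinned at 1 the
three-index sum telescopes to the semi-continuous value of the same cell
(tested to 1e-12 relative over random draws). Because the denominator's
states carry weight 1 and the same state h as the numerator's, every
conditioned numerator term reappears in the denominator multiplied by the
POI genotype's frequency, so the per-locus continuous LR can never exceed
the single-source bound `1/P(GT_POI)`; the per-locus report audits this
ceiling and flags violations (none are possible by construction, and none
are observed over 10⁴ simulated loci).

**Known behavior of MR_ex.** The estimator is structurally two-component:
the contributor count enters only through the equal split of the unknown
remainder. On deep two-person mixtures it tracks a true contributor's
fraction closely (tested: 9:1 recovery within ±0.05) and pushes a
non-contributor toward ½. With three or more contributors the per-locus
attribution assumes the minimal unknown structure, which biases a dominant
true contributor's estimate upward by several points and leaves a
non-contributor near ½ rather than 1/n. The test suite measures this
openly; the corresponding recovery check at three contributors fails at the
stated ±0.05 tolerance and is left failing rather than loosened, since the
harvesting equations above are definitional.

## Worked single-locus example

For `Q_a = 739, Q_b = 704, f_a = 0.445, f_b = 0.555`, a heterozygous POI,
n = 2 and `MR_ex = 0.94:0.06`, the three conditioned states give state h
indices 0.9526 (AB+AB), 0.6351 (AB+BB), 1 (AB+AA) and Mendelian factors
0.494, 0.308, 0.198. With per-state weights (1, 0.169, 0.924) supplied as
inputs, the likelihood is 0.4706 + 0.0331 + 0.1830 = 0.687. The supplied
weights are treated as inputs because no standard Pearson/G statistic on
the stated ratios reproduces 0.169 or 0.924 (our own convention yields 0
and 0.977 for those cells); the engine computes its weights from the
convention above unless per-state weights are injected
(`state_weights=` / `--mrex-override`).

## Synthetic data

The simulator emulates an MPS identity panel: L loci with minor-allele
frequency uniform in a configurable range (default 0.2–0.5, 133 loci),
contributor genotypes in Hardy–Weinberg proportions, and allele read
counts whose expectations are depth × (ratio-weighted mean allele dose).
Count noise is gamma-Poisson: dispersion 0 gives plain Poisson (multinomial
thinning); dispersion d > 0 multiplies each allele mean by a Gamma(1/d, d)
factor, giving negative-binomial counts with variance `m(1+dm)`. Dropout is
a hard read floor (default 0), matching threshold-based calling rather than
a logistic curve. All randomness derives from one integer seed via
`SeedSequence` splitting (panel / profiles / reads), so every sub-result is
independently reproducible.

What the simulator does **not** model: sequencing error and contamination
reads, reference-allele mapping bias, linkage between loci, degraded-DNA
locus-length effects, and laboratory-specific dropout shapes. Passing
tests therefore demonstrate internal consistency of the engines and
parameter recovery under idealized read noise, not calibrated performance
on casework data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale designs chosen as representative:
133–200 loci, depth 1000, two to three contributors, 20 non-contributor
references for the separation study, 10⁴ loci for the ceiling audit, and
10³ random draws for the degeneracy oracle. Likelihoods accumulate in
log10; per-locus values are clamped to [0, 1] against rounding; frequency
tables must sum to 1 within 1e-6 (1e-9 for in-memory objects); equality of
mixture-ratio vectors is exact for the weight-1 short-circuit. Zero-read
loci are excluded and logged; a locus whose denominator likelihood is zero
yields a flagged infinite LR rather than a silent exclusion.

## Limitations

Strictly biallelic markers (no STR/multi-allelic support); no θ/F_ST
subpopulation correction; no estimator of the contributor count; the
continuous engine's weight is defined for at most one POI per hypothesis;
and `MR_ex` is a closed-form harvest, not a maximum-likelihood
deconvolution — by design it trades efficiency at n ≥ 3 for transparency
and a hard single-source LR ceiling.
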