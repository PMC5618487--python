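# Methods

## Encoding model

A protein sequence of length `L` over the 20 canonical residues is encoded
as a vector of `400 + nλ` components.

**Dipeptide block.** The 400 ordered residue pairs are enumerated
first-residue-major (`AA, AC, …, AY, CA, …, YY`); component `u` is
`f_u = count(u)/(L−1)`, so the block sums to exactly 1. The enumeration
order is a convention, not a model choice; it is recorded in the feature
names so serialized matrices are self-describing.

**Correlation block.** For each property `k` of an `n`-property table and
each lag (tier) `t = 1..λ`, the factor
`τ = (1/(L−t)) Σ_i h_k(R_i)·h_k(R_{i+t})` averages the product of
standardized property values over all residue pairs at that lag. Components
are ordered tier-major (tier 1 properties 1..n, then tier 2, …). Larger λ
captures longer-range order; a sequence must satisfy `L > λ`, and shorter
sequences are rejected rather than padded because the tier average is
undefined there.

**Merging.** With weight `ω ≥ 0`, the final vector is
`P_u = f_u/D` (first 400) and `P_u = ω·τ_u/D` (rest), with
`D = Σf + ω·Στ = 1 + ω·T`. The vector sums to 1 whenever `D ≠ 0`.

### Degenerate normalization

Standardized property scales are zero-mean, so `τ` and hence `T` can be
negative; when `ω·T ≤ −1` the normalizer vanishes or flips sign and the
components become unbounded or sign-inverted. We raise an explicit
`EncodingError` at `D ≤ 1e−9` instead of emitting such vectors. On
uniform-random sequences this occurs in roughly 1–7% of draws at the largest
`λ` and `ω` values (more often for short sequences); on sequences with the
mild compositional structure of real proteins and moderate `ω` it is rare.
Negative `τ` values are kept as-is — no clipping or shifting — so the two
block masses are `1/(1+ωT)` and `ωT/(1+ωT)`, either of which may exceed 1 or
be negative while the total stays 1.

## Property table

The default registry entry `default9` holds nine per-residue scales:
hydrophobicity (the classic pseudo-composition scale), hydrophilicity
(Hopp–Woods 1981), side-chain mass, pK of the α-COOH group, pK of the
α-NH3+ group, isoelectric point, average flexibility (Bhaskaran–Ponnuswamy
1988), a rigidity scale derived as `2 −` the Vihinen et al. (1994)
normalized flexibility index, and normalized side-chain van der Waals
volume (Fauchère et al. 1988). The derived rigidity scale is affinely
equivalent to negated Vihinen flexibility, which is all the encoding sees
after standardization. Any `n ≥ 1` table can be supplied instead (TSV: a
header of the 20 residue letters in alphabetical order, one property per
row); every operation takes the table as a parameter.

**Standard conversion.** Each row is mapped to
`(h0 − mean)/sd` with the population SD (denominator 20). This choice makes
the conversion satisfy both of its defining properties — zero mean over the
20 residues, and idempotence (a standardized row is a fixed point) — which
the sum-of-squares variant (no /20) also satisfies but with SD `1/√20`; the
population form is the conventional z-score and is what the tests pin down
(zero mean and idempotence within 1e−12, affine invariance
`std(ax+b) = sign(a)·std(x)`). A constant row has no information and raises
an error naming the property.

## Feature selection

Each feature gets a one-way ANOVA F value `F = MSB/MSW` with
`MSB = Σ n_i(m_i − m)²/(K−1)` and `MSW = Σ_i Σ_j (x_ij − m_i)²/(N−K)`
(group means inside MSW). Edge cases are made total and deterministic:
`MSW = 0, MSB > 0` → `+inf` (a perfect separator on the training data,
sorted first); `MSB = 0` → `0`, with a warning when the feature is constant
everywhere. Ties in the ranking break by ascending original feature index.
The implementation is cross-checked against an independent one-way ANOVA
(scipy) to 1e−10 on random data.

IFS evaluates an injected accuracy function on the top-k prefix for
`k = 1..M` (a `stride` option coarsens the scan for speed, always including
`k = M`) and returns the smallest `k` attaining the maximum — parsimony as
the tie-break. The production evaluator is jackknife SVM accuracy at fixed
hyperparameters; re-tuning the grid inside every prefix is possible by
passing a different evaluator but is quadratically expensive.

## Classification and evaluation

The SVM uses the RBF kernel `exp(−γ‖x−y‖²)` with one-vs-one multiclass
decomposition (libsvm via scikit-learn). The default tuning grid is
exponent ladders `C ∈ {2^−5, 2^−3, …, 2^15}` and
`γ ∈ {2^5, 2^4, …, 2^−15}` — 11 × 21 = 231 pairs — searched exhaustively;
ties break by smaller `C` then smaller `γ`, independent of enumeration
order. A 4×4 `reduced_grid()` subset exists for demos and smoke runs. No
additional feature scaling is applied before the SVM: the encoding already
normalizes each vector to unit sum. No class weighting is applied; the
evaluation reports AA alongside OA precisely so imbalance is visible rather
than corrected.

**Jackknife.** Each of the N samples is predicted by a model trained on the
other N−1; the N held-out predictions form the confusion matrix from which
`Sn/OA/AA` are computed. The procedure is deterministic given deterministic
training, and every class needs ≥ 2 samples so no fold loses a class.

**Tuning protocol.** The default "pooled" mode tunes `(C, γ)` once
on the full dataset and jackknifes with them fixed. This is mildly
optimistic — every held-out sample influenced the tuning — and the library
logs a warning saying so. A "nested" mode re-tunes inside every fold; it is
the unbiased protocol at roughly N times the cost and is provided for users
who need honest generalization estimates.

**Encoder parameter tuning.** The `(λ, ω)` grid is λ = 1..30 step 1 crossed
with ω = 0.05..0.70 step 0.05 (420 combinations), enumerated by
`parameter_grid()`; selecting over it means re-encoding per combination and
is left to the user's budget.

## Hierarchical flow

Three independently trained bundles chain into IC/NIC → VGIC/LGIC → four
VGIC types. Each bundle carries its own encoder parameters, selected
features and property table, since the optimal `(λ, ω)` differ per stage; a
record shorter than a stage's λ yields an explicit `unencodable` verdict
with the stage named. An NIC decision at stage 1 (or LGIC at stage 2)
short-circuits the remaining stages.

## Synthetic data

The generator draws residues i.i.d. from a background distribution (default
uniform — the simplest null) and plants signal two ways:

* **dipeptide enrichment**: for each planted dipeptide with multiplier `m`,
  `round((m−1)(L−1)·p_a·p_b)` extra copies are stamped at non-overlapping
  random positions, bringing its expected count to ≈ `m×` background. A
  spec whose planted mass would occupy more than half the sequence raises
  as infeasible.
* **periodic property patterns**: positions are periodically biased toward
  hydrophobic vs. hydrophilic residue subsets, creating lag-`period`
  autocorrelation visible only to the correlation features.

Default study conditions: the two-class preset uses 60+60 sequences of
length 200 with 5 planted dipeptides at enrichment 8 — strong enough that
the planted features should top the ANOVA ranking, weak enough that single
features are imperfect separators. The hierarchy preset mirrors the class
sizes of the curated benchmark this workflow targets (300 NIC, 150 LGIC,
81/29/12/26 VGIC types), lengths 250–400, nested signals (an IC-wide
signature, a VGIC-wide signature, and per-type pairs) at enrichment 6; the
acceptance script runs it at scale 0.3 with enrichment 8 so the smallest
class keeps ≥ 4 samples, and the test suite at scale 0.15.

**What passing on synthetic data shows — and does not.** Success
demonstrates that encoding, ranking, selection, tuning, evaluation and the
hierarchy are implemented correctly and can recover signal that genuinely
resides in dipeptide composition or lagged property correlation. It does
not demonstrate real-world ion-channel accuracy: real sequences have
compositional biases, domain structure, homology between train and test
items, and far subtler class signal than planted enrichment. Reported
accuracies on synthetic presets (typically 100%) are properties of the
planted signal strength, not claims about biological data.

## Numerical choices

* Normalizer guard `D ≤ 1e−9` → error; vector-sum assertion tolerance 1e−9.
* Standardization tolerances 1e−12 (zero spread detection, idempotence).
* ANOVA zero-detection tolerance scales with the squared data magnitude;
  F edge cases as above.
* All stochastic components (generator, SVM state) are seeded explicitly;
  identical seeds give byte-identical FASTA and evaluation reports.
* Problem sizes in the test suite and acceptance script (e.g. hierarchy at
  scale 0.15–0.3, reduced 4×4 grids, stride in demo IFS scans) are chosen to
  keep full runs in the minutes range on a single CPU while leaving every
  code path exercised at study conditions; the two-class acceptance run uses
  the full-size preset (120 sequences, full-depth IFS).

## Known limitations

* The nine default property scales are a documented, reasonable set; they
  are not guaranteed to equal any particular historical model's scales, so
  absolute feature values differ across property choices (the pipeline is
  invariant in structure, not in numbers).
* The pooled tuning protocol overestimates accuracy; use nested
  mode for unbiased estimates.
* No redundancy filtering is performed; the 40%-identity contract for
  curated datasets is the caller's responsibility (external clustering
  tools operate on metadata and scale this package does not reach into).
* IFS with a jackknife evaluator is O(M·N) SVM fits; for large M use the
  stride option or a cheaper evaluator.
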