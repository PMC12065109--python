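# Methods

## Model

A pore model assigns each k-mer x an expected current level. When a base
inside x is modified, the observed level shifts. The package models that
shift additively:

    v̂(x) = v(x) + h_m + Σ_{(f,b) : x_f = b} h_{m,f,b}

where v is the canonical level, m the (1-based) position of the modification
inside the k-mer, h_m a per-position shift, and h_{m,f,b} pattern shifts tied
to base b occurring at flank position f. The assumptions are:

* **Additivity** — flank effects combine by summation; no interaction terms.
* **Context locality** — all information about the shift is in the k-mer
  window itself.
* **Single-modification training** — rules are derived only from k-mers
  carrying exactly one modification whose motif lies completely inside the
  window. K-mers with several modifications are *imputation targets only*:
  their shift is the sum of the per-position shifts. Because application is
  purely additive, the order in which positions are processed cannot change
  the result.
* **Sign convention** — ΔC = modified − canonical throughout, so a negative
  rule lowers the expected current of the modified k-mer.

Rule derivation is a greedy median-residual decomposition (see README for
the loop). Medians rather than means make the extraction robust to a
minority of discordant or noisy training k-mers; the median of an even-sized
group is the mean of the two central values. Ties in |median| are broken by
the smaller flank position, then alphabetical base, which makes the derived
rule list a deterministic function of the training table (and invariant to
its record order). Derivation is performed once globally per modification
position; imputation is then a pure lookup-and-sum, which is equivalent to
re-running the per-k-mer formulation under the subgroup-wise residual
subtraction used here.

Pattern candidates exclude the motif footprint: inside the footprint the
base is constant across the group, so its median residual is zero by
construction and a rule there would be vacuous.

## Parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| `r` | 0.01 | model units (pA for typical tables) | stopping threshold: extraction at a position ends when no candidate pattern's median residual exceeds r. The value must be rescaled if the table is not on a pA-like scale; the CLI warns when r looks inconsistent with the table's level span. |
| `min_group_size` | 1 | k-mers | smallest training group a pattern rule may be built on. 1 reproduces the reference behaviour; larger values suppress rules fitted to a single noisy observation. |
| `max_iterations_per_position` | 1000 | iterations | guard against floating-point oscillation of re-selected patterns; exceeding it raises an error naming the oscillating pattern. |
| `stdv_increment` | 1.0 | model units | added to level_stdv of alphabet-expanded placeholder entries, marking them untrained (the convention the surrounding toolchain uses). Imputed entries instead inherit the canonical counterpart's stdv unchanged: the +1 marks "untrained", it is not a property of trained values. |
| `target_fraction` (T) | — | fraction | coverage of all complete-motif modified k-mers the training-site selection must reach. |

## What the synthetic generator emulates

`synthetic` produces: i.i.d. random genomes with adjustable GC content;
complete canonical tables with levels uniform in 60–130 and spreads in
1.5–4 (pA-scale, mimicking R9-era 6-mer models); ground-truth rule sets with
shift magnitudes 0.5–5 (the scale of real per-position and flank effects);
forward-applied modified tables; Gaussian training noise on modified levels
only (the canonical table is treated as known, matching the usual setup
where an existing canonical model serves as the basis); and trained subsets
drawn either uniformly over k-mers or via genomic site selection.

Default study conditions used by the end-to-end tests: k = 6, CpG scheme,
10 pattern rules, σ = 0.2, T = 25 % by site-based holdout on a 50 kb random
genome — a quarter coverage of the 1280 modified 6-mers, the regime where
rule learning is expected to stabilize.

**Identifiability and the "balanced" generator default.** The additive rule
decomposition of a ΔC table is not unique: e.g. two same-sign pattern shifts
at one flank position displace their position-group median, and derivation
then converges to a different—but observationally equivalent—rule set (the
imputed table is identical while individual shifts differ). So that
shift-recovery tests are well-posed, the generator lays pattern rules out as
opposite-sign pairs within a (position, flank) slot, which keeps every group
median centred and makes the ground truth the unique fixed point of the
derivation. An `balanced=False` mode draws unconstrained rule sets; for
those, only imputed-table agreement (not per-shift identity) is a meaningful
target.

What the generator does *not* emulate: real flank effects are correlated
with k-mer chemistry rather than i.i.d.; real training noise is not Gaussian
and varies with per-k-mer read depth; real genomes have motif-density
structure (CpG islands) that makes site selection less uniform; enzymatic
conversion is incomplete, which biases, not just perturbs, trained levels.
Passing tests therefore demonstrate correctness of the algorithm and its
statistical behaviour under the stated noise model, not calling accuracy on
sequencing data.

## Numerical choices

* Medians via `numpy.median`; even groups average the two central values.
* Selection requires a strictly larger |median|, so the first candidate in
  (f ascending, b alphabetical) order wins ties — derivation is
  deterministic and record-order invariant.
* Residual subtraction applies only to the k-mers matching the selected
  pattern, and a rule is added to a target k-mer only when it matches;
  pattern matching is against the k-mer as written, so a position holding a
  modification code never matches a canonical pattern base.
* A pattern may be re-selected in later iterations; shifts for the same
  (m, f, b) key are summed when comparing rule sets.
* Model files are written with fixed 6-decimal formatting and
  lexicographically sorted k-mers, so equal models produce byte-identical
  files; rule shifts serialize via `repr` for bit-exact round trips.
* Degenerate inputs: an empty training table raises; a position group of
  size 1 yields its delta as the position rule and no pattern rules (no
  candidate group passes `min_group_size` with a nonzero residual).
* Site selection accepts a site only if it contributes a new k-mer and
  stops at the first acceptance reaching T, so overshoot is bounded by one
  site's contribution (≤ k − |motif| + 1 k-mers).

## Design choices

* **Strand handling** defaults to both strands in genome scanning: common
  methylation motifs are reverse-complement palindromic at motif level but
  their flanks differ, so reverse-strand sites contribute distinct k-mers.
  Sites are not deduplicated across strands; the covered-k-mer union makes
  double counting harmless.
* **Incomplete-motif k-mers** (motif running off the window edge) are
  excluded by default everywhere: no significant shifts are attributable to
  them and counting them (2304 instead of 1280 at k = 6 for CpG) would pad
  coverage percentages with uninformative contexts. A flag re-enables them
  for both enumeration and imputation; imputing them applies no rules (their
  modification position carries none), leaving canonical levels.
* **Trained inventory** is supplied explicitly; `detect_trained_kmers`
  offers the placeholder-stdv heuristic (entries still at canonical stdv + 1
  are untrained) as a logged convenience, not a default.
* **Comparison space**: `compare_models` works on raw levels by default and
  in ΔC space when given the canonical table — the two differ by the
  canonical level variation, which inflates level-space correlations.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
k ≤ 6 tables (4096 canonical + 1280 modified entries), 50 kb genomes, and
five-seed replicates for the noisy-recovery study. These sizes were chosen
as the smallest at which the statistical claims (quarter-coverage recovery,
sub-noise RMSE) are comfortably non-trivial; the algorithm itself is linear
in the number of trained k-mers per iteration and handles k = 9 tables
without modification.

## Known limitations

* No modelling of level_stdv changes under modification, nor of event
  duration statistics (sd_mean / sd_stdv are carried through unchanged).
* Additivity ignores flank–flank interactions; contexts whose shift is
  genuinely epistatic will be imputed with the best additive approximation.
* Multi-modification imputation assumes per-position effects add; there is
  no training data path for multi-modification k-mers.
* The downstream step — using imputed tables in an HMM caller to assign
  per-site log-likelihood ratios — is outside this package.
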