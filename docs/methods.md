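# Methods

## Model and assumptions

`dmi` targets one specific causal pattern: a post-translational modulator M
(kinase/phosphatase) whose presence activates a transcription factor, which
in turn co-regulates a known set of d target genes.  The method assumes

- M's mRNA level is a usable proxy for its protein activity, so sorting
  samples by M's expression separates "modulator present" from "modulator
  absent" regimes;
- the TF's activity is visible as *joint* dependence among its targets, not
  necessarily as correlation between the TF's own transcript and the
  targets (the TF expression level is deliberately never used);
- samples in the compendium are exchangeable draws (no batch/lineage
  structure is modelled).

Dependence among the d targets within a sample bin is quantified by the
Rényi multi-information of order α, estimated via the empirical copula
transformation followed by a generalized nearest-neighbor-graph entropy
estimator, Ĥ = 1/(1−α)·log(L_p/(γ·n^(1−p/d))) with p = d(1−α), and
Î = −Ĥ on the copula sample.  The statistic for a candidate modulator is
ΔI = I_HIGH − I_LOW between the top and bottom expression bins.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.99 | Rényi order; close to 1 so Î approximates the classical multi-information while keeping the estimator's p = d(1−α) > 0 valid. Must lie in (0, 1): the α = 1 limit degenerates (p = 0) and is not implemented. |
| `neighbor_set` S | (1, 2, 3) for the plain estimator; (1, …, 10) in the ranker | Neighbor indices of the NN graph. The graph-length variance enters Ĥ multiplied by 1/(1−α) = 100, so with bins of only ~33–50 profiles that variance dominates ranking error; averaging over ten neighbor indices roughly halves it. At compendium-scale n the choice is immaterial. |
| `n_bins` | 3 | Contiguous equal bins after sorting by modulator expression; ΔI always contrasts the first and last. When the sample count is not divisible the remainder goes to the earliest (Low) bins — any deterministic rule works, this one is documented and stable. |
| `fc_threshold` | 1.0 (log2 units) | Prefilter on the modulator's own between-bin change. A difference of bin means on log2-scale data (2-fold linear); the literal ratio-of-means reading is available via `fc_scale="ratio"`. `None` disables the filter — appropriate for data not on a log2 scale, including the synthetic benchmarks here (mean-0/1 Gaussian units, where a log2-unit cut is meaningless and would remove planted modulators in the skewed-bin variants). |
| `n_permutations` L | 10,000 | Null draws per candidate: random d-gene sets (drawn from all genes except the candidate itself; known targets are not excluded) scored with the same bins. p = #{ΔI_null > ΔI_obs}/L, so p = 0 is possible; `pseudo_counts=True` switches to (r+1)/(L+1). |
| `min_bin_size` | 20 | Bins smaller than this are refused (estimate too unstable); the affected candidate is skipped with a logged reason. |
| calibration (n, reps, reference) | matched n, 20 reps, `"copula"` for RMI / `"uniform"` for raw entropy | See below. |

All randomness flows from explicit integer seeds: the generator seed, the
ranker's `random_state` (from which per-candidate permutation streams and
the γ calibration are derived deterministically, independent of evaluation
order), and per-call seeds in the samplers.  Same seed ⇒ bit-identical
output.

## γ calibration

γ is the constant of the nearest-neighbor graph-length limit; it depends on
(d, p, S).  It is calibrated empirically as the mean over 20 replicates of
L_p(U)/n^(1−p/d) on reference samples U whose Rényi entropy is exactly 0,
and cached in a `GammaTable` keyed by (d, p, S, n, reference) with a
tab-delimited on-disk format.

Two choices matter, both because the 1/(1−α) = 100 prefactor amplifies any
multiplicative offset in L_p a hundredfold:

- **Calibration at the matching n.**  The finite-sample value of
  L_p/n^(1−p/d) approaches its limit slowly; calibrating at a single large
  n and reusing the constant elsewhere leaves a bias of −1.6 nats at
  n = 33 (a typical bin) and −0.02 nats at n = 4,000 (measured on
  independent Gaussians).  Calibrating at the n of the analyzed sample
  removes this exactly; the cache makes the cost negligible because a run
  touches only a handful of distinct n values.  With equal-size bins the
  γ factor cancels in ΔI altogether, so this choice mainly protects the
  absolute RMI values.
- **Calibration reference.**  For raw-sample entropy the reference is
  i.i.d. uniform draws on [0,1]^d (`"uniform"`).  For multi-information the
  estimator only ever sees copula-transformed data, whose columns are
  permutations of the grid {1/n, …, 1} — under independence, uniformly
  random permutations.  Calibrating on copula-transformed uniforms
  (`"copula"`) therefore centres the null exactly; measured at d = 3,
  n = 4,000 this moves the null mean from −0.010 to −0.003 nats.

## Numerical and degenerate-input conventions

- Copula ties use the maximum-rank ("≤") convention; tied values map to
  equal copula values, and every column's maximum is exactly 1.
- Duplicate points produce zero-length NN edges that contribute 0 to L_p,
  with a warning (the log of the total is taken); an all-zero total is a
  degenerate-input error.
- Exact all-pairs distances are used below n = 700 (and a batched
  all-pairs kernel for the thousands of small permutation samples); above
  that, tree/chunked exact kNN via scikit-learn.
- Ranking key: signed ΔI descending, ties by ascending p-value then gene
  id.  The normalized ΔI/(I_HIGH+I_LOW) is emitted with its own secondary
  ordering but is not the within-TF key: its denominator is a noisy
  near-zero quantity for unmodulated candidates and the ratio explodes
  (measured on D1 it demotes up to 7 of the 20 planted modulators).  Its
  role is comparability of hits across TFs with different target sets.
  When I_HIGH + I_LOW = 0 the normalized value is NaN.
- BH adjustment is applied across the candidates actually tested; adjusted
  p-values are ≥ raw ones and monotone in the raw ranking.
- Enrichment p-values are two-sided on |ES| (uniform under a randomly
  ordered ranking); the running sum uses weight exponent 1 by default, 0
  giving the classic Kolmogorov–Smirnov form.

## Synthetic benchmarks

The generators reproduce the standard validation setup.  D1: 100 profiles,
60 genes — 10 targets, 50 candidates of which 20 effective, 10 hidden
(unknown) targets and 20 decoys.  D2: 760 genes, 750 candidates, 50
effective, no hidden targets.  Skewed variants of D2 make the co-regulated
subset 30/40/60/70 of the 100 profiles, so any modulator bin is a noisy
mixture.  In the co-regulated subset, targets (and hidden targets) are
drawn from a zero-mean Gaussian with off-diagonal covariances ρσ²_ij,
ρ = 0.6, σ²_ij ~ U(0, 0.5); elsewhere the covariance is diagonal.
Effective modulators are N(1, 0.1) where co-regulation is on and N(0, 0.1)
where it is off (the second parameter is read as a variance; a flag flips
to sd).  Decoys are zero-mean with per-gene variance in (0, 0.5).  Columns
are shuffled so only expression — not sample order — can separate the
subsets.  Two details are this package's own resolution of ambiguities:
the literal covariance recipe is not guaranteed positive definite, so
eigenvalues are clipped at 10⁻³ before sampling (the realized matrix is
what the closed-form truth is computed from, where applicable); and hidden
targets are treated identically to known targets (co-regulated only in the
dependent subset).

What the generator does *not* emulate: probe-level measurement noise,
batch or tissue structure, realistic (sparse, heavy-tailed) expression
marginals, more than one TF, or modulators whose effect is partial rather
than on/off.  Passing benchmarks therefore demonstrate the machinery —
estimator calibration, binning, ranking, significance — under the model's
own assumptions, not performance on a real compendium.

Convergence of the estimator is exercised against exact references:
the closed-form order-α multi-information of a Gaussian with correlation
matrix R, I_α = [log det(αI + (1−α)R) − (1−α) log det R] / (2(1−α))
(independently cross-checked in the tests by direct 2-D numerical
integration of the divergence), and Beta-marginal samples built on a
Gaussian copula, whose true RMI equals the copula's by rank invariance.

## Problem sizes used by the test suite and acceptance script

Full-scale defaults (L = 10,000 permutations) are impractical to re-run
per candidate in a routine check, so the shipped checks scale down: D1 runs
use L = 500, D2 L = 100, skewed variants L = 25; estimator-convergence
checks use n ∈ {500, 4,000} with 3 replicates and null-calibration checks
20 replicates at n = 4,000.  These sizes were chosen so the whole suite
completes in a few minutes while every assertion stays comfortably inside
its statistical tolerance; none of the scientific conclusions depend on
the reduction.

## Known limitations

- The mRNA-as-activity-proxy assumption fails for modulators regulated
  purely post-translationally themselves.
- ΔI compares only the extreme bins; a modulator acting non-monotonically
  (active only at intermediate expression) is invisible.
- Candidates co-regulated with the targets (hidden targets) can carry
  genuine positive ΔI and rank among true modulators — in D1 this is the
  single recurring source of imperfect recovery.
- p = 0 outputs are literal (fraction of exceeding trials); with small L
  the BH adjustment is correspondingly coarse.
- The estimator needs a few dozen samples per bin; `min_bin_size` guards
  this but small compendia simply cannot be binned three ways.
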