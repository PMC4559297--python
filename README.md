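# dmi — differential multi-information modulator inference

Transcription factors (TFs) are frequently switched on and off
post-translationally, e.g. by kinases and phosphatases, and these modulators
leave no trace in the TF's own mRNA level.  `dmi` infers them indirectly: if
a kinase M activates a TF, then in samples where M is expressed the TF is
active and its target genes are **co-regulated**; where M is absent the
targets decouple.  Given a gene-expression compendium (genes × samples,
log-scale), a list of the TF's target genes and a list of candidate
modulators, `dmi` returns the candidates ranked by how strongly their
expression level separates samples into a co-regulated and an independent
regime.

## Method

Co-regulation of the d target genes is measured with the **Rényi
multi-information** (RMI) of order α ∈ (0, 1),

I_α(X) = D_α( f ‖ ∏ᵢ fᵢ ),

the order-α Rényi divergence between the joint density and the product of
its marginals (0 iff the targets are independent; the classical
multi-information is the α → 1 limit; α = 0.99 by default).  It is
estimated non-parametrically from n samples by

1. the **empirical copula transformation** — each value is replaced by its
   within-column rank / n, making the estimate exactly invariant under
   monotone per-gene transforms — and
2. a **generalized nearest-neighbor-graph entropy estimator**:
   Ĥ = 1/(1−α) · log( L_p / (γ·n^(1−p/d)) ) with p = d(1−α), where L_p is
   the sum of p-th-power Euclidean distances from each point to its k-th
   nearest neighbors (k ∈ S), and γ is an empirical constant calibrated so
   that Ĥ = 0 on reference samples of exactly zero Rényi entropy.
   The RMI estimate is Î_α = −Ĥ(copula sample).

For each candidate modulator M the samples are sorted by M's expression and
cut into n_bins contiguous bins; the **differential multi-information**

ΔI = I_HIGH − I_LOW

contrasts the top and bottom bins.  ΔI > 0 marks an activator (targets
co-regulated only when M is present), ΔI < 0 an inhibitor.  Candidates
whose own expression barely moves between bins (log2 fold change below a
threshold) are prefiltered; significance per candidate comes from a
permutation null (ΔI of random d-gene sets with the same bins), with
Benjamini–Hochberg correction across candidates.  A normalized value
ΔI / (I_HIGH + I_LOW) is reported for comparing hits across different TFs.

## Worked example

The synthetic D1 benchmark plants 100 profiles over 60 genes: 10 TF
targets, 50 candidate modulators of which 20 are effective (their
expression is ~1 in the 50 co-regulated profiles and ~0 elsewhere), 10 are
unknown ("hidden") targets and 20 are pure decoys.

```python
import dmi

expr, truth = dmi.generate_dataset(dmi.preset_spec("d1", seed=1))
results = dmi.run_dmi(expr, truth.target_ids, truth.modulator_ids,
                      n_bins=3, n_permutations=500, fc_threshold=None,
                      random_state=1)
print(results.head(6).round(4))
```

```
modulator_id   i_low  i_high  delta_i  p_value  p_adjusted  rank
 MOD_EFF_018 -0.0498  1.8114   1.8612      0.0         0.0   1.0
 MOD_EFF_013  0.1592  1.9014   1.7423      0.0         0.0   2.0
 MOD_EFF_001 -0.0117  1.6573   1.6690      0.0         0.0   3.0
 MOD_EFF_019  0.0711  1.6691   1.5981      0.0         0.0   4.0
 MOD_EFF_008  0.1043  1.6690   1.5646      0.0         0.0   5.0
 MOD_EFF_016 -0.0856  1.4694   1.5549      0.0         0.0   6.0
```

Every top hit is a planted effective modulator: the targets carry ~1.6–1.9
nats of multi-information in the high-expression bin and none in the low
bin, and no random 10-gene set reached the observed ΔI in 500 permutation
trials (p = 0).  On this seed 19 of the 20 effective modulators fill the
top 20 ranks (a hidden target — itself co-regulated with the TF's targets —
takes one slot); most seeds recover all 20.

The same pipeline is available from the shell:

```sh
dmi simulate --preset d1 --seed 1 --out sim/
dmi run --expr sim/expression.tsv --targets targets.txt \
    --modulators modulators.txt --bins 3 --permutations 500 \
    --no-fc-filter --seed 1 --out run/
dmi evaluate --results run/results.tsv --truth sim/ground_truth.tsv --out eval/
dmi enrich --results run/results.tsv --sets kinase_families.gmt --out enrich/
```

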