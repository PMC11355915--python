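# reva

Topological quantification of left/right asymmetry in paired greyscale
images — built around retinal fundus photography, where the branching
vasculature of the two eyes of one person should be topologically alike —
plus the downstream population analysis: normalized bilateral-trait
asymmetries, top-decile overlap classification across body parts,
correlation with runs-of-homozygosity summaries, and Cox survival models
with asymmetry covariates.

It is aimed at researchers studying fluctuating asymmetry who want a
segmentation-free, registration-light asymmetry score for image pairs, and a
reproducible pipeline from raw pairs to survival tables.

## The measure

A greyscale image is a field `z(i, j)` on an N×M pixel lattice.  The
sublevel-set filtration includes every pixel with `z(i, j) ≤ l`; as the
threshold `l` grows this yields a nested family of cubical complexes.
Persistent homology tracks connected components (dimension 0) and loops
(dimension 1) through the filtration, recording each feature as a
birth/death pair `(b_i, d_i)`.  Each diagram is re-expressed through the
mean age `m_i = (b_i + d_i)/2` and lifetime `l_i = d_i − b_i`, and summed
into the accumulative persistence function

```
APF_k(m) = Σ_i  l_i · 1(m_i ≤ m),
```

a non-decreasing step function per homology dimension `k ∈ {0, 1}`.  The
asymmetry between a right and a left image is the signed supremum
difference

```
ReVA.k = APFk_R(m_k,max) − APFk_L(m_k,max),
m_k,max = argmax_m |APFk_R(m) − APFk_L(m)|,
```

computed after a common intensity transform (min–max to [0, 1] by default,
or global z-standardization).  Identical images give exactly 0; the sign
records which side dominates.  Across a cohort, `|ReVA|` is max-normalized
per dimension like every other bilateral trait, so all asymmetry estimates
are unitless values in [0, 1].

## Worked example

```python
from reva import compute_reva_pair, make_pair, VesselParams

left, right = make_pair((64, 64), VesselParams(), asymmetry_level=0.3, seed=42)
res = compute_reva_pair(left, right, transform="unit")
print(f"reva0={res.reva0:.4f} at m={res.m0_max:.4f}, "
      f"reva1={res.reva1:.4f} at m={res.m1_max:.4f}")
```

prints

```
reva0=1.9090 at m=0.8476, reva1=-4.3036 at m=0.8980
```

meaning the right image carries about 1.9 more units of cumulative
component lifetime by mean age 0.85 (right-dominant component structure),
while the left image carries 4.3 more units of loop lifetime by mean age
0.90.  Feeding the same image in twice returns exactly `(0.0, 0.0)`.

The full pipeline on a simulated cohort:

```python
from reva import RunConfig, run_pipeline

result = run_pipeline(RunConfig(n_subjects=200, image_size=(64, 64), seed=1),
                      outdir="out/")
print(result.log)
```

```
{'seed': 1, 'n_subjects': 200,
 'n_unilateral_hearing_loss_excluded_from_audiometry': 8,
 'n_image_pairs': 200, 'n_complete_flag_profiles': 192,
 'n_multi_asymmetry': 20, 'fraction_multi_asymmetry': 0.104,
 'count_by_n_flags': {0: 139, 1: 33, 2: 18, 3: 2, 4: 0}}
```

Here 20 of 192 complete-case subjects (10.4%) were in the top asymmetry
decile of at least two body-part groups; with fully independent group
asymmetries the expected fraction would be `1 − 0.9⁴ − 4·0.1·0.9³ ≈ 5.2%`,
so the shared asymmetry propensity built into this simulation visibly
clusters the flags.  `out/` contains the cohort, per-subject asymmetry,
flags, Venn partition, correlation and Cox tables, the resolved config and
the run log.

The same stages are scriptable from a shell:

```bash
reva simulate --outdir sim/ --n-subjects 50 --write-images --seed 1
reva compute --left sim/images/S00000_left.png --right sim/images/S00000_right.png
reva pipeline --outdir out/ --seed 1
```

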