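# radiotex

Texture radiomics for 2D tumor ROIs on T2-weighted MRI, built for small
pre-clinical treatment-response studies: does image texture separate treated
from untreated tumors when tumor *size* does not, and do individual texture
features track survival and histological markers?

The package implements the full analysis chain as a library plus thin
analysis drivers:

1. **Feature extraction** — a frozen, canonical 152-feature vector per ROI,
   named `<source>.<family>.<feature>`. Seven families (first-order
   statistics, GLCM, GLRM, rotation-invariant uniform LBP, fractal, HoG,
   shape) over the base image and two filters: the Sobel gradient-magnitude
   image and the four single-level Haar wavelet sub-bands
   (4+6+11+10+2+6 base, 4+6+11 gradient, 4×(1+4+6+11) wavelet, 4 HoG = 152).
2. **Reduction** — greedy removal of features with pairwise Pearson
   |r| > 0.50.
3. **Selection** — exhaustive search over feature subsets of growing size k,
   each scored by leave-one-out accuracy of an RBF-kernel SVM
   (standardization strictly inside each training fold); the search stops
   when best(k) − best(k−1) ≤ 10⁻³.
4. **Association statistics** — Pearson r with t-based two-sided p for
   feature–survival and feature–histology screens, pooled Student t and
   absolute Cohen's d (equal-weight pooled SD,
   d = |m₁ − m₂| / √((s₁² + s₂²)/2), for summary-statistics input) for group
   comparisons, and Kaplan–Meier curves with a two-group log-rank test.
5. **Synthetic cohorts** — because the kind of animal MRI data this targets
   is rarely shareable, a generator produces two-arm cohorts of textured
   elliptical tumors (Gaussian random fields whose correlation length
   differs by arm), survival linked to the realized texture parameter, and
   histology markers correlated with designated features. Every downstream
   stage is tested end-to-end against it.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (16 subjects, 8 per arm):

```sh
python analysis/01_simulate_cohort.py --seed 1   # writes results/cohort/
python analysis/02_extract_features.py           # results/features.csv
python analysis/03_reduce_and_select.py          # reduction.json, trace.json
python analysis/04_associations_survival.py      # assoc.csv, km.json, effect_sizes.csv
```

With `--seed 1` this prints (abridged):

```
overall survival by arm (days):
          mean    std
control  32.10  15.45
treated  54.69  16.09

correlation filter (|r| > 0.5): kept 15 of 152 features
  k=1: best LOO accuracy 0.8125 (15 subsets) ['wav_h.glrm.hgre']
  k=2: best LOO accuracy 0.8750 (105 subsets) ['wav_h.glrm.hgre', 'wav_v.glrm.lgre']
  k=3: best LOO accuracy 0.9375 (455 subsets) ['base.fractal.fd', 'wav_h.glrm.hgre', 'wav_v.glrm.lgre']
  k=4: best LOO accuracy 0.9375 (1365 subsets) [...]
selected ['base.fractal.fd', 'wav_h.glrm.hgre', 'wav_v.glrm.lgre'] at LOO accuracy 0.9375

survival_days    top feature base.fos.entropy   r=+0.702 p=0.002455
fibrosis_pct     top feature hog.fos.entropy    r=+0.849 p=3.202e-05
ck19_pct         top feature hog.fos.entropy    r=-0.965 p=1.716e-09
ki67_per_field   top feature wav_v.fos.mean     r=+0.898 p=2.334e-06
log-rank chi2=9.533, p=0.0020
```

Reading this: a three-feature subset separates the arms at 93.75% leave-one-out
accuracy (15 of 16 subjects classified correctly), and the search stops at
k=4 because the fourth feature adds nothing. The screens recover the
generator's built-in links — the markers were generated to correlate with
`hog.fos.entropy` (ρ = 0.84 and −0.97) and `wav_v.fos.mean` (ρ = 0.81), and
survival with the texture correlation length. The same stages are available
as a CLI (`radiotex simulate|extract|reduce|select|associate|km|run`); a full
run from a TOML config writes schema-validated JSON outputs plus a manifest.

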