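# rootbranch

Stochastic simulation and calibration of **root lateral branching density**.

The linear branching density of a root — equivalently its reciprocal, the
**inter-branch distance (IBD)** between consecutive emerged lateral roots —
is a central trait of root system architecture: acting at every branching
order, it largely sets the total number of roots a plant builds. Measured
IBD distributions are strongly right-skewed and vary widely both within a
plant (with the diameter of the parent root) and between species.

`rootbranch` implements a two-step generative model of this trait, an
indicator-based method to estimate its parameters from measured IBD
tables, a chi-square goodness-of-fit evaluation, a fine/thick
parent-root-diameter sub-population analysis, and a synthetic field-panel
generator so the whole pipeline can be validated by round trip. It is
aimed at root phenotypers and developers of root system architecture
simulators who need branching density as a calibrated, mechanistic module
rather than a fixed average.

## The model

Branching is split into two sub-processes along a (virtual) parent axis:

1. **Potential branching sites** are laid down sequentially, the gap to the
   proximal neighbour drawn i.i.d. from a normal distribution with mean
   `ISD` (inter-site distance, mm) and coefficient of variation `CV_D`,
   truncated to positive values.
2. **Emergence**: each site independently completes the whole branching
   process (primordium initiation through emergence) with probability
   `P_em`, or fails silently.

An observed IBD therefore spans a `Geometric(P_em)` number of consecutive
gaps, giving

```
E[IBD] = ISD / P_em,    IBD ~ Gaussian  in the limit P_em = 1,
```

with a systematic right tail appearing as `P_em` decreases — exactly the
shape of measured IBD distributions.

**Estimation** inverts three summary indicators of the empirical IBD
distribution against a simulated full-factorial parameter grid
(a *calibration table*), each indicator interpolated linearly along its
marginal relation:

| indicator                    | proxy for |
|------------------------------|-----------|
| mode of the kernel density   | `ISD`     |
| quantile(0.10) / mode        | `CV_D`    |
| quantile(0.80) / mode        | `P_em`    |

A 10×10×10 table (20,000 laterals per grid point) ships with the package;
`rootbranch calibrate` rebuilds denser designs (e.g. the full 20×20×20 grid
with 60,000 laterals per point) from a seed.

## Worked example

Recover known parameters from a simulated distribution
(`examples/02_calibrate_and_estimate.py`):

```python
import numpy as np
import rootbranch as rb

rng = np.random.default_rng(7)
table = rb.build_calibration(rb.default_grid_spec(6), n_laterals=10_000, rng=rng)

truth = rb.BranchingParams(isd=1.8, cv_d=0.4, p_em=0.7)
ibd = rb.simulate_ibd(truth, n_laterals=60_000, rng=rng)
result = rb.estimate_params(ibd, table)
```

prints

```
truth:     ISD=1.80  CV_D=0.40  P_em=0.70
estimated: ISD=1.71  CV_D=0.43  P_em=0.72
```

— the mode-based inversion recovers the site spacing within ~5%, and the
two quantile ratios place the gap variability and emergence probability
close to truth. `examples/` contains further narrative scripts: IBD
distribution shape vs `P_em`, a 40-sample panel fit with goodness of fit
and a species ANOVA on log IBD, and the diameter-split analysis.

## Command line

```sh
rootbranch simulate --isd 2 --cv-d 0.35 --p-em 0.7 -n 5000 --seed 1 --out ibd.csv
rootbranch calibrate --n-values 20 --n-laterals 60000 --seed 1 --out table.csv
rootbranch synth --n-samples 40 --seed 1 --out panel.csv      # + ground truth
rootbranch fit --data panel.csv --seed 1 --out report.csv     # + JSON summary
rootbranch splitfit --data panel.csv --seed 1 --out splits.csv
```

Input data are CSV with columns
`sample_id,parent_root_id,parent_diameter_mm,ibd_mm`. All commands are
byte-reproducible for a fixed `--seed`.

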