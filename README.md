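# borneoabc

Coalescent simulation and approximate Bayesian computation (ABC) for the
demographic history of the Bornean elephant (*Elephas maximus borneensis*).

The Bornean elephant carries remarkably little genetic variation — a single
mtDNA haplotype and depressed microsatellite diversity — and two competing
stories have been proposed to explain it: a human introduction of a handful
of animals from the Sulu archipelago ~300 years ago, or an ancient natural
colonization from the Sunda shelf followed by a long period at small
population size.  `borneoabc` implements the simulation machinery needed to
confront such hypotheses with multilocus genetic data:

* **Seven demographic models** — instantaneous decline (ID), exponential
  decline (ED), ancient colonization with a founder event (AC), recent
  introduction (RI), two successive introductions (TI), and the fragmented
  variants ACS/RIS in which the present population is split into four demes
  — each with published or documented priors over
  (N<sub>anc</sub>, N<sub>cur</sub>, N<sub>shrink</sub>, T<sub>shrink</sub>, …).
* **A fast structured-coalescent engine** (numba-jitted, closed-form time
  rescaling through piecewise-exponential epochs, ~30 µs for a 448-tip
  genealogy) with a generalized stepwise mutation model (GSM; geometric
  multi-repeat steps, P(k) = (1−p)p^(k−1)) for microsatellites and
  infinite-sites mutation for mtDNA.
* **Summary statistics**: per-locus number of alleles K, unbiased expected
  heterozygosity H = n/(n−1)·(1−Σp²), allele-size range R and the
  Garza–Williamson ratio M = K/(R+1) (mean and SD across loci), optional
  per-deme means and pairwise Weir–Cockerham F<sub>ST</sub>; haplotype
  count / segregating sites / mean pairwise differences (H, S, π) for
  mtDNA.
* **ABC model choice and estimation**: MAD-standardized Euclidean
  rejection, posterior model probabilities by retained-set proportions and
  by weighted multinomial logistic regression, Bayes factors, a
  marginal-density (KDE) goodness-of-fit p-value, local-linear regression
  adjustment with a heteroscedasticity correction, and weighted posterior
  summaries (5%, mean, median, mode, 95% HPD).
* **Validation experiments**: leave-one-out cross-validation of model
  choice, simulation-based calibration of the 95% HPD intervals, and the
  mtDNA "zero diversity" experiment (how often does each model leave a
  sample of 60 sequences monomorphic, as observed in Sabah?).
* **Synthetic data**: the real 224-individual × 18-locus genotype table is
  not publicly deposited, so the package generates observed-like datasets
  (Genepop + FASTA + a truth sidecar) with exactly that shape.

## Worked example

Generate a synthetic "observed" dataset under the ancient-colonization
model, then run model choice and parameter estimation against a simulated
reference table:

```bash
borneoabc synth --model AC --seed 9 --outdir obs
borneoabc sumstats --genepop obs/microsat.gen --grouping pooled --out obs.tsv
borneoabc simulate --models AC,RI --n 5000 --seed 11 --grouping pooled --out table.tsv
borneoabc choose --table table.tsv --observed obs.tsv --tolerance 0.01 --out choice.tsv
```

```
                 AC        RI
method
rejection  0.810000  0.190000
logistic   0.954538  0.045462
```

The multinomial logistic regression on the 1% closest simulations gives the
true model (AC) a posterior probability of 0.95 over the
recent-introduction alternative.  Estimating AC's parameters:

```bash
borneoabc estimate --table table.tsv --observed obs.tsv --model AC --tolerance 0.02 --out est.tsv
```

```
                          q5          mean        median          mode       hpd_low       hpd_high
parameter
N_anc           15072.851124  44685.852170  35122.883871  28084.145099  10704.960534  112177.484669
N_cur             279.619704    504.755047    471.267999    395.386039    226.347385     863.649502
T_shrink          946.322409   1146.952160   1136.434039   1037.543412    920.983397    1415.651065
N_shrink            7.156258     28.387017     30.481718     36.949686      5.806034      50.754838
mu                  0.000088      0.000188      0.000186      0.000183      0.000057       0.000324
p_gsm               0.059786      0.154114      0.145287      0.123197      0.059581       0.266334
T_shrink_years  14194.836137  17204.282398  17046.510586  15563.151176  13814.750951   21234.765973
```

Each row is a weighted, regression-adjusted posterior summary on the linear
scale (loguniform parameters are adjusted on log10 and back-transformed);
`T_shrink_years` converts generations with the default 15-year generation
time.  The generating truth recorded in `obs/truth.yaml` (N_anc = 74174,
N_cur = 373, T_shrink = 1302 generations, N_shrink = 40, µ = 2.7e−4) falls
inside every 95% HPD interval.

The zero-diversity experiment, with demographic parameters drawn from the
published microsatellite posteriors:

```bash
borneoabc mtdna-zero --models AC,TI,RI --n 10000 --seed 4 --out zero.tsv
```

counts, per model, how often a sample of 60 simulated mtDNA sequences
contains a single haplotype; the ancient-colonization model produces the
monomorphic pattern most often, the recent introduction least.

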