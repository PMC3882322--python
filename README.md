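# stereosim

Virtual design-based stereology of striatal neuron loss.

`stereosim` is a simulation and analysis package for quantitative
neurodegeneration studies of the kind run on the R6/2 mouse model of
Huntington's disease: whole-striatum neuron-number estimation with the
optical dissector / fractionator, cell-body volume estimation with the 2D
nucleator, size-binned population comparison between genotypes, and the
neuron-death kinetics and rescue-study sample-size arithmetic built on top
of the group estimates.

Because raw histology from such studies is rarely available, the package
ships a first-class synthetic-tissue generator: simulated striata with a
known true neuron count and a realistic cell-body volume mixture, so every
stage of the estimation chain can be validated against ground truth. It is
aimed at stereologists and modellers who want to (a) sanity-check a sampling
design before committing microscope time, (b) analyse real per-cell
measurement exports with exactly the same statistics, or (c) study the
power of rescue experiments.

## The estimators

**Optical fractionator.** The tissue is cut exhaustively into coronal
sections of thickness *t*; every *k*-th section is kept after a uniform
random start (section sampling fraction ssf = 1/*k*). On each kept section,
square unbiased counting frames of side *a* sit on a systematic grid of step
*g* with a uniform random offset (area sampling fraction asf = *a*²/*g*²),
and a dissector of height *h* below a guard zone sweeps each frame
(thickness sampling fraction tsf = *h*/*t*). A cell is tallied into ΣQ⁻ iff
its unique counting point lies in the dissector window and inside a frame
under the forbidden-line rule (left/bottom edges and their extensions
excluded, right/top included). The total estimate is

    N̂ = ΣQ⁻ · (1/ssf) · (1/asf) · (1/tsf)

With the conventional parameters used here (t = 40 µm, k = 12, a = 40 µm,
g = 500 µm, h = 20 µm): ssf = 1/12, asf = 0.0064, tsf = 0.5.

**2D nucleator.** Cell-body volume is estimated from n = 5 isotropic rays
from the cell's central point to the profile boundary, systematically
spaced with a random rotation: v̂ = (4π/3)·mean(lᵢ³), unbiased for
star-shaped profiles under isotropic sectioning through the point.

**Population analysis.** Per animal, N̂ is apportioned over 50 µm³
cell-body size bins in proportion to the measured cells (the per-bin
numbers sum to N̂ exactly); groups are compared per bin and in total with
the pooled-variance Student's t-test, and percent decline is reported
relative to the reference genotype.

**Kinetics & power.** Assuming loss begins at a fixed onset age and is
linear in time, the group deficit yields a daily loss rate; a removal
window (default 8 h) converts it to the instantaneous pool of detectably
dying neurons and to the expected number visible in a single section. The
sample-size solver finds the smallest per-group n for which a one- or
two-tailed two-sample t-test (noncentral-t power function, SDs proportional
to the group means) reaches the target power for a given rescue fraction of
the deficit.

## Worked example

Simulate the 12-week comparison (9 wild-type vs 10 HD animals, generating
means 993891 and 868043 neurons, between-animal CV 0.116) and analyse it:

```python
from stereosim.config import validate_config
from stereosim.pipeline import run_study

cfg = validate_config({
    "seed": 0,
    "cohorts": [
        {"genotype": "wild-type", "age_weeks": 12, "n_animals": 9,
         "mean_true_count": 993891},
        {"genotype": "HD", "age_weeks": 12, "n_animals": 10,
         "mean_true_count": 868043},
    ],
})
result = run_study(cfg, "demo_out")
print(result.summary["comparisons"]["12w"])
```

One realization (seed 0) prints:

```
mean_ref 1018333.3   sem_ref 61071.5    (9 wild-type animals)
mean_cmp  853875.0   sem_cmp 40873.5    (10 HD animals)
percent_decline 16.1   t 2.28   p 0.036
```

i.e. the virtual study estimates a 16.1% deficit against the 12.7% implied
by the generating means — within the sampling noise of a 9-vs-10 study in
which each animal contributes only ~260 counted cells. `demo_out/` also
receives `animals.csv`, `cells.csv`, `group_stats.csv` (per-size-bin
statistics) and `summary.json`.

The bespoke calculations are available directly from the shell:

```
$ stereosim kinetics --n-ref 993891 --n-hd 868043
{
  "dying_per_section": 14.57,
  "dying_pool_neurons": 1747.9,
  "loss_rate_per_day": 5243.67
}
```

reading: a 125848-neuron deficit accrued linearly between day 60 and day 84
means ~5244 neurons lost per day; with an 8-hour detectable-death window
~1748 neurons are dying at any instant, of which ~14.6 would sit in one
20 µm section of a 2400 µm anterior–posterior extent under a uniform
density.

```
$ stereosim power --effect 125848 --baseline-mean 868043
{ "rescue_0.5": 35, "rescue_1": 10 }
```

i.e. with SDs proportional to the means (CV 0.116), one-tailed α = 0.05 and
80% power, detecting a full rescue of the deficit needs 10 animals per
group, and a 50% rescue needs 35.

External measurement tables in the same CSV dialects can be analysed with
`stereosim analyze --animals animals.csv --cells cells.csv --out results/`.

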