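# calscreen

Phenotypic drug-screening analysis for neural-spheroid calcium oscillations
and multielectrode-array (MEA) network activity.

## The problem

CDKL5 deficiency disorder (CDD) is an early-onset genetic epileptic
encephalopathy. Patient-derived cortical spheroids show a characteristic
functional phenotype in whole-well calcium imaging: spontaneous calcium
oscillations that are **faster**, of **lower amplitude** and **more
irregular** than healthy controls. A 384-well phenotypic screen asks which of
a compound library pull this signature back toward the control phenotype.

`calscreen` implements the complete analysis for such a screen, for people
who run (or want to prototype) spheroid calcium-imaging screens and organoid
MEA experiments:

* a **synthetic-data generator** that emulates the screen — 10-minute traces
  at 3 Hz, 384-well plates with vehicle controls (DMSO/water), compounds in
  triplicate at 1 µM, planted rescue effects and toxicity, MEA recordings —
  so the whole pipeline is testable with known ground truth;
* **trace featurization**: peak detection/classification and a fixed vector
  of 17 functional descriptors per trace (counts, amplitude/width/timing
  statistics, three relative-height classes, singular/irregular peaks,
  subpeaks);
* **compound scoring**: per-plate, per-vehicle normalization, Scalar
  Perturbation and Parameter Recovery, ranking, hit selection and Hill
  dose–response fits;
* **MEA network metrics**: robust spike detection, active electrodes,
  bursts, network bursts, firing rate and a synchrony index.

## The scores

Let $x_{wf}$ be feature $f$ of well $w$ and $m_f$ the median of the same
plate's vehicle-control wells (matched by vehicle). Each feature is
normalized and standardized against the control distribution,

$$z_{wf} = \frac{\ln\!\big((x_{wf}+\varepsilon)/(m_f+\varepsilon)\big) - \mu_f}{\sigma_f},$$

with $\mu_f, \sigma_f$ the mean and SD of the log-normalized control values.
The **Scalar Perturbation** of one replicate is the Euclidean norm

$$\mathrm{SP}_w = \sqrt{\textstyle\sum_{f\in S} z_{wf}^2},$$

averaged over a compound's replicates; small SP means the treated well sits
close to the reference (healthy-control) signature. **Parameter Recovery**
counts features back inside per-feature boundaries $[\ell_f, u_f]$ derived
from control-vehicle wells (min–max by default):

$$\mathrm{PR}_w = \frac{100}{17}\,\#\{f : \ell_f \le x_{wf} \le u_f\},$$

again averaged over replicates; 100% means every descriptor recovered to the
control range. Leads are compounds in the top-50 lowest SP **and** with PR
strictly above 60% **and** passing the viability rule. Dose–response uses the
four-parameter Hill model
$\mathrm{PR}(c) = \mathrm{bottom} + (\mathrm{top}-\mathrm{bottom})\,c^h/(c^h + \mathrm{EC}_{50}^h)$.

## Worked example

`examples/02_screen_scoring.py` simulates a plate with 20 inert decoys and
three planted full rescuers (one toxic) and runs the whole pipeline:

```
             sp_mean  pr_mean  sp_rank  pr_rank  viability   lead
compound_id
rescuer_B       3.22    96.08        1        1       0.96   True
rescuer_C       3.99    88.24        2        3       0.50  False
rescuer_A       4.01    92.16        3        2       0.99   True
decoy_01        9.57    50.98        4        5       0.99  False
decoy_17       10.17    49.02        5        7       0.98  False
decoy_04       10.19    43.14        6        9       1.00  False

leads: ['rescuer_A', 'rescuer_B']
```

The planted rescuers take the lowest SP ranks (closest to the control
signature) and the highest PR (most features back inside control
boundaries); the toxic rescuer is excluded by the viability rule. The other
examples cover trace featurization (`01`), dose–response fitting (`03`,
recovering a planted EC50 of 0.05 µM) and MEA synchrony (`04`).

A thin CLI mirrors the pipeline stages:

```bash
calscreen simulate-plate --config cfg.yaml --seed 1 --out plate/
calscreen extract-features --traces plate/traces.csv --platemap plate/plate_map.csv --out features.csv
calscreen score-screen --traces plate/traces.csv --platemap plate/plate_map.csv --out results/
calscreen simulate-mea --seed 1 --out mea/
calscreen mea-metrics --spikes mea/spikes.csv --duration 60 --out metrics.json
```

## Layout

```
src/calscreen/
  simulate.py   # traces, plates, dose series, MEA recordings (+ ground truth)
  features.py   # peak detection/classification, 17-descriptor vectors
  scoring.py    # normalization, SP/PR, ranking, dose-response fits
  mea.py        # spikes, bursts, network bursts, synchrony
  io.py         # CSV readers/writers, run configuration
  pipeline.py   # end-to-end screen scoring + manifest
  cli.py        # thin command-line interface
docs/methods.md # model, parameter choices, limitations
examples/       # one narrative script per capability
```
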