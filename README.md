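# vipgate

Analysis pipeline for head-fixed go/no-go visual discrimination with sensory
distractors and simultaneous two-photon calcium imaging — the kind of
experiment used to study how cortical VIP interneurons gate attention and
error signals, and how that gating breaks down in models of
neurodevelopmental conditions.

The package is written for experimentalists who have (or want to prototype
against) three kinds of data: a trial table (stimulus class, distractor flag,
outcome), lick event times, and per-cell fluorescence traces with matched
neuropil traces.  Because no public dataset accompanies this task, the
package ships a first-class **synthetic cohort generator** with fully known
ground truth (licking policies, event rates, stimulus and error gains), so
every analysis stage has a recoverable target and every statistical procedure
can be calibrated end to end.

## What it computes

**Behavior.**  Trials are classified Hit / Miss / CR / FA from licking in the
reward window, and performance is the discriminability index

    d' = Φ⁻¹(Hits / (Hits + Misses)) − Φ⁻¹(FAs / (FAs + CRs)),

with fractions of exactly 0 or 1 replaced by the log-linear correction
1/(2N).  Daily performance uses the trailing 100 trials; within-session
recovery on distractor sessions uses bins of 10 trials, with trials-to-
criterion defined by d′ > 2 (once, or twice consecutively).  A forced
two-choice human variant scores Right / Wrong / No-response with both
fractions normalized by all trials.

**Lick decoding.**  An RBF-kernel SVM predicts the stimulus from lick counts
in 0.1 s bins over the pre-reward window [0, 1.9) s, bootstrapped over
stratified 80/20 splits (1000 iterations; 10,000 per single time bin for the
per-feature accuracy curve), with label-shuffled controls.

**Trace processing.**  Fluorescence is neuropil-corrected (F − 0.7·F_neu),
standardized into a modified Z-score by the mean and SD of the quietest 10 s
window (the stretch minimizing the SD of ΔF/F), and summarized per window as
the AUC rate, mean(z) × frame rate — a Z-score of fluorescence per second
(45 frames for 3 s at 15 Hz).

**Stimulus responsiveness.**  A cell is responsive when the correlation of
its Z-score trace with the stimulus time course beats 1000 epoch-scrambled
surrogates at the <1% upper-tail percentile, where an epoch is a maximal run
of frames with z ≥ 3 and a scramble permutes epoch segments among epoch
slots and gap segments among gap slots.

**Trial modulation.**  Per-trial activity in the stimulus [0, 3) s,
poststimulus [3, 6) s and time-out [6, 12.5) s windows; the error modulation
index (mean activity on FA/Miss trials ÷ mean on Hit/CR trials), split by
distractor condition and by first/last 20 trials; the visual modulation index
(E − S)/(E + S); and the across-animal correlation between error modulation
and % incorrect responses.

**Single-neuron ROC.**  Each Hit/CR trial gets a leave-one-out decision
variable, DV = tᵢ·(meanHit₍k≠i₎ − meanCR) (and symmetrically for CR trials);
sweeping a criterion over DVs yields the ROC curve and its trapezoidal AUC,
the per-neuron discrimination performance.

## Worked example

```python
import numpy as np, warnings
import vipgate as v
from vipgate.pipeline import behavior_summary
from vipgate import modulation, traces

cohort = v.simulate_cohort(v.default_cohort_config(seed=7,
                                                   n_animals_per_genotype=3))
summary = behavior_summary(cohort)
print(summary[["animal", "d_prime", "d_prime_distractor", "pct_incorrect"]]
      .round(2).to_string(index=False))

mods = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for (animal, fov, cell), tr in cohort.traces.items():
        if tr.cell_class != "vip":
            continue
        zt = traces.process_trace(tr)
        aligned = modulation.align_trials(zt, cohort.trial_records[animal],
                                          cohort.task)
        mi = modulation.error_modulation_index(aligned, "poststimulus")
        if mi.defined:
            mods.setdefault(animal.rsplit("_", 1)[0], []).append(mi.value)
for g, vals in sorted(mods.items()):
    print(f"{g} mean poststimulus error modulation: {np.mean(vals):.2f}")
```

prints

```
animal  d_prime  d_prime_distractor  pct_incorrect
 KO_00     1.40                1.13           28.0
 KO_01     1.50                0.67           31.0
 KO_02     1.18                0.77           29.5
 WT_00     2.00                2.20           13.5
 WT_01     1.73                1.79           16.0
 WT_02     2.33                2.06           14.0
KO mean poststimulus error modulation: 1.17
WT mean poststimulus error modulation: 2.06
```

The WT-like animals hold d′ above 2 on distractor trials and their VIP cells
roughly double their poststimulus activity after errors; the KO-like animals
lose discrimination under distraction, make twice the errors, and show little
error modulation — the sign structure the generator is built to emulate.

The same chain runs from the shell:

```bash
vipgate simulate --seed 7 --n-animals 3 --out run/
vipgate run-all --seed 7 --out run/      # every stage + group report
```

## Layout

| module | contents |
| --- | --- |
| `vipgate.config` | task, agent, neuron, genotype and cohort configs |
| `vipgate.synthetic` | session/calcium simulators, dataset bundle I/O |
| `vipgate.behavior` | trial classification, d′ variants, criteria, lick profiles |
| `vipgate.decoding` | lick featurization, SVM bootstrap, controls |
| `vipgate.traces` | neuropil correction, quiet baseline, Z-scores, events, AUC rate |
| `vipgate.responsiveness` | epochs, scrambles, bootstrap test |
| `vipgate.modulation` | trial alignment, modulation indices, early/late splits |
| `vipgate.roc` | leave-one-out DVs, ROC curve and AUC, tuning-breadth fraction |
| `vipgate.studies` | calibration / power / recovery / cohort-ordering studies |
| `vipgate.pipeline`, `vipgate.cli` | orchestration, artifacts, group reports, CLI |

See `docs/methods.md` for the model assumptions, parameter choices, numerical
conventions, and known limitations.
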