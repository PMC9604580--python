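# awia — area-based wave-intensity analysis of the aorta

`awia` implements non-invasive wave-intensity analysis (WIA) of the
ascending aorta from CMR-derived cross-sectional area A(t) and mean
velocity U(t) waveforms, together with the cohort statistics used to
relate pulmonary-regurgitation (PR) severity to ventriculo–arterial
coupling in patients with repaired tetralogy of Fallot. It is aimed at
cardiovascular researchers who have per-beat A/U traces (or want fully
synthetic ones with known ground truth) and need wave speed, aortic
distensibility and forward-wave features plus group-level statistics.

## The analysis

For one beat sampled uniformly at interval dt, the net area-based wave
intensity is the per-sample product

    dI[i] = dU[i] · dlnA[i]

where dU and dlnA are forward differences of velocity and log-area.
Positive dI is a net forward-travelling wave; the sign of dlnA classifies
compression (dlnA > 0) vs expansion (dlnA < 0). The analysis measures:

* **wave speed c** — the least-squares slope of U against lnA over the
  early-systolic upstroke (5%–50% of peak U), where only forward waves
  are present (water-hammer relation dU = c·dlnA);
* **distensibility D = 1/(ρc²)** (Bramwell–Hill), ρ = 1060 kg/m³;
* **FCW / FEW** — the forward compression wave of ventricular ejection
  (before peak U, dlnA > 0) and the forward expansion wave of relaxation
  (after peak U, dlnA < 0): their peaks (m/s) and energies (trapezoidal
  area under dI, units m);
* **forward/backward separation** dI± = ±(dU ± c·dlnA)²/(4c), which sums
  to the net intensity at machine precision.

A synthetic-data module generates beats from the water-hammer
characteristics with analytic ground truth, and four-group severity
cohorts whose defaults copy the published summary statistics of a
201-patient repaired-ToF cohort. Group statistics cover Kruskal–Wallis +
Dunn post hoc, chi-squared, OLS regression and noncentral-t power
analysis. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from awia import BeatSpec, analyse_beat, simulate_beat
from awia.simulate import default_forward_shape

spec = BeatSpec(c_true=4.0,
                forward_wavelets=default_forward_shape(0.78, 1.0))
signal, truth = simulate_beat(spec)      # one noiseless 0.78 s beat at 30 ms
result = analyse_beat(signal)
print(result.summary())
```

prints

```
Wave-Intensity Analysis Results
==============================================
subject:            synthetic
analysis dt:        30.0 ms
wave speed c:       3.982 m/s  (R²=1.0000, n=4)
distensibility D:   7.933 ×10⁻³ 1/mmHg
FCW peak:           2807.738 ×10⁻⁵ m/s
FCW energy:         2.436 ×10⁻³ m
FEW peak:           1279.607 ×10⁻⁵ m/s
FEW energy:         1.368 ×10⁻³ m
flags:              none
```

The beat was generated with true wave speed 4.0 m/s; the lnA–U loop
estimate is 3.982 m/s (−0.5%), and D = 1/(1060·3.982²) = 7.9×10⁻³ 1/mmHg.
The FCW/FEW magnitudes are large because this demonstration beat has a
physiological velocity amplitude (peak U ≈ 1 m/s); cohort simulations are
instead calibrated to published table scales (FCW peak ~10⁻⁵–10⁻⁴ m/s).

Cohort level:

```python
from awia import analyse_beat, default_cohort_spec, group_compare, simulate_cohort
import pandas as pd

sim = simulate_cohort(default_cohort_spec(seed=1))       # 201 subjects
rows = [{"subject_id": s, "c": analyse_beat(sig).c,
         "adjusted": not analyse_beat(sig).wave_speed_eligible}
        for s, sig in sim.signals.items()]
df = pd.DataFrame(rows).merge(sim.table.drop(columns=["adjusted"]),
                              on="subject_id")
cmp = group_compare(df, "c")          # excludes rectified-velocity subjects
print(dict(zip(cmp.group_names, [round(m, 1) for m in cmp.means])),
      f"KW p = {cmp.p_value:.2g}")
```

```
{'none': 3.8, 'mild': 4.6, 'moderate': 5.0, 'severe': 5.9} KW p = 0.0024
```

i.e. estimated group-mean wave speed rises with PR severity and the
Kruskal–Wallis test flags the difference, mirroring the stiffening of the
aorta with increasing regurgitation that motivates the analysis.

There is also a CLI: `wia simulate`, `wia run`, `wia stats`, `wia power`
(see `wia --help`).

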