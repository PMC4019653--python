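# cdkcycle

A data-calibrated ordinary-differential-equation model of mammalian
cell-cycle regulation, built for testing whether dense, correlated
expression profiles of the mitotic cyclins — the kind derivable from
multiparametric flow cytometry of an asynchronous population — can drive
and constrain a mechanistic model of the cyclin/Cdk network.

The package is for systems biologists who want a complete, runnable
cell-cycle oscillator whose observable output matches the programmed
expression of cyclin A2, cyclin B1 and phospho-S10-histone H3 (PHH3) in
a transformed human cell line (K562-like), together with the tooling
such a study needs: observable mapping and normalization, a synthetic
reference-data generator, global parameter calibration, and in-silico
knockout experiments.

## The model

25 coupled ODEs, 103 kinetic rate constants, mass action throughout with
zero-order ultrasensitive (Goldbeter–Koshland-type) activity switches.
Time is in fractions of the cell-cycle time Tc (the wild-type period is
1.0); concentrations are arbitrary units.  The network couples a
growth-signal entry block (ERG/DRG → cyclin D:Cdk4/6 → Rb
phosphorylation → E2F release) to the mitotic engine (cyclins E/A/B, the
CKI Kip1, Wee1/Cdc25 control of CycB:Cdk1, APC/C-Cdh1/Cdc20, and a
cyclin A/Cdk-activated G2 transcription factor shared by the mitotic
cyclins).  Key regulatory commitments, each visible in the data:

* APC/C-Cdh1 degrades cyclin A through G1, delaying detectable cyclin A
  until ~21% of the cycle;
* E2F is autocatalytic, drives cyclin A *and* B transcription, and is
  cleared at mitosis via Cdk phosphorylation plus Cdc20/Cdh1-mediated
  degradation of phospho-E2F;
* Wee1 inactivation — the mitotic trigger — is driven by cyclin A/Cdk,
  after which the CycB:Cdk1–Cdc25 positive feedback fires abruptly;
* cyclin B synthesis continues through mitosis in proportion to active
  CycB:Cdk1, so total cyclin B decays later than cyclin A;
* cyclin A synthesis is split 0.8/0.2 between Cdk2- and Cdk1-bound
  pools, which act in unison.

See `docs/methods.md` for the full account, including what the synthetic
data emulate and the calibration design.

## Worked example

```python
import numpy as np
from cdkcycle import default_parameters, simulate_cycles
from cdkcycle.observables import trajectory_observables, mitotic_onset, onset_time

params = default_parameters()                 # the calibrated 103 constants
traj = simulate_cycles(params, n_cycles=3)    # 3 cycles with division resets

print("division times:", np.round(traj.division_times, 4))
obs = trajectory_observables(traj, normalized=True)
period = traj.periods[0]
print("cyclin A detectable onset:",
      round(onset_time(obs["cyclinA_total"], 0.01) / period, 3))
print("mitotic onset (active CycB:Cdk1):",
      round(mitotic_onset(obs["cycB_cdk1_active"], 0.5) / period, 3))
```

prints

```
division times: [1. 2. 3.]
cyclin A detectable onset: 0.216
mitotic onset (active CycB:Cdk1): 0.962
```

i.e. the model divides once per unit Tc, keeps cyclin A undetectable for
the first ~21% of the cycle, and activates CycB:Cdk1 in the final ~4% —
the PHH3 window.

The numbered drivers under `analysis/` run the full study and write
their tables to `results/`:

```bash
python analysis/01_simulate_wildtype.py       # 3-cycle run + timing metrics
python analysis/02_generate_reference.py      # synthetic K562-style profiles
python analysis/03_sensitivity_and_recovery.py  # ranking + SRES recovery
python analysis/04_knockouts.py               # WT / dD / dDdE comparison
```

A `cdkcycle` command-line tool wraps the same steps
(`cdkcycle simulate|cycles|generate|calibrate|experiment --help`).

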