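# gctetra

Excited-state charge- and proton-transfer analysis for stacked
guanine–cytosine tetramers, with a surface-hopping model-Hamiltonian
simulator that generates verifiable synthetic trajectory ensembles.

## The problem

Photoexcited DNA dissipates UV energy through ultrafast nonradiative decay.
In stacked (GC)₂ tetramers — the minimal system with both π-stacking and
Watson–Crick hydrogen bonding — surface-hopping simulations show the
excitation relaxing into a guanine→cytosine charge-transfer (CT) state,
followed by interstrand proton transfer (PT) that funnels the system back to
the ground state. Analyzing such trajectory ensembles requires several
coupled stages:

* **fragment transition-density descriptors** — with the one-electron
  transition density partitioned over nucleobase fragments into a weight
  matrix Ω (Ω_AB = hole on A, electron on B), the character of a state is
  summarized by CT = Σ_{A≠B} ω_AB (electron–hole separation), the
  participation ratios PR_h = 1/Σ h_A², PR_e = 1/Σ e_B² and their mean PR
  (delocalization), the average positions POS, the effective number of
  natural-transition-orbital pairs PR_NTO = (Σλ)²/Σλ², and the
  hole–electron entanglement number Z_HE = 2^S;
* **character classification** — local excitation, exciton, excimer,
  charge transfer or charge resonance from (CT, PR, PR_NTO) with thresholds
  CT 0.2/0.8, PR 1.25/1.75, PR_NTO 1.25;
* **proton-transfer detection** — an event fires when a Watson–Crick
  hydrogen reaches X–H ≤ 1.1 Å on the opposite base (X = N or O), with a
  custody state machine for back-transfers, bond typing (central N–N,
  amino→carbonyl N–O, reverse C→G) and permanence at the final frame;
* **proton/electron-transfer patterns** — each PT event joined with the
  electron/hole localization at the event time: hydrogen-atom transfer
  (electron and proton from the same base), acceptor-shared or donor-shared
  proton-coupled electron transfer, with interstrand/intrastrand/diagonal
  electron-transfer character and binomial uncertainties;
* **kinetics** — adiabatic occupation curves and exponential decay
  constants from right-censored arrival times (censored MLE
  τ̂ = Σ observed times / n_arrived, plus a curve fit of the S0 rise).

Because the original quantum-chemistry trajectories are expensive and not
reproducible at desk scale, the package ships a decoherence-corrected
fewest-switches surface-hopping (DC-FSSH) simulator on a linear vibronic
model of the four fragments (Baeck–An couplings from gap curvature, 0.5 fs
classical / 0.025 fs quantum steps, energy-based decoherence with
α = 0.1 a.u., termination at a 0.2 eV excited–ground gap, harmonic Wigner
initial conditions in a 4.9 ± 0.5 eV excitation window). Generated
ensembles carry ground-truth logs, so every analysis stage is tested
against known conditions. See `docs/methods.md` for the model and its
limitations.

## Worked example

```python
import numpy as np
from gctetra import (
    SimConfig, gc_tetramer_model, run_ensemble,
    detect_pt_events, classify_permanence, pt_statistics, fit_decay,
)

model = gc_tetramer_model("nonalternating")     # GG/CC arrangement
config = SimConfig(ensemble_size=104, seed=1013, max_time_fs=3000.0)
manifest, records = run_ensemble(model, config)

arrivals, censored = manifest.arrival_times()
fit = fit_decay(arrivals, censored)             # censored MLE
print(f"decay constant: {fit.tau_fs:.1f} +/- {fit.se_fs:.1f} fs "
      f"({fit.n_events} arrivals, {fit.n_censored} censored)")

registry = model.registry()
events = {}
for rec in records:
    evs = detect_pt_events(rec, registry)       # X-H <= 1.1 A criterion
    events[rec.trajectory_id] = classify_permanence(evs, rec, registry)
stats = pt_statistics(events)
print(f"N-N transfer in {stats['bond_type_pct']['NN_central']:.0f}% of trajectories, "
      f"N-O in {stats['bond_type_pct']['NO_amino_carbonyl']:.0f}%")
print(f"{stats['n_no_permanent_pt']} trajectories without a permanent PT")
```

prints

```
decay constant: 63.0 +/- 6.2 fs (104 arrivals, 0 censored)
N-N transfer in 93% of trajectories, N-O in 28%
8 trajectories without a permanent PT
```

i.e. this 104-trajectory nonalternating ensemble decays exponentially with
a ~63 fs time constant (the generator's design point is 64 fs; the quoted
error is the MLE standard error τ̂/√n), nearly every trajectory transfers
the central N–N proton before reaching the ground state, about a quarter
also transfer the amino N–O proton, and eight trajectories decay without
any proton ending up permanently on the opposite base.

The same pipeline is available from the shell:

```
gctetra simulate --tag nonalternating --n 104 --seed 7 --out run/
gctetra classify --ensemble run/ --out character_timeline.csv
gctetra pt       --ensemble run/ --registry run/registry.yaml
gctetra patterns --ensemble run/ --registry run/registry.yaml
gctetra report   --ensemble run/ --registry run/registry.yaml --out-dir out/
```

`report` writes `report.json` plus plotting-ready CSVs (occupation curves,
PT-time vs final-time scatter, descriptor timelines). Externally produced
surface-hopping output can be adapted through
`gctetra.io.read_external_dialect` with a YAML mapping declaring which
files hold geometries, energies and active states; channels absent from an
archive (e.g. transition densities) are flagged unavailable rather than
fabricated.

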