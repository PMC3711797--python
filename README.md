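# ifnosc

Kinetic modeling of the type I interferon (IFN-beta) JAK/STAT response in
macrophages.

Stimulating macrophages with IFN-beta does not produce a simple pulse of
STAT1 activity: phosphorylated STAT1 (pSTAT1) and the mRNA of its inhibitor
SOCS1 overshoot, dip, and peak a second time a few hours later before
dying away -- a *damped relaxation oscillation*. `ifnosc` is a small
systems-biology package for simulating and analysing the nine-species ODE
network behind that behaviour: receptor activation and internalization,
STAT1 phosphorylation with competitive inhibition by SOCS1 (negative
feedback), nucleo-cytoplasmic shuttling of pSTAT1, and IRF1-mediated
activation of STAT1 transcription (positive feedback). It is aimed at
modellers who want a tested, scriptable implementation of this circuit --
to reproduce its phenotypes, scan its parameter space, or use it as a
ground truth for inference experiments.

The core model (species in molecules/cell, time in minutes):

    dS/dt   = b_S - lam_S*S
    dA/dt   = b_exp*Apn + b_deph*Apc + b_A*a - Phi - lam_STAT*A
    dApc/dt = Phi - (b_imp + b_deph + lam_STAT)*Apc
    dApn/dt = b_imp*Apc - (b_exp + lam_STAT)*Apn
    dr/dt   = b_r*H(Apn; k_r, n) - lam_r*r        dR/dt = b_R*r - lam_R*R
    df/dt   = b_f*H(Apn; k_f, m) - lam_f*f        dF/dt = b_F*f - lam_F*F
    da/dt   = b_a*H(F; k_F, u) - lam_a*a + B_STAT

    Phi = b_ph*S*(A/k_A) / (1 + A/k_A + (R/k_I)^q)
    H(x; k, h) = (x/k)^h / (1 + (x/k)^h)

What the package provides:

* **`model_core`** -- the parameter set, state vector, right-hand side,
  analytic Jacobian, and structural feedback knockouts.
* **`simulator`** -- stiff integration (LSODA, rtol 1e-8), dense
  trajectories, derived observables (total pSTAT1 = Apc+Apn, total STAT1
  protein = A+Apc+Apn), and the max-normalization convention used to
  overlay simulations on assay data.
* **`metrics`** -- peak times/amplitudes, half-max decay times, high-
  plateau durations.
* **`stability`** -- clamped-receptor steady states, eigenvalue
  classification of damped-oscillatory vs overdamped regimes, and 2D
  phase diagrams over (b_ph, b_deph) and (b_imp, b_exp).
* **`sensitivity`** -- one-at-a-time +/-20% perturbation envelopes.
* **`experiments`** -- scripted basal, knockout and receptor-sweep runs.
* **`synthetic_data`** -- assay-like pseudo-data (sparse time points,
  duplicates, log-normal noise, max-normalized) and multi-start
  least-squares parameter recovery.
* **`ifnosc`** CLI -- `simulate`, `basal`, `knockout`, `sweep-receptor`,
  `sensitivity`, `stability-scan`, `generate-data`, `fit`, `metrics`.

## Worked example

```python
from ifnosc import basal_experiment, run_knockout_experiment

basal = basal_experiment()          # reference parameters, 0-480 min
print("pSTAT1 peaks:", [(pk.time, round(pk.value)) for pk in basal.pstat1_peaks])
print("SOCS1 mRNA peaks:", [pk.time for pk in basal.socs1_mrna_peaks])
print("IRF1 mRNA half-max decay:", round(basal.irf1_mrna_half_decay_time, 1), "min")

ko = run_knockout_experiment("socs1")
m = ko.metrics["knockout"]["pSTAT1_total"]
print("SOCS1-KO plateau:", round(m["plateau_min"] / 60, 2), "h,",
      len(m["peaks"]), "retained peak(s)")
```

prints

    pSTAT1 peaks: [(1.0, 99992), (230.0, 64809)]
    SOCS1 mRNA peaks: [90.0, 262.0]
    IRF1 mRNA half-max decay: 376.8 min
    SOCS1-KO plateau: 4.98 h, 1 retained peak(s)

Reading: total pSTAT1 spikes within the first minute of stimulation and
rings once more around 230 min at roughly two-thirds of the first
amplitude; SOCS1 mRNA peaks at 90 and ~260 min, trailing the pSTAT1 peaks;
IRF1 mRNA follows a bell-shaped course that falls to half its maximum
around 375 min. Removing the SOCS1 negative feedback abolishes the
oscillation entirely and leaves pSTAT1 sitting on a high plateau for about
5 of the first 8 hours -- the negative feedback is what makes the system
oscillate, while the IRF1 positive feedback only drives the late rise of
STAT1 expression.

The same runs from the shell:

    ifnosc basal --out runs/basal
    ifnosc knockout --which socs1 --out runs/ko
    ifnosc stability-scan --param-x b_imp --param-y b_exp --out runs/scan

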