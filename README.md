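# flymembrane

A biophysical model of the *Drosophila melanogaster* R1-6 photoreceptor
membrane for people studying graded-potential signalling and its energy
cost: how the three voltage-dependent K⁺ conductances of the
photoreceptor soma (Shaker, Shab and the "Novel" conductance) shape
gain, bandwidth and ATP consumption, and how neuromodulators retune
that trade-off.

## The model

The soma is a single electrical compartment (C = 50 pF) holding

* three Hodgkin–Huxley K⁺ conductances, g = ḡ·h·m^γ, with closed-form
  steady-state curves m∞(V), h∞(V) and time constants τ(V)
  (Shaker: γ = 3, a fraction ξ = 0.13 fails to inactivate;
  Shab: γ = 2, two modes of inactivation h = 0.7·h₁ + 0.3·h₂;
  Novel: γ = 1, non-inactivating), all reversing at E_K = −85 mV,
* a 2.1 nS K⁺ leak and a 0.803 nS depolarising leak,
* the light-induced conductance g_light reversing at E_L = +5 mV,
  carried 74 % by Na⁺ and 26 % by Ca²⁺,
* a Na⁺/K⁺ ATPase (2 K⁺ in : 3 Na⁺ out : 1 ATP) and a Na⁺/Ca²⁺
  exchanger (3 Na⁺ in : 1 Ca²⁺ out).

At a steady depolarisation V every net ionic flux must vanish, which is
linear in (g_light, I_P, I_E):

    I(K)  = g_K(V)(E_K − V) + 2 I_P = 0
    I(Na) = 0.74 g_L(E_L − V) − 3 I_P − 3 I_E = 0
    I(Ca) = 0.26 g_L(E_L − V) + 2 I_E = 0

The pump cost in ATP/s is |I_P|/e.  Linearising each conductance about
an operating point yields the RrLC equivalent circuit — a steady
resistance R = 1/(ḡ m^γ h), an inductive activation branch
(r = 1/[(V−E_K) ḡ h d(m∞^γ)/dV], L = τ_m r) and a *negative*
inactivation branch (r_h, L_h = τ_h r_h) per gating variable, all
shunting C — from which the membrane impedance

    1/Z(f) = Σ_c [1/R + (1/r)/(1+i2πfτ_m) + (1/r_h)/(1+i2πfτ_h)]
             + g_K,leak + g_L,leak + g_light + i2πfC

follows in closed form.  Derived quantities: the 3 dB bandwidth above a
2 Hz floor, the gain–bandwidth product GBWP = peak|Z|·bandwidth, the
contrast gain T(f) = ḡ_light(E_L−V)Z(f) and its cGBWP, and pulse
responses with selective freezing of gating variables.  Neuromodulation
is expressed as edits to the gating curves: serotonin shifts Shaker and
Shab towards positive potentials, PIP2 depletion (light-dependent
modulation) shifts Shab activation 10 mV leftward, Ca²⁺/calmodulin
scales ḡ_Shab.

The three maximal conductances are not constrained directly by
experiment; they are calibrated against printed whole-membrane facts
(`flymembrane.calibrate_gbar`, see `docs/methods.md` for the
identifiability analysis).  The shipped values are ḡ_Shaker = 16.07 nS,
ḡ_Shab = 36.42 nS, ḡ_Novel = 2.12 nS.

## Worked example

```python
from flymembrane import (build_channel_set, find_dark_rest,
                         solve_balance_at_voltage, metrics_for_op)

channels = build_channel_set()          # calibrated, unmodulated
dark = find_dark_rest(channels)
bright = solve_balance_at_voltage(-36.0, channels)

for op in (dark, bright):
    m = metrics_for_op(op)
    print(f"V={op.V:7.2f} mV  g_light={op.g_light:5.2f} nS  "
          f"I_P={op.I_P:6.1f} pA  BW={m.bandwidth:5.1f} Hz  "
          f"peak gain={m.peak_gain:6.1f} MOhm  cost={m.energy_cost:.2e} ATP/s")
```

prints

```
V= -68.00 mV  g_light= 0.00 nS  I_P=  22.1 pA  BW= 14.0 Hz  peak gain= 246.1 MOhm  cost=1.38e+08 ATP/s
V= -36.00 mV  g_light= 5.01 nS  I_P=  89.7 pA  BW= 56.0 Hz  peak gain=  71.6 MOhm  cost=5.60e+08 ATP/s
```

i.e. depolarising from the dark resting potential (−68 mV, zero light
conductance) to the brightest steady state quadruples the bandwidth
while the pump cost rises four-fold, and gain falls as the light and K⁺
conductances load the membrane.  The same pipelines are scriptable from
the shell:

```
flymembrane calibrate          # fit and write the conductance config
flymembrane sweep              # light sweep with freeze variants
flymembrane modulate           # serotonin / PIP2 / calmodulin studies
flymembrane pulse --voltage -41 --freeze all
```

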