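# mirsense

Steady-state modeling and in-silico combinatorial screening of **compact
proportional miRNA sensors** — synthetic gene circuits whose fluorescent
output rises with the activity of an input microRNA.

The sensor is a three-stage, feed-forward double-inversion cascade: the
input miRNA (e.g. miR-21) represses a constitutively expressed
transactivator (tTA or PIT2); the activator induces a synthetic microRNA
(miR-FF4) from its cognate inducible promoter (TRE or PIR); miR-FF4
represses the output gene. With input present, the repressor of the output
is low and the output is high. `mirsense` is for synthetic biologists who
want to reason quantitatively about this topology: which parameters limit
the dynamic range, where the optima lie, and what a combinatorial screen
over genetic building blocks should look like before any DNA is cloned.

## Model

Each stage is a non-cooperative Hill relationship in molecules/cell
(1,000 molecules/cell ≈ 1 nM):

```
[Act]     = Act_MAX · IC50_miR / (IC50_miR + [I])
[miR-FF4] = FF4_MAX · [Act] / (K_d + [Act])
[Out]     = Out_MAX · IC50_FF4 / (IC50_FF4 + [miR-FF4])
```

The cascade is feed-forward, so one pass through the three closed forms is
the steady state. Derived metrics: the **Off state** (output at zero
input), the **theoretical On state** (= Out_MAX, the asymptote), the
**practical On state** (output at 3,000 input molecules/cell, a highly
expressed endogenous miRNA), the two **dynamic ranges** (On/Off), and the
**sensor IC50** — the half-max dose `b2` of a Hill-with-leakage fit
`y = b3 + b1·x/(b2 + x)` to the input-output curve, with an independent
inverse-mapping (50%-crossing interpolation) estimator as a cross-check.

On top of the model sit a parameter explorer (1-D sweeps, the
Act_MAX × K_d landscape and its optimal crest), a simulator of the
96-composition combinatorial screen (8 activator constructs × 2 miR-FF4
cassettes × 6 output constructs, On/Off in triplicate with multiplicative
lognormal noise plus output-pool controls), and the pairwise
single-component trend analysis used to read such screens.

## Worked example

`python examples/01_steady_state.py` evaluates the canonical basic
parameter set `SensorParameters.basic()` — (20, 20, 10251, 9755, 3000,
30000) — and prints:

```
input     0.0 molecules/cell -> activator    9755.0, miR-FF4  1462.81, output     404.6
input    20.0 molecules/cell -> activator    4877.5, miR-FF4   967.21, output     607.8
input  3000.0 molecules/cell -> activator      64.6, miR-FF4    18.79, output   15468.8

Off state            :     404.6 molecules/cell
practical On (3000)  :   15468.8 molecules/cell
theoretical On       :   30000.0 molecules/cell
dynamic range (pract):     38.23
dynamic range (theor):     74.14
sensor IC50          :    2893.9 molecules/cell
```

At zero input the activator is maximal, miR-FF4 is high (≈1463) and the
output is squeezed to ≈405; at 3,000 input molecules the activator drops
to ≈65, miR-FF4 to ≈19, and the output recovers to ≈15,469 — a 38-fold
practical dynamic range, about half of the 74-fold theoretical one. The
sensor IC50 of ≈2,894 molecules/cell says half the response needs roughly
a thousand-fold more input than the IC50 of the first stage alone, a
consequence of the intermediate amplification stage.

The `examples/` directory holds one short script per capability
(steady state, IC50 extraction, parameter exploration, screen simulation,
trend analysis); each prints its numbers with a line on what they mean.
A thin `mirsense` CLI mirrors the library
(`simulate | fit-hill | ic50 | scan | landscape | screen | analyze |
trends | run-all`).

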