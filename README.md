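# cardiotrial

In-silico drug trials on spontaneously beating cardiomyocyte models:
pore-block pharmacology, action-potential / Ca²⁺-transient biomarkers,
rule-based arrhythmia classification, and conductance-block sensitivity
maps.

## The problem

Human stem cell-derived cardiomyocytes (hSC-CMs) beat spontaneously and are
widely used for pro-arrhythmia drug screening, with the Ca²⁺-transient
duration at 90% decay (CTD₉₀) as the workhorse readout. Computational cell
models complement those assays: a drug is reduced to per-channel
dose-response curves, the model is run under the corresponding conductance
block, and the simulated change in CTD₉₀ plus any arrhythmic events (EADs,
DADs, repolarization failure, irregular or tachycardia-like rhythm) or
cessation of automaticity (quiescence, residual activity) are compared with
the dish. `cardiotrial` packages that whole workflow — for people building
or evaluating such models, and for anyone who needs a reproducible,
scriptable version of the screening protocol.

## The model

Drug action uses the single pore-block model. For channel *i* with
half-blocking concentration IC₅₀ and Hill coefficient *n*_H, the current at
drug concentration [D] is

    I_i([D]) = I_i' / (1 + ([D]/IC50)^n_H)

i.e. a multiplicative conductance factor in [0, 1] per channel. Cell models
attach through a plugin contract (`CellModelPlugin`): a deterministic ODE
right-hand side whose named currents can be individually scaled, integrated
with an adaptive stiff solver (LSODA, rtol 1e-7), with no external pacing —
all activity is automaticity. A fully specified fixture oscillator (a
FitzHugh–Nagumo-class two-current relaxation oscillator in membrane
millivolts, plus a phenomenological Ca²⁺ follower) ships in-repo so every
pipeline stage is exercised without external model code.

The trial protocol free-runs a model 800 s to its steady state, then runs
200 s per drug concentration from that state, computes CTD₉₀ on the last
eight spontaneous Ca²⁺ transients, classifies the rhythm from explicit
rules (repolarization failure: stable — max upstroke velocity < 0.2 V/s —
membrane potential above −40 mV over the last 15 s; irregular rhythm:
consecutive cycle-length change above 150%; tachycardia-like: rate > 2 Hz;
quiescence / residual activity by peak-potential rules), and reports
ΔCTD₉₀% against a like-for-like control run. Sensitivity maps block two
currents simultaneously at (0, 20, 40, 60, 80, 100)% each — 36 tests per
current pair — and categorize every cell.

## Worked example

Concentration–response trials of two shipped example characterizations
(reconstructed from published per-concentration block percentages; see the
table's provenance column) on the fixture oscillator:

```python
from cardiotrial import registry
from cardiotrial.drugs import example_drug_table
from cardiotrial.protocol import TrialConfig, run_drug_trial
from cardiotrial.traceio import results_to_frame

model = registry.create("fixture")
table = example_drug_table()
cfg = TrialConfig(t_pre=800.0, t_run=200.0)
for name, concs in [("dofetilide", [0.001, 0.01, 0.1]),
                    ("nisoldipine", [0.1, 1.0, 10.0])]:
    spec = next(s for s in table if s.name == name)
    results = run_drug_trial(model, spec, concs, cfg)
    print(results_to_frame(results).to_string(index=False))
```

prints (columns abridged):

```
      drug  conc_uM  baseline_ctd90_ms  drug_ctd90_ms  dCTD90_pct labels  cessation
dofetilide    0.001         942.300508    1086.422028   15.294645 NORMAL      False
dofetilide    0.010         942.300508            NaN         NaN     RF      False
dofetilide    0.100         942.300508            NaN         NaN     RF      False
       drug  conc_uM  baseline_ctd90_ms drug_ctd90_ms dCTD90_pct labels  cessation
nisoldipine      0.1         942.300508          None       None      Q       True
nisoldipine      1.0         942.300508          None       None      Q       True
nisoldipine     10.0         942.300508          None       None      Q       True
```

Read: a predominantly K⁺-current blocker prolongs the Ca²⁺ transient
(+15.3% at the low dose) and, at stronger block, leaves the fixture unable
to repolarize (RF) — CTD₉₀ is then unmeasurable and reported missing with a
reason. The strong L-type Ca²⁺-current blocker suppresses automaticity
outright (quiescence, cessation flag set) at all three doses.

The same operations are available from a shell:

```bash
cardiotrial synth --abnormality RF:10 --out rf.csv   # ground-truth RF trace
cardiotrial classify rf.csv                          # -> {"labels": ["RF"], ...}
cardiotrial trial --model fixture --drug nisoldipine --conc 1.0 --out res.csv
cardiotrial sensmap --model fixture --pair I_Kr I_CaL --out map.csv --plot map.png
cardiotrial batch --config batch.yaml --out results.csv   # models x drugs x concentrations
```

## Layout

| module | contents |
| --- | --- |
| `cardiotrial.core` | ODE engine, `CellModelPlugin` contract, `ChannelScaling`, `Trace`, model registry |
| `cardiotrial.fixture` | self-contained fixture oscillator + algebraic fixed-point oracle |
| `cardiotrial.drugs` | Hill pore-block model, two-point fits, characterization-table I/O |
| `cardiotrial.biomarkers` | cycle detection; APA, MDP, APD₃₀…₉₀, triangulation, rate, CTD₉₀ |
| `cardiotrial.rhythm` | rule-based classifier: EAD, DAD, RF, IRR, VT, Q, RESAC, NORMAL |
| `cardiotrial.protocol` | drug-trial driver, steady-state cache, 6×6 sensitivity maps |
| `cardiotrial.synth` | analytic synthetic AP/CaT generator with ground truth; in vitro table emulation |
| `cardiotrial.report` | in vitro / in silico comparison rows and concordance statistics |
| `cardiotrial.traceio`, `cardiotrial.cli` | CSV/HDF5/JSON round trips; `cardiotrial` command |

See `docs/methods.md` for the scientific and numerical choices in detail.
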