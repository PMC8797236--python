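# ictalwave

A 1-D spatially distributed model of ictal (seizure-like) discharge
generation and propagation in cortical tissue, built on the
conductance-based refractory density (CBRD) formalism with full ionic
and volume dynamics. It is aimed at computational neuroscientists
studying how slow seizure wavefronts (< 1 mm/s) arise from the
interplay of synaptic transmission, extracellular potassium, chloride
homeostasis and the Na⁺/K⁺ pump.

## The model in brief

Two neuronal populations — pyramidal cells (E) and interneurons (I) —
are each described by a density ρ(t, t*) over the time t* since the
last spike, transported with a hazard-function sink,

    ∂ρ/∂t + ∂ρ/∂t* = −ρ H(U, g_tot),
    ν(t) = ρ(t, 0) = ∫ ρ H dt*,

where U(t, t*) and the gating variables obey Hodgkin–Huxley-style
equations per t* cohort, and H(T) combines noise-driven threshold
crossing with deterministic drift, T = (V_th − U)/(√2 σ_V). The
populations interact through AMPA/NMDA/GABA-A conductances with
use-dependent depression, spatially mixed by a Gaussian connection
kernel of length λ = 50 µm along a 2.5 mm strip. A dynamic threshold
models depolarization block.

The tissue state couples back through ion bookkeeping: intracellular
K⁺/Cl⁻/Na⁺ per population, shared extracellular concentrations (with
bath exchange, potassium diffusion, optional glial buffering), the
electrogenic 3Na/2K ATPase, KCC2/NKCC1 cotransport, NMDA-gated
calcium, and osmotic extracellular-volume dynamics. Chloride
accumulation makes GABA depolarizing (GABAergic discharge onset);
extracellular potassium sustains the discharge; sodium-driven pump
activation terminates it and produces the post-ictal potassium
undershoot. See `docs/methods.md` for the full account, including how
ambiguities in the published formulation were resolved.

## Worked example

```python
import numpy as np
from ictalwave import run_scenario
from ictalwave.params import desk_config
from ictalwave import analysis as an

rec = run_scenario(desk_config("control", duration=300.0, seed=1))

events = an.detect_id_events(rec.t_trace, rec.col("K_o_S1"))
ko = list(rec.field_names).index("K_o")
speeds = an.slowest_front_speeds(rec.t_fields, rec.x, rec.fields[:, ko, :])

print(f"{len(events)} discharges at S1")
print(f"peak [K+]o: {rec.fields[:, ko, :].max():.1f} mM")
print(f"min ECS volume ratio: {rec.col('v_S1').min():.2f}")
print(f"median front speed: {np.median(speeds[1:]):.2f} mm/s")
```

prints (seed 1):

```
19 discharges at S1
peak [K+]o: 10.4 mM
min ECS volume ratio: 0.63
median front speed: 0.85 mm/s
```

Nineteen spontaneous discharges occur in 300 s of simulated tissue
time; each raises extracellular potassium from its 3.5 mM baseline to
~10 mM, shrinks the extracellular space by about a third, and
propagates along the strip — the median of the per-discharge
slowest-fragment front speeds is below a millimetre per second,
the slow ictal-wavefront regime (interneuronal/short discharges spread
an order of magnitude faster).

The same runs are available from the shell:

```
ictalwave simulate --scenario control --duration 300 --seed 1 --out run1/
ictalwave analyze --run run1/ --report report.json
ictalwave validate --n 4000 --seed 7
ictalwave sweep --lambdas 50,100,250 --duration 120 --seed 1
```

Scenarios: `control`, `no_diffusion`, `local_only`, `high_diffusion`,
`long_connections` (λ = 250 µm), `all_to_all` (0.2 global fraction),
`fixed_volume`, `glial_buffer`. Every model parameter can be set from
a YAML config (`ictalwave simulate --config my.yaml`).

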