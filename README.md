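# ventcell

Deterministic flux-balance simulation of protocell bioenergetics in natural
pH gradients.

A cell without ion pumps can still be chemiosmotic if geology does the
pumping for it: at the mixing front of an alkaline hydrothermal vent, a
protocell half-bathed in mildly acidic ocean water (pH ~7) and half in
alkaline fluid (pH ~10) sits across a standing proton gradient of three pH
units.  Whether that gradient can actually power ATP synthesis and carbon
fixation depends on quantitative ion dynamics: protons enter through the
ATP synthase and leak through the lipid phase, hydroxide from the alkaline
side neutralizes them, the membrane potential from every permeant ion
feeds back on every flux, and the whole balance shifts with membrane
permeability, protein density, and the presence of a Na+/H+ antiporter or
a primitive pump.  `ventcell` integrates exactly this balance for a 1 µm
spherical protocell and reports the electrochemical free energy available
to membrane proteins.

## Model in brief

For each ion S ∈ {H⁺, OH⁻, Na⁺, K⁺, Cl⁻} the internal amount evolves as

    d[S]ᵢₙ/dt · V = J_lipid,acid + J_lipid,alk + Σ J_protein

with passive flux through each membrane face given by the
Goldman–Hodgkin–Katz equation (u = zFΔψ/RT, inward-positive,
Δψ = ψᵢₙ − ψₒᵤₜ):

    J = P A u ([S]ₒᵤₜ e⁻ᵘ − [S]ᵢₙ) / (1 − e⁻ᵘ)

Δψ is the instantaneous GHK voltage over all five ions; internal H⁺/OH⁻
re-equilibrate against K_w every step; the driving force on each coupling
ion is the proton-motive-force expression

    ΔG = zFΔψ + RT ln([S]ᵢₙ/[S]_acid)     (kJ/mol, acid face)

and the reported −ΔG sums the favorable H⁺ and Na⁺ components — what a
promiscuous H⁺/Na⁺ machine can draw on.  Proteins (ATP synthase, Ech,
Na⁺/H⁺ antiporter, H₂-driven pump) are turnover-limited populations on the
acid face with hyperbolic driving-force kinetics saturating just beyond
20 kJ/mol.  See `docs/methods.md` for the full model, the calibrated
constants, and known limitations.

## Worked example

Run the canonical leaky protocell — 1% ATP synthase, H⁺ permeability
10⁻² cm/s, pH 7∶10 — for ten simulated minutes:

```bash
$ ventcell scenario run fig3a --t-end 600
dpsi: -0.001501845406416122
minus_dg_h: 15.391820079156208
minus_dg_na: 0.1274438437370558
minus_dg_reported: 15.519263922893265
n_records: 1201
ph_internal: 9.67263709967232
stop_reason: t_end
t_final: 600.0
```

The interior has settled at pH 9.67 — almost the alkaline value — because
hydroxide influx through the very leaky membrane neutralizes protons as
fast as the synthase imports them.  The proton gradient is therefore worth
15.4 kJ/mol of the theoretical 17.1 (three pH units at 298 K), the membrane
potential is a negligible −1.5 mV, and the reported −ΔG of 15.5 kJ/mol is
96.8% of the open-system ceiling:

```bash
$ ventcell scenario run open_system
minus_dg_h: 16.033995604975484
minus_dg_na: -1.0804654570828454
minus_dg_reported: 16.033995604975484
```

At 3.3 H⁺ per ATP, 15.5 kJ/mol per proton is ~51 kJ/mol per ATP — enough
to hold the ATP/ADP ratio ~9 orders of magnitude from equilibrium.  Rerun
with `--set membrane.permeability_h_cm_s=1e-5` (a modern, proton-tight
membrane) and the same cell collapses to under 2 kJ/mol within seconds:
equilibrium is death, and leaky membranes are what avoid it.

Other entry points:

```bash
ventcell scenario list                 # every preset experiment family
ventcell sweep fig3a --out sweep.csv   # permeability sweep, CSV + manifest
ventcell run --config my_run.yaml      # your own configuration
ventcell audit fig5a                   # per-step conservation bookkeeping
```

or from Python:

```python
from ventcell.scenarios import run_sweep
table = run_sweep("fig5b")   # SPAP fraction x gradient grid
```

Every output CSV carries a JSON manifest sidecar with the fully resolved
configuration, so any result can be reproduced bit for bit.

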