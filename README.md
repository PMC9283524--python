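# gamdpipe

Tools for studying how ligand efficacy relates to the conformational
stability of an agonist–GPCR–G-protein complex, built around a
Gaussian-accelerated enhanced-sampling engine, cumulant-expansion
free-energy reweighting, receptor-activation trajectory metrics, structural
micro-switch measurements, and the biochemical kinetics and dose–response
models used to quantify signaling.

The package is aimed at computational structural biologists who want a
small, fully testable implementation of this analysis stack: every input the
pipeline needs is produced by a seeded synthetic generator that emulates a
β1-adrenergic-receptor-like system with three ligand classes — a full
agonist, a partial agonist, and a very weak partial agonist — so the whole
comparison runs on a laptop in seconds to minutes.

## The models

**Gaussian-accelerated sampling.** When the system potential V falls below a
reference energy E, a harmonic boost is added:

    ΔV = ½ k (E − V)²  for V < E,   ΔV = 0 otherwise,   V* = V + ΔV

E and k are determined automatically from running statistics of V
(V_max, V_min, V_avg, σ_V) so that V_max ≤ E ≤ V_min + 1/k, with
k = k₀/(V_max − V_min) and, for the lower-bound threshold E = V_max,

    k₀ = min(1, (σ₀/σ_V) · (V_max − V_min)/(V_max − V_avg))

σ₀ (default 6.0 kcal/mol) caps the standard deviation of the applied boost
so reweighting stays accurate. In dual-boost mode one boost acts on the
dihedral energy component and a second on the total potential. The staged
protocol runs unboosted dynamics to collect statistics, a boosted
equilibration that refreshes E and k at a fixed update interval, and three
production replicas with frozen parameters and randomized velocities.

**Reweighting.** The unbiased free-energy profile along a collective
variable is recovered per bin by the second-order cumulant expansion

    F_j = −k_B T ln p*_j − ⟨ΔV⟩_j − (β/2) Var(ΔV)_j

with a frame cutoff (default 500 pooled frames) and the profile anchored at
zero.

**Activation metric.** Receptor activation is tracked by a TM3–TM6
Cα–Cα-like distance: ~8.3 Å in the inactive receptor, 12–14 Å in the
active, G-protein-compatible state. Frames are classified
active/inactive/intermediate on a running-averaged series, giving residence
fractions and first-passage (deactivation) times per replica.

**Assay models.** Complex stability is read out from one-phase exponential
association fits, F(t) = F₀ + (F_max − F₀)(1 − e^(−kt)), with half-life
t₁/₂ = ln 2/k; cellular efficacy from three-parameter
log(agonist)-vs-response fits with unit Hill slope, giving EC50, the
efficacy ratio top/top_reference, and ECq = EC50 · q/(100 − q).

## Worked example

```python
import gamdpipe as gp
from gamdpipe.config import ProtocolConfig

full, partial, weak = gp.default_profiles()
model = gp.build_activation_landscape(partial)
run = gp.run_gamd_protocol(model, ProtocolConfig(), master_seed=7,
                           label=partial.name)
pmf = gp.reweight_pmf(run.production, cv_indices=(0,), bin_width=0.1,
                      min_frames=500)
print(round(pmf.minimum_location(), 2))                    # 12.95
print(round(pmf.minimum_location(window=(6.3, 10.65)), 2)) # 8.35

trace = gp.simulate_association_trace(partial, noise_sd=0.0)
fit = gp.fit_association(trace)
print(round(fit.half_life, 1))                             # 577.6
```

The partial agonist's reweighted activation profile has its global minimum
in the active band (12.95 Å) and a second, inactive-basin minimum at
8.35 Å — the receptor visits both states. The fitted half-life (577.6 s,
i.e. ln 2 / 1.2e-3 s⁻¹) sits between the full agonist's (1733 s) and the
very weak partial agonist's (173 s): more efficacious ligands make a more
stable complex.

The same comparison runs end to end from the shell:

```bash
gamdpipe all --seed 7 --outdir out/
# half-life order: full_agonist > partial_agonist > very_weak_partial
```

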