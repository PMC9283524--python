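# Methods

## Scope and units

The package implements, at desk scale, the computational core of a
ligand-efficacy study on a class-A GPCR: enhanced sampling of receptor
activation, free-energy recovery, trajectory observables, structure
measurements, and the biochemical models that quantify complex stability and
cellular response. Energies are in kcal/mol, distances in Å, and the toy
dynamics run in an internal "toy ps" time unit. One toy ps of production
corresponds to 1/6 ns of an all-atom axis (`config.TOY_PS_PER_NS`); this is
a plotting convenience only — no physical time equivalence is claimed.
k_B·T at the simulation temperature of 310 K is fixed at 0.61597 kcal/mol.

## The synthetic system

Real inputs to this kind of study are all-atom receptor–G-protein complexes
and wet-lab assay plates. The generator replaces them with the smallest
objects that preserve the quantities the analysis measures:

**Activation landscapes.** Receptor activation is reduced to one collective
variable, a TM3–TM6 Cα–Cα-like distance with an inactive basin at 8.3 Å and
an active basin at 13.0 Å (the middle of the 12–14 Å band seen in active
receptor–G-protein structures). Each ligand class defines a double well
V(d) = c(d−m)² − A_i·g(d; μ_i, w_i) − A_a·g(d; μ_a, w_a): two inverted
Gaussians (default widths 1.0 Å) on a quadratic confining background
(c = 0.15 kcal/mol/Å², centered between the wells; strong enough that the
boosted coordinate cannot diffuse to unphysically small distances).
Amplitudes and Gaussian centers are calibrated numerically so that the local
minima sit *exactly* at the basin centers, V(active) − V(inactive) equals
the ligand's `landscape_bias`, and the saddle lies `barrier_height` above
the lower well; the calibration residuals are required to be below 1e-6.
Gradients are analytic. Specs with overlapping wells (centers closer than
the sum of widths) are rejected. An optional second, ligand-RMSD-like
coordinate adds a separable double well for 2D free-energy work; it is off
by default because a second energetic coordinate widens the sampled
potential range and hence the adaptive boost, eroding the ligand-resolved
persistence contrast the default comparison is about.

**Default ligand classes.** Three profiles emulate a full agonist
(isoproterenol-like), a partial agonist (dobutamine-like) and a very weak
partial agonist (cyanopindolol-like):

| profile | bias (kcal/mol) | barrier (kcal/mol) | rel. max | EC50 (M) | k (1/s) |
|---|---|---|---|---|---|
| full_agonist | −2.5 | 8.0 | 1.00 | 1e-9 | 4e-4 |
| partial_agonist | −1.2 | 5.0 | 0.60 | 1e-6 | 1.2e-3 |
| very_weak_partial | +2.5 | 3.0 | 0.24 | 1e-10 | 4e-3 |

The biases order the equilibrium active-state populations (≈0.98 / 0.86 /
0.03 at 310 K by direct Boltzmann quadrature). The barriers set the
kinetics of the comparison: the full agonist's 8 kcal/mol keeps the
receptor active for the whole default production length even under boost,
the very weak partial agonist's shallow active well (3.0 − 2.5 =
0.5 kcal/mol from the active side) deactivates within tens of toy ps, and
the partial agonist is intermediate. The 0.24 relative maximum matches the ~24% relative cAMP response
typical of cyanopindolol at wild-type β1-AR; 0.60 is a representative
value for the dobutamine-like partial-agonist class. EC50 defaults are back-computed
from the near-saturating (EC90) assay concentrations of the three ligands
(EC50 = EC90/9 for a unit Hill slope). Association rate constants span
10× so fitted half-lives order unambiguously.

**Assay data.** Fluorescence association traces follow one-phase
exponential association sampled every 12 s for 60 min (301 points) with
additive Gaussian noise (default 5 RFU on a 500 RFU amplitude); the noise
model is an assumption — per-replicate noise magnitudes for such assays are
rarely published, and the defaults were chosen so fitted confidence
intervals resemble typical plate-reader error bars. Dose–response data come
from a three-parameter logistic with unit Hill slope, 8 log-spaced
concentrations spanning each ligand's EC50 ±3 decades, 3 replicates, and
3% (of the full-agonist plateau) additive noise.

**Structure fixtures.** Miniature PDB-format files (written through
biotite, with alternate-location codes spliced into column 17) provide
synthetic inputs for the coordinate metrics. Deposited receptor models can
be read with the same functions; nothing downloads anything.

What the generator does *not* emulate: all-atom force fields, membranes and
solvent, multi-dimensional activation pathways, assay plate effects or
systematic (non-Gaussian) noise. Passing tests therefore demonstrate
correctness of the machinery and internal consistency of the study design —
not that real receptors behave this way.

## Sampling engine

Dynamics are Langevin with BAOAB splitting (defaults dt = 0.02 toy ps,
friction 1/toy ps, unit masses), chosen for its accurate configurational
sampling at large time steps; one force evaluation per step, and all
randomness flows from `numpy.random.default_rng` seeded per stage. Forces
on the boosted surface are the unbiased forces scaled analytically by
1 − k(E − V) (plus the dihedral-component term in dual-boost mode); there is
no numerical differentiation in the integration loop. Non-finite energies
abort with the failing step named.

The staged protocol mirrors the usual practice: (1) conventional MD
(default 20 000 steps) collects component-energy statistics every step;
(2) boosted equilibration (50 000 steps) re-derives E and k every
5 000 steps from statistics that *accumulate* across the run (running
extrema; a reset-per-window variant is available via
`accumulate_statistics=False`) — the statistics always use the unbiased
component energies, never V + ΔV; (3) three production replicas
(150 000 steps, frames every 10 steps) run with frozen parameters and
randomized initial velocities. The reference energy uses the lower bound
E = V_max by default, with σ₀ = 6.0 kcal/mol for both components. σ_V is
the population SD (n denominator). On 1D landscapes the dihedral component
is identically zero and the engine degrades gracefully to a total-potential
boost; the dual-boost path is exercised on a bonded toy chain whose
periodic dihedral term is a genuine separable component.

Production replicas restart from the active-state configuration (the
experiment's starting complex) with randomized velocities rather than from
the equilibration endpoint. At desk scale the boosted equilibration would
itself deactivate the weaker-ligand landscapes, which would erase the
per-ligand first-passage comparison the protocol exists to make; the
all-atom analog (a short equilibration that leaves the complex in its
starting state) is preserved by restarting. `production_start=
"equilibrated"` restores plain continuation.

Stage lengths are a sampling-budget choice: 3 × 150 000 steps give ~45 000
pooled production frames per ligand, enough for sub-0.1-Å basin-position
estimates and for tight profile recovery on well-mixing landscapes, while
keeping the full three-ligand comparison under a minute on one CPU.

## Reweighting

The total applied boost (sum of the dual-boost components — the quantity
that biases the sampled distribution) is accumulated per bin; each bin gets
the second-order cumulant correction C1 + (β/2)C2, with C2 the unbiased
(n−1) variance (single-frame bins get C2 = 0). Bin widths default to 0.1 Å
in 1D and 1.0 Å in 2D; bins with fewer than 500 *pooled* frames are flagged
excluded (pooling across replicas matches computing profiles from combined
trajectories; a per-replica cutoff would be stricter and is not what the
combined-trajectory convention implies). The profile is anchored so the
lowest included bin is zero. An anharmonicity diagnostic flags bins whose
boost samples have SD above σ₀ or excess kurtosis above a threshold
(default 1.0); flags are reported, never used to drop bins. Cumulant order
is fixed at two — exponential-average and Maclaurin variants are out of
scope, as are WHAM/MBAR combination and bootstrap error bars.

Accuracy at desk scale is limited by barrier-crossing statistics, not by
the truncation: on a 1D landscape ΔV is nearly constant within a 0.1 Å bin,
so C2 is tiny and the expansion is essentially exact, while the *relative
depth* of two basins carries a statistical error of roughly
k_BT/√(number of crossings). With the default protocol a 3 kcal/mol-barrier
well yields recovery errors of 0.08–0.12 kcal/mol (well inside 0.5 k_BT);
the 5 kcal/mol partial-agonist barrier yields ~40 pooled crossings and
basin-depth errors of 0.1–0.5 kcal/mol — which is why recovery *tolerances*
are validated on well-mixing landscapes while basin *positions* (robust at
±0.1 Å) are validated on the default profiles.

## Trajectory and structure metrics

Distance series are the recorded collective variable (or a particle-pair
distance in structure-backed mode), smoothed by a centered running average
(default window 12 toy ps, the analog of the 2 ns smoothing used on
all-atom axes; edges use the truncated window). States: inactive within
±1.0 Å of 8.3 Å, active inside [12, 14] Å, otherwise intermediate; the
margin is a package choice — activation plots conventionally mark these
levels with dashed reference lines without quantifying a cutoff. First passage is the
first time the *smoothed* series enters the inactive margin, suppressing
single-frame recrossings. Overlapping state definitions are rejected.

RMSD uses least-squares (Kabsch) superposition via
`scipy.spatial.transform.Rotation.align_vectors`, with the residual
recomputed from the returned transform (the library's internal residual
carries ~1e-8 cancellation noise). RMSF is computed per replica about that
replica's mean structure, then averaged arithmetically across replicas —
per-replica referencing avoids inflating fluctuations when replicas
drift apart. Ballesteros–Weinstein labels resolve through an explicit
per-structure mapping table (the β1-AR defaults: 3.40→129, 3.49→138,
3.50→139, 5.50→219, 6.30→285, 6.34→289, 6.44→299) rather than by sequence
inference; position 5.50's residue identity is left to the input model.
Salt bridges use the minimum nitrogen–oxygen side-chain distance with an
inclusive 4.0 Å default cutoff (a conventional value; none is stated in the
source analysis). Hydrogens are ignored throughout. Alternate locations
resolve by highest occupancy, first on ties.

## Assay fitting

Association fits leave F₀ and the plateau free (whether to constrain F₀ to the first
measured point varies between labs; leaving it free is the weaker
assumption) and derive t₁/₂ = ln 2/k exactly from the
fitted rate. Monotonically decreasing traces and non-convergent fits are
flagged, never silently defaulted. Dose–response fits fix the Hill slope at
one (the three-parameter "log(agonist) vs. response" model); a
variable-slope option exists but is off by default. Parameter confidence
intervals are asymptotic (from the least-squares covariance) — a
diagnostic addition to the conventional mean ± SD over replicate
experiments. Signaling time courses without a stated parametric model are
summarized descriptively (peak, time-to-peak, terminal slope). ECq uses the
closed form EC50·q/(100−q), valid for unit Hill slope.

## Pipeline determinism

Every stochastic stage consumes a seed derived as the first four bytes of
SHA-256 over (master seed, ligand, stage, replica), kept below 2³¹; reruns
of single stages therefore match the full run, and the consolidated JSON
report (which embeds a config hash and no timestamps) is byte-identical
across runs with the same config and master seed.

## Known limitations

- One (optionally two) collective variables; no multi-dimensional
  activation pathway, no ligand egress.
- Basin-depth estimates on slow-mixing landscapes (barriers ≳5 kcal/mol)
  are crossing-limited at the default stage lengths; lengthen production or
  lower the barrier when quantitative ΔF between basins is the goal.
- The boost acts directly on the 1D landscape potential, which is far more
  aggressive per kcal/mol of barrier than a boost spread over an all-atom
  potential; barrier heights here are tuned for contrast, not transferable
  energetics.
- The assay noise model is additive and Gaussian; real plates show
  heteroscedastic and systematic errors.
- PDB reading only (no mmCIF writing), no automated Ballesteros–Weinstein
  assignment, no rotamer-library classification, no density-map handling.
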