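# premix

**PRE-based ensemble modelling of transient protein complexes.**

`premix` reconstructs the spatial distribution of a weakly, transiently bound
protein partner from paramagnetic relaxation enhancement (PRE) data measured
by methyl-TROSY NMR. It was built around the analysis problem posed by the
complex between a G-protein heterotrimer (Gαβγ) and the cytoplasmic domain of
a G-protein-gated inwardly rectifying potassium (GIRK) channel: the complex
is too dynamic for a single structure, so the data are explained by a sparse
*weighted ensemble* of orientations selected from a large candidate pool.

## What it computes

1. **Intensity → Γ₂.** For a methyl group observed in the paramagnetic
   (spin-label oxidized) and diamagnetic (ascorbate-reduced) states, the HMQC
   peak-intensity ratio is

   I<sup>para</sup>/I<sup>dia</sup> = exp(−Γ₂·t<sub>HMQC</sub>) ·
   R₂<sup>diaH</sup>R₂<sup>diaHC</sup> /
   [(R₂<sup>diaH</sup>+Γ₂)(R₂<sup>diaHC</sup>+Γ₂)]

   which `premix.peaks` inverts by bracketed root finding, with delta-method
   error propagation and flags for broadened-out peaks.
2. **Forward PRE model.** `premix.forward` back-calculates
   Γ₂ = K(τ_c, ω_H)·⟨r⁻⁶⟩ from coordinates (Solomon–Bloembergen point-dipole
   form), averaging r⁻⁶ over a spin-label conformer ensemble and summing the
   symmetric subunit copies of each labeled site.
3. **Candidate pools.** `premix.pool` provides PRE-restrained rigid-body
   docking (Metropolis simulated annealing over the 6-DOF pose with
   soft-sphere repulsion) and linker torsion randomization with clash
   filtering, which generates the orientational candidate pool.
4. **Ensemble reweighting.** `premix.ensemble` optimizes nonnegative
   population weights p_k to minimize

   Q<sub>ens</sub> = √[ Σᵢ (Γ₂<sup>obs</sup>(i) − Σₖ p_k Γ₂<sup>calc,k</sup>(i))² / Σᵢ Γ₂<sup>obs</sup>(i)² ]

   by a stepwise funnel (groups of 100 → merged super-groups → top-10 %
   survivors → final joint optimization), exposed statsmodels-style as
   `PREEnsembleModel(...).fit() → PREEnsembleResults`.
5. **Density maps.** `premix.density` renders the reweighted atomic
   probability density of the mobile partner (Gaussian kernel per heavy atom,
   weight p_k), exported as CCP4/MRC and OpenDX volumes with a contour
   report at ρ = 0.05.
6. **Synthetic ground truth.** `premix.synthetic` builds a four-fold
   symmetric toy receptor with three label sites per subunit and a
   linker-tethered ligand carrying 60 methyl probes, plants a hidden
   5-member true ensemble, and emits noisy intensity tables — so the whole
   chain is testable end-to-end without any external data.

## Worked example

```python
import premix as px
from premix.peaks import gamma2_from_table

# toy complex with a planted 5-member true ensemble (weights 0.30 ... 0.05)
system = px.make_toy_system(seed=3)
tables = px.simulate_observed(system, noise=px.NoiseModel(snr_para=50, snr_dia=50))
observed = [gamma2_from_table(recs, site) for site, recs in tables.items()]

# candidate pool: truth + 2000 linker-randomized decoys, back-calculated Γ₂
pool, truth_idx, matrix = px.make_pool_with_truth(system, 2000)

model = px.PREEnsembleModel(observed, matrix)
result = model.fit("hierarchical", px.FitConfig(seed=3))
print(result.summary())
```

Output from this exact script:

```
PRE ensemble reweighting results
================================================
method:            hierarchical
observables:       180
pool members:      2005
ensemble members:  1000
active members:    7 (>0.1% weight)
total population:  0.8451
Q_ens:             0.0760
per-site Q:
  L366C                0.0596
  Q344C                0.0788
  V351C                0.0863
top members by weight:
  member 0        weight 0.2685
  member 1        weight 0.2336
  member 2        weight 0.1757
  member 3        weight 0.1024
  member 4        weight 0.0482
  ...
```

Members 0–4 are the planted true ensemble; their fitted populations recover
the planted weights (0.30/0.2375/0.175/0.1125/0.05) to within a few
hundredths at a signal-to-noise ratio of 50, with residual Q_ens at the noise
floor. A single-structure fit of the same data (`model.fit("single")`) leaves
Q ≈ 0.5–0.7 — the quantitative signature that one rigid structure cannot
explain PREs produced by an orientational distribution.

The same pipeline is scriptable from the shell:

```sh
premix run --config config.yaml --outdir run1 --verbose
```

with subcommands `simulate`, `extract`, `backcalc`, `dock`, `pool`, `fit`,
`map` for the individual stages; every run writes a JSON report with seeds,
per-stage Q-factors and a SHA-256 manifest of inputs and outputs.

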