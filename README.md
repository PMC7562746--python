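# poreflux

Umbrella-sampling free-energy reconstruction and pore-geometry analysis for
studies of selective permeability in protein shells — the kind of question
posed by bacterial microcompartment (BMC) shell hexamers such as the
β-carboxysome protein CcmK2, whose central pore admits some metabolites
(HCO₃⁻, 3-PGA) while hindering others (O₂, CO₂, cations).

The package covers the full desk-side analysis chain of such a study and, in
place of unreleased all-atom trajectories, ships a Brownian-dynamics
generator with **known ground truth**, so every estimator can be validated by
planted-parameter recovery.

## What it computes

**Free energies from biased sampling.** A molecule's passage through a pore
is described by the collective variable *z* (projection of its center of mass
on the pore axis) and *b* (distance from the axis). Umbrella sampling places
harmonic windows U_bias = ½k(z−z₀)² on a grid (default −26…+26 Å at 0.5 Å,
k = 5 kcal·mol⁻¹·Å⁻², 105 windows, T = 303.15 K, cylindrical flat-bottom
confinement b ≤ 15 Å). The unbiased profile G(z) is reconstructed two ways:

* **WHAM** — iterating the self-consistent equations
  p_j ∝ M_j / Σᵢ Nᵢ exp(β(fᵢ − w_ij)), exp(−βfᵢ) = Σⱼ p_j exp(−βw_ij);
* **DHAM** — a Markov-model route: per-window transition counts between bins
  are unbiased with factors exp(−β(w_k − w_j)/2) and combined; G follows from
  the stationary distribution.

Profiles are anchored to bulk solvent (mean G over |z| ∈ [24, 25] Å ≡ 0),
with standard errors from 5 equal-length trajectory segments per window, and
2D G(z, b) surfaces with optional removal of the radial Jacobian measure.
Unbiased trajectories (free ions) are turned into G = −kBT·ln(density).
With a constant Arrhenius/Kramers prefactor, barrier differences give rate
ratios k_a/k_b = exp(−ΔΔG‡/kBT).

**Pore geometry.** PDB reading (multi-model), Kabsch superposition,
per-residue RMSF, maximal-inscribed-sphere pore-radius profiles along the
axis (the HOLE-style constriction measurement), hexagon pore-entrance areas,
and hydrogen-bond contact detection (donor–acceptor ≤ 3.5 Å,
D–H…A within 30° of linear).

**Statistics.** Pore diameters split by contact/no-contact are compared with
the two-sided Wilcoxon rank-sum test (exact for small tie-free samples),
summarized as violin densities (Gaussian KDE, Silverman bandwidth).

**Synthetic data.** Overdamped Langevin walkers on analytic multi-well
potentials supply umbrella windows and free-ion trajectories; breathing
hexamer-ring ensembles with an optional contact-coupled dilation supply
Fig-5-style coordinate data. All generators are deterministic given a seed.

## Worked example

```bash
poreflux all --config examples/config.yaml --seed 7 --outdir run/
cat run/report.txt
```

On the shipped three-well fixture (minima planted at z ≈ −12, −5 and +6 Å,
echoing a convex-side site, the constriction and a concave-side site) the
report compares every recovered feature with the generator's ground truth:

```
free-energy extrema (WHAM, 5-block mean ± SEM):
  minimum  z =  -12.00 Å  G =  -1.390 (ground truth U =  -1.084) kcal/mol
  maximum  z =   -8.00 Å  G =   1.365 (ground truth U =   1.252) kcal/mol  barrier ΔG‡ = 2.756
  minimum  z =   -5.00 Å  G =  -0.332 (ground truth U =  -0.495) kcal/mol
  maximum  z =    0.50 Å  G =   1.062 (ground truth U =   1.165) kcal/mol  barrier ΔG‡ = 2.564
  minimum  z =    6.00 Å  G =  -1.502 (ground truth U =  -1.497) kcal/mol

contact-conditioned pore diameters (Wilcoxon rank-sum):
  ARG11: insufficient contacts (n_contact=0, n_nocontact=600)
  LYS36: median 3.50 vs 2.56 Å, p = 1.11e-14 (significant)
  SER39: insufficient contacts (n_contact=0, n_nocontact=600)

measured vs planted constriction diameters over 60 frames: max |Δ| = 0.0010 Å, r = 1.0000
```

Reading this: the three planted wells and the two barriers between them are
recovered within the block errors; the synthetic ensemble planted a 1 Å pore
dilation coupled to metabolite–Lys36 contact, and the rank-sum comparison
flags exactly that residue (the medians differ by the planted amount) while
residues without contacts are reported as having insufficient category
sizes; the inscribed-sphere constriction diameters agree with the generator
truth to within 0.001 Å.

Individual stages (`simulate-us`, `wham`, `dham`, `errors`, `simulate-ions`,
`density`, `simulate-pore`, `pore`, `contacts`, `stats`, `kinetics`,
`report`) can be re-run on an existing directory. The same functionality is
available as a library:

```python
from poreflux import (get_fixture, place_windows, SimulationSpec,
                      generate_us_dataset, wham_1d, split_block_errors)
import numpy as np

model = get_fixture("barrier_3.8")
windows = place_windows(-26.0, 26.0, 0.5, 5.0)       # 105 windows
data = generate_us_dataset(model, windows,
                           spec_defaults=SimulationSpec(model=model, bias=None),
                           seed=38)
profile = split_block_errors(data, n_blocks=5,
                             bin_edges=np.arange(-26.25, 26.26, 0.5))
```

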