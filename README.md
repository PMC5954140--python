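# fccs — dual-color fluorescence cross-correlation spectroscopy

`fccs` quantifies protein–protein interactions in live cells the way
dual-color FCCS instruments do: two fluorescence channels (a GFP-tagged and
an mCherry-tagged protein) are recorded through co-aligned confocal
detection volumes, and co-diffusion of the two labels — the signature of a
complex — appears as a non-zero cross-correlation between the channels.
The package is aimed at people who analyze (or want to understand and
validate) such measurements: it implements the full analysis chain and a
Brownian-dynamics photon-trace simulator that stands in for the microscope,
so every stage can be verified against known ground truth at desk scale.

## The statistics at its core

From two binned photon-count traces $I_g(t)$, $I_r(t)$ the correlation
functions are estimated as

$$G_x(\tau) = 1 + \frac{\langle \delta I_i(t)\,\delta I_j(t+\tau)\rangle}
                       {\langle I_i\rangle\langle I_j\rangle},$$

with $(i=j=g)$ and $(i=j=r)$ giving the green and red autocorrelations and
$(i=r,\ j=g)$ the cross-correlation.  Each curve is fitted with the 1–3
component model of free 3D diffusion through a 3D-Gaussian volume with
structure parameter $s = z_0/w_0$,

$$G_x(\tau) = 1 + \frac{1}{N}\sum_i F_i
   \left(1+\frac{\tau}{\tau_i}\right)^{-1}
   \left(1+\frac{\tau}{s^2\tau_i}\right)^{-1/2},$$

optionally multiplied by a triplet (dark-state) factor
$1 + \frac{T}{1-T}e^{-\tau/\tau_T}$.  $N$ is the mean number of particles
in the detection volume ($G(0)-1 = 1/N$), and $\tau_i = w_0^2/4D_i$ the
diffusion time of component $i$.  The interaction strength is the
**relative cross-correlation amplitude**

$$\mathrm{RCA} = \frac{G_c(0)-1}{G_r(0)-1},$$

which under ideal conditions equals the bound fraction $N_c/N_g$ of
green-labeled molecules.  Groups of cells are compared with the two-sample
Student's t-test (stars: \*p<0.05, \*\*p<0.01, \*\*\*p<0.005,
\*\*\*\*p<0.001).

The structure parameter is calibrated from a reference dye of known
diffusion coefficient (Rhodamine-6G-like, D = 400 µm²/s): a one-component
fit with $s$ free yields $s$ and $\tau_D$, and the beam waist follows from
$w_0 = \sqrt{4D\tau_D}$.  $s$ is then held fixed in all cell fits.

## Worked example

Simulate one "interacting" measurement (30 % of each label bound in
double-labeled complexes) and one monomer control, then compare cohorts:

```python
import numpy as np, fccs
from fccs.studies import dual_share_species, simulate_measurement
from fccs.interaction import rca_from_fits

m_int = simulate_measurement(dual_share_species(0.30), seed=42)
m_ctl = simulate_measurement(dual_share_species(0.0), seed=43)
for name, m in (("30% bound", m_int), ("monomer control", m_ctl)):
    res = rca_from_fits(m.fit_gg, m.fit_rr, m.fit_gr)
    print(f"{name}: N_g = {1/res.amplitude_gg:.2f}, "
          f"N_r = {1/res.amplitude_rr:.2f}, RCA = {res.rca:.3f}")

a = [simulate_measurement(dual_share_species(0.30), seed=100+i).rca for i in range(4)]
b = [simulate_measurement(dual_share_species(0.0), seed=200+i).rca for i in range(4)]
cmp = fccs.compare_groups(a, b, label_a="interacting", label_b="control")
print(f"t = {cmp.t_statistic:.2f}, df = {cmp.degrees_of_freedom:.0f}, "
      f"p = {cmp.p_value:.2g} {cmp.stars}")
```

prints

```
30% bound: N_g = 1.07, N_r = 1.04, RCA = 0.261
monomer control: N_g = 1.01, N_r = 1.07, RCA = 0.060
t = 9.36, df = 6, p = 8.4e-05 ****
```

The fitted particle numbers (~1 per detection volume) match the simulated
concentrations; the interacting cell shows an RCA near the simulated bound
fraction 0.30 while the control sits at the estimator's noise floor; the
cohort comparison flags the difference at the **** level.

## Command line

Every stage is also a `fccs` subcommand operating on plain-text files:

```bash
fccs simulate  --config sim.yaml --out trace.csv
fccs correlate --trace trace.csv --kind gr --n-segments 10 --out gr.csv
fccs fit       --curve gr.csv --components 1 --fix s=5.0 --out gr.json
fccs calibrate --curve dye.csv --known-d 400
fccs rca       --gg gg.json --rr rr.json --gr gr.json
fccs compare   --a table.csv:interacting --b table.csv:control
fccs run       --config pipeline.yaml --out results/
```

`fccs run` executes the whole chain (simulate → correlate → fit → rca →
compare) from one YAML config, writing every intermediate artifact plus a
checksum manifest; identical configs reproduce byte-identical result
tables.  File formats are documented in `docs/formats.md`, the scientific
choices and their rationale in `docs/methods.md`.

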