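# uwheel

Physics, swarm-transport and network-targeting simulator for magnetically
actuated colloidal microwheels ("µwheels") rolling on inclined surfaces.

Superparamagnetic beads assembled by a rotating magnetic field into
disc-like clusters roll on a thin lubricating fluid layer. This package
implements the complete computational chain for predicting their motion
and delivery through branching 3-D channel networks:

- **`uwheel.physics`** — single-wheel force-balance model: rotation rate
  from the magnetic/viscous torque balance (ω ∝ 1/R), closed-form
  lubrication gap width from the load/electrostatic-repulsion balance,
  closed-form incline velocity from the wet-friction/drag/weight balance
  (signed; large wheels slip backwards down steep inclines), effective
  incline under switchback headings, and the Peclet / dipole-strength /
  Mason dimensionless groups.
- **`uwheel.params`** — typed SI parameter containers with strict
  YAML/JSON config loading (lab units at the boundary). The shipped
  default set includes the fitted shape constants k1 = 1.50, k2 = 3.11;
  electrostatic values and χ″ are illustrative order-of-magnitude
  defaults, all overridable.
- **`uwheel.swarm`** — swarm modes (rolling / switchback / flipping /
  corkscrew) as truncated log-normal component-radius laws, per-wheel
  state with CSV round-trip, centroid velocity, and time-dependent
  spatial mass-transport profiles.
- **`uwheel.network`** — branching networks as junctions with arc-length
  positions and incline angles; per-branch piecewise-linear φ(x) with
  turn and parallel-channel annotations; JSON/CSV serialization and
  validation.
- **`uwheel.targeting`** — Euler integration (dt = 0.1 s) of every wheel
  through the network; mass-weighted centroid steering; 0.5 σ keep-window
  clipping at turns with parallel-channel losses; 1-mm collection phase;
  per-branch targeting efficiency with exact mass bookkeeping.
- **`uwheel.quantify`** — 16-bit fluorescence scan quantification:
  background threshold (default 3600), beads-per-count calibration, and
  target-ROI/total-intensity efficiency.
- **`uwheel.synthetic`** — generators for swarms, networks (including a
  six-terminal vascular-style preset with 0.6 mm channels) and noisy scan
  pairs with known ground truth, so the whole pipeline is testable
  offline.
- **`uwheel.refit`** — recovery of k1/k2 from (R, φ, V) data by nonlinear
  least squares.

## CLI

```sh
uwheel velocity --R 10um --phi 40                 # V, delta, omega, forces (JSON)
uwheel sweep -o sweep.csv                          # V(R, phi) grid
uwheel swarm --mode rolling -n 500 --seed 7 --phi 0 --t 20   # mass profile CSV
uwheel target --mode rolling -n 500 --seed 7 --network net.json -o result.json
uwheel quantify --pre pre.tif --post post.tif --rois rois.json --target branch1
uwheel gen --seed 1 -o outdir/                     # full synthetic dataset
```

`--params params.yaml` accepts a config with `bead` / `fluid` / `field` /
`fit` sections (unit-suffixed keys, e.g. `a_um`, `B_mT`, `debye_nm`);
unknown keys are rejected. `ModelParams.from_yaml` / `.to_yaml` round-trip
the same schema.

## Library example

```python
import uwheel as uw

p = uw.default_params()
V = uw.velocity(10e-6, 40.0, p)                 # m/s on a 40 deg incline

swarm = uw.gen_swarm("rolling", 500, seed=7, params=p)
net = uw.mca_network("branch1")
res = uw.simulate_targeting(swarm, net, p)
print(res.efficiency, res.termination, res.per_junction_losses)
```
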