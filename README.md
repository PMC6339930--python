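# gridscape

Grid cells in the medial entorhinal cortex fire on a strikingly regular
spatial lattice, yet their hexagonal symmetry bends to the geometry of the
enclosure the animal explores. `gridscape` is a self-contained simulation
laboratory for studying that dependence: it implements a hierarchical
oscillatory network model of grid-cell formation — head-direction coding by
a self-organizing map, path integration by velocity-controlled phase
oscillators, and feature extraction by a lateral anti-Hebbian network
(LAHN) — together with arena generators, a curvature-constrained foraging
simulator, and the spatial analytics (rate maps, autocorrelograms,
hexagonal gridness scores, ellipticity) needed to quantify how the emergent
firing fields change with environmental shape. It is written for
computational-neuroscience researchers who want to probe spatial-cell
models in arbitrary 2-D geometries without collecting animal data.

## The model

The forager's heading `Theta(t)` drives a sheet of head-direction neurons
with cosine tuning `theta_HD,k = cos(Theta - phi_k)` (learned by a Kohonen
SOM over unit vectors). Each HD neuron controls one Hopf limit-cycle
oscillator with instantaneous frequency

    omega_k(t) = Omega_PI + beta * s(t) * theta_HD,k(t),

where `s` is the running speed, so the oscillator's phase accumulates
`Omega_PI t + beta * (X(t) - X(0)) . d_k` — a periodic code for displacement
along its preferred direction `d_k` (oscillatory interference). A 20-neuron
LAHN with Oja-stabilized Hebbian afferents `q` and anti-Hebbian lateral
weights `w`,

    xi_i(t) = sum_j q_ij chi_j(t) + sum_k w_ik xi_k(t-1),
    dq_ij = eta_F (chi_j xi_i - q_ij xi_i^2),   dw_ik = -eta_L xi_i(t) xi_k(t-1),

learns the principal subspace of the oscillator stream; its neurons develop
spatially modulated, weakly hexagonal firing fields. Gridness is scored from
the rate-map autocorrelogram `r(tau)` as

    HGS = min[cor(r, r60), cor(r, r120)] - max[cor(r, r30), cor(r, r90), cor(r, r150)].

Five study families manipulate the arena: two rooms joined by a corridor
(shape and separation), convex square vs trapezoid, concave annulus /
horseshoe / S shapes of growing inner radius, regular polygons with 3–10
sides, and a rectangle that widens into a square while a multilayer
perceptron decodes the configuration from LAHN activity.

## Worked example

Train the model in a small square arena and score its most grid-like neuron:

```python
import numpy as np
from gridscape import geometry, spatial_maps as sm
from gridscape.network import train_model

env = geometry.make_square(0.9)
state = train_model(env, duration=600.0, seed=1)      # 60,000 steps at dt=0.01
ck = state.checkpoints[-1]
resp = state.replay_responses(ck.q, ck.w)             # (60000, 20)

scores = []
for k in range(resp.shape[1]):
    rm = sm.rate_map(state.trajectory, resp[:, k], bin_size=0.02)
    scores.append(sm.hgs(sm.autocorrelogram(rm)))
best = int(np.nanargmax(scores))
print(f"best neuron {best}: HGS = {scores[best]:.3f}")
print(f"population mean HGS = {np.nanmean(scores):.3f}")
```

```
best neuron 9: HGS = 0.684
population mean HGS = -0.144
```

A positive HGS means the autocorrelogram correlates better with its 60/120
degree rotations than with 30/90/150 — six-fold symmetry. Individual
neurons reach scores of ~0.1–0.4 in this model while the population mean
sits near zero, because the LAHN yields a spectrum of spatial cells of
which only a subset are grid-like; all geometry experiments therefore
report averages over neurons and seeds and read out *trends* (e.g. gridness
rising with the number of polygon sides, falling as a concave arena's inner
radius grows) rather than absolute scores.

The same pipeline is scriptable from the shell:

```bash
gridscape env --kind polygon --sides 7 --out heptagon.csv
gridscape forage --kind square --duration 600 --seed 7 --out traj.csv
gridscape run polygon --seeds 1,2,3 --out results/polygon/
```

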