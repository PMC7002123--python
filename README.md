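# viswarm

Agent-based simulator of collective behavior driven **purely by vision**:
each agent perceives nothing but the binary projection of its neighbors'
bodies on an omnidirectional retina — no positions, distances, headings or
identities — and still forms cohesive, collision-free, polarized groups.

The package is aimed at researchers in collective animal behavior, active
matter and swarm robotics who want a reference implementation of the
lowest-order visual-response model: to reproduce its phase behavior, to use
it as a baseline against explicit-interaction models (Vicsek-type, zonal),
or to extend it (graded visual fields, temporal responses).

## The model

In 2D, agent *i* is a disk of diameter BL propelled along its heading
ψ\_i with signed speed v\_i. Its retina coordinate φ ∈ (−π, π] (positive =
left) carries the binary visual field V\_i(φ): 1 where any other body
projects, occlusion being plain set union. The equations of motion are

    dv_i/dt = γ (v0 − v_i) + α0 ∫ dφ cos φ [ −V_i(φ) + α1 (∂φ V_i)² ]
    dψ_i/dt =                β0 ∫ dφ sin φ [ −V_i(φ) + β1 (∂φ V_i)² ]

The −V terms repel: a big silhouette ahead brakes the agent, one to the
side turns it away. The squared-derivative terms fire on silhouette
*edges* and attract. For a binary field the edge functional is evaluated
as a unit-weight Dirac comb — each edge contributes kernel(φ_edge) exactly
once — which makes α1, β1 dimensionless and puts the front-back pair
equilibrium at L_eq = BL/(2 sin arctan α1) ≈ BL/(2 α1).

The cylindrical 3D extension propels spheres with v\_ψ e\_ψ + v\_z e\_z
(no pitch rotation; the retina is heading-anchored in azimuth only) and
adds a vertical equation with coefficients λ0, λ1; edges are detected
left-right only. The geometry is exact in 2D (analytic arc unions) and
grid-based in 3D (default 128 × 64 spherical retina).

## Worked example

```bash
python examples/two_agent_equilibrium.py
```

```
time (BL/v0)   separation (BL)
           0   5.000
         100   11.272
         200   12.196
         300   12.426
         400   12.487
         500   12.504
         600   12.508

predicted balance distance: 12.510 BL (far-field BL/(2*alpha1) = 12.5 BL)
```

Two agents released 5 BL apart drift to the emergent equilibrium spacing —
12.51 BL for α1 = 0.04 — where subtended-angle repulsion balances edge
attraction, with no representation of distance anywhere in the model.

Other example scripts: `pair_response_surface.py` (short-range repulsion /
long-range attraction map and its zero crossing), `collective_states_2d.py`
(fluid swarm vs collision-free crystal-like state at N = 50),
`flattening_3d.py` (the 3D flattening transition in λ1/α1).

A thin CLI mirrors the library for shell use:

```bash
viswarm simulate --set N=50 --set alpha0=0.5 --set beta0=1.0 --seed 1
viswarm sweep2d --config config.yaml --out sweep.csv
viswarm pairmap --d-max 25 --out map.csv
```

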