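# rfbm — reflected fractional Brownian motion fiber simulator

`rfbm` models meandering neural fibers — such as the serotonergic axons that
form a dense matrix throughout vertebrate brains — as paths of discrete
two-dimensional fractional Brownian motion (FBM) confined to bounded,
brain-like domains. Its central result is geometric: without any local
biological control, the steady-state spatial density of such paths depends on
the Hurst index *H* of the motion and on the shape of the domain. Persistent
walks (*H* > ½) accumulate at boundaries, ordinary Brownian walks (*H* = ½)
distribute uniformly, and anti-persistent walks (*H* < ½) deplete the
boundary — a pattern that mirrors the elevated fiber densities seen along
pial and ependymal surfaces in stained tissue sections.

## Model

A fiber is the trajectory of the recursion

    r_{n+1} = r_n + xi_n,

where `xi_n` is two-component fractional Gaussian noise (fGn): each spatial
component is an independent, stationary, zero-mean Gaussian sequence with
per-step standard deviation σ and autocovariance

    gamma(n) = (sigma^2 / 2) * (|n+1|^{2H} - 2|n|^{2H} + |n-1|^{2H}).

Neighbouring increments have correlation `2^{2H-1} - 1`, and the free-path
mean-square displacement grows as `<x^2> ~ n^{2H}`. Confinement uses a
*rejected-step* boundary rule: a proposed step into the forbidden region is
simply not carried out (the walker stays put and the increment is consumed),
preserving the prescribed noise correlations.

The package provides, module by module:

- `rfbm.fgn` — exact fGn generation (circulant embedding, with a spectral
  Fourier-filtering alternative) and the closed-form statistics;
- `rfbm.domains` — bounded 2D regions: digitized contours stored as N×2
  row-interval matrices, an analytic lobed ring
  `R_outer(phi) = 100 (1 + 0.5 cos^2(4 phi))` / `R_inner = 50`, and a
  crowded disk (radius 100 with 1013 radius-2 obstacles packed inside
  radius 90), plus the contour smoothing / symmetrization / digitization
  pipeline;
- `rfbm.walker` — numba-accelerated reflected-walk propagation and
  seed-reproducible ensembles;
- `rfbm.density` — occupancy grids, the Beer–Lambert-like optical transform
  `d_o = 1 - exp(-k d_s)` with mean-matched attenuation `k`, and density
  cuts along segments;
- `rfbm.stats` — MSD and Hurst recovery, boundary-accumulation indices,
  angular boundary profiles, steady-state convergence distances,
  replicate-based uniformity tests, and crowding summaries;
- `rfbm.fixtures` / `rfbm.cli` — built-in study domains, TOML-config runs
  with manifests, and the `rfbm` command-line tool
  (`simulate`, `fixture`, `digitize`, `analyze`, `cut`).

## Worked example

Simulate a small persistent ensemble in the lobed ring and quantify the
boundary accumulation:

```python
import numpy as np
from rfbm import (SimulationConfig, make_fixture, run_ensemble,
                  boundary_accumulation_index, fit_attenuation)

ring = make_fixture("ring")
cfg = SimulationConfig(domain=ring, hurst=0.8, sigma=0.4, n_steps=2**16,
                       n_fibers=8, seed=1, cell_size=1.0)
res = run_ensemble(cfg)
report = boundary_accumulation_index(res.density, ring, band_width=0.8)
print(f"boundary index:     {report.index:.2f}")
print(f"band / interior:    {report.boundary_mean:.1f} / "
      f"{report.interior_mean:.1f} counts per cell")
print(f"rejection rate:     {res.rejection_rates.mean():.3f}")
cx, cy = res.density.center_mesh()
mask = ring.contains_many(cx, cy)
k = fit_attenuation(res.density, 0.35, mask=mask)
print(f"fitted attenuation: k = {k:.4g}")
```

Output:

```
boundary index:     17.71
band / interior:    138.3 / 7.8 counts per cell
rejection rate:     0.212
fitted attenuation: k = 0.07966
```

The boundary index is the mean occupancy in a thin band along the outer
contour divided by the interior mean: 17.7 means the persistent walkers
(*H* = 0.8) pile up against the border nearly twenty-fold relative to the
bulk. About 21 % of proposed steps were rejected at the walls. The fitted
`k` maps raw counts to optical densities in [0, 1) whose in-domain mean
matches the requested 0.35, the normalization used when comparing simulated
maps with stained-section images. Rerunning with `hurst=0.5` drives the
index to ≈ 1 (uniform density), and `hurst=0.3` (step size 1) drives it far
below 1 — the three diffusion regimes.

The same run can be driven from a TOML config:

```sh
rfbm simulate run.toml        # writes density.tsv, report.json, manifest.json
rfbm analyze out/density.tsv out/density_meta.json --fixture-name ring
```

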