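# petalfem

Finite-element analysis of **sclereid reinforcement in *Camellia* petal
laminae under raindrop impact**.

In unopened flower buds, the petal primordia shelter the reproductive
organs. In *Camellia sinensis* — a species with reduced, soft sepals — the
petal laminae are packed with sclereids (branched, lignified stone cells,
ca. 100–300 µm), covering ≥ 50% of the surface and concentrated toward the
petal apex. In *C. japonica*, whose robust sepals do the protecting, petal
sclereid coverage is at most 5% and usually zero. `petalfem` asks the
mechanical question behind this anatomy: *how much does a sclereid network
stiffen a petal lamina against a falling raindrop?*

The package is aimed at plant biomechanics researchers who want a small,
fully scriptable shell/beam FEM pipeline rather than a commercial solver.

## Model

* **Lamina** — a parametric ovate midsurface (default 15 × 10 × 0.3 mm,
  2 mm cup sagitta), triangulated into flat facet shells: constant-strain
  membrane + discrete-Kirchhoff (DKT) plate bending + drilling
  stabilization, 6 DOF per node.
* **Sclereids** — a stochastic network of branched cells (one column
  segment, 100–300 µm, plus 2–6 end branches) sampled against a spatial
  density gradient (apical, central, or uniform) until a target areal
  coverage is reached; each segment becomes a 3-D Euler–Bernoulli beam
  (E = 0.5 GPa, ν = 0.4) sharing nodes with the shell.
* **Raindrop** — a 2 mm sphere at terminal velocity 6 m/s converted to an
  equivalent static force, F = ρ π d² v² / 6 ≈ 0.075 N (momentum closure),
  spread as a cosine-tapered pressure over a 1 mm contact radius at the
  petal apex.
* **Output** — the equivalent (von Mises) elastic strain field,
  ε_eq = (1 + ν′)⁻¹ √(½[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²]),
  evaluated per element at top/mid/bottom surfaces.

The headline experiment solves the same lamina, load and parenchyma twice —
with the sclereid network (model A, *C. sinensis*-like) and without
(model B, *C. japonica*-like) — and reports the max-strain ratio
max_B / max_A. The unknown parenchyma modulus is calibrated once by
bisection so that this ratio matches the published 2.3-fold contrast; all
other findings (apical strain localization, strain–density correlation) are
then emergent.

## Worked example

```python
from petalfem import calibrate_parenchyma, default_config, run_comparison

rec = calibrate_parenchyma(target_ratio=2.3)
print(f"E_parenchyma = {rec.E_parenchyma:.3g} Pa, "
      f"achieved ratio = {rec.achieved_ratio:.3f}")

cfg = default_config()
cfg["materials"]["E_parenchyma"] = rec.E_parenchyma
rep = run_comparison(cfg, seeds=[1, 2, 3, 4, 5], calibration=rec)
print([round(r.strain_ratio, 3) for r in rep.results])
print(f"mean ratio = {rep.ratio_mean:.3f} +/- {rep.ratio_sd:.3f}")
print([round(r.density_strain_correlation, 3) for r in rep.results])
```

prints

```
E_parenchyma = 1e+07 Pa, achieved ratio = 2.335
[2.335, 2.342, 2.368, 2.618, 2.587]
mean ratio = 2.450 +/- 0.140
[0.754, 0.759, 0.734, 0.754, 0.772]
```

Read: with ~50% apically concentrated sclereid coverage, a sclereid-free
lamina reaches a 2.3–2.6× higher peak equivalent strain than the reinforced
one under the identical raindrop; the per-element strain of the reinforced
model correlates positively (Spearman ρ ≈ 0.75) with the local sclereid
density, and the strain maximum falls in the apical half where the
sclereids concentrate.

The same pipeline is available from the shell:

```bash
petalfem calibrate --target-ratio 2.3
petalfem compare --seeds 5 --out out/        # VTU fields + JSON report
petalfem generate --out out/                 # mesh + network only
```

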