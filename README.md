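# fgmem — two-phase fluid membrane Monte Carlo

`fgmem` is a coarse-grained simulator for phase separation in
multi-component lipid membranes (e.g. DOPC/DPPC/cholesterol vesicles).  A
closed, dynamically triangulated sphere represents the membrane; every
triangle carries a phase label σ = +1 (liquid-ordered, Lo) or −1
(liquid-disordered, Ld).  Vesicle shape and domain pattern evolve together
under a Metropolis Monte Carlo scheme, which makes the package useful for
studying how line tension and phase-dependent elasticity drive domain
morphologies — circular domains, stripes, rafts, and budding necks — seen
in three-component vesicle experiments.

## Model

The Hamiltonian at kB·T = 1 is

    S = λ·S0 + S1 + κ·S2

    S0 = Σ_bonds (1 − σᵢσⱼ)              aggregation (line tension)
    S1 = Σ_bonds γᵢⱼ ℓᵢⱼ²               Gaussian / tension energy
    S2 = Σ_bonds κᵢⱼ (1 − nᵢ·nⱼ)        bending energy

where (i, j) are the two triangles sharing a bond, ℓᵢⱼ is the bond length
and nᵢ a unit outward triangle normal.  The phase couples to the elastic
coefficients through a phase-dependent (Finsler-type) metric ratio
ρ = c (Lo) or 1 (Ld):

    κᵢⱼ = (ρᵢ + 1/ρᵢ + ρⱼ + 1/ρⱼ)/4
        = (c + 1/c)/2      on (Lo,Lo) bonds
        = (2 + c + 1/c)/4  on (Lo,Ld) boundary bonds
        = 1                on (Ld,Ld) bonds

**Model 1** uses γᵢⱼ = 1; **Model 2** uses γᵢⱼ = κᵢⱼ, which makes Lo
triangles smaller as well as stiffer.  The composition φ₀ = NTo/NT (Lo
triangle fraction) is conserved exactly: connectivity changes only through
bond flips, and a flip either keeps the two labels or swaps them to random
sides.  S0 equals twice the number of Lo–Ld boundary bonds, so λ·S0 is a
discrete line-tension energy.

Because the partition function is scale invariant, ⟨S1⟩/N = 3(N−1)/(2N) →
3/2 holds exactly for every parameter set — the package's strongest
self-check.

## Worked example

```python
import fgmem as fg

params = fg.ModelParams(lambda_=0.5, kappa=10.0, c=8.37, phi0=0.8,
                        variant=fg.MODEL2)
schedule = fg.RunSchedule(thermalization=50_000, measurement=200_000,
                          measure_interval=100, seed=3)
df, state = fg.run(params, schedule, subdivision=4)   # N = 162 vertices

print(f"<S1>/N            = {df.s1_per_n.mean():.3f}")
print(f"vertex acceptance = {df.vertex_acceptance.mean():.2f}")
print(f"kappa_ij Lo/Lo    = {fg.bond_coefficient(1, 1, 8.37):.2f}")
print(f"kappa_ij Lo/Ld    = {fg.bond_coefficient(1, -1, 8.37):.2f}")
print(f"mean areas  ao={df.ao.mean():.3f}  ad={df.ad.mean():.3f}")
print(f"Lo area fraction  = {df.area_fraction_lo.mean():.2f} (phi0 = 0.8)")
```

Output:

```
<S1>/N            = 1.473
vertex acceptance = 0.50
kappa_ij Lo/Lo    = 4.24
kappa_ij Lo/Ld    = 2.62
mean areas  ao=0.028  ad=0.147
Lo area fraction  = 0.43 (phi0 = 0.8)
```

Reading the numbers: ⟨S1⟩/N sits at the scale-invariance value 3(N−1)/(2N)
= 1.491 within the slow-mode wander of a single run; the move radius was
auto-tuned to ~50% acceptance; the bending coefficient on a bond inside an
Lo domain is 4.24× the Ld value at c = 8.37 and 2.62 on the domain
boundary; and in Model 2 the Lo triangles are ~5× smaller than Ld ones, so
80% of the triangles cover only ~43% of the area.

A YAML-driven command line mirrors the library (`fgmem run --config
cfg.yaml --seed 3`, `fgmem scan ...` for phase-plane grids); it writes a
TSV observable log, a PLY snapshot with σ as a per-face property, and an
HDF5 checkpoint that resumes into the identical trajectory.

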