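# Methods

## Model

`fgmem` simulates a coarse-grained two-phase fluid membrane: a closed,
dynamically triangulated sphere whose triangles carry a binary phase label

    sigma(triangle) = +1  (liquid-ordered, Lo; DPPC/cholesterol-rich)
                      -1  (liquid-disordered, Ld; DOPC-rich)

The Hamiltonian, at fixed temperature kB*T = 1, is

    S(r, T, sigma) = lambda * S0 + S1 + kappa * S2

    S0 = sum_bonds (1 - sigma_i sigma_j)           aggregation (line tension)
    S1 = sum_bonds gamma_ij * l_ij^2               Gaussian / tension energy
    S2 = sum_bonds kappa_ij * (1 - n_i . n_j)      bending energy

where every sum runs once over the undirected bonds of the triangulation,
(i, j) are the two triangles sharing the bond, `l_ij` is the bond length and
`n_i` the unit outward triangle normal.  `S0` is twice the number of
(Lo, Ld) boundary bonds, so `lambda * S0` is a discrete line-tension energy.

The phase enters the elastic coefficients through a phase-dependent
(Finsler-type) surface metric summarized by the metric ratio
rho = c (Lo) or 1 (Ld):

    kappa_ij = (rho_i + 1/rho_i + rho_j + 1/rho_j) / 4
             = (c + 1/c)/2      (Lo, Lo)
             = (2 + c + 1/c)/4  (Lo, Ld)
             = 1                (Ld, Ld)

Two variants are provided: **Model 1** keeps `gamma_ij = 1` (canonical
Gaussian energy, shape coupling only through `kappa_ij`), **Model 2** sets
`gamma_ij = kappa_ij`, so Lo triangles are additionally under higher
tension and shrink relative to Ld triangles.  Both are invariant under
c <-> 1/c; `ModelParams` canonicalizes to c >= 1.

Assumptions inherited from the model class: spherical topology, no
self-avoidance (surfaces may self-intersect, relevant for budding), no
area or volume constraint, no spontaneous curvature, fixed composition
phi0 = NTo / NT (the number of Lo triangles is conserved exactly).

## Monte Carlo protocol

* **Vertex move**: one random vertex is displaced by a vector drawn
  uniformly from a ball of radius R; Metropolis acceptance
  min(1, exp(-dS)).  A proposal that would create a zero-area triangle is
  rejected outright.
* **Bond flip**: one random bond; the shared diagonal of its two triangles
  is replaced by the opposite diagonal.  Flips are rejected when the new
  diagonal already exists, when an endpoint would drop below coordination
  3 (or exceed the capacity cap of 24), or when the two triangles share
  more than one bond.  If the two old triangles have equal sigma the new
  pair keeps it; if they differ, the labels are reassigned to a uniformly
  random side — either way NTo is conserved, and this is the only channel
  through which the phase pattern evolves.  Both proposal kernels are
  symmetric, so detailed balance holds.
* **Sweep**: N vertex attempts plus N flip attempts in a random
  interleaving (fresh Fisher–Yates permutation each sweep; the ordering is
  not prescribed by the model, and random interleaving avoids any
  systematic coupling between the two move types).  After every sweep the
  surface is recentred on the origin; the energy is translation invariant,
  so this is a gauge choice that fixes the centre of mass without biasing
  sampling.
* **Radius tuning**: during thermalization only, R is rescaled every
  tuning window by the factor clip(acceptance / 0.5, 1/2, 2), then frozen
  for the whole measurement phase (acceptance is monotone decreasing in R,
  so this is a stable multiplicative control loop converging to ~50%
  acceptance).
* **Energy bookkeeping**: acceptance decisions use exact local energy
  differences (star of the moved vertex; five-bond quadrilateral patch of
  a flip), verified against from-scratch recomputes to 1e-9 relative
  tolerance.  Component sums (S0, S1, S2) are accumulated incrementally
  and replaced by a full recompute at every measurement, so drift cannot
  accumulate beyond one measurement interval (`MCState.energy_drift`
  exposes the gap; it stays below 1e-6 relative over 1e4 sweeps).

All randomness passes through one seeded master generator (NumPy PCG64).
The compiled kernel is reseeded from the master stream before every block
of sweeps, which makes runs bit-reproducible from (seed, config) and lets
a checkpoint (full tables + counters + master RNG state) resume a run into
exactly the trajectory of the uninterrupted one.  Checkpoints store the
adjacency tables verbatim: rebuilding them from the triangle list would
permute bond ids and hence the RNG-to-bond mapping.

## Initial conditions

The lattice is a frequency-`l` geodesic icosphere (N = 10 l^2 + 2
vertices; `l = 24` gives the 5762-vertex production sphere).  Phase labels
are assigned by drawing exactly round(phi0 * NT) Lo triangles uniformly at
random — the random two-phase coexistence state.

The initial radius is a free choice because the partition function is
scale invariant.  By default the sphere is scaled so the initial Gaussian
energy sits at the scale-invariant fixed point: <gamma l^2> per bond
equals (3/2) N / NB, i.e. l0 = sqrt(1 / (2 gamma_bar)) with gamma_bar the
random-mixing average of the three tension coefficients at the chosen
phi0.  Starting elsewhere merely adds a slowly relaxing global breathing
mode to thermalization (the mean bond length would have to diffuse to its
equilibrium value at a rate set by the tuned move radius).

## The scale-invariance identity

Because Z is invariant under r -> alpha r with the centre of mass fixed,
the Gaussian energy obeys the exact identity

    <S1> = 3 (N - 1) / 2        i.e.  <S1>/N -> 3/2 for large N,

for every parameter set and both variants.  This is the strongest global
correctness check available: it couples the Hamiltonian, the proposal
kernels and the acceptance rule, and any bias shows up as a deviation.
The test suite asserts it at N = 162 (where the exact value is 1.4907)
within +-0.02.  Note that the time average converges slowly: the slow
modes are collective (global scale and shape), and in the
strongly phase-separated Model 2 regime single-run windows of 1e5 sweeps
wander by +-0.02 to +-0.05 around the identity.  The reference protocol
(5e4 thermalization + 2e5 measurement sweeps) keeps the residual wander
within the asserted band.

## Observables

* **Diameters** D1 >= D2 >= D3: full extents of the vertex cloud along
  the principal axes of its gyration tensor.  Extents (max minus min
  projection) rather than RMS surrogates are used because they match the
  intuitive notion of a caliper diameter; the choice affects absolute
  values but not the discontinuity signatures that distinguish prolate
  (stripe) from oblate (two-domain) shapes via D2.
* **Domains**: connected components of same-sigma triangles under bond
  adjacency (SciPy connected components on the triangle-adjacency graph).
  The boundary-bond count equals S0 / 2 identically.
* **Areas**: mean triangle area per phase (a_o, a_d) and the Lo area
  fraction NTo a_o / (NTo a_o + NTd a_d), which equals phi0 exactly only
  when a_o = a_d (Model 1); in Model 2 with c > 1 it falls below phi0.
* **Morphology label**: a pure function of the component statistics with
  documented thresholds (`MorphologyThresholds`): one/two circular Lo
  domains, stripe (one Lo band separating two Ld caps), multi-circular
  raft (3–6 comparable Lo patches), random (many small fragments).
  Budding evidence is a geometric flag, not a claim: a large Lo component
  whose boundary length L and area A satisfy L^2 / (4 pi A) < 0.3 is
  pinched well beyond a hemispherical cap (flat disc ~ 1, hemisphere 1/2,
  closed bud -> 0).

## Parameters

| parameter | meaning | typical range | notes |
|---|---|---|---|
| lambda | aggregation / line-tension coupling | 0 – 3 | in units of kB T per unit of S0 |
| kappa  | bending rigidity | 5 – 20 | multiplies kappa_ij; units 1/kB T |
| c      | metric ratio of the Lo phase | 1 – 10 | c = 1 erases the two-phase distinction |
| phi0   | Lo triangle fraction | 0 – 1 | conserved exactly |
| subdivision | icosphere frequency | 2 – 24 | N = 10 l^2 + 2 |
| R (auto) | move radius | tuned | ~50% acceptance after tuning |

Schedule defaults: measurements every 100 sweeps, tuning every 500
sweeps.  There is no prescribed thermalization fraction; the reference
runs in the tests use 5e4 thermalization + 2e5 measurement sweeps at
N = 162, chosen so the slow collective modes are averaged over many
correlation times while a full run stays in the minutes range on one CPU.

## What the simulations here do and do not show

The package's tests run desk-scale lattices (N = 42 to 642; the 5762-vertex
production sphere is built and validated but not evolved in CI-length
runs).  At these sizes the analytic structure — coefficient table, exact
identities, conservation laws, oracle equivalence of incremental energies
— is fully verified, and the qualitative phase behaviour (random mixing at
weak lambda, condensation into few domains at strong lambda, smaller Lo
triangles in Model 2) is demonstrated.

One quantitative caveat is documented deliberately: with S0 summed once
per undirected bond, the aggregation term is an Ising coupling J = lambda
on the (annealed, 3-regular) triangle-adjacency graph, whose ordering
threshold lies near the honeycomb critical coupling ~0.66; the
sigma-dependence of the elastic terms adds only a weak effective
attraction at Model 1, c = 5.  Consequently phase separation into O(1)
domains at these system sizes requires lambda of order 1 (lambda = 1.5
orders within 3e4 sweeps at N = 642, and a pre-separated state at
lambda = 0.4 melts back into fragments — the mixed state is the
equilibrium there, not a kinetic trap).  Alternative discretizations that
sum the bond energies over *directed* bonds would double every effective
coupling and shift this threshold accordingly; this implementation uses
the symmetrized single-count convention throughout.

## Numerical choices

* Degenerate-normal floor: squared cross-product below 1e-24 (coordinates
  are O(1)) marks a zero-area triangle; such proposals are auto-rejected,
  and a full energy evaluation on a degenerate surface raises.
* Incremental-vs-oracle tolerance: 1e-9 relative (double precision leaves
  ~1e-13 headroom on desk-scale patches).
* Vertex coordination is capped at 24 table slots; flips that would exceed
  the cap are rejected.  Equilibrium coordination numbers stay in the
  5–9 range, far from the cap.
* round(phi0 * NT) fixes NTo; banker's rounding at exact halves.
* Uniform-in-ball displacements by rejection sampling from the bounding
  cube (expected 1.9 draws per proposal).
* Morphology thresholds: random label above 6 Lo fragments with mean size
  below 5% of NT; raft patches "comparable" within a factor 10 in size.

## Known limitations

* No self-avoidance: budded necks can pass through the surface; the
  budding flag reports geometric evidence only.
* Desk-scale runs cannot reproduce full-scale phase diagrams (production
  runs at N = 5762 used elsewhere take 1e8+ sweeps); the scan driver
  (`fgmem.scan`) exists for mapping reduced planes.
* The observable log stores instantaneous measurements; error bars for
  slowly mixing observables (notably S1/N in the separated Model 2
  regime) need blocking analysis over long windows.
* Checkpoint resumption reproduces the uninterrupted trajectory only with
  the same build (the compiled kernel's RNG stream is part of the
  contract).
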