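# Methods

## The question the pipeline answers

A dual-dAb inhibitor is an IgG1-Fc homodimer with a V_H domain antibody fused
via a peptide linker at each Fc N terminus and a V_κ domain antibody via a
linker at each C terminus. Its antigen, the VEGF-A homodimer, presents two
equivalent epitopes related by a two-fold axis, and the two dAbs bind
overlapping sites on those epitopes. Solution data show one inhibitor
molecule carrying two antigen dimers; the pipeline asks which engagement
topology is geometrically consistent with that stoichiometry and with the
inter-terminal distances measurable from the two co-crystal structures
(antigen + V_H·dAb, antigen + V_κ·dAb).

The full calculation runs: read the two complexes → superpose on the shared
antigen → measure three inter-terminal Cα distances → test which site pairs
can clamp one antigen given linker reach → enumerate the complex species the
feasible clamps allow → compare predicted masses with SEC-MALLS mass
profiles → connect the resulting capacity (two antigen dimers per molecule)
to molar potency through an equilibrium competition model.

## Structure handling

Structures are parsed with gemmi; only the first model is kept, altloc A is
retained, and waters are dropped, so every downstream measurement is
deterministic. A chain "terminus" is the first/last *resolved* residue
carrying a Cα — crystal structures routinely lack ordered termini, and the
resolved terminus is the only measurable anchor point. Residues missing a Cα
are skipped in favour of the nearest resolved one.

Superposition uses the closed-form Kabsch algorithm (SVD with determinant
correction, so reflections are never returned). Antigen chains are matched
Cα-to-Cα by identical residue number within user-mapped chain pairs; no
sequence alignment is attempted because the antigen chains being compared
share numbering. An antigen rmsd above 5 Å raises a warning flag rather than
an error — a poor antigen match invalidates the cross-distance, but the
choice of threshold is a sanity cap, not science.

The cross distance (V_H C terminus to the V_κ N terminus at the *other*
epitope) needs to know which binder sits on which epitope. Callers can tag
epitopes explicitly in the role mapping; untagged, the larger of the two
V_H/V_κ pairings is taken, justified by the observation that the two dAbs
bind overlapping sites — same-epitope termini are necessarily the closer
pair. Interfaces are defined by any heavy-atom pair within 4.5 Å
(configurable; a conventional contact cutoff).

Solvent content uses the Matthews convention: V_M = V_cell/(Z·M) and
solvent fraction = 1 − 1.23/V_M, with the general triclinic cell-volume
formula and Z taken from the space-group operation count. The constant 1.23
ų/Da (reciprocal protein density × packing convention) is the standard
choice; the result is clamped to [0, 1).

## Linker reach and engagement classification

Linkers are modelled by contour length alone: 3.5 Å per residue (extended
polypeptide rise; the literature range is roughly 3.4–3.8 and the value is a
parameter). A pair of sites can co-engage one antigen when the measured
distance between their attachment points is within the *summed* extended
contour of the two linkers plus an anchor span — the separation of the two
linker attachment points on the Fc. Defaults: 15-residue linkers (the real
construct's linker sequences are not public, so this is an explicit
placeholder parameter), zero anchor span for the N-terminal pair (the two
heavy-chain N termini emerge adjacently at the hinge), 10 Å for pairs
involving the C-terminal attachment points at the base of the CH3 domains.

The verdict is driven by the extension fraction (required span / available
span): ≤ 0.75 feasible ("easily spans"), ≤ 0.95 marginal (requires an
extremely extended, low-likelihood conformation), above that infeasible.
The cutoffs are configurable; they encode the qualitative distinction
between a comfortable reach and a fully stretched chain, not a free-energy
calculation. With the defaults, 81 Å across two N-terminal linkers is
marginal (0.77), while 70 Å and 77 Å across parameterisations that include
the C-terminal anchor are feasible (0.61, 0.67).

Classification: *end-on* when both like-domain clamps (V_H–V_H and V_κ–V_κ)
are feasible; *side-on* when the V_H–V_H clamp is not feasible but the
V_H + same-half V_κ cross clamp is; *none* when nothing reaches. Marginal
counts as not-feasible for classification — the analysis deliberately treats
"only reachable when almost fully extended" as an unlikely binding mode.

## Species enumeration

A complex species is a connected bipartite multigraph between binder
molecules (with named sites) and antigen units (with two equivalent
epitopes), at most one bond per site and per epitope. Assembly rules encode
the geometry: which site pairs of one molecule may clamp both epitopes of a
single antigen, and whether two different molecules may share one antigen
(the move that lets conventional IgGs polymerise). Species are grown
edge-by-edge (new antigen on a free site / new binder on a free epitope /
internal ring-or-clamp closure), which reaches every connected species, and
deduplicated by graph isomorphism with sites distinguished by domain type
only — which half of the homodimer a bond uses does not change the species.
A Weisfeiler-Lehman hash buckets candidates and exact isomorphism decides
within buckets; enumeration aborts with an explicit overflow error beyond a
configurable species cap.

Default rule sets:

* **dual-dAb**: same-half V_H + V_κ clamps allowed (the side-on wrap), the
  V_κ–V_κ clamp across the bottom allowed (geometrically reachable), the
  V_H–V_H end-on clamp forbidden, and no intermolecular sharing — sharing
  would create a ~370 kDa two-molecule species that solution data do not
  show, so it is off by default and available as a flag.
* **IgG**: two equivalent sites, no intramolecular clamp (a Fab pair cannot
  wrap a small antigen dimer), sharing allowed → open chains and n:n rings.
* **trap** and **monovalent** reference layouts for comparators.

"Closed" species are those with every antigen epitope occupied. Under
dual-dAb rules the closed set is exactly {1:1, 1:2}; under IgG rules it is
the ring series {2:2, 3:3, ...} (plus the two-molecules-one-antigen cap
2:1) — the qualitative contrast between a self-limiting inhibitor and an
immune-complex former. Masses are additive (binder and antigen unit masses
in kDa); species labels are binder:antigen-dimer counts. Mass matching
against an observed mass or interval accepts predictions within a relative
tolerance (default 0.15, the conventional upper bound on SEC-MALLS accuracy
for protein conjugates) and ranks by relative error.

## SEC-MALLS model

The forward model is deliberately minimal: each species elutes as a Gaussian
concentration peak whose integral over elution volume equals the injected
amount; detector responses are RI = c·(dn/dc), UV = c·ε (1 cm path), and
LS = K*·c·M at zero angle with the second virial coefficient dropped (dilute
limit — the analysis reports masses, not interaction virials).
dn/dc defaults to 0.185 mL/g (protein convention), wavelength 658 nm,
solvent index 1.331. Inter-detector delays are simulated as trace shifts and
estimated by cross-correlation against the UV trace during alignment; a flat
correlation leaves the trace untouched with a warning.

The inverse step is the same relation read backwards: c = RI/(dn/dc),
M = LS/(K*·c) wherever c clears a concentration floor; everything below the
floor is masked rather than reported. Peaks are detected on the RI trace
(the concentration proxy — detecting on LS would bias toward high-mass
species), with extents taken at a 95 % height drop so neighbouring peaks do
not contaminate the concentration-weighted peak mass. Because forward and
inverse use the same relation, noiseless recovery is exact to numerical
precision — that property is a correctness check on the plumbing, while the
noise-replicate tests characterise the estimator's robustness.

What the simulation does *not* emulate: band broadening and column
dispersion, tailing from column interaction, partial complex dissociation
on-column (the experimentally observed mass running a few percent below the
arithmetic 1:2 sum is attributed to such effects and is not modelled), or
multi-angle form factors. Passing tests therefore demonstrate the inference
logic — Debye-Zimm inversion plus mass matching — not chromatographic
realism.

## Binding models

Sensorgrams follow the closed-form 1:1 Langmuir solution:
R(t) = R_eq(1 − e^{−(k_aC + k_d)t}) with R_eq = R_max·C/(C + K_D) in
association, first-order decay in dissociation, K_D = k_d/k_a. Fitting is
global across a concentration series, nonlinear least squares on
log-parameters from a fixed ladder of initial guesses (reproducible
multi-start; best cost wins), with standard errors from the Jacobian.
A single analyte concentration cannot separate k_a from k_d, so that input
raises a conditioning error. Mass transport and bivalent-analyte effects are
ignored — matching the instrument-software convention the rate constants
being reproduced came from — and a flag drops the top concentration curve,
mirroring the practice of removing curves distorted at high analyte.

Dose-response extraction is the four-parameter logistic
y = bottom + (top − bottom)/(1 + (EC50/dose)^hill); the two algebraic
orientations of a decreasing curve are normalised to top ≥ bottom with an
`inverted` flag, and the reported EC50 is then an IC50.

The competition model treats an inhibitor molecule as n independent,
equivalent antigen-trapping sites (n = `dimers_trapped_at_saturation`,
deliberately separate from the nominal paratope count so capacity and
per-site affinity vary independently). Free antigen solves the mass-action
conservation V_tot = V_f + n·I·V_f/(K_d + V_f) (closed-form positive root of
the quadratic; K_d = 0 gives the exact stoichiometric limit), and the
receptor-bound signal is the free-antigen occupancy of the receptor
normalised to the no-inhibitor control. In the tight-binding regime the
half-signal point sits at n·I ≈ V_tot − O(K_d,R), so the molar IC50 ratio of
a one-trap to a two-trap binder approaches exactly 2 — the capacity
advantage, independent of per-site affinity. Absolute IC50s of any real
plate assay depend on incubation, detection and washing details that this
equilibrium model does not represent; only the ratio and its limits are
meaningful outputs. Converting assay inputs quoted in ng/mL to molar units
requires an explicit antigen mass argument (e.g. 10 ng/mL of a 48 kDa dimer
≈ 208 pM).

## Synthetic fixtures

`make_toy_complex` builds poly-alanine, Cα-only chains: a zig-zag two-fold
antigen homodimer (non-collinear by construction, so superposition is
well-posed) shared coordinate-identically between the two complexes, and
straight binder domains whose terminal Cαs sit exactly at configurable
separations. The defaults place the V_H–V_H, V_κ–V_κ and cross separations
at 81/70/77 Å — the measured values the geometry stage must reproduce. The
construction is planar-symmetric, which imposes the envelope
d_cross ≥ (d_vh_vh + d_vk_vk)/2; requesting geometry outside it raises an
error. Generators are pure functions of config + seed (seeded jitter is
available but defaults to zero), so outputs are bit-reproducible.

`make_mixing_series` assigns species amounts by simplified occupancy rules —
dual-dAb halves fill sequentially (1:1 then 1:2), the IgG scenario uses a
fixed ring ladder dominated by 2:2, the trap scenario pairs 1:1 — then
forward-simulates chromatograms. These are assignment rules, not
polymerisation kinetics: the tested surface is the mass-profile and
species-assignment logic, not self-assembly physics. Retention times follow
a simple log-linear size model solely so peaks separate.

Every generator writes a ground-truth manifest; recovery tests compare
fitted values against the manifest, never against quantities re-derived from
the simulated signal.

## Problem sizes and numerical choices

Species enumeration runs at limits (4,4) in analyses and (3,3)/(2,2) in
oracle comparisons — the brute-force matching oracle grows factorially and
(2,2) already exercises every rule of the four-site architecture.
Chromatograms use a 1 s grid over 40 min; noise-robustness statistics use
100 seeded replicates at SNR 50. Kinetic recovery is verified across
K_D = 1 pM–10 nM with concentration series spanning 0.12–30× K_D. The 4PL
and 1:1 fits clip log-parameters to ±200 to keep exploratory optimizer steps
finite. All randomness flows through explicit integer seeds.

## Known limitations

* Linker lengths and anchor spans for the real construct are placeholders;
  conclusions about specific feasibility numbers (0.77 vs 0.67 extension)
  move with those parameters, though the side-on/end-on ordering is robust
  across the plausible range.
* The enumeration treats epitopes as strictly equivalent and bonds as
  present/absent; no cooperativity, strain, or partial occupancy.
* The Debye-Zimm stage assumes ideal dilute scattering and Gaussian elution;
  it cannot reproduce the experimentally observed slight mass shortfall of
  weakly associated complexes.
* The competition model has no kinetics, depletion of receptor, or wash
  steps; it is a capacity argument, not an assay simulator.
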