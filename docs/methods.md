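# Methods

## Scope and model

`cgassoc` simulates the association of two proteins as rigid bodies in a
periodic cubic box using kinetic Monte Carlo, and converts ensemble
association probabilities into bimolecular rate constants. The model targets
the *encounter* step of association — diffusional search plus formation of a
loosely bound, partially native-like complex — not induced fit, folding upon
binding, or conformational gating. All intramolecular degrees of freedom are
frozen at the input coordinates.

### Coarse-grained representation

Each residue contributes two interaction sites: its Cα atom and a side-chain
functional center. The functional center is the centroid of the side-chain
heavy atoms; glycine's coincides with its Cα, and residues missing all
side-chain heavy atoms fall back to Cα with a logged warning. The literature
on two-site models chooses functional-center atoms per residue chemistry,
but no complete table is published; the heavy-atom centroid is a
reproducible, residue-complete stand-in, and a per-residue override can be
added through the charge/parameter hooks if a specific atom convention is
preferred.

Side-chain charges (e units, at the SC site only): ASP/GLU −1, LYS/ARG +1,
HIS 0 by default (overridable, e.g. +0.5 for a partially protonated
histidine). Hydropathies are the Kyte–Doolittle scores. Common non-standard
residues (MSE, SEP, TPO, PTR, …) are mapped to their standard parents;
unmappable polymer residues are rejected rather than silently dropped.

### Native contact map

Interface topology is extracted once from the native complex: residues i (of
the receptor) and j (of the ligand) are in native contact when any pair of
their side-chain heavy atoms lies within 5.5 Å. Each contact stores the
native SC–SC center distance r0ᵢⱼ. Zero extracted contacts is a fatal,
diagnosed error (almost always a wrong chain assignment). Glycine, having no
side-chain heavy atoms, is represented by its Cα in the contact criterion.

## Force field

The total intermolecular energy (kT units throughout; Metropolis temperature
is therefore 1) is

    E_tot = (1 − ω) · E_physics + ω · E_statistics,  ω ∈ [0, 1], default 0.6.

### Physics-based terms

* **Screened electrostatics** between charged SC sites:
  E = Σ qᵢqⱼ / (4π ε₀ D_eff rᵢⱼ), with the distance-dependent dielectric
  D_eff = D_s · exp(rᵢⱼ/ξ) (D_s = 80). The Debye length ξ defaults to 10 Å
  and can be set from an ionic strength as ξ = 3.04/√I(M). Pairs beyond
  30 Å (several Debye lengths) are dropped. Coincident charged sites are a
  fatal error; the steric wall makes them unreachable in sampling.
* **Hydrophobic term**: −w_α Σ (HPᵢ + HPⱼ) over SC–SC pairs within 7.5 Å.
  Summed over *all* pairs with no distance window the term would be a
  configuration-independent constant, so a contact window is required; the
  sign is chosen so that burying high-hydropathy side chains is favorable.
  Both window and sign are configurable. w_α (kT per unit summed score,
  default 0.1) is the free balance parameter of the physics potential; no
  published tuned value exists, and the benchmark-scale rescaling of rates
  absorbs moderate miscalibration.
* **Excluded volume**: Σ ε(r) [(σ₀/r)¹² − (σ₀/r)⁶] over all site pairs,
  where ε(r) is a step function: 5 kT inside σ₀ and 0 outside. σ₀ is 3.8 Å
  (Cα–Cα), 2.8 Å (Cα–SC), 2.2 Å (SC–SC).

### Statistics-based term

A Gō-like term over the native contact pairs only, modulated per pair by a
quasi-chemical contact potential u_sc(i,j) over residue types, with
x = (r0/r)⁶ evaluated at the current minimum-image distance. Three
functional forms are provided (`stat_mode`):

* `anchored` (default): attractive pairs (u_sc < 0) get
  |u_sc| (x² − 2x) — a 12-6 well of depth |u_sc| with its minimum exactly at
  the native distance r0; repulsive pairs get u_sc·x².
* `scaled`: |u_sc| (g·x² − f·x) with sign prefactors f = +1/−1 and g = −1/0
  for attractive/repulsive pairs.
* `literal`: the bare g·x² − f·x form, u_sc acting only through its sign.

The `scaled` and `literal` brackets make the attractive branch
−x² − x, which is unbounded below as r → 0: in rigid-body sampling a single
contact pair can slide far below r0 into an effectively bottomless well
(energies of −10⁶ kT and beyond are reached within hundreds of steps on
thin test systems whose sterics cannot block the approach) and the complex
freezes in a non-native geometry. That behavior inverts the expected trend
of association probability with interaction strength, so the anchored form
— the unique minimal modification that bounds the attractive branch and
places its minimum at the native distance — is the default. On real
interfaces, where steric bulk usually prevents sub-native approach, the
three forms behave similarly at moderate |u_sc|; the alternatives remain
available and fully tested.

A pair with u_sc = 0 contributes nothing in every mode (f(0) = g(0) = 0
boundary convention).

### Contact-potential derivation

u_sc(i,j) = −kT ln[ N_obs(i,j) / (χᵢ χⱼ N_obs) ], the quasi-chemical
inversion of interface contact counts. Counting is over *ordered* pairs
(each contact increments (i,j) and (j,i)), which makes the mole fractions χ
exactly the marginals of the count matrix and the table symmetric by
construction. Zero-count cells between observed types receive a pseudo-count
of 1 (avoiding infinite repulsion from sampling zeros); types absent from
the library altogether get u_sc = 0.

The bundled default table (`data/default_usc.tsv`) is produced by this
pipeline from a synthetic million-contact library sampled from a
hydropathy-plus-charge seed potential (`scripts/make_default_table.py`). It
has realistic magnitudes (|u_sc| ≲ 1 kT) and the statistical texture of a
library-derived table, but is synthetic: it is not extracted from any
structural database, and no published table is reproduced. Users with a
domain-interface library can derive and load their own TSV.

The synthetic library generator draws contacts i.i.d. from
P(i,j) ∝ χᵢχⱼ exp(−u/kT). When u does not preserve the background marginals,
the quasi-chemical inversion identifies u only up to per-type additive
shifts; the generator therefore exposes the *implied* self-consistent table
(−ln[P/(mᵢmⱼ)] with m the contact marginals), which is the exact large-sample
limit of the inversion and equals the input table whenever the input is
marginal-preserving (e.g. the null table). Parameter-recovery tests target
the implied table; RMSE at 10⁶ contacts is ≈ 0.016 kT.

## Kinetic Monte Carlo

* **Initialization**: both centers uniform in the box, orientations uniform
  over SO(3) via normalized Gaussian quaternions (naïve uniform Euler angles
  would bias orientations). Whole placements are resampled (≤ 1000
  attempts) until no inter-protein site pair violates its σ₀.
* **Moves**: every step, both proteins receive a Gaussian translation
  (per-axis std √(2 D_t dt)) and a rotation about a uniform random axis by a
  Gaussian angle (std √(2 D_r dt)). The joint move is accepted or rejected
  by a single Metropolis decision, min(1, exp(−ΔE/kT)), on the total
  intermolecular energy. Centers are wrapped into the box; all
  inter-protein distances use the minimum-image convention.
* **Diffusion constants**: Stokes–Einstein for a sphere of hydrodynamic
  radius R_h = 0.9 R_g + 4 Å in water at 298 K (η = 0.89 mPa·s):
  D_t = kT/6πηR_h, D_r = kT/8πηR_h³. Absolute diffusion scale only shifts
  the effective time unit, which the benchmark-level probability-to-rate
  rescaling absorbs; per-protein overrides are available for users with
  measured or boundary-element values.
* **Encounter criteria**: a native contact is *restored* when its current
  SC–SC distance is within 2 Å of r0. The default criterion is ≥ 3 restored
  contacts; optional conjunctive criteria are minimum restored percentage,
  maximum complex RMSD, maximum interface distance (minimum current
  distance among native contact pairs), and maximum total energy. Criteria
  are checked every step (including step 0); trajectories terminate at first
  satisfaction unless termination is disabled for landscape scans, in which
  case per-step diagnostics of all five criterion values can be recorded for
  post-hoc scanning.
* **Bookkeeping**: the total energy is recomputed in full every step from a
  single shared distance matrix (no incremental updates, so no drift).
* **Determinism**: trajectory t uses seed base_seed + t; all randomness
  flows through per-trajectory generators, so ensembles are bitwise
  reproducible and independent of execution order.

Default protocol: 100 Å box, 10³ steps of 1 ns, 10⁴ trajectories per
complex.

## Rate estimation

The association probability Pᵢ (fraction of trajectories forming an
encounter complex) maps to a rate constant by

    konᵢ = kon_min · 10^[(Pᵢ − P_min)/(P_max − P_min) · N],

with P_min/P_max the extreme probabilities over the analyzed set,
kon_min = 1.03×10⁵ M⁻¹s⁻¹ and N = 4 (the experimental floor and span of the
calibration benchmark). No parameter is fitted to experimental rates.
Probabilities outside [P_min, P_max] under a frozen model are reported as
censored bounds. Benchmark agreement is summarized by the Pearson
correlation of log₁₀ rates and by counts of complexes off by more than one
order of magnitude. The ω-scan re-simulates each weight (Metropolis
acceptance depends on ω, so cached-component re-weighting would be
incorrect) and recomputes P_min/P_max per ω; the criteria scan re-evaluates
stored per-step diagnostics over the threshold grids (contacts 0–10,
percentage 0–10 %, RMSD 0–30 Å step 3, interface distance 0–10 Å, energy 0
to −30 kT step 3) and reports the best-correlating combination.

## Trajectory analysis

Complex RMSD superposes the receptor Cα trace onto the native receptor
(least-squares rigid fit) and takes the RMSD over ligand Cα positions,
isolating binding-pose error; an all-Cα variant is available. Analysis uses
the ligand's nearest periodic image relative to the receptor, so boundary
wrapping never inflates distances. The ligand cloud transforms final ligand
centers of mass into the receptor-aligned native frame with deterministic
subsampling. The energy–RMSD correlation over final configurations of all
trajectories (associated or not) is the funnel diagnostic: positive values
mean native-like geometries are energetically favored.

## Synthetic study system and what it does (not) show

Tests and the acceptance study run on generated "mini-protein" dimers:
straight virtual-Cα backbones (3.8 Å spacing) with side-chain pseudo-atoms
2 Å off the backbone, contact residues at every second position pointing at
the partner chain so that a prescribed number of native contacts exists at a
prescribed distance (default 4 Å), all other side chains pointing away. The
fixtures round-trip through the real PDB parsing path.

The scaled association study uses a 9-residue-per-chain uncharged
hydrophobic/polar dimer with 5 native contacts in a 45 Å box, 125–500 steps,
and 400–500 trajectories per condition, with a 4-of-5 contact criterion for
the strength scan (the stricter criterion suppresses the strength-independent
"lucky geometric hit" channel and isolates the well-depth effect). Under
these conditions the association probability rises monotonically with the
Gō-well depth (≈ 0.02 → 0.03 → 0.07 for depths 0.5/2/6 kT) and with
trajectory length, and the final-configuration energy–RMSD correlation is
clearly positive (≈ 0.5).

Two observed regimes are worth recording. In roomy boxes association is
*capture-limited*: probability depends strongly on trajectory length and
only moderately on well depth. Under tight confinement (≈ 25 Å box, long
trajectories) the model becomes *trap-limited*: very deep wells (≳ 10 kT)
hold partners in misregistered single-contact geometries and can *lower*
the association probability relative to weak attraction. Both behaviors are
properties of the model, not artifacts.

The toy systems have none of real interfaces' shape complementarity,
side-chain packing, or charge anisotropy, and the bundled contact table is
synthetic. Passing tests therefore demonstrate the correctness of the
machinery (energies, sampling, criteria, statistics) and the qualitative
physics (electrosteering, funnel correlation, criterion monotonicity) — not
quantitative rate accuracy on real complexes. Reproducing benchmark-scale
correlations against experimental rates requires user-supplied structures
and ~10⁴ trajectories per complex (hours per complex on one core).

## Numerical choices and edge cases

* Energies in kT at 298.15 K; lengths in Å; time in ns. The Coulomb
  prefactor e²/(4πε₀kT) = 560.4 Å is computed from CODATA constants.
* Zero inter-site distance: fatal in the electrostatic and statistical
  terms; +∞ in the excluded-volume term.
* Excluded-volume bracket is exactly 0 at r = σ₀ (both step and bracket
  vanish); the step uses r < σ₀.
* Metropolis accepts ΔE ≤ 0 without drawing, so a zero-interaction system
  performs pure diffusion with acceptance 1.
* RMSD superposition uses an SVD-based least-squares fit (proper rotations
  only).
* Degenerate probability ranges (P_max = P_min) are fatal in rate
  conversion; the criteria scan marks such combinations NaN and skips them
  when selecting the optimum.

## Known limitations

* Rigid bodies only; no flexibility, gating, or folding-upon-binding.
* Two bodies only; no crowding or competition.
* Stokes–Einstein diffusion ignores shape anisotropy and hydrodynamic
  coupling between the partners.
* The hydrophobic term is a contact-count surrogate; hydrogen bonds,
  dipoles and π-stacking enter only implicitly through the statistical
  term.
* kon_min and N are benchmark constants, not transferable physics; applying
  a frozen rate model outside its calibration set yields censored bounds at
  the edges.
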