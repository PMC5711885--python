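# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Poisson vesicle-occupancy model

A reconstitution mixture distributes protein over vesicles in proportion
to membrane area. For a vesicle of radius *r* (nm) at
refractory-corrected protein/phospholipid ratio *x* (g/mol), the number
of functional scramblases is Poisson with mean

    μ(r) = α·x·r²/2,    α = 16/(M·ε²),

which is the number of lipids in the vesicle bilayer (8r²/ε², two
leaflets of area 4πr² at πε² per lipid) times the protein/lipid molar
ratio x/M. A vesicle is scramblase-active iff it carries at least one
functional unit, so averaging 1 − e^(−μ(r)) over the Gaussian radius
distribution N(r̄, σ²) — integrated over the whole real line — gives

    p(≥1) = 1 − (1 + αxσ²)^(−1/2) · exp(−αx·r̄²/2 / (1 + αxσ²)).

With r̄ = 88 nm and σ = 28 nm the coefficients are exactly σ² = 784 nm²
and r̄²/2 = 3872 nm². The synthetic generator instead truncates radii at
zero and resamples; at r̄/σ ≈ 3.14 the truncated mass is < 1e-3 and every
tolerance that compares the two routes budgets an extra 1e-3 for it.

Defaults (all configurable on `VesiclePopulation`): r̄ = 88 nm, σ = 28 nm,
refractory fraction 0.35 (hence PPR* = PPR/0.65), ε = 0.472 nm,
F_o = 45% (protein-free baseline; in practice measured per experiment),
F_max = 82.5% (saturating-protein end point).

**Fitting.** α is estimated by unweighted Levenberg–Marquardt
least squares (lmfit) on p(≥1) versus PPR*, SE from the Jacobian at the
optimum; M = 16/(αε²) with first-order error propagation
(SE_M/M = SE_α/α); the 95% band uses the t quantile on the α SE, valid
because the model is monotone in α. Measured p values are clamped to
[0, 1]; end points below F_o (baseline noise) become p = 0 with a
warning. The start value inverts the small-αx expansion at the median
informative point. The oligomeric order is the mass ratio to the
41,700 g/mol monomer rounded to the nearest integer ≥ 1, flagged "≥n"
when the ratio exceeds n by more than 0.05 — enough that a ratio of
~2.11 reads "≥2" while 0.91 reads "1".

**Assay design.** The default simulated series uses 12 PPR points
spanning 0–3 mg/mmol, dense at low PPR
(0, 0.03, 0.06, 0.09, 0.12, 0.16, 0.2, 0.3, 0.5, 1, 2, 3). For a
monomer-sized scramblase the occupancy curve saturates by PPR ≈ 0.3, so
nearly all Fisher information about α lives below that; the dense-low
design yields a theoretical relative SE on α of ~4.4% at the default
noise (SD 0.03 on p), versus ~17% for a uniform grid. End-point noise
defaults to 1 percentage point on F; trace noise to SD 0.005.

## Quench-trace kinetics

Traces normalized to 1 at dithionite addition are fit to
F(t) = (1 − Plateau)·e^(−Kt) + Plateau − S·t. The half-life is reported
as 0.69/K, keeping the conventional rounded constant (not ln 2) so
values line up digit-for-digit with the assay literature. Initialization
is deterministic — plateau from the last-decile mean, K from a
log-linear fit of the early decaying points, S from zero — and the
optimizer runs unbounded: bound transforms measurably degraded
convergence and SE estimation (half-life error SD 0.40 s bounded vs
0.058 s unbounded at the default noise). A fit whose K SE exceeds K
raises a quality warning. The end point fed to the occupancy analysis is
100·(1 − Plateau), i.e. the fitted plateau rather than the last raw
sample: only the plateau varies with protein load, while the half-life
tracks the rate-limiting dithionite chemistry (~20 s) in all conditions.
Simulated traces default to 2 Hz × 300 s (>10 half-lives).

## Photobleaching step counting

Spot traces (20 Hz default) are segmented by binary-segmentation
change-point detection under a piecewise-constant + Gaussian-noise
model: recursive best-SSE splits, accepted only when the level change
exceeds 3× the noise SD (robustly estimated from the MAD of first
differences) and both segments last ≥ 5 frames. Because all spots in a
movie share one fluorophore, the single-fluorophore step height is
estimated movie-wide (median final downward transition across traces)
and segment levels are quantized to integer multiples of it; the step
count is the total downward movement in quantized levels. This counts
two fluorophores bleaching within one dwell window as two steps and
stops blended partial levels from inflating counts — without it,
counting accuracy on simulated dimer fields falls from ~97% to ~94%.
A trace is "uncountable" when it re-brightens by more than half the
typical step, its residual noise exceeds a third of the step size, it
shows no downward step, or it exceeds 5 steps.

The observation model for an n-mer with per-protomer labeling efficiency
q is Binomial(n, q) conditioned on ≥1 visible fluorophore, convolved —
with probability c — with one independent coincident molecule
(Binomial(n, q)); at realistic spot densities higher-order coincidence
is negligible and is not modeled. Defaults q = 0.8 (SNAP-tag labeling
efficiency, >80% in practice) and c = 0.08 (a calibration choice
reproducing the ~90% one-step fraction characteristic of monomer
preparations; not an independently measured quantity). Oligomer
inference picks n ∈ {1..4} minimizing the squared distance between the
renormalized countable step fractions and the model; candidates tied
within 1e-4 are flagged inconclusive.

Spot distributions are averaged per movie and the SEM taken across
movies, matching how bar-graph summaries with ~5 movies of ~200 spots
are built.

## Residual hydrophobic mismatch

RHM is the hydrophobic-mismatch penalty not relieved by membrane
deformation: hydrophobic residue surface accessible outside the bilayer
hydrophobic core, or polar residue surface buried inside it, each
costing σ_res = 0.0028 kcal/(mol·Å²). The core is modeled as a planar
slab [z_lower, z_upper] (default ±15 Å about the midplane, the typical
acyl-chain half-thickness). Solvent-accessible surface areas come from
an in-package Shrake–Rupley implementation (probe 1.4 Å, deterministic
golden-spiral point sets, 960 points/atom default, NACCESS-compatible
element radii) that retains each atom's accessible surface points so a
residue's area can be partitioned exactly by the z coordinate of those
points; inside + outside area equals the residue's total SASA by
construction. In the full continuum-MD treatment the "membrane-occluded"
SASA is computed with lipid atoms added to the solute; the slab
partition approximates that construction without an explicit bilayer,
and `rhm_from_table` accepts externally computed per-residue
SA_prot/SA_mem tables for workflows that have one. Convergence: helix
energies at 960 vs 4000 points/atom agree within 2%.

Residue classes: hydrophobic {Ala, Val, Leu, Ile, Phe, Met, Pro, Gly,
Cys} (Gly/Pro membership is a convention and overridable); Ser/Thr
always exempt (side-chain hydroxyls hydrogen-bond to the backbone); Trp
exempt when its side-chain reference point (Cβ, falling back to Cα)
lies within the 3 Å headgroup margin of a slab boundary (interfacial
accommodation); Arg/Lys exempt within the same margin (snorkeling);
everything else polar, including unknown residue names (with a
warning). The 3 Å margin quantifies "interfacial"/"near the headgroups",
which has no standard numeric definition; it is configurable.

Statistics mirror replicate-simulation practice: the bootstrap SD draws
four subsets of three replicates (without replacement within a subset),
takes each subset mean, and reports the sample SD of the four means;
construct comparisons use the two-sided unpaired t-test per helix.

## Synthetic data: what it does and does not emulate

Generators are seeded and bit-reproducible. They emulate Gaussian
vesicle-size ensembles with a Bernoulli refractory subpopulation and
Poisson occupancy; end-point series built from sampled occupancy plus
Gaussian measurement noise; quench traces from the trace model plus iid
Gaussian noise; spot traces as step_height × (live fluorophores) with
exponential bleach times and iid Gaussian noise; and ideal poly-residue
α-helices (rise 1.5 Å, twist 100°/residue, one bulk-scaled Cβ
pseudo-sphere per residue) for slab energetics. They do not emulate
vesicle lamellarity or orientation effects, dithionite permeation,
fluorophore blinking, background drift in TIRF movies, camera shot
noise, or real side-chain geometry — so passing tests demonstrate the
estimators recover the generative parameters under the stated noise
model, not robustness to every artifact of real recordings.

## Problem sizes

Default test and script scales were chosen for desk-scale runs: 10⁵–10⁶
vesicles per Monte-Carlo check (binomial SE ≲ 1.6e-3), 12-point assay
series, 100 trace-noise replicates, 200–500 spots per simulated movie
and 50 replicate fields for discrimination checks. All scale linearly if
larger runs are wanted.

## Known limitations

- The slab partition of protein-only SASA is an approximation to
  lipid-in-solute SASA; absolute RHM energies from explicit-bilayer MD
  ensembles are not reproducible from a single static structure, and no
  attempt is made to do so.
- The occupancy fit assumes every reconstituted protein is functional
  and vesicles are unilamellar; violations bias M upward.
- Step counting assumes immobile spots and a stable background; traces
  from drifting or blinking spots should be pre-filtered upstream.
- The coincidence model allows at most one extra molecule per spot.
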