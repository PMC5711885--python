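# scramblefit

Quantitative analyses for phospholipid scramblase reconstitution studies.

Phospholipid scramblases such as the GPCR opsin move lipids between
bilayer leaflets without ATP. Their activity is measured by
reconstituting the protein into large unilamellar vesicles carrying a
trace of NBD-labeled phosphatidylcholine and adding dithionite, a
membrane-impermeant reductant that bleaches only outer-leaflet NBD:
protein-free vesicles lose ~45% of their fluorescence, scramblase-active
vesicles approach the ~82.5% maximum. `scramblefit` implements the four
analyses that turn such measurements into mechanistic conclusions about
the size and stoichiometry of the functional scramblase:

- **Poisson vesicle occupancy** (`scramblefit.occupancy`). A vesicle of
  radius *r* reconstituted at protein/phospholipid ratio PPR (mg/mmol,
  dimensionally g/mol) carries a Poisson-distributed number of
  scramblases with mean μ(r) = α·x·r²/2, where x = PPR* = PPR/0.65
  corrects for the ~35% of vesicles refractory to reconstitution and
  α = 16/(M·ε²) encodes the molar mass M of the functional unit (ε =
  0.472 nm is the lipid cross-sectional radius). Averaging the Poisson
  zero class over the Gaussian vesicle-size distribution (r̄ = 88 nm,
  σ = 28 nm) gives the closed form

      p(≥1) = 1 − (1 + αxσ²)^(−1/2) · exp(−αx·r̄²/2 / (1 + αxσ²))

  with coefficients σ² = 784 nm² and r̄²/2 = 3872 nm². Fitting measured
  p(≥1) versus PPR* yields α, hence M and the oligomeric order
  relative to the 41,700 g/mol monomer.
- **Quench-trace kinetics** (`scramblefit.kinetics`). Traces are fit to
  F(t) = (1 − Plateau)·exp(−K·t) + Plateau − S·t; the half-life 0.69/K
  reports the rate-limiting dithionite chemistry and the plateau gives
  the end-point reduction fed to the occupancy analysis.
- **Photobleaching subunit counting** (`scramblefit.photobleach`).
  Automated change-point step counting on single-molecule spot traces,
  with a binomial labeling + spot-coincidence model to infer the
  oligomeric state from the 1-, 2-, …-step fractions.
- **Residual hydrophobic mismatch (RHM)** (`scramblefit.rhm`). Per-helix
  energies σ_res·ΣSA_res (σ_res = 0.0028 kcal/(mol·Å²)) from a
  Shrake–Rupley SASA partitioned against a planar membrane-core slab,
  with the Ser/Thr, interfacial-Trp and Arg/Lys-snorkeling exemptions,
  replicate bootstrap SDs and unpaired t-tests between constructs.

`scramblefit.synthetic` generates every input with known ground truth —
vesicle ensembles, assay series, quench traces, bleaching spot fields,
ideal toy helices — so the whole pipeline runs with no external data.

## Worked example

`examples/occupancy_molar_mass.py` simulates end-point assay series for
two species and recovers their masses from the data alone:

```
WT-like    alpha =  7.78 +/- 0.34 x1e-4 mol/g/nm^2   M =  92,274 +/-  3,994 g/mol   order >=2
QUAD-like  alpha = 18.79 +/- 0.42 x1e-4 mol/g/nm^2   M =  38,227 +/-    858 g/mol   order 1
```

The first species reconstitutes as a dimer or larger (mass just above
2 × 41,700 g/mol), the second as a monomer — the discrimination at the
heart of the assay. The other examples cover trace fitting
(`trace_kinetics.py`, half-life 22.6 ± 0.03 s across six replicates),
subunit counting (`subunit_counting.py`, 90.6% one-step spots → 1-mer)
and slab energetics (`helix_rhm.py`, interfacial tryptophans cut a
protruding helix's RHM from 2.11 to 0.34 kcal/mol).

A thin CLI mirrors the stages:

```sh
scramblefit simulate assay --molar-mass 41700 --seed 1 --out assay.csv
scramblefit fit-occupancy assay.csv --out report.json
scramblefit fit-traces traces/ --out summary.csv
scramblefit count-steps movie_*.csv --out dist.json
scramblefit rhm helix.pdb --config slab.yaml --out rhm.csv
```

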