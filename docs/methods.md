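# Methods

This package re-implements, as a tested pipeline, the computational analysis
of a series of 28 anti-proliferative curcumin mimics —
3,5-bis(arylidene)-4-oxo-piperidine-1-carboxamides — screened against
HCT116 (colon), MCF7 (breast) and A431 (skin) carcinoma lines, the RPE1
normal line, and human topoisomerase IIα. The analysis has four layers:
a validated compound/activity library, a molecular-descriptor engine, a
best-multilinear-regression (BMLR) QSAR layer with internal validation, and
a pharmacophore fit-value → activity calibration. This note documents the
models, the numerical choices, and what the synthetic data do and do not
establish.

## Compound library

Each compound is one scaffold — a 4-piperidone with two exocyclic
(E)-arylidene olefins at C-3/C-5 and an N-1 carboxamide — so every fixture
SMILES is instantiated from a single template with two substituent slots
(six arylidene classes × five carboxamide classes, 28 realized pairs). The
E,E geometry is encoded with directional bonds and checked by CIP
assignment. Formula arithmetic uses CIAAW conventional atomic weights to
three decimals (C 12.011, H 1.008, N 14.007, O 15.999, F 18.998, Cl 35.45,
S 32.06), which reproduce all 28 published molecular weights to ±0.01 g/mol
and the required C/H/N percentages to ±0.02 points. Reported values are
rounded half-up to two decimals, matching table presentation.

Censored activity entries (">50.00 µM") are stored as a bound plus an
operator, never as bare numbers, because the derived therapeutic indices
propagate them: TI = IC50(RPE1)/IC50(cancer) carries operator `less_than`
whenever the RPE1 entry is a bound (the tables' printed convention), and is
undefined when the cancer-line entry itself is censored.

## Descriptor engine

Nine descriptors, the union of the three published cell-line models:

* **Mean information content (order k)** — Shannon entropy (bits) of the
  atom partition; order 0 partitions by element, each higher order refines
  a class by the multiset of neighbour classes (Morgan-style spheres).
* **Empirical ("Zefirov-type") charges** — Sanderson electronegativity
  equalization: all atoms equalize at the geometric mean S_mol of the
  isolated-atom electronegativities and
  q_i = (S_mol − S_i)/(2.08·√S_i), with a uniform shift enforcing the exact
  molecular charge. Fast and geometry-free; atoms of one element share one
  charge, so automorphism invariance holds by construction, at the cost of
  not resolving chemical environments.
* **Solvent-accessible surface areas** — Shrake–Rupley with a deterministic
  golden-spiral quadrature (default 960 points), probe 1.4 Å, Bondi radii.
  One shared point set makes Σ(atomic SASA) identically the total molecular
  surface area (TMSA). Boundary points of exactly coincident spheres are
  kept by the lowest atom index so a duplicated sphere contributes its
  surface once.
* **CPSA family** — PPSA2/PNSA2 use the "total charge weighted" convention
  (total positive charge × total positively charged surface area);
  FPSA2 = PPSA2/TMSA; HDSA1 is the summed accessible area of
  hydrogen-bond-donor hydrogens (H on N/O/S); the per-element charged
  surface restricts Σ q_A·S_A to one element. The fractional and
  per-carbon descriptors take their charges from the quantum backend (the
  published models name a quantum charge scheme for them); HDSA1 uses the
  empirical charges.
* **Hydrogen-donor site count** — configurable: the classical hetero-H
  policy, or an all-H policy with a charge threshold. The registry default
  is all-H, because published donor-site counts for this family (10 and 16
  for two analogues) are far larger than their single amide N–H; only the
  between-compound ordering is asserted.
* **Quantum-chemical descriptors** — reductions over an electronic
  structure: total one-center electron–electron repulsion per atom; the
  minimum Fukui one-electron reactivity index over atoms of an element
  (Σ c_HOMO·c_LUMO products over the atom's basis functions divided by the
  HOMO–LUMO gap, signed products); the minimum resonance energy
  Σ P_µν·β_µν over bonds of an element pair; and the minimum per-atom
  electron–nuclear attraction.

### Reference electronic-structure backend

The backend is a closed-shell CNDO/2-level zero-differential-overlap SCF
over a minimal valence basis (H, C, N, O, F, S, Cl), with published
electronegativity parameters −(I+A)/2, bonding parameters β⁰ and Slater
exponents. Overlaps are evaluated analytically over three-Gaussian
expansions of the Slater orbitals; two-center Coulomb integrals γ_AB come
from the squared valence-s clouds; resonance integrals are
β_µν = ½(β⁰_A+β⁰_B)·S_µν. SCF starts from an atom-blocked guess, mixes
densities 50:50 from the second iteration, and converges on
‖ΔP‖∞ < 10⁻⁶ (energies in eV). This backend is a self-contained reference
implementation: it supplies internally consistent quantities with the right
physics (e.g. water converges to q(O) ≈ −0.28 e), but it is *not* an
AM1/MOPAC clone, so published per-compound descriptor magnitudes are treated
as ordering evidence only (the e–e repulsion ordering between the
fluoro/chloro and methyl analogues reproduces; exact values do not
transfer).

Conformers are produced by a single seeded ETKDGv3 distance-geometry
embedding followed by MMFF relaxation (seed 20191021 throughout); one
conformer per compound keeps the pipeline deterministic at desk scale, at
the cost of conformational averaging.

## QSAR layer

Responses are per-cell-line: 1/IC50 for HCT116, plain IC50 for MCF7 and
A431 (the scales under which the published observed/estimated activity
table reproduces R² = 0.934/0.951/0.901; the wrong scale gives 0.37–0.88).
Models are OLS with intercept; R², F, s², per-term SE and t follow the
standard definitions. The BMLR heuristic ranks single descriptors by R²,
forms pairs from the top B (default 10) discarding pairs with pairwise
|r| > 0.8, extends the best pairs by one descriptor, and returns the
leading subsets refitted with full statistics; an exhaustive mode serves as
the testing oracle on small pools. Censored activities are never admitted
into a fit.

Validation: leave-one-out R²cv via the PRESS/hat-matrix identity (verified
to 10⁻¹⁰ against explicit refits), and repeated leave-many-out (default
leave-1/3-out, 100 seeded repeats) pooling held-out errors about the
full-sample mean — the pooled form is chosen so that the exhaustive
leave-one-out limit coincides with LOO exactly.

The modelled set is the 24 benzylidene-series compounds; the four
thienylidene compounds are excluded from fitting (as in the source
modelling set) even where their activities are uncensored.

## Pharmacophore layer

A hypothesis is a set of weighted, toleranced features (hydrogen-bond
acceptors, hydrophobics; per-cell-line inventories 3H+1HBA, 2H+1HBA,
2HBA+2H). A mapped molecule scores fit = Σ w·(1 − (d/tol)²) — the standard
quadratic-displacement form; the scoring function is a documented modelling
choice since only fit numbers are published. What the published table does
pin down is the activity link: within each cell line,
fit + log10(estimated IC50/µM) is constant to SD < 0.0013, so a single
constant c per hypothesis (6.885, 6.421, 7.605) converts fit values to
estimates via IC50 = 10^(c − fit). `calibrate_activity_constant` recovers c
(with its SD) from any (fit, IC50) rows; predictions reproduce the printed
estimates to within the propagation of their printed rounding (≤1 %
relative; the largest absolute deviation, 0.018 µM on an 11.5 µM estimate,
is rounding of the 3-decimal fit value). Hypothesis geometries are not
published; shipped example hypotheses are synthetic and reproduce only the
feature inventories.

## Synthetic data

The generators emulate: (a) descriptor matrices with a 3-descriptor linear
signal in standard-normal columns plus Gaussian noise — defaults n=24
compounds, 23-descriptor pool, coefficients (2, −1.5, 1) and noise SD 0.75,
giving population R² ≈ 0.93, the regime of the published models; (b)
censored log-normal IC50 tables stratified by substituent class (median
1.3 µM for halogen-like vs 4.5 µM for methyl/methoxy-like classes, log-SD
0.15, censoring at 50 µM), mirroring the potency separation and ">50"
reporting of the screening table; (c) mock electronic structures (symmetric
density, orthonormal MOs, gap-separated frontier orbitals, per-atom energy
tables) as oracle inputs for the quantum descriptors; (d) exact toy
geometries (isolated/coincident/paired spheres, methane, benzene) for the
surface quadrature. All generators are bit-reproducible from their seed
(default 20191021).

What passing synthetic tests show: the statistical machinery (OLS
identities, PRESS equivalence, subset recovery at the published model's
signal-to-noise, coefficient calibration) and the descriptor reductions are
correct. What they do not show: that this package's descriptor values equal
those of the commercial stack behind the published models — real descriptor
matrices are correlated and backend-dependent, and the published
coefficients/t/F/s² and cross-validated R² are reproducible only with those
matrices, which are not printed.

## Problem sizes and determinism

Default runs use the full 24-compound modelling set, 960 quadrature points,
100 LMO repeats, and 100/200-replicate recovery studies — all chosen as
desk-scale settings that exercise every code path deterministically. One
global seed fans out to per-stage seeds by fixed offsets; identical
configurations produce byte-identical reports.

## Known limitations

* The empirical charge scheme cannot separate same-element environments;
  descriptors needing environment resolution use the backend charges.
* One conformer per compound; no ensemble averaging.
* The ZDO backend omits d functions on S/Cl and uses Gaussian-expansion
  overlaps; magnitudes are internally consistent, not MOPAC-compatible.
* Pharmacophore feature perception is rule-based (SMARTS acceptors, ring
  and alkyl-cluster centroids); no excluded volumes, no automated
  hypothesis learning.
* IC50s are inputs; no dose–response fitting from raw absorbances.
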