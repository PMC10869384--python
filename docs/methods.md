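# Methods

`pepqsar` models the antibacterial activity (pIC50, the negative decadic
logarithm of the molar IC50) of fixed-length peptides from their sequence
(2D route) and from aligned 3D structures (field route), and screens both
with an applicability domain. This note records the models, the numerical
conventions, and the design choices made where the design was genuinely
open.

## Sequence encoding

Each of the 20 canonical residues is represented by 18 principal-component
scores condensed from five families of 3D molecular descriptors computed on
the isolated amino acid: Randic molecular profiles (components 1–2), radial
distribution functions (3–5), WHIM indices (6–9), geometrical descriptors
(10–13) and GETAWAY descriptors (14–18). The scale is shipped as
`data/aa_descriptors.tsv`; recomputing it from structures (Dragon
descriptors, DFT geometries) is out of scope, but `dataio.pca_reduce`
provides the generic PCA stage for users with their own raw descriptor
matrices.

A peptide of length L maps to the concatenation of its residue rows: an
18·L feature vector. Flat column `X_k` refers to component
`((k−1) mod 18)+1` of residue `⌈k/18⌉`; this convention is fixed once and
used everywhere (column maps, model serialization, the CLI). The encoded
scale is close to centred per component over the residue alphabet; the
published table holds every component mean within ±0.30 (components 14 and
16 reach 0.275 and 0.297), so the table validator enforces |mean| ≤ 0.35
rather than a tighter bound.

Because all peptides in a library share one length, no normalisation is
applied by default. z-score and min–max scaling are available for general
use and are always fit on the training rows only, so held-out peptides
cannot leak into the scaling.

## 2D models

* **MLR** — ordinary least squares on a named descriptor subset,
  `pIC50 = b0 + Σ b_j X_j`. Singular designs are rejected with the
  collinear column named.
* **Descriptor subset selection** — the criterion is leave-one-out Q²
  of the OLS fit (computed exactly via the hat-matrix identity
  PRESS = Σ (e_i/(1−h_ii))²), ties broken by lower SEE then lexicographic
  column order. Exhaustive search is allowed up to 10⁶ candidate subsets;
  beyond that forward selection is required (C(360,3) ≈ 7.7M makes blind
  enumeration pointless for the full encoding).
* **PLSR** — PLS1 by the classical NIPALS recursion: each weight vector
  maximises covariance of the X-scores with the deflated response; X is
  deflated by rank-one score/loading products, which makes successive score
  vectors mutually orthogonal. Prediction uses the regression vector
  `W (PᵀW)⁻¹ q` on centred X. At full rank PLSR reproduces OLS, a property
  the tests assert against an independent least-squares solve. The latent
  dimension is chosen by LOO Q² (ties to the smaller count), and the per-Nc
  trend table is returned for plotting.
* **ε-SVR** — the ε-insensitive dual is solved by libsvm (through
  scikit-learn), the solver family whose parameter conventions the model
  follows: kernels linear/RBF/sigmoid/polynomial, complexity C, tube width
  ε, termination tolerance 1e-3, shrinking on, and `gamma = 0` meaning the
  "auto" value 1/p. Solver independence is enforced by `kkt_audit`, which
  checks the box constraint, the equality constraint Σβ = 0 and
  complementary slackness of every training point at tolerance 1e-3; the
  tests additionally match the dual objective against a generic SLSQP
  quadratic-programming solve to 1e-5. Default hyperparameters follow the
  study settings (RBF, C = 1, ε = 0.1 or 0.05, gamma auto); inputs are not
  scaled by default.

## Validation statistics

R² = 1 − SSres/SStot, SEE = √(SSres/(n−k−1)) and
F = (R²/k)/((1−R²)/(n−k−1)) on the training fit. LOO Q² refits the model n
times and uses 1 − PRESS/SStot with SStot about the full training mean (the
standard chemometrics convention; per-fold means are not used). Q² is
unbounded below. SEP = √(PRESS/n) by default, switchable to n−1.
External predictivity r²pred = (SD − PRESS)/SD, where SD is the spread of
the test activities about the *training* mean. Reports carry both the
standard F and the ratio form R²/(1−R²), and for SVR both pseudo-r²
definitions (squared Pearson correlation, and the 1 − PRESS/SStot form that
can go negative). Because the published "Q²" is ambiguous between LOO on
the training set and a test-set statistic, reports label both computations
explicitly.

All statistics are verified against from-scratch brute-force oracles
(normal equations, explicit refit loops) to 1e-10 on small instances.

## Applicability domain

The standardization approach: per descriptor,
S_j = |x_j − mean_j|/sd_j with training mean and sample sd. A peptide is
outside when min_j S_j > 3 (every descriptor anomalous), inside when
max_j S_j ≤ 3, and in the mixed case inside only when
mean(S) + 1.28·sd(S) ≤ 3 — the 1.28 factor being the 90% normal quantile.
Threshold and quantile factor are configurable. The domain is fitted by
default on the fitted model's descriptor columns. On the packaged data all
training peptides fall inside; one S. aureus test peptide
(CKILSKTIKCRIPCGRRKEY) falls outside on the 5-column model, which the test
suite reports rather than hides — which descriptor columns the original
screen used cannot be pinned down (see "Known limitations").

## Molecular interaction fields

Structures arrive pre-aligned (PDB with charges in the charge, occupancy
or B-factor column, or a plain XYZQ text dialect); a rigid Kabsch
superposition helper is provided, but common-substructure alignment and
charge derivation are out of scope — charges come from the user's chemistry
toolkit.

A cubic lattice (default spacing 2.0 Å, margin 4.0 Å) encloses all
molecules. Two chemistries:

* **Probe energies (CoMFA-style)** — steric: Lennard-Jones 12-6,
  ε_ip[(R_ip/r)¹² − 2(R_ip/r)⁶] with R_ip the sum of vdW radii and
  ε_ip the geometric mean of well depths, probe = sp³ carbon
  (r = 1.52 Å, ε = 0.107 kcal/mol, charge +1); electrostatic: Coulomb with
  a distance-dependent dielectric ε(r) = r, i.e. 332.06·q_i·q_probe/r²
  (the conversion constant in kcal·Å/(mol·e²) is a package choice — only
  the dielectric model is prescribed by the method). Both terms truncate
  at ±30 kcal/mol; an atom sitting exactly on a lattice point simply
  saturates the clamp. Where the steric term saturates, the molecule's
  electrostatic entry is physically meaningless (probe inside the vdW
  envelope) and is replaced by the column mean over non-clashing molecules
  — the substitution mask is kept on the matrix so it is auditable.
* **Similarity indices (CoMSIA-style)** — A_q = −Σ_i w_probe·w_i·
  exp(−α·r²) with attenuation α = 0.3, for steric (atom weight = vdW
  volume ∝ r³, probe radius 2.0 Å), electrostatic (partial charge, probe
  +1) and hydrophobic/donor/acceptor unit-weight probes. The probe's
  steric radius is taken as 2.0 Å (the similarity probe), not the 1.52 Å
  energy probe.

Columns whose sample standard deviation across molecules falls below
2.0 kcal/mol are dropped before modelling (noise filtering). A PLS model
over the kept columns, with the component count picked by LOO Q², yields
per-field contribution fractions Σ_cols sd·|coef| normalised over fields,
and per-column StDev·Coeff scores. Contours are the columns at or beyond
the 80th (favourable) and 20th (unfavourable) linear-interpolation
percentiles of StDev·Coeff within a field; when the two thresholds
coincide (degenerate fields) the sign of StDev·Coeff decides.

## Synthetic data

The peptide generator draws sequences uniformly over the alphabet (a
composition-weight hook exists) and sets
pIC50 = b0 + Σ β_j X_j + N(0, σ²) for a small planted column set — the 2D
pipeline's own modelling assumption, with known truth. Defaults: n = 100,
length 20, three planted columns with β = (0.5, −0.3, 0.2), σ = 0.1, 75%
training fraction. All randomness flows from one integer seed through a
single generator.

The structure generator places 8 carbon-like atoms uniformly in an 8 Å box
(vdW radii 1.2–1.9 Å, partial charges ±0.15 e — the realistic magnitude for
aliphatic carbons; larger charges would make the electrostatic field an
equally strong proximity proxy and blur the causal attribution the
generator exists to test). Activity is a stated linear functional of the
exact truncated steric field at the box centre, where the field varies by
tens of kcal/mol across molecules, plus N(0, 0.1²). What these data do
*not* emulate: real peptide conformations, bonded geometry, realistic
charge distributions, or sequence patterns of antimicrobial peptides
(helicity, charge clustering). Passing tests therefore demonstrate that
the machinery recovers known truth under its own assumptions, not that the
models transfer to arbitrary real libraries.

## Problem sizes

The test suite and the acceptance script use the packaged 31- and
40-peptide tables as-is; synthetic checks use n = 200 peptide libraries
(20 replicates for selection-recovery rates), n = 5000 for variance
bookkeeping, and 20-molecule toy structure sets on ~9³-point grids —
sizes at which every brute-force oracle (explicit LOO refits, exhaustive
percentile arithmetic, SLSQP quadratic programming on 60 dual variables)
runs in seconds.

## Known limitations

* The published per-equation descriptor indices (X359/X309/X289 and the
  five S. aureus columns) cannot be reproduced: the original index prose is
  internally inconsistent (no single flattening satisfies all the printed
  position/family readings simultaneously). The package fixes one
  convention, documents it, and treats the published regression
  coefficients as non-reproducible references. Subset selection here
  (exhaustive/forward by LOO Q²) is a documented stand-in for an unstated
  original procedure.
* Published CoMFA/CoMSIA statistics depend on proprietary structure
  building, alignment and Lennard-Jones parameterisation; the field engine
  reproduces the stated settings (spacing, probes, truncation, attenuation,
  column filter, contour levels) but its absolute energies are
  order-of-magnitude comparable only.
* The six designed peptides are shipped as a fixture with their published
  predictions; the search that produced them was manual and is not
  re-derived.
* nu-SVR, kernels beyond the four stated, y-randomisation/bootstrap
  validation, leverage-based domains, toxicity/transmembrane/DNA-binding
  predictions are out of scope.
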