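# pepqsar

Hybrid 2D/3D quantitative structure–activity relationship (QSAR) modelling
of antibacterial peptides, for computational chemists and peptide designers
who want a tested, scriptable version of the classic workflow: encode
fixed-length peptide sequences with an amino-acid descriptor scale, fit and
cross-validate regression models of antibacterial potency, check which
predictions can be trusted, analyse grid-based molecular interaction
fields, and enumerate candidate peptides.

## What it computes

**Sequence route.** Every residue carries 18 principal-component scores
condensed from five 3D-descriptor families (Randic profiles, RDF, WHIM,
geometrical, GETAWAY); a peptide of length L becomes an 18·L vector, and
activity is modelled as

    pIC50 = b0 + b1·X1 + … + bk·Xk        (MLR on a selected subset)

or by partial least squares (NIPALS) on the same columns, or by ε-SVR with
linear/RBF/sigmoid/polynomial kernels. Model quality is reported as
R², SEE, F on the training fit, leave-one-out Q² = 1 − PRESS/SStot with
SEP = √(PRESS/n), and external predictivity r²pred = (SD − PRESS)/SD about
the training mean. A standardization-approach applicability domain
(S = |x−μ|/σ per descriptor, 3σ threshold with the 1.28-quantile mixed-case
rule) flags peptides outside the training chemical space.

**Field route.** On aligned 3D structures with partial charges, a cubic
lattice (2.0 Å spacing) samples steric Lennard-Jones and Coulomb
(distance-dependent dielectric) probe energies truncated at ±30 kcal/mol,
or Gaussian similarity indices (attenuation 0.3) for steric,
electrostatic, hydrophobic and H-bond donor/acceptor properties. After
2.0 kcal/mol column filtering, a PLS model yields per-field contribution
fractions and StDev·Coeff contour points at the 80%/20% levels.

The two packaged peptide sets (31 *E. coli* and 40 *S. aureus* actives with
pIC50 values and train/test roles), the 20×18 descriptor scale and the six
designed candidate peptides ship with the package; a synthetic-data module
generates peptide libraries and toy 3D structures with known ground truth.

## Worked example

```python
import numpy as np
from pepqsar import dataio, qsar2d, validation, appdomain

table = dataio.load_descriptor_table()          # packaged 20 x 18 scale
peptides = dataio.load_ecoli()                  # 31 peptides, 23 train / 8 test
features = dataio.encode_dataset(peptides, table)

train = np.array([r == "train" for r in features.roles])
X, y = features.values, peptides.pic50

columns = qsar2d.select_descriptors(X[train], y[train], k=3, method="forward")
model = qsar2d.fit_mlr(X[train], y[train], columns)

r2, see, f = validation.regression_stats(y[train], model.predict(X[train]), k=3)
q2, sep = validation.loo_q2(
    lambda Xa, ya: qsar2d.fit_mlr(Xa, ya, columns).predict, X[train], y[train]
)
print(f"selected columns: {columns}")
print(f"R2 = {r2:.4f}   SEE = {see:.4f}   F = {f:.3f}")
print(f"LOO Q2 = {q2:.4f}   SEP = {sep:.4f}")

ci = np.asarray(columns) - 1
domain = appdomain.ad_fit(X[train][:, ci], columns=columns)
flags = appdomain.ad_flag(domain, X[:, ci], ids=features.row_ids)
print(f"peptides outside the applicability domain: {int((~flags.inside).sum())}/31")
```

prints

```
selected columns: (207, 229, 297)
R2 = 0.8119   SEE = 0.2451   F = 27.342
LOO Q2 = 0.7135   SEP = 0.2749
peptides outside the applicability domain: 0/31
```

i.e. a three-descriptor linear model explains 81% of the training variance,
holds a cross-validated Q² of 0.71 (a model is usually called predictive
above ~0.5), and every packaged peptide lies inside the model's domain, so
its predictions are applicable to all of them.

The same workflow is available from the shell: `pepqsar run --config
cfg.yaml` drives encode → select/fit → validate → AD from a YAML config
into a run directory (model JSON, JSON+Markdown reports, AD flags CSV,
checksummed manifest); other subcommands (`encode`, `ad`, `design`,
`fields`, `simulate`, `reproduce-paper`) expose the single stages.

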