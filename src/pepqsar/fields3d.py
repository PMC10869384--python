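"""Molecular-interaction-field engine for aligned 3D structures.

Two field chemistries are provided, both sampled on a regular cubic lattice
around the aligned molecules:

* CoMFA-style probe energies: a steric Lennard-Jones 12-6 term for an sp3
  carbon probe (vdW radius 1.52 A, well depth 0.107 kcal/mol) and a
  Coulomb electrostatic term for a +1 charge with a distance-dependent
  dielectric eps(r) = r, i.e. a 1/r^2 law with the 332.06 kcal*A/(mol*e^2)
  conversion constant.  Both energies are truncated at +-30 kcal/mol; where
  the steric term saturates, the electrostatic value is replaced by the
  column mean over the remaining molecules (and the substitution recorded).

* CoMSIA-style similarity indices: Gaussian-attenuated sums
  A_q = -sum_i w_probe * w_i * exp(-alpha * r_iq^2) with attenuation
  alpha = 0.3 by default, evaluated for steric (atomic volume ~ r_vdw^3),
  electrostatic (partial charge), hydrophobic, H-bond donor and H-bond
  acceptor atom weights.

A PLS model over the pooled field columns yields per-field contribution
fractions and StDev*Coeff column scores, from which favourable (80th
percentile) and unfavourable (20th percentile) contour points are read off.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import validation
from .qsar2d import PLSRModel, fit_plsr

__all__ = [
    "COULOMB_CONSTANT",
    "ComfaProbe",
    "ComsiaProbe",
    "Structure3D",
    "Grid3D",
    "FieldMatrix",
    "FieldPLSModel",
    "ContourMap",
    "load_element_table",
    "read_xyzq",
    "read_pdb",
    "superpose",
    "build_grid",
    "comfa_fields",
    "comsia_fields",
    "comfa_field_matrix",
    "comsia_field_matrix",
    "column_filter",
    "fit_field_pls",
    "contour_map",
]

COULOMB_CONSTANT = 332.06  # kcal*A/(mol*e^2)

COMFA_FIELDS = ("steric", "electrostatic")
COMSIA_FIELDS = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")


def load_element_table() -> pd.DataFrame:
    """Packaged per-element van der Waals radii (A) and LJ well depths."""
    text = resources.files("pepqsar.data").joinpath("elements.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", index_col="element")


@dataclass(frozen=True)
class ComfaProbe:
    """sp3 carbon probe: vdW radius 1.52 A, +1 e charge."""

    radius: float = 1.52
    charge: float = 1.0
    epsilon: float = 0.107  # kcal/mol


@dataclass(frozen=True)
class ComsiaProbe:
    """Similarity probe: radius 2.0 A, +1 charge, unit property weights."""

    radius: float = 2.0
    charge: float = 1.0
    hydrophobic: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0

    def weight(self, fieldname: str) -> float:
        if fieldname == "steric":
            return self.radius**3
        if fieldname == "electrostatic":
            return self.charge
        return getattr(self, fieldname)


@dataclass(frozen=True)
class Structure3D:
    """One aligned molecule: elements, coordinates, charges and atom weights."""

    elements: tuple[str, ...]
    coords: np.ndarray  # n x 3, Angstrom
    charges: np.ndarray  # n, elementary charges
    radii: np.ndarray  # n, vdW radii in Angstrom
    lj_epsilon: np.ndarray  # n, kcal/mol
    hydrophobic: np.ndarray | None = None
    donor: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    mol_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        if n < 1:
            raise ValueError("structure needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be n x 3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def property_weights(self, fieldname: str) -> np.ndarray:
        if fieldname == "steric":
            return self.radii**3
        if fieldname == "electrostatic":
            return self.charges
        w = getattr(self, fieldname)
        if w is None:
            raise ValueError(
                f"structure {self.mol_id or '<unnamed>'}: missing {fieldname} "
                f"weights for atoms 1..{self.n_atoms}"
            )
        return w

    def translated(self, shift: Sequence[float]) -> "Structure3D":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))


def _element_params(elements: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    table = load_element_table()
    radii, eps = np.empty(len(elements)), np.empty(len(elements))
    for i, el in enumerate(elements):
        el = el.capitalize()
        if el not in table.index:
            raise ValueError(f"element {el!r} not in the packaged parameter table")
        radii[i] = table.at[el, "vdw_radius"]
        eps[i] = table.at[el, "lj_epsilon"]
    return radii, eps


def read_xyzq(path: str | Path, mol_id: str | None = None) -> Structure3D:
    """Read the plain-text XYZQ dialect.

    Whitespace-delimited columns: ``element x y z charge`` plus optional
    ``radius lj_epsilon hydrophobic donor acceptor``.  Lines starting with
    ``#`` are comments.  Missing radii/well depths fall back to the packaged
    element table.
    """
    path = Path(path)
    names = [
        "element", "x", "y", "z", "charge",
        "radius", "lj_epsilon", "hydrophobic", "donor", "acceptor",
    ]
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: need at least 5 columns (element x y z charge)")
    df.columns = names[: df.shape[1]]
    elements = tuple(str(e) for e in df["element"])
    def_radii, def_eps = _element_params(elements)
    radii = df["radius"].to_numpy(float) if "radius" in df else def_radii
    eps = df["lj_epsilon"].to_numpy(float) if "lj_epsilon" in df else def_eps
    opt = {
        k: (df[k].to_numpy(float) if k in df else None)
        for k in ("hydrophobic", "donor", "acceptor")
    }
    return Structure3D(
        elements=elements,
        coords=df[["x", "y", "z"]].to_numpy(float),
        charges=df["charge"].to_numpy(float),
        radii=radii,
        lj_epsilon=eps,
        mol_id=mol_id or path.stem,
        **opt,
    )


def read_pdb(
    path: str | Path,
    charge_from: Literal["charge", "occupancy", "b_factor"] = "charge",
    mol_id: str | None = None,
) -> Structure3D:
    """Read a PDB file, optionally reinterpreting a numeric column as charge.

    ``charge_from`` selects where partial charges come from: the PDB charge
    field, or the occupancy / B-factor column repurposed by many charge-
    assignment tools.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(
        model=1, extra_fields=["charge", "occupancy", "b_factor"]
    )
    elements = tuple(str(e).capitalize() for e in atoms.element)
    if charge_from == "charge":
        charges = np.asarray(atoms.charge, dtype=float)
    elif charge_from == "occupancy":
        charges = np.asarray(atoms.occupancy, dtype=float)
    elif charge_from == "b_factor":
        charges = np.asarray(atoms.b_factor, dtype=float)
    else:
        raise ValueError(f"unknown charge_from {charge_from!r}")
    radii, eps = _element_params(elements)
    return Structure3D(
        elements=elements,
        coords=np.asarray(atoms.coord, dtype=float),
        charges=charges,
        radii=radii,
        lj_epsilon=eps,
        mol_id=mol_id or path.stem,
    )


def superpose(
    mobile: Structure3D,
    template: Structure3D,
    atom_pairs: Sequence[tuple[int, int]],
) -> Structure3D:
    """Rigid least-squares superposition of ``mobile`` onto ``template``.

    ``atom_pairs`` lists (mobile_index, template_index) 0-based pairs used to
    determine the Kabsch rotation and translation; all atoms are moved.
    """
    from scipy.spatial.transform import Rotation

    pairs = np.asarray(atom_pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs")
    a = mobile.coords[pairs[:, 0]]
    b = template.coords[pairs[:, 1]]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    new_coords = rot.apply(mobile.coords - ca) + cb
    return replace(mobile, coords=new_coords)


# ---------------------------------------------------------------------------
# grid


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned cubic lattice: origin, spacing and point counts."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice coordinates, x fastest-varying last (C order)."""
        axes = [
            self.origin[d] + self.spacing * np.arange(self.shape[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def translated(self, shift: Sequence[float]) -> "Grid3D":
        return replace(self, origin=self.origin + np.asarray(shift, dtype=float))


def build_grid(
    structures: Sequence[Structure3D], spacing: float = 2.0, margin: float = 4.0
) -> Grid3D:
    """Smallest lattice box enclosing every atom plus ``margin`` on each side."""
    if not structures:
        raise ValueError("empty structure list")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = np.vstack([s.coords for s in structures])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    counts = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return Grid3D(origin=lo, spacing=float(spacing), shape=counts)


# ---------------------------------------------------------------------------
# field evaluation


def _distances(grid: Grid3D, coords: np.ndarray) -> np.ndarray:
    pts = grid.points()
    diff = pts[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def comfa_fields(
    s: Structure3D,
    g: Grid3D,
    probe: ComfaProbe | None = None,
    truncation: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point CoMFA steric and electrostatic probe energies (clamped)."""
    steric, electro, _ = _comfa_raw(s, g, probe or ComfaProbe(), truncation)
    return steric, electro


def _comfa_raw(
    s: Structure3D, g: Grid3D, probe: ComfaProbe, truncation: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = _distances(g, s.coords)
    tiny = 1e-6  # atom on a grid point: energies saturate and get clamped
    r = np.maximum(r, tiny)
    R = s.radii + probe.radius  # pairwise equilibrium distance
    eps = np.sqrt(s.lj_epsilon * probe.epsilon)
    with np.errstate(over="ignore"):
        ratio6 = (R[None, :] / r) ** 6
        steric = np.sum(eps[None, :] * (ratio6**2 - 2.0 * ratio6), axis=1)
    clash = steric >= truncation
    steric = np.clip(steric, -truncation, truncation)
    electro = COULOMB_CONSTANT * probe.charge * np.sum(s.charges[None, :] / r**2, axis=1)
    electro = np.clip(electro, -truncation, truncation)
    return steric, electro, clash


def comsia_fields(
    s: Structure3D,
    g: Grid3D,
    properties: Sequence[str] = COMSIA_FIELDS,
    alpha: float = 0.3,
    probe: ComsiaProbe | None = None,
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices A_q = -sum_i w_probe w_i exp(-alpha r^2)."""
    probe = probe or ComsiaProbe()
    unknown = set(properties) - set(COMSIA_FIELDS)
    if unknown:
        raise ValueError(f"unknown CoMSIA properties: {sorted(unknown)}")
    r2 = _distances(g, s.coords) ** 2
    gauss = np.exp(-alpha * r2)
    out = {}
    for prop in properties:
        w = s.property_weights(prop)
        out[prop] = -probe.weight(prop) * gauss @ w
    return out


# ---------------------------------------------------------------------------
# field matrices


@dataclass(frozen=True)
class FieldMatrix:
    """Molecules x (grid point, field) energy matrix with bookkeeping masks."""

    values: np.ndarray  # m x (n_points * n_fields)
    fields: tuple[str, ...]
    grid: Grid3D
    mol_ids: tuple[str, ...]
    kept: np.ndarray  # boolean column mask (after filtering)
    column_field: np.ndarray  # str per column
    column_point: np.ndarray  # grid point index per column
    electro_substituted: np.ndarray | None = None  # m x n_points mask

    def __post_init__(self) -> None:
        m, c = self.values.shape
        if c != self.grid.n_points * len(self.fields):
            raise ValueError("column count != points * fields")
        if self.kept.shape != (c,):
            raise ValueError("kept mask shape mismatch")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    def field_block(self, fieldname: str) -> np.ndarray:
        """Column indices of one field (ignoring the kept mask)."""
        if fieldname not in self.fields:
            raise ValueError(f"field {fieldname!r} not present")
        return np.where(self.column_field == fieldname)[0]

    def kept_values(self) -> np.ndarray:
        return self.values[:, self.kept]


def _assemble(
    per_mol: list[dict[str, np.ndarray]],
    fields: Sequence[str],
    grid: Grid3D,
    mol_ids: Sequence[str],
    electro_substituted: np.ndarray | None = None,
) -> FieldMatrix:
    blocks = [
        np.vstack([d[f] for d in per_mol]) for f in fields
    ]  # each m x n_points
    values = np.hstack(blocks)
    n_pts = grid.n_points
    column_field = np.concatenate([np.full(n_pts, f) for f in fields])
    column_point = np.concatenate([np.arange(n_pts) for _ in fields])
    return FieldMatrix(
        values=values,
        fields=tuple(fields),
        grid=grid,
        mol_ids=tuple(mol_ids),
        kept=np.ones(values.shape[1], dtype=bool),
        column_field=column_field,
        column_point=column_point,
        electro_substituted=electro_substituted,
    )


def comfa_field_matrix(
    structures: Sequence[Structure3D],
    grid: Grid3D | None = None,
    probe: ComfaProbe | None = None,
    truncation: float = 30.0,
    spacing: float = 2.0,
    margin: float = 4.0,
) -> FieldMatrix:
    """CoMFA steric + electrostatic matrix over a shared grid.

    At grid points where a molecule's steric energy saturates at the
    truncation value, its electrostatic entry is unreliable (probe inside
    the vdW envelope) and is replaced by the mean electrostatic value of the
    non-clashing molecules at that point; the substitution mask is kept.
    """
    probe = probe or ComfaProbe()
    if grid is None:
        grid = build_grid(structures, spacing=spacing, margin=margin)
    per_mol, clashes = [], []
    for s in structures:
        steric, electro, clash = _comfa_raw(s, grid, probe, truncation)
        per_mol.append({"steric": steric, "electrostatic": electro})
        clashes.append(clash)
    clash = np.vstack(clashes)  # m x n_points
    electro = np.vstack([d["electrostatic"] for d in per_mol])
    for j in np.where(clash.any(axis=0))[0]:
        ok = ~clash[:, j]
        mean_j = electro[ok, j].mean() if ok.any() else 0.0
        electro[~ok, j] = mean_j
    for i, d in enumerate(per_mol):
        d["electrostatic"] = electro[i]
    return _assemble(per_mol, COMFA_FIELDS, grid, [s.mol_id for s in structures], clash)


def comsia_field_matrix(
    structures: Sequence[Structure3D],
    grid: Grid3D | None = None,
    properties: Sequence[str] = COMSIA_FIELDS,
    alpha: float = 0.3,
    probe: ComsiaProbe | None = None,
    spacing: float = 2.0,
    margin: float = 4.0,
) -> FieldMatrix:
    """CoMSIA similarity-index matrix over a shared grid."""
    if grid is None:
        grid = build_grid(structures, spacing=spacing, margin=margin)
    per_mol = [comsia_fields(s, grid, properties, alpha, probe) for s in structures]
    return _assemble(per_mol, properties, grid, [s.mol_id for s in structures])


def column_filter(fm: FieldMatrix, min_sigma: float = 2.0) -> FieldMatrix:
    """Drop columns whose energy spread across molecules is below min_sigma.

    The spread is the sample standard deviation (ddof=1) over molecules, in
    the field's energy units.  Filtering composes with any existing mask.
    """
    if fm.n_molecules < 2:
        raise ValueError("column filtering needs at least 2 molecules")
    sd = fm.values.std(axis=0, ddof=1)
    kept = fm.kept & (sd >= min_sigma)
    if not kept.any():
        raise ValueError(
            f"column filter at {min_sigma} dropped every column; lower the threshold"
        )
    return replace(fm, kept=kept)


# ---------------------------------------------------------------------------
# field PLS and contours


@dataclass(frozen=True)
class FieldPLSModel:
    """PLS over kept field columns with per-field contribution fractions."""

    pls: PLSRModel
    fm: FieldMatrix
    n_components: int
    contributions: dict[str, float]
    stdev_coeff: np.ndarray  # per kept column, sd_col * coef_col
    stats: dict[str, float]

    def predict(self, fm_or_values) -> np.ndarray:
        if isinstance(fm_or_values, FieldMatrix):
            X = fm_or_values.values[:, self.fm.kept]
        else:
            X = np.asarray(fm_or_values, dtype=float)
        return self.pls.predict(X)


def fit_field_pls(
    fm: FieldMatrix,
    y: Sequence[float],
    nc: int | Literal["auto"] = "auto",
    max_nc: int = 8,
) -> FieldPLSModel:
    """Fit activities to field columns by PLS with LOO-chosen components.

    With ``nc="auto"`` the component count maximising LOO Q^2 in
    1..min(max_nc, rank) is chosen (ties to the smaller count).  Reports
    R^2_ncv, SEE, F, LOO Q^2 (R^2_cv) and SEP, plus per-field contribution
    fractions sum(sd_col * |coef_col|) normalised over fields.
    """
    y = np.asarray(y, dtype=float)
    X = fm.kept_values()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 molecules")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if nc == "auto":
        limit = min(max_nc, rank, n - 2)
        scan = []
        for k in range(1, limit + 1):
            q2, sep = validation.loo_q2(
                lambda Xa, ya, k=k: fit_plsr(Xa, ya, k).predict, X, y
            )
            scan.append((k, q2, sep))
        nc_best, q2, sep = max(scan, key=lambda row: (row[1], -row[0]))
    else:
        nc_best = int(nc)
        if nc_best > rank:
            raise ValueError(f"nc={nc_best} exceeds rank {rank}")
        q2, sep = validation.loo_q2(
            lambda Xa, ya: fit_plsr(Xa, ya, nc_best).predict, X, y
        )
    pls = fit_plsr(X, y, nc_best)
    y_hat = pls.predict(X)
    r2, see, f = validation.regression_stats(y, y_hat, nc_best)
    coef = pls.coefficients
    sd = X.std(axis=0, ddof=1)
    stdev_coeff = sd * coef
    kept_fields = fm.column_field[fm.kept]
    raw = {
        f_name: float(np.sum(sd[kept_fields == f_name] * np.abs(coef[kept_fields == f_name])))
        for f_name in fm.fields
    }
    total = sum(raw.values())
    contributions = {k: (v / total if total > 0 else 0.0) for k, v in raw.items()}
    stats = {
        "r2_ncv": r2,
        "see": see,
        "f": f,
        "q2_cv": q2,
        "sep": sep,
        "nc": nc_best,
    }
    return FieldPLSModel(
        pls=pls,
        fm=fm,
        n_components=nc_best,
        contributions=contributions,
        stdev_coeff=stdev_coeff,
        stats=stats,
    )


@dataclass(frozen=True)
class ContourMap:
    """Favourable / unfavourable lattice points of one field."""

    fieldname: str
    favorable_points: np.ndarray  # k x 3 coordinates
    unfavorable_points: np.ndarray
    favorable_values: np.ndarray  # StDev*Coeff at those points
    unfavorable_values: np.ndarray
    levels: tuple[float, float]


def contour_map(
    model: FieldPLSModel,
    fieldname: str,
    levels: tuple[float, float] = (0.8, 0.2),
) -> ContourMap:
    """Extract contour points by StDev*Coeff percentile within one field.

    Columns at or above the upper-level percentile of sd*coef are favourable,
    columns at or below the lower-level percentile unfavourable (linear-
    interpolation percentiles).  If the two thresholds coincide (e.g. a
    single kept column) the sign of sd*coef decides: positive -> favourable,
    negative -> unfavourable.
    """
    fm = model.fm
    if fieldname not in fm.fields:
        raise ValueError(f"field {fieldname!r} absent from the model")
    kept_idx = np.where(fm.kept)[0]
    in_field = fm.column_field[kept_idx] == fieldname
    v = model.stdev_coeff[in_field]
    cols = kept_idx[in_field]
    if v.size == 0:
        raise ValueError(f"no kept columns for field {fieldname!r}")
    hi_level, lo_level = levels
    hi = np.percentile(v, hi_level * 100)
    lo = np.percentile(v, lo_level * 100)
    if hi > lo:
        fav = v >= hi
        unfav = v <= lo
    else:  # degenerate: thresholds coincide, split by sign
        fav = v > 0
        unfav = v < 0
    pts = fm.grid.points()
    fav_pts = pts[fm.column_point[cols[fav]]]
    unfav_pts = pts[fm.column_point[cols[unfav]]]
    return ContourMap(
        fieldname=fieldname,
        favorable_points=fav_pts,
        unfavorable_points=unfav_pts,
        favorable_values=v[fav],
        unfavorable_values=v[unfav],
        levels=levels,
    )
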