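"""Synthetic peptide libraries and toy 3D structures with known ground truth.

The peptide generator emulates the modelling assumption of the 2D pipeline:
a fixed-length library whose activity is a sparse linear function of a few
encoded descriptor columns plus Gaussian noise,

    pIC50_i = b0 + sum_j beta_j * X_{i,j} + N(0, noise_sd^2).

Residues are drawn uniformly over the 20-letter alphabet (an optional
composition weighting hook is provided).  The structure generator produces
random small molecules in a box whose activity is a stated linear functional
of their exact steric probe field, so the field-PLS machinery can be tested
against a known causal field.  All randomness flows from one integer seed
through a single numpy Generator; nothing touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import (
    AminoAcidDescriptorTable,
    PeptideDataset,
    PeptideRecord,
    encode_peptide,
)
from .fields3d import ComfaProbe, Grid3D, Structure3D, comfa_fields

__all__ = ["SyntheticSpec", "gen_peptide_dataset", "gen_toy_structures"]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for a synthetic peptide library."""

    n_peptides: int = 100
    length: int = 20
    planted_columns: tuple[int, ...] = (18, 120, 261)  # 1-based X-indices
    beta: tuple[float, ...] = (0.5, -0.3, 0.2)
    intercept: float = 5.0
    noise_sd: float = 0.1
    train_fraction: float = 0.75
    seed: int = 0
    composition: tuple[float, ...] | None = None  # optional residue weights

    def __post_init__(self) -> None:
        if self.n_peptides < 1 or self.length < 1:
            raise ValueError("n_peptides and length must be positive")
        if max(self.planted_columns, default=1) > 18 * self.length:
            raise ValueError("planted column outside the encoding")
        if len(self.beta) != len(self.planted_columns):
            raise ValueError("beta and planted_columns lengths differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def gen_peptide_dataset(
    spec: SyntheticSpec, table: AminoAcidDescriptorTable
) -> tuple[PeptideDataset, dict]:
    """Draw a synthetic library; returns (dataset, ground truth record).

    The ground truth dict holds the planted columns, coefficients, intercept,
    noise level and the noiseless activities.
    """
    rng = np.random.default_rng(spec.seed)
    probs = None
    if spec.composition is not None:
        w = np.asarray(spec.composition, dtype=float)
        if w.size != 20 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("composition must be 20 non-negative weights")
        probs = w / w.sum()
    letters = np.array(list(ALPHABET))
    seqs = [
        "".join(rng.choice(letters, size=spec.length, p=probs))
        for _ in range(spec.n_peptides)
    ]
    X = np.vstack([encode_peptide(s, table) for s in seqs])
    cols = np.asarray(spec.planted_columns, dtype=int) - 1
    beta = np.asarray(spec.beta, dtype=float)
    y_clean = spec.intercept + X[:, cols] @ beta
    y = y_clean + rng.normal(0.0, spec.noise_sd, size=spec.n_peptides)
    n_train = int(round(spec.train_fraction * spec.n_peptides))
    n_train = min(max(n_train, 1), spec.n_peptides - 1)
    perm = rng.permutation(spec.n_peptides)
    roles = np.full(spec.n_peptides, "test", dtype=object)
    roles[perm[:n_train]] = "train"
    records = tuple(
        PeptideRecord(id=i + 1, sequence=s, pic50=float(v), role=r)
        for i, (s, v, r) in enumerate(zip(seqs, y, roles))
    )
    truth = {
        "planted_columns": tuple(spec.planted_columns),
        "beta": tuple(spec.beta),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "y_clean": y_clean,
    }
    return PeptideDataset(records, target_organism="synthetic"), truth


def gen_toy_structures(
    n_molecules: int = 20,
    atoms_per_molecule: int = 8,
    box: float = 8.0,
    seed: int = 0,
    noise_sd: float = 0.1,
    signal_scale: float = 2.0,
) -> tuple[list[Structure3D], np.ndarray, dict]:
    """Random aligned toy molecules with a steric-field-driven activity.

    Atoms get uniform coordinates in a cube of side ``box`` centred at the
    origin, partial charges in [-0.15, 0.15] e (the scale of aliphatic
    carbon partial charges), vdW radii in [1.2, 1.9] A and property weights
    in [0, 1].  The activity of molecule i is

        y_i = signal_scale * steric_i(P) + N(0, noise_sd^2)

    where steric_i(P) is its exact (truncated) CoMFA steric probe energy at
    the fixed probe point P at the box centre, recorded in the ground-truth
    dict; the causal field is therefore known by construction and varies by
    tens of kcal/mol across molecules, far above the noise.
    """
    if atoms_per_molecule < 1:
        raise ValueError("atoms_per_molecule must be >= 1")
    rng = np.random.default_rng(seed)
    structures = []
    for i in range(n_molecules):
        n = atoms_per_molecule
        structures.append(
            Structure3D(
                elements=tuple(["C"] * n),
                coords=rng.uniform(-box / 2, box / 2, size=(n, 3)),
                charges=rng.uniform(-0.15, 0.15, size=n),
                radii=rng.uniform(1.2, 1.9, size=n),
                lj_epsilon=np.full(n, 0.107),
                hydrophobic=rng.uniform(0.0, 1.0, size=n),
                donor=rng.uniform(0.0, 1.0, size=n),
                acceptor=rng.uniform(0.0, 1.0, size=n),
                mol_id=f"toy{i + 1}",
            )
        )
    probe_point = np.zeros(3)
    one_point_grid = Grid3D(origin=probe_point, spacing=1.0, shape=(1, 1, 1))
    signal = np.array(
        [comfa_fields(s, one_point_grid, ComfaProbe())[0][0] for s in structures]
    )
    y = signal_scale * signal + rng.normal(0.0, noise_sd, size=n_molecules)
    truth = {
        "probe_point": probe_point,
        "signal_scale": signal_scale,
        "noise_sd": noise_sd,
        "steric_signal": signal,
        "causal_field": "steric",
    }
    return structures, y, truth
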