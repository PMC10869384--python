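"""Loading, validation and encoding of peptide QSAR inputs.

The central object is a 20 x 18 amino-acid descriptor scale: each canonical
residue is represented by 18 principal-component scores condensed from five
families of 3D molecular descriptors computed on the isolated amino acid
(Randic molecular profiles, radial distribution functions, WHIM, geometrical
descriptors and GETAWAY descriptors).  A peptide of length L is encoded by
concatenating the rows of its residues into an 18*L feature vector, so column
X_k of the design matrix refers to component ``((k-1) mod 18)+1`` of residue
``ceil(k/18)``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_BLOCKS",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "AminoAcidDescriptorTable",
    "PeptideRecord",
    "PeptideDataset",
    "FeatureMatrix",
    "DescriptorTableError",
    "PeptideTableError",
    "load_descriptor_table",
    "load_peptide_table",
    "write_peptide_table",
    "load_ecoli",
    "load_saureus",
    "load_designed",
    "pic50_from_ic50",
    "encode_peptide",
    "encode_dataset",
    "split_train_test",
    "pca_reduce",
    "column_to_position_component",
    "position_component_to_column",
]

N_COMPONENTS = 18

#: Descriptor-family spans over the 18 components (1-based, inclusive).
CLASS_BLOCKS: tuple[tuple[str, int, int], ...] = (
    ("Randic", 1, 2),
    ("RDF", 3, 5),
    ("WHIM", 6, 9),
    ("Geometrical", 10, 13),
    ("GETAWAY", 14, 18),
)

ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
THREE_TO_ONE = {v.upper(): k for k, v in ONE_TO_THREE.items()}

CANONICAL_RESIDUES = frozenset(ONE_TO_THREE)


class DescriptorTableError(ValueError):
    """Raised when a descriptor-scale file fails validation."""


class PeptideTableError(ValueError):
    """Raised when a peptide activity table fails validation."""


def component_class(component: int) -> str:
    """Descriptor family owning a 1-based component index."""
    for name, lo, hi in CLASS_BLOCKS:
        if lo <= component <= hi:
            return name
    raise ValueError(f"component {component} outside 1..{N_COMPONENTS}")


def column_to_position_component(k: int) -> tuple[int, int]:
    """Map a 1-based flat column index X_k to (residue position, component)."""
    if k < 1:
        raise ValueError("column index is 1-based")
    return (k - 1) // N_COMPONENTS + 1, (k - 1) % N_COMPONENTS + 1


def position_component_to_column(position: int, component: int) -> int:
    if not 1 <= component <= N_COMPONENTS:
        raise ValueError(f"component {component} outside 1..{N_COMPONENTS}")
    if position < 1:
        raise ValueError("position is 1-based")
    return (position - 1) * N_COMPONENTS + component


@dataclass(frozen=True)
class AminoAcidDescriptorTable:
    """Per-residue descriptor scores, 20 rows x 18 components.

    ``rows`` maps one-letter residue codes to length-18 vectors.  The scores
    are PCA condensates of raw descriptor blocks, so each component is close
    to centred over the residue alphabet (|mean| < 0.35 for the packaged
    scale) -- a property ``validate`` enforces.
    """

    rows: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = sorted(CANONICAL_RESIDUES - set(self.rows))
        if missing:
            raise DescriptorTableError(f"residue {missing[0]} absent")
        extra = sorted(set(self.rows) - CANONICAL_RESIDUES)
        if extra:
            raise DescriptorTableError(f"unknown residue row {extra[0]!r}")
        for res, vec in self.rows.items():
            if vec.shape != (N_COMPONENTS,):
                raise DescriptorTableError(
                    f"row {res} has {vec.shape[0]} components, expected {N_COMPONENTS}"
                )
            if not np.all(np.isfinite(vec)):
                raise DescriptorTableError(f"row {res} contains non-finite values")
        means = self.as_matrix().mean(axis=0)
        if np.abs(means).max() > 0.35:
            raise DescriptorTableError(
                "component means deviate from zero by more than 0.35; "
                "not a centred PCA-score table"
            )

    def as_matrix(self, order: str = "ARNDCQEGHILKMFPSTWYV") -> np.ndarray:
        return np.vstack([self.rows[r] for r in order])

    def __getitem__(self, residue: str) -> np.ndarray:
        return self.rows[residue]


@dataclass(frozen=True)
class PeptideRecord:
    id: int | str
    sequence: str
    pic50: float
    role: Literal["train", "test"] = "train"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise PeptideTableError(f"record {self.id}: empty sequence")
        bad = sorted(set(self.sequence) - CANONICAL_RESIDUES)
        if bad:
            raise PeptideTableError(
                f"record {self.id}: non-canonical residue {bad[0]!r} in sequence"
            )
        if not math.isfinite(self.pic50):
            raise PeptideTableError(f"record {self.id}: non-finite pIC50")


@dataclass(frozen=True)
class PeptideDataset:
    records: tuple[PeptideRecord, ...]
    target_organism: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise PeptideTableError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def pic50(self) -> np.ndarray:
        return np.array([r.pic50 for r in self.records], dtype=float)

    @property
    def roles(self) -> np.ndarray:
        return np.array([r.role for r in self.records])

    def subset(self, role: str) -> "PeptideDataset":
        return PeptideDataset(
            tuple(r for r in self.records if r.role == role), self.target_organism
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Encoded design matrix with a flat-column -> (position, component) map."""

    values: np.ndarray
    column_map: tuple[tuple[int, int, str], ...]
    row_ids: tuple[int | str, ...]
    roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.column_map) != p:
            raise ValueError("column_map length does not match column count")
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def columns(self, x_indices: Sequence[int]) -> np.ndarray:
        """Sub-matrix of 1-based X-indices, in the given order."""
        idx = np.asarray(list(x_indices), dtype=int)
        if idx.size and (idx.min() < 1 or idx.max() > self.p):
            raise IndexError(f"X-index outside 1..{self.p}")
        return self.values[:, idx - 1]

    def rows_by_role(self, role: str) -> np.ndarray:
        mask = np.array([r == role for r in self.roles])
        return self.values[mask]


# ---------------------------------------------------------------------------
# loaders


def _packaged(name: str) -> str:
    return resources.files("pepqsar.data").joinpath(name).read_text()


def load_descriptor_table(source: str | Path | None = None) -> AminoAcidDescriptorTable:
    """Load a residue descriptor scale from TSV (default: the packaged scale).

    The file must have a ``residue`` column (one- or three-letter names) and
    18 numeric component columns.
    """
    if source is None:
        text = _packaged("aa_descriptors.tsv")
        source = "<packaged aa_descriptors.tsv>"
    else:
        text = Path(source).read_text()
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DescriptorTableError(f"{source}: unparseable table: {exc}") from exc
    if df.shape[1] != N_COMPONENTS + 1:
        raise DescriptorTableError(
            f"{source}: expected 1 residue column + {N_COMPONENTS} components, "
            f"found {df.shape[1]} columns"
        )
    rows: dict[str, np.ndarray] = {}
    for i, rec in df.iterrows():
        name = str(rec.iloc[0]).strip()
        code = THREE_TO_ONE.get(name.upper(), name.upper())
        if code not in CANONICAL_RESIDUES:
            raise DescriptorTableError(f"{source}: row {i + 1}: unknown residue {name!r}")
        vals = np.empty(N_COMPONENTS)
        for j in range(N_COMPONENTS):
            cell = str(rec.iloc[j + 1]).replace("−", "-").strip()
            try:
                vals[j] = float(cell)
            except ValueError:
                raise DescriptorTableError(
                    f"{source}: row {name}, component {j + 1}: non-numeric cell {cell!r}"
                ) from None
        rows[code] = vals
    return AminoAcidDescriptorTable(rows)


def _records_from_frame(df: pd.DataFrame, source: str) -> tuple[PeptideRecord, ...]:
    required = {"id", "sequence", "pic50"}
    missing = required - set(df.columns)
    if missing:
        raise PeptideTableError(f"{source}: missing column(s) {sorted(missing)}")
    records = []
    for _, rec in df.iterrows():
        role = "test" if ("test" in df.columns and int(rec["test"]) == 1) else "train"
        records.append(
            PeptideRecord(
                id=rec["id"],
                sequence=str(rec["sequence"]).strip().upper(),
                pic50=float(rec["pic50"]),
                role=role,
            )
        )
    return tuple(records)


def load_peptide_table(
    path: str | Path,
    fmt: Literal["csv", "tsv", "fasta"] | None = None,
    sidecar: str | Path | None = None,
    target_organism: str = "",
    activity: Literal["pic50", "ic50_um"] = "pic50",
) -> PeptideDataset:
    """Load a peptide activity table.

    CSV/TSV files need columns ``id,sequence,pic50[,test]`` with ``test`` in
    {0,1} (1 marks held-out peptides).  FASTA input takes the activities from
    a sidecar CSV keyed by record id.  ``activity="ic50_um"`` interprets the
    activity column as IC50 in micromolar and converts it to pIC50.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"csv": "csv", "tsv": "tsv", "fa": "fasta", "fasta": "fasta"}.get(
            suffix, "csv"
        )
    if fmt == "fasta":
        if sidecar is None:
            raise PeptideTableError("FASTA input requires a sidecar activity CSV")
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        side = pd.read_csv(sidecar, dtype={"id": str})
        side["id"] = side["id"].astype(str)
        unknown = set(side["id"]) - set(seqs)
        if unknown:
            raise PeptideTableError(
                f"{sidecar}: activity rows without FASTA record: {sorted(unknown)}"
            )
        df = side.assign(sequence=[seqs[i] for i in side["id"]])
    else:
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    if df.empty:
        raise PeptideTableError(f"{path}: no records")
    if activity == "ic50_um":
        df = df.assign(pic50=[pic50_from_ic50(v * 1e-6) for v in df["pic50"]])
    return PeptideDataset(_records_from_frame(df, str(path)), target_organism)


def write_peptide_table(ds: PeptideDataset, path: str | Path) -> None:
    """Write a dataset in the CSV dialect ``load_peptide_table`` reads."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in ds.records],
            "sequence": ds.sequences,
            "pic50": [f"{r.pic50:.6g}" for r in ds.records],
            "test": [1 if r.role == "test" else 0 for r in ds.records],
        }
    )
    df.to_csv(path, index=False)


def _load_packaged_dataset(name: str, organism: str) -> PeptideDataset:
    df = pd.read_csv(io.StringIO(_packaged(name)))
    return PeptideDataset(_records_from_frame(df, name), organism)


def load_ecoli() -> PeptideDataset:
    """The packaged 31-peptide E. coli set (23 train / 8 test)."""
    return _load_packaged_dataset("ecoli_peptides.csv", "Escherichia coli")


def load_saureus() -> PeptideDataset:
    """The packaged 40-peptide S. aureus set (30 train / 10 test)."""
    return _load_packaged_dataset("saureus_peptides.csv", "Staphylococcus aureus")


def load_designed() -> pd.DataFrame:
    """The six designed candidate peptides with their published predictions."""
    return pd.read_csv(io.StringIO(_packaged("designed_peptides.csv")))


# ---------------------------------------------------------------------------
# conversions and encoding


def pic50_from_ic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 in mol/L); requires ic50 > 0."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50)


def encode_peptide(sequence: str, table: AminoAcidDescriptorTable) -> np.ndarray:
    """Concatenate the descriptor rows of each residue: an 18*L vector."""
    sequence = sequence.upper()
    bad = sorted(set(sequence) - CANONICAL_RESIDUES)
    if bad:
        raise PeptideTableError(f"non-canonical residue {bad[0]!r} in {sequence!r}")
    return np.concatenate([table[res] for res in sequence])


def _full_column_map(length: int) -> tuple[tuple[int, int, str], ...]:
    return tuple(
        (pos, comp, component_class(comp))
        for pos in range(1, length + 1)
        for comp in range(1, N_COMPONENTS + 1)
    )


def encode_dataset(
    ds: PeptideDataset,
    table: AminoAcidDescriptorTable,
    normalize: Literal["none", "zscore", "minmax"] = "none",
) -> FeatureMatrix:
    """Encode every peptide; rows keep dataset order.

    All sequences must share one length.  When normalisation is requested it
    is fit on the training rows only and applied to every row, so held-out
    peptides never leak into the scaling.
    """
    lengths = {len(s) for s in ds.sequences}
    if len(lengths) != 1:
        ref = len(ds.records[0].sequence)
        bad = [r.id for r in ds.records if len(r.sequence) != ref]
        raise PeptideTableError(f"ragged sequence lengths; offending ids: {bad}")
    X = np.vstack([encode_peptide(s, table) for s in ds.sequences])
    roles = tuple(r.role for r in ds.records)
    if normalize != "none":
        train = X[np.array([r == "train" for r in roles])]
        if train.shape[0] < 2:
            raise PeptideTableError(
                "normalization needs at least 2 training rows (zero variance)"
            )
        if normalize == "zscore":
            mu, sd = train.mean(axis=0), train.std(axis=0, ddof=1)
            if np.any(sd == 0):
                sd = np.where(sd == 0, 1.0, sd)
            X = (X - mu) / sd
        elif normalize == "minmax":
            lo, hi = train.min(axis=0), train.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            X = (X - lo) / span
        else:
            raise ValueError(f"unknown normalization {normalize!r}")
    length = lengths.pop()
    return FeatureMatrix(
        values=X,
        column_map=_full_column_map(length),
        row_ids=tuple(r.id for r in ds.records),
        roles=roles,
    )


def split_train_test(ds: PeptideDataset) -> tuple[PeptideDataset, PeptideDataset]:
    """Partition a dataset by the assigned train/test roles."""
    return ds.subset("train"), ds.subset("test")


# ---------------------------------------------------------------------------
# PCA stage for user-supplied raw descriptor matrices


def pca_reduce(raw: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Project a raw descriptor matrix onto its top-k principal components.

    Returns ``(scores, variance_explained)`` where scores are the projections
    of the column-centred matrix onto the leading right singular directions
    and ``variance_explained`` gives the fraction of total variance captured
    per component (non-increasing, summing to <= 1).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw must be a 2-D matrix")
    m, q = raw.shape
    if m < 2:
        raise ValueError("need at least 2 rows")
    if not 1 <= k <= min(m - 1, q):
        raise ValueError(f"k must be in 1..min(m-1, q) = {min(m - 1, q)}")
    centred = raw - raw.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u[:, :k] * s[:k]
    total = np.sum(s**2)
    variance_explained = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return scores, variance_explained
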