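"""Candidate peptide design: template mutation and model-consensus ranking."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dataio import AminoAcidDescriptorTable, CANONICAL_RESIDUES, encode_peptide

__all__ = ["DesignCandidate", "enumerate_mutants", "rank_candidates"]

ENUMERATION_BUDGET = 10**6


@dataclass
class DesignCandidate:
    sequence: str
    parent: str
    mutated_positions: tuple[int, ...]
    predictions: dict[str, float] = field(default_factory=dict)
    consensus: float = math.nan


def enumerate_mutants(
    template: str,
    positions: Sequence[int],
    alphabet: Iterable[str],
    max_candidates: int | None = None,
) -> list[DesignCandidate]:
    """Cartesian enumeration of substitutions at the given 1-based positions.

    Candidates are produced in lexicographic order of the substituted
    residues, the unmodified template is excluded, and the stream is cut
    deterministically at ``max_candidates`` when given.  An enumeration
    larger than 10^6 without a truncation limit is refused.
    """
    template = template.upper()
    positions = sorted(set(int(p) for p in positions))
    if not positions:
        raise ValueError("no positions given")
    if positions[0] < 1 or positions[-1] > len(template):
        raise ValueError(
            f"positions out of range 1..{len(template)}: {positions}"
        )
    alphabet = sorted(set(a.upper() for a in alphabet))
    bad = set(alphabet) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"non-canonical residues in alphabet: {sorted(bad)}")
    if not alphabet:
        raise ValueError("empty alphabet")
    total = len(alphabet) ** len(positions)
    if max_candidates is None and total > ENUMERATION_BUDGET:
        raise ValueError(
            f"{total} combinations exceed the enumeration budget; "
            "pass max_candidates to truncate"
        )
    out: list[DesignCandidate] = []
    chars = list(template)
    for combo in itertools.product(alphabet, repeat=len(positions)):
        seq = chars.copy()
        for pos, res in zip(positions, combo):
            seq[pos - 1] = res
        seq = "".join(seq)
        if seq == template:
            continue
        mutated = tuple(p for p, r in zip(positions, combo) if template[p - 1] != r)
        out.append(DesignCandidate(sequence=seq, parent=template, mutated_positions=mutated))
        if max_candidates is not None and len(out) >= max_candidates:
            break
    return out


def rank_candidates(
    candidates: Sequence[DesignCandidate],
    models: dict[str, object] | Sequence[object],
    table: AminoAcidDescriptorTable,
) -> list[DesignCandidate]:
    """Predict every candidate with every model and sort by consensus.

    The consensus score is the mean of the per-model predicted pIC50 values;
    ranking is descending with ties broken by sequence lexicographic order.
    Returns new candidate objects; the input order is not modified.
    """
    if not isinstance(models, dict):
        models = {f"model_{i + 1}": m for i, m in enumerate(models)}
    if not candidates:
        return []
    X = np.vstack([encode_peptide(c.sequence, table) for c in candidates])
    ranked = []
    for i, cand in enumerate(candidates):
        preds = {}
        for name, model in models.items():
            preds[name] = float(np.asarray(model.predict(X[i : i + 1])).ravel()[0])
        ranked.append(
            DesignCandidate(
                sequence=cand.sequence,
                parent=cand.parent,
                mutated_positions=cand.mutated_positions,
                predictions=preds,
                consensus=float(np.mean(list(preds.values()))),
            )
        )
    ranked.sort(key=lambda c: (-c.consensus, c.sequence))
    return ranked
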