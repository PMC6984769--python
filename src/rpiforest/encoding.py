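"""Per-pair feature assembly: the five feature sets and design matrices.

A protein-RNA pair is encoded by concatenating per-sequence blocks in a
fixed canonical order — families in the order CTF, CGR, AAC, NC, and
within each family the protein block before the RNA block:

========================  ====================================  ====
name                      blocks                                dim
========================  ====================================  ====
``AAC+NC``                AAC(20) + NC(4)                         24
``CTF``                   CTFprot(343) + CTFrna(256)             599
``CGR``                   CGRprot(24) + CGRrna(16)                40
``CTF+CGR``               CTF + CGR                              639
``CTF+CGR+AAC+NC``        CTF + CGR + AAC + NC                   663
========================  ====================================  ====

No scaling is applied: random forests are scale-insensitive.
:class:`PairFeaturizer` exposes the encoding as a scikit-learn transformer
over ``(protein_seq, rna_seq)`` string pairs so it composes with pipelines;
:func:`build_matrix` is the id-resolving bulk path over pair tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import cgr, ctf
from .seqio import (
    MolType,
    PROTEIN_ALPHABET,
    RNA_ALPHABET,
    PairRecord,
    SequenceRecord,
)

#: Canonical feature-set names -> ordered block lists.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "AAC+NC": ("p_aac", "r_nc"),
    "CTF": ("p_ctf", "r_ctf"),
    "CGR": ("p_cgr", "r_cgr"),
    "CTF+CGR": ("p_ctf", "r_ctf", "p_cgr", "r_cgr"),
    "CTF+CGR+AAC+NC": ("p_ctf", "r_ctf", "p_cgr", "r_cgr", "p_aac", "r_nc"),
}

_BLOCK_DIMS = {"p_ctf": 343, "r_ctf": 256, "p_cgr": 24, "r_cgr": 16,
               "p_aac": 20, "r_nc": 4}

_BLOCK_COLUMNS = {
    "p_ctf": tuple(f"p_ctf_{i:03d}" for i in range(343)),
    "r_ctf": tuple(f"r_ctf_{i:03d}" for i in range(256)),
    "p_cgr": tuple(f"p_cgr_{i:02d}" for i in range(1, 25)),
    "r_cgr": tuple(f"r_cgr_{i:02d}" for i in range(1, 17)),
    "p_aac": tuple(f"p_aac_{a}" for a in PROTEIN_ALPHABET),
    "r_nc": tuple(f"r_nc_{b}" for b in RNA_ALPHABET),
}


class FeatureSetError(ValueError):
    """Unknown feature-set name or mismatched dimensions."""


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named feature set and its expected dimensionality."""

    name: str
    blocks: tuple[str, ...] = field(init=False)
    expected_dim: int = field(init=False)

    def __post_init__(self) -> None:
        canonical = parse_feature_set(self.name)
        object.__setattr__(self, "name", canonical)
        blocks = FEATURE_SETS[canonical]
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(
            self, "expected_dim", sum(_BLOCK_DIMS[b] for b in blocks)
        )

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for b in self.blocks for c in _BLOCK_COLUMNS[b])


def parse_feature_set(name: str) -> str:
    """Resolve a case-insensitive, '+'-separated name to its canonical form."""
    key = "+".join(sorted(p.strip().upper() for p in name.split("+")))
    table = {"+".join(sorted(k.split("+"))): k for k in FEATURE_SETS}
    if key not in table:
        raise FeatureSetError(
            f"unknown feature set {name!r}; choose from {sorted(FEATURE_SETS)}"
        )
    return table[key]


@dataclass
class FeatureMatrix:
    """A design matrix with stable column names and optional labels."""

    values: np.ndarray
    column_names: tuple[str, ...]
    pairs: list[PairRecord]
    labels: Optional[np.ndarray] = None
    feature_set: Optional[FeatureSetSpec] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class PairFeaturizer(TransformerMixin, BaseEstimator):
    """Encode (protein_seq, rna_seq) string pairs into numeric features.

    A stateless scikit-learn transformer: ``fit`` only validates, and
    ``transform`` accepts an array-like of shape (n_pairs, 2) holding the
    protein sequence and the RNA sequence of each pair (already sanitized
    strings), returning the (n_pairs, dim) design matrix of the chosen
    feature set.

    Parameters
    ----------
    feature_set : str, default="CTF+CGR"
        One of the five canonical feature-set names (case-insensitive).
    denominator_mode : {"paper", "exact"}, default="paper"
        Normalization of the RNA 4-mer spectrum (see :mod:`rpiforest.ctf`).
    group_map : mapping or None
        Amino-acid -> vertex-index map (1..12) for the protein CGR;
        None uses the package default partition.
    """

    def __init__(self, feature_set: str = "CTF+CGR",
                 denominator_mode: str = "paper",
                 group_map: Optional[Mapping[str, int]] = None):
        self.feature_set = feature_set
        self.denominator_mode = denominator_mode
        self.group_map = group_map

    def fit(self, X, y=None):
        self.spec_ = FeatureSetSpec(self.feature_set)
        self.n_features_out_ = self.spec_.expected_dim
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "spec_"):
            self.fit(X)
        rows = [
            encode_pair(
                SequenceRecord("p", str(p), MolType.protein),
                SequenceRecord("r", str(r), MolType.rna),
                self.spec_,
                denominator_mode=self.denominator_mode,
                group_map=self.group_map,
            )
            for p, r in X
        ]
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        spec = getattr(self, "spec_", None) or FeatureSetSpec(self.feature_set)
        return np.asarray(spec.column_names, dtype=object)


def _encode_block(block: str, protein: SequenceRecord, rna: SequenceRecord,
                  denominator_mode: str,
                  group_map: Optional[Mapping[str, int]]) -> np.ndarray:
    if block == "p_ctf":
        return ctf.encode_ctf_protein(protein)
    if block == "r_ctf":
        return ctf.encode_ctf_rna(rna, denominator_mode=denominator_mode)
    if block == "p_cgr":
        return cgr.encode_cgr_protein(protein, group_map)
    if block == "r_cgr":
        return cgr.encode_cgr_rna(rna)
    if block == "p_aac":
        return ctf.encode_aac(protein)
    if block == "r_nc":
        return ctf.encode_nc(rna)
    raise FeatureSetError(f"unknown block {block!r}")


def encode_pair(protein: SequenceRecord, rna: SequenceRecord,
                spec: FeatureSetSpec | str, *,
                denominator_mode: str = "paper",
                group_map: Optional[Mapping[str, int]] = None) -> np.ndarray:
    """Feature vector of one pair under the given feature set."""
    if isinstance(spec, str):
        spec = FeatureSetSpec(spec)
    try:
        parts = [
            _encode_block(b, protein, rna, denominator_mode, group_map)
            for b in spec.blocks
        ]
    except Exception as exc:
        raise type(exc)(
            f"pair ({protein.id}, {rna.id}): {exc}"
        ) from exc
    vec = np.concatenate(parts)
    assert len(vec) == spec.expected_dim
    return vec


def build_matrix(pairs: Sequence[PairRecord],
                 proteins: Mapping[str, SequenceRecord],
                 rnas: Mapping[str, SequenceRecord],
                 spec: FeatureSetSpec | str, *,
                 denominator_mode: str = "paper",
                 group_map: Optional[Mapping[str, int]] = None
                 ) -> FeatureMatrix:
    """Assemble the design matrix for a pair table.

    Each distinct sequence is encoded once and its blocks reused across
    pairs; rows follow pair-table order.  Unresolved ids raise with the
    full list of missing ids.
    """
    if isinstance(spec, str):
        spec = FeatureSetSpec(spec)
    missing = sorted(
        {p.protein_id for p in pairs} - set(proteins)
        | {p.rna_id for p in pairs} - set(rnas)
    )
    if missing:
        raise KeyError(f"pair table references missing sequence ids: {missing}")

    cache: dict[tuple[str, str], np.ndarray] = {}

    def block_of(block: str, pair: PairRecord) -> np.ndarray:
        seq_id = pair.protein_id if block.startswith("p_") else pair.rna_id
        key = (block, seq_id)
        if key not in cache:
            cache[key] = _encode_block(
                block, proteins[pair.protein_id], rnas[pair.rna_id],
                denominator_mode, group_map,
            )
        return cache[key]

    rows = np.array([
        np.concatenate([block_of(b, pair) for b in spec.blocks])
        for pair in pairs
    ])
    labels = None
    if pairs and pairs[0].label is not None:
        labels = np.array([p.label for p in pairs], dtype=int)
    return FeatureMatrix(
        values=rows, column_names=spec.column_names, pairs=list(pairs),
        labels=labels, feature_set=spec,
    )
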