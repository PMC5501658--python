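"""Variant identity, labels, dataset containers and flat-file I/O.

A variant is one single-nucleotide substitution in one of the 13
mtDNA-encoded protein genes, addressed by its rCRS coordinate (1-based,
1..16569) and carrying the amino-acid change plus a curation-derived label.
Labels follow the curation convention of the training corpus: a variant is
*pathogenic* when disease-associated in MITOMAP (and not explicitly flagged
non-pathogenic) or clinically pathological in dbSNP; a variant present only
in dbSNP with no reported pathological consequence is *neutral*, as are the
few MITOMAP entries explicitly reported non-pathogenic.

Internally labels are coded +/-1 with +1 = neutral and -1 = pathogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CurationConflictError,
    DuplicateVariantError,
    FormatError,
    ValidationError,
)
from .features import MISSING_SENTINELS, FeatureMatrix, encode_features

PATHOGENIC = "pathogenic"
NEUTRAL = "neutral"
UNKNOWN = "unknown"

#: the 13 mtDNA-encoded protein genes
MT_GENES = frozenset(
    ["ATP6", "ATP8", "COX1", "COX2", "COX3", "CYB",
     "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6"]
)

RCRS_LENGTH = 16569

#: rCRS coding spans (1-based inclusive): (start, end, strand, codon_start).
#: ND6 is the only protein gene on the reverse strand.
RCRS_GENE_SPANS = {
    "ND1": (3307, 4262, "+", 1),
    "ND2": (4470, 5511, "+", 1),
    "COX1": (5904, 7445, "+", 1),
    "COX2": (7586, 8269, "+", 1),
    "ATP8": (8366, 8572, "+", 1),
    "ATP6": (8527, 9207, "+", 1),
    "COX3": (9207, 9990, "+", 1),
    "ND3": (10059, 10404, "+", 1),
    "ND4L": (10470, 10766, "+", 1),
    "ND4": (10760, 12137, "+", 1),
    "ND5": (12337, 14148, "+", 1),
    "ND6": (14149, 14673, "-", 1),
    "CYB": (14747, 15887, "+", 1),
}

IDENTITY_COLUMNS = ("gene", "position", "ref", "alt", "aa_change")

_NUCLEOTIDES = frozenset("ACGT")


def encode_label(label: str) -> int:
    """External {pathogenic, neutral} -> internal +/-1 (+1 = neutral)."""
    if label == NEUTRAL:
        return 1
    if label == PATHOGENIC:
        return -1
    raise ValidationError(f"cannot encode label {label!r}")


def decode_label(y: int) -> str:
    return NEUTRAL if y > 0 else PATHOGENIC


@dataclass(frozen=True)
class VariantRecord:
    """Identity and label of one mitochondrial missense variant."""

    gene: str
    position: int
    ref_allele: str
    alt_allele: str
    aa_change: str
    label: str = UNKNOWN

    def __post_init__(self):
        if self.gene not in MT_GENES:
            raise ValidationError(f"unknown mitochondrial gene symbol {self.gene!r}")
        if not (1 <= int(self.position) <= RCRS_LENGTH):
            raise ValidationError(f"position {self.position} outside rCRS [1, {RCRS_LENGTH}]")
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValidationError(f"alleles must be single nucleotides, got {self.ref_allele!r}>{self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"ref and alt alleles identical at {self.position}")
        if self.label not in (PATHOGENIC, NEUTRAL, UNKNOWN):
            raise ValidationError(f"invalid label {self.label!r}")

    def validate_span(self) -> None:
        start, end, _, _ = RCRS_GENE_SPANS[self.gene]
        if not (start <= self.position <= end):
            raise ValidationError(
                f"{self.gene} position {self.position} outside annotated span [{start}, {end}]"
            )

    @property
    def key(self):
        return (self.position, self.alt_allele)


@dataclass
class LabeledDataset:
    """Aligned variant records and feature matrix (row-for-row)."""

    records: list[VariantRecord]
    features: FeatureMatrix

    def __post_init__(self):
        if len(self.records) != self.features.shape[0]:
            raise ValidationError("record count differs from feature-matrix row count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def y(self) -> np.ndarray:
        """Internal +/-1 label vector; raises if any label is unknown."""
        return np.array([encode_label(r.label) for r in self.records])

    def require_labeled(self) -> None:
        bad = [r for r in self.records if r.label == UNKNOWN]
        if bad:
            raise ValidationError(f"{len(bad)} records carry no pathogenic/neutral label")


@dataclass(frozen=True)
class CurationEntry:
    """Raw curation facts from which a label is derived.

    mitomap_status in {confirmed, reported, absent}; ``mitomap_pathogenic``
    is True/False when MITOMAP states a direction explicitly (False marks the
    explicitly non-pathogenic entries) and None when absent;
    dbsnp_clinical in {pathological, none, absent}.
    """

    key: tuple
    mitomap_status: str = "absent"
    mitomap_pathogenic: bool | None = None
    dbsnp_clinical: str = "absent"

    def __post_init__(self):
        if self.mitomap_status not in ("confirmed", "reported", "absent"):
            raise ValidationError(f"bad mitomap_status {self.mitomap_status!r}")
        if self.dbsnp_clinical not in ("pathological", "none", "absent"):
            raise ValidationError(f"bad dbsnp_clinical {self.dbsnp_clinical!r}")
        if self.mitomap_status == "absent" and self.dbsnp_clinical == "absent":
            raise ValidationError(f"entry {self.key}: no resolvable curation status")


def assign_labels(entries: Sequence[CurationEntry]) -> list[str]:
    """Derive {pathogenic, neutral} labels from curation facts.

    MITOMAP disease-associated entries not explicitly non-pathogenic are
    pathogenic, as are dbSNP entries with a pathological clinical flag;
    MITOMAP explicitly non-pathogenic entries are neutral; dbSNP-only entries
    with no reported pathological consequence are neutral.  Contradictory
    flags raise :class:`CurationConflictError`.
    """
    labels = []
    for e in entries:
        in_mitomap = e.mitomap_status in ("confirmed", "reported")
        explicit_benign = in_mitomap and e.mitomap_pathogenic is False
        disease_linked = (in_mitomap and e.mitomap_pathogenic is not False) or (
            e.dbsnp_clinical == "pathological"
        )
        if explicit_benign and e.dbsnp_clinical == "pathological":
            raise CurationConflictError(
                f"entry {e.key}: MITOMAP non-pathogenic but dbSNP pathological"
            )
        labels.append(PATHOGENIC if disease_linked and not explicit_benign else NEUTRAL)
    return labels


# ---------------------------------------------------------------------------
# Flat-file I/O


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValidationError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")


def read_variant_table(path, dialect: str = "tsv", rules=None,
                       sentinels: Iterable[str] = MISSING_SENTINELS) -> LabeledDataset:
    """Read a flat variant table (variants as rows, scores as columns).

    Identity columns ``gene, position, ref, alt, aa_change`` are required;
    ``label`` is optional.  All remaining columns are treated as predictor
    features and encoded through :func:`apogee.features.encode_features`
    (sentinels and unparseable numeric cells become missing).
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False,
                     na_values=list(sentinels), float_precision="round_trip")
    missing_cols = [c for c in IDENTITY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing identity columns {missing_cols}")

    keys = list(zip(pd.to_numeric(df["position"]).astype(int), df["alt"]))
    seen, dups = set(), []
    for k in keys:
        if k in seen:
            dups.append(k)
        seen.add(k)
    if dups:
        raise DuplicateVariantError(sorted(set(dups)))

    has_label = "label" in df.columns
    records = []
    for _, row in df.iterrows():
        label = row["label"] if has_label and pd.notna(row["label"]) else UNKNOWN
        records.append(
            VariantRecord(
                gene=row["gene"],
                position=int(float(row["position"])),
                ref_allele=row["ref"],
                alt_allele=row["alt"],
                aa_change=row["aa_change"],
                label=label,
            )
        )

    feature_cols = [c for c in df.columns if c not in IDENTITY_COLUMNS + ("label",)]
    if not feature_cols:
        raise FormatError(f"{path}: no predictor feature columns found")
    fm = encode_features(df[feature_cols], rules=rules)
    return LabeledDataset(records, fm)


def dataset_to_frame(dataset: LabeledDataset, include_label: bool = True) -> pd.DataFrame:
    ident = pd.DataFrame(
        {
            "gene": [r.gene for r in dataset.records],
            "position": [r.position for r in dataset.records],
            "ref": [r.ref_allele for r in dataset.records],
            "alt": [r.alt_allele for r in dataset.records],
            "aa_change": [r.aa_change for r in dataset.records],
        }
    )
    if include_label:
        ident["label"] = [r.label for r in dataset.records]
    return pd.concat([ident, dataset.features.to_dataframe()], axis=1)


def write_variant_table(dataset: LabeledDataset, path, dialect: str = "tsv",
                        include_label: bool = True) -> None:
    """Write a dataset back to a flat file; missing cells become 'NA'."""
    dataset_to_frame(dataset, include_label).to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def write_predictions(dataset: LabeledDataset, probabilities, path, dialect: str = "tsv",
                      extra: dict | None = None) -> None:
    """Prediction output: identity columns + apogee_prob (6 dp) + apogee_call."""
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape[0] != len(dataset):
        raise ValidationError("probability vector length differs from dataset size")
    df = dataset_to_frame(dataset, include_label=False)
    df["apogee_prob"] = [f"{p:.6f}" for p in probs]
    df["apogee_call"] = np.where(probs > 0.5, "P", "N")
    if extra:
        for k, v in extra.items():
            df[k] = v
    df.to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def summarize_by_gene(dataset: LabeledDataset) -> pd.DataFrame:
    """Per-gene totals, pathogenic counts and pathogenic percentage (1 dp)."""
    rows = {}
    for r in dataset.records:
        tot, path = rows.get(r.gene, (0, 0))
        rows[r.gene] = (tot + 1, path + (1 if r.label == PATHOGENIC else 0))
    out = pd.DataFrame(
        [
            {"gene": g, "total": t, "pathogenic": p,
             "pathogenic_pct": round(100.0 * p / t, 1)}
            for g, (t, p) in sorted(rows.items())
        ],
        columns=["gene", "total", "pathogenic", "pathogenic_pct"],
    )
    return out
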