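"""Feature layer: heterogeneous predictor outputs -> numeric design matrix.

Upstream pathogenicity predictors emit a mix of raw numeric scores (CADD
phred, MToolBox disease score, COVEC consensus score), categorical calls
(SIFT ``tolerated``/``deleterious``, PolyPhen2 three-way calls) and
significance pairs (p-value + FDR from VEST/CHASM).  This module turns such a
table into a single :class:`FeatureMatrix` — an ``n x p`` real matrix with an
explicit missingness mask — by applying published dichotomization rules:

* numeric thresholds with a "harmful" direction (strictly greater/less);
* total category -> {harmful, neutral} maps;
* the joint significance rule *p < 0.05 and FDR < 0.2*.

It also computes per-site coevolution summaries from a symmetric matrix of
mutual-information Z-scores: the fraction of partner sites whose Z exceeds a
cutoff (6.5 by default) and the mean Z over those coevolving partners.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import UnmappedCategoryError, ValidationError

logger = logging.getLogger(__name__)

HARMFUL = "harmful"
NEUTRAL = "neutral"

#: sentinel strings treated as missing in flat files (configurable per call)
MISSING_SENTINELS = ("", "NA", ".")

RAW_NUMERIC = "raw_numeric"
DICHOTOMIZED = "dichotomized"
COEVOLUTION = "coevolution"

DEFAULT_Z_CUT = 6.5


@dataclass
class DichotomizationRule:
    """How one predictor's output collapses to {harmful, neutral, missing}.

    kind:
        ``numeric_threshold`` — strict comparison of a numeric score against
        ``threshold`` in the harmful ``direction`` ("greater" or "less");
        ``categorical_map`` — exact lookup in ``mapping`` (total over the
        predictor's published category set);
        ``significance_pair`` — harmful iff p < ``p_cutoff`` and
        FDR < ``fdr_cutoff`` (both strict), consuming the two columns named
        by ``p_column``/``fdr_column``.
    """

    name: str
    kind: str
    threshold: float | None = None
    direction: str = "greater"
    mapping: Mapping[str, str] | None = None
    p_cutoff: float = 0.05
    fdr_cutoff: float = 0.2
    p_column: str | None = None
    fdr_column: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric_threshold", "categorical_map", "significance_pair"):
            raise ValidationError(f"unknown rule kind {self.kind!r} for {self.name!r}")
        if self.kind == "numeric_threshold" and self.threshold is None:
            raise ValidationError(f"rule {self.name!r}: numeric_threshold needs a threshold")
        if self.kind == "categorical_map":
            if not self.mapping:
                raise ValidationError(f"rule {self.name!r}: categorical_map needs a mapping")
            bad = {v for v in self.mapping.values()} - {HARMFUL, NEUTRAL}
            if bad:
                raise ValidationError(f"rule {self.name!r}: map targets must be harmful/neutral, got {bad}")
        if self.direction not in ("greater", "less"):
            raise ValidationError(f"rule {self.name!r}: direction must be 'greater' or 'less'")


def dichotomize_numeric(x, rule: DichotomizationRule):
    """Strict-threshold call on a numeric score; non-finite input -> missing."""
    if rule.kind != "numeric_threshold":
        raise ValidationError(f"rule {rule.name!r} is not numeric_threshold")
    if x is None:
        return None
    try:
        xv = float(x)
    except (TypeError, ValueError):
        return None
    if not math.isfinite(xv):
        return None
    if rule.direction == "greater":
        return HARMFUL if xv > rule.threshold else NEUTRAL
    return HARMFUL if xv < rule.threshold else NEUTRAL


def dichotomize_categorical(call, rule: DichotomizationRule):
    """Exact map lookup; missing in -> missing out; unknown category raises."""
    if rule.kind != "categorical_map":
        raise ValidationError(f"rule {rule.name!r} is not categorical_map")
    if call is None or (isinstance(call, float) and math.isnan(call)):
        return None
    key = str(call).strip()
    if key in MISSING_SENTINELS:
        return None
    norm = key.lower()
    for cat, verdict in rule.mapping.items():
        if cat.lower() == norm:
            return verdict
    raise UnmappedCategoryError(rule.name, key)


def significance_call(p_value, fdr, rule: DichotomizationRule | None = None):
    """Joint significance rule: harmful iff p < p_cutoff AND fdr < fdr_cutoff.

    Strict inequalities; either input missing (None/NaN) -> missing.
    Out-of-range probabilities raise :class:`ValidationError`.
    """
    p_cut = rule.p_cutoff if rule is not None else 0.05
    f_cut = rule.fdr_cutoff if rule is not None else 0.2
    vals = []
    for v in (p_value, fdr):
        if v is None:
            return None
        v = float(v)
        if math.isnan(v):
            return None
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"p/FDR value {v} outside [0, 1]")
        vals.append(v)
    return HARMFUL if (vals[0] < p_cut and vals[1] < f_cut) else NEUTRAL


# ---------------------------------------------------------------------------
# FeatureMatrix


@dataclass
class FeatureMatrix:
    """n x p design matrix with missingness mask and per-column kinds.

    ``values`` holds NaN at masked cells; ``mask`` is True where missing.
    Column kinds are one of raw_numeric / dichotomized / coevolution.
    """

    values: np.ndarray
    mask: np.ndarray
    columns: list[str]
    kinds: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValidationError("FeatureMatrix must be 2-D with p >= 1")
        if len(self.columns) != self.values.shape[1] or len(self.kinds) != self.values.shape[1]:
            raise ValidationError("column metadata length mismatch")
        if len(set(self.columns)) != len(self.columns):
            raise ValidationError("column names must be unique")
        # masked cells carry no information downstream
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    @property
    def shape(self):
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def take_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values[idx], self.mask[idx], list(self.columns), list(self.kinds))


class ColumnImputer:
    """Per-column imputation for dense consumers.

    Raw numeric (and coevolution) columns get the training-sample mean;
    dichotomized columns get 0 (neutral).  Fit only on the rows that train a
    given model — for bootstrap members that is the in-bag sample, never the
    out-of-bag rows.
    """

    def __init__(self) -> None:
        self.fill_: np.ndarray | None = None

    def fit(self, fm: FeatureMatrix, rows=None) -> "ColumnImputer":
        vals = fm.values if rows is None else fm.values[np.asarray(rows)]
        fill = np.zeros(vals.shape[1])
        with np.errstate(invalid="ignore"):
            means = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
        for j, kind in enumerate(fm.kinds):
            if kind == DICHOTOMIZED:
                fill[j] = 0.0
            else:
                fill[j] = means[j] if np.isfinite(means[j]) else 0.0
        self.fill_ = fill
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.fill_ is None:
            raise ValidationError("imputer not fitted")
        values = np.asarray(values, dtype=float)
        out = values.copy()
        nan = np.isnan(out)
        out[nan] = np.broadcast_to(self.fill_, out.shape)[nan]
        return out


def _to_float(v):
    if v is None:
        return np.nan
    if isinstance(v, float):
        return v
    try:
        return float(v)  # exact strtod; pd.to_numeric is not round-trippable
    except (TypeError, ValueError):
        return np.nan


def _coerce_numeric(series: pd.Series) -> pd.Series:
    cleaned = series.replace(list(MISSING_SENTINELS), np.nan)
    return cleaned.map(_to_float).astype(float)


def encode_features(
    raw: pd.DataFrame,
    rules: Iterable[DichotomizationRule] | Mapping[str, DichotomizationRule] | None = None,
) -> FeatureMatrix:
    """Build a :class:`FeatureMatrix` from a raw feature table.

    Columns with a matching rule are dichotomized (harmful=1, neutral=0);
    significance-pair rules consume their two named p/FDR columns and emit a
    single call column under the rule's name.  Remaining numeric columns pass
    through unchanged; entirely missing or entirely unparseable columns are
    dropped with a provenance log line.
    """
    if rules is None:
        rules = []
    rule_map = dict(rules) if isinstance(rules, Mapping) else {r.name: r for r in rules}

    consumed: set[str] = set()
    cols: list[str] = []
    kinds: list[str] = []
    data: list[np.ndarray] = []
    provenance: list[str] = []

    # significance-pair rules first: they consume two raw columns each
    for rule in rule_map.values():
        if rule.kind != "significance_pair":
            continue
        pc = rule.p_column or f"{rule.name}_pvalue"
        fc = rule.fdr_column or f"{rule.name}_fdr"
        if pc not in raw.columns or fc not in raw.columns:
            continue
        p = _coerce_numeric(raw[pc])
        f = _coerce_numeric(raw[fc])
        calls = [significance_call(pv if pd.notna(pv) else None, fv if pd.notna(fv) else None, rule)
                 for pv, fv in zip(p, f)]
        data.append(np.array([np.nan if c is None else float(c == HARMFUL) for c in calls]))
        cols.append(rule.name)
        kinds.append(DICHOTOMIZED)
        consumed.update((pc, fc))

    for name in raw.columns:
        if name in consumed:
            continue
        series = raw[name]
        rule = rule_map.get(name)
        if rule is not None and rule.kind == "numeric_threshold":
            num = _coerce_numeric(series)
            calls = [dichotomize_numeric(v if pd.notna(v) else None, rule) for v in num]
            col = np.array([np.nan if c is None else float(c == HARMFUL) for c in calls])
            kind = DICHOTOMIZED
        elif rule is not None and rule.kind == "categorical_map":
            calls = [dichotomize_categorical(v, rule) for v in series]
            col = np.array([np.nan if c is None else float(c == HARMFUL) for c in calls])
            kind = DICHOTOMIZED
        else:
            num = _coerce_numeric(series)
            if series.notna().any() and num.isna().all() and series.dtype == object:
                provenance.append(f"dropped column {name!r}: non-numeric and no rule")
                logger.warning("dropped column %r: non-numeric and no rule", name)
                continue
            col = num.to_numpy(dtype=float)
            kind = COEVOLUTION if name.startswith(("mistic_", "coevo_")) else RAW_NUMERIC
        if np.all(np.isnan(col)):
            provenance.append(f"dropped column {name!r}: all values missing")
            logger.warning("dropped column %r: all values missing", name)
            continue
        data.append(col)
        cols.append(name)
        kinds.append(kind)

    if not data:
        raise ValidationError("no usable feature columns")
    values = np.column_stack(data)
    fm = FeatureMatrix(values, np.isnan(values), cols, kinds)
    fm.provenance = provenance
    return fm


def decode_dichotomized(column: np.ndarray):
    """Inverse of the harmful=1 / neutral=0 / NaN=missing encoding."""
    out = []
    for v in np.asarray(column, dtype=float):
        if np.isnan(v):
            out.append(None)
        elif v == 1.0:
            out.append(HARMFUL)
        elif v == 0.0:
            out.append(NEUTRAL)
        else:
            raise ValidationError(f"not a dichotomized encoding: {v}")
    return out


# ---------------------------------------------------------------------------
# Coevolution statistics


def coevolution_site_stats(matrix, z_cut: float = DEFAULT_Z_CUT) -> pd.DataFrame:
    """Per-site coevolution summaries from a symmetric MI Z-score matrix.

    For each site *i*: ``coevolving_frequency`` = |{j != i : Z(i,j) > z_cut}|
    / (L-1), and ``mean_z`` = mean Z over those supra-threshold partners
    (NaN when there are none).  Strictly greater-than, matching the published
    6.5 cutoff for coevolving pairs.  Sites are indexed 1..L.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("coevolution matrix must be square")
    L = m.shape[0]
    if L < 2:
        raise ValidationError("coevolution matrix needs L >= 2")
    off = ~np.eye(L, dtype=bool)
    a, b = m[off], m.T[off]
    both = np.isfinite(a) & np.isfinite(b)
    if np.any(np.isfinite(a) != np.isfinite(b)) or (both.any() and np.max(np.abs(a[both] - b[both])) > 1e-9):
        raise ValidationError("coevolution matrix not symmetric within 1e-9")

    freq = np.zeros(L)
    mean_z = np.full(L, np.nan)
    for i in range(L):
        row = np.delete(m[i], i)
        hot = row[np.isfinite(row) & (row > z_cut)]
        freq[i] = hot.size / (L - 1)
        if hot.size:
            mean_z[i] = hot.mean()
    return pd.DataFrame({"coevolving_frequency": freq, "mean_z": mean_z},
                        index=pd.RangeIndex(1, L + 1, name="site"))


def read_mi_matrix(path) -> np.ndarray:
    """Read a square tab-delimited MI Z-score matrix with a site-index header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float)


def write_mi_matrix(matrix, path) -> None:
    m = np.asarray(matrix, dtype=float)
    L = m.shape[0]
    pd.DataFrame(m, index=pd.RangeIndex(1, L + 1, name="site"),
                 columns=[str(i) for i in range(1, L + 1)]).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Rule files


def _rule_from_dict(d: Mapping) -> DichotomizationRule:
    return DichotomizationRule(**d)


def load_rules(path) -> list[DichotomizationRule]:
    """Load a YAML or JSON list of dichotomization rules."""
    with open(path) as fh:
        text = fh.read()
    try:
        entries = json.loads(text)
    except json.JSONDecodeError:
        entries = yaml.safe_load(text)
    if not isinstance(entries, list):
        raise ValidationError("rules file must contain a list of rule entries")
    return [_rule_from_dict(e) for e in entries]


def default_rules() -> list[DichotomizationRule]:
    """The published dichotomization thresholds shipped with the package."""
    text = resources.files("apogee").joinpath("data/default_rules.yaml").read_text()
    return [_rule_from_dict(e) for e in yaml.safe_load(text)]


def default_encoding_rules() -> list[DichotomizationRule]:
    """Default learner-facing rule set: categorical and significance-pair
    rules only.  Scores published as numeric pass through raw; the numeric
    thresholds from :func:`default_rules` remain available for explicit
    dichotomization."""
    return [r for r in default_rules() if r.kind != "numeric_threshold"]
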