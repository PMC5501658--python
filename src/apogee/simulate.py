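"""Synthetic two-class feature tables, coevolution matrices and label nulls.

The generator emulates the statistical shape of the curated training corpus:
two classes of unequal size (223 pathogenic, 641 neutral by default),
per-predictor class-conditional distributions (normal for numeric scores,
Bernoulli harmful-call rates for categorical predictors), and per-predictor
missingness matching the shortfall of available predictions in real score
tables.  Variant identities are synthesized over the 13 real mitochondrial
protein genes with positions drawn inside the real rCRS coding spans.

Everything is reproducible from the config seed.  The generator makes no
attempt to imitate the correlation structure among real predictors: columns
are drawn independently given the class.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .features import default_encoding_rules, encode_features
from .variants import (
    LabeledDataset,
    NEUTRAL,
    PATHOGENIC,
    RCRS_GENE_SPANS,
    VariantRecord,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass
class PredictorSpec:
    """Class-conditional distribution of one synthetic predictor column.

    Numeric predictors are normal per class (``mean_pathogenic`` /
    ``mean_neutral``, shared ``sd``); categorical predictors emit
    ``categories[0]`` (the harmful call) with a per-class Bernoulli rate.
    """

    name: str
    kind: str = "numeric"
    mean_pathogenic: float = 0.0
    mean_neutral: float = 0.0
    sd: float = 1.0
    p_harmful_pathogenic: float = 0.5
    p_harmful_neutral: float = 0.5
    missing_rate: float = 0.0
    categories: tuple = ("deleterious", "tolerated")

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ConfigError(f"predictor {self.name!r}: kind must be numeric/categorical")
        if self.sd <= 0:
            raise ConfigError(f"predictor {self.name!r}: sd must be > 0")
        for r in (self.missing_rate, self.p_harmful_pathogenic, self.p_harmful_neutral):
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"predictor {self.name!r}: rates must lie in [0, 1]")


def default_predictors() -> list[PredictorSpec]:
    """A realistic analogue of the aggregated predictor panel: eight numeric
    scores with moderate class separation and two categorical callers, with
    missingness mirroring real prediction shortfalls."""
    return [
        PredictorSpec("cadd_phred", mean_pathogenic=15.0, mean_neutral=8.0, sd=4.0),
        PredictorSpec("mtoolbox_ds", mean_pathogenic=0.62, mean_neutral=0.35, sd=0.18),
        PredictorSpec("provean_score", mean_pathogenic=-5.0, mean_neutral=-1.5, sd=2.5),
        PredictorSpec("covec_wmv", mean_pathogenic=1.0, mean_neutral=-0.8, sd=1.5,
                      missing_rate=0.032),
        PredictorSpec("efin_sp", mean_pathogenic=0.75, mean_neutral=0.45, sd=0.2),
        PredictorSpec("phylop100v", mean_pathogenic=1.8, mean_neutral=0.8, sd=1.2),
        PredictorSpec("phastcons100v", mean_pathogenic=0.7, mean_neutral=0.45, sd=0.25),
        PredictorSpec("panther_score", mean_pathogenic=0.6, mean_neutral=0.4, sd=0.2,
                      missing_rate=0.124),
        PredictorSpec("sift", kind="categorical", p_harmful_pathogenic=0.14,
                      p_harmful_neutral=0.13, categories=("deleterious", "tolerated")),
        PredictorSpec("polyphen2", kind="categorical", p_harmful_pathogenic=0.55,
                      p_harmful_neutral=0.42, missing_rate=0.014,
                      categories=("probably damaging", "benign")),
    ]


@dataclass
class SimulationConfig:
    """Class sizes, predictor panel and seed of one synthetic corpus."""

    n_pathogenic: int = 223
    n_neutral: int = 641
    predictors: list[PredictorSpec] = field(default_factory=default_predictors)
    seed: int = 0

    def __post_init__(self):
        if self.n_pathogenic < 1 or self.n_neutral < 1:
            raise ConfigError("both class sizes must be >= 1")
        if not self.predictors:
            raise ConfigError("at least one predictor is required")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def separable_config(n_pathogenic: int = 223, n_neutral: int = 641,
                     n_informative: int = 5, separation: float = 2.0,
                     n_noise: int = 0, seed: int = 0) -> SimulationConfig:
    """Config with ``n_informative`` unit-SD numeric features whose class
    means sit ``separation`` SDs apart, plus optional pure-noise features."""
    preds = [PredictorSpec(f"signal_{i}", mean_pathogenic=separation, mean_neutral=0.0, sd=1.0)
             for i in range(n_informative)]
    preds += [PredictorSpec(f"noise_{i}", mean_pathogenic=0.0, mean_neutral=0.0, sd=1.0)
              for i in range(n_noise)]
    return SimulationConfig(n_pathogenic=n_pathogenic, n_neutral=n_neutral,
                            predictors=preds, seed=seed)


def _synthesize_identities(n: int, rng) -> list[tuple]:
    genes = sorted(RCRS_GENE_SPANS)
    lengths = np.array([RCRS_GENE_SPANS[g][1] - RCRS_GENE_SPANS[g][0] + 1 for g in genes], float)
    weights = lengths / lengths.sum()
    seen = set()
    out = []
    while len(out) < n:
        g = genes[rng.choice(len(genes), p=weights)]
        start, end, _, _ = RCRS_GENE_SPANS[g]
        pos = int(rng.integers(start, end + 1))
        ref, alt = rng.choice(list(_NT), size=2, replace=False)
        if (pos, alt) in seen:
            continue
        seen.add((pos, alt))
        aa_pos = (pos - start) // 3 + 1
        a, b = rng.choice(list(_AA), size=2, replace=False)
        out.append((g, pos, str(ref), str(alt), f"{a}{aa_pos}{b}"))
    return out


def generate_raw_table(config: SimulationConfig) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Draw (records, raw feature table) from the class-conditional model.

    The raw table carries numeric scores as floats and categorical calls as
    strings, with NaN at missing cells — the same shape a parsed flat file
    has before encoding.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pathogenic + config.n_neutral
    labels = np.array([PATHOGENIC] * config.n_pathogenic + [NEUTRAL] * config.n_neutral)
    rng.shuffle(labels)
    idents = _synthesize_identities(n, rng)
    records = [VariantRecord(g, p, r, a, aa, label=lab)
               for (g, p, r, a, aa), lab in zip(idents, labels)]
    is_path = labels == PATHOGENIC

    data = {}
    for spec in config.predictors:
        if spec.kind == "numeric":
            mu = np.where(is_path, spec.mean_pathogenic, spec.mean_neutral)
            col = rng.normal(mu, spec.sd)
            col = pd.Series(col)
        else:
            p_h = np.where(is_path, spec.p_harmful_pathogenic, spec.p_harmful_neutral)
            harmful = rng.random(n) < p_h
            col = pd.Series(np.where(harmful, spec.categories[0], spec.categories[1]),
                            dtype=object)
        if spec.missing_rate > 0:
            col[rng.random(n) < spec.missing_rate] = np.nan
        data[spec.name] = col
    return records, pd.DataFrame(data)


def generate_dataset(config: SimulationConfig, rules=None) -> LabeledDataset:
    """Generate a labeled dataset with an encoded feature matrix.

    Categorical columns are dichotomized through ``rules`` (the default
    categorical rule set when None); numeric scores pass through raw.
    """
    records, raw = generate_raw_table(config)
    if rules is None:
        rules = default_encoding_rules()
    return LabeledDataset(records, encode_features(raw, rules=rules))


def permute_labels(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Uniformly permute label assignment, preserving the label multiset."""
    rng = np.random.default_rng(seed)
    labels = [r.label for r in dataset.records]
    perm = rng.permutation(len(labels))
    new_records = [dataclasses.replace(r, label=labels[perm[i]])
                   for i, r in enumerate(dataset.records)]
    return LabeledDataset(new_records, dataset.features)


def generate_mi_matrix(L: int, n_hot_pairs: int, z_hot: float = 8.0,
                       seed: int = 0, background_sd: float = 2.0) -> np.ndarray:
    """Symmetric MI Z-score matrix: sub-threshold background noise plus
    exactly ``n_hot_pairs`` planted supra-threshold pairs at ``z_hot``."""
    if n_hot_pairs > L * (L - 1) // 2:
        raise ValidationError("more hot pairs than available site pairs")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, background_sd, size=(L, L))
    m = np.minimum((noise + noise.T) / 2.0, 6.0)  # keep background below the 6.5 cut
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    chosen = rng.choice(len(pairs), size=n_hot_pairs, replace=False)
    for k in np.asarray(chosen, dtype=int).ravel():
        i, j = pairs[k]
        m[i, j] = m[j, i] = z_hot
    np.fill_diagonal(m, 0.0)
    return m
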