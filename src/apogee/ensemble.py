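"""Class-balanced bootstrap aggregation of logistic model trees.

Class sizes in the curated training corpus are unbalanced (223 pathogenic
vs 641 neutral), so each bootstrap iteration draws, with replacement,
m = round(0.7 * n_pathogenic) indices from the pathogenic class and the
same number m from the neutral class.  Under that scheme the expected
inclusion frequency of a variant of a class of size n is 1 - (1 - 1/n)^m —
about 50% for the pathogenic and 22% for the neutral class at the corpus
sizes.  The procedure repeats for 100 iterations; each fitted tree scores
its out-of-bag (OOB) variants, per-variant OOB probabilities are averaged
over iterations, and a variant is called pathogenic when that mean is
strictly greater than 0.5.

Imputation of missing feature cells is refitted on each in-bag sample only,
so OOB rows never leak into any member's training statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import ConfigError, ValidationError, VocabularyMismatchError
from .features import RAW_NUMERIC, ColumnImputer, FeatureMatrix
from .lmt import LogisticModelTree, _check_X

logger = logging.getLogger(__name__)


@dataclass
class BootstrapSpec:
    """Bootstrap scheme: iteration count, balanced class fraction, seeds."""

    n_iterations: int = 100
    pathogenic_fraction: float = 0.7
    master_seed: int = 0
    lmt_config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not (0.0 < self.pathogenic_fraction <= 1.0):
            raise ConfigError("pathogenic_fraction must lie in (0, 1]")


def expected_inclusion_frequency(class_size: int, draws: int) -> float:
    """P(a given index of a class of size n appears in m with-replacement
    draws) = 1 - (1 - 1/n)^m."""
    if class_size < 1:
        raise ValidationError("class_size must be >= 1")
    if draws < 0:
        raise ValidationError("draws must be >= 0")
    return 1.0 - (1.0 - 1.0 / class_size) ** draws


def _round_half_up_int(x: float) -> int:
    return int(np.floor(x + 0.5))


def draw_balanced_bootstrap(labels, spec: BootstrapSpec, iteration_seed):
    """One balanced resample: (in-bag index array, sorted OOB index array).

    Draws m = round(fraction * n_pathogenic) indices with replacement from
    each class; OOB is every index never drawn.  Deterministic given the
    iteration seed.
    """
    y = np.asarray(labels)
    path_idx = np.nonzero(y < 0)[0]
    neut_idx = np.nonzero(y > 0)[0]
    if path_idx.size == 0 or neut_idx.size == 0:
        raise ValidationError("both classes must be present")
    m = _round_half_up_int(spec.pathogenic_fraction * path_idx.size)
    if m == 0:
        raise ConfigError("fraction too small: zero draws per class")
    rng = np.random.default_rng(iteration_seed)
    in_bag = np.concatenate([rng.choice(path_idx, m, replace=True),
                             rng.choice(neut_idx, m, replace=True)])
    oob = np.setdiff1d(np.arange(y.size), in_bag)
    return in_bag, oob


class BalancedBootstrapClassifier(ClassifierMixin, BaseEstimator):
    """Bootstrap-aggregated LMT meta-classifier with OOB probability pooling.

    Fitting stores ``oob_mean_proba_`` (mean per-variant OOB pathogenicity
    probability), ``oob_counts_`` (number of iterations each variant was
    out-of-bag), the strict >0.5 ``oob_call_``, and the fitted members.
    Variants never out-of-bag (vanishingly rare at 100 iterations) fall back
    to the full-ensemble mean and are flagged in ``never_oob_``.
    """

    def __init__(self, n_iterations=100, pathogenic_fraction=0.7,
                 min_node_size=15, max_depth=None, purity_stop=1.0,
                 boost_iterations=30, cv_select=False, random_state=0):
        self.n_iterations = n_iterations
        self.pathogenic_fraction = pathogenic_fraction
        self.min_node_size = min_node_size
        self.max_depth = max_depth
        self.purity_stop = purity_stop
        self.boost_iterations = boost_iterations
        self.cv_select = cv_select
        self.random_state = random_state

    def _spec(self):
        return BootstrapSpec(
            n_iterations=self.n_iterations,
            pathogenic_fraction=self.pathogenic_fraction,
            master_seed=self.random_state or 0,
            lmt_config={
                "min_node_size": self.min_node_size,
                "max_depth": self.max_depth,
                "purity_stop": self.purity_stop,
                "boost_iterations": self.boost_iterations,
                "cv_select": self.cv_select,
            },
        )

    @staticmethod
    def _as_matrix(X, column_kinds=None, feature_names=None):
        if isinstance(X, FeatureMatrix):
            return X
        X = _check_X(X)
        kinds = list(column_kinds) if column_kinds is not None else [RAW_NUMERIC] * X.shape[1]
        names = (list(feature_names) if feature_names is not None
                 else [f"x{j}" for j in range(X.shape[1])])
        return FeatureMatrix(X, np.isnan(X), names, kinds)

    def fit(self, X, y, column_kinds=None, feature_names=None):
        fm = self._as_matrix(X, column_kinds, feature_names)
        self.classes_, y_pm = LogisticModelTree._encode_y(y)
        if fm.shape[0] != y_pm.shape[0]:
            raise ValidationError("X and y lengths differ")
        self.feature_names_ = list(fm.columns)
        self.column_kinds_ = list(fm.kinds)
        self.n_features_in_ = fm.shape[1]
        spec = self._spec()

        ss = np.random.SeedSequence(spec.master_seed)
        n = fm.shape[0]
        members = []
        inbag_list = []
        sums = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        self.iteration_seeds_ = []

        spawned = iter(ss.spawn(4 * spec.n_iterations))  # slack for redraws
        it = 0
        while it < spec.n_iterations:
            child = next(spawned)
            in_bag, oob = draw_balanced_bootstrap(y_pm, spec, child)
            if np.unique(y_pm[in_bag]).size < 2:
                logger.info("iteration %d: single-class in-bag sample, redrawing", it)
                continue
            imputer = ColumnImputer().fit(fm, rows=in_bag)
            X_in = imputer.transform(fm.values[in_bag])
            tree = LogisticModelTree(**spec.lmt_config).fit(
                X_in, y_pm[in_bag], feature_names=self.feature_names_)
            if oob.size:
                p = tree.predict_pathogenic_proba(imputer.transform(fm.values[oob]))
                sums[oob] += p
                counts[oob] += 1
            members.append((tree, imputer))
            inbag_list.append(in_bag)
            self.iteration_seeds_.append(child.entropy)
            it += 1

        self.members_ = members
        self.inbag_indices_ = inbag_list
        self.oob_counts_ = counts
        self.never_oob_ = counts == 0
        mean = np.full(n, np.nan)
        seen = counts > 0
        mean[seen] = sums[seen] / counts[seen]
        if self.never_oob_.any():
            idx = np.nonzero(self.never_oob_)[0]
            logger.warning("%d variants never out-of-bag; using full-ensemble mean", idx.size)
            mean[idx] = self._member_mean(fm.values[idx])
        self.oob_mean_proba_ = mean
        self.oob_call_ = np.where(mean > 0.5, -1, 1)  # strict > 0.5 => pathogenic
        return self

    # -- prediction --------------------------------------------------------
    def _member_mean(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        acc = np.zeros(values.shape[0])
        for tree, imputer in self.members_:
            acc += tree.predict_pathogenic_proba(imputer.transform(values))
        return acc / len(self.members_)

    def _check_vocab(self, feature_names):
        if feature_names is None:
            return
        missing = [c for c in self.feature_names_ if c not in feature_names]
        extra = [c for c in feature_names if c not in self.feature_names_]
        if missing or extra:
            raise VocabularyMismatchError(missing, extra)

    def predict_pathogenic_proba(self, X, feature_names=None):
        """Mean pathogenicity probability over all member models."""
        if isinstance(X, FeatureMatrix):
            self._check_vocab(X.columns)
            values = X.values
        else:
            self._check_vocab(feature_names)
            values = _check_X(X, self.n_features_in_)
        if np.isnan(values).all(axis=1).any():
            logger.warning("all-missing feature row(s) submitted; predictions rely on imputation")
        return self._member_mean(values)

    def predict_proba(self, X):
        p_path = self.predict_pathogenic_proba(X)
        cols = {1: 1.0 - p_path, -1: p_path}
        codes = [1 if c in (1, 1.0, "neutral", "N") else -1 for c in self.classes_]
        return np.column_stack([cols[c] for c in codes])

    def predict(self, X):
        p_path = self.predict_pathogenic_proba(X)
        codes = [1 if c in (1, 1.0, "neutral", "N") else -1 for c in self.classes_]
        code_to_class = {c: cls for cls, c in zip(self.classes_, codes)}
        return np.array([code_to_class[-1 if p > 0.5 else 1] for p in p_path])

    def oob_report(self):
        """Per-variant (mean OOB probability, call, n_oob, never_oob flag)."""
        import pandas as pd

        return pd.DataFrame({
            "oob_mean_proba": self.oob_mean_proba_,
            "call": np.where(self.oob_call_ < 0, "P", "N"),
            "n_oob": self.oob_counts_,
            "never_oob": self.never_oob_,
        })

    # -- serialization -----------------------------------------------------
    def save(self, directory):
        """Serialize to a directory: member JSONs plus a manifest."""
        os.makedirs(directory, exist_ok=True)
        vocab_checksum = hashlib.sha256("\t".join(self.feature_names_).encode()).hexdigest()
        manifest = {
            "format": "apogee-ensemble",
            "version": 1,
            "params": self.get_params(),
            "classes": [c.item() if hasattr(c, "item") else c for c in self.classes_],
            "feature_names": self.feature_names_,
            "column_kinds": self.column_kinds_,
            "vocabulary_sha256": vocab_checksum,
            "n_members": len(self.members_),
            "imputer_fills": [list(map(float, imp.fill_)) for _, imp in self.members_],
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh)
        for i, (tree, _) in enumerate(self.members_):
            tree.to_json(os.path.join(directory, f"member_{i:03d}.json"))

    @classmethod
    def load(cls, directory):
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        if manifest.get("format") != "apogee-ensemble":
            raise ValidationError("not a serialized ensemble directory")
        est = cls(**manifest["params"])
        est.classes_ = np.array(manifest["classes"])
        est.feature_names_ = manifest["feature_names"]
        est.column_kinds_ = manifest["column_kinds"]
        est.n_features_in_ = len(est.feature_names_)
        members = []
        for i in range(manifest["n_members"]):
            tree = LogisticModelTree.from_json(os.path.join(directory, f"member_{i:03d}.json"))
            imp = ColumnImputer()
            imp.fill_ = np.array(manifest["imputer_fills"][i])
            members.append((tree, imp))
        est.members_ = members
        return est


def train_ensemble(X, y, spec: BootstrapSpec) -> BalancedBootstrapClassifier:
    """Functional wrapper: fit a :class:`BalancedBootstrapClassifier` from a
    :class:`BootstrapSpec`."""
    est = BalancedBootstrapClassifier(
        n_iterations=spec.n_iterations,
        pathogenic_fraction=spec.pathogenic_fraction,
        random_state=spec.master_seed,
        **spec.lmt_config,
    )
    return est.fit(X, y)


def classify_oob(model: BalancedBootstrapClassifier):
    """Per-variant OOB classification table (mean probability, call, n_oob)."""
    return model.oob_report()


def predict_new(model: BalancedBootstrapClassifier, X, feature_names=None):
    """Mean member probability and strict >0.5 call for new variants."""
    p = model.predict_pathogenic_proba(X, feature_names=feature_names)
    return p, np.where(p > 0.5, "P", "N")
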