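"""Two-class Logistic Model Tree (LMT) with LogitBoost leaf models.

The model couples top-down decision-tree induction with additive logistic
regression.  The tree recursively splits the instance space with binary,
axis-aligned, information-gain splits and stops when a node is pure enough,
too small, or at maximum depth.  Every node runs LogitBoost — stagewise
fitting of one-variable weighted least-squares regressions to the working
response — warm-started from its parent, so each leaf t carries an additive
logistic model f_t over the subset V_t of predictors that boosting selected.

Class coding is +/-1 with +1 = neutral and -1 = pathogenic.  Writing
F_neutral(x) = F(x) and F_pathogenic(x) = -F(x) keeps the two per-class
functions summing to zero; the posterior is the softmax

    P(neutral | x) = e^{F} / (e^{F} + e^{-F}) = 1 / (1 + e^{-2F}).

The whole tree evaluates f(x) = sum_t f_t(x) I(x in S_t): the leaf regions
S_t are disjoint and cover the space, so each x is routed to exactly one
leaf model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import DegenerateModelError, ValidationError

P_CLAMP = 1e-12       # probability clamp inside working-response computation
Z_MAX = 1e6           # working-response guard against clamped-probability blow-ups
GAIN_TOL = 1e-12      # tie tolerance for information-gain comparison


def _sigmoid(t):
    return 0.5 * (1.0 + np.tanh(0.5 * t))


def _log_loss(F, y):
    """Mean logistic loss, y in {-1,+1}: mean log(1 + e^{-2 y F})."""
    return float(np.mean(np.logaddexp(0.0, -2.0 * y * F)))


@dataclass
class AdditiveLogisticModel:
    """Additive logistic model F(x) = intercept + sum_m (a_m + b_m x_{j_m}).

    The per-class functions are F_neutral = F and F_pathogenic = -F (sum to
    zero by construction); the boosting factor 1/2 is folded into the stored
    coefficients.  ``n_iterations`` counts boosting iterations actually
    performed (across warm starts).
    """

    n_features: int
    intercept: float = 0.0
    components: list = field(default_factory=list)  # (var_index, a, b)
    n_iterations: int = 0

    def copy(self) -> "AdditiveLogisticModel":
        return AdditiveLogisticModel(self.n_features, self.intercept,
                                     [tuple(c) for c in self.components], self.n_iterations)

    def selected_variables(self) -> set:
        """V_t: the variables carrying any nonzero linear component."""
        return {j for j, _a, b in self.components if b != 0.0}

    def decision_function(self, X) -> np.ndarray:
        X = _check_X(X, self.n_features)
        F = np.full(X.shape[0], self.intercept)
        for j, a, b in self.components:
            F += a + b * X[:, j]
        return F

    def coefficients(self) -> tuple[float, np.ndarray]:
        """Collapse components into (intercept, per-variable slope vector)."""
        w = np.zeros(self.n_features)
        c = self.intercept
        for j, a, b in self.components:
            c += a
            w[j] += b
        return c, w


def _check_X(X, n_features=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    if n_features is not None and X.shape[1] != n_features:
        raise ValidationError(f"expected {n_features} features, got {X.shape[1]}")
    return X


def posterior(model: AdditiveLogisticModel, x):
    """(P_pathogenic, P_neutral) for one feature row, by softmax over
    (F_pathogenic, F_neutral) = (-F, F)."""
    F = float(model.decision_function(np.asarray(x, dtype=float).reshape(1, -1))[0])
    p_neutral = float(_sigmoid(2.0 * F))
    return 1.0 - p_neutral, p_neutral


def _boost(X, y, iterations, warm_start=None, intercept_only=False,
           X_val=None, y_val=None):
    """Run LogitBoost iterations; optionally track held-out loss per iteration.

    Returns (model, train_losses, val_losses); losses are indexed 0..m where
    entry 0 is the warm-start/prior state.  Guarantees non-increasing
    training loss: a step that would increase it is halved, and boosting
    stops early when no shrunk step helps.
    """
    X = _check_X(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if warm_start is not None:
        model = warm_start.copy()
    else:
        prior = float(np.clip(np.mean(y > 0), 1.0 / (n + 2), 1.0 - 1.0 / (n + 2)))
        model = AdditiveLogisticModel(p, intercept=0.5 * math.log(prior / (1.0 - prior)))
    F = model.decision_function(X)
    Fv = model.decision_function(X_val) if X_val is not None else None
    y01 = (y > 0).astype(float)

    train_losses = [_log_loss(F, y)]
    val_losses = [_log_loss(Fv, np.asarray(y_val, dtype=float))] if Fv is not None else None

    Xsq = X * X
    for _ in range(iterations):
        prob = np.clip(_sigmoid(2.0 * F), P_CLAMP, 1.0 - P_CLAMP)
        w = prob * (1.0 - prob)
        z = np.clip((y01 - prob) / w, -Z_MAX, Z_MAX)

        sw = w.sum()
        swz = float(w @ z)
        if intercept_only:
            a, b, j_best = swz / sw, 0.0, -1
        else:
            swx = w @ X
            swxx = w @ Xsq
            swxz = (w * z) @ X
            denom = sw * swxx - swx * swx
            with np.errstate(divide="ignore", invalid="ignore"):
                b_all = np.where(denom > 1e-12 * max(sw, 1.0), (sw * swxz - swx * swz) / denom, 0.0)
            a_all = (swz - b_all * swx) / sw
            swzz = float(w @ (z * z))
            sse = (swzz - 2.0 * a_all * swz - 2.0 * b_all * swxz
                   + a_all * a_all * sw + 2.0 * a_all * b_all * swx + b_all * b_all * swxx)
            j_best = int(np.argmin(sse))  # tie -> lowest feature index
            a, b = float(a_all[j_best]), float(b_all[j_best])

        step = 0.5
        contrib = a + (b * X[:, j_best] if j_best >= 0 else 0.0)
        accepted = False
        for _halving in range(12):
            F_new = F + step * contrib
            if _log_loss(F_new, y) <= train_losses[-1] + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        F = F_new
        if j_best >= 0:
            model.components.append((j_best, step * a, step * b))
        else:
            model.intercept += step * a
        model.n_iterations += 1
        train_losses.append(_log_loss(F, y))
        if Fv is not None:
            Fv = Fv + step * (a + (b * X_val[:, j_best] if j_best >= 0 else 0.0))
            val_losses.append(_log_loss(Fv, np.asarray(y_val, dtype=float)))
    return model, train_losses, val_losses


def fit_logitboost(X, y, iterations, warm_start=None):
    """Fit an additive logistic model by LogitBoost variable selection.

    ``y`` must contain both classes (+1 neutral / -1 pathogenic); missing
    cells must be imputed upstream.  With ``iterations=0`` the model is the
    class-prior constant.  Training log-loss is non-increasing across
    iterations.
    """
    X = _check_X(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y lengths differ")
    if X.shape[0] < 2 or len(np.unique(np.sign(y))) < 2:
        raise DegenerateModelError("LogitBoost requires both classes present (n >= 2)")
    if np.isnan(X).any():
        raise ValidationError("X contains missing cells; impute before fitting")
    model, _, _ = _boost(X, y, iterations, warm_start=warm_start)
    return model


# ---------------------------------------------------------------------------
# Tree induction


@dataclass
class TreeNode:
    """Internal node (split) or leaf (region id + additive logistic model)."""

    depth: int
    n_samples: int
    split_var: int | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    region_id: int | None = None
    model: AdditiveLogisticModel | None = None

    @property
    def is_leaf(self) -> bool:
        return self.model is not None and self.split_var is None


def _entropy(counts):
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _per_feature_candidates(X, y):
    """Per feature: the best information-gain midpoint and the most
    balanced midpoint.  Returns a list of (gain, var, threshold) with the
    balance candidates carrying their own gain."""
    n, p = X.shape
    pos = (y > 0).astype(float)
    n_pos = pos.sum()
    parent = _entropy(np.array([n_pos, n - n_pos]))
    out = []
    for j in range(p):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        cum_pos = np.cumsum(pos[order])
        distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after index i
        if distinct.size == 0:
            continue
        n_left = distinct + 1.0
        pos_left = cum_pos[distinct]
        n_right = n - n_left
        pos_right = n_pos - pos_left

        def h(npos, ntot):
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.vstack([npos, ntot - npos]) / ntot
            ent = np.zeros_like(ntot, dtype=float)
            for row in q:
                nz = row > 0
                ent[nz] -= row[nz] * np.log2(row[nz])
            return ent

        child = (n_left * h(pos_left, n_left) + n_right * h(pos_right, n_right)) / n
        gains = parent - child
        k_gain = int(np.argmax(gains))  # first max -> lowest threshold
        k_bal = int(np.argmin(np.abs(n_left - n / 2.0)))
        for k in {k_gain, k_bal}:
            thr = 0.5 * (xs[distinct[k]] + xs[distinct[k] + 1])
            out.append((float(gains[k]), j, float(thr)))
    return out


def _best_split(X, y):
    """Best axis-aligned split by information gain alone.

    Ties (within GAIN_TOL) break toward the lower feature index, then the
    lower threshold.  Returns (gain, var, threshold) or None.
    """
    best = None
    for gain, j, thr in _per_feature_candidates(X, y):
        if best is None or gain > best[0] + GAIN_TOL or (
                abs(gain - best[0]) <= GAIN_TOL and (j, thr) < (best[1], best[2])):
            best = (gain, j, thr)
    return best


class LogisticModelTree(ClassifierMixin, BaseEstimator):
    """Logistic model tree classifier (two classes).

    Parameters
    ----------
    min_node_size : int
        Nodes smaller than this are not split further.
    max_depth : int or None
        Maximum tree depth; ``None`` means unlimited, ``0`` degenerates to a
        single LogitBoost model on the full data.
    purity_stop : float
        Stop splitting once the majority-class fraction reaches this value.
    boost_iterations : int
        LogitBoost iterations run at each node (warm-started from the
        parent), used when ``cv_select`` is off.
    cv_select : bool
        Select the per-node iteration count once at the root by stratified
        internal cross-validation (capped at ``cv_max_iterations``) and
        reuse it down the tree; the fixed-iteration mode is the default.
    random_state : int or None
        Recorded and used only for the cross-validation fold shuffle; tree
        induction itself is deterministic.
    """

    def __init__(self, min_node_size=15, max_depth=None, purity_stop=1.0,
                 boost_iterations=30, cv_select=False, cv_max_iterations=200,
                 cv_folds=5, split_eval_iterations=10, random_state=None):
        self.min_node_size = min_node_size
        self.max_depth = max_depth
        self.purity_stop = purity_stop
        self.boost_iterations = boost_iterations
        self.cv_select = cv_select
        self.cv_max_iterations = cv_max_iterations
        self.cv_folds = cv_folds
        self.split_eval_iterations = split_eval_iterations
        self.random_state = random_state

    # -- label plumbing ----------------------------------------------------
    @staticmethod
    def _encode_y(y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise DegenerateModelError(f"need exactly 2 classes, got {classes.size}")
        internal = {}
        for c in classes:
            if c in (1, 1.0, "neutral", "N"):
                internal[c] = 1
            elif c in (-1, -1.0, "pathogenic", "P"):
                internal[c] = -1
            else:
                raise ValidationError(f"unrecognized class label {c!r}")
        return classes, np.array([internal[v] for v in y])

    def fit(self, X, y, feature_names=None):
        X = _check_X(X)
        if np.isnan(X).any():
            raise ValidationError("X contains missing cells; impute before fitting")
        self.classes_, y_pm = self._encode_y(y)
        if X.shape[0] != y_pm.shape[0]:
            raise ValidationError("X and y lengths differ")
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = (list(feature_names) if feature_names is not None
                               else [f"x{j}" for j in range(X.shape[1])])
        if len(self.feature_names_) != X.shape[1]:
            raise ValidationError("feature_names length differs from X columns")

        m = self.boost_iterations
        if self.cv_select:
            m = self._cv_iterations(X, y_pm)
        self.boost_iterations_ = int(m)

        self._region_counter = 0
        self.root_ = self._build(X, y_pm, depth=0, parent_model=None)
        self.n_leaves_ = self._region_counter
        self.depth_ = self._max_depth(self.root_)
        return self

    def _cv_iterations(self, X, y):
        rng = np.random.default_rng(self.random_state)
        folds = [[] for _ in range(self.cv_folds)]
        for cls in (-1, 1):
            idx = np.nonzero(y == cls)[0]
            rng.shuffle(idx)
            for i, ix in enumerate(idx):
                folds[i % self.cv_folds].append(ix)
        total = None
        for f in folds:
            val = np.array(sorted(f))
            tr = np.setdiff1d(np.arange(len(y)), val)
            if len(np.unique(y[tr])) < 2 or val.size == 0:
                continue
            _, _, vl = _boost(X[tr], y[tr], self.cv_max_iterations,
                              X_val=X[val], y_val=y[val])
            vl = np.asarray(vl)
            if total is None:
                total = np.zeros(self.cv_max_iterations + 1)
            # folds may stop early; pad with their final loss
            padded = np.concatenate([vl, np.full(self.cv_max_iterations + 1 - vl.size, vl[-1])])
            total += padded
        if total is None:
            return self.boost_iterations
        return max(1, int(np.argmin(total)))

    def _build(self, X, y, depth, parent_model):
        n = X.shape[0]
        classes_present = np.unique(y)
        pure = classes_present.size < 2
        if pure:
            model, _, _ = _boost(X, y, self.boost_iterations_,
                                 warm_start=parent_model, intercept_only=True)
            if parent_model is None:
                # fresh single-class node: Laplace-smoothed prior intercept
                prior = (np.sum(y > 0) + 1.0) / (n + 2.0)
                model = AdditiveLogisticModel(X.shape[1],
                                              intercept=0.5 * math.log(prior / (1.0 - prior)))
        else:
            model, _, _ = _boost(X, y, self.boost_iterations_, warm_start=parent_model)

        purity = max(np.mean(y > 0), np.mean(y < 0))
        stop = (
            pure
            or purity >= self.purity_stop
            or n < self.min_node_size
            or (self.max_depth is not None and depth >= self.max_depth)
        )
        split = None if stop else self._choose_split(X, y, model)
        if split is None:
            node = TreeNode(depth=depth, n_samples=n, region_id=self._region_counter, model=model)
            self._region_counter += 1
            return node
        _gain, j, thr = split
        mask = X[:, j] <= thr  # threshold ties route left
        node = TreeNode(depth=depth, n_samples=n, split_var=j, split_threshold=thr)
        node.left = self._build(X[mask], y[mask], depth + 1, model)
        node.right = self._build(X[~mask], y[~mask], depth + 1, model)
        return node

    def _choose_split(self, X, y, node_model):
        """Pick the split whose two child LogitBoost models minimize the
        pooled training log-loss.

        The shortlist holds, per feature, the best information-gain midpoint
        and the most balanced midpoint; each candidate's children are fitted
        with ``split_eval_iterations`` warm-started boosting iterations.
        Scoring splits by the fit of the leaf model class (rather than label
        entropy alone) lets induction find structure — e.g. an XOR layout —
        whose first split carries no label information by itself.  Ties
        break toward the lower feature index, then the lower threshold.
        """
        candidates = _per_feature_candidates(X, y)
        if not candidates:
            return None
        n = X.shape[0]
        best = None
        for gain, j, thr in sorted(candidates, key=lambda c: (c[1], c[2])):
            mask = X[:, j] <= thr
            n_l = int(mask.sum())
            if n_l == 0 or n_l == n:
                continue
            score = 0.0
            for sub in (mask, ~mask):
                Xs, ys = X[sub], y[sub]
                single = np.unique(np.sign(ys)).size < 2
                m, losses, _ = _boost(Xs, ys, self.split_eval_iterations,
                                      warm_start=node_model, intercept_only=single)
                score += sub.sum() * losses[-1]
            score /= n
            if best is None or score < best[0] - 1e-12:
                best = (score, gain, j, thr)
        if best is None:
            return None
        return best[1], best[2], best[3]

    def _max_depth(self, node):
        if node.is_leaf:
            return node.depth
        return max(self._max_depth(node.left), self._max_depth(node.right))

    # -- prediction --------------------------------------------------------
    def _leaf_for(self, x):
        node = self.root_
        while not node.is_leaf:
            node = node.left if x[node.split_var] <= node.split_threshold else node.right
        return node

    def decision_function(self, X):
        """F(x) routed through the leaf partition (positive favours neutral)."""
        X = _check_X(X, self.n_features_in_)
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            leaf = self._leaf_for(x)
            out[i] = leaf.model.decision_function(x.reshape(1, -1))[0]
        return out

    def predict_proba(self, X):
        p_neutral = _sigmoid(2.0 * self.decision_function(X))
        p_path = 1.0 - p_neutral
        cols = {1: p_neutral, -1: p_path}
        _, codes = self._encode_classes()
        return np.column_stack([cols[c] for c in codes])

    def _encode_classes(self):
        codes = []
        for c in self.classes_:
            codes.append(1 if c in (1, 1.0, "neutral", "N") else -1)
        return self.classes_, codes

    def predict_pathogenic_proba(self, X):
        return 1.0 - _sigmoid(2.0 * self.decision_function(X))

    def predict(self, X):
        """Hard call by argmax posterior; a tie at 0.5 resolves to neutral."""
        p_path = self.predict_pathogenic_proba(X)
        _, codes = self._encode_classes()
        code_to_class = {c: cls for cls, c in zip(self.classes_, codes)}
        internal = np.where(p_path > 0.5, -1, 1)
        return np.array([code_to_class[c] for c in internal])

    # -- introspection -----------------------------------------------------
    def decision_rules(self):
        """One human-readable rule per leaf: the root-to-leaf predicate
        conjunction plus the leaf's logistic coefficients."""
        rules = []

        def walk(node, preds):
            if node.is_leaf:
                c0, w = node.model.coefficients()
                coef = ", ".join(f"{self.feature_names_[j]}: {w[j]:+.4f}"
                                 for j in range(len(w)) if w[j] != 0.0)
                pred = " AND ".join(preds) if preds else "(always)"
                rules.append(f"IF {pred} THEN F_neutral = {c0:+.4f}"
                             + (f" with [{coef}]" if coef else " (intercept only)"))
                return
            name = self.feature_names_[node.split_var]
            walk(node.left, preds + [f"{name} <= {node.split_threshold:.6g}"])
            walk(node.right, preds + [f"{name} > {node.split_threshold:.6g}"])

        walk(self.root_, [])
        return rules

    # -- serialization -----------------------------------------------------
    def to_dict(self):
        def node_dict(node):
            if node.is_leaf:
                return {
                    "leaf": True,
                    "region_id": node.region_id,
                    "n_samples": node.n_samples,
                    "model": {
                        "n_features": node.model.n_features,
                        "intercept": node.model.intercept,
                        "components": [list(c) for c in node.model.components],
                        "n_iterations": node.model.n_iterations,
                    },
                }
            return {
                "leaf": False,
                "n_samples": node.n_samples,
                "split_var": node.split_var,
                "split_threshold": node.split_threshold,
                "left": node_dict(node.left),
                "right": node_dict(node.right),
            }

        return {
            "format": "apogee-lmt",
            "version": 1,
            "params": self.get_params(),
            "classes": [c.item() if hasattr(c, "item") else c for c in self.classes_],
            "feature_names": self.feature_names_,
            "n_features": self.n_features_in_,
            "tree": node_dict(self.root_),
        }

    @classmethod
    def from_dict(cls, d):
        if d.get("format") != "apogee-lmt":
            raise ValidationError("not a serialized LMT model")
        est = cls(**d["params"])
        est.classes_ = np.array(d["classes"])
        est.feature_names_ = list(d["feature_names"])
        est.n_features_in_ = d["n_features"]

        def build(nd, depth):
            if nd["leaf"]:
                m = nd["model"]
                model = AdditiveLogisticModel(m["n_features"], m["intercept"],
                                              [tuple(c) for c in m["components"]],
                                              m["n_iterations"])
                return TreeNode(depth=depth, n_samples=nd["n_samples"],
                                region_id=nd["region_id"], model=model)
            node = TreeNode(depth=depth, n_samples=nd["n_samples"],
                            split_var=nd["split_var"], split_threshold=nd["split_threshold"])
            node.left = build(nd["left"], depth + 1)
            node.right = build(nd["right"], depth + 1)
            return node

        est.root_ = build(d["tree"], 0)
        leaves = []

        def count(node):
            if node.is_leaf:
                leaves.append(node)
            else:
                count(node.left)
                count(node.right)

        count(est.root_)
        est.n_leaves_ = len(leaves)
        est.depth_ = est._max_depth(est.root_)
        est.boost_iterations_ = est.boost_iterations
        return est

    def to_json(self, path=None):
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        text = source
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        return cls.from_dict(json.loads(text))


def induce_lmt(X, y, **config) -> LogisticModelTree:
    """Functional wrapper over :class:`LogisticModelTree` fit."""
    return LogisticModelTree(**config).fit(X, y)
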