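"""Shadow-feature (Boruta) selection with out-of-bag permutation importance.

The algorithm proceeds in five steps per iteration: (1) every feature is
duplicated and the duplicate's values are shuffled ("shadow" features);
(2) a random-forest classifier is trained on the combined matrix and each
column's importance is measured as mean decrease accuracy — the mean drop in
a tree's out-of-bag accuracy when the column is permuted within the OOB
sample; (3) each original feature beating the maximum shadow importance
earns a hit; (4) iterations accumulate hits; (5) a binomial test against
p = 0.5 (Bonferroni-corrected across still-undecided features) classifies
features as important or unimportant, leaving the rest tentative.  Runs are
resumable: extending a finished run continues the same random stream, so
``run(n)`` then ``extend(m)`` equals ``run(n + m)``.

Because the endpoint here is a binary day-horizon outcome, patients who died
without the primary event before the horizon are excluded when the feature
matrix is built; censored-before-horizon patients are kept with outcome 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .exposure import ExposureDesign, InvalidArgumentError

logger = logging.getLogger(__name__)

DEFAULT_RF_CONFIG = {"n_estimators": 500, "max_features": "sqrt",
                     "max_depth": None}


def build_feature_matrix(design: ExposureDesign,
                         covariates: pd.DataFrame | None,
                         outcomes: pd.DataFrame,
                         horizon: int = 180) -> tuple[pd.DataFrame, pd.Series]:
    """Patient-level binary feature matrix and day-horizon outcome.

    Exposure columns are 1 if the class was administered in the interval at
    all; the outcome is 1 iff the primary event occurred by the horizon.
    Competing-event (death) patients before the horizon are excluded.
    """
    if horizon <= 0:
        raise InvalidArgumentError("horizon must be > 0")
    out = outcomes.set_index("patient_id").loc[design.patients]
    excluded = ((out["event_type"] == "death")
                & (out["event_day"] <= horizon))
    keep = [p for p, ex in zip(design.patients, excluded) if not ex]
    if not keep:
        raise InvalidArgumentError("all patients excluded (all died without "
                                   "the primary event before the horizon)")
    X = (~design.first_day.loc[keep].isna()).astype(float)
    if covariates is not None:
        X = X.join(covariates.loc[keep])
    y = ((out.loc[keep, "event_type"] == "agvhd")
         & (out.loc[keep, "event_day"] <= horizon)).astype(int)
    return X, y


def shadow_augment(X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append one row-shuffled shadow copy of every column."""
    if X.empty:
        raise InvalidArgumentError("feature matrix must be non-empty")
    out = X.copy()
    for c in X.columns:
        out[f"shadow__{c}"] = rng.permutation(X[c].to_numpy())
    return out


def mean_decrease_accuracy(X_aug: pd.DataFrame, y, rf_config=None,
                           rng: np.random.Generator | None = None,
                           random_state: int | None = None) -> pd.Series:
    """Out-of-bag permutation importance per column.

    importance_j = mean over trees of (OOB accuracy - OOB accuracy with
    column j permuted within the OOB sample).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("outcome must contain both classes")
    cfg = dict(DEFAULT_RF_CONFIG, **(rf_config or {}))
    rng = rng or np.random.default_rng(random_state)
    Xv = np.ascontiguousarray(X_aug.to_numpy(np.float32))
    n, p = Xv.shape
    rf = RandomForestClassifier(bootstrap=True,
                                random_state=int(rng.integers(2 ** 31)),
                                **cfg)
    rf.fit(Xv, y)
    classes = rf.classes_

    def tree_classify(tree, M):
        # low-level predict: skips per-call input validation
        votes = tree.tree_.predict(np.ascontiguousarray(M, dtype=np.float32))
        return classes[np.argmax(votes.reshape(len(M), -1), axis=1)]

    imp = np.zeros(p)
    n_used = 0
    all_idx = np.arange(n)
    for tree, sample_idx in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(all_idx, sample_idx, assume_unique=False)
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = Xv[oob]
        yo = y[oob]
        m = len(oob)
        base = np.mean(tree_classify(tree, Xo) == yo)
        # one batched prediction over all p single-column permutations
        stacked = np.broadcast_to(Xo, (p, m, p)).copy()
        for j in range(p):
            stacked[j, :, j] = Xo[rng.permutation(m), j]
        preds = tree_classify(tree, stacked.reshape(p * m, p)).reshape(p, m)
        imp += base - np.mean(preds == yo[None, :], axis=1)
    if n_used == 0:
        raise RuntimeError("no tree had a non-empty out-of-bag sample")
    return pd.Series(imp / n_used, index=X_aug.columns)


@dataclass
class BorutaResult:
    """Per-feature decisions with full importance history and hit counts."""

    features: list[str]
    decisions: dict                        # feature -> important|unimportant|tentative
    hit_counts: dict
    n_completed_iterations: int
    importance_history: list               # per iteration: feature -> importance
    shadow_max_history: list
    z_scores: dict
    alpha: float
    rf_config: dict
    _rng_state: dict | None = None

    def important(self) -> list[str]:
        return [f for f in self.features if self.decisions[f] == "important"]

    def unimportant(self) -> list[str]:
        return [f for f in self.features if self.decisions[f] == "unimportant"]

    def tentative(self) -> list[str]:
        return [f for f in self.features if self.decisions[f] == "tentative"]

    def to_dict(self) -> dict:
        return {"features": self.features, "decisions": self.decisions,
                "hit_counts": self.hit_counts,
                "n_completed_iterations": self.n_completed_iterations,
                "z_scores": self.z_scores, "alpha": self.alpha,
                "rf_config": self.rf_config,
                "importance_history": self.importance_history,
                "shadow_max_history": self.shadow_max_history}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def save_state(self, path) -> None:
        """Resumable state: decisions, hits, and the random stream position."""
        state = self.to_dict()
        state["rng_state"] = _jsonable_rng_state(self._rng_state)
        with open(path, "w") as fh:
            json.dump(state, fh)


def _jsonable_rng_state(state):
    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, np.ndarray):
            return {"__nd__": x.tolist(), "dtype": str(x.dtype)}
        if isinstance(x, (np.integer,)):
            return int(x)
        return x
    return conv(state)


def _restore_rng_state(state):
    def conv(x):
        if isinstance(x, dict):
            if "__nd__" in x:
                return np.array(x["__nd__"], dtype=x["dtype"])
            return {k: conv(v) for k, v in x.items()}
        return x
    return conv(state)


def _classify(result: BorutaResult) -> None:
    """Binomial hit tests with Bonferroni correction over undecided features."""
    n = result.n_completed_iterations
    undecided = [f for f in result.features
                 if result.decisions[f] == "tentative"]
    if not undecided or n == 0:
        return
    m = len(undecided)
    for f in undecided:
        h = result.hit_counts[f]
        p_two = stats.binomtest(h, n, 0.5).pvalue
        if p_two < result.alpha / m:
            result.decisions[f] = "important" if h > n / 2 else "unimportant"
    for f in result.features:
        h = result.hit_counts[f]
        result.z_scores[f] = (h - n / 2) / np.sqrt(n / 4) if n else 0.0


def _iterate(X: pd.DataFrame, y, result: BorutaResult, n_iter: int,
             rng: np.random.Generator) -> None:
    for _ in range(n_iter):
        X_aug = shadow_augment(X, rng)
        imp = mean_decrease_accuracy(X_aug, y, result.rf_config, rng=rng)
        shadow_max = float(imp[[c for c in X_aug.columns
                                if c.startswith("shadow__")]].max())
        for f in result.features:
            if float(imp[f]) > shadow_max:
                result.hit_counts[f] += 1
        result.importance_history.append(
            {f: float(imp[f]) for f in result.features})
        result.shadow_max_history.append(shadow_max)
        result.n_completed_iterations += 1
        _classify(result)
    result._rng_state = rng.bit_generator.state


def run_boruta(X: pd.DataFrame, y, n_iter: int = 100, alpha: float = 0.05,
               rf_config=None, seed: int = 0) -> BorutaResult:
    """Run the shadow-feature selection for ``n_iter`` iterations.

    Decisions, once made, are final; remaining features are tentative and can
    be resolved by :func:`extend_boruta`.  Identical seed and configuration
    give identical results.
    """
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    features = list(X.columns)
    result = BorutaResult(
        features=features,
        decisions={f: "tentative" for f in features},
        hit_counts={f: 0 for f in features},
        n_completed_iterations=0,
        importance_history=[], shadow_max_history=[],
        z_scores={f: 0.0 for f in features},
        alpha=alpha, rf_config=dict(DEFAULT_RF_CONFIG, **(rf_config or {})))
    rng = np.random.default_rng(seed)
    _iterate(X, y, result, n_iter, rng)
    return result


def extend_boruta(result: BorutaResult, X: pd.DataFrame, y,
                  n_more: int) -> BorutaResult:
    """Continue a run for ``n_more`` iterations on the same random stream."""
    if n_more < 1:
        raise InvalidArgumentError("n_more must be >= 1")
    if result._rng_state is None:
        raise InvalidArgumentError("result carries no resumable random state")
    rng = np.random.default_rng()
    rng.bit_generator.state = _restore_rng_state(result._rng_state)
    _iterate(X, y, result, n_more, rng)
    return result
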