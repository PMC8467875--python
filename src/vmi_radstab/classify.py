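"""Tournament-leave-pair-out classification evaluation.

Model evaluation follows a tournament-leave-pair-out cross-validation
(TLPO-CV): every unordered pair of objects is held out once, models are
trained on the remaining objects, and for each class the pair member with the
higher predicted class probability "wins" the tournament (ties count half).
Per-object win counts serve as rank scores for one-vs-rest Mann–Whitney
AUCs; the pooled out-of-sample class probabilities give a multiclass Brier
score and its scaled variant R² = 1 − BS/BSmax against a non-informative
model that always predicts the training class frequencies.

Hyperparameter search uses random sampling of configurations plus bootstrap
bias correction (BBC): configurations are compared on bootstrap in-bag
predictions and the winner is scored on the out-of-bag objects, removing the
optimism of picking the best of many configurations.

Two learner families are supported behind a common fit/predict-probability
contract: multinomial logistic regression with combined L1/L2 penalty
("elastic net") and random forests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "LearnerSpec",
    "TournamentResult",
    "EvalMetrics",
    "BBCResult",
    "DEFAULT_CONFIGS",
    "feature_subsets",
    "tlpo_splits",
    "run_tournament",
    "ranking_auc",
    "brier_and_r2",
    "bbc_search",
    "evaluate_experiment",
]

LEARNER_FAMILIES = ("elastic_net_logistic", "random_forest")

#: sensible fixed hyperparameters used when no search is requested
DEFAULT_CONFIGS = {
    "elastic_net_logistic": {"C": 10.0, "l1_ratio": 0.7},
    "random_forest": {"n_estimators": 200, "max_depth": None, "max_features": "sqrt"},
}


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus its random hyperparameter search settings.

    Search spaces: elastic net — penalty strength C log-uniform over
    [1e-3, 1e3], mixing ratio uniform [0, 1]; random forest — trees
    100..1000, max depth in {None, 2..10}, features-per-split fraction
    uniform [0.1, 1].
    """

    family: str
    n_configs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"family must be one of {LEARNER_FAMILIES}")
        if self.n_configs < 1:
            raise ValueError("n_configs must be >= 1")

    def sample_configs(self) -> list[dict]:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 11]))
        configs = []
        for _ in range(self.n_configs):
            if self.family == "elastic_net_logistic":
                configs.append(
                    {
                        "C": float(10.0 ** rng.uniform(-3, 3)),
                        "l1_ratio": float(rng.uniform(0, 1)),
                    }
                )
            else:
                depth = rng.choice([0, 2, 3, 4, 6, 8, 10])
                configs.append(
                    {
                        "n_estimators": int(rng.integers(100, 1001)),
                        "max_depth": None if depth == 0 else int(depth),
                        "max_features": float(rng.uniform(0.1, 1.0)),
                    }
                )
        return configs


def make_learner(family: str, config: dict, random_state: int = 0) -> Pipeline:
    """Imputation + scaling + classifier pipeline (fit per fold, no leakage)."""
    if family == "elastic_net_logistic":
        clf = LogisticRegression(
            solver="saga",
            C=config.get("C", 1.0),
            l1_ratio=config.get("l1_ratio", 0.5),
            max_iter=5000,
            random_state=random_state,
        )
    elif family == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=config.get("n_estimators", 200),
            max_depth=config.get("max_depth"),
            max_features=config.get("max_features", "sqrt"),
            random_state=random_state,
        )
    else:
        raise ValueError(f"unknown learner family {family!r}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )


@dataclass
class TournamentResult:
    """Win counts and raw pair predictions from a TLPO tournament."""

    object_ids: tuple[str, ...]
    classes: tuple[str, ...]
    wins: np.ndarray  # (n_objects, n_classes)
    pairs: np.ndarray  # (n_pairs, 2) object indices
    probas: np.ndarray  # (n_pairs, 2, n_classes)


@dataclass
class EvalMetrics:
    auc_per_class: dict[str, float]
    auc_mean: float
    bs: float
    bs_max: float
    r2_scaled: float


@dataclass
class BBCResult:
    corrected: EvalMetrics
    naive: EvalMetrics
    naive_config: dict
    per_config: pd.DataFrame


def feature_subsets(records, c_thr: float = 0.9) -> dict[str, set[str]]:
    """Partition the catalogue into all / repeatable / non-repeatable sets.

    Repeatable means CCC >= threshold (inclusive); an undefined CCC counts as
    non-repeatable. The two subsets always partition the full set.
    """
    all_names: set[str] = set()
    repeatable: set[str] = set()
    for r in records:
        all_names.add(r.feature_name)
        if not np.isnan(r.ccc) and r.ccc >= c_thr:
            repeatable.add(r.feature_name)
    if not repeatable:
        warnings.warn("repeatable feature subset is empty", stacklevel=2)
    return {
        "all": all_names,
        "repeatable": repeatable,
        "non_repeatable": all_names - repeatable,
    }


def tlpo_splits(n: int) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """All leave-pair-out splits in lexicographic order: C(n, 2) of them."""
    if n < 3:
        raise ValueError("need at least 3 objects")
    splits = []
    idx = np.arange(n)
    for i, j in combinations(range(n), 2):
        train = idx[(idx != i) & (idx != j)]
        splits.append((train, (i, j)))
    return splits


def run_tournament(
    features: pd.DataFrame,
    labels: pd.Series,
    family: str = "elastic_net_logistic",
    config: dict | None = None,
    subset: set[str] | None = None,
    random_state: int = 0,
) -> TournamentResult:
    """Fit the learner on every TLPO training fold and play the tournaments.

    Features are median-imputed and standardized by training-fold statistics
    inside every fold. For each held-out pair and each class, the member with
    the higher predicted probability collects one win (half each on a tie).
    """
    if config is None:
        config = DEFAULT_CONFIGS[family]
    labels = labels.loc[features.index]
    cols = sorted(subset) if subset is not None else list(features.columns)
    missing = set(cols) - set(features.columns)
    if missing:
        raise ValueError(f"subset names not in table: {sorted(missing)}")
    if not cols:
        raise ValueError("empty feature subset")
    X = features[cols].to_numpy(dtype=float)
    classes = tuple(sorted(labels.unique()))
    class_index = {c: k for k, c in enumerate(classes)}
    y = labels.map(class_index).to_numpy()
    n, K = len(X), len(classes)

    splits = tlpo_splits(n)
    wins = np.zeros((n, K))
    pairs = np.zeros((len(splits), 2), dtype=int)
    probas = np.zeros((len(splits), 2, K))
    for s, (train, (i, j)) in enumerate(splits):
        model = make_learner(family, config, random_state=random_state)
        try:
            model.fit(X[train], y[train])
        except Exception as exc:  # pragma: no cover - learner failure is rare
            raise RuntimeError(f"learner failed on fold with test pair ({i}, {j})") from exc
        p = model.predict_proba(X[[i, j]])
        full = np.zeros((2, K))
        full[:, model.named_steps["clf"].classes_.astype(int)] = p
        pairs[s] = (i, j)
        probas[s] = full
        for k in range(K):
            if full[0, k] > full[1, k]:
                wins[i, k] += 1.0
            elif full[0, k] < full[1, k]:
                wins[j, k] += 1.0
            else:
                wins[i, k] += 0.5
                wins[j, k] += 0.5

    return TournamentResult(
        object_ids=tuple(features.index),
        classes=classes,
        wins=wins,
        pairs=pairs,
        probas=probas,
    )


def _mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUC with ties counted half."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ranking_auc(
    result: TournamentResult, labels: pd.Series
) -> tuple[dict[str, float], float]:
    """One-vs-rest AUC of the tournament win scores, per class and averaged.

    Classes with no positive or no negative object are skipped with a
    warning; the mean covers the classes actually present.
    """
    labels = labels.loc[list(result.object_ids)]
    per_class: dict[str, float] = {}
    for k, cls in enumerate(result.classes):
        pos = (labels == cls).to_numpy()
        auc = _mann_whitney_auc(result.wins[:, k], pos)
        if np.isnan(auc):
            warnings.warn(f"class {cls!r} lacks positives or negatives; skipped")
            continue
        per_class[cls] = auc
    mean = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return per_class, mean


def _prediction_rows(
    result: TournamentResult, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten pair predictions: (object index, one-hot label, probability)."""
    labels = labels.loc[list(result.object_ids)]
    class_index = {c: k for k, c in enumerate(result.classes)}
    y_idx = labels.map(class_index).to_numpy()
    obj = result.pairs.reshape(-1)
    probs = result.probas.reshape(-1, len(result.classes))
    onehot = np.eye(len(result.classes))[y_idx[obj]]
    return obj, onehot, probs


def brier_and_r2(
    probas: np.ndarray,
    onehot: np.ndarray,
    class_freqs: np.ndarray,
) -> tuple[float, float, float]:
    """Multiclass Brier score, its non-informative benchmark, and scaled R².

    ``BS = mean_rows sum_k (p_k - y_k)^2``; the benchmark always predicts the
    supplied (training) class frequencies; ``R² = 1 - BS/BSmax``.
    """
    probas = np.asarray(probas, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    sums = probas.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise ValueError("predicted probabilities are not normalized")
    bs = float(((probas - onehot) ** 2).sum(axis=1).mean())
    bs_max = float(((class_freqs[None, :] - onehot) ** 2).sum(axis=1).mean())
    r2 = 1.0 - bs / bs_max if bs_max > 0 else float("nan")
    return bs, bs_max, float(r2)


def _metrics_from_result(
    result: TournamentResult, labels: pd.Series
) -> EvalMetrics:
    per_class, auc_mean = ranking_auc(result, labels)
    obj, onehot, probs = _prediction_rows(result, labels)
    labels_al = labels.loc[list(result.object_ids)]
    freqs = np.array([(labels_al == c).mean() for c in result.classes])
    bs, bs_max, r2 = brier_and_r2(probs, onehot, freqs)
    return EvalMetrics(per_class, auc_mean, bs, bs_max, r2)


def bbc_search(
    features: pd.DataFrame,
    labels: pd.Series,
    learner_spec: LearnerSpec,
    subset: set[str] | None = None,
    B: int = 500,
    seed: int = 0,
) -> BBCResult:
    """Random hyperparameter search with bootstrap bias correction.

    Each sampled configuration is evaluated by a full TLPO tournament. For
    every bootstrap replicate, objects are resampled with replacement; the
    configuration minimizing the in-bag Brier score (predictions weighted by
    object multiplicity) is scored on the out-of-bag objects. The
    bias-corrected metrics are the means over replicates; the naive winner
    (best overall Brier score, no correction) is reported alongside.
    Replicates with an empty out-of-bag set are redrawn.
    """
    configs = learner_spec.sample_configs()
    results = []
    rows = []
    for c_idx, config in enumerate(configs):
        res = run_tournament(
            features,
            labels,
            family=learner_spec.family,
            config=config,
            subset=subset,
            random_state=learner_spec.seed + c_idx,
        )
        metrics = _metrics_from_result(res, labels)
        results.append(res)
        rows.append(
            {
                "config_index": c_idx,
                **{f"hp_{k}": v for k, v in config.items()},
                "auc_mean": metrics.auc_mean,
                "bs": metrics.bs,
                "r2_scaled": metrics.r2_scaled,
            }
        )
    per_config = pd.DataFrame(rows)

    n = len(features)
    labels_al = labels.loc[features.index]
    classes = results[0].classes
    freqs = np.array([(labels_al == c).mean() for c in classes])
    # flattened prediction rows per config
    row_obj, onehot, _ = _prediction_rows(results[0], labels)
    row_bs = np.stack(
        [
            ((res.probas.reshape(-1, len(classes)) - onehot) ** 2).sum(axis=1)
            for res in results
        ]
    )  # (n_configs, n_rows)
    row_bsmax = ((freqs[None, :] - onehot) ** 2).sum(axis=1)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    boot_bs, boot_bsmax, boot_auc = [], [], []
    b = 0
    while b < B:
        counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
        oob = counts == 0
        if not oob.any():
            continue  # redraw: no out-of-bag objects
        b += 1
        w = counts[row_obj].astype(float)
        inbag_bs = (row_bs * w[None, :]).sum(axis=1) / w.sum()
        best = int(np.argmin(inbag_bs))
        oob_rows = oob[row_obj]
        boot_bs.append(row_bs[best, oob_rows].mean())
        boot_bsmax.append(row_bsmax[oob_rows].mean())
        # AUC of the winning config's win scores restricted to OOB objects
        aucs = []
        for k, cls in enumerate(classes):
            pos = (labels_al == cls).to_numpy()[oob]
            auc = _mann_whitney_auc(results[best].wins[oob, k], pos)
            if not np.isnan(auc):
                aucs.append(auc)
        boot_auc.append(np.mean(aucs) if aucs else np.nan)

    bs_c = float(np.mean(boot_bs))
    bsmax_c = float(np.mean(boot_bsmax))
    corrected = EvalMetrics(
        auc_per_class={},
        auc_mean=float(np.nanmean(boot_auc)),
        bs=bs_c,
        bs_max=bsmax_c,
        r2_scaled=1.0 - bs_c / bsmax_c,
    )
    naive_idx = int(per_config["bs"].idxmin())
    naive = _metrics_from_result(results[naive_idx], labels)
    return BBCResult(
        corrected=corrected,
        naive=naive,
        naive_config=configs[naive_idx],
        per_config=per_config,
    )


def evaluate_experiment(
    tables: dict[str, pd.DataFrame],
    labels: pd.Series,
    records_by_condition: dict[str, list],
    families: tuple[str, ...] = ("elastic_net_logistic", "random_forest"),
    c_thr: float = 0.9,
    configs: dict[str, dict] | None = None,
    random_state: int = 0,
) -> pd.DataFrame:
    """Condition x feature-subset x learner-family evaluation grid.

    One row per combination with the class-averaged AUC, Brier score and
    scaled R². Empty subsets produce a row of NaNs (with a warning).
    """
    rows = []
    for cond, table in tables.items():
        records = records_by_condition[cond]
        subsets = feature_subsets(records, c_thr=c_thr)
        for sub_name, sub in subsets.items():
            for family in families:
                if not sub:
                    warnings.warn(
                        f"subset {sub_name!r} empty for condition {cond!r}; "
                        "metrics are NaN"
                    )
                    rows.append(
                        {
                            "model": family,
                            "subset": sub_name,
                            "condition": cond,
                            "auc_mean": np.nan,
                            "bs": np.nan,
                            "bs_max": np.nan,
                            "r2_scaled": np.nan,
                        }
                    )
                    continue
                config = (configs or {}).get(family, DEFAULT_CONFIGS[family])
                res = run_tournament(
                    table,
                    labels,
                    family=family,
                    config=config,
                    subset=sub,
                    random_state=random_state,
                )
                m = _metrics_from_result(res, labels)
                rows.append(
                    {
                        "model": family,
                        "subset": sub_name,
                        "condition": cond,
                        "auc_mean": m.auc_mean,
                        "bs": m.bs,
                        "bs_max": m.bs_max,
                        "r2_scaled": m.r2_scaled,
                    }
                )
    return pd.DataFrame(rows)
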