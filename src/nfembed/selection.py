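"""Greedy incremental selection of feature groups and base learners.

Incremental feature selection (IFS) grows a set of named feature groups one
group per round: round 1 scores every single group by mean k-fold
cross-validated F1 (classification) or R^2 (regression) under an evaluation
model; each later round scores the retained set plus each unused group and
keeps the best extension, continuing until every group is included. The
final selection is the global maximum over all evaluated sets, ties broken
by fewer groups, then by evaluation order.

Incremental mutual information (IMI) applies the same greedy scheme to base
learners: candidates are fitted on the Training-60 partition, their outputs
on the Training-40 partition are scored by mutual information (MI, in nats)
against the truth — a plug-in estimate over the joint discrete distribution
of predicted labels for classification, a Kraskov-type k-nearest-neighbor
estimate over stacked real predictions for regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from sklearn.metrics import f1_score, r2_score
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import logger
from .features import FeatureGroupSet
from .stacking import LearnerSpec

DEFAULT_CLS_EVALUATOR = LearnerSpec("xgb")
DEFAULT_REG_EVALUATOR = LearnerSpec("xgbr")


@dataclass
class SelectionTrace:
    """Ordered record of greedy selection rounds.

    ``rounds[r]`` lists (candidate set, score) pairs evaluated in round r;
    ``retained[r]`` is the set kept after round r (extends the previous
    retained set by exactly one item). ``selection`` is the global optimum
    over every evaluated set.
    """

    kind: str  # "ifs" or "imi"
    metric: str
    seed: int
    rounds: list[list[tuple[tuple[str, ...], float]]] = field(default_factory=list)
    retained: list[tuple[str, ...]] = field(default_factory=list)
    selection: tuple[str, ...] = ()
    score: float = float("nan")

    @property
    def n_evaluated(self) -> int:
        return sum(len(r) for r in self.rounds)

    def all_evaluations(self) -> list[tuple[tuple[str, ...], float]]:
        return [item for rnd in self.rounds for item in rnd]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "metric": self.metric,
            "seed": self.seed,
            "rounds": [
                [{"set": list(s), "score": sc} for s, sc in rnd] for rnd in self.rounds
            ],
            "retained": [list(s) for s in self.retained],
            "selection": list(self.selection),
            "score": self.score,
        }

    def to_table(self) -> str:
        """Human-readable per-candidate score table."""
        lines = [f"{'Candidate set':60s}\t{self.metric}"]
        for rnd in self.rounds:
            for s, sc in rnd:
                marker = " *" if s == self.selection else ""
                lines.append(f"{', '.join(s):60s}\t{sc:.4f}{marker}")
        return "\n".join(lines) + "\n"


_TIE_TOL = 1e-9


def _finalize(trace: SelectionTrace) -> SelectionTrace:
    # global max; scores within _TIE_TOL tie -> fewer items, then evaluation order
    best_set, best_score = None, None
    for s, sc in trace.all_evaluations():
        if best_score is None or sc > best_score + _TIE_TOL:
            best_set, best_score = s, sc
        elif abs(sc - best_score) <= _TIE_TOL and len(s) < len(best_set):
            best_set, best_score = s, sc
    trace.selection, trace.score = best_set, best_score
    return trace


def cv_score(
    group_set: FeatureGroupSet,
    group_names,
    y: np.ndarray,
    evaluator: LearnerSpec,
    folds: int = 5,
    repeats: int = 1,
) -> float:
    """Mean k-fold CV score of an evaluator on the concatenated blocks.

    Folds are stratified for classification (scored by F1) and plain
    shuffled for regression (scored by R^2); fold assignment derives from
    the evaluator's seed, with ``repeats > 1`` averaging over reseeded runs.
    """
    X = group_set.design_matrix(tuple(group_names))
    y = np.asarray(y)
    task = evaluator.task
    scores = []
    for rep in range(repeats):
        seed = evaluator.seed + rep
        if task == "classification":
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            y_fit = y.astype(int)
        else:
            cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
            y_fit = y.astype(float)
        for tr, te in cv.split(X, y_fit):
            est = LearnerSpec(evaluator.family, evaluator.params, seed).build()
            est.fit(X[tr], y_fit[tr])
            pred = est.predict(X[te])
            if task == "classification":
                scores.append(f1_score(y_fit[te], pred, zero_division=0))
            else:
                scores.append(r2_score(y_fit[te], pred))
    return float(np.mean(scores))


def ifs_search(
    group_set: FeatureGroupSet,
    y: np.ndarray,
    evaluator: LearnerSpec | None = None,
    folds: int = 5,
    repeats: int = 1,
    group_names=None,
) -> SelectionTrace:
    """Greedy incremental feature-group selection, run to exhaustion.

    With G groups this evaluates G + (G-1) + ... + 1 candidate sets.
    """
    names = list(group_names) if group_names is not None else list(group_set.blocks)
    if len(names) < 2:
        raise ValueError("IFS needs at least 2 feature groups")
    evaluator = evaluator or (
        DEFAULT_CLS_EVALUATOR
        if np.array_equal(np.unique(y), np.unique(y).astype(int))
        and len(np.unique(y)) <= 2
        else DEFAULT_REG_EVALUATOR
    )
    metric = "F1" if evaluator.task == "classification" else "R2"
    trace = SelectionTrace(kind="ifs", metric=metric, seed=evaluator.seed)

    retained: tuple[str, ...] = ()
    remaining = list(names)
    while remaining:
        round_evals = []
        for g in remaining:
            cand = retained + (g,)
            try:
                score = cv_score(group_set, cand, y, evaluator, folds=folds, repeats=repeats)
            except Exception as exc:
                raise RuntimeError(f"evaluator failed on candidate set {cand}") from exc
            round_evals.append((cand, score))
        trace.rounds.append(round_evals)
        best_cand = max(round_evals, key=lambda t: t[1])[0]
        retained = best_cand
        trace.retained.append(retained)
        remaining = [g for g in remaining if g != best_cand[-1]]
    return _finalize(trace)


# ---------------------------------------------------------------------------
# Mutual information estimators
# ---------------------------------------------------------------------------


def discrete_mutual_information(pred, truth) -> float:
    """Plug-in MI (nats) on the joint empirical distribution of two
    discrete vectors. Symmetric; 0 for constant predictions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    n = len(pred)
    if n < 1:
        raise ValueError("empty input")
    mi = 0.0
    for pv in np.unique(pred):
        for tv in np.unique(truth):
            p_joint = np.sum((pred == pv) & (truth == tv)) / n
            if p_joint == 0:
                continue
            p_p = np.sum(pred == pv) / n
            p_t = np.sum(truth == tv) / n
            mi += p_joint * np.log(p_joint / (p_p * p_t))
    return max(float(mi), 0.0)


def _joint_code(columns: np.ndarray) -> np.ndarray:
    """Encode rows of a discrete matrix as single integers."""
    _, codes = np.unique(columns, axis=0, return_inverse=True)
    return codes


def continuous_mutual_information(
    pred, truth, k: int = 3, jitter_seed: int = 0
) -> float:
    """Kraskov-type kNN estimate of MI (nats) between real-valued variables.

    ``pred`` may be a vector or an (n, m) matrix (joint over m learners).
    A deterministic seeded jitter of 1e-10 breaks exact duplicates, which
    the kNN estimator cannot handle; negative estimates are clamped to 0.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
    truth = np.asarray(truth, dtype=float)[:, None]
    n = len(truth)
    if len(pred) != n:
        raise ValueError("pred and truth must have equal length")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples, got {n}")

    rng = np.random.default_rng(jitter_seed)
    x = pred + rng.normal(0, 1e-10, size=pred.shape)
    z = truth + rng.normal(0, 1e-10, size=truth.shape)

    joint = np.hstack([x, z])
    tree_joint = cKDTree(joint)
    # distance to the k-th neighbor (excluding self) in Chebyshev metric
    dists, _ = tree_joint.query(joint, k=k + 1, p=np.inf)
    radius = np.nextafter(dists[:, -1], 0)

    tree_x = cKDTree(x)
    tree_z = cKDTree(z)
    nx = np.array(
        [len(tree_x.query_ball_point(x[i], radius[i], p=np.inf)) - 1 for i in range(n)]
    )
    nz = np.array(
        [len(tree_z.query_ball_point(z[i], radius[i], p=np.inf)) - 1 for i in range(n)]
    )
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(nz + 1))
    return max(float(mi), 0.0)


def _joint_mi(outputs: list[np.ndarray], truth: np.ndarray, task: str) -> float:
    if task == "classification":
        joint = _joint_code(np.column_stack(outputs).astype(int))
        return discrete_mutual_information(joint, np.asarray(truth).astype(int))
    return continuous_mutual_information(np.column_stack(outputs), truth)


def imi_search(
    candidates: list[LearnerSpec],
    X60: np.ndarray,
    y60: np.ndarray,
    X40: np.ndarray,
    y40: np.ndarray,
    task: str,
) -> SelectionTrace:
    """Greedy incremental base-learner selection by mutual information.

    Each candidate is fitted once on the Training-60 partition; its outputs
    on the Training-40 partition (predicted labels for classification,
    predictions for regression) enter a joint MI objective against the
    Training-40 truth. Candidates that fail to fit are skipped with a
    warning. Ties break toward fewer learners, then evaluation order.
    """
    if not candidates:
        raise ValueError("no candidate learners")
    outputs: dict[str, np.ndarray] = {}
    names: list[str] = []
    for spec in candidates:
        try:
            model = spec.build()
            model.fit(X60, y60.astype(int) if task == "classification" else y60)
            out = model.predict(X40)
        except Exception as exc:  # noqa: BLE001 - candidate skipped per policy
            logger.warning("candidate %s failed to fit: %s", spec.family, exc)
            continue
        outputs[spec.family] = np.asarray(out)
        names.append(spec.family)
    if not names:
        raise ValueError("every candidate learner failed to fit")

    trace = SelectionTrace(kind="imi", metric="MI", seed=candidates[0].seed)
    retained: tuple[str, ...] = ()
    remaining = list(names)
    while remaining:
        round_evals = []
        for name in remaining:
            cand = retained + (name,)
            score = _joint_mi([outputs[c] for c in cand], y40, task)
            round_evals.append((cand, score))
        trace.rounds.append(round_evals)
        best_cand = max(round_evals, key=lambda t: t[1])[0]
        retained = best_cand
        trace.retained.append(retained)
        remaining = [c for c in remaining if c != best_cand[-1]]
    return _finalize(trace)
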