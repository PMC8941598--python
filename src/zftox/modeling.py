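"""Repeated double cross-validation (rdCV) random-forest dose-response models.

The variable-selection engine mirrors the MUVR recipe: repeated outer
cross-validation estimates fitness from out-of-fold predictions only, while
within each outer training partition an inner cross-validation drives recursive
elimination of the lowest-importance fraction of variables. The elected feature
set is the consensus of the per-segment selections at the fitness-optimal model
size. Significance is assessed by refitting the whole procedure on permuted
responses.

Five standard model designs are provided for the embryo study: a regression
over all doses (monotonic responses), a 7-group classification (nonmonotonic
responses), top-dose and lowest-dose versus control classifications, and an
edema versus non-edema classification within the top dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import FeatureTable, ROLE_DOSE, ROLE_NEG

MODEL_NAMES = ("AllRegress", "AllClass", "HighClass", "LowClass", "EdemaClass")


@dataclass(frozen=True)
class RdcvParams:
    """Tuning parameters of the rdCV engine."""

    n_repetitions: int = 10
    n_outer_folds: int = 6
    n_inner_folds: int | None = None  # default: n_outer_folds - 1
    elimination_ratio: float = 0.75  # fraction of variables kept per iteration
    model_size: str = "mid"  # min | mid | max
    fitness_tolerance: float = 0.05  # sizes within (1+tol)*best fitness are candidates
    min_features: int = 2  # elimination stops here (set = n features to disable)
    n_estimators: int = 100
    consensus: float = 0.5  # election: present in > consensus of segments
    importance: str = "mdi"  # mdi | permutation

    @property
    def inner_folds(self) -> int:
        return self.n_inner_folds if self.n_inner_folds is not None else self.n_outer_folds - 1


@dataclass
class ModelSpec:
    """One model design: sample selection, response, and rdCV settings."""

    name: str
    mode: str  # regression | classification
    seed: int
    rdcv: RdcvParams = field(default_factory=RdcvParams)
    n_permutations: int = 100
    # sample selection (used by build_model_suite)
    dose_groups: tuple[int, ...] | None = None  # None = all dosed groups + controls
    exclude_dead: bool = True
    exclude_sublethal: bool = False  # drop edema embryos (models over all doses)
    response: str = "dose_group"  # log10_dose | dose_group | edema

    def __post_init__(self) -> None:
        if self.mode not in ("regression", "classification"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass
class ModelResult:
    name: str
    mode: str
    elected_features: list[str]
    fitness: float  # misclassification rate (classification) or Q2 (regression)
    oof_predictions: pd.Series
    y: pd.Series
    n_samples: int
    discarded: bool = False
    permutation_p: float | None = None
    permutation_p_empirical: float | None = None
    n_permutations: int = 0
    error: str | None = None


@dataclass
class PermutationResult:
    observed_fitness: float
    permuted_fitness: np.ndarray
    p_normal: float | None
    p_empirical: float
    n_permutations: int


# ---------------------------------------------------------------------------
# core engine


def _make_rf(mode: str, n_estimators: int, seed: int):
    if mode == "classification":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    return RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def _inner_fitness(pred, truth, mode: str) -> float:
    if mode == "classification":
        return float(np.sum(pred != truth))
    resid = truth - pred
    return float(resid @ resid)


def _variable_importance(rf, Xva, yva, kind: str, seed: int) -> np.ndarray:
    if kind == "mdi":
        return rf.feature_importances_
    from sklearn.inspection import permutation_importance

    r = permutation_importance(rf, Xva, yva, n_repeats=5, random_state=seed, n_jobs=1)
    return r.importances_mean


def _recursive_elimination(
    X: np.ndarray, y: np.ndarray, mode: str, params: RdcvParams, rng: np.random.Generator
) -> np.ndarray:
    """Inner-CV recursive variable elimination on one outer training partition.

    Returns the indices (into X's columns) of the variables at the
    fitness-optimal model size chosen by the min/mid/max rule.
    """
    n, p = X.shape
    if p <= params.min_features:
        # nothing to eliminate and a single candidate size: no inner CV needed
        return np.arange(p)
    n_inner = min(params.inner_folds, n)
    seed = int(rng.integers(2**31 - 1))
    if mode == "classification":
        n_inner = min(n_inner, int(np.min(np.unique(y, return_counts=True)[1])))
        splitter = StratifiedKFold(n_splits=max(n_inner, 2), shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=max(n_inner, 2), shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y if mode == "classification" else None))

    variables = np.arange(p)
    history: list[tuple[np.ndarray, float]] = []
    while True:
        importance = np.zeros(len(variables))
        fit_sum = 0.0
        for tr, va in folds:
            rf = _make_rf(mode, params.n_estimators, int(rng.integers(2**31 - 1)))
            rf.fit(X[np.ix_(tr, variables)], y[tr])
            importance += _variable_importance(
                rf, X[np.ix_(va, variables)], y[va], params.importance,
                int(rng.integers(2**31 - 1)),
            )
            fit_sum += _inner_fitness(rf.predict(X[np.ix_(va, variables)]), y[va], mode)
        history.append((variables.copy(), fit_sum))
        if len(variables) <= params.min_features:
            break
        keep = max(params.min_features, math.floor(len(variables) * params.elimination_ratio))
        if keep >= len(variables):
            keep = len(variables) - 1
        order = np.argsort(-importance, kind="stable")[:keep]
        variables = np.sort(variables[order])

    fitness = np.array([f for _, f in history])
    sizes = np.array([len(v) for v, _ in history])
    best = fitness.min()
    # candidate sizes: inner fitness within the tolerance band around the best
    band = best * (1.0 + params.fitness_tolerance) + 1e-12
    cand = [i for i in range(len(history)) if fitness[i] <= band]
    n_min = min(sizes[i] for i in cand)
    n_max = max(sizes[i] for i in cand)
    if params.model_size == "min":
        target = n_min
    elif params.model_size == "max":
        target = n_max
    else:
        target = math.sqrt(n_min * n_max)
    # among candidate sizes, the one closest to the target (smaller on ties)
    cand.sort(key=lambda i: (abs(sizes[i] - target), sizes[i]))
    return history[cand[0]][0]


def rdcv_rf(X: pd.DataFrame, y, spec: ModelSpec) -> ModelResult:
    """Repeated double cross-validation random forest with variable election.

    X: samples x features; y: response (class labels or continuous).
    Fitness is computed exclusively from outer out-of-fold predictions,
    averaged over repetitions. Deterministic given ``spec.seed``.
    """
    params = spec.rdcv
    y = pd.Series(np.asarray(y), index=X.index)
    n, p = X.shape
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    if spec.mode == "classification":
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("classification requires >= 2 classes")
        if counts.min() < params.n_outer_folds:
            raise ValueError(
                f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples, "
                f"fewer than {params.n_outer_folds} outer folds"
            )
        if counts.min() < 6:
            warnings.warn("a class has fewer than 6 samples; fitness estimates are unstable")
    else:
        if n < 12:
            warnings.warn("fewer than 12 samples for regression; fitness estimates are unstable")
        classes = None

    rng = np.random.default_rng(spec.seed)
    Xm = X.to_numpy(float)
    ym = y.to_numpy()

    votes = np.zeros(p)
    n_segments = 0
    if spec.mode == "classification":
        proba_sum = np.zeros((n, len(classes)))
        class_pos = {c: i for i, c in enumerate(classes)}
    else:
        pred_sum = np.zeros(n)
        pred_count = np.zeros(n)

    for rep in range(params.n_repetitions):
        seed = int(rng.integers(2**31 - 1))
        if spec.mode == "classification":
            outer = StratifiedKFold(params.n_outer_folds, shuffle=True, random_state=seed)
            split = outer.split(Xm, ym)
        else:
            outer = KFold(params.n_outer_folds, shuffle=True, random_state=seed)
            split = outer.split(Xm)
        for tr, te in split:
            selected = _recursive_elimination(Xm[tr], ym[tr], spec.mode, params, rng)
            votes[selected] += 1
            n_segments += 1
            rf = _make_rf(spec.mode, params.n_estimators, int(rng.integers(2**31 - 1)))
            rf.fit(Xm[np.ix_(tr, selected)], ym[tr])
            if spec.mode == "classification":
                proba = rf.predict_proba(Xm[np.ix_(te, selected)])
                for local, c in enumerate(rf.classes_):
                    proba_sum[te, class_pos[c]] += proba[:, local]
            else:
                pred_sum[te] += rf.predict(Xm[np.ix_(te, selected)])
                pred_count[te] += 1

    elected = [X.columns[j] for j in range(p) if votes[j] / n_segments > params.consensus]

    if spec.mode == "classification":
        # consensus class across repetitions; ties broken toward the lowest rung
        best = np.zeros(n, dtype=int)
        for i in range(n):
            row = proba_sum[i]
            best[i] = int(np.flatnonzero(row == row.max())[0])
        oof = pd.Series([classes[b] for b in best], index=X.index)
        fitness = float(np.mean(oof.to_numpy() != ym))
    else:
        oof = pd.Series(pred_sum / pred_count, index=X.index)
        fitness = q2(oof.to_numpy(), ym)

    return ModelResult(
        name=spec.name,
        mode=spec.mode,
        elected_features=elected,
        fitness=fitness,
        oof_predictions=oof,
        y=y,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# fitness measures


def q2(y_pred, y_obs) -> float:
    """Predictive coefficient Q2 = 1 - PRESS/TSS from out-of-fold predictions."""
    y_pred = np.asarray(y_pred, float)
    y_obs = np.asarray(y_obs, float)
    if len(y_pred) != len(y_obs) or len(y_obs) < 2:
        raise ValueError("q2 requires equal-length arrays with >= 2 values")
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in observed response")
    press = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - press / tss


def misclassification_rates(pred_group, true_group, dose_ladder) -> tuple[float, float]:
    """Overall misclassification and the rate counting only errors beyond one
    order of magnitude on the 10x dose ladder (controls sit one rung below the
    lowest dose; adjacent rungs are 'within one order')."""
    ladder = [float(d) for d in dose_ladder]

    def rung(v) -> int:
        v = float(v)
        if v == 0:
            return -1  # control rung, one step below the lowest dose
        if v not in ladder:
            raise ValueError(f"group {v} is not on the dose ladder {ladder}")
        return ladder.index(v)

    pred = np.array([rung(v) for v in np.asarray(pred_group)])
    true = np.array([rung(v) for v in np.asarray(true_group)])
    overall = float(np.mean(pred != true))
    beyond = float(np.mean(np.abs(pred - true) > 1))
    return overall, beyond


def permutation_test(
    X: pd.DataFrame, y, spec: ModelSpec, n_perm: int = 100,
    observed: ModelResult | None = None,
) -> PermutationResult:
    """Refit the full rdCV procedure on permuted responses.

    Reports both a tail probability under a normal approximation to the
    permuted-fitness distribution and the empirical rank p = (r + 1)/(n + 1).
    Lower misclassification / higher Q2 count as better.
    """
    if observed is None:
        observed = rdcv_rf(X, y, spec)
    rng = np.random.default_rng(spec.seed + 104729)
    y = np.asarray(pd.Series(y))
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        pspec = replace(spec, seed=int(rng.integers(2**31 - 1)))
        permuted[k] = rdcv_rf(X, y_perm, pspec).fitness

    obs = observed.fitness
    if spec.mode == "classification":  # lower is better
        r = int(np.sum(permuted <= obs))
    else:  # higher Q2 is better
        r = int(np.sum(permuted >= obs))
    p_emp = (r + 1) / (n_perm + 1)

    p_norm: float | None
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations: reporting empirical p only")
        p_norm = None
    else:
        mu, sd = permuted.mean(), permuted.std(ddof=1)
        if sd == 0:
            p_norm = p_emp
        elif spec.mode == "classification":
            p_norm = float(stats.norm.cdf(obs, mu, sd))
        else:
            p_norm = float(stats.norm.sf(obs, mu, sd))
    return PermutationResult(obs, permuted, p_norm, p_emp, n_perm)


# ---------------------------------------------------------------------------
# model suite over a feature table


def default_model_specs(seed: int, rdcv: RdcvParams | None = None,
                        rdcv_small: RdcvParams | None = None) -> list[ModelSpec]:
    """The five standard embryo-study model designs.

    Models over all doses exclude embryos with lethal or sublethal endpoints;
    the edema model necessarily keeps edema embryos and runs with fewer outer
    folds (its smaller class has only a handful of members).
    """
    rdcv = rdcv or RdcvParams()
    rdcv_small = rdcv_small or replace(rdcv, n_outer_folds=4)
    return [
        ModelSpec("AllRegress", "regression", seed, rdcv=rdcv,
                  exclude_sublethal=True, response="log10_dose"),
        ModelSpec("AllClass", "classification", seed + 1, rdcv=rdcv,
                  exclude_sublethal=True, response="dose_group"),
        ModelSpec("HighClass", "classification", seed + 2, rdcv=rdcv,
                  dose_groups=(0, 6), response="dose_group"),
        ModelSpec("LowClass", "classification", seed + 3, rdcv=rdcv,
                  dose_groups=(0, 1), response="dose_group"),
        ModelSpec("EdemaClass", "classification", seed + 4, rdcv=rdcv_small,
                  dose_groups=(6,), response="edema"),
    ]


def select_model_samples(table: FeatureTable, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Apply a model's sample selector and exclusion rule; returns (X, y)."""
    meta = table.samples
    mask = meta["role"].isin((ROLE_DOSE, ROLE_NEG))
    if spec.dose_groups is not None:
        mask &= meta["dose_group"].isin(spec.dose_groups)
    if spec.exclude_dead:
        mask &= ~(meta["dead_120hpf"] == True)  # noqa: E712 (NA -> keep)
    if spec.exclude_sublethal:
        mask &= ~(meta["edema"] == True)  # noqa: E712
    chosen = meta.index[mask]
    if len(chosen) == 0:
        raise ValueError(f"model {spec.name!r}: sample selector yielded no samples")
    X = table.intensities[chosen].T
    sub = meta.loc[chosen]
    if spec.response == "log10_dose":
        doses = sub["nominal_dose"].to_numpy(float)
        lowest = np.nanmin(doses[doses > 0])
        y = np.where(doses > 0, np.log10(np.where(doses > 0, doses, 1.0)),
                     np.log10(lowest) - 1.0)  # controls one rung below the lowest dose
        y = pd.Series(y, index=chosen)
    elif spec.response == "dose_group":
        y = sub["dose_group"].astype(int)
    elif spec.response == "edema":
        y = (sub["edema"] == True).map({True: "edema", False: "non_edema"})  # noqa: E712
    else:
        raise ValueError(f"unknown response: {spec.response!r}")
    return X, y


def build_model_suite(
    table: FeatureTable, specs: list[ModelSpec] | None = None, seed: int = 0,
    min_elected: int = 5, n_permutations: int = 0,
) -> dict[str, ModelResult]:
    """Fit every model design; flag for discard those electing fewer than
    `min_elected` features. Errors in one model do not abort the others."""
    specs = specs or default_model_specs(seed)
    results: dict[str, ModelResult] = {}
    for spec in specs:
        try:
            X, y = select_model_samples(table, spec)
            res = rdcv_rf(X, y, spec)
            if n_permutations > 0:
                perm = permutation_test(X, y, spec, n_permutations, observed=res)
                res.permutation_p = perm.p_normal
                res.permutation_p_empirical = perm.p_empirical
                res.n_permutations = n_permutations
            res.discarded = len(res.elected_features) < min_elected
        except ValueError as exc:
            res = ModelResult(spec.name, spec.mode, [], float("nan"),
                              pd.Series(dtype=float), pd.Series(dtype=float), 0,
                              discarded=True, error=str(exc))
        results[spec.name] = res
    return results


def elected_union(results: dict[str, ModelResult]) -> list[str]:
    """Union of elected features across retained (non-discarded) models."""
    out: list[str] = []
    for res in results.values():
        if res.error is None and not res.discarded:
            out.extend(f for f in res.elected_features if f not in out)
    return sorted(out)


# ---------------------------------------------------------------------------
# dose-trend summarization


def classify_trend(group_means, fold_threshold: float = 1.5) -> str:
    """Label a dose-response profile of group means over an ascending ladder.

    Checks, in order: interior extremum (u_shape / inverted_u, both arms must
    exceed the fold threshold), a step confined to the top dose
    (high_dose_only), weak monotonicity with sufficient total fold
    (monotonic_up / monotonic_down), otherwise flat.
    """
    m = np.asarray(group_means, float)
    if len(m) < 3:
        raise ValueError("trend classification needs >= 3 dose groups")
    if np.any(m <= 0):
        raise ValueError("group means must be positive")
    thr = fold_threshold
    interior = np.arange(1, len(m) - 1)

    i_min = int(np.argmin(m))
    if i_min in interior and m[0] / m[i_min] >= thr and m[-1] / m[i_min] >= thr:
        return "u_shape"
    i_max = int(np.argmax(m))
    if i_max in interior and m[i_max] / m[0] >= thr and m[i_max] / m[-1] >= thr:
        return "inverted_u"

    body = m[:-1]
    if body.max() / body.min() < thr:
        top_fold = max(m[-1] / body.mean(), body.mean() / m[-1])
        if top_fold >= thr:
            return "high_dose_only"
    diffs = np.diff(m)
    if np.all(diffs >= 0) and m[-1] / m[0] >= thr:
        return "monotonic_up"
    if np.all(diffs <= 0) and m[0] / m[-1] >= thr:
        return "monotonic_down"
    return "flat"


def rescale_rows(matrix) -> pd.DataFrame | np.ndarray:
    """Rescale each row of a group-mean matrix to its own maximum (heatmap
    convention): values in [0, 1], every row attains 1."""
    is_df = isinstance(matrix, pd.DataFrame)
    m = matrix.to_numpy(float) if is_df else np.asarray(matrix, float)
    mx = m.max(axis=1)
    if np.any(mx <= 0):
        idx = np.flatnonzero(mx <= 0)
        names = [str(matrix.index[i]) for i in idx] if is_df else [str(i) for i in idx]
        raise ValueError(f"rows without a positive maximum: {names}")
    out = m / mx[:, None]
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def group_mean_matrix(table: FeatureTable, feature_ids: list[str]) -> pd.DataFrame:
    """Mean intensity per dose group (columns ascending by dose, controls first)
    for the given features; rows ready for `rescale_rows`."""
    meta = table.samples
    mask = meta["role"].isin((ROLE_DOSE, ROLE_NEG))
    groups = sorted(meta.loc[mask, "dose_group"].unique())
    cols = {}
    for g in groups:
        sel = meta.index[mask & (meta["dose_group"] == g)]
        cols[g] = table.intensities.loc[feature_ids, sel].mean(axis=1)
    return pd.DataFrame(cols)
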