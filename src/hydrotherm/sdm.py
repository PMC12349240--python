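"""Presence/pseudo-absence ensemble species distribution modelling.

The procedure: screen environmental variables for collinearity (pairwise
Pearson |r| < 0.7, then VIF < 5), draw uniform-random pseudo-absence sets
outside presence cells, fit every (learner × pseudo-absence set × run)
combination on stratified 80/20 splits, score each on its held-out 20% by
AUC and the True Skill Statistic (max over thresholds of sensitivity +
specificity − 1), and average the members with TSS above a retention cutoff,
weighted by their TSS, into a consensus suitability surface that can be
projected onto scenario climate stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .grids import Raster


# ---------------------------------------------------------------------------
# Environmental stacks


@dataclass
class EnvStack:
    """Aligned environmental layers keyed by name; categorical layers flagged."""

    layers: dict[str, Raster]
    categorical: frozenset = frozenset()

    def __post_init__(self) -> None:
        specs = {layer.spec for layer in self.layers.values()}
        if len(specs) > 1:
            raise ValueError("environment layers do not share a grid")
        self.categorical = frozenset(self.categorical)

    @property
    def spec(self):
        return next(iter(self.layers.values())).spec

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.spec.shape, dtype=bool)
        for layer in self.layers.values():
            m &= layer.mask
        return m

    def table_at_cells(self, rows, cols, variables=None) -> pd.DataFrame:
        variables = variables or self.names
        return pd.DataFrame(
            {v: self.layers[v].values[rows, cols] for v in variables}
        )

    def table_at_points(self, lon, lat, variables=None) -> pd.DataFrame:
        rows, cols = self.spec.cell_of(np.asarray(lon, float), np.asarray(lat, float))
        return self.table_at_cells(rows, cols, variables)


# ---------------------------------------------------------------------------
# Variable screening


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF per column: 1/(1−R²) of each column regressed on the others."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def screen_variables(stack: EnvStack, lon, lat, r_max: float = 0.7,
                     vif_max: float = 5.0):
    """Collinearity screening at sample locations; returns (kept, decision log).

    Pass 1 greedily resolves every pair with |Pearson r| ≥ r_max by dropping
    the pair member with the larger mean |r| against the remaining variables;
    pass 2 iteratively drops the largest-VIF variable until all VIF < vif_max.
    Categorical variables bypass both passes and are always retained.
    """
    numeric = [v for v in stack.names if v not in stack.categorical]
    if len(numeric) < 2:
        raise ValueError("need at least 2 numeric variables to screen")
    tab = stack.table_at_points(lon, lat, numeric).dropna()
    if len(tab) < 30:
        raise ValueError("need at least 30 on-grid samples for screening")
    log: list[dict] = []
    kept = list(numeric)

    while len(kept) > 1:
        r = tab[kept].corr().to_numpy()
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] < r_max:
            break
        mean_r = absr.mean(axis=1)
        drop = kept[i] if mean_r[i] >= mean_r[j] else kept[j]
        log.append({"stage": "pearson", "dropped": drop,
                    "pair": (kept[i], kept[j]), "abs_r": float(absr[i, j])})
        kept.remove(drop)

    while len(kept) > 1:
        vifs = _vif(tab[kept].to_numpy(float))
        worst = int(np.argmax(vifs))
        if vifs[worst] < vif_max:
            break
        log.append({"stage": "vif", "dropped": kept[worst],
                    "vif": float(vifs[worst])})
        kept.pop(worst)

    selected = kept + [v for v in stack.names if v in stack.categorical]
    if len(selected) < 2:
        log.append({"stage": "warning",
                    "message": "fewer than 2 variables survived screening"})
    return selected, log


# ---------------------------------------------------------------------------
# Pseudo-absences and datasets


def sample_pseudo_absences(stack: EnvStack, presence_lon, presence_lat,
                           n_per_set: int = 8000, n_sets: int = 2,
                           seed: int = 0):
    """Uniform-random background cells outside presence cells.

    Returns (sets, warnings): each set is a DataFrame of cell-center lon/lat
    drawn without replacement from unmasked non-presence cells, with an
    independent RNG substream per set id.
    """
    valid = stack.valid_mask
    prow, pcol = stack.spec.cell_of(np.asarray(presence_lon, float),
                                    np.asarray(presence_lat, float))
    presence_cells = np.zeros(stack.spec.shape, dtype=bool)
    presence_cells[prow, pcol] = True
    eligible = np.flatnonzero(valid & ~presence_cells)
    if eligible.size == 0:
        raise ValueError("no eligible cells for pseudo-absence sampling")
    warnings = []
    n_take = min(n_per_set, eligible.size)
    if n_take < n_per_set:
        warnings.append(
            f"n_per_set reduced from {n_per_set} to {n_take} (eligible cells)"
        )
    lon_c = stack.spec.lon_centers()
    lat_c = stack.spec.lat_centers()
    sets = {}
    for k in range(n_sets):
        rng = np.random.default_rng([seed, 1000 + k])
        cells = rng.choice(eligible, size=n_take, replace=False)
        row, col = np.unravel_index(cells, stack.spec.shape)
        sets[k] = pd.DataFrame({"lon": lon_c[col], "lat": lat_c[row]})
    return sets, warnings


def build_design(stack: EnvStack, variables, presence_lon, presence_lat,
                 absence_lon, absence_lat):
    """Design matrix + labels; drops rows with missing environment values."""
    cat_vars = [v for v in variables if v in stack.categorical]
    Xp = stack.table_at_points(presence_lon, presence_lat, variables)
    Xa = stack.table_at_points(absence_lon, absence_lat, variables)
    X = pd.concat([Xp, Xa], ignore_index=True)
    y = np.r_[np.ones(len(Xp)), np.zeros(len(Xa))]
    ok = X.notna().all(axis=1).to_numpy()
    X, y = X.loc[ok].reset_index(drop=True), y[ok]
    if cat_vars:
        X = pd.get_dummies(X, columns=cat_vars, dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# Evaluation: AUC and the True Skill Statistic


@dataclass
class ModelEvaluation:
    auc: float
    tss: float
    optimal_threshold: float


def evaluate_predictions(scores, labels) -> ModelEvaluation:
    """AUC (rank statistic, ties half-credit) and threshold-maximized TSS.

    The classification rule is score ≥ threshold; thresholds range over the
    unique scores, and the smallest threshold attaining the maximal TSS is
    reported as optimal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for evaluation")

    # AUC via midranks (Mann–Whitney with half-credit for ties)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # TSS: sweep thresholds descending; at threshold t, predict positive iff
    # score >= t.  Walk unique scores from high to low, accumulating counts.
    desc = np.argsort(-scores, kind="mergesort")
    s_desc = scores[desc]
    l_desc = labels[desc]
    uniq_mask = np.r_[True, s_desc[1:] != s_desc[:-1]]
    tp = np.cumsum(l_desc)
    fp = np.cumsum(1 - l_desc)
    # counts at the *end* of each tie group = confusion for threshold s
    group_end = np.r_[np.flatnonzero(uniq_mask)[1:] - 1, scores.size - 1]
    sens = tp[group_end] / n_pos
    spec = 1.0 - fp[group_end] / n_neg
    tss_all = sens + spec - 1.0
    best = float(tss_all.max())
    thresholds = s_desc[uniq_mask]
    candidates = thresholds[np.isclose(tss_all, best, rtol=0, atol=1e-15)]
    return ModelEvaluation(auc=float(auc), tss=best,
                           optimal_threshold=float(candidates.min()))


# ---------------------------------------------------------------------------
# Learner registry


class MaxentFeatures(BaseEstimator, TransformerMixin):
    """Quadratic + hinge expansion for the MaxEnt-style learner.

    Hinge knots are the training-set quartiles, frozen at fit time so that
    projection onto scenario stacks uses the same basis.
    """

    def fit(self, X, y=None):
        self.knots_ = np.quantile(np.asarray(X, dtype=float),
                                  [0.25, 0.5, 0.75], axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X, X**2] + [np.maximum(X - k, 0.0) for k in self.knots_]
        return np.hstack(feats)


def _make_glm(seed: int):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(max_iter=1000, random_state=seed)),
    ])


def _make_rf(seed: int):
    return RandomForestClassifier(random_state=seed)


def _make_gbm(seed: int):
    return GradientBoostingClassifier(random_state=seed)


def _make_maxent_like(seed: int):
    return Pipeline([
        ("features", MaxentFeatures()),
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(penalty="l1", C=1.0, solver="liblinear",
                                   max_iter=2000, random_state=seed)),
    ])


def _make_xgb(seed: int):
    from xgboost import XGBClassifier  # optional dependency

    return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)


LEARNER_REGISTRY = {
    "glm": _make_glm,
    "rf": _make_rf,
    "gbm": _make_gbm,
    "maxent_like": _make_maxent_like,
    "xgb": _make_xgb,
}


def _substream_int(*keys) -> int:
    """Deterministic 31-bit integer seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass
class FittedModel:
    learner_id: str
    pa_set: int
    run: int
    evaluation: ModelEvaluation
    estimator: object
    feature_names: list[str] = field(default_factory=list)

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(X[self.feature_names])[:, 1]


def fit_single_model(learner_id: str, X: pd.DataFrame, y: np.ndarray,
                     pa_set: int = 0, run: int = 0, seed: int = 0,
                     test_size: float = 0.2) -> FittedModel:
    """Train one learner on a stratified 80/20 split; score the held-out 20%."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    split_seed = _substream_int(seed, 17, pa_set, run)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=split_seed
    )
    est = LEARNER_REGISTRY[learner_id](_substream_int(seed, 29, pa_set, run))
    est.fit(Xtr, ytr)
    scores = est.predict_proba(Xte)[:, 1]
    return FittedModel(
        learner_id=learner_id, pa_set=pa_set, run=run,
        evaluation=evaluate_predictions(scores, yte),
        estimator=est, feature_names=list(X.columns),
    )


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsemblePrediction:
    members: list[FittedModel]
    weights: np.ndarray
    tss_min: float

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for w, m in zip(self.weights, self.members):
            out += w * m.predict_scores(X)
        return out


def build_ensemble(models, tss_min: float = 0.55) -> EnsemblePrediction:
    """TSS-weighted mean of members with held-out TSS above the cutoff."""
    retained = [m for m in models if m.evaluation.tss > tss_min]
    if not retained:
        best = max((m.evaluation.tss for m in models), default=float("nan"))
        raise ValueError(
            f"no model exceeds tss_min={tss_min} (best observed TSS {best:.3f})"
        )
    w = np.array([m.evaluation.tss for m in retained], dtype=float)
    return EnsemblePrediction(members=retained, weights=w / w.sum(),
                              tss_min=tss_min)


def project(ensemble: EnsemblePrediction, stack: EnvStack,
            categorical_levels: dict | None = None) -> Raster:
    """Consensus suitability on a scenario stack, member weights frozen.

    ``categorical_levels`` maps a categorical variable to the level columns
    produced at training time, so scenario one-hot encodings align.
    """
    base_vars = []
    for m in ensemble.members:
        for v in m.feature_names:
            if v not in base_vars:
                base_vars.append(v)
    _ = categorical_levels
    missing = {
        v for v in base_vars
        if v not in stack.names
        and not any(v.startswith(c + "_") for c in stack.categorical)
    }
    if missing:
        raise ValueError(f"scenario stack is missing variables: {sorted(missing)}")
    valid = stack.valid_mask
    rows, cols = np.nonzero(valid)
    cat_vars = [v for v in stack.names if v in stack.categorical]
    tab = stack.table_at_cells(rows, cols)
    if cat_vars:
        tab = pd.get_dummies(tab, columns=cat_vars, dtype=float)
    for v in base_vars:  # levels absent in the scenario become zero columns
        if v not in tab.columns:
            tab[v] = 0.0
    scores = ensemble.predict_scores(tab)
    vals = np.full(stack.spec.shape, np.nan)
    vals[rows, cols] = scores
    return Raster(stack.spec, vals, name="suitability")


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class SdmConfig:
    learners: tuple = ("glm", "rf", "gbm")
    n_runs: int = 10
    n_pa_sets: int = 2
    n_pa_per_set: int = 8000
    tss_min: float = 0.55
    r_max: float = 0.7
    vif_max: float = 5.0
    seed: int = 0


@dataclass
class SdmResult:
    selected_variables: list[str]
    screening_log: list[dict]
    models: list[FittedModel]
    ensemble: EnsemblePrediction
    suitability: Raster
    scenario_suitability: dict[str, Raster]
    pooled_evaluation: ModelEvaluation
    manifest: dict


def run_sdm_pipeline(stack: EnvStack, presence_lon, presence_lat,
                     config: SdmConfig | None = None,
                     scenarios: dict[str, EnvStack] | None = None) -> SdmResult:
    """Screen → pseudo-absences → (learner × PA set × run) fits → ensemble.

    The consensus evaluation pools every retained member's held-out
    predictions. Each stage draws from a named substream of config.seed and
    every decision lands in the returned manifest.
    """
    cfg = config or SdmConfig()
    selected, log = screen_variables(stack, presence_lon, presence_lat,
                                     cfg.r_max, cfg.vif_max)
    pa_sets, pa_warnings = sample_pseudo_absences(
        stack, presence_lon, presence_lat,
        n_per_set=cfg.n_pa_per_set, n_sets=cfg.n_pa_sets, seed=cfg.seed,
    )
    models: list[FittedModel] = []
    designs = {}
    for k, pa in pa_sets.items():
        designs[k] = build_design(stack, selected, presence_lon, presence_lat,
                                  pa["lon"], pa["lat"])
    for learner in cfg.learners:
        for k in pa_sets:
            X, y = designs[k]
            for run in range(1, cfg.n_runs + 1):
                models.append(
                    fit_single_model(learner, X, y, pa_set=k, run=run,
                                     seed=cfg.seed)
                )
    ensemble = build_ensemble(models, cfg.tss_min)

    # pooled held-out evaluation of the consensus: re-derive each member's
    # held-out rows (same substream seeds) and score the ensemble on them
    pooled_scores, pooled_labels = [], []
    for m in ensemble.members:
        X, y = designs[m.pa_set]
        split_seed = _substream_int(cfg.seed, 17, m.pa_set, m.run)
        _, Xte, _, yte = train_test_split(
            X, y, test_size=0.2, stratify=y, random_state=split_seed
        )
        pooled_scores.append(ensemble.predict_scores(Xte))
        pooled_labels.append(yte)
    pooled_eval = evaluate_predictions(np.concatenate(pooled_scores),
                                       np.concatenate(pooled_labels))

    suitability = project(ensemble, stack)
    scenario_maps = {
        name: project(ensemble, sstack)
        for name, sstack in (scenarios or {}).items()
    }
    manifest = {
        "config": {
            "learners": list(cfg.learners), "n_runs": cfg.n_runs,
            "n_pa_sets": cfg.n_pa_sets, "n_pa_per_set": cfg.n_pa_per_set,
            "tss_min": cfg.tss_min, "r_max": cfg.r_max, "vif_max": cfg.vif_max,
            "seed": cfg.seed,
        },
        "selected_variables": selected,
        "screening_log": log,
        "pa_warnings": pa_warnings,
        "models": [
            {"learner": m.learner_id, "pa_set": m.pa_set, "run": m.run,
             "auc": m.evaluation.auc, "tss": m.evaluation.tss,
             "threshold": m.evaluation.optimal_threshold,
             "retained": m.evaluation.tss > cfg.tss_min}
            for m in models
        ],
        "ensemble": {
            "n_members": len(ensemble.members),
            "weights": ensemble.weights.tolist(),
            "pooled_auc": pooled_eval.auc,
            "pooled_tss": pooled_eval.tss,
        },
    }
    return SdmResult(
        selected_variables=selected, screening_log=log, models=models,
        ensemble=ensemble, suitability=suitability,
        scenario_suitability=scenario_maps, pooled_evaluation=pooled_eval,
        manifest=manifest,
    )
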