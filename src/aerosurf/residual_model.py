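"""IDW-residualized boosted trees with a log-cosh objective.

The dependent variable handed to XGBoost is the observation minus the
same-day IDW interpolation; the IDW is added back to the ensemble output
at prediction time.  Training trees on the residual partly smooths the
otherwise piecewise-constant tree predictions, and the IDW baseline is
still available to the trees as one of the 14 predictors.

The log-cosh loss L(r) = log cosh r behaves like r^2/2 near zero and like
|r| - log 2 far from zero, so it approximates absolute loss while staying
twice differentiable: gradient tanh(r), hessian 1 - tanh^2(r).

Hyperparameters (number of trees, max depth, learning rate eta, ridge
penalty lambda) are drawn from a maximin Latin-hypercube sample of their
domains and selected by twofold station-wise cross-validation scored with
mean absolute error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from aerosurf.spatial_features import FEATURE_COLUMNS, idw_interpolate

N_TREES_CHOICES = (10, 25, 50, 100)
MAX_DEPTH_CHOICES = (3, 6, 9)
ETA_RANGE = (0.01, 0.5)
LAM_RANGE = (2.0**-10, 2.0**10)

#: Tuned values reported for the full-scale study, kept as sensible defaults.
DEFAULT_HP_MEAN = None  # set below
DEFAULT_HP_MAX = None


@dataclass(frozen=True)
class Hyperparameters:
    """One point in the tuning space."""

    n_trees: int
    max_depth: int
    eta: float
    lam: float

    def validate(self, allow_zero_trees: bool = False) -> None:
        if self.n_trees == 0 and allow_zero_trees:
            pass
        elif self.n_trees not in N_TREES_CHOICES:
            raise ValueError(f"n_trees {self.n_trees} not in {N_TREES_CHOICES}")
        if self.max_depth not in MAX_DEPTH_CHOICES:
            raise ValueError(f"max_depth {self.max_depth} not in {MAX_DEPTH_CHOICES}")
        if not ETA_RANGE[0] <= self.eta <= ETA_RANGE[1]:
            raise ValueError(f"eta {self.eta} outside {ETA_RANGE}")
        if not LAM_RANGE[0] <= self.lam <= LAM_RANGE[1]:
            raise ValueError(f"lam {self.lam} outside {LAM_RANGE}")


DEFAULT_HP_MEAN = Hyperparameters(n_trees=10, max_depth=3, eta=0.047, lam=10.0)
DEFAULT_HP_MAX = Hyperparameters(n_trees=25, max_depth=9, eta=0.073, lam=260.0)


def logcosh_objective(residuals: np.ndarray):
    """Gradient and hessian of log cosh at predicted-minus-true residuals.

    tanh is bounded, so both outputs are finite for arbitrarily large
    residuals (no exp overflow).
    """
    r = np.asarray(residuals, float)
    if not np.isfinite(r).all():
        raise ValueError("non-finite residuals")
    t = np.tanh(r)
    return t, 1.0 - t * t


def logcosh_loss(residuals: np.ndarray) -> np.ndarray:
    """Numerically stable log cosh r = |r| + log1p(exp(-2|r|)) - log 2."""
    a = np.abs(np.asarray(residuals, float))
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


# ---------------------------------------------------------------------------
# hyperparameter design

def latin_hypercube_unit(n: int, d: int, seed: int, n_candidates: int = 50) -> np.ndarray:
    """Maximin Latin-hypercube sample on the d-dimensional unit cube.

    Draws ``n_candidates`` scrambled Latin-hypercube designs and keeps the
    one with the greatest minimum pairwise Euclidean distance; every
    candidate already stratifies each axis into n bins hit exactly once.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    sampler = qmc.LatinHypercube(d=d, seed=np.random.default_rng(seed))
    best, best_score = None, -np.inf
    for _ in range(n_candidates):
        design = sampler.random(n)
        score = pdist(design).min()
        if score > best_score:
            best, best_score = design, score
    return best


def _map_unit_to_domain(u: np.ndarray) -> list:
    """Map unit-cube coordinates to hyperparameter domains.

    Discrete axes by equal-width binning; eta and lambda on log scale.
    """
    out = []
    log_eta_lo, log_eta_hi = np.log(ETA_RANGE)
    for row in u:
        n_trees = N_TREES_CHOICES[min(int(row[0] * len(N_TREES_CHOICES)),
                                      len(N_TREES_CHOICES) - 1)]
        depth = MAX_DEPTH_CHOICES[min(int(row[1] * len(MAX_DEPTH_CHOICES)),
                                      len(MAX_DEPTH_CHOICES) - 1)]
        eta = float(np.exp(log_eta_lo + row[2] * (log_eta_hi - log_eta_lo)))
        lam = float(2.0 ** (-10.0 + row[3] * 20.0))
        out.append(Hyperparameters(n_trees=n_trees, max_depth=depth, eta=eta, lam=lam))
    return out


def sample_hyperparameters(n: int = 25, seed: int = 0) -> list:
    """Maximin Latin-hypercube sample of ``n`` hyperparameter vectors."""
    unit = latin_hypercube_unit(n, d=4, seed=seed)
    hps = _map_unit_to_domain(unit)
    for hp in hps:
        hp.validate()
    return hps


# ---------------------------------------------------------------------------
# fitting and prediction

@dataclass
class FittedExposureModel:
    """Trained residual ensemble plus its IDW contract and column order."""

    target_kind: str
    hp: Hyperparameters
    booster: xgb.Booster
    columns: tuple
    n_rows: int
    seed: int

    def save(self, model_path: str, sidecar_path: str | None = None) -> None:
        self.booster.save_model(model_path)
        sidecar = sidecar_path or model_path + ".json"
        meta = {
            "target_kind": self.target_kind,
            "hyperparameters": asdict(self.hp),
            "columns": list(self.columns),
            "n_rows": self.n_rows,
            "seed": self.seed,
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2)


def _xgb_objective(predt: np.ndarray, dtrain: xgb.DMatrix):
    return logcosh_objective(predt - dtrain.get_label())


def _matrix(features: pd.DataFrame, columns) -> xgb.DMatrix:
    X = features.loc[:, list(columns)].to_numpy(float)
    return xgb.DMatrix(X, missing=np.nan, feature_names=list(columns), nthread=1)


def fit(
    features: pd.DataFrame,
    targets: np.ndarray,
    hp: Hyperparameters,
    seed: int = 0,
    target_kind: str | None = None,
    allow_zero_trees: bool = False,
) -> FittedExposureModel:
    """Train the residual ensemble on (target - idw_baseline).

    The trees minimize the log-cosh objective with ridge penalty lambda,
    learning rate eta, ``n_trees`` boosting rounds and the given depth,
    single-threaded with exact splits for bit reproducibility.  The base
    score is pinned at 0 because the target is already a residual.
    """
    hp.validate(allow_zero_trees=allow_zero_trees)
    targets = np.asarray(targets, float)
    if len(features) == 0:
        raise ValueError("empty training set")
    if len(targets) != len(features):
        raise ValueError("targets and features length mismatch")
    if not np.isfinite(targets).all():
        raise ValueError("non-finite target")
    idw = features["idw_baseline"].to_numpy(float)
    if not np.isfinite(idw).all():
        raise ValueError("non-finite idw_baseline in training features")
    if target_kind is None:
        target_kind = str(features["target_kind"].iloc[0]) if "target_kind" in features else "daily_mean"

    dtrain = _matrix(features, FEATURE_COLUMNS)
    dtrain.set_label(targets - idw)
    params = {
        "max_depth": hp.max_depth,
        "eta": hp.eta,
        "lambda": hp.lam,
        "base_score": 0.0,
        "tree_method": "exact",
        "nthread": 1,
        "seed": seed,
        "disable_default_eval_metric": 1,
    }
    booster = xgb.train(
        params, dtrain, num_boost_round=hp.n_trees, obj=_xgb_objective,
        verbose_eval=False,
    )
    return FittedExposureModel(
        target_kind=target_kind, hp=hp, booster=booster,
        columns=tuple(FEATURE_COLUMNS), n_rows=len(features), seed=seed,
    )


def ensemble_output(model: FittedExposureModel, features: pd.DataFrame) -> np.ndarray:
    """Raw residual-ensemble output, without the IDW baseline added back."""
    missing = [c for c in model.columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks contracted columns: {missing}")
    return model.booster.predict(_matrix(features, model.columns))


def predict(model: FittedExposureModel, features: pd.DataFrame) -> np.ndarray:
    """Prediction = idw_baseline + residual-ensemble output, per row."""
    out = ensemble_output(model, features)
    return features["idw_baseline"].to_numpy(float) + out


# ---------------------------------------------------------------------------
# tuning

def _recompute_idw(
    features: pd.DataFrame,
    source_features: pd.DataFrame,
    source_values: np.ndarray,
    exclude_own: bool,
    exponent: float = 2.0,
) -> np.ndarray:
    """Rebuild idw_baseline of ``features`` from a restricted source set.

    Sources are the station-day rows of ``source_features`` with observed
    ``source_values``; station coordinates come from the feature rows
    themselves, so tuning needs no access to the original fixture.
    """
    idw = np.full(len(features), np.nan)
    f = features.reset_index(drop=True)
    src = source_features.reset_index(drop=True)
    by_date = {d: g for d, g in src.groupby("date").groups.items()}
    sxy_all = src[["x", "y"]].to_numpy(float)
    sid_all = src["unit_id"].to_numpy()
    txy = f[["x", "y"]].to_numpy(float)
    tid = f["unit_id"].to_numpy()
    for date, rows in f.groupby("date").groups.items():
        if date not in by_date:
            continue
        srows = np.asarray(by_date[date])
        sxy, sval, sid = sxy_all[srows], source_values[srows], sid_all[srows]
        rows = np.asarray(rows)
        if exclude_own:
            for r in rows:
                keep = sid != tid[r]
                if keep.any():
                    idw[r] = idw_interpolate(txy[r : r + 1], sxy[keep], sval[keep], exponent)[0]
        else:
            idw[rows] = idw_interpolate(txy[rows], sxy, sval, exponent)
    return idw


def tune(
    features: pd.DataFrame,
    targets: np.ndarray,
    station_ids: np.ndarray,
    candidates: list,
    seed: int = 0,
) -> Hyperparameters:
    """Select a hyperparameter vector by twofold station-wise CV under MAE.

    Stations are split at random (under ``seed``) into two folds.  Each
    candidate is fit on one fold's station rows and scored on the other,
    in both directions; within each direction the IDW baselines of both
    training and scored rows are recomputed from the training fold's
    stations only (the scored fold's own observations never leak into the
    baseline).  Training rows additionally exclude their own station,
    except in the degenerate single-station fold where the station's own
    observation is the only source (its residuals are then exactly zero
    and every candidate scores as the bare baseline).  The candidate with
    the smallest pooled MAE wins; ties go to the earlier candidate.
    """
    if not candidates:
        raise ValueError("no candidates")
    targets = np.asarray(targets, float)
    station_ids = np.asarray(station_ids)
    stations = np.unique(station_ids)
    if len(stations) < 2:
        raise ValueError("tuning needs at least 2 distinct stations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(stations)
    half = len(perm) // 2
    fold_a, fold_b = set(perm[:half].tolist()), set(perm[half:].tolist())
    if fold_a & fold_b:
        raise ValueError("a station appears in both folds")

    f = features.reset_index(drop=True)
    directions = []
    for train_fold, test_fold in ((fold_a, fold_b), (fold_b, fold_a)):
        tr = np.isin(station_ids, list(train_fold))
        te = ~tr
        f_tr = f[tr].reset_index(drop=True).copy()
        f_te = f[te].reset_index(drop=True).copy()
        y_tr, y_te = targets[tr], targets[te]
        # Baselines from the training fold's stations only.
        f_tr["idw_baseline"] = _recompute_idw(
            f_tr, f_tr, y_tr, exclude_own=len(train_fold) > 1
        )
        f_te["idw_baseline"] = _recompute_idw(f_te, f_tr, y_tr, exclude_own=False)
        ok_tr = f_tr["idw_baseline"].notna().to_numpy()
        ok_te = f_te["idw_baseline"].notna().to_numpy()
        directions.append(
            (f_tr[ok_tr].reset_index(drop=True), y_tr[ok_tr],
             f_te[ok_te].reset_index(drop=True), y_te[ok_te])
        )

    best_hp, best_mae = None, np.inf
    for hp in candidates:
        errors = []
        for f_tr, y_tr, f_te, y_te in directions:
            model = fit(f_tr, y_tr, hp, seed=seed, allow_zero_trees=True)
            errors.append(np.abs(predict(model, f_te) - y_te))
        mae = float(np.mean(np.concatenate(errors)))
        if mae < best_mae:
            best_hp, best_mae = hp, mae
    return best_hp
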