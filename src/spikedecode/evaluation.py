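"""Scoring, cross-validation, uncertainty and hyperparameter search.

The evaluation protocol is built around three rules:

1. **Score on held-out data.**  The metric is the fraction of variance
   accounted for, ``R^2 = 1 - SS_res / SS_tot`` (averaged over output
   dimensions), which can be negative on a test set.
2. **Rotate contiguous splits.**  J-fold cross-validation splits the
   recording into a training set, a *contiguous* validation set and a
   *contiguous* test set per fold (80/10/10 for the canonical J = 10); the
   J test blocks tile the recording exactly once.  Hyperparameters are
   chosen by validation-set R² only; the test set is touched exactly once
   per fold, after selection.
3. **Respect temporal correlation in uncertainty.**  Fold-to-fold spread is
   summarized with the correlation-corrected SEM ``sigma * sqrt(1/J +
   1/(J-1))`` (plain ``sigma/sqrt(J)`` understates the error because
   training sets overlap across folds), and single-test-set confidence
   intervals use a block bootstrap over 20 contiguous test-set segments
   resampled 1000 times (resampling individual bins would produce highly
   correlated resamples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from spikedecode.data_format import (
    BinnedDataset,
    LagSpec,
    apply_scaler,
    fit_scaler,
    make_design_matrix,
)
from spikedecode.decoders.base import get_decoder
from spikedecode.ensemble import DEFAULT_BASE_FAMILIES, EnsembleModel

__all__ = [
    "r2_score",
    "FoldPlan",
    "make_fold_plan",
    "corrected_sem",
    "block_bootstrap_ci",
    "optimize_hyperparameters",
    "EvaluationReport",
    "run_comparison",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def r2_score(Y_true: np.ndarray, Y_hat: np.ndarray) -> float:
    """Fraction of variance accounted for, averaged over output dimensions.

    Per dimension ``R^2 = 1 - sum((yhat-y)^2) / sum((y-ybar)^2)`` with the
    mean taken from ``Y_true``.  Unbounded below: a decoder worse than
    predicting the mean scores negative.
    """
    def as_cols(arr):
        arr = np.asarray(arr, dtype=float)
        return arr[:, None] if arr.ndim == 1 else arr

    Yt, Yh = as_cols(Y_true), as_cols(Y_hat)
    if Yt.shape != Yh.shape:
        raise ValueError(f"shape mismatch {Yt.shape} vs {Yh.shape}")
    if Yt.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = np.sum((Yt - Yt.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        raise ValueError("zero-variance true output; R^2 undefined")
    ss_res = np.sum((Yh - Yt) ** 2, axis=0)
    return float(np.mean(1.0 - ss_res / ss_tot))


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Per-fold train / contiguous-validation / contiguous-test index sets."""

    n_rows: int
    n_folds: int
    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __iter__(self):
        return iter(self.folds)


def make_fold_plan(K: int, J: int = 10, validation_fraction: float = 0.1) -> FoldPlan:
    """Rotating contiguous-split plan over ``K`` rows.

    Each fold's test block has ``K/J`` rows; blocks start at the end of the
    recording and rotate backwards by ``K/J`` rows per fold, so the J test
    blocks tile the rows exactly once.  The validation block
    (``validation_fraction`` of rows, 10% by default) sits immediately
    before the test block, or immediately after when the test block is at
    the start; everything else is training.  For J = 10 this is the
    80/10/10 plan.  Small J forces a smaller training share (e.g., J = 2
    becomes a 25/25/50 train/validation/test plan, with a warning).
    """
    if J < 2:
        raise ValueError("need at least 2 folds")
    if K < 10 * J:
        raise ValueError(f"K={K} too small for {J} folds (need K >= {10 * J})")
    edges = np.round(np.linspace(0, K, J + 1)).astype(int)
    v_frac = validation_fraction
    max_v = (1.0 - 1.0 / J) / 2.0
    if J == 2 or v_frac > max_v + 1e-12:
        # an 80/10/10-style plan is impossible once the test block must take
        # 1/J of the rows; split the remainder evenly between train and
        # validation (J = 2 becomes a 25/25/50 train/val/test plan)
        warnings.warn(
            f"validation fraction {v_frac} infeasible with J={J}; "
            f"clamped to {max_v:.3f}", stacklevel=2,
        )
        v_frac = max_v
    v_size = max(1, int(round(v_frac * K)))
    folds = []
    all_rows = np.arange(K)
    for j in range(J):
        t0, t1 = edges[J - 1 - j], edges[J - j]   # test rotates from the end
        test = all_rows[t0:t1]
        if t0 >= v_size:
            val = all_rows[t0 - v_size:t0]
        else:
            val = all_rows[t1:t1 + v_size]
        mask = np.ones(K, dtype=bool)
        mask[test] = False
        mask[val] = False
        train = all_rows[mask]
        folds.append((train, val, test))
    return FoldPlan(n_rows=K, n_folds=J, folds=folds)


def corrected_sem(fold_scores: Sequence[float]) -> float:
    """SEM across folds, corrected for overlapping training sets.

    ``sigma * sqrt(1/J + 1/(J-1))`` with sigma the (ddof=1) SD of the fold
    scores.  Always larger than the naive ``sigma/sqrt(J)``.
    """
    scores = np.asarray(fold_scores, dtype=float)
    J = scores.size
    if J < 2:
        raise ValueError("need at least 2 fold scores")
    sigma = scores.std(ddof=1)
    return float(sigma * np.sqrt(1.0 / J + 1.0 / (J - 1)))


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------

def block_bootstrap_ci(
    Y_true: np.ndarray,
    Y_hat: np.ndarray,
    n_subsets: int = 20,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    return_samples: bool = False,
):
    """Percentile CI for test-set R² via a contiguous-block bootstrap.

    The test rows are cut into ``n_subsets`` temporally contiguous, disjoint
    segments covering the whole set; each resample draws ``n_subsets``
    segments with replacement, concatenates their (true, predicted) pairs
    and recomputes R².  The interval is the ``(1-level)/2`` and
    ``1-(1-level)/2`` percentiles of the resampled scores.
    """
    Yt = np.asarray(Y_true, dtype=float)
    Yh = np.asarray(Y_hat, dtype=float)
    Yt = Yt[:, None] if Yt.ndim == 1 else Yt
    Yh = Yh[:, None] if Yh.ndim == 1 else Yh
    n = Yt.shape[0]
    if n < n_subsets:
        raise ValueError(f"{n} test rows < {n_subsets} subsets")
    edges = np.round(np.linspace(0, n, n_subsets + 1)).astype(int)
    segments = [np.arange(edges[i], edges[i + 1]) for i in range(n_subsets)]
    rng = np.random.default_rng(seed)
    scores = np.empty(n_resamples)
    for b in range(n_resamples):
        pick = rng.integers(0, n_subsets, size=n_subsets)
        idx = np.concatenate([segments[p] for p in pick])
        scores[b] = r2_score(Yt[idx], Yh[idx])
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(scores, [alpha, 100.0 - alpha])
    if return_samples:
        return float(lo), float(hi), scores
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    # a list is a discrete choice set; a 2-tuple is a (low, high) range,
    # integer-valued when both endpoints are ints
    params = {}
    for name, spec in space.items():
        if isinstance(spec, list):
            params[name] = spec[rng.integers(len(spec))]
        else:
            lo, hi = spec
            if isinstance(lo, int) and isinstance(hi, int):
                params[name] = int(rng.integers(lo, hi + 1))
            else:
                params[name] = float(rng.uniform(lo, hi))
    return params


def _encode(params: dict, space: dict) -> np.ndarray:
    """Map a parameter dict to the unit cube (categoricals by choice index)."""
    x = []
    for name, spec in space.items():
        v = params[name]
        if isinstance(spec, list):
            x.append(spec.index(v) / max(len(spec) - 1, 1))
        else:
            lo, hi = spec
            x.append((v - lo) / (hi - lo) if hi > lo else 0.0)
    return np.asarray(x)


def _decode(x: np.ndarray, space: dict) -> dict:
    params = {}
    for xi, (name, spec) in zip(x, space.items()):
        if isinstance(spec, list):
            params[name] = spec[int(round(xi * (len(spec) - 1)))]
        else:
            lo, hi = spec
            v = lo + xi * (hi - lo)
            params[name] = int(round(v)) if isinstance(lo, int) and isinstance(hi, int) else float(v)
    return params


def _search(objective: Callable[[dict], float], space: dict, budget: int,
            strategy: str, seed: int):
    """Maximize ``objective`` over ``space``; returns (best_params, log)."""
    rng = np.random.default_rng(seed)
    log: list[tuple[dict, float]] = []

    def evaluate(params: dict) -> float:
        score = float(objective(params))
        log.append((params, score))
        return score

    if strategy == "grid":
        axes = []
        n_per = max(2, int(np.floor(budget ** (1.0 / max(len(space), 1)))))
        for name, spec in space.items():
            if isinstance(spec, list):
                axes.append(spec)
            else:
                lo, hi = spec
                vals = np.linspace(lo, hi, n_per)
                if isinstance(lo, int) and isinstance(hi, int):
                    vals = sorted({int(round(v)) for v in vals})
                axes.append(list(vals))
        mesh = np.meshgrid(*[np.arange(len(a)) for a in axes], indexing="ij")
        combos = np.column_stack([m.ravel() for m in mesh])[:budget]
        for combo in combos:
            evaluate({n: axes[i][c] for i, (n, c) in enumerate(zip(space, combo))})
    elif strategy == "random":
        for _ in range(budget):
            evaluate(_sample_space(space, rng))
    elif strategy == "bayesian":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern
        from scipy.stats import norm

        n_init = min(budget, max(3, len(space) + 1))
        for _ in range(n_init):
            evaluate(_sample_space(space, rng))
        for _ in range(budget - n_init):
            X = np.array([_encode(p, space) for p, _ in log])
            y = np.array([s for _, s in log])
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), alpha=1e-6, normalize_y=True,
                random_state=int(rng.integers(2 ** 31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X, y)
                cand = rng.random((256, len(space)))
                mu, sd = gp.predict(cand, return_std=True)
            best = y.max()
            sd = np.maximum(sd, 1e-12)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            evaluate(_decode(cand[int(np.argmax(ei))], space))
    else:
        raise ValueError(f"unknown search strategy {strategy!r}")

    if not log:
        raise RuntimeError("hyperparameter search evaluated no configurations")
    best_params, _ = max(log, key=lambda item: item[1])
    return best_params, log


def optimize_hyperparameters(
    decoder_family: str,
    search_space: dict | None,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    budget: int = 10,
    strategy: str = "bayesian",
    seed: int = 0,
    fixed_params: dict | None = None,
):
    """Select decoder hyperparameters by validation-set R².

    Fits one decoder per evaluated configuration on the training rows and
    scores it on the validation rows; the configuration with the highest
    validation R² wins.  The test set plays no role here.  Returns
    ``(best_params, log)`` where ``log`` is the full list of
    (configuration, validation R²) pairs, in evaluation order.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    proto = get_decoder(decoder_family)
    space = proto.default_search_space if search_space is None else search_space
    fixed = fixed_params or {}
    failures: list[str] = []

    def objective(params: dict) -> float:
        try:
            dec = get_decoder(decoder_family, **{**fixed, **params})
            dec.fit(X_train, Y_train)
            return r2_score(Y_val, dec.predict(X_val))
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            failures.append(f"{params}: {exc}")
            return -np.inf

    best, log = _search(objective, space, budget, strategy, seed)
    if all(not np.isfinite(s) for _, s in log):
        raise RuntimeError(
            "all hyperparameter evaluations failed:\n" + "\n".join(failures)
        )
    return best, log


# ---------------------------------------------------------------------------
# full comparison driver
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold and aggregate test-set R² for one decoder."""

    decoder: str
    fold_scores: list[float]
    hyperparams: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sem(self) -> float:
        return corrected_sem(self.fold_scores)

    def to_dict(self) -> dict[str, Any]:
        return {
            "decoder": self.decoder,
            "fold_scores": [float(s) for s in self.fold_scores],
            "mean": self.mean,
            "corrected_sem": self.sem,
            "n_folds": len(self.fold_scores),
            "hyperparams": self.hyperparams,
        }


def _window_sum(X_flat: np.ndarray, n_neurons: int) -> np.ndarray:
    """Sum the flat design matrix over its lag blocks -> K x N windowed counts."""
    K, p = X_flat.shape
    B = p // n_neurons
    return X_flat.reshape(K, B, n_neurons).sum(axis=1)


def run_comparison(
    data: BinnedDataset,
    decoders: Sequence[str],
    lags: LagSpec,
    n_folds: int = 10,
    budget: int = 0,
    strategy: str = "bayesian",
    seed: int = 0,
    decoder_params: dict[str, dict] | None = None,
    search_spaces: dict[str, dict] | None = None,
    lag_overrides: dict[str, LagSpec] | None = None,
    ensemble_stacker: str = "feedforward",
    return_predictions: bool = False,
):
    """Cross-validated comparison of decoders on one binned dataset.

    For every fold: the input scaler (z-score) and output scaler (centering)
    are fitted on training rows only; hyperparameters (when ``budget > 0``)
    are selected on the validation block; the test block is scored once.
    The ``"ensemble"`` pseudo-decoder stacks the eight flat/sequence base
    families, training its second-tier model on the bases' validation-block
    predictions (never on rows the bases trained on).

    Returns a dict of decoder name -> :class:`EvaluationReport` (plus a
    predictions dict when ``return_predictions`` is set).
    """
    decoder_params = decoder_params or {}
    search_spaces = search_spaces or {}
    lag_overrides = lag_overrides or {}

    names = list(decoders)
    wants_ensemble = "ensemble" in names
    if wants_ensemble:
        names.remove("ensemble")
    base_set = list(DEFAULT_BASE_FAMILIES) if wants_ensemble else []
    all_names = list(dict.fromkeys(names + base_set))

    # one formatting "context" per distinct lag window; decoders with a lag
    # override get their own design matrix, mapped back to the primary
    # fold plan through the shared output-bin indices.  Ensemble bases
    # always use the primary context so their predictions stay row-aligned.
    class _Ctx:
        def __init__(self, lag_spec: LagSpec):
            self.dm = make_design_matrix(data, lag_spec)
            self.K = self.dm.X.shape[0]
            self.B = lag_spec.n_lags
            self.concurrent = data.counts[self.dm.row_to_bin, :].astype(float)
            self.windowed = _window_sum(self.dm.X, data.n_neurons)

        def rows(self, primary_bins: np.ndarray) -> np.ndarray:
            return np.nonzero(np.isin(self.dm.row_to_bin, primary_bins))[0]

    primary = _Ctx(lags)
    contexts: dict[str, _Ctx] = {}
    for name in all_names:
        if name in lag_overrides and name not in base_set:
            contexts[name] = _Ctx(lag_overrides[name])
    dm = primary.dm
    plan = make_fold_plan(primary.K, n_folds)
    N = data.n_neurons

    reports = {name: EvaluationReport(name, []) for name in list(names) + (
        ["ensemble"] if wants_ensemble else [])}
    predictions: dict[str, list] = {name: [] for name in reports}

    for fold_id, (train, val, test) in enumerate(plan):
        scalers: dict[int, tuple] = {}

        def fold_arrays(ctx: _Ctx, sel_train, sel_val, sel_test):
            """Scaled flat/tensor arrays for one context and fold (train-fit)."""
            key = id(ctx)
            if key not in scalers:
                xs = fit_scaler(ctx.dm.X[sel_train], "zscore")
                ys = fit_scaler(ctx.dm.Y[sel_train], "center")
                Xz = apply_scaler(xs, ctx.dm.X)
                Yc = apply_scaler(ys, ctx.dm.Y)
                Xz3 = Xz.reshape(ctx.K, ctx.B, N).transpose(0, 2, 1)
                scalers[key] = (xs, ys, Xz, Yc, Xz3)
            return scalers[key]

        fitted_bases: dict[str, Any] = {}
        for name in all_names:
            ctx = contexts.get(name, primary)
            if ctx is primary:
                tr, va, te = train, val, test
            else:
                tr = ctx.rows(dm.row_to_bin[train])
                va = ctx.rows(dm.row_to_bin[val])
                te = ctx.rows(dm.row_to_bin[test])
            params = dict(decoder_params.get(name, {}))
            proto = get_decoder(name, **params)
            layout = proto.input_layout
            _, y_scaler, Xz, Yc, Xz3 = fold_arrays(ctx, tr, va, te)
            if layout == "flat":
                Xtr, Xva, Xte = Xz[tr], Xz[va], Xz[te]
                Ytr, Yva_sel = Yc[tr], Yc[va]
            elif layout == "sequence":
                Xtr, Xva, Xte = Xz3[tr], Xz3[va], Xz3[te]
                Ytr, Yva_sel = Yc[tr], Yc[va]
            else:  # state_space: raw units, decoder-specific inputs
                src = ctx.windowed if name == "naive_bayes" else ctx.concurrent
                if name == "kalman_filter":
                    params.setdefault("bin_size", data.bin_size)
                Xtr, Xva, Xte = src[tr], src[va], src[te]
                Ytr, Yva_sel = ctx.dm.Y[tr], ctx.dm.Y[va]

            if budget > 0:
                space = search_spaces.get(name)
                best, log = optimize_hyperparameters(
                    name, space, Xtr, Ytr, Xva, Yva_sel,
                    budget=budget, strategy=strategy,
                    seed=seed * 1009 + fold_id, fixed_params=params,
                )
                params.update(best)

            dec = get_decoder(name, **params)
            dec.fit(Xtr, Ytr)
            if layout in ("flat", "sequence"):
                pred_te = y_scaler.inverse_transform(dec.predict(Xte))
                pred_va = y_scaler.inverse_transform(dec.predict(Xva))
            else:
                pred_te = dec.predict(Xte)
                pred_va = dec.predict(Xva)
            if name in reports:
                reports[name].fold_scores.append(
                    r2_score(ctx.dm.Y[te], pred_te))
                reports[name].hyperparams.append(params)
                if return_predictions:
                    predictions[name].append(
                        {"test_rows": te, "Y_hat": pred_te})
            if name in base_set:
                fitted_bases[name] = (pred_va, pred_te)

        if wants_ensemble:
            P_val = np.column_stack([fitted_bases[b][0] for b in base_set])
            P_test = np.column_stack([fitted_bases[b][1] for b in base_set])
            stacker = EnsembleModel(
                stacker=ensemble_stacker, base_names=tuple(base_set),
                seed=seed * 31 + fold_id,
            ).fit(P_val, dm.Y[val])
            pred_te = stacker.predict(P_test)
            reports["ensemble"].fold_scores.append(r2_score(dm.Y[test], pred_te))
            reports["ensemble"].hyperparams.append({"stacker": ensemble_stacker})
            if return_predictions:
                predictions["ensemble"].append(
                    {"test_rows": test, "Y_hat": pred_te})

    if return_predictions:
        return reports, predictions
    return reports
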