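"""Per-participant logistic estimation and model selection.

Fitting uses Firth's bias-reduction method by default: the log-likelihood is
penalized by half the log-determinant of the Fisher information (a Jeffreys
prior), which keeps estimates finite even under complete separation — a real
risk with 45 binary choices per participant.  The penalized score is

    U*_j(beta) = sum_i ( y_i - pi_i + h_i (1/2 - pi_i) ) x_ij

with h_i the hat values of the weighted design, solved by Newton/IRLS steps.
Plain maximum likelihood is available for comparison.

Model selection over the 10-model space uses repeated random-partition
3-fold cross-validation (fit on 2 folds, score held-out negative
log-likelihood on the third, rotating), averaged over repeats; and BIC
(k ln n - 2 loglik).  Ties break toward fewer parameters, then name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelSpec, design_matrix, enumerate_model_space, get_model_spec
from .task_design import Design

__all__ = [
    "FitResult",
    "CVResult",
    "fit_logistic",
    "fit_trials",
    "bic",
    "cv_model_select",
    "fit_cohort",
]

MAX_ITER = 100
TOL = 1e-8            # relative penalized-loglik change
NLL_CLIP = 1e-12      # probability clipping for held-out NLL


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _loglik(X, y, beta):
    z = X @ beta
    # log(sigma(z)) = -log(1+exp(-z)); stable via logaddexp
    return float(np.sum(y * -np.logaddexp(0, -z) + (1 - y) * -np.logaddexp(0, z)))


def _check_rank(X):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns by correlation structure
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = []
        k = X.shape[1] - 1
        if k > 1:
            for i in range(k):
                for j in range(i + 1, k):
                    if abs(corr[i, j]) > 0.999:
                        bad.append((i + 1, j + 1))
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column pairs (1-based, "
            f"excluding intercept): {bad or 'constant column or perfect combination'}"
        )


@dataclass
class FitResult:
    """One logistic fit: coefficients, uncertainty and fit statistics."""

    spec: ModelSpec
    betas: np.ndarray
    std_errors: np.ndarray
    loglik: float
    bic: float
    mcfadden_r2: float
    converged: bool
    method: str
    n_obs: int
    n_iter: int = 0

    def coef(self, component: str) -> float:
        """Coefficient by component label ('const', 'Rw', 'Gu', 'Iq', 'Ip', 'In')."""
        if component == "const":
            return float(self.betas[0])
        return float(self.betas[1 + self.spec.components.index(component)])


def _irls(X, y, firth: bool, max_iter=MAX_ITER, tol=TOL):
    """Newton/IRLS for (penalized) logistic regression.

    Returns (beta, cov, converged, n_iter, loglik_at_beta).
    """
    n, k = X.shape
    beta = np.zeros(k)
    prev_obj = -np.inf
    converged = False
    XtWX_inv = None
    it = 0
    for it in range(1, max_iter + 1):
        z = X @ beta
        pi = _sigmoid(z)
        w = np.clip(pi * (1 - pi), 1e-300, None)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            XtWX_inv = np.linalg.pinv(XtWX)
        if firth:
            # hat values of the weighted design
            h = np.einsum("ij,jk,ik->i", X, XtWX_inv, Xw)
            score = X.T @ (y - pi + h * (0.5 - pi))
            sign, logdet = np.linalg.slogdet(XtWX)
            obj = _loglik(X, y, beta) + 0.5 * logdet
        else:
            score = X.T @ (y - pi)
            obj = _loglik(X, y, beta)
        step = XtWX_inv @ score
        # step-halving keeps the objective monotone on ill-conditioned data
        new_beta = beta + step
        for _ in range(10):
            trial_obj = _objective(X, y, new_beta, firth)
            if np.isfinite(trial_obj) and trial_obj >= obj - 1e-10:
                break
            step *= 0.5
            new_beta = beta + step
        beta = new_beta
        new_obj = _objective(X, y, beta, firth)
        if abs(new_obj - prev_obj) < tol * (abs(prev_obj) + tol):
            converged = True
            prev_obj = new_obj
            break
        prev_obj = new_obj
    # covariance from the (unpenalized) Fisher information at the estimate
    pi = _sigmoid(X @ beta)
    w = np.clip(pi * (1 - pi), 1e-300, None)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(XtWX)
    return beta, cov, converged, it, _loglik(X, y, beta)


def _objective(X, y, beta, firth):
    ll = _loglik(X, y, beta)
    if not firth:
        return ll
    pi = _sigmoid(X @ beta)
    w = np.clip(pi * (1 - pi), 1e-300, None)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return ll + 0.5 * logdet


def penalized_loglik(X, y, beta):
    """Jeffreys-penalized log-likelihood l(beta) + 0.5 log det I(beta)."""
    return _objective(np.asarray(X, float), np.asarray(y, float), np.asarray(beta, float), True)


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion k ln(n) - 2 l; lower is better."""
    return n_params * np.log(n_obs) - 2.0 * loglik


def _null_loglik(y):
    """Intercept-only maximum log-likelihood: closed form at p = mean(y)."""
    n = len(y)
    k = float(np.sum(y))
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def fit_logistic(X, choices, spec: ModelSpec, method: str = "firth") -> FitResult:
    """Fit one logistic model to a participant's choices.

    Parameters
    ----------
    X
        (n_obs, n_params) design matrix whose first column is the intercept,
        remaining columns ordered as ``spec.components``.
    choices
        Binary vector, 1 = Cooperate.
    method
        ``"firth"`` (bias-reduced, default) or ``"mle"``.

    Non-convergence is flagged on the result, never raised; a rank-deficient
    design raises ``numpy.linalg.LinAlgError`` naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(choices, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_params:
        raise ValueError(f"X must be (n, {spec.n_params}) for {spec.name}, got {X.shape}")
    if X.shape[0] < spec.n_params:
        raise ValueError("need at least as many observations as parameters")
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ValueError("choices must be binary (0 = Defect, 1 = Cooperate)")
    if method not in ("firth", "mle"):
        raise ValueError(f"method must be 'firth' or 'mle', got {method!r}")
    _check_rank(X)
    beta, cov, converged, n_iter, ll = _irls(X, y, firth=(method == "firth"))
    n = X.shape[0]
    ll0 = _null_loglik(y)
    return FitResult(
        spec=spec,
        betas=beta,
        std_errors=np.sqrt(np.clip(np.diag(cov), 0, None)),
        loglik=ll,
        bic=bic(ll, spec.n_params, n),
        mcfadden_r2=1.0 - ll / ll0 if ll0 != 0 else 0.0,
        converged=converged,
        method=method,
        n_obs=n,
        n_iter=n_iter,
    )


def fit_trials(design: Design, choices, spec: ModelSpec, method: str = "firth") -> FitResult:
    """Convenience wrapper: build the design matrix from a Design and fit."""
    return fit_logistic(design_matrix(design, spec), choices, spec, method=method)


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random equal partition; remainders distributed round-robin."""
    labels = np.repeat(np.arange(n_folds), n // n_folds)
    labels = np.concatenate([labels, np.arange(n % n_folds)])
    rng.shuffle(labels)
    return labels


@dataclass
class CVResult:
    """Cross-validated model comparison for one participant."""

    mean_predictive_nll: dict[str, float]
    mean_training_nll: dict[str, float]
    best_model: ModelSpec
    n_repeats: int
    n_folds: int
    seed: int
    partition: str = "partition"


def _held_out_nll(X_test, y_test, beta):
    pi = _sigmoid(X_test @ beta)
    pi = np.clip(pi, NLL_CLIP, 1 - NLL_CLIP)
    return float(-np.sum(y_test * np.log(pi) + (1 - y_test) * np.log(1 - pi)))


def cv_model_select(
    design: Design,
    choices,
    model_space: list[ModelSpec] | None = None,
    n_folds: int = 3,
    n_repeats: int = 500,
    seed: int = 0,
    method: str = "firth",
    partition: str = "partition",
) -> CVResult:
    """Repeated random-partition k-fold CV over the model space.

    Each repeat draws one random equal partition of the trials; every model
    is fit on k-1 folds and scored by negative log-likelihood on the
    held-out fold, rotating through folds; scores are summed within a repeat
    and averaged across repeats.  ``partition="bootstrap"`` instead resamples
    the trials with replacement each repeat before partitioning (the
    alternative reading of a bootstrapped CV).  Deterministic given seed.
    """
    if model_space is None:
        model_space = enumerate_model_space()
    if partition not in ("partition", "bootstrap"):
        raise ValueError("partition must be 'partition' or 'bootstrap'")
    y_all = np.asarray(choices, dtype=float)
    n = len(design)
    if len(y_all) != n:
        raise ValueError("choices length must match design length")
    X_by_model = {spec.name: design_matrix(design, spec) for spec in model_space}
    rng = np.random.default_rng(seed)
    test_nll = {spec.name: 0.0 for spec in model_space}
    train_nll = {spec.name: 0.0 for spec in model_space}
    for _ in range(n_repeats):
        if partition == "bootstrap":
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        labels = _fold_assignment(n, n_folds, rng)
        for fold in range(n_folds):
            tr = idx[labels != fold]
            te = idx[labels == fold]
            for spec in model_space:
                X = X_by_model[spec.name]
                beta, *_ = _irls(X[tr], y_all[tr], firth=(method == "firth"))
                test_nll[spec.name] += _held_out_nll(X[te], y_all[te], beta)
                train_nll[spec.name] += _held_out_nll(X[tr], y_all[tr], beta) * len(te) / len(tr)
    mean_test = {k: v / n_repeats for k, v in test_nll.items()}
    mean_train = {k: v / n_repeats for k, v in train_nll.items()}
    best = min(
        model_space,
        key=lambda s: (round(mean_test[s.name], 12), s.n_params, s.name),
    )
    return CVResult(
        mean_predictive_nll=mean_test,
        mean_training_nll=mean_train,
        best_model=best,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
        partition=partition,
    )


FIT_TABLE_COLUMNS = [
    "pid", "model", "beta_constant", "beta_reward", "beta_guilt",
    "beta_inequity", "beta_iq_pos", "beta_iq_neg",
    "loglik", "bic", "mcfadden_r2", "converged",
]

_BETA_COLUMN = {
    "Rw": "beta_reward", "Gu": "beta_guilt", "Iq": "beta_inequity",
    "Ip": "beta_iq_pos", "In": "beta_iq_neg",
}


def _fit_row(pid, fit: FitResult) -> dict:
    row = {c: np.nan for c in FIT_TABLE_COLUMNS}
    row.update(pid=pid, model=fit.spec.name, beta_constant=fit.betas[0],
               loglik=fit.loglik, bic=fit.bic, mcfadden_r2=fit.mcfadden_r2,
               converged=fit.converged)
    for comp, b in zip(fit.spec.components, fit.betas[1:]):
        row[_BETA_COLUMN[comp]] = b
    return row


def fit_cohort(
    choices_df: pd.DataFrame,
    design: Design,
    spec: ModelSpec | str = "RwGuIq",
    method: str = "firth",
    pooled: bool = False,
) -> pd.DataFrame:
    """Fit one model to every participant in a long-format choices table.

    ``choices_df`` needs columns pid, trial_id, choice (1 = Cooperate).
    With ``pooled=True`` a single extra row (pid = "pooled") stacks all
    participants into one regression, the all-participant fit style.
    """
    if isinstance(spec, str):
        spec = get_model_spec(spec)
    X_full = design_matrix(design, spec)
    rows = []
    for pid, grp in choices_df.groupby("pid", sort=True):
        grp = grp.sort_values("trial_id")
        tid = grp["trial_id"].to_numpy(int)
        fit = fit_logistic(X_full[tid], grp["choice"].to_numpy(float), spec, method=method)
        rows.append(_fit_row(pid, fit))
    if pooled:
        df = choices_df.sort_values(["pid", "trial_id"])
        tid = df["trial_id"].to_numpy(int)
        fit = fit_logistic(X_full[tid], df["choice"].to_numpy(float), spec, method=method)
        rows.append(_fit_row("pooled", fit))
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)
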