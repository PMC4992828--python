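"""Conversion-prediction framework.

Forward stepwise logistic regression by likelihood ratio (entry p < 0.05,
removal p > 0.10, nuisance always retained), repeated stratified
leave-10-out cross-validation (34 rounds by default, metrics averaged over
rounds), ROC AUC with the Youden-index cutoff, label-permutation
significance of the cross-validated AUC, Johnson relative-weight
decomposition of predictor importance with BCa bootstrap intervals, and
Friedman/Wilcoxon comparison of cross-validated models.

The logistic core is a compact IRLS Newton solver with a Firth-penalized
fallback for separated data (routine at n ~ 34 with strong planted
effects).  statsmodels is deliberately not used inside the resampling loops
— a single fit here costs tens of microseconds, which is what makes
10^4-permutation tests tractable — and serves instead as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ClassError,
    CollinearityError,
    DegenerateOutcomeError,
    PairingError,
)


# ---------------------------------------------------------------------------
# logistic core


def _loglik(y, mu):
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _irls(X, y, firth=False, max_iter=60, tol=1e-10):
    """Newton/IRLS logistic fit; returns (beta, deviance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-12
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        resid = y - mu
        if firth:
            try:
                Ainv = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError:
                Ainv = np.linalg.pinv(XtWX)
            h = np.einsum("ij,jk,ik->i", Xw, Ainv, X)
            resid = resid + h * (0.5 - mu)
        grad = X.T @ resid
        try:
            step = np.linalg.solve(XtWX + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return beta, -2.0 * _loglik(y, mu), converged


def _fit_binary(X, y, force_firth=False):
    """Plain fit with automatic Firth fallback on (quasi-)separation."""
    if force_firth:
        beta, dev, _ = _irls(X, y, firth=True)
        return beta, dev, True
    beta, dev, converged = _irls(X, y, firth=False)
    if not converged or np.max(np.abs(beta[1:] if len(beta) > 1 else beta)) > 15.0:
        beta, dev, _ = _irls(X, y, firth=True)
        return beta, dev, True
    return beta, dev, False


def _design(table: pd.DataFrame, predictors, nuisance):
    cols = list(nuisance or []) + list(predictors)
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in cols])
    return X, cols


@dataclass
class LogisticModel:
    selected: list
    nuisance: list
    coefficients: dict  # name (incl. "intercept") -> value
    lr_chi2: float
    df: int
    p: float
    deviance: float
    firth: bool = False

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.coefficients["intercept"])
        for name in self.nuisance + self.selected:
            eta = eta + self.coefficients[name] * table[name].to_numpy(float)
        return eta


def fit_logistic(
    table: pd.DataFrame,
    predictors,
    nuisance=None,
    label_col: str = "converter",
) -> LogisticModel:
    """Maximum-likelihood logistic fit; ``lr_chi2`` is tested against the
    nuisance-only (or intercept-only) model."""
    predictors = list(predictors)
    nuisance = list(nuisance or [])
    y = table[label_col].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome label is constant; logistic fit impossible")
    if min((y == 0).sum(), (y == 1).sum()) < 5:
        warnings.warn("fewer than 5 subjects in one class; estimates will be unstable")

    X_full, cols = _design(table, predictors, nuisance)
    beta, dev_full, used_firth = _fit_binary(X_full, y)
    X_red, _ = _design(table, [], nuisance)
    _, dev_red, _ = _fit_binary(X_red, y, force_firth=used_firth)
    if used_firth:
        warnings.warn("separation detected; Firth-penalized fallback used")
    lr = max(0.0, dev_red - dev_full)
    df = len(predictors)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    coefs = {"intercept": float(beta[0])}
    coefs.update({c: float(b) for c, b in zip(cols, beta[1:])})
    return LogisticModel(
        selected=predictors,
        nuisance=nuisance,
        coefficients=coefs,
        lr_chi2=lr,
        df=df,
        p=p,
        deviance=dev_full,
        firth=used_firth,
    )


def stepwise_lr(
    table: pd.DataFrame,
    candidates,
    nuisance=None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    label_col: str = "converter",
) -> LogisticModel:
    """Forward stepwise logistic regression on the likelihood ratio.

    At each step the candidate with the smallest LR-test p below ``entry_p``
    enters; after every entry, any selected term whose LR removal p exceeds
    ``removal_p`` leaves.  Nuisance covariates are always retained.
    """
    candidates = list(candidates)
    nuisance = list(nuisance or [])
    selected: list = []
    while True:
        changed = False
        best_p, best_c = None, None
        for c in candidates:
            if c in selected:
                continue
            m = fit_logistic(table, selected + [c], nuisance, label_col)
            base = fit_logistic(table, selected, nuisance, label_col) if selected else None
            lr = (base.deviance - m.deviance) if base else (m.lr_chi2)
            p = float(stats.chi2.sf(max(0.0, lr), 1))
            if p < entry_p and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None:
            selected.append(best_c)
            changed = True
        # backward removal sweep
        removed = True
        while removed and selected:
            removed = False
            full = fit_logistic(table, selected, nuisance, label_col)
            worst_p, worst_c = None, None
            for c in selected:
                rest = [s for s in selected if s != c]
                m = fit_logistic(table, rest, nuisance, label_col)
                p = float(stats.chi2.sf(max(0.0, m.deviance - full.deviance), 1))
                if worst_p is None or p > worst_p:
                    worst_p, worst_c = p, c
            if worst_p is not None and worst_p > removal_p:
                selected.remove(worst_c)
                removed = changed = True
        if not changed:
            break
    return fit_logistic(table, selected, nuisance, label_col)


# ---------------------------------------------------------------------------
# ROC / Youden


def roc_auc(scores, labels) -> float:
    """AUC as the probability a random positive outscores a random negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ClassError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_cutoff(scores, labels) -> dict:
    """Cutoff maximizing J = sensitivity + specificity - 1 (ties -> lower cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ClassError("youden_cutoff needs both classes present")
    uniq = np.unique(scores)
    cuts = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    n1 = labels.sum()
    n0 = len(labels) - n1
    best = None
    for c in cuts:  # predicted positive: score >= c
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if best is None or j > best["J"] + 1e-12:
            best = {"cutoff": float(c), "sensitivity": float(sens), "specificity": float(spec), "J": float(j)}
    return best


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    rounds: list = field(default_factory=list)
    mean_auc: float = np.nan
    auc_ci: tuple = (np.nan, np.nan)
    mean_accuracy: float = np.nan
    mean_sensitivity: float = np.nan
    mean_specificity: float = np.nan


def _batched_logistic(Xtr, ytr, n_iter=30, tol=1e-8):
    """Newton/IRLS over a stack of small designs: Xtr (B, n, p), ytr (B, n).

    Separated batches run into the iteration cap with a large but finite
    coefficient vector; held-out metrics only use the score *ranking*, which
    a separating direction already fixes, so no penalized refit is needed
    here.
    """
    B, n, p = Xtr.shape
    beta = np.zeros((B, p))
    ridge = 1e-9 * np.eye(p)
    for _ in range(n_iter):
        eta = np.einsum("bnp,bp->bn", Xtr, beta)
        np.clip(eta, -30.0, 30.0, out=eta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-12
        Xw = Xtr * w[..., None]
        XtWX = np.einsum("bnp,bnq->bpq", Xw, Xtr) + ridge
        grad = np.einsum("bnp,bn->bp", Xtr, ytr - mu)
        step = np.linalg.solve(XtWX, grad[..., None])[..., 0]
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def _round_metrics(scores, k_pos):
    """Per-round AUC / Youden metrics; scores (R, k) with positives first."""
    R, k = scores.shape
    sp = scores[:, :k_pos, None]
    sn = scores[:, None, k_pos:]
    auc = ((sp > sn) + 0.5 * (sp == sn)).mean(axis=(1, 2))
    # candidate cutoffs: the score values themselves, ascending; predicted
    # positive when score >= cutoff; argmax takes the first (lowest) maximum
    thr = np.sort(scores, axis=1)
    pred = scores[:, None, :] >= thr[:, :, None]  # (R, k_thr, k)
    sens = pred[:, :, :k_pos].mean(axis=2)
    spec = 1.0 - pred[:, :, k_pos:].mean(axis=2)
    J = sens + spec - 1.0
    best = np.argmax(J, axis=1)
    idx = np.arange(R)
    truth = np.arange(k) < k_pos
    acc = (pred[idx, best] == truth[None, :]).mean(axis=1)
    return auc, acc, sens[idx, best], spec[idx, best], thr[idx, best]


def _cv_metrics_batch(X_stack, y, n_rounds, rng):
    """Stratified repeated 90/10 holdout CV over a stack of feature matrices.

    ``X_stack`` is (B, n, p); all B matrices share the label vector ``y``
    (label permutation is applied by permuting feature rows).  Returns
    per-batch arrays of per-round metrics, shape (B, n_rounds).
    """
    B, n, p = X_stack.shape
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    k_pos = max(1, int(round(0.1 * len(pos))))
    k_neg = max(1, int(round(0.1 * len(neg))))
    R = n_rounds
    hp = pos[np.argsort(rng.random((B, R, len(pos))), axis=2)[..., :k_pos]]
    hn = neg[np.argsort(rng.random((B, R, len(neg))), axis=2)[..., :k_neg]]
    hold = np.concatenate([hp, hn], axis=2)  # (B, R, k), positives first
    mask = np.ones((B, R, n), dtype=bool)
    np.put_along_axis(mask, hold, False, axis=2)
    n_tr = n - hold.shape[2]
    tr = np.nonzero(mask)[2].reshape(B, R, n_tr)
    b_idx = np.arange(B)[:, None, None]
    Xtr = X_stack[b_idx, tr, :].reshape(B * R, n_tr, p)
    ytr = np.broadcast_to(y, (B, R, n))[np.broadcast_to(mask, (B, R, n))].reshape(B * R, n_tr)
    beta = _batched_logistic(Xtr, ytr.astype(float))
    Xho = X_stack[b_idx, hold, :].reshape(B * R, hold.shape[2], p)
    scores = np.einsum("bkp,bp->bk", Xho, beta)
    auc, acc, sens, spec, cut = _round_metrics(scores, k_pos)
    return tuple(a.reshape(B, R) for a in (auc, acc, sens, spec, cut))


def _cv_rounds_fast(X, y, n_rounds, rng):
    auc, acc, sens, spec, cut = _cv_metrics_batch(X[None, :, :], y, n_rounds, rng)
    return [
        {
            "auc": float(auc[0, r]),
            "accuracy": float(acc[0, r]),
            "sensitivity": float(sens[0, r]),
            "specificity": float(spec[0, r]),
            "cutoff": float(cut[0, r]),
        }
        for r in range(n_rounds)
    ]


def _summarize_rounds(rounds):
    res = CVResult(rounds=rounds)
    if rounds:
        aucs = np.array([r["auc"] for r in rounds])
        res.mean_auc = float(aucs.mean())
        res.auc_ci = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
        res.mean_accuracy = float(np.mean([r["accuracy"] for r in rounds]))
        res.mean_sensitivity = float(np.mean([r["sensitivity"] for r in rounds]))
        res.mean_specificity = float(np.mean([r["specificity"] for r in rounds]))
    return res


def cv_leave10out(
    table: pd.DataFrame,
    predictors,
    nuisance=None,
    n_rounds: int = 34,
    seed: int = 0,
    label_col: str = "converter",
) -> CVResult:
    """Repeated stratified leave-10%-out CV of a fixed-predictor logistic model.

    Per round, 10% of each class (>= 1 subject) is held out; coefficients
    are refit on the remaining 90% and the held-out linear predictors are
    pooled within the round for AUC, Youden cutoff, accuracy, sensitivity
    and specificity.  Metrics are averaged over rounds; the AUC CI is the
    2.5-97.5 percentile interval of per-round AUCs.  Stratification makes a
    one-class validation fold structurally impossible, so no redraws occur.
    """
    if len(table) < 10:
        raise ClassError("cv_leave10out needs at least 10 subjects")
    X, _ = _design(table, list(predictors), list(nuisance or []))
    y = table[label_col].to_numpy(float)
    rng = np.random.default_rng(seed)
    return _summarize_rounds(_cv_rounds_fast(X, y, n_rounds, rng))


@dataclass
class PermutationNull:
    observed: float
    null_stats: np.ndarray
    p: float
    q95: float


def permutation_test(
    table: pd.DataFrame,
    predictors,
    nuisance=None,
    n_perm: int = 10000,
    n_rounds: int = 34,
    seed: int = 0,
    label_col: str = "converter",
) -> PermutationNull:
    """Label-permutation null of the cross-validated mean AUC.

    The fixed-predictor CV (not the stepwise selection) is recomputed for
    each relabeling; ``p = (count >= observed + 1) / (n_perm + 1)``.
    """
    X, _ = _design(table, list(predictors), list(nuisance or []))
    y = table[label_col].to_numpy(float)
    rng = np.random.default_rng(seed)
    n = len(y)
    # permuting labels == permuting feature rows with labels fixed; the whole
    # permutation distribution is then one batched CV over stacked designs
    stack = np.empty((n_perm + 1, n, X.shape[1]))
    stack[0] = X
    for i in range(n_perm):
        stack[i + 1] = X[rng.permutation(n)]
    chunk = 256  # bound peak memory for large n_perm
    mean_aucs = np.empty(n_perm + 1)
    for lo in range(0, n_perm + 1, chunk):
        hi = min(lo + chunk, n_perm + 1)
        auc, *_ = _cv_metrics_batch(stack[lo:hi], y, n_rounds, rng)
        mean_aucs[lo:hi] = auc.mean(axis=1)
    obs, null = mean_aucs[0], mean_aucs[1:]
    p = float((np.sum(null >= obs) + 1.0) / (n_perm + 1.0))
    return PermutationNull(observed=float(obs), null_stats=null, p=p, q95=float(np.percentile(null, 95)))


# ---------------------------------------------------------------------------
# relative weights


@dataclass
class RelativeWeightResult:
    raw: dict  # predictor -> raw weight (variance-scale)
    percent: dict  # predictor -> percent of explained variance
    ci_percent: dict  # predictor -> (lo, hi) BCa interval on the percent scale


def _johnson_weights(X, y):
    """Johnson relative weights of standardized predictors for a binary outcome.

    The predictors are orthogonalized (Z = X R^{-1/2}); a logistic model on Z
    gives coefficients that are squared, attenuated to the logit-scale
    explained-variance metric, and mapped back through the squared loadings
    Lambda = R^{1/2}.
    """
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Xs, rowvar=False)
    R = np.atleast_2d(R)
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < 1e-10:
        raise CollinearityError("singular predictor correlation matrix")
    lam = evecs @ np.diag(np.sqrt(evals)) @ evecs.T  # R^{1/2}
    lam_inv = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    Z = Xs @ lam_inv
    Xd = np.column_stack([np.ones(len(y)), Z])
    beta, _, _ = _fit_binary(Xd, y)
    b = beta[1:]
    # standardize on the logit scale (latent-variable scaling)
    eta = Xd @ beta
    s_total = np.sqrt(np.var(eta, ddof=1) + np.pi**2 / 3.0)
    bstar = b / s_total
    return (lam**2) @ (bstar**2)


def relative_weights(
    table: pd.DataFrame,
    predictors,
    label_col: str = "converter",
    n_boot: int = 2000,
    seed: int = 0,
) -> RelativeWeightResult:
    """Relative importance of each predictor, with BCa bootstrap intervals.

    Percentages are each predictor's share of the summed weights (share of
    the model's explained variance); intervals are bias-corrected and
    accelerated over subject resampling.
    """
    predictors = list(predictors)
    X = table[predictors].to_numpy(float)
    y = table[label_col].to_numpy(float)
    point = _johnson_weights(X, y)
    pct = 100.0 * point / point.sum()

    rng = np.random.default_rng(seed)
    n = len(y)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2 or np.any(np.std(X[idx], axis=0) == 0):
            continue
        try:
            w = _johnson_weights(X[idx], y[idx])
        except CollinearityError:
            continue
        boots.append(100.0 * w / w.sum())
    boots = np.asarray(boots)

    # jackknife for the acceleration constant
    jack = []
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        if len(np.unique(y[idx])) < 2:
            continue
        w = _johnson_weights(X[idx], y[idx])
        jack.append(100.0 * w / w.sum())
    jack = np.asarray(jack)

    cis = {}
    for j, name in enumerate(predictors):
        bj = boots[:, j]
        prop = np.clip(np.mean(bj < pct[j]), 1.0 / (len(bj) + 1), 1 - 1.0 / (len(bj) + 1))
        z0 = stats.norm.ppf(prop)
        jm = jack[:, j].mean()
        num = np.sum((jm - jack[:, j]) ** 3)
        den = 6.0 * (np.sum((jm - jack[:, j]) ** 2) ** 1.5)
        a = num / den if den > 0 else 0.0
        lo_hi = []
        for alpha in (0.025, 0.975):
            z = stats.norm.ppf(alpha)
            adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
            lo_hi.append(float(np.percentile(bj, 100.0 * adj)))
        cis[name] = (min(lo_hi), max(lo_hi))
    return RelativeWeightResult(
        raw=dict(zip(predictors, point.tolist())),
        percent=dict(zip(predictors, pct.tolist())),
        ci_percent=cis,
    )


# ---------------------------------------------------------------------------
# model comparison


def compare_models(cv_results: dict, metrics=("auc", "accuracy")) -> dict:
    """Friedman test across models (rounds as blocks) plus pairwise Wilcoxon
    signed-rank tests with Bonferroni correction over all model pairs."""
    names = list(cv_results)
    if len(names) < 2:
        raise PairingError("compare_models needs at least 2 models")
    n_rounds = {m: len(cv_results[m].rounds) for m in names}
    if len(set(n_rounds.values())) != 1:
        raise PairingError(f"unequal round counts: {n_rounds}")
    out = {}
    n_pairs = len(names) * (len(names) - 1) // 2
    for metric in metrics:
        cols = {m: np.array([r[metric] for r in cv_results[m].rounds]) for m in names}
        mat = np.column_stack(list(cols.values()))
        if np.allclose(mat, mat[:, [0]]):
            fr = {"chi2": 0.0, "p": 1.0}
        else:
            chi2, p = stats.friedmanchisquare(*[mat[:, i] for i in range(mat.shape[1])])
            fr = {"chi2": float(chi2), "p": float(p)}
        pairwise = {}
        for a, b in itertools.combinations(names, 2):
            diff = cols[a] - cols[b]
            if np.allclose(diff, 0.0):
                pairwise[(a, b)] = {"p_bonferroni": 1.0}
                continue
            _, p = stats.wilcoxon(cols[a], cols[b], zero_method="wilcox")
            pairwise[(a, b)] = {"p_bonferroni": float(min(1.0, p * n_pairs))}
        out[metric] = {"friedman": fr, "pairwise": pairwise}
    return out
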