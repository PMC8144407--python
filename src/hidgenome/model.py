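"""Group-lasso-penalized multinomial logistic regression.

The classifier maximizes

    sum_i log softmax_{c_i}(alpha + z_i' Gamma)  -  lambda * sum_l ||Gamma_l,.||_2

over class intercepts alpha (unpenalized, sum-to-zero) and the coefficient
matrix Gamma whose row l spans all K classes.  This is the maximum marginal
a posteriori estimate of a hierarchical Bayesian multinomial model in which
per-predictor coefficient vectors carry scale-mixture normal priors; the
marginal MAP collapses to the group-lasso objective above.  The L2 group
penalty selects whole predictor rows: coefficients across the K classes are
all zero or all free, which is what makes per-feature selection statements
possible.

The solver is FISTA (accelerated proximal gradient) with adaptive restart on
the standardized design, warm-started along a decreasing lambda path, and
certifies its solution with a KKT residual check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from .projection import ProjectedDesign

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# numerics

def _softmax(S: np.ndarray) -> np.ndarray:
    S = S - S.max(axis=1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=1, keepdims=True)


def _nll(alpha: np.ndarray, Gamma: np.ndarray, Z: np.ndarray, Y: np.ndarray) -> float:
    S = alpha[None, :] + Z @ Gamma
    return float(logsumexp(S, axis=1).sum() - (S * Y).sum())


def _nll_grad(alpha, Gamma, Z, Y):
    S = alpha[None, :] + Z @ Gamma
    P = _softmax(S)
    R = P - Y
    return R.sum(axis=0), Z.T @ R, P


def _penalty(Gamma: np.ndarray, lam: float) -> float:
    return lam * float(np.sqrt((Gamma**2).sum(axis=1)).sum())


def _prox_rows(G: np.ndarray, thresh: float) -> np.ndarray:
    """Row-wise group soft-threshold: shrink each row's norm by `thresh`."""
    norms = np.sqrt((G**2).sum(axis=1))
    scale = np.zeros_like(norms)
    nz = norms > thresh
    scale[nz] = 1.0 - thresh / norms[nz]
    return G * scale[:, None]


def _lipschitz(Z: np.ndarray) -> float:
    """Upper bound on the NLL gradient Lipschitz constant.

    The multinomial Hessian is bounded by 0.5 * A'A (A = [1 Z] including the
    intercept column), so L = 0.5 * sigma_max(A)^2.
    """
    A = np.hstack([np.ones((Z.shape[0], 1)), Z])
    smax = np.linalg.norm(A, 2)
    return 0.5 * smax * smax


def _fista(Z, Y, lam, alpha0, Gamma0, L, tol=1e-8, max_iter=3000, kkt_tol=1e-4):
    """FISTA with gradient-based adaptive restart; prox acts on Gamma rows."""
    alpha, Gamma = alpha0.copy(), Gamma0.copy()
    a_y, G_y = alpha.copy(), Gamma.copy()
    t = 1.0
    step = 1.0 / L
    kkt_exit = kkt_tol * max(lam, 1.0)
    for it in range(max_iter):
        ga, gG, _ = _nll_grad(a_y, G_y, Z, Y)
        alpha_new = a_y - step * ga
        Gamma_new = _prox_rows(G_y - step * gG, step * lam)
        restart = (
            (a_y - alpha_new) @ (alpha_new - alpha)
            + ((G_y - Gamma_new) * (Gamma_new - Gamma)).sum()
        ) > 0
        if restart:
            t = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        mom = (t - 1.0) / t_new
        a_y = alpha_new + mom * (alpha_new - alpha)
        G_y = Gamma_new + mom * (Gamma_new - Gamma)
        delta = max(
            np.abs(alpha_new - alpha).max(),
            np.abs(Gamma_new - Gamma).max() if Gamma.size else 0.0,
        )
        alpha, Gamma, t = alpha_new, Gamma_new, t_new
        if delta < tol * max(1.0, np.abs(Gamma).max() if Gamma.size else 1.0):
            if _kkt_max_violation(alpha, Gamma, Z, Y, lam) < kkt_exit:
                break
    return alpha, Gamma


def _kkt_max_violation(alpha, Gamma, Z, Y, lam) -> float:
    """Max KKT residual over groups and the intercept.

    Inactive group: ||grad_g|| <= lam (violation = excess).  Active group:
    grad_g + lam * Gamma_g/||Gamma_g|| = 0 (violation = residual norm).
    Intercept: ||grad_alpha||_inf (projected onto the sum-to-zero space,
    where the softmax gradient already lives).
    """
    ga, gG, _ = _nll_grad(alpha, Gamma, Z, Y)
    viol = np.abs(ga - ga.mean()).max() if ga.size else 0.0
    norms = np.sqrt((Gamma**2).sum(axis=1))
    gnorms = np.sqrt((gG**2).sum(axis=1))
    inactive = norms == 0
    if inactive.any():
        viol = max(viol, float(np.maximum(gnorms[inactive] - lam, 0.0).max()))
    active = ~inactive
    if active.any():
        resid = gG[active] + lam * Gamma[active] / norms[active, None]
        viol = max(viol, float(np.sqrt((resid**2).sum(axis=1)).max()))
    return float(viol)


# ---------------------------------------------------------------------------
# fitted model container

@dataclass
class HidGenomeModel:
    """A fitted projected hidden-genome classifier.

    ``alpha`` and ``Gamma`` are on the original predictor scale (internal
    standardization is undone before storing), so prediction is simply
    softmax(alpha + Z Gamma).  ``col_means``/``col_sds`` are the training
    moments backing the per-SD odds ratios.
    """

    classes: list[str]
    columns: list[str]
    families: list[str]
    alpha: np.ndarray                   # (K,), sum-to-zero
    Gamma: np.ndarray                   # (m, K), original scale
    lambda_: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray | None
    col_means: np.ndarray
    col_sds: np.ndarray
    seed: int | None = None
    kkt_violation: float = np.nan
    dropped_constant: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def K(self) -> int:
        return len(self.classes)

    @property
    def active_groups(self) -> np.ndarray:
        """Boolean mask: predictor rows with any nonzero coefficient."""
        return (self.Gamma != 0).any(axis=1)

    def scores(self, Z: np.ndarray) -> np.ndarray:
        if Z.shape[1] != self.Gamma.shape[0]:
            raise ValueError(
                f"design has {Z.shape[1]} columns, model expects {self.Gamma.shape[0]}"
            )
        return self.alpha[None, :] + Z @ self.Gamma


def _as_matrix(design) -> np.ndarray:
    if isinstance(design, ProjectedDesign):
        return design.dense()
    return np.asarray(design, dtype=float)


def _encode_labels(labels, train_mask):
    labels = list(labels)
    train_labels = [labels[i] for i in np.flatnonzero(train_mask)]
    classes = sorted(set(train_labels))
    lut = {c: k for k, c in enumerate(classes)}
    y = np.array([lut[lab] for lab in train_labels], dtype=np.int64)
    return y, classes


def lambda_max(Zs: np.ndarray, Y: np.ndarray) -> float:
    """Smallest lambda at which every penalized group is zero.

    At Gamma = 0 the optimal intercepts reproduce the class proportions;
    lambda_max is the largest group norm of the NLL gradient there.
    """
    props = Y.mean(axis=0)
    P0 = np.tile(props, (Y.shape[0], 1))
    G = Zs.T @ (P0 - Y)
    return float(np.sqrt((G**2).sum(axis=1)).max())


def _fit_path(Zs, Y, lams, tol, max_iter, kkt_tol=1e-4):
    """Warm-started solutions along a decreasing lambda path.

    Uses sequential strong rules with an active-set loop: at each lambda,
    FISTA runs on the groups surviving the strong-rule screen (plus all
    currently active ones); the full-gradient KKT conditions are then
    checked and any violating group is added before re-solving, so every
    returned solution satisfies the KKT system of the *full* problem.
    """
    n, m = Zs.shape
    K = Y.shape[1]
    props = Y.mean(axis=0)
    alpha0 = np.log(props) - np.log(props).mean()
    alpha, Gamma = alpha0.copy(), np.zeros((m, K))
    P0 = np.tile(props, (n, 1))
    gnorms = np.sqrt(((Zs.T @ (P0 - Y)) ** 2).sum(axis=1))
    lam_prev = float(gnorms.max()) if m else 0.0
    out = []
    for lam in lams:
        active = set(np.flatnonzero((Gamma != 0).any(axis=1)).tolist())
        strong = set(np.flatnonzero(gnorms > 2.0 * lam - lam_prev).tolist())
        E = sorted(active | strong)
        for _round in range(12):
            if E:
                idx = np.asarray(E)
                Zsub = Zs[:, idx]
                L = _lipschitz(Zsub)
                alpha, Gsub = _fista(Zsub, Y, lam, alpha, Gamma[idx], L,
                                     tol=tol, max_iter=max_iter, kkt_tol=kkt_tol)
                Gamma = np.zeros((m, K))
                Gamma[idx] = Gsub
            else:
                alpha, Gamma = alpha0.copy(), np.zeros((m, K))
            _, gG, _ = _nll_grad(alpha, Gamma, Zs, Y)
            gnorms = np.sqrt((gG**2).sum(axis=1))
            zero = (Gamma == 0).all(axis=1)
            viol = np.flatnonzero(zero & (gnorms > lam * (1.0 + 1e-4) + 1e-10))
            new = sorted(set(viol.tolist()) - set(E))
            if not new:
                break
            E = sorted(set(E) | set(new))
        out.append((alpha.copy(), Gamma.copy()))
        lam_prev = lam
    return out


def fit(
    design,
    labels,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    cv_folds: int = 5,
    seed: int = 0,
    selection: str = "min",
    tol: float = 1e-8,
    max_iter: int = 3000,
    kkt_tol: float = 1e-4,
) -> HidGenomeModel:
    """Fit the model; tune lambda by stratified cross-validated deviance.

    Parameters
    ----------
    design : ProjectedDesign or array
        Model matrix.  For a ProjectedDesign, only ``train_mask`` rows are
        fitted and moments are reused; an array is treated as all-training.
    labels : sequence
        Site label per row (ignored for non-training rows).
    lambda_grid : array, optional
        Explicit decreasing grid; default is ``n_lambda`` log-spaced values
        over [lambda_max * lambda_min_ratio, lambda_max].  A single-value
        grid skips cross-validation.
    selection : {"min", "one_se"}
        Minimum mean CV deviance, or the sparsest lambda within one SE of it.
    """
    if isinstance(design, ProjectedDesign):
        Zfull = design.dense()
        train_mask = design.train_mask
        columns, families = design.columns, design.families
        col_means, col_sds = design.col_means, design.col_sds
    else:
        Zfull = np.asarray(design, dtype=float)
        train_mask = np.ones(Zfull.shape[0], dtype=bool)
        columns = [f"z{j}" for j in range(Zfull.shape[1])]
        families = ["predictor"] * Zfull.shape[1]
        tr = Zfull
        col_means = tr.mean(axis=0)
        col_sds = tr.std(axis=0, ddof=1) if tr.shape[0] > 1 else np.ones(tr.shape[1])
    if not np.isfinite(Zfull).all():
        raise ValueError("non-finite design entries")

    y, classes = _encode_labels(labels, train_mask)
    K = len(classes)
    if K < 2:
        raise ValueError("need >= 2 classes")
    counts = np.bincount(y, minlength=K)
    for k, c in enumerate(counts):
        if c < 2:
            raise ValueError(f"class {classes[k]!r} has fewer than 2 members")

    Ztr = Zfull[train_mask]
    n, m = Ztr.shape
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    keep = col_sds > 0
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        logger.info("excluding %d constant column(s) from the fit", dropped.size)
    Zs = (Ztr[:, keep] - col_means[keep]) / col_sds[keep]

    lam_max = lambda_max(Zs, Y)
    if lambda_grid is None:
        lambda_grid = np.geomspace(lam_max, max(lam_max * lambda_min_ratio, 1e-12),
                                   n_lambda)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        if lambda_grid.size == 0:
            raise ValueError("empty lambda grid")

    cv_dev = None
    if lambda_grid.size > 1:
        if counts.min() < cv_folds:
            raise ValueError(
                f"class {classes[int(np.argmin(counts))]!r} has fewer members "
                f"than cv_folds={cv_folds}"
            )
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        dev = np.zeros((cv_folds, lambda_grid.size))
        for f, (itr, ite) in enumerate(skf.split(Zs, y)):
            Zf, Yf = Zs[itr], Y[itr]
            path = _fit_path(Zf, Yf, lambda_grid, tol, max_iter, kkt_tol)
            Zt, yt = Zs[ite], y[ite]
            for li, (a, G) in enumerate(path):
                S = a[None, :] + Zt @ G
                logp = S - logsumexp(S, axis=1, keepdims=True)
                dev[f, li] = -2.0 * logp[np.arange(len(yt)), yt].sum()
        cv_dev = dev.mean(axis=0)
        if selection == "one_se":
            se = dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)
            best = int(np.argmin(cv_dev))
            ok = np.flatnonzero(cv_dev <= cv_dev[best] + se[best])
            li_star = int(ok[0])  # grid is decreasing: first = sparsest
        else:
            li_star = int(np.argmin(cv_dev))
    else:
        li_star = 0

    path = _fit_path(Zs, Y, lambda_grid[: li_star + 1], tol, max_iter, kkt_tol)
    alpha_s, Gamma_s = path[-1]
    lam_star = float(lambda_grid[li_star])
    kkt = _kkt_max_violation(alpha_s, Gamma_s, Zs, Y, lam_star)

    # back-transform to the original predictor scale
    Gamma = np.zeros((m, K))
    Gamma[keep] = Gamma_s / col_sds[keep, None]
    alpha = alpha_s - col_means @ Gamma
    alpha = alpha - alpha.mean()

    return HidGenomeModel(
        classes=classes, columns=list(columns), families=list(families),
        alpha=alpha, Gamma=Gamma, lambda_=lam_star,
        lambda_grid=np.asarray(lambda_grid), cv_deviance=cv_dev,
        col_means=np.asarray(col_means), col_sds=np.asarray(col_sds),
        seed=seed, kkt_violation=kkt, dropped_constant=dropped,
    )


def penalized_objective(model: HidGenomeModel, design, labels) -> float:
    """Eq.-3-style objective (negative log marginal posterior) at the fitted
    solution, evaluated on the standardized training problem."""
    Zfull = _as_matrix(design)
    train_mask = (design.train_mask if isinstance(design, ProjectedDesign)
                  else np.ones(Zfull.shape[0], bool))
    y, classes = _encode_labels(labels, train_mask)
    K = len(model.classes)
    Ztr = Zfull[train_mask]
    Y = np.zeros((len(y), K))
    Y[np.arange(len(y)), y] = 1.0
    keep = model.col_sds > 0
    Zs = (Ztr[:, keep] - model.col_means[keep]) / model.col_sds[keep]
    Gs = model.Gamma[keep] * model.col_sds[keep, None]
    a_s = model.alpha + model.col_means @ model.Gamma
    return _nll(a_s, Gs, Zs, Y) + _penalty(Gs, model.lambda_)


def kkt_residual(model: HidGenomeModel, design, labels) -> float:
    """Recompute the KKT residual of a fitted model on its training rows."""
    Zfull = _as_matrix(design)
    train_mask = (design.train_mask if isinstance(design, ProjectedDesign)
                  else np.ones(Zfull.shape[0], bool))
    y, _ = _encode_labels(labels, train_mask)
    K = len(model.classes)
    Y = np.zeros((len(y), K))
    Y[np.arange(len(y)), y] = 1.0
    keep = model.col_sds > 0
    Zs = (Zfull[train_mask][:, keep] - model.col_means[keep]) / model.col_sds[keep]
    Gs = model.Gamma[keep] * model.col_sds[keep, None]
    a_s = model.alpha + model.col_means @ model.Gamma
    return _kkt_max_violation(a_s, Gs, Zs, Y, model.lambda_)


def predict_proba(model: HidGenomeModel, design) -> np.ndarray:
    """Predictive class probabilities; rows sum to 1."""
    Z = _as_matrix(design)
    return _softmax(model.scores(Z))


def pairwise_proba(probs: np.ndarray, i: int, j: int) -> np.ndarray:
    """Conditional (one-vs-one) probabilities p_i/(p_i+p_j), p_j/(p_i+p_j).

    Accepts a single probability row or an n x K table; rows with
    p_i + p_j = 0 come back as NaN (caller excludes them with a warning).
    """
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    tot = P[:, i] + P[:, j]
    out = np.full((P.shape[0], 2), np.nan)
    ok = tot > 0
    out[ok, 0] = P[ok, i] / tot[ok]
    out[ok, 1] = P[ok, j] / tot[ok]
    if (~ok).any():
        logger.warning("%d row(s) with p_i + p_j = 0 excluded", int((~ok).sum()))
    return out[0] if np.asarray(probs).ndim == 1 else out


FAMILY_ORDER_DEFAULT = ("gene", "sbs96", "region", "epigenome")
_BASELINE = ("variant", "intercept-mf")


def _column_subset(design: ProjectedDesign, fams: set[str]) -> ProjectedDesign:
    idx = np.flatnonzero(np.isin(np.asarray(design.families), list(fams)))
    Z = design.dense()[:, idx]
    import scipy.sparse as sp
    return ProjectedDesign(
        Z_variants=sp.csr_matrix((design.n, 0)),
        Z_meta=Z,
        columns=[design.columns[c] for c in idx],
        families=[design.families[c] for c in idx],
        col_means=design.col_means[idx],
        col_sds=design.col_sds[idx],
        train_mask=design.train_mask,
    )


def ablate(
    design: ProjectedDesign,
    labels,
    families: tuple[str, ...] = FAMILY_ORDER_DEFAULT,
    mode: str = "marginal",
    **fit_kwargs,
) -> dict[str, HidGenomeModel]:
    """Fit feature-family ablations of the full model.

    The baseline uses the screened variants plus the intercept meta-feature
    (sqrt total burden).  ``marginal`` adds one family at a time to the
    baseline; ``cumulative`` adds families left-to-right.  Each fit tunes its
    own lambda.
    """
    known = set(design.families)
    for f in families:
        if f not in known:
            raise ValueError(f"unknown family {f!r}")
    runs: dict[str, set[str]] = {"baseline": set(_BASELINE)}
    if mode == "marginal":
        for f in families:
            runs[f"baseline+{f}"] = set(_BASELINE) | {f}
    elif mode == "cumulative":
        acc = set(_BASELINE)
        for f in families:
            acc = acc | {f}
            runs["+".join(["baseline", *sorted(acc - set(_BASELINE))])] = set(acc)
    else:
        raise ValueError("mode must be 'marginal' or 'cumulative'")
    return {
        name: fit(_column_subset(design, fams), labels, **fit_kwargs)
        for name, fams in runs.items()
    }


def save_model(model: HidGenomeModel, path) -> None:
    np.savez_compressed(
        path,
        classes=np.array(model.classes, dtype=object),
        columns=np.array(model.columns, dtype=object),
        families=np.array(model.families, dtype=object),
        alpha=model.alpha, Gamma=model.Gamma,
        lambda_=np.array([model.lambda_]),
        lambda_grid=model.lambda_grid,
        cv_deviance=(model.cv_deviance if model.cv_deviance is not None
                     else np.array([])),
        col_means=model.col_means, col_sds=model.col_sds,
        seed=np.array([-1 if model.seed is None else model.seed]),
        kkt=np.array([model.kkt_violation]),
        dropped=model.dropped_constant,
    )


def load_model(path) -> HidGenomeModel:
    z = np.load(path, allow_pickle=True)
    cv = z["cv_deviance"]
    return HidGenomeModel(
        classes=list(z["classes"]), columns=list(z["columns"]),
        families=list(z["families"]), alpha=z["alpha"], Gamma=z["Gamma"],
        lambda_=float(z["lambda_"][0]), lambda_grid=z["lambda_grid"],
        cv_deviance=(cv if cv.size else None),
        col_means=z["col_means"], col_sds=z["col_sds"],
        seed=(None if int(z["seed"][0]) < 0 else int(z["seed"][0])),
        kkt_violation=float(z["kkt"][0]), dropped_constant=z["dropped"],
    )
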