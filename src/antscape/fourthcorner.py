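"""Trait-environment (fourth-corner) and multispecies distribution models.

Both models stack the sites x species count matrix into one long response
(one row per site-species cell) and fit a single negative-binomial
regression with a log link and the survey offset:

    log mu_ij = offset_i + a_j + x_i' b  [+ x_i' Gamma' tau_j]

where a_j are species intercepts, b environment main effects, and Gamma the
traits x environment interaction matrix (the "fourth corner"). In SDM mode
the trait matrix is the species indicator matrix, so the interaction block
becomes species-specific environmental responses. Interaction coefficients
carry an L1 (LASSO) penalty whose strength is chosen by site-stratified
cross-validation; species intercepts and environment main effects stay
unpenalized. The penalized likelihood is maximized by FISTA (accelerated
proximal gradient with backtracking), which yields exact zeros in the
penalized block. The dispersion theta is estimated once from the
unpenalized-backbone fit and held fixed along the lambda path, then
re-profiled at the selected lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nbglm import _theta_newton, nb_fit_batch, nb_loglik

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# Design


def _build_block(df: pd.DataFrame, standardize: bool = True) -> tuple[np.ndarray, list[str]]:
    """Columns for a predictor table: z-scored continuous, dummy categoricals."""
    cols, names = [], []
    for c in df.columns:
        s = df[c]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        else:
            x = s.to_numpy(dtype=float)
            if standardize:
                sd = x.std(ddof=0)
                if sd == 0:
                    raise ValueError(f"predictor {c!r} is constant")
                x = (x - x.mean()) / sd
            cols.append(x)
            names.append(c)
    return np.column_stack(cols), names


@dataclass
class StackedDesign:
    """Long-format design over (site, species) cells.

    Rows are ordered site-major (species index varies fastest). `penalized`
    marks the interaction block; `site_of_row` supports site-stratified CV.
    """

    X: np.ndarray  # N x P
    columns: list[str]
    penalized: np.ndarray  # bool mask over columns
    offset: np.ndarray  # N
    site_of_row: np.ndarray  # N integer site index
    n_sites: int
    species: list[str]
    env_names: list[str]
    trait_names: list[str]
    mode: str  # "fourth_corner" | "sdm"


def build_fourth_corner_design(
    env: pd.DataFrame,
    traits: pd.DataFrame,
    offset: pd.Series | np.ndarray,
    mode: str = "fourth_corner",
    env_mains: bool | None = None,
    standardize_traits: bool = True,
) -> StackedDesign:
    """Stack env and trait tables into the cell-level interaction design.

    ``mode="fourth_corner"``: species intercepts + env mains (unpenalized)
    + env x trait interactions (penalized). ``mode="sdm"``: species
    intercepts + env x species blocks (penalized); traits are replaced by
    the species indicator matrix and env mains are omitted (they would be
    collinear with the full indicator interaction). Passing the species
    indicator matrix as `traits` with ``standardize_traits=False`` and
    ``env_mains=False`` reproduces the SDM design exactly.
    """
    n = len(env)
    E, env_names = _build_block(env)
    species = list(traits.index)
    S = len(species)
    if mode == "sdm":
        T = np.eye(S)
        trait_names = list(map(str, species))
    elif mode == "fourth_corner":
        T, trait_names = _build_block(traits, standardize=standardize_traits)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if env_mains is None:
        env_mains = mode == "fourth_corner"

    off = np.asarray(offset, dtype=float)
    N = n * S
    # species indicators
    sp_block = np.tile(np.eye(S), (n, 1))
    blocks = [sp_block]
    names = [f"sp[{s}]" for s in species]
    pen = [False] * S
    if env_mains:
        blocks.append(np.repeat(E, S, axis=0))
        names += list(env_names)
        pen += [False] * E.shape[1]
    # interactions: env_k (site) x trait_l (species)
    env_rep = np.repeat(E, S, axis=0)  # N x p
    t_rep = np.tile(T, (n, 1))  # N x t
    inter = env_rep[:, :, None] * t_rep[:, None, :]  # N x p x t
    blocks.append(inter.reshape(N, -1))
    names += [f"{e}:{t}" for e in env_names for t in trait_names]
    pen += [True] * (E.shape[1] * T.shape[1])

    return StackedDesign(
        X=np.column_stack(blocks),
        columns=names,
        penalized=np.array(pen),
        offset=np.repeat(off, S),
        site_of_row=np.repeat(np.arange(n), S),
        n_sites=n,
        species=species,
        env_names=list(env_names),
        trait_names=list(trait_names),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Penalized NB fitting (FISTA)


def _nb_grad_eta(y, mu, theta):
    """d loglik / d eta per observation."""
    return y - (y + theta) * mu / (mu + theta)


def _smooth_obj(X, y, beta, offset, theta):
    eta = np.clip(offset + X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = nb_loglik(y[None, :], mu[None, :], np.array([theta]))[0]
    return -ll / y.size, mu


def fit_penalized_nb(
    design: StackedDesign,
    counts: pd.DataFrame,
    lam: float,
    theta: float | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> "FourthCornerFit":
    """L1-penalized NB fit at a single penalty strength.

    Minimizes -loglik/N + lam * sum |beta_penalized| by FISTA with
    backtracking; unpenalized coordinates (species intercepts, env mains)
    are never thresholded, so exact zeros appear only in the interaction
    block. `theta` defaults to the backbone estimate (see
    `estimate_backbone_theta`).
    """
    y = _stack_counts(counts, design)
    if theta is None:
        theta = estimate_backbone_theta(design, counts)
    beta, obj = _fista(design.X, y, design.offset, design.penalized, lam, theta,
                       beta0=beta0, max_iter=max_iter, tol=tol)
    _, mu = _smooth_obj(design.X, y, beta, design.offset, theta)
    ll = nb_loglik(y[None, :], mu[None, :], np.array([theta]))[0]
    return FourthCornerFit(
        design=design, coef=beta, theta=float(theta), lam=float(lam),
        loglik=float(ll), counts_index=(list(counts.index), list(counts.columns)),
    )


def _stack_counts(counts: pd.DataFrame, design: StackedDesign) -> np.ndarray:
    if list(counts.columns) != design.species:
        extra = [s for s in counts.columns if s not in design.species]
        if extra:
            raise ValueError(f"species present in counts but absent from traits: {extra}")
        counts = counts.loc[:, design.species]
    y = counts.to_numpy(dtype=float).reshape(-1)  # site-major, species fastest
    if y.size != design.X.shape[0]:
        raise ValueError("counts shape does not match design")
    return y


def _fista(X, y, offset, pen_mask, lam, theta, beta0=None, max_iter=1000, tol=1e-9):
    N, P = X.shape
    beta = np.zeros(P) if beta0 is None else beta0.copy()
    z = beta.copy()
    t_mom = 1.0
    L = 1.0
    f_z, mu = _smooth_obj(X, y, z, offset, theta)
    obj_old = np.inf
    for it in range(max_iter):
        grad = -(X.T @ _nb_grad_eta(y, mu, theta)) / N
        # backtracking on the majorization at z
        for _ in range(60):
            step = z - grad / L
            beta_new = step.copy()
            beta_new[pen_mask] = np.sign(step[pen_mask]) * np.maximum(
                np.abs(step[pen_mask]) - lam / L, 0.0
            )
            d = beta_new - z
            f_new, mu_new = _smooth_obj(X, y, beta_new, offset, theta)
            if f_new <= f_z + grad @ d + 0.5 * L * (d @ d) + 1e-14:
                break
            L *= 2.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = beta_new + ((t_mom - 1.0) / t_new) * (beta_new - beta)
        obj = f_new + lam * np.abs(beta_new[pen_mask]).sum()
        # restart acceleration if the objective rose
        if obj > obj_old + 1e-14:
            z = beta_new.copy()
            t_new = 1.0
        beta, t_mom = beta_new, t_new
        f_z, mu = _smooth_obj(X, y, z, offset, theta)
        if abs(obj_old - obj) < tol * (abs(obj) + 1.0):
            break
        obj_old = obj
        L = max(L / 1.5, 1e-4)
    return beta, obj


def estimate_backbone_theta(design: StackedDesign, counts: pd.DataFrame) -> float:
    """Dispersion from the unpenalized backbone (interactions at zero)."""
    y = _stack_counts(counts, design)
    Xb = design.X[:, ~design.penalized]
    _, th, _, _ = nb_fit_batch(Xb, y[None, :], design.offset)
    return float(th[0])


def lambda_grid(
    design: StackedDesign, counts: pd.DataFrame, theta: float | None = None,
    n_points: int = 50, decades: float = 4.0,
) -> np.ndarray:
    """Log-spaced grid from lambda_max (all interactions zero) downward.

    lambda_max is the largest absolute penalized-score component at the
    backbone fit; above it the soft-threshold step keeps every interaction
    at exactly zero.
    """
    y = _stack_counts(counts, design)
    if theta is None:
        theta = estimate_backbone_theta(design, counts)
    Xb = design.X[:, ~design.penalized]
    bb, _, _, _ = nb_fit_batch(Xb, y[None, :], design.offset)
    beta = np.zeros(design.X.shape[1])
    beta[~design.penalized] = bb[0]
    eta = np.clip(design.offset + design.X @ beta, -_ETA_CLIP, _ETA_CLIP)
    g = design.X[:, design.penalized].T @ _nb_grad_eta(y, np.exp(eta), theta) / y.size
    lam_max = float(np.max(np.abs(g))) * 1.05 + 1e-12
    return np.geomspace(lam_max, lam_max * 10 ** (-decades), n_points)


@dataclass
class FourthCornerFit:
    """A penalized stacked-NB fit (SDM or fourth-corner mode)."""

    design: StackedDesign
    coef: np.ndarray
    theta: float
    lam: float
    loglik: float
    counts_index: tuple[list, list] | None = None
    cv_path: pd.DataFrame | None = None
    pseudo_r2: float | None = None

    def interaction_matrix(self) -> pd.DataFrame:
        """Traits x environment coefficient matrix (standardized scale)."""
        g = self.coef[self.design.penalized]
        mat = g.reshape(len(self.design.env_names), len(self.design.trait_names)).T
        return pd.DataFrame(mat, index=self.design.trait_names, columns=self.design.env_names)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.coef[self.design.penalized] != 0.0))


def cv_select_lambda(
    design: StackedDesign,
    counts: pd.DataFrame,
    k_folds: int = 5,
    lam_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    seed: int | None = None,
) -> "FourthCornerFit":
    """Choose lambda by site-stratified K-fold CV and refit on all data.

    All cells of a site share a fold. For each fold the path is fitted on
    the training sites (warm starts from larger lambda) with theta fixed at
    the training backbone estimate; lambda* maximizes the mean held-out NB
    log-likelihood per cell, ties resolved toward the sparser (larger)
    lambda. The final fit re-profiles theta at lambda*.
    """
    n = design.n_sites
    if n < k_folds:
        raise ValueError(f"need at least {k_folds} sites for {k_folds}-fold CV")
    y = _stack_counts(counts, design)
    theta_all = estimate_backbone_theta(design, counts)
    if lam_grid is None:
        lam_grid = lambda_grid(design, counts, theta=theta_all, n_points=n_lambda)
    rng = np.random.default_rng(seed)
    fold_of_site = np.zeros(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k_folds)):
        fold_of_site[chunk] = f

    held_out = np.zeros((k_folds, len(lam_grid)))
    for f in range(k_folds):
        test_rows = np.isin(design.site_of_row, np.where(fold_of_site == f)[0])
        tr = ~test_rows
        Xtr, ytr, otr = design.X[tr], y[tr], design.offset[tr]
        Xte, yte, ote = design.X[test_rows], y[test_rows], design.offset[test_rows]
        _, th_tr_arr, _, _ = nb_fit_batch(Xtr[:, ~design.penalized], ytr[None, :], otr)
        th_tr = float(th_tr_arr[0])
        beta = None
        for i, lam in enumerate(lam_grid):
            beta, _ = _fista(Xtr, ytr, otr, design.penalized, lam, th_tr,
                             beta0=beta, max_iter=500, tol=1e-8)
            eta = np.clip(ote + Xte @ beta, -_ETA_CLIP, _ETA_CLIP)
            ll = nb_loglik(yte[None, :], np.exp(eta)[None, :], np.array([th_tr]))[0]
            held_out[f, i] = ll / yte.size

    mean_ll = held_out.mean(axis=0)
    best = int(np.argmax(mean_ll + 1e-12 * np.arange(len(lam_grid), 0, -1)))
    # tie toward larger lambda: scan from the largest-lambda end
    tol_tie = 1e-10 * (1 + abs(mean_ll[best]))
    for i in range(len(lam_grid)):
        if mean_ll[i] >= mean_ll[best] - tol_tie:
            best = i
            break

    # warm-started path on the full data down to lambda*
    beta = None
    for lam in lam_grid[: best + 1]:
        beta, _ = _fista(design.X, y, design.offset, design.penalized, lam,
                         theta_all, beta0=beta, max_iter=800, tol=1e-9)
    # re-profile theta at lambda*, then polish
    eta = np.clip(design.offset + design.X @ beta, -_ETA_CLIP, _ETA_CLIP)
    theta_star = float(_theta_newton(y[None, :], np.exp(eta)[None, :],
                                     np.array([theta_all]), n_steps=8)[0])
    beta, _ = _fista(design.X, y, design.offset, design.penalized,
                     lam_grid[best], theta_star, beta0=beta, max_iter=800, tol=1e-10)
    eta = np.clip(design.offset + design.X @ beta, -_ETA_CLIP, _ETA_CLIP)
    ll = float(nb_loglik(y[None, :], np.exp(eta)[None, :], np.array([theta_star]))[0])

    # McFadden pseudo-R2 against the species-intercepts-only model
    S = len(design.species)
    X0 = design.X[:, :S]
    _, _, ll0, _ = nb_fit_batch(X0, y[None, :], design.offset)
    r2 = float(1.0 - ll / ll0[0]) if ll0[0] != 0 else np.nan

    fit = FourthCornerFit(
        design=design, coef=beta, theta=theta_star, lam=float(lam_grid[best]),
        loglik=ll, counts_index=(list(counts.index), list(counts.columns)),
        cv_path=pd.DataFrame({"lambda": lam_grid, "mean_heldout_ll": mean_ll}),
        pseudo_r2=r2,
    )
    return fit


def standardized_coefficients(fit: FourthCornerFit) -> pd.DataFrame:
    """Heatmap-ready coefficient matrix on the standardized-predictor scale.

    Rows are traits (fourth-corner mode) or species (SDM mode); columns are
    environment predictors. Positive entries mean density increases with the
    predictor (or with the trait-predictor combination).
    """
    return fit.interaction_matrix()
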