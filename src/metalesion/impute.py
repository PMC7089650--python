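"""Probabilistic PCA imputation of incomplete score batteries.

A battery of correlated neuropsychological instruments with missing entries
is modelled as a Gaussian latent-factor model,

    x_i = mu + W t_i + eps_i,   t_i ~ N(0, I_k),  eps_i ~ N(0, sigma^2 I_d),

fitted by expectation-maximization over both the latent factors and the
missing entries (instruments are z-scored on their observed entries first,
since IQ points and affect-scale points are incommensurate).  Missing
entries are then singly imputed by their posterior expectation
(back-projection through W) and returned in original units.  The EM variant
used is ECM — mu, then the rows of W, then sigma^2, each maximized against
the same E-step posterior — which preserves the monotone observed-data
log-likelihood guarantee; monotonicity is asserted at every iteration.

Usage follows the Model/Results convention::

    results = PPCA(scores, k=3).fit(seed=0)
    completed = results.impute(scores)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ScoreTable

__all__ = ["PPCA", "PPCAResults", "fit_ppca", "impute", "select_k"]

_SIGMA2_FLOOR = 1e-12


def _as_score_table(scores) -> ScoreTable:
    if isinstance(scores, ScoreTable):
        return scores
    return ScoreTable(pd.DataFrame(scores))


class PPCA:
    """Probabilistic-PCA model of an incomplete score battery.

    Parameters
    ----------
    scores : ScoreTable or DataFrame
        Subjects x instruments, NaN = missing.
    k : int
        Latent dimension; must satisfy ``1 <= k < n_instruments``.
    """

    def __init__(self, scores, k: int) -> None:
        self.scores = _as_score_table(scores)
        d = self.scores.n_instruments
        if not 1 <= int(k) < d:
            raise ValueError(f"k must satisfy 1 <= k < {d}, got {k}")
        self.k = int(k)
        unusable_cols = self.scores.unusable()["instruments"]
        if unusable_cols:
            raise ValueError(f"instruments with no observed entries: {unusable_cols}")

    # -- internals ---------------------------------------------------------

    def _standardize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        Y = self.scores.values.to_numpy(dtype=float)
        obs = np.isfinite(Y)
        mu0 = np.nanmean(Y, axis=0)
        sd0 = np.nanstd(Y, axis=0, ddof=0)
        sd0 = np.where(sd0 > 0, sd0, 1.0)
        Z = (Y - mu0) / sd0
        return Z, obs, mu0, sd0

    @staticmethod
    def _e_step(
        Z: np.ndarray, obs: np.ndarray, W: np.ndarray, mu: np.ndarray, s2: float
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Posterior latent moments and observed-data log-likelihood.

        Batched over subjects: per-subject k x k posterior precisions are
        assembled with einsum and inverted in one vectorized call; the
        marginal likelihood uses the matrix determinant/inversion lemmas so
        only k x k factorizations are needed.
        """
        n, d = Z.shape
        k = W.shape[1]
        obs_f = obs.astype(float)
        R = np.where(obs, Z - mu[None, :], 0.0)  # residuals, zero at missing
        M = np.einsum("jk,ij,jl->ikl", W, obs_f, W) + s2 * np.eye(k)[None]
        Minv = np.linalg.inv(M)
        WtR = R @ W  # (n, k): sum over observed entries only
        Et = np.einsum("ikl,il->ik", Minv, WtR)
        Vt = s2 * Minv
        no = obs.sum(axis=1)
        _, logdet_M = np.linalg.slogdet(M / s2)
        logdet_C = no * math.log(s2) + logdet_M
        quad = ((R**2).sum(axis=1) - np.einsum("ik,ikl,il->i", WtR, Minv, WtR)) / s2
        ll = float(-0.5 * (no * math.log(2 * math.pi) + logdet_C + quad).sum())
        return Et, Vt, ll

    def fit(
        self,
        tol: float = 1e-6,
        max_iter: int = 500,
        seed: int | None = 0,
    ) -> "PPCAResults":
        """Run EM until the relative log-likelihood change drops below
        ``tol`` or ``max_iter`` iterations; ``seed`` jitters the PCA
        initialization to break ties."""
        Z, obs, mu0, sd0 = self._standardize()
        n, d = Z.shape
        k = self.k
        if n < 2:
            raise ValueError("PPCA requires at least 2 subjects")

        # init: classical PCA of the mean-filled (zero-filled after z-score)
        # matrix, sigma2 from the discarded spectrum, seeded jitter
        Z0 = np.where(obs, Z, 0.0)
        cov = Z0.T @ Z0 / max(n - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        s2 = float(np.clip(evals[k:].mean() if d > k else 0.1, _SIGMA2_FLOOR, None))
        W = evecs[:, :k] * np.sqrt(np.clip(evals[:k] - s2, 1e-8, None))
        if seed is not None:
            rng = np.random.default_rng(seed)
            W = W + 1e-8 * rng.standard_normal(W.shape)
        mu = np.zeros(d)

        loglik_path: list[float] = []
        converged = False
        Et, Vt, ll = self._e_step(Z, obs, W, mu, s2)
        loglik_path.append(ll)
        for _ in range(int(max_iter)):
            T2 = Vt + np.einsum("ik,il->ikl", Et, Et)  # <t t^T> per subject
            A = T2.sum(axis=0)  # sum <t t^T>, (k, k)

            # CM-1: mu (W, sigma2 fixed at current values)
            Wt = Et @ W.T  # (n, d): W_j <t_i>
            contrib = np.where(obs, Z - Wt, mu[None, :])
            mu_new = contrib.mean(axis=0)

            # CM-2: rows of W (mu = mu_new, sigma2 fixed)
            R = np.where(obs, Z - mu_new[None, :], 0.0)
            B = R.T @ Et  # observed part of sum <(x - mu) t^T>
            # missing part: (xhat - mu_new) <t>^T + W_old V_i  per entry
            xhat_c = (mu - mu_new)[None, :] + Wt  # posterior mean minus mu_new
            miss = ~obs
            B += (np.where(miss, xhat_c, 0.0)).T @ Et
            Vsum_missing = np.einsum("ij,ikl->jkl", miss.astype(float), Vt)
            B += np.einsum("jl,jlk->jk", W, Vsum_missing)
            W_new = np.linalg.solve(A.T, B.T).T

            # CM-3: sigma2 (mu_new, W_new)
            WT2W = np.einsum("jk,ikl,jl->ij", W_new, T2, W_new)  # (n, d)
            res_obs = np.where(obs, (Z - mu_new[None, :]) ** 2, 0.0)
            cross = np.where(obs, (Z - mu_new[None, :]) * (Et @ W_new.T), 0.0)
            sq_obs = (res_obs - 2 * cross + np.where(obs, WT2W, 0.0)).sum()
            dmu = mu - mu_new
            dW = W - W_new
            lin = dmu[None, :] + Et @ dW.T  # (n, d)
            dWVdW = np.einsum("jk,ikl,jl->ij", dW, Vt, dW)
            sq_mis = (np.where(miss, lin**2 + dWVdW + s2, 0.0)).sum()
            s2_new = float(max((sq_obs + sq_mis) / (n * d), _SIGMA2_FLOOR))

            mu, W, s2 = mu_new, W_new, s2_new
            Et, Vt, ll = self._e_step(Z, obs, W, mu, s2)
            prev = loglik_path[-1]
            if s2 <= 100 * _SIGMA2_FLOOR:
                # degenerate noiseless solution: the likelihood is unbounded
                # in sigma^2 -> 0 and loses numerical monotonicity; stop here
                loglik_path.append(max(ll, prev))
                converged = True
                break
            if ll < prev - 1e-7 * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {prev} -> {ll}"
                )
            loglik_path.append(ll)
            if not np.isfinite(tol):
                # a non-finite tolerance cannot certify convergence: stop
                # after a single accepted iteration, flag unconverged
                break
            if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break

        return PPCAResults(
            model=self,
            W=W,
            mu=mu,
            sigma2=s2,
            k=k,
            converged=converged,
            loglik=float(loglik_path[-1]),
            loglik_path=np.asarray(loglik_path),
            instruments=list(self.scores.instruments),
            scale_mean=mu0,
            scale_sd=sd0,
        )


@dataclass
class PPCAResults:
    """Fitted PPCA parameters plus the standardization statistics.

    ``W`` (instruments x k) and ``mu`` live on the z-scored scale;
    ``scale_mean``/``scale_sd`` restore original units.
    """

    model: PPCA
    W: np.ndarray
    mu: np.ndarray
    sigma2: float
    k: int
    converged: bool
    loglik: float
    loglik_path: np.ndarray
    instruments: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    provenance: pd.DataFrame | None = field(default=None, repr=False)

    def latent_posterior(self, scores: ScoreTable) -> np.ndarray:
        """Posterior mean of the latent factors for each subject."""
        table = _as_score_table(scores)
        self._check_compatible(table)
        Y = table.values.to_numpy(dtype=float)
        Z = (Y - self.scale_mean) / self.scale_sd
        obs = np.isfinite(Z)
        Et, _, _ = PPCA._e_step(Z, obs, self.W, self.mu, self.sigma2)
        return Et

    def impute(self, scores: ScoreTable | None = None) -> ScoreTable:
        """Replace missing entries by their posterior expectation.

        Observed entries are returned untouched; imputations are
        back-projected through ``W`` and de-standardized to original units.
        A per-entry provenance table (observed | imputed) is stored on
        ``self.provenance``.
        """
        table = _as_score_table(scores) if scores is not None else self.model.scores
        self._check_compatible(table)
        Y = table.values.to_numpy(dtype=float)
        Z = (Y - self.scale_mean) / self.scale_sd
        obs = np.isfinite(Z)
        Et, _, _ = PPCA._e_step(Z, obs, self.W, self.mu, self.sigma2)
        Zhat = self.mu[None, :] + Et @ self.W.T
        # observed entries pass through bitwise untouched; only imputations
        # are de-standardized
        Y_completed = np.where(obs, Y, Zhat * self.scale_sd + self.scale_mean)
        out = table.copy()
        out.values.iloc[:, :] = Y_completed
        self.provenance = pd.DataFrame(
            np.where(obs, "observed", "imputed"),
            index=table.values.index,
            columns=table.values.columns,
        )
        return out

    def _check_compatible(self, table: ScoreTable) -> None:
        if list(table.instruments) != self.instruments:
            raise ValueError(
                "instrument set does not match the fitted model: "
                f"{table.instruments} vs {self.instruments}"
            )

    def summary(self) -> str:
        lines = [
            "Probabilistic PCA (EM with missing data)",
            f"  instruments: {len(self.instruments)}   latent dimension k: {self.k}",
            f"  noise variance sigma^2 (z-scored scale): {self.sigma2:.6g}",
            f"  log-likelihood: {self.loglik:.4f}   converged: {self.converged} "
            f"({len(self.loglik_path) - 1} EM iterations)",
            "  loading matrix W (z-scored scale):",
        ]
        for name, row in zip(self.instruments, self.W):
            lines.append(
                "    " + f"{name:>20s}  " + "  ".join(f"{v:+.3f}" for v in row)
            )
        return "\n".join(lines)


def fit_ppca(
    scores,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = 0,
) -> PPCAResults:
    """Functional wrapper: fit PPCA with latent dimension ``k``."""
    return PPCA(scores, k).fit(tol=tol, max_iter=max_iter, seed=seed)


def impute(scores, model: PPCAResults) -> ScoreTable:
    """Functional wrapper around :meth:`PPCAResults.impute`."""
    return model.impute(_as_score_table(scores))


def select_k(
    scores,
    k_grid=range(1, 9),
    n_folds_of_masked_entries: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> int:
    """Choose the latent dimension by held-out entry-masking cross-validation.

    In each fold, 10% of the observed entries are additionally masked; each
    candidate ``k`` is fitted on the degraded table and scored by RMSE of
    its imputations against the held-out values.  Returns the smallest ``k``
    whose mean held-out RMSE is within one standard error (across folds) of
    the overall minimum — the usual parsimony rule, which keeps the latent
    dimension from creeping upward on the shallow tail of the CV curve.
    """
    table = _as_score_table(scores)
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if len(k_grid) == 1:
        return int(k_grid[0])
    Y = table.values.to_numpy(dtype=float)
    obs_idx = np.argwhere(np.isfinite(Y))
    rng = np.random.default_rng(seed)
    errors = np.zeros((len(k_grid), n_folds_of_masked_entries))
    for f in range(n_folds_of_masked_entries):
        n_mask = max(1, int(round(0.10 * len(obs_idx))))
        sel = obs_idx[rng.choice(len(obs_idx), size=n_mask, replace=False)]
        degraded = Y.copy()
        held = Y[sel[:, 0], sel[:, 1]]
        degraded[sel[:, 0], sel[:, 1]] = np.nan
        deg_table = ScoreTable(
            pd.DataFrame(
                degraded, index=table.values.index, columns=table.values.columns
            ),
            dict(table.higher_is_worse),
        )
        for a, k in enumerate(k_grid):
            try:
                res = PPCA(deg_table, int(k)).fit(
                    tol=tol, max_iter=max_iter, seed=int(rng.integers(2**31 - 1))
                )
                completed = res.impute(deg_table)
                pred = completed.values.to_numpy()[sel[:, 0], sel[:, 1]]
                errors[a, f] = float(np.sqrt(np.mean((pred - held) ** 2)))
            except (ValueError, RuntimeError):
                errors[a, f] = np.inf
    mean_err = errors.mean(axis=1)
    best = int(np.argmin(mean_err))
    if not np.isfinite(mean_err[best]):
        raise ValueError("every candidate k failed to fit")
    se = (
        errors[best].std(ddof=1) / np.sqrt(n_folds_of_masked_entries)
        if n_folds_of_masked_entries > 1
        else 0.0
    )
    order = np.argsort(k_grid)
    for a in order:  # smallest k within one SE of the minimum
        if mean_err[a] <= mean_err[best] + se:
            return int(k_grid[int(a)])
    return int(k_grid[best])
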