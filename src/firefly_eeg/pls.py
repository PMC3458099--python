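"""Task partial least squares for condition contrasts with permutation and bootstrap.

The data block is a (subjects, conditions, cells) array where each cell is one
(channel, time) measurement averaged within subject and condition.  The
condition means (averaged over subjects) are deviation-coded (centered across
conditions) and decomposed by SVD; this is the SVD of the covariance between
the condition design and the dependent measures.  Each latent variable (LV)
gets

* a singular value (share of cross-block covariance),
* a permutation p-value: condition labels are re-shuffled independently within
  each subject and p = (1 + #{permuted s_k >= observed s_k}) / (n_perm + 1),
* per-cell saliences (unit-norm right singular vectors) with bootstrap
  standard errors from resampling subjects with replacement (conditions kept
  fixed, saliences sign-aligned to the original SVD), and salience/SE
  "bootstrap ratios", a z-score-like reliability metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DataError

__all__ = ["PLSResult", "PLSContrast", "pls_contrast", "permutation_p", "bootstrap_ratios"]

logger = logging.getLogger(__name__)


@dataclass
class PLSResult:
    """Result container mirroring the fitted attributes of :class:`PLSContrast`."""

    singular_values: np.ndarray  # (n_lv,), non-increasing
    condition_saliences: np.ndarray  # (n_conditions, n_lv)
    saliences: np.ndarray  # (n_lv, n_cells), unit rows
    permutation_p: np.ndarray | None  # (n_lv,)
    bootstrap_se: np.ndarray | None  # (n_cells,) for LV1
    bootstrap_ratios: np.ndarray | None  # (n_cells,) for LV1
    n_permutations: int
    n_bootstraps: int


def _validate(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:  # single cell measure per condition
        X = X[:, :, None]
    if X.ndim != 3:
        raise DataError("X must be (n_subjects, n_conditions, n_cells)")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise DataError("need at least 2 subjects and 2 conditions")
    if not np.isfinite(X).all():
        raise DataError("X contains non-finite values")
    return X


def _cross_block(X: np.ndarray) -> np.ndarray:
    """Deviation-coded condition means: (n_conditions, n_cells), centered across conditions."""
    M = X.mean(axis=0)
    return M - M.mean(axis=0, keepdims=True)


class PLSContrast(BaseEstimator):
    """Mean-centered task PLS over (subjects, conditions, cells) data.

    Parameters
    ----------
    n_permutations : permutations for LV significance (0 disables).
    n_bootstraps : bootstrap resamples for salience reliability (0 disables).
    random_state : seed for both resampling schemes (deterministic given seed).

    Fitted attributes
    -----------------
    singular_values_, condition_saliences_, saliences_, permutation_pvalues_,
    bootstrap_se_, bootstrap_ratios_, n_skipped_bootstraps_.
    Bootstrap SE/ratios are reported for the first (dominant) LV.
    """

    def __init__(self, n_permutations: int = 1000, n_bootstraps: int = 1000,
                 random_state: int | None = None):
        self.n_permutations = n_permutations
        self.n_bootstraps = n_bootstraps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _validate(X)
        n_sub, n_cond, n_cells = X.shape
        R = _cross_block(X)
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        self.singular_values_ = s
        self.condition_saliences_ = U
        self.saliences_ = Vt
        self.n_lv_ = s.size
        rng = np.random.default_rng(self.random_state)

        if self.n_permutations:
            if self.n_permutations < 100:
                raise DataError("need at least 100 permutations")
            count = np.zeros(s.size)
            for _ in range(self.n_permutations):
                Xp = np.empty_like(X)
                for j in range(n_sub):  # re-order conditions within each subject
                    Xp[j] = X[j, rng.permutation(n_cond)]
                sp = np.linalg.svd(_cross_block(Xp), compute_uv=False)
                count += sp >= s
            self.permutation_pvalues_ = (1.0 + count) / (self.n_permutations + 1.0)
        else:
            self.permutation_pvalues_ = None

        if self.n_bootstraps:
            if n_sub < 5:
                raise DataError("need at least 5 subjects for bootstrap")
            boots = np.empty((self.n_bootstraps, n_cells))
            skipped = 0
            b = 0
            while b < self.n_bootstraps:
                idx = rng.integers(0, n_sub, size=n_sub)
                if np.all(idx == idx[0]):  # degenerate resample: one subject only
                    skipped += 1
                    continue
                Rb = _cross_block(X[idx])
                _, _, Vtb = np.linalg.svd(Rb, full_matrices=False)
                v = Vtb[0]
                if np.dot(v, Vt[0]) < 0:  # SVD sign indeterminacy
                    v = -v
                boots[b] = v
                b += 1
            if skipped:
                logger.info("skipped %d degenerate bootstrap resamples", skipped)
            se = boots.std(axis=0, ddof=1)
            self.bootstrap_se_ = se
            ratios = np.empty(n_cells)
            pos = se > 0
            ratios[pos] = Vt[0][pos] / se[pos]
            # zero sampling variance: infinitely reliable unless the salience is 0 too
            degenerate = np.sign(Vt[0][~pos])
            ratios[~pos] = np.where(degenerate > 0, np.inf, np.where(degenerate < 0, -np.inf, 0.0))
            self.bootstrap_ratios_ = ratios
            self.n_skipped_bootstraps_ = skipped
        else:
            self.bootstrap_se_ = None
            self.bootstrap_ratios_ = None
            self.n_skipped_bootstraps_ = 0
        return self

    def result(self) -> PLSResult:
        return PLSResult(
            singular_values=self.singular_values_,
            condition_saliences=self.condition_saliences_,
            saliences=self.saliences_,
            permutation_p=self.permutation_pvalues_,
            bootstrap_se=self.bootstrap_se_,
            bootstrap_ratios=self.bootstrap_ratios_,
            n_permutations=self.n_permutations,
            n_bootstraps=self.n_bootstraps,
        )


def pls_contrast(data: np.ndarray) -> PLSResult:
    """Singular values and saliences of the condition contrast (no resampling)."""
    est = PLSContrast(n_permutations=0, n_bootstraps=0).fit(data)
    return est.result()


def permutation_p(data: np.ndarray, n_perm: int = 1000, seed: int | None = None) -> np.ndarray:
    """Permutation p-value per latent variable (add-one estimator)."""
    est = PLSContrast(n_permutations=n_perm, n_bootstraps=0, random_state=seed).fit(data)
    return est.permutation_pvalues_


def bootstrap_ratios(data: np.ndarray, n_boot: int = 1000, seed: int | None = None) -> np.ndarray:
    """Salience / bootstrap-SE ratio per cell for the dominant latent variable."""
    est = PLSContrast(n_permutations=0, n_bootstraps=n_boot, random_state=seed).fit(data)
    return est.bootstrap_ratios_
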