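"""Partial least squares correlation (PLSC) between two data blocks.

Given a brain matrix X (subjects x measures, here age-adjusted deviation
scores) and a behavior matrix Y (subjects x dichotomous risk factors), both
blocks are z-scored across subjects and the cross-correlation matrix

    R = Y_z^T X_z / (n - 1)

is decomposed by SVD, R = U S V, following the convention that behavior
saliences are the columns of U (n_behavior x n_comp) and brain saliences the
rows of V (n_comp x n_measures). Each singular value s_k measures the
correlation captured by component k; s_k^2 / sum(s^2) is its explained
correlation fraction. Component significance comes from a permutation test
that breaks the subject correspondence between the blocks (Y rows permuted),
comparing the k-th largest permuted singular value against the k-th observed.
Salience stability comes from bootstrap resampling of subjects: bootstrap
score = mean / sd of the (sign-aligned) bootstrap distribution of each
weight, with |score| > 1.96 flagging a robust contributor. Subject latent
scores are the projections L_X = X_z V^T and L_Y = Y_z U, and the component
correlation r_k is the Pearson correlation between paired latent scores.

Sign convention: each component is flipped so that its largest-magnitude
behavior salience is positive; bootstrap components are sign-aligned to the
full-sample reference by the dot product of their stacked saliences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSComponent",
    "BootstrapSummary",
    "LatentScores",
    "PLSResult",
    "zscore_columns",
    "cross_correlation",
    "svd_components",
    "permutation_test",
    "bootstrap_weights",
    "latent_scores",
    "pls_correlation",
]

logger = logging.getLogger(__name__)

STABILITY_THRESHOLD = 1.96  # |bootstrap score| above this ~ 95% robustness


def _as_array(M, what: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), [str(c) for c in M.columns]
    A = np.asarray(M, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{what} must be 2-D")
    return A, [f"{what}{j}" for j in range(A.shape[1])]


def zscore_columns(M) -> np.ndarray:
    """Standardize each column to mean 0, sample sd 1 (n-1 denominator)."""
    A, names = _as_array(M, "col")
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ValueError(f"constant column(s): {[names[j] for j in bad]}")
    return (A - A.mean(axis=0)) / sd


def cross_correlation(Xz: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """R = Yz^T Xz / (n-1): Pearson correlations of behavior x brain pairs."""
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    if Xz.shape[0] != Yz.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    n = Xz.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    return Yz.T @ Xz / (n - 1)


@dataclass(frozen=True)
class PLSComponent:
    index: int
    singular_value: float
    behavior_saliences: np.ndarray  # length n_behavior (column of U)
    brain_saliences: np.ndarray  # length n_measures (row of V)
    explained_correlation: float
    perm_p: float = np.nan


def _apply_sign_convention(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip components so the largest-|.| behavior salience is positive."""
    U = U.copy()
    V = V.copy()
    for k in range(U.shape[1]):
        lead = np.argmax(np.abs(U[:, k]))
        if U[lead, k] < 0:
            U[:, k] = -U[:, k]
            V[k, :] = -V[k, :]
    return U, V


def _svd(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, s, V = np.linalg.svd(R, full_matrices=False)
    U, V = _apply_sign_convention(U, V)
    return U, s, V


def svd_components(R: np.ndarray) -> list[PLSComponent]:
    """SVD of the cross-correlation matrix; min(R.shape) components in
    descending singular-value order, sign convention applied."""
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix contains non-finite entries")
    U, s, V = _svd(R)
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.full_like(s, np.nan)
    return [
        PLSComponent(
            index=k,
            singular_value=float(s[k]),
            behavior_saliences=U[:, k].copy(),
            brain_saliences=V[k, :].copy(),
            explained_correlation=float(frac[k]),
        )
        for k in range(s.size)
    ]


def permutation_test(
    Xz: np.ndarray,
    Yz: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permutation p-value per component.

    Rows of Yz are permuted (breaking the subject pairing), the singular
    values recomputed, and the k-th largest permuted value compared with the
    k-th observed: p_k = (1 + #{s_perm_k >= s_obs_k}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    n = Xz.shape[0]
    if n <= 3:
        raise ValueError("too few subjects for a permutation test")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s_obs = np.linalg.svd(cross_correlation(Xz, Yz), compute_uv=False)
    exceed = np.zeros(s_obs.size)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_perm = np.linalg.svd(cross_correlation(Xz, Yz[perm]), compute_uv=False)
        exceed += s_perm >= s_obs
    return (1.0 + exceed) / (1.0 + n_perm)


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap distributions of the saliences, per component.

    Arrays are (n_components, n_variables); ``behavior_*`` for the 5 risk
    factors, ``brain_*`` for the measures.
    """

    behavior_mean: np.ndarray
    behavior_sd: np.ndarray
    brain_mean: np.ndarray
    brain_sd: np.ndarray
    n_boot: int
    n_redrawn: int = 0

    @property
    def behavior_score(self) -> np.ndarray:
        return _safe_ratio(self.behavior_mean, self.behavior_sd)

    @property
    def brain_score(self) -> np.ndarray:
        return _safe_ratio(self.brain_mean, self.brain_sd)

    @property
    def behavior_stable(self) -> np.ndarray:
        return np.abs(self.behavior_score) > STABILITY_THRESHOLD

    @property
    def brain_stable(self) -> np.ndarray:
        return np.abs(self.brain_score) > STABILITY_THRESHOLD


def _safe_ratio(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf * np.sign(mean))
    return out


def bootstrap_weights(
    Xz: np.ndarray,
    Yz: np.ndarray,
    reference: list[PLSComponent],
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 10000,
) -> BootstrapSummary:
    """Bootstrap stability of the saliences.

    Each resample draws subjects with replacement, re-standardizes both
    blocks, recomputes R and its SVD, and sign-aligns every component to the
    full-sample reference (flip when the dot product of the stacked behavior
    and brain saliences with the reference is negative). Resamples in which
    a behavior column is constant cannot be standardized and are redrawn
    (counted in ``n_redrawn``).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    n = Xz.shape[0]
    if np.unique(Xz, axis=0).shape[0] < 3:
        raise ValueError("too few distinct subjects to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    U_ref = np.column_stack([c.behavior_saliences for c in reference])
    V_ref = np.vstack([c.brain_saliences for c in reference])
    ncomp = len(reference)

    Us = np.empty((n_boot, U_ref.shape[0], ncomp))
    Vs = np.empty((n_boot, ncomp, V_ref.shape[1]))
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Yb = Yz[idx]
        # ptp == 0 is an exact constancy test; std of identical floats can
        # round to a tiny nonzero value
        if np.any(np.ptp(Yb, axis=0) == 0) or np.any(np.ptp(Xz[idx], axis=0) == 0):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        Rb = cross_correlation(zscore_columns(Xz[idx]), zscore_columns(Yb))
        Ub, _, Vb = _svd(Rb)
        for k in range(ncomp):
            if Ub[:, k] @ U_ref[:, k] + Vb[k] @ V_ref[k] < 0:
                Ub[:, k] = -Ub[:, k]
                Vb[k] = -Vb[k]
        Us[b] = Ub[:, :ncomp]
        Vs[b] = Vb[:ncomp]
        b += 1
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resample(s)", redrawn)

    return BootstrapSummary(
        behavior_mean=Us.mean(axis=0).T,  # (ncomp, n_behavior)
        behavior_sd=Us.std(axis=0, ddof=1).T,
        brain_mean=Vs.mean(axis=0),
        brain_sd=Vs.std(axis=0, ddof=1),
        n_boot=n_boot,
        n_redrawn=redrawn,
    )


@dataclass(frozen=True)
class LatentScores:
    L_X: np.ndarray  # subjects x n_components brain scores
    L_Y: np.ndarray  # subjects x n_components behavior scores
    r: np.ndarray  # Pearson correlation per component


def latent_scores(Xz: np.ndarray, Yz: np.ndarray, components: list[PLSComponent]) -> LatentScores:
    """Subject projections L_X = Xz V^T, L_Y = Yz U and their correlations."""
    U = np.column_stack([c.behavior_saliences for c in components])
    V = np.vstack([c.brain_saliences for c in components])
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    if Xz.shape[1] != V.shape[1] or Yz.shape[1] != U.shape[0]:
        raise ValueError("component dimensions do not match the data blocks")
    L_X = Xz @ V.T
    L_Y = Yz @ U
    r = np.array(
        [np.corrcoef(L_X[:, k], L_Y[:, k])[0, 1] for k in range(U.shape[1])]
    )
    return LatentScores(L_X=L_X, L_Y=L_Y, r=r)


@dataclass
class PLSResult:
    """Complete PLSC analysis of one (X, Y) pair."""

    components: list[PLSComponent]
    bootstrap: BootstrapSummary
    scores: LatentScores
    R: np.ndarray
    n_subjects: int
    n_perm: int
    n_boot: int
    seed: int
    brain_labels: list[str] = field(default_factory=list)
    behavior_labels: list[str] = field(default_factory=list)

    @property
    def singular_values(self) -> np.ndarray:
        return np.array([c.singular_value for c in self.components])

    @property
    def perm_p(self) -> np.ndarray:
        return np.array([c.perm_p for c in self.components])

    def n_significant(self, alpha: float = 0.05) -> int:
        return int(np.sum(self.perm_p < alpha))


def pls_correlation(
    X,
    Y,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int = 0,
) -> PLSResult:
    """End-to-end PLSC: z-score, SVD, permutation test, bootstrap, scores.

    ``X`` and ``Y`` may be DataFrames (rows must already be aligned on the
    same subjects) or arrays. Permutation and bootstrap use independent
    substreams of ``seed``.
    """
    Xa, brain_labels = _as_array(X, "x")
    Ya, behavior_labels = _as_array(Y, "y")
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        if not X.index.equals(Y.index):
            raise ValueError("X and Y row indices (subjects) do not match")
    Xz = zscore_columns(Xa)
    Yz = zscore_columns(Ya)
    comps = svd_components(cross_correlation(Xz, Yz))
    perm_rng, boot_rng = np.random.default_rng(seed).spawn(2)
    p = permutation_test(Xz, Yz, n_perm=n_perm, seed=perm_rng)
    comps = [
        PLSComponent(
            c.index, c.singular_value, c.behavior_saliences, c.brain_saliences,
            c.explained_correlation, float(p[k]),
        )
        for k, c in enumerate(comps)
    ]
    boot = bootstrap_weights(Xz, Yz, comps, n_boot=n_boot, seed=boot_rng)
    scores = latent_scores(Xz, Yz, comps)
    return PLSResult(
        components=comps,
        bootstrap=boot,
        scores=scores,
        R=cross_correlation(Xz, Yz),
        n_subjects=Xa.shape[0],
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        brain_labels=brain_labels,
        behavior_labels=behavior_labels,
    )
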