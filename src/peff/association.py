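"""Kinship and per-k-mer linear mixed-model association.

The model is y = 1μ + xβ + u + ε with u ~ N(0, σ²_g K) and
ε ~ N(0, σ²_e I), where x is a binary presence/absence k-mer column and
K a kinship matrix computed from the k-mer matrix itself (centered
cross-product / m, the standard estimator for binary marker panels).
Both null (β = 0) and alternative models are fitted by maximum
likelihood — ML rather than REML, because the likelihood-ratio test
compares fixed-effect structures and nested-model validity requires
ML — via a single eigendecomposition of K and one-dimensional
optimisation over the variance ratio λ = σ²_g/σ²_e on a log grid
refined by bounded search.  The LRT statistic 2(ℓ_alt − ℓ_null) is
referred to χ² with one degree of freedom.

Significance selection is two-tier: k-mers with −log10 p strictly above
the primary threshold (default 5); if none qualify, all k-mers at or
above the fallback threshold (default 4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kmers import KmerMatrix

log = logging.getLogger(__name__)

P_FLOOR = 1e-300
_LOG10_LAMBDA_RANGE = (-5.0, 5.0)
_GRID_POINTS = 21


@dataclass
class KinshipMatrix:
    samples: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise ValueError("kinship shape does not match samples")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")


@dataclass
class AssociationResult:
    kmer: str
    beta: float
    lrt_stat: float
    p_value: float
    neg_log10_p: float


@dataclass
class NullFit:
    """Null-model ML fit plus the rotated quantities reused per marker."""

    loglik: float
    sigma_g2: float
    sigma_e2: float
    lam: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    y_rot: np.ndarray
    ones_rot: np.ndarray


def kinship_from_pa(matrix: KmerMatrix, normalize: bool = False) -> KinshipMatrix:
    """K = Xc·Xcᵀ / m from the column-centered presence matrix.

    With ``normalize=True`` columns are additionally standardised to
    unit variance before the cross-product (per-column weighting
    variant); the default equal-weight form is standard for binary
    marker matrices.
    """
    if matrix.n_kmers == 0:
        raise ValueError("cannot compute kinship from a matrix with zero columns")
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    X = matrix.presence.astype(float)
    Xc = X - X.mean(axis=0)
    if normalize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    K = Xc @ Xc.T / X.shape[1]
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(matrix.samples), K)


def _profile_negloglik(log10_lam: float, d: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative profile log-likelihood over (β, σ²_e) at fixed λ.

    Inputs are already rotated into the eigenbasis of K.
    """
    lam = 10.0 ** log10_lam
    v = lam * d + 1.0
    w = 1.0 / v
    XtW = X.T * w
    A = XtW @ X
    b = XtW @ y
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    r = y - X @ beta
    n = y.size
    rss_w = float(np.sum(w * r * r))
    if rss_w <= 0:
        return np.inf, None, None
    sigma_e2 = rss_w / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_e2) + np.sum(np.log(v)) + n)
    return -ll, beta, sigma_e2


def _ml_fit(d: np.ndarray, X: np.ndarray, y: np.ndarray) -> dict:
    """Maximise the profile likelihood over λ (log grid + bounded refine)."""
    lo, hi = _LOG10_LAMBDA_RANGE
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([_profile_negloglik(t, d, X, y)[0] for t in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    best_t = grid[i]
    if b > a:
        res = optimize.minimize_scalar(
            lambda t: _profile_negloglik(t, d, X, y)[0],
            bounds=(a, b), method="bounded", options={"xatol": 1e-7},
        )
        if res.fun <= vals[i]:
            best_t = float(res.x)
    nll, beta, sigma_e2 = _profile_negloglik(best_t, d, X, y)
    lam = 10.0 ** best_t
    return {
        "loglik": -nll,
        "lam": lam,
        "beta": beta,
        "sigma_e2": sigma_e2,
        "sigma_g2": lam * sigma_e2,
    }


def _as_kinship_array(K) -> np.ndarray:
    return K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def fit_null_lmm(y: np.ndarray, K) -> NullFit:
    """ML fit of the intercept-only mixed model y = 1μ + u + ε."""
    y = np.asarray(y, dtype=float)
    Km = _as_kinship_array(K)
    if y.ndim != 1 or y.size != Km.shape[0]:
        raise ValueError("phenotype length must match kinship dimension")
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    d, U = np.linalg.eigh(Km)
    d = np.clip(d, 0.0, None)
    y_rot = U.T @ y
    ones_rot = U.T @ np.ones_like(y)
    fit = _ml_fit(d, ones_rot[:, None], y_rot)
    return NullFit(
        loglik=fit["loglik"], sigma_g2=fit["sigma_g2"], sigma_e2=fit["sigma_e2"],
        lam=fit["lam"], eigenvalues=d, eigenvectors=U, y_rot=y_rot, ones_rot=ones_rot,
    )


def test_kmer(
    y: np.ndarray,
    x: np.ndarray,
    K=None,
    null_fit: NullFit | None = None,
    kmer: str = "",
) -> AssociationResult | None:
    """LRT of one binary k-mer column added as a fixed effect.

    Variance components are re-optimised under the alternative (exact
    LRT, not the score-test shortcut).  Constant columns are untestable
    and return ``None`` so callers can exclude them.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return None
    if null_fit is None:
        if K is None:
            raise ValueError("provide either K or a null fit")
        null_fit = fit_null_lmm(y, K)
    x_rot = null_fit.eigenvectors.T @ x
    X = np.column_stack([null_fit.ones_rot, x_rot])
    fit = _ml_fit(null_fit.eigenvalues, X, null_fit.y_rot)
    lrt = max(0.0, 2.0 * (fit["loglik"] - null_fit.loglik))
    p = float(stats.chi2.sf(lrt, df=1))
    if p < P_FLOOR:
        warnings.warn("p-value below 1e-300 floored", RuntimeWarning, stacklevel=2)
        p = P_FLOOR
    return AssociationResult(
        kmer=kmer,
        beta=float(fit["beta"][1]),
        lrt_stat=float(lrt),
        p_value=p,
        neg_log10_p=float(-np.log10(p)),
    )


def run_gwas(
    matrix: KmerMatrix,
    pheno: pd.Series,
    trait_name: str = "trait",
    kinship: KinshipMatrix | None = None,
) -> list[AssociationResult]:
    """Test every testable k-mer column against accession-level trait values.

    ``pheno`` is indexed by accession id (typically the per-accession
    replicate mean for one treatment); samples are inner-joined with the
    matrix rows and drops are logged.
    """
    common = [s for s in matrix.samples if s in pheno.index]
    dropped = matrix.n_samples - len(common)
    if dropped:
        log.warning("dropping %d matrix samples without phenotype (%s)", dropped, trait_name)
    if len(common) < 10:
        raise ValueError("fewer than 10 overlapping samples between matrix and phenotype")
    sub = matrix.subset_samples(common) if dropped else matrix
    y = pheno.loc[common].to_numpy(dtype=float)
    K = kinship if kinship is not None else kinship_from_pa(sub)
    null_fit = fit_null_lmm(y, K)
    results: list[AssociationResult] = []
    for j, km in enumerate(sub.kmers):
        res = test_kmer(y, sub.presence[:, j], null_fit=null_fit, kmer=km)
        if res is not None:
            results.append(res)
    return results


def select_significant(
    results: Sequence[AssociationResult],
    primary: float = 5.0,
    fallback: float = 4.0,
) -> tuple[list[AssociationResult], str]:
    """Two-tier selection: strict > primary, else inclusive >= fallback."""
    if not results:
        raise ValueError("no association results to select from")
    hits = [r for r in results if r.neg_log10_p > primary]
    if hits:
        return hits, "primary"
    hits = [r for r in results if r.neg_log10_p >= fallback]
    if hits:
        return hits, "fallback"
    return [], "none"


def results_to_frame(results: Sequence[AssociationResult], tier: str | None = None) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(r.kmer, r.beta, r.lrt_stat, r.p_value, r.neg_log10_p) for r in results],
        columns=["kmer", "beta", "lrt", "p", "neg_log10_p"],
    )
    if tier is not None:
        frame["tier"] = tier
    return frame


def manhattan_qq_tables(
    results: Sequence[AssociationResult],
    positions: dict[str, tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """QQ table (observed vs expected −log10 p) and optional Manhattan table.

    Expected quantiles are −log10((rank − 0.5)/n) with rank 1 assigned
    to the most significant observation; rows are sorted descending by
    the observed value.
    """
    if not results:
        raise ValueError("no association results")
    obs = np.array([r.neg_log10_p for r in results])
    order = np.argsort(-obs)
    n = len(obs)
    ranks = np.arange(1, n + 1)
    qq = pd.DataFrame({
        "kmer": [results[i].kmer for i in order],
        "observed_neg_log10_p": obs[order],
        "expected_neg_log10_p": -np.log10((ranks - 0.5) / n),
    })
    manhattan = None
    if positions is not None:
        rows = []
        for r in results:
            contig, pos = positions.get(r.kmer, (None, None))
            rows.append((r.kmer, contig, pos, r.neg_log10_p))
        manhattan = pd.DataFrame(
            rows, columns=["kmer", "contig", "position", "neg_log10_p"]
        )
    return qq, manhattan
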