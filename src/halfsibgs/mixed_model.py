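"""Single-kernel animal model: REML variance components and (G)BLUP.

The model is y = Xb + Za + e with a ~ N(0, K·σ²_a) and e ~ N(0, I·σ²_e),
where K is any additive relationship kernel: the pedigree matrix A (ABLUP),
the genomic matrix G (GBLUP) or a trait-specific blend T.  The restricted
likelihood is maximized over the single variance ratio γ = σ²_a/σ²_e by
1-D bounded search on log γ after a spectral decomposition of the
training-row kernel, so each likelihood evaluation is O(n).  Individuals
with missing (masked) phenotypes get breeding values by the standard kernel
extension â_v = K_vt (K_tt + λI)⁻¹ (y_t − X_t b̂), λ = σ²_e/σ²_a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import RelationshipMatrix, TraitData

__all__ = [
    "VarianceComponents",
    "BlupFit",
    "block_design",
    "fit_reml",
    "predict_gebv",
    "ablup",
    "gblup",
]

#: diagonal ridge added to the training kernel before decomposition;
#: a finite-SNP G can be singular
KERNEL_RIDGE = 1e-6


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    reml_loglik: float


@dataclass
class BlupFit:
    """Result of one REML + BLUP fit.

    ``breeding_values`` covers every individual in the kernel, including
    those whose phenotypes were masked.
    """

    fixed_effects: np.ndarray
    breeding_values: np.ndarray
    variance: VarianceComponents
    kernel_kind: str
    sample_ids: list
    train_mask: np.ndarray
    gamma: float

    @property
    def lam(self) -> float:
        """Shrinkage parameter λ = σ²_e/σ²_a = 1/γ."""
        return np.inf if self.gamma == 0 else 1.0 / self.gamma


def block_design(postblock) -> np.ndarray:
    """Full-rank fixed-effect design: intercept + (k-1) block dummies."""
    blocks, inverse = np.unique(np.asarray(postblock), return_inverse=True)
    n = len(inverse)
    X = np.ones((n, len(blocks)))
    for j in range(1, len(blocks)):
        X[:, j] = (inverse == j).astype(float)
    return X


def _restricted_loglik(log_gamma: float, s: np.ndarray, ystar: np.ndarray,
                       Xstar: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Profile restricted log-likelihood at γ = exp(log_gamma).

    Returns (loglik, GLS fixed effects, profiled σ²_e).  Everything is in
    the eigenbasis of the training kernel, where γK + I is diagonal.
    """
    gamma = np.exp(log_gamma)
    d = gamma * s + 1.0
    n, p = Xstar.shape
    Xw = Xstar / d[:, None]
    W = Xstar.T @ Xw
    b = np.linalg.solve(W, Xw.T @ ystar)
    r = ystar - Xstar @ b
    q = float(r @ (r / d))
    sigma_e2 = q / (n - p)
    sign, logdet_W = np.linalg.slogdet(W)
    ll = -0.5 * (
        (n - p) * np.log(sigma_e2)
        + np.log(d).sum()
        + logdet_W
        + (n - p)
    )
    return ll, b, sigma_e2


def fit_reml(y, X, K: RelationshipMatrix, ridge: float = KERNEL_RIDGE,
             log_gamma_bounds: tuple = (-10.0, 10.0)) -> BlupFit:
    """REML fit of the animal model under kernel ``K``.

    Parameters
    ----------
    y : phenotype vector over all kernel individuals; NaN marks masked
        (validation) individuals, which are excluded from the likelihood but
        still receive breeding values.
    X : fixed-effect design over all individuals (e.g. :func:`block_design`).
    K : relationship kernel covering every individual in ``y``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_all = K.n
    if y.shape[0] != n_all or X.shape[0] != n_all:
        raise ValueError("y, X and kernel dimensions disagree")
    train = ~np.isnan(y)
    if train.sum() < 2:
        raise ValueError("need at least 2 phenotyped individuals")
    yt = y[train]
    Xt = X[:, :][train]
    if np.var(yt) == 0:
        raise ValueError("zero-variance phenotype")
    if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
        raise ValueError("fixed-effect design is rank-deficient on training rows")

    Kt = K.values[np.ix_(train, train)] + ridge * np.eye(int(train.sum()))
    s, U = np.linalg.eigh(Kt)
    if s.min() < -1e-8:
        raise ValueError(f"kernel not PSD (min eigenvalue {s.min():.3g})")
    s = np.clip(s, 0.0, None)
    ystar = U.T @ yt
    Xstar = U.T @ Xt

    res = minimize_scalar(
        lambda lg: -_restricted_loglik(lg, s, ystar, Xstar)[0],
        bounds=log_gamma_bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_gamma = float(res.x)
    ll, b, sigma_e2 = _restricted_loglik(log_gamma, s, ystar, Xstar)
    gamma = float(np.exp(log_gamma))
    sigma_a2 = gamma * sigma_e2
    vc = VarianceComponents(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        h2=sigma_a2 / (sigma_a2 + sigma_e2),
        reml_loglik=ll,
    )

    # BLUPs for everyone: â = γ K[:, t] (γK_tt + I)⁻¹ (y_t − X_t b̂)
    d = gamma * s + 1.0
    resid = yt - Xt @ b
    hinv_resid = U @ ((U.T @ resid) / d)
    a_hat = gamma * (K.values[:, train] @ hinv_resid)

    return BlupFit(
        fixed_effects=b,
        breeding_values=a_hat,
        variance=vc,
        kernel_kind=K.kind,
        sample_ids=list(K.sample_ids),
        train_mask=train,
        gamma=gamma,
    )


def predict_gebv(fit: BlupFit, validation_ids) -> np.ndarray:
    """Breeding-value estimates for masked individuals, in the given order."""
    pos = {sid: k for k, sid in enumerate(fit.sample_ids)}
    idx = []
    for vid in validation_ids:
        if vid not in pos:
            raise KeyError(f"individual {vid!r} absent from the kernel")
        k = pos[vid]
        if fit.train_mask[k]:
            raise ValueError(f"individual {vid!r} was in the training set")
        idx.append(k)
    return fit.breeding_values[np.asarray(idx, dtype=int)]


def _masked_phenotype(trait: TraitData, sample_ids, validation_ids) -> np.ndarray:
    y = trait.phenotype.astype(float).copy()
    if validation_ids is not None:
        pos = {sid: k for k, sid in enumerate(sample_ids)}
        y[[pos[v] for v in validation_ids]] = np.nan
    return y


def ablup(trait: TraitData, A: RelationshipMatrix, validation_ids=None) -> BlupFit:
    """Pedigree BLUP: the animal model with the numerator relationship A."""
    y = _masked_phenotype(trait, A.sample_ids, validation_ids)
    return fit_reml(y, block_design(trait.postblock), A)


def gblup(trait: TraitData, K: RelationshipMatrix, validation_ids=None) -> BlupFit:
    """Genomic BLUP: the animal model with a genomic kernel (G or T)."""
    y = _masked_phenotype(trait, K.sample_ids, validation_ids)
    return fit_reml(y, block_design(trait.postblock), K)
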