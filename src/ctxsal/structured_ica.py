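"""Block-structured ICA of target–context patch pairs.

The generative model for a (whitened) target vector ``z_c`` and context
vector ``z_s`` is block-triangular::

    z_s = A_ss s_s
    z_c = A_cs s_s + A_cu s_u

with ``s_s`` (context sources) and ``s_u`` (unpaired target sources)
mutually independent and heavy-tailed.  The *paired* target components
``A_cs`` are the linear extension of context structure into the target; the
*unpaired* components ``A_cu`` carry exactly the target structure that the
context cannot explain, and they alone enter the conditional density of a
target given its context.

Fitting is staged so the triangular structure holds by construction:

1. kurtosis-based FastICA on the whitened context recovers ``s_s``;
2. least squares of the whitened target on those sources gives ``A_cs``;
3. FastICA on the whitened regression residual gives the unpaired sources
   and ``A_cu``;
4. the two stages compose into one linear filter ``W_u_joint`` mapping the
   concatenated whitened (target, context) pair straight to unpaired
   amplitudes — the only quantity the saliency measure needs.

Cross-correlation between recovered unpaired and context sources is kept as
a diagnostic of between-group independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .patches import PatchBatch, WhitenTransform, apply_whitening, fit_whitening

__all__ = [
    "FastICAResult",
    "ICAModel",
    "fastica_kurtosis",
    "fit_structured_ica",
    "amplitudes",
]


@dataclass
class FastICAResult:
    W: np.ndarray  # k x k unmixing, rows orthonormal
    A: np.ndarray  # k x k mixing, W @ A = I
    converged: bool
    n_iter: int
    source_kurtosis: np.ndarray


def fastica_kurtosis(
    Z: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_components: int | None = None,
) -> FastICAResult:
    """Symmetric fixed-point FastICA with the kurtosis (cube) contrast.

    ``Z`` must already be whitened (identity covariance within 1e-3).  The
    returned unmixing matrix has orthonormal rows (symmetric decorrelation),
    so the mixing matrix is its transpose restricted to the estimated
    components.  Near-zero source kurtosis flags non-identifiable
    (Gaussian) directions.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, k = Z.shape
    m = k if n_components is None else int(n_components)
    if not 1 <= m <= k:
        raise ValueError("n_components must be in [1, k]")
    cov = (Z - Z.mean(0)).T @ (Z - Z.mean(0)) / (n - 1)
    if np.abs(cov - np.eye(k)).max() > 1e-3:
        raise ValueError("input is not whitened (covariance deviates from identity)")

    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((k, k)))
    W = W[:m]  # m x k, orthonormal rows

    def _decorrelate(M: np.ndarray) -> np.ndarray:
        # symmetric decorrelation: (M M^T)^{-1/2} M
        s, U = np.linalg.eigh(M @ M.T)
        return U @ np.diag(1.0 / np.sqrt(np.maximum(s, 1e-300))) @ U.T @ M

    W = _decorrelate(W)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = Z @ W.T  # n x m projections
        W_new = (Y**3).T @ Z / n - 3.0 * W  # E[z (w.z)^3] - 3 w
        W_new = _decorrelate(W_new)
        # convergence: directions stable up to sign
        delta = np.max(np.abs(1.0 - np.abs(np.sum(W_new * W, axis=1))))
        W = W_new
        if delta < tol:
            converged = True
            break

    Y = Z @ W.T
    kurt = stats.kurtosis(Y, axis=0, fisher=True, bias=True)
    return FastICAResult(W=W, A=W.T, converged=converged, n_iter=it, source_kurtosis=kurt)


@dataclass
class ICAModel:
    """Fitted structured-ICA decomposition, all filters in whitened coordinates."""

    whiten_c: WhitenTransform
    whiten_s: WhitenTransform
    k_s: int
    k_u: int
    W_s: np.ndarray  # k_s x k_s context unmixing (whitened context space)
    A_ss: np.ndarray  # k_s x k_s context mixing
    A_cs: np.ndarray  # k_c x k_s paired-target loadings on context sources
    A_cu: np.ndarray  # k_c x k_u unpaired mixing, unit-norm columns
    W_u_joint: np.ndarray  # k_u x (k_c + k_s) filter on concat(z_c, z_s)
    diagnostics: dict = field(default_factory=dict)

    @property
    def k_c(self) -> int:
        return self.whiten_c.retained_k

    def generate_pairs(
        self, s_s: np.ndarray, s_u: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mix given context/unpaired sources through the fitted blocks.

        Returns raw-space (X_c, X_s) rows; used for the generative
        round-trip identity — filtering these pairs must recover the
        sources exactly.
        """
        s_s = np.atleast_2d(s_s)
        s_u = np.atleast_2d(s_u)
        z_s = s_s @ self.A_ss.T
        z_c = s_s @ self.A_cs.T + s_u @ self.A_cu.T
        x_s = z_s @ self.whiten_s.inverse.T + self.whiten_s.mean
        x_c = z_c @ self.whiten_c.inverse.T + self.whiten_c.mean
        return x_c, x_s


def _fix_sign_and_order(A_cu: np.ndarray, W_rows: np.ndarray, kurt: np.ndarray):
    """Unit-norm columns, largest-magnitude loading positive, order by |kurtosis|."""
    norms = np.linalg.norm(A_cu, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    A_cu = A_cu / norms
    W_rows = W_rows * norms[:, None]  # keep A_cu @ u invariant
    signs = np.array([np.sign(col[np.argmax(np.abs(col))]) or 1.0 for col in A_cu.T])
    A_cu = A_cu * signs
    W_rows = W_rows * signs[:, None]
    order = np.argsort(-np.abs(kurt))
    return A_cu[:, order], W_rows[order], kurt[order]


def fit_structured_ica(
    batch: PatchBatch,
    k_c: int,
    k_s: int,
    k_u: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ICAModel:
    """Fit the block-triangular ICA model to a batch of patch pairs.

    ``k_c`` / ``k_s`` are the retained principal components of target and
    context (whitened separately); ``k_u`` defaults to ``k_c`` so every
    retained target dimension not explained by context gets a component.
    """
    if k_u is None:
        k_u = k_c
    if k_u > k_c:
        raise ValueError("k_u cannot exceed k_c")
    n = batch.n
    if n <= k_c + k_s:
        raise ValueError("need many more samples than retained dimensions")

    whiten_c = fit_whitening(batch.X_c, k_c)
    whiten_s = fit_whitening(batch.X_s, k_s)
    Z_c = apply_whitening(whiten_c, batch.X_c)
    Z_s = apply_whitening(whiten_s, batch.X_s)

    # stage 1: context sources
    res_s = fastica_kurtosis(Z_s, seed=seed, tol=tol, max_iter=max_iter)
    S_s = Z_s @ res_s.W.T  # n x k_s

    # stage 2: paired loadings by least squares of whitened target on context sources
    A_cs, _, rank, _ = np.linalg.lstsq(S_s, Z_c, rcond=None)
    if rank < k_s:
        raise ValueError(f"context sources are rank deficient ({rank} < {k_s})")
    A_cs = A_cs.T  # k_c x k_s
    R = Z_c - S_s @ A_cs.T  # residual: target structure unexplained by context

    # stage 3: unpaired sources from the whitened residual
    whiten_r = fit_whitening(R, k_u)  # raises if k_u exceeds residual rank
    Z_r = apply_whitening(whiten_r, R)
    res_u = fastica_kurtosis(Z_r, seed=seed + 1, tol=tol, max_iter=max_iter)
    S_u = Z_r @ res_u.W.T

    # filter from residual to unpaired amplitudes: F r = W_u (P_r (r - mean_r))
    F = res_u.W @ whiten_r.forward  # k_u x k_c
    F_offset = -F @ whiten_r.mean
    # mixing back into whitened target space
    A_cu = whiten_r.inverse @ res_u.A  # k_c x k_u (mean offset excluded: ~0)

    A_cu, F, kurt = _fix_sign_and_order(A_cu, F, res_u.source_kurtosis)
    F_offset = -F @ whiten_r.mean if np.abs(whiten_r.mean).max() > 0 else np.zeros(k_u)

    # stage 4: one joint filter on concat(z_c, z_s)
    W_u_joint = np.hstack([F, -F @ A_cs @ res_s.W])  # k_u x (k_c + k_s)

    S_u = (F @ R.T).T + F_offset
    cross = S_u.T @ S_s / n
    norm = np.sqrt(np.outer((S_u**2).mean(0), (S_s**2).mean(0)))
    max_cross_corr = float(np.abs(cross / np.maximum(norm, 1e-300)).max())

    diagnostics = {
        "context_converged": res_s.converged,
        "context_n_iter": res_s.n_iter,
        "unpaired_converged": res_u.converged,
        "unpaired_n_iter": res_u.n_iter,
        "unpaired_kurtosis": kurt,
        "max_cross_corr": max_cross_corr,
        "residual_offset": F_offset,
    }
    return ICAModel(
        whiten_c=whiten_c,
        whiten_s=whiten_s,
        k_s=k_s,
        k_u=k_u,
        W_s=res_s.W,
        A_ss=res_s.A,
        A_cs=A_cs,
        A_cu=A_cu,
        W_u_joint=W_u_joint,
        diagnostics=diagnostics,
    )


def amplitudes(model: ICAModel, x_c: np.ndarray, x_s: np.ndarray) -> np.ndarray:
    """Unpaired-component amplitudes of a target given its context.

    ``u = W_u_joint @ concat(whiten(x_c), whiten(x_s))`` — a single linear
    map; by the triangular structure the context-mediated part of the
    target cancels and only unexplained target structure remains.
    Accepts a single pair (1-D) or stacked rows (2-D).
    """
    x_c = np.asarray(x_c, dtype=float)
    x_s = np.asarray(x_s, dtype=float)
    single = x_c.ndim == 1
    x_c = np.atleast_2d(x_c)
    x_s = np.atleast_2d(x_s)
    if x_c.shape[1] != model.whiten_c.d or x_s.shape[1] != model.whiten_s.d:
        raise ValueError(
            f"expected raw dims ({model.whiten_c.d}, {model.whiten_s.d}), "
            f"got ({x_c.shape[1]}, {x_s.shape[1]})"
        )
    z = np.hstack([apply_whitening(model.whiten_c, x_c), apply_whitening(model.whiten_s, x_s)])
    u = z @ model.W_u_joint.T + model.diagnostics.get("residual_offset", 0.0)
    return u[0] if single else u
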