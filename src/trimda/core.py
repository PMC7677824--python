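"""Graph-regularized orthogonal matrix tri-factorization.

The association matrix A (n_m miRNAs x n_d diseases, 0/1 with 0 meaning
*unknown*) is completed as A~ = P D Q^T where P (n_m x r_m) and Q
(n_d x r_d) have orthonormal columns and D (r_m x r_d) is a low-rank core
coupling miRNA features to disease features. The objective is

    min_{P,D,Q}  || R_Omega(A - P D Q^T) ||_F^2
                 + lambda1 * tr(P^T L_m P) + lambda2 * tr(Q^T L_d Q)
                 + lambda3 * ||D||_*
    s.t.  P^T P = I,  Q^T Q = I,

with R_Omega the projection onto the observed index set, L_m / L_d the
unnormalized graph Laplacians of the integrated miRNA / disease
similarities, and ||.||_* the nuclear norm. Minimization alternates three
block updates:

  1. D with P, Q fixed: accelerated proximal gradient (APG) where the prox
     of the nuclear norm is singular-value soft-thresholding.
  2. P with D, Q fixed: APG on the smooth masked loss; each prox-like inner
     sub-problem (Laplacian quadratic + proximity term, subject to
     orthonormal columns) is solved by a Cayley-transform curvilinear
     search that stays on the Stiefel manifold.
  3. Q with D, P fixed: the same sub-problem transposed, so the same inner
     solver serves both sides.

Each block solver returns its best-objective iterate, so the outer
objective trace is non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Union

import numpy as np

from .io_config import AssociationDataset, RunConfig
from .similarity import LaplacianMatrix, SimilarityMatrix, build_laplacian

__all__ = [
    "FactorModel",
    "HyperParams",
    "ApgSettings",
    "MaskIndex",
    "masked_project",
    "objective",
    "svt_prox",
    "grad_f_D",
    "grad_f_factor",
    "solve_D",
    "solve_orthogonal_factor",
    "initialize_model",
    "fit",
    "predict_scores",
    "FitDiverged",
]

_ORTH_TOL = 1e-8


class FitDiverged(RuntimeError):
    """Raised when an alternating sweep increases the objective."""


@dataclass
class HyperParams:
    """Regularization weights: data-fit vs. the two Laplacian smoothness
    terms (lambda1 for miRNAs, lambda2 for diseases) vs. the nuclear-norm
    rank penalty on the core (lambda3)."""

    lambda1: float = 10.0
    lambda2: float = 10.0
    lambda3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("regularization weights must be nonnegative")


@dataclass
class ApgSettings:
    """Controls for the accelerated-proximal-gradient block solvers.

    ``s`` is the proximal parameter (inverse step size); ``"auto"`` sets it
    per sub-problem to a Lipschitz bound of the smooth gradient (2 for the
    core update since P, Q are orthonormal; 2*sigma_max(D)^2 for the factor
    updates) and doubles it whenever the quadratic upper model is violated.
    The momentum sequence starts at ``gamma0`` with the first momentum term
    vanishing. ``cayley_max``/``cayley_tol`` bound the curvilinear search
    used inside each constrained factor step.
    """

    s: Union[float, Literal["auto"]] = "auto"
    gamma0: float = 1.0
    max_inner: int = 100
    inner_tol: float = 1e-5
    max_outer: int = 50
    outer_tol: float = 1e-4
    cayley_max: int = 50
    cayley_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.s != "auto" and not (isinstance(self.s, (int, float)) and self.s > 0):
            raise ValueError("s must be positive or 'auto'")
        if self.inner_tol <= 0 or self.outer_tol <= 0 or self.cayley_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_inner < 1 or self.max_outer < 1 or self.cayley_max < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class MaskIndex:
    """Observed index set Omega with a cached boolean matrix of one shape."""

    observed: frozenset[tuple[int, int]]
    _bool: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _shape: Optional[tuple[int, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.observed = frozenset((int(i), int(j)) for i, j in self.observed)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "MaskIndex":
        return cls(frozenset(pairs))

    @classmethod
    def from_dataset(cls, dataset: AssociationDataset) -> "MaskIndex":
        return cls(dataset.omega)

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "MaskIndex":
        """Every entry observed: R_Omega becomes the identity."""
        n, m = shape
        idx = cls(frozenset((i, j) for i in range(n) for j in range(m)))
        object.__setattr__(idx, "_bool", np.ones(shape, dtype=bool))
        object.__setattr__(idx, "_shape", shape)
        return idx

    def bool_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self._bool is None or self._shape != shape:
            mask = np.zeros(shape, dtype=bool)
            for i, j in self.observed:
                if not (0 <= i < shape[0] and 0 <= j < shape[1]):
                    raise IndexError(f"mask index {(i, j)} out of range for {shape}")
                mask[i, j] = True
            object.__setattr__(self, "_bool", mask)
            object.__setattr__(self, "_shape", shape)
        return self._bool


@dataclass
class FactorModel:
    """The learned triple (P, D, Q); scores are P @ D @ Q.T."""

    P: np.ndarray
    D: np.ndarray
    Q: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (self.P.shape[0], self.Q.shape[0])

    def orthogonality_defect(self) -> float:
        dp = np.abs(self.P.T @ self.P - np.eye(self.P.shape[1])).max()
        dq = np.abs(self.Q.T @ self.Q - np.eye(self.Q.shape[1])).max()
        return max(dp, dq)

    def validate(self) -> "FactorModel":
        r_m, r_d = self.D.shape
        if self.P.shape[1] != r_m or self.Q.shape[1] != r_d:
            raise ValueError("inconsistent factor shapes")
        if self.orthogonality_defect() >= _ORTH_TOL:
            raise ValueError("P or Q columns are not orthonormal")
        return self


def masked_project(M: np.ndarray, mask: MaskIndex) -> np.ndarray:
    """R_Omega(M): keep observed entries, zero the rest."""
    M = np.asarray(M, dtype=float)
    return np.where(mask.bool_mask(M.shape), M, 0.0)


def _masked_residual(A: np.ndarray, mask_bool: np.ndarray, scores: np.ndarray) -> np.ndarray:
    R = A - scores
    R[~mask_bool] = 0.0
    return R


def nuclear_norm(M: np.ndarray) -> float:
    return float(np.linalg.svd(M, compute_uv=False).sum())


def objective(
    A: np.ndarray,
    mask: MaskIndex,
    model: FactorModel,
    L_m: np.ndarray,
    L_d: np.ndarray,
    hp: HyperParams,
) -> tuple[float, dict[str, float]]:
    """Full objective value plus its four addends.

    Returns ``(total, {"fit": .., "laplacian_m": .., "laplacian_d": ..,
    "nuclear": ..})``.
    """
    A = np.asarray(A, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("nonfinite entries in A")
    P, D, Q = model.P, model.D, model.Q
    for name, M in (("P", P), ("D", D), ("Q", Q)):
        if not np.isfinite(M).all():
            raise ValueError(f"nonfinite entries in {name}")
    R = _masked_residual(A, mask.bool_mask(A.shape), P @ D @ Q.T)
    parts = {
        "fit": float(np.sum(R * R)),
        "laplacian_m": float(hp.lambda1 * np.trace(P.T @ L_m @ P)),
        "laplacian_d": float(hp.lambda2 * np.trace(Q.T @ L_d @ Q)),
        "nuclear": float(hp.lambda3 * nuclear_norm(D)),
    }
    return sum(parts.values()), parts


def svt_prox(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding: the prox of tau * ||.||_*.

    Solves argmin_D tau*||D||_* + (1/2)*||D - M||_F^2 in closed form via the
    SVD of M with singular values shrunk by tau.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    M = np.asarray(M, dtype=float)
    if tau == 0:
        return M.copy()
    U, sig, Vt = np.linalg.svd(M, full_matrices=False)
    shrunk = np.maximum(sig - tau, 0.0)
    return (U * shrunk) @ Vt


def grad_f_D(
    A: np.ndarray, mask: MaskIndex, P: np.ndarray, D: np.ndarray, Q: np.ndarray
) -> np.ndarray:
    """Gradient of ||R_Omega(A - P D Q^T)||_F^2 with respect to D."""
    R = _masked_residual(np.asarray(A, float), mask.bool_mask(A.shape), P @ D @ Q.T)
    return -2.0 * P.T @ R @ Q


def grad_f_factor(
    A: np.ndarray,
    mask: MaskIndex,
    P: np.ndarray,
    D: np.ndarray,
    Q: np.ndarray,
    side: Literal["left", "right"],
) -> np.ndarray:
    """Gradient of the masked loss w.r.t. P (side='left') or Q ('right')."""
    R = _masked_residual(np.asarray(A, float), mask.bool_mask(A.shape), P @ D @ Q.T)
    if side == "left":
        return -2.0 * R @ Q @ D.T
    if side == "right":
        return -2.0 * R.T @ P @ D
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def _next_gamma(gamma: float) -> float:
    return (np.sqrt(gamma**4 + 4 * gamma**2) - gamma**2) / 2.0


def _momentum_coef(gamma_k: float, gamma_prev: float) -> float:
    return gamma_k * (1.0 / gamma_prev - 1.0)


def solve_D(
    A: np.ndarray,
    mask: MaskIndex,
    P: np.ndarray,
    Q: np.ndarray,
    hp: HyperParams,
    apg: ApgSettings,
    D_init: np.ndarray,
) -> np.ndarray:
    """Core update: APG on the masked loss with nuclear-norm prox.

    Momentum: Y_k = D_k + gamma_k*(1/gamma_{k-1} - 1)*(D_k - D_{k-1});
    D_{k+1} = svt_prox(Y_k - grad f(Y_k)/s, lambda3/s);
    gamma_{k+1} = (sqrt(gamma_k^4 + 4 gamma_k^2) - gamma_k^2)/2.
    Since P and Q have orthonormal columns and R_Omega is a contraction,
    the smooth gradient is 2-Lipschitz, so s = 2 guarantees the quadratic
    upper model; a backtracking doubling of s covers user-supplied values.
    The best-objective iterate is returned, so the sub-objective never
    exceeds its value at ``D_init``.
    """
    A = np.asarray(A, dtype=float)
    mb = mask.bool_mask(A.shape)

    def f(D: np.ndarray) -> float:
        R = _masked_residual(A, mb, P @ D @ Q.T)
        return float(np.sum(R * R))

    def sub_obj(D: np.ndarray) -> float:
        return f(D) + hp.lambda3 * nuclear_norm(D)

    s = 2.0 if apg.s == "auto" else float(apg.s)
    D_prev = D_init.copy()
    D_k = D_init.copy()
    gamma_prev = apg.gamma0
    gamma_k = apg.gamma0
    best_D, best_val = D_k.copy(), sub_obj(D_k)

    for _ in range(apg.max_inner):
        Y = D_k + _momentum_coef(gamma_k, gamma_prev) * (D_k - D_prev)
        fY = f(Y)
        G = grad_f_D(A, mask, P, Y, Q)
        for _bt in range(30):
            D_next = svt_prox(Y - G / s, hp.lambda3 / s)
            Delta = D_next - Y
            # quadratic upper model f(D) <= f(Y) + <G, D-Y> + s/2 ||D-Y||^2
            if f(D_next) <= fY + np.sum(G * Delta) + 0.5 * s * np.sum(Delta * Delta) + 1e-12:
                break
            s *= 2.0
        val = sub_obj(D_next)
        if val < best_val:
            best_val, best_D = val, D_next.copy()
        rel_change = np.linalg.norm(D_next - D_k) / max(1.0, np.linalg.norm(D_k))
        gamma_prev, gamma_k = gamma_k, _next_gamma(gamma_k)
        D_prev, D_k = D_k, D_next
        if rel_change < apg.inner_tol:
            break
    return best_D


def _reorthonormalize(F: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """QR-orthonormalize F, with column signs matched to ``ref``."""
    Qf, Rf = np.linalg.qr(F)
    signs = np.sign(np.diag(Rf))
    signs[signs == 0] = 1.0
    return Qf * signs


def _cayley_minimize(
    F0: np.ndarray,
    L: np.ndarray,
    lam: float,
    s: float,
    B: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float]:
    """Minimize lam*tr(F^T L F) + (s/2)*||F - B||_F^2 s.t. F^T F = I.

    Curvilinear search on the Stiefel manifold: with Euclidean gradient G,
    the skew matrix W = G F^T - F G^T defines the feasible curve
    F(tau) = (I + tau/2 W)^{-1} (I - tau/2 W) F, which preserves
    orthonormality for every tau. W = U V^T is rank <= 2r (U = [G, F],
    V = [F, -G]), so the curve is evaluated through the
    Sherman-Morrison-Woodbury identity as
    F(tau) = F - tau U (I + tau/2 V^T U)^{-1} V^T F, a 2r x 2r solve
    instead of n x n. Steps start from a Barzilai-Borwein estimate and are
    halved under an Armijo test (the derivative of the sub-objective along
    the curve at tau = 0 is -||W||_F^2 / 2). Iteration stops on relative
    gradient reduction or relative objective decrease below ``tol``.

    Returns ``(F, max_orthogonality_drift_seen)``.
    """
    r = F0.shape[1]
    I2 = np.eye(2 * r)

    def g(F: np.ndarray) -> float:
        diff = F - B
        return float(lam * np.sum(F * (L @ F)) + 0.5 * s * np.sum(diff * diff))

    def grad(F: np.ndarray) -> np.ndarray:
        return 2.0 * lam * (L @ F) + s * (F - B)

    F = F0.copy()
    gF = g(F)
    G = grad(F)
    # inverse of a gradient-Lipschitz bound as the first trial step
    tau = 1.0 / (2.0 * lam * max(np.abs(L).sum(axis=1).max(), 1e-12) + s)
    max_drift = float(np.abs(F.T @ F - np.eye(r)).max())
    wnorm2_0: Optional[float] = None
    dF: Optional[np.ndarray] = None
    dG: Optional[np.ndarray] = None

    for _ in range(max_iter):
        U = np.hstack([G, F])
        V = np.hstack([F, -G])
        VtU = V.T @ U
        VtF = V.T @ F
        # ||W||_F^2 = tr((U^T U)(V^T V)) via the low-rank representation
        wnorm2 = float(np.sum((U.T @ U) * (V.T @ V)))
        if wnorm2_0 is None:
            wnorm2_0 = wnorm2
        if wnorm2 <= max(tol * wnorm2_0, 1e-30):
            break
        if dF is not None:
            denom = abs(float(np.sum(dF * dG)))
            if denom > 1e-18:
                tau = float(np.sum(dF * dF)) / denom
        tau = float(np.clip(tau, 1e-12, 1e6))
        accepted = False
        t = tau
        for _bt in range(30):
            try:
                X = np.linalg.solve(I2 + 0.5 * t * VtU, VtF)
            except np.linalg.LinAlgError:
                t *= 0.5
                continue
            F_new = F - t * (U @ X)
            g_new = g(F_new)
            if g_new <= gF - 1e-4 * t * 0.5 * wnorm2:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        drift = float(np.abs(F_new.T @ F_new - np.eye(r)).max())
        max_drift = max(max_drift, drift)
        if drift > 1e-10:
            F_new = _reorthonormalize(F_new, F)
            g_new = g(F_new)
        G_new = grad(F_new)
        dF, dG = F_new - F, G_new - G
        improved = gF - g_new
        F, gF, G = F_new, g_new, G_new
        if improved <= tol * max(1.0, abs(gF)):
            break
    return F, max_drift


def solve_orthogonal_factor(
    A: np.ndarray,
    mask: MaskIndex,
    fixed_core: np.ndarray,
    other_factor: np.ndarray,
    laplacian: Union[LaplacianMatrix, np.ndarray],
    lambda_reg: float,
    apg: ApgSettings,
    F_init: np.ndarray,
    side: Literal["left", "right"],
    return_info: bool = False,
):
    """Factor update: APG whose inner step is orthogonality-constrained.

    Solves, for side='left' (the miRNA factor P, with Q fixed),

        min_F ||R_Omega(A - F D Q^T)||_F^2 + lambda * tr(F^T L F)
        s.t.  F^T F = I,

    and the transposed problem for side='right' (the disease factor Q, with
    P fixed) — the two sub-problems are identical up to transposition, so
    one routine serves both. The APG outer loop takes momentum steps on the
    smooth masked loss; each resulting proximity sub-problem
    ``min lam*tr(F^T L F) + (s/2)||F - B||^2 s.t. F^T F = I`` is solved by
    the Cayley curvilinear search (:func:`_cayley_minimize`).

    The best iterate by the sub-objective is returned, guaranteeing no
    increase over ``F_init``. With ``return_info=True`` also returns a dict
    with the sub-objective trace and the worst orthogonality drift observed
    at any accepted inner iterate.
    """
    A = np.asarray(A, dtype=float)
    mb = mask.bool_mask(A.shape)
    L = laplacian.L if isinstance(laplacian, LaplacianMatrix) else np.asarray(laplacian)
    D = fixed_core
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    r = F_init.shape[1]
    if np.abs(F_init.T @ F_init - np.eye(r)).max() > 1e-6:
        raise ValueError("F_init columns are not orthonormal")

    if side == "left":
        def f(F: np.ndarray) -> float:
            R = _masked_residual(A, mb, F @ D @ other_factor.T)
            return float(np.sum(R * R))
    else:
        def f(F: np.ndarray) -> float:
            R = _masked_residual(A, mb, other_factor @ D @ F.T)
            return float(np.sum(R * R))

    def grad_smooth(F: np.ndarray) -> np.ndarray:
        if side == "left":
            return grad_f_factor(A, mask, F, D, other_factor, "left")
        return grad_f_factor(A, mask, other_factor, D, F, "right")

    def sub_obj(F: np.ndarray) -> float:
        return f(F) + lambda_reg * float(np.trace(F.T @ L @ F))

    sigma_max = np.linalg.svd(D, compute_uv=False)[0] if D.size else 0.0
    s = max(2.0 * sigma_max**2, 1e-8) if apg.s == "auto" else float(apg.s)

    F_prev = F_init.copy()
    F_k = F_init.copy()
    gamma_prev = apg.gamma0
    gamma_k = apg.gamma0
    best_F, best_val = F_k.copy(), sub_obj(F_k)
    trace = [best_val]
    worst_drift = 0.0

    for _ in range(apg.max_inner):
        Y = F_k + _momentum_coef(gamma_k, gamma_prev) * (F_k - F_prev)
        fY = f(Y)
        G = grad_smooth(Y)
        for _bt in range(30):
            B = Y - G / s
            F_next, drift = _cayley_minimize(
                F_k, L, lambda_reg, s, B, apg.cayley_max, apg.cayley_tol
            )
            Delta = F_next - Y
            if f(F_next) <= fY + np.sum(G * Delta) + 0.5 * s * np.sum(Delta * Delta) + 1e-12:
                break
            s *= 2.0
        worst_drift = max(worst_drift, drift)
        val = sub_obj(F_next)
        trace.append(val)
        if val < best_val:
            best_val, best_F = val, F_next.copy()
        rel_change = np.linalg.norm(F_next - F_k) / max(1.0, np.linalg.norm(F_k))
        gamma_prev, gamma_k = gamma_k, _next_gamma(gamma_k)
        F_prev, F_k = F_k, F_next
        if rel_change < apg.inner_tol:
            break

    if return_info:
        return best_F, {"trace": trace, "max_orthogonality_drift": worst_drift}
    return best_F


def initialize_model(
    A: np.ndarray, mask: MaskIndex, r_m: int, r_d: int, seed: int = 0
) -> FactorModel:
    """SVD warm start: P/Q from the leading singular vectors of the
    zero-filled A, D = P^T A Q.

    Column signs follow a fixed convention (largest-magnitude entry of each
    singular vector made positive) so the start is platform-deterministic.
    Rank requests beyond the numerical rank of A are padded with a seeded
    random orthonormal completion.
    """
    A = np.asarray(A, dtype=float)
    n_m, n_d = A.shape
    if r_m > n_m or r_d > n_d:
        raise ValueError("rank request exceeds matrix dimensions")
    U, sig, Vt = np.linalg.svd(A, full_matrices=True)
    tol = max(n_m, n_d) * np.finfo(float).eps * (sig[0] if sig.size else 0.0)
    rank = int((sig > tol).sum())
    rng = np.random.default_rng(seed)

    def take(Ufull: np.ndarray, r: int) -> np.ndarray:
        F = Ufull[:, :r].copy()
        if r > rank:
            warnings.warn(
                f"requested rank {r} exceeds matrix rank {rank}; "
                "padding with a random orthonormal completion",
                stacklevel=2,
            )
            base = Ufull[:, :rank]
            extra = rng.standard_normal((Ufull.shape[0], r - rank))
            if rank:
                extra -= base @ (base.T @ extra)
            extra, _ = np.linalg.qr(extra)
            F = np.hstack([base, extra[:, : r - rank]])
        # sign convention: largest-|.| entry of each column positive
        for c in range(F.shape[1]):
            k = int(np.argmax(np.abs(F[:, c])))
            if F[k, c] < 0:
                F[:, c] = -F[:, c]
        return F

    P = take(U, r_m)
    Q = take(Vt.T, r_d)
    D = P.T @ A @ Q
    return FactorModel(P=P, D=D, Q=Q).validate()


def fit(
    dataset: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    config: RunConfig,
    observed: Literal["all", "positives"] = "all",
) -> tuple[FactorModel, list[float]]:
    """Alternating minimization: D, then P, then Q per outer sweep.

    ``observed`` selects the index set the data-fit term runs over. The
    default ``"all"`` treats every entry of the training matrix as observed
    — its zeros act as weak negatives, which is what the masking protocols
    (zero a row or column, refit, rank) require to be meaningful.
    ``"positives"`` restricts the loss to the known associations only;
    under that reading the fit term merely interpolates the observed 1s and
    held-out ranking degenerates, so it is kept for completeness, not used
    by the evaluation protocols.

    Stops when the relative objective decrease falls below
    ``config.solver.outer_tol`` or after ``max_outer`` sweeps. Returns the
    model and the per-sweep objective trace (guaranteed non-increasing; a
    genuine increase raises :class:`FitDiverged` with the offending sweep).
    """
    if S_m.ids != dataset.mirna_ids:
        raise ValueError("miRNA similarity ids do not match dataset order")
    if S_d.ids != dataset.disease_ids:
        raise ValueError("disease similarity ids do not match dataset order")
    A = dataset.A
    if observed == "all":
        mask = MaskIndex.full(A.shape)
    elif observed == "positives":
        mask = MaskIndex.from_dataset(dataset)
    else:
        raise ValueError(f"observed must be 'all' or 'positives', got {observed!r}")
    hp = HyperParams(config.lambda1, config.lambda2, config.lambda3)
    apg: ApgSettings = config.solver
    L_m = build_laplacian(S_m).L
    L_d = build_laplacian(S_d).L
    r_m, r_d = config.resolve_ranks(dataset.n_m, dataset.n_d)

    model = initialize_model(A, mask, r_m, r_d, seed=config.seed)
    obj_prev, _ = objective(A, mask, model, L_m, L_d, hp)
    trace = [obj_prev]

    for sweep in range(apg.max_outer):
        D = solve_D(A, mask, model.P, model.Q, hp, apg, model.D)
        model = FactorModel(model.P, D, model.Q)
        P = solve_orthogonal_factor(
            A, mask, model.D, model.Q, L_m, hp.lambda1, apg, model.P, side="left"
        )
        model = FactorModel(P, model.D, model.Q).validate()
        Q = solve_orthogonal_factor(
            A, mask, model.D, model.P, L_d, hp.lambda2, apg, model.Q, side="right"
        )
        model = FactorModel(model.P, model.D, Q).validate()

        obj, parts = objective(A, mask, model, L_m, L_d, hp)
        if obj > obj_prev + 1e-9:
            raise FitDiverged(
                f"objective increased at sweep {sweep}: "
                f"{obj_prev:.12g} -> {obj:.12g}; terms {parts}"
            )
        trace.append(obj)
        if obj_prev - obj <= apg.outer_tol * max(1.0, abs(obj_prev)):
            obj_prev = obj
            break
        obj_prev = obj
    return model, trace


def predict_scores(model: FactorModel) -> np.ndarray:
    """Completed association scores A~ = P D Q^T."""
    return model.P @ model.D @ model.Q.T
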