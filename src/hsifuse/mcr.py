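"""Constrained multivariate curve resolution by alternating least squares.

The measurement model is bilinear (Beer-Lambert-like): the spectrum of a
pixel is a concentration-weighted sum of invariant pure component spectra,

    D = C St + E,

with D the (pixels x channels) matrix, C the (pixels x K) concentration
profiles, St the (K x channels) pure spectra and E the residuals.  MCR-ALS
refines C and St alternately by least squares under constraints: per
component, per mode (C or St) and per block (sample block for C, platform
block for St) one may require non-negativity or force entries to exactly
zero (selectivity / local rank).  Model quality is tracked by the lack of
fit, ``LOF(%) = 100 * sqrt(sum(E^2) / sum(D^2))``, and the explained
variance ``r2 = 1 - sum(E^2) / sum(D^2)``.

The solver is exposed both as the scikit-learn style estimator
:class:`MCRALS` (fit / transform, fitted attributes ``C_``, ``St_``,
``lof_``) and as the thin functional wrapper :func:`run_mcr_als` operating
on a :class:`~hsifuse.multiset.Multiset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .io import refold
from .multiset import Multiset

__all__ = [
    "ConstraintSet",
    "MCRResult",
    "MCRALS",
    "estimate_rank",
    "simplisma_init",
    "als_update_C",
    "als_update_S",
    "normalize_components",
    "lof",
    "r2",
    "run_mcr_als",
    "component_maps",
]


class ComponentDeathError(RuntimeError):
    """A component was annihilated (all-zero spectrum or concentration)."""


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


@dataclass
class _ZeroRule:
    mode: str  # "C" or "S"
    component: int | None  # None = all components
    block: str | None  # None = all blocks
    ranges: Any = "all"  # "all", list of (lo, hi) in axis units (S mode),
    # or list of local row indices (C mode)


@dataclass
class _NonnegRule:
    mode: str
    component: int | None
    block: str | None


class ConstraintSet:
    """Per-component / per-mode / per-block constraint grid.

    ``mode`` is ``"C"`` (concentrations; blocks are samples) or ``"S"``
    (spectra; blocks are platforms).  ``component=None`` or ``block=None``
    means "all".  Spectral zero ranges are given in axis units of the
    corresponding platform block; ``"all"`` zeroes the whole sub-signature
    (the platform does not detect that component).
    """

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("need at least one component")
        self.n_components = int(n_components)
        self._nonneg: list[_NonnegRule] = []
        self._zeros: list[_ZeroRule] = []

    # -- declaration ----------------------------------------------------
    def set_nonneg(
        self, mode: str, component: int | None = None, block: str | None = None
    ) -> "ConstraintSet":
        self._check(mode, component)
        self._nonneg.append(_NonnegRule(mode, component, block))
        return self

    def set_zero(
        self,
        mode: str,
        component: int | None = None,
        block: str | None = None,
        ranges: Any = "all",
    ) -> "ConstraintSet":
        self._check(mode, component)
        self._zeros.append(_ZeroRule(mode, component, block, ranges))
        return self

    def _check(self, mode: str, component: int | None) -> None:
        if mode not in ("C", "S"):
            raise ValueError("mode must be 'C' or 'S'")
        if component is not None and not 0 <= component < self.n_components:
            raise ValueError(f"component {component} out of range")

    # -- config round-trip ----------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "ConstraintSet":
        cs = cls(int(cfg["n_components"]))
        for entry in cfg.get("nonneg", []):
            cs.set_nonneg(
                entry["mode"], entry.get("component"), entry.get("block")
            )
        for entry in cfg.get("zeros", []):
            ranges = entry.get("ranges", "all")
            if ranges != "all":
                ranges = [tuple(r) for r in ranges]
            cs.set_zero(
                entry["mode"], entry.get("component"), entry.get("block"), ranges
            )
        return cs

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "nonneg": [
                {"mode": r.mode, "component": r.component, "block": r.block}
                for r in self._nonneg
            ],
            "zeros": [
                {
                    "mode": r.mode,
                    "component": r.component,
                    "block": r.block,
                    "ranges": r.ranges
                    if r.ranges == "all"
                    else [list(t) for t in r.ranges],
                }
                for r in self._zeros
            ],
        }

    # -- materialization -------------------------------------------------
    def materialize(
        self,
        row_blocks: dict[str, tuple[int, int]],
        col_blocks: dict[str, tuple[int, int]],
        axes: dict[str, np.ndarray],
        shape: tuple[int, int],
    ) -> dict[str, np.ndarray]:
        """Expand the rules into boolean masks for one multiset layout.

        Returns nonneg_C (I, K), nonneg_S (K, J), zero_C (I, K),
        zero_S (K, J).
        """
        I, J = shape
        K = self.n_components
        nonneg_C = np.zeros((I, K), dtype=bool)
        nonneg_S = np.zeros((K, J), dtype=bool)
        zero_C = np.zeros((I, K), dtype=bool)
        zero_S = np.zeros((K, J), dtype=bool)

        def comps(c):
            return range(K) if c is None else [c]

        for rule in self._nonneg:
            if rule.mode == "C":
                for sid, (r0, r1) in row_blocks.items():
                    if rule.block is not None and rule.block != sid:
                        continue
                    for k in comps(rule.component):
                        nonneg_C[r0:r1, k] = True
            else:
                for mod, (c0, c1) in col_blocks.items():
                    if rule.block is not None and rule.block != mod:
                        continue
                    for k in comps(rule.component):
                        nonneg_S[k, c0:c1] = True

        for rule in self._zeros:
            if rule.mode == "S":
                for mod, (c0, c1) in col_blocks.items():
                    if rule.block is not None and rule.block != mod:
                        continue
                    if rule.ranges == "all":
                        sel = np.ones(c1 - c0, dtype=bool)
                    else:
                        ax = axes[mod]
                        sel = np.zeros(c1 - c0, dtype=bool)
                        for lo, hi in rule.ranges:
                            lo, hi = (lo, hi) if lo <= hi else (hi, lo)
                            if hi < ax.min() or lo > ax.max():
                                raise ValueError(
                                    f"zero range ({lo}, {hi}) outside the "
                                    f"{mod} axis span "
                                    f"({ax.min()}, {ax.max()})"
                                )
                            sel |= (ax >= lo) & (ax <= hi)
                    for k in comps(rule.component):
                        zero_S[k, c0:c1] |= sel
            else:
                for sid, (r0, r1) in row_blocks.items():
                    if rule.block is not None and rule.block != sid:
                        continue
                    if rule.ranges == "all":
                        idx = np.arange(r1 - r0)
                    else:
                        idx = np.asarray(rule.ranges, dtype=int)
                        if idx.size and (idx.min() < 0 or idx.max() >= r1 - r0):
                            raise ValueError(
                                f"pixel indices out of range for sample {sid!r}"
                            )
                    for k in comps(rule.component):
                        zero_C[r0 + idx, k] = True

        dead = np.nonzero(zero_S.all(axis=1))[0]
        if dead.size:
            raise ValueError(
                f"component(s) {dead.tolist()} are zeroed in every spectral "
                "block; the model cannot contain an all-zero spectrum"
            )
        return {
            "nonneg_C": nonneg_C,
            "nonneg_S": nonneg_S,
            "zero_C": zero_C,
            "zero_S": zero_S,
        }


def _single_block_layout(I: int, J: int):
    row_blocks = {"all": (0, I)}
    col_blocks = {"all": (0, J)}
    axes = {"all": np.arange(J, dtype=float)}
    return row_blocks, col_blocks, axes


# ---------------------------------------------------------------------------
# Diagnostics (lack of fit, explained variance)
# ---------------------------------------------------------------------------


def lof(M: np.ndarray, Mhat: np.ndarray) -> float:
    """Lack of fit in percent: ``100 * sqrt(sum(E^2) / sum(D^2))``."""
    M = np.asarray(M, dtype=float)
    Mhat = np.asarray(Mhat, dtype=float)
    if M.shape != Mhat.shape:
        raise ValueError("shapes differ")
    ssd = float(np.sum(M * M))
    if ssd == 0:
        raise ValueError("all-zero data matrix")
    e = M - Mhat
    return 100.0 * float(np.sqrt(np.sum(e * e) / ssd))


def r2(M: np.ndarray, Mhat: np.ndarray) -> float:
    """Fraction of variance explained: ``1 - sum(E^2) / sum(D^2)``."""
    M = np.asarray(M, dtype=float)
    Mhat = np.asarray(Mhat, dtype=float)
    if M.shape != Mhat.shape:
        raise ValueError("shapes differ")
    ssd = float(np.sum(M * M))
    if ssd == 0:
        raise ValueError("all-zero data matrix")
    e = M - Mhat
    return 1.0 - float(np.sum(e * e)) / ssd


# ---------------------------------------------------------------------------
# Rank estimation and SIMPLISMA initialization
# ---------------------------------------------------------------------------


def estimate_rank(M: np.ndarray, max_k: int | None = None) -> pd.DataFrame:
    """Advisory PCA-style rank table of an (uncentered) data matrix.

    No mean centering is applied: the signal model is additive, so the
    mean spectrum is itself chemical information.  The choice of the
    number of components remains the user's; the table lists singular
    values and cumulative explained variance.
    """
    M = np.asarray(M, dtype=float)
    full = min(M.shape)
    if max_k is None:
        max_k = full
    if not 0 < max_k <= full:
        raise ValueError(f"max_k must be in [1, {full}]")
    s = np.linalg.svd(M, compute_uv=False)
    var = s**2
    cum = 100.0 * np.cumsum(var) / var.sum()
    return pd.DataFrame(
        {
            "k": np.arange(1, max_k + 1),
            "singular_value": s[:max_k],
            "cumulative_variance_pct": cum[:max_k],
        }
    )


def simplisma_init(
    M: np.ndarray, n_components: int, noise_alpha: float = 5.0
) -> np.ndarray:
    """Select the K purest pixel rows of M as the initial spectral estimate.

    SIMPLISMA purity of row i is ``std_i / (mean_i + offset)`` with
    ``offset = noise_alpha% of the largest row mean``, which damps
    low-intensity (noise-dominated) rows.  After the first pick, candidates are weighted
    by the Gram determinant of the already-selected normalized rows plus
    the candidate, which suppresses rows collinear with earlier picks.
    Deterministic; ties break to the lowest row index.
    """
    M = np.asarray(M, dtype=float)
    I, J = M.shape
    K = int(n_components)
    if K < 1:
        raise ValueError("n_components must be >= 1")
    if not 0 <= noise_alpha <= 100:
        raise ValueError("noise_alpha must be a percentage in [0, 100]")
    if K > I:
        raise ValueError("more components than rows")
    if I <= 4096 and np.unique(M, axis=0).shape[0] < K:
        raise ValueError("fewer distinct rows than components")

    mu = M.mean(axis=1)
    sd = M.std(axis=1)
    offset = (noise_alpha / 100.0) * float(np.abs(mu).max())
    purity = sd / (np.abs(mu) + offset) if offset > 0 else sd / np.where(
        mu == 0, 1.0, np.abs(mu)
    )
    scale = np.sqrt(mu**2 + (sd + offset) ** 2)
    scale[scale == 0] = 1.0
    Z = M / scale[:, None] / np.sqrt(J)

    selected: list[int] = []
    for _ in range(K):
        if not selected:
            w = np.ones(I)
        else:
            Zs = Z[selected]  # (q, J)
            Gs = Zs @ Zs.T
            det_Gs = float(np.linalg.det(Gs))
            A = Z @ Zs.T  # (I, q)
            try:
                sol = np.linalg.solve(Gs, A.T).T
            except np.linalg.LinAlgError:
                sol = (np.linalg.pinv(Gs) @ A.T).T
            schur = np.einsum("ij,ij->i", Z, Z) - np.einsum("ij,ij->i", A, sol)
            w = np.maximum(det_Gs * schur, 0.0)
        score = purity * w
        score[selected] = -np.inf
        pick = int(np.argmax(score))  # argmax returns the first (lowest) index
        selected.append(pick)
    return M[selected].copy()


# ---------------------------------------------------------------------------
# ALS updates
# ---------------------------------------------------------------------------


def _constrained_columns(
    A: np.ndarray, B: np.ndarray, nonneg: np.ndarray, solver: str
) -> np.ndarray:
    """Solve min ||A X - B|| column-wise with selected entries of X >= 0.

    A is (m, K); B is (m, n); nonneg is (K, n) boolean.  The unconstrained
    least-squares solution is kept wherever it is feasible; violating
    columns are re-solved by NNLS (all-constrained) or bounded least
    squares (mixed).  ``solver='clip'`` just clips instead (fast mode).
    """
    X, *_ = np.linalg.lstsq(A, B, rcond=None)
    if not nonneg.any():
        return X
    if solver == "clip":
        X[nonneg & (X < 0)] = 0.0
        return X
    viol = np.nonzero(((X < -1e-13) & nonneg).any(axis=0))[0]
    K = A.shape[1]
    for j in viol:
        mask = nonneg[:, j]
        if mask.all():
            X[:, j], _ = nnls(A, B[:, j])
        else:
            lb = np.where(mask, 0.0, -np.inf)
            res = lsq_linear(A, B[:, j], bounds=(lb, np.full(K, np.inf)))
            X[:, j] = res.x
    X[nonneg & (X < 0)] = 0.0  # exact feasibility (removes solver round-off)
    return X


def als_update_C(
    M: np.ndarray,
    St: np.ndarray,
    nonneg: np.ndarray | None = None,
    zero: np.ndarray | None = None,
    solver: str = "nnls",
) -> np.ndarray:
    """One constrained least-squares update of the concentration matrix.

    ``nonneg`` and ``zero`` are (I, K) boolean masks; zeroed entries are
    hard-set after the non-negativity step.
    """
    K = St.shape[0]
    I = M.shape[0]
    nn = np.zeros((I, K), dtype=bool) if nonneg is None else nonneg
    C = _constrained_columns(St.T, M.T, nn.T, solver).T
    if zero is not None:
        C[zero] = 0.0
    return C


def als_update_S(
    M: np.ndarray,
    C: np.ndarray,
    nonneg: np.ndarray | None = None,
    zero: np.ndarray | None = None,
    solver: str = "nnls",
) -> np.ndarray:
    """One constrained least-squares update of the spectra matrix.

    ``nonneg`` and ``zero`` are (K, J) boolean masks.  Callers normally
    follow this with :func:`normalize_components` so every component's
    augmented spectrum has unit Euclidean norm.
    """
    K = C.shape[1]
    J = M.shape[1]
    nn = np.zeros((K, J), dtype=bool) if nonneg is None else nonneg
    St = _constrained_columns(C, M, nn, solver)
    if zero is not None:
        St[zero] = 0.0
    return St


def normalize_components(
    C: np.ndarray,
    St: np.ndarray,
    sign_free: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each component so its full augmented spectrum has unit norm.

    The inverse factor is absorbed into C, leaving the product C St
    unchanged.  For components unconstrained in sign in both modes
    (``sign_free``), the sign is fixed so the largest-magnitude spectral
    entry is positive.  Raises :class:`ComponentDeathError` on an all-zero
    spectrum or concentration profile.
    """
    C = C.copy()
    St = St.copy()
    K = St.shape[0]
    for k in range(K):
        n = float(np.linalg.norm(St[k]))
        if n < 1e-300 or not np.any(C[:, k]):
            raise ComponentDeathError(
                f"component {k} vanished (all-zero spectrum or concentrations)"
            )
        St[k] /= n
        C[:, k] *= n
        if sign_free is not None and sign_free[k]:
            if St[k, int(np.argmax(np.abs(St[k])))] < 0:
                St[k] = -St[k]
                C[:, k] = -C[:, k]
    return C, St


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


@dataclass
class MCRResult:
    """Outcome of a constrained MCR-ALS run on a multiset."""

    C: np.ndarray
    St: np.ndarray
    lof_trace: list[float]
    lof_final: float
    r2: float
    n_iter: int
    converged: bool
    constraint_echo: ConstraintSet | None = None


class MCRALS(BaseEstimator, TransformerMixin):
    """Multivariate curve resolution by constrained alternating least squares.

    Decomposes a (pixels x channels) matrix — or a fused
    :class:`~hsifuse.multiset.Multiset` — into ``X ~ C_ @ St_`` with K
    pure-component spectra.

    Parameters
    ----------
    n_components : int
        Number of chemical components K.
    init : {"simplisma"} or ndarray of shape (K, J)
        Initial spectral estimate; ``"simplisma"`` selects the purest
        pixel rows of the data.
    constraints : ConstraintSet, optional
        Non-negativity and zero (selectivity/local rank) rules.  Block
        names must match the multiset's sample ids / modalities; for a
        bare matrix use block ``"all"`` or ``block=None``.
    tol_pct : float
        Convergence threshold on the change in lack of fit between
        consecutive iterations, in percentage points (``convergence=
        "absolute"``) or as a relative fraction of the current LOF
        (``"relative"``).
    max_iter : int
        Iteration cap; the best (lowest-LOF) iterate seen is returned
        even if the trace oscillates.
    noise_alpha : float
        SIMPLISMA noise allowance, percent of the global mean.
    nonneg_solver : {"nnls", "clip"}
        Exact constrained least squares per affected vector, or fast
        clipping of negatives.

    Attributes
    ----------
    C_ : ndarray (I, K)
        Concentration profiles of the best iterate.
    St_ : ndarray (K, J)
        Pure spectra, each row unit Euclidean norm over the full
        augmented axis.
    lof_trace_ : list of float
        Lack of fit (%) per iteration.
    lof_ : float
        LOF of the returned model.
    r2_ : float
        Explained variance of the returned model.
    n_iter_ : int
        Iterations executed.
    converged_ : bool
        Whether the tolerance rule triggered before ``max_iter``.
    """

    def __init__(
        self,
        n_components: int = 2,
        init: Any = "simplisma",
        constraints: ConstraintSet | None = None,
        tol_pct: float = 0.1,
        max_iter: int = 50,
        noise_alpha: float = 5.0,
        nonneg_solver: str = "nnls",
        convergence: str = "absolute",
    ):
        self.n_components = n_components
        self.init = init
        self.constraints = constraints
        self.tol_pct = tol_pct
        self.max_iter = max_iter
        self.noise_alpha = noise_alpha
        self.nonneg_solver = nonneg_solver
        self.convergence = convergence

    # -- helpers ---------------------------------------------------------
    def _layout(self, X):
        if isinstance(X, Multiset):
            return X.M, X.row_blocks, X.col_blocks, X.axes
        M = np.asarray(X, dtype=float)
        if M.ndim != 2:
            raise ValueError("X must be a 2-D matrix or a Multiset")
        if not np.all(np.isfinite(M)):
            raise ValueError("X contains non-finite values")
        rb, cb, axes = _single_block_layout(*M.shape)
        return M, rb, cb, axes

    def _masks(self, rb, cb, axes, shape):
        K = self.n_components
        if self.constraints is None:
            I, J = shape
            z = {
                "nonneg_C": np.zeros((I, K), dtype=bool),
                "nonneg_S": np.zeros((K, J), dtype=bool),
                "zero_C": np.zeros((I, K), dtype=bool),
                "zero_S": np.zeros((K, J), dtype=bool),
            }
            return z
        if self.constraints.n_components != K:
            raise ValueError("constraints built for a different K")
        return self.constraints.materialize(rb, cb, axes, shape)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None) -> "MCRALS":
        M, rb, cb, axes = self._layout(X)
        I, J = M.shape
        K = int(self.n_components)
        if not 1 <= K <= min(I, J):
            raise ValueError(f"n_components must be in [1, {min(I, J)}]")
        masks = self._masks(rb, cb, axes, (I, J))
        sign_free = ~(masks["nonneg_S"].any(axis=1) | masks["nonneg_C"].any(axis=0))

        if isinstance(self.init, str) and self.init == "simplisma":
            St = simplisma_init(M, K, self.noise_alpha)
        else:
            St = np.asarray(self.init, dtype=float).copy()
            if St.shape != (K, J):
                raise ValueError(f"init spectra must have shape ({K}, {J})")
        St[masks["zero_S"]] = 0.0
        norms = np.linalg.norm(St, axis=1)
        if np.any(norms < 1e-300):
            raise ComponentDeathError(
                f"initial spectrum of component "
                f"{int(np.argmin(norms))} is all zero"
            )
        St = St / norms[:, None]

        tol = float(self.tol_pct)
        trace: list[float] = []
        best = None
        converged = False
        n_iter = 0
        for it in range(int(self.max_iter)):
            n_iter = it + 1
            C = als_update_C(
                M, St, masks["nonneg_C"], masks["zero_C"], self.nonneg_solver
            )
            St = als_update_S(
                M, C, masks["nonneg_S"], masks["zero_S"], self.nonneg_solver
            )
            C, St = normalize_components(C, St, sign_free)
            cur = lof(M, C @ St)
            trace.append(cur)
            if best is None or cur < best[0]:
                best = (cur, C.copy(), St.copy())
            if it > 0:
                delta = abs(trace[-1] - trace[-2])
                if self.convergence == "relative" and trace[-1] > 0:
                    delta /= trace[-1]
                if delta < tol:
                    converged = True
                    break

        self.C_ = best[1]
        self.St_ = best[2]
        self.lof_trace_ = trace
        self.lof_ = best[0]
        self.r2_ = 1.0 - (best[0] / 100.0) ** 2
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = J
        return self

    def transform(self, X) -> np.ndarray:
        """Concentrations of new pixel spectra under the fitted spectra."""
        if not hasattr(self, "St_"):
            raise RuntimeError("MCRALS is not fitted")
        M = X.M if isinstance(X, Multiset) else np.asarray(X, dtype=float)
        if M.shape[1] != self.n_features_in_:
            raise ValueError("channel count differs from the fitted data")
        nonneg = None
        if self.constraints is not None:
            # apply any global (block=None) concentration non-negativity
            K = self.n_components
            g = np.zeros((M.shape[0], K), dtype=bool)
            for rule in self.constraints._nonneg:
                if rule.mode == "C" and rule.block is None:
                    ks = range(K) if rule.component is None else [rule.component]
                    for k in ks:
                        g[:, k] = True
            nonneg = g
        return als_update_C(M, self.St_, nonneg, None, self.nonneg_solver)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).C_


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def run_mcr_als(
    multiset: Multiset | np.ndarray,
    n_components: int,
    init: Any = "simplisma",
    constraints: ConstraintSet | None = None,
    tol_pct: float = 0.1,
    max_iter: int = 50,
    noise_alpha: float = 5.0,
    nonneg_solver: str = "nnls",
    convergence: str = "absolute",
) -> MCRResult:
    """Run constrained MCR-ALS and return the full result record.

    Alternates concentration and spectra updates until the lack-of-fit
    change drops below ``tol_pct`` (default 0.1 percentage points) or
    ``max_iter``; the lowest-LOF iterate is returned.
    """
    est = MCRALS(
        n_components=n_components,
        init=init,
        constraints=constraints,
        tol_pct=tol_pct,
        max_iter=max_iter,
        noise_alpha=noise_alpha,
        nonneg_solver=nonneg_solver,
        convergence=convergence,
    ).fit(multiset)
    return MCRResult(
        C=est.C_,
        St=est.St_,
        lof_trace=est.lof_trace_,
        lof_final=est.lof_,
        r2=est.r2_,
        n_iter=est.n_iter_,
        converged=est.converged_,
        constraint_echo=constraints,
    )


def component_maps(
    result: MCRResult,
    multiset: Multiset,
    sample_id: str,
    fill: float = np.nan,
) -> np.ndarray:
    """Refold one sample's concentration profiles into K distribution maps.

    Returns an array of shape (K, ny, nx); pixels outside the sample's
    pixel index carry ``fill``.
    """
    if sample_id not in multiset.row_blocks:
        raise KeyError(f"unknown sample {sample_id!r}")
    rows = multiset.row_slice(sample_id)
    idx = multiset.pixel_index[sample_id]
    shape = multiset.shapes[sample_id]
    K = result.C.shape[1]
    return np.stack(
        [refold(result.C[rows, k], idx, shape, fill=fill) for k in range(K)]
    )
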