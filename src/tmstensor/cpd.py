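"""Non-negative canonical polyadic (PARAFAC) decomposition of N-way tensors.

The CP model approximates a tensor W by a sum of R rank-one terms,

    W[i1,...,iN]  ≈  Σ_r  F1[i1,r] · F2[i2,r] · ... · FN[iN,r],

with one factor matrix per mode. Here every factor is constrained to be
non-negative, fitted by alternating least squares in which each mode's
subproblem is solved *exactly* (row-wise active-set NNLS on the normal
equations), so the squared-error objective is non-increasing sweep by
sweep — a property the test suite asserts.

Also provided: explained variance, the CORCONDIA core-consistency
diagnostic, rank sweeps for model selection, canonical normalisation
(all modes except the last carry unit-norm columns; scale lives on the
last mode), and Tucker-congruence component matching for recovery
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Tensor5D",
    "CPModel",
    "DecomposeConfig",
    "khatri_rao",
    "unfold",
    "mttkrp",
    "nnls_rows",
    "nncp_als",
    "explained_variance",
    "corcondia",
    "normalize_model",
    "sweep_rank",
    "congruence",
]

MODE_NAMES_5D = ("space", "frequency", "time", "subject", "condition")


@dataclass
class Tensor5D:
    """Labelled 5-way analysis tensor: space × frequency × time × subject × condition."""

    values: np.ndarray
    channels: list[str]
    freqs: np.ndarray
    times: np.ndarray
    subjects: list[str]
    condition_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5:
            raise ValueError(f"expected a 5-way array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite entries")
        labels = (
            self.channels,
            self.freqs,
            self.times,
            self.subjects,
            self.condition_labels,
        )
        for mode, (size, axis) in enumerate(zip(self.values.shape, labels)):
            if len(axis) != size:
                raise ValueError(
                    f"mode {mode} ({MODE_NAMES_5D[mode]}): {size} entries but "
                    f"{len(axis)} labels"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class CPModel:
    """Fitted CP model: one factor matrix per mode, columns = components."""

    factors: list[np.ndarray]
    rank: int
    fit_percent: float
    iterations: int
    converged: bool
    convention: str = "raw"  # or "unit-norm-except-last"
    objective_trace: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.factors)

    def reconstruct(self) -> np.ndarray:
        """Dense reconstruction Σ_r ⊗_n factors[n][:, r]. Small tensors only."""
        shape = tuple(f.shape[0] for f in self.factors)
        out = khatri_rao(self.factors) @ np.ones(self.rank)
        return out.reshape(shape)


@dataclass
class DecomposeConfig:
    """Controls for the alternating least-squares fit."""

    rank: int = 3
    max_iterations: int = 500
    tol: float = 1e-8
    n_restarts: int = 4
    seed: int = 0
    fixed_modes: tuple[int, ...] = ()
    init_factors: list[np.ndarray] | None = None
    nonneg: bool = True
    init: str = "random"  # "random" | "hosvd" (first restart SVD-based)

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.fixed_modes and self.init_factors is None:
            raise ValueError("fixed_modes requires init_factors for those modes")
        if self.init not in ("random", "hosvd"):
            raise ValueError("init must be 'random' or 'hosvd'")


def _values(tensor) -> np.ndarray:
    return tensor.values if hasattr(tensor, "values") else np.asarray(tensor, float)


def khatri_rao(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product, first matrix varying slowest.

    Row ordering matches a C-order flattening of a multi-index over the
    input matrices' rows, i.e. the ordering produced by :func:`unfold`.
    """
    r = mats[0].shape[1]
    out = np.ones((1, r))
    for m in mats:
        if m.shape[1] != r:
            raise ValueError("all matrices must share the column count")
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, r)
    return out


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding with the remaining modes flattened in C order."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def mttkrp(tensor: np.ndarray, factors: Sequence[np.ndarray], mode: int) -> np.ndarray:
    """Matricised-tensor times Khatri-Rao product for the given mode."""
    others = [factors[m] for m in range(tensor.ndim) if m != mode]
    return unfold(tensor, mode) @ khatri_rao(others)


def nnls_rows(H: np.ndarray, B: np.ndarray, nonneg: bool = True) -> np.ndarray:
    """Solve min_x x'Hx − 2b'x (x ≥ 0 if ``nonneg``) for every row b of B.

    H is the R×R Gram matrix shared by all rows. The non-negative case is
    solved exactly by enumerating active sets (2^R − 1 candidate supports
    plus the origin) and selecting, per row, the candidate satisfying the
    KKT conditions; for positive-definite H that point is the unique
    minimiser. Vectorised across rows, which is what makes the exact
    per-mode ALS update cheap. Intended for the small ranks (R ≤ 10)
    used in component analysis.
    """
    H = np.asarray(H, float)
    B = np.asarray(B, float)
    r = H.shape[0]
    if not nonneg:
        return np.linalg.lstsq(H, B.T, rcond=None)[0].T
    if r > 12:
        raise ValueError("active-set enumeration supports rank <= 12")
    # tiny ridge guards exactly singular subset systems without moving
    # well-conditioned solutions at test tolerances
    ridge = 1e-13 * max(np.trace(H) / r, np.finfo(float).tiny)
    Hr = H + ridge * np.eye(r)

    m = B.shape[0]
    best_obj = np.zeros(m)  # objective of the origin x = 0
    best_x = np.zeros((m, r))
    scale = np.abs(B).max(initial=1.0)
    tol = 1e-11 * max(scale, 1.0)

    for k in range(1, r + 1):
        for subset in combinations(range(r), k):
            S = list(subset)
            try:
                xs = np.linalg.solve(Hr[np.ix_(S, S)], B[:, S].T).T
            except np.linalg.LinAlgError:
                continue
            # primal feasibility on the support
            ok = np.all(xs >= -tol, axis=1)
            # dual feasibility off the support: grad = Hx - b >= 0
            comp = [j for j in range(r) if j not in S]
            if comp:
                grad = xs @ Hr[np.ix_(S, comp)] - B[:, comp]
                ok &= np.all(grad >= -tol, axis=1)
            obj = -np.einsum("ij,ij->i", xs, B[:, S])
            better = ok & (obj < best_obj - 1e-15 * max(scale, 1.0))
            if np.any(better):
                best_obj[better] = obj[better]
                best_x[better] = 0.0
                best_x[np.ix_(np.flatnonzero(better), S)] = np.clip(
                    xs[better], 0.0, None
                )
    # rows where nothing beat the origin keep x = 0 (valid when b <= 0)
    return best_x


def _random_init(shape, rank, rng, nonneg):
    f = rng.standard_normal((shape, rank))
    f = np.abs(f) if nonneg else f
    return f / np.linalg.norm(f, axis=0)


def _hosvd_init(W: np.ndarray, rank: int, nonneg: bool) -> list[np.ndarray]:
    """Leading singular vectors of each unfolding (absolute values under the
    non-negativity constraint), unit-norm columns. Much closer to structured
    components than random starts, which can collapse on sparse factors."""
    factors = []
    for m in range(W.ndim):
        Xm = unfold(W, m)
        G = Xm @ Xm.T
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        k = min(rank, vecs.shape[1])
        F = vecs[:, order[:k]]
        if k < rank:  # pad with uniform columns if the mode is too small
            F = np.column_stack([F, np.ones((F.shape[0], rank - k))])
        if nonneg:
            F = np.abs(F)
        F = F + 1e-12  # avoid exactly zero entries locking the active set
        factors.append(F / np.linalg.norm(F, axis=0))
    return factors


def _gram(f: np.ndarray) -> np.ndarray:
    return f.T @ f


def nncp_als(tensor, cfg: DecomposeConfig) -> CPModel:
    """Non-negative CP fit by exact alternating least squares.

    Modes listed in ``cfg.fixed_modes`` keep their ``init_factors`` matrices
    untouched (bit-identical on return); all other modes are re-estimated
    each sweep. The best of ``n_restarts`` random restarts (by residual) is
    returned; with a provided initialisation a single run is performed.
    """
    W = _values(tensor)
    n_modes = W.ndim
    if n_modes < 3:
        raise ValueError("CP decomposition requires an order >= 3 tensor")
    normsq = float(np.sum(W * W))
    if normsq == 0.0:
        raise ValueError("all-zero tensor cannot be decomposed")
    rank = cfg.rank
    if rank > min(W.shape):
        warnings.warn(
            f"rank {rank} exceeds the smallest mode size {min(W.shape)}",
            stacklevel=2,
        )
    for m in cfg.fixed_modes:
        if not 0 <= m < n_modes:
            raise ValueError(f"fixed mode {m} outside 0..{n_modes - 1}")

    free_modes = [m for m in range(n_modes) if m not in cfg.fixed_modes]
    n_restarts = 1 if cfg.init_factors is not None else cfg.n_restarts

    best = None
    restart = 0
    # a component whose column hits exact zero in two or more modes can never
    # re-enter the active set: such collapsed solutions trigger extra restarts
    max_extra = 0 if cfg.init_factors is not None else 3
    extra_used = 0
    while restart < n_restarts + extra_used:
        rng = np.random.default_rng([max(cfg.seed, 0), restart])
        if cfg.init_factors is not None:
            factors = [np.array(f, dtype=float) for f in cfg.init_factors]
            for m, f in enumerate(factors):
                if f.shape != (W.shape[m], rank):
                    raise ValueError(
                        f"init factor {m} has shape {f.shape}, "
                        f"expected {(W.shape[m], rank)}"
                    )
            # fixed modes must alias the provided arrays exactly
            for m in cfg.fixed_modes:
                factors[m] = cfg.init_factors[m]
        else:
            use_hosvd = cfg.init == "hosvd" and restart == 0
            if use_hosvd:
                factors = _hosvd_init(W, rank, cfg.nonneg)
            else:
                factors = [
                    _random_init(W.shape[m], rank, rng, cfg.nonneg)
                    for m in range(n_modes)
                ]
            # scale the unit-norm init so the model norm matches the data norm;
            # a grossly over-scaled start can zero whole columns in the first
            # exact NNLS update, which is hard to escape
            factors = [f * (np.sqrt(normsq) / np.sqrt(rank)) ** (1.0 / n_modes) for f in factors]

        grams = [_gram(f) for f in factors]
        trace = []
        obj_prev = np.inf
        converged = False
        it = 0
        for it in range(1, cfg.max_iterations + 1):
            for m in free_modes:
                H = np.ones((rank, rank))
                for o in range(n_modes):
                    if o != m:
                        H = H * grams[o]
                Bm = mttkrp(W, factors, m)
                factors[m] = nnls_rows(H, Bm, nonneg=cfg.nonneg)
                grams[m] = _gram(factors[m])
            # exact objective via the last updated mode's MTTKRP
            inner = float(np.sum(factors[free_modes[-1]] * Bm))
            Hall = np.ones((rank, rank))
            for o in range(n_modes):
                Hall = Hall * grams[o]
            modelnorm = float(np.sum(Hall))
            obj = normsq - 2.0 * inner + modelnorm
            trace.append(obj)
            if abs(obj_prev - obj) <= cfg.tol * normsq:
                converged = True
                break
            obj_prev = obj

        if best is None or trace[-1] < best[0]:
            best = (trace[-1], factors, it, converged, np.array(trace))

        restart += 1
        if restart == n_restarts + extra_used and extra_used < max_extra:
            best_collapsed = any(
                np.any(np.linalg.norm(f, axis=0) == 0.0) for f in best[1]
            )
            if best_collapsed:
                extra_used += 1

    def _collapsed(model_factors):
        return any(np.any(np.linalg.norm(f, axis=0) == 0.0) for f in model_factors)

    if (
        cfg.init_factors is None
        and cfg.init != "hosvd"
        and _collapsed(best[1])
    ):
        # last resort: a single SVD-initialised run, which rarely collapses
        retry = nncp_als(W, replace(cfg, init="hosvd", n_restarts=1))
        retry_obj = normsq * (1.0 - retry.fit_percent / 100.0)
        if not _collapsed(retry.factors) and retry_obj <= best[0]:
            return retry

    obj, factors, iterations, converged, trace = best
    fit = 100.0 * (1.0 - max(obj, 0.0) / normsq)
    fit = min(fit, 100.0)
    model = CPModel(
        factors=factors,
        rank=rank,
        fit_percent=fit,
        iterations=iterations,
        converged=converged,
        convention="raw",
        objective_trace=trace,
    )
    if not cfg.nonneg:
        _degeneracy_watch(model)
    return model


def _degeneracy_watch(model: CPModel, threshold: float = -0.85) -> None:
    """Warn on the classical two-component CP degeneracy signature."""
    if model.rank < 2:
        return
    prod = np.ones((model.rank, model.rank))
    for f in model.factors:
        norms = np.linalg.norm(f, axis=0)
        if np.any(norms == 0):
            return
        fn = f / norms
        prod = prod * (fn.T @ fn)
    off = prod[~np.eye(model.rank, dtype=bool)]
    if np.any(off < threshold):
        warnings.warn(
            "possible degenerate CP solution: component congruence product "
            f"below {threshold}",
            stacklevel=3,
        )


def explained_variance(model: CPModel, tensor) -> float:
    """Explained variance 100·(1 − ‖W − Ŵ‖²_F / ‖W‖²_F) of the CP fit.

    Computed from factor Grams and one MTTKRP, never from a dense
    reconstruction, so it is safe at the full study scale.
    """
    W = _values(tensor)
    if W.ndim != model.n_modes:
        raise ValueError("tensor order does not match the model")
    for m, f in enumerate(model.factors):
        if f.shape[0] != W.shape[m]:
            raise ValueError(f"mode {m}: tensor size {W.shape[m]} vs factor {f.shape[0]}")
    normsq = float(np.sum(W * W))
    if normsq == 0.0:
        raise ValueError("zero-norm tensor: explained variance undefined")
    rank = model.rank
    Bm = mttkrp(W, model.factors, model.n_modes - 1)
    inner = float(np.sum(model.factors[-1] * Bm))
    Hall = np.ones((rank, rank))
    for f in model.factors:
        Hall = Hall * _gram(f)
    modelnorm = float(np.sum(Hall))
    resid = normsq - 2.0 * inner + modelnorm
    return min(100.0 * (1.0 - max(resid, 0.0) / normsq), 100.0)


def corcondia(model: CPModel, tensor) -> float:
    """Core-consistency diagnostic of a CP model.

    Fits the least-squares Tucker core G given the model's factor matrices
    and scores its similarity to the ideal superdiagonal core T:
    100·(1 − Σ(g−t)² / Σt²). Near 100 means the data support a fully
    multilinear (trilinear/N-linear) model at this rank; values collapsing
    toward zero or below flag overfactoring. The core is computed on the
    factor-projected (compressed) tensor, which equals the dense
    least-squares core whenever the factors have full column rank.
    """
    W = _values(tensor)
    if W.ndim != model.n_modes:
        raise ValueError("tensor order does not match the model")
    rank = model.rank
    core = W
    for m, f in enumerate(model.factors):
        if f.shape[0] != W.shape[m]:
            raise ValueError(f"mode {m}: tensor size {W.shape[m]} vs factor {f.shape[0]}")
        sv = np.linalg.svd(f, compute_uv=False)
        if sv[0] == 0 or sv[-1] < 1e-10 * sv[0]:
            raise ValueError(
                f"factor matrix for mode {m} is (numerically) rank-deficient; "
                "the core-consistency core is not identified — try a lower rank"
            )
        pinv = np.linalg.pinv(f)
        core = np.moveaxis(np.tensordot(pinv, core, axes=(1, m)), 0, m)
    ideal = np.zeros((rank,) * model.n_modes)
    idx = (np.arange(rank),) * model.n_modes
    ideal[idx] = 1.0
    return float(100.0 * (1.0 - np.sum((core - ideal) ** 2) / rank))


def normalize_model(model: CPModel, strict: bool = True) -> CPModel:
    """Rescale to the canonical convention: unit-norm columns on every mode
    except the last; all component scale absorbed into the last mode.

    The reconstruction is unchanged. With ``strict`` a zero column raises;
    otherwise its scale moves to the last mode as an exact zero and the
    column direction is left in place.
    """
    factors = [np.array(f, dtype=float) for f in model.factors]
    scale = np.ones(model.rank)
    for m in range(model.n_modes - 1):
        norms = np.linalg.norm(factors[m], axis=0)
        zero = norms == 0.0
        if np.any(zero):
            if strict:
                comp = int(np.flatnonzero(zero)[0])
                raise ValueError(
                    f"component {comp} has an all-zero column in mode {m}; "
                    "cannot normalise"
                )
            norms = np.where(zero, 1.0, norms)
            scale = scale * np.where(zero, 0.0, norms)
        else:
            scale = scale * norms
        factors[m] = factors[m] / norms
    factors[-1] = factors[-1] * scale
    return replace(
        model, factors=factors, convention="unit-norm-except-last"
    )


def sweep_rank(
    tensor,
    ranks: Sequence[int] = tuple(range(1, 9)),
    cfg: DecomposeConfig | None = None,
) -> pd.DataFrame:
    """Fit one model per candidate rank and tabulate the selection diagnostics.

    Every rank uses the same seed and restart budget so the rows are
    comparable. CORCONDIA entries are NaN where the fitted factors are
    rank-deficient (a strong overfactoring signal in itself).
    """
    if len(ranks) == 0:
        raise ValueError("ranks must be non-empty")
    base = cfg or DecomposeConfig()
    rows = []
    for r in ranks:
        rcfg = replace(base, rank=int(r))
        model = nncp_als(tensor, rcfg)
        try:
            cc = corcondia(model, tensor)
        except ValueError:
            cc = np.nan
        rows.append(
            {
                "rank": int(r),
                "explained_variance": explained_variance(model, tensor),
                "corcondia": cc,
                "converged": model.converged,
                "iterations": model.iterations,
            }
        )
    return pd.DataFrame(rows)


def congruence(
    model_a: CPModel,
    model_b: CPModel,
    modes: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tucker congruence between components of two models.

    Returns ``(C, matching)`` where ``C[p, q]`` is the congruence between
    component p of ``model_a`` and q of ``model_b`` averaged over ``modes``
    (default: all modes), and ``matching`` is the optimal one-to-one
    assignment (array such that component p of A pairs with
    ``matching[p]`` of B) maximising total congruence.
    """
    if modes is None:
        modes = range(model_a.n_modes)
    modes = list(modes)
    if model_a.n_modes != model_b.n_modes:
        raise ValueError("models have different numbers of modes")
    C = np.zeros((model_a.rank, model_b.rank))
    for m in modes:
        fa, fb = model_a.factors[m], model_b.factors[m]
        if fa.shape[0] != fb.shape[0]:
            raise ValueError(f"mode {m} sizes differ: {fa.shape[0]} vs {fb.shape[0]}")
        na = np.linalg.norm(fa, axis=0)
        nb = np.linalg.norm(fb, axis=0)
        if np.any(na == 0) or np.any(nb == 0):
            raise ValueError(f"zero column in mode {m}; congruence undefined")
        C += (fa / na).T @ (fb / nb)
    C /= len(modes)
    row, col = linear_sum_assignment(-C)
    matching = np.empty(model_a.rank, dtype=int)
    matching[row] = col
    return C, matching
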