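"""Mutation-selection-drift likelihood machinery for unfolded SFS data.

The model is the Poisson-random-field description of segregating new
mutations: a site class of ``L`` sites receives new mutations at per-site
scaled rate ``theta``; a mutation with scaled selection coefficient
``S = N_e * s`` (negative deleterious, positive advantageous) segregates at
population frequency ``x`` with expected sojourn density

    tau(x; S) = 2 (1 - exp(-S (1 - x))) / [x (1 - x) (1 - exp(-S))]

(``2/x`` in the neutral limit).  Sampling ``n`` haploid sequences bins this
density into SFS classes ``i = 1..n``; the fixed-derived class ``i = n``
additionally receives a fixation flux ``theta * T_div * u(S)`` with
``u(S) = S / (1 - exp(-S))`` the fixation probability relative to neutral,
and the invariant class ``i = 0`` is the remainder ``L - sum``.

Fitness effects follow a configurable distribution (DFE): an optional
advantageous point mass ``p_a`` at ``+S_a`` and a deleterious component that
is absent, a point mass, or gamma distributed with mean ``NeSd_mean`` and
shape ``beta_d``.  The seven-model family fitted by :func:`fit_model` nests
these choices; nuisance parameters (``theta``, ``T_div``, and, optionally,
a two-epoch population-size change) are profiled jointly with the neutral
reference class.

All binomially sampled sojourn integrals have a closed form in the Kummer
confluent hypergeometric function, so no quadrature is needed for the
segregating classes; only the fixed-class segregating remainder uses a
fixed Gauss-Legendre rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, special
from scipy import stats as sps

from .wright_fisher import TwoEpochExpectation

__all__ = [
    "DFEParams",
    "DemographyModel",
    "NuisanceParams",
    "ModelFit",
    "EffectBins",
    "LRTResult",
    "sojourn_density",
    "fixation_rate",
    "binomial_sojourn",
    "fixed_class_segregating_integral",
    "expected_sfs",
    "discretize_gamma",
    "fit_neutral",
    "fit_model",
    "effect_bins",
    "lrt",
    "lrt_partition",
    "demography_test",
    "MODEL_N_PARAMS",
]

_GL_X, _GL_W = leggauss(240)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0

#: scaled-effect magnitude beyond which deleterious contributions are clamped
S_CAP = 5000.0

#: number of free selection parameters per model id (nuisances excluded)
MODEL_N_PARAMS = {1: 1, 2: 2, 3: 2, 4: 3, 5: 2, 6: 3, 7: 4}


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DFEParams:
    """Selection-model parameters on the ``N_e s`` scale.

    ``p_a`` and ``S_a`` describe the advantageous point mass; the remaining
    mass ``1 - p_a`` is deleterious with kind ``"none"`` (neutral),
    ``"equal"`` (point mass at ``NeSd_mean``) or ``"gamma"`` (mean
    ``NeSd_mean``, shape ``beta_d``).  ``NeSd_mean = inf`` with kind
    ``"gamma"`` denotes a boundary fit whose deleterious mass lies entirely
    above any finite threshold.
    """

    p_a: float = 0.0
    S_a: float = 0.0
    deleterious_kind: str = "gamma"
    NeSd_mean: float = 0.0
    beta_d: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError(f"p_a must be in [0, 1], got {self.p_a}")
        if self.S_a < 0:
            raise ValueError("S_a is a magnitude and must be >= 0")
        if self.deleterious_kind not in ("none", "equal", "gamma"):
            raise ValueError(f"unknown deleterious kind {self.deleterious_kind!r}")
        if self.deleterious_kind == "gamma" and not self.beta_d > 0:
            raise ValueError("gamma shape beta_d must be > 0")
        if self.NeSd_mean < 0:
            raise ValueError("NeSd_mean is a magnitude and must be >= 0")


@dataclass(frozen=True)
class DemographyModel:
    """Constant size, or a single size change (ratio ``size_ratio``) at
    ``change_time`` (units of 2N generations of the post-change population)."""

    kind: str = "constant"
    size_ratio: float = 1.0
    change_time: float = 0.0
    grid_size: int = 200

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "two_epoch"):
            raise ValueError(f"unknown demography kind {self.kind!r}")
        if self.size_ratio <= 0 or self.change_time < 0:
            raise ValueError("size_ratio must be > 0 and change_time >= 0")


@dataclass(frozen=True)
class NuisanceParams:
    theta: float
    T_div: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and self.theta > 0):
            raise ValueError("theta must be finite and > 0")
        if not (math.isfinite(self.T_div) and self.T_div >= 0):
            raise ValueError("T_div must be finite and >= 0")


@dataclass
class ModelFit:
    model_id: int
    params: DFEParams
    nuisance: NuisanceParams
    demography: DemographyModel
    logL: float
    n_params: int
    converged: bool = True
    boundary_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EffectBins:
    """Proportions of the deleterious distribution in NeSd bins
    (<1, 1-10, 10-100, >100)."""

    p_lt1: float
    p_1_10: float
    p_10_100: float
    p_gt100: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_lt1, self.p_1_10, self.p_10_100, self.p_gt100])


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# sojourn density and sampling integrals


def sojourn_density(x, S):
    """Expected density tau(x; S) of segregating mutations at frequency x.

    Evaluated in an overflow-safe form for arbitrarily strong selection.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("x must lie in the open interval (0, 1)")
    S = float(S)
    if abs(S) < 1e-8:
        return 2.0 / x
    if S < 0:
        A = -S
        num = np.exp(-A * x) - math.exp(-A)
        den = -math.expm1(-A)
    else:
        num = -np.expm1(-S * (1.0 - x))
        den = -math.expm1(-min(S, 700.0))
    return 2.0 * num / (x * (1.0 - x) * den)


def fixation_rate(S):
    """Fixation probability of a new mutation relative to neutral,
    u(S) = S / (1 - exp(-S)); u(0) = 1."""
    S = np.atleast_1d(np.asarray(S, dtype=float))
    out = np.ones_like(S)
    neg = S < -1e-8
    pos = S > 1e-8
    A = -S[neg]
    small = A <= 500.0
    out[neg] = np.where(small, A * np.exp(-np.minimum(A, 500.0)) / (-np.expm1(-np.minimum(A, 500.0))), 0.0)
    out[pos] = S[pos] / (-np.expm1(-S[pos]))
    return out if out.size > 1 else float(out[0])


def _sojourn_ratio(n: int, S: np.ndarray) -> np.ndarray:
    """Stable evaluation of int_0^1 x^i (1-x)^{n-i} tau(x;S) dx divided by
    2 B(i, n-i), for i = 1..n-1, via Kummer's function."""
    i = np.arange(1, n)
    S = np.atleast_1d(np.asarray(S, dtype=float))
    out = np.empty((S.size, n - 1))
    near0 = np.abs(S) < 1e-8
    neg = S < 0
    if np.any(near0):
        out[near0] = (n - i) / n
    mneg = neg & ~near0
    if np.any(mneg):
        A = -S[mneg][:, None]
        M = special.hyp1f1(i[None, :], n, -A)
        out[mneg] = (M - np.exp(-A)) / (-np.expm1(-A))
    mpos = ~neg & ~near0
    if np.any(mpos):
        Sp = S[mpos][:, None]
        out[mpos] = (1.0 - special.hyp1f1(n - i[None, :], n, -Sp)) / (
            -np.expm1(-np.minimum(Sp, 700.0))
        )
    return out


def binomial_sojourn(n: int, S) -> np.ndarray:
    """Expected SFS contribution per unit theta for classes i = 1..n-1.

    Returns an array of shape ``(len(S), n-1)`` whose entry [k, i-1] is
    ``int_0^1 C(n,i) x^i (1-x)^{n-i} tau(x; S_k) dx`` (exactly ``2/i`` at
    S = 0, the Watterson expectation).
    """
    i = np.arange(1, n)
    coef = 2.0 * special.comb(n, i) * special.beta(i, n - i)
    return coef[None, :] * _sojourn_ratio(n, S)


def fixed_class_segregating_integral(n: int, S) -> np.ndarray:
    """int_0^1 x^n tau(x; S) dx: segregating mass sampled as fixed (i = n)."""
    S = np.atleast_1d(np.asarray(S, dtype=float))[:, None]
    x = _GL_X[None, :]
    A = np.abs(S)
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = np.where(
            np.abs(S) < 1e-8,
            1.0 - x,
            np.where(
                S < 0,
                (np.exp(-A * x) - np.exp(-A)) / (-np.expm1(-A)),
                (-np.expm1(-S * (1.0 - x))) / (-np.expm1(-np.minimum(S, 700.0))),
            ),
        )
    return (2.0 * x ** (n - 1) / (1.0 - x) * ratio) @ _GL_W


# ---------------------------------------------------------------------------
# expected SFS


def discretize_gamma(NeSd_mean: float, beta_d: float, K: int = 200,
                     cap: float = S_CAP) -> tuple[np.ndarray, np.ndarray]:
    """Equal-mass discretization of a gamma DFE into K support points.

    Each of the K equal-probability slabs is represented by its conditional
    mean (computed from the shape ``beta_d + 1`` gamma CDF), with mass 1/K;
    points are returned as negative scaled effects, magnitudes clamped at
    ``cap`` to keep downstream exponentials finite.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (NeSd_mean > 0 and beta_d > 0):
        raise ValueError("gamma DFE needs positive mean and shape")
    if K == 1 or not math.isfinite(NeSd_mean):
        pt = min(NeSd_mean, cap) if math.isfinite(NeSd_mean) else cap
        return np.array([-pt]), np.array([1.0])
    scale = NeSd_mean / beta_d
    q = np.concatenate([[0.0], np.arange(1, K) / K, [1.0]])
    edges = sps.gamma.ppf(q, a=beta_d, scale=scale)
    F1 = sps.gamma.cdf(edges, a=beta_d + 1, scale=scale)
    F1[-1] = 1.0
    pts = NeSd_mean * np.diff(F1) * K
    pts = np.minimum(pts, cap)
    return -pts, np.full(K, 1.0 / K)


def dfe_mixture(params: DFEParams, K: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Discrete (S, weight) representation of a DFE."""
    pts: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    if params.p_a > 0:
        pts.append(np.array([params.S_a]))
        wts.append(np.array([params.p_a]))
    w_del = 1.0 - params.p_a
    if w_del > 0:
        if params.deleterious_kind == "none":
            pts.append(np.array([0.0]))
            wts.append(np.array([w_del]))
        elif params.deleterious_kind == "equal":
            pts.append(np.array([-min(params.NeSd_mean, S_CAP)]))
            wts.append(np.array([w_del]))
        else:
            s, w = discretize_gamma(params.NeSd_mean, params.beta_d, K)
            pts.append(s)
            wts.append(w * w_del)
    return np.concatenate(pts), np.concatenate(wts)


def expected_sfs(
    n: int,
    mixture: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    theta: float,
    T_div: float,
    L: float,
    demography: DemographyModel | None = None,
) -> np.ndarray:
    """Expected unfolded SFS counts e_0..e_n for a site class of L sites.

    ``mixture`` is a sequence of (S, weight) pairs (weights summing to 1)
    or a pre-split ``(S_array, w_array)`` tuple.  Under a two-epoch
    demography the segregating classes come from a discrete Wright-Fisher
    grid of ``demography.grid_size`` haploid copies; fixations during the
    post-change epoch are absorbed into the free divergence term.
    """
    if isinstance(mixture, tuple) and len(mixture) == 2 and np.ndim(mixture[0]) == 1:
        S, w = np.asarray(mixture[0], float), np.asarray(mixture[1], float)
    else:
        arr = np.asarray(list(mixture), dtype=float)
        S, w = arr[:, 0], arr[:, 1]
    if np.any(w < 0):
        raise ValueError("mixture weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("mixture weights must sum to 1")

    if demography is not None and demography.kind == "two_epoch":
        model = TwoEpochExpectation(demography.grid_size)
        b = np.zeros(n - 1)
        bn = 0.0
        for Sk, wk in zip(S, w):
            bi, bni = model.sampled_bins(n, demography.size_ratio,
                                         demography.change_time, Sk)
            b += wk * bi
            bn += wk * bni
        scale = model.theta_scale(n)
        e_seg = L * theta * b / scale
        e_n = L * theta * (T_div * float(np.dot(w, np.atleast_1d(fixation_rate(S))))
                           + bn / scale)
    else:
        b = binomial_sojourn(n, S)
        e_seg = L * theta * (w @ b)
        qn = fixed_class_segregating_integral(n, S)
        e_n = L * theta * (T_div * float(np.dot(w, np.atleast_1d(fixation_rate(S))))
                           + float(w @ qn))
    e = np.concatenate([e_seg, [e_n]])
    total = e.sum()
    if total >= L:
        raise ValueError(
            f"expected polymorphic+fixed mass {total:.3g} exceeds L={L}; "
            "theta or T_div too large for this site class"
        )
    return np.concatenate([[L - total], e])


# ---------------------------------------------------------------------------
# likelihood and fitting


def _poisson_loglik(counts: np.ndarray, expected: np.ndarray) -> float:
    e = np.maximum(expected, 1e-300)
    return float(np.sum(counts * np.log(e)) - expected.sum())


def _neutral_expected(n: int, theta: float, T_div: float, L: float) -> np.ndarray:
    return expected_sfs(n, (np.array([0.0]), np.array([1.0])), theta, T_div, L)


def fit_neutral(sfs_counts: np.ndarray, n: int) -> tuple[NuisanceParams, float]:
    """ML estimate of (theta, T_div) from a neutral-class unfolded SFS.

    Closed form: with e_i = theta L b_i for the segregating classes and a
    free fixed-class mean, the Poisson likelihood profiles exactly.
    """
    c = np.asarray(sfs_counts, dtype=float)
    L = c.sum()
    c0, cseg, cn = c[0], c[1:-1], c[-1]
    b = binomial_sojourn(n, np.array([0.0]))[0]
    qn = float(fixed_class_segregating_integral(n, np.array([0.0]))[0])
    Sseg = cseg.sum()
    if Sseg == 0 or c0 == 0:
        raise ValueError("neutral SFS must contain invariant and segregating sites")
    R = L * c0 / (c0 + Sseg + cn)
    theta = Sseg * R / (b.sum() * c0 * L)
    mu_n = cn * R / c0
    T_div = max(mu_n / (theta * L) - qn, 0.0)
    nuis = NuisanceParams(theta=theta, T_div=T_div)
    ll = _poisson_loglik(c, _neutral_expected(n, theta, T_div, L))
    return nuis, ll


class _ModelSpec:
    """Free-parameter layout for one of the seven DFE models."""

    def __init__(self, model_id: int):
        self.model_id = model_id
        # (name, transform) for each free selection parameter
        free = {
            1: ["NeSd_mean"],
            2: ["NeSd_mean", "beta_d"],
            3: ["NeSd_mean", "p_a"],
            4: ["NeSd_mean", "beta_d", "p_a"],
            5: ["p_a", "S_a"],
            6: ["NeSd_mean", "p_a", "S_a"],
            7: ["NeSd_mean", "beta_d", "p_a", "S_a"],
        }[model_id]
        self.free = free
        self.kind = {1: "equal", 2: "gamma", 3: "equal", 4: "gamma",
                     5: "none", 6: "equal", 7: "gamma"}[model_id]
        # models 3 and 4 fix the advantageous effect at ~0
        self.fixed_S_a = 1e-6 if model_id in (3, 4) else None

    _BOUNDS = {
        "NeSd_mean": (math.log(1e-4), math.log(1e7)),
        "beta_d": (math.log(0.02), math.log(60.0)),
        "p_a": (-12.0, 12.0),  # logit scale
        "S_a": (math.log(1e-6), math.log(2e3)),
    }

    def to_params(self, x: np.ndarray) -> DFEParams:
        d = dict(zip(self.free, x))
        p_a = 1.0 / (1.0 + math.exp(-d["p_a"])) if "p_a" in d else 0.0
        S_a = math.exp(d["S_a"]) if "S_a" in d else (self.fixed_S_a or 0.0)
        if "p_a" in d and self.fixed_S_a is not None:
            S_a = self.fixed_S_a
        return DFEParams(
            p_a=p_a,
            S_a=S_a if p_a > 0 else 0.0,
            deleterious_kind=self.kind,
            NeSd_mean=math.exp(d["NeSd_mean"]) if "NeSd_mean" in d else 0.0,
            beta_d=math.exp(d["beta_d"]) if "beta_d" in d else 1.0,
        )

    def in_bounds(self, x: np.ndarray) -> bool:
        return all(lo <= v <= hi for v, (lo, hi) in
                   ((v, self._BOUNDS[name]) for name, v in zip(self.free, x)))

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        draw = {
            "NeSd_mean": lambda: math.log(10.0 ** rng.uniform(-0.5, 3.5)),
            "beta_d": lambda: math.log(10.0 ** rng.uniform(-1.3, 0.6)),
            "p_a": lambda: rng.uniform(-6.0, 0.0),
            "S_a": lambda: math.log(10.0 ** rng.uniform(-3.0, 1.5)),
        }
        return np.array([draw[name]() for name in self.free])

    def default_start(self) -> np.ndarray:
        defaults = {"NeSd_mean": math.log(50.0), "beta_d": math.log(0.4),
                    "p_a": -4.0, "S_a": math.log(1.0)}
        return np.array([defaults[name] for name in self.free])


def fit_model(
    sfs_neutral,
    sfs_selected,
    model_id: int,
    demography_kind: str = "constant",
    n_starts: int = 10,
    seed: int = 0,
    K: int = 200,
    grid_size: int = 200,
) -> ModelFit:
    """Fit one of the seven DFE models by joint maximum likelihood.

    The per-site mutation rate ``theta`` and the divergence nuisance
    ``T_div`` are shared between the neutral and selected classes (the
    neutral-to-selected contrast is what identifies the absolute scale of
    selection) and profiled jointly with the selection parameters; the
    reported ``logL`` is the joint Poisson log-likelihood over both SFS.
    ``n_params`` counts only the free selection parameters.
    """
    if model_id not in MODEL_N_PARAMS:
        raise ValueError(f"model_id must be 1..7, got {model_id}")
    cn_ = np.asarray(getattr(sfs_neutral, "counts", sfs_neutral), dtype=float)
    cs_ = np.asarray(getattr(sfs_selected, "counts", sfs_selected), dtype=float)
    n = len(cn_) - 1
    if len(cs_) != n + 1:
        raise ValueError("neutral and selected SFS must share the sample size n")
    Ln, Ls = cn_.sum(), cs_.sum()

    demog = None
    if demography_kind == "two_epoch":
        raise NotImplementedError(
            "selected-class fitting is defined for the constant-size model; "
            "size change is assessed on the neutral class by demography_test"
        )

    spec = _ModelSpec(model_id)
    nuis0, _ = fit_neutral(cn_, n)
    x_nuis0 = np.array([math.log(nuis0.theta), math.log(max(nuis0.T_div, 1e-3))])

    def selected_negll(x_s: np.ndarray, theta: float, T_div: float) -> float:
        if not spec.in_bounds(x_s):
            return 1e12
        params = spec.to_params(x_s)
        try:
            e_s = expected_sfs(n, dfe_mixture(params, K), theta, T_div, Ls,
                               demography=demog)
        except (ValueError, FloatingPointError):
            return 1e12
        return -_poisson_loglik(cs_, e_s)

    def negll(z: np.ndarray) -> float:
        x_n, x_s = z[:2], z[2:]
        theta, T_div = math.exp(x_n[0]), math.exp(x_n[1])
        if not (1e-8 < theta < 0.5 and T_div < 1e4):
            return 1e12
        try:
            e_n = _neutral_expected(n, theta, T_div, Ln)
        except ValueError:
            return 1e12
        return selected_negll(x_s, theta, T_div) - _poisson_loglik(cn_, e_n)

    # stage 1: selection parameters alone, nuisances held at the neutral fit
    rng = np.random.default_rng(seed)
    stage1_starts = [spec.default_start()]
    for _ in range(max(n_starts - 1, 0)):
        stage1_starts.append(spec.random_start(rng))
    stage1 = []
    for x0 in stage1_starts:
        res = optimize.minimize(
            selected_negll, x0, args=(nuis0.theta, nuis0.T_div),
            method="Nelder-Mead",
            options=dict(xatol=1e-5, fatol=1e-8, maxiter=2000),
        )
        stage1.append(res)
    stage1.sort(key=lambda r: r.fun)

    # stage 2: joint refinement of nuisances + selection from the best
    # stage-1 solutions, with a restart of the winner
    best = None
    for res1 in stage1[:3]:
        res = optimize.minimize(
            negll, np.concatenate([x_nuis0, res1.x]), method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-9, maxiter=4000, maxfev=6000),
        )
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        negll, best.x, method="Nelder-Mead",
        options=dict(xatol=1e-7, fatol=1e-10, maxiter=4000, maxfev=6000),
    )
    if res.fun < best.fun:
        best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(f"model {model_id} fit failed to converge")

    theta, T_div = math.exp(best.x[0]), math.exp(best.x[1])
    params = spec.to_params(best.x[2:])
    flags = []
    if params.deleterious_kind == "gamma" and params.NeSd_mean > 1e6:
        flags.append("NeSd_mean at upper boundary")
    if params.deleterious_kind == "gamma" and params.beta_d <= 0.021:
        flags.append("beta_d at lower boundary")
    return ModelFit(
        model_id=model_id,
        params=params,
        nuisance=NuisanceParams(theta=theta, T_div=T_div),
        demography=DemographyModel(kind="constant", grid_size=grid_size),
        logL=-best.fun,
        n_params=MODEL_N_PARAMS[model_id],
        converged=bool(best.success or best.fun < 1e11),
        boundary_flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# summaries and tests


def effect_bins(params: DFEParams) -> EffectBins:
    """Proportions of the deleterious distribution with NeSd in
    (<1), (1-10), (10-100), (>100).

    A gamma component with an infinite (boundary) mean places all mass in
    the strongest bin.
    """
    if params.deleterious_kind == "none":
        raise ValueError("effect bins are undefined for a model with no "
                         "deleterious component")
    edges = np.array([1.0, 10.0, 100.0])
    if params.deleterious_kind == "equal":
        m = params.NeSd_mean
        idx = int(np.searchsorted(edges, m, side="right"))
        p = np.zeros(4)
        p[idx] = 1.0
    else:
        if not math.isfinite(params.NeSd_mean):
            p = np.array([0.0, 0.0, 0.0, 1.0])
        else:
            cdf = sps.gamma.cdf(edges, a=params.beta_d,
                                scale=params.NeSd_mean / params.beta_d)
            p = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return EffectBins(*p)


def _logl_nparams(fit) -> tuple[float, int]:
    if isinstance(fit, ModelFit):
        return fit.logL, fit.n_params
    logL, k = fit
    return float(logL), int(k)


def lrt(fit_restricted, fit_full, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of nested fits; each argument is a ModelFit or
    a ``(logL, n_params)`` pair."""
    l0, k0 = _logl_nparams(fit_restricted)
    l1, k1 = _logl_nparams(fit_full)
    df = k1 - k0
    if df <= 0:
        raise ValueError("full model must have more free parameters")
    stat = 2.0 * (l1 - l0)
    if stat < -tol:
        raise ValueError(
            f"negative LRT statistic {stat:.4g}: restricted fit beats the "
            "full fit beyond tolerance; optimization failure"
        )
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df,
                     p_value=float(sps.chi2.sf(stat, df)))


def lrt_partition(fit_pooled, fits_by_group: Sequence, tol: float = 1e-6) -> LRTResult:
    """Pooled-vs-partitioned LRT: full log-likelihood is the sum over group
    fits, with df = groups * k - k for k parameters per group."""
    l0, k = _logl_nparams(fit_pooled)
    parts = [_logl_nparams(f) for f in fits_by_group]
    if any(kp != k for _, kp in parts):
        raise ValueError("group fits must estimate the same parameters as "
                         "the pooled fit")
    l1 = sum(lp for lp, _ in parts)
    df = len(parts) * k - k
    stat = 2.0 * (l1 - l0)
    if stat < -tol:
        raise ValueError(f"negative LRT statistic {stat:.4g}")
    return LRTResult(statistic=max(stat, 0.0), df=df,
                     p_value=float(sps.chi2.sf(max(stat, 0.0), df)))


def demography_test(
    sfs_neutral,
    grid_size: int = 200,
    r_bounds: tuple[float, float] = (0.1, 5.0),
    t_bounds: tuple[float, float] = (0.005, 1.0),
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[float, float, dict]:
    """LRT of a two-epoch size change against constant size, on the
    neutral class alone.

    Both hypotheses are evaluated on the same discrete Wright-Fisher grid
    (the constant model is the two-epoch model with size ratio fixed at 1),
    so the null is exactly nested; theta and the fixed-class divergence are
    profiled out in closed form.  Returns ``(statistic, p_value, details)``
    with the p-value from the chi-square upper tail at df = 2.
    """
    c = np.asarray(getattr(sfs_neutral, "counts", sfs_neutral), dtype=float)
    n = len(c) - 1
    L = c.sum()
    model = TwoEpochExpectation(grid_size)

    def profiled(r: float, t: float) -> float:
        b, bn = model.sampled_bins(n, r, t, 0.0)
        return _profiled_grid_loglik(c, b, bn, L)

    ll0 = profiled(1.0, 0.0)

    lo = (math.log(r_bounds[0]), math.log(t_bounds[0]))
    hi = (math.log(r_bounds[1]), math.log(t_bounds[1]))

    def negll(z: np.ndarray) -> float:
        if not all(a <= v <= b for v, a, b in zip(z, lo, hi)):
            return 1e12
        return -profiled(math.exp(z[0]), math.exp(z[1]))

    rng = np.random.default_rng(seed)
    starts = [np.array([math.log(2.0), math.log(0.1)]),
              np.array([math.log(0.5), math.log(0.3)])]
    for _ in range(max(n_starts - 2, 0)):
        starts.append(np.array([rng.uniform(lo[0], hi[0]),
                                rng.uniform(lo[1], hi[1])]))
    best = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-3, fatol=1e-5,
                                             maxiter=250))
        if best is None or res.fun < best.fun:
            best = res
    ll1 = max(-best.fun, ll0)
    stat = 2.0 * (ll1 - ll0)
    p = float(sps.chi2.sf(stat, 2))
    details = {"logL_constant": ll0, "logL_change": ll1,
               "size_ratio": math.exp(best.x[0]),
               "change_time": math.exp(best.x[1])}
    return stat, p, details


def _profiled_grid_loglik(c: np.ndarray, b: np.ndarray, bn_seg: float,
                          L: float) -> float:
    """Poisson log-likelihood with theta and the fixed-class mean profiled
    out in closed form.

    With e_i = theta b_i (i = 1..n-1), a free fixed-class mean mu_n and
    e_0 = L - sum, the stationarity conditions give R = L c_0 / (c_0 + S + c_n),
    theta = S R / (B c_0), mu_n = c_n R / c_0 where S and B are the summed
    segregating counts and masses.
    """
    c0, cseg, cn = c[0], c[1:-1], c[-1]
    S = cseg.sum()
    B = b.sum()
    if S == 0 or c0 == 0 or B <= 0:
        raise ValueError("degenerate SFS for profiled likelihood")
    R = L * c0 / (c0 + S + cn)
    theta = S * R / (B * c0)
    mu_n = cn * R / c0
    ll = c0 * math.log(R) + float(np.sum(cseg * np.log(theta * b))) - L
    if cn > 0:
        ll += cn * math.log(mu_n)
    return ll
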