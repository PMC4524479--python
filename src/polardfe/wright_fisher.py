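"""Discrete Wright-Fisher transition-matrix machinery.

Used for the two-epoch (population size change) expected SFS and as the
numerical backbone of the demography likelihood-ratio test.  The population
is a haploid pool of ``M`` copies; genic selection with per-generation
coefficient ``s`` biases the binomial sampling probability to
``p(1+s)/(1+ps)``.  The scaled effect convention matches the diffusion
sojourn density used elsewhere in the package: a scaled effect ``S``
corresponds to ``s = S / (2 M)``.

Expected segregating-site densities are linear in the mutation influx, so
all results are computed for a reference influx of one new mutation per
generation in the ancestral epoch (``M2 / M1`` per generation after a size
change to ``M2`` copies, mutation supply being proportional to population
size) and rescaled by ``theta`` downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy import stats as sps

__all__ = ["transition_matrix", "equilibrium_density", "TwoEpochExpectation"]


def transition_matrix(M: int, S: float = 0.0) -> np.ndarray:
    """(M+1) x (M+1) Wright-Fisher transition matrix, entry [j, k] the
    probability of moving from j to k copies in one generation."""
    s = S / (2.0 * M)
    p = np.arange(M + 1) / M
    p_sel = p * (1.0 + s) / (1.0 + p * s)
    return sps.binom.pmf(np.arange(M + 1)[None, :], M, p_sel[:, None])


def equilibrium_density(M: int, S: float = 0.0, influx: float = 1.0) -> np.ndarray:
    """Expected number of segregating sites at copy number j = 1..M-1 under
    a constant influx of new mutations (at one copy) per generation."""
    P = transition_matrix(M, S)
    Q = P[1:M, 1:M]
    rhs = np.zeros(M - 1)
    rhs[0] = influx
    return linalg.solve(np.eye(M - 1) - Q.T, rhs)


class TwoEpochExpectation:
    """Expected sample SFS under an instantaneous size change.

    The ancestral population of ``grid_size`` haploid copies sits at its
    mutation-drift-selection equilibrium; at ``change_time`` (units of 2N
    generations of the post-change population) the size jumps to
    ``size_ratio * grid_size`` copies (clamped to [20, 1000] states) and the
    density is evolved generation by generation with influx proportional to
    the new size.  ``size_ratio = 1`` with any change time reproduces the
    constant-size equilibrium exactly, so the constant model is exactly
    nested.  Transition matrices and equilibria are cached per (size, S).
    """

    MIN_STATES = 20
    MAX_STATES = 1000

    def __init__(self, grid_size: int = 200):
        if grid_size < self.MIN_STATES:
            raise ValueError(f"grid_size must be >= {self.MIN_STATES}")
        self.M1 = int(grid_size)
        self._eq_cache: dict[tuple[int, float], np.ndarray] = {}
        self._mat_cache: dict[tuple[int, float], np.ndarray] = {}
        self._resample_cache: dict[tuple[int, int], np.ndarray] = {}

    # -- cached pieces ------------------------------------------------------

    def _equilibrium(self, M: int, S: float) -> np.ndarray:
        key = (M, round(S, 10))
        if key not in self._eq_cache:
            self._eq_cache[key] = equilibrium_density(M, S, influx=1.0)
        return self._eq_cache[key]

    def _matrix_T(self, M: int, S: float) -> np.ndarray:
        key = (M, round(S, 10))
        if key not in self._mat_cache:
            P = transition_matrix(M, S)
            self._mat_cache[key] = np.ascontiguousarray(P[1:M, 1:M].T)
        return self._mat_cache[key]

    def _resampler(self, M1: int, M2: int) -> np.ndarray:
        key = (M1, M2)
        if key not in self._resample_cache:
            self._resample_cache[key] = sps.binom.pmf(
                np.arange(1, M2)[None, :], M2, (np.arange(1, M1) / M1)[:, None]
            )
        return self._resample_cache[key]

    # -- main entry ---------------------------------------------------------

    def states_after_change(self, size_ratio: float) -> int:
        M2 = int(round(size_ratio * self.M1))
        return max(self.MIN_STATES, min(self.MAX_STATES, M2))

    def segregating_density(self, size_ratio: float, change_time: float,
                            S: float = 0.0) -> tuple[np.ndarray, int]:
        """Expected segregating density v_j (j = 1..M2-1) at sampling time,
        for unit ancestral influx; returns (v, M2)."""
        M1 = self.M1
        v1 = self._equilibrium(M1, S)
        M2 = self.states_after_change(size_ratio)
        if M2 == M1:
            # same state space: the equilibrium is invariant under further
            # evolution with matched influx, so no stepping is needed
            return v1, M1
        v = v1 @ self._resampler(M1, M2)
        g = int(round(change_time * M2))
        if g > 0:
            QT = self._matrix_T(M2, S)
            influx = M2 / M1
            for _ in range(g):
                v = QT @ v
                v[0] += influx
        return v, M2

    def sampled_bins(self, n: int, size_ratio: float, change_time: float,
                     S: float = 0.0) -> tuple[np.ndarray, float]:
        """Binomially sample the density into SFS classes.

        Returns ``(b, b_n)`` where ``b[i-1]`` is the expected mass in class
        i = 1..n-1 and ``b_n`` the segregating mass sampled as fixed, both
        per unit ancestral influx.
        """
        v, M2 = self.segregating_density(size_ratio, change_time, S)
        pj = np.arange(1, M2) / M2
        W = sps.binom.pmf(np.arange(1, n + 1)[:, None], n, pj[None, :])
        out = W @ v
        return out[: n - 1], float(out[n - 1])

    def theta_scale(self, n: int = 12) -> float:
        """Influx units per unit theta: ratio of the neutral constant-size
        grid SFS to the diffusion expectation 2/i (averaged over classes)."""
        b, _ = self.sampled_bins(n, 1.0, 0.0, 0.0)
        i = np.arange(1, n)
        return float(np.mean(b * i / 2.0))
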