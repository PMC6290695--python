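"""Quasi-Monte Carlo sampling, the Saltelli design and variance estimators.

The simulator is treated as a stochastic black box f(xi, x): x is the vector
of epistemic inputs (uniform on a box; by default flow velocity, deployment
depth and endothelium regeneration time) and xi is the run's random seed.
A campaign evaluates f on a paired design of M(2n+2) runs built from 2M
Sobol' points, from which the estimators below recover:

* total output moments and the coefficient of variation
  CV = sd / |mean| * 100%;
* the aleatory variance Var^T_xi = (1/2M) sum_j (f(x^j, xi^j) -
  f(x^j, xi^{j+M}))^2, whose square root bounds the mean conditional
  aleatory SD from above (Jensen);
* first-order Sobol indices via Var_{x_i} = (1/M) sum_j (f_A^j - f0)
  (f_FOi^j - f0), with f0 the A-block mean;
* total sensitivity indices via Var^T_{xi,x_i} = (1/2M) sum_j (f_A^j -
  f_TOi^j)^2, which, because the seed is redrawn in every TO block, include
  all interactions with the model's stochasticity.

Error bars come from a bootstrap over design rows that keeps every block's
row j together, preserving the pairings the estimators rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "SaltelliDesign",
    "default_space",
    "sobol_sequence",
    "scale_to_bounds",
    "run_seed",
    "build_design",
    "estimate_moments",
    "aleatory_variance",
    "first_order_index",
    "total_index",
    "bootstrap_estimate",
]

BLOCK_CODES = {"A": 0, "A_RESEED": 1, "FO": 2, "TO": 3}


@dataclass
class ParameterSpace:
    """Ordered uncertain inputs, each uniform on [min, max)."""

    parameters: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        self.parameters = tuple((str(n), float(lo), float(hi))
                                for n, lo, hi in self.parameters)
        for name, lo, hi in self.parameters:
            if not lo < hi:
                raise ValueError(f"{name}: min must be < max")

    @property
    def n(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.parameters)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[p[1], p[2]] for p in self.parameters])


def default_space() -> ParameterSpace:
    """The three standard uncertain inputs with their published bounds."""
    return ParameterSpace((
        ("flow_velocity", 0.432, 0.528),      # m/s, +-10% around 0.48
        ("deployment_depth", 0.09, 0.13),     # mm
        ("regen_time", 15.0, 23.0),           # days to full endothelium
    ))


def sobol_sequence(n_dims: int, n_points: int) -> np.ndarray:
    """First ``n_points`` of the Sobol' sequence, all-zeros point skipped.

    Plain (unscrambled) Joe-Kuo direction numbers; deterministic.
    """
    if n_dims < 1 or n_points < 1:
        raise ValueError("n_dims and n_points must be >= 1")
    try:
        gen = qmc.Sobol(d=n_dims, scramble=False)
    except ValueError as exc:
        raise ValueError(f"unsupported Sobol dimension {n_dims}") from exc
    m = int(np.ceil(np.log2(n_points + 1)))
    pts = gen.random_base2(m)
    return pts[1:n_points + 1]


def scale_to_bounds(u: np.ndarray, space: ParameterSpace) -> np.ndarray:
    """Affine map of unit-cube points onto the parameter box."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != space.n:
        raise ValueError("dimension mismatch between points and space")
    b = space.bounds
    return b[:, 0] + u * (b[:, 1] - b[:, 0])


def _splitmix64(z: np.ndarray) -> np.ndarray:
    z = (z + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def run_seed(seed_root: int, block: str, i: int, j: int | np.ndarray):
    """Stable per-run seed: an independent stream for every (block, i, j).

    A splitmix64 hash of (seed_root, block, i, j), reduced below 2^31; the
    construction guarantees the xi^j vs xi^{j+M} independence the paired
    estimators require.  ``j`` may be an array.
    """
    with np.errstate(over="ignore"):
        h = _splitmix64(np.uint64(int(seed_root) & 0xFFFFFFFFFFFFFFFF))
        h = _splitmix64(h ^ np.uint64(BLOCK_CODES[block]))
        h = _splitmix64(h ^ np.uint64(int(i)))
        h = _splitmix64(h ^ np.asarray(j, dtype=np.uint64))
    out = (h & np.uint64(0x7FFFFFFF)).astype(np.int64)
    return int(out) if np.isscalar(j) or np.ndim(j) == 0 else out


@dataclass
class SaltelliDesign:
    """The M(2n+2)-run evaluation plan.

    ``runs`` is a DataFrame with columns run_id, block, i, j, one column per
    input name, and seed.  Block semantics: A and A_RESEED share input rows
    but use different seeds (aleatory pairs); FO_i takes the complementary
    Sobol block with column i copied from A (first-order pairs); TO_i takes
    the A block with column i from the complementary block and a fresh seed
    (total-effect pairs).
    """

    M: int
    n: int
    names: tuple[str, ...]
    runs: pd.DataFrame

    def block_rows(self, block: str, i: int = 0) -> pd.DataFrame:
        sub = self.runs[(self.runs["block"] == block) & (self.runs["i"] == i)]
        return sub.sort_values("j")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def build_design(space: ParameterSpace, M: int, seed_root: int) -> SaltelliDesign:
    """Build the paired design from 2M Sobol' points; M(2n+2) runs total."""
    if M < 1:
        raise ValueError("M must be >= 1")
    n = space.n
    # A and its complement come from one 2n-dimensional Sobol' stream,
    # column-split: row-splitting a plain (unscrambled) n-dimensional
    # sequence would correlate the two blocks and bias the paired estimators
    u = sobol_sequence(2 * n, M)
    xa = scale_to_bounds(u[:, :n], space)
    xb = scale_to_bounds(u[:, n:], space)
    js = np.arange(M)

    def frame(block: str, i: int, x: np.ndarray) -> pd.DataFrame:
        tag = f"{block}{i}" if block in ("FO", "TO") else block
        data = {"run_id": [f"{tag}_{j:04d}" for j in js],
                "block": block, "i": i, "j": js}
        for c, name in enumerate(space.names):
            data[name] = x[:, c]
        data["seed"] = run_seed(seed_root, block, i, js)
        return pd.DataFrame(data)

    frames = [frame("A", 0, xa), frame("A_RESEED", 0, xa)]
    for i in range(n):
        x = xb.copy()
        x[:, i] = xa[:, i]
        frames.append(frame("FO", i, x))
    for i in range(n):
        x = xa.copy()
        x[:, i] = xb[:, i]
        frames.append(frame("TO", i, x))
    runs = pd.concat(frames, ignore_index=True)
    assert len(runs) == M * (2 * n + 2)
    return SaltelliDesign(M=M, n=n, names=space.names, runs=runs)


# ---------------------------------------------------------------------------
# Estimators (Saltelli / Sobol)
# ---------------------------------------------------------------------------

def estimate_moments(samples: np.ndarray, axis: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mean, unbiased variance, sd, CV%).  CV is NaN where the mean is 0."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[axis] < 2:
        raise ValueError("need at least two samples")
    mean = samples.mean(axis=axis)
    var = samples.var(axis=axis, ddof=1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean) * 100.0, np.nan)
    return mean, var, sd, cv


def aleatory_variance(f_a: np.ndarray, f_a_reseed: np.ndarray, axis: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Aleatory (seed-driven) variance and its Jensen SD bound.

    Var^T_xi = (1/2M) sum (f_A - f_A')^2 over paired rows that share inputs
    but not seeds; sqrt of it bounds E_x[sd_xi(f | x)] from above.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_a_reseed = np.asarray(f_a_reseed, dtype=float)
    if f_a.shape != f_a_reseed.shape:
        raise ValueError("paired blocks must have equal shapes")
    var = 0.5 * np.mean((f_a - f_a_reseed) ** 2, axis=axis)
    return var, np.sqrt(var)


def first_order_index(f_a: np.ndarray, f_fo_i: np.ndarray, axis: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(partial variance, first-order index in %) for one input.

    Uses the A-block mean as f0 and the A-block unbiased variance for
    normalization.  Negative estimates are reported as-is; the index is NaN
    where the total variance is zero.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_fo_i = np.asarray(f_fo_i, dtype=float)
    if f_a.shape != f_fo_i.shape:
        raise ValueError("paired blocks must have equal shapes")
    f0 = f_a.mean(axis=axis, keepdims=True)
    var_i = np.mean((f_a - f0) * (f_fo_i - f0), axis=axis)
    var_tot = f_a.var(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_i = np.where(var_tot > 0, var_i / var_tot * 100.0, np.nan)
    return var_i, s_i


def total_index(f_a: np.ndarray, f_to_i: np.ndarray, axis: int = 0
                ) -> tuple[np.ndarray, np.ndarray]:
    """(partial variance, total index in %) for one input.

    The TO block redraws the seed together with column i, so the total index
    includes all combined effects of x_i with the model's stochasticity.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_to_i = np.asarray(f_to_i, dtype=float)
    if f_a.shape != f_to_i.shape:
        raise ValueError("paired blocks must have equal shapes")
    var_ti = 0.5 * np.mean((f_a - f_to_i) ** 2, axis=axis)
    var_tot = f_a.var(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_ti = np.where(var_tot > 0, var_ti / var_tot * 100.0, np.nan)
    return var_ti, s_ti


def bootstrap_estimate(samples_by_block: dict[str, np.ndarray],
                       estimator: Callable[[dict[str, np.ndarray]], np.ndarray],
                       K: int, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Row-paired bootstrap mean and SD of an arbitrary design statistic.

    Rows j = 1..M are resampled with replacement, keeping every block's row j
    together so the paired estimators stay valid; the statistic is recomputed
    K times and its bootstrap mean and standard deviation (ddof=1) returned.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    blocks = {k: np.asarray(v, dtype=float) for k, v in samples_by_block.items()}
    m_rows = {v.shape[0] for v in blocks.values()}
    if len(m_rows) != 1:
        raise ValueError("all blocks must share the row count M")
    m = m_rows.pop()
    reps = []
    for _ in range(K):
        idx = rng.integers(0, m, size=m)
        reps.append(np.asarray(estimator({k: v[idx] for k, v in blocks.items()}),
                               dtype=float))
    reps = np.stack(reps)
    return reps.mean(axis=0), reps.std(axis=0, ddof=1)
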