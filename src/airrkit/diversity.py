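"""Repertoire diversity: rarefaction and a saturation-plus-read-error model.

The empirical diversity of a sample of N clonotype keys is measured by
rarefaction: draw n of the N keys uniformly without replacement, count the
distinct keys, repeat (five times by default) and average.  Doing this over a
grid of n gives the curve div_calc(n).

As n grows, div_calc saturates toward the true number of unique clonotypes —
but sequencing read errors keep creating new spurious uniques at a roughly
constant per-read rate, so the observed curve is saturation plus a linear
ramp:

    div_mod(n) = a * (1 - exp(-b * n)) + k * n

where ``a`` is the true number of unique clonotypes, ``b`` the per-sequence
saturation rate and ``k`` the fraction of reads whose errors make them
spuriously unique.  The three parameters are fitted to the empirical curve by
minimizing the sum of squared residuals with an elitist (mu+lambda) evolution
strategy; the fitted ``a`` is the diversity estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .repertoire import ClonotypeDefinition, clonotype_key


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

@dataclass
class DiversityCurve:
    """Empirical rarefaction points: replicate unique-counts and their means."""

    N: int
    n_grid: List[int]
    replicates: int
    replicate_counts: List[List[int]]  # per grid point
    div_calc: List[float]              # per grid point (mean over replicates)
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n": self.n_grid, "div_calc": self.div_calc})
        for r in range(self.replicates):
            df[f"replicate_{r + 1}"] = [c[r] for c in self.replicate_counts]
        return df


def rarefy(keys: Sequence[str], n_grid: Sequence[int], replicates: int = 5,
           seed: int = 0) -> DiversityCurve:
    """Rarefaction curve of a sample of clonotype keys.

    For each n in the grid, ``replicates`` independent subsamples of size n
    are drawn without replacement and the distinct keys counted; the mean is
    div_calc(n).  Fully reproducible from the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    N = len(keys)
    codes = pd.factorize(np.asarray(keys, dtype=object))[0]
    rng = np.random.default_rng(seed)
    replicate_counts: List[List[int]] = []
    means: List[float] = []
    for n in n_grid:
        if not 0 <= n <= N:
            raise ValueError(f"subsample size n={n} outside [0, N={N}]")
        if n == 0:
            counts = [0] * replicates
        else:
            counts = []
            for _ in range(replicates):
                sample = rng.choice(N, size=n, replace=False)
                counts.append(int(np.unique(codes[sample]).size))
        replicate_counts.append(counts)
        means.append(float(np.mean(counts)))
    return DiversityCurve(N=N, n_grid=list(n_grid), replicates=replicates,
                          replicate_counts=replicate_counts, div_calc=means,
                          seed=seed)


def expected_unique(abundances: Sequence[int], n: int) -> float:
    """Closed-form expected number of distinct clonotypes in a subsample.

    For clonotype abundances N_i summing to N, a uniform size-n subsample
    without replacement misses clonotype i with hypergeometric probability
    C(N-N_i, n) / C(N, n), so

        E[c_unique] = sum_i [ 1 - C(N-N_i, n) / C(N, n) ].

    Computed in log space (gammaln) to stay finite for large N.
    """
    ab = np.asarray(abundances, dtype=np.int64)
    if (ab <= 0).any():
        raise ValueError("abundances must be positive")
    N = int(ab.sum())
    if not 0 <= n <= N:
        raise ValueError(f"n={n} outside [0, N={N}]")
    if n == 0:
        return 0.0

    def log_comb(top, bottom):
        return gammaln(top + 1) - gammaln(bottom + 1) - gammaln(top - bottom + 1)

    miss = np.zeros(len(ab))
    fits = (N - ab) >= n  # else the clonotype cannot be missed
    rem = (N - ab)[fits]
    miss[fits] = np.exp(log_comb(rem, n) - log_comb(N, n))
    return float(np.sum(1.0 - miss))


# ---------------------------------------------------------------------------
# the saturation-plus-error model
# ---------------------------------------------------------------------------

def div_model(n, a: float, b: float, k: float):
    """Modeled diversity a*(1-exp(-b*n)) + k*n; parameters must be >= 0."""
    if a < 0 or b < 0 or k < 0:
        raise ValueError("model parameters a, b, k must be non-negative")
    n = np.asarray(n, dtype=float)
    out = a * (1.0 - np.exp(-b * n)) + k * n
    return float(out) if out.ndim == 0 else out


@dataclass
class ESConfig:
    """Hyperparameters of the elitist (mu+lambda) evolution strategy."""

    mu: int = 10
    lambda_: int = 50
    generations: int = 500
    sigma_a: float = 0.1    # relative to the initial a
    sigma_log_b: float = 0.5  # natural-log units
    sigma_log_k: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < self.mu:
            raise ValueError("lambda_ must be >= mu")
        if min(self.sigma_a, self.sigma_log_b, self.sigma_log_k) <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class DiversityModelFit:
    a: float
    b: float
    k: float
    objective: float
    initial_objective: float
    es_trace: List[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": ["a", "b", "k", "objective"],
            "value": [self.a, self.b, self.k, self.objective],
        })


_LOG_FLOOR = math.log(1e-12)


def fit_diversity_model(curve: DiversityCurve,
                        config: Optional[ESConfig] = None) -> DiversityModelFit:
    """Fit (a, b, k) to an empirical curve with a (mu+lambda) evolution strategy.

    Genome: a on a linear scale (reflected at 0), b and k on a natural-log
    scale (they span orders of magnitude and must stay positive).  Each
    parameter carries its own mutation step size, self-adapted by log-normal
    perturbation with learning rate tau = 1/sqrt(2*dim).  Selection is elitist
    over parents plus offspring, so the best objective never increases across
    generations.  Reproducible from config.seed.
    """
    config = config or ESConfig()
    n = np.asarray(curve.n_grid, dtype=float)
    y = np.asarray(curve.div_calc, dtype=float)
    if len(n) < 4:
        raise ValueError("need at least 4 grid points to fit 3 parameters")
    rng = np.random.default_rng(config.seed)
    n_max = float(n.max()) if n.max() > 0 else 1.0

    def sse(a, log_b, log_k):
        """Vectorized SSE for arrays of candidate genomes."""
        a = np.atleast_1d(np.asarray(a, dtype=float))
        b = np.exp(np.atleast_1d(log_b))
        k = np.exp(np.atleast_1d(log_k))
        pred = a[:, None] * (1.0 - np.exp(-b[:, None] * n[None, :])) \
            + k[:, None] * n[None, :]
        return np.sum((pred - y[None, :]) ** 2, axis=1)

    # heuristic start: a0 = observed plateau, b0 in the saturating basin,
    # k0 = terminal slope (the error ramp dominates the curve's tail)
    a0 = max(float(y[-1]), 0.0)
    b0 = 3.0 / n_max
    if len(n) >= 2 and n[-1] > n[-2]:
        k0 = max(0.0, float((y[-1] - y[-2]) / (n[-1] - n[-2])))
    else:
        k0 = 0.0
    genome0 = np.array([a0, math.log(b0), max(math.log(k0), _LOG_FLOOR)
                        if k0 > 0 else _LOG_FLOOR])
    sigma0 = np.array([config.sigma_a * max(a0, 1.0),
                       config.sigma_log_b, config.sigma_log_k])

    mu, lam = config.mu, config.lambda_
    tau = 1.0 / math.sqrt(2.0 * 3)

    # parents: the heuristic start plus mu-1 mutated copies (elitism keeps the
    # start, so the final objective can never exceed the initial one)
    par_x = np.tile(genome0, (mu, 1))
    par_s = np.tile(sigma0, (mu, 1))
    jitter = rng.normal(size=(mu - 1, 3))
    par_x[1:] += par_s[1:] * jitter
    par_x[1:, 0] = np.abs(par_x[1:, 0])
    par_x[1:, 1:] = np.maximum(par_x[1:, 1:], _LOG_FLOOR)
    par_f = sse(par_x[:, 0], par_x[:, 1], par_x[:, 2])

    initial_objective = float(sse(genome0[0], genome0[1], genome0[2])[0])
    trace: List[float] = []
    for _ in range(config.generations):
        idx = rng.integers(0, mu, size=lam)
        child_s = par_s[idx] * np.exp(tau * rng.normal(size=(lam, 3)))
        child_x = par_x[idx] + child_s * rng.normal(size=(lam, 3))
        child_x[:, 0] = np.abs(child_x[:, 0])          # reflect a at 0
        child_x[:, 1:] = np.maximum(child_x[:, 1:], _LOG_FLOOR)
        child_f = sse(child_x[:, 0], child_x[:, 1], child_x[:, 2])

        pool_x = np.vstack([par_x, child_x])
        pool_s = np.vstack([par_s, child_s])
        pool_f = np.concatenate([par_f, child_f])
        order = np.argsort(pool_f, kind="stable")[:mu]
        par_x, par_s, par_f = pool_x[order], pool_s[order], pool_f[order]
        trace.append(float(par_f[0]))

    best = par_x[0]
    return DiversityModelFit(
        a=float(best[0]), b=float(math.exp(best[1])), k=float(math.exp(best[2])),
        objective=float(par_f[0]), initial_objective=initial_objective,
        es_trace=trace,
    )


def estimate_repertoire_diversity(
    records: Sequence, definition: Optional[ClonotypeDefinition] = None,
    n_step: int = 1000, replicates: int = 5,
    config: Optional[ESConfig] = None,
) -> Tuple[DiversityCurve, DiversityModelFit]:
    """End-to-end diversity estimate for a sample of annotated reads.

    Builds clonotype keys under ``definition``, rarefies on the grid
    {0, n_step, 2*n_step, ..., N} (N always included as the final point),
    and fits the saturation model; the fitted ``a`` is the estimated true
    number of unique clonotypes in the sample.
    """
    definition = definition or ClonotypeDefinition()
    config = config or ESConfig()
    keys = [k for k in (clonotype_key(r, definition) for r in records)
            if k is not None]
    if not keys:
        raise ValueError("no records yield a clonotype key under this definition")
    N = len(keys)
    grid = list(range(0, N + 1, n_step))
    if grid[-1] != N:
        grid.append(N)
    curve = rarefy(keys, grid, replicates=replicates, seed=config.seed)
    fit = fit_diversity_model(curve, config)
    return curve, fit


def plot_diversity(curve: DiversityCurve, fit: Optional[DiversityModelFit] = None,
                   path: Optional[str] = None):  # pragma: no cover - thin plotting
    """Static export: empirical points, fitted model, and the error-free
    component a*(1-exp(-b*n)) whose plateau is the diversity estimate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve.n_grid, curve.div_calc, "o", color="firebrick",
            label="empirical div_calc(n)")
    if fit is not None:
        grid = np.linspace(0, max(curve.n_grid), 300)
        ax.plot(grid, div_model(grid, fit.a, fit.b, fit.k), color="seagreen",
                label="fitted model")
        ax.plot(grid, div_model(grid, fit.a, fit.b, 0.0), "--", color="steelblue",
                label=f"error-free component (a = {fit.a:,.0f})")
    ax.set_xlabel("subsample size n")
    ax.set_ylabel("unique clonotypes")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
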