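"""Resampling, correlation, and closed-form statistics shared by all analysis stages.

Conventions
-----------
* Correlations are sample Pearson correlations and are Fisher-Z transformed
  (``z = atanh(r)``) before being averaged or differenced across conditions.
* Group inference is nonparametric: participants are resampled with
  replacement, the mean difference is recomputed in each pseudosample, and the
  two-tailed p-value is twice the fraction of pseudosample means whose sign
  opposes the observed mean.
* The binomial test uses exact rational arithmetic with the doubling rule
  (two-tailed p = ``min(1, 2 * min(P(X <= s), P(X >= s)))``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from sklearn.manifold import MDS as _SklearnMDS

__all__ = [
    "ContractError",
    "DegenerateInputError",
    "BootstrapResult",
    "BinomialTestResult",
    "MDSEmbedding",
    "pearson_corr",
    "partial_corr",
    "fisher_z",
    "inverse_fisher_z",
    "bootstrap_mean_difference",
    "binomial_two_tailed",
    "mds_embed",
]

#: correlations are clipped to +/-(1 - FISHER_EPS) before the Fisher transform
FISHER_EPS = 1e-7


class ContractError(ValueError):
    """An argument violates the operation's contract (shape, range, rank)."""


class DegenerateInputError(ValueError):
    """The input is formally valid but statistically degenerate (zero variance)."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.reshape(-1) if arr.size == max(arr.shape, default=0) else arr
    if arr.ndim != 1:
        raise ContractError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length sequences.

    Raises
    ------
    ContractError
        If lengths differ or fewer than 3 samples are given.
    DegenerateInputError
        If either input has zero variance.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.shape != ya.shape:
        raise ContractError(f"length mismatch: {xa.shape[0]} vs {ya.shape[0]}")
    if xa.shape[0] < 3:
        raise ContractError("need at least 3 samples for a correlation")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero-variance input to correlation")
    r = float(xc @ yc) / (sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def partial_corr(
    x: Sequence[float], y: Sequence[float], confounds
) -> float:
    """Correlation of x and y after regressing out confounds (plus intercept).

    ``confounds`` is one confound sequence or a sequence of them (each the
    same length as ``x``). Both variables are residualized against the
    confound design by least squares; the residuals are Pearson correlated.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.shape != ya.shape:
        raise ContractError(f"length mismatch: {xa.shape[0]} vs {ya.shape[0]}")
    n = xa.shape[0]
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    elif conf.ndim == 2 and conf.shape[0] != n and conf.shape[1] == n:
        conf = conf.T
    if conf.shape[0] != n:
        raise ContractError("confound length does not match data length")
    design = np.column_stack([np.ones(n), conf])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ContractError("confound design (with intercept) is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, xa, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ya, rcond=None)
    rx = xa - design @ beta_x
    ry = ya - design @ beta_y
    if float(rx @ rx) <= 1e-24 * n or float(ry @ ry) <= 1e-24 * n:
        raise DegenerateInputError("zero-variance residual after confound removal")
    return pearson_corr(rx, ry)


def fisher_z(r: float) -> float:
    """Fisher Z (variance stabilizing) transform, ``z = atanh(r)``.

    ``r`` is clipped to +/-(1 - 1e-7) first so that correlations of exactly
    1 in magnitude map to a large finite value rather than infinity.
    """
    r = float(r)
    if abs(r) > 1.0:
        raise ContractError(f"correlation out of range: {r}")
    r = float(np.clip(r, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    """Inverse Fisher transform, ``r = tanh(z)``."""
    return float(np.tanh(float(z)))


@dataclass(frozen=True)
class BootstrapResult:
    """Participant-resampling bootstrap of a mean difference.

    ``p_two_tailed`` is twice the fraction of pseudosample means with sign
    opposite to the observed mean, capped at 1. When no pseudosample flips
    sign the numeric p is 0.0 and ``p_label`` reports the resolution floor
    ``"< 2/n_boot"``. An observed mean of exactly zero is flagged degenerate
    and reported as p = 1.
    """

    mean_diff: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    n_boot: int
    seed: int
    degenerate: bool = False
    p_label: str = field(default="")

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_two_tailed": self.p_two_tailed,
            "p_label": self.p_label,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def bootstrap_mean_difference(
    per_participant_diffs: Sequence[float], n_boot: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap test of a per-participant mean difference against zero.

    Participants are resampled with replacement ``n_boot`` times; the p-value
    is the doubled fraction of pseudosample means whose sign opposes the
    observed mean, and the interval is the 2.5/97.5 percentile interval of
    the pseudosample mean distribution (no bias correction).
    """
    diffs = _as_1d(per_participant_diffs, "per_participant_diffs")
    if diffs.size == 0:
        raise ContractError("need at least one participant")
    if n_boot < 1:
        raise ContractError("n_boot must be >= 1")
    observed = float(diffs.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(int(n_boot), diffs.size))
    boot_means = diffs[idx].mean(axis=1)
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5])
    if observed == 0.0:
        return BootstrapResult(
            mean_diff=0.0, ci_low=float(ci_low), ci_high=float(ci_high),
            p_two_tailed=1.0, n_boot=int(n_boot), seed=int(seed),
            degenerate=True, p_label="1 (degenerate: observed mean is 0)",
        )
    flips = int(np.count_nonzero(boot_means * observed < 0))
    p = min(1.0, 2.0 * flips / n_boot)
    label = f"< {2.0 / n_boot:g}" if flips == 0 else f"{p:g}"
    return BootstrapResult(
        mean_diff=observed, ci_low=float(ci_low), ci_high=float(ci_high),
        p_two_tailed=p, n_boot=int(n_boot), seed=int(seed), p_label=label,
    )


@dataclass(frozen=True)
class BinomialTestResult:
    """Exact two-tailed binomial test using the doubling rule."""

    successes: int
    trials: int
    p0: float
    p_two_tailed: float

    def to_dict(self) -> dict:
        return {
            "successes": self.successes,
            "trials": self.trials,
            "p0": self.p0,
            "p_two_tailed": self.p_two_tailed,
        }


def binomial_two_tailed(successes: int, trials: int, p0: float = 0.5) -> BinomialTestResult:
    """Exact two-tailed binomial test, ``p = min(1, 2*min(P(X<=s), P(X>=s)))``.

    Tail masses are computed with exact rational arithmetic (no normal
    approximation), then converted to float.
    """
    s, n = int(successes), int(trials)
    if not (0 <= s <= n):
        raise ContractError(f"invalid counts: successes={s}, trials={n}")
    if not (0.0 < p0 < 1.0):
        raise ContractError(f"null probability must be in (0, 1), got {p0}")
    q = Fraction(p0).limit_denominator(10**9)
    pmf = [
        Fraction(math.comb(n, k)) * q**k * (1 - q) ** (n - k) for k in range(n + 1)
    ]
    lower = sum(pmf[: s + 1])
    upper = sum(pmf[s:])
    p = min(Fraction(1), 2 * min(lower, upper))
    return BinomialTestResult(successes=s, trials=n, p0=float(p0), p_two_tailed=float(p))


@dataclass(frozen=True)
class MDSEmbedding:
    """Metric MDS configuration with Kruskal stress-1 goodness of fit."""

    coordinates: np.ndarray  # (n_points, n_dims)
    stress: float  # Kruskal stress-1; 0 = perfect, < 0.2 conventionally acceptable
    dissimilarity_in: np.ndarray


def kruskal_stress(dissimilarity: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (delta - d)^2 / sum delta^2) over i < j."""
    delta = np.asarray(dissimilarity, dtype=float)
    d = np.sqrt(
        ((coordinates[:, None, :] - coordinates[None, :, :]) ** 2).sum(-1)
    )
    iu = np.triu_indices_from(delta, k=1)
    denom = float((delta[iu] ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((delta[iu] - d[iu]) ** 2).sum() / denom))


def mds_embed(dissimilarity, n_dims: int = 2, seed: int = 0) -> MDSEmbedding:
    """Metric MDS (SMACOF) embedding of a symmetric dissimilarity matrix.

    Best of 8 seeded restarts, 300 iterations, convergence 1e-9; the returned
    stress is Kruskal stress-1 normalized by the input dissimilarities.
    """
    delta = np.asarray(dissimilarity, dtype=float)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise ContractError("dissimilarity must be a square matrix")
    if not np.allclose(delta, delta.T, atol=1e-10):
        raise ContractError("dissimilarity must be symmetric")
    if np.any(delta < 0):
        raise ContractError("dissimilarity must be nonnegative")
    if not np.allclose(np.diag(delta), 0.0, atol=1e-12):
        raise ContractError("dissimilarity must have a zero diagonal")
    n = delta.shape[0]
    n_dims = int(n_dims)
    if n_dims < 1:
        raise ContractError("n_dims must be >= 1")
    if n == 1:
        coords = np.zeros((1, n_dims))
        return MDSEmbedding(coords, 0.0, delta)
    def _fit(init):
        import warnings as _warnings

        mds = _SklearnMDS(
            n_components=n_dims,
            metric=True,
            n_init=1 if init is not None else 8,
            max_iter=300,
            eps=1e-9,
            dissimilarity="precomputed",
            random_state=int(seed),
            normalized_stress=False,
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            return mds.fit_transform(delta, init=init)

    # classical (Torgerson) scaling as one candidate start: exact whenever a
    # Euclidean configuration in n_dims exists
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    classical = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    candidates = [_fit(None), _fit(classical)]
    coords = min(candidates, key=lambda c: kruskal_stress(delta, c))
    return MDSEmbedding(coords, kruskal_stress(delta, coords), delta)
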