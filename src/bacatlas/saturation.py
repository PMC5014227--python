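"""Library-saturation estimation from probe-pool screening data.

The detection matrix (pools x clones, 0/1) is resampled: pool order is
permuted many times and the cumulative number of unique positive clones is
averaged per number of pools applied, giving an accumulation (rarefaction)
curve. A saturating model fitted to the curve extrapolates the asymptotic
number of discoverable clones. Because clones carrying more genes are more
detectable, the asymptote is a lower bound on the true gene-bearing clone
count — the estimate always carries the model name used.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DataError, FitError


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.empty or matrix.shape[0] < 1:
        raise DataError("detection matrix is empty")
    if matrix.index.duplicated().any():
        raise DataError("detection matrix has duplicate pool ids")
    if matrix.columns.duplicated().any():
        raise DataError("detection matrix has duplicate clone ids")
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise DataError("detection matrix entries must be 0/1")


@dataclass
class AccumulationCurve:
    x: np.ndarray            # number of pools applied, 1..P
    mean_unique: np.ndarray
    sd_unique: np.ndarray
    n_permutations: int
    seed: int | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_pools": self.x,
                "mean_unique": np.round(self.mean_unique, 4),
                "sd_unique": np.round(self.sd_unique, 4),
            }
        )


@dataclass
class SaturationEstimate:
    asymptote: float
    model_name: str
    params: dict
    residual_rms: float


def _first_detection_counts(mat: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Cumulative unique-clone counts for a batch of pool orderings.

    mat: (P, C) bool; perms: (B, P) row orders. Returns (B, P) counts.
    """
    permuted = mat[perms]                       # (B, P, C)
    detected = permuted.any(axis=1)             # (B, C)
    first = permuted.argmax(axis=1)             # (B, C); 0 for undetected
    B, P, _ = permuted.shape
    counts = np.zeros((B, P), dtype=np.int64)
    for b in range(B):
        f = first[b][detected[b]]
        counts[b] = np.cumsum(np.bincount(f, minlength=P))
    return counts


def accumulation_curve(
    matrix: pd.DataFrame, n_permutations: int = 10_000, seed: int | None = None
) -> AccumulationCurve:
    """Monte-Carlo accumulation curve over random pool orderings.

    Deterministic given ``seed``. For every permutation the count at the
    last x equals the matrix's total number of positive clones, so the sd
    there is exactly 0.
    """
    validate_matrix(matrix)
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    mat = matrix.to_numpy().astype(bool)
    P = mat.shape[0]
    rng = np.random.default_rng(seed)

    sums = np.zeros(P)
    sq_sums = np.zeros(P)
    batch = 200
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        perms = np.array([rng.permutation(P) for _ in range(b)])
        counts = _first_detection_counts(mat, perms).astype(float)
        sums += counts.sum(axis=0)
        sq_sums += (counts**2).sum(axis=0)
        done += b
    mean = sums / n_permutations
    var = np.maximum(sq_sums / n_permutations - mean**2, 0.0)
    return AccumulationCurve(
        x=np.arange(1, P + 1),
        mean_unique=mean,
        sd_unique=np.sqrt(var),
        n_permutations=n_permutations,
        seed=seed,
    )


def exhaustive_mean_curve(matrix: pd.DataFrame) -> np.ndarray:
    """Exact mean accumulation curve over all P! pool orderings (P <= 8).

    Brute-force enumeration; the oracle the Monte-Carlo curve is checked
    against in tests.
    """
    validate_matrix(matrix)
    mat = matrix.to_numpy().astype(bool)
    P = mat.shape[0]
    if P > 8:
        raise ConfigurationError("exhaustive enumeration limited to 8 pools")
    total = np.zeros(P)
    n = 0
    for order in permutations(range(P)):
        seen = np.zeros(mat.shape[1], dtype=bool)
        for i, p in enumerate(order):
            seen |= mat[p]
            total[i] += seen.sum()
        n += 1
    return total / n


def _negexp(x, A, b):
    return A * (1.0 - np.exp(-b * x))


def _hyperbolic(x, A, B):
    return A * x / (B + x)


_MODELS = {"negexp": _negexp, "hyperbolic": _hyperbolic}


def fit_asymptote(curve: AccumulationCurve, model: str = "negexp") -> SaturationEstimate:
    """Least-squares fit of the accumulation curve to a saturating model.

    negexp: y = A(1 - exp(-b x)); hyperbolic: y = A x / (B + x). A is the
    asymptote and is constrained to be at least the observed unique-clone
    count (an accumulation curve cannot overshoot its own data's total).
    """
    if model not in _MODELS:
        raise ConfigurationError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.mean_unique, dtype=float)
    if x.size < 3:
        raise DataError("curve must have at least 3 points to fit")
    observed = float(y[-1])
    fn = _MODELS[model]
    if model == "negexp":
        p0 = (max(observed, 1.0) * 1.05, 0.5)
        bounds = ([max(observed, 1e-9), 1e-9], [np.inf, np.inf])
        names = ("A", "b")
    else:
        p0 = (max(observed, 1.0) * 1.2, 1.0)
        bounds = ([max(observed, 1e-9), 1e-9], [np.inf, np.inf])
        names = ("A", "B")
    try:
        popt, _ = curve_fit(fn, x, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"asymptote fit ({model}) did not converge: {exc}") from exc
    resid = y - fn(x, *popt)
    return SaturationEstimate(
        asymptote=float(popt[0]),
        model_name=model,
        params={n: float(v) for n, v in zip(names, popt)},
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
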