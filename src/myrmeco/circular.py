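"""Circular uniformity tests for seed bearings around the nest.

Whether seeds are rejected isotropically is assessed on the angles of the
seed positions (radians) with four classical tests: Rayleigh (sensitive to a
unimodal departure), Kuiper and Watson (rotation-invariant EDF tests) and
Rao's spacing test (sensitive to multimodality).

P-value conventions follow what is standard for each test: Rayleigh has a
well-known asymptotic series; Kuiper and Watson use Stephens' modified
statistics whose critical points are distribution-free constants; for Rao's
spacing no closed form exists, so the null distribution is tabulated here by
Monte Carlo (cached per sample size, fixed internal seed) and an exact
rank-based p-value is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: Stephens (1970) upper-tail critical points of the modified statistics.
KUIPER_CRITICAL = {0.10: 1.620, 0.05: 1.747, 0.01: 2.001}
WATSON_CRITICAL = {0.10: 0.152, 0.05: 0.187, 0.01: 0.267}

_RAO_MC_SEED = 180703  # fixed: the cached null distribution is reproducible
_RAO_MC_N = 1999


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float | None
    reject_05: bool
    detail: str = ""


@dataclass
class CircularTestReport:
    rayleigh: TestResult
    kuiper: TestResult
    watson: TestResult
    rao: TestResult

    def as_dict(self) -> dict[str, TestResult]:
        return {
            "rayleigh": self.rayleigh,
            "kuiper": self.kuiper,
            "watson": self.watson,
            "rao": self.rao,
        }


def mean_resultant_length(angles: np.ndarray) -> float:
    """R̄ = |mean of unit vectors|, in [0, 1]."""
    a = np.asarray(angles, dtype=np.float64)
    return float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))


def rayleigh_test(angles: np.ndarray) -> TestResult:
    """Rayleigh test with the standard asymptotic p-value series.

    p ≈ exp(-Z) (1 + (2Z - Z²) / (4n)) with Z = n R̄².
    """
    a = np.asarray(angles, dtype=np.float64)
    n = len(a)
    rbar = mean_resultant_length(a)
    z = n * rbar**2
    p = float(np.exp(-z) * (1 + (2 * z - z**2) / (4 * n)))
    p = min(max(p, 0.0), 1.0)
    return TestResult("rayleigh", rbar, p, reject_05=bool(p <= 0.05))


def kuiper_test(angles: np.ndarray) -> TestResult:
    """Kuiper V_n against the uniform circular distribution.

    The modified statistic V* = V (√n + 0.155 + 0.24/√n) is compared with
    Stephens' critical points; the p-value is reported as a band.
    """
    a = np.mod(np.asarray(angles, dtype=np.float64), 2 * np.pi)
    n = len(a)
    u = np.sort(a) / (2 * np.pi)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    v = d_plus + d_minus
    v_star = v * (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n))
    reject = v_star > KUIPER_CRITICAL[0.05]
    band = _critical_band(v_star, KUIPER_CRITICAL)
    return TestResult("kuiper", float(v_star), None, bool(reject), detail=band)


def watson_test(angles: np.ndarray) -> TestResult:
    """Watson U²_n (rotation-invariant Cramér–von Mises) test.

    U² = Σ (u_(i) - (2i-1)/(2n))² + 1/(12n) - n (ū - ½)², modified per
    Stephens as U²* = (U² - 0.1/n + 0.1/n²)(1 + 0.8/n).
    """
    a = np.mod(np.asarray(angles, dtype=np.float64), 2 * np.pi)
    n = len(a)
    u = np.sort(a) / (2 * np.pi)
    i = np.arange(1, n + 1)
    w2 = np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1 / (12 * n)
    u2 = w2 - n * (u.mean() - 0.5) ** 2
    u2_star = (u2 - 0.1 / n + 0.1 / n**2) * (1 + 0.8 / n)
    reject = u2_star > WATSON_CRITICAL[0.05]
    band = _critical_band(u2_star, WATSON_CRITICAL)
    return TestResult("watson", float(u2_star), None, bool(reject), detail=band)


def rao_spacing_statistic(angles: np.ndarray) -> float:
    """Rao's spacing U = ½ Σ |T_i − 2π/n| (radians), T_i the arc gaps."""
    a = np.sort(np.mod(np.asarray(angles, dtype=np.float64), 2 * np.pi))
    n = len(a)
    gaps = np.diff(a, append=a[0] + 2 * np.pi)
    return float(0.5 * np.sum(np.abs(gaps - 2 * np.pi / n)))


@lru_cache(maxsize=8)
def _rao_null(n: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of Rao's U for sample size n."""
    rng = np.random.default_rng(_RAO_MC_SEED + n)
    # spacings of n uniform points = normalised exponential gaps
    e = rng.exponential(size=(_RAO_MC_N, n))
    gaps = 2 * np.pi * e / e.sum(axis=1, keepdims=True)
    u = 0.5 * np.sum(np.abs(gaps - 2 * np.pi / n), axis=1)
    return np.sort(u)


def rao_spacing_test(angles: np.ndarray) -> TestResult:
    """Rao's spacing test with a Monte-Carlo rank p-value.

    Large U (uneven gaps) rejects uniformity; p = (1 + #{null ≥ U}) /
    (n_mc + 1) from a cached 1999-sample null distribution.
    """
    a = np.asarray(angles, dtype=np.float64)
    u = rao_spacing_statistic(a)
    null = _rao_null(len(a))
    p = (1 + int(np.sum(null >= u))) / (len(null) + 1)
    return TestResult("rao", u, p, reject_05=bool(p <= 0.05))


def _critical_band(stat: float, table: dict[float, float]) -> str:
    alphas = sorted(table)  # ascending alpha = descending critical value
    for alpha in alphas:
        if stat > table[alpha]:
            return f"p <= {alpha}"
    return f"p > {max(alphas)}"


def circular_tests(angles: np.ndarray) -> CircularTestReport:
    """Run all four uniformity tests on a sample of angles (radians)."""
    a = np.asarray(angles, dtype=np.float64)
    if len(a) < 5:
        raise ValueError("need >= 5 angles")
    return CircularTestReport(
        rayleigh=rayleigh_test(a),
        kuiper=kuiper_test(a),
        watson=watson_test(a),
        rao=rao_spacing_test(a),
    )


def bearings(points: np.ndarray) -> np.ndarray:
    """Angles (radians) of (x, y) points as seen from the origin."""
    pts = np.atleast_2d(points)
    return np.arctan2(pts[:, 1], pts[:, 0])
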