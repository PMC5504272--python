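"""Pairwise maximum-entropy (Ising) model fitting for binary network activity.

The model assigns each activity pattern ``v`` (a length-K vector of +/-1
network activities) an energy

    E(v) = - sum_i h_i sigma_i(v) - 1/2 sum_{i != j} J_ij sigma_i(v) sigma_j(v)

and an appearance probability ``P(v) = exp(-E(v)) / Z``.  ``h_i`` is the
basal activity of network ``i`` and ``J_ij`` the pairwise interaction
between networks ``i`` and ``j``.  Fitting matches the model's first and
second moments to the empirical ones by gradient ascent on the
log-likelihood, which is concave, so the fit is deterministic from a fixed
initialization.

All exhaustive operations enumerate the 2**K patterns and therefore apply
only for modest K (the analysis uses K=7 networks; a hard cap refuses
K > ENUMERATION_CAP).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ENUMERATION_CAP",
    "MEMParams",
    "FitReport",
    "pattern_code",
    "pattern_decode",
    "all_patterns",
    "empirical_moments",
    "state_energy",
    "all_state_energies",
    "boltzmann_distribution",
    "independent_model_distribution",
    "empirical_distribution",
    "fit_mem",
    "fit_accuracy",
]

#: exhaustive enumeration is O(2**K); refuse anything beyond this
ENUMERATION_CAP = 20


@dataclass
class MEMParams:
    """Basal activities ``h`` and symmetric pairwise interactions ``J``.

    ``J`` must be symmetric with an exactly-zero diagonal (self-interaction
    is meaningless in the +/-1 convention: sigma_i**2 == 1 only shifts the
    energy by a constant).
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.ndim != 1:
            raise ValueError("h must be a 1-D vector")
        k = self.h.shape[0]
        if self.J.shape != (k, k):
            raise ValueError(f"J must be {k}x{k}, got {self.J.shape}")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0.0):
            raise ValueError("J must have an exactly zero diagonal")

    @property
    def k(self) -> int:
        return self.h.shape[0]

    def to_json(self, **metadata) -> str:
        return json.dumps(
            {
                "h": self.h.tolist(),
                "J": self.J.tolist(),
                "convention": "E=-h.s-0.5*s'Js; P~exp(-E)",
                **metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MEMParams":
        d = json.loads(text)
        return cls(h=np.array(d["h"]), J=np.array(d["J"]))


@dataclass
class FitReport:
    """Goodness-of-fit summary of a pairwise MEM.

    ``r`` is the Pearson correlation between model and empirical pattern
    probabilities; ``accuracy`` is (D1-D2)/D1 where D2 is the KL divergence
    of the empirical distribution from the fitted pairwise model and D1 the
    divergence from the independent (first-order) model.
    """

    r: float = np.nan
    accuracy: float = np.nan
    accuracy_defined: bool = True
    n_iter: int = 0
    converged: bool = False
    max_discrepancy: float = np.nan
    d1: float = np.nan
    d2: float = np.nan


def _check_cap(k: int) -> None:
    if k > ENUMERATION_CAP:
        raise ValueError(
            f"K={k} exceeds the exhaustive-enumeration cap ({ENUMERATION_CAP}); "
            "this analysis enumerates all 2**K patterns and is not intended "
            "for large K"
        )


def pattern_code(v: np.ndarray) -> int:
    """Canonical integer code of a +/-1 activity pattern.

    Bit ``i`` of the code is 1 iff network ``i`` is active (+1), so the
    all-inactive pattern is 0 and the all-active pattern is ``2**K - 1``.
    """
    v = np.asarray(v)
    if v.ndim != 1:
        raise ValueError("pattern must be a 1-D vector")
    if not np.all(np.isin(v, (-1, 1))):
        raise ValueError("pattern entries must be -1 or +1")
    bits = (v > 0).astype(np.int64)
    return int(bits @ (1 << np.arange(v.shape[0], dtype=np.int64)))


def pattern_decode(code: int, k: int) -> np.ndarray:
    """Inverse of :func:`pattern_code`: code -> +/-1 vector of length k."""
    if not 0 <= code < 2**k:
        raise ValueError(f"code {code} out of range for K={k}")
    bits = (code >> np.arange(k)) & 1
    return (2 * bits - 1).astype(np.int8)


def all_patterns(k: int) -> np.ndarray:
    """(2**K, K) matrix of all +/-1 patterns, row ``c`` = decode(c)."""
    _check_cap(k)
    codes = np.arange(2**k)
    bits = (codes[:, None] >> np.arange(k)[None, :]) & 1
    return (2 * bits - 1).astype(np.int8)


def codes_of_rows(values: np.ndarray) -> np.ndarray:
    """Vectorized pattern codes for a T x K matrix of +/-1 activities."""
    values = np.asarray(values)
    bits = (values > 0).astype(np.int64)
    return bits @ (1 << np.arange(values.shape[1], dtype=np.int64))


def empirical_moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Temporal means <sigma_i> and <sigma_i sigma_j> of a T x K +/-1 series.

    The second-moment matrix is symmetric with a unit diagonal.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("need a T x K matrix with T >= 1")
    if not np.all(np.isin(values, (-1.0, 1.0))):
        raise ValueError("entries must be -1 or +1")
    m1 = values.mean(axis=0)
    m2 = values.T @ values / values.shape[0]
    return m1, m2


def state_energy(v: np.ndarray, params: MEMParams) -> float:
    """Energy of a single +/-1 pattern under the pairwise MEM."""
    v = np.asarray(v, dtype=float)
    if v.shape != params.h.shape:
        raise ValueError("pattern length does not match params")
    return float(-params.h @ v - 0.5 * v @ params.J @ v)


def all_state_energies(params: MEMParams) -> np.ndarray:
    """Energies of all 2**K patterns, indexed by pattern code."""
    _check_cap(params.k)
    s = all_patterns(params.k).astype(float)
    return -s @ params.h - 0.5 * np.einsum("ci,ij,cj->c", s, params.J, s)


def boltzmann_distribution(params: MEMParams) -> np.ndarray:
    """Exact Boltzmann probabilities p(v) = exp(-E(v))/Z over all patterns.

    Energies are shifted by their minimum before exponentiation; the result
    is invariant to any constant energy offset.
    """
    e = all_state_energies(params)
    w = np.exp(-(e - e.min()))
    return w / w.sum()


def empirical_distribution(values: np.ndarray) -> np.ndarray:
    """Empirical pattern-appearance probabilities of a T x K +/-1 series."""
    values = np.asarray(values)
    k = values.shape[1]
    _check_cap(k)
    counts = np.bincount(codes_of_rows(values), minlength=2**k)
    return counts / counts.sum()


def independent_model_distribution(m1: np.ndarray) -> np.ndarray:
    """First-order (independent-network) MEM matching means ``m1``.

    With no couplings the maximum-entropy distribution factorizes:
    P(v) = prod_i (1 + sigma_i(v) * m1_i) / 2.
    """
    m1 = np.asarray(m1, dtype=float)
    s = all_patterns(m1.shape[0]).astype(float)
    p = np.prod((1.0 + s * m1) / 2.0, axis=1)
    # guard against tiny negative values from roundoff at |m1| ~ 1
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def fit_mem(
    values: np.ndarray,
    learning_rate: float = 0.2,
    tol: float = 1e-5,
    max_iter: int = 1_000_000,
) -> tuple[MEMParams, FitReport]:
    """Fit the pairwise MEM to a T x K +/-1 series by moment matching.

    Gradient ascent on the (concave) log-likelihood from zero
    initialization:

        h  += eta * (<sigma_i>  - <sigma_i>_model)
        J  += eta * (<sigma_i sigma_j> - <sigma_i sigma_j>_model)

    with ``J`` kept symmetric and zero-diagonal, ``eta`` =
    ``learning_rate / K``.  Stops when the maximum absolute moment
    discrepancy drops below ``tol``; if ``max_iter`` is exhausted first the
    report carries ``converged=False`` and the final discrepancy.

    For group-level analysis pass the per-participant series concatenated
    along time; an individual-level fit is the same call on one
    participant's series.
    """
    values = np.asarray(values)
    k = values.shape[1]
    _check_cap(k)
    if values.shape[0] < 2**k:
        warnings.warn(
            f"T={values.shape[0]} < 2**K={2**k}: empirical pattern "
            "probabilities are sparse and the fit may be unreliable",
            stacklevel=2,
        )
    emp1, emp2 = empirical_moments(values)
    if np.any(np.abs(emp1) == 1.0):
        raise ValueError(
            "some network is constant (+1 or -1 throughout); both binary "
            "values must be present for every network"
        )

    s = all_patterns(k).astype(float)
    eta = learning_rate / k
    h = np.zeros(k)
    J = np.zeros((k, k))
    off = ~np.eye(k, dtype=bool)
    disc = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        e = -s @ h - 0.5 * np.einsum("ci,ij,cj->c", s, J, s)
        w = np.exp(-(e - e.min()))
        p = w / w.sum()
        m1 = s.T @ p
        m2 = (s * p[:, None]).T @ s
        g1 = emp1 - m1
        g2 = emp2 - m2
        disc = max(np.abs(g1).max(), np.abs(g2[off]).max())
        if disc < tol:
            converged = True
            break
        h = h + eta * g1
        J = J + eta * g2
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)

    params = MEMParams(h=h, J=J)
    report = fit_accuracy(params, values)
    report.n_iter = n_iter
    report.converged = converged
    report.max_discrepancy = float(disc)
    return params, report


def fit_accuracy(params: MEMParams, values: np.ndarray) -> FitReport:
    """Goodness of fit of ``params`` against the series it was fitted to.

    ``r``: Pearson correlation over the 2**K (empirical, model)
    probability pairs.  ``accuracy``: (D1-D2)/D1 with D2 = KL(empirical ||
    pairwise model) and D1 = KL(empirical || independent model fitted to
    the means); empirical-zero cells contribute nothing to either KL term.
    When D1 == 0 (the data are already independent) the ratio is undefined
    and the report is flagged.
    """
    p_emp = empirical_distribution(values)
    p_model = boltzmann_distribution(params)
    m1, _ = empirical_moments(values)
    p_ind = independent_model_distribution(m1)

    if np.std(p_emp) == 0.0 or np.std(p_model) == 0.0:
        r = float("nan")  # degenerate: a constant probability vector
    else:
        r = float(np.corrcoef(p_emp, p_model)[0, 1])
    nz = p_emp > 0
    d2 = float(np.sum(p_emp[nz] * np.log(p_emp[nz] / p_model[nz])))
    d1 = float(np.sum(p_emp[nz] * np.log(p_emp[nz] / p_ind[nz])))
    report = FitReport(r=r, d1=d1, d2=d2)
    if d1 <= 0.0:
        report.accuracy_defined = False
        report.accuracy = np.nan
    else:
        report.accuracy = (d1 - d2) / d1
    return report
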