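"""Pairwise maximum-entropy (Ising) model inference for binary patterns.

The pairwise maximum-entropy model (MEM) assigns every activity pattern
``V = (sigma_1, ..., sigma_N)``, ``sigma_i ∈ {+1, −1}``, the energy

    E(V) = − Σ_i h_i σ_i − (1/2) Σ_i Σ_j J_ij σ_i σ_j

and the Boltzmann probability ``P(V) = exp(−E(V)) / Σ_k exp(−E(V_k))``.
``h_i`` is the basal activity (bias) of node ``i`` and ``J_ij`` the
symmetric pairwise coupling between nodes ``i`` and ``j``.  The model is
the least-structured distribution matching the empirical first moments
``⟨σ_i⟩`` and second moments ``⟨σ_i σ_j⟩``; parameters are found by
gradient ascent on the log-likelihood, whose gradient is exactly the
moment mismatch.  Fit quality is quantified as ``(D1 − D2) / D1`` where
``D1``/``D2`` are the Kullback–Leibler divergences of the empirical
pattern distribution from the first-order (independent) and pairwise
model distributions.

The model class follows the ``Model.fit() -> Results`` convention:
``PairwiseMaxEnt`` holds the data (binary series or moments), ``fit``
runs the moment-matching ascent and returns a ``PairwiseMaxEntResults``
carrying parameters, diagnostics and downstream constructors
(``landscape()``, ``simulate()``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .binarize import BinaryTimeSeries, binarize
from .patterns import check_enumerable, pattern_matrix, series_to_codes

__all__ = [
    "MomentSet",
    "MEMParameters",
    "PatternDistribution",
    "FitDiagnostics",
    "PairwiseMaxEnt",
    "PairwiseMaxEntResults",
    "compute_empirical_moments",
    "pattern_energy",
    "boltzmann_distribution",
    "compute_model_moments",
    "fit_independent_mem",
    "fit_pairwise_mem",
    "empirical_pattern_distribution",
    "kl_divergence",
    "fit_accuracy",
]

#: clamp for atanh when a node is (nearly) always on or off in the data
_ATANH_CLAMP = 1.0 - 1e-9


@dataclass
class MomentSet:
    """First and second sample moments of a ±1 pattern series."""

    mean_activity: np.ndarray  # ⟨σ_i⟩, length N
    pairwise: np.ndarray  # ⟨σ_i σ_j⟩, (N, N) symmetric, unit diagonal
    n_samples: int

    def __post_init__(self) -> None:
        self.mean_activity = np.asarray(self.mean_activity, dtype=float)
        self.pairwise = np.asarray(self.pairwise, dtype=float)
        n = self.mean_activity.shape[0]
        if self.pairwise.shape != (n, n):
            raise ValueError("pairwise matrix shape does not match mean vector")
        if np.abs(self.mean_activity).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("moments must lie in [-1, 1]")
        if not np.allclose(self.pairwise, self.pairwise.T):
            raise ValueError("pairwise moment matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.mean_activity.shape[0]


@dataclass
class MEMParameters:
    """Fields ``h`` and couplings ``J`` of a (pairwise) maximum-entropy model."""

    h: np.ndarray
    J: np.ndarray
    order: str = "pairwise"  # "first" or "pairwise"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J shape does not match h")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.abs(np.diag(self.J)).max(initial=0.0) > 1e-12:
            raise ValueError("J must have zero diagonal")
        if self.order not in ("first", "pairwise"):
            raise ValueError("order must be 'first' or 'pairwise'")
        if self.order == "first" and np.abs(self.J).max(initial=0.0) > 0:
            raise ValueError("first-order model requires J == 0")

    @property
    def n_nodes(self) -> int:
        return self.h.shape[0]


@dataclass
class PatternDistribution:
    """Probability of each of the ``2**N`` pattern codes.

    Index ``k`` is the pattern whose code is ``k`` (node 0 in the
    least-significant bit, −1 ↦ 0 and +1 ↦ 1).
    """

    probabilities: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape[0] != 2**self.n_nodes:
            raise ValueError("probability vector length must be 2**n_nodes")
        if (self.probabilities < -1e-15).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class FitDiagnostics:
    """Convergence and accuracy diagnostics of a MEM fit.

    ``accuracy = (d1 - d2) / d1`` is the fraction of the first-order
    model's KL shortfall removed by the pairwise terms; ``undefined`` is
    set when ``d1`` is at the numerical floor (empirical distribution
    already in the independent family) and the ratio is meaningless.
    """

    converged: bool
    n_iterations: int
    max_moment_gap: float
    d1: float | None = None
    d2: float | None = None
    accuracy: float | None = None
    undefined: bool = False

    @property
    def accuracy_percent(self) -> float | None:
        return None if self.accuracy is None else 100.0 * self.accuracy


# ---------------------------------------------------------------------------
# moments and energies


def compute_empirical_moments(
    series: BinaryTimeSeries | np.ndarray | Sequence[BinaryTimeSeries | np.ndarray],
) -> MomentSet:
    """Sample moments ``⟨σ_i⟩`` and ``⟨σ_i σ_j⟩`` of one or several series.

    A list of series is concatenated by simple row stacking — the
    group-level fit pools the binarized timepoints of all subjects.
    """
    if isinstance(series, (BinaryTimeSeries, np.ndarray)):
        series = [series]
    blocks = []
    for s in series:
        v = s.values if isinstance(s, BinaryTimeSeries) else np.asarray(s)
        blocks.append(v)
    n_nodes = blocks[0].shape[1]
    if any(b.shape[1] != n_nodes for b in blocks):
        raise ValueError("all series must have the same node count")
    values = np.concatenate(blocks, axis=0).astype(float)
    if values.shape[0] < 1:
        raise ValueError("need at least one timepoint")
    mean = values.mean(axis=0)
    pairwise = values.T @ values / values.shape[0]
    return MomentSet(mean_activity=mean, pairwise=pairwise, n_samples=values.shape[0])


def pattern_energy(pattern: np.ndarray, params: MEMParameters) -> float:
    """Energy ``E(V) = −Σ h_i σ_i − ½ ΣΣ J_ij σ_i σ_j`` of one pattern."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != params.h.shape:
        raise ValueError("pattern dimension does not match parameters")
    return float(-params.h @ pattern - 0.5 * pattern @ params.J @ pattern)


def _all_energies(params: MEMParameters) -> np.ndarray:
    """Energies of all ``2**N`` patterns, vectorized over the code order."""
    check_enumerable(params.n_nodes)
    S = pattern_matrix(params.n_nodes).astype(float)
    return -S @ params.h - 0.5 * np.einsum("pi,ij,pj->p", S, params.J, S)


def boltzmann_distribution(params: MEMParameters) -> PatternDistribution:
    """Exact Boltzmann distribution ``P(V_k) ∝ exp(−E(V_k))`` by enumeration."""
    energies = _all_energies(params)
    logp = -energies - logsumexp(-energies)
    return PatternDistribution(probabilities=np.exp(logp), n_nodes=params.n_nodes)


def compute_model_moments(params: MEMParameters) -> MomentSet:
    """Exact model expectations ``⟨σ_i⟩_m`` and ``⟨σ_i σ_j⟩_m``."""
    probs = boltzmann_distribution(params).probabilities
    S = pattern_matrix(params.n_nodes).astype(float)
    mean = probs @ S
    pairwise = np.einsum("p,pi,pj->ij", probs, S, S)
    np.fill_diagonal(pairwise, 1.0)
    pairwise = 0.5 * (pairwise + pairwise.T)
    return MomentSet(mean_activity=mean, pairwise=pairwise, n_samples=0)


# ---------------------------------------------------------------------------
# fitting


def fit_independent_mem(moments: MomentSet) -> MEMParameters:
    """First-order (independent) MEM: ``h_i = atanh(⟨σ_i⟩)``, ``J = 0``.

    Moments are clamped to ``±(1 − 1e-9)`` so that nodes that are always
    active or always inactive in a finite sample get a large finite field.
    """
    m = np.clip(moments.mean_activity, -_ATANH_CLAMP, _ATANH_CLAMP)
    h = np.arctanh(m)
    return MEMParameters(h=h, J=np.zeros((moments.n_nodes,) * 2), order="first")


def fit_pairwise_mem(
    moments: MomentSet,
    learning_rate: float = 0.2,
    tol: float = 1e-8,
    max_iter: int = 500_000,
) -> tuple[MEMParameters, FitDiagnostics]:
    """Fit ``h`` and ``J`` by gradient ascent on the log-likelihood.

    Starting from ``h = 0, J = 0``, each iteration nudges the parameters
    by the moment mismatch,

        h_i  += ε (⟨σ_i⟩ − ⟨σ_i⟩_m),
        J_ij += ε (⟨σ_i σ_j⟩ − ⟨σ_i σ_j⟩_m)   (i ≠ j),

    with model moments recomputed by exhaustive enumeration, until the
    largest absolute moment gap falls below ``tol`` or ``max_iter`` is
    reached.  Non-convergence is reported in the diagnostics rather than
    raised: the returned parameters are the last iterate.
    """
    n = moments.n_nodes
    check_enumerable(n)
    S = pattern_matrix(n).astype(float)
    # precompute σ_i σ_j per pattern once; N ≤ 20 keeps this small
    Spair = np.einsum("pi,pj->pij", S, S)
    target_mean = np.clip(moments.mean_activity, -1.0, 1.0)
    target_pair = moments.pairwise.copy()
    np.fill_diagonal(target_pair, 1.0)
    offdiag = ~np.eye(n, dtype=bool)

    h = np.zeros(n)
    J = np.zeros((n, n))
    gap = np.inf
    iteration = 0
    for iteration in range(1, max_iter + 1):
        energies = -S @ h - 0.5 * np.einsum("pij,ij->p", Spair, J)
        logp = -energies - logsumexp(-energies)
        probs = np.exp(logp)
        model_mean = probs @ S
        model_pair = np.einsum("p,pij->ij", probs, Spair)
        grad_h = target_mean - model_mean
        grad_J = target_pair - model_pair
        gap = max(np.abs(grad_h).max(), np.abs(grad_J[offdiag]).max(initial=0.0))
        if gap < tol:
            break
        h += learning_rate * grad_h
        J += learning_rate * np.where(offdiag, grad_J, 0.0)
    converged = gap < tol
    if not converged:
        warnings.warn(
            f"pairwise MEM fit did not reach tol={tol:g} after {max_iter} "
            f"iterations (max moment gap {gap:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    params = MEMParameters(h=h, J=J, order="pairwise")
    diag = FitDiagnostics(
        converged=bool(converged), n_iterations=iteration, max_moment_gap=float(gap)
    )
    return params, diag


# ---------------------------------------------------------------------------
# distributions and fit accuracy


def empirical_pattern_distribution(
    series: BinaryTimeSeries | np.ndarray,
) -> PatternDistribution:
    """Relative frequency of each pattern code in a binary series."""
    values = series.values if isinstance(series, BinaryTimeSeries) else np.asarray(series)
    if values.shape[0] < 1:
        raise ValueError("need at least one timepoint")
    n = values.shape[1]
    check_enumerable(n)
    codes = series_to_codes(values)
    counts = np.bincount(codes, minlength=2**n).astype(float)
    return PatternDistribution(probabilities=counts / counts.sum(), n_nodes=n)


def kl_divergence(p: PatternDistribution, q: PatternDistribution) -> float:
    """``Σ p log(p/q)`` in nats, with ``0 log 0 = 0``.

    Raises when ``q`` has zero mass somewhere ``p`` does not (a Boltzmann
    ``q`` is strictly positive, so this only bites for two empirical
    distributions).
    """
    if p.n_nodes != q.n_nodes:
        raise ValueError("distributions are over different pattern spaces")
    pp, qq = p.probabilities, q.probabilities
    support = pp > 0
    if (qq[support] <= 0).any():
        raise ValueError("KL undefined: q has zero mass on the support of p")
    return float(np.sum(pp[support] * np.log(pp[support] / qq[support])))


def fit_accuracy(
    empirical: PatternDistribution,
    first_order: MEMParameters,
    pairwise: MEMParameters,
    floor: float = 1e-12,
) -> FitDiagnostics:
    """Fit accuracy ``(D1 − D2)/D1`` from empirical and model distributions.

    ``D1``/``D2`` are KL divergences of the empirical distribution from
    the first-order / pairwise Boltzmann distributions.  When ``D1`` is
    below ``floor`` (the independent model already fits perfectly) the
    ratio is undefined and flagged as such.
    """
    if not (empirical.n_nodes == first_order.n_nodes == pairwise.n_nodes):
        raise ValueError("dimension mismatch between distribution and models")
    d1 = kl_divergence(empirical, boltzmann_distribution(first_order))
    d2 = kl_divergence(empirical, boltzmann_distribution(pairwise))
    undefined = d1 < floor
    accuracy = None if undefined else (d1 - d2) / d1
    return FitDiagnostics(
        converged=True,
        n_iterations=0,
        max_moment_gap=0.0,
        d1=d1,
        d2=d2,
        accuracy=accuracy,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# model / results objects


class PairwiseMaxEnt:
    """Pairwise maximum-entropy model of a binary pattern series.

    Parameters
    ----------
    endog
        ``(T, N)`` ±1 array, a :class:`BinaryTimeSeries`, or a list of
        either (concatenated row-wise for a pooled group-level fit).
    node_names
        Optional node labels used in summaries and exports.

    Use :meth:`from_continuous` to binarize raw signals first, or
    :meth:`from_moments` when only moments are available (exact-moment
    fits in simulation studies).
    """

    def __init__(
        self,
        endog: BinaryTimeSeries
        | np.ndarray
        | Sequence[BinaryTimeSeries | np.ndarray]
        | None = None,
        node_names: Sequence[str] | None = None,
        *,
        moments: MomentSet | None = None,
    ) -> None:
        if (endog is None) == (moments is None):
            raise ValueError("provide exactly one of endog or moments")
        self._empirical_dist: PatternDistribution | None = None
        if endog is not None:
            if isinstance(endog, (BinaryTimeSeries, np.ndarray)):
                endog = [endog]
            blocks = [
                e.values if isinstance(e, BinaryTimeSeries) else np.asarray(e)
                for e in endog
            ]
            if node_names is None:
                for e in endog:
                    if isinstance(e, BinaryTimeSeries):
                        node_names = e.node_names
                        break
            self.endog = np.concatenate(blocks, axis=0)
            self.moments = compute_empirical_moments(self.endog)
        else:
            self.endog = None
            self.moments = moments
        self.n_nodes = self.moments.n_nodes
        self.node_names = (
            list(node_names)
            if node_names is not None
            else [f"node{i}" for i in range(self.n_nodes)]
        )
        if len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length must match node count")
        n_required = 2 ** (self.n_nodes - 1)
        if self.endog is not None and self.endog.shape[0] < n_required:
            warnings.warn(
                f"only {self.endog.shape[0]} timepoints for N={self.n_nodes} "
                f"nodes; at least 2**(N-1)={n_required} are recommended for a "
                "sufficiently accurate fit",
                RuntimeWarning,
                stacklevel=2,
            )

    @classmethod
    def from_continuous(
        cls,
        signals: np.ndarray | Sequence[np.ndarray],
        mode: str = "per-timepoint-mean",
        node_names: Sequence[str] | None = None,
    ) -> "PairwiseMaxEnt":
        """Binarize continuous signals (one array per subject) and pool them."""
        if isinstance(signals, np.ndarray):
            signals = [signals]
        series = [binarize(s, mode=mode, node_names=node_names) for s in signals]
        return cls(series, node_names=node_names)

    @classmethod
    def from_moments(cls, moments: MomentSet, node_names=None) -> "PairwiseMaxEnt":
        return cls(moments=moments, node_names=node_names)

    def empirical_distribution(self) -> PatternDistribution:
        if self.endog is None:
            raise ValueError("no pattern data attached (model built from moments)")
        if self._empirical_dist is None:
            self._empirical_dist = empirical_pattern_distribution(self.endog)
        return self._empirical_dist

    def fit(
        self,
        learning_rate: float = 0.2,
        tol: float = 1e-8,
        max_iter: int = 500_000,
    ) -> "PairwiseMaxEntResults":
        """Moment-matching gradient ascent; returns a results object."""
        params, diag = fit_pairwise_mem(
            self.moments, learning_rate=learning_rate, tol=tol, max_iter=max_iter
        )
        first = fit_independent_mem(self.moments)
        if self.endog is not None:
            acc = fit_accuracy(self.empirical_distribution(), first, params)
            diag = FitDiagnostics(
                converged=diag.converged,
                n_iterations=diag.n_iterations,
                max_moment_gap=diag.max_moment_gap,
                d1=acc.d1,
                d2=acc.d2,
                accuracy=acc.accuracy,
                undefined=acc.undefined,
            )
        return PairwiseMaxEntResults(self, params, first, diag)


class PairwiseMaxEntResults:
    """Fitted pairwise MEM: parameters, diagnostics and derived objects."""

    def __init__(
        self,
        model: PairwiseMaxEnt,
        params: MEMParameters,
        first_order: MEMParameters,
        diagnostics: FitDiagnostics,
    ) -> None:
        self.model = model
        self.params = params
        self.first_order = first_order
        self.diagnostics = diagnostics

    @property
    def h(self) -> np.ndarray:
        return self.params.h

    @property
    def J(self) -> np.ndarray:
        return self.params.J

    @property
    def node_names(self) -> list[str]:
        return self.model.node_names

    def boltzmann(self) -> PatternDistribution:
        return boltzmann_distribution(self.params)

    def model_moments(self) -> MomentSet:
        return compute_model_moments(self.params)

    def landscape(self):
        """Energy landscape over all ``2**N`` patterns (see :mod:`landscape`)."""
        from .landscape import enumerate_energies

        return enumerate_energies(self.params, node_names=self.node_names)

    def simulate(self, n_steps: int = 100_000, burn_in: int = 100, seed=None):
        """Metropolis–Hastings random walk under the fitted model."""
        from .dynamics import metropolis_random_walk

        return metropolis_random_walk(
            self.params, n_steps=n_steps, burn_in=burn_in, seed=seed
        )

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Pairwise maximum-entropy model",
            "=" * 46,
            f"nodes:                {self.params.n_nodes}"
            f"  ({', '.join(self.node_names)})",
            f"observations:         {self.model.moments.n_samples}",
            f"converged:            {d.converged} ({d.n_iterations} iterations)",
            f"max moment gap:       {d.max_moment_gap:.3e}",
        ]
        if d.d1 is not None:
            lines.append(f"D1 (first-order KL):  {d.d1:.6f}")
            lines.append(f"D2 (pairwise KL):     {d.d2:.6f}")
            if d.undefined:
                lines.append("fit accuracy:         undefined (D1 ~ 0)")
            else:
                lines.append(
                    f"fit accuracy:         {d.accuracy:.4f} "
                    f"({d.accuracy_percent:.2f}%)"
                )
        lines.append("-" * 46)
        lines.append("h (basal activity):")
        lines.append("  " + "  ".join(f"{v:+.4f}" for v in self.h))
        lines.append("J (couplings, upper triangle):")
        n = self.params.n_nodes
        for i in range(n - 1):
            row = "  ".join(f"{self.J[i, j]:+.4f}" for j in range(i + 1, n))
            lines.append(f"  {self.node_names[i]}: {row}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = self.diagnostics
        return {
            "node_names": self.node_names,
            "h": self.h.tolist(),
            "J": self.J.tolist(),
            "order": self.params.order,
            "fit": {
                "d1": d.d1,
                "d2": d.d2,
                "accuracy": d.accuracy,
                "converged": d.converged,
                "n_iterations": d.n_iterations,
                "max_moment_gap": d.max_moment_gap,
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def load_params(path) -> tuple[MEMParameters, list[str]]:
        """Read back parameters (and node names) from a saved model JSON."""
        with open(path) as fh:
            payload = json.load(fh)
        params = MEMParameters(
            h=np.array(payload["h"]),
            J=np.array(payload["J"]),
            order=payload.get("order", "pairwise"),
        )
        return params, list(payload.get("node_names", []))
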