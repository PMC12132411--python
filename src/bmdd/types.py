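"""Core data containers for the bimodal-Dirichlet imputation model.

The observed data are a sample-by-taxon matrix of sequencing read counts
``W`` (n samples, m taxa) with per-sample depths ``N_i``.  The model places
a per-taxon two-point mixture over Dirichlet shape parameters: taxon ``j``
draws its shape from the low mode ``alpha0[j]`` or the high mode
``alpha1[j]`` according to a Bernoulli(``pi[j]``) indicator.  The
variational approximation of the posterior over the latent composition and
mode indicators is a Dirichlet (parameters ``beta``, one row per sample)
times independent Bernoullis (responsibilities ``gamma``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class BMDDError(ValueError):
    """Base class for invalid-input errors raised by this package."""


def _as_labels(labels, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise BMDDError(f"expected {n} {prefix} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise BMDDError(f"duplicate {prefix} labels")
    return labels


@dataclass
class CountTable:
    """Observed read counts: n samples by m taxa, nonnegative integers.

    ``depths`` are the per-sample row totals (the multinomial size
    parameters); samples with zero depth are rejected because they carry no
    information about the composition.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise BMDDError("counts must be a 2-D samples-by-taxa matrix")
        if not np.all(np.isfinite(counts)):
            raise BMDDError("counts contain NA or non-finite values")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise BMDDError(f"negative count at sample row {i}, taxon column {j}")
        if np.any(counts != np.floor(counts)):
            i, j = np.argwhere(counts != np.floor(counts))[0]
            raise BMDDError(f"non-integer count at sample row {i}, taxon column {j}")
        self.counts = counts.astype(np.int64)
        n, m = self.counts.shape
        self.sample_ids = _as_labels(self.sample_ids, n, "sample")
        self.taxon_ids = _as_labels(self.taxon_ids, m, "taxon")
        depths = self.counts.sum(axis=1)
        if np.any(depths == 0):
            i = int(np.argmin(depths))
            raise BMDDError(
                f"sample {self.sample_ids[i]!r} has zero sequencing depth"
            )

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


@dataclass
class Hyperparams:
    """Per-taxon mixture weights and the two Dirichlet shape modes.

    The ordering convention ``alpha0 <= alpha1`` (low mode first) is a
    labelling choice only; the likelihood is invariant under swapping a
    taxon's modes together with ``pi -> 1 - pi``.
    """

    pi: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.alpha0 = np.atleast_1d(np.asarray(self.alpha0, dtype=float))
        self.alpha1 = np.atleast_1d(np.asarray(self.alpha1, dtype=float))
        m = self.pi.shape[0]
        if self.alpha0.shape != (m,) or self.alpha1.shape != (m,):
            raise BMDDError("pi, alpha0, alpha1 must share one length m")
        if np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise BMDDError("pi must lie strictly inside (0, 1)")
        if np.any(self.alpha0 <= 0) or np.any(self.alpha1 <= 0):
            raise BMDDError("alpha shapes must be strictly positive")

    @property
    def n_taxa(self) -> int:
        return self.pi.shape[0]


@dataclass
class VariationalState:
    """Mean-field parameters: Dirichlet ``beta`` and Bernoulli ``gamma``."""

    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != self.gamma.shape or self.beta.ndim != 2:
            raise BMDDError("beta and gamma must be equal-shape n-by-m matrices")
        if np.any(self.beta <= 0):
            raise BMDDError("beta must be strictly positive")
        if np.any(self.gamma < 0) or np.any(self.gamma > 1):
            raise BMDDError("gamma must lie in [0, 1]")


@dataclass
class Composition:
    """Row-stochastic matrix of relative abundances."""

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] == 0:
            raise BMDDError("composition must be a non-empty 2-D matrix")
        if np.any(values < 0):
            raise BMDDError("relative abundances must be nonnegative")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-10):
            raise BMDDError("composition rows must sum to 1 (tolerance 1e-10)")
        self.values = values
        n, m = values.shape
        self.sample_ids = _as_labels(self.sample_ids, n, "sample")
        self.taxon_ids = _as_labels(self.taxon_ids, m, "taxon")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class FitResult:
    """Output of the variational EM fit."""

    hyperparams: Hyperparams
    state: VariationalState
    elbo_trace: np.ndarray
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.elbo_trace = np.asarray(self.elbo_trace, dtype=float)


@dataclass
class SimTruth:
    """Ground-truth bundle produced by the simulators.

    ``delta`` (mode indicators) is only present for data generated from the
    bimodal-Dirichlet process itself; the parametric misspecified settings
    have no mode structure.  ``group`` / ``differential`` / ``effect_sizes``
    are populated by :func:`bmdd.simulate.spike_signal`.
    """

    table: CountTable
    composition: Composition
    abs_abundance: np.ndarray | None = None
    delta: np.ndarray | None = None
    group: np.ndarray | None = None
    differential: np.ndarray | None = None
    effect_sizes: np.ndarray | None = None
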