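"""Empirical amino-acid substitution models with discrete-gamma rate variation.

A model couples a published exchangeability matrix (JTT by default, the
matrix used for the ancestral reconstruction this package reproduces) with
equilibrium frequencies, a calibrated instantaneous rate matrix Q, and K
equal-weight gamma rate categories of shape alpha.

Branch lengths are measured in expected substitutions per site: Q is scaled
so that -sum_i pi_i Q_ii = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import special, stats

from .formats import AMINO_ACIDS, GAP, UNKNOWN, Alignment

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_BUILTIN_MATRICES = {"JTT": "jtt.dat", "WAG": "wag.dat", "LG": "lg.dat"}


class ModelError(ValueError):
    pass


def read_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-style ``.dat`` model file.

    Layout: 19 rows of lower-triangular exchangeabilities (row i lists
    S[i, 0..i-1] for i = 1..19), then the 20 equilibrium frequencies.
    Lines starting with '#' are comments.
    """
    numbers: list[float] = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        numbers.extend(float(tok) for tok in line.split())
    if len(numbers) < 190 + 20:
        raise ModelError(
            f"model file holds {len(numbers)} numbers; need 190 + 20"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[k]
            k += 1
    pi = np.array(numbers[k : k + N_STATES])
    pi = pi / pi.sum()
    return S, pi


def load_exchangeabilities(name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        fname = _BUILTIN_MATRICES[name.upper()]
    except KeyError:
        raise ModelError(
            f"unknown matrix {name!r}; available: {sorted(_BUILTIN_MATRICES)}"
        ) from None
    text = resources.files("paleofmo.data").joinpath(fname).read_text()
    return read_paml_dat(text)


def discrete_gamma_rates(alpha: float, K: int, method: str = "mean") -> np.ndarray:
    """K equal-probability rate categories of a Gamma(alpha, rate=alpha)
    distribution (mean 1), renormalised to average exactly 1.

    ``method='mean'`` uses the mean of the distribution within each quantile
    bin (the convention of the CODEML default); ``method='median'`` uses bin
    medians instead.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ModelError(f"gamma shape alpha must be finite and > 0, got {alpha}")
    if K < 1:
        raise ModelError(f"need at least one rate category, got {K}")
    if K == 1:
        return np.array([1.0])
    if method == "median":
        q = (2 * np.arange(K) + 1) / (2 * K)
        rates = stats.gamma.ppf(q, a=alpha, scale=1.0 / alpha)
    elif method == "mean":
        # Bin boundaries at quantiles k/K; the conditional mean over
        # (b_{k-1}, b_k] follows from the incomplete gamma of shape alpha+1:
        # E[X; X<=b] = gammainc(alpha+1, alpha*b) for X ~ Gamma(alpha, alpha).
        bounds = stats.gamma.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
        upper = np.concatenate([special.gammainc(alpha + 1, alpha * bounds), [1.0]])
        lower = np.concatenate([[0.0], upper[:-1]])
        rates = K * (upper - lower)
    else:
        raise ModelError(f"unknown discretisation method {method!r}")
    return rates / rates.mean()


def calibrated_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Q_ij = S_ij pi_j (i != j), diagonal closing rows to zero, scaled so
    that -sum_i pi_i Q_ii = 1 (branch lengths in substitutions per site)."""
    Q = np.asarray(S, float) * np.asarray(pi, float)[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


@dataclass
class SubstitutionModel:
    """Calibrated reversible amino-acid model with gamma rate categories."""

    name: str
    S: np.ndarray  # symmetric exchangeabilities, zero diagonal
    pi: np.ndarray  # equilibrium frequencies, sum 1
    Q: np.ndarray  # calibrated generator, rows sum to 0
    alpha: float
    K: int
    rates: np.ndarray  # category rates, mean 1, equal weights 1/K
    # eigendecomposition of the symmetrised generator, for exp(Qt)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    def __post_init__(self):
        if self._eig is None:
            d = np.sqrt(self.pi)
            B = (self.Q * d[:, None]) / d[None, :]
            B = (B + B.T) / 2.0  # symmetric up to round-off by reversibility
            lam, V = np.linalg.eigh(B)
            self._eig = (lam, V / d[:, None] * 1.0, V * d[:, None])
            # left factor: diag(1/sqrt(pi)) V ; right factor: V^T diag(sqrt(pi))

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate) via the symmetrised eigendecomposition."""
        if t < 0:
            raise ModelError(f"negative branch length {t}")
        if rate <= 0:
            raise ModelError(f"rate must be positive, got {rate}")
        lam, L, R = self._eig
        P = (L * np.exp(lam * t * rate)) @ R.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def observed_frequencies(alignment: Alignment, floor: float = 1e-6) -> np.ndarray:
    """Amino-acid frequencies observed in an alignment (gaps and X excluded),
    floored at ``floor`` and renormalised (the +F convention)."""
    counts = np.zeros(N_STATES)
    for i, aa in enumerate(AMINO_ACIDS):
        counts[i] = (alignment.matrix == aa).sum()
    if counts.sum() == 0:
        raise ModelError("alignment contains no residues")
    freqs = np.maximum(counts / counts.sum(), floor)
    return freqs / freqs.sum()


def build_model(
    matrix_name: str = "JTT",
    frequencies_mode: str = "matrix_default",
    alpha: float = 1.114,
    K: int = 4,
    alignment: Alignment | None = None,
    frequencies: np.ndarray | None = None,
    gamma_method: str = "mean",
) -> SubstitutionModel:
    """Build a calibrated substitution model.

    ``frequencies_mode`` is ``matrix_default`` (the frequencies distributed
    with the empirical matrix), ``observed`` (+F, requires ``alignment``), or
    ``custom`` (requires ``frequencies``).
    """
    S, pi_default = load_exchangeabilities(matrix_name)
    if frequencies_mode == "matrix_default":
        pi = pi_default
    elif frequencies_mode == "observed":
        if alignment is None:
            raise ModelError("frequencies_mode='observed' requires an alignment")
        pi = observed_frequencies(alignment)
    elif frequencies_mode == "custom":
        if frequencies is None:
            raise ModelError("frequencies_mode='custom' requires frequencies")
        pi = np.asarray(frequencies, dtype=float)
        if pi.shape != (N_STATES,):
            raise ModelError(f"frequencies must have shape (20,), got {pi.shape}")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ModelError(f"frequencies sum to {pi.sum()}, not 1")
        if (pi < 0).any():
            raise ModelError("negative frequency")
    else:
        raise ModelError(f"unknown frequencies_mode {frequencies_mode!r}")

    Q = calibrated_rate_matrix(S, pi)
    rates = discrete_gamma_rates(alpha, K, method=gamma_method)
    return SubstitutionModel(
        name=matrix_name.upper(), S=S, pi=pi, Q=Q, alpha=alpha, K=K, rates=rates
    )


def transition_matrix(model: SubstitutionModel, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Integer encoding: 0..19 amino acids in ARNDCQEGHILKMFPSTWYV order,
    20 for gap or unknown (treated as missing data in the likelihood)."""
    enc = np.full(alignment.matrix.shape, N_STATES, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        enc[alignment.matrix == aa] = i
    return enc
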