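"""Maximum-entropy model containers: independent, pairwise (Ising) and triplet models.

All models live on ±1 spins. The pairwise model is

    p(s) = (1/Z) exp( sum_i h_i s_i + sum_{i<j} J_ij s_i s_j ),

with symmetric couplings and zero diagonal (no self-connections), for a total
of N(N+1)/2 free parameters. The triplet model adds a fully symmetric
third-order interaction tensor K_ijr that vanishes whenever two indices
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import yaml

__all__ = [
    "IndependentModel",
    "PairwiseModel",
    "TripletModel",
    "enumerate_states",
    "triu_indices",
]

_STATE_CACHE: dict[int, np.ndarray] = {}


def enumerate_states(n: int, dtype=np.float64) -> np.ndarray:
    """All 2^n spin configurations as a (2^n, n) ±1 matrix.

    Rows are in lexicographic order with −1 < +1, so row 0 is the all-silent
    state. Cached per n; callers must not mutate the result.
    """
    if n > 24:
        raise ValueError(f"refusing to enumerate 2^{n} states")
    if n not in _STATE_CACHE:
        bits = ((np.arange(2**n)[:, None] >> np.arange(n - 1, -1, -1)) & 1)
        _STATE_CACHE[n] = (2 * bits - 1).astype(np.int8)
    return _STATE_CACHE[n].astype(dtype, copy=False)


def triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i<j) index pair, row-major — the canonical coupling order."""
    return np.triu_indices(n, k=1)


def _check_symmetric_zero_diag(J: np.ndarray) -> None:
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be a square matrix")
    if not np.allclose(J, J.T, atol=1e-12, rtol=0):
        raise ValueError("J must be symmetric")
    if np.any(np.diag(J) != 0):
        raise ValueError("J must have zero diagonal (self-connections are omitted)")


@dataclass
class IndependentModel:
    """Independent maximum-entropy model: p(s) ∝ exp(sum_i h_i s_i)."""

    h: np.ndarray
    clipped: np.ndarray | None = None  # which means were clipped before atanh

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        if not np.all(np.isfinite(self.h)):
            raise ValueError("independent fields must be finite")

    @property
    def n(self) -> int:
        return self.h.size

    def energy(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        return -(states @ self.h)

    def log_z(self) -> float:
        # Z = prod_i 2 cosh(h_i); logaddexp(h, −h) = log(2 cosh h)
        return float(np.sum(np.logaddexp(self.h, -self.h)))

    def means(self) -> np.ndarray:
        return np.tanh(self.h)

    def spike_probabilities(self) -> np.ndarray:
        """Per-neuron probability of the +1 (active) state."""
        return 0.5 * (1.0 + np.tanh(self.h))

    def as_pairwise(self) -> "PairwiseModel":
        return PairwiseModel(self.h.copy(), np.zeros((self.n, self.n)), method_tag="ind")


@dataclass
class PairwiseModel:
    """Pairwise maximum-entropy (Ising) model with fields h and couplings J."""

    h: np.ndarray
    J: np.ndarray
    method_tag: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        _check_symmetric_zero_diag(self.J)
        if self.J.shape[0] != self.h.size:
            raise ValueError("h and J dimensions disagree")

    @property
    def n(self) -> int:
        return self.h.size

    @property
    def couplings_upper(self) -> np.ndarray:
        return self.J[triu_indices(self.n)]

    def energy(self, states: np.ndarray) -> np.ndarray:
        """E(s) = −Σ_i h_i s_i − Σ_{i<j} J_ij s_i s_j for each row of `states`."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        pair_term = 0.5 * np.einsum("ti,ij,tj->t", states, self.J, states)
        return -(states @ self.h) - pair_term

    def save(self, path) -> None:
        save_model(self, path)


@dataclass
class TripletModel:
    """Maximum-entropy model with third-order interactions K_ijr.

    K is stored dense, fully symmetric under index permutation, and zero on any
    entry with a repeated index; only N ≲ 15 is practical since fitting and
    evaluation enumerate all states.
    """

    h: np.ndarray
    J: np.ndarray
    K: np.ndarray
    method_tag: str = "triplet"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        _check_symmetric_zero_diag(self.J)
        n = self.h.size
        if self.K.shape != (n, n, n):
            raise ValueError("K must be an N×N×N tensor")
        for perm in ((0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
            if not np.allclose(self.K, np.transpose(self.K, perm), atol=1e-10):
                raise ValueError("K must be symmetric under index permutation")
        idx = np.arange(n)
        if (np.any(self.K[idx, idx, :] != 0) or np.any(self.K[idx, :, idx] != 0)
                or np.any(self.K[:, idx, idx] != 0)):
            raise ValueError("K entries with repeated indices must vanish")

    @property
    def n(self) -> int:
        return self.h.size

    def energy(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        pair_term = 0.5 * np.einsum("ti,ij,tj->t", states, self.J, states)
        # dense symmetric K counts each i<j<r triple 3! = 6 times
        trip_term = np.einsum("ti,tj,tk,ijk->t", states, states, states, self.K) / 6.0
        return -(states @ self.h) - pair_term - trip_term


def triplet_upper_entries(K: np.ndarray) -> list[tuple[int, int, int, float]]:
    n = K.shape[0]
    return [(i, j, r, float(K[i, j, r])) for i, j, r in combinations(range(n), 3)]


def dense_k_from_entries(n: int, entries) -> np.ndarray:
    K = np.zeros((n, n, n))
    for i, j, r, v in entries:
        for a, b, c in ((i, j, r), (i, r, j), (j, i, r), (j, r, i), (r, i, j), (r, j, i)):
            K[a, b, c] = v
    return K


def save_model(model, path) -> None:
    """Serialize a model to a structured text (YAML) file.

    Layout: N, spin convention tag, h as a list, J as the upper-triangle list
    in i<j row-major order, and (triplet models) K as (i, j, r, value) tuples.
    """
    doc: dict = {
        "n": int(model.n),
        "spin_convention": "pm1",
        "h": [float(x) for x in model.h],
    }
    if isinstance(model, IndependentModel):
        doc["kind"] = "independent"
    elif isinstance(model, TripletModel):
        doc["kind"] = "triplet"
        doc["j_upper"] = [float(x) for x in model.J[triu_indices(model.n)]]
        doc["k_entries"] = [[i, j, r, v] for i, j, r, v in triplet_upper_entries(model.K)
                            if v != 0.0]
    else:
        doc["kind"] = "pairwise"
        doc["j_upper"] = [float(x) for x in model.couplings_upper]
        doc["method_tag"] = model.method_tag
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("spin_convention", "pm1") != "pm1":
        raise ValueError("only the ±1 spin convention is supported in model files")
    n = int(doc["n"])
    h = np.asarray(doc["h"], dtype=float)
    kind = doc.get("kind", "pairwise")
    if kind == "independent":
        return IndependentModel(h)
    iu = triu_indices(n)
    J = np.zeros((n, n))
    J[iu] = np.asarray(doc["j_upper"], dtype=float)
    J = J + J.T
    if kind == "triplet":
        K = dense_k_from_entries(n, [tuple(e) for e in doc.get("k_entries", [])])
        return TripletModel(h, J, K)
    return PairwiseModel(h, J, method_tag=doc.get("method_tag", ""))
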