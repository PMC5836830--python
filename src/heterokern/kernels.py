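"""Base, normalized, pairwise and combined kernels, plus Gram assembly.

Protein-level kernels (Min, MinMax, scale-normalized Min) operate on
nonnegative profile vectors. Two lifts turn a protein-level kernel K into a
kernel between unordered protein pairs:

* the metric-learning lift: ``(K13 - K14 - K23 + K24)**2``;
* the tensor-product lift: ``K13*K24 + K14*K23``.

The domain-composition kernel is the 0/1 baseline that fires only when the
two pairs' count vectors match exactly under the direct or crossed
assignment. The combined kernel adds ``alpha`` times a chosen pair kernel to
the linear inner product of the 7-dimensional pair feature vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data_model_io import Pair, ProfileTable, ValidationError, WeightedPPINetwork
from .feature_maps import psi_matrix, psi

BASE_KERNELS = ("min", "minmax", "scale-normalized-min")
PAIRWISE_KERNELS = ("mlpk", "tppk", "mlpk+tppk", "domain-composition", "none")
FEATURE_SOURCES = ("dom", "phylo", "local")


# ---------------------------------------------------------------------------
# Scalar protein-level kernels
# ---------------------------------------------------------------------------

def _check_nonneg(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("kernel inputs must be nonnegative")
    return x, y


def min_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of elementwise minima; counts shared elements with multiplicity."""
    x, y = _check_nonneg(x, y)
    return float(np.minimum(x, y).sum())


def minmax_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Ratio of elementwise-min sum to elementwise-max sum, in [0, 1].

    Defined as 0 when the max-sum is 0 (both vectors zero).
    """
    x, y = _check_nonneg(x, y)
    denom = float(np.maximum(x, y).sum())
    if denom == 0.0:
        return 0.0
    return float(np.minimum(x, y).sum()) / denom


def scale_normalize(base: Callable[[np.ndarray, np.ndarray], float]) -> Callable:
    """Wrap a kernel as K(x,y)/sqrt(K(x,x)K(y,y)); 0 if a self-kernel is 0."""

    def normalized(x: np.ndarray, y: np.ndarray) -> float:
        kxx = base(x, x)
        kyy = base(y, y)
        if kxx <= 0.0 or kyy <= 0.0:
            return 0.0
        return base(x, y) / np.sqrt(kxx * kyy)

    return normalized


def base_kernel_function(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if name == "min":
        return min_kernel
    if name == "minmax":
        return minmax_kernel
    if name == "scale-normalized-min":
        return scale_normalize(min_kernel)
    raise ValueError(f"unknown base kernel {name!r}")


# ---------------------------------------------------------------------------
# Pairwise lifts (scalar form)
# ---------------------------------------------------------------------------

def mlpk(base: Callable) -> Callable:
    """Metric-learning lift of a protein-level kernel to pairs."""

    def lifted(pair_a: tuple, pair_b: tuple) -> float:
        x1, x2 = pair_a
        x3, x4 = pair_b
        return (base(x1, x3) - base(x1, x4) - base(x2, x3) + base(x2, x4)) ** 2

    return lifted


def tppk(base: Callable) -> Callable:
    """Tensor-product lift of a protein-level kernel to pairs."""

    def lifted(pair_a: tuple, pair_b: tuple) -> float:
        x1, x2 = pair_a
        x3, x4 = pair_b
        return base(x1, x3) * base(x2, x4) + base(x1, x4) * base(x2, x3)

    return lifted


def domain_composition_kernel(dom_table: ProfileTable) -> Callable[[Pair, Pair], float]:
    """0/1 kernel: 1 iff the two pairs' count vectors match (direct or crossed)."""

    def kernel(pair_a: Pair, pair_b: Pair) -> float:
        v1, v2 = (dom_table.vector(p) for p in pair_a)
        v3, v4 = (dom_table.vector(p) for p in pair_b)
        direct = np.array_equal(v1, v3) and np.array_equal(v2, v4)
        crossed = np.array_equal(v1, v4) and np.array_equal(v2, v3)
        return 1.0 if (direct or crossed) else 0.0

    return kernel


# ---------------------------------------------------------------------------
# Kernel specification and inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Which base kernel, pairwise lift, feature source and mixing weight to use.

    ``pairwise="none"`` reduces the combined kernel to the pair-feature inner
    product; ``pairwise="domain-composition"`` ignores ``base``.
    """

    base: str = "min"
    pairwise: str = "mlpk"
    feature_source: str = "dom"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.base not in BASE_KERNELS:
            raise ValueError(f"base must be one of {BASE_KERNELS}, got {self.base!r}")
        if self.pairwise not in PAIRWISE_KERNELS:
            raise ValueError(f"pairwise must be one of {PAIRWISE_KERNELS}, got {self.pairwise!r}")
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(f"feature_source must be one of {FEATURE_SOURCES}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KernelInputs:
    """Everything kernels consume: the network plus the three profile tables."""

    network: WeightedPPINetwork
    dom_table: ProfileTable
    phylo_table: ProfileTable | None = None
    local_table: ProfileTable | None = None

    def table(self, source: str) -> ProfileTable:
        t = {"dom": self.dom_table, "phylo": self.phylo_table, "local": self.local_table}[source]
        if t is None:
            raise ValueError(f"profile table for feature source {source!r} not provided")
        return t


@dataclass
class GramMatrix:
    """Kernel evaluations between two ordered lists of protein pairs."""

    row_pairs: list[Pair]
    col_pairs: list[Pair]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (len(self.row_pairs), len(self.col_pairs)):
            raise ValueError("entries shape does not match pair lists")

    @property
    def is_square(self) -> bool:
        return self.row_pairs == self.col_pairs

    def write_tsv(self, path: str | Path, spec: KernelSpec | None = None) -> None:
        """Dense TSV with 'A|B' pair identifiers; sidecar JSON records the spec."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pair\t" + "\t".join(f"{a}|{b}" for a, b in self.col_pairs) + "\n")
            for (a, b), row in zip(self.row_pairs, self.entries):
                fh.write(f"{a}|{b}\t" + "\t".join(repr(x) for x in row) + "\n")
        if spec is not None:
            with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
                json.dump(spec.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Vectorized Gram assembly
# ---------------------------------------------------------------------------

def _min_matrix(X: np.ndarray, Y: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Pairwise sum-of-minima between rows of X (n, d) and Y (m, d)."""
    n, d = X.shape
    m = Y.shape[0]
    out = np.zeros((n, m))
    for start in range(0, d, chunk):
        xs = X[:, None, start:start + chunk]
        ys = Y[None, :, start:start + chunk]
        out += np.minimum(xs, ys).sum(axis=2)
    return out


def _max_matrix(X: np.ndarray, Y: np.ndarray, chunk: int = 64) -> np.ndarray:
    n, d = X.shape
    m = Y.shape[0]
    out = np.zeros((n, m))
    for start in range(0, d, chunk):
        xs = X[:, None, start:start + chunk]
        ys = Y[None, :, start:start + chunk]
        out += np.maximum(xs, ys).sum(axis=2)
    return out


def base_gram_proteins(base: str, table: ProfileTable, proteins: Sequence[str]) -> np.ndarray:
    """Square base-kernel matrix over a list of proteins (computed once per Gram)."""
    X = np.vstack([table.vector(p).astype(float) for p in proteins]) if proteins else np.zeros((0, 0))
    if np.any(X < 0):
        raise ValidationError("profile vectors must be nonnegative")
    if base == "min":
        return _min_matrix(X, X)
    if base == "minmax":
        num = _min_matrix(X, X)
        den = _max_matrix(X, X)
        out = np.zeros_like(num)
        np.divide(num, den, out=out, where=den > 0)
        return out
    if base == "scale-normalized-min":
        B = _min_matrix(X, X)
        diag = np.sqrt(np.clip(np.diag(B), 0, None))
        denom = np.outer(diag, diag)
        out = np.zeros_like(B)
        np.divide(B, denom, out=out, where=denom > 0)
        return out
    raise ValueError(f"unknown base kernel {base!r}")


def _pair_indices(pairs: Sequence[Pair], index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([index[p[0]] for p in pairs], dtype=np.intp)
    b = np.array([index[p[1]] for p in pairs], dtype=np.intp)
    return a, b


def _lift_gram(
    pairwise: str,
    B: np.ndarray,
    rows: tuple[np.ndarray, np.ndarray],
    cols: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    a1, a2 = rows
    b1, b2 = cols
    K13 = B[np.ix_(a1, b1)]
    K14 = B[np.ix_(a1, b2)]
    K23 = B[np.ix_(a2, b1)]
    K24 = B[np.ix_(a2, b2)]
    if pairwise == "mlpk":
        return (K13 - K14 - K23 + K24) ** 2
    if pairwise == "tppk":
        return K13 * K24 + K14 * K23
    if pairwise == "mlpk+tppk":
        return (K13 - K14 - K23 + K24) ** 2 + K13 * K24 + K14 * K23
    raise ValueError(f"unknown lift {pairwise!r}")


def _composition_gram(
    dom_table: ProfileTable, pairs_a: Sequence[Pair], pairs_b: Sequence[Pair]
) -> np.ndarray:
    def key(pair: Pair) -> tuple:
        va, vb = (tuple(int(x) for x in dom_table.vector(p)) for p in pair)
        return (va, vb) if va <= vb else (vb, va)

    ids: dict[tuple, int] = {}
    def pair_id(pair: Pair) -> int:
        k = key(pair)
        return ids.setdefault(k, len(ids))

    ra = np.array([pair_id(p) for p in pairs_a])
    rb = np.array([pair_id(p) for p in pairs_b])
    return (ra[:, None] == rb[None, :]).astype(float)


def pair_component_gram(
    spec: KernelSpec, pairs_a: Sequence[Pair], pairs_b: Sequence[Pair], inputs: KernelInputs
) -> np.ndarray:
    """The alpha-independent pair-kernel block (zeros for pairwise='none')."""
    if spec.pairwise == "none":
        return np.zeros((len(pairs_a), len(pairs_b)))
    if spec.pairwise == "domain-composition":
        return _composition_gram(inputs.dom_table, pairs_a, pairs_b)
    table = inputs.table(spec.feature_source)
    proteins = sorted({p for pair in (*pairs_a, *pairs_b) for p in pair})
    index = {p: i for i, p in enumerate(proteins)}
    B = base_gram_proteins(spec.base, table, proteins)
    return _lift_gram(spec.pairwise, B, _pair_indices(pairs_a, index), _pair_indices(pairs_b, index))


def psi_gram(
    pairs_a: Sequence[Pair], pairs_b: Sequence[Pair], inputs: KernelInputs
) -> np.ndarray:
    """Linear-kernel block of the pair feature vectors."""
    Pa = psi_matrix(inputs.network, inputs.dom_table, list(pairs_a))
    Pb = psi_matrix(inputs.network, inputs.dom_table, list(pairs_b))
    return Pa @ Pb.T


def gram(
    spec: KernelSpec,
    pairs_a: Sequence[Pair],
    pairs_b: Sequence[Pair],
    inputs: KernelInputs,
) -> GramMatrix:
    """Combined-kernel Gram matrix between two lists of protein pairs."""
    entries = psi_gram(pairs_a, pairs_b, inputs) + spec.alpha * pair_component_gram(
        spec, pairs_a, pairs_b, inputs
    )
    return GramMatrix(list(pairs_a), list(pairs_b), entries)


# ---------------------------------------------------------------------------
# Scalar combined kernel (reference path; gram() must agree with it)
# ---------------------------------------------------------------------------

def combined_kernel(
    spec: KernelSpec, inputs: KernelInputs, pair_a: Pair, pair_b: Pair
) -> float:
    """Evaluate the combined kernel on a single pair of protein pairs."""
    va = psi(inputs.network, inputs.dom_table, pair_a)
    vb = psi(inputs.network, inputs.dom_table, pair_b)
    value = float(va @ vb)
    if spec.pairwise == "none":
        return value
    if spec.pairwise == "domain-composition":
        pk = domain_composition_kernel(inputs.dom_table)(pair_a, pair_b)
    else:
        table = inputs.table(spec.feature_source)
        base = base_kernel_function(spec.base)
        xa = tuple(table.vector(p).astype(float) for p in pair_a)
        xb = tuple(table.vector(p).astype(float) for p in pair_b)
        if spec.pairwise == "mlpk":
            pk = mlpk(base)(xa, xb)
        elif spec.pairwise == "tppk":
            pk = tppk(base)(xa, xb)
        elif spec.pairwise == "mlpk+tppk":
            pk = mlpk(base)(xa, xb) + tppk(base)(xa, xb)
        else:  # pragma: no cover - exhausted above
            raise ValueError(spec.pairwise)
    return value + spec.alpha * pk
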