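"""Dependence measures between variable pairs.

Two measures are provided: plug-in discrete mutual information (in units of
``log_base``) and the maximal information coefficient (MIC), a grid-based
dependence score in [0, 1] defined as the maximum over axis-aligned grids of
the normalized mutual information of the induced 2-D histogram, subject to a
grid budget ``i * j <= B(n) = floor(n ** b_exponent)``.

The MIC estimator comes in two modes:

``approx``
    Row partitions of one axis are fixed, and the optimal column partition of
    the other axis is found exactly by dynamic programming over clump
    boundaries; both orientations are computed and the characteristic matrix
    takes the entrywise maximum. When the row axis has at most
    ``clump_factor`` candidate cut positions, *all* of its partitions are
    tried (making the entry exact); otherwise the single equipartition of the
    row axis is used — the classic large-n heuristic. Candidate column cuts
    are limited to ``clump_factor * i_max`` superclumps.

``exhaustive``
    Brute-force maximization over *all* grid partitions. Exponential in n;
    intended as a ground-truth oracle for small samples (n around a dozen).
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "AssociationConfig",
    "CharacteristicMatrix",
    "mutual_info_discrete",
    "characteristic_matrix",
    "mic",
    "association_to_label",
    "pairwise_association",
]


@dataclass(frozen=True)
class AssociationConfig:
    """Parameters of the MIC estimator.

    Parameters
    ----------
    b_exponent : float
        Exponent of the grid budget ``B(n) = floor(n ** b_exponent)``;
        must lie in (0, 1).
    clump_factor : int
        Bounds candidate column partitions to ``clump_factor * i_max``
        superclumps in approx mode; must be >= 1.
    log_base : float
        Base of every logarithm (numerator and denominator of the
        normalization alike; the ratio is only base-invariant when both use
        the same base). Mutual information values are in units of this base.
    mode : {"approx", "exhaustive"}
        Estimator mode, see module docstring.
    """

    b_exponent: float = 0.6
    clump_factor: int = 15
    log_base: float = 2.0
    mode: str = "approx"

    def __post_init__(self) -> None:
        if not 0.0 < self.b_exponent < 1.0:
            raise ValueError(f"b_exponent must be in (0, 1), got {self.b_exponent}")
        if self.clump_factor < 1:
            raise ValueError(f"clump_factor must be >= 1, got {self.clump_factor}")
        if self.log_base <= 1.0:
            raise ValueError(f"log_base must be > 1, got {self.log_base}")
        if self.mode not in ("approx", "exhaustive"):
            raise ValueError(f"mode must be 'approx' or 'exhaustive', got {self.mode!r}")

    def grid_budget(self, n: int) -> int:
        """B(n) = floor(n ** b_exponent)."""
        return int(math.floor(n**self.b_exponent))

    def min_n(self) -> int:
        """Smallest sample size whose budget admits a 2x2 grid."""
        n = 2
        while self.grid_budget(n) < 4:
            n += 1
        return n


@dataclass
class CharacteristicMatrix:
    """Normalized maximal grid mutual informations, indexed by (i, j).

    ``entries[(i, j)]`` is the maximal mutual information over i-by-j grids
    divided by ``log(min(i, j))``; defined only for i, j >= 2 with
    ``i * j <= B(n)``. All entries lie in [0, 1]. ``constant_input`` flags
    the degenerate all-zero matrix produced by a constant sequence.
    """

    entries: dict[tuple[int, int], float]
    n: int
    config: AssociationConfig
    constant_input: bool = field(default=False)

    def max_entry(self) -> float:
        return max(self.entries.values())


# ---------------------------------------------------------------------------
# discrete mutual information


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be one-dimensional sequences")
    if len(x) != len(y):
        raise ValueError(f"length mismatch: len(x)={len(x)}, len(y)={len(y)}")
    if len(x) == 0:
        raise ValueError("empty sequences have no defined association")
    return x, y


def mutual_info_discrete(x, y, log_base: float = 2.0) -> float:
    """Plug-in mutual information of two equal-length categorical sequences.

    Computes ``sum p(x,y) log(p(x,y) / (p(x) p(y)))`` over observed joint
    cells with empirical probabilities. Symmetric; bounded by the marginal
    entropies; returned in units of ``log_base`` (bits by default).
    """
    x, y = _check_pair(x, y)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(counts, (xi, yi), 1.0)
    return _mi_from_counts(counts, math.log(log_base))


def _mi_from_counts(counts: np.ndarray, ln_base: float) -> float:
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.divide(p, px * py, out=np.ones_like(p), where=mask)
    terms = p * np.log(ratio)
    # clip tiny negative round-off; MI is nonnegative
    return max(float(terms.sum() / ln_base), 0.0)


# ---------------------------------------------------------------------------
# MIC machinery

# A "clump" is a maximal run of equal values along the sorted axis: cuts may
# only fall between clumps, so tied values are never split across cells.


def _clump_sizes(sorted_vals: np.ndarray) -> np.ndarray:
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0)
    return np.diff(np.concatenate(([0], boundaries + 1, [len(sorted_vals)])))


def _equipartition(vals_sorted_groups: np.ndarray, j: int) -> np.ndarray:
    """Assign sorted clump sizes to <= j rows of near-equal point counts.

    Tied values (one clump) always land in a single row. Returns the row id
    of each clump. May use fewer than j rows when large clumps absorb more
    than their share.
    """
    sizes = vals_sorted_groups
    n = int(sizes.sum())
    row_of = np.empty(len(sizes), dtype=np.intp)
    row = 0
    in_row = 0
    placed = 0
    desired = n / j
    for g, s in enumerate(sizes):
        if in_row > 0 and abs(in_row + s - desired) >= abs(in_row - desired) and row < j - 1:
            row += 1
            in_row = 0
            desired = (n - placed) / (j - row)
        row_of[g] = row
        in_row += s
        placed += s
    return row_of


def _entropy(counts: np.ndarray) -> float:
    """Natural-log entropy of a nonnegative count vector."""
    c = counts[counts > 0]
    n = c.sum()
    p = c / n
    return float(-(p * np.log(p)).sum())


def _optimize_columns(cum: np.ndarray, i_max: int) -> np.ndarray:
    """DP over clump boundaries: best sum of per-bin terms for exactly k bins.

    ``cum`` has shape (m+1, r): cumulative per-row counts after each of the m
    candidate cut positions (clump boundaries), cum[0] = 0. The per-bin term
    of bin (s, t] is the H(P) contribution minus the H(P,Q) contribution,
    both in nats; the mutual information of a k-bin partition is
    ``F[k] + H(Q)``.

    Returns ``best[k]`` for k = 1..i_max (index 0 unused, -inf).
    """
    m = cum.shape[0] - 1
    n = cum[-1].sum()
    # T[s, t] = term of bin (s, t], s < t
    diff = cum[None, :, :] - cum[:, None, :]  # (m+1, m+1, r)
    tot = diff.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_bin = np.where(tot > 0, -(tot / n) * np.log(tot / n), 0.0)
        h_joint = np.where(diff > 0, (diff / n) * np.log(diff / n), 0.0).sum(axis=2)
    T = h_bin + h_joint
    T[np.tril_indices(m + 1)] = -np.inf  # only s < t is a bin

    best = np.full(i_max + 1, -np.inf)
    F = T[0].copy()  # F[t] for exactly 1 bin covering (0, t]
    best[1] = F[m]
    for k in range(2, i_max + 1):
        # F_k[t] = max_s F_{k-1}[s] + T[s, t]
        F = np.max(F[:, None] + T, axis=0)
        best[k] = F[m]
        if not np.isfinite(F[m]):
            break
    return best


# Cap on enumerated row partitions per (axis, j); guards the exact small-n
# path against combinatorial blowup when clumps are few but j is large.
_MAX_ROW_PARTITIONS = 3000


def _row_partitions(y_sizes: np.ndarray, j: int, clump_factor: int):
    """Candidate row assignments (one per y-clump) for a j-row partition.

    Yields every partition of the clump sequence into <= j contiguous rows
    when the axis has at most ``clump_factor`` cut positions (exact small-n
    path); otherwise yields the single near-equal-count equipartition.
    """
    m = len(y_sizes)
    if m - 1 <= clump_factor and math.comb(m - 1, j - 1) <= _MAX_ROW_PARTITIONS:
        for cuts in combinations(range(1, m), j - 1):
            row_of_clump = np.searchsorted(np.asarray(cuts), np.arange(m), side="right")
            yield row_of_clump.astype(np.intp)
    else:
        yield _equipartition(y_sizes, j)


def _half_charmat_approx(
    x: np.ndarray, y: np.ndarray, B: int, clump_factor: int
) -> dict[tuple[int, int], float]:
    """Entries (i_cols_on_x, j_rows_on_y) with x-columns optimized by DP."""
    n = len(x)
    out: dict[tuple[int, int], float] = {}
    order_y = np.argsort(y, kind="stable")
    y_sizes = _clump_sizes(y[order_y])
    order_x = np.argsort(x, kind="stable")
    x_sorted = x[order_x]
    x_sizes = _clump_sizes(x_sorted)
    ends_full = np.cumsum(x_sizes)

    for j in range(2, B // 2 + 1):
        i_max = B // j
        for row_of_clump in _row_partitions(y_sizes, j, clump_factor):
            r = int(row_of_clump.max()) + 1
            if r < 2:
                continue
            # row id per sample, then reorder by x
            rows = np.empty(n, dtype=np.intp)
            rows[order_y] = np.repeat(row_of_clump, y_sizes)
            rows_x = rows[order_x]

            ends = ends_full
            m_cap = clump_factor * i_max
            if len(ends) > m_cap:
                # coarsen to superclumps: keep boundaries closest to an equipartition
                targets = np.linspace(0, n, m_cap + 1)[1:-1]
                keep = np.unique(
                    np.searchsorted(ends, targets, side="left").clip(0, len(ends) - 1)
                )
                ends = np.unique(np.concatenate([ends[keep], [n]]))
            # cumulative per-row counts at each boundary
            onehot = np.zeros((n + 1, r))
            np.add.at(onehot, (np.arange(1, n + 1), rows_x), 1.0)
            cum = np.cumsum(onehot, axis=0)[np.concatenate(([0], ends))]

            hq = _entropy(cum[-1])
            best = _optimize_columns(cum, i_max)
            for i in range(2, i_max + 1):
                v = max(best[i] + hq, 0.0)
                if v > out.get((i, j), 0.0):
                    out[(i, j)] = v
    return out


def _grid_mi(xi: np.ndarray, yi: np.ndarray, x_bins: int, y_bins: int) -> float:
    counts = np.zeros((x_bins, y_bins))
    np.add.at(counts, (xi, yi), 1.0)
    n = counts.sum()
    p = counts[counts > 0] / n
    px = counts.sum(axis=1)
    py = counts.sum(axis=0)
    h = lambda c: _entropy(c)
    return h(px) + h(py) + float((p * np.log(p)).sum())  # H(X)+H(Y)-H(X,Y)


def _exhaustive_entries(x: np.ndarray, y: np.ndarray, B: int) -> dict[tuple[int, int], float]:
    """Max MI over *all* grids with exactly a columns and b rows, a*b <= B."""
    n = len(x)
    order_x = np.argsort(x, kind="stable")
    order_y = np.argsort(y, kind="stable")
    x_sizes = _clump_sizes(x[order_x])
    y_sizes = _clump_sizes(y[order_y])
    # clump id per sample along each axis
    cx = np.empty(n, dtype=np.intp)
    cx[order_x] = np.repeat(np.arange(len(x_sizes)), x_sizes)
    cy = np.empty(n, dtype=np.intp)
    cy[order_y] = np.repeat(np.arange(len(y_sizes)), y_sizes)
    mx, my = len(x_sizes), len(y_sizes)

    exact: dict[tuple[int, int], float] = {}
    a_max = min(B // 2, mx)
    for a in range(2, a_max + 1):
        b_cap = min(B // a, my)
        if b_cap < 2:
            continue
        for xcuts in combinations(range(1, mx), a - 1):
            xb = np.searchsorted(np.asarray(xcuts), cx, side="right")
            for b in range(2, b_cap + 1):
                for ycuts in combinations(range(1, my), b - 1):
                    yb = np.searchsorted(np.asarray(ycuts), cy, side="right")
                    v = _grid_mi(xb, yb, a, b)
                    key = (a, b)
                    if v > exact.get(key, -np.inf):
                        exact[key] = v
    return exact


def characteristic_matrix(x, y, config: AssociationConfig | None = None) -> CharacteristicMatrix:
    """Characteristic matrix of a pair of real sequences.

    Each admissible entry (i, j) is the maximal mutual information over
    i-by-j axis-aligned grid partitions, normalized by ``log(min(i, j))``.
    Constant input yields an all-zero matrix flagged ``constant_input``.

    Raises
    ------
    ValueError
        If the sample is too small for the budget to admit any grid (the
        message names the minimum n for the configured exponent).
    """
    config = config or AssociationConfig()
    x, y = _check_pair(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values are not allowed")
    n = len(x)
    B = config.grid_budget(n)
    if B < 4:
        raise ValueError(
            f"n={n} is too small: B(n)=floor(n^{config.b_exponent})={B} < 4 admits "
            f"no 2x2 grid; minimum n is {config.min_n()}"
        )
    admissible = [
        (i, j) for i in range(2, B // 2 + 1) for j in range(2, B // i + 1)
    ]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CharacteristicMatrix(
            entries={k: 0.0 for k in admissible}, n=n, config=config, constant_input=True
        )

    if config.mode == "exhaustive":
        raw = _exhaustive_entries(x, y, B)
    else:
        half_xy = _half_charmat_approx(x, y, B, config.clump_factor)
        half_yx = _half_charmat_approx(y, x, B, config.clump_factor)
        raw = {
            (i, j): max(half_xy.get((i, j), 0.0), half_yx.get((j, i), 0.0))
            for i, j in admissible
        }
    # Entry (i, j) maximizes over grids with at most i columns and at most j
    # rows (monotone envelope); normalization by log(min(i, j)) is base-free
    # because numerator and denominator use the same (natural) log.
    entries = {}
    for i, j in admissible:
        env = max((v for (a, b), v in raw.items() if a <= i and b <= j), default=0.0)
        entries[(i, j)] = min(env / math.log(min(i, j)), 1.0)
    return CharacteristicMatrix(entries=entries, n=n, config=config)


def mic(x, y, config: AssociationConfig | None = None) -> float:
    """Maximal information coefficient of a pair of real sequences.

    The maximum entry of :func:`characteristic_matrix`; lies in [0, 1],
    equals 1 for noiseless functional dependence (given enough data) and
    tends to 0 for independent pairs.
    """
    return characteristic_matrix(x, y, config).max_entry()


def association_to_label(x, y_labels, config: AssociationConfig | None = None) -> float:
    """MIC between a real feature and a categorical label.

    Labels are coded as their rank among sorted unique values, so the result
    does not depend on the labels' representation. Single-class labels give
    0 with a warning.
    """
    x, y_labels = _check_pair(x, y_labels)
    classes, codes = np.unique(y_labels, return_inverse=True)
    if len(classes) < 2:
        warnings.warn("labels contain a single class; association is 0", stacklevel=2)
        return 0.0
    return mic(x, codes.astype(float), config)


def pairwise_association(
    dataset,
    targets=None,
    config: AssociationConfig | None = None,
    workers: int = 1,
    include_label: bool = True,
):
    """All feature-feature (and feature-label) MIC values for a dataset.

    Returns a pandas DataFrame indexed/columned by feature name, plus a
    ``__label__`` column when ``include_label``. Work is split across
    ``workers`` threads by pair; each value is written into its own slot, so
    the result is bit-identical for any worker count.
    """
    import pandas as pd

    config = config or AssociationConfig()
    if workers < 1:
        raise ValueError("workers must be >= 1")
    X, y, names = dataset.X, dataset.y, list(dataset.feature_names)
    idx = list(range(X.shape[1])) if targets is None else sorted(targets)
    sub = [names[i] for i in idx]
    k = len(idx)
    table = np.ones((k, k))
    jobs = [(a, b) for a in range(k) for b in range(a + 1, k)]

    def feat_pair(ab):
        a, b = ab
        return mic(X[:, idx[a]], X[:, idx[b]], config)

    def label_one(a):
        return association_to_label(X[:, idx[a]], y, config)

    if workers == 1:
        pair_vals = [feat_pair(ab) for ab in jobs]
        label_vals = [label_one(a) for a in range(k)] if include_label else None
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            pair_vals = list(pool.map(feat_pair, jobs))
            label_vals = list(pool.map(label_one, range(k))) if include_label else None
    for (a, b), v in zip(jobs, pair_vals):
        table[a, b] = table[b, a] = v
    for a in range(k):
        col = X[:, idx[a]]
        if np.all(col == col[0]):
            table[a, a] = 0.0  # MIC of a constant with itself is 0, not 1
    df = pd.DataFrame(table, index=sub, columns=sub)
    if include_label:
        df["__label__"] = label_vals
    return df
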