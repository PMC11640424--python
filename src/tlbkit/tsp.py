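"""Top-scoring temperature-pair features.

The classifier does not consume the normalized heat-capacity values
directly; it consumes *ordering* information: for a pair of temperatures
(Ti, Tj), the binary indicator ``1[Cp(Ti) > Cp(Tj)]``.  Such rank-based
features are invariant to any monotone rescaling of a sample's curve, which
is what makes them robust to residual amplitude and baseline effects.

For each candidate pair the **primary TSP score** is

    | P̂(X_Ti > X_Tj | class=1) − P̂(X_Ti > X_Tj | class=0) |

with P̂ the within-class empirical frequency (exact ties count as "not
greater").  Ties in the primary score are ordered by the **secondary score**,
the absolute between-class difference of the mean within-sample rank
difference rank(Ti) − rank(Tj) — pairs whose rank gap differs more between
classes rank higher.  ``ktsp_select`` returns the top pairs, optionally
requiring the pairs to use disjoint temperatures (classical kTSP semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DomainError, GridMismatchError, SelectionError
from .preprocess import FeatureVector


@dataclass(frozen=True)
class PairFeature:
    """An ordered temperature pair with its TSP scores.

    The indicator associated with the pair is ``1[X_ti > X_tj]``; the stored
    direction is canonical: the positive class is the one more likely to
    have ``X_ti > X_tj``.
    """

    ti: float
    tj: float
    score_primary: float
    score_secondary: float

    def __post_init__(self) -> None:
        if self.ti == self.tj:
            raise DomainError(f"pair temperatures must differ, got {self.ti}")
        if not (0.0 <= self.score_primary <= 1.0):
            raise DomainError(
                f"score_primary must lie in [0, 1], got {self.score_primary}"
            )

    def label(self) -> str:
        return f"T{self.ti:g}>T{self.tj:g}"


@dataclass
class PairMatrix:
    """Binary ordering indicators for a set of samples × pairs."""

    sample_ids: list[str]
    pairs: list[PairFeature]
    indicators: np.ndarray  # shape (n_samples, n_pairs), entries in {0, 1}

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators)
        if self.indicators.shape != (len(self.sample_ids), len(self.pairs)):
            raise DomainError(
                f"indicator matrix shape {self.indicators.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.pairs)} pairs"
            )
        if self.indicators.size and not np.isin(self.indicators, (0, 1)).all():
            raise DomainError("indicators must be 0/1")


def _stack(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack FeatureVectors sharing one grid into an (n_samples, n_temps) matrix."""
    if not features:
        raise DomainError("no feature vectors given")
    grid = features[0].grid
    for f in features[1:]:
        if len(f.grid) != len(grid) or not np.array_equal(f.grid, grid):
            raise GridMismatchError(
                f"sample {f.sample_id!r} is on a different feature grid"
            )
    X = np.vstack([f.values for f in features])
    return X, grid, [f.sample_id for f in features]


def _as_binary_labels(labels, sample_ids: list[str]) -> np.ndarray:
    """Accept a sample_id→label map or a sequence; return 0/1 array."""
    if isinstance(labels, dict):
        try:
            seq = [labels[s] for s in sample_ids]
        except KeyError as e:
            raise DomainError(f"no label for sample {e.args[0]!r}") from None
    else:
        seq = list(labels)
        if len(seq) != len(sample_ids):
            raise DomainError(
                f"{len(seq)} labels for {len(sample_ids)} samples"
            )
    out = np.empty(len(seq), dtype=int)
    for i, v in enumerate(seq):
        if v in (0, 1):
            out[i] = int(v)
        elif v == "negative":
            out[i] = 0
        elif v == "positive":
            out[i] = 1
        else:
            raise DomainError(f"unrecognized class label {v!r}")
    return out


def _grid_index(grid: np.ndarray, temp: float) -> int:
    hit = np.flatnonzero(np.abs(grid - temp) < 1e-9)
    if len(hit) != 1:
        raise GridMismatchError(f"temperature {temp} not on the feature grid")
    return int(hit[0])


def pair_score(
    features: list[FeatureVector],
    labels,
    ti: float,
    tj: float,
) -> tuple[float, float]:
    """TSP scores of the ordered pair (ti, tj).

    Returns ``(score_primary, score_secondary)`` as defined in the module
    docstring.  Requires both classes non-empty and ti ≠ tj.
    """
    if ti == tj:
        raise DomainError("ti and tj must differ")
    X, grid, ids = _stack(features)
    y = _as_binary_labels(labels, ids)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise DomainError("both classes must be non-empty")
    i, j = _grid_index(grid, ti), _grid_index(grid, tj)
    gt = X[:, i] > X[:, j]
    primary = abs(gt[y == 1].mean() - gt[y == 0].mean())
    ranks = rankdata(X, axis=1)
    d = ranks[:, i] - ranks[:, j]
    secondary = abs(d[y == 1].mean() - d[y == 0].mean())
    return float(primary), float(secondary)


def _all_pair_scores(X: np.ndarray, y: np.ndarray):
    """Vectorized per-class ordering frequencies and rank-gap means.

    Returns (delta, rankdelta), both (g, g) arrays for the indicator
    X[:, i] > X[:, j]: delta[i, j] = P̂₁(Xi > Xj) − P̂₀(Xi > Xj) and the
    corresponding between-class mean rank-difference gap.
    """
    gt = X[:, :, None] > X[:, None, :]  # (n, g, g)
    p1 = gt[y == 1].mean(axis=0)
    p0 = gt[y == 0].mean(axis=0)
    ranks = rankdata(X, axis=1)
    d = ranks[:, :, None] - ranks[:, None, :]  # (n, g, g)
    r1 = d[y == 1].mean(axis=0)
    r0 = d[y == 0].mean(axis=0)
    return p1 - p0, r1 - r0


def ktsp_select(
    features: list[FeatureVector],
    labels,
    k_max: int = 10,
    disjoint: bool = True,
) -> list[PairFeature]:
    """Select the top-scoring temperature pairs.

    All unordered pairs over the feature grid are scored; each is stored in
    its canonical direction (positive class more likely to satisfy the
    indicator).  Pairs are sorted by (primary desc, secondary desc, (ti, tj)
    asc); with ``disjoint=True`` a greedy pass keeps a pair only if neither
    temperature was used by an already-kept pair.  Returns
    ``min(k_max, available)`` pairs.
    """
    if k_max < 1:
        raise SelectionError(f"k_max must be >= 1, got {k_max}")
    X, grid, ids = _stack(features)
    y = _as_binary_labels(labels, ids)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise DomainError("both classes must be non-empty")
    g = len(grid)
    if g < 2 or (disjoint and g < 2 * 1):
        raise SelectionError("need at least two grid temperatures")

    delta, rankdelta = _all_pair_scores(X, y)
    candidates: list[PairFeature] = []
    for i in range(g):
        for j in range(i + 1, g):
            # canonical direction: larger signed class-frequency difference
            if delta[i, j] >= delta[j, i]:
                a, b = i, j
            else:
                a, b = j, i
            primary = max(float(delta[a, b]), 0.0)
            secondary = abs(float(rankdelta[a, b]))
            candidates.append(
                PairFeature(float(grid[a]), float(grid[b]), primary, secondary)
            )
    candidates.sort(
        key=lambda p: (-p.score_primary, -p.score_secondary, p.ti, p.tj)
    )

    if not disjoint:
        return candidates[:k_max]
    selected: list[PairFeature] = []
    used: set[float] = set()
    for p in candidates:
        if p.ti in used or p.tj in used:
            continue
        selected.append(p)
        used.update((p.ti, p.tj))
        if len(selected) == k_max:
            break
    return selected


def indicator_matrix(
    features: list[FeatureVector], pairs: list[PairFeature]
) -> PairMatrix:
    """Binary matrix of ``1[X_ti > X_tj]`` per sample × pair (ties → 0)."""
    X, grid, ids = _stack(features)
    cols = []
    for p in pairs:
        i, j = _grid_index(grid, p.ti), _grid_index(grid, p.tj)
        cols.append((X[:, i] > X[:, j]).astype(np.int8))
    ind = (
        np.column_stack(cols) if cols else np.zeros((len(ids), 0), dtype=np.int8)
    )
    return PairMatrix(ids, list(pairs), ind)
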