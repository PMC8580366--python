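"""Sample entropy and histogram Shannon entropy of 1-D amplitude series.

Sample entropy (SampEn) measures the irregularity of a time series as the
negative log of the conditional probability that two subseries (templates)
that match over ``m`` consecutive points, within a Chebyshev tolerance
``r`` times the series standard deviation, still match when extended to
``m + 1`` points. Self-matches are excluded. Periodic signals give values
near zero; uncorrelated noise gives large values.

Conventions fixed here and used throughout the package:

* a "match" is a *strict* inequality, Chebyshev distance < r·σ;
* unordered pairs are counted once (i < j);
* σ is the population (1/N) standard deviation;
* template start indices run over ``0 .. N - m - 1`` so that every counted
  template also has an (m+1)-point extension, which guarantees
  ``a_count <= b_count`` structurally;
* an undefined SampEn (no m-matches, no (m+1)-matches, or a zero-variance
  series) is reported as NaN, not raised.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateSeriesError, ParameterError, SeriesTooShortError

__all__ = [
    "MatchCounts",
    "normalize_series",
    "match_counts",
    "sample_entropy",
    "sample_entropy_from_counts",
    "sample_entropy_grid",
    "shannon_entropy",
]


class MatchCounts(NamedTuple):
    """Template-pair match counts at dimensions m (``b_count``) and m+1 (``a_count``)."""

    b_count: int
    a_count: int


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise SeriesTooShortError(f"series needs at least 2 points, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("series contains non-finite values")
    return arr


def _check_params(n: int, m: int, r: float) -> None:
    if m < 1:
        raise ParameterError(f"dimension m must be >= 1, got {m}")
    if r <= 0:
        raise ParameterError(f"tolerance r must be > 0, got {r}")
    if n < m + 2:
        raise SeriesTooShortError(
            f"series of length {n} too short for m={m} (need at least {m + 2})"
        )


def normalize_series(x) -> np.ndarray:
    """Return ``x`` shifted to mean 0 and scaled to population std 1.

    Raises
    ------
    DegenerateSeriesError
        If the series has zero variance.
    """
    arr = _as_series(x)
    sd = arr.std()
    if sd == 0:
        raise DegenerateSeriesError("zero-variance series cannot be normalized")
    return (arr - arr.mean()) / sd


def _pair_counts_blocked(x: np.ndarray, m: int, r_abs: float, block: int = 512) -> MatchCounts:
    """Count matching template pairs with O(block·N) memory."""
    n = x.size
    t = n - m  # templates with both an m- and an (m+1)-point form
    b = 0
    a = 0
    cols = np.arange(t)
    for i0 in range(0, t, block):
        i1 = min(i0 + block, t)
        dist = np.zeros((i1 - i0, t))
        for k in range(m):
            np.maximum(dist, np.abs(x[i0 + k:i1 + k, None] - x[None, k:t + k]), out=dist)
        upper = cols[None, :] > np.arange(i0, i1)[:, None]
        b += int(np.count_nonzero((dist < r_abs) & upper))
        np.maximum(dist, np.abs(x[i0 + m:i1 + m, None] - x[None, m:t + m]), out=dist)
        a += int(np.count_nonzero((dist < r_abs) & upper))
    return MatchCounts(b, a)


def _template_counts(x: np.ndarray, m: int, r_abs: float, template: int) -> MatchCounts:
    """Counts restricted to pairs that involve one fixed template index."""
    n = x.size
    t = n - m
    if not 0 <= template < t:
        raise ParameterError(f"template index {template} outside 0..{t - 1}")
    dist = np.zeros(t)
    for k in range(m):
        np.maximum(dist, np.abs(x[template + k] - x[k:t + k]), out=dist)
    others = np.arange(t) != template
    b = int(np.count_nonzero((dist < r_abs) & others))
    np.maximum(dist, np.abs(x[template + m] - x[m:t + m]), out=dist)
    a = int(np.count_nonzero((dist < r_abs) & others))
    return MatchCounts(b, a)


def match_counts(x, m: int, r: float, template: int | None = None) -> MatchCounts:
    """Count template pairs matching at dimension m and m+1.

    The tolerance is absolute: ``r_abs = r * population_std(x)``, so passing
    an already-normalized series uses ``r`` directly. With ``template`` given,
    only pairs involving that template start index are counted (the
    single-template illustration of the algorithm); otherwise all unordered
    pairs i < j are counted once.
    """
    arr = _as_series(x)
    _check_params(arr.size, m, r)
    sd = arr.std()
    if sd == 0:
        raise DegenerateSeriesError("zero-variance series has no tolerance scale")
    r_abs = r * sd
    if template is not None:
        return _template_counts(arr, m, r_abs, template)
    return _pair_counts_blocked(arr, m, r_abs)


def sample_entropy_from_counts(counts: MatchCounts) -> float:
    """SampEn = -ln(A/B); NaN when either count is zero (undefined)."""
    b, a = counts
    if b <= 0 or a <= 0:
        return float("nan")
    return float(-np.log(a / b)) + 0.0  # avoid -0.0 when A == B


def sample_entropy(x, m: int = 4, r: float = 0.1) -> float:
    """Sample entropy of a series; NaN marks the undefined/degenerate cases.

    The series is normalized internally (the tolerance ``r`` is a fraction of
    its population standard deviation), making the value invariant under
    affine rescaling of the amplitudes.
    """
    arr = _as_series(x)
    _check_params(arr.size, m, r)
    if arr.std() == 0:
        return float("nan")
    z = normalize_series(arr)
    return sample_entropy_from_counts(_pair_counts_blocked(z, m, r))


def sample_entropy_grid(
    x, m_values: Sequence[int], r_values: Sequence[float]
) -> np.ndarray:
    """Sample entropy over a grid of (m, r) settings in one pass.

    Shares the pairwise Chebyshev distance recursion across all dimensions,
    so a full calibration sweep costs little more than the largest single m.
    Returns an array of shape ``(len(m_values), len(r_values))`` with NaN in
    undefined cells. Used by the calibration sweep.
    """
    arr = _as_series(x)
    m_values = [int(m) for m in m_values]
    r_arr = np.asarray(r_values, dtype=float)
    if np.any(r_arr <= 0):
        raise ParameterError("all tolerance values must be > 0")
    m_max = max(m_values)
    _check_params(arr.size, m_max, float(r_arr.min()))
    if arr.std() == 0:
        return np.full((len(m_values), len(r_arr)), np.nan)
    z = normalize_series(arr)
    n = z.size
    r_max = float(r_arr.max())

    b_counts = np.zeros((len(m_values), r_arr.size), dtype=np.int64)
    a_counts = np.zeros_like(b_counts)
    m_index = {m: i for i, m in enumerate(m_values)}

    dist0 = np.abs(z[:, None] - z[None, :])
    dist = dist0.copy()  # top-left (n-k+1)^2 corner holds the k-template distances

    def _bucket_counts(values: np.ndarray) -> np.ndarray:
        # single bucketing pass instead of a sort: bucket index
        # d = #{r_k <= v}, so v < r_j iff d <= j
        small = values[values < r_max]
        buckets = np.bincount(np.searchsorted(r_arr, small, side="right"),
                              minlength=r_arr.size)
        return np.cumsum(buckets)

    for k in range(1, m_max + 2):
        t_k = n - k + 1  # number of k-length templates
        if k > 1:
            # in-place: element (i,j) reads its own previous value and a
            # shifted dist0 entry, so aliasing the output is safe
            np.maximum(dist[:t_k, :t_k], dist0[k - 1:, k - 1:], out=dist[:t_k, :t_k])
        need_a = (k - 1) in m_index  # (m+1)-templates of m = k-1: all t_k
        need_b = k in m_index        # m-templates restricted to the first n-k
        if not (need_a or need_b):
            continue
        view = dist[:t_k, :t_k]
        # symmetric matrix: count the full block, drop the t_k zero
        # self-match diagonal entries, halve
        full_pairs = (_bucket_counts(view) - t_k) // 2
        if need_a:
            a_counts[m_index[k - 1]] = full_pairs
        if need_b:
            # pairs among the first t_k - 1 templates: remove the last
            # template's row from the full count
            b_counts[m_index[k]] = full_pairs - _bucket_counts(view[t_k - 1, :t_k - 1])

    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log(a_counts / b_counts)
    out[(b_counts == 0) | (a_counts == 0)] = np.nan
    # m values too large for this series stay undefined
    for m, i in m_index.items():
        if n < m + 2:
            out[i, :] = np.nan
    return out


def shannon_entropy(x, n_bins: int = 200) -> float:
    """Histogram Shannon entropy, -sum w log2 w, over equal-width bins.

    Bin edges span ``[min(x), max(x)]`` of the analyzed series; empty bins
    contribute nothing; a constant series returns 0. Result lies in
    ``[0, log2(n_bins)]`` and is invariant under positive affine transforms
    of the amplitudes.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 1:
        raise SeriesTooShortError("empty series")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("series contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(arr, bins=n_bins, range=(lo, hi))
    w = counts[counts > 0] / arr.size
    return float(-np.sum(w * np.log2(w)))
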