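"""Soft discretization of continuous observations via B-spline basis functions.

Instead of dropping each concentration into a single histogram bin, every
observation is spread over up to ``k`` adjacent bins with weights given by
open-uniform B-spline basis functions of order ``k`` over ``M`` bins. The
weights are nonnegative and sum to one, so they behave as bin membership
probabilities and are robust to measurement noise near bin borders.

Conventions
-----------
* Bins are 1-based in every public interface (bin indices in ``[1, M]``).
* The basis is evaluated on the transformed domain ``[0, M - k + 1]``; raw
  values are mapped there linearly using per-metabolite min/max.
* ``k = 1`` degenerates to the ordinary equal-width hard histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "make_knot_vector",
    "bspline_basis",
    "transform_observation",
    "bin_probabilities",
    "bin_cohort",
    "BinnedCohort",
]


def make_knot_vector(M: int, k: int) -> np.ndarray:
    """Open-uniform ("uniform non-periodic") knot vector of length ``M + k + 1``.

    ``t[i] = 0`` for ``i < k``; ``t[i] = i - k + 1`` for ``k <= i <= M - 1``;
    ``t[i] = M - k + 1`` for ``i >= M``. The clamped ends make the first basis
    function equal 1 at the left end of the domain and the last one equal 1 at
    the right end.

    Parameters
    ----------
    M : int
        Number of bins (basis functions), ``M >= 1``.
    k : int
        Spline order (number of bins an observation can occupy), ``1 <= k <= M``.
    """
    if not (isinstance(M, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise TypeError("M and k must be integers")
    if k < 1:
        raise ValueError(f"spline order k must be >= 1, got {k}")
    if k > M:
        raise ValueError(f"spline order k={k} exceeds number of bins M={M}")
    i = np.arange(M + k + 1)
    t = np.where(i < k, 0.0, np.where(i <= M - 1, i - k + 1.0, M - k + 1.0))
    return t


def bspline_basis(i: int, k: int, t: np.ndarray, z: float) -> float:
    """Evaluate the ``i``-th (0-based) B-spline basis function of order ``k`` at ``z``.

    Cox-de Boor recursion with the 0/0 := 0 convention. The right endpoint of
    the domain, ``z = t[-1]``, is defined by the left-limit so that the last
    basis function equals 1 there and the partition of unity holds on the
    closed domain.
    """
    zmax = t[-1]
    if z < t[0] or z > zmax:
        raise ValueError(f"z={z} outside basis domain [{t[0]}, {zmax}]")
    return _cox_de_boor(i, k, t, z, zmax)


def _cox_de_boor(i: int, k: int, t: np.ndarray, z: float, zmax: float) -> float:
    if k == 1:
        # half-open [t_i, t_{i+1}); the right endpoint of the whole domain is
        # closed so the maximum observation lands wholly in the last bin
        if t[i] <= z < t[i + 1]:
            return 1.0
        if z == zmax and t[i] < t[i + 1] and t[i + 1] == zmax:
            return 1.0
        return 0.0
    left = 0.0
    den = t[i + k - 1] - t[i]
    if den > 0.0:
        left = (z - t[i]) / den * _cox_de_boor(i, k - 1, t, z, zmax)
    right = 0.0
    den = t[i + k] - t[i + 1]
    if den > 0.0:
        right = (t[i + k] - z) / den * _cox_de_boor(i + 1, k - 1, t, z, zmax)
    return left + right


def transform_observation(value: float, vmin: float, vmax: float, M: int, k: int) -> float:
    """Map a raw observation into the basis domain ``[0, M - k + 1]``.

    ``z = (value - vmin) / (vmax - vmin) * (M - k + 1)``. A degenerate range
    (``vmax == vmin``, i.e. a constant metabolite) maps to 0, and values
    outside ``[vmin, vmax]`` (held-out samples) are clamped to the domain.
    """
    if vmax < vmin:
        raise ValueError("vmax < vmin")
    span = vmax - vmin
    if span == 0:
        return 0.0
    z = (value - vmin) / span * (M - k + 1)
    return float(np.clip(z, 0.0, M - k + 1))


def bin_probabilities(value: float, vmin: float, vmax: float, M: int, k: int) -> np.ndarray:
    """Probability vector of length ``M`` for one observation.

    Component ``i`` (0-based) is the ``i``-th basis function evaluated at the
    transformed observation; at most ``k`` consecutive components are nonzero
    and the vector sums to 1.
    """
    t = make_knot_vector(M, k)
    z = transform_observation(value, vmin, vmax, M, k)
    return np.array([_cox_de_boor(i, k, t, z, t[-1]) for i in range(M)])


@dataclass
class BinnedCohort:
    """Per-sample, per-metabolite bin probability tensor.

    Attributes
    ----------
    probs : ndarray, shape (n_samples, n_metabolites, M)
        ``probs[s, j, i]`` is the probability that sample ``s``'s observation
        of metabolite ``j`` lies in bin ``i + 1``. Rows sum to 1 over bins.
    ranges : ndarray, shape (n_metabolites, 2)
        The (min, max) used for the linear transform of each metabolite;
        recorded so that held-out samples can be binned consistently.
    M, k : int
        Binning parameters.
    """

    probs: np.ndarray
    ranges: np.ndarray
    M: int
    k: int


def bin_cohort(
    values: np.ndarray,
    M: int,
    k: int,
    ranges: np.ndarray | None = None,
) -> BinnedCohort:
    """Bin an (n_samples, n_metabolites) concentration matrix.

    When ``ranges`` is omitted the per-metabolite min/max of ``values`` (the
    training population) define the transform; pass training ranges to bin
    held-out samples, whose out-of-range values are clamped.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (samples x metabolites)")
    n_samples, n_met = values.shape
    if ranges is None:
        ranges = np.column_stack([values.min(axis=0), values.max(axis=0)])
    else:
        ranges = np.asarray(ranges, dtype=float)
        if ranges.shape != (n_met, 2):
            raise ValueError("ranges must have shape (n_metabolites, 2)")
    t = make_knot_vector(M, k)
    zmax = t[-1]
    probs = np.empty((n_samples, n_met, M))
    for j in range(n_met):
        vmin, vmax = ranges[j]
        for s in range(n_samples):
            z = transform_observation(values[s, j], vmin, vmax, M, k)
            for i in range(M):
                probs[s, j, i] = _cox_de_boor(i, k, t, z, zmax)
    return BinnedCohort(probs=probs, ranges=ranges, M=M, k=k)
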