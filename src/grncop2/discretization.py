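"""Adaptive discretization of expression profiles.

Two thresholds map real-valued expression to the two-state alphabet
{-1 (downregulated), +1 (upregulated)}:

* the target discretization threshold (TDT), a per-gene minimum-variance
  bipartition of the gene's own samples, and
* the relative regulation threshold (RRT), a per-(regulator, target)
  threshold chosen among the regulator's observed values to minimize the
  class entropy of the target's already-discretized states.

The TDT search is the 1-D two-cluster problem: sort the samples, scan every
split position, keep the split with the smallest sum of the two parts'
(population) variances.  Splits that isolate fewer than two samples on either
side are treated as outlier artifacts: a gene whose globally optimal split
violates that cardinality constraint is excluded from inference altogether.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoInformativeThreshold, ValidationError

__all__ = [
    "TdtResult",
    "RrtResult",
    "compute_tdt",
    "partition_entropy",
    "compute_rrt",
    "discretize",
]


@dataclass(frozen=True)
class TdtResult:
    """Outcome of the minimum-variance bipartition of one gene's samples.

    ``split_index`` is the 1-based position e in the sorted array: the lower
    part is L[1..e], the upper part L[e+1..n].  ``excluded`` is True when the
    optimal split leaves fewer than two samples on one side, in which case
    ``threshold`` is None and the gene takes no further part in inference.
    """

    threshold: float | None
    excluded: bool
    split_index: int
    objective: float

    def __post_init__(self) -> None:
        if self.excluded != (self.threshold is None):
            raise ValidationError("excluded=True iff threshold is absent")


@dataclass(frozen=True)
class RrtResult:
    """Optimal relative regulation threshold for one (regulator, target) pair."""

    threshold: float
    entropy: float
    do_size: int
    up_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.entropy <= 1.0 + 1e-12:
            raise ValidationError(f"entropy must lie in [0, 1], got {self.entropy}")
        if self.do_size < 1 or self.up_size < 1:
            raise ValidationError("both sides of the Do/Up partition must be non-empty")


def _as_finite_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def compute_tdt(samples) -> TdtResult:
    """Minimum-variance two-set split of a gene's expression samples.

    Scans all split positions e in 1..n-1 of the sorted sample array and
    minimizes var(L[1..e]) + var(L[e+1..n]) (population variances); ties go
    to the smallest e.  If the optimum isolates a single sample on either
    side the gene is excluded (outlier guard).  Requires at least 4 samples.
    """
    x = _as_finite_1d(samples, "samples")
    n = x.size
    if n < 4:
        raise ValidationError(f"at least 4 samples are required to discretize a gene, got {n}")
    L = np.sort(x)
    best_e = 1
    best_obj = np.inf
    for e in range(1, n):
        obj = float(np.var(L[:e]) + np.var(L[e:]))
        if obj < best_obj:
            best_obj = obj
            best_e = e
    if best_e < 2 or best_e > n - 2:
        return TdtResult(threshold=None, excluded=True, split_index=best_e, objective=best_obj)
    threshold = 0.5 * (L[best_e - 1] + L[best_e])
    return TdtResult(threshold=float(threshold), excluded=False, split_index=best_e, objective=best_obj)


def _binary_entropy(states: np.ndarray) -> float:
    # Shannon entropy (base 2) of the +1/-1 label distribution; H(empty) = 0.
    if states.size == 0:
        return 0.0
    p = np.count_nonzero(states == 1) / states.size
    q = 1.0 - p
    h = 0.0
    if p > 0.0:
        h -= p * np.log2(p)
    if q > 0.0:
        h -= q * np.log2(q)
    return float(h)


def partition_entropy(regulator_values, target_states, t: float) -> float:
    """Weighted class entropy of the target states under the Do/Up split at t.

    Do holds the samples where the regulator's value is <= t, Up those where
    it is > t.  Returns (|Do|/N) H(Do) + (|Up|/N) H(Up), with H the binary
    entropy of the target-state labels inside each side.  0 means each side
    is label-pure (ideal predictive split); 1 means both sides are 50/50.
    """
    r = _as_finite_1d(regulator_values, "regulator_values")
    s = np.asarray(target_states, dtype=int)
    if r.size != s.size:
        raise ValidationError(
            f"regulator values and target states differ in length ({r.size} vs {s.size})"
        )
    if r.size == 0:
        raise ValidationError("at least one sample is required")
    do_mask = r <= t
    n = r.size
    do = s[do_mask]
    up = s[~do_mask]
    return (do.size / n) * _binary_entropy(do) + (up.size / n) * _binary_entropy(up)


def compute_rrt(regulator_values, target_states) -> RrtResult:
    """Select the regulator threshold minimizing the partition entropy.

    Candidate thresholds are the distinct observed regulator values; any
    candidate leaving Do or Up empty is skipped (the maximum value always
    empties Up).  Ties are broken toward the smallest threshold value.
    Raises :class:`NoInformativeThreshold` when every candidate is
    degenerate, i.e. the regulator profile is constant.
    """
    r = _as_finite_1d(regulator_values, "regulator_values")
    s = np.asarray(target_states, dtype=int)
    if r.size != s.size:
        raise ValidationError(
            f"regulator values and target states differ in length ({r.size} vs {s.size})"
        )
    if r.size < 4:
        raise ValidationError(f"at least 4 aligned samples are required, got {r.size}")
    best: RrtResult | None = None
    for t in np.unique(r):  # ascending, so first strict improvement = smallest tie-winner
        do_size = int(np.count_nonzero(r <= t))
        up_size = r.size - do_size
        if do_size == 0 or up_size == 0:
            continue
        h = partition_entropy(r, s, float(t))
        if best is None or h < best.entropy:
            best = RrtResult(threshold=float(t), entropy=h, do_size=do_size, up_size=up_size)
    if best is None:
        raise NoInformativeThreshold(
            "constant regulator profile: no candidate threshold yields a non-empty partition"
        )
    return best


def discretize(values, threshold: float) -> np.ndarray:
    """Map expression values to states: +1 where value > threshold, else -1."""
    x = _as_finite_1d(values, "values")
    return np.where(x > threshold, 1, -1).astype(np.int8)
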