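"""Cross-dataset rule consensus and the regulatory-delay window bound.

Running the same inference on K independent time-series datasets yields K
per-delay rule sets.  The consensus step intersects them component-wise
(per delay): a rule — identified by its full statement (regulator, target,
delay, rule type) — survives iff it was found in at least ceil(rca * K)
datasets, where the rule consensus accuracy (RCA) parameter in (0, 1] sets
the minimum supporting fraction.  Datasets are unweighted, and the accuracy
carried by a surviving rule is the minimum score across its supporting
datasets (the most conservative choice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .rules import RULE_TYPES, Rule, format_rule

__all__ = [
    "ConsensusRule",
    "ConsensusRuleSet",
    "support_threshold",
    "consensus",
    "compute_max_delay",
]


@dataclass(frozen=True)
class ConsensusRule:
    """A rule surviving consensus, with its support count and minimum score."""

    regulator: str
    target: str
    delay: int
    rule_type: int
    score: float
    support: int

    def __post_init__(self) -> None:
        if self.rule_type not in RULE_TYPES:
            raise ValidationError(f"rule_type must be non-zero in -3..3, got {self.rule_type}")
        if self.support < 1:
            raise ValidationError("support must be at least 1")

    @property
    def identity(self) -> tuple[str, str, int, int]:
        return (self.regulator, self.target, self.delay, self.rule_type)

    def rule_string(self) -> str:
        return format_rule(self.regulator, self.delay, self.target, self.rule_type)


@dataclass
class ConsensusRuleSet:
    rules: list[ConsensusRule] = field(default_factory=list)
    k_total: int = 1
    rca: float = 1.0

    def __post_init__(self) -> None:
        if self.k_total < 1:
            raise ValidationError("k_total must be at least 1")
        if not 0.0 < self.rca <= 1.0:
            raise ValidationError(f"rca must lie in (0, 1], got {self.rca}")

    @property
    def support_threshold(self) -> int:
        return support_threshold(self.k_total, self.rca)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def by_delay(self) -> dict[int, list[ConsensusRule]]:
        out: dict[int, list[ConsensusRule]] = {}
        for r in self.rules:
            out.setdefault(r.delay, []).append(r)
        return out


def support_threshold(k_total: int, rca: float) -> int:
    """Minimum number of supporting datasets: ceil(rca * k_total), at least 1.

    The "at least" semantics: e.g. with 10 datasets and rca = 0.60 a rule
    must predict well in at least 6 of them, no matter which ones.
    """
    if k_total < 1:
        raise ValidationError("k_total must be at least 1")
    if not 0.0 < rca <= 1.0:
        raise ValidationError(f"rca must lie in (0, 1], got {rca}")
    # epsilon guards against binary representation of rca (never alters exact cases)
    return max(1, math.ceil(rca * k_total - 1e-12))


def consensus(per_dataset_rules: Sequence[Iterable[Rule]], rca: float) -> ConsensusRuleSet:
    """Intersect per-dataset rule sets under the RCA support threshold.

    ``per_dataset_rules`` holds one iterable of rules per dataset (rules
    carry their own delay, so the per-delay intersection is implicit in the
    rule identity).  Duplicate statements within one dataset count once.
    """
    if not 0.0 < rca <= 1.0:
        raise ValidationError(f"rca must lie in (0, 1], got {rca}")
    k = len(per_dataset_rules)
    if k == 0:
        raise ValidationError("at least one dataset's rules are required")
    threshold = support_threshold(k, rca)
    seen: dict[tuple[str, str, int, int], list[float]] = {}
    for dataset_rules in per_dataset_rules:
        best_in_dataset: dict[tuple[str, str, int, int], float] = {}
        for rule in dataset_rules:
            key = rule.identity
            prev = best_in_dataset.get(key)
            if prev is None or rule.score > prev:
                best_in_dataset[key] = rule.score
        for key, score in best_in_dataset.items():
            seen.setdefault(key, []).append(score)
    kept = [
        ConsensusRule(
            regulator=key[0],
            target=key[1],
            delay=key[2],
            rule_type=key[3],
            score=min(scores),
            support=len(scores),
        )
        for key, scores in seen.items()
        if len(scores) >= threshold
    ]
    kept.sort(key=lambda r: (r.delay, r.target, r.regulator, r.rule_type))
    return ConsensusRuleSet(rules=kept, k_total=k, rca=rca)


def compute_max_delay(
    delta_t_hypothesis: float,
    sampling_intervals: Sequence[float],
    sample_counts: Sequence[int],
) -> int:
    """Delay window implied by a regulatory-delay hypothesis.

    W = min( floor(delta_t_hypothesis / min(sampling_intervals)),
             min(sample_counts) - 4 ),
    i.e. the hypothesized maximum regulatory delay (minutes) divided by the
    finest sampling interval, capped by the widest window the shortest
    dataset can support.  A partial sampling step cannot be inferred, hence
    the floor.
    """
    if delta_t_hypothesis < 0:
        raise ValidationError("delta_t_hypothesis must be non-negative")
    if not sampling_intervals or not sample_counts:
        raise ValidationError("sampling intervals and sample counts must be non-empty")
    if any(dt <= 0 for dt in sampling_intervals):
        raise ValidationError("sampling intervals must be positive")
    if any(m < 5 for m in sample_counts):
        raise ValidationError("every dataset needs at least 5 time points")
    ratio = math.floor(delta_t_hypothesis / min(sampling_intervals))
    return min(ratio, min(sample_counts) - 4)
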