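"""Time-lagged regulation rules and their textual syntax.

A rule states how the discrete state of a regulator gene at time-point j
predicts the state of a target gene at time-point j + w, where w >= 0 is the
delay in sampling units.  Seven integer codes describe the logical form of the
relationship; code 0 means "no interaction" and is never emitted as a rule:

====  ==========================================================
code  reading
====  ==========================================================
  1   regulator above threshold <=> target upregulated
 -1   regulator above threshold <=> target downregulated
  2   regulator above threshold  => target upregulated
  3   regulator at/below threshold => target downregulated
 -2   regulator at/below threshold => target upregulated
 -3   regulator above threshold  => target downregulated
====  ==========================================================

The two-sided codes (+/-1) constrain every sample; the one-sided codes
(+/-2, +/-3) constrain only the samples on one side of the regulator
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Rule-type codes eligible for emission (0 excluded).
RULE_TYPES: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)

# (left symbol for the regulator premise, right symbol for the target outcome)
_SYMBOLS: dict[int, tuple[str, str]] = {
    1: ("+/-", "+/-"),
    -1: ("+/-", "-/+"),
    2: ("+", "+"),
    3: ("-", "-"),
    -2: ("-", "+"),
    -3: ("+", "-"),
}


def format_rule(regulator: str, delay: int, target: str, rule_type: int) -> str:
    """Render a rule in the standard arrow syntax, e.g. ``+/- CLB1 3 -> +/- CLB5``."""
    if rule_type not in _SYMBOLS:
        raise ValidationError(f"rule_type must be a non-zero code in -3..3, got {rule_type}")
    left, right = _SYMBOLS[rule_type]
    return f"{left} {regulator} {delay} -> {right} {target}"


@dataclass(frozen=True, order=True)
class Rule:
    """One inferred time-lagged relationship in a single dataset.

    ``score`` is the value of the performance function sigma in [0, 1]: the
    product of positive and negative predictive value for two-sided types,
    a single predictive value for one-sided types.
    """

    regulator: str
    target: str
    delay: int
    rule_type: int
    score: float

    def __post_init__(self) -> None:
        if self.rule_type not in RULE_TYPES:
            raise ValidationError(f"rule_type must be non-zero in -3..3, got {self.rule_type}")
        if self.delay < 0:
            raise ValidationError(f"delay must be non-negative, got {self.delay}")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score must lie in [0, 1], got {self.score}")

    @property
    def identity(self) -> tuple[str, str, int, int]:
        """Rule identity used for cross-dataset intersection (score excluded)."""
        return (self.regulator, self.target, self.delay, self.rule_type)

    def rule_string(self) -> str:
        return format_rule(self.regulator, self.delay, self.target, self.rule_type)
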