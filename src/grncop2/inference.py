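"""Per-dataset, per-delay rule inference via gene-profile classifiers.

For a fixed target gene and delay w, the gene-profile classifier assigns to
every candidate regulator one of the seven rule-type codes.  Because rules
are pairwise, each component can be optimized independently: for every
regulator all six non-zero rule types are scored with the performance
function and the best survivor above the accuracy cutoff is kept; everything
else is type 0 (no interaction).

Time-lagged alignment pairs regulator sample j with target sample j + w by
dropping the first w target samples and the last w regulator samples, so the
aligned length is m - w.  Since a valid target discretization needs at least
4 samples, the delay window is bounded by W <= m - 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretization import TdtResult, compute_rrt, compute_tdt, discretize
from .errors import NoInformativeThreshold, ValidationError
from .io_expression import ExpressionDataset
from .rules import RULE_TYPES, Rule

__all__ = [
    "InferenceParams",
    "ConfusionCounts",
    "RegulatorAssignment",
    "ClassifierProfile",
    "DatasetInference",
    "align_lagged",
    "confusion_counts",
    "score_rule",
    "best_rule_type",
    "infer_profile",
    "infer_rules_dataset",
]

#: Candidate evaluation order; earlier wins score ties (two-sided rules are
#: strictly more informative, positive codes before negative).
_CANDIDATE_ORDER = (1, -1, 2, 3, -2, -3)


@dataclass(frozen=True)
class InferenceParams:
    """Tunable knobs of the rule search.

    ``accuracy`` is the minimum performance score a rule must reach;
    ``scp`` (sample coverage percentage) the minimum TP (TN) fraction of the
    aligned samples that a one-sided rule (types +/-2, +/-3) must cover;
    ``max_delay`` the largest delay W scanned.  Defaults follow the
    recommended operating point: accuracy 0.75, scp 0.95.
    """

    accuracy: float = 0.75
    scp: float = 0.95
    max_delay: int = 0
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy <= 1.0:
            raise ValidationError(f"accuracy must lie in (0, 1], got {self.accuracy}")
        if not 0.0 < self.scp <= 1.0:
            raise ValidationError(f"scp must lie in (0, 1], got {self.scp}")
        if self.max_delay < 0:
            raise ValidationError(f"max_delay must be non-negative, got {self.max_delay}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RegulatorAssignment:
    """One component of a classifier profile: the rule type chosen for a regulator."""

    rule_type: int
    score: float
    rrt_threshold: float | None


@dataclass
class ClassifierProfile:
    """The optimized classifier for one target at one delay in one dataset."""

    target: str
    delay: int
    dataset: str
    assignments: dict[str, RegulatorAssignment] = field(default_factory=dict)

    def rules(self) -> list[Rule]:
        return [
            Rule(regulator=r, target=self.target, delay=self.delay,
                 rule_type=a.rule_type, score=a.score)
            for r, a in self.assignments.items()
            if a.rule_type != 0
        ]


@dataclass
class DatasetInference:
    """All rules found in one dataset, grouped by delay, plus TDT exclusions."""

    name: str
    max_delay: int
    rules_by_delay: dict[int, list[Rule]]
    excluded_by_delay: dict[int, list[str]]

    def all_rules(self) -> list[Rule]:
        return [r for w in sorted(self.rules_by_delay) for r in self.rules_by_delay[w]]


def align_lagged(regulator_values, target_values, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Realign two profiles so regulator sample j is paired with target sample j + w.

    Drops the last w regulator samples and the first w target samples; both
    returned arrays have length m - w.  Requires 0 <= w <= m - 4.
    """
    reg = np.asarray(regulator_values, dtype=float)
    tgt = np.asarray(target_values, dtype=float)
    if reg.size != tgt.size:
        raise ValidationError("regulator and target profiles differ in length")
    m = reg.size
    if w < 0:
        raise ValidationError(f"delay must be non-negative, got {w}")
    if w > m - 4:
        raise ValidationError(f"delay {w} exceeds the window bound m - 4 = {m - 4}")
    if w == 0:
        return reg, tgt
    return reg[:-w], tgt[w:]


def confusion_counts(reg_states, tgt_states, c: int) -> ConfusionCounts:
    """Tally the confusion matrix of a rule of type ``c`` over aligned state pairs.

    With N(a, b) the number of positions where the regulator state is a and
    the target state is b, the positives of a rule are the samples matching
    its "+"-side premise and the negatives those matching its "-"-side
    premise; one-sided types use only the factor named by their premise.
    """
    r = np.asarray(reg_states, dtype=int)
    t = np.asarray(tgt_states, dtype=int)
    if r.size != t.size:
        raise ValidationError("state vectors differ in length")
    if c == 0:
        raise ValidationError("confusion counts are undefined for rule type 0")
    if c not in RULE_TYPES:
        raise ValidationError(f"unknown rule type {c}")
    npp = int(np.count_nonzero((r == 1) & (t == 1)))
    npm = int(np.count_nonzero((r == 1) & (t == -1)))
    nmp = int(np.count_nonzero((r == -1) & (t == 1)))
    nmm = int(np.count_nonzero((r == -1) & (t == -1)))
    if c in (1, 2, 3):
        return ConfusionCounts(tp=npp, fp=npm, tn=nmm, fn=nmp)
    if c == -1:
        return ConfusionCounts(tp=npm, fp=npp, tn=nmp, fn=nmm)
    if c == -3:
        return ConfusionCounts(tp=npm, fp=npp, tn=nmm, fn=nmp)
    # c == -2
    return ConfusionCounts(tp=npm, fp=npp, tn=nmp, fn=nmm)


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def score_rule(counts: ConfusionCounts, c: int, n_samples: int, scp: float) -> tuple[float, bool]:
    """Performance score of a rule of type ``c`` plus its sample-coverage verdict.

    Two-sided types (+/-1) score as positive predictive value times negative
    predictive value and always pass coverage.  One-sided types use the
    single predictive value named by their premise and must cover at least an
    ``scp`` fraction of the ``n_samples`` aligned samples with TP (types 2,
    -3) or TN (types 3, -2).  Any 0/0 factor scores 0.
    """
    if c == 0 or c not in RULE_TYPES:
        raise ValidationError(f"rule type must be non-zero in -3..3, got {c}")
    if c in (1, -1):
        score = _ratio(counts.tp, counts.tp + counts.fp) * _ratio(counts.tn, counts.tn + counts.fn)
        return score, True
    if c in (2, -3):
        return _ratio(counts.tp, counts.tp + counts.fp), _ratio(counts.tp, n_samples) >= scp
    # c in (3, -2)
    return _ratio(counts.tn, counts.tn + counts.fn), _ratio(counts.tn, n_samples) >= scp


def best_rule_type(reg_states, tgt_states, params: InferenceParams) -> tuple[int, float]:
    """Independently score all six rule types and return the best survivor.

    Candidates failing the coverage requirement (one-sided types) or scoring
    below the accuracy cutoff are discarded; if none survives, the result is
    (0, 0.0), i.e. no interaction.
    """
    r = np.asarray(reg_states, dtype=int)
    t = np.asarray(tgt_states, dtype=int)
    if r.size != t.size:
        raise ValidationError("state vectors differ in length")
    if r.size < 4:
        raise ValidationError(f"at least 4 aligned samples are required, got {r.size}")
    best_c, best_score = 0, 0.0
    for c in _CANDIDATE_ORDER:
        counts = confusion_counts(r, t, c)
        score, passes = score_rule(counts, c, r.size, params.scp)
        if not passes or score < params.accuracy:
            continue
        if score > best_score:
            best_c, best_score = c, score
    return best_c, best_score


def infer_profile(
    ds: ExpressionDataset,
    target: str,
    w: int,
    params: InferenceParams,
    tdt: TdtResult,
) -> ClassifierProfile:
    """Build the optimal classifier profile for one target at delay ``w``.

    The target's states come from its TDT on samples w+1..m; each candidate
    regulator gets its own relative regulation threshold computed on samples
    1..m-w against those states, and is then assigned the best rule type.
    Regulators with no informative threshold (constant profiles) are type 0.
    Self-pairing is skipped except, optionally, at w >= 1.
    """
    if tdt.excluded:
        raise ValidationError(f"target {target!r} is excluded by its TDT at delay {w}")
    m = ds.n_timepoints
    if m - w < 4:
        raise ValidationError(f"delay {w} leaves fewer than 4 aligned samples")
    tgt_values = ds.row(target)
    tgt_states = discretize(tgt_values[w:], tdt.threshold)
    profile = ClassifierProfile(target=target, delay=w, dataset=ds.name)
    for i, reg in enumerate(ds.genes):
        if reg == target and not (params.allow_self_loops and w >= 1):
            continue
        reg_aligned = ds.values[i][: m - w] if w else ds.values[i]
        try:
            rrt = compute_rrt(reg_aligned, tgt_states)
        except NoInformativeThreshold:
            profile.assignments[reg] = RegulatorAssignment(0, 0.0, None)
            continue
        reg_states = discretize(reg_aligned, rrt.threshold)
        c, score = best_rule_type(reg_states, tgt_states, params)
        profile.assignments[reg] = RegulatorAssignment(c, score, rrt.threshold)
    return profile


def infer_rules_dataset(ds: ExpressionDataset, params: InferenceParams) -> DatasetInference:
    """Run the full per-delay rule search over one complete dataset.

    For each delay w in 0..W the target discretization thresholds are
    recomputed on samples w+1..m; targets whose optimal split is degenerate
    are excluded at that delay and recorded.  Every non-zero classifier
    component is emitted as a rule.
    """
    if not ds.is_complete:
        raise ValidationError(
            f"dataset {ds.name!r} has {ds.n_missing} missing value(s); impute first"
        )
    m = ds.n_timepoints
    if params.max_delay > m - 4:
        raise ValidationError(
            f"max_delay {params.max_delay} exceeds the window bound m - 4 = {m - 4} "
            f"for dataset {ds.name!r}"
        )
    rules_by_delay: dict[int, list[Rule]] = {}
    excluded_by_delay: dict[int, list[str]] = {}
    for w in range(params.max_delay + 1):
        rules_w: list[Rule] = []
        excluded_w: list[str] = []
        for i, target in enumerate(ds.genes):
            tdt = compute_tdt(ds.values[i][w:])
            if tdt.excluded:
                excluded_w.append(target)
                continue
            profile = infer_profile(ds, target, w, params, tdt)
            rules_w.extend(profile.rules())
        rules_by_delay[w] = rules_w
        excluded_by_delay[w] = excluded_w
    return DatasetInference(
        name=ds.name,
        max_delay=params.max_delay,
        rules_by_delay=rules_by_delay,
        excluded_by_delay=excluded_by_delay,
    )
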