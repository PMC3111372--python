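"""Synthetic multi-dataset time series with planted time-lagged rules.

The generator emulates the structure the inference pipeline is built for:
K replicate datasets over a shared gene list, each gene a two-level signal
(a low and a high expression level around the gene's own latent threshold)
plus Gaussian noise, with a chosen set of lagged pairwise rules planted into
the state sequences.  Two-level signals (rather than, e.g., sinusoids) keep
the planted discretization thresholds analytically known: at zero noise the
target discretization threshold recovered from data equals the gene's latent
threshold exactly, and each regulator's relative threshold is its low level.

Ground truth is returned alongside the data, so recovery tests can measure
precision and sensitivity of inferred rules against the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_expression import ExpressionDataset
from .rules import RULE_TYPES
from .evaluation import Pair, canonical_pair

__all__ = ["PlantedRule", "SyntheticTruth", "default_planted", "generate"]

_MAX_ATTEMPTS = 500


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth rule: regulator state at time j fixes target state at j + delay.

    ``fidelity`` is the fraction of constrained aligned samples that obey the
    rule; at fidelity 1 the rule is classifiable with score 1 at the planted
    thresholds.  Thresholds are filled in by the generator.
    """

    regulator: str
    target: str
    delay: int
    rule_type: int
    regulator_threshold: float | None = None
    target_threshold: float | None = None
    fidelity: float = 1.0

    def __post_init__(self) -> None:
        if self.rule_type not in RULE_TYPES:
            raise ValidationError(f"rule_type must be non-zero in -3..3, got {self.rule_type}")
        if self.delay < 0:
            raise ValidationError("delay must be non-negative")
        if not 0.0 < self.fidelity <= 1.0:
            raise ValidationError(f"fidelity must lie in (0, 1], got {self.fidelity}")

    @property
    def pair(self) -> Pair:
        return canonical_pair(self.regulator, self.target)


@dataclass
class SyntheticTruth:
    """Generated datasets plus the ground truth that produced them."""

    datasets: list[ExpressionDataset]
    rules: list[PlantedRule]
    seed: int
    noise_sd: float = 0.0
    margin: float = 0.5
    gene_thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.datasets[0].genes

    def pairs(self) -> set[Pair]:
        return {r.pair for r in self.rules}


def default_planted(genes: Sequence[str]) -> list[PlantedRule]:
    """Five two-sided rules spanning delays 0-3 over disjoint gene pairs.

    Only two-sided (+/-1) types are planted by default: with balanced
    regulator states, one-sided rules cover about half the samples and can
    never satisfy a sample-coverage requirement near 1, so they are not
    recoverable under the recommended operating point.
    """
    if len(genes) < 10:
        raise ValidationError("the default planted set needs at least 10 genes")
    g = list(genes)
    return [
        PlantedRule(regulator=g[0], target=g[1], delay=0, rule_type=1),
        PlantedRule(regulator=g[2], target=g[3], delay=1, rule_type=-1),
        PlantedRule(regulator=g[4], target=g[5], delay=2, rule_type=1),
        PlantedRule(regulator=g[6], target=g[7], delay=3, rule_type=-1),
        PlantedRule(regulator=g[8], target=g[9], delay=3, rule_type=1),
    ]


def _balanced_states(rng: np.random.Generator, m: int) -> np.ndarray:
    # resample until both states occur at least twice (cheap for m >= 8)
    while True:
        s = rng.choice(np.array([-1, 1], dtype=np.int8), size=m)
        if np.count_nonzero(s == 1) >= 2 and np.count_nonzero(s == -1) >= 2:
            return s


def _apply_rule(
    rng: np.random.Generator,
    states: np.ndarray,
    gene_index: dict[str, int],
    rule: PlantedRule,
) -> None:
    m = states.shape[1]
    w = rule.delay
    reg = states[gene_index[rule.regulator]]
    tgt = states[gene_index[rule.target]]
    for j in range(m - w):
        r = reg[j]
        if rule.rule_type == 1:
            forced = r
        elif rule.rule_type == -1:
            forced = -r
        elif rule.rule_type == 2:
            forced = 1 if r == 1 else None
        elif rule.rule_type == 3:
            forced = -1 if r == -1 else None
        elif rule.rule_type == -3:
            forced = -1 if r == 1 else None
        else:  # -2
            forced = 1 if r == -1 else None
        if forced is None:
            continue
        if rng.random() >= rule.fidelity:
            forced = -forced
        tgt[j + w] = forced


def _feasible(states: np.ndarray, gene_index: dict[str, int], planted: list[PlantedRule]) -> bool:
    # every gene balanced overall; planted windows balanced on both ends so
    # the TDT never excludes the target and the regulator stays informative
    m = states.shape[1]
    for row in states:
        if np.count_nonzero(row == 1) < 2 or np.count_nonzero(row == -1) < 2:
            return False
    for rule in planted:
        w = rule.delay
        tgt_win = states[gene_index[rule.target]][w:]
        reg_win = states[gene_index[rule.regulator]][: m - w]
        for win in (tgt_win, reg_win):
            if np.count_nonzero(win == 1) < 2 or np.count_nonzero(win == -1) < 2:
                return False
    return True


def generate(
    n_genes: int = 12,
    m_timepoints: int = 20,
    k_datasets: int = 3,
    planted: list[PlantedRule] | None = None,
    noise_sd: float = 0.0,
    state_flip_prob: float = 0.0,
    seed: int = 0,
    margin: float = 0.5,
    plant_in_datasets: Sequence[int] | None = None,
) -> SyntheticTruth:
    """Generate K replicate datasets with the given rules planted.

    Each gene g has a latent threshold theta_g (shared across datasets) and
    expresses at theta_g +/- ``margin`` according to its state, plus
    N(0, noise_sd) noise; discretization is recoverable from data whenever
    noise_sd < margin / 4.  State sequences are drawn independently per
    dataset, targets are overwritten at the planted delays per rule type and
    corrupted with probability 1 - fidelity, and every state entry is then
    flipped with probability ``state_flip_prob``.  ``plant_in_datasets``
    restricts planting to the given dataset indices (default: all), which
    lets consensus tests plant a rule in only a subset of replicates.
    Regeneration with the same arguments is bit-identical.
    """
    if n_genes < 2:
        raise ValidationError("at least 2 genes are required")
    if m_timepoints < 8:
        raise ValidationError("at least 8 time points are required")
    if k_datasets < 1:
        raise ValidationError("at least 1 dataset is required")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if not 0.0 <= state_flip_prob < 0.5:
        raise ValidationError("state_flip_prob must lie in [0, 0.5)")
    if margin <= 0:
        raise ValidationError("margin must be positive")
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    if planted is None:
        planted = default_planted(genes)
    for rule in planted:
        if rule.regulator not in gene_index or rule.target not in gene_index:
            raise ValidationError(f"planted rule references unknown gene(s): {rule}")
        if rule.delay > m_timepoints - 4:
            raise ValidationError(
                f"planted delay {rule.delay} exceeds the window bound m - 4 = {m_timepoints - 4}"
            )
    plant_in = set(range(k_datasets)) if plant_in_datasets is None else set(plant_in_datasets)
    if not plant_in <= set(range(k_datasets)):
        raise ValidationError("plant_in_datasets indices out of range")

    rng = np.random.default_rng(seed)
    thresholds = {g: float(t) for g, t in zip(genes, rng.uniform(-0.5, 0.5, size=n_genes))}
    levels_lo = np.array([thresholds[g] - margin for g in genes])
    levels_hi = np.array([thresholds[g] + margin for g in genes])

    datasets: list[ExpressionDataset] = []
    timepoints = [f"T{j + 1:02d}" for j in range(m_timepoints)]
    for k in range(k_datasets):
        planted_here = planted if k in plant_in else []
        for _ in range(_MAX_ATTEMPTS):
            states = np.vstack([_balanced_states(rng, m_timepoints) for _ in range(n_genes)])
            for rule in planted_here:
                _apply_rule(rng, states, gene_index, rule)
            if state_flip_prob > 0.0:
                flips = rng.random(states.shape) < state_flip_prob
                states = np.where(flips, -states, states)
            if _feasible(states, gene_index, planted_here):
                break
        else:
            raise ValidationError(
                "could not draw balanced state sequences for the planted rules; "
                "increase m_timepoints or relax the planted set"
            )
        values = np.where(states == 1, levels_hi[:, None], levels_lo[:, None])
        if noise_sd > 0.0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        datasets.append(
            ExpressionDataset(
                name=f"synthetic_k{k + 1}",
                genes=list(genes),
                timepoints=list(timepoints),
                values=values.astype(float),
            )
        )

    rules = [
        replace(
            r,
            regulator_threshold=thresholds[r.regulator],
            target_threshold=thresholds[r.target],
        )
        for r in planted
    ]
    return SyntheticTruth(
        datasets=datasets,
        rules=rules,
        seed=seed,
        noise_sd=noise_sd,
        margin=margin,
        gene_thresholds=thresholds,
    )
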