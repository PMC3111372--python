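"""Benchmarking inferred rules against scored reference gene-pair sets.

Reference resources (functional-linkage networks, shared-annotation pair
sets, literature co-citation) record undirected gene-gene associations with
no delay and no regulator/target orientation.  To compare fairly, inferred
rule sets are first projected onto undirected gene pairs — collapsing
delays, directions and rule types — and then scored with precision,
sensitivity and specificity over the pairwise search space of the analysis
universe (n genes give n(n-1)/2 possible pairs), plus the mean reference
score of the matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import ValidationError

__all__ = [
    "ReferencePairSet",
    "PairMetrics",
    "canonical_pair",
    "project_pairs",
    "pair_metrics",
    "read_reference_pairs",
    "read_gene_list",
]

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Order-free representation of a gene pair; self-pairs are invalid."""
    if a == b:
        raise ValidationError(f"self-pair {a!r} is not a valid gene association")
    return (a, b) if a < b else (b, a)


@dataclass
class ReferencePairSet:
    """A benchmark set of undirected gene pairs, optionally scored.

    Higher scores denote stronger associations.  Pairs are stored
    canonically; self-pairs are rejected.
    """

    pairs: set[Pair] = field(default_factory=set)
    scores: dict[Pair, float] | None = None

    def __post_init__(self) -> None:
        self.pairs = {canonical_pair(*p) for p in self.pairs}
        if self.scores is not None:
            self.scores = {canonical_pair(*p): float(s) for p, s in self.scores.items()}
            missing = self.pairs - set(self.scores)
            if missing:
                raise ValidationError(f"{len(missing)} reference pair(s) lack a score")

    def restrict(self, genes: set[str]) -> "ReferencePairSet":
        keep = {p for p in self.pairs if p[0] in genes and p[1] in genes}
        scores = None
        if self.scores is not None:
            scores = {p: self.scores[p] for p in keep}
        return ReferencePairSet(pairs=keep, scores=scores)


@dataclass(frozen=True)
class PairMetrics:
    precision: float
    sensitivity: float
    specificity: float
    average_score: float
    average_score_all_predicted: float
    n_predicted: int
    n_reference: int
    n_universe_pairs: int
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "average_score": self.average_score,
            "average_score_all_predicted": self.average_score_all_predicted,
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
            "n_universe_pairs": self.n_universe_pairs,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def project_pairs(rules: Iterable) -> set[Pair]:
    """Collapse a rule set onto undirected gene pairs.

    Each rule contributes the unordered pair {regulator, target}; duplicates
    arising from different delays, directions or rule types merge, and
    self-loops are dropped.  This is the convention under which rule sets are
    compared against reference pair sets, avoiding repeated validation of
    multiple rules through the same benchmark match.
    """
    pairs: set[Pair] = set()
    for rule in rules:
        if rule.regulator == rule.target:
            continue
        pairs.add(canonical_pair(rule.regulator, rule.target))
    return pairs


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def pair_metrics(
    predicted: set[Pair],
    reference: ReferencePairSet,
    universe: Iterable[str],
) -> PairMetrics:
    """Precision, sensitivity, specificity and average score over a gene universe.

    Both the predicted and the reference pairs are restricted to the
    universe before counting.  True negatives are taken over all
    n(n-1)/2 universe pairs.  ``average_score`` averages reference scores
    over matched (predicted and in the reference) pairs only;
    ``average_score_all_predicted`` divides the same total by all predicted
    pairs, counting unmatched predictions as 0.  All 0/0 ratios are 0.
    """
    genes = sorted(set(universe))
    if not genes:
        raise ValidationError("the gene universe is empty")
    gene_set = set(genes)
    n = len(genes)
    n_universe = n * (n - 1) // 2
    pred = {canonical_pair(*p) for p in predicted if p[0] in gene_set and p[1] in gene_set}
    ref = reference.restrict(gene_set)
    tp_pairs = pred & ref.pairs
    tp = len(tp_pairs)
    fp = len(pred) - tp
    fn = len(ref.pairs) - tp
    tn = n_universe - tp - fp - fn
    total_score = 0.0
    if ref.scores is not None:
        total_score = sum(ref.scores[p] for p in tp_pairs)
    return PairMetrics(
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        average_score=_ratio(total_score, tp),
        average_score_all_predicted=_ratio(total_score, len(pred)),
        n_predicted=len(pred),
        n_reference=len(ref.pairs),
        n_universe_pairs=n_universe,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def read_reference_pairs(path) -> ReferencePairSet:
    """Read a reference pair TSV with columns gene_a, gene_b and optional score.

    Self-pairs are dropped; for duplicated pairs the highest score wins.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_a" not in cols or "gene_b" not in cols:
        raise ValidationError("reference file must have gene_a and gene_b columns")
    has_score = "score" in cols
    pairs: set[Pair] = set()
    scores: dict[Pair, float] = {}
    for row in df.itertuples(index=False):
        a = str(getattr(row, cols["gene_a"]))
        b = str(getattr(row, cols["gene_b"]))
        if a == b:
            continue
        p = canonical_pair(a, b)
        pairs.add(p)
        if has_score:
            s = float(getattr(row, cols["score"]))
            scores[p] = max(s, scores.get(p, s))
    return ReferencePairSet(pairs=pairs, scores=scores if has_score else None)


def read_gene_list(path) -> list[str]:
    """Read a gene universe: one identifier per line, blanks ignored."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValidationError("the gene universe file is empty")
    return genes
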