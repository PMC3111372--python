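"""Reading, writing and harmonization of expression matrices and rule tables.

The expression format is a plain tab-separated matrix: first column gene
identifiers, first row time-point labels, cells numeric (log-ratio scale) or
a missing token (``NA`` or empty).  Columns must already be in true temporal
order and equidistant; this module never reorders or resamples them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ConsensusRule, ConsensusRuleSet
from .errors import ParseError, ValidationError
from .rules import format_rule

__all__ = [
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "impute_missing",
    "intersect_genes",
    "write_rules",
    "read_rules",
]

MISSING_TOKENS = ("", "NA")

#: Minimum number of time points: one delay-0 inference needs 4 aligned
#: samples, plus margin so that at least one lag is conceivable.
MIN_TIMEPOINTS = 5


@dataclass
class ExpressionDataset:
    """One gene-expression time series: an n-genes x m-time-points real matrix.

    ``values`` uses NaN for missing entries.  ``sampling_interval`` is the
    time between consecutive columns in minutes, used only for converting a
    regulatory-delay hypothesis into a delay window; it never alters data.
    """

    name: str
    genes: list[str]
    timepoints: list[str]
    values: np.ndarray
    sampling_interval: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.timepoints)):
            raise ValidationError(
                f"dataset {self.name!r}: values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.timepoints)} time points"
            )
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValidationError(f"dataset {self.name!r}: duplicate gene identifier {g!r}")
            seen.add(g)
        if self.n_timepoints < MIN_TIMEPOINTS:
            raise ValidationError(
                f"dataset {self.name!r}: {self.n_timepoints} time points < minimum "
                f"{MIN_TIMEPOINTS}"
            )
        if self.sampling_interval is not None and self.sampling_interval <= 0:
            raise ValidationError(
                f"dataset {self.name!r}: sampling_interval must be positive"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise ValidationError(f"dataset {self.name!r}: unknown gene {gene!r}") from None
        return self.values[i]

    def subset(self, genes: list[str]) -> "ExpressionDataset":
        """Restrict to ``genes`` in the given order (all must be present)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        try:
            rows = [idx[g] for g in genes]
        except KeyError as e:
            raise ValidationError(f"dataset {self.name!r}: unknown gene {e.args[0]!r}") from None
        return replace(self, genes=list(genes), values=self.values[rows].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.timepoints)


def read_dataset(path, name: str | None = None, sampling_interval: float | None = None) -> ExpressionDataset:
    """Read a tab-separated expression matrix.

    Malformed numeric cells raise :class:`ParseError` naming the gene row and
    time-point column; duplicate gene identifiers raise
    :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    genes = [str(g) for g in df.index]
    timepoints = [str(c) for c in df.columns]
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path.name}: duplicate gene identifier(s): {', '.join(map(str, dupes))}")

    raw = df.to_numpy(dtype=object)
    stripped = np.vectorize(lambda s: str(s).strip(), otypes=[object])(raw)
    missing = np.isin(stripped, MISSING_TOKENS)
    numeric = pd.to_numeric(pd.Series(stripped.ravel()), errors="coerce").to_numpy().reshape(stripped.shape)
    bad = np.isnan(numeric) & ~missing
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path.name}: malformed numeric cell {stripped[i, j]!r} at gene {genes[i]!r}, "
            f"time point {timepoints[j]!r}"
        )
    values = np.where(missing, np.nan, numeric).astype(float)
    return ExpressionDataset(
        name=name if name is not None else path.stem,
        genes=genes,
        timepoints=timepoints,
        values=values,
        sampling_interval=sampling_interval,
    )


def write_dataset(ds: ExpressionDataset, path) -> None:
    """Write the matrix as TSV (``NA`` for missing); round-trips finite values exactly."""
    ds.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def impute_missing(ds: ExpressionDataset, method: str = "drop_gene") -> ExpressionDataset:
    """Resolve missing entries so that downstream threshold search sees complete data.

    ``row_mean`` replaces each missing cell with the mean of the gene's
    observed cells (errors on an all-missing gene); ``drop_gene`` removes any
    gene carrying a missing entry.  The conservative default is ``drop_gene``,
    which never invents values.
    """
    if method not in ("row_mean", "drop_gene"):
        raise ValidationError(f"unknown imputation method {method!r}")
    if ds.is_complete:
        return ds
    if method == "drop_gene":
        keep = ~np.isnan(ds.values).any(axis=1)
        genes = [g for g, k in zip(ds.genes, keep) if k]
        if not genes:
            raise ValidationError(f"dataset {ds.name!r}: every gene has missing entries")
        return replace(ds, genes=genes, values=ds.values[keep].copy())
    values = ds.values.copy()
    for i, g in enumerate(ds.genes):
        row = values[i]
        mask = np.isnan(row)
        if mask.all():
            raise ValidationError(f"dataset {ds.name!r}: gene {g!r} has no observed values")
        if mask.any():
            row[mask] = row[~mask].mean()
    return replace(ds, values=values)


def intersect_genes(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the genes measured in all of them.

    The common gene order is the sorted intersection.  Idempotent and
    insensitive to the order of the input list; an empty intersection is an
    error.
    """
    if not datasets:
        raise ValidationError("at least one dataset is required")
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ValidationError("the gene intersection across datasets is empty")
    order = sorted(common)
    return [ds.subset(order) for ds in datasets]


_RULE_COLUMNS = [
    "regulator",
    "delay",
    "target",
    "rule_type",
    "rule_string",
    "accuracy",
    "support_fraction",
]


def write_rules(ruleset: ConsensusRuleSet, path) -> None:
    """Write a consensus rule set as TSV, one rule per row.

    ``accuracy`` is the minimum score across supporting datasets;
    ``support_fraction`` the fraction of datasets in which the rule passed.
    """
    rows = [
        {
            "regulator": r.regulator,
            "delay": r.delay,
            "target": r.target,
            "rule_type": r.rule_type,
            "rule_string": format_rule(r.regulator, r.delay, r.target, r.rule_type),
            "accuracy": r.score,
            "support_fraction": r.support / ruleset.k_total,
        }
        for r in sorted(ruleset.rules, key=lambda r: (r.delay, r.target, r.regulator, r.rule_type))
    ]
    pd.DataFrame(rows, columns=_RULE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_rules(path, k_total: int = 1, rca: float = 1.0) -> ConsensusRuleSet:
    """Read a rule TSV written by :func:`write_rules` back into a rule set.

    Pass the original ``k_total`` to recover exact support counts; with the
    default of 1 each rule is read with support 1, which is sufficient for
    pair-level evaluation.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("regulator", "delay", "target", "rule_type", "accuracy", "support_fraction"):
        if col not in df.columns:
            raise ParseError(f"{Path(path).name}: missing column {col!r}")
    rules = [
        ConsensusRule(
            regulator=str(row.regulator),
            target=str(row.target),
            delay=int(row.delay),
            rule_type=int(row.rule_type),
            score=float(row.accuracy),
            support=max(1, int(round(float(row.support_fraction) * k_total))),
        )
        for row in df.itertuples(index=False)
    ]
    return ConsensusRuleSet(rules=rules, k_total=k_total, rca=rca)
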