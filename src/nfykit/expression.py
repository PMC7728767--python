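"""Two-group differential expression with study-specific filters.

The central object is :class:`ExpressionMatrix`: genes x samples, each sample
labelled ``control`` or ``knockdown``.  Array mode carries log2 intensities;
rnaseq mode carries raw counts (log2(x+1)-transformed before testing).

DEG calling is a per-gene Welch two-sample t-test on the log2 scale with
Benjamini-Hochberg adjustment across all tested genes; a gene is called
``down``/``up`` when both the fold-change and FDR thresholds are met
(inclusive comparisons at the boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LABELS = ("control", "knockdown")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample. Log2 intensities
        in ``array`` mode, nonnegative integer counts in ``rnaseq`` mode.
    group
        Series mapping sample name to ``control`` or ``knockdown``.
    mode
        ``array`` or ``rnaseq``.
    """

    values: pd.DataFrame
    group: pd.Series
    mode: str = "array"

    def __post_init__(self) -> None:
        if self.mode not in ("array", "rnaseq"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()]
            raise ValueError(f"samples without group label: {list(missing)}")
        bad = set(self.group) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.mode == "rnaseq":
            arr = self.values.to_numpy(dtype=float)
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("rnaseq mode requires nonnegative integer counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples(self, label: str) -> list[str]:
        return list(self.group.index[self.group == label])

    def log2_values(self) -> pd.DataFrame:
        """Values on the log2 scale (counts get a +1 pseudocount first)."""
        if self.mode == "array":
            return self.values
        return np.log2(self.values + 1.0)

    def to_tsv(self, path: str | Path) -> None:
        """Write gene_id + one column per sample; header is ``sample|group``."""
        out = self.values.copy()
        out.columns = [f"{s}|{g}" for s, g in self.group.items()]
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "array") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        samples, groups = [], []
        for col in df.columns:
            if "|" not in col:
                raise ValueError(f"header {col!r} lacks '|group' suffix")
            s, g = col.rsplit("|", 1)
            samples.append(s)
            groups.append(g)
        df.columns = samples
        return cls(df, pd.Series(groups, index=samples), mode=mode)


def filter_low_expression(matrix: ExpressionMatrix, mode_param: float) -> ExpressionMatrix:
    """Drop weakly expressed genes, preserving gene order.

    Array mode: ``mode_param`` is a percentile p in (0, 100); genes whose mean
    expression falls strictly below the p-th percentile (linear interpolation)
    of all gene means are removed.  Rnaseq mode: ``mode_param`` is a minimum
    max-count c >= 0; genes whose maximum count across samples is < c are
    removed.
    """
    if matrix.mode == "array":
        p = float(mode_param)
        if not 0 < p < 100:
            raise ValueError(f"percentile must be in (0, 100), got {p}")
        means = matrix.values.mean(axis=1)
        cut = np.percentile(means.to_numpy(), p)
        keep = means >= cut
    else:
        c = float(mode_param)
        if c < 0:
            raise ValueError(f"min max-count must be >= 0, got {c}")
        keep = matrix.values.max(axis=1) >= c
    if not keep.any():
        raise ValueError("low-expression filter removed every gene; check the threshold")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.group, mode=matrix.mode)


@dataclass
class DEGTable:
    """Per-gene differential-expression results.

    ``table`` columns: ``log2fc`` (knockdown - control), ``p_value``,
    ``q_value`` (BH), ``direction`` in {down, up, ns}.
    """

    table: pd.DataFrame
    fc_min: float
    q_max: float

    def genes(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["direction"] == direction])

    @property
    def down(self) -> set[str]:
        return self.genes("down")

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    def counts(self) -> dict[str, int]:
        return {
            "down": int((self.table["direction"] == "down").sum()),
            "up": int((self.table["direction"] == "up").sum()),
            "total": int((self.table["direction"] != "ns").sum()),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, fc_min: float = np.nan, q_max: float = np.nan) -> "DEGTable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"), fc_min, q_max)


def call_degs(matrix: ExpressionMatrix, fc_min: float = 1.0, q_max: float = 0.05) -> DEGTable:
    """Welch t-test per gene on log2 values, BH adjustment, direction calls.

    A zero-variance gene with equal group means gets p = 1 by convention;
    zero variance with unequal means gets p = 0 (infinitely confident limit).
    Direction thresholds are inclusive: ``down`` iff log2fc <= -fc_min and
    q <= q_max.
    """
    if fc_min <= 0:
        raise ValueError("fc_min must be > 0")
    if not 0 < q_max < 1:
        raise ValueError("q_max must be in (0, 1)")
    ctrl = matrix.samples("control")
    kd = matrix.samples("knockdown")
    if len(ctrl) < 2 or len(kd) < 2:
        raise ValueError(
            f"need >=2 samples per group for testing (control={len(ctrl)}, knockdown={len(kd)})"
        )
    log2 = matrix.log2_values()
    a = log2[kd].to_numpy(dtype=float)
    b = log2[ctrl].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)  # zero variance in both groups
    p[degenerate & np.isclose(log2fc, 0.0)] = 1.0
    p[degenerate & ~np.isclose(log2fc, 0.0)] = 0.0
    q = stats.false_discovery_control(p, method="bh")
    direction = np.full(len(p), "ns", dtype=object)
    direction[(log2fc <= -fc_min) & (q <= q_max)] = "down"
    direction[(log2fc >= fc_min) & (q <= q_max)] = "up"
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": q, "direction": direction},
        index=matrix.gene_ids,
    )
    return DEGTable(table, fc_min=fc_min, q_max=q_max)


@dataclass
class NeuronalFilterResult:
    retained: set[str]
    removed: set[str] = field(default_factory=set)


def filter_non_neuronal(
    gene_set: set[str],
    neuron_expr: pd.Series,
    total_expr: pd.Series,
    fold: float = 5.0,
) -> NeuronalFilterResult:
    """Partition a gene set into neuronal-retained and non-neuronal genes.

    A gene is non-neuronal when its expression in isolated neurons drops more
    than ``fold``-fold relative to whole tissue:
    log2((neuron+1)/(total+1)) < -log2(fold).  Both vectors are linear-scale.
    """
    missing = sorted(g for g in gene_set if g not in neuron_expr.index or g not in total_expr.index)
    if missing:
        raise KeyError(f"genes missing from reference expression vectors: {missing}")
    genes = sorted(gene_set)
    ratio = np.log2((neuron_expr[genes] + 1.0) / (total_expr[genes] + 1.0))
    removed = set(ratio.index[ratio < -np.log2(fold)])
    return NeuronalFilterResult(retained=set(genes) - removed, removed=removed)


def overlap_gene_sets(named_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn partition of >=2 named sets.

    Keys are sorted tuples of the set names an element belongs to exactly;
    values sum to the size of the union.  Regions with zero elements are
    included for every nonempty combination of names.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named_sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = 0
    for gene in set().union(*named_sets.values()):
        membership = tuple(n for n in names if gene in named_sets[n])
        regions[membership] += 1
    return regions


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
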