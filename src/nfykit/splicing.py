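"""Exon-inclusion (PSI) estimation from splice-junction read counts.

NF-YA's exon 3 distinguishes the long (NF-YA-L, exon 3 included) and short
(NF-YA-S, exon 3 skipped) isoforms.  Reads spanning the exon2-exon3 and
exon3-exon4 junctions support inclusion; reads spanning exon2-exon4 support
skipping.  The inclusion fraction is

    psi = (n23 + n34) / (n23 + n34 + 2 * n24)

— the skipping count is doubled because one skipped transcript yields one
informative junction read where an included transcript yields two.  A zero
denominator leaves psi undefined (propagated as missing, never as 0).

Junction tables are tab-delimited (chrom, intron_start, intron_end, count)
with 0-based half-open intron coordinates, the convention of aligner SJ
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CorrelationResult, correlate

JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "count"]


@dataclass(frozen=True)
class JunctionCounts:
    """Reads spanning the exon2-3, exon3-4 and exon2-4 junctions."""

    n23: int
    n34: int
    n24: int
    sample: str = ""

    def __post_init__(self) -> None:
        for label, n in (("n23", self.n23), ("n34", self.n34), ("n24", self.n24)):
            if n < 0 or int(n) != n:
                raise ValueError(f"{label} must be a nonnegative integer, got {n}")


@dataclass(frozen=True)
class PsiEstimate:
    value: float | None  # in [0, 1], or None when no informative reads
    total: int  # informative count n23 + n34 + 2*n24

    @property
    def defined(self) -> bool:
        return self.value is not None


def psi(counts: JunctionCounts) -> PsiEstimate:
    """Exon-inclusion fraction from junction-spanning read counts."""
    total = counts.n23 + counts.n34 + 2 * counts.n24
    if total == 0:
        return PsiEstimate(value=None, total=0)
    return PsiEstimate(value=(counts.n23 + counts.n34) / total, total=total)


@dataclass(frozen=True)
class ExonModel:
    """Genomic coordinates of exons 2-4 (0-based half-open, ordered)."""

    chrom: str
    exon2: tuple[int, int]
    exon3: tuple[int, int]
    exon4: tuple[int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        exons = [self.exon2, self.exon3, self.exon4]
        for s, e in exons:
            if s >= e:
                raise ValueError("exon start must be < end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError("exons must be ordered and non-overlapping")

    def intron(self, a: int, b: int) -> tuple[int, int]:
        """Intron (half-open) between exon a and exon b."""
        exons = {2: self.exon2, 3: self.exon3, 4: self.exon4}
        return exons[a][1], exons[b][0]

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"chrom": self.chrom, "exon": i, "start": s, "end": e, "strand": self.strand}
            for i, (s, e) in zip((2, 3, 4), (self.exon2, self.exon3, self.exon4))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExonModel":
        df = pd.read_csv(path, sep="\t").set_index("exon")
        return cls(
            chrom=str(df["chrom"].iloc[0]),
            exon2=(int(df.loc[2, "start"]), int(df.loc[2, "end"])),
            exon3=(int(df.loc[3, "start"]), int(df.loc[3, "end"])),
            exon4=(int(df.loc[4, "start"]), int(df.loc[4, "end"])),
            strand=str(df["strand"].iloc[0]),
        )


def read_junction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=JUNCTION_COLUMNS, comment="#")
    if (df["count"] < 0).any():
        raise ValueError("junction counts must be nonnegative")
    return df


def write_junction_table(df: pd.DataFrame, path: str | Path) -> None:
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def extract_junction_counts(
    junction_table: pd.DataFrame, exon_model: ExonModel, sample: str = ""
) -> JunctionCounts:
    """Pull the three informative junction counts out of a junction table.

    A record contributes to n23 when its (chrom, intron_start, intron_end)
    equals the exon2-exon3 intron, and analogously for n34 and n24; all
    other records are ignored.  Duplicate identical intron records are
    summed with a warning.
    """

    def total_for(intron: tuple[int, int]) -> int:
        hits = junction_table[
            (junction_table["chrom"] == exon_model.chrom)
            & (junction_table["intron_start"] == intron[0])
            & (junction_table["intron_end"] == intron[1])
        ]
        if len(hits) > 1:
            warnings.warn(
                f"duplicate junction records for intron {intron} summed ({len(hits)} rows)"
            )
        return int(hits["count"].sum())

    return JunctionCounts(
        n23=total_for(exon_model.intron(2, 3)),
        n34=total_for(exon_model.intron(3, 4)),
        n24=total_for(exon_model.intron(2, 4)),
        sample=sample,
    )


@dataclass(frozen=True)
class IsoformRatio:
    """Long-isoform protein fraction L/(L+S) from band amounts."""

    ratio_l: float
    cell: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_l <= 1.0:
            raise ValueError("ratio must be in [0, 1]")


def isoform_ratio(l_amount: float, s_amount: float, cell: str = "") -> IsoformRatio:
    if l_amount < 0 or s_amount < 0:
        raise ValueError("band amounts must be nonnegative")
    if l_amount + s_amount == 0:
        raise ValueError("both band amounts are zero; ratio undefined")
    return IsoformRatio(ratio_l=l_amount / (l_amount + s_amount), cell=cell)


def correlate_isoform_with_clusters(
    ratios: pd.Series,
    pop_matrix: pd.DataFrame,
    blocks: dict[str, int],
) -> pd.DataFrame:
    """Per-block Pearson correlation of isoform ratio with summed populations.

    ``ratios`` maps cell label -> long-isoform ratio; ``pop_matrix`` is the
    terms x cells population matrix; ``blocks`` maps term -> block id.
    For each block, the block's term populations are summed per cell and
    correlated with the ratios across the shared cells.
    """
    cells = [c for c in pop_matrix.columns if c in ratios.index]
    if len(cells) < 3:
        raise ValueError(f"need >=3 shared cells, got {len(cells)}")
    r = ratios[cells].astype(float)
    if np.ptp(r.to_numpy()) == 0:
        raise ValueError("isoform ratios are constant; correlation undefined")
    rows = []
    for block in sorted(set(blocks.values())):
        terms = [t for t, b in blocks.items() if b == block and t in pop_matrix.index]
        if not terms:
            continue
        summed = pop_matrix.loc[terms, cells].sum(axis=0)
        joined = pd.DataFrame({"ratio": r, "population": summed})
        res: CorrelationResult = correlate(joined, "ratio", "population")
        rows.append({"block": block, "r": res.r, "n_pairs": res.n_pairs, "n_terms": len(terms)})
    return pd.DataFrame(rows).set_index("block")
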