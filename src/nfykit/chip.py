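"""Consensus ChIP peaks and peak-to-TSS target-gene assignment.

Peaks are 0-based half-open genomic intervals (BED convention).  A consensus
peak is emitted wherever every input experiment contributes a peak such that
all pairwise gaps between the contributing peaks are at most ``max_gap`` bp
(overlap counts as gap 0); the consensus interval is the union of the
contributing peaks, and overlapping consensus intervals are merged.

A gene is a proximal target when some peak center lies within the closed
window [TSS - w, TSS + w] (default w = 2000); genes whose same-chromosome
peaks all fall outside are distal-only.  Distances are center-to-TSS and
strand-ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import overlap_gene_sets

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str, "strand": str},
        comment="#",
    )
    _validate_intervals(df)
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _validate_intervals(df: pd.DataFrame) -> None:
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].head()
        raise ValueError(f"intervals require start < end; offending rows:\n{bad}")
    if (df["chrom"].astype(str).str.len() == 0).any():
        raise ValueError("empty chromosome name")


@dataclass
class TSSIndex:
    """gene id -> (chrom, TSS bp, strand); exactly one TSS per gene."""

    table: pd.DataFrame  # indexed by gene id, columns chrom, tss, strand

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValueError(f"multiple TSSs for genes: {list(dups[:5])}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @classmethod
    def from_bed6(cls, path: str | Path) -> "TSSIndex":
        """Read a BED6 TSS table: one single-bp interval per gene, the name
        column carrying the gene id, the start position being the TSS."""
        df = read_bed6(path)
        table = pd.DataFrame(
            {"chrom": df["chrom"].to_numpy(), "tss": df["start"].to_numpy(), "strand": df["strand"].to_numpy()},
            index=pd.Index(df["name"], name="gene_id"),
        )
        return cls(table)

    def to_bed6(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "chrom": self.table["chrom"].to_numpy(),
                "start": self.table["tss"].to_numpy(),
                "end": self.table["tss"].to_numpy() + 1,
                "name": self.table.index,
                "score": 0,
                "strand": self.table["strand"].to_numpy(),
            }
        )
        write_bed6(out, path)


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; overlap/adjacency -> 0."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_peak_sets(peak_sets: list[pd.DataFrame], max_gap: int = 100) -> pd.DataFrame:
    """Consensus peaks supported by every input set within a gap tolerance.

    For each tuple of peaks, one from each input set, whose pairwise gaps are
    all <= max_gap, the union interval is a candidate consensus; overlapping
    candidates are merged into maximal consensus peaks.  Symmetric in the
    input sets.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    for df in peak_sets:
        _validate_intervals(df)
    chroms = sorted(set().union(*(set(df["chrom"]) for df in peak_sets)))
    out_rows = []
    for chrom in chroms:
        per_set = [
            df[df["chrom"] == chrom][["start", "end"]].sort_values("start").to_numpy()
            for df in peak_sets
        ]
        if any(len(a) == 0 for a in per_set):
            continue
        # anchor on the first set; peaks from other sets must lie within
        # max_gap of the anchor, so a sorted window search bounds candidates
        candidates: list[tuple[int, int]] = []
        for a_start, a_end in per_set[0]:
            choices = []
            feasible = True
            for other in per_set[1:]:
                sel = [
                    (int(s), int(e))
                    for s, e in other
                    if s <= a_end + max_gap and _gap(a_start, a_end, s, e) <= max_gap
                ]
                if not sel:
                    feasible = False
                    break
                choices.append(sel)
            if not feasible:
                continue
            for combo in product(*choices):
                ok = all(
                    _gap(p[0], p[1], q[0], q[1]) <= max_gap
                    for p, q in combinations(combo, 2)
                )
                if ok:
                    ivs = [(int(a_start), int(a_end)), *combo]
                    candidates.append(
                        (min(s for s, _ in ivs), max(e for _, e in ivs))
                    )
        for s, e in _merge_intervals(candidates):
            out_rows.append({"chrom": chrom, "start": s, "end": e})
    out = pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
    out["name"] = [f"consensus_{i}" for i in range(len(out))]
    out["score"] = 0
    out["strand"] = "."
    return out


@dataclass
class TargetCall:
    gene_id: str
    n_supporting: int  # peaks with center inside the window
    min_distance: float  # min |peak center - TSS| over same-chromosome peaks
    klass: str  # 'proximal' or 'distal-only'


def annotate_to_tss(
    peaks: pd.DataFrame, tss_index: TSSIndex, window: int = 2000
) -> pd.DataFrame:
    """Assign target genes by peak-center proximity to the TSS.

    Returns a DataFrame indexed by gene id with columns n_supporting,
    min_distance and class ('proximal' iff some peak center lies within the
    closed +/-window; genes whose same-chromosome peaks all fall outside are
    'distal-only'; genes with no peak on their chromosome are omitted).
    Order-invariant in the peak input.
    """
    _validate_intervals(peaks)
    tss_chroms = set(tss_index.table["chrom"])
    stray = set(peaks["chrom"]) - tss_chroms
    if stray:
        warnings.warn(
            f"peak chromosomes absent from the TSS index (peaks unassigned): {sorted(stray)}"
        )
    centers_by_chrom = {
        chrom: np.sort((sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0)
        for chrom, sub in peaks.groupby("chrom")
    }
    rows = []
    for gene, rec in tss_index.table.iterrows():
        centers = centers_by_chrom.get(rec["chrom"])
        if centers is None or len(centers) == 0:
            continue
        d = np.abs(centers - rec["tss"])
        n_support = int((d <= window).sum())
        rows.append(
            {
                "gene_id": gene,
                "n_supporting": n_support,
                "min_distance": float(d.min()),
                "class": "proximal" if n_support > 0 else "distal-only",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_supporting", "min_distance", "class"]).set_index(
        "gene_id"
    )


def proximal_targets(calls: pd.DataFrame) -> set[str]:
    return set(calls.index[calls["class"] == "proximal"])


def target_set_overlap(
    named_target_sets: dict[str, set[str]]
) -> tuple[dict[tuple[str, ...], int], pd.DataFrame]:
    """Venn-region counts plus pairwise Jaccard indices for target-gene sets."""
    regions = overlap_gene_sets(named_target_sets)
    names = sorted(named_target_sets)
    jac = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        sa, sb = named_target_sets[a], named_target_sets[b]
        union = len(sa | sb)
        j = len(sa & sb) / union if union else 0.0
        jac.loc[a, b] = jac.loc[b, a] = j
    return regions, jac
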