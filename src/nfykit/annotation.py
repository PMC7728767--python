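"""Functional-annotation enrichment, population matrices and clustering.

"Population" here means the percent of an input gene list annotated to a
term, 100*k/n_list — the quantity drawn in the study's pie graphs and the
value clustered/correlated across cell types.  Fold enrichment is the list
hit rate over the universe hit rate, and the enrichment p-value is a plain
two-sided Fisher exact test on the 2x2 table (a deliberate simplification
of DAVID's jackknifed EASE score).

Clustering is agglomerative with Euclidean distance and Ward linkage in the
squared-distance (Ward.D2) convention, via scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass
class AnnotationMap:
    """term -> gene-id set over a background universe, with optional term blocks."""

    terms: dict[str, set[str]]
    universe: set[str]
    blocks: dict[str, str] = field(default_factory=dict)  # term -> block label

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no genes")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} has genes outside the universe: {sorted(stray)[:5]}"
                )

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                desc = self.blocks.get(term, "na")
                genes = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{desc}\t{genes}\n")

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "AnnotationMap":
        """Read GMT (term, description, genes...).  The description column is
        kept as the block label when it is not 'na'.  Universe defaults to the
        union of all annotated genes."""
        terms: dict[str, set[str]] = {}
        blocks: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            term, desc, genes = parts[0], parts[1], set(parts[2:])
            terms[term] = genes
            if desc and desc != "na":
                blocks[term] = desc
        if universe is None:
            universe = set().union(*terms.values()) if terms else set()
        return cls(terms, universe, blocks)


def enrich(gene_list: set[str], annotation: AnnotationMap) -> pd.DataFrame:
    """Per-term enrichment of a gene list against the annotation universe.

    Returns a DataFrame indexed by term with columns k, n_list, K, N,
    population_pct (= 100*k/n_list), fold (= (k/n_list)/(K/N)) and fisher_p
    (two-sided exact).  List members outside the universe are dropped with a
    warning.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    stray = gene_list - annotation.universe
    if stray:
        warnings.warn(f"{len(stray)} list genes outside the universe were dropped")
    genes = gene_list & annotation.universe
    if not genes:
        raise ValueError("no list genes inside the universe")
    n_list = len(genes)
    N = len(annotation.universe)
    rows = []
    for term in sorted(annotation.terms):
        members = annotation.terms[term]
        k = len(genes & members)
        K = len(members)
        table = [[k, n_list - k], [K - k, N - K - n_list + k]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "term": term,
                "k": k,
                "n_list": n_list,
                "K": K,
                "N": N,
                "population_pct": 100.0 * k / n_list,
                "fold": (k / n_list) / (K / N),
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def population_matrix(
    named_lists: dict[str, set[str]],
    annotation: AnnotationMap,
    term_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Terms x gene-lists matrix of population percentages.

    Missing term/list combinations are 0 (a list with no annotated genes
    yields an all-zero column).
    """
    if len(named_lists) < 2:
        raise ValueError("need at least two gene lists")
    terms = term_subset if term_subset is not None else sorted(annotation.terms)
    cols = {}
    for name, genes in named_lists.items():
        inside = genes & annotation.universe
        n_list = len(inside)
        if n_list == 0:
            cols[name] = pd.Series(0.0, index=terms)
            continue
        cols[name] = pd.Series(
            {t: 100.0 * len(inside & annotation.terms.get(t, set())) / n_list for t in terms}
        )
    return pd.DataFrame(cols).loc[terms]


@dataclass
class CorrelationResult:
    r: float
    n_pairs: int


def correlate(matrix: pd.DataFrame, col_a: str, col_b: str) -> CorrelationResult:
    """Pearson correlation between two columns over shared finite term rows."""
    sub = matrix[[col_a, col_b]].dropna()
    sub = sub[np.isfinite(sub).all(axis=1)]
    if len(sub) < 3:
        raise ValueError(f"need >=3 shared terms, got {len(sub)}")
    a, b = sub[col_a].to_numpy(), sub[col_b].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a column; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), n_pairs=len(sub))


@dataclass
class Dendrogram:
    """Ward-linkage dendrogram: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be nondecreasing")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Cut into exactly n_clusters groups; cluster ids are 1..n assigned
        by first appearance in leaf order (stable across relabelings)."""
        if n_clusters > len(self.labels):
            raise ValueError("more clusters requested than leaves")
        raw = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        assignment = dict(zip(self.labels, raw))
        remap: dict[int, int] = {}
        for label in self.leaf_order():
            c = assignment[label]
            if c not in remap:
                remap[c] = len(remap) + 1
        return {label: remap[c] for label, c in assignment.items()}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def cluster(matrix: pd.DataFrame, axis: str = "lists") -> Dendrogram:
    """Hierarchically cluster the population matrix.

    ``axis='lists'`` clusters the columns (cell types/conditions),
    ``axis='terms'`` the rows.  Euclidean distance, Ward linkage (D2
    convention — scipy's 'ward' on observation vectors).
    """
    if axis == "lists":
        data = matrix.T
    elif axis == "terms":
        data = matrix
    else:
        raise ValueError("axis must be 'lists' or 'terms'")
    if data.isna().any().any():
        raise ValueError("matrix contains NaN")
    if len(data) < 2:
        raise ValueError("need >=2 items to cluster")
    Z = hierarchy.linkage(data.to_numpy(dtype=float), method="ward")
    return Dendrogram(Z, list(data.index))


def assign_blocks(term_dendrogram: Dendrogram, n_clusters: int = 4) -> dict[str, int]:
    """Cut the term dendrogram into functional blocks (CL #1-4 analogue)."""
    return term_dendrogram.cut(n_clusters)
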