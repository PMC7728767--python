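"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator emulates one class of study input: two-group expression with
planted fold-changes, TSS-centered promoters with motif copies planted at a
controlled positional spread, annotation maps whose term blocks carry
designed population skews, ChIP peaks clustered near TSSs over a uniform
background, and splice-junction counts drawn from a known exon-inclusion
fraction.  All generators take an explicit integer seed and are bit-stable:
the same seed reproduces the same output exactly.  No global random state
is touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationMap
from .chip import TSSIndex
from .expression import ExpressionMatrix
from .motifs import PromoterSet, reverse_complement
from .splicing import JunctionCounts

#: Per-block population boost factors relative to a flat profile.  The
#: ER-skew profile inflates the endosome/Golgi- and ER/lipid-like blocks
#: (1-2), the cellcycle-skew profile the cell-cycle/mitochondrial-like
#: blocks (3-4), mirroring the neuronal vs proliferative contrast.
PROFILE_BOOSTS = {
    "flat": {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
    "ER-skew": {1: 2.0, 2: 3.0, 3: 0.5, 4: 0.5},
    "cellcycle-skew": {1: 0.5, 2: 0.5, 3: 3.0, 4: 2.0},
}


@dataclass
class SimTruth:
    """Ground truth recorded by the generators, for recovery tests."""

    planted_down: set[str] = field(default_factory=set)
    planted_up: set[str] = field(default_factory=set)
    motif_positions: dict[str, float] = field(default_factory=dict)  # gene -> center offset bp
    true_inclusion_fraction: float | None = None
    non_neuronal_ids: set[str] = field(default_factory=set)
    term_profile_label: str | None = None
    peak_source_gene: list[str] = field(default_factory=list)  # per near-peak

    def __post_init__(self) -> None:
        if self.planted_down & self.planted_up:
            raise ValueError("down and up truth sets must be disjoint")
        if self.true_inclusion_fraction is not None and not 0 <= self.true_inclusion_fraction <= 1:
            raise ValueError("inclusion fraction must be in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_down"] = sorted(d["planted_down"])
        d["planted_up"] = sorted(d["planted_up"])
        d["non_neuronal_ids"] = sorted(d["non_neuronal_ids"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["planted_down"] = set(d["planted_down"])
        d["planted_up"] = set(d["planted_up"])
        d["non_neuronal_ids"] = set(d["non_neuronal_ids"])
        return cls(**d)


def gen_expression(
    n_genes: int,
    n_per_group: int,
    n_down: int,
    n_up: int,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    mode: str = "array",
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    dispersion: float = 0.1,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-group expression with planted differential genes.

    Array mode: per-gene baseline log2 intensity ~ Normal(baseline_mean,
    baseline_sd), Gaussian replicate noise (noise_sd); planted genes are
    shifted by -/+ effect_log2fc in the knockdown group.  Rnaseq mode:
    counts ~ NegativeBinomial around 2**baseline with the given dispersion
    (variance mu + dispersion*mu^2).
    """
    if n_genes <= 0 or n_per_group <= 0:
        raise ValueError("n_genes and n_per_group must be positive")
    if n_down < 0 or n_up < 0 or n_down + n_up > n_genes:
        raise ValueError("need n_down + n_up <= n_genes, both nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if mode not in ("array", "rnaseq"):
        raise ValueError(f"unknown mode {mode!r}")
    if (n_down or n_up) and effect_log2fc == 0:
        raise ValueError("effect_log2fc must be nonzero when planting effects")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    down = set(genes[:n_down])
    up = set(genes[n_down : n_down + n_up])
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    shift = np.zeros(n_genes)
    shift[:n_down] = -effect_log2fc
    shift[n_down : n_down + n_up] = effect_log2fc
    samples = [f"ctrl_{i+1}" for i in range(n_per_group)] + [
        f"kd_{i+1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["control"] * n_per_group + ["knockdown"] * n_per_group, index=samples
    )
    mean_log2 = np.concatenate(
        [
            np.repeat(baseline[:, None], n_per_group, axis=1),
            np.repeat((baseline + shift)[:, None], n_per_group, axis=1),
        ],
        axis=1,
    )
    if mode == "array":
        values = mean_log2 + rng.normal(0.0, noise_sd, size=mean_log2.shape) if noise_sd > 0 else mean_log2
    else:
        mu = np.exp2(mean_log2)
        if dispersion > 0:
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mu)
            values = rng.negative_binomial(n_param, p_param).astype(float)
        else:
            values = rng.poisson(mu).astype(float)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        groups,
        mode=mode,
    )
    return matrix, SimTruth(planted_down=down, planted_up=up)


def gen_promoters(
    n: int,
    length: int = 2001,
    motif_consensus: str = "CCAAT",
    planted_fraction: float = 0.3,
    placement: str = "centered",
    sd_bp: float = 50.0,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[PromoterSet, SimTruth]:
    """Promoters with one exact motif copy planted in a subset of sequences.

    Background bases are i.i.d. with the given GC fraction.  In planted
    sequences the consensus (or its reverse complement, strand chosen
    fairly) REPLACES background bases at an offset drawn from the placement
    law — 'centered': Normal(0, sd_bp) rounded and clipped to the valid
    range; 'uniform': uniform over all valid starts.  Truth records each
    planted sequence's site-center offset relative to the TSS.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    m = len(motif_consensus)
    if m >= length:
        raise ValueError("motif longer than the sequence")
    if length % 2 == 0:
        raise ValueError("length must be odd (TSS at the midpoint)")
    if placement not in ("centered", "uniform"):
        raise ValueError(f"unknown placement {placement!r}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    tss = (length - 1) // 2
    n_planted = int(round(n * planted_fraction))
    planted_idx = set(rng.choice(n, size=n_planted, replace=False).tolist()) if n_planted else set()
    ids, seqs = [], []
    truth_pos: dict[str, float] = {}
    width = len(str(max(n, 1)))
    max_start = length - m
    for i in range(n):
        gid = f"p{i+1:0{width}d}"
        seq = bases[rng.choice(4, size=length, p=p)]
        if i in planted_idx:
            if placement == "centered":
                center = tss + rng.normal(0.0, sd_bp) if sd_bp > 0 else float(tss)
                start = int(round(center - (m - 1) / 2.0))
                start = min(max(start, 0), max_start)
            else:
                start = int(rng.integers(0, max_start + 1))
            motif = motif_consensus if rng.random() < 0.5 else reverse_complement(motif_consensus)
            seq[start : start + m] = list(motif)
            truth_pos[gid] = start + (m - 1) / 2.0 - tss
        ids.append(gid)
        seqs.append("".join(seq))
    return PromoterSet(ids, seqs), SimTruth(motif_positions=truth_pos)


def gen_annotation(
    n_terms: int,
    universe_size: int,
    profile: str,
    list_size: int,
    seed: int = 0,
    map_seed: int | None = None,
    membership_rate: float = 0.05,
) -> tuple[AnnotationMap, set[str], SimTruth]:
    """An annotation map with four term blocks plus a skewed gene list.

    The term-to-gene map is generated from ``map_seed`` (default: the seed
    itself), so calls in the same seed family — same map_seed, different
    seeds — share one annotation and differ only in their gene lists.
    Terms are split into four equal blocks; each universe gene joins each
    term independently at ``membership_rate``.  The gene list of size
    ``list_size`` is drawn without replacement with weights multiplicative
    in the per-block boost of each term a gene belongs to, so a block with
    boost b acquires roughly b times the flat population.
    """
    if n_terms < 4:
        raise ValueError("need at least 4 terms to form four blocks")
    if list_size > universe_size:
        raise ValueError("list_size must be <= universe_size")
    if profile not in PROFILE_BOOSTS:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILE_BOOSTS)}")
    map_rng = np.random.default_rng(seed if map_seed is None else map_seed)
    genes = [f"u{i:05d}" for i in range(1, universe_size + 1)]
    universe = set(genes)
    term_names = [f"t{i:03d}" for i in range(1, n_terms + 1)]
    blocks = {t: (i * 4) // n_terms + 1 for i, t in enumerate(term_names)}
    membership = np.zeros((n_terms, universe_size), dtype=bool)
    for ti in range(n_terms):
        members = map_rng.random(universe_size) < membership_rate
        if not members.any():  # keep terms nonempty
            members[map_rng.integers(universe_size)] = True
        membership[ti] = members
    terms = {
        t: {genes[g] for g in np.flatnonzero(membership[ti])}
        for ti, t in enumerate(term_names)
    }
    boosts = PROFILE_BOOSTS[profile]
    log_w = np.zeros(universe_size)
    for ti, t in enumerate(term_names):
        log_w[membership[ti]] += np.log(boosts[blocks[t]])
    w = np.exp(log_w - log_w.max())
    list_rng = np.random.default_rng(seed)
    chosen = list_rng.choice(universe_size, size=list_size, replace=False, p=w / w.sum())
    gene_list = {genes[g] for g in chosen}
    amap = AnnotationMap(terms, universe, {t: f"CL{b}" for t, b in blocks.items()})
    return amap, gene_list, SimTruth(term_profile_label=profile)


def gen_peaks(
    tss_index: TSSIndex,
    n_near: int,
    near_sd_bp: float,
    n_background: int,
    genome_span: dict[str, int],
    seed: int = 0,
    peak_width: int = 200,
) -> tuple[pd.DataFrame, SimTruth]:
    """ChIP-like peaks: TSS-proximal peaks over a uniform background.

    Near peaks center at TSS + Normal(0, near_sd_bp) for TSSs drawn with
    replacement from the index; background centers are uniform over the
    per-chromosome spans.  All peaks have the stated fixed width.
    """
    for chrom, rec in tss_index.table.groupby("chrom"):
        if chrom not in genome_span:
            raise ValueError(f"genome_span missing chromosome {chrom!r}")
        if rec["tss"].max() >= genome_span[chrom]:
            raise ValueError(f"genome_span does not cover all TSSs on {chrom!r}")
    rng = np.random.default_rng(seed)
    half = peak_width // 2
    rows, source = [], []
    n_genes = len(tss_index.genes)
    for i in range(n_near):
        gi = int(rng.integers(n_genes))
        rec = tss_index.table.iloc[gi]
        center = rec["tss"] + (rng.normal(0.0, near_sd_bp) if near_sd_bp > 0 else 0.0)
        center = int(round(center))
        start = max(0, center - half)
        rows.append(
            {"chrom": rec["chrom"], "start": start, "end": start + peak_width,
             "name": f"near_{i}", "score": 0, "strand": "."}
        )
        source.append(str(tss_index.genes[gi]))
    chroms = sorted(genome_span)
    lengths = np.array([genome_span[c] for c in chroms], dtype=float)
    for i in range(n_background):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        center = int(rng.integers(half, max(genome_span[chroms[ci]] - half, half + 1)))
        rows.append(
            {"chrom": chroms[ci], "start": center - half, "end": center - half + peak_width,
             "name": f"bg_{i}", "score": 0, "strand": "."}
        )
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return peaks, SimTruth(peak_source_gene=source)


def gen_tss_index(
    n_genes: int, chrom: str = "chr1", spacing: int = 50_000, seed: int = 0
) -> TSSIndex:
    """Evenly spaced single-chromosome TSS table with random strands."""
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "tss": (np.arange(n_genes) + 1) * spacing,
            "strand": rng.choice(["+", "-"], size=n_genes),
        },
        index=pd.Index([f"g{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene_id"),
    )
    return TSSIndex(table)


def gen_junctions(
    true_fraction: float, depth: float, seed: int = 0, sample: str = "sim"
) -> tuple[JunctionCounts, SimTruth]:
    """Junction counts from a known inclusion fraction f at sequencing depth
    lambda: n23 ~ Poisson(lambda*f), n34 ~ Poisson(lambda*f),
    n24 ~ Poisson(lambda*(1-f)), independent."""
    if not 0 <= true_fraction <= 1:
        raise ValueError("true_fraction must be in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    counts = JunctionCounts(
        n23=int(rng.poisson(depth * true_fraction)),
        n34=int(rng.poisson(depth * true_fraction)),
        n24=int(rng.poisson(depth * (1 - true_fraction))),
        sample=sample,
    )
    return counts, SimTruth(true_inclusion_fraction=true_fraction)


def junction_table_from_counts(
    counts: JunctionCounts, exon_model, n_decoys: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Embed the three informative junction counts in a junction table with
    decoy introns elsewhere on the same chromosome."""
    rng = np.random.default_rng(seed)
    informative = {
        exon_model.intron(2, 3): counts.n23,
        exon_model.intron(3, 4): counts.n34,
        exon_model.intron(2, 4): counts.n24,
    }
    rows = [
        {"chrom": exon_model.chrom, "intron_start": s, "intron_end": e, "count": c}
        for (s, e), c in informative.items()
    ]
    far = exon_model.exon4[1] + 10_000
    for _ in range(n_decoys):
        s = int(rng.integers(far, far + 100_000))
        rows.append(
            {"chrom": exon_model.chrom, "intron_start": s,
             "intron_end": s + int(rng.integers(100, 5000)),
             "count": int(rng.poisson(50))}
        )
    return pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end", "count"])
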