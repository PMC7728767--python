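"""Promoter-proximal motif centrality.

A positional test in the spirit of CentriMo: score every promoter with a PWM,
keep each sequence's best site, and ask whether best-site centers pile up in
a window around the TSS more than a uniform placement would predict.  The
tail probability is binomial with null probability w/S for a width-w window
among S valid center positions, computed in log space (the interesting
p-values underflow doubles), Bonferroni-adjusted over the tested widths.

Promoters are strand-oriented TSS +/- flank sequences of equal odd length L
with the TSS at index (L-1)/2; offsets are in bp relative to the TSS
(negative = upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.special import logsumexp
from scipy.stats import binom

ALPHABET = "ACGTN"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N

DEFAULT_WINDOW_WIDTHS = (11, 21, 51, 101, 201, 401, 801)

#: Consensus strings for the default motif panel: the NF-Y CCAAT box, the
#: SP2 GC-box and the USF E-box.
DEFAULT_CONSENSUS = {"CCAAT": "CCAAT", "SP2": "GGGCGGG", "EBOX": "CACGTG"}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (unknown letters become N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _CODE["N"], dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class PWM:
    """Position probability matrix over ACGT with a recorded pseudocount.

    ``matrix`` has shape (m, 4) with rows summing to 1.  Probabilities of
    exactly zero are only valid with a positive pseudocount applied upstream;
    :func:`log_odds` rejects them otherwise.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (m, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1 within 1e-9")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_consensus(cls, name: str, consensus: str, pseudocount: float = 0.01) -> "PWM":
        """Build a PWM from a consensus string.

        Each position puts probability 1 on the consensus base; probabilities
        are then floored at the pseudocount and renormalized, so e.g. with
        pseudocount 0.01 the consensus base gets 1/1.03 = 0.97087...
        """
        consensus = consensus.upper()
        if any(b not in "ACGT" for b in consensus):
            raise ValueError(f"consensus must be ACGT only: {consensus!r}")
        m = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus):
            m[i, _CODE[b]] = 1.0
        if pseudocount > 0:
            m = np.maximum(m, pseudocount)
            m /= m.sum(axis=1, keepdims=True)
        return cls(name, m, pseudocount=pseudocount)

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(name, probs, pseudocount=pseudocount)

    @classmethod
    def read_pfm(cls, path: str | Path, name: str | None = None, pseudocount: float = 0.01) -> "PWM":
        """Read a plain-text PFM: 4 rows (A, C, G, T) of whitespace-separated
        counts or probabilities, optional ``>name`` header line."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if lines and lines[0].startswith(">"):
            name = name or lines[0][1:].strip()
            lines = lines[1:]
        if len(lines) != 4:
            raise ValueError(f"PFM must have 4 rows (A/C/G/T), got {len(lines)}")
        rows = [np.array([float(x) for x in ln.split()]) for ln in lines]
        if len({len(r) for r in rows}) != 1:
            raise ValueError("PFM rows have unequal lengths")
        mat = np.stack(rows, axis=1)  # (m, 4)
        if np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            # already probabilities; floor at the pseudocount only when zeros
            # are present, so a clean PFM round-trips unchanged
            probs = mat
            if pseudocount > 0 and (mat == 0).any():
                probs = np.maximum(mat, pseudocount)
            probs = probs / probs.sum(axis=1, keepdims=True)
            return cls(name or Path(path).stem, probs, pseudocount=pseudocount)
        return cls.from_counts(name or Path(path).stem, mat, pseudocount=pseudocount)

    def write_pfm(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for j in range(4):
                fh.write(" ".join(f"{v:.6f}" for v in self.matrix[:, j]) + "\n")


def log_odds(pwm: PWM, background: float = 0.25) -> np.ndarray:
    """Log2(prob/background) score matrix of shape (5, m); N scores 0."""
    if (pwm.matrix <= 0).any():
        if pwm.pseudocount <= 0:
            raise ValueError(
                "PWM contains zero probabilities; rebuild with a positive pseudocount"
            )
        raise ValueError("PWM contains zero probabilities despite a pseudocount")
    lo = np.zeros((5, len(pwm)))
    lo[:4] = np.log2(pwm.matrix.T / background)
    return lo


def max_score(pwm: PWM, background: float = 0.25) -> float:
    """Best achievable log-odds score (sum of per-position maxima)."""
    return float(log_odds(pwm, background)[:4].max(axis=0).sum())


@dataclass
class PromoterSet:
    """Equal-length strand-oriented promoter sequences, TSS at the midpoint."""

    gene_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences must be equal length, got lengths {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) % 2 == 0:
            raise ValueError("sequence length must be odd (TSS at the midpoint)")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def tss_index(self) -> int:
        return (self.length - 1) // 2

    def encoded(self) -> np.ndarray:
        return np.stack([encode(s) for s in self.sequences]) if self.sequences else np.empty((0, 0), np.int8)

    def subset(self, gene_ids: set[str]) -> "PromoterSet":
        pairs = [(g, s) for g, s in zip(self.gene_ids, self.sequences) if g in gene_ids]
        return PromoterSet([g for g, _ in pairs], [s for _, s in pairs])

    def to_fasta(self, path: str | Path) -> None:
        flank = self.tss_index
        with open(path, "w") as fh:
            for g, s in zip(self.gene_ids, self.sequences):
                fh.write(f">{g}|TSS-{flank}..+{flank}\n{s}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PromoterSet":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id.split("|")[0])
            seqs.append(str(rec.seq).upper())
        return cls(ids, seqs)


@dataclass
class BestSite:
    offset: float  # site center in bp relative to the TSS
    strand: str  # '+' or '-'
    score: float
    start: int  # 0-based start within the sequence

    @property
    def found(self) -> bool:
        return np.isfinite(self.score)


def _strand_scores(enc: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-start log-odds scores on both strands for encoded sequences.

    Returns (plus, minus), each (n, S).  The minus-strand score of a window is
    the score of its reverse complement, obtained by scanning with the
    reverse-complemented score matrix.
    """
    m = lo.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(enc, m, axis=1)  # (n, S, m)
    idx = np.arange(m)
    plus = lo[windows, idx].sum(axis=-1)
    lo_rc = lo[_COMPLEMENT][:, ::-1]
    minus = lo_rc[windows, idx].sum(axis=-1)
    return plus, minus


def best_sites(promoters: PromoterSet, pwm: PWM, background: float = 0.25) -> list[BestSite]:
    """Best-scoring site per sequence over all starts and both strands.

    Ties break deterministically: smallest |offset|, then + strand, then
    leftmost start.  An all-N sequence has no site (score -inf).
    """
    m = len(pwm)
    L = promoters.length
    if L < m:
        raise ValueError("sequences shorter than the motif")
    lo = log_odds(pwm, background)
    enc = promoters.encoded()
    plus, minus = _strand_scores(enc, lo)
    n, S = plus.shape
    starts = np.arange(S)
    offsets = starts + (m - 1) / 2.0 - promoters.tss_index  # center relative to TSS
    # lexicographic tie-break key: (|offset|, strand is minus, start); scores
    # within 1e-9 of the maximum count as tied (summation-order noise)
    tol = 1e-9
    tie = ((2.0 * np.abs(offsets)).astype(np.int64) * 2 * (S + 1))[None, :] + starts[None, :]
    results: list[BestSite] = []
    all_n = (enc == _CODE["N"]).all(axis=1)
    both = np.stack([plus, minus])  # (2, n, S)
    best = both.max(axis=(0, 2))
    for i in range(n):
        if all_n[i]:
            results.append(BestSite(np.nan, "+", -np.inf, -1))
            continue
        keys_p = np.where(plus[i] >= best[i] - tol, tie[0], np.iinfo(np.int64).max)
        keys_m = np.where(minus[i] >= best[i] - tol, tie[0] + S + 1, np.iinfo(np.int64).max)
        jp, jm = keys_p.argmin(), keys_m.argmin()
        if keys_p[jp] <= keys_m[jm]:
            j, strand = jp, "+"
        else:
            j, strand = jm, "-"
        results.append(BestSite(float(offsets[j]), strand, float(best[i]), int(j)))
    return results


def best_site(sequence: str, pwm: PWM, background: float = 0.25) -> BestSite:
    """Single-sequence convenience wrapper around :func:`best_sites`."""
    if len(sequence) % 2 == 0:
        # pad with a trailing N to keep the TSS convention; offsets unaffected
        raise ValueError("sequence length must be odd (TSS at midpoint)")
    ps = PromoterSet(["_"], [sequence])
    return best_sites(ps, pwm, background)[0]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def binom_tail_log10(k: int, n: int, p0: float) -> float:
    """log10 P(X >= k) for X ~ Binomial(n, p0), stable far below float range."""
    if k <= 0 or p0 >= 1.0:
        return 0.0
    if k > n:
        return -np.inf
    xs = np.arange(k, n + 1)
    return float(logsumexp(binom.logpmf(xs, n, p0)) / np.log(10.0))


@dataclass
class WindowResult:
    width: int
    k: float  # tie-averaged best-site mass with |offset| <= (width-1)/2
    p0: float  # null probability width/S
    log10_p: float  # raw upper binomial tail
    log10_p_adj: float  # Bonferroni over tested widths, capped at 1

    @property
    def p(self) -> float:
        return 10.0 ** self.log10_p

    @property
    def p_adj(self) -> float:
        return 10.0 ** self.log10_p_adj


@dataclass
class LocalEnrichmentResult:
    motif: str
    n_scored: int  # sequences whose best site reaches the score threshold
    n_sequences: int
    score_threshold: float
    windows: list[WindowResult] = field(default_factory=list)
    no_sites: bool = False

    @property
    def best_window(self) -> WindowResult:
        return min(self.windows, key=lambda w: (w.log10_p_adj, w.width))

    @property
    def population_pct(self) -> float:
        """Percent of input sequences contributing best sites in the best window."""
        if self.no_sites or not self.windows or self.n_sequences == 0:
            return 0.0
        return 100.0 * self.best_window.k / self.n_sequences


def central_enrichment(
    promoters: PromoterSet,
    pwm: PWM,
    score_threshold: float | None = None,
    window_widths: tuple[int, ...] = DEFAULT_WINDOW_WIDTHS,
    background: float = 0.25,
) -> LocalEnrichmentResult:
    """Centered-window binomial test for TSS-proximal best-site enrichment.

    ``score_threshold`` defaults to 60% of the motif's maximum achievable
    log-odds score.  For each odd width w the null probability of a best-site
    center landing within |offset| <= (w-1)/2 is p0 = w/S with
    S = L - m + 1 valid centers; the raw p-value is the upper binomial tail
    over the n_scored contributing sequences, and the adjusted p multiplies
    by the number of widths tested (capped at 1).

    A sequence whose maximum score is reached at several (position, strand)
    sites splits its unit count equally among the tied centers; with
    degenerate consensus motifs exact matches tie routinely, and any
    preferential tie-break would bias the window counts away from the
    uniform null.  The fractional window mass is ceiled before taking the
    binomial tail (conservative).
    """
    m = len(pwm)
    L = promoters.length
    S = L - m + 1
    for w in window_widths:
        if w % 2 == 0:
            raise ValueError(f"window widths must be odd, got {w}")
        if w > S:
            raise ValueError(f"window width {w} exceeds the {S} valid center positions")
    if score_threshold is None:
        score_threshold = 0.6 * max_score(pwm, background)
    lo = log_odds(pwm, background)
    enc = promoters.encoded()
    plus, minus = _strand_scores(enc, lo)
    all_n = (enc == _CODE["N"]).all(axis=1)
    best = np.maximum(plus.max(axis=1), minus.max(axis=1))
    keep = (~all_n) & (best >= score_threshold)
    n_scored = int(keep.sum())
    result = LocalEnrichmentResult(
        motif=pwm.name,
        n_scored=n_scored,
        n_sequences=len(promoters),
        score_threshold=float(score_threshold),
        no_sites=n_scored == 0,
    )
    n_windows = len(window_widths)
    if n_scored == 0:
        for w in window_widths:
            result.windows.append(WindowResult(w, 0.0, w / S, 0.0, 0.0))
        return result
    tol = 1e-9
    tie_p = plus[keep] >= (best[keep, None] - tol)
    tie_m = minus[keep] >= (best[keep, None] - tol)
    n_tied = tie_p.sum(axis=1) + tie_m.sum(axis=1)
    offsets = np.arange(S) + (m - 1) / 2.0 - promoters.tss_index
    for w in window_widths:
        half = (w - 1) / 2
        in_w = np.abs(offsets) <= half
        mass = (tie_p[:, in_w].sum(axis=1) + tie_m[:, in_w].sum(axis=1)) / n_tied
        k = float(mass.sum())
        p0 = w / S
        lp = binom_tail_log10(int(np.ceil(k - 1e-9)), n_scored, p0)
        lp_adj = min(0.0, lp + np.log10(n_windows))
        result.windows.append(WindowResult(w, k, p0, lp, lp_adj))
    return result


def compare_motif_panels(
    promoter_sets: dict[str, PromoterSet],
    pwms: list[PWM],
    score_threshold: float | None = None,
    window_widths: tuple[int, ...] = DEFAULT_WINDOW_WIDTHS,
) -> dict[tuple[str, str], LocalEnrichmentResult]:
    """One centrality result per (promoter set, motif) combination."""
    if not promoter_sets or not pwms:
        raise ValueError("both panels must be nonempty")
    return {
        (set_name, pwm.name): central_enrichment(ps, pwm, score_threshold, window_widths)
        for set_name, ps in promoter_sets.items()
        for pwm in pwms
    }


def default_panel(pseudocount: float = 0.01) -> list[PWM]:
    return [PWM.from_consensus(n, c, pseudocount) for n, c in DEFAULT_CONSENSUS.items()]


def results_to_rows(results: dict[tuple[str, str], LocalEnrichmentResult]) -> list[dict]:
    rows = []
    for (set_name, motif), res in sorted(results.items()):
        bw = res.best_window
        rows.append(
            {
                "set": set_name,
                "motif": motif,
                "n_sequences": res.n_sequences,
                "n_scored": res.n_scored,
                "best_window": bw.width,
                "k": bw.k,
                "log10_p": bw.log10_p,
                "log10_p_adj": bw.log10_p_adj,
                "population_pct": res.population_pct,
                "no_sites": res.no_sites,
            }
        )
    return rows
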