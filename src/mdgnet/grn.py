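"""Gene-regulatory-network layer: motif scanning, miRNA targets, co-expression.

Three edge classes are produced and assembled into a typed network:

* TF -> gene: a position-weight-matrix (PWM) hit in the gene's promoter.
  Scanning scores each window by the log2 likelihood ratio against a
  background base composition; the p-value of a score is computed *exactly*
  (up to score discretization, default 0.01-bit bins) by dynamic programming
  over the background score distribution, and windows with p <= 1e-4 are
  reported on both strands.
* miRNA -> gene: plant-style complementarity scoring of the mature miRNA
  against the transcript.  Penalties per aligned position: mismatch 1.0,
  G:U wobble 0.5, single-nucleotide bulge 1.0 (at most one bulge), all
  doubled within positions 2-13 from the miRNA 5' end; a site is a target
  when the total expectation is <= 3.0.
* gene -- gene: protein-protein interactions with score > 0.40.

Every edge class is additionally validated by co-expression (Pearson r >
0.8, pairwise-complete) whenever expression profiles exist for both
endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import TypedNetwork

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Base-probability motif model, rows in A, C, G, T order."""

    name: str
    matrix: np.ndarray                       # 4 x L probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def score_matrix(self) -> np.ndarray:
        """Per-base log2 likelihood-ratio scores with pseudocount smoothing."""
        p = (self.matrix + self.pseudocount * self.background[:, None]) / (
            1.0 + self.pseudocount
        )
        return np.log2(p / self.background[:, None])

    def reverse_complement(self) -> "PWM":
        rc = self.matrix[::-1, ::-1]
        bg = self.background[::-1]
        return PWM(self.name, rc, bg, self.pseudocount)


def write_meme(pwms: list[PWM], path) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.4f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    lines = open(path).read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            width = int(lines[i].split("w=")[1].split()[0])
            cols = []
            for k in range(width):
                cols.append([float(v) for v in lines[i + 1 + k].split()])
            pwms.append(PWM(name, np.array(cols).T, background))
            i += width + 1
            continue
        i += 1
    return pwms


@dataclass(frozen=True)
class MotifHit:
    motif: str
    gene: str
    position: int      # 1-based start of the window on the forward strand
    strand: str
    score: float       # bits (discretized)
    p_value: float


def _binned_scores(pwm: PWM, bin_width: float) -> np.ndarray:
    return np.round(pwm.score_matrix() / bin_width).astype(int)


def _score_pvalue_table(int_scores: np.ndarray, background: np.ndarray):
    """Exact tail distribution of the window score under the background.

    Dynamic programming over motif columns on the integer (binned) score
    lattice; returns (offset, tail) where tail[k] = Pr(score_bins >= k + offset).
    """
    lo = int(int_scores.min(axis=0).sum())
    hi = int(int_scores.max(axis=0).sum())
    dist = {0: 1.0}
    for col in int_scores.T:
        new: dict[int, float] = {}
        for s, prob in dist.items():
            for b in range(4):
                key = s + int(col[b])
                new[key] = new.get(key, 0.0) + prob * background[b]
        dist = new
    size = hi - lo + 1
    pmf = np.zeros(size)
    for s, prob in dist.items():
        pmf[s - lo] = prob
    tail = np.cumsum(pmf[::-1])[::-1]
    return lo, tail


def pwm_scan(promoter: str, pwm: PWM, gene: str = "", p_max: float = 1e-4,
             bin_width: float = 0.01) -> list[MotifHit]:
    """Scan both strands of a promoter for PWM hits with exact p <= ``p_max``.

    Window scores are sums of binned per-base log2(p/q) terms; the p-value of
    a score is the exact background tail probability from the DP table, so
    p-values are monotone non-increasing in score.  Windows containing a
    non-ACGT character are skipped.
    """
    promoter = promoter.upper()
    L = pwm.length
    if L > len(promoter):
        return []
    base_idx = np.full(len(promoter), -1, dtype=int)
    for k, b in enumerate(BASES):
        base_idx[np.frombuffer(promoter.encode(), dtype=np.uint8) == ord(b)] = k
    windows = np.lib.stride_tricks.sliding_window_view(base_idx, L)
    valid = (windows >= 0).all(axis=1)
    cols = np.arange(L)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        int_scores = _binned_scores(mat, bin_width)
        lo, tail = _score_pvalue_table(int_scores, mat.background)
        hi = lo + len(tail) - 1
        scores = int_scores[np.where(valid[:, None], windows, 0), cols].sum(axis=1)
        pvals = np.where(
            scores < lo, 1.0,
            np.where(scores > hi, 0.0, tail[np.clip(scores - lo, 0, len(tail) - 1)]),
        )
        for start in np.nonzero(valid & (pvals <= p_max))[0]:
            hits.append(
                MotifHit(pwm.name, gene, int(start) + 1, strand,
                         float(scores[start]) * bin_width, float(pvals[start]))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# miRNA target scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetHit:
    mirna: str
    gene: str
    position: int      # 1-based start of the site on the transcript
    expectation: float
    alignment: str     # per-miRNA-position code: '|' pair, 'o' wobble, 'x' mismatch, '-' bulge


_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _pair_penalty(m_base: str, t_base: str) -> tuple[float, str]:
    """Penalty for a miRNA base paired against a target (transcript) base."""
    if m_base == _COMPL.get(t_base):
        return 0.0, "|"
    if (m_base, t_base) in {("G", "T"), ("T", "G")}:  # G:U wobble (DNA alphabet)
        return 0.5, "o"
    return 1.0, "x"


def _ungapped_score(mirna: str, site: str, seed_lo: int, seed_hi: int):
    """Penalty of an ungapped miRNA:site duplex.

    The site is the transcript segment read 5'->3'; miRNA position k (1-based
    from its 5' end) pairs with site position len(site) - k + 1.  Penalties
    double inside miRNA positions ``seed_lo``..``seed_hi``.
    """
    L = len(mirna)
    total = 0.0
    align = []
    for k in range(1, L + 1):
        m = mirna[k - 1]
        t = site[L - k]
        pen, code = _pair_penalty(m, t)
        if seed_lo <= k <= seed_hi:
            pen *= 2.0
        total += pen
        align.append(code)
    return total, "".join(align)


def mirna_target_score(mirna: str, transcript: str, mirna_id: str = "",
                       gene: str = "", e_max: float = 3.0,
                       seed_lo: int = 2, seed_hi: int = 13) -> list[TargetHit]:
    """Slide the miRNA over the transcript and report sites with penalty <= e_max.

    Besides the ungapped duplex at every offset, variants with one bulged
    transcript nucleotide (penalty 1.0, doubled in the seed region) are
    considered; the best-scoring non-overlapping hits are returned sorted by
    position.
    """
    mirna = mirna.upper()
    transcript = transcript.upper()
    if len(mirna) < 19:
        raise ValueError("mature miRNA must be >= 19 nt")
    for seq, label in ((mirna, "miRNA"), (transcript, "transcript")):
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"non-nucleotide characters in {label}: {sorted(bad)}")
    L = len(mirna)
    n_off = len(transcript) - L + 1
    if n_off < 1:
        return []
    # vectorized penalty of every ungapped offset: penalty lookup table P[m, t]
    code = {b: i for i, b in enumerate(BASES)}
    P = np.ones((4, 4))
    for m in BASES:
        for t in BASES:
            P[code[m], code[t]] = _pair_penalty(m, t)[0]
    m_idx = np.array([code[b] for b in mirna])
    t_idx = np.array([code[b] for b in transcript])
    weights = np.array(
        [2.0 if seed_lo <= k <= seed_hi else 1.0 for k in range(1, L + 1)]
    )
    windows = np.lib.stride_tricks.sliding_window_view(t_idx, L)[:, ::-1]
    # windows[o, k-1] is the site base pairing miRNA position k
    ungapped = (P[m_idx[None, :], windows] * weights[None, :]).sum(axis=1)
    best = ungapped.copy()
    # single transcript bulge: site of length L+1 with one skipped base
    if len(t_idx) >= L + 1:
        ext = np.lib.stride_tricks.sliding_window_view(t_idx, L + 1)
        for skip in range(1, L):
            bulged = np.concatenate([ext[:, :skip], ext[:, skip + 1:]], axis=1)[:, ::-1]
            k_mirna = L - skip  # miRNA position adjacent to the bulge
            bulge_pen = 2.0 if seed_lo <= k_mirna <= seed_hi else 1.0
            sc = (P[m_idx[None, :], bulged] * weights[None, :]).sum(axis=1) + bulge_pen
            best[: len(sc)] = np.minimum(best[: len(sc)], sc)
    hits = []
    for start in np.nonzero(best <= e_max)[0]:
        site = transcript[start:start + L]
        _, align = _ungapped_score(mirna, site, seed_lo, seed_hi)
        if best[start] < ungapped[start]:
            align = align + "*"  # best duplex at this offset involves a bulge
        hits.append(TargetHit(mirna_id, gene, int(start) + 1, float(best[start]), align))
    # greedy non-overlap by ascending penalty
    hits.sort(key=lambda h: (h.expectation, h.position))
    kept: list[TargetHit] = []
    for h in hits:
        if all(abs(h.position - k.position) >= L for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.position)
    return kept


# ---------------------------------------------------------------------------
# co-expression and expression-pattern checks
# ---------------------------------------------------------------------------

def coexpression_matrix(expr: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between gene profiles."""
    return expr.T.corr(min_periods=min_samples)


def coexpression_edges(expr: pd.DataFrame, r_min: float = 0.8,
                       min_samples: int = 3) -> list[tuple]:
    """Gene pairs with Pearson r strictly greater than ``r_min``.

    Only positive correlations qualify; constant profiles are skipped (their
    correlation is undefined).
    """
    corr = coexpression_matrix(expr, min_samples)
    genes = list(corr.index)
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = corr.iat[i, j]
            if pd.notna(r) and r > r_min:
                edges.append((genes[i], genes[j], float(r)))
    return edges


def opposite_pattern(lfc_mirna: pd.Series, lfc_gene: pd.Series, stage: str) -> bool:
    """True when the miRNA and gene log2 fold-changes strictly oppose at a stage."""
    if stage not in lfc_mirna.index or stage not in lfc_gene.index:
        import warnings

        warnings.warn(f"stage {stage!r} missing from a fold-change table")
        return False
    a, b = float(lfc_mirna[stage]), float(lfc_gene[stage])
    return a * b < 0  # opposite signs, both nonzero


# ---------------------------------------------------------------------------
# GRN assembly
# ---------------------------------------------------------------------------

def assemble_grn(candidate_genes: set, tfs: set, mirnas: set,
                 motif_hits: list[tuple], target_hits: list[tuple],
                 ppi_edges: pd.DataFrame | None, expr: pd.DataFrame | None,
                 r_min: float = 0.8, ppi_min: float = 0.40) -> TypedNetwork:
    """Assemble the GRN from validated regulatory evidence.

    ``motif_hits`` are (tf, gene) pairs (a PWM hit of the TF's motif in the
    gene's promoter), ``target_hits`` are (mirna, gene) pairs.  PPI rows are
    kept at score > ``ppi_min``.  Any edge whose two endpoints both have
    expression profiles must also be co-expressed at r > ``r_min``; edges
    with a missing profile (e.g. miRNAs) pass through unvalidated.
    """
    net = TypedNetwork()
    for g in sorted(candidate_genes):
        net.add_node(g, "TF" if g in tfs else "gene")
    for t in sorted(tfs):
        net.add_node(t, "TF")
    for m in sorted(mirnas):
        net.add_node(m, "miRNA")

    corr = coexpression_matrix(expr) if expr is not None else None

    def validated(a: str, b: str) -> bool:
        if corr is None or a not in corr.index or b not in corr.index:
            return True
        r = corr.at[a, b]
        return pd.notna(r) and r > r_min

    for tf, gene in motif_hits:
        if tf in net.nodes and gene in net.nodes and validated(tf, gene):
            net.add_edge(tf, gene, "tfbs", directed=True)
    for mir, gene in target_hits:
        if mir in net.nodes and gene in net.nodes and validated(mir, gene):
            net.add_edge(mir, gene, "mirna_target", directed=True)
    if ppi_edges is not None:
        for _, row in ppi_edges.iterrows():
            a, b, score = row["gene_a"], row["gene_b"], float(row["score"])
            if score > ppi_min and a in net.nodes and b in net.nodes \
                    and a != b and validated(a, b):
                net.add_edge(a, b, "ppi", weight=score)
    return net
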