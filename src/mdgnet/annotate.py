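"""Candidate gene and miRNA mining around mapped loci.

Genes and miRNAs are pulled from +/- ``flank_kb`` (default 200 kb) genomic
windows around each significant locus (closed intervals, 1-based inclusive
coordinates, clamped at 1), then filtered by expression evidence:

* ``filter_expressed`` drops genes with FPKM < 1 in every tissue or with more
  than 20% missing samples,
* ``seed_specific`` keeps genes whose seed FPKM is the tissue maximum and at
  least ``margin`` (default 2) times the second-highest tissue,
* ``high_expression_55daf`` keeps genes whose 55-DAF FPKM is at least
  ``multiplier`` (default 2) times the across-stage mean,
* ``deg_high_low_oil`` calls differential expression between high- and
  low-oil accessions with a two-proportion z-test on library-normalized
  counts at raw alpha = 0.05 (no multiplicity correction).

``candidate_genes`` combines them: trait-mode candidates must be in-window,
seed-specific and differentially expressed; metabolite-mode candidates must
be in-window, seed-specific and 55-DAF-high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel


@dataclass(frozen=True)
class Locus:
    """A genomic interval (1-based inclusive) attached to a mapped variable."""

    id: str
    chrom: str
    start: int
    end: int
    variable: str = ""


@dataclass
class CandidateCall:
    gene: GeneModel
    locus: str
    evidence: set = field(default_factory=set)
    annotation: str | None = None


def features_in_window(locus: Locus, features: list[GeneModel],
                       flank_kb: float = 200.0,
                       biotype: str | None = None) -> list[GeneModel]:
    """Features overlapping the locus padded by ``flank_kb`` on both sides.

    Overlap is closed-interval: a feature that merely touches the padded
    boundary is included.  An unknown chromosome yields an empty list with a
    warning rather than an error.
    """
    pad = int(flank_kb * 1000)
    lo = max(1, locus.start - pad)
    hi = locus.end + pad
    chroms = {f.chrom for f in features}
    if locus.chrom not in chroms:
        warnings.warn(f"locus {locus.id}: chromosome {locus.chrom} absent from annotation")
        return []
    hits = [
        f for f in features
        if f.chrom == locus.chrom and f.start <= hi and f.end >= lo
        and (biotype is None or f.biotype == biotype)
    ]
    return sorted(hits, key=lambda f: (f.start, f.id))


def mirnas_in_window(locus: Locus, features: list[GeneModel],
                     flank_kb: float = 200.0) -> list[GeneModel]:
    return features_in_window(locus, features, flank_kb, biotype="miRNA")


def filter_expressed(expr: pd.DataFrame, fpkm_min: float = 1.0,
                     max_missing_frac: float = 0.20) -> set:
    """Genes passing the baseline expression filters.

    Drops genes whose FPKM is below ``fpkm_min`` in *all* samples and genes
    whose missing fraction *exceeds* ``max_missing_frac`` (exactly 20%
    missing is kept).
    """
    if expr.shape[1] < 1:
        raise ValueError("expression matrix has no samples")
    missing_frac = expr.isna().mean(axis=1)
    low_everywhere = (expr.fillna(0.0) < fpkm_min).all(axis=1)
    keep = ~low_everywhere & (missing_frac <= max_missing_frac)
    return set(expr.index[keep])


def seed_specific(expr: pd.DataFrame, seed_column: str = "seed",
                  margin: float = 2.0) -> set:
    """Genes whose seed expression dominates every other tissue.

    A gene qualifies when its seed FPKM is the maximum across tissues and at
    least ``margin`` times the second-highest tissue; all-zero profiles never
    qualify.
    """
    if seed_column not in expr.columns:
        raise ValueError(f"no {seed_column!r} sample in the expression matrix")
    seed = expr[seed_column]
    others = expr.drop(columns=[seed_column]).max(axis=1)
    keep = (seed > 0) & (seed >= others) & (seed >= margin * others)
    return set(expr.index[keep.fillna(False)])


def high_expression_55daf(expr: pd.DataFrame, stage_column: str = "55DAF",
                          multiplier: float = 2.0) -> set:
    """Genes whose 55-DAF FPKM is >= ``multiplier`` x the across-stage mean."""
    if stage_column not in expr.columns:
        raise ValueError(f"no {stage_column!r} stage in the expression matrix")
    mean = expr.mean(axis=1)
    keep = (expr[stage_column] >= multiplier * mean) & (mean > 0)
    return set(expr.index[keep.fillna(False)])


def deg_high_low_oil(counts_high: pd.Series, counts_low: pd.Series,
                     alpha: float = 0.05) -> set:
    """Differentially expressed genes between high- and low-oil accessions.

    Per gene, a two-proportion z-test on library-size-normalized counts (the
    binomial approximation underlying MA-plot DE callers) at raw ``alpha``;
    no multiplicity correction is applied.
    """
    counts_high = counts_high.astype(float)
    counts_low = counts_low.loc[counts_high.index].astype(float)
    n1, n2 = counts_high.sum(), counts_low.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p1 = counts_high / n1
    p2 = counts_low / n2
    pooled = (counts_high + counts_low) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / se
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=counts_high.index)
    pvals[se == 0] = 1.0
    return set(pvals.index[pvals < alpha])


def candidate_genes(locus: Locus, features: list[GeneModel],
                    seed_specific_set: set, deg_set: set,
                    high_55daf_set: set, expressed_set: set,
                    mode: str = "trait", flank_kb: float = 200.0,
                    annotation_map: dict | None = None) -> list[CandidateCall]:
    """Candidate calls for one locus under the trait or metabolite rule set.

    trait mode:      in_window AND seed_specific AND deg_high_low_oil
    metabolite mode: in_window AND seed_specific AND high_55daf
    Genes failing ``filter_expressed`` are never candidates.  When an
    annotation lookup is supplied, matched entries are attached; otherwise
    the call is flagged unannotated (annotation None).
    """
    if mode not in {"trait", "metabolite"}:
        raise ValueError("mode must be 'trait' or 'metabolite'")
    calls = []
    for gene in features_in_window(locus, features, flank_kb):
        if gene.biotype == "miRNA":
            continue
        if gene.id not in expressed_set:
            continue
        evidence = {"in_window", "expressed"}
        if gene.id in seed_specific_set:
            evidence.add("seed_specific")
        if gene.id in deg_set:
            evidence.add("deg_high_low_oil")
        if gene.id in high_55daf_set:
            evidence.add("high_55daf")
        if mode == "trait":
            ok = {"seed_specific", "deg_high_low_oil"} <= evidence
        else:
            ok = {"seed_specific", "high_55daf"} <= evidence
        if ok:
            note = (annotation_map or {}).get(gene.id)
            calls.append(CandidateCall(gene, locus.id, evidence, note))
    return calls
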