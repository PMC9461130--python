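"""Genome layer: LOD-based QTL, mQTL and QTL-by-environment detection.

Two in-repo mapping engines exercise the downstream "detected by >= 2
methods" logic:

* ``interval_mapping`` (method tag ``IM``): Haley-Knott regression on
  expected genotypes at pseudomarkers placed every ``step_cM`` (default 1 cM),
  expectations conditioned on flanking markers through RIL transition
  probabilities R = 2r/(1+2r) with Haldane r; LOD = (n/2) log10(RSS0/RSS1)
  with the cross-of-origin covariate in both models.  Significance LOD >= 2.5.
* ``multilocus_scan`` (method tag ``MLS``): forward selection of markers by
  conditional LOD with backward elimination, threshold LOD >= 3.0.

QTL-by-environment interactions are scanned with a stacked regression
(y = env + g vs y = env + g + g x env) at threshold LOD >= 5.0.

Support intervals are 1.5-LOD drops; peaks on a chromosome are separated by
at least ``min_peak_distance_cM``.  A locus is *stable* when records for the
same variable co-locate across at least two methods and/or two environments;
mQTL records of the same compound class with overlapping supports and >= 2
methods merge into clusters, which can then be co-located against trait QTLs
with a +/- 200 kb pad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeData, haldane_r, ril_selfing_R


@dataclass(frozen=True)
class QTLRecord:
    variable: str
    chrom: str
    left_marker: str
    right_marker: str
    left_cM: float
    right_cM: float
    left_bp: int
    right_bp: int
    peak_cM: float
    lod: float
    effect: float
    r2_pct: float
    method: str          # "IM" | "MLS" | "QEI"
    environment: str     # environment id, replicate id or "BLUP"


@dataclass
class StableQTL:
    variable: str
    chrom: str
    members: list
    peak_cM: float
    left_bp: int
    right_bp: int
    methods: set = field(default_factory=set)
    environments: set = field(default_factory=set)

    @property
    def stable(self) -> bool:
        return len(self.methods) >= 2 or len(self.environments) >= 2


@dataclass
class MQTLCluster:
    category: str
    chrom: str
    members: list
    merged_left_bp: int
    merged_right_bp: int
    methods: set = field(default_factory=set)

    @property
    def variables(self) -> set:
        return {m.variable for m in self.members}

    @property
    def peak_cM(self) -> float:
        return float(np.median([m.peak_cM for m in self.members]))


# ---------------------------------------------------------------------------
# pseudomarker expectations
# ---------------------------------------------------------------------------

def _expected_genotypes(geno: GenotypeData, step_cM: float):
    """Expected +/-1 genotype at pseudomarkers on a step grid, per chromosome.

    Conditioning is on the nearest flanking markers through a two-state
    Markov chain whose transfer probability over distance d is the RIL
    recombinant fraction R(d) = 2r/(1+2r), r Haldane.  At marker positions
    the expectation equals the observed genotype.
    """
    signed = geno.signed().to_numpy(dtype=float)  # n x M in {-1, +1}
    positions = []
    blocks = []
    for chrom, sub in geno.gmap.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy()
        order = np.argsort(cm)
        cm = cm[order]
        idx = sub.index.to_numpy()[order]
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"map for {chrom} not sorted")
        obs = signed[:, idx]  # n x m
        grid = np.arange(0.0, cm[-1] + 1e-9, step_cM)
        if grid[-1] < cm[-1] - 1e-9:
            grid = np.append(grid, cm[-1])
        exp_block = np.empty((obs.shape[0], len(grid)))
        for t, pos in enumerate(grid):
            j = np.searchsorted(cm, pos)
            if j < len(cm) and abs(cm[j] - pos) < 1e-9:
                exp_block[:, t] = obs[:, j]
                continue
            left = j - 1
            right = j if j < len(cm) else -1
            if left < 0:  # before first marker
                R = ril_selfing_R(haldane_r(cm[0] - pos))
                exp_block[:, t] = obs[:, 0] * (1.0 - 2.0 * R)
            elif right == -1:  # beyond last marker
                R = ril_selfing_R(haldane_r(pos - cm[-1]))
                exp_block[:, t] = obs[:, -1] * (1.0 - 2.0 * R)
            else:
                dl, dr = pos - cm[left], cm[right] - pos
                Rl = ril_selfing_R(haldane_r(dl))
                Rr = ril_selfing_R(haldane_r(dr))
                xl, xr = obs[:, left], obs[:, right]
                # P(state=+1 | flanks) along the chain L -> t -> R
                p_l = np.where(xl > 0, 1.0 - Rl, Rl)
                p_r = np.where(xr > 0, 1.0 - Rr, Rr)
                num = p_l * p_r
                den = num + (1.0 - p_l) * (1.0 - p_r)
                exp_block[:, t] = 2.0 * num / den - 1.0
        positions.append(pd.DataFrame({"chrom": chrom, "cM": grid}))
        blocks.append(exp_block)
    pos_df = pd.concat(positions, ignore_index=True)
    return pos_df, np.hstack(blocks)


def _flanking_markers(gmap: pd.DataFrame, chrom: str, left_cM: float,
                      right_cM: float) -> tuple[str, str, int, int]:
    sub = gmap.loc[gmap["chrom"] == chrom].sort_values("cM")
    cm = sub["cM"].to_numpy()
    li = np.searchsorted(cm, left_cM + 1e-9) - 1
    ri = np.searchsorted(cm, right_cM - 1e-9)
    li = max(li, 0)
    ri = min(ri, len(cm) - 1)
    lrow, rrow = sub.iloc[li], sub.iloc[ri]
    return lrow["marker"], rrow["marker"], int(lrow["bp"]), int(rrow["bp"])


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def _lod_profile(y: np.ndarray, G: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """LOD of adding each column of G to the base model Z, via partial r^2."""
    n = len(y)
    ry = _residualize(y[:, None], Z)[:, 0]
    rG = _residualize(G, Z)
    ss_y = float(ry @ ry)
    ss_g = (rG * rG).sum(axis=0)
    cross = rG.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_g > 1e-12, cross**2 / (ss_g * ss_y), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - r2)


def _find_peaks(pos_df: pd.DataFrame, lod: np.ndarray, lod_min: float,
                min_peak_distance_cM: float, prominence: float = 1.5) -> list[int]:
    """Indices of local LOD maxima >= lod_min, separated in cM and prominent.

    Candidates are taken in descending LOD; a lower peak is reported only if
    it is >= ``min_peak_distance_cM`` from every kept peak *and* the profile
    dips below (candidate LOD - ``prominence``) somewhere between it and each
    kept peak, so the shoulders of one broad QTL are not multiply reported.
    """
    chosen: list[int] = []
    for chrom, sub in pos_df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        prof = lod[idx]
        cm = sub["cM"].to_numpy()
        cand = [
            k for k in range(len(prof))
            if prof[k] >= lod_min
            and (k == 0 or prof[k] >= prof[k - 1])
            and (k == len(prof) - 1 or prof[k] >= prof[k + 1])
        ]
        cand.sort(key=lambda k: -prof[k])
        kept: list[int] = []
        for k in cand:
            ok = True
            for j in kept:
                if abs(cm[k] - cm[j]) < min_peak_distance_cM:
                    ok = False
                    break
                lo, hi = sorted((k, j))
                if prof[lo:hi + 1].min() > prof[k] - prominence:
                    ok = False
                    break
            if ok:
                kept.append(k)
        chosen.extend(idx[k] for k in kept)
    return sorted(chosen)


def _support_interval(pos_df: pd.DataFrame, lod: np.ndarray, peak_idx: int,
                      drop: float = 1.5) -> tuple[float, float]:
    chrom = pos_df.loc[peak_idx, "chrom"]
    sub = pos_df.loc[pos_df["chrom"] == chrom]
    idx = sub.index.to_numpy()
    prof = lod[idx]
    cm = sub["cM"].to_numpy()
    k = int(np.where(idx == peak_idx)[0][0])
    floor = prof[k] - drop
    left = k
    while left > 0 and prof[left - 1] >= floor:
        left -= 1
    right = k
    while right < len(prof) - 1 and prof[right + 1] >= floor:
        right += 1
    return float(cm[left]), float(cm[right])


def _effect_r2(y: np.ndarray, g: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    Xf = np.column_stack([Z, g])
    coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ coef
    rss1 = float(resid @ resid)
    coef0, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rss0 = float(np.sum((y - Z @ coef0) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 100.0 * (rss0 - rss1) / tss if tss > 0 else 0.0
    return float(coef[-1]), r2


def _align(geno: GenotypeData, phen: pd.Series, covariate: pd.Series | None):
    common = geno.lines.intersection(phen.dropna().index)
    if len(common) == 0:
        raise ValueError("no lines shared between genotypes and phenotype")
    if len(common) < len(phen.dropna()):
        missing = set(phen.dropna().index) - set(common)
        raise ValueError(f"phenotyped lines absent from genotypes: {sorted(missing)[:5]}")
    y = phen.loc[common].to_numpy(dtype=float)
    Z = np.ones((len(common), 1))
    if covariate is not None:
        Z = np.column_stack([Z, covariate.loc[common].to_numpy(dtype=float)])
    return common, y, Z


# ---------------------------------------------------------------------------
# interval mapping
# ---------------------------------------------------------------------------

def interval_mapping(geno: GenotypeData, phen: pd.Series,
                     covariate: pd.Series | None = None, step_cM: float = 1.0,
                     lod_min: float = 2.5, min_peak_distance_cM: float = 10.0,
                     support_drop: float = 1.5, environment: str = "BLUP",
                     _cache: dict | None = None) -> list[QTLRecord]:
    """Haley-Knott genome scan for one variable in one environment."""
    common, y, Z = _align(geno, phen, covariate)
    key = ("em", step_cM)
    if _cache is not None and key in _cache:
        pos_df, X = _cache[key]
    else:
        pos_df, X = _expected_genotypes(geno, step_cM)
        if _cache is not None:
            _cache[key] = (pos_df, X)
    sel = geno.lines.get_indexer(common)
    Xs = X[sel]
    lod = _lod_profile(y, Xs, Z)
    records = []
    for pk in _find_peaks(pos_df, lod, lod_min, min_peak_distance_cM):
        chrom = pos_df.loc[pk, "chrom"]
        peak_cm = float(pos_df.loc[pk, "cM"])
        left_cm, right_cm = _support_interval(pos_df, lod, pk, support_drop)
        lm, rm, lbp, rbp = _flanking_markers(geno.gmap, chrom, left_cm, right_cm)
        effect, r2 = _effect_r2(y, Xs[:, pk], Z)
        records.append(
            QTLRecord(
                str(phen.name), chrom, lm, rm, left_cm, right_cm, lbp, rbp,
                peak_cm, float(lod[pk]), effect, r2, "IM", environment,
            )
        )
    return records


# ---------------------------------------------------------------------------
# multilocus scan
# ---------------------------------------------------------------------------

def multilocus_scan(geno: GenotypeData, phen: pd.Series,
                    covariate: pd.Series | None = None, lod_min: float = 3.0,
                    environment: str = "BLUP") -> list[QTLRecord]:
    """Forward-selection multilocus marker scan with backward elimination.

    Markers enter by largest conditional LOD while conditional LOD >= lod_min
    and the model keeps <= n/10 markers, then any marker whose drop-LOD falls
    below the threshold is eliminated.  Per-marker LOD is
    (n/2) log10(RSS_without / RSS_with).
    """
    common, y, Z = _align(geno, phen, covariate)
    M = geno.signed().loc[common].to_numpy(dtype=float)
    markers = list(geno.geno.columns)
    n = len(y)
    max_size = max(1, n // 10)
    selected: list[int] = []
    while len(selected) < max_size:
        base = np.column_stack([Z] + [M[:, j] for j in selected])
        remaining = [j for j in range(M.shape[1]) if j not in selected]
        if not remaining:
            break
        lods = _lod_profile(y, M[:, remaining], base)
        best = int(np.argmax(lods))
        if lods[best] < lod_min:
            break
        cand = remaining[best]
        resid_var = _residualize(M[:, [cand]], base).var()
        if resid_var < 1e-10:  # collinear with current model: skip permanently
            break
        selected.append(cand)
    # backward elimination at the same threshold
    changed = True
    while changed and selected:
        changed = False
        for j in list(selected):
            others = [k for k in selected if k != j]
            base = np.column_stack([Z] + [M[:, k] for k in others])
            lod_j = _lod_profile(y, M[:, [j]], base)[0]
            if lod_j < lod_min:
                selected.remove(j)
                changed = True
    records = []
    gmap = geno.gmap.set_index("marker")
    for j in selected:
        others = [k for k in selected if k != j]
        base = np.column_stack([Z] + [M[:, k] for k in others])
        lod_j = float(_lod_profile(y, M[:, [j]], base)[0])
        effect, r2 = _effect_r2(y, M[:, j], base)
        name = markers[j]
        row = gmap.loc[name]
        records.append(
            QTLRecord(
                str(phen.name), row["chrom"], name, name, float(row["cM"]),
                float(row["cM"]), int(row["bp"]), int(row["bp"]),
                float(row["cM"]), lod_j, effect, r2, "MLS", environment,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.peak_cM))
    return records


# ---------------------------------------------------------------------------
# QTL x environment interaction
# ---------------------------------------------------------------------------

def detect_qei(geno: GenotypeData, phen: pd.DataFrame,
               covariate: pd.Series | None = None, step_cM: float = 1.0,
               lod_min: float = 5.0, min_peak_distance_cM: float = 10.0,
               variable: str | None = None) -> list[QTLRecord]:
    """Scan for loci whose effect differs across environments.

    ``phen`` is a long table (line, environment, variable, value) for one
    variable across >= 2 environments sharing lines.  At each pseudomarker the
    stacked models y = env + g and y = env + g + g x env are compared;
    QEI LOD = (N/2) log10(RSS_add / RSS_full) with N the stacked sample size.
    """
    if variable is not None:
        phen = phen.loc[phen["variable"] == variable]
    envs = sorted(phen["environment"].unique())
    if len(envs) < 2:
        raise ValueError("QEI detection requires >= 2 environments")
    wide = phen.pivot(index="line", columns="environment", values="value").dropna()
    common = geno.lines.intersection(wide.index)
    if len(common) == 0:
        raise ValueError("environments share no phenotyped lines with the genotypes")
    wide = wide.loc[common]
    pos_df, X = _expected_genotypes(geno, step_cM)
    sel = geno.lines.get_indexer(common)
    Xs = X[sel]
    n, n_env = len(common), len(envs)
    N = n * n_env
    y = np.concatenate([wide[e].to_numpy(dtype=float) for e in envs])
    env_dummies = np.zeros((N, n_env))
    for k in range(n_env):
        env_dummies[k * n:(k + 1) * n, k] = 1.0
    Zc = env_dummies
    if covariate is not None:
        cov = covariate.loc[common].to_numpy(dtype=float)
        Zc = np.column_stack([Zc, np.tile(cov, n_env)])
    lod = np.zeros(len(pos_df))
    g_stack = np.tile(Xs, (n_env, 1))
    for t in range(Xs.shape[1]):
        g = g_stack[:, t]
        inter = np.column_stack(
            [g * env_dummies[:, k] for k in range(1, n_env)]
        )
        Zadd = np.column_stack([Zc, g])
        resid_add = _residualize(y[:, None], Zadd)[:, 0]
        rss_add = float(resid_add @ resid_add)
        Zfull = np.column_stack([Zadd, inter])
        resid_full = _residualize(y[:, None], Zfull)[:, 0]
        rss_full = float(resid_full @ resid_full)
        if rss_full <= 0:
            lod[t] = np.inf
        else:
            lod[t] = max(0.0, (N / 2.0) * np.log10(rss_add / rss_full))
    var_name = variable or str(phen["variable"].iloc[0])
    records = []
    for pk in _find_peaks(pos_df, lod, lod_min, min_peak_distance_cM):
        chrom = pos_df.loc[pk, "chrom"]
        left_cm, right_cm = _support_interval(pos_df, lod, pk)
        lm, rm, lbp, rbp = _flanking_markers(geno.gmap, chrom, left_cm, right_cm)
        records.append(
            QTLRecord(
                var_name, chrom, lm, rm, left_cm, right_cm, lbp, rbp,
                float(pos_df.loc[pk, "cM"]), float(lod[pk]), 0.0, 0.0,
                "QEI", "multi",
            )
        )
    return records


# ---------------------------------------------------------------------------
# stable QTLs, mQTL clusters, co-location
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def call_stable(records: list, colocate_window_cM: float = 5.0) -> list[StableQTL]:
    """Group co-locating records per variable; keep groups spanning >= 2
    methods and/or >= 2 environments.  Order-independent: groups are formed by
    transitive closure of peak proximity and sorted deterministically."""
    groups: list[StableQTL] = []
    recs = sorted(records, key=lambda r: (r.variable, r.chrom, r.peak_cM, r.method,
                                          r.environment))
    by_key: dict = {}
    for r in recs:
        by_key.setdefault((r.variable, r.chrom), []).append(r)
    for (variable, chrom), rs in sorted(by_key.items()):
        uf = _UnionFind(len(rs))
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                if abs(rs[i].peak_cM - rs[j].peak_cM) <= colocate_window_cM:
                    uf.union(i, j)
        comps: dict = {}
        for i in range(len(rs)):
            comps.setdefault(uf.find(i), []).append(rs[i])
        for members in comps.values():
            g = StableQTL(
                variable, chrom, members,
                float(np.median([m.peak_cM for m in members])),
                min(m.left_bp for m in members),
                max(m.right_bp for m in members),
                {m.method for m in members},
                {m.environment for m in members},
            )
            groups.append(g)
    groups.sort(key=lambda g: (g.variable, g.chrom, g.peak_cM))
    return [g for g in groups if g.stable]


def merge_mqtl_clusters(records: list, class_map: dict,
                        min_methods: int = 2) -> list[MQTLCluster]:
    """Merge same-class mQTLs with overlapping support intervals (transitive
    closure per chromosome and compound class); a cluster is retained when its
    members collectively span >= ``min_methods`` mapping methods."""
    for r in records:
        if r.variable not in class_map:
            raise ValueError(f"variable {r.variable} has no compound class")
    by_key: dict = {}
    for r in sorted(records, key=lambda r: (r.chrom, r.left_bp, r.right_bp,
                                            r.variable, r.method, r.environment)):
        by_key.setdefault((r.chrom, class_map[r.variable]), []).append(r)
    clusters = []
    for (chrom, cls), rs in sorted(by_key.items()):
        uf = _UnionFind(len(rs))
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                if rs[i].left_bp <= rs[j].right_bp and rs[j].left_bp <= rs[i].right_bp:
                    uf.union(i, j)
        comps: dict = {}
        for i in range(len(rs)):
            comps.setdefault(uf.find(i), []).append(rs[i])
        for members in comps.values():
            methods = {m.method for m in members}
            if len(methods) >= min_methods:
                clusters.append(
                    MQTLCluster(
                        cls, chrom, members,
                        min(m.left_bp for m in members),
                        max(m.right_bp for m in members),
                        methods,
                    )
                )
    clusters.sort(key=lambda c: (c.chrom, c.merged_left_bp, c.category))
    return clusters


def colocate(trait_loci: list, mqtl_clusters: list,
             window_kb: float = 200.0) -> list[tuple]:
    """Pairs of (trait locus, mQTL cluster) whose bp intervals, each padded by
    ``window_kb``, intersect on the same chromosome."""
    pad = int(window_kb * 1000)
    pairs = []
    for t in trait_loci:
        tl, tr = t.left_bp - pad, t.right_bp + pad
        for c in mqtl_clusters:
            if c.chrom != t.chrom:
                continue
            cl, cr = c.merged_left_bp - pad, c.merged_right_bp + pad
            if tl <= cr and cl <= tr:
                pairs.append((t, c))
    return pairs


def records_to_frame(records: list) -> pd.DataFrame:
    rows = [
        {
            "variable": r.variable, "chrom": r.chrom, "left_marker": r.left_marker,
            "right_marker": r.right_marker, "left_cM": r.left_cM,
            "right_cM": r.right_cM, "left_bp": r.left_bp, "right_bp": r.right_bp,
            "peak_cM": r.peak_cM, "LOD": r.lod, "effect": r.effect,
            "r2_pct": r.r2_pct, "method": r.method, "environment": r.environment,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "variable", "chrom", "left_marker", "right_marker", "left_cM", "right_cM",
        "left_bp", "right_bp", "peak_cM", "LOD", "effect", "r2_pct", "method",
        "environment",
    ])
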