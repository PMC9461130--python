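"""Synthetic RIL cohorts with planted, recoverable structure.

Every generator here produces data whose ground truth is known exactly: marker
genotypes descend from an explicit selfing pedigree, phenotypes carry planted
QTL effects, metabolite covariation follows a prescribed precision matrix, and
regulatory inputs (annotations, promoters, expression, PPI) come with a ledger
of every planted edge.  Downstream stages can therefore be scored for recovery
rather than eyeballed.

Genotypes are coded 0/2 (the two parental homozygotes); residual heterozygotes
left after the selfing generations are resolved by a random coin flip.  Map
distances are centimorgans with crossovers drawn from the Haldane (no
interference) model; physical coordinates derive from cM at a constant
``bp_per_cM`` so that kb-scale windows are meaningful on a toy genome.

All randomness flows through one ``numpy`` generator per call, seeded by the
required ``seed`` argument: the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel

DEFAULT_BP_PER_CM = 400_000


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapSpec:
    """Genome layout: chromosome sizes and a uniform marker grid.

    ``chromosomes`` is a list of ``(name, length_cM, length_bp)``; markers are
    placed every ``marker_spacing_cM`` starting at 0, i.e.
    ``floor(length/spacing) + 1`` markers per chromosome.
    """

    chromosomes: tuple
    marker_spacing_cM: float
    bp_per_cM: float = DEFAULT_BP_PER_CM

    def __post_init__(self):
        if self.marker_spacing_cM <= 0 or self.bp_per_cM <= 0:
            raise ValueError("marker spacing and bp_per_cM must be positive")
        for name, len_cm, len_bp in self.chromosomes:
            if len_cm <= 0 or len_bp <= 0:
                raise ValueError(f"chromosome {name}: lengths must be positive")

    @classmethod
    def uniform(cls, n_chrom: int, length_cM: float, marker_spacing_cM: float,
                bp_per_cM: float = DEFAULT_BP_PER_CM) -> "MapSpec":
        chroms = tuple(
            (f"chr{i + 1}", length_cM, length_cM * bp_per_cM) for i in range(n_chrom)
        )
        return cls(chroms, marker_spacing_cM, bp_per_cM)

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for name, len_cm, _len_bp in self.chromosomes:
            n_mark = int(np.floor(len_cm / self.marker_spacing_cM)) + 1
            for k in range(n_mark):
                cm = k * self.marker_spacing_cM
                rows.append(
                    {
                        "marker": f"{name}_m{k + 1}",
                        "chrom": name,
                        "cM": cm,
                        "bp": int(round(cm * self.bp_per_cM)) + 1,
                    }
                )
        return pd.DataFrame(rows)

    def chrom_length_bp(self, chrom: str) -> int:
        for name, _len_cm, len_bp in self.chromosomes:
            if name == chrom:
                return int(len_bp)
        raise KeyError(chrom)


@dataclass(frozen=True)
class QtlSpec:
    """A planted locus effect on one variable.

    ``effect`` is the additive effect per allele substitution on the +/-1
    genotype coding; ``env_effects`` overrides it per environment to plant
    QTL-by-environment interactions (e.g. ``(+a, -a)`` for a crossover QEI).
    """

    target: str
    chrom: str
    pos_cM: float
    effect: float
    env_effects: tuple | None = None
    category: str = "trait"


@dataclass(frozen=True)
class PrecisionSpec:
    """Ground-truth Gaussian graphical model for a metabolome layer."""

    labels: tuple
    omega: np.ndarray
    class_map: dict = field(default_factory=dict)

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if omega.shape != (len(self.labels), len(self.labels)):
            raise ValueError("omega shape does not match labels")
        if not np.allclose(omega, omega.T):
            raise ValueError("omega must be symmetric")
        eigvals = np.linalg.eigvalsh(omega)
        if eigvals.min() <= 0:
            raise ValueError("omega must be positive definite")

    @property
    def p(self) -> int:
        return len(self.labels)

    def partial_correlations(self) -> np.ndarray:
        omega = np.asarray(self.omega, dtype=float)
        d = np.sqrt(np.diag(omega))
        pcor = -omega / np.outer(d, d)
        np.fill_diagonal(pcor, 1.0)
        return pcor


@dataclass
class GenotypeData:
    """RIL genotypes plus map and cross-of-origin covariate."""

    geno: pd.DataFrame        # lines x markers, codes {0, 2}
    gmap: pd.DataFrame        # marker, chrom, cM, bp
    cross: pd.Series          # line -> "OC" | "RC"

    @property
    def lines(self) -> pd.Index:
        return self.geno.index

    def signed(self) -> pd.DataFrame:
        """Genotypes recoded to -1/+1."""
        return self.geno - 1

    def covariate(self) -> pd.Series:
        """0/1 numeric cross-of-origin covariate (OC=0, RC=1)."""
        return (self.cross == "RC").astype(float)

    def marker_position(self, marker: str) -> tuple[str, float]:
        row = self.gmap.loc[self.gmap["marker"] == marker].iloc[0]
        return row["chrom"], float(row["cM"])


# ---------------------------------------------------------------------------
# RIL population
# ---------------------------------------------------------------------------

def haldane_r(d_cM: np.ndarray) -> np.ndarray:
    """Per-meiosis recombination fraction for a map distance (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ril_selfing_R(r: np.ndarray) -> np.ndarray:
    """Expected RIL (F-infinity selfing) recombinant fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per line from a diploid (vectorized over lines).

    Crossover events are realized at marker loci via a two-state Markov chain
    whose switch probability per interval is the Haldane recombination
    fraction; marginally this is exact for genotypes observed at markers.
    """
    n, m = hap_a.shape
    pick = np.empty((n, m), dtype=bool)
    pick[:, 0] = rng.random(n) < 0.5
    if m > 1:
        switches = rng.random((n, m - 1)) < r[None, :]
        # cumulative XOR along markers turns switch indicators into states
        pick[:, 1:] = pick[:, [0]] ^ np.logical_xor.accumulate(switches, axis=1)
    return np.where(pick, hap_a, hap_b)


def simulate_ril_population(map_spec: MapSpec, n_lines: int, n_oc: int,
                            seed: int, generations: int = 6) -> GenotypeData:
    """Simulate a biparental RIL population by ``generations`` of selfing.

    Each line descends from its own F1; gametes recombine under the Haldane
    model.  After selfing, residual heterozygous calls (a few percent at G=6)
    are resolved to a random homozygote.  The first ``n_oc`` lines carry the
    OC (orthogonal cross) label, the rest RC (reciprocal cross).
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    if not 0 <= n_oc <= n_lines:
        raise ValueError("n_oc must lie in [0, n_lines]")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    gmap = map_spec.marker_table()
    geno_blocks = []
    for name, _len_cm, _len_bp in map_spec.chromosomes:
        sub = gmap.loc[gmap["chrom"] == name]
        cm = sub["cM"].to_numpy()
        r = haldane_r(np.diff(cm))
        m = len(cm)
        hap_a = np.zeros((n_lines, m), dtype=np.int8)   # parent 1 allele = 0
        hap_b = np.ones((n_lines, m), dtype=np.int8)    # parent 2 allele = 1
        for _ in range(generations):
            gam1 = _meiosis(hap_a, hap_b, r, rng)
            gam2 = _meiosis(hap_a, hap_b, r, rng)
            hap_a, hap_b = gam1, gam2
        dosage = hap_a.astype(np.int16) + hap_b.astype(np.int16)  # 0/1/2
        het = dosage == 1
        dosage[het] = rng.integers(0, 2, size=int(het.sum())) * 2
        geno_blocks.append(dosage)
    geno = pd.DataFrame(
        np.hstack(geno_blocks),
        index=pd.Index([f"RIL{i + 1:04d}" for i in range(n_lines)], name="line"),
        columns=gmap["marker"].tolist(),
        dtype=int,
    )
    cross = pd.Series(
        ["OC" if i < n_oc else "RC" for i in range(n_lines)],
        index=geno.index,
        name="cross",
    )
    return GenotypeData(geno, gmap, cross)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _nearest_marker(geno: GenotypeData, chrom: str, pos_cM: float) -> str:
    sub = geno.gmap.loc[geno.gmap["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"chromosome {chrom} not on the map")
    max_cm = sub["cM"].max()
    if not 0 <= pos_cM <= max_cm:
        raise ValueError(f"position {pos_cM} cM outside chromosome {chrom} [0, {max_cm}]")
    idx = (sub["cM"] - pos_cM).abs().idxmin()
    return sub.loc[idx, "marker"]


def genetic_values(geno: GenotypeData, qtls: list[QtlSpec],
                   environments: list[str]) -> dict[str, pd.DataFrame]:
    """Per-environment genetic value of each line for each QTL target."""
    targets = sorted({q.target for q in qtls})
    out = {
        env: pd.DataFrame(0.0, index=geno.lines, columns=targets)
        for env in environments
    }
    signed = geno.signed()
    for q in qtls:
        x = signed[_nearest_marker(geno, q.chrom, q.pos_cM)].astype(float)
        if q.env_effects is not None:
            if len(q.env_effects) != len(environments):
                raise ValueError(
                    f"QTL {q.target}@{q.chrom}:{q.pos_cM}: env_effects length "
                    f"{len(q.env_effects)} != {len(environments)} environments"
                )
            for env, a in zip(environments, q.env_effects):
                out[env][q.target] += a * x
        else:
            for env in environments:
                out[env][q.target] += q.effect * x
    return out


def simulate_trait_phenotypes(geno: GenotypeData, qtls: list[QtlSpec], h2: float,
                              environments: list[str], seed: int,
                              env_means: dict | None = None) -> pd.DataFrame:
    """Trait values = planted QTL effects + environment mean + Gaussian noise.

    The residual variance is set per environment from the realized genetic
    variance so that broad-sense heritability matches ``h2``; ``h2 = 0``
    zeroes the genetic contribution entirely.
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    env_means = env_means or {}
    gvals = genetic_values(geno, qtls, environments)
    targets = sorted({q.target for q in qtls})
    rows = []
    for env in environments:
        for trait in targets:
            g = gvals[env][trait].to_numpy()
            if h2 == 0:
                g = np.zeros_like(g)
                sigma_e = 1.0
            else:
                var_g = g.var()
                sigma_e = np.sqrt(var_g * (1 - h2) / h2) if var_g > 0 else 1.0
            y = g + env_means.get(env, 0.0) + rng.normal(0.0, sigma_e, size=len(g))
            rows.append(
                pd.DataFrame(
                    {
                        "line": geno.lines,
                        "environment": env,
                        "variable": trait,
                        "value": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_metabolome(prec: PrecisionSpec, geno: GenotypeData,
                        mqtls: list[QtlSpec], n_reps: int, seed: int,
                        rep_noise_sd: float = 0.5) -> pd.DataFrame:
    """Replicated metabolite/lipid measurements with a known GGM backbone.

    Per-line latent effects are drawn from N(0, omega^-1); planted mQTL
    effects are added on the latent (log) scale; each biological replicate is
    the latent value plus replicate noise.  Stored measurements are ``2**x``
    so they are strictly positive — the analysis log2-transforms them back.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    n = len(geno.lines)
    cov = np.linalg.inv(np.asarray(prec.omega, dtype=float))
    latent = rng.multivariate_normal(np.zeros(prec.p), cov, size=n, method="cholesky")
    latent = pd.DataFrame(latent, index=geno.lines, columns=list(prec.labels))
    signed = geno.signed()
    for q in mqtls:
        if q.target not in latent.columns:
            raise ValueError(f"mQTL target {q.target} not among metabolome labels")
        x = signed[_nearest_marker(geno, q.chrom, q.pos_cM)].astype(float)
        latent[q.target] += q.effect * x
    rows = []
    for rep in range(1, n_reps + 1):
        noise = rng.normal(0.0, rep_noise_sd, size=latent.shape)
        vals = latent.to_numpy() + noise
        block = pd.DataFrame(vals, index=geno.lines, columns=latent.columns)
        long = block.reset_index().melt(
            id_vars="line", var_name="variable", value_name="value"
        )
        long["environment"] = f"rep{rep}"
        rows.append(long[["line", "environment", "variable", "value"]])
    table = pd.concat(rows, ignore_index=True)
    table["value"] = np.exp2(table["value"])
    return table


# ---------------------------------------------------------------------------
# regulatory ground truth
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class RegulatoryTruth:
    """Bundle of regulatory-layer inputs plus the planted-edge ledger."""

    features: list            # GeneModel for genes, TFs, miRNAs
    promoters: dict           # gene id -> promoter sequence (5'->3')
    transcripts: dict         # gene id -> transcript sequence
    mirna_seqs: dict          # miRNA id -> mature sequence (5'->3')
    atlas_expr: pd.DataFrame  # genes x tissues FPKM
    stage_expr: pd.DataFrame  # genes x developmental stages FPKM
    deg_counts: pd.DataFrame  # genes x {high_oil, low_oil} read counts
    lfc: pd.DataFrame         # node x stage log2 fold-changes (genes + miRNAs)
    ppi: pd.DataFrame         # gene_a, gene_b, score
    ledger: dict              # planted edges and locus memberships


TISSUES = ["young_leaf", "flower", "pod", "pod_shell", "root", "nodule", "seed"]
STAGES = ["15DAF", "25DAF", "35DAF", "45DAF", "55DAF"]


def simulate_regulatory_truth(map_spec: MapSpec, loci: list[dict], pwm,
                              seed: int, tf_id: str = "TF001",
                              decoy_genes: int = 20,
                              promoter_len: int = 2000,
                              mirna_len: int = 21) -> RegulatoryTruth:
    """Plant a recoverable regulatory layer around a set of genomic loci.

    ``loci`` is a list of dicts with keys ``id``, ``chrom``, ``start_bp``,
    ``end_bp`` and optional booleans ``gene`` (plant a causal gene, default
    True), ``mirna`` (plant a miRNA targeting that gene), ``decoy`` (plant an
    in-window gene that fails the expression filters).  Each causal gene gets:
    a seed-dominant tissue profile, a 55-DAF-high stage profile, a
    differential high/low-oil count pair, a promoter carrying the PWM
    consensus, a transcript carrying a perfect-complement site for its miRNA,
    a TF binding edge (shared TF, motif in promoter, correlated stage
    profile) and a PPI edge to the TF.  Decoy genes elsewhere get flat,
    sub-threshold profiles.  Every planted relationship is recorded in the
    returned ledger.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    features: list[GeneModel] = []
    promoters: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    mirna_seqs: dict[str, str] = {}
    ledger: dict = {
        "tf_edges": [], "mirna_edges": [], "ppi_edges": [],
        "coexpr_pairs": [], "locus_genes": {}, "locus_mirnas": {},
    }
    consensus = pwm.consensus()

    atlas_rows, stage_rows, deg_rows, lfc_rows = {}, {}, {}, {}
    # rising toward 55 DAF; the late stage clears twice the stage mean even
    # after +/-10% multiplicative noise
    base_profile = np.array([4.0, 6.0, 9.0, 14.0, 60.0])

    def plant_gene(gid: str, chrom: str, start: int, biotype: str = "gene"):
        length = 3000
        features.append(GeneModel(gid, chrom, start, start + length - 1, "+", biotype))
        prom = _random_seq(rng, promoter_len)
        pos = int(rng.integers(200, promoter_len - len(consensus) - 200))
        prom = prom[:pos] + consensus + prom[pos + len(consensus):]
        promoters[gid] = prom
        transcripts[gid] = _random_seq(rng, 600)
        # seed-dominant atlas profile: seed max and >= 2x second highest
        other = rng.uniform(1.0, 4.0, size=len(TISSUES) - 1)
        atlas_rows[gid] = np.append(other, other.max() * rng.uniform(2.5, 4.0))
        stage_rows[gid] = base_profile * rng.uniform(0.9, 1.1, size=len(STAGES))
        deg_rows[gid] = (int(rng.integers(800, 1200)), int(rng.integers(30, 80)))
        lfc_rows[gid] = np.log2(
            (np.array(deg_rows[gid][0], dtype=float) + 1) / (deg_rows[gid][1] + 1)
        ) * np.ones(len(STAGES))
        return gid

    # shared transcription factor on the first locus chromosome, outside windows
    tf_chrom = loci[0]["chrom"] if loci else map_spec.chromosomes[0][0]
    plant_gene(tf_id, tf_chrom, 1000, biotype="TF")

    causal_genes = []
    for k, locus in enumerate(loci):
        lid = locus["id"]
        chrom = locus["chrom"]
        mid = (int(locus["start_bp"]) + int(locus["end_bp"])) // 2
        ledger["locus_genes"][lid] = []
        ledger["locus_mirnas"][lid] = []
        if locus.get("gene", True):
            gid = f"Gene{k + 1:03d}"
            plant_gene(gid, chrom, mid)
            causal_genes.append(gid)
            ledger["locus_genes"][lid].append(gid)
            ledger["tf_edges"].append([tf_id, gid])
            ledger["coexpr_pairs"].append([tf_id, gid])
            ledger["ppi_edges"].append([tf_id, gid])
        if locus.get("mirna", False) and locus.get("gene", True):
            rid = f"miR{k + 1:03d}"
            gid = ledger["locus_genes"][lid][0]
            mir = _random_seq(rng, mirna_len)
            mirna_seqs[rid] = mir
            site = reverse_complement(mir)
            tx = transcripts[gid]
            site_pos = 200
            transcripts[gid] = tx[:site_pos] + site + tx[site_pos + len(site):]
            mstart = mid + 50_000
            features.append(
                GeneModel(rid, chrom, mstart, mstart + mirna_len * 5, "+", "miRNA")
            )
            ledger["mirna_edges"].append([rid, gid])
            ledger["locus_mirnas"][lid].append(rid)
            lfc_rows[rid] = -lfc_rows[gid]  # opposite pattern to its target
        if locus.get("decoy", True):
            did = f"Decoy{k + 1:03d}w"
            start = mid + 80_000
            features.append(GeneModel(did, chrom, start, start + 2999, "+", "gene"))
            promoters[did] = _random_seq(rng, promoter_len)
            transcripts[did] = _random_seq(rng, 600)
            atlas_rows[did] = np.full(len(TISSUES), 0.5)  # FPKM < 1 everywhere
            stage_rows[did] = np.full(len(STAGES), 0.5)
            deg_rows[did] = (50, 50)
            lfc_rows[did] = np.zeros(len(STAGES))

    # off-window decoy genes spread across the genome
    chrom_names = [c[0] for c in map_spec.chromosomes]
    for d in range(decoy_genes):
        did = f"Decoy{d + 1:03d}"
        chrom = chrom_names[d % len(chrom_names)]
        start = int(rng.integers(1, map_spec.chrom_length_bp(chrom) - 5000))
        features.append(GeneModel(did, chrom, start, start + 2999, "+", "gene"))
        promoters[did] = _random_seq(rng, promoter_len)
        transcripts[did] = _random_seq(rng, 600)
        atlas_rows[did] = rng.uniform(2.0, 10.0, size=len(TISSUES))  # not seed-specific
        stage_rows[did] = rng.uniform(3.0, 6.0, size=len(STAGES))
        n_reads = int(rng.integers(100, 300))
        deg_rows[did] = (n_reads, n_reads)
        lfc_rows[did] = np.zeros(len(STAGES))

    # stage co-expression: TF and causal genes share the rising profile (planted
    # above); add below-threshold PPI decoys between off-window genes
    for g1, g2 in zip(list(promoters)[-decoy_genes::2], list(promoters)[-decoy_genes + 1::2]):
        ledger.setdefault("ppi_decoys", []).append([g1, g2])

    atlas_expr = pd.DataFrame.from_dict(atlas_rows, orient="index", columns=TISSUES)
    atlas_expr.index.name = "gene"
    stage_expr = pd.DataFrame.from_dict(stage_rows, orient="index", columns=STAGES)
    stage_expr.index.name = "gene"
    deg_counts = pd.DataFrame.from_dict(
        deg_rows, orient="index", columns=["high_oil", "low_oil"]
    )
    deg_counts.index.name = "gene"
    lfc = pd.DataFrame.from_dict(lfc_rows, orient="index", columns=STAGES)
    lfc.index.name = "node"

    ppi_rows = [
        {"gene_a": a, "gene_b": b, "score": round(float(rng.uniform(0.6, 0.95)), 3)}
        for a, b in ledger["ppi_edges"]
    ]
    ppi_rows += [
        {"gene_a": a, "gene_b": b, "score": round(float(rng.uniform(0.05, 0.35)), 3)}
        for a, b in ledger.get("ppi_decoys", [])
    ]
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "score"])

    return RegulatoryTruth(
        features, promoters, transcripts, mirna_seqs, atlas_expr, stage_expr,
        deg_counts, lfc, ppi, ledger,
    )
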