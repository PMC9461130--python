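from itertools import product

import numpy as np
import pandas as pd
import pytest

from mdgnet import grn
from mdgnet.pipeline import demo_pwm


@pytest.fixture(scope="module")
def random_pwm():
    rng = np.random.default_rng(50)
    mat = rng.dirichlet(np.ones(4) * 0.7, size=6).T
    return grn.PWM("rand6", mat)


class TestPWM:
    def test_column_sums_validated(self):
        bad = np.full((4, 5), 0.3)
        with pytest.raises(ValueError):
            grn.PWM("bad", bad)

    def test_meme_round_trip(self, tmp_path, random_pwm):
        grn.write_meme([random_pwm, demo_pwm()], tmp_path / "m.meme")
        back = grn.read_meme(tmp_path / "m.meme")
        assert [p.name for p in back] == ["rand6", demo_pwm().name]
        assert np.allclose(back[0].matrix, random_pwm.matrix, atol=1e-6)

    def test_dp_pvalues_equal_exhaustive_enumeration(self, random_pwm):
        ints = grn._binned_scores(random_pwm, 0.01)
        lo, tail = grn._score_pvalue_table(ints, random_pwm.background)
        enum = {}
        for word in product(range(4), repeat=6):
            s = sum(int(ints[b, j]) for j, b in enumerate(word))
            p = float(np.prod([random_pwm.background[b] for b in word]))
            enum[s] = enum.get(s, 0.0) + p
        for k in range(lo, lo + len(tail)):
            expect = sum(p for s, p in enum.items() if s >= k)
            assert abs(tail[k - lo] - expect) < 1e-6

    def test_consensus_is_top_hit(self, random_pwm):
        prom = "A" * 40 + random_pwm.consensus() + "C" * 40
        hits = grn.pwm_scan(prom, random_pwm, p_max=1.0)
        best = min(hits, key=lambda h: (h.p_value, -h.score))
        assert best.position == 41 and best.strand == "+"

    def test_uniform_pwm_scores_zero_no_hits(self):
        uniform = grn.PWM("u", np.full((4, 6), 0.25))
        hits = grn.pwm_scan("ACGT" * 30, uniform, p_max=1e-4)
        assert hits == []

    def test_pvalues_monotone_in_score(self, random_pwm):
        rng = np.random.default_rng(51)
        prom = "".join(rng.choice(list("ACGT"), size=400))
        hits = grn.pwm_scan(prom, random_pwm, p_max=1.0)
        by_score = sorted(hits, key=lambda h: h.score)
        for a, b in zip(by_score[:-1], by_score[1:]):
            assert a.p_value >= b.p_value - 1e-12

    def test_reverse_complement_promoter_symmetry(self, random_pwm):
        rng = np.random.default_rng(52)
        prom = "".join(rng.choice(list("ACGT"), size=300))
        fwd = grn.pwm_scan(prom, random_pwm, p_max=1e-2)
        rev = grn.pwm_scan(grn.reverse_complement(prom), random_pwm, p_max=1e-2)
        L = random_pwm.length
        mirrored = {(len(prom) - h.position - L + 2,
                     "+" if h.strand == "-" else "-",
                     round(h.score, 6)) for h in rev}
        assert {(h.position, h.strand, round(h.score, 6)) for h in fwd} == mirrored

    def test_n_windows_skipped(self, random_pwm):
        prom = "A" * 10 + "N" + "A" * 10
        hits = grn.pwm_scan(prom, random_pwm, p_max=1.0)
        L = random_pwm.length
        for h in hits:
            assert not (h.position <= 11 <= h.position + L - 1)


class TestMirnaTargets:
    MIR = "ACGGTAAGCTAGGCTGAGCGT"  # 21 nt, position 16 is G

    def test_perfect_complement_scores_zero(self):
        site = grn.reverse_complement(self.MIR)
        hits = grn.mirna_target_score(self.MIR, "A" * 25 + site + "G" * 25)
        assert any(h.expectation == 0.0 and h.position == 26 for h in hits)

    def test_seed_mismatch_scores_two(self):
        L = len(self.MIR)
        site = list(grn.reverse_complement(self.MIR))
        # break the pairing of miRNA position 5 with a non-wobble mismatch
        m5 = self.MIR[4]
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        wobble = {"G": "T", "T": "G"}
        bad = next(b for b in "ACGT"
                   if b != comp[m5] and wobble.get(m5) != b)
        site[L - 5] = bad
        hits = grn.mirna_target_score(self.MIR, "".join(site))
        assert hits[0].expectation == 2.0

    def test_wobble_outside_seed_scores_half(self):
        L = len(self.MIR)
        site = list(grn.reverse_complement(self.MIR))
        site[L - 16] = "T"  # miRNA G16 : target U
        hits = grn.mirna_target_score(self.MIR, "".join(site))
        assert hits[0].expectation == 0.5

    def test_invariant_to_transcript_padding(self):
        site = grn.reverse_complement(self.MIR)
        short = grn.mirna_target_score(self.MIR, site)
        padded = grn.mirna_target_score(self.MIR, "ACGT" * 10 + site + "TGCA" * 10)
        assert min(h.expectation for h in short) == min(
            h.expectation for h in padded)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            grn.mirna_target_score("ACGT", "ACGT" * 20)
        with pytest.raises(ValueError):
            grn.mirna_target_score(self.MIR, "ACGTX" * 10)


class TestCoexpression:
    def test_boundary_strictly_greater(self):
        # two profiles engineered to correlate at exactly 0.8
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = 0.8 * (a - a.mean()) / a.std() + np.array([0.6, -0.6, 0.0, -0.6, 0.6])
        # construct exact r = 0.8 via orthogonal residual
        resid = np.array([1.0, -1.0, 0.0, -1.0, 1.0])
        resid -= resid.mean()
        resid -= resid @ (a - a.mean()) / ((a - a.mean()) @ (a - a.mean())) * (a - a.mean())
        z = (a - a.mean()) / np.linalg.norm(a - a.mean())
        w = resid / np.linalg.norm(resid)
        b = 0.8 * z + 0.6 * w
        expr = pd.DataFrame([a, b], index=["g1", "g2"])
        r = float(grn.coexpression_matrix(expr).loc["g1", "g2"])
        assert r == pytest.approx(0.8, abs=1e-12)
        # r_min equal to the pair's correlation: strict > means no edge
        assert grn.coexpression_edges(expr, r_min=r) == []
        assert [(x, y) for x, y, _ in grn.coexpression_edges(expr, r_min=0.79)] \
            == [("g1", "g2")]

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(53)
        expr = pd.DataFrame(rng.normal(size=(20, 8)),
                            index=[f"g{i}" for i in range(20)])
        edges = {(a, b) for a, b, _ in grn.coexpression_edges(expr, r_min=0.3)}
        C = np.corrcoef(expr.to_numpy())
        expect = {(f"g{i}", f"g{j}") for i in range(20) for j in range(i + 1, 20)
                  if C[i, j] > 0.3}
        assert edges == expect

    def test_constant_profile_skipped(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]],
                            index=["flat", "g"])
        assert grn.coexpression_edges(expr, r_min=0.8) == []


class TestOppositePattern:
    def test_sign_cases(self):
        stages = ["15DAF", "55DAF"]
        mk = lambda v: pd.Series(v, index=stages)
        assert grn.opposite_pattern(mk([0.0, 1.2]), mk([0.0, -0.8]), "55DAF")
        assert not grn.opposite_pattern(mk([0, 1.2]), mk([0, 0.3]), "55DAF")
        assert not grn.opposite_pattern(mk([0, 0.0]), mk([0, -0.8]), "55DAF")

    def test_missing_stage_warns_false(self):
        with pytest.warns(UserWarning):
            assert not grn.opposite_pattern(
                pd.Series({"15DAF": 1.0}), pd.Series({"15DAF": -1.0}), "55DAF")


class TestAssembleGrn:
    def _expr(self, pairs_corr: dict) -> pd.DataFrame:
        base = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        rows = {}
        for g, corr in pairs_corr.items():
            rows[g] = base if corr else base[::-1].copy()
        return pd.DataFrame(rows).T

    def test_coexpression_gate(self):
        expr = self._expr({"TF1": True, "gHi": True, "gLo": False})
        net = grn.assemble_grn(
            {"gHi", "gLo"}, {"TF1"}, set(),
            motif_hits=[("TF1", "gHi"), ("TF1", "gLo")],
            target_hits=[], ppi_edges=None, expr=expr,
        )
        pairs = {(e.a, e.b) for e in net.edges}
        assert ("TF1", "gHi") in pairs and ("TF1", "gLo") not in pairs

    def test_mirna_edge_passes_without_expression(self):
        expr = self._expr({"g1": True})
        net = grn.assemble_grn({"g1"}, set(), {"miR1"}, [], [("miR1", "g1")],
                               None, expr)
        assert [(e.a, e.b, e.provenance) for e in net.edges] == \
            [("miR1", "g1", "mirna_target")]

    def test_ppi_score_threshold(self):
        expr = self._expr({"g1": True, "g2": True, "g3": True})
        ppi = pd.DataFrame({"gene_a": ["g1", "g1"], "gene_b": ["g2", "g3"],
                            "score": [0.41, 0.40]})
        net = grn.assemble_grn({"g1", "g2", "g3"}, set(), set(), [], [], ppi, expr)
        pairs = {(e.a, e.b) for e in net.edges}
        assert ("g1", "g2") in pairs and ("g1", "g3") not in pairs

    def test_planted_regulations_recovered(self, toy_map):
        from mdgnet import simulate as sim

        loci = [
            {"id": f"L{k}", "chrom": f"chr{k % 5 + 1}",
             "start_bp": 5_000_000 + k * 2_000_000,
             "end_bp": 5_200_000 + k * 2_000_000, "mirna": True}
            for k in range(10)
        ]
        truth = sim.simulate_regulatory_truth(toy_map, loci, demo_pwm(), seed=54)
        genes = {g for _, g in truth.ledger["tf_edges"]}
        pwm = demo_pwm()
        motif_pairs = []
        for g in sorted(genes):
            if grn.pwm_scan(truth.promoters[g], pwm, p_max=1e-4):
                motif_pairs.append(("TF001", g))
        target_pairs = []
        for mir, g in truth.ledger["mirna_edges"]:
            if grn.mirna_target_score(truth.mirna_seqs[mir], truth.transcripts[g]):
                target_pairs.append((mir, g))
        net = grn.assemble_grn(
            genes, {"TF001"}, set(truth.mirna_seqs), motif_pairs, target_pairs,
            truth.ppi, truth.stage_expr,
        )
        planted = (
            {(a, b, "tfbs") for a, b in truth.ledger["tf_edges"]}
            | {(a, b, "mirna_target") for a, b in truth.ledger["mirna_edges"]}
            | {(a, b, "ppi") for a, b in truth.ledger["ppi_edges"]}
        )
        got = {(e.a, e.b, e.provenance) for e in net.edges}
        recall = len(planted & got) / len(planted)
        precision = len(planted & got) / len(got)
        assert len(planted) == 30
        assert recall >= 0.8
        assert precision >= 0.9
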