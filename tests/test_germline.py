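"""Germline modeling: identity, clustering, anchors, functionality, motifs."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from equitrb.germline import (
    Defect,
    Functionality,
    FunctionalityRules,
    GeneType,
    GermlineGene,
    RecombinationSignal,
    check_j_motif,
    classify_functionality,
    cluster_subgroups,
    find_anchors,
    identity_matrix,
    pairwise_identity,
    validate_rs,
)
from oracles import nw_identity_oracle, transitive_closure_components

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_single_mismatch(self):
        assert pairwise_identity("ACGTACGT", "ACGTACCT") == 87.5

    def test_n_matches_nothing(self):
        # N against A is a mismatch even though bases are 'compatible'
        assert pairwise_identity("ANGT", "AAGT") == 75.0
        assert pairwise_identity("NNNN", "NNNN") < 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_planted_mismatches_match_oracle(self, rng):
        """300 nt with 60 planted mismatches: ~80% identity, and the
        value must equal the quadratic DP oracle exactly."""
        a = "".join(rng.choice(list("ACGT"), 300))
        pos = rng.choice(300, size=60, replace=False)
        b = list(a)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        got = pairwise_identity(a, b)
        assert got == pytest.approx(nw_identity_oracle(a, b), abs=0)
        assert 75.0 <= got <= 85.0

    def test_random_suite_equals_oracle(self, rng):
        for _ in range(60):
            la, lb = rng.integers(1, 50, size=2)
            a = "".join(rng.choice(list("ACGTN"), la))
            b = "".join(rng.choice(list("ACGTN"), lb))
            assert pairwise_identity(a, b) == nw_identity_oracle(a, b), (a, b)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(a=DNA, b=DNA)
    def test_symmetry_and_reflexivity(self, a, b):
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        assert pairwise_identity(a, a) == 100.0

    def test_identity_matrix_agrees_with_scalar(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), int(n)))
                for n in rng.integers(10, 40, size=6)]
        mat = identity_matrix(seqs)
        for i in range(6):
            for j in range(6):
                expect = 100.0 if i == j else pairwise_identity(seqs[i], seqs[j])
                assert mat[i, j] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# subgroup clustering
# ---------------------------------------------------------------------------

def _v_gene(name, seq):
    return GermlineGene(name=name, gene_type=GeneType.V, coding_nt=seq,
                        v_region_start=0)


class TestClusterSubgroups:
    def test_identical_genes_one_subgroup(self):
        genes = [_v_gene(f"G{i}", "ACGT" * 30) for i in range(3)]
        mapping = cluster_subgroups(genes)
        assert len(set(mapping.values())) == 1

    def test_single_linkage_chain(self, rng):
        """A-B and B-C above threshold but A-C far below: one subgroup, the
        chain membership the published analysis also observed."""
        a = "".join(rng.choice(list("ACGT"), 120))

        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        # scattered mutations so the free-end-gap alignment cannot skip a
        # contiguous mutated block
        b = mutate(a, range(0, 120, 6))      # 20 diffs: ident(a,b) ~ 83
        c = mutate(b, range(3, 120, 5))      # 24 more:  ident(b,c) ~ 80
        genes = [_v_gene("A", a), _v_gene("B", b), _v_gene("C", c)]
        assert pairwise_identity(a, b) > 75
        assert pairwise_identity(b, c) > 75
        assert pairwise_identity(a, c) < 75
        mapping = cluster_subgroups(genes)
        assert len(set(mapping.values())) == 1

    def test_two_families_match_closure_oracle(self, rng):
        """Two 5-gene families over disjoint alphabets: intra-family
        identity > 90, inter-family 0; exactly two subgroups, identical to
        the brute-force transitive closure of the identity matrix."""
        def family(alphabet, n):
            base = "".join(rng.choice(list(alphabet), 120))
            members = []
            for _ in range(n):
                seq = list(base)
                for p in rng.choice(120, size=4, replace=False):
                    seq[p] = alphabet[0] if seq[p] != alphabet[0] else alphabet[1]
                members.append("".join(seq))
            return members

        seqs = family("AC", 5) + family("GT", 5)
        genes = [_v_gene(f"G{i}", s) for i, s in enumerate(seqs)]
        mat = identity_matrix(seqs)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert mat[i, j] > 90
                    assert mat[i + 5, j + 5] > 90
                assert mat[i, j + 5] < 60
        mapping = cluster_subgroups(genes)
        labels = [mapping[g.name] for g in genes]
        assert len(set(labels)) == 2
        expected = transitive_closure_components(mat.tolist(), 75.0)
        got = {}
        for idx, lab in enumerate(labels):
            got.setdefault(lab, set()).add(idx)
        assert sorted(map(sorted, got.values())) == sorted(map(sorted, expected))

    def test_permutation_invariance(self, rng):
        seqs = (["".join(rng.choice(list("AC"), 90)) for _ in range(3)]
                + ["".join(rng.choice(list("GT"), 90)) for _ in range(3)])
        genes = [_v_gene(f"G{i}", s) for i, s in enumerate(seqs)]
        base = cluster_subgroups(genes)
        perm = [genes[i] for i in rng.permutation(len(genes))]
        permuted = cluster_subgroups(perm)

        def partition(mapping):
            groups = {}
            for name, lab in mapping.items():
                groups.setdefault(lab, set()).add(name)
            return sorted(map(sorted, groups.values()))

        assert partition(base) == partition(permuted)

    def test_empty_input(self):
        assert cluster_subgroups([]) == {}

    def test_rejects_non_v(self):
        g = GermlineGene(name="TRBD1", gene_type=GeneType.D, coding_nt="GGG")
        with pytest.raises(ValueError):
            cluster_subgroups([g])


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _region(n_codons, plant=None):
    codons = ["GCA"] * n_codons
    for idx, codon in (plant or {}).items():
        codons[idx] = codon
    return "".join(codons)


class TestFindAnchors:
    def test_planted_anchors_found(self):
        region = _region(60, {22: "TGT", 40: "TGG", 57: "TGC"})
        anchors = find_anchors(region)
        assert anchors.cys23_pos == 22
        assert anchors.trp41_pos == 40
        assert anchors.cys104_pos == 57          # 3rd from last of 60 codons
        assert anchors.all_found

    def test_no_cysteine_reports_not_found(self):
        region = _region(60, {40: "TGG"})
        anchors = find_anchors(region)
        assert not anchors.found["cys23"] and not anchors.found["cys104"]
        gene = GermlineGene(name="V", gene_type=GeneType.V, coding_nt=region,
                            v_region_start=0)
        call = classify_functionality(gene)
        assert call.status is Functionality.P
        assert Defect.MISSING_ANCHOR in call.defects

    def test_non_acgt_codon_not_matched(self):
        region = _region(60, {22: "TGN", 40: "TGG", 57: "TGC"})
        anchors = find_anchors(region)
        assert not anchors.found["cys23"]

    def test_simulated_functional_v_anchor_recovery(self, germline):
        """Anchors recovered at the constructed positions for every
        functional simulated V gene."""
        assert len(germline.functional_v) >= 20
        for g in germline.functional_v:
            anchors = find_anchors(g.v_region)
            assert (anchors.cys23_pos, anchors.trp41_pos, anchors.cys104_pos) \
                == (22, 40, 104), g.name


# ---------------------------------------------------------------------------
# functionality classification
# ---------------------------------------------------------------------------

def _intact_v(tail_last="GCC"):
    codons = ["ATG"] + ["GCA"] * 15
    region = ["GCA"] * 108
    region[22], region[40], region[104] = "TGT", "TGG", "TGC"
    region[107] = tail_last
    rs = RecombinationSignal("CACAGTG", "A" * 23, "ACAAAAACC")
    return GermlineGene(name="V", gene_type=GeneType.V,
                        coding_nt="".join(codons + region),
                        v_region_start=48, rs_3prime=rs)


class TestClassifyFunctionality:
    def test_intact_gene_functional(self):
        call = classify_functionality(_intact_v())
        assert call.status is Functionality.F
        assert call.defects == ()

    def test_terminal_stop_only_is_functional(self):
        """A stop codon confined to the last V-REGION codon does not
        disqualify the gene: the rearrangement usually removes it."""
        call = classify_functionality(_intact_v(tail_last="TAA"))
        assert call.status is Functionality.F
        assert call.defects == (Defect.TERMINAL_STOP_ONLY,)

    def test_internal_stop_is_pseudogene(self):
        gene = _intact_v()
        region = list(gene.coding_nt)
        region[48 + 50 * 3:48 + 50 * 3 + 3] = "TGA"
        gene.coding_nt = "".join(region)
        call = classify_functionality(gene)
        assert call.status is Functionality.P
        assert Defect.INTERNAL_STOP in call.defects

    def test_frameshift_and_missing_start(self):
        gene = _intact_v()
        gene.coding_nt = gene.coding_nt[:100] + gene.coding_nt[101:]
        assert classify_functionality(gene).status is Functionality.P

        gene2 = _intact_v()
        gene2.coding_nt = "ATA" + gene2.coding_nt[3:]
        call2 = classify_functionality(gene2)
        assert call2.status is Functionality.P
        assert Defect.MISSING_START in call2.defects

    def test_poor_rs_yields_orf(self):
        gene = _intact_v()
        gene.rs_3prime = RecombinationSignal("TTTTTTT", "A" * 23, "GGGGGGGGG")
        call = classify_functionality(gene)
        assert call.status is Functionality.ORF
        assert call.defects == (Defect.DEFECTIVE_RS,)

    def test_monotone_under_added_defects(self):
        """Adding a defect never upgrades the status toward F."""
        order = {Functionality.F: 2, Functionality.ORF: 1, Functionality.P: 0}
        base = classify_functionality(_intact_v())
        for breaker in ("internal_stop", "missing_start", "frameshift"):
            gene = _intact_v()
            gene.rs_3prime = RecombinationSignal("TTTTTTT", "A" * 23, "GGGGGGGGG")
            if breaker == "internal_stop":
                s = list(gene.coding_nt)
                s[48 + 150:48 + 153] = "TAA"
                gene.coding_nt = "".join(s)
            elif breaker == "missing_start":
                gene.coding_nt = "ATA" + gene.coding_nt[3:]
            else:
                gene.coding_nt = gene.coding_nt[:-1]
            assert order[classify_functionality(gene).status] <= order[base.status]

    def test_rules_switchable(self):
        gene = _intact_v()
        gene.coding_nt = "ATA" + gene.coding_nt[3:]
        rules = FunctionalityRules(check_missing_start=False)
        assert classify_functionality(gene, rules).status is Functionality.F

    def test_gene_without_coding_rejected(self):
        gene = GermlineGene(name="X", gene_type=GeneType.V, coding_nt="",
                            v_region_start=0)
        with pytest.raises(ValueError):
            classify_functionality(gene)


# ---------------------------------------------------------------------------
# recombination signals
# ---------------------------------------------------------------------------

class TestValidateRs:
    def test_consensus_scores_one(self):
        rs = RecombinationSignal("CACAGTG", "T" * 23, "ACAAAAACC")
        score, passed = validate_rs(rs)
        assert score == 1.0 and passed

    def test_five_substitutions_fail(self):
        # 5 scattered substitutions across heptamer+nonamer: 11/16
        rs = RecombinationSignal("AACAGTC", "T" * 12, "AGTAATACC")
        score, passed = validate_rs(rs)
        assert score == pytest.approx(11 / 16)
        assert not passed

    def test_bad_spacer_fails_regardless_of_score(self):
        rs = RecombinationSignal("CACAGTG", "T" * 15, "ACAAAAACC")
        score, passed = validate_rs(rs)
        assert score == 1.0 and not passed

    def test_malformed_lengths_rejected(self):
        with pytest.raises(ValueError):
            RecombinationSignal("CACAGT", "T" * 12, "ACAAAAACC")
        with pytest.raises(ValueError):
            RecombinationSignal("CACAGTG", "T" * 12, "ACAAAAAC")

    def test_score_one_iff_consensus(self, rng):
        for _ in range(20):
            hept = "".join(rng.choice(list("ACGT"), 7))
            nona = "".join(rng.choice(list("ACGT"), 9))
            score, _ = validate_rs(RecombinationSignal(hept, "T" * 12, nona))
            assert (score == 1.0) == (hept == "CACAGTG" and nona == "ACAAAAACC")


# ---------------------------------------------------------------------------
# J motif
# ---------------------------------------------------------------------------

def _j_gene(nt):
    return GermlineGene(name="TRBJ1-1", gene_type=GeneType.J, coding_nt=nt,
                        cluster_id=1)


class TestCheckJMotif:
    def test_motif_in_frame_zero(self):
        res = check_j_motif(_j_gene("TTTGGAAAAGGG" + "CCA" * 4))
        assert res["motif_found"] and res["frame"] == 0
        assert res["j_phe_codon_index"] == 0

    def test_ablated_motif_not_found(self):
        res = check_j_motif(_j_gene("TTTGCAAAAGGG" + "CCA" * 4))
        assert not res["motif_found"]

    def test_offset_motif_reports_frame(self):
        res = check_j_motif(_j_gene("CA" + "TTCGGCACAGGT" + "CCA" * 4))
        assert res["motif_found"] and res["frame"] == 2

    def test_all_simulated_j_genes_motif_complete(self, germline):
        assert len(germline.j_genes) == 13
        for j in germline.j_genes:
            assert check_j_motif(j)["motif_found"], j.name

    def test_j_length_band(self, germline):
        for j in germline.j_genes:
            assert 47 <= len(j.coding_nt) <= 53
            assert j.structural_problems() == []
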