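"""Synthetic germline construction and V(D)J rearrangement simulation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from equitrb.germline import (
    Functionality,
    classify_functionality,
    cluster_subgroups,
    revcomp,
    translate,
    validate_rs,
)
from equitrb.simulate import (
    SimConfig,
    TrimP,
    build_default_germline,
    read_truth,
    simulate_rearrangement,
    simulate_repertoire,
    spliced_transcript,
    truth_table,
    write_truth,
)
from equitrb.io import write_germline


class TestBuildGermline:
    def test_locus_topology(self, germline):
        """Two D genes of 12 and 17 nt and two D-J-C clusters of 6 and 7
        motif-complete J genes, mirroring the horse locus."""
        assert [len(d.coding_nt) for d in germline.d_genes] == [12, 17]
        assert len(germline.j_genes) == 13
        assert [len(germline.j_by_cluster[c]) for c in (1, 2)] == [6, 7]
        assert len(germline.c_genes) == 2
        for g in germline.d_genes + germline.j_genes:
            assert g.structural_problems() == []

    def test_d_genes_distinct_6mers_and_open_frames(self, germline):
        d1, d2 = (g.coding_nt for g in germline.d_genes)
        k1 = {d1[i:i + 6] for i in range(len(d1) - 5)}
        k2 = {d2[i:i + 6] for i in range(len(d2) - 5)}
        assert not (k1 & k2)
        for d in (d1, d2):
            for frame in range(3):
                assert "*" not in translate(d[frame:])

    def test_functional_v_classified_functional(self, germline, sim_config):
        assert len(germline.functional_v) == sim_config.n_v_functional
        for g in germline.functional_v:
            assert classify_functionality(g).status is Functionality.F

    def test_pseudogenes_classified_p(self, germline, sim_config):
        pseudo = [g for g in germline.v_genes
                  if g.functionality is Functionality.P]
        assert len(pseudo) == sim_config.n_v_pseudo + 1   # + inverted V
        for g in pseudo:
            assert classify_functionality(g).status is Functionality.P

    def test_one_terminal_stop_gene(self, germline):
        """One functional gene carries the in-frame stop at its last
        V-REGION codon (the configuration still classed as functional)."""
        from equitrb.germline import Defect
        flagged = [g for g in germline.functional_v
                   if classify_functionality(g).defects
                   == (Defect.TERMINAL_STOP_ONLY,)]
        assert len(flagged) == 1

    def test_consensus_recombination_signals(self, germline):
        for g in germline:
            for rs in (g.rs_5prime, g.rs_3prime):
                if rs is not None:
                    score, passed = validate_rs(rs)
                    assert score == 1.0 and passed

    def test_subgroup_clustering_recovers_families(self, germline):
        """The 75% single-linkage clustering reproduces the constructed
        families exactly (the identity bands are built to straddle the
        threshold)."""
        vs = [g for g in germline.v_genes]
        mapping = cluster_subgroups(vs)
        partition = {}
        for g in vs:
            partition.setdefault(mapping[g.name], set()).add(g.subgroup)
        # each cluster corresponds to exactly one constructed subgroup
        for members in partition.values():
            assert len(members) == 1
        assert len(partition) == len({g.subgroup for g in vs})

    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimConfig(seed=55, n_v_functional=6, n_v_pseudo=2,
                        n_subgroups=2, verify_identity=False)
        a = build_default_germline(cfg)
        b = build_default_germline(cfg)
        write_germline(a, tmp_path / "a")
        write_germline(b, tmp_path / "b")
        for name in ("genes.fasta", "rs.tsv", "v_spans.tsv"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(class_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SimConfig(read_length=30)
        with pytest.raises(ValueError):
            SimConfig(d_lengths=(0, 17))
        with pytest.raises(ValueError):
            TrimP(v=0.0)


class TestSimulateRearrangement:
    def test_degenerate_junction_is_exact_concatenation(self, degenerate_sim):
        gl = degenerate_sim.germline
        for rec in degenerate_sim.records[:100]:
            v = gl[rec.v_name]
            d = gl[rec.d_name]
            j = gl[rec.j_name]
            from equitrb.germline import j_phe_offset
            expected = (v.coding_nt[-9:] + d.coding_nt
                        + j.coding_nt[:j_phe_offset(j)])
            assert rec.junction_nt == expected
            assert (rec.v_trim, rec.d5_trim, rec.d3_trim, rec.j_trim) == (0, 0, 0, 0)
            assert rec.n1_seq == "" and rec.n2_seq == ""

    def test_pure_intra_mix(self, germline, sim_config):
        cfg = dataclasses.replace(sim_config, class_mix=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(5)
        for i in range(50):
            rec = simulate_rearrangement(germline, cfg, rng)
            d_cluster = germline[rec.d_name].cluster_id
            j_cluster = germline.j_cluster(rec.j_name)
            assert rec.rearrangement_class == "intra"
            assert d_cluster == j_cluster

    def test_class_consistency(self, default_sim):
        gl = default_sim.germline
        for rec in default_sim.records:
            d_cluster = gl[rec.d_name].cluster_id
            j_cluster = gl.j_cluster(rec.j_name)
            expected = {(1, 1): "intra", (2, 2): "intra",
                        (1, 2): "inter", (2, 1): "trans"}[(d_cluster, j_cluster)]
            assert rec.rearrangement_class == expected

    def test_junction_decomposition_reconstructs(self, default_sim):
        for rec in default_sim.records:
            gl = default_sim.germline
            v = gl[rec.v_name]
            j = gl[rec.j_name]
            from equitrb.germline import j_phe_offset
            v_end = v.coding_nt[len(v.coding_nt) - 9:len(v.coding_nt) - rec.v_trim] \
                if rec.v_trim else v.coding_nt[-9:]
            j_start = j.coding_nt[rec.j_trim:j_phe_offset(j)]
            assert rec.junction_nt == (v_end + rec.n1_seq + rec.d_retained
                                       + rec.n2_seq + j_start)
            assert rec.in_frame == (len(rec.junction_nt) % 3 == 0)
            if rec.productive:
                assert rec.in_frame
                assert "*" not in translate(rec.junction_nt)


class TestEmitReads:
    def test_reads_are_exact_transcript_substrings_without_errors(
            self, degenerate_sim):
        gl = degenerate_sim.germline
        by_id = {r.record_id: r for r in degenerate_sim.records}
        for read in degenerate_sim.reads[:200]:
            rec = by_id[read.truth_id]
            transcript, *_ = spliced_transcript(rec, gl)
            norm = read.seq if read.strand == "+" else revcomp(read.seq)
            assert norm in transcript
            assert rec.junction_nt in norm

    def test_window_contains_cdr3_and_c(self, default_sim, sim_config):
        gl = default_sim.germline
        by_id = {r.record_id: r for r in default_sim.records}
        for read in default_sim.reads[:200]:
            rec = by_id[read.truth_id]
            transcript, cys, f_pos, c_start = spliced_transcript(rec, gl)
            norm = read.seq if read.strand == "+" else revcomp(read.seq)
            assert len(norm) == sim_config.read_length
            start = transcript.find(norm) if sim_config.substitution_error_rate == 0 else None
            # structural guarantee: window built to cover [cys, c_start + 9)
            assert c_start + sim_config.min_c_in_read - len(norm) <= cys

    def test_error_rate_binomial(self, germline, sim_config):
        """Observed substitution count at rate 0.01 is within 3 SE of
        Binomial(n_reads * read_length, 0.01)."""
        cfg = dataclasses.replace(sim_config, substitution_error_rate=0.01, seed=77)
        cfg0 = dataclasses.replace(sim_config, substitution_error_rate=0.0, seed=77)
        res = simulate_repertoire(cfg, 1000, germline=germline)
        res0 = simulate_repertoire(cfg0, 1000, germline=germline)
        by_id = {r.read_id.split("|")[1]: r for r in res0.reads}
        mismatches = total = 0
        for read in res.reads:
            clean = by_id[read.truth_id]
            a = read.seq if read.strand == "+" else revcomp(read.seq)
            b = clean.seq if clean.strand == "+" else revcomp(clean.seq)
            assert len(a) == len(b)
            mismatches += sum(x != y for x, y in zip(a, b))
            total += len(a)
        p = 0.01
        se = np.sqrt(total * p * (1 - p))
        assert abs(mismatches - total * p) <= 3 * se

    def test_both_strands_emitted(self, default_sim):
        strands = {r.strand for r in default_sim.reads}
        assert strands == {"+", "-"}


class TestTruthTable:
    def test_roundtrip(self, default_sim, tmp_path):
        path = tmp_path / "truth.tsv"
        records = default_sim.records[:100]
        write_truth(records, path)
        back = read_truth(path)
        assert len(back) == 100
        for a, b in zip(records, back):
            assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("record_id\t")

    def test_row_count(self, default_sim):
        assert len(truth_table(default_sim.records)) == len(default_sim.records)
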