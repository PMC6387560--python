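"""Path-to-variant conversion and end-to-end calling."""

import numpy as np
import pytest

from conftest import make_read
from vihmm import hmm_core as hc
from vihmm.caller import CallerConfig, call_region, decode_region, path_to_variants
from vihmm.pileup import build_gapped_alignment
from vihmm.seq_io import ReferenceSequence
from vihmm.simulator import SimConfig, simulate


def gapped_for(reference, reads=()):
    reads = list(reads) or [
        make_read("cover", 1, [("M", reference.length)], reference.bases,
                  contig=reference.name)
    ]
    return build_gapped_alignment(reference, reads)


def match_path(gapped):
    """All-Match/NoIns state path for a gapped alignment."""
    states = []
    for i in range(gapped.n_columns):
        code = int(gapped.ref_codes[i])
        if gapped.ins_offset[i] > 0:
            states.append(15 + 14)  # s30
        else:
            states.append(hc.genotype_index(code, code))
    return np.array(states)


class TestPathToVariants:
    def test_homozygous_snp(self, reference10):
        g = gapped_for(reference10)
        path = match_path(g)
        path[0] = hc.genotype_index(1, 1)  # CC at ref A (pos 1)
        calls = path_to_variants(path, g, reference10)
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.ref, c.alts, c.genotype, c.var_class) == (
            1, "A", ("C",), (1, 1), "SNP")

    def test_heterozygous_snp_and_alt_alt(self, reference10):
        g = gapped_for(reference10)
        path = match_path(g)
        path[1] = hc.genotype_index(1, 2)  # CG at ref C -> het 0/1 ALT G
        path[3] = hc.genotype_index(0, 1)  # AC at ref T -> 1/2
        calls = path_to_variants(path, g, reference10)
        assert [(c.pos, c.alts, c.genotype) for c in calls] == [
            (2, ("G",), (0, 1)),
            (4, ("A", "C"), (1, 2)),
        ]

    def test_homozygous_deletion_run_merged_and_anchored(self, reference10):
        # ref ACGTACGTAC; delete positions 2-3 (CG), anchor on pos 1
        g = gapped_for(reference10)
        path = match_path(g)
        path[1] = path[2] = hc.genotype_index(4, 4)
        calls = path_to_variants(path, g, reference10)
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.ref, c.alts, c.genotype, c.var_class) == (
            1, "ACG", ("A",), (1, 1), "Del")

    def test_heterozygous_deletion_keeps_reference_allele(self, reference10):
        g = gapped_for(reference10)
        path = match_path(g)
        path[4] = hc.genotype_index(0, 4)  # A- at ref A (pos 5)
        calls = path_to_variants(path, g, reference10)
        c = calls[0]
        assert (c.pos, c.ref, c.alts, c.genotype) == (4, "TA", ("T",), (0, 1))

    def test_deletion_at_contig_start_anchors_right(self, reference10):
        g = gapped_for(reference10)
        path = match_path(g)
        path[0] = hc.genotype_index(4, 4)
        calls = path_to_variants(path, g, reference10)
        c = calls[0]
        assert (c.pos, c.ref, c.alts) == (1, "AC", ("C",))

    def test_mixed_zygosity_deletion_run_splits(self, reference10):
        g = gapped_for(reference10)
        path = match_path(g)
        path[5] = hc.genotype_index(4, 4)      # hom del at pos 6
        path[6] = hc.genotype_index(2, 4)      # het del (G-) at pos 7
        calls = path_to_variants(path, g, reference10)
        assert [(c.pos, c.genotype) for c in calls] == [(5, (1, 1)), (6, (0, 1))]

    def test_homozygous_insertion_run_merged(self, reference10):
        read = make_read("r1", 5, [("M", 3), ("I", 2), ("M", 2)], "CGTTTGT")
        g = gapped_for(reference10, [read])
        path = match_path(g)
        ins_cols = np.nonzero(g.ins_offset > 0)[0]
        for c in ins_cols:
            path[c] = 15 + hc.genotype_index(3, 3)  # TT
        calls = path_to_variants(path, g, reference10)
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.ref, c.alts, c.genotype, c.var_class) == (
            7, "G", ("GTT",), (1, 1), "Ins")

    def test_heterozygous_insertion(self, reference10):
        read = make_read("r1", 5, [("M", 3), ("I", 1), ("M", 2)], "CGTTGT")
        g = gapped_for(reference10, [read])
        path = match_path(g)
        col = int(np.nonzero(g.ins_offset > 0)[0][0])
        path[col] = 15 + hc.genotype_index(3, 4)  # T- : one haplotype inserted
        calls = path_to_variants(path, g, reference10)
        c = calls[0]
        assert (c.pos, c.ref, c.alts, c.genotype) == (7, "G", ("GT",), (0, 1))

    def test_no_call_from_uncallable_columns(self, reference10):
        g = gapped_for(reference10)
        path = match_path(g)
        path[2] = hc.genotype_index(0, 0)  # would be a SNP (AA at ref G)
        mask = np.ones(g.n_columns, dtype=bool)
        mask[2] = False
        assert path_to_variants(path, g, reference10, callable_mask=mask) == []

    def test_class_idempotence(self, reference10):
        """Re-deriving per-column classes from the emitted records reproduces
        the path's non-Match footprint exactly."""
        g = gapped_for(
            reference10,
            [make_read("r1", 5, [("M", 3), ("I", 2), ("M", 2)], "CGTTTGT")],
        )
        path = match_path(g)
        path[1] = hc.genotype_index(2, 2)          # SNP (GG at ref C) at pos 2
        path[3] = hc.genotype_index(4, 4)          # del at pos 4
        ins_cols = np.nonzero(g.ins_offset > 0)[0]
        for c in ins_cols:
            path[c] = 15 + hc.genotype_index(0, 0)  # hom ins AA
        calls = path_to_variants(path, g, reference10)
        covered = set()
        for c in calls:
            covered.update(range(c.columns[0], c.columns[1] + 1))
        want = {1, 3} | {int(c) for c in ins_cols}
        assert covered == want


class TestCallRegion:
    def test_clean_reads_give_zero_calls(self, rng):
        ref = ReferenceSequence("ctg", "".join(rng.choice(list("ACGT"), 300)))
        reads = [
            make_read(f"r{i}", int(1 + (i * 23) % 200), [("M", 100)],
                      ref.bases[(i * 23) % 200:(i * 23) % 200 + 100], contig="ctg")
            for i in range(30)
        ]
        assert call_region(ref, reads) == []

    def test_simulated_homozygous_snp_called_at_locus(self, rng):
        ref = ReferenceSequence("ctg", "".join(rng.choice(list("ACGT"), 200)))
        pos = 100
        alt = "ACGT"[("ACGT".index(ref.bases[pos - 1]) + 1) % 4]
        mutated = ref.bases[: pos - 1] + alt + ref.bases[pos:]
        reads = [
            make_read(f"r{i}", start, [("M", 80)], mutated[start - 1 : start + 79],
                      contig="ctg")
            for i, start in enumerate(rng.integers(40, 100, size=15))
        ]
        calls = call_region(ref, reads)
        assert [(c.pos, c.alts, c.genotype) for c in calls] == [(pos, (alt,), (1, 1))]

    def test_depth_four_locus_is_not_called(self, rng):
        ref = ReferenceSequence("ctg", "".join(rng.choice(list("ACGT"), 120)))
        pos = 60
        alt = "ACGT"[("ACGT".index(ref.bases[pos - 1]) + 2) % 4]
        mutated = ref.bases[: pos - 1] + alt + ref.bases[pos:]
        reads = [
            make_read(f"r{i}", 40, [("M", 50)], mutated[39:89], contig="ctg")
            for i in range(4)
        ]
        assert call_region(ref, reads) == []

    def test_deterministic_given_inputs(self):
        sim = simulate(SimConfig(ref_length=3000, depth=15, seed=11))
        first = call_region(sim.reference, sim.reads)
        second = call_region(sim.reference, sim.reads)
        assert [(c.pos, c.ref, c.alts, c.genotype) for c in first] == [
            (c.pos, c.ref, c.alts, c.genotype) for c in second
        ]

    def test_path_log_prob_attached_to_calls(self):
        sim = simulate(SimConfig(ref_length=2000, depth=15, seed=3))
        result = decode_region(sim.reference, sim.reads)
        for c in result.calls:
            assert c.info["PLP"] == pytest.approx(result.path.log_prob)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_error_recovery_small(self, seed):
        """Error-free deep coverage recovers every homozygous truth variant
        with no false calls (SNPs and deletions, small region)."""
        from vihmm.evaluation import evaluate

        sim = simulate(
            SimConfig(ref_length=5000, depth=20, error_range=(0.0, 0.0),
                      het_rate=0.0, seed=seed)
        )
        calls = call_region(sim.reference, sim.reads)
        for cls in ("SNP", "INDEL"):
            m = evaluate(sim.truth.records, calls, cls)
            if m.tp + m.fn > 0:
                assert m.sensitivity == 1.0
                assert m.precision == 1.0
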