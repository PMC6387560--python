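"""State space, class expansion and Viterbi decoding."""

import itertools

import numpy as np
import pytest

from vihmm import hmm_core as hc
from vihmm.errors import AdmissibilityError, DecodeError, ValidationError


def brute_force_best_path(log_emission, step_log_trans, log_pi):
    """Independent oracle: score every admissible state sequence by direct
    accumulation (no dynamic programming, no max until the very end).

    Inadmissible states carry -inf emissions; enumerating them is pointless
    and blows up memory, so the accumulation runs over each column's
    admissible index list and maps back to full state indices at the end.
    """
    L, S = log_emission.shape
    adm = [np.nonzero(np.isfinite(log_emission[i]))[0] for i in range(L)]
    total = (log_pi + log_emission[0])[adm[0]]  # shape (|adm_0|,)
    for i in range(1, L):
        step = step_log_trans[i - 1][np.ix_(adm[i - 1], adm[i])]
        total = total[..., None] + step + log_emission[i][adm[i]]
        # flatten all prefixes; last axis enumerates z_i over adm[i]
        total = total.reshape(-1, len(adm[i]))
    flat = total.reshape(-1)
    best = int(np.argmax(flat))
    local = np.unravel_index(best, tuple(len(a) for a in adm))
    path = np.array([adm[i][j] for i, j in enumerate(local)])
    return path, float(flat[best])


class TestStateSpace:
    def test_canonical_genotype_order(self):
        assert hc.GENOTYPE_LABELS == (
            "AA", "AC", "AG", "AT", "A-", "CC", "CG", "CT", "C-",
            "GG", "GT", "G-", "TT", "T-", "--",
        )
        assert hc.N_STATES == 30

    @pytest.mark.parametrize(
        "state,ref,expected",
        [
            (0, "A", "Match"),      # AA at R=A
            (14, "A", "Del"),       # -- at R=A (homozygous deletion)
            (4, "A", "Del"),        # A- at R=A (heterozygous deletion)
            (5, "A", "SNP"),        # CC at R=A
            (1, "A", "SNP"),        # AC at R=A
            (15 + 3, "-", "Ins"),   # AT at R=-
            (29, "-", "NoIns"),     # -- at R=- is the no-insertion state
        ],
    )
    def test_classify_state(self, state, ref, expected):
        assert hc.classify_state(state, ref) == expected

    def test_strict_mode_labels_het_del_as_snp(self):
        assert hc.classify_state(4, "A", strict=True) == "SNP"
        assert hc.classify_state(14, "A", strict=True) == "Del"

    def test_inadmissible_combination_raises(self):
        with pytest.raises(AdmissibilityError):
            hc.classify_state(20, "A")
        with pytest.raises(AdmissibilityError):
            hc.classify_state(3, "-")


class TestClassExpansion:
    def test_snp_to_match_mass_preserved(self):
        model = hc.ClassTransitionModel(hc.DEFAULT_CLASS_MATRIX)
        # pre-renormalization, the summed mass from a SNP-class state into
        # the (single) Match state equals the class-level probability
        for dst in "ACGT":
            w = model.dest_weights("SNP", dst, renormalize=False)
            match_mass = sum(
                w[g] for g in range(15)
                if hc.classify_genotype(g, hc.SYMBOL_TO_CODE[dst]) == "Match"
            )
            assert match_mass == pytest.approx(0.9499, abs=1e-12)

    def test_ins_to_match_mass_preserved(self):
        model = hc.ClassTransitionModel(hc.DEFAULT_CLASS_MATRIX)
        w = model.dest_weights("Ins", "G", renormalize=False)
        match_mass = w[hc.genotype_index(2, 2)]
        assert match_mass == pytest.approx(0.2880, abs=1e-12)

    def test_identity_class_matrix_rows_still_stochastic(self):
        model = hc.ClassTransitionModel(np.eye(4))
        for src, dst in itertools.product("ACGT-", repeat=2):
            try:
                block = np.exp(model.log_block(src, dst))
            except DecodeError:
                continue  # e.g. Ins row has nowhere to go at a base column
            sums = block.sum(axis=1)
            finite = np.isfinite(sums)
            assert np.allclose(sums[finite], 1.0, atol=1e-9)

    def test_masking_preserves_row_stochasticity(self, rng):
        for _ in range(20):
            m = rng.random((4, 4)) + 0.05
            m /= m.sum(axis=1, keepdims=True)
            model = hc.ClassTransitionModel(m)
            for src, dst in itertools.product("ACGT-", repeat=2):
                block = np.exp(model.log_block(src, dst))
                assert np.allclose(block.sum(axis=1), 1.0, atol=1e-9)

    def test_non_stochastic_input_rejected(self):
        bad = np.eye(4) * 0.9
        with pytest.raises(ValidationError):
            hc.ClassTransitionModel(bad)

    def test_full_matrix_blocks_row_stochastic(self, rng):
        m = rng.random((30, 30)) + 0.01
        m /= m.sum(axis=1, keepdims=True)
        model = hc.FullTransitionModel(m)
        for src, dst in itertools.product("A-", repeat=2):
            block = np.exp(model.log_block(src, dst))
            assert np.allclose(block.sum(axis=1), 1.0, atol=1e-9)


def _random_instance(rng, L, S=30):
    """Random decoding instance with per-column admissibility masks."""
    symbols = [rng.choice(list("ACGT-")) for _ in range(L)]
    E = np.full((L, S), -np.inf)
    for i, sym in enumerate(symbols):
        adm = list(hc.admissible_states(sym))
        E[i, adm] = rng.normal(0, 2, size=len(adm))
    m = rng.random((4, 4)) + 0.05
    m /= m.sum(axis=1, keepdims=True)
    model = hc.ClassTransitionModel(m)
    T = np.full((max(L - 1, 1), S, S), -np.inf)
    for i in range(1, L):
        blk = model.log_block(symbols[i - 1], symbols[i])
        src = list(hc.admissible_states(symbols[i - 1]))
        dst = list(hc.admissible_states(symbols[i]))
        T[i - 1][np.ix_(src, dst)] = blk
    pi = np.full(S, -np.inf)
    adm0 = list(hc.admissible_states(symbols[0]))
    pi[adm0] = model.log_pi(symbols[0])
    return symbols, E, T, pi, model


class TestViterbi:
    def test_single_column_argmax(self):
        E = np.array([[0.0] + [-5.0] * 29])
        pi = np.zeros(30)
        path = hc.viterbi(E, np.zeros((30, 30)), pi)
        assert list(path.states) == [0]

    def test_forced_path_under_any_transition(self, rng):
        L = 8
        forced = rng.integers(0, 30, size=L)
        E = np.full((L, 30), -np.inf)
        E[np.arange(L), forced] = 0.0
        T = np.log(rng.dirichlet(np.ones(30), size=30))
        pi = np.log(np.full(30, 1 / 30))
        path = hc.viterbi(E, T, pi)
        assert np.array_equal(path.states, forced)

    def test_tie_break_lowest_state_index(self):
        # fully uniform instance: every path ties; the lowest-index path wins
        L = 4
        E = np.zeros((L, 30))
        T = np.log(np.full((30, 30), 1 / 30))
        pi = np.log(np.full(30, 1 / 30))
        path = hc.viterbi(E, T, pi)
        assert list(path.states) == [0] * L

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            L = int(rng.integers(1, 6))
            _, E, T, pi, _ = _random_instance(rng, L)
            got = hc.viterbi(E, T, pi)
            want_path, want_lp = brute_force_best_path(E, T, pi)
            assert np.array_equal(got.states, want_path)
            assert got.log_prob == pytest.approx(want_lp, abs=1e-9)

    def test_path_log_prob_identity(self, rng):
        L = 12
        _, E, T, pi, _ = _random_instance(rng, L)
        got = hc.viterbi(E, T, pi)
        recomputed = hc.path_log_prob(got.states, E, T, pi)
        assert got.log_prob == pytest.approx(recomputed, abs=1e-9)

    def test_dominates_random_admissible_paths(self, rng):
        L = 10
        symbols, E, T, pi, _ = _random_instance(rng, L)
        best = hc.viterbi(E, T, pi)
        for _ in range(1000):
            path = [rng.choice(list(hc.admissible_states(s))) for s in symbols]
            assert hc.path_log_prob(path, E, T, pi) <= best.log_prob + 1e-9

    def test_invariant_to_emission_scaling_at_one_column(self, rng):
        L = 9
        _, E, T, pi, _ = _random_instance(rng, L)
        base = hc.viterbi(E, T, pi)
        E2 = E.copy()
        E2[4] += 3.7  # multiply all emissions at column 4 by a constant
        again = hc.viterbi(E2, T, pi)
        assert np.array_equal(base.states, again.states)

    def test_all_inadmissible_column_raises_with_column(self, rng):
        _, E, T, pi, _ = _random_instance(rng, 5)
        E[3, :] = -np.inf
        with pytest.raises(DecodeError, match="column 3"):
            hc.viterbi(E, T, pi)

    def test_blocked_decoder_equals_generic(self, rng):
        for _ in range(15):
            L = int(rng.integers(2, 40))
            symbols, E, T, pi, model = _random_instance(rng, L)
            generic = hc.viterbi(E, T, pi)
            E15 = np.stack(
                [E[i, list(hc.admissible_states(s))] for i, s in enumerate(symbols)]
            )
            codes = np.array([hc.SYMBOL_TO_CODE[s] for s in symbols])
            blocked = hc.viterbi_columns(E15, codes, model)
            assert np.array_equal(blocked.states, generic.states)
            assert blocked.log_prob == pytest.approx(generic.log_prob, abs=1e-9)
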