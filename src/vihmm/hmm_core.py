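"""The 30-state diploid genotype HMM: state space, transitions, Viterbi decoding.

At every column of the gapped alignment the hidden state pairs the reference
symbol R_i (a base, or "-" for an insertion column) with an unordered diploid
genotype G_i over the alphabet {A, C, G, T, -}.  There are 15 unordered
genotypes; columns where the reference shows a base use states s1..s15 and
insertion columns (R_i = "-") use states s16..s30, giving 30 states in total.
Each state carries a class label -- Match, SNP, Del, Ins, or NoIns -- derived
from how the genotype relates to the reference symbol.

Transitions between adjacent columns come either from a full 30x30 row-
stochastic matrix or from a 4x4 class-level matrix that is expanded on the
fly: the class-level mass into a destination class is split uniformly among
that class's member states at the destination column, then the row is
renormalized over the states admissible there.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .errors import AdmissibilityError, DecodeError, ValidationError

SYMBOLS = "ACGT-"
GAP_CODE = 4
SYMBOL_TO_CODE = {s: i for i, s in enumerate(SYMBOLS)}

#: canonical unordered diploid genotypes: AA, AC, AG, AT, A-, CC, CG, CT, C-,
#: GG, GT, G-, TT, T-, --
GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(5) for b in range(a, 5)
)
GENOTYPE_LABELS = tuple(SYMBOLS[a] + SYMBOLS[b] for a, b in GENOTYPE_PAIRS)
N_GENOTYPES = 15
N_STATES = 30
STATE_LABELS = tuple(f"s{i + 1}" for i in range(N_STATES))

MATCH, SNP, DEL, INS, NOINS = "Match", "SNP", "Del", "Ins", "NoIns"
CLASS_ORDER = (MATCH, SNP, DEL, INS)
CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

#: Packaged default class-level transition matrix (rows/cols in CLASS_ORDER).
#: The SNP->Match (0.9499) and Ins->Match (0.2880) entries are dbSNP-derived
#: conditional frequencies; the remaining rows are Match-heavy, tuned to an
#: overall variant density of roughly one event per kilobase, with mean
#: deletion run ~2 bp and mean insertion run ~3.3 bp.
DEFAULT_CLASS_MATRIX = np.array(
    [
        [0.99900, 0.00070, 0.00015, 0.00015],  # Match
        [0.94990, 0.04000, 0.00500, 0.00510],  # SNP
        [0.50000, 0.00500, 0.49000, 0.00500],  # Del
        [0.28800, 0.00700, 0.00500, 0.70000],  # Ins
    ]
)


def genotype_index(a: int, b: int) -> int:
    """Index of the unordered genotype {a, b} in the canonical ordering."""
    if a > b:
        a, b = b, a
    return GENOTYPE_PAIRS.index((a, b))


def admissible_states(ref_symbol: str) -> range:
    """Canonical state indices (0-based) admissible at a column with this symbol."""
    if ref_symbol == "-":
        return range(N_GENOTYPES, N_STATES)
    return range(0, N_GENOTYPES)


def classify_genotype(g_index: int, ref_code: int, strict: bool = False) -> str:
    """Class label of genotype ``g_index`` at a column whose reference code is
    ``ref_code`` (0..3 for A/C/G/T, 4 for an insertion column).

    With ``strict=True`` genotypes containing exactly one "-" at a base column
    are labeled SNP (the literal class-labeling convention) instead of Del.
    """
    a, b = GENOTYPE_PAIRS[g_index]
    if ref_code == GAP_CODE:
        return NOINS if (a, b) == (GAP_CODE, GAP_CODE) else INS
    if (a, b) == (ref_code, ref_code):
        return MATCH
    if (a, b) == (GAP_CODE, GAP_CODE):
        return DEL
    if GAP_CODE in (a, b):
        return SNP if strict else DEL
    return SNP


def classify_state(state_index: int, ref_symbol: str, strict: bool = False) -> str:
    """Class label of canonical state ``state_index`` (0..29) at ``ref_symbol``.

    Raises :class:`AdmissibilityError` when the state block does not match the
    reference symbol (s16..s30 require R="-", s1..s15 require a base).
    """
    if not 0 <= state_index < N_STATES:
        raise AdmissibilityError(f"state index {state_index} out of range")
    code = SYMBOL_TO_CODE[ref_symbol]
    is_ins_state = state_index >= N_GENOTYPES
    if is_ins_state != (code == GAP_CODE):
        raise AdmissibilityError(
            f"state {STATE_LABELS[state_index]} is inadmissible at R={ref_symbol!r}"
        )
    return classify_genotype(state_index % N_GENOTYPES, code, strict)


def state_genotype(state_index: int) -> tuple[int, int]:
    """Allele-code pair of a canonical state (0..29)."""
    return GENOTYPE_PAIRS[state_index % N_GENOTYPES]


def _validate_rows(matrix: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < -1e-12) or np.any(matrix > 1 + 1e-12):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    sums = matrix.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"transition row {bad} sums to {sums[bad]:.6g}, expected 1"
        )
    return matrix / sums[:, None]


class ClassTransitionModel:
    """30-state transitions derived from a 4x4 class-level matrix.

    ``dest_weights`` exposes the raw uniform split of class mass among the
    destination column's member states; decoding uses the renormalized form
    (mass into classes without members at the destination column, e.g. Ins at
    a non-insertion column, is conditioned away).
    """

    def __init__(self, class_matrix=DEFAULT_CLASS_MATRIX, strict: bool = False):
        m = np.asarray(class_matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"class matrix must be 4x4, got {m.shape}")
        self.class_matrix = _validate_rows(m)
        self.strict = strict
        self._block_cache: dict[tuple[int, int], np.ndarray] = {}
        self._pi_cache: dict[int, np.ndarray] = {}

    def _dest_classes(self, dst_code: int) -> list[str]:
        cls = [classify_genotype(g, dst_code, self.strict) for g in range(N_GENOTYPES)]
        # the no-insertion state rides on the Match row: it is the
        # "nothing happened" outcome at an insertion column
        return [MATCH if c == NOINS else c for c in cls]

    def source_classes(self, src_symbol: str) -> list[str]:
        code = SYMBOL_TO_CODE[src_symbol]
        cls = [classify_genotype(g, code, self.strict) for g in range(N_GENOTYPES)]
        return [MATCH if c == NOINS else c for c in cls]

    def dest_weights(
        self, src_class: str, dst_symbol: str, renormalize: bool = True
    ) -> np.ndarray:
        """Mass placed on each of the 15 admissible destination genotypes."""
        dst_code = SYMBOL_TO_CODE[dst_symbol]
        eff = self._dest_classes(dst_code)
        counts = Counter(eff)
        row = self.class_matrix[CLASS_INDEX[src_class]]
        w = np.array([row[CLASS_INDEX[c]] / counts[c] for c in eff])
        if renormalize:
            total = w.sum()
            if total <= 0:
                raise DecodeError(
                    f"no admissible destination mass from class {src_class} "
                    f"into a column with R={dst_symbol!r}"
                )
            w = w / total
        return w

    def log_block(self, src_symbol: str, dst_symbol: str) -> np.ndarray:
        """(15, 15) log-transition block between two adjacent columns."""
        key = (SYMBOL_TO_CODE[src_symbol], SYMBOL_TO_CODE[dst_symbol])
        block = self._block_cache.get(key)
        if block is None:
            src_classes = self.source_classes(src_symbol)
            rows = {}
            out = np.empty((N_GENOTYPES, N_GENOTYPES))
            for g, c in enumerate(src_classes):
                if c not in rows:
                    w = self.dest_weights(c, dst_symbol, renormalize=True)
                    with np.errstate(divide="ignore"):
                        rows[c] = np.log(w)
                out[g] = rows[c]
            block = out
            self._block_cache[key] = block
        return block

    def log_pi(self, first_symbol: str) -> np.ndarray:
        """Initial log-distribution: the renormalized Match row for the first
        column's reference symbol."""
        key = SYMBOL_TO_CODE[first_symbol]
        pi = self._pi_cache.get(key)
        if pi is None:
            with np.errstate(divide="ignore"):
                pi = np.log(self.dest_weights(MATCH, first_symbol, renormalize=True))
            self._pi_cache[key] = pi
        return pi


class FullTransitionModel:
    """30-state transitions from an explicit 30x30 row-stochastic matrix.

    At decode time rows are masked to the 15 states admissible at the
    destination column and renormalized.
    """

    def __init__(self, values):
        values = np.asarray(values, dtype=float)
        if values.shape != (N_STATES, N_STATES):
            raise ValidationError(f"transition matrix must be 30x30, got {values.shape}")
        self.values = _validate_rows(values)
        self._block_cache: dict[tuple[bool, bool], np.ndarray] = {}

    @staticmethod
    def _slice(symbol: str) -> slice:
        return (
            slice(N_GENOTYPES, N_STATES)
            if symbol == "-"
            else slice(0, N_GENOTYPES)
        )

    def log_block(self, src_symbol: str, dst_symbol: str) -> np.ndarray:
        key = (src_symbol == "-", dst_symbol == "-")
        block = self._block_cache.get(key)
        if block is None:
            sub = self.values[self._slice(src_symbol), self._slice(dst_symbol)]
            sums = sub.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                block = np.where(sums > 0, np.log(sub / np.where(sums > 0, sums, 1.0)), -np.inf)
            self._block_cache[key] = block
        return block

    def log_pi(self, first_symbol: str) -> np.ndarray:
        if first_symbol == "-":
            row = self.values[N_STATES - 1]  # s30, the no-insertion state
        else:
            code = SYMBOL_TO_CODE[first_symbol]
            row = self.values[genotype_index(code, code)]
        w = row[self._slice(first_symbol)]
        total = w.sum()
        if total <= 0:
            raise DecodeError("initial Match row has no admissible mass")
        with np.errstate(divide="ignore"):
            return np.log(w / total)


def expand_class_matrix(
    class_matrix, reference_symbols=None, strict: bool = False
) -> ClassTransitionModel:
    """Expand a 4x4 class matrix into the 30-state transition model.

    ``reference_symbols`` is accepted for symmetry with decoding call sites but
    the expansion is lazy: per-column blocks are materialized on demand from
    the (source symbol, destination symbol) pair.
    """
    return ClassTransitionModel(class_matrix, strict=strict)


@dataclasses.dataclass
class ViterbiPath:
    """Decoded state sequence (canonical 0-based indices) and its log probability."""

    states: np.ndarray
    log_prob: float

    def __len__(self) -> int:
        return len(self.states)


def viterbi(log_emission, log_transition, log_pi) -> ViterbiPath:
    """Log-space Viterbi decoding.

    Parameters
    ----------
    log_emission : (L, S) array
        Per-column emission log-likelihoods; -inf marks inadmissible states.
    log_transition : (S, S) or (L-1, S, S) array
        Stationary or per-step log-transition matrices.
    log_pi : (S,) array
        Initial log-distribution.

    Ties are broken toward the lowest state index, both at the final column
    and at every backtrack step.
    """
    E = np.asarray(log_emission, dtype=float)
    if E.ndim != 2:
        raise ValueError("log_emission must be 2-D (columns x states)")
    L, S = E.shape
    T = np.asarray(log_transition, dtype=float)
    per_step = T.ndim == 3
    dp = np.asarray(log_pi, dtype=float) + E[0]
    if not np.isfinite(dp).any():
        raise DecodeError("all states inadmissible at column 0")
    ptr = np.zeros((L, S), dtype=np.int32)
    idx = np.arange(S)
    for i in range(1, L):
        Ti = T[i - 1] if per_step else T
        scores = dp[:, None] + Ti
        ptr[i] = np.argmax(scores, axis=0)
        dp = scores[ptr[i], idx] + E[i]
        if not np.isfinite(dp).any():
            raise DecodeError(f"all states inadmissible at column {i}")
    states = np.empty(L, dtype=np.int64)
    states[-1] = int(np.argmax(dp))
    for i in range(L - 1, 0, -1):
        states[i - 1] = ptr[i, states[i]]
    return ViterbiPath(states=states, log_prob=float(dp[states[-1]]))


def viterbi_columns(log_emission15, ref_codes, model) -> ViterbiPath:
    """Viterbi decoding specialised to the gapped-column layout.

    ``log_emission15`` has one row per column over the 15 genotypes admissible
    there; ``ref_codes`` gives each column's reference symbol code (4 = "-").
    Returns canonical 30-state indices.  Equivalent to :func:`viterbi` run on
    the full 30-state arrays, but avoids materialising per-step 30x30
    matrices.
    """
    E = np.asarray(log_emission15, dtype=float)
    codes = np.asarray(ref_codes)
    L = len(codes)
    if E.shape != (L, N_GENOTYPES):
        raise ValueError("emission table shape does not match column count")
    blocks: dict[tuple[int, int], np.ndarray] = {}
    step_blocks = []
    for i in range(1, L):
        key = (int(codes[i - 1]), int(codes[i]))
        blk = blocks.get(key)
        if blk is None:
            blk = model.log_block(SYMBOLS[key[0]], SYMBOLS[key[1]])
            blocks[key] = blk
        step_blocks.append(blk)

    dp = model.log_pi(SYMBOLS[int(codes[0])]) + E[0]
    if not np.isfinite(dp).any():
        raise DecodeError("all states inadmissible at column 0")
    ptr = np.empty((L, N_GENOTYPES), dtype=np.int8)
    idx = np.arange(N_GENOTYPES)
    argmax = np.argmax
    for i in range(1, L):
        scores = dp[:, None] + step_blocks[i - 1]
        p = argmax(scores, axis=0)
        ptr[i] = p
        dp = scores[p, idx] + E[i]
    if not np.isfinite(dp).any():
        raise DecodeError("no admissible path through the region")
    g = np.empty(L, dtype=np.int64)
    g[-1] = int(np.argmax(dp))
    log_prob = float(dp[g[-1]])
    for i in range(L - 1, 0, -1):
        g[i - 1] = ptr[i, g[i]]
    states = g + np.where(codes == GAP_CODE, N_GENOTYPES, 0)
    return ViterbiPath(states=states, log_prob=log_prob)


def path_log_prob(states, log_emission, log_transition, log_pi) -> float:
    """Log probability of an explicit state sequence (for invariant checks)."""
    states = np.asarray(states)
    E = np.asarray(log_emission, dtype=float)
    T = np.asarray(log_transition, dtype=float)
    per_step = T.ndim == 3
    total = float(np.asarray(log_pi, dtype=float)[states[0]] + E[0, states[0]])
    for i in range(1, len(states)):
        Ti = T[i - 1] if per_step else T
        total += float(Ti[states[i - 1], states[i]] + E[i, states[i]])
    return total
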