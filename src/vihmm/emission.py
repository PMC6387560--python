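"""Per-column emission log-likelihoods of the pileup under each hidden state.

The likelihood of a column's pileup D_i given a state with genotype
G = {A1, A2} is the product over reads of an equal-weight two-allele mixture,

    P(D_i | Z_i) = prod_k [ 1/2 p(d_ik | A1) + 1/2 p(d_ik | A2) ],

where the single-allele term uses the per-read sequencing error rate e_ik
derived from the Phred score.  Two forms of the allele term are provided:

* ``printed`` -- e if d != A and 1 - e/4 if d == A, the literal form.
  Summed over the five symbols this exceeds one by 15e/4.
* ``normalized`` (default) -- 1 - e if d == A and e/4 otherwise, a proper
  distribution over the five-symbol alphabet {A, C, G, T, -}.

The "-" symbol participates like any base, so deletion evidence enters the
product the same way mismatches do.  Columns whose pileup is smaller than
``min_depth`` carry no emission information: every admissible state gets
log 1 = 0 and the decoded path there is driven purely by the transitions
(calls at such columns are suppressed downstream).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import VihmmError
from .hmm_core import (
    GENOTYPE_PAIRS,
    N_GENOTYPES,
    SYMBOL_TO_CODE,
    admissible_states,
    state_genotype,
)
from .pileup import PileupColumn, passes_depth_filter

MODES = ("printed", "normalized")

_A1 = np.array([p[0] for p in GENOTYPE_PAIRS])
_A2 = np.array([p[1] for p in GENOTYPE_PAIRS])


@dataclasses.dataclass
class EmissionConfig:
    mode: str = "normalized"
    min_depth: int = 5
    fallback_phred: float = 20.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise VihmmError(f"unknown emission mode {self.mode!r}")
        if self.min_depth < 1:
            raise VihmmError("min_depth must be >= 1")


def phred_to_error(q: float) -> float:
    """e = 10^(-Q/10)."""
    if q < 0:
        raise VihmmError(f"negative Phred score {q}")
    return 10.0 ** (-q / 10.0)


def _code(symbol) -> int:
    if isinstance(symbol, str):
        return SYMBOL_TO_CODE[symbol]
    return int(symbol)


def allele_likelihood(d, allele, e: float, mode: str = "normalized") -> float:
    """p(d | A) under the chosen error-model form."""
    d, allele = _code(d), _code(allele)
    if mode == "printed":
        return 1.0 - e / 4.0 if d == allele else e
    if mode == "normalized":
        return 1.0 - e if d == allele else e / 4.0
    raise VihmmError(f"unknown emission mode {mode!r}")


def genotype_likelihood(d, genotype, e: float, mode: str = "normalized") -> float:
    """Equal-weight mixture over the genotype's two alleles."""
    if isinstance(genotype, str):
        a1, a2 = (_code(c) for c in genotype)
    else:
        a1, a2 = (_code(c) for c in genotype)
    return 0.5 * allele_likelihood(d, a1, e, mode) + 0.5 * allele_likelihood(
        d, a2, e, mode
    )


def column_log_emission(
    column: PileupColumn, state_index: int, config: EmissionConfig | None = None
) -> float:
    """Log emission of one pileup column under one canonical state.

    Requires imputed qualities (every observation carries an error rate).
    Inadmissible states return -inf by contract; below-threshold columns
    return 0.0 for every admissible state.
    """
    config = config or EmissionConfig()
    ref_code = SYMBOL_TO_CODE.get(column.ref_symbol, None)
    if ref_code is not None and state_index not in admissible_states(column.ref_symbol):
        return float("-inf")
    if not passes_depth_filter(column, config.min_depth):
        return 0.0
    genotype = state_genotype(state_index)
    total = 0.0
    for obs in column.observations:
        if obs.error is None:
            raise VihmmError(
                f"column {column.column_index}: qualities not imputed"
            )
        p = genotype_likelihood(obs.base, genotype, obs.error, config.mode)
        total += np.log(p) if p > 0 else float("-inf")
    return float(total)


def emission_log_table(
    obs_col, obs_sym, obs_err, n_columns: int, mode: str = "normalized"
) -> np.ndarray:
    """Vectorised (n_columns, 15) emission log-likelihood table.

    Row c holds log P(D_c | G) for each of the 15 genotypes in canonical
    order; the state block (s1..s15 vs s16..s30) is resolved by the decoder
    from each column's reference symbol.
    """
    obs_col = np.asarray(obs_col, dtype=np.int64)
    obs_sym = np.asarray(obs_sym, dtype=np.int64)
    # the mixture takes only three values per observation, set by how many of
    # the genotype's alleles equal the observed symbol (0, 1 or 2); column
    # sums then reduce to three bincounts instead of a 15-way product table
    e = np.clip(np.asarray(obs_err, dtype=float), 1e-30, 1.0)
    if mode == "normalized":
        p_match, p_miss = 1.0 - e, e / 4.0
    elif mode == "printed":
        p_match, p_miss = 1.0 - e / 4.0, e
    else:
        raise VihmmError(f"unknown emission mode {mode!r}")
    with np.errstate(divide="ignore"):
        l0 = np.log(p_miss)  # neither allele matches
        l1 = np.log(0.5 * (p_match + p_miss))  # heterozygous, one match
        l2 = np.log(p_match)  # both alleles match
    base = np.bincount(obs_col, weights=l0, minlength=n_columns)
    key = obs_col * 5 + obs_sym
    het_gain = np.bincount(key, weights=l1 - l0, minlength=5 * n_columns).reshape(
        n_columns, 5
    )
    hom_gain = np.bincount(key, weights=l2 - l0, minlength=5 * n_columns).reshape(
        n_columns, 5
    )
    out = np.empty((n_columns, N_GENOTYPES))
    for g, (a, b) in enumerate(GENOTYPE_PAIRS):
        if a == b:
            out[:, g] = base + hom_gain[:, a]
        else:
            out[:, g] = base + het_gain[:, a] + het_gain[:, b]
    return out


def apply_depth_filter(table: np.ndarray, depth, min_depth: int = 5) -> np.ndarray:
    """Zero the emission rows of columns failing the depth filter.

    Returns the boolean mask of columns that *pass*.
    """
    ok = np.asarray(depth) >= min_depth
    table[~ok] = 0.0
    return ok
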