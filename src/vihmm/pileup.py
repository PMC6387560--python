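"""Gapped column space and per-column pileups.

The caller works over a column-indexed view of the reference: one column per
reference base, plus, at every junction between adjacent bases where at least
one read's CIGAR carries an insertion, a block of gap columns whose length is
the maximum insertion length observed among the reads at that junction.
Reads that span such a junction without the insertion contribute a "-"
observation (with missing quality) at each gap column, which is the evidence
that lets the no-insertion state win; reads with a shorter insertion are
padded with "-" likewise.

Deleted reference bases contribute "-" observations with missing quality;
missing qualities are imputed with the arithmetic mean of the column's
observed Phred scores (falling back to a configurable constant when the whole
column is missing), after which e = 10^(-Q/10).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np

from .errors import RecordError
from .hmm_core import GAP_CODE, SYMBOLS
from .seq_io import MappedRead, ReferenceSequence

_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
_BASE_LUT[ord("N")] = -1

DEFAULT_FALLBACK_PHRED = 20.0


@dataclasses.dataclass
class GappedAlignment:
    """Column-indexed view of a contig with hypothesized insertion columns.

    ``ref_codes[c]`` is the reference symbol code at column ``c`` (0..3 base,
    4 = "-"); ``ref_pos[c]`` is the 1-based reference coordinate (0 at
    insertion columns); ``ins_offset[c]`` is 1, 2, ... inside an insertion
    block and 0 elsewhere.  ``junction[c]`` is, for insertion columns, the
    1-based reference position immediately left of the block (0 when the
    block precedes the first base).
    """

    contig: str
    ref_length: int
    ref_codes: np.ndarray
    ref_pos: np.ndarray
    ins_offset: np.ndarray
    junction: np.ndarray
    junction_lengths: np.ndarray  # ins block length after ref pos j, j = 0..L
    col_of_ref: np.ndarray  # 1-based ref pos -> column index (entry 0 unused)
    n_mask: np.ndarray  # True where the reference base is N (no-call columns)

    @property
    def n_columns(self) -> int:
        return len(self.ref_codes)


@dataclasses.dataclass
class Observation:
    base: str
    phred: Optional[float]
    error: Optional[float]


@dataclasses.dataclass
class PileupColumn:
    """Observed bases and error rates on one gapped-alignment column."""

    column_index: int
    ref_symbol: str
    observations: list[Observation]

    @property
    def depth(self) -> int:
        return len(self.observations)


class Pileup:
    """Array-backed pileup over all columns of a :class:`GappedAlignment`."""

    def __init__(self, gapped: GappedAlignment, obs_col, obs_sym, obs_phred):
        self.gapped = gapped
        self.obs_col = np.asarray(obs_col, dtype=np.int64)
        self.obs_sym = np.asarray(obs_sym, dtype=np.int8)
        self.obs_phred = np.asarray(obs_phred, dtype=float)
        self.depth = np.bincount(self.obs_col, minlength=gapped.n_columns).astype(
            np.int64
        )
        self.obs_error: Optional[np.ndarray] = None

    def impute(self, fallback_phred: float = DEFAULT_FALLBACK_PHRED) -> np.ndarray:
        """Impute missing Phred scores column-wise and return error rates.

        Each missing quality becomes the arithmetic mean of the column's
        non-missing qualities; a column with no observed quality at all uses
        ``fallback_phred``.
        """
        n = self.gapped.n_columns
        have = ~np.isnan(self.obs_phred)
        sums = np.bincount(self.obs_col[have], weights=self.obs_phred[have], minlength=n)
        counts = np.bincount(self.obs_col[have], minlength=n)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), fallback_phred)
        phred = np.where(have, self.obs_phred, means[self.obs_col])
        self.obs_error = np.power(10.0, -phred / 10.0)
        self.obs_phred_imputed = phred
        return self.obs_error

    def column(self, index: int) -> PileupColumn:
        """Materialise one column as a :class:`PileupColumn` (for inspection)."""
        sel = self.obs_col == index
        obs = []
        err = self.obs_error[sel] if self.obs_error is not None else None
        for k, (s, q) in enumerate(zip(self.obs_sym[sel], self.obs_phred[sel])):
            obs.append(
                Observation(
                    base=SYMBOLS[s],
                    phred=None if np.isnan(q) else float(q),
                    error=float(err[k]) if err is not None else None,
                )
            )
        return PileupColumn(
            column_index=index,
            ref_symbol=SYMBOLS[self.gapped.ref_codes[index]]
            if not self.gapped.n_mask[index]
            else "N",
            observations=obs,
        )


def _walk_insertions(read: MappedRead, ref_length: int):
    """Yield (junction, length) for each I op; validate the reference span."""
    refp = read.pos  # next reference base to consume (1-based)
    for op, n in read.cigar:
        if op in "M=X":
            refp += n
        elif op == "D" or op == "N":
            refp += n
        elif op == "I":
            yield refp - 1, n
    if refp - 1 > ref_length:
        raise RecordError(
            f"read {read.name}: alignment extends past the contig end "
            f"({refp - 1} > {ref_length})"
        )


def build_gapped_alignment(
    reference: ReferenceSequence, reads: Iterable[MappedRead], contig: str | None = None
) -> GappedAlignment:
    """Build the gapped column space from a reference and its mapped reads."""
    L = reference.length
    contig = contig or getattr(next(iter(reads), None), "contig", reference.name)
    reads = list(reads)
    ins_len = np.zeros(L + 1, dtype=np.int64)
    for read in reads:
        for junction, length in _walk_insertions(read, L):
            if length > ins_len[junction]:
                ins_len[junction] = length
    total_ins = int(ins_len.sum())
    n_cols = L + total_ins

    # column index of ref base p (1-based): (p-1) + (inserted columns left of it)
    cums = np.cumsum(ins_len)  # cums[j] = ins columns at junctions 0..j
    col_of_ref = np.zeros(L + 1, dtype=np.int64)
    col_of_ref[1:] = np.arange(L) + cums[:L]

    base_codes = _BASE_LUT[np.frombuffer(reference.bases.encode(), dtype=np.uint8)]
    n_mask_ref = base_codes < 0

    ref_codes = np.full(n_cols, GAP_CODE, dtype=np.int8)
    ref_pos = np.zeros(n_cols, dtype=np.int64)
    ins_offset = np.zeros(n_cols, dtype=np.int64)
    junction = np.zeros(n_cols, dtype=np.int64)
    n_mask = np.zeros(n_cols, dtype=bool)

    ref_cols = col_of_ref[1:]
    ref_codes[ref_cols] = np.where(n_mask_ref, 0, base_codes)
    ref_pos[ref_cols] = np.arange(1, L + 1)
    n_mask[ref_cols] = n_mask_ref
    for j in np.nonzero(ins_len)[0]:
        start = col_of_ref[j] + 1 if j >= 1 else 0
        block = slice(start, start + ins_len[j])
        ins_offset[block] = np.arange(1, ins_len[j] + 1)
        junction[block] = j
    return GappedAlignment(
        contig=reference.name,
        ref_length=L,
        ref_codes=ref_codes,
        ref_pos=ref_pos,
        ins_offset=ins_offset,
        junction=junction,
        junction_lengths=ins_len,
        col_of_ref=col_of_ref,
        n_mask=n_mask,
    )


def build_pileups(gapped: GappedAlignment, reads: Iterable[MappedRead]) -> Pileup:
    """Assemble per-column observations from the reads' CIGAR alignments.

    M/=/X ops contribute the read base with its quality, D ops contribute
    "-" with missing quality, I ops contribute the inserted bases at the
    junction's gap columns (padded with "-" up to the block length), and
    reads spanning a gapped junction without an insertion contribute "-"
    at every column of the block.  Soft/hard clips contribute nothing.
    """
    col_of_ref = gapped.col_of_ref
    ins_len = gapped.junction_lengths
    junctions_with_ins = np.nonzero(ins_len)[0]

    cols_parts: list[np.ndarray] = []
    syms_parts: list[np.ndarray] = []
    quals_parts: list[np.ndarray] = []

    for read in reads:
        seq_codes = _BASE_LUT[np.frombuffer(read.seq.encode(), dtype=np.uint8)]
        # unknown read bases (N) are treated as gap-symbol-free: encode as A
        # with their own (usually low) quality; they are rare in practice
        seq_codes = np.where(seq_codes < 0, 0, seq_codes).astype(np.int8)
        quals = read.quals
        refp = read.pos
        qpos = 0
        first_ref = None
        read_ins: dict[int, int] = {}
        for op, n in read.cigar:
            if op in "M=X":
                if refp + n - 1 > gapped.ref_length:
                    raise RecordError(
                        f"read {read.name}: alignment extends past the contig end"
                    )
                cols_parts.append(col_of_ref[refp : refp + n])
                syms_parts.append(seq_codes[qpos : qpos + n])
                quals_parts.append(quals[qpos : qpos + n])
                if first_ref is None:
                    first_ref = refp
                refp += n
                qpos += n
            elif op == "D":
                if refp + n - 1 > gapped.ref_length:
                    raise RecordError(
                        f"read {read.name}: alignment extends past the contig end"
                    )
                cols_parts.append(col_of_ref[refp : refp + n])
                syms_parts.append(np.full(n, GAP_CODE, dtype=np.int8))
                quals_parts.append(np.full(n, np.nan))
                if first_ref is None:
                    first_ref = refp
                refp += n
            elif op == "N":
                refp += n
            elif op == "I":
                j = refp - 1
                have = min(n, int(ins_len[j]))
                start = col_of_ref[j] + 1 if j >= 1 else 0
                cols_parts.append(np.arange(start, start + have))
                syms_parts.append(seq_codes[qpos : qpos + have])
                quals_parts.append(quals[qpos : qpos + have])
                pad = int(ins_len[j]) - n
                if pad > 0:
                    cols_parts.append(np.arange(start + n, start + n + pad))
                    syms_parts.append(np.full(pad, GAP_CODE, dtype=np.int8))
                    quals_parts.append(np.full(pad, np.nan))
                read_ins[j] = n
                qpos += n
            elif op in "SH":
                if op == "S":
                    qpos += n
            else:
                raise RecordError(f"read {read.name}: unsupported CIGAR op {op!r}")
        last_ref = refp - 1
        if first_ref is None:
            continue
        # junctions covered by the read's reference span but lacking an I op
        lo = np.searchsorted(junctions_with_ins, first_ref, side="left")
        hi = np.searchsorted(junctions_with_ins, last_ref, side="left")
        for j in junctions_with_ins[lo:hi]:
            if j in read_ins:
                continue
            start = col_of_ref[j] + 1
            n = int(ins_len[j])
            cols_parts.append(np.arange(start, start + n))
            syms_parts.append(np.full(n, GAP_CODE, dtype=np.int8))
            quals_parts.append(np.full(n, np.nan))

    if cols_parts:
        obs_col = np.concatenate(cols_parts)
        obs_sym = np.concatenate(syms_parts)
        obs_phred = np.concatenate(quals_parts)
    else:
        obs_col = np.empty(0, dtype=np.int64)
        obs_sym = np.empty(0, dtype=np.int8)
        obs_phred = np.empty(0)
    return Pileup(gapped, obs_col, obs_sym, obs_phred)


def impute_missing_quality(
    column: PileupColumn, fallback_phred: float = DEFAULT_FALLBACK_PHRED
) -> PileupColumn:
    """Return a copy of ``column`` with missing Phreds imputed and errors set.

    Missing qualities take the arithmetic mean of the column's non-missing
    Phred scores; when every observation is missing, ``fallback_phred``.
    """
    known = [o.phred for o in column.observations if o.phred is not None]
    fill = float(np.mean(known)) if known else float(fallback_phred)
    new_obs = []
    for o in column.observations:
        q = o.phred if o.phred is not None else fill
        new_obs.append(Observation(base=o.base, phred=q, error=10.0 ** (-q / 10.0)))
    return PileupColumn(
        column_index=column.column_index,
        ref_symbol=column.ref_symbol,
        observations=new_obs,
    )


def passes_depth_filter(column, min_depth: int = 5) -> bool:
    """True iff the column's pileup size n_i is at least ``min_depth``."""
    depth = column if isinstance(column, (int, np.integer)) else column.depth
    return depth >= min_depth
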