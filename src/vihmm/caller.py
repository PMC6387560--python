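"""Orchestrate pileup -> emissions -> Viterbi -> VCF-ready variant records.

The decoded per-column state path is converted to variant records with the
usual VCF conventions: SNP states become single-base records; maximal runs of
consecutive deletion-genotype columns merge into one deletion record anchored
on the reference base immediately left (or right, at the contig start);
maximal runs of insertion columns at a junction merge into one insertion
record anchored on the preceding reference base.  Runs mixing heterozygous
and homozygous genotypes split at the zygosity change so each record carries
a single GT.  Match and no-insertion states emit nothing, and no call is ever
emitted from a column that failed the depth filter.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np

from . import emission as em
from . import hmm_core as hc
from . import pileup as pu
from .seq_io import MappedRead, ReferenceSequence

VAR_SNP, VAR_INS, VAR_DEL = "SNP", "Ins", "Del"


@dataclasses.dataclass
class CallerConfig:
    min_depth: int = 5
    emission_mode: str = "normalized"
    fallback_phred: float = 20.0
    strict_classes: bool = False
    min_mapq: int = 0


@dataclasses.dataclass
class VariantCall:
    """A VCF-ready variant record (1-based anchored position)."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]
    var_class: str
    columns: tuple[int, int] = (0, 0)  # [start, end] gapped-column span
    info: dict = dataclasses.field(default_factory=dict)

    @property
    def is_heterozygous(self) -> bool:
        return self.genotype[0] != self.genotype[1]


@dataclasses.dataclass
class CallResult:
    calls: list[VariantCall]
    path: hc.ViterbiPath
    gapped: pu.GappedAlignment
    pileup: pu.Pileup
    depth_ok: np.ndarray


def decode_region(
    reference: ReferenceSequence,
    reads: Iterable[MappedRead],
    transition=None,
    config: CallerConfig | None = None,
) -> CallResult:
    """Run the full decoding pipeline and keep the intermediate products."""
    config = config or CallerConfig()
    model = transition if transition is not None else hc.ClassTransitionModel(
        strict=config.strict_classes
    )
    reads = [r for r in reads if r.mapq >= config.min_mapq]
    gapped = pu.build_gapped_alignment(reference, reads)
    pile = pu.build_pileups(gapped, reads)
    errors = pile.impute(config.fallback_phred)
    table = em.emission_log_table(
        pile.obs_col, pile.obs_sym, errors, gapped.n_columns, config.emission_mode
    )
    depth_ok = em.apply_depth_filter(table, pile.depth, config.min_depth)
    path = hc.viterbi_columns(table, gapped.ref_codes, model)
    calls = path_to_variants(
        path.states,
        gapped,
        reference,
        callable_mask=depth_ok & ~gapped.n_mask,
        path_log_prob=path.log_prob,
    )
    return CallResult(calls=calls, path=path, gapped=gapped, pileup=pile, depth_ok=depth_ok)


def call_region(
    reference: ReferenceSequence,
    reads: Iterable[MappedRead],
    transition=None,
    config: CallerConfig | None = None,
) -> list[VariantCall]:
    """Decode a region and return its variant calls (deterministic)."""
    return decode_region(reference, reads, transition, config).calls


def _snp_record(contig, ref_base, pos, pair, span, info) -> VariantCall:
    r = hc.SYMBOL_TO_CODE[ref_base]
    a, b = pair
    alts = tuple(hc.SYMBOLS[c] for c in sorted({a, b} - {r}))
    if a == b:
        gt = (1, 1)
    elif r in (a, b):
        gt = (0, 1)
    else:
        gt = (1, 2)
    return VariantCall(
        contig=contig,
        pos=pos,
        ref=ref_base,
        alts=alts,
        genotype=gt,
        var_class=VAR_SNP,
        columns=span,
        info=dict(info),
    )


def _del_record(contig, ref_bases, p1, p2, kept, hom, span, info) -> Optional[VariantCall]:
    """Deletion of reference bases p1..p2 (1-based); ``kept`` is the retained
    haplotype's sequence over those bases ("" when homozygous)."""
    L = len(ref_bases)
    if p1 > 1:
        anchor = p1 - 1
        ref = ref_bases[anchor - 1 : p2]
        alt_del = ref_bases[anchor - 1]
        alt_kept = ref_bases[anchor - 1] + kept
        pos = anchor
    else:
        if p2 >= L:
            return None  # whole-contig deletion: no anchoring base exists
        ref = ref_bases[0 : p2 + 1]
        alt_del = ref_bases[p2]
        alt_kept = kept + ref_bases[p2]
        pos = 1
    if hom:
        alts, gt = (alt_del,), (1, 1)
    elif kept == ref_bases[p1 - 1 : p2]:
        alts, gt = (alt_del,), (0, 1)
    else:
        alts, gt = (alt_del, alt_kept), (1, 2)
    return VariantCall(
        contig=contig,
        pos=pos,
        ref=ref,
        alts=alts,
        genotype=gt,
        var_class=VAR_DEL,
        columns=span,
        info=dict(info),
    )


def _ins_record(contig, ref_bases, junction, seq_a, seq_b, span, info) -> VariantCall:
    """Insertion after reference position ``junction`` (0 = before base 1)."""
    if junction >= 1:
        pos = junction
        anchor = ref_bases[junction - 1]
        ref = anchor
        alt_a = anchor + seq_a
        alt_b = anchor + seq_b if seq_b else None
    else:
        pos = 1
        anchor = ref_bases[0]
        ref = anchor
        alt_a = seq_a + anchor
        alt_b = seq_b + anchor if seq_b else None
    if not seq_b:
        alts, gt = (alt_a,), (0, 1)
    elif seq_a == seq_b:
        alts, gt = (alt_a,), (1, 1)
    else:
        alts, gt = (alt_a, alt_b), (1, 2)
    return VariantCall(
        contig=contig,
        pos=pos,
        ref=ref,
        alts=alts,
        genotype=gt,
        var_class=VAR_INS,
        columns=span,
        info=dict(info),
    )


def path_to_variants(
    states: Sequence[int],
    gapped: pu.GappedAlignment,
    reference: ReferenceSequence,
    callable_mask: Optional[np.ndarray] = None,
    path_log_prob: Optional[float] = None,
) -> list[VariantCall]:
    """Convert a decoded state path into anchored variant records."""
    states = np.asarray(states)
    L = gapped.n_columns
    if len(states) != L:
        raise ValueError("path length does not match the gapped alignment")
    info = {} if path_log_prob is None else {"PLP": path_log_prob}
    contig = gapped.contig
    ref_bases = reference.bases
    codes = gapped.ref_codes
    pairs = [hc.state_genotype(int(s)) for s in states]
    gap = hc.GAP_CODE

    def kind(i: int) -> str:
        if callable_mask is not None and not callable_mask[i]:
            return "skip"
        a, b = pairs[i]
        if codes[i] == gap:
            return "none" if (a, b) == (gap, gap) else "ins"
        if (a, b) == (codes[i], codes[i]):
            return "none"
        if gap in (a, b):
            return "del"
        return "snp"

    calls: list[VariantCall] = []
    i = 0
    while i < L:
        k = kind(i)
        if k in ("none", "skip"):
            i += 1
            continue
        if k == "snp":
            calls.append(
                _snp_record(
                    contig,
                    ref_bases[gapped.ref_pos[i] - 1],
                    int(gapped.ref_pos[i]),
                    pairs[i],
                    (i, i),
                    info,
                )
            )
            i += 1
            continue
        if k == "del":
            hom = pairs[i] == (gap, gap)
            j = i
            kept_parts = []
            while j < L and kind(j) == "del" and (pairs[j] == (gap, gap)) == hom:
                if not hom:
                    a, b = pairs[j]
                    kept_parts.append(hc.SYMBOLS[a if b == gap else b])
                j += 1
            rec = _del_record(
                contig,
                ref_bases,
                int(gapped.ref_pos[i]),
                int(gapped.ref_pos[j - 1]),
                "".join(kept_parts),
                hom,
                (i, j - 1),
                info,
            )
            if rec is not None:
                calls.append(rec)
            i = j
            continue
        # insertion run: same junction, same zygosity (one allele absent or not)
        junction = int(gapped.junction[i])
        het = pairs[i][1] == gap
        j = i
        seq_a_parts, seq_b_parts = [], []
        while (
            j < L
            and kind(j) == "ins"
            and int(gapped.junction[j]) == junction
            and (pairs[j][1] == gap) == het
        ):
            a, b = pairs[j]
            if a != gap:
                seq_a_parts.append(hc.SYMBOLS[a])
            if b != gap:
                seq_b_parts.append(hc.SYMBOLS[b])
            j += 1
        calls.append(
            _ins_record(
                contig,
                ref_bases,
                junction,
                "".join(seq_a_parts),
                "".join(seq_b_parts),
                (i, j - 1),
                info,
            )
        )
        i = j
    return calls
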