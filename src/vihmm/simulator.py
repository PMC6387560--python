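"""Diploid short-read simulator driven by a four-class haplotype HMM.

The generator emulates the aligner-free study conditions used to benchmark
the caller: a uniformly random reference segment (default 50 kb); a first
haplotype drawn by a Markov chain over the classes Match/SNP/Del/Ins along
the reference, where a SNP column substitutes one of the three non-reference
bases uniformly ([1/3, 1/3, 1/3]), an insertion column emits a uniform base
([1/4, 1/4, 1/4, 1/4]), a deletion column emits "-", and Match copies the
reference; a second haplotype obtained by independently reverting each
variant event of the first back to the reference with a pre-specified
heterozygous rate; and reads (default 100 bp) drawn half from each
haplotype with per-base errors sampled uniformly from an error range and
converted to Phred qualities.

Reads carry their true placement: start positions are uniform over an
interval extended by one read length on the left and reads are truncated at
the segment ends, so expected coverage is uniform across the whole segment
(the segment behaves like a window on a longer genome, and read lengths are
100 bp on average).  The read count keeps the identity
N = round(depth * ref_length / read_length).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .caller import VAR_DEL, VAR_INS, VAR_SNP, VariantCall
from .errors import VihmmError
from .hmm_core import DEFAULT_CLASS_MATRIX, DEL, INS, MATCH, SNP, _validate_rows
from .seq_io import MappedRead, ReferenceSequence

_PHRED_CAP = 60.0  # quality assigned when the drawn error rate is ~0
_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass
class SimConfig:
    ref_length: int = 50_000
    class_transition: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_CLASS_MATRIX.copy()
    )
    het_rate: float = 0.5
    read_length: int = 100
    depth: float = 15.0
    error_range: tuple[float, float] = (0.001, 0.01)
    seed: Optional[int] = None
    contig: str = "sim1"

    def __post_init__(self):
        if self.ref_length < 1:
            raise VihmmError("ref_length must be >= 1")
        if not 0.0 <= self.het_rate <= 1.0:
            raise VihmmError("het_rate must lie in [0, 1]")
        if self.depth <= 0:
            raise VihmmError("depth must be positive")
        lo, hi = self.error_range
        if not (0.0 <= lo <= hi < 1.0):
            raise VihmmError("error_range must satisfy 0 <= lo <= hi < 1")


@dataclasses.dataclass
class Event:
    """One variant event on haplotype 1.

    ``kind`` is SNP/Del/Ins; ``pos`` is the 1-based reference position of a
    SNP, the first deleted base of a deletion, or the junction (reference
    base immediately left, 0 = before base 1) of an insertion.  ``length``
    is the event's span in columns and ``seq`` the substituted/inserted
    bases.  ``het`` marks events reverted to reference on haplotype 2.
    """

    kind: str
    pos: int
    length: int
    seq: str
    het: bool = False

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.pos, 1 if self.kind == VAR_INS else 0)


@dataclasses.dataclass
class TruthSet:
    """Ground truth of one simulation: VCF-ready records plus the gapped
    haplotype pair aligned to the gapped reference."""

    records: list[VariantCall]
    events: list[Event]
    ref_gapped: str
    hap1_gapped: str
    hap2_gapped: str
    class_track: list[str]


@dataclasses.dataclass
class SimResult:
    config: SimConfig
    reference: ReferenceSequence
    truth: TruthSet
    reads: list[MappedRead]


def simulate_reference(length: int, rng) -> ReferenceSequence:
    """i.i.d. uniform bases over {A, C, G, T}."""
    if length < 1:
        raise VihmmError("reference length must be >= 1")
    rng = np.random.default_rng(rng)
    codes = rng.integers(0, 4, size=length)
    bases = _ACGT_BYTES[codes].tobytes().decode()
    return ReferenceSequence(name="sim1", bases=bases)


def _sample_events(reference: ReferenceSequence, class_transition, rng) -> list[Event]:
    """Draw the class chain along the reference and return merged events.

    The chain starts as if preceded by a Match column; stretches of Match are
    skipped with geometric jumps, which is an exact simulation of the chain.
    """
    T = _validate_rows(np.asarray(class_transition, dtype=float))
    L = reference.length
    bases = reference.bases
    p_leave = 1.0 - T[0, 0]
    if p_leave <= 0.0:
        return []
    leave = T[0, 1:] / p_leave  # P(SNP/Del/Ins | leaving Match)
    cum_leave = np.cumsum(leave)
    rows_cum = np.cumsum(T, axis=1)

    def next_class(cur: int) -> int:
        return int(np.searchsorted(rows_cum[cur], rng.random(), side="right"))

    atoms: list[tuple[str, int, str]] = []  # (kind, pos-or-junction, allele)
    i = 0  # last reference base consumed
    while True:
        jump = int(rng.geometric(p_leave))
        pos = i + jump
        if pos > L:
            break
        cls = 1 + int(np.searchsorted(cum_leave, rng.random(), side="right"))
        ref_i = pos - 1
        while True:
            if cls == 1:  # SNP
                ref_i += 1
                if ref_i > L:
                    break
                r = "ACGT".index(bases[ref_i - 1])
                alt = "ACGT"[(r + 1 + int(rng.integers(0, 3))) % 4]
                atoms.append((VAR_SNP, ref_i, alt))
            elif cls == 2:  # Del
                ref_i += 1
                if ref_i > L:
                    break
                atoms.append((VAR_DEL, ref_i, ""))
            else:  # Ins (junction after ref_i)
                atoms.append((VAR_INS, ref_i, "ACGT"[int(rng.integers(0, 4))]))
            cls = next_class(cls)
            if cls == 0:
                break
        if ref_i >= L:
            break
        i = ref_i + 1  # the Match column that ended the run
        if i >= L:
            break

    events: list[Event] = []
    for kind, pos, allele in atoms:
        prev = events[-1] if events else None
        if (
            prev is not None
            and kind == VAR_DEL
            and prev.kind == VAR_DEL
            and prev.pos + prev.length == pos
        ):
            prev.length += 1
        elif (
            prev is not None
            and kind == VAR_INS
            and prev.kind == VAR_INS
            and prev.pos == pos
        ):
            prev.length += 1
            prev.seq += allele
        elif kind == VAR_SNP:
            events.append(Event(VAR_SNP, pos, 1, allele))
        elif kind == VAR_DEL:
            events.append(Event(VAR_DEL, pos, 1, ""))
        else:
            events.append(Event(VAR_INS, pos, 1, allele))
    return events


def _gapped_strings(reference: ReferenceSequence, events: list[Event]):
    """Gapped (reference, hap1, hap2, class track) built from the event list."""
    bases = reference.bases
    ref_parts, h1_parts, h2_parts, cls_parts = [], [], [], []
    cur = 1
    for ev in sorted(events, key=lambda e: e.sort_key):
        if ev.kind == VAR_INS:
            seg = bases[cur - 1 : ev.pos]
            ref_parts.append(seg)
            h1_parts.append(seg)
            h2_parts.append(seg)
            cls_parts.extend([MATCH] * len(seg))
            ref_parts.append("-" * ev.length)
            h1_parts.append(ev.seq)
            h2_parts.append("-" * ev.length if ev.het else ev.seq)
            cls_parts.extend([INS] * ev.length)
            cur = ev.pos + 1
        else:
            seg = bases[cur - 1 : ev.pos - 1]
            ref_parts.append(seg)
            h1_parts.append(seg)
            h2_parts.append(seg)
            cls_parts.extend([MATCH] * len(seg))
            span = bases[ev.pos - 1 : ev.pos - 1 + ev.length]
            ref_parts.append(span)
            if ev.kind == VAR_SNP:
                h1_parts.append(ev.seq)
                h2_parts.append(span if ev.het else ev.seq)
                cls_parts.extend([SNP] * ev.length)
            else:
                h1_parts.append("-" * ev.length)
                h2_parts.append(span if ev.het else "-" * ev.length)
                cls_parts.extend([DEL] * ev.length)
            cur = ev.pos + ev.length
    tail = bases[cur - 1 :]
    ref_parts.append(tail)
    h1_parts.append(tail)
    h2_parts.append(tail)
    cls_parts.extend([MATCH] * len(tail))
    return (
        "".join(ref_parts),
        "".join(h1_parts),
        "".join(h2_parts),
        cls_parts,
    )


def simulate_haplotype(reference: ReferenceSequence, class_transition, rng):
    """Draw haplotype 1: returns (gapped_reference, gapped_haplotype,
    per-column class track, events)."""
    rng = np.random.default_rng(rng)
    events = _sample_events(reference, class_transition, rng)
    ref_g, hap_g, _, cls = _gapped_strings(reference, events)
    return ref_g, hap_g, cls, events


def make_diploid(events: list[Event], het_rate: float, rng) -> list[Event]:
    """Mark each variant event heterozygous (reverted on haplotype 2) with
    probability ``het_rate``, independently."""
    rng = np.random.default_rng(rng)
    flags = rng.random(len(events)) < het_rate
    for ev, het in zip(events, flags):
        ev.het = bool(het)
    return events


def truth_records(reference: ReferenceSequence, events: list[Event]) -> list[VariantCall]:
    """Anchored VCF-ready truth records for the event list."""
    bases = reference.bases
    L = reference.length
    out = []
    for ev in sorted(events, key=lambda e: e.sort_key):
        gt = (0, 1) if ev.het else (1, 1)
        if ev.kind == VAR_SNP:
            out.append(
                VariantCall(
                    contig=reference.name,
                    pos=ev.pos,
                    ref=bases[ev.pos - 1],
                    alts=(ev.seq,),
                    genotype=gt,
                    var_class=VAR_SNP,
                )
            )
        elif ev.kind == VAR_DEL:
            p1, p2 = ev.pos, ev.pos + ev.length - 1
            if p1 > 1:
                pos, ref, alt = p1 - 1, bases[p1 - 2 : p2], bases[p1 - 2]
            elif p2 < L:
                pos, ref, alt = 1, bases[0 : p2 + 1], bases[p2]
            else:
                continue  # degenerate whole-contig deletion
            out.append(
                VariantCall(
                    contig=reference.name,
                    pos=pos,
                    ref=ref,
                    alts=(alt,),
                    genotype=gt,
                    var_class=VAR_DEL,
                )
            )
        else:
            if ev.pos >= 1:
                pos, ref, alt = ev.pos, bases[ev.pos - 1], bases[ev.pos - 1] + ev.seq
            else:
                pos, ref, alt = 1, bases[0], ev.seq + bases[0]
            out.append(
                VariantCall(
                    contig=reference.name,
                    pos=pos,
                    ref=ref,
                    alts=(alt,),
                    genotype=gt,
                    var_class=VAR_INS,
                )
            )
    return out


def _haplotype_arrays(reference: ReferenceSequence, events: list[Event], hap: int):
    """Ungapped haplotype base codes and the 1-based reference position of
    each haplotype base (0 for inserted bases)."""
    lut = {c: i for i, c in enumerate("ACGT")}
    bases = reference.bases
    codes_parts, refpos_parts = [], []
    cur = 1
    for ev in sorted(events, key=lambda e: e.sort_key):
        if hap == 2 and ev.het:
            continue
        if ev.kind == VAR_INS:
            seg = bases[cur - 1 : ev.pos]
            if seg:
                codes_parts.append(np.frombuffer(seg.encode(), np.uint8))
                refpos_parts.append(np.arange(cur, ev.pos + 1))
            codes_parts.append(np.frombuffer(ev.seq.encode(), np.uint8))
            refpos_parts.append(np.zeros(ev.length, dtype=np.int64))
            cur = ev.pos + 1
        else:
            seg = bases[cur - 1 : ev.pos - 1]
            if seg:
                codes_parts.append(np.frombuffer(seg.encode(), np.uint8))
                refpos_parts.append(np.arange(cur, ev.pos))
            if ev.kind == VAR_SNP:
                codes_parts.append(np.frombuffer(ev.seq.encode(), np.uint8))
                refpos_parts.append(np.array([ev.pos]))
            cur = ev.pos + ev.length
    tail = bases[cur - 1 :]
    if tail:
        codes_parts.append(np.frombuffer(tail.encode(), np.uint8))
        refpos_parts.append(np.arange(cur, reference.length + 1))
    raw = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint8)
    ascii_lut = np.zeros(256, dtype=np.int8)
    for c, i in lut.items():
        ascii_lut[ord(c)] = i
    codes = ascii_lut[raw]
    refpos = (
        np.concatenate(refpos_parts) if refpos_parts else np.empty(0, np.int64)
    )
    return codes, refpos


def _cigar_from_refpos(refpos: np.ndarray) -> tuple[list[tuple[str, int]], int]:
    """CIGAR and 1-based mapping position for a read slice's refpos track.

    Leading/trailing inserted bases become soft clips (an alignment cannot
    start or end with I); interior refpos jumps become D ops.
    """
    m = len(refpos)
    # fast path: fully aligned, consecutive reference positions -> single M
    if refpos[0] > 0 and refpos[-1] - refpos[0] == m - 1 and refpos.min() > 0:
        return [("M", m)], int(refpos[0])
    aligned = np.nonzero(refpos > 0)[0]
    if len(aligned) == 0:
        return [], 0
    first, last = aligned[0], aligned[-1]
    ops: list[tuple[str, int]] = []
    if first > 0:
        ops.append(("S", int(first)))
    prev_rp = None
    for j in range(first, last + 1):
        rp = int(refpos[j])
        if rp == 0:
            op = "I"
        else:
            if prev_rp is not None and rp > prev_rp + 1:
                ops.append(("D", rp - prev_rp - 1))
            op = "M"
            prev_rp = rp
        if ops and ops[-1][0] == op and op != "D":
            ops[-1] = (op, ops[-1][1] + 1)
        elif op in "MI":
            ops.append((op, 1))
    if last < m - 1:
        ops.append(("S", int(m - 1 - last)))
    return ops, int(refpos[first])


def simulate_reads(
    hap_data: list[tuple[np.ndarray, np.ndarray]],
    config: SimConfig,
    rng,
    contig: str = "sim1",
) -> list[MappedRead]:
    """Generate reads with true placement, exactly half (+-1) per haplotype.

    ``hap_data`` holds (base codes, refpos) per haplotype.  Per base an error
    probability is drawn uniformly from ``config.error_range``; with that
    probability the base flips to one of the three other bases, and the
    quality written is Phred = round(-10 log10 e) (capped when e ~ 0).
    """
    rng = np.random.default_rng(rng)
    rl = config.read_length
    N = int(round(config.depth * config.ref_length / rl))
    counts = [N // 2, N - N // 2]
    lo, hi = config.error_range
    reads: list[MappedRead] = []
    k = 0
    for hap_idx, ((codes, refpos), n_reads) in enumerate(zip(hap_data, counts), 1):
        hap_len = len(codes)
        if hap_len < 1:
            raise VihmmError("haplotype is empty")
        made = 0
        while made < n_reads:
            u = int(rng.integers(-(rl - 1), hap_len))
            a, b = max(0, u), min(hap_len, u + rl)
            if b - a < 1:
                continue
            sub_refpos = refpos[a:b]
            cigar, pos = _cigar_from_refpos(sub_refpos)
            if not cigar:
                continue  # read lies entirely inside an insertion
            m = b - a
            base = codes[a:b].copy()
            err = rng.uniform(lo, hi, size=m)
            flip = rng.random(m) < err
            if flip.any():
                base[flip] = (base[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
            with np.errstate(divide="ignore"):
                quals = np.where(
                    err > 0, np.minimum(np.round(-10.0 * np.log10(np.maximum(err, 1e-300))), _PHRED_CAP), _PHRED_CAP
                )
            seq = _ACGT_BYTES[base].tobytes().decode()
            reads.append(
                MappedRead(
                    name=f"sim_h{hap_idx}_{k}",
                    contig=contig,
                    pos=pos,
                    cigar=cigar,
                    seq=seq,
                    quals=quals.astype(float),
                )
            )
            made += 1
            k += 1
    return reads


def simulate(config: SimConfig, rng=None) -> SimResult:
    """Run the full generator: reference, diploid truth, and placed reads."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    reference = simulate_reference(config.ref_length, rng)
    reference = ReferenceSequence(name=config.contig, bases=reference.bases)
    events = _sample_events(reference, config.class_transition, rng)
    make_diploid(events, config.het_rate, rng)
    records = truth_records(reference, events)
    ref_g, h1_g, h2_g, cls = _gapped_strings(reference, events)
    truth = TruthSet(
        records=records,
        events=events,
        ref_gapped=ref_g,
        hap1_gapped=h1_g,
        hap2_gapped=h2_g,
        class_track=cls,
    )
    hap_data = [
        _haplotype_arrays(reference, events, 1),
        _haplotype_arrays(reference, events, 2),
    ]
    reads = simulate_reads(hap_data, config, rng, contig=config.contig)
    return SimResult(config=config, reference=reference, truth=truth, reads=reads)
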