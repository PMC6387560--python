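"""Reading and writing the standard formats the caller touches.

FASTA references are read through Biopython, mapped reads through pysam
(SAM or BAM), variants are written as plain VCF 4.2 text and read back
through pysam, and transition matrices travel as labeled TSV in either the
full 30x30 form or the 4x4 class form.

Coordinates follow the standards at the boundary: SAM/VCF positions are
1-based inclusive; everything internal to the package is 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam
from Bio import SeqIO

from .errors import ConsistencyError, FormatError, RecordError, ValidationError
from .hmm_core import CLASS_ORDER, N_STATES, STATE_LABELS

_VALID_BASES = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")

#: CIGAR operations that consume the query sequence / the reference
QUERY_OPS = set("MIS=X")
REF_OPS = set("MD=XN")
_CIGAR_CODES = "MIDNSHP=X"


@dataclasses.dataclass
class ReferenceSequence:
    """A single contig: upper-cased bases over {A,C,G,T} plus hard-masked N."""

    name: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class MappedRead:
    """One mapped read with CIGAR and per-base Phred qualities.

    ``pos`` is the 1-based leftmost reference coordinate.  ``quals`` is a
    float array aligned with ``seq``; NaN marks a missing quality.
    """

    name: str
    contig: str
    pos: int
    cigar: list[tuple[str, int]]
    seq: str
    quals: np.ndarray
    mapq: int = 60
    flag: int = 0

    def __post_init__(self):
        if self.pos < 1:
            raise RecordError(f"read {self.name}: pos {self.pos} < 1")
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS and op != "S") + sum(
            n for op, n in self.cigar if op == "S"
        )
        if qlen != len(self.seq):
            raise RecordError(
                f"read {self.name}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise RecordError(
                f"read {self.name}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost reference coordinate."""
        return self.pos - 1 + sum(n for op, n in self.cigar if op in REF_OPS)

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


@dataclasses.dataclass
class TransitionMatrixFile:
    """Parsed transition-matrix TSV: either full 30x30 or 4x4 class form."""

    labels: tuple[str, ...]
    values: np.ndarray

    @property
    def is_class_form(self) -> bool:
        return self.values.shape == (4, 4)


def read_fasta(path, ambiguous: str = "mask") -> list[ReferenceSequence]:
    """Read a FASTA file into :class:`ReferenceSequence` records.

    ``ambiguous`` controls non-ACGT characters: ``"mask"`` (default) replaces
    IUPAC ambiguity codes with N (those columns are later excluded from
    calling), ``"error"`` rejects them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        if not bases:
            raise FormatError(f"contig {rec.id}: empty sequence")
        bad = set(bases) - _VALID_BASES
        if bad:
            if not bad <= _IUPAC or ambiguous == "error":
                raise FormatError(
                    f"contig {rec.id}: non-ACGT characters {sorted(bad)}"
                )
            table = str.maketrans({c: "N" for c in bad})
            bases = bases.translate(table)
        records.append(ReferenceSequence(name=rec.id, bases=bases))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(references: Iterable[ReferenceSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.bases), width):
                fh.write(ref.bases[i : i + width] + "\n")


def _parse_region(region: str) -> tuple[str, Optional[int], Optional[int]]:
    if ":" not in region:
        return region, None, None
    contig, span = region.rsplit(":", 1)
    start, end = span.split("-")
    return contig, int(start), int(end)


def _checked_iter(af, path):
    """Iterate a pysam file, converting parser failures to RecordError."""
    it = iter(af)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as exc:
            raise RecordError(f"malformed alignment record in {path}: {exc}") from exc


def read_alignments(
    path, region: Optional[str] = None, min_mapq: int = 0
) -> Iterator[MappedRead]:
    """Stream mapped reads from a SAM/BAM file as :class:`MappedRead`.

    Unmapped, secondary and supplementary records are excluded.  ``region``
    is ``contig`` or ``contig:start-end`` (1-based inclusive) and is applied
    by overlap filtering, so no index is required.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"alignment file not found: {path}")
    want = _parse_region(region) if region else None
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        records = _checked_iter(af, path)
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            seq = rec.query_sequence
            if seq is None or rec.cigartuples is None:
                raise RecordError(f"read {rec.query_name}: missing SEQ or CIGAR")
            cigar = [(_CIGAR_CODES[op], n) for op, n in rec.cigartuples]
            q = rec.query_qualities
            quals = (
                np.full(len(seq), np.nan)
                if q is None
                else np.asarray(q, dtype=float)
            )
            read = MappedRead(
                name=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start + 1,
                cigar=cigar,
                seq=seq.upper(),
                quals=quals,
                mapq=rec.mapping_quality,
                flag=rec.flag,
            )
            if want is not None:
                contig, start, end = want
                if read.contig != contig:
                    continue
                if start is not None and (read.ref_end < start or read.pos > end):
                    continue
            yield read


def write_sam(
    reads: Iterable[MappedRead],
    references: Iterable[ReferenceSequence],
    path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write reads as a coordinate-sorted plain-text SAM file."""
    refs = list(references)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for ref in refs:
            fh.write(f"@SQ\tSN:{ref.name}\tLN:{ref.length}\n")
        for comment in header_comments:
            fh.write(f"@CO\t{comment}\n")
        for read in sorted(reads, key=lambda r: (r.contig, r.pos)):
            qual = "".join(
                "!" if np.isnan(q) else chr(int(round(min(q, 93))) + 33)
                for q in read.quals
            )
            fh.write(
                "\t".join(
                    [
                        read.name,
                        str(read.flag),
                        read.contig,
                        str(read.pos),
                        str(read.mapq),
                        read.cigar_string(),
                        "*",
                        "0",
                        "0",
                        read.seq,
                        qual,
                    ]
                )
                + "\n"
            )


def write_fastq(reads: Iterable[MappedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(
                "!" if np.isnan(q) else chr(int(round(min(q, 93))) + 33)
                for q in read.quals
            )
            fh.write(f"@{read.name}\n{read.seq}\n+\n{qual}\n")


def _format_gt(genotype: tuple[int, int]) -> str:
    return "/".join(str(a) for a in sorted(genotype))


def write_vcf(
    calls,
    references: Iterable[ReferenceSequence],
    path,
    sample_name: str = "sample1",
    header_comments: Iterable[str] = (),
) -> None:
    """Write variant calls as VCF 4.2 with a single sample's GT field.

    Every REF allele is checked against the reference at POS; a mismatch
    raises :class:`ConsistencyError`.
    """
    refs = {r.name: r for r in references}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vihmm\n")
        for comment in header_comments:
            fh.write(f"##{comment}\n")
        for ref in refs.values():
            fh.write(f"##contig=<ID={ref.name},length={ref.length}>\n")
        fh.write(
            '##INFO=<ID=PLP,Number=1,Type=Float,'
            'Description="Log probability of the whole decoded state path">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_name
            + "\n"
        )
        for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
            ref = refs.get(call.contig)
            if ref is None:
                raise ConsistencyError(f"unknown contig {call.contig}")
            expect = ref.bases[call.pos - 1 : call.pos - 1 + len(call.ref)]
            if expect != call.ref:
                raise ConsistencyError(
                    f"{call.contig}:{call.pos} REF {call.ref!r} does not match "
                    f"reference {expect!r}"
                )
            plp = call.info.get("PLP") if getattr(call, "info", None) else None
            info = "." if plp is None else f"PLP={plp:.4f}"
            fh.write(
                "\t".join(
                    [
                        call.contig,
                        str(call.pos),
                        ".",
                        call.ref,
                        ",".join(call.alts),
                        ".",
                        ".",
                        info,
                        "GT",
                        _format_gt(call.genotype),
                    ]
                )
                + "\n"
            )


@dataclasses.dataclass
class VcfRecord:
    """Minimal in-memory VCF record used by the evaluation layer."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, ...]


def read_vcf(path) -> list[VcfRecord]:
    """Read a (single-sample) VCF into simple records via pysam."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF file not found: {path}")
    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            if samples:
                gt = rec.samples[samples[0]].get("GT") or ()
                genotype = tuple(a for a in gt if a is not None)
            else:
                genotype = ()
            out.append(
                VcfRecord(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    genotype=genotype,
                )
            )
    return out


def read_transition_matrix(path) -> TransitionMatrixFile:
    """Read a labeled TSV transition matrix (30x30 full or 4x4 class form).

    The first row and first column carry labels: s1..s30 in canonical order
    for the full form, or Match/SNP/Del/Ins for the class form.  Rows must be
    stochastic within 1e-6; accepted matrices are renormalized so every row
    sums to 1 within 1e-9.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"transition matrix file not found: {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"empty transition matrix file: {path}")
    header = rows[0][1:]
    body = rows[1:]
    n = len(header)
    if n == N_STATES:
        expected = STATE_LABELS
    elif n == 4:
        expected = CLASS_ORDER
    else:
        raise FormatError(
            f"transition matrix must be 30x30 or 4x4, got {n} columns"
        )
    if tuple(header) != tuple(expected):
        raise FormatError(
            f"column labels {header[:4]}... do not match the canonical "
            f"ordering {expected[:4]}..."
        )
    if len(body) != n:
        raise FormatError(f"expected {n} data rows, got {len(body)}")
    values = np.empty((n, n))
    for i, row in enumerate(body):
        if row[0] != expected[i]:
            raise FormatError(f"row label {row[0]!r} != {expected[i]!r}")
        if len(row) != n + 1:
            raise FormatError(f"row {row[0]}: expected {n} values, got {len(row) - 1}")
        values[i] = [float(x) for x in row[1:]]
    if np.any(values < 0) or np.any(values > 1):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    sums = values.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"row {expected[bad]} sums to {sums[bad]:.6g}, expected 1"
        )
    values = values / sums[:, None]
    return TransitionMatrixFile(labels=tuple(expected), values=values)


def write_transition_matrix(values, path) -> None:
    """Write a 4x4 class or 30x30 full matrix in the labeled TSV dialect."""
    values = np.asarray(values, dtype=float)
    labels = CLASS_ORDER if values.shape == (4, 4) else STATE_LABELS
    if values.shape not in {(4, 4), (N_STATES, N_STATES)}:
        raise ValidationError(f"cannot write matrix of shape {values.shape}")
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, values):
            fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
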