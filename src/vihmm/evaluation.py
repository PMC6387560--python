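"""Scoring calls against truth: TP/FP/FN by exact locus match, the
sensitivity/precision/F1 triple, INDEL-length stratification, and the
multi-replicate simulation benchmark.

Matching is locus-exact within a variant class: a called SNP is a true
positive iff a truth SNP sits at exactly the same (contig, anchored POS);
INDELs likewise.  Genotype agreement is not required by default.  Records
are split into bi-allelic primitives and trimmed (shared suffix, then shared
prefix with a POS shift) before matching so externally produced VCFs compare
on the same representation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import VihmmError

CLASS_SNP, CLASS_INDEL = "SNP", "INDEL"
INDEL_BINS = ("1", "2", "3", "4", "5", "6", ">6")


@dataclasses.dataclass
class SimpleVariant:
    """A normalized bi-allelic variant used for matching."""

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, ...]

    @property
    def var_class(self) -> str:
        return CLASS_SNP if len(self.ref) == 1 and len(self.alt) == 1 else CLASS_INDEL

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def locus(self) -> tuple[str, int]:
        return (self.contig, self.pos)


@dataclasses.dataclass
class Metrics:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = ()


@dataclasses.dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tp_loci: frozenset
    fp_loci: frozenset
    fn_loci: frozenset


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize(records: Iterable) -> list[SimpleVariant]:
    """Split multi-allelic records into trimmed bi-allelic primitives.

    Accepts anything with contig/pos/ref/alts/genotype attributes (package
    :class:`~vihmm.caller.VariantCall` objects or VCF records read back).
    """
    out = []
    for rec in records:
        gt = tuple(getattr(rec, "genotype", ()) or ())
        for i, alt in enumerate(rec.alts, start=1):
            if alt == rec.ref:
                continue
            if gt:
                n_alt = sum(1 for a in gt if a == i)
                sub_gt = (1, 1) if n_alt >= 2 else (0, 1) if n_alt == 1 else (0, 0)
            else:
                sub_gt = ()
            pos, ref, alt_t = _trim(rec.pos, rec.ref, alt)
            out.append(
                SimpleVariant(
                    contig=rec.contig, pos=pos, ref=ref, alt=alt_t, genotype=sub_gt
                )
            )
    return out


def _loci(variants: Sequence[SimpleVariant], var_class: str, require_genotype: bool):
    keys = set()
    for v in variants:
        if v.var_class != var_class:
            continue
        if require_genotype:
            keys.add((v.contig, v.pos, v.ref, v.alt, tuple(sorted(v.genotype))))
        else:
            keys.add(v.locus)
    return keys


def match_calls(
    truth,
    called,
    var_class: str = CLASS_SNP,
    require_genotype: bool = False,
) -> MatchResult:
    """Locus-exact TP/FP/FN within one variant class (SNP or INDEL)."""
    if var_class not in (CLASS_SNP, CLASS_INDEL):
        raise VihmmError(f"var_class must be SNP or INDEL, got {var_class!r}")
    t = normalize(truth)
    c = normalize(called)
    contigs_t = {v.contig for v in t}
    contigs_c = {v.contig for v in c}
    if contigs_t and contigs_c and not (contigs_t & contigs_c):
        raise VihmmError(
            f"truth contigs {sorted(contigs_t)} and call contigs "
            f"{sorted(contigs_c)} do not overlap"
        )
    tk = _loci(t, var_class, require_genotype)
    ck = _loci(c, var_class, require_genotype)
    tp = tk & ck
    return MatchResult(
        tp=len(tp),
        fp=len(ck - tk),
        fn=len(tk - ck),
        tp_loci=frozenset(tp),
        fp_loci=frozenset(ck - tk),
        fn_loci=frozenset(tk - ck),
    )


def compute_metrics(tp: int, fp: int, fn: int) -> Metrics:
    """sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = 2TP/(2TP+FP+FN); 0/0 is reported as 0 and flagged."""
    if min(tp, fp, fn) < 0:
        raise VihmmError("counts must be non-negative")
    undefined = []
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        sens, _ = 0.0, undefined.append("sensitivity")
    if tp + fp > 0:
        prec = tp / (tp + fp)
    else:
        prec, _ = 0.0, undefined.append("precision")
    if 2 * tp + fp + fn > 0:
        f1 = 2 * tp / (2 * tp + fp + fn)
    else:
        f1, _ = 0.0, undefined.append("f1")
    return Metrics(
        tp=tp, fp=fp, fn=fn, sensitivity=sens, precision=prec, f1=f1,
        undefined=tuple(undefined),
    )


def evaluate(truth, called, var_class: str = CLASS_SNP, require_genotype=False) -> Metrics:
    m = match_calls(truth, called, var_class, require_genotype)
    return compute_metrics(m.tp, m.fp, m.fn)


def _length_bin(length: int) -> str:
    return str(length) if 1 <= length <= 6 else ">6"


def stratify_by_indel_length(truth, called) -> dict[str, Metrics]:
    """Per-length-bin metrics for INDELs (bins 1..6 and >6).

    A call counts as TP only when a truth record in the *same* bin shares its
    locus; false positives fall into the bin of the call's own length.
    """
    t = [v for v in normalize(truth) if v.var_class == CLASS_INDEL]
    c = [v for v in normalize(called) if v.var_class == CLASS_INDEL]
    out = {}
    for b in INDEL_BINS:
        tb = {v.locus for v in t if _length_bin(v.indel_length) == b}
        cb = {v.locus for v in c if _length_bin(v.indel_length) == b}
        out[b] = compute_metrics(len(tb & cb), len(cb - tb), len(tb - cb))
    return out


@dataclasses.dataclass
class Summary:
    mean_sensitivity: float
    mean_precision: float
    mean_f1: float
    se_sensitivity: Optional[float]
    se_precision: Optional[float]
    se_f1: Optional[float]
    n: int


def replicate_summary(per_replicate: Sequence[Metrics]) -> Summary:
    """Across-replicate arithmetic means with standard errors."""
    if not per_replicate:
        raise VihmmError("need at least one replicate")
    n = len(per_replicate)
    sens = np.array([m.sensitivity for m in per_replicate])
    prec = np.array([m.precision for m in per_replicate])
    f1 = np.array([m.f1 for m in per_replicate])

    def se(x):
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else None

    return Summary(
        mean_sensitivity=float(sens.mean()),
        mean_precision=float(prec.mean()),
        mean_f1=float(f1.mean()),
        se_sensitivity=se(sens),
        se_precision=se(prec),
        se_f1=se(f1),
        n=n,
    )


def run_simulation_benchmark(
    n_replicates: int,
    depth: float,
    seed,
    ref_length: int = 50_000,
    var_class: str = CLASS_SNP,
    error_range: tuple[float, float] = (0.001, 0.01),
    het_rate: float = 0.5,
    caller_config=None,
    transition=None,
) -> list[Metrics]:
    """Simulate -> call -> score, once per replicate, with derived seeds.

    This is the replicate protocol used throughout the benchmarking: each
    replicate draws a fresh 50 kb reference, diploid truth and true-placement
    reads, runs the caller on them, and scores locus-exact within
    ``var_class``.
    """
    from .caller import CallerConfig, call_region
    from .simulator import SimConfig, simulate

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    config = caller_config or CallerConfig()
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        sim = simulate(
            SimConfig(
                ref_length=ref_length,
                depth=depth,
                error_range=error_range,
                het_rate=het_rate,
            ),
            rng=rng,
        )
        calls = call_region(sim.reference, sim.reads, transition, config)
        out.append(evaluate(sim.truth.records, calls, var_class))
    return out
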