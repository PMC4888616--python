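"""Deterministic flanking-primer design for SSR loci.

One primer pair per locus is chosen by exhaustive enumeration of all
(left window, right window, length) candidates whose amplicon fully
contains the repeat tract and that satisfy every bound (length 18-27 nt,
Tm 55-65 degC, GC 30-70 %, product 100-300 bp).  Candidates are scored
by a fixed penalty -- the weighted absolute deviation from the optima
(length 20 nt, Tm 60 degC, GC 50 %; unit weights) -- and the
minimum-penalty pair wins, with ties broken by smaller product, then
leftmost left-primer start, then shorter left primer.  Identical inputs
always yield the identical pair.

Melting temperatures use the nearest-neighbour model with the unified
thermodynamic parameter set at 50 mM monovalent salt and 50 nM primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .seqio import SequenceRecord, revcomp
from .ssr_scan import SSRLocus


@dataclass(frozen=True)
class DesignConstraints:
    primer_len: tuple[int, int] = (18, 27)
    opt_len: int = 20
    tm: tuple[float, float] = (55.0, 65.0)
    opt_tm: float = 60.0
    gc: tuple[float, float] = (30.0, 70.0)
    opt_gc: float = 50.0
    product: tuple[int, int] = (100, 300)
    # penalty weights per unit deviation (nt, degC, %-point)
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 1.0

    def __post_init__(self):
        for lo_hi, opt in ((self.primer_len, self.opt_len),
                           (self.tm, self.opt_tm), (self.gc, self.opt_gc)):
            if not lo_hi[0] <= opt <= lo_hi[1]:
                raise ValueError(f"optimum {opt} outside bounds {lo_hi}")
        if self.product[0] > self.product[1]:
            raise ValueError("product bounds inverted")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; ``left`` is plus-strand 5'->3', ``right`` is the
    reverse complement of the plus strand, 5'->3' as synthesised."""

    left: str
    right: str
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    expected_product: int
    left_start: int   # 1-based, plus strand, 5' base of left primer
    right_end: int    # 1-based, plus strand, 5' base of right primer
    marker_id: str | None = None


def gc_percent(seq: str) -> float:
    """GC content as a percentage; rejects empty or ambiguous input."""
    if not seq:
        raise ValueError("gc_percent of empty sequence")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"ambiguous base in {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Nearest-neighbour Tm (degC), unified parameter set, 50 mM Na+,
    50 nM primer; deterministic for a given sequence."""
    if not 18 <= len(seq) <= 36:
        raise ValueError(f"Tm defined for 18-36 nt, got {len(seq)}")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"ambiguous base in {seq!r}")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=50, K=0, Tris=0,
                           Mg=0, dNTPs=0, dnac1=50, dnac2=0, saltcorr=5))


def _primer_penalty(seq: str, c: DesignConstraints) -> float | None:
    """Penalty of one primer, or None if it violates a bound."""
    if "N" in seq:
        return None
    gc = gc_percent(seq)
    if not c.gc[0] <= gc <= c.gc[1]:
        return None
    tm = melting_temperature(seq)
    if not c.tm[0] <= tm <= c.tm[1]:
        return None
    return (c.w_len * abs(len(seq) - c.opt_len) +
            c.w_tm * abs(tm - c.opt_tm) +
            c.w_gc * abs(gc - c.opt_gc))


def design_primer_pair(locus: SSRLocus, scaffold: SequenceRecord,
                       constraints: DesignConstraints | None = None
                       ) -> PrimerPair | None:
    """Best-scoring primer pair flanking ``locus``, or None when no
    candidate satisfies every constraint (e.g. the tract sits too close
    to a scaffold edge, or the flanks are too AT-rich)."""
    c = constraints or DesignConstraints()
    if locus.seq_id != scaffold.id:
        raise ValueError(
            f"locus on {locus.seq_id!r} but scaffold is {scaffold.id!r}")
    s = scaffold.residues
    n = len(s)
    s0, e0 = locus.start, locus.end
    lmin, lmax = c.primer_len
    pmin, pmax = c.product

    # Left candidates: primer occupies [a, a+L-1] entirely left of the
    # tract; only a >= s0 - pmax can ever reach a product <= pmax.
    lefts: list[tuple[float, int, int]] = []   # (penalty, a, L)
    for a in range(max(1, s0 - pmax), s0):
        for L in range(lmin, lmax + 1):
            if a + L - 1 > s0 - 1:
                break
            pen = _primer_penalty(s[a - 1:a - 1 + L], c)
            if pen is not None:
                lefts.append((pen, a, L))
    if not lefts:
        return None

    # Right candidates: plus-strand span [b-R+1, b] entirely right of the
    # tract; keyed by b (the amplicon's right end).
    best_right: dict[int, tuple[float, int]] = {}   # b -> (penalty, R)
    for b in range(e0 + lmin, min(n, e0 + pmax) + 1):
        for R in range(lmin, lmax + 1):
            if b - R + 1 < e0 + 1:
                break
            pen = _primer_penalty(revcomp(s[b - R:b]), c)
            if pen is not None:
                cur = best_right.get(b)
                if cur is None or (pen, R) < cur:
                    best_right[b] = (pen, R)
    if not best_right:
        return None

    b_arr = np.array(sorted(best_right), dtype=np.int64)
    p_arr = np.array([best_right[b][0] for b in b_arr])

    best_key: tuple | None = None
    best: tuple[int, int, int] | None = None    # (a, L, b)
    for pen_l, a, L in sorted(lefts, key=lambda t: (t[1], t[2])):
        lo = max(e0 + lmin, a + pmin - 1)
        hi = a + pmax - 1
        i0, i1 = np.searchsorted(b_arr, [lo, hi + 1])
        if i0 >= i1:
            continue
        j = i0 + int(np.argmin(p_arr[i0:i1]))   # first min -> smallest b
        b = int(b_arr[j])
        key = (pen_l + float(p_arr[j]), b - a + 1, a, L)
        if best_key is None or key < best_key:
            best_key, best = key, (a, L, b)
    if best is None:
        return None

    a, L, b = best
    pen_r, R = best_right[b]
    left_seq = s[a - 1:a - 1 + L]
    right_seq = revcomp(s[b - R:b])
    return PrimerPair(
        left=left_seq, right=right_seq,
        left_tm=melting_temperature(left_seq),
        right_tm=melting_temperature(right_seq),
        left_gc=gc_percent(left_seq), right_gc=gc_percent(right_seq),
        expected_product=b - a + 1, left_start=a, right_end=b)
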