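"""Electronic PCR: genome-wide primer-pair placement and the
single-locus uniqueness screen.

A primer site is keyed by its 3'-end position: the 3'-terminal seed word
(default 11 nt) must match the genome exactly -- 3'-proximal mismatches
abolish amplification and the exact word bounds the search -- while the
5' remainder is aligned with a per-primer budget of 2 mismatches and
1 indel (defaults).  N in the genome matches nothing.  Amplimers combine
a forward-annealing primer with an opposing reverse-annealing primer at
admissible spacing: product within the absolute 50-1000 bp bounds and,
when an expected size is supplied, within +/- 50 bp of it (the margin).

A marker whose pair amplifies exactly one site genome-wide is
single-locus; such markers are serialised into an AHGA-named catalog in
(scaffold order, position) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

from .primer_design import DesignConstraints, PrimerPair, design_primer_pair
from .seqio import SequenceRecord, revcomp
from .ssr_scan import (DEFAULT_MAX_INTERRUPTION, DEFAULT_MIN_REPEATS,
                       SSRLocus, decompose_compound, scan_perfect_ssrs)


@dataclass(frozen=True)
class EPCRParams:
    max_mismatch_per_primer: int = 2
    max_gaps_per_primer: int = 1
    margin: int = 50
    product_min: int = 50
    product_max: int = 1000
    seed_word: int = 11

    def __post_init__(self):
        if min(self.max_mismatch_per_primer, self.max_gaps_per_primer,
               self.margin, self.product_min, self.seed_word) < 0:
            raise ValueError("e-PCR parameters must be non-negative")
        if self.product_min > self.product_max:
            raise ValueError("product bounds inverted")


@dataclass(frozen=True)
class PrimerSite:
    """One primer annealing site on the plus strand (1-based inclusive
    span); ``three_prime_end`` is the plus-strand coordinate of the
    primer's 3'-terminal base (== end on '+', == start on '-')."""

    start: int
    end: int
    three_prime_end: int
    mismatches: int
    gaps: int
    strand: str


@dataclass(frozen=True)
class AmplimerHit:
    seq_id: str
    start: int
    end: int
    orientation: str            # plus | minus (strand carrying the left primer)
    product_length: int
    left_mismatches: int
    right_mismatches: int
    left_gaps: int
    right_gaps: int


@dataclass(frozen=True)
class LocusClassification:
    marker_id: str
    n_hits: int
    verdict: str                # none | single_locus | multi_locus


def _align_tail(u: str, s: str, p: int, max_mm: int, max_gaps: int
                ) -> tuple[int, int, int] | None:
    """Best alignment of the 5' remainder ``u`` ending at 0-based genome
    index ``p`` (exclusive).  Returns (mismatches, gaps, genome bases
    consumed) or None when no alignment fits the budgets.  With a budget
    of one indel the alignments are: ungapped, one genome base skipped
    (deletion), or one primer base unpaired (insertion)."""
    m = len(u)
    if m == 0:
        return (0, 0, 0)

    def mm_count(g: str) -> int:
        return sum(1 for a, b in zip(u, g) if a != b or b == "N")

    best: tuple[int, int, int] | None = None
    if p - m >= 0:
        mm = mm_count(s[p - m:p])
        if mm <= max_mm:
            best = (mm, 0, m)
    if max_gaps >= 1:
        if p - m - 1 >= 0:          # one genome base unpaired
            g = s[p - m - 1:p]
            for d in range(m + 1):  # genome index skipped
                aligned = g[:d] + g[d + 1:]
                mm = mm_count(aligned)
                cand = (mm, 1, m + 1)
                if mm <= max_mm and (best is None or cand[:2] < best[:2]):
                    best = cand
        if m >= 2 and p - (m - 1) >= 0:   # one primer base unpaired
            g = s[p - (m - 1):p]
            for d in range(m):      # primer index skipped
                aligned_u = u[:d] + u[d + 1:]
                mm = sum(1 for a, b in zip(aligned_u, g)
                         if a != b or b == "N")
                cand = (mm, 1, m - 1)
                if mm <= max_mm and (best is None or cand[:2] < best[:2]):
                    best = cand
    return best


def _sites_plus(primer: str, s: str, params: EPCRParams) -> list[PrimerSite]:
    W = params.seed_word
    seed = primer[-W:]
    u = primer[:-W]
    out = []
    p = s.find(seed)
    while p != -1:
        tail = _align_tail(u, s, p, params.max_mismatch_per_primer,
                           params.max_gaps_per_primer)
        if tail is not None:
            mm, gaps, consumed = tail
            end = p + W                       # 1-based end of seed
            start = p - consumed + 1          # 1-based start of primer span
            out.append(PrimerSite(start=start, end=end, three_prime_end=end,
                                  mismatches=mm, gaps=gaps, strand="+"))
        p = s.find(seed, p + 1)
    return out


def find_primer_sites(primer: str, record: SequenceRecord,
                      params: EPCRParams | None = None,
                      strand: str = "+") -> list[PrimerSite]:
    """All annealing sites of one primer on one scaffold and strand."""
    params = params or EPCRParams()
    if len(primer) < params.seed_word:
        raise ValueError(
            f"primer shorter than seed word ({len(primer)} < "
            f"{params.seed_word})")
    if strand == "+":
        return _sites_plus(primer, record.residues, params)
    if strand != "-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n = record.length
    rc_sites = _sites_plus(primer, revcomp(record.residues), params)
    out = [PrimerSite(start=n - site.end + 1, end=n - site.start + 1,
                      three_prime_end=n - site.three_prime_end + 1,
                      mismatches=site.mismatches, gaps=site.gaps,
                      strand="-")
           for site in rc_sites]
    out.sort(key=lambda t: t.start)
    return out


def epcr_amplimers(pair: PrimerPair, scaffolds: Sequence[SequenceRecord],
                   params: EPCRParams | None = None,
                   expected_product: int | None = None
                   ) -> list[AmplimerHit]:
    """All amplimers of a primer pair over a scaffold set.

    Both orientations are searched; a hit needs the two primers in
    opposing orientation at admissible spacing.  Hits with identical
    (scaffold, span, orientation) are reported once with the lowest
    (mismatch, gap) cost."""
    params = params or EPCRParams()
    best: dict[tuple, AmplimerHit] = {}
    for rec in scaffolds:
        combos = (
            ("plus", find_primer_sites(pair.left, rec, params, "+"),
                     find_primer_sites(pair.right, rec, params, "-")),
            ("minus", find_primer_sites(pair.right, rec, params, "+"),
                      find_primer_sites(pair.left, rec, params, "-")),
        )
        for orientation, fwd_sites, rev_sites in combos:
            for f in fwd_sites:
                for r in rev_sites:
                    if f.end >= r.start:
                        continue
                    product = r.end - f.start + 1
                    if not params.product_min <= product <= params.product_max:
                        continue
                    if (expected_product is not None and
                            abs(product - expected_product) > params.margin):
                        continue
                    if orientation == "plus":
                        lmm, lg, rmm, rg = (f.mismatches, f.gaps,
                                            r.mismatches, r.gaps)
                    else:
                        lmm, lg, rmm, rg = (r.mismatches, r.gaps,
                                            f.mismatches, f.gaps)
                    hit = AmplimerHit(
                        seq_id=rec.id, start=f.start, end=r.end,
                        orientation=orientation, product_length=product,
                        left_mismatches=lmm, right_mismatches=rmm,
                        left_gaps=lg, right_gaps=rg)
                    key = (rec.id, hit.start, hit.end, orientation)
                    cur = best.get(key)
                    if cur is None or (
                            (hit.left_mismatches + hit.right_mismatches,
                             hit.left_gaps + hit.right_gaps) <
                            (cur.left_mismatches + cur.right_mismatches,
                             cur.left_gaps + cur.right_gaps)):
                        best[key] = hit
    return sorted(best.values(),
                  key=lambda h: (h.seq_id, h.start, h.end, h.orientation))


def classify_copy_number(hits: Sequence[AmplimerHit], marker_id: str = ""
                         ) -> LocusClassification:
    """none / single_locus / multi_locus from a whole-genome hit list."""
    n = len(hits)
    verdict = "none" if n == 0 else ("single_locus" if n == 1
                                     else "multi_locus")
    return LocusClassification(marker_id=marker_id, n_hits=n,
                               verdict=verdict)


@dataclass
class MarkerRecord:
    marker_id: str
    locus: SSRLocus
    pair: PrimerPair
    classification: LocusClassification
    hits: list[AmplimerHit]


@dataclass
class MarkerCatalog:
    """Joined scan/design/screen output for one scaffold set."""

    markers: list[MarkerRecord]
    undesigned: list[SSRLocus] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.markers) + len(self.undesigned)

    def partition(self) -> dict[str, int]:
        counts = {"none": 0, "single_locus": 0, "multi_locus": 0}
        for m in self.markers:
            counts[m.classification.verdict] += 1
        return counts

    def single_locus_markers(self) -> list[MarkerRecord]:
        return [m for m in self.markers
                if m.classification.verdict == "single_locus"]


def develop_markers(scaffolds: Sequence[SequenceRecord],
                    min_repeats: dict[int, int] | None = None,
                    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
                    constraints: DesignConstraints | None = None,
                    epcr_params: EPCRParams | None = None,
                    id_prefix: str = "AHGA", id_width: int = 5
                    ) -> MarkerCatalog:
    """Full marker-development pipeline: SSR scan, compound flagging,
    primer design per locus, genome-wide e-PCR of each designed pair and
    copy-number classification.  Marker ids (``AHGA`` + zero-padded
    serial) are assigned in (scaffold order, position) order."""
    min_repeats = min_repeats or DEFAULT_MIN_REPEATS
    constraints = constraints or DesignConstraints()
    epcr_params = epcr_params or EPCRParams()

    by_id = {rec.id: rec for rec in scaffolds}
    if len(by_id) != len(scaffolds):
        raise ValueError("duplicate scaffold ids")

    markers: list[MarkerRecord] = []
    undesigned: list[SSRLocus] = []
    serial = 0
    for rec in scaffolds:
        loci = decompose_compound(scan_perfect_ssrs(rec, min_repeats),
                                  max_interruption)
        for locus in loci:
            pair = design_primer_pair(locus, rec, constraints)
            if pair is None:
                undesigned.append(locus)
                continue
            serial += 1
            marker_id = f"{id_prefix}{serial:0{id_width}d}"
            hits = epcr_amplimers(pair, scaffolds, epcr_params,
                                  expected_product=pair.expected_product)
            markers.append(MarkerRecord(
                marker_id=marker_id, locus=locus,
                pair=_dc_replace(pair, marker_id=marker_id),
                classification=classify_copy_number(hits, marker_id),
                hits=hits))
    return MarkerCatalog(markers=markers, undesigned=undesigned)
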