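"""Seeded synthetic fixtures: genomes with planted SSRs (optionally
inside duplicated segments), F2 genotype draws and natural-population
genotype matrices.

The genome generator emulates the shape of a draft scaffold assembly:
background base composition at 38 % GC (matching a typical legume
draft), non-repetitive flanks (rejection-sampled so that no unintended
tract meets the scanner thresholds), planted tracts that are maximal by
construction, and duplicated segments wide enough (tract plus
350 bp on each side) that a primer pair designed against one copy
amplifies the other perfectly.  Every planted locus is guaranteed
designable: flanks are re-rolled (bounded retries) until a primer pair
satisfying the default constraints exists, because the truth table
promises a single/multi copy-number verdict, which presupposes a pair.

All randomness flows from one explicit seed per spec; the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .primer_design import DesignConstraints, design_primer_pair
from .seqio import SequenceRecord
from .ssr_scan import (DEFAULT_MIN_REPEATS, canonical_motif, is_primitive,
                       scan_perfect_ssrs)
from .popgen_stats import GenotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedSSR:
    motif: str
    repeats: int
    scaffold: int           # 0-based scaffold index
    start: int              # 1-based tract start
    duplicated: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.repeats - 1


@dataclass
class GenomeSpec:
    seed: int
    n_scaffolds: int = 4
    scaffold_length: int = 25_000
    gc_fraction: float = 0.38
    n_ssrs: int = 30
    frac_duplicated: float = 0.15
    dup_flank: int = 350
    edge_margin: int = 450
    min_spacing: int = 900
    motif_pool: Sequence[str] | None = None
    extra_repeats_max: int = 4      # repeats = class minimum + U(0..this)
    ensure_designable: bool = True
    max_retries: int = 30


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(_BASES, size=n, p=p))


def _random_motif(rng: np.random.Generator) -> str:
    while True:
        k = int(rng.integers(1, 7))
        motif = "".join(rng.choice(_BASES, size=k))
        if is_primitive(motif):
            return motif


def _truth_frame(planted: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(planted, columns=[
        "seq_id", "start", "end", "motif", "motif_class", "unit_length",
        "repeat_count", "expected_verdict", "is_copy", "dup_group"])


def generate_genome(spec: GenomeSpec
                    ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Build scaffolds per ``spec`` and the truth table of planted loci.

    The truth table has one row per expected scanner hit, including the
    tracts inside duplicated-segment copies, with the copy-number
    verdict the development pipeline should reach (``single_locus`` for
    unique loci, ``multi_locus`` for each copy of a duplicated one).
    """
    rng = np.random.default_rng(spec.seed)
    min_reps = DEFAULT_MIN_REPEATS
    n_dup = int(round(spec.frac_duplicated * spec.n_ssrs))
    n_slots = spec.n_ssrs + n_dup

    seqs = [_random_bases(rng, spec.scaffold_length, spec.gc_fraction)
            for _ in range(spec.n_scaffolds)]

    # Deterministic, well-separated slots (tract start positions).
    slots: list[tuple[int, int]] = []
    per = [n_slots // spec.n_scaffolds] * spec.n_scaffolds
    for i in range(n_slots % spec.n_scaffolds):
        per[i] += 1
    for si, k in enumerate(per):
        usable = spec.scaffold_length - 2 * spec.edge_margin
        if k and usable / k < spec.min_spacing:
            raise ValueError("scaffolds too short for requested loci")
        for j in range(k):
            jitter = int(rng.integers(-80, 81))
            pos = spec.edge_margin + int((j + 0.5) * usable / k) + jitter
            slots.append((si, pos))
    rng.shuffle(slots := np.array(slots, dtype=int))
    slots = [tuple(map(int, s)) for s in slots]

    # Plant loci in the first n_ssrs slots.
    planted: list[PlantedSSR] = []
    for idx in range(spec.n_ssrs):
        si, pos = slots[idx]
        if spec.motif_pool:
            motif = str(spec.motif_pool[int(rng.integers(len(spec.motif_pool)))])
        else:
            motif = _random_motif(rng)
        repeats = min_reps[len(motif)] + int(
            rng.integers(0, spec.extra_repeats_max + 1))
        p = PlantedSSR(motif=motif, repeats=repeats, scaffold=si, start=pos,
                       duplicated=idx < n_dup)
        tract = motif * repeats
        seqs[si][pos - 1:pos - 1 + len(tract)] = list(tract)
        planted.append(p)

    def write_copy(p: PlantedSSR, slot: tuple[int, int]) -> PlantedSSR:
        si, pos = slot
        src = seqs[p.scaffold]
        lo = p.start - 1 - spec.dup_flank
        hi = p.end + spec.dup_flank
        segment = src[lo:hi]
        dest_lo = pos - 1 - spec.dup_flank
        seqs[si][dest_lo:dest_lo + len(segment)] = segment
        return PlantedSSR(motif=p.motif, repeats=p.repeats, scaffold=si,
                          start=pos, duplicated=True)

    def truth_rows() -> list[dict]:
        rows = []
        for gi, p in enumerate(planted):
            rows.append({
                "seq_id": f"scaffold_{p.scaffold + 1}", "start": p.start,
                "end": p.end, "motif": p.motif,
                "motif_class": canonical_motif(p.motif),
                "unit_length": len(p.motif), "repeat_count": p.repeats,
                "expected_verdict": ("multi_locus" if p.duplicated
                                     else "single_locus"),
                "is_copy": gi >= spec.n_ssrs,
                "dup_group": dup_group.get(gi, -1)})
        return rows

    def fixup(max_iter: int = 200) -> None:
        """Re-roll any scanned tract that is not exactly a planted one.

        A tract overlapping a planted locus but with different
        coordinates is a boundary extension: only the overhang outside
        the planted span is re-rolled, never the tract itself.
        """
        for _ in range(max_iter):
            dirty = False
            by_scaffold: dict[int, list[PlantedSSR]] = {}
            for p in planted:
                by_scaffold.setdefault(p.scaffold, []).append(p)
            for si, seq in enumerate(seqs):
                rec = SequenceRecord(f"scaffold_{si + 1}", "".join(seq))
                expected = {(p.start, p.end, p.motif, p.repeats)
                            for p in by_scaffold.get(si, [])}
                spans = [(p.start, p.end) for p in by_scaffold.get(si, [])]
                for L in scan_perfect_ssrs(rec, min_reps):
                    if (L.start, L.end, L.motif, L.repeat_count) in expected:
                        continue
                    dirty = True
                    overlapping = [(s, e) for s, e in spans
                                   if L.start <= e and L.end >= s]
                    if overlapping:
                        s, e = overlapping[0]
                        targets = ([*range(L.start, s)] +
                                   [*range(e + 1, L.end + 1)])
                    else:
                        targets = [*range(L.start, L.end + 1)]
                    for t in targets:
                        seq[t - 1] = str(rng.choice(_BASES))
            if not dirty:
                return
        raise RuntimeError("could not purge unintended SSRs from flanks")

    # Duplicated copies occupy the remaining slots.
    dup_group: dict[int, int] = {}
    copy_slot = spec.n_ssrs
    for gi in range(n_dup):
        dup_group[gi] = gi
    for gi in range(n_dup):
        fixup()  # clean source flanks before copying them
        if spec.ensure_designable:
            _ensure_designable(planted[gi], seqs, rng, spec, fixup)
        copy = write_copy(planted[gi], slots[copy_slot])
        planted.append(copy)
        dup_group[len(planted) - 1] = gi
        copy_slot += 1

    fixup()
    if spec.ensure_designable:
        for gi in range(n_dup, spec.n_ssrs):
            _ensure_designable(planted[gi], seqs, rng, spec, fixup)
        fixup()

    records = [SequenceRecord(f"scaffold_{si + 1}", "".join(seq))
               for si, seq in enumerate(seqs)]
    truth = _truth_frame(truth_rows()).sort_values(
        ["seq_id", "start"]).reset_index(drop=True)
    return records, truth


def _ensure_designable(p: PlantedSSR, seqs, rng, spec: GenomeSpec,
                       fixup) -> None:
    constraints = DesignConstraints()
    for _ in range(spec.max_retries):
        rec = SequenceRecord(f"scaffold_{p.scaffold + 1}",
                             "".join(seqs[p.scaffold]))
        locus = next(L for L in scan_perfect_ssrs(rec)
                     if L.start == p.start and L.end == p.end)
        if design_primer_pair(locus, rec, constraints) is not None:
            return
        seq = seqs[p.scaffold]
        for t in range(max(1, p.start - spec.dup_flank), p.start):
            seq[t - 1] = str(rng.choice(_BASES))
        for t in range(p.end + 1,
                       min(len(seq), p.end + spec.dup_flank) + 1):
            seq[t - 1] = str(rng.choice(_BASES))
        fixup()
    raise RuntimeError(
        f"no designable flanks for planted locus at "
        f"scaffold_{p.scaffold + 1}:{p.start} after {spec.max_retries} tries")


def simulate_f2(seed: int, n: int = 154,
                probs: Sequence[float] = (0.25, 0.5, 0.25)
                ) -> tuple[int, int, int]:
    """Multinomial (AA, Aa, aa) genotype counts for an F2 panel; the
    default expectation is the Mendelian 1:2:1."""
    probs = tuple(float(x) for x in probs)
    if len(probs) != 3 or min(probs) < 0 or abs(sum(probs) - 1) > 1e-9:
        raise ValueError("probs must be 3 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return int(counts[0]), int(counts[1]), int(counts[2])


@dataclass
class PopulationSpec:
    """Natural-population genotype fixture; defaults mirror a 96-line
    inbred peanut panel genotyped at 100 single-locus markers with a
    residual heterozygote rate of 1 %."""

    seed: int
    n_markers: int = 100
    n_individuals: int = 96
    model: str = "inbred"           # inbred | outbred
    het_rate: float = 0.01          # inbred model only
    missing_rate: float = 0.0
    allele_freqs: Sequence[Sequence[float]] | None = None
    n_alleles_range: tuple[int, int] = (2, 6)

    def __post_init__(self):
        for r in (self.het_rate, self.missing_rate, ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.model not in ("inbred", "outbred"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.allele_freqs is not None:
            for p in self.allele_freqs:
                if abs(sum(p) - 1) > 1e-9 or min(p) < 0:
                    raise ValueError("allele frequencies must sum to 1")


def simulate_population(spec: PopulationSpec) -> GenotypeMatrix:
    """Draw a marker x individual genotype matrix.

    ``inbred``: one allele per draw (homozygote), except with
    probability ``het_rate`` the call is heterozygous (two distinct
    alleles, the second drawn from the renormalised remainder), so the
    realised Ho approximates ``het_rate``.  ``outbred``: two independent
    alleles per call (Hardy-Weinberg).  Allele labels are fragment sizes
    in bp (2 bp ladder from 150).
    """
    rng = np.random.default_rng(spec.seed)
    markers = [f"M{i + 1:03d}" for i in range(spec.n_markers)]
    individuals = [f"acc{j + 1:03d}" for j in range(spec.n_individuals)]
    gm = GenotypeMatrix(markers=markers, individuals=individuals)
    for mi, m in enumerate(markers):
        if spec.allele_freqs is not None:
            p = np.asarray(spec.allele_freqs[mi % len(spec.allele_freqs)],
                           dtype=float)
        else:
            k = int(rng.integers(spec.n_alleles_range[0],
                                 spec.n_alleles_range[1] + 1))
            p = rng.dirichlet(np.ones(k))
        sizes = [150 + 2 * a for a in range(len(p))]
        for ind in individuals:
            if spec.missing_rate and rng.random() < spec.missing_rate:
                continue
            if spec.model == "outbred":
                a1, a2 = rng.choice(sizes, size=2, p=p)
            elif len(p) >= 2 and rng.random() < spec.het_rate:
                a1 = rng.choice(sizes, p=p)
                rest = [(s_, w) for s_, w in zip(sizes, p) if s_ != a1]
                rp = np.array([w for _, w in rest])
                a2 = rng.choice([s_ for s_, _ in rest], p=rp / rp.sum())
            else:
                a1 = a2 = rng.choice(sizes, p=p)
            gm.set(m, ind, int(a1), int(a2))
    return gm
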