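"""Marker validation statistics for diploid codominant genotypes.

Covers allele frequencies, observed heterozygosity
(Ho = 1 - sum_u p_uu, the fraction of typed individuals that are
heterozygous), polymorphism information content
(PIC = 1 - sum_i p_i^2 - 2 * sum_{i<j} p_i^2 p_j^2), the Pearson
chi-square test of 1:2:1 F2 segregation (df = 2), polymorphism-rate
summaries, a pairwise similarity matrix (simple matching or Dice over
unordered genotypes) and UPGMA clustering on d = 1 - s with Newick
output.

Missing calls are excluded pairwise for per-marker statistics and
listwise per individual pair for similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

Genotype = tuple  # unordered pair of allele labels, stored sorted


@dataclass
class GenotypeMatrix:
    """Diploid calls per (marker, individual); missing = absent key.

    Allele labels are arbitrary hashables (typically fragment sizes in
    bp); a homozygote is an identical pair.
    """

    markers: list[str]
    individuals: list[str]
    calls: dict[tuple[str, str], Genotype] = field(default_factory=dict)

    def get(self, marker: str, individual: str) -> Genotype | None:
        return self.calls.get((marker, individual))

    def set(self, marker: str, individual: str, a1, a2) -> None:
        self.calls[(marker, individual)] = tuple(sorted((a1, a2), key=str))

    def marker_calls(self, marker: str) -> list[Genotype]:
        return [g for ind in self.individuals
                if (g := self.calls.get((marker, ind))) is not None]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        """Long-format TSV: marker, individual, allele1, allele2 with
        '.' for missing alleles."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.lower() for c in df.columns]
        gm = cls(markers=list(dict.fromkeys(df["marker"])),
                 individuals=list(dict.fromkeys(df["individual"])))
        for row in df.itertuples(index=False):
            if row.allele1 == "." or row.allele2 == ".":
                continue
            gm.set(row.marker, row.individual, row.allele1, row.allele2)
        return gm

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("marker\tindividual\tallele1\tallele2\n")
            for m in self.markers:
                for ind in self.individuals:
                    g = self.calls.get((m, ind))
                    a1, a2 = g if g is not None else (".", ".")
                    fh.write(f"{m}\t{ind}\t{a1}\t{a2}\n")


@dataclass(frozen=True)
class AlleleFrequencies:
    marker: str
    p: dict
    n_alleles: int
    n_typed: int


def allele_frequencies(matrix: GenotypeMatrix, marker: str
                       ) -> AlleleFrequencies:
    """Allele frequencies over non-missing calls (each typed diploid
    individual contributes two allele observations)."""
    calls = matrix.marker_calls(marker)
    if not calls:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    counts: dict = {}
    for a1, a2 in calls:
        counts[a1] = counts.get(a1, 0) + 1
        counts[a2] = counts.get(a2, 0) + 1
    total = 2 * len(calls)
    p = {a: c / total for a, c in sorted(counts.items(), key=lambda t: str(t[0]))}
    return AlleleFrequencies(marker=marker, p=p, n_alleles=len(p),
                             n_typed=len(calls))


def observed_heterozygosity(matrix: GenotypeMatrix, marker: str) -> float:
    """Ho = 1 - sum of homozygote frequencies = fraction of typed
    individuals that are heterozygous."""
    calls = matrix.marker_calls(marker)
    if not calls:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    hom = sum(1 for a1, a2 in calls if a1 == a2)
    return 1.0 - hom / len(calls)


def pic(freqs: AlleleFrequencies | Mapping | Sequence[float]) -> float:
    """Polymorphism information content:
    PIC = 1 - sum_i p_i^2 - 2 * sum_{i<j} p_i^2 p_j^2."""
    if isinstance(freqs, AlleleFrequencies):
        p = list(freqs.p.values())
    elif isinstance(freqs, Mapping):
        p = list(freqs.values())
    else:
        p = list(freqs)
    if not p or abs(sum(p) - 1.0) > 1e-6 or min(p) < 0:
        raise ValueError("frequencies must be non-negative and sum to 1")
    sq = [x * x for x in p]
    cross = sum(sq[i] * sq[j]
                for i in range(len(p)) for j in range(i + 1, len(p)))
    return 1.0 - sum(sq) - 2.0 * cross


@dataclass(frozen=True)
class SegregationTest:
    marker: str
    n_AA: int
    n_Aa: int
    n_aa: int
    chi2: float
    df: int
    p_value: float
    passed: bool


def chi_square_1_2_1(counts: Sequence[float], marker: str = "",
                     alpha: float = 0.01) -> SegregationTest:
    """Pearson chi-square of observed (AA, Aa, aa) counts against the
    Mendelian 1:2:1 F2 expectation; df = 2, no continuity correction.
    ``passed`` is p >= alpha (a marker at exactly alpha passes)."""
    if len(counts) != 3:
        raise ValueError("counts must be (n_AA, n_Aa, n_aa)")
    if min(counts) < 0:
        raise ValueError("negative genotype counts")
    n = sum(counts)
    if n < 1:
        raise ValueError("empty F2 panel")
    expected = (n / 4, n / 2, n / 4)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p = float(_scistats.chi2.sf(chi2, df=2))
    return SegregationTest(marker=marker, n_AA=int(counts[0]),
                           n_Aa=int(counts[1]), n_aa=int(counts[2]),
                           chi2=chi2, df=2, p_value=p, passed=p >= alpha)


def polymorphism_rate_by(matrix: GenotypeMatrix,
                         marker_groups: Mapping[str, object]
                         ) -> pd.DataFrame:
    """Per-group polymorphism summary.  A marker is polymorphic iff it
    shows >= 2 alleles among non-missing calls; rate is the percentage
    of polymorphic markers among those tested in the group."""
    rows: dict = {}
    for marker in matrix.markers:
        if marker not in marker_groups:
            continue
        group = marker_groups[marker]
        calls = matrix.marker_calls(marker)
        if not calls:
            continue
        alleles = {a for g in calls for a in g}
        tested, poly = rows.get(group, (0, 0))
        rows[group] = (tested + 1, poly + (len(alleles) >= 2))
    return pd.DataFrame(
        [{"group": g, "n_tested": t, "n_polymorphic": p,
          "rate_pct": 100.0 * p / t}
         for g, (t, p) in sorted(rows.items(), key=lambda kv: str(kv[0]))]
    ).set_index("group")


def similarity_matrix(matrix: GenotypeMatrix, method: str = "simple"
                      ) -> pd.DataFrame:
    """Pairwise similarity over markers typed in both individuals.

    ``simple``: fraction of shared typed markers with identical
    unordered genotypes.  ``dice``: allele-wise Dice coefficient,
    2 * shared alleles / 4 per marker, averaged.  Pairs with no shared
    typed marker are NaN; the diagonal is 1.
    """
    if len(matrix.individuals) < 2:
        raise ValueError("similarity needs >= 2 individuals")
    if method not in ("simple", "dice"):
        raise ValueError(f"unknown similarity method {method!r}")
    inds = matrix.individuals
    sim = pd.DataFrame(np.nan, index=inds, columns=inds, dtype=float)
    for i, a in enumerate(inds):
        sim.loc[a, a] = 1.0
        for b in inds[i + 1:]:
            shared = score = 0
            for m in matrix.markers:
                ga, gb = matrix.get(m, a), matrix.get(m, b)
                if ga is None or gb is None:
                    continue
                shared += 1
                if method == "simple":
                    score += ga == gb
                else:
                    ca, cb = list(ga), list(gb)
                    common = 0
                    for al in ca:
                        if al in cb:
                            cb.remove(al)
                            common += 1
                    score += common / 2
            if shared:
                sim.loc[a, b] = sim.loc[b, a] = score / shared
    return sim


class _Node:
    __slots__ = ("name", "height", "children", "size", "order")

    def __init__(self, name=None, height=0.0, children=(), size=1, order=0):
        self.name, self.height = name, height
        self.children, self.size = list(children), size
        self.order = order      # smallest original leaf index underneath

    def newick(self, parent_height=None) -> str:
        if self.children:
            inner = ",".join(c.newick(self.height) for c in self.children)
            label = f"({inner})"
        else:
            label = str(self.name)
        if parent_height is None:
            return label + ";"
        return f"{label}:{parent_height - self.height:.12g}"

    def leaf_depths(self, acc=0.0, root_height=None) -> dict:
        if root_height is None:
            root_height = self.height
        if not self.children:
            return {self.name: root_height - self.height}
        out = {}
        for c in self.children:
            out.update(c.leaf_depths(root_height=root_height))
        return out

    def cophenetic(self) -> dict:
        """Map frozenset({a, b}) -> cophenetic distance 2 * height of
        the lowest common ancestor."""
        out = {}
        def walk(node):
            leaf_sets = []
            for c in node.children:
                leaf_sets.append(walk(c))
            if not node.children:
                return [node.name]
            for i in range(len(leaf_sets)):
                for j in range(i + 1, len(leaf_sets)):
                    for x in leaf_sets[i]:
                        for y in leaf_sets[j]:
                            out[frozenset((x, y))] = 2.0 * node.height
            return [x for ls in leaf_sets for x in ls]
        walk(self)
        return out


def upgma_tree(similarity: pd.DataFrame) -> _Node:
    """UPGMA (average linkage) on distances d = 1 - s.

    Requires a complete symmetric similarity matrix; ties are broken by
    the smallest (row index, column index) in the current cluster
    ordering.  The result is rooted and ultrametric; ``.newick()``
    serialises it with branch lengths in distance units.
    """
    if similarity.isna().any().any():
        raise ValueError("similarity matrix has missing entries")
    labels = list(similarity.index)
    if list(similarity.columns) != labels:
        raise ValueError("similarity matrix must be square and aligned")
    d = (1.0 - similarity.to_numpy(dtype=float))
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    nodes = [_Node(name=lab, order=i) for i, lab in enumerate(labels)]
    dist = [[float(d[i, j]) for j in range(len(labels))]
            for i in range(len(labels))]
    while len(nodes) > 1:
        bi = bj = -1
        bd = math.inf
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if dist[i][j] < bd:
                    bd, bi, bj = dist[i][j], i, j
        a, b = nodes[bi], nodes[bj]
        ni, nj = a.size, b.size
        if b.order < a.order:
            a, b = b, a
        merged = _Node(height=bd / 2.0, children=(a, b),
                       size=ni + nj, order=a.order)
        new_row = []
        for k in range(len(nodes)):
            if k in (bi, bj):
                continue
            new_row.append((ni * dist[bi][k] + nj * dist[bj][k])
                           / (ni + nj))
        keep = [k for k in range(len(nodes)) if k not in (bi, bj)]
        nodes = [nodes[k] for k in keep] + [merged]
        dist = [[dist[i][j] for j in keep] + [new_row[ii]]
                for ii, i in enumerate(keep)]
        dist.append([new_row[ii] for ii in range(len(keep))] + [0.0])
    return nodes[0]


def diversity_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker A (allele count), Ho and PIC, PowerMarker-style, with
    a trailing Mean row."""
    rows = []
    for m in matrix.markers:
        f = allele_frequencies(matrix, m)
        rows.append({"marker": m, "A": f.n_alleles,
                     "Ho": observed_heterozygosity(matrix, m),
                     "PIC": pic(f)})
    df = pd.DataFrame(rows).set_index("marker")
    df.loc["Mean"] = df.mean()
    return df
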