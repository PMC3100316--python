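"""Whole-genome similarity via maximal unique matches (MUMs).

For each genome pair the gap-free maximal unique matches are found on
both strands; the fraction of each genome covered by the union of its MUM
intervals gives a similarity in [0, 1], and one minus the (by default
arithmetic-mean) combination of the two per-genome coverages gives a
dissimilarity.  Agglomerative clustering of the dissimilarity matrix
yields a tree, written in Newick, in which genomes sharing large
identical tracts — exactly the genomes whose reads co-assemble into
chimeric contigs — group together.

A MUM is an exact match occurring exactly once in each genome (counting
both strands of the second) and extendable in neither direction.  MUMs
are found with a generalized suffix array plus LCP neighbourhood checks;
intended for toy-to-moderate genome sizes (the suffix sort is plain
comparison-based).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .community_sampler import GenomeSet, reverse_complement


@dataclass(frozen=True)
class Mum:
    """A maximal unique match between genome a and genome b.

    ``start_b`` is always a forward-strand coordinate in b; ``strand``
    says on which strand of b the matching substring lies.
    """

    start_a: int
    start_b: int
    length: int
    strand: str

    def interval_a(self) -> tuple[int, int]:
        return self.start_a, self.start_a + self.length

    def interval_b(self) -> tuple[int, int]:
        return self.start_b, self.start_b + self.length


def _suffix_array(s: str) -> list[int]:
    return sorted(range(len(s)), key=lambda i: s[i:])


def _lcp_array(s: str, sa: list[int]) -> list[int]:
    """lcp[i] = longest common prefix of suffixes sa[i] and sa[i+1]."""
    out = []
    for i in range(len(sa) - 1):
        x, y = sa[i], sa[i + 1]
        l = 0
        while x + l < len(s) and y + l < len(s) and s[x + l] == s[y + l]:
            l += 1
        out.append(l)
    return out


def find_mums(a: str, b: str, min_len: int = 20) -> list[Mum]:
    """All maximal matches of length >= min_len unique in both genomes.

    Both strands of ``b`` are considered; uniqueness in b counts
    occurrences on either strand, so a match also occurring as its own
    reverse complement elsewhere in b is rejected.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not a or not b:
        return []
    b_rev = reverse_complement(b)
    # sentinels outside the DNA alphabet terminate each component
    s = a + "\x01" + b + "\x02" + b_rev + "\x03"
    off_b = len(a) + 1
    off_rev = off_b + len(b) + 1

    def component(pos: int) -> str:
        if pos < len(a):
            return "a"
        if off_b <= pos < off_b + len(b):
            return "b"
        if off_rev <= pos < off_rev + len(b_rev):
            return "r"
        return "sentinel"

    sa = _suffix_array(s)
    lcp = _lcp_array(s, sa)
    mums: list[Mum] = []
    for i in range(len(sa) - 1):
        l = lcp[i]
        if l < min_len:
            continue
        ca, cb = component(sa[i]), component(sa[i + 1])
        if {ca, cb} not in ({"a", "b"}, {"a", "r"}):
            continue
        # uniqueness across the whole text: no other suffix shares this
        # l-prefix, i.e. both flanking LCPs are shorter
        if i > 0 and lcp[i - 1] >= l:
            continue
        if i + 1 < len(lcp) and lcp[i + 1] >= l:
            continue
        pa, pb = (sa[i], sa[i + 1]) if ca == "a" else (sa[i + 1], sa[i])
        # left-maximality: preceding characters differ (or a string start)
        if pa > 0 and pb > 0 and s[pa - 1] == s[pb - 1] and s[pa - 1] in "ACGTN":
            continue
        if component(pb) == "b":
            mums.append(Mum(pa, pb - off_b, l, "+"))
        else:
            rev_start = pb - off_rev
            mums.append(Mum(pa, len(b) - rev_start - l, l, "-"))
    mums.sort(key=lambda m: (m.start_a, m.start_b, m.strand))
    return mums


def mum_coverage(genome_length: int, mums: list[Mum], which: str = "a") -> float:
    """Fraction of a genome covered by the union of MUM intervals."""
    if which not in ("a", "b"):
        raise ValueError("which must be 'a' or 'b'")
    intervals = sorted(
        m.interval_a() if which == "a" else m.interval_b() for m in mums
    )
    covered = 0
    cur_start, cur_end = None, None
    for start, end in intervals:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / genome_length


def dissimilarity_matrix(
    gs: GenomeSet, min_len: int = 20, combiner: str = "mean"
) -> tuple[np.ndarray, list[str]]:
    """Pairwise genome dissimilarity: 1 - combined MUM coverage.

    The two per-genome coverages of each pair are combined with
    ``combiner`` in {mean, min, max}; the diagonal is 0.  Each genome's
    replicons are concatenated (sentinel-free at toy scale).
    """
    if len(gs.genomes) < 2:
        raise ValueError("need at least 2 genomes")
    combine = {
        "mean": lambda x, y: (x + y) / 2.0,
        "min": min,
        "max": max,
    }[combiner]
    ids = sorted(gs.genomes)
    seqs = {g: "".join(seq for _, seq in gs.genomes[g]) for g in ids}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mums = find_mums(seqs[ids[i]], seqs[ids[j]], min_len)
            cov_i = mum_coverage(len(seqs[ids[i]]), mums, "a")
            cov_j = mum_coverage(len(seqs[ids[j]]), mums, "b")
            d[i, j] = d[j, i] = 1.0 - combine(cov_i, cov_j)
    return d, ids


def cluster_hierarchical(
    matrix: np.ndarray, labels: list[str], method: str = "average"
) -> str:
    """Agglomerative clustering of a dissimilarity matrix; Newick string.

    Branch heights are merge dissimilarities (ultrametric node heights
    halved onto branches, UPGMA-style).
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.isnan(matrix).any():
        raise ValueError("dissimilarity matrix contains NaN")
    z = linkage(squareform(matrix, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(z, labels)
    return str(tree).strip()
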