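"""Independent brute-force oracles used by the test suite.

Each oracle is a direct, exhaustive implementation of a definition —
never sharing code with the module it checks.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_placements(read_seq, genomes):
    """All (genome, replicon, start, strand) where the read occurs,
    scanning every offset of every replicon on both strands.

    ``genomes``: dict genome_id -> list of (replicon_id, sequence).
    Palindromic sites are reported once with strand '+'.
    """
    L = len(read_seq)
    rc = revcomp(read_seq)
    found = {}
    for gid, replicons in genomes.items():
        for rid, seq in replicons:
            for pos in range(len(seq) - L + 1):
                window = seq[pos : pos + L]
                if window == read_seq:
                    found.setdefault((gid, rid, pos), "+")
                elif window == rc:
                    found.setdefault((gid, rid, pos), "-")
    return {(g, r, p, s) for (g, r, p), s in found.items()}


def brute_force_chimeric(read_genome_sets):
    """A contig is chimeric iff no single genome is compatible with
    every read; checked by enumerating all genomes."""
    all_genomes = set().union(*read_genome_sets)
    return not any(
        all(g in s for s in read_genome_sets) for g in all_genomes
    )


def brute_force_lca(taxids, nodes):
    """Deepest node ancestral to all taxids via ancestor-set
    intersection; depth measured as distance from the root."""
    def ancestors(t):
        out = [t]
        while nodes[out[-1]][0] != out[-1]:
            out.append(nodes[out[-1]][0])
        return out

    paths = [ancestors(t) for t in taxids]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    return max(common, key=lambda t: len(ancestors(t)))


def brute_force_mums(a: str, b: str, min_len: int):
    """Exhaustive MUM enumeration on short inputs.

    For every pair of start positions (a, b-on-either-strand) extend the
    common match maximally, then keep it only if left-maximal and the
    matched substring occurs exactly once in a and exactly once in b
    (counting both strands of b).
    """
    def occurrences(text, sub):
        n, start = 0, 0
        while (i := text.find(sub, start)) != -1:
            n += 1
            start = i + 1
        return n

    b_rc = revcomp(b)
    out = set()
    for strand, bt in (("+", b), ("-", b_rc)):
        for i in range(len(a)):
            for j in range(len(bt)):
                if a[i] != bt[j]:
                    continue
                # left-maximality
                if i > 0 and j > 0 and a[i - 1] == bt[j - 1]:
                    continue
                l = 0
                while i + l < len(a) and j + l < len(bt) and a[i + l] == bt[j + l]:
                    l += 1
                if l < min_len:
                    continue
                sub = a[i : i + l]
                if occurrences(a, sub) != 1:
                    continue
                if occurrences(b, sub) + occurrences(b_rc, sub) != 1:
                    continue
                if strand == "+":
                    out.add((i, j, l, "+"))
                else:
                    out.add((i, len(b) - j - l, l, "-"))
    return out
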