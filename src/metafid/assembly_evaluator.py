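"""Assembly fidelity metrics for read-traceable assemblies.

Given an assembly in ACE format (which records where every read sits in
every contig) and the simulator's provenance table (which records every
identical placement of every read in the reference genomes), each contig
can be tested for chimericity: a contig is chimeric when no single genome
can explain all of its reads.  Because a read occurring verbatim in two
genomes is compatible with both, shared reads do not force chimericity —
only reads whose placement sets are disjoint do.

Additional metrics: the organism assigned to each contig (majority rule,
seeded random tie-break), the taxonomic rank of the lowest common
ancestor of a chimeric contig's reads (how badly taxonomic integrity was
broken), N50 and longest contig, per-contig divergence against the
reference, and the pairwise chimera-sharing matrix between genomes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Sequencing import Ace

from .community_sampler import Placement, reverse_complement

NCBI_RANKS = [
    "root", "superkingdom", "phylum", "class", "order",
    "family", "genus", "species", "strain",
]


@dataclass
class ContigPlacement:
    """A contig's unpadded consensus and its read placements."""

    contig_id: str
    consensus: str
    reads: list[tuple[str, int, str]]  # (read_id, 0-based offset, '+'/'-')


@dataclass
class Taxonomy:
    """Rooted taxonomy supporting LCA queries.

    ``nodes`` maps taxid -> (parent taxid, rank name); the root is
    self-parented.
    """

    nodes: dict[int, tuple[int, str]]
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid in self.nodes:
            self.path_to_root(tid)  # raises on cycles / dangling parents

    def path_to_root(self, taxid: int) -> list[int]:
        """Taxid's lineage from itself up to (and including) the root."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        path = [taxid]
        seen = {taxid}
        while True:
            parent = self.nodes[path[-1]][0]
            if parent == path[-1]:
                return path
            if parent in seen or parent not in self.nodes:
                raise ValueError(f"broken lineage above taxid {taxid}")
            path.append(parent)
            seen.add(parent)

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid][1]

    @classmethod
    def from_dmp(cls, nodes_path: str | Path, names_path: str | Path | None = None
                 ) -> "Taxonomy":
        """Load a nodes.dmp/names.dmp-style subset (fields separated by
        the NCBI ``\\t|\\t`` convention or plain tabs)."""
        def split(line: str) -> list[str]:
            line = line.rstrip("\t|\n")
            return [f.strip() for f in line.replace("\t|\t", "\t").split("\t")]

        nodes: dict[int, tuple[int, str]] = {}
        with open(nodes_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = split(line)
                nodes[int(f[0])] = (int(f[1]), f[2])
        names: dict[int, str] = {}
        if names_path is not None:
            with open(names_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    f = split(line)
                    if len(f) < 4 or f[3] == "scientific name":
                        names[int(f[0])] = f[1]
        return cls(nodes=nodes, names=names)


@dataclass
class AssemblyReport:
    """Summary statistics of one evaluated assembly."""

    n50: int | None
    longest_contig: int | None
    pct_reads_in_chimeras: float | None
    pct_reads_in_chimeras_of_sampled: float | None
    lca_rank_histogram: dict[str, int]
    per_contig: list[dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def per_contig_tsv(self, path: str | Path) -> None:
        cols = ["contig_id", "length", "n_reads", "assigned_genome", "chimeric", "lca_rank"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(cols)
            for row in self.per_contig:
                w.writerow([row.get(c, "") for c in cols])


def parse_ace(path: str | Path) -> list[ContigPlacement]:
    """Parse an ACE assembly into contig placements.

    Consensus padding (``*``) is stripped and read offsets are shifted by
    the number of pads occurring before them.  AF records give 1-based
    padded start positions; offsets returned are 0-based in the unpadded
    consensus (clamped to the consensus for reads hanging off its ends).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty ACE file: {path}")
    try:
        ace = Ace.read(open(path))
    except Exception as exc:  # Bio raises bare ValueError on malformed input
        raise ValueError(f"malformed ACE file {path}: {exc}") from exc
    if ace.ncontigs != len(ace.contigs):
        raise ValueError(
            f"ACE record count mismatch in {path}: AS declares {ace.ncontigs}, "
            f"found {len(ace.contigs)} CO records"
        )
    out: list[ContigPlacement] = []
    for contig in ace.contigs:
        padded = contig.sequence
        if contig.nreads != len(contig.af):
            raise ValueError(
                f"contig {contig.name}: CO declares {contig.nreads} reads, "
                f"found {len(contig.af)} AF records"
            )
        # pads_before[i] = number of '*' strictly before padded position i
        pads_before = np.cumsum([c == "*" for c in padded])
        consensus = padded.replace("*", "")
        reads = []
        for af in contig.af:
            padded_start = af.padded_start - 1  # AF is 1-based
            if padded_start < 0:
                unpadded = padded_start  # read hangs off the left end
            elif padded_start >= len(padded):
                unpadded = len(consensus)
            else:
                unpadded = padded_start - int(pads_before[padded_start - 1]) if padded_start else 0
            strand = "-" if af.coru == "C" else "+"
            reads.append((af.name, max(0, min(unpadded, len(consensus))), strand))
        out.append(ContigPlacement(contig.name, consensus, reads))
    return out


def compatible_organisms(
    read_id: str, provenance: dict[str, list[Placement]]
) -> set[str]:
    """Genomes containing at least one identical placement of the read."""
    if read_id not in provenance:
        raise KeyError(f"read {read_id!r} not in provenance")
    return {p.genome_id for p in provenance[read_id]}


def classify_contig(
    contig: ContigPlacement,
    provenance: dict[str, list[Placement]],
    rng: np.random.Generator,
    *,
    use_alternative_placements: bool = True,
) -> tuple[str, bool]:
    """Assign a contig to an organism and decide whether it is chimeric.

    Chimeric iff the intersection over its reads of the genomes compatible
    with each read is empty (no single organism of origin can explain
    every read).  The assigned genome is the one compatible with the most
    reads; ties are broken by a seeded random draw.

    With ``use_alternative_placements=False`` the naive definition is used
    instead: each read counts only for its origin genome, and the contig
    is chimeric iff reads from more than one origin are present.
    """
    if not contig.reads:
        raise ValueError(f"contig {contig.contig_id} has no reads")
    if use_alternative_placements:
        sets = [compatible_organisms(rid, provenance) for rid, _, _ in contig.reads]
    else:
        # naive mode: only the origin label counts; pass origin-only
        # provenance (e.g. community_sampler.read_origins) in this mode
        sets = [{provenance[rid][0].genome_id} for rid, _, _ in contig.reads]
    common = set.intersection(*sets)
    is_chimeric = len(common) == 0
    votes: dict[str, int] = {}
    for s in sets:
        for gid in s:
            votes[gid] = votes.get(gid, 0) + 1
    best = max(votes.values())
    candidates = sorted(g for g, v in votes.items() if v == best)
    assigned = candidates[0] if len(candidates) == 1 else candidates[int(rng.integers(0, len(candidates)))]
    return assigned, is_chimeric


def percent_reads_in_chimeras(
    contigs: list[ContigPlacement],
    chimeric_flags: dict[str, bool],
    read_length: int,
    *,
    total_sampled_reads: int | None = None,
) -> tuple[float | None, float | None]:
    """Percentage of reads placed in chimeric contigs.

    Only contigs whose consensus is longer than the read length are
    considered, in both numerator and denominator.  Returns a pair: the
    percentage over reads in retained contigs, and (if
    ``total_sampled_reads`` is given) the percentage over all sampled
    reads.  None when the denominator is zero.
    """
    retained = [c for c in contigs if len(c.consensus) > read_length]
    n_total = sum(len(c.reads) for c in retained)
    n_chim = sum(len(c.reads) for c in retained if chimeric_flags[c.contig_id])
    pct_assembled = 100.0 * n_chim / n_total if n_total else None
    pct_sampled = (
        100.0 * n_chim / total_sampled_reads if total_sampled_reads else None
    )
    return pct_assembled, pct_sampled


def lca_rank(taxids: set[int], tax: Taxonomy) -> str:
    """Rank of the lowest common ancestor of a set of taxa.

    The deepest node ancestral to (or equal to) every taxid, found by
    path intersection.  If that node carries "no rank", the nearest named
    ancestor rank is reported.  A singleton set returns its own rank.
    """
    if not taxids:
        raise ValueError("empty taxid set")
    paths = [tax.path_to_root(t) for t in taxids]
    common = set(paths[0]).intersection(*[set(p) for p in paths[1:]])
    # paths are ordered leaf -> root; the first common node on any path is
    # the deepest common ancestor
    lca = next(t for t in paths[0] if t in common)
    node = lca
    while tax.rank(node) == "no rank":
        parent = tax.nodes[node][0]
        if parent == node:
            break
        node = parent
    return tax.rank(node)


def n50(contig_lengths: list[int]) -> int | None:
    """N50: the smallest length among the longest contigs that together
    cover at least half of the total assembly length."""
    if not contig_lengths:
        return None
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= half:
            return ln
    return lengths[-1]


# --- divergence vs reference --------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def divergence_per_base(
    contig: str,
    reference: str | None = None,
    psl_row: dict | None = None,
) -> float | None:
    """Errors per aligned contig base against the reference.

    (mismatches + inserted bases + deleted bases) / aligned contig length.
    Either a PSL alignment row (``parse_psl``) or a raw reference sequence
    (aligned locally with affine gap penalties, both strands tried) may be
    supplied.  None when no alignment is found.
    """
    if psl_row is not None:
        aligned = psl_row["matches"] + psl_row["misMatches"] + psl_row["repMatches"]
        if aligned == 0:
            return None
        errors = (
            psl_row["misMatches"]
            + psl_row["qBaseInsert"]
            + psl_row["tBaseInsert"]
        )
        return errors / (aligned + psl_row["qBaseInsert"])
    if reference is None:
        raise ValueError("supply either psl_row or reference")
    aligner = _make_aligner()
    best = None
    for query in (contig, reverse_complement(contig)):
        alns = aligner.align(reference, query)
        if len(alns) and (best is None or alns.score > best.score):
            best = alns[0]
    if best is None or best.score <= 0:
        return None
    counts = best.counts()
    mismatches = counts.mismatches
    gaps = counts.gaps
    aligned_q = counts.identities + counts.mismatches
    if aligned_q == 0:
        return None
    return (mismatches + gaps) / (aligned_q + gaps)


PSL_COLUMNS = [
    "matches", "misMatches", "repMatches", "nCount",
    "qNumInsert", "qBaseInsert", "tNumInsert", "tBaseInsert",
    "strand", "qName", "qSize", "qStart", "qEnd",
    "tName", "tSize", "tStart", "tEnd",
    "blockCount", "blockSizes", "qStarts", "tStarts",
]
_PSL_INT = set(PSL_COLUMNS[:8]) | {
    "qSize", "qStart", "qEnd", "tSize", "tStart", "tEnd", "blockCount"
}


def parse_psl(path: str | Path) -> list[dict]:
    """Parse a BLAT PSL file (header lines tolerated) into row dicts."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 21 or not parts[0].lstrip("-").isdigit():
                continue
            row = dict(zip(PSL_COLUMNS, parts))
            for k in _PSL_INT:
                row[k] = int(row[k])
            rows.append(row)
    return rows


def chimera_sharing_matrix(
    contigs: list[ContigPlacement],
    chimeric_flags: dict[str, bool],
    provenance: dict[str, list[Placement]],
    reads_per_genome: dict[str, int],
) -> tuple[np.ndarray, list[str]]:
    """Pairwise percentage of reads co-occurring in chimeric contigs.

    Entry (i, j) is 100 x (reads of genome i or j lying in chimeric
    contigs that contain reads of both) / (total reads sampled from i and
    j).  Symmetric; the diagonal is left at zero (a genome does not share
    chimeras with itself).
    """
    genomes = sorted(reads_per_genome)
    gi = {g: k for k, g in enumerate(genomes)}
    shared = np.zeros((len(genomes), len(genomes)))
    for contig in contigs:
        if not chimeric_flags[contig.contig_id]:
            continue
        per_genome_reads: dict[str, int] = {}
        for rid, _, _ in contig.reads:
            for g in compatible_organisms(rid, provenance):
                per_genome_reads[g] = per_genome_reads.get(g, 0) + 1
        present = sorted(per_genome_reads)
        for a_i in range(len(present)):
            for b_i in range(a_i + 1, len(present)):
                a, b = present[a_i], present[b_i]
                if a in gi and b in gi:
                    n = per_genome_reads[a] + per_genome_reads[b]
                    shared[gi[a], gi[b]] += n
                    shared[gi[b], gi[a]] += n
    totals = np.array([reads_per_genome[g] for g in genomes], dtype=float)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * shared / denom, 0.0)
    np.fill_diagonal(pct, 0.0)
    return pct, genomes


def evaluate_assembly(
    contigs: list[ContigPlacement],
    provenance: dict[str, list[Placement]],
    taxonomy: Taxonomy | None,
    genome_taxids: dict[str, int],
    read_length: int,
    seed: int,
    *,
    total_sampled_reads: int | None = None,
    use_alternative_placements: bool = True,
) -> AssemblyReport:
    """Run the full per-assembly evaluation and collect an AssemblyReport."""
    rng = np.random.default_rng(seed)
    flags: dict[str, bool] = {}
    per_contig = []
    lca_hist: dict[str, int] = {}
    for contig in contigs:
        assigned, chim = classify_contig(
            contig, provenance, rng,
            use_alternative_placements=use_alternative_placements,
        )
        flags[contig.contig_id] = chim
        row = {
            "contig_id": contig.contig_id,
            "length": len(contig.consensus),
            "n_reads": len(contig.reads),
            "assigned_genome": assigned,
            "chimeric": chim,
            "lca_rank": "",
        }
        if chim and taxonomy is not None:
            taxids = set()
            for rid, _, _ in contig.reads:
                for g in compatible_organisms(rid, provenance):
                    taxids.add(genome_taxids[g])
            rank = lca_rank(taxids, taxonomy)
            row["lca_rank"] = rank
            lca_hist[rank] = lca_hist.get(rank, 0) + 1
        per_contig.append(row)
    lengths = [len(c.consensus) for c in contigs]
    pct_assembled, pct_sampled = percent_reads_in_chimeras(
        contigs, flags, read_length, total_sampled_reads=total_sampled_reads
    )
    return AssemblyReport(
        n50=n50(lengths),
        longest_contig=max(lengths) if lengths else None,
        pct_reads_in_chimeras=pct_assembled,
        pct_reads_in_chimeras_of_sampled=pct_sampled,
        lca_rank_histogram=lca_hist,
        per_contig=per_contig,
    )
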