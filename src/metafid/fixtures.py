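"""Deterministic toy-input generators with known ground truth.

Every downstream module is exercised against fixtures produced here: toy
genome sets with identical blocks planted between chosen genome pairs,
balanced toy taxonomies with named ranks, non-overlapping gene
annotations with random COG categories, mock assemblies (emitted as valid
ACE) whose chimera structure is planted, and mock homology-hit tables of
controllable fidelity.  Each generator returns machine-readable ground
truth alongside the object itself, so every metric computed downstream
has a hand-computable expected value.  All randomness is seed-driven.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly_evaluator import ContigPlacement, Taxonomy
from .community_sampler import (
    GenomeSet,
    Placement,
    ReadRecord,
    reverse_complement,
)
from .functional_concordance import COG_CATEGORIES, GeneFeature

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Parameters of a toy genome-set fixture."""

    n_genomes: int = 2
    genome_length: int = 10_000
    shared_blocks: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    # each entry: ((genome index i, genome index j), block length)
    genes_per_genome: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for (i, j), block_len in self.shared_blocks:
            if not (0 <= i < self.n_genomes and 0 <= j < self.n_genomes and i != j):
                raise ValueError(f"bad genome pair ({i}, {j})")
            if block_len >= self.genome_length:
                raise ValueError("shared block must be shorter than the genome")


def random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_DNA, size=length).tobytes().decode()


def make_toy_genomes(
    spec: FixtureSpec,
) -> tuple[GenomeSet, list[dict]]:
    """Uniform-random genomes with identical blocks planted between pairs.

    Returns the GenomeSet plus a block registry: one dict per planted
    block with the pair of genome ids and the (0-based half-open)
    coordinates of the copy in each.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"G{i}" for i in range(spec.n_genomes)]
    seqs = {g: bytearray(random_dna(spec.genome_length, rng), "ascii") for g in ids}
    registry: list[dict] = []
    for (i, j), block_len in spec.shared_blocks:
        src, dst = ids[i], ids[j]
        max_start = spec.genome_length - block_len
        s_src = int(rng.integers(0, max_start + 1))
        s_dst = int(rng.integers(0, max_start + 1))
        block = bytes(seqs[src][s_src : s_src + block_len])
        seqs[dst][s_dst : s_dst + block_len] = block
        registry.append(
            {
                "genome_a": src, "genome_b": dst,
                "start_a": s_src, "end_a": s_src + block_len,
                "start_b": s_dst, "end_b": s_dst + block_len,
            }
        )
    gs = GenomeSet(
        genomes={g: [(f"{g}_chr", seqs[g].decode())] for g in ids},
        taxid={g: 1000 + i for i, g in enumerate(ids)},
    )
    return gs, registry


def write_genomes(gs: GenomeSet, fasta_path: str | Path, taxid_path: str | Path) -> None:
    """Emit a GenomeSet as FASTA plus the replicon/genome/taxid TSV."""
    with open(fasta_path, "w") as fh:
        for gid, replicons in gs.genomes.items():
            for rid, seq in replicons:
                fh.write(f">{rid}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
    with open(taxid_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["replicon_id", "genome_id", "taxid"])
        for gid, replicons in gs.genomes.items():
            for rid, _ in replicons:
                w.writerow([rid, gid, gs.taxid[gid]])


def make_toy_taxonomy(
    shape: dict[str, int] | None = None,
) -> tuple[Taxonomy, list[int]]:
    """Balanced taxonomy with named ranks; returns (taxonomy, leaf taxids).

    ``shape`` maps rank name to children per node, ordered root-down,
    default 2 genera x 2 species x 2 strains under one family.  Leaf
    taxids are assigned depth-first so siblings are consecutive.
    """
    if shape is None:
        shape = {"genus": 2, "species": 2, "strain": 2}
    ranks = list(shape)
    nodes: dict[int, tuple[int, str]] = {1: (1, "family")}
    leaves: list[int] = []
    next_id = [2]

    def grow(parent: int, depth: int) -> None:
        if depth == len(ranks):
            leaves.append(parent)
            return
        for _ in range(shape[ranks[depth]]):
            tid = next_id[0]
            next_id[0] += 1
            nodes[tid] = (parent, ranks[depth])
            grow(tid, depth + 1)

    grow(1, 0)
    return Taxonomy(nodes=nodes), leaves


def write_taxonomy(tax: Taxonomy, nodes_path: str | Path) -> None:
    with open(nodes_path, "w") as fh:
        for tid, (parent, rank) in sorted(tax.nodes.items()):
            fh.write(f"{tid}\t|\t{parent}\t|\t{rank}\t|\n")


def make_toy_features(
    gs: GenomeSet, genes_per_genome: int, seed: int,
    gene_length: int = 300, spacing: int = 50,
) -> list[GeneFeature]:
    """Non-overlapping genes with random COG categories, evenly laid out."""
    rng = np.random.default_rng(seed)
    cats = list(COG_CATEGORIES)
    out: list[GeneFeature] = []
    for gid in sorted(gs.genomes):
        for rid, seq in gs.genomes[gid]:
            stride = gene_length + spacing
            n = min(genes_per_genome, max(0, (len(seq) - spacing) // stride))
            for k in range(n):
                start = spacing + k * stride
                out.append(
                    GeneFeature(
                        replicon_id=rid,
                        start=start,
                        end=start + gene_length,
                        strand="+" if rng.random() < 0.5 else "-",
                        cog_category=cats[int(rng.integers(0, len(cats)))],
                    )
                )
    return out


def write_features(features: list[GeneFeature], path: str | Path) -> None:
    """GFF3-like TSV (1-based inclusive) with a cog_category attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            fh.write(
                f"{f.replicon_id}\ttoy\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID=gene{i};cog_category={f.cog_category}\n"
            )


def mock_assemble(
    reads: list[ReadRecord],
    plan: list[list[str]],
    gs: GenomeSet,
    seed: int,
    ace_path: str | Path | None = None,
) -> tuple[list[ContigPlacement], list[bool]]:
    """Build mock contigs from groups of reads; optionally emit ACE.

    ``plan`` lists, per contig, the read ids to stitch together.  The
    consensus is the concatenation of the reads' origin fragments (taken
    from the reference, so an error-free mock), each read placed at its
    cumulative offset.  Ground-truth chimera labels — origin genomes of
    the group not all equal — are returned alongside; note the evaluator
    may legitimately disagree on reads that are shared identically
    between genomes (that is the point of alternative placements).
    """
    by_id = {r.read_id: r for r in reads}
    missing = [rid for group in plan for rid in group if rid not in by_id]
    if missing:
        raise ValueError(f"plan references unknown reads: {missing[:5]}")
    contigs: list[ContigPlacement] = []
    truth: list[bool] = []
    for ci, group in enumerate(plan):
        if not group:
            raise ValueError("empty contig group in plan")
        members = [by_id[rid] for rid in group]
        consensus_parts: list[str] = []
        placements: list[tuple[str, int, str]] = []
        for rec in members:
            o = rec.origin
            frag = gs.replicon(o.genome_id, o.replicon_id)[o.start : o.end]
            placements.append((rec.read_id, sum(map(len, consensus_parts)), o.strand))
            consensus_parts.append(frag)
        consensus = "".join(consensus_parts)
        contigs.append(ContigPlacement(f"contig{ci}", consensus, placements))
        truth.append(len({m.origin.genome_id for m in members}) > 1)
    if ace_path is not None:
        write_ace(contigs, {r.read_id: r.sequence for r in reads}, ace_path)
    return contigs, truth


def write_ace(
    contigs: list[ContigPlacement],
    read_seqs: dict[str, str],
    path: str | Path,
) -> None:
    """Emit a minimal but valid ACE file (unpadded consensus, one AF/RD
    pair per read)."""
    n_reads = sum(len(c.reads) for c in contigs)
    with open(path, "w") as fh:
        fh.write(f"AS {len(contigs)} {n_reads}\n\n")
        for c in contigs:
            fh.write(
                f"CO {c.contig_id} {len(c.consensus)} {len(c.reads)} 1 U\n"
            )
            for k in range(0, len(c.consensus), 50):
                fh.write(c.consensus[k : k + 50] + "\n")
            fh.write("\nBQ\n")
            fh.write(" ".join(["40"] * len(c.consensus)) + "\n\n")
            for rid, offset, strand in c.reads:
                cu = "C" if strand == "-" else "U"
                fh.write(f"AF {rid} {cu} {offset + 1}\n")
            fh.write(f"BS 1 {len(c.consensus)} {c.reads[0][0]}\n\n")
            for rid, offset, strand in c.reads:
                seq = read_seqs[rid]
                if strand == "-":
                    seq = reverse_complement(seq)
                fh.write(f"RD {rid} {len(seq)} 0 0\n")
                for k in range(0, len(seq), 50):
                    fh.write(seq[k : k + 50] + "\n")
                fh.write(f"\nQA 1 {len(seq)} 1 {len(seq)}\n")
                fh.write("DS CHROMAT_FILE: none PHD_FILE: none TIME: none\n\n")


def make_mock_hits(
    features: list[GeneFeature],
    targets: list[tuple[str, str, int, int]],
    fidelity: float,
    seed: int,
) -> list[tuple]:
    """Mock tabular homology hits for reads or contigs.

    ``targets`` lists (query_id, replicon_id, start, end): the reference
    interval each query represents (a read's origin, or a contig's
    span).  For each gene overlapping a query by >= 1 bp one hit row is
    produced; with probability ``fidelity`` its subject carries the true
    COG category, otherwise a uniformly different one.  E-values are
    drawn below the conventional 1e-3 cutoff, with the overlap length
    controlling the bit score so that the most-overlapping gene wins
    best-hit selection.

    Returns rows shaped like 12-column tabular output plus a parallel
    subject -> category map encoded in the subject id (``COG_<cat>_<k>``).
    """
    if not 0 <= fidelity <= 1:
        raise ValueError("fidelity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cats = list(COG_CATEGORIES)
    rows = []
    k = 0
    for qid, rid, qstart, qend in targets:
        for f in features:
            if f.replicon_id != rid:
                continue
            ov = min(qend, f.end) - max(qstart, f.start)
            if ov <= 0:
                continue
            if rng.random() < fidelity:
                cat = f.cog_category
            else:
                others = [c for c in cats if c != f.cog_category]
                cat = others[int(rng.integers(0, len(others)))]
            # hit interval in query coordinates (1-based inclusive)
            h_start = max(qstart, f.start) - qstart + 1
            h_end = min(qend, f.end) - qstart
            subject = f"COG_{cat}_{k}"
            k += 1
            evalue = 10.0 ** (-4 - ov / 100.0)
            rows.append(
                (qid, subject, 95.0, ov, 0, 0, h_start, h_end,
                 1, ov, evalue, float(ov))
            )
    return rows


def write_hits(rows: list[tuple], hits_path: str | Path, cog_map_path: str | Path) -> None:
    with open(hits_path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    with open(cog_map_path, "w") as fh:
        for r in rows:
            subject = r[1]
            cat = subject.split("_")[1]
            fh.write(f"{subject}\t{cat}\n")
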