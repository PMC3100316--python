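"""Sampling of error-free reads from a reference genome set.

A simulated metagenome is drawn from a set of reference genomes according
to a community profile assigning each genome a fold-coverage.  Fragments of
fixed length are selected uniformly at random along each genome's
replicons, reverse-complemented with probability 0.5, and every read keeps
full provenance: its origin placement plus every *alternative* placement at
which an identical sequence occurs anywhere in the sampled genome set.
Alternative placements are what later allows a contig to be declared
non-chimeric when its reads are shared verbatim between genomes.

Coordinates are 0-based half-open internally; TSV output is 1-based
inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N} (N maps to N)."""
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Placement:
    """One genomic placement of a read (0-based, half-open)."""

    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


@dataclass
class GenomeSet:
    """Reference genomes: genome_id -> list of (replicon_id, sequence)."""

    genomes: dict[str, list[tuple[str, str]]]
    taxid: dict[str, int]

    def __post_init__(self) -> None:
        for gid, replicons in self.genomes.items():
            if gid not in self.taxid:
                raise ValueError(f"genome {gid!r} has no taxid")
            for rid, seq in replicons:
                if not seq:
                    raise ValueError(f"empty replicon {rid!r} in genome {gid!r}")

    def genome_length(self, genome_id: str) -> int:
        return sum(len(seq) for _, seq in self.genomes[genome_id])

    def replicon(self, genome_id: str, replicon_id: str) -> str:
        for rid, seq in self.genomes[genome_id]:
            if rid == replicon_id:
                return seq
        raise KeyError(f"replicon {replicon_id!r} not in genome {genome_id!r}")

    @property
    def n_replicons(self) -> int:
        return sum(len(r) for r in self.genomes.values())


@dataclass
class CommunityProfile:
    """Per-genome target fold-coverage and the common read length."""

    entries: list[tuple[str, float]]
    read_length: int

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        for gid, cov in self.entries:
            if not np.isfinite(cov) or cov < 0:
                raise ValueError(f"coverage for {gid!r} must be finite and >= 0")


@dataclass
class ReadRecord:
    """A simulated read with its origin and all identical alternative sites."""

    read_id: str
    sequence: str
    origin: Placement
    alt_sites: list[Placement] = field(default_factory=list)
    is_revcomp: bool = False


def load_genomes(
    fasta_paths: Sequence[str | Path], taxid_table: str | Path
) -> GenomeSet:
    """Load FASTA files into a GenomeSet.

    ``taxid_table`` is a TSV with columns ``replicon_id, genome_id, taxid``
    (header optional); replicons are grouped into genomes through it.
    Sequences are upper-cased; N is preserved.
    """
    repl_to_genome: dict[str, str] = {}
    taxids: dict[str, int] = {}
    with open(taxid_table) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "replicon_id":
                continue
            rid, gid, tid = row[0], row[1], int(row[2])
            repl_to_genome[rid] = gid
            taxids[gid] = tid

    genomes: dict[str, list[tuple[str, str]]] = {}
    for path in fasta_paths:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        for rec in records:
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty record {rec.id!r} in {path}")
            if not set(seq) <= _ALPHABET:
                raise ValueError(f"non-ACGTN characters in record {rec.id!r} of {path}")
            gid = repl_to_genome.get(rec.id)
            if gid is None:
                raise ValueError(f"replicon {rec.id!r} missing from taxid table")
            genomes.setdefault(gid, []).append((rec.id, seq))
    return GenomeSet(genomes=genomes, taxid=taxids)


def compute_read_count(genome_length: int, coverage: float, read_length: int) -> int:
    """Number of reads needed for the target fold-coverage.

    round(coverage * genome_length / read_length), banker's rounding
    (round-half-even, Python built-in round).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    return round(coverage * genome_length / read_length)


def sample_reads(
    gs: GenomeSet,
    profile: CommunityProfile,
    seed: int,
    *,
    find_alt_sites: bool = False,
    max_n_fraction: float | None = None,
) -> list[ReadRecord]:
    """Sample error-free reads according to the community profile.

    Per genome, ``compute_read_count`` reads are drawn with replacement:
    the replicon is chosen with probability proportional to its length and
    the start position uniformly on [0, len - read_length].  Each read is
    reverse-complemented with probability 0.5.  Deterministic given seed.

    Replicons shorter than the read length are skipped (error if the whole
    genome is too short).  ``max_n_fraction`` optionally rejects reads with
    a higher fraction of N (default: keep all).
    """
    rng = np.random.default_rng(seed)
    L = profile.read_length
    reads: list[ReadRecord] = []
    index = _AltSiteIndex(gs, L) if find_alt_sites else None
    serial = 0
    for gid, cov in profile.entries:
        if gid not in gs.genomes:
            raise KeyError(f"profile genome {gid!r} not in genome set")
        usable = [(rid, seq) for rid, seq in gs.genomes[gid] if len(seq) >= L]
        if not usable:
            raise ValueError(f"all replicons of {gid!r} shorter than read length {L}")
        n_reads = compute_read_count(gs.genome_length(gid), cov, L)
        weights = np.array([len(seq) for _, seq in usable], dtype=float)
        weights /= weights.sum()
        repl_choice = rng.choice(len(usable), size=n_reads, p=weights)
        flips = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            rid, seq = usable[repl_choice[i]]
            start = int(rng.integers(0, len(seq) - L + 1))
            fragment = seq[start : start + L]
            if max_n_fraction is not None:
                if fragment.count("N") / L > max_n_fraction:
                    continue
            revcomp = bool(flips[i])
            strand = "-" if revcomp else "+"
            read_seq = reverse_complement(fragment) if revcomp else fragment
            origin = Placement(gid, rid, start, start + L, strand)
            rec = ReadRecord(
                read_id=f"read_{serial:07d}",
                sequence=read_seq,
                origin=origin,
                is_revcomp=revcomp,
            )
            if index is not None:
                rec.alt_sites = index.find(read_seq, origin)
            reads.append(rec)
            serial += 1
    return reads


class _AltSiteIndex:
    """Exact-match index over all fixed-length windows of a genome set.

    Anchors every replicon with k-mers (k = min(read_length, 16)) and
    verifies candidate windows by full string comparison, so the search is
    exact, never heuristic.
    """

    def __init__(self, gs: GenomeSet, read_length: int):
        self.gs = gs
        self.L = read_length
        self.k = min(read_length, 16)
        self.anchors: dict[str, list[tuple[str, str, int]]] = {}
        for gid, replicons in gs.genomes.items():
            for rid, seq in replicons:
                for pos in range(len(seq) - self.k + 1):
                    self.anchors.setdefault(seq[pos : pos + self.k], []).append(
                        (gid, rid, pos)
                    )

    def find(self, read_seq: str, origin: Placement | None = None) -> list[Placement]:
        """All placements where the read sequence occurs on either strand.

        Strand '+' means the genomic forward strand holds the read sequence
        itself; '-' means it holds its reverse complement (so the origin of
        a reverse-complemented read is found with strand '-').
        """
        L = self.L
        hits: set[Placement] = set()
        for strand, text_query in (("+", read_seq), ("-", reverse_complement(read_seq))):
            anchor = text_query[: self.k]
            for gid, rid, pos in self.anchors.get(anchor, ()):
                if pos + L > len(seq := self.gs.replicon(gid, rid)):
                    continue
                if seq[pos : pos + L] == text_query:
                    hits.add(Placement(gid, rid, pos, pos + L, strand))
        # a palindromic fragment matches the same site on both strands;
        # report such a site once, preferring the forward strand
        sites = {}
        for p in sorted(hits, key=lambda p: (p.genome_id, p.replicon_id, p.start, p.strand)):
            sites.setdefault((p.genome_id, p.replicon_id, p.start), p)
        out = list(sites.values())
        if origin is not None and not any(
            (p.genome_id, p.replicon_id, p.start) == (origin.genome_id, origin.replicon_id, origin.start)
            for p in out
        ):
            out.append(origin)
        return out


def find_alternative_sites(read: ReadRecord, gs: GenomeSet) -> list[Placement]:
    """All identical placements of an error-free read across the genome set.

    Scans every genome for exact occurrences of the read sequence on either
    strand; the origin site is always included.  Sites where the fragment
    equals its own reverse complement are reported once.
    """
    index = _AltSiteIndex(gs, len(read.sequence))
    return index.find(read.sequence, read.origin)


def attach_alternative_sites(reads: Iterable[ReadRecord], gs: GenomeSet) -> None:
    """Populate ``alt_sites`` for many reads sharing one read length."""
    reads = list(reads)
    if not reads:
        return
    L = len(reads[0].sequence)
    index = _AltSiteIndex(gs, L)
    for rec in reads:
        rec.alt_sites = index.find(rec.sequence, rec.origin)


def write_reads(
    reads: Sequence[ReadRecord],
    fasta_path: str | Path,
    provenance_path: str | Path,
    *,
    fastq: bool = False,
    quality_char: str = "I",
) -> None:
    """Write reads as FASTA/FASTQ plus a provenance TSV sidecar.

    The sidecar has one row per (read, placement) with 1-based inclusive
    coordinates; the origin row is flagged.
    """
    if not reads:
        raise ValueError("no reads to write")
    with open(fasta_path, "w") as fh:
        for rec in reads:
            if fastq:
                fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{quality_char * len(rec.sequence)}\n")
            else:
                fh.write(f">{rec.read_id}\n{rec.sequence}\n")
    with open(provenance_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "genome", "replicon", "start", "end", "strand", "is_origin"])
        for rec in reads:
            placements = rec.alt_sites if rec.alt_sites else [rec.origin]
            for p in placements:
                is_origin = (
                    p.genome_id == rec.origin.genome_id
                    and p.replicon_id == rec.origin.replicon_id
                    and p.start == rec.origin.start
                )
                w.writerow(
                    [rec.read_id, p.genome_id, p.replicon_id, p.start + 1, p.end, p.strand, int(is_origin)]
                )


def read_provenance(provenance_path: str | Path) -> dict[str, list[Placement]]:
    """Load a provenance TSV into read_id -> list of placements (0-based)."""
    out: dict[str, list[Placement]] = {}
    with open(provenance_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "read_id":
            raise ValueError(f"unexpected provenance header: {header}")
        for row in reader:
            rid, gid, repl, start, end, strand, _ = row
            out.setdefault(rid, []).append(
                Placement(gid, repl, int(start) - 1, int(end), strand)
            )
    return out


def read_origins(provenance_path: str | Path) -> dict[str, list[Placement]]:
    """Load only the origin placement of each read (one-element lists)."""
    out: dict[str, list[Placement]] = {}
    with open(provenance_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            rid, gid, repl, start, end, strand, is_origin = row
            if is_origin == "1":
                out[rid] = [Placement(gid, repl, int(start) - 1, int(end), strand)]
    return out


def read_reads(
    fasta_path: str | Path, provenance_path: str | Path
) -> list[ReadRecord]:
    """Inverse of :func:`write_reads` (FASTA variant)."""
    placements = _origins_and_alts(provenance_path)
    fmt = "fastq" if str(fasta_path).endswith(("fastq", "fq")) else "fasta"
    reads = []
    for rec in SeqIO.parse(str(fasta_path), fmt):
        origin, alts = placements[rec.id]
        reads.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                origin=origin,
                alt_sites=alts,
                is_revcomp=origin.strand == "-",
            )
        )
    return reads


def _origins_and_alts(
    provenance_path: str | Path,
) -> dict[str, tuple[Placement, list[Placement]]]:
    out: dict[str, tuple[Placement | None, list[Placement]]] = {}
    with open(provenance_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            rid, gid, repl, start, end, strand, is_origin = row
            p = Placement(gid, repl, int(start) - 1, int(end), strand)
            origin, alts = out.get(rid, (None, []))
            if is_origin == "1":
                origin = p
            alts.append(p)
            out[rid] = (origin, alts)
    result = {}
    for rid, (origin, alts) in out.items():
        if origin is None:
            raise ValueError(f"read {rid!r} has no origin row")
        result[rid] = (origin, alts)
    return result
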