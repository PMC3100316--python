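"""Three-level functional (COG category) annotation concordance.

Every simulated read can be annotated three ways:

* **real** — from the annotation of the genome it was sampled from: the
  gene overlapping the read's origin coordinates by at least 40 bp that
  overlaps it the most;
* **read level** — from homology hits of the read itself: the best hit
  (lowest e-value, ties by bit score) passing the e-value cutoff (1e-3);
* **contig level** — from homology hits of the contig the read was
  assembled into: overlapping contig hits are merged (keeping the best
  hit's category), then the merged interval overlapping the read's
  contig placement by at least 40 bp the most gives the category.

Comparing the three levels per read yields the verdict classes (correct /
incorrect / no annotation at each level, or unassembled), and comparing
COG category distributions between levels yields the global deviation
statistic: the sum over categories of absolute proportion differences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

COG_CATEGORIES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
MIN_OVERLAP = 40
DEFAULT_E_CUTOFF = 1e-3


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene with a single-letter COG functional category."""

    replicon_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    cog_category: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.cog_category not in COG_CATEGORIES:
            raise ValueError(f"bad COG category {self.cog_category!r}")


@dataclass(frozen=True)
class HomologyHit:
    """One tabular homology hit with its subject's COG category."""

    query_id: str
    query_start: int  # 0-based half-open on the query
    query_end: int
    subject_id: str
    e_value: float
    bit_score: float
    cog_category: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")


@dataclass
class AnnotationVerdict:
    """Per-read annotation outcome at all three levels."""

    read_id: str
    real: str | None
    read_level: str | None
    contig_level: str | None
    assembled: bool
    verdict_class: str = ""

    def __post_init__(self) -> None:
        if not self.verdict_class:
            self.verdict_class = classify_verdict(
                self.real, self.read_level, self.contig_level, self.assembled
            )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def annotate_real(
    origin_start: int,
    origin_end: int,
    origin_replicon: str,
    features: Sequence[GeneFeature],
    min_overlap: int = MIN_OVERLAP,
) -> str | None:
    """Category of the gene most overlapping the read's origin interval.

    Genes must overlap by at least ``min_overlap`` bases; ties between
    equally overlapping genes are broken by leftmost gene start.
    """
    best: tuple[int, int] | None = None  # (-overlap, start) for min()
    best_cat: str | None = None
    for feat in features:
        if feat.replicon_id != origin_replicon:
            continue
        ov = _overlap(origin_start, origin_end, feat.start, feat.end)
        if ov < min_overlap:
            continue
        key = (-ov, feat.start)
        if best is None or key < best:
            best, best_cat = key, feat.cog_category
    return best_cat


def _hit_order(h: HomologyHit) -> tuple:
    # best first: e-value ascending, bit score descending, subject lexical
    return (h.e_value, -h.bit_score, h.subject_id)


def annotate_read_level(
    hits: Iterable[HomologyHit], e_cutoff: float = DEFAULT_E_CUTOFF
) -> str | None:
    """Category of the best hit passing the e-value cutoff, or None."""
    kept = [h for h in hits if h.e_value <= e_cutoff]
    if not kept:
        return None
    return min(kept, key=_hit_order).cog_category


def merge_contig_hits(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Coalesce overlapping query intervals, keeping the best hit of each
    overlap chain as the reference (its category and coordinates)."""
    pool = sorted(hits, key=lambda h: h.query_start)
    merged: list[list[HomologyHit]] = []
    span_end = None
    for h in pool:
        if merged and h.query_start < span_end:
            merged[-1].append(h)
            span_end = max(span_end, h.query_end)
        else:
            merged.append([h])
            span_end = h.query_end
    return [min(group, key=_hit_order) for group in merged]


def annotate_contig_level(
    read_start: int,
    read_end: int,
    merged_hits: Sequence[HomologyHit],
    min_overlap: int = MIN_OVERLAP,
) -> str | None:
    """Category of the merged contig hit most overlapping the read's
    contig placement (at least ``min_overlap`` bases), or None."""
    best_key: tuple | None = None
    best_cat: str | None = None
    for h in merged_hits:
        ov = _overlap(read_start, read_end, h.query_start, h.query_end)
        if ov < min_overlap:
            continue
        key = (-ov, h.query_start)
        if best_key is None or key < best_key:
            best_key, best_cat = key, h.cog_category
    return best_cat


def classify_verdict(
    real: str | None,
    read_level: str | None,
    contig_level: str | None,
    assembled: bool,
) -> str:
    """Cross-classify a read's annotation outcome.

    The class string is ``read:<X>|contig:<Y>`` where X and Y are each
    ``correct`` (equal to the real category), ``incorrect`` (non-None and
    different), or ``none``; unassembled reads get ``contig:unassembled``.
    Reads with no real annotation are scored against None, so a None
    prediction is ``correct`` there.
    """
    def score(pred: str | None) -> str:
        if pred is None:
            return "none"
        return "correct" if pred == real else "incorrect"

    read_part = score(read_level)
    contig_part = "unassembled" if not assembled else score(contig_level)
    return f"read:{read_part}|contig:{contig_part}"


def cog_distribution(categories: Iterable[str]) -> dict[str, float]:
    """Proportion of each observed COG category (sums to 1 if non-empty)."""
    counts: dict[str, int] = {}
    n = 0
    for c in categories:
        if c is None:
            continue
        counts[c] = counts.get(c, 0) + 1
        n += 1
    return {c: k / n for c, k in counts.items()} if n else {}


def distribution_deviation(d1: dict[str, float], d2: dict[str, float]) -> float:
    """Sum over COG categories of |d1(c) - d2(c)| (missing = 0).

    A bounded pseudo-metric on distributions: symmetric, zero on
    identity, at most 2 for proportion-normalised inputs.
    """
    cats = set(d1) | set(d2)
    return sum(abs(d1.get(c, 0.0) - d2.get(c, 0.0)) for c in cats)


# --- tabular I/O ---------------------------------------------------------

def load_features(path: str | Path) -> list[GeneFeature]:
    """Load gene features from a GFF3-like TSV.

    Columns: replicon_id, source, type, start (1-based), end (inclusive),
    score, strand, frame, attributes — with a ``cog_category=X`` key in
    the attributes field.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                GeneFeature(
                    replicon_id=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    cog_category=attrs["cog_category"],
                )
            )
    return out


def load_hits(hits_path: str | Path, cog_map_path: str | Path) -> list[HomologyHit]:
    """Load 12-column tabular hits plus a subject -> COG category TSV.

    Query coordinates in the tabular file are 1-based inclusive and may
    be reversed for minus-strand hits; they are normalised to 0-based
    half-open forward intervals.
    """
    cog_map: dict[str, str] = {}
    with open(cog_map_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row and not row[0].startswith("#"):
                cog_map[row[0]] = row[1]
    out = []
    with open(hits_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qstart, qend = int(f[6]), int(f[7])
            if qstart > qend:
                qstart, qend = qend, qstart
            subject = f[1]
            if subject not in cog_map:
                continue
            out.append(
                HomologyHit(
                    query_id=f[0],
                    query_start=qstart - 1,
                    query_end=qend,
                    subject_id=subject,
                    e_value=float(f[10]),
                    bit_score=float(f[11]),
                    cog_category=cog_map[subject],
                )
            )
    return out


def write_verdicts(verdicts: Sequence[AnnotationVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "real", "read_level", "contig_level", "assembled", "verdict_class"])
        for v in verdicts:
            w.writerow([
                v.read_id, v.real or ".", v.read_level or ".",
                v.contig_level or ".", int(v.assembled), v.verdict_class,
            ])


def verdict_class_counts(verdicts: Sequence[AnnotationVerdict]) -> dict[str, int]:
    """Counts per verdict class; values sum to the number of reads."""
    out: dict[str, int] = {}
    for v in verdicts:
        out[v.verdict_class] = out.get(v.verdict_class, 0) + 1
    return out
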