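"""Assembly evaluation statistics.

Covers the usual size statistics (N50, totals, averages, largest,
gap counts for scaffolds and the contigs obtained by splitting them at
N-runs), gene-territory gap metrics (a gene territory is the gene span
plus 10 kb of flank on each side; territories containing assembly gaps
indicate incompletely assembled genes or promoters), a conserved-exon
coverage screen (an exon counts as covered when its best local
alignment to the assembly exceeds an identity threshold over enough of
its length), and sequencing-read summaries with fold coverage against
an assumed genome size.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from Bio import Align

from .digest import SequenceRecord

__all__ = [
    "AssemblyStats",
    "GeneTerritory",
    "TerritoryGapStats",
    "ExonCoverageResult",
    "ReadRow",
    "ReadSummary",
    "nxx",
    "assembly_stats",
    "avg_size",
    "gene_territories",
    "territory_gap_stats",
    "exon_conservation",
    "percent",
    "read_summary",
]


def nxx(lengths, x: float = 0.5) -> int:
    """Nxx statistic: smallest L with sum of lengths >= L at least x*total.

    N50 (the default) is the length such that elements at least that
    long hold half the total bases.
    """
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    target = x * total
    acc = 0
    for l in lengths:
        acc += l
        if acc >= target:
            return l
    return lengths[-1]


def avg_size(total: int, count: int) -> tuple[float, int]:
    """Exact ratio and its nearest-integer rounding (half away from zero)."""
    if count <= 0:
        raise ValueError("count must be positive")
    ratio = total / count
    return ratio, math.floor(ratio + 0.5)


@dataclass
class AssemblyStats:
    """Size statistics for a scaffold set and its implied contigs."""

    n_scaffolds: int
    total_scaffold_bases: int
    avg_scaffold_size: float
    avg_scaffold_size_int: int
    n50_scaffold: int
    largest_scaffold: int
    total_gaps_in_scaffolds: int
    n_contigs: int
    total_contig_bases: int
    avg_contig_size: float
    avg_contig_size_int: int
    n50_contig: int
    largest_contig: int


def _gap_runs(record: SequenceRecord, min_gap_run: int) -> list[tuple[int, int]]:
    return [(s, e) for s, e in record.n_runs if e - s >= min_gap_run]


def assembly_stats(scaffolds, min_gap_run: int = 10) -> AssemblyStats:
    """Table-style summary of a scaffold FASTA.

    Contigs are obtained by splitting each scaffold at N-runs of at
    least ``min_gap_run`` bp; each such run counts as one gap.  Shorter
    N-runs stay inside contigs, so scaffold bases always equal contig
    bases plus counted gap bases.
    """
    scaffolds = list(scaffolds)
    if not scaffolds:
        raise ValueError("no scaffolds")
    scaffold_lengths = [len(s) for s in scaffolds]
    n_gaps = 0
    contig_lengths: list[int] = []
    for rec in scaffolds:
        runs = _gap_runs(rec, min_gap_run)
        n_gaps += len(runs)
        pos = 0
        for s, e in runs:
            if s > pos:
                contig_lengths.append(s - pos)
            pos = e
        if len(rec) > pos:
            contig_lengths.append(len(rec) - pos)

    total_s = sum(scaffold_lengths)
    total_c = sum(contig_lengths)
    avg_s, avg_s_int = avg_size(total_s, len(scaffold_lengths))
    avg_c, avg_c_int = avg_size(total_c, len(contig_lengths))
    return AssemblyStats(
        n_scaffolds=len(scaffold_lengths),
        total_scaffold_bases=total_s,
        avg_scaffold_size=avg_s,
        avg_scaffold_size_int=avg_s_int,
        n50_scaffold=nxx(scaffold_lengths),
        largest_scaffold=max(scaffold_lengths),
        total_gaps_in_scaffolds=n_gaps,
        n_contigs=len(contig_lengths),
        total_contig_bases=total_c,
        avg_contig_size=avg_c,
        avg_contig_size_int=avg_c_int,
        n50_contig=nxx(contig_lengths),
        largest_contig=max(contig_lengths),
    )


@dataclass
class GeneTerritory:
    """A gene span widened by a symmetric flank, clipped to its scaffold."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int


def gene_territories(
    genes, scaffold_lengths: dict[str, int], flank: int = 10_000
) -> list[GeneTerritory]:
    """Territories (gene span +/- flank, half-open) for every gene.

    ``genes`` yields (gene_id, scaffold_id, start, end) with 0-based
    half-open coordinates.  The flank is applied on both sides
    regardless of strand, then clipped to [0, scaffold length).
    """
    territories = []
    for gene_id, scaffold_id, start, end in genes:
        if scaffold_id not in scaffold_lengths:
            raise KeyError(f"gene {gene_id!r} on unknown scaffold {scaffold_id!r}")
        length = scaffold_lengths[scaffold_id]
        territories.append(
            GeneTerritory(
                gene_id=gene_id,
                scaffold_id=scaffold_id,
                start=max(0, start - flank),
                end=min(length, end + flank),
            )
        )
    return territories


@dataclass
class TerritoryGapStats:
    total_gaps_in_territories: int
    n_territories_with_gaps: int
    n_territories: int


def territory_gap_stats(
    territories: list[GeneTerritory],
    gaps_by_scaffold: dict[str, list[tuple[int, int]]],
) -> TerritoryGapStats:
    """Count assembly gaps falling inside gene territories.

    A gap counts toward a territory when the two intervals intersect;
    a gap overlapping several territories counts once per territory.
    Reports the total incidence count and the number of territories
    containing at least one gap.
    """
    sorted_gaps = {
        sid: sorted(gaps) for sid, gaps in gaps_by_scaffold.items()
    }
    starts = {sid: [g[0] for g in gaps] for sid, gaps in sorted_gaps.items()}
    total = 0
    with_gaps = 0
    for terr in territories:
        gaps = sorted_gaps.get(terr.scaffold_id, [])
        if not gaps:
            continue
        # first gap whose start could still intersect; walk from the
        # first gap ending after terr.start
        idx = bisect_left(starts[terr.scaffold_id], terr.start)
        while idx > 0 and gaps[idx - 1][1] > terr.start:
            idx -= 1
        count = 0
        for s, e in gaps[idx:]:
            if s >= terr.end:
                break
            if e > terr.start:
                count += 1
        total += count
        if count:
            with_gaps += 1
    return TerritoryGapStats(
        total_gaps_in_territories=total,
        n_territories_with_gaps=with_gaps,
        n_territories=len(territories),
    )


@dataclass
class ExonCoverageResult:
    exon_id: str
    best_identity: float
    best_coverage: float
    conserved: bool


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _alignment_identity_coverage(alignment, query_len: int) -> tuple[float, float]:
    t_segs, q_segs = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = 0
    aligned_q = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_segs, q_segs):
        if prev_t_end is not None:
            columns += (ts - prev_t_end) + (qs - prev_q_end)
        seg_len = te - ts
        columns += seg_len
        aligned_q += qe - qs
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
        prev_t_end, prev_q_end = te, qe
    if columns == 0:
        return 0.0, 0.0
    return matches / columns, aligned_q / query_len


def exon_conservation(
    exons,
    assembly,
    id_threshold: float = 0.86,
    cov_threshold: float = 0.87,
    k: int = 11,
    max_candidates: int = 8,
):
    """Screen exons for conserved coverage in an assembly.

    Each exon is located by exact k-mer seeding (both strands) followed
    by local alignment of the exon against a window around each seeded
    diagonal.  Identity is matches over aligned columns (gaps
    included); coverage is aligned exon bases over exon length.  An
    exon is conserved when identity exceeds ``id_threshold`` and
    coverage exceeds ``cov_threshold`` (both strictly).

    Returns (results, percent_conserved).
    """
    exons = list(exons)
    if not exons:
        raise ValueError("empty exon set")
    assembly = list(assembly)
    for rec in exons:
        if len(rec) < 20:
            raise ValueError(f"exon {rec.id!r} shorter than 20 bp")

    # seed index over exon k-mers (both strands), scanned along the assembly
    index: dict[str, list[tuple[int, int, int]]] = {}
    oriented: list[tuple[str, str]] = []  # per exon: (fwd, rev) sequences
    for ei, rec in enumerate(exons):
        fwd = rec.sequence
        rev = _revcomp(fwd)
        oriented.append((fwd, rev))
        for strand, seq in ((0, fwd), (1, rev)):
            for pos in range(0, len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((ei, strand, pos))

    # per exon: (strand, scaffold, diagonal bucket) -> seed count
    hits: list[dict[tuple[int, int, int], int]] = [{} for _ in exons]
    for si, rec in enumerate(assembly):
        seq = rec.sequence
        for pos in range(0, len(seq) - k + 1):
            entry = index.get(seq[pos : pos + k])
            if not entry:
                continue
            for ei, strand, qpos in entry:
                key = (strand, si, (pos - qpos) // 50)
                bucket = hits[ei]
                bucket[key] = bucket.get(key, 0) + 1

    aligner = _make_aligner()
    results = []
    for ei, rec in enumerate(exons):
        exon_len = len(rec)
        margin = max(20, exon_len // 5)
        candidates = [
            (count, si, strand, diag * 50)
            for (strand, si, diag), count in hits[ei].items()
        ]
        candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
        best_id, best_cov, best_score = 0.0, 0.0, float("-inf")
        for _count, si, strand, diag in candidates[:max_candidates]:
            target_seq = assembly[si].sequence
            lo = max(0, diag - margin)
            hi = min(len(target_seq), diag + exon_len + margin + 50)
            window = target_seq[lo:hi]
            query = oriented[ei][strand]
            alignments = aligner.align(window, query)
            score = alignments.score
            if score <= best_score:
                continue
            aln = alignments[0]
            ident, cov = _alignment_identity_coverage(aln, exon_len)
            best_score = score
            best_id, best_cov = ident, cov
        results.append(
            ExonCoverageResult(
                exon_id=rec.id,
                best_identity=best_id,
                best_coverage=best_cov,
                conserved=best_id > id_threshold and best_cov > cov_threshold,
            )
        )
    pct = percent(sum(r.conserved for r in results), len(results), 2, "truncate")
    return results, pct


def percent(
    count: int, total: int, decimals: int = 2, mode: str = "round"
) -> float:
    """Express count/total as a percentage at fixed precision.

    ``mode="round"`` rounds half away from zero; ``mode="truncate"``
    drops the excess digits, the convention behind figures like 96.25%
    for 3,165/3,288.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    value = Decimal(100 * int(count)) / Decimal(int(total))
    quantum = Decimal(1).scaleb(-decimals)
    rounding = {"round": ROUND_HALF_UP, "truncate": ROUND_DOWN}[mode]
    return float(value.quantize(quantum, rounding=rounding))


@dataclass
class ReadRow:
    platform: str
    description: str
    total_reads: int
    total_bases_mb: float
    coverage: float


@dataclass
class ReadSummary:
    rows: list[ReadRow]
    combined: ReadRow
    genome_size: float


def read_summary(rows, genome_size: float = 1.23e9) -> ReadSummary:
    """Summarise per-platform read counts, bases and fold coverage.

    ``rows`` yields (platform, description, total_reads, total_bases_mb).
    Combined reads/bases are exact sums over the platforms; coverage is
    total bases divided by the assumed genome size.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no read rows")
    out = [
        ReadRow(p, d, r, mb, mb * 1e6 / genome_size) for p, d, r, mb in rows
    ]
    tot_reads = sum(r.total_reads for r in out)
    tot_mb = sum(r.total_bases_mb for r in out)
    combined = ReadRow("Combined", "", tot_reads, tot_mb, tot_mb * 1e6 / genome_size)
    return ReadSummary(rows=out, combined=combined, genome_size=genome_size)
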