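"""Chimera calling and megascaffold construction from map alignments.

A scaffold whose restriction map aligns to two or more distinct optical
map contigs is called chimeric — its two parts belong to different
genomic regions, indicating a misjoin.  Chimeric scaffolds are reported
and excluded from joining (validation only; they are not broken).

Megascaffolds are built from end-anchored alignments under three
heuristics: (1) the total of the two facing overhangs at a candidate
join must not exceed 2 Mbp; (2) two scaffolds are bridged only when the
estimated gap between them is under 2 Mbp of Ns; (3) a scaffold that
aligns to several optical maps is placed into the largest one.  Joining
walks each optical contig left to right, greedily chaining neighbouring
placements that satisfy the caps; gap sizes come from optical map
coordinates.  Results are serialised as AGP v2.1 plus gapped FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import MapAlignment
from .digest import RestrictionMap
from .metrics import nxx

__all__ = [
    "ChimeraCall",
    "Placement",
    "Bridge",
    "Megascaffold",
    "ScaffoldAccounting",
    "call_chimeras",
    "filter_end_anchored",
    "assign_unique_map",
    "build_bridges",
    "extend_megascaffolds",
    "emit_agp",
    "emit_fasta",
    "scaffold_assembly",
    "ScaffoldingResult",
]

#: placements overlapping by more than this are flagged and never joined
MAX_OVERLAP = 50_000
#: sentinel N gap used when the optical gap estimate is zero or negative
SENTINEL_GAP = 100


@dataclass
class ChimeraCall:
    scaffold_id: str
    optical_maps_hit: set[str]

    @property
    def is_chimeric(self) -> bool:
        return len(self.optical_maps_hit) >= 2


@dataclass
class Placement:
    """One scaffold positioned on one optical map contig."""

    scaffold_id: str
    orientation: str
    opt_start_bp: int
    opt_end_bp: int
    overhang_left: int
    overhang_right: int
    score: float


@dataclass
class Bridge:
    """All placements on one optical map, ordered by optical position.

    ``gaps[k]`` is the optical distance between the aligned end of
    placement ``k`` and the aligned start of placement ``k+1``; it may
    be negative when the aligned regions overlap.  ``flagged[k]`` marks
    overlaps deeper than ``MAX_OVERLAP``, which are never joined.
    """

    optical_map_id: str
    placements: list[Placement]
    gaps: list[int] = field(default_factory=list)
    flagged: list[bool] = field(default_factory=list)


@dataclass
class Megascaffold:
    """Ordered, oriented scaffolds joined along one optical map.

    ``components`` is a list of (scaffold_id, orientation, gap_before)
    where ``gap_before`` is the run of Ns inserted before the component
    (0 for the first).
    """

    id: str
    components: list[tuple[str, str, int]]
    source_optical_map: str
    total_span: int

    @property
    def scaffold_ids(self) -> list[str]:
        return [c[0] for c in self.components]


@dataclass
class ScaffoldAccounting:
    n_scaffolds_before: int
    n_scaffolds_after: int
    n50_before: int
    n50_after: int


def call_chimeras(
    alignments: list[MapAlignment],
    min_new_fragments: int = 3,
    min_anchor_score: float = 9.0,
) -> list[ChimeraCall]:
    """One call per aligned scaffold; chimeric iff distinct parts of it
    align to two or more optical map contigs.

    Only scaffolds carrying at least one confident alignment (score >=
    ``min_anchor_score``) are assessed: a scaffold with nothing but
    borderline hits is unaligned, not chimeric.  Evidence alignments
    must then explain different stretches of the scaffold: per
    scaffold, the best alignment to each optical map is taken, and
    alignments are admitted greedily by score provided each covers a
    contiguous run of at least ``min_new_fragments`` scaffold
    fragments not already covered by stronger evidence.  A genuine
    misjoin's two parts occupy complementary stretches and both are
    admitted; a spurious secondary hit re-aligns fragments the primary
    alignment already explains and is not.  (Alignments may
    over-extend a little past a misjoin junction, so ranges are
    allowed to overlap as long as the net new contribution is a long
    enough contiguous stretch.)
    """
    by_scaffold: dict[str, dict[str, MapAlignment]] = {}
    for aln in alignments:
        per_map = by_scaffold.setdefault(aln.scaffold_map_id, {})
        cur = per_map.get(aln.optical_map_id)
        if cur is None or aln.score > cur.score:
            per_map[aln.optical_map_id] = aln

    calls = []
    for sid in sorted(by_scaffold):
        alns = sorted(
            by_scaffold[sid].values(), key=lambda a: (-a.score, a.optical_map_id)
        )
        if alns[0].score < min_anchor_score:
            continue
        covered: set[int] = set()
        kept_maps: set[str] = set()
        for aln in alns:
            lo, hi = aln.scaffold_range_original
            run = best_run = 0
            for idx in range(lo, hi):
                run = run + 1 if idx not in covered else 0
                best_run = max(best_run, run)
            if best_run >= min_new_fragments:
                covered.update(range(lo, hi))
                kept_maps.add(aln.optical_map_id)
        calls.append(ChimeraCall(sid, kept_maps))
    return calls


def filter_end_anchored(alignments: list[MapAlignment]) -> list[MapAlignment]:
    """Keep only alignments that reach an end of either map."""
    return [a for a in alignments if a.end_anchored]


def assign_unique_map(
    alignments: list[MapAlignment], optical_maps, score_margin: float = 3.0
) -> list[MapAlignment]:
    """Keep, per scaffold, only alignments to its largest optical map.

    When a scaffold aligns to several optical maps it is placed into
    the one with the greatest total span, choosing only among maps
    whose best alignment scores within ``score_margin`` of the
    scaffold's best overall — map size arbitrates between comparable
    placements, it does not let a large map's marginal hit outrank a
    decisively better alignment elsewhere.  Exact span ties go to the
    lexicographically smaller map id.
    """
    spans = {m.id: m.total_span for m in optical_maps}
    by_scaffold: dict[str, list[MapAlignment]] = {}
    for aln in alignments:
        by_scaffold.setdefault(aln.scaffold_map_id, []).append(aln)
    kept: list[MapAlignment] = []
    for sid in sorted(by_scaffold):
        alns = by_scaffold[sid]
        best_per_map: dict[str, float] = {}
        for a in alns:
            best_per_map[a.optical_map_id] = max(
                best_per_map.get(a.optical_map_id, float("-inf")), a.score
            )
        cutoff = max(best_per_map.values()) - score_margin
        candidates = [mid for mid, s in best_per_map.items() if s >= cutoff]
        chosen = min(candidates, key=lambda mid: (-spans[mid], mid))
        kept.extend(a for a in alns if a.optical_map_id == chosen)
    return kept


def build_bridges(alignments: list[MapAlignment]) -> list[Bridge]:
    """Group placements per optical map; keep maps bridging >= 2 scaffolds.

    A scaffold contributes its single best-scoring alignment to a map.
    Placements are sorted by optical start (ties by scaffold id) and
    neighbour gaps computed from optical coordinates.
    """
    best: dict[tuple[str, str], MapAlignment] = {}
    for aln in alignments:
        key = (aln.optical_map_id, aln.scaffold_map_id)
        cur = best.get(key)
        if cur is None or aln.score > cur.score:
            best[key] = aln

    per_map: dict[str, list[Placement]] = {}
    for (mid, _sid), aln in best.items():
        per_map.setdefault(mid, []).append(
            Placement(
                scaffold_id=aln.scaffold_map_id,
                orientation=aln.orientation,
                opt_start_bp=aln.optical_start_bp,
                opt_end_bp=aln.optical_end_bp,
                overhang_left=aln.scaffold_overhang_left,
                overhang_right=aln.scaffold_overhang_right,
                score=aln.score,
            )
        )

    bridges = []
    for mid in sorted(per_map):
        placements = sorted(per_map[mid], key=lambda p: (p.opt_start_bp, p.scaffold_id))
        if len(placements) < 2:
            continue
        gaps = [
            nxt.opt_start_bp - prev.opt_end_bp
            for prev, nxt in zip(placements, placements[1:])
        ]
        flagged = [g < -MAX_OVERLAP for g in gaps]
        bridges.append(Bridge(mid, placements, gaps, flagged))
    return bridges


def extend_megascaffolds(
    bridges: list[Bridge],
    scaffold_lengths: dict[str, int],
    max_overhang: int = 2_000_000,
    max_gap: int = 2_000_000,
    overlap_slack: int = 10_000,
) -> tuple[list[Megascaffold], ScaffoldAccounting]:
    """Chain neighbouring placements into megascaffolds under the caps.

    Walking each bridge left to right, a neighbour pair is joined when
    (a) the sum of the two facing overhangs is at most ``max_overhang``,
    (b) the optical gap estimate is below ``max_gap``, and (c) the
    facing overhangs physically fit inside the gap: unaligned scaffold
    tails occupy the unmapped interval between the two aligned regions,
    so tails longer than the gap (plus ``overlap_slack`` for sizing
    noise) would overlap the neighbour's aligned sequence — the
    signature of a spurious tail such as the foreign half of an
    undetected chimera.  Zero or negative gap estimates (down to
    ``-MAX_OVERLAP``) are joined with a ``SENTINEL_GAP`` of Ns; deeper
    overlaps are refused.  Scaffolds not joined to anything pass
    through unchanged and are counted in the accounting, which must
    show a non-increasing scaffold count and a non-decreasing N50.

    ``scaffold_lengths`` must cover the whole input scaffold set so the
    before/after accounting reflects the full assembly.
    """
    megas: list[Megascaffold] = []
    joined_ids: set[str] = set()
    for bridge in bridges:
        chains: list[list[tuple[Placement, int]]] = []
        current: list[tuple[Placement, int]] = [(bridge.placements[0], 0)]
        for k, nxt in enumerate(bridge.placements[1:]):
            prev = current[-1][0]
            gap = nxt.opt_start_bp - prev.opt_end_bp
            facing = prev.overhang_right + nxt.overhang_left
            ok = (
                not (gap < -MAX_OVERLAP)
                and gap < max_gap
                and facing <= max_overhang
                and facing <= max(gap, 0) + overlap_slack
            )
            if ok:
                current.append((nxt, gap if gap > 0 else SENTINEL_GAP))
            else:
                chains.append(current)
                current = [(nxt, 0)]
        chains.append(current)

        k = 0
        for chain in chains:
            if len(chain) < 2:
                continue
            components = [
                (p.scaffold_id, p.orientation, gap_before) for p, gap_before in chain
            ]
            span = sum(scaffold_lengths[c[0]] for c in components) + sum(
                c[2] for c in components
            )
            megas.append(
                Megascaffold(
                    id=f"mega_{bridge.optical_map_id}_{k}",
                    components=components,
                    source_optical_map=bridge.optical_map_id,
                    total_span=span,
                )
            )
            joined_ids.update(c[0] for c in components)
            k += 1

    before = list(scaffold_lengths.values())
    after = [
        length for sid, length in scaffold_lengths.items() if sid not in joined_ids
    ]
    after.extend(m.total_span for m in megas)
    accounting = ScaffoldAccounting(
        n_scaffolds_before=len(before),
        n_scaffolds_after=len(after),
        n50_before=nxx(before),
        n50_after=nxx(after),
    )
    return megas, accounting


def emit_agp(
    megascaffolds: list[Megascaffold], scaffold_lengths: dict[str, int]
) -> list[str]:
    """Serialise megascaffolds as AGP v2.1 rows (1-based inclusive).

    Component (W) rows alternate with gap (N) rows of gap_type "map",
    linkage "no".  Returns the lines including the version header.
    """
    lines = ["##agp-version\t2.1"]
    for mega in megascaffolds:
        pos = 0
        part = 0
        for sid, orientation, gap_before in mega.components:
            if sid not in scaffold_lengths:
                raise KeyError(f"unknown scaffold id {sid!r}")
            if part > 0:
                part += 1
                lines.append(
                    "\t".join(
                        [
                            mega.id,
                            str(pos + 1),
                            str(pos + gap_before),
                            str(part),
                            "N",
                            str(gap_before),
                            "map",
                            "no",
                            "na",
                        ]
                    )
                )
                pos += gap_before
            length = scaffold_lengths[sid]
            part += 1
            lines.append(
                "\t".join(
                    [
                        mega.id,
                        str(pos + 1),
                        str(pos + length),
                        str(part),
                        "W",
                        sid,
                        "1",
                        str(length),
                        "+" if orientation == "forward" else "-",
                    ]
                )
            )
            pos += length
    return lines


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def emit_fasta(
    megascaffolds: list[Megascaffold], sequences: dict[str, str]
) -> list[tuple[str, str]]:
    """Build gapped megascaffold sequences as (id, sequence) pairs.

    Components are concatenated in order, reverse-complemented when
    their orientation is reverse, separated by runs of N of the stored
    gap length.  The result length equals ``total_span``.
    """
    out = []
    for mega in megascaffolds:
        parts = []
        for sid, orientation, gap_before in mega.components:
            if sid not in sequences:
                raise KeyError(f"missing sequence for {sid!r}")
            if gap_before:
                parts.append("N" * gap_before)
            seq = sequences[sid]
            parts.append(seq if orientation == "forward" else reverse_complement(seq))
        merged = "".join(parts)
        assert len(merged) == mega.total_span
        out.append((mega.id, merged))
    return out


@dataclass
class ScaffoldingResult:
    """Everything the megascaffolding pipeline produces in one pass."""

    alignments: list[MapAlignment]
    usable_alignments: list[MapAlignment]
    chimera_calls: list[ChimeraCall]
    bridges: list[Bridge]
    megascaffolds: list[Megascaffold]
    accounting: ScaffoldAccounting

    @property
    def chimeric_ids(self) -> set[str]:
        return {c.scaffold_id for c in self.chimera_calls if c.is_chimeric}

    @property
    def placed(self) -> dict[str, str]:
        """Scaffold id -> optical map it was assigned to for bridging."""
        return {a.scaffold_map_id: a.optical_map_id for a in self.usable_alignments}


def scaffold_assembly(
    scaffold_maps: list[RestrictionMap],
    optical_maps: list[RestrictionMap],
    scaffold_lengths: dict[str, int],
    params=None,
    max_overhang: int = 2_000_000,
    max_gap: int = 2_000_000,
    exclude_chimeric: bool = True,
    place_min_score: float = 9.0,
    place_min_coverage: float = 0.7,
) -> ScaffoldingResult:
    """Run the full validate-and-megascaffold pipeline.

    digest-side maps are aligned to the optical maps and chimeras
    called.  Bridging then uses only high-quality placements:
    end-anchored alignments that score at least ``place_min_score``
    and cover at least ``place_min_coverage`` of the scaffold's
    fragments — a whole-scaffold placement, as opposed to the partial
    alignments that drive chimera detection.  Each placed scaffold is
    assigned to its largest optical map, bridges are built and
    megascaffolds extended under the overhang and gap caps.  Chimeric
    scaffolds are excluded from joining (they pass through as
    singletons) unless ``exclude_chimeric`` is False.
    """
    from .align import align_all

    alignments = align_all(scaffold_maps, optical_maps, params)
    calls = call_chimeras(alignments)
    chimeric = {c.scaffold_id for c in calls if c.is_chimeric}

    usable = filter_end_anchored(alignments)
    usable = [
        a
        for a in usable
        if a.score >= place_min_score and a.scaffold_coverage >= place_min_coverage
    ]
    if exclude_chimeric:
        usable = [a for a in usable if a.scaffold_map_id not in chimeric]
    usable = assign_unique_map(usable, optical_maps)
    bridges = build_bridges(usable)
    megas, accounting = extend_megascaffolds(
        bridges, scaffold_lengths, max_overhang=max_overhang, max_gap=max_gap
    )
    return ScaffoldingResult(alignments, usable, calls, bridges, megas, accounting)
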