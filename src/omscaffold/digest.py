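"""In silico restriction digestion of nucleotide sequences.

An ordered restriction map — the list of fragment lengths produced by
cutting a sequence at every occurrence of an enzyme's recognition site —
is the common currency that lets sequence scaffolds be compared with
optical map contigs, which carry fragment sizes but no nucleotide
content.  This module digests sequences with a single enzyme (SwaI by
default, the 8-bp blunt cutter ATTT/AAAT), applies the fragment
qualification filter used to decide whether a scaffold carries enough
restriction information to be aligned at all, and computes the map
resolution statistic (average fragment size over a map set).

Coordinates are 0-based half-open throughout; conversion to 1-based
happens only when writing interchange formats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "EnzymeSpec",
    "SWAI",
    "SequenceRecord",
    "RestrictionMap",
    "QualificationResult",
    "find_sites",
    "digest",
    "qualify_map",
    "map_resolution",
]

_VALID_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site plus cut offset.

    ``cut_offset`` is the distance in bp from the start of the
    recognition site to the cut position on the top strand.  SwaI
    recognises the palindrome ATTTAAAT and cuts bluntly in the middle
    (offset 4).
    """

    name: str = "SwaI"
    recognition_site: str = "ATTTAAAT"
    cut_offset: int = 4

    def __post_init__(self) -> None:
        site = self.recognition_site
        if not site or not re.fullmatch(r"[ACGT]+", site):
            raise ValueError(
                f"recognition_site must be non-empty uppercase A/C/G/T, got {site!r}"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}]"
            )


SWAI = EnzymeSpec()


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with its runs of ambiguous bases.

    ``n_runs`` holds the maximal runs of N as half-open intervals,
    sorted and non-overlapping; they are computed from the sequence.
    """

    id: str
    sequence: str
    n_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not _VALID_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"sequence {self.id!r} has invalid characters {bad}")
        self.n_runs = [(m.start(), m.end()) for m in re.finditer(r"N+", self.sequence)]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RestrictionMap:
    """Ordered fragment lengths (bp) of one molecule or scaffold.

    ``source`` is ``"in_silico"`` for maps digested from sequence and
    ``"optical"`` for maps measured from single molecules.  Optical map
    files carry kb; they are converted to integer bp on read so the two
    kinds share units.
    """

    id: str
    source: str
    fragments: list[int]

    def __post_init__(self) -> None:
        if self.source not in ("in_silico", "optical"):
            raise ValueError(f"unknown map source {self.source!r}")
        if any(f <= 0 for f in self.fragments):
            raise ValueError(f"map {self.id!r} has non-positive fragments")

    @property
    def total_span(self) -> int:
        return sum(self.fragments)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class QualificationResult:
    """Outcome of the fragment-qualification filter for one map."""

    map_id: str
    n_internal_fragments_passing: int
    qualifies: bool
    filtered_map: RestrictionMap


def find_sites(seq: SequenceRecord | str, enzyme: EnzymeSpec = SWAI) -> list[int]:
    """Return cut positions (0-based bp) of ``enzyme`` in ``seq``.

    Overlapping occurrences of the recognition site are all reported.
    Because matching is exact over A/C/G/T, windows containing N can
    never match: a site obscured by ambiguity is skipped rather than
    guessed.  Cuts falling exactly on the sequence boundary (possible
    only for offset 0 or offset = site length) are dropped, so every
    reported cut splits the sequence into two non-empty parts.
    """
    if isinstance(seq, str):
        seq = SequenceRecord("anonymous", seq)
    site = enzyme.recognition_site
    pattern = re.compile(f"(?=({site}))")
    n = len(seq.sequence)
    cuts = [
        m.start() + enzyme.cut_offset
        for m in pattern.finditer(seq.sequence)
        if 0 < m.start() + enzyme.cut_offset < n
    ]
    return cuts


def digest(seq: SequenceRecord | str, enzyme: EnzymeSpec = SWAI) -> RestrictionMap:
    """Digest ``seq`` into an ordered in silico restriction map.

    Fragments are the consecutive differences of [0, cuts..., length];
    their sum always equals the sequence length.  A sequence without
    any site yields a single full-length fragment.
    """
    if isinstance(seq, str):
        seq = SequenceRecord("anonymous", seq)
    cuts = find_sites(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return RestrictionMap(id=seq.id, source="in_silico", fragments=fragments)


def qualify_map(
    rmap: RestrictionMap, min_frag: int = 400, min_internal: int = 3
) -> QualificationResult:
    """Apply the alignability filter to a restriction map.

    A map qualifies when it has at least ``min_internal`` internal
    fragments (end fragments excluded) of at least ``min_frag`` bp.
    Fragments below the size threshold are invisible to the optical
    measurement, so in ``filtered_map`` each sub-threshold internal
    fragment is merged into its left neighbour; end fragments are kept
    as they are.  Total span is preserved by the merge.
    """
    if rmap.n_fragments == 0:
        raise ValueError("cannot qualify an empty map")
    frags = rmap.fragments
    if rmap.n_fragments < 3:
        filtered = RestrictionMap(rmap.id, rmap.source, list(frags))
        return QualificationResult(rmap.id, 0, False, filtered)

    internal = frags[1:-1]
    n_passing = sum(1 for f in internal if f >= min_frag)

    merged = [frags[0]]
    for f in internal:
        if f < min_frag:
            merged[-1] += f
        else:
            merged.append(f)
    merged.append(frags[-1])
    filtered = RestrictionMap(rmap.id, rmap.source, merged)
    return QualificationResult(
        map_id=rmap.id,
        n_internal_fragments_passing=n_passing,
        qualifies=n_passing >= min_internal,
        filtered_map=filtered,
    )


def map_resolution(maps) -> float:
    """Average fragment size over a collection of maps, in kbp.

    This is the resolution statistic quoted for optical map sets: one
    cut every so many kbp, i.e. total span divided by total fragment
    count.
    """
    maps = list(maps)
    total_span = sum(m.total_span for m in maps)
    total_frags = sum(m.n_fragments for m in maps)
    if total_frags == 0:
        raise ValueError("map collection has no fragments")
    return total_span / total_frags / 1000.0
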