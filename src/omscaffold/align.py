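"""Alignment of in silico restriction maps to optical map contigs.

Optical maps measure restriction fragment sizes with multiplicative
sizing error, miss some cuts (two true fragments read as one) and show
spurious extra cuts.  Alignment therefore works on *blocks*: a run of
up to ``max_merge`` consecutive scaffold fragments is matched against a
run of up to ``max_merge`` consecutive optical fragments, scored by a
likelihood-inspired model — a bonus per matched cut, a Gaussian
penalty on the difference of the block sums scaled by the expected
sizing error, and unit penalties for each cut left unmatched inside
the block (missing cuts on the scaffold side, false cuts on the
optical side).

The dynamic program finds the best-scoring chain of blocks placing the
scaffold map inside the (much longer) optical map contig.  Scaffold
ends may be left unaligned: free of charge where the scaffold runs off
an end of the optical contig (the scaffold genuinely extends beyond
the mapped region), or at a per-fragment cost anywhere else.  The
unaligned portions are reported as overhangs — the parts of the
scaffold that do not align to the optical map.  Penalised interior
clipping is what lets a chimeric scaffold produce a qualifying partial
alignment to each of the two optical contigs it straddles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .digest import RestrictionMap

__all__ = [
    "AlignmentParams",
    "MapAlignment",
    "score_block",
    "align_fit",
    "align_all",
    "classify_end_anchored",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class AlignmentParams:
    """Tunable knobs of the block-scoring model and the DP.

    sizing_cv
        Relative standard deviation of an optical fragment size.
    cut_bonus
        Score awarded per matched cut (per block).
    missing_cut_penalty / false_cut_penalty
        Cost per unmatched scaffold / optical cut merged inside a block.
    max_merge
        Maximum fragments merged into a single block on either side.
    min_score
        Acceptance threshold for a whole alignment.
    end_tolerance_fragments
        Slack, in fragments, when deciding whether an alignment reaches
        a map end.
    clip_penalty
        Cost per scaffold fragment left unaligned away from an optical
        map end (interior clipping).
    """

    sizing_cv: float = 0.03
    cut_bonus: float = 3.0
    missing_cut_penalty: float = 1.0
    false_cut_penalty: float = 1.0
    max_merge: int = 4
    min_score: float = 6.0
    end_tolerance_fragments: int = 1
    clip_penalty: float = 0.2

    def __post_init__(self) -> None:
        if self.sizing_cv <= 0:
            raise ValueError("sizing_cv must be positive")
        if self.max_merge < 1:
            raise ValueError("max_merge must be at least 1")
        for name in ("missing_cut_penalty", "false_cut_penalty", "clip_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MapAlignment:
    """Block-wise correspondence between a scaffold map and an optical map.

    Fragment indices refer to the scaffold map *in aligned orientation*
    (reversed fragment order when ``orientation == "reverse"``), so that
    "left" always means toward the start of the optical contig.  Blocks
    are half-open index ranges ``((q_lo, q_hi), (t_lo, t_hi))``.
    """

    scaffold_map_id: str
    optical_map_id: str
    orientation: str
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    score: float
    scaffold_overhang_left: int
    scaffold_overhang_right: int
    optical_offset_start: int
    optical_offset_end: int
    optical_start_bp: int
    optical_end_bp: int
    n_scaffold_fragments: int
    n_optical_fragments: int
    end_anchored: bool = False

    @property
    def scaffold_start_frag(self) -> int:
        return self.blocks[0][0][0]

    @property
    def scaffold_end_frag(self) -> int:
        return self.blocks[-1][0][1]

    @property
    def n_aligned_fragments(self) -> int:
        return self.scaffold_end_frag - self.scaffold_start_frag

    @property
    def scaffold_coverage(self) -> float:
        """Fraction of the scaffold map's fragments inside the alignment."""
        return self.n_aligned_fragments / self.n_scaffold_fragments

    @property
    def scaffold_range_original(self) -> tuple[int, int]:
        """Aligned fragment range in the scaffold's own (unreversed) frame."""
        lo, hi = self.scaffold_start_frag, self.scaffold_end_frag
        if self.orientation == REVERSE:
            m = self.n_scaffold_fragments
            return m - hi, m - lo
        return lo, hi


def score_block(scaffold_frags, optical_frags, params: AlignmentParams) -> float:
    """Score one block matching scaffold fragments against optical ones.

    score = cut_bonus
            - (sum_q - sum_t)^2 / (2 * (sizing_cv * sum_t)^2)
            - missing_cut_penalty * (len(scaffold_frags) - 1)
            - false_cut_penalty * (len(optical_frags) - 1)
    """
    nq, nt = len(scaffold_frags), len(optical_frags)
    if nq == 0 or nt == 0:
        raise ValueError("block sides must be non-empty")
    if nq > params.max_merge or nt > params.max_merge:
        raise ValueError("block exceeds max_merge")
    sq = float(sum(scaffold_frags))
    st = float(sum(optical_frags))
    sizing = (sq - st) ** 2 / (2.0 * (params.sizing_cv * st) ** 2)
    return (
        params.cut_bonus
        - sizing
        - params.missing_cut_penalty * (nq - 1)
        - params.false_cut_penalty * (nt - 1)
    )


def _dp_one_orientation(q, t, params: AlignmentParams):
    """Best chain of blocks aligning fragment list ``q`` into ``t``.

    Returns (score, blocks, q_start, q_end, t_start, t_end) or None.
    Ties are broken toward fewer blocks, then toward a smaller optical
    start index.
    """
    m, n = len(q), len(t)
    mm = params.max_merge
    cb = params.cut_bonus
    mp = params.missing_cut_penalty
    fp = params.false_cut_penalty
    clip = params.clip_penalty
    inv2 = 1.0 / (2.0 * params.sizing_cv * params.sizing_cv)

    pq = [0] * (m + 1)
    for i, f in enumerate(q):
        pq[i + 1] = pq[i] + f
    pt = [0] * (n + 1)
    for j, f in enumerate(t):
        pt[j + 1] = pt[j] + f

    NEG = float("-inf")
    # cell: (score, nblocks, t_start, q_start, prev_i, prev_j)
    cells = [[None] * (n + 1) for _ in range(m + 1)]

    def start_cost(i: int, j: int) -> float:
        # Beginning an alignment at (i, j): scaffold fragments q[:i] are
        # unaligned.  Free at the optical start (genuine overhang) or
        # when nothing is clipped; otherwise pay per clipped fragment.
        if i == 0 or j == 0:
            return 0.0
        return -clip * i

    for i in range(1, m + 1):
        row = cells[i]
        a_max = min(mm, i)
        for j in range(1, n + 1):
            best = None
            for a in range(1, a_max + 1):
                sq = pq[i] - pq[i - a]
                miss = mp * (a - 1)
                pi = i - a
                for b in range(1, min(mm, j) + 1):
                    pj = j - b
                    st = pt[j] - pt[pj]
                    bscore = cb - (sq - st) * (sq - st) * inv2 / (st * st) - miss - fp * (b - 1)
                    prev = cells[pi][pj]
                    # extend an existing chain
                    if prev is not None:
                        cand = (
                            prev[0] + bscore,
                            prev[1] + 1,
                            prev[2],
                            prev[3],
                            pi,
                            pj,
                        )
                        if best is None or _better(cand, best):
                            best = cand
                    # or start a fresh chain at (pi, pj)
                    cand = (start_cost(pi, pj) + bscore, 1, pj, pi, -1, -1)
                    if best is None or _better(cand, best):
                        best = cand
            row[j] = best

    overall = None
    end = None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cell = cells[i][j]
            if cell is None:
                continue
            # Ending at (i, j): scaffold fragments q[i:] are unaligned.
            # Free at the optical end or when nothing remains.
            end_cost = 0.0 if (i == m or j == n) else -clip * (m - i)
            cand = (cell[0] + end_cost, cell[1], cell[2])
            if overall is None or _better(cand, overall):
                overall = cand
                end = (i, j)
    if overall is None:
        return None

    # traceback
    blocks = []
    i, j = end
    while i != -1:
        cell = cells[i][j]
        pi, pj = cell[4], cell[5]
        if pi == -1:
            blocks.append(((cell[3], i), (cell[2], j)))
            break
        blocks.append(((pi, i), (pj, j)))
        i, j = pi, pj
    blocks.reverse()
    q_start, q_end = blocks[0][0][0], blocks[-1][0][1]
    t_start, t_end = blocks[0][1][0], blocks[-1][1][1]
    return overall[0], blocks, q_start, q_end, t_start, t_end


def _better(cand, best) -> bool:
    """Score first; ties toward fewer blocks, then smaller optical start."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] < best[1]
    return cand[2] < best[2]


def align_fit(
    scaffold_map: RestrictionMap,
    optical_map: RestrictionMap,
    params: AlignmentParams | None = None,
) -> MapAlignment | None:
    """Best placement of a scaffold map inside one optical map contig.

    Both orientations of the scaffold map are tried; the better-scoring
    one is returned (forward wins exact ties).  Returns ``None`` when
    either map has fewer than two fragments or the best score falls
    below ``params.min_score``.
    """
    if params is None:
        params = AlignmentParams()
    q = scaffold_map.fragments
    t = optical_map.fragments
    if len(q) < 2 or len(t) < 2:
        return None

    candidates = []
    for orientation, q_or in ((FORWARD, q), (REVERSE, list(reversed(q)))):
        result = _dp_one_orientation(q_or, t, params)
        if result is not None:
            candidates.append((orientation, q_or, result))
    if not candidates:
        return None

    def sort_key(item):
        orientation, _, (score, blocks, *_rest) = item
        return (-score, len(blocks), 0 if orientation == FORWARD else 1)

    candidates.sort(key=sort_key)
    orientation, q_or, (score, blocks, q_start, q_end, t_start, t_end) = candidates[0]
    if score < params.min_score:
        return None

    pt = [0]
    for f in t:
        pt.append(pt[-1] + f)
    overhang_left = sum(q_or[:q_start])
    overhang_right = sum(q_or[q_end:])
    aln = MapAlignment(
        scaffold_map_id=scaffold_map.id,
        optical_map_id=optical_map.id,
        orientation=orientation,
        blocks=blocks,
        score=score,
        scaffold_overhang_left=overhang_left,
        scaffold_overhang_right=overhang_right,
        optical_offset_start=t_start,
        optical_offset_end=t_end,
        optical_start_bp=pt[t_start],
        optical_end_bp=pt[t_end],
        n_scaffold_fragments=len(q),
        n_optical_fragments=len(t),
    )
    aln.end_anchored = classify_end_anchored(aln, scaffold_map, optical_map, params)
    return aln


def classify_end_anchored(
    aln: MapAlignment,
    scaffold_map: RestrictionMap,
    optical_map: RestrictionMap,
    params: AlignmentParams,
) -> bool:
    """True iff the alignment reaches an end of either map.

    "Reaches" allows ``end_tolerance_fragments`` unaligned fragments
    between the alignment and the map end.  Only end-anchored
    alignments are usable as bridging evidence for megascaffolding.
    """
    tol = params.end_tolerance_fragments
    m = scaffold_map.n_fragments
    n = optical_map.n_fragments
    return (
        aln.scaffold_start_frag <= tol
        or m - aln.scaffold_end_frag <= tol
        or aln.optical_offset_start <= tol
        or n - aln.optical_offset_end <= tol
    )


def align_all(
    scaffold_maps,
    optical_maps,
    params: AlignmentParams | None = None,
    min_frag: int = 400,
    min_internal: int = 3,
) -> list[MapAlignment]:
    """Align every qualifying scaffold map against every optical map.

    Scaffold maps are first passed through the qualification filter
    (``min_internal`` internal fragments of at least ``min_frag`` bp);
    sub-threshold fragments are merged before alignment, mirroring the
    optical resolution limit.  For each (scaffold, optical) pair the
    best alignment over both orientations is kept if it scores at least
    ``params.min_score``.  Output order is deterministic: scaffold id,
    then score descending, then optical map id.
    """
    from .digest import qualify_map

    if params is None:
        params = AlignmentParams()
    alignments: list[MapAlignment] = []
    for smap in scaffold_maps:
        qual = qualify_map(smap, min_frag=min_frag, min_internal=min_internal)
        if not qual.qualifies:
            continue
        filtered = replace(qual.filtered_map, id=smap.id)
        for omap in optical_maps:
            aln = align_fit(filtered, omap, params)
            if aln is not None:
                alignments.append(aln)
    alignments.sort(key=lambda a: (a.scaffold_map_id, -a.score, a.optical_map_id))
    return alignments
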