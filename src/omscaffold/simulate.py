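"""Synthetic genomes, optical maps, scaffold sets and annotations.

The generator produces a random genome with restriction sites planted
at exponentially distributed spacings (~14 kb mean, the resolution
scale of a SwaI optical map of a bird-sized genome), measures it into
optical map contigs with the standard error model (multiplicative
lognormal sizing noise, Bernoulli missing cuts, Poisson false cuts),
tiles it into scaffolds with internal N-gaps and random orientations,
plants chimeric misjoins between scaffolds from different map contigs,
and scatters gene/exon annotations.  Every stochastic step draws from
one seeded NumPy PCG64 generator, so a given seed reproduces the
dataset bit for bit.

Ground truth records the planted structure — true intervals,
orientations, map contigs of origin, adjacencies and chimera flags —
so scaffolding output can be scored for join precision/recall and
chimera detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digest import RestrictionMap, SequenceRecord, digest, qualify_map

__all__ = [
    "SimulationConfig",
    "ScaffoldTruth",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_optical_maps",
    "simulate_assembly",
    "simulate_annotation",
    "simulate_dataset",
    "JoinEval",
    "ChimeraEval",
    "evaluate_joins",
    "evaluate_chimeras",
    "truth_eval",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Lengths in bp, probabilities as fractions.  ``false_cut_rate`` is
    cuts per bp; ``n_gap_rate`` is N-gaps per scaffold bp.  The seed is
    mandatory: all randomness flows from it.
    """

    seed: int
    genome_length: int = 10_000_000
    mean_site_spacing: int = 14_000
    sizing_cv: float = 0.03
    missing_cut_prob: float = 0.10
    false_cut_rate: float = 1e-5
    n_map_contigs: int = 8
    scaffold_length_mean: int = 75_000
    scaffold_length_sd: int = 15_000
    min_scaffold_length: int = 10_000
    inter_scaffold_gap_mean: int = 5_000
    n_gap_rate: float = 1e-5
    n_gap_mean: int = 2_000
    chimera_rate: float = 0.05
    chimera_min_fragments: int = 9
    n_genes: int = 100
    enzyme_site: str = "ATTTAAAT"

    def __post_init__(self) -> None:
        for name in ("missing_cut_prob", "chimera_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("genome_length", "mean_site_spacing", "scaffold_length_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ScaffoldTruth:
    """Planted provenance of one scaffold.

    ``intervals`` holds (genome_start, genome_end, orientation) for
    each constituent segment — one for normal scaffolds, two from
    different map contigs for planted chimeras.  Orientation "reverse"
    means the stored sequence is the reverse complement of the genome
    segment.  ``qualifies`` is the fragment-qualification status of the
    scaffold's own digest under the default filter.
    """

    intervals: list[tuple[int, int, str]]
    map_ids: list[str]
    is_chimeric: bool
    qualifies: bool


@dataclass
class GroundTruth:
    site_positions: list[int]
    map_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    scaffolds: dict[str, ScaffoldTruth] = field(default_factory=dict)
    #: genome-ordered pairs of non-chimeric scaffolds on the same map contig
    adjacencies: list[tuple[str, str]] = field(default_factory=list)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SequenceRecord, list[int]]:
    """Random genome with restriction sites at exponential spacings.

    The site (SwaI's palindrome by default) is written over the random
    background at spacings drawn from Exponential(mean_site_spacing);
    background occurrences arising by chance are left in place.  The
    returned site list is the actual cut-position list of the final
    sequence, so a digest recovers it exactly.
    """
    if rng is None:
        rng = config.rng()
    L = config.genome_length
    arr = _BASES[rng.integers(0, 4, size=L)]
    site = np.frombuffer(config.enzyme_site.encode(), dtype=np.uint8)
    w = len(site)
    # random background already contains the (palindromic) site at rate
    # 4^-w per position; thin the planted rate so the *total* cut
    # density comes out at one per mean_site_spacing
    background_rate = 0.25**w
    planted_rate = max(1e-9, 1.0 / config.mean_site_spacing - background_rate)
    pos = 0
    while True:
        gap = max(w, int(round(rng.exponential(1.0 / planted_rate))))
        pos += gap
        if pos + w >= L:
            break
        arr[pos : pos + w] = site
    genome = SequenceRecord("genome", arr.tobytes().decode("ascii"))
    from .digest import EnzymeSpec, find_sites

    enzyme = EnzymeSpec(recognition_site=config.enzyme_site, cut_offset=w // 2)
    sites = find_sites(genome, enzyme)
    return genome, sites


def _lognormal_factors(rng, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_optical_maps(
    genome_length: int,
    site_positions: list[int],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RestrictionMap], dict[str, tuple[int, int]]]:
    """Measure the true map into noisy optical map contigs.

    The genome is partitioned into ``n_map_contigs`` contiguous contigs
    with boundaries snapped to true cut sites.  Within each contig,
    interior cuts are dropped with ``missing_cut_prob`` (merging their
    fragments), false cuts are inserted as a Poisson process along the
    span, and every resulting fragment is scaled by lognormal noise of
    coefficient of variation ``sizing_cv``.  With all noise parameters
    zero the optical maps equal the in silico maps fragment for
    fragment.
    """
    if rng is None:
        rng = config.rng()
    L = genome_length
    sites = np.asarray(site_positions)
    n = config.n_map_contigs
    # boundaries near equal bp quantiles, snapped to true cuts
    bounds = [0]
    for i in range(1, n):
        target = L * i / n + rng.uniform(-0.05, 0.05) * L / n
        snapped = int(sites[np.argmin(np.abs(sites - target))]) if len(sites) else int(target)
        if snapped <= bounds[-1]:
            snapped = bounds[-1] + 1
        bounds.append(snapped)
    bounds.append(L)

    maps = []
    intervals = {}
    for i in range(n):
        start, end = bounds[i], bounds[i + 1]
        mid = f"om_{i:03d}"
        intervals[mid] = (start, end)
        inner = sites[(sites > start) & (sites < end)]
        cuts = [start] + [int(c) for c in inner] + [end]
        frags = np.diff(cuts).astype(float)

        # missing cuts: drop interior boundaries, merging neighbours
        if config.missing_cut_prob > 0 and len(frags) > 1:
            keep = rng.random(len(frags) - 1) >= config.missing_cut_prob
            merged = []
            acc = frags[0]
            for j, k in enumerate(keep):
                if k:
                    merged.append(acc)
                    acc = frags[j + 1]
                else:
                    acc += frags[j + 1]
            merged.append(acc)
            frags = np.array(merged)

        # false cuts: Poisson along the span, each splitting a fragment
        span = end - start
        n_false = rng.poisson(config.false_cut_rate * span)
        if n_false > 0:
            offsets = np.sort(rng.uniform(0, span, size=n_false))
            edges = np.concatenate([[0.0], np.cumsum(frags)])
            pieces = np.sort(np.concatenate([edges, offsets]))
            frags = np.diff(np.unique(pieces))

        frags = frags * _lognormal_factors(rng, len(frags), config.sizing_cv)
        frags_bp = [max(1, int(round(f))) for f in frags]
        maps.append(RestrictionMap(id=mid, source="optical", fragments=frags_bp))
    return maps, intervals


def _primary_map(interval: tuple[int, int], map_intervals) -> str:
    """Map contig holding the largest share of the interval."""
    s, e = interval
    best_id, best_ov = None, -1
    for mid, (ms, me) in map_intervals.items():
        ov = min(e, me) - max(s, ms)
        if ov > best_ov:
            best_id, best_ov = mid, ov
    return best_id


def simulate_assembly(
    genome: SequenceRecord,
    map_intervals: dict[str, tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Tile the genome into scaffolds and plant chimeric misjoins.

    Scaffold lengths are Normal(mean, sd) clipped below; neighbouring
    scaffolds are separated by unsampled genome of exponential mean
    ``inter_scaffold_gap_mean``.  Each scaffold is stored in a random
    orientation and receives Poisson(n_gap_rate * length) internal
    N-gaps whose lengths are exponential with mean ``n_gap_mean`` (the
    underlying bases are replaced, preserving length).  A
    ``chimera_rate`` fraction of the final scaffold set is chimeric:
    two scaffolds from different map contigs concatenated, emulating a
    misjoin between unrelated regions.  Chimera parts are drawn from
    scaffolds that qualify and carry at least
    ``chimera_min_fragments`` resolvable fragments: each part of a
    planted misjoin must be independently alignable, since a misjoin
    between stretches invisible to the optical map is undetectable by
    construction and outside the method's domain.
    """
    if rng is None:
        rng = config.rng()
    if config.chimera_rate > 0 and config.n_map_contigs < 2:
        raise ValueError("chimeras need at least two map contigs")
    L = len(genome)
    seq = genome.sequence

    # tiling
    segments: list[tuple[int, int]] = []
    pos = 0
    while pos < L:
        length = int(round(rng.normal(config.scaffold_length_mean, config.scaffold_length_sd)))
        length = max(config.min_scaffold_length, length)
        end = min(L, pos + length)
        if end - pos >= config.min_scaffold_length:
            segments.append((pos, end))
        pos = end + max(0, int(round(rng.exponential(config.inter_scaffold_gap_mean))))

    records: list[SequenceRecord] = []
    truths: list[ScaffoldTruth] = []
    frag_counts: list[int] = []
    for idx, (s, e) in enumerate(segments):
        body = seq[s:e]
        # internal N-gaps
        n_gaps = rng.poisson(config.n_gap_rate * len(body))
        if n_gaps > 0:
            chars = list(body)
            for _ in range(n_gaps):
                glen = max(50, int(round(rng.exponential(config.n_gap_mean))))
                if glen >= len(body) - 200:
                    continue
                gs = int(rng.integers(100, len(body) - glen - 100))
                chars[gs : gs + glen] = "N" * glen
            body = "".join(chars)
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        if orientation == "reverse":
            body = body.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        rec = SequenceRecord(f"scf_{idx:04d}", body)
        qresult = qualify_map(digest(rec))
        qual = qresult.qualifies
        frag_counts.append(qresult.filtered_map.n_fragments)
        records.append(rec)
        truths.append(
            ScaffoldTruth(
                intervals=[(s, e, orientation)],
                map_ids=[_primary_map((s, e), map_intervals)],
                is_chimeric=False,
                qualifies=qual,
            )
        )

    # plant chimeras among well-mapped scaffolds from different map contigs
    n0 = len(records)
    n_chim = int(round(config.chimera_rate * n0 / (1.0 + config.chimera_rate)))
    candidates = [
        i
        for i, t in enumerate(truths)
        if t.qualifies and frag_counts[i] >= config.chimera_min_fragments
    ]
    order = list(rng.permutation(len(candidates)))
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for oi in order:
        if len(pairs) >= n_chim:
            break
        i = candidates[oi]
        if i in used:
            continue
        for oj in order:
            j = candidates[oj]
            if j in used or j == i or truths[j].map_ids == truths[i].map_ids:
                continue
            pairs.append((i, j))
            used.update((i, j))
            break

    chim_records: list[SequenceRecord] = []
    chim_truths: list[ScaffoldTruth] = []
    for k, (i, j) in enumerate(pairs):
        body = records[i].sequence + records[j].sequence
        rec = SequenceRecord(f"chim_{k:02d}", body)
        chim_records.append(rec)
        chim_truths.append(
            ScaffoldTruth(
                intervals=truths[i].intervals + truths[j].intervals,
                map_ids=truths[i].map_ids + truths[j].map_ids,
                is_chimeric=True,
                qualifies=qualify_map(digest(rec)).qualifies,
            )
        )

    keep = [k for k in range(n0) if k not in used]
    final_records = [records[k] for k in keep] + chim_records
    final_truths = [truths[k] for k in keep] + chim_truths

    truth = GroundTruth(site_positions=[], map_intervals=dict(map_intervals))
    for rec, st in zip(final_records, final_truths):
        truth.scaffolds[rec.id] = st

    # adjacencies: consecutive surviving non-chimeric scaffolds per map contig
    by_map: dict[str, list[tuple[int, str]]] = {}
    for rec, st in zip(final_records, final_truths):
        if st.is_chimeric:
            continue
        by_map.setdefault(st.map_ids[0], []).append((st.intervals[0][0], rec.id))
    for mid in sorted(by_map):
        ordered = [sid for _, sid in sorted(by_map[mid])]
        truth.adjacencies.extend(zip(ordered, ordered[1:]))
    return final_records, truth


def simulate_annotation(
    scaffolds: list[SequenceRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Scatter non-overlapping genes (1-10 exons each) over scaffolds.

    Returns (genes, exons) where genes are (gene_id, scaffold_id,
    start, end, strand) and exons are (exon_id, gene_id, scaffold_id,
    start, end), all 0-based half-open.
    """
    if rng is None:
        rng = config.rng()
    if config.n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    min_gene, max_gene = 2_000, 15_000
    lengths = np.array([len(s) for s in scaffolds])
    if lengths.sum() < config.n_genes * min_gene * 2:
        raise ValueError("genome too short for requested gene count")
    weights = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {}
    genes = []
    exons = []
    attempts = 0
    while len(genes) < config.n_genes and attempts < config.n_genes * 100:
        attempts += 1
        si = rng.choice(len(scaffolds), p=weights)
        rec = scaffolds[si]
        glen = int(rng.integers(min_gene, max_gene))
        if glen + 2 >= len(rec):
            continue
        start = int(rng.integers(0, len(rec) - glen))
        end = start + glen
        clashes = [
            (s, e) for s, e in occupied.get(rec.id, []) if s < end and e > start
        ]
        if clashes:
            continue
        occupied.setdefault(rec.id, []).append((start, end))
        gid = f"gene_{len(genes):04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((gid, rec.id, start, end, strand))
        n_exons = int(rng.integers(1, 11))
        chunk = glen // n_exons
        for x in range(n_exons):
            clo = start + x * chunk
            elen = int(rng.integers(30, max(31, min(300, chunk))))
            eoff = int(rng.integers(0, max(1, chunk - elen)))
            exons.append((f"{gid}.e{x}", gid, rec.id, clo + eoff, clo + eoff + elen))
    if len(genes) < config.n_genes:
        raise ValueError("could not place all genes without overlap")
    return genes, exons


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SequenceRecord
    genome_map: RestrictionMap
    optical_maps: list[RestrictionMap]
    scaffolds: list[SequenceRecord]
    truth: GroundTruth
    genes: list[tuple]
    exons: list[tuple]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset (genome, maps, scaffolds, annotation)."""
    rng = config.rng()
    genome, sites = simulate_genome(config, rng)
    optical_maps, map_intervals = simulate_optical_maps(
        len(genome), sites, config, rng
    )
    scaffolds, truth = simulate_assembly(genome, map_intervals, config, rng)
    truth.site_positions = sites
    genes, exons = simulate_annotation(scaffolds, config, rng)
    return SimulatedDataset(
        config=config,
        genome=genome,
        genome_map=digest(genome),
        optical_maps=optical_maps,
        scaffolds=scaffolds,
        truth=truth,
        genes=genes,
        exons=exons,
    )


# ---------------------------------------------------------------------------
# evaluation against ground truth


@dataclass
class JoinEval:
    n_predicted: int
    n_correct: int
    precision: float
    n_true_pairs: int
    n_recovered: int
    recall: float


@dataclass
class ChimeraEval:
    n_planted: int
    n_detected: int
    n_false: int
    n_straddlers_flagged: int
    n_scaffolds: int
    precision: float
    recall: float

    @property
    def false_per_scaffold(self) -> float:
        return self.n_false / self.n_scaffolds if self.n_scaffolds else 0.0


def _relevant_interval(st: ScaffoldTruth, map_id: str):
    """The scaffold's true interval lying on ``map_id`` (None if absent)."""
    for interval, mid in zip(st.intervals, st.map_ids):
        if mid == map_id:
            return interval
    return None


def _join_is_correct(a, oa, b, ob, map_id: str, truth: GroundTruth) -> bool:
    """Order/orientation consistency of one join on its bridge's map.

    For a chimeric participant the interval on the bridge's map contig
    is the one the placement was driven by; a join is judged on those
    relevant intervals.  (Whether the chimera itself was caught is the
    detection stage's score, not the bridging stage's.)
    """
    ta = truth.scaffolds.get(a)
    tb = truth.scaffolds.get(b)
    if ta is None or tb is None:
        raise KeyError(f"scaffold {a if ta is None else b!r} missing from truth")
    ia = _relevant_interval(ta, map_id)
    ib = _relevant_interval(tb, map_id)
    if ia is None or ib is None:
        return False
    (sa, ea, ra) = ia
    (sb, eb, rb) = ib
    return ea <= sb and oa == ra and ob == rb


def evaluate_joins(
    megascaffolds,
    truth: GroundTruth,
    placed: dict[str, str] | None = None,
) -> JoinEval:
    """Score predicted joins against the planted order.

    A predicted join (consecutive megascaffold components) is correct
    when both scaffolds are non-chimeric, come from the same map
    contig, appear in genome order and carry their true orientations.
    Recall is measured over true adjacent pairs; when ``placed`` maps
    scaffold ids to their assigned optical map, the denominator is
    restricted to pairs whose two members were both placed on their
    true map contig — i.e. recall of the joining stage given the
    placements, with alignment success assessed separately.
    """
    predicted: list[tuple[str, str, str, str, str]] = []
    joined_pairs: dict[tuple[str, str], tuple[str, str, str]] = {}
    for mega in megascaffolds:
        comps = mega.components
        mid = mega.source_optical_map
        for (a, oa, _), (b, ob, _) in zip(comps, comps[1:]):
            predicted.append((a, oa, b, ob, mid))
            joined_pairs[(a, b)] = (oa, ob, mid)

    n_correct = sum(
        _join_is_correct(a, oa, b, ob, mid, truth) for a, oa, b, ob, mid in predicted
    )
    precision = n_correct / len(predicted) if predicted else 1.0

    pairs = truth.adjacencies
    if placed is not None:
        pairs = [
            (a, b)
            for a, b in pairs
            if placed.get(a) == truth.scaffolds[a].map_ids[0]
            and placed.get(b) == truth.scaffolds[b].map_ids[0]
        ]
    n_recovered = 0
    for a, b in pairs:
        if (a, b) in joined_pairs:
            oa, ob, mid = joined_pairs[(a, b)]
            if _join_is_correct(a, oa, b, ob, mid, truth):
                n_recovered += 1
    recall = n_recovered / len(pairs) if pairs else 1.0
    return JoinEval(
        n_predicted=len(predicted),
        n_correct=n_correct,
        precision=precision,
        n_true_pairs=len(pairs),
        n_recovered=n_recovered,
        recall=recall,
    )


def evaluate_chimeras(
    calls, truth: GroundTruth, boundary_margin: int = 10_000
) -> ChimeraEval:
    """Score chimera calls against planted misjoins.

    A non-chimeric scaffold genuinely spanning a map-contig boundary
    (at least ``boundary_margin`` bp on each side) really is aligned
    to two optical map contigs; flagging it is an artefact of map
    contig ends, not a detection error, so such calls are tallied
    separately rather than as false positives.
    """
    for call in calls:
        if call.scaffold_id not in truth.scaffolds:
            raise KeyError(f"scaffold {call.scaffold_id!r} missing from truth")
    straddlers = set()
    for sid, st in truth.scaffolds.items():
        if st.is_chimeric:
            continue
        s, e = st.intervals[0][0], st.intervals[0][1]
        deep = sum(
            1
            for ms, me in truth.map_intervals.values()
            if min(e, me) - max(s, ms) >= boundary_margin
        )
        if deep >= 2:
            straddlers.add(sid)
    flagged = {c.scaffold_id for c in calls if c.is_chimeric}
    planted = {sid for sid, st in truth.scaffolds.items() if st.is_chimeric}
    tp = len(flagged & planted)
    fp = len(flagged - planted - straddlers)
    return ChimeraEval(
        n_planted=len(planted),
        n_detected=tp,
        n_false=fp,
        n_straddlers_flagged=len(flagged & straddlers),
        n_scaffolds=len(truth.scaffolds),
        precision=tp / len(flagged - straddlers) if flagged - straddlers else 1.0,
        recall=tp / len(planted) if planted else 1.0,
    )


def truth_eval(predicted, truth: GroundTruth, placed=None) -> tuple[float, float]:
    """(precision, recall) for megascaffolds or chimera calls."""
    items = list(predicted)
    if items and hasattr(items[0], "components"):
        ev = evaluate_joins(items, truth, placed)
        return ev.precision, ev.recall
    ev = evaluate_chimeras(items, truth)
    return ev.precision, ev.recall
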