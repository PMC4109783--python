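"""Readers and writers for the formats the toolkit exchanges.

FASTA goes through Biopython.  Optical maps travel as a simple TSV,
one map per line::

    map_id <TAB> n_fragments <TAB> f1 <TAB> f2 ... fn

with fragment sizes in kb at three decimals; they are converted to
integer bp on read so both map kinds share units.  Alignments are a
flat TSV.  Gene annotations are GFF3 (1-based inclusive on disk,
0-based half-open in memory).
"""

from __future__ import annotations

import json
from dataclasses import asdict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .align import MapAlignment
from .digest import RestrictionMap, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_optical_tsv",
    "write_optical_tsv",
    "write_alignment_tsv",
    "read_alignment_tsv",
    "read_gff3_genes",
    "write_gff3",
    "write_gaps_bed",
    "write_truth_json",
]


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-record, wrapped, case-insensitive) FASTA file."""
    return [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path, width: int = 60) -> None:
    """Write (id, sequence) pairs or SequenceRecords as wrapped FASTA."""
    bio = []
    for rec in records:
        if isinstance(rec, SequenceRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        bio.append(BioSeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_optical_tsv(maps, path) -> None:
    """Write restriction maps with fragment sizes in kb at 3 decimals."""
    with open(path, "w") as fh:
        for m in maps:
            frags = "\t".join(f"{f / 1000.0:.3f}" for f in m.fragments)
            fh.write(f"{m.id}\t{m.n_fragments}\t{frags}\n")


def read_optical_tsv(path, source: str = "optical") -> list[RestrictionMap]:
    """Read the optical map TSV; kb values become integer bp."""
    maps = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            mid, n = fields[0], int(fields[1])
            frags = [int(round(float(f) * 1000)) for f in fields[2:] if f]
            if len(frags) != n:
                raise ValueError(
                    f"map {mid!r}: declared {n} fragments, found {len(frags)}"
                )
            maps.append(RestrictionMap(id=mid, source=source, fragments=frags))
    return maps


_ALN_COLUMNS = [
    "scaffold_id",
    "optical_id",
    "orientation",
    "score",
    "scaf_start_frag",
    "scaf_end_frag",
    "opt_start_frag",
    "opt_end_frag",
    "overhang_left_bp",
    "overhang_right_bp",
    "end_anchored",
]


def write_alignment_tsv(alignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for a in alignments:
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        a.scaffold_map_id,
                        a.optical_map_id,
                        a.orientation,
                        f"{a.score:.4f}",
                        a.scaffold_start_frag,
                        a.scaffold_end_frag,
                        a.optical_offset_start,
                        a.optical_offset_end,
                        a.scaffold_overhang_left,
                        a.scaffold_overhang_right,
                        int(a.end_anchored),
                    ]
                )
                + "\n"
            )


def read_alignment_tsv(path) -> list[dict]:
    """Read the alignment TSV back as a list of dicts (typed columns)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            row["score"] = float(row["score"])
            for key in (
                "scaf_start_frag",
                "scaf_end_frag",
                "opt_start_frag",
                "opt_end_frag",
                "overhang_left_bp",
                "overhang_right_bp",
            ):
                row[key] = int(row[key])
            row["end_anchored"] = bool(int(row["end_anchored"]))
            rows.append(row)
    return rows


def read_gff3_genes(path):
    """Read gene and exon features from GFF3.

    Returns (genes, exons): genes as (gene_id, scaffold_id, start, end,
    strand) and exons as (exon_id, parent_gene_id, scaffold_id, start,
    end), converted to 0-based half-open coordinates.
    """
    genes, exons = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            lo, hi = int(start) - 1, int(end)
            if ftype == "gene":
                genes.append((attr.get("ID", seqid), seqid, lo, hi, strand))
            elif ftype == "exon":
                exons.append(
                    (
                        attr.get("ID", ""),
                        attr.get("Parent", ""),
                        seqid,
                        lo,
                        hi,
                    )
                )
    return genes, exons


def write_gff3(genes, exons, path) -> None:
    """Write gene/exon tuples (0-based half-open) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, sid, start, end, strand in genes:
            fh.write(
                f"{sid}\tomscaffold\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}\n"
            )
        for eid, gid, sid, start, end in exons:
            fh.write(
                f"{sid}\tomscaffold\texon\t{start + 1}\t{end}\t.\t.\t.\t"
                f"ID={eid};Parent={gid}\n"
            )


def write_gaps_bed(gaps_by_scaffold: dict[str, list[tuple[int, int]]], path) -> None:
    """Write N-run gaps as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for sid in sorted(gaps_by_scaffold):
            for s, e in gaps_by_scaffold[sid]:
                fh.write(f"{sid}\t{s}\t{e}\tgap\n")


def write_truth_json(truth, path) -> None:
    """Serialise a GroundTruth to JSON (documented schema).

    Keys: site_positions, map_intervals, scaffolds (intervals,
    map_ids, is_chimeric, qualifies) and adjacencies.
    """
    payload = {
        "site_positions": [int(p) for p in truth.site_positions],
        "map_intervals": {k: list(v) for k, v in truth.map_intervals.items()},
        "scaffolds": {
            sid: asdict(st) for sid, st in truth.scaffolds.items()
        },
        "adjacencies": [list(p) for p in truth.adjacencies],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
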