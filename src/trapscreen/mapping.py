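"""Insertion-site mapping for gene-trap screens.

Turns flanking-sequence reads (or externally produced SAM alignments) into
deduplicated, orientation-annotated proviral insertion sites. The analysis
keeps only reads that align uniquely with zero mismatches, collapses them to
junction coordinates, and annotates each junction against gene models:
an insertion whose provirus transcribes in the same direction as the host
gene (sense orientation) is the inactivating configuration in a haploid
gene-trap screen.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open internally. The insertion *position*
is the index of the first genomic base 3' of the LTR-genome junction. Because
flanking reads start at the junction by construction of the inverse PCR, the
junction base of a plus-strand read is its leftmost aligned base and the
junction base of a minus-strand read is its rightmost aligned base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("trapscreen")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A named genomic interval with strand; the unit insertions are
    annotated against. ``start``/``end`` are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """One full-length placement of a read on the reference.

    ``n_mismatches`` is ``None`` when the aligner did not report it (for a
    SAM record lacking the NM tag); the strict filter discards such reads.
    ``n_placements`` counts equally good full-length placements; ``span`` is
    the reference-aligned length, needed to locate the junction base of a
    minus-strand read.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    n_mismatches: int | None
    n_placements: int
    span: int


@dataclass(frozen=True)
class InsertionSite:
    """A deduplicated proviral integration locus.

    ``position`` is the 0-based junction base, ``strand`` the provirus
    orientation, ``read_count`` the number of supporting filtered reads.
    ``orientation`` is 'sense', 'antisense' or 'intergenic'; it is
    'intergenic' exactly when ``gene_id`` is empty.
    """

    chrom: str
    position: int
    strand: str
    read_count: int
    gene_id: str = ""
    orientation: str = "intergenic"

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if (self.orientation == "intergenic") != (self.gene_id == ""):
            raise ValueError("orientation is 'intergenic' iff gene_id is empty")


@dataclass
class FilterStats:
    """Read accounting for the unique/zero-mismatch filter."""

    n_input: int = 0
    n_kept: int = 0
    n_unknown_mismatches: int = 0
    n_multi_placement: int = 0
    n_mismatched: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Alignment: built-in exact matcher (desk scale) and SAM ingest
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _best_hamming(genome_arr: np.ndarray, read: str) -> tuple[int, int, int]:
    """Minimum-Hamming placements of ``read`` on one strand.

    Returns (min_mismatches, first_best_offset, n_best).
    """
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(genome_arr, len(read_arr))
    mm = (windows != read_arr).sum(axis=1)
    best = int(mm.min())
    idx = np.flatnonzero(mm == best)
    return best, int(idx[0]), int(idx.size)


def align_reads(
    reads: Iterable[tuple[str, str]],
    genome: str,
    chrom: str = "chr1",
) -> list[AlignedRead]:
    """Search each read full-length against both strands of ``genome``.

    An exact-match substring search drives the common case; when a read has
    no exact placement, the best placement's mismatch count is reported so
    the downstream filter can account for it. Reads are ``(read_id, sequence)``
    pairs (``str(record.seq)`` of a Biopython record works). Deterministic:
    ties resolve to the leftmost placement, plus strand before minus.
    """
    if not genome:
        raise ValueError("empty genome")
    genome = genome.upper()
    genome_rc = reverse_complement(genome)
    genome_arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    genome_rc_arr = np.frombuffer(genome_rc.encode(), dtype=np.uint8)
    glen = len(genome)

    out: list[AlignedRead] = []
    for read_id, seq in reads:
        if not seq:
            raise ValueError(f"empty read {read_id!r}")
        if len(seq) > glen:
            raise ValueError(f"read {read_id!r} longer than genome")
        seq = seq.upper()
        L = len(seq)
        # A minus-strand placement of the read at genomic offset p corresponds
        # to an occurrence of the read in the reverse-complemented genome at
        # offset glen - L - p.
        fwd = _find_all(genome, seq)
        rev = [glen - L - i for i in _find_all(genome_rc, seq)]
        n_exact = len(fwd) + len(rev)
        if n_exact:
            if fwd:
                pos, strand = min(fwd), "+"
            else:
                pos, strand = min(rev), "-"
            out.append(AlignedRead(read_id, chrom, pos, strand, 0, n_exact, L))
            continue
        mm_f, pos_f, n_f = _best_hamming(genome_arr, seq)
        mm_r, off_r, n_r = _best_hamming(genome_rc_arr, seq)
        pos_r = glen - L - off_r
        if mm_f <= mm_r:
            best, pos, strand = mm_f, pos_f, "+"
        else:
            best, pos, strand = mm_r, pos_r, "-"
        n_best = (n_f if mm_f == best else 0) + (n_r if mm_r == best else 0)
        out.append(AlignedRead(read_id, chrom, pos, strand, best, n_best, L))
    return out


def read_alignments(sam_path: str | Path) -> tuple[list[AlignedRead], int]:
    """Load AlignedReads from a SAM file produced by any external aligner.

    Mismatch counts come from the NM tag (absent tag -> ``None``, which the
    strict filter discards: unknown is not zero). Uniqueness is approximated
    as MAPQ > 0 and no secondary/supplementary record sharing the read id.
    Unmapped records are dropped; their count is returned and logged.
    """
    sam_path = str(sam_path)
    multi: set[str] = set()
    with pysam.AlignmentFile(sam_path, "r", check_sq=True) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                multi.add(aln.query_name)

    out: list[AlignedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=True) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            unique = aln.mapping_quality > 0 and aln.query_name not in multi
            out.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    pos=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    n_mismatches=nm,
                    n_placements=1 if unique else 2,
                    span=aln.reference_length or (aln.query_length or 0),
                )
            )
    if n_unmapped:
        logger.info("read_alignments: dropped %d unmapped records", n_unmapped)
    return out, n_unmapped


# ---------------------------------------------------------------------------
# Filter -> collapse -> annotate
# ---------------------------------------------------------------------------


def filter_alignments(
    alignments: Sequence[AlignedRead],
) -> tuple[list[AlignedRead], FilterStats]:
    """Keep exactly the reads that aligned uniquely with zero mismatches.

    Discards are counted by first applicable reason: unknown mismatch count,
    then multiple placements, then nonzero mismatches.
    """
    stats = FilterStats(n_input=len(alignments))
    kept: list[AlignedRead] = []
    for aln in alignments:
        if aln.n_mismatches is None:
            stats.n_unknown_mismatches += 1
        elif aln.n_placements > 1:
            stats.n_multi_placement += 1
        elif aln.n_mismatches > 0:
            stats.n_mismatched += 1
        else:
            kept.append(aln)
    stats.n_kept = len(kept)
    return kept, stats


def junction_position(aln: AlignedRead) -> int:
    """Junction base of an aligned flanking read: leftmost aligned base on
    the plus strand, rightmost on the minus strand."""
    return aln.pos if aln.strand == "+" else aln.pos + aln.span - 1


def collapse_to_sites(alignments: Sequence[AlignedRead]) -> list[InsertionSite]:
    """Group filtered reads by (chrom, junction, strand) into unique sites.

    ``read_count`` is the group size; output is sorted by coordinate.
    """
    groups: dict[tuple[str, int, str], int] = {}
    for aln in alignments:
        key = (aln.chrom, junction_position(aln), aln.strand)
        groups[key] = groups.get(key, 0) + 1
    return [
        InsertionSite(chrom=c, position=p, strand=s, read_count=n)
        for (c, p, s), n in sorted(groups.items())
    ]


def annotate_orientation(
    sites: Sequence[InsertionSite],
    genes: Sequence[GeneModel],
) -> tuple[list[InsertionSite], int]:
    """Fill ``gene_id`` and ``orientation`` for each site.

    A site inside [start, end) of a gene is sense if the provirus strand
    equals the gene strand, else antisense; a site outside all genes is
    intergenic. A site overlapping several genes yields one record per gene.
    Sites on a chromosome absent from the gene annotation space are annotated
    intergenic; their count is returned and logged.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.start)

    out: list[InsertionSite] = []
    n_unknown_chrom = 0
    for site in sites:
        if site.chrom not in by_chrom:
            n_unknown_chrom += 1
            out.append(
                InsertionSite(site.chrom, site.position, site.strand, site.read_count)
            )
            continue
        hits = [
            g
            for g in by_chrom[site.chrom]
            if g.start <= site.position < g.end
        ]
        if not hits:
            out.append(
                InsertionSite(site.chrom, site.position, site.strand, site.read_count)
            )
            continue
        for g in hits:
            orientation = "sense" if site.strand == g.strand else "antisense"
            out.append(
                InsertionSite(
                    site.chrom,
                    site.position,
                    site.strand,
                    site.read_count,
                    gene_id=g.gene_id,
                    orientation=orientation,
                )
            )
    if n_unknown_chrom:
        logger.info(
            "annotate_orientation: %d sites on chromosomes absent from the "
            "gene annotation",
            n_unknown_chrom,
        )
    return out, n_unknown_chrom


# ---------------------------------------------------------------------------
# Format I/O: gene models (GTF/BED) and site tables (TSV/BED)
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chrom", "position", "strand", "read_count", "gene_id", "orientation"]


def sites_to_frame(sites: Sequence[InsertionSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.position, s.strand, s.read_count, s.gene_id, s.orientation) for s in sites],
        columns=SITE_COLUMNS,
    )


def frame_to_sites(df: pd.DataFrame) -> list[InsertionSite]:
    df = df.fillna({"gene_id": "", "orientation": "intergenic"})
    return [
        InsertionSite(
            chrom=str(r.chrom),
            position=int(r.position),
            strand=str(r.strand),
            read_count=int(r.read_count),
            gene_id=str(r.gene_id),
            orientation=str(r.orientation),
        )
        for r in df.itertuples(index=False)
    ]


def write_sites_tsv(sites: Sequence[InsertionSite], path: str | Path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        sites_to_frame(sites).to_csv(fh, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[InsertionSite]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return frame_to_sites(df)


def write_sites_bed(sites: Sequence[InsertionSite], path: str | Path) -> None:
    """BED6; name = gene_id|orientation, score = read_count."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.gene_id}|{s.orientation}" if s.gene_id else s.orientation
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{name}\t{s.read_count}\t{s.strand}\n"
            )


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """BED6, 0-based half-open: chrom, start, end, name, score, strand."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return genes


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """GTF 2.2 gene records (1-based inclusive, converted to 0-based
    half-open). Uses 'gene' features; falls back to the union of transcript
    features per gene_id when no gene feature is present."""
    spans: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("gene", "transcript"):
                continue
            gene_id = ""
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(None, 1)[1].strip().strip('"')
                    break
            if not gene_id:
                raise ValueError(f"GTF record without gene_id: {line.rstrip()}")
            s0, e0 = int(start) - 1, int(end)
            if gene_id not in spans:
                spans[gene_id] = [chrom, s0, e0, strand, feature == "gene"]
                order.append(gene_id)
            else:
                rec = spans[gene_id]
                if feature == "gene":
                    rec[1:3] = [s0, e0]
                    rec[4] = True
                elif not rec[4]:
                    rec[1] = min(rec[1], s0)
                    rec[2] = max(rec[2], e0)
    return [GeneModel(gid, *spans[gid][:4]) for gid in order]


def read_genes(path: str | Path) -> list[GeneModel]:
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return read_genes_gtf(path)
    return read_genes_bed(path)


def map_insertions(
    reads: Iterable[tuple[str, str]] | None,
    genome: str | None,
    genes: Sequence[GeneModel],
    sam_path: str | Path | None = None,
    chrom: str = "chr1",
) -> tuple[list[InsertionSite], FilterStats]:
    """Full mapping stage: align (or ingest SAM), filter, collapse, annotate."""
    if sam_path is not None:
        alignments, _ = read_alignments(sam_path)
    else:
        if reads is None or genome is None:
            raise ValueError("either sam_path or (reads, genome) must be given")
        alignments = align_reads(reads, genome, chrom=chrom)
    kept, stats = filter_alignments(alignments)
    sites = collapse_to_sites(kept)
    annotated, _ = annotate_orientation(sites, genes)
    return annotated, stats
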