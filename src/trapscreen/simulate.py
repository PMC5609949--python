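"""Synthetic data with controlled ground truth.

Two generators back the two analysis arms:

* a desk-scale haploid gene-trap screen — a random genome with non-overlapping
  gene models, a mutagenized library with one insertion per cell (the
  single-copy assumption of a near-haploid screen), drug selection that favours
  sense insertions in designated resistance genes, and junction-flanking reads
  with log-normal per-site read counts emulating clonal expansion and
  inverse-PCR amplification skew;
* median-effect dose-response plates — fraction-affected values drawn from
  fa/(1-fa) = (D/Dm)^m with optional noise on the logit scale, singly or in
  Loewe-additive combination with a known interaction multiplier.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mapping import GeneModel, reverse_complement

logger = logging.getLogger("trapscreen")

CHROM = "chr1"
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Parameters of the simulated resistance screen.

    Defaults describe a desk-scale analogue of a genome-wide screen: 20,000
    independently mutagenized cells over a 50-gene toy genome with one spiked
    resistance gene, near-certain survival for inactivating (sense) insertions
    in that gene and a 1-in-1000 background survival rate. Per-site read
    counts are log-normal (natural-log parameters), spanning several orders of
    magnitude as PCR/expansion-skewed insert counts do.
    """

    genome_length: int = 50_000
    n_genes: int = 50
    n_cells: int = 20_000
    resistance_genes: tuple[str, ...] = ("G000",)
    p_survive_resistant: float = 0.95
    p_survive_background: float = 1e-3
    readcount_log_mean: float = 4.0
    readcount_log_sd: float = 2.5
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.p_survive_background <= self.p_survive_resistant <= 1:
            raise ValueError(
                "need 0 <= p_survive_background <= p_survive_resistant <= 1"
            )
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")


@dataclass
class DoseResponseSimConfig:
    """Parameters of a simulated single-drug dose-response series.

    ``m`` is the median-effect slope (sigmoidicity), ``Dm`` the median-effect
    dose in µM, ``noise_sd`` the SD of additive Gaussian noise on the
    log-odds of the fraction affected. Triplicate wells are the default, as
    in standard viability assays.
    """

    m: float
    Dm: float
    doses: tuple[float, ...]
    replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.Dm <= 0:
            raise ValueError("m and Dm must be positive")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise ValueError("all doses must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Screen arm
# ---------------------------------------------------------------------------


def generate_genome(
    length: int, n_genes: int, seed: int
) -> tuple[str, list[GeneModel]]:
    """Random nucleotide sequence plus non-overlapping gene models.

    The genome is partitioned into equal slots, one gene per slot, each gene
    occupying 30-80% of its slot at a random offset with a random strand, so
    total gene coverage never exceeds 80% of the sequence. Requires
    ``length >= 50 * n_genes`` to pack genes of useful size.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes and length < 50 * n_genes:
        raise ValueError(
            f"cannot pack {n_genes} genes into {length} bases "
            f"(need length >= {50 * n_genes})"
        )
    rng = np.random.default_rng(seed)
    seq = bytes(BASES[rng.integers(0, 4, size=length)]).decode()
    genes: list[GeneModel] = []
    if n_genes:
        slot = length // n_genes
        width = len(str(n_genes - 1)) if n_genes > 1 else 1
        for i in range(n_genes):
            lo, hi = int(0.3 * slot), int(0.8 * slot)
            glen = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(0, slot - glen + 1))
            start = i * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"G{i:0{max(width, 3)}d}", CHROM, start, start + glen, strand)
            )
    return seq, genes


LIBRARY_COLUMNS = ["cell_id", "position", "strand", "gene_id", "orientation"]


def _annotate_positions(
    positions: np.ndarray, strands: np.ndarray, genes: Sequence[GeneModel]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gene/orientation lookup for non-overlapping genes."""
    gene_ids = np.full(positions.shape, "", dtype=object)
    orientation = np.full(positions.shape, "intergenic", dtype=object)
    if genes:
        ordered = sorted(genes, key=lambda g: g.start)
        starts = np.array([g.start for g in ordered])
        ends = np.array([g.end for g in ordered])
        idx = np.searchsorted(starts, positions, side="right") - 1
        inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        g_strands = np.array([g.strand for g in ordered], dtype=object)
        g_ids = np.array([g.gene_id for g in ordered], dtype=object)
        gene_ids[inside] = g_ids[idx[inside]]
        sense = inside & (strands == g_strands[np.clip(idx, 0, None)])
        orientation[inside] = "antisense"
        orientation[sense] = "sense"
    return gene_ids, orientation


def simulate_insertion_library(
    genome: str,
    genes: Sequence[GeneModel],
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """One gene-trap insertion per cell, uniform in position and provirus
    strand, annotated sense/antisense/intergenic against the gene models.

    The insertion position is the index of the first genomic base 3' of the
    LTR junction, 0-based.
    """
    if not genome:
        raise ValueError("empty genome")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    positions = rng.integers(0, len(genome), size=n_cells)
    strands = np.where(rng.random(n_cells) < 0.5, "+", "-").astype(object)
    gene_ids, orientation = _annotate_positions(positions, strands, genes)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "position": positions,
            "strand": strands,
            "gene_id": gene_ids,
            "orientation": orientation,
        }
    )


def simulate_selection(library: pd.DataFrame, config: ScreenSimConfig) -> pd.DataFrame:
    """Drug selection plus clonal expansion / inverse-PCR skew.

    A cell survives with ``p_survive_resistant`` when its insertion is
    sense-orientation inside a resistance gene, else with
    ``p_survive_background``. Each surviving site receives a log-normal read
    count rounded up to at least one read.
    """
    if library.empty:
        raise ValueError("empty insertion library")
    rng = np.random.default_rng(config.seed)
    resistant = (
        library["gene_id"].isin(config.resistance_genes).to_numpy()
        & (library["orientation"] == "sense").to_numpy()
    )
    p = np.where(resistant, config.p_survive_resistant, config.p_survive_background)
    survives = rng.random(len(library)) < p
    survivors = library.loc[survives].copy()
    counts = rng.lognormal(
        config.readcount_log_mean, config.readcount_log_sd, size=len(survivors)
    )
    survivors["read_count"] = np.maximum(1, np.ceil(counts)).astype(int)
    return survivors.reset_index(drop=True)


def generate_reads(
    survivors: pd.DataFrame,
    genome: str,
    read_length: int,
    mismatch_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], int]:
    """Junction-flanking reads for each surviving insertion site.

    Emits ``read_count`` copies of the genomic sequence immediately 3' of the
    junction on the provirus strand (reverse-complemented for minus-strand
    insertions), with independent per-base substitutions at
    ``mismatch_rate``. Read identifiers encode the true site
    (``ins_<position>_<p|m>_<copy>``) for round-trip testing. Sites too close
    to a sequence end for a full-length read are skipped with a warning;
    the skip count is returned.
    """
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    glen = len(genome)
    reads: list[tuple[str, str]] = []
    n_skipped = 0
    for row in survivors.itertuples(index=False):
        pos, strand, count = int(row.position), str(row.strand), int(row.read_count)
        if strand == "+":
            if pos + read_length > glen:
                n_skipped += 1
                logger.warning(
                    "generate_reads: skipping site %d%s too close to sequence end",
                    pos,
                    strand,
                )
                continue
            template = genome[pos : pos + read_length]
        else:
            if pos - read_length + 1 < 0:
                n_skipped += 1
                logger.warning(
                    "generate_reads: skipping site %d%s too close to sequence start",
                    pos,
                    strand,
                )
                continue
            template = reverse_complement(genome[pos - read_length + 1 : pos + 1])
        tag = "p" if strand == "+" else "m"
        for k in range(count):
            seq = template
            if mismatch_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                hit = np.flatnonzero(rng.random(read_length) < mismatch_rate)
                for i in hit:
                    choices = BASES[BASES != arr[i]]
                    arr[i] = choices[rng.integers(0, len(choices))]
                seq = bytes(arr).decode()
            reads.append((f"ins_{pos}_{tag}_{k}", seq))
    return reads, n_skipped


def write_fasta(genome: str, path: str | Path, chrom: str = CHROM) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Phred+33 FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    return str(next(SeqIO.parse(str(path), "fasta")).seq)


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_genes_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """GTF 2.2 gene features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\ttrapscreen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
            )


def library_to_sites(library: pd.DataFrame, genes: Sequence[GeneModel]):
    """Collapse per-cell insertion records directly into annotated
    InsertionSites, bypassing read generation and mapping.

    Cells sharing a junction (position, strand) merge into one site whose
    read_count sums their counts (1 per cell when no ``read_count`` column
    is present). This is the exact-sequencing limit of the full
    reads -> align -> filter -> collapse path.
    """
    from .mapping import InsertionSite, annotate_orientation

    df = library.copy()
    if "read_count" not in df.columns:
        df["read_count"] = 1
    grouped = df.groupby(["position", "strand"], as_index=False)["read_count"].sum()
    sites = [
        InsertionSite(CHROM, int(r.position), str(r.strand), int(r.read_count))
        for r in grouped.itertuples(index=False)
    ]
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    annotated, _ = annotate_orientation(sites, genes)
    return annotated


# ---------------------------------------------------------------------------
# Dose-response arm
# ---------------------------------------------------------------------------


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """Fraction affected per (dose, replicate) from the median-effect law.

    logit(fa) = m (ln D - ln Dm) + eps, eps ~ Normal(0, noise_sd); fa is
    strictly inside (0, 1).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for dose in config.doses:
        mu = config.m * (math.log(dose) - math.log(config.Dm))
        for rep in range(config.replicates):
            eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            rows.append((dose, rep, float(_logistic(mu + eps))))
    return pd.DataFrame(rows, columns=["dose", "replicate", "fa"])


def _loewe_fa(
    m1: float, Dm1: float, m2: float, Dm2: float, d1: float, d2: float, interaction: float
) -> float:
    """Fraction affected of a Loewe-additive combination whose effective
    potency is multiplied by ``interaction``.

    Solves I*d1/Dx1(fa) + I*d2/Dx2(fa) = 1 for fa, where
    Dx_i(fa) = Dm_i * (fa/(1-fa))^(1/m_i). The recovered combination index at
    that fa is then exactly 1/interaction.
    """
    if d1 < 0 or d2 < 0 or d1 + d2 <= 0:
        raise ValueError("need d1, d2 >= 0 with d1 + d2 > 0")
    if d2 == 0:  # single drug 1, dose scaled by the interaction multiplier
        return float(_logistic(m1 * math.log(interaction * d1 / Dm1)))
    if d1 == 0:
        return float(_logistic(m2 * math.log(interaction * d2 / Dm2)))
    if abs(m1 - m2) < 1e-12:
        # shared slope: t^(1/m) = I (d1/Dm1 + d2/Dm2) in odds t = fa/(1-fa)
        u = m1 * math.log(interaction * (d1 / Dm1 + d2 / Dm2))
        return float(_logistic(u))

    def g(u: float) -> float:  # u = ln odds
        return (
            interaction * d1 / (Dm1 * math.exp(u / m1))
            + interaction * d2 / (Dm2 * math.exp(u / m2))
            - 1.0
        )

    u = brentq(g, -500.0, 500.0, xtol=1e-13, rtol=1e-15)
    return float(_logistic(u))


def simulate_combination(
    fit1: tuple[float, float],
    fit2: tuple[float, float],
    dose_pairs: Sequence[tuple[float, float]],
    interaction: float = 1.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Combination plate with known ground-truth interaction.

    ``fit1``/``fit2`` are (m, Dm) per drug. ``interaction`` multiplies the
    Loewe-additive effective potency: 1 is exact additivity (recovered CI of
    1), >1 synergy (CI < 1), <1 antagonism (CI > 1). Noise is applied on the
    logit scale per replicate.
    """
    if interaction <= 0:
        raise ValueError("interaction must be positive")
    m1, Dm1 = fit1
    m2, Dm2 = fit2
    rng = np.random.default_rng(seed)
    rows = []
    for d1, d2 in dose_pairs:
        fa0 = _loewe_fa(m1, Dm1, m2, Dm2, d1, d2, interaction)
        mu = math.log(fa0 / (1 - fa0))
        for rep in range(replicates):
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((d1, d2, rep, float(_logistic(mu + eps))))
    return pd.DataFrame(rows, columns=["drug1_dose", "drug2_dose", "replicate", "fa"])


# ---------------------------------------------------------------------------
# Whole-screen convenience
# ---------------------------------------------------------------------------


@dataclass
class ScreenTruth:
    """Ground truth bundle from one simulated screen."""

    genome: str
    genes: list[GeneModel]
    library: pd.DataFrame
    survivors: pd.DataFrame
    reads: list[tuple[str, str]]
    n_skipped: int


def simulate_screen(config: ScreenSimConfig, mismatch_rate: float = 0.0) -> ScreenTruth:
    """Genome -> library -> selection -> reads, with per-stage seeds fanned
    out from ``config.seed`` by fixed offsets."""
    genome, genes = generate_genome(config.genome_length, config.n_genes, config.seed)
    library = simulate_insertion_library(genome, genes, config.n_cells, config.seed + 1)
    cfg = ScreenSimConfig(**{**config.__dict__, "seed": config.seed + 2})
    survivors = simulate_selection(library, cfg)
    reads, n_skipped = generate_reads(
        survivors, genome, config.read_length, mismatch_rate, config.seed + 3
    )
    return ScreenTruth(genome, genes, library, survivors, reads, n_skipped)
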