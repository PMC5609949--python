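"""Per-gene insertion enrichment and ranking.

In a haploid gene-trap resistance screen, a gene whose loss confers drug
resistance accumulates sense-orientation (inactivating) insertions in the
surviving population far in excess of the unselected mutagenized control.
This module summarizes annotated insertion sites per gene, tests each gene
for enrichment of unique sense sites with a one-sided Fisher exact test,
adjusts for multiple testing with Benjamini-Hochberg, and ranks genes both
by the number of unique insertions and by the total read-supported insertion
count — the two orderings a screen report conventionally carries.

Distinct sites (not reads) are the counting unit for the test: per-site read
counts are inflated by orders of magnitude through clonal expansion and
inverse-PCR skew, so they measure amplification, not independent insertion
events.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mapping import GeneModel, InsertionSite

logger = logging.getLogger("trapscreen")

SUMMARY_COLUMNS = ["gene_id", "unique_sense", "unique_total", "reads_sense", "reads_total"]

REPORT_COLUMNS = SUMMARY_COLUMNS + [
    "k_sel",
    "n_sel",
    "k_ctl",
    "n_ctl",
    "odds_ratio",
    "p_value",
    "q_value",
    "rank_unique",
    "rank_total",
]


def summarize_by_gene(
    sites: Sequence[InsertionSite], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Unique-site and read-count summaries per gene.

    Every gene in the gene set appears (zero counts allowed); intergenic
    sites are excluded. A site annotated against several overlapping genes
    contributes to each of them.
    """
    counts = {
        g.gene_id: {"unique_sense": 0, "unique_total": 0, "reads_sense": 0, "reads_total": 0}
        for g in genes
    }
    for s in sites:
        if not s.gene_id:
            continue
        if s.gene_id not in counts:
            logger.warning("site annotated to unknown gene %s; ignored", s.gene_id)
            continue
        c = counts[s.gene_id]
        c["unique_total"] += 1
        c["reads_total"] += s.read_count
        if s.orientation == "sense":
            c["unique_sense"] += 1
            c["reads_sense"] += s.read_count
    return pd.DataFrame(
        [{"gene_id": gid, **c} for gid, c in counts.items()], columns=SUMMARY_COLUMNS
    )


def fisher_one_sided_p(
    k_sel: np.ndarray | int,
    n_sel: int,
    k_ctl: np.ndarray | int,
    n_ctl: int,
) -> np.ndarray | float:
    """One-sided (enrichment in selected) Fisher exact p for the 2x2 table
    [[k_sel, n_sel - k_sel], [k_ctl, n_ctl - k_ctl]].

    Conditional on the margins, k_sel is hypergeometric; the p-value is the
    upper tail P(X >= k_sel) with X ~ Hypergeom(n_sel + n_ctl, k_sel + k_ctl,
    n_sel). Vectorized over k_sel/k_ctl.
    """
    k_sel = np.asarray(k_sel)
    k_ctl = np.asarray(k_ctl)
    p = hypergeom.sf(k_sel - 1, n_sel + n_ctl, k_sel + k_ctl, n_sel)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def fisher_enrichment(
    selected: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene enrichment of unique sense insertions, selected vs control.

    ``selected``/``control`` are ``summarize_by_gene`` frames over the same
    gene set. The test denominators n_sel and n_ctl are the total unique
    sense sites across all genes in each arm. The sample odds ratio
    k_sel (n_ctl - k_ctl) / ((n_sel - k_sel) k_ctl) may be infinite.
    """
    sel = selected.set_index("gene_id")
    ctl = control.set_index("gene_id")
    if not sel.index.equals(ctl.index):
        ctl = ctl.reindex(sel.index, fill_value=0)
    n_sel = int(sel["unique_sense"].sum())
    n_ctl = int(ctl["unique_sense"].sum())
    if n_sel == 0:
        raise ValueError("selected population has no sense insertion sites")
    if n_ctl == 0:
        raise ValueError("control population has no sense insertion sites")
    k_sel = sel["unique_sense"].to_numpy()
    k_ctl = ctl["unique_sense"].to_numpy()
    p = fisher_one_sided_p(k_sel, n_sel, k_ctl, n_ctl)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (k_sel * (n_ctl - k_ctl)).astype(float) / (
            (n_sel - k_sel) * k_ctl
        ).astype(float)
    odds = np.where((k_sel == 0) & (k_ctl == 0), np.nan, odds)
    out = selected.copy()
    out["k_sel"] = k_sel
    out["n_sel"] = n_sel
    out["k_ctl"] = k_ctl
    out["n_ctl"] = n_ctl
    out["odds_ratio"] = odds
    out["p_value"] = np.atleast_1d(p)
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Fill 1-based ``rank_unique`` and ``rank_total`` columns.

    rank_unique orders genes by unique sense sites descending; rank_total by
    total supporting reads descending. Each rank breaks ties by the other
    count descending, then gene_id ascending, so ranks are well defined and
    invariant to input order.
    """
    out = results.copy()
    by_unique = out.sort_values(
        ["unique_sense", "reads_total", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    by_total = out.sort_values(
        ["reads_total", "unique_sense", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    out.loc[by_unique, "rank_unique"] = np.arange(1, len(out) + 1)
    out.loc[by_total, "rank_total"] = np.arange(1, len(out) + 1)
    out["rank_unique"] = out["rank_unique"].astype(int)
    out["rank_total"] = out["rank_total"].astype(int)
    return out


def enrichment_table(
    selected_sites: Sequence[InsertionSite],
    control_sites: Sequence[InsertionSite],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Full enrichment analysis: summarize both arms, Fisher test, BH
    adjustment, dual ranking. Returns one row per gene, sorted by
    rank_unique."""
    sel = summarize_by_gene(selected_sites, genes)
    ctl = summarize_by_gene(control_sites, genes)
    res = fisher_enrichment(sel, ctl)
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    res = rank_genes(res)
    return res.sort_values("rank_unique").reset_index(drop=True)[REPORT_COLUMNS]


def screen_report(
    results: pd.DataFrame,
    genes: Sequence[GeneModel],
    sites: Sequence[InsertionSite] | None = None,
    diagram_genes: Sequence[str] = (),
    out_path: str | Path | None = None,
    metadata: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, list[dict]]]:
    """Ranked gene table plus per-gene site-diagram coordinates.

    For each requested gene the diagram data lists its annotated sites with
    positions relative to the gene start — the coordinates needed to draw
    unique insertion sites as ticks along the gene body. Requesting an
    unknown gene raises an error listing the known gene ids.
    """
    table = results.sort_values("rank_unique").reset_index(drop=True)
    known = {g.gene_id: g for g in genes}
    diagrams: dict[str, list[dict]] = {}
    for gid in diagram_genes:
        if gid not in known:
            raise ValueError(
                f"unknown gene {gid!r}; known genes: {', '.join(sorted(known))}"
            )
        gene = known[gid]
        entries = []
        for s in sites or ():
            if s.gene_id == gid:
                entries.append(
                    {
                        "position": s.position,
                        "relative_position": s.position - gene.start,
                        "strand": s.strand,
                        "orientation": s.orientation,
                        "read_count": s.read_count,
                    }
                )
        diagrams[gid] = sorted(entries, key=lambda e: e["position"])
    if out_path is not None:
        with open(out_path, "w") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}={v}\n")
            table.to_csv(fh, sep="\t", index=False)
    return table, diagrams
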