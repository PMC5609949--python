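"""End-to-end pipeline orchestration.

Ties the stages into reproducible runs: the screen arm maps selected and
control read sets to insertion sites and ranks genes by enrichment; the
synergy arm normalizes a viability plate, fits the median-effect model per
drug and emits CI and isobologram tables. Every run writes a JSON manifest
recording the package version, parameters, seed and per-stage record counts,
so any output can be regenerated bit-identically. Stages never mutate their
inputs; on error the partial outputs of the failed run are removed.

A single global seed is fanned out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrichment_table, screen_report
from .mapping import (
    map_insertions,
    read_genes,
    read_sites_tsv,
    write_sites_bed,
    write_sites_tsv,
)
from .simulate import read_fasta, read_fastq
from .synergy import FA_MAX_DEFAULT, FA_MIN_DEFAULT, analyze_plate, normalize_viability

logger = logging.getLogger("trapscreen")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_prefix: str
    seed: int = 0
    log_level: str = "INFO"
    # screen arm
    selected_reads: str | None = None
    control_reads: str | None = None
    selected_sam: str | None = None
    control_sam: str | None = None
    genome: str | None = None
    genes: str | None = None
    # synergy arm
    plate: str | None = None
    fa_min: float = FA_MIN_DEFAULT
    fa_max: float = FA_MAX_DEFAULT

    def resolve_paths(self, names: list[str]) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise FileNotFoundError(f"missing required input: --{name}")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file: {value}")


def _out(prefix: Path, suffix: str) -> Path:
    return Path(str(prefix) + suffix)


def _write_manifest(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _cleanup(paths: list[Path]) -> None:
    for p in paths:
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass


def run_screen_pipeline(config: RunConfig) -> pd.DataFrame:
    """Map selected and control reads to sites, then rank genes.

    Writes <prefix>.selected.sites.tsv/.bed, <prefix>.control.sites.tsv/.bed,
    <prefix>.genes.tsv (the ranked report) and <prefix>.manifest.json.
    Returns the ranked gene table.
    """
    required = ["genes"]
    required += ["selected_sam"] if config.selected_sam else ["selected_reads", "genome"]
    required += ["control_sam"] if config.control_sam else ["control_reads", "genome"]
    config.resolve_paths(list(dict.fromkeys(required)))

    genes = read_genes(config.genes)
    genome = read_fasta(config.genome) if config.genome else None
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    meta = {"seed": config.seed, "version": __version__}
    try:
        stage = "map-insertions(selected)"
        sel_sites, sel_stats = map_insertions(
            read_fastq(config.selected_reads) if config.selected_reads else None,
            genome,
            genes,
            sam_path=config.selected_sam,
        )
        stage = "map-insertions(control)"
        ctl_sites, ctl_stats = map_insertions(
            read_fastq(config.control_reads) if config.control_reads else None,
            genome,
            genes,
            sam_path=config.control_sam,
        )
        for label, sites in (("selected", sel_sites), ("control", ctl_sites)):
            tsv = _out(prefix, f".{label}.sites.tsv")
            bed = _out(prefix, f".{label}.sites.bed")
            outputs += [tsv, bed]
            write_sites_tsv(sites, tsv, metadata=meta)
            write_sites_bed(sites, bed)
        stage = "rank-genes"
        table = enrichment_table(sel_sites, ctl_sites, genes)
        report_path = _out(prefix, ".genes.tsv")
        outputs.append(report_path)
        screen_report(table, genes, sites=sel_sites, out_path=report_path, metadata=meta)
    except Exception as exc:
        _cleanup(outputs)
        raise RuntimeError(f"screen pipeline failed at stage {stage}: {exc}") from exc

    manifest = {
        "pipeline": "screen",
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "selected_reads": config.selected_reads,
            "control_reads": config.control_reads,
            "selected_sam": config.selected_sam,
            "control_sam": config.control_sam,
            "genome": config.genome,
            "genes": config.genes,
        },
        "counts": {
            "genes": len(genes),
            "selected": sel_stats.as_dict(),
            "control": ctl_stats.as_dict(),
            "selected_sites": len(sel_sites),
            "control_sites": len(ctl_sites),
        },
        "outputs": [str(p) for p in outputs],
    }
    _write_manifest(_out(prefix, ".manifest.json"), manifest)
    return table


def load_plate(path: str | Path) -> pd.DataFrame:
    """Long-format plate TSV with columns drug1_dose, drug2_dose, replicate
    and one of raw_signal / percent_viability / fa.

    Raw signal is normalized against vehicle wells (both doses zero) on
    load; blank wells, if present, are rows labelled replicate < 0.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"drug1_dose", "drug2_dose", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if "fa" in df.columns:
        return df
    if "percent_viability" in df.columns:
        df["fa"] = (1.0 - df["percent_viability"] / 100.0).clip(0.0, 1.0)
        return df
    if "raw_signal" not in df.columns:
        raise ValueError("plate table needs a raw_signal, percent_viability or fa column")
    blank = df[df["replicate"] < 0]["raw_signal"].to_numpy()
    work = df[df["replicate"] >= 0]
    vehicle = work[(work["drug1_dose"] == 0) & (work["drug2_dose"] == 0)][
        "raw_signal"
    ].to_numpy()
    return normalize_viability(work, vehicle, blank)


def run_synergy_pipeline(config: RunConfig) -> dict:
    """Normalize -> fit both drugs -> CI per combination point -> isobologram.

    Writes <prefix>.fits.tsv, <prefix>.ci.tsv, <prefix>.isobologram.tsv and
    <prefix>.manifest.json. Returns the analyze_plate result dict.
    """
    config.resolve_paths(["plate"])
    plate = load_plate(config.plate)
    result = analyze_plate(plate, fa_min=config.fa_min, fa_max=config.fa_max)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta_lines = f"# seed={config.seed}\n# version={__version__}\n"

    fits_rows = [
        {
            "drug": name,
            "m": f.m,
            "Dm": f.Dm,
            "r": f.r,
            "n_points": f.n_points,
            "n_excluded": f.n_excluded,
            "valid": f.valid,
        }
        for name, f in result["fits"].items()
    ]
    with open(_out(prefix, ".fits.tsv"), "w") as fh:
        fh.write(meta_lines)
        pd.DataFrame(fits_rows).to_csv(fh, sep="\t", index=False)

    ci_df = pd.DataFrame(
        [
            {
                "d1": r.d1,
                "d2": r.d2,
                "fa": r.fa,
                "dx1": r.dx1,
                "dx2": r.dx2,
                "ci": r.ci,
                "interpretation": r.interpretation,
            }
            for r in result["ci"]
        ],
        columns=["d1", "d2", "fa", "dx1", "dx2", "ci", "interpretation"],
    )
    with open(_out(prefix, ".ci.tsv"), "w") as fh:
        fh.write(meta_lines)
        ci_df.to_csv(fh, sep="\t", index=False)

    iso_df = pd.DataFrame(result["isobologram"], columns=["x", "y", "fa"])
    with open(_out(prefix, ".isobologram.tsv"), "w") as fh:
        fh.write(meta_lines)
        iso_df.to_csv(fh, sep="\t", index=False)

    manifest = {
        "pipeline": "synergy",
        "version": __version__,
        "seed": config.seed,
        "inputs": {"plate": config.plate},
        "parameters": {"fa_min": config.fa_min, "fa_max": config.fa_max},
        "counts": {
            "plate_rows": len(plate),
            "combination_points": len(result["ci"]),
            "fits_valid": all(f.valid for f in result["fits"].values()),
        },
        "outputs": [
            str(_out(prefix, s))
            for s in (".fits.tsv", ".ci.tsv", ".isobologram.tsv")
        ],
    }
    _write_manifest(_out(prefix, ".manifest.json"), manifest)
    return result


def rank_genes_from_files(
    selected_path: str | Path,
    control_path: str | Path,
    genes_path: str | Path,
    out_path: str | Path | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment + ranking from two site TSVs and a gene annotation."""
    genes = read_genes(genes_path)
    sel = read_sites_tsv(selected_path)
    ctl = read_sites_tsv(control_path)
    table = enrichment_table(sel, ctl, genes)
    if out_path is not None:
        screen_report(
            table, genes, sites=sel, out_path=out_path,
            metadata={"seed": seed, "version": __version__},
        )
    return table
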