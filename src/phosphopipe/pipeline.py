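"""End-to-end orchestration: filter -> consensus -> patterns (+ optional stages).

Outputs are plain TSV reports plus a JSON run manifest recording the config
snapshot, input digests, seed, package version and per-stage counts, so a
run can be reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus_compare import summarize_cell_line_fraction, venn_counts
from .de_select import annotate_status, compare_regulation, select_regulated
from .insilico_digest import DigestParams, coverage
from .phospho_patterns import summarize_patterns
from .psm_filters import (
    FilterCriteria,
    call_phosphoproteins,
    call_proteins,
    filter_psms,
    localize_sites,
)
from .rare_scanner import hits_to_frame, scan_gene_regions
from .tables_io import (
    RunConfig,
    read_bed,
    read_de_table,
    read_fasta,
    read_psm_table,
    write_de_table,
    write_psm_table,
    write_site_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, input_dir: str | Path, output_dir: str | Path) -> dict:
    """Run every stage whose inputs exist; return the manifest dict.

    On any stage failure the partially written output directory is removed
    and :class:`StageError` (naming the stage) is raised.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    created = not output_dir.exists()
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {},
        "stages": {},
    }
    try:
        _run_stages(config, input_dir, output_dir, manifest)
    except Exception as exc:
        if created:
            shutil.rmtree(output_dir, ignore_errors=True)
        if isinstance(exc, StageError):
            raise
        raise StageError("setup", exc) from exc
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_stages(config: RunConfig, input_dir: Path, output_dir: Path, manifest: dict) -> None:
    psm_path = input_dir / "psms.tsv"
    if not psm_path.exists():
        raise StageError("filter", FileNotFoundError(f"missing PSM table {psm_path}"))
    for p in sorted(input_dir.iterdir()):
        if p.is_file():
            manifest["inputs"][p.name] = _sha256(p)

    # --- filter ---------------------------------------------------------
    try:
        psms = read_psm_table(psm_path)
        criteria = FilterCriteria.from_config(config)
        kept, tally = filter_psms(psms, criteria)
        sites = [s for psm in kept for s in localize_sites(psm, criteria.min_localization)]
        write_psm_table(kept, output_dir / "kept_psms.tsv")
        write_site_table(sites, output_dir / "sites.tsv")
        pd.DataFrame(
            [{"reason": r, "count": c} for r, c in sorted(tally.items())],
            columns=["reason", "count"],
        ).to_csv(output_dir / "rejection_tally.tsv", sep="\t", index=False)
        manifest["stages"]["filter"] = {
            "n_input": len(psms), "n_kept": len(kept),
            "n_rejected": sum(tally.values()), "n_sites": len(sites),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("filter", exc) from exc

    # --- compare --------------------------------------------------------
    try:
        called = call_proteins(kept, criteria.min_peptides_per_protein)
        phospho = call_phosphoproteins(called, kept, criteria.min_phosphopeptides)
        cell_lines = sorted({p.cell_line for p in kept})
        fractions = sorted({p.fraction for p in kept})
        summary_rows, label_rows = [], []
        summaries = {}
        for cl in cell_lines:
            for frac in fractions:
                s = summarize_cell_line_fraction(called, phospho, cl, frac)
                summaries[(cl, frac)] = s
                vc = venn_counts(set(s.phospho_vehicle), set(s.phospho_ra), "vehicle", "RA")
                summary_rows.append({
                    "cell_line": cl, "fraction": frac,
                    "n_consensus_proteins": len(s.consensus_totals),
                    "n_phospho_vehicle": len(s.phospho_vehicle),
                    "n_phospho_ra": len(s.phospho_ra),
                    "n_phospho_both": vc.both,
                    "pct_phosphorylated_vehicle": s.percent_phosphorylated_vehicle,
                })
                for acc, label in sorted(s.response_labels.items()):
                    label_rows.append({"cell_line": cl, "fraction": frac,
                                       "accession": acc, "ra_response": label})
        pd.DataFrame(summary_rows).to_csv(output_dir / "consensus_summary.tsv",
                                          sep="\t", index=False)
        pd.DataFrame(label_rows, columns=["cell_line", "fraction", "accession", "ra_response"],
                     ).to_csv(output_dir / "ra_response_labels.tsv", sep="\t", index=False)
        manifest["stages"]["compare"] = {
            "n_samples": len(called),
            "consensus_sizes": {f"{cl}/{fr}": len(s.consensus_totals)
                                for (cl, fr), s in summaries.items()},
        }
    except Exception as exc:
        raise StageError("compare", exc) from exc

    # --- patterns -------------------------------------------------------
    try:
        phosphopeptides = [p for p in kept if p.n_phospho >= 1]
        pat = summarize_patterns(phosphopeptides, sites)
        pd.DataFrame(pat.to_rows()).to_csv(output_dir / "pattern_summary.tsv",
                                           sep="\t", index=False)
        manifest["stages"]["patterns"] = {
            "total_phosphopeptides": pat.total_peptides, "total_sites": pat.total_sites,
        }
    except Exception as exc:
        raise StageError("patterns", exc) from exc

    # --- digest (optional) ----------------------------------------------
    fasta_path = input_dir / "proteome.fasta"
    if fasta_path.exists():
        try:
            proteome = read_fasta(fasta_path)
            params = DigestParams.from_config(config.digestion)
            rows = []
            for prot in proteome:
                frac_cov, _ = coverage(prot, params)
                rows.append({"accession": prot.accession, "length": len(prot.sequence),
                             "coverage": round(frac_cov, 4)})
            pd.DataFrame(rows).to_csv(output_dir / "digest_coverage.tsv", sep="\t", index=False)
            manifest["stages"]["digest"] = {"n_proteins": len(proteome),
                                            "enzyme": params.enzyme}
        except Exception as exc:
            raise StageError("digest", exc) from exc

    # --- scan-rare (optional) -------------------------------------------
    regions_fasta = input_dir / "regions.fasta"
    regions_bed = input_dir / "regions.bed"
    if regions_fasta.exists() and regions_bed.exists():
        try:
            seqs = {r.accession: r.sequence for r in read_fasta(regions_fasta)}
            regions = read_bed(regions_bed)
            hits, dr_summary, skipped = scan_gene_regions(
                seqs, regions, flank=config.flank, spacings=config.dr_spacings
            )
            hits_to_frame(hits).to_csv(output_dir / "dr_hits.tsv", sep="\t", index=False)
            dr_summary.to_csv(output_dir / "dr_summary.tsv", sep="\t", index=False)
            manifest["stages"]["scan_rare"] = {
                "n_genes": len(regions), "n_hits": len(hits), "n_skipped": len(skipped),
            }
        except Exception as exc:
            raise StageError("scan-rare", exc) from exc

    # --- de-select (optional) -------------------------------------------
    de_paths = sorted(input_dir.glob("de_*.tsv"))
    if de_paths:
        try:
            selections = {}
            for path in de_paths:
                label = path.stem.replace("de_", "")
                rows = annotate_status(read_de_table(path), config.lfc_threshold, config.alpha)
                write_de_table(rows, output_dir / f"de_status_{label}.tsv")
                selections[label] = select_regulated(rows, config.lfc_threshold, config.alpha)
            stage: dict = {
                label: {"n_up": len(up), "n_down": len(down)}
                for label, (up, down) in selections.items()
            }
            if len(selections) == 2:
                (la, (a_up, a_down)), (lb, (b_up, b_down)) = sorted(selections.items())
                comp = compare_regulation(a_up, a_down, b_up, b_down, la, lb)
                pd.DataFrame([{
                    "a_only_up": len(comp.a_only_up), "a_only_down": len(comp.a_only_down),
                    "b_only_up": len(comp.b_only_up), "b_only_down": len(comp.b_only_down),
                    "shared_concordant": len(comp.shared_concordant),
                    "shared_discordant": len(comp.shared_discordant),
                    "pct_a_exclusive": comp.pct_a_exclusive,
                    "pct_b_exclusive": comp.pct_b_exclusive,
                }]).to_csv(output_dir / "regulation_comparison.tsv", sep="\t", index=False)
                stage["pct_a_exclusive"] = comp.pct_a_exclusive
                stage["pct_b_exclusive"] = comp.pct_b_exclusive
            manifest["stages"]["de_select"] = stage
        except Exception as exc:
            raise StageError("de-select", exc) from exc
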