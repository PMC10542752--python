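"""End-to-end orchestration: parse -> merge -> filter -> date -> summarise.

``run_all`` executes the whole analysis on either simulated or on-disk
inputs and writes a reproducible report bundle: the final annotation GFF3,
raw/final per-class summary tables, raw/final repeat landscapes (TSV and
plot), the windowed feature table, the partial-Kendall correlation table
(TE category x genomic feature, Bonferroni-adjusted per feature) and the
macro/micro chromosome comparisons.  Every output directory carries a
manifest with the config hash and seed, and reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import defrag, io_formats, landscape, stats, windows
from .divergence import (
    AgeModel,
    age_mya,
    classify_age,
    count_substitutions,
    kimura2,
)
from .synthetic_data import SimConfig, plant_genome

logger = logging.getLogger("telandscape")

TE_CATEGORIES = ("all", "ancient", "recent")
FEATURES = ("gc", "cpg_cov", "gene_cov", "rec_rate")


@dataclass
class RunConfig:
    """Inputs, model parameters and output location for one full run."""

    outdir: str
    sim: SimConfig | None = None  # simulate inputs when set
    out_path: str | None = None  # .out table (ignored with sim)
    align_path: str | None = None
    library_path: str | None = None
    sizes_path: str | None = None
    genome_path: str | None = None
    genes_path: str | None = None
    cpg_path: str | None = None
    recmap_path: str | None = None
    age_model: AgeModel = field(default_factory=AgeModel)
    merge_params: defrag.MergeParams = field(default_factory=defrag.MergeParams)
    window: int = windows.DEFAULT_WINDOW
    macro_threshold: int = stats.MACRO_THRESHOLD
    exclude_partial: bool = True
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _as_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _load_inputs(config: RunConfig):
    """Return (hits, blocks, library, chrom_meta, sequences, genes, cpg, recmap)."""
    if config.sim is not None:
        ds = plant_genome(config.sim, outdir=Path(config.outdir) / "sim_inputs")
        return (
            ds.hits,
            ds.blocks,
            ds.library,
            ds.chrom_meta,
            ds.sequences,
            ds.genes,
            ds.cpg,
            ds.recmap,
        )
    chrom_meta = io_formats.read_chrom_sizes(config.sizes_path)
    sizes = {c: m["length"] for c, m in chrom_meta.items()}
    library = io_formats.read_library(config.library_path)
    with open(config.out_path) as fh:
        hits = io_formats.parse_rm_out(fh)
    blocks = []
    if config.align_path:
        with open(config.align_path) as fh:
            blocks = io_formats.parse_rm_align(fh, library, hits)
    sequences = None
    if config.genome_path:
        from Bio import SeqIO

        sequences = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(config.genome_path, "fasta")
        }
    genes = (
        io_formats.read_tracks(config.genes_path, "GFF3", sizes)
        if config.genes_path
        else []
    )
    cpg = (
        io_formats.read_tracks(config.cpg_path, "BED", sizes)
        if config.cpg_path
        else []
    )
    recmap = (
        io_formats.read_tracks(config.recmap_path, "TSV-map", sizes)
        if config.recmap_path
        else []
    )
    return hits, blocks, library, chrom_meta, sequences, genes, cpg, recmap


def annotate(hits, blocks, library, config: RunConfig):
    """Fragments -> dated copies: merge, LTR assembly, 80-80-80 filter.

    Returns ``(raw_copies, final_copies, fragment_K)``; fragment
    divergences come from the alignments when available, the table's
    pct_div otherwise, and copies are age-classified on their
    length-weighted mean K.
    """
    fragment_K = {}
    for block in blocks:
        try:
            fragment_K[block.hit_key] = kimura2(count_substitutions(block))
        except ValueError as exc:
            logger.warning("fragment %s skipped: %s", block.hit_key, exc)
    raw = defrag.merge_fragments(hits, config.merge_params, fragment_K)
    assembled = defrag.assemble_ltr(raw, library, config.merge_params)
    final = defrag.filter_808080(assembled, config.merge_params)
    for copies in (raw, assembled, final):
        for c in copies:
            c.age_class = classify_age(c.K, config.age_model)
    logger.info(
        "annotate: %d hits -> %d raw copies -> %d after LTR assembly -> %d final",
        len(hits),
        len(raw),
        len(assembled),
        len(final),
    )
    return raw, final, fragment_K


def correlation_table(
    feature_df: pd.DataFrame, exclude_partial: bool = True
) -> pd.DataFrame:
    """Partial Kendall of each TE category vs each feature on autosomes.

    Controls are the other three features; Bonferroni family is the three
    categories tested per feature.  Partial windows and sex chromosomes
    are excluded; complete cases across all used columns.
    """
    df = feature_df[feature_df["is_autosome"]]
    if exclude_partial:
        df = df[~df["is_partial"]]
    rows = []
    for feat in FEATURES:
        controls = [f for f in FEATURES if f != feat]
        per_feat = []
        for cat in TE_CATEGORIES:
            col = "te_cov_all" if cat == "all" else f"te_cov_{cat}"
            try:
                res = stats.partial_kendall(df, col, feat, controls)
            except ValueError as exc:
                logger.warning("correlation %s vs %s skipped: %s", cat, feat, exc)
                res = None
            per_feat.append((cat, res))
        valid = [r.p_raw for _, r in per_feat if r is not None]
        adj = stats.bonferroni(valid, m=len(per_feat)) if valid else []
        it = iter(adj)
        for cat, res in per_feat:
            if res is not None:
                res.p_adj = next(it)
            rows.append(
                {
                    "te_category": cat,
                    "feature": feat,
                    "n": res.n if res else 0,
                    "tau_partial": res.tau_partial if res else float("nan"),
                    "z": res.z_stat if res else float("nan"),
                    "p_raw": res.p_raw if res else float("nan"),
                    "p_adj": res.p_adj if res else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def macro_micro_report(
    copies, chrom_meta: dict, macro_threshold: int
) -> pd.DataFrame:
    """Per-class macro/micro Kruskal-Wallis on per-chromosome coverage."""
    sizes = {c: m for c, m in chrom_meta.items() if m["is_autosome"]}
    auto_copies = [c for c in copies if c.chrom in sizes]
    rel_all = stats.relative_coverage(auto_copies, sizes, by="all")
    rel_class = stats.relative_coverage(auto_copies, sizes, by="class")
    classes = {"all": rel_all, **rel_class}
    rows = []
    for label, per_chrom in classes.items():
        macro = [
            v
            for c, v in per_chrom.items()
            if stats.chrom_class(sizes[c]["length"], macro_threshold) == "macro"
        ]
        micro = [
            v
            for c, v in per_chrom.items()
            if stats.chrom_class(sizes[c]["length"], macro_threshold) == "micro"
        ]
        try:
            test = stats.kruskal_wallis([macro, micro])
            H, p = test.H, test.p
        except ValueError as exc:
            logger.warning("macro/micro test for %s skipped: %s", label, exc)
            H, p = float("nan"), float("nan")
        rows.append(
            {
                "te_class": label,
                "n_macro": len(macro),
                "n_micro": len(micro),
                "mean_macro": sum(macro) / len(macro) if macro else float("nan"),
                "mean_micro": sum(micro) / len(micro) if micro else float("nan"),
                "H": H,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict of output paths plus the in-memory tables under
    ``tables``.  Any stage failure aborts with the stage named.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        (hits, blocks, library, chrom_meta, sequences, genes, cpg, recmap) = (
            _load_inputs(config)
        )
        genome_len = sum(m["length"] for m in chrom_meta.values())

        stage = "annotate"
        raw_copies, final_copies, fragment_K = annotate(
            hits, blocks, library, config
        )

        stage = "summaries"
        summary_raw = defrag.annotation_summary(raw_copies, genome_len)
        summary_final = defrag.annotation_summary(final_copies, genome_len)

        stage = "landscape"
        raw_items = [
            (h.class_label, fragment_K.get(h.key, h.pct_div), h.length)
            for h in hits
        ]
        final_items = [
            (c.class_label, c.K, c.merged_len) for c in final_copies
        ]
        ls_raw = landscape.build_landscape(
            raw_items, genome_len, age_model=config.age_model
        )
        ls_final = landscape.build_landscape(
            final_items, genome_len, age_model=config.age_model
        )

        stage = "windows"
        win = windows.make_windows(chrom_meta, config.window)
        feat = windows.feature_table(
            win, final_copies, genes, cpg, recmap, sequences, config.age_model
        )

        stage = "correlations"
        corr = correlation_table(feat, config.exclude_partial)

        stage = "chromosome-stats"
        macro_threshold = config.macro_threshold
        if config.sim is not None and macro_threshold == stats.MACRO_THRESHOLD:
            macro_threshold = config.sim.macro_threshold
        mm = macro_micro_report(final_copies, chrom_meta, macro_threshold)

        stage = "write"
        paths = {
            "annotation": outdir / "annotation.gff3",
            "summary_raw": outdir / "summary_raw.tsv",
            "summary_final": outdir / "summary_final.tsv",
            "landscape_raw": outdir / "landscape_raw.tsv",
            "landscape_final": outdir / "landscape_final.tsv",
            "landscape_plot": outdir / "landscape_final.png",
            "feature_table": outdir / "feature_table.tsv",
            "correlations": outdir / "correlations.tsv",
            "macro_micro": outdir / "macro_micro.tsv",
            "manifest": outdir / "manifest.json",
        }
        with open(paths["annotation"], "w") as fh:
            io_formats.write_annotation_gff3(final_copies, fh)
        summary_raw.to_csv(paths["summary_raw"], sep="\t", index=False)
        summary_final.to_csv(paths["summary_final"], sep="\t", index=False)
        landscape.landscape_frame(ls_raw).to_csv(
            paths["landscape_raw"], sep="\t", index=False
        )
        landscape.landscape_frame(ls_final).to_csv(
            paths["landscape_final"], sep="\t", index=False
        )
        landscape.plot_landscape(ls_final, paths["landscape_plot"])
        feat.to_csv(paths["feature_table"], sep="\t", index=False)
        corr.to_csv(paths["correlations"], sep="\t", index=False)
        mm.to_csv(paths["macro_micro"], sep="\t", index=False)
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.sim.seed if config.sim else None,
            "n_hits": len(hits),
            "n_raw_copies": len(raw_copies),
            "n_final_copies": len(final_copies),
            "genome_len": genome_len,
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "tables": {
            "summary_raw": summary_raw,
            "summary_final": summary_final,
            "feature_table": feat,
            "correlations": corr,
            "macro_micro": mm,
        },
        "copies": {"raw": raw_copies, "final": final_copies},
    }
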