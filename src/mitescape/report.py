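"""End-to-end pipeline orchestration and summary tables.

``run_pipeline`` drives the stages from a declarative config: copy detection,
structural classification, family clustering, genomic-context categorization
with chi-squared enrichment, expression (M/g) statistics and, when several
species libraries are given, the cross-species comparison. Every stage logs
its record counts and the thresholds in force, and all outputs are plain
GFF3/BED/TSV so a rerun with the same config is byte-identical.

``summarize_groups`` emits the per-group census table: family and copy
counts, occupied bp and genome percentage, mean copy number per family, mean
element length and the largest family, plus the per-category localization
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import comparative, copyfinder, element_structure, genome_context, seqio, transcription
from .errors import ParameterError

GROUP_ORDER = ("hAT-like", "Mutator-like", "Stowaway", "Tourist", "Unclassified")


@dataclass
class PipelineConfig:
    genome: str
    library: str
    outdir: str
    gff3: str | None = None
    counts: str | None = None
    library_sizes: str | None = None
    proteins: str | None = None
    species_libraries: dict[str, str] = dc_field(default_factory=dict)
    seed: int = 0
    thresholds: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def threshold(self, name: str, default):
        return self.thresholds.get(name, default)


def copies_to_frame(structured) -> pd.DataFrame:
    """Per-copy table: coordinates, structural calls, group."""
    rows = []
    for sc in structured:
        rows.append({
            "copy_id": f"{sc.family}:{sc.contig}:{sc.start}-{sc.end}",
            "contig": sc.contig, "start": sc.start, "end": sc.end,
            "strand": sc.strand, "family": sc.family,
            "identity": round(sc.identity, 2),
            "length": sc.end - sc.start,
            "tsd": sc.tsd.tsd, "tsd_k": sc.tsd.k,
            "tsd_exact": sc.tsd.exact, "ta_stretch": sc.tsd.ta_stretch,
            "tir_arm": sc.tir.arm, "tir_identity": round(sc.tir.identity, 2),
            "superfamily": sc.superfamily, "group": sc.group})
    return pd.DataFrame(rows, columns=[
        "copy_id", "contig", "start", "end", "strand", "family", "identity",
        "length", "tsd", "tsd_k", "tsd_exact", "ta_stretch", "tir_arm",
        "tir_identity", "superfamily", "group"])


def summarize_groups(copies: pd.DataFrame, family_groups: Mapping[str, str],
                     genome_size: int) -> pd.DataFrame:
    """Census table per superfamily group, with a Total row.

    ``copies`` needs columns (family, group, length) and, when present, a
    ``category`` column for the localization counts. Mean fields are rounded
    to the nearest integer for presentation; exact values are kept in
    ``*_exact`` columns. Empty groups carry zeros with NaN means.
    """
    if genome_size <= 0:
        raise ParameterError("genome size must be > 0")
    has_cat = "category" in copies.columns
    rows = []
    groups = [g for g in GROUP_ORDER
              if g in set(family_groups.values()) | set(copies.get("group", []))]
    for group in groups:
        fams = [f for f, g in family_groups.items() if g == group]
        sub = copies[copies["group"] == group]
        n_fam, n_cop = len(fams), len(sub)
        occupied = int(sub["length"].sum())
        fam_sizes = sub.groupby("family").size()
        row = {
            "group": group, "n_families": n_fam, "n_copies": n_cop,
            "occupied_mbp": round(occupied / 1e6, 2),
            "pct_genome": round(100.0 * occupied / genome_size, 2),
            "mean_copies_per_family": (round(n_cop / n_fam) if n_fam and n_cop
                                       else float("nan")),
            "mean_copies_per_family_exact": (n_cop / n_fam if n_fam and n_cop
                                             else float("nan")),
            "mean_length_bp": (round(occupied / n_cop) if n_cop
                               else float("nan")),
            "mean_length_bp_exact": (occupied / n_cop if n_cop
                                     else float("nan")),
            "largest_family": int(fam_sizes.max()) if n_cop else 0,
        }
        if has_cat:
            for cat in genome_context.CATEGORIES:
                row[cat] = int((sub["category"] == cat).sum())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")
    total = {
        "n_families": table["n_families"].sum(),
        "n_copies": table["n_copies"].sum(),
        "occupied_mbp": round(table["occupied_mbp"].sum(), 2),
        "pct_genome": round(100.0 * copies["length"].sum() / genome_size, 2),
        "mean_copies_per_family": float("nan"),
        "mean_copies_per_family_exact": float("nan"),
        "mean_length_bp": float("nan"),
        "mean_length_bp_exact": float("nan"),
        "largest_family": int(table["largest_family"].max()) if len(table) else 0,
    }
    if has_cat:
        for cat in genome_context.CATEGORIES:
            total[cat] = int(table[cat].sum())
    table.loc["Total"] = pd.Series(total)
    for col in ("n_families", "n_copies", "largest_family"):
        table[col] = table[col].astype(int)
    return table


def family_group_assignment(copies: pd.DataFrame) -> dict[str, str]:
    """Group of each family = modal superfamily group of its copies."""
    out = {}
    for fam, sub in copies.groupby("family"):
        counts = sub["group"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        out[str(fam)] = sorted(top)[0]
    return out


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run every stage the config enables; returns the in-memory results and
    writes GFF3/BED/TSV outputs plus a run log to ``config.outdir``."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}",
                            f"thresholds={dict(config.thresholds)}"]
    results: dict = {}

    genome = seqio.read_fasta(config.genome)
    library = seqio.read_fasta(config.library)
    genome_size = sum(len(s) for s in genome.values())
    log_lines.append(f"inputs: contigs={len(genome)} bp={genome_size} "
                     f"consensi={len(library)}")

    min_identity = config.threshold("min_identity", 80.0)
    min_len = config.threshold("min_len", 80)
    min_coverage = config.threshold("min_coverage", 0.8)
    max_end_offset = config.threshold("max_end_offset", 10)

    per_family = copyfinder.find_copies(
        library, genome, min_identity=min_identity, min_len=min_len,
        min_coverage=min_coverage, max_end_offset=max_end_offset)
    accepted = [c for hits in per_family.values() for c in hits if c.accepted]
    resolved = copyfinder.resolve_overlaps(accepted)
    log_lines.append(f"copyfinder: raw={sum(len(v) for v in per_family.values())} "
                     f"accepted={len(accepted)} resolved={len(resolved)}")

    structured = element_structure.structure_copies(genome, resolved)
    copies_df = copies_to_frame(structured)
    clusters = element_structure.cluster_families(library)
    log_lines.append(f"structure: copies={len(structured)} "
                     f"families_in={len(library)} families_80_80_80={len(clusters)}")

    genes = None
    if config.gff3:
        genes = seqio.read_gff3(config.gff3)
        window = config.threshold("window", 1000)
        cats, genes_of = [], []
        for sc in structured:
            cats.append(genome_context.categorize_copy(sc, genes, window))
            genes_of.append(genome_context.assign_gene(sc, genes, window))
        copies_df["category"] = cats
        copies_df["gene"] = genes_of
        log_lines.append(f"context: genes={len(genes)} categorized={len(cats)}")
    else:
        log_lines.append("context: skipped (no GFF3 given)")

    copies_df.to_csv(out / "copies.tsv", sep="\t", index=False)
    seqio.write_mite_gff3(structured, out / "mites.gff3")
    seqio.write_bed6(structured, out / "mites.bed")

    fam_groups = family_group_assignment(copies_df) if len(copies_df) else {}
    summary = summarize_groups(copies_df, fam_groups, genome_size) \
        if len(copies_df) else pd.DataFrame()
    summary.to_csv(out / "summary.tsv", sep="\t")
    results.update(copies=copies_df, summary=summary, clusters=clusters)

    if genes is not None and len(copies_df):
        table = genome_context.localization_table(
            copies_df[["group", "category"]].itertuples(index=False, name=None))
        table.to_csv(out / "localization.tsv", sep="\t")
        try:
            chi = genome_context.enrichment_chisq(table)
            report = chi.contributions.copy()
            report.to_csv(out / "chisq_contributions.tsv", sep="\t")
            with open(out / "chisq.txt", "w") as fh:
                fh.write(f"statistic\t{chi.statistic:.4f}\n"
                         f"df\t{chi.df}\npvalue\t{chi.pvalue:.3g}\n"
                         f"genic_pct\t{genome_context.genic_fraction(table):.1f}\n")
            results["chisq"] = chi
            log_lines.append(f"chisq: statistic={chi.statistic:.3f} "
                             f"df={chi.df} p={chi.pvalue:.3g}")
        except Exception as exc:  # degenerate tables on tiny runs
            log_lines.append(f"chisq: skipped ({exc})")
        results["localization"] = table

    if config.counts and config.library_sizes and "gene" in copies_df.columns:
        counts = pd.read_csv(config.counts, sep="\t")
        sizes = pd.read_csv(config.library_sizes, sep="\t") \
            .set_index("library")["size"].to_dict()
        feat_lens = dict(zip(copies_df["copy_id"], copies_df["length"]))
        if genes is not None:
            feat_lens.update({g.gene_id: g.end - g.start for g in genes})
        pairs = copies_df.dropna(subset=["gene"])[["gene", "copy_id"]] \
            .rename(columns={"copy_id": "mite"})
        known = set(counts["feature_id"])
        pairs = pairs[pairs["mite"].isin(known) & pairs["gene"].isin(known)]
        mg = transcription.mg_ratio(
            pairs, counts, feat_lens, sizes,
            min_gene_rpk=config.threshold("min_gene_rpk", 1.0),
            min_mg=config.threshold("min_mg", 1.9))
        mg.to_csv(out / "mg_records.tsv", sep="\t", index=False)
        selected = mg[mg["selected"]]
        diff = transcription.differential_mg(
            selected, min_range=config.threshold("min_mg_range", 1.5))
        (out / "selected_genes.txt").write_text(
            "\n".join(sorted(diff)) + ("\n" if diff else ""))
        transcription.mg_matrix(mg).to_csv(out / "mg_matrix.tsv", sep="\t")
        results["mg"] = mg
        results["differential_genes"] = diff
        log_lines.append(f"expression: records={len(mg)} "
                         f"selected={int(mg['selected'].sum())} "
                         f"differential_genes={len(diff)}")

    if len(config.species_libraries) >= 2:
        libs = {sp: seqio.read_fasta(p)
                for sp, p in config.species_libraries.items()}
        sharing = comparative.shared_family_network(
            libs,
            min_identity=config.threshold("comparative_min_identity", 60.0),
            min_coverage=config.threshold("comparative_min_coverage", 0.60))
        sharing.matches.to_csv(out / "sharing_matches.tsv", sep="\t",
                               index=False)
        sharing.pair_counts.to_csv(out / "sharing_pairs.tsv", sep="\t")
        sharing.degree_counts.to_csv(out / "sharing_degrees.tsv", sep="\t")
        results["sharing"] = sharing
        log_lines.append(f"comparative: species={len(libs)} "
                         f"related_pairs={len(sharing.matches)}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results["log"] = log_lines
    return results
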