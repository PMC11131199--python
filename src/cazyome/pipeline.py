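"""End-to-end orchestration: read → consensus → filter → CGC →
substrates → metrics → matrices → comparative stats → novelty → report.

Every tunable threshold lives in :class:`PipelineConfig` with the
defaults used throughout the package's analyses; the config is echoed
into the output directory for provenance. Failures in single genomes
are quarantined rather than fatal, unless more than 10% of genomes
fail.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cgc as cgc_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import novelty as novelty_mod
from . import stats as stats_mod
from . import substrates as sub_mod
from .consensus import call_genome, calls_to_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gff_dir: str = ""
    overview_dir: str = ""
    metadata: str = ""
    signalp: str | None = None
    outfmt6: str | None = None
    substrate_map: str | None = None
    outdir: str = "cazyome_out"
    max_gap: int = 2
    min_completeness: float = 75.0
    max_contamination: float = 10.0
    min_cazymes: int = 10
    min_class_size: int = 10
    rare_threshold: float = 0.05
    trend_threshold: float = 2.0  # percent, T1/T2 split
    novelty_threshold: float = 30.0  # percent identity
    kw_alpha: float = 0.05
    lda_threshold: float = 4.0
    n_permutations: int = 999
    seed: int | None = None
    granularity: str = "family"
    max_failed_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and self.seed is None:
            raise ValueError("seed is required when permutation tests are requested")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _float_fmt(x: float) -> str:
    return format(x, ".6g")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write TSV/JSON outputs under ``config.outdir``.

    Returns the report dict (also written as ``report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"stages": {}, "quarantined": {}}

    # --- read ---------------------------------------------------------
    gff_paths = sorted(Path(config.gff_dir).glob("*.gff"))
    genes_by_genome: dict[str, list] = {}
    hits_by_genome: dict[str, list] = {}
    failed: dict[str, str] = {}
    for p in gff_paths:
        gid = p.stem
        try:
            genes_by_genome[gid] = io_mod.read_gff(p, genome_id=gid)
            ov = Path(config.overview_dir) / f"{gid}.tsv"
            hits_by_genome[gid] = io_mod.read_dbcan_overview(ov) if ov.exists() else []
        except Exception as exc:  # noqa: BLE001 — quarantine, don't die
            failed[gid] = str(exc)
            genes_by_genome.pop(gid, None)
    if gff_paths and len(failed) > config.max_failed_fraction * len(gff_paths):
        raise RuntimeError(f"more than {config.max_failed_fraction:.0%} of genomes failed: {failed}")
    report["quarantined"] = failed
    report["stages"]["read"] = {"n_genomes": len(genes_by_genome)}

    metadata = io_mod.read_metadata(config.metadata)
    metadata = [m for m in metadata if m.genome_id in genes_by_genome]

    # --- consensus ----------------------------------------------------
    calls_by_genome = {gid: call_genome(h) for gid, h in hits_by_genome.items()}
    _write_tsv(calls_to_frame(calls_by_genome), outdir / "calls.tsv")
    report["stages"]["consensus"] = {
        "n_classified": int(
            sum(c.is_classified for calls in calls_by_genome.values() for c in calls.values())
        )
    }

    # --- quality filter + class grouping ------------------------------
    retained, exclusion_log = metrics_mod.quality_filter(
        metadata, calls_by_genome, config.min_completeness, config.max_contamination,
        config.min_cazymes,
    )
    _write_tsv(exclusion_log, outdir / "excluded_genomes.tsv")
    meta_retained = [m for m in metadata if m.genome_id in set(retained)]
    groups = metrics_mod.group_small_classes(meta_retained, config.min_class_size)
    report["stages"]["quality_filter"] = {
        "n_retained": len(retained), "n_excluded": len(exclusion_log),
        "n_groups": len(set(groups.values())),
    }

    # --- roles + CGC --------------------------------------------------
    roles_by_genome: dict[str, list] = {}
    all_cgcs: list = []
    frac_rows = []
    for gid in retained:
        roles = cgc_mod.assign_auxiliary(genes_by_genome[gid], calls_by_genome[gid])
        roles_by_genome[gid] = roles
        cgcs = cgc_mod.detect_cgcs_genome(roles, max_gap=config.max_gap)
        all_cgcs.extend(cgcs)
        frac_rows.append(
            {"genome_id": gid, **cgc_mod.cgc_fractions(roles, cgcs, calls_by_genome[gid])}
        )
    cgc_mod.write_cgc_tsv(all_cgcs, roles_by_genome, outdir / "cgcs.tsv")
    cgc_mod.write_cgc_bed(all_cgcs, genes_by_genome, outdir / "cgcs.bed")
    _write_tsv(pd.DataFrame(frac_rows), outdir / "cgc_fractions.tsv")
    report["stages"]["cgc"] = {"n_cgcs": len(all_cgcs)}

    # --- substrates + secretion ---------------------------------------
    smap = (
        sub_mod.SubstrateMap.from_tsv(config.substrate_map)
        if config.substrate_map
        else sub_mod.SubstrateMap.default()
    )
    sp_by_gene: dict[str, io_mod.SignalPeptideCall] = {}
    secretion_status = "ok"
    if config.signalp and Path(config.signalp).exists():
        sp_by_gene = {c.gene_id: c for c in io_mod.read_signalp(config.signalp)}
    else:
        secretion_status = "skipped: missing input" if config.signalp else "skipped: not configured"
    profile_rows = []
    for gid in retained:
        ann = sub_mod.assign_substrates(calls_by_genome[gid].values(), smap)
        if secretion_status == "ok":
            profile_rows.append(sub_mod.substrate_profile(gid, ann, sp_by_gene))
        else:
            row = {"genome_id": gid}
            counts = sub_mod.category_counts(ann)
            for cat in sub_mod.SUBSTRATE_CATEGORIES:
                row[f"n_{cat}"] = counts[cat]
            row["n_unassigned"] = counts[sub_mod.UNASSIGNED]
            row["assigned_ratio"] = sub_mod.assigned_ratio(ann)
            profile_rows.append(row)
    _write_tsv(pd.DataFrame(profile_rows), outdir / "substrate_profiles.tsv")
    report["stages"]["substrates"] = {"secretion": secretion_status}

    # --- per-genome metrics -------------------------------------------
    n_prot = {m.genome_id: m.n_proteins for m in meta_retained}
    summaries = [
        metrics_mod.summarise_genome(
            gid, calls_by_genome[gid], n_prot[gid], config.trend_threshold
        )
        for gid in retained
    ]
    summary_frame = metrics_mod.summaries_to_frame(summaries)
    _write_tsv(summary_frame, outdir / "genome_summaries.tsv")
    if not summary_frame.empty:
        _write_tsv(metrics_mod.taxon_aggregate(summary_frame, groups),
                   outdir / "taxon_aggregates.tsv")
    report["stages"]["metrics"] = {"n_summaries": len(summaries)}

    # --- profile matrix + distances -----------------------------------
    retained_calls = {gid: calls_by_genome[gid] for gid in retained}
    presence = stats_mod.profile_matrix(retained_calls, granularity=config.granularity)
    _write_tsv(presence, outdir / "presence_matrix.tsv", index=True)
    report["stages"]["profile"] = {"n_families": presence.shape[1]}
    if presence.empty or presence.shape[1] == 0:
        report["stages"]["stats"] = {"status": "skipped: empty profile"}
    else:
        rare = metrics_mod.rare_families(presence, config.rare_threshold)
        (outdir / "rare_families.txt").write_text("\n".join(rare) + ("\n" if rare else ""))
        dm = stats_mod.jaccard_matrix(presence)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / "jaccard_distances.tsv", sep="\t", float_format="%.10g"
        )
        ordination = stats_mod.pcoa(dm)
        _write_tsv(ordination.coordinates, outdir / "pcoa_coordinates.tsv", index=True)

        stats_report: dict = {"n_rare_families": len(rare)}
        group_vec = [groups[g] for g in presence.index]
        sizes = pd.Series(group_vec).value_counts()
        if len(sizes) >= 2 and (sizes >= 2).all():
            perm = stats_mod.permanova(dm, group_vec, config.n_permutations, config.seed)
            ano = stats_mod.anosim(dm, group_vec, config.n_permutations, config.seed)
            stats_report.update(
                permanova_F=perm.statistic, permanova_p=perm.p_value,
                anosim_R=ano.statistic, anosim_p=ano.p_value,
            )
            enr = stats_mod.kw_enrichment(presence, groups, alpha=config.kw_alpha)
            lda = stats_mod.lda_effect_size(
                presence, groups, kw_alpha=config.kw_alpha, seed=config.seed or 0
            )
            enr = enr.merge(lda[["family_label", "lda_score", "enriched_group"]],
                            on="family_label", how="left", suffixes=("", "_lda"))
            _write_tsv(enr, outdir / "enrichment.tsv")
            stats_report["n_enriched"] = int(enr["significant"].sum())
        else:
            stats_report["group_tests"] = "skipped: need >=2 groups with >=2 genomes"
        report["stages"]["stats"] = stats_report

    # --- novelty ------------------------------------------------------
    if config.outfmt6 and Path(config.outfmt6).exists():
        hits = io_mod.read_outfmt6(config.outfmt6)
        fam_by_gene = {
            c.gene_id: ";".join(m.label for m in c.modules)
            for calls in retained_calls.values()
            for c in calls.values()
            if c.is_classified
        }
        records = novelty_mod.best_hits(
            hits, queries=sorted(fam_by_gene), family_by_gene=fam_by_gene,
            low_identity=config.novelty_threshold,
        )
        _write_tsv(
            novelty_mod.novelty_summary(records, low_identity=config.novelty_threshold),
            outdir / "novelty_summary.tsv",
        )
        frac_low = [r.low_identity_flag for r in records if r.best_identity is not None]
        report["stages"]["novelty"] = {
            "n_scored": len(frac_low),
            "fraction_low_identity": (sum(frac_low) / len(frac_low)) if frac_low else None,
        }
    else:
        report["stages"]["novelty"] = {"status": "skipped: missing input"}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        for stage, info in report["stages"].items():
            fh.write(f"{stage}: {json.dumps(info, sort_keys=True)}\n")
    return report
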