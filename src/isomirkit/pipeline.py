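"""Stage orchestration: each stage reads files named in the config, runs the
corresponding library module, writes its outputs under the configured output
directory, and records a run manifest (config snapshot, input checksums,
output paths, warnings).  Manifests contain no timestamps, so identical
config + seed yields byte-identical outputs.

All randomness flows from the single config ``rng_seed`` through fixed
per-stage offsets: simulate draws sub-seeds seed+0..seed+3, the surrogate
stage's per-study random control uses seed + study index.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, catalog, enrichment, io, sites, surrogate, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "catalog", "sites", "enrich", "surrogate")


@dataclass
class RunManifest:
    stage: str
    config: dict
    tool_version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def checksum_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[str(path)] = digest

    def record_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        io.write_json(
            path,
            {
                "stage": self.stage,
                "tool_version": self.tool_version,
                "config": self.config,
                "input_checksums": self.input_checksums,
                "outputs": self.outputs,
                "warnings": self.warnings,
            },
        )
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise RuntimeError(f"manifest lists outputs that were not written: {missing}")


def _new_manifest(stage: str, config: PipelineConfig) -> RunManifest:
    return RunManifest(stage=stage, config=config.to_dict(), tool_version=__version__)


def run_stage(stage: str, config: PipelineConfig) -> RunManifest:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "simulate": run_simulate,
        "catalog": run_catalog,
        "sites": run_sites,
        "enrich": run_enrich,
        "surrogate": run_surrogate,
    }[stage]
    manifest = runner(config, out)
    manifest.write(out / f"{stage}_manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out: Path) -> RunManifest:
    """Generate a complete toy data set: locus, read pool, UTRome with
    planted sites, a DE table repressing the planted 3p.1 targets, and a
    host-gene-coupled compendium."""
    m = _new_manifest("simulate", config)
    seed = config.rng_seed
    locus = synthetic.gen_locus(seed)

    # references: the hairpin FASTA record carries the full genomic context
    # (flanks included) so templated-extension calls need no sidecar flanks
    ctx = locus.context
    ann = locus.mature("3p")
    ms = len(locus.flank5) + ann.start
    mature_3p2 = ctx[ms : ms + ann.length]
    mature_3p1 = ctx[ms + 1 : ms + 1 + ann.length]  # 5' shifted by -1
    ann5 = locus.mature("5p")
    ms5 = len(locus.flank5) + ann5.start
    mature_5p = ctx[ms5 : ms5 + ann5.length]

    io.write_fasta(out / "hairpin.fasta", {locus.hairpin_name: ctx})
    io.write_fasta(
        out / "mature.fasta",
        {
            f"{locus.hairpin_name}-5p": mature_5p,
            f"{locus.hairpin_name}-3p.1": mature_3p1,
            f"{locus.hairpin_name}-3p.2": mature_3p2,
        },
    )
    coords = pd.DataFrame(
        [
            {"name": f"{locus.hairpin_name}-5p", "hairpin_name": locus.hairpin_name, "start": ms5, "arm": "5p"},
            {"name": f"{locus.hairpin_name}-3p.2", "hairpin_name": locus.hairpin_name, "start": ms, "arm": "3p"},
        ]
    )
    coords.to_csv(out / "mature_coords.tsv", sep="\t", index=False)

    pool, truth = synthetic.gen_read_pool(
        locus, synthetic.default_read_composition(), rng_seed=seed + 1, arm="3p"
    )
    io.write_seq_counts(out / "reads.tsv", pool)
    io.write_fastq(out / "reads.fastq", pool)
    truth.to_csv(out / "read_truth.tsv", sep="\t", index=False)

    # UTRome with planted sites for the two 3p seed registers
    mirna_seqs = {"3p.1": mature_3p1, "3p.2": mature_3p2}
    planting = []
    site_cycle = ["8mer", "7mer-m8", "7mer-A1"]
    n_genes = 300
    for i in range(50):
        planting.append(
            synthetic.PlantedTargetTruth(
                gene=f"g{i + 1:04d}", planted_isomir="3p.1",
                site_type=site_cycle[i % 3], utr_position=10,
            )
        )
    for i in range(50, 80):
        planting.append(
            synthetic.PlantedTargetTruth(
                gene=f"g{i + 1:04d}", planted_isomir="3p.2",
                site_type=site_cycle[i % 3], utr_position=20,
            )
        )
    utrome, site_truth = synthetic.gen_utrome(
        n_genes, planting, mirna_seqs, rng_seed=seed + 2
    )
    io.write_fasta(out / "utrs.fasta", utrome)
    site_truth.to_csv(out / "site_truth.tsv", sep="\t", index=False)

    targets_3p1 = set(site_truth.loc[site_truth["isomir"] == "3p.1", "gene"])
    de = synthetic.gen_de_table(
        truth_targets=targets_3p1, effect_delta=1.0, noise_sd=0.5,
        n_genes=n_genes, rng_seed=seed + 3,
    )
    io.write_de_table(out / "de.tsv", de)

    comp_spec = synthetic.CompendiumSpec(host_gene=config.host_gene, rng_seed=seed + 4)
    studies, comp_manifest = synthetic.gen_compendium(comp_spec)
    io.write_compendium_dir(out / "compendium", studies, comp_manifest)
    with open(out / "compendium_targets.tsv", "w") as fh:
        fh.write("\n".join(comp_manifest["targets"]) + "\n")

    for name in (
        "hairpin.fasta", "mature.fasta", "mature_coords.tsv", "reads.tsv",
        "reads.fastq", "read_truth.tsv", "utrs.fasta", "site_truth.tsv",
        "de.tsv", "compendium/manifest.json", "compendium_targets.tsv",
    ):
        m.record_output(out / name)
    return m


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def _load_references(config: PipelineConfig) -> tuple[list[catalog.MatureRef], dict[str, catalog.HairpinContext]]:
    hairpins_fa = io.read_fasta(_required(config.hairpin_fasta, "hairpin_fasta"))
    matures_fa = io.read_fasta(_required(config.mature_fasta, "mature_fasta"))
    coords = io.read_mature_coords(_required(config.mature_coords, "mature_coords"))
    hairpins = {
        name: catalog.HairpinContext(name=name, hairpin_seq=seq)
        for name, seq in hairpins_fa.items()
    }
    refs = []
    for row in coords.itertuples(index=False):
        if row.name not in matures_fa:
            raise ValueError(f"coordinate row names unknown mature {row.name!r}")
        refs.append(
            catalog.MatureRef(
                name=row.name,
                sequence=matures_fa[row.name],
                hairpin_name=row.hairpin_name,
                start=int(row.start),
                arm=row.arm,
            )
        )
    return refs, hairpins


def _required(value: str | None, key: str) -> str:
    if value is None:
        raise ValueError(f"config key {key!r} is required for this stage")
    return value


def run_catalog(config: PipelineConfig, out: Path) -> RunManifest:
    """Catalogue reads against the references and summarise the results."""
    m = _new_manifest("catalog", config)
    refs, hairpins = _load_references(config)
    reads_path = _required(config.reads, "reads")
    for p in (config.hairpin_fasta, config.mature_fasta, config.mature_coords, reads_path):
        m.checksum_input(p)
    if reads_path.endswith((".fastq", ".fq")):
        pool = io.read_fastq_counts(reads_path)
    else:
        pool = io.read_seq_counts(reads_path)

    records, rejects = catalog.build_catalog(
        pool.itertuples(index=False), refs, hairpins
    )
    cat_df = pd.DataFrame(
        [
            {
                "sequence": r.sequence, "count": r.count, "ref": r.ref,
                "five_prime_offset": r.five_prime_offset,
                "three_prime_offset": r.three_prime_offset,
                "nontemplated_tail": r.nontemplated_tail,
                "templated": r.templated, "seed": r.seed,
                "category": r.category, "ambiguous": r.ambiguous,
            }
            for r in records
        ]
    ).sort_values("sequence").reset_index(drop=True)
    cat_df.to_csv(out / "catalog.tsv", sep="\t", index=False)

    group_rows = []
    for mirna in sorted({r.ref for r in records}):
        recs = [r for r in records if r.ref == mirna]
        for g in catalog.group_by_seed(recs):
            group_rows.append(
                {
                    "mirna": mirna, "suffix_name": g.suffix_name, "seed": g.seed,
                    "total_count": g.total_count,
                    "fraction_of_mirna": g.fraction_of_mirna,
                    "representative": g.representative,
                }
            )
    pd.DataFrame(group_rows).to_csv(out / "seed_groups.tsv", sep="\t", index=False)

    calls = catalog.call_5p_isomirs(
        records,
        min_reads=config.min_reads,
        min_fraction=config.min_fraction,
        fraction_denominator=config.fraction_denominator,
    )
    pd.DataFrame([vars(c) for c in calls]).to_csv(
        out / "fiveprime_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(rejects, columns=["sequence", "count"]).to_csv(
        out / "rejects.tsv", sep="\t", index=False
    )
    if rejects:
        m.warnings.append(f"{len(rejects)} distinct sequences unassigned")
    tails = catalog.tail_composition(records)
    io.write_json(out / "tail_composition.json", tails)
    for name in ("catalog.tsv", "seed_groups.tsv", "fiveprime_calls.tsv", "rejects.tsv", "tail_composition.json"):
        m.record_output(out / name)
    return m


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

def run_sites(config: PipelineConfig, out: Path) -> RunManifest:
    """Derive site motifs per mature sequence, scan the UTRome, and write
    per-isomiR hit tables and predicted-target sets."""
    m = _new_manifest("sites", config)
    matures = io.read_fasta(_required(config.mature_fasta, "mature_fasta"))
    utrome = io.read_fasta(_required(config.utr_fasta, "utr_fasta"))
    m.checksum_input(config.mature_fasta)
    m.checksum_input(config.utr_fasta)

    hit_rows, target_rows = [], []
    for name in sorted(matures):
        motifs = sites.site_motifs(matures[name], isomir=name)
        for gene in sorted(utrome):
            for h in sites.scan_utr(utrome[gene], motifs, gene):
                hit_rows.append(
                    {
                        "gene": gene, "isomir": name, "start": h.position,
                        "end": h.position + 6, "site_type": h.site_type,
                    }
                )
        tset = sites.predict_targets(utrome, motifs, config.min_site_type)
        target_rows.extend({"isomir": name, "gene": g} for g in sorted(tset.genes))

    pd.DataFrame(hit_rows, columns=["gene", "isomir", "start", "end", "site_type"]).to_csv(
        out / "site_hits.tsv", sep="\t", index=False
    )
    pd.DataFrame(target_rows, columns=["isomir", "gene"]).to_csv(
        out / "target_sets.tsv", sep="\t", index=False
    )
    for name in ("site_hits.tsv", "target_sets.tsv"):
        m.record_output(out / name)
    return m


# ---------------------------------------------------------------------------
# enrich
# ---------------------------------------------------------------------------

def run_enrich(config: PipelineConfig, out: Path) -> RunManifest:
    """Ranked-list landscapes for each mature's 7mer-m8 word plus target
    fold-change summaries against the DE table."""
    m = _new_manifest("enrich", config)
    de = io.read_de_table(_required(config.de_table, "de_table"))
    utrome = io.read_fasta(_required(config.utr_fasta, "utr_fasta"))
    matures = io.read_fasta(_required(config.mature_fasta, "mature_fasta"))
    for p in (config.de_table, config.utr_fasta, config.mature_fasta):
        m.checksum_input(p)

    ranked = enrichment.rank_genes(de)
    step = min(config.landscape_step, len(ranked))
    summary: dict = {"landscapes": {}, "target_stats": {}}
    for name in sorted(matures):
        motifs = sites.site_motifs(matures[name], isomir=name)
        land = enrichment.word_landscape(ranked, utrome, motifs.seven_m8, step=step)
        pd.DataFrame({"cutoff": land.cutoffs, "value": land.values}).to_csv(
            out / f"landscape_{name}.tsv", sep="\t", index=False
        )
        m.record_output(out / f"landscape_{name}.tsv")
        peak_cut, peak_val = land.peak()
        summary["landscapes"][name] = {
            "word": land.word,
            "n_genes": land.n_genes,
            "n_with_word": land.n_with_word,
            "n_dropped_no_utr": land.n_dropped_no_utr,
            "peak_cutoff": peak_cut,
            "peak_value": peak_val,
            "metadata": land.metadata,
        }
        tset = sites.predict_targets(utrome, motifs, config.min_site_type)
        stats_entry = {
            "n_targets": len(tset.genes),
            "mean_log2fc": enrichment.target_fc_summary(de, tset.genes, "mean"),
            "median_log2fc": enrichment.target_fc_summary(de, tset.genes, "median"),
        }
        for direction in ("up", "down", "no_change"):
            stats_entry[f"pct_{direction}"] = enrichment.percent_targets(
                de, tset.genes, direction, config.alpha
            )
        if tset.genes & set(de["gene"]):
            curve = enrichment.cumulative_fraction(de, tset.genes)
            stats_entry["cumulative_fraction_at_minus1"] = curve.value_at(-1.0)
        summary["target_stats"][name] = stats_entry

    io.write_json(out / "enrichment_summary.json", summary)
    m.record_output(out / "enrichment_summary.json")
    return m


# ---------------------------------------------------------------------------
# surrogate
# ---------------------------------------------------------------------------

def run_surrogate(config: PipelineConfig, out: Path) -> RunManifest:
    """Host-gene surrogate analysis over a compendium directory."""
    m = _new_manifest("surrogate", config)
    comp_dir = _required(config.compendium_dir, "compendium_dir")
    studies, comp_manifest = io.read_compendium_dir(comp_dir)
    m.checksum_input(Path(comp_dir) / "manifest.json")

    target_sets: dict[str, set[str]] = {}
    for set_id, path in sorted(config.target_lists.items()):
        target_sets[set_id] = io.read_target_list(path)
        m.checksum_input(path)
    if not target_sets:
        raise ValueError("surrogate stage needs at least one entry in target_lists")

    host = config.host_gene
    comparisons = [
        surrogate.StudyComparison.from_table(sid, de, host)
        for sid, de in sorted(studies.items())
        if (de["gene"] == host).any()
    ]
    n_missing = len(studies) - len(comparisons)
    if n_missing:
        m.warnings.append(f"{n_missing} studies lacked host gene {host}")
    kept = surrogate.filter_studies(comparisons, host, alpha=config.alpha)
    m.warnings.append(f"{len(comparisons) - len(kept)} studies failed the host significance filter")

    summaries = [
        surrogate.study_summary(
            s, target_sets,
            random_set_size=config.random_set_size,
            rng_seed=config.rng_seed + i,
            alpha=config.alpha,
        )
        for i, s in enumerate(kept)
    ]

    sum_rows = []
    for s in summaries:
        for set_id in list(target_sets) + ["random"]:
            sum_rows.append(
                {
                    "study_id": s.study_id, "target_set": set_id,
                    "host_log2fc": s.host_log2fc,
                    "mean_target_log2fc": s.mean_target_log2fc[set_id],
                    "pct_targets_up": s.pct_targets_up[set_id],
                    "pct_targets_down": s.pct_targets_down[set_id],
                    "enrichment_up_down": s.enrichment_up_down[set_id],
                }
            )
    pd.DataFrame(sum_rows).to_csv(out / "surrogate_summaries.tsv", sep="\t", index=False)
    m.record_output(out / "surrogate_summaries.tsv")

    regressions = {}
    for set_id in list(target_sets) + ["random"]:
        res = surrogate.regress_targets_vs_host(summaries, set_id)
        regressions[set_id] = vars(res)
        for branch in ("from_most_up", "from_most_down"):
            trend = surrogate.cumulative_mean_trend(summaries, set_id, branch)
            fname = f"trend_{set_id}_{branch}.tsv"
            trend.to_csv(out / fname, sep="\t", index=False)
            m.record_output(out / fname)
    io.write_json(out / "surrogate_regression.json", regressions)
    m.record_output(out / "surrogate_regression.json")
    return m
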