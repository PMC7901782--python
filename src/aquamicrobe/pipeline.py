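"""End-to-end orchestration: generate -> qc -> quantify -> validate ->
diversity -> nitrogen -> associate, from a single serializable config.

Every stage reads and writes plain text artifacts (FASTQ, PAF, TSV) so each
is independently runnable and inspectable, and a JSON manifest records
per-stage parameters, input/output hashes, seeds and wall time. A single
global seed is expanded into fixed per-stage sub-seeds so adding a stage
never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc_mod
from . import diversity as div_mod
from . import em as em_mod
from . import nitrogen as nit_mod
from . import qc as qc_mod
from . import synthetic as syn_mod
from . import validation as val_mod
from .io_formats import (
    CountTable,
    write_chemistry,
    write_count_table,
    write_fastq,
    write_paf,
    write_phenotypes,
    write_taxonomy,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Fixed stage order and seed slots; appending here never shifts existing slots.
STAGES = ("generate", "qc", "quantify", "validate", "diversity", "nitrogen", "associate")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults follow the study's analysis."""

    seed: int = 42
    # generator
    n_genera: int = 5
    seqs_per_genus: int = 3
    library_scale: float = 8.0  # desk-scale shrink factor on library sizes
    # read QC
    trim5: int = 10
    max_len: int = 1500
    max_ee: float = 200.0
    max_n: int = 2
    # quantification
    max_alignments: int = 100
    em_tolerance: float = 1e-6
    em_max_iterations: int = 1000
    count_cutoff: float = 300.0
    rank: str = "genus"
    kmer_size: int = 9
    # diversity
    rarefaction_depth: int = 9000
    permutations: int = 999
    distance_metric: str = "braycurtis"
    # association
    fdr_level: float = 0.05
    responses: tuple[str, ...] = (
        "inoculum", "dead_fish", "height", "root_length", "leaves",
        "auc_ammonia", "auc_nitrate",
    )
    stages: tuple[str, ...] = STAGES

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["responses"] = list(self.responses)
        data["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        data["responses"] = tuple(data.get("responses", cls.responses))
        data["stages"] = tuple(data.get("stages", STAGES))
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Per-stage sub-seed derived from the global seed; stable under
        pipeline growth because the slot index is fixed."""
        slot = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(slot,))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path], params: dict[str, Any],
               seconds: float, **extra: Any) -> None:
        self.stages[stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "hashes": {k: _sha256(v) for k, v in outputs.items()},
            "params": params,
            "wall_time_s": round(seconds, 3),
            **extra,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "version": self.version, "stages": self.stages}
        Path(path).write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute all enabled stages in dependency order on synthetic inputs.

    Stage outputs land under ``outdir``; a missing upstream output raises an
    error naming the stage. Returns the populated manifest (also written as
    ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    state: dict[str, Any] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        runner = _STAGE_RUNNERS[stage]
        runner(config, out, state, manifest)
        logger.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
    manifest.to_json(out / "manifest.json")
    return manifest


def _require(state: dict, key: str, stage: str) -> Any:
    if key not in state:
        raise RuntimeError(f"stage {stage!r}: missing upstream output {key!r}")
    return state[key]


def _run_generate(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    seed = config.stage_seed("generate")
    rng = np.random.default_rng(seed)
    design = syn_mod.StudyDesign().desk_scale(config.library_scale)
    db = syn_mod.generate_reference_db(
        n_genera=config.n_genera, seqs_per_genus=config.seqs_per_genus, seed=seed
    )
    profiles = syn_mod.simulate_communities(design, db, seed=seed)
    chem = syn_mod.simulate_water_chemistry(design, seed=seed)
    pheno = syn_mod.simulate_phenotypes(design, profiles, seed=seed)

    lo, hi = design.library_size_range
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    sample_reads: dict[str, list] = {}
    truth_frames = []
    for profile in profiles:
        n_reads = int(rng.integers(lo, hi + 1))
        reads, truth = syn_mod.simulate_reads(profile, db, n_reads, seed=int(rng.integers(2**31)))
        sample_reads[profile.sample_id] = reads
        truth["sample_id"] = profile.sample_id
        truth_frames.append(truth.reset_index())
        write_fastq(reads, reads_dir / f"{profile.sample_id}.fastq")
    truth_all = pd.concat(truth_frames, ignore_index=True)

    outputs = {
        "taxonomy": out / "taxonomy.tsv",
        "chemistry": out / "chemistry.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth_profiles": out / "truth_profiles.tsv",
        "read_truth": out / "read_truth.tsv",
    }
    write_taxonomy(db.taxonomy, outputs["taxonomy"])
    write_chemistry(chem, outputs["chemistry"])
    write_phenotypes(pheno, outputs["phenotypes"])
    syn_mod.profiles_to_frame(profiles).to_csv(outputs["truth_profiles"], sep="\t")
    truth_all.to_csv(outputs["read_truth"], sep="\t", index=False)

    state.update(design=design, db=db, profiles=profiles, chem=chem, pheno=pheno,
                 sample_reads=sample_reads, read_truth=truth_all)
    manifest.record("generate", outputs,
                    {"seed": seed, "library_range": [lo, hi]},
                    time.perf_counter() - t0,
                    n_samples=len(profiles))


def _run_qc(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    sample_reads = _require(state, "sample_reads", "qc")
    params = qc_mod.QCParams(trim5=config.trim5, max_len=config.max_len,
                             max_expected_errors=config.max_ee, max_n=config.max_n)
    passed_dir = out / "qc"
    passed_dir.mkdir(exist_ok=True)
    reports = []
    passed_reads: dict[str, list] = {}
    for sid, reads in sample_reads.items():
        passed, report = qc_mod.run_qc(reads, params)
        passed_reads[sid] = passed
        write_fastq(passed, passed_dir / f"{sid}.fastq")
        reports.append({"sample_id": sid, "n_input": report.n_input,
                        "n_fail_ee": report.n_fail_ee, "n_fail_n": report.n_fail_n,
                        "n_dropped_short": report.n_dropped_short,
                        "n_pass": report.n_pass,
                        "pass_fraction": report.pass_fraction})
    report_df = pd.DataFrame(reports).set_index("sample_id")
    outputs = {"qc_report": out / "qc_report.tsv"}
    report_df.to_csv(outputs["qc_report"], sep="\t")
    state.update(passed_reads=passed_reads, qc_report=report_df)
    manifest.record("qc", outputs, dataclasses.asdict(params), time.perf_counter() - t0,
                    overall_pass_fraction=float(report_df["n_pass"].sum()
                                                / report_df["n_input"].sum()))


def _run_quantify(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    passed_reads = _require(state, "passed_reads", "quantify")
    db = _require(state, "db", "quantify")
    design = _require(state, "design", "quantify")
    params = em_mod.QuantParams(max_alignments=config.max_alignments,
                                tolerance=config.em_tolerance,
                                max_iterations=config.em_max_iterations,
                                count_cutoff=config.count_cutoff)
    # scale the read-count cutoff with the desk-scale factor so its
    # relationship to library size matches the full-scale analysis
    cutoff = config.count_cutoff / config.library_scale
    paf_dir = out / "paf"
    paf_dir.mkdir(exist_ok=True)
    rows = {}
    meta_rows = {}
    for profile in _require(state, "profiles", "quantify"):
        sid = profile.sample_id
        aln = syn_mod.score_alignments(passed_reads[sid], db, k=config.kmer_size,
                                       max_candidates=config.max_alignments)
        write_paf(aln, paf_dir / f"{sid}.paf")
        counts = em_mod.quantify_sample(aln, db.taxonomy, params, rank=config.rank,
                                        method="em", cutoff=cutoff)
        rows[sid] = counts
        meta_rows[sid] = {
            "tank": profile.tank,
            "compartment": profile.compartment,
            "inoculum": design.inoculum_of(profile.tank),
            "day": profile.day,
            "dead_fish": design.deaths_of(profile.tank),
        }
    counts_df = pd.DataFrame(rows).T.fillna(0.0)
    counts_df.index.name = "sample_id"
    meta_df = pd.DataFrame(meta_rows).T
    meta_df.index.name = "sample_id"
    table = CountTable(counts_df, meta_df)
    outputs = {"counts": out / "counts.tsv", "metadata": out / "metadata.tsv"}
    write_count_table(table, outputs["counts"], outputs["metadata"])
    state["count_table"] = table
    manifest.record("quantify", outputs,
                    {**dataclasses.asdict(params), "effective_cutoff": cutoff},
                    time.perf_counter() - t0,
                    n_samples=len(counts_df), n_taxa=counts_df.shape[1])


def _run_validate(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    table = _require(state, "count_table", "validate")
    profiles = _require(state, "profiles", "validate")
    truth = syn_mod.profiles_to_frame(profiles)
    genus_cols = [c for c in truth.columns if c not in ("tank", "compartment", "day")]
    est_sum = table.counts.sum(axis=0)
    truth_sum = (truth[genus_cols]).sum(axis=0) * table.counts.sum().sum() / len(truth)
    concordance = val_mod.compare_platforms(est_sum, truth_sum, rank=config.rank)
    est_sp, truth_sp = syn_mod.simulate_validation_tables(seed=config.stage_seed("validate"))
    spurious = val_mod.spurious_fraction_removed(est_sp, truth_sp, cutoff=config.count_cutoff)
    nitrifiers = val_mod.detect_taxa(table.counts, cutoff=config.count_cutoff)
    outputs = {"validation": out / "validation.tsv", "nitrifiers": out / "nitrifiers.tsv"}
    pd.DataFrame([{
        "rank": concordance.rank,
        "n_shared": concordance.n_shared_taxa,
        "n_spurious": concordance.n_spurious,
        "r_squared": concordance.r_squared,
        "spearman_rho": concordance.spearman_rho,
        "spurious_fraction_removed": spurious.fraction_removed,
    }]).to_csv(outputs["validation"], sep="\t", index=False)
    nitrifiers.to_csv(outputs["nitrifiers"], sep="\t", index=False)
    state.update(concordance=concordance, spurious_report=spurious)
    manifest.record("validate", outputs, {"cutoff": config.count_cutoff},
                    time.perf_counter() - t0)


def _run_diversity(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    table = _require(state, "count_table", "diversity")
    seed = config.stage_seed("diversity")
    depth = int(config.rarefaction_depth / config.library_scale)
    sums = table.counts.sum(axis=1)
    too_small = sums[sums < depth]
    if len(too_small):
        raise ValueError(
            f"rarefaction depth {depth} exceeds library size of samples "
            f"{too_small.index.tolist()[:5]}"
        )
    rare = div_mod.rarefy_table(table.counts.round().astype(int), depth, seed=seed)
    alpha = rare.apply(div_mod.shannon, axis=1).rename("shannon")
    dist = div_mod.bray_curtis(rare, metric=config.distance_metric)
    coords, evals, props = div_mod.pcoa(dist)
    meta = table.metadata.copy()
    meta["compartment"] = meta["compartment"].astype(str)
    meta["inoculum"] = meta["inoculum"].astype(str)
    perm = div_mod.permanova(dist, meta,
                             ["compartment", "inoculum", "compartment:inoculum"],
                             n_perm=config.permutations, seed=seed)
    outputs = {
        "alpha": out / "alpha_diversity.tsv",
        "pcoa": out / "pcoa_coords.tsv",
        "permanova": out / "permanova.tsv",
    }
    alpha.to_frame().to_csv(outputs["alpha"], sep="\t")
    coords.iloc[:, :4].to_csv(outputs["pcoa"], sep="\t")
    perm.table.to_csv(outputs["permanova"], sep="\t")
    state.update(alpha=alpha, permanova=perm, pcoa=(coords, evals, props))
    manifest.record("diversity", outputs,
                    {"depth": depth, "metric": config.distance_metric,
                     "n_perm": config.permutations, "seed": seed},
                    time.perf_counter() - t0)


def _run_nitrogen(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    chem = _require(state, "chem", "nitrogen")
    design = _require(state, "design", "nitrogen")
    inoculum = pd.Series({t: design.inoculum_of(t) for t in design.tanks})
    deaths = pd.Series({t: design.deaths_of(t) for t in design.tanks})
    aunc = nit_mod.tank_aucs(chem, "nitrate")
    partition = nit_mod.fit_nitrate_model(aunc, inoculum, deaths)
    t_stat, df, welch_p = nit_mod.welch_t_test(
        aunc[inoculum == "CIT"], aunc[inoculum == "EIT"]
    )
    screen = nit_mod.chemistry_screen(chem, inoculum)
    rho, rho_p = assoc_mod.spearman_corr(deaths.loc[aunc.index], aunc)
    outputs = {"aunc": out / "aunc.tsv", "nitrate_model": out / "nitrate_model.tsv",
               "chemistry_screen": out / "chemistry_screen.tsv"}
    aunc.to_frame().to_csv(outputs["aunc"], sep="\t")
    partition.table.to_csv(outputs["nitrate_model"], sep="\t")
    screen.to_csv(outputs["chemistry_screen"], sep="\t")
    state.update(aunc=aunc, nitrate_partition=partition, welch_p=welch_p,
                 chemistry_screen=screen, deaths_aunc_spearman=(rho, rho_p))
    manifest.record("nitrogen", outputs, {}, time.perf_counter() - t0,
                    welch_p=welch_p)


def _per_sample_responses(table: CountTable, design, chem, pheno,
                          responses: tuple[str, ...]) -> pd.DataFrame:
    """Response columns aligned to the count table's samples.

    Phenotypes are per-tank averages at the sample's day (nearest measured
    day); chemistry AUCs and dead-fish counts are per-tank scalars.
    """
    meta = table.metadata
    out = pd.DataFrame(index=meta.index)
    for resp in responses:
        if resp == "inoculum":
            out[resp] = (meta["inoculum"].astype(str) == "EIT").astype(float)
        elif resp == "dead_fish":
            out[resp] = meta["dead_fish"].astype(float)
        elif resp in ("height", "root_length", "leaves"):
            col = {"height": "height_cm", "root_length": "root_length_cm",
                   "leaves": "leaves"}[resp]
            vals = []
            days = np.array(sorted(pheno["day"].unique()))
            for sid in meta.index:
                tank = int(meta.loc[sid, "tank"])
                day = int(meta.loc[sid, "day"])
                nearest = int(days[np.argmin(np.abs(days - day))])
                sub = pheno[(pheno["tank"] == tank) & (pheno["day"] == nearest)]
                vals.append(float(sub[col].mean()))
            out[resp] = vals
        elif resp.startswith("auc_"):
            analyte = resp[4:]
            aucs = nit_mod.tank_aucs(chem, analyte)
            out[resp] = meta["tank"].astype(int).map(aucs).astype(float)
        else:
            raise ValueError(f"unknown response {resp!r}")
    return out


def _run_associate(config: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    table = _require(state, "count_table", "associate")
    design = _require(state, "design", "associate")
    chem = _require(state, "chem", "associate")
    pheno = _require(state, "pheno", "associate")
    cutoff = config.count_cutoff / config.library_scale
    frames = []
    for compartment in design.compartments:
        in_compartment = table.metadata["compartment"].astype(str) == compartment
        treated = table.metadata["tank"].astype(int) > 0  # drop shared day-0 samples
        sub = table.subset(in_compartment & treated)
        if len(sub.sample_ids) < 4:
            continue
        responses = _per_sample_responses(sub, design, chem, pheno, config.responses)
        responses = responses.loc[:, responses.nunique() > 1]
        res = assoc_mod.associate(sub.counts, responses, report_cutoff=cutoff)
        res.insert(0, "compartment", compartment)
        frames.append(res)
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    outputs = {"associations": out / "associations.tsv"}
    results.to_csv(outputs["associations"], sep="\t", index=False)
    state["associations"] = results
    manifest.record("associate", outputs,
                    {"fdr_level": config.fdr_level, "report_cutoff": cutoff},
                    time.perf_counter() - t0,
                    n_tests=len(results))


_STAGE_RUNNERS = {
    "generate": _run_generate,
    "qc": _run_qc,
    "quantify": _run_quantify,
    "validate": _run_validate,
    "diversity": _run_diversity,
    "nitrogen": _run_nitrogen,
    "associate": _run_associate,
}
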