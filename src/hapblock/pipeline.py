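"""End-to-end orchestration of the haploblock prediction experiment.

Stage order: simulate (or load) -> edit markers -> all-SNP fits -> rank
effects -> build haploblocks -> select (QTL / random grid) -> haploblock
fits -> evaluate.  Each stage reads and writes plain-text artifacts inside a
run directory, so stages are individually re-runnable and composable by
hand; ``run_pipeline`` chains them and records a manifest of content hashes,
which makes end-to-end determinism checkable (same config + seed => same
hashes).

The selection source model always matches the prediction model (blocks
ranked by BLUP SNP effects are fit with BLUP, mixture with mixture); asking
for a crossed pairing is a configuration error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import evaluate_grid, format_report, reliability
from .io_formats import (
    DRPTable,
    PedigreeTable,
    PhasedGenotypes,
    edit_markers,
    read_drp,
    read_pedigree,
    read_phased_vcf,
    write_drp,
    write_pedigree,
    write_phased_vcf,
)
from .ldblocks import (
    Haploblock,
    blocks_to_table,
    build_blocks,
    catalogue_variants,
    design_matrix,
)
from .relmat import build_A_inverse
from .samplers import ModelSpec, fit, predict_gebv, snp_effect_table
from .selection import select_qtl_haploblocks, select_random_haploblocks
from .simdata import SimConfig, generation_of, simulate

logger = logging.getLogger("hapblock")


class ConfigError(ValueError):
    """Invalid run configuration (distinct from runtime failures)."""


@dataclass
class RunConfig:
    """Configuration of one full experiment."""

    seed: int = 1
    sim: SimConfig | None = None
    # alternatively, paths to existing inputs:
    vcf: str | None = None
    pedigree_file: str | None = None
    drp_file: str | None = None
    train_ids_file: str | None = None
    test_ids_file: str | None = None

    maf_min: float = 0.01
    prune_complete_ld: bool = True
    dprime_threshold: float = 0.45
    k_grid: tuple = (50, 100, 250, 500, 1000, 2000)
    models: tuple = ("blup",)
    random_k: int | None = None
    random_replicates: int = 0
    chain_length: int = 5000
    burn_in: int = 2000
    thinning: int = 1

    def __post_init__(self) -> None:
        if self.sim is None and self.vcf is None:
            self.sim = SimConfig(seed=self.seed)
        if self.sim is not None and self.vcf is not None:
            raise ConfigError("give either a sim config or input paths, not both")
        if self.vcf is not None and (
            self.pedigree_file is None
            or self.drp_file is None
            or self.train_ids_file is None
            or self.test_ids_file is None
        ):
            raise ConfigError(
                "loading real inputs requires vcf, pedigree_file, drp_file and "
                "train/test id list files"
            )
        for m in self.models:
            if m not in ("blup", "mixture4"):
                raise ConfigError(f"unknown model {m!r}")
        if self.burn_in >= self.chain_length:
            raise ConfigError("burn_in must be smaller than chain_length")
        if not self.k_grid:
            raise ConfigError("k_grid must be nonempty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "qtl_effect_mixture" in sim:
                sim["qtl_effect_mixture"] = tuple(
                    tuple(x) for x in sim["qtl_effect_mixture"]
                )
            if "drp_reliability_range" in sim:
                sim["drp_reliability_range"] = tuple(sim["drp_reliability_range"])
            raw["sim"] = SimConfig(**sim)
        for key in ("k_grid", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def model_spec(self, model: str, seed_offset: int = 0) -> ModelSpec:
        return ModelSpec(
            model=model,
            chain_length=self.chain_length,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=self.seed + seed_offset,
        )


# ---------------------------------------------------------------------------
# run-directory plumbing
# ---------------------------------------------------------------------------

FILES = {
    "genotypes": "genotypes.vcf",
    "pedigree": "pedigree.csv",
    "drp": "drp.csv",
    "truth": "truth.csv",
    "train_ids": "train_ids.txt",
    "test_ids": "test_ids.txt",
    "kept_markers": "kept_markers.tsv",
    "blocks": "blocks.tsv",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-stage record of declared inputs, outputs and content hashes."""

    def __init__(self, rundir: Path):
        self.rundir = Path(rundir)
        self.path = self.rundir / "manifest.json"
        self.data: dict = {"version": __version__, "stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, inputs: list[str], outputs: list[str],
               params: dict | None = None) -> None:
        self.data["stages"][stage] = {
            "inputs": sorted(inputs),
            "params": params or {},
            "outputs": {
                name: _sha256(self.rundir / name) for name in sorted(outputs)
            },
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def output_hashes(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for stage in self.data["stages"].values():
            out.update(stage["outputs"])
        return out


def _require(rundir: Path, *names: str) -> None:
    for name in names:
        if not (rundir / name).exists():
            raise FileNotFoundError(
                f"missing upstream artifact {name!r} in {rundir} — run the "
                "producing stage first"
            )


def _read_ids(path: Path) -> list[str]:
    return path.read_text().split()


def _load_edited(rundir: Path) -> PhasedGenotypes:
    geno = read_phased_vcf(rundir / FILES["genotypes"])
    kept = pd.read_csv(rundir / FILES["kept_markers"], sep="\t")
    lookup = {m: i for i, m in enumerate(geno.markers["marker_id"])}
    return geno.subset_markers(
        np.array([lookup[m] for m in kept["marker_id"]], dtype=np.int64)
    )


def _load_blocks(rundir: Path, geno: PhasedGenotypes,
                 train_ids: list[str]) -> list[Haploblock]:
    """Rebuild catalogued blocks from the persisted spans (deterministic)."""
    table = pd.read_csv(rundir / FILES["blocks"], sep="\t")
    pos = geno.markers["pos"].to_numpy()
    chrom = geno.markers["chrom"].to_numpy().astype(str)
    blocks = []
    for row in table.itertuples(index=False):
        mask = (
            (chrom == str(row.chrom))
            & (pos >= row.start_bp)
            & (pos <= row.end_bp)
        )
        blocks.append(
            Haploblock(
                block_id=row.block_id,
                chrom=str(row.chrom),
                marker_indices=np.flatnonzero(mask),
            )
        )
    for b in blocks:
        catalogue_variants(b, geno, train_ids)
    return blocks


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, rundir: Path, manifest: Manifest) -> None:
    """Generate (or import) genotypes, pedigree, DRP and the train/test split."""
    rundir.mkdir(parents=True, exist_ok=True)
    if config.sim is not None:
        logger.info("simulating population (seed=%d)", config.sim.seed)
        data = simulate(config.sim)
        write_phased_vcf(data.genotypes, rundir / FILES["genotypes"])
        write_pedigree(data.pedigree, rundir / FILES["pedigree"])
        write_drp(data.drp, rundir / FILES["drp"])
        data.truth.to_frame().to_csv(rundir / FILES["truth"], index=False)
        train, test = data.split()
    else:
        geno = read_phased_vcf(config.vcf)
        write_phased_vcf(geno, rundir / FILES["genotypes"])
        write_pedigree(read_pedigree(config.pedigree_file),
                       rundir / FILES["pedigree"])
        write_drp(read_drp(config.drp_file), rundir / FILES["drp"])
        train = _read_ids(Path(config.train_ids_file))
        test = _read_ids(Path(config.test_ids_file))
    (rundir / FILES["train_ids"]).write_text("\n".join(train) + "\n")
    (rundir / FILES["test_ids"]).write_text("\n".join(test) + "\n")
    outputs = [FILES[k] for k in
               ("genotypes", "pedigree", "drp", "train_ids", "test_ids")]
    if (rundir / FILES["truth"]).exists():
        outputs.append(FILES["truth"])
    manifest.record("simulate", [], outputs,
                    {"seed": config.seed})


def stage_edit(config: RunConfig, rundir: Path, manifest: Manifest) -> None:
    """MAF filter and complete-LD pruning; writes the surviving marker list."""
    _require(rundir, FILES["genotypes"])
    geno = read_phased_vcf(rundir / FILES["genotypes"])
    edited = edit_markers(geno, config.maf_min, config.prune_complete_ld)
    logger.info("marker edit: %d -> %d markers", geno.n_markers,
                edited.n_markers)
    edited.markers[["marker_id"]].to_csv(
        rundir / FILES["kept_markers"], sep="\t", index=False
    )
    manifest.record(
        "edit", [FILES["genotypes"]], [FILES["kept_markers"]],
        {"maf_min": config.maf_min, "prune_complete_ld": config.prune_complete_ld},
    )


def _training_fit(config: RunConfig, rundir: Path, model: str, M: np.ndarray,
                  seed_offset: int):
    ped = read_pedigree(rundir / FILES["pedigree"])
    drp = read_drp(rundir / FILES["drp"])
    train = _read_ids(rundir / FILES["train_ids"])
    a_inv = build_A_inverse(ped)
    spec = config.model_spec(model, seed_offset)
    logger.info("fitting %s: n=%d q=%d chain=%d burn-in=%d seed=%d",
                model, len(train), M.shape[1], spec.chain_length, spec.burn_in,
                spec.seed)
    summary = fit(drp.subset(train), M, spec, a_inverse=a_inv,
                  animal_ids=ped.ids)
    return summary


def stage_fit_snp(config: RunConfig, rundir: Path, manifest: Manifest,
                  model: str) -> None:
    """All-SNP fit on the training animals; writes the ranked effect table."""
    _require(rundir, FILES["kept_markers"], FILES["drp"], FILES["pedigree"],
             FILES["train_ids"])
    geno = _load_edited(rundir)
    train = _read_ids(rundir / FILES["train_ids"])
    test = _read_ids(rundir / FILES["test_ids"])
    X = geno.subset_samples(train).dosages().astype(np.float64)
    summary = _training_fit(config, rundir, model, X, seed_offset=11)
    ranked = snp_effect_table(summary, geno.markers)
    out_effects = f"snp_effects_{model}.tsv"
    ranked.to_csv(rundir / out_effects, sep="\t", index=False,
                  float_format="%.10g")
    X_test = geno.subset_samples(test).dosages().astype(np.float64)
    gebv = predict_gebv(summary, X_test, test)
    out_gebv = f"gebv_{model}_snp.tsv"
    pd.DataFrame({"id": test, "gebv": gebv}).to_csv(
        rundir / out_gebv, sep="\t", index=False, float_format="%.10g"
    )
    manifest.record(
        f"fit-snp[{model}]",
        [FILES[k] for k in ("genotypes", "kept_markers", "drp", "pedigree",
                            "train_ids")],
        [out_effects, out_gebv],
        {"model": model, "chain_length": config.chain_length,
         "burn_in": config.burn_in, "seed": config.seed},
    )


def stage_blocks(config: RunConfig, rundir: Path, manifest: Manifest) -> None:
    """Build haploblocks on the training haplotypes; writes block spans."""
    _require(rundir, FILES["kept_markers"], FILES["train_ids"])
    geno = _load_edited(rundir)
    train = _read_ids(rundir / FILES["train_ids"])
    blocks = build_blocks(geno, config.dprime_threshold, train)
    for b in blocks:
        catalogue_variants(b, geno, train)
    table = blocks_to_table(blocks, geno)
    table.to_csv(rundir / FILES["blocks"], sep="\t", index=False)
    logger.info("built %d blocks (%d excluded) at |D'|>=%.2f",
                len(blocks), int(table["excluded"].sum()),
                config.dprime_threshold)
    manifest.record(
        "blocks",
        [FILES[k] for k in ("genotypes", "kept_markers", "train_ids")],
        [FILES["blocks"]],
        {"dprime_threshold": config.dprime_threshold},
    )


def stage_select(config: RunConfig, rundir: Path, manifest: Manifest,
                 model: str, mode: str = "qtl") -> list[str]:
    """Select blocks for every k in the grid (QTL mode) or per replicate."""
    _require(rundir, FILES["blocks"], FILES["kept_markers"])
    geno = _load_edited(rundir)
    train = _read_ids(rundir / FILES["train_ids"])
    blocks = _load_blocks(rundir, geno, train)
    outputs = []
    if mode == "qtl":
        effects_file = f"snp_effects_{model}.tsv"
        _require(rundir, effects_file)
        ranked = pd.read_csv(rundir / effects_file, sep="\t")
        for k in config.k_grid:
            sel = select_qtl_haploblocks(ranked, blocks, k)
            name = f"selection_{model}_qtl_k{k}.tsv"
            pd.DataFrame({"block_id": sel.block_ids}).to_csv(
                rundir / name, sep="\t", index=False
            )
            outputs.append(name)
        inputs = [FILES["blocks"], effects_file]
    elif mode == "random":
        k = config.random_k or config.k_grid[len(config.k_grid) // 2]
        reps = max(config.random_replicates, 1)
        sels = select_random_haploblocks(
            blocks, geno.n_markers, k, seed=config.seed + 101, replicates=reps
        )
        for r, sel in enumerate(sels):
            name = f"selection_{model}_random_k{k}_rep{r}.tsv"
            pd.DataFrame({"block_id": sel.block_ids}).to_csv(
                rundir / name, sep="\t", index=False
            )
            outputs.append(name)
        inputs = [FILES["blocks"]]
    else:
        raise ConfigError(f"unknown selection mode {mode!r}")
    manifest.record(f"select[{model},{mode}]", inputs, outputs,
                    {"mode": mode, "model": model})
    return outputs


def stage_fit_blocks(config: RunConfig, rundir: Path, manifest: Manifest,
                     model: str, selection_model: str | None = None) -> None:
    """Haploblock fits: full block set plus every persisted selection.

    ``selection_model`` exists only to catch crossed pairings: selections
    ranked by one model must be predicted with the same model.
    """
    if selection_model is not None and selection_model != model:
        raise ConfigError(
            f"selection made with {selection_model!r} cannot be fit with "
            f"{model!r}: the selection source must match the prediction model"
        )
    _require(rundir, FILES["blocks"], FILES["drp"], FILES["pedigree"])
    geno = _load_edited(rundir)
    train = _read_ids(rundir / FILES["train_ids"])
    test = _read_ids(rundir / FILES["test_ids"])
    blocks = _load_blocks(rundir, geno, train)
    included = [b for b in blocks if not b.excluded]
    by_id = {b.block_id: b for b in blocks}

    jobs: list[tuple[str, list[Haploblock]]] = [("full", included)]
    for path in sorted(rundir.glob(f"selection_{model}_*.tsv")):
        ids = pd.read_csv(path, sep="\t")["block_id"].tolist()
        label = path.stem.replace(f"selection_{model}_", "")
        jobs.append((label, [by_id[i] for i in ids]))

    outputs = []
    for offset, (label, job_blocks) in enumerate(jobs):
        design_train = design_matrix(job_blocks, geno, train)
        summary = _training_fit(config, rundir, model, design_train.M,
                                seed_offset=23 + offset)
        design_test = design_matrix(job_blocks, geno, test)
        gebv = predict_gebv(summary, design_test.M, test)
        name = f"gebv_{model}_{label}.tsv"
        pd.DataFrame({"id": test, "gebv": gebv}).to_csv(
            rundir / name, sep="\t", index=False, float_format="%.10g"
        )
        outputs.append(name)
    manifest.record(
        f"fit-blocks[{model}]",
        [FILES[k] for k in ("genotypes", "kept_markers", "blocks", "drp",
                            "pedigree", "train_ids")],
        outputs,
        {"model": model, "chain_length": config.chain_length,
         "burn_in": config.burn_in, "seed": config.seed},
    )


def stage_evaluate(config: RunConfig, rundir: Path, manifest: Manifest,
                   model: str) -> pd.DataFrame:
    """Reliability/bias/HW comparison table for one model's GEBV files."""
    _require(rundir, FILES["drp"], FILES["test_ids"], f"gebv_{model}_full.tsv",
             f"gebv_{model}_snp.tsv")
    drp_all = read_drp(rundir / FILES["drp"])
    test = _read_ids(rundir / FILES["test_ids"])
    drp = drp_all.subset(test)
    mean_r2 = float(drp.reliabilities.mean())

    def load_gebv(name: str) -> np.ndarray:
        df = pd.read_csv(rundir / name, sep="\t")
        if df["id"].tolist() != test:
            raise ValueError(f"{name} does not cover the test set")
        return df["gebv"].to_numpy()

    grid = {
        k: load_gebv(f"gebv_{model}_qtl_k{k}.tsv")
        for k in config.k_grid
        if (rundir / f"gebv_{model}_qtl_k{k}.tsv").exists()
    }
    table = evaluate_grid(
        drp.values, mean_r2, grid,
        load_gebv(f"gebv_{model}_full.tsv"),
        load_gebv(f"gebv_{model}_snp.tsv"),
    )
    rand_rows = []
    for path in sorted(rundir.glob(f"gebv_{model}_random_*.tsv")):
        res = reliability(drp.values, load_gebv(path.name), mean_r2)
        rand_rows.append(
            {"model": "random:" + path.stem.split("_random_")[1],
             "k": np.nan, "reliability": res.reliability, "bias": res.bias,
             "hw_p_vs_full": np.nan}
        )
    if rand_rows:
        table = pd.concat([table, pd.DataFrame(rand_rows)], ignore_index=True)
    if (rundir / FILES["truth"]).exists():
        truth = pd.read_csv(rundir / FILES["truth"]).set_index("id")
        tbv = truth.loc[test, "tbv"].to_numpy()
        cors = []
        for row in table.itertuples(index=False):
            name = _gebv_file_for_row(model, row)
            cors.append(float(np.corrcoef(tbv, load_gebv(name))[0, 1]))
        table["cor_tbv"] = cors
    out = f"comparison_{model}.tsv"
    table.to_csv(rundir / out, sep="\t", index=False, float_format="%.6g")
    report = f"report_{model}.txt"
    (rundir / report).write_text(format_report(table) + "\n")
    manifest.record(
        f"evaluate[{model}]",
        [FILES["drp"], FILES["test_ids"]]
        + [f.name for f in sorted(rundir.glob(f"gebv_{model}_*.tsv"))],
        [out, report], {"model": model},
    )
    return table


def _gebv_file_for_row(model: str, row) -> str:
    if row.model == "qtl":
        return f"gebv_{model}_qtl_k{int(row.k)}.tsv"
    if row.model == "full_blocks":
        return f"gebv_{model}_full.tsv"
    if row.model == "snp":
        return f"gebv_{model}_snp.tsv"
    return f"gebv_{model}_random_{row.model.split(':', 1)[1]}.tsv"


def run_pipeline(config: RunConfig, rundir) -> Manifest:
    """Execute every stage in dependency order; returns the manifest."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(rundir / "config.yaml")
    manifest = Manifest(rundir)
    stage = "simulate"
    try:
        stage_simulate(config, rundir, manifest)
        stage = "edit"
        stage_edit(config, rundir, manifest)
        stage = "blocks"
        stage_blocks(config, rundir, manifest)
        for model in config.models:
            stage = f"fit-snp[{model}]"
            stage_fit_snp(config, rundir, manifest, model)
            stage = f"select[{model}]"
            stage_select(config, rundir, manifest, model, "qtl")
            if config.random_replicates > 0:
                stage_select(config, rundir, manifest, model, "random")
            stage = f"fit-blocks[{model}]"
            stage_fit_blocks(config, rundir, manifest, model)
            stage = f"evaluate[{model}]"
            stage_evaluate(config, rundir, manifest, model)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    return manifest
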