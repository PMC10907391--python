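"""End-to-end orchestration: design -> codebook -> simulate -> preprocess
-> spots -> decode -> count, driven by one YAML config and recorded in a
run manifest.

Per-stage RNG streams are decoupled by deriving stage seeds from the
global seed with fixed offsets, so changing one stage's parameters never
perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cells as cells_mod
from . import codebook as cb_mod
from . import decode as decode_mod
from . import preprocess as pre_mod
from . import probe_design as pd_mod
from . import simulate as sim_mod
from . import spotcall as spot_mod

log = logging.getLogger("fishcoder")

_STAGE_OFFSETS = {
    "design": 101,
    "codebook": 202,
    "simulate": 303,
    "acquire": 404,
    "preprocess": 505,
    "spots": 606,
    "decode": 707,
    "count": 808,
}
_SEED_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1009 + _STAGE_OFFSETS[stage]) % _SEED_MOD


@dataclass
class RunConfig:
    """One serializable document configuring every stage."""

    rng_seed: int = 0
    outdir: str = "fishcoder_run"
    log_level: str = "INFO"
    n_genes: int = 40
    gene_ids: list[str] | None = None
    transcript_len: int = 1200
    n_decoys: int = 20
    design: dict = field(default_factory=dict)
    codebook: dict = field(default_factory=dict)
    fieldspec: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    spotcall: dict = field(default_factory=dict)
    decode: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    # optional externally supplied inputs; a stage with its input given
    # externally is skipped
    external: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, t0: float, **info) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(time.time() - t0, 3), **info}
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages}, fh, indent=2)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in order; any stage error aborts with the
    failing stage named while partial outputs are retained."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest = RunManifest(chash, cfg.rng_seed)
    cfg.to_yaml(outdir / "config.yaml")

    gene_ids = cfg.gene_ids or [f"gene{i:04d}" for i in range(cfg.n_genes)]

    stage = "design"
    try:
        # ---- design -------------------------------------------------
        t0 = time.time()
        if cfg.external.get("probes"):
            log.info("design: external probe library supplied, stage skipped")
            manifest.record(stage, t0, skipped=True, input=str(cfg.external["probes"]))
        else:
            dcfg = pd_mod.DesignConfig(
                rng_seed=stage_seed(cfg.rng_seed, "design"), **cfg.design
            )
            transcripts = pd_mod.synthetic_transcripts(
                gene_ids, cfg.transcript_len, rng_seed=stage_seed(cfg.rng_seed, "design")
            )
            decoys = pd_mod.synthetic_transcripts(
                [f"decoy{i:03d}" for i in range(cfg.n_decoys)],
                cfg.transcript_len,
                rng_seed=stage_seed(cfg.rng_seed, "design") + 1,
            )
            designs = pd_mod.design_probe_library(transcripts, decoys, dcfg)
            pd_mod.write_probe_tsv(designs, outdir / "probes.tsv")
            pd_mod.write_design_report(designs, outdir / "design_report.json", dcfg)
            manifest.record(stage, t0, n_genes=len(designs),
                            output_hash=_file_hash(outdir / "probes.tsv"))
            log.info("design: %d genes", len(designs))

        # ---- codebook -----------------------------------------------
        stage = "codebook"
        t0 = time.time()
        if cfg.external.get("codebook"):
            cb = cb_mod.read_codebook_csv(cfg.external["codebook"])
            manifest.record(stage, t0, skipped=True, input=str(cfg.external["codebook"]))
        else:
            cb = cb_mod.assign_barcodes(
                gene_ids,
                max_shared=cfg.codebook.get("max_shared", 2),
                rng_seed=stage_seed(cfg.rng_seed, "codebook"),
                n_rounds=cfg.codebook.get("n_rounds", 22),
                n_channels=cfg.codebook.get("n_channels", 2),
            )
            cb_mod.write_codebook_csv(cb, outdir / "codebook.csv")
            manifest.record(stage, t0, n_barcodes=len(cb.barcodes),
                            output_hash=_file_hash(outdir / "codebook.csv"))
        report = cb_mod.validate_codebook(cb)
        if not report.valid:
            raise ValueError(f"invalid codebook: {report.violations[:3]}")

        # ---- simulate (truth + rendering) ---------------------------
        stage = "simulate"
        t0 = time.time()
        truth = None
        if cfg.external.get("stack"):
            stack = pre_mod.ImageStack.load(cfg.external["stack"])
            manifest.record(stage, t0, skipped=True, input=str(cfg.external["stack"]))
        else:
            fs_kwargs = dict(cfg.fieldspec)
            if "expression_means" not in fs_kwargs:
                fs_kwargs["expression_means"] = sim_mod.default_expression_means(gene_ids)
            fieldspec = sim_mod.FieldSpec(**fs_kwargs)
            truth = sim_mod.simulate_field(
                fieldspec, cb, rng_seed=stage_seed(cfg.rng_seed, "simulate")
            )
            acq = sim_mod.AcquisitionSpec(
                rng_seed=stage_seed(cfg.rng_seed, "acquire"), **cfg.acquisition
            )
            stack = sim_mod.render_stack(truth, cb, acq)
            sim_mod.write_truth(truth, outdir / "truth")
            stack.save(outdir / "stack_raw")
            manifest.record(stage, t0, n_transcripts=len(truth.transcripts),
                            n_rounds=stack.n_rounds, n_channels=stack.n_channels)
            log.info("simulate: %d transcripts", len(truth.transcripts))

        # ---- preprocess ---------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        pcfg = pre_mod.PreprocessConfig(**cfg.preprocess)
        stack = pre_mod.preprocess_stack(stack, pcfg)
        manifest.record(stage, t0, shifts=[list(s) for s in stack.shifts])

        # ---- spots --------------------------------------------------
        stage = "spots"
        t0 = time.time()
        if cfg.external.get("spots"):
            table = spot_mod.SpotTable.from_csv(cfg.external["spots"])
            manifest.record(stage, t0, skipped=True, input=str(cfg.external["spots"]))
        else:
            scfg_kwargs = dict(cfg.spotcall)
            k_mad = scfg_kwargs.pop("k_mad", None)
            scfg = spot_mod.SpotCallConfig(**scfg_kwargs)
            if k_mad is not None:
                scfg.threshold = spot_mod.ThresholdSpec(k_mad=k_mad)
            table = spot_mod.call_spots(stack, scfg)
            table.provenance = {"config_hash": chash}
            table.to_csv(outdir / "spots.csv")
            manifest.record(stage, t0, n_spots=len(table),
                            output_hash=_file_hash(outdir / "spots.csv"))
            log.info("spots: %d detected", len(table))

        # ---- decode -------------------------------------------------
        stage = "decode"
        t0 = time.time()
        dccfg = decode_mod.DecodeConfig(**cfg.decode)
        calls = decode_mod.decode_spots(table, cb, dccfg)
        frame = decode_mod.calls_to_frame(calls)
        with open(outdir / "decoded.csv", "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            frame.to_csv(fh, index=False)
        info = {"n_calls": len(calls), "output_hash": _file_hash(outdir / "decoded.csv")}
        if truth is not None:
            metrics = decode_mod.evaluate_decoding(calls, truth)
            with open(outdir / "decode_metrics.json", "w") as fh:
                json.dump(metrics.to_dict(), fh, indent=2)
            info["recall"] = round(metrics.recall, 4)
            info["precision"] = round(metrics.precision, 4)
        manifest.record(stage, t0, **info)
        log.info("decode: %d calls", len(calls))

        # ---- count --------------------------------------------------
        stage = "count"
        t0 = time.time()
        ckw = dict(cfg.cells)
        expand_px = ckw.pop("expand_px", 5)
        seg = cells_mod.segment_nuclei(
            stack.nuclear_reference[0], cells_mod.SegmentConfig(**ckw)
        )
        cm = cells_mod.assign_and_count(calls, seg, gene_ids=gene_ids, expand_px=expand_px)
        cm.save(outdir / "counts")
        import tifffile

        tifffile.imwrite(outdir / "labels.tif", seg.astype(np.int32))
        manifest.record(stage, t0, n_cells=len(cm.cell_ids),
                        total_counts=int(cm.matrix.sum()),
                        unassigned=cm.n_unassigned)
        log.info("count: %d cells, %d counts", len(cm.cell_ids), int(cm.matrix.sum()))
    except Exception as e:
        manifest.save(outdir / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    manifest.save(outdir / "manifest.json")
    return manifest
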