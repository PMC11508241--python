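"""End-to-end pipeline orchestration with provenance capture.

A single YAML config drives simulate → catalog → extract → fit → compare →
strandbias → enrich; any stage can be skipped. All randomness flows from one
root seed expanded per stage; the run manifest records the config snapshot,
seeds, per-stage output paths and SHA-256 checksums, so identical config +
seed yields identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    build_catalog,
    genome_trinucleotide_frequencies,
    mutation_type_summary,
    read_calls,
    read_catalog_tsv,
    read_fasta,
    read_gff3,
    write_catalog_tsv,
)
from .compare import rank_matches, read_cosmic
from .enrichment import fisher_enrich, read_gene_list, read_gmt
from .errors import ConfigurationError
from .nmf import fit_exposures, select_k, write_exposures_tsv, write_signatures_tsv
from .simulate import (
    GroupSpec,
    SimConfig,
    default_config,
    default_signatures,
    generate_genome,
    make_cosmic_fixture,
    simulate_clones,
    write_clone_vcfs,
    write_fasta,
    write_gff3,
    write_truth_json,
)
from .strand_bias import strand_bias_table

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_STAGES = ("simulate", "catalog", "extract", "fit", "compare", "strandbias", "enrich")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _enabled(cfg: Mapping[str, Any], stage: str, default: bool = True) -> bool:
    return bool(cfg.get("stages", {}).get(stage, default))


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Schema validation before any computation."""
    version = cfg.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported schema_version {version}")
    unknown = set(cfg) - {
        "schema_version",
        "seed",
        "stages",
        "simulate",
        "catalog",
        "extract",
        "compare",
        "strandbias",
        "enrich",
        "inputs",
    }
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    stages = cfg.get("stages", {})
    if not isinstance(stages, Mapping):
        raise ConfigurationError("'stages' must be a mapping of stage -> bool")
    for s in stages:
        if s not in _STAGES:
            raise ConfigurationError(f"unknown stage {s!r}")
    if not _enabled(cfg, "simulate"):
        inputs = cfg.get("inputs", {})
        needs = ["fasta", "gff", "vcf_dir"]
        missing = [
            k
            for k in needs
            if any(_enabled(cfg, s) for s in ("catalog", "extract", "strandbias"))
            and k not in inputs
        ]
        if missing:
            raise ConfigurationError(
                "simulation disabled but inputs missing: " + ", ".join(missing)
            )
    if _enabled(cfg, "enrich", default=False):
        e = cfg.get("enrich", {})
        for k in ("genes", "gmt", "background"):
            if k not in e:
                raise ConfigurationError(f"enrich stage requires 'enrich.{k}'")


def _sim_config_from(cfg: Mapping[str, Any], seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate", {}) or {})
    strain = sim.pop("strain", "TA1535")
    base = default_config(strain=strain, seed=seed)
    groups = sim.pop("groups", None)
    if groups is not None:
        base.groups = tuple(
            GroupSpec(
                g["name"],
                int(g["n_clones"]),
                float(g["mean_mutations"]),
                tuple(float(x) for x in g["exposures"]),
            )
            for g in groups
        )
    for key, value in sim.items():
        if not hasattr(base, key):
            raise ConfigurationError(f"unknown simulate option {key!r}")
        setattr(base, key, tuple(value) if isinstance(value, list) else value)
    base.seed = seed
    return base


def run_pipeline(config: Mapping[str, Any], outdir: str | Path, seed: int = 0) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))
    manifest: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "bactsig_version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(config, default=str)),
        "stages": {},
    }

    outputs: dict[str, Path] = {}

    def record(stage: str, name: str, path: Path) -> Path:
        manifest["stages"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }
        outputs[name] = path
        return path

    t0 = time.time()
    inputs = dict(config.get("inputs", {}) or {})

    if _enabled(config, "simulate"):
        sim_cfg = _sim_config_from(config, seed)
        signatures = default_signatures()
        genome, genes = generate_genome(sim_cfg)
        result = simulate_clones(genome, genes, signatures, sim_cfg)
        simdir = outdir / "simulate"
        simdir.mkdir(exist_ok=True)
        record("simulate", "fasta", write_fasta(genome, simdir / "genome.fa"))
        record("simulate", "gff", write_gff3(genes, genome, simdir / "genes.gff3"))
        vcfdir = simdir / "vcf"
        for cid, path in write_clone_vcfs(result, vcfdir).items():
            record("simulate", f"vcf:{cid}", path)
        record("simulate", "truth", write_truth_json(result, simdir / "truth.json"))
        record(
            "simulate",
            "planted_signatures",
            make_cosmic_fixture(signatures, simdir / "planted_signatures.tsv"),
        )
        inputs.setdefault("fasta", str(simdir / "genome.fa"))
        inputs.setdefault("gff", str(simdir / "genes.gff3"))
        inputs.setdefault("vcf_dir", str(vcfdir))
        logger.info("simulate: %d clones in %.1fs", len(result.clones), time.time() - t0)

    if _enabled(config, "catalog"):
        t = time.time()
        genome = read_fasta(inputs["fasta"])
        genes = read_gff3(inputs["gff"])
        vcfs = sorted(Path(inputs["vcf_dir"]).glob("*.vcf"))
        snv_lists = {p.stem: read_calls(p, p.stem).snvs for p in vcfs}
        cat = build_catalog(snv_lists, genome)
        catdir = outdir / "catalog"
        catdir.mkdir(exist_ok=True)
        record("catalog", "catalog96", write_catalog_tsv(cat, catdir / "catalog96.tsv"))
        opts = dict(config.get("catalog", {}) or {})
        if opts.get("stranded", True):
            sc = build_catalog(
                snv_lists,
                genome,
                stranded=True,
                annotation=genes,
                convention=opts.get("convention", "cosmic"),
            )
            record(
                "catalog",
                "catalog192",
                write_catalog_tsv(sc.counts, catdir / "catalog192.tsv"),
            )
            record(
                "catalog",
                "catalog192_excluded",
                write_catalog_tsv(sc.excluded, catdir / "catalog192_excluded.tsv"),
            )
        freqs = genome_trinucleotide_frequencies(genome)
        fpath = catdir / "trinucleotide_frequencies.tsv"
        freqs.rename_axis("Context").to_csv(fpath, sep="\t")
        record("catalog", "trinuc_freqs", fpath)
        groups: dict[str, list[Path]] = {}
        for p in vcfs:
            groups.setdefault(p.stem.rsplit("_", 1)[0], []).append(p)
        summary = mutation_type_summary(groups)
        spath = catdir / "mutation_type_summary.tsv"
        summary.rename_axis("Type").to_csv(spath, sep="\t")
        record("catalog", "six_type_summary", spath)
        logger.info("catalog: %d samples in %.1fs", len(snv_lists), time.time() - t)

    if _enabled(config, "extract"):
        t = time.time()
        cat = read_catalog_tsv(outputs.get("catalog96", inputs.get("catalog", "")))
        e = dict(config.get("extract", {}) or {})
        sel = select_k(
            cat,
            k_min=int(e.get("k_min", 1)),
            k_max=int(e.get("k_max", 4)),
            stability_threshold=float(e.get("stability_threshold", 0.8)),
            n_bootstraps=int(e.get("n_bootstraps", 30)),
            n_restarts=int(e.get("n_restarts", 3)),
            max_iter=int(e.get("max_iter", 3000)),
            tol=float(e.get("tol", 1e-7)),
            seed=seed,
        )
        sigdir = outdir / "signatures"
        sigdir.mkdir(exist_ok=True)
        best = sel.signature_sets[sel.recommended_k]
        spath = sigdir / "signatures.tsv"
        write_signatures_tsv(best, spath)
        record("extract", "signatures", spath)
        report = {
            "recommended_k": sel.recommended_k,
            "seed": seed,
            "table": sel.table.to_dict(orient="records"),
            "stability": best.stability.to_dict(),
            "reconstruction_error": best.reconstruction_error,
        }
        rpath = sigdir / "extraction_report.json"
        rpath.write_text(json.dumps(report, indent=1))
        record("extract", "extraction_report", rpath)
        manifest["stages"]["extract"]["recommended_k"] = sel.recommended_k
        logger.info("extract: k=%d in %.1fs", sel.recommended_k, time.time() - t)

    if _enabled(config, "fit"):
        cat = read_catalog_tsv(outputs.get("catalog96", inputs.get("catalog", "")))
        sig_path = outputs.get("signatures", inputs.get("signatures", ""))
        sigs = pd.read_csv(sig_path, sep="\t", index_col=0)
        exp = fit_exposures(cat, sigs)
        epath = outdir / "signatures" / "exposures.tsv"
        epath.parent.mkdir(exist_ok=True)
        write_exposures_tsv(exp, epath)
        record("fit", "exposures", epath)

    if _enabled(config, "compare"):
        c = dict(config.get("compare", {}) or {})
        cosmic_path = c.get("cosmic", outputs.get("planted_signatures"))
        if cosmic_path is None:
            raise ConfigurationError("compare stage requires 'compare.cosmic'")
        cosmic = read_cosmic(cosmic_path)
        sig_path = outputs.get("signatures", inputs.get("signatures", ""))
        sigs = pd.read_csv(sig_path, sep="\t", index_col=0)
        frames = []
        for name in sigs.columns:
            ranked = rank_matches(sigs[name], cosmic, top_n=int(c.get("top", 5)))
            ranked.insert(0, "signature", name)
            frames.append(ranked)
        cpath = outdir / "cosmic_matches.tsv"
        pd.concat(frames, ignore_index=True).to_csv(cpath, sep="\t", index=False)
        record("compare", "cosmic_matches", cpath)

    if _enabled(config, "strandbias"):
        path192 = outputs.get("catalog192", inputs.get("stranded_catalog", ""))
        if path192:
            sc = read_catalog_tsv(path192)
            sb = dict(config.get("strandbias", {}) or {})
            table = strand_bias_table(sc, alpha=float(sb.get("alpha", 0.05)))
            bpath = outdir / "strand_bias.tsv"
            table.to_csv(bpath, sep="\t", index=False)
            record("strandbias", "strand_bias", bpath)

    if _enabled(config, "enrich", default=False):
        e = dict(config["enrich"])
        result = fisher_enrich(
            read_gene_list(e["genes"]), read_gmt(e["gmt"]), int(e["background"])
        )
        epath = outdir / "enrichment.tsv"
        result.to_csv(epath, sep="\t", index=False)
        record("enrich", "enrichment", epath)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return manifest
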