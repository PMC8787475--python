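"""Configuration-driven orchestration: simulate, analyze, report.

A run is described by a YAML/dict config listing stages; every stochastic
stage receives a deterministic child seed derived from the single global
seed via ``numpy.random.SeedSequence(seed).spawn`` indexed by stage order,
so any stage can be rerun independently and reproducibly.  All outputs are
UTF-8 TSV / Newick / JSON; the run writes a manifest with a SHA-256 checksum
per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import community_stats, ecophylo, growth, phylo_structure, spatiotemporal, synthetic_data

__all__ = ["run", "validate_inputs", "stage_seed", "SCHEMA_VERSION"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

STAGES = (
    "simulate",
    "permanova",
    "depth-scan",
    "node-assoc",
    "asv-tests",
    "autocorr",
    "ses-mntd",
    "growth-fit",
    "growth-anova",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def validate_inputs(paths: dict) -> list[str]:
    """Report-only validation of an input bundle.

    Checks that files exist, the tree parses, tables have headers and unique
    IDs, and IDs cross-reference (community taxa vs tree tips, community
    samples vs metadata).  Returns a list of violations (empty = consistent).
    """
    violations: list[str] = []
    resolved = {}
    for key, p in paths.items():
        p = Path(p)
        if not p.exists():
            violations.append(f"{key}: file not found: {p}")
        else:
            resolved[key] = p

    tree = None
    if "tree" in resolved:
        try:
            tree = dendropy.Tree.get(path=str(resolved["tree"]), schema="newick")
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            violations.append(f"tree: does not parse as Newick ({exc})")

    table = None
    if "community" in resolved:
        table = pd.read_csv(resolved["community"], sep="\t", index_col=0)
        if table.index.duplicated().any():
            dups = list(table.index[table.index.duplicated()])
            violations.append(f"community: duplicated sample IDs {dups}")
        if tree is not None:
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            missing = sorted(set(table.columns) - tips)
            for t in missing:
                violations.append(f"community: taxon {t!r} missing from tree")

    if "meta" in resolved:
        meta = pd.read_csv(resolved["meta"], sep="\t", index_col=0)
        if meta.index.duplicated().any():
            dups = sorted(set(meta.index[meta.index.duplicated()]))
            violations.append(f"meta: duplicated sample IDs {dups}")
        if table is not None:
            missing = sorted(set(table.index) - set(meta.index))
            for s in missing:
                violations.append(f"meta: sample {s!r} in community table has no metadata")
        for col in ("x", "y", "D"):
            if col in meta.columns and meta[col].isna().any():
                bad = sorted(meta.index[meta[col].isna()])
                violations.append(f"meta: column {col} incomplete for samples {bad}")
    return violations


def _stage_simulate(cfg: dict, seed: int, outdir: Path) -> dict[str, Path]:
    sim = synthetic_data.SimConfig(seed=seed, **cfg.get("sim", {}))
    effects = synthetic_data.PlantedEffects(**cfg.get("effects", {}))
    tree, clades = synthetic_data.simulate_tree(sim)
    iso = synthetic_data.simulate_isolates(tree, clades, effects, sim)
    counts, meta = synthetic_data.simulate_communities(effects, sim, tree=tree)
    arts = {}
    tree_path = outdir / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    arts["tree"] = tree_path
    arts["isolates"] = _write_tsv(iso, outdir / "isolates.tsv", index=False)
    arts["community"] = _write_tsv(counts, outdir / "community.tsv")
    arts["meta"] = _write_tsv(meta, outdir / "meta.tsv")
    (outdir / "clades.json").write_text(json.dumps(clades, indent=1))
    arts["clades"] = outdir / "clades.json"
    return arts


def run(config: dict, outdir) -> dict:
    """Execute the configured stages in order and write an artifact manifest.

    ``config`` keys: ``seed`` (global seed), ``stages`` (ordered list of
    stage names), optional per-stage sections, optional ``inputs`` mapping
    for externally supplied files.  Missing inputs fail before any stage
    runs; a stage failure leaves a partial manifest with an error record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")

    artifacts: dict[str, Path] = {p_key: Path(p) for p_key, p in config.get("inputs", {}).items()}
    for key, p in artifacts.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input {key!r} missing: {p}")

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "stages": stages,
        "artifacts": {},
        "errors": [],
    }

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    for stage in stages:
        sseed = stage_seed(seed, stage)
        log.info("stage %s (seed %d)", stage, sseed)
        try:
            if stage == "simulate":
                for name, path in _stage_simulate(config.get("simulate", {}), sseed, outdir).items():
                    artifacts[name] = path
                    record(name, path)
            elif stage == "permanova":
                counts = pd.read_csv(artifacts["community"], sep="\t", index_col=0)
                meta = pd.read_csv(artifacts["meta"], sep="\t", index_col=0)
                terms = config.get("permanova", {}).get("terms", ["F", "H", "D", "P"])
                n_perm = config.get("permanova", {}).get("n_perm", 10_000)
                d = community_stats.bray_curtis(community_stats.hellinger(counts))
                res = community_stats.permanova(d, meta, terms, n_perm=n_perm, seed=sseed)
                path = _write_tsv(res.table, outdir / "permanova.tsv")
                record("permanova", path)
            elif stage == "depth-scan":
                tree = dendropy.Tree.get(path=str(artifacts["tree"]), schema="newick")
                ps = synthetic_data.implied_similarity(tree)
                utree = phylo_structure.ultrametricize(tree, ps)
                iso = pd.read_csv(artifacts["isolates"], sep="\t")
                sc = config.get("depth_scan", {})
                res = community_stats.depth_scan(
                    utree, iso, terms=sc.get("terms", ["F", "T_I", "D", "H"]),
                    n_perm=sc.get("n_perm", 999), seed=sseed,
                )
                record("depth_scan", _write_tsv(res, outdir / "depth_scan.tsv", index=False))
            elif stage == "node-assoc":
                tree = dendropy.Tree.get(path=str(artifacts["tree"]), schema="newick")
                ps = synthetic_data.implied_similarity(tree)
                utree = phylo_structure.ultrametricize(tree, ps)
                iso = pd.read_csv(artifacts["isolates"], sep="\t")
                na = config.get("node_assoc", {})
                res = phylo_structure.node_factor_test(
                    utree, iso, na.get("factor", "T_I"),
                    n_perm=na.get("n_perm", 100_000), seed=sseed,
                )
                record("node_assoc", _write_tsv(res, outdir / "node_assoc.tsv", index=False))
            elif stage == "asv-tests":
                counts = pd.read_csv(artifacts["community"], sep="\t", index_col=0)
                meta = pd.read_csv(artifacts["meta"], sep="\t", index_col=0)
                res = community_stats.asv_factor_tests(counts, meta)
                record("asv_tests", _write_tsv(res, outdir / "asv_tests.tsv", index=False))
            elif stage == "autocorr":
                counts = pd.read_csv(artifacts["community"], sep="\t", index_col=0)
                meta = pd.read_csv(artifacts["meta"], sep="\t", index_col=0)
                rel = counts.div(counts.sum(axis=1), axis=0)
                d = community_stats.bray_curtis(rel)
                frames = []
                for forest in meta["F"].unique():
                    sel = meta.index[meta["F"] == forest]
                    sp = spatiotemporal.build_pairs(d.loc[sel, sel], meta.loc[sel], "spatial")
                    tp = spatiotemporal.build_pairs(d.loc[sel, sel], meta.loc[sel], "temporal")
                    for pairs, formula in ((sp, "BC~pDist*D"), (tp, "BC~pTime")):
                        fit = spatiotemporal.autocorr_fit(pairs, formula)
                        frame = fit.summary_frame()
                        frame.insert(0, "forest", forest)
                        frame.insert(1, "model", formula)
                        frames.append(frame)
                res = pd.concat(frames)
                record("autocorr", _write_tsv(res, outdir / "autocorr.tsv"))
                trend = spatiotemporal.homogenization_trend(d, meta)
                record("homogenization", _write_tsv(trend, outdir / "homogenization.tsv", index=False))
            elif stage == "ses-mntd":
                counts = pd.read_csv(artifacts["community"], sep="\t", index_col=0)
                tree = dendropy.Tree.get(path=str(artifacts["tree"]), schema="newick")
                dist = ecophylo.cophenetic_distances(tree)
                shared = [t for t in counts.columns if t in dist.index]
                n_null = config.get("ses_mntd", {}).get("n_null", 999)
                res = ecophylo.ses_mntd(counts[shared], dist, n_null=n_null, seed=sseed)
                record("ses_mntd", _write_tsv(res, outdir / "ses_mntd.tsv"))
            elif stage == "growth-fit":
                layout_cfg = dict(config.get("layout", {}))
                if "isolates" in artifacts and "isolate_ids" not in layout_cfg:
                    iso_ids = pd.read_csv(artifacts["isolates"], sep="\t")["isolate"]
                    layout_cfg["isolate_ids"] = list(
                        iso_ids.unique()[: layout_cfg.pop("n_isolates", 12)]
                    )
                elif "n_isolates" not in layout_cfg and "isolate_ids" not in layout_cfg:
                    layout_cfg["n_isolates"] = 12
                if "treatments" in layout_cfg:
                    layout_cfg["treatments"] = tuple(layout_cfg["treatments"])
                layout = synthetic_data.make_plate_layout(**layout_cfg, seed=sseed)
                effects = synthetic_data.PlantedEffects(**config.get("effects", {}))
                images, truth = synthetic_data.simulate_plate_images(
                    effects, layout, seed=sseed
                )
                series = growth.quantify_spots(images, layout)
                series, _c = growth.competition_correct(series, layout)
                per_spot, per_iso = growth.fit_growth(series)
                record("growth_fits", _write_tsv(per_iso, outdir / "growth_fits.tsv", index=False))
                artifacts["growth_fits"] = outdir / "growth_fits.tsv"
            elif stage == "growth-anova":
                fits = pd.read_csv(artifacts["growth_fits"], sep="\t")
                iso = pd.read_csv(artifacts["isolates"], sep="\t")
                tables = growth.growth_anova(fits, iso, terms=config.get(
                    "growth_anova", {}).get("terms", ["F", "H", "D", "C"]))
                for resp, tab in tables.items():
                    record(f"growth_anova_{resp}",
                           _write_tsv(tab, outdir / f"growth_anova_{resp}.tsv"))
        except Exception as exc:  # noqa: BLE001 - recorded, then re-raised
            manifest["errors"].append({"stage": stage, "error": str(exc)})
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
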