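"""End-to-end orchestration.

Runs simulate/ingest -> per-cohort feature ranking -> threshold adjustment ->
ranking merge -> per-cohort CV rule learning -> model merge -> FDR filter ->
co-predictive networks -> subgroup dissimilarity -> report, writing one
artifact directory per stage plus a manifest (input checksums, parameters,
derived seed) so reruns are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import mcfs, merge, network, rules, subgroups, synthetic

log = logging.getLogger("copredict")

__all__ = ["run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by stage-name hashing."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: Mapping, seed: int, inputs: Sequence[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": {k: v for k, v in params.items()},
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _load_cohorts(config: Mapping, seed: int) -> list[synthetic.ExpressionMatrix]:
    if "synthetic" in config:
        spec_cfg = dict(config["synthetic"])
        spec_cfg.setdefault("seed", seed)
        spec = synthetic.spec_from_dict(spec_cfg)
        return synthetic.generate_cohorts(spec)
    cohorts = []
    for entry in config["cohorts"]:
        for key in ("values", "meta"):
            if not Path(entry[key]).exists():
                raise FileNotFoundError(f"cohort input missing: {entry[key]}")
        cohorts.append(synthetic.read_expression_tsv(entry["values"], entry["meta"]))
    return cohorts


def run_pipeline(config: Mapping, out_dir: str | Path) -> Path:
    """Execute the full analysis described by ``config`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    stage = "ingest"
    try:
        # ---- stage: simulate / ingest ------------------------------------
        seed = stage_seed(master_seed, "ingest")
        cohorts = _load_cohorts(config, seed)
        stage_dir = out / "cohorts"
        stage_dir.mkdir(exist_ok=True)
        inputs: list[Path] = []
        for i, matrix in enumerate(cohorts):
            vpath = stage_dir / f"cohort{i + 1}_values.tsv"
            mpath = stage_dir / f"cohort{i + 1}_meta.tsv"
            synthetic.write_expression_tsv(matrix, vpath, mpath)
            inputs.extend([vpath, mpath])
        _write_manifest(stage_dir, "ingest", config.get("synthetic", {}), seed, inputs)
        cohort_ids = [str(m.sample_meta["cohort_id"].iloc[0]) for m in cohorts]

        # ---- stage: per-cohort feature ranking ---------------------------
        stage = "select-features"
        mcfs_cfg = dict(config.get("mcfs", {}))
        adjust_cfg = dict(config.get("adjust", {}))
        stage_dir = out / "rankings"
        stage_dir.mkdir(exist_ok=True)
        adjusted: list[mcfs.FeatureRanking] = []
        for cid, matrix in zip(cohort_ids, cohorts):
            seed = stage_seed(master_seed, f"mcfs:{cid}")
            labels = pd.Series(
                matrix.sample_meta["class"].to_numpy(), index=matrix.values.index
            )
            ranking = mcfs.mcfs_rank(
                matrix.values,
                labels,
                s=int(mcfs_cfg.get("s", 100)),
                t=int(mcfs_cfg.get("t", 5)),
                m=mcfs_cfg.get("m"),
                u=float(mcfs_cfg.get("u", 1.0)),
                v=float(mcfs_cfg.get("v", 1.0)),
                seed=seed,
                provenance=cid,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                k0 = mcfs.critical_angle_threshold(ranking)
            if adjust_cfg.get("enabled", True):
                folds = int(adjust_cfg.get("folds", 3))
                k_max = int(adjust_cfg.get("k_max", 50))
                cv_seed = stage_seed(master_seed, f"adjust:{cid}")

                def quality(k: int, _r=ranking, _f=matrix.values, _l=labels) -> float:
                    model = rules.crossvalidate(
                        _f[_r.feature_ids[:k]], _l, folds=folds, seed=cv_seed
                    )
                    return mcfs.cv_quality(model.accuracy, model.auc)

                k_adj = mcfs.adjust_fr(ranking, quality, k0, k_max)
            else:
                k_adj = k0
            top = ranking.top(k_adj)
            top.to_tsv(stage_dir / f"ranking_{cid}.tsv")
            adjusted.append(top)
            log.info("cohort %s: k0=%d k_adj=%d", cid, k0, k_adj)
        _write_manifest(stage_dir, "select-features", {**mcfs_cfg, **adjust_cfg}, master_seed, inputs)

        # ---- stage: merge rankings ---------------------------------------
        stage = "merge-rankings"
        id_map = None
        if config.get("id_map"):
            id_map_path = Path(config["id_map"])
            if not id_map_path.exists():
                raise FileNotFoundError(f"id_map missing: {id_map_path}")
            df = pd.read_csv(id_map_path, sep="\t")
            id_map = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        merged_ranking = mcfs.merge_rankings(adjusted, id_map)
        merged_ranking.to_tsv(out / "rankings" / "ranking_merged.tsv")

        # ---- stage: per-cohort learning ----------------------------------
        stage = "learn"
        learn_cfg = dict(config.get("learn", {}))
        folds = int(learn_cfg.get("folds", 10))
        stage_dir = out / "models"
        stage_dir.mkdir(exist_ok=True)
        models: list[rules.RuleModel] = []
        id_maps: list[Mapping[str, str] | None] = []
        for cid, matrix in zip(cohort_ids, cohorts):
            seed = stage_seed(master_seed, f"learn:{cid}")
            frame = matrix.values
            cohort_map = None
            if id_map:
                cohort_map = {s: t for s, t in id_map.items() if s in frame.columns}
                frame = frame.rename(columns=cohort_map)
            feats = [f for f in merged_ranking.feature_ids if f in frame.columns]
            labels = pd.Series(matrix.sample_meta["class"].to_numpy(), index=frame.index)
            use_folds = min(folds, int(labels.value_counts().min()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = rules.crossvalidate(
                    frame[feats], labels, folds=use_folds, seed=seed, provenance=(cid,)
                )
            model.rules = [replace(r, provenance=(cid,)) for r in model.rules]
            model.to_json_lines(stage_dir / f"rules_{cid}.jsonl")
            (stage_dir / f"model_{cid}.json").write_text(json.dumps(model.summary(), indent=1))
            models.append(model)
            id_maps.append(cohort_map)
            log.info("cohort %s: %d rules, acc=%.1f auc=%.2f", cid, len(model.rules), model.accuracy, model.auc)
        _write_manifest(stage_dir, "learn", learn_cfg, master_seed, inputs)

        # ---- stage: merge models -----------------------------------------
        stage = "merge-models"
        merged_table = merge.combine_tables(cohorts, merged_ranking.feature_ids, id_maps=id_maps)
        merged_model = merge.merge_models(models, merged_table)
        merged_model.to_json_lines(out / "models" / "rules_merged.jsonl")
        (out / "models" / "model_merged.json").write_text(json.dumps(merged_model.summary(), indent=1))

        # ---- stage: FDR filter + networks --------------------------------
        stage = "network"
        net_cfg = dict(config.get("network", {}))
        alpha = float(config.get("fdr", {}).get("alpha", 0.05))
        significant = rules.fdr_filter(merged_model.rules, alpha=alpha)
        if not significant:
            log.warning("no FDR-significant rules; using unfiltered rules for networks")
            significant = merged_model.rules
        stage_dir = out / "networks"
        stage_dir.mkdir(exist_ok=True)
        for cls in sorted(merged_model.class_totals):
            net = network.build_network(significant, class_filter=cls)
            if net.is_empty():
                log.warning("empty network for class %s", cls)
                continue
            network.normalize_connections(net)
            network.detect_hubs(net)
            n_top = int(net_cfg.get("top_nodes", 30))
            frac = net_cfg.get("top_edge_fraction")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shown = network.top_nodes(net, n_top, float(frac) if frac else None)
            net.to_graphml(stage_dir / f"network_{cls}.graphml")
            net.to_edge_tsv(stage_dir / f"edges_{cls}.tsv")
            shown.to_graphml(stage_dir / f"network_{cls}_top.graphml")
        _write_manifest(stage_dir, "network", net_cfg, master_seed, inputs)

        # ---- stage: subgroup dissimilarity -------------------------------
        stage = "subgroups"
        sub_cfg = dict(config.get("subgroups", {}))
        seed = stage_seed(master_seed, "subgroups")
        meta = pd.concat([m.sample_meta for m in cohorts], ignore_index=True)
        stage_dir = out / "subgroups"
        stage_dir.mkdir(exist_ok=True)
        assignment = subgroups.assign_rules_to_subgroups(merged_model, meta)
        results = subgroups.permutation_test(
            merged_model,
            meta,
            n_perm=int(sub_cfg.get("n_perm", 500)),
            n_balance=int(sub_cfg.get("n_balance", 20)),
            seed=seed,
            assignment=assignment,
        )
        dist_rows = [asdict(r) for r in results]
        pd.DataFrame(dist_rows).to_csv(stage_dir / "distances.tsv", sep="\t", index=False)

        conn_rows = {}
        for g, g_rules in sorted(assignment.items()):
            net = network.build_network(g_rules)
            conn_rows[g] = {f"{n[0]}={n[1]}": net.node_raw(n) for n in net.nodes}
        conn_table = pd.DataFrame(conn_rows).T.fillna(0.0).sort_index()
        conn_table.to_csv(stage_dir / "node_connections.tsv", sep="\t")
        if conn_table.shape[0] >= 2 and conn_table.shape[1] >= 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kd = subgroups.kendall_distance_matrix(conn_table)
            kd.to_csv(stage_dir / "kendall_distances.tsv", sep="\t")
        _write_manifest(stage_dir, "subgroups", sub_cfg, seed, inputs)

        # ---- stage: report -----------------------------------------------
        stage = "report"
        report = {
            "cohorts": cohort_ids,
            "merged_ranking_size": len(merged_ranking),
            "per_cohort": [m.summary() for m in models],
            "merged_model": merged_model.summary(),
            "n_significant_rules": len(significant),
            "distances": dist_rows,
        }
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
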