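"""End-to-end orchestration of the outline-shape analysis.

Runs the stages in the order the analysis prescribes: reflect right sides,
jointly superimpose with bending-energy sliding, Procrustes ANOVA of
sides, average sides per specimen, pooled within-species allometric
regression, PCA of the residuals, species means onto the tree
(phylogenetic-signal permutation test, Pagel's lambda per axis,
phylomorphospace coordinates), and habitat CVA with distance permutation
tests. All numeric outputs are CSV; the run report is JSON.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import landmark_io, phylo, shape_stats, superimposition
from .simulate import SimulationConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger("opermorph")


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Exactly one of (tps+classifier paths) or a simulate block must be
    present; every stochastic stage has an explicit seed after resolution.
    """

    tps_path: str | None = None
    classifier_path: str | None = None
    newick_path: str | None = None
    simulate: SimulationConfig | None = None
    out_dir: str = "opermorph_out"
    seed: int = 0
    n_perm: int = 1000
    slide: bool = True
    run_phylo: bool = True
    run_cva: bool = True
    n_pc_lambda: int = 2
    merge_map: dict = field(default_factory=dict)

    def validate(self) -> None:
        has_paths = self.tps_path is not None or self.classifier_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError(
                "config must have exactly one of input paths or a simulate block"
            )
        if has_paths and (self.tps_path is None or self.classifier_path is None):
            raise ValueError("both tps and classifier paths are required")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.simulate = SimulationConfig(**sim)
    cfg.validate()
    return cfg


def _stage(report, name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is None:
                report["stages"].append(
                    {"name": name, "status": "ok", "seconds": round(elapsed, 3)}
                )
                logger.info("stage %s: ok (%.2fs)", name, elapsed)
                return False
            report["stages"].append(
                {
                    "name": name,
                    "status": "failed",
                    "seconds": round(elapsed, 3),
                    "error": f"{exc_type.__name__}: {exc}",
                }
            )
            logger.error("stage %s failed: %s", name, exc)
            report["failed"] = name
            report["traceback"] = traceback.format_exc()
            return True  # swallow; caller checks report["failed"]

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the JSON-serializable run report.

    Stages after a failure are skipped; partial outputs are retained and
    the report marks the failure point.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(rng.integers(2**31))
        for name in ("anova", "allometry", "signal", "cva")
    }
    report: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_perm": config.n_perm,
        "conventions": {
            "tps_kernel": "U(r) = r^2 log r",
            "p_value_rule": "(count + 1) / n_perm, observed counted, clamped to 1",
            "size_transform": "identity",
            "sliding_criterion": "bending energy vs consensus",
        },
        "stages": [],
        "failed": None,
    }

    state: dict = {}

    with _stage(report, "load"):
        if config.simulate is not None:
            dataset = generate_dataset(config.simulate)
            paths = dataset.write(out / "simulated")
            report["simulated_paths"] = paths
            tps_records = dataset.configs
            specimen_records = landmark_io.read_specimen_table(paths["classifier"])
            newick_path = paths["newick"]
        else:
            tps_records = landmark_io.read_tps(config.tps_path)
            specimen_records = landmark_io.read_specimen_table(config.classifier_path)
            newick_path = config.newick_path
        matched, tps_orphans, table_orphans = landmark_io.join_records(
            tps_records, specimen_records
        )
        if tps_orphans or table_orphans:
            logger.warning(
                "join: %d TPS orphans, %d classifier orphans",
                len(tps_orphans), len(table_orphans),
            )
        report["join"] = {
            "matched": len(matched),
            "tps_orphans": tps_orphans,
            "table_orphans": table_orphans,
        }
        state["matched"] = matched
        state["newick_path"] = newick_path
    if report["failed"]:
        return _finish(report, out)

    with _stage(report, "align"):
        matched = state["matched"]
        configs = []
        for cfg_lm, rec, side in matched:
            configs.append(
                landmark_io.reflect(cfg_lm) if side == "right" else cfg_lm
            )
        if config.slide:
            aligned = superimposition.slide_and_align(configs)
        else:
            aligned = superimposition.gpa(configs)
        state["aligned"] = aligned
        state["ids"] = [rec.specimen_id for _, rec, _ in matched]
        state["sides"] = [side for _, _, side in matched]
        state["species"] = [rec.species for _, rec, _ in matched]
        state["habitats"] = [rec.habitat for _, rec, _ in matched]
    if report["failed"]:
        return _finish(report, out)

    with _stage(report, "procrustes_anova"):
        table = shape_stats.procrustes_anova(
            state["aligned"].flat(), state["ids"], state["sides"],
        )
        df = table.to_frame()
        df.to_csv(out / "procrustes_anova.csv", index=False)
        report["anova"] = {
            row[0]: {"SS": row[1], "F": row[4], "P": row[5]}
            for row in table.rows
            if row[0] in ("between-specimen", "within-specimen")
        }
    if report["failed"]:
        return _finish(report, out)

    with _stage(report, "average_sides"):
        shapes, sizes, order = superimposition.average_sides(
            state["aligned"], state["ids"], state["sides"]
        )
        by_id = {}
        for sid, sp, hab in zip(state["ids"], state["species"], state["habitats"]):
            by_id[sid] = (sp, hab)
        state["spec_flat"] = np.concatenate(
            [shapes[:, :, 0], shapes[:, :, 1]], axis=1
        )
        state["spec_sizes"] = sizes
        state["spec_ids"] = order
        state["spec_species"] = [by_id[s][0] for s in order]
        state["spec_habitats"] = [by_id[s][1] for s in order]
    if report["failed"]:
        return _finish(report, out)

    with _stage(report, "allometry"):
        model = shape_stats.allometry_regress(
            state["spec_flat"],
            state["spec_sizes"],
            state["spec_species"],
            n_perm=config.n_perm,
            seed=seeds["allometry"],
        )
        report["allometry"] = {
            "percent_predicted": model.percent_predicted,
            "p_value": model.p_value,
        }
        state["residuals"] = model.residuals
    if report["failed"]:
        return _finish(report, out)

    with _stage(report, "pca"):
        ord_ = shape_stats.pca(state["residuals"])
        state["pca"] = ord_
        n_show = min(10, len(ord_.percent_variance))
        report["pca"] = {
            "percent_variance_first_axes": ord_.percent_variance[:n_show].tolist(),
        }
        scores = pd.DataFrame(
            ord_.scores[:, : min(10, ord_.scores.shape[1])],
            columns=[f"PC{i + 1}" for i in range(min(10, ord_.scores.shape[1]))],
        )
        scores.insert(0, "habitat", state["spec_habitats"])
        scores.insert(0, "species", state["spec_species"])
        scores.insert(0, "specimen_id", state["spec_ids"])
        scores.to_csv(out / "pc_scores.csv", index=False)
    if report["failed"]:
        return _finish(report, out)

    if config.run_phylo and state.get("newick_path"):
        with _stage(report, "phylo"):
            tree = phylo.read_newick(state["newick_path"])
            species_arr = np.asarray(state["spec_species"])
            uniq = list(pd.unique(species_arr))
            mean_shapes = np.stack(
                [state["residuals"][species_arr == sp].mean(axis=0) for sp in uniq]
            )
            pruned, tip_shapes, match_report = phylo.match_species(
                tree, uniq, mean_shapes, merge_map=config.merge_map
            )
            report["species_match"] = match_report
            sp_ord = shape_stats.pca(tip_shapes)
            d_scores = min(sp_ord.scores.shape[1], 5)
            sig = phylo.phylo_signal_permutation(
                pruned,
                sp_ord.scores[:, :d_scores],
                n_perm=config.n_perm,
                seed=seeds["signal"],
            )
            report["phylo_signal"] = {
                "observed_tree_length": sig.observed_tree_length,
                "p_value": sig.p_value,
            }
            lam_rows = []
            for ax in range(min(config.n_pc_lambda, sp_ord.scores.shape[1])):
                fit = phylo.pagels_lambda(pruned, sp_ord.scores[:, ax])
                lam_rows.append(
                    {
                        "axis": f"PC{ax + 1}",
                        "lambda": fit.lambda_hat,
                        "p_vs_zero": fit.p_vs_zero,
                        "p_vs_one": fit.p_vs_one,
                    }
                )
            pd.DataFrame(lam_rows).to_csv(out / "pagels_lambda.csv", index=False)
            report["pagels_lambda"] = lam_rows
            anc = phylo.ancestral_states(pruned, sp_ord.scores[:, :d_scores])
            nodes, segments = phylo.phylomorphospace(
                pruned, sp_ord.scores[:, :d_scores], anc
            )
            node_rows = [
                {
                    "node": nid,
                    "is_tip": is_tip,
                    "name": pruned.tip_names[nid] if is_tip else "",
                    **{f"axis{a + 1}": float(c) for a, c in enumerate(coord)},
                }
                for nid, is_tip, coord in nodes
            ]
            pd.DataFrame(node_rows).to_csv(out / "phylomorphospace_nodes.csv", index=False)
            pd.DataFrame(segments, columns=["parent", "child"]).to_csv(
                out / "phylomorphospace_segments.csv", index=False
            )
        if report["failed"]:
            return _finish(report, out)

    if config.run_cva:
        with _stage(report, "cva"):
            res = shape_stats.cva(state["residuals"], state["spec_habitats"])
            maha, proc, p_m, p_p, levels = shape_stats.group_distance_tests(
                state["residuals"],
                state["spec_habitats"],
                n_perm=config.n_perm,
                seed=seeds["cva"],
            )
            report["cva"] = {
                "n_cv": int(res.cv_eigenvalues.size),
                "percent_between_variance": res.percent_between_variance.tolist(),
                "groups": levels,
            }
            rows = []
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    rows.append(
                        {
                            "group_i": levels[i], "group_j": levels[j],
                            "statistic": "mahalanobis",
                            "value": maha[i, j], "p": p_m[i, j],
                        }
                    )
                    rows.append(
                        {
                            "group_i": levels[i], "group_j": levels[j],
                            "statistic": "procrustes",
                            "value": proc[i, j], "p": p_p[i, j],
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "habitat_distances.csv", index=False)
            report["habitat_distances"] = rows
            cv_scores = pd.DataFrame(
                res.scores, columns=[f"CV{i + 1}" for i in range(res.scores.shape[1])]
            )
            cv_scores.insert(0, "habitat", state["spec_habitats"])
            cv_scores.insert(0, "species", state["spec_species"])
            cv_scores.insert(0, "specimen_id", state["spec_ids"])
            cv_scores.to_csv(out / "cv_scores.csv", index=False)
        if report["failed"]:
            return _finish(report, out)

    return _finish(report, out)


def _finish(report: dict, out: Path) -> dict:
    report["ok"] = report.get("failed") is None
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
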