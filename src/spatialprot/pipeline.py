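"""End-to-end orchestration of the synthetic pipeline from one config.

Stages run in dependency order (simulate -> preprocess -> diffexp ->
recurrence / enrich / shift, cluster, mtdna); every artifact is written with
a content digest and identical config + seed yields identical digests.  A
stage whose dependency is disabled refuses to run and the refusal is recorded
in the report; a genuine stage error aborts with the stage name while
partial artifacts persist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import annotation, diffexp, io, preprocess, qpcr, simulate, spatial

log = logging.getLogger("spatialprot")

DEFAULTS = {
    "min_intensity": 1000.0,
    "min_peptides": 2,
    "q": 0.2,
    "recurrence_min": 2,
    "enrichment_p": 1e-3,
    "elbow_floor": 0.1,
    "fuzzifier_m": 2.0,
    "trunc_quantile": 0.75,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages and return a machine-readable report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = dict(config.get("stages", {}))
    params = {**DEFAULTS, **config.get("params", {})}
    seed = int(config.get("seed", 0))
    # one substream per stage so toggling a stage never shifts another's draws
    stage_names = ["simulate", "cluster", "mtdna"]
    substreams = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(stage_names, np.random.SeedSequence(seed).spawn(len(stage_names)))
    }
    report: dict = {
        "seed": seed,
        "parameters": params,
        "stages": {},
        "artifacts": {},
    }

    def record_artifact(name: str, path: Path) -> None:
        report["artifacts"][name] = {"path": str(path), "sha256": _digest(path)}

    def enabled(stage: str) -> bool:
        return bool(stages.get(stage, False))

    def require(stage: str, deps: list[str]) -> bool:
        missing = [d for d in deps if not enabled(d)]
        if missing:
            report["stages"][stage] = {
                "status": "refused",
                "reason": f"disabled dependency stage(s): {missing}",
            }
            log.warning("stage=%s refused missing=%s", stage, missing)
            return False
        return True

    experiment = None
    pm = None
    fits: dict[str, diffexp.TwoComponentFit] = {}
    calls: dict[str, "object"] = {}

    # ---- simulate --------------------------------------------------------
    if enabled("simulate"):
        try:
            sim_cfg = simulate.config_from_dict(
                {**config.get("simulate", {}), "seed": substreams["simulate"]}
            )
            experiment = simulate.simulate_experiment(sim_cfg)
            io.write_psm_table(experiment.psm, out / "psm.tsv")
            io.write_design(experiment.design, out / "design.tsv")
            io.write_annotations(experiment.annotations, out / "annotations.tsv")
            io.write_fold_changes(experiment.transcript_fc, out / "transcript_fc.tsv")
            truth = experiment.truth.table.reset_index()
            io._write_table(
                out / "truth.tsv", list(truth.columns), truth.itertuples(index=False)
            )
            for name in ("psm", "design", "annotations", "transcript_fc", "truth"):
                record_artifact(name, out / f"{name}.tsv")
            report["stages"]["simulate"] = {
                "status": "ok",
                "n_psm": len(experiment.psm),
                "n_proteins": sim_cfg.n_proteins,
                "seed": substreams["simulate"],
            }
            log.info("stage=simulate rows=%d", len(experiment.psm))
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise PipelineError("simulate", str(exc)) from exc

    # ---- preprocess ------------------------------------------------------
    if enabled("preprocess") and require("preprocess", ["simulate"]):
        try:
            filtered = preprocess.filter_psms(
                experiment.psm,
                set(experiment.psm.channels),
                min_intensity=params["min_intensity"],
            )
            fit = preprocess.fit_normalization(filtered)
            peptide_matrix = preprocess.apply_normalization(filtered, fit)
            pm = preprocess.summarize_proteins(
                peptide_matrix, filtered, min_peptides=params["min_peptides"]
            )
            io.write_protein_matrix(pm, out / "protein_matrix.tsv")
            record_artifact("protein_matrix", out / "protein_matrix.tsv")
            report["stages"]["preprocess"] = {
                "status": "ok",
                "n_psm_in": len(experiment.psm),
                "n_psm_filtered": len(filtered),
                "n_proteins": len(pm.proteins),
                "normalization_converged": fit.converged,
            }
            log.info(
                "stage=preprocess rows_in=%d rows_out=%d proteins=%d",
                len(experiment.psm), len(filtered), len(pm.proteins),
            )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("preprocess", str(exc)) from exc

    # ---- diffexp ---------------------------------------------------------
    if enabled("diffexp") and require("diffexp", ["preprocess"]):
        try:
            contrast = tuple(
                config.get("diffexp", {}).get(
                    "contrast", list(experiment.design.regions[:2])
                )
            )
            all_calls = []
            for patient in experiment.design.patients:
                rv = diffexp.center_ratios(pm, experiment.design, patient, contrast)
                fit = diffexp.fit_two_component(
                    rv, trunc_quantile=params["trunc_quantile"]
                )
                fits[patient] = fit
                calls[patient] = diffexp.call_differential(fit, q_threshold=params["q"])
                all_calls.append(calls[patient])
            import pandas as pd

            stacked = pd.concat(all_calls, ignore_index=True)
            io._write_table(
                out / "calls.tsv", list(stacked.columns), stacked.itertuples(index=False)
            )
            record_artifact("calls", out / "calls.tsv")
            report["stages"]["diffexp"] = {
                "status": "ok",
                "contrast": list(contrast),
                "n_called_per_patient": {
                    p: int(t["called"].sum()) for p, t in calls.items()
                },
                "sigma0_per_patient": {p: f.sigma0 for p, f in fits.items()},
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("diffexp", str(exc)) from exc

    # ---- recurrence ------------------------------------------------------
    if enabled("recurrence") and require("recurrence", ["diffexp"]):
        try:
            recurrent, counts = diffexp.recurrence(
                calls, min_specimens=params["recurrence_min"]
            )
            io._write_table(
                out / "recurrence.tsv",
                ["protein_group", "n_specimens", "recurrent"],
                ((p, int(c), p in recurrent) for p, c in counts.items()),
            )
            record_artifact("recurrence", out / "recurrence.tsv")
            report["stages"]["recurrence"] = {
                "status": "ok",
                "n_recurrent": len(recurrent),
                "min_specimens": params["recurrence_min"],
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("recurrence", str(exc)) from exc

    # ---- enrich ----------------------------------------------------------
    if enabled("enrich") and require("enrich", ["diffexp"]):
        try:
            patient = experiment.design.patients[0]
            ranking = (
                fits[patient].z.sort_values(ascending=False).index.tolist()
            )
            gene_sets = config.get("enrich", {}).get("gene_sets")
            if gene_sets is None:
                gene_sets = {
                    t: set(m) for t, m in config.get("enrich", {}).get("sets", {}).items()
                }
            table, skipped = annotation.ranked_enrichment(
                ranking, gene_sets, p_threshold=params["enrichment_p"]
            )
            io._write_table(
                out / "enrichment.tsv", list(table.columns), table.itertuples(index=False)
            )
            record_artifact("enrichment", out / "enrichment.tsv")
            report["stages"]["enrich"] = {
                "status": "ok",
                "n_significant": len(table),
                "n_skipped": len(skipped),
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrich", str(exc)) from exc

    # ---- shift -----------------------------------------------------------
    if enabled("shift") and require("shift", ["diffexp"]):
        try:
            patient = experiment.design.patients[0]
            fc = {p: float(v) for p, v in fits[patient].z.items()}
            label = config.get("shift", {}).get(
                "compartment", experiment.config.compartment_label
            )
            result = annotation.compartment_shift(fc, experiment.annotations, label)
            report["stages"]["shift"] = {
                "status": "ok",
                "compartment": label,
                "median_shift": result.median_shift,
                "p_value": result.p_value,
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("shift", str(exc)) from exc

    # ---- cluster ---------------------------------------------------------
    if enabled("cluster") and require("cluster", ["preprocess"]):
        try:
            sectors_cfg = config.get("cluster", {}).get("sectors")
            design = experiment.design
            if sectors_cfg:
                sector_channels = [
                    design.channels_for_region(s)[0] for s in sectors_cfg
                ]
            else:
                sector_channels = list(pm.samples)
            profiles, dropped = spatial.standardize_profiles(pm, sector_channels)
            c_lo, c_hi = config.get("cluster", {}).get("c_range", [1, 6])
            elbow = spatial.select_c_elbow(
                profiles, (c_lo, c_hi), m=params["fuzzifier_m"],
                seed=substreams["cluster"], floor=params["elbow_floor"],
            )
            fit = spatial.fuzzy_cmeans(
                profiles, elbow.c_star, m=params["fuzzifier_m"],
                seed=substreams["cluster"],
            )
            io._write_table(
                out / "membership.tsv",
                ["protein_group"] + list(fit.membership.columns),
                (
                    [p] + [fit.membership.at[p, c] for c in fit.membership.columns]
                    for p in fit.membership.index
                ),
            )
            io._write_table(
                out / "elbow.tsv",
                ["c", "min_centroid_distance"],
                sorted(elbow.curve.items()),
            )
            record_artifact("membership", out / "membership.tsv")
            record_artifact("elbow", out / "elbow.tsv")
            report["stages"]["cluster"] = {
                "status": "ok",
                "c_star": elbow.c_star,
                "n_profiles": len(profiles),
                "n_dropped": len(dropped),
                "seed": substreams["cluster"],
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cluster", str(exc)) from exc

    # ---- mtdna -----------------------------------------------------------
    if enabled("mtdna"):
        try:
            mcfg = config.get("mtdna", {})
            table, pairs = simulate.simulate_qpcr(
                n_samples=int(mcfg.get("n_samples", 5)),
                true_log2_mt_ratio=mcfg.get("true_log2_mt_ratio", -1.0),
                ct_noise_sd=float(mcfg.get("ct_noise_sd", 0.1)),
                seed=substreams["mtdna"],
            )
            io.write_qpcr(table, out / "ct.tsv")
            record_artifact("ct", out / "ct.tsv")
            results, omitted = qpcr.delta_delta_ct(
                table,
                targets=list(simulate.DEFAULT_QPCR_TARGETS),
                reference_gene=simulate.DEFAULT_QPCR_REFERENCE,
                pairs=pairs,
            )
            io._write_table(
                out / "mtdna.tsv",
                ["tumor_sample", "peritumor_sample", "target", "log2_fc"],
                ((r.tumor_sample, r.peritumor_sample, r.target, r.log2_fc) for r in results),
            )
            record_artifact("mtdna", out / "mtdna.tsv")
            report["stages"]["mtdna"] = {
                "status": "ok",
                "n_results": len(results),
                "n_omitted": len(omitted),
                "seed": substreams["mtdna"],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mtdna", str(exc)) from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    return report
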