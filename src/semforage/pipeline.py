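"""End-to-end pipeline: score -> MVT battery -> CPM -> mediation.

``PipelineConfig`` is loaded from YAML and validated before execution; every
stage derives its randomness from the master seed via fixed per-stage child
seeds, and every written artifact carries a header with the seed and a hash
of the configuration.
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

from . import io as sfio
from ._seeds import child_seed
from .cpm import CPM, summarize_network
from .errors import DataError, FormatError
from .mediation import Mediation
from .mvt import (correlation_battery, irt_irs_model, optimality_regression,
                  ramping_test, test_position)
from .scoring import score
from .synthetic import Cohort, CohortConfig, ForagingPolicy, generate_cohort

log = logging.getLogger("semforage")

RESPONSE_TYPE_COLUMNS = ("n_fast_clustering", "n_fast_switching",
                         "n_slow_clustering", "n_slow_switching")
DEFAULT_MEDIATIONS = (
    {"m": "n_fast_switching", "y": "CAT_CR"},
    {"m": "n_slow_clustering", "y": "AUT_fluency"},
    {"m": "n_slow_clustering", "y": "AUT_uniqueness"},
)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    log_path: str
    out_dir: str
    mode: str = "spoken"
    embeddings_path: str | None = None
    manifest_path: str | None = None
    labels_path: str | None = None
    covariates_path: str | None = None
    alpha_edges: float = 0.01
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 5000
    seed: int = 0
    cpm_targets: tuple = RESPONSE_TYPE_COLUMNS
    mediations: tuple = DEFAULT_MEDIATIONS
    score_families: tuple = ("CAT_CR", "AUT_fluency", "AUT_uniqueness",
                             "Backward_span", "TMT_shifting",
                             "Stroop_interference")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("spoken", "typed"):
            raise FormatError("mode must be 'spoken' or 'typed'")
        if not (0 < self.alpha_edges < 1 and 0 < self.alpha < 1):
            raise FormatError("alpha levels must lie in (0, 1)")
        if self.n_perm < 100:
            raise FormatError("n_perm must be >= 100")
        if self.n_boot < 100:
            raise FormatError("n_boot must be >= 100")
        for p in (self.log_path, self.embeddings_path, self.manifest_path,
                  self.labels_path, self.covariates_path):
            if p is not None and not Path(p).exists():
                raise FormatError(f"input path does not exist: {p}")

    def content_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _headers(config: PipelineConfig) -> list[str]:
    return [f"seed={config.seed}", f"config_hash={config.content_hash()}"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute score -> mvt -> cpm -> mediate, writing artifacts to out_dir.

    Returns a report dict with per-stage row counts and headline statistics.
    A stage failure aborts the run with the failing stage named; artifacts
    written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _headers(config)
    report: dict = {"seed": config.seed, "config_hash": config.content_hash(),
                    "stages": {}}

    stage = "score"
    try:
        logdf = sfio.read_response_log(config.log_path, mode=config.mode)
        emb = (sfio.read_embeddings(config.embeddings_path)
               if config.embeddings_path else None)
        bundle = score(logdf, embeddings=emb, mode=config.mode)
        sfio.write_table(bundle.scored, out / "scored.tsv", hdr)
        sfio.write_table(bundle.summaries, out / "summaries.tsv", hdr)
        sfio.write_table(bundle.anchors, out / "positions.tsv", hdr)
        n_flagged = int(bundle.summaries["flagged_no_switch"].sum())
        report["stages"][stage] = {
            "rows": len(bundle.scored),
            "participants": int(bundle.summaries.shape[0]),
            "participants_without_switch": n_flagged,
        }
        log.info("score: %d rows, %d participants (%d without switches)",
                 len(bundle.scored), bundle.summaries.shape[0], n_flagged)

        stage = "mvt"
        mvt_rows = []
        for subset in ("all", "fast", "slow"):
            for metric in ("irtr", "irsr"):
                try:
                    for r in test_position(bundle.scored, bundle.anchors,
                                           metric=metric, switch_subset=subset):
                        mvt_rows.append(dataclasses.asdict(r))
                except Exception as exc:  # degenerate subsets are reported, not fatal
                    log.warning("position test (%s, %s) skipped: %s",
                                subset, metric, exc)
        try:
            ramp = ramping_test(bundle.scored, bundle.anchors)
            mvt_rows.append(dataclasses.asdict(ramp))
        except Exception as exc:
            log.warning("ramping test skipped: %s", exc)
        mvt_df = pd.DataFrame(mvt_rows)
        sfio.write_table(mvt_df, out / "mvt_position_tests.tsv", hdr)

        reg = optimality_regression(bundle.summaries)
        mixed = {}
        if emb is not None:
            for subset in ("clustering", "switching"):
                try:
                    mixed[subset] = dataclasses.asdict(
                        irt_irs_model(bundle.scored, subset))
                except DataError as exc:
                    log.warning("mixed model (%s) skipped: %s", subset, exc)
        report["stages"][stage] = {
            "position_tests": len(mvt_rows),
            "optimality": dataclasses.asdict(reg),
            "irt_irs_model": mixed,
        }

        counts = bundle.summaries[["participant", *RESPONSE_TYPE_COLUMNS]]
        if config.covariates_path:
            stage = "correlations"
            cov = sfio.read_table(config.covariates_path)
            fam = [c for c in config.score_families if c in cov.columns]
            battery = correlation_battery(counts, cov[["participant", *fam]],
                                          alpha=config.alpha)
            sfio.write_table(battery, out / "correlation_battery.tsv", hdr)
            report["stages"][stage] = {"pairs": len(battery),
                                       "significant":
                                       int(battery["significant"].sum())}

        cpm_report = {}
        if config.manifest_path and config.labels_path:
            stage = "cpm"
            bundles = sfio.read_connectivity(config.manifest_path,
                                             config.labels_path)
            order = {b.subject: b for b in bundles}
            merged = counts.set_index("participant")
            for target in config.cpm_targets:
                subjects = [s for s in merged.index if s in order]
                mats = [order[s] for s in subjects]
                behavior = merged.loc[subjects, target].to_numpy(float)
                model = CPM(mats, behavior, alpha=config.alpha_edges)
                res = model.fit()
                res.permutation_test(config.n_perm,
                                     seed=child_seed(config.seed,
                                                     "cpm_permutation"))
                deg, pairs = summarize_network(res.pos_mask,
                                               mats[0].node_labels)
                sfio.write_table(deg, out / f"cpm_{target}_degrees.tsv", hdr)
                mask_df = pd.DataFrame(
                    [(i, j, "positive") for i, j in sorted(res.pos_mask.edges)]
                    + [(i, j, "negative") for i, j in sorted(res.neg_mask.edges)],
                    columns=["node_i", "node_j", "sign"])
                sfio.write_table(mask_df, out / f"cpm_{target}_mask.tsv", hdr)
                cpm_report[target] = {
                    "rho": res.rho, "p_parametric": res.p_parametric,
                    "p_permutation": res.p_permutation,
                    "n_pos": len(res.pos_mask), "n_neg": len(res.neg_mask),
                }
            report["stages"][stage] = cpm_report
            with open(out / "cpm_results.json", "w") as fh:
                json.dump({"seed": config.seed, **cpm_report}, fh, indent=1)

        if config.covariates_path and config.manifest_path:
            stage = "mediate"
            med_report = {}
            cov = sfio.read_table(config.covariates_path)
            table = counts.merge(cov, on="participant")
            for k, spec in enumerate(config.mediations):
                m_col, y_col = spec["m"], spec["y"]
                x_col = spec.get("x", "pos_strength_" + m_col)
                # predictor: positive-mask strength of the CPM predicting m
                if x_col not in table.columns:
                    target = m_col
                    if target not in cpm_report:
                        log.warning("mediation %s->%s skipped: no CPM for %s",
                                    m_col, y_col, target)
                        continue
                    bundles = sfio.read_connectivity(config.manifest_path,
                                                     config.labels_path)
                    order = {b.subject: b for b in bundles}
                    subjects = [s for s in table["participant"] if s in order]
                    mats = [order[s] for s in subjects]
                    behavior = table.set_index("participant").loc[
                        subjects, target].to_numpy(float)
                    model = CPM(mats, behavior, alpha=config.alpha_edges)
                    res = model.fit()
                    mask = res.pos_mask
                    if len(mask) == 0:
                        # fold-intersection mask empty: fall back to the
                        # full-cohort selection at the same alpha
                        from .cpm import select_edges
                        mask, _ = select_edges([b.matrix for b in mats],
                                               behavior,
                                               alpha=config.alpha_edges)
                        log.warning("final positive mask for %s empty; using "
                                    "full-cohort selection (%d edges)",
                                    target, len(mask))
                    if len(mask) == 0:
                        log.warning("mediation %s->%s skipped: no positive "
                                    "edges selected", m_col, y_col)
                        continue
                    vec = [sum(b.matrix[i, j] for i, j in mask.edges)
                           for b in mats]
                    table = table.set_index("participant").assign(
                        **{x_col: pd.Series(vec, index=subjects)}).reset_index()
                med = Mediation.from_dataframe(table, x_col, m_col, y_col)
                r = med.fit(n_boot=config.n_boot,
                            seed=child_seed(config.seed, "mediate") + k)
                entry = r.to_dict()
                perm_p = cpm_report.get(m_col, {}).get("p_permutation")
                entry["cpm_flag"] = ("CPM not significant"
                                     if perm_p is not None
                                     and perm_p > config.alpha else "ok")
                med_report[f"{x_col}->{m_col}->{y_col}"] = entry
                (out / f"mediation_{k}.txt").write_text(r.summary() + "\n")
            with open(out / "mediation_results.json", "w") as fh:
                json.dump({"seed": config.seed, **med_report}, fh, indent=1)
            report["stages"][stage] = med_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def simulate_to_dir(cohort_config: CohortConfig, seed: int, out_dir) -> Cohort:
    """Generate a cohort and write every artifact the pipeline can consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cohort_config, seed)
    hdr = [f"seed={seed}"]
    sfio.write_response_log(cohort.logs, out / "responses.tsv", hdr)
    sfio.write_embeddings(cohort.space, out / "embeddings.txt")
    sfio.write_table(cohort.covariates, out / "covariates.tsv", hdr)
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    rows = []
    for b in cohort.bundles:
        p = mat_dir / f"{b.subject}.txt"
        sfio.write_matrix(b.matrix, p)
        rows.append(dict(subject_id=b.subject,
                         path=str(p.relative_to(out)), motion=b.motion))
    sfio.write_table(pd.DataFrame(rows), out / "manifest.tsv", hdr)
    sfio.write_node_labels(cohort.bundles[0].node_labels, out / "nodes.tsv")
    (out / "ground_truth.json").write_text(cohort.truth.to_json())
    return cohort
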