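"""End-to-end pipeline: cohort -> rollup -> {embedding, enrichment,
networks, labs} -> replication, driven by a single flat config.

Every stage writes tidy TSVs under the run directory and records its row
counts in ``manifest.json``; identical configs reproduce identical
manifests.  Structured log lines (stage, seed, counts) go to stderr and
``run.log``; no record is dropped silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as co
from . import embedding as em
from . import enrichment as en
from . import hierarchy as hi
from . import labs as lb
from . import networks as nw
from . import replication as rp
from .io import read_code_map, read_tables
from .synthetic import DEFAULT_AD_CODES

log = logging.getLogger("emrpheno.pipeline")

LEVELS_SCANNED = ("level2_category", "level3_category", "full_name")


@dataclass
class RunConfig:
    data_dir: str
    out_dir: str = "runs"
    validation_dir: str | None = None
    code_map_path: str | None = None
    case_codes: tuple[str, ...] = DEFAULT_AD_CODES
    min_age: int = 64
    reference_year: int = 2020
    match_ratio: int = 2
    network_threshold: float = 0.01
    or_high: float = 2.0
    or_low: float = 0.5
    alpha: float = 0.05
    lab_n_sim: int = 500
    min_encounters: int = 10
    min_span_years: float = 1.0
    seed_match: int = 0
    seed_sex_scan: int = 0
    seed_labs: int = 0
    run_embedding: bool = True
    run_enrichment: bool = True
    run_networks: bool = True
    run_labs: bool = True
    run_replication: bool = True
    run_sensitivity: bool = False
    levels: tuple[str, ...] = LEVELS_SCANNED

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("case_codes", "levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not (Path(self.data_dir) / "patients.tsv").exists():
            raise FileNotFoundError(
                f"data_dir {self.data_dir!r} has no patients.tsv")
        if self.validation_dir is not None and self.run_replication:
            if not (Path(self.validation_dir) / "patients.tsv").exists():
                raise FileNotFoundError(
                    f"validation_dir {self.validation_dir!r} has no patients.tsv")
            if self.code_map_path and not Path(self.code_map_path).exists():
                raise FileNotFoundError(
                    f"code_map {self.code_map_path!r} does not exist")
        if self.match_ratio < 1:
            raise ValueError("match_ratio must be >= 1")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    run_dir: Path
    manifest: dict = field(default_factory=dict)


def _write(frame: pd.DataFrame, run_dir: Path, name: str, manifest: dict) -> None:
    path = run_dir / name
    frame.to_csv(path, sep="\t", index=False)
    manifest["outputs"][name] = int(len(frame))
    log.info("wrote %s (%d rows)", name, len(frame))


def _cohort_sets(tables, config: RunConfig, hier, cases, controls, level):
    rolled = hi.rollup(tables.diagnoses, level, hier, strict=False)
    sets = hi.feature_sets(rolled, patient_ids=cases | controls)
    case_sets = {p: sets[p] for p in cases}
    ctrl_sets = {p: sets[p] for p in controls}
    return case_sets, ctrl_sets


def run_all(config: RunConfig) -> RunResult:
    """Execute the configured stages in dependency order."""
    config.validate()
    run_dir = Path(config.out_dir) / f"run_{_config_hash(config)}"
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    logging.getLogger("emrpheno").addHandler(handler)
    manifest: dict = {"config": asdict(config), "config_hash": _config_hash(config),
                      "outputs": {}, "stages": {}}
    try:
        tables = read_tables(config.data_dir)
        hier = hi.Hierarchy.from_frame(tables.hierarchy)

        # ---- cohort --------------------------------------------------------
        cases = co.identify_cases(tables, config.case_codes, config.min_age,
                                  config.reference_year)
        pool = co.eligible_controls(tables, config.case_codes, config.min_age,
                                    config.reference_year)
        if config.run_sensitivity:
            keep = co.encounter_filter(tables.patients, config.min_encounters,
                                       config.min_span_years)
            cases, pool = cases & keep, pool & keep
            log.info("sensitivity filter kept %d cases / %d pool", len(cases), len(pool))
        cov = co.covariates(tables.patients, config.reference_year,
                            include_encounters=config.run_sensitivity)
        scores = co.fit_propensity(cov, cases)
        match = co.nn_match(scores, cases, pool, config.match_ratio,
                            config.seed_match)
        balance = co.balance_report(cov, cases, pool, match)
        controls = set(match.control_ids)
        manifest["stages"]["cohort"] = {
            "n_cases": len(cases), "n_pool": len(pool),
            "n_controls": len(controls), "complete": match.complete,
            "max_smd_after": balance.max_after, "seed": config.seed_match}
        match_rows = [{"patient_id": c, "role": "case", "match_group": c,
                       "ps": float(scores[c])} for c in match.case_ids]
        match_rows += [{"patient_id": ctl, "role": "control", "match_group": c,
                        "ps": float(scores[ctl])}
                       for c, ctls in match.matched.items() for ctl in ctls]
        _write(pd.DataFrame(match_rows), run_dir, "match.tsv", manifest)
        _write(balance.table, run_dir, "balance.tsv", manifest)

        sex_map = dict(zip(tables.patients["patient_id"].astype(str),
                           tables.patients["sex"].astype(str)))

        # ---- embedding -----------------------------------------------------
        if config.run_embedding:
            case_sets, ctrl_sets = _cohort_sets(tables, config, hier, cases,
                                                controls, "full_name")
            all_sets = {**case_sets, **ctrl_sets}
            mat = em.one_hot(all_sets, names=hier.names)
            emb = em.reduce_2d(mat, reducer="pca")
            labels = pd.Series({p: (p in cases) for p in emb.index})
            assoc = em.axis_association(emb, labels, kind="binary")
            assoc.insert(0, "variable", "case_status")
            emb_out = emb.reset_index().rename(columns={"index": "patient_id"})
            _write(emb_out, run_dir, "embedding.tsv", manifest)
            _write(assoc, run_dir, "association.tsv", manifest)
            manifest["stages"]["embedding"] = {"n_patients": len(emb),
                                               "n_features": mat.shape[1]}
        else:
            manifest["stages"]["embedding"] = "skipped"

        # ---- enrichment ----------------------------------------------------
        disc_scans: dict[str, pd.DataFrame] = {}
        if config.run_enrichment:
            frames = []
            for level in config.levels:
                case_sets, ctrl_sets = _cohort_sets(tables, config, hier, cases,
                                                    controls, level)
                res = en.scan(case_sets, ctrl_sets, level=level,
                              alpha=config.alpha, or_high=config.or_high,
                              or_low=config.or_low)
                res["sex_stratum"] = "all"
                res["domain"] = "dx"
                frames.append(res)
                disc_scans[level] = res
                by_sex = en.sex_stratified_scan(case_sets, ctrl_sets, sex_map,
                                                seed=config.seed_sex_scan,
                                                level=level, alpha=config.alpha,
                                                or_high=config.or_high,
                                                or_low=config.or_low)
                for sex, sres in by_sex.items():
                    sres["sex_stratum"] = sex
                    sres["domain"] = "dx"
                    frames.append(sres)
            med_sets = en.medication_sets(tables.medications)
            med_case = {p: med_sets.get(p, set()) for p in cases}
            med_ctrl = {p: med_sets.get(p, set()) for p in controls}
            mres = en.scan(med_case, med_ctrl, level="medication",
                           alpha=config.alpha, or_high=config.or_high,
                           or_low=config.or_low)
            mres["sex_stratum"] = "all"
            mres["domain"] = "meds"
            frames.append(mres)
            enr = pd.concat(frames, ignore_index=True)
            _write(enr, run_dir, "enrichment.tsv", manifest)
            manifest["stages"]["enrichment"] = {
                "n_tests": len(enr), "seed": config.seed_sex_scan,
                "n_significant": int((enr["p_bonferroni"] < config.alpha).sum())}
        else:
            manifest["stages"]["enrichment"] = "skipped"

        # ---- networks ------------------------------------------------------
        if config.run_networks:
            case_sets, ctrl_sets = _cohort_sets(tables, config, hier, cases,
                                                controls, "level3_category")
            nets = {"AD": nw.build_conetwork(case_sets, config.network_threshold, "AD"),
                    "control": nw.build_conetwork(ctrl_sets, config.network_threshold,
                                                  "control")}
            node_rows, edge_rows = [], []
            metric_tables = {}
            for label, net in nets.items():
                metrics = nw.node_metrics(net)
                metric_tables[label] = metrics
                mt = metrics.reset_index().rename(columns={"index": "feature"})
                mt.insert(0, "group", label)
                mt["share"] = mt["feature"].map(net.nodes)
                node_rows.append(mt)
                for (u, v), share in net.edges.items():
                    edge_rows.append({"group": label, "source": u, "target": v,
                                      "pair_share": share})
            _write(pd.concat(node_rows, ignore_index=True), run_dir,
                   "network_nodes.tsv", manifest)
            _write(pd.DataFrame(edge_rows,
                                columns=["group", "source", "target", "pair_share"]),
                   run_dir, "network_edges.tsv", manifest)
            comp = nw.compare_networks(metric_tables["AD"], metric_tables["control"])
            _write(comp, run_dir, "network_compare.tsv", manifest)
            manifest["stages"]["networks"] = {
                lbl: {"nodes": net.n_nodes, "edges": net.n_edges}
                for lbl, net in nets.items()}
        else:
            manifest["stages"]["networks"] = "skipped"

        # ---- labs ----------------------------------------------------------
        if config.run_labs:
            cohort_ids = cases | controls
            med = lb.patient_medians(tables.labs)
            med = med.loc[[i for i in med.index if str(i) in cohort_ids]]
            med = lb.coverage_filter(med)
            compared = lb.compare_labs(med, cases, sex_map)
            _write(compared, run_dir, "lab_compare.tsv", manifest)
            sig = lb.significant_labs(compared, config.alpha)
            profile = lb.group_z(med, sig, cases, sex_map)
            prof_out = profile.reset_index().rename(columns={"index": "lab"})
            _write(prof_out, run_dir, "lab_z.tsv", manifest)
            if len(profile) >= 3:
                _, breaks = lb.cluster_breaks(profile, n_sim=config.lab_n_sim,
                                              alpha=config.alpha,
                                              seed=config.seed_labs)
                brows = [{"node": b.node_id,
                          "members_left": ";".join(b.members_left),
                          "members_right": ";".join(b.members_right),
                          "statistic": b.statistic, "p": b.p,
                          "alpha_level": b.alpha_level, "tested": b.tested,
                          "significant": b.significant} for b in breaks]
                _write(pd.DataFrame(brows), run_dir, "lab_clusters.tsv", manifest)
            manifest["stages"]["labs"] = {"n_labs": int(med.shape[1]),
                                          "n_significant": len(sig),
                                          "seed": config.seed_labs}
        else:
            manifest["stages"]["labs"] = "skipped"

        # ---- replication ---------------------------------------------------
        if config.run_replication and config.validation_dir:
            vtables = read_tables(config.validation_dir)
            vhier = hi.Hierarchy.from_frame(vtables.hierarchy)
            vcases = co.identify_cases(vtables, config.case_codes, config.min_age,
                                       config.reference_year)
            vpool = co.eligible_controls(vtables, config.case_codes,
                                         config.min_age, config.reference_year)
            vcov = co.covariates(vtables.patients, config.reference_year)
            vscores = co.fit_propensity(vcov, vcases)
            vmatch = co.nn_match(vscores, vcases, vpool, config.match_ratio,
                                 config.seed_match)
            vcontrols = set(vmatch.control_ids)
            vcase_sets, vctrl_sets = _cohort_sets(vtables, config, vhier, vcases,
                                                  vcontrols, "full_name")
            code_map = (read_code_map(config.code_map_path)
                        if config.code_map_path else
                        {f: f for sets in disc_scans.values()
                         for f in sets["feature"]})
            disc = disc_scans.get("full_name")
            if disc is None or disc.empty:
                manifest["stages"]["replication"] = "skipped (no discovery scan)"
            else:
                report = rp.replicate(disc, vcase_sets, vctrl_sets, code_map,
                                      alpha=config.alpha)
                _write(report.pairs, run_dir, "replication.tsv", manifest)
                summary = {
                    "n_significant_discovery": report.n_significant_discovery,
                    "n_mapped": report.n_mapped,
                    "n_replicated": report.n_replicated,
                    "replicated_fraction": report.replicated_fraction,
                    "threshold": report.threshold,
                    "spearman_rho": report.spearman_rho,
                    "spearman_p": report.spearman_p}
                (run_dir / "replication_summary.json").write_text(
                    json.dumps(summary, indent=2))
                manifest["stages"]["replication"] = summary
        else:
            manifest["stages"]["replication"] = "skipped"

        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return RunResult(run_dir, manifest)
    except Exception as exc:
        manifest["failed"] = str(exc)
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    finally:
        logging.getLogger("emrpheno").removeHandler(handler)
        handler.close()
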