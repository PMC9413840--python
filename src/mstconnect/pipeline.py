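"""End-to-end orchestration: simulate -> preprocess -> ALFF -> connectome -> stats.

`run_pipeline` executes the whole chain on a synthetic cohort under a
single validated configuration, collects per-subject and group-level
tables, and (optionally) writes a reproducible run directory whose log
records every threshold, every RNG seed, and a content hash per output
file.  Reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mstconnect import alff as _alff
from mstconnect import connectome as _conn
from mstconnect import preprocess as _pre
from mstconnect import stats as _stats
from mstconnect.synthetic import CohortSpec, SubjectRecord, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "participant_flow"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one serializable object.

    All thresholds default to the emulated study's printed constants
    (0.2 mm FD limit, 4 min retention, 0.01-0.08 Hz band, 10 dummy
    volumes, occipital-8 exclusion, alpha 0.05) and are echoed into the
    run log; nothing is hard-wired in stage code.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_dummy: int = 10
    fd_threshold_mm: float = 0.2
    min_minutes: float = 4.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    exclusion: str = "occipital8"
    n_perm: int = 10000
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            for k in ("responder_law", "nonresponder_law"):
                if k in cohort and isinstance(cohort[k], dict):
                    from mstconnect.synthetic import ReductionLaw

                    cohort[k] = ReductionLaw(**cohort[k])
            for k in ("planted_tree_a", "planted_tree_b"):
                if cohort.get(k) is not None:
                    cohort[k] = [tuple(e) for e in cohort[k]]
            cohort = CohortSpec(**cohort)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(cohort=cohort, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """All group-level outputs of one pipeline run."""

    cohort_table: pd.DataFrame
    excluded_subjects: list[str]
    global_results: dict
    nodal_results: pd.DataFrame
    alff_results: pd.DataFrame
    motion_results: dict
    sensitivity: _stats.MotionSensitivityReport | None
    report: dict


def _preprocess_subject(rec: SubjectRecord, cfg: RunConfig):
    """Per-subject preprocessing; returns (fd, flags, keep, resid, tissue)."""
    params = rec.motion.params[cfg.n_dummy :]
    values = _pre.drop_dummy_volumes(rec.roi_ts.values, cfg.n_dummy)
    tissue = {k: v[cfg.n_dummy :] for k, v in rec.tissue_ts.items()}

    fd = _pre.compute_fd_jenkinson(params)
    flags = _pre.flag_spikes(fd, cfg.fd_threshold_mm)
    n_retained = int(flags.size - flags.sum())
    keep = _pre.retention_decision(n_retained, cfg.cohort.tr_seconds, cfg.min_minutes)

    resid = None
    if keep:
        detrended = _pre.detrend_linear(values)
        design = _pre.build_design_36p(
            params,
            tissue,
            include_trend=False,
            spike_regressors=_pre.build_spike_regressors(flags),
        )
        resid = _pre.regress_nuisance(detrended, design)
    return fd, flags, n_retained, keep, resid


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis chain on a synthetic cohort.

    Stages: cohort simulation; per-subject FD/censoring/retention,
    detrending and 36-parameter nuisance regression; ROI ALFF on the
    unfiltered residuals; band-pass filtering, Pearson connectivity, MST
    extraction and graph metrics; responder classification and the
    permutation/FDR statistical battery including the motion-sensitivity
    suite.  Subjects failing the retention rule are excluded from the
    ALFF/connectome analyses but retained for head-motion analysis.
    """
    cfg = config
    spec = cfg.cohort
    records = simulate_cohort(spec)
    tr = spec.tr_seconds

    rows, excluded = [], []
    analyzed: list[str] = []
    alff_maps, matrices, trees = [], [], []
    for rec in records:
        fd, flags, n_retained, keep, resid = _preprocess_subject(rec, cfg)
        motion = _stats.motion_summary_metrics(fd, cfg.fd_threshold_mm)
        responder = _stats.classify_response(rec.caps_pre, rec.caps_post)
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "responder": responder,
            "caps_pre": rec.caps_pre,
            "caps_post": rec.caps_post,
            "age": rec.age,
            "education": rec.education,
            "mean_fd": float(fd.mean()),
            "n_retained": n_retained,
            "retained": keep,
            **motion,
        }
        rows.append(row)
        if not keep:
            excluded.append(rec.subject_id)
            continue
        analyzed.append(rec.subject_id)

        roi_labels = rec.roi_ts.roi_labels
        alff_vals = _alff.compute_alff(resid, tr, cfg.band_hz)
        alff_maps.append(_alff.zscore_map(alff_vals))

        filtered = _pre.bandpass(resid, tr, *cfg.band_hz)
        ts = _pre.RoiTimeSeries(values=filtered, roi_labels=roi_labels, tr_seconds=tr)
        excl = _conn.exclusion_preset(cfg.exclusion, roi_labels)
        W = _conn.connectivity_matrix(ts, exclude=excl)
        tree = _conn.build_mst(W)
        matrices.append(W)
        trees.append(tree)

    cohort_table = pd.DataFrame(rows)
    ana = cohort_table[cohort_table["retained"]].reset_index(drop=True)
    resp_mask = ana["responder"].to_numpy(dtype=bool)

    ss = np.random.SeedSequence(cfg.seed, spawn_key=(101,))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    report: dict = {
        "config": cfg.to_dict(),
        "n_subjects": len(records),
        "n_analyzed": len(analyzed),
        "n_excluded": len(excluded),
        "excluded_subjects": excluded,
        "n_responders_analyzed": int(resp_mask.sum()),
        "n_nonresponders_analyzed": int((~resp_mask).sum()),
        "seeds": seeds,
    }

    # ---- head motion (all subjects, 3*IQR outlier removal per metric) ----
    try:
        motion_results = _motion_analysis(cohort_table, cfg, seeds[0])
        report["motion_omnibus"] = motion_results["omnibus"]
        report["motion_posthoc"] = motion_results["posthoc"].to_dict(orient="records")
    except ValueError as err:  # e.g. a degenerate threshold makes a metric constant
        motion_results = {"omnibus": None, "posthoc": pd.DataFrame(), "skipped": str(err)}
        report["motion_omnibus"] = None
        report["motion_analysis_skipped"] = str(err)

    # ---- connectome / ALFF group analyses (analyzed subjects only) ----
    # need both groups represented and enough subjects for the tau screen
    enough = min(resp_mask.sum(), (~resp_mask).sum()) >= 2 and len(analyzed) >= 10
    sensitivity = None
    global_results = {}
    nodal_results = pd.DataFrame()
    alff_results = pd.DataFrame()
    if enough:
        node_labels = matrices[0].roi_labels
        glob_tab = pd.DataFrame([_conn.global_metrics(t).as_dict() for t in trees])
        nd = np.array([_conn.nodal_metrics(t).degree for t in trees], dtype=float)
        nb = np.array([_conn.nodal_metrics(t).betweenness_centrality for t in trees])
        mat_stack = np.array([m.weights for m in matrices])

        sensitivity = _stats.motion_sensitivity_suite(
            mat_stack, nd, nb, glob_tab, ana["mean_fd"].to_numpy(), alpha=cfg.alpha
        )
        global_results = _global_analysis(
            glob_tab, resp_mask, sensitivity, cfg, seeds[1], seeds[2]
        )
        nodal_results = _nodal_analysis(nd, nb, node_labels, resp_mask, cfg, seeds[3])

        alff_arr = np.array(alff_maps)
        obs, p = _stats.perm_test_two_group_many(
            alff_arr[resp_mask], alff_arr[~resp_mask], n_perm=cfg.n_perm, seed=seeds[4]
        )
        rej, p_adj = _stats.fdr_bh(p, alpha=cfg.alpha)
        alff_results = pd.DataFrame(
            {
                "roi": records[0].roi_ts.roi_labels,
                "mean_diff": obs,
                "p": p,
                "p_fdr": p_adj,
                "significant": rej,
            }
        )
        report.update(
            {
                "global_omnibus": global_results["omnibus"],
                "avg_strength_p": global_results["avg_strength"].p_value,
                "leaf_fraction_excluded": global_results["leaf_fraction_excluded"],
                "n_significant_nodes_bc": int(
                    nodal_results.query("metric == 'betweenness'")["significant"].sum()
                ),
                "n_significant_rois_alff": int(alff_results["significant"].sum()),
                "pct_edges_fd_correlated": sensitivity.pct_significant_edges,
                "edge_fd_tau_mean": sensitivity.edge_tau_mean,
            }
        )
    else:
        report["analysis_skipped"] = (
            "too few analyzable subjects for ALFF/connectome group analysis"
        )

    result = PipelineResult(
        cohort_table=cohort_table,
        excluded_subjects=excluded,
        global_results=global_results,
        nodal_results=nodal_results,
        alff_results=alff_results,
        motion_results=motion_results,
        sensitivity=sensitivity,
        report=report,
    )
    if outdir is not None:
        _write_run(result, cfg, Path(outdir))
    return result


def _motion_analysis(cohort_table: pd.DataFrame, cfg: RunConfig, seed: int) -> dict:
    metrics = ["median_fd", "max_fd", "n_outliers", "iqr_fd"]
    resp = cohort_table["responder"].to_numpy(dtype=bool)

    # omnibus on subjects that are outlier-free on every metric
    clean = np.ones(len(cohort_table), dtype=bool)
    for m in metrics:
        _, removed = _stats.remove_outliers_3iqr(cohort_table[m].to_numpy(float))
        clean[removed] = False
    omnibus = _stats.omnibus_group_by_metric(
        cohort_table.loc[clean, metrics].to_numpy(float),
        resp[clean].astype(int),
        n_perm=cfg.n_perm,
        seed=seed,
    )

    rows = []
    for k, m in enumerate(metrics):
        vals = cohort_table[m].to_numpy(float)
        kept, removed = _stats.remove_outliers_3iqr(vals)
        keep_mask = np.ones(vals.size, dtype=bool)
        keep_mask[removed] = False
        res = _stats.perm_test_two_group(
            vals[keep_mask & resp],
            vals[keep_mask & ~resp],
            n_perm=cfg.n_perm,
            seed=seed + 1 + k,
        )
        rows.append(
            {
                "metric": m,
                "observed_diff": res.observed_stat,
                "p": res.p_value,
                "n_removed_outliers": int(removed.size),
            }
        )
    posthoc = pd.DataFrame(rows)
    rej, p_adj = _stats.fdr_bh(posthoc["p"].to_numpy(), alpha=cfg.alpha)
    posthoc["p_fdr"] = p_adj
    posthoc["significant"] = rej
    return {"omnibus": omnibus, "posthoc": posthoc}


def _global_analysis(glob_tab, resp_mask, sensitivity, cfg, seed_a, seed_b) -> dict:
    strength = glob_tab["avg_strength"].to_numpy()
    avg_strength_res = _stats.perm_test_two_group(
        strength[resp_mask], strength[~resp_mask], n_perm=cfg.n_perm, seed=seed_a
    )
    integration = ["max_bc", "leaf_fraction", "diameter_norm", "avg_eccentricity_norm"]
    leaf_excluded = sensitivity.leaf_fraction_motion_confounded
    if leaf_excluded:
        integration.remove("leaf_fraction")
    omnibus = _stats.omnibus_group_by_metric(
        glob_tab[integration].to_numpy(),
        resp_mask.astype(int),
        n_perm=cfg.n_perm,
        seed=seed_b,
    )
    return {
        "avg_strength": avg_strength_res,
        "omnibus": omnibus,
        "metrics_tested": integration,
        "leaf_fraction_excluded": leaf_excluded,
        "table": glob_tab,
    }


def _nodal_analysis(nd, nb, node_labels, resp_mask, cfg, seed) -> pd.DataFrame:
    frames = []
    for k, (mname, table) in enumerate((("degree", nd), ("betweenness", nb))):
        obs, p = _stats.perm_test_two_group_many(
            table[resp_mask], table[~resp_mask], n_perm=cfg.n_perm, seed=seed + k
        )
        rej, p_adj = _stats.fdr_bh(p, alpha=cfg.alpha)
        frames.append(
            pd.DataFrame(
                {
                    "node": np.arange(len(node_labels)),
                    "roi": node_labels,
                    "metric": mname,
                    "mean_diff": obs,
                    "p": p,
                    "p_fdr": p_adj,
                    "significant": rej,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _write_run(result: PipelineResult, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    result.cohort_table.to_csv(outdir / "cohort_table.csv", index=False)
    if "table" in result.global_results:
        result.global_results["table"].to_csv(outdir / "global_metrics.csv", index=False)
    result.nodal_results.to_csv(outdir / "nodal_results.csv", index=False)
    result.alff_results.to_csv(outdir / "alff_results.csv", index=False)
    result.motion_results["posthoc"].to_csv(outdir / "motion_posthoc.csv", index=False)
    if result.sensitivity is not None:
        result.sensitivity.global_metric_results.to_csv(
            outdir / "sensitivity_global.csv", index=False
        )
        result.sensitivity.nodal_results.to_csv(
            outdir / "sensitivity_nodal.csv", index=False
        )
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2, default=str))
    hashes = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.name != "run_log.json"
    }
    log = {"thresholds": cfg.to_dict(), "seeds": result.report["seeds"], "hashes": hashes}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))


def participant_flow(enrolled: int, exclusions: dict[str, int]) -> tuple[pd.DataFrame, int]:
    """Participant-flow accounting: final n = enrolled - sum of exclusions.

    Returns the flow table (one row per exclusion reason plus the final
    count) and the final n; a negative final n is an error.
    """
    if enrolled < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be non-negative")
    final = enrolled - sum(exclusions.values())
    if final < 0:
        raise ValueError("exclusions exceed enrollment")
    rows = [{"stage": "enrolled", "n": enrolled}]
    rows += [{"stage": f"excluded: {k}", "n": -v} for k, v in exclusions.items()]
    rows.append({"stage": "final", "n": final})
    return pd.DataFrame(rows), final
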