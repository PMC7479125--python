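"""End-to-end orchestration: cohort -> networks -> rich club -> stats.

Stages, in order: fiber-count thresholding, hemisphere split, pooled
group-average network, hub selection, edge classification, per-subject
per-hemisphere connectivity measures (class density/strength, nodal
degree), normalized rich-club curves, asymmetry scores, group x
hemisphere ANOVAs with gated post hoc tests, asymmetry-score tests,
Bonferroni-corrected nodal-degree tests, covariate-adjusted Spearman
correlations with clinical scores, and the edge-wise aberrant-connection
census. Fully deterministic under a fixed master seed; every output
table carries the config hash and seed in its ``attrs``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import construction as con
from . import io as cio
from . import richclub as rc
from . import stats as st
from .synthetic import Cohort, CohortSpec, generate_cohort

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "run_pipeline",
    "report",
    "load_cohort_networks",
    "write_bundle",
]

logger = logging.getLogger("hemirc")

METRICS = [
    f"{cls}_{meas}" for cls in rc.EDGE_CLASSES for meas in ("density", "strength")
]


@dataclass
class RunConfig:
    """All pipeline parameters in one place.

    ``cohort_spec`` generates a synthetic cohort; alternatively pass a
    manifest/phenotype path pair for on-disk matrices. Fixed study
    constants sit at their published defaults: FN adoption threshold 3,
    hub fraction 16%, 1000 null networks, alpha 0.05, Bonferroni m = 45
    for nodal degree.
    """

    cohort_spec: CohortSpec | None = None
    manifest_path: str | None = None
    phenotype_path: str | None = None
    fn_threshold: int = 3
    hub_fraction: float = 0.16
    n_null: int = 1000
    n_swap_per_edge: int = 10
    alpha: float = 0.05
    bonferroni_m: int | None = None  # defaults to node count per hemisphere
    covariates: tuple = ("age", "sex", "handscore")
    average_mode: str = "include_zeros"
    compute_rich_club_curves: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_spec is None and self.manifest_path is None:
            raise ValueError("need either a cohort_spec or a manifest_path")
        if self.fn_threshold < 0:
            raise ValueError("fn_threshold must be nonnegative")
        if not (0 < self.hub_fraction < 1):
            raise ValueError("hub_fraction must be in (0, 1)")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_cohort_networks(manifest_path, phenotype_path):
    """Read per-subject FA/FN matrix pairs listed in a manifest."""
    manifest = cio.read_manifest(manifest_path)
    phenotypes = cio.read_phenotypes(phenotype_path)
    subjects = []
    groups = dict(zip(phenotypes.table["subject_id"], phenotypes.table["group"]))
    for sid, paths in manifest.items():
        fa = cio.read_matrix(paths["fa_path"])
        fn = cio.read_fiber_counts(paths["fn_path"])
        subjects.append((sid, groups[sid], fa, fn))
    return subjects, phenotypes


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a result bundle of DataFrames.

    Bundle keys: hub_partition, metrics (long table), nodal_degree
    (long table), asymmetry, rich_club_curves, anova, posthoc,
    asymmetry_tests, nodal_anova, spearman, edge_census, run_log.
    Any stage failure aborts with an error naming the stage.
    """
    state = {"stage": "ingest"}
    try:
        return _run_stages(config, state)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(
            f"pipeline stage {state['stage']!r} failed: {exc}"
        ) from exc


def _run_stages(config: RunConfig, state: dict) -> dict:
    def _stage(name):
        state["stage"] = name
        logger.info("stage: %s", name)
        return time.perf_counter()

    t0 = time.perf_counter()
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    log_rows = []

    def log_stage(name, t_start):
        log_rows.append({"stage": name, "seconds": time.perf_counter() - t_start, **stamp})

    # --- ingest ---------------------------------------------------------
    t = _stage("ingest")
    if config.cohort_spec is not None:
        cohort = generate_cohort(config.cohort_spec)
        subjects, phenotypes = cohort.subjects, cohort.phenotypes
    else:
        subjects, phenotypes = load_cohort_networks(
            config.manifest_path, config.phenotype_path
        )
    nodes = cio.default_node_table()
    log_stage("ingest", t)

    # --- threshold + split ---------------------------------------------
    t = _stage("threshold+split")
    pairs = {}
    for sid, group, fa, fn in subjects:
        thr = con.apply_fn_threshold(fa, fn, config.fn_threshold)
        pairs[sid] = (group, con.split_hemispheres(thr, nodes))
    log_stage("threshold+split", t)

    # --- pooled group-average network and hubs ---------------------------
    t = _stage("hubs")
    pooled = [hp.left for _g, hp in pairs.values()] + [
        hp.right for _g, hp in pairs.values()
    ]
    # homologue alignment: split_hemispheres already orders right rows to
    # mirror left rows, so the pooled elementwise mean is well defined
    avg_names = [nid.rsplit(".", 1)[0] for nid in pooled[0].node_ids]
    pooled_std = [
        cio.WeightedNetwork(nw.weights, avg_names, ["L"] * nw.n_nodes) for nw in pooled
    ]
    avg_net = con.group_average(pooled_std, mode=config.average_mode)
    hubs = rc.select_hubs(avg_net, fraction=config.hub_fraction)
    full_cls = _full_classification(avg_net.n_nodes, hubs)
    hub_df = pd.DataFrame(
        {"region": avg_net.node_ids, "is_hub": hubs.is_hub_mask(),
         "degree": rc.nodal_degree(avg_net), "strength": rc.nodal_strength(avg_net)}
    )
    log_stage("hubs", t)

    # --- per-subject measures -------------------------------------------
    t = _stage("measures")
    metric_rows, degree_rows = [], []
    edge_left, edge_right, edge_groups, edge_sids = [], [], [], []
    for sid, (group, hp) in pairs.items():
        for hemi, net in hp:
            cls = rc.classify_edges(net, hubs)
            for label in rc.EDGE_CLASSES:
                metric_rows.append(
                    {"subject_id": sid, "group": group, "hemisphere": hemi,
                     "metric": f"{label}_density",
                     "value": rc.class_density(net, cls, label)}
                )
                metric_rows.append(
                    {"subject_id": sid, "group": group, "hemisphere": hemi,
                     "metric": f"{label}_strength",
                     "value": rc.class_strength(net, cls, label)}
                )
            deg = rc.nodal_degree(net)
            for r, dv in zip(avg_net.node_ids, deg):
                degree_rows.append(
                    {"subject_id": sid, "group": group, "hemisphere": hemi,
                     "region": r, "value": int(dv)}
                )
        edge_left.append(hp.left.weights[full_cls.i_idx, full_cls.j_idx])
        edge_right.append(hp.right.weights[full_cls.i_idx, full_cls.j_idx])
        edge_groups.append(group)
        edge_sids.append(sid)
    metrics = pd.DataFrame(metric_rows)
    nodal = pd.DataFrame(degree_rows)
    log_stage("measures", t)

    # --- rich-club curves -------------------------------------------------
    curves = pd.DataFrame(
        columns=["subject_id", "group", "hemisphere", "k", "phi", "phi_null_mean", "phi_norm"]
    )
    if config.compute_rich_club_curves:
        t = _stage("rich club")
        curve_rows = []
        for sid, (group, hp) in pairs.items():
            for hemi, net in hp:
                seed = rc.derive_seed(config.seed, sid, hemi)
                curve = rc.normalized_rich_club(
                    net, n_null=config.n_null, seed=seed,
                    n_swap_per_edge=config.n_swap_per_edge,
                )
                for k, ph, nm, pn, ok in zip(
                    curve.k_values, curve.phi, curve.phi_null_mean,
                    curve.phi_norm, curve.defined_mask,
                ):
                    if ok:
                        curve_rows.append(
                            {"subject_id": sid, "group": group, "hemisphere": hemi,
                             "k": int(k), "phi": ph, "phi_null_mean": nm, "phi_norm": pn}
                        )
        curves = pd.DataFrame(curve_rows)
        log_stage("rich club", t)

    # --- asymmetry scores -------------------------------------------------
    t = _stage("asymmetry")
    ph = phenotypes.table.set_index("subject_id")
    wide = metrics.pivot_table(
        index=["subject_id", "group", "metric"], columns="hemisphere",
        values="value", aggfunc="first",
    ).reset_index()
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        wide["as_value"] = st.asymmetry_score(wide["R"], wide["L"])
    asym = wide[["subject_id", "group", "metric", "as_value"]]
    log_stage("asymmetry", t)

    # --- group statistics --------------------------------------------------
    t = _stage("stats")
    covs = list(config.covariates)
    joined = metrics.merge(
        phenotypes.table[["subject_id"] + covs], on="subject_id"
    )
    anova_rows, posthoc_frames = [], []
    for metric in METRICS:
        sub = joined[joined["metric"] == metric]
        res = st.mixed_anova(sub, covariates=covs)
        row = {"metric": metric, **res.as_dict(), **stamp}
        anova_rows.append(row)
        if min(res.p_group, res.p_hemisphere, res.p_interaction) < config.alpha:
            pt = st.posthoc_tests(sub, covariates=covs)
            pt.insert(0, "metric", metric)
            posthoc_frames.append(pt)
    anova = pd.DataFrame(anova_rows)
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(columns=["metric", "comparison", "stratum", "t", "df", "p"])
    )

    asym_cov = asym.merge(phenotypes.table[["subject_id"] + covs], on="subject_id")
    as_frames = []
    for metric in METRICS:
        sub = asym_cov[asym_cov["metric"] == metric]
        at = st.asymmetry_tests(sub, covariates=covs)
        at.insert(0, "metric", metric)
        as_frames.append(at)
    asym_tests = pd.concat(as_frames, ignore_index=True)

    # nodal degree: per-region ANOVA, Bonferroni over regions
    m_bonf = config.bonferroni_m or nodal["region"].nunique()
    ndeg = nodal.rename(columns={"region": "metric"}).merge(
        phenotypes.table[["subject_id"] + covs], on="subject_id"
    )
    nodal_rows = []
    for region, sub in ndeg.groupby("metric", sort=False):
        res = st.mixed_anova(sub, covariates=covs)
        nodal_rows.append(
            {"region": region,
             "F_group": res.F_group, "p_group": res.p_group,
             "p_group_bonf": st.bonferroni(res.p_group, m_bonf),
             "F_hemisphere": res.F_hemisphere, "p_hemisphere": res.p_hemisphere,
             "p_hemisphere_bonf": st.bonferroni(res.p_hemisphere, m_bonf),
             "F_interaction": res.F_interaction, "p_interaction": res.p_interaction,
             "p_interaction_bonf": st.bonferroni(res.p_interaction, m_bonf)}
        )
    nodal_anova = pd.DataFrame(nodal_rows)

    # clinical correlations: AS of peripheral nodal degree vs YMRS/HAMD in BD
    spearman_rows = []
    bd_ph = ph[ph["group"] == "BD"]
    deg_wide = nodal.pivot_table(
        index=["subject_id", "region"], columns="hemisphere", values="value",
        aggfunc="first",
    ).reset_index()
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        deg_wide["as_value"] = st.asymmetry_score(deg_wide["R"], deg_wide["L"])
    periph = set(hubs.peripheral_ids)
    for region in sorted(periph):
        sub = deg_wide[deg_wide["region"] == region].set_index("subject_id")
        sub = sub.join(bd_ph, how="inner")
        if sub["as_value"].isna().all():
            continue
        cov_m = np.column_stack(
            [pd.factorize(sub[c])[0] if sub[c].dtype == object else sub[c] for c in covs]
        ) if covs else None
        for score in ("ymrs", "hamd"):
            y = sub[score].to_numpy(dtype=float)
            x = sub["as_value"].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 5:
                continue
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                rho, p = st.partial_spearman(
                    x[ok], y[ok], covariates=cov_m[ok] if cov_m is not None else None
                )
                rho_raw, p_raw = st.partial_spearman(x[ok], y[ok])
            spearman_rows.append(
                {"region": region, "score": score, "rho": rho, "p": p,
                 "rho_unadjusted": rho_raw, "p_unadjusted": p_raw, "n": int(ok.sum())}
            )
    spearman = pd.DataFrame(spearman_rows)

    census = st.edgewise_census(
        np.vstack(edge_left), np.vstack(edge_right), np.array(edge_groups),
        full_cls, alpha=config.alpha,
    )
    log_stage("stats", t)

    run_log = pd.DataFrame(log_rows + [{"stage": "total", "seconds": time.perf_counter() - t0, **stamp}])
    bundle = {
        "hub_partition": hub_df,
        "metrics": metrics,
        "nodal_degree": nodal,
        "asymmetry": asym,
        "rich_club_curves": curves,
        "anova": anova,
        "posthoc": posthoc,
        "asymmetry_tests": asym_tests,
        "nodal_anova": nodal_anova,
        "spearman": spearman,
        "edge_census": census,
        "run_log": run_log,
    }
    for df in bundle.values():
        df.attrs.update(stamp)
    return bundle


def _full_classification(n: int, hubs) -> rc.EdgeClassification:
    """Classification over ALL node pairs (for the edge census, where an
    absent edge is a true zero, not missing)."""
    iu, ju = np.triu_indices(n, k=1)
    is_hub = hubs.is_hub_mask()
    ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    labels = np.empty(len(iu), dtype="U9")
    labels[ends == 2] = "rich_club"
    labels[ends == 1] = "feeder"
    labels[ends == 0] = "local"
    return rc.EdgeClassification(iu, ju, labels, n)


def report(bundle: dict) -> str:
    """Markdown summary with the conventional significance stars."""
    for key in ("anova", "asymmetry_tests", "edge_census", "hub_partition"):
        if key not in bundle:
            raise ValueError(f"result bundle missing {key!r}")
    lines = ["# Hemispheric rich-club analysis report", ""]
    stamp = bundle["anova"].attrs
    if stamp:
        lines.append(
            f"config `{stamp.get('config_hash', '?')}`, seed {stamp.get('seed', '?')}"
        )
        lines.append("")
    lines.append("## Hubs")
    hubs = bundle["hub_partition"]
    hub_names = ", ".join(hubs.loc[hubs["is_hub"], "region"])
    lines.append(f"{int(hubs['is_hub'].sum())} hub regions: {hub_names}")
    lines.append("")
    lines.append("## Group x hemisphere ANOVA (connectivity measures)")
    lines.append("| metric | F group (p) | F hemisphere (p) | F interaction (p) |")
    lines.append("|---|---|---|---|")
    for _, r in bundle["anova"].iterrows():
        cells = []
        for eff in ("group", "hemisphere", "interaction"):
            f, p = r[f"F_{eff}"], r[f"p_{eff}"]
            cells.append(f"{f:.2f} ({p:.4f}){st.significance_stars(p)}")
        lines.append(f"| {r['metric']} | " + " | ".join(cells) + " |")
    lines.append("")
    lines.append("## Asymmetry scores")
    lines.append("| metric | comparison | stratum | t | df | p |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in bundle["asymmetry_tests"].iterrows():
        lines.append(
            f"| {r['metric']} | {r['comparison']} | {r['stratum']} | "
            f"{r['t']:.2f} | {r['df']} | {r['p']:.4f}{st.significance_stars(r['p'])} |"
        )
    lines.append("")
    lines.append("## Edge-wise aberrant-connection census")
    lines.append("| effect | class | significant / total | % |")
    lines.append("|---|---|---|---|")
    for _, r in bundle["edge_census"].iterrows():
        lines.append(
            f"| {r['effect']} | {r['class']} | {r['n_significant']} / {r['n_total']} "
            f"| {r['proportion_pct']:.1f} |"
        )
    return "\n".join(lines) + "\n"


def write_bundle(bundle: dict, outdir) -> None:
    """Persist every table as TSV (config hash and seed in a header
    comment) plus the markdown report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            stamp = df.attrs
            fh.write(
                f"# config_hash={stamp.get('config_hash', '')} seed={stamp.get('seed', '')}\n"
            )
            df.to_csv(fh, sep="\t", index=False)
    (outdir / "report.md").write_text(report(bundle))
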