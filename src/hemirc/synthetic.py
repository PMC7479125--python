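"""Synthetic DTI-like cohorts with hub structure and group effects.

Generates whole-brain 90-node FA / fiber-count matrix pairs with a
planted core-periphery (rich-club) architecture, hemisphere-mirrored
topology, configurable left-right asymmetry, and bipolar-disorder-like
group effects concentrated in feeder and local connections. The point is
to exercise every pipeline stage with data whose ground truth is known,
so that effect directions, calibration, and power are testable without
any imaging data.

What the generator emulates: symmetric nonnegative FA-weighted matrices,
a hub set with elevated degree and edge weight (so phi_norm > 1 at high
k by construction), homologous topology across hemispheres, group
deficits applied multiplicatively to feeder/local edge weights, a
leftward feeder asymmetry in patients and a rightward local asymmetry in
controls, fiber counts arranged so a configurable fraction of candidate
edges fails the FN > 3 adoption rule, and clinical scores monotonically
linked to an injected per-patient degree-asymmetry severity. What it
does not emulate: tractography geometry, distance-dependent connection
probabilities, or realistic regional FA profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    FiberCountMatrix,
    PhenotypeTable,
    WeightedNetwork,
    default_node_table,
    write_matrix,
)
from .richclub import derive_seed

__all__ = ["CohortSpec", "Cohort", "generate_base_connectome", "generate_cohort", "write_cohort"]

# hub regions typical of white-matter connectomes (PUT, INS, PCUN, PoCG,
# PreCG, TPOsup, MOG) as positions in the packaged 45-region ordering
DEFAULT_HUB_POSITIONS = (0, 14, 25, 28, 33, 36, 41)


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults follow the study design where stated (55 controls, 49
    patients, 45 regions per hemisphere, 7 hubs) and otherwise sit at
    values typical for FN-thresholded FA networks; see the methods note.
    Asymmetry targets are on the AS scale (percent, [-100, 100]).
    """

    n_nc: int = 55
    n_bd: int = 49
    n_nodes_per_hemi: int = 45
    hub_count: int = 7
    base_density: float = 0.30
    fa_mean: float = 0.45
    fa_sd: float = 0.10
    core_weight_boost: float = 1.3
    bd_feeder_deficit: float = 0.10
    bd_local_deficit: float = 0.15
    nc_local_rightward: float = 5.0
    bd_feeder_leftward: float = 5.0
    severity_local_deletion: float = 0.25
    subject_noise_sd: float = 0.10
    fn_fail_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nc, self.n_bd) < 1:
            raise ValueError("subject counts must be positive")
        if not (0 < self.base_density <= 1):
            raise ValueError("base_density must be in (0, 1]")
        if not (0 < self.fa_mean < 1):
            raise ValueError("fa_mean must be in (0, 1)")
        for name in ("bd_feeder_deficit", "bd_local_deficit", "severity_local_deletion"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0 < self.hub_count < self.n_nodes_per_hemi):
            raise ValueError("hub_count must be in (0, n_nodes_per_hemi)")
        for name in ("nc_local_rightward", "bd_feeder_leftward"):
            if not (0 <= abs(getattr(self, name)) < 100):
                raise ValueError(f"|{name}| must be < 100")

    def hub_positions(self) -> np.ndarray:
        if self.n_nodes_per_hemi == 45 and self.hub_count == 7:
            return np.array(DEFAULT_HUB_POSITIONS)
        return np.unique(
            np.linspace(0, self.n_nodes_per_hemi - 1, self.hub_count).astype(int)
        )


@dataclass
class Cohort:
    """Generated subjects plus ground truth for recovery tests."""

    subjects: list  # (subject_id, group, WeightedNetwork, FiberCountMatrix)
    phenotypes: PhenotypeTable
    template_fa: WeightedNetwork
    template_fn: FiberCountMatrix
    hub_positions: np.ndarray
    spec: CohortSpec


def _deletion_rate(as_target: float) -> float:
    """Edge-deletion rate on the disadvantaged side hitting AS exactly.

    Deleting a fraction f of one hemisphere's class edges scales both
    that class's density and (in expectation) its strength by (1 - f),
    so AS = 100 f / (2 - f) and f = 2 AS / (100 + AS) in closed form —
    one mechanism moves both connectivity measures to the same target.
    """
    a = abs(as_target)
    return 2.0 * a / (100.0 + a)


def _edge_class_masks(n: int, hub_pos: np.ndarray):
    """Boolean upper-triangle masks of hub-hub / feeder / local pairs."""
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hub_pos] = True
    iu, ju = np.triu_indices(n, k=1)
    ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    return iu, ju, {"rich_club": ends == 2, "feeder": ends == 1, "local": ends == 0}


def generate_base_connectome(spec: CohortSpec):
    """Population-template whole-brain FA network and fiber counts.

    Hub-hub pairs connect with probability 0.95 and carry a
    ``core_weight_boost`` weight advantage; feeder pairs connect at 2.5x
    and local pairs at 1x a base rate solved so the whole hemisphere
    hits ``base_density``. The right hemisphere mirrors the left exactly
    (template asymmetry is injected at cohort level, per group).
    """
    nh = spec.n_nodes_per_hemi
    hub_pos = spec.hub_positions()
    iu, ju, masks = _edge_class_masks(nh, hub_pos)
    n_pairs = {c: int(m.sum()) for c, m in masks.items()}
    total_pairs = len(iu)
    m_target = spec.base_density * total_pairs
    p_hh = 0.95
    # solve p_local from: p_hh*n_rc + 2.5*x*n_feeder + x*n_local = m_target
    x = (m_target - p_hh * n_pairs["rich_club"]) / (
        2.5 * n_pairs["feeder"] + n_pairs["local"]
    )
    if not (0 < x and 2.5 * x <= 1):
        raise ValueError(
            "infeasible base_density / hub_count combination for the "
            "core-periphery wiring probabilities"
        )
    p_edge = np.empty(total_pairs)
    p_edge[masks["rich_club"]] = p_hh
    p_edge[masks["feeder"]] = 2.5 * x
    p_edge[masks["local"]] = x

    rng = np.random.default_rng(derive_seed(spec.seed, "template"))
    present = rng.random(total_pairs) < p_edge
    w = np.clip(rng.normal(spec.fa_mean, spec.fa_sd, total_pairs), 0.05, 0.95)
    w[masks["rich_club"]] = np.clip(
        w[masks["rich_club"]] * spec.core_weight_boost, 0.05, 0.98
    )
    w = np.where(present, w, 0.0)

    hemi = np.zeros((nh, nh))
    hemi[iu, ju] = w
    hemi = hemi + hemi.T

    n = 2 * nh
    whole = np.zeros((n, n))
    whole[:nh, :nh] = hemi
    whole[nh:, nh:] = hemi  # exact mirror
    # inter-hemispheric edges: homotopic plus sparse heterotopic
    homotopic = rng.random(nh) < 0.8
    wh = np.clip(rng.normal(spec.fa_mean, spec.fa_sd, nh), 0.05, 0.95) * homotopic
    whole[np.arange(nh), np.arange(nh) + nh] = wh
    hetero = rng.random((nh, nh)) < 0.03
    np.fill_diagonal(hetero, False)
    wx = np.clip(rng.normal(spec.fa_mean, spec.fa_sd, (nh, nh)), 0.05, 0.95) * hetero
    whole[:nh, nh:] += wx
    whole[nh:, :nh] = whole[:nh, nh:].T

    # fiber counts: most adopted edges clear FN > 3, a configurable
    # fraction gets counts in {1,2,3} and is dropped by the filter;
    # counts are mirrored across hemispheres like the FA weights so the
    # template carries no fiber-count asymmetry
    hemi_exists = hemi > 0
    h_fail = np.triu((rng.random((nh, nh)) < spec.fn_fail_fraction), 1)
    h_fail = (h_fail | h_fail.T) & hemi_exists
    fn_h = np.where(hemi_exists, 4 + rng.poisson(20, (nh, nh)), 0)
    fn_h = np.where(h_fail, rng.integers(1, 4, (nh, nh)), fn_h)
    fn_h = np.triu(fn_h, 1)
    fn_h = fn_h + fn_h.T
    fn = np.zeros((n, n), dtype=int)
    fn[:nh, :nh] = fn_h
    fn[nh:, nh:] = fn_h
    inter = whole[:nh, nh:] > 0
    fn_x = np.where(inter, 4 + rng.poisson(20, (nh, nh)), 0)
    fn[:nh, nh:] = fn_x
    fn[nh:, :nh] = fn_x.T
    np.fill_diagonal(fn, 0)

    nodes = default_node_table() if nh == 45 else None
    if nodes is not None:
        labels = nodes.node_labels()
        tags = list(nodes.table["hemisphere"])
    else:
        labels = [f"n{i}" for i in range(n)]
        tags = ["L"] * nh + ["R"] * nh
    fa_net = WeightedNetwork(whole, labels, tags)
    return fa_net, FiberCountMatrix(fn)


def _delete_class_side(w, iu, ju, mask, side: str, rate: float, nh: int, rng):
    """Zero a random fraction of one hemisphere's class edges in place."""
    if rate <= 0:
        return
    block = (ju < nh) if side == "L" else (iu >= nh)
    cand = np.flatnonzero(mask & block & (w > 0))
    if cand.size:
        w[cand[rng.random(cand.size) < rate]] = 0.0


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Per-subject (FA, FN) matrices plus phenotypes.

    Controls carry the template plus a rightward local-connection
    asymmetry at ``nc_local_rightward``; patients get feeder/local FA
    deficits, a leftward feeder asymmetry at ``bd_feeder_leftward``, a
    severity-scaled deletion of right-hemisphere local edges (driving
    recoverable degree asymmetry), and clinical scores monotonically
    linked to that severity. Hemispheric asymmetry is injected by seeded
    edge deletion on the disadvantaged side, which moves connectivity
    density and strength to the same AS target; per-subject Poisson
    jitter on the fiber counts makes near-threshold edges flicker
    through the FN > 3 filter so density varies realistically across
    subjects. All draws derive from the master seed.
    """
    template_fa, template_fn = generate_base_connectome(spec)
    n = template_fa.n_nodes
    nh = spec.n_nodes_per_hemi
    hub_pos = spec.hub_positions()
    whole_hubs = np.concatenate([hub_pos, hub_pos + nh])
    iu, ju, masks = _edge_class_masks(n, whole_hubs)
    base_w = template_fa.weights[iu, ju]

    f_nc = _deletion_rate(spec.nc_local_rightward)
    f_bd = _deletion_rate(spec.bd_feeder_leftward)
    base_fn = template_fn.counts[iu, ju]

    subjects = []
    pheno_rows = []
    order = [("NC", i) for i in range(spec.n_nc)] + [("BD", i) for i in range(spec.n_bd)]
    for group, i in order:
        sid = f"{group.lower()}{i + 1:03d}"
        rng = np.random.default_rng(derive_seed(spec.seed, "subject", sid))
        w = base_w * rng.lognormal(0.0, spec.subject_noise_sd, base_w.shape)
        severity = 0.0
        if group == "NC":
            # rightward local asymmetry: thin the left local edges
            _delete_class_side(w, iu, ju, masks["local"], "L", f_nc, nh, rng)
        else:
            w[masks["feeder"]] *= 1.0 - spec.bd_feeder_deficit
            w[masks["local"]] *= 1.0 - spec.bd_local_deficit
            # leftward feeder asymmetry: thin the right feeder edges
            _delete_class_side(w, iu, ju, masks["feeder"], "R", f_bd, nh, rng)
            # severity-linked deletion of right-hemisphere local edges ->
            # leftward degree asymmetry of peripheral regions
            severity = float(rng.uniform(0.0, 1.0))
            if spec.severity_local_deletion > 0:
                right_local = masks["local"] & (iu >= nh) & (base_w > 0)
                cand = np.flatnonzero(right_local)
                k = int(round(spec.severity_local_deletion * severity * len(cand)))
                if k:
                    w[rng.choice(cand, size=k, replace=False)] = 0.0
        w = np.clip(w, 0.0, 0.995)
        fa = np.zeros((n, n))
        fa[iu, ju] = w
        fa = fa + fa.T
        # Poisson jitter around the template counts: edges near the FN
        # adoption threshold flicker per subject, so post-filter density
        # varies across subjects and hemispheres
        fn_edges = np.where(w > 0, rng.poisson(np.maximum(base_fn, 1)), 0)
        fn = np.zeros((n, n), dtype=int)
        fn[iu, ju] = fn_edges
        fn = fn + fn.T
        net = WeightedNetwork(fa, list(template_fa.node_ids), list(template_fa.hemisphere_tags))
        subjects.append((sid, group, net, FiberCountMatrix(fn)))

        prng = np.random.default_rng(derive_seed(spec.seed, "pheno", sid))
        row = {
            "subject_id": sid,
            "group": group,
            "age": float(np.round(prng.uniform(21, 50), 1)),
            "sex": "M" if prng.random() < 0.5 else "F",
            "handscore": float(np.round(prng.uniform(0.75, 1.0), 3)),
            "ymrs": np.nan,
            "hamd": np.nan,
        }
        if group == "BD":
            # negative-binomial counts with a logistic mean link to severity
            mu_y = 2.0 + 35.0 / (1.0 + np.exp(-4.0 * (severity - 0.5)))
            mu_h = 2.0 + 26.0 / (1.0 + np.exp(-4.0 * (severity - 0.5)))
            size = 15.0
            row["ymrs"] = int(min(41, prng.negative_binomial(size, size / (size + mu_y))))
            row["hamd"] = int(min(32, prng.negative_binomial(size, size / (size + mu_h))))
        pheno_rows.append(row)

    phenotypes = PhenotypeTable(pd.DataFrame(pheno_rows))
    return Cohort(subjects, phenotypes, template_fa, template_fn, hub_pos, spec)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write FA/FN matrices, manifest YAML and phenotype TSV in exactly
    the formats the I/O layer reads back; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": {}}
    for sid, _group, fa, fn in cohort.subjects:
        fa_path = f"{sid}_fa.tsv"
        fn_path = f"{sid}_fn.tsv"
        write_matrix(fa, outdir / fa_path)
        write_matrix(fn, outdir / fn_path)
        manifest["subjects"][sid] = {"fa_path": fa_path, "fn_path": fn_path}
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    cohort.phenotypes.table.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    return outdir / "manifest.yaml"
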