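"""End-to-end pipeline orchestration from a single YAML configuration.

Stages run in dependency order: synth -> preprocess -> niche -> beta ->
assembly -> network (intradomain) -> roles/stability -> interdomain ->
evo.  One master seed feeds named substreams per stage; every output file
is recorded in a manifest with its SHA256, so reruns with an identical
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as assembly_mod
from . import beta as beta_mod
from . import io as io_mod
from . import netinfer, nettopo
from . import niche as niche_mod
from . import preprocess as prep_mod
from ._rng import child_seed
from .evo import bisse_fit, compare_branch_lengths
from .synth import SyntheticDesign, generate_bd_tree, generate_community, \
    simulate_bisse

STAGES = ("synth", "preprocess", "niche", "beta", "assembly", "network",
          "stability", "evo")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (see data/demo.yaml for a sample)."""

    seed: int = 0
    outdir: str = "nichevol_out"
    stages: tuple = STAGES
    synth: dict = field(default_factory=dict)
    synth_euk: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {"min_reads": 10})
    niche: dict = field(default_factory=lambda: {"n_perm": 1000,
                                                 "scheme": "swap"})
    assembly: dict = field(default_factory=lambda: {"n_null": 199,
                                                    "max_pairs": 150})
    network: dict = field(default_factory=lambda: {
        "r_min": 0.6, "alpha": 0.05, "n_bootstrap": 50, "min_reads": 50})
    stability: dict = field(default_factory=lambda: {"fraction": 0.5,
                                                     "reps": 100})
    evo: dict = field(default_factory=lambda: {
        "n_tips": 100, "lambda_g": 1.0, "lambda_s": 2.0,
        "mu_g": 0.2, "mu_s": 0.2, "t_gs": 0.2, "t_sg": 0.1})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                merged = dict(getattr(cfg, key))
                merged.update(val)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, val)
        cfg.stages = tuple(cfg.stages)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = asdict(config)
    resolved.pop("outdir", None)  # analysis identity is location-independent
    manifest: dict = {"config_hash": hashlib.sha256(
        json.dumps(resolved, sort_keys=True, default=str).encode()
    ).hexdigest(), "seed": config.seed, "outputs": {}}
    files: dict[str, Path] = {}
    ctx: dict = {}

    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    files["config"] = out / "config.resolved.yaml"

    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, out, ctx, files)
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    for name, path in sorted(files.items()):
        manifest["outputs"][name] = {"path": str(path.relative_to(out)),
                                     "sha256": _sha256(path)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth(cfg, out, ctx, files):
    design = SyntheticDesign(seed=child_seed(cfg.seed, "synth-prok"),
                             **cfg.synth)
    table, truth = generate_community(design)
    ctx["prok_raw"], ctx["truth"] = table, truth
    io_mod.write_table(table, out / "prok_counts.tsv", out / "metadata.tsv")
    io_mod.write_ground_truth(truth, out / "prok_truth.tsv")
    files["prok_counts"] = out / "prok_counts.tsv"
    files["metadata"] = out / "metadata.tsv"
    files["prok_truth"] = out / "prok_truth.tsv"
    if cfg.synth_euk:
        design_e = SyntheticDesign(seed=child_seed(cfg.seed, "synth-euk"),
                                   **cfg.synth_euk)
        table_e, truth_e = generate_community(design_e)
        table_e.counts.index = ["euk_" + t for t in table_e.counts.index]
        truth_e.labels.index = table_e.counts.index
        ctx["euk_raw"], ctx["euk_truth"] = table_e, truth_e
        io_mod.write_table(table_e, out / "euk_counts.tsv",
                           out / "euk_metadata.tsv")
        files["euk_counts"] = out / "euk_counts.tsv"
        files["euk_metadata"] = out / "euk_metadata.tsv"
    # phylogeny over the prokaryote taxa for the assembly stage
    tree = generate_bd_tree(design.n_taxa, birth=1.0, death=0.0,
                            seed=child_seed(cfg.seed, "taxon-tree"))
    _relabel_tips(tree, list(table.counts.index))
    ctx["taxon_tree"] = tree
    io_mod.write_tree(tree, out / "taxon_tree.nwk")
    files["taxon_tree"] = out / "taxon_tree.nwk"


def _relabel_tips(tree, labels):
    tips = list(tree.taxon_namespace)
    if len(tips) != len(labels):
        raise ValueError("tip/label count mismatch")
    for taxon, lab in zip(tips, labels):
        taxon.label = lab


def _stage_preprocess(cfg, out, ctx, files):
    table = ctx["prok_raw"]
    table = prep_mod.filter_min_reads(table, cfg.preprocess.get("min_reads", 10))
    depth = cfg.preprocess.get("depth") or int(table.sample_totals().min())
    table = prep_mod.rarefy(table, depth,
                            seed=child_seed(cfg.seed, "rarefy-prok"))
    ctx["prok"] = table
    cov = prep_mod.goods_coverage(table)
    io_mod.write_tsv(cov.reset_index().rename(columns={"index": "sample"}),
                     out / "goods_coverage.tsv")
    files["goods_coverage"] = out / "goods_coverage.tsv"
    if "euk_raw" in ctx:
        te = prep_mod.filter_min_reads(ctx["euk_raw"],
                                       cfg.preprocess.get("min_reads", 10))
        de = cfg.preprocess.get("depth") or int(te.sample_totals().min())
        ctx["euk"] = prep_mod.rarefy(te, de,
                                     seed=child_seed(cfg.seed, "rarefy-euk"))


def _classify(cfg, table, stream):
    profs = niche_mod.null_classify(
        table, n_perm=cfg.niche.get("n_perm", 1000),
        envelope=cfg.niche.get("envelope", 0.95),
        seed=child_seed(cfg.seed, stream),
        scheme=cfg.niche.get("scheme", "swap"))
    niche_mod.strict_filter(profs)
    return profs


def _stage_niche(cfg, out, ctx, files):
    profs = _classify(cfg, ctx["prok"], "niche-prok")
    ctx["prok_profiles"] = profs
    io_mod.write_tsv(niche_mod.profiles_frame(profs),
                     out / "prok_niche_profiles.tsv")
    files["prok_niche_profiles"] = out / "prok_niche_profiles.tsv"
    if "euk" in ctx:
        profs_e = _classify(cfg, ctx["euk"], "niche-euk")
        ctx["euk_profiles"] = profs_e
        io_mod.write_tsv(niche_mod.profiles_frame(profs_e),
                         out / "euk_niche_profiles.tsv")
        files["euk_niche_profiles"] = out / "euk_niche_profiles.tsv"


def _class_subtables(table, profiles):
    by_class: dict[str, list[str]] = {}
    for p in profiles:
        by_class.setdefault(p.niche_class, []).append(p.taxon)
    out = {}
    for cls in ("generalist", "specialist"):
        taxa = by_class.get(cls, [])
        if len(taxa) >= 2:
            out[cls] = table.subset_taxa(taxa)
    return out


def _stage_beta(cfg, out, ctx, files):
    rows = []
    for cls, sub in _class_subtables(ctx["prok"], ctx["prok_profiles"]).items():
        fit = beta_mod.decay_fit_from_table(sub, group=cls)
        rows.append((fit.group, fit.beta_slope, fit.intercept_c,
                     fit.r_squared, fit.n_pairs, fit.n_dropped_zero))
        bc = beta_mod.bray_curtis_matrix(sub)
        io_mod.write_tsv(bc, out / f"bray_curtis_{cls}.tsv", index=True)
        files[f"bray_curtis_{cls}"] = out / f"bray_curtis_{cls}.tsv"
    df = pd.DataFrame(rows, columns=["group", "beta_slope", "intercept",
                                     "r_squared", "n_pairs", "n_dropped"])
    io_mod.write_tsv(df, out / "distance_decay.tsv")
    files["distance_decay"] = out / "distance_decay.tsv"


def _stage_assembly(cfg, out, ctx, files):
    rng = np.random.default_rng(child_seed(cfg.seed, "assembly-pairs"))
    n_null = cfg.assembly.get("n_null", 199)
    max_pairs = cfg.assembly.get("max_pairs", 150)
    all_pairs = []
    summaries = []
    for cls, sub in _class_subtables(ctx["prok"], ctx["prok_profiles"]).items():
        taxa = sub.taxa
        dist = assembly_mod.patristic_matrix(ctx["taxon_tree"], taxa)
        counts = sub.counts.to_numpy(float)
        keep = counts.sum(axis=0) > 0
        counts = counts[:, keep]
        samples = [s for s, k in zip(sub.samples, keep) if k]
        occ = (counts > 0).sum(axis=1).astype(float)
        mean_ab = (counts / counts.sum(axis=0, keepdims=True)).mean(axis=1)
        idx_pairs = [(i, j) for i in range(len(samples))
                     for j in range(i + 1, len(samples))]
        if len(idx_pairs) > max_pairs:
            sel = rng.choice(len(idx_pairs), size=max_pairs, replace=False)
            idx_pairs = [idx_pairs[int(k)] for k in sorted(sel)]
        pairs = []
        for i, j in idx_pairs:
            s = child_seed(cfg.seed, f"assembly-{cls}-{i}-{j}")
            b = assembly_mod.bnti(counts[:, i], counts[:, j], dist,
                                  n_null=n_null, seed=s,
                                  degenerate="zero")
            r = assembly_mod.rc_bray(counts[:, i], counts[:, j],
                                     n_null=n_null, seed=s + 1,
                                     occupancy=occ, mean_abundance=mean_ab)
            pairs.append(assembly_mod.AssemblyPair(
                samples[i], samples[j], b, r,
                assembly_mod.classify_process(b, r)))
        all_pairs.extend(pairs)
        summaries.extend(assembly_mod.summarize_assembly(
            pairs, grouping=lambda _: cls))
    io_mod.write_tsv(assembly_mod.pairs_frame(all_pairs),
                     out / "assembly_pairs.tsv")
    rows = [(s.group,
             *[float(s.fractions[p]) for p in assembly_mod.PROCESSES],
             float(s.deterministic), float(s.stochastic), s.n_pairs)
            for s in summaries]
    df = pd.DataFrame(rows, columns=["group", *assembly_mod.PROCESSES,
                                     "deterministic", "stochastic", "n_pairs"])
    io_mod.write_tsv(df, out / "assembly_summary.tsv")
    files["assembly_pairs"] = out / "assembly_pairs.tsv"
    files["assembly_summary"] = out / "assembly_summary.tsv"
    ctx["assembly_summaries"] = summaries


def _stage_network(cfg, out, ctx, files):
    table = ctx["prok"]
    min_reads = cfg.network.get("min_reads", 50)
    keep = table.taxon_totals() > min_reads
    sub = table.subset_taxa(table.counts.index[keep])
    seed = child_seed(cfg.seed, "network-prok")
    corr = netinfer.sparcc(sub.counts.to_numpy(), seed=seed)
    pvals = netinfer.edge_pvalues(sub.counts.to_numpy(), corr,
                                  n_bootstrap=cfg.network.get("n_bootstrap", 50),
                                  seed=seed + 1)
    classes = {p.taxon: p.niche_class for p in ctx["prok_profiles"]}
    ann = pd.DataFrame(index=sub.counts.index)
    ann["domain"] = "prokaryote"
    ann["niche_class"] = [classes.get(t, "unknown") for t in sub.counts.index]
    g = netinfer.threshold_network(corr, pvals, list(sub.counts.index), ann,
                                   r_min=cfg.network.get("r_min", 0.6),
                                   alpha=cfg.network.get("alpha", 0.05))
    ctx["network"] = g
    ctx["classes"] = classes
    io_mod.write_tsv(netinfer.edge_list(g), out / "network_edges.tsv")
    io_mod.write_graphml(g, out / "network.graphml")
    files["network_edges"] = out / "network_edges.tsv"
    files["network_graphml"] = out / "network.graphml"
    if g.number_of_nodes() >= 3:
        stats = netinfer.stats_with_null(
            g, n_random=cfg.network.get("n_random", 100),
            seed=child_seed(cfg.seed, "rewire"))
        io_mod.write_tsv(pd.DataFrame([asdict(stats)]),
                         out / "network_stats.tsv")
        files["network_stats"] = out / "network_stats.tsv"


def _stage_stability(cfg, out, ctx, files):
    g = ctx.get("network")
    if g is None or g.number_of_edges() == 0:
        return
    modules, _ = netinfer.greedy_modules(g)
    roles = nettopo.zi_pi(g, modules)
    io_mod.write_tsv(nettopo.roles_frame(roles), out / "node_roles.tsv")
    files["node_roles"] = out / "node_roles.tsv"
    classes = ctx["classes"]
    totals: dict[str, int] = {}
    for p in ctx["prok_profiles"]:
        totals[p.niche_class] = totals.get(p.niche_class, 0) + 1
    tally = nettopo.keystone_tally(roles, classes, totals)
    io_mod.write_tsv(tally, out / "keystone_tally.tsv")
    files["keystone_tally"] = out / "keystone_tally.tsv"
    reports = []
    for cls in ("generalist", "specialist"):
        targets = [n for n in g.nodes if classes.get(n) == cls]
        if len(targets) < 2:
            continue
        rep = nettopo.removal_experiment(
            g, targets, fraction=cfg.stability.get("fraction", 0.5),
            reps=cfg.stability.get("reps", 100),
            seed=child_seed(cfg.seed, f"removal-{cls}"), target=cls)
        if g.number_of_nodes() >= 3:
            rep.vulnerability = nettopo.vulnerability(g)
            rep.robustness = nettopo.robustness(
                g, reps=cfg.stability.get("reps", 100),
                seed=child_seed(cfg.seed, f"robustness-{cls}"))
        reports.append(rep)
    if reports:
        io_mod.write_tsv(pd.DataFrame([asdict(r) for r in reports]),
                         out / "stability.tsv")
        files["stability"] = out / "stability.tsv"


def _stage_evo(cfg, out, ctx, files):
    e = cfg.evo
    tree, states = simulate_bisse(
        e.get("lambda_g", 1.0), e.get("lambda_s", 2.0),
        e.get("mu_g", 0.2), e.get("mu_s", 0.2),
        e.get("t_gs", 0.2), e.get("t_sg", 0.1),
        n_tips=e.get("n_tips", 100),
        seed=child_seed(cfg.seed, "evo-tree"))
    io_mod.write_tree(tree, out / "state_tree.nwk")
    io_mod.write_tsv(pd.DataFrame(sorted(states.items()),
                                  columns=["tip", "state"]),
                     out / "tip_states.tsv")
    fit = bisse_fit(tree, states, seed=child_seed(cfg.seed, "evo-fit"))
    io_mod.write_tsv(pd.DataFrame([asdict(fit)]), out / "bisse_fit.tsv")
    branch = compare_branch_lengths(tree, states)
    io_mod.write_tsv(pd.DataFrame([branch]), out / "branch_lengths.tsv")
    for name in ("state_tree.nwk", "tip_states.tsv", "bisse_fit.tsv",
                 "branch_lengths.tsv"):
        files[name.split(".")[0]] = out / name
    ctx["bisse_fit"] = fit


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "niche": _stage_niche,
    "beta": _stage_beta,
    "assembly": _stage_assembly,
    "network": _stage_network,
    "stability": _stage_stability,
    "evo": _stage_evo,
}
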