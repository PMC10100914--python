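"""Configuration and end-to-end pipeline driver.

``run_pipeline`` chains the stages: obtain a bundle (load from disk or
simulate), filter rare taxa per marker, CLR-transform, infer one network per
domain variant (BAF, BA, BF, B, F), characterize topology (centralities,
keystones, core), run the random-attack and efficiency comparisons between
variants, and screen fungal taxa against the discretized methane response
with balance selection.  Every output directory carries the master seed and
a config hash so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import balances as bal
from . import netinfer, perturbation, preprocess, synthetic, topology
from .containers import CountTable, EmptyResultError, SampleMetadata
from .io import read_bundle, write_bundle, write_network
from .netinfer import NetInferParams
from .preprocess import DOMAIN_VARIANTS

log = logging.getLogger(__name__)


@dataclass
class Config:
    """All stage parameters with their study defaults."""

    # input: directory with counts/taxonomy/metadata TSVs, or None to simulate
    input_dir: str | None = None
    # synthetic bundle (used when input_dir is None)
    n_taxa: int = 60
    n_samples: int = 130
    edge_density: float = 0.05
    depth_mean: int = 20_000
    zero_inflation: float = 0.05
    # filtering
    min_prevalence: float = 0.30
    min_mean_relabund: float = 1e-4
    # CLR
    pseudocount: float = 1.0
    # inference
    nlambda: int = 20
    lambda_min_ratio: float = 0.005
    stars_threshold: float = 0.05
    n_reps: int = 20
    latent_rank_max: int = 0
    variants: tuple[str, ...] = ("BAF", "BA", "BF", "B", "F")
    # topology
    keystone_percentile: float = 0.80
    core_percentile: float = 0.50
    core_min_edges: int = 3
    # perturbation
    attack_iterations: int = 10_000
    # balances
    smtz_interval_cm: tuple[float, float] = (10.0, 13.0)
    balance_folds: int = 5
    balance_repeats: int = 100
    balance_max_size: int = 8
    signature_threshold: float = 0.30
    # global
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "smtz_interval_cm" in raw:
            raw["smtz_interval_cm"] = tuple(raw["smtz_interval_cm"])
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smtz_interval_cm"] = list(self.smtz_interval_cm)
        d["variants"] = list(self.variants)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def netinfer_params(self, seed_offset: int = 0) -> NetInferParams:
        return NetInferParams(
            nlambda=self.nlambda,
            lambda_min_ratio=self.lambda_min_ratio,
            stars_threshold=self.stars_threshold,
            n_reps=self.n_reps,
            latent_rank_max=self.latent_rank_max,
            seed=self.seed + seed_offset,
        )


def simulate_bundle(config: Config) -> tuple[CountTable, SampleMetadata, synthetic.TrueModel]:
    """Generate a synthetic bundle matching the configured study size."""
    truth = synthetic.make_true_model(
        config.n_taxa, config.edge_density, seed=config.seed
    )
    counts = synthetic.simulate_counts(
        truth, config.n_samples,
        depth_mean=config.depth_mean,
        zero_inflation=config.zero_inflation,
        seed=config.seed + 1,
    )
    # depth-profile metadata: one core of six 5-cm slices per pseudo-site,
    # samples assigned to (site, slice) cells round-robin
    slices = [(5.0 * i, 5.0 * (i + 1)) for i in range(6)]
    n_sites = max(1, int(np.ceil(config.n_samples / len(slices))))
    sites = [f"ROV{i + 1}" for i in range(n_sites)]
    meta = synthetic.simulate_metadata(
        sites, slices, smtz_interval_cm=config.smtz_interval_cm,
        seed=config.seed + 2,
    )
    cells = meta.table.index.to_list()
    assigned = [cells[i % len(cells)] for i in range(config.n_samples)]
    table = meta.table.loc[assigned].copy()
    table.index = counts.sample_ids
    return counts, SampleMetadata(table), truth


def _filter_per_marker(counts: CountTable, config: Config) -> CountTable:
    """Apply the prevalence/abundance filter within each marker block."""
    markers = sorted({counts.marker_of[t] for t in counts.taxon_ids})
    kept: list[str] = []
    for marker in markers:
        block = counts.subset_taxa(
            [t for t in counts.taxon_ids if counts.marker_of[t] == marker]
        )
        filtered = preprocess.filter_taxa(
            block, config.min_prevalence, config.min_mean_relabund
        )
        kept.extend(filtered.taxon_ids)
    return counts.subset_taxa(kept)


def run_pipeline(config: Config, out_dir: str | Path) -> Path:
    """Execute the full workflow; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
        "notices": [],
    }
    stage = "input"
    try:
        if config.input_dir:
            counts, meta = read_bundle(config.input_dir)
            truth = None
        else:
            counts, meta, truth = simulate_bundle(config)
            write_bundle(counts, meta, out / "bundle")
            (out / "bundle" / "true_model.json").write_text(
                json.dumps(truth.to_dict(), indent=1)
            )
        summary["stages"]["input"] = {
            "n_samples": counts.n_samples, "n_taxa": counts.n_taxa,
            "synthetic": truth is not None,
        }

        stage = "filter"
        filtered = _filter_per_marker(counts, config)
        summary["stages"]["filter"] = {
            "n_taxa_before": counts.n_taxa, "n_taxa_after": filtered.n_taxa,
        }

        stage = "networks"
        networks = {}
        for i, name in enumerate(config.variants):
            domains = DOMAIN_VARIANTS[name]
            try:
                sub = preprocess.subset_domains(filtered, domains)
            except EmptyResultError:
                summary["notices"].append(f"variant {name}: no taxa, skipped")
                continue
            if sub.n_taxa < 3:
                summary["notices"].append(f"variant {name}: <3 taxa, skipped")
                continue
            clr = preprocess.clr_transform(sub, config.pseudocount)
            net = netinfer.infer_network(clr, config.netinfer_params(seed_offset=i))
            networks[name] = net
            write_network(net, out / f"network_{name}.graphml", "graphml")
            write_network(net, out / f"network_{name}.edges.tsv", "edgelist",
                          sidecar=False)
        summary["stages"]["networks"] = {
            name: {"n_input_taxa": net.provenance["n_input_taxa"],
                   "n_connected": net.provenance["n_connected"],
                   "n_edges": net.n_edges,
                   "selected_lambda": net.provenance["selected_lambda"]}
            for name, net in networks.items()
        }

        stage = "topology"
        main = next((networks[v] for v in ("BAF", "BA", "BF", "B", "F")
                     if v in networks and networks[v].n_edges > 0), None)
        if main is not None:
            cent = topology.compute_centralities(main)
            cent.to_csv(out / "centralities.tsv", sep="\t")
            keystones = topology.keystone_nodes(cent, config.keystone_percentile)
            keystones.flags.to_csv(out / "keystones.tsv", sep="\t")
            core = topology.core_network(main, config.core_percentile,
                                         config.core_min_edges)
            write_network(core, out / "core_network.graphml", "graphml")
            domains_present = [d for d in ("bacteria", "archaea", "fungus")
                               if (cent["domain"] == d).sum() >= 2]
            comparisons = {}
            for metric in topology.METRICS:
                for a, b in [(x, y) for x in domains_present for y in domains_present
                             if x < y]:
                    cmp_res = topology.compare_domain_metric(cent, metric, a, b)
                    comparisons[f"{metric}:{a}-vs-{b}"] = dataclasses.asdict(cmp_res)
            keystone_domains = {
                d: sum(main.domain_of(k) == d for k in keystones.keystone_ids)
                for d in ("bacteria", "archaea", "fungus")
            }
            summary["stages"]["topology"] = {
                "n_keystones": len(keystones.keystone_ids),
                "keystone_domains": keystone_domains,
                "core_nodes": core.n_nodes,
                "core_edges": core.n_edges,
                "domain_comparisons": comparisons,
            }
        else:
            summary["notices"].append("topology: no non-empty network, skipped")

        stage = "perturbation"
        attack_results = {}
        for i, (name, net) in enumerate(sorted(networks.items())):
            if net.n_nodes < 3 or net.n_edges == 0:
                summary["notices"].append(f"attack {name}: degenerate network, skipped")
                continue
            res = perturbation.attack_robustness(
                net, config.attack_iterations, seed=config.seed + 100 + i
            )
            eff = perturbation.nodal_efficiency(net)
            attack_results[name] = (res, eff)
        perturb_summary: dict = {
            name: {"V_mean": res.V_mean, "V_sd": res.V_sd,
                   "efficiency_mean": eff.mean, "n_nodes": res.n_nodes}
            for name, (res, eff) in attack_results.items()
        }
        if len(attack_results) >= 2:
            pairs = sorted(attack_results)
            contrasts = {}
            for a in pairs:
                for b in pairs:
                    if a < b:
                        vcmp = perturbation.compare_vulnerability(
                            attack_results[a][0], attack_results[b][0]
                        )
                        ecmp = perturbation.compare_efficiency(
                            attack_results[a][1], attack_results[b][1]
                        )
                        contrasts[f"{a}-vs-{b}"] = {
                            "vulnerability": dataclasses.asdict(vcmp),
                            "efficiency": dataclasses.asdict(ecmp),
                        }
            perturb_summary["contrasts"] = contrasts
        elif attack_results:
            summary["notices"].append("perturbation: single network, comparisons skipped")
        summary["stages"]["perturbation"] = perturb_summary

        stage = "balances"
        try:
            fungal = preprocess.subset_domains(filtered, {"fungus"})
        except EmptyResultError:
            fungal = None
        if fungal is not None and fungal.n_taxa >= 2:
            labels = preprocess.discretize_methane(meta, config.smtz_interval_cm)
            if labels.nunique() == 2 and labels.value_counts().min() >= config.balance_folds:
                report = bal.greedy_balance_cv(
                    fungal, labels,
                    n_folds=config.balance_folds,
                    n_repeats=config.balance_repeats,
                    max_size=config.balance_max_size,
                    seed=config.seed + 200,
                )
                report.frequencies.rename_axis("taxon_id").to_csv(
                    out / "balance_frequencies.tsv", sep="\t"
                )
                sig = bal.signature_taxa(report, config.signature_threshold)
                summary["stages"]["balances"] = {
                    "n_fungal_taxa": fungal.n_taxa,
                    "mean_cv_auc": report.mean_cv_auc,
                    "n_signature_taxa": len(sig),
                    "signature_taxa": sorted(sig),
                }
            else:
                summary["notices"].append("balances: response classes too small, skipped")
        else:
            summary["notices"].append("balances: <2 fungal taxa, skipped")
    except Exception:
        (out / "summary.json").write_text(
            json.dumps({**summary, "failed_stage": stage}, indent=1, default=float)
        )
        log.exception("pipeline failed at stage %s", stage)
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    from . import __version__

    (out / "run.log").write_text(
        f"seepnet {__version__}\nseed {config.seed}\n"
        f"config_hash {config.config_hash()}\n"
        f"stages {' '.join(summary['stages'])}\n"
        + "".join(f"notice: {n}\n" for n in summary["notices"])
    )
    return out
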