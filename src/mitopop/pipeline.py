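"""Pipeline orchestration: filter -> diversity -> mismatch -> network ->
structure -> ABC, from one YAML config, with a JSON+TSV report bundle."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import abc_inference as abc
from . import diversity_stats as dv
from . import sequence_core as sc
from . import spatial_structure as ss
from .haplotype_network import build_mj_network
from .scenario_simulator import POPULATIONS, MutationModel


@dataclass
class RunConfig:
    fasta: str
    meta: str
    outdir: str
    group_column: str = "locality"
    exclude_haplogroups: list[str] = field(default_factory=list)
    exclude_sample_ids: list[str] = field(default_factory=list)
    exclude_localities: list[str] = field(default_factory=list)
    max_missing_frac: float = 0.70
    mu_site: float = dv.DEFAULT_MU_SITE
    samova_k: int = 2
    samova_restarts: int = 20
    abc_enabled: bool = True
    abc_n_per_scenario: int = 1000
    abc_tolerance: float = 0.01
    abc_L: int = 1230
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_all(cfg: RunConfig) -> dict[str, str]:
    """Run every stage in dependency order; returns the output manifest.

    Stage outputs are written as they complete, so a late failure leaves
    earlier results intact.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    log = {
        "tool": "mitopop",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "config": cfg.to_dict(),
    }
    _write_json(outdir / "run_log.json", log)
    manifest["run_log"] = str(outdir / "run_log.json")

    aln = sc.read_alignment(cfg.fasta)
    meta = sc.read_sample_table(cfg.meta, validate=False)
    sc.check_metadata_covers(aln, meta)

    excluded = set(cfg.exclude_sample_ids)
    if cfg.exclude_haplogroups and "haplogroup" in meta.columns:
        excluded |= set(
            meta.loc[meta["haplogroup"].isin(cfg.exclude_haplogroups), "sample_id"]
        )
    if cfg.exclude_localities:
        excluded |= set(
            meta.loc[meta["locality"].isin(cfg.exclude_localities), "sample_id"]
        )

    # -- filter stage (whole alignment)
    aln_f, report = sc.filter_sites(aln, cfg.max_missing_frac)
    _write_json(
        outdir / "filter_report.json",
        {
            "n_sites_before": report.n_sites_before,
            "n_sites_after": report.n_sites_after,
            "removed_positions_1based": report.removed_positions_1based(),
            "n_excluded_samples": len(excluded),
            "excluded_samples": sorted(excluded),
        },
    )
    manifest["filter_report"] = str(outdir / "filter_report.json")

    kept_ids = [s for s in aln_f.sample_ids if s not in excluded]
    aln_kept = aln_f.subset(kept_ids)
    meta_kept = meta[meta["sample_id"].isin(kept_ids)]

    rates = dv.RateConstants(mu_site=cfg.mu_site, seq_length=aln_kept.L)

    # -- diversity stage, per group and overall
    diversity: dict = {"seed": cfg.seed, "groups": {}}
    stats_all = dv.tajimas_d(aln_kept)
    diversity["overall"] = {
        "n": stats_all.n,
        "S": stats_all.S,
        "pi": stats_all.pi_site,
        "k_hat": stats_all.k_hat,
        "H": stats_all.H,
        "tajima_D": stats_all.tajima_D,
        "tajima_p_flag": stats_all.tajima_p_flag,
    }
    for g, sub in meta_kept.groupby(cfg.group_column):
        ids = [s for s in aln_kept.sample_ids if s in set(sub["sample_id"])]
        if len(ids) < 4:
            diversity["groups"][str(g)] = {"n": len(ids), "skipped": "n < 4"}
            continue
        st = dv.tajimas_d(aln_kept.subset(ids))
        diversity["groups"][str(g)] = {
            "n": st.n, "S": st.S, "pi": st.pi_site, "k_hat": st.k_hat,
            "H": st.H, "tajima_D": st.tajima_D, "tajima_p_flag": st.tajima_p_flag,
        }
    _write_json(outdir / "diversity.json", diversity)
    manifest["diversity"] = str(outdir / "diversity.json")

    # -- mismatch stage
    diffs = sc.pairwise_differences(aln_kept)
    obs = dv.mismatch_observed(diffs)
    fit = dv.fit_sudden_expansion(obs)
    mm = pd.DataFrame(
        {
            "differences": np.arange(len(obs)),
            "observed": obs,
            "expected": fit.expected_freqs,
        }
    )
    mm.to_csv(outdir / "mismatch.tsv", sep="\t", index=False)
    _write_json(
        outdir / "mismatch_fit.json",
        {
            "tau": fit.tau,
            "theta0": fit.theta0,
            "theta1": fit.theta1,
            "ssd": fit.ssd,
            "expansion_time_years": dv.expansion_time(fit.tau, rates),
            "seed": cfg.seed,
        },
    )
    manifest["mismatch"] = str(outdir / "mismatch.tsv")
    manifest["mismatch_fit"] = str(outdir / "mismatch_fit.json")

    # -- network stage
    ht = sc.collapse_haplotypes(aln_kept)
    locality_of = dict(zip(meta_kept["sample_id"], meta_kept["locality"]))
    if ht.k >= 2:
        net = build_mj_network(ht)
        net.edge_table().to_csv(outdir / "network.tsv", sep="\t", index=False)
        net.node_table(locality_of).to_csv(
            outdir / "network_nodes.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=["u", "v", "steps"]).to_csv(
            outdir / "network.tsv", sep="\t", index=False
        )
    manifest["network"] = str(outdir / "network.tsv")

    # -- structure stage
    structure: dict = {"seed": cfg.seed, "n_used": aln_kept.n}
    groups = meta_kept[cfg.group_column].nunique()
    if groups >= 2:
        pdm = ss.pop_distances(aln_kept, meta_kept, cfg.group_column, diffs=diffs)
        pdm.to_frame().to_csv(outdir / "net_distances.tsv", sep="\t")
        structure["net_distances"] = "net_distances.tsv"
        if len(pdm.labels) >= 2:
            tree = ss.midpoint_root(ss.nj_tree(pdm))
            (outdir / "subpopulations.nwk").write_text(tree.newick() + "\n")
            structure["tree"] = "subpopulations.nwk"
        if 2 <= cfg.samova_k < groups:
            res = ss.samova(
                aln_kept, meta_kept, K=cfg.samova_k, group_by=cfg.group_column,
                n_restarts=cfg.samova_restarts, seed=cfg.seed, diffs=diffs,
            )
            structure["samova"] = res.to_dict()
        else:
            structure["samova"] = {"skipped": f"K={cfg.samova_k} out of range for {groups} groups"}
    else:
        structure["skipped"] = "fewer than 2 groups"
    _write_json(outdir / "structure.json", structure)
    manifest["structure"] = str(outdir / "structure.json")

    # -- ABC stage (requires the three scenario populations)
    abc_out: dict = {"seed": cfg.seed}
    pops_present = set(meta_kept["population"].unique())
    if not cfg.abc_enabled:
        abc_out["skipped"] = "disabled in config"
    elif not set(POPULATIONS) <= pops_present:
        abc_out["skipped"] = (
            f"populations {sorted(set(POPULATIONS) - pops_present)} absent; "
            "scenario comparison needs Madagascar, EastAfrica and WestAsia"
        )
    else:
        sample_sizes = {
            p: int((meta_kept["population"] == p).sum()) for p in POPULATIONS
        }
        table = abc.build_reference_table(
            n_per_scenario=cfg.abc_n_per_scenario,
            sample_sizes=sample_sizes,
            model=MutationModel(),
            L=cfg.abc_L,
            seed=cfg.seed,
        )
        table.to_csv(outdir / "abc_table.tsv", sep="\t", index=False)
        observed = abc.summarize_alignment(aln_kept, meta_kept)
        retained = abc.abc_reject(observed, table, cfg.abc_tolerance)
        result = abc.scenario_posterior(retained, table, observed)
        abc_out["scenario_posterior"] = result.to_dict()
        best = max(result.pp, key=result.pp.get)
        time_param = {1: "T1", 2: "T2", 3: "T3"}[best]
        from .scenario_simulator import scenario as _scn

        bounds = _scn(best).time_priors[time_param]
        post = abc.estimate_params(
            retained, table, observed, best, time_param, prior_bounds=bounds
        )
        abc_out["best_scenario"] = best
        abc_out["param_posterior"] = post.to_dict()
    _write_json(outdir / "abc.json", abc_out)
    manifest["abc"] = str(outdir / "abc.json")

    _write_json(outdir / "manifest.json", manifest)
    return manifest
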