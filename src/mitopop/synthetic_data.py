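"""Study-like synthetic datasets.

Generates an alignment + metadata + truth record emulating a single-island
survey: a dominant star-like haplotype cluster (recent expansion), a
highland-derived subcluster that also includes one designated lowland deme,
and two divergent outlier sequences at a port locality. Also wraps the
scenario simulator to produce pseudo-observed multi-population datasets
for ABC testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity_stats import DEFAULT_MU_SITE
from .scenario_simulator import MutationModel, SimulatedDataset, scenario, simulate_dataset
from .sequence_core import Alignment

_BASES = "ACGT"


@dataclass
class Locality:
    name: str
    region: str
    elevation: float
    n_samples: int
    highland_cluster: bool  # carries the highland-founder haplotype background


def default_localities(n_total: int = 78, n_outliers: int = 2) -> list[Locality]:
    """Eleven localities: two highland (>1000 m), one mid-elevation western
    deme grouped with the highlands, coastal lowlands, and a port locality
    holding only the outliers."""
    spec = [
        ("Ambohimanga", "Highland", 1445.0, True),
        ("Anjozorobe", "Highland", 1270.0, True),
        ("Manja", "Lowland_west", 240.0, True),
        ("Morondava", "Lowland_west", 10.0, False),
        ("Tulear", "Lowland_west", 15.0, False),
        ("Mahajanga", "Lowland_west", 12.0, False),
        ("Beloha", "Lowland_west", 25.0, False),
        ("Mahanoro", "Lowland_east", 8.0, False),
        ("Toamasina", "Lowland_east", 10.0, False),
        ("Antalaha", "Lowland_east", 20.0, False),
    ]
    port = ("Fort Dauphin", "Lowland_east", 11.0, False)
    n_regular = n_total - n_outliers
    base, extra = divmod(n_regular, len(spec))
    locs = [
        Locality(name, region, elev, base + (1 if i < extra else 0), hc)
        for i, (name, region, elev, hc) in enumerate(spec)
    ]
    locs.append(Locality(port[0], port[1], port[2], n_outliers, False))
    return locs


@dataclass
class StudyConfig:
    n_total: int = 78
    localities: list[Locality] | None = None
    star_tau: float = 1.0  # expected pairwise differences within the cluster
    theta0: float = 0.1  # pre-expansion standing variation (expected pairwise)
    highland_divergence: float = 2.85e-4  # per-site net distance of the split
    highland_steps: int | None = None  # override: fixed mutation count of the split
    n_outliers: int = 2
    outlier_steps: int = 20
    L: int = 1230
    seed: int = 0

    def resolved_localities(self) -> list[Locality]:
        locs = self.localities or default_localities(self.n_total, self.n_outliers)
        if sum(l.n_samples for l in locs) != self.n_total:
            raise ValueError("locality sample sizes must sum to n_total")
        return locs

    def resolved_highland_steps(self) -> int:
        if self.highland_steps is not None:
            return self.highland_steps
        return max(1, round(self.highland_divergence * self.L))


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        out[s] = (out[s] + rng.integers(1, 4)) % 4
    return out


def generate_study_like(cfg: StudyConfig) -> tuple[Alignment, pd.DataFrame, dict]:
    """Generate the study-like alignment, metadata table and truth record.

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    FASTA/TSV/JSON output.
    """
    rng = np.random.default_rng(cfg.seed)
    locs = cfg.resolved_localities()
    L = cfg.L
    founder = rng.integers(0, 4, size=L).astype(np.uint8)
    m_split = cfg.resolved_highland_steps()
    highland_founder = _mutate(
        founder, rng.choice(L, size=m_split, replace=False), rng
    )
    outlier_sites = rng.choice(L, size=cfg.outlier_steps, replace=False)
    outlier_founder = _mutate(founder, outlier_sites, rng)

    # standing variation: a few ancestral polymorphic sites shared by random
    # subsets of the pre-expansion cluster (expected pairwise contribution
    # ~ theta0)
    n_anc = rng.poisson(cfg.theta0 * 2)
    anc_sites = rng.choice(L, size=n_anc, replace=False) if n_anc else np.array([], dtype=int)

    ids: list[str] = []
    seqs: list[np.ndarray] = []
    meta_rows = []
    outlier_ids: list[str] = []
    k = 0
    for loc in locs:
        is_port = loc.n_samples == cfg.n_outliers and loc.name == locs[-1].name
        for _ in range(loc.n_samples):
            k += 1
            sid = f"MAD{k:03d}"
            ids.append(sid)
            if is_port:
                seq = outlier_founder.copy()
                outlier_ids.append(sid)
                hap_group = "E"
            else:
                base = highland_founder if loc.highland_cluster else founder
                n_private = rng.poisson(cfg.star_tau / 2.0)
                seq = _mutate(
                    base,
                    rng.choice(L, size=min(n_private, L), replace=False),
                    rng,
                ) if n_private else base.copy()
                for site in anc_sites:
                    if rng.random() < 0.2:
                        seq = _mutate(seq, np.array([site]), rng)
                hap_group = "C2"
            seqs.append(seq)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "locality": loc.name,
                    "region": loc.region,
                    "elevation": loc.elevation,
                    "population": "Madagascar",
                    "haplogroup": hap_group,
                }
            )
    decode = np.array(list(_BASES))
    aln = Alignment(
        sample_ids=ids, seqs=["".join(decode[s]) for s in seqs]
    )
    meta = pd.DataFrame(meta_rows)
    truth = {
        "seed": cfg.seed,
        "n_total": cfg.n_total,
        "L": L,
        "star_tau": cfg.star_tau,
        "theta0": cfg.theta0,
        "highland_steps": m_split,
        "highland_divergence": cfg.highland_divergence,
        "expansion_time_years": cfg.star_tau / (2.0 * DEFAULT_MU_SITE * L),
        "outlier_ids": outlier_ids,
        "outlier_steps": cfg.outlier_steps,
        "highland_cluster_localities": sorted(
            l.name for l in locs if l.highland_cluster
        ),
        "locality_sizes": {l.name: l.n_samples for l in locs},
    }
    return aln, meta, truth


def write_study_dataset(cfg: StudyConfig, outdir: str | Path) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, meta, truth = generate_study_like(cfg)
    fasta = outdir / "study.fasta"
    meta_path = outdir / "study_meta.tsv"
    truth_path = outdir / "study_truth.json"
    aln.write_fasta(fasta)
    meta.to_csv(meta_path, sep="\t", index=False)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"fasta": str(fasta), "meta": str(meta_path), "truth": str(truth_path)}


def generate_scenario_pseudoobs(
    scenario_id: int,
    params: dict[str, float] | None,
    sample_config: dict[str, int],
    seed: int,
    model: MutationModel | None = None,
    L: int = 1230,
) -> SimulatedDataset:
    """One pseudo-observed multi-population dataset with recorded truth."""
    scn = scenario(scenario_id)
    if params is not None:
        full = dict(params)
        rng = np.random.default_rng(seed)
        for pop, (lo, hi) in scn.size_priors.items():
            full.setdefault(f"N_{pop}", rng.uniform(lo, hi))
        for name in scn.time_priors:
            if name not in full:
                raise ValueError(f"missing time parameter {name}")
        params = full
    return simulate_dataset(
        scn, sample_sizes=sample_config, model=model, L=L, seed=seed, params=params
    )


def write_scenario_dataset(
    scenario_id: int,
    sample_config: dict[str, int],
    seed: int,
    outdir: str | Path,
    params: dict[str, float] | None = None,
    L: int = 1230,
) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_scenario_pseudoobs(scenario_id, params, sample_config, seed, L=L)
    fasta = outdir / f"scenario{scenario_id}.fasta"
    meta_path = outdir / f"scenario{scenario_id}_meta.tsv"
    truth_path = outdir / f"scenario{scenario_id}_truth.json"
    ds.alignment.write_fasta(fasta)
    ds.meta.to_csv(meta_path, sep="\t", index=False)
    truth_path.write_text(json.dumps(ds.truth, indent=2, sort_keys=True) + "\n")
    return {"fasta": str(fasta), "meta": str(meta_path), "truth": str(truth_path)}
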