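"""End-to-end orchestration: filter -> stats -> ancestry -> assignment -> Ne
-> genome scan, plus the two named simulation study designs.

All thresholds default to the study's settings, so a bare run reproduces the
analysis conditions. Every stochastic stage takes an explicit seed. Outputs
are plain TSV files plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import assignment as assignmod
from . import filtering, io, ne, scan, stats
from . import sim as simmod
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_study_scenarios",
           "run_stepping_stone_scenario"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for a full pipeline run."""

    vcf: str | None = None
    genepop: str | None = None
    map_table: str | None = None
    metadata: str | None = None
    out_dir: str = "ciscopop_out"
    stages: list = field(default_factory=lambda: [
        "filter", "stats", "ancestry", "assign", "ne", "scan",
    ])
    # filtering
    min_call_rate: float = 0.70
    max_ind_missing: float = 0.50
    min_mac: int = 3
    hdplot_h_max: float = 0.55
    hdplot_d_max: float = 5.0
    # stats / tests
    n_perm: int = 0
    # ancestry
    k_range: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    cv_folds: int = 10
    q_threshold: float = 0.70
    misid_threshold: float = 0.99
    # Ne
    p_crit: float = 0.05
    # scan
    window_width: float = 5.0
    window_step: float = 1.0
    # seeds
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, gm: GenotypeMatrix | None = None,
                 depths=None) -> dict:
    """Run the enabled stages and write their TSV artifacts plus a manifest.

    ``gm`` may be passed directly (e.g. a simulated matrix); otherwise the
    configured VCF or genepop file is read. Returns a dict of in-memory
    results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": asdict(config)}
    results: dict = {}

    if gm is None:
        if config.vcf:
            gm, depths, _ = io.read_vcf(config.vcf)
        elif config.genepop:
            gm, _ = io.read_genepop(config.genepop)
        else:
            raise ValueError("no input: provide gm, vcf or genepop")
    if config.map_table:
        gm = io.attach_map(gm, io.read_map(config.map_table))
    if config.metadata:
        gm = io.attach_metadata(gm, io.read_metadata(config.metadata))

    rng = np.random.default_rng(config.seed)

    if "filter" in config.stages:
        gm, depths, report = filtering.run_filter_cascade(
            gm, depths, config.min_call_rate, config.max_ind_missing,
            config.min_mac, config.hdplot_h_max, config.hdplot_d_max,
        )
        _write(report.to_frame(), out / "filter_report.tsv", manifest)
        results["filter"] = report

    if "stats" in config.stages:
        div = stats.diversity_summary(gm)
        pw = stats.pairwise_differentiation(
            gm, n_perm=config.n_perm, seed=int(rng.integers(2**31)))
        overall = stats.wc_fst(gm)
        per_locus = pd.DataFrame({
            "locus_id": gm.loci.locus_ids,
            "linkage_group": gm.loci.df["linkage_group"],
            "cM": gm.loci.df["cM"],
            "fst": overall.per_locus,
        })
        _write(div.reset_index(), out / "diversity.tsv", manifest)
        _write(pw, out / "pairwise_differentiation.tsv", manifest)
        _write(per_locus, out / "per_locus_fst.tsv", manifest)
        results["stats"] = dict(diversity=div, pairwise=pw, overall=overall,
                                per_locus=per_locus)

    if "ancestry" in config.stages:
        res = anc.admixture_em(
            gm, K=max(2, min(len(gm.pops()), 5)),
            seed=int(rng.integers(2**31)), n_restarts=3,
            init_labels=gm.pop_labels,
        )
        names = anc.match_clusters_to_labels(res.Q, gm.pop_labels)
        cluster_names = [names[k] for k in range(res.K)]
        calls = anc.classify_hybrids(
            res.Q, cluster_names, field_labels=gm.pop_labels,
            q_threshold=config.q_threshold,
            misid_threshold=config.misid_threshold,
        )
        qdf = pd.DataFrame(res.Q, columns=cluster_names,
                           index=gm.individual_ids)
        _write(qdf.reset_index(names="individual"), out / "q_matrix.tsv", manifest)
        _write(calls, out / "hybrid_calls.tsv", manifest)
        results["ancestry"] = dict(fit=res, calls=calls, cluster_names=cluster_names)

    if "assign" in config.stages:
        ares = assignmod.leave_one_out_assign(gm)
        _write(ares.confusion.reset_index(), out / "assignment_confusion.tsv",
               manifest)
        _write(ares.self_assignment.rename_axis("group").reset_index(),
               out / "self_assignment.tsv", manifest)
        results["assign"] = ares

    if "ne" in config.stages:
        ne_rows = []
        for pop in gm.pops():
            sub = gm.subset(ind_idx=gm.pop_indices(pop))
            try:
                est = ne.ne_ld(sub, p_crit=config.p_crit,
                               use_map=bool(gm.loci.mapped.any()))
                ne_rows.append(dict(group=pop, ne=est.ne, ci_low=est.ci_low,
                                    ci_high=est.ci_high, n_pairs=est.n_pairs))
            except ValueError as e:
                log.warning("ne for %s failed: %s", pop, e)
        _write(pd.DataFrame(ne_rows), out / "ne_estimates.tsv", manifest)
        results["ne"] = ne_rows

    if "scan" in config.stages and gm.loci.mapped.any():
        per_locus = stats.wc_fst(gm).per_locus
        sres = scan.smooth_windows(per_locus, gm.loci,
                                   width=config.window_width,
                                   step=config.window_step)
        sres = scan.window_significance(
            sres, per_locus[gm.loci.mapped], seed=int(rng.integers(2**31)),
            step=config.window_step,
        )
        _write(sres.windows, out / "scan_windows.tsv", manifest)
        if sres.segments is not None:
            _write(sres.segments, out / "scan_segments.tsv", manifest)
        results["scan"] = sres

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["stages"][path.name] = _checksum(path)


# ---------------------------------------------------------------------------
# named study scenarios
# ---------------------------------------------------------------------------

def run_stepping_stone_scenario(
    seed: int,
    generations=(2, 5, 10),
    hybridization_m: float = 0.05,
    sample_per_deme: int = 100,
    n_loci: int = 8000,
    deme_size: int = 2000,
    burnin_m: float = 0.001,
    burnin_generations: int = 1000,
    em_seed: int | None = None,
) -> dict:
    """Three-deme hybridization design: burn-in, stepping-stone gene flow,
    admixture at K=3 and hybrid-pair counts at each sampled generation.

    Returns ``{generation: {"counts": Series, "calls": DataFrame, "fst":
    float, "truth": ndarray}}``.
    """
    rng = np.random.default_rng(seed)
    cfg = simmod.SimConfig(
        n_demes=3, deme_size=deme_size, m=burnin_m, n_loci=n_loci,
        burnin_generations=burnin_generations, seed=int(rng.integers(2**31)),
    )
    freqs, _ = simmod.burnin_allele_frequencies(cfg)
    pop = simmod.instantiate_individuals(freqs, deme_size, seed=rng)
    res = simmod.hybridization_phase(
        pop, "stepping_stone_1d", hybridization_m, max(generations),
        seed=rng, sample_per_deme=sample_per_deme, sample_at=list(generations),
    )
    out = {}
    for g, gm in sorted(res.samples.items()):
        # the admixture surface is nearly flat across modes of different Q
        # softness at late generations; converge tightly from several
        # diverse starts and keep the best likelihood
        fit = anc.admixture_em(
            gm, K=3, seed=em_seed if em_seed is not None else int(rng.integers(2**31)),
            n_restarts=4, max_iter=6000, tol=1e-8, init_labels=gm.pop_labels,
        )
        names = anc.match_clusters_to_labels(fit.Q, gm.pop_labels)
        calls = anc.classify_hybrids(
            fit.Q, [names[k] for k in range(3)], field_labels=gm.pop_labels,
        )
        out[g] = dict(
            counts=anc.hybrid_pair_counts(calls), calls=calls,
            fst=stats.wc_fst(gm).theta, truth=gm.ancestry,
        )
    return out


def run_study_scenarios(scenario_name: str, seed: int, out_dir=None) -> pd.DataFrame:
    """Run a named study scenario and return its summary table.

    Names: ``stepping-G2`` / ``stepping-G5`` / ``stepping-G10`` (three-deme
    hybrid counts) and ``erosion-<level>-m<rate>`` with level in {a, b, c}
    and rate in {0.01, 0.05, 0.10} (fifty-replicate FST erosion curves).
    """
    if scenario_name.startswith("stepping-G"):
        gen = int(scenario_name.split("stepping-G")[1])
        res = run_stepping_stone_scenario(seed, generations=(gen,))
        counts = res[gen]["counts"]
        df = counts.rename("n_hybrids").rename_axis("pair").reset_index()
        df.insert(0, "scenario", scenario_name)
    elif scenario_name.startswith("erosion-"):
        _, level, mtag = scenario_name.split("-")
        m = float(mtag.lstrip("m"))
        df = simmod.run_erosion_experiment(level, m, generations=5,
                                           n_replicates=50, seed=seed)
        df.insert(0, "scenario", scenario_name)
    else:
        raise ValueError(f"unknown scenario {scenario_name!r}")
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / f"{scenario_name}.tsv", sep="\t", index=False)
    return df
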