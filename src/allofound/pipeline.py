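"""End-to-end pipeline: simulate -> classify -> founders -> date -> infer
founders -> IBD scan, with a flat config, per-stage seeds and a manifest.

Each stage is a pure function of (inputs, config, seed); stage seeds derive
from the global seed by a fixed counter scheme so any stage can be re-run
in isolation and reproduce its output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .dating import single_founder_dating
from .founder_blocks import count_window_founders, founder_distribution, founder_lower_bound
from .haplotype_sharing import closest_accessions, longest_shared_haplotype_tables
from .io_core import WindowGrid
from .lineage_inference import abc_posterior
from .polymorphism import classify_sites, shared_fraction, window_density
from .synthetic_data import FoundingScenario, simulate_scenario, write_fixture

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "classify", "founders", "date", "infer_founders", "ibd_scan")


@dataclass
class RunConfig:
    """Flat parameter set for a full synthetic run.

    Scenario parameters mirror :class:`FoundingScenario`; analysis
    parameters mirror the per-stage defaults (200-kb windows, 80%
    completeness, mu = 7e-9, AU threshold 0.99).  The simulation sizes
    default to a small genome so a full run stays interactive.
    """

    # scenario
    k_founders: int = 4
    T_found: float = 16_000.0
    mu: float = 7e-9
    L: int = 2_000_000
    window_size: int = 200_000
    N0: float = 5_000.0
    N_anc: float = 200_000.0
    n_suecica: int = 15
    n_parentA: int = 25
    n_parentB: int = 25
    missing_rate: float = 0.0
    # analysis
    min_fraction: float = 0.8
    per_focal: int = 5
    au_threshold: float = 0.99
    au_reps_per_scale: int = 200
    boot_reps: int = 10_000
    abc_n_sims: int = 5_000
    abc_n_keep: int = 100
    abc_n_loci: int = 500
    max_error: float = 0.001
    # run control
    seed: int = 1
    outdir: str = "allofound_run"

    def validate(self) -> None:
        scenario_fields = {f.name for f in dataclasses.fields(FoundingScenario)}
        FoundingScenario(**{
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(RunConfig)
            if f.name in scenario_fields
        })
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not 0 < self.au_threshold < 1:
            raise ValueError("au_threshold must be in (0, 1)")
        if self.abc_n_keep > self.abc_n_sims:
            raise ValueError("abc_n_keep must not exceed abc_n_sims")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: global seed scaled by a fixed counter."""
        return (self.seed * 1_000 + _STAGES.index(stage)) % (2**31)

    def scenario(self) -> FoundingScenario:
        scenario_fields = {f.name for f in dataclasses.fields(FoundingScenario)}
        kwargs = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(RunConfig)
            if f.name in scenario_fields and f.name != "seed"
        }
        return FoundingScenario(seed=self.stage_seed("simulate"), **kwargs)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(RunConfig):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                t = str(types[key])
                kwargs[key] = int(value) if "int" in t else float(value) if "float" in t else value
        return cls(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write stage outputs + a manifest, return the manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    config.to_file(os.path.join(config.outdir, "run_config.cfg"))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "outputs": {},
    }

    # simulate ---------------------------------------------------------------
    scenario = config.scenario()
    sim = simulate_scenario(scenario)
    fixture_dir = os.path.join(config.outdir, "fixture")
    write_fixture(scenario, sim, fixture_dir)
    grid = WindowGrid(contig_length=scenario.L, window_size=scenario.window_size)

    # classify ---------------------------------------------------------------
    classification = classify_sites(sim.subgenomeA, sim.panelA, config.min_fraction)
    dens = window_density(classification, grid, aligned_sites=scenario.window_size)
    dens.to_csv(os.path.join(config.outdir, "classification_density.tsv"), sep="\t", index=False)
    class_summary = classification.counts()
    class_summary["shared_fraction"] = shared_fraction(classification)

    # founders ---------------------------------------------------------------
    rng = np.random.default_rng(config.stage_seed("founders"))
    per_window = []
    for w, window in enumerate(grid.windows):
        result, _ = count_window_founders(
            sim.subgenomeA, sim.panelA, window,
            per_focal=config.per_focal,
            au_threshold=config.au_threshold,
            reps_per_scale=config.au_reps_per_scale,
            seed=rng,
        )
        per_window.append(result.count if result.count >= 1 else 1)
    dist = founder_distribution(per_window)
    with open(os.path.join(config.outdir, "founder_distribution.json"), "w") as fh:
        json.dump({"counts": {str(k): v for k, v in sorted(dist.counts.items())},
                   "total": dist.total,
                   "lower_bound": founder_lower_bound(dist)}, fh, indent=1)

    # date -------------------------------------------------------------------
    single = [w for w, c in enumerate(per_window) if c == 1]
    estimate = single_founder_dating(
        sim.subgenomeA, grid, single,
        mu=config.mu, reps=config.boot_reps, seed=config.stage_seed("date"),
    )
    with open(os.path.join(config.outdir, "origin_estimate.json"), "w") as fh:
        json.dump({"n_single_founder_windows": estimate.n_windows,
                   "median_T_generations": estimate.point,
                   "ci": list(estimate.ci),
                   "median_T_kya": estimate.point_kya}, fh, indent=1)

    # infer founders ---------------------------------------------------------
    abc = abc_posterior(
        dist, n0_fixed=config.N0,
        n_sims=config.abc_n_sims, n_keep=config.abc_n_keep,
        n_loci=config.abc_n_loci, t_query=config.T_found, T=config.T_found,
        n_samples=config.n_suecica, seed=config.stage_seed("infer_founders"),
    )
    np.savetxt(os.path.join(config.outdir, "abc_posterior_nf.tsv"),
               abc.accepted_nf, fmt="%.4f", header="accepted_Nf", comments="")

    # IBD scan ---------------------------------------------------------------
    ranking = closest_accessions(sim.subgenomeA, sim.panelA)
    best_parent = ranking.iloc[0]["accession"]
    share = longest_shared_haplotype_tables(
        sim.subgenomeA, sim.panelA, sim.subgenomeA.accessions[0], best_parent,
        max_error=config.max_error,
    )
    with open(os.path.join(config.outdir, "ibd_longest.bed"), "w") as fh:
        fh.write(f"{share.contig}\t{share.start}\t{share.end}\t"
                 f"{sim.subgenomeA.accessions[0]}|{best_parent}\n")

    # manifest ---------------------------------------------------------------
    summary = {
        "classification": class_summary,
        "founder_distribution": {str(k): v for k, v in sorted(dist.counts.items())},
        "founder_lower_bound": founder_lower_bound(dist),
        "origin_median_T": estimate.point,
        "origin_ci": list(estimate.ci),
        "abc_posterior_median_Nf": abc.posterior_median,
        "ibd_longest_bp": share.length,
    }
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    for root, _, files in os.walk(config.outdir):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            path = os.path.join(root, name)
            rel = os.path.relpath(path, config.outdir)
            manifest["outputs"][rel] = _sha256(path)
    manifest["summary"] = summary
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
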