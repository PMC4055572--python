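"""End-to-end analysis rehearsal: simulate → test → date → partition → structure.

One declarative config drives the whole chain on synthetic data with known
truth.  Each stage writes its artifacts under the output directory together
with a manifest carrying the config hash and seed, so a rerun with an
unchanged config resumes after the last completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .admixsim import AdmixtureScenario, simulate_two_episode
from .config import (
    COMPOSITE_K,
    PAINT_CONFIDENCE,
    PAINT_WINDOW_LOCI,
    Z_THRESHOLD_F3_D,
)
from .fstats import BlockPartition, PopulationFreqs, d_stat, f3
from .lddating import compute_weighted_ld, fit_double, fit_single, compare_models
from .partition import assemble_composite, intersect_sites, paint_windows, threshold_segments
from .popstruct import fst_from_identity, gene_identity_matrix
from .sources import DriftTree, make_genetic_map, simulate_drift_frequencies, simulate_panels

logger = logging.getLogger("hoa_admixkit")

__all__ = ["RunConfig", "run_workflow", "generate_fixtures", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration for the full rehearsal.

    Defaults follow the conventional printed values: 0.8 painting
    confidence, composite depth 12, |Z| threshold 4, 30 years/generation.
    """

    seed: int = 0
    out_dir: str = "run_out"
    n_loci: int = 20_000
    n_chromosomes: int = 10
    chromosome_length: float = 1.0
    source_drift: float = 0.08
    n_source_haplotypes: int = 60
    lambda0: float = 100.0
    lambda1: float = 10.0
    alpha0: float = 0.25
    alpha1: float = 0.10
    n_out: int = 20
    paint_window: int = PAINT_WINDOW_LOCI
    paint_confidence: float = PAINT_CONFIDENCE
    composite_k: int = COMPOSITE_K
    z_threshold: float = Z_THRESHOLD_F3_D

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(report: dict, manifest_path: Path, name: str):
    """Record a completed stage in the resumable manifest."""
    report["stages_done"].append(name)
    manifest_path.write_text(json.dumps(report, indent=2, default=str))


def run_workflow(config: RunConfig, resume: bool = True) -> dict:
    """Execute the full synthetic rehearsal; returns the run report.

    Stages: sources → admixture → admixture tests → LD dating (skipped with a
    reason when the tests find no admixture) → partitioning → structure.
    Artifacts land under ``config.out_dir``; identical config + seed produce
    byte-identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    report: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages_done": [],
        "outputs": {},
    }
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == report["config_hash"]:
            report = prev
    done = set(report["stages_done"])

    rng = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(8)]

    t0 = time.time()
    # -- sources ----------------------------------------------------------
    tree = DriftTree.from_dict(
        {
            "name": "root",
            "children": [
                {"name": "SRC_A", "f": config.source_drift},
                {"name": "SRC_B", "f": config.source_drift},
                {"name": "REF_A", "f": config.source_drift},
            ],
        }
    )
    gmap = make_genetic_map(
        config.n_chromosomes, config.chromosome_length, config.n_loci, seed=seeds[0]
    )
    freqs = simulate_drift_frequencies(tree, config.n_loci, seed=seeds[1])
    panels = simulate_panels(freqs, config.n_source_haplotypes, gmap, seed=seeds[2])
    if "sources" not in done:
        hio.write_frequency_csv(out / "source_frequencies.csv", freqs)
        hio.write_map(out / "loci.map", gmap)
        report["outputs"]["sources"] = ["source_frequencies.csv", "loci.map"]
        logger.info("stage=sources seed=%d elapsed=%.1fs", seeds[1], time.time() - t0)
        _stage(report, manifest_path, "sources")

    # -- admixture ---------------------------------------------------------
    half = config.n_source_haplotypes // 2
    from .sources import HaplotypePanel

    b_first = HaplotypePanel("SRC_B", panels["SRC_B"].haplotypes[:half])
    b_second = HaplotypePanel("SRC_B", panels["SRC_B"].haplotypes[half:])
    scenario = AdmixtureScenario(
        lambda0=config.lambda0,
        lambda1=config.lambda1,
        alpha0=config.alpha0,
        alpha1=config.alpha1,
        n_out=config.n_out,
    )
    cohort = simulate_two_episode(
        panels["SRC_A"], b_first, b_second, gmap, scenario, seed=seeds[3]
    )
    if "admixture" not in done:
        hio.write_tracks(out / "true_tracks.tsv", cohort.track)
        hio.write_tped(
            out / "admixed",
            gmap,
            cohort.panel.haplotypes[cohort.diploid_pairs],
            [f"IND{i}" for i in range(config.n_out)],
            population="ADMIXED",
        )
        report["outputs"]["admixture"] = ["true_tracks.tsv", "admixed.tped", "admixed.tfam"]
        logger.info("stage=admixture seed=%d elapsed=%.1fs", seeds[3], time.time() - t0)
        _stage(report, manifest_path, "admixture")

    # -- admixture tests ---------------------------------------------------
    blocks = BlockPartition.per_chromosome(gmap)
    target = PopulationFreqs.from_genotypes("ADMIXED", cohort.diploid_genotypes())
    pf = {k: PopulationFreqs.from_panel(v) for k, v in panels.items()}
    try:
        f3_res = f3(target, pf["SRC_A"], pf["SRC_B"], blocks)
        d_res = d_stat(pf["REF_A"], target, pf["SRC_A"], pf["SRC_B"], blocks)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("admixture_tests", str(exc))
    admixture_significant = f3_res.z < -config.z_threshold
    if "admixture_tests" not in done:
        (out / "admixture_tests.json").write_text(
            json.dumps(
                {
                    "f3": {"value": f3_res.value, "se": f3_res.se, "z": f3_res.z},
                    "d": {"value": d_res.value, "se": d_res.se, "z": d_res.z},
                    "significant": bool(admixture_significant),
                },
                indent=2,
            )
        )
        report["outputs"]["admixture_tests"] = ["admixture_tests.json"]
        _stage(report, manifest_path, "admixture_tests")

    # -- dating ------------------------------------------------------------
    if "dating" not in done:
        if not admixture_significant:
            report["outputs"]["dating"] = []
            report["dating_skipped"] = "no significant admixture signal (f3)"
            _stage(report, manifest_path, "dating")
        else:
            curve = compute_weighted_ld(
                cohort.diploid_genotypes(), gmap, pf["SRC_A"].p, pf["SRC_B"].p
            )
            single = fit_single(curve)
            try:
                double = fit_double(curve, jackknife=False)
                comparison = compare_models(single, double)
                dual = {
                    "fit": double.to_dict(),
                    "preferred": comparison.dual_preferred,
                    "p_value": comparison.p_value,
                }
            except ValueError:
                dual = None
            curve.to_frame().to_csv(out / "weighted_ld_curve.tsv", sep="\t", index=False)
            (out / "dating.json").write_text(
                json.dumps({"single": single.to_dict(), "dual": dual}, indent=2)
            )
            report["outputs"]["dating"] = ["weighted_ld_curve.tsv", "dating.json"]
            logger.info("stage=dating elapsed=%.1fs", time.time() - t0)
            _stage(report, manifest_path, "dating")

    # -- partitioning ------------------------------------------------------
    # clip donor frequencies away from 0/1: finite-donor-panel smoothing so a
    # single unseen allele cannot zero out a window's likelihood
    eps = 1.0 / (2 * config.n_source_haplotypes)
    post = paint_windows(
        cohort.panel,
        np.clip(pf["SRC_A"].p, eps, 1 - eps),
        np.clip(pf["SRC_B"].p, eps, 1 - eps),
        gmap,
        window_loci=config.paint_window,
    )
    assign = threshold_segments(post, confidence=config.paint_confidence)
    composites = assemble_composite(
        cohort.panel, assign, k=config.composite_k, seed=seeds[4]
    )
    inter = intersect_sites(composites)
    if "partition" not in done:
        (out / "partition.json").write_text(
            json.dumps(
                {
                    "assigned_fraction": assign.assigned_fraction,
                    "retained_loci": int(inter.n_loci),
                    "empty": inter.empty,
                },
                indent=2,
            )
        )
        report["outputs"]["partition"] = ["partition.json"]
        _stage(report, manifest_path, "partition")

    # -- structure ---------------------------------------------------------
    if "structure" not in done:
        j = gene_identity_matrix(list(panels.values()), n_blocks=min(50, config.n_loci))
        j.to_frame().to_csv(out / "gene_identity.tsv", sep="\t")
        (out / "structure.json").write_text(
            json.dumps({"fst_sources": fst_from_identity(j)}, indent=2)
        )
        report["outputs"]["structure"] = ["gene_identity.tsv", "structure.json"]
        _stage(report, manifest_path, "structure")

    report["elapsed_seconds"] = time.time() - t0
    manifest_path.write_text(json.dumps(report, indent=2, default=str))
    return report


def generate_fixtures(seed: int = 0) -> dict:
    """Small deterministic dataset used by the test suite.

    Three source populations on a drift tree, one admixed cohort, 5,000 loci
    on 4 chromosomes.  The admixture parameters (alpha = 0.3, strong source
    divergence) make the cohort's f3 signal decisively negative.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    gmap = make_genetic_map(4, 1.0, 5_000, seed=seeds[0])
    tree = DriftTree.from_dict(
        {
            "name": "root",
            "children": [
                {"name": "SRC_A", "f": 0.08},
                {"name": "SRC_B", "f": 0.08},
                {"name": "REF_A", "f": 0.08},
            ],
        }
    )
    freqs = simulate_drift_frequencies(tree, 5_000, seed=seeds[1])
    panels = simulate_panels(freqs, 60, gmap, seed=seeds[2])
    half = 30
    from .sources import HaplotypePanel

    cohort = simulate_two_episode(
        panels["SRC_A"],
        HaplotypePanel("SRC_B", panels["SRC_B"].haplotypes[:half]),
        HaplotypePanel("SRC_B", panels["SRC_B"].haplotypes[half:]),
        gmap,
        AdmixtureScenario(lambda0=50.0, lambda1=10.0, alpha0=0.25, alpha1=0.10, n_out=20),
        seed=seeds[3],
    )
    return {
        "map": gmap,
        "tree": tree,
        "frequencies": freqs,
        "panels": panels,
        "cohort": cohort,
        "seeds": seeds,
    }
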