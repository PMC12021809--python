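"""Cohort assembly, simulation campaigns, and the end-to-end experiment.

A *virtual patient* (case) pairs one LA and one RA fibrosis map drawn from a
split-specific map pool, simulates a pre-ablation AF episode (features), then
one post-ablation episode per strategy restarting from the pre-ablation final
state with the strategy's non-conducting mask applied (labels).

Leakage rule: the fibrosis-map pools backing train / validation / test are
pairwise disjoint (maps may be reused within a split, never across splits),
mirroring the 80/10/10 split of the 100 clinical maps.  The comparison
training split draws from its own pool of synthetic or noise maps.

Profiles: ``reference`` (400/400/100/100 cases, 15 s episodes, 192x192
grids) is preserved for cluster use; ``desk`` (40/40/10/10, 2 s) and ``smoke`` (tiny
grids, sub-second episodes) scale the same pipeline down to one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ep, features, maps
from .classifier import (ClassifierCase, FusionConfig, TrainConfig,
                         evaluate_roc_auc, train_classifier)
from .remodeling import STRATEGY_ORDER, AblationStrategy, PviRingConfig, \
    build_ablation_masks

log = logging.getLogger("fibrotwin")

SPLITS = ("train_real", "train_comparison", "validation", "test")


@dataclass
class SolverConfig:
    upsample: int = 2
    spacing_mm: float = 0.5
    dt_ms: float = 0.02
    diffusion_dt_ms: float = 0.1
    chi: float = ep.DEFAULT_CHI
    n_spirals: int = 4
    spiral_wavelength_px: float = 40.0
    bridges_enabled: bool = True


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment from a global seed."""

    cohort_sizes: dict = field(default_factory=lambda: dict(
        train_real=40, train_comparison=40, validation=10, test=10))
    pool_sizes: dict = field(default_factory=lambda: dict(
        train_real=80, validation=10, test=10, train_comparison=80))
    comparison_source: str = "noise"        # or "synthetic"
    episode_ms: float = 2000.0
    post_episode_ms: float | None = None    # default: same as episode_ms
    map_resolution: int = 96
    solver: SolverConfig = field(default_factory=SolverConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    training_split: str = "train_real"
    exclude_non_sustained: bool = False     # reference pipeline keeps them
    seed: int = 0

    @classmethod
    def reference_profile(cls) -> "ExperimentConfig":
        """Full-scale configuration (cluster use; never run in tests)."""
        return cls(cohort_sizes=dict(train_real=400, train_comparison=400,
                                     validation=100, test=100),
                   episode_ms=15000.0)

    @classmethod
    def smoke_profile(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(
            cohort_sizes=dict(train_real=4, train_comparison=2,
                              validation=2, test=2),
            pool_sizes=dict(train_real=8, validation=2, test=2,
                            train_comparison=8),
            episode_ms=200.0, post_episode_ms=200.0, map_resolution=48,
            solver=SolverConfig(upsample=1, dt_ms=0.04,
                                chi=32 * ep.DEFAULT_CHI,
                                spiral_wavelength_px=24.0),
            training=TrainConfig(epochs=5, patience=5),
            seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key, sub in (("solver", SolverConfig), ("fusion", FusionConfig),
                         ("training", TrainConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(d, f)


@dataclass
class CaseRecord:
    """One virtual patient."""

    case_id: str
    la_map: maps.FibrosisMap
    ra_map: maps.FibrosisMap
    split: str
    seed_bundle: dict
    la_stack: features.FeatureStack | None = None
    ra_stack: features.FeatureStack | None = None
    labels: dict | None = None              # strategy name -> OutcomeLabel
    sustained: bool | None = None
    failed: bool = False
    failure: str | None = None

    def label_vector(self) -> np.ndarray:
        return np.array([int(self.labels[s.value].terminated)
                         for s in STRATEGY_ORDER], dtype=float)

    def to_classifier_case(self) -> ClassifierCase:
        return ClassifierCase(self.la_stack.channels, self.ra_stack.channels,
                              self.label_vector(), self.case_id,
                              self.la_map.map_id, self.ra_map.map_id)


def _derive_seed(global_seed: int, *parts) -> int:
    """Stable per-purpose sub-seed below 2^31."""
    ss = np.random.SeedSequence([global_seed] + [abs(hash(p)) % (2 ** 31)
                                                 for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_map_pools(config: ExperimentConfig,
                    synthetic_maps: list | None = None) -> dict[str, list]:
    """Disjoint fibrosis-map pools per split.

    LGE-like fixture maps stand in for the clinical 80/10/10 pools; the
    comparison pool holds noise maps or externally supplied synthetic maps.
    """
    pools: dict[str, list] = {}
    counter = 0
    for split in ("train_real", "validation", "test"):
        n = config.pool_sizes[split]
        pool = []
        for _ in range(n):
            seed = _derive_seed(config.seed, "pool", split, counter)
            pool.append(maps.generate_lge_like_fixture(
                seed=seed, shape=(config.map_resolution,) * 2,
                map_id=f"fixture-{split}-{counter}"))
            counter += 1
        pools[split] = pool
    if config.comparison_source == "synthetic":
        if not synthetic_maps:
            raise ValueError("comparison_source='synthetic' requires maps "
                             "sampled from a trained generative model")
        pools["train_comparison"] = list(synthetic_maps)
    else:
        pool = []
        for i in range(config.pool_sizes["train_comparison"]):
            seed = _derive_seed(config.seed, "pool", "comparison", i)
            pool.append(maps.generate_noise_map(
                shape=(config.map_resolution,) * 2, seed=seed,
                map_id=f"noise-comparison-{i}"))
        pools["train_comparison"] = pool
    return pools


def build_cohort(config: ExperimentConfig,
                 synthetic_maps: list | None = None) -> list[CaseRecord]:
    """Assemble the cohort: seeded LA/RA map draws from split-local pools."""
    pools = build_map_pools(config, synthetic_maps)
    cohort: list[CaseRecord] = []
    idx = 0
    for split in SPLITS:
        n_cases = config.cohort_sizes[split]
        pool = pools[split]
        if not pool:
            raise ValueError(f"empty map pool for split {split}")
        rng = np.random.default_rng(_derive_seed(config.seed, "draw", split))
        for _ in range(n_cases):
            la, ra = pool[rng.integers(len(pool))], pool[rng.integers(len(pool))]
            case_id = f"case-{idx:04d}"
            cohort.append(CaseRecord(
                case_id=case_id, la_map=la, ra_map=ra, split=split,
                seed_bundle={
                    "global": config.seed,
                    "spiral": _derive_seed(config.seed, "spiral", case_id),
                },
            ))
            idx += 1
    return cohort


def cohort_manifest(cohort: list[CaseRecord]) -> dict:
    return {
        "cases": [
            {"case_id": c.case_id, "split": c.split,
             "la_map_id": c.la_map.map_id, "ra_map_id": c.ra_map.map_id,
             "seed_bundle": c.seed_bundle, "sustained": c.sustained,
             "labels": None if c.labels is None else {
                 k: v.mean_last_peak_fraction for k, v in c.labels.items()}}
            for c in cohort
        ],
    }


# ---------------------------------------------------------------------------
# Simulation campaign
# ---------------------------------------------------------------------------

def _sheets_for_case(case: CaseRecord, config: ExperimentConfig,
                     la_ablation=None, ra_ablation=None) -> list[ep.TissueSheet]:
    sv = config.solver
    return [
        ep.TissueSheet.from_fibrosis_map(case.la_map, "LA", sv.upsample,
                                         sv.spacing_mm,
                                         ablation_mask=la_ablation),
        ep.TissueSheet.from_fibrosis_map(case.ra_map, "RA", sv.upsample,
                                         sv.spacing_mm,
                                         ablation_mask=ra_ablation),
    ]


def run_case(case: CaseRecord, config: ExperimentConfig,
             trajectory: np.ndarray | None = None) -> CaseRecord:
    """Pre-ablation episode (features), four post-ablation episodes (labels).

    Post-ablation runs restart from the pre-ablation final state with the
    strategy's mask applied as non-conducting tissue.  Solver failures mark
    the case failed (with diagnostics) instead of aborting the campaign.
    """
    sv = config.solver
    t0 = time.perf_counter()
    try:
        sheets = _sheets_for_case(case, config)
        bridges = None if sv.bridges_enabled else []
        init = ep.initiate_spirals(
            sheets, sv.n_spirals, case.seed_bundle["spiral"],
            k_rad_per_px=2 * np.pi / sv.spiral_wavelength_px,
            trajectory=trajectory)
        pre = ep.run_monodomain(sheets, config.episode_ms, sv.dt_ms,
                                sv.diffusion_dt_ms, init_states=init,
                                bridges=bridges, chi=sv.chi)
        case.sustained = ep.is_sustained(pre)
        map_shape = case.la_map.shape
        psd = {n: features.psd_map(pre, i, out_shape=map_shape)
               for i, n in enumerate(("LA", "RA"))}
        df = {n: features.dominant_frequency_map(pre, i, out_shape=map_shape)
              if config.episode_ms >= 1000.0 else
              features.dominant_frequency_map(
                  _padded(pre), i, out_shape=map_shape)
              for i, n in enumerate(("LA", "RA"))}

        post_ms = config.post_episode_ms or config.episode_ms
        labels = {}
        for strat in STRATEGY_ORDER:
            la_mask, ra_mask = build_ablation_masks(case.la_map, case.ra_map,
                                                    strat)
            ab_sheets = _sheets_for_case(case, config, la_mask, ra_mask)
            res = ep.run_monodomain(ab_sheets, post_ms, sv.dt_ms,
                                    sv.diffusion_dt_ms,
                                    init_states=pre.final_state,
                                    bridges=bridges, chi=sv.chi,
                                    keep_final_state=False)
            labels[strat] = res
        gt = features.ground_truth_label(labels)
        case.labels = {s.value: gt[s] for s in STRATEGY_ORDER}

        pvi_la, _ = build_ablation_masks(case.la_map, case.ra_map,
                                         AblationStrategy.PVI)
        fib_la, fib_ra = build_ablation_masks(case.la_map, case.ra_map,
                                              AblationStrategy.PVI_LA_RA)
        case.la_stack = features.build_feature_stack(
            case.la_map.values, pvi_la, fib_la, psd["LA"], df["LA"], "LA")
        case.ra_stack = features.build_feature_stack(
            case.ra_map.values, np.zeros(map_shape), fib_ra, psd["RA"],
            df["RA"], "RA")
    except (ep.SimulationInstabilityError, ep.ConductionBlockError) as exc:
        case.failed = True
        case.failure = str(exc)
        log.error("case %s failed: %s", case.case_id, exc)
    log.info("case %s done in %.1f s (sustained=%s)", case.case_id,
             time.perf_counter() - t0, case.sustained)
    return case


def _padded(result: ep.SimulationResult) -> ep.SimulationResult:
    """Zero-order-hold padding of short recordings to 1 s for the DF spectrum
    (smoke profiles run sub-second episodes; the 1 Hz resolution floor of the
    DF estimator needs 1 s of signal)."""
    need = int(np.ceil(1000.0 / result.downsample_ms)) + 1
    volts = []
    for v in result.voltages:
        if v.shape[0] >= need:
            volts.append(v)
        else:
            pad = np.repeat(v[-1:], need - v.shape[0], axis=0)
            volts.append(np.concatenate([v, pad], axis=0))
    return dataclasses.replace(result, voltages=volts,
                               duration_ms=max(result.duration_ms,
                                               need * result.downsample_ms))


def run_cohort(cohort: list[CaseRecord], config: ExperimentConfig) -> list[CaseRecord]:
    trajectory = ep.limit_cycle_trajectory()
    for case in cohort:
        run_case(case, config, trajectory=trajectory)
    return cohort


# ---------------------------------------------------------------------------
# Experiment
# ---------------------------------------------------------------------------

def label_monotone_fraction(cohort: list[CaseRecord]) -> float:
    """Fraction of cases whose termination labels are monotone under mask
    nesting (more ablation never flips termination back to sustained along
    PVI -> PVI+LA -> PVI+LA+RA and PVI -> PVI+RA -> PVI+LA+RA).  A
    diagnostic, not an invariant: dynamics can be non-monotone."""
    ok, n = 0, 0
    for c in cohort:
        if c.labels is None:
            continue
        t = {s.value: c.labels[s.value].terminated for s in STRATEGY_ORDER}
        chains = (("PVI", "PVI+LA", "PVI+LA+RA"), ("PVI", "PVI+RA", "PVI+LA+RA"))
        mono = all(not (t[a] and not t[b])
                   for chain in chains for a, b in zip(chain, chain[1:]))
        ok += mono
        n += 1
    return float(ok / n) if n else float("nan")


def run_experiment(config: ExperimentConfig, out_dir=None,
                   synthetic_maps: list | None = None,
                   cohort: list[CaseRecord] | None = None) -> dict:
    """Cohort -> simulations -> classifier -> metrics report (JSON/CSV).

    A pre-simulated ``cohort`` may be injected (resuming a campaign, or
    testing the training/evaluation stage in isolation).  When every output
    is single-class across the training labels (the usual desk-scale outcome:
    2D sheets cannot sustain AF, so every strategy terminates), training is
    skipped and the report carries NaN AUCs with ``labels_degenerate`` set.
    """
    t0 = time.perf_counter()
    if cohort is None:
        cohort = build_cohort(config, synthetic_maps)
        run_cohort(cohort, config)

    def usable(split):
        out = [c for c in cohort if c.split == split and not c.failed
               and c.labels is not None]
        if config.exclude_non_sustained and split == config.training_split:
            out = [c for c in out if c.sustained]
        return out

    train = usable(config.training_split)
    val = usable("validation")
    test = usable("test")
    if not train or not val or not test:
        raise ValueError("empty split after simulation campaign")
    train_labels = np.stack([c.label_vector() for c in train])
    degenerate = all(len(np.unique(train_labels[:, k])) < 2 for k in range(4))
    if degenerate:
        log.warning("all four outputs single-class in the training split; "
                    "skipping classifier training")
        history = {"loss": []}
        test_metrics = {"per_strategy": [float("nan")] * 4,
                        "mean": float("nan")}
    else:
        model, history = train_classifier(
            [c.to_classifier_case() for c in train],
            config.fusion, config.training,
            validation_cases=[c.to_classifier_case() for c in val])
        test_metrics = evaluate_roc_auc(
            model, [c.to_classifier_case() for c in test])
    report = {
        "config_seed": config.seed,
        "training_split": config.training_split,
        "comparison_source": config.comparison_source,
        "fusion": config.fusion.mode,
        "backbone": config.training.backbone,
        "n_cases": {s: len(usable(s)) for s in SPLITS},
        "sustained_fraction": float(np.mean([bool(c.sustained)
                                             for c in cohort if not c.failed])),
        "label_monotone_fraction": label_monotone_fraction(cohort),
        "labels_degenerate": degenerate,
        "test_auc_per_strategy": test_metrics["per_strategy"],
        "test_auc_mean": test_metrics["mean"],
        "epochs_run": len(history["loss"]),
        "wall_time_s": time.perf_counter() - t0,
        "manifest": cohort_manifest(cohort),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=2, default=float)
        rows = [{"strategy": s.value, "test_auc": a}
                for s, a in zip(STRATEGY_ORDER, test_metrics["per_strategy"])]
        pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    return report
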