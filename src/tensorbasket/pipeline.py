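"""End-to-end pipeline: ingest → filter → rescale → fit → peel → refit → patterns.

The pipeline mirrors the two-pass analysis workflow: a first fit on the
full scaled tensor flags atypical weeks and product groups via large
loadings; those slices are peeled; the augmentation estimator picks the
ranks for the refit; scores then feed the stratification, decile,
profile, trajectory and flattening-comparison outputs.  All randomness
flows from one root seed, split per stage, so a fixed seed reproduces
every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import comparison_report
from .model import TensorPCA
from .order_selection import augmentation_order
from .patterns import deciles, flag_atypical, group_profile, stratify, trajectory_by_decile
from .preprocess import apply_exclusions, peel, rescale_annual, weekly_share
from .simulate import SyntheticConfig, simulate_tensor
from .tensor import assemble_tensor, read_transactions, write_transactions

logger = logging.getLogger("tensorbasket")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run.

    Exactly one of ``input_path`` (a transaction file) or ``synthetic``
    (generator settings) must be given.
    """

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    week_range: tuple[int, int] = (1, 52)
    max_zero_weeks: int = 8
    min_total: float = 500.0
    rescale_target: float = 1000.0
    remove_ids: tuple[str, ...] = ()
    initial_ranks: tuple[int, int] = (5, 3)
    atypical_threshold: float = 0.3
    peel_weeks: tuple[int, ...] | None = None     # None → use flagged weeks
    peel_groups: tuple[str, ...] | None = None    # None → use flagged groups
    fixed_ranks: tuple[int, int] | None = None    # None → augmentation selection
    augmentation_replicates: int = 50
    k_max: int | None = None
    stratify_pairs: tuple[tuple[int, int], ...] = ((1, 1),)
    stratify_q: float = 0.10
    decile_pair: tuple[int, int] = (1, 1)
    decile_subset: tuple[str, ...] | None = None
    comparison_k: int = 3
    out_dir: str = "tensorbasket_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")
        if not (0 <= self.stratify_q < 0.5):
            raise ValueError("stratify_q must be in [0, 0.5)")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline configuration file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        for key in ("true_ranks", "latent_sds", "holiday_weeks", "zero_inflation_prob",
                    "group_labels"):
            if key in syn and syn[key] is not None:
                syn[key] = tuple(syn[key])
        raw["synthetic"] = SyntheticConfig(**syn)
    for key in ("week_range", "initial_ranks", "fixed_ranks", "peel_weeks", "peel_groups",
                "remove_ids", "decile_pair", "decile_subset"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if "stratify_pairs" in raw and raw["stratify_pairs"] is not None:
        raw["stratify_pairs"] = tuple(tuple(p) for p in raw["stratify_pairs"])
    return PipelineConfig(**raw)


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns the run manifest (also written to ``manifest.json``), which
    records the seed, package version, stage-by-stage dimensions and the
    paths of every artifact.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }

    def stage(name: str, **info: Any) -> None:
        logger.info("stage %s: %s", name, info)
        manifest["stages"][name] = info

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path)

    # -- ingest ---------------------------------------------------------
    if config.synthetic is not None:
        tensor, truth = simulate_tensor(config.synthetic)
        path = out / "transactions.csv"
        write_transactions(tensor, path)
        artifact("transactions", path)
    else:
        truth = None
        records = read_transactions(config.input_path)
        tensor = assemble_tensor(records, config.week_range)
    stage("ingest", shape=list(tensor.shape))

    # -- exclusions and rescaling ---------------------------------------
    tensor, report = apply_exclusions(
        tensor, config.max_zero_weeks, config.min_total, remove_ids=config.remove_ids
    )
    report.to_json(out / "exclusion_report.json")
    artifact("exclusion_report", out / "exclusion_report.json")
    stage("exclusions", **{k: v for k, v in report.to_dict().items()
                           if k.startswith("n_")})
    tensor = rescale_annual(tensor, config.rescale_target)
    stage("rescale", target=config.rescale_target)

    shares = weekly_share(tensor)
    shares.to_csv(out / "weekly_shares.csv")
    artifact("weekly_shares", out / "weekly_shares.csv")

    # -- first pass: flag atypicalities ---------------------------------
    p0_init = min(config.initial_ranks[0], tensor.n_groups)
    t0_init = min(config.initial_ranks[1], tensor.n_weeks)
    first = TensorPCA(tensor).fit(p0_init, t0_init)
    flagged_weeks, flagged_groups = flag_atypical(first, config.atypical_threshold)
    stage("flag_atypical", weeks=flagged_weeks, groups=flagged_groups)

    drop_weeks = config.peel_weeks if config.peel_weeks is not None else flagged_weeks
    drop_groups = config.peel_groups if config.peel_groups is not None else flagged_groups
    peeled = peel(tensor, drop_weeks, drop_groups)
    stage("peel", dropped_weeks=list(drop_weeks), dropped_groups=list(drop_groups),
          shape=list(peeled.shape))

    # -- rank selection and refit ---------------------------------------
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    if config.fixed_ranks is not None:
        p0, t0 = config.fixed_ranks
        order_info = {"fixed": True}
    else:
        ranks = []
        order_info = {"fixed": False}
        for mode, d, name, seq in (
            (1, peeled.n_groups, "products", seeds[0]),
            (2, peeled.n_weeks, "weeks", seeds[1]),
        ):
            if d < 2:  # a single remaining slice cannot be rank-selected
                ranks.append(1)
                order_info[f"k_hat_{name}"] = 1
                continue
            k_max = min(config.k_max, d - 1) if config.k_max else None
            res = augmentation_order(
                peeled, mode,
                n_replicates=config.augmentation_replicates,
                k_max=k_max,
                seed=int(np.random.default_rng(seq).integers(2**31)),
            )
            ranks.append(max(1, res.k_hat))
            res.to_json(out / f"order_selection_{name}.json")
            artifact(f"order_selection_{name}", out / f"order_selection_{name}.json")
            order_info[f"k_hat_{name}"] = res.k_hat
        p0, t0 = ranks
    stage("order_selection", **order_info, p0=p0, t0=t0)

    results = TensorPCA(peeled).fit(p0, t0)
    results.loadings_products.to_csv(out / "loadings_products.csv")
    results.loadings_weeks.to_csv(out / "loadings_weeks.csv")
    _dump_json(results.spectra_dict(), out / "spectra.json")
    for name in ("loadings_products", "loadings_weeks", "spectra"):
        artifact(name, out / f"{name}.{'json' if name == 'spectra' else 'csv'}")
    stage("refit", p0=p0, t0=t0,
          explained_products=results.explained_variance_products,
          explained_weeks=results.explained_variance_weeks)

    scores = results.project()
    scores.to_frame().to_csv(out / "scores.csv", index=False)
    artifact("scores", out / "scores.csv")

    # -- stratification, deciles, profiles, trajectories ----------------
    strat_frames = []
    for pair in config.stratify_pairs:
        pair = (min(pair[0], p0), min(pair[1], t0))
        labels = stratify(scores, pair, config.stratify_q)
        strat_frames.append(labels.to_frame())
        for side in ("high", "low"):
            prof = group_profile(peeled, labels.ids(side))
            prof.z_profile.to_csv(out / f"profile_{pair[0]}_{pair[1]}_{side}.csv")
    strat = pd.concat(strat_frames, ignore_index=True)
    strat.to_csv(out / "stratification.csv", index=False)
    artifact("stratification", out / "stratification.csv")
    stage("stratify", pairs=[list(p) for p in config.stratify_pairs], q=config.stratify_q)

    dec_pair = (min(config.decile_pair[0], p0), min(config.decile_pair[1], t0))
    dec = deciles(scores, dec_pair)
    dec.rename_axis("customer_id").to_csv(out / "deciles.csv")
    artifact("deciles", out / "deciles.csv")
    subset = list(config.decile_subset) if config.decile_subset else [peeled.group_labels[0]]
    subset = [g for g in subset if g in peeled.group_labels] or [peeled.group_labels[0]]
    traj = trajectory_by_decile(peeled, dec, subset)
    traj.to_csv(out / "trajectories.csv")
    artifact("trajectories", out / "trajectories.csv")
    stage("deciles", pair=list(dec_pair), subset=subset)

    # -- flattening comparison ------------------------------------------
    # ground-truth bases only apply while the tensor keeps its original slices
    truth_ok = truth is not None and truth.A.shape[0] == peeled.n_groups and \
        truth.B.shape[0] == peeled.n_weeks
    comp = comparison_report(peeled, results, truth=truth if truth_ok else None,
                             k=config.comparison_k)
    _dump_json(comp, out / "pca_comparison.json")
    artifact("pca_comparison", out / "pca_comparison.json")
    stage("pca_comparison", schemes=list(comp["schemes"].keys()))

    _dump_json(manifest, out / "manifest.json")
    return manifest
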