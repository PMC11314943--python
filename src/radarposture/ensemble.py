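"""Radar-ensemble ablation protocol.

The placement study asks: how few radars, and which ones, still classify
posture well?  Rather than search all 255 subsets of the eight slots, a
pre-planned registry of 22 configurations probes specific hypotheses
(head-radar removal, single head radar, side-radar removal with the
central head radar retained, upper-body-only side coverage, ...).  For
each configuration the classifier is retrained from scratch on view
stacks restricted to the active radars and scored on held-out subjects;
averaging accuracy per radar count summarises the cost of removing
sensors.

The published per-configuration accuracies of the four reference
backbones ship as a packaged fixture (``data/reference_accuracies.csv``)
so the radar-count aggregation arithmetic can be exercised without
retraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import CANONICAL_RADAR_ORDER
from .mvcnn import ModelSpec, TrainConfig, build_model, evaluate, train

__all__ = [
    "EnsembleConfig",
    "AblationResult",
    "config_registry",
    "load_reference_accuracies",
    "subject_split",
    "run_ablation",
    "aggregate_by_count",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """A subset of the eight canonical radar slots.

    ``mask`` is a boolean per slot in canonical order (HL, HC, HR,
    S1..S5); True retains the radar.
    """

    config_id: int
    mask: tuple
    note: str = ""

    def __post_init__(self):
        if len(self.mask) != len(CANONICAL_RADAR_ORDER):
            raise ValueError("mask must cover the 8 canonical radar slots")
        if not any(self.mask):
            raise ValueError("at least one radar must be retained")

    @property
    def n_radars(self) -> int:
        return int(sum(bool(m) for m in self.mask))

    def active_ids(self) -> tuple:
        return tuple(rid for rid, m in zip(CANONICAL_RADAR_ORDER, self.mask) if m)


@dataclass
class AblationResult:
    config_id: int
    model: str
    accuracy: float
    n_radars: int
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


def _cfg(cid, ids, note=""):
    idset = set(ids)
    return EnsembleConfig(
        config_id=cid,
        mask=tuple(rid in idset for rid in CANONICAL_RADAR_ORDER),
        note=note,
    )


_S = ("S1", "S2", "S3", "S4", "S5")
_REGISTRY = (
    _cfg(1, _S + ("HL", "HC", "HR"), "Baseline"),
    _cfg(2, _S + ("HL", "HC"), "Head radar removal"),
    _cfg(3, _S + ("HL", "HR"), "Head radar removal"),
    _cfg(4, _S + ("HC", "HR"), "Head radar removal"),
    _cfg(5, _S + ("HL",), "Retain single head radar"),
    _cfg(6, _S + ("HC",), "Retain single head radar"),
    _cfg(7, _S + ("HR",), "Retain single head radar"),
    _cfg(8, ("S1", "S2", "S3", "S4", "HC"), "Side radar removal with central head radar retained"),
    _cfg(9, ("S1", "S2", "S3", "S5", "HC"), "Side radar removal with central head radar retained"),
    _cfg(10, ("S1", "S2", "S4", "S5", "HC"), "Side radar removal with central head radar retained"),
    _cfg(11, ("S1", "S3", "S4", "S5", "HC"), "Side radar removal with central head radar retained"),
    _cfg(12, ("S2", "S3", "S4", "S5", "HC"), "Side radar removal with central head radar retained"),
    _cfg(13, _S, "No head radar"),
    _cfg(14, ("S2", "S4", "HL", "HR"), "2 head and side radars"),
    _cfg(15, ("S1", "S3", "S5", "HC"), "3 side radars with central head radar retained"),
    _cfg(16, ("S3", "S4", "S5", "HC"), "3 side radars with central head radar retained"),
    _cfg(17, ("S2", "S3", "S4", "HC"), "3 side radars with central head radar retained"),
    _cfg(18, ("S1", "S2", "S3", "HC"), "3 side radars with central head radar retained"),
    _cfg(19, ("S1", "S4", "S5", "HC"), "3 side radars with central head radar retained"),
    _cfg(20, ("S1", "S2", "S5", "HC"), "3 side radars with central head radar retained"),
    _cfg(21, ("S2", "S4", "HC"), "Dual side radars with central head radar"),
    _cfg(22, ("S3", "HC"), "Single side radar with central head radar"),
)


def config_registry() -> list:
    """The 22 pre-planned radar configurations, in protocol order."""
    return list(_REGISTRY)


def load_reference_accuracies() -> pd.DataFrame:
    """Published four-class accuracies of the reference backbones per
    configuration; columns: config_id, n_radars, one column per model."""
    with resources.files("radarposture.data").joinpath("reference_accuracies.csv").open() as f:
        return pd.read_csv(f)


def subject_split(subject_ids, train_n: int | None = None, test_n: int | None = None,
                  seed: int = 0):
    """Disjoint train/test partition at the subject level.

    Every sample of a subject falls on one side of the split, preventing
    identity leakage.  When sizes are omitted they follow the 55:15
    proportion of the reference protocol, scaled to the available count.
    """
    subjects = list(dict.fromkeys(subject_ids))  # stable unique
    n = len(subjects)
    if train_n is None and test_n is None:
        train_n = round(n * 55 / 70)
        test_n = n - train_n
    elif train_n is None:
        train_n = n - test_n
    elif test_n is None:
        test_n = n - train_n
    if train_n + test_n > n:
        raise ValueError(f"requested {train_n}+{test_n} subjects but only {n} available")
    if train_n < 1 or test_n < 1:
        raise ValueError("both sides of the split need at least one subject")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = sorted(subjects[i] for i in order[:train_n])
    test = sorted(subjects[i] for i in order[train_n : train_n + test_n])
    return train, test


def run_ablation(x: np.ndarray, y: np.ndarray, subjects, configs,
                 model_spec: ModelSpec | None = None,
                 train_config: TrainConfig | None = None,
                 seed: int = 0, verbose: bool = False) -> list:
    """Retrain and score the classifier under each radar configuration.

    x : (n_samples, 8, H, W) full eight-view stacks in canonical radar
    order; per-configuration inputs are the active-view slices, which is
    equivalent to rebuilding the stacks under the mask because every view
    is normalised independently.  One shared subject split (derived from
    ``seed``) is used for all configurations so that accuracy differences
    reflect the radar masks alone; each configuration retrains from
    scratch with a config-specific seed offset.
    """
    x = np.asarray(x)
    if x.ndim != 4 or x.shape[1] != len(CANONICAL_RADAR_ORDER):
        raise ValueError("x must be (n_samples, 8, H, W) in canonical radar order")
    model_spec = model_spec or ModelSpec()
    train_config = train_config or TrainConfig()
    subjects = np.asarray(subjects)
    train_subj, test_subj = subject_split(subjects, seed=seed)
    tr = np.isin(subjects, train_subj)
    te = np.isin(subjects, test_subj)

    results = []
    for cfg in configs:
        view_idx = [k for k, m in enumerate(cfg.mask) if m]
        spec = ModelSpec(
            backbone=model_spec.backbone, n_views=len(view_idx),
            n_classes=model_spec.n_classes, pooling=model_spec.pooling,
            input_size=model_spec.input_size, head=model_spec.head,
        )
        cfg_seed = int(seed + 1000 * cfg.config_id) % (2**31)
        model = build_model(spec, seed=cfg_seed)
        tcfg = TrainConfig(
            learning_rate=train_config.learning_rate, betas=train_config.betas,
            weight_decay=train_config.weight_decay, epochs=train_config.epochs,
            batch_size=train_config.batch_size, seed=cfg_seed,
        )
        train(model, x[tr][:, view_idx], y[tr], tcfg, verbose=False)
        acc, _ = evaluate(model, x[te][:, view_idx], y[te])
        if verbose:
            print(f"config #{cfg.config_id:2d} ({cfg.n_radars} radars): accuracy {acc:.3f}")
        results.append(
            AblationResult(config_id=cfg.config_id, model=spec.backbone,
                           accuracy=acc, n_radars=cfg.n_radars, seed=cfg_seed)
        )
    return results


def _decimal_mean3(values) -> float:
    """Group mean in exact decimal arithmetic, half-up rounded to 3 decimals.

    Binary floats misround printed 3-decimal accuracies (e.g. the mean of
    0.698, 0.707, 0.698, 0.708, 0.691, 0.707 is exactly 0.7015, but its
    float is 0.70149999..., which would round down); going through Decimal
    reproduces the arithmetic done on the printed numbers.
    """
    vals = [Decimal(repr(float(v))) for v in values]
    mean = sum(vals) / Decimal(len(vals))
    return float(mean.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def aggregate_by_count(results) -> pd.DataFrame:
    """Mean accuracy per (model, radar count), half-up rounded to 3 decimals.

    Accepts either a list of AblationResult or a wide DataFrame with an
    ``n_radars`` column plus one accuracy column per model (the packaged
    reference-accuracy fixture's layout).  Returns a wide table indexed by
    ``n_radars`` in descending order; empty groups are simply absent.
    """
    if isinstance(results, pd.DataFrame):
        if {"model", "accuracy", "n_radars"} <= set(results.columns):
            long = results[["n_radars", "model", "accuracy"]].copy()
        else:
            df = results.drop(
                columns=[c for c in ("config_id", "mask", "seed") if c in results.columns]
            )
            long = df.melt(id_vars="n_radars", var_name="model", value_name="accuracy")
    else:
        long = pd.DataFrame(
            [{"n_radars": r.n_radars, "model": r.model, "accuracy": r.accuracy} for r in results]
        )
    if long.empty:
        raise ValueError("no results to aggregate")
    table = (
        long.groupby(["n_radars", "model"], sort=False)["accuracy"]
        .agg(_decimal_mean3)
        .unstack("model")
        .sort_index(ascending=False)
    )
    # preserve input column order
    table = table[[m for m in long["model"].unique() if m in table.columns]]
    return table
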