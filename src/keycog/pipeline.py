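"""End-to-end orchestration: simulate → extract → score → train → evaluate.

Every stage is independently re-runnable; `run_all` chains them with one
seed policy and writes tidy CSV reports.  Clinical information is only ever
visible to the models as a training target: a registry-based guard refuses
any feature matrix whose columns collide with clinical or subdomain names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .clinical import (
    DEFAULT_MAPPING,
    SUBDOMAINS,
    SubdomainMappingSpec,
    items_from_frame,
    moca_total,
    subdomain_frame,
)
from .evaluation import association_table, confounder_table
from .features import feature_frame
from .modeling import ModelSpec, assign_folds, cross_validate
from .synthetic import SyntheticConfig, generate_study

log = logging.getLogger("keycog")


class TargetLeakageError(ValueError):
    """A clinical/subdomain column appeared in the feature matrix."""


def leakage_guard(feature_columns: Sequence[str], mapping: SubdomainMappingSpec) -> None:
    """Refuse feature matrices containing any registered target name."""
    registry = set(SUBDOMAINS) | {"moca_total"}
    registry |= {f"{it.scale}—{it.item}" for it in mapping.items}
    registry |= {it.item for it in mapping.items}
    bad = sorted(set(feature_columns) & registry)
    if bad:
        raise TargetLeakageError(
            f"clinical/subdomain columns present in the feature matrix: {bad}"
        )


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mapping: str = "default"
    repetitions: int = 10
    k: int = 3
    seed: int = 0
    variants: tuple[str, ...] = ("independent", "joint", "single")


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the report directory.

    Outputs: the simulated study files, ``features.csv``,
    ``subdomains.csv``, per-variant prediction tables, association tables,
    and the confounder report for the independently optimized variant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mapping = DEFAULT_MAPPING if config.mapping == "default" else None
    if mapping is None:
        from .clinical import load_mapping

        mapping = load_mapping(config.mapping)

    log.info("keycog %s | seed=%d reps=%d k=%d", __version__, config.seed,
             config.repetitions, config.k)

    log.info("stage: simulate")
    subjects, sessions, clinical = generate_study(config.synthetic, out, mapping)

    log.info("stage: extract")
    features = feature_frame(sessions)
    leakage_guard(features.columns, mapping)
    features.to_csv(out / "features.csv")

    log.info("stage: score")
    items_by_subject = items_from_frame(clinical)
    subdomains = subdomain_frame(items_by_subject, mapping)
    moca = pd.Series(
        {sid: moca_total(items) for sid, items in items_by_subject.items()},
        name="moca_total",
    )
    targets = subdomains.join(moca)
    targets = targets.reindex(features.index)
    targets.to_csv(out / "subdomains.csv")

    demographics = pd.DataFrame(
        {
            "age": {s.subject_id: s.age for s in subjects},
            "sex": {s.subject_id: s.sex for s in subjects},
            "group": {s.subject_id: s.group for s in subjects},
        }
    )
    demographics.index.name = "subject_id"

    log.info("stage: train+evaluate")
    folds = assign_folds(
        list(features.index), repetitions=config.repetitions, k=config.k,
        seed=config.seed,
    )
    for variant in config.variants:
        if variant == "single":
            spec = ModelSpec(variant="single", targets=("moca_total",))
        else:
            spec = ModelSpec(variant=variant, targets=tuple(SUBDOMAINS))
        cv = cross_validate(features, targets, spec, folds, base_seed=config.seed)
        cv.predictions.to_csv(out / f"predictions_{variant}.csv", index=False)
        agg = cv.aggregated()
        agg.to_csv(out / f"predictions_{variant}_aggregated.csv")
        assoc = association_table(agg, targets)
        assoc.to_csv(out / f"associations_{variant}.csv", index=False)
        if variant == "independent":
            conf = confounder_table(agg, targets, demographics)
            conf.to_csv(out / "confounders_independent.csv", index=False)
        log.info("variant %s: %d targets evaluated", variant, len(assoc))
    return out
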