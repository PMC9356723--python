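"""Clinical outcomes: normalized subdomain scores from multi-scale items.

Standard neuropsychological instruments (MoCA, DRS-2, FAB, ADLQ) report
heterogeneous items with different ranges and directionalities.  This module
converts each item to a common impairment scale in [0, 1] (0 = no
impairment, 1 = maximal impairment),

    norm(x_i) = x_i / max(x_i)        for items where higher is worse,
    norm(x_i) = 1 - x_i / max(x_i)    for items where higher is better,

and aggregates items into nine cognitive subdomains by averaging the
normalized values of the items mapped to each subdomain over the M valid
(non-missing) contributing items:

    norm(S) = sum_i norm(x_i) / M .

The default mapping ships with the package; custom mappings are loaded from
YAML/JSON and validated against the canonical subdomain names.  MoCA items
enter in the grouped-section format (seven section scores summing to 30).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

SCALES = ("MoCA", "DRS2", "FAB", "ADLQ")

#: the nine canonical cognitive subdomains
SUBDOMAINS = (
    "verbal_memory",
    "non_verbal_memory",
    "visual_motor_ability",
    "language_verbal_skills",
    "executive_function",
    "perception",
    "attention_concentration",
    "visuospatial_function",
    "mental_tracking_monitoring",
)

#: the seven MoCA grouped sections and their standard maxima (sum = 30)
MOCA_SECTIONS = {
    "Visuospatial/Executive": 5,
    "Naming": 3,
    "Attention": 6,
    "Language": 3,
    "Abstraction": 2,
    "Memory": 5,
    "Orientation": 6,
}


class MappingSchemaError(ValueError):
    """A subdomain-mapping file violates the documented schema."""


class MissingValueError(ValueError):
    """A required value is missing."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleItemValue:
    """One scored clinical item: raw value, maximum, directionality."""

    scale: str
    item: str
    raw: float
    max: float
    direction: str  # "higher_worse" | "higher_better"
    missing: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.scale, self.item)


@dataclass(frozen=True)
class ItemDef:
    """Catalogue entry: maximum, directionality and mapped subdomains."""

    scale: str
    item: str
    max: float
    direction: str
    subdomains: tuple[str, ...]


@dataclass(frozen=True)
class SubdomainMappingSpec:
    """(scale, item) -> subdomain set, with per-item max/direction defaults."""

    items: tuple[ItemDef, ...]

    def __post_init__(self) -> None:
        for it in self.items:
            if not it.subdomains:
                raise MappingSchemaError(
                    f"item {it.scale}—{it.item} maps to an empty subdomain set"
                )
            for sd in it.subdomains:
                if sd not in SUBDOMAINS:
                    raise MappingSchemaError(
                        f"item {it.scale}—{it.item} maps to non-canonical "
                        f"subdomain {sd!r}"
                    )
            if it.direction not in ("higher_worse", "higher_better"):
                raise MappingSchemaError(
                    f"item {it.scale}—{it.item}: bad direction {it.direction!r}"
                )
            if it.max <= 0:
                raise MappingSchemaError(
                    f"item {it.scale}—{it.item}: max must be > 0"
                )

    def lookup(self, scale: str, item: str) -> ItemDef | None:
        for it in self.items:
            if it.scale == scale and it.item == item:
                return it
        return None

    def items_for(self, subdomain: str) -> list[ItemDef]:
        if subdomain not in SUBDOMAINS:
            raise ConfigurationError(f"unknown subdomain {subdomain!r}")
        return [it for it in self.items if subdomain in it.subdomains]


def _moca(item: str, subdomains: Sequence[str]) -> ItemDef:
    return ItemDef("MoCA", item, MOCA_SECTIONS[item], "higher_better", tuple(subdomains))


# Default mapping: nine subdomains fed by MoCA grouped sections, DRS-2
# subscales (standard maxima 37/37/6/39/25, higher = better), FAB items
# (max 3 each, higher = better) and the ADLQ self-care subscale (0-3,
# higher = worse).  This is the package's documented approximation of the
# instrument-level mapping; per-item overrides load from YAML.
_DEFAULT_ITEMS: tuple[ItemDef, ...] = (
    _moca("Visuospatial/Executive", ("executive_function", "visuospatial_function")),
    _moca("Naming", ("language_verbal_skills",)),
    _moca(
        "Attention",
        (
            "verbal_memory",
            "non_verbal_memory",
            "attention_concentration",
            "mental_tracking_monitoring",
        ),
    ),
    _moca("Language", ("language_verbal_skills", "executive_function")),
    _moca("Abstraction", ("executive_function",)),
    _moca("Memory", ("verbal_memory", "non_verbal_memory")),
    _moca("Orientation", ("non_verbal_memory", "visuospatial_function")),
    ItemDef("DRS2", "Attention", 37, "higher_better", ("attention_concentration",)),
    ItemDef("DRS2", "Initiation/Perseveration", 37, "higher_better", ("executive_function",)),
    ItemDef("DRS2", "Construction", 6, "higher_better", ("executive_function",)),
    ItemDef("DRS2", "Conceptualization", 39, "higher_better", ("executive_function", "perception")),
    ItemDef("DRS2", "Memory", 25, "higher_better", ("verbal_memory", "non_verbal_memory")),
    ItemDef(
        "FAB", "Lexical Fluency", 3, "higher_better",
        ("verbal_memory", "non_verbal_memory", "language_verbal_skills"),
    ),
    ItemDef("FAB", "Similarities", 3, "higher_better", ("executive_function",)),
    ItemDef(
        "FAB", "Motor Series", 3, "higher_better",
        ("visual_motor_ability", "executive_function"),
    ),
    ItemDef(
        "FAB", "Conflicting Instructions", 3, "higher_better",
        ("visual_motor_ability", "executive_function", "attention_concentration"),
    ),
    ItemDef(
        "FAB", "Go-No-Go", 3, "higher_better",
        ("visual_motor_ability", "executive_function", "attention_concentration"),
    ),
    ItemDef(
        "FAB", "Prehension Behaviour", 3, "higher_better",
        ("executive_function", "perception"),
    ),
    ItemDef("ADLQ", "Self-Care", 3, "higher_worse", ("executive_function",)),
)

DEFAULT_MAPPING = SubdomainMappingSpec(items=_DEFAULT_ITEMS)


@dataclass(frozen=True)
class SubdomainScores:
    """Per-subdomain normalized score (NaN when unreportable) and the count
    M of valid contributing items."""

    scores: Mapping[str, float]
    counts: Mapping[str, int]

    def __getitem__(self, subdomain: str) -> float:
        return self.scores[subdomain]


def normalize_item(item: ScaleItemValue) -> float:
    """Map a raw item value to the common [0, 1] impairment scale."""
    if item.missing:
        raise MissingValueError(f"item {item.scale}—{item.item} is missing")
    if item.max <= 0:
        raise ConfigurationError(f"item {item.scale}—{item.item}: max must be > 0")
    frac = item.raw / item.max
    if item.direction == "higher_worse":
        out = frac
    elif item.direction == "higher_better":
        out = 1.0 - frac
    else:
        raise ConfigurationError(f"bad direction {item.direction!r}")
    if not 0.0 <= out <= 1.0:
        raise ConfigurationError(
            f"item {item.scale}—{item.item}: raw {item.raw} outside [0, {item.max}]"
        )
    return out


def subdomain_score(
    items: Sequence[ScaleItemValue],
    mapping: SubdomainMappingSpec,
    subdomain: str,
    min_items: int = 1,
) -> tuple[float, int]:
    """Mean normalized value of the valid items mapped to ``subdomain``.

    Returns ``(score, M)``; score is NaN when fewer than ``min_items`` valid
    items contribute.
    """
    if subdomain not in SUBDOMAINS:
        raise ConfigurationError(f"unknown subdomain {subdomain!r}")
    mapped_keys = {(it.scale, it.item) for it in mapping.items_for(subdomain)}
    vals = [normalize_item(it) for it in items if it.key in mapped_keys and not it.missing]
    m = len(vals)
    if m < min_items:
        return (math.nan, m)
    # fsum: exactly rounded, so the score is invariant to item order
    return (math.fsum(vals) / m, m)


def score_subject(
    items: Sequence[ScaleItemValue],
    mapping: SubdomainMappingSpec = DEFAULT_MAPPING,
    min_items: int = 1,
) -> SubdomainScores:
    """Compute all nine subdomain scores for one subject's item set.

    Items absent from the mapping are ignored with a warning.
    """
    known = {(it.scale, it.item) for it in mapping.items}
    for it in items:
        if it.key not in known:
            warnings.warn(
                f"item {it.scale}—{it.item} is not in the subdomain mapping; ignored",
                stacklevel=2,
            )
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sd in SUBDOMAINS:
        s, m = subdomain_score(items, mapping, sd, min_items=min_items)
        scores[sd] = s
        counts[sd] = m
    return SubdomainScores(scores=scores, counts=counts)


def moca_total(
    items: Sequence[ScaleItemValue], allow_partial: bool = False
) -> float:
    """MoCA total: sum of the seven grouped section raw scores (higher =
    better, maximum 30).  Missing any section yields NaN unless
    ``allow_partial``, in which case the partial sum is returned with a
    warning."""
    by_name = {
        it.item: it for it in items if it.scale == "MoCA" and not it.missing
    }
    present = [name for name in MOCA_SECTIONS if name in by_name]
    if len(present) < len(MOCA_SECTIONS) and not allow_partial:
        return math.nan
    if len(present) < len(MOCA_SECTIONS):
        warnings.warn(
            f"MoCA total computed from {len(present)}/{len(MOCA_SECTIONS)} sections",
            stacklevel=2,
        )
    if not present:
        return math.nan
    return float(sum(by_name[name].raw for name in present))


def load_mapping(source: str | Path = "default") -> SubdomainMappingSpec:
    """Load a subdomain mapping: ``"default"`` or a YAML/JSON file path.

    File schema::

        scales:
          MoCA:
            Memory: {max: 5, direction: higher_better,
                     subdomains: [verbal_memory, non_verbal_memory]}
    """
    if source == "default":
        return DEFAULT_MAPPING
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "scales" not in doc:
        raise MappingSchemaError("mapping file must contain a top-level 'scales' map")
    items: list[ItemDef] = []
    for scale, entries in doc["scales"].items():
        if not isinstance(entries, dict):
            raise MappingSchemaError(f"scale {scale!r}: expected item map")
        for item, spec in entries.items():
            try:
                items.append(
                    ItemDef(
                        scale=scale,
                        item=item,
                        max=float(spec["max"]),
                        direction=str(spec["direction"]),
                        subdomains=tuple(spec["subdomains"]),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise MappingSchemaError(
                    f"item {scale}—{item}: malformed entry ({exc})"
                ) from exc
    return SubdomainMappingSpec(items=tuple(items))


def items_from_frame(frame) -> dict[str, list[ScaleItemValue]]:
    """Convert a tidy clinical table (subject_id, scale, item, raw, max,
    direction, missing) into per-subject item lists."""
    out: dict[str, list[ScaleItemValue]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            ScaleItemValue(
                scale=row.scale,
                item=row.item,
                raw=float(row.raw) if not bool(row.missing) else math.nan,
                max=float(row.max),
                direction=row.direction,
                missing=bool(row.missing),
            )
        )
    return out


def subdomain_frame(
    items_by_subject: Mapping[str, Sequence[ScaleItemValue]],
    mapping: SubdomainMappingSpec = DEFAULT_MAPPING,
    min_items: int = 1,
):
    """Score every subject; returns a subjects × subdomains DataFrame."""
    import pandas as pd

    rows = {}
    for sid, items in items_by_subject.items():
        sc = score_subject(items, mapping, min_items=min_items)
        rows[sid] = dict(sc.scores)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUBDOMAINS))
    frame.index.name = "subject_id"
    return frame
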