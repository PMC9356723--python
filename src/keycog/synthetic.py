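"""Synthetic cohort with latent subdomain impairment driving typing and items.

The generator emulates the study design the pipeline is built for: a
two-group cohort (impaired / normal) in which each subject carries a latent
impairment value θ_d ∈ [0, 1] for each of the nine cognitive subdomains.
θ is built from a global severity g (drawn per group, truncated to [0, 1])
plus per-subdomain loadings and independent noise, which reproduces the
positive correlation among subdomains that motivates joint multi-output
modelling.  The same θ drives both observable layers:

* **clinical items** — each item's expected normalized impairment is the
  mean θ over its mapped subdomains, mixed with uniform noise at weight
  (1 − item_reliability), and realized as a binomial draw over the item's
  integer range, stored in the item's natural orientation;
* **typing sessions** — log-normal hold and flight times, a pause mixture,
  word structure as categorical key-type runs, backspaces, and (on
  touchscreens) Gaussian tap offsets and Poisson assisted-typing events,
  with each parameter shifted by an effect matrix applied to θ.

Randomness is split into child streams per subject and per (subject, task),
so adding a subject never perturbs another subject's draws, and every
output is byte-identical under a fixed config and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import sessions as sio
from .clinical import DEFAULT_MAPPING, SUBDOMAINS, ScaleItemValue, SubdomainMappingSpec
from .sessions import AssistedEvent, KeyEvent, SessionContext, TypingSession

GROUPS = ("impaired", "normal")


class SyntheticConfigError(ValueError):
    pass


def _clip01(x):
    return float(np.clip(x, 0.0, 1.0))


@dataclass(frozen=True)
class TypingEffect:
    """Per-subdomain shifts of typing parameters at θ = 1.

    Fractional fields multiply the base parameter by (1 + value·θ);
    probability/rate fields add value·θ to the base; word_len_decrement
    subtracts value·θ characters from the mean word length.
    """

    hold_mean_frac: float = 0.0
    flight_mean_frac: float = 0.0
    flight_sd_frac: float = 0.0
    pause_prob: float = 0.0
    backspace_prob: float = 0.0
    word_len_decrement: float = 0.0
    tap_offset_frac: float = 0.0
    autocorrect_per100: float = 0.0


ZERO_EFFECT = TypingEffect()

#: default calibration: strong effects planted on verbal memory (global
#: slowing) and executive function (error correction and timing
#: variability), the subdomains the pipeline is expected to recover.
DEFAULT_EFFECTS: dict[str, TypingEffect] = {
    "verbal_memory": TypingEffect(
        hold_mean_frac=0.35, flight_mean_frac=0.50, pause_prob=0.15
    ),
    "executive_function": TypingEffect(
        flight_sd_frac=0.60,
        backspace_prob=0.10,
        word_len_decrement=1.5,
        tap_offset_frac=0.50,
        autocorrect_per100=2.0,
    ),
}


@dataclass(frozen=True)
class TaskParams:
    """Baseline (θ = 0) typing parameters for one task."""

    n_events: int
    hold_mean_ms: float = 95.0
    hold_cv: float = 0.35  # coefficient of variation of the log-normal
    flight_mean_ms: float = 240.0
    flight_cv: float = 0.55
    pause_prob: float = 0.05
    pause_mean_ms: float = 1600.0
    pause_cv: float = 0.45
    rollover_prob: float = 0.06
    backspace_prob: float = 0.03
    word_len_mean: float = 4.5
    punct_prob: float = 0.12
    enter_prob: float = 0.02
    tap_sigma: float = 0.18  # key widths, touchscreen only
    autocorrect_per100: float = 1.0
    suggestion_per100: float = 0.5


#: copy tasks run longer than free description / conversation
DEFAULT_TASK_PARAMS: dict[str, TaskParams] = {
    "mec_copy": TaskParams(n_events=420),
    "mec_des": TaskParams(n_events=260),
    "tch_copy": TaskParams(n_events=340, flight_mean_ms=320.0),
    "tch_conv": TaskParams(n_events=160, flight_mean_ms=320.0),
}

#: demographic baselines per group: age mean/sd, education mean/sd,
#: probability of male sex (matched, null-by-construction confounders)
DEFAULT_DEMOGRAPHICS = {
    "impaired": {"age": (73.6, 6.4), "education": (16.8, 2.7), "p_male": 23 / 38},
    "normal": {"age": (71.1, 7.3), "education": (16.4, 2.1), "p_male": 20 / 39},
}


@dataclass(frozen=True)
class Subject:
    subject_id: str
    age: float
    sex: str  # "male" | "female"
    education_years: float
    group: str  # "impaired" | "normal"
    latent_impairment: Mapping[str, float] = field(default_factory=dict)

    def theta(self, subdomain: str) -> float:
        return self.latent_impairment[subdomain]


@dataclass(frozen=True)
class SyntheticConfig:
    n_impaired: int = 38
    n_normal: int = 39
    global_severity_means: Mapping[str, float] = field(
        default_factory=lambda: {"impaired": 0.55, "normal": 0.15}
    )
    global_severity_sd: float = 0.12
    subdomain_loading: Mapping[str, float] = field(
        default_factory=lambda: {sd: 1.0 for sd in SUBDOMAINS}
    )
    subdomain_noise_sd: float = 0.08
    effect_matrix: Mapping[str, TypingEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    item_reliability: float = 0.9
    missing_item_rate: float = 0.03
    missing_task_rate: float = 0.03
    seed: int = 0
    task_params: Mapping[str, TaskParams] = field(
        default_factory=lambda: dict(DEFAULT_TASK_PARAMS)
    )
    demographics: Mapping[str, Mapping] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()}
    )

    def validate(self) -> None:
        if self.n_impaired < 0 or self.n_normal < 0:
            raise SyntheticConfigError("subject counts must be ≥ 0")
        for name, p in (
            ("item_reliability", self.item_reliability),
            ("missing_item_rate", self.missing_item_rate),
            ("missing_task_rate", self.missing_task_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {p}")
        for g in GROUPS:
            if g not in self.global_severity_means:
                raise SyntheticConfigError(f"global_severity_means missing group {g!r}")
        for sd in self.effect_matrix:
            if sd not in SUBDOMAINS:
                raise SyntheticConfigError(f"effect_matrix: unknown subdomain {sd!r}")


def null_config(**overrides) -> SyntheticConfig:
    """Study conditions with no typing–cognition pathway (effects all zero)."""
    return SyntheticConfig(effect_matrix={}, **overrides)


def independent_subdomain_config(
    n: int = 200, seed: int = 0, **overrides
) -> SyntheticConfig:
    """Scenario with near-independent subdomains: a single group at fixed
    global severity 0.5 with wide per-subdomain noise, so the latent values
    θ_d are mutually independent.  Used for planted-signal experiments where
    effects on targeted subdomains must not leak into untargeted ones."""
    return SyntheticConfig(
        n_impaired=n // 2,
        n_normal=n - n // 2,
        global_severity_means={"impaired": 0.5, "normal": 0.5},
        global_severity_sd=0.0,
        subdomain_noise_sd=0.25,
        missing_item_rate=0.0,
        missing_task_rate=0.0,
        seed=seed,
        **overrides,
    )


def _child_rng(*keys) -> np.random.Generator:
    """Deterministic child stream keyed by ints/strings (strings via CRC32)."""
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    )
    return np.random.default_rng(np.random.SeedSequence(ints))


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return _clip01(mean) if (lo, hi) == (0.0, 1.0) else float(np.clip(mean, lo, hi))
    for _ in range(64):  # rejection; falls back to clipping
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def generate_cohort(config: SyntheticConfig) -> list[Subject]:
    """Draw the cohort: group labels, demographics, and latent θ per
    subdomain (θ_d = clip(g · loading_d + noise_d))."""
    config.validate()
    subjects: list[Subject] = []
    n_total = config.n_impaired + config.n_normal
    for i in range(n_total):
        group = "impaired" if i < config.n_impaired else "normal"
        rng = _child_rng(config.seed, "subject", i)
        demo = config.demographics[group]
        g = _truncated_normal(
            rng, config.global_severity_means[group], config.global_severity_sd, 0.0, 1.0
        )
        theta = {
            sd: _clip01(
                g * config.subdomain_loading.get(sd, 1.0)
                + (rng.normal(0.0, config.subdomain_noise_sd)
                   if config.subdomain_noise_sd > 0 else 0.0)
            )
            for sd in SUBDOMAINS
        }
        subjects.append(
            Subject(
                subject_id=f"S{i:03d}",
                age=float(rng.normal(*demo["age"])),
                sex="male" if rng.random() < demo["p_male"] else "female",
                education_years=float(rng.normal(*demo["education"])),
                group=group,
                latent_impairment=theta,
            )
        )
    return subjects


def simulate_scale_items(
    subject: Subject,
    mapping: SubdomainMappingSpec = DEFAULT_MAPPING,
    config: SyntheticConfig = SyntheticConfig(),
) -> list[ScaleItemValue]:
    """Draw one subject's clinical items from θ.

    Expected normalized impairment of an item is the mean θ of its mapped
    subdomains; a uniform noise component at weight (1 − item_reliability)
    models imperfect items; the raw score is Binomial(max, ·) stored in the
    item's natural orientation; items go missing at missing_item_rate.
    """
    rng = _child_rng(config.seed, "items", subject.subject_id)
    out: list[ScaleItemValue] = []
    for it in mapping.items:
        if it.max <= 0:
            raise SyntheticConfigError(f"item {it.scale}—{it.item}: max ≤ 0")
        p = float(np.mean([subject.theta(sd) for sd in it.subdomains]))
        u = rng.uniform()
        p_eff = _clip01(config.item_reliability * p + (1 - config.item_reliability) * u)
        impairment = int(rng.binomial(int(round(it.max)), p_eff))
        raw = impairment if it.direction == "higher_worse" else int(round(it.max)) - impairment
        missing = bool(rng.random() < config.missing_item_rate)
        out.append(
            ScaleItemValue(
                scale=it.scale,
                item=it.item,
                raw=float(raw),
                max=float(it.max),
                direction=it.direction,
                missing=missing,
            )
        )
    return out


def _effective_params(
    base: TaskParams, theta: Mapping[str, float], effects: Mapping[str, TypingEffect]
) -> TaskParams:
    """Apply the effect matrix at the subject's θ to baseline parameters."""
    def tot(attr: str) -> float:
        return sum(getattr(eff, attr) * theta[sd] for sd, eff in effects.items())

    return replace(
        base,
        hold_mean_ms=base.hold_mean_ms * (1 + tot("hold_mean_frac")),
        flight_mean_ms=base.flight_mean_ms * (1 + tot("flight_mean_frac")),
        flight_cv=base.flight_cv * (1 + tot("flight_sd_frac")),
        pause_prob=_clip01(base.pause_prob + tot("pause_prob")),
        backspace_prob=_clip01(base.backspace_prob + tot("backspace_prob")),
        word_len_mean=max(1.5, base.word_len_mean - tot("word_len_decrement")),
        tap_sigma=base.tap_sigma * (1 + tot("tap_offset_frac")),
        autocorrect_per100=max(0.0, base.autocorrect_per100 + tot("autocorrect_per100")),
    )


def _lognormal(rng, mean, cv, size=None):
    """Log-normal samples with the requested arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_session(
    subject: Subject,
    task_id: str,
    config: SyntheticConfig = SyntheticConfig(),
) -> TypingSession:
    """Simulate one task session for one subject; deterministic given
    (config.seed, subject_id, task_id) and always validates cleanly."""
    if task_id not in sio.TASKS:
        raise SyntheticConfigError(f"unknown task {task_id!r}")
    device = sio.TASKS[task_id]
    touch = device == "touchscreen"
    rng = _child_rng(config.seed, "session", subject.subject_id, task_id)
    base = config.task_params[task_id]
    par = _effective_params(base, subject.latent_impairment, config.effect_matrix)

    # key-type stream: words of geometric length, space/punct/enter
    # delimiters, backspaces sprinkled per keystroke
    key_types: list[str] = []
    p_word = 1.0 / max(par.word_len_mean, 1.0)
    while len(key_types) < par.n_events:
        wlen = int(rng.geometric(p_word))
        for _ in range(wlen):
            key_types.append("alphanumeric")
            if rng.random() < par.backspace_prob:
                key_types.append("backspace")
                key_types.append("alphanumeric")  # retype the corrected key
        r = rng.random()
        if r < par.enter_prob:
            key_types.append("enter")
        elif r < par.enter_prob + par.punct_prob:
            key_types.append("punctuation")
            key_types.append("space")
        else:
            key_types.append("space")
    key_types = key_types[: par.n_events]

    n = len(key_types)
    holds = _lognormal(rng, par.hold_mean_ms, par.hold_cv, n)
    flights = _lognormal(rng, par.flight_mean_ms, par.flight_cv, n - 1) if n > 1 else np.array([])
    if n > 1:
        pauses = rng.random(n - 1) < par.pause_prob
        flights[pauses] = _lognormal(rng, par.pause_mean_ms, par.pause_cv, int(pauses.sum()))
        roll = (rng.random(n - 1) < par.rollover_prob) & ~pauses
        # rollover: next press before previous release, bounded so press
        # times stay non-decreasing
        overlap = np.abs(rng.normal(30.0, 10.0, int(roll.sum())))
        flights[roll] = -np.minimum(overlap, 0.9 * holds[:-1][roll])

    events: list[KeyEvent] = []
    t = 0.0
    for k in range(n):
        press = t
        release = press + float(holds[k])
        offset = None
        if touch:
            offset = (
                float(rng.normal(0.0, par.tap_sigma)),
                float(rng.normal(0.0, par.tap_sigma)),
            )
        events.append(
            KeyEvent(
                press_time=round(press, 3),
                release_time=round(release, 3),
                zone=int(rng.integers(0, 9)),
                key_type=key_types[k],
                tap_offset=offset,
            )
        )
        if k < n - 1:
            t = release + float(flights[k])

    assisted: list[AssistedEvent] = []
    if touch and n:
        span = events[-1].release_time
        for kind, rate in (
            ("autocorrect", par.autocorrect_per100),
            ("word_suggestion", par.suggestion_per100),
        ):
            count = int(rng.poisson(rate * n / 100.0))
            for _ in range(count):
                assisted.append(
                    AssistedEvent(
                        event_time=round(float(rng.uniform(0, span)), 3),
                        kind=kind,
                        position=int(rng.integers(0, n)),
                    )
                )
        assisted.sort(key=lambda a: a.event_time)

    return TypingSession(
        session_id=f"{subject.subject_id}-{task_id}",
        subject_id=subject.subject_id,
        task_id=task_id,
        device=device,
        events=tuple(events),
        assisted_events=tuple(assisted),
        context=SessionContext(
            start_time="2021-01-01T00:00:00Z",
            app="keycog-simulator",
            device_descriptor=device,
        ),
    )


def generate_study(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
    mapping: SubdomainMappingSpec = DEFAULT_MAPPING,
) -> tuple[list[Subject], list[TypingSession], pd.DataFrame]:
    """Generate the full study: cohort, up to four task sessions per
    subject (task-level missingness applies), and the tidy clinical table.

    When ``out_dir`` is given, writes ``sessions.jsonl``, ``clinical.csv``
    and ``cohort.csv`` there (byte-identical under a fixed config)."""
    config.validate()
    subjects = generate_cohort(config)
    all_sessions: list[TypingSession] = []
    clin_rows: list[dict] = []
    for subj in subjects:
        for task_id in sio.TASKS:
            miss_rng = _child_rng(config.seed, "taskmiss", subj.subject_id, task_id)
            if miss_rng.random() < config.missing_task_rate:
                continue
            all_sessions.append(simulate_session(subj, task_id, config))
        for item in simulate_scale_items(subj, mapping, config):
            clin_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "scale": item.scale,
                    "item": item.item,
                    "raw": item.raw,
                    "max": item.max,
                    "direction": item.direction,
                    "missing": item.missing,
                }
            )
    clinical = pd.DataFrame(
        clin_rows,
        columns=["subject_id", "scale", "item", "raw", "max", "direction", "missing"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_sessions(all_sessions, out / "sessions.jsonl")
        clinical.to_csv(out / "clinical.csv", index=False)
        cohort = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "age": round(s.age, 3),
                    "sex": s.sex,
                    "education_years": round(s.education_years, 3),
                    "group": s.group,
                    **{f"theta.{sd}": round(s.latent_impairment[sd], 6) for sd in SUBDOMAINS},
                }
                for s in subjects
            ]
        )
        cohort.to_csv(out / "cohort.csv", index=False)
    return subjects, all_sessions, clinical


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML file mirroring its field names."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "effect_matrix" in doc:
        doc["effect_matrix"] = {
            sd: TypingEffect(**eff) for sd, eff in doc["effect_matrix"].items()
        }
    if "task_params" in doc:
        doc["task_params"] = {
            t: TaskParams(**p) for t, p in doc["task_params"].items()
        }
    try:
        cfg = SyntheticConfig(**doc)
    except TypeError as exc:
        raise SyntheticConfigError(str(exc)) from exc
    cfg.validate()
    return cfg
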