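"""Synthetic cohorts of immunocompromised children evaluated for infection.

The generator emits episode tables with the statistical structure the
downstream analysis assumes: a 400-episode cohort over 293 subjects (83
enrolled more than once, samples spaced >= 24 h), 15% clinical
deterioration, 5.25% (21/400) 28-day mortality, 15.25% (61/400) ICU
location at evaluation, 37% confirmed bacterial infection, age with median
7.8 y (IQR ~3.1-13.8), platelets with median ~80 K/mcL, and right-skewed
log-normal biomarker concentrations.

Outcomes are generated through a conditional chain — location, then
deterioration given location, then 28-day death and infection given
deterioration — with the conditional anchors chosen so the marginal
prevalences equal the configured targets while reproducing the strong
location/outcome and deterioration/mortality associations of the emulated
population (52% of ICU episodes deteriorate vs ~8% on the wards; 20%
mortality after deterioration vs ~3% without).

Two modes:

``marginal``
    Outcomes drawn from the chain above; biomarkers in the deterioration
    stratum are shifted on the log scale (IL-8 and CCL3 up, MMP-8 mildly
    up, HSPA1B mildly down — directions only; magnitudes are simulation
    conventions, not estimates).

``tree``
    Biomarkers drawn first from the baseline distributions; each episode's
    probability of the truth tree's outcome equals its terminal-node event
    rate, so tree-recovery experiments have an embedded ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import yaml

from .cohort import (
    BIOMARKERS,
    BiomarkerPanel,
    Cohort,
    DeteriorationEvents,
    Episode,
    FLUID_ABSOLUTE_ML,
    FLUID_ML_PER_KG,
    FLUID_WEIGHT_CUT_KG,
    ImmunoCriteria,
    meets_deterioration,
    meets_immunocompromised,
)
from .risk_tree import TreeSpec, load_tree

STUDY_START = datetime(2016, 7, 1)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class MarkerDistribution:
    """Log-normal biomarker distribution with an event-stratum offset.

    ``log_median`` is the natural log of the median concentration (pg/mL)
    in the stable stratum; ``event_shift`` is added to it for episodes with
    clinical deterioration (marginal mode only).
    """

    log_median: float
    log_sd: float
    event_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ConfigError("log_sd must be > 0")


def _default_markers() -> dict[str, MarkerDistribution]:
    # Medians are order-of-magnitude choices for serum concentrations in
    # pg/mL; shifts follow the observed directions (IL-8/CCL3 up with
    # deterioration, HSPA1B down, MMP-8 mildly up, GZMB neutral).
    return {
        "il8": MarkerDistribution(math.log(250.0), 1.5, +1.0),
        "ccl3": MarkerDistribution(math.log(30.0), 1.2, +1.0),
        "hspa1b": MarkerDistribution(math.log(2000.0), 1.3, -0.3),
        "gzmb": MarkerDistribution(math.log(20.0), 1.2, 0.0),
        "mmp8": MarkerDistribution(math.log(3000.0), 1.4, +0.5),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.

    Defaults are calibrated to the emulated 400-episode cohort; see module
    docstring.  ``age_log_median``/``age_log_sd`` parameterize a log-normal
    with median 7.8 y whose quartile spread approximates the 3.1-13.8 IQR;
    likewise platelets (median 80, IQR ~33-190 K/mcL).
    """

    n_episodes: int = 400
    n_subjects: int = 293
    n_repeat_subjects: int = 83
    p_deterioration: float = 0.15
    p_death28: float = 21 / 400
    p_icu: float = 61 / 400
    p_infected: float = 0.37
    # conditional anchors of the outcome chain
    p_det_given_icu: float = 0.52
    p_death28_given_det: float = 0.20
    p_infected_given_det: float = 0.62
    p_death72_given_det_death: float = 0.05
    # demographics
    age_log_median: float = math.log(7.8)
    age_log_sd: float = 1.107
    age_max_years: float = 38.0
    platelet_log_median: float = math.log(80.0)
    platelet_log_sd: float = 1.297
    p_female: float = 0.46
    p_neutropenic: float = 0.48
    marker_distributions: dict[str, MarkerDistribution] = field(
        default_factory=_default_markers
    )
    mode: str = "marginal"  # "marginal" | "tree"
    truth_tree: Optional[TreeSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_deterioration", "p_death28", "p_icu", "p_infected",
            "p_det_given_icu", "p_death28_given_det", "p_infected_given_det",
            "p_death72_given_det_death", "p_female", "p_neutropenic",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_episodes <= 0:
            raise ConfigError("n_episodes must be >= 1")
        if not (1 <= self.n_subjects <= self.n_episodes):
            raise ConfigError("need 1 <= n_subjects <= n_episodes")
        if self.mode not in ("marginal", "tree"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "tree" and self.truth_tree is None:
            raise ConfigError("tree mode requires a truth_tree")
        missing = [m for m in BIOMARKERS if m not in self.marker_distributions]
        if missing:
            raise ConfigError(f"marker_distributions missing {missing}")


def default_paper_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated defaults emulating the 400-episode study cohort."""
    return GeneratorConfig(seed=seed)


def _conditional(p_marginal: float, p_given_pos: float, p_pos: float, what: str) -> float:
    """Solve P(A | not B) so that the marginal P(A) is exact given P(A | B)."""
    if p_pos >= 1.0:
        return p_given_pos
    p = (p_marginal - p_pos * p_given_pos) / (1.0 - p_pos)
    if not (0.0 <= p <= 1.0):
        raise ConfigError(
            f"{what}: conditional anchor incompatible with marginal "
            f"(solved complement {p:.4g} outside [0, 1])"
        )
    return p


def _descend_rate(tree: TreeSpec, values: dict[str, float]) -> float:
    node = tree.root
    while not node.is_terminal:
        v = values[node.split.variable]
        nxt = node.children[0] if v <= node.split.threshold else node.children[1]
        node = tree.nodes[nxt]
    return node.event_rate


def _weight_from_age(age_years: float, rng: np.random.Generator) -> float:
    # crude pediatric growth curve: ~3.5 kg at birth, ~+2.3 kg/y to
    # adolescence, plateauing around adult weight; 10% log-normal noise
    base = 3.5 + 2.3 * min(age_years, 18.0) + 0.4 * max(0.0, age_years - 18.0)
    w = base * float(rng.lognormal(0.0, 0.1))
    return float(np.clip(w, 2.0, 130.0))


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a synthetic cohort; identical config and seed reproduce the
    cohort bit-for-bit.

    Every emitted episode satisfies the immunocompromise eligibility
    predicate, the event flags are consistent with the deterioration label
    under the composite outcome definition, and ``death_72h`` implies
    ``death_28d``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("structure", "demographics", "outcomes", "markers", "events"),
            ss.spawn(5),
        )
    }
    rs, rd, ro, rm, re_ = (
        streams["structure"], streams["demographics"], streams["outcomes"],
        streams["markers"], streams["events"],
    )

    # --- subject structure: who enrolls how many times -------------------
    n_extra = cfg.n_episodes - cfg.n_subjects
    n_repeat = min(cfg.n_repeat_subjects, cfg.n_subjects, n_extra) if n_extra else 0
    counts = np.ones(cfg.n_subjects, dtype=int)
    if n_repeat:
        repeat_idx = rs.choice(cfg.n_subjects, size=n_repeat, replace=False)
        counts[repeat_idx] += 1
        extra_left = n_extra - n_repeat
        if extra_left > 0:
            more = rs.choice(repeat_idx, size=extra_left, replace=True)
            np.add.at(counts, more, 1)

    p_det_ward = _conditional(
        cfg.p_deterioration, cfg.p_det_given_icu, cfg.p_icu, "deterioration|ward"
    )
    p_death_stable = _conditional(
        cfg.p_death28, cfg.p_death28_given_det, cfg.p_deterioration, "death28|stable"
    )
    p_inf_stable = _conditional(
        cfg.p_infected, cfg.p_infected_given_det, cfg.p_deterioration, "infected|stable"
    )

    episodes: list[Episode] = []
    for subj in range(cfg.n_subjects):
        subject_id = f"S{subj + 1:04d}"
        age = float(
            np.clip(rd.lognormal(cfg.age_log_median, cfg.age_log_sd),
                    0.1, cfg.age_max_years)
        )
        sex = "F" if rd.random() < cfg.p_female else "M"
        weight = _weight_from_age(age, rd)
        immuno = _draw_immuno(cfg, rd)

        t = STUDY_START + timedelta(hours=float(rd.uniform(0, 24 * 400)))
        for k in range(counts[subj]):
            if k > 0:
                # re-enrollments are typically weeks-to-months apart
                t = t + timedelta(days=float(rd.uniform(10, 90)))
            culture_time = t
            sample_time = culture_time + timedelta(hours=float(rd.uniform(-3, 3)))

            icu = ro.random() < cfg.p_icu
            location = ("picu" if ro.random() < 48 / 61 else "cicu") if icu else "ward"
            platelet = float(rm.lognormal(cfg.platelet_log_median, cfg.platelet_log_sd))

            if cfg.mode == "tree":
                panel_values = _draw_markers(cfg, rm, event=False)
                tree_vals = dict(panel_values)
                tree_vals["age_years"] = age
                tree_vals["platelet_k_mcl"] = platelet
                rate = _descend_rate(cfg.truth_tree, tree_vals)
                if cfg.truth_tree.outcome_name == "mortality28":
                    death28 = ro.random() < rate
                    det = ro.random() < (
                        cfg.p_det_given_icu if icu else p_det_ward
                    )
                    det = det or death28 and ro.random() < 0.5
                else:
                    det = ro.random() < rate
                    death28 = ro.random() < (
                        cfg.p_death28_given_det if det else p_death_stable
                    )
            else:
                det = ro.random() < (cfg.p_det_given_icu if icu else p_det_ward)
                death28 = ro.random() < (
                    cfg.p_death28_given_det if det else p_death_stable
                )
                panel_values = _draw_markers(cfg, rm, event=det)

            infected = ro.random() < (cfg.p_infected_given_det if det else p_inf_stable)
            death72 = bool(
                det and death28 and re_.random() < cfg.p_death72_given_det_death
            )
            events = _draw_events(det, death72, icu, round(weight, 2), re_)

            ep = Episode(
                subject_id=subject_id,
                episode_id=f"E{k + 1}",
                age_years=round(age, 4),
                sex=sex,
                location=location,
                platelet_k_mcl=round(platelet, 2),
                immuno=immuno,
                culture_time=culture_time.replace(microsecond=0),
                sample_time=sample_time.replace(microsecond=0),
                biomarkers=BiomarkerPanel(
                    **{m: round(panel_values[m], 3) for m in BIOMARKERS}
                ),
                events=events,
                bacterially_infected=bool(infected),
                death_28d=bool(death28),
            )
            assert meets_immunocompromised(ep.immuno)
            assert meets_deterioration(ep.events) == det
            episodes.append(ep)

    return Cohort(episodes)


def _draw_immuno(cfg: GeneratorConfig, rng: np.random.Generator) -> ImmunoCriteria:
    """Eligibility profile: every subject meets at least one criterion."""
    # ANC log-normal placed so ~p_neutropenic of draws fall below 0.5 K/mcL
    z = -float(np.sqrt(2)) * float(_erfinv(1 - 2 * cfg.p_neutropenic))
    anc = float(rng.lognormal(math.log(0.5) - z * 1.5, 1.5))
    anc = round(min(anc, 30.0), 3)
    neutropenic = anc < 0.5
    chemo = bool(rng.random() < 0.55)
    bmt = bool(rng.random() < 0.24)
    sot = bool(rng.random() < 0.21) and not bmt
    immunosupp = bool((bmt or sot) and rng.random() < 0.9)
    if not (neutropenic or chemo or ((bmt or sot) and immunosupp)):
        chemo = True  # guarantee eligibility
    return ImmunoCriteria(
        anc=anc,
        chemo_within_7d=chemo,
        myeloablative_radiation_within_7d=bool(rng.random() < 0.05),
        solid_organ_transplant=sot,
        bone_marrow_transplant=bmt,
        immunosuppression_within_7d=immunosupp,
    )


def _erfinv(x: float) -> float:
    from scipy.special import erfinv

    return float(erfinv(x))


def _draw_markers(
    cfg: GeneratorConfig, rng: np.random.Generator, *, event: bool
) -> dict[str, float]:
    out = {}
    for name in BIOMARKERS:
        dist = cfg.marker_distributions[name]
        mu = dist.log_median + (dist.event_shift if event else 0.0)
        out[name] = float(rng.lognormal(mu, dist.log_sd))
    return out


#: relative frequencies of deterioration manifestations among deteriorated
#: episodes (vasoactives, respiratory support, ICU transfer, altered mental
#: status, large fluid resuscitation)
_MANIFESTATION_P = {
    "vaso": 0.27,
    "resp": 0.26,
    "icu_transfer": 0.25,
    "ams": 0.13,
    "fluid": 0.11,
}


def _draw_events(
    det: bool, death72: bool, in_icu: bool, weight: float,
    rng: np.random.Generator
) -> DeteriorationEvents:
    thresh = (
        FLUID_ML_PER_KG * weight if weight < FLUID_WEIGHT_CUT_KG else FLUID_ABSOLUTE_ML
    )
    if not det:
        return DeteriorationEvents(
            crystalloid_ml_24h=round(float(rng.uniform(0, 0.5)) * thresh, 1),
            weight_kg=round(weight, 2),
        )
    flags = {k: rng.random() < p for k, p in _MANIFESTATION_P.items()}
    if in_icu:
        flags["icu_transfer"] = False  # only meaningful from a non-ICU location
    if death72:
        flags["death"] = True
    if not any(flags.values()):
        allowed = [k for k in _MANIFESTATION_P if not (in_icu and k == "icu_transfer")]
        p = np.array([_MANIFESTATION_P[k] for k in allowed])
        flags[str(rng.choice(allowed, p=p / p.sum()))] = True
    # keep a safety margin above/below the threshold so the 0.1 mL rounding
    # of the recorded volume cannot flip the fluid criterion
    crystalloid = (
        thresh * float(rng.uniform(1.01, 1.6))
        if flags.get("fluid")
        else thresh * float(rng.uniform(0, 0.8))
    )
    return DeteriorationEvents(
        icu_transfer_72h=bool(flags.get("icu_transfer", False)),
        new_respiratory_support_72h=bool(flags.get("resp", False)),
        crystalloid_ml_24h=round(crystalloid, 1),
        weight_kg=round(weight, 2),
        new_vasoactive_72h=bool(flags.get("vaso", False)),
        new_altered_mental_status_72h=bool(flags.get("ams", False)),
        death_72h=death72,
    )


# ---------------------------------------------------------------------------
# Config file I/O


def load_generator_config(path) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML or JSON.

    Field names mirror the dataclass.  ``truth_tree`` may be a path to a
    tree-spec JSON file.  ``marker_distributions`` maps biomarker name to
    ``{log_median, log_sd, event_shift}``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping")
    kwargs = dict(doc)
    if "truth_tree" in kwargs and kwargs["truth_tree"] is not None:
        kwargs["truth_tree"] = load_tree(kwargs["truth_tree"])
    if "marker_distributions" in kwargs:
        kwargs["marker_distributions"] = {
            name: MarkerDistribution(**d)
            for name, d in kwargs["marker_distributions"].items()
        }
    try:
        return GeneratorConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """JSON-serializable view of a config (truth tree by outcome name only)."""
    d = asdict(cfg)
    d["marker_distributions"] = {
        k: asdict(v) for k, v in cfg.marker_distributions.items()
    }
    if cfg.truth_tree is not None:
        d["truth_tree"] = {"outcome_name": cfg.truth_tree.outcome_name}
    return d
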