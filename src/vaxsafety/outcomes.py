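"""Outcome ascertainment in the risk window and the TTS phenotype.

Outcomes are sets of event concepts; composites take the union of their
members' concepts and the earliest event day. Thrombosis with
thrombocytopenia syndrome (TTS) is a thromboembolic event in the 28-day risk
window with evidence of thrombocytopenia — a diagnostic code or a platelet
measurement below threshold — within a concurrency window (default +/-10
days, sensitivity +/-5) around the event. The platelet threshold is a strict
"<" at 150 (sensitivity 100) in units of 10^3 platelets/uL.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .config import ConfigValidationError
from .errors import UnknownOutcomeError
from .synthetic import SyntheticDatabase


@dataclass
class OutcomeDefinition:
    name: str
    concepts: tuple[str, ...] = ()
    composite_of: tuple[str, ...] = ()
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.is_negative_control and self.composite_of:
            raise ConfigValidationError(f"negative control {self.name!r} cannot be a composite")
        if not self.concepts and not self.composite_of:
            raise ConfigValidationError(f"outcome {self.name!r} must list concepts or composite members")


@dataclass
class TTSDefinition:
    """TTS phenotype parameters. The thromboembolic event must be in the risk
    window; the concurrent thrombocytopenia evidence may fall outside it."""

    name: str
    thrombo_outcome: str
    concurrency_window_days: int = 10
    platelet_threshold: float = 150.0
    thrombocytopenia_concepts: tuple[str, ...] = ("thrombocytopenia",)

    def __post_init__(self) -> None:
        if self.concurrency_window_days <= 0:
            raise ConfigValidationError("concurrency_window_days must be > 0")
        if self.platelet_threshold <= 0:
            raise ConfigValidationError("platelet_threshold must be > 0")


class OutcomeRegistry:
    """Name -> definition lookup with composite resolution."""

    def __init__(self, definitions: list[OutcomeDefinition]):
        self._defs = {d.name: d for d in definitions}
        for d in definitions:
            for member in d.composite_of:
                if member not in self._defs:
                    raise ConfigValidationError(
                        f"composite {d.name!r} references unknown member {member!r}"
                    )

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __getitem__(self, name: str) -> OutcomeDefinition:
        try:
            return self._defs[name]
        except KeyError:
            raise UnknownOutcomeError(f"unknown outcome {name!r}") from None

    def names(self) -> list[str]:
        return list(self._defs)

    def negative_controls(self) -> list[str]:
        return [n for n, d in self._defs.items() if d.is_negative_control]

    def member_concepts(self, name: str) -> set[str]:
        d = self[name]
        concepts = set(d.concepts)
        for member in d.composite_of:
            concepts |= self.member_concepts(member)
        return concepts

    @classmethod
    def from_yaml(cls, path: str) -> "OutcomeRegistry":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or []
        defs = [
            OutcomeDefinition(
                name=item["name"],
                concepts=tuple(item.get("concepts", ())),
                composite_of=tuple(item.get("composite_of", ())),
                is_negative_control=bool(item.get("is_negative_control", False)),
            )
            for item in raw
        ]
        return cls(defs)


def default_registry(negative_controls: list[str] | None = None) -> OutcomeRegistry:
    """Study outcome set: individual thromboembolic events, the venous and
    arterial composites, and optional synthetic negative controls."""
    defs = [
        OutcomeDefinition("deep_vein_thrombosis", ("deep_vein_thrombosis",)),
        OutcomeDefinition("pulmonary_embolism", ("pulmonary_embolism",)),
        OutcomeDefinition("ischaemic_stroke", ("ischaemic_stroke",)),
        OutcomeDefinition("myocardial_infarction", ("myocardial_infarction",)),
        OutcomeDefinition("thrombocytopenia", ("thrombocytopenia",)),
        OutcomeDefinition(
            "venous_thromboembolism",
            composite_of=("deep_vein_thrombosis", "pulmonary_embolism"),
        ),
        OutcomeDefinition(
            "arterial_thromboembolism",
            composite_of=("ischaemic_stroke", "myocardial_infarction"),
        ),
    ]
    for nc in negative_controls or []:
        defs.append(OutcomeDefinition(nc, (nc,), is_negative_control=True))
    return OutcomeRegistry(defs)


def _concept_events(db: SyntheticDatabase, concepts: set[str]) -> pd.DataFrame:
    """Events restricted to the given concepts, via a per-database cache of
    the events table grouped by concept (the events frame is treated as
    immutable once analysis starts)."""
    cache = getattr(db, "_concept_cache", None)
    if cache is None:
        cache = dict(tuple(db.events.groupby("concept", observed=True)))
        db._concept_cache = cache
    frames = [cache[c] for c in sorted(concepts) if c in cache]
    if not frames:
        return db.events.iloc[0:0]
    return frames[0] if len(frames) == 1 else pd.concat(frames)


def first_event_days(
    db: SyntheticDatabase,
    cohort: pd.DataFrame,
    outcome: str,
    registry: OutcomeRegistry,
) -> pd.Series:
    """Earliest member-concept event day in (index_day, follow_up_end_day]
    for every cohort entry; NaN where no event occurs. Indexed by person_id."""
    events = _concept_events(db, registry.member_concepts(outcome))
    merged = events.merge(cohort[["person_id", "index_day", "follow_up_end_day"]], on="person_id", how="inner")
    in_window = (merged["day"] > merged["index_day"]) & (merged["day"] <= merged["follow_up_end_day"])
    hit = merged[in_window].groupby("person_id")["day"].min()
    out = pd.Series(np.nan, index=pd.Index(cohort["person_id"], name="person_id"), name="event_day")
    out.loc[hit.index] = hit.astype(float)
    return out


def first_event_day_table(
    db: SyntheticDatabase,
    cohort: pd.DataFrame,
    outcomes: list[str],
    registry: OutcomeRegistry,
) -> dict[str, pd.Series]:
    """Batched :func:`first_event_days` over many outcomes with one pass over
    the events table. Semantically identical per outcome."""
    member = {name: registry.member_concepts(name) for name in outcomes}
    all_concepts = set().union(*member.values()) if member else set()
    events = _concept_events(db, all_concepts)
    merged = events.merge(cohort[["person_id", "index_day", "follow_up_end_day"]], on="person_id", how="inner")
    in_window = merged[(merged["day"] > merged["index_day"]) & (merged["day"] <= merged["follow_up_end_day"])]
    first = in_window.groupby(["concept", "person_id"], observed=True)["day"].min()
    index = pd.Index(cohort["person_id"], name="person_id")
    out: dict[str, pd.Series] = {}
    for name, concepts in member.items():
        present = [c for c in sorted(concepts) if c in first.index.get_level_values(0)]
        series = pd.Series(np.nan, index=index, name="event_day")
        if present:
            sub = first.loc[present].groupby("person_id").min()
            series.loc[sub.index] = sub.astype(float)
        out[name] = series
    return out


def ascertain_first_event(
    db: SyntheticDatabase,
    entry: pd.Series,
    outcome: str,
    registry: OutcomeRegistry,
) -> int | None:
    """Per-entry form of :func:`first_event_days`."""
    cohort = pd.DataFrame([entry[["person_id", "index_day", "follow_up_end_day"]]])
    day = first_event_days(db, cohort, outcome, registry).iloc[0]
    return None if np.isnan(day) else int(day)


def exclude_prior_history(
    cohort: pd.DataFrame,
    db: SyntheticDatabase,
    outcome: str,
    registry: OutcomeRegistry,
) -> pd.DataFrame:
    """Drop entries whose person has any member-concept event strictly before
    the index date (all available history). Applied per outcome, before
    matching."""
    events = _concept_events(db, registry.member_concepts(outcome))
    merged = events.merge(cohort[["person_id", "index_day"]], on="person_id", how="inner")
    prior = merged.loc[merged["day"] < merged["index_day"], "person_id"].unique()
    return cohort[~cohort["person_id"].isin(prior)].reset_index(drop=True)


def detect_thrombocytopenia_days(
    db: SyntheticDatabase,
    person_id: int,
    platelet_threshold: float = 150.0,
    thrombocytopenia_concepts: tuple[str, ...] = ("thrombocytopenia",),
) -> set[int]:
    """Days with thrombocytopenia evidence for one person: diagnosis-code days
    union days with a platelet measurement strictly below the threshold."""
    ev = db.events
    dx_days = ev.loc[
        (ev["person_id"] == person_id) & (ev["concept"].isin(thrombocytopenia_concepts)), "day"
    ]
    ms = db.measurements
    low_days = ms.loc[(ms["person_id"] == person_id) & (ms["value"] < platelet_threshold), "day"]
    return set(dx_days.astype(int)) | set(low_days.astype(int))


def classify_tts(
    thrombo_day: int,
    thrombocytopenia_days: set[int],
    tts: TTSDefinition,
) -> bool:
    """True iff any thrombocytopenia day is within the concurrency window of
    the thromboembolic event."""
    w = tts.concurrency_window_days
    return any(abs(d - thrombo_day) <= w for d in thrombocytopenia_days)


def tts_event_days(
    db: SyntheticDatabase,
    cohort: pd.DataFrame,
    tts: TTSDefinition,
    registry: OutcomeRegistry,
) -> pd.Series:
    """Vectorised TTS ascertainment over a cohort.

    The first in-window thromboembolic event per person is the candidate
    (first-event-only convention); it counts as a TTS event iff concurrent
    thrombocytopenia evidence exists. Returns the thrombo event day where TTS
    is positive, NaN otherwise, indexed by person_id.
    """
    thrombo = first_event_days(db, cohort, tts.thrombo_outcome, registry)
    hit = thrombo.dropna()
    if hit.empty:
        return thrombo
    hit_pids = hit.index.to_numpy()

    ev = _concept_events(db, set(tts.thrombocytopenia_concepts))
    dx = ev[ev["person_id"].isin(hit_pids)][["person_id", "day"]]
    ms = db.measurements
    low = ms[(ms["value"] < tts.platelet_threshold) & (ms["person_id"].isin(hit_pids))][["person_id", "day"]]
    evidence = pd.concat([dx, low], ignore_index=True)
    out = pd.Series(np.nan, index=thrombo.index, name="event_day")
    if evidence.empty:
        return out
    evidence = evidence.merge(hit.rename("thrombo_day"), left_on="person_id", right_index=True)
    concurrent = evidence[
        (evidence["day"] - evidence["thrombo_day"]).abs() <= tts.concurrency_window_days
    ]
    positive = concurrent["person_id"].unique()
    out.loc[positive] = hit.loc[positive]
    return out
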