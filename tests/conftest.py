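import numpy as np
import pandas as pd
import pytest

from vaxsafety.synthetic import SyntheticDatabase


def make_db(persons=None, vaccinations=None, events=None, measurements=None) -> SyntheticDatabase:
    """Hand-built database from row dicts, with the canonical dtypes."""
    p = pd.DataFrame(
        persons or [],
        columns=["person_id", "sex", "birth_year", "observation_start_day", "observation_end_day", "death_day"],
    )
    if len(p):
        p = p.astype(
            {
                "person_id": np.int64,
                "birth_year": float,
                "observation_start_day": np.int64,
                "observation_end_day": np.int64,
                "death_day": float,
            }
        )
    p["sex"] = p["sex"].astype("string") if len(p) else pd.Series(dtype="string")
    v = pd.DataFrame(vaccinations or [], columns=["person_id", "brand", "dose_number", "day"])
    if len(v):
        v = v.astype({"person_id": np.int64, "dose_number": np.int64, "day": np.int64})
    v["brand"] = v["brand"].astype("string") if len(v) else pd.Series(dtype="string")
    e = pd.DataFrame(events or [], columns=["person_id", "concept", "day"])
    if len(e):
        e = e.astype({"person_id": np.int64, "day": np.int64})
    e["concept"] = e["concept"].astype("string") if len(e) else pd.Series(dtype="string")
    m = pd.DataFrame(measurements or [], columns=["person_id", "day", "value"])
    if len(m):
        m = m.astype({"person_id": np.int64, "day": np.int64, "value": float})
    return SyntheticDatabase(p, v, e, m, None)


def person(pid, sex="female", birth_year=1970.0, obs_start=-800, obs_end=400, death=np.nan):
    return {
        "person_id": pid,
        "sex": sex,
        "birth_year": birth_year,
        "observation_start_day": obs_start,
        "observation_end_day": obs_end,
        "death_day": death,
    }


def dose(pid, brand="ChAdOx1-S", dose_number=1, day=50):
    return {"person_id": pid, "brand": brand, "dose_number": dose_number, "day": day}


def event(pid, concept, day):
    return {"person_id": pid, "concept": concept, "day": day}


def measurement(pid, day, value):
    return {"person_id": pid, "day": day, "value": value}


@pytest.fixture
def cohort_of():
    """Cohort frame builder: list of (person_id, index_day, fu_end) tuples."""

    def build(entries, arm="target"):
        return pd.DataFrame(
            [
                {
                    "person_id": pid,
                    "arm": arm,
                    "index_day": idx,
                    "follow_up_end_day": fu,
                    "censor_reason": "window_end",
                }
                for pid, idx, fu in entries
            ],
            columns=["person_id", "arm", "index_day", "follow_up_end_day", "censor_reason"],
        )

    return build
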