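import numpy as np
import pandas as pd
import pytest

from psyews.cohort import build_cohort
from psyews.data import DX_COLUMNS, Dataset
from psyews.features import derive_features
from psyews.simulate import preset_reference, simulate_dataset


def make_patient(pid, org="orgA", age=30.0, gender="female", race="white", dx=("mdd",)):
    row = {
        "patient_id": pid, "org_id": org, "age": age,
        "gender": gender, "race_group": race,
    }
    for c in DX_COLUMNS:
        row[c] = c.removeprefix("dx_") in dx
    return row


def make_dataset(patients, visits, hospitalisations=None, splits=None) -> Dataset:
    """Assemble a typed Dataset from plain row dicts / tuples.

    visits: (patient_id, day, cgi_s, gaf) with None for absent ratings.
    hospitalisations: (patient_id, day).
    """
    pat = pd.DataFrame(patients)
    vis = pd.DataFrame(visits, columns=["patient_id", "day", "cgi_s", "gaf"])
    vis["cgi_s"] = pd.array(vis["cgi_s"], dtype="Int64")
    vis["gaf"] = pd.array(vis["gaf"], dtype="Int64")
    hosp = pd.DataFrame(
        hospitalisations or [], columns=["patient_id", "day"]
    )
    if splits is None:
        splits = pd.DataFrame(
            {"org_id": sorted(pat["org_id"].unique()), "split": "derivation"}
        )
    else:
        splits = pd.DataFrame(splits, columns=["org_id", "split"])
    return Dataset(pat, vis, hosp, splits).validate()


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Ten patients; p0 qualifies cleanly, p1 lacks ratings, p2 hospitalised early."""
    patients = [make_patient(f"p{i}", org=("orgA" if i < 6 else "orgB"),
                             gender=("male" if i % 3 else "female"),
                             race=("non_white" if i % 4 == 1 else "white"),
                             dx=("mdd", "bd") if i % 2 else ("gad",))
                for i in range(10)]
    visits, hosp = [], []
    for i in range(10):
        pid = f"p{i}"
        if i == 1:  # too few ratings anywhere
            visits += [(pid, d, 4, 60) for d in (0, 50, 100)]
        else:
            visits += [(pid, d, 3 + (d // 60) % 3, 60 - d // 20) for d in
                       (0, 30, 60, 90, 120, 150, 200, 250, 300)]
        if i == 2:
            hosp.append((pid, 100))
        if i == 3:
            hosp.append((pid, 250))
    return make_dataset(patients, visits, hosp,
                        splits=[("orgA", "derivation"), ("orgB", "validation")])


@pytest.fixture(scope="session")
def reference_10k():
    """One reference simulation shared across discrimination-level tests."""
    cfg = preset_reference(n_patients=10000, seed=101)
    ds, truth = simulate_dataset(cfg)
    cohort, exclusions = build_cohort(ds)
    feats = derive_features(cohort, ds.visits, ds.patients)
    return {"cfg": cfg, "ds": ds, "truth": truth, "cohort": cohort,
            "exclusions": exclusions, "features": feats}
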