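import datetime as dt
import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quinpv.icsr import (
    ICSR,
    AdverseEvent,
    QUINOLONE_CATALOG,
    SuspectDrug,
    load_pt_dictionary,
    load_table1_counts,
    map_pt_to_soc,
    read_line_listing,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pt_dict():
    return load_pt_dictionary()


@pytest.fixture(scope="session")
def table1():
    return load_table1_counts()


SIX_ROW_LISTING = """\
report_id,receive_date,age_years,gender,drug,preferred_term,onset_date,therapy_start_date
C-001,2018-06-01,63,female,ciprofloxacin,tremor,2018-05-20,2018-05-18
C-001,2018-06-01,63,female,ciprofloxacin,myalgia,2018-05-22,2018-05-18
C-002,2018-07-10,41,male,levofloxacin,tendinitis,2018-07-01,2018-06-28
C-002,2018-07-10,41,male,levofloxacin,nausea,2018-07-01,2018-06-28
C-003,2019-01-05,,unknown,moxifloxacin,insomnia,2019-01-02,2019-01-01
C-003,2019-01-05,,unknown,moxifloxacin,hallucination,2019-01-03,2019-01-01
"""


@pytest.fixture
def six_row_listing():
    return io.StringIO(SIX_ROW_LISTING)


@pytest.fixture
def six_row_icsrs(pt_dict):
    return read_line_listing(io.StringIO(SIX_ROW_LISTING), pt_dict)


def make_icsr(report_id, drugs, pts, pt_dict, *, start=None, onsets=None, **kwargs):
    """Hand-construct a validated ICSR from drug names and preferred terms."""
    start = start or dt.date(2018, 5, 3)
    events = []
    for i, pt in enumerate(pts):
        onset = None if onsets is None else onsets[i]
        events.append(AdverseEvent(pt, map_pt_to_soc(pt, pt_dict), onset))
    icsr = ICSR(
        report_id=report_id,
        receive_date=dt.date(2018, 6, 1),
        suspects=[
            SuspectDrug(QUINOLONE_CATALOG[d], therapy_start_date=start) for d in drugs
        ],
        events=events,
        **kwargs,
    )
    icsr.n_suspect_drugs_total = max(icsr.n_suspect_drugs_total, len(icsr.suspects))
    icsr.validate()
    return icsr


def random_listing(rng: np.random.Generator, n_records: int, pt_dict):
    """A random in-memory line listing over the full catalog and dictionary
    (used for brute-force oracle comparisons)."""
    drug_names = sorted(QUINOLONE_CATALOG)
    pts = sorted(pt_dict) + ["nausea", "rash", "vomiting"]
    icsrs = []
    for i in range(n_records):
        k_drugs = 1 + (rng.random() < 0.15)
        drugs = list(rng.choice(drug_names, size=k_drugs, replace=False))
        k_events = 1 + rng.poisson(1.0)
        chosen = list(rng.choice(pts, size=min(k_events, len(pts)), replace=False))
        icsrs.append(make_icsr(f"R-{i:04d}", drugs, chosen, pt_dict))
    return icsrs
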