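"""Label the simulated cohort and apply the eligibility filter.

Reads results/cohort.csv (written by 01_simulate_cohort.py), assigns CKD
status and T0 to every patient, masks extreme outliers, drops lab-free
visits, and reports the eligibility funnel with per-record rejection reasons.
"""

from __future__ import annotations

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from ckdpipe import default_catalog, read_ehr_table
from ckdpipe.cohort import (
    FilterConfig,
    compute_population_sd,
    drop_lab_free_visits,
    filter_eligible,
    mask_outliers,
)
from ckdpipe.ehr_core import CKDStatus
from ckdpipe.labeling import LabelingRules, label_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    catalog = default_catalog()
    records = read_ehr_table(RESULTS / "cohort.csv", catalog)
    labeled = label_cohort(records, catalog, LabelingRules())

    status_counts = Counter(r.status.value for r in labeled)
    print("status assignment:", dict(status_counts))
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in labeled],
            "status": [r.status.value for r in labeled],
            "t0_years": [r.t0_years for r in labeled],
        }
    ).to_csv(RESULTS / "labels.csv", index=False)

    modelable = [r for r in labeled if r.status in (CKDStatus.CKD, CKDStatus.NO_CKD)]
    cfg = FilterConfig()
    sd = compute_population_sd(modelable, catalog)
    masked = mask_outliers(modelable, catalog, sd, cfg)
    masked = [drop_lab_free_visits(r, catalog) for r in masked]
    kept, rejected = filter_eligible([r for r in masked if r.usable_visits], catalog, cfg)

    reasons = Counter(reason for _, rs in rejected for reason in rs)
    print(f"eligible {len(kept)} / rejected {len(rejected)}; reasons: {dict(reasons)}")
    rows = [{"patient_id": r.patient_id, "kept": True, "reasons": ""} for r in kept] + [
        {"patient_id": r.patient_id, "kept": False, "reasons": "|".join(rs)}
        for r, rs in rejected
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "eligibility.csv", index=False)
    print(
        "Most rejections should cite the urine completeness rule - urinalysis "
        "is missing at ~60% of visits, mirroring routine practice."
    )


if __name__ == "__main__":
    main()
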