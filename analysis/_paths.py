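"""Shared locations for the analysis drivers."""

from pathlib import Path

RESULTS_DIR = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS_DIR / "cohorts"

COHORTS = {"east_asian": ("ckb_like", "ckb"), "european": ("cgps_like", "cgps")}


def load_cohort(name):
    import pandas as pd

    from vitdmr.cohort_io import read_cohort, schema_for_cohort

    path = COHORT_DIR / f"{name}.tsv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run analysis/01_simulate_cohorts.py first")
    head = pd.read_csv(path, sep="\t", nrows=5)
    return read_cohort(path, schema_for_cohort(head))
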