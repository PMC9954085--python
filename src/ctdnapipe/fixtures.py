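"""Packaged cohort tables: clinical characteristics, per-approach detection
counts, and longitudinal ddPCR results for the 47-participant study cohort.

Values are shipped verbatim as TSV package data.  The detection table's
cfDNA masses saturate at 250 ng (the library-prep input cap), so
concentration-ratio statistics computed from it underestimate the true
post-surgical rise and are flagged accordingly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .core import DetectionTable

_CHECKSUMS = {
    "table1_cohort.tsv": "5bb46aa7",
    "table2_detection.tsv": "ac051a72",
    "table3_ddpcr.tsv": "a27c7521",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ctdnapipe.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()[:8]
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise ValueError(
            f"fixture {name} checksum mismatch: {digest} != {expected} (corrupted install?)"
        )
    return pd.read_csv(ref.open("r"), sep="\t", na_values=["NA"])


def load_cohort_table() -> pd.DataFrame:
    """47 participants: localisation, age, sex, stage, overall survival."""
    df = _read("table1_cohort.tsv")
    df["os_event"] = df["alive_at_end_of_study"].str.lower().eq("no")
    return df


def load_detection_table() -> DetectionTable:
    """Per-participant retained-variant counts for approaches A-D at the
    diagnostic and post-surgical timepoints, plus plasma volumes/masses."""
    return DetectionTable(_read("table2_detection.tsv"))


def load_ddpcr_table() -> pd.DataFrame:
    """Longitudinal ddPCR results: per-target VAF, assay false-positive rate,
    total cfDNA copies/mL and the printed positivity calls; ``ci_overlap``
    encodes the overlapping-error-bar footnote."""
    df = _read("table3_ddpcr.tsv")
    df["ci_overlap"] = df["ci_overlap"].eq("yes")
    return df


def load_fixture(name: str):
    """Load a bundled table by short name: 'table1', 'table2' or 'table3'."""
    loaders = {
        "table1": load_cohort_table,
        "table2": load_detection_table,
        "table3": load_ddpcr_table,
    }
    try:
        return loaders[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(loaders)}")
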