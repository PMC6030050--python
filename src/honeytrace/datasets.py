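"""Packaged datasets.

The package ships the per-species Hemiptera read counts of a published
13-honey COI metabarcoding survey (honeydew and blossom honeys from Italy,
Corsica and Eastern Europe), together with the abundance percentages that
survey printed for the taxa it discusses.  These drive the worked-example
report and the summary-stage tests without any sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("honeytrace.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_survey_counts() -> pd.DataFrame:
    """Columns: library, taxon, count, reported_category."""
    df = _read("honey_survey_counts.tsv")
    df["count"] = df["count"].astype(int)
    return df


def load_survey_reported_percentages() -> pd.DataFrame:
    """Columns: library, taxon, reported_pct (as printed, in percent)."""
    return _read("honey_survey_reported.tsv")
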