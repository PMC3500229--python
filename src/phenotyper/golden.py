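"""Access to the packaged person-level validation fixture.

The fixture encodes the published adjudication cross-tabulations of the
primary case definition — 64 catchment encounters meeting it (46 chart-
reviewed) and 187 not meeting it (113 sampled, 30 chart-reviewed) — as one
case record per encounter and one adjudication label per reviewed person,
so every reported validation proportion can be recomputed from rows rather
than asserted as constants.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .case_definition import CaseRecord, read_cases
from .validation_stats import AdjudicationLabel, read_adjudication

__all__ = ["golden_dir", "load_golden"]


def golden_dir() -> Path:
    return Path(str(resources.files("phenotyper").joinpath("data/golden")))


def load_golden() -> tuple[list[CaseRecord], list[AdjudicationLabel], dict]:
    """The packaged fixture: (case records, adjudication labels, sampling counts)."""
    d = golden_dir()
    cases = read_cases(d / "cases_primary.csv")
    labels = read_adjudication(d / "adjudication.csv")
    counts = yaml.safe_load((d / "counts.yaml").read_text())
    return cases, labels, counts
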