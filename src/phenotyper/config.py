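"""Tunable study parameters shared across the cohort builder and the engine.

Defaults encode the study design: ages 6-24 at entry, one year of baseline
enrollment tolerating lapses of at most 7 days, a 365-day study-drug washout
with a 90-day post-discharge allowance, follow-up ending 365 days after the
last day of current use, and the case-definition windows (±120-day PCOS
window, 29-day index-reset lookback, 120-day subtype window).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date


@dataclass(frozen=True, slots=True)
class PipelineConfig:
    study_start: date = date(1996, 1, 1)
    study_end: date = date(2007, 12, 31)

    # cohort eligibility
    min_age_years: int = 6
    max_age_years: int = 25          # exclusive upper bound at entry
    baseline_days: int = 365         # prior-enrollment lookback
    max_enrollment_gap_days: int = 7
    recent_hospital_days: int = 30
    washout_days: int = 365          # study-drug-free lookback
    allowance_days: int = 90         # post-discharge initiation allowance

    # "current use" supply model for the discontinuation censor
    days_supplied_default: int = 30
    grace_period_days: int = 0
    discontinuation_days: int = 365

    # case definition
    pcos_window_days: int = 120
    index_reset_days: int = 29
    subtype_window_days: int = 120
    confirmation_window_days: int | None = None  # None = to end of follow-up
    fall_through: bool = False       # adjudicate later encounters if the first fails
    adjunct_counts_as_insulin: bool = False


DEFAULT_CONFIG = PipelineConfig()
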