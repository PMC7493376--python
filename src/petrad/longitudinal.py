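"""Longitudinal per-feature change between baseline and follow-up exams.

Delta(%) = 100 * (post-treatment value - baseline value) / baseline value.
A zero baseline leaves the change undefined: the feature becomes NaN and is
reported, so downstream selection can exclude it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import FeatureVector

log = logging.getLogger(__name__)


@dataclass
class PairedExam:
    baseline: FeatureVector
    followup: FeatureVector
    patient_id: str = ""
    interval_months: Optional[float] = None

    def __post_init__(self) -> None:
        if self.baseline.names != self.followup.names:
            raise ValueError("baseline and follow-up feature registries differ")


def delta_percent(pair: PairedExam) -> FeatureVector:
    """Per-feature percent change relative to baseline."""
    base = pair.baseline.values
    post = pair.followup.values
    notes = []
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (post - base) / base
    undefined = (base == 0) | ~np.isfinite(delta)
    for name in np.asarray(pair.baseline.names)[undefined]:
        notes.append(f"{name}: delta undefined (zero or non-finite baseline)")
        log.info("patient %s: delta%% undefined for %s", pair.patient_id, name)
    delta = np.where(undefined, np.nan, delta)
    return FeatureVector(list(pair.baseline.names), delta,
                         lesion_id=pair.baseline.lesion_id, units="delta %", notes=notes)
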