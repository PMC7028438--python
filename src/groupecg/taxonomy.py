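"""Two-level diagnostic label taxonomy.

The coarse task distinguishes normal rhythm (N), arrhythmia (AR),
myocardial infarction (MI), ventricular hypertrophy (VH) and atrial
hypertrophy (AH).  The fine task splits each disease into subtypes, giving
15 classes in total:

====  =========================================
N     normal rhythm
SA    sinus arrhythmia                    (AR)
AA    atrial arrhythmia                   (AR)
JA    junctional arrhythmia               (AR)
VA    ventricular arrhythmia              (AR)
HB    heart block                         (AR)
AMI   anterior myocardial infarction      (MI)
IMI   inferior myocardial infarction      (MI)
LMI   lateral myocardial infarction       (MI)
LVH   left ventricular hypertrophy        (VH)
RVH   right ventricular hypertrophy       (VH)
BVH   biventricular hypertrophy           (VH)
LAH   left atrial hypertrophy             (AH)
RAH   right atrial hypertrophy            (AH)
BAH   biatrial hypertrophy                (AH)
====  =========================================
"""

from __future__ import annotations

import numpy as np

TASK1_CLASSES: tuple[str, ...] = ("N", "AR", "MI", "VH", "AH")

TASK2_CLASSES: tuple[str, ...] = (
    "N", "SA", "AA", "JA", "VA", "HB",
    "AMI", "IMI", "LMI",
    "LVH", "RVH", "BVH",
    "LAH", "RAH", "BAH",
)

_TASK2_TO_TASK1: dict[str, str] = {
    "N": "N",
    "SA": "AR", "AA": "AR", "JA": "AR", "VA": "AR", "HB": "AR",
    "AMI": "MI", "IMI": "MI", "LMI": "MI",
    "LVH": "VH", "RVH": "VH", "BVH": "VH",
    "LAH": "AH", "RAH": "AH", "BAH": "AH",
}

TASK1_INDEX = {c: i for i, c in enumerate(TASK1_CLASSES)}
TASK2_INDEX = {c: i for i, c in enumerate(TASK2_CLASSES)}

STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Lead presets used in the lead-count ablation.
LEAD_PRESETS: dict[str, tuple[str, ...]] = {
    "3-lead": ("I", "II", "III"),
    "8-lead": ("II", "III", "V1", "V2", "V3", "V4", "V5", "V6"),
    "12-lead": STANDARD_LEADS,
}


class InvalidLabelError(ValueError):
    """Raised for labels outside the two-level taxonomy."""


def map_task2_to_task1(label2: str) -> str:
    """Map a fine (15-class) label to its coarse (5-class) disease group."""
    try:
        return _TASK2_TO_TASK1[label2]
    except KeyError:
        raise InvalidLabelError(f"unknown fine-task label {label2!r}") from None


def clinical_priors() -> np.ndarray:
    """Fine-class prior emulating a clinical 12-lead corpus.

    Normal rhythm dominates at 61.10%, sinus arrhythmia 18.14%, atrial
    arrhythmia 7.72%; the remaining twelve classes share the residual
    13.04% equally.
    """
    p = np.full(len(TASK2_CLASSES), 0.1304 / 12)
    p[TASK2_INDEX["N"]] = 0.6110
    p[TASK2_INDEX["SA"]] = 0.1814
    p[TASK2_INDEX["AA"]] = 0.0772
    return p / p.sum()
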