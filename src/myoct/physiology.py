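"""Non-imaging per-animal computations.

HOMA-IR insulin-resistance index, grip-strength summarization, and the
SAF-style liver disease label from Kleiner histology sub-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["DiseaseLabel", "homa_ir", "grip_strength_summary", "classify_liver"]


@dataclass(frozen=True)
class DiseaseLabel:
    """Liver disease label derived from the Kleiner sub-scores."""

    steatosis: int
    inflammation: int
    ballooning: int
    nas_total: int
    label: str  # "normal" | "NAFL" | "NASH"


def homa_ir(glycaemia: float, insulinaemia: float) -> float:
    """Homeostatic model assessment of insulin resistance.

    ``glycaemia (mmol/L) × insulinaemia (mU/L) / 22.5``.
    """
    if glycaemia < 0 or insulinaemia < 0:
        raise ValueError("glycaemia and insulinaemia must be non-negative")
    return glycaemia * insulinaemia / 22.5


def grip_strength_summary(trials: Sequence[float]) -> float:
    """Mean of the two highest absolute-force values across pooled trials.

    Trials from the initial session and the 20-minute retest are pooled;
    at least two trials are required.
    """
    if len(trials) < 2:
        raise ValueError("grip strength requires at least two trials")
    top_two = sorted(trials, reverse=True)[:2]
    return (top_two[0] + top_two[1]) / 2.0


def classify_liver(steatosis: int, inflammation: int, ballooning: int) -> DiseaseLabel:
    """SAF-style liver label from Kleiner sub-scores.

    NASH requires a NAFLD activity score (NAS = steatosis + inflammation +
    ballooning) of at least 3 with at least 1 point in *each* sub-score;
    otherwise any steatosis means NAFL; otherwise the liver is normal.
    """
    ranges = {"steatosis": (steatosis, 3), "inflammation": (inflammation, 3), "ballooning": (ballooning, 2)}
    for name, (val, hi) in ranges.items():
        if not isinstance(val, (int,)) or not 0 <= val <= hi:
            raise ValueError(f"{name}={val} outside 0..{hi}")
    nas = steatosis + inflammation + ballooning
    if nas >= 3 and min(steatosis, inflammation, ballooning) >= 1:
        label = "NASH"
    elif steatosis >= 1:
        label = "NAFL"
    else:
        label = "normal"
    return DiseaseLabel(steatosis, inflammation, ballooning, nas, label)
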