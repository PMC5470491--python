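"""Cohort evaluation: run the localizer over phantoms and score hits.

A phantom counts as a hit when an accepted focus-of-attention center falls
inside the ground-truth lesion mask — the weakest defensible reading of
"successful localization", since the circle is a seed for segmentation, not
a contour.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .config import PipelineConfig
from .localization import localize
from .phantom import Phantom

__all__ = ["cohort_hit_rate"]


def cohort_hit_rate(phantoms: Iterable[Phantom],
                    config: Optional[PipelineConfig] = None) -> float:
    """Fraction of phantoms whose accepted FOA center lies in the lesion."""
    config = config or PipelineConfig()
    kwargs = config.localize_kwargs()
    hits = 0
    total = 0
    for ph in phantoms:
        total += 1
        result = localize(ph.image, ph.image, ph.image, **kwargs)
        foa = result.accepted_foa
        if foa is not None and ph.lesion_mask[foa.row, foa.col]:
            hits += 1
    if total == 0:
        raise ValueError("empty cohort")
    return hits / total
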