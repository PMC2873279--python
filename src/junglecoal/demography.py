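"""Demographic parameters of the three-species model ((C,R),G).

All quantities are on the per-site mutation scale: theta = 4*Ne*mu*g is the
expected pairwise diversity within a population, tau = t_s*mu is the expected
number of substitutions per site per lineage since a species split.  C, R and
G denote domestic chickens, red junglefowl and green junglefowl.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

PARAM_NAMES = (
    "theta_c",
    "theta_r",
    "theta_g",
    "theta_cr",
    "theta_rcg",
    "tau_cr",
    "tau_rcg",
)


@dataclass(frozen=True)
class DemographyParams:
    """theta/tau parameter set for the fixed species tree ((C,R),G).

    theta_c/theta_r/theta_g are the extant scaled diversities, theta_cr and
    theta_rcg the ancestral ones, tau_cr and tau_rcg the two split times.
    Invariant: everything non-negative and tau_cr <= tau_rcg.
    """

    theta_c: float
    theta_r: float
    theta_g: float
    theta_cr: float
    theta_rcg: float
    tau_cr: float
    tau_rcg: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if self.tau_cr > self.tau_rcg:
            raise ValueError(
                f"tau_cr ({self.tau_cr}) must not exceed tau_rcg ({self.tau_rcg})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "DemographyParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, a))))


#: Point estimates from the three-species posterior with the two introgressed
#: green-junglefowl birds excluded; used as the default simulation truth.
STUDY_TRUTH = DemographyParams(
    theta_c=0.0026,
    theta_r=0.0011,
    theta_g=0.0034,
    theta_cr=0.0071,
    theta_rcg=0.0161,
    tau_cr=0.0001,
    tau_rcg=0.0063,
)

#: Aligned lengths (bp) of the 30 sequenced introns, in catalog order.
INTRON_LENGTHS_30 = (
    376, 821, 416, 801, 315, 529, 485, 312, 665, 1335,
    449, 286, 698, 571, 1121, 613, 358, 351, 513, 477,
    708, 528, 227, 381, 879, 1006, 561, 625, 957, 676,
)

# Default 26-locus set: autosomal introns with complete three-species data,
# omitting the Z-linked intron, the two introns never recovered from green
# junglefowl and the 1,335-bp outlier.
_EXCLUDED = {3, 9, 17, 28}  # 0-based indices of introns 4, 10, 18, 29
LOCUS_LENGTHS_26 = tuple(
    length for i, length in enumerate(INTRON_LENGTHS_30) if i not in _EXCLUDED
)
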