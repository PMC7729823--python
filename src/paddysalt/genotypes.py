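"""Shipped salinity-response parameter sets for the reference genotypes.

Greenhouse-derived logistic parameters (a: slope at the inflection point,
per dS/m; b: EC at 50% loss, dS/m) for photosynthesis (pn) and
transpiration (tr) of three contrasting indica varieties: IR64 (moderately
tolerant), IR29 (sensitive) and BRRI Dhan47 (tolerant).
"""

from __future__ import annotations

from .salinity import SalinityParams

GENOTYPES = {
    "IR64": SalinityParams("IR64", a_pn=0.21, b_pn=11.17, a_tr=0.21, b_tr=7.83),
    "IR29": SalinityParams("IR29", a_pn=0.31, b_pn=11.08, a_tr=0.31, b_tr=6.83),
    "BRRI Dhan47": SalinityParams(
        "BRRI Dhan47", a_pn=0.21, b_pn=15.15, a_tr=0.21, b_tr=12.30
    ),
}


def get_genotype(name: str) -> SalinityParams:
    """Look up a shipped genotype, tolerant of spacing/case variants."""
    key = name.replace(" ", "").replace("-", "").lower()
    for canonical, params in GENOTYPES.items():
        if canonical.replace(" ", "").lower() == key:
            return params
    raise KeyError(
        f"unknown genotype {name!r}; shipped genotypes: {sorted(GENOTYPES)}"
    )
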