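"""Named analysis presets bundling filter thresholds with rare-haplotype rules.

``3krgp``   — resequencing-panel regime: het→missing, SNP missing >0.2 and
              sample missing >0.2 dropped, MAF <0.001 dropped; haplotypes in
              fewer than 30 samples are rare.
``hdra-us`` — array/U.S.-panel regime: SNP missing >0.15, sample missing
              >0.2, MAF <0.02 and monomorphic SNPs dropped; haplotypes under
              5% panel frequency are rare.
"""

from __future__ import annotations

from .filtering import FilterParams
from .haplotyping import RareRule

PRESETS: dict[str, tuple[FilterParams, RareRule]] = {
    "3krgp": (FilterParams.preset("3krgp"), RareRule("min_count", 30)),
    "hdra-us": (FilterParams.preset("hdra-us"), RareRule("min_frequency", 0.05)),
}


def get_preset(name: str) -> tuple[FilterParams, RareRule]:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
        ) from None
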