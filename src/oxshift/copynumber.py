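"""mtDNA copy number per diploid cell from duplex qPCR.

A mitochondrial amplicon (MT-TL1) and a single-copy nuclear amplicon (B2M)
are quantified in the same reaction; a plasmid carrying both amplicons at a
1:1 ratio calibrates the assay.  With amplification base E (2 = perfect
doubling per cycle),

    CN = 2 * E ** (-ddCq),   ddCq = (Cq_mt - Cq_n)_sample - (Cq_mt - Cq_n)_plasmid

The factor 2 converts "per haploid genome equivalent" to "per diploid cell".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QpcrMeasurement", "mt_copy_number", "cn_ratio"]


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    cq_mt: float
    cq_n: float
    plasmid_cq_mt: float
    plasmid_cq_n: float
    efficiency_base: float = 2.0

    def __post_init__(self):
        for name in ("cq_mt", "cq_n", "plasmid_cq_mt", "plasmid_cq_n"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (1.0 < self.efficiency_base <= 2.0):
            raise ValueError(
                f"efficiency base must be in (1, 2], got {self.efficiency_base}"
            )

    @property
    def ddcq(self) -> float:
        return (self.cq_mt - self.cq_n) - (self.plasmid_cq_mt - self.plasmid_cq_n)


def mt_copy_number(m: QpcrMeasurement) -> float:
    """mtDNA copies per diploid cell, ``2 * E ** (-ddCq)``."""
    return 2.0 * m.efficiency_base ** (-m.ddcq)


def cn_ratio(tumor_cn: float, benign_cn: float) -> float:
    """Tumor/benign copy-number ratio."""
    if benign_cn <= 0:
        raise ValueError(f"benign copy number must be positive, got {benign_cn}")
    return tumor_cn / benign_cn
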