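"""Autosome physical-length tables.

The simulator's crossover model draws per-chromosome recombination counts
from a Poisson distribution whose mean is the chromosome's physical length
in megabases divided by 100 (the ~1 cM/Mb rule of thumb for cattle).  The
packaged table holds the 29 bovine autosomes on UMD3.1 coordinates;
synthetic tables with arbitrary labels/lengths are equally valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# UMD3.1 bovine autosome lengths in base pairs (chromosome 1..29).
UMD31_AUTOSOME_BP: dict[str, int] = {
    "1": 158_337_067,
    "2": 137_060_424,
    "3": 121_430_405,
    "4": 120_829_699,
    "5": 121_191_424,
    "6": 119_458_736,
    "7": 112_638_659,
    "8": 113_384_836,
    "9": 105_708_250,
    "10": 104_305_016,
    "11": 107_310_763,
    "12": 91_163_125,
    "13": 84_240_350,
    "14": 84_648_390,
    "15": 85_296_676,
    "16": 81_724_687,
    "17": 75_158_596,
    "18": 66_004_023,
    "19": 64_057_457,
    "20": 72_042_655,
    "21": 71_599_096,
    "22": 61_435_874,
    "23": 52_530_062,
    "24": 62_714_930,
    "25": 42_904_170,
    "26": 51_681_464,
    "27": 45_407_902,
    "28": 46_312_546,
    "29": 51_505_224,
}


@dataclass(frozen=True)
class ChromosomeTable:
    """Ordered autosome labels with physical lengths in megabases."""

    labels: tuple[str, ...]
    lengths_mb: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.lengths_mb):
            raise ValueError("labels and lengths differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate chromosome labels")
        if any(l <= 0 for l in self.lengths_mb):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_bp(cls, lengths_bp: dict[str, int]) -> "ChromosomeTable":
        return cls(tuple(lengths_bp), tuple(bp / 1e6 for bp in lengths_bp.values()))

    @classmethod
    def umd31(cls) -> "ChromosomeTable":
        """The 29 bovine autosomes on UMD3.1 coordinates."""
        return cls.from_bp(UMD31_AUTOSOME_BP)

    def __len__(self) -> int:
        return len(self.labels)

    def length_mb(self, label: str) -> float:
        return self.lengths_mb[self.labels.index(label)]

    def length_bp(self, label: str) -> int:
        return int(round(self.length_mb(label) * 1e6))

    @property
    def total_mb(self) -> float:
        return float(np.sum(self.lengths_mb))

    def crossover_means(self) -> np.ndarray:
        """Poisson mean crossover count per chromosome: length_Mb / 100."""
        return np.asarray(self.lengths_mb, dtype=float) / 100.0
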