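"""Trinucleotide spectra at splice sites and their background enrichment.

Nomenclature is intron-centric: the "3' splice site" is the acceptor
junction at the *start* of the exon (downstream end of the upstream
intron), and the "5' splice site" is the donor junction at the *end* of the
exon — both in transcription orientation.  Two window conventions are
supported: ``exonic`` reads the three exonic bases adjacent to each
junction (the default), ``intronic`` the three intronic bases on the other
side of the junction.  Exons whose windows contain N (or fall outside the
chromosome) are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (ExonRecord, GenomeSequence, GenomicInterval,
                         fetch_oriented, reverse_complement)

FIVE_PRIME = "five_prime"    # donor side: exon end
THREE_PRIME = "three_prime"  # acceptor side: exon start
EXONIC = "exonic"
INTRONIC = "intronic"

TRINUCLEOTIDES: List[str] = ["".join(p) for p in product("ACGT", repeat=3)]
_TRI_INDEX: Dict[str, int] = {t: i for i, t in enumerate(TRINUCLEOTIDES)}


@dataclass
class TrinucleotideSpectrum:
    side: str
    convention: str
    counts: np.ndarray          # 64 ints, lexicographic over ACGT
    n_excluded: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.full(64, np.nan)
        return self.counts / total

    def frequency(self, tri: str) -> float:
        return float(self.frequencies[_TRI_INDEX[tri.upper()]])


@dataclass
class EnrichmentVector:
    side: str
    convention: str
    ratios: np.ndarray   # 64 floats, NaN where undefined
    defined: np.ndarray  # 64 bools

    def ratio(self, tri: str) -> float:
        return float(self.ratios[_TRI_INDEX[tri.upper()]])

    def to_frame(self, target: TrinucleotideSpectrum,
                 background: TrinucleotideSpectrum) -> pd.DataFrame:
        return pd.DataFrame({
            "trinucleotide": TRINUCLEOTIDES,
            "side": self.side,
            "target_freq": target.frequencies,
            "background_freq": background.frequencies,
            "enrichment": self.ratios,
            "defined": self.defined,
        })


def site_trinucleotides(exon: GenomicInterval, genome: GenomeSequence,
                        convention: str = EXONIC) -> Tuple[Optional[str], Optional[str]]:
    """(acceptor-side, donor-side) trinucleotide for one exon, or None.

    ``exonic``: first / last three exonic bases.  ``intronic``: the three
    intronic bases immediately across each junction.  A window containing N
    or extending past the chromosome returns None for that side.
    """
    if convention not in (EXONIC, INTRONIC):
        raise ValueError(f"unknown convention {convention!r}")
    if convention == EXONIC:
        if exon.length < 3:
            return None, None
        seq = fetch_oriented(genome, exon)
        three, five = seq[:3], seq[-3:]
    else:
        chrom_len = genome.length(exon.chrom)

        def fetch(start: int, end: int) -> Optional[str]:
            if start < 0 or end > chrom_len:
                return None
            s = genome.fetch(exon.chrom, start, end)
            return reverse_complement(s) if exon.strand == "-" else s

        if exon.strand == "+":
            three = fetch(exon.start - 3, exon.start)
            five = fetch(exon.end, exon.end + 3)
        else:
            three = fetch(exon.end, exon.end + 3)
            five = fetch(exon.start - 3, exon.start)
    three = None if (three is None or "N" in three) else three
    five = None if (five is None or "N" in five) else five
    return three, five


def spectrum(exons: Sequence[ExonRecord | GenomicInterval],
             genome: GenomeSequence, side: str,
             convention: str = EXONIC) -> TrinucleotideSpectrum:
    """Trinucleotide counts on one splice-site side over an exon set."""
    if side not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown side {side!r}")
    intervals = [e.interval if isinstance(e, ExonRecord) else e for e in exons]
    if not intervals:
        raise ValueError("empty exon set")
    counts = np.zeros(64, dtype=np.int64)
    excluded = 0
    for iv in intervals:
        three, five = site_trinucleotides(iv, genome, convention=convention)
        tri = three if side == THREE_PRIME else five
        if tri is None:
            excluded += 1
        else:
            counts[_TRI_INDEX[tri]] += 1
    if counts.sum() == 0:
        raise ValueError("all exons excluded from spectrum")
    return TrinucleotideSpectrum(side=side, convention=convention,
                                 counts=counts, n_excluded=excluded)


def enrichment(target: TrinucleotideSpectrum,
               background: TrinucleotideSpectrum) -> EnrichmentVector:
    """Elementwise target/background frequency ratio; 0-background -> undefined."""
    if target.side != background.side or target.convention != background.convention:
        raise ValueError("target and background spectra use different side/convention")
    bg = background.frequencies
    tg = target.frequencies
    defined = bg > 0
    ratios = np.full(64, np.nan)
    ratios[defined] = tg[defined] / bg[defined]
    return EnrichmentVector(side=target.side, convention=target.convention,
                            ratios=ratios, defined=defined)
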