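"""QC of reconstructed ancestry mosaics and per-individual summaries.

Reconstructed hybrid genomes over-represent short (<1 Mb) ancestry
segments. The cleanup applied here mirrors the downstream handling of such
reconstructions: a single short segment flanked by the same founder on both
sides is bridged over (absorbed, no recombination counted); any remaining
maximal run of consecutive short segments is collapsed into one UNKNOWN
segment, which counts as a single parental segment for recombination
purposes and is treated as missing data for genotypes.

Conventions (documented decisions):
- "short" is strictly less than min_len; an exactly-1 Mb segment is kept;
- UNKNOWN segments are never considered short (this makes cleanup
  idempotent);
- a short segment at a chromosome end is masked to UNKNOWN, never bridged;
- bridging restores the interval to the flanking founder (genotypes there
  follow that founder); masked intervals stay missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import NUCLEAR_ARMS
from .synth import UNKNOWN, GenotypeMatrix, MosaicGenome, Segment, _merge_segments


@dataclass
class CleanupReport:
    individual_id: str
    n_segments_before: int = 0
    n_segments_after: int = 0
    n_masked_bp: int = 0
    n_bridged: int = 0
    n_unknown_segments: int = 0
    recombination_count: dict[str, int] = field(default_factory=dict)


def _seg_len(seg: Segment) -> int:
    return seg[1] - seg[0] + 1


def _is_short(seg: Segment, min_len: int) -> bool:
    return seg[2] != UNKNOWN and _seg_len(seg) < min_len


def _clean_haplotype(segs: list[Segment], min_len: int) -> tuple[list[Segment], int, int]:
    """Returns (cleaned segments, n_bridged, masked bp)."""
    # bridging pass: single short segment, identical non-short flanks
    segs = list(segs)
    n_bridged = 0
    i = 1
    while i < len(segs) - 1:
        prev, cur, nxt = segs[i - 1], segs[i], segs[i + 1]
        if (
            _is_short(cur, min_len)
            and not _is_short(prev, min_len)
            and not _is_short(nxt, min_len)
            and prev[2] == nxt[2]
        ):
            segs[i - 1 : i + 2] = [(prev[0], nxt[1], prev[2])]
            n_bridged += 1
            if i > 1:
                i -= 1  # merged segment may now flank another short one
        else:
            i += 1
    # grouping pass: maximal runs of consecutive short segments -> UNKNOWN
    out: list[Segment] = []
    masked_bp = 0
    j = 0
    while j < len(segs):
        if _is_short(segs[j], min_len):
            k = j
            while k + 1 < len(segs) and _is_short(segs[k + 1], min_len):
                k += 1
            out.append((segs[j][0], segs[k][1], UNKNOWN))
            masked_bp += segs[k][1] - segs[j][0] + 1
            j = k + 1
        else:
            out.append(segs[j])
            j += 1
    return _merge_segments(out), n_bridged, masked_bp


def clean_mosaic(mosaic: MosaicGenome, min_len: int = 1_000_000) -> tuple[MosaicGenome, CleanupReport]:
    """Apply bridging then short-run grouping to every haplotype of a mosaic."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    report = CleanupReport(individual_id=mosaic.individual_id)
    new_haps: dict[str, list[list[Segment]]] = {}
    for arm, haps in mosaic.haplotypes.items():
        cleaned_haps = []
        rec = 0
        for hap in haps:
            report.n_segments_before += len(hap)
            cleaned, nb, masked = _clean_haplotype(hap, min_len)
            report.n_bridged += nb
            report.n_masked_bp += masked
            report.n_segments_after += len(cleaned)
            report.n_unknown_segments += sum(1 for s in cleaned if s[2] == UNKNOWN)
            rec += len(cleaned) - 1
            cleaned_haps.append(cleaned)
        new_haps[arm] = cleaned_haps
        report.recombination_count[arm] = rec
    out = MosaicGenome(
        individual_id=mosaic.individual_id,
        generation=mosaic.generation,
        population=mosaic.population,
        sex=mosaic.sex,
        haplotypes=new_haps,
    )
    return out, report


def count_recombinations(mosaic: MosaicGenome) -> dict[str, list[int]]:
    """Per arm, per haploid copy: (number of segments) - 1.

    Assumes UNKNOWN runs were already collapsed by clean_mosaic, so each
    UNKNOWN segment counts as one parental segment.
    """
    return {arm: [len(h) - 1 for h in haps] for arm, haps in mosaic.haplotypes.items()}


def segment_lengths(mosaics: Sequence[MosaicGenome], include_unknown: bool = True) -> np.ndarray:
    """All haploid ancestry-segment lengths (bp) across individuals and arms."""
    out = [
        _seg_len(seg)
        for m in mosaics
        for haps in m.haplotypes.values()
        for hap in haps
        for seg in hap
        if include_unknown or seg[2] != UNKNOWN
    ]
    return np.asarray(out, dtype=np.int64)


def short_segment_fraction(mosaics: Sequence[MosaicGenome], min_len: int = 1_000_000) -> float:
    """Fraction of ancestry segments shorter than min_len."""
    lens = segment_lengths(mosaics)
    if lens.size == 0:
        raise ValueError("no segments")
    return float(np.mean(lens < min_len))


def reconstruction_accuracy(
    reconstructed: np.ndarray,
    truth: np.ndarray,
    founder_het_or_missing_mask: np.ndarray | None = None,
) -> float:
    """Proportion of comparable sites with identical dosage.

    Comparable sites exclude the founder het/missing mask and sites missing
    (-1) in either row; returns NaN (with a warning) when no comparable
    sites remain.
    """
    reconstructed = np.asarray(reconstructed)
    truth = np.asarray(truth)
    if reconstructed.shape != truth.shape:
        raise ValueError("length mismatch between reconstructed and truth rows")
    comparable = (reconstructed >= 0) & (truth >= 0)
    if founder_het_or_missing_mask is not None:
        comparable &= ~np.asarray(founder_het_or_missing_mask, dtype=bool)
    if not comparable.any():
        warnings.warn("no comparable sites; accuracy undefined", stacklevel=2)
        return float("nan")
    return float(np.mean(reconstructed[comparable] == truth[comparable]))


def founder_contributions(
    mosaics: Sequence[MosaicGenome], n_founders: int | None = None
) -> pd.DataFrame:
    """Per-individual genome-wide founder ancestry proportions.

    Columns are founder indices plus "UNKNOWN"; rows sum to 1. Hemizygous
    arms contribute their single haplotype once.
    """
    if len(mosaics) == 0:
        raise ValueError("empty sample")
    if n_founders is None:
        n_founders = 1 + max(
            (f for m in mosaics for haps in m.haplotypes.values() for h in haps for _, _, f in h if f != UNKNOWN),
            default=-1,
        )
    rows = []
    ids = []
    for m in mosaics:
        bp = np.zeros(n_founders + 1)  # last column = UNKNOWN
        for haps in m.haplotypes.values():
            for hap in haps:
                for s, e, f in hap:
                    bp[f if f != UNKNOWN else n_founders] += e - s + 1
        rows.append(bp / bp.sum())
        ids.append(m.individual_id)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="individual_id"))
    df.columns = [*range(n_founders), "UNKNOWN"]
    return df


def contribution_summary(contrib: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/range of per-line contributions across individuals."""
    founders = [c for c in contrib.columns if c != "UNKNOWN"]
    per_line = contrib[founders]
    return pd.DataFrame(
        {
            "mean": per_line.mean(axis=0),
            "median": per_line.median(axis=0),
            "min": per_line.min(axis=0),
            "max": per_line.max(axis=0),
        }
    )


def infer_wolbachia(
    wolbachia_reads: int,
    nuclear_reads: int | Mapping[str, int],
    threshold: float = 0.001,
) -> bool:
    """Infected iff Wolbachia/nuclear read ratio exceeds the 1:1000 threshold.

    The nuclear denominator is restricted to the five major arms (2L, 2R,
    3L, 3R, X) when a per-contig mapping is given.
    """
    if isinstance(nuclear_reads, Mapping):
        denom = sum(int(nuclear_reads.get(a, 0)) for a in NUCLEAR_ARMS)
    else:
        denom = int(nuclear_reads)
    if denom <= 0:
        raise ValueError("nuclear read count must be positive")
    return wolbachia_reads / denom > threshold


def classify_read_ratios(read_ratio: np.ndarray, threshold: float = 0.001) -> np.ndarray:
    """Vectorized Wolbachia classification from precomputed read ratios."""
    return np.asarray(read_ratio) > threshold
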