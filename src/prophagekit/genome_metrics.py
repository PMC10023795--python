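"""GC content, prophage genome fraction, phage-plasmid flagging, size binning,
and the rank-sum comparisons used for prophage-vs-host contrasts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ProphageRegion, Replicon

#: >50% of a plasmid covered by prophage sequence flags a putative phage-plasmid.
PHAGE_PLASMID_FRACTION = 50.0


@dataclass(frozen=True)
class GcRecord:
    entity_id: str
    gc_percent: float
    n_acgt_bases: int


@dataclass(frozen=True)
class FractionRecord:
    replicon_id: str
    prophage_bp: int
    replicon_bp: int
    fraction_percent: float
    is_phage_plasmid: bool


def gc_content(sequence: str) -> float:
    """Percent G+C over unambiguous A/C/G/T bases only."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no A/C/G/T content")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def gc_record(entity_id: str, sequence: str) -> GcRecord:
    seq = sequence.upper()
    n = sum(seq.count(b) for b in "ACGT")
    return GcRecord(entity_id, gc_content(sequence), n)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def prophage_fraction(replicon: Replicon, regions: Sequence[ProphageRegion]) -> FractionRecord:
    """Fraction of a replicon covered by (overlap-merged) prophage regions.

    Plasmids covered more than 50% are flagged as putative phage-plasmids.
    """
    length = len(replicon)
    for r in regions:
        if r.replicon_id != replicon.replicon_id:
            raise ValueError(f"region {r.region_id!r} not on replicon {replicon.replicon_id!r}")
        if r.end > length:
            raise ValueError(
                f"region {r.region_id!r} [{r.start}, {r.end}) exceeds replicon "
                f"length {length}"
            )
    merged = merge_intervals((r.start, r.end) for r in regions)
    covered = sum(e - s for s, e in merged)
    fraction = 100.0 * covered / length
    flagged = replicon.replicon_class == "plasmid" and fraction > PHAGE_PLASMID_FRACTION
    return FractionRecord(replicon.replicon_id, covered, length, fraction, flagged)


def bin_by_genome_size(
    replicon_lengths: Sequence[float],
    prophage_counts: Sequence[float],
    n_bins: int = 4,
) -> pd.DataFrame:
    """Mean prophage count per equal-width genome-size bin.

    Bins partition [min length, max length] into ``n_bins`` equal widths,
    half-open except the last, which is right-closed.  Empty bins report
    ``n=0`` and a NaN mean.  Identical lengths collapse into the first bin.
    """
    lengths = np.asarray(replicon_lengths, dtype=float)
    counts = np.asarray(prophage_counts, dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one genome")
    if lengths.shape != counts.shape:
        raise ValueError("lengths and counts must have equal length")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = lengths.min(), lengths.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    if hi == lo:
        idx = np.zeros(lengths.size, dtype=int)
    else:
        idx = np.minimum(((lengths - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(mask.sum()),
                "mean_prophages": float(counts[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def significance_code(p: float) -> str:
    """Map a p-value to the star codes used in the source figures."""
    if p <= 1e-4:
        return "****"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def rank_sum_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float, str]:
    """Two-sided rank-based comparison of two samples.

    Unpaired: Mann–Whitney U with tie-corrected normal approximation and
    continuity correction.  Paired: Wilcoxon signed-rank with zero
    differences dropped.  Returns ``(statistic, p_value, star code)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs at least one observation")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        diffs = a - b
        if np.all(diffs == 0):
            raise ValueError("degenerate paired comparison: all differences are zero")
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             alternative="two-sided", mode="approx")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p, significance_code(p)


def gc_compare(
    prophage_gc: Sequence[GcRecord],
    host_gc: Sequence[GcRecord],
    prophage_to_host: Mapping[str, str],
    paired: bool = False,
) -> tuple[pd.DataFrame, tuple[float, float, str]]:
    """Per-prophage GC delta versus host, plus a rank-sum test on the pooled
    GC distributions (unpaired by default)."""
    host_by_id = {r.entity_id: r for r in host_gc}
    rows = []
    for rec in prophage_gc:
        host_id = prophage_to_host.get(rec.entity_id)
        if host_id is None or host_id not in host_by_id:
            raise ValueError(f"prophage {rec.entity_id!r} does not join to a host GC record")
        rows.append(
            {
                "region_id": rec.entity_id,
                "replicon_id": host_id,
                "prophage_gc": rec.gc_percent,
                "host_gc": host_by_id[host_id].gc_percent,
                "delta_gc": rec.gc_percent - host_by_id[host_id].gc_percent,
            }
        )
    deltas = pd.DataFrame(rows)
    if len(prophage_gc) < 3:
        warnings.warn("fewer than 3 prophages: rank-sum p-value is unreliable",
                      stacklevel=2)
    if paired:
        hosts = [host_by_id[prophage_to_host[r.entity_id]].gc_percent for r in prophage_gc]
        test = rank_sum_test([r.gc_percent for r in prophage_gc], hosts, paired=True)
    else:
        test = rank_sum_test(
            [r.gc_percent for r in prophage_gc],
            [r.gc_percent for r in host_gc],
            paired=False,
        )
    return deltas, test
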