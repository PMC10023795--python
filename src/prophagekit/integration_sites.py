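"""Prophage position relative to the replication origin, ori/ter half
assignment, positional histograms, flank extraction and tRNA adjacency.

Positions are normalized as the interval midpoint divided by replicon
length, after rotating circular replicons so that oriC sits at 0%.  Linear
replicons are not rotated.  The ori half is 0–25% plus 75–100% of the
chromosome (the quarter on each side of the origin); replicons flagged
``central_ori`` (the Streptomyces linear-chromosome layout, oriC at the
center) invert the convention: ori is 25–75%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ani_cluster import GenomeCluster
from .genome_io import ProphageRegion, Replicon, TrnaGene

DEFAULT_FLANK = 2000
DEFAULT_TRNA_WINDOW = 2000


@dataclass(frozen=True)
class NormalizedPosition:
    region_id: str
    pos_percent: float  # in [0, 100)
    half: str  # "ori" | "ter"


@dataclass(frozen=True)
class FlankPair:
    region_id: str
    upstream_seq: str
    downstream_seq: str
    upstream_interval: tuple[int, int]
    downstream_interval: tuple[int, int]


def _half_for(pos_percent: float, central_ori: bool) -> str:
    in_outer = pos_percent < 25.0 or pos_percent >= 75.0
    if central_ori:
        return "ter" if in_outer else "ori"
    return "ori" if in_outer else "ter"


def normalize_position(region: ProphageRegion, replicon: Replicon) -> NormalizedPosition:
    """Origin-normalized midpoint position (percent of replicon length) and
    ori/ter half of one prophage."""
    length = len(replicon)
    if region.end > length:
        raise ValueError(f"region {region.region_id!r} exceeds replicon bounds")
    mid = region.midpoint
    if replicon.topology == "circular":
        pos = ((mid - replicon.oric_offset) % length) / length * 100.0
    else:
        pos = mid / length * 100.0
    return NormalizedPosition(region.region_id, pos, _half_for(pos, replicon.central_ori))


def position_histogram(
    positions: Sequence[NormalizedPosition],
    bin_width_percent: float = 5.0,
    labels: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Counts of prophages per position bin, plus ori/ter half totals.

    ``bin_width_percent`` must divide 100.  When per-region ``labels``
    (e.g. intact/remnant) are given, counts are split by label.
    """
    n_bins = 100.0 / bin_width_percent
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide 100")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    label_values = sorted(set(labels.values())) if labels else ["all"]
    counts = {lv: np.zeros(n_bins, dtype=int) for lv in label_values}
    for p in positions:
        b = min(int(p.pos_percent / bin_width_percent), n_bins - 1)
        lv = labels.get(p.region_id, "all") if labels else "all"
        if lv not in counts:
            counts[lv] = np.zeros(n_bins, dtype=int)
        counts[lv][b] += 1
    rows = {"bin_low": edges[:-1], "bin_high": edges[1:]}
    rows.update({lv: counts[lv] for lv in counts})
    df = pd.DataFrame(rows)
    totals = {
        "ori": sum(1 for p in positions if p.half == "ori"),
        "ter": sum(1 for p in positions if p.half == "ter"),
    }
    return df, totals


def extract_flanks(
    region: ProphageRegion,
    replicon: Replicon,
    flank: int = DEFAULT_FLANK,
) -> FlankPair:
    """The up-to-``flank`` bases upstream and downstream of a prophage.

    Circular replicons wrap across the origin (flank lengths capped so a
    flank never overlaps the prophage itself); linear replicons truncate at
    the chromosome ends, possibly yielding empty flanks.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    length = len(replicon)
    if region.end > length:
        raise ValueError(f"region {region.region_id!r} exceeds replicon bounds")
    seq = replicon.sequence
    if replicon.topology == "circular":
        avail = length - len(region)
        up_len = min(flank, avail)
        down_len = min(flank, avail)
        up_start = (region.start - up_len) % length
        upstream = _circular_slice(seq, up_start, up_len)
        down_start = region.end % length
        downstream = _circular_slice(seq, down_start, down_len)
        up_iv = (up_start, (up_start + up_len) % length or length)
        down_iv = (down_start, (down_start + down_len) % length or length)
    else:
        up_start = max(0, region.start - flank)
        upstream = seq[up_start:region.start]
        down_end = min(length, region.end + flank)
        downstream = seq[region.end:down_end]
        up_iv = (up_start, region.start)
        down_iv = (region.end, down_end)
    return FlankPair(region.region_id, upstream, downstream, up_iv, down_iv)


def _circular_slice(seq: str, start: int, n: int) -> str:
    if n == 0:
        return ""
    end = start + n
    if end <= len(seq):
        return seq[start:end]
    return seq[start:] + seq[: end - len(seq)]


def _linear_gap(region: ProphageRegion, gene: TrnaGene) -> int:
    if gene.end <= region.start:
        return region.start - gene.end
    if gene.start >= region.end:
        return gene.start - region.end
    return 0


def trna_adjacency(
    region: ProphageRegion,
    trna_genes: Sequence[TrnaGene],
    replicon: Replicon | None = None,
    window: int = DEFAULT_TRNA_WINDOW,
) -> tuple[bool, int | None]:
    """Whether any tRNA gene lies within ``window`` bp of the prophage.

    Returns ``(adjacent, nearest gap in bp)``; the gap is 0 when a tRNA
    overlaps the region and ``None`` when the replicon carries no tRNA.
    Distances wrap around circular replicons.
    """
    genes = [g for g in trna_genes if g.replicon_id == region.replicon_id]
    if not genes:
        return False, None
    circular = replicon is not None and replicon.topology == "circular"
    length = len(replicon) if replicon is not None else None
    best = None
    for g in genes:
        gap = _linear_gap(region, g)
        if circular and gap > 0:
            # the other way around the circle
            wrap = length - (max(g.end, region.end) - min(g.start, region.start))
            gap = min(gap, max(0, wrap))
        best = gap if best is None else min(best, gap)
    return best < window, best


def dereplicate_for_positions(
    positions: Sequence[NormalizedPosition],
    clusters: Sequence[GenomeCluster],
) -> list[NormalizedPosition]:
    """Keep only the positions of cluster representatives (removes redundancy
    from near-identical genomes before positional analysis)."""
    rep_ids = {c.representative_id for c in clusters}
    clustered = {m for c in clusters for m in c.member_ids}
    missing = [p.region_id for p in positions if p.region_id not in clustered]
    if missing:
        raise ValueError(f"positions not covered by any cluster: {sorted(missing)}")
    return [p for p in positions if p.region_id in rep_ids]
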