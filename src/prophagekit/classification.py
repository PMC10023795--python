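"""Intact/remnant/discarded prophage classification from conserved-domain content.

A prophage is called *intact* when it carries at least one integrase-class
domain and at least one structural domain (capsid, tail or portal), *remnant*
("cryptic") when it carries domains but misses one of those two requirements,
and *discarded* when no conserved domain at all was detected on it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .genome_io import DomainHit, ProphageRegion, normalize_accession

#: Integrase-class Pfam accessions: tyrosine recombinase "Phage_integrase"
#: and the rve integrase core domain, which belongs to the same functional
#: group of integrase proteins.
DEFAULT_INTEGRASE = frozenset({"pfam00589", "pfam00665"})

#: Structural (virion morphogenesis) accessions and their sub-category.
DEFAULT_STRUCTURAL: Mapping[str, str] = {
    "pfam05065": "capsid",   # phage capsid protein
    "pfam10145": "tail",     # phage minor tail protein
    "pfam05133": "portal",   # phage portal protein
    "pfam04860": "portal",   # phage portal protein
}

DEFAULT_EVALUE_MAX = 0.01


@dataclass(frozen=True)
class CategoryMap:
    """User-extensible mapping from Pfam accessions to functional categories."""

    integrase_accessions: frozenset[str] = DEFAULT_INTEGRASE
    structural_accessions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL)
    )

    def __post_init__(self) -> None:
        overlap = set(self.integrase_accessions) & set(self.structural_accessions)
        if overlap:
            raise ValueError(
                f"accessions in both integrase and structural sets: {sorted(overlap)}"
            )
        for cat in self.structural_accessions.values():
            if cat not in ("capsid", "tail", "portal"):
                raise ValueError(f"unknown structural sub-category {cat!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryMap":
        """Load a category map from a YAML config with keys ``integrase`` (list)
        and ``structural`` (mapping accession -> capsid/tail/portal)."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        integrase = frozenset(
            normalize_accession(a) for a in cfg.get("integrase", sorted(DEFAULT_INTEGRASE))
        )
        structural = {
            normalize_accession(a): c
            for a, c in cfg.get("structural", dict(DEFAULT_STRUCTURAL)).items()
        }
        return cls(integrase, structural)


@dataclass(frozen=True)
class ClassifiedProphage:
    region_id: str
    label: str  # intact | remnant | discarded
    n_integrase: int
    n_structural: int
    n_domains_total: int


def categorize_domain(hit: DomainHit, category_map: CategoryMap | None = None) -> str:
    """Assign a hit to integrase / capsid / tail / portal / other."""
    category_map = category_map or CategoryMap()
    acc = normalize_accession(hit.accession)
    if acc in category_map.integrase_accessions:
        return "integrase"
    return category_map.structural_accessions.get(acc, "other")


def filter_hits(hits: Iterable[DomainHit], evalue_max: float = DEFAULT_EVALUE_MAX) -> list[DomainHit]:
    """Drop hits whose e-value exceeds the retention cutoff."""
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    return [h for h in hits if h.evalue <= evalue_max]


def classify_prophage(
    region_id: str,
    hits: Sequence[DomainHit],
    category_map: CategoryMap | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> ClassifiedProphage:
    """Classify one prophage region from its retained domain hits.

    intact    — ≥1 integrase and ≥1 structural (capsid/tail/portal) domain
    remnant   — has domains but lacks the integrase or all structural domains
    discarded — no retained conserved domains at all
    """
    category_map = category_map or CategoryMap()
    retained = filter_hits(hits, evalue_max)
    for h in retained:
        if h.region_id != region_id:
            raise ValueError(
                f"hit for region {h.region_id!r} passed to classifier of {region_id!r}"
            )
    categories = Counter(categorize_domain(h, category_map) for h in retained)
    n_integrase = categories["integrase"]
    n_structural = categories["capsid"] + categories["tail"] + categories["portal"]
    total = len(retained)
    if total == 0:
        label = "discarded"
    elif n_integrase >= 1 and n_structural >= 1:
        label = "intact"
    else:
        label = "remnant"
    return ClassifiedProphage(region_id, label, n_integrase, n_structural, total)


def classify_dataset(
    regions: Sequence[ProphageRegion | str],
    hits: Iterable[DomainHit],
    category_map: CategoryMap | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> tuple[list[ClassifiedProphage], dict]:
    """Classify every region and summarize counts.

    Percentages of intact/remnant are computed over annotated (non-discarded)
    prophages; the discarded count is reported separately.  Returns
    ``(records, summary)``; an empty annotated set yields ``None`` percentages.
    """
    region_ids = [r if isinstance(r, str) else r.region_id for r in regions]
    known = set(region_ids)
    if len(known) != len(region_ids):
        raise ValueError("duplicate region ids in dataset")
    by_region: dict[str, list[DomainHit]] = defaultdict(list)
    unknown = set()
    for h in hits:
        if h.region_id not in known:
            unknown.add(h.region_id)
        by_region[h.region_id].append(h)
    if unknown:
        raise ValueError(f"hits reference unknown regions: {sorted(unknown)}")

    records = [
        classify_prophage(rid, by_region.get(rid, []), category_map, evalue_max)
        for rid in region_ids
    ]
    counts = Counter(r.label for r in records)
    n_annotated = counts["intact"] + counts["remnant"]
    summary = {
        "n_regions": len(records),
        "n_intact": counts["intact"],
        "n_remnant": counts["remnant"],
        "n_discarded": counts["discarded"],
        "n_annotated": n_annotated,
        "intact_percent": 100.0 * counts["intact"] / n_annotated if n_annotated else None,
        "remnant_percent": 100.0 * counts["remnant"] / n_annotated if n_annotated else None,
    }
    return records, summary


def top_domains(
    hits: Iterable[DomainHit],
    n: int = 20,
    dedupe_per_region: bool = True,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> pd.DataFrame:
    """Rank accessions by abundance across prophages.

    With ``dedupe_per_region`` (default) each accession counts at most once
    per prophage, i.e. the number of prophages carrying the domain.  Ties are
    broken by accession lexicographic order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    retained = filter_hits(hits, evalue_max)
    if dedupe_per_region:
        pairs = {(h.region_id, normalize_accession(h.accession)) for h in retained}
        counts = Counter(acc for _, acc in pairs)
    else:
        counts = Counter(normalize_accession(h.accession) for h in retained)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return pd.DataFrame(ranked, columns=["accession", "count"])


def go_tally(
    hits: Iterable[DomainHit],
    pfam2go: Mapping[str, set[str]],
    n: int = 20,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> pd.DataFrame:
    """Rank GO terms by the number of retained hits mapping to them.

    Every retained hit contributes one count to each GO term its accession
    maps to; unmapped accessions contribute nothing.  Ties break by GO id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: Counter[str] = Counter()
    for h in filter_hits(hits, evalue_max):
        for go in pfam2go.get(normalize_accession(h.accession), ()):
            counts[go] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return pd.DataFrame(ranked, columns=["go_term", "count"])
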