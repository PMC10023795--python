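"""Input/output for replicons, prophage regions, domain hits, tRNA genes and trees.

All coordinates are stored internally as 0-based half-open intervals; every
emitted table uses 1-based inclusive coordinates (GFF/NCBI convention).  The
conversion happens in exactly one place — the readers and writers in this
module — so downstream code never sees mixed conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

_PFAM2GO_LINE = re.compile(
    r"^Pfam:PF(?P<num>\d{5})\s+(?P<name>\S+)\s*>\s*GO:.*?;\s*(?P<go>GO:\d{7})\s*$"
)


@dataclass
class Replicon:
    """A host sequence (chromosome or plasmid): the coordinate frame for all analyses.

    ``oric_offset`` is the 0-based position of the replication origin on the
    stored sequence; if not given it defaults to 0 for circular replicons and
    to the sequence midpoint for linear ones (the Streptomyces-style
    central-origin layout).  ``central_ori`` switches the ori/ter half
    convention used by the integration-site analysis; it is an explicit flag
    rather than a genus-name heuristic.
    """

    replicon_id: str
    sequence: str
    topology: str = "circular"
    oric_offset: int | None = None
    replicon_class: str = "chromosome"
    host_genus: str = ""
    central_ori: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.replicon_id!r}: sequence is empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"replicon {self.replicon_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.replicon_class not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown replicon_class {self.replicon_class!r}")
        if self.oric_offset is None:
            self.oric_offset = 0 if self.topology == "circular" else len(self.sequence) // 2
        if not 0 <= self.oric_offset < len(self.sequence):
            raise ValueError(
                f"replicon {self.replicon_id!r}: oric_offset {self.oric_offset} "
                f"outside [0, {len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProphageRegion:
    """A predicted prophage interval (0-based half-open) on a replicon."""

    region_id: str
    replicon_id: str
    start: int
    end: int
    source: str = "predictor"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.region_id!r}: negative start")
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id!r}: empty or inverted interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain match on a prophage region.

    ``category`` (integrase/capsid/tail/portal/other) is assigned by the
    classification module, never by the parser.
    """

    region_id: str
    accession: str
    description: str = ""
    evalue: float = 0.0
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("domain hit with empty accession")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class TrnaGene:
    """A tRNA gene interval (0-based half-open) on a replicon."""

    replicon_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid tRNA interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]`` in file order.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids and empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Replicon metadata
# ---------------------------------------------------------------------------

def read_replicons(fasta_path: str | Path, meta_path: str | Path | None = None) -> list[Replicon]:
    """Join FASTA sequences with a metadata TSV into Replicon objects.

    The metadata table (columns ``replicon_id, topology, oric_offset,
    replicon_class, host_genus, central_ori``; all but replicon_id optional)
    supplies topology and origin positions; sequences without a metadata row
    get circular-chromosome defaults.
    """
    meta: dict[str, dict] = {}
    if meta_path is not None:
        df = pd.read_csv(meta_path, sep="\t", dtype={"replicon_id": str})
        if "replicon_id" not in df.columns:
            raise ValueError(f"{meta_path}: missing column replicon_id")
        for row in df.to_dict("records"):
            meta[str(row["replicon_id"])] = row
    replicons = []
    for name, seq in read_fasta(fasta_path):
        row = meta.get(name, {})
        row = {k: v for k, v in row.items() if not (isinstance(v, float) and pd.isna(v))}
        oric = row.get("oric_offset")
        replicons.append(
            Replicon(
                replicon_id=name,
                sequence=seq,
                topology=str(row.get("topology", "circular")),
                oric_offset=None if oric is None or pd.isna(oric) else int(oric),
                replicon_class=str(row.get("replicon_class", "chromosome")),
                host_genus=str(row.get("host_genus", "") or ""),
                central_ori=bool(row.get("central_ori", False)),
            )
        )
    return replicons


def write_replicon_meta(replicons: Iterable[Replicon], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "replicon_id": r.replicon_id,
                "topology": r.topology,
                "oric_offset": r.oric_offset,
                "replicon_class": r.replicon_class,
                "host_genus": r.host_genus,
                "central_ori": r.central_ori,
            }
            for r in replicons
        ],
        columns=["replicon_id", "topology", "oric_offset", "replicon_class",
                 "host_genus", "central_ori"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regions (TSV / GFF3)
# ---------------------------------------------------------------------------

def read_regions(path: str | Path, one_based: bool = False) -> list[ProphageRegion]:
    """Read a prophage-region table (TSV or GFF3) into internal coordinates.

    TSV input needs columns ``region_id, replicon_id, start, end`` (a
    ``source`` column is optional).  With ``one_based`` the input interval
    [s, e] inclusive maps to [s-1, e); GFF3 files are always 1-based
    inclusive regardless of the flag.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_regions_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "replicon_id": str})
    required = {"region_id", "replicon_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    regions = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if one_based:
            start -= 1
        source = getattr(row, "source", "predictor")
        regions.append(
            ProphageRegion(str(row.region_id), str(row.replicon_id), start, end,
                           source=str(source))
        )
    _check_unique_ids(regions)
    return regions


def _read_regions_gff3(path: Path) -> list[ProphageRegion]:
    regions = []
    counter = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, source, _type, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            counter += 1
            region_id = attrs.get("ID", f"{seqid}_region_{counter}")
            regions.append(
                ProphageRegion(region_id, seqid, int(start) - 1, int(end), source=source)
            )
    _check_unique_ids(regions)
    return regions


def _check_unique_ids(regions: Sequence[ProphageRegion]) -> None:
    seen: set[str] = set()
    for r in regions:
        if r.region_id in seen:
            raise ValueError(f"duplicate region_id {r.region_id!r}")
        seen.add(r.region_id)


def write_regions(regions: Iterable[ProphageRegion], path: str | Path) -> None:
    """Write regions as TSV with 1-based inclusive coordinates."""
    df = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "replicon_id": r.replicon_id,
                "start": r.start + 1,
                "end": r.end,
                "source": r.source,
            }
            for r in regions
        ],
        columns=["region_id", "replicon_id", "start", "end", "source"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Domain hits
# ---------------------------------------------------------------------------

def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a conserved-domain hit table (TSV: region_id, accession, description, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "accession": str})
    required = {"region_id", "accession", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        desc = getattr(row, "description", "")
        if pd.isna(desc):
            desc = ""
        hits.append(
            DomainHit(str(row.region_id), str(row.accession), str(desc), float(row.evalue))
        )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "region_id": h.region_id,
                "accession": h.accession,
                "description": h.description,
                "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=["region_id", "accession", "description", "evalue"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tRNA genes (GFF3)
# ---------------------------------------------------------------------------

def read_trna_gff(path: str | Path) -> list[TrnaGene]:
    """Read tRNA gene annotations from GFF3 (features of type tRNA)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            if fields[2] != "tRNA":
                continue
            strand = fields[6] if fields[6] in ("+", "-") else "+"
            genes.append(TrnaGene(fields[0], int(fields[3]) - 1, int(fields[4]), strand))
    return genes


def write_trna_gff(genes: Iterable[TrnaGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes, start=1):
            fh.write(
                f"{g.replicon_id}\tprophagekit\ttRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID=trna_{i}\n"
            )


# ---------------------------------------------------------------------------
# pfam2go
# ---------------------------------------------------------------------------

def read_pfam2go(path: str | Path) -> dict[str, set[str]]:
    """Parse a pfam2go mapping file into ``{"pfamNNNNN": {"GO:NNNNNNN", ...}}``.

    Keys are normalized to lower-case ``pfam`` + 5 digits.  Comment lines
    (starting with ``!``) are ignored; malformed lines are skipped with a
    logged warning.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            m = _PFAM2GO_LINE.match(line)
            if m is None:
                logger.warning("pfam2go %s:%d: skipping malformed line: %r", path, lineno, line)
                continue
            accession = f"pfam{m.group('num')}"
            mapping.setdefault(accession, set()).add(m.group("go"))
    return mapping


def normalize_accession(accession: str) -> str:
    """Normalize a Pfam accession to lower-case ``pfam`` + 5-digit form.

    Accepts ``PF00589``, ``Pfam:PF00589``, ``pfam00589`` and the like; any
    other accession string is lowercased and returned as-is.
    """
    acc = accession.strip()
    m = re.match(r"(?:pfam:)?(?:pf(?:am)?)(\d+)$", acc, flags=re.IGNORECASE)
    if m:
        return f"pfam{int(m.group(1)):05d}"
    return acc.lower()


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a tree (kmer_phylogeny.PhyloTree or skbio TreeNode) as Newick.

    Leaf labels containing whitespace or Newick metacharacters are
    underscore-escaped, consistently.  Trees with fewer than two leaves are
    rejected.
    """
    node = tree.root if hasattr(tree, "root") and not callable(tree.root) else tree
    tips = list(node.tips())
    if len(tips) < 2:
        raise ValueError("refusing to write a tree with fewer than 2 leaves")
    escaped = node.copy()
    for sub in escaped.traverse():
        if sub.is_tip() and sub.name is not None:
            sub.name = re.sub(r"[\s(),:;\[\]']", "_", sub.name)
        if sub.length is not None:
            # suppress float noise (0.30000000000000004 -> 0.3)
            sub.length = round(sub.length, 10)
    escaped.write(str(path), format="newick")
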