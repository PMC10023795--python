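"""Synthetic genomes with planted prophages and a full ground-truth table.

The generator emulates the structure of a lysogen survey: circular and
linear (central-origin) host chromosomes plus plasmids, prophages inserted
(not overwritten) into them with a lower GC than the host, a controllable
intact:remnant ratio realized through conserved-domain content, a positional
bias toward the replication terminus, tRNA genes at a controllable fraction
of integration boundaries, and mutated copies of reference phage genomes at
known nucleotide divergence.  Every stochastic choice is driven by one seed
and recorded in a truth table so each downstream stage can be scored
against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import CategoryMap
from .genome_io import (
    DomainHit,
    ProphageRegion,
    Replicon,
    TrnaGene,
    write_domain_hits,
    write_fasta,
    write_regions,
    write_replicon_meta,
    write_trna_gff,
)
from .integration_sites import normalize_position

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GENERA = ("Mycobacterium", "Corynebacterium", "Bifidobacterium", "Streptomyces")

#: Non-diagnostic accessions seen among the most abundant prophage domains
#: (phage repressors, antirepressors, host regulators, plasmid partitioning).
OTHER_ACCESSIONS = (
    "pfam01381",  # HTH_3 (CI/Cro-type repressor)
    "pfam12728",  # HTH_17
    "pfam03374",  # ANT/KilAC antirepressor
    "pfam02467",  # WhiB
    "pfam11774",  # Lsr2
    "pfam01656",  # ParA/CbiA
    "pfam02195",  # ParB
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror an actinobacterial lysogen survey: high-GC hosts,
    prophages ~5 points lower in GC, up to 8 prophages per genome, a modest
    terminus bias, tRNA genes at 15% of integration boundaries, and a small
    minority of prophages that are recognizable (2%-diverged) relatives of
    known reference phages.
    """

    seed: int = 0
    n_chromosomes: int = 12
    n_plasmids: int = 4
    host_length_range: tuple[int, int] = (1_000_000, 5_000_000)
    plasmid_length_range: tuple[int, int] = (30_000, 200_000)
    host_gc: float = 66.0
    host_gc_jitter: float = 2.0
    linear_fraction: float = 0.25
    prophage_gc_offset: float = -5.0
    prophage_size_range: tuple[int, int] = (5_000, 60_000)
    prophages_per_genome_range: tuple[int, int] = (0, 8)
    intact_fraction: float = 0.53
    discarded_fraction: float = 0.003
    ter_bias: float = 0.6
    trna_fraction: float = 0.15
    phage_relative_fraction: float = 0.1
    relative_divergence: float = 0.02
    n_phage_refs: int = 8
    phage_length_range: tuple[int, int] = (14_000, 80_000)

    def __post_init__(self) -> None:
        for name in ("intact_fraction", "discarded_fraction", "ter_bias",
                     "trna_fraction", "phage_relative_fraction", "linear_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("host_length_range", "plasmid_length_range",
                     "prophage_size_range", "prophages_per_genome_range",
                     "phage_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered: {(lo, hi)}")
        if not 0.0 <= self.relative_divergence < 1.0:
            raise ValueError("relative_divergence must be in [0, 1)")


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 200.0
    p = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])  # A C G T
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def generate_host(
    length: int,
    gc: float,
    topology: str = "circular",
    seed: int | np.random.Generator = 0,
    replicon_id: str = "chr_1",
    replicon_class: str = "chromosome",
    host_genus: str = "",
    central_ori: bool = False,
) -> Replicon:
    """I.i.d. host replicon at the requested GC (P(G)=P(C)=gc/200)."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0.0 < gc < 100.0:
        raise ValueError(f"gc must be in (0, 100), got {gc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Replicon(
        replicon_id=replicon_id,
        sequence=_random_bases(rng, length, gc),
        topology=topology,
        replicon_class=replicon_class,
        host_genus=host_genus,
        central_ori=central_ori,
    )


def mutate(sequence: str, rate: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute each A/C/G/T base independently with probability ``rate``
    (to a uniformly chosen *different* base); length-preserving, no indels."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return sequence
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    codes = code[arr]
    hit = (rng.random(arr.size) < rate) & (codes >= 0)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(codes[hit] + shift) % 4]
    return arr.tobytes().decode("ascii")


def _target_percent(rng: np.random.Generator, half: str, central_ori: bool) -> float:
    """Uniform position (percent) within the requested ori/ter half."""
    outer = (half == "ter") if central_ori else (half == "ori")
    u = rng.uniform(0.0, 50.0)
    if outer:
        return u + 75.0 if u >= 25.0 else u  # [0,25) U [75,100)
    return u + 25.0  # [25,75)


def plant_prophages(
    replicon: Replicon,
    config: SimConfig,
    phage_refs: Sequence[tuple[str, str]] = (),
    seed: int | np.random.Generator = 0,
    n_prophages: int | None = None,
) -> tuple[Replicon, list[ProphageRegion], list[dict], list[TrnaGene]]:
    """Insert prophages into a replicon and return the modified replicon,
    regions, truth rows and planted boundary tRNA genes.

    Prophage sequences are either synthesized at ``host_gc + offset`` or are
    mutated copies of reference phages.  Insertion points are drawn so the
    prophage midpoint lands in a half chosen with probability ``ter_bias``
    for ter; the *realized* half after all insertions (recomputed from final
    coordinates) is what the truth table records.  Insertions lengthen the
    sequence and never overlap.  tRNA genes (76 bp) are written at the
    upstream boundary of ``trna_fraction`` of the prophages.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.prophages_per_genome_range
    n = int(rng.integers(lo, hi + 1)) if n_prophages is None else n_prophages
    L0 = len(replicon)
    if n > max(0, L0 - 1):
        raise ValueError(f"cannot place {n} distinct insertion points on {L0} bp")
    if n == 0:
        return replicon, [], [], []

    drawn: list[tuple[str, dict, float]] = []  # (prophage_seq, meta, target %)
    for i in range(n):
        use_ref = bool(phage_refs) and rng.random() < config.phage_relative_fraction
        if use_ref:
            ref_id, ref_seq = phage_refs[int(rng.integers(len(phage_refs)))]
            pro_seq = mutate(ref_seq, config.relative_divergence, rng)
            meta = {"source_phage_id": ref_id, "divergence": config.relative_divergence}
        else:
            size = int(rng.integers(config.prophage_size_range[0],
                                    config.prophage_size_range[1] + 1))
            gc = config.host_gc + config.prophage_gc_offset
            pro_seq = _random_bases(rng, size, gc)
            meta = {"source_phage_id": "", "divergence": 0.0}

        want_ter = rng.random() < config.ter_bias
        half = "ter" if want_ter else "ori"
        u = _target_percent(rng, half, replicon.central_ori)
        meta["trna_flag"] = bool(rng.random() < config.trna_fraction)
        drawn.append((pro_seq, meta, u))

    # Convert target percentages (of the FINAL, post-insertion length) into
    # insertion anchors on the original sequence, so cumulative length growth
    # does not drag realized positions out of their drawn half.
    L_final = L0 + sum(len(seq) for seq, _, _ in drawn)
    targets = []
    for pro_seq, meta, u in drawn:
        if replicon.topology == "circular":
            mid_f = (replicon.oric_offset + u / 100.0 * L_final) % L_final
        else:
            mid_f = u / 100.0 * L_final
        targets.append((mid_f, pro_seq, meta))
    targets.sort(key=lambda t: t[0])
    pieces: list[tuple[int, str, dict]] = []
    cum = 0
    prev_anchor = 0
    for rank, (mid_f, pro_seq, meta) in enumerate(targets):
        remaining = n - rank - 1
        upper = L0 - 1 - remaining  # leave room for later insertion points
        if upper <= prev_anchor:
            raise ValueError("requested prophage mass exceeds feasible placement")
        anchor = int(mid_f) - cum - len(pro_seq) // 2
        anchor = min(max(anchor, prev_anchor + 1), upper)
        pieces.append((anchor, pro_seq, meta))
        prev_anchor = anchor
        cum += len(pro_seq)
    chunks: list[str] = []
    regions: list[ProphageRegion] = []
    truth_rows: list[dict] = []
    trna_genes: list[TrnaGene] = []
    prev = 0
    offset = 0
    for idx, (anchor, pro_seq, meta) in enumerate(pieces, start=1):
        chunks.append(replicon.sequence[prev:anchor])
        start = anchor + offset
        end = start + len(pro_seq)
        chunks.append(pro_seq)
        region_id = f"{replicon.replicon_id}_fragment_{idx}"
        regions.append(
            ProphageRegion(region_id, replicon.replicon_id, start, end, source="synthetic")
        )
        truth_rows.append({"region_id": region_id, **meta, "start": start, "end": end})
        prev = anchor
        offset += len(pro_seq)
    chunks.append(replicon.sequence[prev:])
    new_seq = "".join(chunks)

    new_oric = replicon.oric_offset
    for anchor, pro_seq, _ in pieces:
        if anchor <= replicon.oric_offset:
            new_oric += len(pro_seq)
    modified = replace(replicon, sequence=new_seq, oric_offset=new_oric)

    from .genome_metrics import gc_content  # deferred: avoid import cycle at module load

    for region, row in zip(regions, truth_rows):
        npos = normalize_position(region, modified)
        row.update(
            {
                "replicon_id": replicon.replicon_id,
                "length": len(region),
                "pos_percent": npos.pos_percent,
                "half": npos.half,
                "gc_planted": gc_content(new_seq[region.start:region.end]),
            }
        )
        if row["trna_flag"]:
            if region.start >= 80:
                trna_genes.append(
                    TrnaGene(replicon.replicon_id, region.start - 80, region.start - 4, "+")
                )
            else:
                trna_genes.append(
                    TrnaGene(replicon.replicon_id, region.end + 4, region.end + 80, "+")
                )
    return modified, regions, truth_rows, trna_genes


def generate_domains(
    truth_rows: list[dict],
    intact_fraction: float,
    category_map: CategoryMap | None = None,
    seed: int | np.random.Generator = 0,
    discarded_fraction: float = 0.0,
    evalue_max: float = 0.01,
) -> list[DomainHit]:
    """Draw a conserved-domain hit table realizing planted intact/remnant/
    discarded labels; writes the drawn label into each truth row.

    Intact prophages receive >=1 integrase and >=1 structural accession;
    remnant prophages miss one of the two; discarded prophages receive no
    hits.  All e-values fall below the retention cutoff.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    category_map = category_map or CategoryMap()
    integrase = sorted(category_map.integrase_accessions)
    structural = sorted(category_map.structural_accessions)
    hits: list[DomainHit] = []

    def evalue() -> float:
        return float(10.0 ** rng.uniform(-30, np.log10(evalue_max) - 0.5))

    def add(region_id: str, pool: Sequence[str], k: int) -> None:
        for _ in range(k):
            acc = pool[int(rng.integers(len(pool)))]
            hits.append(DomainHit(region_id, acc, "", evalue()))

    for row in truth_rows:
        rid = row["region_id"]
        r = rng.random()
        if r < discarded_fraction:
            row["label"] = "discarded"
            continue
        if r < discarded_fraction + (1 - discarded_fraction) * intact_fraction:
            row["label"] = "intact"
            add(rid, integrase, 1 + int(rng.integers(2)))
            add(rid, structural, 1 + int(rng.integers(3)))
            add(rid, OTHER_ACCESSIONS, int(rng.integers(5)))
        else:
            row["label"] = "remnant"
            mode = rng.random()
            if mode < 0.5:  # integrase present, no structural domain
                add(rid, integrase, 1 + int(rng.integers(2)))
                add(rid, OTHER_ACCESSIONS, int(rng.integers(1, 5)))
            elif mode < 0.85:  # structural present, no integrase
                add(rid, structural, 1 + int(rng.integers(2)))
                add(rid, OTHER_ACCESSIONS, int(rng.integers(5)))
            else:  # neither: only accessory domains
                add(rid, OTHER_ACCESSIONS, int(rng.integers(1, 6)))
    return hits


def emit_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate a mutually consistent file bundle and return its paths plus
    the in-memory objects.  Re-running with the same config is byte-identical.

    Files: hosts.fasta, replicons.tsv, phage_refs.fasta, regions.tsv
    (1-based inclusive), domains.tsv, trna.gff3, truth.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    phage_refs: list[tuple[str, str]] = []
    for i in range(config.n_phage_refs):
        length = int(rng.integers(config.phage_length_range[0],
                                  config.phage_length_range[1] + 1))
        gc = config.host_gc + config.prophage_gc_offset
        phage_refs.append((f"phage_{i + 1:03d}", _random_bases(rng, length, gc)))

    replicons: list[Replicon] = []
    all_regions: list[ProphageRegion] = []
    all_truth: list[dict] = []
    all_trna: list[TrnaGene] = []

    def build(replicon_id: str, length_range: tuple[int, int], replicon_class: str,
              genus: str, linear: bool) -> None:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = config.host_gc + float(rng.uniform(-config.host_gc_jitter,
                                                config.host_gc_jitter))
        host = generate_host(
            length, gc,
            topology="linear" if linear else "circular",
            seed=rng,
            replicon_id=replicon_id,
            replicon_class=replicon_class,
            host_genus=genus,
            central_ori=linear,
        )
        modified, regions, truth, trna = plant_prophages(host, config, phage_refs, rng)
        for row in truth:
            row["host_gc"] = gc
        replicons.append(modified)
        all_regions.extend(regions)
        all_truth.extend(truth)
        all_trna.extend(trna)

    for i in range(config.n_chromosomes):
        linear = rng.random() < config.linear_fraction
        genus = "Streptomyces" if linear else _GENERA[int(rng.integers(3))]
        build(f"chr_{i + 1:03d}", config.host_length_range, "chromosome", genus, linear)
    for i in range(config.n_plasmids):
        genus = _GENERA[int(rng.integers(3))]
        build(f"plasmid_{i + 1:03d}", config.plasmid_length_range, "plasmid", genus, False)

    domain_hits = generate_domains(
        all_truth, config.intact_fraction, seed=rng,
        discarded_fraction=config.discarded_fraction,
    )

    paths = {
        "hosts_fasta": out / "hosts.fasta",
        "replicon_meta": out / "replicons.tsv",
        "phage_refs_fasta": out / "phage_refs.fasta",
        "regions_tsv": out / "regions.tsv",
        "domains_tsv": out / "domains.tsv",
        "trna_gff": out / "trna.gff3",
        "truth_tsv": out / "truth.tsv",
    }
    write_fasta(((r.replicon_id, r.sequence) for r in replicons), paths["hosts_fasta"])
    write_replicon_meta(replicons, paths["replicon_meta"])
    write_fasta(phage_refs, paths["phage_refs_fasta"])
    write_regions(all_regions, paths["regions_tsv"])
    write_domain_hits(domain_hits, paths["domains_tsv"])
    write_trna_gff(all_trna, paths["trna_gff"])

    truth_df = pd.DataFrame(all_truth)
    if not truth_df.empty:
        truth_df = truth_df[
            ["region_id", "replicon_id", "start", "end", "length", "label",
             "gc_planted", "host_gc", "pos_percent", "half", "trna_flag",
             "source_phage_id", "divergence"]
        ].copy()
        # truth coordinates use the same 1-based inclusive convention as regions.tsv
        truth_df["start"] = truth_df["start"] + 1
    truth_df.to_csv(paths["truth_tsv"], sep="\t", index=False)

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "replicons": replicons,
        "regions": all_regions,
        "truth": truth_df,
        "domain_hits": domain_hits,
        "trna_genes": all_trna,
        "phage_refs": phage_refs,
    }
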