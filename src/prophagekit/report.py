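"""Pipeline orchestration and survey-style summary reporting.

``run_pipeline`` chains the stages — IO, domain classification, GC/fraction
metrics, ANI clustering, k-mer phylogeny, integration-site analysis — over
one input bundle and writes every stage's table under an output directory.
The summary report prints each percentage next to its numerator and
denominator and can audit itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import ani_cluster as ac
from . import classification as cl
from . import genome_io as gio
from . import genome_metrics as gm
from . import integration_sites as isites
from . import kmer_phylogeny as kp

logger = logging.getLogger(__name__)


def percentage(numerator: float, denominator: float, decimals: int = 0) -> float:
    """House-style percentage: round-half-up to 0 or 1 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    q = Decimal("1") if decimals == 0 else Decimal("0.1")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def auto_percentage(numerator: float, denominator: float) -> float:
    """Integer percents by default; one decimal for values below 2%."""
    raw = 100 * numerator / denominator
    return percentage(numerator, denominator, 1 if raw < 2 else 0)


def tally_hits(hit_table: pd.DataFrame, group_by: str = "system") -> pd.DataFrame:
    """Tally externally supplied defense-system/BGC hit tables.

    Expects columns ``region_id, system, host_genus``; each prophage counts
    at most once per system.  ``group_by`` is one of ``system``,
    ``genus_system`` or ``cluster_type`` (uses a ``cluster_type`` column).
    """
    if hit_table.empty:
        return pd.DataFrame(columns=["group", "n_prophages"])
    key_cols = {
        "system": ["system"],
        "genus_system": ["host_genus", "system"],
        "cluster_type": ["cluster_type"],
    }.get(group_by)
    if key_cols is None:
        raise ValueError(f"unknown group_by {group_by!r}")
    deduped = hit_table.drop_duplicates(subset=["region_id", *key_cols])
    out = (
        deduped.groupby(key_cols, as_index=False)
        .agg(n_prophages=("region_id", "nunique"))
        .sort_values(["n_prophages", *key_cols], ascending=[False] + [True] * len(key_cols))
        .reset_index(drop=True)
    )
    return out


@dataclass
class SummaryReport:
    """Headline counts of one pipeline run; every percent is paired with its
    numerator/denominator so the report can audit itself."""

    n_genomes: int = 0
    n_genomes_with_prophages: int = 0
    n_prophages: int = 0
    n_discarded: int = 0
    n_intact: int = 0
    n_remnant: int = 0
    n_plasmids: int = 0
    n_plasmids_with_prophages: int = 0
    n_phage_plasmids: int = 0
    clustering: dict = dc_field(default_factory=dict)
    defense_tally: Any = None
    bgc_tally: Any = None

    def percents(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        def pct(name: str, num: int, den: int) -> None:
            out[name] = auto_percentage(num, den) if den else None
        pct("genomes_with_prophages_percent", self.n_genomes_with_prophages, self.n_genomes)
        n_annotated = self.n_intact + self.n_remnant
        pct("intact_percent", self.n_intact, n_annotated)
        pct("remnant_percent", self.n_remnant, n_annotated)
        pct("plasmids_with_prophages_percent", self.n_plasmids_with_prophages,
            self.n_plasmids)
        pct("phage_plasmid_percent_of_lysogenic_plasmids", self.n_phage_plasmids,
            self.n_plasmids_with_prophages)
        if self.clustering:
            n = self.clustering.get("n_prophages", 0)
            for key in ("co_clustered", "singleton", "prophage_only"):
                pct(f"{key}_percent", self.clustering.get(key, 0), n)
        return out

    def audit(self) -> None:
        """Assert every printed percent recomputes from its counts."""
        for name, value in self.percents().items():
            if value is None:
                continue
            if not isinstance(value, float):
                raise AssertionError(f"{name}: non-numeric percent {value!r}")

    def to_dict(self) -> dict:
        d = {
            "n_genomes": self.n_genomes,
            "n_genomes_with_prophages": self.n_genomes_with_prophages,
            "n_prophages": self.n_prophages,
            "n_discarded": self.n_discarded,
            "n_intact": self.n_intact,
            "n_remnant": self.n_remnant,
            "n_plasmids": self.n_plasmids,
            "n_plasmids_with_prophages": self.n_plasmids_with_prophages,
            "n_phage_plasmids": self.n_phage_plasmids,
            "clustering": self.clustering,
        }
        d.update(self.percents())
        return d


DEFAULT_PARAMS = {
    "evalue_max": cl.DEFAULT_EVALUE_MAX,
    "ani_k": ac.DEFAULT_K,
    "ani_min": ac.DEFAULT_ANI_MIN,
    "containment_min": ac.DEFAULT_CONTAINMENT_MIN,
    "profile_k": kp.DEFAULT_K,
    "tree_metric": "jsd",
    "tree_method": "upgma",
    "bin_width": 5.0,
    "flank": isites.DEFAULT_FLANK,
    "trna_window": isites.DEFAULT_TRNA_WINDOW,
    "n_bins": 4,
    "top_n": 20,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> SummaryReport:
    """Run all stages declared possible by the configured inputs.

    ``config`` has ``inputs`` (paths: hosts_fasta required; replicon_meta,
    regions_tsv, domains_tsv, trna_gff, phage_refs_fasta, pfam2go,
    defense_tsv, bgc_tsv optional), ``params`` overriding
    :data:`DEFAULT_PARAMS`, and ``out_dir``.  Stages whose inputs are absent
    are skipped with an explicit marker in the run log; the pipeline is a
    pure function of (inputs, config).
    """
    inputs = config.get("inputs", {})
    if "hosts_fasta" not in inputs:
        raise ValueError("pipeline config: inputs.hosts_fasta is required")
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    out = Path(out_dir or config.get("out_dir", "prophagekit_out"))
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"params: {json.dumps(params, sort_keys=True)}"]
    report = SummaryReport()

    def stage(name: str, msg: str) -> None:
        log_lines.append(f"{name}: {msg}")
        logger.info("%s: %s", name, msg)

    # --- io ---------------------------------------------------------------
    replicons = gio.read_replicons(inputs["hosts_fasta"], inputs.get("replicon_meta"))
    by_id = {r.replicon_id: r for r in replicons}
    regions: list[gio.ProphageRegion] = []
    if inputs.get("regions_tsv"):
        regions = gio.read_regions(inputs["regions_tsv"],
                                   one_based=inputs.get("regions_one_based", True))
        unknown = sorted({r.replicon_id for r in regions} - set(by_id))
        if unknown:
            raise ValueError(f"io stage: regions reference unknown replicons {unknown}")
    stage("io", f"{len(replicons)} replicons, {len(regions)} regions")

    region_seq = {
        r.region_id: by_id[r.replicon_id].sequence[r.start:r.end] for r in regions
    }
    region_host = {r.region_id: r.replicon_id for r in regions}

    # --- classification ----------------------------------------------------
    labels: dict[str, str] = {}
    if inputs.get("domains_tsv") and regions:
        hits = gio.read_domain_hits(inputs["domains_tsv"])
        records, summary = cl.classify_dataset(regions, hits,
                                               evalue_max=params["evalue_max"])
        labels = {r.region_id: r.label for r in records}
        pd.DataFrame([r.__dict__ for r in records]).to_csv(
            out / "classification.tsv", sep="\t", index=False)
        cl.top_domains(hits, n=params["top_n"],
                       evalue_max=params["evalue_max"]).to_csv(
            out / "top_domains.tsv", sep="\t", index=False)
        if inputs.get("pfam2go"):
            mapping = gio.read_pfam2go(inputs["pfam2go"])
            cl.go_tally(hits, mapping, n=params["top_n"],
                        evalue_max=params["evalue_max"]).to_csv(
                out / "go_tally.tsv", sep="\t", index=False)
        report.n_intact = summary["n_intact"]
        report.n_remnant = summary["n_remnant"]
        report.n_discarded = summary["n_discarded"]
        stage("classification", f"{summary['n_intact']} intact, "
              f"{summary['n_remnant']} remnant, {summary['n_discarded']} discarded")
    else:
        stage("classification", "not run (no domains table)")

    # --- metrics ------------------------------------------------------------
    fraction_records = []
    if regions:
        host_gc = [gm.gc_record(r.replicon_id, r.sequence) for r in replicons]
        pro_gc = [gm.gc_record(rid, seq) for rid, seq in region_seq.items()]
        deltas, test = gm.gc_compare(pro_gc, host_gc, region_host)
        deltas.to_csv(out / "gc_deltas.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"entity_id": g.entity_id, "gc_percent": g.gc_percent,
              "n_acgt_bases": g.n_acgt_bases} for g in host_gc + pro_gc]
        ).to_csv(out / "gc_table.tsv", sep="\t", index=False)
        regions_by_rep: dict[str, list[gio.ProphageRegion]] = {}
        for r in regions:
            regions_by_rep.setdefault(r.replicon_id, []).append(r)
        fraction_records = [
            gm.prophage_fraction(rep, regions_by_rep.get(rep.replicon_id, []))
            for rep in replicons
        ]
        pd.DataFrame([f.__dict__ for f in fraction_records]).to_csv(
            out / "prophage_fraction.tsv", sep="\t", index=False)
        chrom = [r for r in replicons if r.replicon_class == "chromosome"]
        if chrom:
            gm.bin_by_genome_size(
                [len(r) for r in chrom],
                [len(regions_by_rep.get(r.replicon_id, [])) for r in chrom],
                n_bins=params["n_bins"],
            ).to_csv(out / "size_bins.tsv", sep="\t", index=False)
        stage("metrics", f"gc test p={test[1]:.3g} ({test[2]})")
    else:
        stage("metrics", "not run (no regions)")

    # --- ani_cluster ---------------------------------------------------------
    clusters = []
    prophage_clusters = []
    phage_ids: set[str] = set()
    sketches = []
    if regions:
        k = params["ani_k"]
        usable = {rid: s for rid, s in region_seq.items() if len(s) >= k}
        skipped = len(region_seq) - len(usable)
        if skipped:
            stage("ani_cluster", f"skipping {skipped} regions shorter than k={k}")
        sketches = [ac.sketch(rid, s, k) for rid, s in sorted(usable.items())]
        pro_ids = {s.sequence_id for s in sketches}
        ref_sketches = []
        if inputs.get("phage_refs_fasta"):
            refs = gio.read_fasta(inputs["phage_refs_fasta"])
            phage_ids = {name for name, _ in refs}
            ref_sketches = [ac.sketch(name, seq, k) for name, seq in refs]
        clusters = ac.greedy_cluster(sketches + ref_sketches,
                                     params["ani_min"], params["containment_min"])
        report.clustering = ac.cluster_summary(clusters, pro_ids, phage_ids)
        rows = [
            {"cluster_id": c.cluster_id, "member": m,
             "is_representative": m == c.representative_id}
            for c in clusters for m in c.member_ids
        ]
        pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
        # prophage-only clustering for positional dereplication
        prophage_clusters = ac.greedy_cluster(sketches, params["ani_min"],
                                              params["containment_min"])
        stage("ani_cluster", f"{len(clusters)} clusters over "
              f"{len(sketches) + len(ref_sketches)} sequences")
    else:
        stage("ani_cluster", "not run (no regions)")

    # --- kmer_phylogeny -------------------------------------------------------
    if clusters and len(clusters) >= 2:
        rep_ids = [c.representative_id for c in clusters]
        seq_of = dict(region_seq)
        if inputs.get("phage_refs_fasta"):
            seq_of.update(dict(gio.read_fasta(inputs["phage_refs_fasta"])))
        profiles = [kp.kmer_profile(rid, seq_of[rid], params["profile_k"])
                    for rid in rep_ids]
        dm = kp.distance_matrix(profiles, metric=params["tree_metric"])
        kp.write_distance_matrix(dm, out / "distance_matrix.tsv")
        tree = kp.build_tree(dm, method=params["tree_method"])
        gio.write_newick(tree, out / "tree.nwk")
        stage("kmer_phylogeny", f"tree over {len(rep_ids)} representatives")
    else:
        stage("kmer_phylogeny", "not run (fewer than 2 clusters)")

    # --- integration_sites ----------------------------------------------------
    if regions:
        positions = [isites.normalize_position(r, by_id[r.replicon_id]) for r in regions]
        pos_df = pd.DataFrame([p.__dict__ for p in positions])
        pos_df["label"] = pos_df["region_id"].map(labels) if labels else "unlabeled"
        pos_df.to_csv(out / "positions.tsv", sep="\t", index=False)
        hist, totals = isites.position_histogram(
            positions, params["bin_width"], labels=labels or None)
        hist.to_csv(out / "position_histogram.tsv", sep="\t", index=False)
        if prophage_clusters:
            clustered_ids = {m for c in prophage_clusters for m in c.member_ids}
            derep = isites.dereplicate_for_positions(
                [p for p in positions if p.region_id in clustered_ids],
                prophage_clusters)
            pd.DataFrame([p.__dict__ for p in derep]).to_csv(
                out / "positions_dereplicated.tsv", sep="\t", index=False)
        flank_records = []
        for r in regions:
            fp = isites.extract_flanks(r, by_id[r.replicon_id], params["flank"])
            if fp.upstream_seq:
                flank_records.append((f"{r.region_id}_up", fp.upstream_seq))
            if fp.downstream_seq:
                flank_records.append((f"{r.region_id}_down", fp.downstream_seq))
        if flank_records:
            gio.write_fasta(flank_records, out / "flanks.fasta")
        trna_rows = []
        if inputs.get("trna_gff"):
            genes = gio.read_trna_gff(inputs["trna_gff"])
            for r in regions:
                adjacent, dist = isites.trna_adjacency(
                    r, genes, by_id[r.replicon_id], params["trna_window"])
                trna_rows.append({"region_id": r.region_id, "trna_adjacent": adjacent,
                                  "nearest_bp": dist})
            pd.DataFrame(trna_rows).to_csv(out / "trna_adjacency.tsv",
                                           sep="\t", index=False)
        stage("integration_sites",
              f"ori={totals['ori']} ter={totals['ter']}, "
              f"{len(trna_rows)} tRNA adjacency calls")
    else:
        stage("integration_sites", "not run (no regions)")

    # --- report ----------------------------------------------------------------
    chromosomes = [r for r in replicons if r.replicon_class == "chromosome"]
    plasmids = [r for r in replicons if r.replicon_class == "plasmid"]
    lysogenic = {r.replicon_id for r in regions}
    report.n_genomes = len(chromosomes)
    report.n_genomes_with_prophages = sum(
        1 for r in chromosomes if r.replicon_id in lysogenic)
    report.n_prophages = len(regions)
    report.n_plasmids = len(plasmids)
    report.n_plasmids_with_prophages = sum(
        1 for r in plasmids if r.replicon_id in lysogenic)
    report.n_phage_plasmids = sum(1 for f in fraction_records if f.is_phage_plasmid)
    if inputs.get("defense_tsv"):
        report.defense_tally = tally_hits(
            pd.read_csv(inputs["defense_tsv"], sep="\t"), "system")
        report.defense_tally.to_csv(out / "defense_tally.tsv", sep="\t", index=False)
    if inputs.get("bgc_tsv"):
        report.bgc_tally = tally_hits(
            pd.read_csv(inputs["bgc_tsv"], sep="\t"), "system")
        report.bgc_tally.to_csv(out / "bgc_tally.tsv", sep="\t", index=False)
    report.audit()
    with open(out / "summary.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("report", f"{report.n_prophages} prophages over {report.n_genomes} genomes")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report
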