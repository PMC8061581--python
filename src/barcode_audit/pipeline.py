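"""End-to-end audit orchestration.

Runs QC -> K2P distances -> barcode gap -> Chao1 completeness -> per-family
ultrametric trees -> monophyly -> MOTU delimitation (fixed threshold and,
optionally, GMYC on unique haplotypes) -> concordance -> barcode sharing, and
consolidates everything into one :class:`AuditReport` whose counts all
reconcile with the per-species tables written alongside it.

Trees are built per family (bounding matrix sizes) while distances, sharing
and delimitation operate on the full dataset.  All thresholds live in
:class:`AuditConfig` with the conventional audit defaults: >=500 unambiguous
bp, 2.5% MOTU threshold, >=6 specimens for completeness, 1.5%/Myr pairwise
clock.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from barcode_audit.errors import DataError
from barcode_audit.io_qc import SpecimenRecord, qc_filter, read_dataset
from barcode_audit.distances import (
    pairwise_distance_matrix, gap_summaries, gap_frame, DistanceMatrix,
)
from barcode_audit.haplotypes import (
    collapse_haplotypes, species_completeness, completeness_frame,
)
from barcode_audit.trees import (
    upgma_tree, nj_tree, calibrate_tree, classify_monophyly, monophyly_counts,
)
from barcode_audit.delimitation import (
    threshold_clusters, threshold_flags, gmyc_fit, classify_concordance,
    concordance_frame, MOTUPartition,
)
from barcode_audit.sharing import (
    shared_haplotype_pairs, regional_sharing_summary, group_sharing_summary,
    chi_square_independence, spearman_genus_correlation, family_by_region_table,
)

log = logging.getLogger(__name__)


@dataclass
class AuditConfig:
    """All tunable thresholds of the audit, with their conventional defaults."""

    min_unambiguous: int = 500  # QC length filter, unambiguous bp
    distance_min_overlap: int = 100  # sites for a K2P distance to be defined
    identity_min_overlap: int = 500  # sites for the sequence-identity relation
    motu_threshold: float = 0.025  # fixed MOTU divergence threshold
    completeness_min_n: int = 6  # specimens needed for a Chao1 estimate
    pairwise_rate: float = 0.015  # strict-clock pairwise rate, /Myr
    tree_method: str = "upgma"  # upgma | nj (per-family trees)
    run_gmyc: bool = True
    gmyc_collapse_haplotypes: bool = True


@dataclass
class AuditReport:
    """Consolidated audit summary; every count reconciles with its table."""

    dataset: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    gap: dict = field(default_factory=dict)
    completeness: dict = field(default_factory=dict)
    monophyly: dict = field(default_factory=dict)
    threshold_flags: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)
    sharing: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if obj is pd.NA:
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def _species_attr(records: Sequence[SpecimenRecord], attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in records:
        prev = out.setdefault(rec.species, getattr(rec, attr))
        if prev != getattr(rec, attr):
            log.warning(
                "species %s has inconsistent %s (%r vs %r); keeping the first",
                rec.species, attr, prev, getattr(rec, attr),
            )
    return out


def _per_family_trees(
    records: Sequence[SpecimenRecord],
    matrix: DistanceMatrix,
    config: AuditConfig,
):
    """Ultrametric (or NJ) tree per family; families with <3 specimens skipped."""
    by_family: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, []).append(rec)
    trees = {}
    for family in sorted(by_family):
        members = by_family[family]
        if len(members) < 3:
            log.warning("family %s has %d specimens; no tree built", family, len(members))
            continue
        sub = matrix.submatrix([r.specimen_id for r in members])
        if np.isnan(sub.d).any():
            log.warning("family %s has undefined distances; no tree built", family)
            continue
        trees[family] = upgma_tree(sub) if config.tree_method == "upgma" else nj_tree(sub)
    return trees


def _gmyc_partition(
    records: Sequence[SpecimenRecord],
    matrix: DistanceMatrix,
    config: AuditConfig,
) -> tuple[MOTUPartition, dict]:
    """GMYC per family on unique haplotypes, merged into one partition."""
    by_family: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, []).append(rec)
    assignment: dict[str, str] = {}
    fits: dict[str, dict] = {}
    for family in sorted(by_family):
        members = by_family[family]
        rep_of: dict[str, str] = {}  # specimen -> representative id
        if config.gmyc_collapse_haplotypes:
            by_species: dict[str, list[SpecimenRecord]] = {}
            for rec in members:
                by_species.setdefault(rec.species, []).append(rec)
            reps: list[str] = []
            for sp in sorted(by_species):
                table = collapse_haplotypes(
                    by_species[sp], min_overlap=config.identity_min_overlap
                )
                for hap in table.haplotypes:
                    reps.append(hap.representative_id)
                    for sid in hap.member_ids:
                        rep_of[sid] = hap.representative_id
        else:
            reps = [r.specimen_id for r in members]
            rep_of = {r.specimen_id: r.specimen_id for r in members}
        if len(reps) < 3:
            log.warning("family %s: %d haplotypes, too few for GMYC; singleton MOTUs",
                        family, len(reps))
            for sid, rep in rep_of.items():
                assignment[sid] = f"{family}:HAP:{rep}"
            continue
        sub = matrix.submatrix(reps)
        if np.isnan(sub.d).any():
            log.warning("family %s: undefined distances; GMYC skipped", family)
            for sid, rep in rep_of.items():
                assignment[sid] = f"{family}:HAP:{rep}"
            continue
        tree = calibrate_tree(upgma_tree(sub), pairwise_rate=config.pairwise_rate)
        fit = gmyc_fit(tree)
        fits[family] = fit.summary()
        for sid, rep in rep_of.items():
            assignment[sid] = f"{family}:{fit.clusters.assignment[rep]}"
    partition = MOTUPartition(method="gmyc", assignment=assignment,
                              parameters={"per_family_fits": fits})
    return partition, fits


def run_audit(
    records: Sequence[SpecimenRecord] | None = None,
    fasta: str | Path | None = None,
    metadata: str | Path | None = None,
    config: AuditConfig | None = None,
    out_dir: str | Path | None = None,
) -> AuditReport:
    """Run the full audit; optionally write the TSV/JSON artifact bundle."""
    config = config or AuditConfig()
    if records is None:
        if fasta is None or metadata is None:
            raise DataError("provide either records or fasta+metadata paths")
        records = read_dataset(fasta, metadata)
    records = list(records)
    report = AuditReport()
    artifacts: dict[str, pd.DataFrame] = {}

    report.dataset = {
        "n_records": len(records),
        "n_species": len({r.species for r in records}),
        "n_families": len({r.family for r in records}),
        "n_genera": len({r.genus for r in records}),
    }
    try:
        from importlib.metadata import version

        pkg_version = version("barcode-audit")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    report.provenance = {"config": asdict(config), "package_version": pkg_version}

    # --- QC ---------------------------------------------------------------
    qc = qc_filter(records, min_unambiguous=config.min_unambiguous)
    report.qc = qc.summary()
    artifacts["qc_report"] = qc.to_frame()
    kept_ids = set(qc.kept)
    kept = [r for r in records if r.specimen_id in kept_ids]
    species_of = {r.specimen_id: r.species for r in kept}
    sequences_of = {r.specimen_id: r.sequence for r in kept}

    if len(kept) < 2:
        log.warning("fewer than 2 records pass QC; distance stages undefined")
        return _finish(report, artifacts, out_dir)

    # --- distances & gap ----------------------------------------------------
    matrix = pairwise_distance_matrix(kept, min_overlap=config.distance_min_overlap)
    summaries = gap_summaries(matrix, species_of)
    artifacts["gap_summaries"] = gap_frame(summaries)
    defined = [g for g in summaries if g.gap_present is not None]
    with_gap = [g for g in defined if g.gap_present]
    max_intras = [g.max_intra for g in summaries if g.max_intra is not None]
    nns = [g.nn_distance for g in summaries if g.nn_distance is not None]
    report.gap = {
        "n_species_assessed": len(defined),
        "n_with_gap": len(with_gap),
        "pct_with_gap": _pct(len(with_gap), len(defined)),
        "mean_max_intra": float(np.mean(max_intras)) if max_intras else None,
        "mean_nn_distance": float(np.mean(nns)) if nns else None,
    }

    # --- threshold flags ----------------------------------------------------
    flags_df = threshold_flags(summaries, threshold=config.motu_threshold)
    artifacts["threshold_flags"] = flags_df
    deep = flags_df["deep_split"].astype("boolean").fillna(False)
    shallow = flags_df["shallow_neighbor"].astype("boolean").fillna(False)
    n_deep_defined = int(flags_df["deep_split"].notna().sum())
    n_shallow_defined = int(flags_df["shallow_neighbor"].notna().sum())
    report.threshold_flags = {
        "threshold": config.motu_threshold,
        "n_deep_split": int(deep.sum()),
        "n_deep_split_assessed": n_deep_defined,
        "pct_deep_split": _pct(int(deep.sum()), n_deep_defined),
        "n_shallow_neighbor": int(shallow.sum()),
        "n_shallow_neighbor_assessed": n_shallow_defined,
        "pct_shallow_neighbor": _pct(int(shallow.sum()), n_shallow_defined),
    }

    # --- completeness -------------------------------------------------------
    estimates, pooled = species_completeness(
        kept, min_n=config.completeness_min_n,
        min_overlap=config.identity_min_overlap,
    )
    artifacts["completeness"] = completeness_frame(estimates)
    report.completeness = pooled

    # --- trees & monophyly --------------------------------------------------
    trees = _per_family_trees(kept, matrix, config)
    all_calls = []
    for family in sorted(trees):
        fam_labels = {
            leaf.taxon.label: species_of[leaf.taxon.label]
            for leaf in trees[family].leaf_node_iter()
        }
        all_calls.extend(
            classify_monophyly(
                trees[family], fam_labels, sequences=sequences_of,
                min_overlap=config.identity_min_overlap,
            )
        )
    counts = monophyly_counts(all_calls)
    n_assessed = sum(counts[k] for k in ("monophyletic", "paraphyletic", "polyphyletic"))
    report.monophyly = {
        "counts": counts,
        "n_assessed": n_assessed,
        "pct_monophyletic": _pct(counts["monophyletic"], n_assessed),
        "n_sharing_intruder": sum(
            1 for c in all_calls if c.shares_barcode_with_intruder
        ),
    }
    artifacts["monophyly"] = pd.DataFrame(
        [
            {
                "species": c.species,
                "status": c.status,
                "intruder_species": ";".join(c.intruder_species),
                "shares_barcode_with_intruder": c.shares_barcode_with_intruder,
            }
            for c in all_calls
        ]
    )

    # --- delimitation & concordance ----------------------------------------
    report.concordance = {}
    partition = threshold_clusters(matrix, threshold=config.motu_threshold)
    calls, summary = classify_concordance(species_of, partition)
    report.concordance["threshold"] = summary
    artifacts["concordance_threshold"] = concordance_frame(calls)
    artifacts["motus_threshold"] = partition.to_frame()

    if config.run_gmyc:
        gmyc_part, fits = _gmyc_partition(kept, matrix, config)
        calls_g, summary_g = classify_concordance(species_of, gmyc_part)
        summary_g["per_family_fits"] = fits
        report.concordance["gmyc"] = summary_g
        artifacts["concordance_gmyc"] = concordance_frame(calls_g)
        artifacts["motus_gmyc"] = gmyc_part.to_frame()

    # --- sharing ------------------------------------------------------------
    share = shared_haplotype_pairs(kept, min_overlap=config.identity_min_overlap)
    artifacts["sharing_pairs"] = share.pairs_frame()
    region_of = _species_attr(kept, "region")
    family_of = _species_attr(kept, "family")
    genus_of = _species_attr(kept, "genus")
    regional = regional_sharing_summary(share.flags, region_of)
    family_table = group_sharing_summary(share.flags, family_of)
    genus_table = group_sharing_summary(share.flags, genus_of)
    artifacts["sharing_by_region"] = regional
    artifacts["sharing_by_family"] = family_table
    artifacts["sharing_by_genus"] = genus_table
    artifacts["sharing_family_by_region"] = family_by_region_table(
        share.flags, family_of, region_of
    )
    n_sharing = sum(share.flags.values())
    report.sharing = {
        "n_species": len(share.flags),
        "n_sharing": n_sharing,
        "pct_sharing": _pct(n_sharing, len(share.flags)),
        "n_pairs": len(share.pairs),
        "by_region": regional.to_dict(orient="records"),
        "by_family": family_table.to_dict(orient="records"),
    }
    try:
        stat, dof, p = chi_square_independence(family_table)
        report.sharing["family_chi_square"] = {"statistic": stat, "df": dof, "p": p}
    except DataError as exc:
        report.sharing["family_chi_square"] = {"undefined": str(exc)}
    try:
        rho, rho2, p = spearman_genus_correlation(genus_table)
        report.sharing["genus_spearman"] = {"rho": rho, "rho_squared": rho2, "p": p}
    except DataError as exc:
        report.sharing["genus_spearman"] = {"undefined": str(exc)}

    return _finish(report, artifacts, out_dir)


def _finish(
    report: AuditReport, artifacts: Mapping[str, pd.DataFrame],
    out_dir: str | Path | None,
) -> AuditReport:
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "audit_report.json").write_text(report.to_json() + "\n")
        for name, frame in artifacts.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return report


def plot_gap(gap_table: pd.DataFrame, path: str | Path) -> None:
    """Scatter of max intraspecific distance vs NN distance (gap plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = gap_table.dropna(subset=["max_intra", "nn_distance"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df["max_intra"] * 100, df["nn_distance"] * 100, s=12, alpha=0.6)
    lim = max(1.0, df[["max_intra", "nn_distance"]].max().max() * 110)
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel("Maximum intraspecific K2P distance (%)")
    ax.set_ylabel("Nearest-neighbour K2P distance (%)")
    ax.set_title("Barcode gap")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
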