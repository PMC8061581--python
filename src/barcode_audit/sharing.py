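"""Interspecific barcode sharing, diagnosability, and stratified summaries.

Two specimens of different species "share" a barcode when their sequences are
identical over at least ``min_overlap`` jointly unambiguous positions — the
same identity relation used for haplotype collapsing.  Sharing is summarised
per species, then stratified by the Last-Glacial-Maximum region partition
(north/alpine vs mid-latitude vs south), by family and by genus, with a
Pearson chi-square test of independence across groups and a Spearman rank
correlation between per-genus species counts and sharing counts.

A species is diagnosable when it either carries at least one diagnostic
position (a nucleotide state fixed in the species and absent from all other
species) or, failing single positions, shares no haplotype with any other
species (a diagnostic combination of states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from barcode_audit.errors import DataError
from barcode_audit.distances import encode_sequence
from barcode_audit.haplotypes import sequences_identical
from barcode_audit.io_qc import REGIONS, SpecimenRecord

log = logging.getLogger(__name__)


@dataclass
class SharingReport:
    """Species-level barcode-sharing flags and the pairs behind them."""

    flags: dict[str, bool]  # species -> shares_barcode
    pairs: list[tuple[str, str, int]]  # (species_a, species_b, n_identical_pairs)

    @property
    def sharing_species(self) -> list[str]:
        return sorted(s for s, v in self.flags.items() if v)

    @property
    def proportion(self) -> float:
        return sum(self.flags.values()) / len(self.flags) if self.flags else float("nan")

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["species_a", "species_b", "n_identical_pairs"]
        )


def shared_haplotype_pairs(
    records: Sequence[SpecimenRecord], min_overlap: int = 500
) -> SharingReport:
    """Detect all cross-species identical-sequence pairs.

    Returns per-species flags (True iff the species appears in at least one
    sharing pair) and the species-pair list with the number of identical
    specimen pairs supporting each.
    """
    codes = [encode_sequence(r.sequence) for r in records]
    species = [r.species for r in records]
    pair_counts: dict[tuple[str, str], int] = {}
    n = len(records)
    for i in range(n):
        for j in range(i + 1, n):
            if species[i] == species[j]:
                continue
            if sequences_identical(codes[i], codes[j], min_overlap):
                key = tuple(sorted((species[i], species[j])))
                pair_counts[key] = pair_counts.get(key, 0) + 1
    flags = {sp: False for sp in set(species)}
    for (a, b), _ in pair_counts.items():
        flags[a] = True
        flags[b] = True
    pairs = [(a, b, c) for (a, b), c in sorted(pair_counts.items())]
    return SharingReport(flags=flags, pairs=pairs)


@dataclass
class DiagnosabilityResult:
    """Diagnostic positions (1-based) for one species, if any."""

    species: str
    diagnostic_positions: list[tuple[int, str]] = field(default_factory=list)
    diagnosable: bool = False


def diagnosability(
    records: Sequence[SpecimenRecord], species: str, min_overlap: int = 500
) -> DiagnosabilityResult:
    """Find positions with a state fixed in ``species`` and absent elsewhere.

    A position qualifies iff all the species' unambiguous states there equal
    one state s and no unambiguous record of any other species has s at that
    position.  The species is also diagnosable, absent single positions, when
    none of its haplotypes is shared with another species.
    """
    members = [r for r in records if r.species == species]
    others = [r for r in records if r.species != species]
    if not members or not others:
        raise DataError("diagnosability needs records for the species and its complement")
    mem = np.vstack([encode_sequence(r.sequence) for r in members])
    oth = np.vstack([encode_sequence(r.sequence) for r in others])
    length = mem.shape[1]
    positions: list[tuple[int, str]] = []
    bases = "AGCT"  # matches the encoding order
    for p in range(length):
        col = mem[:, p]
        col = col[col != 255]
        if col.size == 0:
            continue
        if not np.all(col == col[0]):
            continue
        state = int(col[0])
        ocol = oth[:, p]
        if np.any(ocol == state):
            continue
        positions.append((p + 1, bases[state]))
    if positions:
        return DiagnosabilityResult(species=species, diagnostic_positions=positions, diagnosable=True)
    shares = any(
        sequences_identical(m.sequence, o.sequence, min_overlap)
        for m in members
        for o in others
    )
    return DiagnosabilityResult(species=species, diagnostic_positions=[], diagnosable=not shares)


def regional_sharing_summary(
    flags: Mapping[str, bool], region_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Sharing counts and proportions per LGM region.

    Species with region ``unknown`` are excluded (and reported in the
    ``unknown`` row with NA proportion columns kept informative).
    """
    bad = sorted(
        {r for r in region_labels.values() if r not in REGIONS}
    )
    if bad:
        offenders = [s for s, r in region_labels.items() if r in bad]
        raise DataError(f"invalid region values {bad} for species {offenders[:10]}")
    missing = [s for s in flags if s not in region_labels]
    if missing:
        raise DataError(f"species without region assignment: {missing[:10]}")
    rows = []
    for region in REGIONS:
        members = [s for s in flags if region_labels[s] == region]
        if region == "unknown" and not members:
            continue
        sharing = sum(1 for s in members if flags[s])
        total = len(members)
        rows.append(
            {
                "region": region,
                "sharing": sharing,
                "total": total,
                "proportion": sharing / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["region", "sharing", "total", "proportion"])


def group_sharing_summary(
    flags: Mapping[str, bool], group_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Sharing counts per group (family or genus)."""
    missing = [s for s in flags if s not in group_labels]
    if missing:
        raise DataError(f"species without group assignment: {missing[:10]}")
    rows = []
    for group in sorted(set(group_labels[s] for s in flags)):
        members = [s for s in flags if group_labels[s] == group]
        sharing = sum(1 for s in members if flags[s])
        rows.append(
            {
                "group": group,
                "sharing": sharing,
                "total": len(members),
                "proportion": sharing / len(members),
            }
        )
    return pd.DataFrame(rows, columns=["group", "sharing", "total", "proportion"])


def family_by_region_table(
    flags: Mapping[str, bool],
    family_labels: Mapping[str, str],
    region_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Families x regions sharing table with "x/y (z%)" cells plus totals."""
    families = sorted({family_labels[s] for s in flags})
    regions = [r for r in REGIONS if r != "unknown"]

    def _cell(members: list[str]) -> str:
        total = len(members)
        if total == 0:
            return "0"
        sharing = sum(1 for s in members if flags[s])
        return f"{sharing}/{total} ({100.0 * sharing / total:.1f}%)"

    rows = []
    for fam in families + ["Total"]:
        row = {"family": fam}
        for region in regions + ["Total"]:
            members = [
                s for s in flags
                if (fam == "Total" or family_labels[s] == fam)
                and (region == "Total" or region_labels[s] == region)
            ]
            row[region] = _cell(members)
        rows.append(row)
    return pd.DataFrame(rows, columns=["family"] + regions + ["Total"])


def chi_square_independence(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square on a k x 2 (sharing / not sharing) table.

    No continuity correction.  Groups with zero species are dropped with a
    warning.  Returns (statistic, df, p).
    """
    t = table.copy()
    zero = t["total"] == 0
    if zero.any():
        log.warning("dropping %d empty groups from chi-square", int(zero.sum()))
        t = t[~zero]
    if len(t) < 2:
        raise DataError("chi-square needs at least 2 non-empty groups")
    obs = np.column_stack([t["sharing"], t["total"] - t["sharing"]])
    if (obs.sum(axis=0) == 0).any():
        # every group shares (or none does): proportions are identical and
        # the Pearson statistic degenerates to 0
        log.warning("degenerate sharing column; chi-square statistic is 0")
        return 0.0, len(t) - 1, 1.0
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman_genus_correlation(
    genus_table: pd.DataFrame,
) -> tuple[float, float, float]:
    """Spearman rank correlation of sharing count vs species count per genus.

    Average ranks for ties; p-value from the t approximation.  Returns
    (rho, rho_squared, p); constant inputs yield NaN throughout.
    """
    if len(genus_table) < 3:
        raise DataError("Spearman correlation needs at least 3 genera")
    x = genus_table["total"].to_numpy(dtype=float)
    y = genus_table["sharing"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant vector: Spearman correlation undefined")
        return float("nan"), float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    return rho, rho * rho, float(res.pvalue)
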