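"""Haplotype collapsing and Chao1 sampling-completeness estimation.

Two sequences belong to the same haplotype iff they have zero mismatches over
the positions where both are unambiguous, provided they share at least
``min_overlap`` such positions.  This identity relation is non-transitive for
partial sequences, so collapsing is greedy: sequences are processed in
decreasing order of unambiguous length and each joins the first existing
haplotype whose representative it is compatible with (the representative is
the haplotype's most complete member, i.e. its founder).

Per-species sampling completeness uses the bias-corrected Chao1 asymptotic
richness estimator on the haplotype abundance distribution, reporting the
observed haplotype count H, the asymptote H_hat, the fraction of haplotype
diversity retrieved R = H / H_hat, and the number of haplotypes that remain
to be sampled L = H_hat - H.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from barcode_audit.errors import DataError
from barcode_audit.distances import encode_sequence
from barcode_audit.io_qc import SpecimenRecord

log = logging.getLogger(__name__)


def sequences_identical(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, min_overlap: int = 500
) -> bool:
    """True iff zero mismatches over >= min_overlap jointly unambiguous sites."""
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    both = (a != 255) & (b != 255)
    if int(both.sum()) < min_overlap:
        return False
    return bool(np.all(a[both] == b[both]))


@dataclass
class Haplotype:
    representative_id: str
    representative: str  # sequence string of the most complete member
    member_ids: list[str] = field(default_factory=list)

    @property
    def abundance(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeTable:
    """Haplotypes of one species with singleton/doubleton counts."""

    species: str
    n: int
    haplotypes: list[Haplotype]

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def f1(self) -> int:
        return sum(1 for h in self.haplotypes if h.abundance == 1)

    @property
    def f2(self) -> int:
        return sum(1 for h in self.haplotypes if h.abundance == 2)


def collapse_haplotypes(
    records: Sequence[SpecimenRecord], min_overlap: int = 500
) -> HaplotypeTable:
    """Collapse one species' records into haplotypes (greedy, deterministic).

    Ordering is by decreasing unambiguous length, ties broken by specimen id,
    so the result is deterministic for a given record set.
    """
    if not records:
        raise DataError("collapse_haplotypes requires at least one record")
    species = records[0].species
    order = sorted(records, key=lambda r: (-r.n_unambiguous, r.specimen_id))
    haps: list[Haplotype] = []
    codes = {r.specimen_id: encode_sequence(r.sequence) for r in order}
    for rec in order:
        placed = False
        for hap in haps:
            if sequences_identical(
                codes[rec.specimen_id], codes[hap.representative_id], min_overlap
            ):
                hap.member_ids.append(rec.specimen_id)
                placed = True
                break
        if not placed:
            haps.append(
                Haplotype(
                    representative_id=rec.specimen_id,
                    representative=rec.sequence,
                    member_ids=[rec.specimen_id],
                )
            )
    return HaplotypeTable(species=species, n=len(records), haplotypes=haps)


def chao1(h_obs: int, f1: int, f2: int, n: int) -> float:
    """Bias-corrected Chao1 asymptotic richness.

    With doubletons present: H_hat = H + ((n-1)/n) * f1^2 / (2 f2).
    Without doubletons:      H_hat = H + ((n-1)/n) * f1 (f1 - 1) / 2.
    """
    if h_obs < 1 or n < 1 or f1 < 0 or f2 < 0 or f1 + 2 * f2 > n:
        raise DataError(
            f"invalid Chao1 counts: H={h_obs}, f1={f1}, f2={f2}, n={n}"
        )
    correction = (n - 1) / n
    if f2 > 0:
        return h_obs + correction * f1 * f1 / (2.0 * f2)
    return h_obs + correction * f1 * (f1 - 1) / 2.0


@dataclass
class CompletenessEstimate:
    """Per-species haplotype sampling completeness (one table row)."""

    species: str
    n: int
    h: int
    h_hat: float
    r: float  # fraction of haplotype diversity retrieved, in (0, 1]
    l: float  # haplotypes remaining to be sampled, >= 0


def species_completeness(
    records: Sequence[SpecimenRecord],
    min_n: int = 6,
    min_overlap: int = 500,
    grouping: Mapping[str, str] | None = None,
) -> tuple[list[CompletenessEstimate], dict]:
    """Chao1 completeness per species, plus pooled totals.

    Species with fewer than ``min_n`` specimens are excluded.  The pooled
    summary reports sum_N, sum_H, sum_H_hat, the pooled fraction retrieved
    R = sum_H / sum_H_hat, L = sum_H_hat - sum_H, and also the unweighted
    mean of per-species R for comparison.
    """
    by_species: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        key = grouping[rec.specimen_id] if grouping else rec.species
        by_species.setdefault(key, []).append(rec)
    estimates: list[CompletenessEstimate] = []
    for species in sorted(by_species):
        members = by_species[species]
        if len(members) < min_n:
            continue
        table = collapse_haplotypes(members, min_overlap=min_overlap)
        h_hat = chao1(table.h, table.f1, table.f2, table.n)
        estimates.append(
            CompletenessEstimate(
                species=species, n=table.n, h=table.h, h_hat=h_hat,
                r=table.h / h_hat, l=h_hat - table.h,
            )
        )
    pooled: dict = {
        "n_species": len(estimates),
        "sum_n": sum(e.n for e in estimates),
        "sum_h": sum(e.h for e in estimates),
        "sum_h_hat": sum(e.h_hat for e in estimates),
    }
    if estimates:
        pooled["pooled_r"] = pooled["sum_h"] / pooled["sum_h_hat"]
        pooled["pooled_l"] = pooled["sum_h_hat"] - pooled["sum_h"]
        pooled["mean_r"] = float(np.mean([e.r for e in estimates]))
    return estimates, pooled


def completeness_frame(estimates: Sequence[CompletenessEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"species": e.species, "N": e.n, "H": e.h, "H_hat": e.h_hat,
             "R": e.r, "L": e.l}
            for e in estimates
        ],
        columns=["species", "N", "H", "H_hat", "R", "L"],
    )
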