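"""Kimura two-parameter (K2P) distances and barcode-gap statistics.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions from transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions over
pairwise-complete sites (pairwise deletion: a site is usable for a pair iff
both characters are unambiguous A/C/G/T).  The barcode gap compares, per
species, the maximum intraspecific distance against the minimum distance to
any heterospecific specimen (the nearest neighbour, NN): a gap is present iff
max_intra < nn_distance; an exact tie conservatively counts as absence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from barcode_audit.errors import DataError, SaturationError, UndefinedDistanceError
from barcode_audit.io_qc import SpecimenRecord

log = logging.getLogger(__name__)

# Encoding: A=0, G=1 (purines), C=2, T=3 (pyrimidines); anything else 255.
# With this layout code >> 1 gives the purine/pyrimidine class, so a mismatch
# within a class is a transition and across classes a transversion.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("AGCT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (255 = gap/ambiguous)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def k2p_from_proportions(p: float, q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={p:.4f}, Q={q:.4f} (log argument <= 0)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, min_overlap: int = 100
) -> tuple[float, int]:
    """K2P distance between two frame-aligned sequences.

    Returns ``(distance, usable_sites)``.  Raises
    :class:`UndefinedDistanceError` when fewer than ``min_overlap`` sites are
    pairwise complete, and :class:`SaturationError` when divergence exceeds
    the model's correctable range.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise DataError("sequences are not on a common coordinate frame")
    usable = (a != 255) & (b != 255)
    n = int(usable.sum())
    if n < min_overlap:
        raise UndefinedDistanceError(
            f"only {n} pairwise-complete sites (< min_overlap={min_overlap})"
        )
    av, bv = a[usable], b[usable]
    diff = av != bv
    transitions = int((diff & ((av >> 1) == (bv >> 1))).sum())
    transversions = int(diff.sum()) - transitions
    return k2p_from_proportions(transitions / n, transversions / n), n


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair usable-site counts.

    ``d`` holds NaN for pairs whose distance is undefined (insufficient
    overlap or saturated).
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.overlap.shape != (n, n):
            raise DataError("matrix shapes do not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.ids.index(s) for s in keep])
        return DistanceMatrix(
            ids=list(keep), d=self.d[np.ix_(idx, idx)], overlap=self.overlap[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.8f")

    def write_phylip(self, path: str | Path) -> None:
        """Lower-triangular PHYLIP-style writer."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{self.d[i, j]:.8f}" for j in range(i))
                fh.write(f"{sid:<12s} {row}".rstrip() + "\n")


def pairwise_distance_matrix(
    records: Sequence[SpecimenRecord], min_overlap: int = 100
) -> DistanceMatrix:
    """Full symmetric K2P matrix over all records (pairwise deletion).

    Undefined pairs (overlap below ``min_overlap``, or saturated) are stored
    as NaN and logged.
    """
    if len(records) < 2:
        raise DataError("need at least 2 records for a distance matrix")
    n = len(records)
    codes = np.vstack([encode_sequence(r.sequence) for r in records])
    valid = codes != 255
    cls = codes >> 1
    d = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=np.int64)
    n_undefined = 0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        ov = both.sum(axis=1)
        diff = (codes[i] != codes[i + 1 :]) & both
        ts = (diff & (cls[i] == cls[i + 1 :])).sum(axis=1)
        tot = diff.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ov > 0, ts / ov, 0.0)
            q = np.where(ov > 0, (tot - ts) / ov, 0.0)
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            dist = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        bad = (ov < min_overlap) | (w1 <= 0) | (w2 <= 0)
        dist = np.where(bad, np.nan, dist)
        n_undefined += int(bad.sum())
        d[i, i + 1 :] = dist
        d[i + 1 :, i] = dist
        overlap[i, i + 1 :] = ov
        overlap[i + 1 :, i] = ov
    if n_undefined:
        log.warning("%d specimen pairs have undefined K2P distances", n_undefined)
    return DistanceMatrix(ids=[r.specimen_id for r in records], d=d, overlap=overlap)


@dataclass
class GapSummary:
    """Per-species barcode-gap statistics (one point of the gap scatter)."""

    species: str
    n: int
    max_intra: float | None  # None when n < 2 or all intra distances undefined
    nn_distance: float | None
    nn_species: str | None
    gap_present: bool | None  # defined only when max_intra and nn both defined


def gap_summaries(
    matrix: DistanceMatrix, species_labels: Mapping[str, str]
) -> list[GapSummary]:
    """Per-species max intraspecific distance, NN distance and gap flag.

    ``gap_present`` is defined only for species with >= 2 specimens whose
    maximum intraspecific distance is computable; the tie
    ``max_intra == nn_distance`` counts as no gap.
    """
    try:
        sp = np.array([species_labels[s] for s in matrix.ids])
    except KeyError as exc:
        raise DataError(f"specimen {exc.args[0]!r} has no species label") from exc
    out: list[GapSummary] = []
    for species in sorted(set(sp)):
        members = np.flatnonzero(sp == species)
        others = np.flatnonzero(sp != species)
        n = len(members)
        max_intra: float | None = None
        if n >= 2:
            intra = matrix.d[np.ix_(members, members)]
            vals = intra[np.triu_indices(n, k=1)]
            if not np.all(np.isnan(vals)):
                max_intra = float(np.nanmax(vals))
        nn_distance: float | None = None
        nn_species: str | None = None
        if len(others) > 0:
            inter = matrix.d[np.ix_(members, others)]
            if not np.all(np.isnan(inter)):
                flat = np.nanmin(inter, axis=0)
                j = int(np.nanargmin(flat))
                nn_distance = float(flat[j])
                nn_species = str(sp[others[j]])
        gap: bool | None = None
        if n >= 2 and max_intra is not None and nn_distance is not None:
            gap = bool(max_intra < nn_distance)
        out.append(
            GapSummary(
                species=species, n=n, max_intra=max_intra,
                nn_distance=nn_distance, nn_species=nn_species, gap_present=gap,
            )
        )
    return out


def gap_frame(summaries: Sequence[GapSummary]) -> pd.DataFrame:
    """GapSummary list as a DataFrame (mirrors the gap-scatter columns)."""
    return pd.DataFrame(
        [
            {
                "species": g.species,
                "n": g.n,
                "max_intra": np.nan if g.max_intra is None else g.max_intra,
                "nn_distance": np.nan if g.nn_distance is None else g.nn_distance,
                "nn_species": g.nn_species or "",
                "gap_present": "" if g.gap_present is None else g.gap_present,
            }
            for g in summaries
        ]
    )
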