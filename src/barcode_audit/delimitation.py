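"""MOTU delimitation and taxonomy-vs-MOTU concordance.

Two delimitation routes are provided:

* **Fixed-threshold clustering** — single-linkage connected components of the
  K2P distance graph under ``d < threshold`` (default 2.5%, the classic
  intra/interspecific cutoff; a distance exactly equal to the threshold does
  not link).  This is the documented open proxy for BIN-style clustering.

* **Single-threshold GMYC** — the General Mixed Yule Coalescent model on an
  ultrametric tree.  Internal-node ages older than a threshold age T are
  treated as speciation (Yule) events and younger ages as coalescent events
  within the clusters subtended at T.  Each inter-event waiting interval x_i
  contributes ln(b_i) - b_i x_i to the log-likelihood, where b_i is the rate
  of the active process (lambda_yule * k_i above T, with k_i species
  lineages; lambda_coal * sum_j n_ij (n_ij - 1) below, with n_ij lineages in
  cluster j).  Rates are estimated per process as events / lineage-weighted
  time; T is chosen among midpoints of consecutive node ages to maximise the
  likelihood, and compared against a one-process coalescent null by a
  likelihood-ratio test (chi-square, df=3: the threshold plus the two extra
  process parameters, the convention with nominal type-I control).

Any MOTU partition is compared against the Linnaean labels with the
four-way truth table: a species wholly in one MOTU is a **Match** if it has
the MOTU to itself and a **Merge** if other species share it; a species
spread over several MOTUs is a **Split** when none are shared and a
**Mixture** otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2

from barcode_audit.errors import DataError
from barcode_audit.distances import DistanceMatrix, GapSummary
from barcode_audit.trees import node_ages

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.025
GMYC_LR_DF = 3
_AGE_JITTER = 1e-12


@dataclass
class MOTUPartition:
    """Assignment of every specimen to exactly one MOTU."""

    method: str  # threshold | gmyc | external
    assignment: dict[str, str]  # specimen_id -> motu_id
    parameters: dict = field(default_factory=dict)

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, motu in self.assignment.items():
            out.setdefault(motu, []).append(sid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["specimen_id", "motu_id"]
        )


def _relabel_components(ids: Sequence[str], labels: np.ndarray) -> dict[str, str]:
    """Stable MOTU ids: numbered by first occurrence in input order."""
    remap: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for sid, lab in zip(ids, labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = f"MOTU_{len(remap) + 1:04d}"
        assignment[sid] = remap[lab]
    return assignment


def threshold_clusters(
    matrix: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD
) -> MOTUPartition:
    """Single-linkage clusters under d < threshold (strict inequality).

    Specimens with any missing distance are set aside as singleton MOTUs and
    logged, since their linkage cannot be assessed.
    """
    d = np.asarray(matrix.d, dtype=float)
    n = matrix.n
    off_diag_nan = np.isnan(d) & ~np.eye(n, dtype=bool)
    excluded = np.flatnonzero(off_diag_nan.any(axis=1))
    if len(excluded):
        log.warning(
            "%d specimens with missing distances become singleton MOTUs: %s",
            len(excluded), [matrix.ids[i] for i in excluded[:10]],
        )
    ok = np.flatnonzero(~off_diag_nan.any(axis=1))
    labels = np.full(n, -1, dtype=int)
    if len(ok):
        adj = d[np.ix_(ok, ok)] < threshold
        np.fill_diagonal(adj, True)
        _, comp = connected_components(csr_matrix(adj), directed=False)
        labels[ok] = comp
    next_label = labels.max() + 1 if len(ok) else 0
    for i in excluded:
        labels[i] = next_label
        next_label += 1
    assignment = _relabel_components(matrix.ids, labels)
    return MOTUPartition(
        method="threshold", assignment=assignment,
        parameters={"threshold": threshold, "linkage": "single"},
    )


def threshold_flags(
    summaries: Sequence[GapSummary], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-species deep-split / shallow-neighbour flags at a fixed threshold.

    ``deep_split`` is True when the maximum intraspecific distance lies
    strictly above the threshold; ``shallow_neighbor`` when the NN distance
    lies strictly below it.  Flags are NA where the underlying statistic is
    undefined.
    """
    rows = []
    for g in summaries:
        rows.append(
            {
                "species": g.species,
                "deep_split": pd.NA if g.max_intra is None else g.max_intra > threshold,
                "shallow_neighbor": pd.NA if g.nn_distance is None else g.nn_distance < threshold,
            }
        )
    return pd.DataFrame(rows, columns=["species", "deep_split", "shallow_neighbor"])


# ---------------------------------------------------------------------------
# GMYC


@dataclass
class GMYCResult:
    """Fitted single-threshold GMYC model."""

    threshold_age: float
    lambda_yule: float
    lambda_coal: float
    logl_mixed: float
    logl_null: float
    lr: float
    p_value: float
    n_clusters: int
    clusters: MOTUPartition

    def summary(self) -> dict:
        return {
            "threshold_age": self.threshold_age,
            "lambda_yule": self.lambda_yule,
            "lambda_coal": self.lambda_coal,
            "logL_mixed": self.logl_mixed,
            "logL_null": self.logl_null,
            "LR": self.lr,
            "p_value": self.p_value,
            "n_clusters": self.n_clusters,
        }


class _TreeArrays:
    """Flat arrays for fast repeated likelihood evaluation."""

    def __init__(self, tree: dendropy.Tree):
        ages = node_ages(tree)
        nodes = list(tree.preorder_node_iter())
        if len(nodes) < 5:
            raise DataError("GMYC requires at least 3 leaves")
        for nd in nodes:
            if not nd.is_leaf() and len(nd.child_nodes()) != 2:
                raise DataError("GMYC requires a fully bifurcating tree")
        index = {nd: i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.array(
            [index[nd.parent_node] if nd.parent_node else -1 for nd in nodes]
        )
        self.is_leaf = np.array([nd.is_leaf() for nd in nodes])
        self.labels = [nd.taxon.label if nd.is_leaf() else None for nd in nodes]
        age = np.array([ages[nd] for nd in nodes], dtype=float)
        # deterministic jitter breaks exact age ties; earlier (rootward)
        # preorder index gets the larger perturbation so parent > child holds
        # across zero-length branches
        jitter = _AGE_JITTER * (n - np.arange(n))
        age = np.where(self.is_leaf, 0.0, age + jitter)
        self.age = age
        self.n_leaves = int(self.is_leaf.sum())
        self.event_ages = np.sort(age[~self.is_leaf])[::-1]  # descending
        self.root_age = self.event_ages[0]
        # children lists in preorder for cluster-label propagation
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)

    def cluster_labels(self, threshold: float) -> np.ndarray:
        """Cluster id (index of the cluster's root node) per node; -1 = Yule region."""
        n = len(self.age)
        labels = np.full(n, -1, dtype=int)
        for i in range(n):  # preorder: parents before children
            p = self.parent[i]
            if p < 0:
                if self.age[i] <= threshold:
                    labels[i] = i
            elif labels[p] >= 0:
                labels[i] = labels[p]
            elif self.age[i] <= threshold:
                labels[i] = i
        return labels


def _gmyc_loglik(arr: _TreeArrays, threshold: float) -> tuple[float, float, float]:
    """Log-likelihood of the single-threshold model; returns (logL, lam_y, lam_c).

    Both component processes run backward in time from the tips, the
    coalescent convention: during each inter-event interval the active
    process waits at rate b_i (lambda_yule * k_i above the threshold,
    lambda_coal * sum_j n_ij (n_ij - 1) below), and the event closing an
    interval at its older end draws its ln(b_i) factor from that interval's
    lineage counts.  The likelihood is conditioned on the root: the root
    event itself contributes no ln-term, as is standard for genealogical
    likelihoods.  Rates are estimated per process as events divided by
    lineage-weighted time.
    """
    labels = arr.cluster_labels(threshold)
    child = np.flatnonzero(arr.parent >= 0)
    p_age = arr.age[arr.parent[child]]
    c_age = arr.age[child]
    c_label = labels[child]

    events = arr.event_ages  # descending, events[0] = root age
    bps = [arr.root_age]
    inner = sorted(
        {float(a) for a in events[1:]}
        | ({threshold} if 0 < threshold < arr.root_age else set()),
        reverse=True,
    )
    bps.extend(v for v in inner if 0.0 < v < arr.root_age)
    bps.append(0.0)
    event_set = {float(a) for a in events[1:]}  # root conditioned on

    # first pass: per-interval regime, lineage statistic, closing event
    intervals = []  # (x, regime, size, closes_event)
    w_yule = w_coal = 0.0
    s_yule = s_coal = 0
    for hi, lo in zip(bps[:-1], bps[1:]):
        x = hi - lo
        mid = 0.5 * (hi + lo)
        crossing = (p_age > mid) & (c_age < mid)
        if mid > threshold:
            k = int(crossing.sum())
            w_yule += k * x
            regime, size = "Y", k
        else:
            in_cluster = c_label[crossing]
            counts = np.bincount(in_cluster[in_cluster >= 0])
            size = int((counts * (counts - 1)).sum())
            w_coal += size * x
            regime = "C"
        closes_event = hi in event_set  # the event at the interval's older end
        if closes_event:
            if regime == "Y":
                s_yule += 1
            else:
                s_coal += 1
        intervals.append((x, regime, size, closes_event))

    lam_y = s_yule / w_yule if w_yule > 0 else 0.0
    lam_c = s_coal / w_coal if w_coal > 0 else 0.0
    logl = 0.0
    for x, regime, size, closes_event in intervals:
        rate = (lam_y if regime == "Y" else lam_c) * size
        logl -= rate * x
        if closes_event:
            if rate <= 0:
                return -math.inf, lam_y, lam_c
            logl += math.log(rate)
    return logl, lam_y, lam_c


def gmyc_fit(tree: dendropy.Tree, df: int = GMYC_LR_DF) -> GMYCResult:
    """Fit the single-threshold GMYC model to an ultrametric binary tree.

    Candidate thresholds are the midpoints between consecutive internal-node
    ages, plus one above the root (which reproduces the all-coalescent null
    exactly) and one below the youngest internal node (pure Yule).  The LR
    statistic 2(logL_mixed - logL_null) is referred to a chi-square with
    ``df`` degrees of freedom.
    """
    arr = _TreeArrays(tree)
    events = arr.event_ages
    candidates = [arr.root_age * (1.0 + 1e-9) + 1e-15]
    for a, b in zip(events[:-1], events[1:]):
        candidates.append(0.5 * (a + b))
    candidates.append(events[-1] / 2.0)

    logl_null, _, _ = _gmyc_loglik(arr, candidates[0])
    best = (-math.inf, candidates[0], 0.0, 0.0)
    for t in candidates:  # descending; ties keep the older threshold
        logl, lam_y, lam_c = _gmyc_loglik(arr, t)
        if logl > best[0]:
            best = (logl, t, lam_y, lam_c)
    logl_mixed, t_best, lam_y, lam_c = best
    lr = max(2.0 * (logl_mixed - logl_null), 0.0)
    p_value = float(chi2.sf(lr, df))

    labels = arr.cluster_labels(t_best)
    leaf_idx = np.flatnonzero(arr.is_leaf)
    leaf_ids = [arr.labels[i] for i in leaf_idx]
    assignment = _relabel_components(leaf_ids, labels[leaf_idx])
    clusters = MOTUPartition(
        method="gmyc", assignment=assignment,
        parameters={"threshold_age": t_best, "df": df},
    )
    return GMYCResult(
        threshold_age=float(t_best), lambda_yule=lam_y, lambda_coal=lam_c,
        logl_mixed=logl_mixed, logl_null=logl_null, lr=lr, p_value=p_value,
        n_clusters=clusters.n_motus, clusters=clusters,
    )


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class ConcordanceCall:
    """Match/Merge/Split/Mixture status of one species against a partition."""

    species: str
    category: str
    motus: set[str]
    shared_motus: set[str]


def classify_concordance(
    species_labels: Mapping[str, str], partition: MOTUPartition
) -> tuple[list[ConcordanceCall], dict]:
    """Classify every species against a MOTU partition.

    Truth table on (number of MOTUs holding the species, whether any of them
    also holds another species): (1, no) Match; (1, yes) Merge; (>=2, no)
    Split; (>=2, yes) Mixture.
    """
    missing = [s for s in species_labels if s not in partition.assignment]
    if missing:
        raise DataError(f"specimens missing from partition: {missing[:10]}")
    species_of_motu: dict[str, set[str]] = {}
    motus_of_species: dict[str, set[str]] = {}
    for sid, species in species_labels.items():
        motu = partition.assignment[sid]
        species_of_motu.setdefault(motu, set()).add(species)
        motus_of_species.setdefault(species, set()).add(motu)

    calls: list[ConcordanceCall] = []
    counts = {"Match": 0, "Merge": 0, "Split": 0, "Mixture": 0}
    for species in sorted(motus_of_species):
        motus = motus_of_species[species]
        shared = {m for m in motus if len(species_of_motu[m]) > 1}
        if len(motus) == 1:
            category = "Merge" if shared else "Match"
        else:
            category = "Mixture" if shared else "Split"
        counts[category] += 1
        calls.append(
            ConcordanceCall(
                species=species, category=category, motus=motus, shared_motus=shared
            )
        )
    total = len(calls)
    summary = {
        "n_species": total,
        "counts": counts,
        "percent": {
            k: (100.0 * v / total if total else float("nan"))
            for k, v in counts.items()
        },
        "n_motus": partition.n_motus,
        "method": partition.method,
    }
    return calls, summary


def concordance_frame(calls: Sequence[ConcordanceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "category": c.category,
                "n_motus": len(c.motus),
                "motus": ";".join(sorted(c.motus)),
                "shared_motus": ";".join(sorted(c.shared_motus)),
            }
            for c in calls
        ],
        columns=["species", "category", "n_motus", "motus", "shared_motus"],
    )
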