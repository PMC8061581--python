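"""Ground-truth synthetic barcode datasets.

The generator emulates the data structure a barcode-library audit consumes: a
Yule (pure-birth) species tree calibrated in Myr under a strict clock, a
Kingman coalescent genealogy within each species parameterised directly by
its expected pairwise depth in substitutions/site, K80 sequence evolution
with a tunable transition/transversion rate ratio, and optional injected
phenomena — barcode sharing (introgression), deep intraspecific splits, and
over-split taxa — each recorded in a ground-truth object so every pipeline
stage can be checked against what was simulated.

Every terminal species branch is padded by a configurable stem (Myr), the
knob that separates between-species from within-species divergence; with the
defaults, interspecific distances sit well above the 2.5% delimitation
threshold while intraspecific distances stay well below it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from barcode_audit.errors import ConfigurationError, DataError
from barcode_audit.io_qc import SpecimenRecord, write_dataset

log = logging.getLogger(__name__)

_BASES = "AGCT"  # index order matches the distance-module encoding


@dataclass
class SharingEvent:
    """Copy a donor species' haplotype into specimens of a recipient species."""

    donor_species: str
    recipient_species: str
    n_recipients: int = 1


@dataclass
class DeepSplitEvent:
    """Graft a divergent haplogroup into part of one species."""

    species: str
    extra_depth: float = 0.03  # substitutions/site beyond the species' variation
    n_specimens: int | None = None  # default: half the species


@dataclass
class OverSplitEvent:
    """Relabel part of one true cluster as a second nominal species."""

    species: str
    new_label: str | None = None
    fraction: float = 0.5


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 20 species of 10 specimens each with expected intraspecific
    pairwise divergence 0.6% (within_species_depth doubles into a pairwise
    expectation of 2 x 0.003) and interspecific divergence of at least ~4.5%
    (2 x stem x clock rate), i.e. a clean barcode gap unless events are
    injected.
    """

    n_species: int = 20
    specimens_per_species: int | tuple[int, int] = 10
    sequence_length: int = 658
    yule_rate: float = 0.5  # speciation events / Myr on the species tree
    species_stem_myr: float = 1.5  # padding on every terminal species branch
    within_species_depth: float = 0.003  # expected pairwise coalescent depth, subs/site
    kappa: float = 4.0  # transition/transversion rate ratio
    pairwise_clock_rate: float = 0.015  # pairwise divergence, subs/site per Myr
    n_families: int = 3
    genus_size: int = 3
    region_quotas: dict[str, int] | None = None  # region -> number of species
    sharing_events: list[SharingEvent] = field(default_factory=list)
    deep_split_events: list[DeepSplitEvent] = field(default_factory=list)
    over_split_events: list[OverSplitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("yule_rate", "species_stem_myr", "within_species_depth",
                     "kappa", "pairwise_clock_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the audit must recover."""

    species_partition: dict[str, str]  # specimen -> true cluster (pre-relabel)
    label_of: dict[str, str]  # specimen -> emitted species label
    haplotype_counts: dict[str, int]  # emitted label -> distinct sequences
    sharing_pairs: list[tuple[str, str]]
    deep_split_species: list[str]
    over_split_pairs: list[tuple[str, str]]
    tree_newick: str

    def to_json(self) -> str:
        payload = asdict(self)
        payload["sharing_pairs"] = [list(p) for p in self.sharing_pairs]
        payload["over_split_pairs"] = [list(p) for p in self.over_split_pairs]
        return json.dumps(payload, indent=2, sort_keys=True)


def _specimen_counts(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    spec = config.specimens_per_species
    if isinstance(spec, int):
        return [spec] * config.n_species
    low, high = spec
    return [int(rng.integers(low, high + 1)) for _ in range(config.n_species)]


def _simulate_yule_ages(
    n: int, rate: float, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    """Forward-time pure birth; returns merge history as (i, j, node_age)."""
    # simulate split times forward, then convert to ages above the tips
    times = [0.0]
    t = 0.0
    for k in range(1, n):
        t += rng.exponential(1.0 / (rate * k))
        times.append(t)
    total = t
    # build topology: each split event picks a random active lineage
    return times, total


def simulate_genealogy(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Species tree + grafted within-species coalescents, in subs/site.

    Returns an ultrametric genealogy whose leaves are specimen ids, plus the
    specimen -> species map.  Within-species coalescent depths are resampled
    (conditioned) to fit under the species' terminal branch, so all
    cross-species divergences exceed all within-species divergences whenever
    the stem dominates the coalescent depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_lineage_rate = config.pairwise_clock_rate / 2.0  # subs/site per Myr per lineage

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    # --- Yule species tree (forward time, in Myr) -------------------------
    n_sp = config.n_species
    split_times, total = _simulate_yule_ages(n_sp, config.yule_rate, rng)
    # active lineages carry (node, birth_time); root lineage born at 0
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0)]
    for event_time in split_times[1:]:
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.edge.length = (event_time - birth) * per_lineage_rate
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, event_time))
        active.append((right, event_time))
    species_tips: list[tuple[dendropy.Node, float]] = []
    for node, birth in active:
        # terminal branch runs to the present plus the stem padding
        term_myr = (total - birth) + config.species_stem_myr
        species_tips.append((node, term_myr * per_lineage_rate))
    if n_sp == 1:
        species_tips = [(root, config.species_stem_myr * per_lineage_rate)]

    # --- within-species coalescents, grafted ------------------------------
    counts = _specimen_counts(config, rng)
    species_map: dict[str, str] = {}
    for sp_index, ((tip, term_len), m) in enumerate(zip(species_tips, counts), start=1):
        species = f"Species_{sp_index:03d}"
        subtree_root, height = _coalescent_subtree(
            species, m, config.within_species_depth, term_len, ns, rng
        )
        for leaf in _leaves_of(subtree_root):
            species_map[leaf.taxon.label] = species
        if tip.parent_node is None and n_sp == 1:
            tree.seed_node = subtree_root
        else:
            parent = tip.parent_node
            parent.remove_child(tip)
            parent.add_child(subtree_root)
            subtree_root.edge.length = term_len - height
    if n_sp > 1:
        tree.seed_node = root
    tree.is_rooted = True
    return tree, species_map


def _leaves_of(node: dendropy.Node):
    return node.leaf_iter()


def _coalescent_subtree(
    species: str,
    m: int,
    depth: float,
    max_height: float,
    ns: dendropy.TaxonNamespace,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[dendropy.Node, float]:
    """Kingman coalescent over m tips; expected pairwise TMRCA = depth.

    Conditioned (by rejection) on fitting under ``max_height``.
    """
    for _ in range(max_tries):
        if m == 1:
            node = dendropy.Node(taxon=ns.new_taxon(f"{species}_001"))
            return node, 0.0
        times = []
        t = 0.0
        for k in range(m, 1, -1):
            pairs = k * (k - 1) / 2.0
            t += rng.exponential(depth / pairs)
            times.append(t)
        if times[-1] < max_height:
            break
    else:
        raise DataError(
            f"could not fit a coalescent of depth {depth} under a branch of "
            f"length {max_height} for {species}; increase the species stem"
        )
    nodes = [
        (dendropy.Node(taxon=ns.new_taxon(f"{species}_{i + 1:03d}")), 0.0)
        for i in range(m)
    ]
    for merge_time in times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = merge_time - ha
        nb.edge.length = merge_time - hb
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, merge_time))
    root, height = nodes[0]
    return root, height


# stop codons of the invertebrate mitochondrial code (TAA, TAG) in the
# A=0, G=1, C=2, T=3 encoding: first position T, second A, third A or G
_STOP_FIRST, _STOP_SECOND, _STOP_THIRD = 3, 0, (0, 1)


def _frame1_stop_mask(states: np.ndarray) -> np.ndarray:
    """Boolean mask over frame-1 codons that are stops (TAA/TAG)."""
    n_codons = states.shape[-1] // 3
    codons = states[: n_codons * 3].reshape(n_codons, 3)
    return (
        (codons[:, 0] == _STOP_FIRST)
        & (codons[:, 1] == _STOP_SECOND)
        & np.isin(codons[:, 2], _STOP_THIRD)
    )


def random_coding_sequence(
    length: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random sequence with frame-1 stop codons resampled away."""
    state = rng.integers(0, 4, size=length).astype(np.int8)
    while True:
        stops = np.flatnonzero(_frame1_stop_mask(state))
        if not len(stops):
            return state
        for c in stops:
            state[3 * c : 3 * c + 3] = rng.integers(0, 4, size=3)


def evolve_sequences_k80(
    genealogy: dendropy.Tree,
    kappa: float,
    root_sequence: str | None = None,
    seed: int | np.random.Generator = 0,
    sequence_length: int = 658,
    avoid_stop_codons: bool = True,
) -> dict[str, str]:
    """Simulate K80 substitution along a genealogy; returns leaf sequences.

    Branch lengths are in expected substitutions/site.  Transitions occur at
    rate ``kappa`` times each transversion; the root sequence defaults to a
    random draw from the uniform K80 stationary distribution.

    With ``avoid_stop_codons`` (the default) the process emulates the
    purifying selection acting on a protein-coding barcode: substitutions
    are conditioned on never creating a frame-1 stop codon (TAA/TAG of the
    invertebrate mitochondrial code), and the default root sequence is drawn
    stop-free.  Codons already containing a stop in the parent (possible for
    a user-supplied root) are left unconstrained.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code_of = {b: i for i, b in enumerate(_BASES)}
    if root_sequence is None:
        if avoid_stop_codons:
            root = random_coding_sequence(sequence_length, rng)
        else:
            root = rng.integers(0, 4, size=sequence_length).astype(np.int8)
    else:
        root_sequence = root_sequence.upper()
        if set(root_sequence) - set(_BASES):
            raise DataError("root sequence must be unambiguous A/C/G/T")
        root = np.array([code_of[c] for c in root_sequence], dtype=np.int8)
        sequence_length = len(root)

    # substitution rates scaled so a branch of length t expects t subs/site
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta

    def _branch_probs(t: float) -> tuple[float, float]:
        e1 = np.exp(-4.0 * beta * t)
        e2 = np.exp(-2.0 * (alpha + beta) * t)
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv_each = 0.25 - 0.25 * e1
        return p_ts, p_tv_each

    def _mutate(parent_state: np.ndarray, sites: np.ndarray, p_ts: float, p_tv: float) -> np.ndarray:
        """Sample child states for the given sites under K80 branch probabilities."""
        sub = parent_state[sites]
        u = rng.random(len(sites))
        state = sub.copy()
        ts_mask = u < p_ts
        tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
        tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        # transition partner flips the low bit (A<->G, C<->T)
        state[ts_mask] = sub[ts_mask] ^ 1
        other = (1 - (sub >> 1)) * 2  # first base of the other class
        state[tv1_mask] = other[tv1_mask]
        state[tv2_mask] = other[tv2_mask] + 1
        return state

    def _sample_child(parent_state: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return parent_state.copy()
        p_ts, p_tv = _branch_probs(t)
        length = len(parent_state)
        state = parent_state.copy()
        state[:] = _mutate(parent_state, np.arange(length), p_ts, p_tv)
        if avoid_stop_codons:
            allowed = ~_frame1_stop_mask(parent_state)  # pre-existing stops stay free
            while True:
                bad = np.flatnonzero(_frame1_stop_mask(state) & allowed)
                if not len(bad):
                    break
                sites = (3 * bad[:, None] + np.arange(3)).ravel()
                state[sites] = _mutate(parent_state, sites, p_ts, p_tv)
        return state

    states: dict[dendropy.Node, np.ndarray] = {genealogy.seed_node: root}
    out: dict[str, str] = {}
    for node in genealogy.preorder_node_iter():
        if node is not genealogy.seed_node:
            t = node.edge.length or 0.0
            states[node] = _sample_child(states[node.parent_node], t)
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[c] for c in states[node])
    return out


def _records_from(
    sequences: Mapping[str, str],
    species_map: Mapping[str, str],
    config: SimulationConfig,
) -> list[SpecimenRecord]:
    species_list = sorted(set(species_map.values()))
    quotas = config.region_quotas
    if quotas is None:
        n = len(species_list)
        third = n // 3
        quotas = {
            "north_alpine": third,
            "mid_latitude": third,
            "south": n - 2 * third,
        }
    if sum(quotas.values()) != len(species_list):
        raise ConfigurationError(
            f"region quotas sum to {sum(quotas.values())}, expected {len(species_list)}"
        )
    region_of: dict[str, str] = {}
    it = iter(species_list)
    for region, count in quotas.items():
        for _ in range(count):
            region_of[next(it)] = region
    family_of: dict[str, str] = {}
    genus_of: dict[str, str] = {}
    block = max(1, -(-len(species_list) // config.n_families))
    for i, sp in enumerate(species_list):
        family_of[sp] = f"Family_{i // block + 1:02d}"
        genus_of[sp] = f"Genus_{i // config.genus_size + 1:03d}"
    records = []
    for sid in sorted(sequences):
        sp = species_map[sid]
        records.append(
            SpecimenRecord(
                specimen_id=sid, species=sp, genus=genus_of[sp],
                family=family_of[sp], region=region_of[sp],
                sequence=sequences[sid],
            )
        )
    return records


def inject_events(
    records: Sequence[SpecimenRecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> tuple[list[SpecimenRecord], SyntheticTruth]:
    """Apply sharing / deep-split / over-split events; update the truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_species: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)

    def _require(species: str) -> list[SpecimenRecord]:
        if species not in by_species:
            raise DataError(f"event references missing species {species!r}")
        return sorted(by_species[species], key=lambda r: r.specimen_id)

    for ev in config.sharing_events:
        donors = _require(ev.donor_species)
        recipients = _require(ev.recipient_species)
        if ev.n_recipients > len(recipients):
            raise DataError(f"sharing event wants {ev.n_recipients} recipients, "
                            f"{ev.recipient_species} has {len(recipients)}")
        donor = donors[int(rng.integers(len(donors)))]
        chosen = rng.choice(len(recipients), size=ev.n_recipients, replace=False)
        for k in sorted(int(c) for c in chosen):
            recipients[k].sequence = donor.sequence
        truth.sharing_pairs.append(
            tuple(sorted((ev.donor_species, ev.recipient_species)))
        )

    for ev in config.deep_split_events:
        members = _require(ev.species)
        n_move = ev.n_specimens if ev.n_specimens is not None else len(members) // 2
        if not 1 <= n_move <= len(members):
            raise DataError(f"deep-split event size {n_move} invalid for {ev.species}")
        source = members[0]
        divergent = _diverge(source.sequence, ev.extra_depth, config.kappa, rng)
        for rec in members[-n_move:]:
            rec.sequence = divergent
        truth.deep_split_species.append(ev.species)

    for ev in config.over_split_events:
        members = _require(ev.species)
        n_move = max(1, int(round(ev.fraction * len(members))))
        new_label = ev.new_label or f"{ev.species}_b"
        for rec in members[-n_move:]:
            rec.species = new_label
            truth.label_of[rec.specimen_id] = new_label
        truth.over_split_pairs.append((ev.species, new_label))
        by_species[new_label] = [r for r in members[-n_move:]]
        by_species[ev.species] = [r for r in members[:-n_move]]

    truth.haplotype_counts = _haplotype_counts(records)
    return list(records), truth


def _diverge(sequence: str, depth: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve one divergent copy of a sequence along an extra branch."""
    one = dendropy.Tree()
    child = dendropy.Node(taxon=one.taxon_namespace.new_taxon("x"))
    one.seed_node.add_child(child)
    child.edge.length = depth
    return evolve_sequences_k80(one, kappa, root_sequence=sequence, seed=rng)["x"]


def _haplotype_counts(records: Sequence[SpecimenRecord]) -> dict[str, int]:
    pools: dict[str, set[str]] = {}
    for rec in records:
        pools.setdefault(rec.species, set()).add(rec.sequence)
    return {sp: len(seqs) for sp, seqs in sorted(pools.items())}


def generate_dataset(
    config: SimulationConfig, seed: int
) -> tuple[list[SpecimenRecord], SyntheticTruth]:
    """Full generation: genealogy, sequences, records, injected events."""
    rng = np.random.default_rng(seed)
    tree, species_map = simulate_genealogy(config, rng)
    sequences = evolve_sequences_k80(
        tree, config.kappa, seed=rng, sequence_length=config.sequence_length
    )
    records = _records_from(sequences, species_map, config)
    truth = SyntheticTruth(
        species_partition=dict(sorted(species_map.items())),
        label_of={r.specimen_id: r.species for r in records},
        haplotype_counts=_haplotype_counts(records),
        sharing_pairs=[],
        deep_split_species=[],
        over_split_pairs=[],
        tree_newick=tree.as_string(schema="newick").strip(),
    )
    records, truth = inject_events(records, truth, config, rng)
    return records, truth


def emit_dataset(
    records: Sequence[SpecimenRecord],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + metadata TSV + truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "sequences.fasta"
    meta = out / "metadata.tsv"
    truth_path = out / "truth.json"
    write_dataset(records, fasta, meta)
    truth_path.write_text(truth.to_json() + "\n")
    return {"fasta": fasta, "metadata": meta, "truth": truth_path}
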