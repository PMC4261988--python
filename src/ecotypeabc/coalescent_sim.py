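"""Structured-coalescent simulation of multi-marker datasets.

Genealogies are generated backward in time under a
:class:`~ecotypeabc.demographic_models.DemographicScenario` by a Gillespie
walk over coalescence and migration events: within a deme of diploid size
``N`` each lineage pair coalesces at rate ``1/(2N*ne_scale)`` per
generation, and each lineage migrates ``i -> j`` at the epoch's
per-generation probability ``m_ij`` (used directly as a continuous-time
rate, valid for m << 1).  Sequences evolve on the genealogy under a
finite-sites Kimura 2-parameter model.  Three marker classes are
supported: one mitochondrial fragment (haploid, maternal: deme sizes
scaled by 0.25, one sequence per sampled female), nuclear introns (one
haplotype kept per individual), and AFLP loci (20-bp sequences, two
copies per individual) which are converted to dominant band-presence
phenotypes.

The inner event loops are numba-compiled; everything downstream is numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .demographic_models import DemographicScenario, build_scenario

__all__ = [
    "LocusSpec",
    "Genealogy",
    "MultiMarkerDataset",
    "default_locus_roster",
    "simulate_genealogy",
    "mutate_k2p",
    "aflp_phenotypes",
    "simulate_dataset",
]

#: Fixed mitochondrial calibration: rate per base per generation, fraction
#: of substitutions that are transitions, and the haploid/maternal scaling
#: of deme sizes.
MTDNA_MU = 1.5e-8
MTDNA_TS_FRACTION = 0.91
MTDNA_NE_SCALE = 0.25
#: Unbiased transition fraction used for nuclear and AFLP sequences
#: (one of three substitution types is a transition).
NUCLEAR_TS_FRACTION = 0.33

_MAX_EVENTS = 50_000_000  # hard cap per genealogy; exceeded => non-terminating


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus: class, length, mutation model, ploidy handling."""

    name: str
    klass: str  # "mtDNA" | "nuclear" | "AFLP"
    length: int
    mu: float
    ts_fraction: float
    copies_per_individual: int = 1
    ne_scale: float = 1.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValueError("ts_fraction must be in [0,1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.klass not in ("mtDNA", "nuclear", "AFLP"):
            raise ValueError(f"unknown locus class {self.klass!r}")


def default_locus_roster(MU: float, AFLPMU: float, n_aflp: int = 462) -> list[LocusSpec]:
    """The study's marker panel: a 2004-bp mtDNA fragment, three nuclear
    introns (376, 270 and 341 bp; the middle intron is pre-pruned of its
    recombining 5' segment), and ``n_aflp`` 20-bp AFLP loci."""
    roster = [
        LocusSpec("mtDNA", "mtDNA", 2004, MTDNA_MU, MTDNA_TS_FRACTION,
                  copies_per_individual=1, ne_scale=MTDNA_NE_SCALE),
        LocusSpec("Cal", "nuclear", 376, MU, NUCLEAR_TS_FRACTION),
        LocusSpec("ElFac", "nuclear", 270, MU, NUCLEAR_TS_FRACTION),
        LocusSpec("ThioPer", "nuclear", 341, MU, NUCLEAR_TS_FRACTION),
    ]
    for i in range(n_aflp):
        roster.append(
            LocusSpec(f"aflp{i:03d}", "AFLP", 20, AFLPMU, NUCLEAR_TS_FRACTION,
                      copies_per_individual=2)
        )
    return roster


@dataclass(frozen=True)
class Genealogy:
    """A complete coalescent tree over ``n_leaves`` sampled lineages.

    Nodes ``0..n_leaves-1`` are leaves at time 0; internal nodes are
    appended in coalescence order, so node times are non-decreasing in the
    node index and the last node is the root.
    """

    parent: np.ndarray  # (2n-1,) int64, -1 at the root
    time: np.ndarray  # (2n-1,) generations
    deme: np.ndarray  # (2n-1,) deme at sampling / coalescence
    leaf_demes: np.ndarray  # (n,) deme of each leaf

    @property
    def n_leaves(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    @property
    def total_branch_length(self) -> float:
        p = self.parent[:-1]
        return float(np.sum(self.time[p] - self.time[:-1]))


@dataclass
class MultiMarkerDataset:
    """Simulated (or observed) haplotype alignments plus a dominant-marker
    phenotype matrix, grouped by deme."""

    groups: tuple[str, ...]
    sequences: dict  # locus name -> {group name -> (n, L) int8 alignment}
    aflp: np.ndarray  # (n_individuals, n_loci) 0/1
    aflp_groups: np.ndarray  # (n_individuals,) group labels (str)
    aflp_locus_names: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.aflp.size and not np.isin(self.aflp, (0, 1)).all():
            raise ValueError("AFLP matrix entries must be 0/1")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_tree(seed, sizes0, epoch_starts, mig, ev_time, ev_kind, ev_a, ev_b,
              ev_size, lineage_demes, ne_scale):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = lineage_demes.shape[0]
    D = sizes0.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    node_deme = np.zeros(n_nodes, dtype=np.int64)
    sizes = sizes0.copy()

    # per-deme membership lists for O(1) event handling
    members = np.zeros((D, n), dtype=np.int64)
    k = np.zeros(D, dtype=np.int64)
    for i in range(n):
        d = lineage_demes[i]
        node_deme[i] = d
        members[d, k[d]] = i
        k[d] += 1

    t = 0.0
    epoch_idx = 0
    ev_idx = 0
    n_epochs = epoch_starts.shape[0]
    n_ev = ev_time.shape[0]
    next_node = n
    alive = n
    coal_rate = np.zeros(D)
    mig_rate = np.zeros(D)
    events_done = 0

    while alive > 1:
        events_done += 1
        if events_done > _MAX_EVENTS:
            return parent, node_time, node_deme, 2  # runaway

        tb = np.inf
        if epoch_idx + 1 < n_epochs:
            tb = epoch_starts[epoch_idx + 1]
        if ev_idx < n_ev and ev_time[ev_idx] < tb:
            tb = ev_time[ev_idx]

        total = 0.0
        for d in range(D):
            kd = k[d]
            coal_rate[d] = kd * (kd - 1) / (4.0 * sizes[d] * ne_scale)
            mr = 0.0
            for j in range(D):
                mr += mig[epoch_idx, d, j]
            mig_rate[d] = kd * mr
            total += coal_rate[d] + mig_rate[d]

        if total > 0.0:
            dt = np.random.exponential(1.0 / total)
        else:
            dt = np.inf
        if t + dt >= tb:
            if not np.isfinite(tb):
                return parent, node_time, node_deme, 1  # non-terminating
            t = tb
            while ev_idx < n_ev and ev_time[ev_idx] <= t:
                a = ev_a[ev_idx]
                if ev_kind[ev_idx] == 0:  # merge a -> b
                    b = ev_b[ev_idx]
                    for s in range(k[a]):
                        members[b, k[b]] = members[a, s]
                        k[b] += 1
                    k[a] = 0
                else:  # resize
                    sizes[a] = ev_size[ev_idx]
                ev_idx += 1
            while epoch_idx + 1 < n_epochs and epoch_starts[epoch_idx + 1] <= t:
                epoch_idx += 1
            continue

        t += dt
        u = np.random.random() * total
        d = -1
        is_coal = True
        acc = 0.0
        for dd in range(D):
            acc += coal_rate[dd]
            if u < acc:
                d = dd
                is_coal = True
                break
            acc += mig_rate[dd]
            if u < acc:
                d = dd
                is_coal = False
                break
        if d < 0:  # numerical edge: u == total
            d = D - 1
            is_coal = mig_rate[D - 1] == 0.0

        if is_coal:
            kd = k[d]
            i1 = np.random.randint(0, kd)
            i2 = np.random.randint(0, kd - 1)
            if i2 >= i1:
                i2 += 1
            c1 = members[d, i1]
            c2 = members[d, i2]
            node = next_node
            next_node += 1
            parent[c1] = node
            parent[c2] = node
            node_time[node] = t
            node_deme[node] = d
            # replace c1 by the new node, drop c2 (swap with last slot)
            members[d, i1] = node
            members[d, i2] = members[d, kd - 1]
            k[d] = kd - 1
            alive -= 1
        else:
            # choose destination deme proportional to m[d, j]
            row_total = mig_rate[d] / k[d]
            v = np.random.random() * row_total
            dest = -1
            acc2 = 0.0
            for j in range(D):
                acc2 += mig[epoch_idx, d, j]
                if v < acc2:
                    dest = j
                    break
            if dest < 0:
                dest = D - 1
            kd = k[d]
            i1 = np.random.randint(0, kd)
            lin = members[d, i1]
            members[d, i1] = members[d, kd - 1]
            k[d] = kd - 1
            members[dest, k[dest]] = lin
            k[dest] += 1

    return parent, node_time, node_deme, 0


@njit(cache=True)
def _mutate(seed, parent, node_time, n_leaves, L, mu, ts_fraction):  # pragma: no cover
    np.random.seed(seed)
    n_nodes = parent.shape[0]
    seq = np.empty((n_nodes, L), dtype=np.int8)
    root = n_nodes - 1
    for b in range(L):
        seq[root, b] = np.random.randint(0, 4)
    for node in range(n_nodes - 2, -1, -1):
        p = parent[node]
        for b in range(L):
            seq[node, b] = seq[p, b]
        blen = node_time[p] - node_time[node]
        n_mut = np.random.poisson(mu * L * blen)
        for _ in range(n_mut):
            site = np.random.randint(0, L)
            cur = seq[node, site]
            if np.random.random() < ts_fraction:
                seq[node, site] = cur ^ 2  # A<->G, C<->T
            else:
                if np.random.random() < 0.5:
                    seq[node, site] = cur ^ 1
                else:
                    seq[node, site] = cur ^ 3
    return seq[:n_leaves]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_genealogy_arrays(
    compiled: dict, lineage_demes: np.ndarray, ne_scale: float, seed: int
) -> Genealogy:
    """Run the coalescent kernel on pre-compiled scenario arrays."""
    lineage_demes = np.asarray(lineage_demes, dtype=np.int64)
    parent, node_time, node_deme, err = _sim_tree(
        seed,
        compiled["sizes"], compiled["epoch_starts"], compiled["migration"],
        compiled["ev_time"], compiled["ev_kind"], compiled["ev_a"],
        compiled["ev_b"], compiled["ev_size"],
        lineage_demes, float(ne_scale),
    )
    if err == 1:
        raise RuntimeError(
            "non-terminating scenario: lineages isolated with no coalescence, "
            "migration, or merge event ahead"
        )
    if err == 2:
        raise RuntimeError("genealogy simulation exceeded the event cap")
    return Genealogy(parent=parent, time=node_time, deme=node_deme,
                     leaf_demes=lineage_demes.copy())


def simulate_genealogy(
    scenario: DemographicScenario,
    samples: dict[str, int],
    ne_scale: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Genealogy:
    """Simulate one genealogy for ``samples`` lineages per named deme.

    ``samples`` maps deme names to lineage counts; unnamed demes carry no
    samples.  ``ne_scale`` rescales every deme size (0.25 for mtDNA).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    name_to_idx = {d.name: i for i, d in enumerate(scenario.demes)}
    lineage_demes = []
    for name, cnt in samples.items():
        if name not in name_to_idx:
            raise ValueError(f"unknown deme {name!r}")
        if cnt < 1:
            raise ValueError("sample counts must be >= 1")
        lineage_demes.extend([name_to_idx[name]] * int(cnt))
    return simulate_genealogy_arrays(
        scenario.compile(), np.array(lineage_demes), ne_scale, _kernel_seed(rng)
    )


def mutate_k2p(
    genealogy: Genealogy,
    spec: LocusSpec,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Drop K2P mutations on a genealogy; returns an (n_leaves, length)
    int8 alignment with bases encoded A=0, C=1, G=2, T=3.

    Mutation counts per branch are Poisson(mu * length * branch length);
    each hit strikes a uniform site and is a transition with probability
    ``ts_fraction``, else one of the two transversions equally.  The
    ancestral base at each site is uniform over the four nucleotides.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    return _mutate(
        _kernel_seed(rng), genealogy.parent, genealogy.time,
        genealogy.n_leaves, spec.length, spec.mu, spec.ts_fraction,
    )


def aflp_phenotypes(
    locus_haplotypes: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Convert 20-bp haplotype matrices to a dominant band-presence matrix.

    Per locus, one haplotype sequence is drawn uniformly from the distinct
    haplotypes present in the sample and designated the "1" (band) allele;
    every other haplotype is a "0" allele.  Individuals are formed by
    pairing consecutive haplotype rows; the phenotype is 1 (band present)
    iff at least one copy carries the chosen allele.  Loci whose phenotype
    column is all-zero would be unobservable and are removed; under this
    choose-from-present convention that cannot occur, so the returned
    locus count equals the input count.
    """
    cols = []
    weights = (4 ** np.arange(20)).astype(np.int64)
    for hap in locus_haplotypes:
        if hap.shape[0] % 2:
            raise ValueError("odd haplotype count; individuals are haplotype pairs")
        if hap.shape[1] != 20:
            raise ValueError("AFLP loci must be 20 bp")
        codes = hap.astype(np.int64) @ weights
        chosen = rng.choice(np.unique(codes))
        present = codes == chosen
        cols.append(present[0::2] | present[1::2])
    matrix = np.column_stack(cols).astype(np.int8)
    keep = matrix.any(axis=0)
    return matrix[:, keep], int(keep.sum())


def simulate_dataset(
    rec: dict,
    samples_seq: dict[str, int],
    samples_aflp: dict[str, int],
    rng: np.random.Generator,
    loci: list[LocusSpec] | None = None,
    scenario: DemographicScenario | None = None,
) -> MultiMarkerDataset:
    """Simulate the full marker panel under one parameter record.

    ``samples_seq`` gives sequences per group for the sequence loci (one
    haplotype per individual) and ``samples_aflp`` diploid individuals per
    group for the AFLP loci (two haplotypes each).  Groups are the
    scenario's sampled demes.
    """
    if scenario is None:
        scenario = build_scenario(rec)
    if loci is None:
        loci = default_locus_roster(rec["MU"], rec["AFLPMU"])
    compiled = scenario.compile()
    name_to_idx = {d.name: i for i, d in enumerate(scenario.demes)}
    groups = tuple(sorted(samples_seq, key=name_to_idx.__getitem__))

    def lineages(samples: dict[str, int], copies: int) -> np.ndarray:
        out = []
        for g in groups:
            out.extend([name_to_idx[g]] * (samples[g] * copies))
        return np.array(out, dtype=np.int64)

    sequences: dict[str, dict[str, np.ndarray]] = {}
    aflp_haps: list[np.ndarray] = []
    for spec in loci:
        if spec.klass == "AFLP":
            lin = lineages(samples_aflp, 2)
        else:
            lin = lineages(samples_seq, 1)
        g = simulate_genealogy_arrays(compiled, lin, spec.ne_scale, _kernel_seed(rng))
        aln = _mutate(_kernel_seed(rng), g.parent, g.time, g.n_leaves,
                      spec.length, spec.mu, spec.ts_fraction)
        if spec.klass == "AFLP":
            aflp_haps.append(aln)
        else:
            by_group = {}
            ofs = 0
            for gname in groups:
                n = samples_seq[gname]
                by_group[gname] = aln[ofs:ofs + n]
                ofs += n
            sequences[spec.name] = by_group

    if aflp_haps:
        aflp, _ = aflp_phenotypes(aflp_haps, rng)
        labels = np.concatenate([np.repeat(g, samples_aflp[g]) for g in groups])
        names = tuple(s.name for s in loci if s.klass == "AFLP")
    else:
        aflp = np.zeros((0, 0), dtype=np.int8)
        labels = np.zeros(0, dtype="U1")
        names = ()
    return MultiMarkerDataset(
        groups=groups,
        sequences=sequences,
        aflp=aflp,
        aflp_groups=labels,
        aflp_locus_names=names[: aflp.shape[1]],
        provenance={"params": dict(rec)},
    )
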