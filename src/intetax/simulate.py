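"""Synthetic species-complex data generator.

Emulates the data structure of a host-associated cryptic-species complex:
a small number of deeply diverged species (host races), each sampled with
several specimens whose sequences differ only shallowly. Concretely, the
generator produces

* an ultrametric tree whose between-species nodes follow a Yule process
  and whose within-species genealogies follow a neutral coalescent,
* a COI-like alignment evolved under the K2P (K80) substitution model with
  a configurable number of injected fixed between-species differences
  (which downstream diagnostics recover as pure characters),
* 7-landmark forewing configurations per specimen with two digitization
  replicates under per-specimen nuisance similarity transforms,
* a reciprocal mating-cross matrix with compatibility on the diagonal, and
* a labeled reference barcode library (binomial species names) for the
  barcode-gap benchmark.

Default parameters reproduce the statistical conditions the analysis
assumes: ~11% K2P divergence between species, ~1.5% within, three
host-associated species of ten specimens each, 631-bp sequences with 73
fixed diagnostic differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .distances import LabeledAlignment
from .partition import Partition

__all__ = [
    "SimConfig",
    "SpecimenRecord",
    "SyntheticDataset",
    "simulate_species_tree",
    "evolve_sequences",
    "simulate_landmarks",
    "simulate_mating",
    "simulate_reference_library",
    "make_diagnostic_alignment",
    "simulate_dataset",
    "MatingMatrix",
]

# Specimen-metadata vocabulary for decorative host/locality columns: one
# (insect host, [(locality, plant host), ...]) entry per species slot.
_HOST_VOCAB = [
    ("R. sariuoni", [("Beijing, Haidian", "Malus spectabilis"),
                     ("Shandong, Taian", "Prunus cerasifera"),
                     ("Jilin, Changchun", "Prunus persica")]),
    ("E. kuwanai", [("Beijing, Xiangshan", "Sophora japonica"),
                    ("Henan, Zhengzhou", "Sophora japonica"),
                    ("Heilongjiang, Harbin", "Ulmus sp.")]),
    ("T. japonica", [("Jiangsu, Nanjing", "Albizzia julibrissin"),
                     ("Zhejiang, Ningbo", "Loropetalum chinense")]),
]
_SPECIES_CODES = ["RS", "EK", "TJ"]

_BASES = "AGCT"  # code ^ 1 is the transition partner

# A plausible forewing outline: 7 landmarks along the anterior veins
# (1-5), wing tip (6) and posterior margin (7), in arbitrary units.
_BASE_WING = np.array(
    [
        [0.00, 0.00],
        [0.35, 0.08],
        [0.55, 0.10],
        [0.72, 0.09],
        [0.64, 0.02],
        [1.00, -0.05],
        [0.45, -0.30],
    ]
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic species complex.

    ``subs_rate`` converts the tree's relative time (root age 1.0) to
    expected substitutions/site; with the defaults a root-spanning pair is
    ~12% diverged and a within-species pair ~1.5% (2 * coal_theta *
    subs_rate), matching the divergence structure the analysis assumes.
    """

    n_species: int = 3
    n_per_species: int = 10
    yule_rate: float = 3.0
    min_split: float = 0.4
    coal_theta: float = 0.135
    seq_length: int = 631
    kappa: float = 2.0
    subs_rate: float = 0.062
    at_fraction: float = 0.715
    n_fixed_diag: int = 73
    landmark_noise_sd: float = 0.02
    group_shape_sep: float = 0.08
    mating_error: float = 0.0
    mating_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_per_species < 1:
            raise ValueError("counts must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.yule_rate <= 0 or self.coal_theta <= 0 or self.subs_rate <= 0 or self.kappa <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.mating_error <= 1.0:
            raise ValueError("mating_error must be in [0, 1]")
        if not 0.0 < self.at_fraction < 1.0:
            raise ValueError("at_fraction must be in (0, 1)")
        if not 0.0 <= self.min_split < 1.0:
            raise ValueError("min_split must be in [0, 1)")
        if self.n_fixed_diag > self.seq_length:
            raise ValueError("n_fixed_diag cannot exceed seq_length")
        if self.n_fixed_diag > 0 and self.n_species > 4:
            raise ValueError("fixed diagnostics need distinct states: n_species <= 4")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class SpecimenRecord:
    id: str
    group: str
    insect_host: str
    locality: str
    plant_host: str


def species_codes(n_species: int) -> list[str]:
    return [_SPECIES_CODES[i] if i < len(_SPECIES_CODES) else f"S{i + 1}" for i in range(n_species)]


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _coalescent_heights(n: int, theta: float, rng: np.random.Generator):
    """Kingman coalescent genealogy for ``n`` tips; pair rate 1/theta.

    Returns (newick fragment without root length, TMRCA, node ages) with
    tip placeholders {i}.
    """
    nodes = [(f"@{i}@", 0.0) for i in range(n)]
    t = 0.0
    ages = []
    while len(nodes) > 1:
        k = len(nodes)
        rate = k * (k - 1) / (2.0 * theta)
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        merged = (f"({na}:{t - aa:.12g},{nb}:{t - ab:.12g})", t)
        ages.append(t)
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0][0], t, ages


def simulate_species_tree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the mixed Yule/coalescent specimen tree.

    Between-species divergences follow a Yule process (root age normalized
    to 1.0); each species' within-species genealogy is a neutral coalescent
    with time scale ``coal_theta``, accepted only if its depth is at most
    0.9 x the species' stem age (resampled up to 100 times; if a shallow
    stem exhausts the draws, the last genealogy is rescaled onto 0.9 x the
    stem age so the species/coalescent time-scale separation the
    delimitation relies on is preserved). Returns ``(tree, partition)``
    where the partition maps tip label -> species code.
    """
    if rng is None:
        rng = cfg.rng(stream=1)
    codes = species_codes(cfg.n_species)
    n_sp = cfg.n_species

    # --- single species: the normalized coalescent IS the tree ---
    if n_sp == 1:
        labels = [f"{codes[0]}{i + 1:02d}" for i in range(cfg.n_per_species)]
        if cfg.n_per_species == 1:
            tree = dendropy.Tree.get(data=f"({labels[0]}:1.0);", schema="newick",
                                     preserve_underscores=True)
        else:
            frag, tmrca, _ = _coalescent_heights(cfg.n_per_species, cfg.coal_theta, rng)
            newick = _rescale_newick_fragment(frag, 1.0 / tmrca)
            for i, lab in enumerate(labels):
                newick = newick.replace(f"@{i}@", lab)
            tree = dendropy.Tree.get(data=newick + ";", schema="newick",
                                     preserve_underscores=True)
        part = Partition({lab: codes[0] for lab in labels}, provenance="truth")
        return tree, part

    # forward Yule: split times measured from the root split. The draw is
    # conditioned on every split being at least min_split of the root age
    # ("deep between-clade divergence": all species pairs well separated);
    # after 1000 draws the deepest-splitting draw seen is used.
    best_ages: list[float] | None = None
    for _ in range(1000):
        split_times = [0.0]
        t = 0.0
        for k in range(2, n_sp):
            t += rng.exponential(1.0 / (k * cfg.yule_rate))
            split_times.append(t)
        depth = t + rng.exponential(1.0 / (n_sp * cfg.yule_rate))
        ages = [(depth - s) / depth for s in split_times]  # descending, root = 1.0
        if best_ages is None or min(ages) > min(best_ages):
            best_ages = ages
        if min(ages) >= cfg.min_split:
            break
    node_ages = best_ages

    # topology: active lineages; each split divides a uniformly chosen lineage
    class _SpNode:
        __slots__ = ("age", "children", "species")

        def __init__(self, age, children=None, species=None):
            self.age, self.children, self.species = age, children or [], species

    root = _SpNode(node_ages[0])
    a, b = _SpNode(None, species=0), _SpNode(None, species=1)
    root.children = [a, b]
    active = [a, b]
    for split_i in range(1, n_sp - 1):
        pick = int(rng.integers(len(active)))
        nd = active[pick]
        nd.age = node_ages[split_i]
        c1 = _SpNode(None, species=nd.species)
        c2 = _SpNode(None, species=split_i + 1)
        nd.species = None
        nd.children = [c1, c2]
        active[pick] = c1
        active.append(c2)

    # stem age of each species = age of its parent node
    stem_age: dict[int, float] = {}

    def _collect(nd: _SpNode, parent_age: float) -> None:
        if nd.species is not None:
            stem_age[nd.species] = parent_age
        for ch in nd.children:
            _collect(ch, nd.age if nd.age is not None else parent_age)

    _collect(root, math.inf)

    # --- within-species coalescents ---
    sub_newick: dict[int, tuple[str, float]] = {}
    for sp in range(n_sp):
        labels = [f"{codes[sp]}{i + 1:02d}" for i in range(cfg.n_per_species)]
        if cfg.n_per_species == 1:
            sub_newick[sp] = (labels[0], 0.0)
            continue
        for attempt in range(100):
            frag, tmrca, _ = _coalescent_heights(cfg.n_per_species, cfg.coal_theta, rng)
            if tmrca <= 0.9 * stem_age[sp]:
                break
        else:
            # coal_theta deep relative to this stem: rescale the last draw so
            # its root sits at 0.9 x stem age, preserving the threshold signal
            factor = 0.9 * stem_age[sp] / tmrca
            frag = _rescale_newick_fragment(frag, factor)
            tmrca *= factor
        for i, lab in enumerate(labels):
            frag = frag.replace(f"@{i}@", lab)
        sub_newick[sp] = (frag, tmrca)

    def _newick(nd: _SpNode, parent_age: float) -> str:
        if nd.species is not None:
            frag, tmrca = sub_newick[nd.species]
            return f"{frag}:{parent_age - tmrca:.12g}"
        inner = ",".join(_newick(ch, nd.age) for ch in nd.children)
        if parent_age is math.inf:
            return f"({inner})"
        return f"({inner}):{parent_age - nd.age:.12g}"

    newick = _newick(root, math.inf) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    assignment = {
        f"{codes[sp]}{i + 1:02d}": codes[sp]
        for sp in range(n_sp)
        for i in range(cfg.n_per_species)
    }
    part = Partition(assignment, provenance="truth")
    return tree, part


def _rescale_newick_fragment(frag: str, scale: float) -> str:
    out = []
    i = 0
    while i < len(frag):
        c = frag[i]
        if c == ":":
            j = i + 1
            while j < len(frag) and (frag[j].isdigit() or frag[j] in ".eE+-"):
                j += 1
            out.append(f":{float(frag[i + 1:j]) * scale:.12g}")
            i = j
        else:
            out.append(c)
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Sequence evolution (K80)
# ---------------------------------------------------------------------------

def _k80_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after expected ``d`` subs/site."""
    if d <= 0:
        return 1.0, 0.0, 0.0
    bt = d / (kappa + 2.0)
    e4 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * bt * (kappa + 1.0))
    p_tv = 0.25 - 0.25 * e4
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def evolve_sequences(
    tree: dendropy.Tree,
    cfg: SimConfig,
    partition: Partition | None = None,
    rng: np.random.Generator | None = None,
) -> LabeledAlignment:
    """Evolve sequences along the tree under the K80 model.

    Branch lengths (relative time) are converted to expected
    substitutions/site via ``cfg.subs_rate``. Afterwards ``n_fixed_diag``
    sites are engineered to be pure diagnostic characters (rotating over
    the species): preferentially at sites where the designated species
    already carries a state absent from the others — fixing the species at
    that state realizes the diagnostic inside the natural divergence
    instead of inflating it — with arbitrary forced states only as a
    fallback when the natural supply runs out. Requires the species
    partition when n_fixed_diag > 0.
    """
    if rng is None:
        rng = cfg.rng(stream=2)
    L = cfg.seq_length
    seqs: dict[str, np.ndarray] = {}

    def _evolve(parent_seq: np.ndarray, nd) -> None:
        elen = (nd.edge.length or 0.0) * cfg.subs_rate
        p_same, p_ts, p_tv = _k80_probs(elen, cfg.kappa)
        u = rng.random(L)
        tv_pick = rng.integers(0, 2, L)
        seq = parent_seq.copy()
        ts_mask = (u >= p_same) & (u < p_same + p_ts)
        tv_mask = u >= p_same + p_ts
        seq[ts_mask] = parent_seq[ts_mask] ^ 1
        # transversion: jump to the other purine/pyrimidine pair
        base = parent_seq[tv_mask]
        seq[tv_mask] = np.where(base < 2, 2 + tv_pick[tv_mask], tv_pick[tv_mask])
        if nd.is_leaf():
            seqs[nd.taxon.label] = seq
        else:
            for ch in nd.child_nodes():
                _evolve(seq, ch)

    if not tree.seed_node.child_nodes():
        raise ValueError("tree has no tips")
    # AT-rich root composition (insect mtDNA); K80 is symmetric, so the
    # composition persists to the tips at these divergence depths
    half_at = cfg.at_fraction / 2.0
    half_cg = (1.0 - cfg.at_fraction) / 2.0
    root_seq = rng.choice(4, size=L, p=[half_at, half_cg, half_cg, half_at]).astype(np.int64)
    for ch in tree.seed_node.child_nodes():
        _evolve(root_seq, ch)

    ids = sorted(seqs)
    if cfg.n_fixed_diag > 0:
        if partition is None:
            raise ValueError("n_fixed_diag > 0 requires the species partition")
        species = sorted(set(partition.assignment.values()))
        arr = np.stack([seqs[i] for i in ids])
        rows = {
            sp: [k for k, i in enumerate(ids) if partition.assignment[i] == sp]
            for sp in species
        }
        order = rng.permutation(L)
        injected: set[int] = set()
        other_rows = {
            g: np.concatenate([rows[s] for s in species if s != g]) for g in species
        }

        def _try_fix(pos: int, zero_cost_only: bool) -> bool:
            for g in sorted(species):
                other_states = set(arr[other_rows[g], pos].tolist())
                g_col = arr[rows[g], pos]
                cand = [s for s in set(g_col.tolist()) if s not in other_states]
                if not cand:
                    continue
                counts = {s: int((g_col == s).sum()) for s in cand}
                best = max(sorted(cand), key=lambda s: counts[s])
                if zero_cost_only and counts[best] < len(g_col):
                    continue
                if not zero_cost_only and 2 * counts[best] < len(g_col):
                    continue  # only fix along the majority, never a rare variant
                arr[rows[g], pos] = best
                return True
            return False

        # sweep A: sites already pure for some species (no sequence change);
        # sweep B: fix a majority state that the other species lack;
        # sweep C (last resort): force a free state, fixing the others too.
        for zero_cost_only in (True, False):
            for pos in order:
                if len(injected) == cfg.n_fixed_diag:
                    break
                if int(pos) in injected:
                    continue
                if _try_fix(int(pos), zero_cost_only):
                    injected.add(int(pos))
        for pos in order:
            if len(injected) == cfg.n_fixed_diag:
                break
            if int(pos) in injected:
                continue
            g = sorted(species)[len(injected) % len(species)]
            for s in species:
                if s != g:
                    col = arr[rows[s], pos]
                    vals, cnts = np.unique(col, return_counts=True)
                    arr[rows[s], pos] = vals[int(np.argmax(cnts))]
            free = sorted(set(range(4)) - set(arr[other_rows[g], pos].tolist()))
            arr[rows[g], pos] = free[0]
            injected.add(int(pos))
        for k, i in enumerate(ids):
            seqs[i] = arr[k]

    labels = [partition.assignment[i] if partition else "" for i in ids]
    seq_strs = ["".join(_BASES[c] for c in seqs[i]) for i in ids]
    return LabeledAlignment(ids, labels, seq_strs)


# ---------------------------------------------------------------------------
# Landmarks, mating, metadata
# ---------------------------------------------------------------------------

def _group_offsets(n_groups: int, sep: float) -> np.ndarray:
    """Deterministic distinct mean-shape offsets, one per group."""
    offsets = np.zeros((n_groups, _BASE_WING.shape[0], 2))
    for g in range(n_groups):
        a, b = g % 7, (g + 3) % 7
        offsets[g, a] += (sep, -sep)
        offsets[g, b] += (-sep, sep)
    return offsets


def _biological_covariance_root(n_landmarks: int = 7, decay: float = 0.78) -> np.ndarray:
    """Square root of the within-group shape covariance (fixed, anisotropic).

    Real wing-shape variation concentrates in a few directions rather than
    being isotropic over landmarks; a fixed orthonormal basis with
    geometrically decaying standard deviations emulates that, giving the
    relative-warp spectrum a realistic gradual decay.
    """
    d = 2 * n_landmarks
    gen = np.random.default_rng(20120531)  # fixed basis, not per-dataset
    basis, _ = np.linalg.qr(gen.normal(size=(d, d)))
    sds = decay ** (np.arange(d) / 2.0)
    sds /= np.sqrt(np.mean(sds**2))  # unit mean variance
    return basis * sds


def simulate_landmarks(
    partition: Partition, cfg: SimConfig, rng: np.random.Generator | None = None,
    n_replicates: int = 2,
):
    """Simulate digitized wing landmarks for every specimen.

    Per group: a distinct mean configuration (base wing + fixed offset of
    magnitude ``group_shape_sep``). Per specimen: mean + anisotropic
    Gaussian shape noise (overall scale ``landmark_noise_sd``, fixed
    decaying covariance spectrum), then one random rotation / translation /
    scale shared by that specimen's replicates (replicates share the
    digitization frame); each replicate adds small digitization noise
    (sd = 10% of ``landmark_noise_sd``).
    """
    from .morpho import LandmarkSet

    if rng is None:
        rng = cfg.rng(stream=3)
    groups = sorted(set(partition.assignment.values()))
    if not groups:
        raise ValueError("partition has no groups")
    offsets = _group_offsets(len(groups), cfg.group_shape_sep)
    cov_root = _biological_covariance_root(_BASE_WING.shape[0])
    coords, ids, reps = [], [], []
    for spec in sorted(partition.assignment):
        g = groups.index(partition.assignment[spec])
        noise = (cov_root @ rng.normal(0.0, cfg.landmark_noise_sd, 2 * _BASE_WING.shape[0]))
        true_shape = _BASE_WING + offsets[g] + noise.reshape(-1, 2)
        angle = rng.uniform(0.0, 2.0 * math.pi)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        scale = math.exp(rng.uniform(math.log(0.5), math.log(2.0)))
        shift = rng.uniform(-1.0, 1.0, 2)
        for r in range(n_replicates):
            digitized = true_shape + rng.normal(0.0, 0.1 * cfg.landmark_noise_sd, (7, 2))
            coords.append(scale * digitized @ rot.T + shift)
            ids.append(spec)
            reps.append(r)
    return LandmarkSet(
        np.stack(coords), ids, reps,
        groups={s: g for s, g in partition.assignment.items()},
    )


@dataclass
class MatingMatrix:
    """Reciprocal mating-cross outcomes (rows: female population, cols: male).

    ``observed[i, j]`` is True when courtship/mating was seen in at least
    one of ``replicates[i, j]`` pairings. Reciprocal crosses occupy the two
    symmetric cells; compatibility analyses treat an observation in either
    direction as evidence the pair can mate.
    """

    groups: list[str]
    observed: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.groups)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.replicates = np.asarray(self.replicates, dtype=int)
        if self.observed.shape != (k, k) or self.replicates.shape != (k, k):
            raise ValueError("mating matrix must be square over the groups")

    def to_dataframe(self) -> pd.DataFrame:
        sym = [["+" if v else "-" for v in row] for row in self.observed]
        return pd.DataFrame(sym, index=self.groups, columns=self.groups)


def simulate_mating(
    partition: Partition, cfg: SimConfig, rng: np.random.Generator | None = None
) -> MatingMatrix:
    """Identity-pattern mating matrix with per-cell error flips.

    True compatibility holds within a population (diagonal) and fails
    between populations; every cell is flipped independently with
    probability ``mating_error``.
    """
    if rng is None:
        rng = cfg.rng(stream=4)
    groups = sorted(set(partition.assignment.values()))
    k = len(groups)
    truth = np.eye(k, dtype=bool)
    flips = rng.random((k, k)) < cfg.mating_error
    observed = truth ^ flips
    reps = np.full((k, k), cfg.mating_replicates, dtype=int)
    return MatingMatrix(groups, observed, reps)


def specimen_metadata(partition: Partition, rng: np.random.Generator) -> pd.DataFrame:
    """Decorative host/locality metadata mirroring field-collection tables."""
    groups = sorted(set(partition.assignment.values()))
    rows = []
    for spec in sorted(partition.assignment):
        gi = groups.index(partition.assignment[spec])
        host, sites = _HOST_VOCAB[gi % len(_HOST_VOCAB)]
        loc, plant = sites[int(rng.integers(len(sites)))]
        rows.append(
            asdict(SpecimenRecord(spec, partition.assignment[spec], host, loc, plant))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference library and constructed diagnostic alignments
# ---------------------------------------------------------------------------

_REF_GENERA = [
    "Encyrtus", "Copidosoma", "Aphycus", "Metaphycus", "Anagyrus",
    "Ooencyrtus", "Cheiloneurus", "Comperiella",
]
_REF_EPITHETS = [
    "sasakii", "aurantii", "albicoxa", "floridanus", "pseudococci",
    "kuvanae", "elegans", "bifasciata", "lecaniorum", "infelix",
]


def simulate_reference_library(
    n_genera: int = 6,
    n_species_per_genus: int = 4,
    n_per_species: int = 4,
    seq_length: int = 631,
    kappa: float = 2.0,
    congeneric_rate: float = 0.083,
    intraspecific_divergence: float = 0.0075,
    n_nonbinomial: int = 2,
    seed: int = 0,
) -> LabeledAlignment:
    """Labeled reference barcode library with binomial species names.

    Each genus is an independent species complex simulated like the focal
    one. ``congeneric_rate`` (substitutions/site per unit of genus tree
    depth) and ``intraspecific_divergence`` (expected within-species
    pairwise distance) default to values that put the intraspecific
    distance distribution near 0.5% and the congeneric distribution above
    10% — the barcode gap the benchmark relies on. ``n_nonbinomial``
    sequences are labeled 'Genus sp.' to exercise the exclusion rule.
    """
    ids, labels, seqs = [], [], []
    for gi in range(n_genera):
        cfg = SimConfig(
            n_species=min(n_species_per_genus, 4),
            n_per_species=n_per_species,
            coal_theta=intraspecific_divergence / (2.0 * congeneric_rate),
            seq_length=seq_length,
            kappa=kappa,
            subs_rate=congeneric_rate,
            n_fixed_diag=0,
            seed=seed + 1000 + gi,
        )
        tree, part = simulate_species_tree(cfg)
        aln = evolve_sequences(tree, cfg, partition=part)
        genus = _REF_GENERA[gi % len(_REF_GENERA)]
        sp_codes = sorted(set(part.assignment.values()))
        for sid, lab, seq in zip(aln.ids, aln.labels, aln.seqs):
            epithet = _REF_EPITHETS[(gi + sp_codes.index(lab)) % len(_REF_EPITHETS)]
            ids.append(f"G{gi}_{sid}")
            labels.append(f"{genus} {epithet}")
            seqs.append(seq)
    for j in range(n_nonbinomial):
        ids.append(f"SP_{j}")
        labels.append(f"{_REF_GENERA[j % len(_REF_GENERA)]} sp.")
        seqs.append(seqs[j])
    return LabeledAlignment(ids, labels, seqs)


def make_diagnostic_alignment(
    n_pure: int = 73,
    n_private: int = 49,
    n_groups: int = 3,
    n_per_group: int = 10,
    length: int = 631,
    seed: int = 0,
) -> LabeledAlignment:
    """Constructed alignment with exact pure/private diagnostic counts.

    Background sites are monomorphic (never diagnostic). Each pure site
    fixes state A in group 1 and G elsewhere (one pure character, one pure
    site); each private site gives A to a strict subset of group 1 and G to
    everyone else (one private character, one private site). Diagnostics on
    this alignment therefore report exactly ``n_pure`` pure and
    ``n_private`` private characters/sites for group 1.
    """
    if n_pure + n_private > length:
        raise ValueError("too many diagnostic sites for the alignment length")
    if n_groups < 2 or n_per_group < 2:
        raise ValueError("need >= 2 groups of >= 2 members")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    groups = species_codes(n_groups)
    n = n_groups * n_per_group
    arr = np.full((n, length), 3, dtype=np.int8)  # background: all T
    pos = rng.choice(length, size=n_pure + n_private, replace=False)
    pure_pos, private_pos = pos[:n_pure], pos[n_pure:]
    g1 = slice(0, n_per_group)
    arr[:, pure_pos] = 1  # G everywhere
    arr[g1, pure_pos] = 0  # A fixed in group 1
    arr[:, private_pos] = 1
    carriers = max(1, n_per_group // 2)
    arr[0:carriers, private_pos] = 0  # A in part of group 1 only
    ids = [f"{groups[g]}{i + 1:02d}" for g in range(n_groups) for i in range(n_per_group)]
    labels = [groups[g] for g in range(n_groups) for _ in range(n_per_group)]
    seqs = ["".join(_BASES[c] for c in row) for row in arr]
    return LabeledAlignment(ids, labels, seqs)


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, from a single seed."""

    config: SimConfig
    tree: dendropy.Tree
    partition: Partition
    alignment: LabeledAlignment
    metadata: pd.DataFrame
    landmarks: "object"
    mating: MatingMatrix

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA / newick / TSV / TPS files; returns the path map."""
        from pathlib import Path
        from .morpho import write_tps

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": str(out / "alignment.fasta"),
            "tree": str(out / "true_tree.nwk"),
            "metadata": str(out / "metadata.tsv"),
            "landmarks": str(out / "wings.tps"),
            "mating": str(out / "mating.tsv"),
        }
        self.alignment.to_fasta(paths["alignment"])
        self.tree.write(path=paths["tree"], schema="newick")
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        write_tps(self.landmarks, paths["landmarks"])
        self.mating.to_dataframe().to_csv(paths["mating"], sep="\t")
        return paths


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic study from one configuration + seed."""
    tree, part = simulate_species_tree(cfg)
    aln = evolve_sequences(tree, cfg, partition=part)
    landmarks = simulate_landmarks(part, cfg)
    mating = simulate_mating(part, cfg)
    meta = specimen_metadata(part, cfg.rng(stream=5))
    return SyntheticDataset(cfg, tree, part, aln, meta, landmarks, mating)
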