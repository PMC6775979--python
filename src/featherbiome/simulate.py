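"""Synthetic feather-microbiota studies with known ground truth.

Emulates the statistical structure of a multi-species, multi-locality
16S amplicon survey: 7 host species sampled at up to 9 localities (72
samples total), a pool of bacterial OTUs with a phylogeny and evolved
representative sequences, species-specific compositions with tunable
phylosymbiosis (Brownian-motion species effects on the host tree),
smooth spatial community variation (squared-exponential Gaussian process
over localities), trait-labelled reference sequences with controlled
identity, and a hierarchical response dataset for the mixed model.  All
generating parameters are recorded so every downstream estimate can be
checked against truth.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import OtuTable, SampleMetadata, SeqSet, TreeSet
from .funcmap import BPB_CLASSES, TraitReference
from .phylomm import phylo_cov
from .spatial import EARTH_RADIUS_KM

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_host_trees",
    "simulate_bacterial_pool",
    "simulate_community",
    "simulate_trait_reference",
    "simulate_mm_dataset",
    "simulate_study",
    "SPECIES_CODES",
    "DEFAULT_DESIGN",
]

SPECIES_CODES = ("AA", "LL", "FA", "RR", "SE", "PA", "PP")

# Which localities each species is sampled at.  Mirrors the study design:
# three species (AA, LL, FA) come from single sites (two of them the same
# site), one (RR) is sampled at several sites where no other species
# occurs, and the rest share localities -- so species and geography are
# partially confounded and the db-RDA disentangling is exercised.
DEFAULT_DESIGN: dict[str, tuple[int, ...]] = {
    "AA": (0,),
    "LL": (0,),
    "FA": (1,),
    "RR": (2, 3, 4),
    "SE": (5, 6, 7),
    "PA": (5, 6, 8),
    "PP": (6, 7, 8),
}


@dataclass
class SimConfig:
    n_species: int = 7
    samples_per_species: tuple[int, ...] | None = None  # default sums to 72
    n_localities: int = 9
    n_otus: int = 500
    depth_min: int = 2299
    depth_extra_mean: float = 500.0  # Poisson overdispersion above depth_min
    phylosymbiosis_strength: float = 1.0  # sd of BM species effects (log scale)
    spatial_strength: float = 0.5  # sd of GP locality effects (log scale)
    spatial_range: float = 100.0  # km, squared-exponential length scale
    noise_sd: float = 0.5  # per-sample per-OTU log-intensity noise
    base_abundance_sd: float = 1.5  # spread of baseline OTU log abundances
    seq_length: int = 250
    jc_rate: float = 0.05  # substitutions per site per unit branch length
    min_otu_divergence: float = 0.06  # enforced minimum pairwise p-distance
    frac_bpb: float = 0.245
    frac_fdb: float = 0.122
    frac_overlap: float = 0.92  # fraction of FDB that is also BPB
    ref_mutations: int = 0  # substitutions applied to each reference copy
    n_decoys: int = 10
    host_tree_jitter: float = 0.1  # lognormal sd for posterior emulation
    n_host_trees: int = 100
    min_terminal_frac: float = 0.05  # floor on terminal branches (fraction of height)
    # mixed-model generating parameters
    beta_between: float = -4.5
    beta_within: float = 1.0
    slope_sd: float = 0.0  # sd of species-specific within-slope deviations
    mm_intercept: float = 3.0
    mm_sigma_species: float = 0.5
    mm_sigma_phylo: float = 0.3
    mm_sigma_resid: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least 3 host species")
        for name in ("frac_bpb", "frac_fdb", "frac_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")
        if self.samples_per_species is None:
            base, extra = divmod(72, self.n_species)
            self.samples_per_species = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_species)
            )
        if len(self.samples_per_species) != self.n_species:
            raise ValueError("samples_per_species length must equal n_species")

    @property
    def species_codes(self) -> tuple[str, ...]:
        if self.n_species <= len(SPECIES_CODES):
            return SPECIES_CODES[: self.n_species]
        return tuple(f"SP{i:02d}" for i in range(self.n_species))


@dataclass
class SimTruth:
    species_effect: pd.DataFrame  # species x OTU log offsets
    locality_effect: pd.DataFrame  # locality x OTU log offsets
    base_log_abundance: pd.Series
    locality_coords: pd.DataFrame  # locality -> lat, lon
    trait_assignment: pd.DataFrame | None = None  # OTU -> bpb_class, is_fdb
    mm_params: dict = field(default_factory=dict)


def _yule_tree(n_tips: int, labels: list[str], seed: int) -> dendropy.Tree:
    pr = _pyrandom.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=pr,
    )
    # the simulator stops exactly at the n-th speciation, leaving one
    # zero-length cherry; run the clock on to the next (unrealised) event
    extra = pr.expovariate(n_tips * 1.0)
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = label
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # drop the arbitrary stem edge above the first split: a branch leading
    # to every taxon carries no grouping information and distorts UniFrac
    # denominators in tools that count it
    tree.seed_node.edge.length = None
    return tree


def _rescale_unit_height(tree: dendropy.Tree) -> dendropy.Tree:
    tree.calc_node_root_distances()
    height = max(lf.root_distance for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def simulate_host_trees(cfg: SimConfig) -> tuple[dendropy.Tree, list[dendropy.Tree]]:
    """One Yule base tree (unit height) plus jittered posterior copies.

    Each copy multiplies every branch by independent lognormal(0, jitter)
    noise and is rescaled to unit height; topology is preserved.
    """
    ss = np.random.SeedSequence([cfg.seed, 11])
    rng = np.random.default_rng(ss)
    # reject trees with near-zero terminal branches: tips are distinct
    # species, and such trees make the phylogenetic correlation singular
    for _ in range(500):
        base = _yule_tree(cfg.n_species, list(cfg.species_codes),
                          int(rng.integers(2 ** 31)))
        _rescale_unit_height(base)
        shortest = min(lf.edge.length for lf in base.leaf_node_iter())
        if shortest >= cfg.min_terminal_frac:
            break
    copies = []
    for _ in range(cfg.n_host_trees):
        t = base.clone(depth=1)
        if cfg.host_tree_jitter > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= float(
                        rng.lognormal(0.0, cfg.host_tree_jitter)
                    )
        _rescale_unit_height(t)
        copies.append(t)
    return base, copies


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _evolve_sequences(tree: dendropy.Tree, seq_length: int, rate: float,
                      rng: np.random.Generator) -> SeqSet:
    """Jukes-Cantor evolution of a random root sequence along the tree."""
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[str, str] = {}
    tree.seed_node._fb_seq = root_seq
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = node.parent_node._fb_seq
        ln = node.edge.length or 0.0
        p_sub = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * ln))
        seq = parent_seq.copy()
        hit = rng.random(seq_length) < p_sub
        if hit.any():
            # substitute to one of the three other bases uniformly
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        node._fb_seq = seq
        if node.is_leaf():
            seqs[node.taxon.label] = "".join("ACGT"[b] for b in seq)
    return SeqSet(seqs)


def _enforce_divergence(seqs: SeqSet, min_frac: float,
                        rng: np.random.Generator) -> SeqSet:
    """Push every OTU pair to at least ``min_frac`` p-distance.

    OTUs are 97%-identity clusters by definition, so two distinct OTUs
    cannot be near-identical; tips that end up too close after tree-based
    evolution receive extra substitutions at currently-identical sites.
    """
    ids = list(seqs)
    mat = np.array([[ "ACGT".index(c) for c in seqs[i] ] for i in ids], dtype=np.int8)
    n, L = mat.shape
    min_diffs = int(np.ceil(min_frac * L))
    for _ in range(50):
        diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        np.fill_diagonal(diff, L)
        close = np.argwhere(np.triu(diff < min_diffs))
        if len(close) == 0:
            break
        for i, j in close:
            need = min_diffs - int(diff[i, j])
            if need <= 0:
                continue
            same = np.where(mat[i] == mat[j])[0]
            pos = rng.choice(same, size=min(need, len(same)), replace=False)
            mat[j, pos] = (mat[j, pos] + rng.integers(1, 4, size=len(pos))) % 4
    return SeqSet({
        sid: "".join("ACGT"[b] for b in row) for sid, row in zip(ids, mat)
    })


def simulate_bacterial_pool(cfg: SimConfig) -> tuple[dendropy.Tree, SeqSet]:
    """Yule OTU tree with sequences whose divergence tracks patristic distance."""
    ss = np.random.SeedSequence([cfg.seed, 22])
    rng = np.random.default_rng(ss)
    labels = [f"OTU{i + 1:04d}" for i in range(cfg.n_otus)]
    tree = _yule_tree(cfg.n_otus, labels, int(rng.integers(2 ** 31)))
    seqs = _evolve_sequences(tree, cfg.seq_length, cfg.jc_rate, rng)
    if cfg.min_otu_divergence > 0:
        seqs = _enforce_divergence(seqs, cfg.min_otu_divergence, rng)
    return tree, seqs


def _sq_exp_kernel(d_km: np.ndarray, sd: float, length: float) -> np.ndarray:
    return sd ** 2 * np.exp(-(d_km ** 2) / (2 * length ** 2))


def _haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    la, lo = np.radians(lat), np.radians(lon)
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    a = np.sin(dla / 2) ** 2 + np.cos(la[:, None]) * np.cos(la[None, :]) * (
        np.sin(dlo / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def simulate_community(
    cfg: SimConfig,
    base_host_tree: dendropy.Tree,
    design: dict[str, tuple[int, ...]] | None = None,
) -> tuple[OtuTable, SampleMetadata, SimTruth]:
    """Counts with species (phylosymbiotic), spatial and residual structure.

    Per-OTU species effects are Brownian motion on the host tree (sd =
    phylosymbiosis_strength); locality effects are a squared-exponential
    Gaussian process over great-circle locality distances; sample
    log-intensities add independent noise and map to multinomial
    probabilities through a softmax.
    """
    ss = np.random.SeedSequence([cfg.seed, 33])
    rng = np.random.default_rng(ss)
    species = list(cfg.species_codes)
    s = len(species)
    if design is None:
        design = (
            DEFAULT_DESIGN
            if (s == 7 and cfg.n_localities >= 9)
            else {sp: (i % cfg.n_localities,) for i, sp in enumerate(species)}
        )

    # locality coordinates in a Central-European bounding box
    lat = rng.uniform(48.5, 50.5, size=cfg.n_localities)
    lon = rng.uniform(14.0, 18.0, size=cfg.n_localities)
    loc_names = [f"L{i + 1}" for i in range(cfg.n_localities)]

    # BM species effects: cov = sigma^2 * (shared root-path length)
    A = phylo_cov(base_host_tree, species).to_numpy()
    La = np.linalg.cholesky(A + 1e-10 * np.eye(s))
    species_eff = cfg.phylosymbiosis_strength * (
        La @ rng.standard_normal((s, cfg.n_otus))
    )

    d_loc = _haversine_km(lat, lon)
    K = _sq_exp_kernel(d_loc, max(cfg.spatial_strength, 1e-12), cfg.spatial_range)
    Lk = np.linalg.cholesky(K + 1e-10 * np.eye(cfg.n_localities))
    loc_eff = Lk @ rng.standard_normal((cfg.n_localities, cfg.n_otus))

    base = rng.normal(0.0, cfg.base_abundance_sd, size=cfg.n_otus)

    otu_ids = [f"OTU{i + 1:04d}" for i in range(cfg.n_otus)]
    rows, meta_rows, sample_ids = [], [], []
    k = 0
    for sp, n_samp in zip(species, cfg.samples_per_species):
        locs = design[sp]
        for j in range(n_samp):
            loc = locs[j % len(locs)]
            k += 1
            sid = f"S{k:03d}"
            eta = (
                base
                + species_eff[species.index(sp)]
                + loc_eff[loc]
                + rng.normal(0.0, cfg.noise_sd, size=cfg.n_otus)
            )
            p = np.exp(eta - eta.max())
            p /= p.sum()
            depth = cfg.depth_min + rng.poisson(cfg.depth_extra_mean)
            rows.append(rng.multinomial(depth, p))
            sample_ids.append(sid)
            meta_rows.append(
                {"species": sp, "locality": loc_names[loc],
                 "lat": lat[loc], "lon": lon[loc]}
            )
    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=otu_ids)
    # drop OTUs never observed so that every table column is a real taxon
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    tab = OtuTable(counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))
    truth = SimTruth(
        species_effect=pd.DataFrame(species_eff, index=species, columns=otu_ids),
        locality_effect=pd.DataFrame(loc_eff, index=loc_names, columns=otu_ids),
        base_log_abundance=pd.Series(base, index=otu_ids),
        locality_coords=pd.DataFrame({"lat": lat, "lon": lon}, index=loc_names),
    )
    return tab, meta, truth


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    if n_mut == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    lookup = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    for pth in pos:
        arr[pth] = rng.choice(lookup[arr[pth]])
    return arr.tobytes().decode()


def simulate_trait_reference(
    cfg: SimConfig, pool: SeqSet
) -> tuple[TraitReference, pd.DataFrame]:
    """Trait-labelled references copied from designated OTU sequences.

    frac_bpb of OTUs are BPB (split across classes I-III), frac_fdb are
    FDB with frac_overlap of them also BPB.  References are copies of the
    designated sequences with ``ref_mutations`` substitutions (default 0,
    identity 1.0) plus random decoy sequences far from every OTU.
    Returns the reference plus the per-OTU truth table.
    """
    if cfg.frac_overlap * cfg.frac_fdb > cfg.frac_bpb + 1e-12:
        raise ValueError("inconsistent fractions: frac_overlap*frac_fdb > frac_bpb")
    ss = np.random.SeedSequence([cfg.seed, 44])
    rng = np.random.default_rng(ss)
    otu_ids = list(pool)
    n = len(otu_ids)
    n_bpb = int(round(cfg.frac_bpb * n))
    n_fdb = int(round(cfg.frac_fdb * n))
    n_shared = int(round(cfg.frac_overlap * n_fdb))

    order = rng.permutation(n)
    fdb_idx = order[:n_fdb]
    shared_idx = fdb_idx[:n_shared]
    extra_bpb = order[n_fdb: n_fdb + (n_bpb - n_shared)]
    bpb_idx = np.concatenate([shared_idx, extra_bpb])

    classes = np.array(BPB_CLASSES)[rng.integers(0, 3, size=len(bpb_idx))]

    seqs: dict[str, str] = {}
    categories: dict[str, list[str]] = {}
    truth = pd.DataFrame(
        {"bpb_class": [""] * n, "is_fdb": [False] * n}, index=otu_ids
    )
    for idx, cls in zip(bpb_idx, classes):
        oid = otu_ids[idx]
        rid = f"REF_{cls.replace('-', '')}_{oid}"
        seqs[rid] = _mutate(pool[oid], cfg.ref_mutations, rng)
        categories[rid] = [cls]
        truth.loc[oid, "bpb_class"] = cls
    for idx in fdb_idx:
        oid = otu_ids[idx]
        rid = f"REF_FDB_{oid}"
        seqs[rid] = _mutate(pool[oid], cfg.ref_mutations, rng)
        categories[rid] = ["FDB"]
        truth.loc[oid, "is_fdb"] = True
    seq_len = len(next(iter(pool.items()))[1])
    for i in range(cfg.n_decoys):
        rid = f"REF_DECOY_{i + 1:03d}"
        seqs[rid] = "".join("ACGT"[b] for b in rng.integers(0, 4, size=seq_len))
        categories[rid] = [list(BPB_CLASSES)[i % 3], "FDB"][i % 2: i % 2 + 1]
    return TraitReference(SeqSet(seqs), categories), truth


def simulate_mm_dataset(
    cfg: SimConfig,
    meta: SampleMetadata,
    base_host_tree: dendropy.Tree,
) -> tuple[pd.DataFrame, dict]:
    """Hierarchical (sample, species, y, x) data for mixed-model recovery.

    y = a + b_B * mean_s(x) + b_W * (x - mean_s(x)) + u_s + phylo_s + e,
    optionally with species-specific within-slopes (sd = slope_sd).
    """
    ss = np.random.SeedSequence([cfg.seed, 55])
    rng = np.random.default_rng(ss)
    species = list(cfg.species_codes)
    sp_per_sample = meta.species
    s = len(species)

    x_species_mean = rng.normal(0.0, 1.0, size=s)
    x = np.array(
        [x_species_mean[species.index(sp)] for sp in sp_per_sample]
    ) + rng.normal(0.0, 1.0, size=len(sp_per_sample))
    xb = pd.Series(x).groupby(sp_per_sample.to_numpy()).transform("mean").to_numpy()
    xw = x - xb

    u = rng.normal(0.0, cfg.mm_sigma_species, size=s)
    A = phylo_cov(base_host_tree, species).to_numpy()
    a = cfg.mm_sigma_phylo * (
        np.linalg.cholesky(A + 1e-10 * np.eye(s)) @ rng.standard_normal(s)
    )
    slopes = cfg.beta_within + rng.normal(0.0, cfg.slope_sd, size=s)
    codes = np.array([species.index(sp) for sp in sp_per_sample])
    y = (
        cfg.mm_intercept
        + cfg.beta_between * xb
        + slopes[codes] * xw
        + u[codes]
        + a[codes]
        + rng.normal(0.0, cfg.mm_sigma_resid, size=len(x))
    )
    df = pd.DataFrame(
        {"species": sp_per_sample.to_numpy(), "x": x, "y": y},
        index=meta.sample_ids,
    )
    params = {
        "beta_between": cfg.beta_between,
        "beta_within": cfg.beta_within,
        "species_slopes": dict(zip(species, slopes)),
        "u": dict(zip(species, u)),
        "phylo": dict(zip(species, a)),
        "sigma_species": cfg.mm_sigma_species,
        "sigma_phylo": cfg.mm_sigma_phylo,
        "sigma_resid": cfg.mm_sigma_resid,
        "intercept": cfg.mm_intercept,
    }
    return df, params


def simulate_study(cfg: SimConfig) -> dict:
    """Generate a complete synthetic study (all components, shared seed)."""
    base, host_trees = simulate_host_trees(cfg)
    bact_tree, seqs = simulate_bacterial_pool(cfg)
    tab, meta, truth = simulate_community(cfg, base)
    ref, trait_truth = simulate_trait_reference(cfg, seqs)
    mm_df, mm_params = simulate_mm_dataset(cfg, meta, base)
    truth.trait_assignment = trait_truth
    truth.mm_params = mm_params
    return {
        "config": cfg,
        "base_host_tree": base,
        "trees": TreeSet(bacterial_tree=bact_tree, host_trees=host_trees),
        "otu_seqs": seqs,
        "otu_table": tab,
        "metadata": meta,
        "trait_reference": ref,
        "mm_data": mm_df,
        "truth": truth,
    }
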