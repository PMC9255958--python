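"""Synthetic cohort generator.

Emulates the statistical structure of a deep-amplicon gonadal
mosaicism study: sperm donors carrying mosaic variants at long-tailed
allelic fractions, control SNPs with known genotypes, unrelated control
samples, and whole-genome-amplified blastocysts with allelic imbalance
and dropout.

Mosaic variants live on a germline lineage tree: a complete binary
tree whose leaves represent sperm-progenitor clades with a random
(Dirichlet) share of the sperm pool. A variant assigned to a node is
carried by every sperm below that node, so its true sperm AF is half
the subtree's leaf-weight sum (meiosis passes the mutant chromosome to
half the sperm). Variants sharing a root path co-transmit more often
than independence predicts; a flag switches transmission to fully
independent Bernoulli(AF) so both regimes can be studied.

Defaults mirror the study conditions: three donors with 12/13/30
gonadal variants, AFs log-uniform on [0.003, 0.25], 120 control SNPs,
10/8/14 blastocysts (two of the second donor's of poor WGA quality),
ultra-deep tissue coverage and ~100x blastocyst coverage, 6% allelic
dropout in amplified material.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import SampleManifest, variant_id

__all__ = ["SimulationConfig", "LineageTree", "SyntheticCohort",
           "simulate_cohort", "draw_blastocyst", "wga_observe"]

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_donors: int = 3
    n_mosaic_per_donor: int | Sequence[int] = (12, 13, 30)
    n_soma_only_per_donor: int | Sequence[int] = (15, 3, 3)
    af_law: str | Callable = "log_uniform"   # or "point"
    af_min: float = 0.003
    af_max: float = 0.25
    af_point: float = 0.1
    n_snps: int = 120
    snp_common_fraction: float = 0.5
    snp_common_alt_freq: float = 0.3
    n_blastocysts_per_donor: int | Sequence[int] = (10, 8, 14)
    n_low_quality_blastocysts: int | Sequence[int] = (0, 2, 0)
    low_quality_depth_factor: float = 0.02
    depth_mean_tissue: float = 5000.0
    depth_mean_blastocyst: float = 100.0
    depth_dispersion: float = 5.0
    seq_error_rate: float = 0.0005
    wga_dropout_prob: float = 0.06
    wga_imbalance_concentration: float = 5.0
    lineage_depth: int = 8
    lineage_cosegregation: bool = True
    soma_split_depth: int = 2
    n_controls: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in ("seq_error_rate", "wga_dropout_prob", "snp_common_fraction",
                  "snp_common_alt_freq", "low_quality_depth_factor"):
            v = getattr(self, p)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        if self.wga_imbalance_concentration <= 0:
            raise ValueError("wga_imbalance_concentration must be positive")
        if self.lineage_depth < 1:
            raise ValueError("lineage_depth must be >= 1")
        if not (0 < self.af_min <= self.af_max < 1):
            raise ValueError("require 0 < af_min <= af_max < 1")

    def per_donor(self, name: str) -> list[int]:
        v = getattr(self, name)
        if isinstance(v, (int, np.integer)):
            return [int(v)] * self.n_donors
        v = list(v)
        if len(v) < self.n_donors:
            raise ValueError(f"{name}: need {self.n_donors} values, got {len(v)}")
        return [int(x) for x in v[: self.n_donors]]

    def to_dict(self) -> dict:
        d = asdict(self)
        if callable(d.get("af_law")):
            d["af_law"] = getattr(self.af_law, "__name__", "callable")
        return d


class LineageTree:
    """Complete binary tree over sperm-progenitor clades (heap indexing).

    Node 1 is the root; node k has children 2k and 2k+1; leaves are
    nodes 2**depth .. 2**(depth+1)-1. ``leaf_weights`` give each leaf
    clade's share of the sperm pool and sum to 1.
    """

    def __init__(self, depth: int, leaf_weights: np.ndarray):
        leaf_weights = np.asarray(leaf_weights, dtype=float)
        if len(leaf_weights) != 2 ** depth:
            raise ValueError("need one weight per leaf")
        if not np.isclose(leaf_weights.sum(), 1.0):
            raise ValueError("leaf weights must sum to 1")
        self.depth = depth
        self.leaf_weights = leaf_weights / leaf_weights.sum()
        self.n_nodes = 2 ** (depth + 1) - 1
        # subtree leaf-weight sums, computed bottom-up
        w = np.zeros(self.n_nodes + 1)
        w[2 ** depth:] = self.leaf_weights
        for k in range(2 ** depth - 1, 0, -1):
            w[k] = w[2 * k] + w[2 * k + 1]
        self.node_weights = w  # index 0 unused

    @classmethod
    def random(cls, depth: int, rng: np.random.Generator) -> "LineageTree":
        weights = rng.dirichlet(np.ones(2 ** depth))
        return cls(depth, weights)

    def node_depth(self, node: int) -> int:
        return int(np.floor(np.log2(node)))

    def subtree_weight(self, node: int) -> float:
        return float(self.node_weights[node])

    def root_path(self, leaf: int) -> set[int]:
        path = set()
        k = leaf
        while k >= 1:
            path.add(k)
            k //= 2
        return path

    def sample_leaf(self, rng: np.random.Generator) -> int:
        idx = rng.choice(len(self.leaf_weights), p=self.leaf_weights)
        return 2 ** self.depth + int(idx)

    def true_af(self, node: int) -> float:
        """Sperm AF implied by a node: half its clade's pool share."""
        return self.subtree_weight(node) / 2.0

    def assign_node(self, target_af: float, rng: np.random.Generator,
                    kernel_width: float = 0.3) -> int:
        """Pick a node whose implied AF is close to ``target_af``.

        Nodes are sampled with a Gaussian kernel on log-AF distance, so
        variants of similar target AF tend to land on the same or
        nearby nodes — the source of co-segregation.
        """
        nodes = np.arange(2, self.n_nodes + 1)  # exclude root (AF 0.5)
        w = self.node_weights[nodes]
        valid = w > 0
        nodes, w = nodes[valid], w[valid]
        log_d = np.log(w / 2.0) - np.log(target_af)
        p = np.exp(-0.5 * (log_d / kernel_width) ** 2)
        if p.sum() == 0:
            return int(nodes[np.argmin(np.abs(log_d))])
        return int(rng.choice(nodes, p=p / p.sum()))


def draw_blastocyst(tree: LineageTree, variant_nodes: dict,
                    rng: np.random.Generator) -> set:
    """Simulate one fertilisation: which mosaic variants does the embryo get?

    One sperm-progenitor leaf is drawn by pool share; every variant on
    that leaf's root path is then transmitted independently with
    probability 1/2 (meiotic segregation of the mutant chromosome), so
    the marginal transmission probability equals the variant's true AF.
    Variants off the path are never transmitted.
    """
    leaf = tree.sample_leaf(rng)
    path = tree.root_path(leaf)
    return {
        vid for vid, node in variant_nodes.items()
        if node in path and rng.random() < 0.5
    }


def wga_observe(true_status: bool, depth: int, rng: np.random.Generator,
                dropout_prob: float = 0.06, concentration: float = 5.0,
                error_rate: float = 0.0005) -> tuple[int, int]:
    """Read counts at one site in whole-genome-amplified material.

    A heterozygous carrier drops the mutant allele with probability
    ``dropout_prob`` (alt reads then arise only from sequencing error);
    otherwise the allele balance is drawn from a symmetric
    Beta(concentration, concentration) — modelling the amplification
    imbalance WGA is known for — and alt reads are binomial at that
    balance. Non-carriers yield alt reads at the error rate.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not true_status or rng.random() < dropout_prob:
        alt = rng.binomial(depth, error_rate)
    else:
        balance = rng.beta(concentration, concentration)
        alt = rng.binomial(depth, balance)
    return depth - int(alt), int(alt)


@dataclass
class SyntheticCohort:
    """Everything the generator produced, plus ground truth."""

    config: SimulationConfig
    manifest: SampleManifest
    panel: pd.DataFrame
    observations: pd.DataFrame
    truth_variants: pd.DataFrame
    truth_transmission: pd.DataFrame
    trees: dict = field(default_factory=dict)  # donor_id -> LineageTree


def _sample_afs(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(config.af_law):
        return np.asarray(config.af_law(rng, n), dtype=float)
    if config.af_law == "log_uniform":
        lo, hi = np.log(config.af_min), np.log(config.af_max)
        return np.exp(rng.uniform(lo, hi, size=n))
    if config.af_law == "point":
        return np.full(n, config.af_point)
    raise ValueError(f"unknown af_law {config.af_law!r}")


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative-binomial coverage (overdispersed, as amplicon depth is)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort: manifest, panel, read counts, and truth.

    ``seed`` overrides ``config.seed``. Read counts are drawn as:
    tissue carriers binomial(depth, true AF), non-carriers
    binomial(depth, error rate), blastocysts through the WGA model.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    root_ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root_ss)
    donor_rngs = [np.random.default_rng(s) for s in root_ss.spawn(config.n_donors)]

    donors = [f"F{i + 1:02d}" for i in range(config.n_donors)]
    controls = [f"C{i + 1:02d}" for i in range(config.n_controls)]

    # ---- manifest
    man_rows = []
    for i, d in enumerate(donors):
        soma = "blood" if i == 0 else "saliva"
        man_rows.append({"sample_id": f"{d}_sperm", "donor_id": d,
                         "role": "sperm_donor", "tissue": "sperm"})
        man_rows.append({"sample_id": f"{d}_{soma}", "donor_id": d,
                         "role": "sperm_donor", "tissue": soma})
    for c in controls:
        man_rows.append({"sample_id": f"{c}_blood", "donor_id": c,
                         "role": "unrelated_control", "tissue": "blood"})
    n_blast = config.per_donor("n_blastocysts_per_donor")
    n_lowq = config.per_donor("n_low_quality_blastocysts")
    for i, d in enumerate(donors):
        for b in range(n_blast[i]):
            man_rows.append({"sample_id": f"{d}_B{b + 1:02d}", "donor_id": d,
                             "role": "blastocyst", "tissue": "wga_blastocyst"})
    manifest = SampleManifest(df=pd.DataFrame(man_rows))

    all_donor_ids = donors + controls

    # ---- mosaic variants on lineage trees
    n_mosaic = config.per_donor("n_mosaic_per_donor")
    n_soma = config.per_donor("n_soma_only_per_donor")
    trees, panel_rows, truth_rows = {}, [], []
    variant_nodes = {d: {} for d in donors}
    used_pos = set()

    def _new_site(rng):
        while True:
            chrom = _AUTOSOMES[rng.integers(len(_AUTOSOMES))]
            pos = int(rng.integers(1, 200_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                return chrom, pos, str(ref), str(alt)

    for i, d in enumerate(donors):
        rng = donor_rngs[i]
        tree = LineageTree.random(config.lineage_depth, rng)
        trees[d] = tree
        afs = _sample_afs(config, rng, n_mosaic[i])
        for a in afs:
            chrom, pos, ref, alt = _new_site(rng)
            vid = variant_id(chrom, pos, ref, alt)
            if config.lineage_cosegregation:
                node = tree.assign_node(float(a), rng)
                sperm_af = tree.true_af(node)
            else:
                node, sperm_af = -1, float(a)
            node_d = tree.node_depth(node) if node > 0 else -1
            shared = node > 0 and node_d <= config.soma_split_depth
            soma_af = sperm_af if shared else 0.0
            panel_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                               "variant_class": "mosaic_candidate",
                               **{f"gt_{x}": "unknown" for x in all_donor_ids}})
            truth_rows.append({"variant_id": vid, "donor_id": d,
                               "category_true": "shared" if shared else "sperm_only",
                               "true_sperm_af": sperm_af, "true_soma_af": soma_af,
                               "lineage_node": node})
            if node > 0:
                variant_nodes[d][vid] = node
        # soma-only variants (e.g. clonal hematopoiesis); never transmitted
        for a in _sample_afs(config, rng, n_soma[i]):
            chrom, pos, ref, alt = _new_site(rng)
            vid = variant_id(chrom, pos, ref, alt)
            panel_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                               "variant_class": "mosaic_candidate",
                               **{f"gt_{x}": "unknown" for x in all_donor_ids}})
            truth_rows.append({"variant_id": vid, "donor_id": d,
                               "category_true": "soma_only",
                               "true_sperm_af": 0.0, "true_soma_af": float(a),
                               "lineage_node": -1})

    # ---- control SNPs: rare (het in one donor) + common (HWE genotypes)
    n_common = int(round(config.n_snps * config.snp_common_fraction))
    snp_truth = []  # (vid, {donor: gt})
    for s in range(config.n_snps):
        chrom, pos, ref, alt = _new_site(master)
        vid = variant_id(chrom, pos, ref, alt)
        gts = {}
        if s < config.n_snps - n_common:
            carrier = donors[s % len(donors)]
            gts = {x: ("het" if x == carrier else "ref_hom") for x in all_donor_ids}
        else:
            q = config.snp_common_alt_freq
            probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
            while True:
                gts = {x: ["ref_hom", "het", "alt_hom"][master.choice(3, p=probs)]
                       for x in all_donor_ids}
                if any(g != "ref_hom" for g in gts.values()):
                    break  # control SNPs must have >=1 known non-ref genotype
        panel_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                           "variant_class": "control_snp",
                           **{f"gt_{x}": gts[x] for x in all_donor_ids}})
        snp_truth.append((vid, gts))

    panel = pd.DataFrame(panel_rows)
    panel["variant_id"] = [variant_id(*t) for t in
                           zip(panel["chrom"], panel["pos"], panel["ref"], panel["alt"])]
    truth_variants = pd.DataFrame(
        truth_rows, columns=["variant_id", "donor_id", "category_true",
                             "true_sperm_af", "true_soma_af", "lineage_node"])

    # ---- per-blastocyst transmission truth
    trans_rows = []
    blast_transmitted = {}  # sample_id -> set of variant ids
    blast_snp_carrier = {}  # sample_id -> set of SNP variant ids (child carries alt)
    for i, d in enumerate(donors):
        rng = donor_rngs[i]
        dtruth = truth_variants[(truth_variants["donor_id"] == d)
                                & (truth_variants["category_true"] != "soma_only")]
        afs_by_vid = dict(zip(dtruth["variant_id"], dtruth["true_sperm_af"]))
        for b in manifest.blastocysts_of(d):
            if config.lineage_cosegregation:
                got = draw_blastocyst(trees[d], variant_nodes[d], rng)
            else:
                got = {vid for vid, a in afs_by_vid.items() if rng.random() < a}
            blast_transmitted[b] = got
            for vid in dtruth["variant_id"]:
                trans_rows.append({"variant_id": vid, "donor_id": d,
                                   "blastocyst_id": b,
                                   "transmitted": vid in got})
            # SNP inheritance from the father (mothers treated as ref-hom)
            carried = set()
            for vid, gts in snp_truth:
                g = gts[d]
                if g == "alt_hom" or (g == "het" and rng.random() < 0.5):
                    carried.add(vid)
            blast_snp_carrier[b] = carried
    truth_transmission = pd.DataFrame(
        trans_rows, columns=["variant_id", "donor_id", "blastocyst_id", "transmitted"])

    # ---- read counts
    err = config.seq_error_rate
    obs_rows = []

    def _emit(sample_id, chrom, pos, ref, alt, depth, alt_count):
        if depth > 0:
            obs_rows.append({"sample_id": sample_id, "chrom": chrom, "pos": pos,
                             "ref": ref, "alt": alt,
                             "ref_count": int(depth - alt_count),
                             "alt_count": int(alt_count)})

    panel_sites = list(panel.itertuples(index=False))
    truth_by_vid = {r.variant_id: r for r in truth_variants.itertuples(index=False)}
    snp_gt_by_vid = dict(snp_truth)

    lowq_ids = set()
    for i, d in enumerate(donors):
        ids = manifest.blastocysts_of(d)
        lowq_ids.update(ids[len(ids) - n_lowq[i]:] if n_lowq[i] else [])

    for s in manifest.df.itertuples(index=False):
        if s.role == "blastocyst":
            rng = donor_rngs[donors.index(s.donor_id)]
            mean = config.depth_mean_blastocyst
            if s.sample_id in lowq_ids:
                mean *= config.low_quality_depth_factor
            for site in panel_sites:
                depth = int(_nb_depth(rng, mean, config.depth_dispersion))
                if depth == 0:
                    continue
                if site.variant_class == "control_snp":
                    carrier = site.variant_id in blast_snp_carrier[s.sample_id]
                else:
                    carrier = site.variant_id in blast_transmitted[s.sample_id]
                rc, ac = wga_observe(carrier, depth, rng,
                                     dropout_prob=config.wga_dropout_prob,
                                     concentration=config.wga_imbalance_concentration,
                                     error_rate=err)
                _emit(s.sample_id, site.chrom, site.pos, site.ref, site.alt, depth, ac)
        else:
            rng = (donor_rngs[donors.index(s.donor_id)]
                   if s.donor_id in donors else master)
            for site in panel_sites:
                depth = int(_nb_depth(rng, config.depth_mean_tissue,
                                      config.depth_dispersion))
                if depth == 0:
                    continue
                if site.variant_class == "control_snp":
                    g = snp_gt_by_vid[site.variant_id][s.donor_id]
                    p = {"ref_hom": err, "het": 0.5, "alt_hom": 1.0 - err}[g]
                else:
                    tr = truth_by_vid[site.variant_id]
                    if tr.donor_id == s.donor_id:
                        p = tr.true_sperm_af if s.tissue == "sperm" else tr.true_soma_af
                        p = max(p, err)
                    else:
                        p = err
                ac = rng.binomial(depth, p)
                _emit(s.sample_id, site.chrom, site.pos, site.ref, site.alt, depth, ac)

    observations = io_formats.annotate_observations(pd.DataFrame(obs_rows))

    return SyntheticCohort(config=config, manifest=manifest, panel=panel,
                           observations=observations,
                           truth_variants=truth_variants,
                           truth_transmission=truth_transmission,
                           trees=trees)
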