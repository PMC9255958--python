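"""Genotyping of deep amplicon (MPAS) read counts.

Implements the rules used to confirm mosaicism in ultra-deep targeted
resequencing data: exact binomial confidence intervals on allelic
fractions, a cohort-wide noise ceiling ("population threshold") derived
from reference-homozygous SNP sites, three-criterion tissue mosaic
calls against unrelated control samples, SNP genotyping by AF bands,
blastocyst positivity calls, and per-blastocyst coverage QC.

All AF confidence intervals are exact Clopper-Pearson intervals; a call
is only made when it clears both the population threshold and the
control samples' own intervals, so sequencing/amplification noise at a
locus can never masquerade as mosaicism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta

__all__ = [
    "GenotypingThresholds",
    "PopulationThreshold",
    "TransmissionMatrix",
    "GenotypingResult",
    "exact_binomial_ci",
    "exact_binomial_ci_arrays",
    "population_threshold",
    "call_tissue_mosaic",
    "classify_variant",
    "genotype_snp",
    "call_blastocyst",
    "qc_blastocyst",
    "run_genotyping",
]

GONADAL_CATEGORIES = ("sperm_only", "shared")


@dataclass(frozen=True)
class GenotypingThresholds:
    """Tunable cutoffs for all genotyping rules.

    Defaults follow the validated deep-amplicon workflow: tissues must
    reach 100x, blastocysts 20x; a blastocyst is positive for a mosaic
    variant only when the CI lower bound clears 0.05 AF; SNP genotypes
    use the [0.2, 0.8) heterozygous band; blastocysts covered at fewer
    than 10% of panel positions are discarded.
    """

    tissue_min_depth: int = 100
    blastocyst_min_depth: int = 20
    blastocyst_af_floor: float = 0.05
    het_lower: float = 0.2
    het_upper: float = 0.8
    blastocyst_positive_af: float = 0.05
    min_detectable_fraction: float = 0.10
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.het_lower < self.het_upper <= 1.0):
            raise ValueError("require 0 < het_lower < het_upper <= 1")
        if self.tissue_min_depth <= 0 or self.blastocyst_min_depth <= 0:
            raise ValueError("depth thresholds must be positive")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class PopulationThreshold:
    """Scalar noise ceiling on AF derived from reference-homozygous sites."""

    value: float
    n_sites_used: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value < 1.0):
            raise ValueError("population threshold must be in [0, 1)")


@dataclass
class TransmissionMatrix:
    """Variant x blastocyst grid of {positive, negative, no_data} calls.

    Rows are one donor's gonadal mosaic variants, columns that donor's
    QC-passing blastocysts.
    """

    donor_id: str
    calls: pd.DataFrame  # index: variant_id, columns: blastocyst sample_id

    CELL_VALUES = ("positive", "negative", "no_data")

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.values.astype(str))) - set(self.CELL_VALUES) if self.calls.size else set()
        if bad:
            raise ValueError(f"invalid transmission cells: {sorted(bad)}")

    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_blastocysts(self) -> int:
        return self.calls.shape[1]

    def cell_counts(self) -> dict:
        flat = self.calls.values.ravel()
        return {v: int((flat == v).sum()) for v in self.CELL_VALUES}

    def observed_total(self) -> int:
        return int((self.calls.values == "positive").sum())

    def per_blastocyst_counts(self) -> pd.Series:
        return (self.calls == "positive").sum(axis=0)

    def per_variant_rates(self) -> pd.Series:
        """Transmission rate per variant over cells with data; NaN if none."""
        pos = (self.calls == "positive").sum(axis=1)
        with_data = (self.calls != "no_data").sum(axis=1)
        return pos / with_data.replace(0, np.nan)

    def n_units_with_data(self) -> pd.Series:
        return (self.calls != "no_data").sum(axis=1)


def exact_binomial_ci(alt_count: int, depth: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial CI for an allelic fraction.

    The lower bound is 0 exactly when ``alt_count == 0`` and the upper
    bound 1 exactly when ``alt_count == depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0 <= alt_count <= depth):
        raise ValueError("require 0 <= alt_count <= depth")
    a = (1.0 - level) / 2.0
    lower = 0.0 if alt_count == 0 else float(_beta.ppf(a, alt_count, depth - alt_count + 1))
    upper = 1.0 if alt_count == depth else float(_beta.ppf(1.0 - a, alt_count + 1, depth - alt_count))
    return lower, upper


def exact_binomial_ci_arrays(
    alt_count: np.ndarray, depth: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Clopper-Pearson bounds; requires all depths > 0."""
    alt = np.asarray(alt_count, dtype=float)
    dep = np.asarray(depth, dtype=float)
    if np.any(dep <= 0):
        raise ValueError("all depths must be positive")
    a = (1.0 - level) / 2.0
    with np.errstate(invalid="ignore"):
        lower = _beta.ppf(a, alt, dep - alt + 1.0)
        upper = _beta.ppf(1.0 - a, alt + 1.0, dep - alt)
    lower = np.where(alt == 0, 0.0, lower)
    upper = np.where(alt == dep, 1.0, upper)
    return lower, upper


def population_threshold(
    ref_hom_afs: Iterable[float], quantile: float = 0.95
) -> PopulationThreshold:
    """Noise ceiling from AFs observed at reference-homozygous SNP sites.

    Uses the empirical upper quantile ('higher' interpolation, so the
    value is an actually observed AF and the statistic is invariant
    under duplication of the input set).
    """
    afs = np.asarray(list(ref_hom_afs), dtype=float)
    if afs.size == 0:
        raise ValueError("no reference-homozygous observations supplied")
    if np.any((afs < 0) | (afs > 1)):
        raise ValueError("AFs must lie in [0, 1]")
    value = float(np.quantile(afs, quantile, method="higher"))
    # an AF of 1.0 would be a mis-genotyped site, not noise; refuse it
    if value >= 1.0:
        raise ValueError("reference-homozygous AFs include 1.0; check genotypes")
    return PopulationThreshold(value=value, n_sites_used=int(afs.size))


def call_tissue_mosaic(
    obs: Mapping,
    controls: Iterable[Mapping],
    pop_thr: PopulationThreshold,
    thr: GenotypingThresholds = GenotypingThresholds(),
) -> bool | None:
    """Three-criterion mosaic call for one tissue observation.

    1. depth at the position >= ``tissue_min_depth``;
    2. the variant's CI must not overlap the population threshold or
       any control sample's CI upper bound (strictly above both);
    3. at least one control's CI lower bound sits at or below the
       population threshold (i.e. the locus behaves like noise in a
       control, ruling out systematic artefacts).

    Returns ``None`` when no control sample covers the site (uncallable,
    distinct from a negative call).
    """
    controls = list(controls)
    if not controls:
        return None
    if obs["depth"] < thr.tissue_min_depth:
        return False
    ctrl_upper = max(c["ci_upper"] for c in controls)
    ctrl_lower = min(c["ci_lower"] for c in controls)
    crit2 = obs["ci_lower"] > max(pop_thr.value, ctrl_upper)
    crit3 = ctrl_lower <= pop_thr.value
    return bool(crit2 and crit3)


def classify_variant(sperm_flag: bool, soma_flag: bool) -> str:
    """Combine per-tissue mosaic flags into a variant category.

    Gonadal (transmissible) variants are ``sperm_only`` and ``shared``;
    ``soma_only`` variants (e.g. clonal hematopoiesis) are excluded from
    transmission analysis.
    """
    if sperm_flag and soma_flag:
        return "shared"
    if sperm_flag:
        return "sperm_only"
    if soma_flag:
        return "soma_only"
    return "rejected"


def genotype_snp(obs: Mapping, thr: GenotypingThresholds = GenotypingThresholds()) -> str | None:
    """SNP genotype for a tissue sample from its AF.

    af < het_lower -> ref_hom; het_lower <= af < het_upper -> het;
    af >= het_upper -> alt_hom (both boundaries closed on the left).
    Returns ``None`` when depth is below ``tissue_min_depth``.
    """
    if obs["depth"] < thr.tissue_min_depth:
        return None
    af = obs["af"]
    if af < thr.het_lower:
        return "ref_hom"
    if af < thr.het_upper:
        return "het"
    return "alt_hom"


def call_blastocyst(
    obs: Mapping, thr: GenotypingThresholds = GenotypingThresholds(), mode: str = "mosaic"
) -> str:
    """Positive/negative/no_data call for a blastocyst observation.

    mode='mosaic': positive iff the CI lower bound exceeds the 0.05 AF
    floor (the stringent rule for mosaic variants). mode='snp': positive
    iff the point AF exceeds 0.05 (het and hom not distinguished).
    Depth below ``blastocyst_min_depth`` is no_data in either mode.
    """
    if mode not in ("mosaic", "snp"):
        raise ValueError(f"unknown mode {mode!r}")
    if obs["depth"] < thr.blastocyst_min_depth:
        return "no_data"
    if mode == "mosaic":
        return "positive" if obs["ci_lower"] > thr.blastocyst_af_floor else "negative"
    return "positive" if obs["af"] > thr.blastocyst_positive_af else "negative"


def qc_blastocyst(
    blastocyst_obs: pd.DataFrame,
    panel_size: int,
    thr: GenotypingThresholds = GenotypingThresholds(),
) -> tuple[bool, float]:
    """Coverage QC: fraction of panel positions detectable (depth >= 20x).

    A blastocyst fails when fewer than ``min_detectable_fraction`` of
    panel positions are detectable; failing blastocysts are dropped from
    every downstream stage. Panel positions with no observation row
    count as undetectable.
    """
    if panel_size <= 0:
        raise ValueError("panel must be non-empty")
    if len(blastocyst_obs) == 0:
        return False, 0.0
    n_detectable = int((blastocyst_obs["depth"] >= thr.blastocyst_min_depth).sum())
    frac = n_detectable / panel_size
    return frac >= thr.min_detectable_fraction, frac


# ---------------------------------------------------------------------------
# cohort-level orchestration


@dataclass
class GenotypingResult:
    """All outputs of genotyping one cohort."""

    thresholds: GenotypingThresholds
    pop_threshold: PopulationThreshold
    mosaic_calls: pd.DataFrame
    snp_genotypes: pd.DataFrame
    blastocyst_qc: pd.DataFrame
    matrices: dict = field(default_factory=dict)  # donor_id -> TransmissionMatrix
    blastocyst_snp_calls: pd.DataFrame | None = None
    uncallable: pd.DataFrame | None = None

    def gonadal_calls(self) -> pd.DataFrame:
        return self.mosaic_calls[self.mosaic_calls["category"].isin(GONADAL_CATEGORIES)]


def _obs_lookup(observations: pd.DataFrame) -> dict:
    return {
        (r.sample_id, r.variant_id): r
        for r in observations.itertuples(index=False)
    }


def run_genotyping(
    manifest,
    panel: pd.DataFrame,
    observations: pd.DataFrame,
    thr: GenotypingThresholds = GenotypingThresholds(),
) -> GenotypingResult:
    """Full genotyping of a cohort: threshold, mosaic calls, SNP genotypes,
    blastocyst QC and per-donor transmission matrices.

    ``manifest`` is an ``io_formats.SampleManifest``; ``panel`` and
    ``observations`` are the validated tables from ``io_formats``.
    """
    control_samples = manifest.samples_with_role("unrelated_control")["sample_id"].tolist()
    if not control_samples:
        raise ValueError("mosaic calling requires at least one unrelated control sample")

    snps = panel[panel["variant_class"] == "control_snp"]
    candidates = panel[panel["variant_class"] == "mosaic_candidate"]
    gt_cols = {c[len("gt_"):]: c for c in panel.columns if c.startswith("gt_")}

    tissue_samples = manifest.df[~manifest.df["role"].isin(["blastocyst"])]
    obs_by_key = _obs_lookup(observations)

    # --- population threshold from ref-hom control-SNP observations, pooled
    ref_hom_afs = []
    for snp in snps.itertuples(index=False):
        for s in tissue_samples.itertuples(index=False):
            gt_col = gt_cols.get(s.donor_id)
            if gt_col is None or getattr(snp, gt_col) != "ref_hom":
                continue
            row = obs_by_key.get((s.sample_id, snp.variant_id))
            if row is not None and row.depth >= thr.tissue_min_depth:
                ref_hom_afs.append(row.af)
    pop_thr = population_threshold(ref_hom_afs)

    def _ctrl_obs(variant_id):
        out = []
        for sid in control_samples:
            row = obs_by_key.get((sid, variant_id))
            if row is not None:
                out.append({"ci_lower": row.ci_lower, "ci_upper": row.ci_upper})
        return out

    # --- mosaic calls per sperm donor
    mosaic_rows, uncallable_rows = [], []
    sperm_donors = manifest.samples_with_role("sperm_donor")["donor_id"].unique()
    for donor in sperm_donors:
        sperm_sample = manifest.sample_of(donor, "sperm")
        soma_sample = manifest.soma_sample_of(donor)
        for var in candidates.itertuples(index=False):
            ctrls = _ctrl_obs(var.variant_id)
            flags, stats = {}, {}
            for tissue, sid in (("sperm", sperm_sample), ("soma", soma_sample)):
                row = obs_by_key.get((sid, var.variant_id)) if sid else None
                if row is None:
                    flags[tissue] = False
                    stats[tissue] = (np.nan, np.nan, np.nan, 0)
                    continue
                flag = call_tissue_mosaic(
                    {"depth": row.depth, "ci_lower": row.ci_lower},
                    ctrls, pop_thr, thr,
                )
                if flag is None:
                    uncallable_rows.append(
                        {"donor_id": donor, "variant_id": var.variant_id, "tissue": tissue}
                    )
                    flag = False
                flags[tissue] = flag
                stats[tissue] = (row.af, row.ci_lower, row.ci_upper, row.depth)
            category = classify_variant(flags["sperm"], flags["soma"])
            mosaic_rows.append({
                "donor_id": donor,
                "variant_id": var.variant_id,
                "chrom": var.chrom, "pos": var.pos, "ref": var.ref, "alt": var.alt,
                "category": category,
                "sperm_af": stats["sperm"][0], "sperm_ci_lower": stats["sperm"][1],
                "sperm_ci_upper": stats["sperm"][2], "sperm_depth": stats["sperm"][3],
                "soma_af": stats["soma"][0], "soma_ci_lower": stats["soma"][1],
                "soma_ci_upper": stats["soma"][2], "soma_depth": stats["soma"][3],
            })
    mosaic_calls = pd.DataFrame(mosaic_rows)

    # --- SNP genotypes in tissue samples
    snp_rows = []
    for s in tissue_samples.itertuples(index=False):
        for snp in snps.itertuples(index=False):
            row = obs_by_key.get((s.sample_id, snp.variant_id))
            if row is None:
                continue
            gt = genotype_snp({"depth": row.depth, "af": row.af}, thr)
            gt_col = gt_cols.get(s.donor_id)
            wgs_gt = getattr(snp, gt_col) if gt_col else "unknown"
            snp_rows.append({
                "sample_id": s.sample_id, "donor_id": s.donor_id,
                "tissue": s.tissue, "variant_id": snp.variant_id,
                "genotype": gt if gt is not None else "lowdepth",
                "wgs_genotype": wgs_gt,
                "af": row.af, "depth": row.depth,
            })
    snp_genotypes = pd.DataFrame(snp_rows)

    # --- blastocyst QC against the full panel
    qc_rows = []
    panel_size = len(panel)
    blasto = manifest.samples_with_role("blastocyst")
    for b in blasto.itertuples(index=False):
        b_obs = observations[observations["sample_id"] == b.sample_id]
        ok, frac = qc_blastocyst(b_obs, panel_size, thr)
        qc_rows.append({
            "sample_id": b.sample_id, "donor_id": b.donor_id,
            "detectable_fraction": frac, "qc_pass": ok,
        })
    blastocyst_qc = pd.DataFrame(qc_rows)
    qc_pass = set(blastocyst_qc.loc[blastocyst_qc["qc_pass"], "sample_id"])

    # --- transmission matrices: gonadal variants x QC-passing blastocysts
    matrices = {}
    for donor in sperm_donors:
        gcalls = mosaic_calls[
            (mosaic_calls["donor_id"] == donor)
            & mosaic_calls["category"].isin(GONADAL_CATEGORIES)
        ]
        b_ids = [
            b for b in blasto.loc[blasto["donor_id"] == donor, "sample_id"]
            if b in qc_pass
        ]
        grid = pd.DataFrame(
            "no_data", index=list(gcalls["variant_id"]), columns=b_ids, dtype=object
        )
        for vid in gcalls["variant_id"]:
            for bid in b_ids:
                row = obs_by_key.get((bid, vid))
                if row is not None:
                    grid.loc[vid, bid] = call_blastocyst(
                        {"depth": row.depth, "ci_lower": row.ci_lower, "af": row.af},
                        thr, mode="mosaic",
                    )
        matrices[donor] = TransmissionMatrix(donor_id=donor, calls=grid)

    # --- blastocyst SNP calls (used by FN calibration)
    bsnp_rows = []
    for b in blasto.itertuples(index=False):
        for snp in snps.itertuples(index=False):
            row = obs_by_key.get((b.sample_id, snp.variant_id))
            if row is None:
                call = "no_data"
            else:
                call = call_blastocyst(
                    {"depth": row.depth, "ci_lower": row.ci_lower, "af": row.af},
                    thr, mode="snp",
                )
            bsnp_rows.append({
                "sample_id": b.sample_id, "donor_id": b.donor_id,
                "variant_id": snp.variant_id, "call": call,
            })
    blastocyst_snp_calls = pd.DataFrame(bsnp_rows)

    return GenotypingResult(
        thresholds=thr,
        pop_threshold=pop_thr,
        mosaic_calls=mosaic_calls,
        snp_genotypes=snp_genotypes,
        blastocyst_qc=blastocyst_qc,
        matrices=matrices,
        blastocyst_snp_calls=blastocyst_snp_calls,
        uncallable=pd.DataFrame(uncallable_rows, columns=["donor_id", "variant_id", "tissue"]),
    )
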