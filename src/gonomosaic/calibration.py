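"""False-negative / false-positive calibration of blastocyst genotyping.

Whole-genome-amplified blastocyst DNA suffers allelic dropout, so some
truly transmitted variants are missed. Two internal controls quantify
this without external truth:

* **False negatives** — SNPs for which a parent is alternate-homozygous
  must appear in every blastocyst; the fraction of informative
  (SNP, blastocyst) pairs called negative is the FN rate. Heterozygous
  parental SNPs provide a Mendelian sanity check (transmission ~0.5).
* **False positives** — gonadal mosaic variants of one donor should
  never appear in another donor's blastocysts; the fraction of such
  cross-donor pairs called positive is the FP rate.

Pairs with no data (insufficient depth) are excluded from both
numerator and denominator. Rates are reported, not used to correct
downstream transmission counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .mpas_genotyper import (
    GONADAL_CATEGORIES,
    GenotypingResult,
    GenotypingThresholds,
    call_blastocyst,
)

__all__ = ["CalibrationResult", "estimate_false_negative",
           "estimate_false_positive", "calibrate"]


@dataclass(frozen=True)
class CalibrationResult:
    fn_rate: float
    fn_numerator: int
    fn_denominator: int
    fp_rate: float
    fp_numerator: int
    fp_denominator: int
    het_transmission_rate: float

    def __post_init__(self) -> None:
        if self.fn_denominator <= 0 or self.fp_denominator <= 0:
            raise ValueError("calibration denominators must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _parental_genotypes(snp_genotypes: pd.DataFrame, donor_id: str) -> pd.Series:
    """Per-SNP tissue genotype for a donor: soma sample preferred, sperm
    as fallback (WGA is not involved in either, so both are reliable)."""
    own = snp_genotypes[(snp_genotypes["donor_id"] == donor_id)
                        & (snp_genotypes["genotype"] != "lowdepth")]
    soma = own[own["tissue"].isin(["blood", "saliva"])]
    sperm = own[own["tissue"] == "sperm"]
    gts = soma.set_index("variant_id")["genotype"]
    fallback = sperm.set_index("variant_id")["genotype"]
    return gts.combine_first(fallback)


def estimate_false_negative(
    snp_genotypes: pd.DataFrame,
    blastocyst_snp_calls: pd.DataFrame,
) -> tuple[int, int, float]:
    """FN components from parental alt-hom SNPs.

    Returns (numerator, denominator, het_transmission_rate): the
    denominator is every (alt-hom parental SNP, blastocyst of that
    parent) pair with data, the numerator those called negative.
    """
    fn_num = fn_den = het_pos = het_den = 0
    for donor_id, calls in blastocyst_snp_calls.groupby("donor_id"):
        gts = _parental_genotypes(snp_genotypes, donor_id)
        with_data = calls[calls["call"] != "no_data"]
        for row in with_data.itertuples(index=False):
            g = gts.get(row.variant_id)
            if g == "alt_hom":
                fn_den += 1
                fn_num += row.call == "negative"
            elif g == "het":
                het_den += 1
                het_pos += row.call == "positive"
    if fn_den == 0:
        raise ValueError("no informative alt-hom (SNP, blastocyst) pairs")
    het_rate = het_pos / het_den if het_den else float("nan")
    return int(fn_num), int(fn_den), float(het_rate)


def estimate_false_positive(
    mosaic_calls: pd.DataFrame,
    observations: pd.DataFrame,
    manifest,
    qc_pass_blastocysts: set,
    thr: GenotypingThresholds = GenotypingThresholds(),
) -> tuple[int, int]:
    """FP components from cross-donor (variant, blastocyst) pairs.

    Each gonadal mosaic variant of donor X is genotyped in every
    QC-passing blastocyst of every other donor Y; positives are false
    by construction.
    """
    gonadal = mosaic_calls[mosaic_calls["category"].isin(GONADAL_CATEGORIES)]
    donors = gonadal["donor_id"].unique()
    if len(donors) < 2:
        raise ValueError("false-positive calibration needs >= 2 donors")
    obs_by_key = {(r.sample_id, r.variant_id): r
                  for r in observations.itertuples(index=False)}
    num = den = 0
    for donor_x in donors:
        vids = gonadal.loc[gonadal["donor_id"] == donor_x, "variant_id"]
        other_blasts = [
            b for b in manifest.samples_with_role("blastocyst")["sample_id"]
            if manifest.donor_of(b) != donor_x and b in qc_pass_blastocysts
        ]
        for vid in vids:
            for b in other_blasts:
                row = obs_by_key.get((b, vid))
                if row is None:
                    continue
                call = call_blastocyst(
                    {"depth": row.depth, "ci_lower": row.ci_lower, "af": row.af},
                    thr, mode="mosaic")
                if call == "no_data":
                    continue
                den += 1
                num += call == "positive"
    if den == 0:
        raise ValueError("no cross-donor pairs with data")
    return int(num), int(den)


def calibrate(geno: GenotypingResult, observations: pd.DataFrame,
              manifest) -> CalibrationResult:
    """Run both calibrations on a genotyped cohort."""
    fn_num, fn_den, het_rate = estimate_false_negative(
        geno.snp_genotypes, geno.blastocyst_snp_calls)
    qc_pass = set(geno.blastocyst_qc.loc[geno.blastocyst_qc["qc_pass"], "sample_id"])
    fp_num, fp_den = estimate_false_positive(
        geno.mosaic_calls, observations, manifest, qc_pass, geno.thresholds)
    return CalibrationResult(
        fn_rate=fn_num / fn_den, fn_numerator=fn_num, fn_denominator=fn_den,
        fp_rate=fp_num / fp_den, fp_numerator=fp_num, fp_denominator=fp_den,
        het_transmission_rate=het_rate,
    )
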