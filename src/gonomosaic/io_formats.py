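"""Tabular I/O with strict validation.

All artifacts are tab-separated UTF-8 text with '.' for missing
optional fields. Coordinates are 1-based fully closed (VCF convention).
A missing observation (site not covered in a sample) is encoded by row
absence; zero-depth rows are rejected as malformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .mpas_genotyper import TransmissionMatrix, exact_binomial_ci_arrays

SCHEMA_VERSION = "1.0"

ROLES = ("sperm_donor", "egg_donor", "blastocyst", "unrelated_control")
TISSUES = ("sperm", "blood", "saliva", "wga_blastocyst", "na")
VARIANT_CLASSES = ("mosaic_candidate", "control_snp")
WGS_GENOTYPES = ("ref_hom", "het", "alt_hom", "unknown")

MANIFEST_COLUMNS = ["sample_id", "donor_id", "role", "tissue"]
PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_class"]
COUNTS_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


class ManifestError(ValueError):
    """A row refers to a sample/donor the manifest does not define."""


class FormatError(ValueError):
    """A table violates the column or value contract."""


def variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


@dataclass
class SampleManifest:
    """Cohort sample sheet: who each sample belongs to and what it is."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            dupes = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample_id: {dupes}")
        bad_role = set(self.df["role"]) - set(ROLES)
        if bad_role:
            raise FormatError(f"unknown roles: {sorted(bad_role)}")
        bad_tissue = set(self.df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise FormatError(f"unknown tissues: {sorted(bad_tissue)}")
        sperm_donors = set(self.df.loc[self.df["role"] == "sperm_donor", "donor_id"])
        blasto = self.df[self.df["role"] == "blastocyst"]
        orphans = set(blasto["donor_id"]) - sperm_donors
        if orphans:
            raise ManifestError(
                f"blastocysts reference donors with no sperm_donor sample: {sorted(orphans)}"
            )

    def samples_with_role(self, role: str) -> pd.DataFrame:
        return self.df[self.df["role"] == role]

    def sample_of(self, donor_id: str, tissue: str) -> str | None:
        hit = self.df[(self.df["donor_id"] == donor_id) & (self.df["tissue"] == tissue)]
        return hit["sample_id"].iloc[0] if len(hit) else None

    def soma_sample_of(self, donor_id: str) -> str | None:
        """The donor's somatic sample (blood or saliva), if any."""
        for tissue in ("blood", "saliva"):
            sid = self.sample_of(donor_id, tissue)
            if sid is not None:
                return sid
        return None

    def blastocysts_of(self, donor_id: str) -> list[str]:
        hit = self.df[(self.df["role"] == "blastocyst") & (self.df["donor_id"] == donor_id)]
        return hit["sample_id"].tolist()

    def donor_of(self, sample_id: str) -> str:
        hit = self.df[self.df["sample_id"] == sample_id]
        if not len(hit):
            raise ManifestError(f"unknown sample_id: {sample_id}")
        return hit["donor_id"].iloc[0]


def read_manifest(path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleManifest(df=df)


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    """Candidate-variant manifest: mosaic candidates and control SNPs.

    Columns beyond the fixed five that start with ``gt_<donor_id>`` hold
    the donor's WGS genotype at the site ('.' -> unknown).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel missing columns: {missing}")
    df["pos"] = _parse_int(df["pos"], "pos")
    bad = set(df["variant_class"]) - set(VARIANT_CLASSES)
    if bad:
        raise FormatError(f"unknown variant_class: {sorted(bad)}")
    gt_cols = [c for c in df.columns if c.startswith("gt_")]
    for c in gt_cols:
        df[c] = df[c].fillna(".").replace(".", "unknown")
        bad = set(df[c]) - set(WGS_GENOTYPES)
        if bad:
            raise FormatError(f"unknown WGS genotype in {c}: {sorted(bad)}")
    df["variant_id"] = [variant_id(*t) for t in zip(df["chrom"], df["pos"], df["ref"], df["alt"])]
    if df["variant_id"].duplicated().any():
        raise FormatError("duplicate (chrom,pos,ref,alt) in panel")
    if gt_cols:
        snp = df[df["variant_class"] == "control_snp"]
        known = (snp[gt_cols] != "unknown").any(axis=1)
        if not known.all():
            bad_ids = snp.loc[~known, "variant_id"].tolist()
            raise FormatError(f"control SNPs with no known WGS genotype: {bad_ids}")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.drop(columns=["variant_id"], errors="ignore").copy()
    gt_cols = [c for c in out.columns if c.startswith("gt_")]
    for c in gt_cols:
        out[c] = out[c].replace("unknown", ".")
    out.to_csv(path, sep="\t", index=False)


def _parse_int(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() | (out != out.round())
    if bad.any():
        rows = (series.index[bad] + 2).tolist()  # +2: header + 1-based
        raise FormatError(f"column {name}: non-integer values at file rows {rows[:10]}")
    return out.astype(int)


def read_counts_table(path, manifest: SampleManifest, ci_level: float = 0.95) -> pd.DataFrame:
    """Read a per-site read-count table and attach AF and exact CI columns.

    Every row is validated against the manifest; rows are never silently
    dropped. Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts table missing columns: {missing}")
    for col in ("ref_count", "alt_count"):
        df[col] = _parse_int(df[col], col)
        if (df[col] < 0).any():
            rows = (df.index[df[col] < 0] + 2).tolist()
            raise FormatError(f"column {col}: negative counts at file rows {rows[:10]}")
    df["pos"] = _parse_int(df["pos"], "pos")
    unknown = set(df["sample_id"]) - set(manifest.df["sample_id"])
    if unknown:
        raise ManifestError(f"counts table references unknown samples: {sorted(unknown)}")
    return annotate_observations(df, ci_level=ci_level)


def annotate_observations(df: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Derive variant_id, depth, af, and exact CI bounds for count rows."""
    df = df.copy()
    df["variant_id"] = [
        variant_id(*t) for t in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    df["depth"] = df["ref_count"] + df["alt_count"]
    if (df["depth"] == 0).any():
        rows = (df.index[df["depth"] == 0] + 2).tolist()
        raise FormatError(
            f"zero-depth rows at file rows {rows[:10]}; encode missing sites by row absence"
        )
    df["af"] = df["alt_count"] / df["depth"]
    lower, upper = exact_binomial_ci_arrays(
        df["alt_count"].to_numpy(), df["depth"].to_numpy(), level=ci_level
    )
    df["ci_lower"] = lower
    df["ci_upper"] = upper
    return df


def write_counts_table(observations: pd.DataFrame, path) -> None:
    observations[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


# --- transmission matrices: long TSV (variant_id, donor_id, blastocyst, call)


def write_matrices(matrices: dict, path) -> None:
    rows = []
    for donor, m in matrices.items():
        for vid in m.calls.index:
            for bid in m.calls.columns:
                rows.append({
                    "donor_id": donor, "variant_id": vid,
                    "blastocyst_id": bid, "call": m.calls.loc[vid, bid],
                })
    pd.DataFrame(rows, columns=["donor_id", "variant_id", "blastocyst_id", "call"]).to_csv(
        path, sep="\t", index=False
    )


def read_matrices(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("donor_id", "variant_id", "blastocyst_id", "call") if c not in df.columns]
    if missing:
        raise FormatError(f"matrix table missing columns: {missing}")
    out = {}
    for donor, grp in df.groupby("donor_id", sort=False):
        grid = grp.pivot(index="variant_id", columns="blastocyst_id", values="call")
        # preserve first-appearance order
        grid = grid.reindex(index=grp["variant_id"].drop_duplicates(),
                            columns=grp["blastocyst_id"].drop_duplicates())
        grid.index.name = None
        grid.columns.name = None
        out[donor] = TransmissionMatrix(donor_id=donor, calls=grid)
    return out


# --- VCF export of called variants (minimal VCF 4.2)


def write_vcf(calls: pd.DataFrame, path) -> None:
    """Export mosaic calls as VCF 4.2 with sperm AF and category in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allelic fraction in sperm">',
        '##INFO=<ID=CAT,Number=1,Type=String,Description="Mosaic category">',
        '##INFO=<ID=DONOR,Number=1,Type=String,Description="Sperm donor">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in calls.itertuples(index=False):
        af = "." if pd.isna(r.sperm_af) else f"{r.sperm_af:.6g}"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
            f"AF={af};CAT={r.category};DONOR={r.donor_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --- stage reports


def write_report(results: dict, outdir) -> list[str]:
    """Write machine-readable stage outputs plus a human summary.

    ``results`` maps stage names to objects: 'genotyping'
    (GenotypingResult), 'calibration' (CalibrationResult), 'expectation'
    (dict of ExpectationResult-like dicts), 'evenness' (dict of
    PermutationResult-like dicts). Absent stages are skipped; written
    tables round-trip exactly through their readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    geno = results.get("genotyping")
    if geno is not None:
        geno.mosaic_calls.to_csv(outdir / "mosaic_calls.tsv", sep="\t", index=False)
        geno.snp_genotypes.to_csv(outdir / "snp_genotypes.tsv", sep="\t", index=False)
        geno.blastocyst_qc.to_csv(outdir / "blastocyst_qc.tsv", sep="\t", index=False)
        write_matrices(geno.matrices, outdir / "transmission_matrix.tsv")
        written += ["mosaic_calls.tsv", "snp_genotypes.tsv", "blastocyst_qc.tsv",
                    "transmission_matrix.tsv"]
        if len(geno.mosaic_calls):
            write_vcf(geno.gonadal_calls(), outdir / "gonadal_calls.vcf")
            written.append("gonadal_calls.vcf")

    for key, fname in (("calibration", "calibration.json"),
                       ("expectation", "expectation.json"),
                       ("evenness", "evenness.json")):
        obj = results.get(key)
        if obj is not None:
            payload = {"schema_version": SCHEMA_VERSION, key: _to_jsonable(obj)}
            (outdir / fname).write_text(json.dumps(payload, indent=2) + "\n")
            written.append(fname)

    summary = _summary_text(results)
    (outdir / "summary.txt").write_text(summary)
    written.append("summary.txt")
    return written


def _to_jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _summary_text(results: dict) -> str:
    lines = ["gonomosaic pipeline summary", "=" * 28]
    geno = results.get("genotyping")
    if geno is not None:
        gon = geno.gonadal_calls()
        lines.append(f"population threshold: {geno.pop_threshold.value:.6g} "
                     f"({geno.pop_threshold.n_sites_used} ref-hom sites)")
        lines.append(f"gonadal mosaic variants: {len(gon)}")
        for donor, grp in gon.groupby("donor_id"):
            cats = grp["category"].value_counts().to_dict()
            lines.append(f"  {donor}: {len(grp)} ({cats})")
        n_fail = int((~geno.blastocyst_qc["qc_pass"]).sum())
        lines.append(f"blastocysts failing QC: {n_fail}")
        total = sum(m.observed_total() for m in geno.matrices.values())
        lines.append(f"observed transmission events: {total}")
    cal = results.get("calibration")
    if cal is not None:
        d = _to_jsonable(cal)
        lines.append(f"false-negative rate: {d['fn_rate']:.4g} "
                     f"({d['fn_numerator']}/{d['fn_denominator']})")
        lines.append(f"false-positive rate: {d['fp_rate']:.4g} "
                     f"({d['fp_numerator']}/{d['fp_denominator']})")
    exp = results.get("expectation")
    if exp is not None:
        for scope, e in _to_jsonable(exp).items():
            lines.append(f"expected transmissions [{scope}]: "
                         f"mean {e['gaussian_mean']:.2f} "
                         f"ci95 ({e['ci95'][0]:.2f}, {e['ci95'][1]:.2f}) "
                         f"observed {e['observed_total']} -> {e.get('verdict', '?')}")
    ev = results.get("evenness")
    if ev is not None:
        for scope, e in _to_jsonable(ev).items():
            lines.append(f"evenness [{scope}]: stat {e['statistic']} "
                         f"observed {e['observed_value']:.3g} p {e['p_value']:.4g}")
    return "\n".join(lines) + "\n"
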