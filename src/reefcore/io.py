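"""Readers and writers for the pipeline's interchange formats.

CSV dialect is fixed: comma-separated, UTF-8, header row required, empty or
``.`` for missing.  Density profiles and logger series round-trip through
headered CSV; biallelic SNP genotypes through VCF (read via cyvcf2, written
as minimal VCF 4.2); microsatellite raw calls through a long-format CSV; and
ancestry matrices through a STRUCTURE-style whitespace layout
(``individual  %missing  q1 .. qK``).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .densitometry import DensityProfile
from .popgen import MISSING, AncestryMatrix, GenotypeMatrix
from .thermal import TemperatureSeries

__all__ = [
    "VcfFormatError",
    "read_profile_csv",
    "write_profile_csv",
    "read_logger_csv",
    "write_logger_csv",
    "read_vcf",
    "write_vcf",
    "read_microsat_csv",
    "read_structure_q",
    "write_structure_q",
    "load_supplementary_cohort",
]

NA_VALUES = ["", "."]


class VcfFormatError(ValueError):
    """Malformed VCF, reported with the offending line number."""


# ---------------------------------------------------------------------------
# Density profiles and loggers
# ---------------------------------------------------------------------------

def read_profile_csv(
    path, core_id: str | None = None, collection_date=None
) -> DensityProfile:
    """Read a profile CSV with columns ``position_mm, density_g_cm3``."""
    path = Path(path)
    df = pd.read_csv(path, na_values=NA_VALUES)
    for col in ("position_mm", "density_g_cm3"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if collection_date is None:
        collection_date = _dt.date(2012, 1, 1)
    elif isinstance(collection_date, str):
        collection_date = _dt.date.fromisoformat(collection_date)
    return DensityProfile(
        core_id=core_id or path.stem,
        positions=df["position_mm"].to_numpy(dtype=float),
        density=df["density_g_cm3"].to_numpy(dtype=float),
        collection_date=collection_date,
    )


def write_profile_csv(profile: DensityProfile, path) -> None:
    pd.DataFrame(
        {"position_mm": profile.positions, "density_g_cm3": profile.density}
    ).to_csv(path, index=False)


def read_logger_csv(path, site_id: str | None = None, habitat: str = "outer reef") -> TemperatureSeries:
    """Read a logger CSV with columns ``timestamp_iso8601, temp_c``."""
    path = Path(path)
    df = pd.read_csv(path, na_values=NA_VALUES)
    for col in ("timestamp_iso8601", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    idx = pd.DatetimeIndex(pd.to_datetime(df["timestamp_iso8601"]))
    return TemperatureSeries(
        site_id=site_id or path.stem,
        habitat=habitat,
        data=pd.Series(df["temp_c"].to_numpy(dtype=float), index=idx, name="temp_c"),
    )


def write_logger_csv(series: TemperatureSeries, path) -> None:
    pd.DataFrame(
        {
            "timestamp_iso8601": series.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_c": series.data.to_numpy(),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_header(path: Path) -> None:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and not line.startswith("##fileformat=VCF"):
                raise VcfFormatError(f"{path}:1: first line must be ##fileformat=VCF...")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.rstrip("\n").split("\t")
                if fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VcfFormatError(f"{path}:{lineno}: malformed #CHROM header line")
                return
            raise VcfFormatError(f"{path}:{lineno}: data before #CHROM header line")
    raise VcfFormatError(f"{path}: no #CHROM header line found")


def read_vcf(path, metadata: pd.DataFrame | None = None) -> tuple[GenotypeMatrix, int]:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    GT fields are parsed to unordered allele pairs (0 = REF, 1 = ALT);
    half-missing or missing genotypes (``./.``, ``.|0``...) become missing
    cells.  Multiallelic records are skipped; the count of skipped records is
    returned alongside the matrix.
    """
    from cyvcf2 import VCF

    path = Path(path)
    _validate_vcf_header(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    alleles: list[list] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        gts = np.where(gts < 0, MISSING, gts)
        half = (gts == MISSING).any(axis=1)
        gts[half] = MISSING
        loci.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        alleles.append([rec.REF, rec.ALT[0]])
        columns.append(np.sort(gts, axis=1))
    vcf.close()
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0, 2), dtype=np.int32)
    )
    g = GenotypeMatrix(
        samples=samples, loci=loci, alleles=alleles, calls=calls, metadata=metadata
    )
    return g, skipped


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a biallelic GenotypeMatrix as a minimal uncompressed VCF 4.2."""
    if any(len(a) != 2 for a in g.alleles):
        raise ValueError("write_vcf requires biallelic loci")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for l, (locus, (ref, alt)) in enumerate(zip(g.loci, g.alleles)):
            gts = []
            for i in range(g.n_samples):
                a, b = g.calls[i, l]
                gts.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                f"1\t{l + 1}\t{locus}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def read_microsat_csv(path) -> pd.DataFrame:
    """Read raw fragment calls: ``sample, locus, run, allele_size, peak_height``."""
    df = pd.read_csv(path, na_values=NA_VALUES)
    req = {"sample", "locus", "run", "allele_size", "peak_height"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# STRUCTURE-style Q layout
# ---------------------------------------------------------------------------

def write_structure_q(a: AncestryMatrix, path, pct_missing=None) -> None:
    """Write Q in a STRUCTURE-like layout: ``individual %missing q1..qK``."""
    if pct_missing is None:
        pct_missing = np.zeros(len(a.samples))
    with open(path, "wt", encoding="utf-8") as fh:
        for name, miss, row in zip(a.samples, pct_missing, a.Q):
            qs = " ".join(f"{q:.6f}" for q in row)
            fh.write(f"{name} {miss:.1f} {qs}\n")


def read_structure_q(path, K: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a STRUCTURE-like Q layout back.

    Returns ``(samples, pct_missing, Q)``.  Rows whose ancestry proportions
    do not sum to 1 within 1e-3 are renormalized with a warning; rows with
    the wrong number of columns raise an error naming the row.
    """
    import warnings

    samples, miss, rows = [], [], []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2 + K:
                raise ValueError(
                    f"{path}:{lineno}: expected {2 + K} fields for K={K}, got {len(parts)}"
                )
            samples.append(parts[0])
            miss.append(float(parts[1]))
            q = np.array([float(x) for x in parts[2:]])
            total = q.sum()
            if abs(total - 1.0) > 1e-3:
                warnings.warn(
                    f"{path}:{lineno}: ancestry row sums to {total:.4f}; renormalized",
                    stacklevel=2,
                )
                q = q / total
            rows.append(q)
    return samples, np.asarray(miss), np.asarray(rows)


# ---------------------------------------------------------------------------
# Supplementary-table layouts
# ---------------------------------------------------------------------------

#: Default column mapping for the per-core growth table (core_data.txt-style)
#: and the stress-band strata table (strata_all_samples.txt-style).  Override
#: any entry via the ``column_map`` argument / config to match the actual
#: file headers.
DEFAULT_GROWTH_COLUMNS = {
    "id": "id",
    "lineage": "lineage",
    "habitat": "habitat",
    "density": "mean_density_g_cm3",
    "calcification": "mean_calcification_g_cm2_yr",
    "extension": "mean_extension_cm",
}
DEFAULT_STRATA_COLUMNS = {
    "id": "id",
    "year": "year",
    "stress": "stress",
}


def load_supplementary_cohort(
    growth_path,
    strata_path=None,
    growth_columns: dict | None = None,
    strata_columns: dict | None = None,
    event_years: tuple[int, ...] = (1998, 2010),
    sep: str | None = None,
) -> pd.DataFrame:
    """Build a cohort table from supplementary-style growth and strata files.

    ``growth_path`` holds one row per core with lineage, habitat and the
    growth means; ``strata_path`` (optional) holds one row per core x year
    with a stress-band presence value, pivoted here to ``stress_<year>``
    flags.  Column names in the files are declared through the mapping dicts
    (role -> column name); the delimiter is sniffed unless given.
    """
    gmap = {**DEFAULT_GROWTH_COLUMNS, **(growth_columns or {})}
    smap = {**DEFAULT_STRATA_COLUMNS, **(strata_columns or {})}

    growth = pd.read_csv(growth_path, sep=sep, engine="python", na_values=NA_VALUES)
    missing = [c for c in gmap.values() if c not in growth.columns]
    if missing:
        raise ValueError(f"{growth_path}: missing columns {missing}")
    cohort = pd.DataFrame(
        {
            "lineage": growth[gmap["lineage"]].to_numpy(),
            "habitat": growth[gmap["habitat"]].to_numpy(),
            "mean_density_g_cm3": growth[gmap["density"]].to_numpy(),
            "mean_calcification_g_cm2_yr": growth[gmap["calcification"]].to_numpy(),
            "mean_extension_cm": growth[gmap["extension"]].to_numpy(),
        },
        index=pd.Index(growth[gmap["id"]].astype(str), name="id"),
    )

    if strata_path is not None:
        strata = pd.read_csv(strata_path, sep=sep, engine="python", na_values=NA_VALUES)
        missing = [c for c in smap.values() if c not in strata.columns]
        if missing:
            raise ValueError(f"{strata_path}: missing columns {missing}")
        strata = strata.rename(
            columns={smap["id"]: "id", smap["year"]: "year", smap["stress"]: "stress"}
        )
        strata["id"] = strata["id"].astype(str)
        for year in event_years:
            sub = strata[strata["year"] == year].set_index("id")["stress"]
            flag = sub.map(
                lambda v: bool(int(v)) if str(v) not in ("nan", "<NA>") else pd.NA
            )
            cohort[f"stress_{year}"] = cohort.index.map(flag.to_dict()).astype("object")
    return cohort
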