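"""Readers and writers for the package's tabular formats.

All coordinates are 1-based inclusive internally; BED export converts to
0-based half-open via :func:`to_bed`.  Missing values are written as
``NA``.  Matrices (methylation, proteins) are written feature-by-sample
with a header row of sample ids.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import P_FLOOR
from .types import (
    GenotypeMatrix,
    MethylationMatrix,
    SUMSTATS_COLUMNS,
    TrueArchitecture,
)

#: On-disk header for summary statistics (COJO-style .ma layout).
SUMSTATS_HEADER = ["snp_id", "chr", "pos", "a1", "a2", "freq", "b", "se", "p", "n"]

_MAP_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "maf"]


def write_genotypes(geno: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a dosage TSV (samples x SNPs) plus a sidecar map file."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosage.tsv")
    map_path = prefix.with_suffix(".map.tsv")
    geno.dosages.to_csv(dosage_path, sep="\t", index_label="sample_id", na_rep="NA")
    out_map = geno.snp_map.reset_index(names="snp_id")[_MAP_COLUMNS]
    out_map.to_csv(map_path, sep="\t", index=False, na_rep="NA")
    return dosage_path, map_path


def read_genotypes(
    path: str | Path,
    format: str = "dosage_tsv",
    map_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a dosage TSV + map sidecar, or from a VCF.

    Dosages must lie in [0, 2]; duplicate sample or marker ids are
    rejected.  VCF genotypes are converted to alt-allele dosages with the
    ALT allele as the effect allele.
    """
    if format == "dosage_tsv":
        if map_path is None:
            map_path = Path(path).with_suffix("").with_suffix(".map.tsv")
        try:
            dosages = pd.read_csv(path, sep="\t", index_col="sample_id")
        except (pd.errors.ParserError, ValueError) as err:
            raise ValueError(f"malformed dosage file {path}: {err}") from err
        snp_map = pd.read_csv(map_path, sep="\t").set_index("snp_id")
        snp_map.index.name = "id"
        if not dosages.index.is_unique:
            raise ValueError("duplicate sample ids in dosage file")
        if not dosages.columns.is_unique:
            raise ValueError("duplicate marker ids in dosage file")
        vals = dosages.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
            raise ValueError("dosages outside [0, 2]")
        return GenotypeMatrix(dosages=dosages, snp_map=snp_map)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, map_rows = [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in ids:
            raise ValueError(f"duplicate variant id {vid!r} in VCF")
        ids.append(vid)
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (cyvcf2 numbering: 3 hom-alt)
        dos = np.array([sum(a > 0 for a in g[:2]) for g in var.genotypes], dtype=float)
        rows.append(dos)
        alt = var.ALT[0] if var.ALT else "."
        map_rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": alt,
                "other_allele": var.REF,
                "maf": float(min(dos.mean() / 2.0, 1.0 - dos.mean() / 2.0)),
            }
        )
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    snp_map = pd.DataFrame(map_rows, index=pd.Index(ids, name="id"))
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map)


def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> Path:
    """Write a feature x sample matrix as TSV with a header row of sample ids."""
    path = Path(path)
    values.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA",
                       float_precision="round_trip")


def write_methylation(meth: MethylationMatrix, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    vals = write_matrix(meth.values.T, prefix.with_suffix(".meth.tsv"), index_label="probe_id")
    mp = prefix.with_suffix(".probes.tsv")
    meth.cpg_map.reset_index(names="id")[["id", "chrom", "pos", "probe_id"]].to_csv(
        mp, sep="\t", index=False
    )
    return vals, mp


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> Path:
    """Write summary statistics in the canonical TSV layout.

    Rows are sorted deterministically by (chrom, pos); p-values are
    written in scientific notation at full precision, with exact zeros
    clamped to 1e-320 (warned).
    """
    path = Path(path)
    out = stats.copy()
    missing = [c for c in SUMSTATS_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    out = out[SUMSTATS_COLUMNS]
    if len(out):
        if (out["p"] == 0).any():
            warnings.warn("p-values of 0 clamped to 1e-320", stacklevel=2)
            out.loc[out["p"] == 0, "p"] = P_FLOOR
        out = out.sort_values(["chrom", "pos"], kind="mergesort")
        out["p"] = out["p"].map(lambda v: f"{v:.17e}")
    out.columns = SUMSTATS_HEADER
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_sumstats(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values="NA", float_precision="round_trip")
    if list(frame.columns) != SUMSTATS_HEADER:
        raise ValueError(f"unexpected summary-statistics header in {path}")
    frame.columns = SUMSTATS_COLUMNS
    return frame


def write_architecture(arch: TrueArchitecture, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(arch.to_json())
    return path


def read_architecture(path: str | Path) -> TrueArchitecture:
    return TrueArchitecture.from_json(Path(path).read_text())


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, gene ids, tab-separated)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: need name, description, >=1 gene")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive (chrom, start, end) to BED 0-based half-open."""
    out = regions.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    path: str | Path,
    config: dict,
    seeds: dict[str, int],
    inputs: list[str | Path] | None = None,
) -> Path:
    """Persist a reproducibility record: config hash, seeds, input checksums."""
    from importlib.metadata import version, PackageNotFoundError

    try:
        pkg_version = version("protqtl")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        pkg_version = "unknown"
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "package_version": pkg_version,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds,
        "inputs": {str(p): _sha256(p) for p in (inputs or [])},
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
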