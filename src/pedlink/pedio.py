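"""Readers and writers for the pipeline's file formats.

Formats supported:

* LINKAGE-style PED text: ``family id father mother sex affection a1 b1
  a2 b2 ...`` with ``0`` for missing parents/genotypes, sex 1=male
  2=female 0=unknown, affection 2=affected and 1/0=unknown (unaffecteds
  are scored phenotype-unknown). A half-missing genotype ("0 3") is
  treated as fully missing, with a logged warning.
* Marker map TSV: locus, chromosome, cM, bp, comma-separated allele
  frequencies.
* Variant tables as TSV or VCF (v4.x via pysam); for VCF, the effect
  class, gene, depth and qualities come from configurable INFO keys.
* Genotype-count tables and association reports as TSV/JSON, with the
  fixed 2-decimal, half-up float rendering used in published association
  tables.

Every CLI run writes a provenance record (config hash, seed, package
version) sufficient to reproduce deterministic outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from .types import (AssociationResult, GenotypeCountTable, GenotypeMatrix,
                    Individual, Locus, MarkerMap, Pedigree, VariantRecord,
                    logger, validate_pedigree)

__all__ = [
    "read_ped", "write_ped", "read_map", "write_map", "read_variant_table",
    "write_variant_tsv", "read_counts", "write_counts", "fmt2",
    "association_frame", "write_report", "RunConfig", "load_config",
    "write_provenance", "DEFAULT_INFO_KEYS",
]

DEFAULT_INFO_KEYS = {"gene": "GENE", "effect": "EFF", "depth": "DP",
                     "consensus_quality": "CQ", "mapping_quality": "MQ",
                     "known": "KNOWN"}

_SEX_IN = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFF_IN = {"2": "affected", "1": "unknown", "0": "unknown"}


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path, locus_ids: list[str] | None = None,
             marker_map: MarkerMap | None = None,
             ) -> tuple[list[Pedigree], GenotypeMatrix]:
    """Parse a LINKAGE-style PED file.

    ``locus_ids`` names the genotype columns in order (defaults to the
    marker map's loci when given, else M1..Mk). Pedigrees are validated;
    invariant violations raise. Genotype 0 codes missing; a half-missing
    pair is coerced to missing with a warning.
    """
    if locus_ids is None and marker_map is not None:
        locus_ids = [loc.id for loc in marker_map.loci]
    families: dict[str, dict[str, Individual]] = {}
    gm = GenotypeMatrix()
    n_loci = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
                raise ValueError(
                    f"{path}:{ln}: malformed PED line "
                    f"({len(parts)} fields)")
            fam, iid, fa, mo, sex, aff = parts[:6]
            pairs = parts[6:]
            if n_loci is None:
                n_loci = len(pairs) // 2
                if locus_ids is None:
                    locus_ids = [f"M{i + 1}" for i in range(n_loci)]
            if len(pairs) != 2 * len(locus_ids):
                raise ValueError(
                    f"{path}:{ln}: expected {2 * len(locus_ids)} allele "
                    f"fields, got {len(pairs)}")
            if sex not in _SEX_IN:
                raise ValueError(f"{path}:{ln}: bad sex code {sex!r}")
            if aff not in _AFF_IN:
                raise ValueError(f"{path}:{ln}: bad affection code {aff!r}")
            ind = Individual(iid, None if fa == "0" else fa,
                             None if mo == "0" else mo,
                             _SEX_IN[sex], _AFF_IN[aff])
            families.setdefault(fam, {})[iid] = ind
            for j, lid in enumerate(locus_ids):
                try:
                    a, b = int(pairs[2 * j]), int(pairs[2 * j + 1])
                except ValueError as e:
                    raise ValueError(
                        f"{path}:{ln}: non-integer allele at locus "
                        f"{lid}") from e
                if (a == 0) != (b == 0):
                    logger.warning(
                        "%s:%d: half-missing genotype at %s treated as "
                        "missing", path, ln, lid)
                    a = b = 0
                if a != 0:
                    if marker_map is not None:
                        k = marker_map[lid].n_alleles
                        if not (1 <= a <= k and 1 <= b <= k):
                            raise ValueError(
                                f"{path}:{ln}: allele outside 1..{k} at "
                                f"locus {lid}")
                    gm.set(iid, lid, (a, b))
    peds = []
    for fam, members in families.items():
        ped = Pedigree(fam, members)
        violations = validate_pedigree(ped)
        if violations:
            raise ValueError(
                f"{path}: invalid pedigree {fam}: " + "; ".join(violations))
        peds.append(ped)
    return peds, gm


def write_ped(peds: list[Pedigree], gm: GenotypeMatrix,
              locus_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        for ped in peds:
            for ind in ped.topological_order():
                row = [ped.family_id, ind.id, ind.father_id or "0",
                       ind.mother_id or "0", _SEX_OUT[ind.sex],
                       "2" if ind.affection == "affected" else "0"]
                for lid in locus_ids:
                    g = gm.get(ind.id, lid)
                    row.extend(("0", "0") if g is None
                               else (str(g[0]), str(g[1])))
                fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

def read_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    needed = {"locus", "chromosome", "position_cM", "allele_freqs"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing map columns {sorted(missing)}")
    loci = []
    for _, row in df.iterrows():
        freqs = tuple(float(x) for x in str(row["allele_freqs"]).split(","))
        bp = None
        if "position_bp" in df.columns and pd.notna(row["position_bp"]):
            bp = int(row["position_bp"])
        loci.append(Locus(str(row["locus"]), str(row["chromosome"]),
                          float(row["position_cM"]), freqs, bp))
    return MarkerMap(loci)


def write_map(marker_map: MarkerMap, path) -> None:
    rows = [{"locus": l.id, "chromosome": l.chromosome,
             "position_cM": l.position_cM,
             "position_bp": l.position_bp if l.position_bp is not None
             else "",
             "allele_freqs": ",".join(repr(f) for f in l.allele_freqs)}
            for l in marker_map.loci]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_TSV_COLS = ["variant_id", "chromosome", "position_bp", "ref", "alt",
             "gene", "effect_class", "depth", "consensus_quality",
             "mapping_quality", "known_ids", "genotype"]


def read_variant_table(path, format: str = "tsv",
                       info_keys: dict[str, str] | None = None,
                       ) -> list[VariantRecord]:
    """Load one case's (or control's) annotated variants.

    ``format='tsv'`` expects the columns variant_id, chromosome,
    position_bp, ref, alt, gene, effect_class, depth, consensus_quality,
    mapping_quality, known_ids ('.' or comma-separated catalog names) and
    genotype. ``format='vcf'`` reads annotations from the INFO keys named
    by ``info_keys`` (defaults: GENE, EFF, DP, CQ, MQ, KNOWN); unknown
    effect strings map to 'other'.
    """
    if format == "tsv":
        return _read_variant_tsv(path)
    if format == "vcf":
        return _read_variant_vcf(path, {**DEFAULT_INFO_KEYS,
                                        **(info_keys or {})})
    raise ValueError(f"unknown variant-table format {format!r}")


def _effect(value: str) -> str:
    return value if value in {"MS", "NS", "SS", "Indel"} else "other"


def _read_variant_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(_TSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing variant columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        for col in ("depth", "consensus_quality", "mapping_quality",
                    "position_bp"):
            if pd.isna(row[col]):
                raise ValueError(f"{path}: row {i + 2}: missing {col}")
        known = frozenset() if str(row["known_ids"]) in {".", "nan", ""} \
            else frozenset(str(row["known_ids"]).split(","))
        records.append(VariantRecord(
            str(row["variant_id"]), str(row["chromosome"]),
            int(row["position_bp"]), str(row["ref"]), str(row["alt"]),
            str(row["gene"]), _effect(str(row["effect_class"])),
            int(row["depth"]), float(row["consensus_quality"]),
            float(row["mapping_quality"]), known, str(row["genotype"])))
    return records


def _read_variant_vcf(path, keys: dict[str, str]) -> list[VariantRecord]:
    import pysam
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            info = dict(rec.info)
            for field_name in ("depth", "consensus_quality",
                              "mapping_quality", "gene", "effect"):
                if keys[field_name] not in info:
                    raise ValueError(
                        f"{path}: record {i + 1} ({rec.chrom}:{rec.pos}): "
                        f"missing INFO key {keys[field_name]!r}")
            known_raw = info.get(keys["known"], ())
            if isinstance(known_raw, str):
                known_raw = (known_raw,)
            known = frozenset(k for k in known_raw if k and k != ".")
            genotype = "het"
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt and all(a == 1 for a in gt if a is not None):
                    genotype = "hom_alt"
            records.append(VariantRecord(
                rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos,
                rec.ref, rec.alts[0],
                str(info[keys["gene"]]), _effect(str(info[keys["effect"]])),
                int(info[keys["depth"]]),
                float(info[keys["consensus_quality"]]),
                float(info[keys["mapping_quality"]]), known, genotype))
    return records


def write_variant_tsv(records: list[VariantRecord], path) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        d["known_ids"] = ",".join(sorted(r.known_ids)) or "."
        rows.append(d)
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t",
                                                 index=False)


# ---------------------------------------------------------------------------
# Counts and association reports
# ---------------------------------------------------------------------------

_COUNT_COLS = ["stratum", "case_DD", "case_Dd", "case_dd",
               "control_DD", "control_Dd", "control_dd"]


def write_counts(tables: list[GenotypeCountTable], path) -> None:
    pd.DataFrame([asdict(t) for t in tables],
                 columns=_COUNT_COLS).to_csv(path, sep="\t", index=False)


def read_counts(path) -> list[GenotypeCountTable]:
    df = pd.read_csv(path, sep="\t", dtype={"stratum": str})
    missing = set(_COUNT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing count columns {sorted(missing)}")
    return [GenotypeCountTable(str(r["stratum"]), int(r["case_DD"]),
                               int(r["case_Dd"]), int(r["case_dd"]),
                               int(r["control_DD"]), int(r["control_Dd"]),
                               int(r["control_dd"]))
            for _, r in df.iterrows()]


def fmt2(x: float) -> str:
    """Fixed 2-decimal rendering with half-up rounding (the convention of
    published association tables, where e.g. 135.625 prints as 135.63)."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                rounding=ROUND_HALF_UP))


def association_frame(report: dict[str, dict[str, AssociationResult]]
                      ) -> pd.DataFrame:
    """Render {stratum: {model: result}} as a flat table with the fixed
    precision of the report writer (OR/CI/MAF/HWE p/-log10 p to 2
    decimals)."""
    rows = []
    for stratum, by_model in report.items():
        for model, r in by_model.items():
            rows.append({
                "stratum": stratum, "model": model,
                "neglog10_p": fmt2(r.neglog10_p),
                "odds_ratio": fmt2(r.odds_ratio),
                "ci_low": fmt2(r.ci_low), "ci_high": fmt2(r.ci_high),
                "maf_cases": fmt2(r.maf_cases),
                "maf_controls": fmt2(r.maf_controls),
                "hwe_p_cases": fmt2(r.hwe_p_cases),
                "hwe_p_controls": fmt2(r.hwe_p_controls),
                "corrected": r.corrected})
    return pd.DataFrame(rows)


def write_report(results, path, format: str = "tsv") -> None:
    """Write a report table (DataFrame or list of dicts) as TSV or JSON
    with a deterministic column order."""
    df = results if isinstance(results, pd.DataFrame) \
        else pd.DataFrame(list(results))
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(
            json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


# ---------------------------------------------------------------------------
# Config and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands."""

    disease_allele_freq: float = 0.00002
    phenocopy: float = 0.000001
    penetrance_het: float = 1.0
    penetrance_hom: float = 1.0
    ped_path: str | None = None
    map_path: str | None = None
    variant_paths: list[str] = field(default_factory=list)
    control_paths: list[str] = field(default_factory=list)
    known_catalogs: list[str] = field(default_factory=lambda: ["dbSNP131"])
    depth_min: int = 8
    consensus_quality_min: float = 30.0
    mapping_quality_min: float = 20.0
    sharing_k: int = 8
    locus: str | None = None              # "chr:start-end"
    n_reps: int = 10000
    seed: int = 0
    out_dir: str = "."


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    unknown = set(data) - set(RunConfig().__dict__)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def write_provenance(out_dir, config: RunConfig | dict, seed: int) -> Path:
    from . import __version__
    cfg = asdict(config) if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    record = {"config_hash": hashlib.sha256(blob).hexdigest(),
              "seed": int(seed), "version": __version__,
              "config": cfg}
    out = Path(out_dir) / "provenance.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return out
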