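"""Readers/writers for every external format, config, and reproducibility.

Formats: VCF (genotypes, GT), BED12 (transcript models with CDS thick
coordinates), bedGraph (0-based half-open per-base coverage), TSV summary
statistics (SNP, A1, A2, Z, N), and the open two-file weight format (TSV of
per-variant weights + JSON sidecar of model metadata).

Reproducibility contract: every stochastic stage receives a seed derived
deterministically from the master seed by stable hashing of
``(master_seed, stage_name)``; every output table carries provenance
comment headers (config hash, seed, stage version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, Variant
from .twas import WeightModel

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "derive_seed",
    "provenance_header",
    "read_bed12",
    "write_bed12",
    "read_bedgraph",
    "write_bedgraph",
    "write_vcf",
    "read_vcf_dosage",
    "read_sumstats",
    "write_sumstats",
    "write_weight_model",
    "read_weight_model",
    "write_table",
    "read_table",
]

WEIGHT_SCHEMA_VERSION = "1"
BED12_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]
AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Flat, serializable run configuration (key=value file mirror)."""

    seed: int = 0
    window: int = 1_000_000
    n_permutations: int = 1000
    twas_permutations: int = 100_000
    min_seg: int = 100
    step: int = 1
    min_mean_cov: float = 20.0
    min_sample_fraction: float = 0.5
    genotype_pcs: int = 5
    peer_k: int = -1  # -1: pick from the cohort-size ladder
    maf_min: float = 0.01
    h2_gate: float = 0.05
    shrinkage: float = 0.1
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_w: float = 0.15
    pp4_threshold: float = 0.5

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(vars(self).items()):
                fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        kwargs = {}
        types = {f: t for f, t in cls.__annotations__.items()}
        defaults = cls()
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = type(getattr(defaults, key))(value)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def provenance_header(stage: str, config: RunConfig | None = None, seed: int | None = None) -> str:
    from . import __version__

    parts = [f"stage={stage}", f"apatwas={__version__}", f"numpy={np.__version__}", f"pandas={pd.__version__}"]
    if config is not None:
        parts.append(f"config_hash={config.config_hash()}")
        if seed is None:
            seed = config.stage_seed(stage)
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def write_table(df: pd.DataFrame, path: str, stage: str, config: RunConfig | None = None,
                seed: int | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kwargs)


# ---------------------------------------------------------------- BED12

def read_bed12(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 12:
        raise ValueError(f"{path}: BED12 requires 12 columns, found {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BED12_COLUMNS
    return df


def write_bed12(df: pd.DataFrame, path: str) -> None:
    df[BED12_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# -------------------------------------------------------------- bedGraph

def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    return df


def write_bedgraph(profile_segments: pd.DataFrame, path: str, header: str | None = None) -> None:
    """Write (chrom, start, end, value) rows; 0-based half-open."""
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        profile_segments.to_csv(fh, sep="\t", header=False, index=False)


def coverage_to_segments(chrom: str, start: int, values: np.ndarray, strand: str = "+") -> pd.DataFrame:
    """Run-length encode a transcript-oriented profile to genomic bedGraph rows."""
    genomic = values[::-1] if strand == "-" else values
    rows = []
    run_start = 0
    for i in range(1, len(genomic) + 1):
        if i == len(genomic) or genomic[i] != genomic[run_start]:
            if genomic[run_start] != 0:
                rows.append((chrom, start + run_start, start + i, float(genomic[run_start])))
            run_start = i
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ------------------------------------------------------------------ VCF

def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write diploid genotypes as an uncompressed VCF with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if G.seed is not None:
            fh.write(f"##apatwas_seed={G.seed}\n")
        chroms = sorted(set(v.chrom for v in G.variants))
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.sample_ids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in enumerate(G.variants):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in G.dosages[:, j]
            ]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf_dosage(
    path: str,
    region: str | None = None,
    maf_min: float = 0.01,
    drop_indels: bool = True,
    drop_ambiguous: bool = True,
) -> GenotypeMatrix:
    """Read alt-allele dosages from a VCF (GT field) with the standard
    variant filters.

    Filters (with per-filter removal counts logged): multi-allelic records,
    indels, strand-ambiguous A/T and C/G SNPs, and empirical minor-allele
    frequency at or below ``maf_min``.  ``region`` is an optional
    ``chrom[:start-end]`` streaming filter (1-based inclusive).
    """
    from cyvcf2 import VCF

    want_chrom = want_lo = want_hi = None
    if region:
        chrom_part, _, span = region.partition(":")
        want_chrom = chrom_part
        if span:
            lo, _, hi = span.partition("-")
            want_lo, want_hi = int(lo), int(hi)

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    variants: list[Variant] = []
    counts = {"multiallelic": 0, "indel": 0, "ambiguous": 0, "maf": 0, "monomorphic": 0}
    for rec in vcf:
        if want_chrom is not None and rec.CHROM != want_chrom:
            continue
        if want_lo is not None and not (want_lo <= rec.POS <= want_hi):
            continue
        if len(rec.ALT) != 1:
            counts["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if drop_indels and (len(ref) != 1 or len(alt) != 1):
            counts["indel"] += 1
            continue
        if drop_ambiguous and frozenset((ref, alt)) in AMBIGUOUS:
            counts["ambiguous"] += 1
            continue
        gts = np.asarray(rec.genotypes, dtype=object)
        alleles = np.array([[a, b] for a, b, *_ in gts], dtype=float)
        missing = (alleles < 0).any(axis=1)
        dosage = alleles.sum(axis=1)
        dosage[missing] = np.nan
        af = np.nanmean(dosage) / 2.0
        if np.isnan(af) or af in (0.0, 1.0):
            counts["monomorphic"] += 1
            continue
        if min(af, 1 - af) <= maf_min:
            counts["maf"] += 1
            continue
        rows.append(dosage)
        variants.append(
            Variant(chrom=rec.CHROM, pos=rec.POS, id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    ref=ref, alt=alt, maf=float(min(af, 1 - af)))
        )
    logger.info("read %d variants from %s; removed %s", len(variants), path, counts)
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=samples)


# ------------------------------------------------------------- sumstats

SUMSTAT_ALIASES = {
    "snp": ["snp", "rsid", "id", "variant_id"],
    "a1": ["a1", "effect_allele", "alt"],
    "a2": ["a2", "other_allele", "ref"],
    "z": ["z", "zscore"],
    "beta": ["beta", "b", "effect"],
    "se": ["se", "standard_error"],
    "n": ["n", "sample_size"],
}


def read_sumstats(path: str, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read GWAS summary statistics into the canonical (snp, a1, a2, z, n)
    schema.

    z is computed as beta/se when absent.  Column names are matched
    case-insensitively against common aliases, overridable by
    ``column_map`` (canonical -> actual).  Duplicate SNP ids raise (the id
    is the join key for harmonization); missing required columns raise
    naming them.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, aliases in SUMSTAT_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] in df.columns:
                resolved[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in ("snp", "a1", "a2") if c not in resolved]
    if "z" not in resolved and not ("beta" in resolved and "se" in resolved):
        missing.append("z (or beta+se)")
    if missing:
        raise ValueError(f"{path}: missing required sumstat columns: {missing}")

    out = pd.DataFrame({"snp": df[resolved["snp"]].astype(str)})
    out["a1"] = df[resolved["a1"]].astype(str).str.upper()
    out["a2"] = df[resolved["a2"]].astype(str).str.upper()
    if "z" in resolved:
        out["z"] = pd.to_numeric(df[resolved["z"]])
    else:
        out["z"] = pd.to_numeric(df[resolved["beta"]]) / pd.to_numeric(df[resolved["se"]])
    out["n"] = pd.to_numeric(df[resolved["n"]]) if "n" in resolved else np.nan
    if out["snp"].duplicated().any():
        dups = out.loc[out["snp"].duplicated(), "snp"].unique()[:5]
        raise ValueError(f"duplicate SNP ids in {path} (ambiguous join key): {list(dups)}")
    if out.empty:
        logger.warning("%s contains a header but no rows", path)
    bad = ~np.isfinite(out["z"])
    if bad.any():
        logger.info("dropping %d rows with non-finite z", int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    return out


def write_sumstats(df: pd.DataFrame, path: str, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.rename(columns={"snp": "SNP", "a1": "A1", "a2": "A2", "z": "Z", "n": "N"}).to_csv(
            fh, sep="\t", index=False
        )


# -------------------------------------------------------- weight models

def write_weight_model(model: WeightModel, prefix: str) -> None:
    """Open two-file weight format: <prefix>.weights.tsv + <prefix>.json."""
    rows = []
    for j, v in enumerate(model.variants):
        row = {"variant_id": v.id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
        for method, w in model.weights.items():
            row[f"w_{method}"] = repr(float(w[j]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(prefix + ".weights.tsv", sep="\t", index=False)
    meta = {
        "schema_version": WEIGHT_SCHEMA_VERSION,
        "transcript_id": model.transcript_id,
        "h2": model.h2,
        "h2_p": model.h2_p,
        "cv_r2": model.cv_r2,
        "selected": model.selected,
        "n_train": model.n_train,
        "seed": model.seed,
        "panel_id": model.panel_id,
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_weight_model(prefix: str) -> WeightModel:
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != WEIGHT_SCHEMA_VERSION:
        raise ValueError(
            f"weight schema version mismatch: expected {WEIGHT_SCHEMA_VERSION}, "
            f"found {meta.get('schema_version')}"
        )
    df = pd.read_csv(prefix + ".weights.tsv", sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"weight file missing columns: {sorted(required - set(df.columns))}")
    methods = [c[2:] for c in df.columns if c.startswith("w_")]
    variants = [
        Variant(chrom=str(r.chrom), pos=int(r.pos), id=str(r.variant_id),
                ref=str(r.ref), alt=str(r.alt), maf=float("nan"))
        for r in df.itertuples(index=False)
    ]
    weights = {m: df[f"w_{m}"].to_numpy(dtype=float) for m in methods}
    return WeightModel(
        transcript_id=meta["transcript_id"],
        variants=variants,
        weights=weights,
        cv_r2={k: float(v) for k, v in meta["cv_r2"].items()},
        selected=meta["selected"],
        h2=float(meta["h2"]),
        h2_p=float(meta["h2_p"]),
        n_train=int(meta["n_train"]),
        seed=int(meta["seed"]),
        panel_id=meta.get("panel_id", "panel"),
    )
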