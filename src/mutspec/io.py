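"""Readers and writers for the pipeline's on-disk formats.

Formats: pileup/co-occurrence/metadata/spectrum TSVs, BED masks (0-based
half-open), VCF 4.2 with GT fields (via cyvcf2), amplicon maps as YAML +
FASTA, JSON run reports embedding the resolved configuration and seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, PanelData, StrainMeta
from .pool import AmpliconMap, CooccurrenceRecord, MutationCall, PileupSite

logger = logging.getLogger("mutspec")

__all__ = [
    "RunConfig",
    "load_run_config",
    "load_pileup",
    "load_cooccurrence",
    "load_mutant_counts",
    "load_bed",
    "load_amplicon_map",
    "load_variants",
    "write_calls_tsv",
    "write_report",
]

PILEUP_COLUMNS = ["pos", "ref", "depth", "A", "C", "G", "T", "ins", "del"]


@dataclass
class RunConfig:
    """Resolved run configuration; unknown keys are rejected on load."""

    seed: int = 0
    n_mutants: int | None = None
    B: int = 10_000
    n_tests: int = 1
    efficiency: float = 1.0
    max_missing: float = 0.20
    max_daf: float = 0.5
    relative_distance: float = 8000
    population_cap: int = 30
    min_variants: int = 8
    top_fraction: float = 0.05
    verbosity: str = "INFO"
    pool: dict = field(default_factory=dict)  # PoolConfig overrides

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not (0 < self.efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")
        for name in ("max_missing", "max_daf", "top_fraction"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} out of range")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def load_pileup(path) -> list[PileupSite]:
    """Read a pileup TSV (pos, ref, depth, A, C, G, T, ins, del)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty pileup file: {path}")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup missing columns: {sorted(missing)}")
    if not df["pos"].is_monotonic_increasing:
        warnings.warn("pileup not position-sorted; sorting")
        df = df.sort_values("pos")
    df = df.rename(columns={"del": "dels"})
    sites = []
    for row in df.itertuples(index=False):
        counts = {b: int(getattr(row, b)) for b in "ACGT"}
        if sum(counts.values()) > row.depth:
            raise ValueError(f"pileup row at pos {row.pos}: allele counts exceed depth")
        sites.append(PileupSite(pos=int(row.pos), ref=str(row.ref),
                                depth=int(row.depth), counts=counts,
                                ins=int(row.ins), dels=int(row.dels)))
    return sites


def load_cooccurrence(path) -> list[CooccurrenceRecord]:
    df = pd.read_csv(path, sep="\t")
    return [CooccurrenceRecord(pos_i=int(r.pos_i), alt_i=str(r.alt_i),
                               pos_j=int(r.pos_j), alt_j=str(r.alt_j),
                               reads_both=int(r.reads_both),
                               reads_any=int(r.reads_any))
            for r in df.itertuples(index=False)]


def write_pileup_tsv(sites: list[PileupSite], path) -> None:
    rows = []
    for s in sites:
        row = {"pos": s.pos, "ref": s.ref, "depth": s.depth}
        for b in "ACGT":
            row[b] = s.counts.get(b, 0)
        row["ins"], row["del"] = s.ins, s.dels
        rows.append(row)
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cooccurrence_tsv(records: list[CooccurrenceRecord], path) -> None:
    pd.DataFrame([{"pos_i": r.pos_i, "alt_i": r.alt_i, "pos_j": r.pos_j,
                   "alt_j": r.alt_j, "reads_both": r.reads_both,
                   "reads_any": r.reads_any} for r in records]
                 ).to_csv(path, sep="\t", index=False)


def load_mutant_counts(path) -> tuple[list[str], list[int]]:
    """Read a (culture_id, mutant_count) TSV for one fluctuation assay."""
    df = pd.read_csv(path, sep="\t")
    return df["culture_id"].astype(str).tolist(), df["mutant_count"].astype(int).tolist()


def load_bed(path) -> pd.DataFrame:
    """Read a BED file into (chrom, start, end); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
        raise ValueError("malformed BED interval: end <= start")
    return df


def load_amplicon_map(yaml_path) -> AmpliconMap:
    with open(yaml_path) as fh:
        d = yaml.safe_load(fh)
    return AmpliconMap(chrom=d["chrom"], genome_start=int(d["genome_start"]),
                       amplicon_length=int(d["amplicon_length"]),
                       orf_strand=d.get("orf_strand", "+"),
                       cds_start=int(d.get("cds_start", 1)),
                       cds_end=int(d["cds_end"]) if "cds_end" in d else None)


def write_amplicon_map(amap: AmpliconMap, yaml_path) -> None:
    with open(yaml_path, "w") as fh:
        yaml.safe_dump({"chrom": amap.chrom, "genome_start": amap.genome_start,
                        "amplicon_length": amap.amplicon_length,
                        "orf_strand": amap.orf_strand,
                        "cds_start": amap.cds_start, "cds_end": amap.cds_end}, fh)


def load_variants(vcf_path, metadata_path, mappable_bed=None,
                  repeat_bed=None) -> tuple[PanelData, dict]:
    """Load a multi-sample VCF + strain metadata into a :class:`PanelData`.

    Multiallelic and non-SNP records are dropped with a logged count.
    Sample names must match the metadata ``name`` column exactly.
    Returns (panel, stats) where stats counts exclusions.
    """
    from cyvcf2 import VCF

    meta = pd.read_csv(metadata_path, sep="\t")
    strains = [StrainMeta(name=str(r["name"]), clade=str(r.get("clade", "")),
                          ploidy=int(r.get("ploidy", 1)),
                          zygosity=str(r.get("zygosity", "haploid")),
                          include=bool(r.get("include", True)))
               for _, r in meta.iterrows()]
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    expected = [s.name for s in strains]
    if set(samples) != set(expected):
        offenders = sorted(set(samples) ^ set(expected))
        raise ValueError(f"sample-name mismatch between VCF and metadata: {offenders}")
    order = [samples.index(n) for n in expected]

    rows, genos = [], []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        g = np.asarray(rec.gt_types)[order].astype(np.int8)  # 0,1,2; 3=missing
        g[g == 3] = MISSING
        rows.append({"chrom": rec.CHROM, "pos": rec.POS,
                     "ref": rec.REF, "alt": rec.ALT[0]})
        genos.append(g)
    if n_multiallelic:
        logger.info("dropped %d multiallelic records", n_multiallelic)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = (np.vstack(genos) if genos
                 else np.zeros((0, len(strains)), dtype=np.int8))
    panel = PanelData(variants=variants, genotypes=genotypes, strains=strains)
    stats = {"n_loaded": len(rows), "n_multiallelic_dropped": n_multiallelic}
    return panel, stats


def write_calls_tsv(calls: list[MutationCall], path) -> None:
    rows = [{"amplicon_pos": c.amplicon_pos, "genome_chrom": c.genome_chrom or "",
             "genome_pos": c.genome_pos if c.genome_pos is not None else "",
             "ref": c.ref, "alt": c.alt, "kind": c.kind, "length": c.length,
             "frequency": f"{c.frequency:.6g}", "multiplicity": c.multiplicity,
             "consequence": c.consequence or "", "in_mnm": int(c.in_mnm)}
            for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(results: dict, path, config: RunConfig | None = None) -> None:
    """Write a JSON report embedding the schema version and resolved config."""
    payload = {"schema_version": 1,
               "config": asdict(config) if config else None,
               "results": results}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
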