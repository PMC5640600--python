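"""File formats, pipeline configuration and the end-to-end run.

Formats handled here, all plain text:

* summary-statistics TSV — columns ``snp_id chrom pos allele1 allele2 beta
  se p``, written bit-stably (full float repr); the reader is tolerant of
  the common association-output dialect: any whitespace delimiter,
  case-insensitive aliases (SNP/rsid, A1/A2, BP, PVAL, ...), and an ``OR``
  column converted to the log scale when no beta column is present;
* minimal VCF v4.2 with GT fields (REF = allele 2, ALT = allele 1, so ALT
  dosage counts allele 1) read back via cyvcf2;
* dosage TSV (rows = individuals, columns = SNP ids) and two-column
  phenotype TSVs;
* JSON results and manifest, YAML pipeline config.

Readers validate and reject rather than coerce: out-of-range p-values,
missing genotypes and multi-allelic sites are hard errors with the
offending row/site named.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationRecord,
    PairedRegionScan,
    disease_scan,
    eqtl_scan,
    harmonize,
)
from .dec import DECConfig, DECResult, PenaltyParams, SignedPointSet, compute_dec, signed_points, filter_informative
from .null import NullConfig, NullDistribution, dec_significance
from .simulate import RegionDataset, SimulationConfig, generate_dataset

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "read_phenotype",
    "write_phenotype",
    "write_dataset",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_CHROM = "11"  # the synthetic region mimics an 11q13-style window

_COLUMN_ALIASES: Dict[str, Tuple[str, ...]] = {
    "snp_id": ("snp_id", "snp", "id", "rsid", "markername", "marker"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "position", "bp", "base_pair_location"),
    "allele1": ("allele1", "a1", "effect_allele", "ea"),
    "allele2": ("allele2", "a2", "other_allele", "oa", "nea"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "or": ("or", "odds_ratio"),
    "se": ("se", "stderr", "standard_error"),
    "p": ("p", "pval", "p_value", "pvalue", "p_val"),
}
_REQUIRED = ("snp_id", "allele1", "allele2", "p")


def _resolve_columns(columns: Sequence[str]) -> Dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: Dict[str, str] = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_summary_stats(path: Union[str, Path]) -> List[AssociationRecord]:
    """Read one scan's summary statistics from a (whitespace-)delimited table.

    Column names are matched case-insensitively against an alias table; an
    odds-ratio column is converted to beta = log(OR) (logged) when no beta
    column exists. Rows failing validation (p outside (0, 1], non-positive
    OR, missing values) are rejected with their line numbers.
    """
    path = Path(path)
    # dtype=str + Python float() keeps read-back bit-exact; the sniffing
    # python engine would otherwise truncate float precision
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = _resolve_columns(df.columns)
    missing = [c for c in _REQUIRED if c not in cols]
    if "beta" not in cols and "or" not in cols:
        missing.append("beta")
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; aliases tried: "
            + "; ".join(f"{c}: {_COLUMN_ALIASES[c]}" for c in missing)
        )

    use_or = "beta" not in cols
    if use_or:
        logger.info("%s: no beta column; converting OR to log scale", path)

    records: List[AssociationRecord] = []
    bad: List[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        r = dict(zip(df.columns, row))
        try:
            p = float(r[cols["p"]])
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p={p} outside (0, 1]")
            if use_or:
                odds = float(r[cols["or"]])
                if odds <= 0:
                    raise ValueError(f"OR={odds} must be positive")
                beta = float(np.log(odds))
            else:
                beta = float(r[cols["beta"]])
            se = float(r[cols["se"]]) if "se" in cols else float("nan")
            pos = int(r[cols["pos"]]) if "pos" in cols else 0
            records.append(
                AssociationRecord(
                    snp_id=str(r[cols["snp_id"]]),
                    position=pos,
                    allele1=str(r[cols["allele1"]]),
                    allele2=str(r[cols["allele2"]]),
                    beta=beta,
                    se=se,
                    p=p,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise ValueError(f"{path}: {len(bad)} invalid row(s):\n" + "\n".join(bad))
    return records


def write_summary_stats(
    records: Sequence[AssociationRecord],
    path: Union[str, Path],
    chrom: str = DEFAULT_CHROM,
) -> None:
    """Write a scan as TSV; floats use full repr so read-back is exact."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tallele1\tallele2\tbeta\tse\tp\n")
        for r in records:
            fh.write(
                f"{r.snp_id}\t{chrom}\t{r.position}\t{r.allele1}\t{r.allele2}"
                f"\t{r.beta!r}\t{r.se!r}\t{r.p!r}\n"
            )


def write_vcf(
    data: RegionDataset, path: Union[str, Path], chrom: str = DEFAULT_CHROM
) -> None:
    """Write genotypes as minimal VCF v4.2 (REF = allele2, ALT = allele1)."""
    dose_to_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=decstat {__version__}\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.sample_ids)
            + "\n"
        )
        for j in range(data.n_snps):
            gts = "\t".join(dose_to_gt[int(d)] for d in data.dosages[:, j])
            fh.write(
                f"{chrom}\t{int(data.positions[j])}\t{data.snp_ids[j]}\t"
                f"{data.allele2[j]}\t{data.allele1[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_vcf(path: Path) -> RegionDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, positions, a1, a2, columns = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic site {v.ID or v.POS} (ALT={v.ALT}) not supported"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt; dosage counts ALT
        gt = v.gt_types
        if (gt == 2).any():
            who = [samples[i] for i in np.nonzero(gt == 2)[0]]
            raise ValueError(
                f"{path}: missing genotype at site {v.ID or v.POS} for "
                f"sample(s) {', '.join(who)}; no imputation is performed"
            )
        snp_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        positions.append(v.POS)
        a1.append(v.ALT[0])
        a2.append(v.REF)
        columns.append(np.where(gt == 3, 2, gt).astype(np.int8))
    if not snp_ids:
        raise ValueError(f"{path}: no variants found")
    return RegionDataset(
        sample_ids=samples,
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=np.int64),
        allele1=np.asarray(a1),
        allele2=np.asarray(a2),
        dosages=np.column_stack(columns),
    )


def _read_dosage_tsv(path: Path) -> RegionDataset:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy()
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError(f"{path}: dosages must be 0, 1 or 2 with no missing values")
    m = df.shape[1]
    # a bare dosage matrix carries no SNP metadata: positions and alleles
    # are placeholders (documented), sufficient for scans but not for
    # allele-aware export
    return RegionDataset(
        sample_ids=[str(s) for s in df.index],
        snp_ids=[str(c) for c in df.columns],
        positions=np.arange(1, m + 1, dtype=np.int64),
        allele1=np.asarray(["A"] * m),
        allele2=np.asarray(["B"] * m),
        dosages=dosages.astype(np.int8),
    )


def read_genotypes(path: Union[str, Path]) -> RegionDataset:
    """Read genotypes from VCF v4.2 (GT fields) or a dosage TSV.

    VCF: ALT maps to allele 1, dosage = ALT-allele count; missing genotypes
    and multi-allelic sites are hard errors. Dosage TSV (rows =
    individuals, columns = SNP ids) carries no positions/alleles, so
    placeholder metadata (positions 1..m, alleles A/B) is attached.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def write_dosage_tsv(data: RegionDataset, path: Union[str, Path]) -> None:
    """Dosage matrix as TSV: rows = individuals, columns = SNP ids."""
    pd.DataFrame(
        data.dosages, index=list(data.sample_ids), columns=list(data.snp_ids)
    ).to_csv(path, sep="\t", index_label="sample_id")


def write_phenotype(
    sample_ids: Sequence[str], values: np.ndarray, path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tvalue\n")
        for s, v in zip(sample_ids, values):
            fh.write(f"{s}\t{float(v)!r}\n" if isinstance(v, (float, np.floating)) else f"{s}\t{v}\n")


def read_phenotype(
    path: Union[str, Path], sample_ids: Sequence[str]
) -> np.ndarray:
    """Read a two-column phenotype TSV aligned to ``sample_ids``.

    Every genotyped sample must be present exactly once; extra or missing
    samples are an error (no silent subsetting).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "value"]:
        raise ValueError(f"{path}: expected columns 'sample_id' and 'value'")
    mapping = dict(zip(df["sample_id"], df["value"]))
    if len(mapping) != len(df):
        raise ValueError(f"{path}: duplicate sample ids")
    missing = [s for s in sample_ids if s not in mapping]
    extra = sorted(set(mapping) - set(map(str, sample_ids)))
    if missing or extra:
        raise ValueError(
            f"{path}: phenotype/genotype sample mismatch "
            f"(missing: {missing[:5]}, extra: {extra[:5]})"
        )
    return np.array([float(mapping[s]) for s in sample_ids])


def write_dataset(data: RegionDataset, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Export a dataset: VCF, dosage TSV, phenotype TSVs, truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "dosages": out / "dosages.tsv",
    }
    write_vcf(data, paths["vcf"])
    write_dosage_tsv(data, paths["dosages"])
    if data.expression is not None:
        paths["expression"] = out / "expression.tsv"
        write_phenotype(data.sample_ids, data.expression, paths["expression"])
    if data.disease is not None:
        paths["disease"] = out / "disease.tsv"
        write_phenotype(data.sample_ids, data.disease.astype(int), paths["disease"])
    if data.truth is not None:
        paths["truth"] = out / "truth.yaml"
        with open(paths["truth"], "w") as fh:
            yaml.safe_dump(dataclasses.asdict(data.truth), fh, sort_keys=True)
    return paths


def write_signed_points(points: SignedPointSet, path: Union[str, Path]) -> None:
    """Export the duplicated signed scatter (two rows per informative SNP)."""
    with open(path, "w") as fh:
        fh.write("snp_id\tref_allele_used\tsigned_log1p_disease\tsigned_log1p_eqtl\n")
        for s, a, u, v in zip(points.snp_ids, points.ref_alleles, points.u, points.v):
            fh.write(f"{s}\t{a}\t{u!r}\t{v!r}\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible run: generation, DEC and null settings.

    Flat-constructible from a YAML/JSON mapping mirroring the CLI flags via
    :meth:`from_mapping`.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dec: DECConfig = field(default_factory=DECConfig)
    null: NullConfig = field(default_factory=NullConfig)

    @classmethod
    def from_mapping(cls, mapping: Dict, seed: Optional[int] = None) -> "PipelineConfig":
        mapping = dict(mapping)
        if seed is not None:
            mapping["seed"] = seed
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        dec_keys = {"informative_threshold", "min_informative", "sigma_scope"}
        pen_keys = {"k1", "k2"}
        null_keys = {"variance_explained_mode", "r2", "n_replicates_per_snp", "estimator"}
        unknown = set(mapping) - sim_keys - dec_keys - pen_keys - null_keys
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim_kwargs = {k: v for k, v in mapping.items() if k in sim_keys}
        if "maf_range" in sim_kwargs:
            sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
        pen = PenaltyParams(**{k: mapping[k] for k in pen_keys if k in mapping})
        dec_kwargs = {k: mapping[k] for k in dec_keys if k in mapping}
        null_kwargs = {k: mapping[k] for k in null_keys if k in mapping}
        if "seed" in mapping:
            null_kwargs["seed"] = mapping["seed"]
        return cls(
            simulation=SimulationConfig(**sim_kwargs),
            dec=DECConfig(penalty=pen, **dec_kwargs),
            null=NullConfig(**null_kwargs),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path], seed: Optional[int] = None) -> "PipelineConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls.from_mapping(mapping, seed=seed)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance of one pipeline run: enough to re-run it bit-identically."""

    version: str
    config: Dict
    seed: int
    started: str
    finished: str = ""
    input_digests: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_pipeline(
    config: PipelineConfig,
    out_dir: Optional[Union[str, Path]] = None,
    data: Optional[RegionDataset] = None,
) -> Tuple[RunManifest, Dict]:
    """Generate (unless ``data`` is given) → scans → harmonize → DEC → null.

    Returns the manifest and a deterministic results dict; when ``out_dir``
    is set, all stage artifacts (dataset files, scan TSVs, signed points,
    results.json, manifest.json, null DEC values) are written there.
    Results contain no timestamps, so identical config + seed gives
    byte-identical results.json; timestamps live in the manifest only.
    """
    manifest = RunManifest(
        version=__version__,
        config=config.to_dict(),
        seed=config.simulation.seed,
        started=_now(),
    )
    if data is None:
        data = generate_dataset(config.simulation)
    scan_e = eqtl_scan(data)
    scan_d = disease_scan(data)
    pair = harmonize(scan_d, scan_e)
    result = compute_dec(pair, config.dec)
    null = dec_significance(
        data, scan_d, scan_e, result, dec_config=config.dec, null_config=config.null
    )
    manifest.counts = {
        "n_individuals": data.n_individuals,
        "n_snps": data.n_snps,
        "n_scanned_eqtl": len(scan_e),
        "n_scanned_disease": len(scan_d),
        "n_harmonized": len(pair),
        "n_flipped": pair.n_flipped,
        "n_dropped": len(pair.dropped_disease) + len(pair.dropped_eqtl),
        "n_informative": result.n_informative,
        "n_simulations": null.n_sims,
    }
    results = {
        "dec": result.to_dict(),
        "null": {
            "observed_dec": null.observed_dec,
            "n_sims": null.n_sims,
            "n_exceed": null.n_exceed,
            "p_empirical": null.p_empirical,
            "r2_used": null.r2_used,
            "seed": null.seed,
        },
        "seed": config.simulation.seed,
    }
    manifest.finished = _now()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = write_dataset(data, out)
        write_summary_stats(scan_e, out / "eqtl_scan.tsv")
        write_summary_stats(scan_d, out / "disease_scan.tsv")
        points = signed_points(filter_informative(pair, config.dec))
        write_signed_points(points, out / "signed_points.tsv")
        with open(out / "null_dec.tsv", "w") as fh:
            fh.write("simulated_dec\n")
            for v in null.simulated_dec:
                fh.write(f"{float(v)!r}\n")
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.input_digests = {str(p.name): sha256_of(p) for p in paths.values()}
        manifest.write(out / "manifest.json")
    return manifest, results
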