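"""Tabular I/O, configuration and the end-to-end pipeline driver.

Canonical tabular dialect: TSV with a header row, UTF-8, ``.`` as the
missing-value marker.  Schema violations raise :class:`TableSchemaError`
naming the offending row and column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import copynumber, heteroplasmy, mtgenome, respirometry, signature

__all__ = [
    "PipelineConfig",
    "TableSchemaError",
    "read_table",
    "write_table",
    "read_state_tables",
    "write_state_tables",
    "read_heteroplasmy_calls",
    "read_qpcr_table",
    "run_pipeline",
]

MISSING = "."


class TableSchemaError(ValueError):
    pass


#: table name -> (required columns, dtypes)
SCHEMAS = {
    "states": (
        ["sample_id", "tissue", "state", "flux"],
        {"flux": float},
    ),
    "hp_calls": (
        ["patient_id", "sample_id", "tissue", "run_id", "pos", "ref", "alt",
         "vaf", "fwd_cov", "rev_cov", "fwd_alt", "rev_alt"],
        {"pos": int, "vaf": float, "fwd_cov": int, "rev_cov": int,
         "fwd_alt": int, "rev_alt": int},
    ),
    "qpcr": (
        ["sample_id", "cq_mt", "cq_n"],
        {"cq_mt": float, "cq_n": float},
    ),
    "survival": (
        ["sample_id", "time", "event"],
        {"time": float, "event": int},
    ),
}


@dataclass
class PipelineConfig:
    """Validated thresholds and protocol metadata for a pipeline run."""

    min_vaf: float = 0.02
    min_strand_cov: int = 10
    detection_strand_cov: int = 5
    strand_tolerance: Optional[float] = None  # None -> adaptive rule
    homoplasmy_cut: float = 0.95
    gm_threshold: float = 0.27
    r_min: float = 0.4
    inner_fraction: float = 0.8
    high_mutpred: float = 0.75
    chamber_volume_mL: float = 2.0
    plateau_window_s: float = 60.0
    qpcr_efficiency_base: float = 2.0
    plasmid_cq_mt: float = 20.0
    plasmid_cq_n: float = 20.0
    significance_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    _BOUNDS = {
        "min_vaf": (0.0, 1.0),
        "homoplasmy_cut": (0.5, 1.0),
        "gm_threshold": (0.0, 1.0),
        "r_min": (0.0, 1.0),
        "inner_fraction": (0.1, 1.0),
        "high_mutpred": (0.0, 1.0),
        "significance_alpha": (0.0, 1.0),
    }

    def __post_init__(self):
        for key, (lo, hi) in self._BOUNDS.items():
            v = getattr(self, key)
            if not (lo < v <= hi):
                raise ValueError(f"config {key}={v} outside ({lo}, {hi}]")
        for key in ("min_strand_cov", "detection_strand_cov"):
            if getattr(self, key) < 0:
                raise ValueError(f"config {key} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise TableSchemaError(f"{path}: empty or missing input file")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING],
                     keep_default_na=False)
    if df.empty:
        raise TableSchemaError(f"{path}: no data rows")
    cols, dtypes = SCHEMAS[schema]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise TableSchemaError(f"{path}: missing columns {missing_cols}")
    for col, typ in dtypes.items():
        for i, raw in enumerate(df[col]):
            if pd.isna(raw):
                continue
            try:
                typ(raw)
            except (TypeError, ValueError):
                raise TableSchemaError(
                    f"{path}: row {i + 2}, column {col!r}: cannot parse "
                    f"{raw!r} as {typ.__name__}"
                ) from None
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if typ is int:
            df[col] = df[col].astype("Int64")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_state_tables(path: str | Path) -> list[respirometry.SuitStateTable]:
    """Long-format states TSV -> one SuitStateTable per sample."""
    df = read_table(path, "states")
    tables = []
    for (sample, tissue), grp in df.groupby(["sample_id", "tissue"], sort=True):
        flux = dict(zip(grp["state"], grp["flux"].astype(float)))
        mass = None
        if "wet_mass_mg" in grp.columns and grp["wet_mass_mg"].notna().any():
            mass = float(pd.to_numeric(grp["wet_mass_mg"]).iloc[0])
        tables.append(
            respirometry.SuitStateTable(
                sample_id=str(sample), tissue=str(tissue), flux=flux,
                wet_mass_mg=mass,
            )
        )
    return tables


def write_state_tables(
    tables: Sequence[respirometry.SuitStateTable], path: str | Path
) -> None:
    rows = []
    for t in tables:
        for state, v in t.flux.items():
            rows.append(
                {"sample_id": t.sample_id, "tissue": t.tissue, "state": state,
                 "flux": v, "wet_mass_mg": t.wet_mass_mg}
            )
    write_table(pd.DataFrame(rows), path)


def read_heteroplasmy_calls(path: str | Path) -> list[heteroplasmy.HeteroplasmyCall]:
    df = read_table(path, "hp_calls")
    calls = []
    for i, row in df.iterrows():
        try:
            calls.append(
                heteroplasmy.HeteroplasmyCall(
                    patient_id=str(row["patient_id"]),
                    sample_id=str(row["sample_id"]),
                    tissue=str(row["tissue"]),
                    run_id=str(row["run_id"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    vaf=float(row["vaf"]),
                    fwd_cov=int(row["fwd_cov"]),
                    rev_cov=int(row["rev_cov"]),
                    fwd_alt=int(row["fwd_alt"]),
                    rev_alt=int(row["rev_alt"]),
                    mutpred=float(row["mutpred"])
                    if "mutpred" in df.columns and pd.notna(row["mutpred"])
                    else None,
                )
            )
        except ValueError as exc:
            raise TableSchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return calls


def read_heteroplasmy_vcf(
    path: str | Path,
    patient_id: str,
    tissue: str,
    run_id: str,
) -> list[heteroplasmy.HeteroplasmyCall]:
    """Minimal single-sample VCF reader for heteroplasmy calls.

    Expects SNV records against the rCRS contig with the allele fraction in
    the ``AF`` INFO field and per-strand counts in an ``SB``-style tag
    (ref-fwd, ref-rev, alt-fwd, alt-rev); ``DP4`` is accepted as a synonym.
    Multi-allelic records yield one call per alternate allele (AF split
    positionally).  Requires pysam (``pip install oxshift[vcf]``).
    """
    import pysam

    sample_id = f"{patient_id}_{'BE' if tissue == 'benign' else 'CA'}"
    calls: list[heteroplasmy.HeteroplasmyCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            af = rec.info["AF"] if "AF" in rec.info else None
            if af is None:
                raise TableSchemaError(f"{path}: record at {rec.pos} lacks AF")
            afs = af if isinstance(af, (tuple, list)) else (af,)
            sb = next(
                (rec.info[k] for k in ("SB", "DP4") if k in rec.info), None
            )
            if sb is None or len(sb) != 4:
                raise TableSchemaError(
                    f"{path}: record at {rec.pos} lacks SB/DP4 strand counts"
                )
            ref_f, ref_r, alt_f, alt_r = (int(x) for x in sb)
            for alt, vaf in zip(rec.alts, afs):
                if len(rec.ref) != 1 or len(alt) != 1:
                    raise TableSchemaError(
                        f"{path}: indel at {rec.pos} not supported"
                    )
                calls.append(
                    heteroplasmy.HeteroplasmyCall(
                        patient_id=patient_id,
                        sample_id=sample_id,
                        tissue=tissue,
                        run_id=run_id,
                        pos=int(rec.pos),
                        ref=rec.ref,
                        alt=alt,
                        vaf=float(vaf),
                        fwd_cov=ref_f + alt_f,
                        rev_cov=ref_r + alt_r,
                        fwd_alt=alt_f,
                        rev_alt=alt_r,
                    )
                )
    return calls


def read_qpcr_table(
    path: str | Path, config: PipelineConfig
) -> list[copynumber.QpcrMeasurement]:
    df = read_table(path, "qpcr")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                copynumber.QpcrMeasurement(
                    sample_id=str(row["sample_id"]),
                    cq_mt=float(row["cq_mt"]),
                    cq_n=float(row["cq_n"]),
                    plasmid_cq_mt=config.plasmid_cq_mt,
                    plasmid_cq_n=config.plasmid_cq_n,
                    efficiency_base=config.qpcr_efficiency_base,
                )
            )
        except ValueError as exc:
            raise TableSchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id, "sample_id": r.sample_id,
                "tissue": r.tissue, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "hp_level": r.hp_level,
                "genes": ";".join(r.genes) or MISSING,
                "synonymy": r.synonymy or MISSING,
                "protein_change": ";".join(
                    c.protein_change for c in r.consequences if c.protein_change
                ) or MISSING,
                "privacy": r.privacy or MISSING,
                "deleterious": r.deleterious,
                "homoplasmic": r.is_homoplasmic,
                "mutpred": r.mutpred if r.mutpred is not None else MISSING,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    states_path: str | Path,
    hp_calls_path: str | Path,
    qpcr_path: Optional[str | Path],
    out_dir: str | Path,
) -> dict:
    """Run all stages in dependency order and emit a JSON + HTML report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.content_hash(),
                    "config": asdict(config)}

    # respirometry
    tables = [respirometry.rox_correct(t) if "ROX" in t.flux else t
              for t in read_state_tables(states_path)]
    fcr = {}
    for t in tables:
        try:
            fcr[t.sample_id] = respirometry.flux_control_ratios(t)
        except (ValueError, respirometry.ProtocolError):
            pass
    effects = {t.sample_id: respirometry.substrate_effects(t) for t in tables}
    report["n_samples_respirometry"] = len(tables)
    write_state_tables(tables, out / "states_rox_corrected.tsv")

    # heteroplasmy
    model = mtgenome.load_gene_model()
    calls = read_heteroplasmy_calls(hp_calls_path)
    records, merge_report = heteroplasmy.merge_runs(calls)
    records, rejections = heteroplasmy.filter_calls(
        records,
        min_vaf=config.min_vaf,
        min_strand_cov=config.min_strand_cov,
        strand_tolerance=config.strand_tolerance,
        homoplasmy_cut=config.homoplasmy_cut,
    )
    records = heteroplasmy.classify_private_shared(records)
    records = heteroplasmy.classify_consequence(records, model)
    records = heteroplasmy.flag_deleterious(records)
    burden = heteroplasmy.burden_and_strata(records)
    write_table(records_to_frame(records), out / "heteroplasmies.tsv")
    write_table(burden, out / "hp_burden.tsv")
    report["heteroplasmy"] = {
        "n_records": len(records),
        "n_rejected": len(rejections),
        "privacy_counts": records_to_frame(records)["privacy"]
        .value_counts().to_dict() if records else {},
        **merge_report,
    }

    # copy number
    if qpcr_path is not None:
        measurements = read_qpcr_table(qpcr_path, config)
        cn = pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in measurements],
                "mt_cn": [copynumber.mt_copy_number(m) for m in measurements],
            }
        )
        write_table(cn, out / "copy_number.tsv")
        report["copy_number"] = {
            "n": len(cn),
            "median_cn": float(cn["mt_cn"].median()),
        }

    # phenotype labels from relative GM capacity
    labels = []
    for sid, ratios in fcr.items():
        if "GM_P" in ratios:
            labels.append(
                signature.classify_phenotype(sid, max(ratios["GM_P"], 0.0),
                                             config.gm_threshold)
            )
    write_table(
        pd.DataFrame(
            [{"sample_id": l.sample_id, "gm_fcr": l.gm_fcr, "label": l.label}
             for l in labels]
        ),
        out / "phenotype_labels.tsv",
    )
    report["phenotype"] = {
        "n_severe": sum(1 for l in labels if l.label == "severe"),
        "n_mild": sum(1 for l in labels if l.label == "mild"),
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "report.html").write_text(_html_report(report))
    return report


def _html_report(report: dict) -> str:
    body = json.dumps(report, indent=2, default=str)
    return (
        "<html><head><title>oxshift report</title></head><body>"
        f"<h1>oxshift pipeline report</h1><pre>{body}</pre></body></html>"
    )
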